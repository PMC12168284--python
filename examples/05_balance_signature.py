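"""Sparse zero-sum log-contrast (balance) signature of a continuous outcome.

The outcome is generated as log(x_A / x_B) + noise, so the fitted signature
should select exactly taxon A (positive side) and taxon B (negative side).
"""

import numpy as np
import pandas as pd

import plaquestab as ps

rng = np.random.default_rng(8)
n, p = 200, 30
latent = rng.normal(0, 1.5, p) + rng.normal(0, 1.0, (n, p))
probs = np.exp(latent)
probs /= probs.sum(1, keepdims=True)
counts = np.vstack([rng.multinomial(20000, pr) for pr in probs])
table = ps.FeatureTable(pd.DataFrame(
    counts, index=[f"s{i:03d}" for i in range(n)],
    columns=[f"taxon_{j:02d}" for j in range(p)],
))
outcome = pd.Series(latent[:, 0] - latent[:, 1] + rng.normal(0, 0.5, n),
                    index=table.sample_ids)

signature = ps.fit_balance_signature(table, outcome, mode="continuous", seed=9)
print("positive side:", signature.positive_taxa())
print("negative side:", signature.negative_taxa())
print(f"coefficient sum: {signature.coefficients.sum():+.1e} (zero-sum constraint)")
print(f"cross-validated R = {signature.cv_metric:.2f}, "
      f"apparent R = {signature.apparent_metric:.2f}")

prediction = ps.predict_balance(signature, table, outcome)
print(f"training correlation check: R = {prediction.pearson_r:.2f}, "
      f"p = {prediction.p_value:.1e}")
# The balance score is a log contrast of the selected taxa: scale-invariant,
# so it depends only on relative abundances, never on sequencing depth.
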