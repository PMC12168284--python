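"""*S. mutans* phase dynamics: labeling, classification, attribution.

Caries progression is marked by a rise and collapse of *Streptococcus
mutans* on a tooth. Teeth sampled at multiple visits are labeled relative
to a "during" visit where the *S. mutans* relative abundance is high
(≥ 10%): low-abundance visits (≤ 5%) preceding it are "before", those
following it are "after"; proportions strictly between the thresholds stay
unlabeled. A random forest then asks whether the surrounding community
predicts the phase, and Monte-Carlo Shapley values attribute its
predictions to individual taxa.

The target taxon itself is excluded from the classifier features — the
labels are defined by it, so including it would leak them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .composition import DEFAULT_PSEUDOCOUNT, clr_transform
from .tables import FeatureTable, SampleMetadata

TARGET_TAXON = "Streptococcus mutans"
_EPS = 1e-12


@dataclass(frozen=True)
class MutansPhaseLabel:
    sample_id: str
    phase: str  # before | during | after
    subject_id: str
    fdi_code: int
    visit: int
    anchor_visit: int  # the first >= high-threshold visit on this tooth
    proportion: float


def label_mutans_phases(
    table: FeatureTable,
    meta: SampleMetadata,
    target_taxon: str = TARGET_TAXON,
    low: float = 0.05,
    high: float = 0.10,
) -> pd.DataFrame:
    """Phase labels for every tooth timeline containing a high-target visit.

    Boundary behavior is inclusive on both thresholds: exactly ``high`` is
    "during", exactly ``low`` is an eligible low. Teeth with several during
    visits anchor before/after to the first one; later lows count as after.
    """
    if target_taxon not in table.taxon_ids:
        raise ValueError(f"target taxon {target_taxon!r} absent from table")
    totals = table.data.sum(axis=1).replace(0, 1)
    prop = table.data[target_taxon] / totals
    md = meta.data.loc[[s for s in table.sample_ids if s in meta.data.index]]

    labels: list[MutansPhaseLabel] = []
    for (subject, fdi), grp in md.groupby(["subject_id", "fdi_code"], sort=True):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("visit")
        props = prop.loc[grp.index]
        during_mask = props >= high - _EPS
        if not during_mask.any():
            continue
        anchor_visit = int(grp.loc[during_mask.idxmax(), "visit"])
        for sid, row in grp.iterrows():
            p = float(props.loc[sid])
            v = int(row["visit"])
            if p >= high - _EPS:
                phase = "during"
            elif p <= low + _EPS:
                phase = "before" if v < anchor_visit else "after"
                if v == anchor_visit:  # cannot happen: p can't be both
                    continue
            else:
                continue  # gap zone: unlabeled
            labels.append(
                MutansPhaseLabel(sid, phase, subject, int(fdi), v, anchor_visit, p)
            )
    return pd.DataFrame([l.__dict__ for l in labels])


def _subject_folds(subjects: np.ndarray, n_folds: int) -> np.ndarray:
    uniq = sorted(set(subjects))
    fold_of = {s: i % n_folds for i, s in enumerate(uniq)}
    return np.array([fold_of[s] for s in subjects])


def rf_classify_phases(
    table: FeatureTable,
    labels: pd.DataFrame,
    n_trees: int = 500,
    seed: int | None = None,
    cv_by_subject: bool = True,
    n_folds: int = 5,
    min_class_size: int = 5,
    target_taxon: str = TARGET_TAXON,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict:
    """Random-forest phase classification with subject-grouped CV.

    Features are CLR coordinates of the table with the target taxon removed.
    Classes with fewer than ``min_class_size`` samples are dropped with a
    warning. Returns the out-of-fold confusion matrix, per-class recall
    (the fraction of each phase classified correctly), the final model fit
    on all data, and the feature frame.
    """
    if labels.empty:
        raise ValueError("no phase labels")
    counts = labels["phase"].value_counts()
    keep_classes = counts.index[counts >= min_class_size].tolist()
    dropped = counts.index[counts < min_class_size].tolist()
    if dropped:
        warnings.warn(f"dropping classes with <{min_class_size} samples: {dropped}")
    if len(keep_classes) < 2:
        raise ValueError("need at least 2 classes with enough samples")
    lab = labels[labels["phase"].isin(keep_classes)].set_index("sample_id")

    feats_table = table.select_samples(lab.index).select_taxa(
        [t for t in table.taxon_ids if t != target_taxon]
    )
    x = clr_transform(feats_table, pseudocount).data
    y = lab["phase"].to_numpy()
    subjects = (
        lab["subject_id"].to_numpy() if cv_by_subject else np.asarray(lab.index)
    )
    folds = _subject_folds(subjects, n_folds)

    rng = np.random.default_rng(seed)
    classes = sorted(keep_classes)
    oof = pd.Series(index=lab.index, dtype=object)
    for f in sorted(set(folds)):
        tr, va = folds != f, folds == f
        if va.sum() == 0 or len(np.unique(y[tr])) < 2:
            continue
        clf = RandomForestClassifier(
            n_estimators=n_trees,
            max_features="sqrt",
            class_weight="balanced",
            random_state=int(rng.integers(2**31 - 1)),
        )
        clf.fit(x.to_numpy()[tr], y[tr])
        oof.iloc[np.flatnonzero(va)] = clf.predict(x.to_numpy()[va])

    valid = oof.notna()
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    for true, predicted in zip(y[valid.to_numpy()], oof[valid]):
        if predicted in confusion.columns:
            confusion.loc[true, predicted] += 1
    recall = pd.Series(
        {c: confusion.loc[c, c] / max(confusion.loc[c].sum(), 1) for c in classes},
        name="recall",
    )

    final = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        class_weight="balanced",
        random_state=int(rng.integers(2**31 - 1)),
    )
    final.fit(x.to_numpy(), y)
    return {
        "confusion": confusion,
        "recall": recall,
        "model": final,
        "features": x,
        "classes": classes,
        "folds": pd.Series(folds, index=lab.index, name="fold"),
    }


def shapley_attribution(
    model,
    features: pd.DataFrame,
    focal_class,
    background: pd.DataFrame | None = None,
    n_mc_samples: int = 50,
    seed: int | None = None,
    max_background: int = 100,
) -> pd.DataFrame:
    """Monte-Carlo Shapley attribution of class probability to features.

    For each sample, features are switched from a random background row to
    the sample's values in random order; each feature is credited with the
    change in the model's focal-class probability when it switches. Positive
    values push the prediction toward the focal class. Per sample, the
    attributions sum (within Monte-Carlo error) to the sample's score minus
    the background mean score — the telescoping construction makes this
    exact for the drawn backgrounds.
    """
    if n_mc_samples < 10:
        raise ValueError("n_mc_samples must be at least 10")
    rng = np.random.default_rng(seed)
    if background is None:
        background = features.iloc[:max_background]
    bg = background.to_numpy(dtype=float)
    x_all = features.to_numpy(dtype=float)
    n, p = x_all.shape
    class_idx = list(model.classes_).index(focal_class)

    attributions = np.zeros((n, p))
    for i in range(n):
        x = x_all[i]
        rows = np.empty((n_mc_samples * (p + 1), p))
        orders = np.empty((n_mc_samples, p), dtype=int)
        for m in range(n_mc_samples):
            z = bg[rng.integers(len(bg))]
            order = rng.permutation(p)
            orders[m] = order
            current = z.copy()
            base = m * (p + 1)
            rows[base] = current
            for step, j in enumerate(order, start=1):
                current = current.copy()
                current[j] = x[j]
                rows[base + step] = current
        probs = model.predict_proba(rows)[:, class_idx]
        for m in range(n_mc_samples):
            base = m * (p + 1)
            diffs = np.diff(probs[base : base + p + 1])
            attributions[i, orders[m]] += diffs
    attributions /= n_mc_samples
    return pd.DataFrame(attributions, index=features.index, columns=features.columns)
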