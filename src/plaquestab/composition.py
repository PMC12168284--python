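"""Compositional statistics: CLR geometry, diversity, PERMANOVA, effect sizes.

All multivariate analyses in this package run in the Aitchison geometry:
counts are shifted by a pseudocount, centered-log-ratio (CLR) transformed,
and compared by Euclidean distance. The pseudocount default (0.5 added to
every count) and the natural-log convention are fixed package-wide because
zero handling materially affects the geometry; both are configurable.

PERMANOVA follows Anderson's partition of squared distances with a
permutation p-value using the "+1, at least as extreme" convention, and an
exhaustive-enumeration mode for small designs. The subsampled PERMANOVA
procedure balances a two-level factor (e.g. anterior vs posterior teeth) by
repeatedly downsampling the majority level, testing within each stratum,
FDR-adjusting across strata per round, and averaging adjusted p-values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import comb
from scipy.stats import kruskal, mannwhitneyu, pearsonr
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class ClrMatrix:
    """CLR coordinates: sample × taxon real matrix; every row sums to 0."""

    data: pd.DataFrame
    pseudocount: float

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix has a nonzero diagonal")
        self.values = v
        self._index = {s: i for i, s in enumerate(self.ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, ids) -> "DistanceMatrix":
        idx = [self._index[s] for s in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )


@dataclass
class PermanovaResult:
    pseudo_F: float
    R2: float
    p: float
    n_perm: int
    seed: int | None = None
    method: str = "permutation"


@dataclass
class EffectSize:
    cohens_d: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------


def clr_transform(
    table: FeatureTable | pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ClrMatrix:
    """Centered log-ratio transform of a count table.

    ``clr(x)_j = log(x_j + pc) − mean_k log(x_k + pc)`` with natural log.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    df = table.data if isinstance(table, FeatureTable) else table
    logged = np.log(df.to_numpy(dtype=float) + pseudocount)
    clr = logged - logged.mean(axis=1, keepdims=True)
    return ClrMatrix(
        pd.DataFrame(clr, index=df.index, columns=df.columns), pseudocount
    )


def aitchison_distance(clr: ClrMatrix) -> DistanceMatrix:
    """Pairwise Euclidean distance between CLR rows."""
    return DistanceMatrix(clr.sample_ids, squareform(pdist(clr.values, "euclidean")))


def alpha_diversity(table: FeatureTable, metric: str = "shannon") -> pd.Series:
    """Per-sample alpha diversity.

    ``observed`` counts taxa with nonzero reads; ``shannon`` is −Σ p ln p over
    nonzero proportions (natural log). All-zero samples score 0 (warned).
    """
    counts = table.counts.astype(float)
    if (counts.sum(axis=1) == 0).any():
        warnings.warn("all-zero sample(s): diversity reported as 0", stacklevel=2)
    if metric == "observed":
        vals = (counts > 0).sum(axis=1).astype(float)
    elif metric == "shannon":
        totals = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0.0)
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        vals = -plogp.sum(axis=1)
    else:
        raise ValueError(f"unknown metric {metric!r}; use 'observed' or 'shannon'")
    return pd.Series(vals, index=table.sample_ids, name=metric)


# -- PERMANOVA --------------------------------------------------------------


def _permanova_ss(d2: np.ndarray, labels: np.ndarray, uniq: np.ndarray):
    """SS_total and SS_within from squared distances (Anderson partition)."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in uniq:
        mask = labels == g
        ng = int(mask.sum())
        sub = d2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, 1)].sum() / ng
    return ss_total, ss_within


def _pseudo_f(d2, labels, uniq, n, k):
    ss_t, ss_w = _permanova_ss(d2, labels, uniq)
    ss_b = ss_t - ss_w
    if ss_w <= 0:
        return np.inf, 1.0
    f = (ss_b / (k - 1)) / (ss_w / (n - k))
    return f, ss_b / ss_t


def permanova(
    dist: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
    exhaustive: bool = False,
    units=None,
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    ``grouping`` maps each sample id to a group label (dict/Series aligned on
    ids, or a sequence in matrix order). The permutation p-value is
    ``(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)``; with ``exhaustive=True`` all
    distinct label assignments are enumerated and ``p = #{F ≥ F_obs}/N``
    (the identity assignment included).

    ``units`` (optional, aligned like ``grouping``) declares repeated-
    measures blocks: samples of one unit (e.g. the same tooth across visits)
    always carry the same group label, and permutation shuffles labels
    across units rather than samples, preserving exchangeability.
    """
    labels = _align(grouping, dist.ids)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    if counts.min() < 2:
        small = uniq[counts < 2].tolist()
        raise ValueError(f"singleton group(s) not permitted: {small}")
    n, k = len(labels), len(uniq)
    d2 = dist.values**2
    f_obs, r2 = _pseudo_f(d2, labels, uniq, n, k)

    if units is not None:
        unit_arr = _align(units, dist.ids)
        uniq_units, unit_first = np.unique(unit_arr, return_index=True)
        unit_labels = labels[unit_first]
        for u, ul in zip(uniq_units, unit_labels):
            if not (labels[unit_arr == u] == ul).all():
                raise ValueError(f"unit {u!r} mixes group labels")
        sample_of_unit = {u: np.flatnonzero(unit_arr == u) for u in uniq_units}

        def expand(perm_unit_labels):
            out = np.empty(n, dtype=labels.dtype)
            for u, ul in zip(uniq_units, perm_unit_labels):
                out[sample_of_unit[u]] = ul
            return out

        if exhaustive:
            total = ge = 0
            for perm in _distinct_assignments(unit_labels):
                f_perm, _ = _pseudo_f(d2, expand(perm), uniq, n, k)
                total += 1
                if f_perm >= f_obs - 1e-12:
                    ge += 1
            return PermanovaResult(f_obs, r2, ge / total, total, seed, "exhaustive")
        rng = np.random.default_rng(seed)
        ge = 0
        for _ in range(n_perm):
            f_perm, _ = _pseudo_f(d2, expand(rng.permutation(unit_labels)), uniq, n, k)
            if f_perm >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(f_obs, r2, (1 + ge) / (1 + n_perm), n_perm, seed)

    if exhaustive:
        total = 0
        ge = 0
        for perm in _distinct_assignments(labels):
            f_perm, _ = _pseudo_f(d2, perm, uniq, n, k)
            total += 1
            if f_perm >= f_obs - 1e-12:
                ge += 1
        return PermanovaResult(f_obs, r2, ge / total, total, seed, "exhaustive")

    rng = np.random.default_rng(seed)
    ge = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(labels), uniq, n, k)
        if f_perm >= f_obs - 1e-12:
            ge += 1
    p = (1 + ge) / (1 + n_perm)
    return PermanovaResult(f_obs, r2, p, n_perm, seed)


def _align(grouping, ids) -> np.ndarray:
    if isinstance(grouping, dict):
        return np.asarray([grouping[s] for s in ids])
    if isinstance(grouping, pd.Series):
        return grouping.loc[ids].to_numpy()
    arr = np.asarray(list(grouping))
    if len(arr) != len(ids):
        raise ValueError("grouping length does not match distance matrix")
    return arr


def _distinct_assignments(labels: np.ndarray):
    """Yield every distinct assignment of the label multiset to positions."""
    uniq, counts = np.unique(labels, return_counts=True)
    n = len(labels)
    n_total = 1
    rem = n
    for c in counts:
        n_total *= int(comb(rem, c, exact=True))
        rem -= c
    if n_total > 200_000:
        raise ValueError(f"exhaustive enumeration infeasible: {n_total} assignments")

    positions = list(range(n))

    def recurse(remaining, gi, current):
        if gi == len(uniq) - 1:
            out = current.copy()
            for pos in remaining:
                out[pos] = uniq[-1]
            yield out
            return
        for chosen in itertools.combinations(remaining, int(counts[gi])):
            nxt = current.copy()
            for pos in chosen:
                nxt[pos] = uniq[gi]
            rest = [p for p in remaining if p not in chosen]
            yield from recurse(rest, gi + 1, nxt)

    template = np.empty(n, dtype=labels.dtype)
    yield from recurse(positions, 0, template)


def subsampled_permanova(
    table: FeatureTable,
    meta,
    factor: str = "position",
    strata: str = "hiv_status",
    n_rounds: int = 100,
    n_perm: int = 199,
    seed: int | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Depth-balanced stratified PERMANOVA with FDR averaging.

    Units are teeth, not samples: every (subject, FDI code) tooth carries
    all of its visits together. Within each stratum (e.g. HIV group) the
    majority level of ``factor`` (e.g. posterior teeth) is subsampled
    without replacement to the minority's tooth count; a PERMANOVA on the
    Aitchison geometry — with labels permuted across teeth to respect the
    repeated-measures design — is run per stratum; the per-round p-values
    are Benjamini–Hochberg adjusted across strata; the adjusted p and R²
    are averaged over rounds. Returns one row per stratum with
    mean_adjusted_p, mean_R2 and the tooth subsample size used.
    """
    meta_df = meta.data if hasattr(meta, "data") else meta
    meta_df = meta_df.loc[[s for s in table.sample_ids if s in meta_df.index]]
    clr = clr_transform(table, pseudocount)
    dist = aitchison_distance(clr)
    unit = (
        meta_df["subject_id"].astype(str) + ":" + meta_df["fdi_code"].astype(str)
        if {"subject_id", "fdi_code"} <= set(meta_df.columns)
        else pd.Series(meta_df.index, index=meta_df.index)
    )

    strata_levels = sorted(meta_df[strata].unique())
    usable = []
    for s in strata_levels:
        sub = meta_df[meta_df[strata] == s]
        unit_level = (
            sub.assign(unit=unit.loc[sub.index])
            .groupby("unit")[factor]
            .agg(lambda x: x.iloc[0])
        )
        level_counts = unit_level.value_counts()
        if len(level_counts) < 2 or level_counts.min() < 2:
            warnings.warn(f"stratum {s!r}: a {factor} level is absent/singleton; skipped")
            continue
        levels = sorted(level_counts.index)
        # minority = smaller level; on ties the lexicographically first level
        minority = min(levels, key=lambda lv: (level_counts[lv], lv))
        majority = next(lv for lv in levels if lv != minority)
        usable.append(
            (
                s,
                unit_level.index[unit_level == minority].to_numpy(),
                unit_level.index[unit_level == majority].to_numpy(),
            )
        )
    if not usable:
        raise ValueError("no stratum has both factor levels")

    rng = np.random.default_rng(seed)
    rows = {s: {"p": [], "R2": []} for s, _, _ in usable}
    for _ in range(n_rounds):
        round_p = []
        round_r2 = []
        for s, minority_units, majority_units in usable:
            take = rng.choice(majority_units, size=len(minority_units), replace=False)
            units_used = set(minority_units) | set(take)
            ids = meta_df.index[unit.loc[meta_df.index].isin(units_used)].to_numpy()
            sub_dist = dist.submatrix(ids)
            res = permanova(
                sub_dist,
                meta_df.loc[ids, factor],
                n_perm=n_perm,
                seed=int(rng.integers(2**31 - 1)),
                units=unit.loc[ids],
            )
            round_p.append(res.p)
            round_r2.append(res.R2)
        adj = multipletests(round_p, method="fdr_bh")[1]
        for (s, _, _), pa, r2 in zip(usable, adj, round_r2):
            rows[s]["p"].append(pa)
            rows[s]["R2"].append(r2)

    out = pd.DataFrame(
        {
            "stratum": [s for s, _, _ in usable],
            "mean_adjusted_p": [float(np.mean(rows[s]["p"])) for s, _, _ in usable],
            "mean_R2": [float(np.mean(rows[s]["R2"])) for s, _, _ in usable],
            "subsample_size": [len(m) for _, m, _ in usable],
            "n_rounds": n_rounds,
        }
    ).set_index("stratum")
    return out


# -- univariate effect sizes and tests --------------------------------------


def cohens_d(x, y) -> EffectSize:
    """Pooled-SD Cohen's d for x vs y with a 95% normal-approximation CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least two observations per group")
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        raise ValueError("zero pooled variance: Cohen's d undefined")
    d = (x.mean() - y.mean()) / np.sqrt(sp2)
    se = np.sqrt((nx + ny) / (nx * ny) + d**2 / (2 * (nx + ny)))
    return EffectSize(float(d), float(d - 1.96 * se), float(d + 1.96 * se))


def group_test(values, labels) -> float:
    """Nonparametric location test across groups.

    Two groups → Wilcoxon rank-sum (Mann–Whitney U, two-sided); three or more
    → Kruskal–Wallis. Returns the p-value. The two-group test choice is a
    package default surfaced in reports.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    groups = [values[labels == g] for g in uniq]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("need at least two observations per group")
    if len(groups) == 2:
        return float(mannwhitneyu(groups[0], groups[1], alternative="two-sided").pvalue)
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        return 1.0  # all observations identical: no evidence of location shift
    return float(kruskal(*groups).pvalue)


def pearson_with_p(x, y) -> tuple[float, float]:
    r, p = pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)
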