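"""Taxonomic turnover on paired teeth.

Turnover is the Aitchison distance between two plaque samples taken from the
same tooth (matched by FDI code) of the same child at different visits: the
Euclidean norm of the difference of their CLR rows, computed in the common
geometry of the full filtered table. High turnover means the community on
that tooth changed a lot between visits.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist

from .composition import ClrMatrix, cohens_d, group_test
from .tables import SampleMetadata


@dataclass(frozen=True)
class PairedTooth:
    """One tooth observed at two visits — the unit of turnover analysis."""

    subject_id: str
    fdi_code: int
    visit_from: int
    visit_to: int
    sample_id_from: str
    sample_id_to: str
    interval_days: int
    health_from: str
    health_to: str


def match_paired_teeth(meta: SampleMetadata) -> list[PairedTooth]:
    """All (subject, FDI tooth) pairs observed at two or more visits.

    A tooth seen at visits 1, 2 and 3 yields the three pairs 1–2, 2–3 and
    1–3. Pairs that would bridge deciduous and permanent dentition are
    excluded. Duplicate samples for one (subject, tooth, visit) are an error.
    """
    md = meta.data
    dup = md.groupby(["subject_id", "fdi_code", "visit"]).size()
    dups = dup[dup > 1]
    if len(dups):
        raise ValueError(
            f"duplicate samples for (subject, tooth, visit): {dups.index.tolist()}"
        )
    pairs: list[PairedTooth] = []
    for (subject, fdi), grp in md.groupby(["subject_id", "fdi_code"], sort=True):
        grp = grp.sort_values("visit")
        for a, b in itertools.combinations(range(len(grp)), 2):
            ra, rb = grp.iloc[a], grp.iloc[b]
            if ra["dentition"] != rb["dentition"]:
                continue
            pairs.append(
                PairedTooth(
                    subject_id=subject,
                    fdi_code=int(fdi),
                    visit_from=int(ra["visit"]),
                    visit_to=int(rb["visit"]),
                    sample_id_from=grp.index[a],
                    sample_id_to=grp.index[b],
                    interval_days=int(rb["collection_day"] - ra["collection_day"]),
                    health_from=str(ra["tooth_health"]),
                    health_to=str(rb["tooth_health"]),
                )
            )
    return pairs


def _health_change(h_from: str, h_to: str) -> str:
    if h_from == "H" and h_to == "H":
        return "stable_healthy"
    if h_from in ("E", "D") and h_to in ("E", "D") and h_from == h_to:
        return "stable_diseased"
    if h_from in ("E", "D") and h_to in ("E", "D"):
        # stayed within the diseased categories (E or D)
        return "stable_diseased"
    return "changed"


def taxonomic_turnover(clr: ClrMatrix, pairs: list[PairedTooth]) -> pd.DataFrame:
    """Turnover records: one row per paired tooth.

    ``turnover`` is the Euclidean distance between the pair's CLR rows (the
    corresponding Aitchison distance-matrix entry). Pairs whose samples were
    filtered out of the table are dropped with a warning. ``health_change``
    follows the three categories: remained healthy, remained diseased
    (E or D), or changed.
    """
    present = set(clr.sample_ids)
    values = clr.data
    rows = []
    dropped = 0
    for p in pairs:
        if p.sample_id_from not in present or p.sample_id_to not in present:
            dropped += 1
            continue
        # same kernel as aitchison_distance so records match the distance
        # matrix bit for bit
        pair_rows = values.loc[[p.sample_id_from, p.sample_id_to]].to_numpy()
        rows.append(
            {
                "subject_id": p.subject_id,
                "fdi_code": p.fdi_code,
                "visit_from": p.visit_from,
                "visit_to": p.visit_to,
                "sample_id_from": p.sample_id_from,
                "sample_id_to": p.sample_id_to,
                "interval_days": p.interval_days,
                "health_from": p.health_from,
                "health_to": p.health_to,
                "health_change": _health_change(p.health_from, p.health_to),
                "turnover": float(pdist(pair_rows, "euclidean")[0]),
            }
        )
    if dropped:
        warnings.warn(f"{dropped} pair(s) dropped: sample(s) absent from CLR matrix")
    return pd.DataFrame(rows)


def turnover_group_analysis(
    records: pd.DataFrame,
    meta: SampleMetadata,
    grouping: str = "hiv_status",
    healthy_only: bool = False,
) -> dict:
    """Group comparison of turnover.

    Returns a dict with ``summary`` (per-group, per-visit-pair mean/SD/n,
    plus pooled rows) and ``tests`` (pairwise group comparisons per visit
    pair and pooled: Wilcoxon rank-sum p, Cohen's d with 95% CI). With
    ``healthy_only`` the records are restricted to teeth healthy at both
    visits.
    """
    if records.empty:
        raise ValueError("no turnover records")
    rec = records.copy()
    rec["group"] = meta.data.loc[rec["sample_id_from"], grouping].to_numpy()
    if healthy_only:
        rec = rec[(rec["health_from"] == "H") & (rec["health_to"] == "H")]
    rec["visit_pair"] = (
        rec["visit_from"].astype(str) + "-" + rec["visit_to"].astype(str)
    )

    summaries = []
    for vp in list(rec["visit_pair"].unique()) + ["pooled"]:
        sub = rec if vp == "pooled" else rec[rec["visit_pair"] == vp]
        for g, gg in sub.groupby("group"):
            summaries.append(
                {
                    "visit_pair": vp,
                    "group": g,
                    "n": len(gg),
                    "mean_turnover": float(gg["turnover"].mean()),
                    "sd_turnover": float(gg["turnover"].std(ddof=1)) if len(gg) > 1 else np.nan,
                }
            )
    summary = pd.DataFrame(summaries)

    tests = []
    groups = sorted(rec["group"].unique())
    if len(groups) >= 2:
        for vp in list(rec["visit_pair"].unique()) + ["pooled"]:
            sub = rec if vp == "pooled" else rec[rec["visit_pair"] == vp]
            for ga, gb in itertools.combinations(groups, 2):
                xa = sub.loc[sub["group"] == ga, "turnover"].to_numpy()
                xb = sub.loc[sub["group"] == gb, "turnover"].to_numpy()
                if len(xa) < 2 or len(xb) < 2:
                    warnings.warn(f"empty/singleton cell {ga} vs {gb} at {vp}")
                    tests.append(
                        {"visit_pair": vp, "group_a": ga, "group_b": gb,
                         "p": np.nan, "cohens_d": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "test": "wilcoxon_rank_sum"}
                    )
                    continue
                p = group_test(
                    np.concatenate([xa, xb]),
                    np.array([ga] * len(xa) + [gb] * len(xb)),
                )
                try:
                    es = cohens_d(xa, xb)
                    d, lo, hi = es.cohens_d, es.ci_low, es.ci_high
                except ValueError:
                    d = lo = hi = np.nan
                tests.append(
                    {"visit_pair": vp, "group_a": ga, "group_b": gb, "p": p,
                     "cohens_d": d, "ci_low": lo, "ci_high": hi,
                     "test": "wilcoxon_rank_sum"}
                )
    return {"summary": summary, "tests": pd.DataFrame(tests)}
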