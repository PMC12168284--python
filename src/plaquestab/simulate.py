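"""Synthetic longitudinal plaque cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so every stage is testable without real sequencing data:

* three clinical visits per child, three HIV-status groups (HI, HEU, HUU);
* per-tooth latent log-abundance vectors with planted co-occurring taxon
  blocks (logistic-normal counts: multinomial over a softmax of the latent);
* between-visit drift as a Gaussian random walk whose step SD differs by
  group — the "taxonomic turnover" signal;
* a fixed anterior-composition offset whose strength is a per-group
  multiplier — the "spatial differentiation" signal, attenuated in one group;
* cariogenic taxa boosted on diseased teeth, with drift damped on those
  teeth (cariogenic load anti-correlates with turnover) and a CD4-like
  covariate linearly linked to the cariogenic balance;
* lognormal sequencing depth and structural zeros.

Everything is driven by one integer seed; identical seeds produce
byte-identical tables. Structural zeros are applied by masking after the
multinomial draw and the zeroed mass is NOT redistributed, so per-sample
totals may shrink below the drawn depth (totals == depth when
``zero_inflation = 0``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import RANKS, FeatureTable, SampleMetadata, TaxonomyMap

ANTERIOR_FDI = (11, 12, 13, 21, 22, 23, 31, 32, 33, 41, 42, 43)
POSTERIOR_FDI = (14, 15, 16, 17, 24, 25, 26, 27, 34, 35, 36, 37, 44, 45, 46, 47)

CARIOGENIC_SPECIES = (
    "Streptococcus mutans",
    "Scardovia wiggsiae",
    "Prevotella multisaccharivorax",
    "Prevotella denticola",
    "Propionibacterium acidifaciens",
)

_GENUS_POOL = (
    "Streptococcus", "Prevotella", "Leptotrichia", "Capnocytophaga", "Neisseria",
    "Actinomyces", "Corynebacterium", "Fusobacterium", "Porphyromonas", "Rothia",
    "Veillonella", "Haemophilus", "Selenomonas", "Campylobacter", "Gemella",
    "Granulicatella", "Abiotrophia", "Treponema", "Lachnoanaerobaculum", "Kingella",
)


class InvalidConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults are the package's study
    conditions (see docs/methods.md for the rationale behind each value)."""

    n_subjects_per_group: int = 25
    groups: tuple[str, ...] = ("HI", "HEU", "HUU")
    n_visits: int = 3
    n_taxa: int = 75
    n_blocks: int = 3
    block_size: int = 8
    block_corr: float = 0.6
    drift_sd_per_group: dict = field(
        default_factory=lambda: {"HI": 0.4, "HEU": 0.4, "HUU": 1.0}
    )
    spatial_effect_per_group: dict = field(
        default_factory=lambda: {"HI": 0.0, "HEU": 1.0, "HUU": 1.0}
    )
    cariogenic_taxa: tuple[int, ...] = (0, 1, 2, 3, 4)
    caries_effect: float = 2.0
    drift_caries_coupling: float = 0.5
    cd4_model: tuple[float, float, float] = (800.0, -150.0, 150.0)  # a, b, noise SD
    depth_lognormal: tuple[float, float] = (10.0, 0.4)  # meanlog, sdlog
    zero_inflation: float = 0.02
    n_anterior_teeth: int = 2
    n_posterior_teeth: int = 2
    baseline_sd: float = 1.5
    subject_sd: float = 0.3
    latent_sd: float = 1.0
    spatial_offset_frac: float = 0.2
    spatial_offset_scale: float = 1.0
    health_probs: tuple[float, float, float] = (0.7, 0.15, 0.15)  # H, E, D
    health_change_prob: float = 0.15
    frac_unassigned: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa <= 0 or self.n_subjects_per_group <= 0:
            raise InvalidConfigError("n_taxa and n_subjects_per_group must be positive")
        if self.n_visits < 1:
            raise InvalidConfigError("n_visits must be >= 1")
        if len(set(self.groups)) != len(self.groups):
            raise InvalidConfigError("group labels must be distinct")
        if not 0 <= self.block_corr < 1:
            raise InvalidConfigError("block_corr must be in [0, 1)")
        for g in self.groups:
            if g not in self.drift_sd_per_group:
                raise InvalidConfigError(f"no drift SD for group {g!r}")
            if self.drift_sd_per_group[g] < 0:
                raise InvalidConfigError("drift SDs must be >= 0")
        if any(t < 0 or t >= self.n_taxa for t in self.cariogenic_taxa):
            raise InvalidConfigError("cariogenic_taxa indices out of range")
        if not 0 <= self.zero_inflation <= 1:
            raise InvalidConfigError("zero_inflation must be a probability")
        if self.n_blocks * self.block_size > self.n_taxa:
            raise InvalidConfigError("blocks do not fit into n_taxa")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    latent: pd.DataFrame  # sample × taxon latent log-abundance
    block_membership: np.ndarray  # per-taxon block id, -1 = background
    sigma_per_group: dict
    spatial_offset: np.ndarray
    signature_taxa: dict  # taxon index -> planted sign (+1/-1)
    cd4_latent: pd.DataFrame  # subject, visit, cariogenic_balance, cd4
    depths: pd.Series  # drawn depth per sample (pre zero-inflation)
    config: SimulationConfig


def _build_taxonomy(cfg: SimulationConfig, rng: np.random.Generator) -> TaxonomyMap:
    n = cfg.n_taxa
    n_unassigned = int(round(cfg.frac_unassigned * n))
    rows = []
    for i in range(n):
        tid = f"ASV{i + 1:04d}"
        if i >= n - n_unassigned:
            rows.append({"taxon_id": tid, "kingdom": "Bacteria",
                         **{r: "" for r in RANKS[1:]}})
            continue
        if i < len(cfg.cariogenic_taxa) and i < len(CARIOGENIC_SPECIES):
            species = CARIOGENIC_SPECIES[i]
            genus = species.split()[0]
        else:
            genus = _GENUS_POOL[i % len(_GENUS_POOL)]
            species = f"{genus} taxon {i + 1:03d}"
        rows.append(
            {
                "taxon_id": tid,
                "kingdom": "Bacteria",
                "phylum": f"Phylum{(i % 5) + 1}",
                "class": f"Class{(i % 7) + 1}",
                "order": f"Order{(i % 9) + 1}",
                "family": f"{genus}aceae",
                "genus": genus,
                "species": species,
            }
        )
    df = pd.DataFrame(rows).set_index("taxon_id")
    return TaxonomyMap(df)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[FeatureTable, SampleMetadata, TaxonomyMap, GroundTruth]:
    """Generate one cohort: counts, metadata, taxonomy and ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_taxa = cfg.n_taxa

    block_membership = np.full(n_taxa, -1, dtype=int)
    cursor = len(cfg.cariogenic_taxa)  # cariogenic taxa stay background
    for b in range(cfg.n_blocks):
        block_membership[cursor : cursor + cfg.block_size] = b
        cursor += cfg.block_size

    baseline = rng.normal(0.0, cfg.baseline_sd, n_taxa)
    # anterior-offset vector: sparse, fixed for the cohort
    n_offset = max(4, int(round(cfg.spatial_offset_frac * n_taxa)))
    offset_candidates = np.array(
        [i for i in range(n_taxa) if i not in set(cfg.cariogenic_taxa)]
    )
    offset_idx = rng.choice(offset_candidates, size=n_offset, replace=False)
    spatial_offset = np.zeros(n_taxa)
    spatial_offset[offset_idx] = rng.normal(0.0, cfg.spatial_offset_scale, n_offset)

    taxonomy = _build_taxonomy(cfg, rng)

    health_levels = np.array(["H", "E", "D"])
    cario = np.array(sorted(cfg.cariogenic_taxa), dtype=int)
    non_cario = np.array([i for i in range(n_taxa) if i not in set(cario)])
    a_cd4, b_cd4, cd4_noise = cfg.cd4_model

    sample_rows = []
    latents = []
    cd4_rows = []
    sample_ids = []

    for g in cfg.groups:
        sigma_g = cfg.drift_sd_per_group[g]
        spatial_g = cfg.spatial_effect_per_group.get(g, 0.0)
        for si in range(cfg.n_subjects_per_group):
            subject = f"{g}{si + 1:03d}"
            sex = "F" if rng.random() < 0.5 else "M"
            age0 = float(rng.uniform(4.0, 10.0))
            day2 = max(30, int(round(rng.normal(182, 28))))
            day3 = day2 + max(30, int(round(rng.normal(219, 51))))
            days = [0, day2, day3][: cfg.n_visits] + [
                day3 + 200 * k for k in range(1, max(0, cfg.n_visits - 3) + 1)
            ]
            ant = rng.choice(ANTERIOR_FDI, size=cfg.n_anterior_teeth, replace=False)
            post = rng.choice(POSTERIOR_FDI, size=cfg.n_posterior_teeth, replace=False)
            teeth = [int(t) for t in ant] + [int(t) for t in post]
            subject_offset = rng.normal(0.0, cfg.subject_sd, n_taxa)

            # initial tooth health fixes the cariogenic boost and the drift
            # damping for the whole timeline; later health labels may change
            # (observed clinically) without moving the latent state
            health0 = rng.choice(health_levels, size=len(teeth), p=cfg.health_probs)
            health_path = {}
            for ti, t in enumerate(teeth):
                hs = [health0[ti]]
                for _ in range(1, cfg.n_visits):
                    h = hs[-1]
                    if rng.random() < cfg.health_change_prob:
                        i = int(np.where(health_levels == h)[0][0])
                        step = 1 if (i == 0 or (i < 2 and rng.random() < 0.5)) else -1
                        h = health_levels[i + step]
                    hs.append(h)
                health_path[t] = hs

            tooth_latents = {}
            for ti, t in enumerate(teeth):
                u = rng.normal(0.0, 1.0, cfg.n_blocks)
                eps = rng.normal(0.0, 1.0, n_taxa)
                z = np.sqrt(1.0 - cfg.block_corr) * eps
                for b in range(cfg.n_blocks):
                    z[block_membership == b] += np.sqrt(cfg.block_corr) * u[b]
                lat = baseline + subject_offset + cfg.latent_sd * z
                if ti < cfg.n_anterior_teeth:
                    lat = lat + spatial_g * spatial_offset
                h0 = health0[ti]
                boost = cfg.caries_effect * (1.0 if h0 == "D" else 0.5 if h0 == "E" else 0.0)
                lat = lat.copy()
                lat[cario] += boost
                damp = 1.0 - (cfg.drift_caries_coupling if h0 in ("E", "D") else 0.0)
                sigma_t = sigma_g * damp
                path = [lat]
                for _ in range(1, cfg.n_visits):
                    path.append(path[-1] + rng.normal(0.0, sigma_t, n_taxa) if sigma_t > 0
                                else path[-1].copy())
                tooth_latents[t] = path

            for v in range(1, cfg.n_visits + 1):
                visit_lats = np.array([tooth_latents[t][v - 1] for t in teeth])
                balance = float(
                    visit_lats[:, cario].mean() - visit_lats[:, non_cario].mean()
                )
                cd4 = max(50.0, a_cd4 + b_cd4 * balance + rng.normal(0.0, cd4_noise))
                cd4_rows.append(
                    {"subject_id": subject, "visit": v,
                     "cariogenic_balance": balance, "cd4": round(cd4)}
                )
                healths = [health_path[t][v - 1] for t in teeth]
                mouth = "CD" if "D" in healths else "CE" if "E" in healths else "CF"
                for ti, t in enumerate(teeth):
                    th = health_path[t][v - 1]
                    # nesting: an E tooth forces the mouth to at least CE
                    mouth_t = mouth if not (th == "E" and mouth == "CF") else "CE"
                    sid = f"{subject}.V{v}.T{t}"
                    sample_ids.append(sid)
                    latents.append(tooth_latents[t][v - 1])
                    sample_rows.append(
                        {
                            "sample_id": sid,
                            "subject_id": subject,
                            "visit": v,
                            "hiv_status": g,
                            "fdi_code": t,
                            "dentition": "permanent",
                            "tooth_health": th,
                            "mouth_health": mouth_t,
                            "combined_health": f"{th}-{mouth_t}",
                            "position": "anterior" if ti < cfg.n_anterior_teeth else "posterior",
                            "jaw": "maxillary" if t // 10 in (1, 2) else "mandibular",
                            "sex": sex,
                            "age_years": round(age0 + days[v - 1] / 365.25, 2),
                            "cd4_count": round(cd4),
                            "collection_day": days[v - 1],
                        }
                    )

    latent = np.array(latents)
    meanlog, sdlog = cfg.depth_lognormal
    depths = np.round(rng.lognormal(meanlog, sdlog, len(sample_ids))).astype(np.int64)
    probs = np.exp(latent - latent.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    counts = np.empty((len(sample_ids), n_taxa), dtype=np.int64)
    for i in range(len(sample_ids)):
        counts[i] = rng.multinomial(depths[i], probs[i])
    if cfg.zero_inflation > 0:
        mask = rng.random(counts.shape) < cfg.zero_inflation
        counts[mask] = 0

    taxon_ids = list(taxonomy.taxon_ids)
    table = FeatureTable(pd.DataFrame(counts, index=sample_ids, columns=taxon_ids))
    meta = SampleMetadata(
        pd.DataFrame(sample_rows).set_index("sample_id"),
        visits=tuple(range(1, cfg.n_visits + 1)),
    )
    truth = GroundTruth(
        latent=pd.DataFrame(latent, index=sample_ids, columns=taxon_ids),
        block_membership=block_membership,
        sigma_per_group=dict(cfg.drift_sd_per_group),
        spatial_offset=spatial_offset,
        signature_taxa={int(i): -1 for i in cario},
        cd4_latent=pd.DataFrame(cd4_rows),
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        config=cfg,
    )
    return table, meta, taxonomy, truth


def simulate_null_cohort(
    config: SimulationConfig, sigma: float | None = None
) -> tuple[FeatureTable, SampleMetadata, TaxonomyMap, GroundTruth]:
    """As `simulate_cohort` but with every group-distinguishing effect
    equalized: one drift SD for all groups, no anterior-offset differential,
    no caries–drift coupling. Used for type-I-error calibration."""
    if sigma is None:
        sigma = float(np.mean([config.drift_sd_per_group[g] for g in config.groups]))
    null_cfg = replace(
        config,
        drift_sd_per_group={g: sigma for g in config.groups},
        spatial_effect_per_group={g: 0.0 for g in config.groups},
        drift_caries_coupling=0.0,
    )
    return simulate_cohort(null_cfg)


def latent_step_norms(truth: GroundTruth, meta: SampleMetadata) -> pd.DataFrame:
    """Euclidean norm of the latent drift for every paired tooth — the
    brute-force ground-truth counterpart of the observed turnover."""
    md = meta.data
    rows = []
    for (subject, fdi), grp in md.groupby(["subject_id", "fdi_code"]):
        visits = sorted(grp["visit"])
        for i in range(len(visits)):
            for j in range(i + 1, len(visits)):
                v1, v2 = visits[i], visits[j]
                s1 = grp.index[grp["visit"] == v1][0]
                s2 = grp.index[grp["visit"] == v2][0]
                step = np.linalg.norm(
                    truth.latent.loc[s2].to_numpy() - truth.latent.loc[s1].to_numpy()
                )
                rows.append(
                    {
                        "subject_id": subject,
                        "fdi_code": fdi,
                        "hiv_status": grp["hiv_status"].iloc[0],
                        "visit_from": v1,
                        "visit_to": v2,
                        "step_norm": float(step),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Gaussian graphical-model generator for network-inference validation


def simulate_ggm(
    n_nodes: int = 30,
    n_blocks: int = 3,
    n_samples: int = 300,
    partial_corr: float = 0.35,
    seed: int = 0,
    flip_edge: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, set[tuple[str, str]], np.ndarray]:
    """Draw samples from a sparse Gaussian graphical model with planted
    block structure (a chain within each block, nothing between blocks).

    Returns (data, support, precision): ``data`` is an n_samples × n_nodes
    frame with species-like column names, ``support`` the set of true edges
    as canonical name pairs. ``flip_edge`` negates one planted partial
    correlation (for sign-recovery checks).
    """
    if abs(partial_corr) >= 0.5:
        raise ValueError("|partial_corr| must be < 0.5 for a valid chain precision")
    rng = np.random.default_rng(seed)
    names = [f"species_{i + 1:03d}" for i in range(n_nodes)]
    precision = np.eye(n_nodes)
    per_block = n_nodes // n_blocks
    support = set()
    for b in range(n_blocks):
        lo = b * per_block
        hi = lo + per_block if b < n_blocks - 1 else n_nodes
        for i in range(lo, hi - 1):
            rho = -partial_corr
            if flip_edge is not None and (i, i + 1) == tuple(flip_edge):
                rho = partial_corr
            precision[i, i + 1] = precision[i + 1, i] = rho
            support.add((names[i], names[i + 1]))
    cov = np.linalg.inv(precision)
    x = rng.multivariate_normal(np.zeros(n_nodes), cov, size=n_samples)
    data = pd.DataFrame(x, columns=names,
                        index=[f"s{i + 1:04d}" for i in range(n_samples)])
    return data, support, precision


# ---------------------------------------------------------------------------
# Phase-dynamics generator (S. mutans rise-and-fall timelines)


def simulate_phase_cohort(
    n_teeth: int = 60,
    n_background: int = 40,
    marker_boost: float = 6.0,
    depth: int = 20000,
    seed: int = 0,
) -> tuple[FeatureTable, SampleMetadata, dict]:
    """Teeth whose *S. mutans* proportion traces low → high → low across
    three visits, with one taxon boosted only in the "before" community and
    another only in the "after" community.

    Ground truth (returned dict): the marker names, the target taxon name
    and the intended phase per sample.
    """
    rng = np.random.default_rng(seed)
    target = "Streptococcus mutans"
    before_marker = "Streptococcus sanguinis"
    after_marker = "Catonella morbi"
    backgrounds = [f"background_taxon_{i + 1:03d}" for i in range(n_background)]
    taxa = [target, before_marker, after_marker] + backgrounds
    base_weights = np.exp(rng.normal(0.0, 1.0, n_background))

    sm_targets = {"before": 0.02, "during": 0.15, "after": 0.03}
    rows, meta_rows, phases = [], [], {}
    groups = ("HI", "HEU", "HUU")
    fdi_pool = ANTERIOR_FDI + POSTERIOR_FDI
    for t in range(n_teeth):
        subject = f"P{t + 1:03d}"
        fdi = int(fdi_pool[t % len(fdi_pool)])
        for v, phase in enumerate(("before", "during", "after"), start=1):
            p_sm = sm_targets[phase] * float(rng.uniform(0.7, 1.2))
            p_sm = min(p_sm, 0.045) if phase != "during" else max(p_sm, 0.105)
            w = base_weights * np.exp(rng.normal(0.0, 0.4, n_background))
            w_markers = np.array(
                [
                    marker_boost if phase == "before" else 1.0,
                    marker_boost if phase == "after" else 1.0,
                ]
            ) * np.exp(rng.normal(0.0, 0.2, 2))
            rest = np.concatenate([w_markers, w])
            probs = np.concatenate([[p_sm], (1 - p_sm) * rest / rest.sum()])
            counts = rng.multinomial(depth, probs)
            sid = f"{subject}.V{v}.T{fdi}"
            rows.append(pd.Series(counts, index=taxa, name=sid))
            phases[sid] = phase
            meta_rows.append(
                {
                    "sample_id": sid,
                    "subject_id": subject,
                    "visit": v,
                    "hiv_status": groups[t % 3],
                    "fdi_code": fdi,
                    "dentition": "permanent",
                    "tooth_health": "H",
                    "mouth_health": "CF",
                    "combined_health": "H-CF",
                    "position": "anterior" if fdi % 10 <= 3 else "posterior",
                    "jaw": "maxillary" if fdi // 10 in (1, 2) else "mandibular",
                    "sex": "F" if t % 2 else "M",
                    "age_years": 7.0,
                    "cd4_count": 900,
                    "collection_day": (v - 1) * 180,
                }
            )
    table = FeatureTable(pd.DataFrame(rows))
    meta = SampleMetadata(pd.DataFrame(meta_rows).set_index("sample_id"))
    truth = {
        "target": target,
        "before_marker": before_marker,
        "after_marker": after_marker,
        "phase": phases,
    }
    return table, meta, truth
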