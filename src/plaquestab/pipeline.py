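"""Config-driven orchestration of the full analysis with provenance capture.

A run is described by one YAML/dict config (see `examples/demo_config.yaml`)
and a master seed. Per-stage seeds are derived deterministically from the
master seed, so rerunning the same config reproduces every output —
including the stochastic-but-seeded ones — bit-identically. Every stage
writes its artifacts plus a ``manifest.json`` recording the stage,
parameters, seed, inputs and outputs (no timestamps or absolute paths, so
manifests are comparable across runs).
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .composition import (
    aitchison_distance,
    alpha_diversity,
    clr_transform,
    permanova,
    subsampled_permanova,
)
from .filtering import apply_standard_filters, filter_for_networks
from .mutans import label_mutans_phases, rf_classify_phases, shapley_attribution
from .networks import (
    build_can,
    cluster_overlay,
    greedy_modularity,
    infer_network_mb,
    write_edgelist_tsv,
    write_partition_tsv,
)
from .signatures import fit_balance_signature, predict_balance, signature_report
from .simulate import SimulationConfig, simulate_cohort
from .tables import (
    FeatureTable,
    load_feature_table,
    load_metadata,
    load_taxonomy,
)
from .turnover import match_paired_teeth, taxonomic_turnover, turnover_group_analysis

STAGES = (
    "simulate",
    "filter",
    "diversity",
    "turnover",
    "network",
    "spatial",
    "signature",
    "mutans",
    "report",
)

_KNOWN_KEYS = {
    "seed",
    "simulate",
    "inputs",
    "filters",
    "clr",
    "diversity",
    "turnover",
    "network",
    "spatial",
    "signature",
    "mutans",
}


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    unknown = sorted(set(cfg) - _KNOWN_KEYS)
    if unknown:
        raise ConfigError(f"unknown config key(s): {unknown}")
    if "simulate" not in cfg and "inputs" not in cfg:
        raise ConfigError("config needs either a 'simulate' block or 'inputs' paths")
    if "simulate" in cfg and cfg["simulate"] is not None:
        known_sim = set(SimulationConfig.__dataclass_fields__)
        unknown = sorted(set(cfg["simulate"]) - known_sim)
        if unknown:
            raise ConfigError(f"unknown simulate key(s): {unknown}")


def stage_seeds(master_seed: int) -> dict:
    """One deterministic sub-seed per stage, derived from the master seed."""
    state = np.random.SeedSequence(master_seed).generate_state(len(STAGES))
    return {s: int(v % (2**31 - 1)) for s, v in zip(STAGES, state)}


def _write_manifest(stage_dir: Path, stage: str, parameters, seed, inputs, outputs):
    manifest = {
        "stage": stage,
        "version": __version__,
        "parameters": parameters,
        "seed": seed,
        "inputs": sorted(inputs),
        "outputs": sorted(outputs),
    }
    with open(stage_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def _stage_dir(outdir: Path, stage: str) -> Path:
    d = Path(outdir) / stage
    d.mkdir(parents=True, exist_ok=True)
    return d


# -- context loading helpers -------------------------------------------------


def _ensure_raw(ctx, cfg, outdir):
    if "table" in ctx:
        return
    sim_dir = Path(outdir) / "simulate"
    if "inputs" in cfg:
        paths = cfg["inputs"]
        ctx["table"] = load_feature_table(paths["feature_table"])
        ctx["meta"] = load_metadata(paths["metadata"])
        ctx["taxonomy"] = load_taxonomy(paths["taxonomy"])
    elif (sim_dir / "feature_table.tsv").exists():
        ctx["table"] = load_feature_table(sim_dir / "feature_table.tsv")
        ctx["meta"] = load_metadata(sim_dir / "metadata.tsv")
        ctx["taxonomy"] = load_taxonomy(sim_dir / "taxonomy.tsv")
    else:
        raise StageError("no input data: run the simulate stage or provide inputs")


def _ensure_filtered(ctx, cfg, outdir):
    if "filtered" in ctx:
        return
    path = Path(outdir) / "filter" / "filtered_table.tsv"
    if path.exists():
        _ensure_raw(ctx, cfg, outdir)
        ctx["filtered"] = load_feature_table(path)
    else:
        raise StageError("filtered table missing: run the filter stage first")


def _ensure_turnover(ctx, cfg, outdir):
    if "records" in ctx:
        return
    path = Path(outdir) / "turnover" / "turnover_records.tsv"
    if path.exists():
        ctx["records"] = pd.read_csv(path, sep="\t")
    else:
        raise StageError("turnover records missing: run the turnover stage first")


# -- stages ------------------------------------------------------------------


def run_simulate(ctx, cfg, outdir, seed):
    params = dict(cfg.get("simulate") or {})
    params.setdefault("seed", seed)
    sim_cfg = SimulationConfig(**params)
    table, meta, taxonomy, truth = simulate_cohort(sim_cfg)
    d = _stage_dir(outdir, "simulate")
    table.to_tsv(d / "feature_table.tsv")
    meta.to_tsv(d / "metadata.tsv")
    taxonomy.to_tsv(d / "taxonomy.tsv")
    truth.latent.to_csv(d / "ground_truth_latents.tsv", sep="\t")
    gt = {
        "sigma_per_group": truth.sigma_per_group,
        "block_membership": truth.block_membership.tolist(),
        "spatial_offset": [round(v, 10) for v in truth.spatial_offset],
        "signature_taxa": truth.signature_taxa,
    }
    with open(d / "ground_truth.json", "w") as fh:
        json.dump(gt, fh, indent=2, sort_keys=True)
    truth.cd4_latent.to_csv(d / "ground_truth_cd4.tsv", sep="\t", index=False)
    ctx.update(table=table, meta=meta, taxonomy=taxonomy, truth=truth)
    _write_manifest(
        d, "simulate",
        {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()},
        seed, [],
        ["feature_table.tsv", "metadata.tsv", "taxonomy.tsv",
         "ground_truth.json", "ground_truth_latents.tsv", "ground_truth_cd4.tsv"],
    )


def run_filter(ctx, cfg, outdir, seed):
    _ensure_raw(ctx, cfg, outdir)
    params = dict(cfg.get("filters") or {})
    filtered, log = apply_standard_filters(ctx["table"], ctx["taxonomy"], **params)
    d = _stage_dir(outdir, "filter")
    filtered.to_tsv(d / "filtered_table.tsv")
    ctx["filtered"] = filtered
    _write_manifest(
        d, "filter", {**params, "log": {k: list(v) if isinstance(v, tuple) else v for k, v in log.items()}},
        seed, ["simulate/feature_table.tsv"], ["filtered_table.tsv"],
    )


def run_diversity(ctx, cfg, outdir, seed):
    _ensure_filtered(ctx, cfg, outdir)
    params = dict(cfg.get("diversity") or {})
    n_perm = int(params.get("n_perm", 999))
    pc = float((cfg.get("clr") or {}).get("pseudocount", 0.5))
    table = ctx["filtered"]
    meta = ctx["meta"]
    alpha = pd.DataFrame(
        {
            "observed": alpha_diversity(table, "observed"),
            "shannon": alpha_diversity(table, "shannon"),
        }
    )
    clr = clr_transform(table, pc)
    dist = aitchison_distance(clr)
    grouping = meta.data.loc[dist.ids, "hiv_status"]
    res = permanova(dist, grouping, n_perm=n_perm, seed=seed)
    d = _stage_dir(outdir, "diversity")
    alpha.index.name = "sample_id"
    alpha.to_csv(d / "alpha_diversity.tsv", sep="\t")
    with open(d / "permanova_hiv_status.json", "w") as fh:
        json.dump(
            {"pseudo_F": res.pseudo_F, "R2": res.R2, "p": res.p,
             "n_perm": res.n_perm, "seed": res.seed},
            fh, indent=2, sort_keys=True,
        )
    ctx["clr"] = clr
    ctx["dist"] = dist
    _write_manifest(
        d, "diversity", {"n_perm": n_perm, "pseudocount": pc}, seed,
        ["filter/filtered_table.tsv"],
        ["alpha_diversity.tsv", "permanova_hiv_status.json"],
    )


def run_turnover(ctx, cfg, outdir, seed):
    _ensure_filtered(ctx, cfg, outdir)
    pc = float((cfg.get("clr") or {}).get("pseudocount", 0.5))
    meta = ctx["meta"]
    clr = ctx.get("clr") or clr_transform(ctx["filtered"], pc)
    pairs = match_paired_teeth(meta.subset(
        [s for s in meta.sample_ids if s in set(ctx["filtered"].sample_ids)]
    ))
    records = taxonomic_turnover(clr, pairs)
    d = _stage_dir(outdir, "turnover")
    records.to_csv(d / "turnover_records.tsv", sep="\t", index=False)
    outputs = ["turnover_records.tsv"]
    if not records.empty:
        analysis = turnover_group_analysis(records, meta)
        analysis["summary"].to_csv(d / "turnover_summary.tsv", sep="\t", index=False)
        analysis["tests"].to_csv(d / "turnover_tests.tsv", sep="\t", index=False)
        healthy = turnover_group_analysis(records, meta, healthy_only=True)
        healthy["tests"].to_csv(d / "turnover_tests_healthy_only.tsv", sep="\t", index=False)
        outputs += ["turnover_summary.tsv", "turnover_tests.tsv",
                    "turnover_tests_healthy_only.tsv"]
        ctx["turnover_analysis"] = analysis
    ctx["records"] = records
    _write_manifest(
        d, "turnover", {"pseudocount": pc}, seed,
        ["filter/filtered_table.tsv", "simulate/metadata.tsv"], outputs,
    )


def run_network(ctx, cfg, outdir, seed):
    _ensure_filtered(ctx, cfg, outdir)
    params = dict(cfg.get("network") or {})
    groupby = params.get("groupby", "hiv_status")
    set_size_group = float(params.get("set_size_group", 1.0))
    set_size_global = float(params.get("set_size_global", 0.6))
    stars_reps = int(params.get("stars_reps", 20))
    stability = float(params.get("stability_threshold", 0.05))
    min_cluster = int(params.get("min_cluster_size", 10))
    min_samples = int(params.get("min_samples", 20))
    pc = float((cfg.get("clr") or {}).get("pseudocount", 0.5))

    table = filter_for_networks(ctx["filtered"])
    meta = ctx["meta"].data.loc[[s for s in table.sample_ids if s in ctx["meta"].data.index]]
    clr = clr_transform(table, pc)
    rng = np.random.default_rng(seed)
    d = _stage_dir(outdir, "network")
    outputs = []
    visits = sorted(meta["visit"].unique())
    modularity = {}

    def _infer(sample_ids, tag):
        sub = clr.data.loc[sample_ids]
        net = infer_network_mb(
            sub, stars_reps=stars_reps, stability_threshold=stability,
            seed=int(rng.integers(2**31 - 1)), min_samples=min_samples,
        )
        write_edgelist_tsv(net, d / f"network_{tag}.tsv")
        outputs.append(f"network_{tag}.tsv")
        return net

    global_nets = [
        _infer(meta.index[meta["visit"] == v], f"all_v{v}") for v in visits
    ]
    global_can = build_can(global_nets, set_size_global)
    write_edgelist_tsv(global_can, d / "can_global.tsv")
    outputs.append("can_global.tsv")
    global_part = greedy_modularity(global_can)
    write_partition_tsv(global_part, d / "can_global_clusters.tsv", min_cluster)
    outputs.append("can_global_clusters.tsv")
    modularity["global"] = global_part.modularity

    overlays = {}
    for g in sorted(meta[groupby].unique()):
        nets = []
        skip = False
        for v in visits:
            ids = meta.index[(meta[groupby] == g) & (meta["visit"] == v)]
            if len(ids) < min_samples:
                warnings.warn(f"group {g} visit {v}: too few samples for a network")
                skip = True
                break
            nets.append(_infer(ids, f"{g}_v{v}"))
        if skip:
            continue
        can = build_can(nets, set_size_group)
        write_edgelist_tsv(can, d / f"can_{g}.tsv")
        outputs.append(f"can_{g}.tsv")
        part = greedy_modularity(can)
        write_partition_tsv(part, d / f"can_{g}_clusters.tsv", min_cluster)
        outputs.append(f"can_{g}_clusters.tsv")
        modularity[g] = part.modularity
        overlays[g] = cluster_overlay(global_part, can)

    with open(d / "modularity.json", "w") as fh:
        json.dump(modularity, fh, indent=2, sort_keys=True)
    with open(d / "cluster_overlay.json", "w") as fh:
        json.dump(overlays, fh, indent=2, sort_keys=True)
    outputs += ["modularity.json", "cluster_overlay.json"]
    ctx["modularity"] = modularity
    _write_manifest(
        d, "network",
        {"groupby": groupby, "set_size_group": set_size_group,
         "set_size_global": set_size_global, "stars_reps": stars_reps,
         "stability_threshold": stability, "min_cluster_size": min_cluster,
         "pseudocount": pc},
        seed, ["filter/filtered_table.tsv"], outputs,
    )


def run_spatial(ctx, cfg, outdir, seed):
    _ensure_filtered(ctx, cfg, outdir)
    params = dict(cfg.get("spatial") or {})
    factor = params.get("factor", "position")
    strata = params.get("strata", "hiv_status")
    n_rounds = int(params.get("n_rounds", 100))
    n_perm = int(params.get("n_perm", 199))
    restrict = params.get("restrict_tooth_health", "H")
    pc = float((cfg.get("clr") or {}).get("pseudocount", 0.5))
    meta = ctx["meta"].data
    table = ctx["filtered"]
    keep = [
        s for s in table.sample_ids
        if s in meta.index and (restrict is None or meta.loc[s, "tooth_health"] == restrict)
    ]
    result = subsampled_permanova(
        table.select_samples(keep), ctx["meta"].subset(keep),
        factor=factor, strata=strata, n_rounds=n_rounds, n_perm=n_perm,
        seed=seed, pseudocount=pc,
    )
    d = _stage_dir(outdir, "spatial")
    result.to_csv(d / "subsampled_permanova.tsv", sep="\t")
    ctx["spatial"] = result
    _write_manifest(
        d, "spatial",
        {"factor": factor, "strata": strata, "n_rounds": n_rounds,
         "n_perm": n_perm, "restrict_tooth_health": restrict, "pseudocount": pc},
        seed, ["filter/filtered_table.tsv"], ["subsampled_permanova.tsv"],
    )


def run_signature(ctx, cfg, outdir, seed):
    _ensure_filtered(ctx, cfg, outdir)
    _ensure_turnover(ctx, cfg, outdir)
    params = dict(cfg.get("signature") or {})
    cv_folds = int(params.get("cv_folds", 5))
    pc = float((cfg.get("clr") or {}).get("pseudocount", 0.5))
    records = ctx["records"]
    d = _stage_dir(outdir, "signature")
    if records.empty:
        _write_manifest(d, "signature", params, seed, ["turnover/turnover_records.tsv"], [])
        return
    table = ctx["filtered"].select_samples(records["sample_id_from"].unique())
    rec = records.drop_duplicates("sample_id_from").set_index("sample_id_from")
    outcome = rec.loc[table.sample_ids, "turnover"]
    subjects = rec.loc[table.sample_ids, "subject_id"]
    sig = fit_balance_signature(
        table, outcome, mode="continuous", cv_folds=cv_folds,
        seed=seed, subject_ids=subjects, pseudocount=pc,
    )
    sig.to_json(d / "turnover_signature.json")
    outputs = ["turnover_signature.json"]
    if not sig.is_empty:
        pred = predict_balance(sig, table, outcome)
        pd.DataFrame(
            {"balance_score": pred.scores, "turnover": outcome}
        ).to_csv(d / "turnover_signature_predictions.tsv", sep="\t")
        signature_report(sig).to_csv(d / "turnover_signature_report.tsv", sep="\t", index=False)
        outputs += ["turnover_signature_predictions.tsv", "turnover_signature_report.tsv"]
    ctx["signature"] = sig
    _write_manifest(
        d, "signature", {"cv_folds": cv_folds, "outcome": "turnover", "pseudocount": pc},
        seed, ["turnover/turnover_records.tsv"], outputs,
    )


def run_mutans(ctx, cfg, outdir, seed):
    _ensure_filtered(ctx, cfg, outdir)
    params = dict(cfg.get("mutans") or {})
    low = float(params.get("low", 0.05))
    high = float(params.get("high", 0.10))
    n_trees = int(params.get("n_trees", 500))
    n_mc = int(params.get("n_mc_samples", 0))  # 0 disables attribution
    target = params.get("target_taxon", "Streptococcus mutans")
    d = _stage_dir(outdir, "mutans")
    table = ctx["filtered"]
    meta = ctx["meta"].subset([s for s in table.sample_ids if s in ctx["meta"].data.index])
    outputs = []
    if target not in table.taxon_ids:
        warnings.warn(f"{target!r} not in the filtered table; mutans stage writes no labels")
        labels = pd.DataFrame()
    else:
        labels = label_mutans_phases(table, meta, target, low, high)
    labels.to_csv(d / "phase_labels.tsv", sep="\t", index=False)
    outputs.append("phase_labels.tsv")
    enough = (
        not labels.empty
        and (labels["phase"].value_counts() >= 5).sum() >= 2
    )
    if enough:
        rf = rf_classify_phases(table, labels, n_trees=n_trees, seed=seed, target_taxon=target)
        rf["confusion"].to_csv(d / "confusion_matrix.tsv", sep="\t")
        rf["recall"].to_csv(d / "per_class_recall.tsv", sep="\t")
        outputs += ["confusion_matrix.tsv", "per_class_recall.tsv"]
        if n_mc >= 10 and "before" in rf["classes"]:
            attr = shapley_attribution(
                rf["model"], rf["features"], "before", n_mc_samples=n_mc, seed=seed
            )
            attr.abs().mean(axis=0).sort_values(ascending=False).head(20).to_csv(
                d / "shapley_top_taxa_before.tsv", sep="\t"
            )
            outputs.append("shapley_top_taxa_before.tsv")
        ctx["mutans_rf"] = rf
    else:
        warnings.warn("too few labeled phases for classification; skipped")
    ctx["mutans_labels"] = labels
    _write_manifest(
        d, "mutans",
        {"low": low, "high": high, "n_trees": n_trees, "n_mc_samples": n_mc,
         "target_taxon": target},
        seed, ["filter/filtered_table.tsv"], outputs,
    )


def run_report(ctx, cfg, outdir, seed):
    d = _stage_dir(outdir, "report")
    lines = ["# Pipeline report", ""]
    for stage in STAGES[:-1]:
        manifest = Path(outdir) / stage / "manifest.json"
        if not manifest.exists():
            continue
        lines.append(f"## {stage}")
        with open(manifest) as fh:
            m = json.load(fh)
        lines.append(f"- outputs: {', '.join(m['outputs']) or 'none'}")
        if stage == "turnover" and "turnover_analysis" in ctx:
            summ = ctx["turnover_analysis"]["summary"]
            pooled = summ[summ["visit_pair"] == "pooled"]
            for _, row in pooled.iterrows():
                lines.append(
                    f"- mean turnover {row['group']}: {row['mean_turnover']:.3f} (n={row['n']})"
                )
            lines.append(
                "- note: turnover uses raw Aitchison distances; intervals between "
                "visits are unequal and distances are not time-normalized"
            )
        if stage == "network" and "modularity" in ctx:
            for k, v in sorted(ctx["modularity"].items()):
                lines.append(f"- modularity Q ({k}): {v:.3f}")
        if stage == "spatial" and "spatial" in ctx:
            for s, row in ctx["spatial"].iterrows():
                lines.append(
                    f"- {s}: mean adjusted p = {row['mean_adjusted_p']:.4f}, "
                    f"mean R2 = {row['mean_R2']:.4f}"
                )
        if stage == "signature" and "signature" in ctx:
            sig = ctx["signature"]
            if sig.is_empty:
                lines.append("- turnover signature: empty (no taxa survive the 1-SE rule)")
            else:
                lines.append(
                    f"- turnover signature: {len(sig.taxa)} taxa, "
                    f"cv R = {sig.cv_metric:.3f}, apparent R = {sig.apparent_metric:.3f}"
                )
        lines.append("")
    (d / "report.md").write_text("\n".join(lines))
    _write_manifest(d, "report", {}, seed, [], ["report.md"])


_STAGE_FUNCS = {
    "simulate": run_simulate,
    "filter": run_filter,
    "diversity": run_diversity,
    "turnover": run_turnover,
    "network": run_network,
    "spatial": run_spatial,
    "signature": run_signature,
    "mutans": run_mutans,
    "report": run_report,
}


def run_pipeline(cfg: dict, outdir, stages=None) -> dict:
    """Execute the configured stages in order; returns the run context.

    A failing stage raises StageError naming the stage; artifacts written by
    earlier stages are retained.
    """
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    master = int(cfg.get("seed", 0))
    seeds = stage_seeds(master)
    selected = list(STAGES) if stages is None else list(stages)
    unknown = sorted(set(selected) - set(STAGES))
    if unknown:
        raise ConfigError(f"unknown stage(s): {unknown}")
    if "inputs" in cfg and "simulate" in selected and "simulate" not in cfg:
        selected = [s for s in selected if s != "simulate"]
    ctx: dict = {}
    for stage in STAGES:
        if stage not in selected:
            continue
        try:
            _STAGE_FUNCS[stage](ctx, cfg, outdir, seeds[stage])
        except (ConfigError, StageError):
            raise
        except Exception as exc:
            raise StageError(f"stage {stage!r} failed: {exc}") from exc
    return ctx
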