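"""Post-denoising filters applied to the ASV/species count table.

The rules, in the order the pipeline applies them:

1. drop ASVs assigned only to kingdom level (no phylum or below);
2. drop low-abundance ASVs: keep a taxon iff it is present in at least 0.1%
   of samples, unless its total abundance exceeds 1000 reads (rescue);
3. drop samples with fewer than 5000 reads post-filtering;
4. optionally collapse ASVs to species-level buckets;
5. for network inference only: keep species found in at least 1% of samples
   with a minimum of 10 observations.

All filters only drop rows/columns — surviving counts are never modified —
and each is idempotent. The order matters (tables differ under reordering),
so `apply_standard_filters` fixes it and records it in the run manifest.
"""

from __future__ import annotations

import math
import warnings

from .tables import FeatureTable, TaxonomyMap


def filter_unassigned(table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Drop taxa that could not be assigned below kingdom level."""
    keep = [t for t in table.taxon_ids if not taxonomy.is_kingdom_only(t)]
    return table.select_taxa(keep)


def filter_low_abundance(
    table: FeatureTable,
    prevalence_frac: float = 0.001,
    abundance_rescue: int = 1000,
) -> FeatureTable:
    """Prevalence filter with a total-abundance rescue.

    A taxon is retained iff it is present (count > 0) in at least
    ``ceil(prevalence_frac × n_samples)`` samples, OR its total count is
    strictly greater than ``abundance_rescue`` reads.
    """
    n_samples = len(table.sample_ids)
    min_prev = math.ceil(prevalence_frac * n_samples)
    prevalence = (table.data > 0).sum(axis=0)
    totals = table.data.sum(axis=0)
    keep = table.data.columns[(prevalence >= min_prev) | (totals > abundance_rescue)]
    return table.select_taxa(keep)


def filter_low_depth_samples(table: FeatureTable, min_reads: int = 5000) -> FeatureTable:
    """Drop samples with strictly fewer than ``min_reads`` total reads."""
    depths = table.data.sum(axis=1)
    keep = table.data.index[depths >= min_reads]
    return table.select_samples(keep)


def collapse_to_species(table: FeatureTable, taxonomy: TaxonomyMap) -> FeatureTable:
    """Sum ASV counts into species-level buckets.

    ASVs without a species assignment collapse into a synthetic
    ``"<lowest assigned rank> sp."`` bucket (see TaxonomyMap.species_label)
    so that unnamed units remain analyzable. Per-sample totals are preserved
    exactly (pure additivity).
    """
    labels = {t: taxonomy.species_label(t) for t in table.taxon_ids}
    collapsed = table.data.T.groupby(table.data.columns.map(labels)).sum().T
    collapsed = collapsed[sorted(collapsed.columns)]
    return FeatureTable(collapsed)


def filter_for_networks(
    table: FeatureTable,
    min_sample_frac: float = 0.01,
    min_obs: int = 10,
) -> FeatureTable:
    """Species pre-filter for association-network inference.

    Retains a species iff its prevalence is at least ``min_sample_frac`` of
    samples AND its total count is at least ``min_obs`` (both conditions
    required, unlike the low-abundance rescue).
    """
    n_samples = len(table.sample_ids)
    prevalence = (table.data > 0).sum(axis=0)
    totals = table.data.sum(axis=0)
    keep = table.data.columns[
        (prevalence / n_samples >= min_sample_frac) & (totals >= min_obs)
    ]
    return table.select_taxa(keep)


def apply_standard_filters(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    prevalence_frac: float = 0.001,
    abundance_rescue: int = 1000,
    min_reads: int = 5000,
    collapse: bool = True,
) -> tuple[FeatureTable, dict]:
    """Run the fixed filter cascade and return (table, provenance log).

    Order: unassigned → low-abundance → low-depth samples → (optional)
    species collapse. The log records sizes after each step so a run is
    auditable.
    """
    log: dict = {"order": ["unassigned", "low_abundance", "low_depth", "collapse"]}
    t = filter_unassigned(table, taxonomy)
    log["after_unassigned"] = t.shape
    t = filter_low_abundance(t, prevalence_frac, abundance_rescue)
    log["after_low_abundance"] = t.shape
    t = filter_low_depth_samples(t, min_reads)
    log["after_low_depth"] = t.shape
    if collapse:
        t = collapse_to_species(t, taxonomy)
        log["after_collapse"] = t.shape
    if 0 in t.shape:
        warnings.warn("filter cascade produced an empty table", stacklevel=2)
    return t, log
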