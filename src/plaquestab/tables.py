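"""Core data containers: feature table, taxonomy map, sample metadata.

The feature table is a sample × taxon matrix of non-negative integer read
counts — the universal currency of the pipeline. Taxonomy maps each taxon
(ASV or species bucket) to a seven-rank lineage; sample metadata carries the
clinical and positional annotations (subject, visit, HIV status, FDI tooth
code, tooth/mouth health, position) that drive every grouping downstream.

On-disk formats are plain TSV:

* feature table — taxa as rows, a header row of sample ids, integer cells;
* taxonomy — ``taxon_id`` plus the seven rank columns, empty cell = unassigned;
* metadata — one row per sample with the required columns below.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

HIV_GROUPS = ("HI", "HEU", "HUU")
TOOTH_HEALTH = ("H", "E", "D")
MOUTH_HEALTH = ("CF", "CE", "CD")

#: Nested tooth × mouth health combinations that are clinically coherent:
#: a healthy tooth can sit in any mouth, an enamel lesion implies the mouth
#: has at least enamel caries, a dentin cavity implies dentin caries.
ALLOWED_COMBINED_HEALTH = frozenset(
    {"H-CF", "H-CE", "H-CD", "E-CE", "E-CD", "D-CD"}
)

METADATA_COLUMNS = (
    "subject_id",
    "visit",
    "hiv_status",
    "fdi_code",
    "dentition",
    "tooth_health",
    "mouth_health",
    "combined_health",
    "position",
    "jaw",
    "sex",
    "age_years",
    "cd4_count",
    "collection_day",
)


class ParseError(ValueError):
    """Raised when an input file violates the documented TSV dialect."""


def fdi_position(fdi_code: int | str) -> str:
    """Anterior/posterior from an FDI two-digit code.

    Tooth digits 1–3 (incisors and canines) are anterior; 4–8 (premolars and
    molars; 4–5 for deciduous) are posterior.
    """
    tooth = int(str(fdi_code)[-1])
    return "anterior" if tooth <= 3 else "posterior"


def fdi_jaw(fdi_code: int | str) -> str:
    """Maxillary/mandibular from the FDI quadrant digit."""
    quadrant = int(str(fdi_code)[0])
    return "maxillary" if quadrant in (1, 2, 5, 6) else "mandibular"


def fdi_dentition(fdi_code: int | str) -> str:
    """Permanent (quadrants 1–4) vs deciduous (quadrants 5–8)."""
    quadrant = int(str(fdi_code)[0])
    return "permanent" if quadrant <= 4 else "deciduous"


@dataclass
class FeatureTable:
    """Sample × taxon non-negative integer count matrix.

    ``data`` is a pandas DataFrame with sample ids as the index and taxon ids
    as columns. Construction validates uniqueness, dtype and non-negativity.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ParseError(f"duplicate taxon ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ParseError("counts must be integers")
            df = df.astype(np.int64)
            self.data = df
            values = df.to_numpy()
        if values.size and values.min() < 0:
            bad = df.index[(values < 0).any(axis=1)].tolist()
            raise ParseError(f"negative counts in samples: {bad}")

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample closure to proportions (all-zero samples stay zero)."""
        totals = self.data.sum(axis=1).replace(0, 1)
        return self.data.div(totals, axis=0)

    def select_taxa(self, taxa) -> "FeatureTable":
        return FeatureTable(self.data.loc[:, list(taxa)])

    def select_samples(self, samples) -> "FeatureTable":
        return FeatureTable(self.data.loc[list(samples)])

    # -- IO ----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, path) -> "FeatureTable":
        try:
            df = pd.read_csv(path, sep="\t", index_col=0)
        except pd.errors.ParserError as exc:  # ragged rows etc.
            raise ParseError(f"{path}: {exc}") from exc
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ParseError(f"{path}: missing/ragged cells in rows {bad}")
        # on disk: taxa rows × sample columns
        return cls(df.T)

    def to_tsv(self, path) -> None:
        out = self.data.T
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")

    def __eq__(self, other) -> bool:  # convenient for round-trip tests
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return self.data.equals(other.data)


@dataclass
class TaxonomyMap:
    """taxon_id → ranked lineage (kingdom … species); '' marks a missing rank."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [r for r in RANKS if r not in df.columns]
        if missing:
            raise ParseError(f"taxonomy missing rank columns: {missing}")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate taxon ids in taxonomy: {dups}")
        self.data = df[list(RANKS)].fillna("").astype(str)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    def lineage(self, taxon_id: str) -> dict[str, str]:
        return self.data.loc[taxon_id].to_dict()

    def is_kingdom_only(self, taxon_id: str) -> bool:
        row = self.data.loc[taxon_id]
        return all(row[r] == "" for r in RANKS[1:])

    def species_label(self, taxon_id: str) -> str:
        """Species name, or a '<lowest assigned rank> sp.' bucket.

        ASVs carrying a genus but no species collapse to e.g. ``Rothia sp.``
        rather than being dropped — unnamed species-like units are analyzed
        as first-class taxa.
        """
        row = self.data.loc[taxon_id]
        if row["species"]:
            return row["species"]
        for rank in reversed(RANKS[:-1]):
            if row[rank]:
                return f"{row[rank]} sp."
        return "unassigned sp."

    @classmethod
    def from_tsv(cls, path) -> "TaxonomyMap":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "taxon_id"
        out.to_csv(path, sep="\t")


@dataclass
class SampleMetadata:
    """Per-sample clinical/positional annotations, indexed by sample id."""

    data: pd.DataFrame
    visits: tuple[int, ...] = field(default=(1, 2, 3))

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate sample ids in metadata: {dups}")
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ParseError(f"metadata missing columns: {missing}")
        df = df.copy()
        df["visit"] = df["visit"].astype(int)
        bad_visit = sorted(set(df["visit"]) - set(self.visits))
        if bad_visit:
            raise ParseError(f"visits outside declared set {self.visits}: {bad_visit}")
        for col, allowed in (
            ("hiv_status", HIV_GROUPS),
            ("tooth_health", TOOTH_HEALTH),
            ("mouth_health", MOUTH_HEALTH),
            ("position", ("anterior", "posterior")),
            ("dentition", ("deciduous", "permanent")),
            ("jaw", ("maxillary", "mandibular")),
        ):
            bad = sorted(set(df[col].astype(str)) - set(allowed))
            if bad:
                raise ParseError(f"invalid {col} values: {bad}")
        combined = df["tooth_health"].astype(str) + "-" + df["mouth_health"].astype(str)
        declared = df["combined_health"].astype(str)
        mismatch = df.index[combined != declared].tolist()
        if mismatch:
            raise ParseError(
                f"combined_health inconsistent with tooth/mouth health: {mismatch}"
            )
        bad_combo = df.index[~declared.isin(ALLOWED_COMBINED_HEALTH)].tolist()
        if bad_combo:
            raise ParseError(
                "combined_health violates the nested health scheme "
                f"(allowed: {sorted(ALLOWED_COMBINED_HEALTH)}): {bad_combo}"
            )
        self.data = df

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def subset(self, sample_ids) -> "SampleMetadata":
        return SampleMetadata(self.data.loc[list(sample_ids)], visits=self.visits)

    @classmethod
    def from_tsv(cls, path, visits=(1, 2, 3)) -> "SampleMetadata":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, visits=tuple(visits))

    def to_tsv(self, path) -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")


# -- loader front-ends (the module-level API most callers use) --------------


def load_feature_table(path) -> FeatureTable:
    return FeatureTable.from_tsv(path)


def load_taxonomy(path) -> TaxonomyMap:
    return TaxonomyMap.from_tsv(path)


def load_metadata(path, visits=(1, 2, 3)) -> SampleMetadata:
    return SampleMetadata.from_tsv(path, visits=visits)


def cross_reference(table: FeatureTable, meta: SampleMetadata) -> list[str]:
    """Report sample ids present in the table but unknown to the metadata."""
    unknown = sorted(set(table.sample_ids) - set(meta.sample_ids))
    if unknown:
        warnings.warn(f"{len(unknown)} table samples missing from metadata", stacklevel=2)
    return unknown
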