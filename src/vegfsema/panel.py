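"""Gene panels and the expression-matrix data model.

The analyses in this package revolve around a curated panel of 39 genes
covering the VEGF ligand family, its receptor tyrosine kinases, the
neuropilin co-receptors, and the semaphorin/plexin families that modulate
VEGF signalling.  This module defines that panel, a light-weight container
for log2 expression matrices with per-sample clinical metadata, and the
TSV readers/writers every downstream stage consumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Gene families
VEGF_LIGAND = "VEGF_LIGAND"
VEGFR = "VEGFR"
NRP = "NRP"
SEMA3 = "SEMA3"
SEMA4 = "SEMA4"
SEMA5 = "SEMA5"
SEMA6 = "SEMA6"
SEMA7 = "SEMA7"
PLXNA = "PLXNA"
PLXNB = "PLXNB"
PLXNC = "PLXNC"
PLXND = "PLXND"

FAMILIES = (
    VEGF_LIGAND, VEGFR, NRP, SEMA3, SEMA4, SEMA5, SEMA6, SEMA7,
    PLXNA, PLXNB, PLXNC, PLXND,
)

# Tissue types
TISSUE_NORMAL = "normal"
TISSUE_PRIMARY = "primary"
TISSUE_METASTATIC = "metastatic"
TISSUE_TYPES = (TISSUE_NORMAL, TISSUE_PRIMARY, TISSUE_METASTATIC)

# Symbol aliases normalised on input.  FIGF is the symbol used for VEGFD
# and PGF for PlGF throughout; the modern aliases are accepted.
SYMBOL_ALIASES = {"VEGFD": "FIGF", "PLGF": "PGF"}

METADATA_COLUMNS = (
    "sample_id", "dataset_id", "tissue_type", "patient_id",
    "bcr_event", "bcr_time_years", "gleason",
)

_DEFAULT_PANEL: tuple[tuple[str, str], ...] = (
    ("VEGFA", VEGF_LIGAND), ("VEGFB", VEGF_LIGAND), ("VEGFC", VEGF_LIGAND),
    ("FIGF", VEGF_LIGAND), ("PGF", VEGF_LIGAND),
    ("FLT1", VEGFR), ("KDR", VEGFR), ("FLT4", VEGFR),
    ("NRP1", NRP), ("NRP2", NRP),
    ("SEMA3A", SEMA3), ("SEMA3B", SEMA3), ("SEMA3C", SEMA3),
    ("SEMA3D", SEMA3), ("SEMA3E", SEMA3), ("SEMA3F", SEMA3), ("SEMA3G", SEMA3),
    ("SEMA4A", SEMA4), ("SEMA4B", SEMA4), ("SEMA4C", SEMA4),
    ("SEMA4D", SEMA4), ("SEMA4F", SEMA4), ("SEMA4G", SEMA4),
    ("SEMA5A", SEMA5), ("SEMA5B", SEMA5),
    ("SEMA6A", SEMA6), ("SEMA6B", SEMA6), ("SEMA6C", SEMA6), ("SEMA6D", SEMA6),
    ("SEMA7A", SEMA7),
    ("PLXNA1", PLXNA), ("PLXNA2", PLXNA), ("PLXNA3", PLXNA), ("PLXNA4", PLXNA),
    ("PLXNB1", PLXNB), ("PLXNB2", PLXNB), ("PLXNB3", PLXNB),
    ("PLXNC1", PLXNC),
    ("PLXND1", PLXND),
)


def normalize_symbol(symbol: str) -> str:
    """Map accepted gene-symbol aliases onto the panel's canonical symbols."""
    return SYMBOL_ALIASES.get(symbol, symbol)


@dataclass(frozen=True)
class GenePanel:
    """An ordered set of gene symbols with a family label per symbol."""

    genes: tuple[str, ...]
    family: dict[str, str] = field(compare=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene symbols in panel")
        missing = [g for g in self.genes if g not in self.family]
        if missing:
            raise ValueError(f"genes without a family label: {missing}")
        bad = sorted(set(self.family.values()) - set(FAMILIES))
        if bad:
            raise ValueError(f"unknown families: {bad}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.family

    def genes_in_family(self, family: str) -> tuple[str, ...]:
        return tuple(g for g in self.genes if self.family[g] == family)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GenePanel":
        pairs = [(normalize_symbol(g), f) for g, f in pairs]
        return cls(genes=tuple(g for g, _ in pairs), family=dict(pairs))


def default_vegf_sema_panel() -> GenePanel:
    """The 39-gene VEGF/semaphorin panel.

    Five VEGF ligands, three VEGF receptors, two neuropilins, seven class-3
    semaphorins, the class 4-7 semaphorins, and the plexin A-D receptors.
    """
    return GenePanel.from_pairs(_DEFAULT_PANEL)


def _validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    md = metadata.copy()
    if "tissue_type" not in md.columns:
        raise ValueError("metadata must have a tissue_type column")
    bad = set(md["tissue_type"]) - set(TISSUE_TYPES)
    if bad:
        raise ValueError(f"unknown tissue labels: {sorted(bad)}")
    if not md.index.is_unique:
        raise ValueError("duplicate sample_id in metadata")
    has_event = md.get("bcr_event")
    has_time = md.get("bcr_time_years")
    if (has_event is None) != (has_time is None):
        raise ValueError("bcr_event and bcr_time_years must be given together")
    if has_event is not None:
        ev_na = md["bcr_event"].isna()
        t_na = md["bcr_time_years"].isna()
        if not (ev_na == t_na).all():
            raise ValueError("bcr_time_years present iff bcr_event present")
        times = md.loc[~t_na, "bcr_time_years"].astype(float)
        if (times < 0).any():
            raise ValueError("negative bcr_time_years")
    return md


@dataclass
class ExpressionMatrix:
    """Samples x genes log2 expression values plus per-sample metadata.

    ``values`` is a DataFrame indexed by sample_id with gene-symbol columns;
    ``metadata`` is indexed by sample_id and aligned 1:1 with ``values``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("duplicate sample ids")
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene symbol: {dup[0]}")
        self.values = self.values.rename(columns=normalize_symbol)
        dup = self.values.columns[self.values.columns.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene symbol after alias mapping: {dup[0]}")
        self.metadata = _validate_metadata(self.metadata)
        missing = self.values.index.difference(self.metadata.index)
        if len(missing):
            raise ValueError(f"samples absent from metadata: {list(missing[:5])}")
        self.metadata = self.metadata.loc[self.values.index]

    # -- basic accessors -------------------------------------------------
    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_symbols(self) -> pd.Index:
        return self.values.columns

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    def tissue_mask(self, tissue: str) -> np.ndarray:
        return (self.metadata["tissue_type"] == tissue).to_numpy()

    def select_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[list(sample_ids)].copy(),
            metadata=self.metadata.loc[list(sample_ids)].copy(),
        )

    def group_values(self, tissue: str) -> pd.DataFrame:
        return self.values.loc[self.tissue_mask(tissue)]

    # -- I/O -------------------------------------------------------------
    def write_tsv(self, expr_path: str | Path, metadata_path: str | Path,
                  orientation: Literal["genes_as_rows", "samples_as_rows"] = "genes_as_rows",
                  ) -> None:
        expr = self.values.T if orientation == "genes_as_rows" else self.values
        label = "gene" if orientation == "genes_as_rows" else "sample_id"
        expr.to_csv(expr_path, sep="\t", index_label=label, float_format="%.12g")
        md = self.metadata.reset_index(names="sample_id")
        md.to_csv(metadata_path, sep="\t", index=False)


def read_expression_tsv(
    expr_path: str | Path,
    metadata_path: str | Path,
    orientation: Literal["genes_as_rows", "samples_as_rows"] = "genes_as_rows",
) -> ExpressionMatrix:
    """Read a log2 expression TSV plus a sample-metadata TSV.

    In the default ``genes_as_rows`` dialect (GEO series-matrix convention)
    gene symbols are in the first column and sample ids in the header.
    """
    raw = pd.read_csv(expr_path, sep="\t", index_col=0)
    values = raw.T if orientation == "genes_as_rows" else raw
    values.index = values.index.astype(str)
    values.index.name = "sample_id"
    values.columns = [normalize_symbol(str(c)) for c in values.columns]
    dup = pd.Index(values.columns)[pd.Index(values.columns).duplicated()]
    if len(dup):
        raise ValueError(f"duplicate gene symbol: {dup[0]}")
    md = pd.read_csv(metadata_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in md.columns:
        raise ValueError("metadata TSV must have a sample_id column")
    md = md.set_index("sample_id")
    if "bcr_event" in md.columns:
        md["bcr_event"] = md["bcr_event"].map(
            lambda v: v if pd.isna(v) else bool(v) if isinstance(v, (bool, np.bool_))
            else str(v).strip().lower() in ("true", "1", "1.0", "yes"))
    return ExpressionMatrix(values=values, metadata=md)


def subset_to_panel(
    m: ExpressionMatrix,
    p: GenePanel,
    on_missing: Literal["error", "drop"] = "error",
) -> ExpressionMatrix:
    """Restrict gene columns to the panel, in panel order."""
    present = [g for g in p.genes if g in m.values.columns]
    missing = [g for g in p.genes if g not in m.values.columns]
    if missing:
        if on_missing == "error":
            raise ValueError(f"panel genes absent from matrix: {missing}")
        logger.warning("dropping %d absent panel genes: %s", len(missing), missing)
    sub = m.values[present]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing expression values for panel genes: {bad}")
    return ExpressionMatrix(values=sub.copy(), metadata=m.metadata.copy())


def center_on_normals(m: ExpressionMatrix, reference: str = TISSUE_NORMAL) -> ExpressionMatrix:
    """Subtract the reference-group (normal-tissue) mean of each gene.

    After centering, the reference-group mean of every gene is zero, so
    values read directly as log2 fold change relative to the reference.
    Idempotent: centering an already-centered matrix changes nothing.
    """
    mask = m.tissue_mask(reference)
    if not mask.any():
        raise ValueError(f"no samples with tissue_type == {reference!r}")
    ref_mean = m.values.loc[mask].mean(axis=0)
    return ExpressionMatrix(values=m.values - ref_mean, metadata=m.metadata.copy())
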