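"""Shared data model for plate-based single-cell experiments.

An :class:`Experiment` holds a genes × wells UMI count matrix together with
gene and well annotation tables and an append-only provenance history.  It is
the object every pipeline stage consumes and returns; raw counts are never
mutated in place — normalization adds layers on a derived object.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: TCR constant-region genes used for alpha/beta vs gamma/delta lineage calls.
TCR_CONSTANT_GENES = frozenset(
    {"TRGC1", "TRGC2", "TRDC", "TRAC", "TRBC1", "TRBC2"}
)

GENE_CLASSES = ("endogenous", "ercc", "mito", "tcr_constant")
CONDITIONS = ("Ctrl", "CeD", "GFD")
TISSUES = ("LP", "IEL")

_WELL_RE = re.compile(r"^[A-P]([1-9]|1[0-9]|2[0-4])$")


class FormatError(ValueError):
    """A file or table does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """A table violates a schema invariant (bad enum value, duplicate id...)."""


def classify_genes(
    gene_ids: pd.Series | np.ndarray,
    symbols: pd.Series | np.ndarray,
    ercc_prefix: str = "ERCC-",
    mito_prefix: str = "MT-",
) -> np.ndarray:
    """Assign each gene to exactly one class.

    Precedence when prefixes overlap: ercc > mito > tcr_constant > endogenous,
    so spike-ins can never leak into biology.
    """
    gene_ids = np.asarray(gene_ids, dtype=object)
    symbols = np.asarray(symbols, dtype=object)
    classes = np.full(len(gene_ids), "endogenous", dtype=object)
    for i, (gid, sym) in enumerate(zip(gene_ids, symbols)):
        if str(gid).startswith(ercc_prefix):
            classes[i] = "ercc"
        elif str(sym).startswith(mito_prefix):
            classes[i] = "mito"
        elif str(sym) in TCR_CONSTANT_GENES:
            classes[i] = "tcr_constant"
    return classes.astype(str)


def _validate_genes(genes: pd.DataFrame) -> pd.DataFrame:
    if "gene_id" not in genes.columns:
        raise ValidationError("gene table requires a 'gene_id' column")
    if genes["gene_id"].duplicated().any():
        dups = genes.loc[genes["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValidationError(f"duplicate gene_id values: {dups[:5]}")
    genes = genes.copy()
    if "symbol" not in genes.columns:
        genes["symbol"] = genes["gene_id"]
    if "gene_class" not in genes.columns or genes["gene_class"].isna().any():
        genes["gene_class"] = classify_genes(genes["gene_id"], genes["symbol"])
    bad = set(genes["gene_class"]) - set(GENE_CLASSES)
    if bad:
        raise ValidationError(f"unknown gene_class values: {sorted(bad)}")
    return genes.reset_index(drop=True)


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    required = {"cell_id", "plate_id", "well", "barcode", "donor_id",
                "condition", "tissue", "is_empty_well"}
    missing = required - set(wells.columns)
    if missing:
        raise ValidationError(f"well table missing columns: {sorted(missing)}")
    wells = wells.copy().reset_index(drop=True)
    if wells["cell_id"].duplicated().any():
        raise ValidationError("duplicate cell_id values in well table")
    for key in (["plate_id", "well"], ["plate_id", "barcode"]):
        if wells.duplicated(subset=key).any():
            raise ValidationError(f"duplicate {tuple(key)} combination")
    bad_well = ~wells["well"].astype(str).str.match(_WELL_RE)
    if bad_well.any():
        raise ValidationError(
            f"invalid well positions: {wells.loc[bad_well, 'well'].tolist()[:5]}"
        )
    bad_bc = ~wells["barcode"].astype(str).str.fullmatch(r"[ACGT]{8}")
    if bad_bc.any():
        raise ValidationError(
            f"invalid 8-mer barcodes: {wells.loc[bad_bc, 'barcode'].tolist()[:5]}"
        )
    wells["is_empty_well"] = wells["is_empty_well"].astype(bool)
    # conditions/tissues are case-sensitive enums; empty wells are exempt
    occupied = ~wells["is_empty_well"]
    for col, allowed in (("condition", CONDITIONS), ("tissue", TISSUES)):
        bad = occupied & ~wells[col].isin(allowed)
        if bad.any():
            rows = wells.index[bad].tolist()[:5]
            raise ValidationError(
                f"invalid {col} value(s) {wells.loc[bad, col].unique().tolist()} "
                f"in rows {rows}; allowed: {allowed}"
            )
    counts_per_plate = wells.groupby("plate_id").size()
    if (counts_per_plate > 384).any():
        raise ValidationError("a plate holds more than 384 wells")
    return wells


@dataclass
class Experiment:
    """Genes × wells UMI count matrix plus annotations and provenance.

    Parameters
    ----------
    counts
        Sparse (CSR/CSC/COO) or dense nonnegative integer matrix, genes as
        rows and wells as columns.
    genes
        DataFrame with columns ``gene_id`` (unique), ``symbol`` and
        ``gene_class`` (auto-assigned from prefixes when absent).
    wells
        DataFrame with the per-well metadata schema (cell_id, plate_id, well,
        barcode, donor_id, condition, tissue, is_empty_well, facs_*).
    """

    counts: sp.spmatrix
    genes: pd.DataFrame
    wells: pd.DataFrame
    history: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        else:
            self.counts = self.counts.tocsr()
        self.genes = _validate_genes(pd.DataFrame(self.genes))
        self.wells = _validate_wells(pd.DataFrame(self.wells))
        if self.counts.shape != (len(self.genes), len(self.wells)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes × {len(self.wells)} wells"
            )
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValidationError("negative values in count matrix")

    # ------------------------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_wells(self) -> int:
        return len(self.wells)

    @property
    def gene_ids(self) -> np.ndarray:
        return self.genes["gene_id"].to_numpy()

    @property
    def cell_ids(self) -> np.ndarray:
        return self.wells["cell_id"].to_numpy()

    def gene_mask(self, gene_class: str) -> np.ndarray:
        return (self.genes["gene_class"] == gene_class).to_numpy()

    @property
    def empty_mask(self) -> np.ndarray:
        return self.wells["is_empty_well"].to_numpy()

    def log_op(self, name: str, **params) -> None:
        """Append an operation record to the provenance history."""
        self.history.append(
            {
                "operation": name,
                "parameters": _jsonable(params),
                "timestamp": _dt.datetime.now(_dt.timezone.utc).isoformat(),
            }
        )

    def counts_checksum(self) -> str:
        """Stable checksum of the raw count layer (order-canonical COO)."""
        coo = self.counts.tocoo()
        order = np.lexsort((coo.col, coo.row))
        h = hashlib.sha256()
        h.update(np.asarray(self.counts.shape, dtype=np.int64).tobytes())
        h.update(coo.row[order].astype(np.int64).tobytes())
        h.update(coo.col[order].astype(np.int64).tobytes())
        h.update(np.asarray(coo.data[order], dtype=np.float64).tobytes())
        return h.hexdigest()

    def subset(self, gene_mask=None, well_mask=None, op: str | None = None
               ) -> "Experiment":
        """Return a new Experiment restricted to masked genes/wells."""
        gm = np.ones(self.n_genes, bool) if gene_mask is None else np.asarray(gene_mask, bool)
        wm = np.ones(self.n_wells, bool) if well_mask is None else np.asarray(well_mask, bool)
        sub = Experiment(
            counts=self.counts[gm][:, wm].copy(),
            genes=self.genes.loc[gm].reset_index(drop=True),
            wells=self.wells.loc[wm].reset_index(drop=True),
            history=list(self.history),
        )
        if op:
            sub.log_op(op, n_genes=int(gm.sum()), n_wells=int(wm.sum()))
        return sub

    def copy(self) -> "Experiment":
        return Experiment(
            counts=self.counts.copy(),
            genes=self.genes.copy(),
            wells=self.wells.copy(),
            history=list(self.history),
        )


@dataclass
class NormalizedExperiment(Experiment):
    """Experiment plus a normalized layer and the size factors that made it.

    ``normalized[g, c] = counts[g, c] / size_factors[c]`` with the factor set
    split between endogenous genes and spike-ins; ``log_layer`` stores
    ``log2(normalized + 1)`` (dense, as clustering and marker tests consume
    it column- and row-wise).
    """

    normalized: sp.spmatrix | None = None
    log_layer: np.ndarray | None = None
    size_factors: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.normalized is not None:
            if not sp.issparse(self.normalized):
                self.normalized = sp.csr_matrix(np.asarray(self.normalized, float))
            if self.normalized.shape != self.counts.shape:
                raise FormatError("normalized layer shape mismatch")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
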