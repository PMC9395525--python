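"""Reading and writing the on-disk exchange formats.

The exchange dialect is the de facto single-cell one: 1-based coordinate
MatrixMarket with genes as rows and wells as columns, gzip accepted
transparently, plus TSV annotation tables and a JSON history sidecar.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .experiment import (
    Experiment,
    FormatError,
    NormalizedExperiment,
    ValidationError,
)

__all__ = ["load_experiment", "save_experiment"]


def _open_maybe_gz(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rb")
    return open(path, "rb")


def _read_mtx(path: Path) -> sp.csr_matrix:
    try:
        with _open_maybe_gz(path) as fh:
            mat = scipy.io.mmread(fh)
    except Exception as exc:  # noqa: BLE001 - surface file name
        raise FormatError(f"cannot parse MatrixMarket file {path}: {exc}") from exc
    return sp.csr_matrix(mat)


def _find(path: str | Path) -> Path:
    """Resolve a path, accepting a missing/present .gz suffix."""
    p = Path(path)
    if p.exists():
        return p
    alt = p.with_suffix(p.suffix + ".gz") if not str(p).endswith(".gz") else Path(str(p)[:-3])
    if alt.exists():
        return alt
    raise FileNotFoundError(path)


def load_experiment(counts_path, genes_path, wells_path) -> Experiment:
    """Load an :class:`Experiment` from MTX + two TSV annotation tables.

    ``gene_class`` is auto-assigned from the spike-in/mito prefixes and the
    TCR constant-region set when the column is absent.  Dimension mismatches
    raise :class:`FormatError` naming the offending file; invalid enum values
    raise :class:`ValidationError` listing the row.
    """
    counts_path = _find(counts_path)
    counts = _read_mtx(counts_path)
    genes = pd.read_csv(genes_path, sep="\t", dtype=str)
    wells_raw = pd.read_csv(wells_path, sep="\t", dtype=str)
    if counts.shape[0] != len(genes):
        raise FormatError(
            f"{counts_path} has {counts.shape[0]} rows but {genes_path} "
            f"lists {len(genes)} genes"
        )
    if counts.shape[1] != len(wells_raw):
        raise FormatError(
            f"{counts_path} has {counts.shape[1]} columns but {wells_path} "
            f"lists {len(wells_raw)} wells"
        )
    wells = wells_raw.copy()
    if "is_empty_well" in wells.columns:
        truthy = {"true": True, "1": True, "false": False, "0": False}
        try:
            wells["is_empty_well"] = [
                truthy[str(v).lower()] for v in wells["is_empty_well"]
            ]
        except KeyError as exc:
            raise ValidationError(f"unparseable is_empty_well value {exc}") from exc
    for col in wells.columns:
        if col.startswith("facs_"):
            wells[col] = pd.to_numeric(wells[col])
    history: list[dict] = []
    hist_path = Path(counts_path).parent / "history.json"
    if hist_path.exists():
        history = json.loads(hist_path.read_text())
    x = Experiment(counts=counts, genes=genes, wells=wells, history=history)
    # raw layers must be integral
    if x.counts.nnz and not np.allclose(x.counts.data, np.round(x.counts.data)):
        raise ValidationError(f"{counts_path} contains non-integer raw counts")
    x.counts = x.counts.astype(np.int64)
    return x


def save_experiment(x: Experiment, out_dir, gzip_mtx: bool = False) -> dict:
    """Write matrix.mtx(.gz), genes.tsv, wells.tsv and history.json.

    Raw counts are written as an integer MTX; a normalized layer, when
    present on a :class:`NormalizedExperiment`, as a real-valued
    normalized.mtx alongside size_factors.tsv.  Returns the written file map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}

    mtx_name = "matrix.mtx.gz" if gzip_mtx else "matrix.mtx"
    mtx_path = out / mtx_name
    opener = gzip.open if gzip_mtx else open
    with opener(mtx_path, "wb") as fh:
        scipy.io.mmwrite(fh, x.counts.astype(np.int64), field="integer")
    written["matrix"] = str(mtx_path)

    x.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    x.wells.to_csv(out / "wells.tsv", sep="\t", index=False)
    written["genes"] = str(out / "genes.tsv")
    written["wells"] = str(out / "wells.tsv")

    if isinstance(x, NormalizedExperiment) and x.normalized is not None:
        with open(out / "normalized.mtx", "wb") as fh:
            scipy.io.mmwrite(fh, x.normalized, field="real")
        written["normalized"] = str(out / "normalized.mtx")
        if x.size_factors is not None:
            x.size_factors.to_csv(out / "size_factors.tsv", sep="\t", index=False)
            written["size_factors"] = str(out / "size_factors.tsv")

    (out / "history.json").write_text(json.dumps(x.history, indent=1))
    written["history"] = str(out / "history.json")
    return written
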