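"""Cell- and gene-level quality control.

Four filters, applied in the order cells → genes:

1. robust outlier removal on per-cell metrics (library size, spike-in
   fraction, mitochondrial fraction) using the scaled median absolute
   deviation (MAD);
2. a gene-complexity window (default 300–4000 detected genes) that catches
   broken cells and sorting aggregates;
3. low-abundance gene removal (all-zero genes plus a mean-expression
   threshold, optionally placed automatically at the first minimum of a
   kernel-density estimate of the log mean distribution);
4. the empty-well noise/signal filter: spike-ins detected in both cell wells
   and empty-control wells (cERCCs) normalise gene expression on each side;
   the per-gene noise/signal ratio (empty-well over cell expression, averaged
   over cERCCs, the cell side averaged over permutation subsamples of cells
   matched in size to the empty-well pool) flags ambient-dominated genes,
   with the threshold placed at the sharp drop of the sorted ratio curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .experiment import Experiment, ValidationError

__all__ = [
    "CellQCMetrics",
    "NoiseSignalTable",
    "QCReport",
    "compute_cell_qc_metrics",
    "filter_cells_mad",
    "filter_cells_complexity",
    "filter_genes_low_abundance",
    "empty_well_noise_filter",
    "detect_sharp_drop",
    "run_qc",
]

MAD_SCALE = 1.4826  # normal-consistency constant


def compute_cell_qc_metrics(x: Experiment) -> pd.DataFrame:
    """Per-well QC metrics: library size, detected genes, ERCC and mito fractions.

    Computed for every well; empty wells are flagged so cell-level statistics
    can exclude them.  Zero-library wells get fractions of 0 and a flag.
    """
    counts = x.counts.tocsr()
    lib = np.asarray(counts.sum(axis=0)).ravel().astype(float)
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel().astype(int)
    ercc = np.asarray(counts[x.gene_mask("ercc")].sum(axis=0)).ravel()
    mito = np.asarray(counts[x.gene_mask("mito")].sum(axis=0)).ravel()
    with np.errstate(divide="ignore", invalid="ignore"):
        ercc_frac = np.where(lib > 0, ercc / np.maximum(lib, 1), 0.0)
        mito_frac = np.where(lib > 0, mito / np.maximum(lib, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": x.cell_ids,
            "library_size": lib,
            "n_genes_detected": n_genes,
            "ercc_fraction": ercc_frac,
            "mito_fraction": mito_frac,
            "is_empty_well": x.empty_mask,
            "zero_library": lib == 0,
        }
    ).set_index("cell_id")


# keep dataclass aliases for the report contract
CellQCMetrics = pd.DataFrame


def _mad_outliers(values: np.ndarray, nmads: float, upper_only: bool
                  ) -> np.ndarray:
    """True where a value deviates more than nmads scaled MADs from the median."""
    med = np.median(values)
    mad = MAD_SCALE * np.median(np.abs(values - med))
    if mad == 0:
        warnings.warn("MAD is zero; this statistic filters nothing",
                      stacklevel=3)
        return np.zeros(len(values), bool)
    dev = (values - med) / mad
    return dev > nmads if upper_only else np.abs(dev) > nmads


def filter_cells_mad(metrics: pd.DataFrame, nmads: float = 3.0
                     ) -> tuple[pd.Series, pd.DataFrame]:
    """Robust outlier mask over non-empty wells.

    A cell is removed when it deviates more than ``nmads`` scaled MADs on
    log2(library_size + 1) (two-sided), ERCC fraction (upper side only) or
    mitochondrial fraction (upper side only).  Returns (keep mask indexed by
    cell_id over non-empty wells, per-cell removal reasons).
    """
    cells = metrics.loc[~metrics["is_empty_well"]]
    if len(cells) < 5:
        warnings.warn("fewer than 5 cells; MAD filtering skipped")
        keep = pd.Series(True, index=cells.index)
        return keep, pd.DataFrame(index=cells.index)
    log_lib = np.log2(cells["library_size"].to_numpy() + 1.0)
    reasons = pd.DataFrame(
        {
            "low_or_high_library": _mad_outliers(log_lib, nmads, upper_only=False),
            "high_ercc": _mad_outliers(
                cells["ercc_fraction"].to_numpy(), nmads, upper_only=True),
            "high_mito": _mad_outliers(
                cells["mito_fraction"].to_numpy(), nmads, upper_only=True),
        },
        index=cells.index,
    )
    keep = ~reasons.any(axis=1)
    return keep, reasons


def filter_cells_complexity(metrics: pd.DataFrame, min_genes: int = 300,
                            max_genes: int = 4000) -> pd.Series:
    """Keep cells whose detected-gene count lies in [min_genes, max_genes].

    The bounds themselves are kept (the window excludes "less than" /
    "more than" the bounds, strictly).
    """
    if min_genes > max_genes:
        raise ValidationError("min_genes exceeds max_genes")
    cells = metrics.loc[~metrics["is_empty_well"]]
    n = cells["n_genes_detected"]
    return (n >= min_genes) & (n <= max_genes)


def filter_genes_low_abundance(
    x: Experiment,
    keep_cells: pd.Series | None = None,
    min_mean: float | str = 0.01,
) -> tuple[np.ndarray, float]:
    """Remove all-zero genes and genes with mean count below a threshold.

    Means are taken over kept, non-empty wells.  ``min_mean="auto"`` places
    the threshold at the first local minimum of a Gaussian KDE of
    log2(mean + 1) — the valley between the drop-out mode and the expressed
    mode — and falls back to 0.01 when the density is unimodal.  Spike-ins
    are exempt (they are handled by normalization, not abundance filtering).
    Returns (keep mask over genes, threshold used).
    """
    well_mask = ~x.empty_mask
    if keep_cells is not None:
        keep_ids = set(keep_cells.index[keep_cells])
        well_mask &= np.isin(x.cell_ids, list(keep_ids))
    sub = x.counts[:, well_mask]
    means = np.asarray(sub.mean(axis=1)).ravel()

    if min_mean == "auto":
        threshold = _auto_mean_threshold(means)
    else:
        threshold = float(min_mean)
    keep = (means > 0) & (means >= threshold)
    keep |= x.gene_mask("ercc")
    return keep, threshold


def _auto_mean_threshold(means: np.ndarray, fallback: float = 0.01) -> float:
    pos = means[means > 0]
    if len(pos) < 10:
        return fallback
    logm = np.log2(means + 1.0)
    grid = np.linspace(logm.min(), logm.max(), 512)
    try:
        dens = gaussian_kde(logm)(grid)
    except np.linalg.LinAlgError:
        return fallback
    # first interior local minimum of the density
    interior = np.flatnonzero(
        (dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:])) + 1
    if len(interior) == 0:
        warnings.warn("log-mean density is unimodal; using fallback threshold")
        return fallback
    return float(2 ** grid[interior[0]] - 1.0)


# ---------------------------------------------------------------------------
# empty-well noise/signal filter


@dataclass
class NoiseSignalTable:
    """Per-gene noise/signal ratios and the spike-ins that normalised them."""

    ratios: pd.Series            # per endogenous(+mito/tcr) gene
    cercc_ids: list[str]
    n_permutations: int
    seed: int
    threshold: float | None = None
    threshold_mode: str = "manual"

    def to_frame(self) -> pd.DataFrame:
        df = self.ratios.rename("noise_signal_ratio").to_frame()
        if self.threshold is not None:
            df["removed"] = df["noise_signal_ratio"] > self.threshold
        return df


def empty_well_noise_filter(
    x: Experiment,
    n_permutations: int = 1000,
    seed: int = 0,
    threshold: float | str = "auto",
    keep_cells: pd.Series | None = None,
    per_cell_ratio: bool = False,
    with_replacement: bool = False,
) -> tuple[np.ndarray, NoiseSignalTable]:
    """Remove genes whose empty-well (ambient) signal rivals their cell signal.

    Procedure: (1) the cERCC set is the spike-ins with nonzero total in cells
    AND in empty wells; (2) for every gene g and cERCC e the cell-side value
    is the mean over ``n_permutations`` random subsamples of cells (each the
    size of the empty-well pool) of mean(g)/mean(e) within the subsample
    (``per_cell_ratio=True`` switches to the per-cell g/e ratio averaged
    within the subsample, undefined cells dropped); the empty-side value is
    mean over empty wells of g over the same for e; (3) the per-gene
    noise/signal ratio is the mean over cERCCs of empty-side / cell-side;
    (4) genes with ratio above the threshold are removed, the threshold
    placed by :func:`detect_sharp_drop` when ``"auto"``.

    Subsampling is keyed to sorted cell ids, so the mask is invariant to
    column order.  Returns (keep mask over genes, NoiseSignalTable); when no
    empty well or no cERCC exists the filter is skipped with a warning and
    keeps everything.
    """
    empty = x.empty_mask
    cell_mask = ~empty
    if keep_cells is not None:
        keep_ids = set(keep_cells.index[keep_cells])
        cell_mask &= np.isin(x.cell_ids, list(keep_ids))
    n_empty = int(empty.sum())
    if n_empty == 0:
        warnings.warn("no empty wells; noise filter skipped")
        return np.ones(x.n_genes, bool), NoiseSignalTable(
            pd.Series(dtype=float), [], n_permutations, seed)

    counts = np.asarray(x.counts.todense(), dtype=float)
    ercc_mask = x.gene_mask("ercc")
    cells = counts[:, cell_mask]
    empties = counts[:, empty]

    cercc = ercc_mask & (cells.sum(axis=1) > 0) & (empties.sum(axis=1) > 0)
    cercc_ids = list(np.asarray(x.gene_ids)[cercc])
    if not cercc_ids:
        warnings.warn("no spike-in detected in both cells and empty wells; "
                      "noise filter skipped")
        return np.ones(x.n_genes, bool), NoiseSignalTable(
            pd.Series(dtype=float), [], n_permutations, seed)

    target = ~ercc_mask
    gene_ids = np.asarray(x.gene_ids)[target]

    # order-independent subsampling: operate on cells sorted by id
    cell_order = np.argsort(x.cell_ids[cell_mask], kind="stable")
    cells = cells[:, cell_order]
    n_cells = cells.shape[1]
    k = min(n_empty, n_cells)
    rng = np.random.default_rng(seed)

    g_cells = cells[target]           # genes × cells
    e_cells = cells[cercc]            # cERCC × cells
    acc = np.zeros((target.sum(), cercc.sum()))
    n_eff = np.zeros_like(acc)
    for _ in range(n_permutations):
        idx = (rng.choice(n_cells, size=k, replace=True) if with_replacement
               else rng.permutation(n_cells)[:k])
        if per_cell_ratio:
            ge = g_cells[:, idx][:, None, :] / np.where(
                e_cells[:, idx] == 0, np.nan, e_cells[:, idx])[None, :, :]
            val = np.nanmean(ge, axis=2)
            good = np.isfinite(val)
            acc[good] += val[good]
            n_eff += good
        else:
            gm = g_cells[:, idx].mean(axis=1)          # mean gene count
            em = e_cells[:, idx].mean(axis=1)          # mean cERCC count
            with np.errstate(divide="ignore", invalid="ignore"):
                val = gm[:, None] / em[None, :]
            good = np.isfinite(val)
            acc[good] += val[good]
            n_eff += good
    with np.errstate(invalid="ignore"):
        cell_side = np.where(n_eff > 0, acc / np.maximum(n_eff, 1), 0.0)

    g_empty = empties[target].mean(axis=1)
    e_empty = empties[cercc].mean(axis=1)
    empty_side = g_empty[:, None] / e_empty[None, :]   # e_empty > 0 by cERCC def

    with np.errstate(divide="ignore", invalid="ignore"):
        per_e = np.where(
            (cell_side == 0) & (empty_side > 0), np.inf,
            np.where((cell_side == 0) & (empty_side == 0), 0.0,
                     empty_side / np.maximum(cell_side, 1e-300)))
    ratios = pd.Series(per_e.mean(axis=1), index=gene_ids,
                       name="noise_signal_ratio")

    mode = "auto" if threshold == "auto" else "manual"
    thr = (detect_sharp_drop(ratios.to_numpy()) if threshold == "auto"
           else float(threshold))
    keep = np.ones(x.n_genes, bool)
    removed = ratios.index[ratios > thr]
    keep[np.isin(x.gene_ids, removed)] = False
    table = NoiseSignalTable(ratios, cercc_ids, n_permutations, seed,
                             threshold=thr, threshold_mode=mode)
    return keep, table


def detect_sharp_drop(ratios: np.ndarray, min_gap: float = 0.3,
                      gap_dominance: float = 4.0) -> float:
    """Threshold at the sharp drop of the descending sorted ratio curve.

    Positive ratios are sorted descending and examined on a log scale (they
    span orders of magnitude).  The drop is the largest gap between
    consecutive sorted values — equivalently the point of maximal negative
    curvature of the cumulative curve — and the threshold is the geometric
    mean across it.  Zero ratios lie below any positive threshold and carry
    no information about where the drop sits, so they are excluded.  A drop
    only counts as sharp when it spans at least ``min_gap`` decades and
    dominates the neighbouring gaps by ``gap_dominance``×; otherwise (e.g. a
    featureless ramp) the 99th percentile is returned as a documented
    fallback.
    """
    finite = np.asarray(ratios, float)
    finite = finite[np.isfinite(finite)]
    if len(finite) < 10:
        raise ValidationError(
            "fewer than 10 finite noise/signal ratios; supply a manual threshold")
    pos = finite[finite > 0]
    if len(pos) < 4:
        warnings.warn("too few positive ratios for a knee; "
                      "falling back to 99th percentile")
        return float(np.percentile(finite, 99))
    srt = np.sort(pos)[::-1]
    curve = np.log10(srt)
    gaps = curve[:-1] - curve[1:]           # gap i sits between srt[i], srt[i+1]
    i = int(np.argmax(gaps))
    window = gaps[max(0, i - 10): i + 11]
    neighbours = np.delete(window, np.argmax(window))
    local = float(np.median(neighbours)) if len(neighbours) else 0.0
    if gaps[i] < min_gap or gaps[i] < gap_dominance * local:
        warnings.warn("no sharp drop found; falling back to 99th percentile")
        return float(np.percentile(finite, 99))
    # geometric mean across the drop separates the two plateaus
    return float(np.sqrt(srt[i] * srt[i + 1]))


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class QCReport:
    """Everything QC decided: masks, metrics, ratios and applied thresholds."""

    keep_cell: pd.Series                 # over non-empty wells
    keep_gene: pd.Series                 # over genes
    thresholds: dict = field(default_factory=dict)
    metrics: pd.DataFrame | None = None
    removal_reasons: pd.DataFrame | None = None
    noise: NoiseSignalTable | None = None

    def summary(self) -> str:
        nc, ng = int(self.keep_cell.sum()), int(self.keep_gene.sum())
        return (f"QC kept {nc}/{len(self.keep_cell)} cells and "
                f"{ng}/{len(self.keep_gene)} genes; thresholds: "
                f"{self.thresholds}")


def run_qc(
    x: Experiment,
    nmads: float = 3.0,
    min_genes: int = 300,
    max_genes: int = 4000,
    min_mean: float | str = 0.01,
    noise_threshold: float | str = "auto",
    n_permutations: int = 1000,
    seed: int = 0,
) -> tuple[Experiment, QCReport]:
    """Full QC pass: cell filters, then gene filters on surviving cells.

    Returns the filtered experiment (empty wells dropped — they play no
    further role after QC) and the report.
    """
    metrics = compute_cell_qc_metrics(x)
    keep_mad, reasons = filter_cells_mad(metrics, nmads=nmads)
    keep_cplx = filter_cells_complexity(metrics, min_genes, max_genes)
    keep_cell = keep_mad & keep_cplx

    keep_gene_ab, mean_thr = filter_genes_low_abundance(
        x, keep_cells=keep_cell, min_mean=min_mean)
    keep_gene_noise, noise = empty_well_noise_filter(
        x, n_permutations=n_permutations, seed=seed,
        threshold=noise_threshold, keep_cells=keep_cell)
    keep_gene = keep_gene_ab & keep_gene_noise

    thresholds = {
        "nmads": nmads,
        "min_genes": min_genes,
        "max_genes": max_genes,
        "min_mean": mean_thr,
        "noise_threshold": noise.threshold,
        "n_permutations": n_permutations,
        "seed": seed,
    }
    report = QCReport(
        keep_cell=keep_cell,
        keep_gene=pd.Series(keep_gene, index=x.gene_ids),
        thresholds=thresholds,
        metrics=metrics,
        removal_reasons=reasons,
        noise=noise,
    )
    well_keep = (~x.empty_mask) & pd.Series(
        keep_cell, index=keep_cell.index).reindex(x.cell_ids, fill_value=False).to_numpy()
    filtered = x.subset(gene_mask=keep_gene, well_mask=well_keep, op="run_qc")
    filtered.log_op("qc_thresholds", **thresholds)
    return filtered, report


def save_qc_report(report: QCReport, out_dir) -> None:
    """Serialise the report as TSV tables plus a JSON threshold sidecar."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cells = report.metrics.copy()
    cells["keep"] = report.keep_cell.reindex(cells.index)
    if report.removal_reasons is not None and len(report.removal_reasons):
        cells = cells.join(report.removal_reasons)
    cells.to_csv(out / "qc_cells.tsv", sep="\t")
    genes = report.keep_gene.rename("keep").to_frame()
    if report.noise is not None and len(report.noise.ratios):
        genes = genes.join(report.noise.ratios)
    genes.to_csv(out / "qc_genes.tsv", sep="\t", index_label="gene_id")
    thr = {k: (None if v is None else float(v) if isinstance(v, (int, float)) else v)
           for k, v in report.thresholds.items()}
    (out / "qc_thresholds.json").write_text(json.dumps(thr, indent=1))
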