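"""Graph-based clustering, marker annotation and 2-D embedding.

Pipeline: log layer → top highly-variable genes by dispersion rank → PCA →
kNN graph in PC space → modularity community detection (Leiden), labels
relabelled C0, C1, ... by descending cluster size.  Annotation scores each
cluster against a canonical immune marker panel by expressing-cell
fractions.  The 2-D embedding (UMAP) is visualisation-only; nothing
downstream may consume the coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .experiment import NormalizedExperiment, ValidationError

__all__ = [
    "ClusterAssignment",
    "MarkerMap",
    "DEFAULT_MARKER_MAP",
    "cluster_cells",
    "annotate_clusters",
    "embed_2d",
    "select_hvgs",
]

#: canonical immune lineage panel: type → [(symbol, direction)]
DEFAULT_MARKER_MAP: dict[str, list[tuple[str, str]]] = {
    "T": [("CD3D", "high"), ("CD3E", "high")],
    "PC": [("SDC1", "high")],
    "MF-DC": [("ITGAX", "high"), ("HLA-DRA", "high"), ("CD14", "high")],
    "MC": [("KIT", "high"), ("TPSB2", "high"), ("CPA3", "high")],
    "B": [("MS4A1", "high")],
    "NK": [("GNLY", "high"), ("NKG7", "high"),
           ("CD3D", "low"), ("CD3E", "low")],
    "ILC": [("KIT", "high"), ("CD3D", "low"), ("CD3E", "low"),
            ("TPSB2", "low"), ("CPA3", "low")],
}

MarkerMap = dict


@dataclass
class ClusterAssignment:
    labels: pd.Series            # cell_id → "C0", "C1", ... by size desc
    k_neighbors: int
    resolution: float
    seed: int
    n_clusters: int = 0
    pcs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.n_clusters = int(self.labels.nunique())

    def members(self, label: str) -> np.ndarray:
        return self.labels.index[self.labels == label].to_numpy()


def select_hvgs(nx: NormalizedExperiment, n_top: int = 2000) -> np.ndarray:
    """Highly-variable genes by dispersion (variance/mean) rank on the
    normalized layer; spike-ins excluded."""
    norm = np.asarray(nx.normalized.todense(), float)
    mean = norm.mean(axis=1)
    var = norm.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / mean, 0.0)
    disp[nx.gene_mask("ercc")] = -np.inf
    order = np.argsort(-disp, kind="stable")
    keep = np.zeros(nx.n_genes, bool)
    keep[order[: min(n_top, int((disp > -np.inf).sum()))]] = True
    return keep


def _pca_matrix(nx: NormalizedExperiment, n_hvgs: int, n_pcs: int,
                seed: int) -> np.ndarray:
    hvg = select_hvgs(nx, n_hvgs)
    X = nx.log_layer[hvg].T                     # cells × genes
    # center & unit-scale genes, capped like the standard single-cell recipe
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = np.clip((X - mu) / sd, -10, 10)
    n_pcs_eff = min(n_pcs, min(X.shape) - 1)
    if n_pcs_eff < n_pcs:
        warnings.warn(f"n_pcs lowered to {n_pcs_eff} for {X.shape[0]} cells")
    if n_pcs_eff < 1:
        return X
    pca = PCA(n_components=n_pcs_eff, svd_solver="full", random_state=seed)
    pcs = pca.fit_transform(X)
    # sign convention: make the largest-|loading| entry positive
    for j in range(pcs.shape[1]):
        i = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, i] < 0:
            pcs[:, j] *= -1
    return pcs


def cluster_cells(
    nx: NormalizedExperiment,
    k_neighbors: int = 15,
    resolution: float = 0.8,
    n_pcs: int = 30,
    n_hvgs: int = 2000,
    seed: int = 0,
) -> ClusterAssignment:
    """Leiden community detection on the kNN graph of PC space.

    Deterministic given the seed; labels are canonical (C0 is always the
    largest cluster) and invariant to gene and cell order.
    """
    if nx.n_wells < k_neighbors + 1:
        raise ValidationError(
            f"need at least k_neighbors+1={k_neighbors + 1} cells, "
            f"have {nx.n_wells}")
    # canonical cell order so clustering is invariant to column order
    order = np.argsort(nx.cell_ids, kind="stable")
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))

    pcs = _pca_matrix(nx, n_hvgs, n_pcs, seed)[order]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(pcs)
    _, idx = nn.kneighbors(pcs)
    edges = {(min(i, j), max(i, j))
             for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=len(pcs), edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed, n_iterations=-1)
    membership = np.asarray(part.membership)

    # relabel by size descending, ties broken by lowest member index
    sizes = pd.Series(membership).value_counts()
    first = {c: int(np.flatnonzero(membership == c)[0]) for c in sizes.index}
    ranked = sorted(sizes.index, key=lambda c: (-sizes[c], first[c]))
    remap = {c: f"C{r}" for r, c in enumerate(ranked)}
    labels_sorted = np.array([remap[c] for c in membership], dtype=object)
    labels = pd.Series(labels_sorted[inv], index=nx.cell_ids, name="cluster")
    return ClusterAssignment(
        labels=labels, k_neighbors=k_neighbors, resolution=resolution,
        seed=seed, pcs=pcs[inv])


def annotate_clusters(
    nx: NormalizedExperiment,
    clusters: ClusterAssignment,
    markers: MarkerMap | None = None,
) -> pd.DataFrame:
    """Assign a cell-type name to each cluster from a marker panel.

    score(type) = mean over "high" markers of the fraction of the cluster's
    cells expressing the marker, minus the same mean over "low" markers;
    the argmax wins, exact ties give "unassigned".  Marker symbols missing
    from the gene table are ignored with a warning.
    """
    markers = DEFAULT_MARKER_MAP if markers is None else markers
    sym_pos = {}
    for i, s in enumerate(nx.genes["symbol"]):
        sym_pos.setdefault(s, i)
    resolvable = {
        t: [(g, d) for g, d in gs if g in sym_pos]
        for t, gs in markers.items()
    }
    dropped = sorted({g for gs in markers.values() for g, _ in gs}
                     - set(sym_pos))
    if dropped:
        warnings.warn(f"marker symbols not in gene table, ignored: {dropped}")
    if not any(resolvable.values()):
        raise ValidationError("no marker of any type present in gene table")

    norm = np.asarray(nx.normalized.todense(), float)
    expressed = norm > 0
    rows = []
    for label in sorted(clusters.labels.unique(), key=lambda s: int(s[1:])):
        in_cluster = (clusters.labels == label).reindex(nx.cell_ids).to_numpy()
        scores = {}
        for t, gs in resolvable.items():
            hi = [sym_pos[g] for g, d in gs if d == "high"]
            lo = [sym_pos[g] for g, d in gs if d == "low"]
            s = 0.0
            if hi:
                s += float(np.mean(
                    [expressed[g, in_cluster].mean() for g in hi]))
            if lo:
                s -= float(np.mean(
                    [expressed[g, in_cluster].mean() for g in lo]))
            scores[t] = s
        best = max(scores.values())
        winners = [t for t, s in scores.items() if s == best]
        rows.append({
            "cluster": label,
            "cell_type": winners[0] if len(winners) == 1 else "unassigned",
            "score": best,
            **{f"score_{t}": s for t, s in scores.items()},
        })
    return pd.DataFrame(rows).set_index("cluster")


def embed_2d(nx: NormalizedExperiment, seed: int = 0, n_pcs: int = 30,
             n_hvgs: int = 2000, pcs: np.ndarray | None = None
             ) -> pd.DataFrame:
    """UMAP of the PC space, for figures only."""
    import umap

    if pcs is None:
        pcs = _pca_matrix(nx, n_hvgs, n_pcs, seed)
    reducer = umap.UMAP(n_components=2, random_state=seed)
    coords = reducer.fit_transform(pcs)
    return pd.DataFrame(coords, columns=["umap_x", "umap_y"],
                        index=pd.Index(nx.cell_ids, name="cell_id"))
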