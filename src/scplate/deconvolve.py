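"""Signature-based bulk deconvolution.

Builds a genes × types signature matrix of mean normalized expression over
a marker basis, then estimates per-sample type proportions by nonnegative
least squares on the shared-gene subspace, rescaled to the simplex.  This
is the single-reference core of the published multi-reference ensemble
approach; the ensemble weighting is deliberately not reproduced and the
divergence is recorded in the result metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .cluster import ClusterAssignment
from .experiment import NormalizedExperiment, ValidationError
from .markers import wilcoxon_markers

__all__ = ["SignatureMatrix", "DeconvResult", "build_signature",
           "nnls_deconvolve"]


@dataclass
class SignatureMatrix:
    values: pd.DataFrame          # genes × types, mean normalized expression
    basis_genes: list[str]

    @property
    def types(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class DeconvResult:
    proportions: pd.DataFrame     # samples × types, rows on the simplex
    residual_norm: pd.Series
    flags: pd.Series              # e.g. "all_zero_bulk"
    metadata: dict = field(default_factory=dict)


def build_signature(
    nx: NormalizedExperiment,
    labels: pd.Series,
    markers_per_type: int = 50,
) -> SignatureMatrix:
    """Mean-expression signature over the union of top per-type markers.

    Marker ranking comes from the cluster-vs-rest rank-sum test with the
    type labels standing in for clusters; types with fewer than 3 cells are
    excluded with a warning.
    """
    labels = labels.reindex(nx.cell_ids)
    sizes = labels.value_counts()
    small = sizes.index[sizes < 3].tolist()
    if small:
        warnings.warn(f"types with <3 cells excluded from signature: {small}")
    types = sorted(sizes.index[sizes >= 3])
    if len(types) < 2:
        raise ValidationError("need at least 2 types with ≥3 cells")

    # relabel types as pseudo-clusters for the marker machinery
    remap = {t: f"C{i}" for i, t in enumerate(types)}
    pseudo = labels.map(remap).dropna()
    sub_mask = np.isin(nx.cell_ids, pseudo.index)
    sub = _subset_normalized(nx, sub_mask)
    assign = ClusterAssignment(
        labels=pseudo.reindex(sub.cell_ids), k_neighbors=0, resolution=0.0,
        seed=0)
    table = wilcoxon_markers(sub, assign, min_pct=0.0, min_log2_fc=0.0)

    basis: list[str] = []
    inv = {v: k for k, v in remap.items()}
    for c in sorted(inv):
        top = (table[(table["cluster"] == c) & (table["log2_fc"] > 0)]
               .sort_values("p_value")["gene_id"]
               .head(markers_per_type))
        basis.extend(g for g in top if g not in basis)
    if not basis:
        basis = list(nx.gene_ids)

    norm = np.asarray(nx.normalized.todense(), float)
    gene_pos = {g: i for i, g in enumerate(nx.gene_ids)}
    rows = [gene_pos[g] for g in basis]
    cols = {}
    for t in types:
        mask = (labels == t).to_numpy()
        cols[t] = norm[np.ix_(rows, mask)].mean(axis=1)
    values = pd.DataFrame(cols, index=pd.Index(basis, name="gene_id"))
    zero_cols = values.columns[(values.sum(axis=0) == 0)].tolist()
    if zero_cols:
        raise ValidationError(f"all-zero signature column(s): {zero_cols}")
    return SignatureMatrix(values=values, basis_genes=basis)


def _subset_normalized(nx: NormalizedExperiment, mask: np.ndarray
                       ) -> NormalizedExperiment:
    return NormalizedExperiment(
        counts=nx.counts[:, mask],
        genes=nx.genes.copy(),
        wells=nx.wells.loc[mask].reset_index(drop=True),
        history=list(nx.history),
        normalized=nx.normalized[:, mask],
        log_layer=nx.log_layer[:, mask],
        size_factors=None,
    )


def nnls_deconvolve(bulk: pd.DataFrame, sig: SignatureMatrix) -> DeconvResult:
    """Estimate type proportions in bulk profiles.

    Per sample: min ‖S·w − b‖² s.t. w ≥ 0 on the genes shared between bulk
    and signature, then w rescaled to sum 1; the residual of the unscaled
    fit is reported.  All-zero bulk samples get uniform proportions and a
    flag.
    """
    bulk = pd.DataFrame(bulk)
    if (np.asarray(bulk) < 0).any():
        raise ValidationError("bulk matrix contains negative values")
    shared = sig.values.index.intersection(bulk.index)
    if len(shared) == 0:
        raise ValidationError("no genes shared between bulk and signature")
    S = sig.values.loc[shared].to_numpy(float)
    B = bulk.loc[shared].to_numpy(float)
    n_types = S.shape[1]
    props, resids, flags = [], [], []
    for j, sample in enumerate(bulk.columns):
        b = B[:, j]
        if b.sum() == 0:
            props.append(np.full(n_types, 1.0 / n_types))
            resids.append(0.0)
            flags.append("all_zero_bulk")
            continue
        w, r = nnls(S, b)
        total = w.sum()
        if total == 0:
            props.append(np.full(n_types, 1.0 / n_types))
            flags.append("zero_fit")
        else:
            props.append(w / total)
            flags.append("")
        resids.append(float(r))
    proportions = pd.DataFrame(
        props, index=pd.Index(bulk.columns, name="sample"),
        columns=sig.types)
    return DeconvResult(
        proportions=proportions,
        residual_norm=pd.Series(resids, index=proportions.index),
        flags=pd.Series(flags, index=proportions.index),
        metadata={
            "n_shared_genes": int(len(shared)),
            "method": "single-reference NNLS on marker basis; "
                      "no multi-reference ensemble weighting",
        },
    )
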