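"""Cluster-composition testing, TCR lineage calls and panel aggregation.

The composition test follows the subsampling scheme the analysis is built
around: ten independent 50% without-replacement subsamples drawn per
cluster; within each condition the subsampled cells are tallied into
cluster percentages (summing to 100 across clusters per replicate); each
cluster × condition-pair difference is then assessed by a two-sided
Student t-test over the replicate percentages.  Note the replicates share
cells, so the test is anti-conservative relative to a donor-level test —
it reproduces the published procedure, not a calibrated alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterAssignment
from .experiment import NormalizedExperiment, ValidationError

__all__ = [
    "CompositionResult",
    "subsample_proportion_test",
    "classify_tcr",
    "panel_mean_table",
]

TCR_AB = ("TRAC", "TRBC1", "TRBC2")
TCR_GD = ("TRGC1", "TRGC2", "TRDC")


@dataclass
class CompositionResult:
    percentages: pd.DataFrame    # tidy: cluster, condition, replicate, pct
    tests: pd.DataFrame          # cluster, cond_a, cond_b, t, p, degenerate
    n_subsamples: int
    subsample_fraction: float
    seed: int
    equal_var: bool = True
    mode: str = "per_cluster"

    def mean_pct(self) -> pd.DataFrame:
        return (self.percentages.groupby(["cluster", "condition"])["pct"]
                .mean().unstack())


def subsample_proportion_test(
    clusters: ClusterAssignment,
    wells: pd.DataFrame,
    n_subsamples: int = 10,
    fraction: float = 0.5,
    seed: int = 0,
    equal_var: bool = True,
    mode: str = "per_cluster",
) -> CompositionResult:
    """Subsampling-based test of cluster composition differences.

    Per replicate, ⌈fraction·n⌉ cells are drawn without replacement from
    each cluster (``mode="per_condition"`` draws within condition instead);
    percentages are computed within condition across clusters, so the
    replicate-to-replicate spread comes from the varying condition mix of
    each cluster's subsample.  Each (cluster, condition pair) is tested with
    a two-sided Student t (``equal_var=False`` switches to Welch).  Draw
    order is keyed to sorted cell ids, so results are invariant to cell
    ordering.  At ``fraction=1.0`` the subsample is the full data and
    identical cluster membership across conditions yields p = 1 exactly.
    """
    wells = pd.DataFrame(wells)
    cond_of = wells.set_index("cell_id")["condition"]
    labels = clusters.labels
    conds = cond_of.reindex(labels.index)
    if conds.isna().any():
        raise ValidationError("well table missing some clustered cells")
    conditions = sorted(conds.unique())
    if len(conditions) < 2:
        raise ValidationError("need at least 2 conditions")
    cluster_names = sorted(labels.unique(), key=lambda s: int(s[1:]))

    rng = np.random.default_rng(seed)
    if mode == "per_cluster":
        strata = list(cluster_names)
        members_of = {cl: np.sort(labels.index[(labels == cl).to_numpy()])
                      for cl in cluster_names}
    elif mode == "per_condition":
        strata = list(conditions)
        members_of = {cond: np.sort(labels.index[(conds == cond).to_numpy()])
                      for cond in conditions}
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    rows = []
    for rep in range(n_subsamples):
        chosen: list[str] = []
        for g in strata:
            members = members_of[g]
            if len(members) == 0:
                continue
            k = int(np.ceil(fraction * len(members)))
            chosen.extend(rng.permutation(members)[:k])
        sub = pd.Index(chosen)
        sub_cond = conds.loc[sub]
        sub_lab = labels.loc[sub]
        for cond in conditions:
            in_cond = sub_cond == cond
            total = int(in_cond.sum())
            for cl in cluster_names:
                n = int((sub_lab[in_cond] == cl).sum())
                pct = 100.0 * n / total if total else 0.0
                rows.append((cl, cond, rep, pct))
    pct_df = pd.DataFrame(rows, columns=["cluster", "condition", "replicate",
                                         "pct"])

    test_rows = []
    for cl in cluster_names:
        for ca, cb in combinations(conditions, 2):
            a = pct_df.query("cluster == @cl and condition == @ca")["pct"].to_numpy()
            b = pct_df.query("cluster == @cl and condition == @cb")["pct"].to_numpy()
            degenerate = False
            if np.ptp(a) == 0 and np.ptp(b) == 0:
                if a[0] == b[0]:
                    t, p = 0.0, 1.0
                else:
                    t = np.inf if a[0] > b[0] else -np.inf
                    p = 1e-16
                    degenerate = True
            else:
                t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            test_rows.append((cl, ca, cb, float(t), float(p), degenerate))
    tests = pd.DataFrame(test_rows, columns=["cluster", "cond_a", "cond_b",
                                             "t_statistic", "p_value",
                                             "degenerate"])
    return CompositionResult(pct_df, tests, n_subsamples, fraction, seed,
                             equal_var, mode)


# ---------------------------------------------------------------------------
# TCR lineage


def classify_tcr(nx: NormalizedExperiment) -> pd.DataFrame:
    """alpha/beta vs gamma/delta lineage from TCR constant-region expression.

    ab_score sums the normalized TRAC/TRBC1/TRBC2 expression, gd_score the
    TRGC1/TRGC2/TRDC expression; the larger score wins, equal scores (incl.
    both zero) give "unassigned".  Scale-invariant per cell by construction
    of the comparison.
    """
    sym = nx.genes["symbol"].to_numpy()
    ab_idx = [i for i, s in enumerate(sym) if s in TCR_AB]
    gd_idx = [i for i, s in enumerate(sym) if s in TCR_GD]
    if not ab_idx and not gd_idx:
        raise ValidationError(
            "none of the six TCR constant-region genes present")
    norm = np.asarray(nx.normalized.todense(), float)
    ab = norm[ab_idx].sum(axis=0) if ab_idx else np.zeros(nx.n_wells)
    gd = norm[gd_idx].sum(axis=0) if gd_idx else np.zeros(nx.n_wells)
    call = np.where(ab > gd, "alpha_beta",
                    np.where(gd > ab, "gamma_delta", "unassigned"))
    return pd.DataFrame(
        {"call": call, "ab_score": ab, "gd_score": gd},
        index=pd.Index(nx.cell_ids, name="cell_id"))


# ---------------------------------------------------------------------------
# gene-panel aggregation (GWAS panels, cytokine heatmaps)


def panel_mean_table(
    nx: NormalizedExperiment,
    panel: list[str],
    group_by: pd.Series | list[pd.Series],
    z_scale: bool = False,
) -> tuple[pd.DataFrame, list[str]]:
    """Mean log expression of a gene panel per cell group.

    ``group_by`` is one or more per-cell label series (e.g. condition and
    annotated cell type); groups are their tuple combinations.  Panel
    symbols missing from the gene table are returned in the missing list,
    not an error.  ``z_scale`` standardises each gene across groups for
    display.  Empty groups yield NaN columns.
    """
    if isinstance(group_by, pd.Series):
        group_by = [group_by]
    sym_pos = {}
    for i, s in enumerate(nx.genes["symbol"]):
        sym_pos.setdefault(s, i)
    present = [g for g in panel if g in sym_pos]
    missing = [g for g in panel if g not in sym_pos]

    keys = pd.DataFrame(
        {f"g{i}": g.reindex(nx.cell_ids) for i, g in enumerate(group_by)})
    group_label = keys.astype(str).agg("|".join, axis=1)
    log = nx.log_layer
    cols = {}
    for grp in sorted(group_label.dropna().unique()):
        mask = (group_label == grp).to_numpy()
        if mask.sum() == 0:
            cols[grp] = np.full(len(present), np.nan)
        else:
            cols[grp] = log[[sym_pos[g] for g in present]][:, mask].mean(axis=1)
    table = pd.DataFrame(cols, index=pd.Index(present, name="symbol"))
    if z_scale and table.shape[1] > 1:
        mu = table.mean(axis=1)
        sd = table.std(axis=1, ddof=0).replace(0, 1.0)
        table = table.sub(mu, axis=0).div(sd, axis=0)
    return table, missing
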