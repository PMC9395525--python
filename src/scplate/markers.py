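"""Marker-gene statistics and gene-set enrichment.

Two cluster-vs-rest tests on the log-normalized layer:

* the Wilcoxon rank-sum test — exact null by enumeration when both groups
  hold at most 8 cells and the gene has no ties, normal approximation with
  tie and continuity correction otherwise; family-wise (Bonferroni)
  adjustment by default;
* a moderated t-statistic — per-gene residual variances shrunk toward a
  common prior fitted by method of moments on the log sample variances
  (the classic empirical-Bayes formulation), BH adjustment.

Plus one-sided hypergeometric gene-set enrichment with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment
from .experiment import NormalizedExperiment, ValidationError

__all__ = [
    "wilcoxon_markers",
    "moderated_t_markers",
    "enrich_gene_sets",
    "moderated_t_statistics",
    "fit_variance_prior",
    "read_gmt",
]

EXACT_MAX_N = 8


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _rank_sum_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Two-sided rank-sum p-values for each row of a (genes × cells) split.

    Rows where both groups are small and tie-free use the exact null;
    the rest the tie-corrected normal approximation with continuity
    correction.
    """
    n1, n2 = a.shape[1], b.shape[1]
    p = np.empty(a.shape[0])
    small = n1 <= EXACT_MAX_N and n2 <= EXACT_MAX_N
    if small:
        for i in range(a.shape[0]):
            x, y = a[i], b[i]
            tied = len(np.unique(np.concatenate([x, y]))) < n1 + n2
            method = "asymptotic" if tied else "exact"
            p[i] = stats.mannwhitneyu(
                x, y, alternative="two-sided", method=method,
                use_continuity=True).pvalue
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1)
        p[:] = np.asarray(res.pvalue)
    return np.clip(p, 0.0, 1.0)


def wilcoxon_markers(
    nx: NormalizedExperiment,
    clusters: ClusterAssignment,
    min_pct: float = 0.1,
    min_log2_fc: float = 0.25,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Cluster-vs-rest rank-sum marker table.

    Genes enter a cluster's test when expressed in at least ``min_pct`` of
    cells on either side and |log2 fold change| ≥ ``min_log2_fc``; p-values
    are family-wise adjusted over the genes actually tested per cluster.
    """
    if clusters.labels.nunique() < 2:
        raise ValidationError("need at least 2 clusters for marker detection")
    log = nx.log_layer
    norm = np.asarray(nx.normalized.todense(), float)
    rows = []
    label_order = sorted(clusters.labels.unique(), key=lambda s: int(s[1:]))
    for label in label_order:
        in_c = (clusters.labels == label).reindex(nx.cell_ids).to_numpy()
        if in_c.sum() < 3:
            warnings.warn(f"cluster {label} has <3 cells; skipped")
            continue
        out_c = ~in_c
        mean_in = log[:, in_c].mean(axis=1)
        mean_out = log[:, out_c].mean(axis=1)
        lfc = mean_in - mean_out
        pct_in = (norm[:, in_c] > 0).mean(axis=1)
        pct_out = (norm[:, out_c] > 0).mean(axis=1)
        tested = (np.maximum(pct_in, pct_out) >= min_pct) & \
            (np.abs(lfc) >= min_log2_fc)
        if not tested.any():
            continue
        idx = np.flatnonzero(tested)
        pvals = _rank_sum_pvalues(log[idx][:, in_c], log[idx][:, out_c])
        padj = _adjust(pvals, correction)
        for j, gi in enumerate(idx):
            rows.append((nx.gene_ids[gi], label, lfc[gi], pct_in[gi],
                         pct_out[gi], pvals[j], padj[j], "wilcoxon"))
    return pd.DataFrame(
        rows, columns=["gene_id", "cluster", "log2_fc", "pct_in", "pct_out",
                       "p_value", "p_adjusted", "test"])


def _adjust(p: np.ndarray, method: str) -> np.ndarray:
    if len(p) == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method in ("bh", "fdr_bh"):
        return multipletests(p, method="fdr_bh")[1]
    raise ValidationError(f"unknown correction {method!r}")


# ---------------------------------------------------------------------------
# moderated t


@dataclass
class VariancePrior:
    d0: float        # prior degrees of freedom (may be inf)
    s0_sq: float     # prior variance


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(s_sq: np.ndarray, df: float) -> VariancePrior:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Works on z = log(s²): the mean and excess variance of z over its known
    sampling moments identify the prior degrees of freedom d0 and scale s0².
    Degenerate inputs (all variances equal) give d0 = ∞, i.e. complete
    shrinkage to the common value.
    """
    s_sq = np.asarray(s_sq, float)
    ok = np.isfinite(s_sq) & (s_sq > 0)
    z = np.log(s_sq[ok])
    if len(z) < 2 or np.allclose(z, z[0]):
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(z.mean()) if len(z)
                                                    else 1.0))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    excess = float(np.var(e, ddof=1) - special.polygamma(1, df / 2.0))
    if excess <= 0:
        return VariancePrior(d0=np.inf, s0_sq=float(np.exp(e.mean())))
    d0 = 2.0 * _trigamma_inverse(excess)
    s0_sq = float(np.exp(e.mean() + special.digamma(d0 / 2.0)
                         - np.log(d0 / 2.0)))
    return VariancePrior(d0=d0, s0_sq=s0_sq)


def moderated_t_statistics(
    a: np.ndarray, b: np.ndarray, prior: VariancePrior | None = None
) -> pd.DataFrame:
    """Moderated two-group t for each row of a genes × cells split.

    Residual (pooled) variances s_g² on d_g = n1+n2−2 df are shrunk to
    s̃_g² = (d0·s0² + d_g·s_g²)/(d0 + d_g); the statistic
    Δmean / (s̃_g·√(1/n1+1/n2)) is referred to a t distribution on
    d0 + d_g df.  ``prior=None`` fits (d0, s0²) from the data; d0 = 0
    reproduces the ordinary pooled t, d0 = ∞ the fully-shrunk statistic.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least 2 cells per group")
    df = n1 + n2 - 2
    delta = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s_sq = ss / df
    if prior is None:
        prior = fit_variance_prior(s_sq, df)
    d0, s0 = prior.d0, prior.s0_sq
    if np.isinf(d0):
        s_tilde = np.full_like(s_sq, s0)
        df_total = np.inf
    else:
        s_tilde = (d0 * s0 + df * s_sq) / (d0 + df)
        df_total = d0 + df
    denom = np.sqrt(s_tilde * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, delta / denom, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({
        "delta": delta, "t": t, "p_value": np.clip(p, 0, 1),
        "s_sq": s_sq, "s_tilde_sq": s_tilde,
        "df_total": df_total, "d0": d0, "s0_sq": s0,
    })


def moderated_t_markers(
    nx: NormalizedExperiment,
    clusters: ClusterAssignment,
    prior: VariancePrior | None = None,
    pairwise: bool = False,
) -> pd.DataFrame:
    """Cluster-vs-rest (or all-pairs) moderated-t marker table, BH-adjusted."""
    if clusters.labels.nunique() < 2:
        raise ValidationError("need at least 2 clusters for marker detection")
    log = nx.log_layer
    norm = np.asarray(nx.normalized.todense(), float)
    label_order = sorted(clusters.labels.unique(), key=lambda s: int(s[1:]))
    contrasts = ([(la, lb) for i, la in enumerate(label_order)
                  for lb in label_order[i + 1:]] if pairwise
                 else [(la, None) for la in label_order])
    rows = []
    for la, lb in contrasts:
        in_c = (clusters.labels == la).reindex(nx.cell_ids).to_numpy()
        other = ((clusters.labels == lb).reindex(nx.cell_ids).to_numpy()
                 if lb else ~in_c)
        if in_c.sum() < 3 or other.sum() < 3:
            warnings.warn(f"contrast {la} vs {lb or 'rest'} has <3 cells; skipped")
            continue
        res = moderated_t_statistics(log[:, in_c], log[:, other], prior)
        padj = multipletests(res["p_value"], method="fdr_bh")[1]
        pct_in = (norm[:, in_c] > 0).mean(axis=1)
        pct_out = (norm[:, other] > 0).mean(axis=1)
        cname = la if lb is None else f"{la}_vs_{lb}"
        for gi in range(nx.n_genes):
            rows.append((nx.gene_ids[gi], cname, res["delta"][gi],
                         pct_in[gi], pct_out[gi], res["p_value"][gi],
                         padj[gi], "moderated_t"))
    return pd.DataFrame(
        rows, columns=["gene_id", "cluster", "log2_fc", "pct_in", "pct_out",
                       "p_value", "p_adjusted", "test"])


# ---------------------------------------------------------------------------
# gene-set enrichment


def enrich_gene_sets(
    hits: list[str],
    sets: dict[str, list[str]],
    universe: list[str],
    alpha: float = 1e-3,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation with BH correction.

    Each set is intersected with the universe before testing; significance
    is ``p_adjusted < alpha`` (default 1e-3).
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValidationError("empty universe")
    hit_set = set(hits)
    if not hit_set <= universe_set:
        raise ValidationError("hits must be a subset of the universe")
    N, n = len(universe_set), len(hit_set)
    rows = []
    for name, members in sets.items():
        m = universe_set & set(members)
        k = len(hit_set & m)
        K = len(m)
        # P[X >= k] for X ~ Hypergeom(N, K, n)
        p = 1.0 if K == 0 or k == 0 else float(
            stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((name, k, K, n, N, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                     "hits_size", "universe_size", "p_value"])
    if len(df):
        df["p_adjusted"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["significant"] = df["p_adjusted"] < alpha
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Gene sets from a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = [g for g in parts[2:] if g]
    return sets
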