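"""Marker statistics: rank-sum exact/asymptotic, moderated t, enrichment."""

import subprocess
import textwrap
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scplate.cluster import ClusterAssignment
from scplate.markers import (
    VariancePrior,
    _rank_sum_pvalues,
    enrich_gene_sets,
    fit_variance_prior,
    moderated_t_markers,
    moderated_t_statistics,
    wilcoxon_markers,
)


def exact_rank_sum_p(x, y):
    """Enumeration oracle: two-sided rank-sum p over all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = [sum(c) - n1 * (n1 + 1) / 2
          for c in combinations(range(1, len(pooled) + 1), n1)]
    us = np.array(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return min(p, 1.0)


class TestRankSum:
    def test_textbook_exact_case(self):
        p = _rank_sum_pvalues(np.array([[1.0, 2, 3]]), np.array([[4.0, 5, 6]]))
        assert p[0] == pytest.approx(0.1, abs=1e-12)
        assert exact_rank_sum_p([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    @pytest.mark.parametrize("n1,n2", [(2, 3), (3, 3), (4, 6), (5, 5),
                                       (7, 4), (8, 8)])
    def test_exact_branch_equals_enumeration(self, n1, n2):
        rng = np.random.default_rng(n1 * 10 + n2)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n2) + rng.normal()
            ours = _rank_sum_pvalues(x[None, :], y[None, :])[0]
            assert ours == pytest.approx(exact_rank_sum_p(x, y), abs=1e-12)

    def test_identical_groups_p_one(self, immune_nx, immune_clusters):
        nx, _, _ = immune_nx
        p = _rank_sum_pvalues(np.array([[5.0, 5, 5]]), np.array([[5.0, 5, 5]]))
        assert p[0] == 1.0

    def test_null_type_one_error_calibrated(self):
        """Random split of null data rejects at ≈ the nominal 5% level."""
        rng = np.random.default_rng(99)
        data = rng.normal(size=(10_000, 200))
        p = _rank_sum_pvalues(data[:, :100], data[:, 100:])
        rate = (p < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.01)

    def test_planted_markers_detected(self, immune_nx, immune_clusters):
        nx, truth, _ = immune_nx
        table = wilcoxon_markers(nx, immune_clusters)
        ann_types = truth.true_type.reindex(immune_clusters.labels.index)
        shared = {g for t, gs in truth.planted_markers.items() for g in gs
                  if sum(g in gs2 for gs2 in truth.planted_markers.values()) > 1}
        sym2id = dict(zip(nx.genes["symbol"], nx.genes["gene_id"]))
        hit_frac = []
        for t, markers in truth.planted_markers.items():
            clusters_of_t = ann_types.groupby(immune_clusters.labels) \
                .agg(lambda s: (s == t).mean())
            home = clusters_of_t.idxmax()
            if clusters_of_t[home] < 0.5:
                continue
            sub = table[(table["cluster"] == home)
                        & (table["p_adjusted"] < 0.05)
                        & (table["log2_fc"] > 0)]
            found = sub["gene_id"].tolist()
            own = [sym2id[m] for m in markers
                   if m not in shared and m in sym2id]
            hit_frac.append(np.mean([m in found for m in own]))
            # the top-ranked gene of the home cluster is a planted marker
            best = sub.sort_values(["p_value", "log2_fc"],
                                   ascending=[True, False]).iloc[0]
            top10 = sub.nsmallest(10, "p_value")["gene_id"]
            assert any(m in set(top10) for m in own), t
        assert np.mean(hit_frac) >= 0.9

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(6, 40)), rng.normal(0.5, 1, size=(6, 30))
        p1 = _rank_sum_pvalues(a, b)
        p2 = _rank_sum_pvalues(b, a)
        assert np.allclose(p1, p2)


class TestModeratedT:
    def test_d0_zero_is_ordinary_pooled_t(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(30, 8)), rng.normal(size=(30, 9))
        res = moderated_t_statistics(a, b, VariancePrior(d0=0.0, s0_sq=1.0))
        t_ref = stats.ttest_ind(a, b, axis=1).statistic
        assert np.allclose(res["t"], t_ref, atol=1e-12)

    def test_d0_infinite_is_fully_shrunk(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(20, 5)), rng.normal(size=(20, 5))
        s0 = 2.5
        res = moderated_t_statistics(a, b,
                                     VariancePrior(d0=np.inf, s0_sq=s0))
        expect = (a.mean(1) - b.mean(1)) / np.sqrt(s0 * (1 / 5 + 1 / 5))
        assert np.allclose(res["t"], expect, atol=1e-12)

    def test_hand_computed_single_gene(self):
        a = np.array([[1.0, 2, 3]])
        b = np.array([[4.0, 5, 6]])
        res0 = moderated_t_statistics(a, b, VariancePrior(0.0, 1.0))
        assert res0["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)
        # shrinking toward the gene's own variance changes nothing
        s_g = float(res0["s_sq"].iloc[0])
        res = moderated_t_statistics(a, b, VariancePrior(4.0, s_g))
        assert res["t"].iloc[0] == pytest.approx(-3.674, abs=1e-3)

    def test_degenerate_variances_full_shrinkage(self):
        a = np.tile([[1.0, 2.0]], (5, 1))
        b = np.tile([[3.0, 4.0]], (5, 1))
        prior = fit_variance_prior(np.full(5, 0.5), df=2)
        assert np.isinf(prior.d0)
        assert prior.s0_sq == pytest.approx(0.5)

    def test_prior_recovery_on_simulated_variances(self):
        """Method-of-moments recovers a known inverse-chi-square prior."""
        rng = np.random.default_rng(11)
        d0_true, s0_true, df = 6.0, 1.8, 10
        n = 20_000
        true_var = d0_true * s0_true / rng.chisquare(d0_true, size=n)
        s_sq = true_var * rng.chisquare(df, size=n) / df
        prior = fit_variance_prior(s_sq, df)
        assert prior.d0 == pytest.approx(d0_true, rel=0.1)
        assert prior.s0_sq == pytest.approx(s0_true, rel=0.05)

    def test_matches_limma_reference(self, tmp_path):
        """Same moderated t as the Bioconductor empirical-Bayes reference."""
        rng = np.random.default_rng(21)
        n1 = n2 = 6
        a = rng.normal(size=(60, n1)) * rng.gamma(2, 1, size=(60, 1))
        b = a[:, :n2] * 0 + rng.normal(size=(60, n2)) * 1.2
        mat = np.hstack([a, b])
        df = pd.DataFrame(mat, index=[f"g{i}" for i in range(60)])
        df.to_csv(tmp_path / "m.tsv", sep="\t")
        script = textwrap.dedent(f"""
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("{tmp_path}/m.tsv", row.names=1))
            design <- cbind(1, c(rep(1, {n1}), rep(0, {n2})))
            fit <- eBayes(lmFit(m, design))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, "{tmp_path}/limma.tsv", sep="\\t")
        """)
        (tmp_path / "run.R").write_text(script)
        subprocess.run(["Rscript", str(tmp_path / "run.R")], check=True,
                       capture_output=True)
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        res = moderated_t_statistics(a, b)
        assert res["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-3)
        assert res["s0_sq"].iloc[0] == pytest.approx(ref["s0"].iloc[0], rel=1e-3)
        assert np.allclose(res["t"], ref["t"], rtol=1e-4)
        assert np.allclose(res["p_value"], ref["p"], rtol=1e-4)

    def test_marker_table_bh_monotone(self, immune_nx, immune_clusters):
        nx, _, _ = immune_nx
        table = moderated_t_markers(nx, immune_clusters)
        for _, grp in table.groupby("cluster"):
            srt = grp.sort_values("p_value")
            assert srt["p_adjusted"].is_monotonic_increasing


class TestEnrichment:
    def test_closed_form_full_overlap(self):
        universe = [f"g{i}" for i in range(20)]
        res = enrich_gene_sets(universe[:5], {"S": universe[:5]}, universe)
        assert res["p_value"].iloc[0] == pytest.approx(1 / comb(20, 5), rel=1e-9)

    def test_empty_set_p_one(self):
        universe = [f"g{i}" for i in range(10)]
        res = enrich_gene_sets(universe[:3], {"S": []}, universe)
        assert res["p_value"].iloc[0] == 1.0

    def test_monte_carlo_tail_agreement(self):
        """Hypergeometric p equals a sampling estimate within 3 SE."""
        rng = np.random.default_rng(17)
        N, K, n = 50, 12, 15
        universe = [f"g{i}" for i in range(N)]
        members = universe[:K]
        hits = list(rng.choice(universe, size=n, replace=False))
        res = enrich_gene_sets(hits, {"S": members}, universe)
        k = int(res["overlap"].iloc[0])
        draws = rng.hypergeometric(K, N - K, n, size=1_000_000)
        mc = (draws >= k).mean()
        se = max(np.sqrt(mc * (1 - mc) / 1_000_000), 1e-9)
        assert abs(res["p_value"].iloc[0] - mc) <= 3 * se + 1e-6

    def test_bh_and_significance_flag(self):
        universe = [f"g{i}" for i in range(100)]
        sets = {"hit": universe[:10], "miss": universe[50:60]}
        res = enrich_gene_sets(universe[:10], sets, universe, alpha=1e-3)
        res = res.set_index("set_name")
        assert bool(res.loc["hit", "significant"])
        assert not bool(res.loc["miss", "significant"])

    def test_hits_outside_universe_rejected(self):
        from scplate.experiment import ValidationError

        with pytest.raises(ValidationError):
            enrich_gene_sets(["x"], {"S": ["a"]}, ["a", "b"])
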