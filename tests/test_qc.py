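"""Cell and gene quality-control filters."""

import numpy as np
import pandas as pd
import pytest

from scplate import (
    Experiment,
    default_config,
    simulate_experiment,
)
from scplate.experiment import ValidationError
from scplate.qc import (
    compute_cell_qc_metrics,
    detect_sharp_drop,
    empty_well_noise_filter,
    filter_cells_complexity,
    filter_cells_mad,
    filter_genes_low_abundance,
)


def _experiment(counts, gene_ids, n_empty=0):
    from scplate.simulate import plate_barcodes, _well_names

    counts = np.asarray(counts)
    n = counts.shape[1]
    names = _well_names(n)
    wells = pd.DataFrame({
        "cell_id": [f"P1_{w}" for w in names],
        "plate_id": "P1", "well": names, "barcode": plate_barcodes(n),
        "donor_id": "D1", "condition": "Ctrl", "tissue": "LP",
        "is_empty_well": [i >= n - n_empty for i in range(n)]})
    genes = pd.DataFrame({"gene_id": gene_ids, "symbol": gene_ids})
    return Experiment(counts, genes, wells)


class TestCellMetrics:
    def test_fraction_arithmetic(self):
        x = _experiment([[10], [10], [80]], ["ERCC-1", "MT-1", "CD3E"])
        m = compute_cell_qc_metrics(x)
        row = m.iloc[0]
        assert row["library_size"] == 100
        assert row["ercc_fraction"] == pytest.approx(0.10)
        assert row["mito_fraction"] == pytest.approx(0.10)
        assert row["n_genes_detected"] == 3

    def test_zero_library_flagged(self):
        x = _experiment([[0, 5], [0, 5]], ["g1", "g2"])
        m = compute_cell_qc_metrics(x)
        assert m.iloc[0]["zero_library"]
        assert m.iloc[0]["ercc_fraction"] == 0.0

    def test_ercc_fraction_tracks_dilution(self):
        base = dict(n_plates=1, wells_per_plate=96, n_background_genes=120,
                    seed=6)
        lo, _ = simulate_experiment(
            default_config(ercc_dilution_scale=1.0, **base))
        hi, _ = simulate_experiment(
            default_config(ercc_dilution_scale=2.0, **base))
        f_lo = compute_cell_qc_metrics(lo)["ercc_fraction"].mean()
        f_hi = compute_cell_qc_metrics(hi)["ercc_fraction"].mean()
        assert f_hi > 1.5 * f_lo


class TestMADFilter:
    def _metrics(self, libs):
        return pd.DataFrame({
            "library_size": libs,
            "n_genes_detected": 500,
            "ercc_fraction": 0.05,
            "mito_fraction": 0.05,
            "is_empty_well": False,
        }, index=[f"c{i}" for i in range(len(libs))])

    def test_hand_computed_outlier(self):
        """log2 libraries {10.0, 10.1, 10.0, 9.9, 3.0}: the 3.0 cell sits
        ~47 scaled MADs from the median and is the only removal."""
        libs = 2 ** np.array([10.0, 10.1, 10.0, 9.9, 3.0]) - 1
        keep, reasons = filter_cells_mad(self._metrics(libs), nmads=3)
        assert list(keep) == [True, True, True, True, False]
        # median 10.0, MAD = median{0,0.1,0,0.1,7} = 0.1 → scaled 0.14826
        dev = abs(3.0 - 10.0) / 0.14826
        assert dev > 45
        assert reasons.loc["c4", "low_or_high_library"]

    def test_identical_metrics_noop(self):
        with pytest.warns(UserWarning, match="MAD is zero"):
            keep, _ = filter_cells_mad(self._metrics([100.0] * 6), nmads=3)
        assert keep.all()

    def test_infinite_nmads_keeps_all(self):
        libs = [100, 200, 50, 1000, 10, 5]
        keep, _ = filter_cells_mad(self._metrics(libs), nmads=np.inf)
        assert keep.all()

    def test_low_fractions_never_removed(self):
        """ERCC/mito filters are upper-sided: unusually clean cells stay."""
        m = self._metrics([100.0] * 7)
        m["library_size"] = [100, 105, 95, 102, 98, 101, 99]
        m["ercc_fraction"] = [0.05, 0.05, 0.05, 0.052, 0.048, 0.05, 0.0]
        with pytest.warns(UserWarning):
            keep, reasons = filter_cells_mad(m, nmads=3)
        assert keep["c6"]

    def test_planted_outlier_recovery(self):
        cfg = default_config(n_plates=2, seed=17, include_tcr=False,
                             n_low_library_cells=10, n_high_ercc_cells=10)
        x, truth = simulate_experiment(cfg)
        keep, _ = filter_cells_mad(compute_cell_qc_metrics(x), nmads=3)
        planted = set(truth.low_library_cells) | set(truth.high_ercc_cells)
        removed = set(keep.index[~keep])
        assert len(planted & removed) >= 18          # sensitivity ≥ 0.9
        assert len(removed - planted) <= 0.05 * len(keep)  # specificity


class TestComplexityFilter:
    def _m(self, n_genes):
        return pd.DataFrame({
            "n_genes_detected": n_genes, "library_size": 1000.0,
            "ercc_fraction": 0.05, "mito_fraction": 0.05,
            "is_empty_well": False,
        }, index=[f"c{i}" for i in range(len(n_genes))])

    @pytest.mark.parametrize("n,kept", [(299, False), (300, True),
                                        (4000, True), (4001, False)])
    def test_strict_boundaries(self, n, kept):
        keep = filter_cells_complexity(self._m([n, 1000]))
        assert bool(keep.iloc[0]) is kept

    def test_bad_window_rejected(self):
        with pytest.raises(ValidationError):
            filter_cells_complexity(self._m([500]), min_genes=10,
                                    max_genes=5)

    def test_aggregates_removed_preferentially(self):
        # tighter depth spread isolates the aggregates' doubled complexity
        cfg = default_config(n_plates=3, seed=19, include_tcr=False,
                             aggregate_rate=0.05, depth_sigma=0.2)
        x, truth = simulate_experiment(cfg)
        m = compute_cell_qc_metrics(x)
        occupied = m.loc[~m["is_empty_well"]]
        is_agg = occupied.index.isin(truth.aggregate_cells)
        # window calibrated to the fixture's gene universe: upper bound at
        # the singlet complexity tail
        upper = int(np.quantile(occupied.loc[~is_agg, "n_genes_detected"],
                                0.99))
        keep = filter_cells_complexity(occupied, min_genes=0,
                                       max_genes=upper)
        agg_removed = (~keep[is_agg]).mean()
        singlet_removed = (~keep[~is_agg]).mean()
        assert agg_removed >= 0.9
        assert agg_removed > 5 * singlet_removed


class TestLowAbundanceFilter:
    def test_all_zero_gene_removed_any_threshold(self):
        x = _experiment([[0, 0], [5, 5]], ["dead", "alive"])
        keep, _ = filter_genes_low_abundance(x, min_mean=0.0)
        assert list(keep) == [False, True]

    def test_threshold_zero_keeps_everything_else(self):
        x = _experiment([[1, 0], [5, 5]], ["rare", "common"])
        keep, _ = filter_genes_low_abundance(x, min_mean=0.0)
        assert keep.all()

    def test_auto_threshold_splits_bimodal_means(self):
        rng = np.random.default_rng(0)
        n_cells = 200
        noise_means = np.full(300, 0.005)
        signal_means = np.full(200, 1.0)
        means = np.concatenate([noise_means, signal_means])
        counts = rng.poisson(means[:, None], size=(500, n_cells))
        x = _experiment(counts, [f"g{i}" for i in range(500)])
        keep, thr = filter_genes_low_abundance(x, min_mean="auto")
        assert 0.01 < thr < 0.9
        assert not keep[:300][counts[:300].sum(axis=1) > 0].any() or \
            keep[300:].all()


class TestEmptyWellNoiseFilter:
    def _fixture(self):
        # 3 cells + 2 empties; ERCC-1 detected on both sides (cERCC)
        counts = np.array([
            [50, 40, 60, 45, 55],    # ERCC-1
            [20, 24, 16, 0, 0],      # real gene: absent from empties
            [0, 0, 0, 9, 11],        # ghost gene: empties only
            [10, 12, 8, 10, 10],     # ambient gene: equal signal
        ])
        return _experiment(counts, ["ERCC-1", "real", "ghost", "ambient"],
                           n_empty=2)

    def test_empty_only_gene_removed(self):
        x = self._fixture()
        keep, table = empty_well_noise_filter(x, n_permutations=50, seed=1,
                                              threshold=0.5)
        assert np.isinf(table.ratios["ghost"])
        assert not keep[2]

    def test_gene_absent_from_empties_kept(self):
        x = self._fixture()
        keep, table = empty_well_noise_filter(x, n_permutations=50, seed=1,
                                              threshold=1e-6)
        assert table.ratios["real"] == 0.0
        assert keep[1]

    def test_ambient_gene_ratio_near_one(self):
        x = self._fixture()
        _, table = empty_well_noise_filter(x, n_permutations=200, seed=1,
                                           threshold=0.5)
        assert table.ratios["ambient"] == pytest.approx(1.0, rel=0.25)

    def test_bit_reproducible_and_order_independent(self):
        cfg = default_config(n_plates=1, wells_per_plate=96,
                             n_background_genes=120, n_ambient_genes=10,
                             seed=23)
        x, _ = simulate_experiment(cfg)
        _, t1 = empty_well_noise_filter(x, n_permutations=50, seed=9,
                                        threshold=0.5)
        _, t2 = empty_well_noise_filter(x, n_permutations=50, seed=9,
                                        threshold=0.5)
        pd.testing.assert_series_equal(t1.ratios, t2.ratios)
        # permute wells: ratios must not change (seeding keyed to cell ids)
        rng = np.random.default_rng(1)
        perm = rng.permutation(x.n_wells)
        y = Experiment(x.counts[:, perm],
                       x.genes.copy(),
                       x.wells.iloc[perm].reset_index(drop=True))
        _, t3 = empty_well_noise_filter(y, n_permutations=50, seed=9,
                                        threshold=0.5)
        pd.testing.assert_series_equal(t1.ratios, t3.ratios)

    def test_skipped_without_empty_wells(self):
        x = _experiment([[5, 5], [3, 3]], ["ERCC-1", "g"], n_empty=0)
        with pytest.warns(UserWarning, match="skipped"):
            keep, _ = empty_well_noise_filter(x, n_permutations=10, seed=0,
                                              threshold=0.5)
        assert keep.all()

    def test_planted_ambient_genes_separated(self):
        """Pure-ambient genes get ratio ≈ 1, markers ratio ≪ 1."""
        cfg = default_config(n_plates=2, n_empty_wells_per_plate=12,
                             seed=29, include_tcr=False, n_ambient_genes=30)
        x, truth = simulate_experiment(cfg)
        keep, table = empty_well_noise_filter(x, n_permutations=200, seed=4,
                                              threshold=0.5)
        gene_ids = pd.Index(x.gene_ids)
        amb = gene_ids.isin(truth.ambient_genes)
        mk = gene_ids.isin(
            [g for gs in truth.planted_markers.values() for g in gs])
        assert (~keep[amb]).mean() >= 0.95
        assert keep[mk].mean() >= 0.95


class TestSharpDrop:
    def test_two_plateaus_separated(self):
        ratios = np.array([10.0] * 3 + [0.1] * 100)
        thr = detect_sharp_drop(ratios)
        assert 0.1 < thr < 10.0

    def test_linear_ramp_falls_back(self):
        with pytest.warns(UserWarning, match="fallback|99th"):
            thr = detect_sharp_drop(np.linspace(0.01, 1.0, 200))
        assert thr == pytest.approx(np.percentile(
            np.linspace(0.01, 1.0, 200), 99))

    def test_too_few_values_error(self):
        with pytest.raises(ValidationError):
            detect_sharp_drop(np.array([1.0] * 5))

    def test_mixture_classification(self):
        rng = np.random.default_rng(3)
        high = rng.lognormal(0.0, 0.2, size=40)        # ambient component
        low = rng.lognormal(-4.0, 0.5, size=400)       # background
        ratios = np.concatenate([high, low])
        thr = detect_sharp_drop(ratios)
        labels_true = np.r_[np.ones(40, bool), np.zeros(400, bool)]
        labels_hat = ratios > thr
        assert (labels_true == labels_hat).mean() >= 0.95


class TestMonotonicity:
    def test_raising_min_genes_never_rescues(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame({
            "n_genes_detected": rng.integers(100, 5000, 50),
            "library_size": 1000.0, "ercc_fraction": 0.05,
            "mito_fraction": 0.05, "is_empty_well": False,
        }, index=[f"c{i}" for i in range(50)])
        k1 = filter_cells_complexity(m, min_genes=200)
        k2 = filter_cells_complexity(m, min_genes=400)
        assert not (k2 & ~k1).any()

    def test_raising_noise_threshold_never_removes(self):
        cfg = default_config(n_plates=1, wells_per_plate=96,
                             n_background_genes=120, n_ambient_genes=10,
                             seed=31)
        x, _ = simulate_experiment(cfg)
        k1, _ = empty_well_noise_filter(x, n_permutations=30, seed=2,
                                        threshold=0.3)
        k2, _ = empty_well_noise_filter(x, n_permutations=30, seed=2,
                                        threshold=0.9)
        assert not (k1 & ~k2).any()
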