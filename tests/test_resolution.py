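"""Binning, subsampling, richness/turnover and trend smoothing."""

import numpy as np
import pandas as pd
import pytest

from sedadyn import (
    SedaRecord,
    mean_resolution,
    resolution_report,
    richness_series,
    smooth_trend,
    subsample_spatial,
    subsample_temporal,
    turnover_series,
)
from sedadyn.resolution import BinnedSeries, trend_agreement


def build_record(ages, counts, taxa=None, R=8, lake="toy"):
    ids = [f"s{i}" for i in range(len(ages))]
    counts = np.asarray(counts)
    taxa = taxa or [chr(65 + i) for i in range(counts.shape[0])]
    return SedaRecord(
        lake=lake,
        ages=pd.Series(np.asarray(ages, dtype=float), index=ids),
        detections=pd.DataFrame(counts, index=taxa, columns=ids),
        n_replicates=R,
    )


def seventeen_bin_record(samples_per_bin=3, seed=0, n_taxa=5):
    """17 occupied 500-yr bins with a fixed number of samples each."""
    rng = np.random.default_rng(seed)
    ages = []
    for b in range(17):
        ages.extend(np.sort(rng.uniform(b * 500 + 1, (b + 1) * 500 - 1,
                                        samples_per_bin))[::-1])
    ages = np.sort(ages)[::-1]
    counts = rng.integers(0, 9, (n_taxa, len(ages)))
    return build_record(ages, counts)


class TestMeanResolution:
    def test_uniform_spacing(self):
        assert mean_resolution(np.arange(0, 1000, 100)) == 100

    def test_consecutive_differences(self):
        assert mean_resolution([0.0, 100.0, 400.0]) == pytest.approx(200.0)

    def test_span_method(self):
        assert mean_resolution([0.0, 100.0, 400.0], method="span") == (
            pytest.approx(200.0)
        )
        assert mean_resolution([0, 50, 100, 400], method="span") == (
            pytest.approx(400 / 3)
        )

    def test_too_few_ages(self):
        with pytest.raises(ValueError):
            mean_resolution([100.0])


class TestSubsampleTemporal:
    def test_generous_k_keeps_everything(self):
        rec = seventeen_bin_record(3)
        out = subsample_temporal(rec, 500, 10, seed=1)
        assert out.n_samples == rec.n_samples

    @pytest.mark.parametrize("k,expected", [(1, 17), (2, 34), (3, 51)])
    def test_counting_oracle(self, k, expected):
        rec = seventeen_bin_record(3)
        out = subsample_temporal(rec, 500, k, seed=1)
        assert out.n_samples == expected

    def test_seeded_repeatability(self):
        rec = seventeen_bin_record(3)
        a = subsample_temporal(rec, 500, 1, seed=9)
        b = subsample_temporal(rec, 500, 1, seed=9)
        assert list(a.ages.index) == list(b.ages.index)

    def test_output_subset_of_input(self):
        rec = seventeen_bin_record(4, seed=3)
        out = subsample_temporal(rec, 500, 2, seed=2)
        assert set(out.ages.index) <= set(rec.ages.index)
        # order preserved -> ages still strictly monotone
        assert np.all(np.diff(out.ages.to_numpy()) < 0)


class TestRichness:
    def test_all_zero_record(self):
        rec = build_record([800.0, 300.0], np.zeros((3, 2), dtype=int))
        series = richness_series(rec, 500)
        assert np.all(series.values[series.occupied] == 0)

    def test_threshold_count(self):
        rec = build_record([100.0], [[3], [0], [1]])
        assert richness_series(rec, 500).values[0] == 2
        assert richness_series(rec, 500, min_replicates=2).values[0] == 1
        assert richness_series(rec, 500, min_replicates=4).values[0] == 0

    def test_invariant_under_sample_permutation(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 9, (4, 6))
        ages = [450.0, 420, 300, 200, 120, 30]  # all one bin
        base = richness_series(build_record(ages, counts), 500).values[0]
        perm = rng.permutation(6)
        shuffled = richness_series(
            build_record(ages, counts[:, perm]), 500
        ).values[0]
        assert base == shuffled

    def test_monotone_under_added_samples(self):
        """Adding samples to a bin can only add detected taxa."""
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 3, (6, 5))
        ages = np.array([480.0, 400, 300, 200, 100])
        rich = [
            richness_series(
                build_record(ages[: j + 1], counts[:, : j + 1]), 500
            ).values[0]
            for j in range(5)
        ]
        assert all(b >= a for a, b in zip(rich, rich[1:]))


class TestTurnover:
    def test_identical_composition_is_zero(self):
        counts = [[3, 3], [2, 2]]
        rec = build_record([700.0, 200.0], counts)
        t = turnover_series(rec, 500)
        assert t.values[0] == 0.0

    def test_disjoint_composition_is_one(self):
        rec = build_record([700.0, 200.0], [[0, 4], [5, 0]])
        assert turnover_series(rec, 500).values[0] == 1.0

    def test_set_arithmetic(self):
        # X = {A,B,C}, Y = {B,C,D} -> 1 - 4/6 = 1/3
        counts = np.array(
            [[1, 0], [1, 1], [1, 1], [0, 1]]
        )  # columns: young, old
        rec = build_record([200.0 + 500, 200.0][::-1], counts[:, ::-1])
        # build with oldest first: ages (700, 200); col0 = old bin
        rec = build_record([700.0, 200.0], counts[:, ::-1])
        t = turnover_series(rec, 500)
        assert t.values[0] == pytest.approx(1.0 / 3.0)

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(0, 2, (6, 2))
        rec_fwd = build_record([700.0, 200.0], counts)
        rec_rev = build_record([700.0, 200.0], counts[:, ::-1])
        a = turnover_series(rec_fwd, 500).values[0]
        b = turnover_series(rec_rev, 500).values[0]
        assert a == pytest.approx(b)

    def test_range_and_missing(self):
        rec = seventeen_bin_record(2, seed=13)
        t = turnover_series(rec, 500)
        vals = t.values[~np.isnan(t.values)]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_empty_pair_missing(self):
        rec = build_record([700.0, 200.0], np.zeros((2, 2), dtype=int))
        t = turnover_series(rec, 500)
        assert np.isnan(t.values[0])

    def test_braycurtis_variant(self):
        rec = build_record([700.0, 200.0], [[8, 4], [0, 4]])
        t = turnover_series(rec, 500, metric="braycurtis")
        # proportions young (0.5, 0.5) vs old (1, 0) -> BC = 0.5
        assert t.values[0] == pytest.approx(0.5)


class TestSubsampleSpatial:
    def make_lakes(self, n=3, seed=0):
        rng = np.random.default_rng(seed)
        recs = []
        for j in range(n):
            ages = np.sort(rng.uniform(10, 4990, 20))[::-1]
            counts = rng.integers(0, 9, (4, 20))
            recs.append(build_record(ages, counts, lake=f"lake{j}"))
        return recs

    def test_all_lakes_full_pool(self):
        recs = self.make_lakes(3)
        pool = subsample_spatial(recs, 3, None, 500, seed=1)
        assert pool.ages.size == sum(r.n_samples for r in recs)

    def test_single_lake_reduces_to_that_lake(self):
        recs = self.make_lakes(3)
        pool = subsample_spatial(recs, 1, None, 500, seed=4)
        assert pool.ages.size in [r.n_samples for r in recs]

    def test_seeded_repeatability(self):
        recs = self.make_lakes(3)
        a = subsample_spatial(recs, 2, 1, 500, seed=6)
        b = subsample_spatial(recs, 2, 1, 500, seed=6)
        assert list(a.detections.columns) == list(b.detections.columns)

    def test_out_of_range(self):
        recs = self.make_lakes(2)
        with pytest.raises(ValueError):
            subsample_spatial(recs, 5, 1, 500, seed=0)


class TestSmoothTrend:
    def constant_series(self, n=10, value=4.0):
        edges = np.arange(n + 1) * 500.0
        return BinnedSeries(edges, np.full(n, value), np.ones(n, dtype=int))

    def test_constant_series_recovered(self):
        tr = smooth_trend(self.constant_series())
        assert np.allclose(tr.fitted, 4.0, atol=1e-8)
        assert np.all(tr.lower <= 4.0 + 1e-8)
        assert np.all(tr.upper >= 4.0 - 1e-8)

    def test_exact_line_recovered(self):
        edges = np.arange(13) * 500.0
        mids = 0.5 * (edges[:-1] + edges[1:])
        vals = 2.0 + 0.004 * mids
        series = BinnedSeries(edges, vals, np.ones(12, dtype=int))
        tr = smooth_trend(series, basis_dimension=8)
        assert np.max(np.abs(tr.fitted - vals)) < 1e-6

    def test_band_shrinks_with_replication(self):
        """More samples per bin -> less bin noise -> narrower band."""
        rng = np.random.default_rng(21)
        edges = np.arange(21) * 500.0
        mids = 0.5 * (edges[:-1] + edges[1:])
        truth = 10 + 5 * np.sin(mids / 3000.0)

        def band_width(n_rep):
            noise = rng.normal(0, 3.0, (n_rep, 20)).mean(axis=0)
            series = BinnedSeries(edges, truth + noise,
                                  np.full(20, n_rep, dtype=int))
            tr = smooth_trend(series, basis_dimension=8)
            return float(np.mean(tr.upper - tr.lower))

        few = np.mean([band_width(1) for _ in range(10)])
        many = np.mean([band_width(16) for _ in range(10)])
        assert many < few

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            smooth_trend(self.constant_series(n=3))


class TestResolutionReport:
    def test_retained_counts_and_identity(self):
        rec = seventeen_bin_record(3, seed=2, n_taxa=12)
        table = resolution_report(
            rec, bin_width=500, k_values=(1, 2, 3), n_repeats=2, seed=5
        )
        by_k = table.groupby("setting")["retained_samples"].unique()
        assert list(by_k[1]) == [17]
        assert list(by_k[2]) == [34]
        assert list(by_k[3]) == [51]

    def test_full_record_agreement_is_exact(self):
        """Keeping every sample reproduces the reference trend exactly."""
        rec = seventeen_bin_record(3, seed=2, n_taxa=12)
        table = resolution_report(
            rec, bin_width=500, k_values=(3,), n_repeats=1, seed=5
        )
        # k = occupancy keeps all samples -> zero deviation, perfect rank corr
        assert table["mad_richness"].iloc[0] == pytest.approx(0.0, abs=1e-9)
        assert table["rho_richness"].iloc[0] == pytest.approx(1.0)


class TestTrendAgreement:
    def test_identical_trends(self):
        x = np.arange(10) * 500.0 + 250.0
        t = np.linspace(2, 8, 10)
        a = type("T", (), {})
        from sedadyn.resolution import SmoothedTrend

        tr = SmoothedTrend(x, t, np.ones(10), 1.0)
        mad, rho = trend_agreement(tr, tr)
        assert mad == 0.0
        assert rho == pytest.approx(1.0)
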