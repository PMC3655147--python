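"""Band integration, windowed statistics, peaks and pooled correlations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slowflow as sf
from slowflow.band_stats import (
    DEFAULT_BANDS,
    BandDefinition,
    BandSeries,
    band_for_frequency,
    band_integrate,
    benjamini_hochberg,
    cross_band_relation,
    find_peak,
    structure_function_corr,
    window_change_test,
    windowed_correlation,
    windowed_power_anova,
)
from slowflow.wavelet_spectra import TimeFreqGrid, default_freq_grid

DT = 2.0


def make_band_series(values, kind="power", band="slow-4"):
    values = np.asarray(values, dtype=float)
    return BandSeries(
        values=values,
        band=DEFAULT_BANDS[band],
        times=np.arange(values.shape[1]) * DT,
        kind=kind,
    )


class TestBandDefinitions:
    def test_default_edges(self):
        b = DEFAULT_BANDS
        assert (b["slow-5"].lo, b["slow-5"].hi) == (0.010, 0.027)
        assert (b["slow-4"].lo, b["slow-4"].hi) == (0.027, 0.073)
        assert (b["slow-3"].lo, b["slow-3"].hi) == (0.073, 0.198)
        assert (b["slow-2"].lo, b["slow-2"].hi) == (0.198, 0.250)

    @settings(deadline=None, max_examples=100)
    @given(f=st.floats(0.01, 0.25))
    def test_partition_every_frequency_in_exactly_one_band(self, f):
        hits = [b.name for b in DEFAULT_BANDS.values() if b.contains(np.asarray(f))]
        assert len(hits) == 1
        assert band_for_frequency(f) == hits[0]

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            BandDefinition("bad", 0.1, 0.05)


class TestBandIntegrate:
    @pytest.fixture()
    def grid(self):
        return TimeFreqGrid(
            times=np.arange(10) * DT,
            freqs=default_freq_grid(DT),
            sampling_interval=DT,
        )

    def test_flat_spectrum_band_mean_equals_constant(self, grid):
        vals = np.full((2, 10, grid.n_freq), 3.25)
        for band in DEFAULT_BANDS.values():
            bs = band_integrate(vals, grid, band)
            assert np.allclose(bs.values, 3.25)

    def test_sinusoid_concentrates_in_slow4(self):
        rng = np.random.default_rng(0)
        n = 512
        t = np.arange(n) * DT
        x = np.sin(2 * np.pi * 0.05 * t)[None] + 0.05 * rng.standard_normal((20, n))
        ts = sf.MultiTrialTimeSeries(values=x[None], sampling_interval=DT)
        S = sf.spectral_matrix(ts)
        pw = sf.power(S)
        b4 = band_integrate(pw, S.grid, DEFAULT_BANDS["slow-4"])
        b2 = band_integrate(pw, S.grid, DEFAULT_BANDS["slow-2"])
        mid = slice(n // 4, 3 * n // 4)
        assert np.nanmean(b4.values[0, mid]) > 10 * np.nanmean(b2.values[0, mid])

    def test_full_range_mean_between_band_extremes(self, grid):
        rng = np.random.default_rng(1)
        vals = rng.random((1, 10, grid.n_freq)) + 0.5
        full = BandDefinition("full", 0.01, 0.25, closed_hi=True)
        vfull = band_integrate(vals, grid, full).values
        band_means = np.stack(
            [band_integrate(vals, grid, b).values for b in DEFAULT_BANDS.values()]
        )
        assert np.all(vfull >= band_means.min(axis=0) - 1e-12)
        assert np.all(vfull <= band_means.max(axis=0) + 1e-12)

    def test_empty_band_on_grid_rejected(self, grid):
        with pytest.raises(ValueError, match="fewer than 2"):
            band_integrate(
                np.ones((1, 10, grid.n_freq)),
                grid,
                BandDefinition("narrow", 0.0501, 0.0502),
            )

    def test_fully_flagged_times_are_nan(self, grid):
        vals = np.ones((1, 10, grid.n_freq))
        flags = np.zeros((10, grid.n_freq), dtype=bool)
        flags[0] = True
        bs = band_integrate(vals, grid, DEFAULT_BANDS["slow-4"], flags)
        assert np.isnan(bs.values[0, 0])
        assert np.allclose(bs.values[0, 1:], 1.0)


class TestWindowedPowerAnova:
    def test_constant_series_f_zero_p_one(self):
        bs = make_band_series(np.full((1, 95), 2.0))
        out = windowed_power_anova(bs, 19)
        assert out["F"].iloc[0] == 0.0 and out["p"].iloc[0] == 1.0

    def test_reports_dfs_from_window_bookkeeping(self):
        rng = np.random.default_rng(2)
        bs = make_band_series(rng.random((1, 237)) + 1)
        out = windowed_power_anova(bs, 19)
        assert out["df1"].iloc[0] == 11  # 237 // 19 = 12 complete windows
        assert out["df2"].iloc[0] == 12 * 19 - 12

    def test_fewer_than_two_windows_rejected(self):
        bs = make_band_series(np.ones((1, 20)))
        with pytest.raises(ValueError, match="windows"):
            windowed_power_anova(bs, 19)

    def test_planted_step_detected(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate([np.full(114, 1.0), np.full(123, 4.0)])
        vals = vals * (1 + 0.05 * rng.standard_normal(237))
        out = windowed_power_anova(make_band_series(vals[None]), 19)
        assert out["p"].iloc[0] < 1e-6


class TestWindowedCorrelation:
    def test_duplicated_channel_r_one_everywhere(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((5, 237))
        ts = sf.MultiTrialTimeSeries(
            values=np.stack([x, x]), sampling_interval=DT
        )
        out = windowed_correlation(ts, 3)
        assert np.allclose(out["r"], 1.0)
        assert set(out["window"]) == {0, 1, 2}
        assert (out["n"] == 79).all()

    def test_independent_nodes_within_fisher_null_bound(self):
        rng = np.random.default_rng(5)
        ts = sf.MultiTrialTimeSeries(
            values=rng.standard_normal((2, 8, 3000)), sampling_interval=DT
        )
        out = windowed_correlation(ts, 3)
        bound = 1.96 / np.sqrt(1000 - 3)
        assert (np.abs(out["r"]) < 2 * bound).all()

    def test_planted_covariance_step_changes_window_correlation(self):
        rng = np.random.default_rng(6)
        n = 300
        shared = rng.standard_normal(n)
        x = shared + 0.3 * rng.standard_normal(n)
        y = 0.3 * rng.standard_normal(n).copy()
        y[:150] += shared[:150]  # coupled only in the first half
        ts = sf.MultiTrialTimeSeries(
            values=np.stack([x, y])[:, None, :], sampling_interval=DT
        )
        out = windowed_correlation(ts, 2)
        r0 = out[out.window == 0]["r"].iloc[0]
        r1 = out[out.window == 1]["r"].iloc[0]
        assert r0 > r1 + 0.3

    def test_too_short_windows_rejected(self):
        ts = sf.MultiTrialTimeSeries(
            values=np.zeros((2, 1, 8)), sampling_interval=DT
        )
        with pytest.raises(ValueError, match="shorter"):
            windowed_correlation(ts, 4)


class TestWindowChangeTest:
    def test_identical_columns_t_zero_p_one(self):
        corr = np.tile(np.linspace(0.2, 0.8, 5)[:, None], (1, 2))
        out = window_change_test(corr, (0, 1))
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        corr = np.column_stack([np.full(5, 0.6), np.full(5, 0.4)])
        with pytest.raises(ValueError, match="degenerate"):
            window_change_test(corr, (0, 1))

    def test_planted_group_change_detected(self):
        rng = np.random.default_rng(7)
        r1 = np.clip(rng.normal(0.65, 0.05, 17), -0.99, 0.99)
        r2 = np.clip(rng.normal(0.45, 0.05, 17), -0.99, 0.99)
        out = window_change_test(np.column_stack([r1, r2]), (0, 1))
        assert out["p"] < 0.001 and out["t"] > 0
        assert out["n"] == 17 and out["sd"] > 0

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError, match="participants"):
            window_change_test(np.zeros((2, 2)), (0, 1))


class TestFindPeak:
    def test_single_spike(self):
        vals = np.zeros((1, 50))
        vals[0, 17] = 3.0
        pk = find_peak(make_band_series(vals), 0)
        assert pk.time_index == 17 and pk.value == 3.0
        assert pk.time == 17 * DT

    def test_constant_series_earliest_tie(self):
        pk = find_peak(make_band_series(np.ones((1, 30))), 0)
        assert pk.time_index == 0

    def test_gaussian_bump_located(self):
        t = np.arange(200)
        width = 8.0
        rng = np.random.default_rng(8)
        vals = np.exp(-((t - 120.0) ** 2) / (2 * width**2)) + 0.05 * rng.random(200)
        pk = find_peak(make_band_series(vals[None]), 0)
        assert abs(pk.time_index - 120) <= width / 2

    @settings(deadline=None, max_examples=30)
    @given(
        scale=st.floats(0.1, 50.0),
        shift=st.floats(-5.0, 5.0),
        seed=st.integers(0, 1000),
    )
    def test_peak_invariant_to_positive_affine_rescaling(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((1, 40))
        a = find_peak(make_band_series(vals), 0)
        b = find_peak(make_band_series(vals * scale + shift, kind="net_flow"), 0)
        assert a.time_index == b.time_index

    def test_all_flagged_rejected(self):
        vals = np.full((1, 10), np.nan)
        bs = BandSeries(
            values=vals,
            band=DEFAULT_BANDS["slow-4"],
            times=np.arange(10) * DT,
            kind="net_flow",
        )
        with pytest.raises(ValueError, match="flagged"):
            find_peak(bs, 0)


class TestCrossBandRelation:
    def test_power_equal_to_flow_r_one(self):
        rng = np.random.default_rng(9)
        flows = [
            make_band_series(rng.random((4, 60)), kind="net_flow") for _ in range(5)
        ]
        powers = [
            make_band_series(f.values.copy(), kind="power", band="slow-5")
            for f in flows
        ]
        out = cross_band_relation(flows, powers)
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 20

    def test_null_calibration_type1(self):
        """Independent synthetic flows and powers: the pooled peak-matched
        correlation rejects at ~alpha."""
        rng = np.random.default_rng(10)
        hits = 0
        n_reps = 500
        for _ in range(n_reps):
            flows = [make_band_series(rng.random((4, 30)), kind="net_flow")
                     for _ in range(17)]
            powers = [make_band_series(rng.random((4, 30)), band="slow-5")
                      for _ in range(17)]
            out = cross_band_relation(flows, powers)
            hits += int(out["p"] < 0.05)
        assert 0.03 <= hits / n_reps <= 0.07

    def test_planted_coupling_recovered_at_pooled_n68(self):
        """Units whose peak flow and power share a latent: significantly
        positive pooled r in >= 90% of repetitions at n = 68."""
        rng = np.random.default_rng(11)
        hits = 0
        n_reps = 200
        for _ in range(n_reps):
            flows, powers = [], []
            for _p in range(17):
                u = rng.uniform(0.5, 1.5, size=4)
                fvals = u[:, None] * (1 + 0.3 * rng.random((4, 30)))
                pvals = u[:, None] * (1 + 0.3 * rng.random((4, 30)))
                flows.append(make_band_series(fvals, kind="net_flow"))
                powers.append(make_band_series(pvals, band="slow-5"))
            out = cross_band_relation(flows, powers)
            hits += int(out["p"] < 0.05 and out["r"] > 0)
        assert hits / n_reps >= 0.9

    def test_too_few_observations_rejected(self):
        flows = [make_band_series(np.random.rand(1, 10), kind="net_flow")]
        powers = [make_band_series(np.random.rand(1, 10), band="slow-5")]
        with pytest.raises(ValueError, match="3"):
            cross_band_relation(flows, powers)


class TestStructureFunction:
    def _fibers(self, rng):
        f = rng.integers(5, 80, size=(4, 4))
        f = np.triu(f, 1)
        f = f + f.T
        return f

    def test_degree_proportional_flow_r_near_one(self):
        rng = np.random.default_rng(12)
        fibers = self._fibers(rng)
        deg = fibers.sum(axis=1).astype(float)
        flows = []
        for _ in range(6):
            vals = np.full((4, 40), 0.0)
            vals[:, 20] = deg  # peak exactly proportional to degree
            flows.append(make_band_series(vals, kind="net_flow", band="slow-3"))
        out = structure_function_corr(flows, fibers)
        assert out["r"] == pytest.approx(1.0)
        assert out["n"] == 24

    def test_permuted_fiber_labels_destroy_positive_relation(self):
        """Label-deranged fiber tables lose the planted positive relation
        (with 4 nodes the degree-sum constraint pushes deranged correlations
        to zero or below, never spuriously positive)."""
        rng = np.random.default_rng(13)
        pos_hits = 0
        r_true, r_perm = [], []
        n_reps = 200
        for _ in range(n_reps):
            fibers = self._fibers(rng)
            deg = fibers.sum(axis=1).astype(float)
            flows = []
            for _p in range(6):
                vals = deg[:, None] * (1 + 0.2 * rng.random((4, 40)))
                flows.append(make_band_series(vals, kind="net_flow", band="slow-3"))
            while True:
                perm = rng.permutation(4)
                if not np.any(perm == np.arange(4)):
                    break
            out_t = structure_function_corr(flows, fibers)
            out_p = structure_function_corr(flows, fibers[np.ix_(perm, perm)])
            r_true.append(out_t["r"])
            r_perm.append(out_p["r"])
            pos_hits += int(out_p["p"] < 0.05 and out_p["r"] > 0)
        assert np.mean(r_true) > np.mean(r_perm) + 0.5
        assert pos_hits / n_reps < 0.1

    def test_label_mismatch_rejected(self):
        flows = [make_band_series(np.random.rand(3, 10), kind="net_flow")]
        with pytest.raises(ValueError, match="match"):
            structure_function_corr(flows, np.zeros((4, 4), dtype=int))


def test_benjamini_hochberg_monotone_and_bounded():
    p = np.array([0.001, 0.01, 0.02, 0.5, 0.04])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p) and np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)
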