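"""Monitor parsing, profiles, and chi-square periodogram behavior."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chronofly import locomotor as loco
from chronofly import synthetic_data as sd
from chronofly.schedules import LightSchedule


def brute_force_qp(x: np.ndarray, p: int) -> tuple[float, float]:
    """Oracle: explicitly build the fold matrix and apply the definitions."""
    n = len(x)
    grand = x.mean()
    cols = [x[h::p] for h in range(p)]
    col_means = np.array([c.mean() for c in cols])
    col_n = np.array([len(c) for c in cols])
    denom = ((x - grand) ** 2).sum()
    if denom == 0:
        return 0.0, 0.0
    qp = n * ((col_means - grand) ** 2).sum() / denom
    chi2 = n * (col_n * (col_means - grand) ** 2).sum() / denom
    return qp, chi2


class TestMonitorIO:
    def test_write_read_roundtrip_values(self, entrained_dataset, tmp_path):
        path = tmp_path / "monitor.txt"
        loco.write_monitor_file(entrained_dataset, path)
        ds = loco.read_monitor_file(path)
        assert ds.n_flies == 32  # padded to the full monitor
        assert np.array_equal(ds.counts[:8], entrained_dataset.counts)
        assert ds.counts[8:].sum() == 0
        assert ds.bin_minutes == 5.0

    def test_roundtrip_is_byte_identical(self, entrained_dataset, tmp_path):
        first = tmp_path / "a.txt"
        second = tmp_path / "b.txt"
        loco.write_monitor_file(entrained_dataset, first)
        loco.write_monitor_file(loco.read_monitor_file(first), second)
        assert first.read_bytes() == second.read_bytes()

    def test_bad_status_rows_counted_and_excluded(self, tmp_path):
        path = tmp_path / "m.txt"
        lines = []
        for i in range(4):
            status = 1 if i < 3 else 51  # trailing invalid row
            lines.append(f"{i+1}\t1\tJun\t16\t08:{5*i:02d}:00\t{status}\t1\t0\t0\t0"
                         + "\t2" * 32)
        path.write_text("\n".join(lines) + "\n")
        ds = loco.read_monitor_file(path)
        assert ds.n_bins == 3
        assert ds.n_malformed_rows == 1

    def test_non_uniform_spacing_names_row(self, tmp_path):
        path = tmp_path / "m.txt"
        times = ["08:00:00", "08:05:00", "08:15:00"]
        lines = [f"{i+1}\t1\tJun\t16\t{t}\t1\t1\t0\t0\t0" + "\t0" * 32
                 for i, t in enumerate(times)]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="row 3"):
            loco.read_monitor_file(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.raises(ValueError, match="no valid"):
            loco.read_monitor_file(path)

    def test_all_zero_counts_give_zero_totals(self, tmp_path, ld_12_12):
        ds = loco.ActivityDataset(
            fly_ids=["a", "b"], counts=np.zeros((2, 288), dtype=int),
            bin_minutes=5.0, start=sd._DEFAULT_START,
            schedule_segments=[(1, ld_12_12)])
        totals = loco.total_daily_activity(ds, (1, 1))
        assert (totals["counts_per_24h"] == 0).all()


class TestSmooth:
    def test_factor_zero_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        assert np.array_equal(loco.smooth(x, 0), x)

    def test_paper_factor_two_window_five(self):
        x = np.zeros(11)
        x[5] = 5.0
        out = loco.smooth(x, 2)
        assert out[5] == pytest.approx(1.0)  # 5 / window of 5
        assert out[3] == pytest.approx(1.0)
        assert out[2] == pytest.approx(0.0)

    @given(st.floats(-100, 100), st.integers(0, 10), st.integers(1, 50))
    def test_constant_series_invariant(self, c, factor, n):
        out = loco.smooth(np.full(n, c), factor)
        assert np.allclose(out, c)

    def test_symmetric_edge_handling_preserves_reversal(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(3, 50).astype(float)
        assert np.allclose(loco.smooth(x[::-1], 3), loco.smooth(x, 3)[::-1])

    def test_negative_factor_rejected(self):
        with pytest.raises(ValueError):
            loco.smooth(np.ones(5), -1)


class TestProfilesAndTotals:
    def test_profile_shape_and_day_selection(self, entrained_dataset):
        profile = loco.daily_profile(entrained_dataset, (1, 10), 2)
        assert len(profile) == 288
        assert profile["n"].iloc[0] == 8 * 10  # fly-days in range

    def test_single_fly_single_day_sem_zero(self, ld_12_12):
        ds = loco.ActivityDataset(
            fly_ids=["a"], counts=np.arange(288)[None, :] % 7,
            bin_minutes=5.0, start=sd._DEFAULT_START,
            schedule_segments=[(1, ld_12_12)])
        profile = loco.daily_profile(ds, (1, 1), 0)
        assert (profile["sem"] == 0).all()

    def test_profile_peaks_near_generator_phase(self, entrained_dataset):
        profile = loco.daily_profile(entrained_dataset, (1, 10), 2)
        peak_bin = int(profile["mean"].idxmax())
        assert abs(peak_bin - 120) <= 2  # ZT 10 at 5-min bins

    def test_empty_day_range_rejected(self, entrained_dataset):
        with pytest.raises(ValueError, match="day range"):
            loco.daily_profile(entrained_dataset, (11, 10), 2)
        with pytest.raises(ValueError, match="day range"):
            loco.total_daily_activity(entrained_dataset, (1, 99))

    def test_constant_fly_total(self, ld_12_12):
        ds = loco.ActivityDataset(
            fly_ids=["a"], counts=np.ones((1, 2 * 288), dtype=int),
            bin_minutes=5.0, start=sd._DEFAULT_START,
            schedule_segments=[(1, ld_12_12)])
        totals = loco.total_daily_activity(ds, (1, 2))
        assert totals["counts_per_24h"].iloc[0] == pytest.approx(288.0)

    def test_totals_invariant_under_within_day_permutation(self, entrained_dataset):
        before = loco.total_daily_activity(entrained_dataset, (5, 14))
        rng = np.random.default_rng(1)
        shuffled = entrained_dataset.counts.reshape(8, 14, 288).copy()
        for f in range(8):
            for d in range(14):
                rng.shuffle(shuffled[f, d])
        ds2 = loco.ActivityDataset(
            fly_ids=entrained_dataset.fly_ids,
            counts=shuffled.reshape(8, -1), bin_minutes=5.0,
            start=entrained_dataset.start,
            schedule_segments=entrained_dataset.schedule_segments)
        after = loco.total_daily_activity(ds2, (5, 14))
        assert np.allclose(before["counts_per_24h"], after["counts_per_24h"])


class TestActogram:
    def test_double_plot_layout(self):
        x = np.arange(3 * 288)
        mat = loco.actogram_matrix(x, 288, double_plot=True)
        assert mat.shape == (3, 576)
        assert np.array_equal(mat[0, 288:], mat[1, :288])
        assert (mat[-1, 288:] == 0).all()

    def test_single_plot_row_sums_are_daily_totals(self, entrained_dataset):
        x = entrained_dataset.series(0)
        mat = loco.actogram_matrix(x, 288, double_plot=False)
        assert mat.shape == (14, 288)
        daily = x.reshape(14, 288).sum(axis=1)
        assert np.array_equal(mat.sum(axis=1), daily)

    def test_requires_full_day(self):
        with pytest.raises(ValueError):
            loco.actogram_matrix(np.ones(100), 288)


class TestPeriodogram:
    def test_noiseless_periodic_closed_form(self):
        # K whole cycles of an arbitrary P-periodic pattern -> Qp(P) = P
        rng = np.random.default_rng(0)
        for p_bins in (24, 288):
            pattern = rng.poisson(5, p_bins).astype(float)
            x = np.tile(pattern, 6)
            pg = loco.chi_square_periodogram(
                x, (p_bins / 12 - 1, p_bins / 12 + 1), 0.05, 5.0)
            j = np.argmin(np.abs(pg.candidate_periods_hours - p_bins / 12))
            assert pg.qp[j] == pytest.approx(p_bins, abs=1e-9)

    def test_constant_series_all_zero(self):
        pg = loco.chi_square_periodogram(np.full(2880, 7.0), (16, 32), 0.05, 5.0)
        assert (pg.qp == 0).all()
        assert (pg.chi2_stat == 0).all()
        assert not loco.classify_rhythmicity(pg).rhythmic

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = int(rng.integers(50, 400))
            x = rng.poisson(4, n).astype(float)
            for p in range(2, 21):
                pg = loco.chi_square_periodogram(
                    x, (p / 12, p / 12), 0.05, 5.0)
                qp_o, chi2_o = brute_force_qp(x, p)
                assert pg.qp[0] == pytest.approx(qp_o, abs=1e-9)
                assert pg.chi2_stat[0] == pytest.approx(chi2_o, abs=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.poisson(3, 2880).astype(float)
        a = loco.chi_square_periodogram(x, (16, 32), 0.05, 5.0)
        b = loco.chi_square_periodogram(3.7 * x, (16, 32), 0.05, 5.0)
        assert np.allclose(a.qp, b.qp)
        assert np.allclose(a.chi2_stat, b.chi2_stat)

    def test_period_range_outside_support_rejected(self):
        with pytest.raises(ValueError, match="cannot support"):
            loco.chi_square_periodogram(np.ones(100), (16, 32), 0.05, 5.0)

    def test_significance_line_is_chi_square_quantile(self):
        from scipy import stats as sps
        pg = loco.chi_square_periodogram(
            np.random.default_rng(0).poisson(3, 2880), (16, 32), 0.05, 5.0)
        p_bins = np.round(pg.candidate_periods_hours * 12).astype(int)
        assert np.allclose(pg.significance_line,
                           sps.chi2.ppf(0.95, p_bins - 1))


class TestRhythmicity:
    def test_simulated_free_runner_recovered(self, dd):
        cfg = sd.ActivitySimConfig(
            n_flies=6, n_days=10, schedule=dd, period_tau=23.5,
            peaks=[sd.ActivityPeak(10.0, 2.0, 10.0)], baseline=2.0, seed=11)
        ds = sd.simulate_activity(cfg)
        for f in range(ds.n_flies):
            pg = loco.chi_square_periodogram(ds.series(f), (16, 32), 0.05, 5.0)
            call = loco.classify_rhythmicity(pg, ds.fly_ids[f])
            assert call.rhythmic
            assert call.period_hours == pytest.approx(23.5, abs=0.25)

    def test_zero_count_fly_not_rhythmic(self):
        pg = loco.chi_square_periodogram(np.zeros(2880), (16, 32), 0.05, 5.0)
        assert not loco.classify_rhythmicity(pg, "dead").rhythmic

    def test_arrhythmic_fly_usually_not_called(self, dd):
        cfg = sd.ActivitySimConfig(
            n_flies=20, n_days=10, schedule=dd, period_tau=24.0,
            peaks=[sd.ActivityPeak(10.0, 2.0, 10.0)],
            arrhythmic_fraction=1.0, seed=12)
        ds = sd.simulate_activity(cfg)
        called = sum(
            loco.classify_rhythmicity(
                loco.chi_square_periodogram(ds.series(f), (16, 32), 0.05, 5.0)
            ).rhythmic
            for f in range(ds.n_flies))
        assert called <= 2


class TestFreeRunningSummary:
    def _call(self, rhythmic, period=None):
        return loco.RhythmicityCall("f", rhythmic, period, 1.0 if rhythmic else -1.0)

    def test_all_rhythmic_at_24(self):
        calls = [self._call(True, 24.0)] * 5
        out = loco.free_running_summary(calls, ["g"] * 5)
        row = out.iloc[0]
        assert row["percent_rhythmic"] == 100.0
        assert row["mean_period"] == 24.0
        assert row["sd_period"] == 0.0

    def test_arrhythmic_mixture_counting(self):
        n, k = 10, 3
        calls = ([self._call(True, 24.0)] * (n - k) + [self._call(False)] * k)
        out = loco.free_running_summary(calls, ["g"] * n)
        assert out.iloc[0]["percent_rhythmic"] == pytest.approx(100 * (n - k) / n)

    def test_nine_condition_groups_give_nine_rows(self):
        labels = [f"{ld}_{t}" for ld in ("LD8:16", "LD12:12", "LD16:8")
                  for t in (15, 25, 35) for _ in range(4)]
        calls = [self._call(True, 24.0) for _ in labels]
        out = loco.free_running_summary(calls, labels)
        assert len(out) == 9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            loco.free_running_summary([], [])
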