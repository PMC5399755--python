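"""Bleach correction, ΔF/F identities, response summaries, normality."""

import numpy as np
import pandas as pd
import pytest

from osmodrop.calcium import (BaselineError, CalciumTrace, bleach_correct,
                              compute_dff, dff_matrix, normality_check,
                              response_summary)
from osmodrop.simulate import CalciumSimParams, simulate_calcium_trace


def _trace(f, rate=10.0):
    f = np.asarray(f, dtype=float)
    return CalciumTrace(time_s=np.arange(len(f)) / rate, F=f)


class TestBleachCorrect:
    def test_constant_trace_unchanged(self):
        tr = bleach_correct(_trace(np.full(1200, 80.0)))
        assert np.allclose(tr.F_corrected, 80.0, rtol=1e-3)

    @pytest.mark.parametrize("fit_window", ["baseline", "full"])
    def test_pure_exponential_flattened(self, fit_window):
        p = CalciumSimParams(bleach_rate=0.002, noise_sd=0.0)
        raw, _ = simulate_calcium_trace(p)
        tr = bleach_correct(raw, fit_window=fit_window)
        dev = np.abs(tr.F_corrected / tr.F_corrected[0] - 1.0)
        assert dev.max() < 0.005

    def test_step_amplitude_preserved_through_correction(self):
        p = CalciumSimParams(bleach_rate=0.002, step_amplitude_frac=0.2,
                             noise_sd=0.0)
        raw, _ = simulate_calcium_trace(p)
        done = compute_dff(bleach_correct(raw))
        assert response_summary(done) == pytest.approx(20.0, abs=0.4)

    def test_full_window_fit_absorbs_sustained_step(self):
        """Fitting the decay over the whole trace shrinks a 20% step —
        the reason the baseline-window fit is the default."""
        p = CalciumSimParams(bleach_rate=0.002, step_amplitude_frac=0.2,
                             noise_sd=0.0)
        raw, _ = simulate_calcium_trace(p)
        full = response_summary(compute_dff(
            bleach_correct(raw, fit_window="full")))
        base = response_summary(compute_dff(
            bleach_correct(raw, fit_window="baseline")))
        assert base == pytest.approx(20.0, abs=0.4)
        assert full < 15.0  # sizeable fraction of the step absorbed

    def test_nonpositive_fluorescence_rejected(self):
        with pytest.raises(ValueError):
            bleach_correct(_trace(np.linspace(-1.0, 10.0, 100)))

    def test_fallback_to_linear_detrend_warns(self, monkeypatch):
        import osmodrop.calcium as calcium_mod

        def boom(*args, **kwargs):
            raise RuntimeError("Optimal parameters not found")

        monkeypatch.setattr(calcium_mod, "curve_fit", boom)
        f = 100.0 - 0.05 * np.arange(1200)
        with pytest.warns(RuntimeWarning, match="linear detrend"):
            tr = bleach_correct(_trace(f), fit_window="full")
        # linear fallback still flattens a linear decay exactly
        assert np.allclose(tr.F_corrected, 100.0, rtol=1e-9)


class TestComputeDff:
    def test_constant_trace_zero_dff(self):
        done = compute_dff(bleach_correct(_trace(np.full(1200, 100.0))))
        assert np.nanmax(np.abs(done.dff)) < 1e-6

    def test_formula_direct_value(self):
        """F = 1.25 x F_base at one instant gives dff = 25% there."""
        f = np.full(1200, 100.0)
        f[700] = 125.0
        tr = CalciumTrace(time_s=np.arange(1200) / 10.0, F=f, F_corrected=f)
        done = compute_dff(tr)
        assert done.F_base == pytest.approx(100.0)
        assert done.dff[700] == pytest.approx(25.0)

    def test_baseline_window_mean_dff_is_zero(self):
        p = CalciumSimParams(bleach_rate=0.001, step_amplitude_frac=0.1,
                             noise_sd=0.5, seed=3)
        raw, _ = simulate_calcium_trace(p)
        done = compute_dff(bleach_correct(raw))
        base = done.dff[done.time_s < 60.0]
        assert abs(np.nanmean(base)) < 1e-9

    def test_rescaling_invariance(self):
        """dF/F is invariant to global multiplicative rescaling of F."""
        p = CalciumSimParams(bleach_rate=0.002, step_amplitude_frac=0.15,
                             noise_sd=0.0)
        raw, _ = simulate_calcium_trace(p)
        scaled = CalciumTrace(time_s=raw.time_s, F=7.5 * raw.F)
        d1 = compute_dff(bleach_correct(raw))
        d2 = compute_dff(bleach_correct(scaled))
        assert np.allclose(d1.dff, d2.dff, atol=1e-8, equal_nan=True)

    def test_correction_is_noop_for_unbleached_trace(self):
        p = CalciumSimParams(bleach_rate=0.0, step_amplitude_frac=0.2,
                             noise_sd=0.0)
        raw, _ = simulate_calcium_trace(p)
        with_corr = compute_dff(bleach_correct(raw))
        without = compute_dff(CalciumTrace(time_s=raw.time_s, F=raw.F,
                                           F_corrected=raw.F))
        assert np.allclose(with_corr.dff, without.dff, atol=0.5,
                           equal_nan=True)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            compute_dff(_trace(np.full(300, 50.0)))  # 30 s < 120 s window


class TestResponseSummary:
    def test_zero_dff_gives_zero(self):
        done = compute_dff(bleach_correct(_trace(np.full(1200, 100.0))))
        assert response_summary(done) == pytest.approx(0.0, abs=1e-6)

    def test_recovers_simulated_step(self):
        p = CalciumSimParams(bleach_rate=0.003, step_amplitude_frac=0.2,
                             noise_sd=1.0, seed=11)
        raw, _ = simulate_calcium_trace(p)
        done = compute_dff(bleach_correct(raw))
        assert response_summary(done) == pytest.approx(20.0, abs=1.0)

    def test_two_cohorts_separated_by_t_test(self):
        """20% vs 0% step cohorts (n=15/13): t test separates at a=0.01
        in >= 95% of replicate experiments."""
        from osmodrop.stats import two_group_t

        rng = np.random.default_rng(42)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            groups = []
            for n, step in ((15, 0.2), (13, 0.0)):
                vals = []
                for _ in range(n):
                    p = CalciumSimParams(
                        bleach_rate=0.002, step_amplitude_frac=step,
                        noise_sd=5.0, seed=int(rng.integers(2 ** 31)))
                    raw, _ = simulate_calcium_trace(p)
                    vals.append(response_summary(
                        compute_dff(bleach_correct(raw))))
                groups.append(vals)
            if two_group_t(groups[0], groups[1]).p < 0.01:
                hits += 1
        assert hits >= 0.95 * n_rep


class TestNormalityCheck:
    def test_normal_sample_passes_both_tests(self):
        ok = 0
        for s in range(100):
            x = np.random.default_rng(s).normal(size=1000)
            res = normality_check(x)
            ok += (res["ks_p"] > 0.01) and (res["shapiro_p"] > 0.01)
        assert ok >= 95

    def test_exponential_sample_rejected_by_shapiro(self):
        bad = 0
        for s in range(100):
            x = np.random.default_rng(s).exponential(size=1000)
            bad += normality_check(x)["shapiro_p"] < 0.01
        assert bad >= 99

    def test_too_small_or_constant_rejected(self):
        with pytest.raises(ValueError):
            normality_check([1.0, 2.0])
        with pytest.raises(ValueError):
            normality_check([3.0, 3.0, 3.0, 3.0])


class TestHeatmapExport:
    def test_dff_matrix_roundtrips_through_csv(self, tmp_path):
        traces = []
        for i in range(4):
            p = CalciumSimParams(bleach_rate=0.002, step_amplitude_frac=0.1,
                                 noise_sd=2.0, seed=i)
            raw, _ = simulate_calcium_trace(p)
            done = compute_dff(bleach_correct(raw))
            done.animal_id = f"a{i}"
            traces.append(done)
        mat = dff_matrix(traces)
        path = tmp_path / "dff.csv"
        mat.to_csv(path)
        back = pd.read_csv(path, index_col=0)
        assert np.allclose(back.to_numpy(), mat.to_numpy(), equal_nan=True)

    def test_heatmap_png_written(self, tmp_path):
        from osmodrop.calcium import save_heatmap

        p = CalciumSimParams(noise_sd=1.0, seed=0)
        raw, _ = simulate_calcium_trace(p)
        done = compute_dff(bleach_correct(raw))
        done.animal_id = "a0"
        save_heatmap(dff_matrix([done]), tmp_path / "hm.png")
        assert (tmp_path / "hm.png").stat().st_size > 0
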