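"""T2 inversion: forward model, grids, regularized NNLS, peaks, comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectroheal.cohort import simulate_cpmg_decay
from spectroheal.relaxometry import (
    CPMGDecay,
    MagnitudeClass,
    Normalization,
    T2Distribution,
    T2Grid,
    build_t2_grid,
    compare_distributions,
    default_grid,
    detect_peaks,
    forward_model,
    invert_cpmg,
    select_lambda,
)


def gaussian_log_bump(grid: T2Grid, center_ms: float, width_dec: float, area: float):
    """A log-normal-shaped bump on the grid — a hand-made 'peak' for tests."""
    logt = np.log10(grid.values)
    f = area * np.exp(-0.5 * ((logt - np.log10(center_ms)) / width_dec) ** 2)
    return f


class TestForwardModel:
    def test_single_component_exact(self):
        grid = build_t2_grid(1, 1000, 64)
        f = np.zeros(64)
        i = int(np.argmin(np.abs(grid.values - 100.0)))
        f[i] = 1.0
        dist = T2Distribution(grid, f, Normalization.raw)
        tau = np.linspace(70, 200000, 50)
        np.testing.assert_allclose(
            forward_model(dist, tau),
            np.exp(-tau / 1000.0 / grid.values[i]),
            rtol=1e-12,
        )

    def test_zero_time_gives_total_amplitude(self, rng):
        grid = build_t2_grid(0.5, 5000, 64)
        f = rng.random(64)
        dist = T2Distribution(grid, f, Normalization.raw)
        assert forward_model(dist, [0.0])[0] == pytest.approx(f.sum(), rel=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        grid = build_t2_grid(0.5, 5000, 64)
        f = rng.random(64)
        dist = T2Distribution(grid, f, Normalization.raw)
        tau = np.geomspace(10, 300000, 40)
        got = forward_model(dist, tau)
        # independent oracle: explicit double loop over (tau, T2)
        expected = np.array(
            [sum(f[i] * np.exp(-t / 1000.0 / grid.values[i]) for i in range(64)) for t in tau]
        )
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestT2Grid:
    def test_three_point_geometric(self):
        np.testing.assert_allclose(build_t2_grid(1, 100, 3).values, [1, 10, 100])

    def test_ratio_closed_form(self):
        g = build_t2_grid(0.1, 10000, 128)
        ratios = g.values[1:] / g.values[:-1]
        np.testing.assert_allclose(ratios, (1e5) ** (1 / 127), rtol=1e-9)
        assert g.values[0] == pytest.approx(0.1)
        assert g.values[-1] == pytest.approx(10000)

    @pytest.mark.parametrize("args", [(1, 100, 1), (100, 1, 8), (0, 100, 8), (-1, 5, 8)])
    def test_invalid_grids_rejected(self, args):
        with pytest.raises(ValueError):
            build_t2_grid(*args)

    @given(
        t2_min=st.floats(0.01, 10),
        span=st.floats(10, 1e5),
        n=st.integers(8, 200),
    )
    @settings(max_examples=50, deadline=None)
    def test_geometric_ratio_property(self, t2_min, span, n):
        g = build_t2_grid(t2_min, t2_min * span, n)
        ratios = np.diff(np.log(g.values))
        assert np.all(np.abs(ratios - ratios[0]) < 1e-9)


class TestInvertCPMG:
    def test_noiseless_single_exponential_concentrates(self):
        decay = simulate_cpmg_decay([(100.0, 1.0)], 70.0, 3000, noise_sd=0)
        grid = build_t2_grid(0.1, 10000, 128)
        dist = invert_cpmg(decay, grid, lam=1e-6)
        # >= 95% of the recovered area within one grid step of 100 ms
        step = grid.values[1] / grid.values[0]
        near = (grid.values >= 100 / step) & (grid.values <= 100 * step)
        assert dist.f[near].sum() >= 0.95

    def test_forward_inverse_self_consistency(self):
        noise = 0.002
        decay = simulate_cpmg_decay(
            [(5.0, 0.3), (500.0, 0.7)], 70.0, 3000, noise_sd=noise, seed=1
        )
        grid = default_grid()
        dist = invert_cpmg(decay, grid, lam=0.01, normalization="raw")
        recon = forward_model(dist, decay.tau_us)
        rel_rms = np.sqrt(np.mean((recon - decay.M) ** 2)) / abs(decay.M[0])
        assert rel_rms <= 2 * noise / abs(decay.M[0])

    def test_homogeneity_in_signal_scale(self):
        decay = simulate_cpmg_decay([(50.0, 1.0)], 70.0, 800, noise_sd=0)
        grid = build_t2_grid(1, 1000, 64)
        f1 = invert_cpmg(decay, grid, lam=1e-4, normalization="raw").f
        scaled = CPMGDecay(decay.tau_us, 3.0 * decay.M, decay.te_us, decay.n_echoes)
        f3 = invert_cpmg(scaled, grid, lam=3 * 1e-4, normalization="raw").f
        np.testing.assert_allclose(f3, 3.0 * f1, rtol=1e-6, atol=1e-9)

    def test_unit_sum_normalization(self):
        decay = simulate_cpmg_decay([(50.0, 1.0)], 70.0, 500, noise_sd=0.001, seed=2)
        dist = invert_cpmg(decay, build_t2_grid(1, 1000, 64), lam=0.01)
        assert dist.f.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dist.f >= 0)

    def test_roughness_monotone_in_lambda(self):
        decay = simulate_cpmg_decay(
            [(5.0, 0.3), (500.0, 0.7)], 70.0, 1500, noise_sd=0.002, seed=4
        )
        grid = build_t2_grid(0.1, 10000, 96)
        norms = [
            np.linalg.norm(invert_cpmg(decay, grid, lam=lam, normalization="raw").f)
            for lam in [1e-4, 1e-3, 1e-2, 1e-1, 1.0]
        ]
        assert all(b <= a + 1e-9 for a, b in zip(norms[:-1], norms[1:]))

    def test_degenerate_inputs_rejected(self):
        tau = 70.0 * np.arange(1, 11)
        with pytest.raises(ValueError, match="zero"):
            invert_cpmg(CPMGDecay(tau, np.zeros(10), 70.0, 10), build_t2_grid(1, 100, 8))
        with pytest.raises(ValueError, match="lambda"):
            invert_cpmg(
                CPMGDecay(tau, np.ones(10), 70.0, 10), build_t2_grid(1, 100, 8), lam=-1
            )


class TestSelectLambda:
    def test_single_candidate_returned(self):
        decay = simulate_cpmg_decay([(100.0, 1.0)], 70.0, 200, noise_sd=0)
        assert select_lambda(decay, build_t2_grid(1, 1000, 32), [0.5]) == 0.5

    def test_noiseless_decay_chooses_smallest(self):
        decay = simulate_cpmg_decay([(100.0, 1.0)], 70.0, 500, noise_sd=0)
        decay = CPMGDecay(
            decay.tau_us, decay.M, 70.0, 500, noise_sd_estimate=0.0
        )
        grid = build_t2_grid(1, 1000, 64)
        cands = [1e-4, 1e-3, 1e-2, 1e-1]
        assert select_lambda(decay, grid, cands) == 1e-4

    def test_tracks_oracle_best_lambda(self):
        """Discrepancy choice lands within one step of the lambda minimizing
        the true f-error against the planted truth."""
        comps = [(5.0, 0.3), (500.0, 0.7)]
        grid = default_grid()
        truth = np.zeros(grid.n_points)
        for t2, fr in comps:
            truth[np.argmin(np.abs(grid.values - t2))] = fr
        cands = list(np.geomspace(1e-4, 1.0, 9))
        decay = simulate_cpmg_decay(comps, 70.0, 3000, noise_sd=0.002, seed=9)
        errors = [
            np.linalg.norm(invert_cpmg(decay, grid, lam=c).f - truth) for c in cands
        ]
        best = int(np.argmin(errors))
        chosen = select_lambda(decay, grid, cands)
        assert abs(cands.index(chosen) - best) <= 1

    def test_empty_candidates_rejected(self):
        decay = simulate_cpmg_decay([(100.0, 1.0)], 70.0, 100, noise_sd=0)
        with pytest.raises(ValueError):
            select_lambda(decay, build_t2_grid(1, 1000, 32), [])


class TestDetectPeaks:
    def test_unimodal_gives_single_full_peak(self):
        grid = build_t2_grid(0.1, 10000, 128)
        f = gaussian_log_bump(grid, 550, 0.2, 1.0)
        peaks = detect_peaks(T2Distribution(grid, f / f.sum()))
        assert len(peaks) == 1
        assert peaks[0].area_fraction == pytest.approx(1.0, abs=1e-9)
        assert peaks[0].fraction_class.value == "soluble"

    def test_three_planted_components_recovered(self):
        decay = simulate_cpmg_decay(
            [(1.5, 0.05), (8.0, 0.10), (550.0, 0.85)], 70.0, 3000, noise_sd=0
        )
        grid = build_t2_grid(0.1, 10000, 128)
        dist = invert_cpmg(decay, grid, lam=1e-4)
        peaks = sorted(detect_peaks(dist), key=lambda p: p.position_ms)
        assert len(peaks) == 3
        step = grid.values[1] / grid.values[0]
        for peak, t2 in zip(peaks, [1.5, 8.0, 550.0]):
            assert t2 / step <= peak.position_ms <= t2 * step
        classes = [p.fraction_class.value for p in peaks]
        assert classes == ["insoluble", "insoluble", "soluble"]

    def test_full_height_threshold_gives_at_most_one(self):
        grid = build_t2_grid(0.1, 10000, 128)
        f = gaussian_log_bump(grid, 8, 0.15, 0.3) + gaussian_log_bump(grid, 550, 0.2, 0.7)
        peaks = detect_peaks(T2Distribution(grid, f / f.sum()), min_rel_height=1.0)
        assert len(peaks) <= 1

    def test_area_fractions_sum_to_at_most_one(self):
        grid = build_t2_grid(0.1, 10000, 128)
        f = (
            gaussian_log_bump(grid, 1.5, 0.1, 0.05)
            + gaussian_log_bump(grid, 8, 0.1, 0.1)
            + gaussian_log_bump(grid, 550, 0.2, 0.85)
        )
        peaks = detect_peaks(T2Distribution(grid, f / f.sum()))
        assert sum(p.area_fraction for p in peaks) <= 1 + 1e-6


class TestCompareDistributions:
    grid = build_t2_grid(0.1, 10000, 160)

    def _dist(self, *bumps):
        f = np.zeros(self.grid.n_points)
        for center, width, area in bumps:
            f += gaussian_log_bump(self.grid, center, width, area)
        return T2Distribution(self.grid, f / f.sum())

    def test_identical_inputs_no_shift(self):
        d = self._dist((550, 0.15, 0.85), (8, 0.1, 0.15))
        rep = compare_distributions(d, d)
        assert rep.main_peak_shift == 0.0
        assert rep.magnitude_class is MagnitudeClass.none
        assert not rep.new_peaks and not rep.vanished_peaks

    def test_main_peak_shift_arithmetic(self):
        pre = self._dist((550, 0.12, 0.85), (8, 0.1, 0.15))
        post = self._dist((400, 0.12, 0.85), (8, 0.1, 0.15))
        rep = compare_distributions(pre, post)
        assert rep.main_peak_shift == pytest.approx(np.log10(400 / 550), abs=0.02)
        assert rep.magnitude_class is MagnitudeClass.small

    def test_new_peak_promotes_magnitude(self):
        pre = self._dist((550, 0.12, 0.85), (8, 0.1, 0.15))
        post = self._dist((550, 0.12, 0.80), (8, 0.1, 0.12), (200, 0.08, 0.08))
        rep = compare_distributions(pre, post)
        assert len(rep.new_peaks) == 1
        assert 130 <= rep.new_peaks[0].position_ms <= 300
        assert rep.magnitude_class in (MagnitudeClass.medium, MagnitudeClass.large)

    def test_shift_antisymmetry(self):
        a = self._dist((550, 0.12, 0.85), (8, 0.1, 0.15))
        b = self._dist((300, 0.12, 0.85), (8, 0.1, 0.15))
        assert compare_distributions(a, b).main_peak_shift == pytest.approx(
            -compare_distributions(b, a).main_peak_shift, abs=1e-12
        )

    def test_grid_mismatch_rejected(self):
        other = build_t2_grid(0.1, 10000, 96)
        f = gaussian_log_bump(other, 550, 0.2, 1.0)
        d_other = T2Distribution(other, f / f.sum())
        d_self = self._dist((550, 0.2, 1.0))
        with pytest.raises(ValueError, match="grid"):
            compare_distributions(d_self, d_other)
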