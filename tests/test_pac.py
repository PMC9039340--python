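"""Phase-amplitude coupling: MI, surrogates, windows, significance, grouping."""

import numpy as np
import pandas as pd
import pytest

from cortrack import (
    SynthConfig,
    band_group_max,
    canolty_mi,
    compute_pac_grid,
    extract_phase_amp,
    gen_pac_signal,
    nmi,
    significant_windows,
    sliding_windows,
    surrogate_mis,
)
from cortrack.pac import PACGrid, _all_rotation_mis

FS = 100.0


def brute_force_mi(phase, amplitude):
    acc = 0.0 + 0.0j
    for p, a in zip(phase, amplitude):
        acc += a * (np.cos(p) + 1j * np.sin(p))
    return abs(acc / len(phase))


class TestExtractPhaseAmp:
    def test_pure_tone_phase_slope(self):
        t = np.arange(int(60 * FS)) / FS
        x = np.sin(2 * np.pi * 5.0 * t)
        phase, _ = extract_phase_amp(x, 5.0, 40.0, fs=FS)
        interior = slice(600, -600)
        slope = np.polyfit(t[interior], np.unwrap(phase)[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 5.0, rel=0.01)

    def test_pure_tone_amplitude_magnitude(self):
        t = np.arange(int(60 * FS)) / FS
        x = 2.5 * np.sin(2 * np.pi * 40.0 * t)
        _, amp = extract_phase_amp(x, 5.0, 40.0, fs=FS)
        assert np.allclose(amp[600:-600], 2.5, rtol=0.05)

    def test_amplitude_non_negative(self, rng):
        _, amp = extract_phase_amp(rng.standard_normal(4000), 5.0, 30.0, fs=FS)
        assert (amp >= 0).all()

    def test_band_reaching_nyquist_rejected(self, rng):
        with pytest.raises(ValueError):
            extract_phase_amp(rng.standard_normal(4000), 5.0, 48.0, fs=FS)


class TestCanoltyMI:
    def test_matches_brute_force_complex_mean(self, rng):
        for _ in range(20):
            phase = rng.uniform(-np.pi, np.pi, 64)
            amp = rng.uniform(0, 2, 64)
            assert canolty_mi(phase, amp) == pytest.approx(
                brute_force_mi(phase, amp), abs=1e-12
            )

    def test_uniform_phase_constant_amplitude_is_zero(self):
        phase = np.linspace(0, 8 * np.pi, 400, endpoint=False)
        assert canolty_mi(phase, np.full(400, 3.0)) < 1e-10

    def test_analytic_half_for_cosine_coupling(self):
        phase = np.linspace(0, 20 * np.pi, 2000, endpoint=False)
        amp = 1.0 + np.cos(phase)
        assert canolty_mi(phase, amp) == pytest.approx(0.5, abs=1e-3)

    def test_homogeneous_in_amplitude(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 100)
        amp = rng.uniform(0, 1, 100)
        assert canolty_mi(phase, 4.0 * amp) == pytest.approx(
            4.0 * canolty_mi(phase, amp), rel=1e-12
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            canolty_mi(np.zeros(5), np.zeros(6))


class TestSurrogates:
    def test_fft_rotation_identity_equals_literal_roll(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 200)
        amp = rng.uniform(0, 1, 200)
        mi_all = _all_rotation_mis(phase, amp)
        for k in (0, 1, 17, 100, 199):
            assert mi_all[k] == pytest.approx(
                canolty_mi(phase, np.roll(amp, k)), abs=1e-12
            )

    def test_deterministic_and_respects_min_shift(self, rng):
        phase = rng.uniform(-np.pi, np.pi, 500)
        amp = rng.uniform(0, 1, 500)
        a = surrogate_mis(phase, amp, 50, seed=3, min_shift=100)
        b = surrogate_mis(phase, amp, 50, seed=3, min_shift=100)
        assert np.array_equal(a, b)

    def test_real_mi_within_surrogate_range_for_independent_series(self):
        inside = 0
        for seed in range(40):
            r = np.random.default_rng(seed)
            phase = np.angle(np.fft.ifft(np.fft.fft(r.standard_normal(600)) *
                                         (np.abs(np.fft.fftfreq(600, 1 / FS)) < 8)))
            amp = np.abs(r.standard_normal(600))
            real = canolty_mi(phase, amp)
            sur = surrogate_mis(phase, amp, 100, seed=seed, min_shift=60)
            inside += sur.min() <= real <= sur.max()
        assert inside >= 32  # ~95 % nominal with binomial slack

    def test_too_few_surrogates_rejected(self, rng):
        with pytest.raises(ValueError):
            surrogate_mis(rng.uniform(size=100), rng.uniform(size=100), 1)


class TestNMI:
    def test_zero_when_equal_to_surrogate_mean(self, rng):
        sur = rng.uniform(1, 2, 100)
        assert nmi(sur.mean(), sur) == pytest.approx(0.0)

    def test_two_sd_above_mean_gives_two(self, rng):
        sur = rng.uniform(1, 2, 100)
        assert nmi(sur.mean() + 2 * sur.std(), sur) == pytest.approx(2.0)

    def test_zero_spread_rejected(self):
        with pytest.raises(ValueError):
            nmi(1.0, np.full(10, 0.5))


class TestSlidingWindows:
    def test_20s_at_default_settings_gives_7_windows(self):
        wins = sliding_windows(2000, FS, window=5.0, overlap=2.5)
        assert len(wins) == 7
        assert [a for a, _ in wins] == [0, 250, 500, 750, 1000, 1250, 1500]

    def test_exactly_one_window(self):
        assert len(sliding_windows(500, FS)) == 1

    def test_too_short_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert sliding_windows(490, FS) == []

    def test_overlap_must_be_smaller_than_window(self):
        with pytest.raises(ValueError):
            sliding_windows(1000, FS, window=5.0, overlap=5.0)


class TestSignificantWindows:
    def test_all_null_windows_none_kept(self):
        n_w, n_s = 20, 100
        rng = np.random.default_rng(0)
        sur = rng.uniform(1, 2, (n_w, n_s))
        real = sur.mean(axis=1)  # nMI = 0 everywhere
        kept, nmis = significant_windows(real, sur.mean(1), sur.std(1),
                                         surrogate_mi_matrix=sur)
        assert not kept.any()
        assert np.allclose(nmis, 0.0, atol=1e-9)

    def test_single_strong_window_survives_holm(self):
        # spec'd Holm arithmetic: one z=10 among near-null windows
        rng = np.random.default_rng(1)
        sur = rng.uniform(1, 2, (10, 200))
        real = sur.mean(axis=1)
        real[4] += 10 * sur.std(axis=1)[4]
        kept, nmis = significant_windows(real, sur.mean(1), sur.std(1), method="holm")
        assert kept[4]
        assert kept.sum() == 1
        assert nmis[4] == pytest.approx(10.0)

    def test_single_strong_window_survives_maxstat(self):
        rng = np.random.default_rng(2)
        sur = rng.normal(1.5, 0.1, (10, 200))
        real = sur.mean(axis=1)
        real[7] += 10 * sur.std(axis=1)[7]
        kept, _ = significant_windows(real, sur.mean(1), sur.std(1),
                                      surrogate_mi_matrix=sur)
        assert kept[7]
        assert kept.sum() == 1

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            significant_windows(np.ones(3), np.ones(3), np.ones(3), method="fdr")


class TestBandGrouping:
    def _grid_from_cells(self, rows):
        return PACGrid(cells=pd.DataFrame(rows), fs=FS)

    def test_amp_center_edge_assignment(self):
        # 27.5 Hz centre belongs to beta, 32.5 Hz to gamma
        rows = [
            {"channel": "E1", "phase_center": 5.0, "amp_center": 27.5,
             "n_windows": 10, "n_sig_windows": 1, "mean_nmi": 3.0},
            {"channel": "E1", "phase_center": 5.0, "amp_center": 32.5,
             "n_windows": 10, "n_sig_windows": 1, "mean_nmi": 4.0},
        ]
        res = {r.grouping: r for r in band_group_max(self._grid_from_cells(rows))}
        assert res["theta/beta"].best_nmi == 3.0
        assert res["theta/gamma"].best_nmi == 4.0
        assert np.isnan(res["delta/beta"].best_nmi)

    def test_phase_4hz_assigned_to_theta(self):
        rows = [{"channel": "E1", "phase_center": 4.0, "amp_center": 37.5,
                 "n_windows": 10, "n_sig_windows": 2, "mean_nmi": 5.0}]
        res = {r.grouping: r for r in band_group_max(self._grid_from_cells(rows))}
        assert res["theta/gamma"].best_nmi == 5.0
        assert np.isnan(res["delta/gamma"].best_nmi)

    def test_single_cell_wins_its_grouping_with_channel(self):
        rows = [{"channel": "E3", "phase_center": 3.0, "amp_center": 22.5,
                 "n_windows": 10, "n_sig_windows": 1, "mean_nmi": 2.2}]
        res = {r.grouping: r for r in band_group_max(self._grid_from_cells(rows))}
        assert res["delta/beta"].best_channel == "E3"
        assert res["delta/beta"].best_nmi == 2.2


class TestEndToEnd:
    def test_planted_theta_gamma_coupling_detected(self):
        # single strongly-coupled subject; statistics over seeds live in the
        # acceptance suite
        cfg = SynthConfig(n_channels=4, fs=FS, pac_phase_freq=5.0,
                          pac_amp_freq=40.0, pac_depth=1.0, trf_snr=1.0, seed=0)
        rec = gen_pac_signal(300.0, cfg)
        grid = compute_pac_grid(rec, seed=0)
        res = {r.grouping: r.best_nmi for r in band_group_max(grid)}
        assert np.isfinite(res["theta/gamma"])
        assert res["theta/gamma"] > 4.0
        theta_gamma_cells = grid.cells[
            (grid.cells["phase_center"].between(4, 8))
            & (grid.cells["amp_center"] >= 30)
        ]
        assert theta_gamma_cells["n_sig_windows"].sum() > 10

    def test_nmi_invariant_to_amplitude_scaling(self):
        cfg = SynthConfig(n_channels=4, fs=FS, pac_depth=0.8, trf_snr=2.0, seed=3)
        rec = gen_pac_signal(60.0, cfg)
        g1 = compute_pac_grid(rec, phase_centers=(5.0,), amp_centers=(37.5,), seed=5)
        rec.data *= 10.0
        g2 = compute_pac_grid(rec, phase_centers=(5.0,), amp_centers=(37.5,), seed=5)
        pd.testing.assert_frame_equal(g1.cells, g2.cells)
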