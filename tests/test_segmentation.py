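import numpy as np
import pytest

from melbreath.audio_io import AudioSignal
from melbreath.segmentation import (
    compute_cmw,
    compute_tcw,
    find_cycle_boundaries,
    merge_weak_pauses,
    moment_waveforms,
    segment,
)
from melbreath.simulate import SyntheticConfig, gen_breath_burst, gen_night

from conftest import cmw_oracle, tcw_oracle

FS = 11025.0


class TestTcw:
    def test_constant_signal_zero_variance(self):
        sig = AudioSignal(np.full(4000, 0.5), FS)
        tcw = compute_tcw(sig, delta_s=0.1)
        np.testing.assert_allclose(tcw, 0.0, atol=1e-12)

    def test_white_noise_matches_two_delta(self):
        # E[TCW] for unit-variance noise is the window duration 2*delta
        means = []
        for seed in range(10):
            x = np.random.default_rng(seed).standard_normal(int(FS))
            tcw = compute_tcw(AudioSignal(x, FS), delta_s=0.1)
            means.append(np.mean(tcw[1200:-1200]))
        assert np.mean(means) == pytest.approx(0.2, rel=0.05)

    def test_sinusoid_matches_analytic_variance(self):
        t = np.arange(int(2 * FS)) / FS
        amp = 0.7
        sig = AudioSignal(amp * np.sin(2 * np.pi * 100 * t), FS)
        tcw = compute_tcw(sig, delta_s=0.1)
        expected = 0.2 * amp**2 / 2  # 2*delta * A^2/2
        interior = tcw[2205:-2205]
        np.testing.assert_allclose(interior, expected, rtol=0.02)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="delta window"):
            compute_tcw(AudioSignal(np.zeros(100), FS), delta_s=0.1)


class TestCmw:
    def test_constant_tcw_closed_form(self):
        # integral of (tau-t)^2 * c0 over [-l, l] = c0 * (2/3) l^3
        c0, l_s = 0.7, 0.2
        cmw = compute_cmw(np.full(11025, c0), l_s, FS)
        L = int(round(l_s * FS))
        interior = cmw[L:-L]
        np.testing.assert_allclose(interior, c0 * (2 / 3) * l_s**3, rtol=0.01)

    def test_zero_tcw(self):
        np.testing.assert_array_equal(compute_cmw(np.zeros(5000), 0.1, FS), 0.0)

    def test_unit_impulse(self):
        tcw = np.zeros(8000)
        tau0 = 4000
        tcw[tau0] = 1.0
        l_s = 0.15
        cmw = compute_cmw(tcw, l_s, FS)
        L = int(round(l_s * FS))
        dt = 1.0 / FS
        t = np.arange(8000)
        expected = np.where(np.abs(t - tau0) <= L, ((tau0 - t) * dt) ** 2 * dt, 0.0)
        np.testing.assert_allclose(cmw, expected, atol=1e-15)

    def test_window_longer_than_tcw_rejected(self):
        with pytest.raises(ValueError, match="moment window"):
            compute_cmw(np.zeros(100), 1.0, FS)


class TestOracleAgreement:
    """Running-sum / FFT implementations vs direct per-window summation."""

    @pytest.mark.parametrize("seed", range(10))
    def test_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(int(FS))
        sig = AudioSignal(y, FS)
        tcw = compute_tcw(sig, delta_s=0.1)
        np.testing.assert_allclose(
            tcw, tcw_oracle(y, FS, 0.1), rtol=1e-9, atol=1e-12
        )
        cmw = compute_cmw(tcw, 0.3, FS)
        np.testing.assert_allclose(
            cmw, cmw_oracle(tcw, FS, 0.3), rtol=1e-9, atol=1e-12
        )


def _breathing_clip(n_cycles, seed=0, **kw):
    cfg = SyntheticConfig(
        n_cycles=n_cycles, p_snore=0, p_abnormal=0, p_apnea=0, p_hypopnea=0,
        seed=seed, **kw,
    )
    return gen_night(cfg)


class TestBoundaries:
    def test_periodic_breathing_cycle_count(self):
        # ~60 s of 4 s cycles -> 15 +- 1 recovered
        rec = _breathing_clip(15)
        res = segment(rec.audio)
        assert 14 <= len(res.cycles) <= 16

    def test_silence_degenerate(self):
        sig = AudioSignal(np.zeros(int(30 * FS)), FS)
        with pytest.warns(UserWarning):
            res = find_cycle_boundaries(moment_waveforms(sig))
        assert len(res.cycles) <= 1

    def test_two_bursts_with_long_gap(self, rng):
        fs = FS
        burst = lambda: gen_breath_burst(2.5, level=0.1, rng=rng, fs=fs)
        x = np.concatenate(
            [np.zeros(int(2 * fs)), burst(), np.zeros(int(12 * fs)),
             burst(), np.zeros(int(2 * fs))]
        )
        x += 0.001 * rng.standard_normal(len(x))
        res = segment(AudioSignal(x, fs))
        assert len(res.cycles) == 2
        gaps = [(b - a) / res.fs for a, b in res.pauses]
        assert max(gaps) == pytest.approx(12.0, abs=0.5)

    def test_cycles_sorted_nonoverlapping_long_enough(self):
        rec = gen_night(SyntheticConfig(n_cycles=30, seed=3))
        res = segment(rec.audio)
        for prev, cur in zip(res.cycles, res.cycles[1:]):
            assert prev.end_idx <= cur.start_idx
        assert all(c.duration_s >= 1.5 for c in res.cycles)
        # every pause sits between actives or at the edges
        for a, b in res.pauses:
            assert 0 <= a < b <= res.n_samples

    def test_translation_equivariance(self, rng):
        fs = FS
        burst = gen_breath_burst(2.0, level=0.1, rng=rng, fs=fs)
        noise = 0.002 * rng.standard_normal(int(30 * fs))
        x = noise.copy()
        for start in (3.0, 7.0, 11.0, 15.0, 19.0, 23.0):
            i = int(start * fs)
            x[i : i + len(burst)] += burst
        k = int(0.8 * fs)
        x_shift = np.concatenate([noise[:k], x[:-k]])
        b1 = segment(AudioSignal(x, fs)).extrema["boundaries"]
        b2 = segment(AudioSignal(x_shift, fs)).extrema["boundaries"]
        # interior boundaries move by exactly k (within a couple of samples
        # of floating-point slack in the cumulative sums)
        interior1 = [b for b in b1 if 2 * fs < b < 26 * fs]
        matched = 0
        for b in interior1:
            if np.min(np.abs(np.asarray(b2) - (b + k))) <= 3:
                matched += 1
        assert matched >= len(interior1) - 1


class TestMergeWeakPauses:
    def _fixture(self, rng, blip_level):
        fs = FS
        # short tails: trailing silence long enough to form its own edge
        # segment would (correctly) be removed as a weak cycle
        dur = 27.5 if blip_level else 21.5
        x = 0.001 * rng.standard_normal(int(dur * fs))
        for start in (2.0, 6.0, 10.0, 14.0, 18.0):
            b = gen_breath_burst(2.5, level=0.2, rng=rng, fs=fs)
            i = int(start * fs)
            x[i : i + len(b)] += b
        if blip_level:
            b = gen_breath_burst(2.5, level=blip_level, rng=rng, fs=fs)
            i = int(24.0 * fs)
            x[i : i + len(b)] += b
        return AudioSignal(x, fs)

    def test_noise_blip_removed(self, rng):
        sig = self._fixture(rng, blip_level=0.01)  # 5 % of real amplitude
        res = find_cycle_boundaries(moment_waveforms(sig))
        merged = merge_weak_pauses(res, sig, alpha=0.2)
        # the blip's segment(s) disappear; the five real breaths remain
        assert len(res.cycles) > 5
        assert len(merged.cycles) == 5
        # remaining active phases all lie on the real bursts (before 21 s)
        assert all(b / merged.fs <= 21.0 for _, b in merged.active_phases)

    def test_uniform_amplitudes_unchanged(self, rng):
        sig = self._fixture(rng, blip_level=0.0)
        res = find_cycle_boundaries(moment_waveforms(sig))
        merged = merge_weak_pauses(res, sig, alpha=0.2)
        assert len(merged.cycles) == len(res.cycles)

    def test_alpha_zero_disables(self, rng):
        sig = self._fixture(rng, blip_level=0.01)
        res = find_cycle_boundaries(moment_waveforms(sig))
        assert merge_weak_pauses(res, sig, alpha=0.0) is res


def test_long_recording_uses_decimated_grid():
    rec = _breathing_clip(8, seed=1)
    mw_full = moment_waveforms(rec.audio)
    assert mw_full.fs == FS
    mw_grid = moment_waveforms(rec.audio, max_full_rate_s=10.0)
    assert mw_grid.fs == pytest.approx(100.0, rel=0.01)
    # boundaries from both grids agree to within the hop resolution
    r_full = find_cycle_boundaries(mw_full)
    r_grid = find_cycle_boundaries(mw_grid)
    assert abs(len(r_full.cycles) - len(r_grid.cycles)) <= 1
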