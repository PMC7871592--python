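import numpy as np
import pytest
from scipy.special import i0, i1

from connkit import (
    SpikeTrain,
    extract_mua,
    gen_locked_spikes,
    gen_phase_lagged_pair,
    mrl,
    phase_angle_compare,
    shifted_mrl,
    spike_phase_coupling,
    theta_phase_interp,
)

RAW_RATE = 10_000.0


def inject_spikes(rng, n_spikes=200, seconds=10.0, amp_sd=6.0, rate=RAW_RATE):
    """Gaussian noise with fast biphasic spikes of known times injected."""
    noise = rng.standard_normal(int(seconds * rate))
    tt = np.arange(-15, 16) / rate
    wave = -amp_sd * np.exp(-0.5 * (tt / 3e-4) ** 2) * np.cos(2 * np.pi * 1500 * tt)
    idx = np.sort(
        rng.choice(np.arange(int(0.1 * rate), int((seconds - 0.1) * rate)), n_spikes, replace=False)
    )
    # enforce a minimum separation so injected events are unambiguous
    idx = idx[np.r_[True, np.diff(idx) > int(0.005 * rate)]]
    sig = noise.copy()
    for s in idx:
        sig[s - 15 : s + 16] += wave
    return sig, idx / rate


class TestExtractMua:
    def test_flat_signal_empty_train(self):
        assert extract_mua(np.zeros(50_000), RAW_RATE).n == 0

    def test_injected_spikes_recovered(self, rng):
        sig, true_t = inject_spikes(rng)
        st = extract_mua(sig, RAW_RATE)
        d = np.abs(st.times[None, :] - true_t[:, None])
        hit_rate = (d.min(axis=1) < 0.001).mean()
        assert hit_rate >= 0.95

    def test_long_artifact_excluded(self, rng):
        # rule operates on the filtered trace; feed one directly (hp_hz=None)
        sig = 0.1 * rng.standard_normal(100_000)
        sig[50_000 : 50_000 + 30] -= 50.0  # 3 ms supra-threshold excursion
        sig[20_000 : 20_000 + 5] -= 50.0  # 0.5 ms genuine spike
        st = extract_mua(sig, RAW_RATE, hp_hz=None)
        assert not np.any(np.abs(st.times - 5.0) < 0.004)
        assert np.any(np.abs(st.times - 2.0) < 0.001)

    def test_refractory_pair_cleaned(self, rng):
        sig, _ = inject_spikes(rng, n_spikes=50)
        st = extract_mua(sig, RAW_RATE)
        if st.n > 1:
            assert np.min(np.diff(st.times)) >= 0.001

    def test_redetection_stable(self, rng):
        sig, _ = inject_spikes(rng)
        st1 = extract_mua(sig, RAW_RATE)
        st2 = extract_mua(sig, RAW_RATE)
        assert np.array_equal(st1.times, st2.times)


class TestThetaPhaseInterp:
    def test_pure_sinusoid_matches_analytic(self):
        rate = 1000.0
        t = np.arange(int(30 * rate)) / rate
        lfp = np.cos(2 * np.pi * 8 * t)
        ps = theta_phase_interp(lfp, rate)
        # analytic phase with trough at 0 deg: cos trough at 180 deg of cycle
        analytic = (np.degrees(2 * np.pi * 8 * t) + 180.0) % 360.0
        inner = slice(int(2 * rate), int(28 * rate))
        err = np.abs(((ps.phase[inner] - analytic[inner]) + 180) % 360 - 180)
        assert np.percentile(err, 95) < 1.0

    def test_gaps_masked(self):
        rate = 1000.0
        t = np.arange(int(20 * rate)) / rate
        gate = ((t // 2) % 2 == 0).astype(float)  # 2 s on / 2 s off
        lfp = gate * np.cos(2 * np.pi * 8 * t)
        ps = theta_phase_interp(lfp, rate)
        on = ps.valid_mask[(t > 0.5) & (t < 1.5)]
        off = ps.valid_mask[(t > 2.5) & (t < 3.5)]
        assert on.mean() > 0.9
        assert off.mean() < 0.1

    def test_no_troughs_rejected(self):
        with pytest.raises(ValueError, match="troughs"):
            theta_phase_interp(np.zeros(2_000), 250.0)


@pytest.fixture(scope="module")
def phase_series():
    rec = gen_phase_lagged_pair(8.0, 0.0, 50.0, 180.0, 1000.0, seed=2)
    return theta_phase_interp(rec.data[0], 1000.0)


class TestSpikePhaseCoupling:
    def test_perfect_locking(self, phase_series):
        # spike exactly where phase = 90 in every cycle
        times = gen_locked_spikes(phase_series.phase, 1000.0, 90.0, 1e6, 4000, seed=1)
        res = spike_phase_coupling(SpikeTrain(times=times), phase_series, seed=0)
        assert res.mrl > 0.999
        assert abs(res.mean_angle_deg - 90.0) < 2.0

    def test_four_point_symmetric_phases_zero_mrl(self):
        r, _ = mrl(np.array([0.0, 90.0, 180.0, 270.0] * 10))
        assert r < 1e-12

    def test_von_mises_kappa_one(self, phase_series):
        times = gen_locked_spikes(phase_series.phase, 1000.0, 90.0, 1.0, 6000, seed=3)
        res = spike_phase_coupling(SpikeTrain(times=times), phase_series, seed=4)
        expect = i1(1) / i0(1)
        se = np.sqrt((1 - expect**2) / 2 / 1000)
        assert abs(res.mrl - expect) < 3 * se
        assert abs(((res.mean_angle_deg - 90.0) + 180) % 360 - 180) < 5.0

    def test_insufficient_spikes_excluded_not_error(self, phase_series):
        res = spike_phase_coupling(SpikeTrain(times=np.array([1.0, 2.0])), phase_series)
        assert res.status == "excluded"
        assert np.isnan(res.mrl)

    def test_rotation_equivariance(self):
        phases = np.random.default_rng(0).vonmises(0, 2.0, 500)
        deg = np.degrees(phases) % 360
        r0, a0 = mrl(deg)
        r1, a1 = mrl((deg + 70.0) % 360)
        assert np.isclose(r0, r1, atol=1e-12)
        assert np.isclose((a1 - a0) % 360, 70.0, atol=1e-9)

    def test_subsample_reproducible(self, phase_series):
        times = gen_locked_spikes(phase_series.phase, 1000.0, 90.0, 1.0, 6000, seed=5)
        st = SpikeTrain(times=times)
        r1 = spike_phase_coupling(st, phase_series, seed=9)
        r2 = spike_phase_coupling(st, phase_series, seed=9)
        assert r1.mrl == r2.mrl


class TestShiftedMrl:
    def test_delay_recovered(self, fm_theta):
        lfp, rate = fm_theta
        ps = theta_phase_interp(lfp, rate)
        times = gen_locked_spikes(ps.phase, rate, 90.0, 3.0, 6000, delay_ms=24.0, seed=5)
        res = shifted_mrl(SpikeTrain(times=np.sort(times)), ps, seed=6)
        assert res.offsets_ms.size == 51
        # shifting by -24 ms cancels the delay: best offset within 2 grid steps
        assert abs(res.best_offset_ms + 24.0) <= 8.0

    def test_no_delay_flat_near_zero(self, fm_theta):
        lfp, rate = fm_theta
        ps = theta_phase_interp(lfp, rate)
        times = gen_locked_spikes(ps.phase, rate, 90.0, 3.0, 6000, seed=7)
        res = shifted_mrl(SpikeTrain(times=times), ps, seed=8)
        assert abs(res.best_offset_ms) <= 12.0


class TestWatsonWilliams:
    def test_identical_groups(self):
        g = np.array([10.0, 20.0, 30.0, 40.0])
        res = phase_angle_compare(g, g)
        assert res["p"] > 0.9

    def test_separated_groups_power(self):
        rng = np.random.default_rng(1)
        rejections = 0
        n_rep = 50
        for _ in range(n_rep):
            a = np.degrees(rng.vonmises(0.0, 2.0, 15)) % 360
            b = np.degrees(rng.vonmises(np.pi / 2, 2.0, 15)) % 360
            if phase_angle_compare(a, b)["p"] < 0.05:
                rejections += 1
        assert rejections / n_rep > 0.9

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            phase_angle_compare([10.0], [20.0, 30.0])
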