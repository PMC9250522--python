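import numpy as np
import pytest
from scipy.signal import butter, sosfreqz

from odorbarrel.orofacial import (
    WHISK_BAND,
    analytic_decompose,
    breath_cycles,
    combine_whiskers,
    curvature_change,
    epoch_kinematics,
    resample,
    trial_epoch_stats,
    whisk_cycles,
)
from odorbarrel.protocol import make_protocol
from odorbarrel.synth import OrofacialParams, simulate_orofacial

FS = 500.0


def _sine(freq, amp=1.0, offset=0.0, dur=10.0, fs=FS, phase=0.0):
    t = np.arange(0, dur, 1 / fs)
    return offset + amp * np.sin(2 * np.pi * freq * t + phase)


class TestAnalyticDecompose:
    def test_in_band_sinusoid_envelope_and_phase(self):
        x = _sine(8.0, amp=3.0)
        filt, env, phase = analytic_decompose(x, FS, WHISK_BAND)
        core = slice(int(FS), -int(FS))  # away from the edges
        assert env[core].mean() == pytest.approx(3.0, rel=0.01)
        assert np.allclose(env[core], 3.0, rtol=0.02)
        # phase advances 2*pi per period
        slope = np.polyfit(np.arange(len(phase))[core] / FS, phase[core], 1)[0]
        assert slope / (2 * np.pi) == pytest.approx(8.0, rel=0.01)

    def test_constant_signal_removed(self):
        filt, env, _ = analytic_decompose(np.full(5000, 12.0), FS, WHISK_BAND)
        assert np.abs(filt).max() < 1e-9

    def test_below_band_attenuation_matches_filter_oracle(self):
        """A 1 Hz tone is attenuated >10x relative to an in-band tone, and the
        measured attenuation matches the Butterworth magnitude response."""
        x_out = _sine(1.0, amp=1.0, dur=20.0)
        x_in = _sine(10.0, amp=1.0, dur=20.0)
        core = slice(int(2 * FS), -int(2 * FS))
        _, env_out, _ = analytic_decompose(x_out, FS, WHISK_BAND)
        _, env_in, _ = analytic_decompose(x_in, FS, WHISK_BAND)
        ratio = env_out[core].mean() / env_in[core].mean()
        assert ratio < 0.1
        # oracle: squared magnitude (forward-backward) of the same SOS filter
        sos = butter(2, WHISK_BAND, btype="bandpass", fs=FS, output="sos")
        w, h = sosfreqz(sos, worN=[1.0, 10.0], fs=FS)
        expected = np.abs(h[0]) ** 2 / np.abs(h[1]) ** 2
        assert ratio == pytest.approx(expected, rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="band"):
            analytic_decompose(np.zeros(100), 50.0, (4.0, 30.0))


class TestWhiskCycles:
    def test_sinusoid_amplitude_and_setpoint(self):
        """10 + 5 sin(2 pi 8 t): amplitude (range) 10 deg, setpoint 10 deg."""
        tab = whisk_cycles(_sine(8.0, amp=5.0, offset=10.0), FS)
        assert len(tab) > 50
        assert tab.amplitude.mean() == pytest.approx(10.0, rel=0.02)
        assert tab.setpoint.mean() == pytest.approx(10.0, rel=0.02)
        assert tab.frequency.mean() == pytest.approx(8.0, rel=0.02)

    def test_constant_angle_empty_table(self):
        assert len(whisk_cycles(np.full(5000, 15.0), FS)) == 0

    def test_amplitude_linear_setpoint_invariant(self):
        t1 = whisk_cycles(_sine(8.0, amp=4.0, offset=20.0), FS)
        t2 = whisk_cycles(_sine(8.0, amp=8.0, offset=20.0), FS)
        assert t2.amplitude.mean() == pytest.approx(2 * t1.amplitude.mean(), rel=0.01)
        assert t2.setpoint.mean() == pytest.approx(t1.setpoint.mean(), abs=0.1)

    def test_cycles_disjoint_ordered_amplitude_nonnegative(self):
        tab = whisk_cycles(_sine(11.0, amp=3.0, offset=5.0), FS)
        assert (tab.amplitude >= 0).all()
        assert (tab.t_start.to_numpy()[1:] >= tab.t_end.to_numpy()[:-1] - 1e-9).all()
        assert tab.frequency.between(WHISK_BAND[0] * 0.85, WHISK_BAND[1] * 1.15).all()


class TestBreathCycles:
    def test_frequency_from_cycle_duration(self):
        tab = breath_cycles(_sine(6.0, amp=2.0), FS)
        assert tab.frequency.mean() == pytest.approx(6.0, rel=0.02)

    def test_amplitude_scales_frequency_invariant(self):
        t1 = breath_cycles(_sine(6.0, amp=1.0), FS)
        t2 = breath_cycles(_sine(6.0, amp=2.0), FS)
        assert t2.amplitude.mean() == pytest.approx(2 * t1.amplitude.mean(), rel=0.01)
        assert t2.frequency.mean() == pytest.approx(t1.frequency.mean(), rel=0.01)

    def test_silence_gives_empty_table(self):
        assert len(breath_cycles(np.zeros(5000), FS)) == 0

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError, match="sampling"):
            breath_cycles(np.zeros(100), 30.0)


@pytest.fixture(scope="module")
def proto():
    return make_protocol(seed=0)


@pytest.fixture(scope="module")
def kin_sessions():
    """Three noiseless synthetic sessions with known odor gains."""
    params = OrofacialParams()  # whisk gain 1.3, breath gain 0.7
    protos, stats = [], []
    for s in range(3):
        pr = make_protocol(seed=100 + s)
        tr = simulate_orofacial(pr, params, seed=s)
        protos.append(pr)
        stats.append(trial_epoch_stats(tr, pr))
    return stats, protos


class TestCurvatureChange:
    def test_constant_curvature_gives_zero(self, proto):
        n = int(proto.trial_duration_s * proto.behavior_rate_hz)
        kappa = np.full((2, n), 0.02)
        assert np.allclose(curvature_change(kappa, proto), 0.0)

    def test_step_change_recovered(self, proto):
        fs = proto.behavior_rate_hz
        n = int(proto.trial_duration_s * fs)
        t = np.arange(n) / fs - proto.stim_onset_s
        kappa = np.where(t >= 0, 0.03, 0.01)[None, :]
        out = curvature_change(kappa, proto)
        assert np.allclose(out[0, t >= 0], 0.02)

    def test_rectification_precedes_baselining(self, proto):
        """Sign-flipping curvature of constant magnitude gives |dk| = 0."""
        fs = proto.behavior_rate_hz
        n = int(proto.trial_duration_s * fs)
        kappa = 0.02 * np.sign(np.sin(2 * np.pi * 8 * np.arange(n) / fs) + 0.5)[None, :]
        kappa[kappa == 0] = 0.02
        out = curvature_change(np.abs(kappa) * np.sign(kappa), proto)
        assert np.allclose(out, 0.0, atol=1e-12)


class TestUtilities:
    def test_resample_preserves_sinusoid(self):
        x = _sine(6.0, amp=2.0, dur=4.0, fs=500.0)
        y = resample(x, 500.0, 100.0)
        assert y.size == 400
        t = np.arange(y.size) / 100.0
        core = slice(50, -50)
        assert np.allclose(y[core], 2.0 * np.sin(2 * np.pi * 6.0 * t)[core], atol=0.02)

    def test_combine_whiskers_ignores_missing_detections(self):
        traces = np.array([[1.0, 2.0], [3.0, np.nan]])
        assert np.allclose(combine_whiskers(traces), [2.0, 2.0])


class TestEpochKinematics:
    def test_whisk_amplitude_gain_recovered(self, kin_sessions):
        stats, protos = kin_sessions
        kc = epoch_kinematics(stats, protos, contrast="without_grating")
        amp = kc.measures.set_index("measure").loc["whisk_amplitude"]
        assert amp.mean_odor / amp.mean_no_odor == pytest.approx(1.3, rel=0.02)
        assert amp.p_between < 0.26  # n=3 sessions: smallest two-sided Wilcoxon p is 0.25

    def test_breath_amplitude_gain_sign(self, kin_sessions):
        stats, protos = kin_sessions
        kc = epoch_kinematics(stats, protos, contrast="without_grating")
        ba = kc.measures.set_index("measure").loc["breath_amplitude"]
        assert ba.mean_odor < ba.mean_no_odor
        assert ba.mean_odor / ba.mean_no_odor == pytest.approx(0.7, rel=0.05)

    def test_within_session_pvalues_significant(self, kin_sessions):
        stats, protos = kin_sessions
        kc = epoch_kinematics(stats, protos, contrast="without_grating")
        assert (kc.p_within["whisk_amplitude"] < 0.001).all()

    def test_unknown_contrast_rejected(self, kin_sessions):
        stats, protos = kin_sessions
        with pytest.raises(ValueError, match="contrast"):
            epoch_kinematics(stats, protos, contrast="bogus")
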