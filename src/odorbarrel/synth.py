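"""Synthetic olfacto-tactile sessions with known ground truth.

Every downstream stage of the package (preprocessing, modulation statistics,
orofacial kinematics, decoding) is exercised on sessions produced here.  The
generator emulates:

* two-photon ROI fluorescence with GCaMP6s-like slow transients (single
  exponential decay), shared neuropil contamination and white noise, for a
  population containing configurable fractions of tactile-responsive and
  odor-modulated (enhanced / suppressed) cells, plus a low-dimensional
  odor-identity subspace whose angle to the tactile discriminant is a
  parameter;
* whisker-pad angle and curvature and breathing pressure at 500 Hz, with
  odor-triggered gain changes on whisking amplitude, setpoint, curvature and
  breathing amplitude / frequency;
* facial motion-energy matrices (time x pixels) of configurable rank, with
  or without odor information.

With all odor effects set to zero the condition-wise response distributions
are exchangeable across odor / no-odor labels, so shuffle-null and
calibration properties of the analysis can be tested exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .protocol import StimulusProtocol, parse_mixture

__all__ = [
    "PopulationParams",
    "OrofacialParams",
    "RoiFluorescence",
    "GroundTruth",
    "OrofacialTraces",
    "FacialMotion",
    "simulate_population",
    "simulate_orofacial",
    "simulate_facial_motion",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass
class RoiFluorescence:
    """Raw ROI fluorescence and matched neuropil traces, cells x trials x frames (a.u.)."""

    F: np.ndarray
    F_n: np.ndarray
    frame_times_s: np.ndarray  # relative to stimulus onset

    def __post_init__(self) -> None:
        if self.F.shape != self.F_n.shape:
            raise ValueError("F and F_n must have the same shape")


@dataclass
class GroundTruth:
    """Every effect injected into a simulated population.

    ``amplitudes`` is the cells x conditions table of mean evoked dF/F
    amplitudes; all other fields decompose it.  ``effect_size`` is the signed
    odor-modulation amplitude in dF/F units (0 for unmodulated cells).
    """

    tactile_responsive: np.ndarray  # bool per cell
    odor_modulated: np.ndarray  # bool per cell
    direction: np.ndarray  # 'enhanced' | 'suppressed' | 'none' per cell
    effect_size: np.ndarray  # signed dF/F per cell
    tactile_amp: np.ndarray  # dF/F per cell
    tactile_discriminant: np.ndarray  # unit vector over cells
    odor_loadings: dict[str, np.ndarray]  # pure odor -> unit vector over cells
    subspace_angle_deg: float
    amplitudes: np.ndarray  # cells x conditions

    @property
    def responsive(self) -> np.ndarray:
        return self.tactile_responsive | self.odor_modulated


@dataclass
class OrofacialTraces:
    """Whisker-pad angle (deg), curvature (1/mm) and breathing pressure (a.u.), trials x samples."""

    angle: np.ndarray
    curvature: np.ndarray
    pressure: np.ndarray
    fs_hz: float
    sample_times_s: np.ndarray  # relative to stimulus onset


@dataclass
class FacialMotion:
    """Facial motion-energy matrix, (total video frames) x pixels, with trial geometry."""

    motion: np.ndarray
    fs_hz: float
    n_trials: int
    frames_per_trial: int

    def trial_view(self) -> np.ndarray:
        """Reshape to trials x frames x pixels."""
        return self.motion.reshape(self.n_trials, self.frames_per_trial, -1)


# --------------------------------------------------------------------------
# neural population
# --------------------------------------------------------------------------


@dataclass
class PopulationParams:
    """Knobs of the neural-population generator.

    Amplitudes are in dF/F units; fluorescence baselines in arbitrary units.
    Odor-modulation effect sizes are drawn log-normal (the field provides no
    canonical effect-size distribution; see the methods note).
    """

    n_cells: int = 200
    frac_tactile: float = 0.5  # tactile-responsive fraction
    frac_modulated: float = 0.2  # odor-modulated fraction
    frac_enhanced: float = 0.5  # of the modulated cells
    tactile_amp_median: float = 0.4  # dF/F, log-normal median
    tactile_amp_sigma: float = 0.5  # log-normal shape
    mod_effect_median: float = 0.25  # dF/F, log-normal median of |effect|
    mod_effect_sigma: float = 0.5
    orientation_coef: float = 0.15  # dF/F scale of orientation tuning
    odor_identity_coef: float = 0.0  # dF/F scale of the odor-identity subspace
    subspace_angle_deg: float = 90.0  # angle of odor loadings to tactile discriminant
    kernel_tau_s: float = 1.5  # GCaMP6s-like decay
    noise_sigma: float = 5.0  # a.u., white noise on F and F_n
    neuropil_sigma: float = 10.0  # a.u., shared slow fluctuation
    neuropil_timescale_s: float = 0.5
    neuropil_r: float = 0.7  # contamination coefficient mixed into F
    baseline_f: float = 100.0  # a.u., median ROI baseline
    baseline_f_sigma: float = 0.3
    neuropil_baseline_f: float = 50.0  # a.u.

    def validate(self) -> None:
        for name in ("frac_tactile", "frac_modulated", "frac_enhanced"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.kernel_tau_s <= 0:
            raise ValueError("kernel_tau_s must be > 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


def _response_kernel(protocol: StimulusProtocol, tau_s: float) -> np.ndarray:
    """Unit evoked-transient waveform over the trial.

    A boxcar over the stimulation epoch convolved with a single-exponential
    decay, scaled so that its mean over the stimulation epoch is exactly 1:
    a cell with injected amplitude ``a`` then shows a stimulus-epoch mean
    dF/F of ``a``.
    """
    t = protocol.frame_times()
    dt = 1.0 / protocol.frame_rate_hz
    box = protocol.frames_in(protocol.stim_epoch_s).astype(float)
    kern = np.exp(-np.arange(0, 6 * tau_s, dt) / tau_s)
    kern /= kern.sum()
    resp = np.convolve(box, kern)[: t.size]
    stim = protocol.frames_in(protocol.stim_epoch_s)
    mean_stim = resp[stim].mean()
    if mean_stim <= 0:
        raise ValueError("stimulation epoch produced no response support")
    return resp / mean_stim


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


def _odor_loading(u_tact: np.ndarray, angle_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Unit loading vector at a given principal angle to the tactile discriminant."""
    if u_tact.size == 1:
        # no orthogonal complement in one dimension
        return u_tact.copy()
    w = rng.standard_normal(u_tact.size)
    w -= (w @ u_tact) * u_tact
    w = _unit(w)
    a = np.deg2rad(angle_deg)
    return np.cos(a) * u_tact + np.sin(a) * w


def _condition_amplitudes(
    protocol: StimulusProtocol, p: PopulationParams, gt_parts: dict, rng: np.random.Generator
) -> np.ndarray:
    """Mean evoked dF/F amplitude per cell per condition."""
    n_cells = p.n_cells
    conds = protocol.conditions
    gratings = sorted({c.grating for c in conds if c.grating is not None})
    pure_odors = sorted(
        {c.odor for c in conds if c.odor is not None and parse_mixture(c.odor) is None}
    )

    u_tact = _unit(rng.standard_normal(n_cells))
    loadings = {o: _odor_loading(u_tact, p.subspace_angle_deg, rng) for o in pure_odors}

    A = np.zeros((n_cells, len(conds)))
    orient_sign = {g: (1.0 if i == 0 else -1.0) for i, g in enumerate(gratings)}
    for k, c in enumerate(conds):
        a = np.zeros(n_cells)
        if c.grating is not None:
            a += gt_parts["tactile_amp"]
            a += p.orientation_coef * orient_sign[c.grating] * u_tact
        if c.odor is not None:
            a += gt_parts["effect_size"]
            mix = parse_mixture(c.odor)
            weights = mix if mix is not None else {c.odor: 1.0}
            for o, w in weights.items():
                if o not in loadings:
                    raise ValueError(f"mixture component {o!r} has no pure-odor condition")
                a += p.odor_identity_coef * w * loadings[o]
        A[:, k] = a

    # fluorescence cannot drop below zero: suppression saturates at -0.9 dF/F
    np.clip(A, -0.9, None, out=A)

    gt_parts["tactile_discriminant"] = u_tact
    gt_parts["odor_loadings"] = loadings
    return A


def simulate_population(
    protocol: StimulusProtocol,
    params: PopulationParams | None = None,
    seed: int = 0,
) -> tuple[RoiFluorescence, GroundTruth]:
    """Simulate a population recording for one session.

    The ROI trace is built as ``F = B + r * F_n_true + B * dff(t) + noise``
    with ``F_n = F_n_true + noise``: the ROI contains the neuropil signal at
    the same coefficient the correction subtracts, so in the noiseless case
    neuropil correction recovers ``B * (1 + dff)`` exactly.

    Returns the raw fluorescence container and the full ground truth.
    """
    p = params or PopulationParams()
    p.validate()
    rng = np.random.default_rng(seed)
    n_cells, n_trials, n_frames = p.n_cells, protocol.n_trials, protocol.n_frames

    # --- per-cell identities -------------------------------------------------
    tactile = rng.random(n_cells) < p.frac_tactile
    modulated = rng.random(n_cells) < p.frac_modulated
    enhanced = rng.random(n_cells) < p.frac_enhanced

    tactile_amp = np.where(
        tactile,
        p.tactile_amp_median * np.exp(p.tactile_amp_sigma * rng.standard_normal(n_cells)),
        0.0,
    )
    sign = np.where(enhanced, 1.0, -1.0)
    effect = np.where(
        modulated,
        sign * p.mod_effect_median * np.exp(p.mod_effect_sigma * rng.standard_normal(n_cells)),
        0.0,
    )
    direction = np.where(modulated, np.where(enhanced, "enhanced", "suppressed"), "none")

    gt_parts: dict = {"tactile_amp": tactile_amp, "effect_size": effect}
    A = _condition_amplitudes(protocol, p, gt_parts, rng)

    # --- dF/F signal ---------------------------------------------------------
    resp = _response_kernel(protocol, p.kernel_tau_s)  # (frames,)
    trial_amp = A[:, protocol.condition_labels()]  # cells x trials
    dff = trial_amp[:, :, None] * resp[None, None, :]
    # fluorescence saturates at zero: the trace cannot drop below -1 dF/F
    np.clip(dff, -0.95, None, out=dff)

    # --- fluorescence with neuropil and noise --------------------------------
    B = p.baseline_f * np.exp(p.baseline_f_sigma * rng.standard_normal(n_cells))
    npil = gaussian_filter1d(
        rng.standard_normal((n_trials, n_frames)),
        sigma=p.neuropil_timescale_s * protocol.frame_rate_hz,
        axis=-1,
        mode="nearest",
    )
    npil *= p.neuropil_sigma
    fn_true = p.neuropil_baseline_f + npil[None, :, :]

    F = (
        B[:, None, None] * (1.0 + dff)
        + p.neuropil_r * fn_true
        + p.noise_sigma * rng.standard_normal(dff.shape)
    )
    F_n = fn_true + p.noise_sigma * rng.standard_normal(dff.shape)

    gt = GroundTruth(
        tactile_responsive=tactile,
        odor_modulated=modulated,
        direction=direction,
        effect_size=effect,
        tactile_amp=tactile_amp,
        tactile_discriminant=gt_parts["tactile_discriminant"],
        odor_loadings=gt_parts["odor_loadings"],
        subspace_angle_deg=p.subspace_angle_deg,
        amplitudes=A,
    )
    return RoiFluorescence(F=F, F_n=F_n, frame_times_s=protocol.frame_times()), gt


# --------------------------------------------------------------------------
# orofacial channels
# --------------------------------------------------------------------------


@dataclass
class OrofacialParams:
    """Whisking / breathing generator.  Angles in degrees, curvature in 1/mm.

    ``whisk_amp_deg`` is the sine amplitude; the per-cycle whisking amplitude
    (range of motion) extracted downstream is twice this value.  Gains of 1
    make odor trials statistically identical to the others.
    """

    whisk_f0_hz: float = 8.0
    whisk_amp_deg: float = 7.5
    setpoint_deg: float = 40.0
    curvature_amp: float = 0.02  # 1/mm, oscillatory component
    contact_curvature: float = 0.02  # 1/mm extra |curvature| on grating contact
    breath_f0_hz: float = 6.0
    breath_amp: float = 1.0  # a.u.
    odor_whisk_gain: float = 1.3  # multiplies whisk amplitude from odor onset
    odor_setpoint_shift_deg: float = 2.0
    odor_curvature_gain: float = 1.2
    odor_breath_gain: float = 0.7  # breathing amplitude reduction under odor
    odor_breath_freq_gain: float = 1.0
    angle_noise_deg: float = 0.0
    curvature_noise: float = 0.0
    pressure_noise: float = 0.0

    def validate(self) -> None:
        if not 4.0 < self.whisk_f0_hz < 30.0:
            warnings.warn(
                f"whisk_f0_hz={self.whisk_f0_hz} outside the 4-30 Hz whisking analysis "
                "band; extracted cycles will be attenuated",
                stacklevel=3,
            )
        if not 4.0 < self.breath_f0_hz < 20.0:
            warnings.warn(
                f"breath_f0_hz={self.breath_f0_hz} outside the 4-20 Hz breathing "
                "analysis band; extracted cycles will be attenuated",
                stacklevel=3,
            )


def simulate_orofacial(
    protocol: StimulusProtocol,
    params: OrofacialParams | None = None,
    seed: int = 0,
) -> OrofacialTraces:
    """Simulate whisker-pad angle / curvature and breathing pressure per trial.

    angle(t) = setpoint(t) + A(t) sin(phase); on odor trials the whisking
    amplitude, setpoint, curvature and breathing change by the configured
    gains from stimulus onset onward.  Inhalations are negative pressure
    deflections.
    """
    p = params or OrofacialParams()
    p.validate()
    rng = np.random.default_rng(seed)
    fs = protocol.behavior_rate_hz
    n_samp = int(round(protocol.trial_duration_s * fs))
    t = np.arange(n_samp) / fs - protocol.stim_onset_s  # onset-relative
    post = t >= 0.0

    n_trials = protocol.n_trials
    conds = protocol.trial_conditions()
    has_odor = np.array([c.odor is not None for c in conds])
    has_grating = np.array([c.grating is not None for c in conds])

    angle = np.empty((n_trials, n_samp))
    curv = np.empty((n_trials, n_samp))
    press = np.empty((n_trials, n_samp))

    stim = (t >= protocol.stim_epoch_s[0]) & (t < protocol.stim_epoch_s[1])

    for tr in range(n_trials):
        phi_w = rng.uniform(0, 2 * np.pi)
        phi_b = rng.uniform(0, 2 * np.pi)
        amp = np.full(n_samp, p.whisk_amp_deg)
        setp = np.full(n_samp, p.setpoint_deg)
        camp = np.full(n_samp, p.curvature_amp)
        bamp = np.full(n_samp, p.breath_amp)
        f_b = np.full(n_samp, p.breath_f0_hz)
        if has_odor[tr]:
            amp[post] *= p.odor_whisk_gain
            setp[post] += p.odor_setpoint_shift_deg
            camp[post] *= p.odor_curvature_gain
            bamp[post] *= p.odor_breath_gain
            f_b[post] *= p.odor_breath_freq_gain

        w_phase = 2 * np.pi * p.whisk_f0_hz * (t - t[0]) + phi_w
        angle[tr] = setp + amp * np.sin(w_phase)
        curv[tr] = camp * np.sin(w_phase)
        if has_grating[tr]:
            # contact during the stimulation epoch raises |curvature|
            curv[tr, stim] += p.contact_curvature * np.sign(np.sin(w_phase[stim]) + 1e-12)
        b_phase = 2 * np.pi * np.cumsum(f_b) / fs + phi_b
        press[tr] = -bamp * np.sin(b_phase)

    if p.angle_noise_deg > 0:
        angle += p.angle_noise_deg * rng.standard_normal(angle.shape)
    if p.curvature_noise > 0:
        curv += p.curvature_noise * rng.standard_normal(curv.shape)
    if p.pressure_noise > 0:
        press += p.pressure_noise * rng.standard_normal(press.shape)

    return OrofacialTraces(angle=angle, curvature=curv, pressure=press, fs_hz=fs, sample_times_s=t)


# --------------------------------------------------------------------------
# facial motion energy
# --------------------------------------------------------------------------


def simulate_facial_motion(
    protocol: StimulusProtocol,
    rank: int = 5,
    odor_informative: bool = False,
    seed: int = 0,
    n_pixels: int = 400,
    noise_sigma: float = 0.0,
    odor_effect: float = 2.0,
) -> FacialMotion:
    """Simulate a low-rank facial motion-energy matrix (time x pixels).

    When ``odor_informative`` is False the temporal components are
    independent of odor labels; when True, each pure odor adds its own
    pattern of component amplitudes during the stimulation epoch, so facial
    behavior carries odor identity.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    fs = protocol.facial_rate_hz
    fpt = int(round(protocol.trial_duration_s * fs))
    n_time = protocol.n_trials * fpt

    # smooth temporal components with decreasing energy
    U = gaussian_filter1d(rng.standard_normal((n_time, rank)), sigma=fs * 0.25, axis=0)
    U /= np.linalg.norm(U, axis=0, keepdims=True)
    scales = 10.0 * 0.5 ** np.arange(rank)

    if odor_informative:
        t = np.arange(fpt) / fs - protocol.stim_onset_s
        stim = (t >= protocol.stim_epoch_s[0]) & (t < protocol.stim_epoch_s[1])
        conds = protocol.trial_conditions()
        odors = sorted({c.odor for c in conds if c.odor is not None})
        patterns = {o: rng.standard_normal(rank) for o in odors}
        boost = np.zeros((n_time, rank))
        for tr, c in enumerate(conds):
            if c.odor is not None:
                sl = slice(tr * fpt, (tr + 1) * fpt)
                boost[sl][stim] += odor_effect * patterns[c.odor] / np.sqrt(n_time)
        U = U + boost

    V = np.linalg.qr(rng.standard_normal((n_pixels, rank)))[0]
    M = (U * scales) @ V.T
    if noise_sigma > 0:
        M = M + noise_sigma * rng.standard_normal(M.shape)
    return FacialMotion(motion=M, fs_hz=fs, n_trials=protocol.n_trials, frames_per_trial=fpt)
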