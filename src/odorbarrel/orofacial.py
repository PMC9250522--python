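"""Whisking and breathing kinematics from band-limited analytic signals.

Whisker-pad angle is band-pass filtered (2nd-order Butterworth, 4-30 Hz,
zero-phase) and the Hilbert transform provides the whisking phase; cycles
are delimited by phase crossings, and per-cycle amplitude and setpoint are
the range and center of angular motion after quadratic interpolation of the
raw-angle extrema.  Breathing pressure is treated the same way in the
4-20 Hz band (negative deflections are inhalations); per-cycle amplitude
comes from the analytic envelope and frequency from the cycle duration.
Whisker curvature is rectified (absolute value) and baselined on the 1-2 s
pre-stimulus window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, hilbert, sosfiltfilt

from .protocol import StimulusProtocol
from .synth import OrofacialTraces

__all__ = [
    "WHISK_BAND",
    "BREATH_BAND",
    "analytic_decompose",
    "whisk_cycles",
    "breath_cycles",
    "curvature_change",
    "trial_epoch_stats",
    "epoch_kinematics",
    "KinematicsContrast",
    "resample",
    "combine_whiskers",
]

WHISK_BAND = (4.0, 30.0)  # Hz
BREATH_BAND = (4.0, 20.0)  # Hz
_MIN_ENVELOPE = 1e-6  # below this the band holds no oscillation
_BAND_EDGE_TOL = 0.15  # fractional tolerance on per-cycle rates at the band edges


def resample(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling of a behavior channel along the last axis."""
    from fractions import Fraction

    from scipy.signal import resample_poly

    frac = Fraction(fs_out / fs_in).limit_denominator(10_000)
    return resample_poly(x, frac.numerator, frac.denominator, axis=-1)


def combine_whiskers(traces: np.ndarray) -> np.ndarray:
    """Average per-whisker angle or curvature traces (whiskers x time) into
    one whisker-pad trace, ignoring missing detections (NaN)."""
    return np.nanmean(np.asarray(traces, dtype=float), axis=0)


def analytic_decompose(
    x: np.ndarray,
    fs: float,
    band: tuple[float, float],
    order: int = 2,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Zero-phase band-pass filter + analytic signal.

    Returns ``(filtered, envelope, phase)`` where envelope is the magnitude
    and phase the unwrapped angle of the analytic signal.  Zero-phase
    (forward-backward) filtering keeps landmark timing unbiased.
    """
    x = np.asarray(x, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("signal contains non-finite values")
    lo, hi = band
    if not 0.0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, fs/2) = (0, {fs / 2})")
    sos = butter(order, band, btype="bandpass", fs=fs, output="sos")
    filt = sosfiltfilt(sos, x)
    analytic = hilbert(filt)
    return filt, np.abs(analytic), np.unwrap(np.angle(analytic))


def _quad_interp_extremum(y: np.ndarray, i: int, sign: float) -> float:
    """Parabolic refinement of the extremum value around sample ``i``.

    Fits a parabola through the 3 samples around the sampled extremum of the
    raw signal and returns the vertex value; falls back to ``y[i]`` at the
    array edges or for a degenerate fit.
    """
    if i <= 0 or i >= y.size - 1:
        return float(y[i])
    ym, y0, yp = y[i - 1], y[i], y[i + 1]
    denom = ym - 2 * y0 + yp
    if denom == 0:
        return float(y0)
    delta = 0.5 * (ym - yp) / denom
    if not -1.0 <= delta <= 1.0:
        return float(y0)
    return float(y0 - 0.25 * (ym - yp) * delta)


def _cycle_bounds(phase: np.ndarray) -> list[tuple[int, int]]:
    """Cycle boundaries: crossings of odd multiples of pi in the unwrapped phase."""
    k = np.floor((phase - np.pi) / (2 * np.pi)).astype(int)
    edges = np.flatnonzero(np.diff(k) > 0) + 1
    return [(edges[i], edges[i + 1]) for i in range(edges.size - 1)]


def _empty_cycle_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "t_start",
            "t_end",
            "amplitude",
            "setpoint",
            "frequency",
            "t_peak",
            "t_trough",
        ]
    ).astype(float)


def whisk_cycles(
    angle: np.ndarray,
    fs: float,
    band: tuple[float, float] = WHISK_BAND,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Per-cycle whisking amplitude and setpoint from a whisker-pad angle trace.

    Cycles come from phase crossings of the band-limited analytic signal;
    within each cycle the raw-angle maximum (protraction) and minimum
    (retraction) are refined by quadratic interpolation.  Amplitude is
    max - min, setpoint (max + min) / 2.  Returns a tidy cycle table; empty
    when the band contains no oscillation (e.g. a constant angle).
    """
    angle = np.asarray(angle, dtype=float)
    filt, env, phase = analytic_decompose(angle, fs, band)
    if env.max(initial=0.0) < _MIN_ENVELOPE:
        return _empty_cycle_table()

    rows = []
    for i0, i1 in _cycle_bounds(phase):
        if i1 - i0 < 3:
            continue
        seg = angle[i0:i1]
        imax, imin = int(np.argmax(seg)), int(np.argmin(seg))
        vmax = _quad_interp_extremum(angle, i0 + imax, +1)
        vmin = _quad_interp_extremum(angle, i0 + imin, -1)
        dur = (i1 - i0) / fs
        freq = 1.0 / dur
        if not band[0] * (1 - _BAND_EDGE_TOL) <= freq <= band[1] * (1 + _BAND_EDGE_TOL):
            continue
        rows.append(
            {
                "t_start": t0 + i0 / fs,
                "t_end": t0 + i1 / fs,
                "amplitude": vmax - vmin,
                "setpoint": 0.5 * (vmax + vmin),
                "frequency": freq,
                "t_peak": t0 + (i0 + imax) / fs,
                "t_trough": t0 + (i0 + imin) / fs,
            }
        )
    return pd.DataFrame(rows) if rows else _empty_cycle_table()


def breath_cycles(
    pressure: np.ndarray,
    fs: float,
    band: tuple[float, float] = BREATH_BAND,
    t0: float = 0.0,
) -> pd.DataFrame:
    """Per-cycle breathing amplitude and frequency from a pressure trace.

    Amplitude is the mean analytic envelope over the cycle; frequency is the
    inverse cycle duration.  ``t_trough`` marks the inhalation peak (most
    negative filtered pressure; inhalation = negative deflection).
    """
    pressure = np.asarray(pressure, dtype=float)
    if fs <= 2 * band[1]:
        raise ValueError(f"sampling rate {fs} Hz too low for band {band}")
    filt, env, phase = analytic_decompose(pressure, fs, band)
    if env.max(initial=0.0) < _MIN_ENVELOPE:
        return _empty_cycle_table()

    rows = []
    for i0, i1 in _cycle_bounds(phase):
        if i1 - i0 < 3:
            continue
        dur = (i1 - i0) / fs
        freq = 1.0 / dur
        if not band[0] * (1 - _BAND_EDGE_TOL) <= freq <= band[1] * (1 + _BAND_EDGE_TOL):
            continue
        seg = filt[i0:i1]
        rows.append(
            {
                "t_start": t0 + i0 / fs,
                "t_end": t0 + i1 / fs,
                "amplitude": float(env[i0:i1].mean()),
                "setpoint": np.nan,
                "frequency": freq,
                "t_peak": t0 + (i0 + int(np.argmax(seg))) / fs,
                "t_trough": t0 + (i0 + int(np.argmin(seg))) / fs,
            }
        )
    return pd.DataFrame(rows) if rows else _empty_cycle_table()


def curvature_change(curvature: np.ndarray, protocol: StimulusProtocol) -> np.ndarray:
    """Baseline-subtracted absolute curvature |dk|, trials x samples.

    Rectification precedes baselining: |k(t)| minus the per-trial mean of
    |k| over the pre-stimulus baseline epoch.
    """
    curv = np.asarray(curvature, dtype=float)
    one_d = curv.ndim == 1
    if one_d:
        curv = curv[None]
    fs = protocol.behavior_rate_hz
    t = np.arange(curv.shape[1]) / fs - protocol.stim_onset_s
    base = (t >= protocol.baseline_epoch_s[0]) & (t < protocol.baseline_epoch_s[1])
    if not base.any():
        raise ValueError("baseline epoch contains no samples")
    rect = np.abs(curv)
    out = rect - rect[:, base].mean(axis=1, keepdims=True)
    return out[0] if one_d else out


# --------------------------------------------------------------------------
# epoch statistics
# --------------------------------------------------------------------------

_MEASURES = ("whisk_amplitude", "whisk_setpoint", "dcurvature", "breath_amplitude", "breath_frequency")


def trial_epoch_stats(
    traces: OrofacialTraces,
    protocol: StimulusProtocol,
    window: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-trial kinematic means over an onset-relative window (default: stimulation epoch).

    Whisking and breathing cycles are assigned to the window by their
    midpoint; trials with no cycle in the window get NaN for that measure.
    """
    window = window or protocol.stim_epoch_s
    fs = traces.fs_hz
    t = traces.sample_times_s
    in_win = (t >= window[0]) & (t < window[1])
    if not in_win.any():
        raise ValueError(f"window {window} contains no samples")
    dk = curvature_change(traces.curvature, protocol)

    rows = []
    t0 = float(t[0])
    for tr in range(traces.angle.shape[0]):
        wc = whisk_cycles(traces.angle[tr], fs, t0=t0)
        bc = breath_cycles(traces.pressure[tr], fs, t0=t0)
        row = {"trial_id": tr}
        for name, tab, cols in (
            ("whisk", wc, ("amplitude", "setpoint")),
            ("breath", bc, ("amplitude", "frequency")),
        ):
            if len(tab):
                mid = 0.5 * (tab["t_start"] + tab["t_end"])
                sel = tab[(mid >= window[0]) & (mid < window[1])]
            else:
                sel = tab
            for col in cols:
                row[f"{name}_{col}"] = float(sel[col].mean()) if len(sel) else np.nan
        row["dcurvature"] = float(dk[tr, in_win].mean())
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class KinematicsContrast:
    """Odor vs no-odor kinematic comparison, within and between sessions."""

    measures: pd.DataFrame
    # columns: measure, mean_odor, mean_no_odor, p_between, plus per-session means
    session_means: dict[str, tuple[np.ndarray, np.ndarray]]  # measure -> (odor, no_odor)
    p_within: dict[str, np.ndarray]  # measure -> per-session Mann-Whitney p


_CONTRASTS = {
    "with_grating": ("bimodal", "grating_only"),
    "without_grating": ("odor_only", "blank"),
}


def epoch_kinematics(
    session_stats: list[pd.DataFrame],
    protocols: list[StimulusProtocol],
    contrast: str = "without_grating",
) -> KinematicsContrast:
    """Odor vs no-odor epoch kinematics across sessions.

    ``contrast`` selects the trial categories compared: ``'with_grating'``
    (bimodal vs grating-only) or ``'without_grating'`` (odor-only vs blank).
    Within each session, trial-wise epoch means are compared with a
    two-sided Mann-Whitney U; across sessions, session means are compared
    with a paired Wilcoxon signed-rank test (skipped for a single session).
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"contrast must be one of {sorted(_CONTRASTS)}")
    if len(session_stats) != len(protocols):
        raise ValueError("session_stats and protocols must align")
    cat_odor, cat_no = _CONTRASTS[contrast]

    session_means: dict[str, tuple[list, list]] = {m: ([], []) for m in _MEASURES}
    p_within: dict[str, list] = {m: [] for m in _MEASURES}
    for df, proto in zip(session_stats, protocols):
        odor_trials = proto.trials_where(category=cat_odor)
        no_trials = proto.trials_where(category=cat_no)
        for m in _MEASURES:
            if m not in df.columns:
                warnings.warn(f"measure {m!r} missing; skipped", stacklevel=2)
                continue
            a = df.loc[df.trial_id.isin(odor_trials), m].dropna().to_numpy()
            b = df.loc[df.trial_id.isin(no_trials), m].dropna().to_numpy()
            if a.size == 0 or b.size == 0:
                warnings.warn(f"measure {m!r}: empty trial group; skipped", stacklevel=2)
                continue
            session_means[m][0].append(a.mean())
            session_means[m][1].append(b.mean())
            if np.ptp(np.concatenate([a, b])) == 0:
                p_within[m].append(1.0)
            else:
                p_within[m].append(
                    float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
                )

    rows = []
    means_out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    pw_out: dict[str, np.ndarray] = {}
    for m in _MEASURES:
        mo = np.asarray(session_means[m][0])
        mn = np.asarray(session_means[m][1])
        if mo.size == 0:
            continue
        means_out[m] = (mo, mn)
        pw_out[m] = np.asarray(p_within[m])
        if mo.size >= 2:
            d = mo - mn
            p_between = 1.0 if np.allclose(d, 0) else float(stats.wilcoxon(mo, mn).pvalue)
        else:
            p_between = np.nan
        rows.append(
            {
                "measure": m,
                "mean_odor": float(mo.mean()),
                "mean_no_odor": float(mn.mean()),
                "p_between": p_between,
            }
        )
    return KinematicsContrast(
        measures=pd.DataFrame(rows), session_means=means_out, p_within=pw_out
    )
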