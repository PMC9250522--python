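"""Raw fluorescence to baseline-subtracted dF/F0.

The pipeline is: neuropil correction ``F_cor = F - r * F_n`` (r = 0.7),
per-trial baseline ``F0`` as the 8th percentile of the corrected trace,
``dff = (F_cor - F0) / F0``, then subtraction of the mean dF/F over the
pre-stimulus baseline epoch (1-2 s before onset) from the whole trial.
Also houses the intrinsic-imaging relative reflectance map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import StimulusProtocol

__all__ = [
    "DffTensor",
    "ReflectanceMap",
    "neuropil_correct",
    "compute_dff",
    "epoch_average",
    "intrinsic_response_map",
]

DEFAULT_NEUROPIL_R = 0.7
DEFAULT_F0_PERCENTILE = 8.0


@dataclass
class DffTensor:
    """Baseline-subtracted dF/F0, cells x trials x frames.

    ``valid`` flags cell/trial pairs whose F0 was positive; the others are
    NaN in ``dff`` and must be excluded from downstream statistics.  By
    construction the mean of ``dff`` over the baseline epoch is zero for
    every valid cell/trial.
    """

    dff: np.ndarray
    F0: np.ndarray  # cells x trials, a.u.
    valid: np.ndarray  # cells x trials, bool
    protocol: StimulusProtocol
    percentile: float = DEFAULT_F0_PERCENTILE

    @property
    def n_cells(self) -> int:
        return self.dff.shape[0]

    @property
    def n_trials(self) -> int:
        return self.dff.shape[1]


@dataclass
class ReflectanceMap:
    """Relative reflectance change (R_stim - R_base) / R_base per pixel."""

    map: np.ndarray
    stim_epoch: tuple[int, int]
    base_epoch: tuple[int, int]


def neuropil_correct(F: np.ndarray, F_n: np.ndarray, r: float = DEFAULT_NEUROPIL_R) -> np.ndarray:
    """Subtract the scaled neuropil trace: ``F_cor = F - r * F_n``."""
    F = np.asarray(F, dtype=float)
    F_n = np.asarray(F_n, dtype=float)
    if F.shape != F_n.shape:
        raise ValueError(f"shape mismatch: F {F.shape} vs F_n {F_n.shape}")
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"neuropil coefficient r={r} must lie in [0, 1]")
    return F - r * F_n


def compute_dff(
    F_cor: np.ndarray,
    protocol: StimulusProtocol,
    percentile: float = DEFAULT_F0_PERCENTILE,
    baseline_subtract: bool = True,
) -> DffTensor:
    """dF/F0 with per-trial percentile baseline and pre-stimulus zeroing.

    Parameters
    ----------
    F_cor:
        Neuropil-corrected fluorescence, cells x trials x frames.
    percentile:
        Percentile of the per-trial corrected trace used as F0 (linear
        interpolation between order statistics).
    baseline_subtract:
        Subtract, per cell and trial, the scalar mean dF/F over the
        protocol's baseline epoch from the whole trial.

    Cell/trial pairs with F0 <= 0 cannot be normalised; they are flagged
    invalid and their dF/F set to NaN.
    """
    F_cor = np.asarray(F_cor, dtype=float)
    if F_cor.ndim != 3:
        raise ValueError("F_cor must be cells x trials x frames")
    if F_cor.shape[1] != protocol.n_trials:
        raise ValueError(
            f"F_cor has {F_cor.shape[1]} trials but protocol defines {protocol.n_trials}"
        )
    if F_cor.shape[2] < 2:
        raise ValueError("need at least 2 frames per trial")

    F0 = np.percentile(F_cor, percentile, axis=-1)  # cells x trials
    valid = F0 > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        dff = (F_cor - F0[:, :, None]) / F0[:, :, None]
    dff[~valid] = np.nan

    if baseline_subtract:
        base = protocol.frames_in(protocol.baseline_epoch_s)
        if not base.any():
            raise ValueError("baseline epoch contains no frames")
        dff = dff - dff[:, :, base].mean(axis=-1, keepdims=True)

    return DffTensor(dff=dff, F0=F0, valid=valid, protocol=protocol, percentile=percentile)


def epoch_average(dff: DffTensor | np.ndarray, window: tuple[float, float],
                  protocol: StimulusProtocol | None = None) -> np.ndarray:
    """Mean dF/F over a half-open [start, end) window, cells x trials.

    Frames are included when their onset-relative time satisfies
    ``start <= t < end``.  Accepts either a :class:`DffTensor` or a raw
    cells x trials x frames array plus a protocol.
    """
    if isinstance(dff, DffTensor):
        arr, protocol = dff.dff, dff.protocol
    else:
        if protocol is None:
            raise ValueError("protocol required when passing a bare array")
        arr = np.asarray(dff, dtype=float)
    mask = protocol.frames_in(window)
    if not mask.any():
        raise ValueError(f"window {window} contains no frames")
    return arr[:, :, mask].mean(axis=-1)


def intrinsic_response_map(
    R_stack: np.ndarray,
    stim_epoch: tuple[int, int],
    base_epoch: tuple[int, int],
) -> ReflectanceMap:
    """Relative reflectance change from an intrinsic-imaging stack.

    ``R_stack`` is frames x pixels (one repetition) or repetitions x frames
    x pixels; repetition maps are averaged.  Epochs are half-open frame
    ranges.  Pixels with R_base = 0 are returned as NaN.
    """
    R = np.asarray(R_stack, dtype=float)
    if R.ndim == 2:
        R = R[None]
    if R.ndim != 3:
        raise ValueError("R_stack must be (frames x pixels) or (reps x frames x pixels)")
    for name, (a, b) in (("stim_epoch", stim_epoch), ("base_epoch", base_epoch)):
        if not 0 <= a < b <= R.shape[1]:
            raise ValueError(f"{name}={a, b} is empty or outside the stack")
    r_stim = R[:, stim_epoch[0] : stim_epoch[1]].mean(axis=1)
    r_base = R[:, base_epoch[0] : base_epoch[1]].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_rep = np.where(r_base != 0, (r_stim - r_base) / r_base, np.nan)
    return ReflectanceMap(map=per_rep.mean(axis=0), stim_epoch=stim_epoch, base_epoch=base_epoch)
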