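"""Trial-structured stimulation protocols.

A session interleaves olfactory and tactile stimuli in a pseudo-random
trial order.  The default protocol follows the olfacto-tactile design used
throughout the package: two grating orientations crossed with two odors
(bimodal, 10 repetitions each), each grating and each odor alone (20
repetitions each), and a blank condition (30 repetitions), for a total of
150 trials of 11 s imaged at 31.5 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "StimulusProtocol",
    "make_protocol",
    "default_conditions",
    "multi_odor_conditions",
]


@dataclass(frozen=True)
class Condition:
    """A single stimulation condition: a grating orientation, an odor, both, or neither."""

    grating: str | None = None  # e.g. "0", "90"; None = no tactile stimulus
    odor: str | None = None  # e.g. "AA", "EB"; None = no odor

    @property
    def category(self) -> str:
        """One of 'bimodal', 'grating_only', 'odor_only', 'blank'."""
        if self.grating is not None and self.odor is not None:
            return "bimodal"
        if self.grating is not None:
            return "grating_only"
        if self.odor is not None:
            return "odor_only"
        return "blank"

    @property
    def label(self) -> str:
        g = self.grating if self.grating is not None else "-"
        o = self.odor if self.odor is not None else "-"
        return f"g{g}|o{o}"


def default_conditions(
    gratings: tuple[str, ...] = ("0", "90"),
    odors: tuple[str, ...] = ("AA", "EB"),
) -> tuple[list[Condition], list[int]]:
    """The 9-condition olfacto-tactile set with its repetition counts.

    Returns (conditions, reps): 4 bimodal x 10, 2 grating-only x 20,
    2 odor-only x 20, 1 blank x 30 -> 150 trials.
    """
    conditions: list[Condition] = []
    reps: list[int] = []
    for g in gratings:
        for o in odors:
            conditions.append(Condition(grating=g, odor=o))
            reps.append(10)
    for g in gratings:
        conditions.append(Condition(grating=g, odor=None))
        reps.append(20)
    for o in odors:
        conditions.append(Condition(grating=None, odor=o))
        reps.append(20)
    conditions.append(Condition())
    reps.append(30)
    return conditions, reps


def multi_odor_conditions(
    odors: tuple[str, ...] = ("AA", "EB", "Hep", "Lim", "Hex"),
    mixtures: tuple[str, ...] = ("AA80:EB20", "AA60:EB40", "AA40:EB60", "AA20:EB80"),
    reps_per_odor: int = 10,
    reps_per_mixture: int = 10,
    n_blank: int = 10,
) -> tuple[list[Condition], list[int]]:
    """Odor-only condition set for multi-odor decoding and mixture categorization.

    Mixture labels encode component ratios as 'AA80:EB20' (80/20 % AA/EB).
    """
    conditions = [Condition(odor=o) for o in odors]
    reps = [reps_per_odor] * len(odors)
    for m in mixtures:
        conditions.append(Condition(odor=m))
        reps.append(reps_per_mixture)
    conditions.append(Condition())
    reps.append(n_blank)
    return conditions, reps


def parse_mixture(odor_label: str) -> dict[str, float] | None:
    """Parse a mixture label like 'AA80:EB20' into {'AA': 0.8, 'EB': 0.2}.

    Returns None if the label is not a mixture.
    """
    if odor_label is None or ":" not in odor_label:
        return None
    parts = odor_label.split(":")
    out: dict[str, float] = {}
    for p in parts:
        i = len(p)
        while i > 0 and p[i - 1].isdigit():
            i -= 1
        name, frac = p[:i], p[i:]
        if not name or not frac:
            return None
        out[name] = float(frac) / 100.0
    return out


@dataclass(frozen=True)
class StimulusProtocol:
    """Condition set, repetition counts, trial timing and sampling rates of a session.

    Epoch windows are in seconds relative to stimulus onset and are half-open
    ``[start, end)``.  ``trial_order`` maps trial index -> condition index and
    is a seeded pseudo-random permutation of the repetition blocks.
    """

    conditions: tuple[Condition, ...]
    reps_per_condition: tuple[int, ...]
    trial_order: tuple[int, ...]
    trial_duration_s: float = 11.0
    iti_s: float = 8.0
    frame_rate_hz: float = 31.5
    stim_onset_s: float = 4.0
    stim_epoch_s: tuple[float, float] = (0.0, 2.0)
    baseline_epoch_s: tuple[float, float] = (-2.0, -1.0)
    behavior_rate_hz: float = 500.0
    facial_rate_hz: float = 20.0
    seed: int = 0

    # ---- basic geometry -------------------------------------------------
    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return len(self.trial_order)

    @property
    def n_frames(self) -> int:
        return int(round(self.trial_duration_s * self.frame_rate_hz))

    def frame_times(self) -> np.ndarray:
        """Frame times in seconds relative to stimulus onset."""
        return np.arange(self.n_frames) / self.frame_rate_hz - self.stim_onset_s

    def frames_in(self, window: tuple[float, float]) -> np.ndarray:
        """Boolean frame mask for a half-open [start, end) window (s, onset-relative)."""
        t = self.frame_times()
        return (t >= window[0]) & (t < window[1])

    # ---- trial bookkeeping ----------------------------------------------
    def trial_conditions(self) -> list[Condition]:
        return [self.conditions[i] for i in self.trial_order]

    def trial_table(self) -> pd.DataFrame:
        """Tidy trial table: trial_id, condition index, grating, odor, category, onset_s."""
        rows = []
        period = self.trial_duration_s + self.iti_s
        for t, ci in enumerate(self.trial_order):
            c = self.conditions[ci]
            rows.append(
                {
                    "trial_id": t,
                    "condition": ci,
                    "grating": c.grating if c.grating is not None else "",
                    "odor": c.odor if c.odor is not None else "",
                    "category": c.category,
                    "onset_s": t * period + self.stim_onset_s,
                }
            )
        return pd.DataFrame(rows)

    def trials_where(
        self,
        category: str | tuple[str, ...] | None = None,
        grating: str | None = None,
        odor: str | None = None,
    ) -> np.ndarray:
        """Trial indices matching the given filters (AND-combined)."""
        if isinstance(category, str):
            category = (category,)
        keep = []
        for t, c in enumerate(self.trial_conditions()):
            if category is not None and c.category not in category:
                continue
            if grating is not None and c.grating != grating:
                continue
            if odor is not None and c.odor != odor:
                continue
            keep.append(t)
        return np.asarray(keep, dtype=int)

    def condition_labels(self) -> np.ndarray:
        """Per-trial condition index, aligned with the trial axis."""
        return np.asarray(self.trial_order, dtype=int)

    def with_seed(self, seed: int) -> "StimulusProtocol":
        """Same protocol with a re-drawn trial order."""
        order = _draw_order(self.reps_per_condition, seed)
        return replace(self, trial_order=tuple(order), seed=seed)


def _draw_order(reps: tuple[int, ...] | list[int], seed: int) -> np.ndarray:
    blocks = np.repeat(np.arange(len(reps)), reps)
    rng = np.random.default_rng(seed)
    return rng.permutation(blocks)


def make_protocol(
    conditions: list[Condition] | None = None,
    reps_per_condition: list[int] | None = None,
    seed: int = 0,
    **timing,
) -> StimulusProtocol:
    """Build a validated protocol with a seeded pseudo-random trial order.

    Parameters
    ----------
    conditions, reps_per_condition:
        Condition set and repetition counts; defaults to the 150-trial
        9-condition olfacto-tactile design.
    seed:
        Seed for the trial-order permutation.
    **timing:
        Overrides for the timing/sampling fields of `StimulusProtocol`.
    """
    if conditions is None:
        if reps_per_condition is not None:
            raise ValueError("reps_per_condition given without conditions")
        conditions, reps_per_condition = default_conditions()
    if reps_per_condition is None:
        raise ValueError("conditions given without reps_per_condition")
    if len(conditions) != len(reps_per_condition):
        raise ValueError(
            f"len(conditions)={len(conditions)} != "
            f"len(reps_per_condition)={len(reps_per_condition)}"
        )
    if any(r <= 0 for r in reps_per_condition):
        raise ValueError("reps_per_condition: all repetition counts must be > 0")

    proto = StimulusProtocol(
        conditions=tuple(conditions),
        reps_per_condition=tuple(int(r) for r in reps_per_condition),
        trial_order=tuple(_draw_order(reps_per_condition, seed)),
        seed=seed,
        **timing,
    )
    _validate_epochs(proto)
    return proto


def _validate_epochs(p: StimulusProtocol) -> None:
    dur = p.trial_duration_s
    for name, (a, b) in (
        ("stim_epoch_s", p.stim_epoch_s),
        ("baseline_epoch_s", p.baseline_epoch_s),
    ):
        if not a < b:
            raise ValueError(f"{name}: start {a} must precede end {b}")
        lo, hi = a + p.stim_onset_s, b + p.stim_onset_s
        if lo < 0 or hi > dur:
            raise ValueError(
                f"{name}: window ({a}, {b}) relative to onset {p.stim_onset_s}s "
                f"falls outside the [0, {dur}]s trial"
            )
    if p.baseline_epoch_s[1] > 0:
        raise ValueError("baseline_epoch_s: baseline must end at or before stimulus onset")
    if not 0 <= p.stim_onset_s <= dur:
        raise ValueError("stim_onset_s: onset outside trial")
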