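"""HDF5 session container and CSV exports.

One file per session with groups ``/protocol``, ``/neural`` (F, F_n),
``/orofacial`` (angle, curvature, pressure), ``/facial`` (motion) and
``/ground_truth``; the trial table is also exportable as CSV
(trial_id, grating, odor, category, onset_s).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from .protocol import Condition, StimulusProtocol, make_protocol
from .synth import FacialMotion, GroundTruth, OrofacialTraces, RoiFluorescence

__all__ = ["Session", "save_session", "load_session", "export_trial_table"]

_TIMING_ATTRS = (
    "trial_duration_s",
    "iti_s",
    "frame_rate_hz",
    "stim_onset_s",
    "behavior_rate_hz",
    "facial_rate_hz",
)


@dataclass
class Session:
    """In-memory view of one recorded or simulated session."""

    protocol: StimulusProtocol
    fluorescence: RoiFluorescence | None = None
    ground_truth: GroundTruth | None = None
    orofacial: OrofacialTraces | None = None
    facial: FacialMotion | None = None


def _write_protocol(g: h5py.Group, p: StimulusProtocol) -> None:
    for a in _TIMING_ATTRS:
        g.attrs[a] = getattr(p, a)
    g.attrs["seed"] = p.seed
    g.attrs["stim_epoch_s"] = p.stim_epoch_s
    g.attrs["baseline_epoch_s"] = p.baseline_epoch_s
    enc = lambda v: "" if v is None else v  # noqa: E731
    g.create_dataset(
        "grating", data=np.array([enc(c.grating) for c in p.conditions], dtype="S16")
    )
    g.create_dataset("odor", data=np.array([enc(c.odor) for c in p.conditions], dtype="S16"))
    g.create_dataset("reps_per_condition", data=np.asarray(p.reps_per_condition))
    g.create_dataset("trial_order", data=np.asarray(p.trial_order))


def _read_protocol(g: h5py.Group) -> StimulusProtocol:
    dec = lambda b: (b.decode() or None)  # noqa: E731
    conditions = [
        Condition(grating=dec(gr), odor=dec(od))
        for gr, od in zip(g["grating"][()], g["odor"][()])
    ]
    reps = [int(r) for r in g["reps_per_condition"][()]]
    timing = {a: float(g.attrs[a]) for a in _TIMING_ATTRS}
    timing["stim_epoch_s"] = tuple(g.attrs["stim_epoch_s"])
    timing["baseline_epoch_s"] = tuple(g.attrs["baseline_epoch_s"])
    proto = make_protocol(conditions, reps, seed=int(g.attrs["seed"]), **timing)
    stored = tuple(int(i) for i in g["trial_order"][()])
    if stored != proto.trial_order:
        proto = StimulusProtocol(
            conditions=proto.conditions,
            reps_per_condition=proto.reps_per_condition,
            trial_order=stored,
            seed=int(g.attrs["seed"]),
            **timing,
        )
    return proto


def save_session(path: str | Path, session: Session) -> None:
    """Write a session to the HDF5 container layout."""
    with h5py.File(path, "w") as f:
        _write_protocol(f.create_group("protocol"), session.protocol)
        if session.fluorescence is not None:
            g = f.create_group("neural")
            g.create_dataset("F", data=session.fluorescence.F, compression="gzip")
            g.create_dataset("F_n", data=session.fluorescence.F_n, compression="gzip")
            g.create_dataset("frame_times_s", data=session.fluorescence.frame_times_s)
        if session.orofacial is not None:
            g = f.create_group("orofacial")
            for name in ("angle", "curvature", "pressure"):
                g.create_dataset(name, data=getattr(session.orofacial, name), compression="gzip")
            g.attrs["fs_hz"] = session.orofacial.fs_hz
            g.create_dataset("sample_times_s", data=session.orofacial.sample_times_s)
        if session.facial is not None:
            g = f.create_group("facial")
            g.create_dataset("motion", data=session.facial.motion, compression="gzip")
            g.attrs["fs_hz"] = session.facial.fs_hz
            g.attrs["frames_per_trial"] = session.facial.frames_per_trial
        if session.ground_truth is not None:
            gt = session.ground_truth
            g = f.create_group("ground_truth")
            g.create_dataset("tactile_responsive", data=gt.tactile_responsive)
            g.create_dataset("odor_modulated", data=gt.odor_modulated)
            g.create_dataset("direction", data=gt.direction.astype("S16"))
            g.create_dataset("effect_size", data=gt.effect_size)
            g.create_dataset("tactile_amp", data=gt.tactile_amp)
            g.create_dataset("tactile_discriminant", data=gt.tactile_discriminant)
            g.create_dataset("amplitudes", data=gt.amplitudes)
            g.attrs["subspace_angle_deg"] = gt.subspace_angle_deg
            lg = g.create_group("odor_loadings")
            for odor, vec in gt.odor_loadings.items():
                lg.create_dataset(odor, data=vec)


def load_session(path: str | Path) -> Session:
    """Read a session written by :func:`save_session`."""
    with h5py.File(path, "r") as f:
        proto = _read_protocol(f["protocol"])
        fluor = oro = facial = gt = None
        if "neural" in f:
            g = f["neural"]
            fluor = RoiFluorescence(
                F=g["F"][()], F_n=g["F_n"][()], frame_times_s=g["frame_times_s"][()]
            )
        if "orofacial" in f:
            g = f["orofacial"]
            oro = OrofacialTraces(
                angle=g["angle"][()],
                curvature=g["curvature"][()],
                pressure=g["pressure"][()],
                fs_hz=float(g.attrs["fs_hz"]),
                sample_times_s=g["sample_times_s"][()],
            )
        if "facial" in f:
            g = f["facial"]
            facial = FacialMotion(
                motion=g["motion"][()],
                fs_hz=float(g.attrs["fs_hz"]),
                n_trials=proto.n_trials,
                frames_per_trial=int(g.attrs["frames_per_trial"]),
            )
        if "ground_truth" in f:
            g = f["ground_truth"]
            gt = GroundTruth(
                tactile_responsive=g["tactile_responsive"][()].astype(bool),
                odor_modulated=g["odor_modulated"][()].astype(bool),
                direction=np.array([b.decode() for b in g["direction"][()]]),
                effect_size=g["effect_size"][()],
                tactile_amp=g["tactile_amp"][()],
                tactile_discriminant=g["tactile_discriminant"][()],
                odor_loadings={k: v[()] for k, v in g["odor_loadings"].items()},
                subspace_angle_deg=float(g.attrs["subspace_angle_deg"]),
                amplitudes=g["amplitudes"][()],
            )
    return Session(protocol=proto, fluorescence=fluor, ground_truth=gt, orofacial=oro, facial=facial)


def export_trial_table(path: str | Path, protocol: StimulusProtocol) -> None:
    """Write the trial table (trial_id, grating, odor, category, onset_s) as CSV."""
    protocol.trial_table().to_csv(path, index=False)
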