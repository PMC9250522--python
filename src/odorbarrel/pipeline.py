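"""Reproducible simulate -> preprocess -> analyze -> report runs.

A run is driven by a :class:`RunConfig` (YAML-serializable) and a seed;
config and seed fully determine every output.  Each stage writes its
tables under the run directory and registers them in ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decode as dec
from . import modstats, orofacial
from .preprocess import compute_dff, epoch_average, neuropil_correct
from .protocol import make_protocol
from .session_io import Session, export_trial_table, load_session, save_session
from .synth import (
    OrofacialParams,
    PopulationParams,
    simulate_orofacial,
    simulate_population,
)

__all__ = ["RunConfig", "run_pipeline", "report"]

STAGES = ("simulate", "preprocess", "modulate", "kinematics", "decode")


@dataclass
class RunConfig:
    """Everything that defines a run; serialized verbatim into the output."""

    n_sessions: int = 20
    seed: int = 0
    out_dir: str = "run"
    protocol: dict = field(default_factory=dict)  # make_protocol overrides
    population: dict = field(default_factory=dict)  # PopulationParams overrides
    orofacial: dict = field(default_factory=dict)  # OrofacialParams overrides
    alpha: float = 0.05
    n_shuffles: int = 100  # trial-label shuffles for the modulation null
    n_boot: int = 1000
    k_folds: int = 10
    n_decode_shuffles: int = 100
    bin_s: float = 1.0
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        return d

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def _session_seed(base: int, i: int) -> int:
    return int((base + 7919 * (i + 1)) % (2**31))


def _epoch_means(session: Session) -> tuple[np.ndarray, "object"]:
    proto = session.protocol
    f_cor = neuropil_correct(session.fluorescence.F, session.fluorescence.F_n)
    dff = compute_dff(f_cor, proto)
    return epoch_average(dff, proto.stim_epoch_s), dff


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the run report payload.

    Stage failures mark the stage failed in the manifest and skip the
    stages that depend on it.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    manifest: dict = {"config_hash": config.hash(), "stages": {}, "outputs": []}
    report_payload: dict = {"config_hash": config.hash(), "warnings": []}

    def _register(name: str, status: str, *files: Path) -> None:
        manifest["stages"][name] = status
        manifest["outputs"].extend(str(f.relative_to(out)) for f in files)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    sessions: list[Session] = []
    failed = False
    for stage in STAGES:
        if stage not in config.stages:
            continue
        if failed:
            _register(stage, "skipped")
            continue
        try:
            if stage == "simulate":
                files = _stage_simulate(config, out, sessions)
            elif stage == "preprocess":
                files = _stage_preprocess(config, out, sessions, report_payload)
            elif stage == "modulate":
                files = _stage_modulate(config, out, sessions, report_payload)
            elif stage == "kinematics":
                files = _stage_kinematics(config, out, sessions, report_payload)
            elif stage == "decode":
                files = _stage_decode(config, out, sessions, report_payload)
            _register(stage, "ok", *files)
        except Exception as e:  # noqa: BLE001 - stage isolation is the contract
            warnings.warn(f"stage {stage!r} failed: {e}", stacklevel=2)
            report_payload["warnings"].append(f"stage {stage} failed: {e}")
            _register(stage, f"failed: {e}")
            failed = True

    (out / "report.json").write_text(json.dumps(report_payload, indent=2, default=float))
    return report_payload


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_simulate(config: RunConfig, out: Path, sessions: list[Session]) -> list[Path]:
    sdir = out / "sessions"
    sdir.mkdir(exist_ok=True)
    files = []
    pop = PopulationParams(**config.population)
    oro = OrofacialParams(**config.orofacial)
    for i in range(config.n_sessions):
        seed = _session_seed(config.seed, i)
        proto = make_protocol(seed=seed, **config.protocol)
        fluor, gt = simulate_population(proto, pop, seed=seed)
        traces = simulate_orofacial(proto, oro, seed=seed)
        s = Session(protocol=proto, fluorescence=fluor, ground_truth=gt, orofacial=traces)
        sessions.append(s)
        path = sdir / f"session_{i:02d}.h5"
        save_session(path, s)
        export_trial_table(sdir / f"session_{i:02d}_trials.csv", proto)
        files.append(path)
    return files


def _stage_preprocess(
    config: RunConfig, out: Path, sessions: list[Session], payload: dict
) -> list[Path]:
    if not sessions:
        sessions.extend(
            load_session(p) for p in sorted((out / "sessions").glob("session_*.h5"))
        )
    rows = []
    for i, s in enumerate(sessions):
        em, dff = _epoch_means(s)
        rows.append(
            {
                "session": i,
                "n_cells": dff.n_cells,
                "n_trials": dff.n_trials,
                "n_invalid_f0": int((~dff.valid).sum()),
                "mean_stim_dff": float(np.nanmean(em)),
            }
        )
    df = pd.DataFrame(rows)
    path = out / "preprocess_summary.csv"
    df.to_csv(path, index=False)
    payload["preprocess"] = df.to_dict(orient="records")
    return [path]


_CONTRASTS = {
    "bimodal_vs_grating": ("bimodal", "grating_only"),
    "odor_vs_blank": ("odor_only", "blank"),
}


def _stage_modulate(
    config: RunConfig, out: Path, sessions: list[Session], payload: dict
) -> list[Path]:
    files = []
    payload["modulation"] = {}
    cell_rows = []
    for cname, (cat_a, cat_b) in _CONTRASTS.items():
        results, nulls = [], []
        for i, s in enumerate(sessions):
            em, _ = _epoch_means(s)
            a = s.protocol.trials_where(category=cat_a)
            b = s.protocol.trials_where(category=cat_b)
            res = modstats.score_modulation(em, a, b, alpha=config.alpha)
            nul = modstats.shuffle_null_proportion(
                em, a, b, alpha=config.alpha, n_shuffles=config.n_shuffles,
                seed=_session_seed(config.seed, 1000 + i),
            )
            results.append(res)
            nulls.append(nul)
            for c in range(em.shape[0]):
                cell_rows.append(
                    {
                        "session": i,
                        "contrast": cname,
                        "cell_id": c,
                        "p_mod": res.p_modulated[c],
                        "mi": res.mi[c],
                        "direction": res.direction[c],
                    }
                )
        summ = modstats.summarize_sessions(
            results, nulls, n_boot=config.n_boot, seed=config.seed
        )
        payload["modulation"][cname] = {
            "mean_proportion_pct": summ.mean_proportion,
            "proportion_ci": summ.proportion_ci,
            "null_mean_pct": summ.mean_null,
            "null_ci": summ.null_ci,
            "p_real_vs_null": summ.p_real_vs_null,
            "mean_enhanced_pct": summ.mean_enhanced_pct,
            "mean_suppressed_pct": summ.mean_suppressed_pct,
            "p_enhanced_vs_suppressed": summ.p_enhanced_vs_suppressed,
            "p_mi_ks": summ.p_mi_ks,
        }
    path = out / "modulation_cells.csv"
    pd.DataFrame(cell_rows).to_csv(path, index=False)
    files.append(path)
    spath = out / "modulation_summary.json"
    spath.write_text(json.dumps(payload["modulation"], indent=2, default=float))
    files.append(spath)
    return files


def _stage_kinematics(
    config: RunConfig, out: Path, sessions: list[Session], payload: dict
) -> list[Path]:
    stats_per_session = [
        orofacial.trial_epoch_stats(s.orofacial, s.protocol) for s in sessions
    ]
    payload["kinematics"] = {}
    frames = []
    for contrast in ("with_grating", "without_grating"):
        kc = orofacial.epoch_kinematics(
            stats_per_session, [s.protocol for s in sessions], contrast=contrast
        )
        df = kc.measures.assign(contrast=contrast)
        frames.append(df)
        payload["kinematics"][contrast] = df.to_dict(orient="records")
    path = out / "kinematics.csv"
    pd.concat(frames).to_csv(path, index=False)
    return [path]


def _stage_decode(
    config: RunConfig, out: Path, sessions: list[Session], payload: dict
) -> list[Path]:
    payload["decode"] = {"orientation_per_session": [], "transfer": []}
    for i, s in enumerate(sessions):
        proto = s.protocol
        em_f_cor = neuropil_correct(s.fluorescence.F, s.fluorescence.F_n)
        dff = compute_dff(em_f_cor, proto)
        pv = dec.build_features(dff, bin_s=config.bin_s)
        conds = proto.trial_conditions()
        grat = np.asarray([c.grating or "" for c in conds], dtype=object)
        has_odor = np.asarray([c.odor is not None for c in conds])
        tact = np.flatnonzero(grat != "")

        # orientation decoding on grating trials, stimulus-epoch bins only
        sub = pv.restrict(trials=tact, y=grat[tact]).restrict(bins=pv.stim_bins)
        res = dec.permutation_pvalue(
            sub, decoder="centroid", k=config.k_folds,
            n_shuffles=config.n_decode_shuffles, seed=_session_seed(config.seed, 2000 + i),
        )
        payload["decode"]["orientation_per_session"].append(
            {
                "session": i,
                "stim_bin_accuracy_pct": float(res.accuracy[0]),
                "p": float(res.pvalues[0]),
            }
        )

        # transfer: orientation decoder trained without odors, tested with odors
        train = np.flatnonzero((grat != "") & ~has_odor)
        test = np.flatnonzero((grat != "") & has_odor)
        tr = dec.transfer_test(pv, grat, train, test, k=min(config.k_folds, 10),
                               seed=_session_seed(config.seed, 3000 + i))
        # odor decoder trained without touch, tested with touch
        odor = np.asarray([c.odor or "" for c in conds], dtype=object)
        train_o = np.flatnonzero((odor != "") & (grat == ""))
        test_o = np.flatnonzero((odor != "") & (grat != ""))
        tro = dec.transfer_test(pv, odor, train_o, test_o, k=min(config.k_folds, 10),
                                seed=_session_seed(config.seed, 4000 + i))
        payload["decode"]["transfer"].append(
            {
                "session": i,
                "orientation_in_pct": tr.in_domain_accuracy,
                "orientation_out_pct": tr.out_domain_accuracy,
                "odor_in_pct": tro.in_domain_accuracy,
                "odor_out_pct": tro.out_domain_accuracy,
            }
        )
    path = out / "decode.json"
    path.write_text(json.dumps(payload["decode"], indent=2, default=float))
    return [path]


# --------------------------------------------------------------------------
# report
# --------------------------------------------------------------------------


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    rp = run_dir / "report.json"
    if not rp.exists():
        return f"no run found in {run_dir}"
    payload = json.loads(rp.read_text())
    lines = [f"# Run summary ({payload.get('config_hash', '?')})", ""]

    mod = payload.get("modulation")
    if mod:
        lines.append("## Odor-modulated cells vs shuffle null")
        for cname, m in mod.items():
            sig = "significant" if (m["p_real_vs_null"] or 1) < 0.05 else "not significant"
            lines.append(
                f"- {cname}: {m['mean_proportion_pct']:.2f}% "
                f"(CI {m['proportion_ci'][0]:.2f}-{m['proportion_ci'][1]:.2f}) vs "
                f"shuffled {m['null_mean_pct']:.2f}% "
                f"(CI {m['null_ci'][0]:.2f}-{m['null_ci'][1]:.2f}); "
                f"p={m['p_real_vs_null']:.3g} ({sig})"
            )
        lines.append("")
    else:
        lines.append("## Odor-modulated cells: absent\n")

    kin = payload.get("kinematics")
    if kin:
        lines.append("## Odor vs no-odor kinematics (stimulation epoch)")
        for contrast, rows in kin.items():
            for r in rows:
                star = "*" if (r["p_between"] or 1) < 0.05 else ""
                lines.append(
                    f"- {contrast} / {r['measure']}: odor {r['mean_odor']:.3g} vs "
                    f"no-odor {r['mean_no_odor']:.3g} (p={r['p_between']:.3g}){star}"
                )
        lines.append("")
    else:
        lines.append("## Kinematics: absent\n")

    de = payload.get("decode")
    if de:
        lines.append("## Decoding")
        accs = [r["stim_bin_accuracy_pct"] for r in de["orientation_per_session"]]
        if accs:
            lines.append(
                f"- orientation (stimulus bin): mean {np.mean(accs):.1f}% across "
                f"{len(accs)} sessions"
            )
        for r in de["transfer"]:
            lines.append(
                f"- transfer session {r['session']}: orientation "
                f"{r['orientation_in_pct']:.0f}% -> {r['orientation_out_pct']:.0f}% with odors; "
                f"odor {r['odor_in_pct']:.0f}% -> {r['odor_out_pct']:.0f}% with touch"
            )
        lines.append("")
    else:
        lines.append("## Decoding: absent\n")

    if payload.get("warnings"):
        lines.append("## Warnings")
        lines.extend(f"- {w}" for w in payload["warnings"])
    return "\n".join(lines)
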