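"""Session-log serialization (CSV and HDF5) and protocol files.

Two on-disk forms, both lossless and round-trip tested:

* CSV: ``<stem>.csv`` holds the trial table with one extra column per
  electrode first-spike latency (``elec_00`` ...; empty cell = missing),
  ``<stem>.events.csv`` the spontaneous NS onsets, ``<stem>.meta.json`` the
  config snapshot, schema version and row counts (used to reject truncated
  files).
* HDF5: a single container with the same content.

A protocol file (YAML or JSON) chains sessions on a continuing plant — e.g.
closed loop followed by an open-loop replay of the amplitudes the controller
generated — with a single global seed fanned out deterministically to stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .control import ControllerConfig, SetpointSchedule
from .plant import Plant, PlantConfig
from .sessions import (
    SCHEMA_VERSION,
    SessionLog,
    calibrate_baseline,
    run_closed_loop,
    run_no_stimulation,
    run_open_loop,
    shuffled_series,
)

__all__ = [
    "save_session_log",
    "load_session_log",
    "SessionLogFormatError",
    "ProtocolError",
    "ProtocolStage",
    "ProtocolSpec",
    "load_protocol",
    "run_protocol",
    "write_raster_csv",
]


class SessionLogFormatError(RuntimeError):
    """Unreadable, truncated, or version-incompatible session log."""


_TRIAL_COLS = [
    "n", "t_n_s", "amplitude_mV", "p_star", "y", "latency_ms",
    "p_tau", "l_tau_ms", "e", "integral_sum",
]


def _elec_cols(n: int) -> list[str]:
    return [f"elec_{i:02d}" for i in range(n)]


def save_session_log(log: SessionLog, path: str | Path) -> None:
    """Write a log as ``.csv`` (plus sidecars) or ``.h5`` by extension."""
    path = Path(path)
    if path.suffix == ".h5":
        _save_h5(log, path)
    elif path.suffix == ".csv":
        _save_csv(log, path)
    else:
        raise SessionLogFormatError(f"unknown log format {path.suffix!r}")


def load_session_log(path: str | Path) -> SessionLog:
    path = Path(path)
    if path.suffix == ".h5":
        return _load_h5(path)
    if path.suffix == ".csv":
        return _load_csv(path)
    raise SessionLogFormatError(f"unknown log format {path.suffix!r}")


def _save_csv(log: SessionLog, path: Path) -> None:
    n_elec = log.config.get("n_electrodes", log.electrode_latencies.shape[1] if
                            log.electrode_latencies.ndim == 2 else 0)
    table = log.trials.copy()
    if log.electrode_latencies.size:
        for i, col in enumerate(_elec_cols(n_elec)):
            table[col] = log.electrode_latencies[:, i]
    table.to_csv(path, index=False)
    log.spontaneous.to_csv(path.with_suffix(".events.csv"), index=False)
    meta = dict(log.config)
    meta["n_spontaneous"] = len(log.spontaneous)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=1))


def _load_csv(path: Path) -> SessionLog:
    meta_path = path.with_suffix(".meta.json")
    if not meta_path.exists():
        raise SessionLogFormatError(f"missing sidecar {meta_path.name}")
    config = json.loads(meta_path.read_text())
    _check_version(config)
    table = pd.read_csv(path, float_precision="round_trip")
    n_elec = config["n_electrodes"]
    ecols = [c for c in _elec_cols(n_elec) if c in table.columns]
    if len(table) != config["n_trials"]:
        raise SessionLogFormatError(
            f"trial table has {len(table)} rows, metadata says {config['n_trials']}"
        )
    elec = (
        table[ecols].to_numpy(dtype=float) if ecols else np.empty((0, n_elec))
    )
    trials = table[_TRIAL_COLS].copy()
    spont = pd.read_csv(path.with_suffix(".events.csv"))
    if "onset_s" not in spont.columns:
        spont = pd.DataFrame({"onset_s": pd.Series(dtype=float)})
    if len(spont) != config.pop("n_spontaneous", len(spont)):
        raise SessionLogFormatError("spontaneous-event file truncated")
    return SessionLog(trials, elec, spont, config)


def _save_h5(log: SessionLog, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = log.config.get("schema_version", SCHEMA_VERSION)
        f.attrs["config_json"] = json.dumps(log.config)
        g = f.create_group("trials")
        for col in _TRIAL_COLS:
            g.create_dataset(col, data=log.trials[col].to_numpy(dtype=float))
        f.create_dataset("electrode_latencies", data=log.electrode_latencies)
        f.create_dataset(
            "spontaneous_onsets", data=log.spontaneous.onset_s.to_numpy(dtype=float)
        )


def _load_h5(path: Path) -> SessionLog:
    try:
        with h5py.File(path, "r") as f:
            config = json.loads(f.attrs["config_json"])
            _check_version(config)
            data = {col: f["trials"][col][...] for col in _TRIAL_COLS}
            elec = f["electrode_latencies"][...]
            onsets = f["spontaneous_onsets"][...]
    except (OSError, KeyError) as exc:
        raise SessionLogFormatError(f"cannot read {path}: {exc}") from exc
    trials = pd.DataFrame(data)
    trials["n"] = trials["n"].astype(int)
    trials["y"] = trials["y"].astype(int)
    if len(trials) != config["n_trials"]:
        raise SessionLogFormatError("trial table truncated")
    return SessionLog(trials, elec, pd.DataFrame({"onset_s": onsets}), config)


def _check_version(config: dict) -> None:
    v = config.get("schema_version")
    if v != SCHEMA_VERSION:
        raise SessionLogFormatError(
            f"log schema version {v} incompatible with reader version {SCHEMA_VERSION}"
        )


def write_raster_csv(raster: np.ndarray, path: str | Path) -> None:
    """Plain-text event list with columns (electrode_id, time_s)."""
    pd.DataFrame(raster, columns=["electrode_id", "time_s"]).to_csv(
        Path(path), index=False
    )


# --- protocols ---------------------------------------------------------------


class ProtocolError(ValueError):
    """Invalid protocol specification."""


@dataclass
class ProtocolStage:
    stage_id: str
    mode: str                     # closed | open_constant | open_replay | open_shuffle | no_stim
    duration_s: float = 7200.0
    p_star: Optional[float] = None
    setpoint: Optional[dict] = None          # full schedule spec (overrides p_star)
    source: Optional[str] = None             # stage id for replay/shuffle/constant
    amplitude: Optional[float] = None        # open_constant explicit value
    dual_control_start: Optional[float] = None
    fresh_plant: bool = False                # reset the plant before this stage
    controller: dict = field(default_factory=dict)   # gain overrides


@dataclass
class ProtocolSpec:
    stages: list[ProtocolStage]
    plant: PlantConfig
    stim_period: float = 5.0
    tau: float = 250.0
    seed: int = 0


_MODES = {"closed", "open_constant", "open_replay", "open_shuffle", "no_stim"}


def load_protocol(path: str | Path) -> ProtocolSpec:
    """Parse and validate a YAML/JSON protocol file."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "stages" not in raw:
        raise ProtocolError("protocol file must define a 'stages' list")
    plant_cfg = PlantConfig.from_dict(raw.get("plant", {}))
    stages = []
    seen: set[str] = set()
    closed_seen: set[str] = set()
    for i, item in enumerate(raw["stages"]):
        stage = ProtocolStage(
            stage_id=str(item.get("id", f"stage{i}")),
            mode=item.get("mode", "closed"),
            duration_s=float(item.get("duration_s", 7200.0)),
            p_star=item.get("p_star"),
            setpoint=item.get("setpoint"),
            source=item.get("source"),
            amplitude=item.get("amplitude"),
            dual_control_start=item.get("dual_control_start"),
            fresh_plant=bool(item.get("fresh_plant", False)),
            controller=item.get("controller", {}),
        )
        if stage.mode not in _MODES:
            raise ProtocolError(f"stage {stage.stage_id}: unknown mode {stage.mode!r}")
        if stage.stage_id in seen:
            raise ProtocolError(f"duplicate stage id {stage.stage_id!r}")
        if stage.mode in ("open_replay", "open_shuffle") or (
            stage.mode == "open_constant" and stage.amplitude is None
        ):
            if stage.source is None or stage.source not in closed_seen:
                raise ProtocolError(
                    f"stage {stage.stage_id}: mode {stage.mode} must reference an "
                    f"earlier closed-loop stage (got source={stage.source!r})"
                )
        seen.add(stage.stage_id)
        if stage.mode == "closed":
            closed_seen.add(stage.stage_id)
        stages.append(stage)
    return ProtocolSpec(
        stages=stages,
        plant=plant_cfg,
        stim_period=float(raw.get("stim_period", 5.0)),
        tau=float(raw.get("tau", 250.0)),
        seed=int(raw.get("seed", 0)),
    )


def _stage_schedule(stage: ProtocolStage) -> SetpointSchedule:
    if stage.setpoint is not None:
        sp = dict(stage.setpoint)
        if "segments" in sp:
            sp["segments"] = tuple(tuple(s) for s in sp["segments"])
        return SetpointSchedule(**sp)
    return SetpointSchedule.constant(stage.p_star if stage.p_star is not None else 0.5)


def run_protocol(
    spec: ProtocolSpec, seed: Optional[int] = None, outdir: Optional[Path] = None
) -> dict[str, SessionLog]:
    """Execute the stages in order on a continuing plant state.

    The global seed is fanned out to one child seed per stage (used for plant
    resets and shuffles), so each stage is reproducible in isolation.
    """
    seed = spec.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(spec.stages) + 1)
    plant = Plant(
        PlantConfig(**{**spec.plant.to_dict(),
                       "seed": int(children[0].generate_state(1)[0] % 2**31)})
    )
    logs: dict[str, SessionLog] = {}
    for stage, child in zip(spec.stages, children[1:]):
        stage_seed = int(child.generate_state(1)[0] % 2**31)
        if stage.fresh_plant:
            plant = Plant(PlantConfig(**{**spec.plant.to_dict(), "seed": stage_seed}))
        if stage.mode == "closed":
            sched = _stage_schedule(stage)
            baseline = calibrate_baseline(
                plant, sched.base if sched.kind != "piecewise" else
                sched.segments[0][1]
            )
            ctrl = ControllerConfig(
                setpoint=sched, a_baseline=baseline, **stage.controller
            )
            log = run_closed_loop(
                plant, ctrl, stage.duration_s,
                stim_period=spec.stim_period, tau=spec.tau,
                dual_control_start=stage.dual_control_start,
            )
        elif stage.mode == "no_stim":
            log = run_no_stimulation(plant, stage.duration_s)
        else:
            n_trials = int(round(stage.duration_s / spec.stim_period))
            if stage.mode == "open_constant":
                value = (
                    stage.amplitude
                    if stage.amplitude is not None
                    else float(logs[stage.source].trials.amplitude_mV.mean())
                )
                amps = np.full(n_trials, value)
            else:
                src = logs[stage.source].trials.amplitude_mV.to_numpy()
                if src.size < n_trials:
                    raise ProtocolError(
                        f"stage {stage.stage_id}: source series shorter than stage"
                    )
                amps = src[:n_trials].copy()
                if stage.mode == "open_shuffle":
                    amps = np.random.default_rng(stage_seed).permutation(amps)
            log = run_open_loop(
                plant, amps, stim_period=spec.stim_period, tau=spec.tau,
                mode=stage.mode,
            )
        log.config["stage_id"] = stage.stage_id
        log.config["protocol_seed"] = seed
        log.config["stage_seed"] = stage_seed
        logs[stage.stage_id] = log
        if outdir is not None:
            outdir = Path(outdir)
            outdir.mkdir(parents=True, exist_ok=True)
            save_session_log(log, outdir / f"{stage.stage_id}.h5")
    return logs
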