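"""Config-driven pipeline wiring the stages together.

A :class:`RunConfig` is a declarative description of one stage run
(synthesis, simulation, or analysis); :func:`run` executes it and writes
machine-readable JSON results plus a small log.  Every result file embeds
the full provenance (config, config hash, seed, package version) needed to
regenerate it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import yaml

from .damping import DampingCurve, fit_damping_curve, invert_steps, titration_to_kd
from .errors import ConfigError, PhotocytError
from .kinetic_core import (IlluminationProtocol, simulate_continuous,
                           simulate_flash_train)
from .synthetic import (NoiseModel, default_flash_protocol,
                        generate_continuous_experiment,
                        generate_ferricyanide_titration,
                        generate_flash_experiment, strain_preset)
from .traces import (AbsorbanceTrace, absorbance_to_concentration,
                     extract_steps, fit_three_phases)

__all__ = ["RunConfig", "run", "COMMANDS"]

COMMANDS = ("simulate", "analyze-steps", "analyze-phases", "fit-damping",
            "titrate", "make-synthetic")

log = logging.getLogger("photocyt")


@dataclass
class RunConfig:
    """Declarative description of one pipeline stage run."""

    command: str
    label: str = "run"
    output_dir: str = "."
    seed: int = 0
    # --- synthesis / simulation ---
    kind: str = "flash"                 # flash | continuous | titration
    preset: str = "rvx_wt"
    treatment: str = "none"
    t_inc_s: float = 0.0
    sigma_delta_a: float = 1e-4
    n_averages: int = 32
    rc_conc_uM: float = 1.0
    observable: str = "cyt"
    n_flashes: int = 3
    flash_spacing_s: float = 400e-6
    duration_s: float = 20e-3
    k_L: float = 1.5e4
    continuous_mode: str = "auto"
    incubation_times_s: Tuple[float, ...] = (0.0, 1800.0, 3600.0, 5400.0, 7200.0)
    # --- analysis options ---
    input: Optional[str] = None
    window_s: Tuple[float, float] = (100e-6, 350e-6)
    ka1: Optional[float] = None          # finite acceptor constants, if known
    ka2: Optional[float] = None
    clip_tol: Optional[float] = None
    fit_init: Optional[Tuple[float, float]] = None

    def __post_init__(self):
        if self.command not in COMMANDS:
            raise ConfigError(
                f"unknown command {self.command!r}; valid: {', '.join(COMMANDS)}")
        if self.kind not in ("flash", "continuous", "titration"):
            raise ConfigError("kind must be flash, continuous or titration")

    # ---- serialization (lossless round trip) ----
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("incubation_times_s", "window_s", "fit_init"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("incubation_times_s", "window_s", "fit_init"):
            if d.get(key) is not None:
                d[key] = tuple(d[key])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(config: RunConfig) -> dict:
    from . import __version__
    return {"package": "photocyt", "version": __version__,
            "seed": config.seed, "config_hash": config.config_hash(),
            "config": config.to_dict()}


def _require_input(config: RunConfig) -> Path:
    if not config.input:
        raise ConfigError(f"command {config.command!r} requires an input path")
    path = Path(config.input)
    if not path.exists():
        raise ConfigError(f"input file not found: {path}")
    return path


def _noise(config: RunConfig) -> NoiseModel:
    return NoiseModel(sigma_delta_a=config.sigma_delta_a,
                      n_averages=config.n_averages, seed=config.seed)


def _protocol(config: RunConfig) -> IlluminationProtocol:
    if config.kind == "continuous":
        return IlluminationProtocol.continuous(config.duration_s)
    return default_flash_protocol(spacing=config.flash_spacing_s,
                                  n_flashes=config.n_flashes)


def _steps_from_trace(trace: AbsorbanceTrace, config: RunConfig) -> dict:
    if trace.protocol is None:
        raise ConfigError("trace has no protocol metadata; cannot locate flashes")
    conc = absorbance_to_concentration(trace)
    steps = extract_steps(conc, trace.protocol, window=tuple(config.window_s))
    acceptor = None
    if config.ka1 is not None or config.ka2 is not None:
        acceptor = (config.ka1 if config.ka1 is not None else math.inf,
                    config.ka2 if config.ka2 is not None else math.inf)
    kd = invert_steps(steps, acceptor=acceptor, clip_tol=config.clip_tol)
    return {"steps": steps.to_dict(), "equilibrium_constants": kd.to_dict()}


def run(config: RunConfig) -> dict:
    """Execute one configured stage; returns and writes the result record."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / f"{config.label}.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    prov = _provenance(config)
    log.info("photocyt %s | command=%s | seed=%d | config_hash=%s",
             prov["version"], config.command, config.seed, prov["config_hash"])
    try:
        result = _dispatch(config, outdir)
        result["provenance"] = prov
        out_path = outdir / f"{config.label}.result.json"
        out_path.write_text(json.dumps(result, indent=1, default=float))
        result["result_path"] = str(out_path)
        log.info("wrote %s", out_path)
        return result
    except PhotocytError as exc:
        log.error("stage %s failed: %s", config.command, exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def _dispatch(config: RunConfig, outdir: Path) -> dict:
    cmd = config.command
    if cmd == "make-synthetic":
        return _make_synthetic(config, outdir)
    if cmd == "simulate":
        return _simulate(config, outdir)
    if cmd == "analyze-steps":
        trace = AbsorbanceTrace.from_csv(_require_input(config))
        return _steps_from_trace(trace, config)
    if cmd == "analyze-phases":
        trace = AbsorbanceTrace.from_csv(_require_input(config))
        conc = absorbance_to_concentration(trace)
        return {"phase_fit": fit_three_phases(conc).to_dict()}
    if cmd == "fit-damping":
        curve = DampingCurve.from_csv(_require_input(config))
        fit = fit_damping_curve(curve, init=config.fit_init)
        return {"damping_fit": fit.summary(), "flash_pair": curve.flash_pair}
    if cmd == "titrate":
        return _titrate(config)
    raise ConfigError(f"unknown command {cmd!r}")


def _make_synthetic(config: RunConfig, outdir: Path) -> dict:
    preset = strain_preset(config.preset, config.treatment, t_inc=config.t_inc_s)
    noise = _noise(config)
    if config.kind == "flash":
        trace, truth = generate_flash_experiment(
            preset, _protocol(config), noise,
            rc_conc_uM=config.rc_conc_uM, observable=config.observable)
        csv_path = outdir / f"{config.label}.csv"
        trace.to_csv(csv_path)
        (outdir / f"{config.label}.truth.json").write_text(
            json.dumps(truth, indent=1, default=float))
        return {"trace": str(csv_path), "truth": truth}
    if config.kind == "continuous":
        trace, truth = generate_continuous_experiment(
            preset, duration=config.duration_s, k_L=config.k_L, noise=noise,
            mode=config.continuous_mode, rc_conc_uM=config.rc_conc_uM)
        csv_path = outdir / f"{config.label}.csv"
        trace.to_csv(csv_path)
        (outdir / f"{config.label}.truth.json").write_text(
            json.dumps(truth, indent=1, default=float))
        return {"trace": str(csv_path), "truth": truth}
    # titration
    experiments, truth = generate_ferricyanide_titration(
        preset, config.incubation_times_s, noise=noise,
        rc_conc_uM=config.rc_conc_uM)
    manifest = []
    for t_inc, trace in experiments:
        csv_path = outdir / f"{config.label}_t{int(t_inc)}.csv"
        trace.to_csv(csv_path)
        manifest.append([t_inc, str(csv_path)])
    manifest_path = outdir / f"{config.label}.manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    (outdir / f"{config.label}.truth.json").write_text(
        json.dumps(truth, indent=1, default=float))
    return {"manifest": str(manifest_path), "truth": truth}


def _simulate(config: RunConfig, outdir: Path) -> dict:
    preset = strain_preset(config.preset, config.treatment, t_inc=config.t_inc_s)
    protocol = _protocol(config)
    if config.kind == "continuous":
        sim = simulate_continuous(preset.rates.with_(k_L=config.k_L), protocol)
    else:
        sim = simulate_flash_train(preset.rates, protocol)
    csv_path = outdir / f"{config.label}.trajectory.csv"
    sim.to_frame().to_csv(csv_path, index=False)
    (outdir / f"{config.label}.trajectory.json").write_text(
        json.dumps(sim.sidecar(), indent=1, default=float))
    out = {"trajectory": str(csv_path),
           "final_cyt3_per_rc": float(sim.cyt3_per_rc[-1]),
           "final_pplus_per_rc": float(sim.pplus_per_rc[-1])}
    if sim.step_heights is not None:
        out["steps"] = sim.step_heights.to_dict()
    return out


def _titrate(config: RunConfig) -> dict:
    manifest_path = _require_input(config)
    manifest = json.loads(manifest_path.read_text())
    series = []
    for t_inc, csv_path in manifest:
        trace = AbsorbanceTrace.from_csv(csv_path)
        conc = absorbance_to_concentration(trace)
        steps = extract_steps(conc, trace.protocol, window=tuple(config.window_s))
        series.append((float(t_inc), steps))
    kd_series = titration_to_kd(series, clip_tol=config.clip_tol)
    return {"titration": [
        {"t_inc_s": t, "equilibrium_constants": kd.to_dict(),
         "steps": steps.to_dict()}
        for (t, kd), (_, steps) in zip(kd_series, series)]}
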