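"""Configuration schema (YAML), validation, and provenance-stamped output.

One configuration file drives every run.  Schema version 1:

.. code-block:: yaml

    schema_version: 1
    seed: 0
    output_dir: out
    stack:
      top_boundary: no_flux            # or fixed_fraction
      top_fraction: null               # required iff fixed_fraction
      layers:
        - name: membrane
          kind: membrane               # membrane | scaffold | media
          thickness_um: 165
          medium: {name: pdms, D: 3.5e-5, alpha: 1.1e-6}
        - name: hydrogel
          kind: scaffold
          thickness_um: 500
          medium: {name: hydrogel, D: 1.87e-5, alpha: 1.1e-6}
          rho_cell: 0.0
          sOCR: 0.0
          K_m: 0.0
    schedule:
      events_per_hour: 60
      high_percent: 20.0
      low_percent: 0.0
      duty: 0.5
      duration_s: null                 # default: one period
      gas_chamber_lag_tau_s: 0.0
    grid:
      target_dz_um: 10.0
    solver:
      dt_s: null                       # default: period/600
      theta: 1.0
      newton_tol: 1.0e-10
      newton_max_iter: 25
      psss_tol: 0.001
      psss_max_cycles: 200
    sensor:
      t90_s: 2.0
      noise_sd_percent: 0.2
      sample_rate_hz: 1.0

Unknown keys are rejected by name; defaulted physical parameters are logged
(a missing medium ``alpha`` defaults to the water value, with a warning for
the membrane, since PDMS solubility only matters through the product D·α).
Every output table carries a provenance header with the config hash, the
seed and the package version, so identical config + seed gives byte-identical
files.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .sensor import SensorSpec
from .solver import SolverSettings
from .stack import IHSchedule, Layer, Medium, Stack, TopBoundary
from .units import ALPHA_WATER

__all__ = ["RunConfig", "parse_config", "serialize_config", "write_table",
           "config_hash", "ConfigError", "SCHEMA_VERSION"]

log = logging.getLogger("oxcycle")

SCHEMA_VERSION = 1


class ConfigError(ValueError):
    """Invalid configuration; the message names the offending key."""


@dataclass
class RunConfig:
    """Fully validated run description."""

    stack: Stack
    schedule: IHSchedule
    target_dz: float          # cm
    settings: SolverSettings
    sensor: SensorSpec
    seed: int
    output_dir: Path
    sha256: str               # hash of the normalized config document


def _require_mapping(obj, where: str) -> dict:
    if obj is None:
        return {}
    if not isinstance(obj, dict):
        raise ConfigError(f"{where}: expected a mapping")
    return obj


def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    extra = set(d) - allowed
    if extra:
        raise ConfigError(f"{where}: unknown key(s) {sorted(extra)}")


def _get(d: dict, key: str, default, where: str, *, lo=None, hi=None,
         log_default: bool = True):
    if key in d and d[key] is not None:
        v = d[key]
    else:
        v = default
        if log_default and default is not None:
            log.info("%s.%s defaulted to %r", where, key, default)
    if v is not None and lo is not None and not lo <= v:
        raise ConfigError(f"{where}.{key}: value {v!r} below {lo}")
    if v is not None and hi is not None and not v <= hi:
        raise ConfigError(f"{where}.{key}: value {v!r} above {hi}")
    return v


def _parse_medium(d, where: str) -> Medium:
    d = _require_mapping(d, where)
    _check_keys(d, {"name", "D", "alpha"}, where)
    if "D" not in d:
        raise ConfigError(f"{where}.D: required")
    alpha = d.get("alpha")
    if alpha is None:
        alpha = ALPHA_WATER.alpha
        log.warning("%s.alpha defaulted to the water value %.3g mol/(cm3*atm)",
                    where, alpha)
    try:
        return Medium(name=str(d.get("name", "medium")), D=float(d["D"]),
                      alpha=float(alpha))
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_layer(d, where: str) -> Layer:
    d = _require_mapping(d, where)
    _check_keys(d, {"name", "kind", "thickness_um", "medium",
                    "rho_cell", "sOCR", "K_m"}, where)
    for key in ("thickness_um", "medium"):
        if key not in d:
            raise ConfigError(f"{where}.{key}: required")
    kind = d.get("kind", "scaffold")
    if kind not in ("membrane", "scaffold", "media"):
        raise ConfigError(f"{where}.kind: {kind!r} not one of membrane/scaffold/media")
    try:
        return Layer(
            name=str(d.get("name", kind)),
            thickness=float(d["thickness_um"]) * 1e-4,
            medium=_parse_medium(d["medium"], f"{where}.medium"),
            kind=kind,
            rho_cell=float(_get(d, "rho_cell", 0.0, where, lo=0.0)),
            sOCR=float(_get(d, "sOCR", 0.0, where, lo=0.0)),
            K_m=float(_get(d, "K_m", 0.0, where, lo=0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_stack(d, where: str = "stack") -> Stack:
    d = _require_mapping(d, where)
    _check_keys(d, {"top_boundary", "top_fraction", "layers"}, where)
    layers_raw = d.get("layers")
    if not layers_raw or not isinstance(layers_raw, list):
        raise ConfigError(f"{where}.layers: need a non-empty list")
    layers = tuple(
        _parse_layer(la, f"{where}.layers[{i}]") for i, la in enumerate(layers_raw)
    )
    kind = _get(d, "top_boundary", "no_flux", where)
    if kind == "no_flux":
        top = TopBoundary("no_flux")
    elif kind == "fixed_fraction":
        frac = d.get("top_fraction")
        if frac is None or not 0.0 <= float(frac) <= 1.0:
            raise ConfigError(
                f"{where}.top_fraction: required fraction in [0, 1] for fixed_fraction"
            )
        top = TopBoundary("fixed_fraction", float(frac))
    else:
        raise ConfigError(f"{where}.top_boundary: {kind!r} not no_flux/fixed_fraction")
    try:
        return Stack(layers=layers, top=top)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_schedule(d, where: str = "schedule") -> IHSchedule:
    d = _require_mapping(d, where)
    _check_keys(d, {"events_per_hour", "high_percent", "low_percent", "duty",
                    "duration_s", "gas_chamber_lag_tau_s"}, where)
    for key in ("events_per_hour", "high_percent", "low_percent"):
        if key not in d:
            raise ConfigError(f"{where}.{key}: required")
    rate = float(d["events_per_hour"])
    if rate <= 0:
        raise ConfigError(f"{where}.events_per_hour: must be positive")
    high = float(_get(d, "high_percent", None, where, lo=0.0, hi=100.0)) / 100.0
    low = float(_get(d, "low_percent", None, where, lo=0.0, hi=100.0)) / 100.0
    period = 3600.0 / rate
    duration = d.get("duration_s")
    try:
        return IHSchedule(
            high_fraction=high,
            low_fraction=low,
            period=period,
            duty=float(_get(d, "duty", 0.5, where)),
            total_duration=float(duration) if duration is not None else period,
            gas_chamber_lag_tau=float(_get(d, "gas_chamber_lag_tau_s", 0.0, where,
                                           lo=0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def parse_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    doc = _require_mapping(doc, "config")
    _check_keys(doc, {"schema_version", "seed", "output_dir", "stack",
                      "schedule", "grid", "solver", "sensor"}, "config")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"schema_version: expected {SCHEMA_VERSION}, got {version!r}"
        )
    if "stack" not in doc:
        raise ConfigError("stack: required")
    if "schedule" not in doc:
        raise ConfigError("schedule: required")

    stack = _parse_stack(doc["stack"])
    schedule = _parse_schedule(doc["schedule"])

    g = _require_mapping(doc.get("grid"), "grid")
    _check_keys(g, {"target_dz_um"}, "grid")
    target_dz = float(_get(g, "target_dz_um", 10.0, "grid", lo=1e-3)) * 1e-4

    s = _require_mapping(doc.get("solver"), "solver")
    _check_keys(s, {"dt_s", "theta", "newton_tol", "newton_max_iter",
                    "psss_tol", "psss_max_cycles"}, "solver")
    try:
        settings = SolverSettings(
            dt=float(s["dt_s"]) if s.get("dt_s") is not None else None,
            theta=float(_get(s, "theta", 1.0, "solver")),
            newton_tol=float(_get(s, "newton_tol", 1e-10, "solver")),
            newton_max_iter=int(_get(s, "newton_max_iter", 25, "solver", lo=1)),
            psss_tol=float(_get(s, "psss_tol", 1e-3, "solver")),
            psss_max_cycles=int(_get(s, "psss_max_cycles", 200, "solver", lo=1)),
            target_dz=target_dz,
        )
    except ValueError as exc:
        raise ConfigError(f"solver: {exc}") from exc

    sn = _require_mapping(doc.get("sensor"), "sensor")
    _check_keys(sn, {"t90_s", "noise_sd_percent", "sample_rate_hz"}, "sensor")
    try:
        sensor = SensorSpec(
            t90=float(_get(sn, "t90_s", 2.0, "sensor", lo=0.0)),
            noise_sd=float(_get(sn, "noise_sd_percent", 0.2, "sensor", lo=0.0)),
            sample_rate=float(_get(sn, "sample_rate_hz", 1.0, "sensor")),
            seed=int(doc.get("seed", 0)),
        )
    except ValueError as exc:
        raise ConfigError(f"sensor: {exc}") from exc

    return RunConfig(
        stack=stack,
        schedule=schedule,
        target_dz=target_dz,
        settings=settings,
        sensor=sensor,
        seed=int(_get(doc, "seed", 0, "config")),
        output_dir=Path(doc.get("output_dir", "out")),
        sha256=config_hash(doc),
    )


def serialize_config(cfg: RunConfig) -> str:
    """Render a RunConfig back to canonical YAML (parses to an equal config)."""
    stack = cfg.stack
    doc = {
        "schema_version": SCHEMA_VERSION,
        "seed": cfg.seed,
        "output_dir": str(cfg.output_dir),
        "stack": {
            "top_boundary": stack.top.kind,
            "top_fraction": stack.top.fraction,
            "layers": [
                {
                    "name": la.name,
                    "kind": la.kind,
                    "thickness_um": la.thickness * 1e4,
                    "medium": {"name": la.medium.name, "D": la.medium.D,
                               "alpha": la.medium.alpha},
                    "rho_cell": la.rho_cell,
                    "sOCR": la.sOCR,
                    "K_m": la.K_m,
                }
                for la in stack.layers
            ],
        },
        "schedule": {
            "events_per_hour": cfg.schedule.events_per_hour,
            "high_percent": 100.0 * cfg.schedule.high_fraction,
            "low_percent": 100.0 * cfg.schedule.low_fraction,
            "duty": cfg.schedule.duty,
            "duration_s": cfg.schedule.total_duration,
            "gas_chamber_lag_tau_s": cfg.schedule.gas_chamber_lag_tau,
        },
        "grid": {"target_dz_um": cfg.target_dz * 1e4},
        "solver": {
            "dt_s": cfg.settings.dt,
            "theta": cfg.settings.theta,
            "newton_tol": cfg.settings.newton_tol,
            "newton_max_iter": cfg.settings.newton_max_iter,
            "psss_tol": cfg.settings.psss_tol,
            "psss_max_cycles": cfg.settings.psss_max_cycles,
        },
        "sensor": {
            "t90_s": cfg.sensor.t90,
            "noise_sd_percent": cfg.sensor.noise_sd,
            "sample_rate_hz": cfg.sensor.sample_rate,
        },
    }
    return yaml.safe_dump(doc, sort_keys=True)


def config_hash(doc: dict) -> str:
    """SHA-256 of the canonical YAML rendering of a config document."""
    return hashlib.sha256(yaml.safe_dump(doc, sort_keys=True).encode()).hexdigest()


def write_table(df: pd.DataFrame, path: str | Path, cfg: RunConfig | None = None,
                note: str = "") -> None:
    """Write a CSV with a provenance header (package version, config hash, seed).

    Comma-separated, ``.`` decimal, LF endings; float formatting is fixed so
    identical inputs give byte-identical files.
    """
    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"# oxcycle {__version__}\n")
        if cfg is not None:
            fh.write(f"# config_sha256: {cfg.sha256}\n")
            fh.write(f"# seed: {cfg.seed}\n")
        if note:
            fh.write(f"# {note}\n")
        df.to_csv(fh, index=False, float_format="%.6g", lineterminator="\n")
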