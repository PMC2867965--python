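"""Configuration loading, validation and result serialization.

Run configurations are YAML documents with sections mirroring the
parameter types::

    scenario: fig3        # optional; pre-fills sections from the registry
    model:     {alpha1: 3.0, ..., g22: 0.0}
    tumor:     {gamma_T: 0.005, L_T: 100, r11: 0.005, r22: 0.2}
    treatment: {v1: 0.001, v2: 0.008, t_start: 600}
    bone:      {k1: 0.0748, k2: 0.0006395, z0: 100}
    spatial:   {sigma1: 1.0e-6, ...}
    grid:      {n: 101}
    sim:       {t0: 0, t_end: 1000, samples_per_day: 1, rtol: 1.0e-8, atol: 1.0e-10}
    init:      {C: 11.16, B: 231.72}          # 0-D initial state
    ics:       {C: {baseline: steady, bumps: [[0.5, 10.0, 0.05]]}, ...}

Explicit keys override the scenario's values; unknown sections or keys are
rejected with the offending name.  Results are written as delimited text
(trajectories wide, fields long-format) with 17 significant digits so a
round trip reproduces every array bit-exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .model import (
    BoneMassParams,
    ParameterError,
    RemodelingParams,
    State0D,
    TreatmentParams,
    TumorParams,
)
from .scenarios import RegimeSurface, Scenario, get_scenario
from .simulate import SimSpec, Trajectory
from .spatial import FieldTrajectory, GridSpec, SpatialParams

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "build_bundle",
    "write_results",
    "read_trajectory",
    "read_field",
]

log = logging.getLogger(__name__)

_SECTIONS = {
    "scenario", "model", "tumor", "treatment", "bone",
    "spatial", "grid", "sim", "init", "ics", "output",
}

_SECTION_TYPES = {
    "model": RemodelingParams,
    "tumor": TumorParams,
    "treatment": TreatmentParams,
    "bone": BoneMassParams,
    "spatial": SpatialParams,
    "grid": GridSpec,
    "sim": SimSpec,
    "init": State0D,
}


class ConfigError(ValueError):
    """Malformed or invalid run configuration."""


@dataclass
class RunConfig:
    """Validated section dictionaries plus the optional scenario name."""

    scenario: Optional[str] = None
    sections: Dict[str, Dict] = dataclasses.field(default_factory=dict)


def load_config(source: Union[str, os.PathLike]) -> RunConfig:
    """Parse and validate a YAML run configuration.

    ``source`` is a path to a config file, or the YAML text itself when it
    contains a newline/colon (convenient for tests and one-liners).
    """
    text = None
    s = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(s, str) and ("\n" in s or ":" in s) and not os.path.exists(s):
        text = s
    else:
        with open(s) as fh:
            text = fh.read()
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"config parse error: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping of sections")

    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(f"unknown config section(s): {', '.join(sorted(unknown))}")

    scenario = raw.pop("scenario", None)
    sections: Dict[str, Dict] = {}
    for name, payload in raw.items():
        if name in ("ics", "output"):
            sections[name] = payload
            continue
        if not isinstance(payload, dict):
            raise ConfigError(f"section {name!r} must be a mapping")
        cls = _SECTION_TYPES[name]
        valid = {f.name for f in dataclasses.fields(cls)}
        bad = set(payload) - valid
        if bad:
            raise ConfigError(
                f"unknown key(s) in section {name!r}: {', '.join(sorted(bad))}"
            )
        sections[name] = dict(payload)
    cfg = RunConfig(scenario=scenario, sections=sections)
    build_bundle(cfg)  # validate eagerly so errors name the offending key
    return cfg


def _merged(base, override: Optional[Dict], cls):
    if base is None and override is None:
        return None
    fields = {}
    if base is not None:
        fields = {f.name: getattr(base, f.name) for f in dataclasses.fields(cls)}
    if override:
        fields.update(override)
    try:
        return cls(**fields)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    except TypeError as exc:
        raise ConfigError(f"invalid {cls.__name__} section: {exc}") from exc


def build_bundle(cfg: RunConfig) -> Dict:
    """Resolve a config into constructed parameter objects.

    Returns a dict with keys ``p, tp, trt, bp, sp, grid, sim, init, ics,
    output, scenario`` (absent components are ``None``).  Scenario values
    are applied first, then explicit section keys override field-wise.
    """
    sc: Optional[Scenario] = get_scenario(cfg.scenario) if cfg.scenario else None
    s = cfg.sections
    p = _merged(sc.p if sc else None, s.get("model"), RemodelingParams)
    if p is None:
        raise ConfigError("config must define a 'model' section or name a scenario")
    tp = _merged(sc.tp if sc else None, s.get("tumor"), TumorParams)
    trt = _merged(sc.trt if sc else None, s.get("treatment"), TreatmentParams)
    bp = _merged(sc.bp if sc else None, s.get("bone"), BoneMassParams)
    sp = _merged(sc.sp if sc else None, s.get("spatial"), SpatialParams)
    grid = _merged(sc.grid if sc else None, s.get("grid"), GridSpec)
    sim = _merged(sc.sim if sc else SimSpec(), s.get("sim"), SimSpec)
    try:
        init = _merged(sc.init if sc else None, s.get("init"), State0D)
    except ConfigError:
        raise
    if trt is not None and tp is None:
        raise ConfigError("a 'treatment' section requires a 'tumor' section")
    if trt is not None:
        try:
            trt.validate_against(p)
        except ParameterError as exc:
            raise ConfigError(str(exc)) from exc
    ics = s.get("ics", sc.ics if sc else None)
    if isinstance(ics, dict):
        ics = {
            var: {
                "baseline": d.get("baseline", 0.0),
                "bumps": [tuple(b) for b in d.get("bumps", [])],
            }
            for var, d in ics.items()
        }
    return {
        "scenario": sc,
        "p": p,
        "tp": tp,
        "trt": trt,
        "bp": bp,
        "sp": sp,
        "grid": grid,
        "sim": sim,
        "init": init,
        "ics": ics,
        "output": s.get("output"),
    }


# ---------------------------------------------------------------------------
# Result serialization

_FORMATS = {"csv": ",", "tsv": "\t"}
_FLOAT_FMT = "%.17g"


def _sep(fmt: str) -> str:
    try:
        return _FORMATS[fmt]
    except KeyError:
        raise ConfigError(
            f"unknown format {fmt!r}; supported: {', '.join(sorted(_FORMATS))}"
        ) from None


def write_results(
    obj: Union[Trajectory, FieldTrajectory, RegimeSurface],
    path: Union[str, os.PathLike],
    format: str = "csv",
) -> None:
    """Serialize a result object as delimited text.

    Trajectories are written wide (``t, C, B[, T][, z]``); field
    trajectories long (``t, x, variable, value``); regime surfaces as
    ``r11, r22, value`` triples.  Floats carry 17 significant digits so the
    matching reader reproduces them exactly.
    """
    sep = _sep(format)
    if isinstance(obj, Trajectory):
        df = pd.DataFrame(obj.column_dict())
    elif isinstance(obj, FieldTrajectory):
        frames = []
        for var in ("C", "B", "T", "z"):
            arr = getattr(obj, var)
            if arr is None:
                continue
            tt, xx = np.meshgrid(obj.times, obj.x, indexing="ij")
            frames.append(
                pd.DataFrame(
                    {
                        "t": tt.ravel(),
                        "x": xx.ravel(),
                        "variable": var,
                        "value": arr.ravel(),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
    elif isinstance(obj, RegimeSurface):
        aa, bb = np.meshgrid(obj.r11, obj.r22, indexing="ij")
        df = pd.DataFrame(
            {"r11": aa.ravel(), "r22": bb.ravel(), "value": obj.values.ravel()}
        )
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    log.info("wrote %d rows to %s", len(df), path)


def read_trajectory(path: Union[str, os.PathLike], format: str = "csv") -> Trajectory:
    """Read back a wide-format trajectory file."""
    df = pd.read_csv(path, sep=_sep(format), float_precision="round_trip")
    return Trajectory(
        times=df["t"].to_numpy(),
        C=df["C"].to_numpy(),
        B=df["B"].to_numpy(),
        T=df["T"].to_numpy() if "T" in df else None,
        z=df["z"].to_numpy() if "z" in df else None,
    )


def read_field(path: Union[str, os.PathLike], format: str = "csv") -> FieldTrajectory:
    """Read back a long-format field trajectory file."""
    df = pd.read_csv(path, sep=_sep(format), float_precision="round_trip")
    times = np.unique(df["t"].to_numpy())
    x = np.unique(df["x"].to_numpy())
    arrays = {}
    for var, sub in df.groupby("variable"):
        sub = sub.sort_values(["t", "x"])
        arrays[var] = sub["value"].to_numpy().reshape(len(times), len(x))
    return FieldTrajectory(
        times=times,
        x=x,
        C=arrays["C"],
        B=arrays["B"],
        T=arrays.get("T"),
        z=arrays.get("z"),
    )
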