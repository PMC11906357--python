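"""Shared configuration and table I/O.

Configuration files are flat YAML key/value mappings whose keys mirror the
simulation parameters (``dt``, ``kappa``, ``alpha``, ``epsilon``,
``growth_rate``, ``kT``, ``ecm_enabled``, ``seed`` plus dotted ``j.<a>_<b>``
and ``phi.<a>_<b>`` entries).  Unknown keys are rejected by name; every
consumed value is echoed to the log so a run is reproducible from its logged
config and seed alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .potts import CellType, SimParams

log = logging.getLogger("icmsort")

_SCALAR_KEYS = {
    "kappa": float, "alpha": float, "epsilon": float, "kT": float,
    "dt": float, "growth_rate": float, "seed": int, "ecm_enabled": bool,
}
_LIST_KEYS = {"division_volumes"}


@dataclass
class RunConfig:
    """Validated run configuration: seed, paths and parameter overrides."""

    params: SimParams
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    log_level: str = "INFO"


def _parse_pair(key: str, prefix: str) -> tuple[CellType, CellType]:
    body = key[len(prefix):]
    try:
        a, b = body.split("_")
        return CellType[a.upper()], CellType[b.upper()]
    except (ValueError, KeyError):
        raise ValueError(f"cannot parse type pair in config key '{key}'")


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> RunConfig:
    """Load and validate a flat YAML config, applying dotted-key overrides.

    An empty or missing-content file yields all defaults.  Unknown keys and
    type mismatches raise errors naming the offending key.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a key/value mapping")
        raw.update(loaded)
    for k, v in (overrides or {}).items():
        raw[k] = v

    kwargs: dict = {}
    J = dict(SimParams().J)
    phi: dict = {}
    for key, value in raw.items():
        if key in _SCALAR_KEYS:
            caster = _SCALAR_KEYS[key]
            try:
                kwargs[key] = caster(value)
            except (TypeError, ValueError):
                raise ValueError(
                    f"config key '{key}' expects {caster.__name__}, "
                    f"got {value!r}")
        elif key in _LIST_KEYS:
            kwargs[key] = [float(v) for v in value]
        elif key.startswith("j."):
            a, b = _parse_pair(key, "j.")
            J[(a, b)] = float(value)
        elif key.startswith("phi."):
            a, b = _parse_pair(key, "phi.")
            phi[(a, b)] = float(value)
        else:
            raise ValueError(f"unknown config key '{key}'")
    kwargs["J"] = J
    if phi:
        kwargs["phi"] = phi
    params = SimParams(**kwargs)
    for key in sorted(raw):
        log.info("config: %s = %r", key, raw[key])
    return RunConfig(params=params, seed=params.seed,
                     overrides=dict(overrides or {}))


def table_roundtrip(records: pd.DataFrame, path: str | Path,
                    required: list[str] | None = None) -> pd.DataFrame:
    """Write a table to CSV and read it back value-identically.

    Floats are written with round-trip-safe repr; column order is canonical
    (the input order on write, enforced on read).  A missing header column on
    read raises an error naming the column.
    """
    path = Path(path)
    records.to_csv(path, index=False, float_format="%.17g")
    out = read_table(path, required=required or list(records.columns))
    return out[list(records.columns)]


def read_table(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df
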