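"""Flat YAML configuration documents and provenance-carrying run records.

Schema (all units explicit in the key names):

Sequence document::

    method: SPGR | bSSFP | DESS | TESS | MRF_spoiled | MRF_balanced
    flips_deg: [..]              # list, degrees
    trs_ms: [..] or scalar       # milliseconds
    te_ms: float
    rf_phases_deg: [..]          # optional
    driven_equilibrium: bool     # optional, default false
    recovery_delay_ms: float     # optional, default 0
    include_recovery: bool       # optional, default false
    n_measurements: int          # optional; checked against flips length

Tissue document (single mapping or a list of them)::

    t1_ms: float
    t2_ms: float
    m0: float          # optional, default 1
    phi0_rad: float    # optional, default 0
    omega0_hz: float   # optional, default 0

Every result file written by the CLI embeds its full
:class:`RunConfig` (JSON files under a ``"config"`` key, CSV files as
``# config: {...}`` comment header lines), so a run can be reproduced from
its output alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib.metadata import PackageNotFoundError, version

import numpy as np
import pandas as pd
import yaml

from .params import SequenceSettings, TissueParams

__all__ = [
    "RunConfig",
    "load_sequence",
    "save_sequence",
    "load_tissues",
    "write_csv",
    "write_json",
    "parse_grid",
]

try:
    _VERSION = version("qmreff")
except PackageNotFoundError:  # pragma: no cover
    _VERSION = "unknown"


class ConfigError(ValueError):
    """A configuration document failed schema validation."""


def _require(doc: dict, key: str, context: str):
    if key not in doc:
        raise ConfigError(f"missing required key {key!r} in {context} document")
    return doc[key]


@dataclass
class RunConfig:
    """Full provenance record of one CLI run."""

    command: str
    parameters: dict
    seed: int
    version: str = _VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer, np.floating)):
        return x.item()
    raise TypeError(f"not JSON-serializable: {type(x)}")


def load_sequence(path) -> SequenceSettings:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return sequence_from_dict(doc)


def sequence_from_dict(doc: dict) -> SequenceSettings:
    method = _require(doc, "method", "sequence")
    flips = np.atleast_1d(np.asarray(_require(doc, "flips_deg", "sequence"), float))
    trs = _require(doc, "trs_ms", "sequence")
    te = float(_require(doc, "te_ms", "sequence"))
    n = doc.get("n_measurements")
    if n is not None and method not in ("DESS", "TESS") and int(n) != flips.size:
        raise ConfigError(
            f"n_measurements={n} does not match {flips.size} flip angles"
        )
    return SequenceSettings(
        method=method, flips=flips, trs=trs, te=te,
        rf_phases=doc.get("rf_phases_deg"),
        driven_equilibrium=bool(doc.get("driven_equilibrium", False)),
        recovery_delay=float(doc.get("recovery_delay_ms", 0.0)),
        include_recovery=bool(doc.get("include_recovery", False)),
    )


def save_sequence(u: SequenceSettings, path) -> None:
    doc = {
        "method": u.method,
        "flips_deg": [float(f) for f in u.flips],
        "trs_ms": [float(t) for t in u.trs],
        "te_ms": float(u.te),
        "driven_equilibrium": bool(u.driven_equilibrium),
        "recovery_delay_ms": float(u.recovery_delay),
        "include_recovery": bool(u.include_recovery),
        "n_measurements": int(u.n_measurements),
    }
    if u.rf_phases is not None:
        doc["rf_phases_deg"] = [float(p) for p in u.rf_phases]
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def tissue_from_dict(doc: dict) -> TissueParams:
    return TissueParams(
        t1=float(_require(doc, "t1_ms", "tissue")),
        t2=float(_require(doc, "t2_ms", "tissue")),
        m0=float(doc.get("m0", 1.0)),
        phi0=float(doc.get("phi0_rad", 0.0)),
        omega0=float(doc.get("omega0_hz", 0.0)),
    )


def load_tissues(path) -> list[TissueParams]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = [doc]
    return [tissue_from_dict(d) for d in doc]


def parse_grid(expr: str) -> np.ndarray:
    """Parse ``start:stop:step`` (inclusive stop) or a comma list."""
    if ":" in expr:
        start, stop, step = (float(x) for x in expr.split(":"))
        return np.arange(start, stop + step / 2, step)
    return np.array([float(x) for x in expr.split(",")])


def write_csv(df: pd.DataFrame, path, config: RunConfig) -> None:
    """CSV with the run configuration embedded as comment header lines."""
    with open(path, "w") as fh:
        fh.write(f"# config: {config.to_json()}\n")
        df.to_csv(fh, index=False)


def write_json(payload: dict, path, config: RunConfig) -> None:
    payload = dict(payload)
    payload["config"] = json.loads(config.to_json())
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
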