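"""Parameter containers: tissue properties, acquisition settings, signals.

Conventions used throughout the package:

* All sequence timings (TR, TE, delays) are in milliseconds at interfaces;
  efficiencies convert the total acquisition time to seconds internally.
* Flip angles and RF phases are in degrees at interfaces, radians internally.
* Off-resonance ``omega0`` is in Hz, receiver phase ``phi0`` in radians.
* Complex signals are in the units of ``m0`` (arbitrary).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "TissueParams",
    "SequenceSettings",
    "SignalRecord",
    "METHODS",
    "BALANCED_METHODS",
    "TRANSIENT_METHODS",
    "MIN_READOUT_MARGIN_MS",
]

METHODS = ("SPGR", "bSSFP", "DESS", "TESS", "MRF_spoiled", "MRF_balanced")
#: methods whose signal depends on off-resonance and measurement phase
BALANCED_METHODS = ("bSSFP", "MRF_balanced")
TRANSIENT_METHODS = ("MRF_spoiled", "MRF_balanced")

#: minimum time between echo and the end of a repetition period (ms); TRs
#: shorter than ``te + MIN_READOUT_MARGIN_MS`` are rejected as infeasible.
MIN_READOUT_MARGIN_MS = 0.3


@dataclass(frozen=True)
class TissueParams:
    """Single-voxel tissue parameter vector p = {T1, T2, M0, phi0, omega0}.

    Parameters
    ----------
    t1, t2:
        Longitudinal / transverse relaxation times in ms.  Must be positive.
        ``t2 > t1`` is unphysical for a single pool and triggers a warning,
        but the models remain evaluable.
    m0:
        Equilibrium magnetization (arbitrary units, >= 0).  All signal models
        are exactly linear in ``m0``.
    phi0:
        Receiver/measurement phase in radians.
    omega0:
        Off-resonance frequency in Hz.  Only balanced sequences depend on it.
    """

    t1: float
    t2: float
    m0: float = 1.0
    phi0: float = 0.0
    omega0: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError(
                f"relaxation times must be positive, got t1={self.t1}, t2={self.t2}"
            )
        if self.m0 < 0:
            raise ValueError(f"m0 must be non-negative, got {self.m0}")
        if self.t2 > self.t1:
            warnings.warn(
                f"t2={self.t2} ms exceeds t1={self.t1} ms (unphysical for a "
                "single pool); models remain evaluable",
                stacklevel=2,
            )

    def replace(self, **kw) -> "TissueParams":
        return replace(self, **kw)


def _as_float_array(x, n: int | None = None) -> np.ndarray:
    a = np.atleast_1d(np.asarray(x, dtype=float))
    if n is not None and a.size == 1 and n > 1:
        a = np.full(n, float(a[0]))
    return a


@dataclass(frozen=True, eq=False)
class SequenceSettings:
    """Acquisition settings u for one sequence (or pulse train).

    For steady-state methods (``SPGR``, ``bSSFP``) each entry of ``flips`` /
    ``trs`` describes an independent steady-state measurement.  For
    ``DESS``/``TESS`` a single flip/TR is shared and 2 (resp. 3) echo
    pathways are read out per TR.  For transient methods (``MRF_*``) the
    entries form an ordered pulse train with one measurement per pulse.

    ``rf_phases`` (degrees) holds the per-pulse RF phase for transient
    methods and the per-measurement phase-cycling increment for steady-state
    balanced methods (default 180 degrees, i.e. alternating excitation).

    ``driven_equilibrium`` marks a cyclically repeated train whose initial
    state is the periodic fixed point of one full cycle rather than thermal
    equilibrium.

    ``recovery_delay`` (ms) is dead time appended after the train; it is
    excluded from ``t_acq`` unless ``include_recovery`` is set.
    """

    method: str
    flips: np.ndarray
    trs: np.ndarray
    te: float
    rf_phases: np.ndarray | None = None
    driven_equilibrium: bool = False
    recovery_delay: float = 0.0
    include_recovery: bool = False

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        flips = _as_float_array(self.flips)
        trs = _as_float_array(self.trs, flips.size)
        if trs.size not in (1, flips.size):
            raise ValueError(
                f"trs has length {trs.size}, expected 1 or {flips.size}"
            )
        if trs.size == 1:
            trs = np.full(flips.size, float(trs[0]))
        object.__setattr__(self, "flips", flips)
        object.__setattr__(self, "trs", trs)
        if np.any(flips < 0.0) or np.any(flips > 180.0):
            raise ValueError("flip angles must lie in [0, 180] degrees")
        if self.te < 0:
            raise ValueError("te must be non-negative")
        if np.any(trs < self.te + MIN_READOUT_MARGIN_MS):
            raise ValueError(
                f"all trs must be >= te + {MIN_READOUT_MARGIN_MS} ms readout margin"
            )
        if self.method in ("DESS", "TESS") and flips.size != 1:
            raise ValueError(f"{self.method} uses a single shared flip angle and TR")
        if self.rf_phases is not None:
            ph = _as_float_array(self.rf_phases, flips.size)
            if ph.size == 1:
                ph = np.full(flips.size, float(ph[0]))
            if ph.size != flips.size:
                raise ValueError("rf_phases must match flips in length")
            object.__setattr__(self, "rf_phases", ph)
        if self.recovery_delay < 0:
            raise ValueError("recovery_delay must be non-negative")

    @property
    def n_measurements(self) -> int:
        if self.method == "DESS":
            return 2
        if self.method == "TESS":
            return 3
        return int(self.flips.size)

    @property
    def is_balanced(self) -> bool:
        return self.method in BALANCED_METHODS

    @property
    def is_transient(self) -> bool:
        return self.method in TRANSIENT_METHODS

    @property
    def t_acq(self) -> float:
        """Total acquisition duration in ms (sum of TRs, plus the recovery
        delay only when ``include_recovery`` is set)."""
        t = float(np.sum(self.trs))
        if self.include_recovery:
            t += self.recovery_delay
        return t

    def phase_train(self) -> np.ndarray:
        """Per-pulse RF phases in degrees, with method defaults filled in."""
        if self.rf_phases is not None:
            return self.rf_phases
        n = self.flips.size
        if self.method in ("bSSFP", "MRF_balanced"):
            # alternating 0/180 excitation (the standard bSSFP phase cycle)
            if self.method == "MRF_balanced":
                return np.where(np.arange(n) % 2 == 0, 0.0, 180.0)
            return np.full(n, 180.0)  # phase-cycling increment per measurement
        return np.zeros(n)

    def replace(self, **kw) -> "SequenceSettings":
        return replace(self, **kw)


@dataclass(frozen=True, eq=False)
class SignalRecord:
    """Complex signal timecourse with per-measurement timing.

    ``times`` are measurement (echo) times in ms from the start of the train;
    ``t_acq`` is the total acquisition duration in ms.
    """

    signal: np.ndarray
    times: np.ndarray
    t_acq: float

    def __post_init__(self) -> None:
        sig = np.atleast_1d(np.asarray(self.signal, dtype=complex))
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        if sig.shape != times.shape:
            raise ValueError("signal and times must have the same length")
        if times.size and self.t_acq < times.max() - 1e-9:
            raise ValueError("t_acq must cover all measurement times")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "times", times)

    def to_frame(self):
        """Export as a DataFrame with columns index, time_ms, re, im."""
        import pandas as pd

        return pd.DataFrame(
            {
                "index": np.arange(self.signal.size),
                "time_ms": self.times,
                "re": self.signal.real,
                "im": self.signal.imag,
            }
        )
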