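"""Fisher information, Cramér–Rao lower bounds, and the efficiency metric.

The precision of an unbiased estimate of a tissue parameter theta is
captured by the parameter-to-noise ratio ``thetaNR = theta / sigma_theta``.
Normalizing by the best achievable SNR of a single measurement
(``SNR_max = M0 / sigma0``) and by the square root of the total acquisition
time gives the intrinsic efficiency

    eta(theta) = (theta / sigma_theta) * (sigma0 / M0) / sqrt(T_acq),

in units of ``s**-1/2``.  With ``sigma_theta`` set to its Cramér–Rao lower
bound this is an upper bound on the efficiency of any unbiased estimator,
and is independent of both ``sigma0`` and ``M0`` (they cancel exactly).

Noise convention: ``sigma0`` is the per-quadrature standard deviation of the
additive complex Gaussian noise on each measurement, and the Fisher matrix
for complex-valued data is ``F = Re(J^H J) / sigma0**2`` where ``J`` is the
Jacobian of the complex signal with respect to the parameters.  Jointly
estimated nuisance parameters are included in ``J`` so their uncertainty is
fully propagated.

Derivatives are obtained by central finite differences (relative step 1e-4,
absolute floor 1e-6 in the parameter's native unit) for T1, T2 and omega0;
the M0 and phi0 columns are analytic (the models are exactly linear in M0,
and phi0 enters only as a global phase, so ``ds/dphi0 = i * s``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import models
from .params import SequenceSettings, TissueParams

__all__ = [
    "FisherBundle",
    "EfficiencyResult",
    "UnidentifiableParameterWarning",
    "jacobian",
    "crlb_std",
    "efficiency",
    "efficiency_batch",
    "default_params",
]

PARAM_ORDER = ("t1", "t2", "m0", "phi0", "omega0")
_FD_PARAMS = ("t1", "t2", "omega0")
FD_REL_STEP = 1e-4
FD_ABS_FLOOR = 1e-6


class UnidentifiableParameterWarning(UserWarning):
    """Raised (as a warning) when the Fisher matrix is singular and a
    parameter's variance bound is infinite, i.e. its efficiency is zero."""


def default_params(settings) -> tuple[str, ...]:
    """Jointly estimated parameter set for a sequence combination.

    Spoiled-only combinations estimate {T1, T2, M0}; as soon as a balanced
    readout participates, the measurement phase and off-resonance frequency
    become relevant and {T1, T2, M0, phi0, omega0} are estimated jointly.
    """
    if isinstance(settings, SequenceSettings):
        settings = [settings]
    if any(u.is_balanced for u in settings):
        return ("t1", "t2", "m0", "phi0", "omega0")
    return ("t1", "t2", "m0")


# ----------------------------------------------------------------------
# finite-difference machinery (batched over tissues)

def _stack_tissues(tissues) -> dict:
    if isinstance(tissues, TissueParams):
        tissues = [tissues]
    if isinstance(tissues, dict):
        return models.tissue_arrays(tissues)
    cols = {f: np.array([getattr(p, f) for p in tissues], float)
            for f in PARAM_ORDER}
    return cols


def fd_tissue_rows(tissues, params: Sequence[str],
                   rel_step: float = FD_REL_STEP,
                   abs_floor: float = FD_ABS_FLOOR):
    """Build the perturbed tissue table for one batched model sweep.

    Returns ``(flat, meta)`` where ``flat`` is a tissue dict of arrays with
    ``P * R`` entries (row-major over tissues then perturbation rows:
    base, then +/- pairs for each finite-differenced parameter) and ``meta``
    carries the bookkeeping needed by :func:`assemble_jacobian`.
    """
    base = _stack_tissues(tissues)
    P = base["t1"].size
    fd = [q for q in params if q in _FD_PARAMS]
    R = 1 + 2 * len(fd)
    table = {f: np.tile(base[f][:, None], (1, R)) for f in PARAM_ORDER}
    steps = np.empty((P, len(fd)))
    for j, q in enumerate(fd):
        h = np.maximum(rel_step * np.abs(base[q]), abs_floor)
        steps[:, j] = h
        table[q][:, 1 + 2 * j] = base[q] + h
        table[q][:, 2 + 2 * j] = base[q] - h
    flat = {f: v.reshape(P * R) for f, v in table.items()}
    meta = {"params": tuple(params), "fd": tuple(fd), "steps": steps,
            "P": P, "R": R, "base": base}
    return flat, meta


def assemble_jacobian(sig: np.ndarray, meta: dict) -> np.ndarray:
    """Assemble ``J`` of shape ``(..., P, N, n_params)`` from a model sweep
    of shape ``(..., P, R, N)`` produced with :func:`fd_tissue_rows`."""
    base = sig[..., 0, :]
    fd = meta["fd"]
    cols = []
    for q in meta["params"]:
        if q == "m0":
            m0 = meta["base"]["m0"][:, None]
            with np.errstate(invalid="ignore", divide="ignore"):
                col = np.where(m0 > 0, base / np.where(m0 > 0, m0, 1.0), 0.0)
        elif q == "phi0":
            col = 1j * base
        else:
            j = fd.index(q)
            h = meta["steps"][:, j][:, None]
            col = (sig[..., 1 + 2 * j, :] - sig[..., 2 + 2 * j, :]) / (2.0 * h)
        cols.append(col)
    J = np.stack(cols, axis=-1)
    if not np.all(np.isfinite(J)):
        bad = [meta["params"][k] for k in range(J.shape[-1])
               if not np.all(np.isfinite(J[..., k]))]
        raise FloatingPointError(
            f"non-finite model output while differentiating {bad}"
        )
    return J


def fisher_matrix(J: np.ndarray, sigma0: float = 1.0) -> np.ndarray:
    """Fisher information ``Re(J^H J) / sigma0**2`` (complex-data, per
    quadrature noise convention)."""
    F = np.einsum("...ni,...nj->...ij", np.conj(J), J).real
    return F / float(sigma0) ** 2


def crlb_sigmas(J: np.ndarray, sigma0: float = 1.0, warn: bool = True) -> np.ndarray:
    """CRLB standard deviations for all parameters, shape ``(..., n_params)``.

    Singular Fisher matrices yield ``inf`` (zero efficiency) rather than an
    exception, so optimizers can traverse degenerate regions.
    """
    F = fisher_matrix(J, sigma0)
    p = F.shape[-1]
    flatF = F.reshape(-1, p, p)
    diag = np.empty((flatF.shape[0], p))
    try:
        diag[:] = np.diagonal(np.linalg.inv(flatF), axis1=-2, axis2=-1)
    except np.linalg.LinAlgError:
        for i, Fi in enumerate(flatF):
            try:
                diag[i] = np.diag(np.linalg.inv(Fi))
            except np.linalg.LinAlgError:
                diag[i] = np.inf
    bad = ~np.isfinite(diag) | (diag <= 0)
    if np.any(bad):
        diag = np.where(bad, np.inf, diag)
        if warn:
            warnings.warn(
                "singular Fisher information: some parameters are "
                "unidentifiable (their CRLB is reported as inf)",
                UnidentifiableParameterWarning,
                stacklevel=2,
            )
    return np.sqrt(diag).reshape(F.shape[:-1])


# ----------------------------------------------------------------------
# public containers and single-tissue API

@dataclass
class FisherBundle:
    """Complex-signal Jacobian and the noise level it is paired with."""

    jacobian: np.ndarray  # (n_measurements, n_params) complex
    sigma0: float
    param_order: tuple[str, ...]
    t_acq_ms: float
    tissue: TissueParams | None = None

    @property
    def fisher(self) -> np.ndarray:
        return fisher_matrix(self.jacobian, self.sigma0)


@dataclass
class EfficiencyResult:
    """Efficiencies (s**-1/2) and normalized parameter-to-noise ratios."""

    eta_t1: float
    eta_t2: float
    tnr_t1: float
    tnr_t2: float
    t_acq: float  # seconds
    tissue: TissueParams
    settings: list
    sigmas: dict = field(default_factory=dict)

    def eta(self, name: str) -> float:
        return {"t1": self.eta_t1, "t2": self.eta_t2}[name]


def jacobian(p: TissueParams, settings, params: Sequence[str] | None = None,
             sigma0: float = 1.0,
             rel_step: float = FD_REL_STEP,
             abs_floor: float = FD_ABS_FLOOR) -> FisherBundle:
    """Jacobian of the stacked signal of ``settings`` w.r.t. ``params``.

    ``settings`` may be a single :class:`SequenceSettings` or a list that is
    fitted jointly (measurements stacked, acquisition times summed).
    """
    if params is None:
        params = default_params(settings)
    flat, meta = fd_tissue_rows([p], params, rel_step, abs_floor)
    sig, t_acq = models.signals_batch(flat, settings)
    sig = sig.reshape(meta["P"], meta["R"], -1)
    J = assemble_jacobian(sig, meta)[0]
    return FisherBundle(J, sigma0, tuple(params), t_acq, tissue=p)


def crlb_std(fb: FisherBundle, param_name: str) -> float:
    """CRLB standard deviation of one parameter, all other parameters in
    ``param_order`` treated as jointly estimated nuisance parameters."""
    if param_name not in fb.param_order:
        raise KeyError(f"{param_name!r} not in {fb.param_order}")
    sig = crlb_sigmas(fb.jacobian[None], fb.sigma0)[0]
    return float(sig[fb.param_order.index(param_name)])


def _etas_from_sigmas(sigmas, thetas, m0, sigma0, t_acq_s):
    with np.errstate(divide="ignore"):
        tnr = np.where(np.isfinite(sigmas), thetas / sigmas, 0.0) * (sigma0 / m0)
    return tnr / np.sqrt(t_acq_s), tnr


def efficiency(p: TissueParams, settings,
               params: Sequence[str] | None = None,
               sigma0: float = 1.0,
               poi: Sequence[str] = ("t1", "t2")) -> EfficiencyResult:
    """CRLB efficiency of a sequence combination for one tissue.

    By construction the result is independent of ``sigma0`` and of ``M0``
    rescaling; ``t_acq`` is converted to seconds so eta is in s**-1/2.
    """
    if params is None:
        params = default_params(settings)
    fb = jacobian(p, settings, params, sigma0)
    sigmas = crlb_sigmas(fb.jacobian[None], sigma0)[0]
    t_acq_s = fb.t_acq_ms * 1e-3
    if t_acq_s <= 0:
        raise ValueError("t_acq must be positive")
    out = {}
    tnr_out = {}
    for name in poi:
        idx = list(params).index(name)
        theta = getattr(p, name)
        eta_v, tnr_v = _etas_from_sigmas(sigmas[idx], theta, p.m0, sigma0, t_acq_s)
        out[name] = float(eta_v)
        tnr_out[name] = float(tnr_v)
    sig_map = {q: float(sigmas[i]) for i, q in enumerate(params)}
    u_list = settings if isinstance(settings, list) else [settings]
    return EfficiencyResult(
        eta_t1=out.get("t1", 0.0), eta_t2=out.get("t2", 0.0),
        tnr_t1=tnr_out.get("t1", 0.0), tnr_t2=tnr_out.get("t2", 0.0),
        t_acq=t_acq_s, tissue=p, settings=list(u_list), sigmas=sig_map,
    )


def efficiency_batch(tissues: Sequence[TissueParams], settings,
                     params: Sequence[str] | None = None,
                     poi: Sequence[str] = ("t1", "t2"),
                     sigma0: float = 1.0,
                     warn: bool = True) -> np.ndarray:
    """Efficiencies for many tissues in one vectorized sweep.

    Returns an array of shape ``(n_tissues, len(poi))``.
    """
    if params is None:
        params = default_params(settings)
    flat, meta = fd_tissue_rows(tissues, params)
    sig, t_acq = models.signals_batch(flat, settings)
    sig = sig.reshape(meta["P"], meta["R"], -1)
    J = assemble_jacobian(sig, meta)
    sigmas = crlb_sigmas(J, sigma0, warn=warn)  # (P, n_params)
    t_acq_s = t_acq * 1e-3
    etas = np.empty((meta["P"], len(poi)))
    for k, name in enumerate(poi):
        idx = list(params).index(name)
        theta = meta["base"][name]
        etas[:, k], _ = _etas_from_sigmas(
            sigmas[:, idx], theta, meta["base"]["m0"], sigma0, t_acq_s
        )
    return etas
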