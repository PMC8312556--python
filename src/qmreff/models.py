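"""Forward signal models for steady-state and transient gradient-echo qMRI.

The module provides closed-form steady states (SPGR Ernst formula, balanced
SSFP via the per-TR fixed point), EPG steady-state echo pathways (DESS/TESS),
transient propagation for fingerprinting trains with gradient-spoiled (EPG)
or balanced (single-isochromat Bloch) readouts, and cyclic driven-equilibrium
fixed points.

Model conventions
-----------------
* SPGR is the ideally spoiled Ernst steady state.  Decay between excitation
  and echo is a T2* effect for spoiled readouts and is deliberately omitted,
  so the SPGR signal carries no T2 information (as in DESPOT1).
* All other models evaluate the transverse magnetization at the echo time,
  applying ``exp(-te/T2)`` decay and the off-resonance precession phase
  ``2*pi*omega0*te``.
* The receiver phase ``phi0`` multiplies every signal as ``exp(i*phi0)``.
* RF pulses are instantaneous rotations; the per-pulse rotation follows the
  EPG mixing-matrix convention (a 90 degree pulse with zero phase takes
  thermal equilibrium to ``F+_0 = -i*M0``).
* Balanced signals are demodulated by the phase of the exciting pulse
  (receiver phase tracks the RF phase cycle).

Every internal engine accepts 1-D tissue-parameter arrays and, for the
transient engines, per-batch flip/TR trains, so that finite-difference
Jacobians and design perturbations are evaluated in single vectorized
sweeps.
"""

from __future__ import annotations

import warnings

import numpy as np

from .epg import EPGState, apply_relaxation, apply_rf, apply_shift, top_order_energy
from .params import SequenceSettings, SignalRecord, TissueParams

__all__ = [
    "spgr_signal",
    "bssfp_signal",
    "steady_state_echoes",
    "epg_spoiled_transient",
    "bloch_balanced_transient",
    "driven_equilibrium_state",
    "simulate",
    "signals_batch",
    "tissue_arrays",
]

#: truncation-growth tolerance: highest-order EPG amplitude relative to m0
EPG_TRUNCATION_TOL = 1e-12
#: driven-equilibrium fixed-point residual tolerance relative to m0
DE_RESIDUAL_TOL = 1e-10
_K_START = 24
_K_MAX = 256
#: largest batched dense cycle-matrix size (elements of A) for the direct
#: driven-equilibrium solve; above this the extrapolated iteration is used
_DE_DIRECT_BUDGET = 400_000


# ----------------------------------------------------------------------
# tissue batching helpers

_TISSUE_FIELDS = ("t1", "t2", "m0", "phi0", "omega0")


def tissue_arrays(p: TissueParams | dict, n: int | None = None) -> dict:
    """Normalize a tissue description to a dict of equal-length 1-D arrays."""
    if isinstance(p, TissueParams):
        d = {f: np.atleast_1d(np.asarray(getattr(p, f), float)) for f in _TISSUE_FIELDS}
    else:
        d = {f: np.atleast_1d(np.asarray(p[f], float)) for f in _TISSUE_FIELDS}
    b = max(v.size for v in d.values()) if n is None else n
    return {f: (v if v.size == b else np.full(b, v[0])) for f, v in d.items()}


def _te_factor(t2, omega0, phi0, te) -> np.ndarray:
    return np.exp(-te / t2) * np.exp(1j * (2 * np.pi * omega0 * te * 1e-3 + phi0))


# ----------------------------------------------------------------------
# closed-form steady states

def _spgr_batch(tissue: dict, flips_deg, trs) -> np.ndarray:
    """Ernst steady state; no TE dependence (see module docstring).

    ``flips_deg``/``trs`` of shape ``(..., N)`` broadcast against the tissue
    arrays; output shape is the full broadcast ``(..., N)``.
    """
    t1 = tissue["t1"][..., None]
    a = np.radians(np.atleast_2d(np.asarray(flips_deg, float)))
    tr = np.atleast_2d(np.asarray(trs, float))
    e1 = np.exp(-tr / t1)
    s = np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))
    out = tissue["m0"][..., None] * s * np.exp(1j * tissue["phi0"][..., None])
    shape = np.broadcast_shapes(out.shape, a.shape, tr.shape)
    return np.broadcast_to(out, shape).astype(complex)


def _rot_x(alpha):
    """Per-pulse mixing of (Mx, My, Mz) for a zero-phase pulse, matching the
    EPG convention: My' = cos(a) My - sin(a) Mz, Mz' = sin(a) My + cos(a) Mz."""
    alpha = np.asarray(alpha, float)
    ca, sa = np.cos(alpha), np.sin(alpha)
    R = np.zeros(alpha.shape + (3, 3))
    R[..., 0, 0] = 1.0
    R[..., 1, 1] = ca
    R[..., 1, 2] = -sa
    R[..., 2, 1] = sa
    R[..., 2, 2] = ca
    return R


def _rot_z(psi):
    psi = np.asarray(psi, float)
    c, s = np.cos(psi), np.sin(psi)
    R = np.zeros(psi.shape + (3, 3))
    R[..., 0, 0] = c
    R[..., 0, 1] = -s
    R[..., 1, 0] = s
    R[..., 1, 1] = c
    R[..., 2, 2] = 1.0
    return R


def _bssfp_batch(tissue: dict, flips_deg, trs, te, phase_inc_deg) -> np.ndarray:
    """Balanced SSFP steady state at TE, demodulated by the RF phase cycle.

    Solves the per-TR affine fixed point ``m = E Rz(theta_e) Rx(alpha) m + b``
    in the frame rotating with the phase cycle, where
    ``theta_e = 2*pi*omega0*TR - dphi``.
    """
    t1 = tissue["t1"][..., None]
    t2 = tissue["t2"][..., None]
    m0 = tissue["m0"][..., None]
    om = tissue["omega0"][..., None]
    zeros = np.zeros(
        np.broadcast_shapes(t1.shape, np.atleast_2d(np.asarray(flips_deg)).shape,
                            np.atleast_2d(np.asarray(trs)).shape)
    )
    a = np.radians(np.atleast_2d(np.asarray(flips_deg, float))) + zeros
    tr = np.atleast_2d(np.asarray(trs, float)) + zeros
    dphi = np.radians(np.atleast_2d(np.asarray(phase_inc_deg, float))) + np.zeros_like(zeros)
    e1 = np.exp(-tr / t1)
    e2 = np.exp(-tr / t2)
    theta_e = 2 * np.pi * om * tr * 1e-3 - dphi

    rot = _rot_x(a)
    L = _rot_z(theta_e) @ rot
    E = np.zeros(L.shape)
    E[..., 0, 0] = e2
    E[..., 1, 1] = e2
    E[..., 2, 2] = e1
    L = E @ L
    rhs = np.zeros(L.shape[:-1])
    rhs[..., 2] = m0 * (1.0 - e1)
    m_pre = np.linalg.solve(np.eye(3) - L, rhs[..., None])[..., 0]
    v = (rot @ m_pre[..., None])[..., 0]
    u = v[..., 0] + 1j * v[..., 1]
    return u * _te_factor(t2, om, tissue["phi0"][..., None], te)


# ----------------------------------------------------------------------
# transient propagation: gradient-spoiled (EPG)

def _epg_run(tissue, flips_rad, trs, te, phases_rad, state: EPGState,
             record: bool = True, grow: bool = True):
    """Propagate one pass of the train; optionally record echoes.

    ``flips_rad``/``trs`` have shape ``(N,)`` or ``(B, N)``; tissue arrays
    broadcast against the state's batch shape.  Per pulse: RF rotation,
    readout of F_0 at TE, relaxation over the full TR, ideal crusher shift.
    """
    t1, t2, m0, om = tissue["t1"], tissue["t2"], tissue["m0"], tissue["omega0"]
    n = flips_rad.shape[-1]
    sig = None
    if record:
        sig = np.empty(state.batch_shape + (n,), complex)
        fac = _te_factor(t2, om, tissue["phi0"], te)
    m0max = float(np.max(m0))
    for i in range(n):
        apply_rf(state, flips_rad[..., i], phases_rad[..., i])
        if record:
            sig[..., i] = state.f_plus[..., 0] * fac
        apply_relaxation(state, trs[..., i], t1, t2, m0, om)
        apply_shift(state)
        if grow and top_order_energy(state) > EPG_TRUNCATION_TOL * max(m0max, 1e-30):
            k_new = min(int(state.max_order * 1.6) + 8, _K_MAX)
            if k_new > state.max_order:
                warnings.warn(f"EPG truncation order grown to {k_new}", stacklevel=2)
                g = state.grown(k_new)
                state.f_plus, state.f_minus, state.z = g.f_plus, g.f_minus, g.z
    return state, sig


def _epg_cycle_factory(tissue, flips_rad, trs, te, phases_rad, recovery_delay):
    def cycle(state: EPGState) -> EPGState:
        state, _ = _epg_run(tissue, flips_rad, trs, te, phases_rad, state,
                            record=False, grow=False)
        if recovery_delay > 0:
            apply_relaxation(state, recovery_delay, tissue["t1"], tissue["t2"],
                             tissue["m0"], tissue["omega0"])
        return state

    return cycle


def _epg_transient_batch(tissue: dict, flips_deg, trs, te, phases_deg=None,
                         driven_equilibrium: bool = False,
                         recovery_delay: float = 0.0,
                         initial: EPGState | None = None) -> np.ndarray:
    flips = np.radians(np.asarray(flips_deg, float))
    trs = np.asarray(trs, float) + np.zeros_like(flips)
    n = flips.shape[-1]
    batch = np.broadcast_shapes(flips.shape[:-1], tissue["t1"].shape)
    phases = (
        np.radians(np.asarray(phases_deg, float))
        if phases_deg is not None
        else np.zeros(n)
    )
    if initial is not None:
        k1 = initial.max_order + 1
        state = EPGState(
            np.broadcast_to(initial.f_plus, batch + (k1,)).copy(),
            np.broadcast_to(initial.f_minus, batch + (k1,)).copy(),
            np.broadcast_to(initial.z, batch + (k1,)).copy(),
        )
    elif driven_equilibrium:
        cycle = _epg_cycle_factory(tissue, flips, trs, te, phases, recovery_delay)
        state = _de_fixed_point(cycle, max(min(n + 1, 64), _K_START), batch,
                                float(tissue["m0"].max()))
    else:
        state = EPGState.thermal(tissue["m0"], max(min(n + 1, 64), 8), batch)
    _, sig = _epg_run(tissue, flips, trs, te, phases, state, record=True)
    return sig


# ----------------------------------------------------------------------
# transient propagation: balanced (single-isochromat Bloch, complex rep)

def _bloch_run(tissue, flips_rad, trs, te, phases_rad, recovery_delay,
               u, mz, record: bool):
    """Propagate the balanced train; ``u = Mx + i My`` and ``mz`` may carry
    any broadcast-compatible batch shape."""
    t1, t2, m0, om = tissue["t1"], tissue["t2"], tissue["m0"], tissue["omega0"]
    th = 2 * np.pi * om * 1e-3  # precession, rad per ms
    n = flips_rad.shape[-1]
    sig = None
    if record:
        sig = np.empty(u.shape + (n,), complex)
        e2te = np.exp(-te / t2) * np.exp(1j * (th * te + tissue["phi0"]))
    for i in range(n):
        al = flips_rad[..., i]
        eip = np.exp(1j * phases_rad[..., i])
        c2 = np.cos(al / 2.0) ** 2
        s2 = np.sin(al / 2.0) ** 2
        sa = np.sin(al)
        u_new = c2 * u + eip**2 * s2 * np.conj(u) - 1j * eip * sa * mz
        mz = sa * np.imag(u * np.conj(eip)) + np.cos(al) * mz
        u = u_new
        if record:
            sig[..., i] = np.conj(eip) * u * e2te
        tr_i = trs[..., i]
        e1 = np.exp(-tr_i / t1)
        u = u * np.exp(-tr_i / t2) * np.exp(1j * th * tr_i)
        mz = mz * e1 + m0 * (1.0 - e1)
    if recovery_delay > 0:
        e1 = np.exp(-recovery_delay / t1)
        u = u * np.exp(-recovery_delay / t2) * np.exp(1j * th * recovery_delay)
        mz = mz * e1 + m0 * (1.0 - e1)
    return u, mz, sig


def _de_balanced_fixed_point(tissue, flips_rad, trs, te, phases_rad,
                             recovery_delay, batch: tuple):
    """Direct affine solve of the 3-dimensional balanced cycle map."""
    u_off, mz_off, _ = _bloch_run(tissue, flips_rad, trs, te, phases_rad,
                                  recovery_delay, np.zeros(batch, complex),
                                  np.zeros(batch), record=False)
    basis = [(1.0 + 0j, 0.0), (1j, 0.0), (0j, 1.0)]
    tissue0 = dict(tissue, m0=np.zeros_like(tissue["m0"]))
    A = np.empty(batch + (3, 3))
    for j, (uu, zz) in enumerate(basis):
        u1, mz1, _ = _bloch_run(tissue0, flips_rad, trs, te, phases_rad,
                                recovery_delay, np.full(batch, uu, complex),
                                np.full(batch, zz, float), record=False)
        A[..., 0, j] = u1.real
        A[..., 1, j] = u1.imag
        A[..., 2, j] = mz1
    rhs = np.stack([u_off.real, u_off.imag, mz_off + np.zeros(batch)], axis=-1)
    m = np.linalg.solve(np.eye(3) - A, rhs[..., None])[..., 0]
    return m[..., 0] + 1j * m[..., 1], m[..., 2]


def _bloch_transient_batch(tissue: dict, flips_deg, trs, te, phases_deg=None,
                           driven_equilibrium: bool = False,
                           recovery_delay: float = 0.0,
                           initial: np.ndarray | None = None) -> np.ndarray:
    flips = np.radians(np.asarray(flips_deg, float))
    trs = np.asarray(trs, float) + np.zeros_like(flips)
    n = flips.shape[-1]
    batch = np.broadcast_shapes(flips.shape[:-1], tissue["t1"].shape)
    if phases_deg is None:
        phases_deg = np.where(np.arange(n) % 2 == 0, 0.0, 180.0)
    phases = np.radians(np.asarray(phases_deg, float))

    if initial is not None:
        init = np.asarray(initial, float)
        u0 = np.broadcast_to(init[..., 0] + 1j * init[..., 1], batch).astype(complex)
        mz0 = np.broadcast_to(init[..., 2], batch).astype(float)
    elif driven_equilibrium:
        u0, mz0 = _de_balanced_fixed_point(tissue, flips, trs, te, phases,
                                           recovery_delay, batch)
    else:
        u0 = np.zeros(batch, complex)
        mz0 = np.broadcast_to(tissue["m0"], batch).astype(float)
    _, _, sig = _bloch_run(tissue, flips, trs, te, phases, recovery_delay,
                           u0.copy(), mz0.copy(), record=True)
    return sig


# ----------------------------------------------------------------------
# driven-equilibrium fixed points (EPG)

def _de_direct_solve(cycle, k: int, batch_shape: tuple, m0max: float) -> EPGState:
    """Fixed point by direct linear solve of the affine cycle map.

    The cycle map is affine and real-linear (the crusher shift conjugates
    across k = 0), so the solve runs in real-stacked coordinates of
    dimension ``2 * 3 * (K+1)``.  Basis states are propagated with a leading
    basis axis so tissue arrays broadcast over the trailing batch axes.
    """
    d = 3 * (k + 1)
    bflat = int(np.prod(batch_shape)) if batch_shape else 1
    zero = EPGState.thermal(0.0, k, batch_shape)
    b_vec = cycle(zero).to_vector()  # batch + (d,)
    basis = np.zeros((2 * d,) + (1,) * len(batch_shape) + (d,), complex)
    idx = np.arange(d)
    basis[idx, ..., idx] = 1.0
    basis[d + idx, ..., idx] = 1j
    basis = np.broadcast_to(basis, (2 * d,) + batch_shape + (d,)).copy()
    out = cycle(EPGState.from_vector(basis)).to_vector() - b_vec[None]
    # out: (2d,) + batch + (d,)  ->  A: batch + (2d, 2d)
    out = np.moveaxis(out, 0, -1)  # batch + (d, 2d)
    A = np.concatenate([out.real, out.imag], axis=-2)
    rhs = np.concatenate([b_vec.real, b_vec.imag], axis=-1)
    eye = np.eye(2 * d)
    try:
        x = np.linalg.solve(eye - A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        warnings.warn("singular driven-equilibrium cycle map; using least squares")
        Af = A.reshape(bflat, 2 * d, 2 * d)
        rf = rhs.reshape(bflat, 2 * d)
        x = np.stack(
            [np.linalg.lstsq(eye - Af[i], rf[i], rcond=None)[0] for i in range(bflat)]
        ).reshape(batch_shape + (2 * d,))
    return EPGState.from_vector(x[..., :d] + 1j * x[..., d:])


def _de_iterative_solve(cycle, k: int, batch_shape: tuple, m0max: float,
                        tol: float, max_cycles: int = 500) -> EPGState:
    """Fixed point by extrapolated fixed-point iteration.

    Successive substitution with Aitken extrapolation of the dominant decay
    mode; used for batched evaluation where the dense cycle matrix of the
    direct solve would be too large.
    """
    x = EPGState.thermal(m0max, k, batch_shape).to_vector()
    d_prev = None
    scale = max(m0max, 1e-30)
    err = np.inf
    for _ in range(max_cycles):
        x1 = cycle(EPGState.from_vector(x.copy())).to_vector()
        delta = x1 - x
        err = float(np.abs(delta).max())
        if err <= tol * scale:
            return EPGState.from_vector(x1)
        if d_prev is not None:
            num = np.sum((delta * np.conj(d_prev)).real, axis=-1)
            den = np.sum((d_prev * np.conj(d_prev)).real, axis=-1)
            rho = np.clip(num / np.maximum(den, 1e-300), -0.995, 0.995)
            x1 = x1 + (rho / (1.0 - rho))[..., None] * delta
            d_prev = None
        else:
            d_prev = delta
        x = x1
    warnings.warn(
        f"driven-equilibrium iteration stopped at residual {err:.2e} "
        f"(tolerance {tol * scale:.2e})"
    )
    return EPGState.from_vector(x)


def _de_fixed_point(cycle, k0: int, batch_shape: tuple, m0max: float,
                    direct_budget: int = _DE_DIRECT_BUDGET,
                    k_max: int = _K_MAX) -> EPGState:
    b = int(np.prod(batch_shape)) if batch_shape else 1
    k = k0
    while True:
        if b * (2 * 3 * (k + 1)) ** 2 <= direct_budget:
            state = _de_direct_solve(cycle, k, batch_shape, m0max)
        else:
            state = _de_iterative_solve(cycle, k, batch_shape, m0max,
                                        DE_RESIDUAL_TOL)
        top = top_order_energy(state)
        if top <= EPG_TRUNCATION_TOL * max(m0max, 1e-30):
            return state
        if k >= k_max:
            # short-TR constant-flip trains carry configuration tails over
            # ~T2/TR orders; beyond the cap the discarded amplitude only
            # matters if it is non-negligible against M0
            if top > 1e-6 * max(m0max, 1e-30):
                warnings.warn(
                    f"EPG truncation order capped at {k_max} with top-order "
                    f"amplitude {top:.2e}"
                )
            return state
        k = min(int(k * 1.6) + 8, k_max)


# ----------------------------------------------------------------------
# gradient-spoiled steady-state echoes (DESS / TESS)

def _sss_echoes_batch(tissue: dict, flip_deg, tr, te, n_echoes: int) -> np.ndarray:
    """First ``n_echoes`` pathway amplitudes at TE, shape ``(B, n_echoes)``.

    Echo convention (see methods note): echoes are the post-RF configuration
    amplitudes F_0, F_-1 and (for TESS) F_+1, each read at TE with
    ``exp(-te/T2)`` decay and the off-resonance phase.
    """
    b = tissue["t1"].size
    alpha = np.radians(np.full(1, float(np.atleast_1d(flip_deg)[0])))
    trs = np.full(1, float(np.atleast_1d(tr)[0]))
    cycle = _epg_cycle_factory(tissue, alpha, trs, te, np.zeros(1), 0.0)
    state = _de_fixed_point(cycle, 40, (b,), float(tissue["m0"].max()),
                            direct_budget=8_000_000, k_max=128)
    apply_rf(state, alpha[0], 0.0)
    fac = _te_factor(tissue["t2"], tissue["omega0"], tissue["phi0"], te)
    paths = [state.f_plus[..., 0], np.conj(state.f_minus[..., 1]), state.f_plus[..., 1]]
    return np.stack([p * fac for p in paths[:n_echoes]], axis=-1)


def transient_signals(tissue: dict, method: str, flips_deg, trs, te,
                      phases_deg=None, driven_equilibrium: bool = False,
                      recovery_delay: float = 0.0) -> np.ndarray:
    """Transient-train signals with arbitrary broadcastable batching.

    ``flips_deg``/``trs`` may carry leading batch axes (e.g. design
    perturbations) that broadcast against the tissue arrays; the returned
    signal has shape ``broadcast(batch, tissue) + (N,)``.
    """
    fn = _epg_transient_batch if method == "MRF_spoiled" else _bloch_transient_batch
    return fn(tissue, flips_deg=flips_deg, trs=trs, te=te,
              phases_deg=phases_deg, driven_equilibrium=driven_equilibrium,
              recovery_delay=recovery_delay)


# ----------------------------------------------------------------------
# dispatch

def signals_batch(tissue: dict | TissueParams, settings) -> tuple[np.ndarray, float]:
    """Evaluate a sequence (or list of jointly fitted sequences) for a batch
    of tissue-parameter vectors.

    Returns ``(signals, t_acq_ms)`` with ``signals`` of shape
    ``(B, n_measurements)``; measurements of listed sequences are stacked in
    order and their acquisition times summed.
    """
    if isinstance(settings, SequenceSettings):
        settings = [settings]
    tissue = tissue_arrays(tissue)
    parts = []
    t_acq = 0.0
    for u in settings:
        m = u.method
        if m == "SPGR":
            parts.append(_spgr_batch(tissue, u.flips, u.trs))
        elif m == "bSSFP":
            parts.append(_bssfp_batch(tissue, u.flips, u.trs, u.te, u.phase_train()))
        elif m in ("DESS", "TESS"):
            parts.append(
                _sss_echoes_batch(tissue, u.flips[0], u.trs[0], u.te,
                                  2 if m == "DESS" else 3)
            )
        elif m == "MRF_spoiled":
            parts.append(
                _epg_transient_batch(
                    tissue, u.flips, u.trs, u.te, u.rf_phases,
                    driven_equilibrium=u.driven_equilibrium,
                    recovery_delay=u.recovery_delay,
                )
            )
        elif m == "MRF_balanced":
            parts.append(
                _bloch_transient_batch(
                    tissue, u.flips, u.trs, u.te, u.rf_phases,
                    driven_equilibrium=u.driven_equilibrium,
                    recovery_delay=u.recovery_delay,
                )
            )
        else:  # pragma: no cover
            raise ValueError(f"unknown method {m!r}")
        t_acq += u.t_acq
    return np.concatenate(parts, axis=1), t_acq


# ----------------------------------------------------------------------
# public single-voxel operations

def spgr_signal(p: TissueParams, flip: float, tr: float, te: float = 0.0) -> complex:
    """Ideally spoiled gradient-echo (Ernst) steady-state signal.

    ``te`` is accepted for interface uniformity but does not enter the
    model: echo-time decay of an ideally spoiled readout is a T2* effect,
    which is outside the single-pool Bloch model used here.
    """
    if not 0.0 <= flip <= 180.0:
        raise ValueError("flip must lie in [0, 180] degrees")
    if tr <= 0:
        raise ValueError("tr must be positive")
    return complex(_spgr_batch(tissue_arrays(p), [flip], [tr])[0, 0])


def bssfp_signal(p: TissueParams, flip: float, tr: float, te: float,
                 rf_phase_increment: float = 180.0) -> complex:
    """Balanced SSFP steady-state signal at TE including off-resonance.

    ``rf_phase_increment`` (degrees) is the per-TR RF phase-cycling
    increment; 180 degrees is the standard alternating excitation.
    """
    if te > tr:
        raise ValueError("te must not exceed tr")
    if not 0.0 <= flip <= 180.0:
        raise ValueError("flip must lie in [0, 180] degrees")
    return complex(
        _bssfp_batch(tissue_arrays(p), [flip], [tr], te, [rf_phase_increment])[0, 0]
    )


def steady_state_echoes(p: TissueParams, flip: float, tr: float, te: float,
                        n_echoes: int) -> np.ndarray:
    """Gradient-spoiled steady-state echo pathway amplitudes (DESS/TESS).

    Returns the first ``n_echoes`` of (F_0, F_-1, F_+1) read at TE, computed
    from the fixed point of the per-TR EPG operator.
    """
    if n_echoes not in (2, 3):
        raise ValueError("n_echoes must be 2 (DESS) or 3 (TESS)")
    return _sss_echoes_batch(tissue_arrays(p), flip, tr, te, n_echoes)[0]


def _record(u: SequenceSettings, sig: np.ndarray) -> SignalRecord:
    if u.method in ("DESS", "TESS"):
        times = np.full(sig.size, u.te)
    else:
        starts = np.cumsum(u.trs) - u.trs
        times = starts + u.te
    return SignalRecord(sig, times, u.t_acq)


def epg_spoiled_transient(p: TissueParams, u: SequenceSettings,
                          initial: EPGState | None = None) -> SignalRecord:
    """Gradient-spoiled fingerprinting train via EPG propagation.

    Per pulse: RF rotation, readout of the F_0 state at TE, relaxation over
    the TR, ideal crusher shift.  The initial state defaults to thermal
    equilibrium, or to the cyclic driven-equilibrium fixed point when
    ``u.driven_equilibrium`` is set.
    """
    if u.method != "MRF_spoiled":
        raise ValueError("epg_spoiled_transient expects method='MRF_spoiled'")
    sig = _epg_transient_batch(
        tissue_arrays(p), u.flips, u.trs, u.te, u.rf_phases,
        driven_equilibrium=u.driven_equilibrium,
        recovery_delay=u.recovery_delay, initial=initial,
    )[0]
    return _record(u, sig)


def bloch_balanced_transient(p: TissueParams, u: SequenceSettings,
                             initial: np.ndarray | None = None) -> SignalRecord:
    """Balanced fingerprinting train via single-isochromat Bloch recursion."""
    if u.method != "MRF_balanced":
        raise ValueError("bloch_balanced_transient expects method='MRF_balanced'")
    sig = _bloch_transient_batch(
        tissue_arrays(p), u.flips, u.trs, u.te, u.rf_phases,
        driven_equilibrium=u.driven_equilibrium,
        recovery_delay=u.recovery_delay, initial=initial,
    )[0]
    return _record(u, sig)


def driven_equilibrium_state(p: TissueParams, u: SequenceSettings):
    """Periodic fixed point m* of one full-train propagation.

    Returns an :class:`~qmreff.epg.EPGState` for gradient-spoiled trains or a
    magnetization vector ``[Mx, My, Mz]`` for balanced trains, satisfying
    ``|A(m*) - m*| <= 1e-10 * M0``.  Obtained by direct linear solve of the
    affine cycle map, with extrapolated power iteration as the fallback for
    large truncation orders or a singular cycle map.
    """
    tissue = tissue_arrays(p)
    flips = np.radians(np.asarray(u.flips, float))
    trs = np.asarray(u.trs, float)
    n = flips.size
    if u.method == "MRF_spoiled":
        phases = (
            np.radians(np.asarray(u.rf_phases, float))
            if u.rf_phases is not None
            else np.zeros(n)
        )
        cycle = _epg_cycle_factory(tissue, flips, trs, u.te, phases,
                                   u.recovery_delay)
        state = _de_fixed_point(cycle, max(min(n + 1, 64), _K_START), (1,),
                                float(tissue["m0"][0]))
        return EPGState(state.f_plus[0], state.f_minus[0], state.z[0])
    if u.method == "MRF_balanced":
        phases = np.radians(u.phase_train())
        u0, mz0 = _de_balanced_fixed_point(tissue, flips, trs, u.te, phases,
                                           u.recovery_delay, (1,))
        return np.array([u0[0].real, u0[0].imag, mz0[0]])
    raise ValueError("driven_equilibrium_state expects a transient method")


def simulate(p: TissueParams, u: SequenceSettings) -> SignalRecord:
    """Evaluate any catalogued method for one tissue-parameter vector."""
    sig, _ = signals_batch(p, u)
    return _record(u, sig[0])
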