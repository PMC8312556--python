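"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's EPG/linear-solve machinery: rotations
come from scipy's Rotation class, magnetization is propagated per isochromat
as explicit 3-vectors, and configuration-state amplitudes are extracted by a
discrete Fourier transform over the isochromat dephasing phases.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def _rf_matrix(alpha_deg: float, phase_deg: float = 0.0) -> np.ndarray:
    """Rotation by ``alpha`` about the transverse axis at azimuth ``phase``
    (right-handed; matches the convention that a zero-phase pulse maps
    My -> cos(a) My - sin(a) Mz)."""
    a = np.radians(alpha_deg)
    ph = np.radians(phase_deg)
    axis = np.array([np.cos(ph), np.sin(ph), 0.0])
    return Rotation.from_rotvec(a * axis).as_matrix()


def _relax(m, dt, p, precess_rad=0.0):
    e1, e2 = np.exp(-dt / p.t1), np.exp(-dt / p.t2)
    rz = Rotation.from_rotvec([0, 0, precess_rad]).as_matrix()
    m = m @ rz.T
    out = np.empty_like(m)
    out[..., 0] = m[..., 0] * e2
    out[..., 1] = m[..., 1] * e2
    out[..., 2] = m[..., 2] * e1 + p.m0 * (1 - e1)
    return out


def spoiled_transient_isochromats(p, flips_deg, trs, te, n_iso=10000):
    """Transient gradient-spoiled train: ensemble of isochromats that each
    pick up a fixed crusher phase per TR; returns the mean transverse signal
    at TE after every pulse (phi0 applied)."""
    psi = 2 * np.pi * np.arange(n_iso) / n_iso
    m = np.zeros((n_iso, 3))
    m[:, 2] = p.m0
    crush = np.stack(
        [Rotation.from_rotvec([0, 0, ps]).as_matrix() for ps in psi]
    )
    sig = []
    for a, tr in zip(np.atleast_1d(flips_deg), np.atleast_1d(trs)):
        m = m @ _rf_matrix(a).T
        s = np.mean(m[:, 0] + 1j * m[:, 1]) * np.exp(-te / p.t2)
        sig.append(s * np.exp(1j * (p.phi0 + 2 * np.pi * p.omega0 * te * 1e-3)))
        m = _relax(m, tr, p, precess_rad=2 * np.pi * p.omega0 * tr * 1e-3)
        m = np.einsum("nij,nj->ni", crush, m)
    return np.array(sig)


def sss_pathways_isochromats(p, flip_deg, tr, te, orders=(0, -1, 1),
                             n_iso=10000):
    """Steady-state echo pathway amplitudes of the constant-flip spoiled
    sequence: per-isochromat steady state solved exactly (3x3 affine fixed
    point), post-RF, pathways extracted by DFT over the crusher phase."""
    psi = 2 * np.pi * np.arange(n_iso) / n_iso
    R = _rf_matrix(flip_deg)
    e1, e2 = np.exp(-tr / p.t1), np.exp(-tr / p.t2)
    E = np.diag([e2, e2, e1])
    b = np.array([0.0, 0.0, p.m0 * (1 - e1)])
    total = psi + 2 * np.pi * p.omega0 * tr * 1e-3
    rz = np.stack([Rotation.from_rotvec([0, 0, t]).as_matrix() for t in total])
    L = np.einsum("ij,njk,kl->nil", E, rz, R)
    m_pre = np.linalg.solve(np.eye(3) - L, np.broadcast_to(b, (n_iso, 3))[..., None])[
        ..., 0
    ]
    m_post = m_pre @ R.T
    mp = m_post[:, 0] + 1j * m_post[:, 1]
    fac = np.exp(-te / p.t2) * np.exp(
        1j * (p.phi0 + 2 * np.pi * p.omega0 * te * 1e-3)
    )
    return np.array([np.mean(mp * np.exp(-1j * k * psi)) for k in orders]) * fac


def ideally_spoiled_spgr(p, flip_deg, tr, n_tr=5000):
    """Long-run Bloch propagation with the transverse magnetization
    destroyed before every pulse (ideal spoiling)."""
    a = np.radians(flip_deg)
    mz = p.m0
    e1 = np.exp(-tr / p.t1)
    s = 0.0
    for _ in range(n_tr):
        s = mz * np.sin(a)
        mz = mz * np.cos(a) * e1 + p.m0 * (1 - e1)
    return s * np.exp(1j * p.phi0)


def bssfp_lab_frame(p, flip_deg, tr, te, dphi_deg=180.0, n_tr=None):
    """Balanced steady state by lab-frame iteration with explicit per-pulse
    RF phase; signal demodulated by the phase of the final pulse."""
    if n_tr is None:
        n_tr = int(40 * p.t1 / tr) * 2  # even count: settle on one phase parity
    m = np.array([0.0, 0.0, p.m0])
    th_tr = 2 * np.pi * p.omega0 * tr * 1e-3
    phase = 0.0
    for i in range(n_tr):
        m = m @ _rf_matrix(flip_deg, np.degrees(phase)).T
        if i == n_tr - 1:
            mte = _relax(m, te, p, precess_rad=2 * np.pi * p.omega0 * te * 1e-3)
            s = (mte[0] + 1j * mte[1]) * np.exp(1j * p.phi0) * np.exp(-1j * phase)
            return s
        m = _relax(m, tr, p, precess_rad=th_tr)
        phase += np.radians(dphi_deg)


def gauss_newton_fit(model_fn, theta0: np.ndarray, data: np.ndarray,
                     n_iter: int = 25, damping: float = 1e-10) -> np.ndarray:
    """Vectorized per-draw nonlinear least squares on complex data.

    ``model_fn(theta (D, P)) -> (D, N) complex``; all D draws are iterated
    simultaneously with forward-difference Jacobians and Levenberg damping.
    Used as the maximum-likelihood estimator oracle for Cramér-Rao
    attainability checks (initialized at truth; the check concerns the
    variance of the local least-squares solution).
    """
    theta = theta0.astype(float).copy()
    D, P = theta.shape
    for _ in range(n_iter):
        base = model_fn(theta)
        J = np.empty(base.shape + (P,), complex)
        for j in range(P):
            tp = theta.copy()
            h = np.maximum(1e-6 * np.abs(theta[:, j]), 1e-9)
            tp[:, j] += h
            J[..., j] = (model_fn(tp) - base) / h[:, None]
        r = data - base
        A = np.einsum("dni,dnj->dij", J.conj(), J).real
        g = np.einsum("dni,dn->di", J.conj(), r).real
        A[:, np.arange(P), np.arange(P)] *= 1.0 + damping
        A[:, np.arange(P), np.arange(P)] += damping
        theta = theta + np.linalg.solve(A, g[..., None])[..., 0]
    return theta
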