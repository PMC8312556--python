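"""Extended phase graph (EPG) configuration-state engine.

The magnetization of a voxel subjected to ideal crusher gradients is tracked
in the configuration-state basis: complex amplitudes ``F+_k``, ``F-_k`` and
``Z_k`` indexed by dephasing order ``k >= 0``, with the usual storage
convention ``F-_k = conj(F(-k))`` so that ``F-_0 = conj(F+_0)``.

All operators support an arbitrary leading batch shape: the state arrays have
shape ``batch + (K+1,)`` and tissue parameters broadcast against ``batch``.
This is what makes finite-difference Jacobians and multi-start optimization
cheap -- every perturbed tissue/design point rides along in the same arrays.

Operators mutate the state in place and also return it, so they can be
chained.  The RF operator is complex-linear in the state; the gradient shift
is only real-linear (it conjugates the amplitude crossing k = 0), which is
why the driven-equilibrium solver in :mod:`qmreff.models` works with
real-stacked coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPGState",
    "rf_matrix",
    "apply_rf",
    "apply_relaxation",
    "apply_shift",
    "top_order_energy",
]


@dataclass
class EPGState:
    """EPG state amplitudes over dephasing orders ``0..max_order``."""

    f_plus: np.ndarray
    f_minus: np.ndarray
    z: np.ndarray

    @property
    def max_order(self) -> int:
        return self.f_plus.shape[-1] - 1

    @property
    def batch_shape(self) -> tuple:
        return self.f_plus.shape[:-1]

    @classmethod
    def thermal(cls, m0=1.0, max_order: int = 32, batch_shape: tuple = ()) -> "EPGState":
        """Thermal equilibrium: all states zero except ``Z_0 = m0``."""
        shape = tuple(batch_shape) + (max_order + 1,)
        fp = np.zeros(shape, dtype=complex)
        fm = np.zeros(shape, dtype=complex)
        z = np.zeros(shape, dtype=complex)
        z[..., 0] = m0
        return cls(fp, fm, z)

    def copy(self) -> "EPGState":
        return EPGState(self.f_plus.copy(), self.f_minus.copy(), self.z.copy())

    def grown(self, max_order: int) -> "EPGState":
        """Return a copy truncated/padded to a new maximum order."""
        k_old = self.max_order
        if max_order == k_old:
            return self.copy()
        shape = self.batch_shape + (max_order + 1,)
        out = EPGState(
            np.zeros(shape, dtype=complex),
            np.zeros(shape, dtype=complex),
            np.zeros(shape, dtype=complex),
        )
        n = min(max_order, k_old) + 1
        out.f_plus[..., :n] = self.f_plus[..., :n]
        out.f_minus[..., :n] = self.f_minus[..., :n]
        out.z[..., :n] = self.z[..., :n]
        return out

    def to_vector(self) -> np.ndarray:
        """Flatten to shape ``batch + (3*(K+1),)`` complex."""
        return np.concatenate([self.f_plus, self.f_minus, self.z], axis=-1)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "EPGState":
        n = vec.shape[-1] // 3
        return cls(
            np.ascontiguousarray(vec[..., :n]),
            np.ascontiguousarray(vec[..., n : 2 * n]),
            np.ascontiguousarray(vec[..., 2 * n :]),
        )


def rf_matrix(alpha, phase=0.0) -> np.ndarray:
    """Mixing matrix of an instantaneous RF rotation.

    ``alpha`` (rad) is the flip angle, ``phase`` (rad) the azimuth of the
    rotation axis in the transverse plane.  Broadcasts to shape
    ``batch + (3, 3)`` acting on stacked ``(F+, F-, Z)_k`` per order k.
    """
    alpha = np.asarray(alpha, dtype=float)
    phase = np.asarray(phase, dtype=float)
    c2 = np.cos(alpha / 2.0) ** 2
    s2 = np.sin(alpha / 2.0) ** 2
    sa = np.sin(alpha)
    eip = np.exp(1j * phase)
    batch = np.broadcast(alpha, phase).shape
    T = np.empty(batch + (3, 3), dtype=complex)
    T[..., 0, 0] = c2
    T[..., 0, 1] = eip**2 * s2
    T[..., 0, 2] = -1j * eip * sa
    T[..., 1, 0] = np.conj(eip) ** 2 * s2
    T[..., 1, 1] = c2
    T[..., 1, 2] = 1j * np.conj(eip) * sa
    T[..., 2, 0] = -0.5j * np.conj(eip) * sa
    T[..., 2, 1] = 0.5j * eip * sa
    T[..., 2, 2] = np.cos(alpha)
    return T


def apply_rf(state: EPGState, alpha, phase=0.0) -> EPGState:
    """Apply an instantaneous RF rotation (angles in radians)."""
    alpha = np.asarray(alpha, dtype=float)[..., None]
    phase = np.asarray(phase, dtype=float)[..., None]
    c2 = np.cos(alpha / 2.0) ** 2
    s2 = np.sin(alpha / 2.0) ** 2
    sa = np.sin(alpha)
    ca = np.cos(alpha)
    eip = np.exp(1j * phase)
    eim = np.conj(eip)
    fp, fm, z = state.f_plus, state.f_minus, state.z
    state.f_plus = c2 * fp + (eip * eip * s2) * fm + (-1j * eip * sa) * z
    state.f_minus = (eim * eim * s2) * fp + c2 * fm + (1j * eim * sa) * z
    state.z = (-0.5j * eim * sa) * fp + (0.5j * eip * sa) * fm + ca * z
    return state


def apply_relaxation(state: EPGState, dt, t1, t2, m0, omega0=0.0) -> EPGState:
    """Free evolution over ``dt`` ms: relaxation, recovery and precession.

    Tissue arrays broadcast against the state's batch shape.  Off-resonance
    ``omega0`` (Hz) adds coherent phase to all transverse orders.
    """
    dt = np.asarray(dt, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    e1 = np.exp(-dt / t1)
    e2 = np.exp(-dt / t2)
    decay = e2 * np.exp(2j * np.pi * np.asarray(omega0, float) * dt * 1e-3)
    state.f_plus *= decay[..., None]
    state.f_minus *= np.conj(decay)[..., None]
    state.z *= e1[..., None]
    state.z[..., 0] += m0 * (1.0 - e1)
    return state


def apply_shift(state: EPGState) -> EPGState:
    """Ideal unit crusher gradient: shift all dephasing orders by +1."""
    fp, fm = state.f_plus, state.f_minus
    new_fp = np.empty_like(fp)
    new_fp[..., 1:] = fp[..., :-1]
    new_fp[..., 0] = np.conj(fm[..., 1]) if fp.shape[-1] > 1 else 0.0
    new_fm = np.empty_like(fm)
    new_fm[..., :-1] = fm[..., 1:]
    new_fm[..., -1] = 0.0
    new_fm[..., 0] = np.conj(new_fp[..., 0])
    state.f_plus = new_fp
    state.f_minus = new_fm
    return state


def top_order_energy(state: EPGState) -> float:
    """Largest amplitude sitting in the highest tracked order (truncation
    diagnostic: should stay below ~1e-12 * m0)."""
    return float(
        max(
            np.abs(state.f_plus[..., -1]).max(initial=0.0),
            np.abs(state.f_minus[..., -1]).max(initial=0.0),
            np.abs(state.z[..., -1]).max(initial=0.0),
        )
    )
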