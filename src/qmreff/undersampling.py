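"""Efficiency loss under k-space undersampling: the dynamics factor d_R.

A zero-filled reconstruction treats the aliasing produced by undersampling
as additional noise.  Modelling that aliasing as independent Gaussian noise
of standard deviation ``sigma_alias``, the image-domain standard deviation
of an R-fold undersampled experiment is

    sigma_image_R = sqrt(sigma_alias**2 + R * sigma_image**2),

and the resulting error amplification of a least-squares parameter fit is
the dynamics factor

    d_R ~= (1/sqrt(R)) * sigma_image_R / sigma_image
        =  sqrt((1/R) * (SNR_image / SaR_image)**2 + 1),

where ``SNR_image`` is the fully-encoded image SNR and ``SaR_image`` the
signal-to-aliasing ratio of a noiseless undersampled reconstruction.  The
undersampled efficiency is ``eta_R = eta / d_R``.  Empirically the
aliasing-to-signal ratio grows as ``k * sqrt(R - 1)``, which gives the
closed-form model ``d_R ~= sqrt(k**2 (R-1)/R * SNR_image**2 + 1)``.

Conventions (documented design choices):

* ``zero_filled_recon`` scales by the inverse sampled fraction so a fully
  sampled mask reproduces the input exactly; this density compensation is
  what makes the thermal-noise term scale as ``R * sigma_image**2``.
* Random masks are redrawn for every Monte-Carlo trial (aliasing behaves as
  pseudo-noise along an MRF timecourse); spiral masks are re-rotated by a
  fresh random angle per trial.  A fixed-mask mode is provided for ablation.
* ``SNR_image`` is (mean phantom intensity over its nonzero support) /
  (per-quadrature image-domain noise std of the fully sampled
  reconstruction).
* Per-pixel standard deviations are per-quadrature equivalents,
  ``sqrt((var_re + var_im)/2)``, so the fully sampled case gives d_R = 1
  identically.
* The spiral is an Archimedean trajectory rasterized to the nearest
  Cartesian grid points (no gridding/NUFFT); its arm spacing is scaled so
  the sampled fraction is close to 1/R.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "shepp_logan",
    "SamplingMask",
    "make_mask",
    "zero_filled_recon",
    "monte_carlo_dr",
    "DynamicsFactorResult",
    "fit_aliasing_scaling",
    "dr_model",
    "eta_undersampled",
]

# Modified Shepp-Logan ellipse table: intensity, a, b, x0, y0, angle(deg).
# Axes and centres are in units of the half-width of the image.
_SHEPP_LOGAN = [
    (1.00, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-0.80, 0.6624, 0.874, 0.0, -0.0184, 0.0),
    (-0.20, 0.11, 0.31, 0.22, 0.0, -18.0),
    (-0.20, 0.16, 0.41, -0.22, 0.0, 18.0),
    (0.10, 0.21, 0.25, 0.0, 0.35, 0.0),
    (0.10, 0.046, 0.046, 0.0, 0.1, 0.0),
    (0.10, 0.046, 0.046, 0.0, -0.1, 0.0),
    (0.10, 0.046, 0.023, -0.08, -0.605, 0.0),
    (0.10, 0.023, 0.023, 0.0, -0.606, 0.0),
    (0.10, 0.023, 0.046, 0.06, -0.605, 0.0),
]


def shepp_logan(n: int) -> np.ndarray:
    """Standard 10-ellipse (modified) Shepp-Logan phantom on an n x n grid.

    Intensities are clipped to [0, 1]; the skull ellipse has intensity 1 and
    the background is 0.
    """
    if n < 32:
        raise ValueError("grid size must be at least 32")
    axis = (np.arange(n) - (n - 1) / 2.0) / (n / 2.0)
    x, y = np.meshgrid(axis, -axis)  # row 0 = top of the head
    img = np.zeros((n, n))
    for val, a, b, x0, y0, ang in _SHEPP_LOGAN:
        th = np.radians(ang)
        xr = (x - x0) * np.cos(th) + (y - y0) * np.sin(th)
        yr = -(x - x0) * np.sin(th) + (y - y0) * np.cos(th)
        img[(xr / a) ** 2 + (yr / b) ** 2 <= 1.0] += val
    return np.clip(img, 0.0, 1.0)


@dataclass
class SamplingMask:
    """Binary Cartesian k-space sampling pattern.

    ``weights`` are density-compensation factors: the inverse sampling rate
    of the density region each point belongs to (1 for the always-sampled
    centre block of random masks), zero at unsampled points.  They make the
    zero-filled reconstruction unbiased over mask draws and reduce to the
    global ``N / n_sampled`` scale for uniform sampling.
    """

    kind: str
    shape: tuple
    R: float
    mask: np.ndarray
    seed: int | None = None
    weights: np.ndarray | None = None

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())

    def dcf(self) -> np.ndarray:
        if self.weights is not None:
            return self.weights
        return self.mask * (self.mask.size / self.mask.sum())


def _random_mask(shape, R, rng):
    n_total = int(np.prod(shape))
    n_samp = int(round(n_total / R))
    if n_samp < 16:
        raise ValueError(f"R={R} leaves fewer than 16 sampled points")
    mask = np.zeros(n_total, bool)
    # fully sampled 4x4 centre block (k-space origin at the array centre)
    cy, cx = shape[0] // 2, shape[1] // 2
    centre = np.zeros(shape, bool)
    centre[cy - 2 : cy + 2, cx - 2 : cx + 2] = True
    centre_idx = np.flatnonzero(centre.ravel())
    mask[centre_idx] = True
    remaining = max(n_samp - centre_idx.size, 0)
    pool = np.flatnonzero(~mask)
    mask[rng.choice(pool, size=remaining, replace=False)] = True
    mask = mask.reshape(shape)
    # density compensation: centre sampled at rate 1, remainder at
    # remaining/(N-16)
    w = np.zeros(shape)
    rate = remaining / max(n_total - centre_idx.size, 1)
    w[mask] = 1.0 / rate
    w[centre] = 1.0
    return mask, w


_SPIRAL_CACHE: dict = {}


def _spiral_track(shape, g_out: float) -> tuple:
    """Variable-density Archimedean-like track in polar coordinates.

    The radial gap between successive turns grows linearly from 1 grid unit
    at the centre to ``g_out`` at the edge (the dense core emulates the
    variable-density spirals used for transient imaging); points are placed
    at roughly unit arc spacing.
    """
    r_max = float(np.hypot(*shape)) / 2.0
    pts_r, pts_phi = [], []
    r, phi = 0.0, 0.0
    ds = 0.7
    while r <= r_max:
        pts_r.append(r)
        pts_phi.append(phi)
        gap = 1.0 + (g_out - 1.0) * (r / r_max)
        dphi = ds / max(r, 0.5)
        phi += dphi
        r += gap * dphi / (2 * np.pi)
    return np.array(pts_r), np.array(pts_phi)


def _rasterize_polar(shape, r, phi, rot: float):
    ny, nx = shape
    ky = np.rint(r * np.sin(phi + rot) + ny // 2).astype(int)
    kx = np.rint(r * np.cos(phi + rot) + nx // 2).astype(int)
    keep = (ky >= 0) & (ky < ny) & (kx >= 0) & (kx < nx)
    mask = np.zeros(shape, bool)
    mask[ky[keep], kx[keep]] = True
    return mask


def _radial_dcf(mask: np.ndarray, bin_width: float = 2.0) -> np.ndarray:
    """Empirical density compensation: inverse sampled fraction per radial
    annulus, assigned to the sampled points of that annulus."""
    ny, nx = mask.shape
    yy, xx = np.meshgrid(np.arange(ny) - ny // 2, np.arange(nx) - nx // 2,
                         indexing="ij")
    rr = np.hypot(yy, xx)
    bins = (rr / bin_width).astype(int)
    w = np.zeros(mask.shape)
    for b in range(bins.max() + 1):
        sel = bins == b
        n_samp = mask[sel].sum()
        if n_samp:
            w[sel & mask] = sel.sum() / n_samp
    return w


def _spiral_mask(shape, R, rng):
    """Variable-density spiral rasterized to the nearest grid points.

    The outer arm spacing is calibrated (and cached per shape/R) so that the
    sampled fraction is close to 1/R; each draw rotates the trajectory by a
    random angle.  Density compensation is empirical (inverse sampled
    fraction per radial annulus).
    """
    key = (tuple(shape), float(R))
    if key not in _SPIRAL_CACHE:
        n_target = int(np.prod(shape)) / R
        lo, hi = 1.0, 12.0 * R
        for _ in range(18):
            mid = 0.5 * (lo + hi)
            r, phi = _spiral_track(shape, mid)
            count = _rasterize_polar(shape, r, phi, 0.0).sum()
            if count > n_target:
                lo = mid
            else:
                hi = mid
        _SPIRAL_CACHE[key] = _spiral_track(shape, 0.5 * (lo + hi))
    r, phi = _SPIRAL_CACHE[key]
    mask = _rasterize_polar(shape, r, phi, rng.uniform(0.0, 2 * np.pi))
    if mask.sum() < 16:
        raise ValueError(f"R={R} leaves fewer than 16 sampled points")
    return mask, _radial_dcf(mask)


def make_mask(kind: str, shape, R: float, seed: int | None = 0,
              rng: np.random.Generator | None = None) -> SamplingMask:
    """Build a sampling mask; ``R = 1`` gives the all-ones mask for both
    kinds."""
    shape = tuple(shape)
    if R < 1:
        raise ValueError("undersampling factor R must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if R == 1:
        ones = np.ones(shape)
        return SamplingMask(kind, shape, 1.0, ones.astype(bool), seed, ones)
    if kind == "random":
        m, w = _random_mask(shape, R, rng)
    elif kind == "spiral":
        m, w = _spiral_mask(shape, R, rng)
    else:
        raise ValueError(f"unknown mask kind {kind!r}; use 'random' or 'spiral'")
    return SamplingMask(kind, shape, float(R), m, seed, w)


def zero_filled_recon(image: np.ndarray, mask: SamplingMask | np.ndarray) -> np.ndarray:
    """Inverse FFT of the masked spectrum with density-compensation
    weighting; a fully sampled mask returns the input exactly."""
    if isinstance(mask, SamplingMask):
        w = mask.dcf()
    else:
        m = np.asarray(mask)
        w = m * (m.size / m.sum())
    if w.shape != image.shape:
        raise ValueError("image and mask shapes must match")
    k = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image), norm="ortho"))
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(k * w), norm="ortho"))


@dataclass
class DynamicsFactorResult:
    """Monte-Carlo dynamics-factor estimate for one (R, SNR) setting."""

    R: float
    snr_image: float
    d_r_map: np.ndarray
    d_r_mean: float
    sar_image: float
    n_trials: int
    kind: str
    #: excess kurtosis of the aliasing residual over the support (diagnostic
    #: of the Gaussian-aliasing assumption; ~0 for Gaussian)
    alias_kurtosis: float = float("nan")


def _k_noise(shape, sigma, rng):
    return sigma * (
        rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    )


def monte_carlo_dr(phantom: np.ndarray, kind: str, R: float, snr_image: float,
                   n_trials: int = 5000, seed: int = 0,
                   redraw_mask: bool = True,
                   chunk: int = 250) -> DynamicsFactorResult:
    """Monte-Carlo estimate of the dynamics factor d_R.

    Per trial, complex Gaussian noise at the level implied by ``snr_image``
    is added to the (masked) k-space data and the per-pixel standard
    deviation of the zero-filled reconstructions across trials is formed;
    ``d_R = sigma_image_R / (sqrt(R) * sigma_image)`` per pixel, averaged
    over the nonzero phantom support.  The signal-to-aliasing ratio
    ``SaR_image`` comes from a single noiseless undersampled reconstruction
    (mean support intensity over the rms aliasing residual on the support).
    """
    if n_trials < 100:
        raise ValueError("n_trials must be at least 100")
    phantom = np.asarray(phantom, float)
    rng = np.random.default_rng(seed)
    support = phantom > 0
    mu = phantom[support].mean()
    # per-quadrature k-space noise; with the orthonormal FFT this equals the
    # image-domain per-quadrature noise std of a fully sampled acquisition
    sigma_k = mu / snr_image if snr_image > 0 else 0.0

    k0 = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(phantom), norm="ortho"))
    base_mask = make_mask(kind, phantom.shape, R, rng=rng)

    # noiseless aliasing level for SaR
    recon0 = zero_filled_recon(phantom, base_mask)
    resid = (recon0 - phantom)[support]
    sigma_alias = np.sqrt(np.mean(np.abs(resid) ** 2) / 2.0)
    sar = mu / sigma_alias if sigma_alias > 0 else np.inf
    r_c = np.concatenate([resid.real, resid.imag])
    kurt = float(np.mean(r_c**4) / np.mean(r_c**2) ** 2 - 3.0) if resid.size else np.nan

    s1 = np.zeros(phantom.shape, complex)
    s2 = np.zeros(phantom.shape)
    done = 0
    while done < n_trials:
        b = min(chunk, n_trials - done)
        if redraw_mask and R > 1:
            dcfs = np.stack(
                [make_mask(kind, phantom.shape, R, rng=rng).dcf() for _ in range(b)]
            )
        else:
            dcfs = np.broadcast_to(base_mask.dcf(), (b,) + phantom.shape)
        noisy = (k0[None] + _k_noise((b,) + phantom.shape, sigma_k, rng)) * dcfs
        rec = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(noisy, axes=(-2, -1)), norm="ortho",
                         axes=(-2, -1)),
            axes=(-2, -1),
        )
        s1 += rec.sum(axis=0)
        s2 += (rec.real**2 + rec.imag**2).sum(axis=0)
        done += b
    mean = s1 / n_trials
    var = s2 / n_trials - (mean.real**2 + mean.imag**2)
    sigma_r = np.sqrt(np.maximum(var, 0.0) / 2.0)  # per-quadrature equivalent
    if sigma_k > 0:
        d_map = sigma_r / (np.sqrt(R) * sigma_k)
    else:
        d_map = np.full(phantom.shape, np.nan)
    d_mean = float(d_map[support].mean()) if sigma_k > 0 else float("nan")
    return DynamicsFactorResult(
        R=float(R), snr_image=float(snr_image), d_r_map=d_map, d_r_mean=d_mean,
        sar_image=float(sar), n_trials=int(n_trials), kind=kind,
        alias_kurtosis=kurt,
    )


def fit_aliasing_scaling(R_values, sar_values):
    """Least-squares fit of the aliasing-to-signal ratio 1/SaR against
    ``sqrt(R - 1)`` through the origin.

    Returns ``(k, residual_norm)`` where ``residual_norm`` is the norm of
    the fit residual relative to nothing (absolute); callers usually compare
    it against ``norm(1/SaR)``.
    """
    R_values = np.asarray(R_values, float)
    sar_values = np.asarray(sar_values, float)
    if R_values.size < 3 or np.unique(R_values).size < 3 or np.any(R_values <= 1):
        raise ValueError("need at least 3 distinct R values, all > 1")
    x = np.sqrt(R_values - 1.0)
    y = 1.0 / sar_values
    k = float(np.dot(x, y) / np.dot(x, x))
    resid = float(np.linalg.norm(y - k * x))
    return k, resid


def dr_model(R, snr_image, k) -> np.ndarray:
    """Closed-form dynamics-factor prediction
    ``sqrt(k**2 * (R-1)/R * SNR_image**2 + 1)`` with ``k`` the fitted
    aliasing-to-signal scaling constant (slope of 1/SaR vs sqrt(R-1))."""
    R = np.asarray(R, float)
    snr = np.asarray(snr_image, float)
    if np.any(R < 1):
        raise ValueError("R must be >= 1")
    if np.any(snr < 0):
        raise ValueError("snr_image must be non-negative")
    return np.sqrt(k**2 * (R - 1.0) / R * snr**2 + 1.0)


def eta_undersampled(eta, d_r):
    """Undersampled efficiency eta_R = eta / d_R (elementwise)."""
    eta = np.asarray(eta, float)
    d_r = np.asarray(d_r, float)
    if np.any(d_r == 0):
        raise ValueError("d_r must be nonzero")
    if np.any(d_r < 1.0 - 1e-6):
        import warnings

        warnings.warn("d_r < 1 encountered; below the least-squares bound")
    return eta / d_r
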