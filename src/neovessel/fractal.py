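"""Fractal analysis: box-counting, Fourier, and multifractal features.

Eight features summarize vessel-pattern complexity:

* ``fd_box`` — box-counting (Hausdorff-style) dimension of the binary
  vessel mask; neovascular tufts add fine space-filling structure and
  raise it.
* ``ffd_slope``, ``ffd_intercept`` — slope and intercept of the
  log radially-averaged power spectrum vs log frequency of the
  grayscale image (the "Fourier fractal dimension" pair; needs no
  segmentation).
* Multifractal spectrum of the grayscale measure via box-counting
  moments: Hoelder exponents alpha(q) and spectrum f(alpha), from which
  ``alpha_min``, ``alpha_max``, ``alpha_0`` (local) and
  ``f_at_alpha_min``, ``f_at_alpha_max`` (global) are reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "FRACTAL_FEATURE_NAMES",
    "box_counting_fd",
    "fourier_fd",
    "multifractal_spectrum",
    "MultifractalSpectrum",
    "fractal_vector",
]

FRACTAL_FEATURE_NAMES = (
    "fd_box", "ffd_slope", "ffd_intercept",
    "alpha_min", "alpha_max", "alpha_0",
    "f_at_alpha_min", "f_at_alpha_max",
)

# finite intercept reported for a spectrum with no AC power
_INTERCEPT_SENTINEL = -50.0

DEFAULT_Q = tuple(np.arange(-5.0, 5.01, 0.5))


def _dyadic_sizes(side: int) -> list[int]:
    sizes, e = [], 2
    while e <= side // 4:
        sizes.append(e)
        e *= 2
    return sizes


def _box_reduce(arr: np.ndarray, e: int, how: str) -> np.ndarray:
    """Aggregate an array over an e x e box grid (pad with zeros)."""
    h, w = arr.shape
    ph, pw = (-h) % e, (-w) % e
    if ph or pw:
        arr = np.pad(arr, ((0, ph), (0, pw)))
    h, w = arr.shape
    blocks = arr.reshape(h // e, e, w // e, e)
    return blocks.max(axis=(1, 3)) if how == "max" else \
        blocks.sum(axis=(1, 3))


def box_counting_fd(mask: np.ndarray) -> float:
    """Box-counting fractal dimension of a binary mask.

    Occupied boxes are counted at dyadic sizes from 2 px up to a
    quarter of the short side (larger boxes carry strong finite-size
    bias and are excluded); the dimension is minus the slope of the
    least-squares fit of log N(eps) against log eps.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no foreground pixels")
    sizes = _dyadic_sizes(min(mask.shape))
    if len(sizes) < 2:
        raise ValueError("mask too small for box counting")
    counts = [int(_box_reduce(mask, e, "max").sum()) for e in sizes]
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return float(-slope)


def fourier_fd(img: np.ndarray, f_min: float = 4.0,
               n_bins: int = 24) -> tuple[float, float]:
    """Spectral-slope fractal descriptor of a grayscale surface.

    The 2-D power spectrum of the mean-subtracted image is averaged in
    log-spaced radial-frequency bins between ``f_min`` cycles/image and
    half the Nyquist frequency, and (slope, intercept) of the natural-
    log power vs log frequency regression are returned.
    """
    img = np.asarray(img, dtype=float)
    if min(img.shape) < 64:
        raise ValueError("image must be at least 64 x 64")
    centered = img - img.mean()
    power = np.abs(np.fft.fft2(centered)) ** 2
    if power.sum() < 1e-20:
        logger.warning("fourier_fd: constant image, sentinel intercept")
        return 0.0, _INTERCEPT_SENTINEL
    h, w = img.shape
    fy = np.fft.fftfreq(h)[:, None] * h   # cycles per image
    fx = np.fft.fftfreq(w)[None, :] * w
    r = np.hypot(fy * (min(h, w) / h), fx * (min(h, w) / w))
    f_max = min(h, w) / 4.0               # half Nyquist
    edges = np.geomspace(f_min, f_max, n_bins + 1)
    log_f, log_p = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (r >= lo) & (r < hi)
        if sel.any():
            log_f.append(np.log(np.sqrt(lo * hi)))
            log_p.append(np.log(power[sel].mean() + 1e-300))
    slope, intercept = np.polyfit(log_f, log_p, 1)
    return float(slope), float(intercept)


@dataclass
class MultifractalSpectrum:
    """Sampled (alpha, f(alpha)) curve from box-counting moments."""

    q_values: np.ndarray
    tau: np.ndarray
    alpha: np.ndarray
    f_alpha: np.ndarray
    fit_r2: np.ndarray


def _fit_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R^2 of y on x."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / ss_tot if ss_tot > 0 else 1.0
    return float(slope), float(r2)


def multifractal_spectrum(img: np.ndarray,
                          q_values=DEFAULT_Q) -> MultifractalSpectrum:
    """Multifractal spectrum of a nonnegative image treated as a measure.

    For each box size eps, box masses mu(box) are obtained by summing
    the normalized image over an eps-grid.  tau(q) is the scaling
    exponent of the partition sum Z(q, eps) = sum mu^q; the Hoelder
    exponent alpha(q) comes from the moment (Chhabra-Jensen) estimator
    — the slope over eps of sum_i mu_i(q) log mu_i with weights
    mu_i(q) = mu^q / Z — and f(alpha(q)) = q alpha(q) - tau(q).
    Empty boxes are excluded before exponentiation so negative q stay
    finite.
    """
    img = np.asarray(img, dtype=float)
    q_values = np.asarray(list(q_values), dtype=float)
    if img.min() < 0:
        img = img - img.min()
    total = img.sum()
    if total <= 0:
        raise ValueError("image has no mass")
    mu0 = img / total
    sizes = _dyadic_sizes(min(img.shape))
    if len(sizes) < 2:
        raise ValueError("image too small for multifractal analysis")
    log_eps = np.log(np.asarray(sizes, float) / min(img.shape))

    tau = np.empty(q_values.size)
    alpha = np.empty(q_values.size)
    r2 = np.empty(q_values.size)
    log_z = np.empty(len(sizes))
    a_num = np.empty(len(sizes))
    for qi, q in enumerate(q_values):
        for ei, e in enumerate(sizes):
            mu = _box_reduce(mu0, e, "sum").ravel()
            mu = mu[mu > 1e-14]
            z = (mu**q).sum()
            log_z[ei] = np.log(z)
            w = mu**q / z
            a_num[ei] = (w * np.log(mu)).sum()
        tau[qi], _ = _fit_slope(log_eps, log_z)
        alpha[qi], r2[qi] = _fit_slope(log_eps, a_num)
    f_alpha = q_values * alpha - tau
    return MultifractalSpectrum(q_values=q_values, tau=tau, alpha=alpha,
                                f_alpha=f_alpha, fit_r2=r2)


def _local_global_params(spec: MultifractalSpectrum,
                         min_r2: float = 0.9) -> tuple[float, ...]:
    """alpha_min / alpha_max / alpha_0 and f at the extremes, using only
    q values whose alpha regression reached ``min_r2``."""
    ok = spec.fit_r2 >= min_r2
    if not ok.any():
        ok = np.ones_like(ok, dtype=bool)
        logger.warning("multifractal fit quality low for every q")
    alpha, f_alpha, q = spec.alpha[ok], spec.f_alpha[ok], spec.q_values[ok]
    i_min, i_max = int(np.argmin(alpha)), int(np.argmax(alpha))
    i0 = int(np.argmin(np.abs(q)))
    return (float(alpha[i_min]), float(alpha[i_max]), float(alpha[i0]),
            float(f_alpha[i_min]), float(f_alpha[i_max]))


def fractal_vector(img: np.ndarray, mask: np.ndarray,
                   q_values=DEFAULT_Q) -> np.ndarray:
    """The 8-value fractal descriptor, ordered as
    :data:`FRACTAL_FEATURE_NAMES`.  Box counting runs on the binary
    vessel mask; the spectral and multifractal features run on the
    grayscale image."""
    mask = np.asarray(mask, dtype=bool)
    fd = box_counting_fd(mask) if mask.any() else 0.0
    slope, intercept = fourier_fd(img)
    spec = multifractal_spectrum(img, q_values=q_values)
    a_min, a_max, a_0, f_min_, f_max_ = _local_global_params(spec)
    return np.array([fd, slope, intercept,
                     a_min, a_max, a_0, f_min_, f_max_])
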