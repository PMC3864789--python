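"""Higher-order spectra (bispectral) features.

The bispectrum B(f1, f2) = E[X(f1) X(f2) X*(f1 + f2)] of a 1-D signal
is the Fourier transform of its third-order cumulant; it vanishes for
Gaussian processes and concentrates at (f1, f2) pairs that are
quadratically phase coupled.  For a real signal it is fully determined
on the principal (non-redundant) triangular domain

    Omega: 0 <= f2 <= f1, f1 + f2 <= 1   (frequency in Nyquist units).

Per image we take ten Radon projections (angles 0, 18, ..., 162
degrees) of the mean-subtracted image, estimate each projection's
bispectrum with the direct (segment-averaged FFT) method, and summarize
it over Omega by five statistics: the mean magnitude and four entropies
(normalized magnitude, squared and cubed magnitude, and the phase
histogram), giving 5 x 10 = 50 features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann
from skimage.transform import radon

__all__ = [
    "HOS_ANGLES_DEG",
    "HOS_STAT_NAMES",
    "hos_feature_names",
    "radon_projection",
    "bispectrum",
    "hos_features_at_angle",
    "hos_vector",
]

HOS_ANGLES_DEG = tuple(range(0, 180, 18))      # 10 angles
HOS_STAT_NAMES = ("Mave", "Ent1", "Ent2", "Ent3", "EntPh")


def hos_feature_names() -> tuple[str, ...]:
    """The 50 feature names, angle-major: Mave_a0, Ent1_a0, ..."""
    return tuple(f"{stat}_a{ang}" for ang in HOS_ANGLES_DEG
                 for stat in HOS_STAT_NAMES)


def _next_pow2(n: int) -> int:
    return 1 << max(6, (n - 1).bit_length())    # at least 64


def radon_projection(img: np.ndarray, theta: float) -> np.ndarray:
    """Line-integral projection of the mean-subtracted image at angle
    ``theta`` (degrees in [0, 180)), zero-padded to a power of two."""
    img = np.asarray(img, dtype=float)
    if not 0 <= theta < 180:
        raise ValueError("theta must be in [0, 180)")
    centered = img - img.mean()
    proj = radon(centered, theta=[theta], circle=False)[:, 0]
    out = np.zeros(_next_pow2(proj.size))
    out[: proj.size] = proj
    return out


@dataclass
class Bispectrum:
    """Direct bispectrum estimate on a discrete frequency grid."""

    values: np.ndarray      # complex (M+1) x (M+1), M = nfft // 2
    omega: np.ndarray       # bool mask of the principal domain
    nfft: int


def principal_domain(nfft: int) -> np.ndarray:
    """Boolean mask of Omega on the (nfft//2 + 1)^2 frequency grid."""
    m = nfft // 2
    k1, k2 = np.indices((m + 1, m + 1))
    return (k2 <= k1) & (k1 + k2 <= m)


def bispectrum(signal: np.ndarray, nfft: int = 256,
               n_segments: int | None = None) -> Bispectrum:
    """Direct bispectrum estimate of a real 1-D signal.

    The signal is split into ``n_segments`` Hann-windowed segments with
    50 % overlap (segment length = nfft, or the whole signal if it is
    shorter); triple products X(f1) X(f2) X*(f1+f2) are averaged over
    segments, realizing the expectation in the bispectrum definition.
    """
    x = np.asarray(signal, dtype=float).ravel()
    if nfft & (nfft - 1) or nfft < 2:
        raise ValueError("nfft must be a power of two")
    seg_len = min(nfft, x.size)
    step = max(1, seg_len // 2)
    if n_segments is None:
        n_segments = max(1, (x.size - seg_len) // step + 1)
    if x.size < seg_len:
        seg_len = x.size
        n_segments = 1
    m = nfft // 2
    window = hann(seg_len, sym=False)
    acc = np.zeros((m + 1, m + 1), dtype=complex)
    k1, k2 = np.indices((m + 1, m + 1))
    used = 0
    for s in range(n_segments):
        start = s * step
        if start + seg_len > x.size:
            break
        seg = x[start: start + seg_len]
        seg = (seg - seg.mean()) * window
        spec = np.fft.fft(seg, n=nfft)
        xs = spec[: m + 1]
        acc += xs[k1] * xs[k2] * np.conj(spec[(k1 + k2) % nfft])
        used += 1
    if used == 0:  # degenerate fall-back: single short segment
        seg = (x - x.mean()) * hann(x.size, sym=False)
        spec = np.fft.fft(seg, n=nfft)
        xs = spec[: m + 1]
        acc = xs[k1] * xs[k2] * np.conj(spec[(k1 + k2) % nfft])
        used = 1
    return Bispectrum(values=acc / used, omega=principal_domain(nfft),
                      nfft=nfft)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum()) if p.size else 0.0


def hos_features_at_angle(b: Bispectrum,
                          phase_bins: int = 64) -> np.ndarray:
    """Five bispectral statistics over the principal domain Omega:
    mean magnitude, entropies of the normalized magnitude and of its
    second and third powers, and the phase-histogram entropy (natural
    logarithms, ``phase_bins`` equal bins on (-pi, pi])."""
    vals = b.values[b.omega]
    if vals.size == 0:
        raise ValueError("empty principal domain")
    mag = np.abs(vals)
    total = mag.sum()
    if total <= 0 or mag.max() < 1e-30:
        # degenerate (e.g. constant-image) bispectrum: zeros by convention
        return np.zeros(5)
    mave = float(mag.mean())
    ent1 = _entropy(mag / total)
    ent2 = _entropy(mag**2 / (mag**2).sum())
    ent3 = _entropy(mag**3 / (mag**3).sum())
    phases = np.angle(vals)
    hist, _ = np.histogram(phases, bins=phase_bins, range=(-np.pi, np.pi))
    ent_ph = _entropy(hist / hist.sum())
    return np.array([mave, ent1, ent2, ent3, ent_ph])


def hos_vector(img: np.ndarray, nfft: int = 256,
               phase_bins: int = 64) -> np.ndarray:
    """The 50-value higher-order-spectra descriptor (angle-major
    order matching :func:`hos_feature_names`)."""
    out = []
    for ang in HOS_ANGLES_DEG:
        proj = radon_projection(img, float(ang))
        b = bispectrum(proj, nfft=nfft)
        out.append(hos_features_at_angle(b, phase_bins=phase_bins))
    return np.concatenate(out)
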