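"""Statistical texture analysis: GLCM and run-length features.

Seventeen features describe the second-order gray-level statistics of a
preprocessed fundus image: twelve from the gray-level co-occurrence
matrix (energy, entropy, contrast, homogeneity, four distribution
moments of the pixel-pair gray-level difference, correlation,
dissimilarity, inverse difference momentum, maximum probability) and
five from the gray-level run-length matrix (short/long run emphasis,
gray-level and run-length non-uniformity, run percentage), the latter
averaged over the four scan directions 0/45/90/135 degrees.

Images are quantized uniformly to a small number of gray levels
(default 8) before counting; all upstream processing is real-valued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

__all__ = [
    "STA_FEATURE_NAMES",
    "quantize",
    "compute_glcm",
    "glcm_features",
    "compute_rlm",
    "rlm_features",
    "sta_vector",
]

STA_FEATURE_NAMES = (
    "energy", "entropy", "contrast", "homogeneity",
    "moment1", "moment2", "moment3", "moment4",
    "correlation", "dissimilarity", "inverse_difference_momentum",
    "max_probability",
    "SRE", "LRE", "GLN", "RLN", "RP",
)

RLM_DIRECTIONS = (0, 45, 90, 135)


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Uniformly quantize a [0, 1] image into ``levels`` integer bins."""
    img = np.asarray(img, dtype=float)
    q = np.floor(img * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


@dataclass
class GLCMatrix:
    """Co-occurrence counts and probabilities at a pixel offset family."""

    counts: np.ndarray      # L x L, averaged over the offsets used
    probs: np.ndarray       # counts normalized to sum 1
    levels: int
    distance: int


def compute_glcm(img: np.ndarray, levels: int = 8, distance: int = 1,
                 angles: tuple[float, ...] | None = None,
                 symmetric: bool = True) -> GLCMatrix:
    """Gray-level co-occurrence matrix of a quantized image.

    Counts pixel pairs separated by ``distance`` along the four offsets
    (0, d), (d, 0), (d, d), (d, -d) (skimage angle convention), averages
    the four matrices and normalizes to probabilities.
    """
    if levels < 2 or distance < 1:
        raise ValueError("levels must be >= 2 and distance >= 1")
    img = np.asarray(img, dtype=float)
    if min(img.shape) < 2:
        raise ValueError("image must be at least 2 px in each dimension")
    q = quantize(img, levels).astype(np.uint8)
    if angles is None:
        angles = (0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4)
    raw = graycomatrix(q, distances=[distance], angles=list(angles),
                       levels=levels, symmetric=symmetric, normed=False)
    counts = raw[:, :, 0, :].astype(float).mean(axis=-1)
    total = counts.sum()
    if total == 0:
        raise ValueError("no valid pixel pairs")
    return GLCMatrix(counts=counts, probs=counts / total,
                     levels=levels, distance=distance)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The 12 co-occurrence features.

    Moments 1-4 summarize the distribution of the absolute gray-level
    difference |i - j| under P: mean, standard deviation, standardized
    skewness and kurtosis.  "Inverse difference momentum" uses the
    squared difference normalized by the squared number of levels,
    which keeps it distinct from homogeneity.
    """
    p = np.asarray(m.probs, dtype=float)
    if p.sum() <= 0:
        raise ValueError("empty co-occurrence matrix")
    L = m.levels
    i, j = np.indices(p.shape)
    d = np.abs(i - j)

    nz = p[p > 0]
    energy = float((p**2).sum())
    entropy = float(-(nz * np.log2(nz)).sum())
    contrast = float(((i - j) ** 2 * p).sum())
    homogeneity = float((p / (1.0 + (i - j) ** 2)).sum())

    m1 = float((d * p).sum())
    var = float(((d - m1) ** 2 * p).sum())
    m2 = float(np.sqrt(var))
    if m2 > 1e-12:
        m3 = float((((d - m1) / m2) ** 3 * p).sum())
        m4 = float((((d - m1) / m2) ** 4 * p).sum())
    else:
        m3, m4 = 0.0, 0.0

    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    sd_i = float(np.sqrt(((i - mu_i) ** 2 * p).sum()))
    sd_j = float(np.sqrt(((j - mu_j) ** 2 * p).sum()))
    if sd_i > 1e-12 and sd_j > 1e-12:
        correlation = float((((i - mu_i) * (j - mu_j) * p).sum())
                            / (sd_i * sd_j))
    else:
        correlation = 1.0  # degenerate: all mass on one gray level

    dissimilarity = float((d * p).sum())
    idm = float((p / (1.0 + (i - j) ** 2 / L**2)).sum())
    max_probability = float(p.max())

    return {
        "energy": energy, "entropy": entropy, "contrast": contrast,
        "homogeneity": homogeneity,
        "moment1": m1, "moment2": m2, "moment3": m3, "moment4": m4,
        "correlation": correlation, "dissimilarity": dissimilarity,
        "inverse_difference_momentum": idm,
        "max_probability": max_probability,
    }


@dataclass
class RLMatrix:
    """Run-length counts: entry (i, j-1) = number of maximal runs of
    quantized gray level i with length j along ``direction``."""

    counts: np.ndarray
    direction: int
    n_pixels: int


def _scan_lines(q: np.ndarray, direction: int):
    """Yield the scan lines of a 2-D array along a direction (deg)."""
    h, w = q.shape
    if direction == 0:
        for r in range(h):
            yield q[r, :]
    elif direction == 90:
        for c in range(w):
            yield q[:, c]
    elif direction == 45:
        # anti-diagonals, lower-left to upper-right
        fl = q[::-1, :]
        for k in range(-(h - 1), w):
            yield np.diagonal(fl, offset=k)
    elif direction == 135:
        for k in range(-(h - 1), w):
            yield np.diagonal(q, offset=k)
    else:
        raise ValueError("direction must be one of 0, 45, 90, 135")


def compute_rlm(img: np.ndarray, levels: int = 8,
                direction: int = 0) -> RLMatrix:
    """Run-length matrix: counts of maximal constant-level runs."""
    img = np.asarray(img, dtype=float)
    q = quantize(img, levels)
    rmax = max(img.shape)
    counts = np.zeros((levels, rmax), dtype=np.int64)
    for line in _scan_lines(q, direction):
        line = np.asarray(line)
        if line.size == 0:
            continue
        # boundaries of maximal runs
        change = np.flatnonzero(np.diff(line)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [line.size]))
        for s, e in zip(starts, ends):
            counts[line[s], e - s - 1] += 1
    return RLMatrix(counts=counts, direction=direction,
                    n_pixels=int(img.size))


def rlm_features(m: RLMatrix) -> dict[str, float]:
    """Short/long run emphasis, gray-level and run-length
    non-uniformity, and run percentage of one run-length matrix."""
    r = np.asarray(m.counts, dtype=float)
    n_runs = r.sum()
    if n_runs == 0:
        raise ValueError("empty run-length matrix")
    jj = np.arange(1, r.shape[1] + 1, dtype=float)
    sre = float((r / jj**2).sum() / n_runs)
    lre = float((r * jj**2).sum() / n_runs)
    gln = float((r.sum(axis=1) ** 2).sum() / n_runs)
    rln = float((r.sum(axis=0) ** 2).sum() / n_runs)
    rp = float(n_runs / m.n_pixels)
    return {"SRE": sre, "LRE": lre, "GLN": gln, "RLN": rln, "RP": rp}


def sta_vector(img: np.ndarray, levels: int = 8,
               distance: int = 1) -> np.ndarray:
    """The full 17-value statistical-texture descriptor, in the fixed
    order of :data:`STA_FEATURE_NAMES`.  Run-length features are the
    average of the four directional values."""
    glcm = glcm_features(compute_glcm(img, levels=levels,
                                      distance=distance))
    rl_acc = {k: 0.0 for k in ("SRE", "LRE", "GLN", "RLN", "RP")}
    for direction in RLM_DIRECTIONS:
        f = rlm_features(compute_rlm(img, levels=levels,
                                     direction=direction))
        for k in rl_acc:
            rl_acc[k] += f[k] / len(RLM_DIRECTIONS)
    merged = {**glcm, **rl_acc}
    return np.array([merged[name] for name in STA_FEATURE_NAMES])
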