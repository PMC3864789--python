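"""Synthetic fundus-like image generator.

Renders labeled retinal-photograph surrogates: a bright, orange-ish,
textured circular field of view crossed by a dark branching vessel tree.
Positive cases additionally carry a localized tuft of fine, tortuous,
high-density vessels emulating the appearance of neovascularization
(either on-disc, NVD-like, or elsewhere, NVE-like).  Ground-truth vessel
masks are returned alongside the rendered image, so segmentation and
box-counting stages can be validated without any external data.

Backgrounds are generated from a random stream that is independent of the
tuft stream: two images rendered from the same seed that differ only in
``tuft_density`` are pixel-identical outside the tuft.  A classifier
trained on such data can therefore only exploit the lesion itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi


@dataclass
class SynthConfig:
    """Parameters of one synthetic fundus image.

    Attributes
    ----------
    image_size : int
        Side of the square image in pixels.  Default 192: a desk-scale
        stand-in for the 960-1536 px photographs of real screening
        archives, with vessel geometry scaled to match.
    n_branches : int
        Number of primary vessel trunks leaving the disc region.
    branch_depth : int
        Recursion depth of the branching tree.
    vessel_width : int
        Width (px) of the primary trunks; children get thinner.
    tuft_density : float
        0 disables the lesion (negative class).  Otherwise scales the
        number of fine random-walk segments in the tuft.
    tuft_tortuosity : float
        Angular diffusion of the tuft walks; higher = more tortuous.
    illumination_gradient : float
        Amplitude of the additive linear illumination ramp (intensity
        units on [0, 1]).
    noise_sd : float
        Gaussian pixel noise standard deviation (intensity units).
    texture_amplitude : float
        Amplitude of the low-frequency background texture; 0 gives a
        flat background outside vessels.
    seed : int
        Seed for the per-image random streams.
    """

    image_size: int = 192
    n_branches: int = 5
    branch_depth: int = 5
    vessel_width: int = 3
    tuft_density: float = 0.0
    tuft_tortuosity: float = 0.85
    illumination_gradient: float = 0.15
    noise_sd: float = 0.02
    texture_amplitude: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        for name in ("tuft_density", "tuft_tortuosity",
                     "illumination_gradient", "noise_sd",
                     "texture_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# fraction of the image width occupied by the tuft disc radius
_TUFT_RADIUS_FRAC = 0.12
# base background color (R, G, B) of the retinal field, 0-1 scale
_BG_COLOR = np.array([0.82, 0.55, 0.20])
# multiplicative darkening of the green channel under a vessel
_VESSEL_DARKEN = 0.45


def _smooth_noise(rng: np.random.Generator, size: int, cells: int,
                  amplitude: float) -> np.ndarray:
    """Low-frequency value-noise texture (Perlin-style surrogate)."""
    coarse = rng.normal(0.0, 1.0, size=(cells, cells))
    fine = ndi.zoom(coarse, size / cells, order=3)[:size, :size]
    if fine.shape != (size, size):  # zoom rounding
        out = np.zeros((size, size))
        out[: fine.shape[0], : fine.shape[1]] = fine
        fine = out
    fine = fine / (np.abs(fine).max() + 1e-12)
    return amplitude * fine


def _stamp_disk(mask: np.ndarray, r: float, c: float, radius: float) -> None:
    """Set a filled disc of ``radius`` to True, clipped to the image."""
    n = mask.shape[0]
    r0, r1 = int(max(0, r - radius - 1)), int(min(n, r + radius + 2))
    c0, c1 = int(max(0, c - radius - 1)), int(min(n, c + radius + 2))
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2


def _draw_walk(mask: np.ndarray, rng: np.random.Generator,
               start: np.ndarray, heading: float, length: float,
               width: float, wiggle: float) -> np.ndarray:
    """Draw a meandering stroke of given width; returns the end point."""
    pos = start.astype(float).copy()
    n_steps = max(2, int(length))
    for _ in range(n_steps):
        heading += rng.normal(0.0, wiggle)
        pos += np.array([np.sin(heading), np.cos(heading)])
        _stamp_disk(mask, pos[0], pos[1], max(width / 2.0, 0.5))
    return pos


def _vessel_tree(rng: np.random.Generator, cfg: SynthConfig) -> np.ndarray:
    """Recursive branching tree of dark vessels, as a boolean mask."""
    n = cfg.image_size
    mask = np.zeros((n, n), dtype=bool)
    disc = np.array([n * 0.5, n * 0.18])  # optic-disc-like origin
    stack = []
    for b in range(cfg.n_branches):
        heading = rng.uniform(-1.1, 1.1) + (np.pi / 2.0)
        # headings fan out to the right of the disc, like arcades
        stack.append((disc.copy(), heading, cfg.branch_depth,
                      float(cfg.vessel_width)))
    while stack:
        pos, heading, depth, width = stack.pop()
        seg_len = rng.uniform(0.10, 0.22) * n
        end = _draw_walk(mask, rng, pos, heading, seg_len, width,
                         wiggle=0.08)
        if depth <= 1 or width < 1.0:
            continue
        split = rng.uniform(0.25, 0.55)
        stack.append((end, heading + split, depth - 1, width * 0.75))
        stack.append((end, heading - split, depth - 1, width * 0.75))
    return mask


def _tuft(rng: np.random.Generator, cfg: SynthConfig,
          fov: np.ndarray) -> np.ndarray:
    """Localized cluster of fine, tortuous vessels (the lesion)."""
    n = cfg.image_size
    mask = np.zeros((n, n), dtype=bool)
    if cfg.tuft_density <= 0:
        return mask
    radius = _TUFT_RADIUS_FRAC * n
    # center well inside the field of view
    while True:
        center = rng.uniform(0.3 * n, 0.7 * n, size=2)
        if fov[int(center[0]), int(center[1])]:
            break
    n_segments = max(4, int(round(220 * cfg.tuft_density)))
    for _ in range(n_segments):
        ang = rng.uniform(0, 2 * np.pi)
        rad = radius * np.sqrt(rng.uniform(0, 1))
        start = center + rad * np.array([np.sin(ang), np.cos(ang)])
        _draw_walk(mask, rng, start, rng.uniform(0, 2 * np.pi),
                   length=rng.uniform(0.3, 1.0) * radius, width=1.1,
                   wiggle=cfg.tuft_tortuosity)
    # clip the lesion to its disc so density stays localized
    lesion_zone = np.zeros((n, n), dtype=bool)
    _stamp_disk(lesion_zone, center[0], center[1], radius * 1.5)
    return mask & lesion_zone & fov


def make_image(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray, int]:
    """Render one synthetic fundus image.

    Returns
    -------
    image : (H, W, 3) uint8 array
    vessel_mask : (H, W) bool array — ground truth (tree plus tuft)
    label : int — 1 if the image carries a neovascular tuft, else 0
    """
    n = cfg.image_size
    # independent streams: identical background for a given seed,
    # regardless of whether the tuft is enabled
    rng_bg = np.random.default_rng([cfg.seed, 0x0BAC])
    rng_tuft = np.random.default_rng([cfg.seed, 0x70F7])
    rng_noise = np.random.default_rng([cfg.seed, 0x401E])

    rr, cc = np.mgrid[0:n, 0:n]
    fov = (rr - n / 2) ** 2 + (cc - n / 2) ** 2 <= (0.48 * n) ** 2

    tree = _vessel_tree(rng_bg, cfg) & fov
    tuft = _tuft(rng_tuft, cfg, fov)
    vessels = tree | tuft

    texture = _smooth_noise(rng_bg, n, cells=12,
                            amplitude=cfg.texture_amplitude)
    img = np.empty((n, n, 3), dtype=float)
    for ch in range(3):
        img[:, :, ch] = _BG_COLOR[ch] + texture * (0.4 + 0.6 * (ch == 1))
    # vessels darken the field, most visibly in green
    dark = np.where(vessels, _VESSEL_DARKEN, 1.0)
    img[:, :, 0] *= np.where(vessels, 0.75, 1.0)
    img[:, :, 1] *= dark
    img[:, :, 2] *= np.where(vessels, 0.65, 1.0)

    if cfg.illumination_gradient > 0:
        ramp = cfg.illumination_gradient * (cc - n / 2) / n
        img += ramp[:, :, None]
    if cfg.noise_sd > 0:
        img += rng_noise.normal(0.0, cfg.noise_sd, size=img.shape)

    img[~fov] = 0.02
    img = np.clip(img, 0.0, 1.0)
    image = np.round(img * 255).astype(np.uint8)
    return image, vessels, int(cfg.tuft_density > 0)


def make_dataset(n_pos: int, n_neg: int, seed: int = 0,
                 base: SynthConfig | None = None):
    """Generate a labeled set of ``n_pos + n_neg`` synthetic images.

    Per-image seeds are derived from the master ``seed``; nuisance
    parameters (tree depth, vessel width, illumination, noise) are
    jittered within documented ranges so the background varies across
    the cohort.  Positives draw tuft density in [0.6, 1.0].

    Returns
    -------
    images : list of (H, W, 3) uint8 arrays
    masks : list of (H, W) bool ground-truth vessel masks
    labels : (n,) int array, 1 = neovascularization present
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    base = base if base is not None else SynthConfig()
    master = np.random.default_rng(seed)
    images, masks, labels = [], [], []
    for i in range(n_pos + n_neg):
        positive = i < n_pos
        sub = master.integers(0, 2**31 - 1)
        jit = np.random.default_rng([sub, 0x317])
        cfg = replace(
            base,
            seed=int(sub),
            n_branches=int(jit.integers(5, 7)),
            branch_depth=int(jit.integers(5, 7)),
            vessel_width=int(jit.integers(3, 5)),
            illumination_gradient=float(jit.uniform(0.05, 0.25)),
            noise_sd=float(jit.uniform(0.01, 0.03)),
            tuft_density=float(jit.uniform(0.7, 1.0)) if positive else 0.0,
            tuft_tortuosity=float(jit.uniform(0.7, 1.0)),
        )
        img, mask, label = make_image(cfg)
        images.append(img)
        masks.append(mask)
        labels.append(label)
    return images, masks, np.asarray(labels, dtype=int)
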