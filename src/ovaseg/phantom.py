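"""Seeded B-mode-like phantom generator with ground truth.

The phantom emulates the gross appearance of a transvaginal B-mode view
of an ovary: a mid-gray elliptical ovary containing dark circular
follicles, embedded in a brighter tissue background.  The clean
piecewise-constant scene is degraded by a Gaussian point-spread blur
followed by fully developed multiplicative speckle, modelled as
unit-mean Gamma noise whose shape parameter ("looks") sets the
speckle contrast: the intensity variance of a homogeneous patch scales
as 1/looks.  What the phantom does *not* model: depth-dependent
attenuation, anisotropic speckle cells, shadowing and refraction
artefacts; conclusions drawn on phantoms transfer to clinical images
only insofar as those effects are secondary to speckle itself.

Ground truth is a 3-class label map (1 background, 2 ovary,
3 follicle) drawn from the same geometry before any degradation, so it
is independent of the noise settings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import GRAY_MAX, GrayImage, LabelMap

BACKGROUND_LABEL = 1
OVARY_LABEL = 2
FOLLICLE_LABEL = 3


@dataclass(frozen=True)
class PhantomConfig:
    height: int = 128
    width: int = 128
    background_gray: float = 150.0
    ovary_gray: float = 90.0
    follicle_gray: float = 30.0
    n_follicles: int = 3
    ovary_axes: tuple[float, float] = (44.0, 32.0)  # semi-axes (row, col), px
    follicle_radius: tuple[float, float] = (8.0, 12.0)  # min, max radius, px
    speckle_looks: float = 4.0
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.follicle_gray < self.ovary_gray < self.background_gray <= GRAY_MAX:
            raise ValueError("need 0 <= follicle < ovary < background <= 255")
        if self.n_follicles < 0:
            raise ValueError("n_follicles must be >= 0")
        if self.speckle_looks <= 0:
            raise ValueError("invalid looks")
        if self.blur_sigma < 0:
            raise ValueError("blur_sigma must be >= 0")


def apply_speckle(img: GrayImage, looks: float, seed: int) -> GrayImage:
    """Multiply each pixel by an independent unit-mean Gamma(looks) draw.

    ``looks = inf`` is the noiseless limit and returns the image
    unchanged.  Output is clipped to the working gray range.
    """
    if looks <= 0:
        raise ValueError("invalid looks")
    if math.isinf(looks):
        return GrayImage(img.pixels.copy())
    rng = np.random.default_rng(seed)
    noise = rng.gamma(shape=looks, scale=1.0 / looks, size=img.shape)
    return GrayImage(np.clip(img.pixels * noise, 0.0, GRAY_MAX))


def _follicle_centers(cfg: PhantomConfig, rng: np.random.Generator):
    """Rejection-sample non-overlapping follicle centers inside the ovary."""
    cy, cx = cfg.height / 2.0, cfg.width / 2.0
    ay, ax = cfg.ovary_axes
    placed: list[tuple[float, float, float]] = []
    for _ in range(cfg.n_follicles):
        ok = False
        for _ in range(200):
            r = rng.uniform(*cfg.follicle_radius)
            # stay strictly inside the ellipse eroded by the radius
            u, v = rng.uniform(-1, 1), rng.uniform(-1, 1)
            y = cy + u * (ay - r - 2.0)
            x = cx + v * (ax - r - 2.0)
            if ((y - cy) / (ay - r - 2.0)) ** 2 + ((x - cx) / (ax - r - 2.0)) ** 2 > 1.0:
                continue
            if any(
                math.hypot(y - py, x - px) < r + pr + 2.0 for py, px, pr in placed
            ):
                continue
            placed.append((y, x, r))
            ok = True
            break
        if not ok:
            raise RuntimeError("cannot place follicles")
    return placed


def make_phantom(cfg: PhantomConfig) -> tuple[GrayImage, LabelMap]:
    """Generate a speckled phantom and its clean ground-truth label map."""
    rng = np.random.default_rng(cfg.seed)
    rr, cc = np.mgrid[0 : cfg.height, 0 : cfg.width]
    cy, cx = cfg.height / 2.0, cfg.width / 2.0
    ay, ax = cfg.ovary_axes
    labels = np.full((cfg.height, cfg.width), BACKGROUND_LABEL, dtype=np.int64)
    inside = ((rr - cy) / ay) ** 2 + ((cc - cx) / ax) ** 2 <= 1.0
    labels[inside] = OVARY_LABEL
    for y, x, r in _follicle_centers(cfg, rng):
        labels[(rr - y) ** 2 + (cc - x) ** 2 <= r * r] = FOLLICLE_LABEL

    grays = np.array([0.0, cfg.background_gray, cfg.ovary_gray, cfg.follicle_gray])
    clean = grays[labels]
    if cfg.blur_sigma > 0:
        clean = gaussian_filter(clean, cfg.blur_sigma, mode="reflect")
    # independent sub-stream so the truth geometry never depends on looks
    speckle_seed = int(np.random.SeedSequence([cfg.seed, 1]).generate_state(1)[0] % (2**31))
    noisy = apply_speckle(GrayImage(clean), cfg.speckle_looks, seed=speckle_seed)
    truth = LabelMap(labels)
    if cfg.n_follicles == 0:
        truth = truth.compacted()
    return noisy, truth
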