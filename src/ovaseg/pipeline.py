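"""End-to-end segmentation pipeline and its configuration.

Stage order: normalize working range -> texture energies -> weighting
coefficient z_t -> joint mean shift filtering (adaptive or fixed
bandwidth) -> mode labelling -> threshold merging at H -> absorption of
non-protruding modes -> fragment removal.  ``segment_image`` returns the
final LabelMap together with a manifest of every resolved parameter, so
a run can be reproduced exactly from its manifest.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from typing import Any

import numpy as np
from skimage.filters import threshold_otsu

from . import region_merge, texture
from .image_io import GrayImage, LabelMap
from .meanshift import (
    DEFAULT_F_MAX,
    DEFAULT_H_S,
    DEFAULT_MAX_ITER,
    DEFAULT_TOL,
    BandwidthParams,
    ModeMap,
    filter_image,
)

log = logging.getLogger(__name__)

# every tunable of the pipeline, with its documented default
DEFAULTS: dict[str, Any] = {
    "texture.window": texture.DEFAULT_WINDOW,
    "merge.h_min": texture.H_MIN_DEFAULT,
    "merge.h_max": texture.H_MAX_DEFAULT,
    "merge.threshold_override": None,
    "merge.gray_tol": region_merge.DEFAULT_GRAY_TOL,
    "merge.connectivity": region_merge.DEFAULT_CONNECTIVITY,
    "merge.min_size": region_merge.DEFAULT_MIN_SIZE,
    "merge.prominence": region_merge.DEFAULT_PROMINENCE,
    "bandwidth.f_max": DEFAULT_F_MAX,
    "bandwidth.h_s": DEFAULT_H_S,
    "bandwidth.sigma_roi": None,  # None -> gray std of the image
    "bandwidth.adaptive": True,
    "meanshift.tol": DEFAULT_TOL,
    "meanshift.max_iter": DEFAULT_MAX_ITER,
    "roi.seed": None,  # (row, col) or None -> Otsu foreground mean
}


def resolve_config(overrides: dict[str, Any] | None = None) -> dict[str, Any]:
    """Merge overrides onto the documented defaults; unknown keys are rejected."""
    cfg = dict(DEFAULTS)
    for k, v in (overrides or {}).items():
        if k not in cfg:
            raise KeyError(f"unknown config key: {k}")
        cfg[k] = v
    return cfg


def roi_gray(img: GrayImage, seed: tuple[int, int] | None) -> float:
    """Representative gray of the region of interest.

    With a seed pixel, the median of the surrounding 5x5 patch (robust
    to speckle); without one, the mean of the Otsu foreground (pixels
    above the Otsu threshold).
    """
    if seed is not None:
        r, c = int(seed[0]), int(seed[1])
        if not (0 <= r < img.height and 0 <= c < img.width):
            raise IndexError("ROI seed outside image")
        patch = img.pixels[max(0, r - 2) : r + 3, max(0, c - 2) : c + 3]
        return float(np.median(patch))
    px = img.pixels
    if px.min() == px.max():
        return float(px.min())
    thr = threshold_otsu(px)
    fg = px[px > thr]
    return float(fg.mean()) if fg.size else float(px.mean())


@dataclass(frozen=True)
class SegmentationResult:
    labels: LabelMap
    modes: ModeMap
    manifest: dict[str, Any]


def segment_image(img: GrayImage, config: dict[str, Any] | None = None) -> SegmentationResult:
    """Run the full segmentation pipeline on a GrayImage."""
    cfg = resolve_config(config)
    t0 = time.perf_counter()

    adaptive = bool(cfg["bandwidth.adaptive"])
    z_t = 0.0
    threshold_auto = None
    fs = texture.texture_energy_maps(img, int(cfg["texture.window"]))
    try:
        z_t_val = texture.weighting_coefficient(fs)
    except ValueError:
        log.warning("textureless image; z_t falls back to 0")
        z_t_val = 0.0
    if adaptive:
        z_t = z_t_val

    sigma_roi = cfg["bandwidth.sigma_roi"]
    if sigma_roi is None:
        sigma_roi = max(float(img.pixels.std()), 1.0)
    t_roi = roi_gray(img, cfg["roi.seed"])
    params = BandwidthParams(
        f_max=float(cfg["bandwidth.f_max"]),
        t_roi=t_roi,
        z_t=z_t,
        sigma_roi=float(sigma_roi),
        h_s=float(cfg["bandwidth.h_s"]),
        adaptive=adaptive,
    )
    log.info("filtering: adaptive=%s z_t=%.4f t_roi=%.1f", adaptive, z_t, t_roi)
    modes = filter_image(img, params, float(cfg["meanshift.tol"]), int(cfg["meanshift.max_iter"]))
    t1 = time.perf_counter()

    # Merging statistics come from the filtered image: the threshold
    # compares pixel averages of regions of the *filtered* image, and
    # the automatic H measures the residual directional texture left
    # after filtering (raw speckle energy would only measure the noise).
    filtered = GrayImage(np.clip(modes.mode_gray, 0.0, 255.0))
    if cfg["merge.threshold_override"] is not None:
        H = float(cfg["merge.threshold_override"])
    else:
        fs_filt = texture.texture_energy_maps(filtered, int(cfg["texture.window"]))
        energy = texture.direction_energy_map(fs_filt, rescale=False)
        threshold_auto = texture.auto_threshold_H(
            energy, float(cfg["merge.h_min"]), float(cfg["merge.h_max"])
        )
        H = threshold_auto
    log.info("merge threshold H=%.2f", H)

    conn = int(cfg["merge.connectivity"])
    labels = region_merge.label_modes(modes, float(cfg["merge.gray_tol"]), conn)
    labels = region_merge.merge_regions(labels, filtered, H, conn)
    labels = region_merge.merge_nonprotruding(
        labels, modes, img, float(cfg["merge.prominence"]), conn
    )
    labels = region_merge.remove_fragments(labels, filtered, int(cfg["merge.min_size"]), conn)
    t2 = time.perf_counter()
    log.info(
        "segmented %dx%d: %d regions (filter %.2fs, merge %.2fs)",
        img.height, img.width, labels.n_regions, t1 - t0, t2 - t1,
    )

    manifest = {
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        "resolved": {
            "z_t": z_t,
            "z_t_unused": None if adaptive else z_t_val,
            "t_roi": t_roi,
            "sigma_roi": float(sigma_roi),
            "merge_threshold_H": H,
            "merge_threshold_auto": threshold_auto,
            "adaptive": adaptive,
            "n_regions": labels.n_regions,
        },
    }
    return SegmentationResult(labels=labels, modes=modes, manifest=manifest)


# ---------------------------------------------------------------------------
# Phantom benchmark: improved vs traditional on seeded speckle phantoms
# ---------------------------------------------------------------------------

def follicle_roi_seed(truth: LabelMap) -> tuple[int, int]:
    """Center pixel of the first follicle in a phantom ground truth.

    Mirrors how an operator would seed the region of interest: a click
    inside the target structure.
    """
    from scipy import ndimage

    from .phantom import FOLLICLE_LABEL

    follicles = truth.labels == FOLLICLE_LABEL
    if not follicles.any():
        raise ValueError("phantom has no follicle class")
    comp, _ = ndimage.label(follicles)
    r, c = ndimage.center_of_mass(follicles, comp, 1)
    return int(round(r)), int(round(c))


def score_follicles(labels: LabelMap, truth: LabelMap):
    """RDD/ROD/Dice of the follicle target recovered from a segmentation."""
    from .metrics import BinaryMask, extract_target, report
    from .phantom import FOLLICLE_LABEL

    truth_mask = BinaryMask(truth.labels == FOLLICLE_LABEL)
    seg_mask = extract_target(labels, truth_mask)
    return report(seg_mask, truth_mask)


def phantom_study(
    n_phantoms: int = 20,
    seed: int = 0,
    looks: float = 4.0,
    config: dict[str, Any] | None = None,
):
    """Segment seeded phantoms with both algorithm variants and score them.

    Returns a pandas DataFrame with one row per (phantom, algorithm):
    columns image_id, algorithm ("improved" / "traditional"), rdd, rod,
    dice.  Phantom seeds are ``seed .. seed + n_phantoms - 1``.
    """
    import pandas as pd

    from .phantom import PhantomConfig, make_phantom

    rows = []
    for i in range(n_phantoms):
        cfg = PhantomConfig(seed=seed + i, speckle_looks=looks)
        img, truth = make_phantom(cfg)
        roi = follicle_roi_seed(truth)
        for name, adaptive in (("improved", True), ("traditional", False)):
            overrides = dict(config or {})
            overrides["roi.seed"] = roi
            overrides["bandwidth.adaptive"] = adaptive
            res = segment_image(img, overrides)
            rep = score_follicles(res.labels, truth)
            rows.append(
                {"image_id": cfg.seed, "algorithm": name,
                 "rdd": rep.rdd, "rod": rep.rod, "dice": rep.dice}
            )
    return pd.DataFrame(rows)
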