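"""Segmentation accuracy metrics: RDD, ROD and the Dice coefficient.

All three compare a segmented target mask U1 against a ground-truth
target mask U2 of the same shape:

    RDD  = | |U2| - |U1| | / |U2| * 100          (relative difference degree)
    ROD  = min(|U1 n U2|/|U2|, |U1 n U2|/|U1|) * 100   (relative overlap degree)
    Dice = 2 |U1 n U2| / (|U1| + |U2|)

RDD measures area agreement only (0 is perfect), ROD the weaker of the
two directional overlap fractions (100 is perfect), Dice the symmetric
overlap (1 is perfect).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import LabelMap


@dataclass(frozen=True)
class BinaryMask:
    """Boolean target mask."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            raise ValueError("mask must be boolean")
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "mask", m)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass(frozen=True)
class MetricsReport:
    """RDD/ROD/Dice for one (segmentation, truth) pair."""

    rdd: float
    rod: float
    dice: float


def _areas(u1: BinaryMask, u2: BinaryMask) -> tuple[int, int, int]:
    if u1.mask.shape != u2.mask.shape:
        raise ValueError("mask shapes differ")
    return u1.area, u2.area, int(np.logical_and(u1.mask, u2.mask).sum())


def dice(u1: BinaryMask, u2: BinaryMask) -> float:
    """Dice coefficient 2|U1 n U2| / (|U1| + |U2|) in [0, 1]."""
    a1, a2, inter = _areas(u1, u2)
    if a1 + a2 == 0:
        raise ValueError("undefined Dice: both masks empty")
    return 2.0 * inter / (a1 + a2)


def rod(u1: BinaryMask, u2: BinaryMask) -> float:
    """Relative overlap degree: the weaker directional overlap, in percent."""
    a1, a2, inter = _areas(u1, u2)
    if a1 == 0 or a2 == 0:
        raise ValueError("undefined ROD: empty mask")
    return min(inter / a2, inter / a1) * 100.0


def rdd(u1: BinaryMask, u2: BinaryMask) -> float:
    """Relative difference degree: absolute area difference over |U2|, percent."""
    a1, a2, _ = _areas(u1, u2)
    if a2 == 0:
        raise ValueError("undefined RDD: empty ground truth")
    return abs(a2 - a1) / a2 * 100.0


def rdd_setdiff(u1: BinaryMask, u2: BinaryMask) -> float:
    """Set-difference reading of RDD: |U2 \\ U1| / |U2| * 100."""
    _, a2, inter = _areas(u1, u2)
    if a2 == 0:
        raise ValueError("undefined RDD: empty ground truth")
    return (a2 - inter) / a2 * 100.0


def report(u1: BinaryMask, u2: BinaryMask) -> MetricsReport:
    return MetricsReport(rdd=rdd(u1, u2), rod=rod(u1, u2), dice=dice(u1, u2))


def extract_target(labels: LabelMap, truth: BinaryMask) -> BinaryMask:
    """Pick the union of segmented regions that best covers the truth target.

    Regions are considered in decreasing order of the fraction of their
    pixels lying inside the truth mask and added greedily while the
    Dice coefficient of the running union improves.  On a perfect
    segmentation this returns exactly the truth pixels even when the
    target consists of several disconnected structures (one region
    each); with a single dominant region it reduces to picking that
    region.
    """
    lab = labels.labels
    if lab.shape != truth.mask.shape:
        raise ValueError("shape mismatch")
    t = truth.mask
    a2 = int(t.sum())
    if a2 == 0:
        raise ValueError("empty truth target")
    uniq = np.unique(lab)
    uniq = uniq[uniq > 0]
    sizes = np.bincount(lab.ravel())
    inters = np.bincount(lab.ravel(), weights=t.ravel().astype(float))
    cand = [
        (float(inters[l] / sizes[l]), int(l))
        for l in uniq
        if inters[l] > 0
    ]
    cand.sort(key=lambda x: (-x[0], x[1]))
    best = np.zeros_like(t)
    size_u, inter_u = 0, 0
    best_dice = 0.0
    for _, l in cand:
        new_size = size_u + int(sizes[l])
        new_inter = inter_u + int(inters[l])
        new_dice = 2.0 * new_inter / (new_size + a2)
        if new_dice > best_dice:
            best |= lab == l
            size_u, inter_u, best_dice = new_size, new_inter, new_dice
        else:
            break
    return BinaryMask(best)


def evaluate_batch(pairs: list[tuple[BinaryMask, BinaryMask]]) -> pd.DataFrame:
    """Mean and standard deviation of each metric across mask pairs.

    Returns a DataFrame indexed by metric name with columns
    ``mean`` and ``sd`` (population standard deviation).
    """
    if not pairs:
        raise ValueError("no pairs")
    rows = [report(u1, u2) for u1, u2 in pairs]
    df = pd.DataFrame({"rdd": [r.rdd for r in rows],
                       "rod": [r.rod for r in rows],
                       "dice": [r.dice for r in rows]})
    return pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=0)})
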