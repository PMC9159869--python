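"""Directional texture-energy features.

The adaptive bandwidth of the segmentation core is scaled by a texture
weighting coefficient

    z_t = Q_max / sum_i Q_i

where ``Q_i`` is the mean of the i-th directional texture-energy map and
``Q_max`` the largest of those means.  The same energy maps also supply
the automatic merge threshold ``H``: the mean of the pixel-wise direction
energy map, expressed in gray units and clamped to a configurable band.

The filter bank holds four oriented first-derivative kernels at
0/45/90/135 degrees (Sobel operator and its 45-degree rotation).  The
bank is closed under 90-degree image rotation, so rotating the input
permutes the four energies exactly.  "Energy" is the local mean of the
absolute filter response over a square window, the classical
texture-energy construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve, uniform_filter

from .image_io import GRAY_MAX, GrayImage

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 15
H_MIN_DEFAULT = 2.0
H_MAX_DEFAULT = 64.0

# Oriented derivative kernels; direction = orientation of the gray
# gradient each kernel responds to.  rot90 maps 0<->90 and 45<->135
# (up to sign, which the absolute response removes).  Gain-normalized
# so a gray step of height h yields a peak response of h: energies are
# then expressed in gray levels, the unit the merge threshold needs.
_K0 = np.array([[-1.0, 0.0, 1.0], [-2.0, 0.0, 2.0], [-1.0, 0.0, 1.0]]) / 4.0
_K45 = np.array([[0.0, 1.0, 2.0], [-1.0, 0.0, 1.0], [-2.0, -1.0, 0.0]]) / 4.0
_K90 = np.rot90(_K0)
_K135 = np.rot90(_K45)

KERNELS: tuple[np.ndarray, ...] = (_K0, _K45, _K90, _K135)
DIRECTIONS_DEG: tuple[int, ...] = (0, 45, 90, 135)


@dataclass(frozen=True)
class TextureFeatureSet:
    """Per-direction energy maps and their global means (the Q_i)."""

    energy_maps: tuple[np.ndarray, ...]
    q_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.energy_maps) != len(self.q_values) or not self.energy_maps:
            raise ValueError("need one q value per energy map, at least one map")
        if any(q < 0 for q in self.q_values):
            raise ValueError("texture energies must be non-negative")

    @property
    def q_max(self) -> float:
        return max(self.q_values)


def texture_energy_maps(img: GrayImage, window: int = DEFAULT_WINDOW) -> TextureFeatureSet:
    """Compute the four directional texture-energy maps of ``img``.

    Each map is the ``window`` x ``window`` local mean of the absolute
    response of one oriented derivative kernel (reflect boundary).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    maps = []
    for k in KERNELS:
        resp = convolve(img.pixels, k, mode="reflect")
        maps.append(uniform_filter(np.abs(resp), size=window, mode="reflect"))
    q = tuple(float(m.mean()) for m in maps)
    return TextureFeatureSet(tuple(maps), q)


def weighting_coefficient(fs: TextureFeatureSet) -> float:
    """Return z_t = Q_max / sum(Q_i), in (0, 1].

    Raises on a textureless image (all Q_i zero); the segmentation
    pipeline falls back to z_t = 0 in that case, which disables the
    bandwidth adaptation.
    """
    total = sum(fs.q_values)
    if total <= 0:
        raise ValueError("degenerate texture; caller must fall back to z_t = 0")
    return fs.q_max / total


def direction_energy_map(fs: TextureFeatureSet, rescale: bool = True) -> np.ndarray:
    """Pixel-wise maximum over the directional maps.

    With ``rescale`` (the default, for display and export) the map is
    stretched so its peak sits at 255.  ``rescale=False`` keeps the
    native gray-level units, which is what the automatic merge
    threshold works on: the gain-normalized kernels make the raw energy
    directly comparable to gray differences between regions.
    """
    if not fs.energy_maps:
        raise ValueError("no energy maps")
    combined = np.maximum.reduce(list(fs.energy_maps))
    if not rescale:
        return combined
    peak = combined.max()
    if peak <= 0:
        return np.zeros_like(combined)
    return combined * (GRAY_MAX / peak)


def auto_threshold_H(
    energy: np.ndarray,
    h_min: float = H_MIN_DEFAULT,
    h_max: float = H_MAX_DEFAULT,
) -> float:
    """Merge threshold H: mean of the direction energy map, clamped.

    The clamp band (defaults 2..64 gray levels) keeps the threshold in a
    regime where genuinely distinct tissues are never merged outright
    while flat images still get a usable floor.
    """
    energy = np.asarray(energy, dtype=np.float64)
    if not np.any(energy > 0):
        log.warning("all-zero direction energy map; merge threshold clamped to %g", h_min)
        return float(h_min)
    return float(min(max(energy.mean(), h_min), h_max))
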