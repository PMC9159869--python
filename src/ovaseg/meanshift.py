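"""Joint spatial-gray mean shift filtering with adaptive gray bandwidth.

Each pixel is a sample point x_i = (row_i, col_i, gray_i).  Mode seeking
iterates the Gaussian-kernel weighted mean

    y  <-  sum_i w_i x_i / sum_i w_i,
    w_i = exp(-|y_s - x_s,i|^2 / (2 h_s^2)) * exp(-(y_g - g_i)^2 / (2 h_g^2))

from every pixel until the gray component of the shift drops below a
tolerance.  The traditional algorithm keeps the gray bandwidth h_g fixed
at ``f_max``; the improved variant re-evaluates

    h_g(t) = f_max * (1 - z_t * exp(-(t - t_roi)^2 / (2 sigma_roi^2)))

at the current iterate's gray value t each iteration, so the bandwidth
contracts to f_max*(1 - z_t) at the region-of-interest gray and relaxes
to f_max far from it.  The raw form of this bandwidth law carries no
gray scale in its exponent, which would leave it inert on 8-bit data;
``sigma_roi`` (default: the gray standard deviation of the image) sets
that scale while preserving the law's shape.

Numerical conventions
---------------------
* Sample grays are snapped to the integer 8-bit grid [0, 255] on entry
  (ultrasound exports are 8-bit; the snap lets the gray kernel be
  evaluated through a 256-entry table instead of one exp per neighbour).
  Iterate grays remain continuous.
* The spatial kernel is truncated at 3 h_s around the current iterate;
  the gray kernel is never truncated.  On images smaller than the
  truncation radius the result is identical to an untruncated
  computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .image_io import GRAY_MAX, GrayImage

DEFAULT_F_MAX = 24.0
DEFAULT_H_S = 8.0
DEFAULT_TOL = 0.1
DEFAULT_MAX_ITER = 100
TRUNCATE = 3.0  # spatial kernel support in units of h_s
_NGRAY = 256
HG_FLOOR = 1e-2  # numerical floor on h_g inside the filter (z_t = 1 at t_roi)


def _quantized(img: GrayImage) -> tuple[np.ndarray, np.ndarray]:
    """Sample grays snapped to the 8-bit grid: integer index and float value."""
    gidx = np.clip(np.rint(img.pixels), 0, GRAY_MAX).astype(np.int64)
    return gidx, gidx.astype(np.float64)


@dataclass(frozen=True)
class BandwidthParams:
    """Bandwidths of the joint-domain kernel.

    f_max      -- maximum (and traditional fixed) gray bandwidth, gray levels
    t_roi      -- gray level of the region of interest
    z_t        -- texture weighting coefficient in [0, 1]
    sigma_roi  -- gray scale of the ROI Gaussian in the bandwidth law
    h_s        -- spatial bandwidth, pixels
    adaptive   -- False reproduces the traditional fixed-bandwidth algorithm
    """

    f_max: float = DEFAULT_F_MAX
    t_roi: float = 128.0
    z_t: float = 0.0
    sigma_roi: float = 48.0
    h_s: float = DEFAULT_H_S
    adaptive: bool = True

    def __post_init__(self) -> None:
        if self.f_max <= 0 or self.h_s <= 0 or self.sigma_roi <= 0:
            raise ValueError("f_max, h_s and sigma_roi must be positive")
        if not 0.0 <= self.z_t <= 1.0:
            raise ValueError("z_t must lie in [0, 1]")

    def fixed(self) -> "BandwidthParams":
        return replace(self, adaptive=False)


@dataclass(frozen=True)
class ModeMap:
    """Converged state of every pixel after mean shift filtering."""

    mode_gray: np.ndarray  # converged gray value per pixel
    mode_pos: np.ndarray  # (H, W, 2) converged (row, col) per pixel
    iterations: np.ndarray  # update steps taken per pixel
    params: BandwidthParams

    @property
    def shape(self) -> tuple[int, int]:
        return self.mode_gray.shape


def gray_bandwidth(t: float | np.ndarray, p: BandwidthParams) -> float | np.ndarray:
    """Adaptive gray bandwidth h_g(t); returns f_max when adaptivity is off."""
    if not p.adaptive:
        return p.f_max if np.isscalar(t) else np.full_like(np.asarray(t, float), p.f_max)
    u = (np.asarray(t, dtype=np.float64) - p.t_roi) / p.sigma_roi
    out = p.f_max * (1.0 - p.z_t * np.exp(-0.5 * u * u))
    return float(out) if np.isscalar(t) else out


@njit(fastmath=True)
def _seek(gidx, gval, r0, c0, f_max, t_roi, z_t, sigma_roi, h_s, adaptive,
          tol, max_iter, radius, etab, wr, wc):
    H, W = gval.shape
    yr, yc, yg = float(r0), float(c0), gval[r0, c0]
    inv2hs2 = 1.0 / (2.0 * h_s * h_s)
    it = 0
    for _ in range(max_iter):
        if adaptive:
            u = (yg - t_roi) / sigma_roi
            hg = f_max * (1.0 - z_t * math.exp(-0.5 * u * u))
            if hg < 1e-2:
                hg = 1e-2
        else:
            hg = f_max
        inv2hg2 = 1.0 / (2.0 * hg * hg)
        for k in range(_NGRAY):
            d = k - yg
            etab[k] = math.exp(-d * d * inv2hg2)
        rlo = max(0, int(math.floor(yr - radius)))
        rhi = min(H - 1, int(math.ceil(yr + radius)))
        clo = max(0, int(math.floor(yc - radius)))
        chi = min(W - 1, int(math.ceil(yc + radius)))
        for r in range(rlo, rhi + 1):
            d = r - yr
            wr[r - rlo] = math.exp(-d * d * inv2hs2)
        for c in range(clo, chi + 1):
            d = c - yc
            wc[c - clo] = math.exp(-d * d * inv2hs2)
        sw = 0.0
        sr = 0.0
        sc = 0.0
        sg = 0.0
        for r in range(rlo, rhi + 1):
            rowf = wr[r - rlo]
            rsw = 0.0
            rsc = 0.0
            rsg = 0.0
            for c in range(clo, chi + 1):
                e = etab[gidx[r, c]] * wc[c - clo]
                rsw += e
                rsc += e * c
                rsg += e * gval[r, c]
            sw += rowf * rsw
            sr += rowf * rsw * r
            sc += rowf * rsc
            sg += rowf * rsg
        if sw == 0.0:  # all weights underflowed (degenerate bandwidth)
            break
        ng = sg / sw
        gshift = abs(ng - yg)
        yr, yc, yg = sr / sw, sc / sw, ng
        it += 1
        if gshift < tol:
            break
    return yr, yc, yg, it


@njit(fastmath=True)
def _filter_all(gidx, gval, f_max, t_roi, z_t, sigma_roi, h_s, adaptive,
                tol, max_iter, radius):
    H, W = gval.shape
    mg = np.empty((H, W))
    mp = np.empty((H, W, 2))
    its = np.empty((H, W), dtype=np.int64)
    etab = np.empty(_NGRAY)
    nwin = int(2 * radius) + 3
    wr = np.empty(nwin)
    wc = np.empty(nwin)
    for r in range(H):
        for c in range(W):
            yr, yc, yg, it = _seek(
                gidx, gval, r, c, f_max, t_roi, z_t, sigma_roi, h_s, adaptive,
                tol, max_iter, radius, etab, wr, wc,
            )
            mg[r, c] = yg
            mp[r, c, 0] = yr
            mp[r, c, 1] = yc
            its[r, c] = it
    return mg, mp, its


def seek_mode(
    row: int,
    col: int,
    img: GrayImage,
    p: BandwidthParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> tuple[tuple[float, float], float, int]:
    """Run mode seeking from one pixel.

    Returns ((row, col) of the converged point, converged gray,
    number of update steps taken).
    """
    if not (0 <= row < img.height and 0 <= col < img.width):
        raise IndexError("pixel outside image")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    gidx, gval = _quantized(img)
    radius = TRUNCATE * p.h_s
    nwin = int(2 * radius) + 3
    yr, yc, yg, it = _seek(
        gidx, gval, row, col, p.f_max, p.t_roi, p.z_t, p.sigma_roi,
        p.h_s, p.adaptive, tol, max_iter, radius,
        np.empty(_NGRAY), np.empty(nwin), np.empty(nwin),
    )
    return (yr, yc), yg, it


def filter_image(
    img: GrayImage,
    p: BandwidthParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ModeMap:
    """Mean shift filter: run :func:`seek_mode` from every pixel."""
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be positive and max_iter >= 1")
    gidx, gval = _quantized(img)
    radius = TRUNCATE * p.h_s
    mg, mp, its = _filter_all(
        gidx, gval, p.f_max, p.t_roi, p.z_t, p.sigma_roi,
        p.h_s, p.adaptive, tol, max_iter, radius,
    )
    return ModeMap(mg, mp, its, p)


def seek_trajectory(
    row: int,
    col: int,
    img: GrayImage,
    p: BandwidthParams,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
) -> np.ndarray:
    """All iterates of mode seeking from one pixel, start included.

    Returns an (n_states, 4) array of rows (row, col, gray, h_g) where
    h_g is the gray bandwidth used for the step *leaving* that state
    (the last state's entry is the bandwidth that would apply next).
    Pure-Python mirror of the compiled update, intended for diagnostics
    such as density-ascent checks.
    """
    if not (0 <= row < img.height and 0 <= col < img.width):
        raise IndexError("pixel outside image")
    _, gval = _quantized(img)
    H, W = gval.shape
    radius = TRUNCATE * p.h_s
    yr, yc, yg = float(row), float(col), float(gval[row, col])
    states = [(yr, yc, yg, max(float(gray_bandwidth(yg, p)), HG_FLOOR))]
    for _ in range(max_iter):
        hg = max(float(gray_bandwidth(yg, p)), HG_FLOOR)
        rlo = max(0, int(math.floor(yr - radius)))
        rhi = min(H - 1, int(math.ceil(yr + radius)))
        clo = max(0, int(math.floor(yc - radius)))
        chi = min(W - 1, int(math.ceil(yc + radius)))
        rr, cc = np.mgrid[rlo : rhi + 1, clo : chi + 1]
        gg = gval[rlo : rhi + 1, clo : chi + 1]
        w = np.exp(
            -((rr - yr) ** 2 + (cc - yc) ** 2) / (2 * p.h_s**2)
            - (gg - yg) ** 2 / (2 * hg**2)
        )
        sw = w.sum()
        nr, nc, ng = (w * rr).sum() / sw, (w * cc).sum() / sw, (w * gg).sum() / sw
        gshift = abs(ng - yg)
        yr, yc, yg = nr, nc, ng
        states.append((yr, yc, yg, max(float(gray_bandwidth(yg, p)), HG_FLOOR)))
        if gshift < tol:
            break
    return np.asarray(states)


@njit
def _kde_many(gidx, pr, pc, pg, f_max, t_roi, z_t, sigma_roi, h_s, adaptive, radius):
    """Joint KDE of the image samples, evaluated at points (pr, pc, pg).

    Samples outside ``radius`` of the evaluation point are skipped, the
    same spatial truncation the filter uses.
    """
    H, W = gidx.shape
    n = pr.shape[0]
    out = np.empty(n)
    inv2hs2 = 1.0 / (2.0 * h_s * h_s)
    norm0 = 1.0 / (H * W * (2.0 * math.pi) ** 1.5 * h_s * h_s)
    etab = np.empty(_NGRAY)
    for k in range(n):
        if adaptive:
            u = (pg[k] - t_roi) / sigma_roi
            hg = f_max * (1.0 - z_t * math.exp(-0.5 * u * u))
            if hg < 1e-2:
                hg = 1e-2
        else:
            hg = f_max
        inv2hg2 = 1.0 / (2.0 * hg * hg)
        for j in range(_NGRAY):
            d = j - pg[k]
            etab[j] = math.exp(-d * d * inv2hg2)
        rlo = max(0, int(math.floor(pr[k] - radius)))
        rhi = min(H - 1, int(math.ceil(pr[k] + radius)))
        clo = max(0, int(math.floor(pc[k] - radius)))
        chi = min(W - 1, int(math.ceil(pc[k] + radius)))
        s = 0.0
        for r in range(rlo, rhi + 1):
            dr = r - pr[k]
            er = math.exp(-dr * dr * inv2hs2)
            rs = 0.0
            for c in range(clo, chi + 1):
                dc = c - pc[k]
                rs += math.exp(-dc * dc * inv2hs2) * etab[gidx[r, c]]
            s += er * rs
        out[k] = s * norm0 / hg
    return out


def kde_values(
    img: GrayImage,
    points: np.ndarray,
    p: BandwidthParams,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Joint (space, gray) kernel density of the image samples.

    ``points`` is an (n, 3) array of (row, col, gray) evaluation points.
    With adaptive bandwidths the gray bandwidth is taken at each
    evaluation point's gray value (balloon-estimator convention) unless
    ``bandwidth`` pins it explicitly.  Sample grays are snapped to the
    same 8-bit grid the filter uses.
    """
    pts = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    gidx, _ = _quantized(img)
    radius = TRUNCATE * p.h_s
    if bandwidth is not None:
        return _kde_many(
            gidx, pts[:, 0].copy(), pts[:, 1].copy(), pts[:, 2].copy(),
            float(bandwidth), p.t_roi, 0.0, p.sigma_roi, p.h_s, False, radius,
        )
    return _kde_many(
        gidx, pts[:, 0].copy(), pts[:, 1].copy(), pts[:, 2].copy(),
        p.f_max, p.t_roi, p.z_t, p.sigma_roi, p.h_s, p.adaptive, radius,
    )
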