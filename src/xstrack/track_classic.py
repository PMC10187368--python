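"""Classical windowed speckle trackers: ZNCC and UMPA.

Both trackers compare, for every pixel, a (2M+1)x(2M+1) window of the sample
image against windows of the reference displaced by integer candidate shifts
within a search radius, then refine the best integer shift to sub-pixel
precision from the local shape of the correlation (ZNCC, separable Gaussian
peak fit) or cost surface (UMPA, 2D paraboloid fit).

ZNCC maximizes the zero-normalized cross-correlation of mean-subtracted
windows.  UMPA minimizes the windowed squared residual between the sample and
a transmission-scaled shifted reference, solving for the scalar transmission T
in closed form at every candidate shift, and therefore also returns a T map.

The implementation is dense (stride 1) and fully vectorized: windowed sums are
separable box/taper filters, so the cost volume over all pixels and shifts is
built in O(n_shifts * n_pixels).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

from .deform import DisplacementField
from .wave_optics import SpeckleImage

__all__ = [
    "TrackerConfig",
    "TrackingResult",
    "gaussian_subpixel",
    "paraboloid_subpixel",
    "zncc_track",
    "umpa_track",
]

_EPS = 1e-12


@dataclass
class TrackerConfig:
    """Window and search settings shared by the classical trackers.

    half_window : M, window side is 2M+1 pixels
    search_radius : largest integer shift tested per axis
    window_function : "uniform" or "hamming" taper
    """

    half_window: int = 15
    search_radius: int = 3
    window_function: str = "uniform"

    def __post_init__(self) -> None:
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.search_radius < 1:
            raise ValueError("search_radius must be >= 1")
        if self.window_function not in ("uniform", "hamming"):
            raise ValueError("window_function must be 'uniform' or 'hamming'")


@dataclass
class TrackingResult:
    displacement: DisplacementField
    valid_mask: NDArray[np.bool_]
    quality: NDArray[np.floating]
    transmission: NDArray[np.floating] | None = None
    config: TrackerConfig | None = None


def _as_array(img) -> NDArray[np.floating]:
    if isinstance(img, SpeckleImage):
        return img.data
    return np.asarray(img, dtype=np.float64)


def _window_mean(a: NDArray, config: TrackerConfig) -> NDArray:
    size = 2 * config.half_window + 1
    if config.window_function == "uniform":
        return ndimage.uniform_filter(a, size=size, mode="constant")
    w = np.hamming(size)
    w /= w.sum()
    out = ndimage.correlate1d(a, w, axis=0, mode="constant")
    return ndimage.correlate1d(out, w, axis=1, mode="constant")


def _shift_order(radius: int) -> list[tuple[int, int]]:
    # smallest |shift| first, then lexicographic: argmax/argmin pick the first
    # occurrence, implementing the documented tie-break
    shifts = [(dy, dx) for dy in range(-radius, radius + 1) for dx in range(-radius, radius + 1)]
    shifts.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    return shifts


# ----------------------------------------------------------------------------
# sub-pixel refinement primitives


def gaussian_subpixel(triple: NDArray) -> tuple[NDArray, NDArray]:
    """Per-axis Gaussian peak interpolation of a 3-point correlation section.

    ``triple`` holds (c_-1, c_0, c_+1) in its last axis; values must be
    positive with the centre a local maximum.  Returns ``(offset, ok)`` where
    the offset is (ln c_-1 - ln c_+1) / (2 (ln c_-1 - 2 ln c_0 + ln c_+1)),
    clamped to [-0.5, 0.5]; degenerate inputs give offset 0 with ok False.
    """
    t = np.asarray(triple, dtype=np.float64)
    cm, c0, cp = t[..., 0], t[..., 1], t[..., 2]
    ok = (cm > 0) & (c0 > 0) & (cp > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lm = np.where(ok, np.log(np.where(ok, cm, 1.0)), 0.0)
        l0 = np.where(ok, np.log(np.where(ok, c0, 1.0)), 0.0)
        lp = np.where(ok, np.log(np.where(ok, cp, 1.0)), 0.0)
        denom = 2.0 * (lm - 2.0 * l0 + lp)
        ok = ok & (denom < -_EPS)
        offset = np.where(ok, (lm - lp) / np.where(ok, denom, 1.0), 0.0)
    offset = np.clip(offset, -0.5, 0.5)
    return offset, ok


# constant normal-equation inverse for the (1, x^2, y^2) block of the 3x3
# paraboloid least-squares fit (columns 1, x, y, x^2, y^2, xy on offsets -1..1)
_PARAB_M_INV = np.linalg.inv(np.array([[9.0, 6.0, 6.0], [6.0, 6.0, 4.0], [6.0, 4.0, 6.0]]))


def paraboloid_subpixel(neigh: NDArray) -> tuple[NDArray, NDArray, NDArray]:
    """Stationary point of a least-squares 2D quadratic fit to 3x3 costs.

    ``neigh`` has shape (..., 3, 3) with the centre a local minimum (row axis
    = y, column axis = x).  Returns ``(dx, dy, ok)`` with each offset clamped
    to [-0.5, 0.5]; a non-positive-definite Hessian gives (0, 0) and ok False.
    """
    f = np.asarray(neigh, dtype=np.float64)
    y = np.array([-1.0, 0.0, 1.0])[:, None]
    x = np.array([-1.0, 0.0, 1.0])[None, :]
    s1 = f.sum(axis=(-2, -1))
    sx = (f * x).sum(axis=(-2, -1))
    sy = (f * y).sum(axis=(-2, -1))
    sxx = (f * x * x).sum(axis=(-2, -1))
    syy = (f * y * y).sum(axis=(-2, -1))
    sxy = (f * x * y).sum(axis=(-2, -1))
    b = sx / 6.0
    c = sy / 6.0
    g = sxy / 4.0
    rhs = np.stack([s1, sxx, syy], axis=-1)
    ade = rhs @ _PARAB_M_INV.T
    d, e = ade[..., 1], ade[..., 2]
    # minimum requires Hessian [[2d, g], [g, 2e]] positive definite
    det = 4.0 * d * e - g * g
    ok = (d > _EPS) & (det > _EPS)
    det_safe = np.where(ok, det, 1.0)
    dx = np.where(ok, (-2.0 * e * b + g * c) / det_safe, 0.0)
    dy = np.where(ok, (-2.0 * d * c + g * b) / det_safe, 0.0)
    return np.clip(dx, -0.5, 0.5), np.clip(dy, -0.5, 0.5), ok


# ----------------------------------------------------------------------------
# cost-volume machinery


def _gather(volume: NDArray, iy: NDArray, ix: NDArray) -> NDArray:
    """volume[(iy, ix), pixel] for per-pixel shift indices."""
    s = volume.shape[0]
    flat = volume.reshape(s * s, -1)
    return flat[iy.ravel() * s + ix.ravel(), np.arange(flat.shape[1])].reshape(iy.shape)


def _border_mask(shape: tuple[int, int], margin: int) -> NDArray[np.bool_]:
    mask = np.zeros(shape, dtype=bool)
    if margin < min(shape) // 2:
        mask[margin : shape[0] - margin, margin : shape[1] - margin] = True
    return mask


def zncc_track(reference, sample, config: TrackerConfig | None = None) -> TrackingResult:
    """Dense zero-normalized cross-correlation tracking with Gaussian peak fit.

    For every valid pixel the ZNCC between the mean-subtracted sample window
    and mean-subtracted reference windows shifted by all integer displacements
    within the search radius is evaluated; the argmax is refined per axis by a
    3-point Gaussian fit.  Flat (zero-variance) windows are marked invalid.
    """
    config = config or TrackerConfig()
    ref = _as_array(reference)
    sam = _as_array(sample)
    if ref.shape != sam.shape:
        raise ValueError("reference and sample must have the same shape")
    radius = config.search_radius
    nshift = 2 * radius + 1
    shifts = _shift_order(radius)

    sm = _window_mean(sam, config)
    svar = _window_mean(sam * sam, config) - sm * sm
    corr_sorted = np.empty((len(shifts),) + ref.shape, dtype=np.float32)
    corr = np.empty((nshift, nshift) + ref.shape, dtype=np.float32)
    for k, (dy, dx) in enumerate(shifts):
        rs = np.roll(ref, (dy, dx), axis=(0, 1))
        rm = _window_mean(rs, config)
        rvar = _window_mean(rs * rs, config) - rm * rm
        cov = _window_mean(sam * rs, config) - sm * rm
        denom = np.sqrt(np.clip(svar * rvar, 0.0, None))
        good = denom > _EPS * max(1.0, float(np.abs(sam).max()) ** 2)
        c = np.where(good, cov / np.where(good, denom, 1.0), -np.inf)
        corr_sorted[k] = c
        corr[dy + radius, dx + radius] = c

    best = np.argmax(corr_sorted, axis=0)
    sy = np.array([s[0] for s in shifts])[best]
    sx = np.array([s[1] for s in shifts])[best]
    iy = sy + radius
    ix = sx + radius
    interior = (iy > 0) & (iy < nshift - 1) & (ix > 0) & (ix < nshift - 1)
    iyc = np.clip(iy, 1, nshift - 2)
    ixc = np.clip(ix, 1, nshift - 2)
    peak = _gather(corr, iyc, ixc)
    # correlation values can be negative; lift before the log-Gaussian fit
    lift = 1.0 + 1e-6
    tri_x = np.stack(
        [_gather(corr, iyc, ixc - 1) + lift, peak + lift, _gather(corr, iyc, ixc + 1) + lift],
        axis=-1,
    )
    tri_y = np.stack(
        [_gather(corr, iyc - 1, ixc) + lift, peak + lift, _gather(corr, iyc + 1, ixc) + lift],
        axis=-1,
    )
    off_x, _okx = gaussian_subpixel(tri_x)
    off_y, _oky = gaussian_subpixel(tri_y)
    # a numerically perfect integer match admits no sub-pixel refinement
    perfect = peak > 1.0 - 1e-6
    refine = interior & ~perfect
    ux = np.where(refine, sx + off_x, sx)
    uy = np.where(refine, sy + off_y, sy)

    margin = config.half_window + radius
    valid = _border_mask(ref.shape, margin) & np.isfinite(peak) & (peak > -1.5)
    quality = np.where(np.isfinite(peak), peak, 0.0)
    return TrackingResult(
        displacement=DisplacementField(ux, uy),
        valid_mask=valid,
        quality=quality,
        config=config,
    )


def umpa_track(reference, sample, config: TrackerConfig | None = None) -> TrackingResult:
    """Dense UMPA tracking: windowed least squares in transmission and shift.

    At every candidate integer shift the windowed residual
    sum w (I_s - T I_r(x+u))^2 is minimized over the scalar transmission T in
    closed form (T = <I_s I_r(x+u)> / <I_r(x+u)^2>); the residual surface is
    minimized over shifts and refined with a 3x3 paraboloid fit.  Windows with
    vanishing reference energy (singular T solve) are marked invalid.
    """
    config = config or TrackerConfig()
    ref = _as_array(reference)
    sam = _as_array(sample)
    if ref.shape != sam.shape:
        raise ValueError("reference and sample must have the same shape")
    radius = config.search_radius
    nshift = 2 * radius + 1
    shifts = _shift_order(radius)

    ss = _window_mean(sam * sam, config)
    scale = max(float(np.abs(ref).max()) ** 2, _EPS)
    cost_sorted = np.empty((len(shifts),) + ref.shape, dtype=np.float32)
    cost = np.empty((nshift, nshift) + ref.shape, dtype=np.float32)
    tmap_all = np.empty((nshift, nshift) + ref.shape, dtype=np.float32)
    singular_center = None
    for k, (dy, dx) in enumerate(shifts):
        rs = np.roll(ref, (dy, dx), axis=(0, 1))
        srr = _window_mean(rs * rs, config)
        ssr = _window_mean(sam * rs, config)
        good = srr > _EPS * scale
        t = np.where(good, ssr / np.where(good, srr, 1.0), 0.0)
        c = np.where(good, ss - t * ssr, np.inf)
        cost_sorted[k] = c
        cost[dy + radius, dx + radius] = c
        tmap_all[dy + radius, dx + radius] = t
        if dy == 0 and dx == 0:
            singular_center = ~good

    best = np.argmin(cost_sorted, axis=0)
    sy = np.array([s[0] for s in shifts])[best]
    sx = np.array([s[1] for s in shifts])[best]
    iy = sy + radius
    ix = sx + radius
    interior = (iy > 0) & (iy < nshift - 1) & (ix > 0) & (ix < nshift - 1)
    iyc = np.clip(iy, 1, nshift - 2)
    ixc = np.clip(ix, 1, nshift - 2)
    neigh = np.empty(ref.shape + (3, 3), dtype=np.float64)
    for j in (-1, 0, 1):
        for i in (-1, 0, 1):
            neigh[..., j + 1, i + 1] = _gather(cost, iyc + j, ixc + i)
    off_x, off_y, _ok = paraboloid_subpixel(neigh)
    tmap = _gather(tmap_all, iy, ix)
    min_cost = _gather(cost, iy, ix)
    # a numerically perfect integer match (zero residual) is not refined
    perfect = min_cost < 1e-10 * scale
    refine = interior & ~perfect
    ux = np.where(refine, sx + off_x, sx)
    uy = np.where(refine, sy + off_y, sy)

    margin = config.half_window + radius
    valid = _border_mask(ref.shape, margin) & np.isfinite(min_cost)
    if singular_center is not None:
        valid &= ~singular_center
    return TrackingResult(
        displacement=DisplacementField(ux, uy),
        valid_mask=valid,
        quality=np.where(np.isfinite(min_cost), min_cost, np.inf),
        transmission=tmap.astype(np.float64),
        config=config,
    )
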