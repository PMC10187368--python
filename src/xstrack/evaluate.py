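"""Tracker evaluation protocol: accuracy, spatial resolution, noise/window sweeps, timing.

Accuracy is measured on constant displacement maps (0 to 1 px in 0.1 px
steps) applied to independently simulated speckle references with 90%
transmission and Poisson noise; reported per pair are the relative bias of
the mean recovered displacement,

    bias = (u_GT - mean(u)) / u_GT,

and the root-mean-square error RMSE = sqrt(mean((u - u_GT)^2)).  Spatial
resolution uses a star displacement map — a unidirectional sinusoid of
constant 0.5 px amplitude whose wavelength shrinks linearly toward the left —
and is defined as the wavelength at which the moving-averaged amplitude bias
reaches 10%.  Additional sweeps vary the Poisson noise level (expressed as a
loss of image SNR, mapped to fluence via SNR ~ sqrt(fluence)) and the
correlation window size, and time the trackers against image size.

A tracker here is any callable ``tracker(reference, sample, truth=None) ->
(DisplacementField, valid_mask)``; classical trackers, the CNN and a
ground-truth oracle all fit this signature.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from . import track_classic
from .deform import DisplacementField, add_poisson_noise, apply_transmission, warp
from .wave_optics import SpeckleImage

__all__ = [
    "MetricResult",
    "StarPattern",
    "ResolutionResult",
    "bias",
    "rmse",
    "make_zncc_tracker",
    "make_umpa_tracker",
    "make_cnn_tracker",
    "oracle_tracker",
    "apply_noise_and_transmission",
    "accuracy_sweep",
    "grand_means",
    "make_star_pattern",
    "star_bias_profile",
    "find_bias_crossing",
    "spatial_resolution",
    "noise_sweep",
    "window_sweep",
    "timing",
]

DEFAULT_FLUENCE = 10000.0  # photons per pixel for the reference noise level


# ----------------------------------------------------------------------------
# metrics


def bias(prediction, truth, mask: NDArray | None = None) -> float:
    """Relative bias of the mean prediction against a constant-truth map.

    For a region where the ground truth is the constant u_GT this is
    (u_GT - mean(u)) / u_GT; it is undefined (raises) when the truth is zero
    over the whole region.
    """
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    if mask is not None:
        p, t = p[mask], t[mask]
    t_mean = t.mean()
    if t_mean == 0.0:
        raise ZeroDivisionError(
            "bias is undefined for zero ground truth; use the mean error instead"
        )
    return float((t_mean - p.mean()) / t_mean)


def rmse(prediction, truth, mask: NDArray | None = None) -> float:
    """Root-mean-square of the per-pixel scalar error."""
    p = np.asarray(prediction, dtype=np.float64)
    t = np.asarray(truth, dtype=np.float64)
    if p.shape != t.shape:
        raise ValueError("shape mismatch")
    d = p - t
    if mask is not None:
        d = d[mask]
    return float(np.sqrt(np.mean(d**2)))


@dataclass
class MetricResult:
    algorithm: str
    condition: dict
    bias: float | None
    rmse: float
    n: int


# ----------------------------------------------------------------------------
# tracker adapters


def make_zncc_tracker(config: track_classic.TrackerConfig | None = None):
    config = config or track_classic.TrackerConfig()

    def tracker(ref, sam, truth=None):
        res = track_classic.zncc_track(ref, sam, config)
        return res.displacement, res.valid_mask

    tracker.__name__ = "zncc"
    return tracker


def make_umpa_tracker(config: track_classic.TrackerConfig | None = None):
    config = config or track_classic.TrackerConfig()

    def tracker(ref, sam, truth=None):
        res = track_classic.umpa_track(ref, sam, config)
        return res.displacement, res.valid_mask

    tracker.__name__ = "umpa"
    return tracker


def make_cnn_tracker(model, border: int = 18):
    """Wrap a trained CADE model; the border margin mirrors the classical
    trackers' invalid frame so comparisons use matching regions."""
    from .track_cnn import predict

    def tracker(ref, sam, truth=None):
        fieldd = predict(model, ref, sam)
        mask = np.zeros(fieldd.shape, dtype=bool)
        mask[border:-border, border:-border] = True
        return fieldd, mask

    tracker.__name__ = "cade"
    return tracker


def oracle_tracker(ref, sam, truth=None):
    """Ground-truth passthrough used to test the evaluation plumbing."""
    if truth is None:
        raise ValueError("oracle tracker requires the ground-truth field")
    mask = np.ones(truth.shape, dtype=bool)
    return truth, mask


# ----------------------------------------------------------------------------
# accuracy sweep


def apply_noise_and_transmission(
    reference: SpeckleImage,
    sample: SpeckleImage,
    rng: np.random.Generator,
    transmission: float = 0.9,
    fluence: float = DEFAULT_FLUENCE,
) -> tuple[SpeckleImage, SpeckleImage]:
    """Uniform sample transmission plus independent Poisson noise on both images."""
    sam = SpeckleImage(sample.data * transmission, sample.pixel_pitch, dict(sample.meta))
    ref_n = add_poisson_noise(reference, fluence, seed=rng)
    sam_n = add_poisson_noise(sam, fluence, seed=rng)
    return ref_n, sam_n


def accuracy_sweep(
    trackers: dict[str, callable],
    references: list[SpeckleImage],
    shifts: NDArray | None = None,
    transmission: float = 0.9,
    fluence: float = DEFAULT_FLUENCE,
    seed: int = 0,
) -> pd.DataFrame:
    """Constant-shift accuracy protocol.

    Each reference is warped by every constant displacement map (shift along
    x), transmission and Poisson noise are applied, every tracker runs, and
    bias/RMSE are recorded per (algorithm, shift, reference).  Bias is omitted
    at zero shift where it is undefined.
    """
    if shifts is None:
        shifts = np.round(np.arange(0.0, 1.05, 0.1), 10)
    rows = []
    for r_i, ref in enumerate(references):
        for shift in shifts:
            fieldd = DisplacementField.constant(ref.shape, float(shift), 0.0)
            sam = warp(ref, fieldd)
            rng = np.random.default_rng((seed, r_i, int(round(shift * 10))))
            ref_n, sam_n = apply_noise_and_transmission(ref, sam, rng, transmission, fluence)
            for name, tracker in trackers.items():
                pred, mask = tracker(ref_n, sam_n, truth=fieldd)
                b = None
                if shift != 0.0:
                    b = bias(pred.ux, fieldd.ux, mask)
                rows.append(
                    {
                        "algorithm": name,
                        "shift": float(shift),
                        "reference": r_i,
                        "bias": b,
                        "rmse_x": rmse(pred.ux, fieldd.ux, mask),
                        "rmse_y": rmse(pred.uy, fieldd.uy, mask),
                        "n": int(mask.sum()),
                    }
                )
    return pd.DataFrame(rows)


def grand_means(table: pd.DataFrame) -> pd.DataFrame:
    """Headline per-algorithm numbers: mean RMSE over all shifts and references
    and mean |bias| over the nonzero shifts."""
    out = []
    for name, g in table.groupby("algorithm"):
        out.append(
            {
                "algorithm": name,
                "mean_rmse": g["rmse_x"].mean(),
                "mean_abs_bias": g["bias"].dropna().abs().mean(),
            }
        )
    return pd.DataFrame(out).set_index("algorithm")


# ----------------------------------------------------------------------------
# star pattern / spatial resolution


@dataclass
class StarPattern:
    field: DisplacementField
    wavelength_map: NDArray[np.floating]  # local wavelength per column, px
    phase: NDArray[np.floating]  # accumulated phase per column
    amplitude: float


@dataclass
class ResolutionResult:
    limiting_wavelength: float
    crossed: bool
    wavelengths: NDArray[np.floating]
    bias_profile: NDArray[np.floating]
    bias_profile_raw: NDArray[np.floating]


def make_star_pattern(
    shape: tuple[int, int] = (256, 256),
    amplitude: float = 0.5,
    wavelength_range: tuple[float, float] = (4.0, 200.0),
) -> StarPattern:
    """Unidirectional sinusoidal displacement with wavelength shrinking leftward.

    The local wavelength decreases linearly from ``wavelength_range[1]`` at
    the right edge to ``wavelength_range[0]`` at the left edge; the amplitude
    is exactly ``amplitude`` pixels on every row (in particular on the central
    row), and the transverse component is zero.
    """
    lam_min, lam_max = wavelength_range
    if lam_min < 2.0:
        raise ValueError("wavelengths below 2 px are unresolvable")
    if lam_min >= lam_max:
        raise ValueError("wavelength_range must be increasing")
    h, w = shape
    cols = np.arange(w)
    lam = lam_min + (lam_max - lam_min) * cols / (w - 1)
    phase = np.concatenate([[0.0], np.cumsum(2.0 * np.pi / lam[1:])])
    ux_row = amplitude * np.sin(phase)
    ux = np.broadcast_to(ux_row, shape).copy()
    return StarPattern(
        field=DisplacementField(ux, np.zeros(shape)),
        wavelength_map=lam,
        phase=phase,
        amplitude=amplitude,
    )


def star_bias_profile(
    recovered: DisplacementField,
    star: StarPattern,
    mask: NDArray | None = None,
) -> NDArray[np.floating]:
    """Per-column amplitude bias of a recovered star displacement.

    The row-averaged recovered profile is fitted, in a sliding one-period
    window, against the known quadrature pair (sin, cos of the star phase);
    the recovered local amplitude A(c) gives bias(c) = 1 - A(c)/A_true.
    """
    import warnings as _warnings

    u = np.where(mask, recovered.ux, np.nan) if mask is not None else recovered.ux
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN border columns
        prof = np.nanmean(u, axis=0)
    w = len(prof)
    phase = star.phase
    out = np.full(w, np.nan)
    for c in range(w):
        lo, hi = c, c
        while lo > 0 and phase[c] - phase[lo - 1] <= np.pi:
            lo -= 1
        while hi < w - 1 and phase[hi + 1] - phase[c] <= np.pi:
            hi += 1
        seg = slice(lo, hi + 1)
        y = prof[seg]
        good = np.isfinite(y)
        if good.sum() < 8:
            continue
        design = np.column_stack([np.sin(phase[seg][good]), np.cos(phase[seg][good])])
        coef, *_ = np.linalg.lstsq(design, y[good], rcond=None)
        out[c] = 1.0 - float(np.hypot(*coef)) / star.amplitude
    return out


def find_bias_crossing(
    wavelengths: NDArray, bias_profile: NDArray, threshold: float = 0.10
) -> tuple[float, bool]:
    """Largest wavelength at which the bias profile first exceeds the threshold.

    Scans from long to short wavelengths; returns ``(wavelength, crossed)``
    with the minimum wavelength and ``crossed=False`` when the profile never
    reaches the threshold.
    """
    order = np.argsort(wavelengths)[::-1]
    lam = np.asarray(wavelengths, dtype=np.float64)[order]
    b = np.asarray(bias_profile, dtype=np.float64)[order]
    prev_lam, prev_b = None, None
    for L, bb in zip(lam, b):
        if not np.isfinite(bb):
            continue
        if bb >= threshold:
            if prev_b is not None and bb != prev_b:
                frac = (threshold - prev_b) / (bb - prev_b)
                return float(prev_lam + frac * (L - prev_lam)), True
            return float(L), True
        prev_lam, prev_b = L, bb
    return float(np.nanmin(lam)), False


def _moving_average(a: NDArray, window: int) -> NDArray:
    out = np.full_like(a, np.nan)
    half = window // 2
    for i in range(len(a)):
        seg = a[max(0, i - half) : i + half + 1]
        good = np.isfinite(seg)
        if good.any():
            out[i] = seg[good].mean()
    return out


def spatial_resolution(
    tracker,
    reference_pairs: list[tuple[SpeckleImage, SpeckleImage]],
    star: StarPattern,
    moving_avg_window: int | None = None,
    threshold: float = 0.10,
) -> ResolutionResult:
    """Limiting wavelength at which the moving-averaged star bias reaches 10%.

    ``reference_pairs`` are (noisy reference, noisy star-warped sample) pairs;
    bias profiles are averaged over pairs, moving-averaged along the
    wavelength axis (default window: one tenth of the axis span), and scanned
    from long to short wavelengths for the first threshold crossing.
    """
    import warnings as _warnings

    profiles = []
    for ref_n, sam_n in reference_pairs:
        pred, mask = tracker(ref_n, sam_n, truth=star.field)
        profiles.append(star_bias_profile(pred, star, mask))
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN border columns
        raw = np.nanmean(np.stack(profiles), axis=0)
    if moving_avg_window is None:
        moving_avg_window = max(3, len(raw) // 10)
    smooth = _moving_average(raw, moving_avg_window)
    lam_limit, crossed = find_bias_crossing(star.wavelength_map, smooth, threshold)
    return ResolutionResult(
        limiting_wavelength=lam_limit,
        crossed=crossed,
        wavelengths=star.wavelength_map,
        bias_profile=smooth,
        bias_profile_raw=raw,
    )


def star_pairs(
    references: list[SpeckleImage],
    star: StarPattern,
    transmission: float = 0.9,
    fluence: float = DEFAULT_FLUENCE,
    seed: int = 0,
) -> list[tuple[SpeckleImage, SpeckleImage]]:
    """Warp references by the star field and apply the standard noise protocol."""
    pairs = []
    for r_i, ref in enumerate(references):
        sam = warp(ref, star.field)
        rng = np.random.default_rng((seed, r_i, 777))
        pairs.append(apply_noise_and_transmission(ref, sam, rng, transmission, fluence))
    return pairs


# ----------------------------------------------------------------------------
# noise / window sweeps, timing


def gradient_field(shape: tuple[int, int], max_shift: float = 1.0) -> DisplacementField:
    """Linear horizontal-gradient displacement from 0 (left) to max_shift (right)."""
    h, w = shape
    ux = np.broadcast_to(np.linspace(0.0, max_shift, w), shape).copy()
    return DisplacementField(ux, np.zeros(shape))


def snr_loss_to_fluence(loss_percent: float, base_fluence: float = DEFAULT_FLUENCE) -> float:
    """Map a stated SNR loss (percent) to a Poisson fluence via SNR ~ sqrt(fluence)."""
    return base_fluence * (1.0 - loss_percent / 100.0) ** 2

def noise_sweep(
    trackers: dict[str, callable],
    references: list[SpeckleImage],
    snr_loss_levels: NDArray | None = None,
    transmission: float = 0.9,
    base_fluence: float = DEFAULT_FLUENCE,
    seed: int = 0,
) -> pd.DataFrame:
    """RMSE per tracker per noise level on the linear-gradient deformation.

    Noise levels are coupled by sequential photon thinning: the photon counts
    are drawn once per image at the base fluence and each subsequent level is
    binomially thinned from the previous one, so moving along the sweep only
    ever removes photons and the noise trend is not swamped by
    independent-realization variance.
    """
    if snr_loss_levels is None:
        snr_loss_levels = np.arange(0.0, 7.0)
    levels = sorted(float(x) for x in snr_loss_levels)
    rows = []
    for r_i, ref in enumerate(references):
        fieldd = gradient_field(ref.shape)
        sam = warp(ref, fieldd)
        sam = SpeckleImage(sam.data * transmission, sam.pixel_pitch, dict(sam.meta))
        rng = np.random.default_rng((seed, r_i))
        scale_r = base_fluence / ref.data.mean()
        scale_s = base_fluence / sam.data.mean()
        cr = rng.poisson(np.clip(ref.data * scale_r, 0, None))
        cs = rng.poisson(np.clip(sam.data * scale_s, 0, None))
        prev_keep = 1.0
        for level in levels:
            fluence = snr_loss_to_fluence(level, base_fluence)
            keep = fluence / base_fluence
            if keep < prev_keep:
                cr = rng.binomial(cr, keep / prev_keep)
                cs = rng.binomial(cs, keep / prev_keep)
                prev_keep = keep
            ref_n = SpeckleImage(cr / (scale_r * keep), ref.pixel_pitch, dict(ref.meta))
            sam_n = SpeckleImage(cs / (scale_s * keep), sam.pixel_pitch, dict(sam.meta))
            for name, tracker in trackers.items():
                pred, mask = tracker(ref_n, sam_n, truth=fieldd)
                rows.append(
                    {
                        "algorithm": name,
                        "snr_loss_percent": float(level),
                        "reference": r_i,
                        "rmse_x": rmse(pred.ux, fieldd.ux, mask),
                        "n": int(mask.sum()),
                    }
                )
    return pd.DataFrame(rows)


def window_sweep(
    references: list[SpeckleImage],
    windows: tuple[int, ...] = (11, 15, 21, 31, 41, 51),
    star: StarPattern | None = None,
    cnn_tracker=None,
    transmission: float = 0.9,
    fluence: float = DEFAULT_FLUENCE,
    seed: int = 0,
) -> pd.DataFrame:
    """Accuracy (gradient-map RMSE) and star resolution versus window size.

    Window sizes are full widths 2M+1; the CNN, when given, is evaluated once
    and repeated across the window column as the window-independent baseline.
    """
    star = star or make_star_pattern(references[0].shape)
    rows = []
    grad = gradient_field(references[0].shape)
    grad_pairs = []
    for r_i, ref in enumerate(references):
        sam = warp(ref, grad)
        rng = np.random.default_rng((seed, r_i, 55))
        grad_pairs.append(apply_noise_and_transmission(ref, sam, rng, transmission, fluence))
    s_pairs = star_pairs(references, star, transmission, fluence, seed)

    def eval_tracker(name, tracker, window):
        rmses = []
        for ref_n, sam_n in grad_pairs:
            pred, mask = tracker(ref_n, sam_n, truth=grad)
            rmses.append(rmse(pred.ux, grad.ux, mask))
        res = spatial_resolution(tracker, s_pairs, star)
        rows.append(
            {
                "algorithm": name,
                "window": window,
                "rmse_x": float(np.mean(rmses)),
                "limiting_wavelength": res.limiting_wavelength,
                "crossed": res.crossed,
            }
        )

    for win in windows:
        m = max(1, (win - 1) // 2)
        cfg = track_classic.TrackerConfig(half_window=m)
        eval_tracker("zncc", make_zncc_tracker(cfg), win)
        eval_tracker("umpa", make_umpa_tracker(cfg), win)
    if cnn_tracker is not None:
        eval_tracker("cade", cnn_tracker, windows[0])
        base = [r for r in rows if r["algorithm"] == "cade"][0]
        for win in windows[1:]:
            rows.append({**base, "window": win})
    return pd.DataFrame(rows)


def timing(
    trackers: dict[str, callable],
    sizes: tuple[int, ...] = (256, 512, 768),
    n_pairs: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Wall-clock time per tracker per image size, with a linear fit in pixels.

    Numbers are environment-relative measurements, logged rather than asserted.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        ref = SpeckleImage(1.0 + 0.3 * rng.standard_normal((size, size)))
        sam = warp(ref, DisplacementField.constant((size, size), 0.3, -0.2))
        for name, tracker in trackers.items():
            t0 = time.perf_counter()
            for _ in range(n_pairs):
                tracker(ref, sam, truth=None)
            dt = (time.perf_counter() - t0) / n_pairs
            rows.append({"algorithm": name, "size": size, "n_pixels": size * size, "seconds": dt})
    table = pd.DataFrame(rows)
    fits = []
    for name, g in table.groupby("algorithm"):
        slope, intercept = np.polyfit(g["n_pixels"], g["seconds"], 1)
        pred = slope * g["n_pixels"] + intercept
        ss_res = float(np.sum((g["seconds"] - pred) ** 2))
        ss_tot = float(np.sum((g["seconds"] - g["seconds"].mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        fits.append({"algorithm": name, "seconds_per_pixel": slope, "r_squared": r2})
    table.attrs["linear_fit"] = fits
    return table
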