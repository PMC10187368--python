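"""Wave-optics simulation of speckle-based x-ray phase-contrast image formation.

The imaging chain is: a monochromatic point source illuminates a stack of
sandpaper diffuser layers, the disturbed wavefield propagates to the detector
plane (optionally traversing a sample), and the detector integrates the
intensity over finite pixels with a Gaussian point-spread function.  Free-space
propagation uses the band-limited angular-spectrum method; objects enter in
projection approximation (a thin-object transmission function built from the
projected thickness, the refractive index decrement ``delta`` and the linear
attenuation coefficient ``mu``).

The divergent (cone-beam) geometry is handled with the Fresnel scaling theorem:
an equivalent parallel-beam system is simulated at the object plane with the
effective propagation distance ``z_eff = z1*z2/(z1+z2)`` and the result is read
out on a grid magnified by ``M = (z1+z2)/z1``.  The source focal spot enters as
a Gaussian blur of the detected image with FWHM ``focal_spot * z2/z1``
(source-size convolution theorem).

Internal length unit for wavefields is micrometres; geometry distances along
the optical axis are given in metres and converted at the boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import NDArray
from scipy import fft as sp_fft
from scipy import ndimage

__all__ = [
    "OPTICAL_CONSTANTS",
    "wavelength_from_energy",
    "WaveField",
    "ImagingGeometry",
    "SampleModel",
    "DiffuserSpec",
    "SpeckleImage",
    "AliasingError",
    "plane_wave",
    "propagate",
    "apply_object",
    "synthesize_diffuser",
    "detect",
    "simulate_pair",
    "speckle_visibility",
    "autocorrelation_fwhm",
]

M_TO_UM = 1.0e6

# delta (refractive index decrement) and mu (linear attenuation, 1/um) at
# 30 keV.  delta computed from r_e * lambda^2 * n_e / (2*pi) with bulk
# densities 3.95 (Al2O3), 1.101 (diethyl pyrocarbonate C6H10O5), 1.19 (PMMA)
# g/cm^3; mu from NIST XCOM mass-attenuation coefficients at 30 keV.
OPTICAL_CONSTANTS: dict[str, dict[str, float]] = {
    "Al2O3": {"delta": 8.94e-07, "mu": 3.06e-04},
    "C6H10O5": {"delta": 2.69e-07, "mu": 3.55e-05},
    "PMMA": {"delta": 2.96e-07, "mu": 3.62e-05},
}


def wavelength_from_energy(energy_kev: float) -> float:
    """Photon wavelength in micrometres for an energy in keV (hc = 1.23984193 eV um)."""
    if energy_kev <= 0:
        raise ValueError("photon energy must be positive")
    return 1.23984193e-3 / energy_kev


# diffuser-plane grain FWHMs (um) spanning detector-level speckle sizes of
# roughly 2 to 10 pixels (22 to 110 um) in the default 1 m / 3 m geometry
GRAIN_SWEEP_UM: tuple[float, ...] = (8.0, 12.0, 18.0, 26.0, 37.0, 50.0)


class AliasingError(ValueError):
    """Raised when a propagation distance violates the angular-spectrum sampling bound."""


@dataclass
class WaveField:
    """Complex scalar disturbance sampled on a regular 2D grid.

    amplitude : complex array (rows, cols)
    grid_pitch : sample spacing in um
    wavelength : in um
    """

    amplitude: NDArray[np.complexfloating]
    grid_pitch: float
    wavelength: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=np.complex128)
        if self.grid_pitch <= 0:
            raise ValueError("grid_pitch must be positive")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not np.all(np.isfinite(self.amplitude)):
            raise ValueError("wavefield amplitude must be finite")

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.amplitude.shape  # type: ignore[return-value]

    def total_intensity(self) -> float:
        """Total power: sum |amplitude|^2 * pitch^2."""
        return float(np.sum(np.abs(self.amplitude) ** 2) * self.grid_pitch**2)

    def copy(self) -> "WaveField":
        return WaveField(self.amplitude.copy(), self.grid_pitch, self.wavelength)


@dataclass
class ImagingGeometry:
    """Cone-beam speckle imaging geometry (axial distances in metres)."""

    source_to_diffuser: float = 1.0
    source_to_detector: float = 3.0
    sample_position: float = 1.0  # from source; default: sample at the diffuser plane
    detector_pixel_pitch: float = 12.0  # um
    focal_spot_fwhm: float = 10.0  # um
    psf_sigma: float = 1.0 / 2.355  # detector pixels (FWHM ~ 1 px)
    photon_energy: float = 30.0  # keV

    def __post_init__(self) -> None:
        if not 0 < self.source_to_diffuser < self.source_to_detector:
            raise ValueError("need 0 < source_to_diffuser < source_to_detector")
        if not 0 < self.sample_position < self.source_to_detector:
            raise ValueError("sample_position must lie between source and detector")
        if self.detector_pixel_pitch <= 0:
            raise ValueError("detector_pixel_pitch must be positive")

    @property
    def magnification(self) -> float:
        return self.source_to_detector / self.source_to_diffuser

    @property
    def diffuser_to_detector(self) -> float:
        return self.source_to_detector - self.source_to_diffuser

    @property
    def sample_to_detector(self) -> float:
        return self.source_to_detector - self.sample_position

    @property
    def effective_distance(self) -> float:
        """Fresnel-scaling equivalent parallel-beam distance z1*z2/(z1+z2), metres."""
        z1 = self.source_to_diffuser
        z2 = self.diffuser_to_detector
        return z1 * z2 / (z1 + z2)

    @property
    def wavelength(self) -> float:
        return wavelength_from_energy(self.photon_energy)


@dataclass
class SampleModel:
    """Projected thickness map plus the material's optical constants.

    thickness_map : t(x, y) in um on a grid of spacing ``grid_pitch`` um
    delta : refractive index decrement
    mu : linear attenuation coefficient in 1/um
    """

    thickness_map: NDArray[np.floating]
    delta: float
    mu: float
    label: str = ""
    grid_pitch: float = 1.0

    def __post_init__(self) -> None:
        self.thickness_map = np.asarray(self.thickness_map, dtype=np.float64)
        if np.any(self.thickness_map < 0):
            raise ValueError("thickness_map must be non-negative")
        if self.delta <= 0:
            raise ValueError("delta must be positive for x-ray energies considered")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")

    @classmethod
    def from_material(
        cls, thickness_map: NDArray, material: str, grid_pitch: float = 1.0
    ) -> "SampleModel":
        c = OPTICAL_CONSTANTS[material]
        return cls(thickness_map, c["delta"], c["mu"], label=material, grid_pitch=grid_pitch)


@dataclass
class DiffuserSpec:
    """Stack of sandpaper sheets: rough abrasive grain layers on uniform backings.

    grain_fwhm controls the lateral grain (hence speckle) size at the diffuser
    plane; roughness_rms scales the height fluctuations of the rough surface.
    When roughness_rms is None it defaults to 0.22 * grain_fwhm**1.35: coarser
    sandpaper grit has taller grains, and the slightly superlinear growth
    keeps the near-field speckle visibility roughly constant (0.25-0.4)
    across the grain-size range instead of fading for coarse grains.
    """

    n_layers: int = 10
    grain_fwhm: float = 15.0  # um, at the diffuser plane
    backing_thickness: float = 200.0  # um
    layer_materials: tuple[str, str] = ("Al2O3", "C6H10O5")
    roughness_rms: float | None = None  # um per layer; None -> 0.22 * grain_fwhm**1.35
    layer_spacing: float = 200.0  # um between consecutive rough surfaces
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.grain_fwhm <= 0:
            raise ValueError("grain_fwhm must be positive")
        if self.roughness_rms is None:
            self.roughness_rms = 0.22 * self.grain_fwhm**1.35


@dataclass
class SpeckleImage:
    """Detector-plane intensity image with pixel pitch (um) and metadata."""

    data: NDArray[np.floating]
    pixel_pitch: float = 12.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def copy(self) -> "SpeckleImage":
        return SpeckleImage(self.data.copy(), self.pixel_pitch, dict(self.meta))


# ----------------------------------------------------------------------------
# propagation


def plane_wave(shape: tuple[int, int], grid_pitch: float, wavelength: float) -> WaveField:
    """Unit-amplitude plane wave on the given grid."""
    return WaveField(np.ones(shape, dtype=np.complex128), grid_pitch, wavelength)


def _angular_spectrum_kernel(
    shape: tuple[int, int], pitch: float, wavelength: float, distance: float
) -> NDArray[np.complexfloating]:
    fy = sp_fft.fftfreq(shape[0], d=pitch)
    fx = sp_fft.fftfreq(shape[1], d=pitch)
    f2 = fy[:, None] ** 2 + fx[None, :] ** 2
    kz2 = 1.0 / wavelength**2 - f2
    kernel = np.empty(shape, dtype=np.complex128)
    prop = kz2 >= 0
    kernel[prop] = np.exp(2j * np.pi * distance * np.sqrt(kz2[prop]))
    # evanescent components decay; for negative distances keep them bounded
    kernel[~prop] = np.exp(-2.0 * np.pi * abs(distance) * np.sqrt(-kz2[~prop]))
    return kernel


def propagate(fieldin: WaveField, distance: float, pad_fraction: float = 0.25) -> WaveField:
    """Free-space angular-spectrum propagation over ``distance`` um.

    The field is edge-padded by ``pad_fraction`` per side to suppress FFT
    wrap-around, filtered with the exact angular-spectrum kernel, and cropped
    back to the original grid.  Negative distances back-propagate.

    Raises :class:`AliasingError` when |distance| exceeds the sampling bound
    ``N * pitch^2 / wavelength`` of the padded grid.
    """
    if distance == 0:
        return fieldin.copy()
    pad_r = int(np.ceil(fieldin.grid_shape[0] * pad_fraction))
    pad_c = int(np.ceil(fieldin.grid_shape[1] * pad_fraction))
    a = np.pad(fieldin.amplitude, ((pad_r, pad_r), (pad_c, pad_c)), mode="edge")
    n_min = min(a.shape)
    z_max = n_min * fieldin.grid_pitch**2 / fieldin.wavelength
    if abs(distance) > z_max:
        raise AliasingError(
            f"propagation distance {distance:g} um exceeds the angular-spectrum "
            f"sampling bound N*pitch^2/lambda = {z_max:g} um for this grid; "
            "use a finer pitch or a larger grid"
        )
    kernel = _angular_spectrum_kernel(a.shape, fieldin.grid_pitch, fieldin.wavelength, distance)
    out = sp_fft.ifft2(sp_fft.fft2(a, workers=-1) * kernel, workers=-1)
    out = out[pad_r : pad_r + fieldin.grid_shape[0], pad_c : pad_c + fieldin.grid_shape[1]]
    return WaveField(out, fieldin.grid_pitch, fieldin.wavelength)


def apply_object(fieldin: WaveField, sample: SampleModel) -> WaveField:
    """Apply a thin object in projection approximation.

    Amplitude is attenuated by exp(-mu*t/2) and the phase advanced by
    -2*pi*delta*t/lambda.  The thickness map is resampled to the field grid
    when the pitches differ.
    """
    t = sample.thickness_map
    if sample.grid_pitch != fieldin.grid_pitch:
        zoom = sample.grid_pitch / fieldin.grid_pitch
        t = ndimage.zoom(t, zoom, order=1, mode="nearest")
    if t.shape != fieldin.grid_shape:
        raise ValueError(
            f"thickness map shape {t.shape} does not match field grid "
            f"{fieldin.grid_shape} after resampling"
        )
    trans = np.exp(-0.5 * sample.mu * t - 2j * np.pi * sample.delta * t / fieldin.wavelength)
    return WaveField(fieldin.amplitude * trans, fieldin.grid_pitch, fieldin.wavelength)


# ----------------------------------------------------------------------------
# diffuser


def synthesize_diffuser(
    spec: DiffuserSpec, grid_shape: tuple[int, int], grid_pitch: float
) -> list[list[SampleModel]]:
    """Random multi-layer sandpaper diffuser.

    Each layer is a pair of :class:`SampleModel` maps: a random rough-surface
    grain layer (white noise low-pass filtered with a Gaussian of the grain
    FWHM, scaled to ``roughness_rms`` and shifted to non-negative thickness)
    atop a uniform backing.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    grain_mat, backing_mat = spec.layer_materials
    sigma = spec.grain_fwhm / 2.355 / grid_pitch
    layers: list[list[SampleModel]] = []
    for _ in range(spec.n_layers):
        h = rng.standard_normal(grid_shape)
        h = ndimage.gaussian_filter(h, sigma, mode="wrap")
        std = h.std()
        if std > 0:
            h *= spec.roughness_rms / std
        h -= h.min()
        grain = SampleModel.from_material(h, grain_mat, grid_pitch)
        backing = SampleModel.from_material(
            np.full(grid_shape, spec.backing_thickness), backing_mat, grid_pitch
        )
        layers.append([grain, backing])
    return layers


# ----------------------------------------------------------------------------
# detection


def detect(fieldin: WaveField, geometry: ImagingGeometry, apply_source_blur: bool = True) -> SpeckleImage:
    """Detector readout: intensity, Gaussian PSF blur, pixel binning.

    The field grid (object plane) maps to the detector plane through the
    geometric magnification; its magnified pitch must divide the detector
    pixel pitch by an integer oversampling factor.  The detected image is
    |amplitude|^2 blurred by a Gaussian of sigma ``psf_sigma`` detector pixels
    (combined in quadrature with the magnified focal-spot blur when
    ``apply_source_blur``), then averaged over detector pixels.  No noise is
    added here.
    """
    m = geometry.magnification
    pitch_det_plane = fieldin.grid_pitch * m
    ratio = geometry.detector_pixel_pitch / pitch_det_plane
    oversample = int(round(ratio))
    if abs(ratio - oversample) > 1e-9 or oversample < 1:
        raise ValueError(
            f"field pitch {pitch_det_plane:g} um (detector plane) must divide the "
            f"detector pixel pitch {geometry.detector_pixel_pitch:g} um by an integer"
        )
    intensity = np.abs(fieldin.amplitude) ** 2 / m**2
    sigma_px = geometry.psf_sigma
    if apply_source_blur:
        z1 = geometry.source_to_diffuser
        z2 = geometry.diffuser_to_detector
        src_fwhm_det = geometry.focal_spot_fwhm * z2 / z1  # um at detector plane
        src_sigma_px = src_fwhm_det / 2.355 / geometry.detector_pixel_pitch
        sigma_px = float(np.hypot(sigma_px, src_sigma_px))
    if sigma_px > 0:
        intensity = ndimage.gaussian_filter(intensity, sigma_px * oversample, mode="nearest")
    rows = intensity.shape[0] // oversample
    cols = intensity.shape[1] // oversample
    intensity = intensity[: rows * oversample, : cols * oversample]
    binned = intensity.reshape(rows, oversample, cols, oversample).mean(axis=(1, 3))
    return SpeckleImage(
        binned,
        pixel_pitch=geometry.detector_pixel_pitch,
        meta={"oversample": oversample, "magnification": m, "psf_sigma_px": sigma_px},
    )


# ----------------------------------------------------------------------------
# full chain


def _diffused_field(
    geometry: ImagingGeometry,
    diffuser_spec: DiffuserSpec,
    detector_shape: tuple[int, int],
    oversample: int,
) -> WaveField:
    m = geometry.magnification
    pitch_obj = geometry.detector_pixel_pitch / (m * oversample)
    shape_fine = (detector_shape[0] * oversample, detector_shape[1] * oversample)
    fieldw = plane_wave(shape_fine, pitch_obj, geometry.wavelength)
    layers = synthesize_diffuser(diffuser_spec, shape_fine, pitch_obj)
    for i, (grain, backing) in enumerate(layers):
        fieldw = apply_object(fieldw, grain)
        fieldw = apply_object(fieldw, backing)
        if i < len(layers) - 1 and diffuser_spec.layer_spacing > 0:
            fieldw = propagate(fieldw, diffuser_spec.layer_spacing)
    return fieldw


def ground_truth_displacement(
    sample: SampleModel, geometry: ImagingGeometry, detector_shape: tuple[int, int], oversample: int
) -> NDArray[np.floating]:
    """Analytic speckle displacement (detector pixels) from a sample's refraction.

    alpha = -delta * grad t (small-angle, projection approximation) at the
    object plane; the speckle shift at the detector is alpha * d / p with d the
    sample-to-detector distance, averaged over detector pixels.  Returns an
    array [component(ux, uy), row, col].
    """
    d_um = geometry.sample_to_detector * M_TO_UM
    p = geometry.detector_pixel_pitch
    gy, gx = np.gradient(sample.thickness_map, sample.grid_pitch)
    ux = -sample.delta * gx * d_um / p
    uy = -sample.delta * gy * d_um / p
    out = np.empty((2, detector_shape[0], detector_shape[1]))
    for k, comp in enumerate((ux, uy)):
        r = detector_shape[0] * oversample
        c = detector_shape[1] * oversample
        out[k] = comp[:r, :c].reshape(
            detector_shape[0], oversample, detector_shape[1], oversample
        ).mean(axis=(1, 3))
    return out


def simulate_pair(
    geometry: ImagingGeometry,
    diffuser_spec: DiffuserSpec,
    sample: SampleModel | None = None,
    seed: int | None = None,
    detector_shape: tuple[int, int] = (256, 256),
    oversample: int = 4,
):
    """End-to-end simulation source -> diffuser -> (sample) -> detector.

    Returns ``(reference, sample_image, ground_truth)`` where ground_truth is
    the analytic displacement array [2, rows, cols] in detector pixels (None
    when no sample is given).  The reference and sample image share the same
    diffuser realization; ``seed`` overrides ``diffuser_spec.seed``.
    """
    if seed is not None:
        diffuser_spec = dataclasses.replace(diffuser_spec, seed=seed)
    z_eff_um = geometry.effective_distance * M_TO_UM
    fieldw = _diffused_field(geometry, diffuser_spec, detector_shape, oversample)
    ref = detect(propagate(fieldw, z_eff_um), geometry)
    if sample is None:
        return ref, ref.copy(), None
    field_s = apply_object(fieldw, sample)
    sam = detect(propagate(field_s, z_eff_um), geometry)
    gt = ground_truth_displacement(sample, geometry, detector_shape, oversample)
    return ref, sam, gt


# ----------------------------------------------------------------------------
# speckle statistics


def speckle_visibility(image: SpeckleImage | NDArray, trim: int = 4) -> float:
    """Speckle contrast std/mean, ignoring a border of ``trim`` pixels."""
    a = image.data if isinstance(image, SpeckleImage) else np.asarray(image)
    if trim > 0:
        a = a[trim:-trim, trim:-trim]
    return float(a.std() / a.mean())


def autocorrelation_fwhm(image: SpeckleImage | NDArray, trim: int = 4) -> float:
    """FWHM (pixels) of the speckle autocorrelation function.

    Computed from the FFT autocorrelation of the mean-subtracted image,
    averaged over the two axes, with linear interpolation of the half-maximum
    crossing.
    """
    a = image.data if isinstance(image, SpeckleImage) else np.asarray(image)
    if trim > 0:
        a = a[trim:-trim, trim:-trim]
    a = a - a.mean()
    f = sp_fft.fft2(a)
    ac = sp_fft.ifft2(np.abs(f) ** 2).real
    ac /= ac[0, 0]
    widths = []
    for profile in (ac[:, 0], ac[0, :]):
        n = len(profile) // 2
        p = profile[:n]
        below = np.nonzero(p < 0.5)[0]
        if len(below) == 0:
            widths.append(float(n))
            continue
        i = below[0]
        # linear interpolation between samples i-1 and i
        x = (0.5 - p[i - 1]) / (p[i] - p[i - 1]) + (i - 1) if i > 0 else 0.5
        widths.append(2.0 * x)
    return float(np.mean(widths))
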