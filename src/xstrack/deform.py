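"""Sub-pixel deformation, attenuation and noise augmentation of speckle images.

Training and evaluation pairs are produced by warping a clean reference
speckle image with a known displacement field (inverse mapping with cubic
spline interpolation), multiplying by a piecewise-interpolated transmission
map, and applying independent Poisson noise to the reference and the sample
image.  Random piecewise-smooth deformations are built from independent
patches: within each patch the field is bilinear between four random corner
values that share a single sign per component, so displacements are smooth in
only one direction per patch; pooled over many draws the values are symmetric
around zero and bounded by +-1 pixel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

from .wave_optics import SpeckleImage

__all__ = [
    "DisplacementField",
    "DeformationSpec",
    "DatasetManifest",
    "DEFORMATION_KINDS",
    "PATCH_SIZES",
    "generate_deformation",
    "warp",
    "apply_transmission",
    "add_poisson_noise",
    "build_dataset",
]

DEFORMATION_KINDS = ("random_patches", "identity", "constant_x", "constant_y", "constant_xy")
PATCH_SIZES = (4, 8, 16, 32, 64, 128)


@dataclass
class DisplacementField:
    """Per-pixel displacement (ux, uy) in detector-pixel units."""

    ux: NDArray[np.floating]
    uy: NDArray[np.floating]

    def __post_init__(self) -> None:
        self.ux = np.asarray(self.ux, dtype=np.float64)
        self.uy = np.asarray(self.uy, dtype=np.float64)
        if self.ux.shape != self.uy.shape:
            raise ValueError("ux and uy must have the same shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ux.shape  # type: ignore[return-value]

    def as_array(self) -> NDArray[np.floating]:
        """Stack to [component(ux, uy), row, col]."""
        return np.stack([self.ux, self.uy])

    @classmethod
    def from_array(cls, a: NDArray) -> "DisplacementField":
        return cls(a[0], a[1])

    @classmethod
    def constant(cls, shape: tuple[int, int], ux: float, uy: float) -> "DisplacementField":
        return cls(np.full(shape, float(ux)), np.full(shape, float(uy)))


@dataclass
class DeformationSpec:
    kind: str = "random_patches"
    patch_size: int = 8
    amplitude_range: tuple[float, float] = (-1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DEFORMATION_KINDS:
            raise ValueError(f"unknown deformation kind {self.kind!r}")
        lo, hi = self.amplitude_range
        if lo < -1.0 or hi > 1.0 or lo > hi:
            raise ValueError("amplitude_range must be within [-1, +1]")


def _patch_grid_interpolate(corner_values: NDArray, patch: int) -> NDArray:
    """Bilinear interpolation of per-patch corner values to pixels.

    ``corner_values`` has shape (py, px, 4) holding the (top-left, top-right,
    bottom-left, bottom-right) corner value of each independent patch; patches
    do not share corners, so the output field may be discontinuous at patch
    boundaries while being linear inside each patch.
    """
    py, px, _ = corner_values.shape
    f = np.arange(patch) / patch  # fractional position inside the patch
    wy = f[None, :, None, None]
    wx = f[None, None, None, :]
    tl = corner_values[:, :, 0][:, None, :, None]
    tr = corner_values[:, :, 1][:, None, :, None]
    bl = corner_values[:, :, 2][:, None, :, None]
    br = corner_values[:, :, 3][:, None, :, None]
    block = (
        tl * (1 - wy) * (1 - wx)
        + tr * (1 - wy) * wx
        + bl * wy * (1 - wx)
        + br * wy * wx
    )
    return block.reshape(py * patch, px * patch)


def _random_patch_component(
    shape: tuple[int, int], patch: int, amp: tuple[float, float], rng: np.random.Generator
) -> NDArray:
    py, px = shape[0] // patch, shape[1] // patch
    lo, hi = amp
    sign = np.where(rng.random((py, px)) < 0.5, -1.0, 1.0)
    # per-patch single-sign corner values; magnitudes uniform up to the range bound
    mag_pos = hi if hi > 0 else 0.0
    mag_neg = -lo if lo < 0 else 0.0
    mags = rng.uniform(0.0, 1.0, (py, px, 4))
    corners = np.where(sign[..., None] > 0, mags * mag_pos, -mags * mag_neg)
    return _patch_grid_interpolate(corners, patch)


def generate_deformation(spec: DeformationSpec, image_shape: tuple[int, int]) -> DisplacementField:
    """Random displacement field of the requested kind.

    ``random_patches`` tiles the image with independent ``patch_size`` squares,
    each bilinear between four single-signed corner draws; the constant kinds
    draw one uniform value per active component from ``amplitude_range``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = image_shape
    if spec.kind == "random_patches":
        if h % spec.patch_size or w % spec.patch_size:
            raise ValueError(
                f"patch_size {spec.patch_size} does not divide image shape {image_shape}"
            )
        ux = _random_patch_component(image_shape, spec.patch_size, spec.amplitude_range, rng)
        uy = _random_patch_component(image_shape, spec.patch_size, spec.amplitude_range, rng)
        return DisplacementField(ux, uy)
    if spec.kind == "identity":
        return DisplacementField.constant(image_shape, 0.0, 0.0)
    cx = float(rng.uniform(*spec.amplitude_range))
    cy = float(rng.uniform(*spec.amplitude_range))
    if spec.kind == "constant_x":
        return DisplacementField.constant(image_shape, cx, 0.0)
    if spec.kind == "constant_y":
        return DisplacementField.constant(image_shape, 0.0, cy)
    return DisplacementField.constant(image_shape, cx, cy)  # constant_xy


def warp(reference: SpeckleImage, fieldd: DisplacementField, order: int = 3) -> SpeckleImage:
    """Apply a displacement field: sample(x) = reference(x - u(x)).

    Inverse mapping with spline interpolation of the given order; border
    pixels are filled by edge extension and flagged in the metadata.
    """
    ref = reference.data
    if fieldd.shape != ref.shape:
        raise ValueError("displacement field shape must match the image")
    if not (np.any(fieldd.ux) or np.any(fieldd.uy)):
        out = reference.copy()
        out.meta["warped"] = True
        return out
    rows, cols = np.indices(ref.shape, dtype=np.float64)
    coords = np.stack([rows - fieldd.uy, cols - fieldd.ux])
    data = ndimage.map_coordinates(ref, coords, order=order, mode="nearest")
    out = SpeckleImage(data, reference.pixel_pitch, dict(reference.meta))
    out.meta["warped"] = True
    out.meta["border_fill"] = "edge-extension"
    return out


def apply_transmission(
    image: SpeckleImage,
    patch_size: int = 8,
    transmission_range: tuple[float, float] = (0.5, 1.0),
    seed: int = 0,
) -> tuple[SpeckleImage, NDArray[np.floating]]:
    """Patchwise random attenuation mimicking partial sample transmission.

    The transmission map T(x, y) is built with the same independent-patch
    bilinear scheme as the deformations (fresh randomness, no sign constraint)
    with values inside ``transmission_range``; the attenuated image and T are
    returned.
    """
    lo, hi = transmission_range
    if not (0.0 < lo <= hi <= 1.0):
        raise ValueError("transmission_range must lie within (0, 1]")
    h, w = image.shape
    if h % patch_size or w % patch_size:
        raise ValueError(f"patch_size {patch_size} does not divide image shape {image.shape}")
    rng = np.random.default_rng(seed)
    corners = rng.uniform(lo, hi, (h // patch_size, w // patch_size, 4))
    tmap = _patch_grid_interpolate(corners, patch_size)
    out = SpeckleImage(image.data * tmap, image.pixel_pitch, dict(image.meta))
    out.meta["transmission_range"] = (lo, hi)
    return out, tmap


def add_poisson_noise(
    image: SpeckleImage, mean_photons_per_pixel: float, seed: int | np.random.Generator = 0
) -> SpeckleImage:
    """Poisson noise at a photon fluence of ``mean_photons_per_pixel``.

    Pixel values are scaled so their mean equals the fluence, Poisson sampled,
    and rescaled back to the original intensity units.
    """
    if mean_photons_per_pixel <= 0:
        raise ValueError("mean_photons_per_pixel must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = mean_photons_per_pixel / image.data.mean()
    noisy = rng.poisson(np.clip(image.data * scale, 0, None)).astype(np.float64) / scale
    out = SpeckleImage(noisy, image.pixel_pitch, dict(image.meta))
    out.meta["poisson_fluence"] = mean_photons_per_pixel
    return out


@dataclass
class DatasetManifest:
    """Composition of a training/testing dataset of image triplets."""

    n_references: int = 364
    deformations_per_reference: dict = dc_field(
        default_factory=lambda: {"train": 60, "test": 10}
    )
    special_map_fraction: float = 0.02  # split evenly over the four special kinds
    transmission_range: tuple[float, float] = (0.5, 1.0)
    small_constant_range: tuple[float, float] = (-0.15, 0.15)
    photon_fluence: float = 10000.0
    patch_sizes: tuple[int, ...] = PATCH_SIZES
    seed: int = 0


def build_dataset(
    manifest: DatasetManifest,
    references: list[SpeckleImage],
    out_path: str | Path,
    split: str = "train",
) -> dict:
    """Generate and persist (reference, sample, ground-truth field) triplets.

    Roughly 98% of pairs use random patch deformations (patch size drawn from
    ``manifest.patch_sizes``); the remaining ~2% are split evenly across the
    four special kinds (identity, constant x, constant y, constant xy) with
    constants drawn within the small-displacement range.  Every triplet's
    deformation spec and seeds are recorded in a JSON manifest next to the
    HDF5 file, so the dataset regenerates bit-identically.
    """
    out_path = Path(out_path)
    n_def = manifest.deformations_per_reference[split]
    rng = np.random.default_rng(manifest.seed + (0 if split == "train" else 1))
    records = []
    n_total = len(references) * n_def
    special = ("identity", "constant_x", "constant_y", "constant_xy")
    kinds = np.array(["random_patches"] * n_total, dtype=object)
    n_special_each = int(round(manifest.special_map_fraction / 4 * n_total))
    if n_special_each:
        pick = rng.choice(n_total, size=min(4 * n_special_each, n_total), replace=False)
        for j, idx in enumerate(pick):
            kinds[idx] = special[j % 4]
    with h5py.File(out_path, "w") as f:
        f.attrs["split"] = split
        ds_ref = None
        item = 0
        for r_i, ref in enumerate(references):
            for d_i in range(n_def):
                kind = str(kinds[item])
                spec = DeformationSpec(
                    kind=kind,
                    patch_size=int(rng.choice(manifest.patch_sizes)),
                    amplitude_range=(
                        manifest.small_constant_range
                        if kind.startswith("constant")
                        else (-1.0, 1.0)
                    ),
                    seed=int(rng.integers(2**31)),
                )
                t_seed = int(rng.integers(2**31))
                n_seed = int(rng.integers(2**31))
                fieldd = generate_deformation(spec, ref.shape)
                sam = warp(ref, fieldd)
                sam, _ = apply_transmission(
                    sam, spec.patch_size, manifest.transmission_range, seed=t_seed
                )
                ref_noisy = add_poisson_noise(ref, manifest.photon_fluence, seed=n_seed)
                sam_noisy = add_poisson_noise(sam, manifest.photon_fluence, seed=n_seed + 1)
                if ds_ref is None:
                    h, w = ref.shape
                    ds_ref = f.create_dataset("reference", (n_total, h, w), dtype="f4")
                    ds_sam = f.create_dataset("sample", (n_total, h, w), dtype="f4")
                    ds_disp = f.create_dataset("displacement", (n_total, 2, h, w), dtype="f4")
                ds_ref[item] = ref_noisy.data
                ds_sam[item] = sam_noisy.data
                ds_disp[item] = fieldd.as_array()
                records.append(
                    {
                        "item": item,
                        "reference_index": r_i,
                        "kind": kind,
                        "patch_size": spec.patch_size,
                        "deformation_seed": spec.seed,
                        "transmission_seed": t_seed,
                        "noise_seed": n_seed,
                    }
                )
                item += 1
    info = {
        "split": split,
        "n_items": n_total,
        "n_references": len(references),
        "deformations_per_reference": n_def,
        "photon_fluence": manifest.photon_fluence,
        "transmission_range": list(manifest.transmission_range),
        "special_counts": {k: int(np.sum(kinds == k)) for k in special},
        "items": records,
    }
    out_path.with_suffix(".manifest.json").write_text(json.dumps(info, indent=1))
    return info
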