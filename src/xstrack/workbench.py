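"""Shared plumbing: image/field I/O, configuration, seeding, fixtures, reports.

Images are stored as single-channel 32-bit float TIFF; simulated pairs and
datasets as HDF5 with groups ``/reference``, ``/sample`` and ``/displacement``
(axis order [component, row, col]).  Geometry and diffuser settings live in a
YAML config whose keys mirror the dataclass field names.  Every random
consumer derives its stream from the global seed combined with a stage name
through SHA-256, so stages are reproducible independently of execution order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .deform import DisplacementField, DeformationSpec, generate_deformation, warp
from .wave_optics import (
    DiffuserSpec,
    ImagingGeometry,
    SpeckleImage,
    simulate_pair,
    speckle_visibility,
)

__all__ = [
    "RunConfig",
    "FixtureSet",
    "derive_seed",
    "read_image",
    "write_image",
    "save_pair",
    "load_pair",
    "load_run_config",
    "make_fixtures",
    "report",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of (global_seed, stage) mod 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class RunConfig:
    """Top-level configuration tying the pipeline stages together."""

    geometry: ImagingGeometry = dc_field(default_factory=ImagingGeometry)
    diffuser: DiffuserSpec = dc_field(default_factory=DiffuserSpec)
    global_seed: int = 0
    output_dir: str = "out"
    log_level: str = "INFO"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.global_seed, stage)


def load_run_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    geometry = ImagingGeometry(**raw.get("geometry", {}))
    diff_kwargs = dict(raw.get("diffuser", {}))
    if "layer_materials" in diff_kwargs:
        diff_kwargs["layer_materials"] = tuple(diff_kwargs["layer_materials"])
    diffuser = DiffuserSpec(**diff_kwargs)
    return RunConfig(
        geometry=geometry,
        diffuser=diffuser,
        global_seed=int(raw.get("global_seed", 0)),
        output_dir=str(raw.get("output_dir", "out")),
        log_level=str(raw.get("log_level", "INFO")),
    )


# ----------------------------------------------------------------------------
# image / pair I/O


def write_image(path: str | Path, image: SpeckleImage) -> None:
    tifffile.imwrite(
        Path(path),
        image.data.astype(np.float32),
        metadata={"pixel_pitch_um": image.pixel_pitch},
    )


def read_image(path: str | Path) -> SpeckleImage:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim != 2:
        raise ValueError(f"expected a single-channel 2D image, got shape {data.shape}")
    if not np.issubdtype(data.dtype, np.floating):
        warnings.warn(f"integer TIFF {path.name} promoted to float32", stacklevel=2)
        data = data.astype(np.float32)
    return SpeckleImage(data)


def save_pair(
    path: str | Path,
    reference: SpeckleImage,
    sample: SpeckleImage,
    displacement: DisplacementField | None = None,
    meta: dict | None = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("reference", data=reference.data.astype(np.float32))
        f.create_dataset("sample", data=sample.data.astype(np.float32))
        if displacement is not None:
            f.create_dataset("displacement", data=displacement.as_array().astype(np.float32))
        f.attrs["pixel_pitch_um"] = reference.pixel_pitch
        for k, v in (meta or {}).items():
            f.attrs[k] = v


def load_pair(path: str | Path):
    with h5py.File(path, "r") as f:
        pitch = float(f.attrs.get("pixel_pitch_um", 12.0))
        ref = SpeckleImage(f["reference"][()], pitch)
        sam = SpeckleImage(f["sample"][()], pitch)
        disp = (
            DisplacementField.from_array(f["displacement"][()].astype(np.float64))
            if "displacement" in f
            else None
        )
    return ref, sam, disp


# ----------------------------------------------------------------------------
# fixtures


@dataclass
class FixtureSet:
    """Small deterministic test inputs generated from the simulator."""

    speckle_pair: tuple[SpeckleImage, SpeckleImage]
    known_shift: tuple[float, float]
    known_shift_pair: tuple[SpeckleImage, SpeckleImage]
    star_reference: SpeckleImage
    training_set: dict
    visibility: float
    seed: int


def make_fixtures(seed: int = 0, detector_px: int = 64, n_train: int = 8) -> FixtureSet:
    """Deterministic fixtures: a small speckle pair, a known sub-pixel shift
    pair, and a tiny training set of patchwise-deformed pairs."""
    geometry = ImagingGeometry()
    diffuser = DiffuserSpec(seed=derive_seed(seed, "fixture-diffuser"))
    ref, _, _ = simulate_pair(
        geometry, diffuser, detector_shape=(detector_px, detector_px), oversample=4
    )
    shift = (0.3, -0.2)
    shifted = warp(ref, DisplacementField.constant(ref.shape, *shift))
    refs, sams, disps = [], [], []
    for i in range(n_train):
        d2 = DiffuserSpec(seed=derive_seed(seed, f"fixture-train-{i}"))
        r, _, _ = simulate_pair(
            geometry, d2, detector_shape=(detector_px, detector_px), oversample=4
        )
        # the smoothest patch size: one bilinear patch per image, so the tiny
        # training set probes optimization rather than memorization capacity
        spec = DeformationSpec(
            kind="random_patches", patch_size=detector_px, seed=derive_seed(seed, f"fixture-def-{i}")
        )
        fieldd = generate_deformation(spec, r.shape)
        s = warp(r, fieldd)
        refs.append(r.data)
        sams.append(s.data)
        disps.append(fieldd.as_array())
    training = {
        "reference": np.stack(refs),
        "sample": np.stack(sams),
        "displacement": np.stack(disps),
    }
    return FixtureSet(
        speckle_pair=(ref, ref.copy()),
        known_shift=shift,
        known_shift_pair=(ref, shifted),
        star_reference=ref,
        training_set=training,
        visibility=speckle_visibility(ref),
        seed=seed,
    )


# ----------------------------------------------------------------------------
# reports


def report(tables: dict[str, pd.DataFrame], out_dir: str | Path, config: dict | None = None,
           seed: int | None = None) -> dict:
    """Write experiment tables as CSV plus a JSON summary with provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "config": _jsonable(config) if config else None,
        "tables": {},
    }
    for name, table in tables.items():
        csv_path = out_dir / f"{name}.csv"
        table.to_csv(csv_path, index=False)
        summary["tables"][name] = {
            "path": csv_path.name,
            "n_rows": int(len(table)),
            "columns": list(table.columns),
        }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=_jsonable))
    return summary


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
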