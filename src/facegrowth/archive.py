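"""Growth-curve model archives on disk.

Layout: one directory per (model, sex) holding a human-readable
``manifest.json`` (format version, sex, age grid, kernel settings,
retained-variance fraction, axis convention), ``triangles.npy`` with the
template connectivity, and one ``age_XXXX.npz`` numpy container per grid
age (expected face, normals, pointwise SDs, SSM modes and variances).
Arrays round-trip bitwise.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ArchiveIntegrityError, UnsupportedVersionError
from .mesh import AxisConvention, TriangleTopology
from .regression import KernelConfig
from .variation import GrowthCurveModel, ModelEntry, PointwiseSD, SSM

__all__ = ["FORMAT_VERSION", "save_growth_model", "load_growth_model"]

FORMAT_VERSION = 1

_ENTRY_ARRAYS = (
    "expected", "normals", "sd_ml", "sd_si", "sd_ap", "sd_normal",
    "sd_magnitude", "modes", "mode_variances",
)


def _entry_filename(index: int) -> str:
    return f"age_{index:04d}.npz"


def save_growth_model(model: GrowthCurveModel, path: str | Path) -> Path:
    """Write a model archive; returns the archive directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "sex": model.sex,
        "ages": [float(a) for a in model.ages],
        "kernel": {
            "sigma_floor": model.kernel.sigma_floor,
            "min_effective_n": model.kernel.min_effective_n,
        },
        "retained_fraction": model.retained_fraction,
        "allow_scale": model.allow_scale,
        "axis_convention": model.topology.axis_convention.to_dict(),
        "n_vertices": model.topology.n_vertices,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    np.save(path / "triangles.npy", model.topology.triangles)
    for i, entry in enumerate(model.entries):
        np.savez(
            path / _entry_filename(i),
            expected=entry.expected,
            normals=entry.normals,
            sd_ml=entry.sd.sd_ml,
            sd_si=entry.sd.sd_si,
            sd_ap=entry.sd.sd_ap,
            sd_normal=entry.sd.sd_normal,
            sd_magnitude=entry.sd.sd_magnitude,
            modes=entry.ssm.modes,
            mode_variances=entry.ssm.mode_variances,
            scalars=np.array([
                entry.age, entry.sigma, entry.effective_n,
                entry.ssm.total_variance, entry.ssm.retained_fraction,
                entry.ssm.n_effective,
            ]),
        )
    return path


def load_growth_model(path: str | Path) -> GrowthCurveModel:
    """Load a model archive, verifying version and completeness."""
    path = Path(path)
    manifest_path = path / "manifest.json"
    if not manifest_path.exists():
        raise ArchiveIntegrityError(f"{path}: missing manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    version = manifest.get("format_version")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"{path}: archive format version {version!r}; this build reads "
            f"version {FORMAT_VERSION}"
        )
    tri_path = path / "triangles.npy"
    if not tri_path.exists():
        raise ArchiveIntegrityError(f"{path}: missing triangles.npy")
    topology = TriangleTopology(
        n_vertices=int(manifest["n_vertices"]),
        triangles=np.load(tri_path),
        axis_convention=AxisConvention.from_dict(manifest["axis_convention"]),
    )
    kernel = KernelConfig(
        sigma_floor=float(manifest["kernel"]["sigma_floor"]),
        min_effective_n=float(manifest["kernel"]["min_effective_n"]),
    )
    ages = manifest["ages"]
    entries = []
    for i, age in enumerate(ages):
        entry_path = path / _entry_filename(i)
        if not entry_path.exists():
            raise ArchiveIntegrityError(
                f"{path}: missing arrays for age {age} ({entry_path.name})"
            )
        with np.load(entry_path) as data:
            missing = [k for k in _ENTRY_ARRAYS if k not in data]
            if missing or "scalars" not in data:
                raise ArchiveIntegrityError(
                    f"{entry_path}: missing arrays {missing or ['scalars']}"
                )
            scalars = data["scalars"]
            sd = PointwiseSD(
                sd_ml=data["sd_ml"], sd_si=data["sd_si"], sd_ap=data["sd_ap"],
                sd_normal=data["sd_normal"], sd_magnitude=data["sd_magnitude"],
            )
            ssm = SSM(
                modes=data["modes"],
                mode_variances=data["mode_variances"],
                retained_fraction=float(scalars[4]),
                n_effective=float(scalars[5]),
                total_variance=float(scalars[3]),
            )
            entries.append(
                ModelEntry(
                    age=float(scalars[0]), expected=data["expected"],
                    normals=data["normals"], sd=sd, ssm=ssm,
                    sigma=float(scalars[1]), effective_n=float(scalars[2]),
                )
            )
    return GrowthCurveModel(
        sex=manifest["sex"],
        ages=np.asarray(ages, dtype=np.float64),
        entries=entries,
        topology=topology,
        kernel=kernel,
        retained_fraction=float(manifest["retained_fraction"]),
        allow_scale=bool(manifest["allow_scale"]),
    )
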