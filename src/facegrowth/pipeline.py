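"""File-level workflows tying the pipeline together.

These functions are the scriptable surface of the package: each takes
paths, runs one end-to-end task (simulate / build / assess /
normal-equivalent / morph) and writes its outputs plus a ``provenance.json``
recording the fully resolved configuration and seed, so every run is
reproducible from its output directory alone.  The ``examples/`` scripts
in the repository are thin narrations over these functions.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .archive import load_growth_model, save_growth_model
from .assess import (
    export_signature_colormap,
    facial_signature,
    make_morph,
    normal_equivalent_for,
)
from .cohort import load_cohort
from .errors import ValidationError
from .mesh import TriangleTopology, read_corresponded_mesh, write_mesh, write_ply
from .regression import KernelConfig
from .simulate import GenerativeSpec, base_topology, mean_shape, simulate_cohort
from .variation import build_growth_curves, default_age_grid

__all__ = ["simulate", "build", "assess", "normal_equivalent_report", "morph"]

logger = logging.getLogger(__name__)


def _write_provenance(out_dir: Path, task: str, config: dict) -> None:
    record = {"tool": "facegrowth", "version": __version__, "task": task,
              "config": config}
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, default=str)


def simulate(
    out_dir: str | Path,
    n: int,
    spec: GenerativeSpec | str | Path | None = None,
    seed: int | None = None,
    sex: str | None = None,
):
    """Generate a synthetic cohort on disk (PLY meshes + cohort.csv).

    ``spec`` may be a :class:`GenerativeSpec`, a path to a JSON file of
    spec fields, or ``None`` for the defaults.
    """
    if spec is None:
        spec = GenerativeSpec()
    elif not isinstance(spec, GenerativeSpec):
        with open(spec) as fh:
            raw = json.load(fh)
        for key in ("ellipsoid_axes", "mode_sds", "age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        try:
            spec = GenerativeSpec(**raw)
        except TypeError as exc:
            raise ValidationError(f"invalid generative spec: {exc}") from exc
    out_dir = Path(out_dir)
    shapes, table = simulate_cohort(spec, n, seed=seed, sex=sex, out_dir=out_dir)
    # the template mesh doubles as the topology definition for later builds
    topo = base_topology(spec)
    mid_age = 0.5 * (spec.age_range[0] + spec.age_range[1])
    write_mesh(out_dir / "template.ply", mean_shape(spec, mid_age), topo.triangles)
    _write_provenance(out_dir, "simulate",
                      {"n": n, "seed": seed, "sex": sex,
                       "spec": dataclasses.asdict(spec)})
    return shapes, table


def build(
    cohort_csv: str | Path,
    template: str | Path,
    sex: str,
    out_dir: str | Path,
    age_min: float | None = None,
    age_max: float | None = None,
    age_step: float = 0.3,
    sigma_floor: float = 1.0,
    min_effective_n: float = 200.0,
    retained_fraction: float = 0.98,
    allow_scale: bool = False,
):
    """Build and archive a growth-curve model for one sex.

    Defaults reproduce the published export convention: a grid every 0.3
    years (0.5-68.9 for females, 0.5-51.8 for males) and 98% retained
    variance.
    """
    topology = TriangleTopology.from_mesh(template)
    shapes = load_cohort(cohort_csv, topology, sex=sex)
    if age_min is None or age_max is None:
        grid = default_age_grid(sex, step=age_step)
    else:
        n_steps = int(round((age_max - age_min) / age_step)) + 1
        grid = age_min + age_step * np.arange(n_steps)
    kernel = KernelConfig(sigma_floor=sigma_floor, min_effective_n=min_effective_n)
    model = build_growth_curves(
        shapes, topology, sex=sex, age_grid=grid, kernel=kernel,
        retained_fraction=retained_fraction, allow_scale=allow_scale,
    )
    out_dir = Path(out_dir)
    save_growth_model(model, out_dir)
    _write_provenance(out_dir, "build", {
        "cohort_csv": str(cohort_csv), "template": str(template), "sex": sex,
        "age_grid": [float(grid[0]), float(grid[-1]), age_step],
        "sigma_floor": sigma_floor, "min_effective_n": min_effective_n,
        "retained_fraction": retained_fraction, "allow_scale": allow_scale,
    })
    return model


def assess(
    model_dir: str | Path,
    mesh_path: str | Path,
    age: float,
    sex: str,
    out_dir: str | Path,
):
    """Facial signature of one patient mesh against an archived model.

    Writes ``signature.ply`` (patient geometry with the signed z_normal
    scalar) and ``signature.json`` with summary statistics.
    """
    model = load_growth_model(model_dir)
    patient = read_corresponded_mesh(mesh_path, model.topology, age=age, sex=sex)
    sig = facial_signature(patient, model)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    export_signature_colormap(sig, model.topology, out_dir / "signature.ply")
    z = sig.z_normal[sig.mask]
    summary = {
        "model_age": sig.model_age, "target_age": sig.target_age,
        "sex": sig.sex,
        "n_masked_vertices": int((~sig.mask).sum()),
        "z_normal_rms": float(np.sqrt(np.mean(z**2))),
        "z_normal_max_abs": float(np.abs(z).max()),
        "fraction_outside_2sd": float(np.mean(np.abs(z) > 2.0)),
    }
    with open(out_dir / "signature.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    _write_provenance(out_dir, "assess", {
        "model_dir": str(model_dir), "mesh": str(mesh_path),
        "age": age, "sex": sex,
    })
    return sig, summary


def normal_equivalent_report(
    model_dir: str | Path,
    mesh_path: str | Path,
    age: float,
    sex: str,
    out_dir: str | Path,
    p_crit: float = 0.05,
    max_iter: int = 10,
):
    """Normal equivalent of one patient mesh, with meshes and a JSON report."""
    model = load_growth_model(model_dir)
    patient = read_corresponded_mesh(mesh_path, model.topology, age=age, sex=sex)
    ne = normal_equivalent_for(patient, model, p_crit=p_crit, max_iter=max_iter)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mesh(out_dir / "normal_equivalent.ply", ne.vertices,
               model.topology.triangles)
    write_ply(out_dir / "difference.ply", ne.vertices, model.topology.triangles,
              binary=False,
              vertex_scalars={"difference_mm": ne.normal_difference})
    report = {
        "p_crit": p_crit,
        "mahalanobis_sq": ne.mahalanobis_sq,
        "tail_probability": ne.tail_probability,
        "iterations": ne.iterations,
        "max_abs_normal_difference_mm": float(np.abs(ne.normal_difference).max()),
    }
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _write_provenance(out_dir, "normal_equivalent", {
        "model_dir": str(model_dir), "mesh": str(mesh_path), "age": age,
        "sex": sex, "p_crit": p_crit, "max_iter": max_iter,
    })
    return ne, report


def morph(
    mesh_paths: list[str | Path],
    ages: list[float],
    template: str | Path,
    out_path: str | Path,
):
    """Average a small set of corresponded faces into a morph.

    Unit-size GPA, vertex-wise averaging, rescaling to the members' mean
    centroid size; the morph's age is the members' mean age.  Writes the
    morph mesh plus a metadata JSON next to it.
    """
    if len(mesh_paths) != len(ages):
        raise ValidationError("need one age per mesh")
    topology = TriangleTopology.from_mesh(template)
    shapes = [
        read_corresponded_mesh(p, topology, age=a)
        for p, a in zip(mesh_paths, ages)
    ]
    m = make_morph(shapes)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    write_mesh(out_path, m.vertices, topology.triangles)
    meta = {"members": m.member_ids, "age": m.age, "centroid_size_mm": m.size}
    with open(out_path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=2)
    _write_provenance(out_path.parent, "morph", {
        "meshes": [str(p) for p in mesh_paths], "ages": ages,
        "template": str(template),
    })
    return m
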