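"""Cohort metadata tables (CSV) and bulk mesh loading.

The cohort table is a CSV with columns ``id,age,sex,path`` — one row per
training subject.  ``path`` is the mesh file, absolute or relative to the
CSV's own directory.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .mesh import CorrespondedShape, TriangleTopology, read_corresponded_mesh

__all__ = ["COHORT_COLUMNS", "validate_cohort_table", "read_cohort_table",
           "write_cohort_table", "load_cohort"]

COHORT_COLUMNS = ("id", "age", "sex", "path")


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a cohort table in place and return it.

    Checks: required columns present, subject ids unique, ages finite and
    non-negative, sex restricted to the two-level domain.
    """
    missing = [c for c in COHORT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"cohort table missing columns {missing}")
    if table["id"].duplicated().any():
        dupes = table.loc[table["id"].duplicated(), "id"].tolist()
        raise ValidationError(f"duplicate subject ids: {dupes[:5]}")
    ages = pd.to_numeric(table["age"], errors="coerce").to_numpy(dtype=float)
    if not np.isfinite(ages).all() or (ages < 0).any():
        raise ValidationError("ages must be finite and non-negative")
    bad_sex = set(table["sex"]) - {"male", "female"}
    if bad_sex:
        raise ValidationError(f"sex must be 'male' or 'female', got {sorted(bad_sex)}")
    table = table.copy()
    table["age"] = ages
    return table


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return validate_cohort_table(pd.read_csv(path, dtype={"id": str, "sex": str}))


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_cohort_table(table).to_csv(path, index=False)


def load_cohort(
    csv_path: str | Path,
    topology: TriangleTopology,
    sex: str | None = None,
) -> list[CorrespondedShape]:
    """Load every mesh referenced by a cohort CSV, optionally one sex only."""
    csv_path = Path(csv_path)
    table = read_cohort_table(csv_path)
    if sex is not None:
        table = table[table["sex"] == sex]
    shapes = []
    for row in table.itertuples(index=False):
        mesh_path = Path(row.path)
        if not mesh_path.is_absolute():
            mesh_path = csv_path.parent / mesh_path
        shapes.append(
            read_corresponded_mesh(
                mesh_path, topology, subject_id=str(row.id),
                age=float(row.age), sex=str(row.sex),
            )
        )
    return shapes
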