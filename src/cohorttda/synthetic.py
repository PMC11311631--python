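"""Synthetic cohorts with planted topology, and geometric point-cloud fixtures.

Every pipeline stage is testable without any external data via three cohort
generators:

* **loop cohorts** -- subjects live on a noisy latent circle; two continuous
  features are the noisy coordinates, and three binary features are
  phase-shifted half-circle indicators (each level covers a 180-degree arc,
  phases 0/120/240 degrees by default), mimicking dichotomized prognostic
  factors that straddle a loop.  Nuisance continuous and binary features
  plus completely-at-random missingness make the table realistically messy.
* **void cohorts** -- subjects sit near the 8 vertices of a unit cube,
  diffused and (by default) pushed radially onto the circumscribed sphere so
  the interior is empty; the three planted binary features are the vertex
  coordinate signs, three near-independent axes around a central void.
* **null cohorts** -- unstructured multivariate-normal data, the reference
  model under which barcode durations follow the exponential null.

``sample_shapes`` provides exact geometric fixtures (square corners,
octahedron) and sampled manifolds (circle, sphere, torus) as distance
matrices for the persistence engine's unit tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .cohort_io import FeatureSchema, MixedDataset
from .mixed_distance import DistanceMatrix

__all__ = [
    "LoopCohortSpec",
    "VoidCohortSpec",
    "generate_loop_cohort",
    "generate_void_cohort",
    "generate_null_cohort",
    "sample_shapes",
]


def _validate_common(n: int, missing_rate: float) -> None:
    if n < 30:
        raise ValueError("n must be at least 30")
    if not 0 <= missing_rate < 0.5:
        raise ValueError("missing_rate must be in [0, 0.5)")


@dataclass(frozen=True)
class LoopCohortSpec:
    """Study conditions for a planted-loop cohort."""

    n: int = 300
    radius: float = 1.0
    radial_sd: float = 0.1
    binary_phases: tuple[float, ...] = (0.0, 120.0, 240.0)
    n_noise_continuous: int = 2
    n_noise_binary: int = 2
    missing_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        _validate_common(self.n, self.missing_rate)
        if self.radius <= 0 or self.radial_sd < 0:
            raise ValueError("radius must be positive and radial_sd non-negative")
        for ph in self.binary_phases:
            if not 0 <= ph < 360:
                raise ValueError("phases must lie in [0, 360)")


@dataclass(frozen=True)
class VoidCohortSpec:
    """Study conditions for a planted-void cohort."""

    n: int = 120
    sd: float = 0.15
    shell: float = 1.0
    n_noise_continuous: int = 2
    n_noise_binary: int = 2
    missing_rate: float = 0.05
    seed: int | None = None

    def __post_init__(self) -> None:
        _validate_common(self.n, self.missing_rate)
        if self.sd < 0 or not 0 <= self.shell <= 1:
            raise ValueError("sd must be non-negative and shell in [0, 1]")


def _apply_missing(values: pd.DataFrame, rate: float, rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    mask = rng.random(values.shape) < rate
    for c, name in enumerate(values.columns):
        col = values[name].copy()
        col[mask[:, c]] = np.nan
        values[name] = col


def _subject_ids(n: int) -> list[str]:
    width = len(str(n))
    return [f"S{i + 1:0{width}d}" for i in range(n)]


def generate_loop_cohort(spec: LoopCohortSpec) -> tuple[MixedDataset, dict]:
    """Generate a mixed-type cohort with a planted latent loop.

    Returns the dataset plus ground truth: the latent angle of each subject
    (degrees) and the planted phase of each binary loop feature.
    """
    rng = np.random.default_rng(spec.seed)
    phi = rng.uniform(0, 2 * np.pi, spec.n)
    r = spec.radius + rng.normal(0, spec.radial_sd, spec.n)
    x = r * np.cos(phi)
    y = r * np.sin(phi)

    schema: list[FeatureSchema] = [
        FeatureSchema("coord_x", "continuous"),
        FeatureSchema("coord_y", "continuous"),
    ]
    cols: dict[str, object] = {"coord_x": x, "coord_y": y}
    phase_features = []
    for ph in spec.binary_phases:
        name = f"phase{int(round(ph)):03d}"
        phase_features.append(name)
        ind = np.cos(phi - np.radians(ph)) > 0
        cols[name] = np.where(ind, "High", "Low")
        schema.append(FeatureSchema(name, "binary_symmetric", levels=("Low", "High")))
    for i in range(spec.n_noise_continuous):
        name = f"noise_c{i + 1}"
        cols[name] = rng.normal(0, 1, spec.n)
        schema.append(FeatureSchema(name, "continuous"))
    for i in range(spec.n_noise_binary):
        name = f"noise_b{i + 1}"
        cols[name] = np.where(rng.random(spec.n) < 0.5, "No", "Yes")
        schema.append(FeatureSchema(name, "binary_symmetric", levels=("No", "Yes")))

    values = pd.DataFrame(cols, index=_subject_ids(spec.n))
    for f in schema:
        if f.ftype != "continuous":
            values[f.name] = values[f.name].astype(object)
    _apply_missing(values, spec.missing_rate, rng)
    ds = MixedDataset(schema=schema, values=values, name="loop_cohort")
    truth = {
        "kind": "loop",
        "angle_deg": list(np.degrees(phi) % 360.0),
        "planted_features": phase_features,
        "phases_deg": list(spec.binary_phases),
    }
    return ds, truth


_CUBE_VERTICES = np.array(
    [[sx, sy, sz] for sx in (-0.5, 0.5) for sy in (-0.5, 0.5) for sz in (-0.5, 0.5)]
)


def generate_void_cohort(spec: VoidCohortSpec) -> tuple[MixedDataset, dict]:
    """Generate a mixed-type cohort with a planted central void.

    Subjects are assigned uniformly to the 8 vertices of a unit cube,
    diffused with isotropic Gaussian noise, and pushed radially onto the
    circumscribed sphere (radius sqrt(3)/2) with probability ``shell`` so
    the interior stays empty.  The three planted binary features are the
    vertex coordinate signs.  Returns the dataset plus the vertex assignment.
    """
    rng = np.random.default_rng(spec.seed)
    vertex = rng.integers(0, 8, spec.n)
    pos = _CUBE_VERTICES[vertex] + rng.normal(0, spec.sd, (spec.n, 3))
    push = rng.random(spec.n) < spec.shell
    norms = np.linalg.norm(pos, axis=1)
    norms[norms == 0] = 1.0
    radius = np.sqrt(3) / 2
    pos[push] = pos[push] / norms[push, None] * radius

    schema: list[FeatureSchema] = [
        FeatureSchema("coord_x", "continuous"),
        FeatureSchema("coord_y", "continuous"),
        FeatureSchema("coord_z", "continuous"),
    ]
    cols: dict[str, object] = {
        "coord_x": pos[:, 0], "coord_y": pos[:, 1], "coord_z": pos[:, 2],
    }
    axis_features = []
    for i, ax in enumerate("xyz"):
        name = f"axis_{ax}"
        axis_features.append(name)
        cols[name] = np.where(_CUBE_VERTICES[vertex][:, i] > 0, "High", "Low")
        schema.append(FeatureSchema(name, "binary_symmetric", levels=("Low", "High")))
    for i in range(spec.n_noise_continuous):
        name = f"noise_c{i + 1}"
        cols[name] = rng.normal(0, 1, spec.n)
        schema.append(FeatureSchema(name, "continuous"))
    for i in range(spec.n_noise_binary):
        name = f"noise_b{i + 1}"
        cols[name] = np.where(rng.random(spec.n) < 0.5, "No", "Yes")
        schema.append(FeatureSchema(name, "binary_symmetric", levels=("No", "Yes")))

    values = pd.DataFrame(cols, index=_subject_ids(spec.n))
    for f in schema:
        if f.ftype != "continuous":
            values[f.name] = values[f.name].astype(object)
    _apply_missing(values, spec.missing_rate, rng)
    ds = MixedDataset(schema=schema, values=values, name="void_cohort")
    truth = {
        "kind": "void",
        "vertex": [int(v) for v in vertex],
        "planted_features": axis_features,
    }
    return ds, truth


def generate_null_cohort(n: int, p: int, seed: int | None = None) -> MixedDataset:
    """Unstructured cohort: n x p independent standard-normal features."""
    if n < 20 or p < 2:
        raise ValueError("need n >= 20 and p >= 2")
    rng = np.random.default_rng(seed)
    names = [f"v{i + 1}" for i in range(p)]
    values = pd.DataFrame(rng.normal(0, 1, (n, p)), index=_subject_ids(n), columns=names)
    schema = [FeatureSchema(name, "continuous") for name in names]
    return MixedDataset(schema=schema, values=values, name="null_cohort")


def sample_shapes(
    shape: str,
    n: int | None = None,
    noise: float = 0.0,
    seed: int | None = None,
) -> DistanceMatrix:
    """Euclidean distance matrix of points on a named manifold.

    ``square_corners`` and ``octahedron`` are exact vertex fixtures;
    ``circle`` places n equally spaced points on the unit circle (plus
    optional Gaussian noise); ``sphere`` and ``torus`` sample uniformly at
    random (torus: major radius 2, minor radius 1).
    """
    rng = np.random.default_rng(seed)
    if shape == "square_corners":
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
    elif shape == "octahedron":
        pts = np.array(
            [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]],
            dtype=float,
        )
    elif shape == "circle":
        if n is None or n < 3:
            raise ValueError("circle needs n >= 3")
        th = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([np.cos(th), np.sin(th)])
    elif shape == "sphere":
        if n is None or n < 4:
            raise ValueError("sphere needs n >= 4")
        g = rng.normal(size=(n, 3))
        pts = g / np.linalg.norm(g, axis=1, keepdims=True)
    elif shape == "torus":
        if n is None or n < 4:
            raise ValueError("torus needs n >= 4")
        u = rng.uniform(0, 2 * np.pi, n)
        v = rng.uniform(0, 2 * np.pi, n)
        pts = np.column_stack(
            [(2 + np.cos(v)) * np.cos(u), (2 + np.cos(v)) * np.sin(u), np.sin(v)]
        )
    else:
        raise ValueError(f"unknown shape {shape!r}")
    if noise > 0:
        pts = pts + rng.normal(0, noise, pts.shape)
    D = squareform(pdist(pts))
    return DistanceMatrix(values=D, labels=tuple(range(pts.shape[0])))


def write_cohort_bundle(
    ds: MixedDataset,
    truth: dict | None,
    prefix: str | Path,
) -> dict[str, Path]:
    """Write cohort CSV + schema YAML (+ ground-truth JSON) for CLI consumption."""
    from .cohort_io import write_cohort

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": prefix.with_suffix(".csv"),
        "schema": prefix.parent / (prefix.name + ".schema.yaml"),
    }
    write_cohort(ds, paths["table"], paths["schema"])
    if truth is not None:
        paths["truth"] = prefix.parent / (prefix.name + ".truth.json")
        paths["truth"].write_text(json.dumps(truth, indent=2))
    return paths
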