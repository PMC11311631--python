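"""Embeddings and geometric interpretation of loops and voids.

Once a persistent loop or void is deemed significant, the question becomes
*which clinical features explain it*.  The tools here:

* classical MDS and UMAP embeddings of the subject distance matrix;
* sector averaging around a loop centroid: subjects are binned into angular
  sectors (default width 20 degrees) and each numerically-encoded feature
  is averaged per sector;
* a sinusoidal regression of sector means on (1, sin, cos) with the
  goodness-of-fit statistic kappa = MSE / sigma^2 -- small kappa means the
  feature varies circularly around the loop and helps explain it;
* centroid separation: the distance between the mean positions of the two
  groups defined by a binary feature, whose axis interprets loop/void
  directions;
* void tools: three binary axes in a 3-D embedding with a linear-
  independence diagnostic, unit-sphere projection of subjects around the
  void centroid, and an OFF mesh export of the representative skeleton.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_io import MixedDataset, to_numeric
from .mixed_distance import DistanceMatrix
from .rips import PersistencePair

__all__ = [
    "Embedding",
    "SinusoidFit",
    "LoopFit",
    "embed",
    "loop_centroid",
    "assign_sectors",
    "sector_profile",
    "fit_sinusoid",
    "fit_loop",
    "centroid_separation",
    "circos_table",
    "void_axes",
    "sphere_projection",
    "export_off",
]

DEFAULT_SECTOR_WIDTH = 20.0


@dataclass
class Embedding:
    """Low-dimensional coordinates of subjects derived from a distance matrix."""

    coords: np.ndarray
    method: str
    labels: tuple = ()

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2:
            raise ValueError("coords must be 2-D (subjects x k)")
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")

    @property
    def k(self) -> int:
        return self.coords.shape[1]

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.coords,
            index=list(self.labels) or range(self.coords.shape[0]),
            columns=[f"dim{i + 1}" for i in range(self.k)],
        )
        df.index.name = "subject"
        df.to_csv(path, sep="\t")


def _classical_mds(D: np.ndarray, k: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1][:k]
    lam = np.clip(evals[order], 0.0, None)
    return evecs[:, order] * np.sqrt(lam)


def embed(
    d: DistanceMatrix,
    method: str = "mds",
    k: int = 2,
    seed: int | None = None,
) -> Embedding:
    """Embed subjects in k dimensions from their distance matrix.

    ``mds`` is classical (Torgerson) scaling: eigendecomposition of the
    double-centered squared-distance matrix, top-k coordinates.  ``umap``
    runs UMAP on the precomputed distances with a fixed seed.
    """
    if k > d.n - 1:
        raise ValueError(f"k = {k} must be at most n - 1 = {d.n - 1}")
    if method == "mds":
        coords = _classical_mds(d.values, k)
    elif method == "umap":
        import umap  # heavy import, deferred

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(
                n_components=k, metric="precomputed", random_state=seed
            )
            coords = reducer.fit_transform(d.values)
        coords = np.asarray(coords, dtype=float)
    else:
        raise ValueError(f"unknown embedding method {method!r}")
    return Embedding(coords=coords, method=method, labels=d.labels)


def loop_centroid(emb: Embedding, rep: Sequence[tuple[int, ...]]) -> np.ndarray:
    """Mean embedded position of the distinct vertices of a representative cycle."""
    if rep is None or len(rep) == 0:
        raise ValueError("representative chain is empty")
    verts = sorted({v for simplex in rep for v in simplex})
    if max(verts) >= emb.coords.shape[0]:
        raise ValueError("representative refers to vertices outside the embedding")
    return emb.coords[verts].mean(axis=0)


def assign_sectors(
    emb: Embedding,
    centroid: np.ndarray,
    width: float = DEFAULT_SECTOR_WIDTH,
) -> np.ndarray:
    """Bin subjects into angular sectors about a centroid (2-D embeddings only).

    Returns one sector index (0 .. 360/width - 1) per subject; subjects
    sitting exactly at the centroid are excluded with a warning and marked -1.
    """
    if emb.k != 2:
        raise ValueError("sector assignment requires a 2-D embedding")
    n_sectors = 360.0 / width
    if abs(n_sectors - round(n_sectors)) > 1e-9:
        raise ValueError(f"sector width {width} does not divide 360")
    n_sectors = int(round(n_sectors))
    delta = emb.coords - np.asarray(centroid, dtype=float)
    at_centroid = np.all(delta == 0, axis=1)
    if at_centroid.any():
        warnings.warn(
            f"{at_centroid.sum()} subject(s) at the exact centroid excluded from sectors",
            stacklevel=2,
        )
    angles = np.degrees(np.arctan2(delta[:, 1], delta[:, 0])) % 360.0
    sectors = np.floor(angles / width).astype(int)
    sectors = np.clip(sectors, 0, n_sectors - 1)  # guard the 360.0 edge case
    sectors[at_centroid] = -1
    return sectors


def sector_profile(
    values: Sequence[float],
    sectors: np.ndarray,
    n_sectors: int | None = None,
) -> np.ndarray:
    """Per-sector arithmetic mean of a numeric feature; empty sectors are NaN."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(sectors)
    if n_sectors is None:
        n_sectors = int(s.max()) + 1
    out = np.full(n_sectors, np.nan)
    for sec in range(n_sectors):
        sel = (s == sec) & ~np.isnan(v)
        if sel.any():
            out[sec] = float(v[sel].mean())
    return out


@dataclass(frozen=True)
class SinusoidFit:
    """OLS fit of sector means on (1, sin theta, cos theta)."""

    beta0: float
    beta1: float
    beta2: float
    mse: float
    sigma2: float
    kappa: float
    peak_angle_deg: float
    n_sectors: int
    constant: bool = False

    def predict(self, theta_deg) -> np.ndarray:
        th = np.radians(np.asarray(theta_deg, dtype=float))
        return self.beta0 + self.beta1 * np.sin(th) + self.beta2 * np.cos(th)


def sector_center_angles(n_sectors: int, width: float = DEFAULT_SECTOR_WIDTH) -> np.ndarray:
    return (np.arange(n_sectors) + 0.5) * width


def fit_sinusoid(
    sector_means: Sequence[float],
    width: float = DEFAULT_SECTOR_WIDTH,
) -> SinusoidFit:
    """Fit mean(theta) = b0 + b1 sin(theta) + b2 cos(theta) to sector means.

    MSE = RSS / S and sigma^2 = total sum of squares about the mean / S over
    the same S non-missing sectors, so kappa = MSE / sigma^2 lies in [0, 1];
    small kappa indicates circular behavior.  Constant sector means leave
    kappa undefined: the result is flagged and excluded from rankings.
    """
    y = np.asarray(sector_means, dtype=float)
    ok = ~np.isnan(y)
    S = int(ok.sum())
    if S < 4:
        raise ValueError(f"need at least 4 non-missing sector means, got {S}")
    theta = np.radians(sector_center_angles(y.size, width))[ok]
    yy = y[ok]
    X = np.column_stack([np.ones(S), np.sin(theta), np.cos(theta)])
    beta, *_ = np.linalg.lstsq(X, yy, rcond=None)
    resid = yy - X @ beta
    mse = float(resid @ resid) / S
    sigma2 = float(np.sum((yy - yy.mean()) ** 2)) / S
    if sigma2 == 0.0:
        return SinusoidFit(
            beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
            mse=mse, sigma2=0.0, kappa=float("nan"),
            peak_angle_deg=float("nan"), n_sectors=S, constant=True,
        )
    peak = math.degrees(math.atan2(beta[1], beta[2])) % 360.0
    return SinusoidFit(
        beta0=float(beta[0]), beta1=float(beta[1]), beta2=float(beta[2]),
        mse=mse, sigma2=sigma2, kappa=mse / sigma2,
        peak_angle_deg=peak, n_sectors=S,
    )


@dataclass
class LoopFit:
    """Full sector-averaged interpretation of one loop."""

    centroid: np.ndarray
    sector_width: float
    sectors: np.ndarray
    sector_means: pd.DataFrame  # features x sectors
    fits: dict[str, SinusoidFit]

    @property
    def kappa(self) -> pd.Series:
        return pd.Series(
            {name: f.kappa for name, f in self.fits.items()}, name="kappa"
        )

    def ranked_features(self) -> list[str]:
        """Features ordered by kappa ascending; undefined-kappa fits excluded."""
        valid = {n: f.kappa for n, f in self.fits.items() if not f.constant}
        return sorted(valid, key=valid.get)

    def peak_angles(self) -> pd.Series:
        return pd.Series(
            {n: f.peak_angle_deg for n, f in self.fits.items() if not f.constant},
            name="peak_angle_deg",
        )


def _analysis_features(ds: MixedDataset) -> list[str]:
    """Features usable for sector/centroid analyses.

    Nominal features with more than two levels are excluded (their integer
    codes are unordered labels); dichotomize first to include them.
    """
    keep = []
    for f in ds.schema:
        if f.ftype == "nominal" and len(f.levels or ()) > 2:
            continue
        keep.append(f.name)
    return keep


def fit_loop(
    ds: MixedDataset,
    emb: Embedding,
    rep: Sequence[tuple[int, ...]],
    width: float = DEFAULT_SECTOR_WIDTH,
    features: list[str] | None = None,
) -> LoopFit:
    """Sector-average every analysis feature around a loop and fit sinusoids."""
    centroid = loop_centroid(emb, rep)
    sectors = assign_sectors(emb, centroid, width)
    n_sectors = int(round(360.0 / width))
    numeric = to_numeric(ds)
    if features is None:
        features = _analysis_features(ds)
    profiles = {}
    fits = {}
    for name in features:
        prof = sector_profile(numeric[name].to_numpy(), sectors, n_sectors)
        profiles[name] = prof
        if (~np.isnan(prof)).sum() >= 4:
            fits[name] = fit_sinusoid(prof, width)
    sector_means = pd.DataFrame(
        profiles, index=[f"sector_{s}" for s in range(n_sectors)]
    ).T
    return LoopFit(
        centroid=centroid, sector_width=width, sectors=sectors,
        sector_means=sector_means, fits=fits,
    )


@dataclass(frozen=True)
class CentroidSeparation:
    feature: str
    distance: float
    level_low: str
    level_high: str
    n_low: int
    n_high: int
    axis: np.ndarray  # 2 x k segment endpoints


def centroid_separation(
    ds: MixedDataset,
    coords: np.ndarray,
    feature: str,
) -> CentroidSeparation:
    """Distance between the mean positions of a binary feature's two groups.

    ``coords`` is any subjects x k coordinate matrix: a 2-D/3-D embedding
    (default pipeline choice) or the full numeric feature space.
    """
    f = ds.feature(feature)
    if not f.is_binary:
        raise ValueError(f"feature {feature!r} is not binary; dichotomize first")
    coords = np.asarray(coords, dtype=float)
    col = ds.values[feature]
    lv0, lv1 = f.levels
    m0 = (col == lv0).to_numpy()
    m1 = (col == lv1).to_numpy()
    if not m0.any() or not m1.any():
        raise ValueError(f"feature {feature!r}: one level has no subjects")
    c0 = coords[m0].mean(axis=0)
    c1 = coords[m1].mean(axis=0)
    return CentroidSeparation(
        feature=feature,
        distance=float(np.linalg.norm(c1 - c0)),
        level_low=lv0, level_high=lv1,
        n_low=int(m0.sum()), n_high=int(m1.sum()),
        axis=np.vstack([c0, c1]),
    )


def circos_table(
    loopfit: LoopFit,
    features: list[str] | None = None,
) -> pd.DataFrame:
    """Feature x sector grid for circular plotting.

    Rows are ordered by kappa ascending (best circular fits first); each row
    is min-max scaled to [0, 1].  Constant rows scale to all zeros and keep
    a ``constant`` marker in the index name ordering (they sort last).
    """
    if features is None:
        features = loopfit.ranked_features()
    rows = {}
    for name in features:
        prof = loopfit.sector_means.loc[name].to_numpy(dtype=float)
        lo, hi = np.nanmin(prof), np.nanmax(prof)
        rows[name] = np.zeros_like(prof) if hi == lo else (prof - lo) / (hi - lo)
    return pd.DataFrame(rows, index=loopfit.sector_means.columns).T


@dataclass
class VoidAxes:
    features: list[str]
    segments: dict[str, np.ndarray]  # feature -> 2 x 3 centroid endpoints
    directions: np.ndarray  # 3 x 3 unit direction cosines (rows = features)
    determinant: float
    collinear: bool


def void_axes(
    ds: MixedDataset,
    emb3: Embedding,
    features: Sequence[str],
    det_tol: float = 1e-6,
) -> VoidAxes:
    """Binary-feature axes of a void in a 3-D embedding.

    For each of three binary features, the segment joins its two group
    centroids.  The 3x3 matrix of unit axis directions and its determinant
    diagnose linear independence: statistically dependent features can still
    span three independent directions.  A near-zero determinant is flagged,
    not an error.
    """
    if emb3.k != 3:
        raise ValueError("void axes require a 3-D embedding")
    features = list(features)
    if len(features) != 3:
        raise ValueError("exactly three binary features are required")
    segments = {}
    dirs = []
    for name in features:
        sep = centroid_separation(ds, emb3.coords, name)
        segments[name] = sep.axis
        v = sep.axis[1] - sep.axis[0]
        norm = np.linalg.norm(v)
        dirs.append(v / norm if norm > 0 else v)
    directions = np.vstack(dirs)
    det = float(np.linalg.det(directions))
    collinear = abs(det) < det_tol
    if collinear:
        warnings.warn(
            f"void axes nearly collinear (|det| = {abs(det):.2e})", stacklevel=2
        )
    return VoidAxes(
        features=features, segments=segments, directions=directions,
        determinant=det, collinear=collinear,
    )


def sphere_projection(
    emb3: Embedding,
    centroid: np.ndarray,
    values: Sequence[float],
) -> pd.DataFrame:
    """Project subjects onto the unit sphere around a void centroid.

    Each subject's displacement from the centroid is normalized to unit
    length and paired with its (numeric) feature value for surface plots.
    Subjects at the exact centroid are excluded with a warning.
    """
    if emb3.k != 3:
        raise ValueError("sphere projection requires a 3-D embedding")
    delta = emb3.coords - np.asarray(centroid, dtype=float)
    norms = np.linalg.norm(delta, axis=1)
    keep = norms > 0
    if (~keep).any():
        warnings.warn(
            f"{(~keep).sum()} subject(s) at the void centroid excluded", stacklevel=2
        )
    unit = delta[keep] / norms[keep, None]
    labels = np.asarray(list(emb3.labels) or range(delta.shape[0]))[keep]
    vals = np.asarray(values, dtype=float)[keep]
    return pd.DataFrame(
        {"x": unit[:, 0], "y": unit[:, 1], "z": unit[:, 2], "value": vals},
        index=labels,
    )


def export_off(
    triangles: Sequence[tuple[int, int, int]],
    coords: np.ndarray,
    path: str | Path,
) -> None:
    """Write a triangle skeleton (e.g. a void representative) as an OFF mesh."""
    coords = np.asarray(coords, dtype=float)
    verts = sorted({v for t in triangles for v in t})
    remap = {v: i for i, v in enumerate(verts)}
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(verts)} {len(triangles)} 0\n")
        for v in verts:
            x, y, z = (coords[v].tolist() + [0.0, 0.0])[:3]
            fh.write(f"{x:.8f} {y:.8f} {z:.8f}\n")
        for t in triangles:
            fh.write("3 " + " ".join(str(remap[v]) for v in t) + "\n")
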