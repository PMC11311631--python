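"""Gower ("daisy") dissimilarities for mixed-type cohorts.

The subject-by-subject distance is the Gower general dissimilarity
coefficient: a missing-aware weighted average of per-feature contributions,

    d(i, j) = sum_k delta_ijk * d_ijk / sum_k delta_ijk

where continuous and ordinal features contribute the absolute difference
scaled by the feature's observed range (ordinal values first replaced by
rank codes), nominal and symmetric-binary features contribute a 0/1
mismatch indicator, and asymmetric-binary features are excluded from the
average for pairs in which both subjects lack the trait.  All distances lie
in [0, 1].

The module also provides two binary *feature*-space distances (Sokal-
Michener matching distance and a Pearson-correlation distance) used to
cluster binary clinical features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort_io import MixedDataset, to_numeric

__all__ = [
    "DistanceMatrix",
    "UndefinedDistanceError",
    "daisy_distance",
    "binary_feature_distance",
]


class UndefinedDistanceError(ValueError):
    """A pair of subjects shares no usable feature, so their distance is undefined."""


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with zero diagonal."""

    values: np.ndarray
    labels: tuple

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.labels) != v.shape[0]:
            raise ValueError("label count does not match matrix size")
        finite = np.isfinite(v) | np.isnan(v)
        if not finite.all():
            raise ValueError("distance matrix contains infinities")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(v - v.T)) > 1e-10:
                raise ValueError("distance matrix is not symmetric")
            if np.nanmax(np.abs(np.diag(v))) > 0:
                raise ValueError("distance matrix diagonal is not zero")
        self.values = v
        self.labels = tuple(self.labels)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def max_distance(self) -> float:
        return float(np.nanmax(self.values))

    # -- I/O -----------------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.values, index=self.labels, columns=self.labels).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(values=df.to_numpy(dtype=float), labels=tuple(df.index))

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style text export."""
        with open(path, "w") as fh:
            fh.write(f"{self.n}\n")
            for i in range(self.n):
                row = " ".join(f"{self.values[i, j]:.10f}" for j in range(i))
                name = str(self.labels[i])[:10].ljust(10)
                fh.write(f"{name} {row}".rstrip() + "\n")


def _ordinal_ranks(levels: tuple) -> dict:
    return {lv: float(i) for i, lv in enumerate(levels)}


def daisy_distance(ds: MixedDataset, weights: dict | None = None) -> DistanceMatrix:
    """Gower dissimilarity between all subject pairs of a mixed dataset.

    Parameters
    ----------
    ds
        The cohort.  Every pair of subjects must share at least one feature
        observed in both (otherwise :class:`UndefinedDistanceError`).
    weights
        Optional per-feature weights (name -> weight); default uniform.

    Notes
    -----
    Continuous features with zero observed range carry no information and
    are dropped with a warning rather than erroring, since real clinical
    extracts contain constant columns.
    """
    n = ds.n_subjects
    num = np.zeros((n, n))
    den = np.zeros((n, n))
    for f in ds.schema:
        w = 1.0 if weights is None else float(weights.get(f.name, 1.0))
        col = ds.values[f.name]
        valid = col.notna().to_numpy()
        both = np.outer(valid, valid)
        if f.ftype in ("continuous", "ordinal"):
            if f.ftype == "continuous":
                x = col.to_numpy(dtype=float)
            else:
                x = col.map(_ordinal_ranks(f.levels)).to_numpy(dtype=float)
            obs = x[valid]
            rng = float(np.max(obs) - np.min(obs)) if obs.size else 0.0
            if rng == 0.0:
                warnings.warn(
                    f"feature {f.name!r} has zero observed range; dropped from Gower sum",
                    stacklevel=2,
                )
                continue
            x0 = np.where(valid, x, 0.0)
            contrib = np.abs(x0[:, None] - x0[None, :]) / rng
            delta = both
        else:
            codes = np.full(n, -1, dtype=int)
            lut = {lv: i for i, lv in enumerate(f.levels)}
            codes[valid] = [lut[v] for v in col[valid]]
            contrib = (codes[:, None] != codes[None, :]).astype(float)
            delta = both
            if f.ftype == "binary_asymmetric":
                pos = lut[f.positive_level]
                neg_code = 1 - pos
                is_neg = valid & (codes == neg_code)
                delta = both & ~np.outer(is_neg, is_neg)
        num += w * np.where(delta, contrib, 0.0)
        den += w * delta

    np.fill_diagonal(den, 1.0)  # diagonal distance is 0 by definition
    np.fill_diagonal(num, 0.0)
    bad = den == 0
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise UndefinedDistanceError(
            f"subjects {ds.subjects[i]!r} and {ds.subjects[j]!r} share no usable feature"
        )
    d = num / den
    d = 0.5 * (d + d.T)  # symmetrize exact floating ties
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(values=d, labels=tuple(ds.subjects))


def binary_feature_distance(
    ds: MixedDataset,
    metric: str = "sokal_michener",
    features: list[str] | None = None,
) -> DistanceMatrix:
    """Distance between binary *features*, for feature clustering.

    ``sokal_michener``: 1 - (matches / comparisons) over pairwise-complete
    subjects.  ``pearson``: (1 - r) / 2 with r the Pearson correlation of the
    two 0/1 vectors, mapping perfect agreement to 0 and perfect
    anti-agreement to 1.  A feature constant on the pairwise-complete subset
    leaves the Pearson distance undefined; the entry is reported missing
    (NaN) with a warning.
    """
    if metric not in ("sokal_michener", "pearson"):
        raise ValueError(f"unknown metric {metric!r}")
    if features is None:
        features = ds.binary_features()
    for name in features:
        if not ds.feature(name).is_binary:
            raise ValueError(f"feature {name!r} is not binary")
    X = to_numeric(ds)[features].to_numpy(dtype=float)
    p = len(features)
    d = np.zeros((p, p))
    for a in range(p):
        for b in range(a + 1, p):
            ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
            u, v = X[ok, a], X[ok, b]
            if u.size == 0:
                d[a, b] = np.nan
                warnings.warn(f"features {features[a]!r}/{features[b]!r}: no shared subjects")
            elif metric == "sokal_michener":
                d[a, b] = 1.0 - float(np.mean(u == v))
            else:
                if np.all(u == u[0]) or np.all(v == v[0]):
                    d[a, b] = np.nan
                    warnings.warn(
                        f"feature {features[a]!r} or {features[b]!r} constant on shared "
                        "subjects; Pearson distance undefined"
                    )
                else:
                    r = float(np.corrcoef(u, v)[0, 1])
                    d[a, b] = (1.0 - r) / 2.0
            d[b, a] = d[a, b]
    return DistanceMatrix(values=d, labels=tuple(features))
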