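"""Vietoris-Rips filtrations and persistent homology over Z/2.

A Rips complex at scale tau contains every simplex whose vertices are
pairwise within tau.  Sweeping tau from 0 to the maximum observed distance
yields a filtration; persistent homology tracks when connected components
(dimension 0), loops (dimension 1), and voids (dimension 2) appear and
disappear.  Each finite class is reported as a (birth, death) pair together
with a representative cycle (the reduced boundary column at the death
simplex), so loops can be drawn and interpreted in patient space.

Dimension 0 is computed by Kruskal union-find (single-linkage equivalence);
dimensions 1 and 2 by sparse GF(2) boundary reduction with the clearing
optimization.  The combinatorial size of the filtration grows as
choose(n, d+2); a resource guard refuses runs whose projected simplex count
exceeds a configurable ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._reduction import extract_column, reduce_boundary
from .mixed_distance import DistanceMatrix

__all__ = [
    "Simplex",
    "PersistencePair",
    "BarcodeSet",
    "FiltrationSizeError",
    "projected_simplex_counts",
    "build_filtration",
    "persistent_homology",
    "representative_cycle",
    "cut_clusters",
]

DEFAULT_SIMPLEX_CEILING = 50_000_000


class FiltrationSizeError(RuntimeError):
    """The projected filtration is too large to build."""


@dataclass(frozen=True)
class Simplex:
    """A simplex of the filtration: sorted vertex tuple plus its diameter."""

    vertices: tuple[int, ...]
    diameter: float

    @property
    def dim(self) -> int:
        return len(self.vertices) - 1


@dataclass(frozen=True)
class PersistencePair:
    """One homology class: dimension, birth/death scales, representative chain.

    ``representative`` is a tuple of vertex tuples: edges for dimension 1,
    triangles for dimension 2, and the vertex set of the component for
    dimension 0.  Infinite classes in dimension >= 1 carry no representative.
    """

    dim: int
    birth: float
    death: float
    representative: tuple[tuple[int, ...], ...] | None = None

    @property
    def duration(self) -> float:
        return self.death - self.birth

    @property
    def is_infinite(self) -> bool:
        return math.isinf(self.death)


@dataclass
class BarcodeSet:
    """All persistence pairs of one run, with the filtration parameters used."""

    pairs: list[PersistencePair]
    max_dim: int
    max_scale: float
    n_points: int
    labels: tuple = ()

    def in_dim(self, dim: int) -> list[PersistencePair]:
        return [p for p in self.pairs if p.dim == dim]

    def finite(self, dim: int | None = None) -> list[PersistencePair]:
        sel = self.pairs if dim is None else self.in_dim(dim)
        return [p for p in sel if not p.is_infinite]

    def durations(self, dim: int) -> np.ndarray:
        return np.array([p.duration for p in self.finite(dim)], dtype=float)

    def most_persistent(self, dim: int) -> PersistencePair | None:
        fin = self.finite(dim)
        return max(fin, key=lambda p: p.duration) if fin else None

    # -- TSV dialect: dim, birth, death, duration, representative ------------
    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("dim\tbirth\tdeath\tduration\trepresentative\n")
            for p in sorted(self.pairs, key=lambda q: (q.dim, q.birth, q.death)):
                rep = ""
                if p.representative is not None:
                    rep = ";".join("-".join(map(str, s)) for s in p.representative)
                death = "inf" if p.is_infinite else repr(p.death)
                dur = "inf" if p.is_infinite else repr(p.duration)
                fh.write(f"{p.dim}\t{p.birth!r}\t{death}\t{dur}\t{rep}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, max_dim: int = 2, max_scale: float = float("nan"),
                 n_points: int = 0) -> "BarcodeSet":
        pairs = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:3] != ["dim", "birth", "death"]:
                raise ValueError(f"{path}: not a barcode TSV")
            for line in fh:
                f = line.rstrip("\n").split("\t")
                rep = None
                if len(f) > 4 and f[4]:
                    rep = tuple(tuple(int(v) for v in s.split("-")) for s in f[4].split(";"))
                pairs.append(PersistencePair(int(f[0]), float(f[1]), float(f[2]), rep))
        return cls(pairs=pairs, max_dim=max_dim, max_scale=max_scale, n_points=n_points)


# ---------------------------------------------------------------------------
# sizing guard


def projected_simplex_counts(n_points: int, max_dim: int) -> dict[int, int]:
    """Simplex counts by dimension for a full complex on ``n_points`` vertices.

    Building homology through dimension ``max_dim`` requires simplices up to
    dimension ``max_dim + 1``; the count in dimension d is choose(n, d+1).
    This combinatorial growth is what makes higher-dimensional holes
    infeasible to assess on desktop hardware.
    """
    return {d: math.comb(n_points, d + 1) for d in range(max_dim + 2)}


def _check_ceiling(n: int, max_dim: int, ceiling: int) -> None:
    counts = projected_simplex_counts(n, max_dim)
    total = sum(counts.values())
    if total > ceiling:
        detail = ", ".join(f"choose({n}, {d + 1}) = {c:,}" for d, c in counts.items())
        raise FiltrationSizeError(
            f"projected filtration of {total:,} simplices exceeds the ceiling of "
            f"{ceiling:,} ({detail}); lower max_dim or max_scale"
        )


# ---------------------------------------------------------------------------
# simplex enumeration (vectorized per leading vertex)


def _enumerate_edges(D: np.ndarray, max_scale: float):
    n = D.shape[0]
    iu, ju = np.triu_indices(n, 1)
    w = D[iu, ju]
    keep = w <= max_scale
    iu, ju, w = iu[keep], ju[keep], w[keep]
    order = np.lexsort((ju, iu, w))
    return np.column_stack([iu[order], ju[order]]).astype(np.int64), w[order]


def _enumerate_triangles(D: np.ndarray, max_scale: float):
    n = D.shape[0]
    vs, ds = [], []
    for i in range(n - 2):
        m = n - 1 - i
        jj, kk = np.triu_indices(m, 1)
        j = i + 1 + jj
        k = i + 1 + kk
        diam = np.maximum(np.maximum(D[i, j], D[i, k]), D[j, k])
        keep = diam <= max_scale
        if keep.any():
            vs.append(np.column_stack([np.full(keep.sum(), i), j[keep], k[keep]]))
            ds.append(diam[keep])
    if not vs:
        return np.empty((0, 3), np.int64), np.empty(0, float)
    verts = np.concatenate(vs).astype(np.int64)
    diam = np.concatenate(ds)
    order = np.lexsort((verts[:, 2], verts[:, 1], verts[:, 0], diam))
    return verts[order], diam[order]


def _enumerate_tetrahedra(D: np.ndarray, max_scale: float):
    n = D.shape[0]
    vs, ds = [], []
    for i in range(n - 3):
        for j in range(i + 1, n - 2):
            if D[i, j] > max_scale:
                continue
            m = n - 1 - j
            kk, ll = np.triu_indices(m, 1)
            k = j + 1 + kk
            lo = j + 1 + ll
            diam = np.maximum.reduce(
                [
                    np.full(k.shape, D[i, j]),
                    D[i, k], D[i, lo], D[j, k], D[j, lo], D[k, lo],
                ]
            )
            keep = diam <= max_scale
            if keep.any():
                vs.append(
                    np.column_stack(
                        [np.full(keep.sum(), i), np.full(keep.sum(), j), k[keep], lo[keep]]
                    )
                )
                ds.append(diam[keep])
    if not vs:
        return np.empty((0, 4), np.int64), np.empty(0, float)
    verts = np.concatenate(vs).astype(np.int64)
    diam = np.concatenate(ds)
    order = np.lexsort((verts[:, 3], verts[:, 2], verts[:, 1], verts[:, 0], diam))
    return verts[order], diam[order]


_ENUM = {1: _enumerate_edges, 2: _enumerate_triangles, 3: _enumerate_tetrahedra}


def _simplex_keys(verts: np.ndarray, n: int) -> np.ndarray:
    key = np.zeros(verts.shape[0], np.int64)
    for c in range(verts.shape[1]):
        key = key * n + verts[:, c]
    return key


def _face_ranks(verts_hi: np.ndarray, verts_lo: np.ndarray, n: int) -> np.ndarray:
    """Rank (filtration index) of every codim-1 face of each high simplex."""
    keys_lo = _simplex_keys(verts_lo, n)
    order = np.argsort(keys_lo)
    sorted_keys = keys_lo[order]
    m, w = verts_hi.shape
    faces = np.empty((m, w), np.int64)
    for omit in range(w):
        cols = [c for c in range(w) if c != omit]
        fkeys = _simplex_keys(verts_hi[:, cols], n)
        pos = np.searchsorted(sorted_keys, fkeys)
        faces[:, omit] = order[pos]
    return faces


@dataclass
class Filtration:
    """Simplices of a Rips filtration grouped by dimension, in filtration order."""

    verts: dict[int, np.ndarray]
    diam: dict[int, np.ndarray]
    max_dim: int
    max_scale: float
    n_points: int

    def count(self, dim: int | None = None) -> int:
        if dim is not None:
            return self.verts[dim].shape[0] if dim in self.verts else 0
        return sum(v.shape[0] for v in self.verts.values())

    def simplices(self) -> Iterator[Simplex]:
        """All simplices sorted by (diameter, dimension, lexicographic vertices)."""
        items = []
        for d in sorted(self.verts):
            v, dm = self.verts[d], self.diam[d]
            for r in range(v.shape[0]):
                items.append(Simplex(tuple(int(x) for x in v[r]), float(dm[r])))
        items.sort(key=lambda s: (s.diameter, s.dim, s.vertices))
        return iter(items)


def build_filtration(
    d: DistanceMatrix,
    max_dim: int,
    max_scale: float | None = None,
    ceiling: int = DEFAULT_SIMPLEX_CEILING,
) -> Filtration:
    """Enumerate all simplices of dimension <= max_dim + 1 with diameter <= max_scale."""
    if max_dim not in (1, 2):
        raise ValueError("max_dim must be 1 or 2")
    if max_scale is None:
        max_scale = d.max_distance()
    if max_scale <= 0:
        raise ValueError("max_scale must be positive")
    n = d.n
    _check_ceiling(n, max_dim, ceiling)
    D = d.values
    verts = {0: np.arange(n, dtype=np.int64)[:, None]}
    diam = {0: np.zeros(n)}
    for sd in range(1, max_dim + 2):
        verts[sd], diam[sd] = _ENUM[sd](D, max_scale)
    return Filtration(verts=verts, diam=diam, max_dim=max_dim,
                      max_scale=float(max_scale), n_points=n)


# ---------------------------------------------------------------------------
# dimension 0: Kruskal union-find with component tracking


def _dim0_pairs(n: int, edges: np.ndarray, weights: np.ndarray):
    parent = list(range(n))
    members: list[list[int] | None] = [[i] for i in range(n)]

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pairs = []
    for e in range(edges.shape[0]):
        a, b = int(edges[e, 0]), int(edges[e, 1])
        ra, rb = find(a), find(b)
        if ra == rb:
            continue
        # the smaller component dies (tie: larger root index), its vertex set
        # is the representative of the dying class
        if (len(members[ra]), -ra) < (len(members[rb]), -rb):
            ra, rb = rb, ra
        w = float(weights[e])
        if w > 0:
            pairs.append(
                PersistencePair(0, 0.0, w, tuple((v,) for v in sorted(members[rb])))
            )
        parent[rb] = ra
        members[ra] = members[ra] + members[rb]  # type: ignore[operator]
        members[rb] = None
    roots = {find(i) for i in range(n)}
    for r in sorted(roots):
        pairs.append(
            PersistencePair(0, 0.0, math.inf, tuple((v,) for v in sorted(members[r])))
        )
    return pairs


# ---------------------------------------------------------------------------
# main driver


def persistent_homology(
    d: DistanceMatrix,
    max_dim: int = 2,
    max_scale: float | None = None,
    ceiling: int = DEFAULT_SIMPLEX_CEILING,
    with_representatives: bool = True,
) -> BarcodeSet:
    """Persistent homology of the Rips filtration of a distance matrix.

    Returns all positive-duration classes in dimensions 0..max_dim, each with
    birth and death scales and (for finite classes) a representative cycle.
    With the default ``max_scale`` (the maximum observed distance) dimension 0
    has exactly one essential class and no higher dimension has any.
    """
    n = d.n
    if max_scale is None:
        # Beyond the enclosing radius min_i max_j d(i, j) the complex is a
        # cone, hence contractible: no class in dimension >= 1 is born or
        # still alive there.  Enumerating dims >= 1 only up to that radius
        # leaves their diagrams identical and trims the filtration.
        full_scale = d.max_distance()
        enum_scale = float(min(full_scale, np.min(np.max(d.values, axis=1))))
    else:
        full_scale = enum_scale = float(max_scale)
    filt = build_filtration(d, max_dim, enum_scale, ceiling)
    if full_scale > enum_scale:
        edges0, w0 = _enumerate_edges(d.values, full_scale)
    else:
        edges0, w0 = filt.verts[1], filt.diam[1]
    pairs: list[PersistencePair] = list(_dim0_pairs(n, edges0, w0))

    # reduce top dimension down to 2 so clearing information flows downward
    results: dict[int, tuple] = {}
    cleared: dict[int, np.ndarray] = {}
    for sd in range(max_dim + 1, 1, -1):
        vhi, dhi = filt.verts[sd], filt.diam[sd]
        vlo = filt.verts[sd - 1]
        ncols = vhi.shape[0]
        n_rows = vlo.shape[0]
        if ncols == 0:
            results[sd] = (np.full(n_rows, -1, np.int64), np.zeros(0, bool), None)
            continue
        columns = _face_ranks(vhi, vlo, n)
        skip = None
        if sd in cleared:
            skip = np.zeros(ncols, np.uint8)
            skip[cleared[sd]] = 1
        pivot_col, is_zero, store = reduce_boundary(columns, n_rows, skip)
        results[sd] = (pivot_col, is_zero, store)
        # rows claimed as pivots are positive columns one dimension down
        cleared[sd - 1] = np.nonzero(pivot_col >= 0)[0]

    # positive d-simplices (creators) per dimension
    for dim in range(1, max_dim + 1):
        vlo, dlo = filt.verts[dim], filt.diam[dim]
        vhi, dhi = filt.verts[dim + 1], filt.diam[dim + 1]
        pivot_col, _, store = results[dim + 1]
        if dim == 1:
            # positive edges: those that do not merge components
            creators = _positive_edges(n, filt.verts[1])
        else:
            _, is_zero2, _ = results[dim]
            creators = np.nonzero(is_zero2)[0]
        creator_mask = np.zeros(vlo.shape[0], bool)
        creator_mask[creators] = True
        for p in creators:
            j = int(pivot_col[p]) if pivot_col.size else -1
            if j >= 0:
                birth, death = float(dlo[p]), float(dhi[j])
                if death > birth:
                    rep = None
                    if with_representatives and store is not None:
                        rows = extract_column(store, j)
                        rep = tuple(
                            tuple(int(x) for x in vlo[r]) for r in rows
                        )
                    pairs.append(PersistencePair(dim, birth, death, rep))
            else:
                pairs.append(PersistencePair(dim, float(dlo[p]), math.inf, None))

    pairs.sort(key=lambda p: (p.dim, p.birth, p.death))
    return BarcodeSet(pairs=pairs, max_dim=max_dim, max_scale=full_scale,
                      n_points=n, labels=d.labels)


def _positive_edges(n: int, edges: np.ndarray) -> np.ndarray:
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pos = []
    for e in range(edges.shape[0]):
        ra, rb = find(int(edges[e, 0])), find(int(edges[e, 1]))
        if ra == rb:
            pos.append(e)
        else:
            parent[rb] = ra
    return np.asarray(pos, dtype=np.int64)


def representative_cycle(pair: PersistencePair) -> tuple[tuple[int, ...], ...]:
    """The representative chain attached to a finite pair.

    For dimension 0 the representative is the vertex set of the component;
    infinite classes in dimension >= 1 have no representative.
    """
    if pair.is_infinite and pair.dim >= 1:
        raise ValueError("infinite classes in dimension >= 1 have no representative")
    if pair.representative is None:
        raise ValueError("pair carries no representative (computed with_representatives=False?)")
    return pair.representative


def cut_clusters(d: DistanceMatrix, k: int) -> np.ndarray:
    """Average-linkage hierarchical clustering cut to k clusters (labels 0..k-1)."""
    if not 1 <= k <= d.n:
        raise ValueError(f"k must be in [1, {d.n}]")
    if k == d.n:
        return np.arange(d.n)
    Z = hierarchy.linkage(squareform(d.values, checks=False), method="average")
    return hierarchy.fcluster(Z, t=k, criterion="maxclust") - 1
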