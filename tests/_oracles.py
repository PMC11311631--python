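"""Independent brute-force oracles used only by the test suite.

These deliberately share no code with the package: persistence is computed
by enumerating every simplex and reducing a dense GF(2) boundary matrix of
the full complex with Python sets; the Gower distance is an explicit
per-pair, per-feature loop following the textbook definition.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd


def brute_force_ph(D: np.ndarray, max_dim: int = 2, max_scale: float | None = None):
    """All positive-duration persistence pairs (dim, birth, death) of a Rips
    filtration, by naive full-boundary-matrix reduction.  Infinite classes in
    dimensions <= max_dim are included with death = inf."""
    n = D.shape[0]
    if max_scale is None:
        max_scale = float(D.max())
    simplices = []
    for k in range(1, max_dim + 3):
        for comb in itertools.combinations(range(n), k):
            diam = 0.0 if k == 1 else max(
                D[a, b] for a, b in itertools.combinations(comb, 2)
            )
            if diam <= max_scale:
                simplices.append((float(diam), k - 1, comb))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}
    cols: list[set[int]] = []
    for diam, dim, comb in simplices:
        if dim == 0:
            cols.append(set())
        else:
            cols.append({index[f] for f in itertools.combinations(comb, dim)})
    low_owner: dict[int, int] = {}
    for j in range(len(simplices)):
        col = cols[j]
        while col:
            low = max(col)
            if low in low_owner:
                col ^= cols[low_owner[low]]
            else:
                low_owner[low] = j
                break
        cols[j] = col
    deaths = {low: j for low, j in low_owner.items()}
    results = []
    for i, (diam, dim, comb) in enumerate(simplices):
        if cols[i]:
            continue  # negative simplex: kills a class, births nothing
        if i in deaths:
            death = simplices[deaths[i]][0]
            if death > diam:
                results.append((dim, diam, death))
        elif dim <= max_dim:
            results.append((dim, diam, math.inf))
    return sorted(results)


def brute_force_gower(ds) -> np.ndarray:
    """Per-pair, per-feature Gower dissimilarity straight from the definition."""
    n = ds.n_subjects
    vals = ds.values
    ranges = {}
    ranks = {}
    for f in ds.schema:
        if f.ftype == "continuous":
            obs = vals[f.name].dropna().astype(float)
            ranges[f.name] = float(obs.max() - obs.min()) if len(obs) else 0.0
        elif f.ftype == "ordinal":
            ranks[f.name] = {lv: float(i) for i, lv in enumerate(f.levels)}
            obs = vals[f.name].dropna().map(ranks[f.name])
            ranges[f.name] = float(obs.max() - obs.min()) if len(obs) else 0.0
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            num = den = 0.0
            for f in ds.schema:
                vi, vj = vals[f.name].iloc[i], vals[f.name].iloc[j]
                if pd.isna(vi) or pd.isna(vj):
                    continue
                if f.ftype in ("continuous", "ordinal"):
                    r = ranges[f.name]
                    if r == 0:
                        continue
                    if f.ftype == "ordinal":
                        vi, vj = ranks[f.name][vi], ranks[f.name][vj]
                    num += abs(float(vi) - float(vj)) / r
                    den += 1.0
                elif f.ftype == "binary_asymmetric":
                    if vi != f.positive_level and vj != f.positive_level:
                        continue
                    num += 0.0 if vi == vj else 1.0
                    den += 1.0
                else:
                    num += 0.0 if vi == vj else 1.0
                    den += 1.0
            out[i, j] = out[j, i] = num / den
    return out


def textbook_silhouette(D: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Silhouette widths computed directly from the definition."""
    labels = np.asarray(labels)
    n = D.shape[0]
    s = np.zeros(n)
    for i in range(n):
        same = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not same:
            s[i] = 0.0
            continue
        a = float(np.mean([D[i, j] for j in same]))
        b = math.inf
        for c in set(labels) - {labels[i]}:
            others = [j for j in range(n) if labels[j] == c]
            b = min(b, float(np.mean([D[i, j] for j in others])))
        s[i] = (b - a) / max(a, b)
    return s


def random_mixed_dataset(rng: np.random.Generator, n: int = 10, missing_rate: float = 0.1):
    """A random small mixed-type table exercising all five feature types."""
    from cohorttda.cohort_io import FeatureSchema, MixedDataset

    schema = [
        FeatureSchema("age", "continuous"),
        FeatureSchema("score", "continuous"),
        FeatureSchema("stage", "ordinal", levels=("I", "II", "III", "IV")),
        FeatureSchema("subtype", "nominal", levels=("A", "B", "C")),
        FeatureSchema("sex", "binary_symmetric", levels=("F", "M")),
        FeatureSchema("mutation", "binary_asymmetric", levels=("Absent", "Present"),
                      positive_level="Present"),
    ]
    cols = {
        "age": rng.normal(60, 10, n),
        "score": rng.uniform(0, 100, n),
        "stage": rng.choice(["I", "II", "III", "IV"], n),
        "subtype": rng.choice(["A", "B", "C"], n),
        "sex": rng.choice(["F", "M"], n),
        "mutation": rng.choice(["Absent", "Present"], n, p=[0.7, 0.3]),
    }
    values = pd.DataFrame(cols, index=[f"P{i}" for i in range(n)])
    for name in ("stage", "subtype", "sex", "mutation"):
        values[name] = values[name].astype(object)
    if missing_rate > 0:
        mask = rng.random(values.shape) < missing_rate
        # always keep one feature complete so no pair is fully unobserved
        mask[:, 0] = False
        for c, name in enumerate(values.columns):
            col = values[name].copy()
            col[mask[:, c]] = np.nan
            values[name] = col
    return MixedDataset(schema=schema, values=values)
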