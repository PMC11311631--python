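"""Pairwise dependence of binary features and cluster-quality diagnostics.

Three binary variables can only carve out a void if they separate patients
along three different directions; whether they are *statistically*
independent is a separate question.  This module quantifies statistical
dependence with pairwise chi-squared tests on 2x2 contingency tables
(Yates-corrected by default, matching R's ``chisq.test``), exports the
-log10 p-value heatmap matrix, clusters binary features under two metrics
(Sokal-Michener and Pearson), and computes silhouette widths of subject
clusters over an arbitrary distance matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy.stats import chi2_contingency

from .cohort_io import MixedDataset, to_numeric
from .mixed_distance import DistanceMatrix, binary_feature_distance

__all__ = [
    "DependenceTable",
    "pairwise_chi2",
    "silhouette_widths",
    "FeatureClustering",
    "cluster_features",
]


@dataclass
class DependenceTable:
    """Symmetric chi-squared statistics and p-values between binary features."""

    features: list[str]
    chi2: pd.DataFrame
    pvals: pd.DataFrame

    @property
    def neglog10p(self) -> pd.DataFrame:
        return -np.log10(self.pvals)

    def to_csv(self, path: str | Path) -> None:
        self.neglog10p.to_csv(path)


def pairwise_chi2(
    ds: MixedDataset,
    features: list[str] | None = None,
    correction: bool = True,
    bonferroni: bool = False,
) -> DependenceTable:
    """Chi-squared tests of association for every pair of binary features.

    Each pair uses its pairwise-complete subjects.  By default the 2x2
    tables get the Yates continuity correction.  A table with an empty row
    or column margin is uninformative: its p-value is set to 1 with a
    warning.  Diagonal p-values are 1 by convention (for heatmap display).
    ``bonferroni`` optionally multiplies off-diagonal p-values by the number
    of pairs tested.
    """
    if features is None:
        features = ds.binary_features()
    if len(features) < 2:
        raise ValueError("need at least 2 binary features")
    for name in features:
        if not ds.feature(name).is_binary:
            raise ValueError(f"feature {name!r} is not binary")
    X = to_numeric(ds)[features].to_numpy(dtype=float)
    p = len(features)
    chi2 = np.zeros((p, p))
    pvals = np.ones((p, p))
    n_pairs = p * (p - 1) // 2
    for a in range(p):
        for b in range(a + 1, p):
            ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
            u = X[ok, a].astype(int)
            v = X[ok, b].astype(int)
            table = np.zeros((2, 2))
            for i in range(2):
                for j in range(2):
                    table[i, j] = np.sum((u == i) & (v == j))
            if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
                warnings.warn(
                    f"features {features[a]!r}/{features[b]!r}: empty margin; p set to 1",
                    stacklevel=2,
                )
                stat, pval = 0.0, 1.0
            else:
                res = chi2_contingency(table, correction=correction)
                stat, pval = float(res.statistic), float(res.pvalue)
                if bonferroni:
                    pval = min(1.0, pval * n_pairs)
            chi2[a, b] = chi2[b, a] = stat
            pvals[a, b] = pvals[b, a] = pval
    idx = list(features)
    return DependenceTable(
        features=idx,
        chi2=pd.DataFrame(chi2, index=idx, columns=idx),
        pvals=pd.DataFrame(pvals, index=idx, columns=idx),
    )


def silhouette_widths(d: DistanceMatrix, labels) -> np.ndarray:
    """Per-subject silhouette widths over an arbitrary distance matrix.

    s(i) = (b(i) - a(i)) / max(a(i), b(i)), where a is the mean distance to
    the other members of i's cluster and b is the smallest mean distance to
    any other cluster.  Members of singleton clusters score 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != d.n:
        raise ValueError("one label per subject required")
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("silhouette widths require at least 2 clusters")
    D = d.values
    s = np.zeros(d.n)
    for i in range(d.n):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            s[i] = 0.0
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


@dataclass
class FeatureClustering:
    """Feature clusterings under two binary metrics plus their agreement."""

    features: list[str]
    order: dict[str, list[str]]  # metric -> dendrogram leaf order
    labels: dict[str, np.ndarray]  # metric -> flat cluster labels
    agreed_groups: list[tuple[str, ...]]  # co-clustered under both metrics


def cluster_features(
    ds: MixedDataset,
    features: list[str] | None = None,
    n_clusters: int = 3,
    metrics: tuple[str, str] = ("sokal_michener", "pearson"),
) -> FeatureClustering:
    """Average-linkage clustering of binary features under two metrics.

    Reports the dendrogram leaf order and flat clustering per metric, plus
    the groups of features (size >= 2) placed together by *both* metrics --
    the robustly co-clustered feature blocks.
    """
    if features is None:
        features = ds.binary_features()
    if len(features) == 1:
        return FeatureClustering(
            features=list(features),
            order={m: list(features) for m in metrics},
            labels={m: np.ones(1, int) for m in metrics},
            agreed_groups=[],
        )
    order = {}
    labels = {}
    for metric in metrics:
        dm = binary_feature_distance(ds, metric=metric, features=features)
        vals = dm.values.copy()
        if np.isnan(vals).any():
            warnings.warn(f"{metric}: undefined entries replaced by max distance")
            vals[np.isnan(vals)] = 1.0
            np.fill_diagonal(vals, 0.0)
        Z = hierarchy.linkage(squareform(vals, checks=False), method="average")
        leaf = hierarchy.leaves_list(Z)
        order[metric] = [features[i] for i in leaf]
        k = min(n_clusters, len(features))
        labels[metric] = hierarchy.fcluster(Z, t=k, criterion="maxclust")

    # intersection partition: features co-clustered under every metric
    keys = {}
    for i, name in enumerate(features):
        keys.setdefault(tuple(labels[m][i] for m in metrics), []).append(name)
    agreed = [tuple(v) for v in keys.values() if len(v) >= 2]
    agreed.sort(key=lambda g: (-len(g), g))
    return FeatureClustering(
        features=list(features), order=order, labels=labels, agreed_groups=agreed
    )
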