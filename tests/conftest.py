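"""Shared fixtures.

The expensive planted-loop and null-cohort batteries are session-scoped so
the empirical-Bayes operating characteristics, the kappa-ranking recovery
check, and the null-calibration tests all reuse one set of pipeline runs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from cohorttda.eb import score_barcodes
from cohorttda.geometry import embed, fit_loop
from cohorttda.mixed_distance import daisy_distance
from cohorttda.rips import persistent_homology
from cohorttda.synthetic import (
    LoopCohortSpec,
    generate_loop_cohort,
    generate_null_cohort,
)

N_REPLICATES = 20


@pytest.fixture(scope="session")
def null_runs():
    """20 unstructured multivariate-normal cohorts (n=100, p=10) through
    daisy -> persistence (dims <= 2) -> EB scoring."""
    runs = []
    for seed in range(N_REPLICATES):
        ds = generate_null_cohort(100, 10, seed=seed)
        dm = daisy_distance(ds)
        bars = persistent_homology(dm, max_dim=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, models = score_barcodes(bars)
        runs.append({"seed": seed, "bars": bars, "scored": table, "models": models})
    return runs


@pytest.fixture(scope="session")
def loop_runs():
    """20 planted-loop cohorts (n=300) through the full loop pipeline:
    daisy -> persistence (dim <= 1) -> EB -> MDS -> sector/kappa fits."""
    runs = []
    for seed in range(N_REPLICATES):
        ds, truth = generate_loop_cohort(LoopCohortSpec(seed=seed))
        dm = daisy_distance(ds)
        bars = persistent_homology(dm, max_dim=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, models = score_barcodes(bars)
            top = bars.most_persistent(1)
            emb = embed(dm, "mds", 2)
            loopfit = fit_loop(ds, emb, top.representative)
        runs.append(
            {
                "seed": seed,
                "ds": ds,
                "truth": truth,
                "dm": dm,
                "bars": bars,
                "scored": table,
                "top": top,
                "emb": emb,
                "loopfit": loopfit,
            }
        )
    return runs


@pytest.fixture
def rng():
    return np.random.default_rng(20240726)
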