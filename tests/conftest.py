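"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest


def enumerate_min_path(cost, alpha, beta, half_neighbors):
    """Exhaustive minimal-path oracle: enumerate every monotone path.

    Independent of the DP implementation: generates all row sequences,
    filters those whose consecutive steps stay within N, and evaluates the
    displacement-penalized edge-cost sum directly.
    """
    cost = np.asarray(cost, dtype=float)
    n_r, n_c = cost.shape
    grids = np.meshgrid(*([np.arange(n_r)] * n_c), indexing="ij")
    paths = np.stack([g.ravel() for g in grids], axis=1)
    steps = np.abs(np.diff(paths, axis=1))
    paths = paths[(steps <= half_neighbors).all(axis=1)]
    steps = np.abs(np.diff(paths, axis=1)).astype(float)
    c_now = cost[paths[:, 1:], np.arange(1, n_c)]
    c_prev = cost[paths[:, :-1], np.arange(n_c - 1)]
    with np.errstate(invalid="ignore"):
        totals = ((c_now + c_prev) * (1.0 + alpha * steps**beta)).sum(axis=1)
    totals = np.where(np.isnan(totals), np.inf, totals)
    k = int(np.argmin(totals))
    return paths[k], float(totals[k])


@pytest.fixture
def enum_oracle():
    return enumerate_min_path


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
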