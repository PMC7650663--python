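"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from bbbkit.angiography import AngioSeries


def rank_oracle(pool):
    """Brute-force average (midrank) ranking: for each element, one plus the
    count of strictly smaller elements, plus half the count of equal others."""
    pool = list(pool)
    ranks = []
    for x in pool:
        below = sum(1 for y in pool if y < x)
        equal = sum(1 for y in pool if y == x)
        ranks.append(below + (equal + 1) / 2.0)
    return np.array(ranks)


def mwu_exact_p_oracle(a, b):
    """Two-tailed exact Mann-Whitney p by full enumeration of group labels."""
    a, b = list(a), list(b)
    pool = a + b
    n = len(a)

    def u_stat(idx_a):
        sa = [pool[i] for i in idx_a]
        sb = [pool[i] for i in range(len(pool)) if i not in idx_a]
        u = 0.0
        for x in sa:
            for y in sb:
                u += (x > y) + 0.5 * (x == y)
        return u

    observed = u_stat(tuple(range(n)))
    m = len(b)
    mean_u = n * m / 2.0
    dev = abs(observed - mean_u)
    total = more = 0
    for idx in combinations(range(len(pool)), n):
        total += 1
        if abs(u_stat(idx) - mean_u) >= dev - 1e-12:
            more += 1
    return more / total


def weighted_vector_oracle(values, edges):
    """Loop-based weighted histogram vector x_i * f_i over occupied bins."""
    values = np.asarray(values, dtype=float)
    out = []
    total = len(values)
    for lo, hi, last in zip(edges[:-1], edges[1:],
                            [False] * (len(edges) - 2) + [True]):
        if last:
            count = np.sum((values >= lo) & (values <= hi))
        else:
            count = np.sum((values >= lo) & (values < hi))
        if count:
            out.append(0.5 * (lo + hi) * count / total)
    return np.array(out)


@pytest.fixture
def make_series():
    """Factory for small synthetic angiography series from explicit frames."""

    def _make(frames, frame_rate=5.0, tracer_mode="clearing", t0=0.0):
        frames = np.asarray(frames, dtype=float)
        times = t0 + np.arange(frames.shape[0]) / frame_rate
        return AngioSeries(frames=frames, times=times, frame_rate=frame_rate,
                           tracer_mode=tracer_mode)

    return _make


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260926)
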