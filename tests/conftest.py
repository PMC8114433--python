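"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid every code path of the package:
co-occurrence counting is a literal double loop over pixels, features
are dense whole-matrix sums, and rank correlation is rank-then-Pearson
by hand. Tests compare package output against these.
"""

from __future__ import annotations

import math

import numpy as np
import pytest


@pytest.fixture
def fixture_4x4() -> np.ndarray:
    """Small hand-enumerable gray image used across the texture tests."""
    return np.array([[0, 0, 1, 1],
                     [0, 0, 1, 1],
                     [0, 2, 2, 2],
                     [2, 2, 3, 3]], dtype=np.uint8)


def brute_counts(q: np.ndarray, dr: int, dc: int, levels: int) -> np.ndarray:
    """Ordered-pair co-occurrence counts by explicit double loop."""
    counts = np.zeros((levels, levels), dtype=np.int64)
    h, w = q.shape
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[q[r, c], q[r2, c2]] += 1
    return counts


def brute_features(counts: np.ndarray, variant: str = "walker") -> dict:
    """Dense-sum texture features straight from the definitions."""
    n = counts.sum()
    p = counts / n
    nz = p[p > 0]
    i, j = np.indices(p.shape)
    px, py = p.sum(axis=1), p.sum(axis=0)
    lev = np.arange(p.shape[0], dtype=float)
    mux, muy = (px * lev).sum(), (py * lev).sum()
    vx = (px * lev**2).sum() - mux**2
    vy = (py * lev**2).sum() - muy**2
    cov = (i * j * p).sum() - mux * muy
    denom = math.sqrt(vx * vy) if variant == "haralick" else vx * vy
    return {
        "asm": (p**2).sum(),
        "entropy": float(-(nz * np.log(nz)).sum()),
        "idm": (p / (1.0 + (i - j) ** 2)).sum(),
        "contrast": (((i - j) ** 2) * p).sum(),
        "correlation": cov / denom if denom > 0 else math.nan,
    }


def brute_spearman(x, y) -> float:
    """Rank (average ties) then Pearson, written out longhand."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            jj = i
            while jj + 1 < len(v) and v[order[jj + 1]] == v[order[i]]:
                jj += 1
            r[order[i:jj + 1]] = (i + jj) / 2.0 + 1.0
            i = jj + 1
        return r
    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum()
                 / math.sqrt((rx**2).sum() * (ry**2).sum()))


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
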