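"""Fisher's alpha diversity and binary Bray-Curtis dissimilarity.

Fisher's alpha is the parameter of the log-series species-abundance model
and satisfies ``S = alpha * ln(1 + N / alpha)`` for observed richness S
and total abundance N; it is widely used because it is comparatively
insensitive to sample size.  We solve the defining equation by bracketed
root finding (Brent) to a residual below 1e-10.

Community composition uses the binary (presence/absence) form of the
Bray-Curtis dissimilarity, (b + c) / (2a + b + c), where a is the number
of lineages shared by the two units and b, c the numbers unique to each.
This equals 1 minus the Sorensen similarity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .hierarchy import AggregatedData
from .tables import PresenceMatrix

__all__ = [
    "fisher_alpha",
    "bray_curtis_binary",
    "pairwise_dissimilarity",
    "unit_diversity",
    "DiversityResult",
    "DissimilarityMatrix",
]

_RESIDUAL_TOL = 1e-10


@dataclass
class DiversityResult:
    unit_id: str
    S: int
    N: int
    fisher_alpha: float
    converged: bool


def fisher_alpha(S: int, N: int) -> float:
    """Fisher's alpha: the root of ``alpha * ln(1 + N/alpha) = S``.

    Returns 0 for S = 0 and ``inf`` when S = N (every sequence a distinct
    lineage; the log-series has no finite parameter there).
    """
    if S < 0 or N < 0 or S > N:
        raise ValueError(f"need 0 <= S <= N, got S={S}, N={N}")
    if S == 0:
        return 0.0
    if S == N:
        return math.inf

    def f(a: float) -> float:
        return a * math.log1p(N / a) - S

    # f is increasing in alpha, from 0+ (limit 0) to N as alpha -> inf,
    # so a root exists for 0 < S < N; bracket on a log-spaced interval.
    lo, hi = 1e-12, 1.0
    while f(hi) < 0:
        hi *= 10.0
        if hi > 1e18:  # pragma: no cover - unreachable for valid S < N
            raise RuntimeError("failed to bracket Fisher alpha")
    alpha = brentq(f, lo, hi, xtol=1e-14, rtol=8.9e-16, maxiter=200)
    # polish against the defining equation
    if abs(f(alpha)) > _RESIDUAL_TOL:  # pragma: no cover - Brent converges
        raise RuntimeError(f"Fisher alpha residual {f(alpha):.2e} too large")
    return float(alpha)


def unit_diversity(aggregated: AggregatedData) -> list[DiversityResult]:
    """Fisher's alpha per analysis unit from presence richness and
    (normalized) sequence totals."""
    if aggregated.sequence_mass is None:
        raise ValueError(
            "sequence mass is required for Fisher alpha; aggregate with counts"
        )
    results = []
    richness = aggregated.presence.richness()
    for unit_id in aggregated.presence.unit_ids:
        S = int(richness[unit_id])
        N = int(aggregated.sequence_mass[unit_id])
        if S == N or (S == 0 and N == 0):
            alpha, converged = (math.inf if S else 0.0), False
        else:
            alpha, converged = fisher_alpha(S, N), True
        results.append(DiversityResult(unit_id, S, N, alpha, converged))
    return results


def diversity_frame(results: list[DiversityResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.unit_id, r.S, r.N, r.fisher_alpha, r.converged) for r in results],
        columns=["unit_id", "S", "N", "fisher_alpha", "converged"],
    ).set_index("unit_id")


def bray_curtis_binary(x, y) -> float:
    """Binary Bray-Curtis dissimilarity (b+c)/(2a+b+c) of two 0/1 vectors.

    A pair of all-zero vectors has no defined value; it is reported as 0
    with a warning so dissimilarity matrices stay valid.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("inputs must be binary 0/1 vectors")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    denom = 2 * a + b + c
    if denom == 0:
        warnings.warn("binary Bray-Curtis of two empty units; reporting 0")
        return 0.0
    return (b + c) / denom


@dataclass
class DissimilarityMatrix:
    unit_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("entries must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.unit_ids,
                            columns=self.unit_ids)


def pairwise_dissimilarity(presence: PresenceMatrix) -> DissimilarityMatrix:
    """Full symmetric matrix of binary Bray-Curtis over all unit pairs."""
    units = presence.unit_ids
    if len(units) < 2:
        raise ValueError("need at least two units for pairwise dissimilarity")
    mat = presence.values().astype(bool)
    n = len(units)
    out = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                out[i, j] = out[j, i] = bray_curtis_binary(
                    mat[:, i].astype(int), mat[:, j].astype(int)
                )
    return DissimilarityMatrix(units, out)
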