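"""Ranked Species Occupancy Curves: construction, fitting, model competition.

An RSOC plots each lineage's occupancy (prevalence: the fraction of host
individuals in which it was detected) against its descending rank.  The
curve's shape diagnoses community structure: a sigmoidal curve indicates
a bimodal community (a mode of common species plus a mode of rare ones),
while an exponentially concave curve indicates a community dominated by a
single unimodal peak of rare species.

Six candidate regression forms are competed (coefficients a, b, c, d;
R is the 1-based rank, n the number of ranked lineages):

==============================  ==========================================
``exponential_concave``         Q = c + a * exp(-b * R)
``exponential_convex``          Q = c + a * (1 - exp(-b * (n + 1 - R)))
                                (the saturating form mirrored so the
                                curve decreases in R)
``lognormal``                   Q = a * exp(-(ln R - b)^2 / (2 c^2))
``sigmoidal_symmetric``         Q = a / (1 + exp((R - b) / c))
``sigmoidal_asymmetric``        Q = a * exp(-exp((R - b) / c))
                                (decreasing Gompertz: the drop from the
                                upper plateau is steeper than the
                                approach to zero)
``linear``                      Q = a - b * R
==============================  ==========================================

Models are fitted by bounded nonlinear least squares with Latin-hypercube
multi-starts and ranked by the small-sample corrected Akaike information
criterion, AICc = n ln(RSS/n) + 2k' + 2k'(k'+1)/(n-k'-1) with k' equal to
the number of curve coefficients plus one for the error variance.  Akaike
weights w_i = exp(-delta_i/2) / sum_j exp(-delta_j/2) give each model's
plausibility of being the best of the competed set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "OccupancyCurve",
    "ModelFit",
    "MODEL_REGISTRY",
    "rank_occupancy",
    "fit_model",
    "compete_models",
    "akaike_weights",
    "RankedOccupancyModel",
    "OccupancyModelCompetition",
]

_RSS_FLOOR = 1e-300  # keeps AICc finite on exact fits


@dataclass
class OccupancyCurve:
    """Lineage prevalences ranked in decreasing order for one community."""

    community: str
    Q: np.ndarray          # prevalences, sorted non-increasing, in [0, 1]
    n_hosts: int
    lineage_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=float)
        if q.ndim != 1:
            raise ValueError("Q must be one-dimensional")
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError("prevalences must lie in [0, 1]")
        if np.any(np.diff(q) > 1e-12):
            raise ValueError("prevalences must be sorted non-increasing")
        self.Q = q

    @property
    def R(self) -> np.ndarray:
        return np.arange(1, len(self.Q) + 1)

    def __len__(self) -> int:
        return len(self.Q)


def rank_occupancy(occupancy_counts, n_hosts: int,
                   community: str = "") -> OccupancyCurve:
    """Build an RSOC from per-lineage occupancy counts.

    ``occupancy_counts`` may be a mapping/Series (lineage -> count) or a
    plain sequence.  Zero-count lineages are excluded; ties in prevalence
    are broken by lineage ID for determinism.
    """
    if n_hosts <= 0:
        raise ValueError("n_hosts must be positive")
    if isinstance(occupancy_counts, pd.Series):
        s = occupancy_counts
    elif isinstance(occupancy_counts, dict):
        s = pd.Series(occupancy_counts)
    else:
        arr = np.asarray(occupancy_counts)
        s = pd.Series(arr, index=[f"L{i}" for i in range(len(arr))])
    if (s > n_hosts).any():
        bad = s.index[s > n_hosts].tolist()
        raise ValueError(f"occupancy exceeds n_hosts={n_hosts} for: {bad}")
    if (s < 0).any():
        raise ValueError("occupancy counts must be non-negative")
    s = s[s > 0]
    order = np.lexsort((s.index.astype(str), -s.to_numpy(float)))
    s = s.iloc[order]
    return OccupancyCurve(community=community, Q=s.to_numpy(float) / n_hosts,
                          n_hosts=n_hosts, lineage_ids=list(s.index))


# ---------------------------------------------------------------------------
# model registry
# ---------------------------------------------------------------------------

class _Model:
    def __init__(self, name, params, func, bounds, guess):
        self.name = name
        self.params = params          # coefficient names, in order
        self.func = func              # func(R, theta, n) -> Q
        self.bounds = bounds          # bounds(n) -> (lower, upper) arrays
        self.guess = guess            # guess(R, Q, n) -> initial theta

    @property
    def k(self) -> int:
        return len(self.params)


def _exp_concave(R, t, n):
    a, b, c = t
    return c + a * np.exp(-b * R)


def _exp_convex(R, t, n):
    a, b, c = t
    return c + a * (1.0 - np.exp(-b * (n + 1 - R)))


def _lognormal(R, t, n):
    a, b, c = t
    return a * np.exp(-((np.log(R) - b) ** 2) / (2.0 * c * c))


def _sig_sym(R, t, n):
    a, b, c = t
    z = np.clip((R - b) / c, -500, 500)
    return a / (1.0 + np.exp(z))


def _sig_asym(R, t, n):
    a, b, c = t
    z = np.clip((R - b) / c, -500, 500)
    return a * np.exp(-np.exp(z))


def _linear(R, t, n):
    a, b = t
    return a - b * R


def _g_exp_concave(R, Q, n):
    c = max(Q.min(), 1e-4)
    a = max(Q.max() - c, 1e-3)
    return [a, 3.0 / n, c]


def _g_exp_convex(R, Q, n):
    c = max(Q.min(), 1e-4)
    a = max(Q.max() - c, 1e-3)
    return [a, 3.0 / n, c]


def _g_lognormal(R, Q, n):
    return [max(Q.max(), 1e-3), 0.0, 1.5]


def _g_sig_sym(R, Q, n):
    half = Q.max() / 2.0
    b = float(R[np.argmin(np.abs(Q - half))])
    return [max(Q.max(), 1e-3), b, max(n / 10.0, 0.5)]


def _g_sig_asym(R, Q, n):
    return _g_sig_sym(R, Q, n)


def _g_linear(R, Q, n):
    b, a = np.polyfit(R, Q, 1)
    return [float(a), float(-b)]


MODEL_REGISTRY: dict[str, _Model] = {
    m.name: m for m in [
        _Model("exponential_concave", ("a", "b", "c"), _exp_concave,
               lambda n: ([0.0, 1e-6, 0.0], [1.5, 20.0, 1.5]),
               _g_exp_concave),
        _Model("exponential_convex", ("a", "b", "c"), _exp_convex,
               lambda n: ([0.0, 1e-6, 0.0], [1.5, 20.0, 1.5]),
               _g_exp_convex),
        _Model("lognormal", ("a", "b", "c"), _lognormal,
               lambda n: ([0.0, -5.0, 1e-3], [1.5, math.log(n) + 5.0, 20.0]),
               _g_lognormal),
        _Model("sigmoidal_symmetric", ("a", "b", "c"), _sig_sym,
               lambda n: ([0.0, -float(n), 1e-3], [1.5, 2.0 * n, 4.0 * n]),
               _g_sig_sym),
        _Model("sigmoidal_asymmetric", ("a", "b", "c"), _sig_asym,
               lambda n: ([0.0, -2.0 * n, 1e-3], [1.5, 2.0 * n, 4.0 * n]),
               _g_sig_asym),
        _Model("linear", ("a", "b"), _linear,
               lambda n: ([0.0, 0.0], [1.5, 1.5]),
               _g_linear),
    ]
}


@dataclass
class ModelFit:
    """One model's least-squares fit to an RSOC."""

    model: str
    coefficients: dict
    rss: float
    n: int
    k: int                 # fitted curve coefficients
    aicc: float
    akaike_weight: float | None = None
    converged: bool = True

    @property
    def k_total(self) -> int:
        return self.k + 1  # + error variance


def aicc_from_rss(rss: float, n: int, k: int) -> float:
    """Least-squares AICc with the error variance counted as a parameter."""
    kp = k + 1
    if n <= kp + 1:
        raise ValueError(f"AICc undefined for n={n}, k'={kp}")
    rss = max(float(rss), _RSS_FLOOR)
    return n * math.log(rss / n) + 2 * kp + 2 * kp * (kp + 1) / (n - kp - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    """Akaike weights over a competed model set.

    Invariant to adding a constant to every AICc; weights sum to one.
    """
    vals = np.asarray(aicc_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least two AICc values")
    if not np.all(np.isfinite(vals)):
        raise ValueError("AICc values must all be finite")
    delta = vals - vals.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


class RankedOccupancyModel(BaseEstimator, RegressorMixin):
    """Bounded nonlinear least-squares fit of one RSOC regression form.

    Parameters
    ----------
    model:
        One of the registered form names (see ``MODEL_REGISTRY``).
    multi_start:
        Number of starts: one data-driven heuristic start plus
        Latin-hypercube samples of the bounded coefficient box.
    random_state:
        Seed for the Latin-hypercube start sampler.

    Attributes (after ``fit``)
    --------------------------
    coef_ : dict of fitted coefficients
    rss_, aicc_, n_, k_ : fit summaries
    """

    def __init__(self, model: str = "exponential_concave",
                 multi_start: int = 20, random_state=None):
        self.model = model
        self.multi_start = multi_start
        self.random_state = random_state

    def _spec(self) -> _Model:
        if self.model not in MODEL_REGISTRY:
            raise KeyError(
                f"unknown RSOC model {self.model!r}; registered: "
                f"{sorted(MODEL_REGISTRY)}"
            )
        return MODEL_REGISTRY[self.model]

    def fit(self, X, y) -> "RankedOccupancyModel":
        spec = self._spec()
        R = np.asarray(X, dtype=float).reshape(-1)
        Q = np.asarray(y, dtype=float).reshape(-1)
        n = len(R)
        if n < spec.k + 2:
            raise ValueError(
                f"{spec.name} needs n >= {spec.k + 2} points, got {n}"
            )
        lo, hi = (np.asarray(v, float) for v in spec.bounds(int(R.max())))
        nmax = int(R.max())

        def resid(theta):
            return spec.func(R, theta, nmax) - Q

        starts = [np.clip(spec.guess(R, Q, nmax), lo, hi)]
        extra = max(self.multi_start - 1, 0)
        if extra:
            sampler = qmc.LatinHypercube(d=len(lo), seed=self.random_state)
            starts.extend(lo + sampler.random(extra) * (hi - lo))
        best = None
        for x0 in starts:
            try:
                sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                                    xtol=1e-15, ftol=1e-15, gtol=1e-15,
                                    max_nfev=2000)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0]:
                best = (rss, sol.x)
        if best is None:
            raise RuntimeError(f"all starts failed for model {spec.name}")
        rss, theta = best
        self.n_ = n
        self.k_ = spec.k
        self.coef_ = dict(zip(spec.params, (float(t) for t in theta)))
        self.rss_ = rss
        self.nmax_ = nmax
        self.aicc_ = aicc_from_rss(rss, n, spec.k)
        return self

    def fit_curve(self, curve: OccupancyCurve) -> "RankedOccupancyModel":
        return self.fit(curve.R, curve.Q)

    def predict(self, X) -> np.ndarray:
        spec = self._spec()
        R = np.asarray(X, dtype=float).reshape(-1)
        theta = [self.coef_[p] for p in spec.params]
        return spec.func(R, theta, self.nmax_)

    def to_model_fit(self) -> ModelFit:
        return ModelFit(model=self.model, coefficients=dict(self.coef_),
                        rss=self.rss_, n=self.n_, k=self.k_, aicc=self.aicc_)


class OccupancyModelCompetition(BaseEstimator):
    """Fit a set of RSOC forms and rank them by AICc / Akaike weight."""

    def __init__(self, models=None, multi_start: int = 20, random_state=None):
        self.models = models
        self.multi_start = multi_start
        self.random_state = random_state

    def fit(self, X, y) -> "OccupancyModelCompetition":
        names = list(self.models) if self.models else list(MODEL_REGISTRY)
        fits: list[ModelFit] = []
        failures: list[str] = []
        for i, name in enumerate(names):
            seed = (None if self.random_state is None
                    else int(self.random_state) + i)
            est = RankedOccupancyModel(model=name,
                                       multi_start=self.multi_start,
                                       random_state=seed)
            try:
                est.fit(X, y)
            except (RuntimeError, ValueError):
                failures.append(name)
                continue
            fits.append(est.to_model_fit())
        if len(fits) < 2:
            raise RuntimeError(
                f"model competition needs >= 2 successful fits; "
                f"failed: {failures}"
            )
        weights = akaike_weights([f.aicc for f in fits])
        for f, w in zip(fits, weights):
            f.akaike_weight = float(w)
        fits.sort(key=lambda f: f.aicc)
        self.fits_ = fits
        self.failed_ = failures
        self.best_model_ = fits[0].model
        self.weights_ = {f.model: f.akaike_weight for f in fits}
        return self

    def fit_curve(self, curve: OccupancyCurve) -> "OccupancyModelCompetition":
        return self.fit(curve.R, curve.Q)

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for f in self.fits_:
            row = {"model": f.model, "rss": f.rss, "n": f.n, "k": f.k,
                   "aicc": f.aicc, "akaike_weight": f.akaike_weight}
            row.update({f"coef_{p}": v for p, v in f.coefficients.items()})
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")


# -- functional wrappers -----------------------------------------------------

def fit_model(curve: OccupancyCurve, model: str, multi_start: int = 20,
              seed=None) -> ModelFit:
    est = RankedOccupancyModel(model=model, multi_start=multi_start,
                               random_state=seed).fit_curve(curve)
    return est.to_model_fit()


def compete_models(curve: OccupancyCurve, models=None, multi_start: int = 20,
                   seed=None) -> list[ModelFit]:
    comp = OccupancyModelCompetition(models=models, multi_start=multi_start,
                                     random_state=seed).fit_curve(curve)
    return comp.fits_
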