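"""Factorial effect tests and SIMPER discriminating-lineage analysis.

Two companion tests quantify how host species and host (community)
diversity structure the blood bacterial communities:

* :func:`diversity_effects` — a two-factor linear model on per-unit
  Fisher's alpha with sequential (type-I) sums of squares and permutation
  p-values (unit labels permuted), reporting percent variance explained
  per term.
* :func:`composition_effects` — the multivariate analogue (PERMANOVA) on
  a dissimilarity matrix: the matrix is Gower-centered and each term's
  sum of squares is the trace of its incremental projection applied to
  the centered matrix (McArdle-Anderson), with pseudo-F statistics and
  permutation p-values.

:func:`simper` decomposes the average between-group binary Bray-Curtis
dissimilarity into per-lineage contributions; lineages whose mean/SD
contribution ratio exceeds one are flagged as consistent ("good")
discriminators.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diversity import DissimilarityMatrix
from .tables import PresenceMatrix

__all__ = ["EffectTable", "SimperResult", "diversity_effects",
           "composition_effects", "simper"]

_EXACT_ENUM_LIMIT = 9  # enumerate all n! permutations up to this n


@dataclass
class EffectTable:
    """Per-term statistic, permutation p-value and % variance explained."""

    data: pd.DataFrame  # index: term; columns df, SS, F, p_value, pct_var
    n_perm: int
    skipped: list

    def __post_init__(self) -> None:
        pv = self.data["pct_var"]
        if ((pv < -1e-9) | (pv > 100 + 1e-9)).any():
            raise ValueError("percent variance out of [0, 100]")


def _term_designs(factors: pd.DataFrame, interaction: bool) -> list[tuple[str, np.ndarray]]:
    """Sequential term design blocks (dummy-coded, no intercept column)."""
    terms = []
    cols = list(factors.columns)
    for name in cols:
        dummies = pd.get_dummies(factors[name].astype("category"), drop_first=True)
        terms.append((name, dummies.to_numpy(dtype=float)))
    if interaction and len(cols) == 2:
        a = pd.get_dummies(factors[cols[0]].astype("category"), drop_first=True)
        b = pd.get_dummies(factors[cols[1]].astype("category"), drop_first=True)
        inter = np.einsum("ij,ik->ijk", a.to_numpy(float), b.to_numpy(float))
        inter = inter.reshape(len(factors), -1)
        terms.append((f"{cols[0]}:{cols[1]}", inter))
    return terms


def _sequential_basis(n: int, terms: list[tuple[str, np.ndarray]], tol: float = 1e-9):
    """Gram-Schmidt orthonormal columns added term by term after the
    intercept; returns (Q, term label per column, df per term)."""
    basis = [np.full(n, 1.0 / math.sqrt(n))]
    labels: list[str] = []
    dfs: dict[str, int] = {}
    for name, block in terms:
        df = 0
        for j in range(block.shape[1]):
            v = block[:, j].astype(float)
            for q in basis:
                v = v - (q @ v) * q
            nrm = np.linalg.norm(v)
            if nrm > tol * math.sqrt(n):
                basis.append(v / nrm)
                labels.append(name)
                df += 1
        dfs[name] = df
    Q = np.column_stack(basis[1:]) if labels else np.zeros((n, 0))
    return Q, np.array(labels), dfs


def _permutations(n: int, permutations, seed) -> tuple[np.ndarray, bool]:
    """Index matrix of permutations (identity first) and exactness flag."""
    if permutations == "exact" or (
        permutations is None and n <= _EXACT_ENUM_LIMIT
    ):
        perms = np.array(list(itertools.permutations(range(n))))
        return perms, True
    n_perm = int(permutations)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    return perms, False


def _effect_table(term_ss, dfs, ss_res, df_res, ss_total, perm_term_ss,
                  perm_ss_res, exact, skipped) -> EffectTable:
    rows = []
    n_used = perm_term_ss.shape[1]
    for i, (name, ss) in enumerate(term_ss.items()):
        df = dfs[name]
        if df == 0:
            continue
        ms_res = ss_res / df_res if df_res > 0 else np.nan
        f_obs = (ss / df) / ms_res if ms_res and ms_res > 0 else np.inf
        with np.errstate(divide="ignore", invalid="ignore"):
            f_perm = (perm_term_ss[i] / df) / (perm_ss_res / df_res)
        f_perm = np.where(np.isnan(f_perm), np.inf, f_perm)
        ge = np.sum(f_perm >= f_obs - 1e-12)
        if exact:
            p = ge / n_used
        else:
            p = (1 + ge) / (1 + n_used)
        # binary Bray-Curtis is semi-metric, so sequential SS can stray
        # marginally outside [0, SS_total]; the report clamps to [0, 100]
        pct = (float(np.clip(100.0 * ss / ss_total, 0.0, 100.0))
               if ss_total > 0 else 0.0)
        rows.append((name, df, ss, f_obs, p, pct))
    df_out = pd.DataFrame(
        rows, columns=["term", "df", "SS", "F", "p_value", "pct_var"]
    ).set_index("term")
    return EffectTable(df_out, n_perm=n_used, skipped=skipped)


def _prepare(factors: pd.DataFrame, interaction: bool):
    skipped = [c for c in factors.columns if factors[c].nunique() < 2]
    kept = factors[[c for c in factors.columns if c not in skipped]]
    use_inter = interaction and kept.shape[1] == 2
    if interaction and not use_inter and kept.shape[1] >= 1:
        skipped = skipped + ["interaction"]
    return kept, use_inter, skipped


def diversity_effects(
    response,
    factors: pd.DataFrame,
    n_perm: int | str = 999,
    seed=None,
    interaction: bool = True,
) -> EffectTable:
    """Sequential two-factor permutation ANOVA on a per-unit response.

    ``response`` is a sequence of per-unit values (e.g. Fisher's alpha)
    aligned with the rows of ``factors``.  Terms with a single observed
    level are skipped with a notice in ``EffectTable.skipped``.
    """
    y = np.asarray(response, dtype=float)
    if len(y) != len(factors):
        raise ValueError("response and factors must align")
    kept, use_inter, skipped = _prepare(factors, interaction)
    terms = _term_designs(kept, use_inter)
    n = len(y)
    Q, labels, dfs = _sequential_basis(n, terms)
    yc = y - y.mean()
    ss_total = float(yc @ yc)
    proj = Q.T @ yc if Q.size else np.zeros(0)
    term_names = [name for name, _ in terms]
    term_ss = {name: float(np.sum(proj[labels == name] ** 2))
               for name in term_names}
    ss_res = ss_total - sum(term_ss.values())
    df_res = n - 1 - sum(dfs.values())

    perms, exact = _permutations(n, n_perm if n_perm != "exact" else "exact", seed)
    Yp = yc[perms.T]                      # n x n_perm
    Pp = Q.T @ Yp if Q.size else np.zeros((0, perms.shape[0]))
    perm_term_ss = np.stack([
        np.sum(Pp[labels == name] ** 2, axis=0) for name in term_names
    ]) if term_names else np.zeros((0, perms.shape[0]))
    perm_ss_res = ss_total - perm_term_ss.sum(axis=0)
    return _effect_table(term_ss, dfs, ss_res, df_res, ss_total,
                         perm_term_ss, perm_ss_res, exact, skipped)


def gower_center(d: np.ndarray) -> np.ndarray:
    """Double-centered -0.5 * D^2 matrix used by PERMANOVA."""
    a = -0.5 * np.asarray(d, dtype=float) ** 2
    n = a.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    return j @ a @ j


def composition_effects(
    dissimilarity: DissimilarityMatrix,
    factors: pd.DataFrame,
    n_perm: int | str = 9999,
    seed=None,
    interaction: bool = True,
    strata=None,
) -> EffectTable:
    """Sequential two-factor PERMANOVA on a dissimilarity matrix.

    Permutes raw unit labels freely by default; pass ``strata`` (a
    sequence of group labels) to permute only within strata.
    """
    d = dissimilarity.values
    if len(factors) != d.shape[0]:
        raise ValueError("factors must align with the dissimilarity matrix")
    kept, use_inter, skipped = _prepare(factors, interaction)
    terms = _term_designs(kept, use_inter)
    n = d.shape[0]
    Q, labels, dfs = _sequential_basis(n, terms)
    G = gower_center(d)
    ss_total = float(np.trace(G))
    term_names = [name for name, _ in terms]

    def _term_stats(g: np.ndarray) -> np.ndarray:
        if not Q.size:
            return np.zeros(len(term_names))
        M = np.einsum("ij,jk,ki->i", Q.T, g, Q)  # q_i^T G q_i per column
        return np.array([float(M[labels == name].sum()) for name in term_names])

    obs = _term_stats(G)
    term_ss = dict(zip(term_names, obs))
    ss_res = ss_total - obs.sum()
    df_res = n - 1 - sum(dfs.values())

    if strata is not None:
        strata = np.asarray(strata)
        rng = np.random.default_rng(seed)
        n_p = int(n_perm)
        perms = np.tile(np.arange(n), (n_p, 1))
        for g in np.unique(strata):
            idx = np.flatnonzero(strata == g)
            for r in range(n_p):
                perms[r, idx] = idx[rng.permutation(len(idx))]
        exact = False
    else:
        perms, exact = _permutations(n, n_perm, seed)
    perm_term_ss = np.empty((len(term_names), perms.shape[0]))
    for r, perm in enumerate(perms):
        gp = G[np.ix_(perm, perm)]
        perm_term_ss[:, r] = _term_stats(gp)
    perm_ss_res = ss_total - perm_term_ss.sum(axis=0)
    return _effect_table(term_ss, dfs, ss_res, df_res, ss_total,
                         perm_term_ss, perm_ss_res, exact, skipped)


@dataclass
class SimperResult:
    """Per-lineage contributions to between-group dissimilarity."""

    data: pd.DataFrame
    # columns: mean_contribution, sd_contribution, ratio, cumulative_pct,
    #          good_discriminator
    mean_between_dissimilarity: float


def simper(presence: PresenceMatrix, group_labels, groups: tuple) -> SimperResult:
    """SIMPER decomposition of mean between-group binary Bray-Curtis.

    For every pair of units (one from each group), a lineage's
    contribution to that pair's dissimilarity is its mismatch indicator
    divided by the pair's (2a + b + c); contributions are averaged over
    all between-group pairs.  Good discriminators contribute consistently
    (mean/SD ratio > 1).  The per-lineage averages sum exactly to the
    mean between-group dissimilarity.
    """
    group_labels = np.asarray(group_labels)
    if len(group_labels) != len(presence.unit_ids):
        raise ValueError("group labels must align with units")
    g1, g2 = groups
    idx1 = np.flatnonzero(group_labels == g1)
    idx2 = np.flatnonzero(group_labels == g2)
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError(f"both groups must be non-empty: {g1!r}, {g2!r}")
    mat = presence.values().astype(bool)
    contribs = []  # per pair: vector of per-lineage contributions
    for i in idx1:
        for j in idx2:
            x, y = mat[:, i], mat[:, j]
            mismatch = x ^ y
            denom = 2 * int(np.sum(x & y)) + int(mismatch.sum())
            contribs.append(mismatch / denom if denom > 0
                            else np.zeros(mat.shape[0]))
    C = np.asarray(contribs)                    # pairs x lineages
    mean_c = C.mean(axis=0)
    sd_c = C.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(sd_c > 0, mean_c / sd_c, np.inf)
    ratio = np.where(mean_c == 0, 0.0, ratio)
    df = pd.DataFrame({
        "mean_contribution": mean_c,
        "sd_contribution": sd_c,
        "ratio": ratio,
    }, index=presence.data.index)
    # sort by mean contribution descending, ties broken by lineage ID
    df = df.iloc[np.lexsort((df.index.astype(str),
                             -df["mean_contribution"].to_numpy()))]
    total = mean_c.sum()
    df["cumulative_pct"] = (
        100.0 * df["mean_contribution"].cumsum() / total if total > 0 else 0.0
    )
    df["good_discriminator"] = df["ratio"] > 1
    return SimperResult(df, float(total))
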