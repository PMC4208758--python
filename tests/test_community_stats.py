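"""Permutation ANOVA, PERMANOVA and SIMPER."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hostmicro.community_stats import (
    composition_effects,
    diversity_effects,
    gower_center,
    simper,
)
from hostmicro.diversity import DissimilarityMatrix, pairwise_dissimilarity
from hostmicro.tables import PresenceMatrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def seq_ss_oracle(y, factors, interaction=True):
    """Sequential sums of squares via RSS differences of nested OLS fits
    (independent of the package's Gram-Schmidt projections)."""
    y = np.asarray(y, float)
    n = len(y)

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(np.sum((y - X @ beta) ** 2))

    blocks = [np.ones((n, 1))]
    names = []
    for col in factors.columns:
        d = pd.get_dummies(factors[col].astype("category"),
                           drop_first=True).to_numpy(float)
        blocks.append(d)
        names.append(col)
    if interaction and factors.shape[1] == 2:
        a = pd.get_dummies(factors.iloc[:, 0].astype("category"),
                           drop_first=True).to_numpy(float)
        b = pd.get_dummies(factors.iloc[:, 1].astype("category"),
                           drop_first=True).to_numpy(float)
        inter = np.einsum("ij,ik->ijk", a, b).reshape(n, -1)
        blocks.append(inter)
        names.append("interaction")
    ss = {}
    prev_rss = rss(blocks[0])
    X = blocks[0]
    for name, block in zip(names, blocks[1:]):
        X = np.hstack([X, block])
        cur = rss(X)
        ss[name] = prev_rss - cur
        prev_rss = cur
    return ss, prev_rss  # term SS, residual SS


def permanova_f_oracle(d, labels):
    """Single-factor pseudo-F from first principles (hat-matrix trace)."""
    d = np.asarray(d, float)
    n = d.shape[0]
    a = -0.5 * d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    X = pd.get_dummies(pd.Series(labels)).to_numpy(float)
    H = X @ np.linalg.pinv(X.T @ X) @ X.T
    Hc = H - np.ones((n, n)) / n
    ss_a = np.trace(Hc @ g)
    ss_total = np.trace(g)
    ss_r = ss_total - ss_a
    df_a = X.shape[1] - 1
    df_r = n - X.shape[1]
    return (ss_a / df_a) / (ss_r / df_r), 100 * ss_a / ss_total


# ---------------------------------------------------------------------------


class TestDiversityEffects:
    def _factors(self, species, richness):
        return pd.DataFrame({"host_species": species,
                             "host_diversity": richness})

    def test_constant_response_null(self):
        f = self._factors(["GA"] * 4 + ["GP"] * 4, [1, 2] * 4)
        out = diversity_effects(np.full(8, 3.3), f, n_perm=99, seed=0)
        assert (out.data["p_value"] == 1.0).all()
        assert (out.data["pct_var"] == 0.0).all()

    def test_strong_species_effect_detected(self, rng):
        species = ["GA"] * 10 + ["GP"] * 10
        richness = ([1, 2, 3] * 7)[:20]
        y = np.where(np.array(species) == "GA", 0.0, 5.0)
        y = y + rng.normal(0, 1, 20)
        out = diversity_effects(y, self._factors(species, richness),
                                n_perm=999, seed=1)
        assert out.data.loc["host_species", "p_value"] <= 0.001

    def test_exact_p_matches_full_enumeration(self):
        # 6 units, 2x2 design with unequal cell sizes
        species = ["GA", "GA", "GA", "GP", "GP", "GP"]
        richness = [1, 1, 2, 1, 2, 2]
        y = np.array([1.0, 2.0, 4.5, 2.5, 6.0, 5.5])
        factors = self._factors(species, richness)
        out = diversity_effects(y, factors, n_perm="exact", seed=0)

        ss_obs, rss_obs = seq_ss_oracle(y, factors)
        df = {"host_species": 1, "host_diversity": 1,
              "host_species:host_diversity": 1}
        name_map = {"host_species": "host_species",
                    "host_diversity": "host_diversity",
                    "interaction": "host_species:host_diversity"}
        df_res = 6 - 1 - 3

        def f_stats(perm):
            yp = y[list(perm)]
            ss, rss = seq_ss_oracle(yp, factors)
            return {name_map[k]: (v / 1) / (rss / df_res)
                    for k, v in ss.items()}

        obs = f_stats(range(6))
        counts = {k: 0 for k in obs}
        total = 0
        for perm in itertools.permutations(range(6)):
            total += 1
            fs = f_stats(perm)
            for k in counts:
                if fs[k] >= obs[k] - 1e-9:
                    counts[k] += 1
        for term in out.data.index:
            assert out.data.loc[term, "p_value"] == pytest.approx(
                counts[term] / total, abs=1e-12)

    def test_term_ss_match_nested_ols_oracle(self, rng):
        species = rng.choice(["GA", "GP", "GG"], size=18)
        richness = rng.choice([1, 2, 3], size=18)
        y = rng.normal(size=18)
        factors = self._factors(species, richness)
        out = diversity_effects(y, factors, n_perm=49, seed=0)
        ss, _ = seq_ss_oracle(y, factors)
        assert out.data.loc["host_species", "SS"] == pytest.approx(
            ss["host_species"], abs=1e-9)
        assert out.data.loc["host_diversity", "SS"] == pytest.approx(
            ss["host_diversity"], abs=1e-9)

    def test_single_level_factor_skipped(self):
        f = self._factors(["GA"] * 6, [1, 2, 3, 1, 2, 3])
        out = diversity_effects(np.arange(6.0), f, n_perm=49, seed=0)
        assert "host_species" in out.skipped
        assert "host_species" not in out.data.index


class TestCompositionEffects:
    def test_perfect_separation(self):
        # two groups of 8 with disjoint lineage supports
        n = 16
        d = np.ones((n, n))
        d[:8, :8] = 0
        d[8:, 8:] = 0
        np.fill_diagonal(d, 0)
        dm = DissimilarityMatrix([f"U{i}" for i in range(n)], d)
        factors = pd.DataFrame({"group": ["A"] * 8 + ["B"] * 8})
        out = composition_effects(dm, factors, n_perm=199, seed=3,
                                  interaction=False)
        row = out.data.loc["group"]
        assert row["p_value"] == pytest.approx(1 / 200)
        assert row["pct_var"] == pytest.approx(100.0, abs=1e-9)

    def test_pseudo_f_matches_hat_matrix_oracle(self, rng):
        mat = rng.integers(0, 2, size=(30, 5))
        pres = PresenceMatrix(pd.DataFrame(
            mat, index=[f"L{i}" for i in range(30)],
            columns=[f"U{j}" for j in range(5)]))
        dm = pairwise_dissimilarity(pres)
        labels = ["A", "A", "B", "B", "B"]
        out = composition_effects(dm, pd.DataFrame({"g": labels}),
                                  n_perm=49, seed=0, interaction=False)
        f_exp, pct_exp = permanova_f_oracle(dm.values, labels)
        assert out.data.loc["g", "F"] == pytest.approx(f_exp, abs=1e-9)
        assert out.data.loc["g", "pct_var"] == pytest.approx(pct_exp, abs=1e-9)

    def test_matches_skbio_permanova_statistic(self, rng):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        mat = rng.integers(0, 2, size=(25, 8))
        pres = PresenceMatrix(pd.DataFrame(
            mat, index=[f"L{i}" for i in range(25)],
            columns=[f"U{j}" for j in range(8)]))
        dm = pairwise_dissimilarity(pres)
        labels = ["A", "A", "A", "B", "B", "B", "B", "B"]
        out = composition_effects(dm, pd.DataFrame({"g": labels}),
                                  n_perm=49, seed=0, interaction=False)
        sk = skbio_distance.permanova(
            skbio_distance.DistanceMatrix(dm.values, dm.unit_ids),
            grouping=labels, permutations=0)
        assert out.data.loc["g", "F"] == pytest.approx(
            float(sk["test statistic"]), abs=1e-9)

    def test_pct_var_invariant_to_unit_reordering(self, rng):
        mat = rng.integers(0, 2, size=(30, 9))
        labels = np.array(["A", "B", "C"] * 3)
        pres = PresenceMatrix(pd.DataFrame(
            mat, index=[f"L{i}" for i in range(30)],
            columns=[f"U{j}" for j in range(9)]))
        dm = pairwise_dissimilarity(pres)
        out1 = composition_effects(dm, pd.DataFrame({"g": labels}),
                                   n_perm=49, seed=0, interaction=False)
        order = rng.permutation(9)
        dm2 = DissimilarityMatrix(
            [dm.unit_ids[i] for i in order],
            dm.values[np.ix_(order, order)])
        out2 = composition_effects(dm2, pd.DataFrame({"g": labels[order]}),
                                   n_perm=49, seed=0, interaction=False)
        assert out1.data["pct_var"]["g"] == pytest.approx(
            out2.data["pct_var"]["g"], abs=1e-9)

    def test_gower_centering_against_direct_formula(self, rng):
        d = np.abs(rng.normal(size=(6, 6)))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        g = gower_center(d)
        n = 6
        a = -0.5 * d ** 2
        expected = np.empty_like(a)
        for i in range(n):
            for j in range(n):
                expected[i, j] = (a[i, j] - a[i].mean() - a[:, j].mean()
                                  + a.mean())
        assert np.allclose(g, expected, atol=1e-12)


class TestSimper:
    def _presence(self, mat, units):
        return PresenceMatrix(pd.DataFrame(
            mat, index=[f"L{i}" for i in range(len(mat))], columns=units))

    def test_ubiquitous_lineage_contributes_nothing(self):
        mat = [[1, 1, 1, 1], [1, 1, 0, 0], [0, 1, 1, 0]]
        pres = self._presence(mat, ["A1", "A2", "B1", "B2"])
        res = simper(pres, ["A", "A", "B", "B"], ("A", "B"))
        assert res.data.loc["L0", "mean_contribution"] == 0.0
        assert not res.data.loc["L0", "good_discriminator"]

    def test_group_exclusive_lineage_ranks_first(self):
        mat = [[1, 1, 0, 0],       # in all of A, none of B
               [1, 1, 1, 1],
               [0, 1, 0, 1]]
        pres = self._presence(mat, ["A1", "A2", "B1", "B2"])
        res = simper(pres, ["A", "A", "B", "B"], ("A", "B"))
        assert res.data.index[0] == "L0"
        assert res.data.loc["L0", "good_discriminator"]

    def test_contributions_conserve_mean_dissimilarity(self, rng):
        mat = rng.integers(0, 2, size=(40, 6))
        pres = self._presence(mat, [f"U{j}" for j in range(6)])
        labels = ["A", "A", "A", "B", "B", "B"]
        res = simper(pres, labels, ("A", "B"))
        from hostmicro.diversity import bray_curtis_binary
        pair_d = [bray_curtis_binary(mat[:, i], mat[:, j])
                  for i in range(3) for j in range(3, 6)]
        assert res.data["mean_contribution"].sum() == pytest.approx(
            np.mean(pair_d), abs=1e-12)
        assert res.mean_between_dissimilarity == pytest.approx(
            np.mean(pair_d), abs=1e-12)

    def test_cumulative_percent_reaches_100(self, rng):
        mat = rng.integers(0, 2, size=(25, 6))
        pres = self._presence(mat, [f"U{j}" for j in range(6)])
        res = simper(pres, ["A"] * 3 + ["B"] * 3, ("A", "B"))
        assert res.data["cumulative_pct"].iloc[-1] == pytest.approx(100.0)

    def test_empty_group_rejected(self):
        pres = self._presence([[1, 0]], ["U1", "U2"])
        with pytest.raises(ValueError, match="non-empty"):
            simper(pres, ["A", "A"], ("A", "B"))
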