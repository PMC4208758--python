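"""Niche-breadth classification, exact GOF testing and risk summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from hostmicro.niche_risk import (
    classify_niche,
    exact_gof,
    holm_adjust,
    report_percent,
    zoonotic_summary,
)
from hostmicro.tables import LineageAnnotation, PresenceMatrix

from conftest import make_metadata


def presence_from_positives(positives, samples, lineages):
    mat = np.zeros((len(lineages), len(samples)), dtype=int)
    s_idx = {s: j for j, s in enumerate(samples)}
    for i, lid in enumerate(lineages):
        for s in positives.get(lid, []):
            mat[i, s_idx[s]] = 1
    return PresenceMatrix(pd.DataFrame(mat, index=lineages, columns=samples))


class TestClassifyNiche:
    def _setup(self, shares):
        """10 hosts in multi-species plots: 5 GA, 5 GP; `shares` maps
        lineage -> (positives in GA, positives in GP)."""
        meta = make_metadata([
            ("P1", 2, ["GA", "GA", "GA", "GP", "GP"]),
            ("P2", 2, ["GA", "GA", "GP", "GP", "GP"]),
        ])
        samples = meta.sample_ids
        ga = [s for s in samples
              if meta.indexed().loc[s, "host_species"] == "GA"]
        gp = [s for s in samples
              if meta.indexed().loc[s, "host_species"] == "GP"]
        positives = {}
        for lid, (na, nb) in shares.items():
            positives[lid] = ga[:na] + gp[:nb]
        pres = presence_from_positives(positives, samples, list(shares))
        return pres, meta

    def test_ninety_percent_single_species_is_specific(self):
        # 10 positive hosts, 9 on one species -> dominant fraction 0.9
        meta = make_metadata([
            ("P1", 2, ["GA"] * 9 + ["GP"] * 3),
        ])
        samples = meta.sample_ids
        pres = presence_from_positives({"L": samples[:10]}, samples, ["L"])
        (cls,) = classify_niche(pres, meta)
        assert cls.n_positive_hosts == 10
        assert cls.dominant_fraction == pytest.approx(0.9)
        assert cls.niche_class == "host_specific"

    def test_below_min_occupancy_unclassified(self):
        pres, meta = self._setup({"L": (1, 1)})
        (cls,) = classify_niche(pres, meta)
        assert cls.niche_class == "unclassified"

    def test_eighty_percent_share_is_opportunist(self):
        pres, meta = self._setup({"L": (4, 1)})
        (cls,) = classify_niche(pres, meta)
        assert cls.dominant_fraction == pytest.approx(0.8)
        assert cls.niche_class == "host_opportunist"

    def test_single_host_plots_excluded_by_default(self):
        meta = make_metadata([
            ("P1", 1, ["GA", "GA", "GA"]),
            ("P2", 2, ["GA", "GP"]),
        ])
        samples = meta.sample_ids
        pres = presence_from_positives({"L": samples}, samples, ["L"])
        (cls,) = classify_niche(pres, meta)
        assert cls.n_positive_hosts == 2  # only the multi-host plot counts
        (cls_all,) = classify_niche(pres, meta, multi_host_plots_only=False)
        assert cls_all.n_positive_hosts == 5

    def test_invariant_to_sample_order(self, small_study):
        pres = small_study.counts.to_presence()
        shuffled = PresenceMatrix(
            pres.data[list(reversed(pres.unit_ids))])
        a = classify_niche(pres, small_study.metadata)
        b = classify_niche(shuffled, small_study.metadata)
        assert [(c.lineage_id, c.niche_class) for c in a] == \
               [(c.lineage_id, c.niche_class) for c in b]


class TestExactGof:
    def enumeration_oracle(self, k, n, p):
        probs = binom.pmf(np.arange(n + 1), n, p)
        return float(probs[probs <= probs[k] * (1 + 1e-12)].sum())

    @pytest.mark.parametrize("k,n,p", [
        (12, 72, 1 / 53), (4, 76, 1 / 53), (0, 20, 0.3), (10, 37, 4 / 36),
    ])
    def test_matches_enumeration(self, k, n, p):
        assert exact_gof(k, n, p) == pytest.approx(
            self.enumeration_oracle(k, n, p), abs=1e-12)

    def test_observation_at_expectation_near_one(self):
        p = 1 / 53
        k = round(72 * p)
        assert exact_gof(k, 72, p) > 0.5

    def test_closed_form_extreme_tail(self):
        assert exact_gof(0, 10, 0.5) == pytest.approx(2 * 0.5 ** 10, abs=1e-15)

    def test_degenerate_proportion_rejected(self):
        with pytest.raises(ValueError):
            exact_gof(1, 10, 0.0)
        with pytest.raises(ValueError):
            exact_gof(1, 10, 1.0)


class TestHolm:
    def test_single_p_unchanged(self):
        assert holm_adjust([0.03]).tolist() == [0.03]

    def test_two_values_hand_computed(self):
        assert np.allclose(holm_adjust([0.01, 0.04]), [0.02, 0.04])

    def test_ties_capped_monotone(self):
        assert np.allclose(holm_adjust([0.05, 0.05, 0.05]),
                           [0.15, 0.15, 0.15])

    def test_order_preserved_and_dominates_input(self, rng):
        p = rng.uniform(size=8)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        # adjusted values non-decreasing when sorted by raw p
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])


class TestReportPercent:
    @pytest.mark.parametrize("num,den,expected", [
        (1, 53, 2), (4, 76, 5), (12, 72, 17),
        (4, 36, 11), (10, 37, 27), (5, 17, 29),
    ])
    def test_rounding_rule_reproduces_printed_values(self, num, den, expected):
        assert report_percent(num, den) == expected


class TestZoonoticSummary:
    def _study(self):
        meta = make_metadata([
            ("P1", 1, ["GA", "GA", "GA"]),
            ("P2", 2, ["GA", "GP", "GP"]),
        ])
        samples = meta.sample_ids  # S1-3 richness1; S4-6 richness2
        lineages = ["Z1", "N1", "N2"]
        positives = {
            "Z1": [samples[0], samples[3], samples[4]],
            "N1": samples,
            "N2": [samples[1], samples[5]],
        }
        pres = presence_from_positives(positives, samples, lineages)
        ann = LineageAnnotation(pd.DataFrame({
            "lineage_id": lineages,
            "zoonotic_candidate": [True, False, False],
        }))
        return pres, meta, ann

    def test_per_class_counts_and_percentages(self):
        pres, meta, ann = self._study()
        out = zoonotic_summary(pres, meta, ann)
        r1 = out.per_class.loc[1]
        r2 = out.per_class.loc[2]
        assert (r1["n_lineages_total"], r1["n_zoonotic"]) == (3, 1)
        assert r1["pct_zoonotic"] == report_percent(1, 3)
        assert (r2["n_hosts"], r2["n_hosts_with_zoonotic"]) == (3, 2)
        assert r2["pct_hosts_with_zoonotic"] == report_percent(2, 3)

    def test_mean_and_se_per_host(self):
        pres, meta, ann = self._study()
        out = zoonotic_summary(pres, meta, ann)
        counts_r1 = [1, 0, 0]  # Z1 hits only S1 in richness-1
        assert out.per_class.loc[1, "mean_zoonotic_per_host"] == \
            pytest.approx(np.mean(counts_r1))
        assert out.per_class.loc[1, "se_zoonotic_per_host"] == \
            pytest.approx(np.std(counts_r1, ddof=1) / math.sqrt(3))

    def test_zero_zoonotic_class(self):
        pres, meta, ann = self._study()
        ann2 = LineageAnnotation(ann.data.assign(
            zoonotic_candidate=[False, False, False]))
        out = zoonotic_summary(pres, meta, ann2)
        assert (out.per_class["pct_zoonotic"] == 0).all()
        assert (out.per_class["mean_zoonotic_per_host"] == 0).all()

    def test_tests_compare_against_baseline(self):
        pres, meta, ann = self._study()
        out = zoonotic_summary(pres, meta, ann)
        assert len(out.lineage_tests) == 1
        row = out.lineage_tests.iloc[0]
        assert row["expected_proportion"] == pytest.approx(1 / 3)
        assert row["p_value"] == pytest.approx(
            exact_gof(1, 3, 1 / 3), abs=1e-12)

    def test_missing_annotation_named(self):
        pres, meta, ann = self._study()
        ann_short = LineageAnnotation(ann.data.iloc[:2])
        with pytest.raises(ValueError, match="N2"):
            zoonotic_summary(pres, meta, ann_short)
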