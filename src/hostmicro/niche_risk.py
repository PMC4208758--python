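"""Niche-breadth classification and zoonotic-risk summaries.

A lineage's niche breadth is judged from the host individuals it infects
in the multiple-host-species plots (where more than one host species was
available to it): lineages detected in fewer than ``min_occupancy``
(default 3) positive hosts there are left unclassified; otherwise a
lineage is *host specific* if a single host species accounts for at
least ``threshold`` (default 90%) of its positive hosts and *host
opportunist* otherwise.

Risk summaries count, per community-richness class, the candidate
zoonotic lineages among all detected lineages, the hosts carrying at
least one candidate, and the mean (+/- SE) candidates per host; classes
are compared with exact binomial goodness-of-fit tests against the
proportion expected from a baseline class, with Holm (sequential
Bonferroni) correction across the comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .tables import LineageAnnotation, PresenceMatrix, SampleMetadata

__all__ = [
    "NicheClass",
    "NicheClassifier",
    "RiskSummary",
    "classify_niche",
    "zoonotic_summary",
    "exact_gof",
    "holm_adjust",
    "report_percent",
]

CLASS_SPECIFIC = "host_specific"
CLASS_OPPORTUNIST = "host_opportunist"
CLASS_UNCLASSIFIED = "unclassified"


@dataclass
class NicheClass:
    lineage_id: str
    n_positive_hosts: int
    dominant_species: str | None
    dominant_fraction: float
    niche_class: str


class NicheClassifier(BaseEstimator):
    """Classify lineages as host specific vs host opportunist.

    Parameters
    ----------
    min_occupancy:
        Minimum positive hosts (in the restriction set) required to
        attempt classification.
    threshold:
        Minimum share of positive hosts from one species for the
        host-specific call.
    multi_host_plots_only:
        Restrict positive hosts to plots with community richness > 1,
        where a lineage has a real choice of host species.
    """

    def __init__(self, min_occupancy: int = 3, threshold: float = 0.90,
                 multi_host_plots_only: bool = True):
        self.min_occupancy = min_occupancy
        self.threshold = threshold
        self.multi_host_plots_only = multi_host_plots_only

    def fit(self, presence: PresenceMatrix,
            metadata: SampleMetadata) -> "NicheClassifier":
        meta = metadata.indexed()
        samples = [s for s in presence.unit_ids]
        metadata.require_samples(samples)
        if self.multi_host_plots_only:
            keep = [s for s in samples if meta.loc[s, "community_richness"] > 1]
        else:
            keep = samples
        keep = sorted(keep)  # order-invariant
        sub = presence.data[keep]
        species = meta.loc[keep, "host_species"]
        classes: list[NicheClass] = []
        for lid in presence.lineage_ids:
            row = sub.loc[lid]
            positive = row.index[row > 0]
            n_pos = len(positive)
            if n_pos == 0:
                classes.append(NicheClass(lid, 0, None, 0.0,
                                          CLASS_UNCLASSIFIED))
                continue
            shares = species.loc[positive].value_counts().sort_index()
            dominant = shares.idxmax()
            frac = float(shares.max() / n_pos)
            if n_pos < self.min_occupancy:
                cls = CLASS_UNCLASSIFIED
            elif frac >= self.threshold:
                cls = CLASS_SPECIFIC
            else:
                cls = CLASS_OPPORTUNIST
            classes.append(NicheClass(lid, n_pos, dominant, frac, cls))
        self.classes_ = classes
        return self

    def results_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.lineage_id, c.n_positive_hosts, c.dominant_species,
              c.dominant_fraction, c.niche_class) for c in self.classes_],
            columns=["lineage_id", "n_positive_hosts", "dominant_species",
                     "dominant_fraction", "niche_class"],
        ).set_index("lineage_id")


def classify_niche(presence: PresenceMatrix, metadata: SampleMetadata,
                   min_occupancy: int = 3, threshold: float = 0.90,
                   multi_host_plots_only: bool = True) -> list[NicheClass]:
    return NicheClassifier(
        min_occupancy=min_occupancy, threshold=threshold,
        multi_host_plots_only=multi_host_plots_only,
    ).fit(presence, metadata).classes_


def report_percent(numerator: int, denominator: int) -> int:
    """Percentage rounded to the nearest integer (reporting rule)."""
    if denominator <= 0:
        return 0
    return int(round(100.0 * numerator / denominator))


def exact_gof(observed_successes: int, n_trials: int,
              expected_proportion: float) -> float:
    """Two-sided exact binomial goodness-of-fit p-value.

    Sums the probabilities of all outcomes no more likely than the
    observed one under Binomial(n, p).
    """
    if not 0 <= observed_successes <= n_trials:
        raise ValueError("need 0 <= observed <= n_trials")
    if not 0 < expected_proportion < 1:
        raise ValueError("expected_proportion must lie strictly in (0, 1)")
    return float(stats.binomtest(observed_successes, n_trials,
                                 expected_proportion).pvalue)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down (sequential Bonferroni) adjusted p-values,
    input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class RiskSummary:
    """Zoonotic-candidate statistics per community-richness class."""

    per_class: pd.DataFrame      # indexed by community_richness
    lineage_tests: pd.DataFrame  # pairwise exact GOF vs baseline, Holm-adj
    host_tests: pd.DataFrame
    baseline_richness: int


def zoonotic_summary(
    presence: PresenceMatrix,
    metadata: SampleMetadata,
    annotations: LineageAnnotation,
    baseline_richness: int = 1,
) -> RiskSummary:
    """Summarize candidate-zoonotic burden across community-richness classes.

    Per class: the number and percentage of detected lineages flagged as
    zoonotic candidates, the number and percentage of hosts carrying at
    least one, and the mean +/- SE candidates per host.  Each non-baseline
    class is compared to the baseline class's proportions with two-sided
    exact binomial tests; the p-values are Holm-adjusted within each
    family (lineage-level, host-level).
    """
    meta = metadata.indexed()
    metadata.require_samples(presence.unit_ids)
    flags = annotations.zoonotic_flags()
    missing = set(presence.lineage_ids) - set(flags.index)
    if missing:
        raise ValueError(
            f"lineage(s) without annotation: {sorted(missing)[:5]}"
        )
    flags = flags.loc[presence.lineage_ids]
    zoo_vec = flags.to_numpy(bool)
    mat = presence.values() > 0

    rows = []
    for rich, grp in meta.groupby("community_richness", sort=True):
        cols = [presence.unit_ids.index(s) for s in grp.index
                if s in presence.unit_ids]
        sub = mat[:, cols]
        detected = sub.any(axis=1)
        n_total = int(detected.sum())
        n_zoo = int((detected & zoo_vec).sum())
        per_host = sub[zoo_vec].sum(axis=0)        # candidates per host
        n_hosts = sub.shape[1]
        n_hosts_zoo = int((per_host > 0).sum())
        mean = float(per_host.mean()) if n_hosts else 0.0
        se = (float(per_host.std(ddof=1) / np.sqrt(n_hosts))
              if n_hosts > 1 else 0.0)
        rows.append({
            "community_richness": int(rich),
            "n_lineages_total": n_total,
            "n_zoonotic": n_zoo,
            "pct_zoonotic": report_percent(n_zoo, n_total),
            "n_hosts": n_hosts,
            "n_hosts_with_zoonotic": n_hosts_zoo,
            "pct_hosts_with_zoonotic": report_percent(n_hosts_zoo, n_hosts),
            "mean_zoonotic_per_host": mean,
            "se_zoonotic_per_host": se,
        })
    per_class = pd.DataFrame(rows).set_index("community_richness")
    if baseline_richness not in per_class.index:
        raise ValueError(
            f"baseline richness class {baseline_richness} absent from data"
        )

    def _tests(num_col: str, den_col: str) -> pd.DataFrame:
        base = per_class.loc[baseline_richness]
        p_expected = (base[num_col] / base[den_col]
                      if base[den_col] else np.nan)
        recs = []
        for rich in per_class.index:
            if rich == baseline_richness or not 0 < p_expected < 1:
                continue
            row = per_class.loc[rich]
            p = exact_gof(int(row[num_col]), int(row[den_col]), p_expected)
            recs.append({"community_richness": int(rich),
                         "expected_proportion": float(p_expected),
                         "p_value": p})
        df = pd.DataFrame(recs)
        if len(df):
            df["p_holm"] = holm_adjust(df["p_value"].to_numpy())
        return df

    return RiskSummary(
        per_class=per_class,
        lineage_tests=_tests("n_zoonotic", "n_lineages_total"),
        host_tests=_tests("n_hosts_with_zoonotic", "n_hosts"),
        baseline_richness=baseline_richness,
    )
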