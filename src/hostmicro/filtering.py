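"""Negative-control contamination filtering and depth normalization.

Blood microbiome surveys run reagent-only negative controls alongside the
samples; reagent contaminants show up in those controls at high relative
abundance.  A lineage is kept for analysis only if

(a) it reaches at least ``rel_abund_threshold`` (default 2%) of the
    sequences in at least one blood sample, and
(b) its relative abundance is significantly higher in the blood samples
    than in the negative controls.

Condition (b) is operationalized as a one-sided Mann-Whitney rank test of
the lineage's relative abundances in its positive blood samples against
its relative abundances in all control samples (exact enumeration when the
joint sample size is small).  A lineage never detected in any control
satisfies (b) by definition: a lineage absent from every reagent control
cannot be a reagent contaminant, and a rank test against an all-zero
reference is exactly the limiting case of this rule.

Depth normalization is rarefaction: each sample is subsampled without
replacement to a common target depth so that richness comparisons are not
confounded by sequencing effort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .tables import LineageTable, PresenceMatrix, ValidationError

__all__ = [
    "ContaminantFilter",
    "RarefactionNormalizer",
    "PresenceBinarizer",
    "FilterReport",
    "filter_contaminants",
    "normalize_depth",
    "to_presence",
]

REASON_BELOW_THRESHOLD = "below_2pct"
REASON_NOT_ABOVE_CONTROLS = "not_above_controls"
REASON_RETAINED = "retained"

# joint n at or below which the rank test is run by exact permutation
EXACT_ENUMERATION_LIMIT = 12


@dataclass
class FilterReport:
    """Per-lineage record of the contamination-filter decision."""

    data: pd.DataFrame  # columns: max_rel_abund, statistic, p_value, retained, reason

    def retained_ids(self) -> list:
        return list(self.data.index[self.data["retained"]])

    def to_tsv(self, path) -> None:
        df = self.data.copy()
        df.index.name = "lineage_id"
        df.to_csv(path, sep="\t")


def _rank_test_greater(blood: np.ndarray, controls: np.ndarray) -> tuple[float, float]:
    """One-sided test that `blood` values are stochastically larger.

    Exact permutation enumeration for small joint n (handles ties
    exactly); tie-corrected normal approximation otherwise.
    """
    blood = np.asarray(blood, dtype=float)
    controls = np.asarray(controls, dtype=float)
    n = blood.size + controls.size
    if blood.size == 0 or controls.size == 0:
        return np.nan, 1.0
    u_stat = stats.mannwhitneyu(
        blood, controls, alternative="greater", method="asymptotic"
    ).statistic
    if n <= EXACT_ENUMERATION_LIMIT:
        # exact permutation null of the rank-sum (midranks handle ties)
        ranks = stats.rankdata(np.concatenate([blood, controls]))
        observed = ranks[: blood.size].sum()
        hits = total = 0
        for idx in itertools.combinations(range(n), blood.size):
            total += 1
            if ranks[list(idx)].sum() >= observed - 1e-12:
                hits += 1
        return float(u_stat), hits / total
    p = stats.mannwhitneyu(
        blood, controls, alternative="greater", method="asymptotic"
    ).pvalue
    return float(u_stat), float(p)


class ContaminantFilter(BaseEstimator, TransformerMixin):
    """Drop reagent-contaminant lineages by the controls-based rule.

    Parameters
    ----------
    rel_abund_threshold:
        Minimum relative abundance the lineage must reach in at least one
        blood sample (default 0.02, i.e. 2% of the sample's sequences).
    alpha:
        Significance level for the one-sided rank test against controls.

    Attributes
    ----------
    retained_ : list of retained lineage IDs
    report_ : FilterReport covering every input lineage
    """

    def __init__(self, rel_abund_threshold: float = 0.02, alpha: float = 0.05):
        self.rel_abund_threshold = rel_abund_threshold
        self.alpha = alpha

    def fit(self, counts: LineageTable, controls: LineageTable) -> "ContaminantFilter":
        if list(counts.lineage_ids) != list(controls.lineage_ids):
            raise ValidationError(
                "counts and controls must share an identical lineage axis"
            )
        if controls.shape[1] == 0:
            raise ValidationError(
                "no control samples: the inclusion rule is undefined without controls"
            )
        totals = counts.sample_totals()
        if (totals == 0).any():
            bad = totals.index[totals == 0].tolist()
            raise ValidationError(f"samples with zero total sequences: {bad}")

        rel = counts.relative_abundance()
        rel_ctrl = controls.relative_abundance()
        records = []
        for lid in counts.lineage_ids:
            blood = rel.loc[lid].to_numpy(dtype=float)
            ctrl = rel_ctrl.loc[lid].to_numpy(dtype=float)
            max_rel = float(blood.max()) if blood.size else 0.0
            if max_rel < self.rel_abund_threshold:
                records.append((lid, max_rel, np.nan, np.nan, False,
                                REASON_BELOW_THRESHOLD))
                continue
            if ctrl.sum() == 0:
                # absent from every reagent control: not a contaminant
                records.append((lid, max_rel, np.nan, 0.0, True, REASON_RETAINED))
                continue
            positive = blood[blood > 0]
            u, p = _rank_test_greater(positive, ctrl)
            if p < self.alpha:
                records.append((lid, max_rel, u, p, True, REASON_RETAINED))
            else:
                records.append((lid, max_rel, u, p, False,
                                REASON_NOT_ABOVE_CONTROLS))
        df = pd.DataFrame(
            records,
            columns=["lineage_id", "max_rel_abund", "statistic", "p_value",
                     "retained", "reason"],
        ).set_index("lineage_id")
        self.report_ = FilterReport(df)
        self.retained_ = self.report_.retained_ids()
        return self

    def transform(self, counts: LineageTable) -> LineageTable:
        if not hasattr(self, "retained_"):
            raise RuntimeError("ContaminantFilter is not fitted")
        return counts.select_lineages(self.retained_)

    def fit_transform(self, counts: LineageTable, controls: LineageTable,
                      **kwargs) -> LineageTable:
        return self.fit(counts, controls).transform(counts)


class RarefactionNormalizer(BaseEstimator, TransformerMixin):
    """Rarefy every sample to a common sequencing depth.

    Subsamples each sample's sequences without replacement (multivariate
    hypergeometric draw) to exactly ``target_depth`` sequences.  Rows that
    become all-zero are retained so the lineage axis stays aligned; they
    are listed in ``zeroed_lineages_`` after transform.
    """

    def __init__(self, target_depth: int | str = "min", random_state=None):
        self.target_depth = target_depth
        self.random_state = random_state

    def fit(self, counts: LineageTable, y=None) -> "RarefactionNormalizer":
        totals = counts.sample_totals()
        if self.target_depth == "min":
            self.depth_ = int(totals.min())
        else:
            self.depth_ = int(self.target_depth)
            shallow = totals.index[totals < self.depth_].tolist()
            if shallow:
                raise ValidationError(
                    f"target depth {self.depth_} exceeds total sequences in "
                    f"sample(s): {shallow}"
                )
        return self

    def transform(self, counts: LineageTable) -> LineageTable:
        if not hasattr(self, "depth_"):
            raise RuntimeError("RarefactionNormalizer is not fitted")
        totals = counts.sample_totals()
        shallow = totals.index[totals < self.depth_].tolist()
        if shallow:
            raise ValidationError(
                f"target depth {self.depth_} exceeds total sequences in "
                f"sample(s): {shallow}"
            )
        rng = np.random.default_rng(self.random_state)
        mat = counts.counts()
        out = np.empty_like(mat)
        for j in range(mat.shape[1]):
            col = mat[:, j]
            if col.sum() == self.depth_:
                out[:, j] = col
            else:
                out[:, j] = rng.multivariate_hypergeometric(col, self.depth_)
        rarefied = LineageTable(
            pd.DataFrame(out, index=counts.data.index, columns=counts.data.columns)
        )
        row_sums = rarefied.data.sum(axis=1)
        self.zeroed_lineages_ = row_sums.index[row_sums == 0].tolist()
        return rarefied

    def fit_transform(self, counts: LineageTable, y=None, **kwargs) -> LineageTable:
        return self.fit(counts).transform(counts)


class PresenceBinarizer(BaseEstimator, TransformerMixin):
    """Convert counts to presence/absence (1 iff count > 0).

    Presence/absence rather than abundance is used downstream to reduce
    the weight of pyrosequencing abundance errors.
    """

    def fit(self, counts: LineageTable, y=None) -> "PresenceBinarizer":
        return self

    def transform(self, counts: LineageTable) -> PresenceMatrix:
        return counts.to_presence()


# -- functional wrappers -----------------------------------------------------

def filter_contaminants(
    counts: LineageTable,
    controls: LineageTable,
    rel_abund_threshold: float = 0.02,
    alpha: float = 0.05,
) -> tuple[LineageTable, FilterReport]:
    est = ContaminantFilter(rel_abund_threshold=rel_abund_threshold, alpha=alpha)
    filtered = est.fit_transform(counts, controls)
    return filtered, est.report_


def normalize_depth(
    counts: LineageTable,
    method: str = "rarefy",
    target_depth: int | str = "min",
    seed=None,
) -> LineageTable:
    if method != "rarefy":
        raise ValueError(f"unknown normalization method {method!r}")
    return RarefactionNormalizer(
        target_depth=target_depth, random_state=seed
    ).fit_transform(counts)


def to_presence(counts: LineageTable) -> PresenceMatrix:
    return counts.to_presence()
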