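"""Aggregation of presence data across organization levels and spatial scales.

The study grid crosses three organization levels (host individuals, host
species populations, host communities) with three spatial scales (the
individual host, the 1-ha plot, the region).  Five combinations are
meaningful:

=============  ===============  =============================================
level          scale            one unit per
=============  ===============  =============================================
individual     host_individual  blood sample (host individual)
population     plot             (plot, host species)
community      plot             plot
population     region           (community richness class, host species)
community      region           community richness class
=============  ===============  =============================================

Regional units are stratified by community-richness class because the
regional analyses contrast single-, two- and three-species communities.
Unit-level presence is the union (logical OR) of member presences; the
per-lineage occupancy count (number of positive member hosts) and the
unit's total sequence mass are carried alongside for prevalence and
diversity computations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import LineageTable, PresenceMatrix, SampleMetadata, ValidationError

__all__ = ["AnalysisUnit", "VALID_COMBINATIONS", "build_units",
           "aggregate_presence", "AggregatedData"]

VALID_COMBINATIONS = (
    ("individual", "host_individual"),
    ("population", "plot"),
    ("community", "plot"),
    ("population", "region"),
    ("community", "region"),
)


@dataclass
class AnalysisUnit:
    """A group of blood samples analyzed as one community observation."""

    unit_id: str
    level: str
    scale: str
    member_sample_ids: list = field(default_factory=list)
    host_species: str | None = None
    plot_id: str | None = None
    community_richness: int | None = None

    @property
    def n_hosts(self) -> int:
        return len(self.member_sample_ids)


def build_units(metadata: SampleMetadata, level: str, scale: str) -> list[AnalysisUnit]:
    """Enumerate every analysis unit at one (level, scale) combination."""
    if (level, scale) not in VALID_COMBINATIONS:
        raise ValueError(
            f"invalid (level, scale) = ({level!r}, {scale!r}); valid pairs: "
            f"{list(VALID_COMBINATIONS)}"
        )
    df = metadata.data
    units: list[AnalysisUnit] = []
    if (level, scale) == ("individual", "host_individual"):
        for row in df.itertuples(index=False):
            units.append(AnalysisUnit(
                unit_id=str(row.sample_id), level=level, scale=scale,
                member_sample_ids=[row.sample_id],
                host_species=row.host_species, plot_id=row.plot_id,
                community_richness=int(row.community_richness)))
    elif (level, scale) == ("population", "plot"):
        for (plot, sp), grp in df.groupby(["plot_id", "host_species"], sort=True):
            units.append(AnalysisUnit(
                unit_id=f"{plot}|{sp}", level=level, scale=scale,
                member_sample_ids=list(grp["sample_id"]),
                host_species=sp, plot_id=plot,
                community_richness=int(grp["community_richness"].iloc[0])))
    elif (level, scale) == ("community", "plot"):
        for plot, grp in df.groupby("plot_id", sort=True):
            units.append(AnalysisUnit(
                unit_id=str(plot), level=level, scale=scale,
                member_sample_ids=list(grp["sample_id"]), plot_id=plot,
                community_richness=int(grp["community_richness"].iloc[0])))
    elif (level, scale) == ("population", "region"):
        for (rich, sp), grp in df.groupby(["community_richness", "host_species"],
                                          sort=True):
            units.append(AnalysisUnit(
                unit_id=f"richness{rich}|{sp}", level=level, scale=scale,
                member_sample_ids=list(grp["sample_id"]),
                host_species=sp, community_richness=int(rich)))
    else:  # community, region
        for rich, grp in df.groupby("community_richness", sort=True):
            units.append(AnalysisUnit(
                unit_id=f"richness{rich}", level=level, scale=scale,
                member_sample_ids=list(grp["sample_id"]),
                community_richness=int(rich)))
    return units


@dataclass
class AggregatedData:
    """Unit-level presence, occupancy counts and sequence mass."""

    presence: PresenceMatrix           # lineages x units, union of members
    occupancy: pd.DataFrame            # lineages x units, positive member hosts
    unit_sizes: pd.Series              # member hosts per unit
    sequence_mass: pd.Series | None    # total sequences per unit (if counts given)


def aggregate_presence(
    presence: PresenceMatrix,
    units: list[AnalysisUnit],
    counts: LineageTable | None = None,
) -> AggregatedData:
    """Aggregate sample-level presence into unit-level presence/occupancy."""
    sample_index = {s: i for i, s in enumerate(presence.unit_ids)}
    for u in units:
        orphans = [s for s in u.member_sample_ids if s not in sample_index]
        if orphans:
            raise ValidationError(
                f"unit {u.unit_id!r} references sample(s) absent from the "
                f"presence matrix: {orphans}"
            )
        if not u.member_sample_ids:
            raise ValidationError(f"unit {u.unit_id!r} has no members")
    mat = presence.values()
    occ = np.zeros((mat.shape[0], len(units)), dtype=np.int64)
    for j, u in enumerate(units):
        cols = [sample_index[s] for s in u.member_sample_ids]
        occ[:, j] = mat[:, cols].sum(axis=1)
    unit_ids = [u.unit_id for u in units]
    occupancy = pd.DataFrame(occ, index=presence.data.index, columns=unit_ids)
    agg_presence = PresenceMatrix((occupancy > 0).astype(np.int8))
    unit_sizes = pd.Series([u.n_hosts for u in units], index=unit_ids)
    mass = None
    if counts is not None:
        totals = counts.sample_totals()
        mass = pd.Series(
            [sum(totals[s] for s in u.member_sample_ids) for u in units],
            index=unit_ids, dtype=np.int64)
    return AggregatedData(agg_presence, occupancy, unit_sizes, mass)
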