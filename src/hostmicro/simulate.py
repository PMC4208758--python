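"""Synthetic study generator for the hierarchical blood-microbiome design.

Generates count tables, sample metadata, reagent-control tables, lineage
annotations and per-lineage truth records with the statistical structure
the downstream analyses assume:

* 34 one-hectare plots split 13 / 14 / 7 across single-, two- and
  three-host-species communities, with nested species sets
  ({GA} within {GA, GP} within {GA, GP, GG});
* shallow per-sample sequencing depths (35-353 total sequences);
* a long tail of lineages detected in exactly one host individual;
* one dominant lineage with high overall prevalence and a marked
  preference for one host species;
* reagent-contaminant lineages present in every negative control at high
  relative abundance and only sporadically (at low abundance) in blood
  samples, so the controls-based inclusion rule can separate them.

The occurrence model is per-lineage, per-host-species Bernoulli presence;
counts for the lineages present in a sample are drawn from a Dirichlet-
multinomial over the sample's lineage set, with every present lineage
guaranteed at least one sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .rsoc import MODEL_REGISTRY, OccupancyCurve
from .tables import LineageAnnotation, LineageTable, SampleMetadata

__all__ = ["GeneratorParams", "TruthRecord", "StudyData", "generate_study",
           "generate_rsoc_curve"]

SPECIES_BY_RICHNESS = {1: ["GA"], 2: ["GA", "GP"], 3: ["GA", "GP", "GG"]}


class ParameterError(ValueError):
    """Generator parameters are infeasible or inconsistent."""


@dataclass
class GeneratorParams:
    """Knobs of the synthetic study.

    Defaults reproduce the study conditions: the 13/14/7 plot split, the
    35-353 depth range, a lineage pool of 161 with ~80% single-host
    lineages, one dominant lineage at ~55% overall prevalence with 90%
    of its occurrences on its preferred host species, and ~8% of
    lineages flagged as zoonotic candidates.
    """

    n_plots_by_richness: dict = field(
        default_factory=lambda: {1: 13, 2: 14, 3: 7})
    hosts_per_plot_range: tuple = (1, 4)
    depth_range: tuple = (35, 353)
    n_lineages: int = 161
    singleton_fraction: float = 0.80
    dominant_prevalence: float = 0.55
    dominant_host_preference: float = 0.90
    n_contaminants: int = 10
    n_controls: int = 8
    zoonotic_fraction: float = 0.08
    specific_fraction: float = 0.25     # of non-singleton, non-dominant pool
    occurrence_prob_range: tuple = (0.05, 0.30)
    seed: int | None = None

    def validate(self) -> None:
        for name in ("singleton_fraction", "dominant_prevalence",
                     "dominant_host_preference", "zoonotic_fraction",
                     "specific_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {v}")
        if sum(self.n_plots_by_richness.values()) < 1:
            raise ParameterError("need at least one plot")
        for name in ("hosts_per_plot_range", "depth_range",
                     "occurrence_prob_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} interval is empty: ({lo}, {hi})")
        if self.hosts_per_plot_range[0] < 1:
            raise ParameterError("each plot needs at least one host")
        if self.n_lineages < 1:
            raise ParameterError("n_lineages must be positive")
        if self.singleton_fraction >= 1.0 and self.dominant_prevalence > 0:
            raise ParameterError(
                "singleton_fraction = 1 is incompatible with a dominant "
                "lineage (dominant_prevalence > 0)"
            )


@dataclass
class TruthRecord:
    """Ground truth for one generated lineage (enables recovery tests)."""

    lineage_id: str
    role: str                   # dominant | singleton | common | contaminant
    niche_class: str            # specific | opportunist | (n/a for others)
    zoonotic: bool
    occurrence_probs: dict      # per host species


@dataclass
class StudyData:
    counts: LineageTable
    metadata: SampleMetadata
    controls: LineageTable
    annotations: LineageAnnotation
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {"lineage_id": t.lineage_id, "role": t.role,
                   "niche_class": t.niche_class, "zoonotic": t.zoonotic}
            row.update({f"p_{sp}": t.occurrence_probs.get(sp, 0.0)
                        for sp in SPECIES_BY_RICHNESS[3]})
            rows.append(row)
        return pd.DataFrame(rows).set_index("lineage_id")


def _make_metadata(params: GeneratorParams, rng) -> SampleMetadata:
    records = []
    plot_no = 0
    host_no = 0
    lo, hi = params.hosts_per_plot_range
    for rich in sorted(params.n_plots_by_richness):
        species = SPECIES_BY_RICHNESS[rich]
        for _ in range(params.n_plots_by_richness[rich]):
            plot_no += 1
            plot_id = f"P{plot_no:02d}"
            n_hosts = int(rng.integers(lo, hi + 1))
            # every species in the community gets a chance; assignment uniform
            assigned = [species[i % len(species)] for i in range(n_hosts)]
            rng.shuffle(assigned)
            for sp in assigned:
                host_no += 1
                records.append({
                    "sample_id": f"S{host_no:03d}",
                    "host_individual_id": f"H{host_no:03d}",
                    "host_species": sp,
                    "plot_id": plot_id,
                    "community_richness": rich,
                })
    return SampleMetadata(pd.DataFrame(records))


def _assign_roles(params: GeneratorParams, rng):
    """Split the lineage pool into dominant / singleton / common roles."""
    n = params.n_lineages
    ids = [f"L{i:03d}" for i in range(1, n + 1)]
    has_dominant = params.dominant_prevalence > 0 and n >= 1
    n_singletons = int(round(params.singleton_fraction * n))
    n_singletons = min(n_singletons, n - (1 if has_dominant else 0))
    roles = {}
    pool = list(ids)
    if has_dominant:
        roles[pool.pop(0)] = "dominant"
    for lid in pool[:n_singletons]:
        roles[lid] = "singleton"
    for lid in pool[n_singletons:]:
        roles[lid] = "common"
    return ids, roles


def generate_study(params: GeneratorParams | None = None,
                   seed=None) -> StudyData:
    """Draw one synthetic study (counts, metadata, controls, annotations,
    truth records), mutually consistent."""
    params = params or GeneratorParams()
    params.validate()
    if seed is None:
        seed = params.seed
    rng = np.random.default_rng(seed)

    metadata = _make_metadata(params, rng)
    meta = metadata.data
    samples = list(meta["sample_id"])
    sp_of = dict(zip(meta["sample_id"], meta["host_species"]))

    ids, roles = _assign_roles(params, rng)
    all_species = SPECIES_BY_RICHNESS[3]

    # --- occurrence probabilities and truth records ---
    lo_p, hi_p = params.occurrence_prob_range
    truth: list[TruthRecord] = []
    occ_probs: dict[str, dict[str, float]] = {}
    pref_species = "GA"   # the dominant lineage prefers the ubiquitous host
    for lid in ids:
        role = roles[lid]
        if role == "dominant":
            # solve per-species probabilities so that the overall prevalence
            # target is met with `dominant_host_preference` of occurrences on
            # the preferred species (species counts enter via the metadata)
            n_by_sp = meta["host_species"].value_counts()
            n_tot = len(meta)
            n_pref = int(n_by_sp.get(pref_species, 0))
            n_other = n_tot - n_pref
            target = params.dominant_prevalence * n_tot
            pref_mass = params.dominant_host_preference
            p_pref = min(target * pref_mass / max(n_pref, 1), 1.0)
            p_other = (min(target * (1 - pref_mass) / n_other, 1.0)
                       if n_other else 0.0)
            probs = {sp: (p_pref if sp == pref_species else p_other)
                     for sp in all_species}
            niche = "specific" if pref_mass >= 0.9 else "opportunist"
        elif role == "singleton":
            probs = {sp: 0.0 for sp in all_species}
            niche = "specific"
        else:  # common
            if rng.random() < params.specific_fraction:
                niche = "specific"
                target_sp = all_species[int(rng.integers(len(all_species)))]
                # near-complete fidelity: the off-host leak must be small
                # enough that the expected single-species share clears the
                # 90% rule even for the rarest host species
                base = float(rng.uniform(lo_p, hi_p))
                probs = {sp: (base if sp == target_sp else base / 200.0)
                         for sp in all_species}
            else:
                niche = "opportunist"
                probs = {sp: float(rng.uniform(lo_p, hi_p))
                         for sp in all_species}
        occ_probs[lid] = probs
        truth.append(TruthRecord(lid, role, niche, False, probs))

    # --- presence draws ---
    presence: dict[str, set] = {lid: set() for lid in ids}
    for s in samples:
        sp = sp_of[s]
        for lid in ids:
            if roles[lid] == "singleton":
                continue
            if rng.random() < occ_probs[lid][sp]:
                presence[lid].add(s)
    # plant each singleton in one uniformly chosen host individual
    for lid in ids:
        if roles[lid] == "singleton":
            host = samples[int(rng.integers(len(samples)))]
            presence[lid].add(host)
            occ_probs[lid] = {sp: 0.0 for sp in all_species}
            for t in truth:
                if t.lineage_id == lid:
                    t.occurrence_probs = occ_probs[lid]

    # --- contaminants ---
    contaminant_ids = [f"C{i:02d}" for i in range(1, params.n_contaminants + 1)]
    for cid in contaminant_ids:
        truth.append(TruthRecord(cid, "contaminant", "n/a", False,
                                 {sp: 0.0 for sp in all_species}))
    contam_presence: dict[str, set] = {cid: set() for cid in contaminant_ids}
    for cid in contaminant_ids:
        for s in samples:
            if rng.random() < 0.10:     # sporadic low-level carryover
                contam_presence[cid].add(s)

    all_ids = ids + contaminant_ids

    # --- counts: Dirichlet-multinomial per sample over its lineage set ---
    d_lo, d_hi = params.depth_range
    counts = pd.DataFrame(0, index=all_ids, columns=samples, dtype=np.int64)
    for s in samples:
        true_here = [lid for lid in ids if s in presence[lid]]
        contam_here = [cid for cid in contaminant_ids
                       if s in contam_presence[cid]]
        depth = int(rng.integers(d_lo, d_hi + 1))
        n_here = len(true_here) + len(contam_here)
        if n_here == 0:
            # pad an empty sample from the multi-host pool so totals stay in
            # the depth range; singletons are never reused (their single-host
            # occupancy is a construction guarantee).  All-singleton pools
            # leave the sample empty.
            pool = [lid for lid in ids if roles[lid] != "singleton"]
            if not pool:
                continue
            lid = pool[int(rng.integers(len(pool)))]
            presence[lid].add(s)
            true_here = [lid]
            n_here = 1
        if n_here > depth:
            raise ParameterError(
                f"sample {s} hosts {n_here} lineages, above depth {depth}; "
                "reduce occurrence probabilities or raise depth_range"
            )
        # concentration: dominant lineage pulls more reads; contaminants are
        # trace carryover and stay near the detection floor
        conc = np.array(
            [8.0 if roles.get(lid) == "dominant" else 1.5 for lid in true_here]
            + [0.3] * len(contam_here)
        )
        w = rng.dirichlet(conc)
        extra = rng.multinomial(depth - n_here, w)
        col = extra + 1
        counts.loc[true_here + contam_here, s] = col

    # --- negative controls: contaminants at high relative abundance ---
    control_ids = [f"NC{i:02d}" for i in range(1, params.n_controls + 1)]
    controls = pd.DataFrame(0, index=all_ids, columns=control_ids,
                            dtype=np.int64)
    if contaminant_ids:
        for nc in control_ids:
            depth = int(rng.integers(d_lo, d_hi + 1))
            w = rng.dirichlet(np.full(len(contaminant_ids), 2.0))
            controls.loc[contaminant_ids, nc] = (
                rng.multinomial(depth - len(contaminant_ids), w) + 1
            )

    # --- zoonotic flags (drawn among true lineages, known pre-analysis);
    # candidates are predominantly rare, so weight the draw toward the
    # single-host tail (4:1) rather than flagging uniformly ---
    n_zoo = int(round(params.zoonotic_fraction * len(ids)))
    weights = np.array([4.0 if roles[lid] == "singleton" else 1.0
                        for lid in ids])
    weights /= weights.sum()
    zoo_ids = (set(rng.choice(ids, size=n_zoo, replace=False, p=weights))
               if n_zoo else set())
    for t in truth:
        t.zoonotic = t.lineage_id in zoo_ids
    annotations = LineageAnnotation(pd.DataFrame({
        "lineage_id": all_ids,
        "zoonotic_candidate": [lid in zoo_ids for lid in all_ids],
        "best_match_label": ["synthetic lineage" for _ in all_ids],
    }))

    return StudyData(
        counts=LineageTable(counts),
        metadata=metadata,
        controls=LineageTable(controls),
        annotations=annotations,
        truth=truth,
    )


def generate_rsoc_curve(model: str, coefficients: dict, n_lineages: int,
                        noise_sd: float = 0.0, seed=None,
                        community: str = "synthetic") -> OccupancyCurve:
    """Synthesize a ranked occupancy curve from one registered model form.

    Evaluates Q_i = f(R_i) + eps_i with eps ~ Normal(0, noise_sd), clips
    to [0, 1] (prevalences are proportions) and re-sorts non-increasing.
    """
    if model not in MODEL_REGISTRY:
        raise KeyError(f"unknown RSOC model {model!r}; registered: "
                       f"{sorted(MODEL_REGISTRY)}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    spec = MODEL_REGISTRY[model]
    missing = [p for p in spec.params if p not in coefficients]
    if missing:
        raise ValueError(f"model {model} missing coefficient(s): {missing}")
    R = np.arange(1, n_lineages + 1, dtype=float)
    theta = [float(coefficients[p]) for p in spec.params]
    q = spec.func(R, theta, n_lineages)
    if noise_sd > 0:
        q = q + np.random.default_rng(seed).normal(0.0, noise_sd, n_lineages)
    q = np.clip(q, 0.0, 1.0)
    q = np.sort(q)[::-1]
    return OccupancyCurve(community=community, Q=q, n_hosts=max(n_lineages, 1))
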