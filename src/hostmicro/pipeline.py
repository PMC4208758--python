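"""Config-driven end-to-end pipeline with provenance logging.

``run_pipeline`` executes filter -> normalize -> presence -> aggregate ->
{diversity, composition, simper, rsoc, niche, risk} from a single config
mapping and writes one machine-readable report per stage plus a run
manifest (seed, package version, resolved parameter values).  All
randomized stages draw their seeds deterministically from the single
top-level seed, so identical configs produce byte-identical reports.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community_stats import composition_effects, diversity_effects, simper
from .diversity import diversity_frame, pairwise_dissimilarity, unit_diversity
from .filtering import ContaminantFilter, RarefactionNormalizer
from .hierarchy import aggregate_presence, build_units
from .niche_risk import NicheClassifier, zoonotic_summary
from .rsoc import OccupancyModelCompetition, rank_occupancy
from .simulate import GeneratorParams, generate_study
from .tables import (LineageAnnotation, LineageTable, SampleMetadata,
                     read_annotations, read_lineage_table, read_metadata)

__all__ = ["ConfigError", "run_pipeline", "DEFAULT_CONFIG"]


class ConfigError(ValueError):
    """The pipeline config is missing or misusing a parameter."""


DEFAULT_CONFIG = {
    "seed": None,                    # required
    "inputs": None,                  # {counts, metadata, controls, annotations}
    "simulate": None,                # GeneratorParams fields; exclusive with inputs
    "filter": {"rel_abund_threshold": 0.02, "alpha": 0.05},
    "normalize": {"target_depth": "min"},
    "compare": {"n_perm": 999, "interaction": True},
    "simper": {"groups": None},      # default: two most common host species
    "rsoc": {"multi_start": 20, "min_lineages": 8},
    "niche": {"min_occupancy": 3, "threshold": 0.90,
              "multi_host_plots_only": True},
    "risk": {"baseline_richness": 1},
}


def _resolve_config(config: dict) -> dict:
    cfg = {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
    for key, default in DEFAULT_CONFIG.items():
        value = config.get(key, default)
        if isinstance(default, dict) and default is not None:
            value = dict(value or {})
            bad = set(value) - set(default)
            if bad:
                raise ConfigError(
                    f"unknown parameter(s) in section {key!r}: {sorted(bad)}"
                )
            merged = dict(default)
            merged.update(value)
            for pname, pval in merged.items():
                if pval is None and default[pname] is not None:
                    raise ConfigError(
                        f"missing stage parameter: {key}.{pname}")
            value = merged
        cfg[key] = value
    if cfg["seed"] is None:
        raise ConfigError("missing top-level parameter: seed")
    if (cfg["inputs"] is None) == (cfg["simulate"] is None):
        raise ConfigError("config needs exactly one of 'inputs' or 'simulate'")
    return cfg


def _load_inputs(cfg: dict, seeds: dict):
    if cfg["simulate"] is not None:
        params = GeneratorParams(**{k: v for k, v in cfg["simulate"].items()})
        data = generate_study(params, seed=seeds["simulate"])
        return data.counts, data.metadata, data.controls, data.annotations
    paths = cfg["inputs"]
    for key in ("counts", "metadata", "controls", "annotations"):
        if key not in paths:
            raise ConfigError(f"inputs section missing path: {key}")
    return (
        read_lineage_table(paths["counts"]),
        read_metadata(paths["metadata"]),
        read_lineage_table(paths["controls"]),
        read_annotations(paths["annotations"]),
    )


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _stage_seeds(seed: int) -> dict:
    names = ["simulate", "normalize", "compare_div", "compare_comp", "rsoc"]
    ss = np.random.SeedSequence(int(seed))
    states = [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(len(names))]
    return dict(zip(names, states))


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage and write reports under ``out_dir``.

    Returns a summary dict mirroring the manifest.
    """
    cfg = _resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg["seed"])

    counts, metadata, controls, annotations = _load_inputs(cfg, seeds)
    metadata.require_samples(counts.sample_ids)

    # -- filter ------------------------------------------------------------
    filt = ContaminantFilter(**cfg["filter"]).fit(counts, controls)
    filtered = filt.transform(counts)
    filt.report_.to_tsv(out / "filter_report.tsv")
    filtered.to_tsv(out / "filtered_counts.tsv")

    # -- normalize ---------------------------------------------------------
    normalizer = RarefactionNormalizer(
        target_depth=cfg["normalize"]["target_depth"],
        random_state=seeds["normalize"])
    normalized = normalizer.fit_transform(filtered)
    normalized.to_tsv(out / "normalized_counts.tsv")

    presence = normalized.to_presence()

    # -- aggregate (all five level x scale combinations) --------------------
    aggregates = {}
    for level, scale in (("individual", "host_individual"),
                         ("population", "plot"), ("community", "plot"),
                         ("population", "region"), ("community", "region")):
        units = build_units(metadata, level, scale)
        aggregates[(level, scale)] = (
            units, aggregate_presence(presence, units, counts=normalized))
    occ = aggregates[("community", "region")][1].occupancy
    occ.to_csv(out / "occupancy_region.tsv", sep="\t")

    # -- diversity + factorial effects at the individual level --------------
    units_ind, agg_ind = aggregates[("individual", "host_individual")]
    div = unit_diversity(agg_ind)
    div_df = diversity_frame(div)
    div_df.to_csv(out / "diversity.tsv", sep="\t")

    meta_ind = metadata.indexed().loc[[u.unit_id for u in units_ind]]
    factors = pd.DataFrame({
        "host_species": meta_ind["host_species"].to_numpy(),
        "host_diversity": meta_ind["community_richness"].to_numpy(),
    })
    finite = np.isfinite(div_df["fisher_alpha"].to_numpy())
    eff_div = diversity_effects(
        div_df["fisher_alpha"].to_numpy()[finite], factors[finite],
        n_perm=cfg["compare"]["n_perm"], seed=seeds["compare_div"],
        interaction=cfg["compare"]["interaction"])
    dist = pairwise_dissimilarity(agg_ind.presence)
    eff_comp = composition_effects(
        dist, factors, n_perm=cfg["compare"]["n_perm"],
        seed=seeds["compare_comp"],
        interaction=cfg["compare"]["interaction"])
    _json_dump({
        "diversity": json.loads(eff_div.data.to_json(orient="index")),
        "composition": json.loads(eff_comp.data.to_json(orient="index")),
        "skipped": {"diversity": eff_div.skipped,
                    "composition": eff_comp.skipped},
    }, out / "effects.json")

    # -- SIMPER between host species ----------------------------------------
    groups = cfg["simper"]["groups"]
    if groups is None:
        groups = list(meta_ind["host_species"].value_counts().index[:2])
    if len(set(groups)) >= 2:
        sim = simper(agg_ind.presence, meta_ind["host_species"].to_numpy(),
                     tuple(groups))
        sim.data.to_csv(out / "simper.tsv", sep="\t")

    # -- RSOC competition per regional community ----------------------------
    units_reg, agg_reg = aggregates[("community", "region")]
    rsoc_report = {}
    for u in units_reg:
        curve = rank_occupancy(agg_reg.occupancy[u.unit_id], u.n_hosts,
                               community=u.unit_id)
        if len(curve) < cfg["rsoc"]["min_lineages"]:
            rsoc_report[u.unit_id] = {"skipped": f"only {len(curve)} lineages"}
            continue
        comp = OccupancyModelCompetition(
            multi_start=cfg["rsoc"]["multi_start"],
            random_state=seeds["rsoc"]).fit_curve(curve)
        rsoc_report[u.unit_id] = {
            "n_lineages": len(curve), "n_hosts": u.n_hosts,
            "best_model": comp.best_model_,
            "fits": json.loads(
                comp.results_frame().to_json(orient="index")),
        }
    _json_dump(rsoc_report, out / "rsoc.json")

    # -- niche + risk --------------------------------------------------------
    niche = NicheClassifier(**cfg["niche"]).fit(presence, metadata)
    niche.results_frame().to_csv(out / "niche.tsv", sep="\t")
    risk = zoonotic_summary(presence, metadata, annotations,
                            baseline_richness=cfg["risk"]["baseline_richness"])
    _json_dump({
        "per_class": json.loads(risk.per_class.to_json(orient="index")),
        "lineage_tests": json.loads(
            risk.lineage_tests.to_json(orient="records")),
        "host_tests": json.loads(risk.host_tests.to_json(orient="records")),
        "baseline_richness": risk.baseline_richness,
    }, out / "risk.json")

    manifest = {
        "seed": int(cfg["seed"]),
        "stage_seeds": seeds,
        "hostmicro_version": __version__,
        "parameters": {k: cfg[k] for k in
                       ("filter", "normalize", "compare", "simper",
                        "rsoc", "niche", "risk")},
        "n_samples": len(counts.sample_ids),
        "n_lineages_input": len(counts.lineage_ids),
        "n_lineages_retained": len(filtered.lineage_ids),
        "rarefaction_depth": normalizer.depth_,
        "reports": sorted(p.name for p in out.iterdir() if p.is_file()
                          and p.name != "manifest.json"),
    }
    _json_dump(manifest, out / "manifest.json")
    return manifest
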