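# hostmicro

Hierarchical host–microbial diversity analysis for blood-microbiome
surveys across a host-species-richness gradient.

## The problem

Whether microbial diversity rises or falls with host species diversity
depends on the niche breadth of the microbes and on the spatial scale of
the comparison. Surveys that test this — for example 16S phylotype
("lineage") tables from rodent blood sampled in 1-ha plots holding one,
two or three gerbil species — need a chain of analyses that no single
tool provides end-to-end:

1. **Contamination filtering** against reagent-only negative controls: a
   lineage is kept only if it reaches ≥ 2% of the sequences in at least
   one blood sample *and* its relative abundance is significantly higher
   in blood than in the controls (one-sided exact Mann–Whitney; a
   lineage never detected in any control passes the control condition by
   definition).
2. **Rarefaction** of every sample to a common sequencing depth.
3. **Multi-scale aggregation** of presence/absence data over the five
   meaningful organization-level × spatial-scale combinations:
   individuals, species populations per plot, communities per plot, and
   regional populations/communities stratified by community richness.
4. **Diversity and composition statistics**: Fisher's alpha (the root of
   `S = α·ln(1 + N/α)`) per analysis unit; binary Bray–Curtis
   dissimilarity `(b+c)/(2a+b+c)` between units; two-factor sequential
   permutation ANOVA and PERMANOVA for host-species × host-diversity
   effects (% variance explained per term); SIMPER decomposition of
   between-group dissimilarity with the mean/SD > 1 "good discriminator"
   rule.
5. **Ranked Species Occupancy Curves (RSOC)**: lineage prevalences
   against descending rank, fitted with six nonlinear forms
   (exponential concave `Q = c + a·e^{−bR}`, exponential convex,
   lognormal, symmetric and asymmetric sigmoid, linear) and competed by
   AICc; Akaike weights `w_i = e^{−Δ_i/2}/Σ_j e^{−Δ_j/2}` summarize
   model plausibility. A sigmoidal winner indicates a bimodal
   (common + rare) community; an exponential concave winner indicates a
   community of predominantly rare lineages.
6. **Niche breadth and zoonotic risk**: lineages found in ≥ 3 hosts in
   multi-host plots are host *specific* if one species accounts for
   ≥ 90% of their positive hosts, otherwise host *opportunists*;
   per-community-richness summaries of candidate zoonotic lineages with
   two-sided exact binomial goodness-of-fit tests and Holm (sequential
   Bonferroni) correction.

A synthetic-study generator reproduces the sampling design these
analyses assume (34 plots split 13/14/7 across community types, nested
species sets, 35–353 sequences per sample, a long single-host tail, one
dominant host-preferring lineage, seeded reagent contaminants), with
ground-truth records so every stage is testable without the original
sequencing data.

## Worked example

```python
from hostmicro import (GeneratorParams, generate_study, filter_contaminants,
                       normalize_depth, build_units, aggregate_presence,
                       unit_diversity, compete_models, rank_occupancy,
                       zoonotic_summary)

data = generate_study(GeneratorParams(), seed=1)
filtered, report = filter_contaminants(data.counts, data.controls)
print(f"retained {len(filtered.lineage_ids)} of {len(data.counts.lineage_ids)} lineages")

norm = normalize_depth(filtered, target_depth="min", seed=1)
pres = norm.to_presence()
units = build_units(data.metadata, "community", "region")
agg = aggregate_presence(pres, units, counts=norm)
for d in unit_diversity(agg):
    print(f"{d.unit_id}: S={d.S} N={d.N} alpha={d.fisher_alpha:.1f}")

u3 = next(u for u in units if u.community_richness == 3)
curve = rank_occupancy(agg.occupancy[u3.unit_id], u3.n_hosts)
fits = compete_models(curve, multi_start=8, seed=1)
print(f"best RSOC model for three-species communities: {fits[0].model} "
      f"(Akaike weight {fits[0].akaike_weight:.2f})")
```

prints

```
retained 151 of 171 lineages
richness1: S=74 N=1394 alpha=16.7
richness2: S=72 N=1476 alpha=15.8
richness3: S=57 N=861 alpha=13.7
best RSOC model for three-species communities: exponential_concave (Akaike weight 0.63)
```

The filter discarded the 10 seeded reagent contaminants (high abundance
in every control, sporadic traces in blood) and 10 true lineages that
never reached 2% of any sample. `S` is the number of lineages detected
in each regional community, `N` the rarefied sequence total, and alpha
the log-series diversity parameter: comparable across communities
despite their very different host counts. The exponential-concave RSOC
winner says the three-species community is dominated by a single peak of
rare lineages rather than a bimodal common/rare mix.

The same run is available from the shell:

```bash
hostmicro simulate --seed 1 --out-dir sim/
hostmicro filter --counts sim/counts.tsv --controls sim/controls.tsv --out-dir out/
hostmicro run-all --config config.yaml --seed 1 --out-dir out/
```

`run-all` writes one machine-readable report per stage plus a
`manifest.json` recording the seed, per-stage derived seeds and every
resolved parameter; identical config + seed gives byte-identical
reports.

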