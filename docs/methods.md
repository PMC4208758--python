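# Methods

This note documents the statistical procedures implemented in
`hostmicro`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data generator does and does not emulate.

## Study design assumed by the pipeline

The pipeline analyzes a lineage-by-sample count matrix from blood
samples of hosts trapped in 1-ha plots, where each plot belongs to a
community-richness class (1, 2 or 3 host species) and the species sets
are nested: single-species plots hold *Gerbillus andersoni* (GA),
two-species plots add *G. pyramidum* (GP), three-species plots add
*G. gerbillus* (GG). One blood sample corresponds to one host
individual. Reagent-only negative controls are sequenced alongside the
samples.

## Contamination filtering

A lineage is retained iff

* (a) its relative abundance (count / sample total, computed on the raw,
  pre-rarefaction counts, because the rule refers to the composition of
  each sequenced sample) reaches `rel_abund_threshold` (default 0.02) in
  at least one blood sample, and
* (b) it is *higher in blood than in the controls*: if the lineage is
  detected in at least one control, a one-sided Mann–Whitney rank test
  compares its relative abundances in its positive blood samples against
  all control samples and must reject at `alpha` (default 0.05); a
  lineage with zero counts in every control satisfies (b) by definition.

Rationale for the positive-sample restriction and the absence rule: a
blood-borne lineage typically occupies few hosts (most lineages occur in
a single host individual), so pooling its many zero samples into the
rank test makes the two distributions nearly identical and the test
powerless regardless of effect size — under a pooled test no singleton
lineage could ever be retained, which contradicts the long singleton
tail such surveys report. Conversely a lineage absent from every
reagent control cannot be a reagent contaminant; the absence rule is the
natural limit of the rank test as the control counts go to zero. The
test is run by exact enumeration of the rank-sum permutation null
(midranks for ties) when the joint sample size is ≤ 12, and by the
tie-corrected normal approximation otherwise.

The filter is monotone in the threshold (lowering it can only add
retained lineages) and reports one row per input lineage with a reason
code (`below_2pct`, `not_above_controls`, `retained`).

## Depth normalization

Rarefaction without replacement: each sample is subsampled to exactly
`target_depth` sequences (default: the minimum sample total) with a
multivariate hypergeometric draw, seeded. Rows that become all-zero are
kept so the lineage axis never shifts; they are listed by the
transformer. Rarefaction is performed after filtering; Fisher's alpha is
computed from the rarefied totals (configurable by reordering the stages
in code, but the default is fixed and recorded in the run manifest).

## Aggregation grid

Presence/absence (not abundance) is aggregated, to limit the influence
of pyrosequencing abundance noise. Five organization-level × scale
combinations are supported; unit presence is the union of member
presences, and the per-lineage occupancy count (number of positive
member hosts) and rarefied sequence mass are carried with each unit.
Regional units are stratified by community-richness class — the regional
question is precisely the contrast of single- vs two- vs three-species
communities — and regional population units additionally by host
species. Union aggregation is associative, so regional units computed
from plot units equal those computed directly from individuals; the test
suite asserts this.

## Diversity and composition

**Fisher's alpha** solves `S = α·ln(1 + N/α)` by Brent root finding on a
bracketing interval, with the back-substitution residual required to be
below 1e-10. `S = 0` maps to 0, `S = N` to infinity with the
convergence flag cleared (the log-series has no finite parameter when
every sequence is distinct). Alpha is strictly increasing in S at fixed
N and strictly decreasing in N at fixed S.

**Binary Bray–Curtis** `(b+c)/(2a+b+c)` (equal to 1 − Sørensen, and to
the Dice dissimilarity) is used for all composition work. A pair of
empty units has no defined value and is reported as 0 with a warning so
matrices stay valid.

## Factorial effect tests

Both tests use sequential (type-I) sums of squares for host species,
host diversity, and their interaction, with percent variance explained
= term SS / total SS × 100 and p-values from permutation of unit labels
(all terms recomputed per permutation; exact enumeration of all n!
permutations when n ≤ 9 or on request).

* Univariate (Fisher's alpha response): term SS from orthonormalized
  design increments; equivalent to a Gaussian-identity linear model, but
  inference is permutation-based so no distributional claim is made.
* Multivariate (PERMANOVA): the dissimilarity matrix is Gower-centered
  (G = −½·JD²J) and each term's SS is the trace of its incremental
  projection applied to G, with pseudo-F = (SS_term/df_term) /
  (SS_res/df_res). Binary Bray–Curtis is semi-metric, so G can have
  negative eigenvalues and sequential SS can stray marginally outside
  [0, SS_total]; reported percentages are clamped to [0, 100] while F
  and p use the raw values. Permutations are free by default; a
  `strata` argument restricts them to within-stratum shuffles (e.g.,
  within plots) when the design calls for it.

Terms whose factor has a single observed level are skipped and listed.
Under an exchangeable null the type-I error at α = 0.05 is nominal
(checked by simulation in the acceptance suite).

## SIMPER

For each between-group pair of units, a lineage's contribution to that
pair's binary Bray–Curtis is its mismatch indicator divided by the
pair's (2a + b + c); only between-group pairs enter. Per-lineage mean
and SD over pairs, the mean/SD ratio, the descending cumulative
percentage (ties broken by lineage ID) and the ratio > 1 "good
discriminator" flag are reported. The per-lineage means sum exactly to
the mean between-group dissimilarity.

## Ranked Species Occupancy Curves

Prevalence Q_i = occupancy_i / n_hosts, ranked descending (ties by
lineage ID), zero-occupancy lineages excluded. Six forms are fitted by
bounded nonlinear least squares (`scipy.optimize.least_squares`, TRF)
with one data-driven start plus Latin-hypercube starts (default
`multi_start = 20`; the acceptance suite uses 3, which the recovery
experiments show is sufficient at n = 60):

| name | form | k |
|---|---|---|
| exponential_concave | Q = c + a·e^(−bR) | 3 |
| exponential_convex | Q = c + a·(1 − e^(−b(n+1−R))) | 3 |
| lognormal | Q = a·exp(−(ln R − b)²/(2c²)) | 3 |
| sigmoidal_symmetric | Q = a/(1 + e^((R−b)/c)) | 3 |
| sigmoidal_asymmetric | Q = a·exp(−e^((R−b)/c)) (Gompertz) | 3 |
| linear | Q = a − bR | 2 |

The asymmetric sigmoid is the decreasing Gompertz curve: a three-
coefficient asymmetric form that does not nest the symmetric logistic,
so the AICc contest between the two sigmoids is a genuine shape
comparison rather than a nested-model penalty race. Bounds keep the
amplitude and offset coefficients in [0, 1.5] (prevalences are
proportions) and rate/width coefficients positive.

Model comparison uses least-squares AICc with the error variance counted
as a parameter: AICc = n·ln(RSS/n) + 2k′ + 2k′(k′+1)/(n−k′−1),
k′ = k + 1. Akaike weights are location-invariant and sum to one. A
model whose every start fails is excluded and logged; a competition
needs at least two successful fits.

### Synthetic curves and the sorting caveat

`generate_rsoc_curve` returns f(R) + ε with ε ~ N(0, noise_sd), clipped
to [0, 1] and re-sorted non-increasing — matching how empirical RSOCs
are constructed (ranked order statistics). Sorting makes plateau noise
systematic: a flat stretch of the true curve becomes a shallow ramp that
flexible competitors fit better than the generating form. Parameter-
recovery experiments therefore use generating coefficients under which
the curve retains structure across all ranks (e.g. exponential-concave
decay rate b = 0.08 at n = 60 rather than a value that flattens after
rank ~15, and a lognormal peak inside the observed rank range so all
three coefficients are identified). Under those conditions the
generating model wins the six-way competition in ≥ 90% of 200 noisy
curves per form (noise SD 0.02, n = 60) with < 10% median relative
coefficient error.

## Niche breadth and zoonotic risk

Classification uses positive hosts in multi-host plots only (default):
lineages in fewer than `min_occupancy = 3` such hosts are unclassified;
otherwise host-specific iff the dominant species' share of positive
hosts is ≥ `threshold = 0.90`.

Risk summaries per community-richness class: lineages detected in the
class and the candidate-zoonotic subset (percentages rounded to the
nearest integer, the reporting convention of such surveys); hosts
carrying ≥ 1 candidate; mean ± SE (sample SD/√n) candidates per host.
Classes are compared with two-sided exact binomial goodness-of-fit
tests — summing the probabilities of all outcomes no more likely than
the observed one — against the proportion expected from a configurable
baseline class (default: the single-species class), Holm-corrected
within each test family. Both lineage-level and host-level families are
computed because the appropriate unit of comparison is a design
decision, not a statistical one.

## Synthetic-data generator

What it emulates: the 13/14/7 plot split; nested species sets; 1–4
hosts per plot (~90 samples); per-sample depths uniform on [35, 353];
a lineage pool of 161 with 80% singletons planted in one host each; one
dominant lineage with target overall prevalence 0.55 and 90% of its
occurrence mass on GA; common lineages split into host-specific
(off-host occurrence 200× lower, so their expected dominant share
clears the 90% rule even for the rarest host species) and opportunist
(independent uniform occurrence probabilities per species); 10 reagent
contaminants present in every control at high relative abundance and in
~10% of blood samples at trace abundance; ~8% of true lineages flagged
zoonotic, weighted 4:1 toward the singleton tail because published
candidate lists are dominated by rare lineages. Counts for the lineages
present in a sample follow a Dirichlet-multinomial (concentration 8 for
the dominant lineage, 1.5 for other true lineages, 0.3 for contaminant
carryover) with one guaranteed sequence per present lineage.

What it does not emulate: phylogenetic structure among lineages,
within-plot spatial structure (hosts in a plot are exchangeable),
temporal dynamics, PCR/chimera artifacts, and abundance correlations
between co-occurring lineages. Tests passing on these fixtures
demonstrate the statistical machinery and the filter's operating
characteristics under the stated occurrence model — not performance on
real amplicon data, whose contaminant profiles are messier.

Ground-truth records (role, niche class, zoonotic flag, per-species
occurrence probabilities) accompany every generated lineage; the filter
achieves sensitivity and specificity ≥ 0.9 against them at default
parameters, and the niche classifier recovers ≥ 90% of true classes for
lineages with ≥ 30 positive hosts.

## Determinism and provenance

All randomized stages consume seeds derived deterministically from one
top-level seed via `numpy.random.SeedSequence`. `run_pipeline` writes a
manifest (seed, derived stage seeds, package version, every resolved
parameter, table dimensions, rarefaction depth) and one report per
stage; identical config + seed yields byte-identical reports. Config
validation (unknown sections/parameters, missing seed, missing input
paths) happens before any computation.

## Problem sizes used in the test suites

The acceptance suite runs the PERMANOVA null calibration at 12 units ×
1,000 replicates × 99 permutations, RSOC recovery at 200 curves per
form with 3 starts per fit, and the end-to-end determinism check on a
13-plot synthetic study with 199 permutations — sizes chosen to exercise
the asymptotics that matter while keeping the full suite in the
few-minute range on one core.

## Known limitations

* The Mann–Whitney normal approximation (joint n > 12) is conservative
  for very sparse lineages; the exact branch covers the cases that
  matter for the retention decision.
* Sequential (type-I) SS make term order meaningful in unbalanced
  designs; host species is fitted before host diversity, matching the
  scientific priority of the factors.
* AICc absolute values depend on the error-variance convention
  (k′ = k + 1); weights and rankings are unaffected by any shared
  convention.
* The exact binomial baseline comparison treats the baseline proportion
  as known rather than estimated; with baseline denominators in the
  tens, this understates uncertainty slightly.
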