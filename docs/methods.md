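# Methods

This note records the models, assumptions, parameter choices and numerical
conventions behind `metaniche`, in the order the pipeline runs them.

## Constraint-based core

A metabolic model is a stoichiometric network with bounded reactions
(fluxes in mmol gDW⁻¹ h⁻¹), boundary exchange reactions that each touch a
single external metabolite, and a biomass reaction as objective. All bounds
live in [−1000, 1000]: reversible reactions span the full range, irreversible
ones start at 0. Uptake is negative exchange flux internally; the
`MediaSpec` interface exposes only uptake *magnitudes* to keep sign
conventions out of user code.

FBA solves `max v_biomass s.t. S v = 0, lb ≤ v ≤ ub` with HiGHS through
`scipy.optimize.linprog` at primal/dual tolerances of 1e-9, single-threaded
and with a fixed variable ordering, so repeated solves are bit-identical.
Growth is declared when μ > 1e-6. FBA has alternate optima in general; the
pinned solver configuration makes the *reported uptake fluxes* reproducible,
but users swapping solvers should expect class-limitation reference fluxes
(below) to shift within the optimal face.

**Replete media** caps every exchange's uptake at the flux bound (1000) —
the bound convention doubles as the "maximum flux" definition, since no
per-compound maxima are specified elsewhere.

**Minimal media** is a two-stage MILP (HiGHS through
`scipy.optimize.milp`): stage 1 minimizes the *number* of active imports
(binary indicator per exchange, big-M linking with M = 1000, growth
constrained to μ ≥ μ_target·(1 − 1e-6)); stage 2 fixes that cardinality and
minimizes total uptake flux. Minimizing the count rather than the flux sum
matches the minimal-media behavior of the COBRA tooling this emulates;
the flux tie-break removes the remaining degeneracy. On every toy network
with ≤ 10 exchanges the stage-1 cardinality equals an exhaustive 2^n subset
search (tested).

## Ensembles and consensus

An ensemble is a members × reactions binary presence matrix over the *union*
of member reaction sets — a reaction absent from every member is
unobservable from the ensemble file and is dropped before scoring, and the
consensus denominator R is the union size. The consensus score is the mean
over reactions of the fraction of members carrying each reaction; the
quality filter keeps genomes with C ≥ 0.8 (ties inclusive). Member models
are materialized by setting both bounds of absent reactions to zero — never
by deleting them — so all members share the base model's shape.

## Growth-sensitivity profiling

Per ensemble member: replete FBA → minimal media at the replete μ → one
limitation run per organic class. The limitation media caps each of the
class's minimal-media exchanges at f × its replete uptake (f = 0.5 default)
and *closes* the class's other exchanges, so the model cannot dodge the
limitation through an unused isomer; every other exchange stays fully open.
The statistic S = (1/f)(1 − μ_n/μ) is clipped to [0, 1]: small negative
values arise from LP tolerance, and values above 1 can arise when a class
gates an essential cofactor (μ_n < (1−f)μ); both are collapsed to the
statistic's defined range. Caps are per-compound; an aggregate class-level
cap is a conceivable alternative reading and could be added behind the same
interface, but the per-compound rule is the one implemented and tested.

Inorganics and "other" compounds are never limited and never profiled, but
their exchanges stay open at replete caps during limitation runs.

Members with zero replete growth are recorded as failed and excluded. A
genome whose 60-member profiles have cumulative across-member population
variance (summed over the 11 classes) above 0.1 is excluded before
clustering as unstable.

## Synthetic data

The generators produce every input the pipeline consumes, with the
structure the analysis assumes:

* **Toy networks.** Each substrate gets an exchange → transport →
  conversion chain. Non-limiting classes convert into one shared carbon
  pool (interchangeable, emulating organisms that substitute metabolites);
  each limiting class converts into a class-specific biomass precursor
  required at a small stoichiometry (0.01 per unit biomass by default), so
  the class is irreplaceable. Per-substrate capacity lives on the transport
  reaction; exchanges keep the ±1000 convention. A `biomass_cap` below
  total supply creates the slack that makes a network a generalist (S ≈ 0
  everywhere).
* **Ensemble dropout.** Each non-core reaction is independently absent with
  a given probability per member; biomass and exchanges are always kept.
  Expected consensus is then a mixture of core (1.0) and non-core (1 −
  dropout) columns — used to test the quality gate.
* **Archetype profiles.** Eight niche archetypes mirror the bundled
  reference clusters: limiting classes pinned at S = 0.9, the remaining
  classes sharing the rest so the 11-class mean equals the published
  per-cluster mean (all rows land in [0, 1]). The published table prints
  only the cluster mean and the limiting classes, so this even spread is
  this package's reconstruction, not a published vector. Member noise is
  Gaussian clipped to [0, 1] (no within-ensemble noise distribution is
  published; clipping preserves the statistic's range), default sd 0.02 —
  cumulative 11-class variance ≈ 11·0.02² ≈ 0.004, the order of magnitude
  reported for real high-quality ensembles.
* **Tables.** dCUB values are Gaussian around archetype means; abundance
  tables are lognormal per-genome baselines times region × cluster
  enrichment factors; growth matrices replicate a reference toy network's
  true sole-substrate capabilities (computed by FBA) with a configurable
  bit-flip error rate.
* One global seed fans out to per-generator streams via
  `numpy.random.SeedSequence.spawn`, so adding a generator does not perturb
  the draws of existing ones.

What the generators do **not** emulate: annotation error processes, genome
incompleteness, correlated reaction dropout, compositional noise in read
recruitment, or real chemical diversity within compound classes. Passing
recovery tests therefore shows the pipeline is correct and well-calibrated
under its own assumptions, not that real marine data will cluster as
cleanly.

## SOM and clustering

Online Kohonen training on a 20×20 toroidal hexagonal grid: 1500 iterations,
every entry visited per iteration in a fresh seeded permutation, learning
rate decaying linearly 0.025 → 0.01. The neighborhood is a bubble (uniform
within radius) with radius decaying linearly from one-third of the grid
diagonal to 1 — the exact kernel and schedule are not published, so this
follows the common default of classic SOM implementations and is recorded
here as an assumption. Grid height must be even for hexagonal row parity to
close around the torus; inter-node distances are minima over the nine wrap
images of plain Euclidean distances on the offset hex lattice. Codebooks
initialize uniformly within each feature's data range. Profiles enter
unscaled (S is already in [0, 1]); a standardization switch exists but
defaults off. The training inner loop is JIT-compiled with numba, with a
pure-numpy fallback.

Nodes are partitioned by k-means (k = 8 default, 25 seeded restarts,
k-means++ seeding, via scikit-learn); the elbow diagnostic (mean
intracluster distance over a k range) is exposed. Genomes take the cluster
with the plurality of member BMUs; exact ties go to the lowest cluster
index and flag the genome ambiguous. Stability is measured as pairwise ARI
across independently seeded SOM + k-means runs against a random-label
baseline.

## Growth-strategy statistics

dCUB (difference in codon usage bias, ribosomal proteins vs genome
background) proxies maximal growth: more negative = faster, reliable only
below −0.08, so `fast` means dcub strictly below −0.08. Cluster dCUB
distributions are compared with two-sided rank-sum tests
(`scipy.stats.mannwhitneyu`, exact for small samples, normal approximation
with continuity correction otherwise) under Bonferroni correction with the
pair count as factor — Bonferroni rather than Holm for comparability with
the published analysis. The fast-grower bootstrap resamples 185 genomes
(the mean cluster size) from the pooled dCUB values 10,000 times and labels
each cluster below/within/above the null mean ± 2 SD. Composite labels
such as "slow-intermediate" follow from which reference clusters a cluster
is statistically indistinguishable from; the exact decision table is not
published, so the package reports the pairwise test matrix and leaves the
label mapping to configuration. Cluster-level mean sensitivity is regressed
on mean dCUB by OLS with adjusted R² = 1 − (1−R²)(n−1)/(n−2).

## Validation protocol

Sole-carbon media: the target substrate's exchange at cap 10, all other
organic exchanges closed, inorganic/"other" exchanges (the non-carbon
essentials) fully open — the published protocol names no caps, so these
mirror the common single-carbon-source convention. The ensemble call is
no-growth only if *no* member grows and growth if more than half do;
fractions in (0, 0.5] are an explicit `indeterminate` class, excluded from
accuracy by default (configurable), since the published rule leaves that
gap open. Disagreements are retried with every 1- then 2-subset of the
rescue pool, in deterministic sorted order, at trace caps (< 1% of the flux
bound; default 0.5%); the first subset restoring agreement yields category
ii. The iii/iv split uses topological reachability from the substrate's
external metabolite to any biomass precursor over the member's non-zeroed
reactions (both directions for reversible reactions), in a majority of
members — stoichiometric feasibility is deliberately ignored because the
split only needs evidence that the pathway is annotated. Confounded
substrates (e.g. chemically unstable ones) can be excluded by name before
scoring. The permutation null redistributes each strain's positive
substrates uniformly (row sums preserved exactly), scores each permuted
matrix against the observed data, and declares the real accuracy
significant above the null mean + 2 SD.

## Biogeography

Site × genome RPKM values are summed by cluster and normalized per site;
zero-total sites are flagged and excluded. Bootstrap recruitment draws
10,000 values with replacement *independently per (region × cluster) pool*
(the joint-draw reading of the procedure is possible but not what the text
describes) for 1000 iterations with fixed seed 123 by default; means and
percentile 2.5/97.5 intervals are reported. Dissimilarity is Bray-Curtis;
regional dendrograms use McQuitty (WPGMA) linkage.

NMDS is implemented directly (Kruskal stress-1, isotonic regression of
embedding distances on the dissimilarity rank order, Guttman-transform
majorization) so ordination is dependency-light and seed-deterministic.
The first restart starts from the classical-MDS configuration; further
restarts (default 4 total) are random, and a later restart must beat the
incumbent stress by 1e-4 — this tie-break guards against the classic
degenerate NMDS solution in which well-separated groups collapse to a
point at numerically zero stress. Environmental ecotypes standardize the
(incommensurable) environmental variables, ordinate, k-means the embedding
(k = 3 default) and return per-ecotype convex hulls; sites with missing
metadata are labeled "Other".

## Pipeline sizes and determinism

The end-to-end synthetic study in the CLI defaults to 8 clusters × 8
genomes × 12 members with a 10×10 SOM at 150 iterations, and scaled-down
bootstrap counts — sizes chosen so a full demonstration run finishes in
seconds while every stage exercises the same code paths as the full-size
configuration. The acceptance suite runs the full-size recovery experiment
(20×20 grid, 1500 iterations, 60 members, ~100 genomes). Every stochastic
stage takes an explicit seed; re-running a stage with an identical config
reproduces identical artifacts.

## Known limitations

* The toy networks have linear yield structure; real GEMs have cofactor
  coupling, maintenance ATP and redox constraints that can make S exceed 1
  before clipping far more often.
* The SOM neighborhood kernel/schedule is an assumption (see above), so
  absolute quantization errors are not comparable with other SOM software,
  though cluster recovery is robust to the choice in the tested regimes.
* Composite growth-strategy labels are configuration, not a published rule.
* The validation bench demonstrates the protocol on synthetic matrices; it
  does not reproduce published accuracy figures, which require external
  genomes and reconstructions.
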