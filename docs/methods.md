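# Methods

## The diagnostic model

The package operationalises a fixed-difference SNP diagnostic for a
population complex. A locus is *diagnostic within a scope S of groups* when
every group in S is 100% homozygous-fixed at the locus (among non-missing
calls, with a per-group call rate of at least `min_call_rate`) and the two
fixed alleles split S into two nonempty sides. Fixation is strict by design:
the markers this class of assay is built on are strict fixed differences in
the design cohort, and a single heterozygous or third-allele call demotes
the group to "mixed". `min_call_rate` (default 0.8) is exposed because no
published tolerance exists; missingness does not otherwise affect fixation.

Scope-restricted markers are first-class: a locus may be diagnostic within
{SSA-ECA, SSA-WA} while carrying mixed alleles elsewhere, so the search is
run per scope (full scope, then within subsets), mirroring the two-stage
manual search such panels come from.

### Decision tree

`build_decision_tree` is a greedy recursive key: at each node, among markers
whose scope covers the current group set and whose partition splits it,
choose the most balanced split; ties are broken by position in the input
marker list, and a specific root can be pinned. Markers inducing the *same*
split at a node are attached as confirmation/fallback markers rather than
new nodes. With the seven canonical markers listed in their published table
order this reproduces the published flow chart exactly: the species-gateway
marker BTS99-319 at the root ({SSA-ECA, SSA-WA} vs the rest), BTS22-762
splitting SSA-ECA/SSA-WA, BTS141 splitting {SSA2, SSA4} from
{SSA-ESA, SSA-CA} with BTS613 as confirmation, BTS55-473 isolating SSA2,
and BTS46-203 splitting SSA-ESA/SSA-CA with BTS1161 as fallback. A
lexicographic tie-break would instead place BTS141 at the root, so list
order is the documented rule. The exact branch order among the markers on
the non-{SSA-ECA, SSA-WA} side is this package's reconstruction of the
published flow; the packaged panel JSON flags it as such.

### Classification semantics

Walking the tree, only decisive homozygous states (XX/YY) choose a branch.
A heterozygous or failed call at a node falls through to that node's
confirmation/fallback markers (flag `used_fallback`); if none is decisive
the sample is `unresolved` with `missing_marker` (call absent/failed) or
`inconsistent_profile` (heterozygous at a marker where the panel admits
only homozygotes). A decisive confirmation call contradicting the primary
branch yields `confirmation_discordant` + unresolved — a heterozygous
sample is treated as a mismatch, never forced into a genotype class. The
species gateway is a PCR-product presence observation: an explicit
`amplified=False` flag, or failing that a profile with no successful call
at any marker, classifies as `non-target`.

## Endpoint caller

No algorithm is published for the visual "distinct clusters only" scoring
this replaces, so the caller is a deterministic, auditable analogue with
declared defaults (not values inferred from any dataset):

* normalisation: signal = max(0, post-read − pre-read) per dye;
* polar geometry: theta in degrees from the FAM (allele X) axis toward the
  HEX (allele Y) axis; magnitude = Euclidean norm;
* NTC gate: sample wells with magnitude ≤ `ntc_factor` × (NTC mean +
  `ntc_sd_mult` × NTC SD) are `no_call("low signal")`; defaults 2.0 and 3.
  Zero NTC wells is an error unless NTC-free mode is enabled (then an
  absolute floor applies — the only scale-dependent threshold in the
  caller);
* state bands: XX [0°, 30°), XY [30°, 60°], YY (60°, 90°]. Absolute bands
  rather than cluster ranks, so plates containing only one or two genotype
  classes (common in practice) are still called correctly; the
  heterozygous band is symmetric about 45° because dual-dye incorporation
  yields intermediate signal;
* cluster-quality gate: thetas of gate-passing wells are k-means-clustered
  in 1-D with k ∈ {1, 2, 3}; k ≥ 2 is accepted when its mean silhouette
  reaches `split_silhouette` (0.6), otherwise the wells form one cluster
  whose per-well quality decays linearly with distance from the cluster
  mean (0 at 45° away). Wells with silhouette below `quality_threshold`
  (0.5), or within `band_margin` (5°) of a band boundary while their
  cluster mean lies in a different band, are `no_call("ambiguous
  cluster")`. k-means is initialised at theta quantiles, making calls
  independent of well order.

All thresholds but the NTC-free floor are relative, so calls are invariant
to rescaling all fluorescence by a positive constant. The safety property
this buys (verified in the test suite over 20 seeds per noise level): as
simulation noise grows, errors appear as no-calls before miscalls —
no-calls dominate wrong calls at every noise level and wrong calls remain
essentially zero while noise ≤ 10% of cluster magnitude. Note that *any*
caller that emits calls at all will make some confident wrong calls under
extreme noise; the guarantee is dominance, not absolute monotonicity.

## Synthetic data: what it emulates and what it does not

`simulate_genotype_matrix` plants diagnostic loci (in-scope groups exactly
homozygous for their side's allele; out-of-scope samples uniform over
{XX, XY, YY}) among background loci drawn from a shared per-locus
Hardy-Weinberg frequency (uniform 0.05–0.95), so background loci carry no
group signal. Observation noise: `missing_rate` masks observed calls
(sequencing dropout — the underlying DNA keeps its genotype, so simulated
plates are driven by the biological truth, not the masked matrix);
`het_rate` perturbs the biological genotype at in-scope diagnostic loci
and is reflected in the truth; `apply_allelic_dropout` converts
heterozygotes to random homozygotes, emulating allele loss at low read
depth. Defaults are the design-cohort conditions: group sizes
60/52/33/10/50/12 (217 samples), 100 background loci, `missing_rate` 0.02,
`het_rate` 0 (the canonical markers are strict fixed differences in their
cohort), dropout 0. Within-group heterozygosity and missingness of the
real genome-wide matrix are unpublished, so these are free parameters, not
estimates.

`simulate_plate` places sample wells on their true state's polar ray
(defaults 10°/45°/80°, magnitude lognormal around 1000 units with sigma
0.15) plus Gaussian axis noise (default SD 50 = 5% of magnitude); NTCs sit
near the origin at ~5% of sample magnitude; failed amplifications are
rendered as NTC-level signal; the pre-read baseline is 5% of the post-read
(pre-reads exist for background subtraction but no values are published —
the fraction is a modelling choice). One 96-well plate per marker with 2
NTCs, overflowing to further plates as needed.

What passing tests on these simulations show: the discovery code is exact
(it matches a brute-force oracle), the tree resolves what the markers can
resolve, and the caller meets its recovery/withholding targets under
Gaussian-plus-lognormal cluster noise. What they do not show: robustness to
real-plate pathologies the generator does not model — dye cross-talk,
plate-edge effects, curved cluster arms, template-quality gradients — nor
the field accuracy of the canonical panel, which is why the published
152-sample validation counts are packaged and recomputed separately.

## Concordance and rounding

Percentages are rounded half-away-from-zero to one decimal (decimal
arithmetic, no binary-float artefacts); this rule reproduces every
percentage printed in the original validation tables from their printed
counts (99.3 = 151/152, 98.6 = 72/73, 95.1 = 39/41, 80.5 = 33/41,
18.4 = 28/152). Heterozygous KASP calls against a homozygous reference
count as mismatches. The confusion matrix tallies unresolved/non-target in
separate columns; overall concordance is trace/total over named
assignments.

COI misidentification uses a nominal one-to-one label map
(SSA1-SG1→SSA-ECA, SSA1-SG3→SSA-ESA, SSA1-SG5→SSA-WA, SSA2→SSA2,
SSA4→SSA4; overridable). Labels outside the map (SSA1-SG2, SSA1-SG1/SG2,
SSA3) identify no genome-wide haplogroup and therefore count toward the
misidentified total, flagged "unmappable" in the breakdown; blank/unknown
labels are excluded from the count but stay in the denominator. This is a
deliberate design choice: the published mismatch categories are not
reproducible from the many-to-one "comprises" relation alone (labels like
SSA3 occur inside groups they do not name), and the strict nominal map is
the reading consistent with all seven published categories.

The packaged 152-sample validation data are summary *counts*; per-sample
records expanded from them are synthetic (ids invented; countries attached
only to mismatching samples, per the published mismatch-origin columns;
the two concordant SSA-CA samples carry an "unknown" COI label because no
per-sample appendix is packaged).

## Numerical and degenerate-input choices

* Genotypes are unordered nucleotide pairs ("A/G" ≡ "G/A"), "./." missing;
  published "A:A" notation is accepted on input. Coordinates are 1-based
  inclusive.
* Allele X of a discovered marker is the locus reference allele when the
  reference allele is fixed in some group, else the alphabetically first
  fixed allele; alleles are kept as given on the plus strand, with no
  reverse-complement normalisation (the canonical BTS1161 marker stores
  its reference-sequencing allele labels as separate metadata because they
  differ from the KASP allele space and no conversion is published).
* Marker coordinates in the packaged panel are inferred from the published
  amplicon range start plus the trailing number in the marker id
  (consistent for six of seven markers; BTS1161's offset exceeds its
  printed range and is flagged unverified). They are metadata only.
* theta of a (0, 0) well is undefined (NaN) and reserved for no_call.
* Submission windows cover `window` bases counting the variant once
  ((window−1)//2 left context); truncation by contig ends emits a warning.
* Simulations are reproducible from a single integer seed
  (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs.

## Problem sizes

The test suite and the acceptance script run at desk scale by construction:
217-sample × 107-locus cohorts for discovery, 1,000 wells for caller
recovery, 100 random 12 × 30 matrices for oracle equivalence, 20 seeds per
noise level for the safety property. The full suite and the acceptance
script each complete in seconds on one CPU.

## Known limitations

* No primer/oligo thermodynamic design; vendor primer sequences ship as
  inert metadata.
* Endpoint reads only — no amplification curves, no dye spectral
  deconvolution.
* The classifier is a deterministic key; no probabilistic assignment.
* The caller's thresholds are declared defaults, not fitted to instrument
  data; labs with unusual cluster geometry should recalibrate the bands.
* The published "721 tests" pooled per-marker total is not decomposable
  from the printed per-marker counts; the report prints pooled and
  per-marker totals without asserting their composition.
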