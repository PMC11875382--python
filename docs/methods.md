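# Methods

This note records the models implemented in `fawkit`, the parameter choices
that matter, what the synthetic-data generators do and do not emulate, and
the numerical decisions taken where the underlying methods left room.

## Marker typing

### COI CSh classification

The CSh classes are defined by the allele pair at two mitochondrial sites:
A·A → CSh1, A·G → CSh2, G·A → CSh3, G·G → CSh4, and T·A diagnostic of the
R-strain. The classifier is total over IUPAC input: the T·G configuration
has never been assigned a class, and any ambiguity code at either site makes
the call impossible, so both return `undetermined` rather than guessing.
CSh3 stays in the label universe even when absent from a survey, so profiles
remain comparable across studies.

### Site location by flanks, not coordinates

Marker site names (mCOI1164D, gTpi183Y, …) are assay-relative labels; no
genome coordinate system ships with the assays. Sites are therefore located
by unique 15-mer flanking sequences with exactly one bracketed base. This
makes typing robust to indels outside the flanks and portable to drop-in
reference sequences: building a `MarkerConfig` from any reference amplicon
re-derives the flanks. A consequence is that the synthetic *Tpi* exon spaces
its three SNP sites ≥ 20 bp apart — two of the named sites are only 3 bp
apart in the real assay, too close for independent flanks once both are
polymorphic, and nothing downstream depends on the spacing.

### Strain call from *Tpi*

The gTpi183Y exon site carries the strain signal: C → C-strain,
T → R-strain by default (the convention of the companion reference sets;
overridable in `MarkerConfig.tpi_strain_map`). A `Y` is a potential
interstrain heterozygote and returns `undetermined`. The neighbouring sites
gTpi165Y and gTpi168Y are read and reported but do not affect the call;
`strict_tpi=True` additionally requires 2-of-3 concordance.

### Heterozygote exclusion

*Tpi* is Z-linked, so males (ZZ) carry two copies. Direct Sanger sequencing
of a heterozygote superimposes both alleles: substitution differences appear
as IUPAC ambiguity codes, and a length (indel) difference collapses the
chromatogram from the first discordant position. Both forms are modelled and
both are excluded: any ambiguity code inside the TpiI4a200 segment flags the
read (`heterozygous`), and a collapsed read fails intron extraction
(`truncated`). Restricting analysis to the first 60% of the intron
(`TpiI4a200`, segment = first ⌊0.6 × intron length⌋ bases) reduces the
chance that downstream-only heterozygosity invalidates a read.

### Haplotype identity

Haplotypes are exact string matches over the anchored TpiI4a200 window — no
alignment, because every segment starts at the same splice donor, and
length-discordant segments are by definition distinct haplotypes. Segments
matching a reference entry take its published-style label; new sequences get
`novel-k` in discovery order.

## Profiles and homogeneity testing

A profile is the count vector over a declared label universe (zeros kept).
Pooling is count-wise, so pooled n is the sum of member n and every pooled
frequency lies within the member range.

Surveys of this kind usually present profiles descriptively. As the minimal
quantitative backing for "profiles differ" statements the package uses a
Monte-Carlo chi-square homogeneity test: Pearson X² on the 2×K table,
with the null distribution generated by redrawing both collections (at their
observed sizes) from the pooled frequencies, and the add-one correction
p = (1 + #{X²\* ≥ X²})/(B + 1) so p is never 0 and remains valid for small
counts and zero cells, where the asymptotic χ² reference is not. The test's
type-I error is verified by simulation (2000 null pairs of n = 50) to sit
inside 0.05 ± 0.02 at α = 0.05. An exact-conditional alternative
(`fisher_exact_2xk`) uses scipy's exact 2×2 test for two labels and a
fixed-margin Monte-Carlo version of the probability-ordering test for K > 2.

## Phylogenetic strain grouping

The reference workflow for this marker runs a likelihood tree search inside
a commercial GUI; the only conclusion drawn from the tree is membership in
one of two strain clades. This package instead uses deterministic,
closed-form components that reproduce that two-group classification:

* **Alignment** — center-star progressive alignment: the center sequence
  minimizes summed pairwise distance (ties by label); every other sequence
  is globally aligned to it (match +1, mismatch −1, gap open −4, extend −1)
  and merged under once-a-gap-always-a-gap. The result is independent of
  input order. For ~200 bp anchored haplotypes with sparse indels this is
  equivalent in practice to a guide-tree progressive aligner at a fraction
  of the complexity.
* **Distances** — p, JC69 (−¾ ln(1 − 4p/3)) and TN93 closed forms, with
  pairwise deletion of gap/ambiguity columns (the intron has frequent
  indels; complete deletion would discard most of the signal). TN93 stands
  in for maximum-composite-likelihood distances; the two agree closely at
  the divergences involved here (≪ 0.1 substitutions/site). All three
  models are verified against `ape::dist.dna` reference values. Saturated
  pairs are capped at 5.0 substitutions/site and flagged.
* **Neighbor joining** — canonical Q-criterion NJ. Ties in the Q minimum
  break by lexicographically smallest subtree label pair; negative branch
  lengths are clamped to zero with the deficit transferred to the sibling
  edge, preserving the joined pair's path length. On additive matrices the
  generating topology and branch lengths are recovered exactly (property-
  tested over random 5–8 taxon trees, and cross-checked against
  scikit-bio's independent NJ).
* **Bootstrap** — B column resamples (default 100); support of an internal
  bipartition of the optimal tree is the percentage of replicate trees
  containing it. Internal edges of ~zero length are collapsed first, so an
  alignment of identical sequences yields a star tree with no resolved
  bipartitions rather than arbitrary zero-length structure.
* **Strain assignment** — k-nearest-reference vote (default k = 1) by model
  distance after aligning the query with the full reference set; a split
  vote or an exact distance tie returns `unassigned`, and the distances to
  the nearest C and R references are always reported so that discordant
  cases (e.g. an exon-C haplotype grouping with the R clade) surface rather
  than disappear.

## Climate suitability engine

A Compare-Locations style index model on a 52-week year (7-day blocks;
day 365 discarded). Weekly mean temperature is (Tmin + Tmax)/2; no diurnal
interpolation is attempted since inputs carry no sub-weekly detail.

Parameters (fall armyworm preset): temperature thresholds DV0–DV3 =
12/25/30/36 °C; soil moisture thresholds SM0–SM3 = 0.15/0.8/1.5/2.0
(fractions of bucket capacity); stress thresholds/rates TTHS = 39 °C with
0.0025 wk⁻¹, cold rate 0.005 wk⁻¹, SMDS = 0.1 with 0.005 wk⁻¹, SMWS = 3
with 0.002 wk⁻¹; PDD = 400 °C·days per generation; top-up irrigation
2.5 mm/day in weeks with under 25 mm of rain. Published rate signs
(negative for cold/dry) are treated as magnitudes applied in the
stress-increasing direction. The published cold-stress temperature
threshold prints implausibly (98 °C); `ClimexParams` therefore has **no
default** for `ttcs` — the `FAW_PARAMS` preset reads it as 9.8 °C (a
decimal-point slip), and a `degree_day` cold-stress mode is available for
the alternative reading (threshold in °C·days/week).

Component contracts:

* TI and MI are trapezoids over their four thresholds (0 outside, linear
  shoulders, 1 on the optimal plateau).
* Soil moisture is a single bucket (default capacity 100 mm):
  SM′ = clamp(SM + (effective rain − evaporation)/capacity, 0, SM3), with
  evaporation = `evap_coefficient` × max(weekly mean T, 0) mm/week. The
  coefficient defaults to 0.6 so that the 17.5 mm/week irrigation top-up is
  materially meaningful; commercial hydrology is proprietary and this
  bucket is this package's model choice, not a published fact. One spin-up
  year removes initial-condition artifacts. *Caveat:* because the bucket
  has no drainage term, additive irrigation in already-wet weeks can push
  SM past the SM2 optimum and reduce MI — irrigation is guaranteed to help
  only while moisture remains at or below the optimal plateau (it strictly
  rescues the arid regime, which is the scenario it exists for).
* GI_w = TI_w × MI_w; GI_A = 100 × mean(GI_w).
* Stress: weekly exceedance of the threshold (below/above), weighted by
  weeks elapsed (stress compounds as the season runs), times the rate
  magnitude, summed, scaled by `stress_display_scale` (100) to the 0–1000
  display range and capped at 1000. Zero iff the threshold is never
  crossed. An exponential-accumulation variant was considered and not
  implemented: the linear-cumulative form is the one whose display scale
  the published maps use.
* Degree-days: Σ max(0, T − DV0) × 7 over 52 weeks.
* EI = GI_A × Π(1 − Sᵢ/1000), zero when annual degree-days < PDD, clamped
  to [0, 100]. The combination formula is not published; the multiplicative
  form is fixed here as a documented contract. It guarantees EI ≤ GI_A and
  EI = 0 at any capped stress.

Grids run per-cell with no spatial smoothing.

## Dispersal trajectory projector

A kinematic stand-in for a full Lagrangian atmospheric model, keeping only
what the single-night analyses use: one deterministic trajectory per night,
12 h from dusk (19:00 local solar time by default — "dusk" is not defined
numerically anywhere authoritative), altitude held at the 500 m AGL start
level and capped at 1500 m AGL. Integration is explicit midpoint (RK2) with
bilinear spatial and linear temporal interpolation, on a flat-earth local
tangent plane (trajectories span < 500 km, where the distortion is far
below grid resolution); reported displacements and bearings use great-circle
formulas with Earth radius 6371 km. Trajectories terminate early, flagged,
on leaving the wind grid. Consecutive-night flights are deliberately not
chained.

Ensembles reduce to an occupancy grid over the wind-grid cells: a cell is
entered if any path segment intersects it (segments super-sampled at half
the grid spacing), and its frequency is the percentage of nights entering
it; the source cell is always 100. Directionality is summarized by the
circular mean and resultant length R of endpoint bearings — uniform strong
winds give R near 1 (a directional corridor), isotropic nightly scatter
gives R near 0 (localized dispersal) — and the mean great-circle
displacement. Endpoints coincident with the source have undefined bearing
and are excluded from the circular statistics.

## Synthetic data: what it does and does not emulate

The generators exist because none of the three data streams behind studies
of this kind (specimen sequences, 10′ climatology, wind reanalysis) are
publicly deposited.

* **Sequences** — reference COI/Tpi amplicons are random backbones with the
  published primer sites at the ends and marker sites at known offsets
  (flanks verified unique at build time); the TpiI4a200 library holds 13
  C-strain variants under the field's haplotype nomenclature plus a
  12-substitution-diverged R-strain clade. Specimens are multinomial draws
  from specified haplotype frequencies; heterozygotes merge two intron
  alleles into IUPAC codes or truncate at a length discordance. Emulated:
  marker topology, strain structure, Z-linked heterozygosity, chromatogram
  collapse. Not emulated: base-calling error, real divergence patterns,
  chromatograms themselves (input is base-called sequence only). Tests
  passing on this material validate the pipeline's logic, not the wet-lab
  assay.
* **Climate** — four regimes (incubator 27 °C/optimal moisture; cold 5 °C;
  arid zero-rain; seasonal sinusoid ±10 °C with seeded noise and rainfall
  sized to keep the bucket mid-range) plus a south-warm/north-cold gradient
  grid for qualitative map structure. No real climatology, no 10′
  resolution, no inter-annual variability.
* **Wind** — uniform, solid-body rotational, and per-night von Mises
  bearing scatter (concentration κ) around a seasonal mean. Bearing is the
  direction blown *toward* (90° → u > 0). No vertical structure, no
  boundary-layer physics, no reanalysis formats.

All randomness flows from one explicit seed per call; identical spec + seed
reproduces byte-identical output.

## Problem sizes used in the test suite

Round-trip typing runs at n = 1000 specimens; the homogeneity test's
type-I calibration uses 2000 simulated null pairs at 999 resamples each;
NJ recovery is property-tested over random 5–8 taxon trees; bootstrap runs
at B = 100 on 8-per-clade alignments of length 200; trajectory properties
use 12-h flights at a 10-minute step on ~33 × 37 grids. These sizes give
stable statistical verdicts for every contract while keeping the full suite
in the tens of seconds.

## Known limitations

* The soil-moisture bucket and EI combination are fixed contracts, not
  reproductions of the commercial model; absolute EI values should not be
  compared against commercial output, only the qualitative geography.
* TN93 is an approximation to maximum-composite-likelihood distances;
  differences are negligible below ~0.1 substitutions/site but grow with
  divergence.
* Heterozygote phase is never resolved (real surveys discard such reads;
  so does the pipeline), which biases haplotype tables toward homozygotes
  if heterozygosity correlates with haplotype — a limitation inherited
  from the assay design.
* The trajectory model ignores insect airspeed, flight layering and
  vertical wind; it measures what wind alone would do to a passive flyer
  in the stated altitude band.
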