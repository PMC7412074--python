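# Methods

This note documents the statistical and geometric procedures implemented in
clonescape, the assumptions behind them, the defaults and why they were
chosen, and the limits of what the synthetic test bed can demonstrate.

## Data model

A sampling unit is one ramet: an id, planar coordinates in metres (an
internal Cartesian frame, ~5 cm precision is typical of tape-measure
geocoding), a patch label, and a diploid genotype at `L` codominant loci.
Allele labels are opaque positive integers (fragment sizes scored
upstream); no binning is performed. Missing calls are allowed and encoded
as 0/empty in files; a unit missing any locus is excluded from clone
discrimination and flagged on the results, because a partial genotype
cannot be placed in an exact-identity partition without an arbitrary
matching rule.

## Clone discrimination

The pairwise distance between two genotypes is the allelic mismatch count:
per locus `2 − |multiset intersection|` of the two allele pairs, summed
over loci (range 0..2L). Units are grouped by single linkage over pairs
with mismatch ≤ t. The default threshold is **t = 0** (exact MLGs):
merging at t ≥ 1 is only warranted when the mismatch histogram shows a
clear gap attributable to somatic mutation or scoring error, and the
histogram is produced precisely so the analyst can make that call. MLG ids
are assigned by first occurrence after lexicographic sort of sample ids,
making the labelling independent of row order.

`Pgen` multiplies per-locus genotype probabilities (`p²` homozygous, `2pq`
heterozygous under HWE; `p² + p(1−p)F_IS` and `2pq(1−F_IS)` under a stated
departure). With a negative fitted `F_IS` the homozygote form can go
(slightly) negative for rare alleles; per-locus terms are clamped to
[0, 1]. `Psex` is the binomial tail `P(X ≥ n)` with `X ~ Binomial(N,
Pgen)` — the "at least n occurrences" convention. Both default to
round-robin allele frequencies: for each locus, genotypes are identified
from the other loci, and one observation per such genotype enters the
frequency count at the focal locus. This clone-censors the estimate
without using the focal locus to define the clones, avoiding circularity.
The multilocus `F_IS` used for the `(F_IS)` variants is
`(mean He − mean Ho)/mean He` over loci on the censored data.

## Clonal diversity

Per-locus statistics are computed on one representative per MLG. `He` is
the uncorrected gene diversity `1 − Σp²` (no small-sample correction);
this choice makes the identity `F_IS = (He − Ho)/He` reproduce, within
rounding, the published per-locus tables this package was checked against.
PIC follows Botstein: `1 − Σpᵢ² − Σ_{i<j} 2pᵢ²pⱼ²`. A monomorphic locus
reports `He = 0` and `F_IS = NaN` with a warning.

Genotypic richness is `R = (G − 1)/(N − 1)`; equitability `E_H` is the
Shannon evenness of clone sizes, defined as 0 for a single genet (the
natural limit of the verbal definition, though `ln S = 0` there). The
Pareto slope β is the negated OLS slope of `log N(≥X)` on `log X` over
the distinct observed clone sizes — the cumulative form, unweighted;
weighting by class counts and dropping the largest class are exposed as
options since the literature is not uniform on this. The clonal subrange
is the maximum clonemate-to-clonemate distance, 0 (with a warning) when
no MLG repeats.

## Spatial structure

The aggregation index compares `Psp`, the observed fraction of units whose
nearest neighbour is a clonemate, with `Psg = Σ n_g(n_g−1) / (N(N−1))`,
the probability that two random distinct units are clonemates:
`Ac = (Psp − Psg)/(1 − Psg)`, 0 under random placement, 1 at full
aggregation. Nearest-neighbour ties break to the smallest sample id.
Significance comes from permuting spatial positions among units, which is
implemented as permuting genotype labels over the fixed nearest-neighbour
graph — the two are the same null, and the graph need only be built once.

The Loiselle kinship estimator is

    F_ij = Σ_l Σ_a (x_ia − p_a)(x_ja − p_a) / Σ_l Σ_a p_a(1 − p_a) + 1/(n−1)

with `x_ia ∈ {0, ½, 1}` the within-individual allele frequency and `p_a`
the reference frequency; the additive term corrects the bias from
estimating `p` on the sample itself. Profiles are built over distance
classes holding equal pair counts (differing by at most one), the
convention that keeps per-class standard errors comparable; the default is
10 classes. Ramet-level profiles use all units and per-ramet frequencies;
genet-level profiles use one genotype per MLG at the arithmetic centroid
of its ramets, with clone-censored frequencies. Envelopes are the
2.5 %/97.5 % quantiles of permuted class means (positions permuted among
individuals), with a two-sided permutation p-value per class. The
ramet-minus-genet contrast isolates the imprint of clonal growth from
plain isolation by distance.

Note that the Loiselle estimator assigns positive kinship to pairs that
*share the absence* of common alleles, so small groups of rare genotypes
can show mildly positive `F_ij` without any relatedness — a known property
worth remembering when reading the profiles.

## Genet geometry

Genets with ≥ 3 non-collinear ramets get convex hull footprints. The mean
hull area `A₃` of genets with exactly three ramets calibrates the rest:
singletons are assigned `A₃/3`, pairs `A₃/1.5` — the rationale being that
a genet's sampled ramet count is roughly proportional to its occupied
area under uniform grid sampling. These areas are realised as
constant-area polygons: a disc of radius `√(A/π)` for singletons, and for
pairs at distance `d` a stadium whose half-width solves
`πw² + 2dw = A`, i.e. `w = (−d + √(d² + πA))/π`. Collinear ≥ 3-ramet
genets (zero-area hulls) are handled by the pair rule applied to their two
extreme ramets with the `A₃` target. The stored `A_GEN` is the exact
closed form; polygon discretisation (256 segments per circle) keeps the
realised area within far less than 1 % of it. A genet sampled in several
patches gets a single pooled footprint.

Overlap is reported as `100 × area(covered by ≥ 2 footprints) /
area(union of footprints)`. The union denominator was chosen over the sum
of patch areas because it asks the sharper question — of the ground genets
actually occupy, how much is contested; a flag can switch the denominator.
Multiplicity beyond pairs is detected exactly by testing triple
intersections among mutually overlapping pairs.

## Patch analysis

Per patch with ≥ 2 sampled units: `R_p` and `E_H` on the within-patch
clone sizes, and `S_mix = N_Pdif/N_Ptot`, where each ramet contributes its
nearest within-patch neighbour (a *directed* relation, so
`N_Ptot = n_p`). The directed reading of "pairs of nearest neighbouring
ramets" was chosen because it is deterministic, keeps `S_mix` in [0, 1]
under every configuration, and weights each ramet equally; an unordered
mode (mutual pairs collapsed) is available. The three indices all increase
with richness, evenness and mixing, and are regressed on patch area `A_P`
by univariate OLS with Pearson r and the two-sided t-test p-value
(reported to 3 decimals and never as exactly zero in formatted output).

Local genotypic richness is `(G_local − 1)/(N_local − 1)` over the units
within 1 m of each ramet (0 for an isolated unit, consistent with the
monoclonal limit of `R`). Surfaces are interpolated by inverse-distance
weighting, which reproduces the data values at the data points and cannot
overshoot their range; cells farther than the mask radius from any unit
are masked. The surface is a visualisation aid — no headline number
depends on the interpolant, which is why a simple Shepard scheme was
preferred over spline machinery.

## Synthetic populations

The generator draws per-locus allele frequencies from a symmetric
Dirichlet (default allele counts 8, 5, 4, 7, 16, 11, 14, 8 — an 8-locus
microsatellite panel of the kind used in such surveys), founder genotypes
under HWE (optionally inflated homozygosity at selfing equilibrium
`F = s/(2−s)`), clone sizes as `floor` of a Pareto variate (default
exponent 1.1, cap 400), genet seed points uniformly with a minimum
spacing of 1.8 m under the phalanx architecture, ramet displacements
isotropic Gaussian (default σ = 0.7 m; a guerrilla habit uses large σ and
no exclusion), and somatic mutations per allele copy to brand-new labels
(infinite-alleles), so mismatch classes 1–2 appear when the rate is
positive. Patches are single-linkage spatial components (default
connectivity 1.5 m) outlined by buffered convex hulls, and the grid
sampler applies the field protocol: per 1 × 1 m quadrant, 2 samples from a
patch covering > 50 % of the quadrant (or lying wholly inside it), 1
otherwise, capped by availability. The defaults were set so that one
default-scenario draw lands at the scale of the motivating survey
(~240 genets, ~700 sampled units).

What the simulator does *not* emulate: demographic dynamics through time
(growth, death, disturbance), mating-system detail (geitonogamy,
pollen flow), genotyping error, or irregular patch shapes beyond buffered
hulls. Tests passing on this test bed therefore demonstrate the
correctness of the estimators and the qualitative behaviour of the
indices, not field realism of any particular parameter value.

## Test problem sizes and numerical choices

The test suite validates each estimator against an independent oracle
(brute-force double sums, Monte-Carlo integration, shoelace areas, hand
OLS) on instances of ≤ 50 units, recovers simulator truth exactly at zero
mutation rate, contrasts phalanx and guerrilla architectures over 50
replicate pairs at matched clone sizes, calibrates the permutation tests
on 100 null replicates at 200 permutations each (~120-unit populations),
and checks the regression sign structure over 50 replicates of an aging
phalanx scenario — 12 patches whose age drives both area (clonal
expansion) and composition (old patches dominated by one large genet and
purged of young singletons; young patches are singleton nurseries). These
problem sizes were chosen as the smallest at which the contrasts are
unambiguous.

All randomness flows through explicit seeds (`numpy.random.default_rng`);
rerunning any analysis with the same seed is bit-identical. Known
limitations: Psex assumes independent sexual events and free recombination
across loci; the aggregation-index permutation test conditions on the
observed clone-size distribution; buffer-area imputation is a coarse
allometry that should not be over-interpreted for any single genet; and
equal-count distance classes make class *edges* data-dependent, so
profiles from different datasets are comparable by class rank, not by
metre marks.
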