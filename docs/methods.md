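# Methods

## The matched-null model

The framework treats each trait-associated region as a unit and asks
whether the median value of an evolutionary measure over the region's
variants is extreme relative to regions that look the same to a GWAS:
same minor allele frequency at the lead, same local LD richness, same gene
architecture. The null hypothesis is therefore not "neutral genome" but
"genome conditioned on MAF, LD and gene context", which removes the main
confounders shared by GWAS power and evolutionary statistics.

The empirical p for one region × measure is the count rule
p = #{control medians ≥ observed} / n_used for upper-tail measures, and
p = min(1, 2·min(#{≥}, #{≤})/n_used) for two-sided ones (PhyloP, TMRCA,
alignment block age, whose extremes are meaningful in both directions).
p = 0 is reported as printed by the count rule — no pseudocount — with
n_used recorded so downstream users can floor at 1/n_used if they prefer.
z-scores standardise the observed median against the control medians
(sd with n−1). Both are undefined (reported missing, never 0) when the
usable null is too small; the floor is 100 control medians.

Control bookkeeping follows two thresholds: a control region that matched
fewer than 90% of the required variants is *marked* and excluded from the
null; when ≥ 60% of a region's controls are marked, that region × measure
is *removed*. An unmarked control none of whose members carries a value on
the measure's track contributes no median and is likewise excluded (logged);
this situation does not arise with full-coverage tracks and is the package's
own extension of the marking rule to missing data.

## Matching windows

MAF is matched absolutely (±0.05 on the folded frequency, the SNPSNAP
percentage-point convention); LD-buddy count, gene density and gene
distance are matched relatively (±10%, ±500%, ±500%), with the lower bound
clipped at zero. The relative windows collapse to exact equality when the
lead's value is 0 (a genic lead, distance 0, only matches genic controls —
the intended behaviour). A relative MAF window was rejected because at
±5% relative it would be an order of magnitude tighter than the
percentage-point reading and make thousands of matches implausible.
Gene density uses a 100 kb window centred on the variant (configurable);
LD buddies are counted within the clump window at r² > 0.9, self excluded.
Control LD partners are drawn within the same clump window as region
definition; distance ties to the nearest gene break toward the lower
coordinate.

## Measures

**Weir–Cockerham F_ST** uses the two-population variance-component
estimator θ̂ = a/(a+b+c) computed from diploid sample sizes, allele
frequencies and observed heterozygosities; monomorphic sites are missing.
The implementation is validated to 1e-12 against an independent ANOVA
mean-squares derivation on random genotype configurations.

**EHH family.** EHH at offset x from a core site is the probability that
two random carrier haplotypes are identical over [core, x], computed
marker by marker outward; iHH integrates the curve trapezoidally in
physical bp while both segment endpoints are ≥ 0.05. Distances are
physical — no genetic map — matching the common default; gap-penalty and
max-gap refinements of rehh-style implementations are deliberately
omitted. iHS = ln(iHH_anc/iHH_der), standardised within derived-frequency
bins of width 0.025 (bins under 10 variants are missing); iES integrates
the all-haplotype EHHS; XP-EHH = ln(iES_A/iES_B) standardised over scored
variants, positive when homozygosity is longer in A. Internally the EHH
curve is computed by a sort-based partition algorithm (lexicographic row
ordering, first-mismatch depths, reverse union-find) that is exactly
equivalent to marker-by-marker refinement but linear in carriers × markers.
Note that a non-informative marker (all carriers agree) leaves EHH values
unchanged at every marker but does perturb the trapezoid integral by the
interpolation wedge; iHH is therefore defined relative to the marker set.

**Beta score.** β = θ̂_β − θ̂_W on folded frequencies, with similarity
weight w = 1 − |f_i − f_c|/0.5 and the neutral normalisation
E_w = Σ_{k=1}^{n−1} (1/k)·w(fold(k/n), f_c). On windows drawn from the
neutral folded SFS the two estimators agree in expectation, which the test
suite checks by simulation; numeric equivalence with the original BetaScan
binary is not claimed. The scan window is ±500 bp around the core
(window_bp = 1000), core excluded; an empty window gives β = 0.

**Alignment block age** is the age (Myr) of the MRCA of the species present
in an alignment block on a time-calibrated tree, required ultrametric to
1e-6 so ages are well-defined; a single-species block has age 0.

**Ingested tracks** (PhyloP, PhastCons, GERP, LINSIGHT, TMRCA) enter as
per-position values and are indistinguishable from computed measures
downstream. The YAML registry declares each measure's tail; iHS enters as
a magnitude (|iHS|) by default because its sign tracks allele polarity
rather than sweep strength — this is configurable, as the choice of signed
versus absolute region-level iHS is genuinely open.

## Clustering and enrichment

z-vectors are clustered with complete-linkage hierarchical agglomeration on
Euclidean distances and the dendrogram cut at height 7 (both configurable;
these are the common defaults of heatmap tooling, and "branch length
cutoff" is read as the cut height). Measures missing in more than half the
regions are dropped; remaining missing z-values are imputed as 0 for the
clustering geometry only and can never make a region "extreme" — the
imputation mask is carried alongside the matrix.

Genome-wide enrichment samples 5000 random-region medians per iteration
(without replacement from a precomputed pool), takes their 95th percentile
as the cutoff and counts trait regions at or above it; 1000 iterations give
the count's mean and 5–95% spread. The analytic null is Binomial(n, 0.05):
for 215 regions the expectation is 10.75, and the reported significance is
P(X ≥ round(mean count)). Matched enrichment counts trait regions with
matched-null p < 0.05 and compares against equally sized random sets that
are each run through the full matching-and-evaluation machinery (no
shortcut null), flagged when the observed count exceeds the null's 95th
percentile.

## Ancestral reconstruction

Five states (A, C, G, T, gap), unit cost, Sankoff dynamic programming.
Gap is an ordinary fifth state — no affine treatment — and multifurcations
are handled natively rather than resolved arbitrarily, which avoids hidden
nondeterminism. Columns with more than one gap are discarded before
reconstruction (alignment uncertainty). Per-node MPR sets are exact,
computed from inside (subtree) and outside cost vectors; the root set
equals the set of root states attaining the global minimum. Tips absent
from a column are fully ambiguous. The tree is taken as given and rooted.

## The synthetic generator

Panels are founder mosaics: each haplotype copies one of `n_founders`
(default 8) founder haplotypes, switching founders per-bp with probability
`recomb_per_bp` at each inter-variant gap, then mutating each site
independently (`mutation_rate` 0.002). Founder allele patterns repeat over
runs of adjacent sites (`pattern_repeat` 0.9), producing blocks of high r²
with sharp decay — the LD geometry that clumping, buddy counting and EHH
need. Defaults give two populations of 50 diploids over ~400 kb with
~4000 variants.

What it does *not* emulate: coalescent genealogies, realistic site
frequency spectra, recombination hotspots, population splits with drift
times, or background selection. Passing tests therefore demonstrate that
the statistical machinery is correct and calibrated on data with realistic
LD block structure, not that any particular biological dataset would yield
particular signatures.

Planted signals give the framework known targets: `differentiated` shifts
a column's frequency by Δ in one population (shifting away from the
boundary when Δ would clip); `sweep` copies one donor haplotype's segment
into a target fraction of haplotypes; `balanced` pins folded frequencies
near 0.5 with matched neighbours; `conserved_track` adds an offset to a
score track. For the validation experiments, signals are planted on
exactly the member columns of already-clumped regions so that the rest of
the genome — the control pool — remains null, and differentiation touches
only the non-anchor population so matching covariates are unaffected.

## Validation experiments and problem sizes

`experiments.null_calibration_experiment` evaluates 200 unplanted regions
against up to 500 matched controls each (window 4 kb, 50 bp variant
spacing, ~2.5 kb LD blocks, 24 000 extra control-only columns so matched
pools run deep); the fraction of regions with empirical p < 0.05 lands
near 0.05 for every measure. `experiments.planted_recovery_experiment`
uses 50 regions with 10 planted differentiated (Δ = 0.6) and 10 planted
conserved-track (+3 sd) regions, scoring recovery as |z| ≥ 1.5 with
positive z and p < 0.05. These sizes complete in roughly one and half a
minute respectively on a single CPU; they are the package's chosen desk
scale, and all thresholds (0.05, 1.5, 90%, 60%) are the framework's stated
parameters, not tuned values.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive after ingestion; bedGraph and BED are
  converted on read. Score lookups at absent positions return an explicit
  missing marker, never 0.
- Monomorphic columns have undefined LD (error), undefined F_ST (missing).
- A variant column with any missing genotype is dropped at VCF read; an
  unphased genotype is an error naming the record.
- Clumping ties in p break by (chrom, pos) ascending, making output
  independent of input row order.
- Control sampling is without replacement within a region; the same pool
  variant may serve different trait regions. All sampling flows from
  per-region seeds derived from the run seed, so reruns are byte-identical.
- Region medians ignore missing member values and require at least one
  non-missing member; even counts take the mean of the central pair.

## Known limitations

- F_ST is the two-population estimator only; multi-population θ̂ is out of
  scope.
- iHS requires an explicit ancestral-allele map; there is no inference
  fallback.
- Beta is the folded-spectrum β(1); the substitution-aware β(2) is not
  implemented.
- The generator's founder mosaic underestimates low-frequency variant
  density relative to coalescent expectations, so absolute values of
  frequency-spectrum statistics (Beta especially) should be read
  comparatively, not literally.
- Matched pools at desk scale are orders of magnitude smaller than a
  genome-wide variant pool; regions with unusual covariate combinations
  can fall below the 100-control floor and report missing p.
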