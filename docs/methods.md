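# Methods

This note documents the models behind each analysis stage, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.

## Coordinates and conventions

All genomic coordinates are 0-based half-open internally; conversion to
1-based happens only when SAM is written (via pysam).  Fold changes are
positive ratios internally; user-facing tables use the signed display
convention `f ≥ 1 → +f`, `f < 1 → −1/f`, which round-trips exactly.
Copy-number estimates are reported both raw and rounded to the nearest
integer (ties round half-up).

## Synthetic genome and paired-end reads

The host chromosome is i.i.d. random DNA at a configurable GC fraction
(default 0.42, a typical mammalian autosome value).  An insertion allele
is built as `host[:site] + dup + concatemer + dup + host[site+dup:]`, so
the `dup_length` bases downstream of the integration site appear once on
each side of the array — the read-depth signature of a target-site
duplication.  The concatemer interleaves the two co-injected transgene
units round-robin (equimolar co-injection makes alternation the natural
default); unit lengths default to 7 kb each with 50 copies per unit per
allele, so the default array totals 700 kb.  Unit lengths and composition
are package choices, declared here, not inferred quantities: only the
duplication length (26 kb), total size (~700 kb) and homozygosity are
fixed features of the reference architecture.

Fragments are sampled uniformly per allele with Gaussian lengths
(mean 400, sd 35, truncated to [2·read_len, 2·mean]; the library protocol
gives only a 300–500 bp range, and these moments keep essentially all
mass inside it).  The number of pairs is
`coverage × Σ allele lengths / (4 × read_len)`, so supplying the two
alleles of a diploid yields `coverage`-fold depth over the haploid
reference.  Reads are exact substrings of their source allele; an optional
uniform substitution error rate is applied only when sequences are
materialised for FASTQ/SAM.  No quality-score realism, indels, or GC bias
are modelled, and no aligner is run: the simulator emits truth alignments
(externally aligned SAM/BAM is accepted by the mapper).  Consequently the
simulation does not probe alignment ambiguity in repetitive host sequence
— the duplicated flank is genuinely ambiguous in real data, and the
mapper reports the duplication once rather than attempting phasing.

Truth mapping is block-based: a read fully inside one host segment or one
repeat copy maps to that contig; a read spanning any junction is emitted
unmapped with its mate informative (pair-level evidence only — the
downstream inference uses pair mapping, not split reads, so soft-clip
modelling is deliberately omitted).  Pairs with both mates mapped to the
same contig at a sane insert are flagged proper; everything else is
discordant.

## Insertion mapper

*Depth*: mapped read starts are binned into fixed windows (default 1 kb);
the baseline is the **median** host-window count, which is robust to the
duplication itself (26 of ~2,000 windows cannot move a median).
*Duplication calls* are maximal runs of windows with normalised depth in
[1.3, 2.7] spanning at least 10 kb (both configurable), snapped to window
boundaries; mean depth ≥ 1.75 is called homozygous (~2 expected), and
[1.3, 1.75) heterozygous (~1.5 expected: three copies over two alleles).

*Junctions*: chimeric pairs (host + transgene mates, non-proper) are split
by host-read strand — forward-strand host reads face the array from the
left, reverse-strand from the right.  The breakpoint estimate is the
innermost host coordinate of each cluster extended by
`(insert_mean − 2·read_len)/2`, the expected distance from the innermost
read end to the junction for a single uniformly sampled straddling
fragment; reported uncertainty is one insert sd.  At high support the
innermost read end converges on the junction, so the extension becomes a
small conservative overshoot (≲ 100 bp here) — well inside the one-insert
tolerance this estimator targets.  A minimum of 5 supporting pairs per
side is required.

*Copy number*: a host window at baseline represents two allele copies, so
a unit at `c` copies per carrier allele over `n` carrier alleles shows
normalised depth `c·n/2`; copies per allele are `depth × 2/n` and total
size is `Σ copies × unit length`.  Known bias: reads whose start falls in
the last `read_len − 1` bases of a repeat copy span into the next unit
and are left unmapped, deflating unit depth by a factor
`≈ (L − read_len + 1)/L` (1.4% for 7 kb units and 100 bp reads).  The
estimate is reported uncorrected — the bias is an order of magnitude
below the 10% accuracy the architecture question requires — and the
rounded integer copies absorb most of it.

*Band-ratio genotyping* converts a transgene/chromosomal band-density
ratio to an allele count by scaling with the same ratio measured in a
known heterozygote and rounding (0/1/2 = wild-type/het/hom).

## Tipping-point model

Ganglionic fractions are truncated-normal on [0, 100] with sex-specific
means (weaning 79/89%, neonate 74/90%; sd 5 is a package default — only
the means are fixed by the modelled phenotype) and megacolon is
deterministic below the threshold (default 80%), reflecting obstruction
occurring systematically beneath a minimal innervated length.  Under this
model penetrance is `Φ((T − μ)/σ)` (`σ = 0` degenerates to a step), and
simulated cohort penetrances converge to it.  The critical region is
defined purely empirically by the two group extremes, with no smoothing; a
logistic threshold fit is available as a clearly-labelled optional extra.
Group means are compared with Welch's unequal-variance t
(Satterthwaite df) — a robust superset of the equal-variance t-test
ordinarily quoted for such comparisons; with both variances zero and equal
means the test is vacuous and p = 1 by convention.

Because obstruction is deterministic in simulation, every simulated
affected animal lies strictly below the threshold and every healthy one at
or above it — the empirical critical region brackets the generator
threshold by construction, which the tests verify.  Real cohorts need not
be perfectly separable; the critical-region operation handles overlap and
reports it.

## Migration statistics

Tracks use uniform time steps; speed is total path length over elapsed
time.  "Directionality" is not formula-standardised in this assay
literature, so two candidates are computed and reported side by side:
(i) circular statistics of per-step heading deviations from the reference
axis (circular mean deviation and resultant length R) — used for the group
test, matching the circular-ANOVA convention — and (ii) straightness
(net displacement / path length).  Zero-length steps carry no heading and
are skipped; an entirely stationary track has undefined direction and is
an error.  The generator draws headings from a von Mises distribution
(concentration κ, default 4) because no specific circular law is implied
by the data; speeds are folded-normal per step with the control default
0.58 µm/min.  Identity exchange between leading cells ("leapfrogging") is
not modelled: tracks are taken as given.

The Watson–Williams test uses the high-concentration F approximation with
the `1 + 3/(8κ̂)` correction, κ̂ from the pooled mean resultant length via
the standard ML approximation; a warning is raised when pooled R̄ < 0.45.
In the small-angle limit it agrees with linear one-way ANOVA, which the
tests check.  Feret's diameter is the maximum pairwise distance, exact by
construction (convex hull first for n > 500); the 200 µm active-migration
threshold is a **strict** inequality.

## Expression screen

Size factors are median-of-ratios over genes nonzero in all samples.
Dispersion φ parametrises variance as `µ + φµ²`.

Scheme A (exact): per-gene method-of-moments dispersions (pooled
within-group variance of normalised counts) are shrunk toward their mean
over informative genes with 20 prior degrees of freedom; counts are
equalised to common depth, and the two group sums are compared by a
conditional NB exact test — all splits of the observed total no more
likely than the observed one are summed.  The conditional support is
evaluated on a ±20-sd window around the conditional mean (mass outside is
negligible at double precision) and renormalised.

Scheme B (LRT): method-of-moments dispersions are shrunk (8 prior df)
toward a fitted `a/µ + b` mean-dispersion trend; with dispersion fixed,
group abundances are NB maximum likelihood (Newton iteration on the
score, moment start) and twice the log-likelihood-ratio is referred to
χ²(1).

Each scheme is BH-adjusted separately and the consensus rule requires
|displayed fold| ≥ 2 **and both** adjusted p < 0.001 (the adjusted — not
raw — reading of the 0.001 threshold is used).  These two schemes are this
package's own constructions in the spirit of the exact-test and GLM
families of NB testers; they are deliberately independent so that the
consensus behaves like an intersection of two different methods.  Fold
changes are ratios of normalised group means with a half-count pseudo in
both numerator and denominator, which makes label swapping invert every
fold exactly.  Genes with all-zero counts are excluded and flagged.
Null simulations (the test suite uses 20 replicates of 5,000 genes at
dispersion 0.05) show the consensus call rate well below nominal, and
planted 5-fold signals at µ ≥ 200 are detected at ≥ 80% power even in a
2 + 2 design.

Candidate prioritisation ranks **upregulated** genes on the insertion
chromosome by nearest-boundary distance to the insertion position
(relief-of-repression acts in cis; downregulated genes are never ranked).
The packaged demo coordinate (47,985,420) is derived from the top
candidate's start minus its known ~3.6 Mb offset and is labelled as
derived.  Enrichment uses two-sided hypergeometric tails (twice the
smaller tail, capped at 1), BH across terms, and the ≥ 2-fold /
adjusted-p < 0.01 reporting rule; term maps are user-supplied.

The packaged fixture tables preserve printed fold changes verbatim and
never recompute them from the printed mean raw counts, whose
normalisation factors are not recoverable (e.g. the top candidate's
printed fold 4.99 ≠ 391/85).  Fixture records carry both adjusted
p-values at the tables' stated ceiling (every included gene satisfied
adjusted p < 0.001) so the consensus filter can run on them; two rows of
the large deregulated-genes table are labelled placeholders restoring its
published tallies where the available transcription is truncated.

## Problem sizes and determinism

All generators are bit-reproducible given (parameters, seed); the
acceptance script derives independent sub-seeds from a single `--seed`
via `numpy.random.SeedSequence`.  The acceptance-scale insertion
simulation uses a 2 Mb host (≈ 409k pairs at 30×) — large enough that
window noise, junction support (~30 pairs/side) and copy-number error are
at realistic relative magnitudes, while one simulation completes in
seconds.  Cohort estimates use 500 animals per sex (SE ≈ 0.22 on a
sd-5 fraction).  Stochastic tests fix seeds and use tolerance bands of at
least four standard errors.

## Known limitations

* No sequencing-error realism, alignment, or repeat-mapping ambiguity;
  passing tests validate the inference logic, not robustness to aligner
  artefacts.
* Breakpoints are pair-level (± ~insert length), not base-pair exact; the
  internal order of the concatemer is not reconstructed.
* The NB schemes are two-group only, with no covariates or weights.
* The tipping-point model treats obstruction as perfectly deterministic
  at a sharp threshold; biological thresholds are presumably softer, and
  the logistic extra exists to explore that.
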