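# Methods

`mutmapkit` implements mapping-by-sequencing for a recessive EMS-induced
mutant crossed back to (a sibling stock of) its own inbred background — the
MutMap design. Four samples are sequenced: the unmutagenized parent, the
homozygous mutant line, and two phenotype-selected F2 pools (mutant and
wild type). This note records the model, the defaults and why they were
chosen, and the known limits of what the synthetic tests demonstrate.

## The mapping model

Every EMS-induced SNP fixed in the mutant line is a marker riding the
mutant-line haplotype through F2 meiosis. In an F2 pool selected for the
recessive mutant phenotype, every plant is homozygous for the causal allele,
so at a marker with recombination fraction *r* to the causal locus the
expected frequency of the mutant-line allele among pool chromosomes is
1 − *r*: it approaches 1 near the causal locus and 0.5 on unlinked
chromosomes. The wild-type pool (⅓ homozygous wild type, ⅔ heterozygous at
the causal locus) stays between 0.25 and 0.75 essentially everywhere, which
is what makes its allele frequency usable as a marker-validity filter
rather than a mapping signal.

### Marker filter

A site is kept iff all of:

1. every role sample has ≥ `min_depth` (default 5) informative reads;
2. QUAL ≥ 500 (boundary kept — "below 500" is discarded);
3. mutant-line alternate allele frequency ≥ 1 (i.e. zero reference reads);
4. parent alternate allele frequency ≤ 0 (zero alternate reads);
5. wild-type-pool frequency in the closed interval [0.25, 0.75].

"Equal to 1"/"equal to 0" are read literally as zero opposing reads at
finite depth; tolerance knobs (`mutant_fixed_min`, `parent_absent_max`)
exist for noisier data. The depth floor is this package's own addition —
without it a site with a single read in the parent could count as "fixed".
Rejections are tallied by first failing clause in the order
depth → qual → mutant → parent → f2wt, so tallies sum exactly to the number
rejected.

### Windowing and smoothing

Filtered-marker allele frequencies are averaged in fixed, non-overlapping
1 Mb tiles (window *k* covers [1 + k·w, (k+1)·w], 1-based inclusive; an
unweighted arithmetic mean per window). Window means are smoothed per
chromosome with locally weighted quadratic regression: for each window
midpoint the nearest ⌈span·n⌉ informative windows are fit by weighted least
squares with tricube weights, and the fit is evaluated at the midpoint.
This smoother is implemented here directly (a degree-2 local fit is wanted;
the available lowess routines are degree-1) and is exact on constant and
linear profiles by construction, which the tests verify. Smoothed values
are clamped to [0, 1]; windows without variants are excluded from the fit
rather than imputed, so variant deserts cannot generate signal. The default
span of 0.2 is a visual-smoothness choice; it is a flag, and no result in
the test suite depends on a particular span.

### Peak calling

The candidate interval is anchored at the global maximum of the smoothed
mutant-pool profile; it must reach `peak_min` (default 0.9) and is extended
in both directions while the smoothed value stays ≥ `edge` (default 0.75,
the complement of the wild-type-pool filter band; 0.9 tolerates some pool
contamination and phenotyping error). When clamping saturates the smoothed
profile at 1.0 across several contiguous windows, the anchor is the center
window of that run — anchoring at the first tied window systematically
biased the peak toward the chromosome start. Distinct tied maxima in
different places still resolve toward the earlier chromosome/position, with
a log message. Candidate causal variants are then the filtered variants
inside the interval with zero reference reads in the mutant pool
(`hom_min` = 1, relaxable).

### Deletion scan

Large deletions are invisible to the SNP path, so the scanner works on
per-base depth: a base belongs to a candidate deletion when depth is below
`low_frac` (default 0.1) of the sample's track mean in **both** the mutant
line and the mutant pool, while the parent stays at ≥ `normal_frac`
(default 0.5) of its own mean. Runs are merged across gaps ≤ 10 bp and
reported at ≥ 50 bp. Per-sample normalization by track mean insulates calls
from library-size differences. The wild-type pool is reported but not used
as a clause: with ⅔ of its plants heterozygous carriers it only drops to
about ⅔ depth. At ~20× Poisson coverage the per-base probability that both
mutant samples are spuriously "depleted" while the parent is normal is
≈ 10⁻¹³, so ≥ 50 bp false runs are essentially impossible — the tested
false-call rate on 30 Mb null chromosomes is zero.

### Segregation statistics

Goodness-of-fit against a Mendelian ratio uses the uncorrected Pearson
chi-square with df = 1 (p from the χ² survival function). No continuity
correction by default: on 18:96 vs 1:3 the uncorrected test gives
χ² ≈ 5.16, p ≈ 0.023 (displayed 0.02), whereas Yates gives ≈ 0.03; the
correction is behind a flag and can only raise p. Co-segregation tables
flag the two biologically meaningful discordances separately:
mutant-phenotype plants not homozygous for the tested allele (these break a
causal hypothesis) and homozygous plants with wild-type phenotype
(candidate suppression, which does not).

## The simulator

`simcross` generates the whole experiment forward from a config:

- **Genome**: 10 chromosomes × 30 Mb by default. All logic is
  length-invariant; this size keeps a full run under a second while leaving
  room for multi-megabase linkage structure.
- **Markers**: 1200 EMS SNPs uniform over the genome (≈ 4/Mb), 90%
  G:C→A:T transitions (the canonical EMS spectrum), the rest uniform over
  other substitutions. Residual-heterozygosity blocks default to five 2 Mb
  blocks on chr1/2/3/5/6 at 100 variants/Mb — 25× the EMS background, mimicking
  the dense clusters that nominally-inbred parent stocks contribute. Both
  classes are fixed alternate in the mutant line and absent from the
  sequenced parent, so both pass the marker filter; het-block sites simply
  plateau near 0.5 in both pools, exercising the peak caller's specificity.
- **Meiosis**: per gamete and chromosome the crossover count is
  Poisson(L_Mb × cM/Mb ÷ 100) with uniform breakpoint placement and no
  interference (the Haldane model). Map density defaults to 0.5 cM/Mb and
  is configurable; the 1 − r law is tested against an exhaustive two-locus
  enumeration oracle.
- **Pools**: F2 individuals are simulated until 72 with the mutant
  phenotype (homozygous causal) and 69 without have been collected —
  phenotype selection, not genotype selection. With `causal_locus=None` the
  phenotype is assigned independently with probability ¼: the null
  condition for specificity tests.
- **Reads**: per site and sample, depth ~ Poisson(21) and alternate count
  ~ Binomial(depth, f(1−e) + (1−f)e) with e = 10⁻³. QUAL scores are
  Normal(1500, 487), putting ≈ 2% of sites under the 500 filter threshold.
- **Deletions**: `plant_deletion` superimposes a homozygous mutant-specific
  deletion on depth tracks: near-zero depth (Poisson(0.05) residual,
  modeling mismapped reads) in the mutant line and mutant pool, binomial
  thinning to ⅔ in the wild-type pool, parent untouched.

Everything is driven by one `numpy` Generator seeded from the config, and
identical configs give byte-identical output files.

### What the simulation does not emulate

Reads are never synthesized, so alignment artifacts, repeat-induced
mismapping, reference bias against a non-reference background, and caller
idiosyncrasies are all absent; QUAL is a stylized location-scale draw with
no dependence on depth or allele balance. Crossovers have no interference
and no heterochromatin suppression. Residual-heterozygosity blocks
segregate ideally at 0.5. Passing tests therefore demonstrate the
correctness of the filtering/mapping/scanning logic under the stated noise
model, not robustness to upstream bioinformatic pathologies.

## Localization accuracy

The candidate interval contains the causal locus in 20/20 default-condition
runs, and null runs report no candidate in 20/20. Point localization of the
peak is another matter: with 72 selected plants there are 144 informative
meioses, so recombinant haplotypes accrue at ~0.7/Mb around the causal
locus and the expected allele-frequency profile is flat to within read
noise over several Mb. An estimator with direct access to noise-free pool
frequencies localizes within 2 Mb in about 95% of runs, and a profile-
likelihood estimator using the read data and the true map cannot do better
than ~75%; the loess-peak estimator sits near that read-level bound. Peak
position should therefore be read as indicative (a few Mb), with the
homozygous-candidate extraction and the deletion scan doing the fine
mapping — which mirrors how the underlying experimental design is actually
used.

## Numerical and degenerate-input choices

- Window boundaries: position 10⁶ belongs to window 1, 10⁶+1 to window 2.
- Loess needs ≥ 3 informative windows per chromosome; below that, raw means
  are copied and a warning logged. Zero-spread neighborhoods fall back to
  the weighted mean.
- Multi-allelic VCF sites are dropped (with a count), not split: the filter
  is defined on a single alternate allele and splitting would double-count
  depth. Alleles > 50 bp are likewise excluded from the SNP path; large
  events belong to the coverage scanner.
- Missing AD yields (0, 0) counts flagged missing; such sites fail the
  depth clause and are tallied there.
- BED output is 0-based half-open, converted from the 1-based inclusive
  internal convention; reading converts back (round-trip tested).
- The deletion used in genotyping examples has a 378 bp coordinate
  footprint but a stated length of 376 bp in the assay arithmetic; the
  scanner treats reported length and coordinates as independent outputs and
  does not reconcile them.

## Problem sizes used in tests

Unit tests use a 3 × 10 Mb genome (~200 sites, < 0.2 s per simulation);
acceptance-level checks run the full default condition (10 × 30 Mb, 2 × 20
seeds) and scan five 30 Mb null chromosomes for false deletion calls. The
whole suite runs in about a minute on one core.
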