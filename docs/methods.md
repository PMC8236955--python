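# Methods

This note documents the models behind each stage, the defaults and why they
were chosen, what the synthetic data emulate, and the limitations a user
should know before trusting results on real data.

## Somatic small-variant calling

Each pileup site is scored with a two-hypothesis binomial model on the
tumor counts. Under H0 the alt count is Binomial(depth, e) with background
error rate e; under H1 it is Binomial(depth, v̂) with v̂ the observed alt
fraction floored at e. The floor makes the generalized likelihood ratio —
depth · KL(v̂ ‖ e) on the log scale — monotone non-decreasing in the alt
count, so a higher alt count never lowers the posterior. The posterior
combines the ratio with a per-site somatic prior (default 10⁻⁶; at 700×
even a handful of alt reads overwhelms it, so the prior mainly suppresses
1–2-read noise). Sites where a one-sided binomial test rejects the
background-error hypothesis in the matched normal (α = 10⁻⁴) are vetoed as
germline: this removes het and hom germline variants without genotype
modeling and is deliberately conservative at 343× normal depth.

Quality corrections are realized as pre-filters: mean base quality ≥ 20,
mean mapping quality ≥ 30; sites flagged as short-tandem-repeat regions
need twice the usual alt-read support. These are configuration, not
statistics — the filters the cascade is named for are:

| rule | pass condition |
|---|---|
| alt_reads | alt-supporting reads ≥ 8 |
| vaf | alt fraction ≥ 0.1 (raw observed VAF, no purity adjustment) |
| consequence | exonic or splicing |
| strand_bias | max(fwd, rev)/(fwd+rev) < 0.9 |
| indel_length | ≤ 40 bp |
| population_af | ≤ 0.015 in every bundled population table |

Boundaries are inclusive exactly as written (8 passes, 0.9 fails, 40
passes, 0.015 passes). The VAF rule applies to the raw observed fraction:
applying it after purity correction would make callability depend on the
purity fit, and a 10% observed fraction is already the natural limit of an
8-read rule at panel depth. Population frequencies come from a bundled
table object standing in for public population databases; the maximum over
tables is compared to the cutoff because a variant common in any one
database is presumed germline.

## Copy number

**Panel of normals.** Each normal bin-depth profile is scaled to the mean
library size (median depth) and the per-bin median across ≥ 2 normals
becomes the reference; bins whose reference falls below 10× are masked.
The median is robust to a single aberrant normal and matches the pooled
("mixed") construction.

**GC correction.** Depths are grouped into GC strata of width 0.02;
sparse strata are merged rightward until each group holds ≥ 20 bins, then
each depth is divided by its group median and rescaled to preserve the
overall median. The merge matters on small panels: with only a few bins
per stratum, copy-number-altered bins would otherwise contaminate their
stratum median and shrink the very signal being measured. The correction
removes any monotone sample-level GC bias; assay-level bias shared by
tumor and reference cancels in the ratio regardless.

**Segmentation.** Log₂ ratios (tumor/PON, per chromosome, masked bins
dropped) are segmented by circular binary segmentation: the statistic is
|mean_in − mean_out| / √(1/k + 1/(n−k)) maximized over all circular arcs
(wrap-around arcs are complements of linear arcs and share the same |t|,
so scanning i < j covers the circle). A split is accepted when the
permutation p-value is below α = 0.01; permutations are seeded and stop
early once acceptance is impossible. Defaults: 1,000 permutations
(library), 200 in the recovery tests and acceptance script, which changes
only the resolution of the p-value, not the statistic. Adjacent segments
whose means differ by < 0.1 are re-merged. Constant vectors, and segments
shorter than 4 bins, are returned unsplit.

**Purity and ploidy.** Grid search over p ∈ [0.2, 1] (step 0.01) and
ψ ∈ [1, 8] (step 0.05). For each segment the candidate copy number is the
rounded inverse of the expected-ratio model; the score sums squared
residuals of (a) the segment mean log₂ against its re-quantized
expectation and (b) the mean *mirrored* BAF max(b, 1−b) of het SNPs in the
segment against its model expectation. The mirrored mean is used instead
of a folded median because mirroring biases balanced segments upward by
≈ σ√(2/π); the fit therefore compares against the analytic expectation of
the mirrored statistic (folded-normal moment at the binomial σ), which
makes balanced and unbalanced segments commensurable. SNPs are restricted
to those heterozygous in the matched normal (BAF in [0.4, 0.6]).

The two residual types are inverse-variance weighted: the BAF residual by
n_snps / (0.02)² and the log₂ residual by n_bins / (0.08)², the nominal
per-SNP mirrored-BAF and per-bin log₂ noise scales at panel depth. Without
this, segment-mean depth noise (sd ≈ 0.025 on a 10-bin segment) outvotes
the far more precise allelic evidence (sd ≈ 0.004 on its mean) and can
shift the purity optimum by several grid steps.

The genome-doubling transformation p′ = p/(2−p), C′ = 2C, ψ′ = 2ψ
reproduces both observables *exactly*, so the likelihood alone cannot
choose between a diploid solution and its doubled image. The score adds a
parsimony penalty of about one normalized-residual unit per segment,
ploidy_penalty · n_segments · ((ψ−2)² + (1−p)²), selecting the
least-doubled point on the ridge — the same convention purity/ploidy
callers adopt. Exact residual ties (the flat diploid genome,
where purity is unidentifiable) are flagged `ambiguous` and resolved toward
purity 1 and ploidy 2. Samples with no informative het SNPs raise an error
instructing the caller to fall back to (p=1, ψ=2); the end-to-end caller
does this automatically and marks the fit `defaulted`.

Absolute copy number C = (2^l (pψ + 2(1−p)) − 2(1−p))/p is floored at 0
and rounded; gain/loss cutoffs are round(ψ) ± 1. Genes are called from the
overlapping segment with the largest overlap.

Identifiability caveat: a tumor whose only event is a balanced, even-copy
amplification constrains (p, ψ) weakly — a nearby (p′, C′) pair can match
the observations almost as well. Recovery to ±0.05 purity presumes at
least one allelically informative segment (an odd copy number or a loss),
which the simulated tumors in the recovery tests carry.

## Rearrangements and fusions

Read pairs are selected when mates map to different chromosomes or more
than 2 kb apart (strict: exactly 2,000 bp is concordant). Selection is
idempotent and order-free. Single-linkage clustering joins reads whose
canonically ordered ends both lie within 500 bp; clusters with ≥ 5 reads
become calls with median-position breakpoints and majority strands. The
window and support defaults are typical for panel SV calling and
configurable. Classification: interchromosomal → translocation; same
strand → inversion; +/− over > 2 kb → long deletion; −/+ → duplication.
Breakpoints are read-pair-level (median), not base-pair precise — there is
no split-read assembly.

Fusion annotation maps each breakpoint to the flanking exon in
transcription direction (intronic breakpoints map to the adjacent exon);
the partner whose read strand matches its gene strand donates its upstream
exons (5′ side). Retained domains are those wholly inside the retained
genomic region. The in-frame check compares donor and acceptor coding
phases (cumulative exon lengths mod 3) and returns unknown for mid-exon
breakpoints or ambiguous orientations. Intergenic and intragenic calls are
reported as rearrangements but not as fusions.

## Microsatellite instability

Per locus, the tumor and normal repeat-length histograms form a 2×L count
table; tail bins with expected count < 5 are merged inward and a chi-square
test (no continuity correction, ≥ 2 bins) gives the p-value; p < 0.05
marks the locus unstable. A Kolmogorov–Smirnov alternative is available by
configuration. Loci with < 30 reads on either side are not evaluable and
count toward neither side. No multiple-testing correction is applied
across the 100 loci — the sample rule (MSI-H iff ≥ 75 unstable loci)
dominates error control, since ~5 false-positive loci at α = 0.05 cannot
approach 75. The 75-locus rule denominates on the absolute count, not the
evaluable count; when fewer than 75 loci are evaluable MSI-H is
unreachable and the result carries a warning flag.

## Cohort landscape

Frequencies are distinct-sample counts over group sizes, rounded to one
decimal (percent) for gene/CNV frequencies and to integers in pathway
summaries. The proportion test is the chi-square test of equal
proportions, with Yates continuity correction for two groups only;
identical all-zero (or all-full) margins return p = 1. FDR is
Benjamini–Hochberg. The rank-sum test enumerates exactly when both groups
have ≤ 10 observations and no ties, otherwise uses the tie-corrected
normal approximation with continuity correction. Mutual exclusivity is a
pairwise two-sided Fisher exact test on sample mutation indicators.
Pathway membership and oncogene/tumor-suppressor roles ship as an editable
map covering RTK/RAS/PI3K, cell cycle, NF-κB and Wnt/β-catenin–NOTCH/FAT1;
a sample counts once per pathway regardless of how many member genes are
hit, and SNVs/indels, CNVs and fusions all count. Actionability matches
alterations against a bundled static knowledge table (gene × alteration
type × evidence level × drugs); a sample's level is its highest-priority
match (1 > 2 > 3A > 3B > 4), and "oncogenic" is a separate rule attribute
so the oncogenic fraction can exceed the actionable fraction. Pathway
percentages use per-site denominators; actionability uses the whole
cohort, including unknown-site samples.

## Synthetic data: what it emulates, and what it does not

The generator fabricates a panel on fictional 0-based half-open
coordinates: named recurrent genes first (with the CCND1/FGF4/FGF3/FGF19
block adjacent to emulate 11q13 co-amplification, and NTRK2 carrying a
tyrosine-kinase domain over exons 16–19), ~13 SNP loci per gene (≈ 5,000
at full panel size), and 100 microsatellite loci. Cohorts follow the
study's composition: 317 samples over seven site groups; Poisson mutation
loads with site means 8.3 (larynx), 7.3 (hypopharynx), 4.5 (oral cavity),
3.6 (nasopharynx), 5.5 elsewhere; per-(gene, site) Bernoulli mutation
indicators for the recurrent genes (e.g. TP53 at 86.1/90.0/24.1/70.3% in
HPC/LC/NPC/OCC) with the residual load spread over background genes so the
configured frequencies are preserved; a 42.2% C>T-dominated spectrum;
13.5% indels; purity uniform on [0.2, 1]; ploidy 2.

The noise model: depths are negative binomial with variance
(1 + 0.1)·mean — the constant-overdispersion (NB1) parametrization, chosen
because it yields the ~4% bin-level coefficient of variation typical of
normalized capture depth at 730×; alt reads are binomial at the purity-
and copy-number-adjusted allele fraction pvC/(pC + 2(1−p)); sequencing
error adds binomial noise at 10⁻³; bin means are modulated by a smooth
quadratic GC bias (per-bin GC is i.i.d., as capture bins' GC varies bin to
bin); het-SNP BAFs are binomial around the allele-specific expectation
with the B allele on a uniformly chosen haplotype; fusions emit 20
discordant pairs flanking both breakpoints plus scattered noise pairs;
unstable microsatellite loci mix a left-shifted, widened length
distribution into the tumor histogram with weight 0.9·purity.

Not emulated: alignment and mapping artifacts, FFPE deamination chemistry,
subclonal structure, reference bias at SNPs, realistic repeat-unit stutter
asymmetries, and inter-bin correlation of coverage. Passing tests
therefore demonstrate the correctness of the statistical machinery under
its stated model, not robustness to artifacts the model excludes.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale configurations
chosen as the smallest sizes at which the estimators are informative:
panels of 12–60 genes (the full 383-gene panel is exercised once for its
invariants), 20 tumors for purity/ploidy recovery with 200 CBS
permutations, 50 tumor/normal pairs for caller sensitivity/precision, 100
random vectors against the brute-force CBS oracle, and a 97-sample
four-site cohort for the end-to-end landscape. Seeds are explicit
everywhere; generators are bit-reproducible for a fixed seed, and fixture
files round-trip through `%.17g` formatting with pandas'
`float_precision="round_trip"` parser. Degenerate inputs are defined, not
special-cased: constant vectors segment to one piece, a zero-alt site has
undefined strand bias (error), zero tumor depth has an undefined somatic
score (error), empty cohort fixture files are valid with headers.

## Known limitations

- Purity below 0.2 is outside the fitted grid by design (the study's
  inclusion threshold the generator enforces); samples below it are forced
  to the grid boundary.
- The breakpoint model is read-pair-level; exon joins are exact only when
  breakpoints fall in introns, which the generator guarantees but real
  data do not.
- The caller's germline veto assumes a matched normal; tumor-only mode is
  deliberately unsupported.
- The actionability table is a static bundled snapshot; it is meant to be
  versioned and edited, not to track a live knowledge base.
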