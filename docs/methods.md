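# Methods

This note documents the models and procedures implemented in `depthgauge`,
the parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Fragment model

The atomic unit throughout is the *fragment*: the genomic interval of one
cDNA molecule, represented as a 0-based half-open interval with a transcript
strand. Internally fragments travel as pandas DataFrames (columns `contig,
start, end, strand, fragment_id, origin`); all coordinate conversions to
1-based conventions (GFF3, SAM) happen in the I/O layer only.

**Pair resolution.** A read pair is *proper* when both mates map to the same
contig on opposite strands, inward-facing (the forward-strand mate starts at
or left of the reverse-strand mate), with outer span ≤ `max_span` (default
450 bp, the library's size-selection ceiling). A proper pair becomes one
fragment from the leftmost start to the rightmost end — the unsequenced gap
between mates is deliberately filled, because the cDNA physically covered
it. For an improper pair one mate is discarded; we keep the mate with the
lower genomic start, a deterministic rule chosen so that re-runs are
bit-identical (any single-mate rule is equally defensible). Orphans and
unpaired reads become fragments of their own extent. Whether the 450 bp
limit bounds the outer span or the inner gap is ambiguous in principle; we
bound the outer span (a fragment cannot be longer than the longest
size-selected cDNA) and expose `max_span` for the other reading.

**Strand convention.** Under the dUTP second-strand protocol the second
cDNA strand is destroyed before amplification, so R2 aligns on the
transcript strand (`dUTP_R2_sense`, the default); `R1_sense` is the exact
mirror, and flipping the protocol flips every fragment strand (and hence
swaps sense/antisense count columns exactly — a tested symmetry).

## Coverage, position categories, background subtraction

Coverage is dense: two `int64` vectors of length *L* (one per strand),
memory 16·L bytes — appropriate for bacteria-scale genomes, not mammalian
ones. `Csum` (total strand-specific coverage) equals the summed fragment
lengths exactly.

Every strand-specific position gets one category: sense positions of
features take the feature class with precedence rRNA > ncRNA > ORF (so
rRNA positions never dilute mRNA statistics when annotations overlap);
positions opposite a gene are antisense (AS) only when no gene occupies
them on their own strand; everything else is intergenic (IGR). Summary
tables carry a `Total` row over all 2·L positions, and empty categories
report NaN rather than a misleading 0.

**Background model.** gDNA contamination is assumed uniform over both
strands, so its expected per-position coverage is a single constant

    Cbkg = Csum · (pctBkg/100) / (2·L).

A compact published form of this expression reads `Csum·pctBkg/1000`,
which is dimensionally inconsistent for a per-nucleotide expectation (it
ignores genome length); the uniform-distribution assumption forces the
division by 2·L. The literal expression remains available via
`literal_formula=True` for auditability; the corrected form is the default
and the one all tests and results use. `pctBkg` is an assumed scenario
(0.5% or 1% are typical), not estimated from data — estimating it is out of
scope by design.

Subtraction uses stochastic rounding: with d = C − Cbkg, Ceff is 0 for
d ≤ 0, ⌊d⌋ for d ≥ 1, and Bernoulli(d) otherwise, so E[Ceff] is continuous
in d and low-coverage positions are removed probabilistically rather than
by a hard cut. Bernoulli draws consume a single named stream in genome
order (plus strand first), making runs bit-reproducible per seed. The
tested consequence: on data with known 1% gDNA and no antisense
transcription, 1% subtraction removes a far larger share of covered AS+IGR
positions than of covered ORF positions.

## Counting and RPKM

A fragment overlapping k ≥ 1 features (≥ 1 bp, strand-blind overlap)
contributes 1/k to each feature, in the sense column when strands agree and
the antisense column otherwise; k counts all overlapped features regardless
of strand agreement, the closest literal reading of an equal-split rule,
and it generalises uniformly to k > 2. Fragment mass is conserved to
1e-6: assigned + unassigned = total. The implementation uses a vectorised
searchsorted join when the annotation is non-overlapping (the common
bacterial case) and an interval tree otherwise; both are verified against a
quadratic brute force.

RPKM uses **non-rRNA fragments** as the depth denominator — depth
recommendations are expressed in informative fragments, and rRNA content
varies with depletion efficiency, not with the mRNA pool.

The sense/antisense correlation QC computes R² of per-ORF mean coverage on
the two strands, i.e. of count/length (the constant mean fragment length
cancels). Per-base mean coverage rather than raw counts is an assumption;
for fixed fragment length the two differ only by a constant factor, which
R² ignores.

## Depth experiments

Subsampling is simple random sampling without replacement. Saturation
curves use *nested* (telescoping) subsamples: one permutation per seed,
each depth a prefix, so every metric is monotone in depth pathwise, not
just in expectation; independent per-depth draws are available
(`nested=False`) for variance studies. Count scaling offers a
`proportional` mode (round-half-even of count·f — preserves relative
expression exactly before rounding; half-even keeps totals unbiased) and a
`binomial` mode (stochastic thinning, preserving expectation), the former
being the default because its purpose is to change depth while holding
expression ratios fixed.

## Differential expression

An original, compact NB test, not a port of any published package:

- **Size factors**: median over all-nonzero genes of count/geometric-mean.
- **Dispersion** (Var = μ + αμ²): per-gene method of moments on normalised
  counts within each replicated condition, pooled with (n−1) weights and
  clamped at 0; a trend α(μ) = a₁/μ + a₀ is fitted by least squares over
  all expressed genes (clamped zeros included — excluding them would bias
  the trend upward), and each gene takes max(own estimate, trend). With no
  replicated condition the estimator pools all samples as one group and
  warns.
- **Test**: conditional on the pooled total K = kA + kB, the null
  probability of each split (a, K−a) is the product of the two condition-sum
  NB laws with common rate q = K/(sA+sB) and variances μ + α·Σ(q·fⱼ)²; the
  two-sided p-value sums the probabilities of splits no likelier than the
  observed one. For K > 1024 (enumeration cost bound) a moment-matched
  normal approximation with continuity correction replaces the enumeration;
  the two regimes agree to within half a log10 unit of p at moderate
  significance, though they diverge in deep tails (p < 1e-10), which is
  immaterial at the 1e-3 call threshold.
- **Calls**: fold ≥ 2 on the ratio of normalised condition means (0.5
  pseudocount on both means when either is zero) and raw p < 10⁻³ — no
  multiple-testing correction, mirroring screen-style practice. Calibration
  is validated by simulation: type-I error at nominal 0.05 sits near
  0.03–0.04 (slightly conservative, never anti-conservative), and planted
  ≥10-fold changes at expected counts ≥ 20 are detected with power > 0.9.

One observed consequence of max-rule dispersion sharing with 2+2 designs:
for very large fold changes a handful of genes can be *more* significant
after a 10-fold depth cut than at full depth, because at lower totals the
exact path applies and noisy gene-wise dispersion estimates shrink. The
depth-effect ordering that matters — modest (2–5×) changes are lost at
reduced depth much faster than >10× changes — is robust to this and holds
in every simulation.

## Synthetic-data generator

The generator is first-class, tested code; it defines the study conditions
for every property above.

**What it emulates.** A single linear bacterial contig with non-overlapping
ORFs (300–1500 bp), ncRNAs (80–300 bp) and 4.5 kb rRNA operons separated by
≥ 20 bp intergenic gaps; i.i.d. log-normal expression (default σ = 2,
giving the several-orders-of-magnitude dynamic range of real
transcriptomes); fragment lengths normal(159, 40) clipped to
[read length, 450] bp, matching a 150–450 bp size selection with 159 bp
mean; uniform gDNA contamination on both strands (default 1%, the upper
assumed scenario); rRNA fragments at a tunable fraction of transcription
(default 0.15%, a well-depleted library; 0.82 emulates an undepleted one);
and low-rate antisense transcription (default 2% — no measured value
exists, this is a plausible low rate for spurious antisense) in two modes:
`uniform` (antisense lands on features by length only, uncorrelated with
expression — clean dUTP chemistry, sense/antisense R² ≈ 0) and `mirrored`
(antisense tracks each gene's own expression — a library without
second-strand excision, R² > 0.8). Sampling weight is abundance × length:
fragments, not molecules, are what coverage and RPKM measure.

**What it does not emulate.** Sequencing errors, quality strings, GC and
positional bias, multi-mapping, operonic (shared-transcript) structure,
transcript boundaries extending beyond annotated features, or the dUTP
leakage mechanism itself (only its observable antisense rate). Passing
tests therefore demonstrate correctness of the *computations* under clean
mapping assumptions, not robustness to alignment artifacts.

All randomness flows from one integer seed through named per-operation
substreams, so each operation is reproducible in isolation.

## Problem sizes

Tests and the acceptance script run at bacteria-appropriate but desk-scale
sizes chosen by us: oracle comparisons on ≤ 10⁴ bp genomes with ≤ 10⁴
fragments; background-subtraction and saturation studies on 1 Mb genomes
with up to 2×10⁶ fragments over 10–20 seeds; DE simulations at 2000 genes
with 2+2 replicates. These sizes put sampling error well below the margins
asserted (3σ bands throughout) while keeping the full suite to a few
minutes.
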