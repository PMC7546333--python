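# Methods

## The analysis in one paragraph

A spike-stalk-injection (SSI) variant is compared with its recipient
cultivar at the genotype level, its selfed F2 progeny are genotyped sparsely
(RAD-seq style), and trait changes are mapped to recombination bins.  The
package implements each stage — site filtering and classification,
heterozygosity and mutation-rate estimation, genotype calling, sliding-window
breakpoint detection, bin-map and genetic-map construction, and a
regression-based approximation of composite interval mapping — together with
a forward simulator that generates populations with the study's structure
and a truth set, so every estimator can be checked for parameter recovery.

## Founder and population model

The recipient is nearly homozygous with residual genomic heterozygosity
*h_rec* (default 3.36×10⁻⁴ heterozygous sites per covered base).  The
variant is modelled as a hybrid-like derivative of the recipient: it
inherits the recipient's residual heterozygous sites and carries additional
heterozygous sites at rate *h_var − h_rec* so that its **total** genomic
heterozygosity is *h_var* (default 25.96×10⁻⁴), plus homozygous non-recipient
alleles at rate µ (default 0.182×10⁻⁴).  With *h_var* = µ = 0 the variant is
identical to the recipient, and the realised rates of a simulated genome are
binomial around their targets.  At heterozygous variant sites the
non-recipient allele is phased onto haplotype 2 (coupling phase), which is
what "behaves like an F1" implies; classification and genotyping never rely
on the phase, only the simulator's meiosis does.

Meiosis draws a Poisson number of crossovers with mean equal to the
chromosome's genetic length in Morgans, positions uniform on the genetic map
(taken linear in physical position), and a random starting haplotype — no
crossover interference, so Haldane's map function round-trips exactly.  A
selfed line is produced by *g* successive generations of two independent
gametes from the same plant; the expected heterozygous fraction at
founder-heterozygous sites is 2⁻ᵍ and single-site segregation at *g* = 1 is
1:2:1.  The number of selfing generations is exposed as a parameter
(default 1) because the study population's observed homozygosity lies
between the *g* = 1 (50%) and *g* = 2 (75%) expectations.

Traits follow y = µ_t + Σᵢ (aᵢxᵢ + dᵢzᵢ) + N(0, σ²) with additive codes
x ∈ {−1, 0, +1} and dominance codes z = 1 for heterozygotes, residual noise
only (no polygenic background) — the simplest model that supports planting a
QTL with a chosen variance share: for a single additive QTL at *g* = 1,
Var(x) = ½, so a = σ·√(2R²/(1−R²)) yields a variance share R².  A planted
R² = 8% QTL realises a mean R̂² of ~9% over replicates (the +2/n fitting
bias of a 2-df regression at n = 216 accounts for the difference).

Observations emulate RAD-seq: each (line, site) pair is seen with
probability equal to the site coverage (default 0.0597); given coverage, the
read count is zero-truncated Poisson with rate 3.23 (coverage and depth are
reported separately in such designs, so depth is conditional on being
covered); each read samples one of the line's two alleles uniformly and is
flipped to a uniformly chosen different base with probability `base_error`.
The default `base_error` is 0.01, a typical post-filter Illumina
substitution-error scale.  All randomness flows from one integer seed;
identical configurations reproduce byte-identical outputs.

Population-level de novo mutations can be planted at monomorphic founder
sites (`n_population_mutation_sites`, default 0) with a per-line carrier
probability (default 0.15, giving ~32 carriers among 216 lines — safely
above the >20-line reporting rule); carriers become homozygous for a novel
allele and are recorded in the truth set.

## Site filtering and classification

Single-sample filters retain a call iff mapping quality > 20 (strict),
1 ≤ depth ≤ 300 (inclusive), and copy number < 2 (strict); among the
survivors, any call within 5 bp of another call on the same chromosome is
removed together with that neighbour (the rule is symmetric and does not
privilege either member).  Applying the attribute rules before the adjacency
rule makes the filter idempotent.  Pairwise gates on the
recipient/variant comparison require depth > 2 at homozygous variant sites
and > 6 at heterozygous ones; missing genotypes are dropped.

Classification is defined only for a homozygous recipient genotype R/R:
sample R/R → non-variant, X/X → homo-SNP, R/X → hetero-SNP, X/Y → mutation-
SNP; recipient-heterozygous sites are left unclassified and excluded from
the comparison.  The four classes partition all 40 recipient-homozygous
combinations (4 recipient homozygotes × 10 unordered sample genotypes),
which the tests verify against an independent enumeration.

Coding effects translate the reference and substituted codon with the
standard genetic code (reverse-complemented on minus-strand models); only
single-nucleotide substitutions are annotated, multi-exon CDS models are
supported, and a site under several overlapping models is non-synonymous if
it changes any of their proteins.

## Genotyping, windows and bins

Single-site genotypes come from allele counts (n_a recipient allele, n_b
variant allele) with likelihoods (1−e)^{n_a}e^{n_b}, (½)^{n_a+n_b},
e^{n_a}(1−e)^{n_b}, F2 priors (¼, ½, ¼), and a call only when the maximum
posterior exceeds 0.95.  Sites whose total read depth across the population
is not above 40 are excluded beforehand (applied as a site filter, the
conservative reading; the expected population depth under the default
design is ~42, so the filter removes the genuinely under-covered half of
the site list).  Likelihoods are computed in log space with the error rate
floored at 10⁻³⁰⁰ so a zero error rate stays well-defined.

At ~3× depth a homozygous call requires ≥ 6 concordant reads, so confident
single-site calls are too sparse to segment a chromosome.  The sliding
window therefore summarises **allele counts**: over each window of 15
consecutive sites observed in a line (step 1, at least 5 informative sites),
f_b is the fraction of reads carrying the non-recipient allele;
f_b ≤ 1−0.9 → aa, f_b ≥ 0.9 → bb, otherwise ab.  When applied to known
genotype calls, each call contributes its two alleles and the statistic
reduces to (#b alleles)/(2 × called sites) — the same rule, so error-free
full-coverage data and sparse read data go through one code path.  Boundary
fractions are compared with a 10⁻¹² tolerance so exact ratios such as 3/30
fall on the intended side.

Runs of identical window states form segments; runs shorter than 2 windows
are absorbed into the longer flanking run (ties go left) until stable.  A
breakpoint is placed at the midpoint between the flanking informative window
centres, **corrected for the threshold-crossing offset**: a 15-site window
switches into a heterozygous state once ⌊2W(1−hom)⌋+1 = 4 of its sites lie
past the crossover, but into a homozygous state only after
⌈W(2·hom−1)⌉ = 12 do, so the raw midpoint is biased ~4 sites toward the
homozygous side and heterozygous segments are systematically extended.
Subtracting the offset restores unbiasedness; on error-free full-coverage
data the bin genotypes then agree with the truth at ≥ 99% of entries, and
the mean homozygous fraction of simulated *g* = 1 populations moves from
~41% (uncorrected) to ~48% against the 50% expectation.

The union of all lines' breakpoints partitions each chromosome into
half-open bins [start, end), 1-based, length end − start (this convention
reproduces the printed bin-length arithmetic exactly and converts to BED by
subtracting one from both edges).  Every line is constant within every bin
by construction.  Recombination fractions between adjacent bins are
estimated by EM for codominant F2 markers in coupling — every two-locus cell
determines its recombinant-gamete count except the double heterozygote,
whose expected count is 2r²/(r² + (1−r)²) — and converted to centimorgans
with Kosambi's function by default (Haldane provided; the linkage package
used for the original map does not state its convention).  Estimates are
clipped at r = 0.495 before conversion so one noisy unlinked-looking pair
cannot contribute an unbounded distance.

## Population statistics

Genomic heterozygosity and mutation rates are count/covered-bases ratios.
The founder mutation-rate denominator defaults to the recipient's covered
bases (the convention that reproduces the published arithmetic; the
variant's own denominator is a configuration choice away).  Spontaneous
population mutations use the shared-homozygous-founder predicate by
default: candidate sites are those where both founders are homozygous for
the same allele G and a line is discordant if its confident call differs
from G/G; a site is reported when more than 20 lines (strict) among at
least 20 called lines are discordant.  The literal "not identical to either
founder" reading is kept as the `novel-allele` predicate, because at sites
segregating from a heterozygous founder a quarter of selfed lines
legitimately match neither founder genotype and the literal rule would count
them.  Per-line rates divide a line's discordant calls by its observed-site
count (sites with ≥ 1 read), since no line-level denominator is defined
elsewhere.

## QTL scanning

Bins are dense, so composite interval mapping is approximated by testing
each bin directly: null model intercept + cofactors, full model + the bin's
x and z columns (2 df, codominant F2), complete cases per bin (lines missing
the trait, the bin, or a cofactor genotype are dropped; no imputation),
LOD = (n/2)·log₁₀(RSS₀/RSS₁) with n the per-bin complete-case count, and
R² = 1 − RSS₁/RSS₀ = 1 − 10^(−2·LOD/n).  Background cofactors are chosen by
forward selection against the full current model (entry threshold LOD 3,
at most 10 cofactors, ties broken by genome order); during profiling,
cofactors within 10 cM of the tested bin are omitted from both models, and
bins collinear with the cofactor design are skipped with a log notice.
Genome-wide significance comes from permuting trait values across lines
(1000 permutations, threshold = the 95th percentile of the per-permutation
maximum LOD); the scan additionally reports every peak above a fixed LOD 3.5
reporting threshold, chosen so the weakest QTL the study reports (LOD 3.53)
would be reportable.  Reported peaks are separated by at least 10 cM and
carry a support interval of contiguous bins within 1.5 LOD of the peak.

## What the simulations show — and what they do not

The generator reproduces the study's *genotype-level* structure: founder
rates, Mendelian selfing, sparse low-depth observation, planted QTL variance
shares.  It does not model reference-alignment artefacts, mapping bias,
restriction-site dropout (coverage is independent across sites and lines),
indels or structural variants, crossover interference, segregation
distortion, or polygenic trait backgrounds.  Passing recovery tests
therefore validates the estimators under the stated stochastic model, not
the upstream read processing of real data.

Desk-scale runs shrink the physical genome (default `layout_scale` 0.05,
i.e. a 18.7 Mb twelve-chromosome genome) while keeping the full 1489.7 cM
genetic map, which preserves per-line crossover counts, segregation and
rate estimation exactly but compresses physical window resolution: windows
span more centimorgans than at full scale, so short double-crossover
segments are missed more often and the detected map underestimates the
simulated length (~1000 of 1489.7 cM at the default scale; the same
detection limit, milder, applies to the real design).  The test-suite's
problem sizes (10 Mb single-chromosome founder checks, 2 000-line
segregation checks, 200-replicate power and calibration runs on a
2 × 120 cM genome, n = 500 recombination-fraction recovery) were chosen so
each Monte-Carlo check resolves its 3σ band comfortably.

Statistical power context: for a QTL explaining 8% of variance at n = 216,
detection at a permutation-calibrated genome-wide 5% threshold has ~83%
power on a 240 cM genome, but requiring the global LOD peak to fall within
10 cM of the true position *and* exceed a fixed LOD 3.5 succeeds in only
~60% of replicates — peak localisation at this effect size is intrinsically
noisy, which is worth remembering when interpreting single-population QTL
coordinates.

## Numerical and convention summary

* Alleles are encoded 0–3 (A, C, G, T), missing −1; genotype codes
  0/1/2 = aa/ab/bb (A/H/B/«−» in matrix files).
* Sites and bins are 1-based; bins half-open; BED output 0-based half-open.
* EM for r̂ starts at 0.25, tolerance 10⁻⁹, ≤ 200 iterations, clamped to
  [0, 0.5].
* Permutation thresholds use QR projections per bin over all permuted
  trait vectors at once; the same seed yields the same threshold.
* Every writer stamps a header with the package version, seed and a hash of
  the scientific configuration (output paths excluded).
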