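# Methods

This note documents the statistical models behind `mmcap`, the default
parameters and their rationale, the numerical choices, and the limits of the
synthetic data generators. Problem sizes quoted here (probe counts, cohort
sizes, replicate counts) are the package's own test-design choices.

## Depth-ratio copy-number model

For probe *i* with tumor depth `t_i` and normal depth `n_i`, the log ratio is

```
r_i = log2((t_i + eps) / (n_i + eps)) - median_j r_j
```

with pseudocount `eps = 0.5` (stabilizes low-depth probes) and the median
taken over unmasked autosomal probes, which forces the diploid background to
0. Probes with normal depth below `min_normal_depth = 10` are masked: a ratio
against a near-zero denominator is dominated by sampling noise. Two analytic
landmarks pin the scale: a clonal 3-copy gain gives `log2(3/2) = 0.58` and a
clonal 1-copy loss gives `log2(1/2) = -1`. With tumor purity `p` and total
copy number `C`, the expected ratio is `log2(p*C/2 + 1 - p)`.

### Segmentation

Recursive binary segmentation: within a segment the split point maximizing
the pooled two-sample t-statistic (computed with cumulative sums, O(n) per
scan) is accepted when `t > stat_threshold = 5.0`; segments shorter than
`min_probes = 10` are not split. The threshold was chosen analytically: for
pure noise of length 500 the maximal split statistic concentrates around
3.2-3.8, while a purity-0.6 single-copy event spanning 30+ probes yields
t > 13, so 5.0 separates the two regimes with margin on both sides (verified
by simulation in the test suite: >=95% of noise-only tracks stay unsplit, and
planted breakpoints are recovered within 5 probes).

### Noise model and state calls

A 1-D Gaussian mixture (K = 1..3, chosen by BIC = -2 logL + (3K-1) ln n) is
fitted to the unmasked ratios by EM with k-means++-style restarts
(`n_restarts = 3`) and a standard-deviation floor of 1e-4 (prevents
degenerate spikes). The component with mean nearest 0 is the diploid
component; the neutral band is its mean ± z_{1-alpha/2} sd (`alpha = 0.05`).
A segment is called non-neutral when its mean lies outside the band **and**
its one-sample z-test against the diploid mean has p < alpha. State
cut-points: <= -1.6 homozygous loss, below the band loss, above the band
gain, >= 1.0 amplification — the -1.6/1.0 cut-points are the expected ratios
of clonal CN 0/4 events diluted to ~85% purity. Arm events require same-sign
called segments covering >= `min_arm_fraction = 0.6` of the arm's probes;
hyperdiploidy requires whole-chromosome gains of >= 2 odd chromosomes
(3, 5, 7, 9, 11, 15, 19, 21; q-arm only for acrocentric chromosomes).

## SV support thresholds

Candidates carry split-read (SR) and discordant-pair (PE) support. Threshold
triples `(min_sr, min_pe, min_total)` act componentwise (`sr >= s`, `pe >= p`,
`sr + pe >= t`). The retained set is monotone non-increasing in each
threshold, so the search grid only needs the observed values plus one:
`{0} ∪ {v+1 : v observed}` per axis. Tuning against labels maximizes
precision, then recall, then minimality (smallest component sum, ties broken
toward ascending `(min_total, min_pe, min_sr)`); sum-minimality implies
Pareto-minimality among optima. Normal-panel mode returns the smallest triple
retaining zero normal-sample candidates — a guarantee, not an estimate, and
verified exhaustively in the tests. Translocation classes are assigned by
breakpoint overlap with a region table (IGH, MYC, and partner loci on
GRCh37-like coordinates); intrachromosomal MYC events need >= 100 kb
separation to exclude local artifacts.

## Variant integration

Variants are dropped (with a recorded reason) when the effect is
silent/intronic/intergenic/flanking, the site lies in IGH (deliberately
excluded from somatic driver calling because AID hypermutation saturates
it), or the call is germline-flagged. Cross-run matching keys on
`(sample, chrom, pos, ref, alt)`. Detection-yield curves thin read counts
binomially (fraction `f`: `alt' ~ Bin(alt, f)`) and re-apply the detection
rule (>= 4 alt reads and VAF >= 0.05); a curve is declared plateaued at the
smallest fraction whose incremental yield falls below 2%. Clonality
summaries report per-gene VAF quantiles (linear interpolation) over variants
outside called CNVs, since copy-number changes distort VAF.

## Integrative statistics

**Fisher exact tests.** For each feature pair the 2x2 table is tested
one-sided in both directions by hypergeometric tail summation. Both raw
p-values are reported; a Benjamini-Hochberg column over min(p) is appended
for reference. Degenerate (zero-margin) tables give p = 1 and an undefined
odds ratio. Calibration note: an exact conditional test is discrete, so its
true size at n = 95 is ~0.032 at nominal alpha = 0.05, not 0.05 — no exact
test can do better without randomization. The acceptance checks therefore
compare the empirical rejection rate against the exact attainable size
(computed per table from the hypergeometric null), plus a validity bound at
the nominal level.

**Hypermutator exclusion.** Samples with mutations/Mb above Q3 + 3 IQR
(panel footprint 3.3 Mb) are excluded before association testing: a
hypermutator inflates every co-occurrence cell.

**AID signature.** WRCY / RGYW hotspot motifs (W = A/T, R = A/G, Y = C/T)
are scanned with overlap-preserving regex lookahead; the mutable base is the
C at offset +2 (forward) or the G at offset +1 (reverse-strand footprint).
The null probability is the fraction of C/G positions inside a motif;
enrichment is the exact upper binomial tail P(X >= observed).

**Survival.** Kaplan-Meier product-limit curves; the two-group log-rank test
(observed-minus-expected with hypergeometric variance at each event time);
Cox proportional hazards for one binary covariate with Breslow tie handling,
maximized by Newton iteration on the log hazard ratio with steps clipped to
±2 (guards the first iterations when a group is small), Wald 95% CI. When
either group has no events the estimate diverges and is flagged
non-estimable. All three are implemented in-repo so the oracle tests
(hand-computed product limits, permutation nulls, grid-search partial
likelihood, and cross-checks against `lifelines`) exercise the real code
paths.

## Synthetic generators and their limits

Depths are Gamma-Poisson (negative binomial): mean `m`, variance
`m(1 + d m)` with dispersion `d` (`d = 0` is Poisson). Defaults
`mean_depth_tumor = 104`, `mean_depth_normal = 107`, `d = 0.002` give a
per-probe log-ratio sd of ~0.22, a realistic normalized-capture noise level.
Tumor probe means are scaled by `purity*CN/2 + (1 - purity)`. Mutation
matrices plant pairwise log-odds via the Plackett copula joint for the 2x2
cell probabilities (infeasible marginal/odds combinations are rejected with
the attainable bound). Survival times are exponential with rate
`baseline * HR^x` and independent exponential censoring. AID sequences plant
WRCY 4-mers (in deficit-sized batches, one motif scan per batch) until a
target hotspot density is reached.

Limitations: probes are evenly tiled (no GC or mappability structure); depth
noise is exchangeable across probes (no wavy background); copy-number events
are clonal with a single global purity (no subclones); SV support is Poisson
without mapping-quality structure; survival has no covariate-dependent
censoring. These generators are designed to give planted, recoverable ground
truth for testing — not to emulate every artifact of real capture data.

## Reproducibility

Every stochastic routine draws from `SeedSequence([root_seed,
crc32(stream_name)])`, so results are exactly reproducible from a single
root seed (valid range [0, 2^31)) and independent across named streams. The
demo pipeline writes a SHA-256 manifest (`checksums.json`) over all outputs;
rerunning with the same seed reproduces it bit-for-bit.
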