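# Methods

This note documents the models and numerical choices behind `mbddmr`: what
is assumed, what is tunable, and what the synthetic-data tests do and do not
establish about real MBD-Seq data.

## The measurement model

MBD-Seq reads out methylation indirectly: genomic DNA is fragmented to
roughly 200 bp, fragments carrying methylated CpGs are enriched by a
methyl-CpG-binding domain protein, and the captured fragments are paired-end
sequenced. The number of read pairs whose insert overlaps a genomic interval
("probe") is therefore a monotone proxy of that interval's methylated-CpG
content. The analysis treats per-probe, per-sample pair counts as negative
binomial:

    y_gi ~ NB(mu_gi, phi_g),    log mu_gi = x_i' beta_g + log(L_i f_i)

where `L_i` is the sample's kept-pair library size, `f_i` its TMM
normalization factor, `x_i` encodes the design (arm membership, or the full
strain x treatment 2x2), and `phi_g` the probe's overdispersion (`phi = 0`
is the Poisson limit). Positive log2 fold change is always oriented
control-over-DEHP: hyper-methylated in controls, equivalently de-methylated
under exposure.

## Probe design and filtering

* Genome tiles: consecutive 2.2 kb windows exactly partitioning each
  chromosome (final partial tile kept). Each tile gets a single feature by
  the priority promoter > exon > intron > enhancer > intergenic.
* Promoter probes: 2 000 bp transcriptionally upstream through 200 bp
  downstream of the TSS, where the TSS (the first transcribed base) counts
  as the first downstream base; minus-strand windows are mirrored, and
  windows are truncated at chromosome edges. This is deliberately a broad,
  operational promoter definition.
* Selection: a probe is analyzed iff it contains at least one CpG —
  counting CpGs that exist only in one strain because of a SNP — and has
  more than 3 read pairs in more than 2 samples (read strictly: >=4 pairs in
  >=3 samples, pooled over all arms). Both thresholds are configurable.
* Read-pair filtration precedes counting: a pair is dropped if its two reads
  map to different chromosomes or face each other across more than 600 bp
  (inner gap between facing read ends; overlapping reads are concordant), if
  it maps to multiple positions, or if its insert contains no CpG of the
  sample's own strain. Rules apply in that order and each rejection is
  attributed to the first failing rule, so tallies are conservative by
  construction. The "space between reads" criterion is interpreted as the
  inner gap rather than the outer span — with 2x50 bp reads these differ by
  100 bp — and the cutoff is exposed as configuration.

## Counting rules

The counted unit is the insert (fragment), since MBD captures fragments.
Disjoint genome tiles use midpoint counting (each kept pair increments
exactly one tile, making per-sample column sums equal kept-pair counts — a
tested conservation law). Promoter windows may overlap each other, so they
use any-overlap counting (a pair increments every probe its insert touches);
consequently promoter counts stochastically dominate midpoint counts.

## Normalization

TMM (trimmed mean of M-values): the reference sample is the one whose 75th
count-proportion percentile is closest to the across-sample mean; per
sample, log2 count-proportion ratios against the reference are doubly
trimmed (30% of M-values and 5% of A-values from each tail) and averaged
with inverse delta-method-variance weights; factors are rescaled to
geometric mean 1 and enter the GLM as offsets `log(L_i f_i)`. Trimming makes
the factors robust to a minority of genuinely differential probes; with a
large one-sided differential fraction (upwards of ~20% of probes) the
trimmed mean is partially contaminated and fold changes shrink slightly —
the recovery tests therefore embed truth probes in a realistic minority
(5%).

## Dispersion estimation

The common dispersion maximizes the Cox–Reid adjusted profile likelihood
(APL: the NB profile log-likelihood minus half the log-determinant of the
weighted information, which corrects the downward bias of plugging in
fitted means) summed over all non-zero probes, via bounded scalar
optimization on the log scale. Per-probe dispersions use weighted-likelihood
empirical Bayes on a 31-point log-spaced grid from 1e-5 to 5: probe g
maximizes `APL_g(phi) + w * mean_g' APL_g'(phi)` with prior weight `w = 10`
(configurable), followed by parabolic interpolation around the grid argmax.
Single-probe dispersion estimates at five samples per arm are far too noisy
to stand alone, and letting them drift measurably inflates the type-I error
of the downstream tests; the strong pull toward the pooled likelihood keeps
the null calibration inside its binomial band (a tested property) while
still letting strongly discrepant probes move.

## Testing

Per-probe GLMs are fitted by Fisher scoring, vectorized across probes
(batched p x p solves; initialization from least squares on shifted log
counts; steps clipped to ±5; linear predictors clipped to ±30 around the
offset; convergence at 1e-10 max step). Two-group and interaction tests are
likelihood-ratio chi-square tests with 1 df between nested fits at the same
dispersion. Probes with zero counts everywhere are reported with p = 1 and
log2FC = 0, not dropped; when one arm is all-zero the reported fold change
falls back to a prior-count formula `log2((m_A + 0.125)/(m_B + 0.125))` on
normalized means — a display convention that never enters the likelihood.

A conditional exact test is provided for two-group comparisons with
(approximately) equal effective libraries: conditioning on the probe's total
count, the arm-A sum follows the distribution of an NB(n_A/phi) versus
NB(n_B/phi) split — binomial in the Poisson limit — and two-sided p-values
sum all outcomes no more likely than the observed one. At phi = 0 this
reproduces direct binomial enumeration to machine precision (a tested
oracle); the chi-square LRT agrees with it closely in the bulk but, being an
asymptotic approximation, is not held to tail-exactness.

Calling: genome-wide tiles require |log2FC| > 1 and unadjusted p < 1e-2
(the tile analysis is a descriptive genome-wide picture, not a
target-identification screen); promoter probes require |log2FC| > 1 and
p < alpha/m (Bonferroni over the m selected promoter probes, 0.05/22 480 ≈
2.2e-6 at the real study's scale). The interaction contrast
`Z = (s1.control − s1.dehp) − (s2.control − s2.dehp)` is the interaction
coefficient of the saturated 2x2 GLM (log2 scale); because the model is
saturated, Z equals the difference of the two stratified per-strain log2
fold changes exactly (a tested identity). Interaction results carry both
Benjamini–Hochberg FDR and the Bonferroni genome-wide flag.

## Power statistics

The minimal detectable group-mean difference solves
`power(delta) = P(|T'| > t_{1-alpha/2, 2n-2})` with `T'` noncentral t at
`ncp = delta / (sd sqrt(2/n))`, by bracketing and Brent root-finding to 1e-6
relative tolerance. The equal-variance df = 2n−2 is the conventional choice
for the power solve; observed data are tested with Welch's statistic and
Satterthwaite df. At n = 8 per group, sd = 3, alpha = 0.05 and power 0.80
the solve gives 4.52, i.e. 4.5 to one decimal (reports elsewhere that round
to 4.4 are within rounding of the same computation). Display rounding for
concentration-scale quantities is one decimal; raw values are retained.

## The synthetic-data generator

The generator exists so that every stage has known truth; it emulates the
study conditions at desk scale.

* **Genome**: random sequences in which every CpG is planted explicitly
  (accidental CGs from the random background are removed first), at
  `background_cpg_rate` genome-wide (default 0.008/bp, near the
  CpG-depleted mammalian genome average) and `cpg_island_rate` in promoter
  windows (default 0.04/bp, mimicking CpG-island enrichment). Gene symbols
  include configurable fractions of Vmn/Olfr/Mir names (defaults 10/15/15%)
  to exercise class aggregation. Defaults: 2 chromosomes x 110 kb, 30
  genes.
* **Variants**: homozygous SNPs at `snp_rate` (default 0.002/bp, the
  order of the ~4.9 M SNPs between C57BL/6J and FVB/N over the mouse
  genome), a `frac_cpg_affecting_snps` share (default 0.2) placed to create
  or destroy a CpG (half each); flags are recomputed from the sequence, not
  trusted from placement intent; simulated depth Poisson(30)+3. Indels are
  excluded from CpG logic.
* **Methylation**: per-CpG baseline probabilities Beta(4,4) clipped to
  [0.02, 0.98], shared across arms; methylation states are drawn per
  fragment per CpG — the simplest generative model consistent with bulk
  capture of a cell population.
* **Capture**: a fragment with k methylated CpGs is retained with
  probability `p_bg + (p_max − p_bg) · k/(k + k_half)` (defaults 0.01,
  0.95, 2). The saturating Michaelis–Menten form is this package's
  assumption — motivated by MBD binding to short (~12 bp) methylated
  footprints, so capture cannot grow without bound in k — not an inference
  about any commercial kit. Fragment lengths are truncated normal
  (200 ± 30, clipped to [80, 400]); 2x50 bp reads are emitted at the
  fragment ends. Library sizes vary log-normally (CV 0.2 by default) around
  `target_pairs_per_sample` (default 5 000 — thousands instead of the
  12–15 M pairs of a real library, chosen so full-pipeline simulations are
  routine); small configured fractions of pairs are flagged multi-mapped
  (2%) or displaced into discordance (1%) purely to exercise filtration.
* **Truth injection**: inside each truth region the control/DEHP logits are
  shifted by ±delta/2, with delta solved by Brent iteration so that the
  expected capture rate of fragments whose midpoints fall in the region
  differs by the requested log2 fold change between the arms. The
  expectation is exact over methylation states (Poisson-binomial dynamic
  program per fragment) and Monte-Carlo over 400 fragment placements held
  fixed across iterations (common random numbers), so the generator is
  deterministic given the seed. The realized expected-count log-ratio is
  recorded per strain on each truth record; interaction regions flip the
  shift's sign in the second strain. Because downstream promoter counting
  is any-overlap rather than midpoint, realized count ratios in the
  analysis can deviate from the injected value by edge effects of order a
  fragment length over the region length (~10%); recovery tests use this
  tolerance. Default truth regions are promoter windows of non-class genes,
  kept mutually disjoint with a 500 bp margin so effects cannot cancel.

What passing these tests shows: the pipeline's bookkeeping is exactly
conservative, its test statistics are calibrated under the generator's NB
world, and injected effects of the magnitude the thresholds target (4-fold)
are recovered with correct sign and genome-wide significance at depths of a
few thousand pairs per sample. What it does not show: robustness to
features the generator omits — base-call errors, mapping bias, PCR
duplicates, copy-number variation, batch structure, hydroxymethylation
(invisible to MBD capture distinctions), or fragment-size selection
artifacts.

## Simulation scales used in the checks

Statistical calibration checks run at 2 000–10 000 probes with 5 samples
per arm: type-I error at mean 100 and phi = 0.05 (p < 0.01 fraction within
the 99% binomial band), dispersion recovery at phi = 0.2 (common estimate
in [0.15, 0.25]), fold-change recovery with 500 truth probes among 10 000
(median within 2 ± 0.15 of the injected 2.0), and interaction recovery with
100 opposite-effect probes among 2 000 (>90% pass Bonferroni at m = 10 000;
after permuting strain labels within treatment — with dispersion honestly
re-estimated on the permuted data — at most 5% of truth probes stay below
p = 0.05). End-to-end runs use the generator defaults above at ~2 000 pairs
per sample. These sizes are the package's standing validation conditions;
the same machinery runs unchanged at larger scales.

## Known limitations

* The NB stack reproduces the behavior of the reference edgeR framework
  closely (tested: identical common dispersion to ~1e-4, log2FC within
  0.05, Spearman rho of p-values > 0.98 on a shared fixture) but is not a
  re-implementation of its exact trimming and shrinkage details, so
  numerical identity with analyses run in edgeR is not expected.
* The exact test assumes equal effective library sizes across samples
  within the two arms; it is intended as an oracle and a small-sample
  fallback, not the default path.
* Quasi-likelihood F-tests, covariates beyond the 2x2 design, and
  hydroxymethylation are out of scope.
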