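# Methods

## The replicate-free exact test

Each of the eleven samples is a single library, so no per-gene dispersion can
be estimated. The test therefore assumes a common biological coefficient of
variation, default BCV = 0.4 (a conventional value for inter-individual
variation in well-controlled animal experiments), giving a negative-binomial
dispersion φ = BCV² = 0.16 and variance μ + φμ² for a count with mean μ.

For one gene and one contrast with counts (y₁, y₂) and library sizes
(n₁, n₂):

* s = y₁ + y₂, pooled relative abundance p̂ = s/(n₁+n₂);
* under the null both counts are NB with means p̂n₁ and p̂n₂ and dispersion φ;
* the conditional law of Y₁ given Y₁+Y₂ = s is obtained by normalizing
  f(y; p̂n₁, φ)·f(s−y; p̂n₂, φ) over y = 0…s;
* the two-sided p-value sums the conditional probabilities of every
  partition whose probability is ≤ that of the observed y₁, counting ties at
  a relative tolerance of 1e−7 (the convention used by exact binomial
  tests); the p-value is capped at 1.

Unequal library sizes enter through the unequal conditional means; no
pseudo-count equalization is applied. This formulation is exhaustively
enumerable, which is what the test suite exploits: the implementation (log-
space, vectorized gamma-ln arithmetic) is checked to 1e−10 against a pure
Python brute-force enumeration for every partition of every total ≤ 40, at
two library-size configurations and BCV ∈ {0, 0.4}. With BCV = 0 the
conditional distribution is exactly Binomial(s, n₁/(n₁+n₂)), which provides
a second, closed-form oracle. Totals above 10⁶ (never reached at bulk
RNA-seq depth for a single gene) fall back to a normal approximation of the
conditional distribution, with a loud log message.

The log fold change is reported as
log₂[((y₁+0.5)/(n₁+1)) / ((y₂+0.5)/(n₂+1))]; the +0.5/+1 guard keeps it
finite for zero counts. Only its **sign** is consumed by the screen (the
ovary-up direction requirement); no fold-change thresholding is done on it.

FDR control is Benjamini–Hochberg (step-up), applied per contrast across all
genes, delegated to `statsmodels.stats.multitest` and property-tested
against a direct step-up implementation.

An optional TMM (trimmed mean of M-values) effective-library-size mode
(doubly trimmed 30 % on M / 5 % on A, precision-weighted, geometric-mean
rescaled) is available behind a flag for the exact-test stage only; the
default uses raw column totals.

## Normalization

RPKM(g, s) = 10⁹·c(g,s)/(N_s·L_g), with N_s the column sum and L_g the
transcript length in nucleotides (summed exon lengths when read from GFF3,
whose coordinates are 1-based inclusive). Zero counts give exactly zero
RPKM; the pseudocount used by ratio statistics is a *substitution* for zeros
at the point of use, never an additive offset and never applied during
normalization — an additive offset would distort ratios for small non-zero
values. A consequence of N being the realized column sum is the identity
Σ_g RPKM(g,s)·L_g = 10⁹ for every sample, which the tests assert exactly.

## The screen

* **Intersection**: FDR ≤ α (boundary included) and logFC > 0 in all four
  contrasts. The ovary-up requirement is a deliberate addition — a
  tissue-specificity screen wants enrichment, not mere difference — and can
  be disabled.
* **Ratio filter**: ovary RPKM over the mean of the four off-target RPKMs,
  zeros substituted by `pseudocount` (default 0.1), pass iff strictly
  \> `fold_threshold` (default 100).
* **Follicle-cell flag**: 0–1 hr embryo RPKM < `embryo_min_rpkm`
  (default 1.0, strict <). Somatic follicle cells express in the ovary but
  do not load the oocyte, so absence of signal in freshly laid embryos
  despite strong ovary expression marks them. The 1.0 RPKM default is a
  declared choice — "no expression" needs a number to be testable — and is
  configurable and recorded in the run summary.
* **Zygotic flag**: RPKM at any embryo window > `zygotic_fold` (default 2.0)
  × the previous window (zero predecessors substituted) flags renewed
  transcription from the embryo's own genome against the expected maternal
  decay; the first implicated interval is reported. Flagged genes are
  annotated, never removed: maternal deposition plus zygotic re-expression
  is still germline expression.
* **Blood-meal class**: PBM/previtellogenic ovary RPKM fold > 2 → "up",
  < 1/2 → "down", else "same".
* **Final call**: strict-intersection member and not follicle-flagged.

The per-gene table is emitted in a fixed, documented column order and the
summary reports the five headline counts in screen order (strict, relaxed,
ratio, ratio∩strict, final) plus the fraction of strict-set genes whose
*maximum* off-target RPKM is below 11 and below 5 (the maximum-based reading
of off-target leakage).

Genes expressed in tissues outside the eleven-sample design (e.g. testes)
are invisible to this screen; the final call is a first approximation by
construction.

## Synthetic data

The generator is deliberately well specified for the test: counts are drawn
NB(μ, φ = BCV²) via the gamma–Poisson mixture with μ = rpkm·L·N/10⁹, i.e.
the same noise family the exact test assumes, so recovery failures indicate
pipeline defects rather than model mismatch. (A misspecified regime can be
probed by generating with a different BCV than the screen assumes.)

Default composition, 5,000 genes: 200 germline-maternal, 20 follicle-cell,
30 maternal+zygotic, 50 zygotic-only, 4,500 housekeeping, 200 silent.
Library sizes are fixed per role between 5 M and 20 M reads; transcript
lengths are uniform on 500–5,000 nt; peak expression levels are log-uniform
(50–1,000 RPKM for ovary classes, 5–100 for housekeeping, 20–500 for
zygotic-only). Class profiles: germline genes deposit 0.8× their ovary level
into the 0–1 hr embryo, decaying by 0.5 per window; the whole-female sample
receives 0.25× the ovary level on top of background (it contains the ovary,
which is why it is not a contrast sample); off-target leakage is 0.5 RPKM
for germline classes and zero for follicle-cell; the maternal+zygotic class
deposits 0.5× and adds 1.5× from its onset window; each ovary gene draws a
blood-meal factor log-uniform on (0.25, 4) so all three response classes
occur. A per-gene truth table carries the class, the true per-sample RPKM,
and the analytically expected screen outcome (a gene is expected in the
strict set when its true ovary RPKM is ≥ 5 and ≥ 10× every contrast
sample's true level — under the defaults this separates the classes
unambiguously).

Two scale effects are worth knowing. First, the generator's `rpkm`
parameters are relative abundances on a 10⁹ scale; realized RPKM is computed
against the realized column sum, so its absolute scale depends on the total
transcriptional output of the simulated gene set (as in real RNA-seq).
Second, with NB noise on off-target counts the realized >100-fold set is
smaller than the truth-level one (about 210 of 250 at the default seed) —
the fold filter is noisier than the exact test, which is precisely why it is
a secondary statistic.

What the generator does **not** emulate: read-level artifacts (positional/GC
bias, multimapping), isoforms, correlated gene modules, and composition
shifts beyond those induced by the planted classes. Passing recovery tests
therefore demonstrates the pipeline's correctness under its stated model,
not robustness to every real-data pathology.

## Quantification

ddPCR: λ = −ln(1 − positives/total droplets) copies per droplet; saturated
wells (all positive) are an error, not infinity. Ratios of λ between target
and reference assays on the same cDNA cancel the droplet volume. Knockdown
is 100·(1 − mean transgenic ratio / mean control ratio), averaging
per-individual ratios (the ratio-of-group-means alternative is exposed as a
flag). The significance test is Welch's unequal-variance t on the
per-individual ratios — robust at the n = 4–8 group sizes typical of these
experiments, and swappable.

ΔΔCt: ΔCt = Ct_target − Ct_reference per sample, ΔΔCt relative to the single
flagged calibrator, RQ = 2^(−ΔΔCt); the calibrator's RQ is set to exactly 1
(not merely approximately, avoiding float residue). Amplification-efficiency
corrections are out of scope.

## Problem sizes and determinism

The test suite and the acceptance script run entirely on generated data: the
full screen on the 5,000-gene default dataset (~10 s), a 5,000-gene null
calibration, and oracle enumeration up to totals of 40. Identical inputs and
configuration produce byte-identical output tables; all randomness derives
from explicit seeds, and every CLI run writes a manifest with input digests
and the configuration actually applied.

## Known limitations

* The exact test's unequal-mean conditioning is asymptotically, not
  numerically, identical to quantile-adjusted pseudo-count equalization;
  gene-level decisions near the FDR boundary can differ between the two
  conventions by a few genes on real data.
* The BCV is a single global assumption; genes with unusually high
  biological variability will be anti-conservative.
* The follicle-cell and zygotic thresholds quantify judgments that are
  ultimately biological; both are configurable and logged.
* The ortholog Venn partition only summarizes a user-supplied membership
  table; it cannot validate the upstream ortholog inference.
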