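# Methods

## Scope

`gwascnn` is an analysis pipeline for case-control genotype classification:
summary-statistics-driven SNP selection → minor-allele additive encoding →
a small 1D CNN classifier → Grad-CAM per-SNP attribution → negative
controls → a clumped polygenic-score baseline. Real clinical genotype
cohorts of this design are access-restricted, so the package's claims are
established on synthetic cohorts with planted ground truth; this note
records the generative model, the tunable parameters, and the design
decisions taken where the methodology was genuinely open.

## Synthetic cohort model

**Genotypes.** Each SNP n has a minor-allele frequency q_n ∈ (0, 0.5].
Genotypes are drawn from a latent-Gaussian copula: a standard-normal
latent z_n is cut at the Hardy-Weinberg quantiles Φ⁻¹((1−q)²) and
Φ⁻¹(1−q²), giving minor-allele counts 0/1/2 with HW frequencies. SNPs
sharing an LD block draw their latents with equicorrelation
`ld_block_r` (one common factor per block), which induces a tunable
genotype r² verified in the tests against a brute-force Monte-Carlo draw
of the same copula. This produces block-wise LD without phased haplotype
machinery; it does not model recombination-map decay, population
structure or admixture.

**Phenotype.** Disease status is prospective-logistic and purely additive:
P(case | g) = σ(β₀ + Σ_n β_n g_n) with β_n the per-minor-allele log odds
ratio. The study design is retrospective case-control, so fixed quotas
(`n_cases`, `n_controls`; default 872/5,486) are filled by rejection
sampling conditional on simulated status. The intercept β₀ is bisected so
the population prevalence is ≈ 5% before conditioning (configurable;
keeps rejection sampling efficient). A pathological intercept that cannot
fill a quota in a bounded number of draws raises an error naming the
achieved prevalence.

**Effect spectrum.** Default panels place `n_causal = 20` causal SNPs
among `n_snps = 2,000`, with MAF ~ U[0.1, 0.5] and |log OR| ~
U[ln 1.3, ln 2.0] with random sign — the magnitude range of replicated
susceptibility loci for a common arrhythmia phenotype (detected-locus ORs
of roughly 0.32–2.01 at MAF 13–50%). Null SNPs have log OR exactly 0.

**Missingness and covariates.** Genotype calls are set missing
completely at random at `missing_rate` (default 1%; real chip-QC'd
missingness mechanisms are not modeled). Age is Normal(50.4, 7.9) for
cases and Normal(55.6, 8.6) for controls; P(male) is 0.805 / 0.455 —
the demographic imbalance of an early-onset ablation-referral case group
against population controls. Covariates never feed the genotype model;
they exist to exercise propensity-score matching.

**Reference summary statistics.** `simulate_summary_stats` draws an
*independent* cohort from the same variant panel (default 3,000/3,000)
and publishes its association scan as the external GWAS. Null SNPs
therefore carry asymptotically uniform p-values, so the p ≥ 0.99
negative-control subset always exists at scale.

What passing tests on these cohorts do **not** show: robustness to
population stratification, imputation artefacts, non-additive
(dominance/epistatic) effects, or cross-ancestry transfer of weights —
none of which the generator emulates.

## Pipeline stages

**Harmonization.** External records are matched to cohort variants by
rsid (chips of this family share rsid namespaces; position is used only
for ordering). An effect allele equal to the cohort minor allele keeps
its OR; equal to the major allele, the OR is inverted ("flipped");
strand-ambiguous A/T and C/G pairs are dropped outright — the
conservative standard, since frequency-based strand resolution is
unreliable near MAF 0.5. Feature sets use strict `p < t` for thresholds
(grid 5e-8 … 1e-3) and `p ≥ 0.99` for the control rule; sets are ordered
by (chrom, bp), so stricter sets nest inside looser ones and the control
set is disjoint from every threshold set.

**Encoding.** The model consumes raw codes {−1, 0, 1, 2}; −1 (missing)
is fed as-is with no imputation, and inputs are not standardized — the
codes are small, same-scale integers and the additive dose is the signal
itself. The minor allele is designated from the pooled study cohort (not
an external reference); exact-0.5 ties break lexicographically by allele
character so encoding is deterministic.

**Association scan.** Per SNP, a single-predictor logistic regression of
status on minor-allele count (missing excluded), implemented as a
Newton-Raphson vectorized across SNPs in column chunks — the per-SNP
score and 2×2 information are accumulated simultaneously for all SNPs,
which is ~100× faster than a model-object loop at 10³–10⁴ SNPs and is
cross-checked against statsmodels GLM in the tests. Wald intervals and
p-values are reported (deterministic, and the standard output format for
this table shape); monomorphic or separated columns fall back to the
allelic 2×2 cross-product OR with a two-sided Fisher exact p, applying
the Haldane-Anscombe 0.5 correction only when a cell is empty (the
uncorrected cross-product is exact otherwise). No covariate adjustment
or multiple-testing correction happens inside the scan; thresholds are
applied downstream.

## Classifier

Architecture: input N×1 → Conv1D(`n_filters`, `kernel_size`, stride 1,
ReLU) → flatten → dropout → Dense(`fc_units`, ReLU) → sigmoid unit.
Training minimizes class-weighted binary cross-entropy (inverse-frequency
weights by default — the cohort is ~1:6.3 imbalanced; toggleable) with
Adam (lr 1e-3), evaluates validation loss each epoch with the same
weighting, stops after `patience` = 10 epochs without improvement
(`max_epochs` = 200) and restores the best-epoch weights. All randomness
(init, shuffling, dropout masks) flows from one `ModelConfig.seed`, so a
fixed seed reproduces the training history exactly. The network,
backpropagation, Adam, MC dropout and the Grad-CAM gradient are written
directly on NumPy arrays: the model is two hidden layers, and exact
control of the analytic gradient at the conv feature map is what the
attribution consumes.

Defaults: `n_filters = 16`, `kernel_size = 2`, `fc_units = 32`,
`dropout_rate = 0.5`, `batch_size = 128`. Two observations fixed these:
(a) per-SNP attribution resolution — a width-k receptive field smears the
Grad-CAM peak over ±(k−1)/2 SNPs, and k = 2 keeps single-SNP localization
sharp after center-anchored linear upsampling; (b) trainability on
weak-signal panels — a wider flatten→dense head (32 filters × 64 units ≈
10⁶ parameters at 500 SNPs) memorizes the training partition before the
validation loss ever improves, so early stopping returns near-initial
weights; halving both layers and doubling the batch makes the validation
signal reliably precede overfitting. All sizes remain exposed in
`ModelConfig`; none of these defaults is a claim about any previously
published architecture.

Splits are stratified 64/16/20 (test 20% first, then 80/20 of the
remainder), re-shuffled per repeat with a repeat-specific seed; five
repeats by default. The decision threshold for sensitivity/specificity is
the Youden-J optimum on the validation partition, frozen for test.
Baselines: the trained CNN under Monte-Carlo dropout at rate 0.5 with 100
forward passes (Bayesian approximation), and L1-penalized, L2-penalized
and unpenalized logistic regression (scikit-learn); a singular
unpenalized fit falls back to a near-zero ridge penalty and is flagged,
not fatal.

## Saliency

Grad-CAM is taken at the pre-sigmoid score (avoids vanishing gradients at
saturated outputs): α_k = mean_u ∂y/∂A^k_u, L_u = ReLU(Σ_k α_k A^k_u).
L (conv-output length) is upsampled to the N SNPs by linear interpolation
with each conv position anchored at its receptive-field *centre*
u·stride + (k−1)/2 — anchoring at the left edge biases the peak left by
half a kernel. Saliency is computed over the true cases by default
(toggleable to all samples); per-SNP means are divided by their maximum,
so the top SNP scores exactly 1.0 whenever any score is nonzero.
The comparison against the association scan caps −log10 p at 50 (p-values
underflow long before saliency resolution matters) and reports a
zero-variance correlation as undefined rather than NaN. Note that this
correlation is only informative on wide panels with a broad p spectrum;
on a panel of a few dozen uniformly significant SNPs its value is
dominated by within-panel noise and can sit near zero even when every
top-saliency SNP is causal.

## PRS baseline

Greedy p-value-ordered clumping: candidates below the threshold are
visited best-p first (ties broken by chrom, bp, rsid, so the result is
independent of input row order); each index SNP removes remaining
candidates on the same chromosome within ±250 kb (inclusive,
index-centred) whose genotype r² with it exceeds 0.1. The LD reference is
the analysis cohort's own genotype matrix. Scores are Σ w_i g_i with
w = harmonized log OR; missing genotypes contribute their expectation
2·MAF (the standard scoring behaviour of the usual tooling).

## Metrics and controls

AUC uses the Mann-Whitney rank formulation with average-rank tie
handling, verified against the all-pairs definition; Gini ≡ 2·AUC − 1 by
construction. Log-loss clips probabilities at ε = 1e-7 — unbounded losses
from saturated mispredictions are real but untestable, so the clip is
declared rather than hidden. The parity control replaces labels with
registration-index parity (balanced by construction for consecutive
indices) and must sit at chance; the null-SNP control re-runs the whole
cycle on the p ≥ 0.99 subset and must also sit at chance on truly null
synthetic SNPs. Propensity matching fits status ~ age + sex, then greedily
1:1 nearest-neighbour matches on the logit without replacement, caliper
0.2 pooled SD (standard practice), warning if >20% of cases go unmatched.

## Reproducibility and problem sizes

Every stage seed derives from one master seed via
`SeedSequence([master, stage_counter]) % 2^31`, recorded with input
SHA-256 fingerprints in a run manifest; replay re-runs the experiment and
rewrites all metric JSONs byte-identically (canonical sorted-key
serialization). The shipped validation suite runs at the study's own
sample size (6,358 subjects) on panels of 150–2,000 SNPs with reference
cohorts of up to 6,000 — sizes at which every planted-truth check
(calibration within 3 SE, KS uniformity of null p-values, top-rank
saliency recovery) is statistically sharp while the whole suite completes
in minutes on one CPU. Simulator calibration checks run on LD-free panels:
with LD, the *marginal* per-SNP estimate of a null SNP correlated with a
causal neighbour is legitimately nonzero, which would conflate LD
tagging with miscalibration.

## Known limitations

* The generator's LD is block-equicorrelated, not map-based; clumping
  behaviour on realistic decay patterns is untested.
* Missing genotypes are MCAR; informative missingness would bias both
  the scan and the −1-coded CNN input in ways the suite cannot see.
* The CNN's advantage over linear baselines cannot appear under this
  generator — the planted signal is additive by construction, so CNN and
  PRS land in the same AUC band; the pipeline demonstrates *capability
  and honesty* (controls at chance, attribution on the causal loci), not
  architectural superiority.
* Single-threaded NumPy training: panels beyond ~10⁴ SNPs per feature
  set are out of intended scope.
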