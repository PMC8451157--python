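# Methods

This document describes the statistical methods implemented in
`methylrestore`. The package analyses placental DNA-methylation studies
with three sample groups — never-smokers, smokers randomised to placebo,
and smokers randomised to vitamin-C supplementation — and asks whether
supplementation restores smoking-associated methylation changes toward
the never-smoker state.

## Notation

Beta values `b ∈ (0,1)` are the methylated fraction at a CpG probe.
M-values are `M = log2(b / (1 − b))` after clipping `b` to
`[eps, 1 − eps]` (default `eps = 0.001`). Statistical testing is done on
the M scale, where variance is approximately independent of the mean;
effect sizes are reported on the beta scale, where they are
interpretable as methylation differences. Group contrasts are
`PN` (placebo − never-smoker: the smoking effect) and
`VP` (vitamin-C − placebo: the supplementation effect).

## Probe quality control (`methylrestore.qc`)

Probes are removed by six rules, applied in a fixed order with
first-match attribution: non-CpG probes, probes with bead count `< 3`
(or missing) in at least 5 % of samples, probes overlapping SNPs,
probes with detection `p > 0.01` in any sample, cross-reactive probes,
and probes on sex chromosomes. The filter report retains both the
first-match attribution (a partition of the removed probes) and the full
per-rule match sets, so audits and planted-failure recovery checks can
distinguish the two.

## Reference-free cell-type deconvolution (`methylrestore.decon`)

Bulk beta values are modelled as a convex mixture
`B ≈ M Ωᵀ` where `M` (probes × k) holds cell-type methylation profiles
in `[0,1]` and each row of `Ω` (samples × k) lies on the probability
simplex. The model is fit by alternating constrained least squares on
the top-variance probes: profiles are solved per probe with box
constraints, proportions per sample with an exact active-set simplex
solver. `k = 1` reduces to the row-mean profile in closed form.

The number of components is chosen by bootstrap cross-validation:
for each candidate `k`, samples are resampled with replacement, the
model is fit on the bootstrap sample, and held-out (out-of-bootstrap)
samples are scored by Gaussian deviance
`mean_p( log σ̂²_p + r²_p / σ̂²_p )` with per-probe variances `σ̂²_p`
frozen from the bootstrap fit. Unlike plain held-out squared error —
which decreases weakly in `k` because extra frozen-profile columns only
widen the attainable span — the deviance penalises the understated
training variances of an overfit `k` and attains its minimum at the
true component count. Ties are broken toward smaller `k`.

Because components are identified only up to permutation,
`align_components` matches estimated to reference columns by minimising
total absolute error over permutations before computing the mean
absolute error of proportions.

## Probe-level EWAS (`methylrestore.ewas`)

Each probe's M-values are regressed on group indicators plus
covariates (infant sex, gestational age centered, and `k − 1` of the
`k` estimated cell proportions) using Huber M-estimation
(tuning constant `c = 1.345`, MAD scale). The variance estimate is the
ψ-based robust variance with the standard finite-sample correction
`K² / mean(ψ′)²`, `K = 1 + (p/n)·var(ψ′)/mean(ψ′)²`, paired with the
classical `(XᵀX)⁻¹` covariance.

Per-probe variances are then moderated with an empirical-Bayes
scaled-inverse-chi-square prior fit by method of moments on `log s²`
(trigamma inversion). The posterior variance
`s²_post = (d0·s0² + d·s²) / (d0 + d)` yields moderated t statistics
with `d0 + d` degrees of freedom. When the observed spread of `log s²`
does not exceed chi-square sampling noise, `d0 = ∞` and every probe is
assigned the point-mass variance `s0² = exp(mean log s²)`.

Multiple testing uses Bonferroni (`min(1, m·p)`) and
Benjamini–Hochberg FDR. Genomic inflation is
`λ = median(χ²_obs) / 0.4549…` computed from two-sided p-values.
Models are fit on both scales: M for inference, beta for effect sizes.

## DMR calling (`methylrestore.dmr` via `combp`)

Differentially methylated regions are called comb-p style from the
probe-level p-value track:

1. The autocorrelation of probit-transformed p-values is estimated in
   50-bp distance bins up to 500 bp (negative estimates truncated at 0,
   empty bins inherit the previous bin).
2. Each probe's p-value is smoothed by the Stouffer–Liptak–Kechris
   combination of its neighbours within the window, using the binned
   ACF as the correlation model (Cholesky with diagonal repair for
   non-positive-definite blocks).
3. Regions are grown seed-and-extend: probes with smoothed `p` below
   the seed threshold (default 0.05) within the distance window are
   merged; a region needs at least two seed probes.
4. Each region is scored by the Stouffer–Liptak combination of its raw
   member p-values and corrected across the genome with the Šidák
   correction `1 − (1 − p)^(covered / length)`, computed via
   `log1p/expm1` for numerical accuracy at small `p`. Covered bases sum
   `min(gap, dist)` over neighbouring probes per chromosome.

## Restoration analysis (`methylrestore.restore`)

A smoking-associated CpG (nominally significant in `PN`) is classified
as *restored* when the `VP` contrast is also nominally significant with
the opposite sign. Percent restoration is `(−Δβ_VP / Δβ_PN)·100`.
The module reports the restored fraction among candidate CpGs, overlaps
restored probes with `VP` DMRs (half-open intervals, ≥ 1 bp), and
provides a replication lookup (nominal/FDR overlap, direction
concordance, Pearson and Spearman correlation of effect sizes) for
comparing two studies.

## eQTM analysis (`methylrestore.eqtm`)

CpG–transcript pairs are formed cis within ±250 kb (inclusive) on the
same chromosome. Methylation (beta) and log-CPM expression are each
residualised on covariates — sex, gestational age, cell proportions,
and RNA batch on the expression side — and the expression residuals are
regressed on the methylation residuals per pair. P-values are adjusted
jointly by Benjamini–Hochberg. Pairs with zero residual variance are
skipped and reported.

## Clinical outcome models (`methylrestore.outcomes`)

For candidate CpGs, forced expiratory flow (FEF75) is regressed on
methylation plus infant length, sex, and gestational age with the same
Huber estimator as the EWAS, among smokers only. Wheeze is analysed by
logistic regression on the same design. The composite wheeze indicator
is true if any of (wheeze report, wheeze diagnosis, wheeze medication)
is true, missing only when all three are missing, otherwise false.

## Synthetic data (`methylrestore.synth`)

The generator produces a complete study under known truth: cell-profile
mixtures (`k_true` components with bimodal profiles), smoking effects
drawn from a gamma magnitude model (82 % hypomethylating) placed on
intermediate-methylation probes, a configurable restored fraction with
opposite-sign vitamin-C effects, DMR clusters (3–10 probes spaced
< 500 bp; all other probes > 1000 bp apart), cis eQTM pairs with a
common planted slope, outcome-linked CpGs, and homoskedastic Gaussian
noise on the M scale mapped back through the inverse logit. All
randomness flows through named substreams of a single seed, so
identical seed and configuration give byte-identical outputs.

## Pipeline (`methylrestore.pipeline`)

`run_pipeline` chains QC (when detection/beadcount artifacts are
present), deconvolution, EWAS (both contrasts), DMR calling,
restoration, eQTM (when expression data are present), and outcome
models, writing TSV/BED/JSON artifacts plus a manifest with per-stage
status and a parameter hash that covers scientific parameters only
(not filesystem paths), so reruns of the same study are byte-identical
wherever they are placed.
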