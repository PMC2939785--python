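# Methods notes

This note records the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical corner cases. It states no result that
the test suite or `scripts/acceptance.py` does not itself compute.

## qPCR preprocessing

Threshold-cycle (Ct) values are inversely log-proportional to template
abundance (~1 cycle per 2-fold). An assay is **informative** when detected
at Ct < 35 (strict) in at least 25 % of samples (inclusive); both bounds
are exposed (`ct_cutoff`, `min_fraction`). Undetected reactions are
missing values throughout — detection at a fixed cycle cutoff carries no
magnitude, so no pseudo-Ct is ever imputed at this stage.

Between-sample normalization subtracts a per-sample global centring
statistic computed over detected informative assays, and reports
`−(Ct − centre)` so larger = more abundant. Both mean and median centring
are available; **mean is the default** because a global mean over expressed
assays is the normalisation factor this assay design is usually normalized
with, and the two differ only by a per-sample constant shift that cancels
in every downstream rank- or correlation-based step. The operation is
exactly invariant to adding a per-sample constant to all Ct values
(property-tested).

## Clustering and association

Samples are clustered with complete linkage on Euclidean distances,
typically over the 50 assays with largest standard deviation (ties broken
lexicographically for determinism). Missing values are imputed **only
here**, with the per-feature minimum observed expression: undetected ≈ low
abundance is the mildest assumption that yields a complete distance
matrix, and the choice is switchable (`impute_feature_min`).

The cluster number k ∈ {2..6} by default maximises the average silhouette
width; ties prefer the smaller k. Significance of the observed width uses
a feature-wise shuffle null: each feature's values are permuted across
samples independently, destroying inter-sample structure while preserving
feature marginals, and the full silhouette-maximising pipeline is re-run
per permutation. p = (1 + #{perm ≥ obs}) / (B + 1), which is exact under
exchangeability and uniform under the null (verified by KS calibration in
the acceptance suite).

The global association test uses the quadratic score statistic
Q = ‖Z y_c‖² (Z standardized features × samples, y_c the centred binary
outcome) — the Goeman-type random-effects score statistic — calibrated by
outcome permutation rather than its asymptotic mixture distribution:
identical null logic, exact under permutation, and invariant to feature
rescaling by construction. Contingency-table tests are Pearson χ² without
continuity correction; that convention reproduces the printed p-values of
the published clinicopathological table to printed precision (0.052,
0.395, 0.125, < 0.001), which is how the convention was fixed.

## Differential expression

The two-group test is a two-sided Mann–Whitney U (exact for small groups
without ties, normal approximation with tie correction otherwise), with
direction from the median difference. Constant features get p = 1 and a
flag rather than an error, since qPCR panels routinely contain dead
assays. FDR control is Benjamini–Hochberg step-up, applied per family
(all assays; or the five processing genes TRBP2/DICER1/AGO1/AGO2/DROSHA
alone for that dedicated comparison).

Covariate-adjusted confirmation fits logistic `group ~ miRNA + N + M +
stage + HER2`. With ~70 samples and four binary covariates
quasi-separation is common, so on non-convergence, exploding coefficients
(|β| > 15) or unstable standard errors the model refits with an L2
penalty on slopes (α = 1, intercept unpenalized) and Wald p from the
penalized Hessian, flagged `method="ridge"`. Stage enters dichotomized
(I/II vs III/IV), the natural binary coding when stage is a confounder
rather than the estimand.

## Target inference

Spearman correlations use midranks and the t approximation
`t = ρ√((n−2)/(1−ρ²))`; |ρ| = 1 maps to p = 0. Missing miRNA values are
handled pairwise-complete (a pair needs ≥ 5 complete samples). BH is
applied **jointly over all miRNA–gene pairs as one family** — the
discovery claim is over pairs, not per miRNA — and pairs at q < 0.1 are
kept, partitioned by sign.

All enrichment is upper-tail hypergeometric. The universe is always the
set of genes present on the mRNA matrix (enrichment must condition on
testable genes). Prediction-database concordance draws the predicted
targets against the miRNA's correlated genes as reference; miRNAs at BH
q < 0.1 are flagged concordant, and only the intersection (correlated ∩
predicted = "direct targets") feeds downstream functional enrichment and
scoring. A transcription of the published four direct-target gene lists
ships with the package (`datasets.direct_target_genes`); where the source
tables disagree on one count, the per-gene list is taken as authoritative.

## Prognosis scoring

The signed target-set score (mean over positively correlated targets minus
mean over negatively correlated targets) is a per-sample proxy for the
miRNA's activity on expression platforms that do not measure the miRNA
itself. Standardization subtracts the **median** and divides by the
standard deviation — a hybrid, kept deliberately, so the Kaplan–Meier
cut-point at 0 is the median split while the Cox hazard ratio stays
per-s.d. The score is linear in expression and exactly antisymmetric
under swapping the two gene sets.

Cox fits use lifelines' partial likelihood; the pooled "Total" analysis is
dataset-stratified by default (each dataset keeps its own baseline
hazard), with dataset fixed effects as the exposed alternative. Fits
require ≥ 10 events; monotone-likelihood failures are reported as NaN
rows, not silently dropped.

## Regulatory-effect scores

Signed RE of a family in one sample: rank all G genes ascending by
expression, RE = (mean rank of non-targets − mean rank of targets) /
((G+1)/2). The normalization bounds |RE| ≤ G/(G+1) < 1 for every target
set size (extremal placement argument; property-tested), making scores
comparable across gene universes.

The symmetric variant is this package's concrete operationalisation of
"weighing inhibitory and activating effects equally": rank genes by
|expression − per-gene cross-sample median| and score targets' mean rank
minus non-targets'. Strong up- or down-regulation of targets both raise
it. Known limitation: because the reference point is the cross-sample
median, a shift affecting close to half of the samples drags the median
and partially masks itself; the variant is most sensitive when the
affected group is a minority of samples, and group comparisons should
lean on the SAM contrast rather than absolute RE levels.

The group comparison is SAM-style: d = Δmean / (s + s₀) with s the
pooled standard error and s₀ the 5 % quantile of the s distribution
(fudge factor against near-zero-variance families). FDR comes from
group-label permutations with the median false-call estimate at each
family's own |d| threshold, made monotone in |d| step-up style; s₀ is
frozen at its observed value across permutations. A per-family p from
the pooled permuted |d| distribution is reported alongside and is
uniform under the null (KS-calibrated in the acceptance suite).

## Synthetic cohorts

The generator emulates the study design, not its biology:

- 20 IBC + 50 non-IBC samples, 384 assays, 44-sample mRNA subset
  (all IBC first, non-IBC to fill), and a **2000-gene** universe — a
  deliberate scale-down from genome-wide that preserves every statistical
  property the pipeline relies on while keeping the default suite fast.
- Ct = per-assay baseline U(22, 32) + N(0, 1 Ct); ~10 % of assays get
  baselines U(35.5, 39) so the informative filter has real work; 5 % of
  entries are masked undetected at random. Planted differential assays
  (default 4 % ≈ 15, near the 13 reported) shift by −2 Ct in IBC
  (~4-fold up).
- Each planted miRNA gets 30 target genes generated from its latent
  relative expression through a bivariate-normal link calibrated so the
  **Spearman** magnitude is the configured 0.7 (Pearson = 2 sin(πρₛ/6)),
  60 % positive / 40 % negative — mirroring the reported excess of
  positive miRNA–mRNA pairs. AGO2 is shifted up and DICER1 down by 1.5
  log-units in IBC.
- The prediction database holds each planted miRNA's true targets plus an
  equal number of decoy genes, and decoy families with random gene lists;
  gene-set collections include one term per planted miRNA (half its
  targets plus padding) among random terms.
- Survival times are exponential with log-hazard = `hazard_log_hr` × a
  standard-normal planted score, censored uniformly on 24–120 months.
- Clinical covariates follow the published cohort's marginal frequencies
  but are independent of expression — so cluster-clinical associations
  are null by design in synthetic runs.

Not emulated: plate/batch effects, pre-amplification bias, heteroscedastic
Ct noise, correlated gene co-expression modules, miRNA family seed
sharing, and any real dependence of clinical covariates on expression.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to real
array artefacts.

## Problem sizes in the test and acceptance suites

Recovery metrics run on 3–4 cohorts at the full default scale (384 × 70
Ct, 2000 × 44 mRNA); Cox recovery uses 8–10 cohorts of n = 500; RE power
uses 150 random 30-gene families with a +0.3 shift on 30 of them; null
calibrations use 200 replicates with 100–200 permutations each. These
sizes give Monte-Carlo error comfortably below the asserted margins while
keeping a full run to a couple of minutes on one core.

## Numerical conventions

- Permutation p-values always use the add-one rule; the minimum attainable
  p is 1/(B+1).
- Silhouette ties across k go to the smaller k; feature-s.d. ties break
  lexicographically.
- BH is statsmodels' `fdr_bh`, cross-checked against a brute-force
  step-up oracle in the tests.
- Degenerate inputs fail loudly: all-identical samples (zero distances),
  constant outcomes, constant scores, empty gene sets after universe
  intersection, samples with zero detected assays.
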