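# mirna-integrate

Integrated miRNA/mRNA expression analysis for case-control tumour cohorts,
built around the workflow used to characterise the inflammatory breast
cancer (IBC) subtype: qPCR-array miRNA profiling of an IBC vs non-IBC
cohort, integration with matched mRNA arrays to infer miRNA targets by
correlation, and indirect evaluation of those targets against prognosis in
external survival cohorts.

## Who this is for

Computational biologists analysing TaqMan-array style miRNA panels (a few
hundred assays, tens of samples) alongside genome-wide mRNA expression for
a subset of the same samples, who need the full chain from raw threshold
cycles to target inference, enrichment and survival read-outs — with every
statistical step testable on synthetic data with known ground truth.

## The methods at a glance

- **Ct preprocessing** — an assay is *informative* if detected at
  Ct < 35 in ≥ 25 % of samples; relative expression is the negative
  globally centred Ct, ΔCt-style: `x = −(Ct − c_s)` with `c_s` the
  per-sample mean (or median) over detected informative assays.
  Undetected reactions stay missing; they are never imputed as Ct 40.
- **Clustering** — complete-linkage on Euclidean sample distances over the
  50 most-varying miRNAs; the cluster number maximises the average
  silhouette width, with significance from feature-shuffle permutations;
  cluster-clinical associations by Pearson χ² (no continuity correction)
  and a permutation-calibrated global (Goeman-style) test
  `Q = ‖Z y_c‖²` on standardized expression `Z`.
- **Differential miRNAs** — two-sided Mann–Whitney U per assay with
  Benjamini–Hochberg FDR (q < 0.1), then per-candidate confirmation in a
  logistic model `group ~ miRNA + N + M + stage + HER2` with a
  ridge-stabilised fallback under separation.
- **Target inference** — Spearman correlation (midranks, both signs)
  between each candidate miRNA and every gene over the shared samples, BH
  jointly over all pairs; concordance of correlated genes with a
  TargetScan-style prediction database by upper-tail hypergeometric
  enrichment; direct targets = correlated ∩ predicted; GO/KEGG-style GMT
  enrichment of the direct targets.
- **Prognosis score** — per sample,
  `score = mean(expr positively correlated targets) − mean(expr negatively
  correlated targets)`, standardized to median 0 / s.d. 1 per dataset, then
  Cox proportional hazards per dataset and pooled (dataset-stratified
  partial likelihood), plus Kaplan–Meier strata split at 0.
- **Regulatory-effect (RE) score** — per miRNA family and sample, the
  normalized mean-rank displacement of targets vs non-targets in the
  genome-wide expression ranking; a symmetric variant ranks absolute
  deviations from per-gene medians so inhibitory and activating effects
  weigh equally. Group shifts in RE are tested with a SAM-style moderated
  d statistic and permutation FDR.

## Worked example

Everything runs on the bundled synthetic cohort generator, whose defaults
emulate the study design (20 IBC + 50 non-IBC samples, 384 assays,
44-sample mRNA subset) and record the planted truth:

```python
import mirna_integrate as mi
from mirna_integrate.prognosis import score_from_pairs

cohort = mi.generate_cohort(mi.CohortConfig(seed=42))
informative = mi.filter_informative(cohort.ct)
expr = mi.normalize_global_centre(informative)
# 348 of 384 assays informative

ibc = (cohort.samples["subtype"] == "IBC").loc[expr.columns]
de = mi.rank_test(expr, ibc)
hits = de[de["q"] < 0.1]
# 16 differential miRNAs at q < 0.1 (planted: 15)

mir_sub = expr[cohort.mrna.columns]
pairs = mi.mirna_mrna_correlations(mir_sub.loc[hits.index.intersection(mir_sub.index)],
                                   cohort.mrna)
# 3386 correlated miRNA-mRNA pairs (2032 positive, 1354 negative)

conc, inters = mi.concordant_targets(pairs, cohort.target_db, set(cohort.mrna.index))
m = conc[conc["concordant"]].index[0]
score = score_from_pairs(cohort.mrna, pairs, m, restrict_to=inters[m])
rho = mi.score_mirna_concordance(score, mir_sub.loc[m])
# score vs miRNA Spearman rho for miR-004: 0.96

surv, planted = mi.generate_survival_cohort(500, hazard_log_hr=0.5, seed=42)
cox, km = mi.cox_evaluate(mi.standardize(planted), surv)
# dataset_id  hazard_ratio            p   n  n_events
#        DS1      1.633674 7.415577e-18 500       362
```

The differential hits are almost exactly the planted miRNAs, the
correlated pairs split roughly 60/40 positive/negative as planted, the
target-gene score tracks its miRNA (Spearman ρ ≈ 0.9), and the Cox fit
recovers a hazard ratio near `exp(0.5) ≈ 1.65` for the planted per-unit
log-hazard of 0.5.

A CLI mirrors the library for file-based runs:

```sh
mirna-integrate preprocess --ct mirna_ct.tsv --cutoff 35 --min-frac 0.25 -o expr.tsv
mirna-integrate de --expr expr.tsv --samples samples.tsv \
    --adjust n_status,m_status,stage,her2 -o de.tsv
mirna-integrate targets --mirna-expr expr.tsv --mrna-expr mrna_expr.tsv \
    --db targets.tsv --fdr 0.1 -o pairs.tsv
```

File dialects (TSV matrices with empty cells for undetected reactions,
flat miRNA→gene target tables, GMT gene sets, survival tables) are
documented in `mirna_integrate/io.py`.

## Layout

- `src/mirna_integrate/qpcr.py` — Ct filtering and normalization
- `src/mirna_integrate/cluster.py` — clustering, silhouette permutation, χ², global test
- `src/mirna_integrate/de.py` — rank tests, BH FDR, covariate-adjusted confirmation
- `src/mirna_integrate/targets.py` — Spearman pairs, hypergeometric enrichment, concordance
- `src/mirna_integrate/prognosis.py` — signed target score, Cox / Kaplan–Meier
- `src/mirna_integrate/regulatory.py` — RE scores and SAM-style comparison
- `src/mirna_integrate/synthetic.py` — cohort generator and truth table
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
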