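# metspread

Analysis of metastatic progression patterns across major human cancers from
patient-level autopsy registries.

Autopsy remains the definitive way to measure total metastatic burden: a
registry row records, for one autopsied patient, the primary tumor site (one
of 16 categories: lung, esophagus and stomach, colon and rectum, breast,
pancreas, biliary system, head and neck, kidney, neuroendocrine tumors,
prostate, liver, urinary tract, melanoma, ovary, cervix, testicles) and a
20-bit indicator vector of secondary sites harboring metastases (ADR adrenal
gland, OSS bone, MAR bone marrow, BRA brain, HEA heart, REN kidney, HEP
liver, PUL lung, LYM non-regional lymph nodes, MEN meninges, OVA ovary, PAN
pancreas, PC pericardium, PER peritoneum, PLE pleura, SKI skin, ST soft
tissue, SPL spleen, THY thyroid, OTH other).  `metspread` turns such a
registry into a quantitative landscape of organotropism — which cancers seed
which organs, how strongly, and with what consequences — for clinical
oncologists, pathologists and cancer biologists.

## What it computes

* **Inclusion cascade.**  From all autopsies, keep patients with a diagnosed
  metastatic cancer from exactly one of the 16 primary sites; count
  exclusions by reason (no cancer → no metastasis → rare/multiple primary).
* **Fractional method.**  Conditional proportions: P(site s | primary p)
  (progression matrix), P(primary p | site s) (origin matrix), and the
  Jaccard co-occurrence |A∩B|/|A∪B| between two secondary sites.
* **Relative-risk method.**  RR(a, b) = f(a ∧ b) / (f(a) · f(b)) with
  relative frequencies f over the whole included cohort; RR > 1 marks
  enrichment, RR < 1 depletion.  Cell significance by the two-sided Fisher
  exact test with Benjamini–Hochberg FDR control at 5% per matrix.
* **Subgroup contrasts.**  Per-site Fisher comparisons between
  adenocarcinoma and squamous cell carcinoma, smoking- and
  non-smoking-related primaries (tobacco PAF ≥ 20%), N+ and N− disease, and
  the sexes, optionally scoped to one primary.
* **Primary-site prediction (the CUP question).**  Per-primary multivariate
  logistic regressions give odds ratios OR(s | p) for each secondary site; a
  multinomial logistic classifier predicts the primary from the 20-bit
  profile, validated by 1000 random 2/3–1/3 training/test splits with top-1,
  top-2 and top-3 accuracy (mean and 2.5th/97.5th percentile CIs).
* **Total-lifetime hazards.**  Cox proportional hazards on age at death
  (cancer-related deaths as events, others censored) with sex, primary site
  (lung reference) and the 20 site indicators as covariates; Wald tests,
  Breslow ties (Efron available).
* **Clustering and networks.**  Average-linkage clustering (Manhattan on
  percentages, Euclidean on log2 RR/OR) and GraphML export of the
  primary→secondary progression network with node sizes, edge weights and
  enrichment colors.

Because real autopsy registries are rarely shareable, the package ships a
seedable synthetic-registry generator (`metspread.synthetic`): a Gaussian-
copula latent-threshold model draws correlated metastasis vectors with
configurable per-primary marginals and co-occurrence coupling, plus a
Weibull proportional-hazards lifetime model — so the entire pipeline is
testable end to end.

## Worked example

```python
import metspread as ms

cohort = ms.apply_inclusion_filters(ms.make_reference_registry(seed=2013))
print(f"included {len(cohort)} of {cohort.n_total}; exclusions: {cohort.exclusions}")

rr = ms.relative_risk(cohort, "prostate", "OSS")
print(f"RR(prostate, bone) = {rr.rr:.2f}, Fisher p = {rr.p:.2e}")

rep = ms.cross_validate(cohort, n_splits=50, seed=7)
print(rep.summary_table.round(3))

res = ms.fit_lifetime(cohort)
print(res.table.loc[["primary[prostate]", "met[OVA]"]].round(3))
```

prints

```
included 1008 of 6597; exclusions: {'no_cancer': 4497, 'no_metastasis': 1016, 'rare_or_multiple_primary': 76}
RR(prostate, bone) = 2.22, Fisher p = 1.38e-13
       mean  ci_low  ci_high
top1  0.334   0.295    0.377
top2  0.488   0.444    0.522
top3  0.585   0.546    0.629
                      hr  ci_low  ci_high  wald_p      block
primary[prostate]  0.477   0.324    0.703     0.0    primary
met[OVA]           5.319   3.632    7.788     0.0  secondary
```

Reading: of 6597 simulated autopsies, 1008 metastatic single-primary cases
enter the analysis.  Prostate cancer co-occurs with bone metastasis 2.2
times more often than cohort-wide frequencies predict.  The metastasis
profile alone identifies the primary site in a third of held-out patients,
and places it in the top three candidates for ~59%.  Metastatic prostate
cancer carries a lower lifetime hazard than lung cancer (HR 0.48 — death at
older ages), while ovarian metastases mark a sharply elevated hazard.

The same workflow is scriptable from a shell:

```sh
metspread simulate --seed 17 --out registry.csv
metspread filter --in registry.csv --out cohort.csv --report exclusions.json
metspread rr --cohort cohort.csv --out rr/
metspread cv --cohort cohort.csv --splits 1000 --seed 7 --out cv.json
metspread survival --cohort cohort.csv --out lifetime.tsv
metspread network --cohort cohort.csv --out progression.graphml
```

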