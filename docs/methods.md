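# Methods

This note documents the statistical procedures implemented in `metspread`,
the assumptions behind them, the synthetic-registry model used for testing,
and the design choices made where the problem is genuinely open.

## Cohort construction

A registry row is one autopsied patient.  The inclusion cascade keeps
patients with a diagnosed metastatic cancer arising from exactly one of the
16 canonical primary sites.  The filter order is fixed — (1) no cancer,
(2) cancer without metastasis, (3) rare or multiple primary — and every
excluded record is counted once, under the *first* matching reason.  This
precedence is a package convention: exclusion totals are well defined
regardless, but per-reason counts are only deterministic with an ordering,
and the audit trail (`Cohort.exclusions`) conserves the input size exactly
(`n_total = |included| + Σ exclusions`).

Regional lymph-node involvement is carried by `nodal_status` (N+/N−) and is
*not* a metastasis code; only non-regional nodes (LYM) count toward the
20-bit vector.  Smoking-related primaries (tobacco population attributable
fraction ≥ 20%) are lung, head and neck, esophagus and stomach, kidney,
pancreas, urinary tract and cervix; the remaining nine are non-smoking-
related.

## Association statistics

**Fractional method.**  progression(p, s) = |patients with primary p and
site s| / |patients with primary p|; origin(s, p) normalizes the same joint
count by the site total instead, so the two matrices satisfy the identity
`prog(p,s)·n_p = orig(s,p)·n_s` cell-by-cell (a test enforces this).
Co-occurrence between two secondary sites is the Jaccard fraction
|A∩B| / |A∪B| over patient sets.  Cells with an empty denominator are
undefined (NaN), never zero.

**Relative-risk method.**  RR(a, b) = f(a∧b) / (f(a)·f(b)) with all
frequencies relative to the whole included cohort.  Significance per cell is
the two-sided Fisher exact test on the 2×2 patient table, with the two-sided
p defined by summation of all tables with point probability ≤ the observed
one (the conventional definition; both enrichment and depletion are
flagged, so a one-sided test would be incoherent).  Benjamini–Hochberg FDR
control at 5% is applied across all defined cells of each emitted matrix as
one family; for the symmetric secondary-pair matrix the family consists of
the 190 unique unordered pairs and the adjusted q is mirrored to both
cells, since counting mirror duplicates would artificially double the
family.  Undefined cells (a zero-frequency margin) are excluded from the
family and reported with RR = NaN, p = 1.

**Burden and heterogeneity.**  The number of involved secondary sites per
patient is compared across primaries by the Kruskal–Wallis rank test with
tie correction (asymptotic chi-square p, as in standard statistical
environments).  Heterogeneity of per-site hit counts across the 20
secondary sites uses a chi-square goodness-of-fit against equal
proportions; this is a pragmatic descriptive test — the site indicators of
one patient are correlated, so the p-value is heuristic and is labelled as
such in the output.

**Subgroup contrasts** are per-site two-sided Fisher tests between two
strata (histology, smoking relation, nodal status, sex), BH-corrected
across the 20 sites of the comparison.  Fisher was chosen over a
normal-approximation two-proportion test for exactness at the small counts
that rare sites produce.  Records whose stratum value is unknown are
dropped from that comparison only and their number is reported.

## Primary-site prediction

**OR profiles.**  Separately per primary, a multivariate logistic
regression of indicator(primary = target) on the 20 site bits.  Rare sites
(thyroid, bone marrow, spleen at < 5% prevalence) can separate perfectly in
small strata, so the fit carries a weak ridge penalty, λ = 1.0 on the
summed log-likelihood scale (intercept unpenalized) — negligible bias at
cohort sizes of ~1000 but enough to keep separated coefficients finite.
Wald intervals use the penalized observed information; covariates with a
zero cell against the outcome are additionally flagged `separated`.  BH is
applied across the 20 covariates of each profile.

**Multinomial classifier.**  A multinomial logistic model over the 16
classes with the 20 site bits (including OTH) as covariates, L2-regularized
(C = 1.0, the scikit-learn default, exposed as a parameter).  Top-k
prediction takes the k highest-probability classes, with ties broken by the
fixed vocabulary order — determinism over optimism.

**Validation** is repeated random subsampling: `n_splits` independent
unstratified draws of floor(2/3·n) training patients without replacement
(672 of 1008), the remainder tested.  Summaries are the mean and the
2.5th/97.5th percentiles of the per-split accuracies.  Per-primary top-3
recall pools test-set outcomes across splits (pooling, rather than
averaging per-split recalls, keeps rare primaries estimable).  A split
whose training set lacks a class is retained; that class's test rows are
scored against the fitted classes and necessarily miss.

## Total-lifetime model

Cox proportional hazards with time axis = age at death: cancer-related
deaths are events, other deaths are censored at their age.  Covariates: sex,
primary site one-hot with lung (the most common primary) as reference, and
the 20 site indicators.  This measures the population-level lifetime burden
associated with tumor and metastasis locations, *not* post-diagnosis
prognosis.  Left truncation (patients must survive to diagnosis) is not
modelled; this is a known limitation of the plain age-at-death analysis.

The partial likelihood is maximized by L-BFGS (markedly more stable than a
raw Newton iteration on 36 correlated indicator covariates).  Ties use the
Breslow approximation by default — matching the convention of the major
desktop statistics packages — with Efron available by flag; ages are
effectively continuous here so the two nearly coincide.  Constant covariate
columns are dropped with a logged note.  The implementation is
statsmodels' PHReg; an independent cross-check against lifelines'
`CoxPHFitter` (coefficients and standard errors to 1e-4) runs in the test
suite.

## Synthetic-registry model

The generator emulates the structure of a large hospital autopsy series so
that every downstream stage is testable without patient data.

* **Strata.**  Defaults: 6597 autopsies of which 4497 are cancer-free, 1016
  have cancer without metastasis, 76 are metastatic with rare or multiple
  primaries and 1008 are eligible — the canonical stratum counts of the
  emulated series.  `make_reference_registry()` fixes these counts exactly.
* **Primary mixture.**  For the eligible stratum only aggregate constraints
  are published (1008 total, 592 smoking-related vs 416 non-smoking-related,
  lung the most common, all 16 sites present); the default per-primary
  breakdown realizes those constraints and is otherwise illustrative.
* **Metastasis vectors** come from a latent-threshold (Gaussian-copula)
  model: draw z ~ N(0, C) with C the 20×20 coupling matrix, set bit j iff
  z_j < Φ⁻¹(p_{primary,j}).  Marginals are therefore exact regardless of
  coupling, and raising an off-diagonal coupling entry raises that pair's
  co-occurrence RR without moving marginals — the property the RR analyses
  need.  The coupling is specified on the latent-normal scale, not the RR
  scale.  Slightly indefinite matrices are repaired by eigenvalue clipping
  with a logged note; matrices with smallest eigenvalue below −0.2 are
  rejected.
* **Eligibility truncation.**  Eligible patients must be metastatic, so
  all-zero draws are redrawn (up to 100 times; survivors get one site
  sampled proportional to the marginals, with a logged note).  This
  truncation conditions on ≥ 1 site and induces a small negative dependence
  of order (1−p̄)²⁰; at the default marginals it is negligible, and null-
  calibration tests use uniform marginals of 0.3 where the effect is < 0.1%.
* **Default marginals** encode the organotropism the analysis is designed to
  detect (bone-seeking prostate and breast cancer, peritoneum-seeking
  pancreatic and ovarian cancer, promiscuous melanoma, sparse liver-cancer
  spread, overall site frequencies led by liver/nodes/lung/bone/pleura),
  with sex-impossible combinations (ovarian metastases of male-only
  cancers) set to zero.
* **Lifetimes** follow a Weibull proportional-hazards model on age (shape
  6, scale 72 years — median ≈ 68, matching the age structure of an adult
  autopsy series) with log-hazard coefficients for sex, primary site (lung
  reference; prostate −0.8, testicles +3.5 reflecting late- and early-life
  cancers) and secondary sites (ovary +1.2, heart +0.47, brain +0.4, ...).
  The event indicator is an independent Bernoulli (cancer-related death
  probability 0.8 for metastatic patients).

What the generator does *not* emulate: calendar-time trends, within-hospital
referral bias, histology–site interactions, and the correlation between
nodal status and metastatic burden.  Passing tests therefore demonstrate
correctness of the statistical machinery under a known truth, not clinical
conclusions about real registries.

## Numerical choices and degenerate inputs

* Undefined matrix cells are NaN throughout; they are excluded from BH
  families and from clustering distances.
* Clustering: percentages use Manhattan distance on raw fractions; RR/OR
  matrices use Euclidean distance on log2 values; both with average
  linkage.  Cells undefined on the log scale are masked pairwise and the
  distance over mutually defined coordinates is rescaled by coverage
  (×m/k inside the sum), so sparsely observed pairs are not artificially
  close.  The dendrogram mirror ambiguity is canonicalized: at every merge
  the subtree containing the lexicographically smallest label comes first,
  making leaf order invariant to input row permutation.
* Kruskal–Wallis with all observations identical returns H = 0, p = 1
  rather than an error.
* Top-k ties (identical predicted probabilities) are broken by vocabulary
  order.
* All generators and the CV splitter take explicit integer seeds; identical
  seeds give byte-identical registry files, CV reports and GraphML exports.

## Problem sizes used in checks

Oracle-equivalence checks run exhaustively on cohorts of ≤ 30–40 patients
(relative risk by patient enumeration, Fisher by hypergeometric
enumeration, partial likelihood by 1-D brute-force maximization).
Null calibration of the RR screen uses an independence simulation with
50,000 eligible patients; marginal recovery uses 20,000; parameter-recovery
studies use 100 replicates at n = 1200–1500 (logistic) and n = 250–300
(Cox); the multinomial baseline comparison uses 5000 patients and 50
splits, and the reproduction script summarizes prediction over 200 random
splits of the 1008-patient fixture.  These sizes make each claim testable
with comfortable Monte-Carlo margins while keeping the default suite quick
to run.
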