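"""Core association statistics for metastatic progression patterns.

Two complementary views are computed over an included cohort:

* the *fractional* method — simple conditional proportions: the fraction of
  tumors of a primary that progress to a secondary site (progression matrix),
  the fraction of a site's metastases contributed by each primary (origin
  matrix), and the Jaccard co-occurrence fraction between two secondary sites;

* the *relative-risk* method — RR(a, b) = f(a and b) / (f(a) * f(b)), with
  all relative frequencies f taken over the whole included cohort.  RR > 1
  marks enrichment of an association relative to the cohort-wide expectation
  under independence, RR < 1 depletion.  Cell significance uses the two-sided
  Fisher exact test on the underlying 2x2 patient table, with
  Benjamini-Hochberg FDR control at 5% across each emitted matrix as one
  family.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .registry import Cohort
from .vocab import SiteVocabulary

logger = logging.getLogger(__name__)

FLAG_ENRICHED = "enriched"
FLAG_DEPLETED = "depleted"
FLAG_NULL = "null"


@dataclass
class BurdenSummary:
    """Metastasis burden (number of involved secondary sites) per primary."""

    per_primary: pd.DataFrame  # index=primary, columns n / mean / sd
    kruskal_h: float
    kruskal_p: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.per_primary.to_string()}\n"
            f"Kruskal-Wallis H = {self.kruskal_h:.3f}, p = {self.kruskal_p:.3g}"
        )


@dataclass
class AssociationMatrix:
    """A labelled grid of an association statistic with its significance.

    ``statistic`` holds fractions, RRs or ORs (NaN marks undefined cells);
    ``p``/``q`` the raw and BH-adjusted Fisher p-values; ``flag`` one of
    {enriched, depleted, null}; ``counts`` the per-cell 2x2 table
    [[both, a only], [b only, neither]].
    """

    kind: str
    statistic: pd.DataFrame
    p: pd.DataFrame | None = None
    q: pd.DataFrame | None = None
    flag: pd.DataFrame | None = None
    counts: np.ndarray | None = None  # (rows, cols, 2, 2)
    family: str | None = None  # BH family description

    @property
    def row_labels(self) -> tuple[str, ...]:
        return tuple(self.statistic.index)

    @property
    def col_labels(self) -> tuple[str, ...]:
        return tuple(self.statistic.columns)

    def to_dir(self, outdir) -> None:
        """Write statistic/p/q/flags TSV files with labelled headers."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.statistic.to_csv(outdir / "statistic.tsv", sep="\t")
        if self.p is not None:
            self.p.to_csv(outdir / "p.tsv", sep="\t")
        if self.q is not None:
            self.q.to_csv(outdir / "q.tsv", sep="\t")
        if self.flag is not None:
            self.flag.to_csv(outdir / "flags.tsv", sep="\t")


@dataclass
class RelativeRisk:
    """RR for one pair of sites, with its Fisher p and the 2x2 table."""

    rr: float  # NaN when undefined (a zero-frequency margin)
    p: float
    counts: np.ndarray  # 2x2: [[both, a only], [b only, neither]]


def burden_summary(cohort: Cohort) -> BurdenSummary:
    """Per-primary number of involved secondary sites and the across-primary test.

    Groups are the patients of each primary; the across-group comparison uses
    the Kruskal-Wallis rank test with tie correction.  Primaries without any
    patient are dropped from the test with a warning.
    """
    if len(cohort) == 0:
        raise ValueError("burden_summary requires a nonempty cohort")
    counts = cohort.met_matrix().sum(axis=1)
    primaries = cohort.primaries()
    rows = []
    groups = []
    for p in cohort.vocab.primary_sites:
        vals = counts[primaries == p]
        if vals.size == 0:
            warnings.warn(f"primary {p!r} has no patients; dropped from the burden test")
            continue
        rows.append(
            {"primary": p, "n": int(vals.size), "mean": float(vals.mean()),
             "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0}
        )
        groups.append(vals)
    per_primary = pd.DataFrame(rows).set_index("primary")
    flat = np.concatenate(groups)
    if len(groups) < 2 or np.all(flat == flat[0]):
        h, p_val = 0.0, 1.0
    else:
        h, p_val = stats.kruskal(*groups)
    return BurdenSummary(per_primary=per_primary, kruskal_h=float(h), kruskal_p=float(p_val))


def site_frequency(cohort: Cohort) -> tuple[pd.Series, float]:
    """Fraction of patients with each secondary site, plus a heterogeneity p.

    Heterogeneity across the 20 sites is assessed by a chi-square
    goodness-of-fit of the per-site hit counts against equal proportions.
    """
    if len(cohort) == 0:
        raise ValueError("site_frequency requires a nonempty cohort")
    hits = cohort.met_matrix().sum(axis=0)
    frac = pd.Series(hits / len(cohort), index=list(cohort.vocab.secondary_sites))
    if hits.sum() == 0:
        return frac, 1.0
    _, p = stats.chisquare(hits)
    return frac, float(p)


def progression_matrix(cohort: Cohort) -> AssociationMatrix:
    """16x20 fractions: share of each primary's tumors hitting each site."""
    v = cohort.vocab
    mets = cohort.met_matrix()
    primaries = cohort.primaries()
    stat = np.full((v.n_primary, v.n_secondary), np.nan)
    for i, p in enumerate(v.primary_sites):
        mask = primaries == p
        n_p = int(mask.sum())
        if n_p == 0:
            continue  # undefined row
        stat[i] = mets[mask].sum(axis=0) / n_p
    return AssociationMatrix(
        kind="progression_fraction",
        statistic=pd.DataFrame(stat, index=list(v.primary_sites), columns=list(v.secondary_sites)),
    )


def origin_matrix(cohort: Cohort) -> AssociationMatrix:
    """20x16 fractions: share of each site's metastases per primary of origin."""
    v = cohort.vocab
    mets = cohort.met_matrix()
    primaries = cohort.primaries()
    stat = np.full((v.n_secondary, v.n_primary), np.nan)
    onehot = np.stack([(primaries == p).astype(int) for p in v.primary_sites], axis=1)
    for j in range(v.n_secondary):
        hit = mets[:, j] == 1
        n_s = int(hit.sum())
        if n_s == 0:
            continue  # site never hit: undefined row
        stat[j] = onehot[hit].sum(axis=0) / n_s
    return AssociationMatrix(
        kind="origin_fraction",
        statistic=pd.DataFrame(stat, index=list(v.secondary_sites), columns=list(v.primary_sites)),
    )


def cooccurrence_matrix(cohort: Cohort) -> AssociationMatrix:
    """20x20 Jaccard co-occurrence fractions |A∩B| / |A∪B| between sites."""
    v = cohort.vocab
    mets = cohort.met_matrix()
    inter = mets.T @ mets
    hits = mets.sum(axis=0)
    union = hits[:, None] + hits[None, :] - inter
    with np.errstate(invalid="ignore"):
        stat = np.where(union > 0, inter / np.maximum(union, 1), np.nan)
    return AssociationMatrix(
        kind="cooccurrence_fraction",
        statistic=pd.DataFrame(stat, index=list(v.secondary_sites), columns=list(v.secondary_sites)),
    )


def _membership(cohort: Cohort, label: str) -> np.ndarray:
    """Boolean patient membership for a primary label or secondary code."""
    v = cohort.vocab
    if label in v.secondary_sites:
        return cohort.met_matrix()[:, v.secondary_index(label)] == 1
    if label in v.primary_sites:
        return cohort.primaries() == label
    raise ValueError(f"{label!r} is neither a primary label nor a secondary code")


def _rr_from_membership(in_a: np.ndarray, in_b: np.ndarray, n: int) -> RelativeRisk:
    both = int(np.sum(in_a & in_b))
    a_only = int(np.sum(in_a & ~in_b))
    b_only = int(np.sum(~in_a & in_b))
    neither = n - both - a_only - b_only
    counts = np.array([[both, a_only], [b_only, neither]])
    n_a, n_b = both + a_only, both + b_only
    if n_a == 0 or n_b == 0:
        return RelativeRisk(rr=float("nan"), p=1.0, counts=counts)
    rr = (both / n) / ((n_a / n) * (n_b / n))
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return RelativeRisk(rr=float(rr), p=float(p), counts=counts)


def relative_risk(cohort: Cohort, a: str, b: str) -> RelativeRisk:
    """RR(a, b) = f(a and b) / (f(a) f(b)) over the whole included cohort.

    ``a`` may be a primary label or a secondary code; ``b`` is a secondary
    code.  Undefined when either marginal frequency is zero (rr = NaN, p = 1).
    Significance is the two-sided Fisher exact test on the 2x2 patient table.
    """
    n = len(cohort)
    if n == 0:
        raise ValueError("relative_risk requires a nonempty cohort")
    return _rr_from_membership(_membership(cohort, a), _membership(cohort, b), n)


def rr_screen(cohort: Cohort, mode: str = "primary_to_secondary") -> AssociationMatrix:
    """RR matrix with Fisher p, BH-adjusted q and enrichment/depletion flags.

    ``mode`` is ``primary_to_secondary`` (16x20) or ``secondary_pairs``
    (20x20, symmetric, diagonal undefined).  BH is applied across all defined
    cells of the matrix as one family (unique unordered pairs for the
    symmetric matrix, q mirrored); flags require q < 0.05.
    """
    v = cohort.vocab
    n = len(cohort)
    if n == 0:
        raise ValueError("rr_screen requires a nonempty cohort")
    if mode == "primary_to_secondary":
        rows, cols = list(v.primary_sites), list(v.secondary_sites)
        pairs = [(i, j) for i in range(len(rows)) for j in range(len(cols))]
    elif mode == "secondary_pairs":
        rows = cols = list(v.secondary_sites)
        pairs = [(i, j) for i in range(len(rows)) for j in range(i + 1, len(cols))]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    members_r = {lab: _membership(cohort, lab) for lab in rows}
    members_c = {lab: _membership(cohort, lab) for lab in cols}

    rr_m = np.full((len(rows), len(cols)), np.nan)
    p_m = np.ones((len(rows), len(cols)))
    counts = np.zeros((len(rows), len(cols), 2, 2), dtype=np.int64)
    for i, j in pairs:
        res = _rr_from_membership(members_r[rows[i]], members_c[cols[j]], n)
        rr_m[i, j], p_m[i, j] = res.rr, res.p
        counts[i, j] = res.counts
        if mode == "secondary_pairs":
            rr_m[j, i], p_m[j, i] = res.rr, res.p
            counts[j, i] = res.counts.T

    defined = [(i, j) for i, j in pairs if np.isfinite(rr_m[i, j])]
    q_m = np.full_like(p_m, np.nan)
    if defined:
        pvals = np.array([p_m[i, j] for i, j in defined])
        _, qvals, _, _ = multipletests(pvals, alpha=0.05, method="fdr_bh")
        for (i, j), qv in zip(defined, qvals):
            q_m[i, j] = qv
            if mode == "secondary_pairs":
                q_m[j, i] = qv

    flags = np.full((len(rows), len(cols)), FLAG_NULL, dtype=object)
    sig = np.isfinite(q_m) & (q_m < 0.05)
    flags[sig & (rr_m > 1)] = FLAG_ENRICHED
    flags[sig & (rr_m < 1)] = FLAG_DEPLETED

    family = (
        "all defined cells" if mode == "primary_to_secondary"
        else "unique unordered secondary pairs (q mirrored)"
    )
    return AssociationMatrix(
        kind=f"relative_risk[{mode}]",
        statistic=pd.DataFrame(rr_m, index=rows, columns=cols),
        p=pd.DataFrame(p_m, index=rows, columns=cols),
        q=pd.DataFrame(q_m, index=rows, columns=cols),
        flag=pd.DataFrame(flags, index=rows, columns=cols),
        counts=counts,
        family=family,
    )
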