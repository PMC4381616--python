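"""Stratified comparisons of metastatic patterns between patient subgroups.

Supported stratifiers: histology (adenocarcinoma vs squamous cell carcinoma),
smoking etiology of the primary (smoking- vs non-smoking-related), regional
nodal status (N+ vs N-) and sex.  Per secondary site, a two-sided Fisher
exact test compares hit proportions between the two strata;
Benjamini-Hochberg FDR control at 5% is applied across the 20 sites of the
comparison as one family.  An optional primary-site ``scope`` restricts the
comparison to one primary (e.g. the lung-only histology subanalysis).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ComparisonError
from .registry import Cohort, classify_smoking

STRATIFIERS = ("histology", "smoking", "nodal", "sex")


@dataclass
class GroupComparison:
    """Per-site contrast of hit fractions between two patient strata."""

    stratifier: str
    scope: str | None
    group_names: tuple[str, str]
    group_sizes: tuple[int, int]
    n_dropped_unknown: int
    table: pd.DataFrame
    # columns: fraction_g1, fraction_g2, n11, n12, n21, n22, p, q, significant
    # (n11 = group-1 patients with the site, n12 = group-1 without, ...)

    def significant_sites(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def _strata(cohort: Cohort, stratifier: str):
    """Return (labels, group_names) with None for records dropped as unknown."""
    if stratifier == "histology":
        names = ("adenocarcinoma", "squamous")
        labels = [r.histology if r.histology in names else None for r in cohort.included]
    elif stratifier == "smoking":
        names = ("smoking_related", "non_smoking_related")
        labels = [classify_smoking(r.primary_site, cohort.vocab) for r in cohort.included]
    elif stratifier == "nodal":
        names = ("N+", "N-")
        labels = [r.nodal_status if r.nodal_status in names else None for r in cohort.included]
    elif stratifier == "sex":
        names = ("male", "female")
        labels = [r.sex for r in cohort.included]
    else:
        raise ValueError(f"stratifier must be one of {STRATIFIERS}, got {stratifier!r}")
    return labels, names


def compare_groups(
    cohort: Cohort, stratifier: str, scope: str | None = None
) -> GroupComparison:
    """Compare per-site metastasis frequencies between two strata.

    Records whose stratum value is unknown for the chosen stratifier are
    dropped from this comparison only and counted in ``n_dropped_unknown``.
    Raises :class:`ComparisonError` when a stratum is empty after scoping.
    """
    if scope is not None:
        if scope not in cohort.vocab.primary_sites:
            raise ComparisonError(f"scope must be a primary-site label, got {scope!r}")
        cohort = cohort.subset([r.primary_site == scope for r in cohort.included])
    labels, names = _strata(cohort, stratifier)

    mets = cohort.met_matrix()
    lab = np.array([l if l is not None else "" for l in labels], dtype=object)
    g1, g2 = mets[lab == names[0]], mets[lab == names[1]]
    n_dropped = int(np.sum(lab == ""))
    if len(g1) == 0 or len(g2) == 0:
        empty = names[0] if len(g1) == 0 else names[1]
        raise ComparisonError(
            f"stratum {empty!r} is empty for stratifier {stratifier!r}"
            + (f" within scope {scope!r}" if scope else "")
        )

    sites = list(cohort.vocab.secondary_sites)
    rows = []
    for j, site in enumerate(sites):
        n11, n21 = int(g1[:, j].sum()), int(g2[:, j].sum())
        n12, n22 = len(g1) - n11, len(g2) - n21
        _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
        rows.append(
            {
                "site": site,
                "fraction_g1": n11 / len(g1),
                "fraction_g2": n21 / len(g2),
                "n11": n11, "n12": n12, "n21": n21, "n22": n22,
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows).set_index("site")
    _, q, _, _ = multipletests(table["p"].to_numpy(), alpha=0.05, method="fdr_bh")
    table["q"] = q
    table["significant"] = table["q"] < 0.05
    return GroupComparison(
        stratifier=stratifier,
        scope=scope,
        group_names=names,
        group_sizes=(len(g1), len(g2)),
        n_dropped_unknown=n_dropped,
        table=table,
    )
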