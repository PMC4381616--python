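"""Total-lifetime hazard analysis.

Cox proportional-hazards modelling of *age at death* (not post-diagnosis
survival): cancer-related deaths are the events, deaths from other causes are
retained but censored.  Covariates are sex, the primary site as one-hot
indicators with lung (the most common primary) as reference, and the 20
secondary-site bits; per-covariate significance is the Wald test.  Ties are
handled by the Breslow approximation by default, with Efron available.

This describes population-level lifetime burden of tumor/metastasis
locations, not individual prognosis after diagnosis.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from .errors import FitError
from .registry import Cohort

logger = logging.getLogger(__name__)

REFERENCE_PRIMARY = "lung"


def design_frame(cohort: Cohort, reference: str = REFERENCE_PRIMARY) -> pd.DataFrame:
    """Design matrix with duration/event columns and all covariate blocks."""
    v = cohort.vocab
    recs = cohort.included
    df = pd.DataFrame(
        {
            "age_at_death": [r.age_at_death for r in recs],
            "event": [int(r.cancer_related_death) for r in recs],
            "sex_female": [int(r.sex == "female") for r in recs],
        }
    )
    for p in v.primary_sites:
        if p == reference:
            continue
        df[f"primary[{p}]"] = [int(r.primary_site == p) for r in recs]
    for j, code in enumerate(v.secondary_sites):
        df[f"met[{code}]"] = [r.mets[j] for r in recs]
    return df


@dataclass
class LifetimeResults:
    """Hazard ratios for sex, primary site (vs lung) and secondary sites."""

    table: pd.DataFrame   # index covariate; columns hr, ci_low, ci_high, wald_p, block
    n_events: int
    n_censored: int
    ties: str
    dropped: tuple[str, ...]   # constant covariates removed before fitting
    params: pd.Series          # log-hazard coefficients
    bse: pd.Series

    def summary(self) -> str:
        return (
            f"Cox proportional hazards on age at death "
            f"({self.n_events} events, {self.n_censored} censored, {self.ties} ties)\n"
            + self.table.round(4).to_string()
            + (f"\ndropped constant covariates: {', '.join(self.dropped)}" if self.dropped else "")
        )


class LifetimeModel:
    """Cox model of total lifetime for an included cohort.

    ``LifetimeModel(cohort).fit()`` returns :class:`LifetimeResults`.
    """

    def __init__(self, cohort: Cohort, reference: str = REFERENCE_PRIMARY):
        self.cohort = cohort
        self.reference = reference
        self.frame = design_frame(cohort, reference=reference)

    def fit(self, ties: str = "breslow") -> LifetimeResults:
        if ties not in ("breslow", "efron"):
            raise ValueError(f"ties must be 'breslow' or 'efron', got {ties!r}")
        df = self.frame
        n_events = int(df["event"].sum())
        if n_events < 2:
            raise FitError("lifetime fit requires at least 2 cancer-related deaths")

        covariates = [c for c in df.columns if c not in ("age_at_death", "event")]
        dropped = tuple(c for c in covariates if df[c].nunique() <= 1)
        for c in dropped:
            logger.info("dropping constant covariate %s from the lifetime model", c)
        kept = [c for c in covariates if c not in dropped]
        if not kept:
            raise FitError("no non-constant covariates to fit")

        model = PHReg(
            df["age_at_death"].to_numpy(float),
            df[kept].to_numpy(float),
            status=df["event"].to_numpy(int),
            ties=ties,
        )
        try:
            # quasi-Newton is markedly more stable than the default Newton
            # iteration on this many correlated indicator covariates
            res = model.fit(method="lbfgs", maxiter=500, disp=False)
        except Exception as exc:  # convergence / singularity
            raise FitError(f"Cox partial-likelihood fit failed: {exc}") from exc
        params = np.asarray(res.params, float)
        bse = np.asarray(res.bse, float)
        if not np.all(np.isfinite(params)) or not np.all(np.isfinite(bse)):
            flat = [kept[i] for i in range(len(kept))
                    if not (np.isfinite(params[i]) and np.isfinite(bse[i]))]
            raise FitError(f"Cox fit did not converge; flat directions: {flat}")

        z = stats.norm.ppf(0.975)
        blocks = []
        for c in kept:
            if c == "sex_female":
                blocks.append("sex")
            elif c.startswith("primary["):
                blocks.append("primary")
            else:
                blocks.append("secondary")
        table = pd.DataFrame(
            {
                "hr": np.exp(params),
                "ci_low": np.exp(params - z * bse),
                "ci_high": np.exp(params + z * bse),
                "wald_p": 2 * stats.norm.sf(np.abs(params / bse)),
                "block": blocks,
            },
            index=kept,
        )
        return LifetimeResults(
            table=table,
            n_events=n_events,
            n_censored=len(df) - n_events,
            ties=ties,
            dropped=dropped,
            params=pd.Series(params, index=kept),
            bse=pd.Series(bse, index=kept),
        )


def fit_lifetime(cohort: Cohort, ties: str = "breslow") -> LifetimeResults:
    """Convenience wrapper: fit the Cox lifetime model on a cohort."""
    return LifetimeModel(cohort).fit(ties=ties)
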