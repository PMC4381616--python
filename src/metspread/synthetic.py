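"""Seedable synthetic autopsy-registry generator.

The generator emulates the statistical structure the downstream analysis
assumes: a large autopsy series in which most patients are cancer-free, a
further stratum has cancer without metastasis, a small stratum has rare or
multiple primaries, and the remainder are eligible metastatic patients with a
single primary among the 16 categories.

Eligible patients draw a primary site from a mixture, then a 20-bit metastasis
vector from a latent-threshold (Gaussian-copula) model: a 20-dimensional
standard normal with correlation matrix ``coupling`` is drawn and bit *j* is
set iff the latent value falls below the normal quantile of the per-primary
marginal probability.  The coupling therefore controls co-occurrence between
secondary sites without changing the marginals.  Lifetimes follow a Weibull
proportional-hazards model on age at death with log-hazard contributions from
sex, primary site (lung as reference) and each secondary site.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy import stats

from .errors import ConfigError
from .registry import PatientRecord
from .vocab import DEFAULT_VOCAB, RARE_OTHER, SiteVocabulary

logger = logging.getLogger(__name__)

# Canonical stratum counts of the emulated autopsy series: out of 6597
# autopsies, 4497 had no cancer, 1016 had cancer without metastasis, 76 were
# metastatic with rare or multiple primaries, and 1008 were eligible.
REFERENCE_STRATA = {
    "no_cancer": 4497,
    "cancer_no_mets": 1016,
    "rare_or_multiple": 76,
    "eligible": 1008,
}
REFERENCE_N_TOTAL = 6597

# Eligible-cohort per-primary counts.  Only aggregate constraints are known
# for the original series (1008 total; 592 smoking-related vs 416 not; lung
# the most common primary; all 16 sites present); this breakdown realizes
# those constraints and is otherwise illustrative.
REFERENCE_PRIMARY_COUNTS = {
    "lung": 300,
    "esophagus and stomach": 102,
    "colon and rectum": 120,
    "breast": 110,
    "pancreas": 50,
    "biliary system": 35,
    "head and neck": 60,
    "kidney": 45,
    "neuroendocrine tumors": 30,
    "prostate": 45,
    "liver": 30,
    "urinary tract": 25,
    "melanoma": 20,
    "ovary": 20,
    "cervix": 10,
    "testicles": 6,
}

# Baseline per-site metastasis probabilities (whole-cohort scale): liver,
# non-regional nodes, lung, bone and pleura frequent; pancreas, skin, ovary,
# thyroid, bone marrow and spleen rare.
_BASE_SITE_PROBS = {
    "ADR": 0.20, "OSS": 0.38, "MAR": 0.04, "BRA": 0.20, "HEA": 0.10,
    "REN": 0.13, "HEP": 0.59, "PUL": 0.44, "LYM": 0.53, "MEN": 0.05,
    "OVA": 0.04, "PAN": 0.04, "PC": 0.07, "PER": 0.27, "PLE": 0.38,
    "SKI": 0.04, "ST": 0.08, "SPL": 0.04, "THY": 0.04, "OTH": 0.10,
}

# Per-primary deviations from the baseline, encoding the organotropism the
# analysis is designed to detect (bone-seeking prostate and breast cancer,
# sparse liver-cancer spread, promiscuous melanoma, peritoneum-seeking
# pancreatic cancer, ...).
_PRIMARY_OVERRIDES: dict[str, dict[str, float]] = {
    "lung": {"ADR": 0.35, "BRA": 0.35, "REN": 0.20, "PC": 0.12, "SPL": 0.10, "HEA": 0.14},
    "breast": {"HEP": 0.80, "OSS": 0.79, "LYM": 0.60, "PUL": 0.54, "PLE": 0.52,
               "OVA": 0.15, "SKI": 0.14, "MEN": 0.12, "BRA": 0.25},
    "prostate": {"OSS": 0.91, "HEP": 0.35, "PUL": 0.30, "PLE": 0.15, "PER": 0.08,
                 "BRA": 0.06, "ADR": 0.10},
    "melanoma": {"SPL": 0.25, "SKI": 0.30, "MEN": 0.16, "BRA": 0.45, "HEA": 0.22,
                 "HEP": 0.65, "PUL": 0.60, "LYM": 0.65, "OSS": 0.45, "PER": 0.35,
                 "PAN": 0.18, "REN": 0.25, "ADR": 0.30, "ST": 0.25, "OTH": 0.20},
    "liver": {"HEP": 0.10, "PUL": 0.45, "LYM": 0.40, "OSS": 0.18, "PLE": 0.20,
              "PER": 0.20, "ADR": 0.12, "BRA": 0.05},
    "pancreas": {"PER": 0.45, "HEP": 0.70, "OSS": 0.14, "SKI": 0.08, "OVA": 0.08,
                 "SPL": 0.10, "PLE": 0.30},
    "colon and rectum": {"HEP": 0.70, "PER": 0.40, "OSS": 0.14, "BRA": 0.08},
    "kidney": {"PUL": 0.60, "OSS": 0.45, "PLE": 0.40, "PER": 0.30, "HEP": 0.35},
    "ovary": {"PER": 0.70, "PLE": 0.45, "HEP": 0.45, "OSS": 0.12, "OVA": 0.0},
    "cervix": {"PER": 0.35, "LYM": 0.60, "PUL": 0.40},
    "testicles": {"PUL": 0.70, "LYM": 0.75, "HEP": 0.45, "BRA": 0.15},
    "esophagus and stomach": {"PER": 0.35, "HEP": 0.55, "LYM": 0.58, "PLE": 0.30},
    "neuroendocrine tumors": {"HEP": 0.70, "LYM": 0.55, "OSS": 0.30},
}

# Latent-scale couplings for a few secondary-site pairs with elevated
# co-occurrence, on top of a weak global background correlation.
_COUPLING_BUMPS = {
    ("PAN", "SKI"): 0.35,
    ("PAN", "OVA"): 0.35,
    ("PAN", "SPL"): 0.35,
    ("PUL", "LYM"): 0.25,
    ("PLE", "PUL"): 0.25,
    ("PC", "HEA"): 0.30,
    ("MEN", "BRA"): 0.30,
}
_BACKGROUND_COUPLING = 0.10


@dataclass
class LifetimeParams:
    """Weibull proportional-hazards lifetime model on age at death.

    Hazard h(t|x) = h0(t) * exp(eta) with Weibull baseline (shape k, scale
    lambda, ages in years) and eta the linear predictor over sex, primary site
    (lung = reference) and secondary-site indicators.
    """

    weibull_shape: float = 6.0
    weibull_scale: float = 72.0
    sex_female: float = -0.20
    primary_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "prostate": -0.80,
            "testicles": 3.50,
            "esophagus and stomach": 0.26,
            "pancreas": 0.20,
            "melanoma": 0.10,
        }
    )
    secondary_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "OVA": 1.20, "HEA": 0.47, "BRA": 0.40, "MEN": 0.34,
            "LYM": 0.18, "OSS": 0.18,
        }
    )


@dataclass
class SyntheticConfig:
    """Full parameterization of the registry generator.

    Defaults reproduce the emulated study conditions: 6597 autopsies with the
    published stratum fractions, the illustrative 16-way primary mixture, the
    organotropic 16x20 marginal-probability matrix and a weakly coupled
    co-occurrence structure.
    """

    n_total: int = REFERENCE_N_TOTAL
    stratum_fractions: dict[str, float] = field(
        default_factory=lambda: {
            k: REFERENCE_STRATA[k] / REFERENCE_N_TOTAL
            for k in ("no_cancer", "cancer_no_mets", "rare_or_multiple")
        }
    )
    primary_mixture: np.ndarray | None = None   # 16-vector, sums to 1
    marginal_probs: np.ndarray | None = None    # 16 x 20 in [0, 1]
    coupling: np.ndarray | None = None          # 20 x 20 latent correlation
    histology_probs: dict[str, tuple[float, float, float, float]] | None = None
    nodal_probs: tuple[float, float, float] = (0.55, 0.35, 0.10)  # N+, N-, unknown
    lifetime_model: LifetimeParams = field(default_factory=LifetimeParams)
    cancer_death_prob: float = 0.80
    male_fraction: float = 0.57
    seed: int = 0
    vocab: SiteVocabulary = field(default=DEFAULT_VOCAB)
    # exact per-stratum counts (no_cancer, cancer_no_mets, rare_or_multiple,
    # eligible); overrides stratum_fractions when set
    stratum_counts: tuple[int, int, int, int] | None = None
    # exact per-primary counts for the eligible stratum; overrides the mixture
    primary_counts: dict[str, int] | None = None

    def __post_init__(self) -> None:
        v = self.vocab
        if self.primary_mixture is None:
            counts = np.array([REFERENCE_PRIMARY_COUNTS[p] for p in v.primary_sites], float)
            self.primary_mixture = counts / counts.sum()
        self.primary_mixture = np.asarray(self.primary_mixture, dtype=float)
        if self.marginal_probs is None:
            self.marginal_probs = default_marginal_probs(v)
        self.marginal_probs = np.asarray(self.marginal_probs, dtype=float)
        if self.coupling is None:
            self.coupling = default_coupling(v)
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.histology_probs is None:
            self.histology_probs = default_histology_probs(v)
        self.validate()

    def validate(self) -> None:
        v = self.vocab
        if self.primary_mixture.shape != (v.n_primary,):
            raise ConfigError(f"primary_mixture must have length {v.n_primary}")
        if abs(float(self.primary_mixture.sum()) - 1.0) > 1e-9:
            raise ConfigError("primary_mixture must sum to 1 (tolerance 1e-9)")
        if (self.primary_mixture < 0).any():
            raise ConfigError("primary_mixture entries must be nonnegative")
        if self.marginal_probs.shape != (v.n_primary, v.n_secondary):
            raise ConfigError(
                f"marginal_probs must be {v.n_primary} x {v.n_secondary}"
            )
        if ((self.marginal_probs < 0) | (self.marginal_probs > 1)).any():
            raise ConfigError("marginal_probs must lie in [0, 1]")
        fr = self.stratum_fractions
        if any(not 0 <= fr[k] <= 1 for k in fr) or sum(fr.values()) > 1 + 1e-12:
            raise ConfigError("stratum_fractions must be probabilities summing to <= 1")
        self.coupling = repair_coupling(self.coupling, v.n_secondary)

    def to_yaml(self, path: str) -> None:
        d = asdict(self)
        d.pop("vocab")
        for k in ("primary_mixture", "marginal_probs", "coupling"):
            d[k] = np.asarray(d[k]).tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "lifetime_model" in d and isinstance(d["lifetime_model"], dict):
            d["lifetime_model"] = LifetimeParams(**d["lifetime_model"])
        for k in ("primary_mixture", "marginal_probs", "coupling"):
            if d.get(k) is not None:
                d[k] = np.asarray(d[k], dtype=float)
        if d.get("stratum_counts") is not None:
            d["stratum_counts"] = tuple(d["stratum_counts"])
        if d.get("nodal_probs") is not None:
            d["nodal_probs"] = tuple(d["nodal_probs"])
        if d.get("histology_probs") is not None:
            d["histology_probs"] = {k: tuple(vv) for k, vv in d["histology_probs"].items()}
        return cls(**d)


def default_marginal_probs(vocab: SiteVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """Illustrative 16x20 per-primary metastasis-probability matrix."""
    probs = np.zeros((vocab.n_primary, vocab.n_secondary))
    for i, primary in enumerate(vocab.primary_sites):
        over = _PRIMARY_OVERRIDES.get(primary, {})
        for j, code in enumerate(vocab.secondary_sites):
            probs[i, j] = over.get(code, _BASE_SITE_PROBS.get(code, 0.05))
    # sex-specific sites: no ovarian metastases in male-only cancers
    ova = vocab.secondary_index("OVA")
    for male_only in ("prostate", "testicles"):
        probs[vocab.primary_index(male_only), ova] = 0.0
    return probs


def default_coupling(vocab: SiteVocabulary = DEFAULT_VOCAB) -> np.ndarray:
    """Weak global latent correlation plus elevated entries for a few pairs."""
    m = vocab.n_secondary
    c = np.full((m, m), _BACKGROUND_COUPLING)
    np.fill_diagonal(c, 1.0)
    for (a, b), rho in _COUPLING_BUMPS.items():
        i, j = vocab.secondary_index(a), vocab.secondary_index(b)
        c[i, j] = c[j, i] = rho
    return c


def default_histology_probs(
    vocab: SiteVocabulary = DEFAULT_VOCAB,
) -> dict[str, tuple[float, float, float, float]]:
    """Per-primary (adeno, squamous, other, unknown) histology mixtures."""
    generic_adeno = (0.85, 0.0, 0.10, 0.05)
    table = {
        "lung": (0.45, 0.30, 0.20, 0.05),
        "esophagus and stomach": (0.60, 0.30, 0.05, 0.05),
        "head and neck": (0.05, 0.85, 0.05, 0.05),
        "cervix": (0.15, 0.75, 0.05, 0.05),
        "urinary tract": (0.10, 0.15, 0.70, 0.05),
        "melanoma": (0.0, 0.0, 0.95, 0.05),
        "neuroendocrine tumors": (0.0, 0.0, 0.95, 0.05),
        "testicles": (0.0, 0.0, 0.95, 0.05),
        "liver": (0.20, 0.0, 0.75, 0.05),
        "kidney": (0.30, 0.05, 0.60, 0.05),
    }
    return {p: table.get(p, generic_adeno) for p in vocab.primary_sites}


def repair_coupling(coupling: np.ndarray, m: int, tol: float = 0.2) -> np.ndarray:
    """Validate/repair a latent correlation matrix.

    The matrix must be symmetric with unit diagonal.  Slightly indefinite
    matrices (smallest eigenvalue > -tol) are repaired by clipping negative
    eigenvalues to zero and renormalizing the diagonal, with a logged note;
    anything worse is a configuration error.
    """
    coupling = np.asarray(coupling, dtype=float)
    if coupling.shape != (m, m):
        raise ConfigError(f"coupling must be {m} x {m}")
    if not np.allclose(coupling, coupling.T, atol=1e-10):
        raise ConfigError("coupling must be symmetric")
    if not np.allclose(np.diag(coupling), 1.0, atol=1e-10):
        raise ConfigError("coupling must have unit diagonal")
    w = np.linalg.eigvalsh(coupling)
    if w[0] >= -1e-10:
        return coupling
    if w[0] < -tol:
        raise ConfigError(
            f"coupling is not positive semi-definite (min eigenvalue {w[0]:.3g}) "
            f"and beyond the repair tolerance {-tol}"
        )
    logger.info("repairing slightly indefinite coupling (min eigenvalue %.3g)", w[0])
    vals, vecs = np.linalg.eigh(coupling)
    vals = np.clip(vals, 0.0, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _coupling_root(coupling: np.ndarray) -> np.ndarray:
    """Matrix square root for sampling MVN(0, coupling); tolerates PSD rank loss."""
    vals, vecs = np.linalg.eigh(coupling)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _draw_met_vectors(
    rng: np.random.Generator,
    probs_row: np.ndarray,
    root: np.ndarray,
    n: int,
    max_retries: int = 100,
) -> np.ndarray:
    """Draw n correlated 20-bit metastasis vectors with at least one bit set.

    Latent-threshold model: bit j set iff z_j < Phi^-1(p_j) for a latent
    normal z with the configured correlation.  All-zero draws are redrawn up
    to ``max_retries``; survivors get one site sampled proportional to the
    marginal probabilities so eligibility stays well defined.
    """
    m = probs_row.shape[0]
    thresh = stats.norm.ppf(np.clip(probs_row, 0.0, 1.0))
    out = np.zeros((n, m), dtype=np.int64)
    pending = np.arange(n)
    for _ in range(max_retries):
        if pending.size == 0:
            break
        z = rng.standard_normal((pending.size, m)) @ root.T
        bits = (z < thresh).astype(np.int64)
        out[pending] = bits
        pending = pending[bits.sum(axis=1) == 0]
    if pending.size:
        if probs_row.sum() <= 0:
            raise ConfigError("cannot assign a fallback site: all marginals are zero")
        logger.info("assigning fallback single site to %d all-zero draws", pending.size)
        p = probs_row / probs_row.sum()
        sites = rng.choice(m, size=pending.size, p=p)
        out[pending] = 0
        out[pending, sites] = 1
    return out


def _draw_sex(rng: np.random.Generator, primary: str | None, male_fraction: float) -> str:
    if primary in ("prostate", "testicles"):
        return "male"
    if primary in ("ovary", "cervix"):
        return "female"
    if primary == "breast":
        return "female" if rng.random() < 0.99 else "male"
    return "male" if rng.random() < male_fraction else "female"


def _draw_lifetime(
    rng: np.random.Generator,
    lm: LifetimeParams,
    sex: str,
    primary: str | None,
    mets: np.ndarray,
    vocab: SiteVocabulary,
) -> float:
    eta = 0.0
    if sex == "female":
        eta += lm.sex_female
    if primary is not None and primary in lm.primary_coefs:
        eta += lm.primary_coefs[primary]
    for code, beta in lm.secondary_coefs.items():
        if mets[vocab.secondary_index(code)]:
            eta += beta
    e = rng.exponential()
    age = lm.weibull_scale * (e / np.exp(eta)) ** (1.0 / lm.weibull_shape)
    return float(np.clip(age, 1.0, 110.0))


def _categorical(rng: np.random.Generator, labels: tuple[str, ...], probs) -> str:
    return labels[rng.choice(len(labels), p=np.asarray(probs, float) / np.sum(probs))]


def generate_registry(config: SyntheticConfig) -> list[PatientRecord]:
    """Generate a full synthetic registry (all strata), reproducibly by seed."""
    v = config.vocab
    rng = np.random.default_rng(config.seed)
    lm = config.lifetime_model

    if config.stratum_counts is not None:
        n_nc, n_cnm, n_rm, n_el = config.stratum_counts
        if n_nc + n_cnm + n_rm + n_el != config.n_total:
            raise ConfigError("stratum_counts must sum to n_total")
    else:
        fr = config.stratum_fractions
        draws = rng.multinomial(
            config.n_total,
            [
                fr["no_cancer"],
                fr["cancer_no_mets"],
                fr["rare_or_multiple"],
                max(0.0, 1.0 - fr["no_cancer"] - fr["cancer_no_mets"] - fr["rare_or_multiple"]),
            ],
        )
        n_nc, n_cnm, n_rm, n_el = (int(x) for x in draws)

    root = _coupling_root(config.coupling)
    zero = tuple([0] * v.n_secondary)
    records: list[PatientRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"P{counter:05d}"

    # stratum 1: cancer-free autopsies
    for _ in range(n_nc):
        sex = _draw_sex(rng, None, config.male_fraction)
        records.append(
            PatientRecord(
                id=next_id(),
                age_at_death=_draw_lifetime(rng, lm, sex, None, np.zeros(v.n_secondary), v),
                sex=sex,
                autopsy_year=int(rng.integers(2000, 2014)),
                has_cancer=False,
                n_primaries=0,
                primary_site=None,
                histology="unknown",
                nodal_status="unknown",
                mets=zero,
                cancer_related_death=False,
            )
        )

    # stratum 2: cancer without metastasis
    for _ in range(n_cnm):
        p_idx = rng.choice(v.n_primary, p=config.primary_mixture)
        primary = v.primary_sites[p_idx]
        sex = _draw_sex(rng, primary, config.male_fraction)
        records.append(
            PatientRecord(
                id=next_id(),
                age_at_death=_draw_lifetime(rng, lm, sex, primary, np.zeros(v.n_secondary), v),
                sex=sex,
                autopsy_year=int(rng.integers(2000, 2014)),
                has_cancer=True,
                n_primaries=1,
                primary_site=primary,
                histology=_categorical(rng, ("adenocarcinoma", "squamous", "other", "unknown"),
                                       config.histology_probs[primary]),
                nodal_status=_categorical(rng, ("N+", "N-", "unknown"),
                                          (0.25, 0.60, 0.15)),
                mets=zero,
                cancer_related_death=bool(rng.random() < config.cancer_death_prob * 0.5),
            )
        )

    # stratum 3: metastatic but rare primary or multiple primaries
    for _ in range(n_rm):
        multiple = rng.random() < 0.5
        p_idx = rng.choice(v.n_primary, p=config.primary_mixture)
        primary = v.primary_sites[p_idx] if multiple else RARE_OTHER
        bits = _draw_met_vectors(rng, config.marginal_probs[p_idx], root, 1)[0]
        sex = _draw_sex(rng, primary, config.male_fraction)
        records.append(
            PatientRecord(
                id=next_id(),
                age_at_death=_draw_lifetime(rng, lm, sex, None, bits, v),
                sex=sex,
                autopsy_year=int(rng.integers(2000, 2014)),
                has_cancer=True,
                n_primaries=2 if multiple else 1,
                primary_site=primary,
                histology="unknown",
                nodal_status="unknown",
                mets=tuple(int(b) for b in bits),
                cancer_related_death=bool(rng.random() < config.cancer_death_prob),
            )
        )

    # stratum 4: eligible metastatic patients
    if config.primary_counts is not None:
        order: list[int] = []
        for i, p in enumerate(v.primary_sites):
            order.extend([i] * config.primary_counts.get(p, 0))
        if len(order) != n_el:
            raise ConfigError("primary_counts must sum to the eligible stratum size")
        primary_idx = np.array(order)
    else:
        primary_idx = rng.choice(v.n_primary, size=n_el, p=config.primary_mixture)

    for i in np.unique(primary_idx):
        n_i = int((primary_idx == i).sum())
        primary = v.primary_sites[i]
        bit_block = _draw_met_vectors(rng, config.marginal_probs[i], root, n_i)
        for bits in bit_block:
            sex = _draw_sex(rng, primary, config.male_fraction)
            records.append(
                PatientRecord(
                    id=next_id(),
                    age_at_death=_draw_lifetime(rng, lm, sex, primary, bits, v),
                    sex=sex,
                    autopsy_year=int(rng.integers(2000, 2014)),
                    has_cancer=True,
                    n_primaries=1,
                    primary_site=primary,
                    histology=_categorical(
                        rng, ("adenocarcinoma", "squamous", "other", "unknown"),
                        config.histology_probs[primary]),
                    nodal_status=_categorical(rng, ("N+", "N-", "unknown"), config.nodal_probs),
                    mets=tuple(int(b) for b in bits),
                    cancer_related_death=bool(rng.random() < config.cancer_death_prob),
                )
            )
    return records


def make_reference_registry(seed: int = 2013) -> list[PatientRecord]:
    """Deterministic 6597-record fixture with the published stratum counts.

    Exactly 4497 cancer-free records, 1016 cancer-without-metastasis records,
    76 metastatic records with rare or multiple primaries, and 1008 eligible
    metastatic records spread over all 16 primaries (592 smoking-related, 416
    not).  Running :func:`metspread.registry.apply_inclusion_filters` on the
    fixture therefore yields a 1008-patient cohort.
    """
    cfg = SyntheticConfig(
        n_total=REFERENCE_N_TOTAL,
        stratum_counts=(
            REFERENCE_STRATA["no_cancer"],
            REFERENCE_STRATA["cancer_no_mets"],
            REFERENCE_STRATA["rare_or_multiple"],
            REFERENCE_STRATA["eligible"],
        ),
        primary_counts=dict(REFERENCE_PRIMARY_COUNTS),
        seed=seed,
    )
    return generate_registry(cfg)


def make_eligible_cohort_config(
    n_eligible: int,
    seed: int = 0,
    coupling: np.ndarray | None = None,
    marginal_probs: np.ndarray | None = None,
    primary_mixture: np.ndarray | None = None,
) -> SyntheticConfig:
    """Convenience config generating only eligible metastatic patients."""
    return SyntheticConfig(
        n_total=n_eligible,
        stratum_counts=(0, 0, 0, n_eligible),
        coupling=coupling,
        marginal_probs=marginal_probs,
        primary_mixture=primary_mixture,
        seed=seed,
    )
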