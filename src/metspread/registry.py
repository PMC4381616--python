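"""Patient-level registry data model, file I/O and the inclusion-filter cascade.

A registry is a table with one row per autopsied patient.  The analysis cohort
is the subset with a diagnosed metastatic cancer arising from exactly one of
the 16 canonical primary sites; every other patient is excluded and counted
under the first matching exclusion reason (no cancer, then no metastasis, then
rare or multiple primary), so the audit trail is deterministic and conserves
the input size.
"""
from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import RegistryParseError, SchemaError, VocabularyError
from .vocab import (
    DEFAULT_VOCAB,
    HISTOLOGIES,
    NODAL_STATUSES,
    RARE_OTHER,
    SEXES,
    SiteVocabulary,
)

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "id",
    "age_at_death",
    "sex",
    "autopsy_year",
    "has_cancer",
    "n_primaries",
    "primary_site",
    "histology",
    "nodal_status",
    "cancer_related_death",
)

EXCLUSION_REASONS = ("no_cancer", "no_metastasis", "rare_or_multiple_primary")


@dataclass(frozen=True)
class PatientRecord:
    """One autopsied individual.

    ``mets`` is a 20-bit indicator tuple aligned one-to-one with
    ``SiteVocabulary.secondary_sites``; ``primary_site`` is one of the 16
    labels, the rare/other sentinel, or None for cancer-free patients.
    """

    id: str
    age_at_death: float
    sex: str
    autopsy_year: int
    has_cancer: bool
    n_primaries: int
    primary_site: str | None
    histology: str
    nodal_status: str
    mets: tuple[int, ...]
    cancer_related_death: bool

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise VocabularyError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.histology not in HISTOLOGIES:
            raise VocabularyError(f"unknown histology {self.histology!r}")
        if self.nodal_status not in NODAL_STATUSES:
            raise VocabularyError(f"unknown nodal status {self.nodal_status!r}")
        if self.age_at_death < 0:
            raise ValueError(f"age_at_death must be nonnegative, got {self.age_at_death}")
        if not self.has_cancer and (self.n_primaries != 0 or any(self.mets)):
            raise ValueError(
                f"record {self.id}: cancer-free patients must have n_primaries=0 and no metastases"
            )

    @property
    def n_mets(self) -> int:
        """Number of involved secondary sites."""
        return int(sum(self.mets))

    def met_codes(self, vocab: SiteVocabulary = DEFAULT_VOCAB) -> tuple[str, ...]:
        return tuple(c for c, bit in zip(vocab.secondary_sites, self.mets) if bit)


@dataclass
class Cohort:
    """The included patients plus an audit trail of exclusion counts."""

    included: list[PatientRecord]
    exclusions: dict[str, int]
    n_total: int
    vocab: SiteVocabulary = field(default=DEFAULT_VOCAB)

    def __post_init__(self) -> None:
        n_accounted = len(self.included) + sum(self.exclusions.values())
        if n_accounted != self.n_total:
            raise ValueError(
                f"cohort does not conserve counts: {len(self.included)} included + "
                f"{sum(self.exclusions.values())} excluded != {self.n_total} total"
            )

    def __len__(self) -> int:
        return len(self.included)

    def met_matrix(self) -> np.ndarray:
        """(n_patients, 20) 0/1 indicator matrix over secondary sites."""
        return np.array([r.mets for r in self.included], dtype=np.int64).reshape(
            len(self.included), self.vocab.n_secondary
        )

    def primaries(self) -> np.ndarray:
        return np.array([r.primary_site for r in self.included], dtype=object)

    def to_frame(self) -> pd.DataFrame:
        """Flat DataFrame view with one ``met_<CODE>`` column per secondary site."""
        df = records_to_frame(self.included, vocab=self.vocab, mets_as="columns")
        return df

    def subset(self, mask: Sequence[bool]) -> "Cohort":
        """Sub-cohort from a boolean mask; exclusion audit is not carried over."""
        kept = [r for r, m in zip(self.included, mask) if m]
        return Cohort(included=kept, exclusions={}, n_total=len(kept), vocab=self.vocab)


def classify_smoking(primary_site: str, vocab: SiteVocabulary = DEFAULT_VOCAB) -> str:
    """Classify a primary site as ``smoking_related`` or ``non_smoking_related``.

    Smoking-related primaries are those with tobacco PAF >= 20%: lung, head and
    neck, esophagus and stomach, kidney, pancreas, urinary tract and cervix.
    """
    if primary_site not in vocab.primary_sites:
        raise VocabularyError(f"unknown primary site: {primary_site!r}")
    return "smoking_related" if primary_site in vocab.smoking_related else "non_smoking_related"


def apply_inclusion_filters(
    records: Iterable[PatientRecord], vocab: SiteVocabulary = DEFAULT_VOCAB
) -> Cohort:
    """Apply the inclusion cascade and return the cohort with its audit trail.

    Filter order is fixed: (1) drop cancer-free patients, (2) drop cancer
    patients without any metastasis, (3) drop metastatic patients with more
    than one primary or a primary outside the 16 categories.  Each excluded
    record is counted once, under the first matching reason.
    """
    included: list[PatientRecord] = []
    exclusions = dict.fromkeys(EXCLUSION_REASONS, 0)
    n_total = 0
    for rec in records:
        n_total += 1
        if not rec.has_cancer:
            exclusions["no_cancer"] += 1
        elif rec.n_mets == 0:
            exclusions["no_metastasis"] += 1
        elif rec.n_primaries != 1 or rec.primary_site not in vocab.primary_sites:
            exclusions["rare_or_multiple_primary"] += 1
        else:
            included.append(rec)
    return Cohort(included=included, exclusions=exclusions, n_total=n_total, vocab=vocab)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n", ""}


def _parse_bool(value: object, column: str, row: int) -> bool:
    s = str(value).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise RegistryParseError(f"cannot parse {column}={value!r} as boolean", row=row)


def _infer_sep(path: str, dialect: str | None) -> str:
    if dialect is not None:
        return dialect
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def read_registry(
    path: str,
    dialect: str | None = None,
    vocab: SiteVocabulary = DEFAULT_VOCAB,
) -> list[PatientRecord]:
    """Read a registry CSV/TSV into patient records.

    Metastasis sites may be given either as one ``mets`` column holding a
    semicolon-delimited code list, or as 20 indicator columns
    ``met_ADR ... met_OTH``.  Unrecognized secondary codes are mapped to OTH
    with a logged warning; missing optional fields map to "unknown".  No
    inclusion filtering happens here.
    """
    sep = _infer_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"registry file is missing required column(s): {', '.join(missing)}")

    met_cols = [f"met_{c}" for c in vocab.secondary_sites]
    has_indicator_cols = all(c in df.columns for c in met_cols)
    if not has_indicator_cols and "mets" not in df.columns:
        raise SchemaError(
            "registry file must provide either a 'mets' code-list column or "
            "all 20 'met_<CODE>' indicator columns"
        )

    oth_idx = vocab.secondary_index("OTH")
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        try:
            age = float(row["age_at_death"])
        except ValueError:
            raise RegistryParseError(
                f"cannot parse age_at_death={row['age_at_death']!r}", row=i
            ) from None
        try:
            year = int(row["autopsy_year"])
        except ValueError:
            raise RegistryParseError(
                f"cannot parse autopsy_year={row['autopsy_year']!r}", row=i
            ) from None

        bits = [0] * vocab.n_secondary
        if has_indicator_cols:
            for j, col in enumerate(met_cols):
                bits[j] = 1 if str(row[col]).strip() in {"1", "true", "True"} else 0
        else:
            for code in str(row["mets"]).split(";"):
                code = code.strip()
                if not code:
                    continue
                if code in vocab.secondary_sites:
                    bits[vocab.secondary_index(code)] = 1
                else:
                    logger.warning("row %d: unknown secondary code %r mapped to OTH", i, code)
                    bits[oth_idx] = 1

        primary = row["primary_site"].strip() or None
        histology = row["histology"].strip() or "unknown"
        nodal = row["nodal_status"].strip() or "unknown"
        records.append(
            PatientRecord(
                id=str(row["id"]),
                age_at_death=age,
                sex=str(row["sex"]).strip().lower(),
                autopsy_year=year,
                has_cancer=_parse_bool(row["has_cancer"], "has_cancer", i),
                n_primaries=int(row["n_primaries"] or 0),
                primary_site=primary,
                histology=histology,
                nodal_status=nodal,
                mets=tuple(bits),
                cancer_related_death=_parse_bool(
                    row["cancer_related_death"], "cancer_related_death", i
                ),
            )
        )
    return records


def records_to_frame(
    records: Sequence[PatientRecord],
    vocab: SiteVocabulary = DEFAULT_VOCAB,
    mets_as: str = "list",
) -> pd.DataFrame:
    """Tabulate records; ``mets_as`` is "list" (semicolon codes) or "columns"."""
    base = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "age_at_death": [r.age_at_death for r in records],
            "sex": [r.sex for r in records],
            "autopsy_year": [r.autopsy_year for r in records],
            "has_cancer": [int(r.has_cancer) for r in records],
            "n_primaries": [r.n_primaries for r in records],
            "primary_site": [r.primary_site or "" for r in records],
            "histology": [r.histology for r in records],
            "nodal_status": [r.nodal_status for r in records],
            "cancer_related_death": [int(r.cancer_related_death) for r in records],
        }
    )
    if mets_as == "list":
        base["mets"] = [";".join(r.met_codes(vocab)) for r in records]
    elif mets_as == "columns":
        for j, code in enumerate(vocab.secondary_sites):
            base[f"met_{code}"] = [r.mets[j] for r in records]
    else:  # pragma: no cover - guarded by callers
        raise ValueError(f"mets_as must be 'list' or 'columns', got {mets_as!r}")
    return base


def write_registry(
    records: Sequence[PatientRecord],
    path: str,
    dialect: str | None = None,
    vocab: SiteVocabulary = DEFAULT_VOCAB,
    mets_as: str = "list",
) -> None:
    """Write records to CSV/TSV in the canonical column layout (UTF-8)."""
    sep = _infer_sep(path, dialect)
    df = records_to_frame(records, vocab=vocab, mets_as=mets_as)
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")
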