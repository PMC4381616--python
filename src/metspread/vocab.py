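"""Controlled vocabularies for primary and secondary anatomical sites.

Primary tumors are classified into the 16 most common solid-cancer sites of a
large autopsy series; metastases are coded by 20 secondary-site codes
(e.g. HEP = liver, OSS = bone, LYM = non-regional lymph nodes, OTH = any rarer
site).  Smoking-related primaries are those with a population attributable
fraction (PAF) for tobacco smoking of at least 20%.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .errors import VocabularyError

#: The 16 primary-site categories, in canonical display order.
PRIMARY_SITES: tuple[str, ...] = (
    "lung",
    "esophagus and stomach",
    "colon and rectum",
    "breast",
    "pancreas",
    "biliary system",
    "head and neck",
    "kidney",
    "neuroendocrine tumors",
    "prostate",
    "liver",
    "urinary tract",
    "melanoma",
    "ovary",
    "cervix",
    "testicles",
)

#: The 20 secondary-site codes, in canonical order.  OTH collects rarer sites.
SECONDARY_SITES: tuple[str, ...] = (
    "ADR",  # adrenal gland
    "OSS",  # bone
    "MAR",  # bone marrow
    "BRA",  # brain
    "HEA",  # heart
    "REN",  # kidney
    "HEP",  # liver
    "PUL",  # lung
    "LYM",  # non-regional lymph nodes
    "MEN",  # meninges
    "OVA",  # ovary
    "PAN",  # pancreas
    "PC",   # pericardium
    "PER",  # peritoneum
    "PLE",  # pleura
    "SKI",  # skin
    "ST",   # soft tissue
    "SPL",  # spleen
    "THY",  # thyroid
    "OTH",  # other, rarer sites
)

#: Primaries with smoking PAF >= 20%.
SMOKING_RELATED: frozenset[str] = frozenset(
    {
        "lung",
        "head and neck",
        "esophagus and stomach",
        "kidney",
        "pancreas",
        "urinary tract",
        "cervix",
    }
)

#: Sentinel primary-site label for rare tumors outside the 16 categories.
RARE_OTHER: str = "rare/other"

SEXES: tuple[str, str] = ("male", "female")
HISTOLOGIES: tuple[str, ...] = ("adenocarcinoma", "squamous", "other", "unknown")
NODAL_STATUSES: tuple[str, ...] = ("N+", "N-", "unknown")


@dataclass(frozen=True)
class SiteVocabulary:
    """The site vocabularies used throughout the pipeline.

    The default instance encodes the canonical 16 primary / 20 secondary
    classification; a custom instance may be supplied for reduced test
    vocabularies, but must satisfy the same structural invariants.
    """

    primary_sites: tuple[str, ...] = PRIMARY_SITES
    secondary_sites: tuple[str, ...] = SECONDARY_SITES
    smoking_related: frozenset[str] = SMOKING_RELATED

    def __post_init__(self) -> None:
        if len(set(self.primary_sites)) != len(self.primary_sites):
            raise VocabularyError("duplicate primary-site labels")
        if len(set(self.secondary_sites)) != len(self.secondary_sites):
            raise VocabularyError("duplicate secondary-site codes")
        if self.secondary_sites.count("OTH") != 1:
            raise VocabularyError("secondary sites must contain OTH exactly once")
        unknown = set(self.smoking_related) - set(self.primary_sites)
        if unknown:
            raise VocabularyError(f"smoking_related labels not in primary_sites: {sorted(unknown)}")

    @property
    def n_primary(self) -> int:
        return len(self.primary_sites)

    @property
    def n_secondary(self) -> int:
        return len(self.secondary_sites)

    def primary_index(self, label: str) -> int:
        try:
            return self.primary_sites.index(label)
        except ValueError:
            raise VocabularyError(f"unknown primary site: {label!r}") from None

    def secondary_index(self, code: str) -> int:
        try:
            return self.secondary_sites.index(code)
        except ValueError:
            raise VocabularyError(f"unknown secondary site code: {code!r}") from None


#: Module-level default vocabulary (16 primaries, 20 secondaries).
DEFAULT_VOCAB = SiteVocabulary()
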