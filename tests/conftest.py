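import numpy as np
import pytest

from metspread import (
    Cohort,
    PatientRecord,
    apply_inclusion_filters,
    make_reference_registry,
)
from metspread.vocab import DEFAULT_VOCAB


def make_record(
    id="P1",
    primary="lung",
    met_codes=("HEP",),
    age=70.0,
    sex="male",
    year=2005,
    has_cancer=True,
    n_primaries=1,
    histology="adenocarcinoma",
    nodal="N+",
    cancer_death=True,
):
    """Hand-build a patient record from secondary-site codes."""
    bits = [0] * DEFAULT_VOCAB.n_secondary
    for c in met_codes:
        bits[DEFAULT_VOCAB.secondary_index(c)] = 1
    if not has_cancer:
        n_primaries, primary, bits = 0, None, [0] * DEFAULT_VOCAB.n_secondary
    return PatientRecord(
        id=id,
        age_at_death=age,
        sex=sex,
        autopsy_year=year,
        has_cancer=has_cancer,
        n_primaries=n_primaries,
        primary_site=primary,
        histology=histology,
        nodal_status=nodal,
        mets=tuple(bits),
        cancer_related_death=cancer_death,
    )


def make_cohort(records):
    """Wrap pre-filtered records into a cohort without exclusions."""
    return Cohort(included=list(records), exclusions={}, n_total=len(records))


def random_small_cohort(rng, n, p=0.3, primaries=("lung", "breast")):
    """A small random cohort for exhaustive oracle checks."""
    recs = []
    for i in range(n):
        bits = rng.random(DEFAULT_VOCAB.n_secondary) < p
        if not bits.any():
            bits[rng.integers(DEFAULT_VOCAB.n_secondary)] = True
        codes = [c for c, b in zip(DEFAULT_VOCAB.secondary_sites, bits) if b]
        recs.append(
            make_record(
                id=f"R{i}",
                primary=primaries[rng.integers(len(primaries))],
                met_codes=codes,
                age=float(rng.uniform(40, 95)),
                sex="male" if rng.random() < 0.5 else "female",
            )
        )
    return make_cohort(recs)


@pytest.fixture(scope="session")
def reference_records():
    return make_reference_registry()


@pytest.fixture(scope="session")
def reference_cohort(reference_records):
    return apply_inclusion_filters(reference_records)
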