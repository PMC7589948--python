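import math

import pytest

from intrathecal import (
    PairedSpecimen,
    PatientRecord,
    DiagnosisGroup,
    IEFPattern,
    default_paperlike_config,
    derive_all,
    generate_cohort,
)


def make_record(
    rid: str,
    kappa_index: float,
    pattern: IEFPattern = IEFPattern.POLYCLONAL,
    diagnosis: DiagnosisGroup = DiagnosisGroup.MISCELLANEOUS,
    q_alb: float = 0.01,
    serum_kflc: float = 10.0,
) -> PatientRecord:
    """Record with an exactly prescribed kappa index (q_alb fixed at 0.01)."""
    serum_albumin = 40000.0
    specimen = PairedSpecimen(
        serum_albumin=serum_albumin,
        csf_albumin=q_alb * serum_albumin,
        serum_igg=10000.0,
        csf_igg=0.6 * q_alb * 10000.0,
        serum_kflc=serum_kflc,
        csf_kflc=kappa_index * q_alb * serum_kflc,
    )
    return PatientRecord(id=rid, specimen=specimen, pattern=pattern, diagnosis=diagnosis)


@pytest.fixture(scope="session")
def paperlike_records():
    """One default synthetic cohort (n=540), derived, shared across tests."""
    records = generate_cohort(default_paperlike_config(), seed=1)
    derive_all(records)
    return records
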