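import pytest

import psncohort as pc


@pytest.fixture(scope="session")
def realworld():
    """The deterministic study-shaped cohort plus derived objects."""
    fx = pc.build_realworld_fixture()
    profiles = pc.build_pathway_profiles(fx.cohort)
    strata = pc.stratify(fx.cohort.patients)
    return {
        "fixture": fx,
        "cohort": fx.cohort,
        "profiles": profiles,
        "strata": strata,
        "patients_by_id": {p.patient_id: p for p in fx.cohort.patients},
        "profiles_by_id": {p.patient_id: p for p in profiles},
        "strata_by_id": {s.patient_id: s for s in strata},
    }


@pytest.fixture(scope="session")
def catalog():
    return pc.default_catalog()
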