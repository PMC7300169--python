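"""Shared fixtures: the pinned synthetic cohort and small helper cohorts."""

import math

import pytest

import ossdosim as od

#: Seed of the pinned synthetic cohort used by regression-style tests.
PINNED_SEED = 1


@pytest.fixture(scope="session")
def grid():
    return od.default_grid()


@pytest.fixture(scope="session")
def pinned_cohort():
    """The default 13-patient synthetic cohort at the pinned seed."""
    return od.sample_cohort(od.CohortConfig(), seed=PINNED_SEED)


def make_monoexp_patient(patient_id="mono1", a0=7300.0, kidney_t_eff=40.0,
                         lesion_t_effs=(50.0, 60.0)):
    """A patient with pure mono-exponential kinetics (instantaneous uptake)."""
    return od.VirtualPatient(
        patient_id=patient_id,
        a0=a0,
        kidney=od.monoexp_kinetics(amplitude=0.02 * a0, t_eff=kidney_t_eff),
        lesions=tuple(
            od.monoexp_kinetics(amplitude=0.005 * a0, t_eff=t)
            for t in lesion_t_effs
        ),
    )


@pytest.fixture(scope="session")
def monoexp_cohort():
    """Three patients with mono-exponential truths spanning the T_eff ranges."""
    return [
        make_monoexp_patient("mono1", 7300.0, 40.0, (50.0, 60.0)),
        make_monoexp_patient("mono2", 7000.0, 32.0, (36.0, 90.0)),
        make_monoexp_patient("mono3", 7600.0, 58.0, (44.0, 70.0)),
    ]
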