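import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from aftclock.data_model import (
    Apoe4,
    BiomarkerObservation,
    CohortDataset,
    Marker,
    ParticipantCovariates,
)


def make_participant(pid, apoe=Apoe4.NONCARRIER, female=False, education=14.0,
                     referral=False):
    return ParticipantCovariates(pid, apoe, female, education, referral)


def obs(pid, marker, age, raw, transformed=None, scanner=None):
    return BiomarkerObservation(pid, marker, age, raw, transformed, scanner)


@pytest.fixture
def tiny_cohort():
    """Three participants: PET at 49 only; MRI only; fully eligible."""
    observations = [
        obs("young", Marker.AMYLOID_PET, 49.0, 1.4),
        obs("young", Marker.WMH_PCT, 49.5, 0.8),
        obs("mri_only", Marker.WMH_PCT, 72.0, 1.2),
        obs("mri_only", Marker.FA_GCC, 72.0, 0.61),
        obs("eligible", Marker.AMYLOID_PET, 71.0, 1.6),
        obs("eligible", Marker.TAU_PET, 71.0, 1.2),
        obs("eligible", Marker.WMH_PCT, 71.5, 0.9),
    ]
    covariates = [
        make_participant("young"),
        make_participant("mri_only", female=True),
        make_participant("eligible", apoe=Apoe4.CARRIER),
    ]
    return CohortDataset(observations=observations, covariates=covariates)


@pytest.fixture(scope="session")
def small_fit():
    """One small cohort fit shared across API-level tests (kept cheap)."""
    from aftclock.aft_model import MCMCConfig, fit_aft
    from aftclock.synthetic import CohortConfig, generate_cohort

    dataset, truth = generate_cohort(CohortConfig(n_participants=80, seed=5))
    posterior = fit_aft(
        dataset,
        mcmc_config=MCMCConfig(chains=2, warmup=150, draws=120, max_depth=6),
        seed=9,
    )
    return dataset, truth, posterior
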