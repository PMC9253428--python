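import numpy as np
import pytest

import nccclaims as nc


@pytest.fixture(scope="session")
def worked_fixture():
    """The hand-built 12-participant cohort covering every case-finder branch."""
    return nc.make_worked_fixture()


@pytest.fixture(scope="session")
def worked_cohort(worked_fixture):
    records, profiles = worked_fixture
    cohort = nc.build_cohort(records, profiles)
    classifications = nc.classify_cohort(records, cohort)
    return records, profiles, cohort, classifications


def null_scenario(seed: int, n: int = 4000, prevalence: float = 0.2) -> nc.ScenarioConfig:
    """No true effects, no confounding: exposures independent of case status."""
    return nc.ScenarioConfig(
        n_participants=n,
        seed=seed,
        baseline_allergy_logodds=float(np.log(0.08 / 0.92)),
        true_log_or={},
        coprescription_prevalence={d: prevalence for d in nc.TARGET_CONCOMITANTS},
        covariate_effects_on_coprescription={},
        covariate_effects_on_allergy={},
    )


def confounded_scenario(seed: int, n: int = 4000) -> nc.ScenarioConfig:
    """Strong covariate-driven co-prescription and allergy risk, no true drug effect."""
    return nc.ScenarioConfig(
        n_participants=n,
        seed=seed,
        baseline_allergy_logodds=float(np.log(0.06 / 0.94)),
        true_log_or={},
        coprescription_prevalence={"ambroxol": 0.25, "gentamicin": 0.10},
        covariate_effects_on_coprescription={"age_z": 1.5, "inpatient": 1.2},
        covariate_effects_on_allergy={"age_z": 1.5, "inpatient": 1.2},
    )


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One cached small end-to-end pipeline run shared by orchestration tests."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = {
        "scenario": {"n_participants": 3000, "seed": 42},
        "mode": "primary",
        "seed": 42,
        "outdir": str(outdir),
    }
    manifest, results = nc.run_pipeline(cfg)
    return cfg, outdir, manifest, results
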