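"""Seeded synthetic prescription-claims cohorts with known ground truth.

The generator emulates the data-generating process the analysis pipeline
assumes: a cohort of index-drug (XYP) users, each with one index episode;
covariate-dependent same-day co-prescription of 25 target drugs; an allergy
event whose log-odds are a linear function of the true per-drug effects
(plus optional covariate effects, which is what makes the covariates genuine
confounders when they also drive co-prescription); a marker-drug
prescription 0-3 days after the index date for allergic participants; and a
low background rate of marker prescriptions unrelated to allergy, scattered
over the whole observation window so the washout and timing exclusions are
exercised on realistic noise.

Every random draw flows from one :class:`numpy.random.Generator` seeded in
the scenario config; the same config and seed reproduce the cohort
byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .claims_io import (
    DEFAULT_VOCABULARY,
    DrugVocabulary,
    ParticipantProfile,
    PrescriptionRecord,
    TARGET_CONCOMITANTS,
)

#: Covariate keys accepted in the effect maps. "age_z" is age standardized to
#: mean 30, SD 25 (roughly the cohort mixture's scale); the rest are 0/1
#: indicators.
COVARIATE_KEYS = ("age_z", "female", "inpatient", "secondary", "primary_healthcare")

#: Default same-day co-prescription prevalence per target drug, mirroring the
#: qualitative frequency ordering of the published univariate table
#: (common mucolytics/vitamins at 10-25%, rare carbapenems below 1%).
DEFAULT_PREVALENCE: dict[str, float] = {
    "ambroxol": 0.255,
    "vitamin c": 0.214,
    "potassium chloride": 0.168,
    "vitamin b6": 0.124,
    "ribavirin": 0.111,
    "penicillin": 0.090,
    "levofloxacin": 0.079,
    "azithromycin": 0.079,
    "bromhexine": 0.078,
    "pantoprazole": 0.071,
    "heparin": 0.067,
    "cefuroxime": 0.058,
    "sodium bicarbonate": 0.055,
    "cefathiamidine": 0.055,
    "lidocaine": 0.040,
    "aminophylline": 0.035,
    "cefazolin": 0.034,
    "amoxicillin-clavulanate": 0.025,
    "ceftazidime": 0.024,
    "gentamicin": 0.021,
    "ceftriaxone": 0.018,
    "moxifloxacin": 0.014,
    "amikacin": 0.005,
    "cefoperazone-sulbactam": 0.004,
    "meropenem": 0.002,
}

#: Default true effects: the multivariable odds ratios the published analysis
#: reports, planted as the generator's ground truth.
DEFAULT_TRUE_LOG_OR: dict[str, float] = {
    "gentamicin": math.log(4.29),
    "cefoperazone-sulbactam": math.log(4.26),
    "lidocaine": math.log(2.76),
    "aminophylline": math.log(1.73),
    "ribavirin": math.log(1.54),
    "potassium chloride": math.log(1.45),
    "vitamin c": math.log(1.32),
    "cefathiamidine": math.log(0.29),
}


class ScenarioConfigError(ValueError):
    """Invalid or degenerate scenario configuration."""


@dataclass
class ScenarioConfig:
    """Everything the generator needs to produce one synthetic cohort.

    Defaults describe a scaled-down analogue of a one-year national-claims
    cohort of index-drug users: ~2% of participants have a true allergic
    reaction at baseline (before exposure effects), markers for true
    allergies arrive mostly within a day of the index prescription, and a
    small per-day background rate produces marker prescriptions unrelated to
    the index drug.
    """

    n_participants: int = 20_000
    seed: int = 0
    baseline_allergy_logodds: float = -3.9  # logit(~2%)
    true_log_or: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_TRUE_LOG_OR))
    coprescription_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    covariate_effects_on_coprescription: dict[str, float] = field(
        default_factory=lambda: {"age_z": 0.3, "inpatient": 0.5}
    )
    covariate_effects_on_allergy: dict[str, float] = field(
        default_factory=lambda: {"age_z": 0.2, "inpatient": 0.3}
    )
    background_marker_rate: float = 0.0006  # per participant-day
    marker_delay_distribution: dict[int, float] = field(
        default_factory=lambda: {0: 0.40, 1: 0.40, 2: 0.15, 3: 0.05}
    )
    xyp_continuation_probability: float = 0.5
    observation_days: int = 365
    age_mixture_weights: tuple[float, float, float] = (0.43, 0.37, 0.20)  # child/adult/elderly
    p_female: float = 0.47
    p_inpatient: float = 0.76
    hospital_level_probs: tuple[float, float, float] = (0.26, 0.52, 0.22)  # tertiary/secondary/primary

    @property
    def same_day_marker_fraction(self) -> float:
        """Probability an allergy's marker is prescribed on the index day itself."""
        return self.marker_delay_distribution.get(0, 0.0)

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ScenarioConfigError("n_participants must be >= 2")
        if self.observation_days < 10:
            raise ScenarioConfigError("observation_days must be >= 10")
        delays = self.marker_delay_distribution
        if set(delays) - {0, 1, 2, 3}:
            raise ScenarioConfigError("marker delays must lie in {0,1,2,3}")
        if abs(sum(delays.values()) - 1.0) > 1e-9:
            raise ScenarioConfigError("marker_delay_distribution must sum to 1")
        probs = (
            list(self.coprescription_prevalence.values())
            + list(delays.values())
            + [
                self.background_marker_rate,
                self.xyp_continuation_probability,
                self.p_female,
                self.p_inpatient,
                *self.hospital_level_probs,
                *self.age_mixture_weights,
            ]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ScenarioConfigError("all probabilities must lie in [0, 1]")
        if abs(sum(self.age_mixture_weights) - 1.0) > 1e-9:
            raise ScenarioConfigError("age_mixture_weights must sum to 1")
        if abs(sum(self.hospital_level_probs) - 1.0) > 1e-9:
            raise ScenarioConfigError("hospital_level_probs must sum to 1")
        unknown = set(self.true_log_or) - set(TARGET_CONCOMITANTS)
        if unknown:
            raise ScenarioConfigError(f"true_log_or names unknown drugs: {sorted(unknown)}")
        for m in (self.covariate_effects_on_coprescription, self.covariate_effects_on_allergy):
            bad = set(m) - set(COVARIATE_KEYS)
            if bad:
                raise ScenarioConfigError(f"unknown covariate keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScenarioConfig":
        kwargs = dict(raw)
        if "marker_delay_distribution" in kwargs:
            kwargs["marker_delay_distribution"] = {
                int(k): float(v) for k, v in kwargs["marker_delay_distribution"].items()
            }
        for key in ("age_mixture_weights", "hospital_level_probs"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg


@dataclass
class TruthLedger:
    """Ground truth per participant: allergy status, marker offset, exposures.

    ``frame`` columns: ``participant_id``, ``allergic`` (bool), ``marker_offset``
    (0-3, or -1 for non-allergic participants) and one 0/1 column per target
    drug giving the true same-day co-prescription status.
    """

    frame: pd.DataFrame


def _draw_ages(rng: np.random.Generator, n: int, weights) -> np.ndarray:
    comp = rng.choice(3, size=n, p=list(weights))
    ages = np.empty(n)
    child = comp == 0
    adult = comp == 1
    elderly = comp == 2
    ages[child] = rng.uniform(0.0, 18.0, child.sum())
    ages[adult] = np.clip(rng.normal(40.0, 12.0, adult.sum()), 18.0, 64.9)
    ages[elderly] = np.clip(65.0 + rng.exponential(6.0, elderly.sum()), 65.0, 95.0)
    return ages


def _covariate_design(
    ages: np.ndarray,
    female: np.ndarray,
    inpatient: np.ndarray,
    secondary: np.ndarray,
    primary_hc: np.ndarray,
) -> dict[str, np.ndarray]:
    return {
        "age_z": (ages - 30.0) / 25.0,
        "female": female.astype(float),
        "inpatient": inpatient.astype(float),
        "secondary": secondary.astype(float),
        "primary_healthcare": primary_hc.astype(float),
    }


def generate_cohort_frames(
    config: ScenarioConfig, vocab: DrugVocabulary = DEFAULT_VOCABULARY
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLedger]:
    """Vectorised core of :func:`generate_cohort`, returning DataFrames.

    The records frame has columns ``participant_id, drug, date, setting,
    hospital_level``; the profiles frame matches
    :func:`nccclaims.claims_io.profiles_frame`. Dates are day indices with
    the observation window at ``[0, observation_days]``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    width = len(str(n - 1))
    pids = np.array([f"P{i:0{width}d}" for i in range(n)])

    ages = _draw_ages(rng, n, config.age_mixture_weights)
    female = rng.random(n) < config.p_female
    inpatient = rng.random(n) < config.p_inpatient
    level = rng.choice(3, size=n, p=list(config.hospital_level_probs))
    secondary = level == 1
    primary_hc = level == 2
    level_names = np.array(["tertiary", "secondary", "primary_healthcare"])[level]
    setting_names = np.where(inpatient, "inpatient", "outpatient")

    # index date: keep a small margin at the end so 0-3 day marker offsets fit
    xyp_day = rng.integers(0, config.observation_days - 4, size=n)

    cov = _covariate_design(ages, female, inpatient, secondary, primary_hc)
    conf_shift = np.zeros(n)
    for key, eff in config.covariate_effects_on_coprescription.items():
        conf_shift += eff * cov[key]

    drugs = list(vocab.target_concomitants)
    exposure = np.zeros((n, len(drugs)), dtype=np.int8)
    for k, drug in enumerate(drugs):
        prev = config.coprescription_prevalence.get(drug, 0.0)
        if prev <= 0.0:
            continue
        base = math.log(prev / (1.0 - prev))
        p = 1.0 / (1.0 + np.exp(-(base + conf_shift)))
        exposure[:, k] = rng.random(n) < p

    allergy_logit = np.full(n, config.baseline_allergy_logodds)
    for key, eff in config.covariate_effects_on_allergy.items():
        allergy_logit += eff * cov[key]
    for k, drug in enumerate(drugs):
        b = config.true_log_or.get(drug, 0.0)
        if b:
            allergy_logit += b * exposure[:, k]
    allergic = rng.random(n) < 1.0 / (1.0 + np.exp(-allergy_logit))

    offsets = np.array(sorted(config.marker_delay_distribution))
    offset_p = np.array([config.marker_delay_distribution[o] for o in offsets])
    marker_offset = np.where(
        allergic, rng.choice(offsets, size=n, p=offset_p), -1
    )
    marker_names = np.array(sorted(vocab.marker_drugs))
    allergy_marker = marker_names[rng.integers(0, len(marker_names), size=n)]
    continue_xyp = rng.random(n) < config.xyp_continuation_probability

    # background (non-allergy) marker prescriptions: per-day Bernoulli thinned
    # to a per-participant count, spread uniformly over the window
    n_background = rng.binomial(config.observation_days, config.background_marker_rate, size=n)

    rec_pid: list[str] = []
    rec_drug: list[str] = []
    rec_date: list[int] = []
    obs_days = config.observation_days

    for i in range(n):
        pid = pids[i]

        def emit(drug: str, day: int) -> None:
            rec_pid.append(pid)
            rec_drug.append(drug)
            rec_date.append(int(day))

        emit(vocab.xyp_name, xyp_day[i])
        for k in np.flatnonzero(exposure[i]):
            emit(drugs[k], xyp_day[i])
        if allergic[i]:
            day = xyp_day[i] + marker_offset[i]
            emit(allergy_marker[i], day)
            if marker_offset[i] == 0 and continue_xyp[i]:
                emit(vocab.xyp_name, xyp_day[i] + 1)
        if n_background[i]:
            days = rng.integers(0, obs_days + 1, size=n_background[i])
            marks = marker_names[rng.integers(0, len(marker_names), size=n_background[i])]
            for d, mk in zip(days, marks):
                emit(str(mk), int(d))

    rec_df = pd.DataFrame(
        {
            "participant_id": rec_pid,
            "drug": rec_drug,
            "date": rec_date,
        }
    )
    per_part = pd.DataFrame(
        {
            "participant_id": pids,
            "setting": setting_names,
            "hospital_level": level_names,
        }
    )
    rec_df = rec_df.merge(per_part, on="participant_id", how="left")
    rec_df = rec_df.sort_values(["participant_id", "date", "drug"], kind="stable").reset_index(
        drop=True
    )

    prof_df = pd.DataFrame(
        {
            "participant_id": pids,
            "age": np.round(ages, 1),
            "gender": np.where(female, "female", "male"),
            "first_xyp_setting": setting_names,
            "first_xyp_hospital_level": level_names,
            "observation_start": 0,
            "observation_end": obs_days,
        }
    )

    truth = pd.DataFrame(
        {
            "participant_id": pids,
            "allergic": allergic,
            "marker_offset": marker_offset,
        }
    )
    for k, drug in enumerate(drugs):
        truth[drug] = exposure[:, k]
    return rec_df, prof_df, TruthLedger(truth)


def generate_cohort(
    config: ScenarioConfig, vocab: DrugVocabulary = DEFAULT_VOCABULARY
) -> tuple[list[PrescriptionRecord], list[ParticipantProfile], TruthLedger]:
    """Generate one synthetic cohort as record/profile objects plus ground truth."""
    rec_df, prof_df, truth = generate_cohort_frames(config, vocab)
    records = [
        PrescriptionRecord(
            participant_id=str(r.participant_id),
            drug=str(r.drug),
            date=int(r.date),
            setting=str(r.setting),
            hospital_level=str(r.hospital_level),
        )
        for r in rec_df.itertuples(index=False)
    ]
    profiles = [
        ParticipantProfile(
            participant_id=str(r.participant_id),
            age=float(r.age),
            gender=str(r.gender),
            first_xyp_setting=str(r.first_xyp_setting),
            first_xyp_hospital_level=str(r.first_xyp_hospital_level),
            observation_start=int(r.observation_start),
            observation_end=int(r.observation_end),
        )
        for r in prof_df.itertuples(index=False)
    ]
    return records, profiles, truth


def simulate_matched_pairs(
    n_pairs: int,
    log_or: Mapping[str, float],
    prevalence: Mapping[str, float],
    seed: int = 0,
) -> "pd.DataFrame":
    """Matched-pair exposure data with exact planted conditional effects.

    For each pair, both members draw independent exposures at the given
    prevalences; which member is the case is then drawn from the conditional
    (pair-level) logistic model, so the matched-pair conditional odds ratio
    of each drug is exactly ``exp(log_or[drug])``. Returns a frame in the
    :class:`nccclaims.estimators.ExposureMatrix` layout.
    """
    drugs = list(prevalence)
    beta = np.array([log_or.get(d, 0.0) for d in drugs])
    p = np.array([prevalence[d] for d in drugs])
    rng = np.random.default_rng(seed)
    x1 = (rng.random((n_pairs, len(drugs))) < p).astype(int)  # member 1
    x2 = (rng.random((n_pairs, len(drugs))) < p).astype(int)  # member 2
    s1 = np.exp(x1 @ beta)
    s2 = np.exp(x2 @ beta)
    member1_is_case = rng.random(n_pairs) < s1 / (s1 + s2)
    case = np.where(member1_is_case[:, None], x1, x2)
    ctrl = np.where(member1_is_case[:, None], x2, x1)

    rows = []
    for j in range(n_pairs):
        rows.append(
            {"pair_id": j, "participant_id": f"C{j}", "arm": "case",
             **{d: int(case[j, k]) for k, d in enumerate(drugs)}}
        )
        rows.append(
            {"pair_id": j, "participant_id": f"K{j}", "arm": "control",
             **{d: int(ctrl[j, k]) for k, d in enumerate(drugs)}}
        )
    frame = pd.DataFrame(rows)
    frame["n_exposures"] = frame[drugs].sum(axis=1)
    return frame


# ---------------------------------------------------------------------------
# hand-built worked fixture
# ---------------------------------------------------------------------------

def make_worked_fixture(
    vocab: DrugVocabulary = DEFAULT_VOCABULARY,
) -> tuple[list[PrescriptionRecord], list[ParticipantProfile]]:
    """A 12-participant fixture covering every case-finder branch.

    Hand-traced outcomes (observation window day 0-365, washout 30 days):

    ========  ====================================  =======================
    id        prescriptions (day)                   classification
    ========  ====================================  =======================
    F01       XYP 100, marker 101                   primary case
    F02       XYP 100, marker 103                   primary case (boundary)
    F03       XYP 100, marker 104                   excluded: marker_gt_3_days
    F04       XYP 100, marker 60                    excluded: marker_before_xyp
    F05       XYP 100, marker 100 (no XYP 101)      expanded_same_day case
    F06       XYP 100+101, marker 100               excluded: same_day_continued
    F07       XYP 50, marker 10                     no_marker (washout runway fails)
    F08       XYP 100 & 140                         no_marker control (index 100)
    F09       ambroxol 30 only                      not in cohort (no XYP)
    F10       XYP 200                               no_marker control
    F11       XYP 100, markers 95 & 101             excluded: marker_before_xyp
    F12       XYP 100, gentamicin 100               no_marker control
    ========  ====================================  =======================

    Primary case set: {F01, F02} (2 members); sensitivity (expanded) case
    set adds F05 (3 members). Concomitant prescriptions on several index
    dates exercise exposure coding downstream.
    """
    rows: list[tuple[str, str, int]] = [
        ("F01", "xyp", 100), ("F01", "gentamicin", 100), ("F01", "vitamin c", 100),
        ("F01", "promethazine", 101),
        ("F02", "xyp", 100), ("F02", "ribavirin", 100), ("F02", "dexamethasone", 103),
        ("F03", "xyp", 100), ("F03", "adrenaline", 104),
        ("F04", "xyp", 100), ("F04", "calcium gluconate", 60),
        ("F05", "xyp", 100), ("F05", "lidocaine", 100), ("F05", "promethazine", 100),
        ("F06", "xyp", 100), ("F06", "xyp", 101), ("F06", "dexamethasone", 100),
        ("F07", "xyp", 50), ("F07", "promethazine", 10),
        ("F08", "xyp", 100), ("F08", "ambroxol", 100), ("F08", "xyp", 140),
        ("F09", "ambroxol", 30),
        ("F10", "xyp", 200), ("F10", "vitamin c", 200),
        ("F11", "xyp", 100), ("F11", "promethazine", 95), ("F11", "promethazine", 101),
        ("F12", "xyp", 100), ("F12", "gentamicin", 100),
    ]
    demo = {
        "F01": (5.0, "male", "inpatient", "secondary"),
        "F02": (9.0, "female", "inpatient", "secondary"),
        "F03": (35.0, "male", "outpatient", "tertiary"),
        "F04": (42.0, "female", "inpatient", "secondary"),
        "F05": (70.0, "male", "inpatient", "tertiary"),
        "F06": (12.0, "female", "outpatient", "primary_healthcare"),
        "F07": (28.0, "male", "inpatient", "secondary"),
        "F08": (6.0, "female", "inpatient", "secondary"),
        "F09": (50.0, "male", "outpatient", "tertiary"),
        "F10": (33.0, "female", "outpatient", "primary_healthcare"),
        "F11": (67.0, "male", "inpatient", "secondary"),
        "F12": (8.0, "female", "inpatient", "tertiary"),
    }
    records = []
    for pid, drug, day in rows:
        age, gender, setting, level = demo[pid]
        name = vocab.xyp_name if drug == "xyp" else drug
        records.append(
            PrescriptionRecord(
                participant_id=pid,
                drug=name,
                date=day,
                setting=setting,
                hospital_level=level,
            )
        )
    profiles = [
        ParticipantProfile(
            participant_id=pid,
            age=age,
            gender=gender,
            first_xyp_setting=setting,
            first_xyp_hospital_level=level,
            observation_start=0,
            observation_end=365,
        )
        for pid, (age, gender, setting, level) in sorted(demo.items())
    ]
    return records, profiles
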