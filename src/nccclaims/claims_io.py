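"""Claims data model and delimited-file I/O.

This module defines the atomic record types every other stage consumes —
one prescription row per drug per calendar date per participant — plus the
controlled drug vocabulary (the index drug, the four anti-allergic marker
drugs used as a surrogate allergy signal, and the 25 target concomitant
medications), and readers/writers for the package's two delimited formats.

Dates are handled internally as integer day indices (days since 1970-01-01).
All temporal window arithmetic downstream is integer subtraction; the claims
sources this models carry no time-of-day information.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

logger = logging.getLogger("nccclaims")

EPOCH = _dt.date(1970, 1, 1)

SETTINGS = ("outpatient", "inpatient")
HOSPITAL_LEVELS = ("tertiary", "secondary", "primary_healthcare")
GENDERS = ("male", "female")

CLAIMS_COLUMNS = (
    "participant_id",
    "age",
    "gender",
    "date",
    "drug",
    "setting",
    "hospital_level",
)

ESTIMATE_COLUMNS = (
    "drug",
    "n_cases_exposed",
    "n_controls_exposed",
    "OR",
    "CI_low",
    "CI_high",
    "p_value",
    "estimator",
)

#: Placeholder used in report files for undefined odds ratios (zero cells).
UNDEFINED_MARK = "—"  # em dash


class ClaimsFormatError(ValueError):
    """Raised for malformed claims or estimate files (bad dates, missing columns)."""


def to_day_index(iso_date: str) -> int:
    """Convert an ISO-8601 date string to an integer day index (days since 1970-01-01)."""
    d = _dt.date.fromisoformat(iso_date)
    return (d - EPOCH).days


def from_day_index(day: int) -> str:
    """Convert an integer day index back to an ISO-8601 date string."""
    return (EPOCH + _dt.timedelta(days=int(day))).isoformat()


def normalize_drug(name: str) -> str:
    """Whitespace-collapse and case-fold a drug name for vocabulary matching."""
    return " ".join(str(name).split()).casefold()


@dataclass(frozen=True)
class PrescriptionRecord:
    """One drug prescription for one participant on one calendar date."""

    participant_id: str
    drug: str
    date: int  # day index
    setting: str
    hospital_level: str

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.hospital_level not in HOSPITAL_LEVELS:
            raise ValueError(f"unknown hospital_level {self.hospital_level!r}")
        if not self.drug:
            raise ValueError("drug name is empty after normalization")


@dataclass(frozen=True)
class ParticipantProfile:
    """Demographics plus the visit attributes used as propensity covariates.

    ``first_xyp_setting`` / ``first_xyp_hospital_level`` are taken from the
    participant's earliest index-drug prescription row; for participants who
    never received the index drug (and hence never enter the cohort) they
    fall back to the first prescription row.
    """

    participant_id: str
    age: float
    gender: str
    first_xyp_setting: str
    first_xyp_hospital_level: str
    observation_start: int
    observation_end: int

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"negative age for participant {self.participant_id}")
        if self.gender not in GENDERS:
            raise ValueError(f"unknown gender {self.gender!r}")
        if self.observation_start > self.observation_end:
            raise ValueError("observation_start must be <= observation_end")


@dataclass(frozen=True)
class DrugVocabulary:
    """The controlled vocabulary: index drug, marker drugs, target concomitants."""

    xyp_name: str
    marker_drugs: frozenset[str]
    target_concomitants: tuple[str, ...]

    def __post_init__(self) -> None:
        groups = [{self.xyp_name}, set(self.marker_drugs), set(self.target_concomitants)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("index drug, marker drugs and concomitants must be disjoint")
        if len(self.target_concomitants) != len(set(self.target_concomitants)):
            raise ValueError("duplicate concomitant drug names")

    def classify(self, drug: str) -> str:
        """Return one of ``{"xyp", "marker", "concomitant", "other"}`` for a normalized name."""
        if drug == self.xyp_name:
            return "xyp"
        if drug in self.marker_drugs:
            return "marker"
        if drug in self.target_concomitants:
            return "concomitant"
        return "other"


#: The four anti-allergic marker drugs that signal a suspected allergic reaction.
MARKER_DRUGS = frozenset(
    {"promethazine", "dexamethasone", "calcium gluconate", "adrenaline"}
)

#: The 25 target concomitant medications, in reporting order.
TARGET_CONCOMITANTS = (
    "amoxicillin-clavulanate",
    "penicillin",
    "cefuroxime",
    "cefathiamidine",
    "cefoperazone-sulbactam",
    "ceftriaxone",
    "ceftazidime",
    "cefazolin",
    "meropenem",
    "amikacin",
    "gentamicin",
    "azithromycin",
    "levofloxacin",
    "moxifloxacin",
    "vitamin b6",
    "vitamin c",
    "aminophylline",
    "ambroxol",
    "heparin",
    "ribavirin",
    "lidocaine",
    "pantoprazole",
    "sodium bicarbonate",
    "bromhexine",
    "potassium chloride",
)

DEFAULT_VOCABULARY = DrugVocabulary(
    xyp_name="xiyanping",
    marker_drugs=MARKER_DRUGS,
    target_concomitants=TARGET_CONCOMITANTS,
)


@dataclass
class EffectEstimate:
    """One odds-ratio estimate for one drug (or contrast), with 95% CI and p-value.

    ``or_value``/``ci_low``/``ci_high``/``p_value`` are ``None`` when the
    estimate is undefined (zero cells without continuity correction); report
    writers render these as an em dash, as is conventional in published
    tables.
    """

    drug: str
    or_value: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    estimator: str
    n_exposed_cases: int = 0
    n_exposed_controls: int = 0

    def __post_init__(self) -> None:
        if self.or_value is not None:
            if not (self.ci_low is None or self.ci_low <= self.or_value + 1e-12):
                raise ValueError("ci_low must not exceed the point estimate")
            if not (self.ci_high is None or self.or_value <= self.ci_high + 1e-12):
                raise ValueError("ci_high must not fall below the point estimate")


# ---------------------------------------------------------------------------
# claims reading / writing
# ---------------------------------------------------------------------------

def records_frame(records) -> pd.DataFrame:
    """Normalize a list of PrescriptionRecord (or an equivalent DataFrame) to a DataFrame."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame(
        {
            "participant_id": [r.participant_id for r in records],
            "drug": [r.drug for r in records],
            "date": [r.date for r in records],
            "setting": [r.setting for r in records],
            "hospital_level": [r.hospital_level for r in records],
        }
    )


def profiles_frame(profiles) -> pd.DataFrame:
    """Normalize a list of ParticipantProfile (or an equivalent DataFrame) to a DataFrame."""
    if isinstance(profiles, pd.DataFrame):
        return profiles
    return pd.DataFrame(
        {
            "participant_id": [p.participant_id for p in profiles],
            "age": [p.age for p in profiles],
            "gender": [p.gender for p in profiles],
            "first_xyp_setting": [p.first_xyp_setting for p in profiles],
            "first_xyp_hospital_level": [p.first_xyp_hospital_level for p in profiles],
            "observation_start": [p.observation_start for p in profiles],
            "observation_end": [p.observation_end for p in profiles],
        }
    )


def _derive_profiles(
    df: pd.DataFrame,
    vocabulary: DrugVocabulary,
    observation_window: tuple[int, int] | None,
) -> list[ParticipantProfile]:
    if observation_window is None:
        obs_start = int(df["date"].min())
        obs_end = int(df["date"].max())
    else:
        obs_start, obs_end = int(observation_window[0]), int(observation_window[1])

    profiles: list[ParticipantProfile] = []
    # first index-drug row per participant; fall back to the first row overall
    for pid, grp in df.sort_values(["date"], kind="stable").groupby(
        "participant_id", sort=True
    ):
        xyp_rows = grp[grp["drug"] == vocabulary.xyp_name]
        anchor = xyp_rows.iloc[0] if len(xyp_rows) else grp.iloc[0]
        profiles.append(
            ParticipantProfile(
                participant_id=str(pid),
                age=float(grp["age"].iloc[0]),
                gender=str(grp["gender"].iloc[0]),
                first_xyp_setting=str(anchor["setting"]),
                first_xyp_hospital_level=str(anchor["hospital_level"]),
                observation_start=obs_start,
                observation_end=obs_end,
            )
        )
    return profiles


def read_claims(
    path: str | Path,
    vocabulary: DrugVocabulary = DEFAULT_VOCABULARY,
    observation_window: tuple[int, int] | None = None,
) -> tuple[list[PrescriptionRecord], list[ParticipantProfile]]:
    """Read a claims CSV into prescription records and per-participant profiles.

    The file is UTF-8, comma-delimited, with header
    ``participant_id,age,gender,date,drug,setting,hospital_level`` and
    ISO-8601 dates. Drug names are normalized (whitespace-collapsed,
    case-folded); names outside the controlled vocabulary are retained
    verbatim but logged. When ``observation_window`` (a ``(start, end)`` pair
    of day indices) is not given, a shared study window is inferred as the
    global minimum/maximum prescription date in the file.

    Raises
    ------
    ClaimsFormatError
        If a required column is missing (fatal) or a date fails to parse
        (the error names the offending line).
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CLAIMS_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    if df.empty:
        return [], []

    days = []
    for i, raw in enumerate(df["date"]):
        try:
            days.append(to_day_index(raw))
        except ValueError as exc:
            # +2: header line plus 1-based numbering
            raise ClaimsFormatError(f"{path}, line {i + 2}: invalid date {raw!r}") from exc
    df = df.assign(date=days, drug=df["drug"].map(normalize_drug))
    df["age"] = pd.to_numeric(df["age"], errors="raise")

    unknown = sorted(
        {d for d in df["drug"].unique() if vocabulary.classify(d) == "other"}
    )
    if unknown:
        logger.warning(
            "read_claims: %d drug name(s) outside the controlled vocabulary "
            "retained verbatim: %s",
            len(unknown),
            ", ".join(unknown[:10]),
        )

    records = [
        PrescriptionRecord(
            participant_id=str(r.participant_id),
            drug=str(r.drug),
            date=int(r.date),
            setting=str(r.setting),
            hospital_level=str(r.hospital_level),
        )
        for r in df.itertuples(index=False)
    ]
    profiles = _derive_profiles(df, vocabulary, observation_window)
    return records, profiles


def write_claims(records, profiles, path: str | Path) -> None:
    """Write prescription records (joined with profile demographics) to a claims CSV."""
    rec = records_frame(records)
    prof = profiles_frame(profiles)[["participant_id", "age", "gender"]]
    out = rec.merge(prof, on="participant_id", how="left", validate="many_to_one")
    if out["age"].isna().any():
        orphans = sorted(out.loc[out["age"].isna(), "participant_id"].unique())
        raise ValueError(f"records without a matching profile: {orphans[:5]}")
    out = out.assign(date=out["date"].map(from_day_index))
    out = out[list(CLAIMS_COLUMNS)]
    out = out.sort_values(["participant_id", "date", "drug"], kind="stable")
    out.to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# estimate tables
# ---------------------------------------------------------------------------

def _fmt_or(x: float | None) -> str:
    return UNDEFINED_MARK if x is None or not math.isfinite(x) else f"{x:.2f}"


def format_p(p: float | None) -> str:
    """Render a p-value to 2 decimals with a ``<0.01`` floor, table style."""
    if p is None or not math.isfinite(p):
        return UNDEFINED_MARK
    if p < 0.005:
        return "<0.01"
    return f"{p:.2f}"


def write_estimates(rows: Sequence[EffectEstimate], path: str | Path) -> None:
    """Write effect estimates as a delimited report table.

    Odds ratios and confidence limits are rounded to 2 decimals; p-values are
    floored at ``<0.01``; undefined estimates (zero cells) render as an em
    dash.
    """
    if not rows:
        raise ValueError("write_estimates: no rows to write")
    df = pd.DataFrame(
        {
            "drug": [r.drug for r in rows],
            "n_cases_exposed": [r.n_exposed_cases for r in rows],
            "n_controls_exposed": [r.n_exposed_controls for r in rows],
            "OR": [_fmt_or(r.or_value) for r in rows],
            "CI_low": [_fmt_or(r.ci_low) for r in rows],
            "CI_high": [_fmt_or(r.ci_high) for r in rows],
            "p_value": [format_p(r.p_value) for r in rows],
            "estimator": [r.estimator for r in rows],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_estimates(path: str | Path) -> list[EffectEstimate]:
    """Read back an estimates table written by :func:`write_estimates`.

    Values come back at rendered precision (2 decimals); ``<0.01`` p-values
    are read as 0.0 and em dashes as ``None``.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ESTIMATE_COLUMNS if c not in df.columns]
    if missing:
        raise ClaimsFormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    def _num(s: str) -> float | None:
        if s == UNDEFINED_MARK:
            return None
        if s == "<0.01":
            return 0.0
        return float(s)

    return [
        EffectEstimate(
            drug=str(r.drug),
            or_value=_num(r.OR),
            ci_low=_num(r.CI_low),
            ci_high=_num(r.CI_high),
            p_value=_num(r.p_value),
            estimator=str(r.estimator),
            n_exposed_cases=int(r.n_cases_exposed),
            n_exposed_controls=int(r.n_controls_exposed),
        )
        for r in df.itertuples(index=False)
    ]
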