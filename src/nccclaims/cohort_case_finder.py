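"""Cohort construction and surrogate case ascertainment.

The cohort is every participant with at least one index-drug prescription;
the index date is the earliest such prescription. A suspected allergic
reaction is ascertained from the first *incident* anti-allergic marker-drug
prescription — one preceded by at least a configurable washout (default 30
marker-free observed days) — and classified by its day offset from the index
date:

* offset 1–3 days  → primary-definition case;
* offset 0 with the index drug *not* re-prescribed the next day →
  expanded-definition case (used in sensitivity analyses); the next-day stop
  is read as the prescriber reacting to a same-day allergy;
* offset 0 with the index drug continued, offset > 3, or a marker before the
  index date → excluded from both case and control sets;
* no qualifying marker at all → control-eligible.

Every cohort member falls in exactly one of those buckets, which is also the
accounting the attrition flowchart reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .claims_io import (
    DEFAULT_VOCABULARY,
    DrugVocabulary,
    profiles_frame,
    records_frame,
)

DEFAULT_WASHOUT_DAYS = 30

#: Exhaustive classification outcomes (case definitions + exclusion reasons).
CLASSIFICATIONS = (
    "primary",
    "expanded_same_day",
    "no_marker",
    "marker_before_xyp",
    "same_day_continued",
    "marker_gt_3_days",
)

CASE_WINDOW_DAYS = 3  # markers up to this many days after the index date count


class CohortConsistencyError(ValueError):
    """Raised when claims rows and profiles disagree (e.g. an orphan participant)."""


@dataclass(frozen=True)
class CohortMember:
    participant_id: str
    index_date: int
    age: float
    gender: str
    setting: str
    hospital_level: str
    observation_start: int
    observation_end: int


@dataclass(frozen=True)
class CaseRecord:
    participant_id: str
    index_date: int
    first_marker_date: int
    marker_drug: str
    definition: str  # "primary" | "expanded_same_day"

    def __post_init__(self) -> None:
        d = self.first_marker_date - self.index_date
        if self.definition == "primary" and not (1 <= d <= CASE_WINDOW_DAYS):
            raise ValueError(f"primary case offset {d} outside 1..{CASE_WINDOW_DAYS}")
        if self.definition == "expanded_same_day" and d != 0:
            raise ValueError("expanded_same_day case must have marker on the index date")


@dataclass(frozen=True)
class Classification:
    """Outcome of classify_case: either a CaseRecord or an exclusion reason."""

    participant_id: str
    outcome: str  # one of CLASSIFICATIONS
    case: CaseRecord | None = None


def build_cohort(
    records,
    profiles,
    vocab: DrugVocabulary = DEFAULT_VOCABULARY,
) -> list[CohortMember]:
    """One CohortMember per participant with >=1 index-drug prescription.

    The index date is the earliest index-drug prescription; the setting and
    hospital-level covariates are taken from that prescription row (smallest
    date, ties broken by row order).
    """
    rec = records_frame(records)
    prof = profiles_frame(profiles)

    xyp = rec[rec["drug"] == vocab.xyp_name]
    if xyp.empty:
        return []
    first = (
        xyp.sort_values(["participant_id", "date"], kind="stable")
        .drop_duplicates("participant_id", keep="first")
    )
    merged = first.merge(
        prof, on="participant_id", how="left", validate="one_to_one", indicator=True
    )
    orphans = merged.loc[merged["_merge"] != "both", "participant_id"]
    if len(orphans):
        raise CohortConsistencyError(
            f"index-drug records without profiles: {sorted(orphans)[:5]}"
        )
    return [
        CohortMember(
            participant_id=str(r.participant_id),
            index_date=int(r.date),
            age=float(r.age),
            gender=str(r.gender),
            setting=str(r.setting),
            hospital_level=str(r.hospital_level),
            observation_start=int(r.observation_start),
            observation_end=int(r.observation_end),
        )
        for r in merged.itertuples(index=False)
    ]


def find_incident_marker(
    records,
    member: CohortMember,
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    vocab: DrugVocabulary = DEFAULT_VOCABULARY,
) -> tuple[int, str] | None:
    """Earliest incident marker prescription for one cohort member, or None.

    A marker prescription on day ``m`` is incident when (a) at least
    ``washout_days`` of observation precede it (``m - observation_start >=
    washout_days``) and (b) no marker prescription falls in
    ``[m - washout_days, m - 1]``. Returns ``(date, marker_drug)`` for the
    earliest qualifying prescription.
    """
    rec = records_frame(records)
    mine = rec[rec["participant_id"] == member.participant_id]
    markers = mine[mine["drug"].isin(vocab.marker_drugs)].sort_values(
        ["date", "drug"], kind="stable"
    )
    if markers.empty:
        return None
    dates = markers["date"].to_numpy()
    for i in range(len(markers)):
        m = int(dates[i])
        if m - member.observation_start < washout_days:
            continue
        prior_in_washout = ((dates >= m - washout_days) & (dates <= m - 1)).any()
        if prior_in_washout:
            continue
        return m, str(markers["drug"].iloc[i])
    return None


def classify_case(
    member: CohortMember,
    incident_marker: tuple[int, str] | None,
    records,
    vocab: DrugVocabulary = DEFAULT_VOCABULARY,
) -> Classification:
    """Map one cohort member to a case record or an exclusion reason.

    Total over the cohort: every member receives exactly one of the six
    outcomes in :data:`CLASSIFICATIONS`.
    """
    pid = member.participant_id
    if incident_marker is None:
        return Classification(pid, "no_marker")
    marker_date, marker_drug = incident_marker
    d = marker_date - member.index_date
    if d < 0:
        return Classification(pid, "marker_before_xyp")
    if d == 0:
        rec = records_frame(records)
        mine = rec[rec["participant_id"] == pid]
        continued = (
            (mine["drug"] == vocab.xyp_name) & (mine["date"] == member.index_date + 1)
        ).any()
        if continued:
            return Classification(pid, "same_day_continued")
        case = CaseRecord(pid, member.index_date, marker_date, marker_drug, "expanded_same_day")
        return Classification(pid, "expanded_same_day", case)
    if d <= CASE_WINDOW_DAYS:
        case = CaseRecord(pid, member.index_date, marker_date, marker_drug, "primary")
        return Classification(pid, "primary", case)
    return Classification(pid, "marker_gt_3_days")


def classify_cohort(
    records,
    cohort: Iterable[CohortMember],
    washout_days: int = DEFAULT_WASHOUT_DAYS,
    vocab: DrugVocabulary = DEFAULT_VOCABULARY,
) -> list[Classification]:
    """Vectorized classification of a whole cohort (same rules as the per-member path)."""
    rec = records_frame(records)
    members = list(cohort)

    # per-participant marker (date, drug) arrays via one global sort + slicing
    marker_rows = rec[rec["drug"].isin(vocab.marker_drugs)].sort_values(
        ["participant_id", "date", "drug"], kind="stable"
    )
    mk_pid = marker_rows["participant_id"].to_numpy()
    mk_date = marker_rows["date"].to_numpy()
    mk_drug = marker_rows["drug"].to_numpy()
    uniq, starts = np.unique(mk_pid, return_index=True)
    bounds = np.append(starts, len(mk_pid))
    markers_by_pid: dict[str, tuple[np.ndarray, np.ndarray]] = {
        str(uniq[i]): (mk_date[bounds[i] : bounds[i + 1]], mk_drug[bounds[i] : bounds[i + 1]])
        for i in range(len(uniq))
    }
    xyp_rows = rec[rec["drug"] == vocab.xyp_name]
    xyp_dates_by_pid: dict[str, set] = {}
    for pid, d in zip(xyp_rows["participant_id"].to_numpy(), xyp_rows["date"].to_numpy()):
        xyp_dates_by_pid.setdefault(str(pid), set()).add(int(d))

    out: list[Classification] = []
    for m in members:
        found = markers_by_pid.get(m.participant_id)
        incident: tuple[int, str] | None = None
        if found is not None:
            dates, drugs = found
            for i in range(len(dates)):
                md = int(dates[i])
                if md - m.observation_start < washout_days:
                    continue
                if ((dates >= md - washout_days) & (dates <= md - 1)).any():
                    continue
                incident = (md, str(drugs[i]))
                break
        if incident is None:
            out.append(Classification(m.participant_id, "no_marker"))
            continue
        marker_date, marker_drug = incident
        d = marker_date - m.index_date
        if d < 0:
            out.append(Classification(m.participant_id, "marker_before_xyp"))
        elif d == 0:
            if m.index_date + 1 in xyp_dates_by_pid.get(m.participant_id, ()):
                out.append(Classification(m.participant_id, "same_day_continued"))
            else:
                case = CaseRecord(
                    m.participant_id, m.index_date, marker_date, marker_drug, "expanded_same_day"
                )
                out.append(Classification(m.participant_id, "expanded_same_day", case))
        elif d <= CASE_WINDOW_DAYS:
            case = CaseRecord(m.participant_id, m.index_date, marker_date, marker_drug, "primary")
            out.append(Classification(m.participant_id, "primary", case))
        else:
            out.append(Classification(m.participant_id, "marker_gt_3_days"))
    return out


class EmptyCaseSetError(RuntimeError):
    """Raised when ascertainment yields no cases (the pipeline cannot proceed)."""


def select_analysis_sets(
    cohort: Iterable[CohortMember],
    classifications: Iterable[Classification],
    mode: str = "primary",
) -> tuple[list[CaseRecord], list[CohortMember]]:
    """Split the classified cohort into the case set and the control pool.

    ``mode="primary"`` keeps primary-definition cases only; ``mode=
    "sensitivity"`` adds the expanded same-day cases. The control pool is the
    members with no qualifying incident marker; members excluded for marker
    timing appear in neither set.
    """
    if mode not in ("primary", "sensitivity"):
        raise ValueError(f"unknown mode {mode!r}")
    member_by_id = {m.participant_id: m for m in cohort}
    wanted = ("primary",) if mode == "primary" else ("primary", "expanded_same_day")
    cases = [c.case for c in classifications if c.outcome in wanted]
    controls = [member_by_id[c.participant_id] for c in classifications if c.outcome == "no_marker"]
    if not cases:
        raise EmptyCaseSetError(
            f"case ascertainment produced no {mode} cases; nothing to analyze"
        )
    return cases, controls


def classification_counts(classifications: Iterable[Classification]) -> dict[str, int]:
    """Count members per classification bucket (flowchart accounting)."""
    counts = {k: 0 for k in CLASSIFICATIONS}
    for c in classifications:
        counts[c.outcome] += 1
    return counts
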