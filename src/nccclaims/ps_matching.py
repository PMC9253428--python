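"""Propensity-score estimation and 1:1 greedy nearest-neighbour matching.

The propensity score is the modelled probability of being a case given four
baseline covariates — age (continuous), gender, visit setting
(outpatient/inpatient), and hospital level (tertiary / secondary / primary
healthcare, tertiary as reference) — fitted by a maximum-likelihood logistic
regression (iteratively reweighted least squares). Matching is greedy
without replacement: cases are processed in descending propensity score and
each takes the closest unused control on the probability scale.

All orderings are made deterministic by documented tie-breaks (ascending
participant id), so a given case/control input always yields the same pairs
regardless of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort_case_finder import CohortMember

COEF_NAMES = (
    "intercept",
    "age",
    "gender_female",
    "setting_inpatient",
    "level_secondary",
    "level_primary_healthcare",
)

MAX_IRLS_ITER = 100
SCORE_TOL = 1e-8


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist; names the covariate."""


@dataclass
class MatchedPair:
    case_id: str
    control_id: str
    ps_case: float
    ps_control: float

    @property
    def distance(self) -> float:
        return abs(self.ps_case - self.ps_control)


@dataclass
class PropensityModel:
    coefficients: np.ndarray  # length 6, order COEF_NAMES
    fitted: bool
    n_iterations: int
    final_score_norm: float

    def design_matrix(self, members: Sequence[CohortMember]) -> np.ndarray:
        X = np.empty((len(members), 6))
        for i, m in enumerate(members):
            X[i] = (
                1.0,
                m.age,
                1.0 if m.gender == "female" else 0.0,
                1.0 if m.setting == "inpatient" else 0.0,
                1.0 if m.hospital_level == "secondary" else 0.0,
                1.0 if m.hospital_level == "primary_healthcare" else 0.0,
            )
        return X

    def predict(self, members: Sequence[CohortMember]) -> np.ndarray:
        """Propensity scores (probability scale) for a sequence of members."""
        if not self.fitted:
            raise RuntimeError("model has not been fitted")
        eta = self.design_matrix(members) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))


def _check_separation(X: np.ndarray, y: np.ndarray) -> None:
    """Raise SeparationError if any single covariate perfectly separates cases."""
    for j, name in enumerate(COEF_NAMES[1:], start=1):
        xj = X[:, j]
        lo1, hi1 = xj[y == 1].min(), xj[y == 1].max()
        lo0, hi0 = xj[y == 0].min(), xj[y == 0].max()
        if hi1 < lo0 or hi0 < lo1:
            raise SeparationError(
                f"covariate {name!r} perfectly separates cases from controls; "
                "the propensity model cannot be estimated"
            )


def fit_propensity(
    cases: Sequence[CohortMember], control_pool: Sequence[CohortMember]
) -> PropensityModel:
    """Fit the four-covariate case-status logistic model by IRLS.

    Converges when the maximum absolute score (gradient of the
    log-likelihood) falls below 1e-8, within 100 iterations. Perfect
    separation raises :class:`SeparationError` naming the separating
    covariate rather than returning divergent coefficients.
    """
    if not len(cases) or not len(control_pool):
        raise ValueError("need at least one case and one control to fit the model")
    members = list(cases) + list(control_pool)
    model = PropensityModel(np.zeros(6), fitted=False, n_iterations=0, final_score_norm=np.inf)
    X = model.design_matrix(members)
    y = np.concatenate([np.ones(len(cases)), np.zeros(len(control_pool))])
    _check_separation(X, y)

    # drop constant non-intercept columns (no variation -> unidentified); keep
    # their coefficients at zero
    active = [0] + [j for j in range(1, 6) if np.ptp(X[:, j]) > 0]
    Xa = X[:, active]
    beta = np.zeros(len(active))
    # stabilizing start: intercept at the logit of the case fraction
    pbar = y.mean()
    beta[0] = np.log(pbar / (1 - pbar))

    score_norm = np.inf
    for it in range(1, MAX_IRLS_ITER + 1):
        eta = Xa @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        score = Xa.T @ (y - p)
        score_norm = float(np.max(np.abs(score)))
        if score_norm < SCORE_TOL:
            break
        w = p * (1.0 - p)
        if np.max(w) < 1e-12 or np.max(np.abs(beta)) > 50:
            raise SeparationError(
                "propensity model diverged (quasi-separation); "
                "check covariates for complete separation"
            )
        XtWX = (Xa * w[:, None]).T @ Xa
        try:
            delta = np.linalg.solve(XtWX, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        beta = beta + delta
    else:
        it = MAX_IRLS_ITER
    if score_norm >= SCORE_TOL and np.max(np.abs(beta)) > 50:
        raise SeparationError("propensity model failed to converge (quasi-separation)")

    full = np.zeros(6)
    full[active] = beta
    model.coefficients = full
    model.fitted = True
    model.n_iterations = it
    model.final_score_norm = score_norm
    return model


def greedy_match(
    cases: Sequence[CohortMember],
    control_pool: Sequence[CohortMember],
    model: PropensityModel,
    caliper: float | None = None,
    seed: int = 0,
    order: str = "descending",
) -> list[MatchedPair]:
    """1:1 greedy nearest-neighbour matching without replacement.

    Cases are processed in descending propensity score (ties broken by
    ascending participant id; ``order="random"`` shuffles with ``seed``
    instead). Each case takes the unused control minimising the absolute
    propensity-score difference, ties again by ascending control id. With a
    ``caliper`` (probability-scale width), cases with no control inside it
    stay unmatched. Fewer controls than cases yields a partial matching.
    """
    if order not in ("descending", "random"):
        raise ValueError(f"unknown matching order {order!r}")
    ps_case = model.predict(cases)
    ps_ctrl = model.predict(control_pool)
    case_ids = np.array([m.participant_id for m in cases])
    ctrl_ids = np.array([m.participant_id for m in control_pool])

    if order == "descending":
        case_order = np.lexsort((case_ids, -ps_case))
    else:
        case_order = np.random.default_rng(seed).permutation(len(cases))

    # canonical control order (by id) so float-distance ties resolve by id
    ctrl_sort = np.argsort(ctrl_ids, kind="stable")
    ctrl_ids = ctrl_ids[ctrl_sort]
    ps_ctrl = ps_ctrl[ctrl_sort]
    available = np.ones(len(ctrl_ids), dtype=bool)

    pairs: list[MatchedPair] = []
    for i in case_order:
        if not available.any():
            break
        dist = np.abs(ps_ctrl - ps_case[i])
        dist[~available] = np.inf
        best = float(dist.min())
        if caliper is not None and best > caliper:
            continue
        if not np.isfinite(best):
            continue
        j = int(np.flatnonzero(dist == best)[0])  # ids ascending -> first is smallest id
        available[j] = False
        pairs.append(
            MatchedPair(
                case_id=str(case_ids[i]),
                control_id=str(ctrl_ids[j]),
                ps_case=float(ps_case[i]),
                ps_control=float(ps_ctrl[j]),
            )
        )

    _assert_no_replacement(pairs, len(cases), len(control_pool))
    return pairs


def _assert_no_replacement(pairs: Sequence[MatchedPair], n_cases: int, n_controls: int) -> None:
    case_ids = [p.case_id for p in pairs]
    ctrl_ids = [p.control_id for p in pairs]
    assert len(set(case_ids)) == len(case_ids), "duplicate case in matching"
    assert len(set(ctrl_ids)) == len(ctrl_ids), "duplicate control in matching"
    assert len(pairs) <= min(n_cases, n_controls)


def _smd_continuous(x1: np.ndarray, x0: np.ndarray) -> float:
    m1, m0 = x1.mean(), x0.mean()
    s = np.sqrt((x1.var(ddof=1) + x0.var(ddof=1)) / 2.0) if len(x1) > 1 and len(x0) > 1 else 0.0
    return 0.0 if s == 0 else float((m1 - m0) / s)


def _smd_proportion(p1: float, p0: float) -> float:
    s = np.sqrt((p1 * (1 - p1) + p0 * (1 - p0)) / 2.0)
    return 0.0 if s == 0 else float((p1 - p0) / s)


def balance_table(
    pairs: Sequence[MatchedPair],
    cases: Sequence[CohortMember],
    controls: Sequence[CohortMember],
) -> pd.DataFrame:
    """Covariate balance between matched cases and matched controls.

    One row per covariate level: the case and control summaries (mean ± SD
    for age, n (%) for categorical levels) and the standardized mean
    difference.
    """
    if not pairs:
        raise ValueError("balance_table requires at least one matched pair")
    case_by_id = {m.participant_id: m for m in cases}
    ctrl_by_id = {m.participant_id: m for m in controls}
    mc = [case_by_id[p.case_id] for p in pairs]
    mk = [ctrl_by_id[p.control_id] for p in pairs]

    rows = []
    age1 = np.array([m.age for m in mc])
    age0 = np.array([m.age for m in mk])
    rows.append(
        {
            "covariate": "age",
            "level": "",
            "cases": f"{age1.mean():.2f} ± {age1.std(ddof=1):.2f}" if len(age1) > 1 else f"{age1.mean():.2f}",
            "controls": f"{age0.mean():.2f} ± {age0.std(ddof=1):.2f}" if len(age0) > 1 else f"{age0.mean():.2f}",
            "smd": _smd_continuous(age1, age0),
        }
    )
    categorical = (
        ("gender", lambda m: m.gender, ("male", "female")),
        ("setting", lambda m: m.setting, ("outpatient", "inpatient")),
        (
            "hospital_level",
            lambda m: m.hospital_level,
            ("tertiary", "secondary", "primary_healthcare"),
        ),
    )
    n1, n0 = len(mc), len(mk)
    for name, get, levels in categorical:
        for level in levels:
            k1 = sum(get(m) == level for m in mc)
            k0 = sum(get(m) == level for m in mk)
            p1, p0 = k1 / n1, k0 / n0
            rows.append(
                {
                    "covariate": name,
                    "level": level,
                    "cases": f"{k1} ({100 * p1:.2f})",
                    "controls": f"{k0} ({100 * p0:.2f})",
                    "smd": _smd_proportion(p1, p0),
                }
            )
    return pd.DataFrame(rows, columns=["covariate", "level", "cases", "controls", "smd"])


def balance_table_unmatched(
    cases: Sequence[CohortMember], controls: Sequence[CohortMember]
) -> pd.DataFrame:
    """Pre-matching balance: cases vs the whole control pool (same layout)."""
    case_list, ctrl_list = list(cases), list(controls)
    rows = []
    age1 = np.array([m.age for m in case_list])
    age0 = np.array([m.age for m in ctrl_list])
    rows.append(
        {
            "covariate": "age",
            "level": "",
            "cases": f"{age1.mean():.2f} ± {age1.std(ddof=1):.2f}",
            "controls": f"{age0.mean():.2f} ± {age0.std(ddof=1):.2f}",
            "smd": _smd_continuous(age1, age0),
        }
    )
    for name, get, levels in (
        ("gender", lambda m: m.gender, ("male", "female")),
        ("setting", lambda m: m.setting, ("outpatient", "inpatient")),
        ("hospital_level", lambda m: m.hospital_level, ("tertiary", "secondary", "primary_healthcare")),
    ):
        for level in levels:
            p1 = sum(get(m) == level for m in case_list) / len(case_list)
            p0 = sum(get(m) == level for m in ctrl_list) / len(ctrl_list)
            rows.append(
                {
                    "covariate": name,
                    "level": level,
                    "cases": f"{100 * p1:.2f}%",
                    "controls": f"{100 * p0:.2f}%",
                    "smd": _smd_proportion(p1, p0),
                }
            )
    return pd.DataFrame(rows, columns=["covariate", "level", "cases", "controls", "smd"])
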