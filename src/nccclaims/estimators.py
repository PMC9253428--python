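"""Exposure coding and odds-ratio estimation for matched case-control data.

Exposure to a target concomitant medication is same-date co-prescription
with the participant's index-drug prescription; for cases the co-prescription
must additionally not postdate the first marker-drug prescription (which is
automatic under same-date coding, and asserted). Marker drugs themselves are
never exposures.

Three estimators are provided for each drug:

* ``crude`` — the unmatched 2×2 cross-product odds ratio with a Woolf
  (log-scale Wald) confidence interval;
* ``discordant_pair`` — the matched-pair odds ratio ``n10/n01`` with an
  exact McNemar p-value (doubled binomial tail);
* ``conditional_multivariable`` — conditional logistic regression on the
  pair differences, maximised by Newton-Raphson, with Wald intervals; a
  backward-elimination wrapper reproduces the usual stepwise model-building
  at a fixed two-sided alpha.

For a single binary exposure the conditional-logistic estimate equals
``ln(n10/n01)`` in closed form; that identity is used as a cross-check in
the test-suite rather than assumed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .claims_io import (
    DEFAULT_VOCABULARY,
    DrugVocabulary,
    EffectEstimate,
    profiles_frame,
    records_frame,
)
from .cohort_case_finder import CaseRecord
from .ps_matching import MatchedPair

logger = logging.getLogger("nccclaims")

Z95 = 1.959963984540054  # two-sided 95% normal quantile

AGE_BANDS = ("<18", "18-64", ">=65")

NEWTON_TOL = 1e-8
NEWTON_MAX_ITER = 200


class UnidentifiedEffectError(RuntimeError):
    """A coefficient has no finite MLE (zero or monotone discordance); names the drug(s).

    ``drugs`` carries the offending drug names when they can be attributed,
    so callers (backward elimination) can drop them and continue.
    """

    def __init__(self, message: str, drugs: tuple[str, ...] = ()):
        super().__init__(message)
        self.drugs = tuple(drugs)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-status table: a/b exposed/unexposed cases, c/d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass
class ExposureMatrix:
    """One row per matched participant: pair id, arm, 25 binary indicators.

    ``frame`` columns: ``pair_id``, ``participant_id``, ``arm`` ("case" /
    "control") and one 0/1 column per target drug, plus ``n_exposures`` (the
    row sum). Every pair id appears exactly twice, once per arm.
    """

    frame: pd.DataFrame
    drugs: tuple[str, ...]

    def __post_init__(self) -> None:
        f = self.frame
        expected = f[list(self.drugs)].sum(axis=1)
        if not (f["n_exposures"] == expected).all():
            raise ValueError("n_exposures must equal the row sum of the indicators")
        per_pair = f.groupby("pair_id")["arm"].agg(["count", "nunique"])
        if not ((per_pair["count"] == 2) & (per_pair["nunique"] == 2)).all():
            raise ValueError("every pair_id must appear exactly twice, once per arm")

    @property
    def n_pairs(self) -> int:
        return self.frame["pair_id"].nunique()

    def arm(self, which: str) -> pd.DataFrame:
        return (
            self.frame[self.frame["arm"] == which]
            .set_index("pair_id")
            .sort_index()
        )

    def pair_differences(self, drugs: Sequence[str] | None = None) -> np.ndarray:
        """Case-minus-control indicator differences, one row per pair."""
        drugs = list(drugs if drugs is not None else self.drugs)
        cases = self.arm("case")[drugs].to_numpy(dtype=float)
        ctrls = self.arm("control")[drugs].to_numpy(dtype=float)
        return cases - ctrls

    def two_by_two(self, drug: str) -> TwoByTwo:
        case_arm = self.frame[self.frame["arm"] == "case"]
        ctrl_arm = self.frame[self.frame["arm"] == "control"]
        a = int(case_arm[drug].sum())
        c = int(ctrl_arm[drug].sum())
        return TwoByTwo(a=a, b=len(case_arm) - a, c=c, d=len(ctrl_arm) - c)


def code_exposures(
    pairs: Sequence[MatchedPair],
    records,
    vocab: DrugVocabulary = DEFAULT_VOCABULARY,
    cases: Sequence[CaseRecord] | None = None,
) -> ExposureMatrix:
    """Build the matched exposure matrix from claims records.

    A participant is exposed to a target drug iff they have a prescription
    for it dated exactly on their index (first index-drug) date. For case
    arms the exposure date must not exceed the first marker date — asserted,
    since the marker never precedes the index date for an ascertained case.
    """
    rec = records_frame(records)
    wanted_ids = {p.case_id for p in pairs} | {p.control_id for p in pairs}
    missing = wanted_ids - set(rec["participant_id"].unique())
    if missing:
        raise ValueError(f"matched participants missing from claims: {sorted(missing)[:5]}")

    xyp = rec[rec["drug"] == vocab.xyp_name]
    index_date = xyp.groupby("participant_id")["date"].min()

    case_marker = {c.participant_id: c.first_marker_date for c in (cases or [])}

    conc = rec[rec["drug"].isin(vocab.target_concomitants)]
    conc = conc.merge(index_date.rename("index_date"), on="participant_id")
    on_index = conc[conc["date"] == conc["index_date"]]
    exposed = {
        (str(r.participant_id), str(r.drug)) for r in on_index.itertuples(index=False)
    }

    rows = []
    for pair_no, p in enumerate(pairs):
        for arm, pid in (("case", p.case_id), ("control", p.control_id)):
            ind = {drug: int((pid, drug) in exposed) for drug in vocab.target_concomitants}
            if arm == "case" and pid in case_marker:
                # same-date coding: the exposure date is the index date, which
                # never exceeds the marker date of an ascertained case
                assert int(index_date[pid]) <= case_marker[pid], (
                    f"case {pid}: exposure date after the marker date"
                )
            rows.append(
                {"pair_id": pair_no, "participant_id": pid, "arm": arm, **ind}
            )
    frame = pd.DataFrame(rows)
    drug_cols = list(vocab.target_concomitants)
    frame["n_exposures"] = frame[drug_cols].sum(axis=1)
    return ExposureMatrix(frame=frame, drugs=tuple(drug_cols))


# ---------------------------------------------------------------------------
# univariate estimators
# ---------------------------------------------------------------------------

def crude_or(
    t: TwoByTwo, drug: str = "", zero_cell: str = "dash"
) -> EffectEstimate:
    """Cross-product odds ratio with a Woolf 95% CI and Wald p-value.

    Any zero cell makes the estimate undefined unless ``zero_cell=
    "haldane"`` adds 0.5 to every cell (Haldane-Anscombe correction).
    """
    if zero_cell not in ("dash", "haldane"):
        raise ValueError(f"unknown zero-cell policy {zero_cell!r}")
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if zero_cell == "dash":
            return EffectEstimate(drug, None, None, None, None, "crude", t.a, t.c)
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = np.log(a * d / (b * c))
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p = 2 * stats.norm.sf(abs(z))
    return EffectEstimate(
        drug,
        float(np.exp(log_or)),
        float(np.exp(log_or - Z95 * se)),
        float(np.exp(log_or + Z95 * se)),
        float(p),
        "crude",
        t.a,
        t.c,
    )


def discordant_pair_or(
    exposures: ExposureMatrix, drug: str
) -> EffectEstimate:
    """Matched-pair odds ratio ``n10/n01`` with exact McNemar p-value.

    ``n10`` counts pairs with the case exposed and control unexposed,
    ``n01`` the reverse. The p-value is the doubled exact binomial tail at
    ``p = 1/2`` over the discordant pairs, capped at 1. Zero discordant
    pairs, or a zero on either side, yield an undefined OR (and, for the
    one-sided-zero situation, a defined p but no CI).
    """
    diff = exposures.pair_differences([drug])[:, 0]
    n10 = int((diff > 0).sum())
    n01 = int((diff < 0).sum())
    t = exposures.two_by_two(drug)
    n = n10 + n01
    if n == 0:
        logger.info("discordant_pair_or(%s): no discordant pairs; estimate undefined", drug)
        return EffectEstimate(drug, None, None, None, None, "discordant_pair", t.a, t.c)
    p = min(1.0, 2.0 * float(stats.binom.cdf(min(n10, n01), n, 0.5)))
    if n10 == 0 or n01 == 0:
        return EffectEstimate(drug, None, None, None, float(p), "discordant_pair", t.a, t.c)
    log_or = np.log(n10 / n01)
    se = np.sqrt(1 / n10 + 1 / n01)
    return EffectEstimate(
        drug,
        float(np.exp(log_or)),
        float(np.exp(log_or - Z95 * se)),
        float(np.exp(log_or + Z95 * se)),
        float(p),
        "discordant_pair",
        t.a,
        t.c,
    )


def univariate_table(
    exposures: ExposureMatrix,
    estimator: str = "crude",
    zero_cell: str = "dash",
) -> list[EffectEstimate]:
    """Per-drug univariate estimates in vocabulary (reporting) order."""
    out = []
    for drug in exposures.drugs:
        if estimator == "crude":
            out.append(crude_or(exposures.two_by_two(drug), drug, zero_cell=zero_cell))
        elif estimator == "discordant":
            out.append(discordant_pair_or(exposures, drug))
        else:
            raise ValueError(f"unknown univariate estimator {estimator!r}")
    return out


# ---------------------------------------------------------------------------
# conditional logistic regression (1:1 matched pairs)
# ---------------------------------------------------------------------------

@dataclass
class ConditionalLogitResult:
    drugs: tuple[str, ...]
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_pairs: int
    n_iterations: int

    def wald_p(self) -> np.ndarray:
        se = np.sqrt(np.diag(self.cov))
        z = self.beta / se
        return 2 * stats.norm.sf(np.abs(z))

    def estimates(self, exposures: ExposureMatrix | None = None) -> list[EffectEstimate]:
        se = np.sqrt(np.diag(self.cov))
        p = self.wald_p()
        out = []
        for k, drug in enumerate(self.drugs):
            n_ec = n_eo = 0
            if exposures is not None:
                t = exposures.two_by_two(drug)
                n_ec, n_eo = t.a, t.c
            out.append(
                EffectEstimate(
                    drug,
                    float(np.exp(self.beta[k])),
                    float(np.exp(self.beta[k] - Z95 * se[k])),
                    float(np.exp(self.beta[k] + Z95 * se[k])),
                    float(p[k]),
                    "conditional_multivariable",
                    n_ec,
                    n_eo,
                )
            )
        return out


def _collinear_columns(D: np.ndarray, drugs: Sequence[str]) -> list[str]:
    """Columns of D linearly dependent on earlier ones (QR diagonal test)."""
    k = D.shape[1]
    if k == 0:
        return []
    if D.shape[0] < k:
        return list(drugs[D.shape[0] :])
    r = np.linalg.qr(D, mode="r")
    diag = np.abs(np.diag(r))
    scale = max(float(diag.max()), 1.0)
    return [drugs[j] for j in range(k) if diag[j] < 1e-8 * scale]


def _conditional_loglik(beta: np.ndarray, D: np.ndarray) -> float:
    eta = D @ beta
    return float(-np.logaddexp(0.0, -eta).sum())


def conditional_logit_fit(
    exposures: ExposureMatrix, drugs: Sequence[str] | None = None
) -> ConditionalLogitResult:
    """Maximise the 1:1 matched-pair conditional likelihood by Newton-Raphson.

    Works on the pair-difference representation: with ``d_j`` the
    case-minus-control exposure difference of pair ``j``, the conditional
    log-likelihood is ``sum_j -log(1 + exp(-beta . d_j))``. Convergence is
    max |gradient| < 1e-8 within 200 iterations; the covariance is the
    inverse observed information at the maximum.

    Raises
    ------
    UnidentifiedEffectError
        If an included drug has zero discordance (coefficient drops out of
        the likelihood) or monotone discordance (the MLE diverges); the
        error names the drug(s). Unconverged estimates are never returned.
    """
    drugs = tuple(drugs if drugs is not None else exposures.drugs)
    D = exposures.pair_differences(drugs)
    n_pairs = D.shape[0]

    concordant = [drug for k, drug in enumerate(drugs) if not np.any(D[:, k])]
    if concordant:
        raise UnidentifiedEffectError(
            "no discordant pairs for: " + ", ".join(concordant), tuple(concordant)
        )
    monotone = [
        drug
        for k, drug in enumerate(drugs)
        if D[:, k].min() >= 0 or D[:, k].max() <= 0
    ]
    if monotone:
        raise UnidentifiedEffectError(
            "monotone discordance (infinite MLE) for: " + ", ".join(monotone),
            tuple(monotone),
        )
    dependent = _collinear_columns(D, drugs)
    if dependent:
        raise UnidentifiedEffectError(
            "collinear exposure-difference columns for: " + ", ".join(dependent),
            tuple(dependent),
        )

    beta = np.zeros(len(drugs))
    for it in range(1, NEWTON_MAX_ITER + 1):
        eta = D @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        grad = D.T @ (1.0 - p)
        if float(np.max(np.abs(grad))) < NEWTON_TOL:
            break
        w = p * (1.0 - p)
        H = (D * w[:, None]).T @ D  # observed information
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            # the information degenerates as quasi-separated coefficients
            # drift; attribute to the runaway coefficients
            runaway = tuple(
                drugs[k] for k in np.flatnonzero(np.abs(beta) > 5.0)
            ) or (drugs[int(np.argmax(np.abs(beta)))],)
            raise UnidentifiedEffectError(
                "singular information matrix (quasi-separation) for: "
                + ", ".join(runaway),
                runaway,
            ) from exc
        # dampen overly long steps for stability far from the optimum
        norm = float(np.max(np.abs(step)))
        if norm > 5.0:
            step *= 5.0 / norm
        beta = beta + step
        if float(np.max(np.abs(beta))) > 30:
            # attribute the divergence to the runaway coefficients
            runaway = tuple(
                drugs[k] for k in np.flatnonzero(np.abs(beta) > 15.0)
            ) or (drugs[int(np.argmax(np.abs(beta)))],)
            raise UnidentifiedEffectError(
                "conditional likelihood diverged (quasi-separation) for: "
                + ", ".join(runaway),
                runaway,
            )
    else:
        raise UnidentifiedEffectError(
            f"Newton-Raphson failed to converge in {NEWTON_MAX_ITER} iterations"
        )

    eta = D @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    H = (D * w[:, None]).T @ D
    cov = np.linalg.inv(H)
    return ConditionalLogitResult(
        drugs=drugs,
        beta=beta,
        cov=cov,
        loglik=_conditional_loglik(beta, D),
        n_pairs=n_pairs,
        n_iterations=it,
    )


def backward_select(
    exposures: ExposureMatrix,
    alpha: float = 0.05,
    drugs: Sequence[str] | None = None,
) -> list[EffectEstimate]:
    """Backward elimination on the multivariable conditional-logistic model.

    Drugs that cannot enter the model (zero or monotone discordance) are
    pre-dropped and logged. The full model is then refitted after removing,
    one at a time, the single drug with the largest Wald p-value above
    ``alpha``, until every remaining drug has p <= alpha. Returns the final
    model's estimates sorted by descending odds ratio; empty if everything
    is eliminated.
    """
    candidates = list(drugs if drugs is not None else exposures.drugs)
    D = exposures.pair_differences(candidates)
    keep = []
    for k, drug in enumerate(candidates):
        col = D[:, k]
        if not np.any(col) or col.min() >= 0 or col.max() <= 0:
            logger.info("backward_select: pre-dropping %s (insufficient discordance)", drug)
        else:
            keep.append(drug)
    current = keep
    fit = None
    while current:
        try:
            fit = conditional_logit_fit(exposures, current)
        except UnidentifiedEffectError as exc:
            # joint quasi-separation the single-column pre-checks cannot see:
            # drop the drugs the solver attributes the divergence to
            if not exc.drugs:
                raise
            logger.info("backward_select: dropping %s (%s)", ", ".join(exc.drugs), exc)
            current = [d for d in current if d not in exc.drugs]
            fit = None
            continue
        p = fit.wald_p()
        worst = int(np.argmax(p))
        if p[worst] <= alpha:
            break
        logger.info(
            "backward_select: removing %s (p = %.3f)", current[worst], p[worst]
        )
        current = current[:worst] + current[worst + 1 :]
        fit = None
    if not current:
        logger.warning("backward_select: all drugs eliminated at alpha = %s", alpha)
        return []
    est = fit.estimates(exposures)
    return sorted(est, key=lambda e: -e.or_value)


# ---------------------------------------------------------------------------
# concomitant-count contrast and subgroups
# ---------------------------------------------------------------------------

def concomitant_count_analysis(
    exposures: ExposureMatrix, zero_cell: str = "dash"
) -> tuple[pd.DataFrame, EffectEstimate]:
    """Distribution of the number of target drugs per participant, by arm,
    plus the crude odds ratio for using >=1 target drug versus none.

    The distribution table has one row per observed count with per-arm
    counts and percentages (each arm's percentages sum to 100).
    """
    f = exposures.frame
    dist = (
        f.groupby(["n_exposures", "arm"]).size().unstack("arm", fill_value=0)
        .reindex(columns=["case", "control"], fill_value=0)
        .rename(columns={"case": "n_cases", "control": "n_controls"})
        .reset_index()
        .rename(columns={"n_exposures": "n_concomitants"})
    )
    for arm in ("cases", "controls"):
        total = dist[f"n_{arm}"].sum()
        dist[f"pct_{arm}"] = 100.0 * dist[f"n_{arm}"] / total if total else 0.0

    case_arm = f[f["arm"] == "case"]
    ctrl_arm = f[f["arm"] == "control"]
    a = int((case_arm["n_exposures"] >= 1).sum())
    b = int((case_arm["n_exposures"] == 0).sum())
    c = int((ctrl_arm["n_exposures"] >= 1).sum())
    d = int((ctrl_arm["n_exposures"] == 0).sum())
    est = crude_or(TwoByTwo(a, b, c, d), drug=">=1 concomitant vs 0", zero_cell=zero_cell)
    return dist, est


def age_band(age: float) -> str:
    """Study age bands: <18, 18-64, >=65 (a 17.9-year-old is ``<18``)."""
    if age < 18:
        return AGE_BANDS[0]
    if age < 65:
        return AGE_BANDS[1]
    return AGE_BANDS[2]


@dataclass
class SubgroupResult:
    subgroup: str
    n_pairs: int
    status: str  # "ok" | "insufficient_data"
    univariate: list[EffectEstimate]
    multivariable: list[EffectEstimate]


def subgroup_analysis(
    exposures: ExposureMatrix,
    profiles,
    grouping: str,
    alpha: float = 0.05,
    min_discordant_pairs: int = 10,
    zero_cell: str = "dash",
) -> dict[str, SubgroupResult]:
    """Stratified re-estimation by the case's age band or gender.

    Pairs are assigned to the stratum of their *case* member (matching makes
    pairs near-homogeneous in these covariates). Each stratum is re-analysed
    with the same univariate and backward-selected multivariable machinery;
    strata with fewer than ``min_discordant_pairs`` pairs discordant on any
    drug report ``insufficient_data`` instead of estimates.
    """
    if grouping not in ("age_band", "gender"):
        raise ValueError(f"unknown grouping {grouping!r}")
    prof = profiles_frame(profiles).set_index("participant_id")
    f = exposures.frame
    case_rows = f[f["arm"] == "case"]

    def group_of(pid: str) -> str:
        if grouping == "gender":
            return str(prof.loc[pid, "gender"])
        return age_band(float(prof.loc[pid, "age"]))

    pair_group = {
        int(r.pair_id): group_of(str(r.participant_id))
        for r in case_rows.itertuples(index=False)
    }
    levels = AGE_BANDS if grouping == "age_band" else ("male", "female")

    out: dict[str, SubgroupResult] = {}
    for level in levels:
        pair_ids = [pid for pid, g in pair_group.items() if g == level]
        if not pair_ids:
            out[level] = SubgroupResult(level, 0, "insufficient_data", [], [])
            continue
        sub_frame = f[f["pair_id"].isin(pair_ids)].copy()
        sub = ExposureMatrix(frame=sub_frame, drugs=exposures.drugs)
        D = sub.pair_differences()
        n_disc = int((np.abs(D).sum(axis=1) > 0).sum())
        if n_disc < min_discordant_pairs:
            out[level] = SubgroupResult(level, len(pair_ids), "insufficient_data", [], [])
            continue
        uni = univariate_table(sub, estimator="crude", zero_cell=zero_cell)
        multi = backward_select(sub, alpha=alpha)
        out[level] = SubgroupResult(level, len(pair_ids), "ok", uni, multi)
    return out
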