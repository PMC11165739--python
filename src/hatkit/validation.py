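"""Predictive-capacity validation of the health score.

AUC (with DeLong 95% CI) from unadjusted logistic regressions for the
binary outcomes; unadjusted Cox regression plus Harrell's C (with a
Noether-type asymptotic CI) for time to death; stratified analyses by
sex and the age-78 boundary; and decile reliability (calibration)
tables.

Tie conventions (documented, used consistently by both the production
path and test oracles): tied scores contribute 1/2 to concordance; pairs
tied on event time are unusable unless exactly one member is an event,
in which case the censored member is known to survive longer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = [
    "ValidationResult",
    "auc_logistic",
    "harrell_c",
    "stratified_validation",
    "reliability_table",
    "results_to_frame",
    "OUTCOMES",
]

OUTCOMES = ("mort_1y", "mort_3y", "mort_5y", "time_to_death", "admit_1y", "admit_3y")
AGE_BOUNDARY = 78.0


@dataclass
class ValidationResult:
    cohort: str
    outcome: str
    metric: str          # "AUC" | "HarrellC"
    estimate: float
    ci_lo: float
    ci_hi: float
    stratum: str = "overall"
    n: int = 0
    n_events: int = 0
    all_admissions: bool = False   # provenance: admissions not distinguishable

    def __post_init__(self):
        if not (self.ci_lo <= self.estimate <= self.ci_hi):
            raise ValueError("CI must bracket the point estimate")


def results_to_frame(results: list[ValidationResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


# ---------------------------------------------------------------------------
# AUC with DeLong CI
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sx = x[order]
    i = 0
    while i < len(x):
        j = i
        while j < len(x) and sx[j] == sx[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
    return ranks


def delong_auc(score: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance (structural components)."""
    score = np.asarray(score, dtype=float)
    y = np.asarray(y).astype(int)
    pos = score[y == 1]
    neg = score[y == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both outcome classes required for AUC")
    all_ranks = _midranks(np.concatenate([pos, neg]))
    pos_ranks = _midranks(pos)
    neg_ranks = _midranks(neg)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    var = s10 / m + s01 / n
    return float(auc), float(var)


def auc_logistic(score: np.ndarray, outcome_flag: np.ndarray, cohort: str = "",
                 outcome: str = "", stratum: str = "overall",
                 all_admissions: bool = False) -> ValidationResult:
    """AUC of an unadjusted logistic regression of the outcome on the score.

    The ROC of the fitted probability equals the ROC of the score with
    the orientation given by the sign of the fitted slope (the fitted
    probability is a strictly monotone transform of the score), so the
    AUC and its DeLong CI are computed on the suitably oriented score.
    Missing scores are dropped with a log entry.
    """
    score = np.asarray(score, dtype=float)
    y = np.asarray(outcome_flag, dtype=float)
    keep = ~np.isnan(score) & ~np.isnan(y)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("auc_logistic: dropped %d records with missing score/outcome", dropped)
    score, y = score[keep], y[keep].astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class outcome")

    import statsmodels.api as sm
    slope = None
    try:
        with np.errstate(all="ignore"):
            fit = sm.GLM(y, sm.add_constant(score), family=sm.families.Binomial()).fit()
        slope = float(fit.params[1])
    except Exception:   # separation etc.
        logger.warning("logistic fit failed (separation?); orienting score by rank association")
    if slope is None:
        slope = float(np.corrcoef(score, y)[0, 1]) if len(score) > 1 else 1.0
    oriented = score if slope >= 0 else -score

    auc, var = delong_auc(oriented, y)
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return ValidationResult(cohort=cohort, outcome=outcome, metric="AUC",
                            estimate=auc,
                            ci_lo=max(0.0, min(auc, auc - half)),
                            ci_hi=min(1.0, max(auc, auc + half)),
                            stratum=stratum, n=int(len(y)), n_events=int(y.sum()),
                            all_admissions=all_admissions)


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def _concordance_counts(risk: np.ndarray, time: np.ndarray, event: np.ndarray,
                        chunk: int = 256) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Concordant-weight and usable-pair totals plus per-subject sums.

    A pair is usable when the shorter time belongs to an event (or times
    are tied with exactly one event).  Concordance weight is 1 if the
    higher risk has the shorter time, 1/2 on risk ties.
    """
    n = len(time)
    conc_i = np.zeros(n)
    pairs_i = np.zeros(n)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        dt = time[sl, None] - time[None, :]           # t_i - t_j
        usable_i = (dt < 0) & (event[sl, None] == 1)  # i earlier, i event
        usable_j = (dt > 0) & (event[None, :] == 1)   # j earlier, j event
        tied_t = (dt == 0) & (event[sl, None] != event[None, :])
        usable = usable_i | usable_j | tied_t
        # self-pairs never count
        idx = np.arange(sl.start, sl.stop)
        usable[np.arange(sl.stop - sl.start), idx] = False

        dr = risk[sl, None] - risk[None, :]
        # earlier subject within the pair
        early_is_i = usable_i | (tied_t & (event[sl, None] == 1))
        conc = np.where(early_is_i, (dr > 0) + 0.5 * (dr == 0),
                        (dr < 0) + 0.5 * (dr == 0))
        conc = np.where(usable, conc, 0.0)
        conc_i[sl] += conc.sum(axis=1)
        pairs_i[sl] += usable.sum(axis=1)
    return conc_i.sum() / 2.0, pairs_i.sum() / 2.0, conc_i, pairs_i


def harrell_c(score: np.ndarray, time: np.ndarray, event_flag: np.ndarray,
              cohort: str = "", outcome: str = "time_to_death",
              stratum: str = "overall") -> ValidationResult:
    """Harrell's C of the score against survival ordering.

    The score is protective (higher = healthier), so concordance is
    computed for risk = -score.  An unadjusted Cox model is fitted
    alongside (mirroring the analysis plan); its coefficient is recorded
    in the log only.  CI from the Noether-type U-statistic variance.
    """
    score = np.asarray(score, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event_flag).astype(int)
    keep = ~np.isnan(score) & ~np.isnan(time)
    score, time, event = score[keep], time[keep], event[keep]
    if (time < 0).any():
        raise ValueError("negative survival times")
    if event.sum() == 0:
        raise ValueError("all observations censored")

    try:
        from lifelines import CoxPHFitter
        df = pd.DataFrame({"t": time, "e": event, "score": score})
        cph = CoxPHFitter()
        cph.fit(df, duration_col="t", event_col="e")
        logger.info("cox coefficient for score: %.4f", cph.params_["score"])
    except Exception:
        logger.warning("Cox fit failed; concordance reported without it")

    risk = -score
    conc, pairs, conc_i, pairs_i = _concordance_counts(risk, time, event)
    if pairs == 0:
        raise ValueError("no usable pairs")
    c = conc / pairs
    # delta-method variance of the ratio of U-statistics via per-subject
    # influence sums: var(C) ~ sum_i (c_i - C m_i)^2 / pairs^2
    n = len(time)
    resid = conc_i - c * pairs_i
    var = float((resid ** 2).sum()) / (pairs ** 2) if n > 1 else 0.0
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return ValidationResult(cohort=cohort, outcome=outcome, metric="HarrellC",
                            estimate=float(c),
                            ci_lo=max(0.0, min(c, c - half)),
                            ci_hi=min(1.0, max(c, c + half)),
                            stratum=stratum, n=int(n), n_events=int(event.sum()))


# ---------------------------------------------------------------------------
# stratified runs and reliability
# ---------------------------------------------------------------------------

def _binary_outcome(table: pd.DataFrame, outcome: str) -> np.ndarray:
    if outcome.startswith("mort_"):
        years = float(outcome.split("_")[1].rstrip("y"))
        return ((table["death_event"] == 1) & (table["death_time"] <= years)).to_numpy(dtype=int)
    return table[outcome].to_numpy(dtype=float)


def stratified_validation(table: pd.DataFrame, scores: np.ndarray,
                          outcomes: tuple[str, ...] = OUTCOMES,
                          cohort: str = "") -> list[ValidationResult]:
    """Overall plus four strata (sex, age-78 split) for every outcome.

    Degenerate strata (single outcome class, no events) are skipped with
    a log entry, mirroring the printed-table layout.
    """
    scores = np.asarray(scores, dtype=float)
    all_adm = False
    if "admissions_unplanned" in table.columns:
        all_adm = bool((table["admissions_unplanned"] == 0).any())
    strata = {
        "overall": np.ones(len(table), dtype=bool),
        "male": (table["sex"] == "male").to_numpy(),
        "female": (table["sex"] == "female").to_numpy(),
        "age<78": (table["age"] < AGE_BOUNDARY).to_numpy(),
        "age>=78": (table["age"] >= AGE_BOUNDARY).to_numpy(),
    }
    results = []
    for outcome in outcomes:
        for name, mask in strata.items():
            if mask.sum() < 2:
                logger.info("stratum %s skipped: too few records", name)
                continue
            sub = table[mask]
            s = scores[mask]
            try:
                if outcome == "time_to_death":
                    res = harrell_c(s, sub["death_time"].to_numpy(dtype=float),
                                    sub["death_event"].to_numpy(), cohort=cohort,
                                    outcome=outcome, stratum=name)
                else:
                    y = _binary_outcome(sub, outcome)
                    flag = all_adm and outcome.startswith("admit")
                    res = auc_logistic(s, y, cohort=cohort, outcome=outcome,
                                       stratum=name, all_admissions=flag)
            except ValueError as exc:
                logger.info("stratum %s / outcome %s skipped: %s", name, outcome, exc)
                continue
            results.append(res)
    return results


def reliability_table(predicted_prob: np.ndarray, outcome_flag: np.ndarray,
                      n_bins: int = 10) -> pd.DataFrame:
    """Decile-binned calibration: mean predicted vs observed event rate."""
    p = np.asarray(predicted_prob, dtype=float)
    y = np.asarray(outcome_flag, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities outside [0, 1]")
    edges = np.quantile(p, np.linspace(0, 1, n_bins + 1))
    edges[0] -= 1e-12
    edges[-1] += 1e-12
    edges = np.unique(edges)
    bins = np.digitize(p, edges[1:-1])
    rows = []
    for b in range(len(edges) - 1):
        sel = bins == b
        if not sel.any():
            continue
        rows.append({"bin": b, "n": int(sel.sum()),
                     "mean_predicted": float(p[sel].mean()),
                     "observed_rate": float(y[sel].mean())})
    return pd.DataFrame(rows)


def predicted_mortality_prob(scores: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Fitted probabilities from the unadjusted logistic model (for reliability plots)."""
    import statsmodels.api as sm
    X = sm.add_constant(np.asarray(scores, dtype=float))
    fit = sm.GLM(np.asarray(y, dtype=float), X, family=sm.families.Binomial()).fit()
    return expit(X @ fit.params)
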