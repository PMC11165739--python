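import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hatkit.validation import (
    auc_logistic,
    delong_auc,
    harrell_c,
    predicted_mortality_prob,
    reliability_table,
    results_to_frame,
    stratified_validation,
)


# ---------------------------------------------------------------------------
# oracles (independent O(n^2) implementations)
# ---------------------------------------------------------------------------

def auc_pairwise_oracle(score, y):
    """Exhaustive case-control pair count; ties count 1/2."""
    cases = score[y == 1]
    controls = score[y == 0]
    total = 0.0
    for s in cases:
        for c in controls:
            total += 1.0 if s > c else (0.5 if s == c else 0.0)
    return total / (len(cases) * len(controls))


def harrell_oracle(risk, time, event):
    """Exhaustive usable-pair concordance with the documented tie rules."""
    n = len(time)
    conc = pairs = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = time[i], time[j]
            ei, ej = event[i], event[j]
            if ti == tj:
                if ei == ej:
                    continue
                early = i if ei == 1 else j
            elif ti < tj:
                if ei != 1:
                    continue
                early = i
            else:
                if ej != 1:
                    continue
                early = j
            late = j if early == i else i
            pairs += 1
            if risk[early] > risk[late]:
                conc += 1.0
            elif risk[early] == risk[late]:
                conc += 0.5
    return conc / pairs


def test_auc_matches_pairwise_oracle():
    rng = np.random.default_rng(0)
    score = np.round(rng.normal(0, 1, 200), 1)  # rounding forces ties
    y = (rng.random(200) < 1 / (1 + np.exp(-score))).astype(int)
    res = auc_logistic(score, y)
    assert res.estimate == pytest.approx(auc_pairwise_oracle(score, y), abs=1e-12)


def test_auc_perfect_separation():
    score = np.concatenate([np.zeros(50), np.ones(50)])
    y = score.astype(int)
    res = auc_logistic(score, y)
    assert res.estimate == 1.0


def test_auc_protective_score_oriented_by_logistic_slope():
    rng = np.random.default_rng(1)
    health = rng.normal(0, 1, 500)
    y = (rng.random(500) < 1 / (1 + np.exp(health))).astype(int)  # high health -> few events
    res = auc_logistic(health, y)
    assert res.estimate > 0.5
    assert res.estimate == pytest.approx(auc_pairwise_oracle(-health, y), abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(seed=st.integers(0, 10_000), scale=st.floats(0.1, 5), shift=st.floats(-3, 3))
def test_auc_invariant_to_monotone_transform(seed, scale, shift):
    rng = np.random.default_rng(seed)
    score = rng.normal(0, 1, 80)
    y = np.zeros(80, dtype=int)
    y[rng.choice(80, 20, replace=False)] = 1
    a1, _ = delong_auc(score, y)
    a2, _ = delong_auc(np.exp(scale * score + shift), y)
    assert a1 == pytest.approx(a2, abs=1e-12)


def test_delong_ci_contains_estimate():
    rng = np.random.default_rng(2)
    score = rng.normal(0, 1, 300)
    y = (rng.random(300) < 1 / (1 + np.exp(-score))).astype(int)
    res = auc_logistic(score, y)
    assert res.ci_lo <= res.estimate <= res.ci_hi
    assert res.ci_hi - res.ci_lo < 0.3


def test_auc_single_class_rejected():
    with pytest.raises(ValueError, match="single-class"):
        auc_logistic(np.arange(10.0), np.zeros(10))


def test_missing_scores_dropped():
    score = np.array([np.nan, 1.0, 2.0, 3.0, 0.0, 4.0])
    y = np.array([1, 0, 1, 1, 0, 1])
    res = auc_logistic(score, y)
    assert res.n == 5


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def test_harrell_matches_bruteforce_oracle():
    rng = np.random.default_rng(3)
    n = 300
    score = np.round(rng.normal(0, 1, n), 1)
    time = np.round(rng.exponential(5, n), 1)       # rounded -> tied times
    event = (rng.random(n) > 0.3).astype(int)        # ~30% censoring
    res = harrell_c(score, time, event)
    expected = harrell_oracle(-score, time, event)
    assert res.estimate == pytest.approx(expected, abs=1e-12)


def test_harrell_perfect_antirank_no_censoring():
    time = np.arange(1.0, 51.0)
    score = time.copy()          # healthiest live longest
    event = np.ones(50, dtype=int)
    res = harrell_c(score, time, event)
    assert res.estimate == 1.0


def test_harrell_null_score():
    rng = np.random.default_rng(4)
    n = 2000
    res = harrell_c(rng.normal(0, 1, n), rng.exponential(5, n),
                    np.ones(n, dtype=int))
    assert res.estimate == pytest.approx(0.5, abs=0.03)


def test_harrell_all_censored_rejected():
    with pytest.raises(ValueError, match="censored"):
        harrell_c(np.arange(5.0), np.arange(1.0, 6.0), np.zeros(5))


def test_harrell_invariant_to_monotone_transform():
    rng = np.random.default_rng(5)
    n = 150
    score = rng.normal(0, 1, n)
    time = rng.exponential(5, n)
    event = (rng.random(n) > 0.4).astype(int)
    c1 = harrell_c(score, time, event).estimate
    c2 = harrell_c(3.0 * score + 7.0, time, event).estimate
    assert c1 == pytest.approx(c2, abs=1e-12)


def test_harrell_equals_auc_in_uncensored_binary_limit():
    # all events, two distinct death times -> usable pairs are exactly the
    # early-vs-late pairs, i.e. a Mann-Whitney comparison
    rng = np.random.default_rng(6)
    n = 120
    score = rng.normal(0, 1, n)
    early = rng.random(n) < 1 / (1 + np.exp(score))
    time = np.where(early, 1.0, 2.0)
    event = np.ones(n, dtype=int)
    c = harrell_c(score, time, event).estimate
    auc, _ = delong_auc(-score, early.astype(int))
    assert c == pytest.approx(auc, abs=1e-12)


# ---------------------------------------------------------------------------
# stratified runs
# ---------------------------------------------------------------------------

def _scored_table(n=600, seed=7):
    rng = np.random.default_rng(seed)
    health = rng.normal(0, 1, n)
    age = rng.uniform(62, 95, n)
    t = pd.DataFrame({
        "age": age,
        "sex": rng.choice(["female", "male"], n),
        "death_time": np.minimum(rng.exponential(8, n) * np.exp(0.3 * health), 16),
        "admit_1y": (rng.random(n) < 0.2).astype(int),
    })
    t["death_event"] = (t["death_time"] < 16).astype(int)
    t["admit_3y"] = np.maximum(t["admit_1y"], (rng.random(n) < 0.2).astype(int))
    return t, health


def test_stratified_age_partition():
    t, score = _scored_table()
    results = stratified_validation(t, score, outcomes=("mort_5y",))
    by = {r.stratum: r for r in results}
    assert by["age<78"].n + by["age>=78"].n == by["overall"].n


def test_stratified_degenerate_stratum_skipped():
    t, score = _scored_table()
    t.loc[t["sex"] == "male", "admit_1y"] = 0   # males: single class
    results = stratified_validation(t, score, outcomes=("admit_1y",))
    strata = {r.stratum for r in results}
    assert "male" not in strata
    assert "overall" in strata


def test_stratified_weaker_association_in_young():
    rng = np.random.default_rng(8)
    n = 6000
    age = rng.uniform(60, 96, n)
    health = rng.normal(0, 1, n)
    old = age >= 78
    logit = -2.5 + np.where(old, -1.2 * health, -0.1 * health)
    t = pd.DataFrame({"age": age, "sex": "female",
                      "death_time": 16.0, "death_event": 0,
                      "admit_1y": (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(int)})
    t["admit_3y"] = t["admit_1y"]
    res = {r.stratum: r.estimate
           for r in stratified_validation(t, health, outcomes=("admit_1y",))}
    assert res["age<78"] < res["overall"] < res["age>=78"]


def test_results_frame_tidy():
    t, score = _scored_table()
    df = results_to_frame(stratified_validation(t, score))
    assert {"cohort", "outcome", "metric", "estimate", "ci_lo", "ci_hi",
            "stratum", "n", "n_events"} <= set(df.columns)


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def test_reliability_self_consistent_simulation():
    rng = np.random.default_rng(9)
    p = rng.uniform(0.01, 0.6, 20000)
    y = (rng.random(20000) < p).astype(int)
    table = reliability_table(p, y)
    for _, row in table.iterrows():
        se = np.sqrt(row["mean_predicted"] * (1 - row["mean_predicted"]) / row["n"])
        assert abs(row["observed_rate"] - row["mean_predicted"]) < 4 * se + 0.01


def test_reliability_bins_partition():
    rng = np.random.default_rng(10)
    p = rng.random(500)
    y = (rng.random(500) < p).astype(int)
    table = reliability_table(p, y)
    assert table["n"].sum() == 500


def test_reliability_constant_predictions():
    p = np.full(200, 0.3)
    y = np.zeros(200)
    y[:60] = 1
    table = reliability_table(p, y)
    assert len(table) == 1
    assert table["observed_rate"].iloc[0] == pytest.approx(0.3)


def test_reliability_rejects_bad_probs():
    with pytest.raises(ValueError):
        reliability_table(np.array([0.5, 1.2]), np.array([0, 1]))


def test_predicted_probabilities_calibrated_in_sample():
    rng = np.random.default_rng(11)
    score = rng.normal(0, 1, 3000)
    y = (rng.random(3000) < 1 / (1 + np.exp(-score + 1))).astype(int)
    p = predicted_mortality_prob(score, y)
    assert p.mean() == pytest.approx(y.mean(), abs=1e-6)  # logistic MLE property
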