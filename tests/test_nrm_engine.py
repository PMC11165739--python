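import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hatkit.nrm_engine import (
    CurveTable,
    IndicatorCutoffs,
    NRMFit,
    NRMItemParams,
    categorize,
    category_prob,
    eap_score,
    fit_nrm,
    tcc,
    tif,
)


def _simulate_nrm(items, n, seed):
    """Data-generating oracle: draw responses from known item parameters."""
    rng = np.random.default_rng(seed)
    theta = rng.normal(0, 1, n)
    resp = np.empty((n, len(items)), dtype=np.int64)
    for j, it in enumerate(items):
        p = category_prob(it, theta)
        cum = p.cumsum(axis=1)
        u = rng.random(n)[:, None]
        resp[:, j] = (u > cum).sum(axis=1)
    return theta, resp


# ---------------------------------------------------------------------------
# categorize
# ---------------------------------------------------------------------------

def _table(**cols):
    base = {"gait_speed": [1.0], "mmse": [28.0], "n_chronic": [2.0],
            "iadl": [0.0], "padl": [0.0]}
    base.update({k: list(np.atleast_1d(v)) for k, v in cols.items()})
    return pd.DataFrame(base)


CUT = IndicatorCutoffs(thresholds={
    "gait_speed": (0.6, 1.0), "mmse": (24, 28), "n_chronic": (2, 5),
    "iadl": (1, 3), "padl": (1,),
})


def test_mmse_30_top_category():
    r = categorize(_table(mmse=30.0), CUT)
    assert r[0, 1] == 2


def test_gait_zero_lowest_category():
    r = categorize(_table(gait_speed=0.0), CUT)
    assert r[0, 0] == 0


def test_boundary_value_goes_up():
    r = categorize(_table(gait_speed=0.6), CUT)
    assert r[0, 0] == 1
    r = categorize(_table(gait_speed=0.5999), CUT)
    assert r[0, 0] == 0


def test_reverse_direction_health_ordering():
    # chronic count: value below first threshold is healthiest (top code)
    assert categorize(_table(n_chronic=0.0), CUT)[0, 2] == 2
    assert categorize(_table(n_chronic=10.0), CUT)[0, 2] == 0
    assert categorize(_table(padl=6.0), CUT)[0, 4] == 0


def test_missing_value_rejected():
    with pytest.raises(ValueError, match="missing"):
        categorize(_table(mmse=np.nan), CUT)


def test_cutoffs_must_increase():
    with pytest.raises(ValueError, match="increasing"):
        IndicatorCutoffs(thresholds={"gait_speed": (1.0, 0.5)})


# ---------------------------------------------------------------------------
# category_prob
# ---------------------------------------------------------------------------

def test_zero_params_uniform():
    it = NRMItemParams(np.zeros(4), np.zeros(4))
    p = category_prob(it, 1.7)
    np.testing.assert_allclose(p, 0.25)


@settings(max_examples=50, deadline=None)
@given(theta=st.floats(-50, 50),
       a=st.lists(st.floats(-5, 5), min_size=2, max_size=5),
       c=st.lists(st.floats(-5, 5), min_size=2, max_size=5))
def test_probabilities_sum_to_one(theta, a, c):
    k = min(len(a), len(c))
    it = NRMItemParams(np.array(a[:k]), np.array(c[:k]))
    p = category_prob(it, theta)
    assert np.isfinite(p).all()
    assert p.sum() == pytest.approx(1.0, abs=1e-12)


def test_extreme_theta_concentrates_on_max_slope():
    it = NRMItemParams(np.array([-1.0, 0.2, 0.8]), np.array([0.0, 0.0, 0.0]))
    p = category_prob(it, 700.0)
    assert np.isfinite(p).all()
    assert p[2] == pytest.approx(1.0)
    p = category_prob(it, -700.0)
    assert p[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# fit_nrm
# ---------------------------------------------------------------------------

def _twopl_items(slopes, diffs):
    # 2PL as an NRm: a-vector (0, slope), c-vector (0, -slope*difficulty)
    return [NRMItemParams(np.array([0.0, a]) - a / 2,
                          np.array([0.0, -a * b]) + a * b / 2)
            for a, b in zip(slopes, diffs)]


def test_2pl_slope_recovery():
    slopes = [1.5, 1.0, 2.0, 0.8, 1.2]
    diffs = [0.0, -0.5, 0.5, 0.2, -0.3]
    _, resp = _simulate_nrm(_twopl_items(slopes, diffs), n=5000, seed=3)
    fit = fit_nrm(resp)
    for j, true_a in enumerate(slopes):
        est = fit.items[j].a[1] - fit.items[j].a[0]
        assert est == pytest.approx(true_a, abs=0.25)


def test_em_loglik_monotone():
    items = _twopl_items([1.2, 0.9, 1.6], [0.0, 0.4, -0.4])
    _, resp = _simulate_nrm(items, n=1000, seed=5)
    fit = fit_nrm(resp)
    assert fit.converged
    assert (np.diff(fit.trace) >= -1e-7).all()


def test_sum_to_zero_identification():
    items = _twopl_items([1.2, 0.9], [0.0, 0.4])
    _, resp = _simulate_nrm(items, n=800, seed=6)
    fit = fit_nrm(resp)
    for it in fit.items:
        assert abs(it.a.sum()) < 1e-8
        assert abs(it.c.sum()) < 1e-8


def test_quadrature_weights_sum_to_one():
    items = _twopl_items([1.0], [0.0])
    _, resp = _simulate_nrm(items, n=200, seed=7)
    fit = fit_nrm(resp)
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)


def test_constant_item_collapsed_leaves_others_unchanged():
    items = _twopl_items([1.3, 0.9], [0.1, -0.2])
    _, resp = _simulate_nrm(items, n=1200, seed=8)
    const = np.full((1200, 1), 2, dtype=np.int64)
    with pytest.warns(UserWarning, match="constant"):
        fit3 = fit_nrm(np.hstack([resp, const]))
    fit2 = fit_nrm(resp)
    for j in range(2):
        np.testing.assert_allclose(fit3.items[j].a, fit2.items[j].a, atol=1e-6)
    assert fit3.items[2].n_categories == 1


def test_empty_middle_category_collapsed():
    items = _twopl_items([1.3], [0.0])
    _, resp = _simulate_nrm(items, n=500, seed=9)
    resp3 = resp.copy()
    resp3[resp3 == 1] = 2  # categories {0, 2}: code 1 empty
    with pytest.warns(UserWarning, match="collapsing"):
        fit = fit_nrm(resp3)
    assert fit.items[0].n_categories == 2
    assert fit.category_maps[0] == {0: 0, 2: 1}


def test_too_few_respondents_warns():
    items = _twopl_items([1.0], [0.0])
    _, resp = _simulate_nrm(items, n=30, seed=10)
    with pytest.warns(UserWarning, match="respondents"):
        fit_nrm(resp, max_iter=20)


def test_fit_json_round_trip(tmp_path):
    items = _twopl_items([1.2, 0.8], [0.0, 0.3])
    _, resp = _simulate_nrm(items, n=400, seed=11)
    fit = fit_nrm(resp)
    p = tmp_path / "fit.json"
    fit.to_json(p)
    loaded = NRMFit.from_json(p)
    assert loaded.loglik == pytest.approx(fit.loglik)
    e1, _ = eap_score(fit, resp)
    e2, _ = eap_score(loaded, resp)
    np.testing.assert_allclose(e1, e2)


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------

def _toy_fit():
    items = [NRMItemParams(np.array([-1.0, 0.0, 1.0]), np.array([0.3, -0.1, -0.2])),
             NRMItemParams(np.array([-0.7, 0.7]), np.array([0.2, -0.2]))]
    from hatkit.nrm_engine import _quadrature
    nodes, w = _quadrature(41)
    return NRMFit(items=items, nodes=nodes, weights=w, loglik=0.0, trace=[0.0],
                  converged=True, n_respondents=0, n_patterns=0,
                  category_maps=[{0: 0, 1: 1, 2: 2}, {0: 0, 1: 1}])


def test_zero_slope_item_flat_tcc_zero_tif():
    fit = _toy_fit()
    fit.items[1] = NRMItemParams(np.zeros(2), np.array([0.5, -0.5]))
    grid = np.linspace(-3, 3, 13)
    ct = tcc(fit, grid)
    assert np.ptp(ct.per_item[1]) < 1e-12
    it = tif(fit, grid)
    np.testing.assert_allclose(it.per_item[1], 0.0, atol=1e-14)


def test_tif_nonnegative_and_total_is_sum():
    fit = _toy_fit()
    grid = np.linspace(-4, 4, 33)
    ct = tif(fit, grid)
    assert (ct.per_item >= 0).all()
    np.testing.assert_allclose(ct.total, ct.per_item.sum(axis=0))


def test_tcc_bounded_by_category_range():
    fit = _toy_fit()
    grid = np.linspace(-6, 6, 25)
    ct = tcc(fit, grid)
    assert (ct.per_item[0] >= 0).all() and (ct.per_item[0] <= 2).all()
    assert (ct.per_item[1] >= 0).all() and (ct.per_item[1] <= 1).all()


def test_tif_matches_finite_difference_oracle():
    # oracle: Fisher information = E[(d log P / d theta)^2], numerically
    fit = _toy_fit()
    grid = np.linspace(-2.5, 2.5, 11)
    h = 1e-5
    expected = np.zeros((2, grid.size))
    for j, it in enumerate(fit.items):
        p0 = category_prob(it, grid)
        dlogp = (np.log(category_prob(it, grid + h)) -
                 np.log(category_prob(it, grid - h))) / (2 * h)
        expected[j] = (p0 * dlogp ** 2).sum(axis=1)
    got = tif(fit, grid)
    np.testing.assert_allclose(got.per_item, expected, atol=1e-6)


def test_curvetable_frame_export(tmp_path):
    fit = _toy_fit()
    ct = tif(fit, np.linspace(-2, 2, 5))
    df = ct.to_frame()
    assert list(df.columns) == ["theta", "total", "item_0", "item_1"] or \
        set(df.columns) == {"theta", "total"} | {it.name for it in fit.items}
    ct.to_csv(tmp_path / "tif.csv")
    assert (tmp_path / "tif.csv").exists()


# ---------------------------------------------------------------------------
# EAP
# ---------------------------------------------------------------------------

def test_uninformative_items_give_prior_mean():
    fit = _toy_fit()
    fit.items = [NRMItemParams(np.zeros(3), np.zeros(3)),
                 NRMItemParams(np.zeros(2), np.zeros(2))]
    resp = np.array([[0, 0], [2, 1], [1, 0]])
    eap, sd = eap_score(fit, resp)
    np.testing.assert_allclose(eap, 0.0, atol=1e-10)
    np.testing.assert_allclose(sd, 1.0, atol=1e-3)


def test_eap_monotone_in_ordered_item():
    fit = _toy_fit()
    resp = np.array([[0, 0], [1, 0], [2, 0]])
    eap, _ = eap_score(fit, resp)
    assert eap[0] < eap[1] < eap[2]


def test_eap_matches_dense_grid_oracle():
    fit = _toy_fit()
    resp = np.array([[0, 0], [1, 1], [2, 1], [0, 1]])
    eap, sd = eap_score(fit, resp)
    grid = np.linspace(-9, 9, 20001)
    prior = np.exp(-grid ** 2 / 2)
    for i, row in enumerate(resp):
        like = prior.copy()
        for j, it in enumerate(fit.items):
            like *= category_prob(it, grid)[:, row[j]]
        mean = (grid * like).sum() / like.sum()
        var = ((grid - mean) ** 2 * like).sum() / like.sum()
        assert eap[i] == pytest.approx(mean, abs=1e-4)
        assert sd[i] == pytest.approx(np.sqrt(var), abs=1e-4)


def test_unseen_category_code_rejected():
    items = _twopl_items([1.0], [0.0])
    _, resp = _simulate_nrm(items, n=300, seed=12)
    fit = fit_nrm(resp)
    with pytest.raises(ValueError, match="unseen"):
        eap_score(fit, np.array([[7]]))
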