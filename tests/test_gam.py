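"""Trend-model tests: basis, penalty, design, PIRLS, smoothing, prediction."""

import dataclasses
import math
import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import careband as cb
from careband.gam import (
    CyclicBasisSpec,
    FitError,
    PenaltySpec,
    PredictionError,
    build_design,
    cyclic_basis,
    cyclic_penalty,
    fit_pirls,
    fit_trend_model,
    select_lambda,
    _penalty_full,
)
from careband.months import trend_index
from careband.synth import Disruption

from helpers import curated_rates


# -- trend index ----------------------------------------------------------

@pytest.mark.parametrize(
    "month,expected",
    [("2020-03", 0.0), ("2019-03", -1.0), ("2022-05", 2 + 2 / 12),
     ("2018-11", -16 / 12), ("2024-03", 4.0)],
)
def test_trend_index_reference_points(month, expected):
    assert trend_index(month) == pytest.approx(expected, abs=1e-12)


def test_trend_index_consecutive_months_differ_by_one_twelfth():
    months = cb.month_range("2018-11", "2024-03")
    t = np.array([trend_index(m) for m in months])
    assert np.allclose(np.diff(t), 1 / 12)
    assert len(np.unique(t)) == len(t)


# -- cyclic basis ---------------------------------------------------------

@given(st.floats(-30, 30, allow_nan=False))
@settings(deadline=None)
def test_partition_of_unity(m):
    b = cyclic_basis(m)
    assert b.shape == (1, 6)
    assert b.sum() == pytest.approx(1.0, abs=1e-10)
    assert (b >= -1e-12).all()


def test_periodicity_across_wrap():
    left = cyclic_basis(12.0 - 1e-9)
    right = cyclic_basis(0.0)
    assert np.allclose(left, right, atol=1e-6)
    # modular reduction of out-of-range inputs
    assert np.allclose(cyclic_basis(25.0), cyclic_basis(1.0))


def _de_boor(x, knots, degree, i):
    """Cox-de Boor recursion, written independently of scipy."""
    if degree == 0:
        return 1.0 if knots[i] <= x < knots[i + 1] else 0.0
    left = 0.0
    if knots[i + degree] != knots[i]:
        left = (x - knots[i]) / (knots[i + degree] - knots[i]) * _de_boor(
            x, knots, degree - 1, i
        )
    right = 0.0
    if knots[i + degree + 1] != knots[i + 1]:
        right = (knots[i + degree + 1] - x) / (
            knots[i + degree + 1] - knots[i + 1]
        ) * _de_boor(x, knots, degree - 1, i + 1)
    return left + right


def test_basis_matches_de_boor_on_unrolled_knots():
    """Folded basis equals de Boor recursion on a 3-period knot vector."""
    spec = CyclicBasisSpec(k=6, degree=3)
    h = spec.period / spec.k
    # unrolled knot vector spanning one period plus degree intervals each side
    knots = h * np.arange(-spec.degree, spec.k + spec.degree + 1)
    grid = np.linspace(0, 12, 241, endpoint=False)
    ours = cyclic_basis(grid, spec)
    n_basis = len(knots) - spec.degree - 1
    raw = np.array(
        [[_de_boor(x, knots, spec.degree, i) for i in range(n_basis)] for x in grid]
    )
    folded = np.zeros_like(ours)
    for j in range(n_basis):
        folded[:, j % spec.k] += raw[:, j]
    assert np.max(np.abs(ours - folded)) < 1e-10


# -- cyclic penalty -------------------------------------------------------

def test_penalty_annihilates_constants_and_is_psd():
    for k, order in [(6, 2), (6, 1), (8, 3)]:
        S = cyclic_penalty(CyclicBasisSpec(k=k, degree=3), PenaltySpec(order=order))
        assert np.allclose(S, S.T)
        assert np.allclose(S @ np.ones(k), 0.0, atol=1e-12)
        assert np.linalg.eigvalsh(S).min() > -1e-12


def test_penalty_first_order_equals_wrapped_difference_sum(rng):
    S = cyclic_penalty(CyclicBasisSpec(k=4, degree=3), PenaltySpec(order=1))
    for _ in range(20):
        c = rng.normal(size=4)
        brute = sum((c[(i + 1) % 4] - c[i]) ** 2 for i in range(4))
        assert c @ S @ c == pytest.approx(brute)


def test_penalty_order_must_be_below_k():
    with pytest.raises(ValueError):
        cyclic_penalty(CyclicBasisSpec(k=4, degree=3), PenaltySpec(order=4))


# -- design ---------------------------------------------------------------

def _toy_rates(months="2018-11", end="2020-02", strata=None):
    idx = cb.month_range(months, end)
    rows = []
    strata = strata or [{}]
    for s in strata:
        for m in idx:
            rows.append({"month": m, "count": 5, "denominator": 1000, **s})
    return pd.DataFrame(rows)


def test_design_column_count_single_stratum():
    k = 6
    X, y, offset, info = build_design(_toy_rates(), CyclicBasisSpec(k=k))
    # intercept + (k-1) constrained seasonal columns + trend
    assert X.shape[1] == 1 + (k - 1) + 1
    assert np.allclose(offset, math.log(1000))


def test_design_column_count_with_interactions():
    strata = [
        {"age_band": a, "sex": s}
        for a in ("18-39", "40-59", "60-79", "80+")
        for s in ("female", "male")
    ]
    k = 6
    X, _, _, info = build_design(
        _toy_rates(strata=strata), CyclicBasisSpec(k=k), stratify=("age_band", "sex")
    )
    # treatment coding: intercept + 3 age + 1 sex dummies, (k-1) seasonal,
    # trend, and 4 trend interactions
    n_dummies = 3 + 1
    assert X.shape[1] == 1 + n_dummies + (k - 1) + 1 + n_dummies
    assert info.columns[0] == "(Intercept)"


def test_design_requires_positive_denominators():
    rates = _toy_rates()
    rates.loc[0, "denominator"] = 0
    with pytest.raises(ValueError):
        build_design(rates)


# -- PIRLS ----------------------------------------------------------------

def test_intercept_only_fit_is_sample_mean():
    X = np.ones((3, 1))
    y = np.array([1.0, 2.0, 3.0])
    fit = fit_pirls(X, y, np.zeros(3))
    assert fit["beta"][0] == pytest.approx(math.log(2.0), abs=1e-10)
    assert fit["converged"]


def test_unpenalized_fit_matches_statsmodels_glm(rng):
    """lambda=0 PIRLS equals an independent Poisson GLM fit to 1e-8."""
    n = 50
    X = np.column_stack(
        [np.ones(n), rng.normal(size=n), rng.uniform(-1, 1, size=n)]
    )
    offset = rng.uniform(0, 1, size=n)
    beta_true = np.array([1.0, 0.3, -0.5])
    y = rng.poisson(np.exp(X @ beta_true + offset)).astype(float)
    fit = fit_pirls(X, y, offset)
    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    assert np.max(np.abs(fit["beta"] - glm.params)) < 1e-8


def test_unpenalized_spline_design_matches_statsmodels(clean_config):
    cfg = dataclasses.replace(clean_config, seasonal_amplitude={"bp": 0.15})
    rates, _, _ = curated_rates(cfg)
    fit_rates = rates[(rates["month"] >= pd.Period("2018-11", "M"))
                      & (rates["month"] <= pd.Period("2020-02", "M"))]
    X, y, offset, info = build_design(fit_rates)
    fit = fit_pirls(X, y, offset)
    glm = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
    assert np.max(np.abs(fit["beta"] - glm.params)) < 1e-8


def test_dispersion_near_one_when_equidispersed(rng):
    n = 400
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    y = rng.poisson(np.exp(X @ np.array([3.0, 0.2]))).astype(float)
    fit = fit_pirls(X, y, np.zeros(n))
    assert 0.9 <= fit["phi"] <= 1.1


def test_offset_contract(rng):
    """Shifting the offset by c moves only the intercept (by -c)."""
    n = 60
    X = np.column_stack([np.ones(n), rng.normal(size=n)])
    offset = np.full(n, 2.0)
    y = rng.poisson(np.exp(1.0 + 0.3 * X[:, 1] + offset)).astype(float)
    f1 = fit_pirls(X, y, offset)
    f2 = fit_pirls(X, y, offset + 0.7)
    assert f2["beta"][0] == pytest.approx(f1["beta"][0] - 0.7, abs=1e-8)
    assert f2["beta"][1] == pytest.approx(f1["beta"][1], abs=1e-8)
    assert np.allclose(f1["mu"], f2["mu"], rtol=1e-8)


def test_all_zero_counts_warns():
    X = np.ones((4, 1))
    with pytest.warns(RuntimeWarning):
        fit_pirls(X, np.zeros(4), np.zeros(4))


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        fit_pirls(np.ones((2, 1)), np.array([-1.0, 1.0]), np.zeros(2))


# -- smoothing selection --------------------------------------------------

def test_single_grid_value_is_returned(clean_config):
    rates, _, _ = curated_rates(clean_config)
    fit_rates = rates[rates["month"] <= pd.Period("2020-02", "M")]
    X, y, offset, info = build_design(fit_rates)
    S = _penalty_full(info, PenaltySpec())
    assert select_lambda(X, y, offset, S, [3.7]) == 3.7
    with pytest.raises(ValueError):
        select_lambda(X, y, offset, S, [])


def test_flat_seasonality_selects_heavy_smoothing(clean_config):
    """With no true seasonal signal GCV favors the smooth end of the grid."""
    cfg = dataclasses.replace(clean_config, n_persons=3000, seed=21)
    rates, _, _ = curated_rates(cfg)
    fit_rates = rates[rates["month"] <= pd.Period("2020-02", "M")]
    X, y, offset, info = build_design(fit_rates)
    S = _penalty_full(info, PenaltySpec())
    grid = [0.01, 0.1, 1.0, 10.0, 100.0]
    lam = select_lambda(X, y, offset, S, grid)
    assert lam in grid[-2:]


def test_gcv_matches_brute_force_recomputation(clean_config):
    rates, _, _ = curated_rates(clean_config)
    fit_rates = rates[rates["month"] <= pd.Period("2020-02", "M")]
    X, y, offset, info = build_design(fit_rates)
    S = _penalty_full(info, PenaltySpec())
    grid = [0.1, 1.0, 10.0]
    gcvs = []
    for lam in grid:
        f = fit_pirls(X, y, offset, S, lam)
        gcvs.append(len(y) * f["pearson"] / (len(y) - f["edf"]) ** 2)
    best = max(
        [lam for lam, g in zip(grid, gcvs) if g == min(gcvs)]
    )
    assert select_lambda(X, y, offset, S, grid) == best


# -- prediction -----------------------------------------------------------

def test_predict_eta_on_training_rows(clean_config):
    rates, _, _ = curated_rates(clean_config)
    model = fit_trend_model(rates, factor="bp")
    fit_rates = rates[rates["month"] <= pd.Period("2020-02", "M")]
    eta, se = model.predict_eta(fit_rates[["month"]])
    X, y, offset, info = build_design(fit_rates)
    assert np.allclose(eta, X @ model.beta)
    assert (se >= 0).all()
    # delta-method brute force via the full covariance
    brute = np.sqrt([x @ model.cov @ x for x in X])
    assert np.allclose(se, brute)


def test_predict_unseen_level_raises(clean_config):
    rates, _, _ = curated_rates(clean_config, stratify=("sex",))
    model = fit_trend_model(rates, factor="bp", stratify=("sex",))
    bad = pd.DataFrame({"month": [pd.Period("2020-06", "M")], "sex": ["other"]})
    with pytest.raises(PredictionError, match="other"):
        model.predict_eta(bad)


def test_model_json_roundtrip(tmp_path, clean_config):
    rates, _, _ = curated_rates(clean_config)
    model = fit_trend_model(rates, factor="bp")
    path = tmp_path / "model.json"
    model.save(path)
    loaded = cb.FittedTrendModel.load(path)
    new = pd.DataFrame({"month": cb.month_range("2020-03", "2021-03")})
    e1, s1 = model.predict_eta(new)
    e2, s2 = loaded.predict_eta(new)
    assert np.allclose(e1, e2) and np.allclose(s1, s2)


def test_seasonal_curve_is_periodic(clean_config):
    """Predicted linear predictor agrees across the December-January wrap."""
    rates, _, _ = curated_rates(clean_config)
    model = fit_trend_model(rates, factor="bp")
    b = cyclic_basis(np.array([0.0, 12.0]), model.info.spec) @ model.info.Z
    assert np.allclose(b[0], b[1])


def test_trend_slope_ci_covers_truth():
    """Nominal 95% Wald CI for the annual slope covers the generative truth.

    60 replicates of a declining-trend scenario; the pass threshold 0.80
    allows binomial noise at this replicate count plus spline-vs-cosine
    misspecification slack.
    """
    from careband.synth import ContaminantProbs, ScenarioConfig

    hits = 0
    reps = 60
    for s in range(reps):
        cfg = ScenarioConfig(
            n_persons=3000,
            baseline_log_rate={"bp": math.log(0.115)},
            seasonal_amplitude={"bp": 0.1},
            annual_trend=-0.02,
            disruption={"bp": Disruption(depth=1.0)},
            contaminants=ContaminantProbs(0.0, 0.0, 0.0, 0.0),
            dup_prob=0.0,
            valueless_prob=0.0,
            seed=9000 + s,
        )
        rates, _, _ = curated_rates(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            model = fit_trend_model(rates, factor="bp")
        i = model.info.columns.index("t")
        half = 1.959963984540054 * math.sqrt(model.cov[i, i])
        if abs(model.beta[i] - (-0.02)) <= half:
            hits += 1
    assert hits / reps >= 0.80
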