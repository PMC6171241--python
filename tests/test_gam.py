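import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosetrait import (
    DoseResponseTable,
    SplineModelSpec,
    build_basis,
    deviance_explained,
    fit_gamma_gam,
    gcv_score,
    load_paper_fixture,
    predict,
)
from dosetrait.gam import _pirls, _Link

DOSES = np.array([0.0, 0.05, 0.1, 0.25, 0.5, 0.75, 1.0])


def _table(doses, y, source="synthetic", kind="biomass"):
    return DoseResponseTable(source, kind,
                             pd.DataFrame({"dose": doses, "response": y}))


# ---------------------------------------------------------------- basis ----

@pytest.mark.parametrize("basis_kind", ["thin_plate", "cubic"])
def test_basis_rank_and_shape(basis_kind):
    spec = SplineModelSpec(basis_kind=basis_kind)
    basis = build_basis(DOSES, spec)
    X = basis.design(DOSES)
    assert X.shape == (7, 5)  # intercept + 4 free smooth functions
    assert np.linalg.matrix_rank(X) == 5


@pytest.mark.parametrize("basis_kind", ["thin_plate", "cubic"])
def test_penalty_null_space_is_exactly_linear(basis_kind):
    basis = build_basis(DOSES, SplineModelSpec(basis_kind=basis_kind))
    S = basis.penalty
    # coefficients representing the straight line 3 - 1.7x cost nothing
    if basis_kind == "thin_plate":
        beta_line = np.zeros(S.shape[0])
        beta_line[:2] = [3.0, -1.7]     # columns are [1, x, wiggly...]
        beta_wiggly = np.ones(S.shape[0])
    else:
        beta_line = 3.0 - 1.7 * basis.knots  # cardinal basis: knot values
        beta_wiggly = np.sin(3 * basis.knots)
    assert beta_line @ S @ beta_line == pytest.approx(0.0, abs=1e-10)
    # any coefficient with wiggle costs something, and S is PSD
    assert beta_wiggly @ S @ beta_wiggly > 0
    eigs = np.linalg.eigvalsh(S)
    assert eigs.min() >= -1e-10
    assert S.shape[0] - np.linalg.matrix_rank(S, tol=1e-10) == 2  # {1, x}


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.1, 10.0), min_size=5, max_size=5, unique=True),
       st.floats(-5, 5), st.floats(-5, 5))
def test_penalty_annihilates_every_line_on_random_grids(doses, a, b):
    doses = np.sort(np.array([0.0] + doses))
    basis = build_basis(doses, SplineModelSpec())
    beta = np.zeros(basis.penalty.shape[0])
    beta[:2] = [a, b]
    assert abs(beta @ basis.penalty @ beta) < 1e-10 * (1 + a * a + b * b)


def test_too_few_distinct_doses_advises_lower_k():
    with pytest.raises(ValueError, match="lower k"):
        build_basis(np.array([0.0, 0.5, 1.0]), SplineModelSpec(k=4))


def test_basis_derivative_matches_finite_differences():
    basis = build_basis(DOSES, SplineModelSpec())
    x = np.linspace(0.01, 0.99, 23)
    h = 1e-6
    fd = (basis.design(x + h) - basis.design(x - h)) / (2 * h)
    np.testing.assert_allclose(basis.derivative(x), fd, atol=1e-6)


# ------------------------------------------------------------------ gcv ----

def test_gcv_score_direct_arithmetic():
    assert gcv_score(1.0, 4, 1.0, 1.0) == pytest.approx(4.0 / 9.0)


def test_gcv_inflation_raises_score():
    assert gcv_score(1.0, 21, 4.0, 1.4) > gcv_score(1.0, 21, 4.0, 1.0)


def test_gcv_rejects_oversized_model():
    with pytest.raises(ValueError, match="too complex"):
        gcv_score(1.0, 4, 3.0, 1.4)


def test_selected_lambda_agrees_with_finer_grid_oracle(glucose_fit):
    """Brute force on a 10x finer grid finds the same GCV minimum."""
    spec = glucose_fit.spec
    table = load_paper_fixture("glucose", "biomass")
    d, y, pw = table.observations("auto")
    basis = build_basis(d, spec)
    X, S = basis.design(d), basis.penalty
    link = _Link.make(spec.link)
    fine = np.logspace(-6, 4, 1001)
    scores = []
    for lam in fine:
        _, _, dev, edf, _ = _pirls(X, S, y, pw, lam, link, 200, 1e-10)
        scores.append(np.inf if len(y) <= 1.4 * edf else gcv_score(dev, len(y), edf, 1.4))
    lam_fine = fine[int(np.argmin(scores))]
    coarse_step = 0.1  # log10 spacing of the default grid
    assert abs(np.log10(glucose_fit.lambda_) - np.log10(lam_fine)) <= coarse_step + 1e-9


# ----------------------------------------------------------------- fits ----

def test_lambda_to_zero_interpolates_noiseless_data():
    """With k+1 = n basis functions and no penalty the fit reproduces data."""
    doses = np.array([0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0])
    y = 10 + 6 * np.sin(np.pi * doses)
    spec = SplineModelSpec(k=6, paper_mode=False)
    curve = fit_gamma_gam(_table(doses, y), spec, lambda_fixed=0.0)
    np.testing.assert_allclose(curve.mean(doses), y, rtol=1e-6)
    assert deviance_explained(curve) == pytest.approx(1.0, abs=1e-6)


def test_lambda_to_infinity_converges_to_linear_gamma_glm():
    """Huge lambda leaves only the {1, x} null space: a log-linear Gamma GLM."""
    table = load_paper_fixture("glucose", "biomass")
    spec = SplineModelSpec(lambda_grid=np.array([1e9, 1e10]))
    curve = fit_gamma_gam(table, spec)
    assert curve.edf == pytest.approx(2.0, abs=1e-4)
    # brute-force 2-parameter Gamma GLM by direct deviance minimization
    from scipy.optimize import minimize

    d, y, pw = table.observations("auto")

    def dev(beta):
        mu = np.exp(beta[0] + beta[1] * d)
        return 2 * np.sum(pw * ((y - mu) / mu - np.log(y / mu)))

    res = minimize(dev, x0=[np.log(y.mean()), 0.0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12})
    assert curve.deviance == pytest.approx(res.fun, abs=1e-8)


def test_edf_is_nonincreasing_in_lambda():
    table = load_paper_fixture("glycerol", "biomass")
    d, y, pw = table.observations("auto")
    spec = SplineModelSpec()
    basis = build_basis(d, spec)
    X, S = basis.design(d), basis.penalty
    link = _Link.make("log")
    edfs = [_pirls(X, S, y, pw, lam, link, 200, 1e-10)[3]
            for lam in np.logspace(-6, 4, 21)]
    assert all(a >= b - 1e-8 for a, b in zip(edfs, edfs[1:]))
    assert 2.0 - 1e-6 <= min(edfs) and max(edfs) <= 5.0 + 1e-6


def test_fitted_mean_positive_on_dense_grid(fixture_fits):
    xs = np.linspace(0.0, 1.0, 1001)
    for (src, kind), (curve, _) in fixture_fits.items():
        assert (curve.mean(xs) > 0).all(), (src, kind)


def test_constant_response_reduces_to_intercept():
    y = np.full(7, 9.58)
    curve = fit_gamma_gam(_table(DOSES, y))
    assert any("constant" in f for f in curve.flags)
    np.testing.assert_allclose(curve.mean(DOSES), y, rtol=1e-6)
    assert deviance_explained(curve) == pytest.approx(0.0, abs=1e-8)


def test_inverse_link_also_fits_the_fixtures():
    curve = fit_gamma_gam(load_paper_fixture("glucose", "biomass"),
                          SplineModelSpec(link="inverse"))
    assert (curve.mean(np.linspace(0, 1, 501)) > 0).all()
    assert deviance_explained(curve) > 0.85


def test_spec_validation():
    with pytest.raises(ValueError, match="fewer than five"):
        SplineModelSpec(k=5)
    with pytest.raises(ValueError, match="gcv_gamma"):
        SplineModelSpec(gcv_gamma=0.5)
    with pytest.raises(ValueError, match="lambda_grid"):
        SplineModelSpec(lambda_grid=np.array([1e-3, 1e-4]))
    SplineModelSpec(k=6, paper_mode=False)  # allowed outside study mode


# -------------------------------------------------------------- predict ----

def test_predict_self_consistency_and_interval_flag(glucose_fit):
    d = DOSES
    mu = predict(glucose_fit, d)
    assert mu.shape == (7,) and (mu > 0).all()
    out = predict(glucose_fit, d, with_interval=True)
    assert len(out) == 3
    mean, lower, upper = out
    assert (lower <= mean).all() and (mean <= upper).all()
    assert (lower > 0).all()


def test_prediction_band_wider_at_sparse_domain_edge(glucose_fit):
    """Leverage: SE at the data-sparse right edge exceeds SE mid-domain."""
    _, lo_mid, up_mid = predict(glucose_fit, np.array([0.35]), with_interval=True)
    _, lo_edge, up_edge = predict(glucose_fit, np.array([0.99]), with_interval=True)
    rel_mid = (up_mid - lo_mid) / predict(glucose_fit, np.array([0.35]))
    rel_edge = (up_edge - lo_edge) / predict(glucose_fit, np.array([0.99]))
    assert rel_edge > rel_mid


def test_extrapolation_refused_unless_requested(glucose_fit):
    with pytest.raises(ValueError, match="extrapolation"):
        predict(glucose_fit, np.array([1.2]))
    val = predict(glucose_fit, np.array([1.2]), allow_extrapolation=True)
    assert np.isfinite(val).all()


def test_deviance_explained_on_fixture_is_high(glucose_fit):
    # the study reports R^2 ~ 0.95 for this relationship
    assert 0.85 <= deviance_explained(glucose_fit) <= 1.0
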