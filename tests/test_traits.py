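import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dosetrait import (
    CallableCurve,
    TraitConfig,
    TraitSet,
    extract_traits,
    find_p_max,
    find_t_max,
    safe_dose_moments,
)
from dosetrait.synth import SyntheticSpec, peaked_mean, peaked_mean_derivative


def _sine_bump(b=9.5, a=6.0, L=1.0):
    return CallableCurve(
        fn=lambda x: b + a * np.sin(np.pi * x / L),
        domain=(0.0, L),
        dfn=lambda x: a * np.pi / L * np.cos(np.pi * x / L),
    )


def test_sine_bump_peak_is_at_midpoint_by_symmetry():
    p_max, flags = find_p_max(_sine_bump())
    assert p_max == pytest.approx(0.5, abs=1e-4)
    assert flags == ()


def test_sine_bump_returns_to_baseline_at_domain_end():
    curve = _sine_bump()
    p_max, _ = find_p_max(curve)
    t_max, _ = find_t_max(curve, p_max)
    assert t_max == pytest.approx(1.0, abs=1e-4)


def test_peaked_family_stationary_point_is_theta():
    spec = SyntheticSpec(theta=0.55, p=1.5)
    p_max, flags = find_p_max(spec.curve())
    assert p_max == pytest.approx(0.55, abs=1e-4)
    assert flags == ()


def test_exponential_bump_maximizer_closed_form():
    """m(x) = b + a x exp(-x/theta) has its stationary point at x = theta."""
    theta = 0.3
    curve = CallableCurve(
        fn=lambda x: 5.0 + 20.0 * x * np.exp(-x / theta),
        domain=(0.0, 1.0),
        dfn=lambda x: 20.0 * np.exp(-x / theta) * (1 - x / theta),
    )
    p_max, _ = find_p_max(curve)
    assert p_max == pytest.approx(theta, abs=1e-5)


def test_monotone_curve_reports_boundary_maximum():
    curve = CallableCurve(fn=lambda x: 1.0 + x, domain=(0.0, 1.0))
    p_max, flags = find_p_max(curve)
    assert p_max == 1.0
    assert any("boundary" in f for f in flags)


def test_constant_curve_has_no_tolerance_limit():
    curve = CallableCurve(fn=lambda x: np.full_like(x, 7.0), domain=(0.0, 1.0))
    t_max, flags = find_t_max(curve, p_max=0.5)
    assert t_max == 1.0
    assert any("no tolerance limit" in f for f in flags)


def test_curve_below_control_gives_undefined_t_max():
    curve = CallableCurve(fn=lambda x: 10.0 - 5.0 * x, domain=(0.0, 1.0))
    t_max, flags = find_t_max(curve, p_max=0.4)
    assert t_max is None
    assert any("undefined" in f for f in flags)


def test_uniform_curve_moments_closed_form():
    curve = CallableCurve(fn=lambda x: np.full_like(x, 3.0), domain=(0.0, 1.0))
    t = 0.8
    mu, sigma = safe_dose_moments(curve, t)
    assert mu == pytest.approx(t / 2, abs=1e-6)
    assert sigma == pytest.approx(t / np.sqrt(12), abs=1e-6)


def test_linear_curve_moments_closed_form():
    # f(x) = x on [0, 1]: mu = 2/3, sigma = sqrt(1/18) by direct integration
    curve = CallableCurve(fn=lambda x: np.asarray(x, float), domain=(0.0, 1.0))
    mu, sigma = safe_dose_moments(curve, 1.0)
    assert mu == pytest.approx(2.0 / 3.0, abs=1e-6)
    assert sigma == pytest.approx(np.sqrt(1.0 / 18.0), abs=1e-6)


def test_negative_integrand_is_an_error():
    curve = CallableCurve(fn=lambda x: x - 0.5, domain=(0.0, 1.0))
    with pytest.raises(ValueError, match="non-positive integrand"):
        safe_dose_moments(curve, 1.0)


def test_simpson_agrees_with_dense_riemann_oracle():
    spec = SyntheticSpec()
    curve = spec.curve()
    mu, sigma = safe_dose_moments(curve, 1.0, TraitConfig(grid_n=2001))
    # midpoint Riemann sum on 1e6 intervals as the independent oracle
    edges = np.linspace(0.0, 1.0, 1_000_001)
    mid = (edges[:-1] + edges[1:]) / 2
    f = curve.mean(mid)
    mass = f.sum()
    mu_o = (mid * f).sum() / mass
    sg_o = np.sqrt(((mid - mu_o) ** 2 * f).sum() / mass)
    assert mu == pytest.approx(mu_o, rel=1e-6)
    assert sigma == pytest.approx(sg_o, rel=1e-6)


def test_extract_traits_composes_and_orders(fixture_fits):
    for (src, kind), (curve, ts) in fixture_fits.items():
        assert 0 < ts.p_max <= ts.t_max <= ts.domain_end + 1e-9, (src, kind)
        assert 0 < ts.mu < ts.t_max
        assert 0 < ts.sigma <= ts.t_max / 2
        assert ts.f_at_pmax >= ts.f_at_mu


def test_acetate_mu_exceeds_p_max_due_to_right_skew(fixture_fits):
    # the right-skewed acetate curve puts the safe-dose mean above the peak
    _, ts = fixture_fits[("sodium_acetate", "biomass")]
    assert ts.mu > ts.p_max


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    b=st.floats(1.0, 50.0),
    s=st.floats(0.2, 2.0),
    theta=st.floats(0.15, 0.9),
    p=st.floats(1.0, 4.0),
)
def test_trait_invariants_hold_on_random_peaked_curves(b, s, theta, p):
    curve = CallableCurve(
        fn=lambda x: peaked_mean(x, b, s, theta, p),
        domain=(0.0, 1.0),
        dfn=lambda x: peaked_mean_derivative(x, b, s, theta, p),
    )
    ts = extract_traits(curve, TraitConfig(grid_n=1001))
    assert 0 < ts.p_max <= ts.t_max <= 1.0 + 1e-9
    assert 0 < ts.mu < ts.t_max
    assert 0 < ts.sigma <= ts.t_max / 2 + 1e-9
    assert ts.p_max == pytest.approx(theta, abs=2e-3)


def test_trait_set_invariant_violations_raise():
    with pytest.raises(ValueError, match="ordering"):
        TraitSet(p_max=0.9, t_max=0.5, mu=0.3, sigma=0.1, f_at_pmax=10.0,
                 f_at_mu=9.0, domain_end=1.0)
    with pytest.raises(ValueError, match="sigma"):
        TraitSet(p_max=0.4, t_max=0.8, mu=0.4, sigma=0.6, f_at_pmax=10.0,
                 f_at_mu=9.0, domain_end=1.0)


def test_trait_config_validation():
    with pytest.raises(ValueError):
        TraitConfig(grid_n=50)
    with pytest.raises(ValueError):
        TraitConfig(root_tol=0.0)
    assert TraitConfig(grid_n=2000).odd_grid_n == 2001
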