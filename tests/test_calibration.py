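import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize_scalar

from cryoleak import (
    SimConfig,
    convert_to_ln_standard,
    deming_slope,
    deming_zero_intercept,
    mean_control_ratio,
    refit_under_converted_control,
    simulate_control_pairs,
    simulate_leakage_experiment,
    standardize_dataset,
)
from cryoleak.errors import DomainError


def rectangle_loss(s, x, y, delta=1.0):
    return np.sum((y - s * x) ** 2) / (delta + s * s)


def test_exact_line_gives_exact_slope_and_unit_r2():
    x = np.array([10.0, 50.0, 120.0, 200.0])
    y = 0.5 * x
    fit = deming_zero_intercept(x, y, n_boot=200, seed=0)
    assert fit.slope == pytest.approx(0.5, abs=1e-12)
    assert fit.r2_xy == pytest.approx(1.0)
    assert fit.r2_yx == pytest.approx(1.0)
    assert fit.outlier_idx == []
    assert fit.ci_low <= fit.slope <= fit.ci_high


@settings(derandomize=True, max_examples=50, deadline=None)
@given(seed=st.integers(0, 10_000))
def test_reciprocity_of_orthogonal_slope(seed):
    """With equal error variances, swapping axes inverts the slope exactly:
    slope(y~x) * slope(x~y) = 1."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(5.0, 200.0, size=30)
    y = rng.uniform(0.3, 0.9) * x * (1.0 + rng.normal(0.0, 0.1, size=30))
    assert deming_slope(x, y) * deming_slope(y, x) == pytest.approx(1.0, abs=1e-9)


def test_closed_form_matches_numeric_minimizer_of_rectangle_loss():
    rng = np.random.default_rng(42)
    x = rng.uniform(5.0, 200.0, size=60)
    y = 0.576 * x * (1.0 + rng.normal(0.0, 0.08, size=60))
    for delta in (0.5, 1.0, 2.0):
        s_closed = deming_slope(x, y, delta)
        s_num = minimize_scalar(
            rectangle_loss, bounds=(0.01, 10.0), args=(x, y, delta), method="bounded",
            options={"xatol": 1e-12},
        ).x
        assert s_closed == pytest.approx(s_num, abs=1e-6)


def test_scale_equivariance_of_slope():
    """Scaling y by a multiplies the slope by a exactly when the error-variance
    ratio scales with it (delta -> a^2 delta); with delta held at 1 the
    equivariance is only approximate. Scaling both axes leaves the slope
    unchanged exactly."""
    rng = np.random.default_rng(7)
    x = rng.uniform(5.0, 200.0, size=40)
    y = 0.6 * x * (1.0 + rng.normal(0.0, 0.05, size=40))
    s = deming_slope(x, y)
    assert deming_slope(x, 3.0 * y, delta=9.0) == pytest.approx(3.0 * s, rel=1e-12)
    assert deming_slope(3.0 * x, 3.0 * y) == pytest.approx(s, rel=1e-12)
    assert deming_slope(x, 3.0 * y) == pytest.approx(3.0 * s, rel=2e-3)


def test_input_validation():
    with pytest.raises(DomainError):
        deming_zero_intercept([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(Exception):
        deming_zero_intercept([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])


def test_outlier_screening_single_pass():
    rng = np.random.default_rng(3)
    x = rng.uniform(20.0, 200.0, size=50)
    y = 0.576 * x * (1.0 + rng.normal(0.0, 0.02, size=50))
    y[7] *= 2.5  # one wild tube
    fit = deming_zero_intercept(x, y, n_boot=0)
    assert 7 in fit.outlier_idx
    assert fit.n_used == 50 - len(fit.outlier_idx)
    assert fit.slope == pytest.approx(0.576, abs=0.01)
    # single pass: refitting the retained pairs with screening off reproduces it
    keep = [i for i in range(50) if i not in fit.outlier_idx]
    refit = deming_zero_intercept(x[keep], y[keep], n_boot=0, outlier_policy="none")
    assert refit.slope == pytest.approx(fit.slope, rel=1e-12)


def test_bootstrap_ci_brackets_slope_and_narrows_with_n():
    def ci_width(n, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(20.0, 200.0, size=n)
        y = 0.576 * x * (1.0 + rng.normal(0.0, 0.05, size=n))
        fit = deming_zero_intercept(x, y, n_boot=2000, seed=11, outlier_policy="none")
        assert fit.ci_low <= fit.slope <= fit.ci_high
        return fit.ci_high - fit.ci_low

    assert ci_width(200, 1) < ci_width(20, 1)


def test_bootstrap_ci_is_seed_reproducible():
    rng = np.random.default_rng(5)
    x = rng.uniform(20.0, 200.0, size=60)
    y = 0.576 * x * (1.0 + rng.normal(0.0, 0.05, size=60))
    f1 = deming_zero_intercept(x, y, n_boot=500, seed=9)
    f2 = deming_zero_intercept(x, y, n_boot=500, seed=9)
    assert (f1.ci_low, f1.ci_high) == (f2.ci_low, f2.ci_high)


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "r, slope, expected",
    [(0.288, 0.576, 0.5), (0.0, 0.576, 0.0), (0.7, 0.576, 1.0)],
)
def test_convert_to_ln_standard(r, slope, expected):
    assert convert_to_ln_standard(r, slope) == pytest.approx(expected)


def test_convert_warns_on_cap_and_supports_uncapped():
    with pytest.warns(UserWarning, match="capped"):
        assert convert_to_ln_standard(0.7, 0.576) == 1.0
    assert convert_to_ln_standard(0.7, 0.576, cap=None) == pytest.approx(0.7 / 0.576)
    with pytest.raises(DomainError):
        convert_to_ln_standard(0.5, 0.0)


def test_mean_control_ratio():
    assert mean_control_ratio({1: 58.0, 2: 116.0}, {1: 100.0, 2: 200.0}).mean == (
        pytest.approx(0.58)
    )
    stats = mean_control_ratio({k: 0.58 * v for k, v in enumerate([50.0, 80.0, 120.0])},
                               dict(enumerate([50.0, 80.0, 120.0])))
    assert stats.mean == pytest.approx(0.58)
    assert stats.sd == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(DomainError, match="unpaired"):
        mean_control_ratio({1: 1.0, 3: 2.0}, {1: 1.0, 2: 2.0})


# ---------------------------------------------------------------------------
# refit under converted control
# ---------------------------------------------------------------------------


def test_iadj_invariant_under_control_conversion():
    """The control scale cancels from the adjusted index: converting every
    tube's relative leakage by the calibration slope leaves I_adj unchanged
    to 1e-12."""
    from cryoleak import ConductivityRecord

    cfg = SimConfig(n_species=2, seed=13)
    records, _ = simulate_leakage_experiment(cfg)
    converted = [
        ConductivityRecord(r.species, r.genotype, r.replicate, r.temperature_C,
                           r.L_T / 0.576, r.L_K, "liquid_nitrogen")
        for r in records
    ]
    before = standardize_dataset(records, "I_adj")
    after = standardize_dataset(converted, "I_adj")
    for a, b in zip(before, after):
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


def test_converted_anderson_plateau_approaches_100():
    """When the generator's true plateau fraction equals the calibration
    slope, conversion lifts the Anderson upper asymptote to ~100%."""
    cfg = SimConfig(n_species=3, m=0.576, noise_sd=0.0, seed=21)
    records, _ = simulate_leakage_experiment(cfg)
    result = refit_under_converted_control(records, 0.576)
    for fit in result.fits_ln["R"].values():
        assert 100.0 * fit.d == pytest.approx(100.0, abs=1.0)
    for fit in result.fits_autoclave["R"].values():
        assert 100.0 * fit.d == pytest.approx(57.6, abs=1.0)


def test_slope_one_conversion_is_identity():
    cfg = SimConfig(n_species=1, seed=3)
    records, _ = simulate_leakage_experiment(cfg)
    result = refit_under_converted_control(records, 1.0)
    for g, fit in result.fits_autoclave["R"].items():
        assert result.fits_ln["R"][g].u == pytest.approx(fit.u, abs=1e-9)
        assert result.fits_ln["R"][g].d == pytest.approx(fit.d, abs=1e-9)


def test_control_pair_generator_recovers_slope_exactly_when_noiseless():
    cfg = SimConfig(noise_sd=0.0, seed=2)
    x, y = simulate_control_pairs(cfg, slope=0.576, n_pairs=20)
    assert deming_zero_intercept(x, y, n_boot=0).slope == pytest.approx(0.576, abs=1e-12)
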