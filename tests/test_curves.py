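import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cryoleak import (
    GompertzFit,
    LeakageSeries,
    critical_value_table,
    fit_gompertz,
    fit_loglogistic,
    fit_species,
    gompertz_eval,
    loglogistic_eval,
    lt_from_loglogistic,
    lt_max_gompertz,
    lt_p_gompertz,
)
from cryoleak.errors import DegenerateDataError, DomainError

TEMPS7 = np.array([4.0, -10.0, -20.0, -30.0, -40.0, -60.0, -80.0])


def logistic_series(c, d, b, u, reps=3, temps=TEMPS7, kind="I_adj"):
    t = np.repeat(temps, reps)
    return LeakageSeries("sp", "g", kind, t, loglogistic_eval(t, c, d, b, u))


# ---------------------------------------------------------------------------
# model evaluation
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "c, d, expected", [(0.0, 100.0, 50.0), (10.0, 60.0, 35.0)]
)
def test_loglogistic_midpoint_at_inflection(c, d, expected):
    assert loglogistic_eval(-25.0, c, d, 0.3, -25.0) == pytest.approx(expected)


def test_loglogistic_cold_asymptote():
    assert loglogistic_eval(-1e6, 0.0, 100.0, 0.3, -25.0) == pytest.approx(100.0)
    assert loglogistic_eval(1e6, 0.0, 100.0, 0.3, -25.0) == pytest.approx(0.0)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_lim_fit_recovers_exact_logistic_truth():
    series = logistic_series(0.0, 100.0, 0.3, -25.0)
    fit = fit_loglogistic(series, "lim_c0_d100")
    assert fit.converged
    assert fit.u == pytest.approx(-25.0, abs=1e-6)
    assert fit.b == pytest.approx(0.3, abs=1e-6)
    assert fit.c == 0.0 and fit.d == 100.0


def test_anderson_fit_nests_the_constrained_truth():
    series = logistic_series(0.0, 100.0, 0.3, -25.0)
    fit = fit_loglogistic(series, "anderson_free")
    assert fit.c == pytest.approx(0.0, abs=1e-3)
    assert fit.d == pytest.approx(100.0, abs=1e-3)
    assert fit.u == pytest.approx(-25.0, abs=1e-4)


def test_flint_fit_pins_lower_asymptote_only():
    series = logistic_series(0.0, 53.3, 0.22, -23.0, kind="I")
    fit = fit_loglogistic(series, "flint_c0")
    assert fit.c == 0.0
    assert fit.d == pytest.approx(53.3, abs=1e-5)
    assert fit.u == pytest.approx(-23.0, abs=1e-5)


def test_flat_series_raises_degenerate():
    t = np.repeat(TEMPS7, 3)
    series = LeakageSeries("sp", "g", "I_adj", t, np.full_like(t, 40.0))
    with pytest.raises(DegenerateDataError, match="flat"):
        fit_loglogistic(series, "lim_c0_d100")
    with pytest.raises(DegenerateDataError):
        fit_gompertz(series)


def test_too_few_temperatures_raises():
    series = LeakageSeries(
        "sp", "g", "I_adj", [4.0, -20.0, -40.0], [0.0, 50.0, 100.0]
    )
    with pytest.raises(DegenerateDataError, match="4 distinct"):
        fit_loglogistic(series, "lim_c0_d100")


def test_gompertz_recovers_its_own_truth():
    t = np.repeat(TEMPS7, 3)
    series = LeakageSeries("sp", "g", "I_adj", t, gompertz_eval(t, 2.0, -0.15))
    fit = fit_gompertz(series)
    assert fit.converged
    assert fit.b == pytest.approx(2.0, abs=1e-6)
    assert fit.k == pytest.approx(-0.15, abs=1e-6)


def test_gompertz_fits_logistic_truth_well():
    """Cross-family robustness: a Gompertz fit to symmetric-logistic data on
    the standard 7-temperature design still explains >95% of the variance."""
    series = logistic_series(0.0, 100.0, 0.3, -25.0)
    fit = fit_gompertz(series)
    assert fit.converged
    assert fit.pseudo_R2 > 0.95


def test_species_fit_pools_replicate_points():
    s1 = logistic_series(0.0, 100.0, 0.3, -25.0)
    assert fit_species([s1, s1], "lim_c0_d100").u == pytest.approx(-25.0, abs=1e-6)
    fits = [logistic_series(0.0, 100.0, 0.3, u) for u in (-20.0, -25.0, -30.0)]
    pooled = fit_species(fits, "lim_c0_d100")
    assert -30.0 < pooled.u < -20.0
    with pytest.raises(DomainError):
        fit_species([], "lim_c0_d100")


@settings(derandomize=True, max_examples=25, deadline=None)
@given(
    a=st.floats(0.5, 80.0),
    m=st.floats(0.0, 20.0),
    b=st.floats(0.1, 0.5),
    u=st.floats(-35.0, -12.0),
)
def test_anderson_refit_invariant_under_affine_rescaling(a, m, b, u):
    """Scaling/shifting the response is absorbed by the free asymptotes; the
    location and slope of the fitted curve do not move."""
    base = logistic_series(0.1, 0.6, b, u)
    scaled = LeakageSeries(
        "sp", "g", "I_adj", base.temperatures, a * base.values + m
    )
    f1 = fit_loglogistic(base, "anderson_free", d_max=np.inf)
    f2 = fit_loglogistic(scaled, "anderson_free", d_max=np.inf)
    assert f2.u == pytest.approx(f1.u, abs=1e-6)
    assert f2.b == pytest.approx(f1.b, abs=1e-6)


# ---------------------------------------------------------------------------
# critical temperatures
# ---------------------------------------------------------------------------


def test_lt50_is_the_inflection_for_every_mode():
    series = logistic_series(5.0, 95.0, 0.25, -24.0)
    for mode in ("anderson_free", "flint_c0"):
        fit = fit_loglogistic(series, mode)
        assert lt_from_loglogistic(fit, 50.0) == pytest.approx(fit.u)


@pytest.mark.parametrize(
    "p, expected",
    [(50.0, -25.0), (20.0, -25.0 + math.log(4.0) / 0.2), (80.0, -25.0 - math.log(4.0) / 0.2)],
)
def test_lt_p_closed_form(p, expected):
    from cryoleak.curves import LogisticFit

    fit = LogisticFit(0.0, 100.0, 0.2, -25.0, "lim_c0_d100", 1.0, True, 21, 0.0)
    lt = lt_from_loglogistic(fit, p)
    assert lt == pytest.approx(expected, abs=1e-9)
    # inversion round-trips through the forward model
    assert fit(lt) == pytest.approx(p, abs=1e-9)


def test_lt_p_ordering_and_domain():
    from cryoleak.curves import LogisticFit

    fit = LogisticFit(0.0, 100.0, 0.2, -25.0, "lim_c0_d100", 1.0, True, 21, 0.0)
    lts = [lt_from_loglogistic(fit, p) for p in (20.0, 50.0, 80.0)]
    assert lts[0] > lts[1] > lts[2]
    with pytest.raises(DomainError):
        lt_from_loglogistic(fit, 0.0)
    with pytest.raises(DomainError):
        lt_from_loglogistic(fit, 100.0)


def test_absolute_threshold_variant():
    from cryoleak.curves import LogisticFit

    fit = LogisticFit(0.0, 58.0, 0.2, -25.0, "anderson_free", 1.0, True, 21, 0.0)
    # absolute 29% = relative 50% of the 0->58 span
    assert lt_from_loglogistic(fit, 29.0, absolute=True) == pytest.approx(-25.0)
    with pytest.warns(UserWarning, match="outside fitted span"):
        assert math.isnan(lt_from_loglogistic(fit, 70.0, absolute=True))


@pytest.mark.parametrize(
    "b, k, expected",
    [(1.0, -0.2, 0.0), (math.e, -0.1, -10.0), (2.0, -0.15, math.log(2.0) / -0.15)],
)
def test_lt_max_gompertz_closed_form(b, k, expected):
    fit = GompertzFit(b, k, 1.0, True, 21, 0.0)
    assert lt_max_gompertz(fit) == pytest.approx(expected)


def test_lt_max_is_the_steepest_point():
    fit = GompertzFit(2.0, -0.15, 1.0, True, 21, 0.0)
    grid = np.arange(-60.0, 20.0, 0.001)
    slope = np.abs(np.gradient(gompertz_eval(grid, fit.b, fit.k), grid))
    assert grid[np.argmax(slope)] == pytest.approx(lt_max_gompertz(fit), abs=0.002)


def test_lt_p_gompertz_round_trip_and_identities():
    fit = GompertzFit(2.0, -0.15, 1.0, True, 21, 0.0)
    lt50 = lt_p_gompertz(fit, 50.0)
    assert lt50 == pytest.approx(-7.0644, abs=1e-3)
    assert gompertz_eval(lt50, fit.b, fit.k) == pytest.approx(50.0, abs=1e-9)
    # b = ln 2 puts the 50% crossing at T = 0
    assert lt_p_gompertz(GompertzFit(math.log(2.0), -0.3, 1.0, True, 21, 0.0), 50.0) == (
        pytest.approx(0.0, abs=1e-12)
    )
    # the value attained at T = 0 is 100 e^{-b}
    p0 = 100.0 * math.exp(-fit.b)
    assert lt_p_gompertz(fit, p0) == pytest.approx(0.0, abs=1e-9)


def test_gompertz_ltmax_warmer_than_lt50_when_k_negative():
    for b, k in [(2.0, -0.15), (0.02, -0.25), (5.0, -0.08)]:
        fit = GompertzFit(b, k, 1.0, True, 21, 0.0)
        assert lt_max_gompertz(fit) > lt_p_gompertz(fit, 50.0)


def test_critical_value_table_shape_and_omissions():
    good = fit_loglogistic(logistic_series(0.0, 100.0, 0.3, -25.0), "lim_c0_d100")
    bad = fit_loglogistic(logistic_series(0.0, 100.0, 0.3, -20.0), "lim_c0_d100")
    bad.converged = False
    with pytest.warns(UserWarning, match="not converged"):
        table = critical_value_table({"g1": good, "g2": bad}, (20.0, 50.0, 80.0))
    assert set(table["name"]) == {"g1"}
    assert len(table) == 3
    assert set(table["approach"]) == {"Lim_logistic"}
    gfit = fit_gompertz(
        LeakageSeries(
            "sp", "g", "I_adj",
            np.repeat(TEMPS7, 3),
            gompertz_eval(np.repeat(TEMPS7, 3), 2.0, -0.15),
        )
    )
    gtable = critical_value_table({"g1": gfit})
    assert "LTmax" in set(gtable["metric"])
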