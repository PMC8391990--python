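import dataclasses
import math

import numpy as np
import pytest
from pytest import approx
from sklearn.base import clone

from codonusage.composition import CompositionProfile
from codonusage.forces import (
    ABOVE,
    BELOW,
    NeutralityRegression,
    ON,
    enc_gc3_assessment,
    expected_enc,
    neutrality_fit,
    parity_point,
    parity_summary,
    third_position_regressions,
)


def make_profile(**overrides):
    base = {f.name: 25.0 for f in dataclasses.fields(CompositionProfile)}
    base.update(GC=50.0, GC1=50.0, GC2=50.0, GC3=50.0, GC12=50.0)
    base.update(overrides)
    return CompositionProfile(**base)


# ---------------------------------------------------------------------------
# expected ENc curve


def test_expected_enc_closed_form_values():
    assert expected_enc(0.5) == approx(60.5)
    assert expected_enc(0.0) == approx(31.0)
    assert expected_enc(1.0) == approx(32.0)  # 2 + 1 + 29


@pytest.mark.parametrize("s", [0.0, 0.1, 0.25, 0.37, 0.5])
def test_expected_enc_symmetric_up_to_linear_term(s):
    # the curve's rational part is symmetric; the +s term makes the two
    # branches differ by exactly (1 - 2s)
    assert expected_enc(1 - s) - expected_enc(s) == approx(1 - 2 * s)


def test_expected_enc_peaks_at_half():
    grid = np.linspace(0, 1, 101)
    values = [expected_enc(s) for s in grid]
    assert max(values) == approx(expected_enc(0.5))
    with pytest.raises(ValueError):
        expected_enc(1.2)


# ---------------------------------------------------------------------------
# neutrality plot


def test_exact_line_recovered():
    gc3 = np.array([30.0, 40.0, 55.0, 70.0, 82.0])
    fit = NeutralityRegression().fit(gc3, 0.5 * gc3 + 10.0)
    assert fit.slope_ == approx(0.5)
    assert fit.intercept_ == approx(10.0)
    assert fit.r_squared_ == approx(1.0)
    assert fit.pct_mutation_ == approx(50.0)
    assert fit.pct_selection_ == approx(50.0)
    assert fit.predict([50.0]) == approx([35.0])


def test_mutation_and_selection_shares_sum_to_100(rng):
    gc3 = rng.uniform(30, 85, size=100)
    gc12 = 0.27 * gc3 + 32 + rng.normal(0, 4, size=100)
    fit = neutrality_fit(
        [make_profile(GC3=x, GC12=y) for x, y in zip(gc3, gc12)]
    )
    assert fit.pct_mutation + fit.pct_selection == approx(100.0)
    assert 0 < fit.r_squared < 1


def test_degenerate_inputs_are_errors():
    est = NeutralityRegression()
    with pytest.raises(ValueError, match="zero variance"):
        est.fit([50.0, 50.0, 50.0], [40.0, 41.0, 42.0])
    with pytest.raises(ValueError, match="at least 3"):
        est.fit([50.0, 60.0], [40.0, 41.0])


def test_estimator_api_contract():
    est = NeutralityRegression()
    assert est.get_params() == {}
    clone(est)  # must be cloneable for model selection


# ---------------------------------------------------------------------------
# parity rule 2


def test_pr2_equilibrium_is_center():
    p = parity_point(make_profile(pA3=20, pT3=20, pG3=30, pC3=30))
    assert (p.x, p.y) == approx((0.5, 0.5))


def test_pr2_direct_ratio():
    p = parity_point(make_profile(pA3=10, pT3=30, pG3=30, pC3=30))
    assert p.x == approx(0.25)
    assert p.y == approx(0.5)


def test_pr2_zero_denominator_is_missing():
    p = parity_point(make_profile(pA3=0, pT3=0, pG3=50, pC3=50))
    assert math.isnan(p.x) and p.y == approx(0.5)


def test_pr2_summary_mean_and_sd(rng):
    profiles = [
        make_profile(pA3=a, pT3=50 - a, pG3=25, pC3=25)
        for a in rng.uniform(10, 40, size=30)
    ]
    summary = parity_summary(profiles)
    xs = [parity_point(p).x for p in profiles]
    assert summary["x_mean"] == approx(np.mean(xs))
    assert summary["x_sd"] == approx(np.std(xs, ddof=1))
    assert summary["y_mean"] == approx(0.5)


# ---------------------------------------------------------------------------
# ENc-GC3 curve placement


def test_curve_verdicts_with_tolerance_band():
    gc3 = [0.5, 0.5, 0.5]
    enc_values = [60.4, 55.0, 61.5]  # expected at 0.5 is 60.5
    result = enc_gc3_assessment(["a", "b", "c"], gc3, enc_values, tolerance=0.5)
    assert list(result.table["verdict"]) == [ON, BELOW, ABOVE]
    assert result.table.loc["b", "residual"] == approx(-5.5)


def test_curve_missing_enc_propagates():
    result = enc_gc3_assessment(["a"], [0.5], [None])
    assert result.table.loc["a", "verdict"] == "MISSING"


# ---------------------------------------------------------------------------
# third-position regressions


def test_identity_panel_gives_unit_slopes(rng):
    profiles = []
    for _ in range(20):
        a, c, g = rng.uniform(15, 35, size=3)
        t = 100 - a - c - g
        profiles.append(
            make_profile(pA=a, pC=c, pG=g, pT=t, pA3=a, pC3=c, pG3=g, pT3=t)
        )
    for res in third_position_regressions(profiles).values():
        assert res.slope == approx(1.0)
        assert res.r_squared == approx(1.0)
        assert res.p_value < 1e-10


def test_shuffled_panel_destroys_association(rng):
    overall = rng.uniform(15, 35, size=50)
    third = rng.uniform(15, 35, size=50)  # independent of overall
    profiles = [
        make_profile(pA=o, pA3=t3, pC=25, pC3=25 + i * 1e-3, pG=25, pG3=25 - i * 1e-3, pT=25, pT3=25 + i * 2e-3)
        for i, (o, t3) in enumerate(zip(overall, third))
    ]
    res = third_position_regressions(profiles)["A"]
    assert res.r_squared < 0.1
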