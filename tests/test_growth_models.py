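"""Unit and property tests for the growth-function registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import growthcompare as gc
from growthcompare.growth_models import DomainError, UnknownModelError

ALL_MODELS = list(gc.MODEL_NAMES)
BREEDS = ("danish", "french")


def test_registry_contains_exactly_ten_models_with_declared_arities():
    assert len(gc.MODEL_NAMES) == 10
    assert len(set(gc.MODEL_NAMES)) == 10
    expected_p = {"negative_exponential": 2, "richards": 4, "weibull": 4}
    for name in gc.MODEL_NAMES:
        spec = gc.get_model(name)
        assert spec.p == len(spec.parameter_names)
        assert spec.p == expected_p.get(name, 3)


# Frozen oracle values: direct evaluation of each functional form at day 1
# with the published parameter presets (independent hand computation).
DAY1_EXPECTED = [
    ("danish", "gompertz", 43.9246),
    ("french", "gompertz", 57.3742),
    ("danish", "richards", 58.8674),
    ("danish", "weibull", 66.2625),
    ("danish", "logistic", 102.3122),
]


@pytest.mark.parametrize("breed,model,expected", DAY1_EXPECTED)
def test_evaluate_matches_direct_computation_at_day_one(breed, model, expected):
    ps = gc.preset_params(breed, model)
    assert gc.evaluate(model, ps, 1.0) == pytest.approx(expected, abs=5e-4)


def test_negative_exponential_is_zero_at_age_zero():
    ps = gc.make_params("negative_exponential", a=100.0, k=0.1)
    assert gc.evaluate("negative_exponential", ps, 0.0) == 0.0
    # derivative at t = 0 is a*k
    assert gc.agr("negative_exponential", ps, 0.0) == pytest.approx(10.0)


def test_unknown_model_and_missing_parameter_raise():
    with pytest.raises(UnknownModelError):
        gc.get_model("sinusoidal")
    with pytest.raises(ValueError, match="missing parameter"):
        gc.evaluate("gompertz", {"a": 1.0, "b": 2.0}, 1.0)


@pytest.mark.parametrize("model", ["morgan", "lomolino"])
def test_singular_models_reject_age_zero(model):
    ps = gc.preset_params("danish", model)
    with pytest.raises(DomainError):
        gc.evaluate(model, ps, 0.0)
    with pytest.raises(DomainError):
        gc.agr(model, ps, np.array([0.0, 1.0]))
    # strictly positive ages are fine
    assert np.isfinite(gc.evaluate(model, ps, 1.0))


@pytest.mark.parametrize("breed", BREEDS)
@pytest.mark.parametrize("model", ALL_MODELS)
def test_analytic_agr_matches_central_difference(breed, model):
    """d(evaluate)/dt oracle: 200 interior grid ages, 1e-6 relative."""
    ps = gc.preset_params(breed, model)
    ts = np.linspace(1.0, 49.0, 200)
    h = 1e-5
    analytic = np.asarray(gc.agr(model, ps, ts))
    numeric = (np.asarray(gc.evaluate(model, ps, ts + h))
               - np.asarray(gc.evaluate(model, ps, ts - h))) / (2 * h)
    np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-9)


def test_gompertz_agr_maximum_is_a_k_over_e(gompertz_danish):
    t_star = math.log(gompertz_danish["b"]) / gompertz_danish["k"]
    peak = gc.agr("gompertz", gompertz_danish, t_star)
    assert peak == pytest.approx(
        gompertz_danish["a"] * gompertz_danish["k"] / math.e, rel=1e-12
    )
    assert peak == pytest.approx(60.126, abs=1e-3)
    # t* is a maximum on a local grid
    for eps in (-0.01, 0.01):
        assert peak >= gc.agr("gompertz", gompertz_danish, t_star + eps)


@pytest.mark.parametrize(
    "breed,model,expected",
    [
        ("danish", "gompertz", 23.4095),
        ("french", "gompertz", 23.9598),
        ("danish", "weibull", 24.05),
        ("french", "weibull", 24.07),
    ],
)
def test_closed_form_inflection_times(breed, model, expected):
    ps = gc.preset_params(breed, model)
    assert gc.inflection_time(model, ps) == pytest.approx(expected, abs=1e-4)


@pytest.mark.parametrize("model", ["brody", "negative_exponential"])
@pytest.mark.parametrize("breed", BREEDS)
def test_monotone_agr_models_have_no_inflection(model, breed):
    assert gc.inflection_time(model, gc.preset_params(breed, model)) is None


@pytest.mark.parametrize("breed", BREEDS)
@pytest.mark.parametrize("model", ["gompertz", "logistic", "von_bertalanffy", "weibull"])
def test_closed_form_inflection_agrees_with_numeric_argmax(breed, model):
    """Independent oracle: bounded maximisation of the AGR on [1, 60]."""
    from scipy.optimize import minimize_scalar

    ps = gc.preset_params(breed, model)
    t_star = gc.inflection_time(model, ps)
    res = minimize_scalar(lambda x: -gc.agr(model, ps, float(x)),
                          bounds=(1.0, 60.0), method="bounded",
                          options={"xatol": 1e-10})
    assert t_star == pytest.approx(res.x, abs=1e-4)


def test_weibull_inflection_is_its_ip_parameter():
    ps = gc.make_params("weibull", a=2000.0, b=55.0, k=2.4, ip=21.5)
    assert gc.inflection_time("weibull", ps) == 21.5


def test_weibull_parameter_constraints_enforced():
    with pytest.raises(ValueError, match="k > 1"):
        gc.make_params("weibull", a=1.0, b=0.5, k=0.9, ip=20.0)
    with pytest.raises(ValueError, match="ip > 0"):
        gc.make_params("weibull", a=1.0, b=0.5, k=2.0, ip=-1.0)


@pytest.mark.parametrize(
    "breed,model,expected",
    [
        ("danish", "gompertz", 2603.78),
        ("danish", "lomolino", 3367.4),
        ("danish", "richards", 2472.33),
        ("french", "weibull", 2327.4),
        ("danish", "morgan", 0.0),
        ("danish", "schumacher", 0.0),
    ],
)
def test_asymptotes(breed, model, expected):
    ps = gc.preset_params(breed, model)
    assert gc.asymptote(model, ps) == pytest.approx(expected)


@pytest.mark.parametrize("model", ["brody", "negative_exponential"])
def test_asymptote_divergent_for_negative_k(model):
    ps = gc.preset_params("danish", model)  # published fits have k < 0
    assert gc.asymptote(model, ps) is None


def test_initial_guess_properties(noiseless_gompertz_dataset):
    ds = noiseless_gompertz_dataset
    wmax = float(np.max(ds.weights))
    for model in ALL_MODELS:
        guess = gc.initial_guess(ds, model)
        assert guess.model == model
        vals = guess.as_array()
        assert np.all(np.isfinite(vals))
        if "k" in guess.values:
            assert guess["k"] > 0  # monotone-increasing data
    g = gc.initial_guess(ds, "gompertz")
    assert wmax <= g["a"] <= 2 * wmax


def test_initial_guess_requires_enough_observations():
    ds = gc.GrowthDataset("tiny", np.array([1.0, 7.0, 14.0, 21.0]),
                          np.array([50.0, 150.0, 400.0, 800.0]))
    with pytest.raises(ValueError, match="at least 5"):
        gc.initial_guess(ds, "richards")


def test_initial_guess_is_deterministic(noiseless_gompertz_dataset):
    a = gc.initial_guess(noiseless_gompertz_dataset, "weibull").as_array()
    b = gc.initial_guess(noiseless_gompertz_dataset, "weibull").as_array()
    np.testing.assert_array_equal(a, b)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    a=st.floats(100.0, 5000.0),
    b=st.floats(0.5, 50.0),
    k=st.floats(0.01, 0.5),
    model=st.sampled_from(["gompertz", "logistic", "von_bertalanffy"]),
)
def test_standard_sigmoids_increase_and_stay_below_asymptote(a, b, k, model):
    """With b > 0, k > 0 the sigmoids rise monotonically towards a."""
    if model == "von_bertalanffy" and b >= 1.0:
        b = 0.99  # cube root form needs b < 1 to stay positive from t = 0
    ps = gc.make_params(model, a=a, b=b, k=k)
    # stay on the rising part of the curve; far past saturation successive
    # float64 values become exactly equal and "strictly increasing" is moot
    ts = np.linspace(0.0, min(120.0, 6.0 / k), 200)
    y = np.asarray(gc.evaluate(model, ps, ts))
    dy = np.asarray(gc.agr(model, ps, ts))
    assert np.all(np.diff(y) > 0)
    assert np.all(y <= a + 1e-9 * a)
    assert np.all(dy > 0)


def test_model_variants_are_antiderivative_sigmoids():
    """Printed hump forms are the derivatives of the sigmoid variants."""
    h = 1e-6
    for name in ("schumacher", "morgan"):
        ps = gc.preset_params("danish", name)
        printed = gc.get_model(name)
        sig = gc.get_model(name, variant="sigmoid")
        ts = np.linspace(2.0, 45.0, 50)
        hump = np.asarray(gc.evaluate(printed, ps, ts))
        dsig = (np.asarray(gc.evaluate(sig, ps, ts + h))
                - np.asarray(gc.evaluate(sig, ps, ts - h))) / (2 * h)
        np.testing.assert_allclose(hump, dsig, rtol=1e-6)
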