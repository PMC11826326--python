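"""Published reference values for Danish and French Pekin duck lines.

Parameter estimates and goodness-of-fit statistics from a comparative
growth-curve study of two conserved Pekin duck lines (Danish P8, French
P9) weighed at 1, 7, 14, 21, 28, 35, 42 and 49 days of age, with one
breed-mean weight per age (n = 8).  These serve as generator defaults for
the synthetic-data module, as worked-example inputs, and as cross-check
material for the statistic suite.  The raw weights behind them were never
published, so per-fit quantities that need the data (TSS, residuals) are
not reconstructable; RMSE/AIC/BIC are mutually consistent through
RSS = RMSE^2 * (n - p).
"""

from __future__ import annotations

from .growth_models import ParameterSet, make_params

__all__ = [
    "OBSERVATION_AGES",
    "N_OBSERVATIONS",
    "PRESET_PARAMETERS",
    "REFERENCE_GOF",
    "REFERENCE_DW_CLASS",
    "ANOMALOUS_BIC_MODELS",
    "preset_params",
]

OBSERVATION_AGES: tuple[int, ...] = (1, 7, 14, 21, 28, 35, 42, 49)
N_OBSERVATIONS: int = len(OBSERVATION_AGES)

_DANISH = {
    "brody": dict(a=-14015.1, b=0.9939, k=-0.00311),
    "negative_exponential": dict(a=-4987.92, k=-0.00752),
    "logistic": dict(a=2230.02, b=23.4414, k=0.119732),
    "gompertz": dict(a=2603.78, b=4.3467, k=0.06277),
    "von_bertalanffy": dict(a=2974.50, b=0.8610, k=0.04335),
    "richards": dict(a=2472.33, b=-1.2733, k=0.07484, m=0.20869),
    "schumacher": dict(a=41.79, b=20.2632, k=0.495034),
    "morgan": dict(a=234354.8, b=80.16505, k=2.63234),
    "lomolino": dict(a=3367.4, b=95.2484, k=36.9441),
    "weibull": dict(a=2377.6, b=64.5174, k=2.0503, ip=24.05),
}

_FRENCH = {
    "brody": dict(a=-11526.6, b=0.9950, k=-0.00344),
    "negative_exponential": dict(a=-5291.76, k=-0.0067),
    "logistic": dict(a=2111.62, b=20.2639, k=0.11262),
    "gompertz": dict(a=2511.22, b=4.0042, k=0.057903),
    "von_bertalanffy": dict(a=2932.57, b=0.8093, k=0.039018),
    "richards": dict(a=2401.12, b=-0.7805, k=0.06647, m=0.153525),
    "schumacher": dict(a=82.91, b=23.6164, k=0.398277),
    "morgan": dict(a=264080.8, b=89.98532, k=2.514388),
    "lomolino": dict(a=3683.9, b=55.6420, k=44.3791),
    "weibull": dict(a=2327.4, b=68.7798, k=1.9212, ip=24.07),
}

PRESET_PARAMETERS: dict[str, dict[str, dict[str, float]]] = {
    "danish": _DANISH,
    "french": _FRENCH,
}

#: Published fit statistics per breed (n = 8; p = 2 for the negative
#: exponential, 4 for Richards and Weibull, 3 otherwise).
REFERENCE_GOF: dict[str, dict[str, dict[str, float]]] = {
    "danish": {
        "r2_adj": dict(brody=0.9822, negative_exponential=0.9825, logistic=0.9957,
                       gompertz=0.9976, von_bertalanffy=0.9960, richards=0.9973,
                       schumacher=0.9970, morgan=0.9963, lomolino=0.9954,
                       weibull=0.9969),
        "dw": dict(brody=1.50, negative_exponential=1.30, logistic=2.23,
                   gompertz=3.20, von_bertalanffy=2.43, richards=3.37,
                   schumacher=2.81, morgan=2.39, lomolino=2.13, weibull=3.31),
        "rmse": dict(brody=106.6, negative_exponential=105.7, logistic=52.67,
                     gompertz=39.17, von_bertalanffy=50.40, richards=41.62,
                     schumacher=43.95, morgan=48.79, lomolino=54.25,
                     weibull=44.30),
        "aic": dict(brody=93.58, negative_exponential=92.90, logistic=82.30,
                    gompertz=77.56, von_bertalanffy=81.60, richards=78.75,
                    schumacher=79.40, morgan=81.08, lomolino=82.77,
                    weibull=79.75),
        "bic": dict(brody=77.19, negative_exponential=76.42, logistic=65.90,
                    gompertz=61.16, von_bertalanffy=65.20, richards=62.43,
                    schumacher=63.01, morgan=64.68, lomolino=69.27,
                    weibull=67.29),
    },
    "french": {
        "r2_adj": dict(brody=0.9871, negative_exponential=0.9878, logistic=0.9965,
                       gompertz=0.9986, von_bertalanffy=0.9974, richards=0.9984,
                       schumacher=0.9981, morgan=0.9970, lomolino=0.9959,
                       weibull=0.9980),
        "dw": dict(brody=1.47, negative_exponential=1.32, logistic=1.86,
                   gompertz=3.31, von_bertalanffy=2.39, richards=3.41,
                   schumacher=2.85, morgan=1.93, lomolino=1.79, weibull=3.29),
        "rmse": dict(brody=83.14, negative_exponential=80.79, logistic=43.47,
                     gompertz=27.58, von_bertalanffy=37.45, richards=29.60,
                     schumacher=31.68, morgan=39.95, lomolino=46.91,
                     weibull=32.97),
        "aic": dict(brody=89.60, negative_exponential=88.60, logistic=79.23,
                    gompertz=71.95, von_bertalanffy=76.84, richards=73.29,
                    schumacher=74.17, morgan=77.88, lomolino=80.45,
                    weibull=75.02),
        "bic": dict(brody=73.21, negative_exponential=72.13, logistic=62.83,
                    gompertz=55.55, von_bertalanffy=60.45, richards=56.98,
                    schumacher=57.77, morgan=61.49, lomolino=66.95,
                    weibull=62.56),
    },
}

#: Residual-autocorrelation classifications the published study reports
#: for the Danish line (used to anchor the descriptive DW bands).
REFERENCE_DW_CLASS: dict[str, str] = {
    "brody": "positive", "negative_exponential": "positive",
    "logistic": "none", "von_bertalanffy": "none", "morgan": "none",
    "lomolino": "none", "gompertz": "negative", "richards": "negative",
    "schumacher": "negative", "weibull": "negative",
}

#: BIC cells inconsistent with the RSS = RMSE^2 (n - p) reconstruction
#: that reproduces every other cell (likely computed by different
#: software); excluded from internal-consistency checks.
ANOMALOUS_BIC_MODELS: tuple[str, ...] = ("lomolino", "weibull")


def preset_params(breed: str, model: str) -> ParameterSet:
    """Published :class:`ParameterSet` for one breed line and model."""
    try:
        vals = PRESET_PARAMETERS[breed.lower()][model]
    except KeyError as exc:
        raise KeyError(f"no preset for breed={breed!r}, model={model!r}") from exc
    return make_params(model, **vals)
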