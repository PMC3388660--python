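"""Population fluid-responsiveness model.

A synthetic stand-in for a pre/post-bolus hemodynamic database (PPV, CO, MAP,
HR measured before and after a 500-ml colloid bolus) and the prediction layer
built on it: the probability that a patient is a fluid responder (>= 15%
cardiac-output rise after a 500-ml bolus) and the expected percentage CO
change, both as monotone functions of PPV with small bounded modifiers from
CO, MAP and HR.

The generative truth is a saturating-linear expected response,
``dCO% = clip(2.5 * (PPV - 5.6), -5, 32) + N(0, 7)``, which yields an
indeterminate ("gray zone") band at PPV ~9-13% where the responder
probability is near one half.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "BolusResponseRecord",
    "ResponseModel",
    "ResponsePrediction",
    "generate_population_dataset",
    "fit_response_model",
    "predict",
    "default_response_model",
    "dataset_to_frame",
    "RESPONDER_THRESHOLD_PCT",
    "REFERENCE_BOLUS_ML",
]

RESPONDER_THRESHOLD_PCT = 15.0  # %dCO defining a fluid responder
REFERENCE_BOLUS_ML = 500.0      # bolus volume the database responses refer to

# generative truth for the synthetic database
TRUE_SLOPE = 2.5        # %dCO per PPV point
TRUE_PPV_INTERCEPT = 5.6  # PPV at which expected dCO crosses zero
TRUE_FLOOR = -5.0
TRUE_CAP = 32.0
NOISE_SD = 7.0          # percentage points of dCO

ZONE_LOW_PCT = 5.0      # expected dCO below which no fluid is indicated
ZONE_HIGH_PCT = 15.0    # expected dCO above which a bolus is indicated

#: frozen seed of the database the default controller ships with
DEFAULT_POPULATION_SEED = 414


@dataclass(frozen=True)
class BolusResponseRecord:
    """One patient's hemodynamics before/after a 500-ml colloid bolus."""

    ppv_pre: float       # percent
    co_pre: float        # L/min
    map_pre: float       # mm Hg
    hr_pre: float        # beats/min
    co_post: float       # L/min
    delta_co_pct: float  # percent

    def __post_init__(self) -> None:
        if self.co_pre <= 0:
            raise ValueError("co_pre must be positive")


@dataclass(frozen=True)
class ResponsePrediction:
    """Output of the population layer for one set of hemodynamics."""

    p_responder: float          # probability in [0, 1]
    expected_delta_co_pct: float  # % CO change expected from a 500-ml bolus
    zone: str                   # 'negative' | 'gray' | 'positive'


@dataclass(frozen=True)
class ResponseModel:
    """Deterministically fitted population constants."""

    logit_intercept: float
    logit_slope: float
    dco_slope: float
    dco_ppv_intercept: float
    dco_floor: float
    dco_cap: float
    zone_low: float = ZONE_LOW_PCT
    zone_high: float = ZONE_HIGH_PCT

    def expected_dco(self, ppv: float) -> float:
        return float(np.clip(self.dco_slope * (ppv - self.dco_ppv_intercept),
                             self.dco_floor, self.dco_cap))

    def p_responder(self, ppv: float) -> float:
        z = self.logit_intercept + self.logit_slope * ppv
        return float(1.0 / (1.0 + np.exp(-z)))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ResponseModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def true_expected_dco(ppv) -> np.ndarray:
    """Generative expected %dCO curve (the known truth behind the dataset)."""
    return np.clip(TRUE_SLOPE * (np.asarray(ppv, dtype=float) - TRUE_PPV_INTERCEPT),
                   TRUE_FLOOR, TRUE_CAP)


def true_p_responder(ppv) -> np.ndarray:
    """Generative responder probability P(dCO >= 15 | PPV)."""
    from scipy.stats import norm

    return norm.sf((RESPONDER_THRESHOLD_PCT - true_expected_dco(ppv)) / NOISE_SD)


def generate_population_dataset(n: int, rng) -> list[BolusResponseRecord]:
    """Draw ``n`` synthetic pre/post-bolus records.

    PPV is drawn from a two-component mixture spanning 2-25% (a normovolemic
    mode near 7.5% and a hypovolemic mode near 15%), the CO response from the
    saturating-linear truth plus Gaussian noise.
    """
    if n < 50:
        raise ValueError("n must be >= 50 for a stable downstream fit")
    low_mode = rng.random(n) < 0.5
    ppv = np.where(low_mode, rng.normal(7.5, 2.5, n), rng.normal(15.0, 4.5, n))
    ppv = np.clip(ppv, 2.0, 25.0)
    delta = true_expected_dco(ppv) + rng.normal(0.0, NOISE_SD, n)
    co_pre = np.clip(rng.normal(5.2, 1.0, n), 2.5, 9.0)
    map_pre = np.clip(rng.normal(82.0, 12.0, n), 50.0, 120.0)
    hr_pre = np.clip(rng.normal(78.0, 12.0, n), 45.0, 130.0)
    co_post = co_pre * (1.0 + delta / 100.0)
    return [
        BolusResponseRecord(
            ppv_pre=float(ppv[i]),
            co_pre=float(co_pre[i]),
            map_pre=float(map_pre[i]),
            hr_pre=float(hr_pre[i]),
            co_post=float(co_post[i]),
            delta_co_pct=float(delta[i]),
        )
        for i in range(n)
    ]


def dataset_to_frame(dataset: list[BolusResponseRecord]) -> pd.DataFrame:
    """Serialize records to a DataFrame (CSV-ready, six columns)."""
    return pd.DataFrame([asdict(r) for r in dataset])


def fit_response_model(dataset: list[BolusResponseRecord]) -> ResponseModel:
    """Fit the monotone responder-probability and expected-dCO curves.

    The responder curve is a logistic regression of responder status on PPV
    (GLM/binomial, IRLS — deterministic).  The expected-dCO curve is a
    saturating piecewise-linear fit obtained in two deterministic stages:
    tail means estimate the floor and cap, ordinary least squares on the
    central PPV band estimates slope and intercept.  Both fits are invariant
    to duplicating every record.
    """
    df = dataset_to_frame(dataset)
    responder = (df["delta_co_pct"] >= RESPONDER_THRESHOLD_PCT).astype(float)
    if responder.nunique() < 2:
        raise ValueError("dataset must contain both responders and non-responders")

    exog = sm.add_constant(df["ppv_pre"].to_numpy())
    glm = sm.GLM(responder.to_numpy(), exog, family=sm.families.Binomial())
    import warnings

    with warnings.catch_warnings():
        # a perfectly separated dataset still yields a usable steep curve
        warnings.simplefilter("ignore")
        res = glm.fit()
    b0, b1 = float(res.params[0]), float(res.params[1])
    if b1 < 0:  # guard: responder probability must be nondecreasing in PPV
        b1 = 0.0

    ppv = df["ppv_pre"].to_numpy()
    dco = df["delta_co_pct"].to_numpy()
    low_tail = dco[ppv <= 5.0]
    high_tail = dco[ppv >= 20.0]
    floor = float(low_tail.mean()) if low_tail.size else TRUE_FLOOR
    cap = float(high_tail.mean()) if high_tail.size else TRUE_CAP
    mid = (ppv >= 6.0) & (ppv <= 17.0)
    if mid.sum() >= 10:
        slope, intercept = np.polyfit(ppv[mid], dco[mid], 1)
    else:  # tiny/degenerate datasets: chord between tail means
        slope = (cap - floor) / 15.0
        intercept = floor - slope * 5.0
    slope = max(float(slope), 1e-6)
    x0 = -float(intercept) / slope
    if cap <= floor:
        cap = floor + 1e-6
    return ResponseModel(
        logit_intercept=b0,
        logit_slope=b1,
        dco_slope=slope,
        dco_ppv_intercept=x0,
        dco_floor=floor,
        dco_cap=cap,
    )


def predict(ppv: float, co: float, map_: float, hr: float,
            model: ResponseModel) -> ResponsePrediction:
    """Population prediction for the current hemodynamics.

    PPV is the primary driver; CO, MAP and HR apply only bounded
    multiplicative modifiers (at most +/-20% of the expected dCO).
    """
    if ppv < 0:
        raise ValueError("ppv must be non-negative")
    expected = model.expected_dco(ppv)
    modifier = 1.0
    if co < 4.5:          # low output: benefit of preload slightly raised
        modifier *= 1.10
    elif co > 7.0:
        modifier *= 0.95
    if map_ < 65.0 and hr > 100.0:  # shock pattern
        modifier *= 1.05
    modifier = float(np.clip(modifier, 0.8, 1.2))
    expected *= modifier

    p = model.p_responder(ppv)
    if map_ < 65.0 and hr > 100.0:
        p = min(1.0, p * 1.1)

    if expected < model.zone_low:
        zone = "negative"
    elif expected >= model.zone_high:
        zone = "positive"
    else:
        zone = "gray"
    return ResponsePrediction(p_responder=p, expected_delta_co_pct=float(expected), zone=zone)


_default_model: ResponseModel | None = None


def default_response_model() -> ResponseModel:
    """The model fitted once on the frozen 414-record synthetic database."""
    global _default_model
    if _default_model is None:
        rng = np.random.default_rng(DEFAULT_POPULATION_SEED)
        _default_model = fit_response_model(generate_population_dataset(414, rng))
    return _default_model
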