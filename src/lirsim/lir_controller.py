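"""Adaptive closed-loop fluid-administration controller.

The decision engine maps the population prediction (expected %CO increase
from a reference 500-ml bolus) and the recent CO trend to one of a small set
of actions: do nothing, start a bolus, quicken or halt a running infusion,
let it continue, or probe with a small test bolus in the indeterminate
("gray") range.  Boluses are discrete so the controller can compare each
observed response with its prediction and adapt: a failed test bolus raises
the bar for future tests, a much-larger-than-expected response lowers the
bolus threshold, and a running observed/predicted ratio rescales the
population prediction for the current patient (all bounded, for loop
stability under sensor noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .population_response import (
    ResponseModel,
    ResponsePrediction,
    predict,
    REFERENCE_BOLUS_ML,
    RESPONDER_THRESHOLD_PCT,
)

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "BolusRecord",
    "ActiveInfusion",
    "Action",
    "decide",
    "update_infusion",
    "adapt",
    "LIRController",
]


@dataclass(frozen=True)
class ControllerConfig:
    """Tunable constants of the rule-based layer.

    Thresholds are in expected %dCO for the reference 500-ml bolus; the
    negative / positive zone boundaries (5 / 15%) map through the default
    population model to PPV of roughly 7.6% and 13%, bracketing the 9-13%
    gray zone.
    """

    low_threshold: float = 5.0        # below: no fluid; halt if infusing
    high_threshold: float = 15.0      # above: start (or quicken) a bolus
    test_bolus_threshold: float = 8.0  # gray zone: minimum to justify a test
    bolus_volume: float = 250.0       # ml
    bolus_rate: float = 50.0          # ml/min
    test_bolus_volume: float = 100.0  # ml
    evaluation_delay: float = 2.0     # min after bolus end to read the response
    co_trend_window: float = 5.0      # min of CO history for the trend test
    adaptation_step: float = 0.10     # multiplicative threshold step
    quicken_factor: float = 1.5
    max_rate: float = 100.0           # ml/min cap after quickening
    #: fractional CO decline over the trend window that counts as downward
    #: (relative, so numerical drift never masquerades as deterioration)
    trend_epsilon: float = 0.005
    #: optional median filter over the last N PPV readings (1 = raw signal;
    #: commercial monitors already average PPV over respiratory cycles)
    ppv_filter_width: int = 1
    threshold_bound_factor: float = 2.0  # thresholds stay in [x/2, 2x] defaults
    scale_bounds: tuple = (0.5, 2.0)  # per-patient prediction rescale bounds

    def __post_init__(self) -> None:
        if not self.low_threshold < self.high_threshold:
            raise ValueError("low_threshold must be below high_threshold")
        for name in ("bolus_volume", "bolus_rate", "test_bolus_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.adaptation_step <= 0.5:
            raise ValueError("adaptation_step must be in (0, 0.5]")

    def bounds(self, name: str) -> tuple:
        default = {"low_threshold": 5.0, "high_threshold": 15.0,
                   "test_bolus_threshold": 8.0}[name]
        k = self.threshold_bound_factor
        return (default / k, default * k)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["scale_bounds"] = list(d["scale_bounds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ControllerConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "scale_bounds" in d:
            d["scale_bounds"] = tuple(d["scale_bounds"])
        return cls(**d)


@dataclass
class ActiveInfusion:
    remaining_volume: float  # ml
    rate: float              # ml/min
    is_test: bool
    record: "BolusRecord"


@dataclass
class BolusRecord:
    """Pre/post hemodynamic ledger of one bolus; drives adaptation."""

    t_start: float
    volume: float
    is_test: bool
    pre: dict                       # {'ppv','co','map','hr'} at start
    predicted_delta_co_pct: float   # prediction prorated to this volume
    t_end: float | None = None
    post: dict | None = None        # measurements at t_end + evaluation_delay
    observed_delta_co_pct: float | None = None

    def close_observation(self, post: dict) -> None:
        self.post = dict(post)
        self.observed_delta_co_pct = 100.0 * (post["co"] - self.pre["co"]) / self.pre["co"]


@dataclass
class ControllerState:
    """Current (possibly adapted) config, bolus history, and loop state."""

    config: ControllerConfig
    low_threshold: float = None  # type: ignore[assignment]
    high_threshold: float = None  # type: ignore[assignment]
    test_bolus_threshold: float = None  # type: ignore[assignment]
    prediction_scale: float = 1.0
    history: list = field(default_factory=list)
    active_infusion: ActiveInfusion | None = None
    awaiting_evaluation: BolusRecord | None = None
    failed_test_streak: int = 0

    def __post_init__(self) -> None:
        if self.low_threshold is None:
            self.low_threshold = self.config.low_threshold
        if self.high_threshold is None:
            self.high_threshold = self.config.high_threshold
        if self.test_bolus_threshold is None:
            self.test_bolus_threshold = self.config.test_bolus_threshold


@dataclass(frozen=True)
class Action:
    """One controller decision; rate in ml/min where applicable."""

    kind: str  # none | start_bolus | start_test_bolus | quicken | continue | halt
    rate: float = 0.0


def _co_trend(recent_co) -> float:
    """Fractional CO change across the trend window (last vs first sample)."""
    seq = list(recent_co)
    if not seq:
        raise ValueError("recent_co must be non-empty")
    if seq[0] <= 0:
        return 0.0
    return (seq[-1] - seq[0]) / seq[0]


def decide(prediction: ResponsePrediction, recent_co, state: ControllerState) -> Action:
    """Map the (patient-rescaled) prediction and CO trend to an action.

    Below the low threshold no fluid is given and a running infusion is
    halted; above the high threshold a bolus is started or quickened; in the
    middle range a running bolus continues, and a test bolus is started only
    on a downward CO trend with sufficient expected benefit.
    """
    expected = prediction.expected_delta_co_pct * state.prediction_scale
    trend = _co_trend(recent_co)
    cfg = state.config
    infusing = state.active_infusion is not None

    if expected < state.low_threshold:
        return Action("halt") if infusing else Action("none")
    if expected >= state.high_threshold:
        if infusing:
            new_rate = min(cfg.max_rate, state.active_infusion.rate * cfg.quicken_factor)
            return Action("quicken", rate=new_rate)
        if state.awaiting_evaluation is not None:
            return Action("none")  # last bolus still being evaluated
        return Action("start_bolus", rate=cfg.bolus_rate)
    # gray zone
    if infusing:
        return Action("continue", rate=state.active_infusion.rate)
    if (trend < -cfg.trend_epsilon
            and expected >= state.test_bolus_threshold
            and state.awaiting_evaluation is None):
        return Action("start_test_bolus", rate=cfg.bolus_rate)
    return Action("none")


def update_infusion(state: ControllerState, dt: float) -> float:
    """Deliver fluid for ``dt`` minutes; return the crystalloid rate (ml/min).

    When the bolus finishes mid-step the rate is prorated so the delivered
    volume equals the programmed volume exactly; the finished record then
    awaits its post-bolus measurement after the evaluation delay.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    inf = state.active_infusion
    if inf is None:
        return 0.0
    if inf.remaining_volume < 0:
        raise RuntimeError("negative remaining bolus volume")
    delivered = min(inf.remaining_volume, inf.rate * dt)
    inf.remaining_volume -= delivered
    if inf.remaining_volume <= 1e-9:
        state.awaiting_evaluation = inf.record
        state.active_infusion = None
    return delivered / dt


def adapt(state: ControllerState, completed: BolusRecord) -> ControllerState:
    """Learn from one completed bolus (mutates and returns ``state``).

    * failed test bolus (observed below the volume-prorated responder
      cutoff): the test-bolus threshold is raised;
    * observed response at least 1.5x the prediction: the bolus threshold
      is lowered;
    * clearly over-predicted full bolus: the bolus threshold is nudged up
      (damping); a clearly successful test nudges the test threshold down.

    The per-patient prediction rescale tracks the running observed/predicted
    ratio, bounded to the configured interval.
    """
    if completed.post is None or completed.observed_delta_co_pct is None:
        raise ValueError("bolus record has no post-bolus measurements")
    cfg = state.config
    s = cfg.adaptation_step
    obs = completed.observed_delta_co_pct
    pred = completed.predicted_delta_co_pct
    cutoff = RESPONDER_THRESHOLD_PCT * completed.volume / REFERENCE_BOLUS_ML

    if completed.is_test:
        lo, hi = cfg.bounds("test_bolus_threshold")
        if obs < cutoff:
            # repeated futile challenges only add interstitial fluid, so the
            # bar escalates with the streak of consecutive failures
            state.failed_test_streak += 1
            factor = (1.0 + s) ** state.failed_test_streak
            state.test_bolus_threshold = min(hi, state.test_bolus_threshold * factor)
        else:
            state.failed_test_streak = 0
            state.test_bolus_threshold = max(lo, state.test_bolus_threshold * (1.0 - s / 2.0))
    if pred > 0:
        lo, hi = cfg.bounds("high_threshold")
        if obs >= 1.5 * pred:
            state.high_threshold = max(lo, state.high_threshold * (1.0 - s))
        elif obs < 0.5 * pred and not completed.is_test:
            state.high_threshold = min(hi, state.high_threshold * (1.0 + s / 2.0))
        ratio = min(max(obs / pred, 0.25), 4.0)
        lo_s, hi_s = cfg.scale_bounds
        state.prediction_scale = min(hi_s, max(lo_s, 0.5 * state.prediction_scale + 0.5 * ratio))
    state.history.append(completed)
    return state


class LIRController:
    """Stateful wrapper running the closed loop at a fixed polling interval.

    The scenario engine feeds it one sensor reading (reported PPV, CO, MAP,
    HR) per polling tick via :meth:`observe`, and queries the commanded
    crystalloid rate every simulator step via :meth:`infusion_rate`.  Every
    decision is appended to ``event_log`` for audit.
    """

    def __init__(self, config: ControllerConfig | None = None,
                 model: ResponseModel | None = None,
                 poll_interval: float = 0.5) -> None:
        from .population_response import default_response_model

        self.config = config or ControllerConfig()
        self.model = model if model is not None else default_response_model()
        self.poll_interval = poll_interval  # min between sensor readings
        self.state = ControllerState(config=self.config)
        self.event_log: list[dict] = []
        self._co_history: list[tuple] = []  # (t, co)
        self._ppv_history: list[float] = []  # raw readings for the median filter

    # -- sensor/decision tick ------------------------------------------------
    def observe(self, t: float, ppv: float, co: float, map_: float, hr: float) -> Action:
        self._co_history.append((t, co))
        window = self.config.co_trend_window
        self._co_history = [(u, c) for (u, c) in self._co_history if u >= t - window - 1e-9]
        recent_co = [c for (_, c) in self._co_history]

        # median filter over the last readings conditions the PPV signal
        self._ppv_history.append(ppv)
        width = max(1, self.config.ppv_filter_width)
        self._ppv_history = self._ppv_history[-width:]
        ppv_f = float(sorted(self._ppv_history)[len(self._ppv_history) // 2])

        self._maybe_evaluate(t, ppv=ppv_f, co=co, map=map_, hr=hr)

        prediction = predict(ppv_f, co, map_, hr, self.model)
        action = decide(prediction, recent_co, self.state)
        self._execute(action, t, prediction, ppv=ppv_f, co=co, map=map_, hr=hr)

        self.event_log.append({
            "t": t, "ppv_reported": ppv, "co": co, "map": map_, "hr": hr,
            "expected_delta_co_pct": prediction.expected_delta_co_pct,
            "scaled_expected": prediction.expected_delta_co_pct * self.state.prediction_scale,
            "p_responder": prediction.p_responder,
            "zone": prediction.zone,
            "action": action.kind,
            "rate": action.rate,
            "low_threshold": self.state.low_threshold,
            "high_threshold": self.state.high_threshold,
            "test_bolus_threshold": self.state.test_bolus_threshold,
            "prediction_scale": self.state.prediction_scale,
        })
        return action

    def _execute(self, action: Action, t: float, prediction: ResponsePrediction,
                 **measurements) -> None:
        st = self.state
        if action.kind in ("start_bolus", "start_test_bolus"):
            is_test = action.kind == "start_test_bolus"
            volume = self.config.test_bolus_volume if is_test else self.config.bolus_volume
            scaled = prediction.expected_delta_co_pct * st.prediction_scale
            record = BolusRecord(
                t_start=t, volume=volume, is_test=is_test,
                pre=dict(measurements),
                predicted_delta_co_pct=scaled * volume / REFERENCE_BOLUS_ML,
            )
            st.active_infusion = ActiveInfusion(
                remaining_volume=volume, rate=action.rate, is_test=is_test, record=record)
        elif action.kind == "quicken" and st.active_infusion is not None:
            st.active_infusion.rate = action.rate
        elif action.kind == "halt" and st.active_infusion is not None:
            # partial bolus: evaluate what was actually delivered
            inf = st.active_infusion
            delivered = inf.record.volume - inf.remaining_volume
            if delivered > 1e-6:
                inf.record.volume = delivered
                inf.record.predicted_delta_co_pct *= delivered / (delivered + inf.remaining_volume)
                st.awaiting_evaluation = inf.record
            st.active_infusion = None

    def _maybe_evaluate(self, t: float, **measurements) -> None:
        rec = self.state.awaiting_evaluation
        if rec is None:
            return
        if rec.t_end is None:
            rec.t_end = t  # first tick after completion
        if t >= rec.t_end + self.config.evaluation_delay - 1e-9:
            rec.close_observation(measurements)
            adapt(self.state, rec)
            self.state.awaiting_evaluation = None

    # -- fluid delivery ------------------------------------------------------
    def infusion_rate(self, dt: float) -> float:
        """Crystalloid rate (ml/min) commanded over the next ``dt`` minutes."""
        return update_infusion(self.state, dt)

    @property
    def total_bolus_volume(self) -> float:
        done = sum(r.volume for r in self.state.history)
        if self.state.awaiting_evaluation is not None:
            done += self.state.awaiting_evaluation.volume
        inf = self.state.active_infusion
        if inf is not None:
            done += inf.record.volume - inf.remaining_volume
        return done

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(self.event_log)
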