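"""Scenario definition and batch execution of the in-silico study phases.

Scenarios are timelines: a constant-rate hemorrhage window, a steady
maintenance crystalloid infusion (200 ml/h), per-phase baseline randomization
ranges, and the management mode (none or closed loop).  A noise specification
corrupts only the *reported* PPV stream seen by the controller — the
simulator state and the true PPV are untouched — with an optional per-trial
constant bias and/or a fresh uniform fluctuation per reading, both of
amplitude 5 percentage points by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import hemodynamic_model as hm
from .hemodynamic_model import PatientParams, PatientState
from .lir_controller import ControllerConfig, LIRController
from .population_response import ResponseModel, default_response_model

__all__ = [
    "ScenarioSpec",
    "NoiseSpec",
    "TrialResult",
    "PPVSensor",
    "builtin_scenario",
    "corrupt_ppv",
    "run_trial",
    "run_batch",
    "BUILTIN_SCENARIOS",
    "SAMPLE_INTERVAL_MIN",
    "SIM_DT_MIN",
    "MAINTENANCE_RATE_ML_H",
    "FLUID_WINDOW_MIN",
]

SIM_DT_MIN = 1.0 / 12.0       # 5-s fixed integration step
SAMPLE_INTERVAL_MIN = 0.5     # sensor sampling / controller polling: 30 s
MAINTENANCE_RATE_ML_H = 200.0
#: fluid totals are accounted from hemorrhage onset to onset + 90 min
#: (clipped to scenario end), uniformly across scenarios
FLUID_WINDOW_MIN = 90.0

NOISE_MODES = ("accurate", "biased", "fluctuating", "biased_and_fluctuating")


@dataclass(frozen=True)
class ScenarioSpec:
    """Timeline and randomization recipe of one experiment."""

    name: str
    duration: float               # min
    hemorrhage_start: float       # min
    hemorrhage_volume: float      # ml
    hemorrhage_duration: float    # min
    baseline_ranges: dict
    management: str = "none"      # none | closed_loop | manual
    maintenance_rate: float = MAINTENANCE_RATE_ML_H  # ml/h
    n_trials: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hemorrhage_volume < 0:
            raise ValueError("hemorrhage volume must be >= 0")
        if self.hemorrhage_start + self.hemorrhage_duration > self.duration + 1e-9:
            raise ValueError("hemorrhage window must fit inside the scenario")
        if self.management not in ("none", "closed_loop", "manual"):
            raise ValueError("management must be none | closed_loop | manual")

    @property
    def hemorrhage_rate(self) -> float:
        if self.hemorrhage_duration <= 0:
            return 0.0
        return self.hemorrhage_volume / self.hemorrhage_duration

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["baseline_ranges"] = {k: tuple(v) for k, v in d["baseline_ranges"].items()}
        return cls(**d)


@dataclass(frozen=True)
class NoiseSpec:
    """PPV corruption mode for the reported (sensor) PPV stream."""

    mode: str = "accurate"
    bias_amplitude: float = 5.0         # percent, absolute
    fluctuation_amplitude: float = 5.0  # percent, absolute

    def __post_init__(self) -> None:
        if self.mode not in NOISE_MODES:
            raise ValueError(f"unknown noise mode {self.mode!r}; allowed: {NOISE_MODES}")
        if self.bias_amplitude < 0 or self.fluctuation_amplitude < 0:
            raise ValueError("noise amplitudes must be >= 0")

    @property
    def has_bias(self) -> bool:
        return self.mode in ("biased", "biased_and_fluctuating")

    @property
    def has_fluctuation(self) -> bool:
        return self.mode in ("fluctuating", "biased_and_fluctuating")


def corrupt_ppv(ppv_true: float, noise: NoiseSpec, rng, bias: float | None = None) -> float:
    """One corrupted PPV reading.

    ``bias`` is the per-trial constant offset; if the mode is biased and no
    bias is supplied, one is drawn from the rng (callers wanting trial
    persistence should draw it once — see :class:`PPVSensor`).  Fluctuation
    is a fresh uniform draw per reading.  The result is clamped at 0.
    """
    if ppv_true < 0:
        raise ValueError("ppv_true must be >= 0")
    reported = ppv_true
    if noise.has_bias:
        if bias is None:
            bias = float(rng.uniform(-noise.bias_amplitude, noise.bias_amplitude))
        reported += bias
    if noise.has_fluctuation:
        reported += float(rng.uniform(-noise.fluctuation_amplitude,
                                      noise.fluctuation_amplitude))
    return max(0.0, reported)


class PPVSensor:
    """Per-trial PPV sensor: draws its bias once, fluctuates per reading."""

    def __init__(self, noise: NoiseSpec, rng) -> None:
        self.noise = noise
        self.rng = rng
        self.bias = (float(rng.uniform(-noise.bias_amplitude, noise.bias_amplitude))
                     if noise.has_bias else 0.0)

    def read(self, ppv_true: float) -> float:
        return corrupt_ppv(ppv_true, self.noise, self.rng, bias=self.bias)


@dataclass
class TrialResult:
    """Full trace and event log of one simulated trial."""

    spec: ScenarioSpec
    noise: NoiseSpec
    seed: int
    params: PatientParams
    baseline: PatientState
    timeseries: pd.DataFrame
    events: pd.DataFrame
    total_fluid_window: float  # ml of crystalloid inside the accounting window
    sensor_bias: float


BUILTIN_SCENARIOS = {
    # stability testing: bleed starts at 30 min, 2.5-h scenario
    "phase1_mild": dict(duration=150.0, hemorrhage_start=30.0,
                        hemorrhage_volume=500.0, hemorrhage_duration=90.0,
                        ranges=hm.PHASE1_RANGES),
    "phase1_moderate": dict(duration=150.0, hemorrhage_start=30.0,
                            hemorrhage_volume=1500.0, hemorrhage_duration=90.0,
                            ranges=hm.PHASE1_RANGES),
    "phase1_massive": dict(duration=150.0, hemorrhage_start=30.0,
                           hemorrhage_volume=2000.0, hemorrhage_duration=20.0,
                           ranges=hm.PHASE1_RANGES),
    # management comparison: 1-h case, bleed at 15 min
    "phase2_massive": dict(duration=60.0, hemorrhage_start=15.0,
                           hemorrhage_volume=2000.0, hemorrhage_duration=20.0,
                           ranges=hm.PHASE23_RANGES),
    # noise tolerance: 2-h, 1,000-ml loss, bleed at 30 min (slower and longer
    # than the massive scenario: 33 ml/min over 30 min)
    "phase3_slow": dict(duration=120.0, hemorrhage_start=30.0,
                        hemorrhage_volume=1000.0, hemorrhage_duration=30.0,
                        ranges=hm.PHASE23_RANGES),
}


def builtin_scenario(name: str, management: str = "none", n_trials: int = 20,
                     seed: int = 0) -> ScenarioSpec:
    """One of the named study scenarios with its printed timeline."""
    try:
        d = BUILTIN_SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; valid names: {sorted(BUILTIN_SCENARIOS)}"
        ) from None
    return ScenarioSpec(
        name=name,
        duration=d["duration"],
        hemorrhage_start=d["hemorrhage_start"],
        hemorrhage_volume=d["hemorrhage_volume"],
        hemorrhage_duration=d["hemorrhage_duration"],
        baseline_ranges=dict(d["ranges"]),
        management=management,
        n_trials=n_trials,
        seed=seed,
    )


def run_trial(spec: ScenarioSpec, noise: NoiseSpec | None = None,
              controller_config: ControllerConfig | None = None,
              seed: int = 0, model: ResponseModel | None = None,
              dose_schedule: list | None = None) -> TrialResult:
    """Run one trial: sample a patient, simulate, optionally close the loop.

    The simulator advances at a fixed 5-s step; the sensor is sampled and the
    controller polled every 30 s.  Maintenance crystalloid runs throughout;
    hemorrhage is constant-rate inside its window.

    ``dose_schedule`` (list of :class:`~lirsim.hemodynamic_model.DoseEvent`)
    is the stub for manual play: pre-scripted vasoactive/opioid boluses are
    applied at their scheduled times regardless of the management mode.
    """
    noise = noise or NoiseSpec()
    ss = np.random.SeedSequence(seed)
    rng_patient, rng_sensor = (np.random.default_rng(c) for c in ss.spawn(2))

    params = hm.sample_patient(spec.baseline_ranges, rng_patient)
    state = hm.baseline_state(params)
    sensor = PPVSensor(noise, rng_sensor)

    controller = None
    if spec.management == "closed_loop":
        controller = LIRController(config=controller_config,
                                   model=model or default_response_model(),
                                   poll_interval=SAMPLE_INTERVAL_MIN)

    maint = spec.maintenance_rate / 60.0  # ml/min
    h_start = spec.hemorrhage_start
    h_end = spec.hemorrhage_start + spec.hemorrhage_duration
    h_rate = spec.hemorrhage_rate
    window_end = min(h_start + FLUID_WINDOW_MIN, spec.duration)

    n_steps = int(round(spec.duration / SIM_DT_MIN))
    steps_per_sample = int(round(SAMPLE_INTERVAL_MIN / SIM_DT_MIN))

    rows = []
    total_fluid_window = 0.0
    reported_ppv = sensor.read(state.ppv_true)

    def record(state: PatientState, reported: float, cry_rate: float, hem_rate: float) -> None:
        rows.append((state.t, state.hr, state.sbp, state.dbp, state.map,
                     state.co, state.ppv_true, reported, cry_rate, hem_rate,
                     state.intravascular_volume, state.cumulative_hemorrhage,
                     state.cumulative_infused_crystalloid))

    if controller is not None:
        controller.observe(0.0, reported_ppv, state.co, state.map, state.hr)
    record(state, reported_ppv, maint, 0.0)

    baseline = state.copy()

    doses = sorted(dose_schedule or [], key=lambda d: d.t)
    for i in range(n_steps):
        t = i * SIM_DT_MIN
        hem = h_rate if (h_start - 1e-9 <= t < h_end - 1e-9) else 0.0
        cry = maint
        if controller is not None:
            cry += controller.infusion_rate(SIM_DT_MIN)
        if h_start - 1e-9 <= t < window_end - 1e-9:
            total_fluid_window += cry * SIM_DT_MIN
        due = [d for d in doses if t <= d.t < t + SIM_DT_MIN]
        state = hm.step(state, params,
                        {"hemorrhage_rate": hem, "crystalloid_rate": cry,
                         "dose_events": due}, SIM_DT_MIN)
        if (i + 1) % steps_per_sample == 0:
            reported_ppv = sensor.read(state.ppv_true)
            if controller is not None:
                controller.observe(state.t, reported_ppv, state.co, state.map, state.hr)
            record(state, reported_ppv, cry, hem)

    timeseries = pd.DataFrame(rows, columns=[
        "t", "hr", "sbp", "dbp", "map", "co", "ppv_true", "ppv_reported",
        "crystalloid_rate", "hemorrhage_rate", "intravascular_volume",
        "cumulative_hemorrhage", "cumulative_infused_crystalloid"])
    events = (controller.events_frame() if controller is not None
              else pd.DataFrame(columns=["t", "action"]))
    return TrialResult(
        spec=spec, noise=noise, seed=seed, params=params, baseline=baseline,
        timeseries=timeseries, events=events,
        total_fluid_window=total_fluid_window, sensor_bias=sensor.bias,
    )


def run_batch(spec: ScenarioSpec, noise: NoiseSpec | None = None,
              controller_config: ControllerConfig | None = None,
              n: int | None = None, master_seed: int = 0,
              model: ResponseModel | None = None) -> list[TrialResult]:
    """Run ``n`` independent trials with deterministic child seeds."""
    n = n if n is not None else spec.n_trials
    if n < 1:
        raise ValueError("n must be >= 1")
    children = np.random.SeedSequence(master_seed).spawn(n)
    shared_model = model or (default_response_model()
                             if spec.management == "closed_loop" else None)
    results = []
    for child in children:
        child_seed = int(child.generate_state(1, dtype=np.uint32)[0]) % (2 ** 31)
        results.append(run_trial(spec, noise, controller_config,
                                 seed=child_seed, model=shared_model))
    return results
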