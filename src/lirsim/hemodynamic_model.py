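"""Beat-averaged discrete-time hemodynamic patient model.

The simulated patient is a lumped circulatory model driven by the effective
intravascular volume deficit.  Stroke volume follows a saturating
Frank-Starling curve of preload, a baroreflex raises heart rate and vascular
tone as volume is lost, pressures are recomputed from cardiac output times
resistance, and pulse-pressure variation (PPV) is computed analytically from
the deficit fraction (no per-beat waveform is synthesized).  Crystalloid
follows two-pool kinetics: it enters the plasma instantly and redistributes
exponentially to the interstitium down to a steady-state retention fraction;
colloid stays intravascular on scenario timescales.

All responses are deterministic functions of the state, so trajectories are
bit-identical under a fixed seed and scenario.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "PatientParams",
    "PatientState",
    "DoseEvent",
    "ModelGains",
    "sample_patient",
    "baseline_state",
    "ppv_from_deficit",
    "step",
    "apply_drug",
    "PHASE1_RANGES",
    "PHASE23_RANGES",
]

# ---------------------------------------------------------------------------
# Frozen model constants
# ---------------------------------------------------------------------------

BLOOD_VOLUME_ML_PER_KG = 70.0
PPV_BASELINE_PCT = 6.0  # normovolemic patients sit below the 9-13% gray zone

#: PPV rises with the deficit fraction along a baseline-normalized logistic
#: with ceiling ``PPV_MAX``.  The slope and midpoint were solved once through
#: the calibration anchors (600 ml deficit -> 10%, 700 ml -> 15% for the
#: default 75-kg, 5,250-ml patient) and are stored as constants.
PPV_MAX = 25.0
PPV_MIDPOINT = 0.134947  # deficit fraction at the logistic midpoint
PPV_SLOPE = 0.015616

#: Frank-Starling stroke-volume multiplier: normalized falling logistic in the
#: deficit fraction (1.0 at euvolemia), plus a nearly-flat plateau bonus for
#: volume overload (Starling saturation: < 2% CO gain per 500 ml past
#: euvolemia).
SV_MIDPOINT = 0.26
SV_WIDTH = 0.05
OVERLOAD_GAIN = 0.02
OVERLOAD_WIDTH = 0.10

#: Baroreflex heart-rate multiplier: normalized rising logistic in the deficit
#: fraction.  Gain and shape were pinned to the unmanaged endpoint anchors
#: (mild / moderate / massive hemorrhage) and the 10%-rise detection time.
HR_GAIN = 1.15
HR_MIDPOINT = 0.27
HR_WIDTH = 0.04
#: Fraction of the baroreflex drive expressed as vasoconstriction.
SVR_GAIN = 0.30

HR_FLOOR, HR_CEIL = 30.0, 180.0
SV_FLOOR = 5.0

CRYSTALLOID_RETENTION = 0.45  # steady-state intravascular fraction
REDISTRIBUTION_HALF_LIFE_MIN = 25.0

_LN2 = math.log(2.0)


def _sigmoid(x: float) -> float:
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    z = math.exp(x)
    return z / (1.0 + z)


# logistic values at zero deficit, used to normalize each curve to exactly 1
# (resp. the PPV baseline) at euvolemia so the baseline state is a fixed point
_PPV_S0 = _sigmoid(-PPV_MIDPOINT / PPV_SLOPE)
_SV_NUM = 1.0 + math.exp(-SV_MIDPOINT / SV_WIDTH)
_HR_S0 = _sigmoid(-HR_MIDPOINT / HR_WIDTH)


# ---------------------------------------------------------------------------
# Drug pharmacodynamics (only used for optional manual play)
# ---------------------------------------------------------------------------

#: drug -> (half-life min, HR offset bpm, HR half-saturation, SVR gain,
#:          SVR half-saturation, inotropy gain, inotropy half-saturation)
#: Effects use soft saturation level/(level + half_sat) so stacked doses add
#: sub-linearly and can never drive HR or SV negative.
DRUG_TABLE = {
    # one 100-ug dose raises MAP ~8-12 mm Hg in moderate shock
    "phenylephrine": dict(half_life=8.0, hr=-6.0, hr_k=100.0, svr=0.25, svr_k=100.0, ino=0.0, ino_k=1.0),
    "ephedrine": dict(half_life=20.0, hr=15.0, hr_k=10.0, svr=0.05, svr_k=10.0, ino=0.15, ino_k=10.0),
    "epinephrine": dict(half_life=5.0, hr=20.0, hr_k=50.0, svr=0.10, svr_k=50.0, ino=0.20, ino_k=50.0),
    "fentanyl": dict(half_life=30.0, hr=-8.0, hr_k=100.0, svr=0.0, svr_k=1.0, ino=0.0, ino_k=1.0),
}


# ---------------------------------------------------------------------------
# Baseline randomization ranges (per study phase)
# ---------------------------------------------------------------------------

PHASE1_RANGES = {
    "weight": (60.0, 100.0),   # kg
    "height": (62.0, 72.0),    # inches
    "hr_base": (55.0, 85.0),   # beats/min
    "sbp_base": (105.0, 145.0),
    "dbp_base": (60.0, 90.0),  # mm Hg
    "lvedv_base": (130.0, 150.0),
    "lvesv_base": (42.0, 58.0),  # ml
}

#: Narrowed ranges used for the management-comparison and noise phases.
PHASE23_RANGES = {
    "weight": (70.0, 85.0),
    "height": (65.0, 68.0),
    "hr_base": (65.0, 75.0),
    "sbp_base": (110.0, 130.0),
    "dbp_base": (70.0, 80.0),
    "lvedv_base": (130.0, 150.0),
    "lvesv_base": (42.0, 58.0),
}


@dataclass(frozen=True)
class ModelGains:
    """Named physiological gain constants carried by each patient."""

    baroreflex_gain: float = HR_GAIN
    starling_curvature: float = SV_WIDTH
    svr_gain: float = SVR_GAIN
    crystalloid_retention: float = CRYSTALLOID_RETENTION
    redistribution_half_life: float = REDISTRIBUTION_HALF_LIFE_MIN


@dataclass(frozen=True)
class PatientParams:
    """Static randomized baseline traits of one simulated patient."""

    weight: float          # kg
    height: float          # inches
    hr_base: float         # beats/min
    sbp_base: float        # mm Hg
    dbp_base: float        # mm Hg
    lvedv_base: float      # ml
    lvesv_base: float      # ml
    blood_volume_base: float  # ml, 70 ml/kg
    ppv_base: float = PPV_BASELINE_PCT  # percent
    gains: ModelGains = field(default_factory=ModelGains)

    def __post_init__(self) -> None:
        if self.lvedv_base <= self.lvesv_base:
            raise ValueError("lvedv_base must exceed lvesv_base")
        if self.sbp_base <= self.dbp_base:
            raise ValueError("sbp_base must exceed dbp_base")
        if self.blood_volume_base <= 0:
            raise ValueError("blood_volume_base must be positive")

    @property
    def sv_base(self) -> float:
        return self.lvedv_base - self.lvesv_base

    @property
    def co_base(self) -> float:
        return self.hr_base * self.sv_base / 1000.0

    @property
    def map_base(self) -> float:
        return self.dbp_base + (self.sbp_base - self.dbp_base) / 3.0

    @property
    def pp_base(self) -> float:
        return self.sbp_base - self.dbp_base


@dataclass
class PatientState:
    """Evolving physiological state of one simulated patient."""

    t: float  # minutes
    intravascular_volume: float  # ml
    interstitial_excess: float  # ml of infused crystalloid lost to interstitium
    cumulative_hemorrhage: float  # ml
    cumulative_infused_crystalloid: float  # ml
    cumulative_infused_colloid: float  # ml
    hr: float      # beats/min
    sv: float      # ml
    co: float      # L/min
    sbp: float     # mm Hg
    dbp: float     # mm Hg
    map: float     # mm Hg
    ppv_true: float  # percent
    drug_effects: dict = field(default_factory=dict)  # drug -> effect level

    def copy(self) -> "PatientState":
        return replace(self, drug_effects=dict(self.drug_effects))


@dataclass(frozen=True)
class DoseEvent:
    """A vasoactive / opioid bolus (mg for ephedrine, ug otherwise)."""

    drug: str
    dose: float
    t: float  # minutes

    def __post_init__(self) -> None:
        if self.drug not in DRUG_TABLE:
            raise ValueError(
                f"unknown drug {self.drug!r}; allowed: {sorted(DRUG_TABLE)}"
            )
        if self.dose < 0:
            raise ValueError("dose must be non-negative")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def sample_patient(ranges: dict, rng) -> PatientParams:
    """Draw a patient uniformly and independently from per-field ranges.

    Parameters
    ----------
    ranges : dict
        Field name -> (min, max) for the seven randomized traits (see
        ``PHASE1_RANGES``).
    rng : numpy.random.Generator
        Seeded random stream.
    """
    values = {}
    for name, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"reversed range for field {name!r}: {lo} > {hi}")
        values[name] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    weight = values["weight"]
    return PatientParams(
        weight=weight,
        height=values["height"],
        hr_base=values["hr_base"],
        sbp_base=values["sbp_base"],
        dbp_base=values["dbp_base"],
        lvedv_base=values["lvedv_base"],
        lvesv_base=values["lvesv_base"],
        blood_volume_base=weight * BLOOD_VOLUME_ML_PER_KG,
    )


def baseline_state(params: PatientParams) -> PatientState:
    """Initial euvolemic state at t = 0 with all cumulative ledgers zero."""
    sv = params.sv_base
    co = params.hr_base * sv / 1000.0
    return PatientState(
        t=0.0,
        intravascular_volume=params.blood_volume_base,
        interstitial_excess=0.0,
        cumulative_hemorrhage=0.0,
        cumulative_infused_crystalloid=0.0,
        cumulative_infused_colloid=0.0,
        hr=params.hr_base,
        sv=sv,
        co=co,
        sbp=params.sbp_base,
        dbp=params.dbp_base,
        map=params.map_base,
        ppv_true=params.ppv_base,
        drug_effects={},
    )


def ppv_from_deficit(deficit_fraction: float, params: PatientParams) -> float:
    """Analytic PPV (%) as a monotone function of the deficit fraction.

    ``deficit_fraction`` is the effective intravascular deficit divided by the
    baseline blood volume; it is clamped into [0, 1].  Returns ``ppv_base``
    exactly at zero deficit and saturates at ``PPV_MAX``.
    """
    f = min(max(deficit_fraction, 0.0), 1.0)
    s = _sigmoid((f - PPV_MIDPOINT) / PPV_SLOPE)
    frac = (s - _PPV_S0) / (1.0 - _PPV_S0)
    return params.ppv_base + (PPV_MAX - params.ppv_base) * frac


def _sv_multiplier(f: float, o: float, gains: ModelGains) -> float:
    """Starling multiplier: falling logistic in deficit, flat overload bonus."""
    base = _SV_NUM / (1.0 + math.exp((f - SV_MIDPOINT) / gains.starling_curvature))
    bonus = 1.0 + OVERLOAD_GAIN * (1.0 - math.exp(-o / OVERLOAD_WIDTH))
    return base * bonus


def _baroreflex_drive(f: float, gains: ModelGains) -> float:
    """Normalized baroreflex activation in [0, 1); 0 at euvolemia."""
    return (_sigmoid((f - HR_MIDPOINT) / HR_WIDTH) - _HR_S0) / (1.0 - _HR_S0)


def _drug_modifiers(levels: dict) -> tuple:
    """(hr offset bpm, SVR multiplier, inotropy multiplier) from effect levels."""
    hr_off, svr_mult, ino = 0.0, 1.0, 1.0
    for drug, level in levels.items():
        if level <= 0.0:
            continue
        d = DRUG_TABLE[drug]
        hr_off += d["hr"] * level / (level + d["hr_k"])
        svr_mult *= 1.0 + d["svr"] * level / (level + d["svr_k"])
        ino *= 1.0 + d["ino"] * level / (level + d["ino_k"])
    return hr_off, svr_mult, ino


def _recompute_outputs(state: PatientState, params: PatientParams) -> None:
    """Fill HR/SV/CO/pressures/PPV from the current volume state in place."""
    g = params.gains
    bv = params.blood_volume_base
    v = state.intravascular_volume
    f = max(0.0, (bv - v) / bv)
    o = max(0.0, v / bv - 1.0)

    hr_off, svr_drug, ino = _drug_modifiers(state.drug_effects)
    drive = _baroreflex_drive(f, g)

    sv = max(SV_FLOOR, params.sv_base * _sv_multiplier(f, o, g) * ino)
    hr = min(HR_CEIL, max(HR_FLOOR, params.hr_base * (1.0 + g.baroreflex_gain * drive) + hr_off))
    co = hr * sv / 1000.0

    svr_base = params.map_base / params.co_base  # mm Hg per L/min
    map_ = co * svr_base * (1.0 + g.svr_gain * g.baroreflex_gain * drive) * svr_drug
    pp = params.pp_base * sv / params.sv_base
    state.hr = hr
    state.sv = sv
    state.co = co
    state.map = map_
    state.sbp = map_ + 2.0 * pp / 3.0
    state.dbp = map_ - pp / 3.0
    state.ppv_true = ppv_from_deficit(f, params)


def step(state: PatientState, params: PatientParams, inputs: dict, dt: float) -> PatientState:
    """Advance the patient one fixed step of ``dt`` minutes.

    ``inputs`` may contain ``hemorrhage_rate``, ``crystalloid_rate``,
    ``colloid_rate`` (ml/min, all >= 0) and ``dose_events`` (list of
    :class:`DoseEvent` applied during this step).
    """
    if not (0.0 < dt <= 0.5):
        raise ValueError("dt must be in (0, 0.5] minutes")
    h_rate = float(inputs.get("hemorrhage_rate", 0.0))
    c_rate = float(inputs.get("crystalloid_rate", 0.0))
    col_rate = float(inputs.get("colloid_rate", 0.0))
    for name, r in (("hemorrhage_rate", h_rate), ("crystalloid_rate", c_rate),
                    ("colloid_rate", col_rate)):
        if r < 0:
            raise ValueError(f"{name} must be non-negative")

    g = params.gains
    new = state.copy()
    new.t = state.t + dt
    new.cumulative_hemorrhage += h_rate * dt
    new.cumulative_infused_crystalloid += c_rate * dt
    new.cumulative_infused_colloid += col_rate * dt

    # two-pool crystalloid kinetics: plasma crystalloid X relaxes toward the
    # steady-state retained fraction of everything infused so far
    x = (state.cumulative_infused_crystalloid - state.interstitial_excess) + c_rate * dt
    target = g.crystalloid_retention * new.cumulative_infused_crystalloid
    decay = math.exp(-_LN2 * dt / g.redistribution_half_life)
    x = target + (x - target) * decay
    new.interstitial_excess = new.cumulative_infused_crystalloid - x

    new.intravascular_volume = (
        params.blood_volume_base
        - new.cumulative_hemorrhage
        + x
        + new.cumulative_infused_colloid
    )

    # exponential decay of drug effect levels, then any new doses this step
    for drug in list(new.drug_effects):
        d = DRUG_TABLE[drug]
        new.drug_effects[drug] *= math.exp(-_LN2 * dt / d["half_life"])
    for event in inputs.get("dose_events", ()):
        _add_dose(new, event)

    _recompute_outputs(new, params)
    return new


def _add_dose(state: PatientState, event: DoseEvent) -> None:
    if event.dose == 0:
        return
    state.drug_effects[event.drug] = state.drug_effects.get(event.drug, 0.0) + event.dose


def apply_drug(state: PatientState, params: PatientParams, event: DoseEvent) -> PatientState:
    """Return the state with a drug bolus added (effects decay in ``step``)."""
    new = state.copy()
    _add_dose(new, event)
    _recompute_outputs(new, params)
    return new


def ledger_residual(state: PatientState, params: PatientParams) -> float:
    """Volume-conservation residual (ml); closes to < 0.1 ml at every step.

    Baseline blood volume minus hemorrhage plus everything infused must equal
    intravascular volume plus the crystalloid lost to the interstitium.
    """
    lhs = (
        params.blood_volume_base
        - state.cumulative_hemorrhage
        + state.cumulative_infused_crystalloid
        + state.cumulative_infused_colloid
    )
    rhs = state.intravascular_volume + state.interstitial_excess
    return lhs - rhs
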