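"""Per-trial endpoint metrics, group summaries, and machine-readable reports.

Endpoints mirror the usual resuscitation-study tables: fluid totals,
detection/intervention times (reported on two clocks: from hemorrhage onset
and from simulation start), mean/minimum/final cardiac output and pressure,
and the within-trial CO coefficient of variation (population SD / mean, %).
Two-group comparisons use the Mann-Whitney U test; multi-group comparisons
use one-way ANOVA with Tukey HSD post hoc, at the 0.05 level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .hemodynamic_model import PatientState
from .scenario_engine import TrialResult

__all__ = [
    "TrialMetrics",
    "GroupSummary",
    "summarize_trial",
    "summarize_group",
    "compare_groups",
    "compare_many_groups",
    "write_report",
    "read_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class TrialMetrics:
    """Endpoint metrics of a single trial (NaN where an event never occurs)."""

    total_fluid: float                 # ml inside the accounting window
    time_to_first_bolus: float         # min from hemorrhage onset
    time_to_first_bolus_from_start: float  # min from simulation start
    mean_co: float
    min_co: float
    final_co: float                    # L/min
    mean_map: float
    final_map: float                   # mm Hg
    final_hr: float                    # beats/min
    co_cov: float                      # percent
    time_to_co_drop_10pct: float       # min from hemorrhage onset
    time_to_map_drop_10pct: float
    time_to_hr_rise_10pct: float
    time_to_ppv_10: float
    time_to_ppv_15: float

    def as_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroupSummary:
    """Across-trial mean +/- SD per metric for one group."""

    name: str
    n: int
    means: dict
    sds: dict
    comparisons: list = field(default_factory=list)


def _first_crossing(t: np.ndarray, y: np.ndarray, threshold: float,
                    direction: str, t0: float) -> float:
    """Time (relative to ``t0``) of the first threshold crossing at/after t0.

    Linear interpolation between samples; NaN when the threshold is never
    crossed.  ``direction`` is 'up' or 'down'.
    """
    mask = t >= t0 - 1e-9
    t, y = t[mask], y[mask]
    if direction == "down":
        y = -y
        threshold = -threshold
    hit = np.nonzero(y >= threshold - 1e-12)[0]
    if hit.size == 0:
        return float("nan")
    i = int(hit[0])
    if i == 0:
        return float(t[0] - t0)
    frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]) - t0)


def summarize_trial(result: TrialResult, baseline: PatientState | None = None) -> TrialMetrics:
    """Compute the endpoint metrics of one trial trace."""
    ts = result.timeseries
    if ts.empty:
        raise ValueError("trial has an empty trace")
    baseline = baseline or result.baseline
    t = ts["t"].to_numpy()
    co = ts["co"].to_numpy()
    map_ = ts["map"].to_numpy()
    hr = ts["hr"].to_numpy()
    ppv = ts["ppv_true"].to_numpy()
    onset = result.spec.hemorrhage_start

    mean_co = float(co.mean())
    co_cov = 100.0 * float(co.std(ddof=0)) / mean_co if mean_co else float("nan")

    starts = result.events[result.events["action"].isin(
        ["start_bolus", "start_test_bolus"])] if not result.events.empty else result.events
    if starts is not None and len(starts):
        t_first = float(starts["t"].iloc[0])
        ttb_start = t_first
        ttb_onset = t_first - onset
    else:
        ttb_start = ttb_onset = float("nan")

    return TrialMetrics(
        total_fluid=result.total_fluid_window,
        time_to_first_bolus=ttb_onset,
        time_to_first_bolus_from_start=ttb_start,
        mean_co=mean_co,
        min_co=float(co.min()),
        final_co=float(co[-1]),
        mean_map=float(map_.mean()),
        final_map=float(map_[-1]),
        final_hr=float(hr[-1]),
        co_cov=co_cov,
        time_to_co_drop_10pct=_first_crossing(t, co, 0.9 * baseline.co, "down", onset),
        time_to_map_drop_10pct=_first_crossing(t, map_, 0.9 * baseline.map, "down", onset),
        time_to_hr_rise_10pct=_first_crossing(t, hr, 1.1 * baseline.hr, "up", onset),
        time_to_ppv_10=_first_crossing(t, ppv, 10.0, "up", onset),
        time_to_ppv_15=_first_crossing(t, ppv, 15.0, "up", onset),
    )


def _metric_frame(metrics: list[TrialMetrics]) -> pd.DataFrame:
    return pd.DataFrame([m.as_dict() for m in metrics])


def summarize_group(metrics: list[TrialMetrics], name: str = "group") -> GroupSummary:
    """Across-trial mean +/- sample SD per metric (NaNs excluded per metric)."""
    if len(metrics) < 2:
        raise ValueError("a group needs at least 2 trials (SD undefined)")
    df = _metric_frame(metrics)
    means = {k: float(v) for k, v in df.mean(skipna=True).items()}
    sds = {k: float(v) for k, v in df.std(ddof=1, skipna=True).items()}
    return GroupSummary(name=name, n=len(metrics), means=means, sds=sds)


def compare_groups(a: list[TrialMetrics], b: list[TrialMetrics],
                   metrics: list[str] | None = None) -> list[dict]:
    """Two-group Mann-Whitney U comparison per metric."""
    fa, fb = _metric_frame(a), _metric_frame(b)
    if set(fa.columns) != set(fb.columns):
        raise ValueError("mismatched metric sets")
    out = []
    for m in metrics or fa.columns:
        x = fa[m].dropna().to_numpy()
        y = fb[m].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            continue
        if np.ptp(np.concatenate([x, y])) == 0:
            stat, p = float("nan"), 1.0  # all values identical
        else:
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        out.append({"metric": m, "test": "mann-whitney", "statistic": float(stat),
                    "p_value": float(p), "significant": bool(p < ALPHA)})
    return out


def compare_many_groups(groups: dict, metrics: list[str] | None = None) -> list[dict]:
    """One-way ANOVA across groups with Tukey HSD post hoc where significant."""
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    frames = {name: _metric_frame(ms) for name, ms in groups.items()}
    cols = next(iter(frames.values())).columns
    out = []
    for m in metrics or cols:
        samples = {name: f[m].dropna().to_numpy() for name, f in frames.items()}
        samples = {k: v for k, v in samples.items() if len(v) >= 2}
        if len(samples) < 2:
            continue
        values = list(samples.values())
        if np.ptp(np.concatenate(values)) == 0:
            out.append({"metric": m, "test": "anova", "statistic": float("nan"),
                        "p_value": 1.0, "significant": False, "tukey": []})
            continue
        stat, p = stats.f_oneway(*values)
        entry = {"metric": m, "test": "anova", "statistic": float(stat),
                 "p_value": float(p), "significant": bool(p < ALPHA), "tukey": []}
        if p < ALPHA:
            data = np.concatenate(values)
            labels = np.concatenate([[k] * len(v) for k, v in samples.items()])
            tk = pairwise_tukeyhsd(data, labels, alpha=ALPHA)
            from itertools import combinations

            pairs = list(combinations(tk.groupsunique, 2))
            entry["tukey"] = [
                {"group1": str(g1), "group2": str(g2), "p_adj": float(pa),
                 "significant": bool(rej)}
                for (g1, g2), pa, rej in zip(pairs, tk.pvalues, tk.reject)
            ]
        out.append(entry)
    return out


def write_report(summaries: list[GroupSummary], path,
                 comparisons: list[dict] | None = None) -> dict:
    """Write a JSON summary and a CSV long table; returns the written paths.

    Output is bit-identical for identical inputs (sorted keys, fixed column
    order).
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = {
        "groups": [
            {"name": s.name, "n": s.n, "means": s.means, "sds": s.sds,
             "comparisons": s.comparisons}
            for s in summaries
        ],
        "comparisons": comparisons or [],
    }
    json_path = path / "summary.json"
    try:
        with open(json_path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, allow_nan=True)
        rows = []
        for s in summaries:
            for metric in sorted(s.means):
                rows.append({"group": s.name, "metric": metric, "n": s.n,
                             "mean": s.means[metric], "sd": s.sds[metric]})
        csv_path = path / "summary.csv"
        pd.DataFrame(rows, columns=["group", "metric", "n", "mean", "sd"]).to_csv(
            csv_path, index=False)
    except OSError as exc:
        raise OSError(f"failed writing report under {path}: {exc}") from exc
    return {"json": json_path, "csv": csv_path}


def read_report(path) -> dict:
    """Parse a written JSON report back into its dict structure."""
    with open(Path(path) / "summary.json") as fh:
        return json.load(fh)


def plot_trial(result: TrialResult, path=None):
    """Convenience per-trial CO / MAP line plot (matplotlib required)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ts = result.timeseries
    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(7, 5))
    ax1.plot(ts["t"], ts["co"], lw=1.2)
    ax1.set_ylabel("CO (L/min)")
    ax2.plot(ts["t"], ts["map"], lw=1.2, color="tab:red")
    ax2.set_ylabel("MAP (mm Hg)")
    ax2.set_xlabel("time (min)")
    fig.suptitle(result.spec.name)
    if path is not None:
        fig.savefig(path, dpi=110)
        plt.close(fig)
    return fig
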