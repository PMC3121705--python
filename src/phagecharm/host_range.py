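"""Microplate host-range phenotyping and one-step growth parameters.

Detection time is the time a well's optical density first rises a fixed
increment (default 0.3 OD) above its baseline. The difference between a
phage-challenged well's detection time and its uninfected control's sorts
strains into four reaction categories:

* ``N`` — no delay (growth like the control),
* ``D`` — detection delayed by less than 5 h,
* ``D+`` — detection delayed by 5 h or more (closed boundary: 5.0 h is D+),
* ``C`` — complete inhibition: no detection within the run (24 h).

One-step growth curves (titer vs time after synchronized infection) yield the
latent period, rise period and burst size by change-point detection on the
log-titer slope, mirroring how the parameters are read off the plotted curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

DELTA_OD_DEFAULT = 0.3
BASELINE_READINGS = 3
N_BAND_HOURS = 0.5
DPLUS_HOURS = 5.0


@dataclass
class GrowthCurve:
    times: list[float]  # hours, strictly increasing
    od: list[float]
    well_id: str = ""
    strain_id: str = ""
    treatment: str = "phage"  # phage | control | blank

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")


@dataclass
class ReactionCall:
    strain_id: str
    dt_control: float
    dt_test: Optional[float]
    dt_diff: Optional[float]
    category: str  # N | D | D+ | C


def detection_time(curve: GrowthCurve, delta_od: float = DELTA_OD_DEFAULT,
                   baseline_readings: int = BASELINE_READINGS) -> Optional[float]:
    """First time the OD reaches baseline + delta_od, linearly interpolated.

    The baseline is the minimum of the first ``baseline_readings`` readings.
    Returns None when the threshold is never reached within the series.
    Adding a constant to every OD reading leaves the result unchanged.
    """
    if len(curve.od) < 2:
        raise ValueError("need at least 2 readings")
    baseline = min(curve.od[:baseline_readings])
    threshold = baseline + delta_od
    for i, od in enumerate(curve.od):
        if od >= threshold:
            if i == 0:
                return curve.times[0]
            t0, t1 = curve.times[i - 1], curve.times[i]
            y0, y1 = curve.od[i - 1], curve.od[i]
            return t0 + (t1 - t0) * (threshold - y0) / (y1 - y0)
    return None


def _mean_detection(curves: Sequence[GrowthCurve], delta_od: float) -> Optional[float]:
    """Mean detection time over replicates; None if no replicate detects."""
    dts = [detection_time(c, delta_od) for c in curves]
    dts = [d for d in dts if d is not None]
    return sum(dts) / len(dts) if dts else None


def classify_reaction(test: Union[GrowthCurve, Sequence[GrowthCurve]],
                      control: Union[GrowthCurve, Sequence[GrowthCurve]],
                      delta_od: float = DELTA_OD_DEFAULT,
                      dplus_hours: float = DPLUS_HOURS,
                      n_band_hours: float = N_BAND_HOURS) -> ReactionCall:
    """Classify a strain's reaction to phage challenge.

    Replicate curves are accepted for both arms; detection times are averaged
    per arm before differencing. A control that never detects makes the assay
    uninterpretable and raises. dt_diff within +/- ``n_band_hours`` (and any
    negative excess) is N; the D+ boundary at ``dplus_hours`` is closed
    (a 5.0 h delay is D+).
    """
    tests = [test] if isinstance(test, GrowthCurve) else list(test)
    controls = [control] if isinstance(control, GrowthCurve) else list(control)
    strain = tests[0].strain_id or controls[0].strain_id
    dt_c = _mean_detection(controls, delta_od)
    if dt_c is None:
        raise ValueError(f"control for strain {strain!r} never reached detection")
    dt_t = _mean_detection(tests, delta_od)
    if dt_t is None:
        return ReactionCall(strain, dt_c, None, None, "C")
    diff = dt_t - dt_c
    if diff >= dplus_hours:
        cat = "D+"
    elif diff > n_band_hours:
        cat = "D"
    else:
        cat = "N"
    return ReactionCall(strain, dt_c, dt_t, diff, cat)


def summarize_host_range(calls: Sequence[Union[ReactionCall, str]]) -> dict[str, int]:
    """Count reaction categories; accepts calls or bare category codes."""
    counts = {"N": 0, "D": 0, "D+": 0, "C": 0}
    for c in calls:
        cat = c if isinstance(c, str) else c.category
        if cat not in counts:
            raise ValueError(f"unknown reaction category {cat!r}")
        counts[cat] += 1
    counts["total"] = len(calls)
    return counts


# ---------------------------------------------------------------------------
# Plate table handling
# ---------------------------------------------------------------------------

def read_plate_csv(path) -> list[GrowthCurve]:
    """Read a plate CSV with columns time_h, well, od, strain, treatment[, replicate]."""
    df = pd.read_csv(path)
    required = {"time_h", "well", "od", "strain", "treatment"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    curves = []
    for well, sub in df.groupby("well", sort=False):
        sub = sub.sort_values("time_h")
        curves.append(GrowthCurve(
            times=sub["time_h"].tolist(), od=sub["od"].tolist(),
            well_id=str(well), strain_id=str(sub["strain"].iloc[0]),
            treatment=str(sub["treatment"].iloc[0]),
        ))
    return curves


def classify_plate(curves: Sequence[GrowthCurve],
                   delta_od: float = DELTA_OD_DEFAULT,
                   dplus_hours: float = DPLUS_HOURS,
                   n_band_hours: float = N_BAND_HOURS) -> list[ReactionCall]:
    """Group a plate's curves by strain and classify each strain."""
    by_strain: dict[str, dict[str, list[GrowthCurve]]] = {}
    for c in curves:
        if c.treatment == "blank":
            continue
        by_strain.setdefault(c.strain_id, {}).setdefault(c.treatment, []).append(c)
    calls = []
    for strain in by_strain:
        arms = by_strain[strain]
        if "phage" not in arms or "control" not in arms:
            raise ValueError(f"strain {strain!r} lacks a phage or control arm")
        calls.append(classify_reaction(arms["phage"], arms["control"],
                                       delta_od, dplus_hours, n_band_hours))
    return calls


# ---------------------------------------------------------------------------
# One-step growth
# ---------------------------------------------------------------------------

@dataclass
class OneStepResult:
    latent_min: float
    rise_min: float
    burst_size: float


def one_step_parameters(times: Sequence[float], titers: Sequence[float],
                        slope_threshold: float = 0.02) -> OneStepResult:
    """Latent period, rise period and burst size from a one-step growth curve.

    ``times`` in minutes, ``titers`` in PFU/mL (all > 0, >= 5 points). The
    curve is split into a pre-burst plateau, a rise, and a post-burst plateau
    by thresholding the slope of log10 titer between consecutive points
    (default 0.02 log units/min). The latent period is the last pre-rise time,
    the rise period runs to the first post-rise point, and the burst size is
    the ratio of the post- to pre-burst plateau means.
    """
    times = list(times)
    titers = list(titers)
    if len(times) < 5:
        raise ValueError("need at least 5 titer points")
    if any(t <= 0 for t in titers):
        raise ValueError("titers must be positive")
    logt = [math.log10(v) for v in titers]
    slopes = [(logt[i + 1] - logt[i]) / (times[i + 1] - times[i])
              for i in range(len(times) - 1)]
    rising = [s >= slope_threshold for s in slopes]
    if not any(rising):
        raise ValueError("no rise detected in titer series")
    first_rise = rising.index(True)
    last_rise = len(rising) - 1 - rising[::-1].index(True)
    latent = times[first_rise]
    rise_end = times[last_rise + 1]
    pre = [v for v in titers[: first_rise + 1]]
    post = [v for v in titers[last_rise + 1 :]]
    burst = (sum(post) / len(post)) / (sum(pre) / len(pre))
    if burst < 1:
        raise ValueError("post-burst titer below pre-burst plateau")
    return OneStepResult(latent_min=latent, rise_min=rise_end - latent,
                         burst_size=burst)
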