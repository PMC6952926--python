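"""Single-cell force spectroscopy (SCFS) retraction analysis.

A cell bound to the cantilever is pressed onto a protein-coated substrate
and pulled away; the retraction trace shows adhesive (below-baseline) force
and discrete unbinding steps.  This module computes:

* the **work of detachment** — the integral of adhesive force over pulled
  distance from the contact point to the last force interaction;
* **step detection** — positive jumps of the moving-median-smoothed force
  exceeding a noise-scaled threshold;
* **rupture/tether classification** — by the slope of the force preceding
  each step: a loaded ramp (receptor anchored to the cytoskeleton) marks a
  rupture, a near-flat plateau (membrane tether) marks a tether;
* the **rupture ratio** — ruptures over total steps, and per-cell averages
  of repeats (one value per cell for group statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from .errors import InvalidParameterError, StageError
from .forcecurve import (
    BaselineModel,
    ContactPoint,
    ForceCurve,
    ForceSegment,
    detect_contact_point,
    estimate_baseline,
)


@dataclass
class StepEvent:
    """One unbinding step on the retraction trace."""

    position_m: float  # z of the sample just before the jump
    step_force_N: float
    pre_slope_N_per_m: float = float("nan")
    label: Optional[str] = None  # 'rupture' | 'tether' after classification
    index: int = -1


@dataclass
class SCFSResult:
    work_J: float
    events: list[StepEvent]
    rupture_ratio: Optional[float]
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class SCFSConfig:
    """Tunable parameters of the retraction pipeline."""

    baseline_fraction: float = 0.15
    contact_threshold_multiplier: float = 3.0
    step_threshold_multiplier: float = 5.0
    min_step_N: Optional[float] = None
    smooth_window: int = 11
    pre_window_m: float = 100e-9
    slope_threshold_N_per_m: Optional[float] = None


def _pulled_distance(retract: ForceSegment, contact: ContactPoint) -> np.ndarray:
    """Distance pulled past the contact point (nonnegative beyond contact)."""
    return contact.z0_m - retract.z_m


def detachment_work(
    retract: ForceSegment,
    spring_constant_N_per_m: float,
    baseline: BaselineModel,
    contact: ContactPoint,
    events: Optional[Sequence[StepEvent]] = None,
) -> float:
    """Work of detachment: adhesive area under the retraction trace.

    ``W = integral of max(0, -(F - F_baseline)) ds`` by the trapezoid rule
    from the contact point to the end of the last detected event; without
    events, to the last sample where ``|F - F_baseline| > 3 sigma``.  Beyond
    that bound the integrand is zero.  Invariant under baseline offset and
    nonnegative by construction.
    """
    z = retract.z_m
    if contact.z0_m < z.min() - 1e-12:
        raise InvalidParameterError("contact point lies beyond the segment end")
    force = spring_constant_N_per_m * retract.deflection_m - baseline.force_at(z)
    s = _pulled_distance(retract, contact)
    adhesive = np.clip(-force, 0.0, None)
    if events:
        s_last = max(contact.z0_m - ev.position_m for ev in events)
        # median smoothing delays the detected step by a few samples; pad the
        # bound so the final step's area is fully covered (overshoot into the
        # flat baseline is harmless, the integrand there is ~0)
        ds = float(np.median(np.abs(np.diff(s)))) if s.size > 1 else 0.0
        s_last = s_last + 8 * ds
    else:
        beyond = np.abs(force) > 3.0 * baseline.noise_sigma_N
        past = beyond & (s > 0)
        s_last = float(s[past].max()) if past.any() else 0.0
    integrand = np.where((s >= 0) & (s <= s_last), adhesive, 0.0)
    order = np.argsort(s)
    return float(max(np.trapezoid(integrand[order], s[order]), 0.0))


def detect_steps(
    retract: ForceSegment,
    spring_constant_N_per_m: float,
    baseline: BaselineModel,
    min_step_N: Optional[float] = None,
    threshold_multiplier: float = 5.0,
    smooth_window: int = 11,
) -> list[StepEvent]:
    """Detect unbinding steps (unlabeled) on a retraction trace.

    The baseline-corrected force is smoothed with a moving median; candidate
    steps are local positive jumps of the smoothed trace over a span of
    <= 5 samples exceeding ``max(min_step_N, threshold_multiplier * sigma)``.
    Candidates closer than the smoothing window are merged.  An empty list
    is a valid result.
    """
    force = (
        spring_constant_N_per_m * retract.deflection_m
        - baseline.force_at(retract.z_m)
    )
    smooth = median_filter(force, size=smooth_window, mode="nearest")
    span = 5
    n = smooth.size
    if n <= span:
        return []
    jump = smooth[span:] - smooth[:-span]  # jump[i] spans samples i .. i+span
    thr = threshold_multiplier * baseline.noise_sigma_N
    if min_step_N is not None:
        thr = max(thr, min_step_N)
    cand = np.nonzero(jump > thr)[0]
    if cand.size == 0:
        return []
    # group candidates separated by more than the smoothing window
    groups: list[list[int]] = [[int(cand[0])]]
    for idx in cand[1:]:
        if idx - groups[-1][-1] <= smooth_window:
            groups[-1].append(int(idx))
        else:
            groups.append([int(idx)])
    events: list[StepEvent] = []
    for grp in groups:
        local = max(grp, key=lambda i: jump[i])
        # sharpest single-sample rise inside the candidate span
        seg = slice(local, min(local + span + 1, n - 1))
        rise = np.diff(smooth[seg.start : seg.stop + 1])
        j = seg.start + int(np.argmax(rise))
        lo = max(j - smooth_window, 0)
        hi = min(j + 1 + smooth_window, n)
        pre = float(np.median(smooth[lo : j + 1]))
        post = float(np.median(smooth[j + 1 : hi]))
        step = post - pre
        if step <= 0:
            continue
        events.append(
            StepEvent(
                position_m=float(retract.z_m[j]),
                step_force_N=step,
                index=j,
            )
        )
    return events


def _baseline_slope_noise(
    s: np.ndarray,
    force: np.ndarray,
    window_samples: int,
    baseline_fraction: float,
    noise_sigma_N: float,
) -> float:
    """SD of pre-window slope estimates fitted along the free baseline tail."""
    n = s.size
    tail = slice(int(n * (1.0 - baseline_fraction)), n)
    st, ft = s[tail], force[tail]
    w = max(window_samples, 4)
    slopes = []
    step = max(w // 2, 1)
    for start in range(0, st.size - w, step):
        sl = np.polyfit(st[start : start + w], ft[start : start + w], 1)[0]
        slopes.append(sl)
    if len(slopes) >= 3:
        return float(np.std(slopes, ddof=1))
    # analytic fallback: var(slope) = sigma^2 / sum((x - xbar)^2)
    ds = float(np.median(np.abs(np.diff(s)))) or 1e-12
    sxx = ds**2 * w * (w**2 - 1) / 12.0
    return float(noise_sigma_N * np.sqrt(1.0 / sxx))


def classify_steps(
    events: Sequence[StepEvent],
    retract: ForceSegment,
    spring_constant_N_per_m: float,
    baseline: BaselineModel,
    pre_window_m: float = 100e-9,
    slope_threshold_N_per_m: Optional[float] = None,
    baseline_fraction: float = 0.15,
) -> list[StepEvent]:
    """Label detected steps as rupture or tether from the pre-step slope.

    The slope of the baseline-corrected force over ``pre_window_m`` of
    pulled distance before each step is fitted by least squares (windows
    are truncated at the previous event, never an error).  ``|slope|``
    above the threshold marks a rupture (loaded ramp), below it a tether
    (plateau).  The default threshold is 3x the SD of same-size-window
    slope estimates along the free baseline, so it scales with noise; it is
    additionally floored per event at 10% of the step force divided by the
    pre-window (a rupture ramp reaching the step force over the window has
    slope well above this, a plateau sits well below), which keeps the
    decision meaningful on noise-free data where the noise-derived
    threshold collapses to zero.
    """
    force = (
        spring_constant_N_per_m * retract.deflection_m
        - baseline.force_at(retract.z_m)
    )
    s = -retract.z_m  # monotonically increasing along the pull
    ds = float(np.median(np.abs(np.diff(s)))) if s.size > 1 else 1e-9
    w_samples = max(int(round(pre_window_m / ds)), 4)
    if slope_threshold_N_per_m is None:
        slope_threshold_N_per_m = 3.0 * _baseline_slope_noise(
            s, force, w_samples, baseline_fraction, baseline.noise_sigma_N
        )
    ordered = sorted(events, key=lambda ev: ev.index)
    labeled: list[StepEvent] = []
    prev_end = 0
    for ev in ordered:
        lo = max(ev.index - w_samples, prev_end, 0)
        hi = ev.index + 1
        if hi - lo >= 3:
            slope = float(np.polyfit(s[lo:hi], force[lo:hi], 1)[0])
        else:
            slope = 0.0
        thr_ev = max(
            slope_threshold_N_per_m, 0.1 * ev.step_force_N / pre_window_m
        )
        label = "rupture" if abs(slope) > thr_ev else "tether"
        labeled.append(
            StepEvent(
                position_m=ev.position_m,
                step_force_N=ev.step_force_N,
                pre_slope_N_per_m=slope,
                label=label,
                index=ev.index,
            )
        )
        prev_end = ev.index + 2
    return labeled


def analyze_retraction(
    curve: ForceCurve, config: Optional[SCFSConfig] = None
) -> SCFSResult:
    """Full retraction pipeline: baseline -> contact -> steps -> labels -> work."""
    cfg = config or SCFSConfig()
    k = curve.spring_constant_N_per_m
    try:
        retract = curve.segment("withdraw")
    except InvalidParameterError as exc:
        raise StageError("segments", exc) from exc
    try:
        baseline = estimate_baseline(retract, k, cfg.baseline_fraction)
    except Exception as exc:
        raise StageError("baseline", exc) from exc
    try:
        contact = detect_contact_point(
            retract,
            k,
            baseline,
            cfg.contact_threshold_multiplier,
            contact_exponent=1.0,  # SCFS press region unloads roughly linearly
        )
    except Exception as exc:
        raise StageError("contact", exc) from exc
    try:
        events = detect_steps(
            retract,
            k,
            baseline,
            min_step_N=cfg.min_step_N,
            threshold_multiplier=cfg.step_threshold_multiplier,
            smooth_window=cfg.smooth_window,
        )
        events = classify_steps(
            events,
            retract,
            k,
            baseline,
            pre_window_m=cfg.pre_window_m,
            slope_threshold_N_per_m=cfg.slope_threshold_N_per_m,
            baseline_fraction=cfg.baseline_fraction,
        )
    except Exception as exc:
        raise StageError("steps", exc) from exc
    try:
        work = detachment_work(retract, k, baseline, contact, events)
    except Exception as exc:
        raise StageError("work", exc) from exc
    if events:
        ratio = sum(ev.label == "rupture" for ev in events) / len(events)
    else:
        ratio = None
    return SCFSResult(work_J=work, events=events, rupture_ratio=ratio)


def summarize_cells(results_by_cell: pd.DataFrame) -> pd.DataFrame:
    """Average per-curve SCFS results into one row per cell.

    Expects columns ``cell_id``, ``group``, ``work_J``, ``rupture_ratio``
    (NaN allowed when a curve had no events).
    """
    if results_by_cell.empty:
        raise InvalidParameterError("no SCFS results to summarize")
    return (
        results_by_cell.groupby(["cell_id", "group"], as_index=False)
        .agg(
            work_J=("work_J", "mean"),
            rupture_ratio=("rupture_ratio", "mean"),
            n_repeats=("work_J", "size"),
        )
    )
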