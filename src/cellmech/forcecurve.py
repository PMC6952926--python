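"""Force-curve containers, file I/O, baseline estimation, and contact geometry.

An AFM force cycle is stored as a :class:`ForceCurve`: one or more
:class:`ForceSegment` traces (piezo position ``z``, cantilever deflection
``d``, time) plus the instrument metadata needed to convert deflection to
force (``F = k d``).  All internal quantities are SI (m, N, s, Pa, J).

Sign and axis conventions
-------------------------
* ``z`` increases toward the cell; within an approach segment ``z`` rises,
  within a withdraw segment it falls.
* Repulsive (contact) force is positive; adhesive force is negative.
* Indentation ``delta = (z - z0) - (d - d0)`` is nonnegative past contact.

The on-disk format is a TSV dialect: ``#``-prefixed ``key = value`` metadata
header followed by columns ``time_s  z_m  deflection_m  segment``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import CurveFormatError, InvalidParameterError, NoContactError

MIN_SEGMENT_SAMPLES = 16

_DIRECTIONS = ("approach", "dwell", "withdraw")


@dataclass
class ForceSegment:
    """One monotonic piezo sweep: approach, dwell, or withdraw."""

    direction: str
    z_m: np.ndarray
    deflection_m: np.ndarray
    time_s: np.ndarray

    def __post_init__(self) -> None:
        self.z_m = np.asarray(self.z_m, dtype=float)
        self.deflection_m = np.asarray(self.deflection_m, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.direction not in _DIRECTIONS:
            raise InvalidParameterError(f"unknown segment direction {self.direction!r}")
        n = self.z_m.size
        if not (self.deflection_m.size == n == self.time_s.size):
            raise InvalidParameterError("segment arrays must have equal length")
        if n < MIN_SEGMENT_SAMPLES:
            raise InvalidParameterError(
                f"segment needs >= {MIN_SEGMENT_SAMPLES} samples, got {n}"
            )
        if self.direction != "dwell":
            dz = np.diff(self.z_m)
            if self.direction == "approach" and not np.all(dz > 0):
                raise InvalidParameterError("approach z must be strictly increasing")
            if self.direction == "withdraw" and not np.all(dz < 0):
                raise InvalidParameterError("withdraw z must be strictly decreasing")

    @property
    def n_samples(self) -> int:
        return int(self.z_m.size)


@dataclass
class ForceCurve:
    """A full force cycle plus instrument metadata."""

    segments: list[ForceSegment]
    spring_constant_N_per_m: float
    speed_m_per_s: float
    setpoint_N: Optional[float] = None
    dwell_s: Optional[float] = None
    cell_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.spring_constant_N_per_m <= 0:
            raise InvalidParameterError("spring constant must be positive")
        if not self.segments:
            raise InvalidParameterError("curve needs at least one segment")

    def segment(self, direction: str) -> ForceSegment:
        for seg in self.segments:
            if seg.direction == direction:
                return seg
        raise InvalidParameterError(f"curve has no {direction!r} segment")

    def has_segment(self, direction: str) -> bool:
        return any(s.direction == direction for s in self.segments)


@dataclass
class BaselineModel:
    """Linear force baseline F_b(z) = slope*z + intercept, with noise level."""

    slope_N_per_m: float
    intercept_N: float
    noise_sigma_N: float

    def force_at(self, z: np.ndarray) -> np.ndarray:
        return self.slope_N_per_m * np.asarray(z, dtype=float) + self.intercept_N


@dataclass
class ContactPoint:
    """Tip-sample contact: sample index plus refined (z0, d0) coordinates."""

    index: int
    z0_m: float
    d0_m: float


@dataclass
class ForceIndentation:
    """Baseline-corrected force vs indentation past the contact point."""

    indentation_m: np.ndarray
    force_N: np.ndarray
    contact: ContactPoint


# ---------------------------------------------------------------------------
# File I/O


_REQUIRED_KEYS = ("spring_constant_N_per_m", "speed_m_per_s")
_OPTIONAL_KEYS = ("setpoint_N", "dwell_s", "cell_id", "group_label")


def write_force_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write ``curve`` to the TSV dialect; returns the path written."""
    path = Path(path)
    lines = []
    lines.append(f"# spring_constant_N_per_m = {float(curve.spring_constant_N_per_m)!r}")
    lines.append(f"# speed_m_per_s = {float(curve.speed_m_per_s)!r}")
    if curve.setpoint_N is not None:
        lines.append(f"# setpoint_N = {float(curve.setpoint_N)!r}")
    if curve.dwell_s is not None:
        lines.append(f"# dwell_s = {float(curve.dwell_s)!r}")
    if curve.cell_id:
        lines.append(f"# cell_id = {curve.cell_id}")
    if curve.group_label:
        lines.append(f"# group_label = {curve.group_label}")
    lines.append("time_s\tz_m\tdeflection_m\tsegment")
    for seg in curve.segments:
        for t, z, d in zip(seg.time_s, seg.z_m, seg.deflection_m):
            # repr of a Python float round-trips to full precision
            lines.append(f"{float(t)!r}\t{float(z)!r}\t{float(d)!r}\t{seg.direction}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_force_curve(path: str | Path) -> ForceCurve:
    """Parse the TSV dialect; round-trips :func:`write_force_curve` exactly."""
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, float, str]] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" not in line:
                    raise CurveFormatError(f"{path}:{lineno}: malformed metadata line")
                key, _, value = line.lstrip("#").partition("=")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = line.split("\t")
                if cols[:4] != ["time_s", "z_m", "deflection_m", "segment"]:
                    raise CurveFormatError(f"{path}:{lineno}: unexpected column header")
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise CurveFormatError(f"{path}:{lineno}: expected 4 columns")
            try:
                rows.append((float(parts[0]), float(parts[1]), float(parts[2]), parts[3]))
            except ValueError as exc:
                raise CurveFormatError(f"{path}:{lineno}: {exc}") from exc
    for key in _REQUIRED_KEYS:
        if key not in meta:
            raise CurveFormatError(f"{path}: missing required metadata key {key!r}")
    if not rows:
        raise CurveFormatError(f"{path}: no data rows")

    segments: list[ForceSegment] = []
    start = 0
    for i in range(1, len(rows) + 1):
        if i == len(rows) or rows[i][3] != rows[start][3]:
            chunk = rows[start:i]
            segments.append(
                ForceSegment(
                    direction=chunk[0][3],
                    time_s=np.array([r[0] for r in chunk]),
                    z_m=np.array([r[1] for r in chunk]),
                    deflection_m=np.array([r[2] for r in chunk]),
                )
            )
            start = i
    return ForceCurve(
        segments=segments,
        spring_constant_N_per_m=float(meta["spring_constant_N_per_m"]),
        speed_m_per_s=float(meta["speed_m_per_s"]),
        setpoint_N=float(meta["setpoint_N"]) if "setpoint_N" in meta else None,
        dwell_s=float(meta["dwell_s"]) if "dwell_s" in meta else None,
        cell_id=meta.get("cell_id", ""),
        group_label=meta.get("group_label", ""),
    )


# ---------------------------------------------------------------------------
# Baseline and contact


def _free_end_window(segment: ForceSegment, fit_fraction: float) -> slice:
    """Index window covering the non-contact (free) end of the segment.

    For an approach the tip starts far from the cell, so the free end is the
    head of the array; for a withdraw/retract it is the tail.
    """
    n = segment.n_samples
    nw = max(int(round(fit_fraction * n)), 0)
    if segment.direction == "withdraw":
        return slice(n - nw, n)
    return slice(0, nw)


def estimate_baseline(
    segment: ForceSegment,
    spring_constant_N_per_m: float,
    fit_fraction: float = 0.6,
) -> BaselineModel:
    """Robust linear baseline fit over the free-end window of a segment.

    Ordinary least squares on force vs z followed by one round of 3-sigma
    outlier rejection; ``noise_sigma_N`` is the SD of the final residuals
    (floored at a tiny positive value so thresholds stay well defined on
    noise-free synthetic data).
    """
    if not (0 < fit_fraction <= 0.9):
        raise InvalidParameterError("fit_fraction must be in (0, 0.9]")
    window = _free_end_window(segment, fit_fraction)
    z = segment.z_m[window]
    f = spring_constant_N_per_m * segment.deflection_m[window]
    if z.size < 8:
        raise InvalidParameterError(
            f"baseline window has {z.size} points; need at least 8"
        )
    coef = np.polyfit(z, f, 1)
    resid = f - np.polyval(coef, z)
    sigma = float(np.std(resid))
    if sigma > 0:
        keep = np.abs(resid) <= 3.0 * sigma
        if keep.sum() >= 8 and keep.sum() < z.size:
            coef = np.polyfit(z[keep], f[keep], 1)
            resid = f[keep] - np.polyval(coef, z[keep])
    sigma = float(np.std(resid, ddof=2)) if resid.size > 2 else float(np.std(resid))
    # Floor keeps noise_sigma strictly positive (pN-scale data, ~1e-17 N floor).
    sigma = max(sigma, 1e-17)
    return BaselineModel(
        slope_N_per_m=float(coef[0]), intercept_N=float(coef[1]), noise_sigma_N=sigma
    )


def _corrected_force(
    segment: ForceSegment, spring_constant: float, baseline: BaselineModel
) -> np.ndarray:
    return spring_constant * segment.deflection_m - baseline.force_at(segment.z_m)


def _refine_contact_z0(
    z: np.ndarray,
    f: np.ndarray,
    idx: int,
    half_window: int,
    exponent: float,
    reach_back: int | None = None,
) -> float:
    """Refine a threshold-crossing contact estimate.

    Fits the piecewise model ``F(z) = 0`` for ``z < z0``,
    ``c (z - z0)^exponent`` for ``z >= z0`` over a window around ``idx``
    (arrays ordered free end -> deep end), scanning candidate ``z0`` on the
    sample grid and minimizing the sum of squared residuals; the minimum is
    interpolated parabolically for sub-sample resolution.  This intersects
    the (already subtracted) baseline with a local power-law model of the
    contact region and is robust to noise, unlike a plain local root.  The
    exponent should match the expected contact law (2 for a conical tip,
    3/2 for a spherical/paraboloid one).  ``reach_back`` extends the
    candidate range toward the free end beyond ``half_window`` (the
    threshold crossing overshoots the true contact when the contact force
    rises slowly out of the noise floor).
    """
    if reach_back is None:
        reach_back = half_window
    lo = max(idx - reach_back - half_window, 0)
    hi = min(idx + half_window + 1, z.size)
    zw, fw = z[lo:hi], f[lo:hi]
    if zw.size < 8:
        return float(z[idx])
    cand = np.arange(max(idx - reach_back, 0), min(hi - 2, z.size - 2))
    if cand.size == 0:
        return float(z[idx])
    sse = np.empty(cand.size)
    for j, ci in enumerate(cand):
        g = np.clip(zw - z[ci], 0.0, None) ** exponent
        denom = float(g @ g)
        c = float(g @ fw) / denom if denom > 0 else 0.0
        c = max(c, 0.0)
        r = fw - c * g
        sse[j] = float(r @ r)
    k = int(np.argmin(sse))
    z0 = float(z[cand[k]])
    if 0 < k < cand.size - 1:
        # parabolic interpolation of the SSE minimum
        s0, s1, s2 = sse[k - 1], sse[k], sse[k + 1]
        denom = s0 - 2 * s1 + s2
        if denom > 0:
            shift = 0.5 * (s0 - s2) / denom
            shift = float(np.clip(shift, -1.0, 1.0))
            step = float(z[cand[k] + 1] - z[cand[k]]) if shift >= 0 else float(
                z[cand[k]] - z[cand[k] - 1]
            )
            z0 = z0 + shift * step
    return z0


def detect_contact_point(
    segment: ForceSegment,
    spring_constant_N_per_m: float,
    baseline: BaselineModel,
    threshold_multiplier: float = 3.0,
    contact_exponent: float = 1.5,
) -> ContactPoint:
    """Locate the tip-sample contact point in a segment.

    Scanning from the deepest indentation toward the free end, the contact
    index is the last sample whose baseline-corrected force exceeds
    ``threshold_multiplier * noise_sigma``; the estimate is then refined by
    a local piecewise power-law fit (see :func:`_refine_contact_z0`), whose
    ``contact_exponent`` should match the expected contact law.
    """
    fc = _corrected_force(segment, spring_constant_N_per_m, baseline)
    z = segment.z_m
    # Corrected deflection gives the tip-sample separation axis x = z - d,
    # on which the contact force is an exact power law in (x - x0); fitting
    # there avoids the small cantilever-bending bias of fitting against z.
    dc = segment.deflection_m - baseline.force_at(z) / spring_constant_N_per_m
    x = z - dc
    # Order arrays from free end to deep end.
    if segment.direction == "withdraw":
        order = slice(None, None, -1)
    else:
        order = slice(None)
    xo = x[order]
    zo = z[order]
    fo = fc[order]
    thr = threshold_multiplier * baseline.noise_sigma_N
    above = fo > thr
    if not above.any() or not above[-1]:
        # deepest sample must be in contact for a meaningful crossing
        raise NoContactError("no baseline-corrected force excursion above threshold")
    # last crossing scanning deep -> free: first index of the trailing True run
    run_start = int(np.nonzero(~above)[0][-1]) + 1 if not above.all() else 0
    if run_start == 0:
        raise NoContactError("segment appears to be entirely in contact")
    half_window = max(10, zo.size // 20)
    # With a soft sample and a finite noise floor, the threshold crossing can
    # sit well beyond the true contact; let the candidate scan reach far back
    # toward the free end.
    reach = 6 * half_window
    x0 = _refine_contact_z0(
        xo, fo, run_start, half_window, contact_exponent, reach_back=reach
    )
    z0 = float(np.interp(x0, xo, zo))
    d0 = float(baseline.force_at(z0) / spring_constant_N_per_m)
    # report index in the segment's own sample order
    idx = run_start if segment.direction != "withdraw" else z.size - 1 - run_start
    return ContactPoint(index=int(idx), z0_m=z0, d0_m=d0)


def to_force_indentation(
    segment: ForceSegment,
    spring_constant_N_per_m: float,
    contact: ContactPoint,
    baseline: BaselineModel,
) -> ForceIndentation:
    """Convert a segment to baseline-corrected force vs indentation.

    ``F = k d - F_baseline(z)`` and ``delta = (z - z0) - (d - d0)`` with
    ``d0 = F_baseline(z0)/k``; only samples beyond contact (``z > z0``) are
    retained, in the segment's own time order.
    """
    if spring_constant_N_per_m <= 0:
        raise InvalidParameterError("spring constant must be positive")
    z = segment.z_m
    if not (z.min() - 1e-12 <= contact.z0_m <= z.max() + 1e-12):
        raise InvalidParameterError("contact point lies outside the segment")
    force = _corrected_force(segment, spring_constant_N_per_m, baseline)
    d0 = baseline.force_at(contact.z0_m) / spring_constant_N_per_m
    delta = (z - contact.z0_m) - (segment.deflection_m - d0)
    keep = z > contact.z0_m
    delta = np.clip(delta[keep], 0.0, None)
    return ForceIndentation(
        indentation_m=delta, force_N=force[keep], contact=contact
    )
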