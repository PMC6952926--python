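"""Indentation elasticity and hysteresis analysis.

Young's modulus is estimated by fitting a contact-mechanics power law

    F = B * delta**m

to the shallow portion of the approach force-indentation curve, with the
prefactor B and exponent m set by the tip geometry:

* cone (Sneddon), half-angle alpha:   B = (2/pi) tan(alpha) E / (1 - nu^2),  m = 2
* sphere / paraboloid (Hertz), R:     B = (4/3) sqrt(R) E / (1 - nu^2),      m = 3/2

The plasticity index quantifies the loading/unloading hysteresis of a cycle:

    eta = 1 - A2 / A1

where A1 is the area under the loading (approach) curve and A2 the area
under the unloading (withdraw) curve, both over force vs indentation.
eta = 0 is fully elastic (the unloading curve retraces the loading one),
eta = 1 fully plastic (no force is recovered on unloading).

Per protocol, consecutive indentations at one position are averaged so that
each cell contributes a single value to group statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InvalidParameterError, StageError
from .forcecurve import (
    ContactPoint,
    ForceCurve,
    ForceIndentation,
    detect_contact_point,
    estimate_baseline,
    to_force_indentation,
)


@dataclass(frozen=True)
class TipModel:
    """Probe geometry and sample Poisson ratio.

    ``geometry`` is one of ``cone`` (half_angle_rad required), ``sphere`` or
    ``paraboloid`` (radius_m required).  Sphere is treated in the Hertzian
    (paraboloid) small-indentation limit, which shares the 3/2 power law.
    """

    geometry: str = "paraboloid"
    half_angle_rad: Optional[float] = None
    radius_m: Optional[float] = 1e-6
    poisson_ratio: float = 0.5

    def __post_init__(self) -> None:
        if self.geometry not in ("cone", "sphere", "paraboloid"):
            raise InvalidParameterError(f"unknown tip geometry {self.geometry!r}")
        if not (0.0 <= self.poisson_ratio <= 0.5):
            raise InvalidParameterError("poisson_ratio must be in [0, 0.5]")
        if self.geometry == "cone":
            if self.half_angle_rad is None or not (0 < self.half_angle_rad < math.pi / 2):
                raise InvalidParameterError("cone needs half_angle_rad in (0, pi/2)")
        else:
            if self.radius_m is None or self.radius_m <= 0:
                raise InvalidParameterError("sphere/paraboloid needs radius_m > 0")

    @property
    def exponent(self) -> float:
        """Power-law exponent m of F = B delta^m."""
        return 2.0 if self.geometry == "cone" else 1.5

    def prefactor(self, young_modulus_Pa: float) -> float:
        """Prefactor B (N / m^m) for a given Young's modulus."""
        reduced = young_modulus_Pa / (1.0 - self.poisson_ratio**2)
        if self.geometry == "cone":
            return (2.0 / math.pi) * math.tan(self.half_angle_rad) * reduced
        return (4.0 / 3.0) * math.sqrt(self.radius_m) * reduced

    def modulus_from_prefactor(self, B: float) -> float:
        """Invert :meth:`prefactor`."""
        return B / self.prefactor(1.0)


@dataclass
class YoungFit:
    E_Pa: float
    fit_range_m: tuple[float, float]
    rms_residual_N: float
    r_squared: float


@dataclass
class PlasticityResult:
    A1_J: float
    A2_J: float
    eta: float
    clipped: bool = False


@dataclass
class IndentationResult:
    young: YoungFit
    plasticity: PlasticityResult
    contact: ContactPoint
    qc_flags: set[str] = field(default_factory=set)


@dataclass
class CellSummary:
    cell_id: str
    group_label: str
    mean_E_Pa: float
    mean_eta: float
    n_repeats: int


@dataclass
class IndentConfig:
    """Tunable parameters of the indentation pipeline."""

    tip: TipModel = field(default_factory=TipModel)
    fit_fraction: float = 0.10
    cell_height_m: Optional[float] = None
    baseline_fraction: float = 0.25
    contact_threshold_multiplier: float = 3.0


def fit_young_modulus(
    fi: ForceIndentation,
    tip: TipModel,
    fit_fraction: float = 0.10,
    cell_height_m: Optional[float] = None,
) -> YoungFit:
    """Fit the contact power law over the shallow-indentation window.

    The fit depth is capped at ``fit_fraction`` of the cell height when a
    height is supplied, else at ``fit_fraction`` of the maximum recorded
    indentation.  The nonlinear solve (B free, m fixed by the tip) is seeded
    from a log-log linear regression.
    """
    delta = np.asarray(fi.indentation_m, dtype=float)
    force = np.asarray(fi.force_N, dtype=float)
    if delta.size == 0:
        raise FitError("empty force-indentation curve")
    depth_ref = cell_height_m if cell_height_m is not None else float(delta.max())
    delta_cap = fit_fraction * depth_ref
    mask = (delta > 0) & (delta <= delta_cap)
    if mask.sum() < 20:
        raise FitError(
            f"only {int(mask.sum())} samples at indentation <= {delta_cap:.3g} m; "
            "need >= 20 (shallow_indent)"
        )
    x, y = delta[mask], force[mask]
    m = tip.exponent
    pos = y > 0
    if pos.sum() >= 2:
        b0 = float(np.exp(np.mean(np.log(y[pos]) - m * np.log(x[pos]))))
    else:
        b0 = 1.0
    try:
        popt, _ = curve_fit(lambda d, B: B * d**m, x, y, p0=[b0], maxfev=2000)
    except RuntimeError as exc:
        raise FitError(f"power-law fit did not converge: {exc}") from exc
    B = float(popt[0])
    if B <= 0:
        raise FitError(f"non-physical prefactor B = {B:.3g}")
    resid = y - B * x**m
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return YoungFit(
        E_Pa=tip.modulus_from_prefactor(B),
        fit_range_m=(float(x.min()), float(x.max())),
        rms_residual_N=float(np.sqrt(np.mean(resid**2))),
        r_squared=r2,
    )


def plasticity_index(
    approach: ForceIndentation, withdraw: ForceIndentation
) -> PlasticityResult:
    """Hysteresis plasticity index eta = 1 - A2/A1 of one indentation cycle.

    A1 integrates the approach force over indentation (trapezoid rule);
    A2 integrates the nonnegative part of the withdraw force from maximum
    indentation down to its zero-force crossing, so adhesive (negative)
    forces never drive eta outside [0, 1].  Raw values outside [0, 1]
    (numerical noise) are clipped and flagged.
    """
    # approach indentation is nondecreasing, so the signed integral is the
    # loading area; a non-positive value means an unusable curve
    a1 = float(np.trapezoid(approach.force_N, approach.indentation_m))
    if a1 <= 0:
        raise InvalidParameterError("approach curve has non-positive area A1")
    fw = np.clip(withdraw.force_N, 0.0, None)
    a2 = abs(float(np.trapezoid(fw, withdraw.indentation_m)))
    raw = 1.0 - a2 / a1
    clipped = not (0.0 <= raw <= 1.0)
    eta = float(np.clip(raw, 0.0, 1.0))
    return PlasticityResult(A1_J=a1, A2_J=a2, eta=eta, clipped=clipped)


def analyze_indentation_cycle(
    curve: ForceCurve, config: Optional[IndentConfig] = None
) -> IndentationResult:
    """Run baseline -> contact -> force-indentation -> modulus + plasticity.

    Deterministic given the curve and configuration; stage failures are
    re-raised as :class:`StageError` naming the failing stage.
    """
    cfg = config or IndentConfig()
    k = curve.spring_constant_N_per_m
    qc: set[str] = set()
    try:
        approach = curve.segment("approach")
        withdraw = curve.segment("withdraw")
    except InvalidParameterError as exc:
        stage = "segments" if not curve.has_segment("approach") else "plasticity"
        raise StageError(stage, exc) from exc
    try:
        baseline = estimate_baseline(approach, k, cfg.baseline_fraction)
    except Exception as exc:
        raise StageError("baseline", exc) from exc
    try:
        contact = detect_contact_point(
            approach,
            k,
            baseline,
            cfg.contact_threshold_multiplier,
            contact_exponent=cfg.tip.exponent,
        )
    except Exception as exc:
        raise StageError("contact", exc) from exc
    try:
        fi_app = to_force_indentation(approach, k, contact, baseline)
        fi_wd = to_force_indentation(withdraw, k, contact, baseline)
    except Exception as exc:
        raise StageError("force_indentation", exc) from exc
    try:
        young = fit_young_modulus(
            fi_app, cfg.tip, cfg.fit_fraction, cfg.cell_height_m
        )
    except FitError as exc:
        if "shallow_indent" in str(exc):
            qc.add("shallow_indent")
        raise StageError("young_fit", exc) from exc
    try:
        plast = plasticity_index(fi_app, fi_wd)
    except Exception as exc:
        raise StageError("plasticity", exc) from exc
    if plast.clipped:
        qc.add("clipped_eta")
    if young.r_squared < 0.8:
        qc.add("poor_fit")
    return IndentationResult(young=young, plasticity=plast, contact=contact, qc_flags=qc)


def summarize_cell(
    results: Sequence[IndentationResult], cell_id: str, group_label: str
) -> CellSummary:
    """Average repeat indentations into one per-cell value (n = 1 per cell)."""
    if not results:
        raise InvalidParameterError("cannot summarize an empty result list")
    return CellSummary(
        cell_id=cell_id,
        group_label=group_label,
        mean_E_Pa=float(np.mean([r.young.E_Pa for r in results])),
        mean_eta=float(np.mean([r.plasticity.eta for r in results])),
        n_repeats=len(results),
    )
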