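"""Synthetic AFM, imaging, and expression data with recorded ground truth.

Everything the analysis pipelines consume can be generated here:

* single indentation cycles whose loading branch follows the tip-model power
  law ``F = B delta^m`` and whose unloading branch is a power law with
  exponent ``p = (m + 1)/(1 - eta) - 1``, so the loading/unloading area
  ratio — and hence the plasticity index — is known in closed form;
* SCFS retraction traces with discrete unbinding events, each either a
  loaded rupture ramp or a tether plateau, with analytically known work;
* cell populations (log-normal stiffness, truncated-normal plasticity) with
  within-cell repeat variability, written as curve files plus a manifest;
* filament-plus-puncta fluorescence images with pixel-exact ground-truth
  masks;
* qPCR Ct tables and log2 fold-change tables with exact group effects.

Each generator returns a :class:`SyntheticGroundTruth` carrying the true
values so recovery can be tested without circularity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, LayoutError
from .forcecurve import ForceCurve, ForceSegment, write_force_curve
from .indentation import TipModel

DEFAULT_INDENT_SPRING_CONSTANT = 0.08  # N/m, indentation cantilever
DEFAULT_SCFS_SPRING_CONSTANT = 0.32  # N/m, SCFS cantilever
DEFAULT_SPEED = 1e-6  # m/s approach/withdraw speed
DEFAULT_SCFS_SETPOINT = 0.5e-9  # N contact force during SCFS dwell
DEFAULT_SCFS_DWELL = 20.0  # s


@dataclass
class SyntheticGroundTruth:
    """True values attached to every simulated object."""

    true_E_Pa: Optional[float] = None
    true_eta: Optional[float] = None
    true_work_J: Optional[float] = None
    event_labels: Optional[list[dict[str, float | str]]] = None
    true_aggregate_fraction_percent: Optional[float] = None
    generator_params: Any = None
    extras: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Indentation cycles


@dataclass(frozen=True)
class IndentSimParams:
    """Inputs of :func:`simulate_indentation_cycle`."""

    young_modulus_Pa: float = 1.5e3
    target_eta: float = 0.3
    tip: TipModel = field(default_factory=TipModel)
    spring_constant_N_per_m: float = DEFAULT_INDENT_SPRING_CONSTANT
    speed_m_per_s: float = DEFAULT_SPEED
    max_indentation_m: float = 1e-6
    contact_offset_m: float = 0.5e-6
    baseline_slope_N_per_m: float = 0.0
    noise_sigma_N: float = 0.0
    relative_noise: float = 0.0
    n_samples_per_segment: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_eta < 1.0):
            raise InvalidParameterError("target_eta must lie in [0, 1)")
        if self.young_modulus_Pa <= 0:
            raise InvalidParameterError("young_modulus_Pa must be positive")
        if self.max_indentation_m <= 0:
            raise InvalidParameterError("max_indentation_m must be positive")
        if self.noise_sigma_N < 0 or self.relative_noise < 0:
            raise InvalidParameterError("noise levels must be nonnegative")
        if self.spring_constant_N_per_m <= 0 or self.speed_m_per_s <= 0:
            raise InvalidParameterError("spring constant and speed must be positive")


def unloading_exponent(m: float, target_eta: float) -> float:
    """Unloading power-law exponent giving area ratio A2/A1 = 1 - eta.

    With loading F = B delta^m and unloading F = F_max (delta/delta_max)^p,
    A1 = F_max delta_max/(m+1) and A2 = F_max delta_max/(p+1), so choosing
    p = (m+1)/(1-eta) - 1 makes 1 - A2/A1 = eta exactly.
    """
    if not (0.0 <= target_eta < 1.0):
        raise InvalidParameterError("target_eta must lie in [0, 1)")
    return (m + 1.0) / (1.0 - target_eta) - 1.0


def _delta_of_z(
    z: np.ndarray, z0: float, delta_max: float, force_of_delta, k: float
) -> np.ndarray:
    """Invert z = z0 + delta + F(delta)/k on a dense interpolation table."""
    dense = np.linspace(0.0, delta_max, 20 * max(z.size, 200))
    z_table = z0 + dense + force_of_delta(dense) / k
    return np.interp(z, z_table, dense, left=0.0)


def simulate_indentation_cycle(
    params: IndentSimParams,
) -> tuple[ForceCurve, SyntheticGroundTruth]:
    """Simulate one approach/withdraw indentation cycle.

    The curve is expressed as piezo position and deflection (d = F_total/k,
    including baseline tilt and noise), sampled uniformly in z as a
    constant-speed piezo sweep would be.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    m = p.tip.exponent
    B = p.tip.prefactor(p.young_modulus_Pa)
    dmax = p.max_indentation_m
    f_max = B * dmax**m
    k = p.spring_constant_N_per_m
    z0 = p.contact_offset_m
    z_end = z0 + dmax + f_max / k
    n = p.n_samples_per_segment
    z = np.linspace(0.0, z_end, n)

    load = lambda d: B * d**m
    p_exp = unloading_exponent(m, p.target_eta)
    unload = lambda d: f_max * (d / dmax) ** p_exp

    delta_app = np.where(z > z0, _delta_of_z(z, z0, dmax, load, k), 0.0)
    f_app = load(delta_app)
    if p.target_eta == 0.0:
        # fully elastic: withdrawal retraces the approach bit-for-bit
        f_wd = f_app.copy()
    else:
        delta_wd = np.where(z > z0, _delta_of_z(z, z0, dmax, unload, k), 0.0)
        f_wd = unload(np.clip(delta_wd, 0.0, dmax))

    def emit(fc: np.ndarray, zz: np.ndarray) -> np.ndarray:
        total = fc.copy()
        if p.relative_noise > 0:
            total = total * (1.0 + p.relative_noise * rng.standard_normal(total.size))
        total = total + p.baseline_slope_N_per_m * zz
        if p.noise_sigma_N > 0:
            total = total + p.noise_sigma_N * rng.standard_normal(total.size)
        return total / k

    d_app = emit(f_app, z)
    z_wd = z[::-1].copy()
    d_wd = emit(f_wd[::-1], z_wd)
    t_app = z / p.speed_m_per_s
    t_wd = t_app[-1] + (z_end - z_wd) / p.speed_m_per_s

    curve = ForceCurve(
        segments=[
            ForceSegment("approach", z, d_app, t_app),
            ForceSegment("withdraw", z_wd, d_wd, t_wd),
        ],
        spring_constant_N_per_m=k,
        speed_m_per_s=p.speed_m_per_s,
    )
    truth = SyntheticGroundTruth(
        true_E_Pa=p.young_modulus_Pa,
        true_eta=p.target_eta,
        generator_params=p,
        extras={
            "A1_J": f_max * dmax / (m + 1.0),
            "A2_J": f_max * dmax / (p_exp + 1.0),
            "contact_offset_m": z0,
            "unloading_exponent": p_exp,
            "max_force_N": f_max,
        },
    )
    return curve, truth


# ---------------------------------------------------------------------------
# SCFS retraction curves


@dataclass(frozen=True)
class RetractSimParams:
    """Inputs of :func:`simulate_retraction_curve`.

    ``step_forces_N`` lists the unbinding force of every event (ruptures
    first is *not* assumed; labels are interleaved randomly).  When empty it
    is filled with ``tether_plateau_force_N`` for tethers and 100 pN for
    ruptures.
    """

    n_ruptures: int = 2
    n_tethers: int = 3
    step_forces_N: tuple[float, ...] = ()
    rupture_preslope_N_per_m: float = 1e-3
    tether_plateau_force_N: float = 60e-12
    plateau_length_m: float = 0.2e-6
    pull_length_m: float = 4e-6
    press_depth_m: float = 0.3e-6
    spring_constant_N_per_m: float = DEFAULT_SCFS_SPRING_CONSTANT
    speed_m_per_s: float = DEFAULT_SPEED
    setpoint_N: float = DEFAULT_SCFS_SETPOINT
    dwell_s: float = DEFAULT_SCFS_DWELL
    noise_sigma_N: float = 0.0
    baseline_slope_N_per_m: float = 0.0
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ruptures < 0 or self.n_tethers < 0:
            raise InvalidParameterError("event counts must be nonnegative")
        n_events = self.n_ruptures + self.n_tethers
        if self.step_forces_N and len(self.step_forces_N) != n_events:
            raise InvalidParameterError(
                "len(step_forces_N) must equal n_ruptures + n_tethers"
            )
        if self.step_forces_N and any(f <= 0 for f in self.step_forces_N):
            raise InvalidParameterError("step forces must be positive")
        if self.rupture_preslope_N_per_m == 0:
            raise InvalidParameterError("rupture_preslope must be nonzero")
        if self.pull_length_m <= 0:
            raise InvalidParameterError("pull_length must be positive")
        if self.noise_sigma_N < 0:
            raise InvalidParameterError("noise_sigma must be nonnegative")


def _event_plan(
    p: RetractSimParams, rng: np.random.Generator
) -> list[dict[str, float | str]]:
    """Lay events out along the pull with jittered spacing.

    Each event occupies ``[start, end]`` in pulled distance s; the unbinding
    step happens at ``end``.  Events are separated by at least three times
    the 100 nm classification pre-window and the last 20% of the pull is
    kept event-free so the free baseline is observable.
    """
    n_events = p.n_ruptures + p.n_tethers
    if n_events == 0:
        return []
    labels = ["rupture"] * p.n_ruptures + ["tether"] * p.n_tethers
    rng.shuffle(labels)
    if p.step_forces_N:
        forces = list(p.step_forces_N)
    else:
        forces = [
            100e-12 if lab == "rupture" else p.tether_plateau_force_N
            for lab in labels
        ]
    slope = abs(p.rupture_preslope_N_per_m)
    extents = [
        f / slope if lab == "rupture" else p.plateau_length_m
        for lab, f in zip(labels, forces)
    ]
    min_sep = 3 * 100e-9
    s_lo, s_hi = 0.1e-6, 0.8 * p.pull_length_m
    free = (s_hi - s_lo) - sum(extents) - min_sep * (n_events - 1)
    if free < 0:
        raise LayoutError(
            f"pull length {p.pull_length_m:.3g} m too short for {n_events} events"
        )
    gaps = rng.dirichlet(np.ones(n_events + 1)) * free
    events = []
    s = s_lo
    for i, (lab, f, ext) in enumerate(zip(labels, forces, extents)):
        s += gaps[i] + (min_sep if i > 0 else 0.0)
        events.append({"label": lab, "force_N": f, "s_start": s, "s_end": s + ext})
        s += ext
    return events


def simulate_retraction_curve(
    params: RetractSimParams,
) -> tuple[ForceCurve, SyntheticGroundTruth]:
    """Simulate one SCFS retraction (withdraw) trace.

    The trace starts in contact (repulsive force ramping down from the
    setpoint), crosses the contact point at z = 0, then shows adhesive
    (negative) force events as the cell is pulled away: a rupture loads
    linearly before an instantaneous step back to baseline, a tether sits
    on a flat plateau before its step.  The analytic work of detachment is
    the summed below-baseline area: 1/2 F^2/|slope| per rupture and
    F * plateau_length per tether.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    events = _event_plan(p, rng)
    slope = abs(p.rupture_preslope_N_per_m)

    z = np.linspace(p.press_depth_m, -p.pull_length_m, p.n_samples)
    s = -z  # pulled distance past contact
    force = np.zeros_like(z)
    in_contact = z > 0
    force[in_contact] = p.setpoint_N * (z[in_contact] / p.press_depth_m)
    for ev in events:
        sel = (s >= ev["s_start"]) & (s < ev["s_end"])
        if ev["label"] == "rupture":
            force[sel] = -slope * (s[sel] - ev["s_start"])
        else:
            force[sel] = -ev["force_N"]
    true_work = sum(
        0.5 * ev["force_N"] ** 2 / slope
        if ev["label"] == "rupture"
        else ev["force_N"] * (ev["s_end"] - ev["s_start"])
        for ev in events
    )
    total = force + p.baseline_slope_N_per_m * z
    if p.noise_sigma_N > 0:
        total = total + p.noise_sigma_N * rng.standard_normal(total.size)
    deflection = total / p.spring_constant_N_per_m
    t = (p.press_depth_m - z) / p.speed_m_per_s

    curve = ForceCurve(
        segments=[ForceSegment("withdraw", z, deflection, t)],
        spring_constant_N_per_m=p.spring_constant_N_per_m,
        speed_m_per_s=p.speed_m_per_s,
        setpoint_N=p.setpoint_N,
        dwell_s=p.dwell_s,
    )
    labels = [
        {"label": ev["label"], "z_m": -ev["s_end"], "force_N": ev["force_N"]}
        for ev in events
    ]
    truth = SyntheticGroundTruth(
        true_work_J=float(true_work),
        event_labels=labels,
        generator_params=p,
        extras={"n_ruptures": p.n_ruptures, "n_tethers": p.n_tethers},
    )
    return curve, truth


# ---------------------------------------------------------------------------
# Cell populations


@dataclass(frozen=True)
class GroupSpec:
    """Population-level distribution of one experimental group.

    Stiffness is log-normal, parameterized by its median and quartiles as
    figure captions report them; plasticity is normal truncated to [0, 0.95];
    SCFS work of detachment is log-normal.  ``cv_intracell`` is the
    multiplicative within-cell repeat variability.
    """

    name: str
    median_E_Pa: float = 1.5e3
    q25_E_Pa: Optional[float] = None
    q75_E_Pa: Optional[float] = None
    sigma_log_E: Optional[float] = None
    eta_mean: float = 0.30
    eta_sd: float = 0.07
    median_work_J: float = 3e-16
    sigma_log_work: float = 0.5
    mean_events: float = 6.0
    rupture_prob: float = 0.35
    cv_intracell: float = 0.05

    def log_sigma_E(self) -> float:
        if self.q25_E_Pa is not None and self.q75_E_Pa is not None:
            return (math.log(self.q75_E_Pa) - math.log(self.q25_E_Pa)) / (2 * 0.674490)
        if self.q75_E_Pa is not None:
            return math.log(self.q75_E_Pa / self.median_E_Pa) / 0.674490
        return self.sigma_log_E if self.sigma_log_E is not None else 0.4


@dataclass
class PopulationDataset:
    """Simulated population: manifest rows aligned with in-memory curves."""

    manifest: pd.DataFrame
    curves: list[ForceCurve]
    truths: list[SyntheticGroundTruth]
    out_dir: Optional[Path] = None


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def simulate_population(
    group_specs: Sequence[GroupSpec],
    n_cells_per_group: int,
    repeats_per_cell: int = 3,
    seed: int = 0,
    mode: str = "indent",
    out_dir: Optional[str | Path] = None,
    **sim_overrides: Any,
) -> PopulationDataset:
    """Simulate a multi-group cell population of force curves.

    ``mode='indent'`` produces full indentation cycles (default three
    repeats per cell); ``mode='scfs'`` produces retraction traces (use 4-6
    repeats).  Repeats within a cell share the cell's true values times
    multiplicative Gaussian intra-cell noise.  With ``out_dir`` each curve
    is written as a TSV file and a ``manifest.csv`` is emitted; curves are
    always returned in memory as well.  Extra keyword arguments override
    fields of the per-curve simulation parameters (e.g. ``noise_sigma_N``,
    ``n_samples_per_segment``, ``tip``).
    """
    if n_cells_per_group < 1:
        raise InvalidParameterError("n_cells_per_group must be >= 1")
    if repeats_per_cell < 1:
        raise InvalidParameterError("repeats_per_cell must be >= 1")
    if mode not in ("indent", "scfs"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    rows: list[dict[str, Any]] = []
    curves: list[ForceCurve] = []
    truths: list[SyntheticGroundTruth] = []
    for spec in group_specs:
        sigma_e = spec.log_sigma_E()
        for ci in range(n_cells_per_group):
            cell_id = f"{spec.name}_c{ci:03d}"
            if mode == "indent":
                e_cell = float(
                    np.exp(math.log(spec.median_E_Pa) + sigma_e * rng.standard_normal())
                )
                eta_cell = _truncated_normal(rng, spec.eta_mean, spec.eta_sd, 0.0, 0.95)
            else:
                w_cell = float(
                    np.exp(
                        math.log(spec.median_work_J)
                        + spec.sigma_log_work * rng.standard_normal()
                    )
                )
            for ri in range(repeats_per_cell):
                jitter = 1.0 + spec.cv_intracell * rng.standard_normal()
                jitter = max(jitter, 0.1)
                rep_seed = int(rng.integers(0, 2**31 - 1))
                if mode == "indent":
                    params = IndentSimParams(
                        young_modulus_Pa=e_cell * jitter,
                        target_eta=float(np.clip(eta_cell * jitter, 0.0, 0.95)),
                        noise_sigma_N=sim_overrides.get("noise_sigma_N", 10e-12),
                        seed=rep_seed,
                        **{
                            key: val
                            for key, val in sim_overrides.items()
                            if key != "noise_sigma_N"
                        },
                    )
                    curve, truth = simulate_indentation_cycle(params)
                    truth_cols = {
                        "true_E_Pa": truth.true_E_Pa,
                        "true_eta": truth.true_eta,
                    }
                else:
                    n_ev = max(int(rng.poisson(spec.mean_events)), 1)
                    n_rup = int(rng.binomial(n_ev, spec.rupture_prob))
                    w_rep = w_cell * jitter
                    # unit-force layout, then scale forces so the analytic
                    # work matches the drawn repeat work (rupture extent is
                    # fixed, so work is linear in the force scale)
                    ext_r = sim_overrides.get("rupture_extent_m", 0.15e-6)
                    base_forces = 60e-12 * np.exp(
                        0.3 * rng.standard_normal(n_ev)
                    )
                    plateau = sim_overrides.get("plateau_length_m", 0.2e-6)
                    labels = ["rupture"] * n_rup + ["tether"] * (n_ev - n_rup)
                    w_unit = sum(
                        0.5 * f * ext_r if lab == "rupture" else f * plateau
                        for lab, f in zip(labels, base_forces)
                    )
                    scale = w_rep / w_unit if w_unit > 0 else 1.0
                    forces = tuple(float(f * scale) for f in base_forces)
                    mean_f = float(np.mean(forces))
                    params_r = RetractSimParams(
                        n_ruptures=n_rup,
                        n_tethers=n_ev - n_rup,
                        step_forces_N=forces,
                        rupture_preslope_N_per_m=mean_f / ext_r,
                        plateau_length_m=plateau,
                        noise_sigma_N=sim_overrides.get("noise_sigma_N", 5e-12),
                        n_samples=sim_overrides.get("n_samples", 2000),
                        seed=rep_seed,
                    )
                    # rupture extents now vary with each force; recompute truth
                    curve, truth = simulate_retraction_curve(params_r)
                    truth_cols = {
                        "true_work_J": truth.true_work_J,
                        "true_n_ruptures": n_rup,
                        "true_n_tethers": n_ev - n_rup,
                    }
                curve.cell_id = cell_id
                curve.group_label = spec.name
                fname = f"{cell_id}_r{ri}.tsv"
                if out_path is not None:
                    write_force_curve(curve, out_path / fname)
                rows.append(
                    {
                        "cell_id": cell_id,
                        "group": spec.name,
                        "repeat": ri,
                        "path": str(out_path / fname) if out_path else "",
                        **truth_cols,
                    }
                )
                curves.append(curve)
                truths.append(truth)
    manifest = pd.DataFrame(rows)
    if out_path is not None:
        manifest.to_csv(out_path / "manifest.csv", index=False)
    return PopulationDataset(
        manifest=manifest, curves=curves, truths=truths, out_dir=out_path
    )


# ---------------------------------------------------------------------------
# Fluorescence images


def simulate_actin_image(
    width: int = 256,
    height: int = 256,
    n_filaments: int = 12,
    n_puncta: int = 0,
    puncta_radius_px: int = 3,
    noise_sigma: float = 80.0,
    seed: int = 0,
    target_fraction_percent: Optional[float] = None,
    filament_amplitude: float = 6000.0,
    puncta_amplitude: float = 14000.0,
    background: float = 800.0,
    filament_halfwidth_px: int = 3,
    edge_sigma_px: float = 1.0,
) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Simulate a phalloidin-like image: filaments plus bright puncta.

    Filaments are straight strokes of half-width ``filament_halfwidth_px``
    with slightly blurred (``edge_sigma_px``) edges, so the filament area
    is insensitive to the exact segmentation threshold; puncta are bright
    discs centered on the filament network (aggregates sit on the
    cytoskeleton).  Ground-truth masks record the cytoskeleton and the
    puncta, and the true aggregate fraction is the pixel-exact
    ``100 * |puncta & cyto| / |cyto|``.  If ``target_fraction_percent`` is
    given, puncta are added until the true fraction reaches it (overriding
    ``n_puncta``).
    """
    from scipy.ndimage import binary_dilation, gaussian_filter
    from skimage.draw import disk, line
    from skimage.morphology import disk as disk_footprint

    if width <= 0 or height <= 0:
        raise InvalidParameterError("image dimensions must be positive")
    rng = np.random.default_rng(seed)
    centerlines = np.zeros((height, width), dtype=float)
    diag = math.hypot(width, height)
    for _ in range(n_filaments):
        cx, cy = rng.uniform(0, width), rng.uniform(0, height)
        theta = rng.uniform(0, math.pi)
        dx, dy = math.cos(theta), math.sin(theta)
        half = 0.6 * diag
        r0 = int(np.clip(cy - half * dy, 0, height - 1))
        c0 = int(np.clip(cx - half * dx, 0, width - 1))
        r1 = int(np.clip(cy + half * dy, 0, height - 1))
        c1 = int(np.clip(cx + half * dx, 0, width - 1))
        rr, cc = line(r0, c0, r1, c1)
        centerlines[rr, cc] = 1.0
    stroke = binary_dilation(
        centerlines > 0, structure=disk_footprint(filament_halfwidth_px)
    )
    fil = gaussian_filter(stroke.astype(float), edge_sigma_px) * filament_amplitude
    cyto_mask = fil > 0.5 * filament_amplitude
    cyto_area = int(cyto_mask.sum())
    if cyto_area == 0 and (n_puncta > 0 or target_fraction_percent):
        raise LayoutError("no cytoskeleton to place puncta on")

    candidates = np.argwhere(cyto_mask)
    if candidates.size:
        candidates = candidates[rng.permutation(candidates.shape[0])]
    agg_mask = np.zeros_like(cyto_mask)
    puncta_img = np.zeros_like(fil)
    centers: list[tuple[int, int]] = []
    min_dist = 3.0 * puncta_radius_px

    def place_one() -> bool:
        for r, c in candidates:
            if all(math.hypot(r - rr, c - cc) >= min_dist for rr, cc in centers):
                if not (
                    puncta_radius_px <= r < height - puncta_radius_px
                    and puncta_radius_px <= c < width - puncta_radius_px
                ):
                    continue
                rr_, cc_ = disk((r, c), puncta_radius_px, shape=cyto_mask.shape)
                agg_mask[rr_, cc_] |= cyto_mask[rr_, cc_]
                puncta_img[rr_, cc_] = puncta_amplitude
                centers.append((int(r), int(c)))
                return True
        return False

    if target_fraction_percent is not None:
        target = target_fraction_percent / 100.0
        while cyto_area > 0 and agg_mask.sum() / cyto_area < target:
            if not place_one():
                raise LayoutError("cannot reach target aggregate fraction")
    else:
        for _ in range(n_puncta):
            if not place_one():
                raise LayoutError(f"cannot place {n_puncta} puncta")

    img = background + fil + gaussian_filter(puncta_img, 0.6)
    if noise_sigma > 0:
        img = img + noise_sigma * rng.standard_normal(img.shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    true_fraction = 100.0 * agg_mask.sum() / cyto_area if cyto_area else 0.0
    truth = SyntheticGroundTruth(
        true_aggregate_fraction_percent=float(true_fraction),
        extras={
            "cyto_mask": cyto_mask,
            "aggregate_mask": agg_mask,
            "n_puncta_placed": len(centers),
        },
    )
    return img, truth


# ---------------------------------------------------------------------------
# Expression tables


def simulate_expression_tables(
    ct_spec: dict[str, Any],
    deg_spec: dict[str, Any],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a qPCR Ct table and a DEG table with miR-target flags.

    ``ct_spec`` keys: ``groups`` (mapping group -> {"target_shift": cycles}),
    ``target_gene``, ``reference_gene``, ``n_replicates`` (default 4),
    ``base_ct_target``/``base_ct_reference`` and ``ct_sd`` (default 0.2).
    A positive shift means later amplification, i.e. lower expression.

    ``deg_spec`` keys: ``n_targets``, and either ``n_down`` or
    ``fraction_down``; optional ``n_background`` non-target genes.  The
    returned table contains exactly the requested number of negative
    log2 fold changes among flagged targets.
    """
    rng = np.random.default_rng(seed)
    groups = ct_spec["groups"]
    target = ct_spec.get("target_gene", "Itga1")
    reference = ct_spec.get("reference_gene", "Rpl37")
    n_rep = int(ct_spec.get("n_replicates", 4))
    base_t = float(ct_spec.get("base_ct_target", 24.0))
    base_r = float(ct_spec.get("base_ct_reference", 18.0))
    ct_sd = float(ct_spec.get("ct_sd", 0.2))
    rows = []
    for gname, gspec in groups.items():
        shift = float(gspec.get("target_shift", 0.0))
        for rep in range(n_rep):
            noise_t = ct_sd * rng.standard_normal() if ct_sd > 0 else 0.0
            noise_r = ct_sd * rng.standard_normal() if ct_sd > 0 else 0.0
            rows.append(
                {"group": gname, "replicate": rep, "gene": target,
                 "ct": base_t + shift + noise_t}
            )
            rows.append(
                {"group": gname, "replicate": rep, "gene": reference,
                 "ct": base_r + noise_r}
            )
    ct_table = pd.DataFrame(rows)

    n_targets = int(deg_spec["n_targets"])
    if "n_down" in deg_spec:
        n_down = int(deg_spec["n_down"])
    else:
        frac = float(deg_spec.get("fraction_down", 0.5))
        if not (0.0 <= frac <= 1.0):
            raise InvalidParameterError("fraction_down must lie in [0, 1]")
        n_down = int(round(frac * n_targets))
    if not (0 <= n_down <= n_targets):
        raise InvalidParameterError("n_down must lie in [0, n_targets]")
    n_bg = int(deg_spec.get("n_background", 0))
    lfc_down = -np.abs(rng.normal(1.0, 0.5, n_down)) - 1e-6
    lfc_up = np.abs(rng.normal(0.8, 0.4, n_targets - n_down)) + 1e-6
    lfc_bg = rng.normal(0.0, 1.0, n_bg)
    deg = pd.DataFrame(
        {
            "gene": [f"gene_{i:05d}" for i in range(n_targets + n_bg)],
            "log2_fold_change": np.concatenate([lfc_down, lfc_up, lfc_bg]),
            "is_target": [True] * n_targets + [False] * n_bg,
        }
    )
    deg = deg.sample(frac=1.0, random_state=int(rng.integers(0, 2**31 - 1)))
    return ct_table, deg.reset_index(drop=True)
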