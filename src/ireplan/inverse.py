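"""The two inversions: conductivity calibration and threshold extraction.

Calibration: the fully-electroporated conductivity ceiling sigma_max is the
one free parameter of the dynamic tissue law.  It is recovered per patient
by matching the simulated delivered current of the first pair activation
(the largest-spacing pair, evaluated first clinically to avoid compounding
effects from multiple treatments) to the measured current.  The forward
current is monotone non-decreasing in sigma_max, so the match is found by
bisection on [sigma0, 2.0] S/m.

Threshold: the lethal electric-field threshold is the field contour whose
super-level-set volume, computed from the voxelwise-maximum field over all
activations, matches the observed ablation volume.  Thresholds are scanned
on a 1 V/cm grid and the closest volume wins; ties go to the lower
threshold (the conservative, larger predicted kill zone).
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np

from .conductivity import TissueModel
from .geometry import Electrode, SimulationDomain
from .protocol import PlanResult, TreatmentPlan, run_plan
from .solver import solve_pair

__all__ = [
    "CalibrationResult",
    "ThresholdResult",
    "CalibrationRangeError",
    "calibrate_sigma_max",
    "superlevel_volume",
    "superlevel_volumes",
    "find_threshold",
    "InferenceResult",
    "infer_patient",
]

SIGMA_MAX_UPPER = 2.0  # S/m, upper calibration bracket
CURRENT_MATCH_RTOL = 1e-3
BRACKET_TOL = 1e-4  # S/m


class CalibrationRangeError(ValueError):
    """Measured current outside the achievable interval of the model."""


@dataclass
class CalibrationResult:
    sigma_max_hat: float  # S/m
    achieved_current: float  # A
    target_current: float  # A
    search_iterations: int

    @property
    def current_mismatch(self) -> float:
        return abs(self.achieved_current - self.target_current) / self.target_current


@dataclass
class ThresholdResult:
    e_threshold: int  # V/cm
    matched_volume: float  # cm^3
    target_volume: float  # cm^3


def calibrate_sigma_max(
    domain: SimulationDomain,
    electrodes: list[Electrode],
    plan: TreatmentPlan,
    measured_current: float,
    sigma0: float = 0.284,
    *,
    upper: float = SIGMA_MAX_UPPER,
    current_rtol: float = CURRENT_MATCH_RTOL,
    bracket_tol: float = BRACKET_TOL,
    grid_step: float | None = None,
    model_template: TissueModel | None = None,
    **solver_kwargs,
) -> CalibrationResult:
    """Recover sigma_max by matching the first-pair dynamic current.

    By default the root is bracketed by bisection (the forward current is
    monotone in sigma_max); passing ``grid_step`` (e.g. 0.01 S/m) instead
    scans a parametric sweep and returns the closest grid point.
    """
    if not measured_current > 0:
        raise ValueError("measured_current must be > 0")
    if len(plan) == 0:
        raise ValueError("plan is empty")
    act = plan.first_pair
    base = model_template or TissueModel(sigma0=sigma0, mode="dynamic")

    from .solver import electrode_masks

    masks = solver_kwargs.pop("masks", None) or electrode_masks(domain, electrodes)
    warm = {"phi": solver_kwargs.pop("x0", None), "sigma": None}

    def forward(sigma_max: float) -> float:
        sol = solve_pair(domain, electrodes, (act.source, act.sink), act.voltage,
                         base.with_sigma_max(sigma_max), x0=warm["phi"],
                         sigma_init=warm["sigma"], masks=masks, **solver_kwargs)
        warm["phi"] = sol.phi
        warm["sigma"] = sol.sigma
        return sol.source_current

    i_lo = forward(sigma0)
    i_hi = forward(upper)
    if not (i_lo <= measured_current <= i_hi):
        raise CalibrationRangeError(
            f"measured current {measured_current:.3f} A outside the achievable "
            f"interval [{i_lo:.3f}, {i_hi:.3f}] A for sigma_max in "
            f"[{sigma0}, {upper}] S/m"
        )

    if grid_step is not None:
        grid = np.arange(sigma0, upper + grid_step / 2, grid_step)
        best, best_i, niter = sigma0, i_lo, 0
        for s in grid[1:]:
            i = forward(float(s))
            niter += 1
            if abs(i - measured_current) < abs(best_i - measured_current):
                best, best_i = float(s), i
        return CalibrationResult(best, best_i, measured_current, niter)

    lo, hi = sigma0, upper
    mid, i_mid = sigma0, i_lo
    niter = 2
    while hi - lo > bracket_tol:
        mid = 0.5 * (lo + hi)
        i_mid = forward(mid)
        niter += 1
        if abs(i_mid - measured_current) / measured_current < current_rtol:
            break
        if i_mid < measured_current:
            lo = mid
        else:
            hi = mid
    else:
        mid = 0.5 * (lo + hi)
        i_mid = forward(mid)
        niter += 1
    return CalibrationResult(mid, i_mid, measured_current, niter)


def superlevel_volume(e_field: np.ndarray, e_t: float,
                      domain: SimulationDomain) -> float:
    """Volume (cm^3) of the region where the field magnitude >= e_t (V/cm)."""
    if e_t < 0:
        raise ValueError("threshold must be >= 0")
    return float(np.count_nonzero(e_field >= e_t)) * domain.voxel_volume


def superlevel_volumes(e_field: np.ndarray, domain: SimulationDomain,
                       thresholds: np.ndarray) -> np.ndarray:
    """Super-level-set volumes for many thresholds at once (sorted scan)."""
    flat = np.sort(e_field.ravel())
    counts = flat.size - np.searchsorted(flat, thresholds, side="left")
    return counts * domain.voxel_volume


def find_threshold(e_field: np.ndarray, target_volume: float,
                   domain: SimulationDomain) -> ThresholdResult:
    """Scan integer thresholds (1 V/cm steps) for the best volume match."""
    total = domain.edge_length**3
    if not 0 < target_volume <= total:
        raise ValueError(
            f"target volume {target_volume} cm^3 outside (0, {total}] cm^3"
        )
    e_hi = int(math.ceil(float(e_field.max())))
    ts = np.arange(1, e_hi + 1, dtype=float)
    vols = superlevel_volumes(e_field, domain, ts)
    err = np.abs(vols - target_volume)
    k = int(np.argmin(err))  # argmin takes the first (lowest) threshold on ties
    return ThresholdResult(e_threshold=int(ts[k]), matched_volume=float(vols[k]),
                           target_volume=float(target_volume))


@dataclass
class InferenceResult:
    """Full patient-level inference: both model variants plus calibration."""

    threshold_static: int  # V/cm
    threshold_dynamic: int  # V/cm
    sigma_max_hat: float  # S/m
    calibration: CalibrationResult
    static_result: PlanResult
    dynamic_result: PlanResult


def infer_patient(
    domain: SimulationDomain,
    electrodes: list[Electrode],
    plan: TreatmentPlan,
    measured_current: float,
    target_volume: float,
    *,
    sigma0: float = 0.284,
    model_template: TissueModel | None = None,
    **solver_kwargs,
) -> InferenceResult:
    """Run the full inference chain for one patient.

    1. static solve of every activation -> threshold by volume matching;
    2. calibrate sigma_max from the measured first-pair current;
    3. dynamic solve of every activation with the calibrated law ->
       threshold by volume matching.
    """
    from .solver import electrode_masks

    masks = electrode_masks(domain, electrodes)
    base = model_template or TissueModel(sigma0=sigma0, mode="dynamic")
    static_model = TissueModel(sigma0=base.sigma0, sigma_max=base.sigma0,
                               e_center=base.e_center, e_width=base.e_width,
                               mode="static")
    static_res = run_plan(domain, electrodes, plan, static_model, masks=masks,
                          keep_solutions=True, **solver_kwargs)
    thr_static = find_threshold(static_res.e_max, target_volume, domain)

    static_phis = [s.phi for s in static_res.solutions]
    cal = calibrate_sigma_max(domain, electrodes, plan, measured_current,
                              sigma0=base.sigma0, model_template=base,
                              masks=masks, x0=static_phis[0], **solver_kwargs)
    dyn_model = base.with_sigma_max(cal.sigma_max_hat)
    dyn_res = run_plan(domain, electrodes, plan, dyn_model, masks=masks,
                       x0_fields=static_phis, **solver_kwargs)
    thr_dyn = find_threshold(dyn_res.e_max, target_volume, domain)

    return InferenceResult(
        threshold_static=thr_static.e_threshold,
        threshold_dynamic=thr_dyn.e_threshold,
        sigma_max_hat=cal.sigma_max_hat,
        calibration=cal,
        static_result=static_res,
        dynamic_result=dyn_res,
    )
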