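"""Synthetic patients emulating the clinical trial's treatment records.

No clinical geometry or imaging is shipped with the study, so validation
runs on synthetic patients with known ground truth.  Each patient is a
four-needle square array with spacing and exposure drawn from the trial's
ranges, a tissue law with a planted conductivity ceiling sigma_max, and a
planted lethal threshold.  The "measured" current is the forward-simulated
dynamic first-pair current (optionally with multiplicative Gaussian noise),
and the ablation mask is the super-level set of the forward maximum-field
distribution at the planted threshold.  Feeding these records back through
the inference chain must recover the planted parameters (closed loop).

Pre-treatment PSA is drawn from a Gaussian copula against the planted
threshold so cohort-level correlation analyses have a known effect to
detect; the study observes, not models, this association, so the copula
correlation is a free parameter defaulting to the observed value.

The change-in-current column has no stated clinical definition; here it is
defined as the dynamic minus static first-pair current, i.e. the current
rise attributable to electroporation.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.stats import norm

from .conductivity import TissueModel
from .geometry import AblationMask, Electrode, GeometryError, SimulationDomain, make_domain, place_electrode_grid
from .protocol import TreatmentPlan, make_plan, run_plan
from .solver import solve_pair

__all__ = ["SyntheticPatient", "CohortConfig", "generate_cohort", "export_patient"]

# Study-condition sampling ranges (clinical table / calibrated-conductivity range)
SPACING_RANGE = (1.4, 2.2)  # cm
EXPOSURE_CHOICES = (1.5, 2.0)  # cm
SIGMA_MAX_RANGE = (0.55, 1.0)  # S/m
THRESHOLD_RANGE = (412.0, 614.0)  # V/cm
PSA_RANGE = (3.8, 10.03)  # ng/mL
PSA_THRESHOLD_RHO = -0.624  # Gaussian-copula correlation, PSA vs threshold


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults are the emulated study conditions."""

    edge_length: float = 7.5  # cm
    resolution: int = 64
    sigma0: float = 0.284  # S/m
    current_noise: float = 0.01  # relative sd of the measured current
    rho: float = PSA_THRESHOLD_RHO
    simulate: str = "full"  # "full" | "first_pair" | "none"


@dataclass
class SyntheticPatient:
    patient_id: str
    seed: int
    domain: SimulationDomain
    electrodes: list[Electrode]
    plan: TreatmentPlan
    spacing: float  # cm, square side
    exposure_length: float  # cm
    sigma_max_true: float  # S/m
    threshold_true: float  # V/cm
    psa_pre: float  # ng/mL
    measured_current: float | None = None  # A, first pair (noisy)
    delta_current: float | None = None  # A, dynamic - static first pair
    mask: AblationMask | None = None

    @property
    def ablation_volume(self) -> float | None:
        return None if self.mask is None else self.mask.volume


def _sample_parameters(rng: np.random.Generator, rho: float):
    spacing = float(rng.uniform(*SPACING_RANGE))
    exposure = float(rng.choice(EXPOSURE_CHOICES))
    sigma_max = float(rng.uniform(*SIGMA_MAX_RANGE))
    # Gaussian copula: correlated uniforms for threshold and PSA
    z = rng.standard_normal(2)
    z2 = rho * z[0] + np.sqrt(1.0 - rho**2) * z[1]
    u_thr, u_psa = norm.cdf(z[0]), norm.cdf(z2)
    thr = THRESHOLD_RANGE[0] + (THRESHOLD_RANGE[1] - THRESHOLD_RANGE[0]) * u_thr
    psa = PSA_RANGE[0] + (PSA_RANGE[1] - PSA_RANGE[0]) * u_psa
    return spacing, exposure, sigma_max, float(thr), float(psa)


def generate_cohort(
    n_patients: int,
    seed: int,
    config: CohortConfig = CohortConfig(),
    **solver_kwargs,
) -> list[SyntheticPatient]:
    """Generate ``n_patients`` synthetic treatment records.

    Each patient draws from an independent substream of ``seed``, so a
    cohort is extensible without reshuffling earlier patients and
    regeneration with the same seed is bit-identical.

    ``config.simulate`` controls how much forward physics runs: "full"
    solves every activation (measured current, change in current and
    ablation mask all populated), "first_pair" solves only the calibration
    pair (no mask), "none" samples parameters only.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    domain = make_domain(config.edge_length, config.resolution)
    streams = np.random.SeedSequence(seed).spawn(n_patients)
    cohort = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        patient = None
        for attempt in range(5):
            spacing, exposure, sigma_max, thr, psa = _sample_parameters(rng, config.rho)
            try:
                electrodes = place_electrode_grid(4, spacing, exposure, domain=domain)
            except GeometryError as exc:  # pragma: no cover - ranges are feasible
                warnings.warn(f"patient {i}: infeasible geometry ({exc}); resampling")
                continue
            patient = SyntheticPatient(
                patient_id=f"S{i + 1}",
                seed=seed,
                domain=domain,
                electrodes=electrodes,
                plan=make_plan(electrodes),
                spacing=spacing,
                exposure_length=exposure,
                sigma_max_true=sigma_max,
                threshold_true=thr,
                psa_pre=psa,
            )
            break
        if patient is None:
            raise GeometryError(f"patient {i}: no feasible geometry after 5 attempts")
        if config.simulate != "none":
            _simulate_patient(patient, config, rng, **solver_kwargs)
        cohort.append(patient)
    return cohort


def _simulate_patient(p: SyntheticPatient, config: CohortConfig,
                      rng: np.random.Generator, **solver_kwargs) -> None:
    dyn = TissueModel(sigma0=config.sigma0, sigma_max=p.sigma_max_true,
                      mode="dynamic")
    static = TissueModel(sigma0=config.sigma0, mode="static")
    first = p.plan.first_pair

    from .solver import electrode_masks

    masks = electrode_masks(p.domain, p.electrodes)
    sol_static = solve_pair(p.domain, p.electrodes, (first.source, first.sink),
                            first.voltage, static, masks=masks, **solver_kwargs)
    if config.simulate == "first_pair":
        sol_dyn = solve_pair(p.domain, p.electrodes, (first.source, first.sink),
                             first.voltage, dyn, x0=sol_static.phi, masks=masks,
                             **solver_kwargs)
        first_current = sol_dyn.source_current
    else:
        x0s = [sol_static.phi] + [None] * (len(p.plan) - 1)
        res = run_plan(p.domain, p.electrodes, p.plan, dyn, masks=masks,
                       x0_fields=x0s, **solver_kwargs)
        first_current = res.pair_currents[0]
        p.mask = AblationMask(p.domain, res.e_max >= p.threshold_true)

    noise = 1.0 + config.current_noise * float(rng.standard_normal())
    p.measured_current = first_current * noise
    p.delta_current = first_current - sol_static.source_current


def export_patient(patient: SyntheticPatient, config_path, mask_path=None,
                   *, include_truth: bool = True) -> None:
    """Write a patient to a treatment config file (+ optional mask file).

    Round-trips bit-exactly through :func:`ireplan.config.read_patient_config`.
    """
    from . import config as io_config

    io_config.write_patient_config(patient, config_path, include_truth=include_truth)
    if mask_path is not None:
        if patient.mask is None:
            raise ValueError("patient has no ablation mask (simulate='full' needed)")
        io_config.save_mask_nifti(patient.mask, mask_path)
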