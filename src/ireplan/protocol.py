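"""NanoKnife treatment-plan emulation.

The clinical generator pulses every unordered electrode pair in turn
(including diagonals: six activations for four needles).  The applied
voltage per pair follows a constant voltage-to-distance rule, 1500 V/cm
times the inter-electrode spacing, capped at the generator's 3000 V
maximum.  Pairs are activated from the highest voltage (largest spacing) to
the lowest.  Pulse-train metadata (90 pulses of 70 us per pair) is carried
for provenance but has no electrostatic consequence in this model.

Pairs are solved independently and aggregated by the voxelwise maximum of
the field magnitude (and of the conductivity, in dynamic mode) across
activations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .conductivity import TissueModel
from .geometry import Electrode, SimulationDomain
from .solver import FieldSolution, solve_pair

__all__ = [
    "PairActivation",
    "TreatmentPlan",
    "PlanResult",
    "enumerate_pairs",
    "pair_voltage",
    "order_plan",
    "make_plan",
    "run_plan",
]

VOLTAGE_TO_DISTANCE = 1500.0  # V/cm
VOLTAGE_CAP = 3000.0  # V
PULSES_PER_PAIR = 90
PULSE_LENGTH_US = 70.0


@dataclass(frozen=True)
class PairActivation:
    source: int  # electrode index
    sink: int
    voltage: float  # V
    spacing: float  # cm


@dataclass(frozen=True)
class TreatmentPlan:
    """Ordered pair activations plus (unsimulated) pulse metadata."""

    activations: tuple[PairActivation, ...]
    pulses_per_pair: int = PULSES_PER_PAIR
    pulse_length_us: float = PULSE_LENGTH_US

    def __post_init__(self):
        v = [a.voltage for a in self.activations]
        if any(x > VOLTAGE_CAP for x in v):
            raise ValueError(f"plan voltage exceeds the {VOLTAGE_CAP:.0f} V cap")
        if any(v[i] < v[i + 1] for i in range(len(v) - 1)):
            raise ValueError("plan must be ordered by non-increasing voltage")

    def __len__(self):
        return len(self.activations)

    @property
    def first_pair(self) -> PairActivation:
        """The first activation (largest spacing); current calibration uses it."""
        return self.activations[0]


def enumerate_pairs(electrodes: list[Electrode]) -> list[tuple[int, int]]:
    """All unordered electrode index pairs, n(n-1)/2 of them."""
    if len(electrodes) < 2:
        raise ValueError("need at least 2 electrodes to form a pair")
    return list(combinations(range(len(electrodes)), 2))


def pair_voltage(spacing: float, ratio: float = VOLTAGE_TO_DISTANCE,
                 cap: float = VOLTAGE_CAP) -> float:
    """Applied voltage for a pair: min(ratio * spacing, cap)."""
    if not spacing > 0:
        raise ValueError(f"spacing must be > 0 cm, got {spacing}")
    return min(ratio * spacing, cap)


def _electrode_spacing(a: Electrode, b: Electrode) -> float:
    """Distance between electrode axes at the exposure midpoint (cm)."""
    ca = a.tip_position + 0.5 * a.exposure_length * a.axis
    cb = b.tip_position + 0.5 * b.exposure_length * b.axis
    return float(np.linalg.norm(ca - cb))


def order_plan(activations: list[PairActivation]) -> TreatmentPlan:
    """Sort activations by descending voltage, largest spacing first on ties.

    The voltage cap can level the voltages of pairs with different spacings
    (e.g. sides and diagonals of a wide square array); the wider pair still
    goes first, mirroring the clinical largest-spacing-first rule.  Remaining
    ties keep electrode-index order.
    """
    ordered = sorted(
        activations,
        key=lambda a: (-a.voltage, -a.spacing, a.source, a.sink),
    )
    return TreatmentPlan(activations=tuple(ordered))


def make_plan(electrodes: list[Electrode], ratio: float = VOLTAGE_TO_DISTANCE,
              cap: float = VOLTAGE_CAP) -> TreatmentPlan:
    """Build the ordered plan for an electrode array from the voltage rule."""
    acts = []
    for i, j in enumerate_pairs(electrodes):
        s = _electrode_spacing(electrodes[i], electrodes[j])
        acts.append(PairActivation(i, j, pair_voltage(s, ratio, cap), s))
    return order_plan(acts)


@dataclass
class PlanResult:
    """Aggregated result of running every activation of a plan."""

    e_max: np.ndarray  # voxelwise max |E| across pairs, V/cm
    sigma_max_field: np.ndarray  # voxelwise max conductivity, S/m
    pair_currents: list[float]  # source current per activation, A
    solutions: list[FieldSolution] = field(default_factory=list, repr=False)


def run_plan(
    domain: SimulationDomain,
    electrodes: list[Electrode],
    plan: TreatmentPlan,
    model: TissueModel,
    *,
    keep_solutions: bool = False,
    x0_fields: list[np.ndarray] | None = None,
    **solver_kwargs,
) -> PlanResult:
    """Solve every activation and aggregate by voxelwise maximum.

    Activations are independent: no permeabilization carry-over between
    pairs is modeled.  Raises with the pair identity attached if any single
    solve fails.  ``x0_fields`` optionally warm-starts each activation
    (e.g. with the static solution of the same pair).
    """
    from .solver import electrode_masks

    masks = solver_kwargs.pop("masks", None) or electrode_masks(domain, electrodes)
    e_max = np.zeros(domain.shape)
    s_max = np.zeros(domain.shape)
    currents: list[float] = []
    sols: list[FieldSolution] = []
    for k, act in enumerate(plan.activations):
        try:
            sol = solve_pair(domain, electrodes, (act.source, act.sink),
                             act.voltage, model, masks=masks,
                             x0=None if x0_fields is None else x0_fields[k],
                             **solver_kwargs)
        except Exception as exc:
            raise RuntimeError(
                f"pair ({act.source}, {act.sink}) at {act.voltage:.0f} V failed"
            ) from exc
        np.maximum(e_max, sol.e_mag, out=e_max)
        np.maximum(s_max, sol.sigma, out=s_max)
        currents.append(sol.source_current)
        if keep_solutions:
            sols.append(sol)
    return PlanResult(e_max=e_max, sigma_max_field=s_max, pair_currents=currents,
                      solutions=sols)
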