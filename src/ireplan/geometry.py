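"""Simulation domain, electrodes, ablation masks and clinical records.

The simulation domain is a cube of prostate-scale tissue discretized on a
regular, isotropic, cell-centered voxel grid.  Needle electrodes are the
active (uninsulated) cylinders of NanoKnife-style probes; only the exposed
cylinder is modeled — insulated shaft and sharp tip are excluded.  Lengths
at this interface are centimeters; electric fields are reported in V/cm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "SimulationDomain",
    "Electrode",
    "AblationMask",
    "PatientRecord",
    "GeometryError",
    "make_domain",
    "place_electrode_grid",
    "mask_volume",
    "load_table1",
]

#: conductivity of stainless-steel needle electrodes, S/m
STEEL_CONDUCTIVITY = 2.0e6

#: default electrode radius, cm (1 mm-diameter monopolar probe)
DEFAULT_ELECTRODE_RADIUS = 0.05


class GeometryError(ValueError):
    """Raised for invalid domains or electrode placements."""


@dataclass(frozen=True)
class SimulationDomain:
    """Cubic tissue domain on an isotropic cell-centered voxel grid.

    Parameters
    ----------
    edge_length : float
        Side of the cube in cm.
    resolution : int
        Number of voxels along each axis (>= 16).
    origin : ndarray
        Center of the cube in cm; the default grid is origin-centered.
    """

    edge_length: float = 7.5
    resolution: int = 64
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        if not self.edge_length > 0:
            raise GeometryError(f"edge_length must be > 0, got {self.edge_length}")
        if int(self.resolution) != self.resolution or self.resolution < 16:
            raise GeometryError(
                f"resolution must be an integer >= 16, got {self.resolution}"
            )
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))

    @property
    def spacing(self) -> float:
        """Isotropic voxel spacing in cm."""
        return self.edge_length / self.resolution

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.resolution,) * 3

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in cm^3."""
        return self.spacing**3

    def axis_centers(self) -> np.ndarray:
        """Voxel-center coordinates along one axis (cm), shape (resolution,)."""
        h = self.spacing
        half = self.edge_length / 2.0
        return -half + h * (np.arange(self.resolution) + 0.5)

    def centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate grids (cm), each of shape ``self.shape``."""
        c = self.axis_centers()
        x = c + self.origin[0]
        y = c + self.origin[1]
        z = c + self.origin[2]
        return np.meshgrid(x, y, z, indexing="ij")

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        """True where points (…, 3) lie inside the cube shrunk by ``margin`` cm."""
        p = np.asarray(points, dtype=float) - self.origin
        half = self.edge_length / 2.0 - margin
        return np.all(np.abs(p) <= half, axis=-1)


@dataclass(frozen=True)
class Electrode:
    """Active cylinder of one needle electrode.

    ``tip_position`` is the distal end of the exposed cylinder; the cylinder
    extends ``exposure_length`` cm from the tip along ``axis``.
    """

    tip_position: np.ndarray
    axis: np.ndarray
    exposure_length: float
    radius: float = DEFAULT_ELECTRODE_RADIUS
    conductivity: float = STEEL_CONDUCTIVITY

    def __post_init__(self):
        tip = np.asarray(self.tip_position, dtype=float)
        ax = np.asarray(self.axis, dtype=float)
        if abs(np.linalg.norm(ax) - 1.0) > 1e-9:
            raise GeometryError("electrode axis must be a unit vector")
        if not self.exposure_length > 0:
            raise GeometryError("exposure_length must be > 0")
        if not self.radius > 0:
            raise GeometryError("electrode radius must be > 0")
        object.__setattr__(self, "tip_position", tip)
        object.__setattr__(self, "axis", ax)

    @property
    def end_position(self) -> np.ndarray:
        return self.tip_position + self.exposure_length * self.axis

    def rasterize(self, domain: SimulationDomain) -> np.ndarray:
        """Boolean voxel mask of the electrode cylinder.

        Occupancy follows a center-inside rule against an effective radius
        ``max(radius, 0.71 * spacing)`` so the rasterized electrode is a
        contiguous column at least one voxel wide even when the physical
        radius (0.05 cm by default) is below the grid spacing.
        """
        for end in (self.tip_position, self.end_position):
            if not domain.contains(end, margin=2.5 * domain.spacing):
                raise GeometryError(
                    "electrode cylinder extends outside the simulation domain "
                    f"(endpoint {end}, cube edge {domain.edge_length} cm)"
                )
        r_eff = max(self.radius, 0.71 * domain.spacing)
        x, y, z = domain.centers()
        p = np.stack([x, y, z], axis=-1) - self.tip_position
        t = p @ self.axis
        t_clamped = np.clip(t, 0.0, self.exposure_length)
        closest = t_clamped[..., None] * self.axis
        dist = np.linalg.norm(p - closest, axis=-1)
        return dist <= r_eff


@dataclass
class AblationMask:
    """Binary voxel occupancy of an ablation volume on a domain grid."""

    domain: SimulationDomain
    occupancy: np.ndarray

    def __post_init__(self):
        occ = np.asarray(self.occupancy, dtype=bool)
        if occ.shape != self.domain.shape:
            raise GeometryError(
                f"mask shape {occ.shape} does not match domain grid {self.domain.shape}"
            )
        self.occupancy = occ

    @property
    def volume(self) -> float:
        """Occupied volume in cm^3."""
        return float(self.occupancy.sum()) * self.domain.voxel_volume


@dataclass(frozen=True)
class PatientRecord:
    """One row of the clinical treatment table (or a synthetic equivalent)."""

    patient_id: str
    psa_pre: float  # ng/mL
    max_voltage: float  # V
    max_spacing: float  # cm
    delta_current: float  # A
    threshold_dynamic: float  # V/cm
    ablation_volume: float  # cm^3

    def __post_init__(self):
        numeric = {
            "psa_pre": self.psa_pre,
            "max_voltage": self.max_voltage,
            "max_spacing": self.max_spacing,
            "delta_current": self.delta_current,
            "threshold_dynamic": self.threshold_dynamic,
            "ablation_volume": self.ablation_volume,
        }
        for name, value in numeric.items():
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value}")
        if self.max_voltage > 3000:
            raise ValueError(
                f"max_voltage {self.max_voltage} V exceeds the 3000 V generator limit"
            )


def make_domain(edge_length: float = 7.5, resolution: int = 64) -> SimulationDomain:
    """Build the cubic simulation domain, centered at the origin."""
    return SimulationDomain(edge_length=edge_length, resolution=resolution)


def place_electrode_grid(
    n_electrodes: int,
    spacing: float,
    exposure_length: float,
    center: np.ndarray = (0.0, 0.0, 0.0),
    *,
    radius: float = DEFAULT_ELECTRODE_RADIUS,
    domain: SimulationDomain | None = None,
) -> list[Electrode]:
    """Place parallel needle electrodes on a square grid.

    The clinical configuration emulated here is four parallel needles at the
    corners of a square of side ``spacing`` (cm), axes along +z, with the
    exposed cylinder centered (in z) on ``center``.  ``spacing`` is capped at
    2.2 cm, slightly above the not-more-than-2-cm placement rule, to admit
    the widest spacing seen clinically.
    """
    if n_electrodes != 4:
        raise GeometryError("the square-grid generator places exactly 4 electrodes")
    if not 0 < spacing <= 2.2:
        raise GeometryError(f"spacing must be in (0, 2.2] cm, got {spacing}")
    center = np.asarray(center, dtype=float)
    half = spacing / 2.0
    offsets = [(-half, -half), (half, -half), (-half, half), (half, half)]
    axis = np.array([0.0, 0.0, 1.0])
    electrodes = []
    for dx, dy in offsets:
        tip = center + np.array([dx, dy, -exposure_length / 2.0])
        electrodes.append(
            Electrode(tip_position=tip, axis=axis, exposure_length=exposure_length,
                      radius=radius)
        )
    if domain is not None:
        for e in electrodes:
            e.rasterize(domain)  # raises GeometryError if outside
    return electrodes


def mask_volume(mask: AblationMask) -> float:
    """Volume of an ablation mask in cm^3 (voxel count x voxel volume)."""
    v = mask.volume
    if v == 0.0:
        import warnings

        warnings.warn("ablation mask is empty; volume is 0 cm^3", stacklevel=2)
    return v


def load_table1() -> list[PatientRecord]:
    """Load the packaged clinical treatment table (10 patients).

    Columns: pre-treatment PSA (ng/mL), maximum applied voltage (V), maximum
    electrode spacing (cm), change in delivered current (A), lethal field
    threshold from the dynamic-conductivity model (V/cm), and MRI ablation
    volume (cm^3).
    """
    with resources.files("ireplan.data").joinpath("table1.csv").open() as f:
        df = pd.read_csv(f)
    return [PatientRecord(**row) for row in df.to_dict(orient="records")]


def table1_frame() -> pd.DataFrame:
    """The clinical table as a DataFrame (column order preserved)."""
    with resources.files("ireplan.data").joinpath("table1.csv").open() as f:
        return pd.read_csv(f)
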