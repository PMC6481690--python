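"""Patient/treatment configuration files, mask and field I/O, run settings.

Treatment configs are JSON: domain settings, electrode geometry, the
ordered activation plan, measured quantities (first-pair current, target
ablation volume, PSA), the tissue-law parameters, and — for synthetic
patients — the planted ground truth.  Floats survive the round trip
bit-exactly (JSON carries full ``repr`` precision).

Masks use NIfTI with an affine carrying the isotropic voxel spacing;
scalar fields export to legacy ASCII VTK structured-points files for
visual inspection.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import nibabel as nib
import numpy as np

from .conductivity import TissueModel
from .geometry import AblationMask, Electrode, SimulationDomain, make_domain
from .protocol import PairActivation, TreatmentPlan, VOLTAGE_CAP

__all__ = [
    "PatientInputs",
    "RunConfig",
    "ConfigError",
    "write_patient_config",
    "read_patient_config",
    "save_mask_nifti",
    "load_mask_nifti",
    "save_field_vtk",
]

FORMAT_TAG = "ireplan-patient"


class ConfigError(ValueError):
    """Schema or unit violation in a configuration file."""


@dataclass
class PatientInputs:
    """Validated inputs for one patient inference run."""

    patient_id: str
    domain: SimulationDomain
    electrodes: list[Electrode]
    plan: TreatmentPlan
    tissue: TissueModel
    measured_current: float | None  # A; None -> static-only mode
    target_volume: float | None  # cm^3
    psa_pre: float | None  # ng/mL
    delta_current: float | None  # A
    truth: dict | None = None  # planted ground truth for synthetic patients


@dataclass
class RunConfig:
    """Solver / protocol settings shared across runs."""

    edge_length: float = 7.5  # cm
    resolution: int = 64
    cg_rtol: float = 1e-7
    current_rtol: float = 1e-3
    relaxation: float = 0.5
    max_picard: int = 100
    voltage_ratio: float = 1500.0  # V/cm
    voltage_cap: float = 3000.0  # V
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self):
        if self.resolution < 16:
            raise ConfigError("resolution must be >= 16")
        for name in ("cg_rtol", "current_rtol", "relaxation"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as f:
            return cls(**json.load(f))

    def solver_kwargs(self) -> dict:
        return {
            "cg_rtol": self.cg_rtol,
            "current_rtol": self.current_rtol,
            "relaxation": self.relaxation,
            "max_picard": self.max_picard,
        }


def _require(condition: bool, message: str) -> None:
    if not condition:
        raise ConfigError(message)


def write_patient_config(patient, path, *, include_truth: bool = True) -> None:
    """Serialize a synthetic patient or :class:`PatientInputs` to JSON."""
    from .synthetic import SyntheticPatient

    if isinstance(patient, SyntheticPatient):
        measurements = {
            "measured_current": patient.measured_current,
            "target_volume": patient.ablation_volume,
            "psa_pre": patient.psa_pre,
            "delta_current": patient.delta_current,
        }
        tissue = {"sigma0": 0.284, "e_center": 500.0, "e_width": 800.0}
        truth = {
            "sigma_max": patient.sigma_max_true,
            "threshold": patient.threshold_true,
        } if include_truth else None
    elif isinstance(patient, PatientInputs):
        measurements = {
            "measured_current": patient.measured_current,
            "target_volume": patient.target_volume,
            "psa_pre": patient.psa_pre,
            "delta_current": patient.delta_current,
        }
        tissue = {
            "sigma0": patient.tissue.sigma0,
            "e_center": patient.tissue.e_center,
            "e_width": patient.tissue.e_width,
        }
        truth = patient.truth if include_truth else None
    else:
        raise TypeError(f"cannot serialize {type(patient).__name__}")

    doc = {
        "format": FORMAT_TAG,
        "patient_id": patient.patient_id,
        "domain": {
            "edge_length": patient.domain.edge_length,
            "resolution": patient.domain.resolution,
        },
        "tissue": tissue,
        "electrodes": [
            {
                "tip_position": list(e.tip_position),
                "axis": list(e.axis),
                "exposure_length": e.exposure_length,
                "radius": e.radius,
            }
            for e in patient.electrodes
        ],
        "plan": [
            {"source": a.source, "sink": a.sink, "voltage": a.voltage,
             "spacing": a.spacing}
            for a in patient.plan.activations
        ],
        "measurements": measurements,
    }
    if truth is not None:
        doc["truth"] = truth
    with open(path, "w") as f:
        json.dump(doc, f, indent=1)


def read_patient_config(path) -> PatientInputs:
    """Read and validate a patient treatment config.

    Validation names the offending field; units are cm / V / A / cm^3.
    A missing measured current is allowed (calibration unavailable,
    static-only inference); a missing target volume disables threshold
    matching.
    """
    with open(path) as f:
        doc = json.load(f)
    _require(doc.get("format") == FORMAT_TAG,
             f"config 'format' must be {FORMAT_TAG!r}, got {doc.get('format')!r}")
    for key in ("domain", "electrodes", "plan"):
        _require(key in doc, f"config missing required section {key!r}")

    dom = doc["domain"]
    _require(dom.get("edge_length", 0) > 0, "domain.edge_length (cm) must be > 0")
    domain = make_domain(dom["edge_length"], dom["resolution"])

    electrodes = []
    for k, e in enumerate(doc["electrodes"]):
        for fieldname in ("tip_position", "axis", "exposure_length"):
            _require(fieldname in e, f"electrodes[{k}] missing {fieldname!r}")
        electrodes.append(
            Electrode(
                tip_position=np.array(e["tip_position"], dtype=float),
                axis=np.array(e["axis"], dtype=float),
                exposure_length=float(e["exposure_length"]),
                radius=float(e.get("radius", 0.05)),
            )
        )

    acts = []
    for k, a in enumerate(doc["plan"]):
        _require(0 < a["voltage"] <= VOLTAGE_CAP,
                 f"plan[{k}].voltage must be in (0, {VOLTAGE_CAP:.0f}] V, "
                 f"got {a['voltage']}")
        _require(a["spacing"] > 0, f"plan[{k}].spacing (cm) must be > 0")
        acts.append(PairActivation(int(a["source"]), int(a["sink"]),
                                   float(a["voltage"]), float(a["spacing"])))
    plan = TreatmentPlan(activations=tuple(
        sorted(acts, key=lambda a: (-a.voltage, -a.spacing, a.source, a.sink))))

    tis = doc.get("tissue", {})
    tissue = TissueModel(sigma0=tis.get("sigma0", 0.284),
                         sigma_max=tis.get("sigma0", 0.284),
                         e_center=tis.get("e_center", 500.0),
                         e_width=tis.get("e_width", 800.0), mode="dynamic")

    meas = doc.get("measurements", {})
    current = meas.get("measured_current")
    if current is not None:
        _require(current > 0, "measurements.measured_current (A) must be > 0")
    volume = meas.get("target_volume")
    if volume is not None:
        _require(volume > 0, "measurements.target_volume (cm^3) must be > 0")

    return PatientInputs(
        patient_id=doc.get("patient_id", "?"),
        domain=domain,
        electrodes=electrodes,
        plan=plan,
        tissue=tissue,
        measured_current=current,
        target_volume=volume,
        psa_pre=meas.get("psa_pre"),
        delta_current=meas.get("delta_current"),
        truth=doc.get("truth"),
    )


def save_mask_nifti(mask: AblationMask, path) -> None:
    """Write a binary mask as NIfTI; the affine carries the voxel spacing."""
    h = mask.domain.spacing
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = mask.domain.axis_centers()[0] + mask.domain.origin
    img = nib.Nifti1Image(mask.occupancy.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask_nifti(path, domain: SimulationDomain | None = None) -> AblationMask:
    """Read a binary voxel mask; the domain is rebuilt from the affine."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj) > 0
    if domain is None:
        zooms = img.header.get_zooms()[:3]
        _require(np.allclose(zooms, zooms[0], rtol=1e-6),
                 "mask voxels must be isotropic")
        _require(len(set(data.shape)) == 1, "mask grid must be cubic")
        domain = make_domain(float(zooms[0]) * data.shape[0], data.shape[0])
    return AblationMask(domain, data)


def save_field_vtk(field: np.ndarray, domain: SimulationDomain, path,
                   name: str = "field") -> None:
    """Export a voxel scalar field as a legacy ASCII VTK structured-points file."""
    n = domain.resolution
    h = domain.spacing
    org = domain.axis_centers()[0] + domain.origin
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(f"{name}\nASCII\nDATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {n} {n} {n}\n")
        f.write(f"ORIGIN {org[0]} {org[1]} {org[2]}\n")
        f.write(f"SPACING {h} {h} {h}\n")
        f.write(f"POINT_DATA {n**3}\n")
        f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
        # VTK structured points vary x fastest
        np.savetxt(f, field.transpose(2, 1, 0).reshape(-1, n), fmt="%.6g")
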