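"""Static and dynamic (electroporation-dependent) tissue conductivity.

Electroporation opens conductive pores in cell membranes, so bulk tissue
conductivity rises with the local electric-field magnitude.  The dynamic law
used here is a smoothed step: baseline ``sigma0`` below the transition zone,
fully-electroporated ``sigma_max`` above it, joined over a transition of
width ``e_width`` centered at ``e_center`` by a polynomial smoothstep with a
continuous second derivative.  The static law ignores the field and returns
``sigma0`` everywhere.

Defaults: sigma0 = 0.284 S/m (low-voltage pre-pulse measurement in normal
prostate), transition 800 V/cm wide centered at 500 V/cm.  ``sigma_max`` is
patient-specific and is calibrated from the delivered current (see
:mod:`ireplan.inverse`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TissueModel", "sigma_of_e", "smoothstep_quintic"]

SIGMA0_DEFAULT = 0.284  # S/m
E_CENTER_DEFAULT = 500.0  # V/cm
E_WIDTH_DEFAULT = 800.0  # V/cm


def smoothstep_quintic(t: np.ndarray) -> np.ndarray:
    """Quintic smoothstep 6t^5 - 15t^4 + 10t^3 on [0, 1].

    The minimal-order polynomial with s(0)=0, s(1)=1 and first AND second
    derivatives vanishing at both ends, giving the conductivity law C^2
    continuity across the transition edges.
    """
    t = np.clip(t, 0.0, 1.0)
    return t * t * t * (t * (6.0 * t - 15.0) + 10.0)


@dataclass(frozen=True)
class TissueModel:
    """Tissue conductivity law.

    mode="static" uses ``sigma0`` regardless of field; mode="dynamic" applies
    the smoothed step from ``sigma0`` to ``sigma_max``.
    """

    sigma0: float = SIGMA0_DEFAULT
    sigma_max: float = SIGMA0_DEFAULT
    e_center: float = E_CENTER_DEFAULT
    e_width: float = E_WIDTH_DEFAULT
    mode: str = "dynamic"

    def __post_init__(self):
        if not self.sigma0 > 0:
            raise ValueError("sigma0 must be > 0")
        if self.sigma_max < self.sigma0:
            raise ValueError("sigma_max must be >= sigma0")
        if not self.e_width > 0:
            raise ValueError("e_width must be > 0")
        if self.e_center - self.e_width / 2.0 < 0:
            raise ValueError("lower transition edge must be >= 0 V/cm")
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"mode must be 'static' or 'dynamic', got {self.mode!r}")

    def with_sigma_max(self, sigma_max: float) -> "TissueModel":
        return TissueModel(self.sigma0, sigma_max, self.e_center, self.e_width,
                           self.mode)

    @property
    def is_dynamic(self) -> bool:
        return self.mode == "dynamic"


def sigma_of_e(e_mag, model: TissueModel):
    """Tissue conductivity (S/m) at field magnitude ``e_mag`` (V/cm).

    Vectorized over ``e_mag``; scalar in, scalar out.
    """
    e = np.asarray(e_mag, dtype=float)
    if np.any(e < 0):
        raise ValueError("field magnitude must be >= 0")
    if model.mode == "static":
        out = np.full_like(e, model.sigma0)
        return float(out) if np.isscalar(e_mag) else out
    lower = model.e_center - model.e_width / 2.0
    t = (e - lower) / model.e_width
    s = smoothstep_quintic(t)
    out = model.sigma0 + (model.sigma_max - model.sigma0) * s
    return float(out) if np.isscalar(e_mag) else out
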