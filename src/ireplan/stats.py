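"""Correlation statistics and the transmembrane-potential utility.

Reproduces the study-level statistics from the clinical treatment table:
pairwise Pearson correlations between pre-treatment PSA, change in
delivered current, ablation volume, and the inferred lethal field
threshold, with two-sided p-values and retrospective (observed) power.

Power follows the retrospective convention of commercial stats packages:
the noncentral-F probability of exceeding the alpha-level critical value
with noncentrality equal to the observed F statistic,
F = (n-2) r^2 / (1 - r^2) on (1, n-2) degrees of freedom.  A Fisher-z
approximation is available as an alternative method.

Also includes the steady-state Schwan estimate of the maximum induced
transmembrane potential of a spherical cell, TMP_max = 1.5 E r: at fixed
field, larger cells polarize more, which is the physical argument for a
size-dependent (hence possibly PSA-correlated) lethal threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import PatientRecord

__all__ = [
    "CorrelationReport",
    "CellModel",
    "pearson",
    "posthoc_power",
    "reproduce_table2",
    "tmp_max",
]


@dataclass(frozen=True)
class CorrelationReport:
    x_label: str
    y_label: str
    r: float
    p: float  # two-sided
    power: float  # fraction in [0, 1]
    n: int

    def __post_init__(self):
        if not (abs(self.r) <= 1 and 0 <= self.p <= 1 and 0 <= self.power <= 1):
            raise ValueError("correlation report fields out of range")
        if self.n < 3:
            raise ValueError("need n >= 3")


@dataclass(frozen=True)
class CellModel:
    """Spherical cell for the Schwan transmembrane-potential estimate."""

    radius: float  # m

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError("cell radius must be > 0")


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t transform, n-2 dof)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def posthoc_power(r: float, n: int, alpha: float = 0.05,
                  method: str = "observed-f") -> float:
    """Retrospective power of the two-sided Pearson test at effect size r.

    method="observed-f": noncentral F with noncentrality equal to the
    observed F statistic (the convention behind printed retrospective-power
    columns).  method="fisher": Fisher z approximation,
    z = atanh(r), SE = 1/sqrt(n-3).
    """
    if not abs(r) < 1:
        raise ValueError("need |r| < 1")
    if n < 4:
        raise ValueError("need n >= 4")
    if method == "observed-f":
        f_obs = (n - 2) * r**2 / (1 - r**2)
        f_crit = sps.f.ppf(1 - alpha, 1, n - 2)
        return float(sps.ncf.sf(f_crit, 1, n - 2, f_obs))
    if method == "fisher":
        delta = np.arctanh(abs(r)) * np.sqrt(n - 3)
        z_a = sps.norm.ppf(1 - alpha / 2)
        return float(sps.norm.sf(z_a - delta) + sps.norm.cdf(-z_a - delta))
    raise ValueError(f"unknown power method {method!r}")


#: the change-in-PSA correlation cannot be recomputed: post-treatment PSA
#: values are not part of the clinical table.
MISSING_ROWS = ("Change in PSA vs Ablation volume (post-treatment PSA not tabulated)",)


def reproduce_table2(records: list[PatientRecord],
                     alpha: float = 0.05) -> list[CorrelationReport]:
    """Correlation table from the clinical records.

    Rows: PSA vs threshold, PSA vs change in current, PSA vs ablation
    volume, threshold vs ablation volume.  The change-in-PSA row of the
    published analysis is omitted (see ``MISSING_ROWS``).
    """
    psa = [rec.psa_pre for rec in records]
    d_i = [rec.delta_current for rec in records]
    thr = [rec.threshold_dynamic for rec in records]
    vol = [rec.ablation_volume for rec in records]
    n = len(records)
    rows = [
        ("Pre-treatment PSA", "Electric field threshold", psa, thr),
        ("Pre-treatment PSA", "Change in current", psa, d_i),
        ("Pre-treatment PSA", "Ablation volume", psa, vol),
        ("Electric field threshold", "Ablation volume", thr, vol),
    ]
    out = []
    for xl, yl, x, y in rows:
        r, p = pearson(x, y)
        out.append(CorrelationReport(xl, yl, r, p, posthoc_power(r, n, alpha), n))
    return out


def tmp_max(e_field: float, cell: CellModel) -> float:
    """Schwan steady-state maximum transmembrane potential, 1.5 E r (V).

    ``e_field`` in V/m, cell radius in m.
    """
    if e_field < 0:
        raise ValueError("field must be >= 0")
    return 1.5 * e_field * cell.radius
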