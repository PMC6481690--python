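"""Electrostatic solver for one electrode-pair activation.

Solves the current-conservation equation div(sigma grad phi) = 0 on the
voxel grid with Dirichlet conditions on the active electrode surfaces
(applied voltage on the source, ground on the sink) and zero normal current
on the outer cube boundary.  With static conductivity this is a single
linear solve; with the dynamic (field-dependent) law the conductivity is
updated by under-relaxed Picard iteration sigma_k = sigma(|E_{k-1}|) until
the delivered current stabilizes.

Discretization: cell-centered finite volumes on the regular grid, 7-point
stencil, harmonic-mean face conductivities.  The scheme is locally
conservative, so the current computed as the discrete flux out of any voxel
region enclosing an electrode is surface-independent up to solver tolerance.

Linear solves use conjugate gradients preconditioned by a spectrally exact
constant-coefficient Poisson inverse (type-II DCT, matching the Neumann
outer boundary); electrode Dirichlet voxels are handled by subspace
embedding.  Everything is matrix-free: the operator is applied with shifted
array arithmetic, so Picard updates cost no re-assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.fft
from scipy.sparse.linalg import LinearOperator, cg

from .conductivity import TissueModel, sigma_of_e
from .geometry import Electrode, GeometryError, SimulationDomain

__all__ = [
    "FieldSolution",
    "SolverError",
    "solve_laplace",
    "solve_pair",
    "pair_current",
    "field_magnitude",
]

CM_TO_M = 0.01

#: conductivity contrast cap for inactive-electrode inclusions (x sigma0).
#: Beyond contrast ~1e3 the solution is insensitive; the cap keeps the
#: linear systems well conditioned.
INACTIVE_CONTRAST_CAP = 1.0e4


class SolverError(RuntimeError):
    """Raised when a linear solve fails to converge."""


def _face_conductances(sigma: np.ndarray, h_cm: float):
    """Harmonic-mean conductance (S) of each interior face along each axis.

    Face conductance = sigma_face * A / d with A = h^2 and d = h (meters),
    i.e. sigma_face * h_m.
    """
    h_m = h_cm * CM_TO_M
    out = []
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        a, b = sigma[tuple(lo)], sigma[tuple(hi)]
        out.append(2.0 * a * b / (a + b) * h_m)
    return out


def _apply_operator(phi: np.ndarray, faces) -> np.ndarray:
    """A phi with A = -div(g grad), Neumann outer boundary (full grid)."""
    out = np.zeros_like(phi)
    for ax, g in enumerate(faces):
        d = g * np.diff(phi, axis=ax)  # g * (phi_hi - phi_lo)
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        out[tuple(lo)] -= d
        out[tuple(hi)] += d
    return out


def _dct_poisson_inverse(n: int, h_cm: float, sigma_ref: float):
    """Inverse of the constant-coefficient Neumann operator via DCT-II.

    Used as a preconditioner; the zero (constant) mode is regularized.
    """
    g0 = sigma_ref * h_cm * CM_TO_M
    k = np.arange(n)
    lam1 = g0 * (2.0 * np.sin(np.pi * k / (2 * n))) ** 2
    lam = lam1[:, None, None] + lam1[None, :, None] + lam1[None, None, :]
    lam.flat[0] = g0 * 1e-6

    def apply(r: np.ndarray) -> np.ndarray:
        rhat = scipy.fft.dctn(r, type=2, norm="ortho")
        rhat /= lam
        return scipy.fft.idctn(rhat, type=2, norm="ortho")

    return apply


def solve_laplace(
    domain: SimulationDomain,
    sigma: np.ndarray,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    *,
    rtol: float = 1e-7,
    maxiter: int = 5000,
    x0: np.ndarray | None = None,
    face_corrections: list[tuple[int, np.ndarray, float]] | None = None,
):
    """Solve div(sigma grad phi) = 0 with fixed-potential voxels.

    Parameters
    ----------
    sigma : (n,n,n) conductivity in S/m.
    dirichlet_mask : bool (n,n,n), True where the potential is imposed.
    dirichlet_values : (n,n,n) potential (V) at the imposed voxels.
    x0 : optional full-grid warm start.
    face_corrections : optional (axis, voxel_mask, factor) triples; the
        conductances of axis-normal faces between ``voxel_mask`` and free
        tissue are scaled by ``factor`` (sub-grid wire correction).

    Returns
    -------
    phi : (n,n,n) potential in V
    info : dict with cg iteration count and face conductances
    """
    n = domain.resolution
    if not dirichlet_mask.any():
        raise SolverError("no Dirichlet voxels: the electrostatic problem is singular")
    faces = _face_conductances(sigma, domain.spacing)
    # The imposed potential lives on the conductor SURFACE, i.e. on the voxel
    # faces bounding the Dirichlet region: the free-side path is half a cell,
    # so Dirichlet-adjacent face conductances double.
    for ax in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        boundary = dirichlet_mask[tuple(lo)] ^ dirichlet_mask[tuple(hi)]
        faces[ax][boundary] *= 2.0
    for ax, vmask, factor in face_corrections or ():
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        fmask = (vmask[tuple(lo)] & ~dirichlet_mask[tuple(hi)]) | (
            vmask[tuple(hi)] & ~dirichlet_mask[tuple(lo)])
        faces[ax][fmask] *= factor
    free = ~dirichlet_mask
    free_idx = free.ravel()

    phi_d = np.where(dirichlet_mask, dirichlet_values, 0.0)
    rhs_full = -_apply_operator(phi_d, faces)
    b = rhs_full.ravel()[free_idx]

    shape3 = domain.shape

    def matvec(x):
        full = np.zeros(n**3)
        full[free_idx] = x
        out = _apply_operator(full.reshape(shape3), faces)
        return out.ravel()[free_idx]

    pinv = _dct_poisson_inverse(n, domain.spacing, float(np.median(sigma[free])))

    def precond(r):
        full = np.zeros(n**3)
        full[free_idx] = r
        out = pinv(full.reshape(shape3))
        return out.ravel()[free_idx]

    nfree = int(free_idx.sum())
    A = LinearOperator((nfree, nfree), matvec=matvec)
    M = LinearOperator((nfree, nfree), matvec=precond)

    iters = [0]

    def cb(_):
        iters[0] += 1

    x0_free = None if x0 is None else np.asarray(x0).ravel()[free_idx]
    x, code = cg(A, b, x0=x0_free, rtol=rtol, atol=0.0, maxiter=maxiter, M=M,
                 callback=cb)
    if code != 0:
        raise SolverError(
            f"conjugate gradients did not converge (code {code}, "
            f"{iters[0]} iterations, rtol {rtol})"
        )
    phi = phi_d.copy()
    phi.ravel()[free_idx.nonzero()[0]] = x
    return phi, {"cg_iterations": iters[0], "faces": faces}


def field_magnitude(phi: np.ndarray, domain: SimulationDomain) -> np.ndarray:
    """|E| = |grad phi| in V/cm (central differences, one-sided at edges)."""
    gx, gy, gz = np.gradient(phi, domain.spacing)
    return np.sqrt(gx * gx + gy * gy + gz * gz)


def region_current(phi: np.ndarray, faces, region: np.ndarray) -> float:
    """Net conduction current (A) flowing out of a voxel region.

    Sums the discrete face fluxes g * (phi_in - phi_out) over the closed
    surface of voxel faces separating ``region`` from its complement.
    """
    total = 0.0
    for ax, g in enumerate(faces):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[ax] = slice(0, -1)
        hi[ax] = slice(1, None)
        r_lo, r_hi = region[tuple(lo)], region[tuple(hi)]
        dphi = phi[tuple(lo)] - phi[tuple(hi)]  # in - out when region is lo
        out_faces = r_lo & ~r_hi
        in_faces = ~r_lo & r_hi
        total += float((g[out_faces] * dphi[out_faces]).sum())
        total -= float((g[in_faces] * dphi[in_faces]).sum())
    return total


@dataclass
class FieldSolution:
    """Converged solution of one electrode-pair activation."""

    phi: np.ndarray  # V
    e_mag: np.ndarray  # V/cm
    sigma: np.ndarray  # S/m
    source_current: float  # A
    sink_current: float  # A
    iterations: int  # Picard iterations (1 for static)
    cg_iterations: int  # cumulative linear-solver iterations
    converged: bool
    source_mask: np.ndarray | None = None
    sink_mask: np.ndarray | None = None

    @property
    def current_imbalance(self) -> float:
        """|I_source - I_sink| / I_source."""
        return abs(self.source_current - self.sink_current) / abs(self.source_current)


def pair_current(solution: FieldSolution, which: str = "source") -> float:
    """Delivered current (A) of the pair, from the stored flux integrals."""
    if which == "source":
        return solution.source_current
    if which == "sink":
        return solution.sink_current
    raise ValueError("which must be 'source' or 'sink'")


def electrode_masks(domain: SimulationDomain,
                    electrodes: list[Electrode]) -> list[np.ndarray]:
    """Rasterize every electrode once (reusable across repeated solves)."""
    return [e.rasterize(domain) for e in electrodes]


def solve_pair(
    domain: SimulationDomain,
    electrodes: list[Electrode],
    active_pair: tuple[int, int],
    voltage: float,
    model: TissueModel,
    *,
    relaxation: float = 0.8,
    current_rtol: float = 1e-3,
    max_picard: int = 100,
    cg_rtol: float = 1e-6,
    include_inactive: bool = True,
    x0: np.ndarray | None = None,
    sigma_init: np.ndarray | None = None,
    masks: list[np.ndarray] | None = None,
) -> FieldSolution:
    """Solve one pair activation (source at ``voltage`` V, sink grounded).

    Active electrodes are imposed as equipotential Dirichlet voxel sets
    (metal at 2e6 S/m is equipotential to machine precision).  Inactive
    electrodes are retained as conductive inclusions with conductivity
    capped at ``INACTIVE_CONTRAST_CAP * sigma0`` unless ``include_inactive``
    is False.

    In dynamic mode the conductivity is iterated: sigma(|E|) with
    under-relaxation ``relaxation``, stopping when the relative change of
    the source current drops below ``current_rtol`` (or ``max_picard``
    iterations, in which case the solution is returned flagged
    unconverged).

    ``x0`` and ``sigma_init`` warm-start the potential and the tissue
    conductivity (e.g. from a nearby solve during calibration); they change
    only the iteration path, not the converged solution.
    """
    i_src, i_snk = active_pair
    if i_src == i_snk:
        raise ValueError("active pair must name two distinct electrodes")
    if not voltage > 0:
        raise ValueError("voltage must be > 0")

    if masks is None:
        masks = electrode_masks(domain, electrodes)
    src_mask, snk_mask = masks[i_src], masks[i_snk]
    if (src_mask & snk_mask).any():
        raise GeometryError("source and sink electrodes overlap on the grid")
    dir_mask = src_mask | snk_mask
    dir_vals = np.where(src_mask, float(voltage), 0.0)

    # Sub-grid wire correction: when the physical radius is below the grid
    # spacing the rasterized column is artificially thick, and the current
    # of a cylinder electrode depends logarithmically on its radius.  The
    # lateral Dirichlet-face conductances are rescaled so the tissue
    # resistance from the wire surface (radius r_w) to the neighbor cell
    # center matches radial flow through a quarter annulus:
    # g = sigma * h * (pi/2) / ln(h / r_w), in place of the default 2*sigma*h.
    h = domain.spacing
    corrections = []
    for idx in (i_src, i_snk):
        e = electrodes[idx]
        if e.radius < h:
            factor = (np.pi / 2) / (2.0 * np.log(h / e.radius))
            for ax in range(3):
                if abs(e.axis[ax]) < 0.7:  # face normal ~perpendicular to wire
                    corrections.append((ax, masks[idx], factor))

    if sigma_init is not None:
        sigma_tissue = np.clip(sigma_init, model.sigma0, max(model.sigma_max,
                                                             model.sigma0))
    else:
        sigma_tissue = np.full(domain.shape, model.sigma0)
    inactive = np.zeros(domain.shape, dtype=bool)
    if include_inactive:
        for j, m in enumerate(masks):
            if j not in (i_src, i_snk):
                inactive |= m

    def compose(sig_tissue):
        sig = sig_tissue.copy()
        if inactive.any():
            cap = INACTIVE_CONTRAST_CAP * model.sigma0
            sig[inactive] = min(cap, electrodes[0].conductivity)
        return sig

    total_cg = 0
    phi, info = solve_laplace(domain, compose(sigma_tissue), dir_mask, dir_vals,
                              rtol=cg_rtol, x0=x0,
                              face_corrections=corrections)
    total_cg += info["cg_iterations"]
    current = region_current(phi, info["faces"], src_mask)

    iterations = 1
    converged = True
    if model.is_dynamic:
        converged = False
        for iterations in range(2, max_picard + 2):
            e_mag = field_magnitude(phi, domain)
            target = sigma_of_e(e_mag, model)
            sigma_tissue = sigma_tissue + relaxation * (target - sigma_tissue)
            phi, info = solve_laplace(domain, compose(sigma_tissue), dir_mask,
                                      dir_vals, rtol=cg_rtol, x0=phi,
                                      face_corrections=corrections)
            total_cg += info["cg_iterations"]
            new_current = region_current(phi, info["faces"], src_mask)
            rel = abs(new_current - current) / abs(new_current)
            current = new_current
            if rel < current_rtol:
                converged = True
                break

    faces = info["faces"]
    i_src_val = region_current(phi, faces, src_mask)
    i_snk_val = -region_current(phi, faces, snk_mask)
    return FieldSolution(
        phi=phi,
        e_mag=field_magnitude(phi, domain),
        sigma=compose(sigma_tissue),
        source_current=i_src_val,
        sink_current=i_snk_val,
        iterations=iterations if model.is_dynamic else 1,
        cg_iterations=total_cg,
        converged=converged,
        source_mask=src_mask,
        sink_mask=snk_mask,
    )
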