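import numpy as np
import pytest

import ireplan as ir
from ireplan.conductivity import TissueModel
from ireplan.solver import (
    SolverError,
    electrode_masks,
    field_magnitude,
    region_current,
    solve_laplace,
    solve_pair,
)

SIGMA0 = 0.284
STATIC = TissueModel(sigma0=SIGMA0, mode="static")


def plate_problem(domain, voltage=100.0, sigma=SIGMA0):
    """Two opposite cube faces as 1-voxel-slab electrodes."""
    sig = np.full(domain.shape, sigma)
    dm = np.zeros(domain.shape, bool)
    dv = np.zeros(domain.shape)
    dm[0] = True
    dv[0] = voltage
    dm[-1] = True
    return sig, dm, dv


def plate_gap(domain):
    # imposed potential sits on the inner faces of the electrode slabs
    return domain.edge_length - 2 * domain.spacing


class TestAnalyticSurrogates:
    def test_parallel_plate_field_and_current(self, small_domain):
        sig, dm, dv = plate_problem(small_domain)
        phi, info = solve_laplace(small_domain, sig, dm, dv, rtol=1e-10)
        d = plate_gap(small_domain)
        e = field_magnitude(phi, small_domain)[2:-2]
        assert np.allclose(e, 100.0 / d, rtol=1e-3)
        source = np.zeros(small_domain.shape, bool)
        source[0] = True
        current = region_current(phi, info["faces"], source)
        analytic = SIGMA0 * 100.0 * 0.075**2 / (d * 0.01)
        assert current == pytest.approx(analytic, rel=1e-3)

    def test_current_linear_in_sigma_and_voltage(self, small_domain):
        results = {}
        for scale_s, scale_v in [(1, 1), (2, 1), (1, 3)]:
            sig, dm, dv = plate_problem(
                small_domain, voltage=100.0 * scale_v, sigma=SIGMA0 * scale_s
            )
            phi, info = solve_laplace(small_domain, sig, dm, dv, rtol=1e-10)
            src = np.zeros(small_domain.shape, bool)
            src[0] = True
            results[(scale_s, scale_v)] = region_current(phi, info["faces"], src)
        assert results[(2, 1)] == pytest.approx(2 * results[(1, 1)], rel=1e-9)
        assert results[(1, 3)] == pytest.approx(3 * results[(1, 1)], rel=1e-9)

    def test_concentric_cylinders(self):
        # radial Laplace problem: phi(r) = V ln(b/r)/ln(b/a)
        dom = ir.make_domain(7.5, 64)
        x, y, _ = dom.centers()
        r = np.sqrt(x**2 + y**2)
        a, b, volt = 1.0, 3.0, 100.0
        dm = (r <= a) | (r >= b)
        dv = np.where(r <= a, volt, 0.0)
        sig = np.full(dom.shape, SIGMA0)
        phi, info = solve_laplace(dom, sig, dm, dv, rtol=1e-9)
        current = region_current(phi, info["faces"], r <= a)
        analytic = 2 * np.pi * SIGMA0 * 0.075 * volt / np.log(b / a)
        assert current == pytest.approx(analytic, rel=0.03)
        mid = dom.resolution // 2
        for i in np.flatnonzero((dom.axis_centers() > 1.3) & (dom.axis_centers() < 2.7)):
            rr = dom.axis_centers()[i]
            expected = volt * np.log(b / rr) / np.log(b / a)
            assert phi[i, mid, mid] == pytest.approx(expected, abs=0.03 * volt)


class TestFieldMagnitude:
    def test_linear_ramp(self, tiny_domain):
        x, _, _ = tiny_domain.centers()
        phi = 100.0 * x  # 100 V per cm
        assert np.allclose(field_magnitude(phi, tiny_domain), 100.0, rtol=1e-12)

    def test_constant_potential(self, tiny_domain):
        assert np.all(field_magnitude(np.ones(tiny_domain.shape), tiny_domain) == 0)

    def test_quadratic_truncation_order(self):
        # phi = x^2 -> |E| = 2|x|; central-difference error is O(h^2),
        # and for a pure quadratic it vanishes identically in the interior
        errs = {}
        for res in (16, 32):
            dom = ir.make_domain(7.5, res)
            x, _, _ = dom.centers()
            e = field_magnitude(x**2, dom)
            errs[res] = np.abs(e - 2 * np.abs(x))[1:-1].max()
        assert errs[16] < 1e-10 and errs[32] < 1e-10


@pytest.fixture(scope="module")
def static_solution(small_domain, square_electrodes):
    plan = ir.make_plan(square_electrodes)
    act = plan.first_pair
    return act, solve_pair(
        small_domain, square_electrodes, (act.source, act.sink),
        act.voltage, STATIC,
    )


class TestPairSolve:

    def test_maximum_principle(self, static_solution):
        act, sol = static_solution
        assert sol.phi.min() >= -1e-6 * act.voltage
        assert sol.phi.max() <= act.voltage * (1 + 1e-6)

    def test_current_conservation(self, static_solution):
        _, sol = static_solution
        assert sol.current_imbalance < 0.01

    def test_source_sink_labels(self, static_solution):
        _, sol = static_solution
        assert ir.pair_current(sol, "source") == sol.source_current
        assert ir.pair_current(sol, "sink") == sol.sink_current
        with pytest.raises(ValueError):
            ir.pair_current(sol, "both")

    def test_polarity_swap_leaves_magnitude(self, small_domain, square_electrodes):
        plan = ir.make_plan(square_electrodes)
        act = plan.first_pair
        fwd = solve_pair(small_domain, square_electrodes,
                         (act.source, act.sink), act.voltage, STATIC,
                         cg_rtol=1e-10)
        rev = solve_pair(small_domain, square_electrodes,
                         (act.sink, act.source), act.voltage, STATIC,
                         cg_rtol=1e-10)
        scale = np.abs(fwd.e_mag).max()
        assert np.allclose(fwd.e_mag, rev.e_mag, atol=1e-6 * scale)

    def test_degenerate_dynamic_equals_static_bitwise(self, small_domain,
                                                      square_electrodes):
        plan = ir.make_plan(square_electrodes)
        act = plan.first_pair
        pair = (act.source, act.sink)
        st_sol = solve_pair(small_domain, square_electrodes, pair, act.voltage,
                            STATIC)
        dyn0 = TissueModel(sigma0=SIGMA0, sigma_max=SIGMA0, mode="dynamic")
        dyn_sol = solve_pair(small_domain, square_electrodes, pair, act.voltage,
                             dyn0)
        assert np.array_equal(st_sol.phi, dyn_sol.phi)
        assert dyn_sol.source_current == st_sol.source_current
        assert dyn_sol.iterations == 2  # one static solve + one fixed-point check

    def test_dynamic_current_superlinear_in_voltage(self, square_electrodes):
        dom = ir.make_domain(7.5, 24)
        dyn = TissueModel(sigma0=SIGMA0, sigma_max=0.9)
        plan = ir.make_plan(square_electrodes)
        act = plan.first_pair
        ratios = []
        for v in (500.0, 1500.0, 3000.0):
            sol = solve_pair(dom, square_electrodes, (act.source, act.sink), v,
                             dyn)
            ratios.append(sol.source_current / v)
        assert ratios[0] < ratios[1] < ratios[2]

    def test_dynamic_current_monotone_in_sigma_max(self, square_electrodes):
        dom = ir.make_domain(7.5, 16)
        plan = ir.make_plan(square_electrodes)
        act = plan.first_pair
        currents = []
        for smax in np.linspace(SIGMA0, 1.5, 10):
            sol = solve_pair(dom, square_electrodes, (act.source, act.sink),
                             act.voltage, TissueModel(sigma0=SIGMA0,
                                                      sigma_max=float(smax)))
            currents.append(sol.source_current)
        assert all(a <= b + 1e-9 for a, b in zip(currents, currents[1:]))

    def test_grid_convergence_of_current(self):
        # grid-resolved electrode radius: the continuum limit is fixed, so
        # successive refinements must bring the current differences down
        els = ir.place_electrode_grid(4, 1.8, 1.5, radius=0.35)
        plan = ir.make_plan(els)
        act = plan.first_pair
        currents = {}
        for res in (24, 48, 96):
            dom = ir.make_domain(7.5, res)
            sol = solve_pair(dom, els, (act.source, act.sink),
                             act.voltage, STATIC, cg_rtol=1e-9)
            currents[res] = sol.source_current
        d1 = abs(currents[48] - currents[24])
        d2 = abs(currents[96] - currents[48])
        assert d2 < d1

    def test_invalid_inputs(self, small_domain, square_electrodes):
        with pytest.raises(ValueError):
            solve_pair(small_domain, square_electrodes, (1, 1), 3000.0, STATIC)
        with pytest.raises(ValueError):
            solve_pair(small_domain, square_electrodes, (0, 1), -5.0, STATIC)
        with pytest.raises(SolverError):
            solve_laplace(small_domain, np.full(small_domain.shape, SIGMA0),
                          np.zeros(small_domain.shape, bool),
                          np.zeros(small_domain.shape))

    def test_inactive_electrode_contrast_insensitivity(self, square_electrodes):
        """Beyond ~1e3 contrast the inclusions no longer change the current."""
        import ireplan.solver as solver_mod

        dom = ir.make_domain(7.5, 24)
        plan = ir.make_plan(square_electrodes)
        act = plan.first_pair
        currents = {}
        for cap in (1e3, 1e4):
            old = solver_mod.INACTIVE_CONTRAST_CAP
            solver_mod.INACTIVE_CONTRAST_CAP = cap
            try:
                sol = solve_pair(dom, square_electrodes,
                                 (act.source, act.sink), act.voltage, STATIC,
                                 cg_rtol=1e-9)
            finally:
                solver_mod.INACTIVE_CONTRAST_CAP = old
            currents[cap] = sol.source_current
        assert currents[1e4] == pytest.approx(currents[1e3], rel=1e-3)

    def test_masks_precomputation_equivalent(self, small_domain,
                                             square_electrodes):
        plan = ir.make_plan(square_electrodes)
        act = plan.first_pair
        masks = electrode_masks(small_domain, square_electrodes)
        a = solve_pair(small_domain, square_electrodes, (act.source, act.sink),
                       act.voltage, STATIC)
        b = solve_pair(small_domain, square_electrodes, (act.source, act.sink),
                       act.voltage, STATIC, masks=masks)
        assert np.array_equal(a.phi, b.phi)
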