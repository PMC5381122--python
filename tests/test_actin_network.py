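"""Network mechanics: WLC law, construction, relaxation, strain readouts."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from cytostretch import (
    KB,
    ActinNetwork,
    LoadSpec,
    NetworkParams,
    RelaxConfig,
    abp_force,
    build_network,
    contour_length,
    make_load,
    network_forces,
    relax_network,
    simulate_stretch_curve,
    strain_of,
    vertex_force,
    wlc_force,
)

_UM = 1e-6


def two_vertex_network(
    lc_um: float = 1.0, lp_um: float = 10.0, delta_r0: float = 0.0, k_c: float = 1e-3
) -> ActinNetwork:
    """Minimal fixture: one WLC filament along z at its rest length."""
    params = NetworkParams(
        N_AF=1, L_p=lp_um, delta_r0=delta_r0, k_c=k_c,
        # choose C_AF so the derived contour length equals lc_um
        C_AF=math.pi * (800 * 10**0.2 * 7e-3 / 2 / lc_um) ** 2,
    )
    assert params.contour_length_um == pytest.approx(lc_um)
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, lc_um * _UM]])
    return ActinNetwork(
        vertices=pos,
        filament_edges=np.array([[0, 1]]),
        filament_rest=np.array([lc_um * _UM]),
        abp_edges=np.empty((0, 2), dtype=np.int64),
        abp_rest=np.empty(0),
        pole_plus=np.array([1]),
        pole_minus=np.array([0]),
        params=params,
        rng_seed=0,
        core=np.array([0, 1]),
    )


class TestContourLength:
    def test_unit_crosslink_density_drops_r_term(self):
        base = contour_length(1.0, 7.0, 15.0)
        assert base == pytest.approx(800 * (7e-3 / 2) * math.sqrt(math.pi / 15))

    def test_doubling_concentration_divides_by_sqrt2(self):
        a = contour_length(2.0, 7.0, 15.0)
        b = contour_length(2.0, 7.0, 30.0)
        assert a / b == pytest.approx(math.sqrt(2.0))

    def test_direct_arithmetic_value(self):
        got = contour_length(2.0, 7.0, 15.0)
        expected = 800.0 * 2.0**0.2 * (7.0e-3 / 2.0) * math.sqrt(math.pi / 15.0)
        assert got == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        for bad in [(0, 7, 15), (2, -1, 15), (2, 7, 0)]:
            with pytest.raises(ValueError):
                contour_length(*bad)


class TestWlcForce:
    def test_zero_at_zero_total_extension(self):
        assert wlc_force(0.0, 0.0, 10.0, 1.0) == 0.0
        # pre-extension cancelled by compression
        assert wlc_force(-0.005, 0.005, 10.0, 1.0) == pytest.approx(0.0, abs=1e-30)

    def test_strictly_increasing_and_continuous_through_zero(self):
        limit = 1.0**2 / (6 * 10.0)
        xs = np.linspace(-0.3 * limit, 0.95 * limit, 200)
        fs = [wlc_force(x, 0.0, 10.0, 1.0) for x in xs]
        assert np.all(np.diff(fs) > 0)
        assert abs(wlc_force(1e-12, 0.0, 10.0, 1.0)) < 1e-18

    def test_divergence_at_extension_limit(self):
        limit = 1.0**2 / (6 * 10.0)  # um
        f_near = wlc_force(limit * (1 - 1e-6), 0.0, 10.0, 1.0)
        assert f_near > 1e3 * wlc_force(limit * 0.5, 0.0, 10.0, 1.0)
        with pytest.raises(ValueError, match="extension limit"):
            wlc_force(limit, 0.0, 10.0, 1.0)
        # pre-extension shifts the limit
        with pytest.raises(ValueError):
            wlc_force(limit - 0.004, 0.005, 10.0, 1.0)

    def test_value_matches_independent_symbolic_evaluation(self):
        import sympy as sp

        dr, lp, lc, T = sp.Rational(1, 100), sp.Integer(10), sp.Integer(1), 300
        kb = sp.Float(KB, 30)
        um = sp.Rational(1, 10**6)
        x, lp_m, lc_m = dr * um, lp * um, lc * um
        expr = (
            81 * kb * T * lp_m**2 * lc_m**2 * x
            / ((lc_m**2 - 6 * lp_m * x) ** 2 * (lc_m**2 + 3 * lp_m * x))
        )
        expected = float(sp.N(expr, 30))
        assert wlc_force(0.01, 0.0, 10.0, 1.0, 300.0) == pytest.approx(
            expected, rel=1e-12
        )


class TestAbpForce:
    def test_linearity_and_direct_product(self):
        assert abp_force(0.0, 1e-5) == 0.0
        assert abp_force(0.2, 1e-5) == 2 * abp_force(0.1, 1e-5)
        assert abp_force(0.1, 1e-5) == pytest.approx(1e-12)


class TestBuildNetwork:
    def test_deterministic_for_fixed_seed(self):
        p = NetworkParams(N_AF=100)
        a = build_network(p, 5)
        b = build_network(p, 5)
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.filament_edges, b.filament_edges)
        assert np.array_equal(a.abp_edges, b.abp_edges)
        c = build_network(p, 6)
        assert not np.array_equal(a.vertices, c.vertices)

    def test_single_filament(self):
        net = build_network(NetworkParams(N_AF=1), 0)
        assert len(net.filament_edges) == 1
        assert len(net.abp_edges) == 0

    def test_shell_radii_and_crosslink_density(self):
        p = NetworkParams(R_E=7.02, R_I=6.21, N_AF=500, R=5.0)
        net = build_network(p, 9)
        radii = np.linalg.norm(net.vertices, axis=1) / _UM
        assert radii.min() >= 6.21 - 1e-9
        assert radii.max() <= 7.02 + 1e-9
        target = 5.0 * 500
        assert abs(len(net.abp_edges) - target) / target < 0.05
        # filament lengths equal the derived contour length
        d = np.linalg.norm(
            net.vertices[net.filament_edges[:, 1]]
            - net.vertices[net.filament_edges[:, 0]],
            axis=1,
        )
        assert np.allclose(d, p.contour_length_um * _UM)

    def test_infeasible_geometry_raises(self):
        # contour length far larger than the shell diameter
        p = NetworkParams(R_E=1.0, R_I=0.9, N_AF=5, C_AF=0.01)
        assert p.contour_length_um > 2.0
        with pytest.raises(Exception, match="cannot place"):
            build_network(p, 0)


class TestVertexForce:
    def test_rest_state_has_zero_force(self):
        net = two_vertex_network()
        assert np.allclose(network_forces(net), 0.0)
        assert np.allclose(vertex_force(net, 0), 0.0)

    def test_index_validation(self):
        net = two_vertex_network()
        with pytest.raises(IndexError):
            vertex_force(net, 7)

    def test_internal_forces_cancel_pairwise(self):
        net = build_network(NetworkParams(N_AF=60), 2)
        rng = np.random.default_rng(0)
        jittered = dataclasses.replace(
            net, vertices=net.vertices + rng.normal(0, 5e-9, net.vertices.shape)
        )
        total = network_forces(jittered).sum(axis=0)
        scale = np.linalg.norm(network_forces(jittered), axis=1).max()
        assert np.linalg.norm(total) < 1e-9 * scale
        # with an external load the sum equals the (zero) net load
        load = make_load(jittered, 1e-9)
        total_loaded = network_forces(jittered, load).sum(axis=0)
        assert np.linalg.norm(total_loaded) < 1e-9 * scale + 1e-24


class TestRelaxation:
    def test_zero_load_zero_prestress_is_already_equilibrium(self):
        net = two_vertex_network(delta_r0=0.0)
        res = relax_network(net, make_load(net, 0.0))
        assert res.converged
        assert np.allclose(res.network.vertices, net.vertices)

    def test_two_vertex_equilibrium_matches_bisection_root(self):
        f_ext = 2e-12  # N, axial pull
        net = two_vertex_network(lc_um=1.0, lp_um=10.0)
        cfg = RelaxConfig(force_tolerance=1e-16)
        res = relax_network(net, make_load(net, f_ext), cfg)
        assert res.converged
        got_ext = (
            res.network.vertices[1, 2] - res.network.vertices[0, 2]
        ) / _UM - 1.0
        # independent 1D root of the force-extension law
        expected = brentq(
            lambda dr: wlc_force(dr, 0.0, 10.0, 1.0) - f_ext,
            1e-9,
            (1.0 / 60.0) * (1 - 1e-9),
            xtol=1e-15,
        )
        assert got_ext == pytest.approx(expected, rel=1e-3)

    @pytest.mark.parametrize("method", ["euler", "inertial"])
    def test_dynamics_integrators_agree_with_minimizer(self, method):
        f_ext = 2e-12
        net = two_vertex_network()
        lbfgs = RelaxConfig(force_tolerance=1e-16)
        ref = relax_network(net, make_load(net, f_ext), lbfgs).network
        cfg = RelaxConfig(method=method, time_step=2e-6, max_iterations=300_000,
                          force_tolerance=1e-14)
        res = relax_network(net, make_load(net, f_ext), cfg)
        assert res.converged
        lc = net.filament_rest[0]
        ext_a = ref.vertices[1, 2] - ref.vertices[0, 2] - lc
        ext_b = res.network.vertices[1, 2] - res.network.vertices[0, 2] - lc
        assert ext_b == pytest.approx(ext_a, rel=5e-3)

    def test_converged_run_satisfies_tolerance(self, small_relaxed):
        cfg = RelaxConfig()
        load = make_load(small_relaxed, 0.5e-9)
        res = relax_network(small_relaxed, load, cfg)
        if res.converged:
            assert res.max_residual <= cfg.force_tolerance
        forces = network_forces(res.network, load)
        assert np.linalg.norm(forces, axis=1).max() == pytest.approx(
            res.max_residual
        )

    def test_load_path_independence_for_small_loads(self, small_relaxed):
        direct = relax_network(small_relaxed, make_load(small_relaxed, 0.1e-9))
        stepped_state = small_relaxed
        for f in (0.025e-9, 0.05e-9, 0.1e-9):
            stepped_state = relax_network(
                stepped_state, make_load(small_relaxed, f)
            ).network
        s_direct = strain_of(direct.network, small_relaxed)
        s_stepped = strain_of(stepped_state, small_relaxed)
        assert s_direct == pytest.approx(s_stepped, abs=0.02)

    def test_crosslinks_stiffen_the_network(self, small_params):
        net = build_network(small_params, seed=3)
        ref = relax_network(net, make_load(net, 0.0)).network
        floppy = dataclasses.replace(
            net,
            abp_edges=np.empty((0, 2), dtype=np.int64),
            abp_rest=np.empty(0),
        )
        floppy_ref = relax_network(floppy, make_load(floppy, 0.0)).network
        f = 0.3e-9
        s_linked = strain_of(
            relax_network(ref, make_load(ref, f)).network, ref
        )
        s_floppy = strain_of(
            relax_network(floppy_ref, make_load(floppy_ref, f)).network, floppy_ref
        )
        assert s_floppy >= s_linked


class TestStrain:
    def test_identity_and_affine_stretch(self, small_relaxed):
        assert strain_of(small_relaxed, small_relaxed) == 0.0
        stretched = dataclasses.replace(
            small_relaxed, vertices=small_relaxed.vertices * np.array([1, 1, 1.2])
        )
        assert strain_of(stretched, small_relaxed) == pytest.approx(0.2)

    def test_radius_ratio_consistency(self):
        # (8.61 - 7) / 7 = 0.23: the readout is the relative change of the
        # half-extent along the stretch axis
        net = two_vertex_network(lc_um=14.0, lp_um=140.0)
        deformed = dataclasses.replace(
            net, vertices=net.vertices * np.array([1, 1, 8.61 / 7.0])
        )
        assert strain_of(deformed, net) == pytest.approx(0.23, abs=0.0001)

    def test_topology_mismatch_rejected(self, small_relaxed):
        other = build_network(small_relaxed.params, seed=99)
        with pytest.raises(ValueError):
            strain_of(small_relaxed, other)


class TestStretchCurve:
    def test_zero_force_zero_prestress_gives_zero_strain(self):
        p = NetworkParams(N_AF=60, delta_r0=0.0)
        curve = simulate_stretch_curve(p, np.array([0.0]), replicates=2, seed=1)
        assert curve.strain_mean[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.strain_se[0] == pytest.approx(0.0, abs=1e-12)

    def test_mean_strain_monotone_in_force(self, small_params):
        curve = simulate_stretch_curve(
            small_params, np.array([0.2e-9, 0.6e-9, 1.2e-9]), replicates=3, seed=4
        )
        assert np.all(np.diff(curve.strain_mean) > 0)

    def test_doubling_concentration_stiffens(self):
        # the concentration-stiffening direction is a property of the
        # well-connected regime, so probe it at the full filament count
        from cytostretch.inference import FIT_RELAX

        p = NetworkParams()  # N_AF = 500 study condition
        forces = np.array([0.5e-9, 1e-9, 2e-9])
        lo = simulate_stretch_curve(p, forces, replicates=3, seed=4,
                                    config=FIT_RELAX)
        hi = simulate_stretch_curve(
            dataclasses.replace(p, C_AF=2 * p.C_AF),
            forces, replicates=3, seed=4, config=FIT_RELAX,
        )
        assert np.all(hi.strain_mean <= lo.strain_mean)

    def test_curve_determinism(self, small_params):
        forces = np.array([0.3e-9, 0.8e-9])
        a = simulate_stretch_curve(small_params, forces, replicates=2, seed=7)
        b = simulate_stretch_curve(small_params, forces, replicates=2, seed=7)
        assert np.array_equal(a.strain_mean, b.strain_mean)
        assert np.array_equal(a.strain_se, b.strain_se)

    def test_curve_validation(self):
        from cytostretch import StrainForceCurve

        with pytest.raises(ValueError):
            StrainForceCurve(force=np.array([1e-9, 0.5e-9]), strain_mean=np.zeros(2))
        with pytest.raises(ValueError):
            StrainForceCurve(
                force=np.array([1e-9]), strain_mean=np.zeros(1),
                strain_se=np.array([-0.1]),
            )


class TestLoadSpec:
    def test_balanced_by_construction(self, small_relaxed):
        load = make_load(small_relaxed, 1e-9)
        assert np.abs(load.forces.sum(axis=0)).max() < 1e-18
        plus = load.forces[small_relaxed.pole_plus, 2]
        assert np.allclose(plus, plus[0]) and plus[0] > 0

    def test_unbalanced_load_rejected(self):
        with pytest.raises(ValueError):
            LoadSpec(total_force=1e-9, forces=np.array([[0.0, 0.0, 1e-9]]))
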