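import dataclasses
import math

import numpy as np
import pytest
from scipy.special import erfc

from luminachip.geometry import (
    ChipGeometry,
    LUMEN_LEFT,
    LUMEN_RIGHT,
    MATRIX,
    build_domain_mask,
    build_slab_mask,
)
from luminachip.transport import (
    ConcentrationField,
    SimulationConfig,
    Species,
    StabilityError,
    analytic_slab_solution,
    dextran_10kda,
    dextran_70kda,
    initial_field,
    partition_flux,
    run_scenario,
    simulate_transport,
)


def slab_error(pitch, D=100.0, t=10.0, length=400.0, dt=None):
    if dt is None:
        dt = 0.02 * (pitch / 2.0) ** 2  # keep temporal error subordinate to spatial
    mask = build_slab_mask(length, pitch)
    species = Species("tracer", 10.0, D, D, 1.0)
    config = SimulationConfig(dt=dt, t_end=t, sample_times=(t,))
    res = simulate_transport(mask, species, config)
    numeric = res.field_at(t).values[0, 1:]
    exact = analytic_slab_solution(mask.x[1:], t, D)
    return float(np.abs(numeric - exact).max())


class TestAnalyticSlab:
    def test_boundary_and_far_field(self):
        assert analytic_slab_solution(0.0, 5.0, 100.0) == pytest.approx(1.0)
        assert analytic_slab_solution(1e6, 5.0, 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_similarity_point(self):
        # x = 2√(Dt) → erfc(1)
        D, t = 100.0, 7.0
        x = 2 * math.sqrt(D * t)
        assert analytic_slab_solution(x, t, D) == pytest.approx(erfc(1.0), rel=1e-12)

    def test_invalid_time(self):
        with pytest.raises(ValueError):
            analytic_slab_solution(1.0, 0.0, 100.0)


class TestPartitionFlux:
    def test_equilibrium_is_zero(self):
        for k in (0.05, 0.5, 1.0):
            assert partition_flux(1.0, k, k, 100.0, 5.0) == pytest.approx(0.0, abs=1e-14)

    def test_stated_discrete_form(self):
        assert partition_flux(1.0, 0.0, 1.0, 100.0, 5.0) == pytest.approx(20.0)

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            partition_flux(1.0, 0.0, 0.0, 100.0, 5.0)


class TestSolverAgainstSlabOracle:
    def test_erfc_profile_within_one_percent(self):
        assert slab_error(2.0) < 0.01

    def test_grid_convergence_factor(self):
        e2, e1 = slab_error(2.0), slab_error(1.0)
        assert e2 / e1 >= 1.8

    def test_explicit_matches_implicit(self):
        mask = build_slab_mask(200.0, 4.0)
        species = Species("tracer", 10.0, 100.0, 100.0, 1.0)
        dt = 4.0**2 / (4 * 100.0) * 0.9
        out = {}
        for scheme in ("implicit", "explicit"):
            config = SimulationConfig(dt=dt, t_end=5.0, sample_times=(5.0,), scheme=scheme)
            out[scheme] = simulate_transport(mask, species, config).field_at(5.0).values
        assert np.abs(out["implicit"] - out["explicit"]).max() < 0.02


class TestConservationAndBounds:
    def test_closed_system_mass_conserved_1000_steps(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=2.0, t_end=2000.0, lumen_mode="closed")
        res = simulate_transport(mask10, species, config)
        assert len(res.times) >= 1000
        assert res.mass_drift <= 1e-6

    def test_maximum_principle(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=10.0, t_end=600.0, sample_times=(300.0, 600.0))
        res = simulate_transport(mask10, species, config)
        for f in res.fields:
            active = mask10.labels != 0
            assert f.values[active].min() >= -1e-12
            assert f.values[active].max() <= 1.0 + 1e-9

    def test_uniform_equilibrium_stays_put(self, mask10):
        # k = 1, everything at concentration 1, closed: nothing moves
        species = Species("tracer", 10.0, 100.0, 100.0, 1.0)
        init = initial_field(mask10, 1.0, 1.0, matrix=1.0)
        config = SimulationConfig(dt=20.0, t_end=400.0, lumen_mode="closed", sample_times=(400.0,))
        res = simulate_transport(mask10, species, config, init)
        active = mask10.labels != 0
        assert np.allclose(res.field_at(400.0).values[active], 1.0, atol=1e-10)

    def test_mirror_symmetry(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=10.0, t_end=600.0, sample_times=(600.0,))
        vals = simulate_transport(mask10, species, config).field_at(600.0).values
        assert np.abs(vals - vals[:, ::-1]).max() < 1e-9

    def test_partition_equilibrium_ratio(self, mask10):
        # long closed run: interface concentration ratio approaches k
        for k in (0.05, 0.85):
            species = Species("tracer", 10.0, 100.0, 100.0, k)
            config = SimulationConfig(dt=100.0, t_end=40000.0, lumen_mode="closed",
                                      sample_times=(40000.0,))
            vals = simulate_transport(mask10, species, config).field_at(40000.0).values
            ratios = [vals[b] / vals[a] for a, b in mask10.interface_left]
            assert np.mean(ratios) == pytest.approx(k, rel=0.01)


class TestModesAndScenarios:
    def test_explicit_stability_guard(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=5.0, t_end=100.0, scheme="explicit")
        with pytest.raises(StabilityError, match="dt"):
            simulate_transport(mask10, species, config)

    def test_held_lumen_stays_at_one(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=10.0, t_end=600.0, sample_times=(600.0,))
        vals = simulate_transport(mask10, species, config).field_at(600.0).values
        assert np.allclose(vals[mask10.labels == LUMEN_LEFT], 1.0)

    def test_partition_k_orders_matrix_mass(self, mask10):
        # tighter barrier (k = 0.05) admits less tracer by 30 min
        config = SimulationConfig(dt=10.0, t_end=1800.0, sample_times=(1800.0,))
        masses = {}
        for sp in (dextran_10kda(), dextran_70kda()):
            sp_same_D = dataclasses.replace(sp, D_lumen=100.0, D_matrix=100.0)
            res = simulate_transport(mask10, sp_same_D, config)
            masses[sp.partition_k] = res.field_at(1800.0).compartment_mass(MATRIX)
        assert masses[0.85] > masses[0.05]

    def test_replenished_flow_refills_lumen(self, mask10):
        species = dextran_70kda()
        base = dict(dt=10.0, t_end=1200.0, sample_times=(1200.0,))
        closed = simulate_transport(
            mask10, species, SimulationConfig(lumen_mode="closed", **base)
        ).field_at(1200.0)
        repl = simulate_transport(
            mask10, species, SimulationConfig(lumen_mode="replenished_flow", **base)
        ).field_at(1200.0)
        assert repl.compartment_mean(LUMEN_LEFT) > closed.compartment_mean(LUMEN_LEFT)

    def test_scenario_monotone_in_matrix_diffusivity(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=10.0, t_end=900.0, sample_times=(900.0,))
        centre = {}
        for sc in ("high_concentration_gel", "moderate", "low_concentration_gel"):
            f = run_scenario(mask10, species, config, sc).field_at(900.0)
            iz, ix = f.values.shape[0] // 2, int(np.abs(mask10.x).argmin())
            centre[sc] = f.values[iz, ix]
        assert (
            centre["high_concentration_gel"]
            < centre["moderate"]
            < centre["low_concentration_gel"]
        )

    def test_moderate_scenario_is_identity(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=10.0, t_end=300.0, sample_times=(300.0,))
        a = run_scenario(mask10, species, config, "moderate").field_at(300.0).values
        b = simulate_transport(mask10, species, config).field_at(300.0).values
        assert np.array_equal(a, b)

    def test_extra_right_source_shifts_minimum_right(self, mask10):
        species = dextran_10kda()
        config = SimulationConfig(dt=10.0, t_end=900.0, sample_times=(900.0,))
        iz = mask10.labels.shape[0] // 2
        sel = mask10.labels[iz] == MATRIX

        def argmin_x(scenario):
            f = run_scenario(mask10, species, config, scenario).field_at(900.0)
            return mask10.x[sel][np.argmin(f.values[iz][sel])]

        assert argmin_x("extra_right_source") > argmin_x("moderate") + 50.0

    def test_unknown_scenario_rejected(self, mask10):
        with pytest.raises(ValueError, match="scenario"):
            run_scenario(mask10, dextran_10kda(), SimulationConfig(), "bogus")


class TestValidation:
    def test_species_invariants(self):
        with pytest.raises(ValueError):
            Species("x", 10.0, -1.0, 100.0, 0.5)
        with pytest.raises(ValueError):
            Species("x", 10.0, 100.0, 100.0, 0.0)
        with pytest.raises(ValueError):
            Species("x", 10.0, 100.0, 100.0, 1.5)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(lumen_mode="open_bar")
        with pytest.raises(ValueError):
            SimulationConfig(reaction_rate=0.1)

    def test_initial_shape_checked(self, mask10):
        bad = ConcentrationField(values=np.zeros((3, 3)), time=0.0, mask=mask10)
        with pytest.raises(ValueError, match="shape"):
            simulate_transport(mask10, dextran_10kda(), SimulationConfig(), bad)
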