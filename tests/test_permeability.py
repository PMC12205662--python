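import dataclasses
import math

import numpy as np
import pytest

from luminachip.geometry import ChipGeometry, build_domain_mask, exposed_perimeter_fraction
from luminachip.permeability import (
    IntensityProfile,
    PermeabilityInputs,
    compute_permeability,
    estimate_delta_I0,
    extract_profile,
    fit_partition_coefficient,
    normalize_profiles,
    permeability_from_frames,
    permeability_from_simulation,
    profile_from_frame,
    total_intensity,
)
from luminachip.transport import (
    SimulationConfig,
    Species,
    dextran_10kda,
    simulate_transport,
)


def profile(positions, intensities, time=0.0, pitch=1.0):
    return IntensityProfile(
        positions=np.asarray(positions, float),
        intensities=np.asarray(intensities, float),
        time=time,
        pixel_pitch=pitch,
    )


class TestExtractProfile:
    def test_constant_image(self):
        stack = np.full((1, 20, 20), 7.0)
        prof = extract_profile(stack, (5.0, 2.0), (0, 1), 10.0, 0, 1.0)
        assert np.allclose(prof.intensities, 7.0)
        assert prof.positions[0] == 0.0

    def test_diagonal_ramp_slope(self):
        # 45° line across a linear ramp: slope scales by √2
        h = w = 64
        ramp = np.tile(np.arange(w, dtype=float), (h, 1))  # gradient 1 per px along x
        prof = extract_profile(ramp[None], (5.0, 5.0), (1, 1), 40.0, 0, 1.0)
        slopes = np.diff(prof.intensities) / np.diff(prof.positions)
        assert np.allclose(slopes, 1.0 / math.sqrt(2), rtol=1e-9)

    def test_line_must_stay_inside(self):
        stack = np.zeros((1, 10, 10))
        with pytest.raises(ValueError, match="bounds"):
            extract_profile(stack, (5.0, 8.0), (0, 1), 10.0, 0, 1.0)

    def test_pitch_required(self):
        stack = np.zeros((1, 10, 10))
        with pytest.raises(ValueError, match="pitch"):
            extract_profile(stack, (5.0, 1.0), (0, 1), 5.0, 0, 0.0)

    def test_round_trip_through_simulator(self, mask10, geometry):
        # a noiseless rendered frame reproduces the simulated concentrations
        config = SimulationConfig(dt=10.0, t_end=600.0, sample_times=(600.0,))
        field = simulate_transport(mask10, dextran_10kda(), config).field_at(600.0)
        prof = profile_from_frame(field.values, mask10, time=600.0)
        pairs = mask10.interface_left
        central = min(pairs, key=lambda pr: abs(mask10.z[pr[0][0]]))
        iz, ix = central[1]
        expected = field.values[iz, ix : ix + prof.positions.size]
        assert np.allclose(prof.intensities, expected, atol=1e-6)


class TestProfileArithmetic:
    def test_total_intensity_constant(self):
        assert total_intensity(profile([0, 50, 100], [1, 1, 1])) == pytest.approx(100.0)

    def test_total_intensity_triangle(self):
        pos = np.linspace(0, 100, 101)
        assert total_intensity(profile(pos, 1 - pos / 100)) == pytest.approx(50.0)

    def test_total_intensity_needs_two_samples(self):
        with pytest.raises(ValueError):
            total_intensity(profile([0.0], [1.0]))

    def test_delta_I0_is_lumen_mean(self):
        assert estimate_delta_I0(profile([0, 1, 2], [0.9, 1.0, 1.1])) == pytest.approx(1.0)

    def test_normalization_scale_invariance(self):
        p1 = profile([0, 1, 2], [2.0, 4.0, 6.0])
        p2 = profile([0, 1, 2], [1.0, 2.0, 3.0])
        n1 = normalize_profiles([p1], 2.0)[0]
        n2 = normalize_profiles([p2], 1.0)[0]
        assert np.allclose(n1.intensities, n2.intensities)
        with pytest.raises(ValueError):
            normalize_profiles([p1], 0.0)


class TestComputePermeability:
    def test_no_transport_means_zero(self):
        inputs = PermeabilityInputs(1.0, 50.0, 50.0, 0.0, 900.0, 300.0, 0.0318)
        assert compute_permeability(inputs).P == 0.0

    def test_worked_arithmetic(self):
        # unit ΔI₀ and unit TI rate with the device geometry: P = f·D/4
        f = exposed_perimeter_fraction(ChipGeometry())
        inputs = PermeabilityInputs(1.0, 0.0, 900.0, 0.0, 900.0, 300.0, f)
        assert compute_permeability(inputs).P == pytest.approx(2.387, abs=2e-3)

    def test_sign_follows_intensity_change(self):
        inputs = PermeabilityInputs(1.0, 60.0, 50.0, 0.0, 900.0, 300.0, 0.0318)
        assert compute_permeability(inputs).P < 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"t_f": 0.0},
            {"delta_I0": 0.0},
            {"exposed_fraction": 0.0},
            {"exposed_fraction": 1.5},
        ],
    )
    def test_input_validation(self, kwargs):
        base = dict(delta_I0=1.0, TI_0=0.0, TI_f=1.0, t_0=0.0, t_f=900.0,
                    vessel_diameter=300.0, exposed_fraction=0.03)
        base.update(kwargs)
        with pytest.raises(ValueError):
            PermeabilityInputs(**base)

    def test_cm_per_s_conversion(self):
        inputs = PermeabilityInputs(1.0, 0.0, 900.0, 0.0, 900.0, 300.0, 0.5)
        res = compute_permeability(inputs)
        assert res.P_cm_per_s == pytest.approx(res.P * 1e-4)


@pytest.fixture(scope="module")
def estimates(mask10, geometry):
    """Ideal permeability estimates over a ladder of partition coefficients."""
    config = SimulationConfig(dt=10.0, t_end=900.0, sample_times=(0.0, 900.0))
    out = {}
    for k in (0.05, 0.5, 0.85, 1.0):
        species = Species("tracer", 10.0, 100.0, 100.0, k)
        res = simulate_transport(mask10, species, config)
        out[k] = permeability_from_simulation(res, mask10, geometry).P
    return out


class TestEstimatorOnSyntheticAssays:
    def test_fig3_control_ordering(self, estimates):
        # no endothelium (k=1) leaks most; tight barrier leaks least
        assert estimates[1.0] > estimates[0.85] > estimates[0.05] > 0

    def test_barrier_disruption_raises_P(self, estimates):
        ks = sorted(estimates)
        ps = [estimates[k] for k in ks]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_scale_invariance_of_estimate(self, mask10, geometry):
        config = SimulationConfig(dt=10.0, t_end=900.0, sample_times=(0.0, 900.0))
        res = simulate_transport(mask10, dextran_10kda(), config)
        f0, ff = res.field_at(0.0).values, res.field_at(900.0).values
        p1 = permeability_from_frames(f0, ff, mask10, geometry).P
        p2 = permeability_from_frames(37.0 * f0, 37.0 * ff, mask10, geometry).P
        assert p2 == pytest.approx(p1, rel=1e-12)


class TestPartitionCoefficientFit:
    @pytest.mark.parametrize("k_true,tol", [(0.85, 0.05), (0.05, 0.02)])
    def test_noiseless_recovery(self, mask10, k_true, tol):
        species = Species("tracer", 10.0, 100.0, 100.0, k_true)
        config = SimulationConfig(dt=10.0, t_end=900.0, sample_times=(0.0, 900.0))
        res = simulate_transport(mask10, species, config)
        obs = [profile_from_frame(res.field_at(t).values, mask10, time=t) for t in (0.0, 900.0)]
        k_hat = fit_partition_coefficient(mask10, species, observed=obs,
                                          config=dataclasses.replace(config))
        assert k_hat == pytest.approx(k_true, abs=tol)

    def test_transparent_barrier_hits_upper_bound(self, mask10):
        species = Species("tracer", 10.0, 100.0, 100.0, 1.0)
        config = SimulationConfig(dt=10.0, t_end=600.0, sample_times=(0.0, 600.0))
        res = simulate_transport(mask10, species, config)
        obs = [profile_from_frame(res.field_at(600.0).values, mask10, time=600.0)]
        with pytest.warns(UserWarning, match="bound"):
            k_hat = fit_partition_coefficient(mask10, species, observed=obs, config=config)
        assert k_hat == pytest.approx(1.0, abs=0.01)

    def test_requires_exactly_one_observation_kind(self, mask10):
        with pytest.raises(ValueError, match="exactly one"):
            fit_partition_coefficient(mask10, dextran_10kda())

    def test_bad_bounds(self, mask10):
        with pytest.raises(ValueError, match="bounds"):
            fit_partition_coefficient(
                mask10, dextran_10kda(), target_P=0.1,
                geometry=ChipGeometry(), bounds=(0.5, 0.1),
            )
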