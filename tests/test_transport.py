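"""Monte Carlo transport engine: free paths, kinematics, bookkeeping and
the transmission/attenuation virtual experiments."""

import math

import numpy as np
import pytest
from scipy import stats

from pyrscat import (
    Channel,
    GasConditions,
    pressure_to_density,
)
from pyrscat.transport import (
    CULL_ENERGY_EV,
    Physics,
    SimConfig,
    TransmissionCurve,
    _rotate,
    axial_energy,
    rpa_curve,
    run_beam,
    virtual_tcs,
)


def vacuum(**kw):
    return GasConditions(pressure_mtorr=0.0, **kw)


class ForwardOnly(Physics):
    """Test double: every collision scatters through exactly 0 degrees."""

    def sample_angle(self, channel, energy, energy_loss, rng):
        return 0.0


class TestVacuumAndGeometry:
    def test_zero_pressure_passes_every_primary_unchanged(self, physics):
        config = SimConfig(gas=vacuum(), beam_energy=15.0, n_electrons=500, seed=3)
        result = run_beam(config, physics)
        assert len(result.exits) == 500
        assert not result.events and not result.backscattered
        for state in result.exits:
            assert state.direction[2] == 1.0 and state.n_collisions == 0
        assert result.ledger["deposited"] == 0.0

    def test_monoenergetic_beam_with_zero_spread(self, physics):
        config = SimConfig(
            gas=vacuum(), beam_energy=10.0, beam_fwhm=0.0, n_electrons=50, seed=0
        )
        result = run_beam(config, physics)
        assert all(s.energy == 10.0 for s in result.exits)

    def test_forced_forward_elastic_only_preserves_energy(self, dataset):
        """theta = 0 elastic recoil vanishes, so exit energy equals entry."""
        physics = ForwardOnly.default(dataset)
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=2.0),
            beam_energy=10.0,
            beam_fwhm=0.0,
            n_electrons=300,
            seed=9,
            channels=(Channel.ELASTIC,),
        )
        result = run_beam(config, physics)
        assert len(result.exits) == 300
        assert all(s.energy == 10.0 for s in result.exits)
        assert any(s.n_collisions > 0 for s in result.exits)


class TestFreePaths:
    def test_zero_collision_survival_matches_beer_lambert(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=0.5),
            beam_energy=20.0,
            beam_fwhm=0.0,
            n_electrons=20_000,
            seed=2,
        )
        result = run_beam(config, physics)
        density = pressure_to_density(config.gas)
        sigma = physics.dataset.total_sigma(20.0) * 1e-20
        expected = math.exp(-density * sigma * config.gas.cell_length)
        stderr = math.sqrt(expected * (1 - expected) / config.n_electrons)
        assert abs(result.zero_collision_fraction - expected) < 3 * stderr

    def test_doubling_pressure_squares_survival(self, physics):
        fractions = []
        for pressure in (0.4, 0.8):
            config = SimConfig(
                gas=GasConditions(pressure_mtorr=pressure),
                beam_energy=20.0,
                beam_fwhm=0.0,
                n_electrons=20_000,
                seed=11,
            )
            fractions.append(run_beam(config, physics).zero_collision_fraction)
        assert fractions[1] == pytest.approx(fractions[0] ** 2, abs=0.015)


class TestKinematics:
    def test_rotation_preserves_norm_and_polar_angle(self, rng):
        for _ in range(200):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            theta = rng.uniform(0.0, math.pi)
            phi = rng.uniform(0.0, 2 * math.pi)
            out = _rotate(d, theta, phi)
            assert np.linalg.norm(out) == pytest.approx(1.0, abs=1e-12)
            assert float(np.dot(out, d)) == pytest.approx(math.cos(theta), abs=1e-12)

    def test_axial_energy_of_unscattered_and_single_scatter(self):
        from pyrscat.transport import ElectronState

        state = ElectronState(
            position=np.zeros(3), direction=np.array([0.0, 0.0, 1.0]), energy=15.0
        )
        assert axial_energy(state) == 15.0
        scattered = ElectronState(
            position=np.zeros(3),
            direction=_rotate(np.array([0.0, 0.0, 1.0]), math.radians(60.0), 1.2),
            energy=15.0,
        )
        # cos^2(60 deg) = 1/4
        assert axial_energy(scattered) == pytest.approx(15.0 / 4.0, rel=1e-12)

    def test_two_scatters_compose_as_rotations(self):
        """The axial cosine after two scatters matches an explicit
        rotation-matrix composition."""
        from scipy.spatial.transform import Rotation

        d0 = np.array([0.0, 0.0, 1.0])
        t1, p1, t2, p2 = 0.7, 1.1, 0.4, 5.2
        d1 = _rotate(d0, t1, p1)
        d2 = _rotate(d1, t2, p2)
        # oracle: rotate d1 by t2 about any axis perpendicular to d1, then
        # azimuthally by p2 about d1 itself
        perp = np.cross(d1, [1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        candidate = Rotation.from_rotvec(p2 * d1).apply(
            Rotation.from_rotvec(t2 * perp).apply(d1)
        )
        assert float(np.dot(d2, d1)) == pytest.approx(math.cos(t2), abs=1e-12)
        assert float(np.dot(candidate, d1)) == pytest.approx(math.cos(t2), abs=1e-12)


class TestBookkeeping:
    def test_energy_ledger_closes(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=2.0, cell_length=0.14),
            beam_energy=30.0,
            n_electrons=400,
            seed=21,
        )
        ledger = run_beam(config, physics).ledger
        outgoing = (
            ledger["exited_forward"]
            + ledger["exited_backward"]
            + ledger["deposited"]
            + ledger["culled"]
            + ledger["secondary_untracked"]
        )
        assert outgoing == pytest.approx(ledger["injected"], rel=1e-12)

    def test_untracked_secondaries_stay_in_the_ledger(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=3.0, cell_length=0.14),
            beam_energy=90.0,
            n_electrons=200,
            seed=22,
            track_secondaries=False,
        )
        result = run_beam(config, physics)
        assert result.ledger["secondary_untracked"] > 0.0
        assert all(s.generation == 0 for s in result.exits)

    def test_identical_seeds_give_bit_identical_event_logs(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=2.0),
            beam_energy=15.0,
            n_electrons=300,
            seed=17,
        )
        a = run_beam(config, physics)
        b = run_beam(config, physics)
        assert a.events == b.events
        assert a.ledger == b.ledger
        c = run_beam(
            SimConfig(
                gas=GasConditions(pressure_mtorr=2.0),
                beam_energy=15.0,
                n_electrons=300,
                seed=18,
            ),
            physics,
        )
        assert c.events != a.events

    def test_all_electrons_culled_below_threshold(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=2.0, cell_length=0.14),
            beam_energy=15.0,
            n_electrons=200,
            seed=23,
        )
        result = run_beam(config, physics)
        for state in result.exits + result.backscattered:
            assert state.energy >= CULL_ENERGY_EV

    def test_backscatter_policies(self, physics):
        base = dict(
            gas=GasConditions(pressure_mtorr=4.0, cell_length=0.14),
            beam_energy=1.0,
            n_electrons=300,
            seed=31,
        )
        lost = run_beam(SimConfig(**base, backscatter_policy="lost"), physics)
        assert lost.backscattered  # low energy, thick target: some return
        reflected = run_beam(
            SimConfig(**base, backscatter_policy="reflected"), physics
        )
        assert not reflected.backscattered

    def test_config_validation(self, physics):
        with pytest.raises(ValueError):
            SimConfig(gas=vacuum(), beam_energy=15.0, n_electrons=0)
        with pytest.raises(ValueError):
            SimConfig(gas=vacuum(), beam_energy=15.0, backscatter_policy="bounce")
        with pytest.raises(ValueError):
            SimConfig(gas=vacuum(), beam_energy=0.05)
        with pytest.raises(ValueError):
            run_beam(SimConfig(gas=vacuum(), beam_energy=200.0), physics)


class TestTransmissionCurve:
    def test_vacuum_curve_equals_beam_complementary_cdf(self, physics):
        config = SimConfig(gas=vacuum(), beam_energy=15.0, n_electrons=20_000, seed=4)
        result = run_beam(config, physics)
        grid = np.linspace(13.0, 17.0, 41)
        curve = rpa_curve(result, grid)
        sigma = 0.45 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        expected = 1.0 - stats.norm.cdf(grid, 15.0, sigma)
        assert np.max(np.abs(curve.counts - expected)) < 0.01

    def test_counts_non_increasing_and_bounded(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=2.0, cell_length=0.14),
            beam_energy=15.0,
            n_electrons=500,
            seed=5,
        )
        curve = rpa_curve(run_beam(config, physics), np.linspace(0.0, 18.0, 50))
        assert np.all(np.diff(curve.counts) <= 1e-15)
        assert curve.counts[0] <= 1.0
        with pytest.raises(ValueError):
            TransmissionCurve(np.array([0.0, 1.0]), np.array([0.1, 0.5]))

    def test_monoenergetic_elastic_step_decomposition(self, dataset, physics):
        """Thin elastic-only gas: a step of height exp(-n sigma L) at the beam
        energy plus a scattered tail below it."""
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=1.0),
            beam_energy=10.0,
            beam_fwhm=0.0,
            n_electrons=20_000,
            seed=6,
            channels=(Channel.ELASTIC,),
        )
        result = run_beam(config, physics)
        density = pressure_to_density(config.gas)
        x = density * dataset.sigma("elastic", 10.0) * 1e-20 * config.gas.cell_length
        curve = rpa_curve(result, np.array([0.0, 9.99, 10.01]))
        stderr = math.sqrt(math.exp(-x) * (1 - math.exp(-x)) / config.n_electrons)
        assert curve.counts[1] >= math.exp(-x) - 3 * stderr
        assert curve.counts[2] == 0.0
        assert curve.counts[0] <= 1.0
        assert curve.counts[0] == pytest.approx(result.transmitted_fraction)

    def test_gas_curve_lies_below_vacuum_curve(self, physics):
        """Scattering only removes axial energy: the 15 eV gas curve sits
        below the vacuum curve at every positive barrier."""
        kw = dict(beam_energy=15.0, n_electrons=3000, seed=7)
        vac = run_beam(SimConfig(gas=vacuum(cell_length=0.14), **kw), physics)
        gas = run_beam(
            SimConfig(
                gas=GasConditions(pressure_mtorr=2.0, cell_length=0.14), **kw
            ),
            physics,
        )
        grid = np.linspace(0.5, 14.0, 28)
        vac_curve = rpa_curve(vac, grid)
        gas_curve = rpa_curve(gas, grid)
        assert np.all(gas_curve.counts < vac_curve.counts)

    def test_empty_exit_set_warns(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=40.0, cell_length=0.5),
            beam_energy=0.5,
            beam_fwhm=0.0,
            n_electrons=5,
            seed=8,
        )
        result = run_beam(config, physics)
        if not result.exits:
            with pytest.warns(UserWarning):
                curve = rpa_curve(result, np.array([0.0, 1.0]))
            assert np.all(curve.counts == 0.0)


class TestVirtualTCS:
    def test_perfect_discrimination_recovers_total_cross_section(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=0.3),
            beam_energy=20.0,
            beam_fwhm=0.0,
            n_electrons=30_000,
            seed=12,
        )
        sigma_eff = virtual_tcs(config, physics)
        sigma_true = physics.dataset.total_sigma(20.0)
        density = pressure_to_density(config.gas)
        survival = math.exp(-density * sigma_true * 1e-20 * config.gas.cell_length)
        stderr_sigma = (
            math.sqrt((1 - survival) / (survival * config.n_electrons))
            / (density * config.gas.cell_length)
            / 1e-20
        )
        assert abs(sigma_eff - sigma_true) < 3 * stderr_sigma

    def test_isotropic_halved_by_hemisphere_acceptance(self, dataset, physics):
        """Isotropic elastic-only scattering with a pi/2 acceptance counts
        half the scattered electrons: sigma_eff ~ sigma/2."""
        iso = Physics(
            dataset=dataset,
            elastic=lambda e, t: np.ones_like(np.asarray(t, dtype=float)),
            rotational=physics.rotational,
            inelastic=physics.inelastic,
            loss_models=physics.loss_models,
        )
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=0.2),
            beam_energy=10.0,
            beam_fwhm=0.0,
            n_electrons=40_000,
            seed=13,
            channels=(Channel.ELASTIC,),
        )
        sigma_eff = virtual_tcs(config, iso, acceptance=("angle", math.pi / 2))
        sigma_el = dataset.sigma("elastic", 10.0)
        assert sigma_eff == pytest.approx(sigma_el / 2.0, rel=0.06)

    def test_sigma_eff_non_increasing_in_acceptance(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=0.3),
            beam_energy=20.0,
            beam_fwhm=0.0,
            n_electrons=15_000,
            seed=14,
        )
        values = [
            virtual_tcs(config, physics, acceptance=("angle", a))
            for a in (math.pi / 24, math.pi / 6, math.pi / 2)
        ]
        assert values[0] >= values[1] >= values[2]

    def test_opaque_target_raises(self, physics):
        config = SimConfig(
            gas=GasConditions(pressure_mtorr=80.0, cell_length=0.5),
            beam_energy=1.0,
            beam_fwhm=0.0,
            n_electrons=20,
            seed=15,
        )
        with pytest.raises(ValueError):
            virtual_tcs(config, physics)
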