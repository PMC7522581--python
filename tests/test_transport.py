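"""Positron transport: stopping power, helix, scattering, range statistics."""

import numpy as np
import pytest

import petmrsim as pm
from petmrsim.transport import (
    AnnihilationCloud,
    collision_stopping_power_kev_mm,
    csda_range_mm,
    gyroradius_mm,
    momentum_kev,
    transport_batch,
)


class TestStoppingPower:
    def test_water_value_near_1mev(self):
        # reference collision stopping power of water at 1 MeV is ~1.85 MeV/cm
        s = collision_stopping_power_kev_mm(np.array([1000.0]), pm.get_material("water"))
        assert s[0] * 10.0 / 1000.0 == pytest.approx(1.85, rel=0.05)

    def test_csda_range_f18_endpoint(self):
        # full-energy 18F positron path length in unit-density tissue ~2.3 mm
        r = csda_range_mm(633.5, pm.get_material("soft"))
        assert 2.0 < r < 2.8

    def test_density_scaling(self):
        soft = csda_range_mm(1000.0, pm.get_material("soft"))
        lung = csda_range_mm(1000.0, pm.get_material("lung"))
        assert lung == pytest.approx(soft / 0.3, rel=1e-6)


class TestHelix:
    def test_gyroradius_1mev_3t(self):
        # p = sqrt(1.511^2 - 0.511^2) = 1.4220 MeV/c -> r = p/(0.29979*B)
        assert momentum_kev(1000.0) == pytest.approx(1422.0, abs=0.5)
        assert gyroradius_mm(1000.0, 3.0) == pytest.approx(1.5811, rel=1e-3)

    def test_lossfree_orbit_matches_closed_form(self, soft_cube, rng):
        """Trajectory radius within 1% of the analytic gyroradius."""
        cfg = pm.TransportConfig(
            magnetic_field=(0.0, 0.0, 3.0),
            scattering=False,
            energy_loss=False,
            max_step=0.05,
        )
        state = pm.PositronState(
            position=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]),
            kinetic_energy=1000.0,
        )
        r_g = gyroradius_mm(1000.0, 3.0)
        pts = []
        for _ in range(400):
            state = pm.step(state, pm.get_material("soft"), cfg, rng)
            pts.append(state.position.copy())
        pts = np.array(pts)
        assert np.all(np.abs(pts[:, 2]) < 1e-9)  # orbit stays in the plane
        center = np.array([0.0, -r_g, 0.0])  # charge sense fixes the center
        radii = np.linalg.norm(pts[:, :2] - center[:2], axis=1)
        assert np.max(np.abs(radii - r_g)) < 0.01 * r_g

    def test_helix_pitch_preserves_axial_velocity(self, rng):
        cfg = pm.TransportConfig(
            magnetic_field=(0.0, 0.0, 3.0), scattering=False, energy_loss=False,
            max_step=0.1,
        )
        d0 = np.array([1.0, 0.0, 1.0]) / np.sqrt(2.0)
        state = pm.PositronState(position=np.zeros(3), direction=d0, kinetic_energy=500.0)
        for _ in range(50):
            state = pm.step(state, pm.get_material("soft"), cfg, rng)
        assert state.direction[2] == pytest.approx(d0[2], abs=1e-9)

    def test_zero_field_straight_step(self, rng):
        cfg = pm.TransportConfig(scattering=False, energy_loss=False, max_step=1.0)
        state = pm.PositronState(
            position=np.zeros(3), direction=np.array([0.0, 1.0, 0.0]),
            kinetic_energy=500.0,
        )
        out = pm.step(state, pm.get_material("soft"), cfg, rng)
        np.testing.assert_allclose(out.position, [0.0, 1.0, 0.0], atol=1e-12)


class TestStep:
    def test_energy_strictly_decreases(self, rng):
        cfg = pm.TransportConfig()
        state = pm.PositronState(
            position=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]),
            kinetic_energy=800.0,
        )
        for _ in range(20):
            new = pm.step(state, pm.get_material("soft"), cfg, rng)
            assert new.kinetic_energy < state.kinetic_energy
            state = new

    def test_step_below_cutoff_rejected(self, rng):
        cfg = pm.TransportConfig(energy_cutoff=10.0)
        state = pm.PositronState(
            position=np.zeros(3), direction=np.array([1.0, 0.0, 0.0]),
            kinetic_energy=5.0,
        )
        with pytest.raises(ValueError):
            pm.step(state, pm.get_material("soft"), cfg, rng)


class TestTransport:
    def test_at_cutoff_annihilates_at_origin(self, soft_cube):
        cfg = pm.TransportConfig(energy_cutoff=10.0, seed=4)
        rec = pm.transport(10.0, (1.0, 2.0, 3.0), soft_cube, cfg)
        np.testing.assert_allclose(rec.annihilation_point, [1.0, 2.0, 3.0])
        assert rec.path_length == 0.0

    def test_displacement_bounded_by_csda(self, soft_cube):
        """18F endpoint positrons never displace beyond the CSDA path."""
        cfg = pm.TransportConfig(seed=8)
        cloud = transport_batch(
            np.full(2000, 633.5),
            np.zeros((2000, 3)),
            np.random.default_rng(0).normal(size=(2000, 3)),
            soft_cube,
            cfg,
            np.random.default_rng(1),
        )
        disp = np.linalg.norm(cloud.displacement, axis=1)
        assert np.all(disp <= cloud.path_length + 1e-9)
        assert np.max(disp) < 3.0

    def test_two_cube_cloud_extends_farther_into_lung(self):
        world = pm.build_two_cube_world("lung", "soft")
        ga = pm.get_isotope("Ga68")
        cfg = pm.TransportConfig(seed=10)
        cloud = pm.simulate_cloud(ga, world, cfg, 20_000, origin=(0.0, 0.0, 0.0))
        ann = cloud.annihilated().annihilation
        lung_side = ann[:, 0] < 0
        # mean penetration depth into the lung half exceeds the soft half
        assert np.abs(ann[lung_side, 0]).mean() > 2.0 * np.abs(ann[~lung_side, 0]).mean()

    def test_fixed_seed_reproducible(self, f18, soft_cube):
        cfg = pm.TransportConfig(seed=21)
        a = pm.simulate_cloud(f18, soft_cube, cfg, 2000)
        b = pm.simulate_cloud(f18, soft_cube, cfg, 2000)
        np.testing.assert_array_equal(a.annihilation, b.annihilation)

    def test_record_invariants(self, f18, soft_cube):
        cloud = pm.simulate_cloud(f18, soft_cube, pm.TransportConfig(seed=3), 500)
        rec = cloud[0]
        assert np.linalg.norm(rec.displacement) <= rec.path_length + 1e-9


class TestRangeStatistics:
    def test_single_axial_record(self):
        rec = pm.AnnihilationRecord(
            emission_point=np.zeros(3), annihilation_point=np.array([0.0, 0.0, 2.0]),
            path_length=2.5,
        )
        stats = pm.range_statistics([rec])
        assert stats.mean_3d == pytest.approx(2.0)
        assert stats.mean_axial == pytest.approx(2.0)
        assert stats.mean_transversal == pytest.approx(0.0)

    def test_isotropic_unit_shell_projections(self, rng):
        """E|z| = r/2 for isotropic directions on a unit shell."""
        n = 40_000
        d = rng.normal(size=(n, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        cloud = AnnihilationCloud(
            emission=np.zeros((n, 3)), annihilation=d,
            path_length=np.ones(n), escaped=np.zeros(n, dtype=bool),
        )
        stats = pm.range_statistics(cloud)
        assert stats.mean_3d == pytest.approx(1.0, abs=1e-9)
        assert stats.mean_axial == pytest.approx(0.5, abs=0.01)
        assert stats.mean_transversal == pytest.approx(0.5, abs=0.01)

    def test_empty_cloud_rejected(self):
        with pytest.raises(ValueError):
            pm.range_statistics([])

    def test_radial_convention_exceeds_projection(self, f18, soft_cube):
        cloud = pm.simulate_cloud(f18, soft_cube, pm.TransportConfig(seed=6), 5000)
        proj = pm.range_statistics(cloud, "projection").mean_transversal
        radial = pm.range_statistics(cloud, "radial").mean_transversal
        assert radial > proj


@pytest.fixture(scope="module")
def clouds():
    """Range statistics for every isotope/tissue at both field strengths."""
    out = {}
    worlds = {t: pm.build_tissue_cube(t) for t in ("lung", "soft", "bone")}
    for name in ("F18", "O15", "N13", "C11", "Ga68", "Rb82"):
        iso = pm.get_isotope(name)
        for tissue, world in worlds.items():
            for b in (0.0, 3.0):
                cfg = pm.TransportConfig(magnetic_field=(0.0, 0.0, b), seed=37)
                out[(name, tissue, b)] = pm.range_statistics(
                    pm.simulate_cloud(iso, world, cfg, 8000)
                )
    return out


class TestRangePhysics:
    def test_density_monotonicity(self, clouds):
        for name in ("F18", "O15", "N13", "C11", "Ga68", "Rb82"):
            lung = clouds[(name, "lung", 0.0)].mean_3d
            soft = clouds[(name, "soft", 0.0)].mean_3d
            bone = clouds[(name, "bone", 0.0)].mean_3d
            assert lung > soft > bone

    def test_endpoint_energy_monotonicity(self, clouds):
        order = ["F18", "C11", "N13", "O15", "Ga68", "Rb82"]
        for tissue in ("lung", "soft", "bone"):
            ranges = [clouds[(n, tissue, 0.0)].mean_3d for n in order]
            assert ranges == sorted(ranges)

    def test_axial_range_unaffected_by_field(self, clouds):
        for (name, tissue, b), stats in clouds.items():
            if b == 0.0:
                continue
            ref = clouds[(name, tissue, 0.0)]
            se = 3.0 * ref.mean_axial / np.sqrt(ref.n)  # ~3x MC standard error
            assert abs(stats.mean_axial - ref.mean_axial) < max(3.0 * se, 0.05 * ref.mean_axial)

    def test_transverse_confinement(self, clouds):
        for (name, tissue, b), stats in clouds.items():
            if b == 0.0:
                continue
            ref = clouds[(name, tissue, 0.0)]
            assert stats.mean_transversal <= ref.mean_transversal * 1.05
        for name in ("Rb82", "Ga68", "O15"):
            ratio = (
                clouds[(name, "lung", 0.0)].mean_transversal
                / clouds[(name, "lung", 3.0)].mean_transversal
            )
            assert ratio >= 3.0


def test_step_budget_guard_raises(soft_cube):
    cfg = pm.TransportConfig(seed=1, max_iterations=3)
    with pytest.raises(RuntimeError, match="did not terminate"):
        pm.transport(3000.0, (0.0, 0.0, 0.0), soft_cube, cfg)


def test_geometry_dumps_are_json_serializable():
    import json

    scanner = pm.build_scanner()
    world = pm.build_necr_phantom()
    json.dumps(scanner.to_dict())
    json.dumps(world.to_dict())
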