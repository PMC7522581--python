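"""Photon emission, tracking, digitization and coincidence logic."""

import numpy as np
import pandas as pd
import pytest

import petmrsim as pm
from petmrsim.detection import (
    SingleEvent,
    classify_coincidences,
    compton_scattered_energy,
    isotropic_directions,
    project_to_ring,
    sample_compton,
    track_photons_batch,
)
from petmrsim.transport import AnnihilationRecord


def _record(point=(0.0, 0.0, 0.0)):
    return AnnihilationRecord(
        emission_point=np.zeros(3), annihilation_point=np.asarray(point, float),
        path_length=0.0,
    )


class TestEmission:
    def test_pair_antiparallel_511(self, rng):
        p1, p2 = pm.emit_annihilation_pair(_record(), event_id=7, time_ns=0.0, rng=rng)
        assert p1["energy"] == 511.0 and p2["energy"] == 511.0
        assert float(np.dot(p1["direction"], p2["direction"])) == pytest.approx(-1.0, abs=1e-12)

    def test_orientation_isotropy(self, rng):
        n = 10_000
        d = isotropic_directions(n, rng)
        assert np.linalg.norm(d.mean(axis=0)) < 0.03  # CLT bound ~1/sqrt(n)

    def test_noncollinearity_blur(self, rng):
        p1, p2 = pm.emit_annihilation_pair(
            _record(), 0, 0.0, rng, noncollinearity_fwhm_rad=0.01
        )
        dot = float(np.dot(p1["direction"], p2["direction"]))
        assert -1.0 <= dot < -0.999


class TestComptonSampling:
    def test_energy_at_90_degrees(self):
        assert compton_scattered_energy(511.0, 0.0) == pytest.approx(255.5)

    def test_kahn_samples_respect_kinematic_bounds(self, rng):
        e, cos_t = sample_compton(np.full(50_000, 511.0), rng)
        e_min = 511.0 / 3.0  # backscatter limit at eps = 1
        assert np.all(e >= e_min - 1e-9)
        assert np.all(e <= 511.0 + 1e-9)
        assert np.all((cos_t >= -1) & (cos_t <= 1))
        # energies and angles satisfy the Compton relation sample-by-sample
        np.testing.assert_allclose(
            e, 511.0 / (1.0 + (511.0 / 511.0) * (1.0 - cos_t)), rtol=1e-9
        )

    def test_mean_scattered_energy_matches_quadrature(self, rng):
        """Oracle: expectation of E' under Klein-Nishina by quadrature."""
        eps = 1.0
        cos = np.linspace(-1.0, 1.0, 20_001)
        ratio = 1.0 / (1.0 + eps * (1.0 - cos))  # E'/E
        # KN differential in cos(theta), unnormalized
        dcs = ratio**2 * (ratio + 1.0 / ratio - (1.0 - cos**2))
        expected = np.trapezoid(ratio * dcs, cos) / np.trapezoid(dcs, cos) * 511.0
        e, _ = sample_compton(np.full(200_000, 511.0), rng)
        assert e.mean() == pytest.approx(expected, rel=0.005)


class TestTracking:
    def test_zero_attenuation_world_photon_escapes(self, rng, scanner):
        world = pm.World(shapes=[], background=pm.get_material("air"))
        pos, dirs, en, scat, alive = track_photons_batch(
            np.zeros((10, 3)), isotropic_directions(10, rng), np.full(10, 511.0),
            world, rng,
        )
        assert np.all(alive)
        assert np.all(scat == 0)

    def test_mean_free_path_in_water(self, rng):
        """Transmission through a water slab vs exp(-mu x), mu from KN."""
        half = 51.84  # mm, one mean free path at 511 keV (1/0.0958 cm)
        from petmrsim.materials import Box

        world = pm.World(
            shapes=[(Box((0.0, 0.0, 0.0), (half, 10_000.0, 10_000.0)),
                     pm.get_material("water"))],
            background=pm.get_material("vacuum"),
        )
        n = 100_000
        pos = np.tile([-half + 1e-6, 0.0, 0.0], (n, 1))
        dirs = np.tile([1.0, 0.0, 0.0], (n, 1))
        _, _, _, scat, alive = track_photons_batch(
            pos, dirs, np.full(n, 511.0), world, rng,
        )
        unscattered = alive & (scat == 0)
        mu = pm.get_material("water").linear_attenuation(511.0) / 10.0
        expected = np.exp(-mu * 2 * half)
        assert unscattered.mean() == pytest.approx(expected, rel=0.03)

    def test_project_to_ring_hits_crystal(self, scanner):
        pos = np.array([[0.0, 0.0, 0.0]])
        theta, z = scanner.crystal_angle_z(np.array([scanner.n_crystals // 2]))
        d = np.array([[np.cos(theta[0]), np.sin(theta[0]), 0.0]])
        crystal, _ = project_to_ring(pos, d, scanner)
        r, b, a, t = scanner.crystal_components(crystal)
        r0, b0, a0, t0 = scanner.crystal_components(np.array([scanner.n_crystals // 2]))
        assert b[0] == b0[0] and t[0] == t0[0]

    def test_axial_ray_misses_ring(self, scanner):
        crystal, _ = project_to_ring(
            np.array([[0.0, 0.0, 0.0]]), np.array([[0.0, 0.0, 1.0]]), scanner
        )
        assert crystal[0] == -1


def _hits(times, energies=None, crystals=None, blocks=None):
    n = len(times)
    return pd.DataFrame(
        {
            "crystal": crystals if crystals is not None else np.zeros(n, dtype=int),
            "block": blocks if blocks is not None else np.zeros(n, dtype=int),
            "time": np.asarray(times, dtype=float),
            "energy": energies if energies is not None else np.full(n, 511.0),
            "event_id": np.arange(n),
            "scatter_count": np.zeros(n, dtype=int),
        }
    )


class TestDigitize:
    def test_out_of_window_rejected_without_blur(self, rng):
        cfg = pm.DigitizerConfig(energy_resolution_fwhm=0.0, dead_time_tau_ns=0.0)
        hits = _hits([0.0, 1.0, 2.0], energies=np.array([400.0, 511.0, 700.0]))
        out = pm.digitize(hits, cfg, rng)
        assert list(out["event_id"]) == [1]

    def test_zero_tau_keeps_all_in_window(self, rng):
        cfg = pm.DigitizerConfig(energy_resolution_fwhm=0.0, dead_time_tau_ns=0.0)
        hits = _hits(np.arange(100.0))
        assert len(pm.digitize(hits, cfg, rng)) == 100

    def test_unsorted_input_rejected(self, rng):
        cfg = pm.DigitizerConfig()
        with pytest.raises(ValueError):
            pm.digitize(_hits([1.0, 0.5]), cfg, rng)

    def test_paralyzable_dead_time_closed_form(self, rng):
        """Observed rate m = n exp(-n tau) for Poisson singles on one block."""
        tau = 1000.0  # ns
        rate = 1e-4  # per ns = 100 kcps
        n = 300_000
        times = np.sort(rng.uniform(0, n / rate, n))
        cfg = pm.DigitizerConfig(energy_resolution_fwhm=0.0, dead_time_tau_ns=tau)
        out = pm.digitize(_hits(times), cfg, rng)
        observed = len(out) / (n / rate)
        assert observed == pytest.approx(rate * np.exp(-rate * tau), rel=0.01)

    def test_dead_time_rate_sweep_matches_model(self, rng):
        """10-point sweep of the paralyzable transfer curve."""
        tau = 2000.0
        cfg = pm.DigitizerConfig(energy_resolution_fwhm=0.0, dead_time_tau_ns=tau)
        for rate in np.linspace(2e-5, 2e-4, 10):
            n = 60_000
            times = np.sort(rng.uniform(0, n / rate, n))
            out = pm.digitize(_hits(times), cfg, rng)
            observed = len(out) / (n / rate)
            expected = rate * np.exp(-rate * tau)
            assert observed == pytest.approx(expected, rel=0.05)

    def test_non_paralyzable_model(self, rng):
        """m = n / (1 + n tau) for the non-paralyzable variant."""
        tau = 2000.0
        rate = 2e-4
        n = 100_000
        times = np.sort(rng.uniform(0, n / rate, n))
        cfg = pm.DigitizerConfig(
            energy_resolution_fwhm=0.0, dead_time_tau_ns=tau,
            dead_time_model="non-paralyzable",
        )
        out = pm.digitize(_hits(times), cfg, rng)
        observed = len(out) / (n / rate)
        assert observed == pytest.approx(rate / (1.0 + rate * tau), rel=0.02)

    def test_blocks_independent(self, rng):
        cfg = pm.DigitizerConfig(energy_resolution_fwhm=0.0, dead_time_tau_ns=100.0)
        # two hits 1 ns apart on different blocks both survive
        hits = _hits([0.0, 1.0], blocks=np.array([0, 1]))
        assert len(pm.digitize(hits, cfg, rng)) == 2


def _singles(times, crystals):
    return pd.DataFrame(
        {
            "crystal": crystals,
            "block": np.zeros(len(times), dtype=int),
            "time": np.asarray(times, dtype=float),
            "energy": np.full(len(times), 511.0),
            "event_id": np.arange(len(times)),
            "scatter_count": np.zeros(len(times), dtype=int),
        }
    )


class TestCoincidences:
    def test_pair_within_window(self):
        out = pm.sort_coincidences(_singles([0.0, 2.0], [1, 2]), window_ns=4.57)
        assert len(out) == 1

    def test_pair_outside_window(self):
        out = pm.sort_coincidences(_singles([0.0, 5.0], [1, 2]), window_ns=4.57)
        assert len(out) == 0

    def test_triple_take_all_goods(self):
        out = pm.sort_coincidences(_singles([0.0, 1.0, 2.0], [1, 2, 3]), window_ns=4.57)
        assert len(out) == 3  # all pairs within the window

    def test_self_pairs_excluded(self):
        out = pm.sort_coincidences(_singles([0.0, 1.0], [5, 5]), window_ns=4.57)
        assert len(out) == 0

    def test_classification_rules(self):
        df = pd.DataFrame(
            {
                "event_id1": [7, 7, 7],
                "event_id2": [9, 7, 7],
                "scatter1": [0, 0, 0],
                "scatter2": [0, 0, 2],
            }
        )
        np.testing.assert_array_equal(
            classify_coincidences(df), ["random", "true", "scattered"]
        )

    def test_scalar_classifier_matches(self):
        e1 = SingleEvent(0, 0.0, 511.0, 7, 0)
        assert pm.classify_coincidence(
            pm.CoincidenceEvent(e1, SingleEvent(1, 1.0, 511.0, 9, 0))
        ) == "random"
        assert pm.classify_coincidence(
            pm.CoincidenceEvent(e1, SingleEvent(1, 1.0, 511.0, 7, 0))
        ) == "true"
        assert pm.classify_coincidence(
            pm.CoincidenceEvent(e1, SingleEvent(1, 1.0, 511.0, 7, 2))
        ) == "scattered"


@pytest.fixture(scope="module")
def small_acq(scanner, digitizer_no_deadtime):
    world = pm.build_necr_phantom()
    return pm.simulate_acquisition(
        pm.get_isotope("F18"), world, scanner, digitizer_no_deadtime,
        activity_bq=2e5, n_decays=60_000, seed=5, efficiency=1.0,
    )


class TestAcquisition:

    def test_true_lors_pass_near_source(self, small_acq, scanner):
        """Unscattered same-decay LORs intersect the line-source position."""
        trues = small_acq.coincidences[small_acq.coincidences["label"] == "true"]
        p1 = scanner.crystal_position(trues["crystal1"].to_numpy(dtype=int))
        p2 = scanner.crystal_position(trues["crystal2"].to_numpy(dtype=int))
        d = p2[:, :2] - p1[:, :2]
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        rel = np.array([0.0, -45.0]) - p1[:, :2]
        dist = np.abs(rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0])
        # crystal quantization (4 mm pitch) plus source radius
        assert np.median(dist) < 6.0

    def test_rate_conservation(self, small_acq):
        c = small_acq.coincidences
        assert len(c) <= small_acq.singles_rate_cps * small_acq.duration_s

    def test_scattered_fraction_plausible(self, small_acq):
        labels = small_acq.coincidences["label"]
        sf = (labels == "scattered").sum() / max((labels != "random").sum(), 1)
        assert 0.25 < sf < 0.55

    def test_prompt_gamma_contamination_for_rb82(self, scanner, digitizer_no_deadtime):
        """With prompt gammas, some same-decay LORs miss the source entirely."""
        world = pm.build_necr_phantom()
        acq = pm.simulate_acquisition(
            pm.get_isotope("Rb82"), world, scanner, digitizer_no_deadtime,
            activity_bq=2e5, n_decays=80_000, seed=6, efficiency=1.0,
            prompt_gammas=True,
        )
        same = acq.coincidences[acq.coincidences["label"] != "random"]
        p1 = scanner.crystal_position(same["crystal1"].to_numpy(dtype=int))
        p2 = scanner.crystal_position(same["crystal2"].to_numpy(dtype=int))
        d = p2[:, :2] - p1[:, :2]
        norms = np.linalg.norm(d, axis=1)
        keep = norms > 1e-9  # drop LORs with no transaxial extent
        d = d[keep] / norms[keep, None]
        rel = np.array([0.0, -45.0]) - p1[keep, :2]
        dist = np.abs(rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0])
        # a visible tail of same-decay LORs far from the source: the
        # prompt-gamma pile-up mechanism
        assert (dist > 120.0).mean() > 0.005
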