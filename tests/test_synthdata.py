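"""Synthetic data generators: pools, phototransects, recovery fixtures."""

import numpy as np
import pytest

from coraldemog.matrices import build_transition_matrix
from coraldemog.projection import RecruitmentSeries, project_series
from coraldemog.synthdata import (
    assign_size_class,
    chagos_like_world,
    generate_life_table_pool,
    generate_recovery_fixture,
    required_spat,
    simulate_phototransect,
)

PAPER_LIKE_DENSITIES = {2: 22.0, 3: 2.0, 4: 0.6, 5: 0.25}


class TestLifeTablePools:
    def test_pool_entries_build_valid_subcritical_matrices(self):
        for gf in ("arborescent", "branching_encrusting", "massive"):
            pool = generate_life_table_pool(gf, 15, rng_seed=2)
            for lt in pool:
                tm = build_transition_matrix(lt)
                np.testing.assert_allclose(tm.sigma, lt.sigma, rtol=1e-12)
                assert tm.lambda_ < 1.0

    def test_survival_increases_with_size(self):
        pool = generate_life_table_pool("massive", 10, rng_seed=4)
        for lt in pool:
            assert lt.sigma[0] < lt.sigma[2] < lt.sigma[4]

    def test_seed_determinism(self):
        a = generate_life_table_pool("arborescent", 5, rng_seed=6)
        b = generate_life_table_pool("arborescent", 5, rng_seed=6)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.sigma, y.sigma)
            np.testing.assert_array_equal(x.duration, y.duration)


class TestSizeClasses:
    @pytest.mark.parametrize(
        "radius,expected",
        [(0.0, 1), (0.99, 1), (1.0, 2), (4.99, 2), (5.0, 3), (10.0, 4),
         (19.99, 4), (20.0, 5), (120.0, 5)],
    )
    def test_half_open_lower_inclusive_bins(self, radius, expected):
        assert assign_size_class(radius) == expected


class TestPhototransect:
    def test_zero_density_yields_empty_transect(self):
        ts = simulate_phototransect({2: 0.0, 3: 0.0}, rng_seed=0)
        assert ts.records == []
        assert ts.counts.total == 0.0

    def test_spat_never_detected(self):
        ts = simulate_phototransect({1: 50.0, 2: 5.0}, rng_seed=1)
        assert ts.counts.n[0] == 0.0
        assert all(r.assigned_class != 1 for r in ts.records if r.included)

    def test_expected_counts_match_density_times_area(self):
        """Law of large numbers over seeds: mean recruit count approaches
        density x 10 m^2 (~220 for the quadrat-derived 22/m^2)."""
        counts = [
            simulate_phototransect({2: 22.0}, rng_seed=s).counts.n[1]
            for s in range(40)
        ]
        assert np.mean(counts) == pytest.approx(220.0, rel=0.05)

    def test_every_included_colony_has_exactly_one_class(self):
        ts = simulate_phototransect(PAPER_LIKE_DENSITIES, rng_seed=3)
        included = [r for r in ts.records if r.included]
        assert all(r.assigned_class in range(1, 6) for r in included)
        binned = np.zeros(5)
        for r in included:
            binned[r.assigned_class - 1] += 1
        np.testing.assert_array_equal(binned, ts.counts.n)

    def test_truncation_losses_in_small_classes_stay_below_five_percent(self):
        """At realistic densities and sizes, fewer than 5% of recruit- and
        juvenile-sized colonies are lost to edge-truncation ambiguity."""
        lost = total = 0
        for s in range(25):
            ts = simulate_phototransect(PAPER_LIKE_DENSITIES, rng_seed=s)
            small = [r for r in ts.records if assign_size_class(r.radius_cm) in (2, 3)]
            total += len(small)
            lost += sum(not r.included for r in small)
        assert total > 2000
        assert lost / total < 0.05

    def test_giant_truncated_colonies_are_kept_in_largest_class(self):
        ts = simulate_phototransect(
            {5: 0.8}, rng_seed=5, radius_ranges={5: (25.0, 35.0)}
        )
        truncated = [r for r in ts.records if r.truncated]
        assert truncated  # 25-35 cm colonies in a 50 cm corridor must clip
        assert all(r.included and r.assigned_class == 5 for r in truncated)


class TestRequiredSpat:
    def test_quadrat_juveniles_imply_twenty_two_thousand_spat(self):
        assert required_spat(220.0, 0.01) == pytest.approx(22000.0)

    def test_full_survivorship_is_identity(self):
        assert required_spat(37.0, 1.0) == 37.0

    def test_no_juveniles_need_no_spat(self):
        assert required_spat(0.0, 0.01) == 0.0

    def test_rejects_zero_survivorship(self):
        with pytest.raises(ValueError):
            required_spat(100.0, 0.0)


class TestWorldAndFixture:
    def test_world_covers_all_growth_forms_and_grids(self, world):
        assert set(world.matrices) == {
            "arborescent", "branching_encrusting", "massive"
        }
        from coraldemog.hindcast import DEFAULT_NU_GRID, DEFAULT_START_SURVIVAL_GRID

        for nu in world.nu_true.values():
            assert set(nu) <= set(DEFAULT_NU_GRID)
        for fs, fl in world.start_fractions.values():
            assert fs in DEFAULT_START_SURVIVAL_GRID
            assert fl in DEFAULT_START_SURVIVAL_GRID

    def test_pre_disturbance_is_stationary(self, world):
        for key, pre in world.pre_disturbance.items():
            A = world.matrices[key[1]].A
            nu = np.zeros(5)
            nu[0] = world.nu_true[key].mean()
            np.testing.assert_allclose(A @ pre + nu, pre, rtol=1e-10)

    def test_zero_years_fixture_equals_start_vector(self, world):
        fix = generate_recovery_fixture(world, years=0)
        for key, sd in fix.observed.items():
            np.testing.assert_array_equal(sd.n, world.start_vector(key))

    def test_fixture_matches_manual_projection(self, world, recovery_fixture):
        key = ("lagoon", "massive")
        traj = project_series(
            world.matrices["massive"],
            world.start_vector(key),
            RecruitmentSeries(nu=world.nu_true[key], mode="imported_only"),
            world.years,
        )
        np.testing.assert_array_equal(
            recovery_fixture.observed[key].n, traj[-1].n
        )

    def test_lagoon_supply_exceeds_ocean_supply(self, world):
        for gf in ("branching_encrusting", "massive"):
            assert (
                world.nu_true[("lagoon", gf)].sum()
                > world.nu_true[("ocean_facing", gf)].sum()
            )

    def test_observation_noise_is_multiplicative_and_seeded(self, world):
        a = generate_recovery_fixture(world, noise_sigma=0.2, rng_seed=8)
        b = generate_recovery_fixture(world, noise_sigma=0.2, rng_seed=8)
        clean = generate_recovery_fixture(world)
        for key in a.observed:
            np.testing.assert_array_equal(a.observed[key].n, b.observed[key].n)
            assert not np.array_equal(a.observed[key].n, clean.observed[key].n)

    def test_world_seed_determinism(self):
        w1 = chagos_like_world(rng_seed=3, n_trials=200)
        w2 = chagos_like_world(rng_seed=3, n_trials=200)
        for gf in w1.matrices:
            np.testing.assert_array_equal(w1.matrices[gf].A, w2.matrices[gf].A)
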