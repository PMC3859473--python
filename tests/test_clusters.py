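import math

import numpy as np
import pytest

from zoonet.clusters import (
    ClusterCurve,
    NetworkIndex,
    RatioCurve,
    class_ratio_curve,
    cluster_report,
    default_radius_grid,
    eligible_species,
    exhaustive_cluster_probability,
    mc_cluster_probability,
    metapopulation_size,
    optimal_cluster,
    pairwise_distance_matrix,
    species_cluster_curve,
    zoo_cluster,
)
from zoonet.datamodel import (
    ChecklistOrder,
    Holding,
    IUCNCategory,
    SpeciesTaxon,
    Zoo,
    haversine_km,
    validate_dataset,
)


def brute_force_probability(dataset, species_id, radius, m):
    """Independent oracle: nested loops over focal zoos with direct
    haversine calls, no shared machinery with the engine under test."""
    held = dataset.holdings_of(species_id)
    hits, sizes, present = [], [], []
    for focal in dataset.zoos:
        members = [
            z for z in dataset.zoos
            if haversine_km((focal.latitude, focal.longitude), (z.latitude, z.longitude))
            <= radius
        ]
        pooled = sum(held.get(z.zoo_id, 0) for z in members)
        hits.append(pooled >= m)
        sizes.append(len(members))
        present.append(sum(1 for z in members if held.get(z.zoo_id, 0) > 0))
    n = len(dataset.zoos)
    return sum(hits) / n, sum(sizes) / n, sum(present) / n


class TestDistanceMatrix:
    def test_single_zoo(self):
        d = pairwise_distance_matrix([Zoo("Z1", 10.0, 20.0)])
        assert d.matrix.shape == (1, 1) and d.matrix[0, 0] == 0.0

    def test_antipodal(self):
        d = pairwise_distance_matrix([Zoo("A", 0, 0), Zoo("B", 0, -180)])
        assert d.matrix[0, 1] == pytest.approx(6371 * math.pi, rel=1e-9)

    def test_symmetry_and_triangle(self):
        rng = np.random.default_rng(0)
        zoos = [
            Zoo(f"Z{i}", float(lat), float(lon))
            for i, (lat, lon) in enumerate(
                zip(rng.uniform(-90, 90, 12), rng.uniform(-180, 179.9, 12))
            )
        ]
        d = pairwise_distance_matrix(zoos).matrix
        assert np.array_equal(d, d.T)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, k] <= d[i, j] + d[j, k] + 1e-6

    def test_matches_scalar_haversine(self):
        zoos = [Zoo("A", 12.0, -30.0), Zoo("B", -45.0, 100.0)]
        d = pairwise_distance_matrix(zoos)
        assert d.matrix[0, 1] == pytest.approx(haversine_km((12, -30), (-45, 100)), rel=1e-12)


class TestClusterPrimitives:
    def test_cluster_contains_focal(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        c = zoo_cluster(dmat, "A", 0.0)
        assert c.members == ("A",)

    def test_cluster_membership_inclusive(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        r = dmat.matrix[0, 1]  # exact distance A-B
        assert "B" in zoo_cluster(dmat, "A", r).members

    def test_metapopulation_size_single_zoo(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        c = zoo_cluster(dmat, "A", 0.0)
        assert metapopulation_size("sp1", c, four_zoo_toy.holdings) == 20

    def test_metapopulation_size_addition(self):
        zoos = [Zoo("X", 0, 0), Zoo("Y", 0.1, 0), Zoo("W", 0, 0.1)]
        species = [SpeciesTaxon("s", "Aves", "o", IUCNCategory.VU)]
        holdings = [Holding("X", "s", 10), Holding("W", "s", 45)]
        ds = validate_dataset(zoos, species, holdings, [ChecklistOrder("Aves", "o", 5, 2)])
        dmat = pairwise_distance_matrix(ds.zoos)
        c = zoo_cluster(dmat, "X", 100.0)
        assert c.size == 3
        assert metapopulation_size("s", c, ds.holdings) == 55

    def test_holding_count(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        c = zoo_cluster(dmat, "A", 100.0, species_zoos=["A", "B"])
        assert c.holding_count == 2

    def test_full_network_cluster_equals_global_total(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        c = zoo_cluster(dmat, "A", dmat.diameter() + 1)
        assert metapopulation_size("sp1", c, four_zoo_toy.holdings) == 60


class TestEligibleSpecies:
    def _dataset(self, total):
        zoos = [Zoo("Z1", 0, 0)]
        species = [SpeciesTaxon("s", "Aves", "o", IUCNCategory.CR)]
        holdings = [Holding("Z1", "s", total)]
        return validate_dataset(zoos, species, holdings, [ChecklistOrder("Aves", "o", 5, 2)])

    def test_boundary_excluded(self):
        assert eligible_species(self._dataset(49), "Aves", 50) == []

    def test_boundary_included(self):
        assert eligible_species(self._dataset(50), "Aves", 50) == ["s"]

    def test_non_threatened_excluded(self, four_zoo_toy):
        assert eligible_species(four_zoo_toy, "Reptilia", 50) == ["sp1"]

    def test_generator_bookkeeping(self):
        from zoonet.synth import demo_scenario, generate_dataset

        ds, truth = generate_dataset(demo_scenario(seed=21))
        for cls in ds.class_names():
            expected = sorted(
                sid
                for sid, total in truth["species_totals"].items()
                if ds.species_by_id(sid).class_name == cls
                and ds.species_by_id(sid).is_threatened
                and total >= 100
            )
            assert eligible_species(ds, cls, 100) == expected


class TestFourZooToy:
    def test_exhaustive_hand_enumeration(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        p, mean_zoos, mean_present = exhaustive_cluster_probability(
            "sp1", 150.0, 50, dmat, four_zoo_toy.holdings
        )
        # A, B, C clusters pool 60 >= 50; D's cluster is D alone (0): p = 3/4
        assert p == 0.75
        assert mean_zoos == pytest.approx((3 + 3 + 3 + 1) / 4)
        assert mean_present == pytest.approx((3 + 3 + 3 + 0) / 4)

    def test_brute_force_oracle_agrees(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        for r in (0.0, 100.0, 150.0, 4_000.0, 5_200.0):
            got = exhaustive_cluster_probability("sp1", r, 50, dmat, four_zoo_toy.holdings)
            expected = brute_force_probability(four_zoo_toy, "sp1", r, 50)
            assert got == pytest.approx(expected)

    def test_monte_carlo_within_three_se(self, four_zoo_toy):
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        S = 2_000
        p_mc, _, _ = mc_cluster_probability(
            "sp1", 150.0, 50, dmat, four_zoo_toy.holdings, iterations=S, seed=1
        )
        p = 0.75
        assert abs(p_mc - p) <= 3 * math.sqrt(p * (1 - p) / S) + 1 / S

    def test_curve_steps_to_one(self, four_zoo_toy):
        curve = species_cluster_curve(four_zoo_toy, "sp1", 50)
        # 0.75 until the far zoo joins every cluster (~5,060 km), then 1.0
        assert curve.p[0] == 0.75
        assert curve.p[-1] == 1.0
        jumps = np.nonzero(np.diff(curve.p))[0]
        assert len(jumps) == 1
        assert curve.radii[jumps[0] + 1] == 5_100.0

    def test_curve_monotone_and_saturates(self, four_zoo_toy):
        curve = species_cluster_curve(four_zoo_toy, "sp1", 50)
        assert np.all(np.diff(curve.p) >= 0)
        dmat = pairwise_distance_matrix(four_zoo_toy.zoos)
        assert np.all(curve.p[curve.radii >= dmat.diameter()] == 1.0)

    def test_species_below_threshold_rejected(self, four_zoo_toy):
        with pytest.raises(ValueError, match="eligible"):
            species_cluster_curve(four_zoo_toy, "sp1", 100)

    def test_mc_curve_deterministic(self, four_zoo_toy):
        a = species_cluster_curve(four_zoo_toy, "sp1", 50, engine="monte_carlo", seed=5)
        b = species_cluster_curve(four_zoo_toy, "sp1", 50, engine="monte_carlo", seed=5)
        assert np.array_equal(a.p, b.p)
        assert np.array_equal(a.mean_zoos, b.mean_zoos)


def _make_curve(radii, p, species_id="s", m=50):
    radii = np.asarray(radii, dtype=float)
    p = np.asarray(p, dtype=float)
    z = np.zeros_like(p)
    return ClusterCurve(species_id, m, radii, p, z, z)


class TestRatioAndOptimum:
    def test_all_zero(self):
        c = _make_curve([100, 200, 300], [0, 0, 0])
        rc = class_ratio_curve("Aves", 50, [c])
        assert np.all(rc.ratio == 0)

    def test_single_species_reciprocal(self):
        c = _make_curve([100, 200, 400], [1, 1, 1])
        rc = class_ratio_curve("Aves", 50, [c])
        assert rc.ratio == pytest.approx([1 / 100, 1 / 200, 1 / 400])
        assert np.all(np.diff(rc.ratio) < 0)

    def test_two_species_hand_average(self):
        c1 = _make_curve([100, 200], [0.2, 0.8], "a")
        c2 = _make_curve([100, 200], [0.4, 0.6], "b")
        rc = class_ratio_curve("Aves", 50, [c1, c2])
        assert rc.ratio == pytest.approx([(0.2 / 100 + 0.4 / 100) / 2,
                                          (0.8 / 200 + 0.6 / 200) / 2])

    def test_empty_eligible_set(self):
        with pytest.raises(ValueError, match="Aves"):
            class_ratio_curve("Aves", 50, [])

    def test_mismatched_grid_rejected(self):
        c1 = _make_curve([100, 200], [0.2, 0.8], "a")
        c2 = _make_curve([100, 300], [0.4, 0.6], "b")
        with pytest.raises(ValueError, match="grid"):
            class_ratio_curve("Aves", 50, [c1, c2])

    def test_decreasing_ratio_picks_first_radius(self):
        c = _make_curve([100, 200, 300], [1, 1, 1])
        opt = optimal_cluster(class_ratio_curve("Aves", 50, [c]), [c])
        assert opt.radius_km == 100.0

    def test_constructed_max_at_300(self):
        # ratios: .1/100=.001, .25/200=.00125, .6/300=.002, .7/400=.00175
        c = _make_curve([100, 200, 300, 400], [0.1, 0.25, 0.6, 0.7])
        opt = optimal_cluster(class_ratio_curve("Aves", 50, [c]), [c])
        assert opt.radius_km == 300.0
        assert opt.probability == pytest.approx(0.6)

    def test_tie_breaks_to_smallest_radius(self):
        # r=200 and r=400 both give ratio 0.001
        c = _make_curve([200, 300, 400], [0.2, 0.25, 0.4])
        opt = optimal_cluster(class_ratio_curve("Aves", 50, [c]), [c])
        assert opt.radius_km == 200.0


@pytest.fixture(scope="module")
def network():
    from zoonet.synth import demo_scenario, generate_dataset

    ds, _ = generate_dataset(demo_scenario(seed=13))
    return ds


class TestSyntheticNetworkProperties:
    def test_monotone_nondecreasing_everywhere(self, network):
        radii = default_radius_grid(10_000, 500)
        for cls in network.class_names():
            for sid in eligible_species(network, cls, 50)[:5]:
                curve = species_cluster_curve(network, sid, 50, radii=radii)
                assert np.all(np.diff(curve.p) >= 0)

    def test_threshold_ordering(self, network):
        radii = default_radius_grid(10_000, 1_000)
        for cls in network.class_names():
            sids = {m: set(eligible_species(network, cls, m)) for m in (50, 100, 250)}
            assert sids[250] <= sids[100] <= sids[50]
            for sid in sorted(sids[250]):
                p = {
                    m: species_cluster_curve(network, sid, m, radii=radii).p
                    for m in (50, 100, 250)
                }
                assert np.all(p[50] >= p[100]) and np.all(p[100] >= p[250])

    def test_cluster_report_schema(self, network):
        table, curves = cluster_report(network, thresholds=(50,), radii=default_radius_grid(10_000, 1_000))
        assert list(table.columns) == [
            "class", "threshold", "species_in_cluster", "radial_distance_km",
            "probability", "avg_zoos_in_cluster", "avg_zoos_with_species",
        ]
        assert set(table["class"]) <= set(network.class_names())
        for (_, m), cs in curves.items():
            assert all(c.threshold == m for c in cs)
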