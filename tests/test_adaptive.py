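import numpy as np
import pytest

from adasmooth.adaptive import (
    RateSurface,
    build_neighbor_ordering,
    crude_zone_mean,
    estimate_rates,
    estimate_state_rates,
    state_rate,
    surface_to_frame,
)
from adasmooth.errors import ConfigError
from adasmooth.geography import AgeStratum, StudyRegion
from adasmooth.simulate import ReplicateCaseSet, run_replications


def _region(pops, centroids=None, label="A", rate=500.0):
    pops = np.asarray(pops, dtype=np.int64)
    n = pops.size
    if centroids is None:
        centroids = np.column_stack([np.arange(n, dtype=float), np.zeros(n)])
    return StudyRegion(
        zone_ids=[f"z{i:03d}" for i in range(n)],
        centroids=np.asarray(centroids, dtype=float),
        populations={label: pops},
        strata=[AgeStratum(label, rate, int(pops.sum()))],
    )


def _cases(region, counts, label="A"):
    counts = np.asarray(counts, dtype=np.int64)
    return ReplicateCaseSet(1, 0, {label: counts}, {label: int(counts.sum())})


def brute_force_rates(region, cases, label, threshold):
    """Re-sorts every zone from scratch; the independent oracle."""
    n = region.n_zones
    ids = list(region.zone_ids)
    pops = region.populations[label]
    cv = cases.cases[label]
    rates = np.empty(n)
    radii = np.empty(n)
    for z in range(n):
        d = np.sqrt(((region.centroids - region.centroids[z]) ** 2).sum(axis=1))
        idx = sorted(range(n), key=lambda j: (d[j], j != z, ids[j]))
        cum = cc = 0
        for j in idx:
            cum += int(pops[j])
            cc += int(cv[j])
            last = j
            if cum >= threshold:
                break
        rates[z] = 1e5 * cc / cum
        radii[z] = d[last]
    return rates, radii


class TestNeighborOrdering:
    def test_two_zones(self):
        region = _region([10, 20])
        o = build_neighbor_ordering(region)
        assert o.order.tolist() == [[0, 1], [1, 0]]
        assert o.distance[0, 0] == 0.0

    def test_self_first_and_id_tiebreak(self):
        # zones 1 and 2 are equidistant from zone 0; tie broken by id
        centroids = [[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]]
        region = _region([5, 5, 5], centroids=centroids)
        o = build_neighbor_ordering(region)
        assert o.order[0].tolist() == [0, 1, 2]
        assert all(o.order[i, 0] == i for i in range(3))

    def test_duplicate_centroids_warn_not_fail(self):
        region = _region([5, 5], centroids=[[0.0, 0.0], [0.0, 0.0]])
        with pytest.warns(UserWarning, match="duplicate"):
            o = build_neighbor_ordering(region)
        assert all(o.order[i, 0] == i for i in range(2))

    def test_matches_full_sort_oracle_100_zones(self):
        rng = np.random.default_rng(8)
        region = _region(rng.integers(1, 500, 100), centroids=rng.uniform(0, 10, (100, 2)))
        o = build_neighbor_ordering(region)
        ids = list(region.zone_ids)
        for z in range(100):
            d = np.sqrt(((region.centroids - region.centroids[z]) ** 2).sum(axis=1))
            oracle = sorted(range(100), key=lambda j: (d[j], j != z, ids[j]))
            assert o.order[z].tolist() == oracle

    def test_cumulative_population_monotone(self, standard_region, standard_ordering):
        for lab in standard_region.stratum_labels:
            cp = standard_ordering.cum_pop[lab]
            assert np.all(np.diff(cp, axis=1) >= 0)


class TestEstimateRates:
    def test_self_contained_kernel(self):
        region = _region([1000, 50])
        cases = _cases(region, [5, 0])
        o = build_neighbor_ordering(region)
        surf = estimate_rates(region, cases, "A", 1000.0, o)
        assert surf.rate[0] == pytest.approx(500.0)
        assert surf.radius[0] == 0.0

    def test_threshold_below_min_pop_gives_crude_rates(self, small_region):
        reps, _ = run_replications(small_region, 1, 5)
        o = build_neighbor_ordering(small_region)
        t = float(small_region.populations["A"].min())
        surf = estimate_rates(small_region, reps[0], "A", t, o)
        crude = 1e5 * reps[0].cases["A"] / small_region.populations["A"]
        assert np.allclose(surf.rate, crude, rtol=1e-12)
        assert np.all(surf.radius == 0.0)

    def test_threshold_at_total_gives_flat_surface(self, small_region):
        reps, _ = run_replications(small_region, 1, 5)
        o = build_neighbor_ordering(small_region)
        total = float(small_region.populations["A"].sum())
        surf = estimate_rates(small_region, reps[0], "A", total, o)
        assert np.ptp(surf.rate) == 0.0
        assert not surf.underfilled.any()
        regional = 1e5 * reps[0].total_cases["A"] / total
        assert surf.rate[0] == pytest.approx(regional)

    def test_underfilled_flag(self, small_region):
        reps, _ = run_replications(small_region, 1, 5)
        o = build_neighbor_ordering(small_region)
        total = float(small_region.populations["A"].sum())
        surf = estimate_rates(small_region, reps[0], "A", total + 1, o)
        assert surf.underfilled.all()
        assert np.all(surf.enclosed_pop == total)

    def test_matches_brute_force_oracle(self, small_region):
        reps, _ = run_replications(small_region, 3, 5)
        o = build_neighbor_ordering(small_region)
        for rep in reps:
            for t in (30.0, 200.0, 1000.0, 4000.0):
                surf = estimate_rates(small_region, rep, "A", t, o)
                oracle_rates, oracle_radii = brute_force_rates(small_region, rep, "A", t)
                assert np.array_equal(surf.rate, oracle_rates)
                assert np.array_equal(surf.radius, oracle_radii)

    def test_errors(self, small_region):
        reps, _ = run_replications(small_region, 1, 5)
        o = build_neighbor_ordering(small_region)
        with pytest.raises(ConfigError):
            estimate_rates(small_region, reps[0], "A", 0.0, o)
        with pytest.raises(ConfigError):
            estimate_rates(small_region, reps[0], "nope", 10.0, o)


class TestStateRate:
    def test_uniform_rate_identity(self):
        region = _region([100, 900])
        surf = RateSurface("A", 10.0, "t", 1, list(region.zone_ids),
                           np.array([250.0, 250.0]), np.zeros(2), np.array([100.0, 900.0]),
                           np.array([0.0, 0.0]), np.zeros(2, dtype=bool))
        assert state_rate(surf, region) == pytest.approx(250.0)

    def test_two_zone_weighted_mean(self):
        region = _region([100, 900])
        surf = RateSurface("A", 10.0, "t", 1, list(region.zone_ids),
                           np.array([0.0, 1000.0]), np.zeros(2), np.array([100.0, 900.0]),
                           np.array([0.0, 9.0]), np.zeros(2, dtype=bool))
        assert state_rate(surf, region) == pytest.approx(900.0)

    def test_conservation_identity_every_replicate(self, small_region):
        reps, baseline = run_replications(small_region, 20, 77)
        o = build_neighbor_ordering(small_region)
        t = float(small_region.populations["A"].min())
        for l, rep in enumerate(reps):
            surf = estimate_rates(small_region, rep, "A", t, o)
            assert state_rate(surf, small_region) == pytest.approx(
                baseline.rates["A"][l], rel=1e-12
            )


class TestCrudeZoneMean:
    def test_identical_zones(self):
        region = _region([100, 100, 100])
        cases = _cases(region, [2, 2, 2])
        assert crude_zone_mean(region, cases, "A") == pytest.approx(2000.0)

    def test_zero_population_zone_excluded(self):
        region = _region([0, 100])
        cases = _cases(region, [0, 1])
        assert crude_zone_mean(region, cases, "A") == pytest.approx(1000.0)

    def test_crude_varies_more_than_weighted_state_rate(self, standard_region,
                                                        standard_replicates,
                                                        standard_ordering):
        reps, _ = standard_replicates
        lab = "65+"
        crude = np.array([crude_zone_mean(standard_region, r, lab) for r in reps])
        t = standard_region.populations[lab].min() * 50.0
        states, _ = estimate_state_rates(standard_region, reps, lab, {"t": t},
                                         standard_ordering)
        assert crude.var(ddof=1) > np.var(states["t"], ddof=1)


class TestBatchEstimation:
    def test_batch_matches_per_replicate_loop(self, small_region):
        reps, _ = run_replications(small_region, 10, 3)
        o = build_neighbor_ordering(small_region)
        thresholds = {"a": 100.0, "b": 1500.0}
        states, zone_sds = estimate_state_rates(small_region, reps, "A", thresholds, o)
        for name, t in thresholds.items():
            loop = np.array(
                [state_rate(estimate_rates(small_region, r, "A", t, o), small_region)
                 for r in reps]
            )
            assert np.allclose(states[name], loop, rtol=1e-12)
        assert set(zone_sds) == {"a", "b"}

    def test_monotone_smoothing_ladder(self, standard_region, standard_replicates,
                                       standard_ordering):
        reps, _ = standard_replicates
        ladder = {f"{t}": float(t) for t in (50, 100, 500, 1000, 5000, 10000)}
        for lab in ("35-44", "65+"):
            _, zone_sds = estimate_state_rates(standard_region, reps, lab, ladder,
                                               standard_ordering)
            sds = [zone_sds[k] for k in ladder]
            for lo, hi in zip(sds[1:], sds[:-1]):
                assert lo <= hi * 1.05

    def test_surface_frame_columns(self, small_region):
        reps, _ = run_replications(small_region, 1, 3)
        o = build_neighbor_ordering(small_region)
        surf = estimate_rates(small_region, reps[0], "A", 100.0, o, threshold_name="x")
        frame = surface_to_frame(surf)
        assert list(frame.columns) == [
            "replicate", "stratum", "threshold_name", "zone_id", "rate_per_100k",
            "radius", "enclosed_pop", "enclosed_cases", "underfilled",
        ]
        assert len(frame) == small_region.n_zones
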