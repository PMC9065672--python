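"""Synthetic farm population: marginals, determinism, location classes, I/O."""

import copy
import json
import math

import numpy as np
import pytest

from siactors import tables
from siactors.population import (
    DEFAULT_VILLAGE_CENTERS,
    FarmRecord,
    PopulationConfig,
    classify_locations,
    farm_size_from_payment,
    generate_farm_population,
    largest_remainder,
    read_population_csv,
    write_population_csv,
    write_population_geojson,
)


def marginal_of(farms, sector, getter):
    sub = [getter(f) for f in farms if f.sector == sector]
    return {v: sub.count(v) / len(sub) for v in set(sub)}


class TestQuotaGeneration:
    def test_default_counts_match_case_study(self, default_population):
        assert len(default_population) == 355
        assert sum(f.sector == "dairy" for f in default_population) == 284
        assert sum(f.sector == "fruit" for f in default_population) == 71

    @pytest.mark.parametrize("sector,n", [("dairy", 284), ("fruit", 71)])
    @pytest.mark.parametrize("attr", list(tables.CHARACTERISTIC_STATES))
    def test_marginals_within_one_over_n(self, default_population, sector, n, attr):
        getters = {
            "age": lambda f: f.age_class,
            "size": lambda f: f.size_class,
            "location": lambda f: f.location_class,
            "successor": lambda f: "yes" if f.successor else "no",
            "innovative": lambda f: f.innovative,
            "intrinsic_attitude": lambda f: f.intrinsic_attitude,
        }
        emp = marginal_of(default_population, sector, getters[attr])
        target = dict(zip(
            tables.CHARACTERISTIC_STATES[attr],
            tables.normalize(tables.CHARACTERISTIC_PRIORS[sector][attr]),
        ))
        if attr == "innovative":
            # the innovator share is pinned at exactly round(0.10 n)/n
            target["yes"] = round(0.10 * n) / n
            rest = 1 - target["yes"]
            sub = np.asarray(tables.CHARACTERISTIC_PRIORS[sector][attr][1:])
            target["neutral"], target["no"] = rest * sub / sub.sum()
        for state, p in target.items():
            assert abs(emp.get(state, 0.0) - p) <= 1.0 / n + 1e-12

    def test_innovator_count_is_exact(self, default_population):
        for sector, n in (("dairy", 284), ("fruit", 71)):
            got = sum(
                f.sector == sector and f.innovative == "yes"
                for f in default_population
            )
            assert got == round(0.10 * n)

    def test_deterministic_given_seed(self):
        a = generate_farm_population(PopulationConfig(seed=3))
        b = generate_farm_population(PopulationConfig(seed=3))
        assert a == b
        c = generate_farm_population(PopulationConfig(seed=4))
        assert a != c

    def test_empty_population(self):
        assert generate_farm_population(PopulationConfig(n_dairy=0, n_fruit=0)) == []

    def test_size_ha_positive_and_ordered_by_class(self, default_population):
        for f in default_population:
            assert f.size_ha > 0
        by_class = {}
        for f in default_population:
            by_class.setdefault((f.sector, f.size_class), []).append(f.size_ha)
        for sector in ("dairy", "fruit"):
            assert max(by_class[(sector, "small")]) <= min(by_class[(sector, "large")])

    def test_direct_sales_favors_close_farms(self, default_population):
        dairy = [f for f in default_population if f.sector == "dairy"]
        close = [f for f in dairy if f.location_class == "close"]
        far = [f for f in dairy if f.location_class != "close"]
        rate_close = sum(f.has_direct_sales for f in close) / len(close)
        rate_far = sum(f.has_direct_sales for f in far) / len(far)
        assert rate_close > rate_far


class TestConfigValidation:
    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(n_dairy=-1)

    def test_all_zero_marginal_rejected(self):
        cfg = {
            s: {k: tuple(v) for k, v in tables.CHARACTERISTIC_PRIORS[s].items()}
            for s in tables.SECTORS
        }
        cfg["dairy"]["age"] = (0.0, 0.0, 0.0)
        with pytest.raises(ValueError):
            PopulationConfig(marginals=cfg)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            PopulationConfig(sampling_mode="systematic")


class TestBernoulliMode:
    def test_successor_fraction_unbiased(self):
        # Monte-Carlo: over many seeds the empirical dairy successor fraction
        # is an unbiased estimate of the configured 29%.
        n, reps, p = 284, 200, tables.CHARACTERISTIC_PRIORS["dairy"]["successor"][0]
        fracs = []
        for seed in range(reps):
            farms = generate_farm_population(
                PopulationConfig(n_fruit=0, seed=seed, sampling_mode="bernoulli")
            )
            fracs.append(sum(f.successor for f in farms) / n)
        se = math.sqrt(p * (1 - p) / n) / math.sqrt(reps)
        assert abs(np.mean(fracs) - p) < 3 * se


class TestFarmSize:
    @pytest.mark.parametrize("payment,ha", [(26_000, 100.0), (0, 0.0), (5_200, 20.0)])
    def test_payment_to_hectares(self, payment, ha):
        assert farm_size_from_payment(payment) == pytest.approx(ha)

    def test_negative_payment_rejected(self):
        with pytest.raises(ValueError):
            farm_size_from_payment(-1.0)

    def test_linear_and_invertible(self):
        pays = np.linspace(0, 1e5, 11)
        sizes = [farm_size_from_payment(p) for p in pays]
        assert np.allclose(np.asarray(sizes) * 260.0, pays)


class TestLocationClassification:
    def _farm(self, i, x, y):
        return FarmRecord(
            farm_id=f"F{i}", sector="dairy", age_class="medium",
            size_class="medium", size_ha=30.0, location_class="close",
            successor=False, innovative="neutral", intrinsic_attitude="neutral",
            has_direct_sales=False, has_sle=False, x=x, y=y,
        )

    def test_three_clusters_map_to_three_classes(self):
        rng = np.random.default_rng(0)
        farms = []
        for i, d in enumerate([1.0] * 5 + [10.0] * 5 + [50.0] * 5):
            angle = rng.uniform(0, 2 * np.pi)
            farms.append(self._farm(
                i, d * np.cos(angle) + rng.normal(0, 0.05),
                d * np.sin(angle) + rng.normal(0, 0.05),
            ))
        classify_locations(farms, [(0.0, 0.0)])
        assert [f.location_class for f in farms] == (
            ["close"] * 5 + ["medium"] * 5 + ["remote"] * 5
        )

    def test_colocated_farms_infeasible(self):
        farms = [self._farm(i, 1.0, 1.0) for i in range(5)]
        with pytest.raises(ValueError):
            classify_locations(farms, [(0.0, 0.0)])

    def test_three_farms_three_classes(self):
        farms = [self._farm(0, 1, 0), self._farm(1, 5, 0), self._farm(2, 30, 0)]
        classify_locations(farms, [(0.0, 0.0)])
        assert [f.location_class for f in farms] == ["close", "medium", "remote"]

    def test_no_centers_rejected(self):
        with pytest.raises(ValueError):
            classify_locations([self._farm(0, 1, 1)], [])

    def test_generated_classes_consistent_with_jenks(self, default_population):
        # The invariant: re-deriving classes from coordinates reproduces the
        # classes assigned by the generator.
        farms = copy.deepcopy(default_population)
        classify_locations(farms, DEFAULT_VILLAGE_CENTERS)
        assert [f.location_class for f in farms] == [
            f.location_class for f in default_population
        ]


class TestLargestRemainder:
    def test_counts_sum_and_bound(self):
        probs = (0.26, 0.58, 0.17)
        counts = largest_remainder(np.asarray(probs) / sum(probs), 284)
        assert sum(counts) == 284
        for c, p in zip(counts, np.asarray(probs) / sum(probs)):
            assert abs(c / 284 - p) <= 1 / 284


class TestIO:
    def test_csv_round_trip(self, default_population, tmp_path):
        path = tmp_path / "farms.csv"
        write_population_csv(default_population, path)
        back = read_population_csv(path)
        assert back == default_population

    def test_geojson_structure(self, default_population, tmp_path):
        path = tmp_path / "farms.geojson"
        write_population_geojson(default_population, path)
        doc = json.loads(path.read_text())
        assert doc["type"] == "FeatureCollection"
        assert len(doc["features"]) == len(default_population)
        feat = doc["features"][0]
        assert feat["geometry"]["type"] == "Point"
        assert feat["properties"]["sector"] in ("dairy", "fruit")
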