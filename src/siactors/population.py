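"""Synthetic farm population for the case-study region.

The confidential farm data behind the study (farm accounts, payment records,
parcel maps) cannot be redistributed, so this module generates a synthetic
population whose printed structure matches the case study: 284 dairy farms
and 71 fruit farms with categorical marginals for age, size, location,
successor, innovativeness and intrinsic attitude, plus planar coordinates
around village centers whose natural-breaks distance classification
reproduces the assigned location classes.

Two sampling modes exist: ``quota`` (largest-remainder apportionment; the
default, hitting every marginal exactly at the configured population size)
and ``bernoulli`` (independent draws; unbiased but noisy).
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from . import tables
from .jenks import classify_by_breaks, jenks_breaks

__all__ = [
    "PopulationConfig",
    "FarmRecord",
    "generate_farm_population",
    "classify_locations",
    "farm_size_from_payment",
    "largest_remainder",
    "write_population_csv",
    "read_population_csv",
    "write_population_geojson",
    "DEFAULT_VILLAGE_CENTERS",
]

EURO_PER_HECTARE = 260.0  # CAP basic payment rate used to infer farm size

CSV_HEADER = [
    "farm_id", "sector", "age_class", "size_class", "size_ha",
    "location_class", "successor", "innovative", "intrinsic_attitude",
    "has_direct_sales", "has_sle", "x", "y",
]

#: Widely separated village centers so that distance-to-nearest-center is the
#: distance to the center a farm was scattered around.
DEFAULT_VILLAGE_CENTERS = ((0.0, 0.0), (120.0, 0.0), (0.0, 120.0), (120.0, 120.0))

#: Distance bands (km-scale, arbitrary units) per location class.  The gaps
#: between bands are wide relative to the within-band spread, so a 3-class
#: natural-breaks classification of the pooled distances recovers the classes.
_DISTANCE_BANDS = {"close": (0.5, 3.0), "medium": (8.0, 14.0), "remote": (22.0, 35.0)}

#: size_ha bounds per sector and size class (hectares).  Dutch dairy farms
#: are grassland-based and an order of magnitude larger than fruit orchards.
_SIZE_BOUNDS = {
    "dairy": {"small": (5.0, 25.0), "medium": (25.0, 60.0), "large": (60.0, 150.0)},
    "fruit": {"small": (1.0, 5.0), "medium": (5.0, 15.0), "large": (15.0, 60.0)},
}


@dataclass
class PopulationConfig:
    """Configuration of the synthetic population.

    Defaults reproduce the case-study structure; all categorical marginals
    are renormalized on construction (several printed rows do not sum to
    100%).
    """

    n_dairy: int = tables.N_DAIRY
    n_fruit: int = tables.N_FRUIT
    seed: int = 0
    sampling_mode: str = "quota"
    marginals: dict = field(default_factory=lambda: {
        s: {k: tuple(v) for k, v in tables.CHARACTERISTIC_PRIORS[s].items()}
        for s in tables.SECTORS
    })
    innovative_fraction: float = 0.10
    initial_uptake: dict = field(default_factory=lambda: {
        s: {
            "direct_sales": tables.UPTAKE_TARGETS[s]["FoA4"],
            "landscape_elements": tables.UPTAKE_TARGETS[s]["FoA1_3"],
        }
        for s in tables.SECTORS
    })
    village_centers: tuple = DEFAULT_VILLAGE_CENTERS
    close_direct_sales_odds: float = 2.0
    size_bounds: dict = field(default_factory=lambda: {
        s: {k: tuple(v) for k, v in _SIZE_BOUNDS[s].items()} for s in tables.SECTORS
    })

    def __post_init__(self) -> None:
        if self.n_dairy < 0 or self.n_fruit < 0:
            raise ValueError("invalid config: farm counts must be >= 0")
        if self.sampling_mode not in ("quota", "bernoulli"):
            raise ValueError(f"invalid sampling_mode {self.sampling_mode!r}")
        if not 0.0 <= self.innovative_fraction <= 1.0:
            raise ValueError("innovative_fraction must be in [0, 1]")
        if not self.village_centers:
            raise ValueError("at least one village center is required")
        for sector in self.marginals:
            for attr, probs in self.marginals[sector].items():
                self.marginals[sector][attr] = tables.normalize(
                    probs, f"{sector}/{attr} marginal"
                )
        for sector, rates in self.initial_uptake.items():
            for key, r in rates.items():
                if not 0.0 <= r <= 1.0:
                    raise ValueError(f"initial uptake {sector}/{key} not in [0,1]")

    @classmethod
    def from_yaml(cls, path) -> "PopulationConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class FarmRecord:
    """One synthetic farm."""

    farm_id: str
    sector: str
    age_class: str
    size_class: str
    size_ha: float
    location_class: str
    successor: bool
    innovative: str
    intrinsic_attitude: str
    has_direct_sales: bool
    has_sle: bool
    x: float
    y: float

    @property
    def basic_payment(self) -> float:
        return self.size_ha * EURO_PER_HECTARE


def farm_size_from_payment(basic_payment: float) -> float:
    """Farm size in hectares implied by the CAP basic payment (260 EUR/ha)."""
    if basic_payment < 0:
        raise ValueError("basic payment must be >= 0")
    return basic_payment / EURO_PER_HECTARE


def largest_remainder(probs: Sequence[float], n: int) -> list[int]:
    """Apportion n units to classes by the largest-remainder method.

    Ties in remainder are broken by class order (earlier classes first), so
    the result is deterministic.
    """
    probs = np.asarray(probs, dtype=float)
    quotas = probs * n
    counts = np.floor(quotas).astype(int)
    remainder = int(n - counts.sum())
    if remainder:
        order = sorted(
            range(len(probs)), key=lambda i: (-(quotas[i] - counts[i]), i)
        )
        for i in order[:remainder]:
            counts[i] += 1
    return counts.tolist()


def _quota_labels(states, probs, n, rng) -> list[str]:
    counts = largest_remainder(probs, n)
    labels = [s for s, c in zip(states, counts) for _ in range(c)]
    rng.shuffle(labels)
    return labels


def _bernoulli_labels(states, probs, n, rng) -> list[str]:
    return list(rng.choice(states, size=n, p=np.asarray(probs) / np.sum(probs)))


def _innovative_labels(config, sector, n, rng) -> list[str]:
    """Exactly round(f*n) innovators in quota mode; the rest split
    neutral/no in the proportions of the printed innovativeness row."""
    probs = config.marginals[sector]["innovative"]
    if config.sampling_mode == "bernoulli":
        p_yes = config.innovative_fraction
        rest = np.asarray(probs[1:], dtype=float)
        rest = rest / rest.sum() * (1 - p_yes)
        return _bernoulli_labels(
            tables.CHARACTERISTIC_STATES["innovative"], (p_yes, *rest), n, rng
        )
    n_yes = round(config.innovative_fraction * n)
    rest_counts = largest_remainder(np.asarray(probs[1:]) / sum(probs[1:]), n - n_yes)
    labels = (
        ["yes"] * n_yes + ["neutral"] * rest_counts[0] + ["no"] * rest_counts[1]
    )
    rng.shuffle(labels)
    return labels


def _assign_flags(n: int, rate: float, weights, mode: str, rng) -> np.ndarray:
    """Boolean flags at a target rate, preferentially where weights are high."""
    w = np.asarray(weights, dtype=float)
    if mode == "bernoulli":
        p = np.clip(rate * w / w.mean() if w.mean() > 0 else w, 0.0, 1.0)
        return rng.random(n) < p
    k = round(rate * n)
    flags = np.zeros(n, dtype=bool)
    if k > 0:
        idx = rng.choice(n, size=min(k, n), replace=False, p=w / w.sum())
        flags[idx] = True
    return flags


def generate_farm_population(config: PopulationConfig | None = None) -> list[FarmRecord]:
    """Generate the synthetic population (deterministic given ``config.seed``)."""
    config = config or PopulationConfig()
    farms: list[FarmRecord] = []
    centers = np.asarray(config.village_centers, dtype=float)
    for sector, n in (("dairy", config.n_dairy), ("fruit", config.n_fruit)):
        rng = np.random.default_rng((config.seed, {"dairy": 1, "fruit": 2}[sector]))
        if n == 0:
            continue
        m = config.marginals[sector]
        pick = _quota_labels if config.sampling_mode == "quota" else _bernoulli_labels
        age = pick(tables.CHARACTERISTIC_STATES["age"], m["age"], n, rng)
        size_cls = pick(tables.CHARACTERISTIC_STATES["size"], m["size"], n, rng)
        loc = pick(tables.CHARACTERISTIC_STATES["location"], m["location"], n, rng)
        succ = pick(tables.CHARACTERISTIC_STATES["successor"], m["successor"], n, rng)
        att = pick(
            tables.CHARACTERISTIC_STATES["intrinsic_attitude"],
            m["intrinsic_attitude"], n, rng,
        )
        innov = _innovative_labels(config, sector, n, rng)

        size_ha = np.array([
            rng.uniform(*config.size_bounds[sector][c]) for c in size_cls
        ])

        # Coordinates: scatter each farm around a random village center at a
        # distance drawn from its location class's band.
        center_idx = rng.integers(len(centers), size=n)
        dist = np.array([rng.uniform(*_DISTANCE_BANDS[c]) for c in loc])
        angle = rng.uniform(0, 2 * math.pi, size=n)
        xy = centers[center_idx] + np.column_stack(
            [dist * np.cos(angle), dist * np.sin(angle)]
        )

        ds_weights = np.where(
            np.asarray(loc) == "close", config.close_direct_sales_odds, 1.0
        )
        has_ds = _assign_flags(
            n, config.initial_uptake[sector]["direct_sales"],
            ds_weights, config.sampling_mode, rng,
        )
        has_sle = _assign_flags(
            n, config.initial_uptake[sector]["landscape_elements"],
            np.ones(n), config.sampling_mode, rng,
        )

        for i in range(n):
            farms.append(FarmRecord(
                farm_id=f"{sector[0].upper()}{i + 1:04d}",
                sector=sector,
                age_class=age[i],
                size_class=size_cls[i],
                size_ha=float(size_ha[i]),
                location_class=loc[i],
                successor=succ[i] == "yes",
                innovative=innov[i],
                intrinsic_attitude=att[i],
                has_direct_sales=bool(has_ds[i]),
                has_sle=bool(has_sle[i]),
                x=float(xy[i, 0]),
                y=float(xy[i, 1]),
            ))
    return farms


def classify_locations(
    farms: list[FarmRecord], village_centers: Sequence[tuple[float, float]]
) -> list[FarmRecord]:
    """Set each farm's location class by 3-class natural breaks on the
    distance to the nearest village center (classes ordered close < medium <
    remote by distance).  Returns the same records, mutated."""
    if not village_centers:
        raise ValueError("at least one village center is required")
    centers = np.asarray(village_centers, dtype=float).reshape(-1, 2)
    pts = np.array([[f.x, f.y] for f in farms])
    if len(farms) == 0:
        return farms
    d = np.sqrt(((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
    breaks = jenks_breaks(d, 3)  # raises if < 3 distinct distances
    classes = classify_by_breaks(d, breaks)
    names = tables.CHARACTERISTIC_STATES["location"]
    for farm, c in zip(farms, classes):
        farm.location_class = names[int(c)]
    return farms


# ---------------------------------------------------------------------------
# I/O


def write_population_csv(farms: list[FarmRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for f in farms:
            row = asdict(f)
            writer.writerow([row[k] for k in CSV_HEADER])


def read_population_csv(path) -> list[FarmRecord]:
    farms = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            farms.append(FarmRecord(
                farm_id=row["farm_id"],
                sector=row["sector"],
                age_class=row["age_class"],
                size_class=row["size_class"],
                size_ha=float(row["size_ha"]),
                location_class=row["location_class"],
                successor=row["successor"] == "True",
                innovative=row["innovative"],
                intrinsic_attitude=row["intrinsic_attitude"],
                has_direct_sales=row["has_direct_sales"] == "True",
                has_sle=row["has_sle"] == "True",
                x=float(row["x"]),
                y=float(row["y"]),
            ))
    return farms


def write_population_geojson(farms: list[FarmRecord], path, extra: dict | None = None) -> None:
    """GeoJSON FeatureCollection of Point features (planar coordinates).

    ``extra`` maps farm_id -> dict of additional properties (e.g. scenario
    probability differences)."""
    features = []
    for f in farms:
        props = asdict(f)
        x, y = props.pop("x"), props.pop("y")
        if extra and f.farm_id in extra:
            props.update(extra[f.farm_id])
        features.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [x, y]},
            "properties": props,
        })
    doc = {"type": "FeatureCollection", "features": features}
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
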