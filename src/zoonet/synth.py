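"""Synthetic zoo-network generator with known ground truth.

Emulates the shape of a global zoo registry: zoos clustered into
continental regions, per-order world species pools spanning orders of
magnitude, a threatened fraction per order, and strongly right-skewed
per-species holdings spread over many zoos.  A per-order selection bias
``beta`` controls how strongly threatened species are favoured when zoo
collections are assembled (``beta = 1`` is unbiased random collection —
exactly the null hypothesis of the representation test; ``beta = 0``
excludes threatened species entirely).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import yaml

from .datamodel import (
    ChecklistOrder,
    Holding,
    SpeciesTaxon,
    ValidatedDataset,
    IUCNCategory,
    Zoo,
    validate_dataset,
)

_KM_PER_DEG = 111.19492664455873  # pi/180 * 6371 km

_THREATENED_SPLIT = (("VU", 0.5), ("EN", 0.3), ("CR", 0.2))
_NON_THREATENED_SPLIT = (("LC", 0.80), ("NT", 0.12), ("DD", 0.08))


@dataclass(frozen=True)
class Region:
    """A continental region: zoos scatter around its center."""

    latitude: float
    longitude: float
    share: float
    spread_km: float = 500.0


@dataclass(frozen=True)
class OrderSpec:
    """World totals and collection bias for one taxonomic order."""

    class_name: str
    order_name: str
    n_total: int
    n_threatened: int
    bias: float = 1.0  # selection weight of threatened species; 1 = null
    held_fraction: float | None = None  # overrides the scenario default
    n_held: int | None = None  # exact distinct species held, overrides fractions

    def __post_init__(self) -> None:
        if not 0 <= self.n_threatened <= self.n_total:
            raise ValueError(f"{self.order_name}: need 0 <= n_threatened <= n_total")
        if self.bias < 0:
            raise ValueError(f"{self.order_name}: bias must be >= 0")


@dataclass(frozen=True)
class AbundanceModel:
    """Distribution of a species' network-wide individual count.

    Laws: ``lognormal`` (params ``median``, ``sigma``; discretized, default
    — most totals < 100, a small fraction > 1,000), ``zipf`` (params ``a``,
    ``shift``) and ``fixed`` (param ``value``).
    """

    law: str = "lognormal"
    params: Mapping[str, float] = field(default_factory=dict)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        p = dict(self.params)
        if self.law == "lognormal":
            median = p.get("median", 40.0)
            sigma = p.get("sigma", 1.2)
            x = rng.lognormal(mean=np.log(median), sigma=sigma, size=size)
            return np.maximum(1, np.rint(x)).astype(int)
        if self.law == "zipf":
            a = p.get("a", 1.8)
            shift = int(p.get("shift", 20))
            return shift + rng.zipf(a, size=size)
        if self.law == "fixed":
            return np.full(size, int(p.get("value", 60)))
        raise ValueError(f"unknown abundance law {self.law!r}")


@dataclass(frozen=True)
class SyntheticScenario:
    seed: int = 0
    n_zoos: int = 20
    regions: Sequence[Region] = ()
    orders: Sequence[OrderSpec] = ()
    held_fraction: float = 0.3
    mean_zoos_per_species: float = 3.0
    abundance: AbundanceModel = field(default_factory=AbundanceModel)
    range_clustering: bool = False
    range_spread_km: float = 2000.0

    def __post_init__(self) -> None:
        if self.n_zoos < 1:
            raise ValueError("need at least one zoo")
        if not self.regions:
            raise ValueError("need at least one region")
        if not self.orders:
            raise ValueError("need at least one order")
        total_share = sum(r.share for r in self.regions)
        if abs(total_share - 1.0) > 1e-9:
            raise ValueError(f"region shares sum to {total_share}, not 1")
        if not 0 < self.held_fraction <= 1:
            raise ValueError("held_fraction must lie in (0, 1]")
        if self.mean_zoos_per_species < 1:
            raise ValueError("mean_zoos_per_species must be >= 1")

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SyntheticScenario":
        d = dict(d)
        d["regions"] = tuple(Region(**r) for r in d.get("regions", ()))
        d["orders"] = tuple(OrderSpec(**o) for o in d.get("orders", ()))
        if "abundance" in d:
            a = dict(d["abundance"])
            law = a.pop("law", "lognormal")
            params = a.pop("params", a)
            d["abundance"] = AbundanceModel(law, dict(params))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SyntheticScenario":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["regions"] = [dataclasses.asdict(r) for r in self.regions]
        d["orders"] = [dataclasses.asdict(o) for o in self.orders]
        d["abundance"] = {"law": self.abundance.law, "params": dict(self.abundance.params)}
        return d

    def resolved_n_held(self, spec: OrderSpec) -> int:
        if spec.n_held is not None:
            n = spec.n_held
        else:
            frac = spec.held_fraction if spec.held_fraction is not None else self.held_fraction
            n = int(round(frac * spec.n_total))
        return min(max(n, 0), spec.n_total)


def demo_scenario(seed: int = 0) -> SyntheticScenario:
    """Small two-region, six-order scenario used for smoke tests and docs."""
    return SyntheticScenario(
        seed=seed,
        n_zoos=20,
        regions=(
            Region(50.0, 10.0, share=0.6, spread_km=700.0),
            Region(40.0, -95.0, share=0.4, spread_km=700.0),
        ),
        orders=(
            OrderSpec("Mammalia", "Carnivora", 60, 18),
            OrderSpec("Mammalia", "Rodentia", 120, 25),
            OrderSpec("Aves", "Passeriformes", 150, 20),
            OrderSpec("Aves", "Psittaciformes", 80, 25),
            OrderSpec("Reptilia", "Testudines", 70, 30),
            OrderSpec("Amphibia", "Caudata", 90, 45),
        ),
        held_fraction=0.35,
        mean_zoos_per_species=3.0,
    )


def _region_allocation(shares: Sequence[float], n: int) -> list[int]:
    """Largest-remainder allocation of n zoos to regions."""
    raw = [s * n for s in shares]
    counts = [int(x) for x in raw]
    rema = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[rema[i % len(rema)]] += 1
    return counts


def generate_zoos(scenario: SyntheticScenario, seed: int | None = None) -> list[Zoo]:
    """Scatter zoos around region centers with Gaussian spread (in km)."""
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    counts = _region_allocation([r.share for r in scenario.regions], scenario.n_zoos)
    zoos: list[Zoo] = []
    i = 0
    for region, k in zip(scenario.regions, counts):
        for _ in range(k):
            dy, dx = rng.normal(0.0, region.spread_km, size=2) if region.spread_km > 0 else (0.0, 0.0)
            lat = region.latitude + dy / _KM_PER_DEG
            lat = float(np.clip(lat, -89.999, 89.999))
            coslat = max(np.cos(np.radians(region.latitude)), 1e-6)
            lon = region.longitude + dx / (_KM_PER_DEG * coslat)
            lon = float((lon + 180.0) % 360.0 - 180.0)
            zoos.append(Zoo(f"Z{i:04d}", lat, lon))
            i += 1
    return zoos


def generate_checklist_and_species(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[list[ChecklistOrder], list[SpeciesTaxon]]:
    """World species pool per order with exactly n_threatened threatened."""
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 1_000_003
    )
    checklist: list[ChecklistOrder] = []
    species: list[SpeciesTaxon] = []
    for spec in scenario.orders:
        checklist.append(
            ChecklistOrder(spec.class_name, spec.order_name, spec.n_total, spec.n_threatened)
        )
        threatened_idx = set(
            rng.choice(spec.n_total, size=spec.n_threatened, replace=False).tolist()
        )
        for k in range(spec.n_total):
            if k in threatened_idx:
                codes, probs = zip(*_THREATENED_SPLIT)
            else:
                codes, probs = zip(*_NON_THREATENED_SPLIT)
            cat = IUCNCategory(rng.choice(codes, p=probs))
            species.append(
                SpeciesTaxon(f"{spec.order_name}_{k:04d}", spec.class_name, spec.order_name, cat)
            )
    return checklist, species


def _weighted_subset(
    rng: np.random.Generator, weights: np.ndarray, k: int
) -> np.ndarray:
    """Weighted sampling without replacement (Gumbel top-k on log weights)."""
    with np.errstate(divide="ignore"):
        keys = np.log(weights) + rng.gumbel(size=weights.size)
    k = min(k, int((weights > 0).sum()))
    if k == 0:
        return np.array([], dtype=int)
    return np.argpartition(-keys, k - 1)[:k]


def sample_zoo_collections(
    scenario: SyntheticScenario,
    zoos: Sequence[Zoo],
    species: Sequence[SpeciesTaxon],
    seed: int | None = None,
) -> tuple[list[Holding], dict]:
    """Assemble zoo holdings and return them with ground-truth bookkeeping.

    Per order, the network-held species set is a weighted draw without
    replacement (weight ``beta`` for threatened species, 1 otherwise), so
    under ``beta = 1`` the held threatened count is exactly hypergeometric.
    Each held species receives a heavy-tailed global abundance, split across
    a Poisson-sized set of holding zoos (uniform, or anchored near a random
    zoo when range clustering is on).
    """
    rng = np.random.default_rng(
        (scenario.seed if seed is None else seed) + 2_000_029
    )
    by_order: dict[str, list[SpeciesTaxon]] = {}
    for s in species:
        by_order.setdefault(s.order_name, []).append(s)

    dmat = None
    if scenario.range_clustering:
        from .clusters import pairwise_distance_matrix

        dmat = pairwise_distance_matrix(list(zoos))

    holdings: list[Holding] = []
    truth: dict = {
        "orders": {},
        "species_totals": {},
        "total_individuals": 0,
    }
    n_zoos = len(zoos)
    for spec in scenario.orders:
        pool = by_order.get(spec.order_name, [])
        if len(pool) != spec.n_total:
            raise ValueError(f"species pool for {spec.order_name!r} does not match spec")
        n_held = scenario.resolved_n_held(spec)
        weights = np.array([spec.bias if s.is_threatened else 1.0 for s in pool])
        chosen = _weighted_subset(rng, weights, n_held)
        held = [pool[i] for i in sorted(chosen.tolist())]
        totals = scenario.abundance.draw(rng, len(held))
        for sp, total in zip(held, totals):
            total = int(total)
            k = 1 + int(rng.poisson(scenario.mean_zoos_per_species - 1.0))
            k = max(1, min(k, n_zoos, total))
            if dmat is not None:
                anchor = int(rng.integers(n_zoos))
                zw = np.exp(-dmat.matrix[anchor] / max(scenario.range_spread_km, 1e-9))
                zoo_idx = _weighted_subset(rng, zw, k)
            else:
                zoo_idx = rng.choice(n_zoos, size=k, replace=False)
            # every holding zoo gets at least one individual
            alloc = np.ones(k, dtype=int)
            alloc += rng.multinomial(total - k, np.full(k, 1.0 / k))
            for zi, cnt in zip(zoo_idx, alloc):
                holdings.append(Holding(zoos[int(zi)].zoo_id, sp.species_id, int(cnt)))
            truth["species_totals"][sp.species_id] = total
            truth["total_individuals"] += total
        truth["orders"][spec.order_name] = {
            "class": spec.class_name,
            "z": len(held),
            "w": sum(1 for s in held if s.is_threatened),
            "held_species": [s.species_id for s in held],
        }
    return holdings, truth


def generate_dataset(
    scenario: SyntheticScenario, seed: int | None = None
) -> tuple[ValidatedDataset, dict]:
    """Compose the three generators and validate the result."""
    base = scenario.seed if seed is None else seed
    zoos = generate_zoos(scenario, base)
    checklist, species = generate_checklist_and_species(scenario, base)
    holdings, truth = sample_zoo_collections(scenario, zoos, species, base)
    dataset = validate_dataset(zoos, species, holdings, checklist)
    return dataset, truth
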