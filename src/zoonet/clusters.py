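"""Radial zoo-cluster analysis of threatened-species metapopulations.

A *cluster* is the set of zoos within great-circle radius ``r`` of a focal
zoo.  For each threatened species and threshold ``m`` (50/100/250
individuals) the analysis estimates, as a function of ``r``, the
probability that a cluster around a randomly chosen focal zoo pools at
least ``m`` individuals.  Per taxonomic class, the radius maximizing the
mean probability-to-distance ratio is the *optimal cluster* radius.

Two engines are provided: Monte Carlo (focal zoos drawn uniformly with
replacement, the procedure described in the source method) and exhaustive
(every zoo as focal once — exact, and the oracle for the Monte Carlo
engine).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import Holding, ValidatedDataset, Zoo, haversine_km

Engine = Literal["monte_carlo", "exhaustive"]

#: Monte Carlo iteration count used by the source procedure.
DEFAULT_ITERATIONS = 2_000


def default_radius_grid(r_max: float = 10_000.0, step: float = 100.0) -> np.ndarray:
    """Radius grid in km: ``step, 2*step, ..., r_max``."""
    if step <= 0 or r_max < step:
        raise ValueError("need 0 < step <= r_max")
    return np.arange(step, r_max + step / 2, step)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric great-circle distance matrix over the zoos, in km."""

    zoo_ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.zoo_ids), len(self.zoo_ids)):
            raise ValueError("matrix shape does not match zoo ids")
        if not np.all(np.isfinite(m)) or np.any(m < 0):
            raise ValueError("distances must be finite and non-negative")
        if np.any(np.diag(m) != 0) or not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric with zero diagonal")

    @property
    def n_zoos(self) -> int:
        return len(self.zoo_ids)

    def diameter(self) -> float:
        return float(self.matrix.max())

    def index_of(self, zoo_id: str) -> int:
        return self.zoo_ids.index(zoo_id)


@dataclass(frozen=True)
class ZooCluster:
    """Zoos within ``radius`` km of a focal zoo (the focal zoo included)."""

    focal_zoo: str
    radius: float
    members: tuple[str, ...]
    holding_count: int = 0

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class ClusterCurve:
    """Per-species threshold-attainment probability as a function of radius."""

    species_id: str
    threshold: int
    radii: np.ndarray
    p: np.ndarray
    mean_zoos: np.ndarray
    mean_zoos_with_species: np.ndarray
    iterations: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class RatioCurve:
    """Class-mean probability/distance ratio per radius."""

    class_name: str
    threshold: int
    radii: np.ndarray
    ratio: np.ndarray
    n_species: int


@dataclass(frozen=True)
class OptimalCluster:
    """Radius maximizing the probability-to-distance ratio for one class."""

    class_name: str
    threshold: int
    n_species: int
    radius_km: float
    probability: float
    mean_zoos: float
    mean_zoos_with_species: float


def pairwise_distance_matrix(zoos: Sequence[Zoo]) -> DistanceMatrix:
    """Haversine distance matrix over the zoos, vectorized."""
    if len(zoos) < 1:
        raise ValueError("need at least one zoo")
    lat = np.radians([z.latitude for z in zoos])
    lon = np.radians([z.longitude for z in zoos])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    from .datamodel import EARTH_RADIUS_KM

    m = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(m, 0.0)
    m = (m + m.T) / 2  # enforce exact symmetry against fp noise
    return DistanceMatrix(tuple(z.zoo_id for z in zoos), m)


def zoo_cluster(
    dmat: DistanceMatrix,
    focal_zoo: str,
    radius: float,
    species_zoos: Iterable[str] = (),
) -> ZooCluster:
    """Resolve the cluster around ``focal_zoo`` (membership: distance <= r)."""
    j = dmat.index_of(focal_zoo)
    mask = dmat.matrix[j] <= radius
    members = tuple(zid for zid, keep in zip(dmat.zoo_ids, mask) if keep)
    holders = set(species_zoos)
    return ZooCluster(focal_zoo, radius, members, sum(1 for z in members if z in holders))


def metapopulation_size(
    species_id: str, cluster: ZooCluster, holdings: Iterable[Holding]
) -> int:
    """Individuals of ``species_id`` pooled over the cluster's member zoos."""
    members = set(cluster.members)
    return sum(
        h.count for h in holdings if h.species_id == species_id and h.zoo_id in members
    )


def eligible_species(
    dataset: ValidatedDataset, class_name: str, m: int
) -> list[str]:
    """Threatened species of a class whose network-wide total reaches ``m``.

    Species that cannot reach the threshold even when pooling every zoo are
    excluded from the cluster analysis.
    """
    out = [
        s.species_id
        for s in dataset.species
        if s.class_name == class_name
        and s.is_threatened
        and dataset.global_total(s.species_id) >= m
    ]
    return sorted(out)


class NetworkIndex:
    """Precomputed per-focal-zoo cumulative structure for fast radial queries.

    For each focal zoo the other zoos are sorted by distance; species counts
    re-ordered the same way admit cumulative sums, so the pooled count
    within any radius is a single lookup.
    """

    def __init__(self, dmat: DistanceMatrix):
        self.dmat = dmat
        self._order = np.argsort(dmat.matrix, axis=1, kind="stable")
        self._sorted_d = np.take_along_axis(dmat.matrix, self._order, axis=1)
        self._grid_cache: dict[tuple[float, ...], np.ndarray] = {}

    def cluster_sizes(self, radii: np.ndarray) -> np.ndarray:
        """(n_zoos, n_radii) membership counts, inclusive of the focal zoo."""
        key = tuple(np.asarray(radii, dtype=float))
        idx = self._grid_cache.get(key)
        if idx is None:
            idx = np.vstack(
                [np.searchsorted(row, radii, side="right") for row in self._sorted_d]
            )
            self._grid_cache[key] = idx
        return idx

    def pooled_counts(
        self, counts: np.ndarray, radii: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per (focal zoo, radius): pooled individuals and zoos holding the species.

        ``counts`` is the per-zoo individual count vector for one species.
        """
        idx = self.cluster_sizes(radii)
        ordered = counts[self._order]  # (Z, Z)
        csum = np.concatenate(
            [np.zeros((ordered.shape[0], 1)), np.cumsum(ordered, axis=1)], axis=1
        )
        psum = np.concatenate(
            [
                np.zeros((ordered.shape[0], 1)),
                np.cumsum(ordered > 0, axis=1),
            ],
            axis=1,
        )
        rows = np.arange(ordered.shape[0])[:, None]
        return csum[rows, idx], psum[rows, idx]


def _species_count_vector(
    species_id: str,
    dmat: DistanceMatrix,
    holdings: Iterable[Holding] | Mapping[str, int],
) -> np.ndarray:
    counts = np.zeros(dmat.n_zoos)
    pos = {zid: i for i, zid in enumerate(dmat.zoo_ids)}
    if isinstance(holdings, Mapping):
        items = holdings.items()
    else:
        items = (
            (h.zoo_id, h.count) for h in holdings if h.species_id == species_id
        )
    for zid, count in items:
        counts[pos[zid]] += count
    return counts


def exhaustive_cluster_probability(
    species_id: str,
    radius: float,
    m: int,
    dmat: DistanceMatrix,
    holdings: Iterable[Holding] | Mapping[str, int],
    index: NetworkIndex | None = None,
) -> tuple[float, float, float]:
    """Exact cluster statistics with every zoo serving as focal once.

    Returns ``(p, mean_zoos, mean_zoos_with_species)`` where ``p`` is the
    fraction of focal zoos whose radius-``r`` cluster pools >= ``m``
    individuals.
    """
    index = index or NetworkIndex(dmat)
    counts = _species_count_vector(species_id, dmat, holdings)
    radii = np.array([float(radius)])
    pooled, present = index.pooled_counts(counts, radii)
    sizes = index.cluster_sizes(radii)
    return (
        float((pooled[:, 0] >= m).mean()),
        float(sizes[:, 0].mean()),
        float(present[:, 0].mean()),
    )


def mc_cluster_probability(
    species_id: str,
    radius: float,
    m: int,
    dmat: DistanceMatrix,
    holdings: Iterable[Holding] | Mapping[str, int],
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    index: NetworkIndex | None = None,
) -> tuple[float, float, float]:
    """Monte Carlo cluster statistics.

    Each iteration draws a focal zoo uniformly with replacement from all
    zoos, forms the radius-``r`` cluster, and scores 1 iff the pooled count
    reaches ``m``.  Means of cluster size and zoos-holding-the-species are
    taken over all sampled clusters.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    index = index or NetworkIndex(dmat)
    counts = _species_count_vector(species_id, dmat, holdings)
    radii = np.array([float(radius)])
    pooled, present = index.pooled_counts(counts, radii)
    sizes = index.cluster_sizes(radii)
    rng = np.random.default_rng(seed)
    focal = rng.integers(0, dmat.n_zoos, size=iterations)
    return (
        float((pooled[focal, 0] >= m).mean()),
        float(sizes[focal, 0].mean()),
        float(present[focal, 0].mean()),
    )


def species_cluster_curve(
    dataset: ValidatedDataset,
    species_id: str,
    m: int,
    radii: np.ndarray | None = None,
    engine: Engine = "exhaustive",
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    dmat: DistanceMatrix | None = None,
    index: NetworkIndex | None = None,
) -> ClusterCurve:
    """Probability and mean zoo counts across the whole radius grid."""
    sp = dataset.species_by_id(species_id)
    if species_id not in eligible_species(dataset, sp.class_name, m):
        raise ValueError(
            f"species {species_id!r} not eligible at threshold {m}; "
            "see eligible_species()"
        )
    if radii is None:
        radii = default_radius_grid()
    radii = np.asarray(radii, dtype=float)
    if radii.size == 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radius grid must be non-empty and strictly increasing")
    dmat = dmat or pairwise_distance_matrix(dataset.zoos)
    index = index or NetworkIndex(dmat)
    counts = _species_count_vector(species_id, dmat, dataset.holdings_of(species_id))
    pooled, present = index.pooled_counts(counts, radii)
    sizes = index.cluster_sizes(radii)
    if engine == "exhaustive":
        p = (pooled >= m).mean(axis=0)
        mean_zoos = sizes.mean(axis=0)
        mean_present = present.mean(axis=0)
        return ClusterCurve(species_id, m, radii, p, mean_zoos, mean_present)
    if engine == "monte_carlo":
        rng = np.random.default_rng(seed)
        focal = rng.integers(0, dmat.n_zoos, size=iterations)
        p = (pooled[focal] >= m).mean(axis=0)
        mean_zoos = sizes[focal].mean(axis=0)
        mean_present = present[focal].mean(axis=0)
        return ClusterCurve(species_id, m, radii, p, mean_zoos, mean_present, iterations, seed)
    raise ValueError(f"unknown engine {engine!r}")


def class_ratio_curve(
    class_name: str,
    m: int,
    curves: Sequence[ClusterCurve],
    radii: np.ndarray | None = None,
) -> RatioCurve:
    """Mean over eligible species of p(r) / r, per radius."""
    if not curves:
        raise ValueError(f"no eligible species for class {class_name!r} at threshold {m}")
    if radii is None:
        radii = curves[0].radii
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("ratio undefined at radius 0; grid must be positive")
    for c in curves:
        if c.threshold != m:
            raise ValueError(f"curve for {c.species_id} has threshold {c.threshold}, not {m}")
        if not np.array_equal(c.radii, radii):
            raise ValueError(f"curve for {c.species_id} is on a different radius grid")
    p = np.vstack([c.p for c in curves])
    ratio = (p / radii[None, :]).mean(axis=0)
    return RatioCurve(class_name, m, radii, ratio, len(curves))


def optimal_cluster(
    ratio_curve: RatioCurve, curves: Sequence[ClusterCurve]
) -> OptimalCluster:
    """Pick the grid radius maximizing the ratio (smallest radius on ties).

    The reported probability and zoo counts are species means at that
    radius.
    """
    best = int(np.argmax(ratio_curve.ratio))  # argmax takes the first max
    r_star = float(ratio_curve.radii[best])
    p = float(np.mean([c.p[best] for c in curves]))
    mean_zoos = float(np.mean([c.mean_zoos[best] for c in curves]))
    mean_present = float(np.mean([c.mean_zoos_with_species[best] for c in curves]))
    return OptimalCluster(
        ratio_curve.class_name,
        ratio_curve.threshold,
        ratio_curve.n_species,
        r_star,
        p,
        mean_zoos,
        mean_present,
    )


def cluster_report(
    dataset: ValidatedDataset,
    thresholds: Sequence[int] = (50, 100, 250),
    radii: np.ndarray | None = None,
    engine: Engine | Literal["auto"] = "auto",
    iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    classes: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, int], list[ClusterCurve]]]:
    """Optimal-cluster summary per (class, threshold), plus all curves.

    Engine ``auto`` resolves to exhaustive enumeration up to 1,000 zoos
    (exact and cheap with the precomputed index) and Monte Carlo beyond.
    Classes with no eligible species at a threshold are skipped.
    """
    if radii is None:
        radii = default_radius_grid()
    radii = np.asarray(radii, dtype=float)
    if engine == "auto":
        engine = "exhaustive" if len(dataset.zoos) <= 1_000 else "monte_carlo"
    dmat = pairwise_distance_matrix(dataset.zoos)
    index = NetworkIndex(dmat)
    classes = list(classes) if classes is not None else dataset.class_names()
    root = np.random.SeedSequence(seed)

    rows = []
    all_curves: dict[tuple[str, int], list[ClusterCurve]] = {}
    for class_name in classes:
        for m in thresholds:
            species_ids = eligible_species(dataset, class_name, m)
            if not species_ids:
                continue
            curves = [
                species_cluster_curve(
                    dataset,
                    sid,
                    m,
                    radii=radii,
                    engine=engine,
                    iterations=iterations,
                    seed=int(root.spawn(1)[0].generate_state(1)[0]),
                    dmat=dmat,
                    index=index,
                )
                for sid in species_ids
            ]
            all_curves[(class_name, m)] = curves
            opt = optimal_cluster(class_ratio_curve(class_name, m, curves, radii), curves)
            rows.append(
                {
                    "class": opt.class_name,
                    "threshold": opt.threshold,
                    "species_in_cluster": opt.n_species,
                    "radial_distance_km": opt.radius_km,
                    "probability": opt.probability,
                    "avg_zoos_in_cluster": opt.mean_zoos,
                    "avg_zoos_with_species": opt.mean_zoos_with_species,
                }
            )
    return pd.DataFrame(rows), all_curves


def curves_to_frame(
    curves: Mapping[tuple[str, int], Sequence[ClusterCurve]]
) -> pd.DataFrame:
    """Flatten per-species curves into a long-format table."""
    rows = []
    for (class_name, m), cs in curves.items():
        for c in cs:
            for i, r in enumerate(c.radii):
                rows.append(
                    {
                        "class": class_name,
                        "threshold": m,
                        "species": c.species_id,
                        "radius_km": float(r),
                        "p": float(c.p[i]),
                        "mean_zoos": float(c.mean_zoos[i]),
                        "mean_zoos_with_species": float(c.mean_zoos_with_species[i]),
                    }
                )
    return pd.DataFrame(rows)
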