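"""Domain types, CSV readers/writers, validation and geodesic distance.

The dataset consists of four tables:

* ``zoos.csv`` — ``zoo_id,latitude,longitude``
* ``species.csv`` — ``species_id,class_name,order_name,category``
* ``holdings.csv`` — ``zoo_id,species_id,count``
* ``checklist.csv`` — ``class_name,order_name,n_total,n_threatened``

All files are UTF-8, comma-separated, with a mandatory header row.
"""

from __future__ import annotations

import csv
import logging
import math
import os
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("zoonet")

#: Mean Earth radius used for all great-circle distances, in kilometres.
EARTH_RADIUS_KM = 6371.0


class ValidationError(ValueError):
    """Raised when one or more input rows violate the data contract.

    ``problems`` carries every individual failure so callers see the full
    report at once rather than the first offending row.
    """

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class IUCNCategory(str, Enum):
    """IUCN Red List category code.

    ``VU``, ``EN`` and ``CR`` are collectively the *threatened* categories.
    """

    DD = "DD"
    LC = "LC"
    NT = "NT"
    VU = "VU"
    EN = "EN"
    CR = "CR"
    EW = "EW"

    @property
    def is_threatened(self) -> bool:
        return self in (IUCNCategory.VU, IUCNCategory.EN, IUCNCategory.CR)

    @classmethod
    def parse(cls, raw: str) -> "IUCNCategory":
        """Parse a code, normalizing case; unknown codes are an error."""
        code = str(raw).strip().upper()
        try:
            return cls(code)
        except ValueError:
            raise ValidationError([f"unknown IUCN category {raw!r}"]) from None


#: Category codes counted as threatened.
THREATENED_CODES = frozenset({"VU", "EN", "CR"})


@dataclass(frozen=True)
class Zoo:
    zoo_id: str
    latitude: float
    longitude: float


@dataclass(frozen=True)
class SpeciesTaxon:
    species_id: str
    class_name: str
    order_name: str
    category: IUCNCategory

    @property
    def is_threatened(self) -> bool:
        return self.category.is_threatened


@dataclass(frozen=True)
class Holding:
    zoo_id: str
    species_id: str
    count: int


@dataclass(frozen=True)
class ChecklistOrder:
    class_name: str
    order_name: str
    n_total: int
    n_threatened: int


def haversine_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Great-circle distance in km between two (latitude, longitude) pairs.

    Uses the haversine formula on a sphere of radius ``EARTH_RADIUS_KM``.
    Symmetric, non-negative, and zero iff the points coincide.
    """
    lat1, lon1, lat2, lon2 = map(math.radians, (a[0], a[1], b[0], b[1]))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = math.sin(dlat / 2.0) ** 2 + math.cos(lat1) * math.cos(lat2) * math.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


def _open_table(path: str | os.PathLike, required: Sequence[str]) -> tuple[list[dict], list[str]]:
    """Read a CSV into dict rows, checking the header; returns (rows, problems)."""
    if not os.path.exists(path):
        raise ValidationError([f"file not found: {path}"])
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required if c not in header]
        if missing:
            raise ValidationError(
                [f"{path}: missing required column(s) {', '.join(missing)}"]
            )
        return list(reader), []


def read_zoo_table(path: str | os.PathLike) -> list[Zoo]:
    """Read ``zoos.csv``; row order preserved, duplicate ids rejected."""
    rows, problems = _open_table(path, ["zoo_id", "latitude", "longitude"])
    zoos: list[Zoo] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):  # header is line 1
        zid = (row["zoo_id"] or "").strip()
        if not zid:
            problems.append(f"row {i}: empty zoo_id")
            continue
        if zid in seen:
            problems.append(f"row {i}: duplicate zoo_id {zid!r}")
            continue
        try:
            lat = float(row["latitude"])
            lon = float(row["longitude"])
        except (TypeError, ValueError):
            problems.append(f"row {i}: unparsable coordinate for zoo {zid!r}")
            continue
        if not (math.isfinite(lat) and -90.0 <= lat <= 90.0):
            problems.append(f"row {i}: latitude {lat} out of range [-90, 90]")
            continue
        if not (math.isfinite(lon) and -180.0 <= lon < 180.0):
            problems.append(f"row {i}: longitude {lon} out of range [-180, 180)")
            continue
        seen.add(zid)
        zoos.append(Zoo(zid, lat, lon))
    if problems:
        raise ValidationError(problems)
    return zoos


def read_species_table(path: str | os.PathLike) -> list[SpeciesTaxon]:
    """Read ``species.csv``; IUCN codes are normalized to upper case."""
    rows, problems = _open_table(path, ["species_id", "class_name", "order_name", "category"])
    species: list[SpeciesTaxon] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        sid = (row["species_id"] or "").strip()
        if not sid:
            problems.append(f"row {i}: empty species_id")
            continue
        if sid in seen:
            problems.append(f"row {i}: duplicate species_id {sid!r}")
            continue
        try:
            cat = IUCNCategory.parse(row["category"])
        except ValidationError as exc:
            problems.append(f"row {i}: {exc.problems[0]}")
            continue
        seen.add(sid)
        species.append(
            SpeciesTaxon(sid, row["class_name"].strip(), row["order_name"].strip(), cat)
        )
    if problems:
        raise ValidationError(problems)
    return species


def read_holdings_table(path: str | os.PathLike) -> list[Holding]:
    """Read ``holdings.csv``. Referential checks happen in ``validate_dataset``."""
    rows, problems = _open_table(path, ["zoo_id", "species_id", "count"])
    holdings: list[Holding] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=2):
        key = (row["zoo_id"].strip(), row["species_id"].strip())
        if key in seen:
            problems.append(f"row {i}: duplicate (zoo_id, species_id) {key}")
            continue
        try:
            count = int(row["count"])
        except (TypeError, ValueError):
            problems.append(f"row {i}: unparsable count {row['count']!r}")
            continue
        if count < 0:
            problems.append(f"row {i}: negative count {count}")
            continue
        seen.add(key)
        holdings.append(Holding(key[0], key[1], count))
    if problems:
        raise ValidationError(problems)
    return holdings


def read_checklist_table(path: str | os.PathLike) -> list[ChecklistOrder]:
    """Read ``checklist.csv`` of per-order world totals."""
    rows, problems = _open_table(path, ["class_name", "order_name", "n_total", "n_threatened"])
    checklist: list[ChecklistOrder] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(rows, start=2):
        key = (row["class_name"].strip(), row["order_name"].strip())
        if key in seen:
            problems.append(f"row {i}: duplicate (class, order) {key}")
            continue
        try:
            n_total = int(row["n_total"])
            n_threatened = int(row["n_threatened"])
        except (TypeError, ValueError):
            problems.append(f"row {i}: unparsable count")
            continue
        if not (0 <= n_threatened <= n_total):
            problems.append(
                f"row {i}: need 0 <= n_threatened <= n_total, got "
                f"({n_threatened}, {n_total}) for order {key[1]!r}"
            )
            continue
        seen.add(key)
        checklist.append(ChecklistOrder(key[0], key[1], n_total, n_threatened))
    if problems:
        raise ValidationError(problems)
    return checklist


def write_zoo_table(zoos: Iterable[Zoo], path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["zoo_id", "latitude", "longitude"])
        for z in zoos:
            w.writerow([z.zoo_id, repr(z.latitude), repr(z.longitude)])


def write_species_table(species: Iterable[SpeciesTaxon], path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["species_id", "class_name", "order_name", "category"])
        for s in species:
            w.writerow([s.species_id, s.class_name, s.order_name, s.category.value])


def write_holdings_table(holdings: Iterable[Holding], path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["zoo_id", "species_id", "count"])
        for h in holdings:
            w.writerow([h.zoo_id, h.species_id, h.count])


def write_checklist_table(checklist: Iterable[ChecklistOrder], path: str | os.PathLike) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["class_name", "order_name", "n_total", "n_threatened"])
        for c in checklist:
            w.writerow([c.class_name, c.order_name, c.n_total, c.n_threatened])


@dataclass
class ValidatedDataset:
    """A cross-checked zoo-network dataset.

    Construct via :func:`validate_dataset`; the constructor itself performs
    no checks.  Derived indexes are built lazily and cached.
    """

    zoos: list[Zoo]
    species: list[SpeciesTaxon]
    holdings: list[Holding]
    checklist: list[ChecklistOrder]

    _species_by_id: dict[str, SpeciesTaxon] = field(default_factory=dict, repr=False)
    _zoo_index: dict[str, int] = field(default_factory=dict, repr=False)
    _totals: dict[str, int] = field(default_factory=dict, repr=False)
    _held: dict[str, dict[str, int]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._species_by_id = {s.species_id: s for s in self.species}
        self._zoo_index = {z.zoo_id: i for i, z in enumerate(self.zoos)}
        held: dict[str, dict[str, int]] = defaultdict(dict)
        totals: Counter = Counter()
        for h in self.holdings:
            held[h.species_id][h.zoo_id] = h.count
            totals[h.species_id] += h.count
        self._held = dict(held)
        self._totals = dict(totals)

    # -- lookups -----------------------------------------------------------
    def species_by_id(self, species_id: str) -> SpeciesTaxon:
        return self._species_by_id[species_id]

    def zoo_index(self) -> Mapping[str, int]:
        """Zoo id -> position in ``self.zoos`` (stable row order)."""
        return self._zoo_index

    def global_total(self, species_id: str) -> int:
        """Total individuals of a species summed over every zoo."""
        return self._totals.get(species_id, 0)

    def holdings_of(self, species_id: str) -> Mapping[str, int]:
        """Per-zoo counts for one species (zoos without it are absent)."""
        return self._held.get(species_id, {})

    def held_species_ids(self) -> set[str]:
        """Species present with count > 0 in at least one zoo."""
        return set(self._held)

    def class_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.checklist:
            seen.setdefault(c.class_name)
        return list(seen)

    def coordinates(self) -> np.ndarray:
        """(n_zoos, 2) array of latitude, longitude in zoo row order."""
        return np.array([[z.latitude, z.longitude] for z in self.zoos], dtype=float)


def validate_dataset(
    zoos: Sequence[Zoo],
    species: Sequence[SpeciesTaxon],
    holdings: Sequence[Holding],
    checklist: Sequence[ChecklistOrder],
) -> ValidatedDataset:
    """Cross-check the four collections and assemble a :class:`ValidatedDataset`.

    All invariant failures are aggregated into a single
    :class:`ValidationError`.  Holdings with ``count == 0`` are dropped with
    a logged warning (only living individuals count).
    """
    problems: list[str] = []

    zoo_ids = {z.zoo_id for z in zoos}
    if len(zoo_ids) != len(zoos):
        problems.append("duplicate zoo ids")
    species_by_id = {s.species_id: s for s in species}
    if len(species_by_id) != len(species):
        problems.append("duplicate species ids")
    checklist_orders = {(c.class_name, c.order_name): c for c in checklist}
    if len(checklist_orders) != len(checklist):
        problems.append("duplicate (class, order) rows in checklist")

    for s in species:
        if (s.class_name, s.order_name) not in checklist_orders:
            problems.append(
                f"species {s.species_id!r}: order {s.order_name!r} "
                f"(class {s.class_name!r}) absent from checklist"
            )

    kept: list[Holding] = []
    n_zero = 0
    for h in holdings:
        if h.zoo_id not in zoo_ids:
            problems.append(f"holding references unknown zoo {h.zoo_id!r}")
            continue
        if h.species_id not in species_by_id:
            problems.append(f"holding references unknown species {h.species_id!r}")
            continue
        if h.count == 0:
            n_zero += 1
            continue
        kept.append(h)
    if n_zero:
        logger.warning("dropped %d zero-count holding rows", n_zero)

    # Per-order zoo-held counts must fit inside the world checklist.
    held_ids = {h.species_id for h in kept}
    z_per_order: Counter = Counter()
    w_per_order: Counter = Counter()
    for sid in held_ids:
        s = species_by_id.get(sid)
        if s is None:
            continue
        key = (s.class_name, s.order_name)
        z_per_order[key] += 1
        if s.is_threatened:
            w_per_order[key] += 1
    for key, z_i in z_per_order.items():
        chk = checklist_orders.get(key)
        if chk is None:
            continue  # already reported above
        if z_i > chk.n_total:
            problems.append(
                f"order {key[1]!r}: {z_i} zoo-held species exceeds checklist n_total {chk.n_total}"
            )
        if w_per_order[key] > chk.n_threatened:
            problems.append(
                f"order {key[1]!r}: {w_per_order[key]} zoo-held threatened species "
                f"exceeds checklist n_threatened {chk.n_threatened}"
            )

    if problems:
        raise ValidationError(problems)

    ds = ValidatedDataset(list(zoos), list(species), list(kept), list(checklist))
    for cls in ds.class_names():
        held = [sid for sid in held_ids if species_by_id[sid].class_name == cls]
        thr = sum(1 for sid in held if species_by_id[sid].is_threatened)
        logger.info("class %s: %d species held, %d threatened", cls, len(held), thr)
    return ds


def read_dataset(directory: str | os.PathLike) -> ValidatedDataset:
    """Load and validate the four CSV tables from ``directory``."""
    d = os.fspath(directory)
    return validate_dataset(
        read_zoo_table(os.path.join(d, "zoos.csv")),
        read_species_table(os.path.join(d, "species.csv")),
        read_holdings_table(os.path.join(d, "holdings.csv")),
        read_checklist_table(os.path.join(d, "checklist.csv")),
    )


def write_dataset(dataset: ValidatedDataset, directory: str | os.PathLike) -> None:
    """Write the four CSV tables into ``directory`` (created if needed)."""
    d = os.fspath(directory)
    os.makedirs(d, exist_ok=True)
    write_zoo_table(dataset.zoos, os.path.join(d, "zoos.csv"))
    write_species_table(dataset.species, os.path.join(d, "species.csv"))
    write_holdings_table(dataset.holdings, os.path.join(d, "holdings.csv"))
    write_checklist_table(dataset.checklist, os.path.join(d, "checklist.csv"))
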