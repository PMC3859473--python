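"""Resampling test of threatened-species representation per taxonomic order.

For an order with ``n_total`` species worldwide of which ``n_threatened``
are threatened, and ``n_in_zoos`` species held in the zoo network, the null
model draws ``n_in_zoos`` species uniformly without replacement from the
world list and counts how many are threatened.  The observed zoo-held
threatened count is then located in the tails of that null distribution.

Two engines estimate the null distribution: a Monte Carlo resampler (an
empirical PMF built from repeated draws) and an exact engine — sampling
without replacement makes the null law hypergeometric, so the exact PMF is
available in closed form and doubles as an oracle for the resampler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import ValidatedDataset

Classification = Literal["under_represented", "over_represented", "indistinguishable"]

#: Default Monte Carlo iteration count.
DEFAULT_ITERATIONS = 10_000


@dataclass(frozen=True)
class OrderCounts:
    """World and zoo-held species counts for one taxonomic order."""

    order_name: str
    n_total: int
    n_threatened: int
    n_in_zoos: int
    n_threatened_in_zoos: int

    def __post_init__(self) -> None:
        n, m, z, w = self.n_total, self.n_threatened, self.n_in_zoos, self.n_threatened_in_zoos
        if not (0 <= m <= n):
            raise ValueError(f"{self.order_name}: need 0 <= n_threatened <= n_total")
        if not (0 <= z <= n):
            raise ValueError(f"{self.order_name}: need 0 <= n_in_zoos <= n_total")
        lo, hi = max(0, z - (n - m)), min(z, m)
        if not (lo <= w <= hi):
            raise ValueError(
                f"{self.order_name}: observed threatened count {w} outside "
                f"feasible range [{lo}, {hi}]"
            )

    @property
    def feasible_min(self) -> int:
        return max(0, self.n_in_zoos - (self.n_total - self.n_threatened))

    @property
    def feasible_max(self) -> int:
        return min(self.n_in_zoos, self.n_threatened)


@dataclass(frozen=True)
class EmpiricalPMF:
    """Distribution of the threatened count under random collection.

    ``iterations`` and ``seed`` are ``None`` for the exact engine; for the
    Monte Carlo engine every probability is a multiple of ``1/iterations``.
    """

    order_name: str
    support: np.ndarray
    probabilities: np.ndarray
    iterations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.support.shape != self.probabilities.shape:
            raise ValueError("support and probabilities must align")
        total = float(self.probabilities.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"probabilities sum to {total}, not 1")

    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    def point_probability(self, j: int) -> float:
        idx = np.nonzero(self.support == j)[0]
        return float(self.probabilities[idx[0]]) if idx.size else 0.0

    def lower_tail(self, j: int) -> float:
        return float(self.probabilities[self.support <= j].sum())

    def upper_tail(self, j: int) -> float:
        return float(self.probabilities[self.support >= j].sum())


@dataclass(frozen=True)
class RepresentationVerdict:
    order_name: str
    observed: int
    point_probability: float
    lower_tail: float
    upper_tail: float
    classification: Classification


def order_counts(dataset: ValidatedDataset, order_name: str) -> OrderCounts:
    """Compute (n, m, z, w) for one order of a validated dataset.

    ``z`` counts distinct species of the order held with count > 0 in at
    least one zoo; ``w`` is the threatened subset of those.
    """
    entry = next((c for c in dataset.checklist if c.order_name == order_name), None)
    if entry is None:
        raise KeyError(f"order {order_name!r} not in checklist")
    held = dataset.held_species_ids()
    in_zoos = [
        s for s in dataset.species if s.order_name == order_name and s.species_id in held
    ]
    z = len(in_zoos)
    w = sum(1 for s in in_zoos if s.is_threatened)
    return OrderCounts(order_name, entry.n_total, entry.n_threatened, z, w)


def simulate_representation_pmf(
    counts: OrderCounts, iterations: int = DEFAULT_ITERATIONS, seed: int | None = None
) -> EmpiricalPMF:
    """Monte Carlo empirical PMF of the threatened count under random draws.

    Each iteration samples ``n_in_zoos`` species without replacement from a
    pool of ``n_total`` containing ``n_threatened`` threatened ones, then
    tallies the threatened count.  Sampling is implemented as taking the
    ``z`` smallest of ``n`` i.i.d. uniform keys, which is a uniform random
    subset; tallies are normalized by the iteration count.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    n, m, z = counts.n_total, counts.n_threatened, counts.n_in_zoos
    support = np.arange(0, min(z, m) + 1)
    tallies = np.zeros(support.size, dtype=np.int64)
    if z == 0 or m == 0:
        tallies[0] = iterations
    else:
        rng = np.random.default_rng(seed)
        # chunk so the key matrix stays ~16 MB regardless of n
        chunk = max(1, int(2_000_000 // n))
        done = 0
        while done < iterations:
            c = min(chunk, iterations - done)
            keys = rng.random((c, n))
            picked = np.argpartition(keys, z - 1, axis=1)[:, :z]
            hits = (picked < m).sum(axis=1)
            tallies += np.bincount(hits, minlength=support.size)
            done += c
    return EmpiricalPMF(
        counts.order_name, support, tallies / float(iterations), iterations, seed
    )


def hypergeometric_pmf(counts: OrderCounts) -> EmpiricalPMF:
    """Exact null PMF: hypergeometric law on the same support.

    P(J = j) = C(m, j) C(n - m, z - j) / C(n, z) on the feasible range and
    zero elsewhere.
    """
    n, m, z = counts.n_total, counts.n_threatened, counts.n_in_zoos
    support = np.arange(0, min(z, m) + 1)
    probs = stats.hypergeom.pmf(support, n, m, z)
    probs = np.clip(probs, 0.0, None)
    probs /= probs.sum()
    return EmpiricalPMF(counts.order_name, support, probs)


def classify_order(
    pmf: EmpiricalPMF, observed: int, alpha: float = 0.05
) -> RepresentationVerdict:
    """Locate the observed threatened count in the null distribution.

    Classification uses cumulative tails: lower tail <= alpha flags
    under-representation, upper tail <= alpha flags over-representation
    (ties at the cutoff inclusive).  The point probability at the observed
    value is reported alongside.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if observed < int(pmf.support[0]) or observed > int(pmf.support[-1]):
        raise ValueError(
            f"{pmf.order_name}: observed {observed} outside support "
            f"[{pmf.support[0]}, {pmf.support[-1]}] — inconsistent data"
        )
    lower = pmf.lower_tail(observed)
    upper = pmf.upper_tail(observed)
    point = pmf.point_probability(observed)
    if lower <= alpha:
        cls: Classification = "under_represented"
    elif upper <= alpha:
        cls = "over_represented"
    else:
        cls = "indistinguishable"
    return RepresentationVerdict(pmf.order_name, observed, point, lower, upper, cls)


def representation_report(
    dataset: ValidatedDataset,
    iterations: int = DEFAULT_ITERATIONS,
    alpha: float = 0.05,
    seed: int | None = None,
    engine: Literal["monte_carlo", "exact"] = "exact",
) -> pd.DataFrame:
    """Run the representation test for every checklist order.

    Returns one row per order with the observed and expected threatened
    counts, tail probabilities and classification.  Orders not held in any
    zoo (z = 0) are reported with classification ``not_held``.
    """
    if engine not in ("monte_carlo", "exact"):
        raise ValueError(f"unknown engine {engine!r}")
    # one child seed per order keeps the report reproducible regardless of
    # checklist ordering changes upstream
    seeds: Sequence[np.random.SeedSequence]
    seeds = np.random.SeedSequence(seed).spawn(len(dataset.checklist))
    rows = []
    for entry, child in zip(dataset.checklist, seeds):
        counts = order_counts(dataset, entry.order_name)
        row = {
            "order": entry.order_name,
            "class": entry.class_name,
            "n_total": entry.n_total,
            "n_threatened": entry.n_threatened,
            "n_in_zoos": counts.n_in_zoos,
            "w_observed": counts.n_threatened_in_zoos,
        }
        if counts.n_in_zoos == 0:
            row.update(
                expected_w=0.0,
                point_prob=np.nan,
                lower_tail=np.nan,
                upper_tail=np.nan,
                classification="not_held",
            )
        else:
            if engine == "exact":
                pmf = hypergeometric_pmf(counts)
            else:
                pmf = simulate_representation_pmf(
                    counts, iterations, int(child.generate_state(1)[0])
                )
            verdict = classify_order(pmf, counts.n_threatened_in_zoos, alpha)
            row.update(
                expected_w=pmf.mean(),
                point_prob=verdict.point_probability,
                lower_tail=verdict.lower_tail,
                upper_tail=verdict.upper_tail,
                classification=verdict.classification,
            )
        rows.append(row)
    return pd.DataFrame(rows)
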