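"""Summary matrices (species by IUCN category, population-size bands) and
percentage arithmetic with explicit rounding."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import ValidatedDataset

CATEGORY_ORDER = ["DD", "LC", "NT", "VU", "EN", "CR", "EW"]

#: Default population-size band edges; bands are half-open (lower, upper].
DEFAULT_BAND_EDGES = (0, 50, 100, 250, 500, 1000, 2000)


def percent_threatened(numerator: int, denominator: int, decimals: int = 1) -> float:
    """100 * numerator / denominator rounded half-away-from-zero."""
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    ratio = Decimal(100 * numerator) / Decimal(denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(ratio.quantize(quantum, rounding=ROUND_HALF_UP))


def summarize_by_category(dataset: ValidatedDataset) -> pd.DataFrame:
    """Distinct zoo-held species per taxonomic class and IUCN category.

    Rows are classes plus a ``Total`` row; the ``threatened`` column is the
    VU + EN + CR sum and ``pct_threatened`` its share of the class's held
    species (one decimal, half-away-from-zero; NaN when the class holds
    nothing).
    """
    held = dataset.held_species_ids()
    classes = dataset.class_names()
    table = pd.DataFrame(0, index=classes, columns=CATEGORY_ORDER, dtype=int)
    for sid in held:
        s = dataset.species_by_id(sid)
        table.loc[s.class_name, s.category.value] += 1
    table.loc["Total"] = table.sum(axis=0)
    table["total_species"] = table[CATEGORY_ORDER].sum(axis=1)
    table["threatened"] = table[["VU", "EN", "CR"]].sum(axis=1)
    table["pct_threatened"] = [
        percent_threatened(int(t), int(n), 1) if n > 0 else np.nan
        for t, n in zip(table["threatened"], table["total_species"])
    ]
    table.index.name = "class"
    return table


def _band_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"{int(lo)}-{int(hi)}" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f">{int(edges[-1])}")
    return labels


def summarize_population_thresholds(
    dataset: ValidatedDataset, band_edges: Sequence[float] = DEFAULT_BAND_EDGES
) -> pd.DataFrame:
    """Held species per (class, population band) and IUCN category.

    Each species falls in exactly one half-open band (lower, upper] of its
    network-wide individual total; totals above the last edge land in the
    open-ended top band.
    """
    edges = list(band_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("band edges must be strictly increasing")
    labels = _band_labels(edges)
    classes = dataset.class_names()
    index = pd.MultiIndex.from_product([classes, labels], names=["class", "band"])
    table = pd.DataFrame(0, index=index, columns=CATEGORY_ORDER, dtype=int)
    upper = np.array(edges[1:] + [np.inf])
    for sid in dataset.held_species_ids():
        s = dataset.species_by_id(sid)
        total = dataset.global_total(sid)
        band = labels[int(np.searchsorted(upper, total, side="left"))]
        table.loc[(s.class_name, band), s.category.value] += 1
    return table


def plot_expected_vs_observed(report: pd.DataFrame, path: str) -> None:
    """Scatter of expected vs observed threatened counts per order."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tested = report[report["classification"] != "not_held"]
    fig, ax = plt.subplots(figsize=(6, 6))
    palette = {
        "indistinguishable": "0.6",
        "under_represented": "tab:blue",
        "over_represented": "tab:red",
    }
    for cls, group in tested.groupby("classification"):
        ax.scatter(
            group["expected_w"],
            group["w_observed"],
            label=cls,
            color=palette.get(cls, "k"),
            alpha=0.8,
        )
    lim = max(1.0, tested[["expected_w", "w_observed"]].to_numpy().max() * 1.05)
    ax.plot([0, lim], [0, lim], ls="--", c="0.8", lw=1)
    ax.set_xlabel("expected threatened species (null)")
    ax.set_ylabel("observed threatened species")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ratio_curves(curves: dict, path: str) -> None:
    """Probability-to-distance ratio curves per (class, threshold)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .clusters import class_ratio_curve

    fig, ax = plt.subplots(figsize=(7, 5))
    for (class_name, m), cs in curves.items():
        rc = class_ratio_curve(class_name, m, cs)
        ax.plot(rc.radii, rc.ratio * 1_000, label=f"{class_name}, m={m}")
    ax.set_xlabel("cluster radius (km)")
    ax.set_ylabel("mean probability / distance (x1000)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
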