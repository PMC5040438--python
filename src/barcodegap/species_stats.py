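"""Per-species release-criteria statistics.

For every species in a reference library this module derives, from the full
pairwise distance table:

* the spread of intraspecific distances (min / max / mean / median; undefined
  for singletons),
* the closest heterospecific species — the neighbor minimizing the smallest
  cross-species pairwise distance, with min / max / median over *all* cross
  pairs between the two species, and
* the genetically most distant congener — the same-genus allospecific species
  maximizing the largest cross pairwise distance.

Ranking and tie detection use the full-precision distances; ties (exact
equality of the ranking key) yield one result tuple per tied neighbor.
Rounding happens only when a table is serialized.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import NamedTuple, Optional

import numpy as np
import pandas as pd

from .distance import DistanceTable, pairwise_matrix
from .seqio import BarcodeDataset

logger = logging.getLogger(__name__)


class IntraStats(NamedTuple):
    min: float
    max: float
    mean: float
    median: float


class NeighborStats(NamedTuple):
    neighbor: str
    min: float
    max: float
    median: float


class CongenerStats(NamedTuple):
    congener: str
    max: float


def _defined(values: np.ndarray) -> np.ndarray:
    return values[~np.isnan(values)]


def intraspecific_stats(table: DistanceTable, species: str) -> Optional[IntraStats]:
    """Min/max/mean/median over all conspecific pairs; None for singletons.

    Undefined (NaN) distances under the table's metric are excluded; if every
    conspecific pair is undefined the result is None as well.
    """
    members = np.flatnonzero(np.asarray(table.species, dtype=object) == species)
    if members.size == 0:
        raise KeyError(f"species {species!r} not in dataset")
    if members.size == 1:
        return None
    in_sp = np.zeros(table.n, dtype=bool)
    in_sp[members] = True
    vals = _defined(table.distances[in_sp[table.i] & in_sp[table.j]])
    if vals.size == 0:
        logger.warning("all intraspecific distances undefined for %s", species)
        return None
    return IntraStats(float(vals.min()), float(vals.max()),
                      float(vals.mean()), float(np.median(vals)))


def cross_species_stats(table: DistanceTable) -> pd.DataFrame:
    """Aggregate defined distances over every unordered species pair.

    Returns a DataFrame with columns ``species_a``, ``species_b`` (a < b by
    record-position code), ``min``, ``max``, ``median``, ``n_pairs``,
    ``n_defined``; one row per species pair with at least one cross pair.
    Intraspecific "pairs" are included (species_a == species_b) so callers can
    reuse the same aggregation.
    """
    sc = table.species_codes
    a = np.minimum(sc[table.i], sc[table.j])
    b = np.maximum(sc[table.i], sc[table.j])
    names = list(dict.fromkeys(table.species))
    df = pd.DataFrame({"a": a, "b": b, "d": table.distances})
    grouped = df.groupby(["a", "b"], sort=True)["d"]
    agg = grouped.agg(min="min", max="max", median="median", n_defined="count",
                      n_pairs="size").reset_index()
    agg["species_a"] = [names[c] for c in agg["a"]]
    agg["species_b"] = [names[c] for c in agg["b"]]
    return agg[["species_a", "species_b", "min", "max", "median", "n_pairs", "n_defined"]]


def _pairs_for(cross: pd.DataFrame, species: str) -> pd.DataFrame:
    """Rows of `cross` involving `species` with a `neighbor` column added."""
    hit = cross[(cross["species_a"] == species) ^ (cross["species_b"] == species)].copy()
    hit["neighbor"] = np.where(hit["species_a"] == species,
                               hit["species_b"], hit["species_a"])
    return hit


def closest_species(
    table: DistanceTable, species: str, cross: Optional[pd.DataFrame] = None
) -> list[NeighborStats]:
    """Closest heterospecific species by smallest cross-species distance.

    No genus information is used: the neighbor may belong to any genus.
    Exact full-precision ties on the minimum produce one tuple per tied
    neighbor, sorted by neighbor name.
    """
    if species not in table.species:
        raise KeyError(f"species {species!r} not in dataset")
    if len(set(table.species)) < 2:
        raise ValueError("closest-species scan requires at least 2 species")
    if cross is None:
        cross = cross_species_stats(table)
    hit = _pairs_for(cross, species)
    hit = hit[hit["n_defined"] > 0]
    if hit.empty:
        logger.warning("no defined cross-species distance for %s", species)
        return []
    best = hit["min"].min()
    ties = hit[hit["min"] == best].sort_values("neighbor")
    return [
        NeighborStats(r.neighbor, float(r.min), float(r.max), float(r.median))
        for r in ties.itertuples()
    ]


def most_distant_congener(
    table: DistanceTable, species: str, cross: Optional[pd.DataFrame] = None
) -> list[CongenerStats]:
    """Same-genus allospecific species maximizing the largest cross distance.

    Returns an empty list when the genus has a single sampled species. Exact
    ties produce multiple tuples, sorted by congener name.
    """
    if species not in table.species:
        raise KeyError(f"species {species!r} not in dataset")
    genus_of = dict(zip(table.species, table.genus))
    genus = genus_of[species]
    if cross is None:
        cross = cross_species_stats(table)
    hit = _pairs_for(cross, species)
    hit = hit[(hit["n_defined"] > 0)
              & (hit["neighbor"].map(genus_of) == genus)]
    if hit.empty:
        return []
    best = hit["max"].max()
    ties = hit[hit["max"] == best].sort_values("neighbor")
    return [CongenerStats(r.neighbor, float(r.max)) for r in ties.itertuples()]


#: Output column order of the per-species statistics table (percent scale).
STATS_COLUMNS = (
    "species", "n_specimens",
    "intra_min", "intra_max", "intra_mean", "intra_median",
    "closest_species", "closest_min", "closest_max", "closest_median",
    "farthest_congener", "farthest_congener_max",
)


def distats_table(
    dataset: BarcodeDataset,
    metric: str = "p",
    threads: int = 1,
    table: Optional[DistanceTable] = None,
) -> pd.DataFrame:
    """One row per species (plus tie rows) with all release-criteria statistics.

    Distances are reported on the percent scale at full precision; round at
    serialization, never before ranking. Rows are sorted alphabetically by
    species. When a species has both closest-neighbor ties and
    farthest-congener ties of different multiplicity, rows are emitted up to
    the larger multiplicity, repeating the last value of the shorter list.
    """
    if table is None:
        if len(dataset.species_index) < 2:
            raise ValueError("per-species statistics require at least 2 species")
        table = pairwise_matrix(dataset, metric=metric, threads=threads)
    elif table.metric != metric:
        table = table.with_metric(metric)
    if len(set(table.species)) < 2:
        raise ValueError("per-species statistics require at least 2 species")

    cross = cross_species_stats(table)
    # Drop intraspecific rows from the cross-pair view once; reused per species.
    cross_hetero = cross[cross["species_a"] != cross["species_b"]]
    counts: dict[str, int] = {}
    for s in table.species:
        counts[s] = counts.get(s, 0) + 1

    rows: list[dict] = []
    pct = lambda x: None if x is None else 100.0 * x
    for species in sorted(counts):
        intra = intraspecific_stats(table, species)
        neighbors = closest_species(table, species, cross=cross_hetero)
        congeners = most_distant_congener(table, species, cross=cross_hetero)
        n_rows = max(len(neighbors), len(congeners), 1)
        for k in range(n_rows):
            nb = neighbors[min(k, len(neighbors) - 1)] if neighbors else None
            cg = congeners[min(k, len(congeners) - 1)] if congeners else None
            rows.append(
                {
                    "species": species,
                    "n_specimens": counts[species],
                    "intra_min": pct(intra.min) if intra else None,
                    "intra_max": pct(intra.max) if intra else None,
                    "intra_mean": pct(intra.mean) if intra else None,
                    "intra_median": pct(intra.median) if intra else None,
                    "closest_species": nb.neighbor if nb else None,
                    "closest_min": pct(nb.min) if nb else None,
                    "closest_max": pct(nb.max) if nb else None,
                    "closest_median": pct(nb.median) if nb else None,
                    "farthest_congener": cg.congener if cg else None,
                    "farthest_congener_max": pct(cg.max) if cg else None,
                }
            )
    return pd.DataFrame(rows, columns=list(STATS_COLUMNS))
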