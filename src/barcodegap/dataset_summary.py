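"""Dataset-level barcoding-gap summaries.

Aggregates over the full pairwise distance table: intraspecific vs
interspecific distance structure per taxonomic group (with the 95th
intraspecific and 5th interspecific percentiles that bracket the putative
barcoding gap), candidate taxonomic *splits* (conspicuously large conspecific
distances) and *lumps* (conspicuously small congeneric allospecific
distances), haplotype collapse and shared-haplotype detection, base
composition, and the three distance categories used for box plots
(allogeneric / congeneric-allospecific / intraspecific).

"Interspecific" in the gap summary includes allogeneric pairs, i.e. all
heterospecific comparisons, not congeners only. Percentiles use linear
interpolation between order statistics. All distance outputs are on the
percent scale.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .distance import (
    ALLOGENERIC,
    CATEGORY_NAMES,
    CONGENERIC,
    INTRASPECIFIC,
    DistanceTable,
)
from .seqio import BarcodeDataset
from .species_stats import closest_species, cross_species_stats, most_distant_congener

logger = logging.getLogger(__name__)

GROUP_LEVELS = ("order", "family", "genus", "none")


def _pct(values: np.ndarray) -> np.ndarray:
    return values[~np.isnan(values)] * 100.0


def _group_positions(table: DistanceTable, group_by: str) -> dict[str, list[int]]:
    if group_by in (None, "none", "all"):
        return {"all": list(range(table.n))}
    if group_by not in ("order", "family", "genus"):
        raise ValueError(f"group_by must be one of {GROUP_LEVELS}")
    labels = getattr(table, group_by)
    groups: dict[str, list[int]] = {}
    for pos, lab in enumerate(labels):
        groups.setdefault(lab if lab else "(unassigned)", []).append(pos)
    return groups


def gap_summary(table: DistanceTable, group_by: str = "none") -> pd.DataFrame:
    """Distance-structure estimators per taxonomic group (percent scale).

    For each group: median/mean/min/max and 95th percentile of intraspecific
    distances; median/mean/min/max and 5th percentile of interspecific (all
    heterospecific) distances; the range and median of per-species smallest
    closest-pair distances, the overall maximum among all distances of closest
    pairs (the "parenthetical" maximum), pooled-closest-pair median; and the
    range and median of per-species farthest-congener maxima. Groups lacking a
    category get NA fields with a logged warning.
    """
    rows = []
    for label, positions in sorted(_group_positions(table, group_by).items()):
        sub = table.subset(positions)
        intra = _pct(sub.distances[sub.intraspecific_mask])
        inter = _pct(sub.distances[sub.interspecific_mask])
        row: dict = {
            "group": label,
            "metric": table.metric,
            "n_records": sub.n,
            "n_species": len(set(sub.species)),
            "intra_n": intra.size,
            "inter_n": inter.size,
        }
        if intra.size:
            row.update(
                intra_median=np.median(intra), intra_mean=intra.mean(),
                intra_min=intra.min(), intra_max=intra.max(),
                intra_p95=np.percentile(intra, 95),
            )
        else:
            logger.warning("group %s has no intraspecific pair", label)
        if inter.size:
            row.update(
                inter_median=np.median(inter), inter_mean=inter.mean(),
                inter_min=inter.min(), inter_max=inter.max(),
                inter_p5=np.percentile(inter, 5),
            )
        else:
            logger.warning("group %s has no interspecific pair", label)

        species_here = sorted(set(sub.species))
        if len(species_here) >= 2 and inter.size:
            cross = cross_species_stats(sub)
            cross = cross[cross["species_a"] != cross["species_b"]]
            closest_mins: list[float] = []
            closest_pool: list[np.ndarray] = []
            sp_arr = np.asarray(sub.species, dtype=object)
            for sp in species_here:
                ties = closest_species(sub, sp, cross=cross)
                if not ties:
                    continue
                closest_mins.append(ties[0].min)
                in_focal = sp_arr == sp
                for t in ties:
                    in_nb = sp_arr == t.neighbor
                    m = (in_focal[sub.i] & in_nb[sub.j]) | (in_nb[sub.i] & in_focal[sub.j])
                    closest_pool.append(sub.distances[m])
            if closest_mins:
                mins = np.asarray(closest_mins) * 100.0
                pool = _pct(np.concatenate(closest_pool))
                row.update(
                    closest_pair_min=mins.min(), closest_pair_max=mins.max(),
                    closest_pair_overall_max=pool.max(),
                    closest_pair_median=np.median(pool),
                )
            congener_maxima = []
            for sp in species_here:
                ties = most_distant_congener(sub, sp, cross=cross)
                if ties:
                    congener_maxima.append(ties[0].max)
            if congener_maxima:
                cg = np.asarray(congener_maxima) * 100.0
                row.update(
                    farthest_congener_min=cg.min(), farthest_congener_max=cg.max(),
                    farthest_congener_median=np.median(cg),
                )
        rows.append(row)
    columns = [
        "group", "metric", "n_records", "n_species", "intra_n",
        "intra_median", "intra_mean", "intra_min", "intra_max", "intra_p95",
        "inter_n", "inter_median", "inter_mean", "inter_min", "inter_max", "inter_p5",
        "closest_pair_min", "closest_pair_max", "closest_pair_overall_max",
        "closest_pair_median",
        "farthest_congener_min", "farthest_congener_max", "farthest_congener_median",
    ]
    return pd.DataFrame(rows).reindex(columns=columns)


def _pair_frame(table: DistanceTable, mask: np.ndarray) -> pd.DataFrame:
    ids = np.asarray(table.ids, dtype=object)
    sp = np.asarray(table.species, dtype=object)
    return pd.DataFrame(
        {
            "species_i": sp[table.i[mask]],
            "species_j": sp[table.j[mask]],
            "specimen_i": ids[table.i[mask]],
            "specimen_j": ids[table.j[mask]],
            "distance_pct": table.distances[mask] * 100.0,
            "comparable_sites": table.comparable_sites[mask],
        }
    )


def splits_report(table: DistanceTable, threshold_pct: float = 3.0) -> pd.DataFrame:
    """Conspecific pairs at or above ``threshold_pct`` (candidate splits).

    Sorted by distance descending, then species, then specimen ids, so ties
    are deterministic. The threshold is inclusive.
    """
    d = table.distances * 100.0
    mask = table.intraspecific_mask & ~np.isnan(d) & (d >= threshold_pct)
    df = _pair_frame(table, mask)
    df = df.rename(columns={"species_i": "species"}).drop(columns=["species_j"])
    return df.sort_values(
        ["distance_pct", "species", "specimen_i", "specimen_j"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)[
        ["species", "specimen_i", "specimen_j", "distance_pct", "comparable_sites"]
    ]


def lumps_report(table: DistanceTable, threshold_pct: float = 5.0) -> pd.DataFrame:
    """Congeneric allospecific pairs at or below ``threshold_pct`` (lumps).

    Sorted ascending by distance, then species names, then specimen ids.
    The threshold is inclusive.
    """
    d = table.distances * 100.0
    mask = table.congeneric_mask & ~np.isnan(d) & (d <= threshold_pct)
    df = _pair_frame(table, mask)
    # Canonical unordered species naming for stable output.
    flip = df["species_i"] > df["species_j"]
    for a, b in (("species_i", "species_j"), ("specimen_i", "specimen_j")):
        df.loc[flip, [a, b]] = df.loc[flip, [b, a]].to_numpy()
    df = df.rename(columns={"species_i": "species_a", "species_j": "species_b"})
    return df.sort_values(
        ["distance_pct", "species_a", "species_b", "specimen_i", "specimen_j"],
        kind="mergesort",
    ).reset_index(drop=True)[
        ["species_a", "species_b", "specimen_i", "specimen_j",
         "distance_pct", "comparable_sites"]
    ]


@dataclasses.dataclass(frozen=True)
class HaplotypeGroup:
    """Specimens sharing a byte-identical aligned sequence."""

    sequence: str
    member_ids: tuple[str, ...]
    species: tuple[str, ...]  # unique species represented, sorted


@dataclasses.dataclass(frozen=True)
class HaplotypeSummary:
    groups: tuple[HaplotypeGroup, ...]
    distinct_count: int
    nonunique_sequence_count: int  # n - distinct_count
    ambiguity_only_group_pairs: Optional[int] = None


def haplotype_collapse(
    dataset: BarcodeDataset, check_ambiguity_overlap: bool = False
) -> HaplotypeSummary:
    """Group specimens by exact (uppercase) sequence identity.

    Two sequences differing only at ambiguity codes (e.g. N vs A) are distinct
    haplotypes under this rule; with ``check_ambiguity_overlap`` the number of
    group pairs whose differences are confined to non-ACGT symbols is counted
    for diagnostics (O(groups^2), informative only).
    """
    by_seq: dict[str, list[int]] = {}
    for pos, r in enumerate(dataset.records):
        by_seq.setdefault(r.sequence, []).append(pos)
    groups = tuple(
        HaplotypeGroup(
            sequence=seq,
            member_ids=tuple(dataset.records[p].specimen_id for p in positions),
            species=tuple(sorted({dataset.records[p].species for p in positions})),
        )
        for seq, positions in by_seq.items()
    )
    ambiguity_pairs = None
    if check_ambiguity_overlap:
        from .distance import encode_sequences

        codes = encode_sequences([g.sequence for g in groups])
        ambiguity_pairs = 0
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                both = (codes[a] < 4) & (codes[b] < 4)
                if not np.any(both & (codes[a] != codes[b])):
                    ambiguity_pairs += 1
    return HaplotypeSummary(
        groups=groups,
        distinct_count=len(groups),
        nonunique_sequence_count=len(dataset) - len(groups),
        ambiguity_only_group_pairs=ambiguity_pairs,
    )


def shared_haplotype_pairs(summary: HaplotypeSummary) -> pd.DataFrame:
    """Unordered species pairs co-occurring in a haplotype group.

    One row per species pair with at least one shared haplotype, with the
    supporting specimen ids joined by ';'.
    """
    hits: dict[tuple[str, str], list[str]] = {}
    for g in summary.groups:
        if len(g.species) < 2:
            continue
        for ai in range(len(g.species)):
            for bi in range(ai + 1, len(g.species)):
                hits.setdefault((g.species[ai], g.species[bi]), []).extend(g.member_ids)
    rows = [
        {"species_a": a, "species_b": b, "specimen_ids": ";".join(ids)}
        for (a, b), ids in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["species_a", "species_b", "specimen_ids"])


def base_composition(dataset: BarcodeDataset) -> dict[str, float]:
    """Pooled A/C/G/T percentages and AT content over all sequences.

    Gaps, N and ambiguity codes are excluded from numerator and denominator.
    A dataset with zero unambiguous bases is a hard error.
    """
    counts = {b: 0 for b in "ACGT"}
    for r in dataset:
        for b in "ACGT":
            counts[b] += r.sequence.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no unambiguous A/C/G/T base in dataset")
    out = {b: 100.0 * c / total for b, c in counts.items()}
    out["AT"] = out["A"] + out["T"]
    return out


def category_distances(table: DistanceTable) -> dict[str, np.ndarray]:
    """Defined distances (percent) split into the three pair categories."""
    d = table.distances * 100.0
    return {
        name: d[(table.categories == code) & ~np.isnan(d)]
        for code, name in zip((ALLOGENERIC, CONGENERIC, INTRASPECIFIC),
                              ("allogeneric", "congeneric", "intraspecific"))
    }


def category_summary(table: DistanceTable) -> pd.DataFrame:
    """Box-plot statistics (Tukey style) per distance category.

    Q1/median/Q3 by linear interpolation; whiskers at the most extreme values
    within 1.5 x IQR of the box; points beyond the whiskers are outliers.
    """
    rows = []
    for name, vals in category_distances(table).items():
        row = {"category": name, "n": int(vals.size)}
        if vals.size:
            q1, med, q3 = np.percentile(vals, [25, 50, 75])
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = vals[(vals >= lo_fence) & (vals <= hi_fence)]
            row.update(
                q1=q1, median=med, q3=q3,
                whisker_low=inside.min(), whisker_high=inside.max(),
                outlier_count=int(((vals < lo_fence) | (vals > hi_fence)).sum()),
            )
        rows.append(row)
    columns = ["category", "n", "q1", "median", "q3",
               "whisker_low", "whisker_high", "outlier_count"]
    return pd.DataFrame(rows).reindex(columns=columns)


def high_divergence_species(
    table: DistanceTable, threshold_pct: float = 3.0
) -> pd.DataFrame:
    """Species whose maximum intraspecific distance exceeds ``threshold_pct``.

    Returns species and max_intra_pct sorted by divergence descending — the
    census used to flag candidate cryptic diversity.
    """
    d = table.distances * 100.0
    mask = table.intraspecific_mask & ~np.isnan(d)
    sp = np.asarray(table.species, dtype=object)[table.i[mask]]
    df = pd.DataFrame({"species": sp, "d": d[mask]})
    agg = df.groupby("species")["d"].max().reset_index(name="max_intra_pct")
    agg = agg[agg["max_intra_pct"] > threshold_pct]
    return agg.sort_values(
        ["max_intra_pct", "species"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def plot_category_boxes(table: DistanceTable, path: str, title: str = "") -> None:
    """Render the category box plot (SVG/PNG by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = category_distances(table)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot([cats["allogeneric"], cats["congeneric"], cats["intraspecific"]],
               tick_labels=["allogeneric", "congeneric", "intraspecific"], whis=1.5)
    ax.set_ylabel(f"{table.metric}-distance [%]")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
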