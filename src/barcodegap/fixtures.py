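"""Deterministic synthetic alignments with planted distance ground truth.

The planted generator builds a three-level hierarchy (genus ancestor ->
species consensus -> specimen) on top of one random root sequence. Every
substitution is planted at a globally *disjoint* alignment site, drawn
without replacement, so no back-substitution or collision can occur and the
number of differing sites between any two specimens is exactly the number of
substitutions on the tree path connecting them. Each substitution's
transition/transversion identity is recorded, so the per-pair P and Q
proportions are ground truth too. Noise (ambiguity codes and gaps) can be
injected per site afterwards; the shipped ground-truth table is then
recounted column by column from the emitted sequences with a naive
reference routine that is independent of the distance engine.

This is deliberately not a sequence-evolution simulator: there is no
substitution model and no indel evolution. It exists so that every analysis
module can be tested against exact, known answers.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import pandas as pd

from .seqio import BarcodeDataset, BarcodeRecord

_BASES = "ACGT"


@dataclasses.dataclass(frozen=True)
class ToySpec:
    """Parameters of a planted toy dataset.

    Defaults emulate the distance structure of a dense temperate COI library:
    a 653-column window, conspecific specimens ~0.3% apart (1 private
    substitution each), sister species ~9% apart (29 substitutions per
    species branch) and genera ~18% apart (30 per genus branch).
    """

    n_genera: int = 3
    species_per_genus: int = 2
    specimens_per_species: int = 3
    alignment_width: int = 653
    intra_mutations: int = 1
    inter_mutations: int = 29
    genus_mutations: int = 30
    ambiguity_rate: float = 0.0
    gap_rate: float = 0.0
    n_orders: int = 1
    seed: int = 0

    @property
    def n_records(self) -> int:
        return self.n_genera * self.species_per_genus * self.specimens_per_species

    @property
    def sites_needed(self) -> int:
        n_species = self.n_genera * self.species_per_genus
        return (
            self.n_genera * self.genus_mutations
            + n_species * self.inter_mutations
            + self.n_records * self.intra_mutations
        )


def naive_pair_counts(a: str, b: str) -> tuple[int, int, int, int]:
    """Per-column reference count: (comparable, diff, transitions, transversions).

    Pure per-position bookkeeping over the pairwise-complete-deletion rule;
    kept independent of the vectorized engine so it can serve as its oracle.
    """
    comparable = diff = ts = 0
    purines = {"A", "G"}
    for x, y in zip(a.upper(), b.upper()):
        if x in _BASES and y in _BASES:
            comparable += 1
            if x != y:
                diff += 1
                if (x in purines) == (y in purines):
                    ts += 1
    return comparable, diff, ts, diff - ts


def _mutate(seq: np.ndarray, sites: np.ndarray, rng: np.random.Generator
            ) -> list[tuple[int, int, int]]:
    """Substitute at the given sites in place; return (site, old, new) events."""
    events = []
    for site in sites:
        old = int(seq[site])
        new = (old + int(rng.integers(1, 4))) % 4
        seq[site] = new
        events.append((int(site), old, new))
    return events


def _is_transition(old: int, new: int) -> bool:
    # Codes 0..3 = A,C,G,T; purines (A,G) are even, pyrimidines odd.
    return (old & 1) == (new & 1)


def make_toy_dataset(
    spec: ToySpec, with_truth: bool = True
) -> tuple[BarcodeDataset, Optional[pd.DataFrame]]:
    """Build a planted dataset and its exact ground-truth pair table.

    The truth table has one row per unordered specimen pair with columns
    ``id_i, id_j, comparable_sites, diff_sites, transitions, transversions``
    recounted from the emitted sequences, plus ``planted_diff_sites``,
    ``planted_transitions`` and ``planted_transversions`` from the tree path
    (these equal the recount whenever no noise is injected). Same seed, same
    bytes. Raises ``ValueError`` for infeasible specs (more planted sites
    than alignment columns).
    """
    if spec.sites_needed > spec.alignment_width:
        raise ValueError(
            f"infeasible spec: {spec.sites_needed} planted sites exceed "
            f"alignment width {spec.alignment_width}"
        )
    rng = np.random.default_rng(spec.seed)
    root = rng.integers(0, 4, spec.alignment_width, dtype=np.int64)
    site_pool = rng.permutation(spec.alignment_width)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = site_pool[cursor : cursor + k]
        cursor += k
        return out

    records: list[BarcodeRecord] = []
    # Branch-event bookkeeping per leaf: chain of (level-key -> events).
    leaf_chains: list[tuple[tuple, list[list[tuple[int, int, int]]]]] = []
    sequences: list[np.ndarray] = []
    for g in range(spec.n_genera):
        genus_name = f"Genus{g + 1:02d}"
        order_name = f"Order{g * spec.n_orders // spec.n_genera + 1:02d}"
        family_name = f"Family{g + 1:02d}"
        genus_seq = root.copy()
        genus_events = _mutate(genus_seq, take(spec.genus_mutations), rng)
        for s in range(spec.species_per_genus):
            species_name = f"{genus_name} species{s + 1:02d}"
            species_seq = genus_seq.copy()
            species_events = _mutate(species_seq, take(spec.inter_mutations), rng)
            for k in range(spec.specimens_per_species):
                leaf_seq = species_seq.copy()
                leaf_events = _mutate(leaf_seq, take(spec.intra_mutations), rng)
                sid = f"G{g + 1:02d}S{s + 1:02d}-{k + 1:02d}"
                records.append(
                    BarcodeRecord(
                        specimen_id=sid,
                        species=species_name,
                        genus=genus_name,
                        family=family_name,
                        order=order_name,
                        sequence="",  # filled after noise injection
                    )
                )
                leaf_chains.append(((g, s, len(records) - 1),
                                    [genus_events, species_events, leaf_events]))
                sequences.append(leaf_seq)

    # Emit strings, injecting per-site noise after the planted structure.
    out_seqs: list[str] = []
    for seq in sequences:
        chars = np.array(list(_BASES))[seq]
        if spec.ambiguity_rate > 0:
            chars[rng.random(spec.alignment_width) < spec.ambiguity_rate] = "N"
        if spec.gap_rate > 0:
            chars[rng.random(spec.alignment_width) < spec.gap_rate] = "-"
        out_seqs.append("".join(chars))
    records = [r.replace(sequence=s) for r, s in zip(records, out_seqs)]
    dataset = BarcodeDataset(records)

    truth = None
    if with_truth:
        rows = []
        for i in range(len(records)):
            (gi, si, _), chain_i = leaf_chains[i]
            for j in range(i + 1, len(records)):
                (gj, sj, _), chain_j = leaf_chains[j]
                # Shared prefix of the branch chain cancels out.
                if gi != gj:
                    path = chain_i[0:] + chain_j[0:]
                elif si != sj:
                    path = chain_i[1:] + chain_j[1:]
                else:
                    path = chain_i[2:] + chain_j[2:]
                events = [e for branch in path for e in branch]
                planted_diff = len(events)
                planted_ts = sum(1 for _, old, new in events if _is_transition(old, new))
                comparable, diff, ts, tv = naive_pair_counts(out_seqs[i], out_seqs[j])
                rows.append(
                    {
                        "id_i": records[i].specimen_id,
                        "id_j": records[j].specimen_id,
                        "comparable_sites": comparable,
                        "diff_sites": diff,
                        "transitions": ts,
                        "transversions": tv,
                        "planted_diff_sites": planted_diff,
                        "planted_transitions": planted_ts,
                        "planted_transversions": planted_diff - planted_ts,
                    }
                )
        truth = pd.DataFrame(rows)
    return dataset, truth


def make_shared_haplotype_case(seed: int = 0) -> BarcodeDataset:
    """Two congeneric species, three specimens each, one shared haplotype.

    Mirrors the real-world situation of nominal species sharing identical
    barcodes: the cross-species minimum distance is exactly 0 and the pair
    must surface in a lumps report at 0.00%.
    """
    rng = np.random.default_rng(seed)
    width = 653
    root = rng.integers(0, 4, width, dtype=np.int64)
    sites = rng.permutation(width)
    sp_b = root.copy()
    _mutate(sp_b, sites[:20], rng)
    a3 = root.copy()
    _mutate(a3, sites[20:22], rng)
    b3 = sp_b.copy()
    _mutate(b3, sites[22:24], rng)
    to_str = lambda arr: "".join(np.array(list(_BASES))[arr])
    genus = "Genus01"
    recs = [
        BarcodeRecord("SHARE-A1", f"{genus} species01", to_str(root), genus=genus,
                      family="Family01", order="Order01"),
        BarcodeRecord("SHARE-A2", f"{genus} species01", to_str(root), genus=genus,
                      family="Family01", order="Order01"),
        BarcodeRecord("SHARE-A3", f"{genus} species01", to_str(a3), genus=genus,
                      family="Family01", order="Order01"),
        # B1 carries the haplotype shared with species01.
        BarcodeRecord("SHARE-B1", f"{genus} species02", to_str(root), genus=genus,
                      family="Family01", order="Order01"),
        BarcodeRecord("SHARE-B2", f"{genus} species02", to_str(sp_b), genus=genus,
                      family="Family01", order="Order01"),
        BarcodeRecord("SHARE-B3", f"{genus} species02", to_str(b3), genus=genus,
                      family="Family01", order="Order01"),
    ]
    return BarcodeDataset(recs)


def random_dataset(
    n_records: int,
    alignment_width: int = 653,
    seed: int = 0,
    specimens_per_species: int = 6,
    species_per_genus: int = 2,
) -> BarcodeDataset:
    """Unstructured uniform-random alignment for scale and counting checks.

    No planted distances — sequences are i.i.d. uniform over A/C/G/T — but
    taxon labels are still assigned so category bookkeeping works. Use
    :func:`make_toy_dataset` when ground-truth distances are required.
    """
    rng = np.random.default_rng(seed)
    mat = rng.integers(0, 4, (n_records, alignment_width), dtype=np.int64)
    lut = np.array(list(_BASES))
    records = []
    for idx in range(n_records):
        sp_idx = idx // specimens_per_species
        genus_idx = sp_idx // species_per_genus
        records.append(
            BarcodeRecord(
                specimen_id=f"R{idx + 1:05d}",
                species=f"Genus{genus_idx + 1:03d} species{sp_idx + 1:04d}",
                genus=f"Genus{genus_idx + 1:03d}",
                family=f"Family{genus_idx + 1:03d}",
                order="Order01",
                sequence="".join(lut[mat[idx]]),
            )
        )
    return BarcodeDataset(records)


def write_toy(
    dataset: BarcodeDataset,
    truth: Optional[pd.DataFrame],
    out_dir: str,
    seed: Optional[int] = None,
) -> dict[str, str]:
    """Write toy FASTA + metadata TSV (+ truth TSV); returns written paths.

    The seed is echoed in a comment line of each TSV and in the free-text
    field of each FASTA header so artifacts are self-describing.
    """
    import os

    from .seqio import write_barcode_fasta, write_metadata

    os.makedirs(out_dir, exist_ok=True)
    tag = f"seed={seed}" if seed is not None else "seed=unset"
    fasta = os.path.join(out_dir, "toy.fasta")
    with open(fasta, "w", encoding="utf-8", newline="\n") as fh:
        for r in dataset:
            fh.write(f">{r.specimen_id}|{r.species}|{tag}\n")
            for start in range(0, len(r.sequence), 80):
                fh.write(r.sequence[start : start + 80] + "\n")
    meta = os.path.join(out_dir, "toy_metadata.tsv")
    with open(meta, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# barcodegap simulate {tag}\n")
        rows = pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in dataset],
                "order": [r.order or "" for r in dataset],
                "family": [r.family or "" for r in dataset],
                "genus": [r.genus for r in dataset],
                "species": [r.species for r in dataset],
            }
        )
        rows.to_csv(fh, sep="\t", index=False, lineterminator="\n")
    paths = {"fasta": fasta, "metadata": meta}
    if truth is not None:
        tpath = os.path.join(out_dir, "toy_truth.tsv")
        with open(tpath, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# barcodegap simulate ground truth {tag}\n")
            truth.to_csv(fh, sep="\t", index=False, lineterminator="\n")
        paths["truth"] = tpath
    return paths
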