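"""Degenerate-primer utilities: expansion, degeneracy and mismatch matching.

Primers may contain the IUPAC nucleotide degeneracies and inosine (I), which
is modeled as pairing with any base — the standard approximation for a
universal-pairing nucleotide, so it contributes a factor of 4 to degeneracy
while never producing a mismatch. A "cocktail" is a named set of primers
mixed in one reaction; matching against a cocktail takes the best (minimum
mismatch) member.

The package ships the degenerate COI amplification/sequencing primers it was
built around as a TSV data file (``load_packaged_primers``).
"""

from __future__ import annotations

import dataclasses
import itertools
from importlib import resources
from math import prod
from typing import Iterable

import pandas as pd

#: Option set per primer symbol. Inosine (I) pairs universally.
SYMBOL_OPTIONS: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT", "I": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
    "N": "N", "I": "N",  # complement of universal-pairing I is "anything"
}


class PrimerError(ValueError):
    """Invalid primer alphabet or refused expansion."""


@dataclasses.dataclass(frozen=True)
class PrimerDef:
    """A named primer written 5'->3' over the degenerate DNA alphabet."""

    name: str
    sequence: str
    source: str = ""
    used_at: str = ""

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise PrimerError(f"primer {self.name!r}: empty sequence")
        bad = sorted({c for c in seq if c not in SYMBOL_OPTIONS})
        if bad:
            raise PrimerError(f"primer {self.name!r}: invalid symbol(s) {bad}")
        object.__setattr__(self, "sequence", seq)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PrimerCocktail:
    """A named mixture of primers used together in one reaction."""

    name: str
    members: tuple[PrimerDef, ...]


def degeneracy(primer: PrimerDef | str) -> int:
    """Number of concrete sequences the primer represents (product rule)."""
    seq = primer.sequence if isinstance(primer, PrimerDef) else primer.upper()
    try:
        return prod(len(SYMBOL_OPTIONS[c]) for c in seq)
    except KeyError as exc:
        raise PrimerError(f"invalid primer symbol {exc.args[0]!r}") from None


def expand_degenerate(primer: PrimerDef | str, limit: int = 4096) -> list[str]:
    """All concrete sequences of a degenerate primer, lexicographically sorted.

    Refuses (with the computed degeneracy in the message) when the expansion
    would exceed ``limit``.
    """
    seq = primer.sequence if isinstance(primer, PrimerDef) else primer.upper()
    deg = degeneracy(seq)
    if deg > limit:
        name = primer.name if isinstance(primer, PrimerDef) else seq
        raise PrimerError(
            f"refusing to expand {name!r}: degeneracy {deg} exceeds limit {limit}"
        )
    options = [sorted(SYMBOL_OPTIONS[c]) for c in seq]
    return ["".join(combo) for combo in itertools.product(*options)]


def match_primer(primer: PrimerDef | PrimerCocktail | str, target: str) -> int:
    """Mismatch count of a primer against an equal-length concrete window.

    A position matches when the target base is among the primer symbol's
    options (so I matches everything). For a cocktail the minimum mismatch
    count over members is returned (lengths must then each match the window).
    """
    if isinstance(primer, PrimerCocktail):
        return min(match_primer(m, target) for m in primer.members)
    seq = primer.sequence if isinstance(primer, PrimerDef) else primer.upper()
    tgt = target.upper()
    if len(seq) != len(tgt):
        raise PrimerError(f"length mismatch: primer {len(seq)} vs target {len(tgt)}")
    return sum(1 for p, t in zip(seq, tgt) if t not in SYMBOL_OPTIONS[p])


def reverse_complement(sequence: str) -> str:
    """Degeneracy-aware reverse complement (I maps to N)."""
    try:
        return "".join(_COMPLEMENT[c] for c in reversed(sequence.upper()))
    except KeyError as exc:
        raise PrimerError(f"cannot complement symbol {exc.args[0]!r}") from None


def scan_sequence(
    primer: PrimerDef | str,
    target: str,
    both_strands: bool = True,
) -> pd.DataFrame:
    """Slide the primer over a concrete sequence and score every window.

    Positions where the target window contains non-ACGT characters are
    skipped. Returns a DataFrame (position 0-based, strand '+'/'-',
    mismatches) sorted by mismatches then position; the reverse strand scans
    the reverse-complemented primer against the forward target.
    """
    seq = primer.sequence if isinstance(primer, PrimerDef) else primer.upper()
    tgt = target.upper()
    variants = [("+", seq)]
    if both_strands:
        variants.append(("-", reverse_complement(seq)))
    rows = []
    for strand, probe in variants:
        for pos in range(0, len(tgt) - len(probe) + 1):
            window = tgt[pos : pos + len(probe)]
            if any(c not in "ACGT" for c in window):
                continue
            rows.append(
                {"position": pos, "strand": strand,
                 "mismatches": match_primer(probe, window)}
            )
    df = pd.DataFrame(rows, columns=["position", "strand", "mismatches"])
    return df.sort_values(["mismatches", "position", "strand"],
                          kind="mergesort").reset_index(drop=True)


def load_packaged_primers() -> tuple[dict[str, PrimerDef], dict[str, PrimerCocktail]]:
    """Load the packaged primer table.

    Returns (primers, cocktails); cocktail rows reference member primers by
    name with a ``cocktail:A+B`` sequence field.
    """
    with resources.files("barcodegap.data").joinpath("primers.tsv").open("r") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    primers: dict[str, PrimerDef] = {}
    cocktail_rows: list[tuple[str, list[str]]] = []
    for row in df.itertuples():
        if row.sequence.startswith("cocktail:"):
            cocktail_rows.append((row.name, row.sequence[len("cocktail:"):].split("+")))
        else:
            primers[row.name] = PrimerDef(row.name, row.sequence,
                                          source=row.source, used_at=row.used_at)
    cocktails = {
        name: PrimerCocktail(name, tuple(primers[m] for m in members))
        for name, members in cocktail_rows
    }
    return primers, cocktails
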