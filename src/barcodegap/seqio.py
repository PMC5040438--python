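"""Reading, validating and writing aligned barcode FASTA plus specimen metadata.

A barcode reference library here is a single multiple sequence alignment of
mitochondrial COI (or any other marker) in which every record carries a
specimen identifier and a binomial species name. Taxon labels may be encoded
directly in FASTA headers or supplied through a companion tab-separated
metadata table.
"""

from __future__ import annotations

import dataclasses
import logging
from collections import Counter
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes accepted in aligned sequences.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
#: Characters treated as missing data; preserved on round trip.
MISSING = frozenset("-?")
ALPHABET = IUPAC_DNA | MISSING

#: Supported FASTA header dialects.
DIALECTS = ("gbol", "bold", "plain")

#: Metadata columns that must be present when headers carry no taxonomy.
REQUIRED_METADATA_COLUMNS = ("specimen_id", "order", "family", "genus", "species")


class BarcodeIOError(ValueError):
    """Raised for malformed input: bad headers, alphabet or alignment shape."""


@dataclasses.dataclass(frozen=True)
class BarcodeRecord:
    """One specimen's aligned sequence plus its taxon labels.

    ``genus`` defaults to the first whitespace-delimited token of ``species``
    when not given explicitly.
    """

    specimen_id: str
    species: str
    sequence: str
    genus: str = ""
    family: Optional[str] = None
    order: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.genus:
            token = self.species.split()[0] if self.species.strip() else ""
            object.__setattr__(self, "genus", token)

    @property
    def ungapped_length(self) -> int:
        """Number of non-gap, non-'?' characters (ambiguity codes count)."""
        seq = self.sequence
        return len(seq) - seq.count("-") - seq.count("?")

    def replace(self, **kwargs) -> "BarcodeRecord":
        return dataclasses.replace(self, **kwargs)


@dataclasses.dataclass
class BarcodeDataset:
    """An ordered collection of records sharing one alignment width."""

    records: list[BarcodeRecord]
    metadata: Optional[pd.DataFrame] = None
    alignment_width: int = dataclasses.field(init=False, default=0)
    species_index: dict[str, list[int]] = dataclasses.field(init=False, default_factory=dict)
    genus_index: dict[str, list[int]] = dataclasses.field(init=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if self.records:
            widths = {len(r.sequence) for r in self.records}
            if len(widths) > 1:
                expected = len(self.records[0].sequence)
                bad = [r.specimen_id for r in self.records if len(r.sequence) != expected]
                raise BarcodeIOError(
                    f"ragged alignment: widths {sorted(widths)}; "
                    f"records differing from first record's width {expected}: {bad}"
                )
            self.alignment_width = widths.pop()
        seen: set[str] = set()
        dupes: list[str] = []
        for r in self.records:
            if r.specimen_id in seen:
                dupes.append(r.specimen_id)
            seen.add(r.specimen_id)
        if dupes:
            raise BarcodeIOError(f"duplicate specimen_id(s): {sorted(set(dupes))}")
        self.species_index = {}
        self.genus_index = {}
        for pos, r in enumerate(self.records):
            self.species_index.setdefault(r.species, []).append(pos)
            self.genus_index.setdefault(r.genus, []).append(pos)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def species_names(self) -> list[str]:
        return list(self.species_index)

    def subset(self, positions: Sequence[int]) -> "BarcodeDataset":
        return BarcodeDataset([self.records[p] for p in positions], metadata=self.metadata)


def _clean_species(token: str) -> str:
    return " ".join(token.replace("_", " ").split())


def _parse_header(description: str, dialect: str) -> tuple[str, Optional[str]]:
    """Return (specimen_id, species-or-None) from one FASTA description line."""
    fields = [f.strip() for f in description.split("|")]
    specimen_id = fields[0].split()[0] if fields[0].split() else ""
    species = None
    if dialect in ("gbol", "bold") and len(fields) >= 2 and fields[1]:
        species = _clean_species(fields[1])
    return specimen_id, species


def read_metadata(path: str | Path, *, require_taxonomy: bool = False) -> pd.DataFrame:
    """Read a specimen metadata TSV (header row required, '#' lines skipped)."""
    meta = pd.read_csv(path, sep="\t", dtype=str, comment="#").fillna("")
    if "specimen_id" not in meta.columns or "species" not in meta.columns:
        raise BarcodeIOError(
            f"metadata {path} must contain 'specimen_id' and 'species' columns; "
            f"found {list(meta.columns)}"
        )
    if require_taxonomy:
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in meta.columns]
        if missing:
            raise BarcodeIOError(f"metadata {path} lacks required column(s) {missing}")
    if meta["specimen_id"].duplicated().any():
        dupes = meta.loc[meta["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise BarcodeIOError(f"duplicate specimen_id(s) in metadata: {dupes}")
    return meta


def read_barcode_fasta(
    path: str | Path,
    dialect: str = "gbol",
    metadata: Optional[str | Path | pd.DataFrame] = None,
) -> BarcodeDataset:
    """Read an aligned FASTA into a :class:`BarcodeDataset`.

    Parameters
    ----------
    path
        FASTA file with one aligned block (wrapped or single-line) per record.
    dialect
        Header grammar: ``"gbol"`` = ``>specimenID|Genus species[|free text]``,
        ``"bold"`` = ``>processID|Taxon|marker|accession``, ``"plain"`` =
        ``>specimenID`` with all taxonomy taken from ``metadata``.
    metadata
        Optional metadata TSV path or DataFrame. Mandatory for the plain
        dialect; for the others it overrides/fills taxon fields by specimen_id.

    Sequences are uppercased. Input order is preserved. Hard errors name the
    offending record and, for alphabet violations, the 1-based position.
    """
    if dialect not in DIALECTS:
        raise BarcodeIOError(f"unknown header dialect {dialect!r}; expected one of {DIALECTS}")
    meta_df: Optional[pd.DataFrame] = None
    if metadata is not None:
        if isinstance(metadata, pd.DataFrame):
            meta_df = metadata
        else:
            meta_df = read_metadata(metadata, require_taxonomy=(dialect == "plain"))
    elif dialect == "plain":
        raise BarcodeIOError("'plain' dialect requires a metadata table")
    meta_by_id: dict[str, dict] = {}
    if meta_df is not None:
        meta_by_id = {row["specimen_id"]: dict(row) for _, row in meta_df.iterrows()}

    records: list[BarcodeRecord] = []
    for seqrec in SeqIO.parse(str(path), "fasta"):
        specimen_id, species = _parse_header(seqrec.description, dialect)
        if not specimen_id:
            raise BarcodeIOError(f"empty specimen id in header {seqrec.description!r}")
        family = order = None
        genus = ""
        row = meta_by_id.get(specimen_id)
        if row is not None:
            species = _clean_species(row.get("species", "")) or species
            genus = row.get("genus", "") or ""
            family = row.get("family") or None
            order = row.get("order") or None
        if not species:
            raise BarcodeIOError(
                f"record {specimen_id!r}: no species in header (dialect {dialect!r}) "
                f"and specimen absent from metadata"
            )
        seq = str(seqrec.seq).upper()
        for pos, char in enumerate(seq, start=1):
            if char not in ALPHABET:
                raise BarcodeIOError(
                    f"record {specimen_id!r}: non-IUPAC character {char!r} at position {pos}"
                )
        records.append(
            BarcodeRecord(
                specimen_id=specimen_id,
                species=species,
                genus=genus,
                family=family,
                order=order,
                sequence=seq,
            )
        )
    return BarcodeDataset(records, metadata=meta_df)


def write_barcode_fasta(
    dataset: BarcodeDataset,
    path: str | Path,
    dialect: str = "gbol",
    wrap: int = 80,
) -> None:
    """Write the dataset back to FASTA (sequence lines wrapped at ``wrap``)."""
    if dialect not in DIALECTS:
        raise BarcodeIOError(f"unknown header dialect {dialect!r}")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in dataset:
            if dialect == "plain":
                header = r.specimen_id
            elif dialect == "bold":
                header = f"{r.specimen_id}|{r.species}|COI-5P|"
            else:
                header = f"{r.specimen_id}|{r.species}"
            fh.write(f">{header}\n")
            for start in range(0, len(r.sequence), wrap):
                fh.write(r.sequence[start : start + wrap] + "\n")


def write_metadata(dataset: BarcodeDataset, path: str | Path) -> None:
    """Write a minimal metadata TSV (order, family, genus, species per record)."""
    rows = [
        {
            "specimen_id": r.specimen_id,
            "order": r.order or "",
            "family": r.family or "",
            "genus": r.genus,
            "species": r.species,
        }
        for r in dataset
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, lineterminator="\n")


def apply_length_filter(
    dataset: BarcodeDataset, min_length: int = 500
) -> tuple[BarcodeDataset, list[str]]:
    """Drop records whose ungapped length is below ``min_length``.

    Returns the filtered dataset (input order preserved) and the list of
    rejected specimen ids for logging. Idempotent; an empty result is allowed.
    """
    kept: list[BarcodeRecord] = []
    rejected: list[str] = []
    for r in dataset:
        if r.ungapped_length >= min_length:
            kept.append(r)
        else:
            rejected.append(r.specimen_id)
    if rejected:
        logger.info("length filter (< %d bp): rejected %d record(s): %s",
                    min_length, len(rejected), rejected)
    return BarcodeDataset(kept, metadata=dataset.metadata), rejected


@dataclasses.dataclass
class ValidationReport:
    """Pure descriptive report on an alignment; never raises."""

    n_records: int
    alignment_width: Optional[int]
    ungapped_lengths: dict[str, int]
    alphabet_census: dict[str, int]
    alphabet_violations: list[tuple[str, int, str]]  # (specimen_id, 1-based pos, char)
    duplicate_ids: list[str]

    @property
    def ok(self) -> bool:
        return not self.alphabet_violations and not self.duplicate_ids


def validate_alignment(records: Iterable[BarcodeRecord] | BarcodeDataset) -> ValidationReport:
    """Report width, per-record ungapped lengths, residue census and problems.

    Accepts a dataset or a bare record iterable so that even collections that
    would fail :class:`BarcodeDataset` construction can be audited.
    """
    recs = list(records.records) if isinstance(records, BarcodeDataset) else list(records)
    census: Counter[str] = Counter()
    violations: list[tuple[str, int, str]] = []
    lengths: dict[str, int] = {}
    seen: set[str] = set()
    dupes: list[str] = []
    for r in recs:
        census.update(r.sequence)
        lengths[r.specimen_id] = r.ungapped_length
        if r.specimen_id in seen:
            dupes.append(r.specimen_id)
        seen.add(r.specimen_id)
        for pos, char in enumerate(r.sequence, start=1):
            if char not in ALPHABET:
                violations.append((r.specimen_id, pos, char))
    widths = {len(r.sequence) for r in recs}
    width = widths.pop() if len(widths) == 1 else None
    return ValidationReport(
        n_records=len(recs),
        alignment_width=width,
        ungapped_lengths=lengths,
        alphabet_census=dict(census),
        alphabet_violations=violations,
        duplicate_ids=sorted(set(dupes)),
    )
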