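"""Pairwise p- and K2P-distance engine over an aligned barcode dataset.

Distances use pairwise complete deletion: for each sequence pair, every
alignment column where either residue is not an unambiguous A/C/G/T (gaps,
'?', N and all IUPAC ambiguity codes) is excluded from both numerator and
denominator. With that rule the uncorrected distance decomposes exactly into
the transition proportion P (A<->G, C<->T) and the transversion proportion Q,
p = P + Q, and the Kimura two-parameter distance is

    K = -1/2 * ln((1 - 2P - Q) * sqrt(1 - 2Q))

which is undefined (flagged, not clamped) when a logarithm argument is
non-positive or when a pair shares no comparable site.

All distances are carried internally as fractions at full double precision;
report surfaces multiply by 100 and round only at serialization.
"""

from __future__ import annotations

import dataclasses
import math
from concurrent.futures import ThreadPoolExecutor
from functools import cached_property
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .seqio import BarcodeDataset

#: Flag value for a distance that cannot be computed (checked with math.isnan).
UNDEFINED = math.nan

METRICS = ("p", "k2p")

#: Pair category codes (by increasing taxonomic distance of the pair).
INTRASPECIFIC, CONGENERIC, ALLOGENERIC = 0, 1, 2
CATEGORY_NAMES = ("intraspecific", "congeneric", "allogeneric")

# A,C,G,T -> 0..3 (purines even, pyrimidines odd so transitions share parity);
# everything else -> 4 = "missing" under pairwise complete deletion.
_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in zip(b"ACGT", range(4)):
    _CODE_LUT[_b] = _c


def expected_pair_count(n: int) -> int:
    """Number of unordered pairs n(n-1)/2 the engine must produce for n records."""
    return n * (n - 1) // 2


def encode_sequences(sequences: Sequence[str]) -> np.ndarray:
    """Encode equal-length sequences as a (n, width) uint8 matrix (4 = missing)."""
    n = len(sequences)
    if n == 0:
        return np.empty((0, 0), dtype=np.uint8)
    width = len(sequences[0])
    buf = np.frombuffer("".join(sequences).encode("ascii"), dtype=np.uint8)
    return _CODE_LUT[buf].reshape(n, width)


def k2p_distance(P: float, Q: float) -> float:
    """Kimura two-parameter distance from transition/transversion proportions.

    Returns :data:`UNDEFINED` (NaN) when the correction is outside its domain
    (1-2P-Q <= 0 or 1-2Q <= 0). Arguments outside [0, 1] or with P+Q > 1 are a
    hard error.
    """
    if not (0.0 <= P <= 1.0 and 0.0 <= Q <= 1.0 and P + Q <= 1.0 + 1e-12):
        raise ValueError(f"P={P}, Q={Q} must lie in [0,1] with P+Q <= 1")
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return UNDEFINED
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _k2p_vector(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
    return out


@dataclasses.dataclass(frozen=True)
class PairStats:
    """Site counts and distances for one aligned sequence pair."""

    comparable_sites: int
    diff_sites: int
    transitions: int
    transversions: int
    P: float  # transition proportion among comparable sites
    Q: float  # transversion proportion among comparable sites
    p_distance: float  # fraction, NaN when no comparable site
    k2p_distance: float  # fraction, NaN when undefined


def pair_stats(a: str, b: str) -> PairStats:
    """Compute all pairwise quantities for two aligned sequences."""
    if len(a) != len(b):
        raise ValueError(f"aligned sequences differ in length: {len(a)} vs {len(b)}")
    codes = encode_sequences([a.upper(), b.upper()])
    ca, cb = codes[0], codes[1]
    valid = (ca < 4) & (cb < 4)
    comparable = int(valid.sum())
    neq = valid & (ca != cb)
    diff = int(neq.sum())
    ts = int((neq & ((ca & 1) == (cb & 1))).sum())
    tv = diff - ts
    if comparable == 0:
        return PairStats(0, 0, 0, 0, UNDEFINED, UNDEFINED, UNDEFINED, UNDEFINED)
    P = ts / comparable
    Q = tv / comparable
    return PairStats(comparable, diff, ts, tv, P, Q, diff / comparable, k2p_distance(P, Q))


#: Alias matching the operation's common name in the field.
p_distance = pair_stats


def _pair_block(codes: np.ndarray, i0: int, i1: int) -> tuple[np.ndarray, ...]:
    """Compute stats for all pairs (i, j>i) with i in [i0, i1)."""
    n = codes.shape[0]
    iis, jjs, comps, diffs, tss = [], [], [], [], []
    for i in range(i0, i1):
        if i + 1 >= n:
            continue
        a = codes[i]
        b = codes[i + 1 :]
        valid = (a < 4) & (b < 4)
        comparable = valid.sum(axis=1).astype(np.int32)
        neq = valid & (a != b)
        diff = neq.sum(axis=1).astype(np.int32)
        ts = (neq & ((a & 1) == (b & 1))).sum(axis=1).astype(np.int32)
        m = n - i - 1
        iis.append(np.full(m, i, dtype=np.int32))
        jjs.append(np.arange(i + 1, n, dtype=np.int32))
        comps.append(comparable)
        diffs.append(diff)
        tss.append(ts)
    cat = lambda parts: np.concatenate(parts) if parts else np.empty(0, dtype=np.int32)
    return cat(iis), cat(jjs), cat(comps), cat(diffs), cat(tss)


@dataclasses.dataclass
class DistanceTable:
    """All n(n-1)/2 unordered pairwise distances plus per-record taxon labels.

    Only pairs with i < j are stored; symmetry is implicit and self-distance is
    conceptually zero. ``metric`` selects which distance :attr:`distances`
    exposes; both p and K2P columns are always present at full precision.
    """

    metric: str
    n: int
    alignment_width: int
    ids: list[str]
    species: list[str]
    genus: list[str]
    family: list[Optional[str]]
    order: list[Optional[str]]
    i: np.ndarray
    j: np.ndarray
    comparable_sites: np.ndarray
    diff_sites: np.ndarray
    transitions: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    p: np.ndarray
    k2p: np.ndarray

    def __len__(self) -> int:
        return len(self.i)

    @property
    def distances(self) -> np.ndarray:
        """Distance fractions under the table's metric (NaN = undefined)."""
        return self.p if self.metric == "p" else self.k2p

    @cached_property
    def species_codes(self) -> np.ndarray:
        uniq = {s: c for c, s in enumerate(dict.fromkeys(self.species))}
        return np.array([uniq[s] for s in self.species], dtype=np.int32)

    @cached_property
    def genus_codes(self) -> np.ndarray:
        uniq = {g: c for c, g in enumerate(dict.fromkeys(self.genus))}
        return np.array([uniq[g] for g in self.genus], dtype=np.int32)

    @cached_property
    def categories(self) -> np.ndarray:
        """Per-pair category: intraspecific, congeneric-allospecific, allogeneric."""
        sc, gc = self.species_codes, self.genus_codes
        same_sp = sc[self.i] == sc[self.j]
        same_gen = gc[self.i] == gc[self.j]
        out = np.full(len(self), ALLOGENERIC, dtype=np.uint8)
        out[same_gen] = CONGENERIC
        out[same_sp] = INTRASPECIFIC
        return out

    @property
    def intraspecific_mask(self) -> np.ndarray:
        return self.categories == INTRASPECIFIC

    @property
    def congeneric_mask(self) -> np.ndarray:
        return self.categories == CONGENERIC

    @property
    def allogeneric_mask(self) -> np.ndarray:
        return self.categories == ALLOGENERIC

    @property
    def interspecific_mask(self) -> np.ndarray:
        """Heterospecific pairs regardless of genus (congeneric + allogeneric)."""
        return self.categories != INTRASPECIFIC

    def undefined_count(self) -> int:
        """Pairs whose distance under the current metric is undefined."""
        return int(np.isnan(self.distances).sum())

    def subset(self, positions: Sequence[int]) -> "DistanceTable":
        """Restrict to the given record positions (pairs with both ends kept)."""
        positions = sorted(positions)  # preserve original order so i < j holds
        keep_rec = np.zeros(self.n, dtype=bool)
        keep_rec[positions] = True
        remap = np.full(self.n, -1, dtype=np.int32)
        remap[positions] = np.arange(len(positions), dtype=np.int32)
        mask = keep_rec[self.i] & keep_rec[self.j]
        pick = lambda xs: [xs[p] for p in positions]
        return DistanceTable(
            metric=self.metric,
            n=len(positions),
            alignment_width=self.alignment_width,
            ids=pick(self.ids),
            species=pick(self.species),
            genus=pick(self.genus),
            family=pick(self.family),
            order=pick(self.order),
            i=remap[self.i[mask]],
            j=remap[self.j[mask]],
            comparable_sites=self.comparable_sites[mask],
            diff_sites=self.diff_sites[mask],
            transitions=self.transitions[mask],
            P=self.P[mask],
            Q=self.Q[mask],
            p=self.p[mask],
            k2p=self.k2p[mask],
        )

    def with_metric(self, metric: str) -> "DistanceTable":
        if metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        return dataclasses.replace(self, metric=metric)

    def to_frame(self) -> pd.DataFrame:
        """Full pairwise matrix as a long-format DataFrame (percent scale)."""
        ids = np.asarray(self.ids, dtype=object)
        sp = np.asarray(self.species, dtype=object)
        cats = np.asarray(CATEGORY_NAMES, dtype=object)[self.categories]
        return pd.DataFrame(
            {
                "id_i": ids[self.i],
                "id_j": ids[self.j],
                "species_i": sp[self.i],
                "species_j": sp[self.j],
                "category": cats,
                "comparable_sites": self.comparable_sites,
                "p_distance_pct": self.p * 100.0,
                "k2p_distance_pct": self.k2p * 100.0,
            }
        )


def pairwise_matrix(
    dataset: BarcodeDataset,
    metric: str = "p",
    threads: int = 1,
    min_comparable_sites: int = 0,
) -> DistanceTable:
    """Compute all unordered pairwise distances for a validated dataset.

    The O(n^2) kernel is split into row blocks that may be processed by a
    thread pool; blocks are merged in deterministic order, so the result is
    bit-identical for any thread count. ``min_comparable_sites`` additionally
    flags pairs with too few comparable sites as undefined (default 0: only
    the zero-overlap case is flagged).
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    n = len(dataset)
    if n < 2:
        raise ValueError(f"need at least 2 records, got {n}")
    if threads < 1:
        raise ValueError("threads must be >= 1")
    codes = encode_sequences([r.sequence for r in dataset.records])

    if threads == 1:
        blocks = [_pair_block(codes, 0, n)]
    else:
        # More chunks than threads smooths the triangular workload.
        n_chunks = min(n, threads * 4)
        bounds = np.linspace(0, n, n_chunks + 1).astype(int)
        spans = [(int(a), int(b)) for a, b in zip(bounds[:-1], bounds[1:]) if a < b]
        with ThreadPoolExecutor(max_workers=threads) as pool:
            blocks = list(pool.map(lambda s: _pair_block(codes, *s), spans))

    i = np.concatenate([b[0] for b in blocks])
    j = np.concatenate([b[1] for b in blocks])
    comparable = np.concatenate([b[2] for b in blocks])
    diff = np.concatenate([b[3] for b in blocks])
    ts = np.concatenate([b[4] for b in blocks])

    usable = comparable > max(0, min_comparable_sites)
    denom = comparable.astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(usable, ts / denom, np.nan)
        Q = np.where(usable, (diff - ts) / denom, np.nan)
        p = np.where(usable, diff / denom, np.nan)
    k2p = _k2p_vector(P, Q)

    return DistanceTable(
        metric=metric,
        n=n,
        alignment_width=dataset.alignment_width,
        ids=[r.specimen_id for r in dataset.records],
        species=[r.species for r in dataset.records],
        genus=[r.genus for r in dataset.records],
        family=[r.family for r in dataset.records],
        order=[r.order for r in dataset.records],
        i=i,
        j=j,
        comparable_sites=comparable,
        diff_sites=diff,
        transitions=ts,
        P=P,
        Q=Q,
        p=p,
        k2p=k2p,
    )
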