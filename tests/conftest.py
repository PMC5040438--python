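import numpy as np
import pytest

from barcodegap import BarcodeDataset, BarcodeRecord, ToySpec, make_toy_dataset


@pytest.fixture
def tiny_dataset() -> BarcodeDataset:
    """2 genera x 2 species x 2 specimens, width 20, handmade distances."""
    base = "ACGTACGTACGTACGTACGT"

    def mut(seq: str, positions: dict[int, str]) -> str:
        chars = list(seq)
        for pos, b in positions.items():
            chars[pos] = b
        return "".join(chars)

    rows = [
        ("a1", "Alpha one", base),
        ("a2", "Alpha one", mut(base, {0: "C"})),
        ("b1", "Alpha two", mut(base, {4: "G", 5: "A"})),
        ("b2", "Alpha two", mut(base, {4: "G", 5: "A", 1: "T"})),
        ("c1", "Beta one", mut(base, {8: "T", 9: "G", 10: "A"})),
        ("c2", "Beta one", mut(base, {8: "T", 9: "G", 10: "A", 2: "A"})),
        ("d1", "Beta two", mut(base, {12: "A", 13: "C", 14: "T", 15: "G"})),
        ("d2", "Beta two", mut(base, {12: "A", 13: "C", 14: "T", 15: "G", 3: "C"})),
    ]
    return BarcodeDataset(
        [
            BarcodeRecord(sid, sp, seq, order="OrdA", family="FamA")
            for sid, sp, seq in rows
        ]
    )


@pytest.fixture
def toy():
    dataset, truth = make_toy_dataset(ToySpec(seed=7))
    return dataset, truth


def random_aligned_pair(rng: np.random.Generator, width: int) -> tuple[str, str]:
    """Random aligned sequences including ambiguity codes and gaps."""
    alphabet = np.array(list("ACGTACGTACGTNRYSWKMBDHV-?"))
    a = "".join(rng.choice(alphabet, size=width))
    b = "".join(rng.choice(alphabet, size=width))
    return a, b
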