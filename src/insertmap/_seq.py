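"""Tiny sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# integer codes: A=0 C=1 G=2 T=3, anything else 4 (invalid for k-mers)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Sequence -> uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=n)])


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each base independently with probability `rate`."""
    if rate <= 0:
        return seq
    arr = encode(seq).astype(np.int64)
    hit = rng.random(arr.size) < rate
    # shift by 1..3 mod 4 guarantees a different base
    arr[hit] = (arr[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return "".join(BASES[c] for c in arr)


def phred_to_ascii(quals) -> str:
    return "".join(chr(int(q) + 33) for q in quals)


def ascii_to_phred(s: str) -> list[int]:
    return [ord(c) - 33 for c in s]


def mean_quality(quals) -> float:
    return float(np.mean(quals)) if len(quals) else 0.0
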