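"""Small sequence utilities shared across modules."""

from __future__ import annotations

import numpy as np

DNA = "ACGT"
RNA = "ACGU"
AA = "ACDEFGHIKLMNPQRSTVWY"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

_DNA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate(DNA):
    _DNA_INDEX[ord(_b)] = _i
_DNA_INDEX[ord("U")] = 3  # T ≡ U

_AA_INDEX = np.full(128, -1, dtype=np.int8)
for _i, _a in enumerate(AA):
    _AA_INDEX[ord(_a)] = _i


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def encode_dna(seq: str) -> np.ndarray:
    """Map ACGT (and U) to 0..3; other characters map to -1."""
    return _DNA_INDEX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def encode_aa(seq: str) -> np.ndarray:
    return _AA_INDEX[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


_DNA_ARR = np.array(list(DNA))
_AA_ARR = np.array(list(AA))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_DNA_ARR[rng.integers(0, 4, size=length)])


def random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(_AA_ARR[rng.integers(0, 20, size=length)])


def mutate_dna(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability `rate`."""
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [b for b in DNA if b != chars[i].upper()]
        chars[i] = choices[rng.integers(3)]
    return "".join(chars)


def mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        choices = [a for a in AA if a != chars[i]]
        chars[i] = choices[rng.integers(len(choices))]
    return "".join(chars)
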