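"""Small sequence utilities shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: bytes view of the nucleotide alphabet, used for fast random-sequence generation
_BASES = np.frombuffer(b"ACGT", dtype="S1")

ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def validate_dna(seq: str, what: str = "sequence") -> None:
    """Raise ``ValueError`` unless *seq* is non-empty and strictly A/C/G/T."""
    if not seq:
        raise ValueError(f"{what} is empty")
    if not ALPHABET.issuperset(seq):
        bad = sorted(set(seq) - ALPHABET)
        raise ValueError(f"{what} contains non-ACGT characters: {bad}")


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """Random nucleotide string of length *n* with expected GC fraction *gc*."""
    if n < 0:
        raise ValueError("length must be non-negative")
    at = (1.0 - gc) / 2.0
    p = [at, gc / 2.0, gc / 2.0, at]
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)
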