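"""Small shared helpers: complements, seeded RNG fan-out, sequence encoding."""

from __future__ import annotations

import hashlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def stage_seed(global_seed: int, label: str) -> int:
    """Derive a per-stage RNG seed (< 2**31) from a global seed and a stage label."""
    digest = hashlib.sha256(f"{global_seed}:{label}".encode()).hexdigest()
    return int(digest[:8], 16) % (2**31)


def seq_to_u8(seq: str) -> np.ndarray:
    """Byte view of an ASCII sequence for vectorized comparison."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def modal_fraction(seq: str) -> float:
    """Fraction of positions occupied by the most common character."""
    if not seq:
        return 0.0
    return max(seq.count(b) for b in set(seq)) / len(seq)


def nonmodal_count(seq: str) -> int:
    """Number of positions not occupied by the most common nucleotide.

    Used by the low-complexity filters: e.g. ``GTCCGAAAAAAAAA`` has modal base A
    (9 copies) and 5 nonmodal nucleotides.
    """
    if not seq:
        return 0
    return len(seq) - max(seq.count(b) for b in set(seq))
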