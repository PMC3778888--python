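"""Non-genome-encoded oligo(A) tail detection and censuses.

A mapped read whose alignment stops short of its 3' end carries a candidate
non-encoded tail (the soft-clipped residues).  The tail is accepted as an
oligo(A) tail when it contains two or more As and fewer than one in five
non-A residues.  Because the adaptor, linker and mapped region consume most
of a short sequencing read, long tails are censored; a complementary census
simply counts terminal A runs on (unmapped) adaptor-clipped reads of a fixed
length band, trading genome/tail discrimination for reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation


@dataclass
class ATailCall:
    read_id: str
    tail: str
    length: int
    non_a: int
    accepted: bool
    contig: str
    strand: str
    last_encoded: int      # genomic coordinate of the 3'-most aligned base


def classify_tail(tail: str) -> bool:
    """Accept when the tail has >= 2 As and strictly fewer than len/5 non-As."""
    n_a = tail.count("A")
    non_a = len(tail) - n_a
    return n_a >= 2 and non_a < len(tail) / 5


def call_atails(mapped) -> list[ATailCall]:
    """Classify the 3' soft-clipped tail of every adaptor-confirmed read.

    Reads without a detected 3' adaptor are not evaluated (their true 3' end
    was never observed).  Rejected reads are retained with accepted=False.
    """
    out = []
    for r in mapped:
        if not r.adaptor_found:
            continue
        tail = r.clipped_tail
        last = r.end - 1 if r.strand == "+" else r.start
        out.append(
            ATailCall(
                r.id, tail, len(tail), len(tail) - tail.count("A"),
                classify_tail(tail), r.contig, r.strand, last,
            )
        )
    return out


def tail_length_distribution(calls: list[ATailCall], normalize_to_len2: bool = False) -> pd.Series:
    """Histogram of accepted tail lengths, optionally relative to 2 nt tails."""
    lengths = [c.length for c in calls if c.accepted]
    if not lengths:
        raise ValueError("no accepted A-tail calls")
    s = pd.Series(lengths).value_counts().sort_index().astype(float)
    if normalize_to_len2:
        if 2 not in s.index:
            raise ValueError("no 2 nt tails to normalize against")
        s = s / s[2]
    return s


def raw_read_tail_census(processed, min_len: int = 30, max_len: int = 35) -> pd.Series:
    """Terminal A-run length spectrum (% of reads) on adaptor-clipped raw reads.

    Restricted to reads of ``min_len``..``max_len`` nt after adaptor removal so
    read-length differences between libraries do not bias the spectrum.  Makes
    no genome-encoded/non-encoded distinction, but is not censored by the
    mapped-region requirement.
    """
    runs = []
    for r in processed:
        if not r.adaptor_found or not (min_len <= len(r.sequence) <= max_len):
            continue
        n = 0
        for b in reversed(r.sequence):
            if b != "A":
                break
            n += 1
        runs.append(n)
    if not runs:
        raise ValueError("no qualifying reads (adaptor-clipped, length in band)")
    s = pd.Series(runs).value_counts().sort_index()
    return s * 100.0 / s.sum()


def atail_prevalence_by_class(
    calls: list[ATailCall],
    mapped,
    annotation: Annotation,
    five_flank: int = 0,
    three_flank: int = 0,
) -> pd.Series:
    """Fraction of adaptor-confirmed reads per transcript class carrying an
    accepted A-tail.  Classes with no reads are reported as NaN."""
    accepted = {c.read_id for c in calls if c.accepted}
    evaluated = {c.read_id for c in calls}
    totals: dict[str, int] = {}
    tailed: dict[str, int] = {}
    for r in mapped:
        if r.id not in evaluated:
            continue
        t = annotation.assign(r.contig, r.strand, r.start, r.end, five_flank, three_flank)
        cls = t.class_label if t else "intergenic"
        totals[cls] = totals.get(cls, 0) + 1
        if r.id in accepted:
            tailed[cls] = tailed.get(cls, 0) + 1
    if not totals:
        raise ValueError("no reads to assess")
    return pd.Series(
        {c: (tailed.get(c, 0) / n if n else np.nan) for c, n in sorted(totals.items())}
    )


DEFAULT_TAIL_STRATA = ((1, 3), (4, 6), (7, 12), (13, 10**9))


def stratify_by_tail_length(mapped, calls: list[ATailCall],
                            strata=DEFAULT_TAIL_STRATA) -> dict[str, list]:
    """Split reads into tail-length bins (accepted calls only) for
    tail-stratified profile analyses."""
    by_id = {r.id: r for r in mapped}
    out: dict[str, list] = {f"{lo}-{hi}": [] for lo, hi in strata}
    for c in calls:
        if not c.accepted or c.read_id not in by_id:
            continue
        for lo, hi in strata:
            if lo <= c.length <= hi:
                out[f"{lo}-{hi}"].append(by_id[c.read_id])
                break
    return out
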