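"""Seed-and-extend read mapping for the toy genome, with SAM interchange.

The alignment model is deliberately narrow, matching what crosslinking reads
need: an ungapped local alignment anchored at the read 5' end, optionally
interrupted by one single-nucleotide genomic deletion (the crosslink
signature), with unalignable 3' residues reported as a soft-clipped tail
(candidate non-encoded oligo(A)).  Reads with multiple equally best loci are
discarded as ambiguous so outputs stay deterministic.  Real data can bypass
this aligner entirely through ``read_sam``.
"""

from __future__ import annotations

import hashlib
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._util import revcomp, seq_to_u8
from .readprep import ProcessedRead

MATCH, MISMATCH, DELETION = 1, -2, -3


@dataclass
class MappedRead:
    id: str
    contig: str
    strand: str
    start: int                       # genomic, 0-based half-open
    end: int
    deletions: tuple[int, ...]       # genomic 0-based positions of deleted bases
    clipped_tail: str                # 3' soft-clip, read orientation
    random_tag: str = ""
    sample: str = ""
    adaptor_found: bool = False
    seq: str = ""                    # full processed read sequence, read orientation
    score: int = 0

    @property
    def aligned_read_length(self) -> int:
        return len(self.seq) - len(self.clipped_tail) if self.seq else (
            self.end - self.start - len(self.deletions)
        )

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


class GenomeIndex:
    """12-mer seed index over both orientations of every contig."""

    def __init__(self, genome: dict[str, str], k: int = 12):
        if not genome or all(len(s) == 0 for s in genome.values()):
            raise ValueError("empty genome")
        self.k = k
        self.genome = genome
        self.targets: dict[tuple[str, str], str] = {}
        self.arrays: dict[tuple[str, str], np.ndarray] = {}
        self.seeds: dict[str, list[tuple[str, str, int]]] = {}
        for name, seq in genome.items():
            for strand, s in (("+", seq), ("-", revcomp(seq))):
                self.targets[(name, strand)] = s
                self.arrays[(name, strand)] = seq_to_u8(s)
                for i in range(len(s) - k + 1):
                    self.seeds.setdefault(s[i : i + k], []).append((name, strand, i))

    def lookup(self, kmer: str):
        return self.seeds.get(kmer, ())

    def checksum(self) -> str:
        h = hashlib.md5()
        for name in sorted(self.genome):
            h.update(self.genome[name].encode())
        return h.hexdigest()


def _extend(read: np.ndarray, target: np.ndarray, t: int, dpos: int | None,
            max_mismatch: int):
    """Best-scoring read-prefix alignment starting at target position t.

    With ``dpos`` set, the target base at t+dpos is treated as deleted from the
    read (read positions >= dpos align one base further right).  Returns
    (score, aligned_read_len, mismatches, dpos_used) or None.
    """
    shift = 0 if dpos is None else 1
    m = min(len(read), len(target) - t - shift)
    if m <= 0:
        return None
    if dpos is None:
        eq = read[:m] == target[t : t + m]
    else:
        if dpos >= m:
            return None
        eq = np.empty(m, dtype=bool)
        eq[:dpos] = read[:dpos] == target[t : t + dpos]
        eq[dpos:] = read[dpos:m] == target[t + dpos + 1 : t + m + 1]
    mis = np.cumsum(~eq)
    score = np.cumsum(np.where(eq, MATCH, MISMATCH))
    valid = mis <= max_mismatch
    if dpos is not None:
        score = score + DELETION
        valid[:dpos] = False  # the deletion must sit inside the alignment
    idx = np.nonzero(valid)[0]
    if idx.size == 0:
        return None
    best = idx[np.argmax(score[idx])]
    used = dpos if (dpos is not None and best >= dpos) else None
    return int(score[best]), int(best) + 1, int(mis[best]), used


def _candidates(seq: str, index: GenomeIndex) -> set[tuple[str, str, int]]:
    k = index.k
    cands: set[tuple[str, str, int]] = set()
    if len(seq) >= k:
        for c, s, p in index.lookup(seq[:k]):
            cands.add((c, s, p))
    off = k + 1
    if len(seq) >= off + k:
        for c, s, p in index.lookup(seq[off : off + k]):
            cands.add((c, s, p - off))
            cands.add((c, s, p - off - 1))
    if not cands and len(seq) >= k - 1:
        # gapped-prefix rescue: a deletion within the first k nt breaks both seeds
        for d in range(1, k):
            for b in "ACGT":
                probe = (seq[:d] + b + seq[d:])[:k]
                for c, s, p in index.lookup(probe):
                    cands.add((c, s, p))
    return {(c, s, p) for c, s, p in cands if p >= 0}


def align_reads(
    processed: Iterable[ProcessedRead],
    genome: dict[str, str] | GenomeIndex,
    min_len: int = 18,
    max_mismatch: int = 2,
) -> tuple[list[MappedRead], Counter]:
    """Map processed reads; returns (mapped, unmapped-reason counts)."""
    index = genome if isinstance(genome, GenomeIndex) else GenomeIndex(genome)
    mapped: list[MappedRead] = []
    unmapped: Counter = Counter()

    for r in processed:
        seq = r.sequence
        if len(seq) < min_len:
            unmapped["too_short"] += 1
            continue
        rb = seq_to_u8(seq)
        best = None           # (score, key, alen, mis, dused)
        best_score, n_best_loci = None, 0
        for key in sorted(_candidates(seq, index)):
            target = index.arrays[key[:2]]
            t = key[2]
            res = _extend(rb, target, t, None, max_mismatch)
            options = [res] if res else []
            # a genomic deletion is only plausible at the first mismatch of
            # the ungapped pass (crosslink deletions are single-nt)
            m = min(len(rb), len(target) - t)
            if m > 0:
                miss = np.nonzero(rb[:m] != target[t : t + m])[0]
                if miss.size and miss[0] >= 1:
                    res_d = _extend(rb, target, t, int(miss[0]), max_mismatch)
                    if res_d:
                        options.append(res_d)
            for score, alen, mis, dused in options:
                if alen < min_len:
                    continue
                cand = (score, key, alen, mis, dused)
                if best_score is None or score > best_score:
                    best, best_score, n_best_loci = cand, score, 1
                elif score == best_score:
                    # same locus refinement vs a genuinely different locus
                    if key[:2] == best[1][:2] and abs(key[2] - best[1][2]) <= 1:
                        if (mis, -alen) < (best[3], -best[2]):
                            best = cand
                    else:
                        n_best_loci += 1
        if best is None:
            unmapped["no_alignment"] += 1
            continue
        if n_best_loci > 1:
            unmapped["ambiguous"] += 1
            continue

        score, (contig, strand, t), alen, mis, dused = best
        glen = alen + (1 if dused is not None else 0)
        L = len(index.genome[contig])
        if strand == "+":
            start, end = t, t + glen
            dels = (t + dused,) if dused is not None else ()
        else:
            start, end = L - (t + glen), L - t
            dels = (L - 1 - (t + dused),) if dused is not None else ()
        mapped.append(
            MappedRead(
                id=r.id, contig=contig, strand=strand, start=start, end=end,
                deletions=dels, clipped_tail=seq[alen:], random_tag=r.random_tag,
                sample=r.sample, adaptor_found=r.adaptor_found, seq=seq, score=score,
            )
        )
    return mapped, unmapped


# --------------------------------------------------------------------------
# SAM interchange (pysam)
# --------------------------------------------------------------------------

_CIGAR_M, _CIGAR_D, _CIGAR_S = 0, 2, 4


def write_sam(mapped: list[MappedRead], genome: dict[str, str], path: str) -> None:
    import pysam

    names = sorted(genome)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(genome[n])} for n in names],
        "CO": [f"crac_atlas genome md5 {GenomeIndex(genome).checksum()}"],
    }
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for r in sorted(mapped, key=lambda x: (x.contig, x.start, x.id)):
            a = pysam.AlignedSegment(fh.header)
            a.query_name = r.id
            a.reference_name = r.contig
            a.reference_start = r.start
            a.mapping_quality = 255
            a.flag = 0 if r.strand == "+" else 16
            blocks = _match_blocks(r)
            cig = []
            for kind, ln in blocks:
                cig.append((kind, ln))
            tail = [( _CIGAR_S, len(r.clipped_tail))] if r.clipped_tail else []
            # CIGAR is always reference-ordered; for a minus-strand read the
            # 3' soft clip sits at the reference-left end
            if r.strand == "+":
                a.cigartuples = cig + tail
                a.query_sequence = r.seq
            else:
                a.cigartuples = tail + cig
                a.query_sequence = revcomp(r.seq)
            a.set_tag("XT", r.random_tag or "*")
            a.set_tag("XF", int(r.adaptor_found))
            a.set_tag("XS", r.sample or "*")
            fh.write(a)


def _match_blocks(r: MappedRead):
    """CIGAR M/D blocks over the genomic interval, genome order."""
    blocks = []
    pos = r.start
    for d in sorted(r.deletions):
        if d > pos:
            blocks.append((_CIGAR_M, d - pos))
        blocks.append((_CIGAR_D, 1))
        pos = d + 1
    if r.end > pos:
        blocks.append((_CIGAR_M, r.end - pos))
    return blocks


def read_sam(path: str) -> list[MappedRead]:
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            strand = "-" if a.is_reverse else "+"
            cig = a.cigartuples or []
            for op, _ in cig:
                if op not in (_CIGAR_M, _CIGAR_D, _CIGAR_S):
                    raise ValueError(
                        f"record {a.query_name}: unsupported CIGAR op {op}"
                    )
            # soft clips: only a 3'-end clip (read orientation) is allowed
            sclips = [i for i, (op, _) in enumerate(cig) if op == _CIGAR_S]
            tail_len = 0
            if sclips:
                expected = len(cig) - 1 if strand == "+" else 0
                if sclips != [expected]:
                    raise ValueError(
                        f"record {a.query_name}: unexpected soft-clip placement"
                    )
                tail_len = cig[expected][1]
            dels = []
            pos = a.reference_start
            for op, ln in cig:
                if op == _CIGAR_M:
                    pos += ln
                elif op == _CIGAR_D:
                    if ln != 1:
                        raise ValueError(
                            f"record {a.query_name}: multi-nt deletion unsupported"
                        )
                    dels.append(pos)
                    pos += ln
            seq = a.query_sequence or ""
            if strand == "-":
                seq = revcomp(seq)
            tail = seq[len(seq) - tail_len :] if tail_len else ""
            tag = a.get_tag("XT") if a.has_tag("XT") else ""
            out.append(
                MappedRead(
                    id=a.query_name, contig=a.reference_name, strand=strand,
                    start=a.reference_start, end=pos, deletions=tuple(dels),
                    clipped_tail=tail,
                    random_tag="" if tag == "*" else tag,
                    sample=(a.get_tag("XS") if a.has_tag("XS") else "") or "",
                    adaptor_found=bool(a.get_tag("XF")) if a.has_tag("XF") else False,
                    seq=seq,
                )
            )
    return out
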