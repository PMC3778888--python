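"""Splicing-stage analysis: exon-exon vs intron-exon junction read ratio.

Reads are mapped to two transcript libraries per intron-containing gene
(spliced and unspliced).  A read spanning an exon-exon junction can only map
to the spliced library, one spanning an intron-exon junction only to the
unspliced one, and purely exonic reads map equally well to both and are
discarded as ambiguous by the aligner — so only junction-informative reads
enter the ratio.  A high EE:IE ratio means the factor binds after splicing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .align import align_reads
from .annotation import Annotation
from .readprep import ProcessedRead

SPLICED, UNSPLICED = "sp", "un"


@dataclass
class JunctionEntry:
    gene: str
    spliced_seq: str
    unspliced_seq: str
    ee_junctions: tuple[int, ...]   # spliced-transcript coordinates (first base of next exon)
    ie_junctions: tuple[int, ...]   # unspliced-transcript coordinates (both intron edges)


def build_junction_libraries(annotation: Annotation, genome: dict[str, str]) -> dict[str, JunctionEntry]:
    """Spliced/unspliced sequence pairs with junction coordinates, for every
    intron-containing gene (intronless genes are excluded)."""
    out: dict[str, JunctionEntry] = {}
    for t in annotation:
        if not t.has_introns:
            continue
        exon_lens = [b - a for a, b in t.exons]
        intron_lens = [b - a for a, b in t.introns]
        if t.strand == "-":
            exon_lens = exon_lens[::-1]
            intron_lens = intron_lens[::-1]
        ee, ie = [], []
        sp_pos, un_pos = 0, 0
        for ex, intr in zip(exon_lens, intron_lens):
            sp_pos += ex
            ee.append(sp_pos)
            un_pos += ex
            ie.append(un_pos)            # exon|intron boundary
            un_pos += intr
            ie.append(un_pos)            # intron|exon boundary
        out[t.id] = JunctionEntry(
            t.id,
            t.spliced_sequence(genome),
            t.span_sequence(genome),
            tuple(ee),
            tuple(ie),
        )
    if not out:
        raise ValueError("no intron-containing genes in annotation")
    return out


def _library_genome(libraries: dict[str, JunctionEntry]) -> dict[str, str]:
    contigs = {}
    for g, e in libraries.items():
        contigs[f"{SPLICED}::{g}"] = e.spliced_seq
        contigs[f"{UNSPLICED}::{g}"] = e.unspliced_seq
    return contigs


@dataclass
class SpliceRatio:
    ee: int
    ie: int
    ratio: float       # ee/ie; math.inf when ie == 0 and ee > 0; nan when undefined
    status: str        # "ok" | "infinite" | "undefined"


def ee_ie_ratio(
    reads: list[tuple[str, str]] | list[ProcessedRead],
    libraries: dict[str, JunctionEntry],
    min_overhang: int = 3,
    min_len: int = 18,
    max_mismatch: int = 2,
) -> SpliceRatio:
    """Ratio of reads spanning exon-exon to intron-exon junctions.

    A read spans a junction when it covers at least ``min_overhang`` nt on
    each side.  Reads may be (id, sequence) pairs or ProcessedReads.
    """
    processed = [
        r if isinstance(r, ProcessedRead)
        else ProcessedRead(r[0], "jx", r[1], "I" * len(r[1]), "", "", True)
        for r in reads
    ]
    mapped, _ = align_reads(processed, _library_genome(libraries),
                            min_len=min_len, max_mismatch=max_mismatch)
    ee = ie = 0
    for r in mapped:
        if r.strand != "+":
            continue
        kind, gene = r.contig.split("::", 1)
        entry = libraries[gene]
        junctions = entry.ee_junctions if kind == SPLICED else entry.ie_junctions
        for j in junctions:
            if r.start <= j - min_overhang and r.end >= j + min_overhang:
                if kind == SPLICED:
                    ee += 1
                else:
                    ie += 1
    if ee == 0 and ie == 0:
        return SpliceRatio(0, 0, math.nan, "undefined")
    if ie == 0:
        return SpliceRatio(ee, 0, math.inf, "infinite")
    return SpliceRatio(ee, ie, ee / ie, "ok")
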