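"""Read preprocessing and PCR-duplicate collapse.

Mirrors the standard fastx-style preprocessing of crosslinking libraries:
quality filtering, homopolymer-artifact removal, barcode demultiplexing,
extraction of the random 3 nt tag from the 5' linker, and 3' adaptor clipping.
PCR duplicates are collapsed after mapping on (random tag, strand-aware 5'
genomic coordinate).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from ._util import modal_fraction

UNDETERMINED = "undetermined"


@dataclass
class ProcessedRead:
    id: str
    sample: str
    sequence: str          # insert (+ any non-encoded tail) after clipping
    quality: str
    barcode: str
    random_tag: str
    adaptor_found: bool


def validate_barcodes(barcode_table: dict[str, str]) -> None:
    codes = sorted(barcode_table)
    for i, a in enumerate(codes):
        for b in codes[i + 1 :]:
            if b.startswith(a) or a.startswith(b):
                raise ValueError(f"barcode collision: {a!r} is a prefix of {b!r}")


def preprocess(
    reads: Iterable[tuple[str, str, str]],
    adaptor: str,
    barcode_table: dict[str, str],
    tag_length: int = 3,
    quality_min: int = 20,
    artifact_modal_fraction: float = 0.9,
    min_adaptor_overlap: int = 6,
) -> tuple[dict[str, list[ProcessedRead]], dict]:
    """Partition raw reads by barcode, returning per-sample streams and a report.

    A read is dropped if any base quality is below ``quality_min`` (high
    quality throughout) or if one base occupies more than
    ``artifact_modal_fraction`` of the raw read (homopolymer artifact).  The 3'
    adaptor is clipped where found, either in full or as a terminal prefix of
    at least ``min_adaptor_overlap`` nt; ``adaptor_found`` records the outcome,
    since tail and motif analyses only trust reads whose 3' end was observed.
    """
    validate_barcodes(barcode_table)
    streams: dict[str, list[ProcessedRead]] = {s: [] for s in barcode_table.values()}
    streams[UNDETERMINED] = []
    report = Counter()

    for rid, seq, qual in reads:
        report["total"] += 1
        if any(ord(q) - 33 < quality_min for q in qual):
            report["low_quality"] += 1
            continue
        if modal_fraction(seq) > artifact_modal_fraction:
            report["artifact"] += 1
            continue
        sample, barcode = UNDETERMINED, ""
        for bc, name in barcode_table.items():
            if seq.startswith(bc):
                sample, barcode = name, bc
                break
        if sample == UNDETERMINED:
            report[UNDETERMINED] += 1
            streams[UNDETERMINED].append(
                ProcessedRead(rid, UNDETERMINED, seq, qual, "", "", False)
            )
            continue
        body = seq[len(barcode) :]
        tag, body = body[:tag_length], body[tag_length:]
        qbody = qual[len(barcode) + tag_length :]

        idx = body.find(adaptor)
        found = idx >= 0
        if found:
            body, qbody = body[:idx], qbody[:idx]
        else:
            # a terminal adaptor prefix is still clipped; only an overlap of
            # >= min_adaptor_overlap nt counts as a confident detection
            for k in range(min(len(adaptor) - 1, len(body)), 0, -1):
                if body.endswith(adaptor[:k]):
                    body, qbody = body[:-k], qbody[:-k]
                    found = k >= min_adaptor_overlap
                    break
        report[f"sample:{sample}"] += 1
        streams[sample].append(
            ProcessedRead(rid, sample, body, qbody, barcode, tag, found)
        )
    return streams, dict(report)


def collapse_identical(processed: list[ProcessedRead]) -> list[ProcessedRead]:
    """Pre-mapping collapse of byte-identical (tag, sequence) reads."""
    seen: dict[tuple[str, str], ProcessedRead] = {}
    for r in processed:
        seen.setdefault((r.random_tag, r.sequence), r)
    return list(seen.values())


def collapse_duplicates(mapped: list) -> tuple[list, dict]:
    """Post-mapping PCR-duplicate collapse.

    One representative is kept per (sample, random tag, strand-aware 5'
    genomic coordinate) group: the longest-aligned member, ties broken by
    lexicographically smallest read sequence.  Reads lacking a random tag are
    counted and passed through unchanged.
    """
    groups: dict[tuple, list] = {}
    passthrough = []
    for r in mapped:
        if not r.random_tag:
            passthrough.append(r)
            continue
        five = r.start if r.strand == "+" else r.end - 1
        groups.setdefault((r.sample, r.random_tag, r.contig, r.strand, five), []).append(r)
    out = [
        min(members, key=lambda r: (-(r.end - r.start), r.seq, r.id))
        for members in groups.values()
    ]
    out.sort(key=lambda r: r.id)
    report = {
        "in": len(mapped),
        "out": len(out) + len(passthrough),
        "untagged_passthrough": len(passthrough),
    }
    if passthrough:
        import warnings

        warnings.warn(f"{len(passthrough)} mapped reads lack a random tag; passed through")
    return out + passthrough, report
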