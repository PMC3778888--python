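"""Poly(A)-site calling from A-tailed reads and flanking-sequence profiling.

The last genome-encoded nucleotide of an accepted A-tailed read defines a
candidate poly(A) (pA) site.  Low-complexity reads (genome-encoded portion
with fewer than 8 nonmodal nucleotides) are excluded to avoid A-rich
mismapping, as are reads whose 5' end lies within 200 nt of the assigned
gene's TSS (likely upstream transcripts).  Per gene, the most frequently
observed coordinate is the major pA site.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import nonmodal_count, revcomp
from .annotation import Annotation, Transcript
from .tails import ATailCall


@dataclass
class PASite:
    gene: str
    coord: int             # genomic coordinate of the last encoded nucleotide
    count: int
    is_major: bool = False


def _encoded_sequence(r, genome: dict[str, str]) -> str:
    s = genome[r.contig][r.start : r.end]
    return s if r.strand == "+" else revcomp(s)


def assign_gene(r, annotation: Annotation, three_flank: int = 300) -> Transcript | None:
    """Gene whose span (extended by a 3' flank on every class) contains the
    read; ties go to the gene with the nearest annotated 3' end."""
    classes = tuple({t.class_label for t in annotation})
    hits = annotation.overlapping(
        r.contig, r.strand, r.start, r.end,
        five_flank=0, three_flank=three_flank, flank_classes=classes,
    )
    if not hits:
        return None
    read3 = r.end - 1 if r.strand == "+" else r.start
    return min(hits, key=lambda t: (abs(t.end3 - read3), t.id))


def call_pa_sites(
    calls: list[ATailCall],
    mapped,
    annotation: Annotation,
    genome: dict[str, str],
    min_nonmodal: int = 8,
    tss_exclusion: int = 200,
    classes: tuple[str, ...] = ("mRNA", "SUT"),
) -> tuple[list[PASite], dict]:
    """Aggregate accepted A-tail calls into per-gene pA sites.

    Returns (sites, report); the report counts reads excluded by each filter
    and orphans not assignable to any gene.  The two filters commute, so their
    order is immaterial.
    """
    by_id = {r.id: r for r in mapped}
    per_gene: dict[str, Counter] = {}
    report = Counter()
    for c in calls:
        if not c.accepted or c.read_id not in by_id:
            continue
        r = by_id[c.read_id]
        if nonmodal_count(_encoded_sequence(r, genome)) < min_nonmodal:
            report["low_complexity"] += 1
            continue
        gene = assign_gene(r, annotation)
        if gene is None or gene.class_label not in classes:
            report["orphan"] += 1
            continue
        five_oriented = gene.to_oriented(r.five_prime)
        if 0 <= five_oriented < tss_exclusion:
            report["tss_proximal"] += 1
            continue
        per_gene.setdefault(gene.id, Counter())[c.last_encoded] += 1
        report["used"] += 1

    sites: list[PASite] = []
    for gene_id, counter in sorted(per_gene.items()):
        gene = annotation.by_id[gene_id]
        gene_sites = [PASite(gene_id, coord, n) for coord, n in sorted(counter.items())]
        major = major_site(gene_sites, gene.strand)
        for s in gene_sites:
            s.is_major = s is major
        sites.extend(gene_sites)
    return sites, dict(report)


def major_site(sites: list[PASite], strand: str) -> PASite:
    """Most frequently observed site; ties broken toward the 3'-most (distal)
    coordinate in transcript orientation."""
    if not sites:
        raise ValueError("no sites")
    direction = 1 if strand == "+" else -1
    return max(sites, key=lambda s: (s.count, direction * s.coord))


def write_pa_bed(sites: list[PASite], annotation: Annotation, path: str) -> None:
    with open(path, "w") as fh:
        for s in sites:
            t = annotation.by_id[s.gene]
            name = f"{s.gene}{':major' if s.is_major else ''}"
            fh.write(f"{t.contig}\t{s.coord}\t{s.coord + 1}\t{name}\t{s.count}\t{t.strand}\n")


def pa_flank_profiles(
    sites: list[PASite],
    annotation: Annotation,
    genome: dict[str, str],
    window: tuple[int, int] = (-200, 101),
    motifs: tuple[str, ...] = ("TATATA", "AATAAA"),
    major_only: bool = True,
):
    """Nucleotide frequencies and motif-occurrence profiles around pA sites.

    Offset 0 is the last encoded nucleotide; sequences are taken in transcript
    orientation (motifs given in DNA sense, U->T).  Returns (freq, motif_profiles,
    n_used, n_skipped): ``freq`` rows (one per offset) each sum to 1;
    ``motif_profiles[m][o]`` is the fraction of sites whose flank carries
    motif m starting at offset o.  Sites whose window leaves the contig are
    skipped.
    """
    lo, hi = window
    width = hi - lo
    chosen = [s for s in sites if s.is_major or not major_only]
    rows = []
    for s in chosen:
        t = annotation.by_id[s.gene]
        L = len(genome[t.contig])
        if t.strand == "+":
            a, b = s.coord + lo, s.coord + hi
            if a < 0 or b > L:
                continue
            rows.append(genome[t.contig][a:b])
        else:
            a, b = s.coord - hi + 1, s.coord - lo + 1
            if a < 0 or b > L:
                continue
            rows.append(revcomp(genome[t.contig][a:b]))
    if not rows:
        raise ValueError("no sites with full flanking sequence")
    arr = np.array([list(r) for r in rows])
    offsets = np.arange(lo, hi)
    freq = pd.DataFrame(
        {b: (arr == b).mean(axis=0) for b in "ACGT"}, index=offsets
    )
    profiles = {}
    for m in motifs:
        k = len(m)
        occ = np.zeros(width)
        for r in rows:
            for o in range(width - k + 1):
                if r[o : o + k] == m:
                    occ[o] += 1
        profiles[m] = pd.Series(occ / len(rows), index=offsets)
    return freq, profiles, len(rows), len(chosen) - len(rows)
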