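"""Transcript annotation container with GTF/BED interchange and strand-aware overlap.

Coordinates are 0-based half-open internally; GTF conversion (1-based inclusive)
happens only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from ._util import revcomp

#: transcript classes, in the single-assignment precedence order used for
#: class breakdowns (a read is attributed to the highest-precedence class it overlaps)
CLASS_PRECEDENCE = (
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "mRNA",
    "CUT",
    "SUT",
    "XUT",
)

LNCRNA_CLASSES = ("CUT", "SUT", "XUT")


@dataclass
class Transcript:
    """One annotated feature: genomic exon structure plus 3'-end metadata.

    ``pa_sites`` holds (genomic coordinate of last encoded nucleotide, usage weight)
    pairs; ``efficiency_element`` is the genomic start of a planted UAUAUA element
    when the generator placed one.
    """

    id: str
    class_label: str
    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    pa_sites: tuple[tuple[int, float], ...] = ()
    efficiency_element: int | None = None

    def __post_init__(self) -> None:
        ex = tuple(sorted((int(a), int(b)) for a, b in self.exons))
        for (a, b), (c, d) in zip(ex, ex[1:]):
            if c < b:
                raise ValueError(f"overlapping exons in {self.id}")
        object.__setattr__(self, "exons", ex)

    # --- span geometry -------------------------------------------------
    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        """Unspliced (genomic span) length."""
        return self.end - self.start

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def end3(self) -> int:
        """Genomic coordinate of the annotated last transcribed nucleotide."""
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def has_introns(self) -> bool:
        return len(self.exons) > 1

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple((a[1], b[0]) for a, b in zip(self.exons, self.exons[1:]))

    @property
    def major_pa_site(self) -> int:
        if self.pa_sites:
            return max(self.pa_sites, key=lambda cw: cw[1])[0]
        return self.end3

    # --- coordinate transforms ----------------------------------------
    def to_oriented(self, genomic_pos: int) -> int:
        """Genomic coordinate -> 5'->3' offset within the unspliced span."""
        if self.strand == "+":
            return genomic_pos - self.start
        return self.end - 1 - genomic_pos

    def to_genomic(self, oriented_pos: int) -> int:
        if self.strand == "+":
            return self.start + oriented_pos
        return self.end - 1 - oriented_pos

    # --- sequences -----------------------------------------------------
    def span_sequence(self, genome: dict[str, str]) -> str:
        """Unspliced transcript sequence, 5'->3'."""
        s = genome[self.contig][self.start : self.end]
        return s if self.strand == "+" else revcomp(s)

    def spliced_sequence(self, genome: dict[str, str]) -> str:
        parts = [genome[self.contig][a:b] for a, b in self.exons]
        s = "".join(parts)
        return s if self.strand == "+" else revcomp(s)


class Annotation:
    """Ordered set of transcripts with strand-aware interval lookup."""

    def __init__(self, transcripts: Iterable[Transcript]):
        self.transcripts: list[Transcript] = list(transcripts)
        self.by_id = {t.id: t for t in self.transcripts}
        if len(self.by_id) != len(self.transcripts):
            raise ValueError("duplicate transcript ids")
        self._trees: dict[tuple[str, str, int, int], dict] = {}

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts)

    def of_class(self, *labels: str) -> list[Transcript]:
        return [t for t in self.transcripts if t.class_label in labels]

    # --- extended spans ------------------------------------------------
    def extended_span(self, t: Transcript, five_flank: int = 50, three_flank: int = 300,
                      flank_classes: Sequence[str] = ("mRNA",)) -> tuple[int, int]:
        """Feature span extended by flanks (applied to ``flank_classes`` only),
        truncated at the nearest same-strand neighbour."""
        lo, hi = t.start, t.end
        if t.class_label in flank_classes:
            up, down = (five_flank, three_flank) if t.strand == "+" else (three_flank, five_flank)
            lo, hi = lo - up, hi + down
            for other in self.transcripts:
                if other.id == t.id or other.contig != t.contig or other.strand != t.strand:
                    continue
                if other.end <= t.start:
                    lo = max(lo, other.end)
                if other.start >= t.end:
                    hi = min(hi, other.start)
            lo = max(lo, 0)
        return lo, hi

    def _tree(self, contig: str, strand: str, five_flank: int, three_flank: int,
              flank_classes: Sequence[str] = ("mRNA",)) -> IntervalTree:
        key = (contig, strand, five_flank, three_flank, tuple(flank_classes))
        cached = self._trees.get(key)
        if cached is not None:
            return cached
        tree = IntervalTree()
        for t in self.transcripts:
            if t.contig != contig or t.strand != strand:
                continue
            lo, hi = self.extended_span(t, five_flank, three_flank, flank_classes)
            if hi > lo:
                tree[lo:hi] = t
        self._trees[key] = tree
        return tree

    def overlapping(self, contig: str, strand: str, start: int, end: int,
                    five_flank: int = 0, three_flank: int = 0,
                    flank_classes: Sequence[str] = ("mRNA",)) -> list[Transcript]:
        """Same-strand transcripts whose (optionally flank-extended) span overlaps
        [start, end) by at least one nucleotide."""
        tree = self._tree(contig, strand, five_flank, three_flank, flank_classes)
        return [iv.data for iv in tree.overlap(start, end)]

    def assign(self, contig: str, strand: str, start: int, end: int,
               five_flank: int = 0, three_flank: int = 0) -> Transcript | None:
        """Single-assignment by class precedence (ties within a class -> smaller id)."""
        hits = self.overlapping(contig, strand, start, end, five_flank, three_flank)
        if not hits:
            return None
        rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
        return min(hits, key=lambda t: (rank.get(t.class_label, len(rank)), t.id))

    # --- GTF / BED interchange -----------------------------------------
    def write_gtf(self, path: str) -> None:
        with open(path, "w") as fh:
            for t in self.transcripts:
                attrs = (
                    f'gene_id "{t.id}"; transcript_id "{t.id}"; '
                    f'transcript_biotype "{t.class_label}";'
                )
                if t.pa_sites:
                    pa = ",".join(f"{c}:{w:g}" for c, w in t.pa_sites)
                    attrs += f' pa_sites "{pa}";'
                if t.efficiency_element is not None:
                    attrs += f' efficiency_element "{t.efficiency_element}";'
                fh.write(
                    f"{t.contig}\tcrac_atlas\ttranscript\t{t.start + 1}\t{t.end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
                for a, b in t.exons:
                    fh.write(
                        f"{t.contig}\tcrac_atlas\texon\t{a + 1}\t{b}\t.\t{t.strand}\t.\t{attrs}\n"
                    )

    @classmethod
    def read_gtf(cls, path: str) -> "Annotation":
        import gffutils

        db = gffutils.create_db(
            path, ":memory:", force=True, keep_order=True,
            disable_infer_genes=True, disable_infer_transcripts=True,
        )
        out = []
        for f in db.features_of_type("transcript"):
            exons = [
                (e.start - 1, e.end)
                for e in db.children(f, featuretype="exon", order_by="start")
            ]
            if not exons:
                exons = [(f.start - 1, f.end)]
            pa = ()
            if "pa_sites" in f.attributes:
                # gffutils may split the comma-separated value into a list
                joined = ",".join(f.attributes["pa_sites"])
                pa = tuple(
                    (int(p.split(":")[0]), float(p.split(":")[1]))
                    for p in joined.split(",")
                )
            ee = None
            if "efficiency_element" in f.attributes:
                ee = int(f.attributes["efficiency_element"][0])
            out.append(
                Transcript(
                    id=f.attributes["transcript_id"][0],
                    class_label=f.attributes["transcript_biotype"][0],
                    contig=f.seqid,
                    strand=f.strand,
                    exons=tuple(exons),
                    pa_sites=pa,
                    efficiency_element=ee,
                )
            )
        return cls(out)

    def write_class_bed(self, path: str, classes: Sequence[str] = LNCRNA_CLASSES) -> None:
        """BED6 table of the lncRNA classes (name=id, score=0, class in column 7)."""
        with open(path, "w") as fh:
            for t in self.transcripts:
                if t.class_label in classes:
                    fh.write(
                        f"{t.contig}\t{t.start}\t{t.end}\t{t.id}\t0\t{t.strand}\t{t.class_label}\n"
                    )
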