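"""Per-dataset hit tables over annotated features, normalization and comparison.

A "hit" is a deduplicated mapped read.  Hit tables count a read toward every
same-strand feature whose (flank-extended, for mRNAs) span it overlaps;
class breakdowns instead assign each read once, by class precedence, so the
proportions partition the library.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Annotation, CLASS_PRECEDENCE

#: normalization denominators: hits per million hits in these transcript classes
DENOMINATORS = {
    "polII_all": ("mRNA", "CUT", "SUT", "snRNA", "snoRNA"),
    "mcs": ("mRNA", "CUT", "SUT"),
}


@dataclass
class HitTable:
    dataset: str
    table: pd.DataFrame       # index: feature id; columns: class, raw, hpm
    denominator: str | None = None

    def raw(self, feature: str) -> int:
        return int(self.table.loc[feature, "raw"])

    def hpm(self, feature: str) -> float:
        return float(self.table.loc[feature, "hpm"])


def count_hits(
    mapped,
    annotation: Annotation,
    dataset: str = "sample",
    five_flank: int = 50,
    three_flank: int = 300,
) -> HitTable:
    """Raw per-feature hit counts (multi-overlap counting; hpm left unset).

    Flanks apply to mRNAs only and are truncated at neighbouring same-strand
    features, catching hits just outside misannotated ends.
    """
    contigs_ann = {t.contig for t in annotation}
    contigs_reads = {r.contig for r in mapped}
    missing = contigs_reads - contigs_ann
    counts = Counter()
    for r in mapped:
        if r.contig in missing:
            raise ValueError(f"reads on contigs absent from annotation: {sorted(missing)}")
        for t in annotation.overlapping(
            r.contig, r.strand, r.start, r.end, five_flank, three_flank
        ):
            counts[t.id] += 1
    rows = {
        t.id: {"class": t.class_label, "raw": counts.get(t.id, 0), "hpm": np.nan}
        for t in annotation
    }
    return HitTable(dataset, pd.DataFrame.from_dict(rows, orient="index"))


def normalize_hpm(ht: HitTable, denominator: str = "polII_all") -> HitTable:
    """Populate hits-per-million using the given denominator class set."""
    classes = DENOMINATORS[denominator]
    total = ht.table.loc[ht.table["class"].isin(classes), "raw"].sum()
    if total <= 0:
        raise ValueError(f"zero hits in denominator set {denominator}")
    table = ht.table.copy()
    table["hpm"] = table["raw"] * 1e6 / total
    return replace(ht, table=table, denominator=denominator)


def replicate_correlation(a: HitTable, b: HitTable) -> float:
    """Spearman rank correlation over features detected (raw >= 1) in both tables."""
    shared = a.table.index.intersection(b.table.index)
    ra, rb = a.table.loc[shared, "raw"], b.table.loc[shared, "raw"]
    keep = (ra >= 1) & (rb >= 1)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 shared detected features")
    rho, _ = stats.spearmanr(ra[keep], rb[keep])
    return float(rho)


def class_breakdown(mapped, annotation: Annotation,
                    five_flank: int = 0, three_flank: int = 0) -> pd.Series:
    """Proportion of reads per transcript class (single assignment by
    precedence; unassigned reads fall into 'intergenic').  Sums to 1."""
    if not mapped:
        raise ValueError("no mapped reads")
    counts = Counter()
    for r in mapped:
        t = annotation.assign(r.contig, r.strand, r.start, r.end, five_flank, three_flank)
        counts[t.class_label if t else "intergenic"] += 1
    order = [c for c in (*CLASS_PRECEDENCE, "intergenic") if counts.get(c)]
    s = pd.Series({c: counts[c] for c in order}, dtype=float)
    return s / s.sum()
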