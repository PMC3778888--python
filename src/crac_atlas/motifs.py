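"""k-mer enrichment, motif-anchored distributions, binding-site motif
fractions, and CNN-repeat censuses.

The k-mer Z score compares observed occurrences within genome-encoded read
sequences to a randomization null in which each read is replaced by an
equal-length interval placed uniformly within its source transcript — so the
null carries the sequence composition of the transcripts the hits map to.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import nonmodal_count, revcomp
from .annotation import Annotation, Transcript
from .profiles import coverage_tracks, deletion_tracks


def _encoded(r, genome) -> str:
    s = genome[r.contig][r.start : r.end]
    return s if r.strand == "+" else revcomp(s)


def count_kmers(seq: str, k: int, into: Counter | None = None) -> Counter:
    c = into if into is not None else Counter()
    for i in range(len(seq) - k + 1):
        c[seq[i : i + k]] += 1
    return c


def eligible_reads(mapped, annotation: Annotation, genome, min_nonmodal: int = 7):
    """Reads usable for motif work: 3' adaptor detected, genome-encoded portion
    not low-complexity (e.g. ``GTCCGAAAAAAAAA`` has 5 nonmodal nt and is
    excluded), and assignable to a transcript."""
    out = []
    for r in mapped:
        if not r.adaptor_found:
            continue
        enc = _encoded(r, genome)
        if nonmodal_count(enc) < min_nonmodal:
            continue
        t = annotation.assign(r.contig, r.strand, r.start, r.end)
        if t is None:
            continue
        out.append((r, t, enc))
    return out


def kmer_zscores(
    mapped,
    annotation: Annotation,
    genome: dict[str, str],
    k: int,
    n_randomizations: int = 100,
    seed: int = 0,
    min_nonmodal: int = 7,
) -> pd.DataFrame:
    """Overrepresentation Z score per k-mer.

    Z = (observed - null mean) / null sd over ``n_randomizations`` uniform
    re-placements of each read within its source transcript.  sd = 0 with
    observed == mean gives Z = 0; sd = 0 otherwise gives an infinite sentinel.
    """
    if not 1 <= k <= 12:
        raise ValueError("k out of range")
    rng = np.random.default_rng(seed)
    reads = eligible_reads(mapped, annotation, genome, min_nonmodal)
    if not reads:
        raise ValueError("no eligible reads")
    observed = Counter()
    for _, _, enc in reads:
        count_kmers(enc, k, observed)

    tseqs = {t.id: t.span_sequence(genome) for _, t, _ in reads}
    placements = []  # (transcript seq, read length)
    for r, t, enc in reads:
        placements.append((tseqs[t.id], len(enc)))

    kmers = sorted(observed)
    kindex = {m: i for i, m in enumerate(kmers)}
    null = np.zeros((n_randomizations, len(kmers)))
    for it in range(n_randomizations):
        acc = Counter()
        for seq, ln in placements:
            hi = len(seq) - ln
            s = int(rng.integers(0, hi + 1)) if hi > 0 else 0
            count_kmers(seq[s : s + ln], k, acc)
        for m, n in acc.items():
            j = kindex.get(m)
            if j is not None:
                null[it, j] = n

    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    obs = np.array([observed[m] for m in kmers], float)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (obs - mean) / sd
    z[(sd == 0) & (obs == mean)] = 0.0
    z[(sd == 0) & (obs != mean)] = np.inf
    df = pd.DataFrame(
        {"kmer": kmers, "observed": obs, "mean": mean, "sd": sd, "z": z}
    ).sort_values("z", ascending=False, kind="mergesort")
    df["rank"] = np.arange(1, len(df) + 1)
    return df.reset_index(drop=True)


def motif_anchored_profile(
    mapped,
    annotation: Annotation,
    genome: dict[str, str],
    motif: str,
    contig_lengths: dict[str, int],
    window: tuple[int, int] = (-100, 101),
    track: str = "hits",
):
    """Summed per-offset counts around every transcriptomic occurrence of a motif.

    Offset 0 is the first motif base, orientation is the transcript's;
    ``track`` selects read coverage ("hits") or single-nt deletion positions
    ("deletions").  Returns (profile, offsets).
    """
    if not motif:
        raise ValueError("empty motif")
    maker = coverage_tracks if track == "hits" else deletion_tracks
    tracks = maker(mapped, contig_lengths)
    lo, hi = window
    acc = np.zeros(hi - lo)
    n_occ = 0
    for t in annotation:
        seq = t.span_sequence(genome)
        i = seq.find(motif)
        while i != -1:
            n_occ += 1
            tr = tracks[(t.contig, t.strand)]
            for oi, off in enumerate(range(lo, hi)):
                g = t.to_genomic(i + off)
                if 0 <= g < len(tr):
                    acc[oi] += tr[g]
            i = seq.find(motif, i + 1)
    if n_occ == 0:
        warnings.warn(f"motif {motif} absent from the transcriptome")
    return acc, np.arange(lo, hi)


@dataclass
class BindingSite:
    contig: str
    strand: str
    start: int
    end: int
    support: int
    transcript: str | None = None
    region: str | None = None


def binding_sites(mapped, annotation: Annotation, min_reads: int = 5,
                  three_flank: int = 300) -> list[BindingSite]:
    """Maximal runs of overlapping deduplicated reads with >= min_reads support,
    assigned to a host transcript and labelled 3'-terminal when the site
    midpoint falls in the last quarter of the transcript's extended span."""
    by_key: dict[tuple[str, str], list] = {}
    for r in mapped:
        by_key.setdefault((r.contig, r.strand), []).append((r.start, r.end))
    sites: list[BindingSite] = []
    for (c, s), ivs in sorted(by_key.items()):
        ivs.sort()
        cur_s, cur_e, n = ivs[0][0], ivs[0][1], 1
        for a, b in ivs[1:]:
            if a < cur_e:
                cur_e, n = max(cur_e, b), n + 1
            else:
                sites.append(BindingSite(c, s, cur_s, cur_e, n))
                cur_s, cur_e, n = a, b, 1
        sites.append(BindingSite(c, s, cur_s, cur_e, n))
    sites = [x for x in sites if x.support >= min_reads]
    classes = tuple({t.class_label for t in annotation})
    for x in sites:
        mid = (x.start + x.end) // 2
        hits = annotation.overlapping(x.contig, x.strand, mid, mid + 1,
                                      three_flank=three_flank, flank_classes=classes)
        if not hits:
            continue
        t = min(hits, key=lambda tt: tt.id)
        x.transcript = t.id
        lo, hi = annotation.extended_span(t, 0, three_flank, classes)
        opos = (mid - lo) if t.strand == "+" else (hi - 1 - mid)
        x.region = "three_prime" if opos >= 0.75 * (hi - lo) else "body"
    return sites


def site_motif_fraction(
    sites: list[BindingSite],
    genome: dict[str, str],
    motif: str,
    region: str | None = None,
    transcript_classes: tuple[str, ...] | None = None,
    annotation: Annotation | None = None,
):
    """Fraction of binding sites containing the motif; returns (fraction, n)
    with fraction None when no site passes the filters."""
    if not motif:
        raise ValueError("empty motif")
    chosen = []
    for x in sites:
        if region is not None and x.region != region:
            continue
        if transcript_classes is not None:
            if x.transcript is None or annotation is None:
                continue
            if annotation.by_id[x.transcript].class_label not in transcript_classes:
                continue
        chosen.append(x)
    if not chosen:
        return None, 0
    n_with = 0
    for x in chosen:
        s = genome[x.contig][x.start : x.end]
        if x.strand == "-":
            s = revcomp(s)
        if motif in s:
            n_with += 1
    return n_with / len(chosen), len(chosen)


def longest_cnn_repeat(seq: str) -> int:
    """Longest n with C at positions i, i+3, ..., i+3(n-1), any frame."""
    best = 0
    n = len(seq)
    run = [0] * (n + 3)
    for i in range(n - 1, -1, -1):
        if seq[i] == "C":
            run[i] = 1 + (run[i + 3] if i + 3 < n else 0)
            if run[i] > best:
                best = run[i]
    return best


def cnn_repeat_census(annotation: Annotation, genome: dict[str, str]) -> pd.DataFrame:
    """Per transcript class, the proportion of transcripts whose longest
    (CNN)_n repeat is n, as a class x n table (rows sum to 1)."""
    per_class: dict[str, Counter] = {}
    for t in annotation:
        n = longest_cnn_repeat(t.span_sequence(genome))
        per_class.setdefault(t.class_label, Counter())[n] += 1
    max_n = max((max(c) for c in per_class.values()), default=0)
    rows = {}
    for cls, counter in sorted(per_class.items()):
        total = sum(counter.values())
        rows[cls] = [counter.get(n, 0) / total for n in range(max_n + 1)]
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(max_n + 1))
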