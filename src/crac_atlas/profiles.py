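"""Positional binding summaries.

Per-nucleotide coverage, 120-bin length-scaled metagene profiles (10 bins per
100 nt flank + 100 body bins, each transcript normalized to sum 100 so every
transcript contributes equally), TSS-aligned length-sorted heatmaps, and
window-anchored average distributions.  All operations accept any read subset,
so tail-stratified or deletion-bearing profiles come for free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .annotation import Annotation, Transcript


def coverage_tracks(mapped, contig_lengths: dict[str, int]) -> dict[tuple[str, str], np.ndarray]:
    """Per-(contig, strand) hit coverage; a read adds 1 to every aligned
    position, deletions excluded."""
    tracks = {
        (c, s): np.zeros(n, dtype=np.int64)
        for c, n in contig_lengths.items() for s in "+-"
    }
    for r in mapped:
        tr = tracks[(r.contig, r.strand)]
        tr[r.start : r.end] += 1
        for d in r.deletions:
            tr[d] -= 1
    return tracks


def deletion_tracks(mapped, contig_lengths: dict[str, int]) -> dict[tuple[str, str], np.ndarray]:
    tracks = {
        (c, s): np.zeros(n, dtype=np.int64)
        for c, n in contig_lengths.items() for s in "+-"
    }
    for r in mapped:
        for d in r.deletions:
            tracks[(r.contig, r.strand)][d] += 1
    return tracks


def coverage(mapped, contig: str, start: int, end: int, strand: str,
             contig_lengths: dict[str, int]) -> np.ndarray:
    """Hit counts for each nucleotide of [start, end) on one strand."""
    if contig not in contig_lengths or start < 0 or end > contig_lengths[contig]:
        raise ValueError(f"region {contig}:{start}-{end} outside contig")
    out = np.zeros(end - start, dtype=np.int64)
    for r in mapped:
        if r.contig != contig or r.strand != strand:
            continue
        lo, hi = max(start, r.start), min(end, r.end)
        if hi > lo:
            out[lo - start : hi - start] += 1
        for d in r.deletions:
            if start <= d < end:
                out[d - start] -= 1
    return out


def _oriented_window(track: np.ndarray, t: Transcript, flank: int) -> np.ndarray | None:
    lo, hi = t.start - flank, t.end + flank
    if lo < 0 or hi > len(track):
        return None
    win = track[lo:hi].astype(float)
    return win if t.strand == "+" else win[::-1]


def rank_transcripts(mapped, annotation: Annotation, top_n: int) -> list[Transcript]:
    """Transcripts ranked by raw hit count (desc), ties by id; zero-hit dropped."""
    from .annot_hits import count_hits

    ht = count_hits(mapped, annotation, five_flank=0, three_flank=0)
    raw = ht.table["raw"]
    ranked = sorted(annotation, key=lambda t: (-raw[t.id], t.id))
    return [t for t in ranked if raw[t.id] > 0][:top_n]


@dataclass
class MetageneProfile:
    dataset: str
    values: np.ndarray            # 120 bins; flanks are bins 0-9 and 110-119
    n_transcripts: int
    per_transcript: np.ndarray | None = None

    @property
    def argmax_bin(self) -> int:
        return int(np.argmax(self.values))


def metagene(
    mapped,
    annotation: Annotation,
    contig_lengths: dict[str, int],
    top_n: int = 1000,
    flank: int = 100,
    body_bins: int = 100,
    flank_bins: int = 10,
    transcripts: list[Transcript] | None = None,
    dataset: str = "sample",
    keep_matrix: bool = False,
) -> MetageneProfile:
    """Average 120-bin binding profile over the most abundantly bound transcripts.

    Per transcript: per-nucleotide hits are divided by bin length to give
    densities, the 120 densities are scaled to sum to 100, then profiles are
    averaged unweighted.  Transcripts shorter than ``body_bins`` nt (bins
    under 1 nt) or with flanks running off the contig are skipped.
    """
    tracks = coverage_tracks(mapped, contig_lengths)
    if transcripts is None:
        transcripts = rank_transcripts(mapped, annotation, top_n)
    nbins = 2 * flank_bins + body_bins
    profiles = []
    for t in transcripts:
        if t.length < body_bins:
            warnings.warn(f"{t.id}: shorter than {body_bins} nt, skipped")
            continue
        win = _oriented_window(tracks[(t.contig, t.strand)], t, flank)
        if win is None:
            continue
        L = t.length
        vals = np.zeros(nbins)
        up, body, down = win[:flank], win[flank : flank + L], win[flank + L :]
        fb_len = flank / flank_bins
        np.add.at(vals, (np.arange(flank) / fb_len).astype(int), up)
        vals[:flank_bins] /= fb_len
        body_idx = flank_bins + (np.arange(L) * body_bins // L)
        np.add.at(vals, body_idx, body)
        vals[flank_bins : flank_bins + body_bins] /= L / body_bins
        down_idx = flank_bins + body_bins + (np.arange(flank) / fb_len).astype(int)
        np.add.at(vals, down_idx, down)
        vals[flank_bins + body_bins :] /= fb_len
        total = vals.sum()
        if total <= 0:
            continue
        profiles.append(vals * (100.0 / total))
    if not profiles:
        raise ValueError("no usable transcripts with hits")
    mat = np.vstack(profiles)
    return MetageneProfile(
        dataset, mat.mean(axis=0), len(profiles), mat if keep_matrix else None
    )


def tss_heatmap(
    mapped,
    annotation: Annotation,
    contig_lengths: dict[str, int],
    n: int = 1000,
    transcripts: list[Transcript] | None = None,
):
    """TSS-aligned, length-sorted, per-row max-scaled coverage matrix.

    Returns (matrix, transcript ids, lengths); rows are in increasing length
    order, columns are absolute positions from the TSS; all-zero transcripts
    stay all-zero.
    """
    tracks = coverage_tracks(mapped, contig_lengths)
    if transcripts is None:
        transcripts = rank_transcripts(mapped, annotation, n)
    chosen = sorted(transcripts, key=lambda t: (t.length, t.id))
    if not chosen:
        raise ValueError("no transcripts")
    width = max(t.length for t in chosen)
    mat = np.zeros((len(chosen), width))
    for i, t in enumerate(chosen):
        win = _oriented_window(tracks[(t.contig, t.strand)], t, 0)
        if win is None:
            continue
        peak = win.max()
        mat[i, : t.length] = win / peak if peak > 0 else win
    return mat, [t.id for t in chosen], [t.length for t in chosen]


def flatten_reads(mapped):
    """Merge overlapping reads into maximal single-weight contigs per
    (contig, strand), removing abundance bias."""
    from .align import MappedRead

    by_key: dict[tuple[str, str], list] = {}
    for r in mapped:
        by_key.setdefault((r.contig, r.strand), []).append((r.start, r.end))
    out = []
    i = 0
    for (c, s), ivs in sorted(by_key.items()):
        ivs.sort()
        cur_s, cur_e = ivs[0]
        for a, b in ivs[1:]:
            if a <= cur_e:
                cur_e = max(cur_e, b)
            else:
                out.append(MappedRead(f"flat:{i}", c, s, cur_s, cur_e, (), ""))
                i += 1
                cur_s, cur_e = a, b
        out.append(MappedRead(f"flat:{i}", c, s, cur_s, cur_e, (), ""))
        i += 1
    return out


def anchored_average(
    mapped,
    anchors: list[tuple[str, int, str]],
    contig_lengths: dict[str, int],
    window: tuple[int, int] = (-300, 301),
    flatten: bool = False,
):
    """Strand-oriented mean coverage around anchor positions.

    ``window`` is a half-open offset range; anchors whose window leaves the
    contig are skipped (their count is returned).  With ``flatten``,
    overlapping reads are first merged into single contigs.
    """
    reads = flatten_reads(mapped) if flatten else mapped
    tracks = coverage_tracks(reads, contig_lengths)
    lo, hi = window
    acc = np.zeros(hi - lo)
    used = skipped = 0
    for contig, pos, strand in anchors:
        L = contig_lengths.get(contig)
        if L is None:
            skipped += 1
            continue
        if strand == "+":
            a, b = pos + lo, pos + hi
            if a < 0 or b > L:
                skipped += 1
                continue
            acc += tracks[(contig, strand)][a:b]
        else:
            a, b = pos - hi + 1, pos - lo + 1
            if a < 0 or b > L:
                skipped += 1
                continue
            acc += tracks[(contig, strand)][a:b][::-1]
        used += 1
    if used == 0:
        raise ValueError("no usable anchors")
    return acc / used, np.arange(lo, hi), skipped
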