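"""Synthetic CRAC library generator.

Emulates the statistical structure a crosslinking-and-cDNA-analysis pipeline
assumes: a toy genome with annotated transcripts of every Pol II / Pol III
class, protein-specific positional binding distributions, crosslink-induced
single-nucleotide deletions, RNase fragmentation to short inserts, a 5' linker
carrying a sample barcode and a random 3 nt tag, non-genome-encoded A-tails in
three regimes (oligo(A) ~4-5 nt, deadenylated ~10-12 nt, long poly(A)), PCR
duplication, and read-length censoring by the sequencer.

Every emitted read has a ground-truth row, so downstream stages can be scored
exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import revcomp
from .annotation import Annotation, Transcript

ADAPTOR_3P = "TGGAATTCTCGGGTGCCAAGG"  # small-RNA style 3' sequencing adaptor
BARCODES = ("ACTGC", "GTCAA", "TGGCA", "CAATG", "GACTT", "TCAGG", "AGGTC", "CTTAG")

POSITIONAL_ARCHETYPES = (
    "five_prime_peak",
    "three_prime_peak",
    "body_uniform",
    "motif_anchored",
    "promoter_proximal",
)

TAIL_REGIMES = ("none", "oligoA", "deadenylated", "polyA")


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters for the toy genome."""

    contigs: tuple[tuple[str, int], ...] = (("chrI", 50_000), ("chrII", 50_000))
    gc_fraction: float = 0.40
    seed: int = 0

    def __post_init__(self):
        if len(self.contigs) == 0:
            raise ValueError("GenomeSpec requires at least one contig")
        for name, length in self.contigs:
            if length < 2000:
                raise ValueError(f"contig {name} shorter than 2000 nt")
        if not 0.0 < self.gc_fraction < 1.0:
            raise ValueError("gc_fraction must lie in (0, 1)")


@dataclass
class ProteinBindingModel:
    """Positional and 3'-tail behaviour of one RNA-binding protein.

    ``mixture`` weighs the positional archetypes; ``class_mixture`` optionally
    overrides it per transcript class (e.g. a poly(A)-binding factor peaks at
    mRNA/SUT 3' ends but binds lncRNAs lacking cleavage signals diffusely).
    ``tail_regime`` maps transcript class -> distribution over tail regimes.
    ``class_weights`` set relative expression sampled per class.
    """

    name: str
    mixture: dict[str, float]
    motif: str | None = None
    deletion_prob: float = 0.15
    tail_regime: dict[str, dict[str, float]] = field(default_factory=dict)
    class_mixture: dict[str, dict[str, float]] = field(default_factory=dict)
    class_weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS))

    def __post_init__(self):
        for mix in [self.mixture, *self.class_mixture.values()]:
            total = sum(mix.values())
            if total <= 0 or any(w < 0 for w in mix.values()):
                raise ValueError("mixture weights must be >= 0 and sum > 0")
            for k in mix:
                if k not in POSITIONAL_ARCHETYPES:
                    raise ValueError(f"unknown archetype {k}")
            for k in mix:
                mix[k] /= total
        if not 0.0 <= self.deletion_prob <= 1.0:
            raise ValueError("deletion_prob must lie in [0, 1]")

    def mixture_for(self, class_label: str) -> dict[str, float]:
        return self.class_mixture.get(class_label, self.mixture)

    def tails_for(self, class_label: str) -> dict[str, float]:
        return self.tail_regime.get(class_label, {"none": 1.0})


DEFAULT_CLASS_WEIGHTS = {
    "mRNA": 1.0, "SUT": 0.35, "CUT": 0.35, "XUT": 0.2,
    "snoRNA": 0.4, "snRNA": 0.25, "tRNA": 0.4,
}

_MRNA_SUT_POLYA = {"mRNA": {"polyA": 0.75, "none": 0.25}, "SUT": {"polyA": 0.6, "none": 0.4}}


def protein_preset(name: str) -> ProteinBindingModel:
    """Built-in binding archetypes named after the factors they emulate."""
    presets = {
        # cap-binding: 5' peak
        "cbc1": ProteinBindingModel("cbc1", {"five_prime_peak": 0.9, "body_uniform": 0.1}),
        # TRAMP helicase: promoter-proximal, oligo(A) surveillance tails
        "mtr4": ProteinBindingModel(
            "mtr4", {"promoter_proximal": 0.8, "body_uniform": 0.2},
            tail_regime={c: {"oligoA": 0.6, "none": 0.4}
                         for c in ("mRNA", "CUT", "SUT", "XUT", "snoRNA", "snRNA")},
        ),
        # nuclear poly(A)-binding: 3' peak with long tails
        "nab2": ProteinBindingModel(
            "nab2", {"three_prime_peak": 0.7, "body_uniform": 0.3},
            tail_regime=dict(_MRNA_SUT_POLYA),
        ),
        # cytoplasmic poly(A)-binding: sharp 3' peak on cleaved/polyadenylated
        # classes, diffuse on CUTs (no cleavage signals planted there)
        "pab1": ProteinBindingModel(
            "pab1", {"three_prime_peak": 0.9, "body_uniform": 0.1},
            class_mixture={"CUT": {"body_uniform": 1.0}, "XUT": {"body_uniform": 1.0}},
            tail_regime=dict(_MRNA_SUT_POLYA),
        ),
        # export factor: body
        "mex67": ProteinBindingModel("mex67", {"body_uniform": 1.0}),
        # 5'->3' exonuclease: body with mild 5' lean
        "xrn1": ProteinBindingModel("xrn1", {"body_uniform": 0.85, "five_prime_peak": 0.15}),
        # exosome helper: 3'-biased, deadenylated tails
        "ski2": ProteinBindingModel(
            "ski2", {"body_uniform": 0.6, "three_prime_peak": 0.4},
            tail_regime={c: {"deadenylated": 0.5, "none": 0.5} for c in ("mRNA", "SUT")},
        ),
        # cleavage factor binding the UAUAUA efficiency element
        "hrp1": ProteinBindingModel(
            "hrp1", {"motif_anchored": 0.85, "body_uniform": 0.15},
            motif="TATATA", deletion_prob=0.3,
        ),
        "hek2": ProteinBindingModel("hek2", {"body_uniform": 1.0}),
    }
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"no preset for {name!r}; available: {sorted(presets)}") from None


# --------------------------------------------------------------------------
# genome + annotation generation
# --------------------------------------------------------------------------

_DEFAULT_COMPOSITION = (
    # (class, count, min_len, max_len)
    ("mRNA", 26, 500, 1500),
    ("CUT", 8, 300, 600),
    ("SUT", 8, 400, 800),
    ("XUT", 4, 400, 800),
    ("snoRNA", 5, 120, 250),
    ("snRNA", 3, 120, 300),
    ("tRNA", 6, 80, 120),
)


def generate_genome(
    spec: GenomeSpec,
    composition=_DEFAULT_COMPOSITION,
    n_intron_mrnas: int = 3,
) -> tuple[dict[str, str], Annotation]:
    """Random toy genome plus a transcript annotation of every class.

    mRNAs and SUTs get planted 3'-end signals: an A-biased upstream stretch, a
    UAUAUA efficiency element 30-70 nt upstream of the major poly(A) site,
    often an AAUAAA positioning element 10-30 nt upstream, an A as the last
    encoded base, and a non-A base immediately downstream of the cleavage
    point.  CUTs and XUTs carry no planted cleavage signals.
    """
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seqs = {
        name: rng.choice(list("ACGT"), size=length, p=probs)
        for name, length in spec.contigs
    }

    # plan transcript lengths, shuffled, then lay out left-to-right with random gaps
    plan: list[tuple[str, int]] = []
    for label, count, lo, hi in composition:
        for _ in range(count):
            plan.append((label, int(rng.integers(lo, hi + 1))))
    order = rng.permutation(len(plan))
    plan = [plan[i] for i in order]

    contig_names = [name for name, _ in spec.contigs]
    contig_lens = dict(spec.contigs)
    cursor = {name: int(rng.integers(100, 400)) for name in contig_names}
    transcripts: list[Transcript] = []
    intron_budget = n_intron_mrnas
    serial = {label: 0 for label, *_ in composition}

    ci = 0
    for label, length in plan:
        placed = False
        for _ in range(len(contig_names)):
            name = contig_names[ci % len(contig_names)]
            if cursor[name] + length + 200 <= contig_lens[name]:
                start = cursor[name]
                cursor[name] = start + length + int(rng.integers(60, 400))
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"contigs too short to place a {length} nt {label} transcript"
            )
        ci += 1
        strand = "+" if rng.random() < 0.5 else "-"
        end = start + length
        serial[label] += 1
        tid = f"{label}_{serial[label]:03d}"

        exons: tuple[tuple[int, int], ...] = ((start, end),)
        if label == "mRNA" and intron_budget > 0 and length >= 600:
            intron_budget -= 1
            intron_len = int(rng.integers(80, 201))
            e1 = int(rng.integers(150, length - intron_len - 150))
            exons = ((start, start + e1), (start + e1 + intron_len, end))

        pa_sites: tuple[tuple[int, float], ...] = ()
        efficiency = None
        if label in ("mRNA", "SUT"):
            t_tmp = Transcript(tid, label, name, strand, exons)
            major = t_tmp.end3
            pa = [(major, 0.8)]
            if rng.random() < 0.5:
                d = int(rng.integers(25, 61))
                pa.append((t_tmp.to_genomic(t_tmp.to_oriented(major) - d), 0.2))
            else:
                pa = [(major, 1.0)]
            pa_sites = tuple(pa)
            seq = seqs[name]
            _plant_pa_context(seq, t_tmp, major, rng)
            if len(pa) > 1:
                _plant_pa_context(seq, t_tmp, pa[1][0], rng, arich=False)
            # efficiency element at -70..-36, positioning element at -25..-10:
            # disjoint windows so later plants never overwrite the element
            u = int(rng.integers(36, 71))
            efficiency = _plant_oriented_motif(
                seq, t_tmp, t_tmp.to_oriented(major) - u, "TATATA"
            )
            if rng.random() < 0.5:
                d2 = int(rng.integers(10, 26))
                _plant_oriented_motif(seq, t_tmp, t_tmp.to_oriented(major) - d2, "AATAAA")

        transcripts.append(
            Transcript(tid, label, name, strand, exons, pa_sites, efficiency)
        )

    genome = {name: "".join(arr) for name, arr in seqs.items()}
    return genome, Annotation(sorted(transcripts, key=lambda t: (t.contig, t.start)))


def _plant_oriented_motif(seq_arr, t: Transcript, oriented_start: int, motif: str) -> int:
    """Overwrite genome bases so `motif` reads in transcript orientation starting
    at the oriented offset; returns the genomic start of the planted element."""
    positions = [t.to_genomic(oriented_start + i) for i in range(len(motif))]
    bases = motif if t.strand == "+" else revcomp(motif)
    lo = min(positions)
    for i, p in enumerate(sorted(positions)):
        seq_arr[p] = bases[i]
    return lo


def _plant_pa_context(seq_arr, t: Transcript, pa: int, rng, arich: bool = True) -> None:
    """A-biased upstream context, A as last encoded base, non-A just downstream."""
    opos = t.to_oriented(pa)
    if arich:
        for o in range(max(0, opos - 80), opos):
            if rng.random() < 0.55:
                base = rng.choice(list("AT"), p=[0.65, 0.35])
                g = t.to_genomic(o)
                seq_arr[g] = base if t.strand == "+" else revcomp(base)
    seq_arr[pa] = "A" if t.strand == "+" else "T"
    for o in range(opos + 1, opos + 3):
        g = t.to_genomic(o)
        if 0 <= g < len(seq_arr):
            base = rng.choice(list("CGT"))
            seq_arr[g] = base if t.strand == "+" else revcomp(base)


def write_fasta(genome: dict[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(s), id=n, description="") for n, s in genome.items()],
        path,
        "fasta",
    )


def read_fasta(path: str) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# --------------------------------------------------------------------------
# library simulation
# --------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "read_id", "sample", "family", "transcript", "class_label", "contig", "strand",
    "frag_start", "frag_end", "five_prime_coord", "deletion_pos",
    "tail_type", "tail_len", "tag", "barcode",
]


def simulate_library(
    genome: dict[str, str],
    annotation: Annotation,
    binding: ProteinBindingModel,
    n_fragments: int,
    pcr_dup_mean: float = 1.0,
    seed: int = 0,
    sample: str | None = None,
    barcode: str = BARCODES[0],
    read_length: int = 54,
    fragment_length: tuple[int, int] = (20, 45),
    seq_error_rate: float = 0.0,
    tail_nona_rate: float = 0.0,
    polya_mean: float = 40.0,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one CRAC sequencing library.

    Returns ``(reads, truth)`` where reads are ``(id, sequence, quality)``
    FASTQ triples (read = barcode + random 3 nt tag + insert + tail + 3'
    adaptor, truncated at ``read_length``) and ``truth`` has one row per
    emitted read (PCR duplicates included).
    """
    if n_fragments < 1:
        raise ValueError("n_fragments must be >= 1")
    if pcr_dup_mean < 1:
        raise ValueError("pcr_dup_mean must be >= 1")
    rng = np.random.default_rng(seed)
    sample = sample or binding.name

    motif_occurrences: dict[str, list[int]] = {}
    if binding.motif:
        any_occ = False
        for t in annotation:
            s = t.span_sequence(genome)
            occ = _find_all(s, binding.motif)
            motif_occurrences[t.id] = occ
            any_occ = any_occ or bool(occ)
        if not any_occ:
            warnings.warn(
                f"motif {binding.motif} absent from the genome; "
                "motif_anchored weight renormalized away"
            )

    # per-class transcript choice weights: expression x length
    class_lists: dict[str, list[Transcript]] = {}
    for t in annotation:
        class_lists.setdefault(t.class_label, []).append(t)
    classes = sorted(c for c in class_lists if binding.class_weights.get(c, 0) > 0)
    cweights = np.array([binding.class_weights[c] for c in classes], float)
    cweights /= cweights.sum()

    flo, fhi = fragment_length
    reads: list[tuple[str, str, str]] = []
    truth_rows: list[tuple] = []
    used_keys: set[tuple] = set()
    bases = np.array(list("ACGT"))

    for fam in range(n_fragments):
        cls = classes[rng.choice(len(classes), p=cweights)]
        cand = class_lists[cls]
        lw = np.array([t.length for t in cand], float)
        t = cand[rng.choice(len(cand), p=lw / lw.sum())]
        L = t.length
        span_seq = t.span_sequence(genome)

        mix = binding.mixture_for(cls)
        keys = sorted(mix)
        arch = keys[rng.choice(len(keys), p=np.array([mix[k] for k in keys]))]
        if arch == "motif_anchored" and not motif_occurrences.get(t.id):
            arch = "body_uniform"

        tails = binding.tails_for(cls)
        tkeys = sorted(tails)
        tail_type = tkeys[rng.choice(len(tkeys), p=np.array([tails[k] for k in tkeys]))]

        flen = int(rng.integers(flo, fhi + 1))
        flen = min(flen, L)
        s = _sample_start(arch, t, L, flen, span_seq, motif_occurrences, rng,
                          binding.motif)

        if tail_type != "none":
            # pin poly(A)-regime fragments of a 3'-peaked factor to a cleavage site
            if arch == "three_prime_peak" and t.pa_sites:
                coords = [c for c, _ in t.pa_sites]
                w = np.array([w for _, w in t.pa_sites], float)
                pa = coords[rng.choice(len(coords), p=w / w.sum())]
                s = max(0, t.to_oriented(pa) + 1 - flen)
            # identifiability: nudge the fragment end so the next two encoded
            # bases are not A (a templated A is indistinguishable from a tail A)
            e = s + flen
            for shift in range(11):
                if e - shift <= 1:
                    break
                ee = e - shift
                nxt = span_seq[ee] if ee < L else ""
                nxt2 = span_seq[ee + 1] if ee + 1 < L else ""
                if nxt != "A" and nxt2 != "A":
                    e -= shift
                    break
            s = max(0, e - flen)
            flen = e - s
        e = s + flen

        if tail_type == "oligoA":
            tail_len = int(rng.integers(4, 6))
        elif tail_type == "deadenylated":
            tail_len = int(rng.integers(10, 13))
        elif tail_type == "polyA":
            tail_len = int(rng.geometric(1.0 / polya_mean))
        else:
            tail_len = 0
        tail = ""
        if tail_len:
            tarr = np.full(tail_len, "A")
            if tail_nona_rate > 0:
                sub = rng.random(tail_len) < tail_nona_rate
                tarr[sub] = rng.choice(list("CGT"), size=int(sub.sum()))
            tail = "".join(tarr)

        del_oriented = -1
        insert = span_seq[s:e]
        if flen >= 10 and rng.random() < binding.deletion_prob:
            # keep the deletion >= 5 nt from the fragment 3' end so the
            # alignment unambiguously extends through it
            lo_d, hi_d = s + 2, e - 6
            if arch == "motif_anchored" and binding.motif:
                inside = [p for m in motif_occurrences.get(t.id, [])
                          for p in range(m, m + len(binding.motif))
                          if lo_d <= p <= hi_d]
                del_oriented = int(rng.choice(inside)) if inside else int(rng.integers(lo_d, hi_d + 1))
            else:
                del_oriented = int(rng.integers(lo_d, hi_d + 1))
            insert = span_seq[s:del_oriented] + span_seq[del_oriented + 1 : e]

        # genomic coordinates of the fragment
        g1, g2 = t.to_genomic(s), t.to_genomic(e - 1)
        frag_start, frag_end = min(g1, g2), max(g1, g2) + 1
        five_prime = t.to_genomic(s)
        del_genomic = t.to_genomic(del_oriented) if del_oriented >= 0 else -1

        tag = "".join(rng.choice(list("ACGT"), size=3))
        key = (tag, t.contig, t.strand, five_prime)
        tries = 0
        while key in used_keys and tries < 100:
            tag = "".join(rng.choice(list("ACGT"), size=3))
            key = (tag, t.contig, t.strand, five_prime)
            tries += 1
        used_keys.add(key)

        full = barcode + tag + insert + tail + ADAPTOR_3P
        full = full[:read_length]

        n_copies = int(rng.geometric(1.0 / pcr_dup_mean)) if pcr_dup_mean > 1 else 1
        for c in range(n_copies):
            seq = full
            if seq_error_rate > 0:
                arr = np.array(list(seq))
                sub = rng.random(len(arr)) < seq_error_rate
                arr[sub] = bases[rng.integers(0, 4, size=int(sub.sum()))]
                seq = "".join(arr)
            rid = f"{sample}:{fam:06d}:{c}"
            reads.append((rid, seq, "I" * len(seq)))
            truth_rows.append(
                (rid, sample, fam, t.id, cls, t.contig, t.strand,
                 frag_start, frag_end, five_prime, del_genomic,
                 tail_type, tail_len, tag, barcode)
            )

    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return reads, truth


def _find_all(s: str, motif: str) -> list[int]:
    out, i = [], s.find(motif)
    while i != -1:
        out.append(i)
        i = s.find(motif, i + 1)
    return out


def _sample_start(arch, t, L, flen, span_seq, motif_occurrences, rng, motif):
    hi = max(0, L - flen)
    if arch == "five_prime_peak":
        return min(int(abs(rng.normal(0, 30))), hi)
    if arch == "promoter_proximal":
        return int(rng.integers(0, max(1, min(400, L) - flen + 1)))
    if arch == "three_prime_peak":
        end_target = L - int(rng.exponential(20))
        return int(np.clip(end_target - flen, 0, hi))
    if arch == "motif_anchored":
        occ = motif_occurrences.get(t.id, [])
        m = int(rng.choice(occ))
        lo_s = max(0, m + len(motif) - flen)
        hi_s = min(m, hi)
        if lo_s > hi_s:
            return int(np.clip(m - (flen - len(motif)) // 2, 0, hi))
        return int(rng.integers(lo_s, hi_s + 1))
    return int(rng.integers(0, hi + 1))


def write_fastq(reads, path: str) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str):
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


# --------------------------------------------------------------------------
# auxiliary simulators for specific analyses
# --------------------------------------------------------------------------

def simulate_junction_reads(
    libraries, spliced_fraction: float, n_reads: int, seed: int = 0,
    fragment_length: tuple[int, int] = (20, 45), min_overhang: int = 3,
):
    """Reads straddling splice junctions, drawn from spliced templates with
    probability ``spliced_fraction`` (an early-acting factor binds mostly
    unspliced pre-mRNA, a late one mostly spliced mRNA)."""
    rng = np.random.default_rng(seed)
    genes = sorted(libraries)
    out = []
    for i in range(n_reads):
        g = genes[rng.integers(0, len(genes))]
        entry = libraries[g]
        if rng.random() < spliced_fraction:
            template, junctions = entry.spliced_seq, entry.ee_junctions
        else:
            template, junctions = entry.unspliced_seq, entry.ie_junctions
        j = int(junctions[rng.integers(0, len(junctions))])
        flen = int(rng.integers(*fragment_length))
        lo = max(0, j - flen + min_overhang)
        hi = min(len(template) - flen, j - min_overhang)
        if hi < lo:
            continue
        s = int(rng.integers(lo, hi + 1))
        out.append((f"jx:{i:06d}", template[s : s + flen]))
    return out


def simulate_rnp_profiles(n: int = 600, seed: int = 0,
                          mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
                          noise_sigma: float = 0.35):
    """Three-archetype RNP-profile simulation for clustering recovery.

    Archetypes: surveillance-bound lncRNA-like (high Mtr4, low Mex67, low
    poly(A)-peak score), exported mRNA-like (high Mex67/Xrn1/Ski2, high peak
    score), and an intermediate class.  Returns (X, labels, channel names):
    X has the six unit-norm channels plus the [0,1] peak score.
    """
    rng = np.random.default_rng(seed)
    channels = ["cbc1", "mtr4", "nab2", "mex67", "xrn1", "ski2"]
    templates = np.array(
        [
            [1.0, 3.0, 1.5, 0.3, 0.5, 0.5],   # lncRNA-like
            [1.0, 0.5, 1.0, 2.5, 2.5, 2.0],   # mRNA-like
            [1.6, 1.6, 1.5, 1.1, 1.1, 1.0],   # mixed
        ]
    )
    peak_ab = [(2.0, 8.0), (8.0, 2.0), (4.0, 4.0)]
    labels = rng.choice(3, size=n, p=np.asarray(mix) / np.sum(mix))
    raw = templates[labels] * rng.lognormal(0.0, noise_sigma, size=(n, 6))
    X6 = raw / np.linalg.norm(raw, axis=1, keepdims=True)
    peak = np.array([rng.beta(*peak_ab[k]) for k in labels])
    return np.column_stack([X6, peak]), labels, channels + ["pab1_peak"]
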