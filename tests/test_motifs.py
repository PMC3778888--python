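"""k-mer Z scores (with exhaustive-null oracle), anchored profiles, sites, CNN census."""

import numpy as np
import pytest

from crac_atlas import motifs
from crac_atlas.annotation import Annotation, Transcript
from crac_atlas.motifs import (
    binding_sites, cnn_repeat_census, count_kmers, kmer_zscores,
    longest_cnn_repeat, motif_anchored_profile, site_motif_fraction,
)

from conftest import mk_read


def test_low_complexity_read_excluded_from_motif_analysis():
    genome = {"c": "GTCCG" + "A" * 9 + "GTACCATGGTTACATGGATCCTGACCTGATTGCCAAGGTTACA"}
    t = Transcript("t", "mRNA", "c", "+", ((0, len(genome["c"])),))
    ann = Annotation([t])
    lc = mk_read(0, 14, contig="c", rid="lc")      # "GTCCGAAAAAAAAA": 5 nonmodal
    ok = mk_read(14, 44, contig="c", rid="ok")
    chosen = motifs.eligible_reads([lc, ok], ann, genome)
    assert [r.id for r, _, _ in chosen] == ["ok"]


def _tiny_instance():
    """Two 60 nt transcripts, 10 reads: small enough to enumerate the null."""
    rng = np.random.default_rng(5)
    seq = "".join(rng.choice(list("ACGT"), size=200))
    t1 = Transcript("t1", "mRNA", "c", "+", ((10, 70),))
    t2 = Transcript("t2", "mRNA", "c", "+", ((100, 160),))
    genome = {"c": seq}
    ann = Annotation([t1, t2])
    reads = []
    for i, (s, ln) in enumerate(
        [(12, 20), (25, 22), (40, 21), (15, 30), (30, 25),
         (105, 20), (110, 24), (120, 23), (130, 21), (135, 20)]
    ):
        reads.append(mk_read(s, s + ln, contig="c", rid=f"r{i}"))
    return genome, ann, reads


def _exhaustive_oracle(genome, ann, reads, k):
    """Exact null mean/sd per k-mer by enumerating every placement per read
    (placements are independent, so means and variances add)."""
    means, variances = {}, {}
    for r in reads:
        t = ann.assign(r.contig, r.strand, r.start, r.end)
        seq = t.span_sequence(genome)
        ln = r.end - r.start
        starts = range(0, len(seq) - ln + 1)
        per_kmer = {}
        for s in starts:
            for m, n in count_kmers(seq[s : s + ln], k).items():
                per_kmer.setdefault(m, []).append(n)
        n_pl = len(list(starts))
        for m, counts in per_kmer.items():
            counts = counts + [0] * (n_pl - len(counts))
            mu = np.mean(counts)
            means[m] = means.get(m, 0.0) + mu
            variances[m] = variances.get(m, 0.0) + np.var(counts)
    return means, variances


def test_monte_carlo_z_matches_exhaustive_oracle():
    genome, ann, reads = _tiny_instance()
    k, n_rand = 2, 2000
    df = kmer_zscores(reads, ann, genome, k=k, n_randomizations=n_rand,
                      seed=1, min_nonmodal=0).set_index("kmer")
    means, variances = _exhaustive_oracle(genome, ann, reads, k)
    for m in df.index:
        sd = np.sqrt(variances[m])
        if sd == 0:
            continue
        z_exact = (df.loc[m, "observed"] - means[m]) / sd
        tol = 3.0 * (1.0 + abs(z_exact)) / np.sqrt(n_rand)
        assert abs(df.loc[m, "z"] - z_exact) < tol, m


def test_z_seed_stability_on_tiny_instance():
    genome, ann, reads = _tiny_instance()
    z1 = kmer_zscores(reads, ann, genome, 2, 1000, seed=1, min_nonmodal=0).set_index("kmer")["z"]
    z2 = kmer_zscores(reads, ann, genome, 2, 1000, seed=2, min_nonmodal=0).set_index("kmer")["z"]
    finite = z1.index[np.isfinite(z1) & np.isfinite(z2)]
    tol = 6.0 * (1.0 + np.abs(z1[finite])) / np.sqrt(1000)
    assert (np.abs(z1[finite] - z2[finite]) < tol).all()


def test_planted_motif_attains_top_six_mer_z(toy, hrp1_lib):
    genome, ann = toy
    df = kmer_zscores(hrp1_lib.dedup, ann, genome, k=6, n_randomizations=100, seed=2)
    assert df.iloc[0]["kmer"] == "TATATA"


def test_anchored_profile_rectangle_and_additivity():
    genome = {"c": "T" * 40 + "GGCATT" + "T" * 40}
    t = Transcript("t", "mRNA", "c", "+", ((0, 86),))
    ann = Annotation([t])
    CL = {"c": 86}
    r1 = mk_read(35, 55, contig="c", rid="a")
    r2 = mk_read(42, 60, contig="c", rid="b")
    prof, off = motif_anchored_profile([r1], ann, genome, "GGCATT", CL, window=(-10, 11))
    assert prof.sum() == 16  # read [35,55) covers offsets -5..+10 of the window
    assert prof[list(off).index(-5)] == 1 and prof[list(off).index(-6)] == 0
    p1, _ = motif_anchored_profile([r1], ann, genome, "GGCATT", CL, window=(-10, 11))
    p2, _ = motif_anchored_profile([r2], ann, genome, "GGCATT", CL, window=(-10, 11))
    both, _ = motif_anchored_profile([r1, r2], ann, genome, "GGCATT", CL, window=(-10, 11))
    assert np.allclose(both, p1 + p2)


def test_deletion_track_peaks_inside_planted_motif(toy, contig_lengths, hrp1_lib):
    genome, ann = toy
    prof, off = motif_anchored_profile(
        hrp1_lib.dedup, ann, genome, "TATATA", contig_lengths, track="deletions"
    )
    assert 0 <= off[int(np.argmax(prof))] <= 5


def test_anchored_profile_agrees_with_generic_anchored_average(toy, contig_lengths, hrp1_lib):
    """Stop-codon-style anchors give the same numbers through either module."""
    from crac_atlas.profiles import anchored_average

    genome, ann = toy
    motif = "TATATA"
    anchors = []
    for t in ann:
        seq = t.span_sequence(genome)
        i = seq.find(motif)
        while i != -1:
            anchors.append((t.contig, t.to_genomic(i), t.strand))
            i = seq.find(motif, i + 1)
    prof, off = motif_anchored_profile(hrp1_lib.dedup, ann, genome, motif,
                                       contig_lengths, window=(-50, 51))
    avg, off2, skipped = anchored_average(hrp1_lib.dedup, anchors, contig_lengths,
                                          window=(-50, 51))
    assert skipped == 0
    assert np.allclose(avg * len(anchors), prof)


def test_empty_motif_rejected(toy, contig_lengths):
    genome, ann = toy
    with pytest.raises(ValueError, match="empty motif"):
        motif_anchored_profile([], ann, genome, "", contig_lengths)
    with pytest.raises(ValueError, match="empty motif"):
        site_motif_fraction([], genome, "")


def test_binding_site_motif_fractions(toy, hrp1_lib):
    genome, ann = toy
    sites = binding_sites(hrp1_lib.dedup, ann, min_reads=5)
    assert all(s.support >= 5 for s in sites)
    frac_all, n_all = site_motif_fraction(sites, genome, "TATATA")
    assert n_all > 0 and frac_all is not None
    m3, nm = site_motif_fraction(
        sites, genome, "TATATA", region="three_prime",
        transcript_classes=("mRNA",), annotation=ann,
    )
    assert nm > 0 and m3 >= 0.8
    none, nz = site_motif_fraction([], genome, "TATATA")
    assert none is None and nz == 0


@pytest.mark.parametrize(
    "seq,n", [("CAACGG", 2), ("GGGTTT", 0), ("C", 1), ("CATCATCAT", 3), ("ACCGCCG", 2)]
)
def test_longest_cnn_repeat_examples(seq, n):
    assert longest_cnn_repeat(seq) == n


def test_cnn_census_detects_planted_repeat_and_orientation():
    rng = np.random.default_rng(9)
    base = "".join(rng.choice(list("AGT"), size=300))     # C-free background
    planted = base[:100] + ("CAT" * 8) + base[100:]
    genome = {"c": planted + base}
    ts = [
        Transcript("with_repeat", "mRNA", "c", "+", ((50, 250),)),
        Transcript("without", "CUT", "c", "+", ((400, 600),)),
    ]
    ann = Annotation(ts)
    census = cnn_repeat_census(ann, genome)
    assert census.loc["mRNA", 8] == 1.0
    assert census.loc["CUT"].idxmax() == 0
    # orientation sensitivity: the reverse complement breaks the repeat
    from crac_atlas._util import revcomp

    assert longest_cnn_repeat("CAT" * 8) == 8
    assert longest_cnn_repeat(revcomp("CAT" * 8)) != 8
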