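"""Generator contracts: determinism, planted signals, tail regimes, duplication."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crac_atlas import syndata
from crac_atlas.syndata import GenomeSpec, generate_genome, simulate_library


def test_same_seed_reproduces_genome_and_truth_byte_identically(tmp_path):
    out = []
    for rep in range(2):
        genome, ann = generate_genome(GenomeSpec(seed=11))
        fa, gtf = tmp_path / f"g{rep}.fa", tmp_path / f"a{rep}.gtf"
        syndata.write_fasta(genome, fa)
        ann.write_gtf(gtf)
        model = syndata.protein_preset("pab1")
        reads, truth = simulate_library(genome, ann, model, 200, pcr_dup_mean=2, seed=3)
        out.append((fa.read_bytes(), gtf.read_bytes(), reads, truth))
    assert out[0][0] == out[1][0]
    assert out[0][1] == out[1][1]
    assert out[0][2] == out[1][2]
    pd.testing.assert_frame_equal(out[0][3], out[1][3])


def test_invalid_genome_specs_rejected():
    with pytest.raises(ValueError):
        GenomeSpec(contigs=())
    with pytest.raises(ValueError):
        GenomeSpec(contigs=(("c", 500),))
    with pytest.raises(ValueError):
        GenomeSpec(gc_fraction=1.2)
    with pytest.raises(ValueError):
        generate_genome(GenomeSpec(contigs=(("c", 2000), ("d", 2000))))


def test_planted_efficiency_elements_verified_by_sequence_scan(toy):
    genome, ann = toy
    planted = [t for t in ann if t.efficiency_element is not None]
    assert planted, "generator should plant efficiency elements"
    for t in planted:
        s = t.span_sequence(genome)
        o = t.to_oriented(t.efficiency_element if t.strand == "+" else t.efficiency_element + 5)
        assert s[o : o + 6] == "TATATA"
        dist = t.to_oriented(t.major_pa_site) - o
        assert 30 <= dist <= 70
    # CUTs carry no planted cleavage signals
    for t in ann.of_class("CUT", "XUT"):
        assert not t.pa_sites and t.efficiency_element is None


def test_pa_site_weights_sum_to_one(annotation):
    for t in annotation:
        if t.pa_sites:
            assert sum(w for _, w in t.pa_sites) == pytest.approx(1.0)


def test_no_duplication_yields_distinct_tag_coordinate_pairs(toy):
    genome, ann = toy
    reads, truth = simulate_library(
        genome, ann, syndata.protein_preset("mex67"), 100, pcr_dup_mean=1, seed=2
    )
    assert len(reads) == 100
    pairs = set(zip(truth.tag, truth.contig, truth.strand, truth.five_prime_coord))
    assert len(pairs) == 100


def test_duplicate_family_sizes_conserve_read_count(toy):
    genome, ann = toy
    reads, truth = simulate_library(
        genome, ann, syndata.protein_preset("mex67"), 300, pcr_dup_mean=3, seed=4
    )
    assert truth.groupby("family").size().sum() == len(reads)
    # family members share fragment, tag and tail
    for _, grp in truth.groupby("family"):
        assert grp[["frag_start", "frag_end", "tag", "tail_len"]].nunique().max() == 1


def test_polya_tail_lengths_match_geometric_law(toy):
    genome, ann = toy
    model = syndata.ProteinBindingModel(
        "polyA_only", {"three_prime_peak": 1.0},
        tail_regime={c: {"polyA": 1.0} for c in ("mRNA", "SUT")},
        class_weights={"mRNA": 1.0, "SUT": 0.3},
    )
    _, truth = simulate_library(genome, ann, model, 10_000, seed=8, polya_mean=40.0)
    assert abs(truth.tail_len.mean() - 40.0) < 3.0


def test_oligoa_regime_tail_lengths_forced_to_4_or_5(toy):
    genome, ann = toy
    model = syndata.ProteinBindingModel(
        "oligo_only", {"body_uniform": 1.0},
        tail_regime={c: {"oligoA": 1.0} for c in ("mRNA", "CUT", "SUT")},
    )
    _, truth = simulate_library(genome, ann, model, 2000, seed=9)
    tailed = truth[truth.tail_type == "oligoA"]
    assert len(tailed)
    assert set(tailed.tail_len) <= {4, 5}


def test_tail_regime_chisquare_goodness_of_fit(toy):
    """Tail-regime draws match the configured distribution (alpha = 0.01)."""
    genome, ann = toy
    model = syndata.ProteinBindingModel(
        "mixed", {"body_uniform": 1.0},
        tail_regime={"mRNA": {"oligoA": 0.5, "none": 0.5}},
        class_weights={"mRNA": 1.0},
    )
    _, truth = simulate_library(genome, ann, model, 10_000, seed=10)
    obs = truth.tail_type.value_counts()
    chi2 = stats.chisquare([obs.get("oligoA", 0), obs.get("none", 0)], [5000, 5000])
    assert chi2.pvalue > 0.01
    # within oligoA, 4 vs 5 nt are equiprobable
    lens = truth.loc[truth.tail_type == "oligoA", "tail_len"].value_counts()
    n = lens.sum()
    chi2 = stats.chisquare([lens.get(4, 0), lens.get(5, 0)], [n / 2, n / 2])
    assert chi2.pvalue > 0.01


def test_absent_motif_renormalized_with_warning(toy):
    genome, ann = toy
    model = syndata.ProteinBindingModel(
        "ghost", {"motif_anchored": 0.8, "body_uniform": 0.2}, motif="ACGTACGTACGTACGT"
    )
    with pytest.warns(UserWarning, match="absent"):
        reads, truth = simulate_library(genome, ann, model, 50, seed=1)
    assert len(reads) == 50


def test_fragment_intervals_lie_within_source_span(toy, annotation):
    genome, ann = toy
    _, truth = simulate_library(genome, ann, syndata.protein_preset("pab1"), 500, seed=12)
    for row in truth.itertuples():
        t = annotation.by_id[row.transcript]
        assert t.start <= row.frag_start < row.frag_end <= t.end
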