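"""Hit tables, hpm normalization, replicate correlation, class breakdown."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crac_atlas import annot_hits
from crac_atlas.annot_hits import (
    HitTable, class_breakdown, count_hits, normalize_hpm, replicate_correlation,
)

from conftest import mk_read


def _inside(t, offset=10, length=25):
    if t.strand == "+":
        return mk_read(t.start + offset, t.start + offset + length,
                       strand=t.strand, contig=t.contig)
    return mk_read(t.end - offset - length, t.end - offset,
                   strand=t.strand, contig=t.contig)


def test_single_read_increments_only_host_feature(annotation):
    t = annotation.of_class("mRNA")[0]
    ht = count_hits([_inside(t)], annotation)
    assert ht.raw(t.id) == 1
    assert ht.table["raw"].sum() == 1


def test_read_in_three_prime_flank_counted_for_mrna(annotation):
    t = annotation.of_class("mRNA")[2]
    lo, hi = annotation.extended_span(t, 50, 300)
    if t.strand == "+":
        r = mk_read(t.end + 40, min(t.end + 65, hi), strand=t.strand, contig=t.contig)
        assert hi > t.end + 40, "flank truncated too aggressively for this fixture"
    else:
        r = mk_read(max(t.start - 65, lo), t.start - 40, strand=t.strand, contig=t.contig)
        assert lo < t.start - 40
    ht = count_hits([r], annotation)
    assert ht.raw(t.id) == 1


def test_flanks_truncated_at_same_strand_neighbour(annotation):
    same = {}
    for t in annotation:
        same.setdefault((t.contig, t.strand), []).append(t)
    found = False
    for (c, s), ts in same.items():
        ts.sort(key=lambda t: t.start)
        for a, b in zip(ts, ts[1:]):
            if a.class_label == "mRNA" and b.start - a.end < 300:
                lo, hi = annotation.extended_span(a, 50, 300)
                if a.strand == "+":
                    assert hi <= b.start
                found = True
    assert found


def test_hpm_arithmetic():
    table = pd.DataFrame(
        {"class": ["mRNA", "mRNA"], "raw": [100, 1_999_900], "hpm": np.nan},
        index=["a", "b"],
    )
    ht = normalize_hpm(HitTable("d", table), "polII_all")
    assert ht.hpm("a") == pytest.approx(50.0)
    assert ht.hpm("b") == pytest.approx(1e6 - 50.0)


def test_smaller_denominator_gives_larger_hpm(annotation, pab1_lib):
    ht = count_hits(pab1_lib.dedup, annotation)
    a = normalize_hpm(ht, "polII_all").table["hpm"]
    b = normalize_hpm(ht, "mcs").table["hpm"]
    assert (b >= a - 1e-9).all() and (b > a).any()


def test_zero_denominator_rejected():
    table = pd.DataFrame({"class": ["tRNA"], "raw": [5], "hpm": np.nan}, index=["t"])
    with pytest.raises(ValueError, match="denominator"):
        normalize_hpm(HitTable("d", table), "mcs")


def _ht(vals):
    table = pd.DataFrame(
        {"class": "mRNA", "raw": vals, "hpm": np.nan},
        index=[f"f{i}" for i in range(len(vals))],
    )
    return HitTable("d", table)


def test_spearman_on_scaled_and_reversed_tables():
    a = _ht([1, 5, 9, 14, 20])
    assert replicate_correlation(a, _ht([2, 10, 18, 28, 40])) == pytest.approx(1.0)
    assert replicate_correlation(a, _ht([20, 14, 9, 5, 1])) == pytest.approx(-1.0)


def test_spearman_with_ties_matches_rank_oracle():
    x = [3, 3, 7, 1, 9, 7, 2]
    y = [5, 2, 8, 1, 9, 9, 2]
    rho = replicate_correlation(_ht(x), _ht(y))
    # independent oracle: Pearson on average ranks
    oracle = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
    assert rho == pytest.approx(oracle)


def test_too_few_shared_features_rejected():
    with pytest.raises(ValueError, match="fewer than 3"):
        replicate_correlation(_ht([1, 0, 0, 0]), _ht([1, 1, 0, 0]))


def test_breakdown_all_reads_in_trnas(annotation):
    reads = [_inside(t, 5, 20) for t in annotation.of_class("tRNA")]
    bd = class_breakdown(reads, annotation)
    assert bd["tRNA"] == pytest.approx(1.0)


def test_breakdown_sums_to_one_and_mrna_dominates_pab1(annotation, pab1_lib):
    bd = class_breakdown(pab1_lib.dedup, annotation)
    assert bd.sum() == pytest.approx(1.0, abs=1e-9)
    assert bd.idxmax() == "mRNA"


def test_counts_additive_and_hpm_scale_invariant(annotation, pab1_lib):
    reads = pab1_lib.dedup
    half = len(reads) // 2
    a = count_hits(reads[:half], annotation).table["raw"]
    b = count_hits(reads[half:], annotation).table["raw"]
    whole = count_hits(reads, annotation).table["raw"]
    assert (a + b == whole).all()
    doubled = normalize_hpm(count_hits(reads + reads, annotation), "polII_all")
    single = normalize_hpm(count_hits(list(reads), annotation), "polII_all")
    assert np.allclose(doubled.table["hpm"], single.table["hpm"])


def test_body_uniform_counts_proportional_to_length(toy, annotation, genome_index):
    """Chi-square vs the simulator expectation (counts ~ class weight x length)."""
    from conftest import make_library
    from crac_atlas import syndata

    genome, ann = toy
    lib = make_library(genome, ann, genome_index, "mex67", 4000, seed=21)
    ht = count_hits(lib.dedup, ann, five_flank=0, three_flank=0)
    w = syndata.DEFAULT_CLASS_WEIGHTS
    mrnas = ann.of_class("mRNA")
    obs = np.array([ht.raw(t.id) for t in mrnas])
    lens = np.array([t.length for t in mrnas], float)
    exp = obs.sum() * lens / lens.sum()
    p = stats.chisquare(obs, exp).pvalue
    assert p > 0.001


def test_contig_mismatch_raises(annotation):
    r = mk_read(10, 40, contig="chrX")
    with pytest.raises(ValueError, match="chrX"):
        count_hits([r], annotation)
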