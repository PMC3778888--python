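"""RNP profile assembly, peak-sharpness score, and k-medians clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from crac_atlas import rnpcluster, syndata
from crac_atlas.annot_hits import HitTable
from crac_atlas.rnpcluster import (
    CHANNELS, assemble_profiles, kmedians, normalize_unit, peak_ratio,
    scale_scores, cluster_summary,
)


def test_unit_normalization_arithmetic():
    v = normalize_unit([3, 4, 0, 0, 0, 0])
    assert np.allclose(v, [0.6, 0.8, 0, 0, 0, 0])
    assert np.sum(v**2) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        normalize_unit([0, 0, 0])


def _tables(values: dict[str, dict[tuple[str, int], float]], total=1_000_000):
    """Build per-(protein, rep) HitTables from per-transcript hpm-like raws.

    A filler feature absorbs the remaining counts so raw == hpm numerically.
    """
    feats = sorted(values)
    tables = {}
    for ch in CHANNELS:
        for rep in (1, 2):
            raws = {f: values[f].get((ch, rep), 0.0) for f in feats}
            filler = total - sum(raws.values())
            table = pd.DataFrame(
                {
                    "class": ["mRNA"] * len(feats) + ["SUT"],
                    "raw": [raws[f] for f in feats] + [filler],
                    "hpm": np.nan,
                },
                index=feats + ["filler"],
            )
            tables[(ch, rep)] = HitTable(f"{ch}_{rep}", table)
    return tables


def test_assembly_filters_and_normalizes():
    good = {(ch, rep): 100.0 * (i + 1) for i, ch in enumerate(CHANNELS) for rep in (1, 2)}
    weak = {(ch, rep): 49.0 for ch in CHANNELS for rep in (1, 2)}           # < 50 hpm
    anti = {  # anticorrelated replicates -> Spearman filter rejects
        (ch, rep): (100.0 * (i + 1) if rep == 1 else 100.0 * (6 - i))
        for i, ch in enumerate(CHANNELS) for rep in (1, 2)
    }
    tables = _tables({"good": good, "weak": weak, "anti": anti})
    prof = assemble_profiles(tables, pab1_scores=pd.Series({"good": 0.7}))
    assert list(prof.index) == ["good"]
    six = prof.loc["good", list(CHANNELS)].to_numpy(float)
    assert np.sum(six**2) == pytest.approx(1.0, abs=1e-9)
    assert prof.loc["good", "pab1_peak"] == 0.7


def test_missing_channel_rejected():
    tables = _tables({"g": {}})
    del tables[("cbc1", 1)], tables[("cbc1", 2)]
    with pytest.raises(ValueError, match="cbc1"):
        assemble_profiles(tables, pd.Series(dtype=float))


def test_profile_invariant_to_expression_scaling():
    base = {(ch, rep): 40.0 * (i + 1) for i, ch in enumerate(CHANNELS) for rep in (1, 2)}
    scaled = {k: v * 7.0 for k, v in base.items()}
    p1 = assemble_profiles(_tables({"t": base}), pd.Series({"t": 0.0}))
    p2 = assemble_profiles(_tables({"t": scaled}), pd.Series({"t": 0.0}))
    assert np.allclose(p1.loc["t", list(CHANNELS)].to_numpy(float),
                       p2.loc["t", list(CHANNELS)].to_numpy(float))


# --- peak score ------------------------------------------------------------

def test_single_unit_read_scores_exactly_one():
    assert peak_ratio([(250, 251)], 1000, rng=np.random.default_rng(0)) == 1.0


def test_stacked_reads_outscore_spread_reads():
    wins = 0
    for seed in range(30):
        rng = np.random.default_rng(seed)
        stacked = [(480, 510)] * 30
        spread = [(i * 33, i * 33 + 30) for i in range(30)]
        rs = peak_ratio(stacked, 1000, n_randomizations=50, rng=rng)
        rp = peak_ratio(spread, 1000, n_randomizations=50, rng=rng)
        wins += rs > rp
    assert wins >= 29


def test_min_max_scaling():
    scaled = scale_scores(pd.Series({"a": 1.0, "b": 2.0, "c": 5.0}))
    assert scaled.to_dict() == {"a": 0.0, "b": 0.25, "c": 1.0}
    flat = scale_scores(pd.Series({"a": 2.0, "b": 2.0}))
    assert (flat == 0.0).all()


# --- k-medians -------------------------------------------------------------

def test_two_separated_clouds_split_exactly():
    rng = np.random.default_rng(3)
    a = rng.normal(0, 0.1, size=(40, 3))
    b = rng.normal(5, 0.1, size=(40, 3))
    X = np.vstack([a, b])
    res = kmedians(X, 2, restarts=5, seed=1)
    labels = res.labels
    assert len(set(labels[:40])) == 1 and len(set(labels[40:])) == 1
    assert labels[0] != labels[40]


def test_centroid_is_coordinatewise_median():
    X = np.array([[0.0, 0.0], [0.0, 2.0], [0.0, 10.0]])
    res = kmedians(X, 1, restarts=1, seed=0)
    assert np.allclose(res.centroids[0], [0.0, 2.0])


def test_k_larger_than_n_rejected():
    with pytest.raises(ValueError):
        kmedians(np.zeros((3, 2)), 5)
    with pytest.raises(ValueError, match="distinct"):
        kmedians(np.zeros((10, 2)), 3)


def test_objective_non_increasing_and_recovery():
    aris = []
    for seed in range(5):
        X, labels, _ = syndata.simulate_rnp_profiles(600, seed=seed)
        res = kmedians(X, 3, restarts=20, seed=seed)
        hist = res.objective_history
        assert all(b <= a + 1e-9 for a, b in zip(hist, hist[1:]))
        aris.append(adjusted_rand_score(labels, res.labels))
    assert min(aris) >= 0.8


def test_cluster_summary_composition():
    X, labels, _ = syndata.simulate_rnp_profiles(300, seed=2)
    res = kmedians(X, 3, restarts=10, seed=2)
    classes = pd.Series(np.where(labels == 0, "CUT", "mRNA"),
                        index=[f"t{i}" for i in range(len(labels))])
    summary = cluster_summary(res, classes)
    frac_cols = [c for c in summary.columns if c.startswith("frac_")]
    assert np.allclose(summary[frac_cols].sum(axis=1), 1.0)
    assert summary["n"].sum() == 300
    # the CUT-dominated cluster has the highest Mtr4 median
    df = pd.DataFrame(X, columns=list(CHANNELS) + ["pab1_peak"], index=classes.index)
    df["cluster"] = res.labels
    cut_cluster = summary[frac_cols].get("frac_CUT", pd.Series(0, index=summary.index)).idxmax()
    med = df.groupby("cluster")["mtr4"].median()
    assert med.idxmax() == cut_cluster
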