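"""RNP-profile assembly and k-medians classification of transcripts.

Each mRNA/CUT/SUT gets a vector of normalized binding to six proteins
(replicate-filtered and averaged, then scaled per gene to unit sum of
squares) plus a poly(A)-binding peak-sharpness score in [0, 1].  Profiles are
clustered by k-medians (Euclidean assignment, coordinate-wise median
centroids), the procedure Cluster 3.0 popularized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist

from .annotation import Annotation
from .annot_hits import HitTable, normalize_hpm

CHANNELS = ("cbc1", "mtr4", "nab2", "mex67", "xrn1", "ski2")


# --------------------------------------------------------------------------
# profile assembly
# --------------------------------------------------------------------------

def assemble_profiles(
    tables: dict[tuple[str, int], HitTable],
    pab1_scores: pd.Series,
    channels: tuple[str, ...] = CHANNELS,
    classes: tuple[str, ...] = ("mRNA", "CUT", "SUT"),
    min_hpm: float = 50.0,
    min_detected_in: int = 2,
    spearman_min: float = 0.37,
    filter_replicates: tuple[int, int] = (1, 2),
) -> pd.DataFrame:
    """Filtered, replicate-averaged, unit-norm RNP profiles.

    ``tables`` maps (protein, replicate number) -> HitTable.  Transcripts are
    kept when they reach ``min_hpm`` hits per million (mRNA+CUT+SUT
    denominator) in at least ``min_detected_in`` datasets and their six-protein
    profiles correlate (Spearman >= ``spearman_min``) between the two
    ``filter_replicates``; additional replicates join only the averaging.
    Returns a frame with the six channels (sum of squares 1 per row), the
    pab1 peak score, and the class label.
    """
    for ch in channels:
        if not any(p == ch for p, _ in tables):
            raise ValueError(f"protein channel {ch!r} missing entirely")
    norm = {key: normalize_hpm(ht, "mcs") for key, ht in tables.items()}
    any_tab = next(iter(norm.values())).table
    feats = [f for f in any_tab.index if any_tab.loc[f, "class"] in classes]

    hpm = pd.DataFrame(
        {key: nt.table.loc[feats, "hpm"] for key, nt in norm.items()}
    )
    detected = (hpm >= min_hpm).sum(axis=1) >= min_detected_in

    r1, r2 = filter_replicates
    rows = []
    for f in hpm.index[detected]:
        v1 = [hpm.loc[f, (ch, r1)] for ch in channels]
        v2 = [hpm.loc[f, (ch, r2)] for ch in channels]
        with warnings.catch_warnings():
            # a constant replicate vector has undefined rho -> rejected below
            warnings.simplefilter("ignore", stats.ConstantInputWarning)
            rho = stats.spearmanr(v1, v2).statistic
        if not np.isfinite(rho) or rho < spearman_min:
            continue
        reps: dict[str, list[float]] = {ch: [] for ch in channels}
        for (p, rep), val in hpm.loc[f].items():
            if p in reps:
                reps[p].append(val)
        mean6 = np.array([np.mean(reps[ch]) for ch in channels])
        nrm = np.linalg.norm(mean6)
        if nrm == 0:
            continue
        rows.append((f, *(mean6 / nrm), float(pab1_scores.get(f, 0.0)),
                     any_tab.loc[f, "class"]))
    out = pd.DataFrame(
        rows, columns=["transcript", *channels, "pab1_peak", "class"]
    ).set_index("transcript")
    return out


def normalize_unit(vec) -> np.ndarray:
    """Scale a channel vector so the sum of squares is 1."""
    v = np.asarray(vec, float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero profile")
    return v / n


# --------------------------------------------------------------------------
# poly(A)-binding peak-sharpness score
# --------------------------------------------------------------------------

def peak_ratio(
    read_intervals: list[tuple[int, int]],
    length: int,
    window: int = 400,
    n_randomizations: int = 100,
    rng=None,
) -> float:
    """Observed peak height over the mean randomized maximum.

    ``read_intervals`` are oriented [start, end) offsets within a transcript of
    ``length`` nt.  The observed coverage peak is divided by the mean, over
    randomizations, of the maximum coverage obtained when every read
    overlapping the ``window`` nt around the peak is re-placed uniformly
    within that window.  Sharp 3'-end peaks score high; diffuse binding
    scores near 1.
    """
    if not read_intervals:
        raise ValueError("no reads on transcript")
    rng = np.random.default_rng(rng)
    cov = np.zeros(length + 1)
    for a, b in read_intervals:
        cov[max(0, a)] += 1
        cov[min(length, b)] -= 1
    cov = np.cumsum(cov)[:length]
    peak = int(np.argmax(cov))
    h_obs = cov[peak]

    w0, w1 = max(0, peak - window // 2), min(length, peak + window // 2)
    inside = [(a, b) for a, b in read_intervals if a < w1 and b > w0]
    wlen = w1 - w0
    maxima = np.empty(n_randomizations)
    diff = np.zeros((n_randomizations, wlen + 1))
    for a, b in inside:
        ln = min(b - a, wlen)
        starts = rng.integers(0, wlen - ln + 1, size=n_randomizations)
        np.add.at(diff, (np.arange(n_randomizations), starts), 1)
        np.add.at(diff, (np.arange(n_randomizations), starts + ln), -1)
    maxima = np.cumsum(diff, axis=1)[:, :wlen].max(axis=1)
    return float(h_obs / maxima.mean())


def scale_scores(raw: pd.Series) -> pd.Series:
    """Min-max scale raw peak ratios to [0, 1] across the analysis set."""
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return raw * 0.0
    return (raw - lo) / (hi - lo)


def pab1_peak_scores(
    mapped,
    annotation: Annotation,
    transcripts=None,
    window: int = 400,
    n_randomizations: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Scaled peak-sharpness score for every transcript with >= 1 read."""
    rng = np.random.default_rng(seed)
    per_t: dict[str, list[tuple[int, int]]] = {}
    chosen = {t.id: t for t in (transcripts if transcripts is not None else annotation)}
    for r in mapped:
        t = annotation.assign(r.contig, r.strand, r.start, r.end)
        if t is None or t.id not in chosen:
            continue
        a = t.to_oriented(r.five_prime)
        b = t.to_oriented(r.three_prime)
        lo, hi = min(a, b), max(a, b) + 1
        per_t.setdefault(t.id, []).append((max(0, lo), min(t.length, hi)))
    raw = pd.Series(
        {
            tid: peak_ratio(ivs, chosen[tid].length, window, n_randomizations, rng)
            for tid, ivs in sorted(per_t.items())
        }
    )
    return scale_scores(raw)


# --------------------------------------------------------------------------
# k-medians
# --------------------------------------------------------------------------

@dataclass
class ClusterResult:
    k: int
    labels: np.ndarray
    centroids: np.ndarray
    objective: float                 # total within-cluster Euclidean distance
    seed: int
    restarts: int
    objective_history: list[float] = field(default_factory=list)


def kmedians(
    X,
    k: int,
    restarts: int = 20,
    seed: int = 0,
    max_iter: int = 200,
) -> ClusterResult:
    """k-medians: Euclidean assignment, coordinate-wise median centroids.

    Lloyd-style alternation, best of ``restarts`` seeded initializations by
    total within-cluster distance.  A centroid update is only accepted if it
    does not increase the objective (the coordinate-wise median is an L1
    minimizer, not an L2 one), so the recorded objective history is
    non-increasing by construction.  Empty clusters are reseeded from the
    point farthest from its centroid.
    """
    X = np.asarray(X, float)
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds {n} points")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in profiles")
    uniq = np.unique(X, axis=0)
    if len(uniq) < k:
        raise ValueError(
            f"only {len(uniq)} distinct profiles for k={k}; reduce k or deduplicate"
        )
    rng = np.random.default_rng(seed)
    best: ClusterResult | None = None
    for _ in range(max(1, restarts)):
        C = uniq[rng.choice(len(uniq), size=k, replace=False)].copy()
        history: list[float] = []
        labels = None
        prev_C = C
        for _it in range(max_iter):
            D = cdist(X, C)
            new_labels = D.argmin(axis=1)
            obj = float(D[np.arange(n), new_labels].sum())
            if history and obj > history[-1] + 1e-9:
                # median update worsened the L2 objective: revert and stop
                C = prev_C
                break
            history.append(obj)
            if labels is not None and np.array_equal(new_labels, labels):
                labels = new_labels
                break
            labels = new_labels
            prev_C = C
            newC = C.copy()
            for j in range(k):
                members = X[labels == j]
                if len(members):
                    newC[j] = np.median(members, axis=0)
                else:
                    worst = int(np.argmax(D[np.arange(n), labels]))
                    newC[j] = X[worst]
            C = newC
        D = cdist(X, C)
        labels = D.argmin(axis=1)
        obj = float(D[np.arange(n), labels].sum())
        res = ClusterResult(k, labels, C, obj, seed, restarts, history)
        if best is None or res.objective < best.objective:
            best = res
    return best


def cluster_summary(result: ClusterResult, classes: pd.Series) -> pd.DataFrame:
    """Per-cluster size and class composition (fractions sum to 1 per cluster)."""
    labels = pd.Series(result.labels, index=classes.index, name="cluster")
    rows = []
    for c in range(result.k):
        members = classes[labels == c]
        row = {"cluster": c, "n": len(members)}
        frac = members.value_counts(normalize=True)
        for cls, p in frac.items():
            row[f"frac_{cls}"] = p
        rows.append(row)
    return pd.DataFrame(rows).set_index("cluster").fillna(0.0)


def export_matrix(result: ClusterResult, profiles: pd.DataFrame) -> pd.DataFrame:
    """Heatmap-ready matrix: rows ordered by cluster, then by distance to the
    cluster centroid."""
    num = profiles.select_dtypes(include=[np.number])
    D = cdist(num.to_numpy(float), result.centroids)
    dist = D[np.arange(len(num)), result.labels]
    out = profiles.copy()
    out["cluster"] = result.labels
    out["dist"] = dist
    return out.sort_values(["cluster", "dist"]).drop(columns="dist")
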