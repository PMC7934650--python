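"""Recursive gap-statistic partitioning (PART) with a minimum cluster size.

The gap statistic compares the log within-cluster dispersion of a k-group
clustering with its expectation under B structureless reference datasets
drawn uniformly from the per-variable range box of the data; the chosen k
is the smallest k whose gap is within one simulation standard error of the
next gap (Tibshirani's "1-SE" rule).  PART applies this recursively: split
into the chosen number of groups, then look for further structure inside
each group large enough to possibly split again; terminal groups smaller
than ``minsize`` become outliers (cluster id 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from delimita.nc import CentroidMatrix

KMEANS_RESTARTS = 25


@dataclass
class GapResult:
    k_range: list[int]
    W: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    B: int
    chosen_k: int


def _within_dispersion(x: np.ndarray, labels: np.ndarray) -> float:
    """Sum over clusters of within-cluster squared distances to the centroid."""
    w = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        w += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return w


def _relocate(x: np.ndarray, labels: np.ndarray, iters: int = 25) -> np.ndarray:
    """Nearest-centroid relocation of a hierarchical cut.

    Agglomerative cuts freeze early greedy merges; a few relocation passes
    (k-means iterations seeded by the cut) let boundary cases cross over to
    the closer group.  Clusters may empty out, healing an over-cut.
    """
    labels = labels.copy()
    for _ in range(iters):
        uniq = np.unique(labels)
        cents = np.stack([x[labels == l].mean(axis=0) for l in uniq])
        d = ((x[:, None, :] - cents[None, :, :]) ** 2).sum(axis=-1)
        new = uniq[d.argmin(axis=1)]
        if (new == labels).all():
            break
        labels = new
    return labels


def _fit_labels(x: np.ndarray, k: int, method: str, rng: np.random.Generator) -> np.ndarray:
    if k == 1:
        return np.zeros(len(x), dtype=int)
    if method == "hierarchical":
        Z = hierarchy.linkage(x, method="ward", metric="euclidean")
        return _relocate(x, hierarchy.fcluster(Z, t=k, criterion="maxclust"))
    if method == "kmeans":
        km = KMeans(
            n_clusters=k,
            n_init=KMEANS_RESTARTS,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        return km.fit_predict(x)
    raise ValueError(f"unknown base clusterer {method!r}")


def gap_statistic(
    x: CentroidMatrix | np.ndarray,
    kmax: int = 10,
    B: int = 100,
    method: str = "hierarchical",
    seed: int = 0,
    reference: str = "box",
) -> GapResult:
    """Estimate the number of clusters by the gap statistic.

    Reference datasets are uniform over a box aligned with the data's
    principal axes (``reference="pca"``, the variant recommended for
    elongated clusters — morphometric data are strongly size-correlated)
    or over the raw per-variable range box (``reference="box"``).
    ``chosen_k`` is the smallest k with ``gap(k) >= gap(k+1) - s(k+1)``,
    else ``kmax``.
    """
    arr = x.values.to_numpy() if isinstance(x, CentroidMatrix) else np.asarray(x, dtype=float)
    n = len(arr)
    if n < 2:
        raise ValueError("gap statistic needs at least 2 cases")
    if B < 10:
        raise ValueError("B must be >= 10")
    kmax = int(min(kmax, n - 1))
    rng = np.random.default_rng(seed)

    if np.allclose(arr, arr[0]):
        warnings.warn("all cases identical; chosen_k = 1")
        ks = list(range(1, kmax + 1))
        z = np.zeros(kmax)
        return GapResult(ks, z, z, z, B, 1)

    if reference == "pca":
        mu = arr.mean(axis=0)
        _, _, vt = np.linalg.svd(arr - mu, full_matrices=False)
        rot = (arr - mu) @ vt.T
        lo, hi = rot.min(axis=0), rot.max(axis=0)

        def draw() -> np.ndarray:
            return rng.uniform(lo, hi, size=rot.shape) @ vt + mu

    elif reference == "box":
        lo, hi = arr.min(axis=0), arr.max(axis=0)

        def draw() -> np.ndarray:
            return rng.uniform(lo, hi, size=arr.shape)

    else:
        raise ValueError(f"unknown reference distribution {reference!r}")

    ks = list(range(1, kmax + 1))
    logW = np.empty(kmax)
    for i, k in enumerate(ks):
        logW[i] = np.log(max(_within_dispersion(arr, _fit_labels(arr, k, method, rng)), 1e-300))

    logWstar = np.empty((B, kmax))
    for b in range(B):
        ref = draw()
        for i, k in enumerate(ks):
            logWstar[b, i] = np.log(
                max(_within_dispersion(ref, _fit_labels(ref, k, method, rng)), 1e-300)
            )

    gap = logWstar.mean(axis=0) - logW
    s = logWstar.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B)

    chosen = kmax
    for i in range(kmax - 1):
        if gap[i] >= gap[i + 1] - s[i + 1]:
            chosen = ks[i]
            break
    return GapResult(ks, np.exp(logW), gap, s, B, chosen)


@dataclass
class Partition:
    """Case -> cluster id; 0 marks outliers (groups below minsize)."""

    assignments: dict[str, int]
    method: str
    minsize: int
    seed: int
    gap_trace: list[GapResult] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return len({c for c in self.assignments.values() if c > 0})

    def members(self, cluster: int) -> list[str]:
        return [case for case, c in self.assignments.items() if c == cluster]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"case": list(self.assignments), f"cluster_{self.method}": list(self.assignments.values())}
        )


def part(
    x: CentroidMatrix,
    method: str = "hierarchical",
    minsize: int = 5,
    B: int = 100,
    kmax: int = 10,
    seed: int = 0,
    reference: str = "box",
) -> Partition:
    """Recursive gap-statistic partitioning with an outlier floor.

    Groups are split as long as the gap statistic supports more than one
    cluster; a group with fewer than ``2 * minsize`` cases is never split
    further (no split of it could produce two valid clusters); terminal
    groups below ``minsize`` are relabeled 0.
    """
    if minsize < 1:
        raise ValueError("minsize must be >= 1")
    cases = list(x.values.index)
    arr = x.values.to_numpy()
    rng = np.random.default_rng(seed)
    trace: list[GapResult] = []

    terminal: list[list[int]] = []

    def recurse(idx: np.ndarray) -> None:
        sub = arr[idx]
        if len(idx) < 2 * minsize or len(idx) < 2:
            terminal.append(list(idx))
            return
        sub_kmax = int(min(kmax, len(idx) - 1))
        res = gap_statistic(sub, kmax=sub_kmax, B=B, method=method,
                            seed=int(rng.integers(0, 2**31 - 1)), reference=reference)
        trace.append(res)
        if res.chosen_k <= 1:
            terminal.append(list(idx))
            return
        labels = _fit_labels(sub, res.chosen_k, method, rng)
        for lab in np.unique(labels):
            child = idx[labels == lab]
            if len(child) >= 2 * minsize:
                recurse(child)
            else:
                terminal.append(list(child))

    recurse(np.arange(len(arr)))

    assignments: dict[str, int] = {}
    next_id = 1
    # deterministic cluster numbering: by smallest member's case label
    terminal.sort(key=lambda grp: min(cases[i] for i in grp))
    for grp in terminal:
        if len(grp) >= minsize:
            cid = next_id
            next_id += 1
        else:
            cid = 0
        for i in grp:
            assignments[cases[i]] = cid
    assignments = {case: assignments[case] for case in cases}
    return Partition(assignments, method, minsize, seed, trace)


def partition_concordance(p1: Partition, p2: Partition) -> dict[str, float]:
    """Pairwise agreement and adjusted Rand index between two partitions."""
    if set(p1.assignments) != set(p2.assignments):
        raise ValueError("partitions cover different case sets")
    cases = sorted(p1.assignments)
    a = [p1.assignments[c] for c in cases]
    b = [p2.assignments[c] for c in cases]
    n = len(cases)
    same = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            pairs += 1
            if (a[i] == a[j]) == (b[i] == b[j]):
                same += 1
    return {
        "pairwise_agreement": same / pairs if pairs else 1.0,
        "adjusted_rand": float(adjusted_rand_score(a, b)),
    }
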