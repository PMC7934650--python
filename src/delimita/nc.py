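"""Nest-centroid clustering: the "NC" half of NC-PART.

Workers of one ant colony are near-clonal in shape, so the collection
event (nest) — not the individual — is the statistical case.  Each nest is
collapsed to the arithmetic mean of its members' (transformed) trait
vectors, variables are z-scored, and the nest centroids are clustered
hierarchically on Euclidean distances.

Default variable set: the 15 CWb shape ratios plus log head width (shape
plus one explicit size axis) — the same quantities the group summaries and
the identification key work with; ``variables="log_traits"`` clusters on
log-transformed raw measurements instead for a sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from delimita.io import MorphoMatrix, ValidationError
from delimita.morphometry import compute_ratios, ratios_frame

#: drop a nest when more than this fraction of variables have no usable value
MAX_MISSING_FRACTION = 0.25


@dataclass
class CentroidMatrix:
    """One row per nest; values are transformed, possibly standardized."""

    values: pd.DataFrame  # index: nest codes, columns: variables
    member_map: dict[str, list[str]] = field(default_factory=dict)
    transform_log: list[str] = field(default_factory=list)

    @property
    def cases(self) -> list[str]:
        return list(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


def specimen_variables(m: MorphoMatrix, variables: str = "ratios") -> pd.DataFrame:
    """Per-specimen variable table used for clustering and LDA.

    ``ratios`` (default): the 15 CWb ratios plus ln(CWb) as the size axis.
    ``log_traits``: ln of each of the 16 raw traits.
    """
    if variables == "log_traits":
        df = m.to_frame().set_index("specimen_id")[list(m.trait_order)].astype(float)
        if (df <= 0).any().any():
            bad = df.index[(df <= 0).any(axis=1)].tolist()
            raise ValidationError(f"nonpositive trait values for specimens {bad}")
        return np.log(df)
    if variables == "ratios":
        rf = ratios_frame(compute_ratios(m))
        out = rf.drop(columns=["CL/POOC", "SPST/EL"])
        out["CWb"] = np.log(rf["CWb"])
        return out
    raise ValueError(f"unknown variable set {variables!r}")


def nest_centroids(m: MorphoMatrix, variables: str = "ratios") -> CentroidMatrix:
    """Collapse specimens to nest-mean vectors.

    A specimen missing a trait is excluded from that variable's nest mean;
    a nest left with more than 25% missing variables is dropped with a
    warning.
    """
    df = specimen_variables(m, variables)
    nests = pd.Series({r.specimen_id: r.nest_code for r in m.records})
    grouped = df.groupby(nests.reindex(df.index))
    cent = grouped.mean()

    missing_frac = cent.isna().mean(axis=1)
    bad = cent.index[missing_frac > MAX_MISSING_FRACTION]
    if len(bad):
        warnings.warn(f"dropping nests with >25% missing variables: {list(bad)}")
        cent = cent.drop(index=bad)
    if cent.isna().any().any():
        # remaining holes: fill with the variable's overall mean (logged)
        cent = cent.fillna(cent.mean())
    member_map = {
        nest: [sid for sid, nc in nests.items() if nc == nest] for nest in cent.index
    }
    # lexicographic case order makes downstream tie-breaking deterministic
    cent = cent.sort_index()
    return CentroidMatrix(cent, member_map, transform_log=[f"variables={variables}", "nest mean"])


def standardize(c: CentroidMatrix) -> CentroidMatrix:
    """Z-score every variable (mean 0, sample SD 1); constants are dropped."""
    if len(c) < 2:
        raise ValidationError("standardize needs at least 2 cases")
    sd = c.values.std(ddof=1)
    constant = sd.index[sd == 0]
    vals = c.values
    if len(constant):
        warnings.warn(f"dropping constant variables: {list(constant)}")
        vals = vals.drop(columns=constant)
        sd = sd.drop(index=constant)
    z = (vals - vals.mean()) / sd
    return CentroidMatrix(z, dict(c.member_map), c.transform_log + ["z-score"])


@dataclass
class Dendrogram:
    linkage: np.ndarray  # scipy linkage matrix, (n-1) x 4
    cases: list[str]
    method: str

    def cut(self, k: int) -> dict[str, int]:
        """Partition cases into k groups (flat cut of the merge history)."""
        flat = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.cases, (int(v) for v in flat)))

    def to_newick(self) -> str:
        return _linkage_to_newick(self.linkage, self.cases)


def cluster_dendrogram(c: CentroidMatrix, linkage: str = "ward") -> Dendrogram:
    """Agglomerate nest centroids on Euclidean distances.

    Cases are sorted lexicographically first, so equal-distance merges
    resolve the same way on any input ordering.
    """
    if len(c) < 2:
        raise ValidationError("need at least 2 cases to cluster")
    if linkage not in ("ward", "average", "complete"):
        raise ValueError(f"unsupported linkage {linkage!r}")
    vals = c.values.sort_index()
    Z = hierarchy.linkage(vals.to_numpy(), method=linkage, metric="euclidean")
    return Dendrogram(Z, list(vals.index), linkage)


def _linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy merge history as a rooted Newick string.

    Branch lengths are height differences between a node and its parent
    merge, so cutting the Newick at any depth induces the same case
    partitions as cutting the linkage matrix.
    """
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    children: dict[int, tuple[int, int]] = {}
    for j, (a, b, h, _cnt) in enumerate(Z):
        node = n + j
        children[node] = (int(a), int(b))
        heights[node] = float(h)

    def render(node: int, parent_h: float) -> str:
        bl = max(parent_h - heights[node], 0.0)
        if node < n:
            return f"{labels[node]}:{bl:.10g}"
        a, b = children[node]
        return f"({render(a, heights[node])},{render(b, heights[node])}):{bl:.10g}"

    root = n + len(Z) - 1
    return render(root, heights[root]) + ";"
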