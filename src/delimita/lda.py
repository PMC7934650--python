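"""Confirmatory linear discriminant analysis with wildcard typing.

A species hypothesis is accepted morphometrically when a shared-covariance
Gaussian discriminant trained on it classifies specimens almost perfectly
under leave-one-out cross-validation.  Name-bearing type specimens enter
as *wildcards* — no label, only a posterior probability vector — and a
syntype series is assigned by the renormalized geometric mean of its
members' posteriors.

Variables default to the same transformed set used for clustering; priors
default to uniform so unequal species sampling does not sway the placement
of a type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from delimita.io import ValidationError


@dataclass
class DiscriminantModel:
    classes: list[str]
    variables: list[str]
    priors: np.ndarray
    _clf: LinearDiscriminantAnalysis

    def posteriors(self, x: pd.DataFrame) -> pd.DataFrame:
        missing = [v for v in self.variables if v not in x.columns]
        if missing:
            raise ValidationError(f"missing variables {missing}")
        p = self._clf.predict_proba(x[self.variables].to_numpy())
        return pd.DataFrame(p, index=x.index, columns=self.classes)


@dataclass
class PosteriorReport:
    specimen_id: str
    posteriors: dict[str, float]
    predicted: str


@dataclass
class SeriesAssignment:
    type_series_id: str
    members: list[str]
    posteriors: dict[str, float]  # geometric mean, renormalized
    assigned: str


def _check_labels(labels: pd.Series) -> None:
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValidationError("need at least 2 classes")
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        raise ValidationError(f"class(es) with a single case cannot be fit: {singletons}")


def fit_lda(x: pd.DataFrame, labels: dict[str, str] | pd.Series, priors: str = "uniform") -> DiscriminantModel:
    """Fit a shared-covariance Gaussian discriminant.

    ``x``: cases x variables (index = case ids); ``labels``: case -> class
    for the training cases (wildcards simply don't appear here).  The svd
    solver tolerates collinear variables (scikit-learn warns and proceeds).
    """
    lab = pd.Series(labels) if not isinstance(labels, pd.Series) else labels
    lab = lab.reindex(x.index).dropna()
    xt = x.loc[lab.index]
    _check_labels(lab)
    classes = sorted(lab.unique())
    if priors == "uniform":
        pri = np.full(len(classes), 1.0 / len(classes))
    elif priors == "proportional":
        pri = lab.value_counts().reindex(classes).to_numpy(dtype=float)
        pri = pri / pri.sum()
    else:
        raise ValueError("priors must be 'uniform' or 'proportional'")
    arr = xt.to_numpy()
    centered = arr - pd.DataFrame(arr, index=lab.to_numpy()).groupby(level=0).transform("mean").to_numpy()
    if np.linalg.matrix_rank(centered) < arr.shape[1]:
        warnings.warn("collinear variables: pooled covariance is singular; "
                      "svd solver proceeds on the reduced rank")
    clf = LinearDiscriminantAnalysis(solver="svd", priors=pri)
    clf.fit(arr, lab.to_numpy())
    return DiscriminantModel(classes=list(clf.classes_), variables=list(x.columns), priors=pri, _clf=clf)


def loocv_success(
    x: pd.DataFrame, labels: dict[str, str] | pd.Series, priors: str = "uniform"
) -> tuple[float, pd.DataFrame]:
    """Leave-one-out classification success, in percent, plus confusion table.

    Each case is predicted by a model trained on everything else; a fold
    whose removal empties a class is skipped and reported in the confusion
    table's ``skipped`` attribute.
    """
    lab = pd.Series(labels).reindex(x.index).dropna()
    xt = x.loc[lab.index]
    _check_labels(lab)
    classes = sorted(lab.unique())
    confusion = pd.DataFrame(0, index=classes, columns=classes)
    skipped: list[str] = []
    correct = 0
    total = 0
    for case in xt.index:
        train_lab = lab.drop(case)
        if train_lab.value_counts().min() < 2:
            skipped.append(case)
            continue
        model = fit_lda(xt.drop(index=case), train_lab, priors=priors)
        pred = model.posteriors(xt.loc[[case]]).idxmax(axis=1).iloc[0]
        confusion.loc[lab[case], pred] += 1
        correct += int(pred == lab[case])
        total += 1
    confusion.attrs["skipped"] = skipped
    return (100.0 * correct / total if total else float("nan")), confusion


def classify_wildcards(
    model: DiscriminantModel,
    wildcards: pd.DataFrame,
    series: dict[str, str] | None = None,
) -> tuple[list[PosteriorReport], list[SeriesAssignment]]:
    """Posterior placement of unlabeled (type) specimens.

    ``series`` maps specimen_id -> type_series_id; the per-series class
    vector is the geometric mean of member posteriors, renormalized to sum
    to one (geometric means of probability vectors are not themselves
    normalized), and the series is assigned to the argmax class.
    """
    post = model.posteriors(wildcards)
    reports = [
        PosteriorReport(str(sid), {c: float(post.loc[sid, c]) for c in model.classes},
                        str(post.loc[sid].idxmax()))
        for sid in post.index
    ]
    assignments: list[SeriesAssignment] = []
    if series:
        by_series: dict[str, list[str]] = {}
        for sid, ser in series.items():
            if sid in post.index:
                by_series.setdefault(ser, []).append(sid)
        for ser in sorted(by_series):
            members = by_series[ser]
            block = post.loc[members].to_numpy()
            # geometric mean in log space; floor avoids log(0) for
            # posteriors that underflowed to exactly zero
            gm = np.exp(np.log(np.maximum(block, 1e-300)).mean(axis=0))
            gm = gm / gm.sum()
            vec = dict(zip(model.classes, map(float, gm)))
            assignments.append(
                SeriesAssignment(ser, members, vec, max(vec, key=vec.__getitem__))
            )
    return reports, assignments


def geometric_mean_posteriors(vectors: np.ndarray) -> np.ndarray:
    """Renormalized per-class geometric mean across member posterior vectors."""
    arr = np.asarray(vectors, dtype=float)
    gm = np.exp(np.log(np.maximum(arr, 1e-300)).mean(axis=0))
    return gm / gm.sum()
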