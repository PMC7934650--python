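"""Size-normalized ratios, per-group summaries, and the worker key.

All shape ratios are formed by dividing a trait by cephalic size (CWb,
maximum head width), the standard size denominator in ant morphometrics.
``NOL`` (petiole node length) is the petiole-length trait ``PEL`` under its
ratio-table alias; the two additional ratios ``CL/POOC`` and ``SPST/EL``
exist only because the dichotomous key uses them.

The identification key for workers of the Malagasy *Aphaenogaster
swammerdami* group is implemented as a deterministic rule engine over four
couplets; boundary values fall in none of the printed species ranges and
are returned as ``indeterminate`` rather than silently assigned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from delimita.io import MorphoMatrix, ValidationError

#: names of the 15 CWb ratios, in report order
CWB_RATIOS: tuple[str, ...] = (
    "CL/CWb",
    "POOC/CWb",
    "FRS/CWb",
    "FL/CWb",
    "SL/CWb",
    "MW/CWb",
    "SPTI/CWb",
    "PEW/CWb",
    "PPW/CWb",
    "ML/CWb",
    "SPST/CWb",
    "NOL/CWb",
    "NOH/CWb",
    "PPH/CWb",
    "EL/CWb",
)

#: numerator trait behind each CWb ratio (NOL is the PEL trait's alias)
_NUMERATOR = {
    "CL/CWb": "CL",
    "POOC/CWb": "PoOC",
    "FRS/CWb": "FRS",
    "FL/CWb": "FL",
    "SL/CWb": "SL",
    "MW/CWb": "MW",
    "SPTI/CWb": "SPTI",
    "PEW/CWb": "PEW",
    "PPW/CWb": "PPW",
    "ML/CWb": "ML",
    "SPST/CWb": "SPST",
    "NOL/CWb": "PEL",
    "NOH/CWb": "NOH",
    "PPH/CWb": "PPH",
    "EL/CWb": "EL",
}

KEY_RATIOS: tuple[str, ...] = ("CL/POOC", "SPST/EL")

ALL_RATIOS: tuple[str, ...] = CWB_RATIOS + KEY_RATIOS

KEY_SPECIES: tuple[str, ...] = ("bressleri", "gonacantha", "makay", "sahafina", "swammerdami")


@dataclass
class RatioVector:
    specimen_id: str
    ratios: dict[str, float]
    cwb: float


def compute_ratios(m: MorphoMatrix) -> list[RatioVector]:
    """Exact CWb quotients plus the key-only ratios CL/POOC and SPST/EL."""
    out: list[RatioVector] = []
    for rec in m.records:
        rec.validate(require_all=True)
        t = rec.traits
        for denom in ("CWb", "PoOC", "EL"):
            if t[denom] <= 0:
                raise ValidationError(f"{rec.specimen_id}: {denom} must be > 0")
        ratios = {name: t[_NUMERATOR[name]] / t["CWb"] for name in CWB_RATIOS}
        ratios["CL/POOC"] = t["CL"] / t["PoOC"]
        ratios["SPST/EL"] = t["SPST"] / t["EL"]
        out.append(RatioVector(rec.specimen_id, ratios, cwb=t["CWb"]))
    return out


def ratios_frame(ratios: list[RatioVector]) -> pd.DataFrame:
    df = pd.DataFrame([{"specimen_id": r.specimen_id, "CWb": r.cwb, **r.ratios} for r in ratios])
    return df.set_index("specimen_id")


@dataclass
class GroupSummary:
    group: str
    n: int
    stats: pd.DataFrame  # rows: CWb + ratio names; cols: mean, sd, min, max


def summarize_groups(ratios: list[RatioVector], labels: dict[str, str]) -> list[GroupSummary]:
    """Per-group mean / sample SD / min / max for CWb and every ratio.

    ``labels`` maps specimen_id to a group name.  SD of a single specimen is
    reported as 0.  Empty groups are skipped with a warning.
    """
    df = ratios_frame(ratios)
    df["__group"] = [labels.get(i) for i in df.index]
    unlabeled = df["__group"].isna()
    if unlabeled.any():
        raise ValidationError(f"unlabeled specimens: {list(df.index[unlabeled])}")
    out: list[GroupSummary] = []
    for group in pd.unique(df["__group"]):
        sub = df.loc[df["__group"] == group].drop(columns="__group")
        if sub.empty:
            warnings.warn(f"group {group!r} is empty; skipped")
            continue
        stats = pd.DataFrame(
            {
                "mean": sub.mean(),
                "sd": sub.std(ddof=1).fillna(0.0),
                "min": sub.min(),
                "max": sub.max(),
            }
        )
        out.append(GroupSummary(str(group), len(sub), stats))
    return out


def summary_table(summaries: list[GroupSummary]) -> pd.DataFrame:
    """Wide ratio-by-species table of 'mean +/- sd [min-max]' strings."""
    cols = {}
    for s in summaries:
        fmt = s.stats.apply(
            lambda r: f"{r['mean']:.2f} ± {r['sd']:.2f} [{r['min']:.2f}–{r['max']:.2f}]", axis=1
        )
        cols[f"{s.group} (n={s.n})"] = fmt
    return pd.DataFrame(cols)


@dataclass
class KeyOutcome:
    label: str  # one of KEY_SPECIES or "indeterminate"
    path: list[str] = field(default_factory=list)
    used_ratios: dict[str, float] = field(default_factory=dict)


# Couplet thresholds of the worker key.  Equality is indeterminate: the
# printed per-species ranges (e.g. 1.92-2.11 vs 1.63-1.88 for CL/POOC)
# exclude each threshold, so a specimen sitting exactly on one matches no
# species' range.
_CLPOOC_SPLIT = 1.9
_SPST_CWB_SPLIT = 0.25
_SPST_EL_SPLIT = 2.0
_DIVERGENT_LO = 1.05  # flange tips divergent (gonacantha): 1.05-1.25
_CONVERGENT_HI = 1.03  # flange tips not divergent (sahafina): <= 1.03


def key_classify(
    r: RatioVector,
    femur_flange: str,
    flange_divergence: float | None = None,
    couplet4_fallback=None,
) -> KeyOutcome:
    """Run a specimen through the four-couplet worker key.

    ``femur_flange`` is the qualitative state of the hind-femur apical
    flange (``"rounded"`` or ``"acute"``); ``flange_divergence`` is the
    tip-distance / femur-width ratio used at couplet 4.  When the legs are
    missing (no divergence ratio), ``couplet4_fallback`` — a callable
    mapping (PEW/NOH, SPST/PPH) to ``"gonacantha"``/``"sahafina"`` such as
    the discriminant from :func:`fit_couplet4_fallback` — separates the two
    species; with neither available the outcome is ``indeterminate``.
    """
    if femur_flange not in ("rounded", "acute"):
        raise ValidationError(f"femur_flange must be 'rounded' or 'acute', got {femur_flange!r}")
    rr = r.ratios
    used = {"CL/POOC": rr["CL/POOC"]}
    path = []

    cl_pooc = rr["CL/POOC"]
    if cl_pooc == _CLPOOC_SPLIT:
        return KeyOutcome("indeterminate", ["couplet1: CL/POOC on threshold"], used)
    if femur_flange == "rounded" and cl_pooc > _CLPOOC_SPLIT:
        path.append("couplet1: rounded flange, CL/POOC > 1.9 -> couplet 2")
        spst_cwb = rr["SPST/CWb"]
        used["SPST/CWb"] = spst_cwb
        if spst_cwb == _SPST_CWB_SPLIT:
            return KeyOutcome("indeterminate", path + ["couplet2: SPST/CWb on threshold"], used)
        if spst_cwb < _SPST_CWB_SPLIT:
            path.append("couplet2: SPST/CWb < 0.25 -> makay")
            return KeyOutcome("makay", path, used)
        path.append("couplet2: SPST/CWb > 0.25 -> swammerdami")
        return KeyOutcome("swammerdami", path, used)

    path.append("couplet1: not (rounded flange and CL/POOC > 1.9) -> couplet 3")
    spst_el = rr["SPST/EL"]
    used["SPST/EL"] = spst_el
    if spst_el == _SPST_EL_SPLIT:
        return KeyOutcome("indeterminate", path + ["couplet3: SPST/EL on threshold"], used)
    if spst_el < _SPST_EL_SPLIT:
        path.append("couplet3: SPST/EL < 2.0 -> bressleri")
        return KeyOutcome("bressleri", path, used)

    path.append("couplet3: SPST/EL > 2.0 -> couplet 4 (gonacantha complex)")
    if flange_divergence is not None:
        used["flange_divergence"] = flange_divergence
        if flange_divergence >= _DIVERGENT_LO:
            path.append("couplet4: flange tips divergent (>= 1.05) -> gonacantha")
            return KeyOutcome("gonacantha", path, used)
        if flange_divergence <= _CONVERGENT_HI:
            path.append("couplet4: flange tips not divergent (<= 1.03) -> sahafina")
            return KeyOutcome("sahafina", path, used)
        return KeyOutcome("indeterminate", path + ["couplet4: divergence in (1.03, 1.05)"], used)

    if couplet4_fallback is not None:
        pew_noh = rr["PEW/CWb"] / rr["NOH/CWb"]
        spst_pph = rr["SPST/CWb"] / rr["PPH/CWb"]
        used["PEW/NOH"] = pew_noh
        used["SPST/PPH"] = spst_pph
        label = couplet4_fallback(pew_noh, spst_pph)
        path.append(f"couplet4: legless fallback on PEW/NOH, SPST/PPH -> {label}")
        return KeyOutcome(label, path, used)

    return KeyOutcome("indeterminate", path + ["couplet4: no divergence ratio, no fallback"], used)


def fit_couplet4_fallback(ratios: list[RatioVector], labels: dict[str, str]):
    """Train the legless couplet-4 discriminant (gonacantha vs sahafina).

    A linear discriminant on (PEW/NOH, SPST/PPH) fitted from reference
    specimens of the two species; returns a callable for
    :func:`key_classify`.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    xs, ys = [], []
    for r in ratios:
        lab = labels.get(r.specimen_id)
        if lab in ("gonacantha", "sahafina"):
            xs.append([r.ratios["PEW/CWb"] / r.ratios["NOH/CWb"], r.ratios["SPST/CWb"] / r.ratios["PPH/CWb"]])
            ys.append(lab)
    if len(set(ys)) < 2:
        raise ValidationError("need reference specimens of both gonacantha and sahafina")
    clf = LinearDiscriminantAnalysis().fit(np.asarray(xs), ys)

    def fallback(pew_noh: float, spst_pph: float) -> str:
        return str(clf.predict([[pew_noh, spst_pph]])[0])

    return fallback
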