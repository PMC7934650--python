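"""Synthetic nest-structured morphometric tables and clade-structured COI data.

The generator carries ground truth so every pipeline stage has a recovery
test.  Morphometrics: a specimen's CWb and shape ratios are drawn around
species templates with a shared nest (colony) effect — workers of one
colony resemble each other far more than workers of different colonies —
and traits are reconstituted as ratio x CWb in micrometres.  Sequences:
Jukes-Cantor substitutions along a rooted species tree whose branch
lengths are solved from target intra- and interspecific uncorrected
p-distances (at low divergence the expected p-distance between two tips
is just under the total path length).

:func:`study_preset` builds the default study emulation: five species with
templates anchored to the published per-species ratio means/SDs and head
widths, 96 nests, 177 measured workers (one species with only 3), 658-bp
alignment of 89 ingroup + 2 outgroup sequences, and the published
intra/inter divergence targets — including one species composed of three
morphometric sub-morphs that share a single mitochondrial clade, so the
lump rule has real work to do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np

from delimita.io import (
    Alignment,
    MorphoMatrix,
    Role,
    SequenceRecord,
    SpecimenRecord,
    TypeStatus,
)
from delimita.morphometry import CWB_RATIOS, _NUMERATOR


def jc_expected_p(branch: float) -> float:
    """Expected uncorrected p-distance across a path of ``branch`` subs/site."""
    return 0.75 * (1.0 - math.exp(-4.0 * branch / 3.0))


def jc_branch_for_p(p: float) -> float:
    """Path length (expected subs/site) whose expected p-distance is ``p``."""
    if not 0 <= p < 0.75:
        raise ValueError(f"JC saturates at p=0.75; got {p}")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class SpeciesTemplate:
    name: str
    n_nests: int
    n_specimens: int
    cwb_mean: float
    cwb_sd: float
    ratio_means: dict[str, float]
    ratio_sds: dict[str, float]
    #: optional morphometric sub-structure: one offset dict (ratio -> delta
    #: added to the mean) per morph; nests are split evenly between morphs
    morph_offsets: list[dict[str, float]] | None = None
    flange: str = "acute"
    flange_divergence: float | None = None

    def __post_init__(self) -> None:
        if self.cwb_mean <= 0 or any(v <= 0 for v in self.ratio_means.values()):
            raise ValueError(f"{self.name}: template means must be positive")
        if self.cwb_sd < 0 or any(v < 0 for v in self.ratio_sds.values()):
            raise ValueError(f"{self.name}: template SDs must be >= 0")
        if self.n_specimens < self.n_nests:
            raise ValueError(f"{self.name}: fewer specimens than nests")


@dataclass
class TypeSeriesSpec:
    series_id: str
    species: str
    n: int
    status: TypeStatus = TypeStatus.SYNTYPE


@dataclass
class SynthConfig:
    species: list[SpeciesTemplate]
    #: share of the trait SD carried by the colony effect; the bulk of the
    #: printed per-species SD is individual + measurement variation, so
    #: nest centroids are substantially tighter than specimens
    nest_sd_fraction: float = 0.2
    #: loading of a common within-species shape factor on every ratio
    #: (0 = ratios drawn independently)
    factor_loading: float = 0.0
    type_series: list[TypeSeriesSpec] = field(default_factory=list)
    seq_length: int = 658
    seqs_per_species: dict[str, int] | None = None
    intra_p: dict[str, float] | float = 0.005
    inter_p: float = 0.035
    species_tree: str | None = None  # newick over species names (paths between ancestors)
    n_outgroups: int = 2
    outgroup_branch: float = 0.13
    n_duplicate_seqs: int = 0
    seed: int = 0


@dataclass
class GroundTruth:
    species_of_specimen: dict[str, str] = field(default_factory=dict)
    morph_of_specimen: dict[str, str] = field(default_factory=dict)
    species_of_sequence: dict[str, str] = field(default_factory=dict)
    flange_of_species: dict[str, str] = field(default_factory=dict)
    divergence_of_species: dict[str, float | None] = field(default_factory=dict)
    tree: dendropy.Tree | None = None
    config: SynthConfig | None = None


def _nest_sizes(n_specimens: int, n_nests: int) -> list[int]:
    base = n_specimens // n_nests
    extra = n_specimens - base * n_nests
    return [base + (1 if i < extra else 0) for i in range(n_nests)]


def simulate_morpho(cfg: SynthConfig) -> tuple[MorphoMatrix, GroundTruth]:
    """Draw a specimen x trait table with nest structure.

    Each variable v of a specimen is ``mean_v + nest_effect + noise`` where
    the nest effect is shared by nest mates with SD ``f * sd_v`` and the
    individual noise has SD ``sqrt(1 - f^2) * sd_v`` (total SD equals the
    template SD).  Within both components the ratios share a common shape
    factor with loading ``factor_loading`` — within-species ratio deviations
    covary in real material — while every marginal SD still equals the
    template SD.  For a ratio given morph offsets, the within-morph SD is
    shrunk so the species-wide SD still matches the template.  Traits are
    ratio x CWb; all draws are floored at a thousandth of their mean.
    """
    rng = np.random.default_rng(cfg.seed)
    f = cfg.nest_sd_fraction
    if not 0 <= f <= 1:
        raise ValueError("nest_sd_fraction must be in [0, 1]")
    lam = cfg.factor_loading
    if not 0 <= lam <= 1:
        raise ValueError("factor_loading must be in [0, 1]")
    resid = math.sqrt(1.0 - lam * lam)
    g_nest, g_ind = f, math.sqrt(max(1.0 - f * f, 0.0))

    def ratio_deviation(sds: dict[str, float]) -> dict[str, float]:
        """One unit-variance-per-ratio draw with the common-factor structure."""
        g = rng.normal()
        return {r: sds[r] * (lam * g + resid * rng.normal()) for r in CWB_RATIOS}

    records: list[SpecimenRecord] = []
    truth = GroundTruth(config=cfg)
    nest_counter = 0
    spec_counter = 0

    for tpl in cfg.species:
        truth.flange_of_species[tpl.name] = tpl.flange
        truth.divergence_of_species[tpl.name] = tpl.flange_divergence
        morphs = tpl.morph_offsets or [dict()]
        n_morphs = len(morphs)

        # per-morph effective SDs: subtract the between-morph variance the
        # offsets introduce so total SD matches the template
        eff_sds: list[dict[str, float]] = []
        for m in morphs:
            sds = dict(tpl.ratio_sds)
            for ratio in m:
                deltas = [mm.get(ratio, 0.0) for mm in morphs]
                between = float(np.var(deltas))
                sds[ratio] = math.sqrt(max(tpl.ratio_sds[ratio] ** 2 - between,
                                           (0.25 * tpl.ratio_sds[ratio]) ** 2))
            eff_sds.append(sds)

        sizes = _nest_sizes(tpl.n_specimens, tpl.n_nests)
        for nest_i, size in enumerate(sizes):
            nest_counter += 1
            nest_code = f"NEST{nest_counter:04d}"
            morph_i = nest_i % n_morphs
            offsets = morphs[morph_i]
            sds = eff_sds[morph_i]
            cwb_nest = rng.normal(0.0, g_nest * tpl.cwb_sd)
            ratio_nest = ratio_deviation(sds)
            for _ in range(size):
                spec_counter += 1
                sid = f"SPM{spec_counter:05d}"
                cwb = tpl.cwb_mean + cwb_nest + rng.normal(0.0, g_ind * tpl.cwb_sd)
                cwb = max(cwb, tpl.cwb_mean * 1e-3)
                traits = {"CWb": cwb}
                ratio_ind = ratio_deviation(sds)
                for ratio in CWB_RATIOS:
                    mean = tpl.ratio_means[ratio] + offsets.get(ratio, 0.0)
                    val = mean + g_nest * ratio_nest[ratio] + g_ind * ratio_ind[ratio]
                    val = max(val, mean * 1e-3)
                    traits[_NUMERATOR[ratio]] = val * cwb
                records.append(
                    SpecimenRecord(sid, nest_code, traits, qualitative_label=tpl.name)
                )
                truth.species_of_specimen[sid] = tpl.name
                truth.morph_of_specimen[sid] = f"{tpl.name}.m{morph_i + 1}"

    # name-bearing types: wildcard specimens outside the labeled sample
    tpl_by_name = {t.name: t for t in cfg.species}
    for ts in cfg.type_series:
        tpl = tpl_by_name[ts.species]
        nest_counter += 1
        nest_code = f"TYPE{nest_counter:04d}"
        cwb_nest = rng.normal(0.0, g_nest * tpl.cwb_sd)
        ratio_nest = ratio_deviation(tpl.ratio_sds)
        for _ in range(ts.n):
            spec_counter += 1
            sid = f"TYPE{spec_counter:05d}"
            cwb = max(tpl.cwb_mean + cwb_nest + rng.normal(0.0, g_ind * tpl.cwb_sd),
                      tpl.cwb_mean * 1e-3)
            traits = {"CWb": cwb}
            ratio_ind = ratio_deviation(tpl.ratio_sds)
            for ratio in CWB_RATIOS:
                mean = tpl.ratio_means[ratio]
                val = max(mean + g_nest * ratio_nest[ratio] + g_ind * ratio_ind[ratio],
                          mean * 1e-3)
                traits[_NUMERATOR[ratio]] = val * cwb
            records.append(
                SpecimenRecord(sid, nest_code, traits, qualitative_label=None,
                               type_status=ts.status, type_series_id=ts.series_id)
            )
            truth.species_of_specimen[sid] = ts.species
    return MorphoMatrix(records), truth


# ---------------------------------------------------------------------------
# sequences


def _star_species_tree(names: list[str], intra: dict[str, float], inter: float) -> str:
    """Star tree over species ancestors with equal expected inter distances."""
    parts = []
    for name in names:
        stem = (jc_branch_for_p(inter) - jc_branch_for_p(intra[name])) / 2.0
        if stem <= 0:
            raise ValueError(f"inter_p must exceed intra_p for {name}")
        parts.append(f"{name}:{stem:.8g}")
    return "(" + ",".join(parts) + ");"


def simulate_sequences(
    cfg: SynthConfig,
    seq_ids: dict[str, list[str]] | None = None,
) -> tuple[Alignment, dict[str, str], dendropy.Tree, GroundTruth]:
    """Evolve an alignment along the species tree under Jukes-Cantor.

    ``seq_ids`` optionally names the sequences per species (e.g. specimen
    ids); otherwise ids are ``<species>_s<i>``.  Within a species, tips
    radiate from the species ancestor with tip branches solved from the
    intra-divergence target; outgroups hang off the root on long branches.
    Returns the alignment, the ingroup species map, the true rooted tree
    and ground truth.
    """
    if len(cfg.species) < 2:
        raise ValueError("need >= 2 species for interspecific structure")
    rng = np.random.default_rng(cfg.seed + 1)
    names = [t.name for t in cfg.species]
    intra = (
        {n: float(cfg.intra_p) for n in names}
        if not isinstance(cfg.intra_p, dict)
        else {n: cfg.intra_p.get(n, 0.005) for n in names}
    )
    for n, p in intra.items():
        if not 0 <= p < 0.75:
            raise ValueError(f"intra divergence {p} out of range for {n}")
    if not 0 <= cfg.inter_p < 0.75:
        raise ValueError("inter divergence out of JC range")

    newick = cfg.species_tree or _star_species_tree(names, intra, cfg.inter_p)
    sp_tree = dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted", preserve_underscores=True)

    counts = cfg.seqs_per_species or {n: 5 for n in names}
    if seq_ids is None:
        seq_ids = {n: [f"{n}_s{i + 1}" for i in range(counts[n])] for n in names}

    L = cfg.seq_length
    if L < 1:
        raise ValueError("sequence length must be >= 1")

    def mutate(seq: np.ndarray, branch: float) -> np.ndarray:
        p_sub = 0.75 * (1.0 - math.exp(-4.0 * max(branch, 0.0) / 3.0))
        hit = rng.random(L) < p_sub
        out = seq.copy()
        # substitute with one of the three other bases, uniformly
        out[hit] = (seq[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
        return out

    root_seq = rng.integers(0, 4, size=L)

    # evolve down the species tree to each species ancestor
    anc_seq: dict[str, np.ndarray] = {}
    node_seq = {sp_tree.seed_node: root_seq}
    for node in sp_tree.preorder_node_iter():
        if node is sp_tree.seed_node:
            continue
        parent = node_seq[node.parent_node]
        node_seq[node] = mutate(parent, node.edge.length or 0.0)
        if node.is_leaf():
            anc_seq[node.taxon.label] = node_seq[node]

    alphabet = np.array(list("ACGT"))
    seqs: list[SequenceRecord] = []
    species_map: dict[str, str] = {}
    truth = GroundTruth(config=cfg)

    tip_newick_parts: dict[str, str] = {}
    for name in names:
        t_tip = jc_branch_for_p(intra[name]) / 2.0
        tips = []
        for sid in seq_ids[name]:
            tip_seq = mutate(anc_seq[name], t_tip)
            seqs.append(SequenceRecord(sid, "".join(alphabet[tip_seq])))
            species_map[sid] = name
            truth.species_of_sequence[sid] = name
            tips.append(f"{sid}:{t_tip:.8g}")
        # a one-tip fan is kept as a unifurcation so the stem length survives
        tip_newick_parts[name] = "(" + ",".join(tips) + ")"

    # exact duplicates, to exercise haplotype collapsing
    for i in range(cfg.n_duplicate_seqs):
        src = seqs[i % len(seqs)]
        dup = SequenceRecord(f"{src.seq_id}_dup{i + 1}", src.residues)
        seqs.append(dup)
        species_map[dup.seq_id] = species_map[src.seq_id]
        truth.species_of_sequence[dup.seq_id] = species_map[src.seq_id]

    for i in range(cfg.n_outgroups):
        og_seq = mutate(root_seq, cfg.outgroup_branch)
        og_id = f"OUTGROUP{i + 1}"
        seqs.append(SequenceRecord(og_id, "".join(alphabet[og_seq]), Role.OUTGROUP))

    # true tree: species tree with each species leaf replaced by its tip fan
    true_newick = newick
    for name in names:
        rep = tip_newick_parts[name]
        true_newick = true_newick.replace(f"{name}:", f"@@{name}@@:", 1)
        true_newick = true_newick.replace(f"@@{name}@@", rep, 1)
    og_parts = ",".join(f"OUTGROUP{i + 1}:{cfg.outgroup_branch:.8g}" for i in range(cfg.n_outgroups))
    if cfg.n_outgroups:
        true_newick = "(" + true_newick.rstrip(";\n ") + ("," + og_parts) + ");"
    tree = dendropy.Tree.get(data=true_newick, schema="newick", rooting="force-rooted", preserve_underscores=True)
    truth.tree = tree

    return Alignment(seqs), species_map, tree, truth


# ---------------------------------------------------------------------------
# the study emulation preset

#: per-species (mean, SD) shape-ratio templates and head widths (um),
#: anchored to the published per-species summary table
_STUDY = {
    "bressleri": dict(
        n=53, nests=29, cwb=(1292, 70),
        ratios={
            "CL/CWb": (1.79, 0.04), "POOC/CWb": (0.98, 0.03), "FRS/CWb": (0.23, 0.01),
            "FL/CWb": (0.32, 0.01), "SL/CWb": (2.36, 0.06), "MW/CWb": (0.77, 0.02),
            "SPTI/CWb": (0.31, 0.06), "PEW/CWb": (0.26, 0.01), "PPW/CWb": (0.40, 0.02),
            "ML/CWb": (2.44, 0.07), "SPST/CWb": (0.45, 0.04), "NOL/CWb": (0.50, 0.03),
            "NOH/CWb": (0.22, 0.02), "PPH/CWb": (0.39, 0.02), "EL/CWb": (0.27, 0.02),
        },
        flange="acute", divergence=None,
    ),
    "gonacantha": dict(
        n=27, nests=15, cwb=(1453, 73),
        ratios={
            "CL/CWb": (1.75, 0.04), "POOC/CWb": (0.97, 0.03), "FRS/CWb": (0.24, 0.02),
            "FL/CWb": (0.34, 0.01), "SL/CWb": (2.25, 0.07), "MW/CWb": (0.71, 0.01),
            "SPTI/CWb": (0.45, 0.07), "PEW/CWb": (0.26, 0.02), "PPW/CWb": (0.39, 0.02),
            "ML/CWb": (2.34, 0.05), "SPST/CWb": (0.70, 0.04), "NOL/CWb": (0.50, 0.02),
            "NOH/CWb": (0.21, 0.01), "PPH/CWb": (0.36, 0.02), "EL/CWb": (0.25, 0.01),
        },
        flange="acute", divergence=1.15,
    ),
    "makay": dict(
        n=3, nests=2, cwb=(1134, 97),
        ratios={
            "CL/CWb": (1.72, 0.03), "POOC/CWb": (0.88, 0.02), "FRS/CWb": (0.25, 0.01),
            "FL/CWb": (0.33, 0.01), "SL/CWb": (2.22, 0.07), "MW/CWb": (0.78, 0.02),
            "SPTI/CWb": (0.24, 0.01), "PEW/CWb": (0.30, 0.01), "PPW/CWb": (0.42, 0.05),
            "ML/CWb": (2.37, 0.02), "SPST/CWb": (0.22, 0.01), "NOL/CWb": (0.54, 0.02),
            "NOH/CWb": (0.28, 0.01), "PPH/CWb": (0.44, 0.01), "EL/CWb": (0.27, 0.01),
        },
        flange="rounded", divergence=None,
    ),
    "sahafina": dict(
        n=32, nests=17, cwb=(1295, 89),
        ratios={
            "CL/CWb": (1.76, 0.05), "POOC/CWb": (0.99, 0.03), "FRS/CWb": (0.24, 0.02),
            "FL/CWb": (0.34, 0.01), "SL/CWb": (2.30, 0.08), "MW/CWb": (0.70, 0.02),
            "SPTI/CWb": (0.40, 0.05), "PEW/CWb": (0.25, 0.01), "PPW/CWb": (0.38, 0.02),
            "ML/CWb": (2.39, 0.07), "SPST/CWb": (0.64, 0.04), "NOL/CWb": (0.53, 0.02),
            "NOH/CWb": (0.22, 0.02), "PPH/CWb": (0.38, 0.02), "EL/CWb": (0.25, 0.01),
        },
        flange="acute", divergence=1.0,
    ),
    "swammerdami": dict(
        n=62, nests=33, cwb=(1374, 147),
        ratios={
            "CL/CWb": (1.61, 0.07), "POOC/CWb": (0.80, 0.04), "FRS/CWb": (0.24, 0.01),
            "FL/CWb": (0.33, 0.01), "SL/CWb": (1.92, 0.12), "MW/CWb": (0.74, 0.03),
            "SPTI/CWb": (0.26, 0.03), "PEW/CWb": (0.26, 0.01), "PPW/CWb": (0.40, 0.02),
            "ML/CWb": (2.24, 0.10), "SPST/CWb": (0.33, 0.03), "NOL/CWb": (0.47, 0.03),
            "NOH/CWb": (0.25, 0.01), "PPH/CWb": (0.40, 0.02), "EL/CWb": (0.27, 0.01),
        },
        flange="rounded", divergence=None,
    ),
}

#: three sub-morphs inside bressleri (the published six-cluster structure):
#: one latent shape direction (m1 = -delta, m2 = 0, m3 = +delta) across all
#: ratios, with per-morph offsets of +/- one species SD.  Between-morph
#: spread then accounts for ~64% of each ratio's printed species-wide
#: variance and the within-morph SD is shrunk to match the printed total,
#: so the species summary still reproduces the published row while the
#: sub-structure is strong enough for the partitioning stage to find —
#: which is exactly what happened in the study.
#: sign pattern of the morph contrast: waist/spine ratios move against the
#: head/body ratios, keeping the contrast a shape change (nearly orthogonal
#: to the common within-species factor, which inflates all ratios together)
_MORPH_SIGN = {
    "SPTI/CWb": +1, "SPST/CWb": +1, "NOH/CWb": +1, "PPH/CWb": +1,
    "PEW/CWb": +1, "NOL/CWb": +1, "PPW/CWb": +1,
    "CL/CWb": -1, "POOC/CWb": -1, "FRS/CWb": -1, "FL/CWb": -1,
    "SL/CWb": -1, "MW/CWb": -1, "ML/CWb": -1, "EL/CWb": -1,
}


def _bressleri_morphs(ratio_sds: dict[str, float]) -> list[dict[str, float]]:
    delta = {r: 0.98 * sd * _MORPH_SIGN[r] for r, sd in ratio_sds.items()}
    return [
        {r: -d for r, d in delta.items()},
        {r: 0.0 for r in delta},
        {r: +d for r, d in delta.items()},
    ]

#: published per-species mean intraspecific p-distances (proportions)
_STUDY_INTRA = {
    "bressleri": 0.019,
    "gonacantha": 0.020,
    "makay": 0.001,
    "sahafina": 0.020,
    "swammerdami": 0.005,
}

#: sequenced sample sizes per species (89 ingroup total)
_STUDY_SEQ_N = {"bressleri": 27, "gonacantha": 14, "makay": 3, "sahafina": 16, "swammerdami": 29}


def _study_species_tree() -> str:
    """Species-ancestor tree solved from the published divergence targets.

    Closest-pair targets: sahafina-gonacantha 3.6%, swammerdami-makay 3.3%,
    bressleri to the sahafina+gonacantha pair 3.9%; the two sides of the
    root are set ~5% apart.
    """
    T = jc_branch_for_p
    t_tip = {n: T(_STUDY_INTRA[n]) / 2.0 for n in _STUDY_INTRA}
    h_sg = (T(0.036) - T(0.020)) / 2.0
    r1 = T(0.039) - (T(0.019) + T(0.020)) / 2.0 - h_sg
    a_to_b, bre_to_b = 0.2 * r1, 0.8 * r1
    r2 = T(0.033) - (T(0.005) + T(0.001)) / 2.0
    h_sm = r2 / 2.0
    inner = t_tip["swammerdami"] + h_sm + a_to_b + h_sg + t_tip["sahafina"]
    r3 = max(T(0.05) - inner, 0.002)
    half = r3 / 2.0
    return (
        f"(((sahafina:{h_sg:.8g},gonacantha:{h_sg:.8g}):{a_to_b:.8g},"
        f"bressleri:{bre_to_b:.8g}):{half:.8g},"
        f"(swammerdami:{h_sm:.8g},makay:{h_sm:.8g}):{half:.8g});"
    )


def study_preset(seed: int = 0) -> SynthConfig:
    """The five-species study emulation (see module docstring)."""
    species = []
    for name, d in _STUDY.items():
        species.append(
            SpeciesTemplate(
                name=name,
                n_nests=d["nests"],
                n_specimens=d["n"],
                cwb_mean=d["cwb"][0],
                cwb_sd=d["cwb"][1],
                ratio_means={r: mv[0] for r, mv in d["ratios"].items()},
                ratio_sds={r: mv[1] for r, mv in d["ratios"].items()},
                morph_offsets=(
                    _bressleri_morphs({r: mv[1] for r, mv in d["ratios"].items()})
                    if name == "bressleri"
                    else None
                ),
                flange=d["flange"],
                flange_divergence=d["divergence"],
            )
        )
    type_series = [
        TypeSeriesSpec("gonacantha_types", "gonacantha", 2),
        TypeSeriesSpec("swammerdami_types", "swammerdami", 3),
        TypeSeriesSpec("clara_types", "swammerdami", 1),
        TypeSeriesSpec("curta_types", "swammerdami", 2),
        TypeSeriesSpec("spinipes_types", "swammerdami", 1),
    ]
    return SynthConfig(
        species=species,
        type_series=type_series,
        seq_length=658,
        seqs_per_species=dict(_STUDY_SEQ_N),
        intra_p=dict(_STUDY_INTRA),
        inter_p=0.036,
        species_tree=_study_species_tree(),
        n_outgroups=2,
        seed=seed,
    )


def simulate_study_bundle(seed: int = 0):
    """Morphometric table + alignment + species map + true tree, linked.

    Sequenced specimens are the first k measured specimens of each species
    (sequence id = specimen id), mirroring a study where a subset of the
    measured material was barcoded.
    """
    cfg = study_preset(seed)
    morpho, truth_m = simulate_morpho(cfg)
    by_sp: dict[str, list[str]] = {}
    for rec in morpho.records:
        if rec.type_status is TypeStatus.NONE:
            by_sp.setdefault(truth_m.species_of_specimen[rec.specimen_id], []).append(rec.specimen_id)
    seq_ids = {name: by_sp[name][: cfg.seqs_per_species[name]] for name in by_sp}
    aln, species_map, tree, truth_s = simulate_sequences(cfg, seq_ids=seq_ids)
    truth_m.species_of_sequence = truth_s.species_of_sequence
    truth_m.tree = tree
    return morpho, aln, species_map, tree, truth_m
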