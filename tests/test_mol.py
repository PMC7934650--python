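"""COI metrics: haplotypes, p-distances, trees, monophyly, PID, P(AB)."""

from fractions import Fraction

import numpy as np
import pytest

from delimita.io import Alignment, SequenceRecord, ValidationError, read_newick
from delimita.mol import (
    DistanceMatrix,
    dedup_haplotypes,
    delimitation_report,
    enumerate_pab_oracle,
    intra_inter,
    is_monophyletic,
    n_rooted_topologies,
    nj_tree,
    p_distance,
    pid_liberal,
    pid_liberal_empirical,
    rosenberg_pab,
    sister_group,
)


def _aln(seqs: dict[str, str], outgroups=()) -> Alignment:
    from delimita.io import Role

    return Alignment([
        SequenceRecord(k, v, Role.OUTGROUP if k in outgroups else Role.INGROUP)
        for k, v in seqs.items()
    ])


# ---------------------------------------------------------------- haplotypes


def test_dedup_collapses_identical_sequences():
    aln = _aln({"x1": "ACGT", "x2": "ACGT", "y": "ACGA"})
    ded, idmap = dedup_haplotypes(aln)
    assert ded.ids == ["x1", "y"]  # first occurrence represents
    assert idmap == {"x1": "x1", "x2": "x1", "y": "y"}


def test_dedup_identity_on_unique_input_and_idempotence():
    aln = _aln({"a": "ACGT", "b": "ACGA", "c": "TCGA"})
    ded, _ = dedup_haplotypes(aln)
    assert ded.ids == aln.ids
    ded2, _ = dedup_haplotypes(ded)
    assert ded2.ids == ded.ids


def test_duplicates_do_not_change_deduplicated_metrics():
    base = {"a1": "AAAA", "a2": "AAAT", "b1": "TTTT", "b2": "TTTA"}
    sp = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
    tbl1 = intra_inter(p_distance(dedup_haplotypes(_aln(base))[0]), sp)
    dup = dict(base, a3="AAAA")  # exact duplicate haplotype
    sp2 = dict(sp, a3="A")
    tbl2 = intra_inter(p_distance(dedup_haplotypes(_aln(dup))[0]), sp2)
    assert np.allclose(tbl1["intra_dist_pct"], tbl2["intra_dist_pct"], equal_nan=True)


# ----------------------------------------------------------------- distances


def test_p_distance_hand_oracles(toy_alignment):
    d = p_distance(toy_alignment).frame()
    assert d.loc["a", "a"] == 0.0
    assert d.loc["a", "b"] == pytest.approx(0.25)  # 1 mismatch / 4 sites
    assert d.loc["a", "c"] == pytest.approx(0.0)  # gap deleted pairwise: 0/3
    comp = p_distance(toy_alignment).comparable
    assert comp[0, 2] == 3


def test_p_distance_treats_n_as_missing():
    d = p_distance(_aln({"a": "ACGT", "b": "NCGA"}))
    assert d.frame().loc["a", "b"] == pytest.approx(1 / 3)


def test_p_distance_no_comparable_sites_is_undefined():
    with pytest.warns(UserWarning, match="no comparable sites"):
        d = p_distance(_aln({"a": "AC--", "b": "--GT"}))
    assert np.isnan(d.frame().loc["a", "b"])


def test_p_distance_symmetry_and_bounds(rng):
    alphabet = np.array(list("ACGT-N"))
    seqs = {f"s{i}": "".join(rng.choice(alphabet, size=30)) for i in range(6)}
    d = p_distance(_aln(seqs)).d
    assert np.allclose(d, d.T, equal_nan=True)
    finite = d[np.isfinite(d)]
    assert ((finite >= 0) & (finite <= 1)).all()
    assert np.allclose(np.diag(d), 0)


# --------------------------------------------------------------------- trees


def test_nj_recovers_additive_four_taxon_tree():
    # additive matrix for ((A,B),(C,D)) with internal branch 3
    ids = ["A", "B", "C", "D"]
    m = np.array([
        [0, 0.2, 0.5, 0.6],
        [0.2, 0, 0.5, 0.6],
        [0.5, 0.5, 0, 0.3],
        [0.6, 0.6, 0.3, 0],
    ])
    d = DistanceMatrix(ids, m, np.full((4, 4), 100))
    tree = nj_tree(d, outgroup_ids=["D"])
    assert is_monophyletic(tree, {"A", "B"}, exclude={"D"})
    assert is_monophyletic(tree, {"C"}, exclude={"D"})


def test_nj_requires_outgroup_and_defined_distances():
    ids = ["A", "B", "C"]
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = np.nan
    with pytest.raises(ValidationError, match="undefined"):
        nj_tree(DistanceMatrix(ids, m, np.ones((3, 3), dtype=int)), ["C"])
    with pytest.raises(ValidationError, match="outgroup"):
        nj_tree(DistanceMatrix(ids, np.zeros((3, 3)), np.ones((3, 3), dtype=int)), ["Z"])


def test_monophyly_examples():
    t = read_newick("((A1,A2),(B1,B2));")
    assert is_monophyletic(t, {"A1", "A2"})
    assert is_monophyletic(t, {"A1"})  # a leaf is a clade
    t2 = read_newick("(((A1,B1),A2),B2);")
    assert not is_monophyletic(t2, {"A1", "A2"})
    with pytest.raises(ValidationError, match="ZZ"):
        is_monophyletic(t, {"ZZ"})


def test_monophyly_excludes_outgroup_from_universe():
    t = read_newick("(((A1,OG),A2),B1);")
    assert not is_monophyletic(t, {"A1", "A2"})
    assert is_monophyletic(t, {"A1", "A2"}, exclude={"OG"})


def test_sister_group():
    t = read_newick("(((A1,A2),(B1,B2)),C);")
    assert sister_group(t, {"A1", "A2"}) == {"B1", "B2"}


# ------------------------------------------------------------- intra / inter


def test_intra_inter_basic():
    aln = _aln({"a1": "AAAA", "a2": "AAAA", "b1": "TTTT", "b2": "TTTT"})
    tbl = intra_inter(p_distance(aln), {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    assert tbl.loc["A", "intra_dist_pct"] == 0.0
    assert tbl.loc["A", "inter_dist_closest_pct"] == pytest.approx(100.0)
    assert tbl.loc["A", "closest_species"] == "B"


def test_intra_inter_closest_of_three():
    aln = _aln({
        "a": "AAAAAAAAAA", "a2": "AAAAAAAAAT",
        "b": "AAAAATTTTT", "c": "TTTTTTTTTT",
    })
    tbl = intra_inter(p_distance(aln), {"a": "A", "a2": "A", "b": "B", "c": "C"})
    assert tbl.loc["A", "closest_species"] == "B"
    assert np.isnan(tbl.loc["B", "intra_dist_pct"])  # singleton species


# ----------------------------------------------------------------------- PID


def test_pid_limit_and_monotonicity():
    mean0, lo0, hi0 = pid_liberal(0.0, 0.2, n=10)
    assert mean0 > 0.999 and 0 <= lo0 <= hi0 <= 1
    grid = [pid_liberal(r * 0.03, 0.03, n=10)[0] for r in np.linspace(0, 1, 11)]
    assert all(a >= b - 1e-12 for a, b in zip(grid, grid[1:]))
    with pytest.raises(ValidationError):
        pid_liberal(0.01, 0.0, n=5)


def test_pid_empirical_identifies_tight_species():
    aln = _aln({
        "a1": "AAAAAAAAAA", "a2": "AAAAAAAAAT", "a3": "AAAAAAAATT",
        "b1": "TTTTTTTTTT", "b2": "TTTTTTTTAA",
    })
    sp = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B"}
    mean, lo, hi = pid_liberal_empirical(p_distance(aln), sp, "A")
    assert mean == 1.0
    assert lo <= mean <= hi <= 1.0


# -------------------------------------------------------------------- P(AB)


def test_topology_counts():
    assert [n_rooted_topologies(n) for n in (1, 2, 3, 4, 5)] == [1, 1, 3, 15, 105]


@pytest.mark.parametrize("a,b,expected", [(1, 1, Fraction(1)), (1, 2, Fraction(1, 3)),
                                          (2, 2, Fraction(1, 15))])
def test_rosenberg_small_cases(a, b, expected):
    assert rosenberg_pab(a, b) == expected
    assert enumerate_pab_oracle(a, b) == expected


def test_oracle_refuses_large_inputs():
    with pytest.raises(ValidationError):
        enumerate_pab_oracle(5, 5)


def test_rosenberg_validates():
    with pytest.raises(ValidationError):
        rosenberg_pab(0, 3)


# -------------------------------------------------------------------- report


def _two_clade_alignment(rng, paraphyletic=False):
    from delimita.synth import SynthConfig, SpeciesTemplate, simulate_sequences

    cfg = SynthConfig(
        species=[_tpl("A"), _tpl("B")],
        seq_length=400,
        seqs_per_species={"A": 5, "B": 5},
        intra_p=0.005,
        inter_p=0.05,
        n_outgroups=1,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    return simulate_sequences(cfg)


def _tpl(name):
    from delimita.synth import SpeciesTemplate
    from delimita.morphometry import CWB_RATIOS

    return SpeciesTemplate(name, 2, 4, 1000.0, 10.0,
                           {r: 0.5 for r in CWB_RATIOS}, {r: 0.01 for r in CWB_RATIOS})


def test_delimitation_report_two_clean_clades(rng):
    aln, spmap, tree, _ = _two_clade_alignment(rng)
    rep = delimitation_report(aln, spmap, tree=tree)
    assert rep.table["monophyletic"].all()
    for sp in ("A", "B"):
        assert rep.table.loc[sp, "intra_dist_pct"] < rep.table.loc[sp, "inter_dist_closest_pct"]
        assert rep.table.loc[sp, "pid_mean"] >= 0.9
        assert 0 < rep.table.loc[sp, "rosenberg_pab"] <= 1


def test_delimitation_report_flags_paraphyly(rng):
    aln, spmap, tree, _ = _two_clade_alignment(rng)
    # relabel one A sequence as B: B becomes non-monophyletic by construction
    moved = next(k for k, v in spmap.items() if v == "A")
    spmap = dict(spmap, **{moved: "B"})
    rep = delimitation_report(aln, spmap, tree=tree)
    assert not rep.table.loc["B", "monophyletic"]


def test_delimitation_report_nj_fallback(rng):
    aln, spmap, tree, _ = _two_clade_alignment(rng)
    rep = delimitation_report(aln, spmap, tree=None)  # builds NJ rooted on outgroup
    assert rep.table["monophyletic"].all()
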