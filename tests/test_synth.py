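"""The synthetic-data generator: bookkeeping, calibration, ground truth."""

import math

import numpy as np
import pytest

from delimita.io import TypeStatus
from delimita.morphometry import CWB_RATIOS, _NUMERATOR
from delimita.mol import dedup_haplotypes, intra_inter, p_distance
from delimita.synth import (
    SpeciesTemplate,
    SynthConfig,
    TypeSeriesSpec,
    jc_branch_for_p,
    jc_expected_p,
    study_preset,
    simulate_morpho,
    simulate_sequences,
)


def _tpl(name, n_nests=10, n_specimens=20, cwb=(1000.0, 20.0), ratio_mean=0.5, sd=0.01):
    return SpeciesTemplate(
        name, n_nests, n_specimens, cwb[0], cwb[1],
        {r: ratio_mean for r in CWB_RATIOS}, {r: sd for r in CWB_RATIOS},
    )


def test_zero_sd_reproduces_template_exactly():
    tpl = _tpl("sp", n_nests=2, n_specimens=4, cwb=(1000.0, 0.0), sd=0.0)
    m, truth = simulate_morpho(SynthConfig(species=[tpl], seed=3))
    for rec in m.records:
        assert rec.traits["CWb"] == pytest.approx(1000.0)
        for ratio in CWB_RATIOS:
            assert rec.traits[_NUMERATOR[ratio]] == pytest.approx(500.0)


def test_bookkeeping_counts():
    cfg = SynthConfig(species=[_tpl(f"sp{i}", 10, 20) for i in range(5)], seed=1)
    m, truth = simulate_morpho(cfg)
    assert len(m) == 100
    assert len(m.nest_codes) == 50
    assert len(set(truth.species_of_specimen.values())) == 5


def test_group_means_recover_templates_within_three_se():
    tpl = _tpl("sp", n_nests=25, n_specimens=50, cwb=(1200.0, 60.0), sd=0.02)
    m, _ = simulate_morpho(SynthConfig(species=[tpl], seed=9))
    ratios = np.array([r.traits[_NUMERATOR["SL/CWb"]] / r.traits["CWb"] for r in m.records])
    se = 0.02 / math.sqrt(50)
    assert abs(ratios.mean() - 0.5) < 3 * se
    cwb = np.array([r.traits["CWb"] for r in m.records])
    assert abs(cwb.mean() - 1200.0) < 3 * 60.0 / math.sqrt(50)


def test_template_validation():
    with pytest.raises(ValueError, match="positive"):
        SpeciesTemplate("bad", 1, 2, -5.0, 1.0,
                        {r: 0.5 for r in CWB_RATIOS}, {r: 0.0 for r in CWB_RATIOS})
    with pytest.raises(ValueError, match="SD"):
        SpeciesTemplate("bad", 1, 2, 10.0, -1.0,
                        {r: 0.5 for r in CWB_RATIOS}, {r: 0.0 for r in CWB_RATIOS})


def test_type_series_are_flagged_wildcards():
    cfg = SynthConfig(
        species=[_tpl("sp", 3, 6)],
        type_series=[TypeSeriesSpec("t1", "sp", 2)],
        seed=2,
    )
    m, truth = simulate_morpho(cfg)
    typed = [r for r in m.records if r.type_status is not TypeStatus.NONE]
    assert len(typed) == 2
    assert {r.type_series_id for r in typed} == {"t1"}
    assert all(r.qualitative_label is None for r in typed)
    assert all(truth.species_of_specimen[r.specimen_id] == "sp" for r in typed)


def test_jc_helpers_are_inverse():
    for p in (0.001, 0.01, 0.2, 0.5):
        assert jc_expected_p(jc_branch_for_p(p)) == pytest.approx(p)
    with pytest.raises(ValueError):
        jc_branch_for_p(0.8)


def test_zero_depth_sequences_are_identical():
    cfg = SynthConfig(species=[_tpl("a"), _tpl("b")], seq_length=120,
                      seqs_per_species={"a": 3, "b": 3},
                      intra_p=0.0, inter_p=0.0, n_outgroups=0, seed=4)
    # a zero-divergence star tree is degenerate for the builder; build by hand
    cfg.species_tree = "(a:0.0,b:0.0);"
    aln, spmap, tree, _ = simulate_sequences(cfg)
    residues = {s.residues for s in aln.sequences}
    assert len(residues) == 1


def test_divergence_out_of_jc_range_is_config_error():
    cfg = SynthConfig(species=[_tpl("a"), _tpl("b")], intra_p=0.8, seed=0)
    with pytest.raises(ValueError):
        simulate_sequences(cfg)


def test_intra_inter_calibration_recovered_over_seeds():
    """JC simulation hits the generator's divergence targets within 0.3 points."""
    intras, inters = [], []
    for seed in range(10):
        cfg = SynthConfig(
            species=[_tpl("a"), _tpl("b")], seq_length=500,
            seqs_per_species={"a": 8, "b": 8},
            intra_p=0.005, inter_p=0.035, n_outgroups=0, seed=seed,
        )
        aln, spmap, tree, _ = simulate_sequences(cfg)
        tbl = intra_inter(p_distance(aln), spmap)
        intras += list(tbl["intra_dist_pct"])
        inters += list(tbl["inter_dist_closest_pct"])
    assert abs(np.mean(intras) - 0.5) < 0.3
    assert abs(np.mean(inters) - 3.5) < 0.3


def test_exact_duplicates_collapse_and_truth_stays_consistent():
    cfg = SynthConfig(species=[_tpl("a"), _tpl("b")], seq_length=200,
                      seqs_per_species={"a": 3, "b": 3},
                      n_duplicate_seqs=2, n_outgroups=2, seed=6)
    aln, spmap, tree, truth = simulate_sequences(cfg)
    assert len(aln.ingroup()) == 8
    ded, idmap = dedup_haplotypes(aln.ingroup())
    assert len(ded) <= 6
    for orig, rep in idmap.items():
        assert truth.species_of_sequence[orig] == truth.species_of_sequence[rep]


def test_study_preset_shape(study_bundle):
    morpho, aln, spmap, tree, truth = study_bundle
    assert aln.length == 658
    assert len(aln) == 91 and len(aln.ingroup()) == 89
    by_sp = {}
    for sid, sp in spmap.items():
        by_sp[sp] = by_sp.get(sp, 0) + 1
    assert by_sp["makay"] == 3
    assert sum(by_sp.values()) == 89
    # the true tree covers every sequence plus the outgroups
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    assert set(spmap) <= leaves
    assert {"OUTGROUP1", "OUTGROUP2"} <= leaves
    cfg = study_preset(0)
    assert sum(t.n_specimens for t in cfg.species) == 177
    assert sum(t.n_nests for t in cfg.species) == 96
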