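"""Evidence reconciliation: lump/add rules, stopping rule, pipeline driver."""

import numpy as np
import pandas as pd
import pytest

from delimita.io import MorphoMatrix, read_newick
from delimita.integrate import (
    EvidenceBundle,
    reconcile,
    run_pipeline,
    stopping_rule,
)
from delimita.part import Partition
from delimita.synth import SpeciesTemplate, SynthConfig, simulate_morpho
from delimita.morphometry import CWB_RATIOS


def _tpl(name, mean, n_nests=10, n_specimens=20, sd=0.04):
    means = {r: mean for r in CWB_RATIOS}
    return SpeciesTemplate(name, n_nests, n_specimens, 1000.0 + 400 * mean, 15.0,
                           means, {r: sd for r in CWB_RATIOS})


def _bundle(rng_seed=0, clusters_per_nest=None, tree_newick=None, species=None):
    """A small two-species world with direct control over the partition."""
    cfg = SynthConfig(species=species or [_tpl("alpha", 0.4), _tpl("beta", 0.9)],
                      seed=rng_seed)
    morpho, truth = simulate_morpho(cfg)
    nests = list(dict.fromkeys(r.nest_code for r in morpho.records))
    if clusters_per_nest is None:
        # concordant partition: one cluster per species
        sp_of_nest = {n: truth.species_of_specimen[
            next(r.specimen_id for r in morpho.records if r.nest_code == n)] for n in nests}
        ids = {sp: i + 1 for i, sp in enumerate(sorted(set(sp_of_nest.values())))}
        clusters_per_nest = {n: ids[sp_of_nest[n]] for n in nests}
    p = Partition(clusters_per_nest, "hierarchical", 5, 0)
    tree = read_newick(tree_newick) if tree_newick else None
    # sequence ids: first two specimens of each species
    spec_by_sp = {}
    for r in morpho.records:
        spec_by_sp.setdefault(truth.species_of_specimen[r.specimen_id], []).append(r.specimen_id)
    linkage = {}
    if tree is not None:
        leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
        linkage = {sid: sid for sid in leaves if any(sid in v for v in spec_by_sp.values())}
    return morpho, truth, EvidenceBundle(
        morpho, {"hierarchical": p}, None, tree, linkage), spec_by_sp


def test_concordant_evidence_passes_through():
    morpho, truth, bundle, _ = _bundle()
    hyp = reconcile(bundle, minsize=5)
    assert sorted(hyp.species) == ["alpha", "beta"]
    assert all(hyp.labels[s] == truth.species_of_specimen[s] for s in hyp.labels)
    assert all(d["status"] == "confirmed" for d in hyp.provenance.values())
    assert hyp.loocv_pct == 100.0


def test_reconcile_is_deterministic_and_stable():
    _, _, bundle, _ = _bundle()
    h1 = reconcile(bundle, minsize=5)
    h2 = reconcile(bundle, minsize=5)
    assert h1.labels == h2.labels
    # provenance conservation: every specimen labeled, none invented
    assert set(h1.labels) == {r.specimen_id for r in bundle.morpho.records}


def test_rule_l_lumps_clusters_sharing_a_clade():
    """Morphometric sub-structure without molecular distinction collapses."""
    morpho, truth, bundle, spec_by_sp = _bundle()
    nests = list(dict.fromkeys(r.nest_code for r in morpho.records))
    # split alpha's nests into two artificial clusters (1, 2); beta = 3
    sp_of_nest = {n: truth.species_of_specimen[
        next(r.specimen_id for r in morpho.records if r.nest_code == n)] for n in nests}
    alpha_nests = [n for n in nests if sp_of_nest[n] == "alpha"]
    cl = {}
    for n in nests:
        if sp_of_nest[n] == "beta":
            cl[n] = 3
        else:
            cl[n] = 1 if alpha_nests.index(n) % 2 == 0 else 2
    a = spec_by_sp["alpha"][:4]
    b = spec_by_sp["beta"][:4]
    newick = f"((({a[0]},{a[1]}),({a[2]},{a[3]})),({b[0]},({b[1]},({b[2]},{b[3]}))));"
    morpho2, truth2, bundle2, _ = _bundle(clusters_per_nest=cl, tree_newick=newick)
    hyp = reconcile(bundle2, minsize=5)
    assert sorted(hyp.species) == ["alpha", "beta"]
    assert hyp.provenance["alpha"]["status"] == "lumped"
    assert len(hyp.provenance["alpha"]["lumped_from"]) == 2


def test_rule_a_adds_small_distinct_group():
    """Three specimens with their own label and clade become a species."""
    tiny = _tpl("gamma", 1.6, n_nests=1, n_specimens=3)
    species = [_tpl("alpha", 0.4), _tpl("beta", 0.9), tiny]
    cfg = SynthConfig(species=species, seed=1)
    morpho, truth = simulate_morpho(cfg)
    nests = list(dict.fromkeys(r.nest_code for r in morpho.records))
    sp_of_nest = {n: truth.species_of_specimen[
        next(r.specimen_id for r in morpho.records if r.nest_code == n)] for n in nests}
    # gamma's nest goes unrecognized (outlier 0), as below-minsize groups do
    ids = {"alpha": 1, "beta": 2, "gamma": 0}
    cl = {n: ids[sp_of_nest[n]] for n in nests}
    spec_by_sp = {}
    for r in morpho.records:
        spec_by_sp.setdefault(truth.species_of_specimen[r.specimen_id], []).append(r.specimen_id)
    a, b, g = (spec_by_sp[k] for k in ("alpha", "beta", "gamma"))
    newick = f"((({a[0]},{a[1]}),({b[0]},{b[1]})),({g[0]},({g[1]},{g[2]})));"
    tree = read_newick(newick)
    linkage = {sid: sid for sid in [*a[:2], *b[:2], *g]}
    bundle = EvidenceBundle(morpho, {"hierarchical": Partition(cl, "hierarchical", 5, 0)},
                            None, tree, linkage)
    hyp = reconcile(bundle, minsize=5)
    assert "gamma" in hyp.species
    assert hyp.provenance["gamma"]["status"] == "added_below_minsize"
    assert all(hyp.labels[s] == "gamma" for s in g)
    verdicts = stopping_rule(hyp, bundle)
    assert verdicts.loc["gamma", "verdict"] == "describe"
    assert "exception" in verdicts.loc["gamma", "note"]


def test_stopping_rule_verdicts():
    morpho, truth, bundle, spec_by_sp = _bundle()
    hyp = reconcile(bundle, minsize=5)
    verdicts = stopping_rule(hyp, bundle)
    assert (verdicts["verdict"] == "describe").all()


def test_stopping_rule_flags_molecular_conflict():
    """A species reported non-monophyletic is flagged, not described."""
    import dendropy

    morpho, truth, bundle, spec_by_sp = _bundle()
    hyp = reconcile(bundle, minsize=5)
    fake = pd.DataFrame(
        {"monophyletic": [False, True]}, index=["alpha", "beta"]
    )

    class FakeDelim:
        table = fake

    bundle.delim = FakeDelim()
    verdicts = stopping_rule(hyp, bundle)
    assert verdicts.loc["alpha", "verdict"] == "flag"
    assert verdicts.loc["beta", "verdict"] == "describe"


def test_run_pipeline_morpho_only(tmp_path):
    """The driver runs without molecular inputs and writes its artifacts."""
    cfg = SynthConfig(species=[_tpl("alpha", 0.4), _tpl("beta", 0.9)], seed=3)
    morpho, truth = simulate_morpho(cfg)
    hyp, art = run_pipeline(
        {"morpho": morpho, "params": {"B": 20, "kmax": 4, "seed": 5}},
        outdir=tmp_path / "out",
    )
    assert len(hyp.species) == 2
    assert hyp.loocv_pct == 100.0
    assert (tmp_path / "out" / "final_labels.tsv").exists()
    assert (tmp_path / "out" / "report.json").exists()
    assert (tmp_path / "out" / "dendro.nwk").exists()
    labels = pd.read_csv(tmp_path / "out" / "final_labels.tsv", sep="\t")
    assert len(labels) == len(morpho)


def test_run_pipeline_single_species_nothing_lumped():
    cfg = SynthConfig(species=[_tpl("solo", 0.5, n_nests=12, n_specimens=24)], seed=2)
    morpho, _ = simulate_morpho(cfg)
    hyp, art = run_pipeline({"morpho": morpho, "params": {"B": 20, "kmax": 4, "seed": 1}})
    assert len(hyp.species) == 1
    assert all(d["status"] != "lumped" for d in hyp.provenance.values())
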