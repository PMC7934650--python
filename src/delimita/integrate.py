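"""Reconciling morphometric, qualitative and molecular evidence.

Three rules produce the final species hypothesis:

* **Rule L (lump)** — morphometric clusters whose sequences do not form
  mutually exclusive monophyletic groups on the tree are merged into one
  species: sub-structure in shape without matching structure in the gene
  tree is treated as intraspecific variation.
* **Rule A (add)** — a specimen group too small for the clustering
  threshold (``minsize``) but distinct in both its qualitative label and
  its molecular clade is added as a species of its own.
* **Rule C (confirm)** — the final labeling is re-tested by leave-one-out
  cross-validated LDA; its success rate and confusion table travel with
  the hypothesis.

The stopping rule then issues a per-species verdict: *describe* when all
available evidence lines agree (with a recorded exception path for
species known only from a below-threshold sample), *flag* otherwise.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from delimita.io import (
    Alignment,
    MorphoMatrix,
    ValidationError,
    read_fasta_alignment,
    read_morpho_table,
    read_newick,
    write_newick,
)
from delimita.lda import classify_wildcards, fit_lda, loocv_success
from delimita.mol import DelimReport, delimitation_report, is_monophyletic
from delimita.morphometry import compute_ratios, summarize_groups, summary_table
from delimita.nc import cluster_dendrogram, nest_centroids, specimen_variables, standardize
from delimita.part import Partition, part, partition_concordance


@dataclass
class EvidenceBundle:
    morpho: MorphoMatrix
    partitions: dict[str, Partition]  # per base method, at nest level
    delim: DelimReport | None
    tree: dendropy.Tree | None
    specimen_to_seq: dict[str, str]  # measured specimen -> sequence id
    support_threshold: float = 0.95

    def qualitative(self) -> dict[str, str | None]:
        return {r.specimen_id: r.qualitative_label for r in self.morpho.records}


@dataclass
class SpeciesHypothesis:
    labels: dict[str, str]  # specimen -> final species
    provenance: dict[str, dict]  # species -> {status, ...}
    loocv_pct: float | None = None
    confusion: pd.DataFrame | None = None
    log: list[str] = field(default_factory=list)

    @property
    def species(self) -> list[str]:
        return sorted(set(self.labels.values()))


def _specimen_clusters(e: EvidenceBundle, method: str) -> dict[str, int]:
    """Propagate a nest-level partition to specimens via nest membership.

    ``method="consensus"`` intersects all available partitions: nests form a
    cluster only when every base method keeps them together, and cells below
    the minsize threshold become outliers.  Disagreement between the two
    base clusterers is thereby resolved toward the finer, agreed structure.
    """
    nest_of = {r.specimen_id: r.nest_code for r in e.morpho.records}
    if method == "consensus":
        parts = [e.partitions[m] for m in sorted(e.partitions)]
        if len(parts) == 1:
            method = parts[0].method
        else:
            minsize = parts[0].minsize
            cells: dict[tuple, list[str]] = {}
            outliers: list[str] = []
            for nest in dict.fromkeys(nest_of.values()):
                key = tuple(p.assignments.get(nest, 0) for p in parts)
                if all(k > 0 for k in key):
                    cells.setdefault(key, []).append(nest)
                else:
                    outliers.append(nest)
            assign: dict[str, int] = {n: 0 for n in outliers}
            cid = 1
            for key in sorted(cells):
                ok = len(cells[key]) >= minsize
                for n in cells[key]:
                    assign[n] = cid if ok else 0
                cid += ok
            return {sid: assign.get(nest, 0) for sid, nest in nest_of.items()}
    p = e.partitions[method]
    return {sid: p.assignments.get(nest, 0) for sid, nest in nest_of.items()}


def _cluster_sequences(e: EvidenceBundle, clusters: dict[str, int]) -> dict[int, set[str]]:
    tree_labels = (
        {lf.taxon.label for lf in e.tree.leaf_node_iter()} if e.tree is not None else set()
    )
    out: dict[int, set[str]] = {}
    for sid, cid in clusters.items():
        seq = e.specimen_to_seq.get(sid)
        if seq is not None and seq in tree_labels:
            out.setdefault(cid, set()).add(seq)
    return out


def _node_support_ok(tree: dendropy.Tree, members: set[str], threshold: float) -> bool:
    """Support of the node separating ``members``; missing support passes."""
    taxa = [t for t in tree.taxon_namespace if t.label in members]
    if len(taxa) < 2:
        return True
    node = tree.mrca(taxa=taxa)
    label = node.label
    if label is None:
        return True
    try:
        return float(label) >= threshold
    except ValueError:
        return True


def _majority_putative(
    e: EvidenceBundle, clusters: dict[str, int], cid: int
) -> str | None:
    """Majority a-priori (qualitative) species among a cluster's specimens."""
    qual = e.qualitative()
    labels = [qual[s] for s, c in clusters.items() if c == cid and qual.get(s)]
    if not labels:
        return None
    return pd.Series(labels).mode().iloc[0]


def _species_sequences(e: EvidenceBundle, clusters: dict[str, int]) -> dict[str, set[str]]:
    """Putative species -> sequence ids present on the tree."""
    tree_labels = (
        {lf.taxon.label for lf in e.tree.leaf_node_iter()} if e.tree is not None else set()
    )
    qual = e.qualitative()
    out: dict[str, set[str]] = {}
    for sid in clusters:
        q = qual.get(sid)
        seq = e.specimen_to_seq.get(sid)
        if q and seq and seq in tree_labels:
            out.setdefault(q, set()).add(seq)
    return out


def reconcile(
    e: EvidenceBundle, minsize: int = 5, primary_method: str = "consensus"
) -> SpeciesHypothesis:
    """Apply Rules L, A and C to an evidence bundle.

    Deterministic given its inputs; idempotent (re-running on the produced
    hypothesis changes nothing because lumping and adding are exhaustive on
    the first pass).  Every input specimen receives a final label; the
    labeling is finished by a discriminant confirmation pass (the final
    hypothesis is by definition the one confirmed by cross-validated LDA).
    """
    log: list[str] = []
    clusters = _specimen_clusters(e, primary_method)
    qual = e.qualitative()

    # ---- Rule L: merge morphometric clusters that the molecular evidence
    # does not keep apart.  Each cluster is anchored to its majority
    # a-priori species; two clusters merge when they anchor to the same
    # putative clade (shape sub-structure without molecular distinction) or
    # when their two putative species fail reciprocal monophyly or node
    # support on the tree.  Clusters without any anchor fall back to a
    # strict test on their own sequence sets.
    cluster_ids = sorted({c for c in clusters.values() if c > 0})
    merged: dict[int, int] = {c: c for c in cluster_ids}

    def find(c: int) -> int:
        while merged[c] != c:
            merged[c] = merged[merged[c]]
            c = merged[c]
        return c

    if e.tree is not None and cluster_ids:
        sp_seqs = _species_sequences(e, clusters)
        anchor = {c: _majority_putative(e, clusters, c) for c in cluster_ids}
        cl_seqs = _cluster_sequences(e, clusters)
        universe = set().union(*sp_seqs.values()) if sp_seqs else set()
        exclude_all = {lf.taxon.label for lf in e.tree.leaf_node_iter()} - universe

        def reciprocally_exclusive(s1: set[str], s2: set[str]) -> bool:
            if not s1 or not s2:
                return True  # no molecular evidence against separation
            local_exclude = exclude_all | (universe - s1 - s2)
            return (
                is_monophyletic(e.tree, s1, exclude=local_exclude)
                and is_monophyletic(e.tree, s2, exclude=local_exclude)
                and _node_support_ok(e.tree, s1, e.support_threshold)
                and _node_support_ok(e.tree, s2, e.support_threshold)
            )

        for i, c1 in enumerate(cluster_ids):
            for c2 in cluster_ids[i + 1 :]:
                a1, a2 = anchor[c1], anchor[c2]
                if a1 is not None and a1 == a2:
                    merge, why = True, f"both anchor to putative '{a1}'"
                elif a1 is not None and a2 is not None:
                    merge = not reciprocally_exclusive(sp_seqs.get(a1, set()), sp_seqs.get(a2, set()))
                    why = f"putative '{a1}' and '{a2}' not reciprocally monophyletic"
                else:
                    merge = not reciprocally_exclusive(cl_seqs.get(c1, set()), cl_seqs.get(c2, set()))
                    why = "cluster sequence sets not reciprocally monophyletic"
                if merge:
                    if find(c1) != find(c2):
                        log.append(f"Rule L: clusters {c1} + {c2} merged ({why})")
                    merged[find(c2)] = find(c1)
        for c in cluster_ids:
            merged[c] = find(c)
        for c in cluster_ids:
            if not cl_seqs.get(c) and anchor[c] is None:
                log.append(f"cluster {c}: molecular evidence missing; left unlumped")
    groups: dict[int, list[int]] = {}
    for c in cluster_ids:
        groups.setdefault(merged[c], []).append(c)

    # ---- name species groups by majority qualitative label
    labels: dict[str, str] = {}
    provenance: dict[str, dict] = {}
    for root_c, members_c in sorted(groups.items()):
        specs = [sid for sid, c in clusters.items() if c in members_c]
        quals = [qual[s] for s in specs if qual.get(s)]
        name = (
            pd.Series(quals).mode().iloc[0]
            if quals
            else f"cluster_{root_c}"
        )
        base = name
        k = 2
        while name in provenance:  # two cluster groups sharing a majority label
            name = f"{base}_{k}"
            k += 1
        for s in specs:
            labels[s] = name
        provenance[name] = (
            {"status": "lumped", "lumped_from": sorted(members_c)}
            if len(members_c) > 1
            else {"status": "confirmed", "cluster": members_c[0]}
        )
        if len(members_c) > 1:
            log.append(f"Rule L: {sorted(members_c)} -> '{name}'")

    # ---- Rule A: small groups distinct in qualitative label AND molecular clade.
    # Candidates are qualitative labels not carried by any recognized species:
    # a below-minsize group may sit in the outlier class or be absorbed into a
    # larger cluster, having gone unrecognized by the gap statistic either way.
    by_qual: dict[str, list[str]] = {}
    for sid in clusters:
        q = qual.get(sid)
        if q and q not in provenance:
            by_qual.setdefault(q, []).append(sid)
    for q, specs in sorted(by_qual.items()):
        if len(specs) >= minsize:
            continue  # not a below-threshold case; leave to LDA placement
        seqs = {e.specimen_to_seq[s] for s in specs if e.specimen_to_seq.get(s)}
        if e.tree is not None and seqs:
            tree_labels = {lf.taxon.label for lf in e.tree.leaf_node_iter()}
            seqs = seqs & tree_labels
        if not seqs or e.tree is None:
            log.append(f"Rule A candidate '{q}': no molecular evidence; not added")
            continue
        if is_monophyletic(e.tree, seqs, exclude=set()):
            for s in specs:
                labels[s] = q
            provenance[q] = {"status": "added_below_minsize", "n": len(specs)}
            log.append(f"Rule A: '{q}' ({len(specs)} specimens) added as species")
        else:
            log.append(f"Rule A candidate '{q}': sequences not monophyletic; not added")

    # ---- place remaining outliers with the discriminant
    x = specimen_variables(e.morpho)
    leftover = [sid for sid in clusters if sid not in labels]
    if leftover:
        model = fit_lda(x.loc[[s for s in x.index if s in labels]],
                        {s: labels[s] for s in labels})
        post = model.posteriors(x.loc[leftover])
        for sid in leftover:
            labels[sid] = str(post.loc[sid].idxmax())
        log.append(f"{len(leftover)} outlier specimens placed by LDA posterior")

    # ---- confirmation pass: the final labeling is the fixed point that
    # survives reclassification by the discriminant trained on itself —
    # the hypothesis the cross-validated LDA actually confirms
    for _ in range(5):
        lab = pd.Series(labels)
        if lab.nunique() < 2 or lab.value_counts().min() < 2:
            break
        model = fit_lda(x.loc[lab.index], lab)
        pred = model.posteriors(x.loc[lab.index]).idxmax(axis=1)
        changed = [s for s in lab.index if str(pred[s]) != labels[s]]
        if not changed:
            break
        if set(pred.unique()) < set(lab.unique()):
            break  # a pass may not erase a species outright
        for s in changed:
            labels[s] = str(pred[s])
        log.append(f"confirmation pass moved {len(changed)} specimens")

    # ---- Rule C
    if len(set(labels.values())) >= 2:
        loocv_pct, confusion = loocv_success(x, labels)
        log.append(f"Rule C: LOOCV success {loocv_pct:.1f}%")
    else:
        loocv_pct, confusion = None, None
        log.append("Rule C skipped: single-species hypothesis")
    return SpeciesHypothesis(labels, provenance, loocv_pct, confusion, log)


def stopping_rule(
    h: SpeciesHypothesis,
    e: EvidenceBundle,
    primary_method: str = "consensus",
    supermajority: float = 0.8,
) -> pd.DataFrame:
    """Per-species verdict: describe iff all available evidence lines agree.

    *morphometric* line: the species owns (is the majority of) at least one
    non-outlier cluster and nearly all its specimens sit in clusters it
    owns; absent when the species' sample went mostly unrecognized (below
    the minsize threshold);
    *qualitative* line: nearly all the species' specimens share one
    qualitative label and nearly all bearers of that label are in the
    species;
    *molecular* line: the species is monophyletic in the delimitation
    report (absent when unsequenced).

    "Nearly all" is the ``supermajority`` fraction (default four-fifths) —
    evidence lines are judged at the level of clusters and labels, not
    individual boundary specimens.

    A species with the morphometric line absent (below-threshold sample)
    but the other two agreeing is described with an exception note.
    """
    clusters = _specimen_clusters(e, primary_method)
    qual = e.qualitative()
    rows = []
    sp_of = h.labels
    majority_of_cluster: dict[int, str] = {}
    for cid in {c for c in clusters.values() if c > 0}:
        members = [sp_of[s] for s, c in clusters.items() if c == cid and s in sp_of]
        if members:
            majority_of_cluster[cid] = pd.Series(members).mode().iloc[0]
    for species_name in h.species:
        specs = [s for s, lab in sp_of.items() if lab == species_name]
        owned = {c for c, m in majority_of_cluster.items() if m == species_name}
        n_outlier = sum(clusters[s] == 0 for s in specs)
        n_owned = sum(clusters[s] in owned for s in specs)
        morpho_line: bool | None
        if n_outlier > 0.5 * len(specs) or not any(clusters[s] > 0 for s in specs):
            morpho_line = None
        elif owned and n_owned >= supermajority * (len(specs) - n_outlier):
            morpho_line = True
        else:
            morpho_line = False

        own_quals = [qual[s] for s in specs if qual.get(s)]
        if not own_quals:
            qual_line = None
        else:
            top = pd.Series(own_quals).mode().iloc[0]
            bearers = [s for s in sp_of if qual.get(s) == top]
            qual_line = (
                own_quals.count(top) >= supermajority * len(own_quals)
                and sum(sp_of[s] == species_name for s in bearers)
                >= supermajority * len(bearers)
            )

        mol_line: bool | None = None
        if e.delim is not None and species_name in e.delim.table.index:
            mono = e.delim.table.loc[species_name, "monophyletic"]
            mol_line = None if mono is None else bool(mono)
        elif e.tree is not None:
            tree_labels = {lf.taxon.label for lf in e.tree.leaf_node_iter()}
            seqs = {e.specimen_to_seq[s] for s in specs
                    if e.specimen_to_seq.get(s) in tree_labels}
            if seqs:
                mol_line = is_monophyletic(e.tree, seqs, exclude=set())

        lines = {"morphometric": morpho_line, "qualitative": qual_line, "molecular": mol_line}
        available = {k: v for k, v in lines.items() if v is not None}
        if available and all(available.values()):
            verdict = "describe"
            note = ""
            if morpho_line is None and qual_line and mol_line:
                note = "exception: below-minsize sample; qualitative + molecular agreement"
        else:
            verdict = "flag"
            note = "disagreement: " + ", ".join(k for k, v in available.items() if not v)
        rows.append({"species": species_name, **lines, "verdict": verdict, "note": note})
    return pd.DataFrame(rows).set_index("species")


# ---------------------------------------------------------------------------
# pipeline driver


DEFAULT_PARAMS = {
    "variables": "ratios",
    "linkage": "ward",
    "minsize": 5,
    "B": 100,
    "kmax": 10,
    "seed": 0,
    "priors": "uniform",
    "pid_mode": "empirical",
    "support_threshold": 0.95,
}


def run_pipeline(config: dict | str | Path, outdir: str | Path | None = None):
    """Execute the whole analysis from a config mapping (or YAML path).

    Config keys: ``traits`` (CSV/TSV path) or ``morpho`` (a MorphoMatrix),
    ``alignment``/``fasta`` path or object, ``species_map`` (seq id ->
    putative species, or TSV path), ``outgroups`` (ids), optional ``tree``
    (Newick path or object), ``specimen_to_seq`` map (defaults to identity
    on shared ids), and ``params`` overriding :data:`DEFAULT_PARAMS`.

    Returns ``(SpeciesHypothesis, artifacts dict)`` and, when ``outdir`` is
    given, writes final_labels.tsv, table2.tsv, table3.tsv, dendro.nwk,
    report.json and the effective config.
    """
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    params = {**DEFAULT_PARAMS, **config.get("params", {})}

    morpho: MorphoMatrix = (
        config["morpho"] if "morpho" in config else read_morpho_table(config["traits"])
    )

    # ---- morphometrics
    cent = standardize(nest_centroids(morpho, variables=params["variables"]))
    dendro = cluster_dendrogram(cent, linkage=params["linkage"])
    partitions = {
        m: part(cent, method=m, minsize=params["minsize"], B=params["B"],
                kmax=params["kmax"], seed=params["seed"])
        for m in ("hierarchical", "kmeans")
    }
    concordance = partition_concordance(partitions["hierarchical"], partitions["kmeans"])

    # ---- molecular
    aln: Alignment | None = None
    delim = None
    tree = None
    if "alignment" in config or "fasta" in config:
        src = config.get("alignment", config.get("fasta"))
        outgroups = list(config.get("outgroups", []))
        aln = src if isinstance(src, Alignment) else read_fasta_alignment(src, outgroup_ids=outgroups)
        spmap = config["species_map"]
        if not isinstance(spmap, dict):
            df = pd.read_csv(spmap, sep="\t")
            spmap = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))
        tree = config.get("tree")
        if tree is not None and not isinstance(tree, dendropy.Tree):
            tree = read_newick(tree)
        delim = delimitation_report(aln, spmap, tree=tree, pid_mode=params["pid_mode"])
        tree = delim.tree

    specimen_to_seq = config.get("specimen_to_seq")
    if specimen_to_seq is None:
        seq_ids = set(aln.ids) if aln is not None else set()
        specimen_to_seq = {r.specimen_id: r.specimen_id for r in morpho.records
                           if r.specimen_id in seq_ids}

    bundle = EvidenceBundle(
        morpho=morpho,
        partitions=partitions,
        delim=delim,
        tree=tree,
        specimen_to_seq=specimen_to_seq,
        support_threshold=params["support_threshold"],
    )
    hypothesis = reconcile(bundle, minsize=params["minsize"])
    verdicts = stopping_rule(hypothesis, bundle)

    # ---- confirmatory extras: wildcard typing if type specimens flagged
    wildcard_reports = None
    series_assignments = None
    typed = [r for r in morpho.records if r.type_status.value != "none"]
    if typed:
        x = specimen_variables(morpho, params["variables"])
        train_ids = [r.specimen_id for r in morpho.records if r.type_status.value == "none"]
        model = fit_lda(x.loc[train_ids],
                        {s: hypothesis.labels[s] for s in train_ids}, priors=params["priors"])
        series = {r.specimen_id: (r.type_series_id or r.specimen_id) for r in typed}
        wildcard_reports, series_assignments = classify_wildcards(
            model, x.loc[[r.specimen_id for r in typed]], series
        )

    summaries = summarize_groups(compute_ratios(morpho), hypothesis.labels)
    artifacts = {
        "centroids": cent,
        "dendrogram": dendro,
        "partitions": partitions,
        "concordance": concordance,
        "delim": delim,
        "tree": tree,
        "verdicts": verdicts,
        "summaries": summaries,
        "wildcards": wildcard_reports,
        "series": series_assignments,
        "params": params,
    }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(hypothesis.labels, name="species").rename_axis("specimen_id").to_csv(
            outdir / "final_labels.tsv", sep="\t"
        )
        if delim is not None:
            delim.table.to_csv(outdir / "table2.tsv", sep="\t")
            write_newick(delim.tree, outdir / "tree.nwk")
        summary_table(summaries).to_csv(outdir / "table3.tsv", sep="\t")
        (outdir / "dendro.nwk").write_text(dendro.to_newick() + "\n")
        report = {
            "species": hypothesis.species,
            "provenance": hypothesis.provenance,
            "loocv_pct": hypothesis.loocv_pct,
            "concordance": concordance,
            "verdicts": json.loads(verdicts.to_json(orient="index")),
            "log": hypothesis.log,
            "params": params,
        }
        (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return hypothesis, artifacts
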