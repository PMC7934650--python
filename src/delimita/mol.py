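"""COI-based species delimitation metrics.

Putative species (assigned a priori from morphology) are tested on a
mitochondrial alignment: haplotype deduplication, uncorrected p-distances
with pairwise deletion of gaps and ambiguous sites, monophyly on a rooted
tree, mean intra- and closest-interspecific divergence, PID (Liberal) —
the probability that an unknown sequence is identified as its species or
that species' sister — and Rosenberg's P(AB), the probability that
reciprocal monophyly of two groups arises by chance on a random labeled
topology.

A species passes when it is monophyletic, intra < inter, PID is high and
P(AB) is small.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from delimita.io import Alignment, Role, SequenceRecord, ValidationError

# ---------------------------------------------------------------------------
# haplotypes and distances

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4, "N": 5}


def _encode(a: Alignment) -> np.ndarray:
    return np.array([[_CODE[ch] for ch in s.residues] for s in a.sequences], dtype=np.int8)


def dedup_haplotypes(a: Alignment) -> tuple[Alignment, dict[str, str]]:
    """Collapse sequences identical over all columns.

    The representative of each haplotype is its first occurrence in input
    order; the returned map sends every original id to its representative.
    """
    reps: dict[str, SequenceRecord] = {}
    id_map: dict[str, str] = {}
    for s in a.sequences:
        key = s.residues
        if key not in reps:
            reps[key] = s
        id_map[s.seq_id] = reps[key].seq_id
    return Alignment(list(reps.values())), id_map


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray  # proportions in [0,1]; NaN where no comparable sites
    comparable: np.ndarray  # per-pair count of pairwise-complete columns

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def get(self, i: str, j: str) -> float:
        return float(self.frame().loc[i, j])


def p_distance(a: Alignment) -> DistanceMatrix:
    """Uncorrected pairwise distances with pairwise deletion.

    A column enters a pair's comparison only when both residues are plain
    nucleotides; gaps ('-') and missing data ('N') are deleted pairwise.
    A pair with zero comparable columns is undefined (NaN) and excluded
    from any downstream average.
    """
    enc = _encode(a)
    valid = enc <= 3  # A/C/G/T
    n = len(enc)
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    undefined = []
    for i in range(n):
        both = valid[i] & valid[i + 1 :]
        diff = (enc[i] != enc[i + 1 :]) & both
        counts = both.sum(axis=1)
        comp[i, i + 1 :] = comp[i + 1 :, i] = counts
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(counts > 0, diff.sum(axis=1) / np.maximum(counts, 1), np.nan)
        d[i, i + 1 :] = d[i + 1 :, i] = vals
        for j_off, cnt in enumerate(counts):
            if cnt == 0:
                undefined.append((a.ids[i], a.ids[i + 1 + j_off]))
    comp[np.diag_indices(n)] = valid.sum(axis=1)
    if undefined:
        warnings.warn(f"pairs with no comparable sites (excluded from averages): {undefined}")
    return DistanceMatrix(list(a.ids), d, comp)


# ---------------------------------------------------------------------------
# trees


def nj_tree(d: DistanceMatrix, outgroup_ids: list[str]) -> dendropy.Tree:
    """Neighbor-joining tree rooted on the outgroup.

    A desk-scale stand-in for a Bayesian consensus tree: any rooted Newick
    can be supplied to the report instead.  Ids are presented to the NJ
    implementation in lexicographic order so ties resolve reproducibly.
    """
    if np.isnan(d.d).any():
        pairs = [
            (d.ids[i], d.ids[j])
            for i, j in zip(*np.where(np.isnan(d.d)))
            if i < j
        ]
        raise ValidationError(f"undefined distances for pairs {pairs}")
    if len(d.ids) < 3:
        raise ValidationError("NJ needs at least 3 taxa")
    missing_og = [o for o in outgroup_ids if o not in d.ids]
    if missing_og or not outgroup_ids:
        raise ValidationError(f"outgroup not in matrix: {missing_og or outgroup_ids}")

    order = sorted(range(len(d.ids)), key=lambda i: d.ids[i])
    ids = [d.ids[i] for i in order]
    mat = d.d[np.ix_(order, order)]

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        src=_matrix_csv(ids, mat), delimiter=","
    )
    tree = pdm.nj_tree()
    tree.is_rooted = True

    taxa = {t.label: t for t in tree.taxon_namespace}
    og_taxa = [taxa[o] for o in outgroup_ids]
    if len(og_taxa) == 1:
        node = tree.find_node_with_taxon_label(outgroup_ids[0])
    else:
        node = tree.mrca(taxa=og_taxa)
        if node is tree.seed_node:
            node = tree.find_node_with_taxon_label(outgroup_ids[0])
    tree.reroot_at_edge(node.edge, update_bipartitions=True)
    return tree


def _matrix_csv(ids: list[str], mat: np.ndarray):
    import io as _io

    lines = ["," + ",".join(ids)]
    for i, name in enumerate(ids):
        lines.append(name + "," + ",".join(f"{v:.12g}" for v in mat[i]))
    return _io.StringIO("\n".join(lines))


def is_monophyletic(tree: dendropy.Tree, members: set[str], exclude: set[str] = frozenset()) -> bool:
    """True iff the smallest clade containing ``members`` is exactly them.

    ``exclude`` (normally the outgroup ids) is removed from the leaf
    universe before the test.
    """
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    unknown = set(members) - labels
    if unknown:
        raise ValidationError(f"members not in tree: {sorted(unknown)}")
    universe = labels - set(exclude)
    members = set(members) & universe
    if len(members) <= 1:
        return True
    taxa = [t for t in tree.taxon_namespace if t.label in members]
    mrca = tree.mrca(taxa=taxa)
    clade = {lf.taxon.label for lf in mrca.leaf_iter()} & universe
    return clade == members


def sister_group(tree: dendropy.Tree, members: set[str], exclude: set[str] = frozenset()) -> set[str]:
    """Leaves of the sister clade of ``members``' MRCA (ingroup only)."""
    taxa = [t for t in tree.taxon_namespace if t.label in members]
    mrca = tree.mrca(taxa=taxa) if len(taxa) > 1 else tree.find_node_with_taxon_label(next(iter(members)))
    parent = mrca.parent_node
    if parent is None:
        return set()
    sis = set()
    for child in parent.child_nodes():
        if child is not mrca:
            sis |= {lf.taxon.label for lf in child.leaf_iter()}
    return sis - set(exclude)


# ---------------------------------------------------------------------------
# intra / inter / PID


def intra_inter(
    d: DistanceMatrix, species: dict[str, str]
) -> pd.DataFrame:
    """Mean within-species and closest mean between-species p-distance, in %.

    ``species`` maps sequence id -> putative species (ids absent from the
    map are ignored, e.g. outgroups).  Intra is blank (NaN) for singleton
    species.  Undefined pairs are excluded from every average.
    """
    by_sp: dict[str, list[int]] = {}
    for i, sid in enumerate(d.ids):
        sp = species.get(sid)
        if sp is not None:
            by_sp.setdefault(sp, []).append(i)
    if len(by_sp) < 2:
        raise ValidationError("need at least 2 species")
    rows = []
    for sp, idx in by_sp.items():
        if len(idx) > 1:
            block = d.d[np.ix_(idx, idx)]
            vals = block[np.triu_indices(len(idx), k=1)]
            intra = float(np.nanmean(vals)) * 100.0
        else:
            intra = float("nan")
        best_sp, best = None, float("inf")
        for other, odx in by_sp.items():
            if other == sp:
                continue
            mean = float(np.nanmean(d.d[np.ix_(idx, odx)])) * 100.0
            if mean < best:
                best, best_sp = mean, other
        rows.append({"species": sp, "n": len(idx), "intra_dist_pct": intra,
                     "inter_dist_closest_pct": best, "closest_species": best_sp})
    return pd.DataFrame(rows).set_index("species")


def pid_liberal(intra: float, inter: float, n: int, length: int = 658) -> tuple[float, float, float]:
    """Predictive PID (Liberal): mean and 95% CI.

    Site-count model: the number of differences between a query and a
    conspecific is X ~ Poisson(L*intra) and to the sister species
    Y ~ Poisson(L*inter); the query is identified correctly when X < Y
    (ties split evenly).  ``intra``/``inter`` are proportions in [0,1]
    (divide Table-style percentages by 100).  The CI treats the mean as a
    binomial proportion observed on the species' n members (Wilson).

    Monotone non-increasing in intra/inter; tends to 1 as intra -> 0 with
    inter large.
    """
    if inter <= 0:
        raise ValidationError("PID undefined for inter <= 0")
    mu_x, mu_y = length * intra, length * inter
    if not np.isfinite(mu_x) or mu_x < 0:
        mu_x = 0.0
    if mu_x == 0.0:
        # conspecific distance is exactly zero: correct unless Y ties at 0
        p = 1.0 - 0.5 * math.exp(-mu_y)
    else:
        # P(X < Y) + 0.5 P(X = Y) with X-Y ~ Skellam(mu_x, mu_y)
        p = float(stats.skellam.cdf(-1, mu_x, mu_y) + 0.5 * stats.skellam.pmf(0, mu_x, mu_y))
    lo, hi = _wilson(p, max(n, 1))
    return p, lo, hi


def _wilson(p: float, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * np.sqrt(max(p * (1 - p), 0.0) / n + z * z / (4 * n * n)) / denom
    # rounding must not push the interval off the point estimate
    return max(0.0, min(centre - half, p)), min(1.0, max(centre + half, p))


def pid_liberal_empirical(
    d: DistanceMatrix, species: dict[str, str], target: str, sister: str | None = None
) -> tuple[float, float, float]:
    """Empirical PID (Liberal): leave-one-out nearest-neighbour frequency.

    Each member of ``target`` is queried against all other mapped
    sequences; the identification is correct when the nearest neighbour
    belongs to the target species or to ``sister`` (defaulting to the
    closest species by mean distance).  Returns mean and Wilson 95% CI.
    """
    idx = {sid: i for i, sid in enumerate(d.ids)}
    members = [sid for sid in d.ids if species.get(sid) == target]
    if not members:
        raise ValidationError(f"no sequences mapped to {target!r}")
    if sister is None:
        tbl = intra_inter(d, species)
        sister = tbl.loc[target, "closest_species"]
    allowed = {target, sister}
    others = [sid for sid in d.ids if species.get(sid) is not None]
    correct = 0
    usable = 0
    for sid in members:
        dists = [(d.d[idx[sid], idx[o]], o) for o in others if o != sid]
        dists = [(v, o) for v, o in dists if np.isfinite(v)]
        if not dists:
            continue
        usable += 1
        best = min(v for v, _ in dists)
        nn_species = {species[o] for v, o in dists if v == best}
        if nn_species <= allowed:
            correct += 1
    if usable == 0:
        raise ValidationError("no usable comparisons")
    p = correct / usable
    lo, hi = _wilson(p, usable)
    return p, lo, hi


# ---------------------------------------------------------------------------
# Rosenberg's P(AB)


def _double_factorial(m: int) -> int:
    out = 1
    while m > 1:
        out *= m
        m -= 2
    return out


def n_rooted_topologies(n: int) -> int:
    """(2n-3)!! rooted, binary, labeled topologies on n tips (1 for n<=1)."""
    if n <= 1:
        return 1
    return _double_factorial(2 * n - 3)


def rosenberg_pab(a: int, b: int) -> Fraction:
    """Probability of reciprocal monophyly of two groups by chance.

    Two disjoint groups of sizes a and b covering all a+b tips are
    reciprocally monophyletic on a rooted binary topology exactly when the
    root splits them, so among equiprobable labeled topologies
    P = T(a) * T(b) / T(a+b) with T(n) = (2n-3)!!.  Exact rational result.
    """
    if a < 1 or b < 1:
        raise ValidationError("group sizes must be >= 1")
    return Fraction(n_rooted_topologies(a) * n_rooted_topologies(b), n_rooted_topologies(a + b))


@lru_cache(maxsize=8)
def _all_topologies(n: int):
    """All rooted binary labeled topologies on tips 0..n-1, as nested frozensets.

    Built by sequential tip insertion: every tree on k tips yields trees on
    k+1 tips by attaching the new tip on each edge (including above the
    root), giving the (2k-1) factor of the double factorial.
    """

    def insert(tree, tip):
        # attach at the root
        yield frozenset((tree, tip))
        if isinstance(tree, frozenset):
            left, right = tuple(tree)
            for sub in insert(left, tip):
                yield frozenset((sub, right))
            for sub in insert(right, tip):
                yield frozenset((left, sub))

    trees = [0]
    for tip in range(1, n):
        trees = [t for base in trees for t in insert(base, tip)]
    return trees


def _clades(tree, acc: list[frozenset]) -> frozenset:
    if not isinstance(tree, frozenset):
        return frozenset((tree,))
    left, right = tuple(tree)
    tips = _clades(left, acc) | _clades(right, acc)
    acc.append(tips)
    return tips


def enumerate_pab_oracle(a: int, b: int) -> Fraction:
    """Exhaustive-enumeration oracle for :func:`rosenberg_pab`.

    Walks every (2n-3)!! rooted labeled topology and counts those where
    tip sets {0..a-1} and {a..a+b-1} are both clades.  Refuses beyond
    a+b = 9 tips (combinatorial blow-up).
    """
    n = a + b
    if n > 9:
        raise ValidationError("enumeration oracle limited to a+b <= 9")
    if n == 1:
        return Fraction(1)
    group_a = frozenset(range(a))
    group_b = frozenset(range(a, n))
    hits = 0
    total = 0
    for tree in _all_topologies(n):
        total += 1
        acc: list[frozenset] = []
        _clades(tree, acc)
        clades = set(acc)
        ok_a = a == 1 or group_a in clades
        ok_b = b == 1 or group_b in clades
        hits += ok_a and ok_b
    assert total == n_rooted_topologies(n)
    return Fraction(hits, total)


# ---------------------------------------------------------------------------
# report


@dataclass
class DelimReport:
    table: pd.DataFrame  # index: species; Table-2-style columns
    tree: dendropy.Tree
    n_haplotypes: int

    def __str__(self) -> str:
        return self.table.to_string()


def delimitation_report(
    a: Alignment,
    species: dict[str, str],
    tree: dendropy.Tree | None = None,
    dedup: bool = True,
    pid_mode: str = "empirical",
) -> DelimReport:
    """Per-species delimitation metrics on the (deduplicated) ingroup.

    ``species`` maps ingroup sequence ids to putative species.  When
    ``tree`` is None a neighbor-joining tree rooted on the alignment's
    outgroup sequences is built.  P(AB) uses a = species size and
    b = size of the tree sister group (ingroup leaves only).
    """
    outgroups = [s.seq_id for s in a.sequences if s.role is Role.OUTGROUP]
    unmapped = [s.seq_id for s in a.sequences if s.role is Role.INGROUP and s.seq_id not in species]
    if unmapped:
        raise ValidationError(f"ingroup sequences without species mapping: {unmapped}")

    work = a
    sp = dict(species)
    if dedup:
        ingroup_dedup, id_map = dedup_haplotypes(a.ingroup())
        keep = {s.seq_id for s in ingroup_dedup.sequences}
        work = Alignment([s for s in a.sequences if s.seq_id in keep or s.role is Role.OUTGROUP])
        sp = {sid: lab for sid, lab in species.items() if sid in keep}

    d = p_distance(work)
    if tree is None:
        tree = nj_tree(d, outgroups)
    tree_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    # leaves outside the analyzed (deduplicated) set leave the monophyly universe
    universe_exclude = set(outgroups) | (tree_labels - set(sp))

    ingroup_ids = [s.seq_id for s in work.sequences if s.role is Role.INGROUP]
    d_in = p_distance(Alignment([s for s in work.sequences if s.role is Role.INGROUP]))
    tbl = intra_inter(d_in, sp)

    rows = []
    for species_name in tbl.index:
        members = {sid for sid in ingroup_ids if sp.get(sid) == species_name}
        present = members & tree_labels
        row: dict[str, object] = {
            "n": int(tbl.loc[species_name, "n"]),
            "intra_dist_pct": tbl.loc[species_name, "intra_dist_pct"],
            "inter_dist_closest_pct": tbl.loc[species_name, "inter_dist_closest_pct"],
            "closest_species": tbl.loc[species_name, "closest_species"],
        }
        if not present:
            row.update(monophyletic=None, pid_mean=np.nan, pid_lo=np.nan, pid_hi=np.nan,
                       rosenberg_pab=np.nan, incomplete=True)
            rows.append({"species": species_name, **row})
            continue
        row["incomplete"] = len(present) < len(members)
        row["monophyletic"] = is_monophyletic(tree, present, exclude=universe_exclude)
        if pid_mode == "empirical":
            pid, lo, hi = pid_liberal_empirical(
                d_in, sp, species_name, sister=str(tbl.loc[species_name, "closest_species"])
            )
        else:
            pid, lo, hi = pid_liberal(
                float(np.nan_to_num(tbl.loc[species_name, "intra_dist_pct"])) / 100.0,
                float(tbl.loc[species_name, "inter_dist_closest_pct"]) / 100.0,
                n=int(tbl.loc[species_name, "n"]),
                length=work.length,
            )
        row.update(pid_mean=pid, pid_lo=lo, pid_hi=hi)
        sis = sister_group(tree, present, exclude=universe_exclude)
        b = max(len(sis), 1)
        row["rosenberg_pab"] = float(rosenberg_pab(len(present), b))
        rows.append({"species": species_name, **row})

    table = pd.DataFrame(rows).set_index("species")
    return DelimReport(table, tree, n_haplotypes=len(ingroup_ids))
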