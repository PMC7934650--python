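# Methods

`delimita` implements an integrative species-delimitation pipeline for
nest-structured morphometric data and mitochondrial (COI) barcodes, of the
kind used in quantitative ant taxonomy. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not establish.

## Data model

A *specimen* carries 16 continuous worker measurements in micrometres
(head, mesosoma, waist and spine dimensions; `CWb`, maximum head width, is
the size reference), a *nest code* identifying the collecting event, an
optional qualitative species label (the a-priori hypothesis from external
characters), and a type status. Shape is expressed as the 15 ratios
`X/CWb`; `NOL/CWb` is the petiole-length trait `PEL` under its
ratio-table alias, and two further ratios (`CL/POOC`, `SPST/EL`) exist for
the identification key. Ratios are exact quotients; unit changes cancel.

## Nest-centroid clustering (NC)

Workers of one colony are near-replicates, so the statistical case is the
nest, not the individual. Specimen variables (default: the 15 CWb ratios
plus ln CWb as an explicit size axis; alternatively ln of the 16 raw
traits) are averaged per nest, z-scored per variable (sample SD; constant
variables dropped), and clustered by Ward's method on Euclidean
distances. Cases are processed in lexicographic order so equal-distance
merges are reproducible. A specimen missing a trait is excluded from that
variable's nest mean; a nest missing more than 25 % of variables is
dropped with a warning.

The ratio variable set is the default because the size axis (`CWb` spans
roughly 1.0–1.9 mm across these species, with large within-species spread)
otherwise leaks into all 16 log-trait coordinates and drowns the shape
signal that actually separates species.

## Cluster number: the gap statistic and PART

For a candidate partition into k groups, the within dispersion is
W_k = Σ_clusters Σ_i ||x_i − x̄_cluster||². The gap statistic compares
log W_k with its mean over B reference datasets drawn uniformly over the
per-variable range box of the data (`reference="box"`, default; a
PCA-rotated box is available for strongly correlated data):

    Gap(k) = (1/B) Σ_b log W*_kb − log W_k,
    s_k    = sd_b(log W*_kb) · sqrt(1 + 1/B),

and the chosen k is the smallest k with Gap(k) ≥ Gap(k+1) − s_{k+1}, else
kmax (the one-standard-error rule). Defaults: B = 100, kmax = 10, both
configurable; the Monte-Carlo seed is an explicit parameter recorded in
all outputs.

PART applies this recursively: estimate k on the current case set; if
k = 1, the set is a terminal cluster; otherwise split into k groups with
the base clusterer and recurse into every group with at least 2·minsize
cases (a smaller group could not yield two valid clusters). Terminal
groups smaller than `minsize` (default 5) are relabelled 0 — the outlier
class. Two base clusterers are provided: `hierarchical` (Ward cut into k
groups, followed by nearest-centroid relocation passes — agglomerative
cuts freeze early greedy merges, and relocation lets boundary cases cross
to the closer group and lets an over-cut fragment empty out) and `kmeans`
(Lloyd with 25 restarts, best inertia). Identical seeds give identical
partitions for both methods.

The recursion can only split, never merge, so a node that over-estimates
k leaves spurious sub-clusters behind. Two mechanisms downstream absorb
this: the consensus partition (below) and the molecular lump rule, which
merges morphometric sub-structure that the gene tree does not support.
This division of labour is deliberate: the partitioning stage is allowed
to be slightly over-eager, because over-splits are recoverable and
under-splits are not.

## Consensus partition

Both base methods are run; the *consensus* partition keeps nests together
only when both methods keep them together (intersection of the two
partitions). Cells below `minsize` become outliers. Disagreements between
the methods are thereby resolved toward the finer agreed structure; a
nest stranded on the wrong side of a boundary by one method becomes an
outlier and is later placed by the discriminant rather than by the
accident of a linkage tie.

## Confirmatory LDA

A shared-covariance Gaussian discriminant (uniform class priors by
default, so unequal species sampling does not sway type placement; svd
solver, which tolerates collinear variables — a rank-deficient pooled
covariance triggers a warning and proceeds on the reduced rank).
Classification success is measured by leave-one-out cross-validation:
every case predicted by a model trained without it. Name-bearing type
specimens are *wildcards*: excluded from training, they receive posterior
probability vectors only. A syntype series is assigned by the per-class
geometric mean of its members' posteriors, renormalized to sum to one
(geometric means of probability vectors are not normalized), argmax wins.
Posteriors are invariant under affine changes of the variable units.

## Molecular delimitation

* **Haplotypes.** Sequences identical over all columns collapse to their
  first occurrence; every downstream distance is computed on the
  deduplicated ingroup by default (a flag restores all-sequence mode).
  Note that deduplication reweights averages toward rare variants; the
  generator's calibration tests therefore check the full alignment.
* **Distances.** Uncorrected p-distance with pairwise deletion: a column
  counts for a pair only when both residues are plain nucleotides; `N`
  (missing) and `-` (gap) are distinct states but both excluded. Pairs
  with zero comparable columns are undefined and excluded from averages,
  never imputed. Intra Dist is the mean within-species pairwise distance
  (blank for singletons); Inter Dist Closest is the smallest mean
  between-species distance, with the closest species named.
* **Tree.** Any rooted Newick is accepted; without one, a neighbor-joining
  tree is built from the distance matrix (taxa presented in lexicographic
  order for reproducible ties) and rooted on the outgroup. A putative
  species is monophyletic iff the smallest clade containing its sequences
  contains nothing else, with outgroups and unanalyzed leaves excluded
  from the universe.
* **PID (Liberal)** — the probability that an unknown sequence is
  identified as its species or that species' sister. The default is
  empirical: each member is queried by leave-one-out nearest neighbour
  (correct when the neighbour is conspecific or from the closest
  species), with a Wilson 95 % CI. A predictive mode is also provided as
  this package's own site-count model: the differences to a conspecific
  and to the sister species are X ~ Poisson(L·intra) and
  Y ~ Poisson(L·inter), and PID = P(X < Y) + ½P(X = Y) via the Skellam
  distribution. It satisfies the expected limits (→ 1 as intra → 0, with
  inter large) and is monotone non-increasing in intra/inter. It is *not*
  the regression published with the Geneious species-delimitation plugin,
  whose coefficients are not reproduced here; comparisons to plugin
  output should use the empirical mode.
* **Rosenberg's P(AB)** — the probability that two groups of a and b tips
  covering a rooted binary labeled topology are reciprocally monophyletic
  by chance. Both groups are clades exactly when the root splits them, so
  with T(n) = (2n−3)!! equiprobable topologies,
  P = T(a)·T(b) / T(a+b), computed in exact rational arithmetic and
  verified against an exhaustive enumeration oracle for all a+b ≤ 8
  (135 135 topologies at n = 8; the oracle refuses beyond n = 9). Small
  values indicate distinctiveness: text sources that print the
  significance direction inconsistently are resolved as
  small-is-significant.

## Reconciliation rules

Evidence enters as: the consensus morphometric partition, the qualitative
(a-priori) labels, and the tree/delimitation report, linked by a
specimen→sequence map.

* **Rule L (lump).** Each cluster is anchored to the majority a-priori
  species among its specimens. Two clusters merge when they anchor to the
  same putative species (shape sub-structure without molecular
  distinction) or when their two putative species fail reciprocal
  monophyly — tested with the leaf universe restricted to the two
  sequence sets — or when the separating nodes carry support below a
  configurable threshold (default 0.95; trees without support values
  pass). Anchoring at the cluster level makes the rule robust to single
  stray specimens; clusters with no anchor fall back to a strict test on
  their own sequence sets, and clusters with no sequenced member are left
  unlumped and flagged.
* **Rule A (add).** A qualitative label not carried by any recognized
  species, with fewer than `minsize` specimens and a monophyletic
  sequence set, becomes its own species — the escape hatch for good
  species with samples below the clustering threshold, whether their
  nests landed in the outlier class or were absorbed into a larger
  cluster.
* **Rule C (confirm).** Remaining outlier specimens are placed by LDA
  posterior; the labeling is then iterated to a fixed point under
  reclassification (at most five passes, never erasing a species), which
  is what "final hypothesis after confirmation by cross-validated LDA"
  means operationally; LOOCV success and the confusion table travel with
  the hypothesis.

The **stopping rule** issues per-species verdicts: *describe* when all
available evidence lines agree, *flag* otherwise. Lines are judged at the
level of clusters and labels with a four-fifths supermajority (a single
boundary specimen does not veto a species); a species whose sample went
mostly unrecognized by the clustering (the Rule-A path) has its
morphometric line *absent*, and is described on qualitative + molecular
agreement with an exception note.

## Synthetic data

The generator emulates the two study inputs with full ground truth.

*Morphometrics.* Specimen CWb and each shape ratio are drawn around
species templates: value = mean + nest effect + individual noise, the
nest effect shared by nest mates. `nest_sd_fraction` (default 0.2) is the
share of the template SD carried by the colony effect; the published
per-species SDs are treated as mostly individual-plus-measurement
variation, so nest centroids are substantially tighter than specimens.
An optional common within-species shape factor (`factor_loading`,
default 0 — ratios independent) adds realistic covariance when wanted;
marginal SDs always match the templates. Traits are reconstituted as
ratio × CWb. A species may carry *morphs*: per-morph offsets added to the
ratio means, with within-morph SDs shrunk so the species-wide SD still
matches the template.

*Sequences.* Jukes–Cantor evolution along a rooted species tree; branch
lengths are solved from target uncorrected distances with the exact JC
map p = ¾(1 − e^{−4ℓ/3}), so intra- and inter-specific expectations hit
their targets without simulation tuning. Tips radiate from each species
ancestor; outgroups hang off the root; divergences ≥ 0.75 are refused
(JC saturation). Exact duplicate sequences can be injected to exercise
haplotype collapsing.

*The study preset* (`study_preset`, `simulate_study_bundle`) instantiates
five species from the published per-species ratio means/SDs and head
widths (n = 53/27/3/32/62 across 96 nests; the three-worker species gets
two nests), a 658-bp alignment of 89 ingroup + 2 outgroup sequences with
the published intra-specific (0.1–2.0 %) and closest-interspecific
(3.3–3.9 %) divergence targets, type series as unlabeled wildcards (one
two-worker pair for the medium-spined eastern species; four lots for the
widespread western species), and one species built from three morphs
sharing a single mitochondrial clade — offsets of ±1 template SD per
ratio along a shape contrast (spine/waist against head/body), between-morph
spread ≈ 64 % of the printed variance — so the lump rule faces the same
configuration the published analysis did.

*What the emulation does not reproduce.* Real within-species trait
covariance (independent ratios by default), geographic structure,
measurement error structure, rate heterogeneity and non-JC substitution,
and the raw data's column dialects. Consequently, recovery tests show
the pipeline's logic is correct under the published summary statistics —
not that those statistics fully determine the raw data. Quantities that
depend on the unpublished raw measurements (exact wildcard posteriors,
the exact haplotype count after collapsing) vary around the published
values from seed to seed; decision-level outcomes (six clusters → lump →
five species, the Rule-A addition, perfect or near-perfect LOOCV, correct
type placement) are stable across seeds.

## Numerical choices and degenerate inputs

Ties in clustering are fixed by lexicographic case order; k-means is
seeded per call from the pipeline seed. Identical cases give chosen
k = 1 with a warning. Singleton training classes are an error naming the
class; a rank-deficient pooled covariance warns and proceeds. Posterior
geometric means floor member posteriors at 1e−300 before the log. Wilson
intervals are clamped to contain the point estimate. Boundary equality in
the identification key (e.g. `CL/POOC` exactly 1.9) returns
*indeterminate*, never a silent assignment, because the printed species
ranges exclude the thresholds.

## Problem sizes used by the tests and the acceptance script

The test suite runs the study emulation once (seed 1, B = 60) plus
smaller simulations (two-blob recovery over 20 seeds at n = 44, B = 30;
divergence calibration over 10–20 seeds at 500–658 bp); the acceptance
script runs one full pipeline at B = 100. A full study-scale pipeline
takes about two minutes on one core; the enumeration oracle's 135 135
topologies at n = 8 take a few seconds.

## Known limitations

* The gap statistic's one-SE rule over-estimates k on very small, very
  tight groups in high dimension (near-zero within-dispersion on the log
  scale); PART then fragments them, and the lump rule is what restores
  the species-level result. Cluster counts on borderline data should be
  read per seed, with decisions taken from the reconciled hypothesis.
* PID's predictive mode is a transparent Poisson model, not the published
  plugin regression; its CIs are binomial approximations.
* Rule L's support-threshold branch needs node labels interpretable as
  support values; trees without them pass the support check silently.
* The equiprobable-topology null for P(AB) is the enumeration-checkable
  choice; a Yule-null variant is documented but not implemented.
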