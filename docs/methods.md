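# Methods

This note documents the models, decision rules, parameter defaults and
numerical choices behind `clademark`, and what the synthetic-data generators
do and do not emulate.

## Tree primitives

Monophyly is defined on the **unrooted** tree via edge bipartitions: a focal
leaf set is monophyletic iff it equals one side of some edge's bipartition.
Single-gene trees rarely carry a defensible root, so a rooted input (root of
degree 2) is read as unrooted by suppressing the root; singleton focal sets
and the full leaf set pass vacuously. The *minimal spanning side* of a focal
set is the smallest bipartition side containing it (the full leaf set when no
proper side does), with size ties broken by lexicographic order of the sorted
label tuple. This is the formal stand-in for the visual judgement "the focal
sequences cluster with clade X": if the smallest clade spanning the focal
sequences contains a leaf from an excluded clade, the family is treated as
contaminated.

Newick parsing and writing are delegated to dendropy (quoted labels
supported; internal node labels ignored on read; absent branch lengths
default to 0.0). Neighbor joining is delegated to scikit-bio and is intended
only as a basic builder for synthetic end-to-end runs — it is exact on
additive matrices; negative branch-length estimates are clamped to zero with
a logged warning. Robinson–Foulds is the symmetric difference of nontrivial
bipartitions. p-distances use **pairwise deletion** (per pair, only columns
where neither sequence is gapped), which preserves per-pair signal on short
alignments; the Jukes–Cantor correction −(3/4)ln(1 − 4d/3) errors at d ≥ 3/4
by default (configurable to +inf).

## Marker screen

Filters apply in a fixed order, and each rejected family records exactly its
first failing rule:

1. **Eligibility** — a genome counts iff completeness is *strictly* above
   `completeness_min` (default 85%). Strictness mirrors the usual ">85%"
   phrasing of MAG-quality thresholds.
2. **Single copy** — rejected iff any eligible genome carries ≥2 copies.
3. **Occupancy** — rejected iff the fraction of eligible genomes carrying
   the family is below `occupancy_min`. Default 0.5 ("at least half");
   set 1.0 for a strict "present in every counted genome" reading. The two
   readings exist because published screens are ambiguous about whether
   "single-copy in each MAG" tolerates absences in incomplete MAGs.
4. **Monophyly** — rejected iff the focal-clade leaves of the gene tree are
   not monophyletic. Families with fewer than two focal leaves pass
   vacuously (logged): monophyly of one sequence is undefined-but-true.
5. **Contamination** — rejected iff the focal minimal spanning side contains
   a leaf from an excluded clade. An optional strict mode additionally
   requires focal monophyly here.
6. **Trimming** — a column is removed iff its gap fraction is *strictly*
   greater than `max_gap_frac` (default 0.05); a column at exactly the
   threshold stays.
7. **Concatenation** — one row per eligible genome; genomes absent from a
   family receive all-gap filler; the partition map records 0-based
   half-open column intervals (also written RAxML-style, 1-based inclusive).

## Group delineation

Identity is **aligned-column identity** — matches over columns where neither
sequence is gapped — on a supplied multiple alignment; de novo pairwise
alignment is out of scope and published identity thresholds do not specify a
k-mer alternative, so the alignment-based definition is fixed and documented.
The length filter keeps sequences with ungapped length ≥ `min_len`
(default 700 bp; "less than 700" excluded, so 700 itself passes).

Representative clustering is greedy centroid clustering at
`rep_cluster = 0.99`: sequences are processed in decreasing ungapped length
(ties by id), each joining the first centroid it matches at ≥ threshold or
founding a new one. This mimics common centroid-clustering practice
(USEARCH-style) without reproducing any specific tool's tie-breaking.

Groups are connected components of the graph linking representatives at
identity **strictly above** `intra_min = 0.97`. Component pairs whose
maximum cross-identity reaches `inter_max = 0.91` are flagged *unresolved*
rather than merged: the 91–97% band has no published rule, so the package
surfaces the ambiguity instead of deciding it. Queries are assigned to the
group of their best-matching representative when that identity exceeds
`intra_min`, else reported unassigned with the best identity.

## Pathway and antioxidant profiling

A pathway is *present* iff strictly more than half of its genes have copy
number ≥1 (an even gene count therefore needs n/2 + 1), *partial* iff at
least `min_key_subunits = 2` of its key cluster are present ("more than one
subunit"), else *absent*. Calls are monotone: adding a gene never demotes a
call. Gene symbols missing from the annotation table count as 0 with a
logged note — absence of evidence is routine for incomplete MAGs and must
not be an error.

Definitions ship as editable JSON because the exact "associated gene" lists
behind published presence/absence figures depend on the annotation pipeline.
The default WL definition uses the archaeal H4MPT methyl branch (fwd, ftr,
mch, mtd, mer) plus the CODH/ACS carbonyl cluster (cdhA–E, the key cluster);
mcr (mcrABCDG) and mtr (mtrA–H) are included, mtr without a key cluster so a
lone *mtrH* is called absent under the majority rule.

The antioxidant panel (sor, rubredoxin, rubrerythrin, bcp-2) grades genomes
none-detected (0) / minimal (1) / partial (2–3) / full (4); "none-detected"
marks a strictly-anaerobic candidate.

## Abundance and correlations

RPKM = mapped / ((genome length/10³) × (total reads/10⁶)). Published
descriptions sometimes print the formula without the two scaling constants;
the package applies standard RPKM scaling and notes that every downstream
use (rankings, correlations, shares) is invariant to them. "Metagenome
size" is read as total reads (a per-base variant would only rescale).
Per-sample *fractions* are mapped/total; *shares* renormalize RPKM to sum
to 1 across genomes, which undoes the reads-proportional-to-length mapping
bias and estimates cell-level relative abundance. Samples with no mapped
reads get missing shares.

Spearman's rho is the Pearson correlation of average ranks (ties averaged),
computed with pairwise missing-value removal; p-values use the
t-approximation by default with a seeded permutation option recommended
below n = 10; multiple parameters are Benjamini–Hochberg adjusted. Constant
inputs leave rho undefined and raise rather than returning NaN silently.

## Gene-content history

The two-state model has gain rate g (0→1) and loss rate l (1→0) per
branch-length unit, with closed-form transition probabilities
P01(t) = π1(1−e^(−rt)), r = g+l, π1 = g/r; zero-length branches are identity.
The root prior defaults to the stationary distribution (configurable).
Likelihoods use Felsenstein pruning; marginal node posteriors and per-branch
joint parent/child posteriors come from a standard up–down pass. *Expected*
branch events sum the posterior endpoint-transition probabilities
P(parent=0, child=1 | data) (gains) and the reverse (losses); they therefore
estimate endpoint state changes, not path-level event counts — a 0→1→0
excursion within one branch is invisible to both the data and the estimator.

Fitch parsimony requires a rooted binary tree; ambiguous internal states
resolve to absence (0), a deliberate tie-break that never changes the
minimum count. Parsimony branch events count transitions along that optimal
labeling, so their total equals the Fitch minimum by construction.

Rate estimation maximizes the summed pruning log-likelihood over an 8×8
log-spaced grid (10⁻² to 10^1.5) followed by coordinate-wise golden-section
searches on the log-rates (window ±1.5 log units, tolerance 10⁻⁶, 6 sweeps).

**This module is not a reconciliation method.** It reconstructs
presence/absence histories only: a horizontal transfer into a clade is
indistinguishable from an independent gain on the recipient branch, and
copy numbers above one are thresholded away. Questions about transfer
donors/recipients or per-node copy-number estimates need gene-tree-aware
reconciliation, which is outside this package's scope.

## Synthetic data: what it emulates, and what it does not

All generators are bit-reproducible under a fixed seed; the pipeline derives
per-stage substreams from one master seed.

- **Species trees** are ultrametric Yule shapes with nested named clades
  (each clade, including a parent clade as the union of its subclades, is
  monophyletic by construction). Depth is specified in expected
  substitutions/site (default 0.3 root-to-tip); at each nesting level half
  the remaining height goes to the backbone between sibling clades.
- **Gene families** evolve inside the species tree under
  duplication–transfer–loss: a single lineage enters at the root;
  duplications split it in place, losses terminate it, transfers copy it to
  a uniformly chosen *other* branch at a uniform insertion point (an
  "undated" transfer model — the trees carry substitution distances, not
  times, so contemporaneity is undefined). Sequences evolve under JC69 only;
  richer substitution models are deliberately out of scope. Two calibration
  facts matter for testing: the expected duplication count is
  δ·∫e^(δ·depth) (copies compound — *not* simply δ × tree length), and
  transfer-free families are only guaranteed focal-monophyletic when
  duplications are also off, because a duplication ancestral to the
  focal/non-focal split leaves interleaving paralogs.
- **16S-like groups** radiate from group ancestors on a JC-calibrated star
  phylogeny so realized mean within-group identity hits the target (default
  0.98) and between-group identity its target (default 0.88), with member
  depth subtracted from the ancestor spacing so member–member inter-group
  identity is what hits the target. Sequences cover random windows
  (ungapped lengths uniform in 600–1500 bp over 1500 columns, all windows
  containing the central 500 columns so every pair stays comparable),
  which deliberately puts some sequences below the 700 bp filter.
- **Annotation tables** give each genome its group's signature genes, each
  independently retained with probability completeness/100 when dropout is
  on — the simplest model that makes completeness thresholds consequential.
- **Read counts** are per-sample multinomials with mapping probability
  ∝ cell fraction × genome length.

None of this emulates real sequencing error, chimeras, alignment error,
annotation false positives, rate heterogeneity across sites or lineages, or
non-uniform transfer preferences. Passing the planted-truth tests therefore
shows the *procedures* implement their rules correctly and recover structure
when the generating assumptions hold — not that the thresholds themselves
are optimal for any particular real dataset.

## Demo conditions

The demo plants an 8-group focal phylum (3 genomes/group) with three
outgroup clades (4 genomes each), 12 transfer-free and 6 disrupted marker
families (disrupted families are conditioned on at least one
boundary-crossing transfer in their event log), 6 sequences per 16S group,
three samples of 2×10⁵ reads, and group signatures in which three
root-proximal groups exclusively carry the full WL gene set and differ in
antioxidant complement (one none, one rubrerythrin-only, one three-of-four;
remaining groups carry all four). Sizes were chosen so the full demo runs in
seconds while leaving every recovery statistic well away from its noise
floor. Dropout is off by default so planted profiles are recovered exactly;
enabling it at low completeness demonstrates partial-call demotion.

## Known limitations

- Identity and distance computations are O(n²) pure-Python loops over pairs;
  adequate for hundreds of sequences, not tens of thousands.
- The greedy clusterer does not reproduce any specific external tool's
  centroid order or tie-breaking, so representative *sets* (not the final
  groups) may differ from e.g. USEARCH on the same input.
- `fitch_min_changes` requires strictly binary rooted trees; multifurcations
  must be resolved upstream.
- Mk rate estimation assumes all profiles share one (g, l) pair; per-family
  rates are not modeled.
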