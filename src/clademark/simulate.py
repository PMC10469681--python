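"""Seeded generators for every input the pipeline consumes, with planted truth.

The generators emulate, at desk scale, the data a MAG-based clade study works
from: a species tree with named monophyletic clades, gene families evolving on
it under duplication-transfer-loss (DTL), 16S-like sequence sets with planted
group structure, genome annotation tables with group-specific pathway
signatures and completeness-driven dropout, and multinomial mapped-read
counts.  Everything is bit-reproducible under a fixed seed.

Transfers pick their recipient uniformly among all other branches and a
uniform insertion point on it (an "undated" transfer model: the trees carry
substitution distances, not time calibrations, so contemporaneity is not
defined).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .abundance import AbundanceTable
from .alignment import Alignment, jc_correct
from .records import GeneFamily, GenomeRecord, SeqRecord
from .tree import PhyloTree

__all__ = [
    "SpeciesTreeSimParams",
    "GeneFamilySimParams",
    "GroupSeqSimParams",
    "SimEvent",
    "simulate_species_tree",
    "simulate_gene_family",
    "evolve_sequences",
    "simulate_16s_groups",
    "simulate_read_counts",
    "simulate_annotation_table",
    "jc_expected_p_distance",
    "crossing_transfers",
]

_BASES = "ACGT"


def jc_expected_p_distance(d: float) -> float:
    """Expected proportion of differing sites at JC69 distance ``d``."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


# ---------------------------------------------------------------------------
# species trees
# ---------------------------------------------------------------------------


@dataclass
class SpeciesTreeSimParams:
    """Clade sizes and shape parameters for the species-tree generator.

    clades
        clade label -> taxon count, or a nested dict of subclades (e.g. a
        focal phylum containing named groups).  Every named clade — including
        a parent clade, as the union of its subclades — comes out
        monophyletic.
    birth_rate
        Yule speciation rate (events/lineage/time); shapes node heights only,
        since the tree is rescaled to ``depth`` afterwards.
    depth
        root-to-tip height in expected substitutions/site (the tree is
        ultrametric); at each nesting level half the remaining height is
        spent on the backbone between sibling clades, half inside them.
    """

    clades: dict[str, "int | dict"]
    birth_rate: float = 1.0
    depth: float = 0.3
    seed: int = 0

    def __post_init__(self):
        def check(spec, name):
            if isinstance(spec, dict):
                if not spec:
                    raise ValueError(f"clade {name!r}: empty subclade map")
                for k, v in spec.items():
                    check(v, k)
            elif spec < 1:
                raise ValueError(f"clade {name!r}: need >=1 taxon")

        if not self.clades:
            raise ValueError("need at least one clade")
        check(self.clades, "<root>")
        if self.birth_rate <= 0 or self.depth <= 0:
            raise ValueError("rates and depth must be positive")


def _yule_shape(n: int, birth: float, rng: np.random.Generator) -> tuple[dendropy.Node, float]:
    """Ultrametric Yule tree shape on ``n`` unnamed tips; returns (root, height)."""
    root = dendropy.Node()
    if n == 1:
        return root, 0.0
    start = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (len(active) * birth))
        idx = int(rng.integers(len(active)))
        parent = active.pop(idx)
        parent.edge.length = None  # set below via start times
        parent._split_time = t
        for _ in range(2):
            child = dendropy.Node()
            start[child] = t
            parent.add_child(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / (n * birth))
    # edge lengths from start/split times
    def _assign(node, node_start):
        if node.child_nodes():
            split = node._split_time
            for c in node.child_nodes():
                c.edge.length = (c._split_time if c.child_nodes() else t_end) - split
                _assign(c, split)
    _assign(root, 0.0)
    # the initial [0, first-split] stretch is a root edge this shape drops,
    # so the usable height runs from the root's own split to the present
    return root, t_end - root._split_time


def _scale_subtree(root: dendropy.Node, factor: float) -> None:
    for nd in root.preorder_iter():
        if nd is not root and nd.edge.length is not None:
            nd.edge.length *= factor


def _graft_clade(
    tip: dendropy.Node,
    name: str,
    spec,
    budget: float,
    birth: float,
    rng: np.random.Generator,
    clade_map: dict[str, str],
) -> None:
    """Grow the clade ``spec`` below ``tip``, consuming exactly ``budget`` height.

    Shortfall between the grown subtree's height and the budget is absorbed
    into the pendant edge above ``tip``, keeping the whole tree ultrametric.
    """
    if isinstance(spec, dict):
        names = sorted(spec)
        if len(names) == 1:  # pass-through wrapper: no backbone needed
            _graft_clade(tip, names[0], spec[names[0]], budget, birth, rng, clade_map)
            return
        backbone, h = _yule_shape(len(names), birth, rng)
        _scale_subtree(backbone, (budget / 2.0) / h)
        for c in list(backbone.child_nodes()):
            backbone.remove_child(c)
            tip.add_child(c)
        subtips = [lf for lf in tip.leaf_iter()]
        for subtip, sub in zip(subtips, names):
            _graft_clade(subtip, sub, spec[sub], budget / 2.0, birth, rng, clade_map)
        return
    n = int(spec)
    sub_root, h = _yule_shape(n, birth, rng)
    if n == 1:
        tip.edge.length = (tip.edge.length or 0.0) + budget
        tip._leaf_label = f"{name}_1"
        clade_map[tip._leaf_label] = name
        return
    _scale_subtree(sub_root, budget / h)
    for c in list(sub_root.child_nodes()):
        sub_root.remove_child(c)
        tip.add_child(c)
    for i, lf in enumerate(tip.leaf_iter()):
        lf._leaf_label = f"{name}_{i + 1}"
        clade_map[lf._leaf_label] = name


def simulate_species_tree(
    params: SpeciesTreeSimParams,
) -> tuple[PhyloTree, dict[str, str]]:
    """Ultrametric species tree in which every named clade is monophyletic.

    Nested clade maps produce nested monophyletic structure (a parent clade's
    leaves are the union of its subclades').  Returns the tree and a
    leaf-label -> innermost-clade map; leaf labels are ``<clade>_<i>`` and
    internal nodes get stable ids used by event logs.
    """
    rng = np.random.default_rng(params.seed)
    root = dendropy.Node()
    root.edge.length = None
    clade_map: dict[str, str] = {}
    _graft_clade(root, "<root>", params.clades, params.depth, params.birth_rate, rng, clade_map)
    tree = dendropy.Tree(seed_node=root)
    tns = tree.taxon_namespace
    k = 0
    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.taxon = tns.new_taxon(getattr(nd, "_leaf_label"))
        else:
            nd.label = f"N{k}"
            k += 1
    return PhyloTree(tree), clade_map


# ---------------------------------------------------------------------------
# gene families under duplication-transfer-loss
# ---------------------------------------------------------------------------


@dataclass
class GeneFamilySimParams:
    """DTL and sequence-evolution parameters for one gene family."""

    dup_rate: float = 0.0       # duplications per branch-length unit
    transfer_rate: float = 0.0  # transfers per branch-length unit
    loss_rate: float = 0.0      # losses per branch-length unit
    seq_length: int = 300       # sites; 0 skips sequence evolution
    model: str = "JC69"
    seed: int = 0

    def __post_init__(self):
        if min(self.dup_rate, self.transfer_rate, self.loss_rate) < 0:
            raise ValueError("rates must be nonnegative")
        if self.seq_length < 0:
            raise ValueError("sequence length must be >= 0")
        if self.model != "JC69":
            raise ValueError("only JC69 is supported")


@dataclass
class SimEvent:
    """One recorded DTL event; branches are named by the species node below them."""

    kind: str                       # duplication | transfer | loss
    branch: str                     # donor branch
    recipient: Optional[str] = None  # transfer target branch
    time: float = 0.0               # root-to-event distance on the donor branch


class _GNode:
    __slots__ = ("children", "length", "label")

    def __init__(self, length=0.0, label=None):
        self.children: list[_GNode] = []
        self.length = float(length)
        self.label = label


def _gnode_newick(node: _GNode) -> str:
    if not node.children:
        return f"'{node.label}':{node.length:.10g}"
    inner = ",".join(_gnode_newick(c) for c in node.children)
    return f"({inner}):{node.length:.10g}"


def _branch_name(nd: dendropy.Node) -> str:
    return nd.taxon.label if nd.is_leaf() else nd.label


def simulate_gene_family(
    species_tree: PhyloTree,
    params: GeneFamilySimParams,
    family_id: str = "fam",
) -> tuple[GeneFamily, list[SimEvent]]:
    """Evolve one gene family inside a species tree under DTL.

    A single gene lineage enters at the root and follows the species tree;
    along each branch it experiences duplications (split in place), transfers
    (a copy restarts at a uniform point on a uniformly chosen other branch)
    and losses (termination) as independent Poisson processes.  Surviving
    lineages at species-tree tips become family members labeled
    ``genome|copy``; sequences evolve under JC69 along the gene tree.

    With all rates zero the gene tree is congruent with the species tree and
    every genome carries exactly one copy.  A family whose lineages all die is
    returned empty, not an error.
    """
    rng = np.random.default_rng(params.seed)
    sp = species_tree.dendropy_tree
    root = sp.seed_node
    # stable ids for unlabeled internals (user-supplied trees)
    k = 0
    for nd in sp.preorder_node_iter():
        if not nd.is_leaf() and nd.label is None:
            nd.label = f"N{k}"
            k += 1
    branches = [nd for nd in sp.preorder_node_iter() if nd is not root]
    depth_above = {root: 0.0}
    for nd in sp.preorder_node_iter():
        if nd is not root:
            depth_above[nd] = depth_above[nd.parent_node] + (nd.edge.length or 0.0)

    total_rate = params.dup_rate + params.transfer_rate + params.loss_rate
    events: list[SimEvent] = []
    copy_counter: dict[str, int] = {}

    def new_leaf(sp_leaf: dendropy.Node) -> _GNode:
        g = sp_leaf.taxon.label
        copy_counter[g] = copy_counter.get(g, 0) + 1
        return _GNode(label=f"{g}|{copy_counter[g]}")

    def merge(kids: list[_GNode], consumed: float) -> Optional[_GNode]:
        kids = [c for c in kids if c is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].length += consumed
            return kids[0]
        node = _GNode(length=consumed)
        node.children = kids
        return node

    def sim_from(sp_node: dendropy.Node, start: float) -> Optional[_GNode]:
        """Gene lineage entering the branch above ``sp_node`` at ``start``."""
        L = sp_node.edge.length or 0.0
        pos = start
        while True:
            dt = rng.exponential(1.0 / total_rate) if total_rate > 0 else math.inf
            if pos + dt >= L:
                if sp_node.is_leaf():
                    leaf = new_leaf(sp_node)
                    leaf.length = L - start
                    return leaf
                kids = [sim_from(c, 0.0) for c in sp_node.child_nodes()]
                return merge(kids, L - start)
            pos += dt
            abs_time = depth_above[sp_node.parent_node] + pos
            u = rng.random() * total_rate
            if u < params.loss_rate:
                events.append(SimEvent("loss", _branch_name(sp_node), time=abs_time))
                return None
            if u < params.loss_rate + params.dup_rate:
                events.append(SimEvent("duplication", _branch_name(sp_node), time=abs_time))
                kids = [sim_from(sp_node, pos), sim_from(sp_node, pos)]
                return merge(kids, pos - start)
            # transfer
            others = [b for b in branches if b is not sp_node]
            if not others:
                continue  # nowhere to go; ignore the event
            recip = others[int(rng.integers(len(others)))]
            rpos = rng.random() * (recip.edge.length or 0.0)
            events.append(
                SimEvent("transfer", _branch_name(sp_node), _branch_name(recip), abs_time)
            )
            kids = [sim_from(sp_node, pos), sim_from(recip, rpos)]
            return merge(kids, pos - start)

    survivors = merge([sim_from(c, 0.0) for c in root.child_nodes()], 0.0)

    genomes = [lf.taxon.label for lf in sp.leaf_node_iter()]
    counts = {g: copy_counter.get(g, 0) for g in genomes}
    if survivors is None:
        return GeneFamily(family_id, copy_counts=counts), events

    survivors.length = 0.0
    nwk = _gnode_newick(survivors)
    if not survivors.children:  # a single surviving copy: wrap as a 1-leaf tree
        nwk = f"({nwk})"
    gene_tree = PhyloTree.from_newick(nwk + ";")
    members: dict[str, Optional[str]] = {lf: None for lf in gene_tree.leaf_labels}
    aln = None
    if params.seq_length > 0:
        aln = evolve_sequences(gene_tree, params.seq_length, rng=rng)
        members = dict(zip(aln.labels, aln.rows))
    fam = GeneFamily(family_id, copy_counts=counts, members=members, alignment=aln, tree=gene_tree)
    return fam, events


def crossing_transfers(
    events: Sequence[SimEvent], species_tree: PhyloTree, focal_genomes: set[str]
) -> list[SimEvent]:
    """Transfers whose donor and recipient branches disagree on focal membership.

    A branch is "inside" the focal clade iff every species-tree leaf below it
    is a focal genome.  Such transfers are the events that can break focal
    monophyly in the gene tree.
    """
    sp = species_tree.dendropy_tree
    inside: dict[str, bool] = {}
    below: dict = {}
    for nd in sp.postorder_node_iter():
        if nd.is_leaf():
            below[nd] = {nd.taxon.label}
        else:
            below[nd] = set().union(*(below[c] for c in nd.child_nodes()))
        inside[_branch_name(nd)] = below[nd] <= focal_genomes
    out = []
    for ev in events:
        if ev.kind != "transfer" or ev.recipient is None:
            continue
        if inside[ev.branch] != inside[ev.recipient]:
            out.append(ev)
    return out


def simulate_marker_families(
    species_tree: PhyloTree,
    clade_map: dict[str, str],
    focal: str,
    n_vertical: int = 60,
    n_disrupted: int = 40,
    disrupted_params: Optional[GeneFamilySimParams] = None,
    seq_length: int = 200,
    seed: int = 0,
    max_tries: int = 200,
) -> tuple[list[GeneFamily], set[str]]:
    """A planted marker-screen dataset: clean families plus DTL-disrupted ones.

    Vertical families evolve with all DTL rates zero (congruent, single-copy,
    full occupancy).  Each disrupted family is drawn under ``disrupted_params``
    and conditioned on its event log containing at least one transfer crossing
    the focal-clade boundary — the planted signal the screen should reject
    (the rejection may fire at the copy-number, occupancy or monophyly stage).
    Returns the shuffled family list and the set of vertical family ids.
    """
    if disrupted_params is None:
        disrupted_params = GeneFamilySimParams(
            dup_rate=0.2, transfer_rate=1.0, loss_rate=0.7, seq_length=seq_length
        )
    rng = np.random.default_rng(seed)
    focal_genomes = {g for g, c in clade_map.items() if c == focal}
    families: list[GeneFamily] = []
    vertical_ids: set[str] = set()
    for i in range(n_vertical):
        p = GeneFamilySimParams(seq_length=seq_length, seed=int(rng.integers(2**31)))
        fam, _ = simulate_gene_family(species_tree, p, family_id=f"v{i + 1:03d}")
        families.append(fam)
        vertical_ids.add(fam.id)
    for i in range(n_disrupted):
        for _ in range(max_tries):
            p = GeneFamilySimParams(
                dup_rate=disrupted_params.dup_rate,
                transfer_rate=disrupted_params.transfer_rate,
                loss_rate=disrupted_params.loss_rate,
                seq_length=seq_length,
                seed=int(rng.integers(2**31)),
            )
            fam, events = simulate_gene_family(species_tree, p, family_id=f"d{i + 1:03d}")
            if fam.tree is not None and crossing_transfers(events, species_tree, focal_genomes):
                families.append(fam)
                break
        else:
            raise RuntimeError(
                "could not plant a boundary-crossing transfer; raise transfer_rate"
            )
    order = rng.permutation(len(families))
    return [families[i] for i in order], vertical_ids


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def evolve_sequences(
    tree: PhyloTree,
    length: int,
    model: str = "JC69",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> Alignment:
    """Evolve an ungapped alignment along a tree under JC69.

    The root sequence is uniform over {A,C,G,T}; each branch substitutes each
    site independently with probability (3/4)(1 - e^(-4d/3)) for branch length
    ``d`` in expected substitutions/site, the replacement base uniform among
    the other three.
    """
    if model != "JC69":
        raise ValueError("only JC69 is supported")
    if rng is None:
        rng = np.random.default_rng(seed)
    dtree = tree.dendropy_tree
    root = dtree.seed_node
    seqs: dict = {root: rng.integers(0, 4, size=length)}
    labels, rows = [], []
    for nd in dtree.preorder_node_iter():
        if nd is not root:
            d = nd.edge.length or 0.0
            p_change = jc_expected_p_distance(d)
            parent_seq = seqs[nd.parent_node]
            mask = rng.random(length) < p_change
            child = parent_seq.copy()
            if mask.any():
                child[mask] = (child[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
            seqs[nd] = child
        if nd.is_leaf():
            labels.append(nd.taxon.label)
            rows.append("".join(_BASES[b] for b in seqs[nd]))
    return Alignment(labels, rows)


# ---------------------------------------------------------------------------
# 16S-like group structure
# ---------------------------------------------------------------------------


@dataclass
class GroupSeqSimParams:
    """Planted group structure for 16S-like sequences.

    Sequences radiate from group ancestors placed so that realized mean
    within-group identity hits ``intra_identity`` and between-group identity
    hits ``inter_identity`` (JC-calibrated star phylogeny).  Each sequence
    covers a random window of the alignment, with ungapped lengths uniform in
    ``length_range`` (deliberately dipping below 700 bp so the length filter
    has work to do); all windows contain the central ``core`` columns, mimicking
    amplicons that share a conserved region, so every pair stays comparable.
    """

    n_groups: int = 3
    seqs_per_group: int = 10
    length: int = 1500
    intra_identity: float = 0.98
    inter_identity: float = 0.88
    length_range: tuple[int, int] = (600, 1500)
    core: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_groups < 1 or self.seqs_per_group < 1:
            raise ValueError("need >=1 group and >=1 sequence per group")
        if not (0.0 < self.inter_identity < self.intra_identity <= 1.0):
            raise ValueError(
                "need 0 < inter_identity < intra_identity <= 1 "
                f"(got inter={self.inter_identity}, intra={self.intra_identity})"
            )
        lo, hi = self.length_range
        if not (0 < lo <= hi <= self.length):
            raise ValueError("length_range must satisfy 0 < lo <= hi <= length")
        if self.core > lo:
            raise ValueError("core region cannot exceed the minimum sequence length")


def simulate_16s_groups(
    params: GroupSeqSimParams,
) -> tuple[list[SeqRecord], dict[str, str]]:
    """Aligned 16S-like sequences with planted groups; returns (records, truth map)."""
    rng = np.random.default_rng(params.seed)
    b = jc_correct(1.0 - params.intra_identity) / 2.0  # member depth below ancestor
    if params.n_groups > 1:
        d_inter = jc_correct(1.0 - params.inter_identity)
        a = (d_inter - 2.0 * b) / 2.0  # ancestor depth below root
        if a <= 0:
            raise ValueError("identity targets infeasible: groups would overlap")
    else:
        a = 0.0

    parts = []
    for g in range(1, params.n_groups + 1):
        tips = ",".join(
            f"g{g}_s{s}:{b:.10g}" for s in range(1, params.seqs_per_group + 1)
        )
        if params.seqs_per_group == 1:
            parts.append(f"g{g}_s1:{a + b:.10g}")
        else:
            parts.append(f"({tips}):{a:.10g}")
    if params.n_groups == 1:
        newick = f"({parts[0]});" if params.seqs_per_group == 1 else parts[0] + ";"
    else:
        newick = "(" + ",".join(parts) + ");"
    tree = PhyloTree.from_newick(newick)
    aln = evolve_sequences(tree, params.length, rng=rng)

    lo, hi = params.length_range
    L = params.length
    core_start = (L - params.core) // 2
    core_end = core_start + params.core
    records, truth = [], {}
    for label, row in aln:
        ell = int(rng.integers(lo, hi + 1))
        smin = max(0, core_end - ell)
        smax = min(core_start, L - ell)
        start = int(rng.integers(smin, smax + 1))
        gapped = "-" * start + row[start : start + ell] + "-" * (L - start - ell)
        group = label.split("_")[0]
        records.append(SeqRecord(label, gapped, metadata={"group": group}))
        truth[label] = group
    return records, truth


# ---------------------------------------------------------------------------
# read counts and annotation tables
# ---------------------------------------------------------------------------


def simulate_read_counts(
    true_fractions: dict[str, float],
    genome_lengths: dict[str, int],
    total_reads: dict[str, int],
    seed: int = 0,
) -> AbundanceTable:
    """Multinomial mapped-read counts per sample.

    Mapping probability is proportional to (cell fraction x genome length):
    longer genomes soak up proportionally more reads, which RPKM
    normalization later undoes.  ``true_fractions`` must sum to 1.
    """
    genomes = sorted(true_fractions)
    f = np.array([true_fractions[g] for g in genomes], float)
    if not math.isclose(f.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("true_fractions must sum to 1")
    lens = np.array([genome_lengths[g] for g in genomes], float)
    if (lens <= 0).any():
        raise ValueError("genome lengths must be positive")
    p = f * lens
    p /= p.sum()
    rng = np.random.default_rng(seed)
    counts = {}
    totals = {}
    for sample in sorted(total_reads):
        n = int(total_reads[sample])
        counts[sample] = dict(zip(genomes, rng.multinomial(n, p).tolist()))
        totals[sample] = n
    return AbundanceTable.from_dicts(counts, totals, {g: int(genome_lengths[g]) for g in genomes})


def simulate_annotation_table(
    genomes: Sequence[GenomeRecord],
    signatures: dict[str, set[str] | list[str]],
    completeness_dropout: bool = False,
    seed: int = 0,
):
    """Genome x gene-symbol copy table from group signatures.

    Each genome receives every signature gene of its group (copy 1); with
    dropout on, each gene is independently retained with probability
    completeness/100, emulating annotation loss in incomplete MAGs.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    all_genes = sorted({g for genes in signatures.values() for g in genes})
    rows = {}
    for gm in genomes:
        if gm.group not in signatures:
            raise KeyError(f"genome {gm.id}: unknown group {gm.group!r}")
        sig = set(signatures[gm.group])
        row = {}
        for gene in all_genes:
            present = gene in sig
            if present and completeness_dropout:
                present = rng.random() < gm.completeness / 100.0
            row[gene] = 1 if present else 0
        rows[gm.id] = row
    return pd.DataFrame.from_dict(rows, orient="index", columns=all_genes).fillna(0).astype(int)
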