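"""16S-style group delineation: length filter, greedy centroid clustering at a
representative threshold, intra/inter-identity group delineation, and query
assignment.

Identity is aligned-column identity on a supplied multiple alignment
(matches / columns where neither sequence has a gap); de novo pairwise
alignment is out of scope, so sequences must share a common alignment.
Representative pairs falling between the inter and intra thresholds (the
91-97% ambiguous band) are flagged "unresolved" rather than merged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx

from .records import SeqRecord

__all__ = [
    "GroupModel",
    "length_filter",
    "pairwise_identity",
    "greedy_cluster",
    "delineate_groups",
    "assign_to_group",
]


def length_filter(seqs: Sequence[SeqRecord], min_len: int = 700) -> list[SeqRecord]:
    """Keep sequences whose ungapped length is at least ``min_len`` bp."""
    return [s for s in seqs if s.length >= min_len]


def pairwise_identity(a: SeqRecord | str, b: SeqRecord | str) -> float:
    """Aligned-column identity: matches over columns where neither has a gap."""
    sa = a.sequence if isinstance(a, SeqRecord) else a
    sb = b.sequence if isinstance(b, SeqRecord) else b
    if len(sa) != len(sb):
        raise ValueError("sequences are not rows of a common alignment")
    matches = comparable = 0
    for x, y in zip(sa, sb):
        if x == "-" or y == "-":
            continue
        comparable += 1
        if x == y:
            matches += 1
    if comparable == 0:
        ida = a.id if isinstance(a, SeqRecord) else "<a>"
        idb = b.id if isinstance(b, SeqRecord) else "<b>"
        raise ValueError(f"no comparable columns between {ida!r} and {idb!r}")
    return matches / comparable


def greedy_cluster(
    seqs: Sequence[SeqRecord], threshold: float = 0.99
) -> tuple[dict[str, list[str]], list[SeqRecord]]:
    """Centroid-greedy clustering at an identity threshold.

    Sequences are processed in decreasing ungapped length (ties broken by
    lexicographic id); each joins the first existing centroid it matches at
    identity >= ``threshold``, else founds a new cluster.  Returns
    (centroid id -> member ids, centroid records).
    """
    if not seqs:
        raise ValueError("no sequences to cluster")
    ordered = sorted(seqs, key=lambda s: (-s.length, s.id))
    centroids: list[SeqRecord] = []
    clusters: dict[str, list[str]] = {}
    for s in ordered:
        placed = False
        for c in centroids:
            if pairwise_identity(s, c) >= threshold:
                clusters[c.id].append(s.id)
                placed = True
                break
        if not placed:
            centroids.append(s)
            clusters[s.id] = [s.id]
    return clusters, centroids


@dataclass
class GroupModel:
    """Delineated groups over representative sequences.

    ``groups`` maps a group label to its representative ids; ``unresolved``
    lists group pairs whose closest representatives fall in the ambiguous
    identity band [inter_max, intra_min].
    """

    groups: dict[str, list[str]]
    representatives: dict[str, str]  # rep id -> aligned sequence
    intra_min: float = 0.97
    inter_max: float = 0.91
    rep_cluster: float = 0.99
    unresolved: list[tuple[str, str, float]] = field(default_factory=list)

    def __post_init__(self):
        if not (0.0 < self.inter_max < self.intra_min < 1.0 + 1e-12):
            raise ValueError("need 0 < inter_max < intra_min <= rep_cluster <= 1")

    def group_of(self, rep_id: str) -> str:
        for g, reps in self.groups.items():
            if rep_id in reps:
                return g
        raise KeyError(rep_id)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "groups": self.groups,
                    "representatives": self.representatives,
                    "thresholds": {
                        "intra_min": self.intra_min,
                        "inter_max": self.inter_max,
                        "rep_cluster": self.rep_cluster,
                    },
                    "unresolved": [list(u) for u in self.unresolved],
                },
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path) -> "GroupModel":
        d = json.loads(Path(path).read_text())
        return cls(
            groups=d["groups"],
            representatives=d["representatives"],
            intra_min=d["thresholds"]["intra_min"],
            inter_max=d["thresholds"]["inter_max"],
            rep_cluster=d["thresholds"]["rep_cluster"],
            unresolved=[tuple(u) for u in d["unresolved"]],
        )


def delineate_groups(
    reps: Sequence[SeqRecord],
    intra_min: float = 0.97,
    inter_max: float = 0.91,
    rep_cluster: float = 0.99,
) -> GroupModel:
    """Delineate groups among representatives by identity connectivity.

    Representatives with identity strictly above ``intra_min`` are linked;
    groups are the connected components (singletons form singleton groups).
    Component pairs whose maximum cross-identity reaches ``inter_max`` are
    flagged unresolved: they are closer than clearly distinct groups should
    be, but not close enough to merge.  Output is invariant to input order
    (groups are labeled G1, G2, ... by their lexicographically first member).
    """
    if not reps:
        raise ValueError("no representatives")
    graph = nx.Graph()
    graph.add_nodes_from(s.id for s in reps)
    ident: dict[tuple[str, str], float] = {}
    for i, si in enumerate(reps):
        for sj in reps[i + 1 :]:
            d = pairwise_identity(si, sj)
            ident[tuple(sorted((si.id, sj.id)))] = d
            if d > intra_min:
                graph.add_edge(si.id, sj.id)
    comps = sorted((sorted(c) for c in nx.connected_components(graph)), key=lambda c: c[0])
    groups = {f"G{i + 1}": comp for i, comp in enumerate(comps)}
    unresolved = []
    names = sorted(groups)
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            best = max(
                ident[tuple(sorted((x, y)))] for x in groups[ga] for y in groups[gb]
            )
            if best >= inter_max:
                unresolved.append((ga, gb, best))
    return GroupModel(
        groups=groups,
        representatives={s.id: s.sequence for s in reps},
        intra_min=intra_min,
        inter_max=inter_max,
        rep_cluster=rep_cluster,
        unresolved=unresolved,
    )


def assign_to_group(query: SeqRecord, model: GroupModel) -> tuple[str, float, str]:
    """Assign a query to its best representative's group.

    Returns (group label or "unassigned", best identity, best representative
    id).  Assignment requires identity strictly above the model's intra
    threshold.  The query must be aligned to the model's columns.
    """
    best_rep, best_id = None, -1.0
    for rep_id in sorted(model.representatives):
        d = pairwise_identity(query.sequence, model.representatives[rep_id])
        if d > best_id:
            best_rep, best_id = rep_id, d
    if best_id > model.intra_min:
        return model.group_of(best_rep), best_id, best_rep
    return "unassigned", best_id, best_rep
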