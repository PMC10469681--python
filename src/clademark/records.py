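"""Shared record types: genomes, gene families, sequence records.

Gene-family member sequences are labeled ``<genome>|<copy>`` so that the
genome of origin is recoverable from any gene-tree leaf.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .alignment import Alignment
from .tree import PhyloTree

__all__ = ["GenomeRecord", "GeneFamily", "SeqRecord", "genome_of"]


def genome_of(member_label: str) -> str:
    """Genome id encoded in a gene-family member label (``genome|copy``)."""
    return member_label.split("|", 1)[0]


@dataclass
class GenomeRecord:
    """A genome or MAG with assembly-quality metadata and clade labels."""

    id: str
    phylum: str = ""
    group: str = ""
    completeness: float = 100.0
    contamination: float = 0.0
    length_bp: int = 1
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0.0 <= self.completeness <= 100.0):
            raise ValueError(f"{self.id}: completeness outside [0, 100]")
        if not (0.0 <= self.contamination <= 100.0):
            raise ValueError(f"{self.id}: contamination outside [0, 100]")
        if self.length_bp <= 0:
            raise ValueError(f"{self.id}: genome length must be positive")


@dataclass
class GeneFamily:
    """A homolog family: per-genome copy counts, members, and optional tree/alignment.

    ``copy_counts`` maps genome id -> nonnegative copy number; ``members`` maps
    ``genome|copy`` labels to (possibly None) sequences.  When a gene tree is
    attached its leaves must be a subset of the member labels.
    """

    id: str
    copy_counts: dict[str, int] = field(default_factory=dict)
    members: dict[str, Optional[str]] = field(default_factory=dict)
    alignment: Optional[Alignment] = None
    tree: Optional[PhyloTree] = None

    def __post_init__(self):
        for g, c in self.copy_counts.items():
            if c < 0:
                raise ValueError(f"family {self.id}: negative copy count for {g}")
        if self.members:
            from collections import Counter

            counted = Counter(genome_of(m) for m in self.members)
            for g, c in counted.items():
                if self.copy_counts.get(g, 0) != c:
                    raise ValueError(
                        f"family {self.id}: copy count for {g} inconsistent with members"
                    )
        if self.tree is not None and self.members:
            extra = self.tree.leaf_labels - set(self.members)
            if extra:
                raise ValueError(f"family {self.id}: tree leaves not in members: {sorted(extra)}")

    @property
    def genomes_present(self) -> set[str]:
        return {g for g, c in self.copy_counts.items() if c >= 1}

    def focal_leaves(self, clade_of: dict[str, str], focal: str) -> set[str]:
        """Gene-tree leaves whose genome belongs to the focal clade."""
        if self.tree is None:
            raise ValueError(f"family {self.id} has no gene tree")
        return {lf for lf in self.tree.leaf_labels if clade_of.get(genome_of(lf)) == focal}


@dataclass
class SeqRecord:
    """A (possibly aligned) sequence with its ungapped length and metadata."""

    id: str
    sequence: str
    metadata: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        """Ungapped length in bp."""
        return len(self.sequence) - self.sequence.count("-")
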