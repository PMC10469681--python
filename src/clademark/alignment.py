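"""Alignment container, FASTA I/O and pairwise distances.

Sequences are stored as uppercase strings over a nucleotide or amino-acid
alphabet plus ``-`` for gaps; all rows of an :class:`Alignment` have equal
length and unique labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = ["Alignment", "p_distance", "jc_correct", "read_fasta", "write_fasta"]

GAP = "-"


@dataclass
class Alignment:
    """An ordered multiple alignment: parallel lists of labels and gapped rows."""

    labels: list[str] = field(default_factory=list)
    rows: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in length")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate labels in alignment")
        lens = {len(r) for r in self.rows}
        if len(lens) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lens)}")

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.labels, self.rows))

    def __getitem__(self, label: str) -> str:
        try:
            return self.rows[self.labels.index(label)]
        except ValueError:
            raise KeyError(label) from None

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def subset(self, labels: Iterable[str]) -> "Alignment":
        keep = [l for l in self.labels if l in set(labels)]
        return Alignment(keep, [self[l] for l in keep])

    def columns(self, indices: Iterable[int]) -> "Alignment":
        idx = list(indices)
        return Alignment(list(self.labels), ["".join(r[i] for i in idx) for r in self.rows])

    # I/O ---------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path) -> "Alignment":
        labels, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            labels.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(labels, rows)

    def to_fasta(self, path) -> None:
        write_fasta(path, zip(self.labels, self.rows))


def read_fasta(path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (label, sequence) pairs as FASTA wrapped at 80 columns."""
    recs = [SeqRecord(Seq(s), id=l, description="") for l, s in records]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        SeqIO.write(recs, fh, "fasta")


def jc_correct(d_p: float, on_saturation: str = "error") -> float:
    """Jukes-Cantor correction -(3/4) ln(1 - (4/3) d_p).

    ``d_p >= 3/4`` is beyond the model's reach; by default this errors,
    ``on_saturation='inf'`` returns +inf instead.
    """
    if d_p >= 0.75:
        if on_saturation == "inf":
            return math.inf
        raise ValueError(f"p-distance {d_p:.4f} >= 3/4: JC correction undefined")
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * d_p)


def p_distance(
    aln: Alignment, correction: str = "none", on_saturation: str = "error"
) -> np.ndarray:
    """Pairwise distance matrix under pairwise gap deletion.

    For each pair only columns where neither sequence has a gap are compared;
    ``d_p`` = mismatches / compared sites.  ``correction='JC'`` applies the
    Jukes-Cantor transform.  A pair with zero comparable sites is an error.
    """
    if correction not in ("none", "JC"):
        raise ValueError(f"unknown correction {correction!r}")
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 sequences")
    arr = np.array([list(r) for r in aln.rows])
    gap = arr == GAP
    n = aln.n_seqs
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~gap[i] & ~gap[j]
            m = int(usable.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable sites for pair ({aln.labels[i]!r}, {aln.labels[j]!r})"
                )
            d = float((arr[i][usable] != arr[j][usable]).sum()) / m
            if correction == "JC":
                d = jc_correct(d, on_saturation=on_saturation)
            D[i, j] = D[j, i] = d
    return D
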