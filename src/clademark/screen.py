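"""Marker-gene curation: single-copy, occupancy, monophyly and contamination
screens over gene families, then gap trimming and supermatrix concatenation.

The screen formalizes how phylogenomic marker sets are curated from MAG
collections: only genomes above a completeness floor count; a family must be
single-copy in every counted genome and present in enough of them; its gene
tree must place the focal clade's sequences as a monophyletic group; and the
smallest clade spanning the focal sequences must not contain sequences from
excluded clades (the operational reading of "clusters with" contamination).
Filters apply in that fixed order and each discarded family carries exactly
its first failing rule.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .alignment import Alignment
from .records import GeneFamily, GenomeRecord, genome_of
from .tree import PhyloTree

logger = logging.getLogger(__name__)

__all__ = [
    "ScreenConfig",
    "MarkerReport",
    "eligible_genomes",
    "single_copy_families",
    "monophyly_screen",
    "contamination_screen",
    "trim_alignment",
    "concatenate",
    "run_marker_screen",
    "read_genomes_tsv",
    "write_genomes_tsv",
    "load_families",
    "write_families",
]

KEPT = "kept"
R_MULTI_COPY = "multi-copy"
R_OCCUPANCY = "low-occupancy"
R_NON_MONOPHYLETIC = "non-monophyletic"
R_CONTAMINATION = "contamination"


@dataclass
class ScreenConfig:
    """Thresholds for the marker screen.

    completeness_min
        strict lower bound (percent) for a genome to count in the screen.
    occupancy_min
        minimum fraction of eligible genomes a family must occur in
        (1.0 reproduces a "present in every counted MAG" reading, 0.5 the
        "at least half" refinement).
    focal / excluded
        clade labels (matched against GenomeRecord.phylum) defining the
        monophyly and contamination screens.
    max_gap_frac
        columns with a strictly greater gap fraction are trimmed.
    strict_contamination
        if True the contamination screen additionally requires focal
        monophyly (a stricter reading of "does not cluster with").
    """

    focal: str
    excluded: frozenset = frozenset()
    completeness_min: float = 85.0
    occupancy_min: float = 0.5
    max_gap_frac: float = 0.05
    strict_contamination: bool = False

    def __post_init__(self):
        if not (0.0 <= self.completeness_min <= 100.0):
            raise ValueError("completeness_min outside [0, 100]")
        if not (0.0 <= self.occupancy_min <= 1.0):
            raise ValueError("occupancy_min outside [0, 1]")
        if not (0.0 <= self.max_gap_frac <= 1.0):
            raise ValueError("max_gap_frac outside [0, 1]")
        self.excluded = frozenset(self.excluded)


@dataclass
class MarkerReport:
    """Outcome of a full marker screen."""

    verdicts: pd.DataFrame          # family, kept, reason
    supermatrix: Optional[Alignment]
    partitions: list[tuple[str, int, int]]  # (family, start, end) 0-based half-open
    eligible: set[str] = field(default_factory=set)

    @property
    def kept_families(self) -> list[str]:
        return list(self.verdicts.loc[self.verdicts["kept"], "family"])

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.verdicts.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
        with open(outdir / "partitions.json", "w") as fh:
            json.dump(
                [{"family": f, "start": s, "end": e} for f, s, e in self.partitions], fh, indent=1
            )
        with open(outdir / "partitions.txt", "w") as fh:
            for fam, s, e in self.partitions:
                fh.write(f"GENE, {fam} = {s + 1}-{e}\n")  # 1-based inclusive, RAxML-style
        if self.supermatrix is not None:
            self.supermatrix.to_fasta(outdir / "supermatrix.fasta")


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------


def eligible_genomes(genomes: Sequence[GenomeRecord], completeness_min: float = 85.0) -> set[str]:
    """Genome ids with completeness strictly above the threshold."""
    return {g.id for g in genomes if g.completeness > completeness_min}


def _single_copy_reason(fam: GeneFamily, eligible: set[str], occupancy_min: float) -> str:
    counts = [fam.copy_counts.get(g, 0) for g in eligible]
    if any(c >= 2 for c in counts):
        return R_MULTI_COPY
    occupancy = sum(1 for c in counts if c >= 1) / len(eligible)
    if occupancy < occupancy_min:
        return R_OCCUPANCY
    return KEPT


def single_copy_families(
    families: Sequence[GeneFamily], eligible: set[str], occupancy_min: float = 0.5
) -> list[str]:
    """Families single-copy in every eligible genome and occupying enough of them.

    Kept iff no eligible genome carries >=2 copies and the fraction of
    eligible genomes carrying the family is >= ``occupancy_min``.
    """
    if not eligible:
        raise ValueError("eligible genome set is empty")
    return [
        f.id for f in families if _single_copy_reason(f, eligible, occupancy_min) == KEPT
    ]


def _focal_leaves(fam: GeneFamily, clade_of: dict[str, str], focal: str) -> set[str]:
    if fam.tree is None:
        raise ValueError(f"family {fam.id} has no gene tree")
    return {lf for lf in fam.tree.leaf_labels if clade_of.get(genome_of(lf)) == focal}


def _monophyly_reason(fam: GeneFamily, clade_of: dict[str, str], focal: str) -> str:
    focal_lv = _focal_leaves(fam, clade_of, focal)
    if len(focal_lv) < 2:
        logger.info("family %s: <2 focal leaves, monophyly passes vacuously", fam.id)
        return KEPT
    return KEPT if fam.tree.is_monophyletic(focal_lv) else R_NON_MONOPHYLETIC


def monophyly_screen(
    families: Sequence[GeneFamily], clade_of: dict[str, str], focal: str
) -> list[str]:
    """Families whose focal-clade sequences are monophyletic in the gene tree.

    Families with fewer than two focal leaves pass vacuously (logged).
    """
    return [f.id for f in families if _monophyly_reason(f, clade_of, focal) == KEPT]


def _contamination_reason(
    fam: GeneFamily, clade_of: dict[str, str], focal: str, excluded: frozenset, strict: bool
) -> str:
    focal_lv = _focal_leaves(fam, clade_of, focal)
    if not focal_lv:
        return KEPT
    if strict and len(focal_lv) >= 2 and not fam.tree.is_monophyletic(focal_lv):
        return R_CONTAMINATION
    side = fam.tree.minimal_spanning_side(focal_lv)
    for lf in side:
        if clade_of.get(genome_of(lf)) in excluded:
            return R_CONTAMINATION
    return KEPT


def contamination_screen(
    families: Sequence[GeneFamily],
    clade_of: dict[str, str],
    focal: str,
    excluded: frozenset | set,
    strict: bool = False,
) -> list[str]:
    """Families whose focal minimal spanning side is free of excluded-clade leaves."""
    excluded = frozenset(excluded)
    return [
        f.id
        for f in families
        if _contamination_reason(f, clade_of, focal, excluded, strict) == KEPT
    ]


# ---------------------------------------------------------------------------
# trimming and concatenation
# ---------------------------------------------------------------------------


def trim_alignment(aln: Alignment, max_gap_frac: float = 0.05) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction strictly exceeds ``max_gap_frac``.

    A column with exactly the threshold fraction of gaps is kept ("more than"
    is read strictly).  Returns the trimmed alignment and the kept column
    indices (original order).
    """
    if aln.n_seqs == 0:
        raise ValueError("empty alignment")
    n = aln.n_seqs
    kept = [
        i for i in range(aln.n_cols)
        if sum(r[i] == "-" for r in aln.rows) / n <= max_gap_frac
    ]
    if not kept:
        logger.warning("trim_alignment: every column exceeded the gap threshold")
    return aln.columns(kept), kept


def concatenate(
    alignments: dict[str, Alignment], genomes: Sequence[str]
) -> tuple[Alignment, list[tuple[str, int, int]]]:
    """Concatenate per-family alignments into a supermatrix.

    Rows are the given genomes (one row each); a genome absent from a family
    gets all-gap filler for that block.  Family alignment rows must be
    labeled by genome id, at most once each.  Returns the supermatrix and the
    partition list of 0-based half-open column intervals, in input order.
    """
    genomes = list(genomes)
    partitions: list[tuple[str, int, int]] = []
    blocks: dict[str, list[str]] = {g: [] for g in genomes}
    start = 0
    for fam_id, aln in alignments.items():
        if len(set(aln.labels)) != len(aln.labels):
            raise ValueError(f"family {fam_id}: duplicate genome rows (single-copy violated)")
        width = aln.n_cols
        for g in genomes:
            blocks[g].append(aln[g] if g in aln else "-" * width)
        partitions.append((fam_id, start, start + width))
        start += width
    sup = Alignment(genomes, ["".join(blocks[g]) for g in genomes])
    return sup, partitions


# ---------------------------------------------------------------------------
# the full screen
# ---------------------------------------------------------------------------


def _family_genome_alignment(fam: GeneFamily, genomes: set[str]) -> Alignment:
    """Family alignment restricted to the given genomes, rows relabeled by genome."""
    labels, rows = [], []
    for label, row in zip(fam.alignment.labels, fam.alignment.rows):
        g = genome_of(label)
        if g in genomes:
            if g in labels:
                raise ValueError(f"family {fam.id}: duplicate sequence for genome {g}")
            labels.append(g)
            rows.append(row)
    return Alignment(labels, rows)


def run_marker_screen(
    families: Sequence[GeneFamily],
    genomes: Sequence[GenomeRecord],
    config: ScreenConfig,
) -> MarkerReport:
    """Apply the full marker screen and assemble the trimmed supermatrix.

    Order: genome eligibility -> single-copy/occupancy -> focal monophyly ->
    excluded-clade contamination -> per-family gap trimming -> concatenation.
    The verdict table lists every family with its first failing rule; the
    supermatrix covers the eligible genomes (None when no family has an
    alignment or none survive).
    """
    eligible = eligible_genomes(genomes, config.completeness_min)
    if not families:
        logger.warning("run_marker_screen: no families supplied")
        return MarkerReport(
            pd.DataFrame(columns=["family", "kept", "reason"]), None, [], eligible
        )
    if not eligible:
        raise ValueError("no genome passes the completeness threshold")
    clade_of = {g.id: g.phylum for g in genomes}

    verdicts = []
    survivors: list[GeneFamily] = []
    for fam in families:
        reason = _single_copy_reason(fam, eligible, config.occupancy_min)
        if reason == KEPT:
            reason = _monophyly_reason(fam, clade_of, config.focal)
        if reason == KEPT:
            reason = _contamination_reason(
                fam, clade_of, config.focal, config.excluded, config.strict_contamination
            )
        verdicts.append({"family": fam.id, "kept": reason == KEPT, "reason": reason})
        if reason == KEPT:
            survivors.append(fam)

    vdf = pd.DataFrame(verdicts, columns=["family", "kept", "reason"])
    supermatrix, partitions = None, []
    with_aln = [f for f in survivors if f.alignment is not None]
    if with_aln:
        if len(with_aln) < len(survivors):
            logger.warning(
                "run_marker_screen: %d kept families lack alignments and are "
                "excluded from the supermatrix", len(survivors) - len(with_aln),
            )
        trimmed = {}
        for fam in with_aln:
            sub = _family_genome_alignment(fam, eligible)
            if sub.n_seqs == 0:
                continue
            t, _ = trim_alignment(sub, config.max_gap_frac)
            trimmed[fam.id] = t
        if trimmed:
            rows = sorted(eligible)
            supermatrix, partitions = concatenate(trimmed, rows)
    elif survivors:
        logger.warning("run_marker_screen: no kept family carries an alignment")
    return MarkerReport(vdf, supermatrix, partitions, eligible)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_COLS = ["id", "phylum", "group", "completeness", "contamination", "length_bp"]


def read_genomes_tsv(path) -> list[GenomeRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"genome metadata missing columns: {sorted(missing)}")
    return [
        GenomeRecord(
            id=str(r["id"]), phylum=str(r["phylum"]), group=str(r["group"]),
            completeness=float(r["completeness"]), contamination=float(r["contamination"]),
            length_bp=int(r["length_bp"]),
        )
        for _, r in df.iterrows()
    ]


def write_genomes_tsv(path, genomes: Sequence[GenomeRecord]) -> None:
    pd.DataFrame(
        [
            {
                "id": g.id, "phylum": g.phylum, "group": g.group,
                "completeness": g.completeness, "contamination": g.contamination,
                "length_bp": g.length_bp,
            }
            for g in genomes
        ],
        columns=_META_COLS,
    ).to_csv(path, sep="\t", index=False)


def load_families(directory, counts_tsv=None) -> list[GeneFamily]:
    """Load families from ``<dir>/<id>.fasta`` (+ optional ``<id>.nwk`` trees).

    Copy counts are derived from the ``genome|copy`` member labels unless a
    families x genomes counts TSV is supplied.
    """
    directory = Path(directory)
    counts = None
    if counts_tsv is not None:
        counts = pd.read_csv(counts_tsv, sep="\t", index_col=0)
    fams = []
    for fa in sorted(directory.glob("*.fasta")):
        fam_id = fa.stem
        aln = Alignment.from_fasta(fa)
        members = dict(zip(aln.labels, aln.rows))
        if counts is not None and fam_id in counts.index:
            cc = {g: int(c) for g, c in counts.loc[fam_id].items()}
        else:
            cc = {}
            for label in aln.labels:
                g = genome_of(label)
                cc[g] = cc.get(g, 0) + 1
        tree = None
        nwk = directory / f"{fam_id}.nwk"
        if nwk.exists():
            tree = PhyloTree.from_newick(nwk.read_text())
        fams.append(GeneFamily(fam_id, copy_counts=cc, members=members, alignment=aln, tree=tree))
    return fams


def write_families(directory, families: Sequence[GeneFamily], genomes=None) -> None:
    """Write ``<id>.fasta``/``<id>.nwk`` per family plus a copy-count TSV."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    all_genomes = sorted(
        set(genomes or ()) | {g for f in families for g in f.copy_counts}
    )
    rows = {}
    for fam in families:
        rows[fam.id] = {g: fam.copy_counts.get(g, 0) for g in all_genomes}
        if fam.alignment is not None:
            fam.alignment.to_fasta(directory / f"{fam.id}.fasta")
        if fam.tree is not None:
            (directory / f"{fam.id}.nwk").write_text(fam.tree.to_newick() + "\n")
    pd.DataFrame.from_dict(rows, orient="index")[all_genomes].to_csv(
        directory / "copy_counts.tsv", sep="\t"
    )
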