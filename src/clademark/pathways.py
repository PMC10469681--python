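"""Pathway presence calls and antioxidant (oxygen-sensitivity) profiling.

A pathway is called *present* when strictly more than half of its associated
genes are found, *partial* when at least two subunits of its key gene cluster
are found (e.g. the archaeal CODH/ACS cluster cdhABCDE for the
Wood-Ljungdahl pathway), and *absent* otherwise.  The antioxidant panel
(superoxide reductase, rubredoxin, rubrerythrin, bcp-2) grades genomes from
"none-detected" (a strict-anaerobe candidate) to "full".

Pathway definitions ship as editable JSON: the exact associated-gene lists
behind published figures vary by annotation pipeline, so the defaults here
are a documented, replaceable convention rather than a fixed truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayDefinition",
    "AntioxidantPanel",
    "call_pathway",
    "antioxidant_profile",
    "profile_matrix",
    "default_pathways",
    "load_pathways",
    "save_pathways",
    "PRESENT",
    "PARTIAL",
    "ABSENT",
]

PRESENT = "present"
PARTIAL = "partial"
ABSENT = "absent"

_CATEGORY_ORDER = {ABSENT: 0, PARTIAL: 1, PRESENT: 2}


@dataclass
class PathwayDefinition:
    """A named gene set with a strict-majority presence rule.

    key_cluster
        subset of ``genes`` whose partial presence (strictly more than one
        subunit) still earns a "partial" call; empty disables partial calls.
    """

    name: str
    genes: list[str]
    key_cluster: list[str] = field(default_factory=list)
    min_key_subunits: int = 2

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"pathway {self.name!r}: empty gene list")
        extra = set(self.key_cluster) - set(self.genes)
        if extra:
            raise ValueError(f"pathway {self.name!r}: key cluster not in gene list: {sorted(extra)}")
        if self.min_key_subunits < 1:
            raise ValueError("min_key_subunits must be >= 1")


@dataclass
class AntioxidantPanel:
    """The four-gene oxygen-defense panel; extensible via config."""

    genes: tuple[str, ...] = ("sor", "rubredoxin", "rubrerythrin", "bcp-2")


def _present_set(row: Mapping[str, int], symbols: Sequence[str]) -> list[str]:
    return [g for g in symbols if int(row.get(g, 0)) >= 1]


def call_pathway(row: Mapping[str, int], pathway: PathwayDefinition) -> str:
    """Call one pathway for one genome's gene-copy row.

    present  iff strictly more than half of the pathway's genes have copy >= 1
    partial  iff at least ``min_key_subunits`` key-cluster subunits are present
    absent   otherwise.  Gene symbols missing from the row count as 0.
    """
    n_present = len(_present_set(row, pathway.genes))
    if n_present > len(pathway.genes) / 2.0:
        return PRESENT
    if pathway.key_cluster:
        if len(_present_set(row, pathway.key_cluster)) >= pathway.min_key_subunits:
            return PARTIAL
    return ABSENT


def antioxidant_profile(
    row: Mapping[str, int], panel: AntioxidantPanel | None = None
) -> tuple[str, list[str]]:
    """Grade a genome's antioxidant gene complement.

    none-detected (0 of the panel), minimal (exactly 1), partial (2-3),
    full (all).  Returns the category and the present genes.
    """
    panel = panel or AntioxidantPanel()
    present = _present_set(row, panel.genes)
    k, n = len(present), len(panel.genes)
    if k == 0:
        cat = "none-detected"
    elif k == 1:
        cat = "minimal"
    elif k == n:
        cat = "full"
    else:
        cat = "partial"
    return cat, present


def profile_matrix(
    matrix: pd.DataFrame,
    pathway_defs: Sequence[PathwayDefinition] | None = None,
    panel: AntioxidantPanel | None = None,
) -> pd.DataFrame:
    """Per-genome profile: one pathway call per definition plus the antioxidant grade.

    ``matrix`` is genomes x gene symbols (copy counts).  Symbols referenced by
    a definition but absent from the matrix count as 0 everywhere (logged):
    absence of evidence is routine for incomplete MAGs.
    """
    if matrix.index.has_duplicates:
        dupes = sorted(matrix.index[matrix.index.duplicated()].unique())
        raise ValueError(f"duplicate genome ids: {dupes}")
    pathway_defs = list(pathway_defs) if pathway_defs is not None else default_pathways()
    panel = panel or AntioxidantPanel()
    wanted = {g for p in pathway_defs for g in p.genes} | set(panel.genes)
    unknown = sorted(wanted - set(matrix.columns))
    if unknown:
        logger.info("profile_matrix: symbols absent from annotation table: %s", unknown)
    rows = []
    for genome in matrix.index:
        row = matrix.loc[genome].to_dict()
        rec = {"genome": genome}
        for p in pathway_defs:
            rec[p.name] = call_pathway(row, p)
        cat, present = antioxidant_profile(row, panel)
        rec["antioxidant"] = cat
        rec["antioxidant_genes"] = ",".join(present)
        rows.append(rec)
    cols = ["genome"] + [p.name for p in pathway_defs] + ["antioxidant", "antioxidant_genes"]
    return pd.DataFrame(rows, columns=cols).set_index("genome")


def default_pathways() -> list[PathwayDefinition]:
    """Default definitions: WL pathway (key cluster cdhABCDE), mcr, mtr.

    The Wood-Ljungdahl list covers the archaeal H4MPT methyl branch plus the
    CODH/ACS carbonyl branch; the tetrahydromethanopterin S-methyltransferase
    (mtr) complex has no key cluster, so only the strict majority applies and
    a lone mtrH is called absent.
    """
    return [
        PathwayDefinition(
            name="WL",
            genes=["fwd", "ftr", "mch", "mtd", "mer", "cdhA", "cdhB", "cdhC", "cdhD", "cdhE"],
            key_cluster=["cdhA", "cdhB", "cdhC", "cdhD", "cdhE"],
        ),
        PathwayDefinition(
            name="mcr",
            genes=["mcrA", "mcrB", "mcrC", "mcrD", "mcrG"],
            key_cluster=["mcrA", "mcrB", "mcrG"],
        ),
        PathwayDefinition(
            name="mtr",
            genes=[f"mtr{x}" for x in "ABCDEFGH"],
        ),
    ]


def save_pathways(path, pathway_defs: Sequence[PathwayDefinition]) -> None:
    Path(path).write_text(
        json.dumps(
            [
                {
                    "name": p.name,
                    "genes": p.genes,
                    "key_cluster": p.key_cluster,
                    "min_key_subunits": p.min_key_subunits,
                }
                for p in pathway_defs
            ],
            indent=1,
        )
    )


def load_pathways(path) -> list[PathwayDefinition]:
    data = json.loads(Path(path).read_text())
    return [
        PathwayDefinition(
            name=d["name"],
            genes=list(d["genes"]),
            key_cluster=list(d.get("key_cluster", [])),
            min_key_subunits=int(d.get("min_key_subunits", 2)),
        )
        for d in data
    ]
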