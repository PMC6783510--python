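"""Construction of antagonistic functional gene module pairs.

A functional gene module here is a set of genes evidencing one side of a
phenotype — for the vasodilation use case, the positive module (PFGM)
collects genes that positively regulate blood vessel diameter
(GO:0097755 core annotations plus their co-expressed partners) and the
negative module (NFGM) the mirror set for GO:0097756. Because the TES
contrast assumes the two modules are antagonistic evidence sets, any
gene landing in both candidate sets is removed from both.

Inputs are plain files: a term→gene annotation table (2-column TSV or
GAF 2.x), an optional OBO ontology for descendant propagation, and
co-expression query exports (gene, score, p-value per row). Modules are
exchanged as GMT.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CoexpressionRecord",
    "GeneModule",
    "ModulePair",
    "read_annotations",
    "read_ontology",
    "core_genes_for_term",
    "read_coexpression_table",
    "filter_coexpression",
    "assemble_module_pair",
    "GeneSet",
    "read_gmt",
    "write_gmt",
    "write_provenance",
]


class CoexpressionRecord(NamedTuple):
    """One row of a co-expression query export."""

    gene_id: str
    score: float
    p_value: float


@dataclass(frozen=True)
class GeneModule:
    """Core + co-expressed genes for one side of a phenotype.

    A gene annotated to the term itself counts as core even if it also
    appeared in the co-expression evidence; ``members`` is the disjoint
    union of the two origins.
    """

    name: str
    term_id: str
    core_genes: frozenset[str]
    coexpressed_genes: frozenset[str]

    def __post_init__(self) -> None:
        overlap = self.core_genes & self.coexpressed_genes
        if overlap:
            raise ValueError(
                f"module {self.name}: genes listed as both core and co-expressed: "
                f"{sorted(overlap)}"
            )
        if not (self.core_genes or self.coexpressed_genes):
            raise ValueError(f"module {self.name} is empty")

    @property
    def members(self) -> frozenset[str]:
        return self.core_genes | self.coexpressed_genes

    def origin(self, gene: str) -> str:
        if gene in self.core_genes:
            return "core"
        if gene in self.coexpressed_genes:
            return "coexpressed"
        raise KeyError(gene)


@dataclass(frozen=True)
class ModulePair:
    """The antagonistic positive/negative module pair."""

    positive: GeneModule
    negative: GeneModule

    def __post_init__(self) -> None:
        shared = self.positive.members & self.negative.members
        if shared:
            raise ValueError(
                f"modules {self.positive.name} and {self.negative.name} share "
                f"genes: {sorted(shared)}"
            )


# ---------------------------------------------------------------------------
# annotations and ontology


def read_annotations(path: str | Path, format: str | None = None) -> dict[str, set[str]]:
    """Read a term→gene table from 2-column TSV or GAF 2.x.

    TSV rows are ``term_id<TAB>gene_id`` (a header line starting with
    ``term`` is skipped). GAF rows use column 5 (GO id) and column 3
    (object symbol); comment lines start with ``!``.
    """
    path = Path(path)
    if format is None:
        format = "gaf" if path.suffix.lower() in (".gaf", ".gaf2") else "tsv"
    table: dict[str, set[str]] = {}
    if format == "gaf":
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 5:
                raise ValueError(f"{path}: GAF line with <5 columns: {line[:60]!r}")
            table.setdefault(cols[4], set()).add(cols[2])
    elif format == "tsv":
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            if lineno == 1 and cols[0].lower().startswith("term"):
                continue
            table.setdefault(cols[0], set()).add(cols[1])
    else:
        raise ValueError(f"unknown annotation format {format!r}")
    return table


def read_ontology(path: str | Path) -> nx.MultiDiGraph:
    """Parse an OBO file into a child→parent graph (via obonet)."""
    import obonet

    return obonet.read_obo(str(path))


_PROPAGATING = {"is_a", "part_of"}


def _descendants(ontology: nx.MultiDiGraph | nx.DiGraph, term_id: str) -> set[str]:
    """Terms below ``term_id`` through is_a / part_of edges.

    obonet graphs point child → parent, so descendants of a term are its
    graph-theoretic ancestors along the retained relation types.
    """
    sub = nx.DiGraph()
    sub.add_nodes_from(ontology.nodes)
    if isinstance(ontology, nx.MultiDiGraph):
        edges = [(u, v) for u, v, k in ontology.edges(keys=True) if k in _PROPAGATING]
    else:
        edges = [
            (u, v)
            for u, v, d in ontology.edges(data=True)
            if d.get("relation", "is_a") in _PROPAGATING
        ]
    sub.add_edges_from(edges)
    return set(nx.ancestors(sub, term_id))


def core_genes_for_term(
    annotations: Mapping[str, set[str]] | str | Path,
    term_id: str,
    propagate: bool = False,
    ontology: nx.MultiDiGraph | nx.DiGraph | str | Path | None = None,
) -> set[str]:
    """Genes annotated to ``term_id`` (optionally plus its descendants).

    With ``propagate`` the is_a/part_of transitive closure of descendant
    terms is included, so a gene annotated to a narrower term counts for
    the broader query term — the standard GO true-path reading.
    """
    if isinstance(annotations, (str, Path)):
        annotations = read_annotations(annotations)
    terms = {term_id}
    if propagate:
        if ontology is None:
            raise ValueError("propagate=True requires an ontology graph")
        if isinstance(ontology, (str, Path)):
            ontology = read_ontology(ontology)
        if term_id not in ontology:
            raise KeyError(f"term {term_id!r} not in ontology")
        terms |= _descendants(ontology, term_id)
    if term_id not in annotations and not (terms & annotations.keys()):
        raise KeyError(f"term {term_id!r} not found in annotation source")
    genes: set[str] = set()
    for t in terms:
        genes |= annotations.get(t, set())
    if not genes:
        raise ValueError(f"term {term_id!r} has no annotated genes; module would be empty")
    return genes


# ---------------------------------------------------------------------------
# co-expression evidence


def read_coexpression_table(path: str | Path) -> list[CoexpressionRecord]:
    """Read a (gene, score, p_value) TSV export with a header row."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (gene, score, p_value)")
    records = []
    for row in df.itertuples(index=False):
        records.append(CoexpressionRecord(str(row[0]), float(row[1]), float(row[2])))
    return records


def filter_coexpression(
    records: Iterable[CoexpressionRecord],
    score_min: float = 0.0,
    p_max: float = 0.01,
) -> set[str]:
    """Genes with co-expression score strictly above ``score_min`` and
    p-value strictly below ``p_max``; duplicates collapse to one entry.
    """
    kept: set[str] = set()
    for rec in records:
        if not (0.0 <= rec.p_value <= 1.0):
            raise ValueError(f"p_value outside [0,1] for {rec.gene_id}: {rec.p_value}")
        if not math.isfinite(rec.score):
            raise ValueError(f"non-finite score for {rec.gene_id}")
        if rec.score > score_min and rec.p_value < p_max:
            kept.add(rec.gene_id)
    return kept


# ---------------------------------------------------------------------------
# pair assembly


def assemble_module_pair(
    core_pos: set[str],
    coexp_pos: set[str],
    core_neg: set[str],
    coexp_neg: set[str],
    pos_name: str = "PFGM",
    neg_name: str = "NFGM",
    pos_term: str = "GO:0097755",
    neg_term: str = "GO:0097756",
) -> ModulePair:
    """Assemble the antagonistic pair with cross-module overlap removal.

    Genes occurring in both the positive candidate set (core ∪
    co-expressed) and the negative candidate set are deleted from BOTH
    modules: a gene cannot evidence dilation and constriction at once,
    and disjointness is what makes the TES contrast meaningful. Within a
    module, a co-expressed gene that is already core is counted once, as
    core.
    """
    if not core_pos or not core_neg:
        raise ValueError("core gene sets must be nonempty")
    pos_cand = set(core_pos) | set(coexp_pos)
    neg_cand = set(core_neg) | set(coexp_neg)
    shared = pos_cand & neg_cand
    if shared:
        logger.info("removing %d genes shared between candidate modules", len(shared))

    pos_core = set(core_pos) - shared
    pos_coexp = set(coexp_pos) - set(core_pos) - shared
    neg_core = set(core_neg) - shared
    neg_coexp = set(coexp_neg) - set(core_neg) - shared
    if not (pos_core or pos_coexp):
        raise ValueError(f"module {pos_name} emptied by overlap removal")
    if not (neg_core or neg_coexp):
        raise ValueError(f"module {neg_name} emptied by overlap removal")

    return ModulePair(
        positive=GeneModule(pos_name, pos_term, frozenset(pos_core), frozenset(pos_coexp)),
        negative=GeneModule(neg_name, neg_term, frozenset(neg_core), frozenset(neg_coexp)),
    )


# ---------------------------------------------------------------------------
# GMT exchange


class GeneSet(NamedTuple):
    name: str
    description: str
    genes: frozenset[str]


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (name, description, tab-separated members)."""
    sets: list[GeneSet] = []
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs ≥3 fields")
        name, desc, members = fields[0], fields[1], fields[2:]
        if name in seen:
            raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
        seen.add(name)
        if len(set(members)) != len(members):
            logger.warning("%s:%d: duplicate members in set %s collapsed", path, lineno, name)
        sets.append(GeneSet(name, desc, frozenset(members)))
    return sets


def write_gmt(
    sets: ModulePair | Iterable[GeneModule | GeneSet | tuple],
    path: str | Path,
) -> None:
    """Write gene sets (or a module pair) as GMT, members sorted."""
    if isinstance(sets, ModulePair):
        sets = [sets.positive, sets.negative]
    with open(path, "w") as fh:
        for s in sets:
            if isinstance(s, GeneModule):
                name, desc, genes = s.name, s.term_id, s.members
            elif isinstance(s, GeneSet):
                name, desc, genes = s.name, s.description, s.genes
            else:
                name, desc, genes = s
            fh.write("\t".join([name, desc, *sorted(genes)]) + "\n")


def write_provenance(pair: ModulePair, path: str | Path) -> None:
    """Per-gene origin table: module, gene, core|coexpressed."""
    with open(path, "w") as fh:
        fh.write("module\tgene\torigin\n")
        for module in (pair.positive, pair.negative):
            for gene in sorted(module.members):
                fh.write(f"{module.name}\t{gene}\t{module.origin(gene)}\n")
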