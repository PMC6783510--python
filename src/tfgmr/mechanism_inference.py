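"""Shared-mechanism inference from compound-regulated gene sets.

Compounds acting through a common mechanism should regulate overlapping
subsets of the reference modules. Two tools quantify this:

* pairwise overlap of leading-edge gene sets, tested with the two-sided
  Fisher exact test on the 2×2 membership table over a shared universe;
* over-representation analysis (ORA) of a compound's regulated genes
  against a functional annotation collection — one-sided hypergeometric
  upper-tail p per term, Benjamini–Hochberg adjusted across terms —
  exported as a compound–function bipartite edge list.

The overlap universe defaults to the union of the two reference modules
(leading edges are subsets of the modules); the full measured gene
universe can be passed instead, and the choice travels with the output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ContingencyTable2x2",
    "OraResult",
    "leading_edge_overlap",
    "pairwise_overlap_table",
    "ora",
    "export_bipartite",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Membership counts for two gene sets over a universe.

    a = in both, b = A only, c = B only, d = neither.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]])


@dataclass(frozen=True)
class OraResult:
    """Over-representation of one annotation term in a query set."""

    term_id: str
    term_size: int
    overlap: int
    p_value: float
    adjusted_p: float


def leading_edge_overlap(
    set_a: set[str],
    set_b: set[str],
    universe: set[str],
) -> tuple[ContingencyTable2x2, float]:
    """Two-sided Fisher exact test of the overlap of two gene sets.

    Both sets must lie inside the universe. The p-value is the classical
    point-probability two-sided Fisher p: the sum of hypergeometric
    probabilities of all tables (at fixed margins) no more probable than
    the observed one.
    """
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if len(universe) < 2:
        raise ValueError("universe must contain at least 2 genes")
    if not set_a <= universe:
        raise ValueError(f"set A has genes outside the universe: {sorted(set_a - universe)[:5]}")
    if not set_b <= universe:
        raise ValueError(f"set B has genes outside the universe: {sorted(set_b - universe)[:5]}")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    d = len(universe) - a - b - c
    table = ContingencyTable2x2(a, b, c, d)
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return table, float(p)


def pairwise_overlap_table(
    sets: Mapping[str, set[str]],
    universe: set[str],
) -> pd.DataFrame:
    """All pairwise Fisher overlap tests among named gene sets.

    Returns a long-format frame (set_a, set_b, overlap, size_a, size_b,
    universe, p_value) for every unordered pair.
    """
    names = sorted(sets)
    rows = []
    for i, na in enumerate(names):
        for nb in names[i + 1 :]:
            table, p = leading_edge_overlap(sets[na], sets[nb], universe)
            rows.append(
                {
                    "set_a": na,
                    "set_b": nb,
                    "overlap": table.a,
                    "size_a": table.a + table.b,
                    "size_b": table.a + table.c,
                    "universe": table.n,
                    "p_value": p,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["set_a", "set_b", "overlap", "size_a", "size_b", "universe", "p_value"],
    )


def ora(
    query: set[str],
    annotation: Mapping[str, set[str] | frozenset[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> list[OraResult]:
    """Hypergeometric over-representation of annotation terms in a query.

    For each term with at least one gene in the universe, the one-sided
    upper-tail p is P[X ≥ overlap] for X hypergeometric(|universe|,
    term∩universe, |query|); adjusted p-values are Benjamini–Hochberg
    across all tested terms. Results are sorted by adjusted p ascending
    (ties by term id). ``alpha`` is carried along for downstream
    filtering; all tested terms are returned.
    """
    query, universe = set(query), set(universe)
    if not query:
        raise ValueError("empty query gene set")
    if not annotation:
        raise ValueError("empty annotation table")
    if not query <= universe:
        raise ValueError(
            f"query has genes outside the universe: {sorted(query - universe)[:5]}"
        )
    m = len(universe)
    nq = len(query)
    terms, pvals, sizes, overlaps = [], [], [], []
    for term, genes in annotation.items():
        in_universe = set(genes) & universe
        if not in_universe:
            continue
        k = len(query & in_universe)
        # P[X >= k], X ~ Hypergeom(M=m, n=|term|, N=|query|)
        p = float(stats.hypergeom.sf(k - 1, m, len(in_universe), nq))
        terms.append(term)
        pvals.append(min(p, 1.0))
        sizes.append(len(in_universe))
        overlaps.append(k)
    if not terms:
        raise ValueError("no annotation term intersects the universe")
    _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    results = [
        OraResult(t, s, k, p, float(min(ap, 1.0)))
        for t, s, k, p, ap in zip(terms, sizes, overlaps, pvals, adjusted)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.term_id))
    return results


def export_bipartite(
    results: Mapping[str, Iterable[OraResult]],
    threshold: float = 0.05,
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Compound–function bipartite edge list at an adjusted-p threshold.

    One edge per (compound, term) with adjusted_p ≤ threshold, annotated
    with node degrees (how many functions a compound hits, how many
    compounds share a function). An empty edge list is still a valid
    frame/file. If ``path`` is given, the frame is written as TSV.
    """
    edges = []
    for compound in sorted(results):
        for r in results[compound]:
            if r.adjusted_p <= threshold:
                edges.append({"compound": compound, "term_id": r.term_id, "adjusted_p": r.adjusted_p})
    df = pd.DataFrame(edges, columns=["compound", "term_id", "adjusted_p"])
    if len(df):
        df["compound_degree"] = df.groupby("compound")["term_id"].transform("size")
        df["term_degree"] = df.groupby("term_id")["compound"].transform("size")
    else:
        df["compound_degree"] = pd.Series(dtype=int)
        df["term_degree"] = pd.Series(dtype=int)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
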