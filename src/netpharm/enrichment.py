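"""Hypergeometric over-representation analysis (ORA) with BH correction.

A query gene list is tested against GO-style (BP/CC/MF) and pathway gene
sets. For each set with at least one overlapping gene the upper-tail
hypergeometric probability P(X >= k) is computed, where k is the overlap,
n the in-universe query size, K the set size and N the universe size.
BH adjustment is applied within each category separately by default (the
standard reporting convention when BP/CC/MF/pathway results are listed
independently); a pooled mode is available. Sets with zero overlap are
excluded from testing and hence from the BH family size m.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import pandas as pd
from scipy import stats

from .bipartite import BipartiteNet
from .deg import bh_adjust
from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "EnrichmentRow",
    "OraResult",
    "hypergeom_test",
    "run_ora",
    "target_pathway_net",
    "read_gmt",
    "write_gmt",
]

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    category: str  # one of CATEGORIES
    genes: FrozenSet[str]

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise InputError(
                f"category must be one of {CATEGORIES}, got {self.category!r}"
            )
        if not self.genes:
            raise InputError(f"gene set {self.set_id!r} is empty")


@dataclass
class GeneSetCollection:
    """Named gene sets plus the annotation universe they live in."""

    sets: Dict[str, GeneSet] = field(default_factory=dict)

    def add(self, gs: GeneSet) -> None:
        if gs.set_id in self.sets:
            raise InputError(f"duplicate set id {gs.set_id!r}")
        self.sets[gs.set_id] = gs

    @property
    def universe(self) -> Set[str]:
        """All genes annotated in at least one set."""
        u: Set[str] = set()
        for gs in self.sets.values():
            u |= gs.genes
        return u

    def by_category(self, category: str) -> List[GeneSet]:
        return [gs for gs in self.sets.values() if gs.category == category]

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentRow:
    """One gene-set test result."""

    set_id: str
    name: str
    category: str
    k: int  # overlap
    n: int  # in-universe query size
    K: int  # set size
    N: int  # universe size
    p_raw: float
    p_adj: float
    overlap_genes: Tuple[str, ...]


@dataclass
class OraResult:
    """Full table plus the significant slice, both as DataFrames."""

    table: pd.DataFrame
    significant: pd.DataFrame
    rows: List[EnrichmentRow]

    def significant_rows(self) -> List[EnrichmentRow]:
        return [r for r in self.rows if r.set_id in set(self.significant["set_id"])]


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N: universe size, K: annotated (set) genes, n: draws (query size),
    k: observed overlap.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N:
        raise InputError(
            f"inconsistent hypergeometric counts k={k}, n={n}, K={K}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    universe: Optional[Set[str]] = None,
    pool_categories: bool = False,
    min_set_size: Optional[int] = None,
    max_set_size: Optional[int] = None,
) -> OraResult:
    """Over-representation of ``query`` in every set with overlap >= 1.

    ``universe`` defaults to all genes annotated in the collection; pass an
    explicit set (for example all measured genes) to change the background.
    Returns the full table and the slice with p_adj < alpha sorted by
    p_adj ascending. Both gene-ratio conventions are emitted:
    ``gene_ratio`` = k / n (in-universe query) and ``gene_ratio_raw`` =
    k / raw query size.
    """
    query = set(query)
    if not query:
        raise InputError("query gene set is empty")
    if not (0.0 <= alpha <= 1.0):
        raise InputError(f"alpha must lie in [0, 1], got {alpha!r}")
    uni = set(universe) if universe is not None else collection.universe
    n_raw = len(query)
    in_uni = query & uni
    dropped = query - uni
    if dropped:
        logger.info("%d query genes outside the universe dropped: %s",
                    len(dropped), ", ".join(sorted(dropped)[:10]))
    if not in_uni:
        raise InputError("no query gene is present in the universe")
    N, n = len(uni), len(in_uni)

    tested: List[dict] = []
    for gs in collection.sets.values():
        members = gs.genes & uni
        K = len(members)
        if K == 0:
            continue
        if min_set_size is not None and K < min_set_size:
            continue
        if max_set_size is not None and K > max_set_size:
            continue
        overlap = sorted(in_uni & members)
        k = len(overlap)
        if k == 0:
            continue
        tested.append({
            "set_id": gs.set_id, "name": gs.name, "category": gs.category,
            "k": k, "n": n, "K": K, "N": N,
            "p_raw": hypergeom_test(k, n, K, N),
            "overlap_genes": ";".join(overlap),
        })
    table = pd.DataFrame(
        tested,
        columns=["set_id", "name", "category", "k", "n", "K", "N",
                 "p_raw", "overlap_genes"],
    )
    if len(table):
        if pool_categories:
            table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
        else:
            table["p_adj"] = float("nan")
            for cat, idx in table.groupby("category").groups.items():
                table.loc[idx, "p_adj"] = bh_adjust(table.loc[idx, "p_raw"].to_numpy())
        table["gene_ratio"] = table["k"] / table["n"]
        table["gene_ratio_raw"] = table["k"] / n_raw
        table = table.sort_values(["p_adj", "p_raw", "set_id"]).reset_index(drop=True)
    else:
        for col in ("p_adj", "gene_ratio", "gene_ratio_raw"):
            table[col] = pd.Series(dtype=float)
    significant = table.loc[table["p_adj"] < alpha].reset_index(drop=True)
    rows = [
        EnrichmentRow(
            set_id=r.set_id, name=r.name, category=r.category,
            k=int(r.k), n=int(r.n), K=int(r.K), N=int(r.N),
            p_raw=float(r.p_raw), p_adj=float(r.p_adj),
            overlap_genes=tuple(r.overlap_genes.split(";")),
        )
        for r in table.itertuples(index=False)
    ]
    logger.info("ORA: %d sets tested, %d significant at adj-p<%g",
                len(table), len(significant), alpha)
    return OraResult(table=table, significant=significant, rows=rows)


def target_pathway_net(result: OraResult, category: str = "pathway") -> BipartiteNet:
    """Bipartite network of query genes vs significant sets of a category.

    Left nodes are the genes appearing in at least one significant set;
    right nodes are the significant sets; an edge records membership of the
    overlapping gene. A gene's degree counts the pathways it joins, and a
    pathway's degree the genes it contains (the node-size conventions of
    the usual target-pathway figure).
    """
    net = BipartiteNet()
    sig = result.significant
    for row in sig.itertuples(index=False):
        if row.category != category:
            continue
        net.node_attrs[row.set_id] = {
            "type": "pathway", "name": row.name, "p_adj": float(row.p_adj),
        }
        for gene in row.overlap_genes.split(";"):
            net.add_edge(gene, row.set_id)
            net.node_attrs.setdefault(gene, {"type": "target"})
    net.validate()
    return net


# ----------------------------------------------------------------- GMT I/O

def read_gmt(path, category: Optional[str] = None) -> GeneSetCollection:
    """Read gene sets from GMT (set name, description, members...).

    For combined files the description field carries the category (BP, CC,
    MF or pathway); a ``category`` argument overrides it for per-category
    files whose description is free text.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            name, desc = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            cat = category or (desc if desc in CATEGORIES else "pathway")
            coll.add(GeneSet(set_id=name, name=name, category=cat, genes=genes))
    return coll


def write_gmt(collection: GeneSetCollection, path) -> None:
    """Write as combined GMT with the category in the description field."""
    with open(path, "w") as fh:
        for sid in sorted(collection.sets):
            gs = collection.sets[sid]
            fh.write("\t".join([gs.set_id, gs.category, *sorted(gs.genes)]) + "\n")
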