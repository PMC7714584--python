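"""Ingredient-target (and target-pathway) bipartite networks.

Targets of the screened ingredients are intersected with the
disease-specific gene list; ingredients left without any surviving target
are pruned, and the remainder forms an undirected, unweighted bipartite
network. The same container also serves the target-pathway network built
from enrichment results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .compounds import CompoundRecord
from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "BipartiteNet",
    "intersect_targets",
    "prune_ingredients",
    "build_bipartite",
    "multi_target_report",
    "read_target_map",
]


def read_target_map(path) -> List[Tuple[str, str]]:
    """Read a compound-to-target TSV with columns molecule_id, gene_symbol."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"molecule_id", "gene_symbol"}
    if not required <= set(frame.columns):
        raise InputError(
            f"target map must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    return [(r.molecule_id, r.gene_symbol) for r in frame.itertuples(index=False)]

#: namespace prefixes applied on export so molecule IDs, gene symbols and
#: pathway IDs can never collide in a flat node-name space
_PREFIX = {"ingredient": "mol:", "target": "gene:", "pathway": "path:"}
_UNPREFIX = {v: k for k, v in _PREFIX.items()}


@dataclass
class BipartiteNet:
    """Two-sided network with typed nodes and untyped undirected edges."""

    left_nodes: Set[str] = field(default_factory=set)
    right_nodes: Set[str] = field(default_factory=set)
    edges: Set[Tuple[str, str]] = field(default_factory=set)
    node_attrs: Dict[str, dict] = field(default_factory=dict)

    def validate(self) -> None:
        if self.left_nodes & self.right_nodes:
            raise InputError(
                f"nodes on both sides: {sorted(self.left_nodes & self.right_nodes)}"
            )
        for l, r in self.edges:
            if l not in self.left_nodes or r not in self.right_nodes:
                raise InputError(f"edge ({l!r}, {r!r}) has an endpoint outside its side")

    def add_edge(self, left: str, right: str) -> None:
        self.left_nodes.add(left)
        self.right_nodes.add(right)
        self.edges.add((left, right))

    def degree(self, node: str) -> int:
        if node in self.left_nodes:
            return sum(1 for l, _ in self.edges if l == node)
        if node in self.right_nodes:
            return sum(1 for _, r in self.edges if r == node)
        raise KeyError(node)

    def degrees(self) -> Dict[str, int]:
        deg = {n: 0 for n in self.left_nodes | self.right_nodes}
        for l, r in self.edges:
            deg[l] += 1
            deg[r] += 1
        return deg

    @property
    def n_nodes(self) -> int:
        return len(self.left_nodes) + len(self.right_nodes)

    # ------------------------------------------------------------ exports

    def _node_type(self, node: str) -> str:
        return self.node_attrs.get(node, {}).get(
            "type", "ingredient" if node in self.left_nodes else "target"
        )

    def _prefixed(self, node: str) -> str:
        return _PREFIX[self._node_type(node)] + node

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for side, nodes in (("left", self.left_nodes), ("right", self.right_nodes)):
            for n in nodes:
                attrs = {k: v for k, v in self.node_attrs.get(n, {}).items()
                         if v is not None}
                attrs.setdefault("type", self._node_type(n))
                g.add_node(self._prefixed(n), side=side, label=n, **attrs)
        for l, r in self.edges:
            g.add_edge(self._prefixed(l), self._prefixed(r))
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "BipartiteNet":
        net = cls()
        for n, data in g.nodes(data=True):
            label = data.get("label", n)
            for pref, typ in _UNPREFIX.items():
                if str(n).startswith(pref):
                    label = str(n)[len(pref):]
                    break
            attrs = {k: v for k, v in data.items() if k not in ("side", "label")}
            net.node_attrs[label] = attrs
            (net.left_nodes if data.get("side") == "left" else net.right_nodes).add(label)
        for u, v in g.edges():
            lu = g.nodes[u].get("side")
            left, right = (u, v) if lu == "left" else (v, u)
            net.edges.add((net._strip(left), net._strip(right)))
        net.validate()
        return net

    @staticmethod
    def _strip(node: str) -> str:
        for pref in _UNPREFIX:
            if str(node).startswith(pref):
                return str(node)[len(pref):]
        return str(node)

    @classmethod
    def read_graphml(cls, path) -> "BipartiteNet":
        return cls.from_networkx(nx.read_graphml(path))

    def write_sif(self, path, interaction: str = "bp") -> None:
        with open(path, "w") as fh:
            for l, r in sorted(self.edges):
                fh.write(f"{self._prefixed(l)}\t{interaction}\t{self._prefixed(r)}\n")

    def node_table(self) -> pd.DataFrame:
        deg = self.degrees()
        rows = []
        for n in sorted(self.left_nodes) + sorted(self.right_nodes):
            row = {"node": n, "side": "left" if n in self.left_nodes else "right",
                   "type": self._node_type(n), "degree": deg[n]}
            for k, v in self.node_attrs.get(n, {}).items():
                if k != "type":
                    row[k] = v
            rows.append(row)
        return pd.DataFrame(rows)


def intersect_targets(
    target_map: Iterable[Tuple[str, str]],
    deg_genes: Iterable[str],
) -> List[Tuple[str, str]]:
    """Keep (molecule_id, gene) pairs whose gene is disease-specific.

    ``deg_genes`` may be a call_degs table (its ``gene`` column is used),
    any iterable of gene symbols, or a set. Pairs are deduplicated and
    returned sorted for determinism.
    """
    if isinstance(deg_genes, pd.DataFrame):
        deg_genes = deg_genes["gene"]
    genes = set(deg_genes)
    kept = sorted({(m, g) for m, g in target_map if g in genes})
    logger.info(
        "target intersection: %d pairs over %d distinct genes survive",
        len(kept), len({g for _, g in kept}),
    )
    return kept


def prune_ingredients(
    bcis: Sequence[CompoundRecord],
    kept_pairs: Iterable[Tuple[str, str]],
) -> List[CompoundRecord]:
    """Keep ingredients with at least one surviving target pair."""
    with_target = {m for m, _ in kept_pairs}
    kept = [c for c in bcis if c.molecule_id in with_target]
    logger.info("pruned ingredients: %d of %d have a disease-specific target",
                len(kept), len(bcis))
    return kept


def build_bipartite(
    bcis: Sequence[CompoundRecord],
    kept_pairs: Iterable[Tuple[str, str]],
    degs: pd.DataFrame,
) -> BipartiteNet:
    """Assemble the ingredient-target network.

    Ingredient nodes carry their source herbs; target nodes carry the
    regulation direction and log2 fold-change from the DEG table. Every
    pair must reference a retained (non-pruned) ingredient.
    """
    by_id = {c.molecule_id: c for c in bcis}
    deg_info = degs.set_index("gene")[["log2fc", "direction"]] if len(degs) else None
    net = BipartiteNet()
    for mol, gene in kept_pairs:
        if mol not in by_id:
            raise InputError(
                f"target pair references molecule {mol!r} absent from the "
                "pruned ingredient list"
            )
        net.add_edge(mol, gene)
        net.node_attrs[mol] = {"type": "ingredient", "source_herbs": by_id[mol].herb,
                               "molecule_name": by_id[mol].molecule_name}
        if deg_info is not None and gene in deg_info.index:
            net.node_attrs[gene] = {
                "type": "target",
                "direction": str(deg_info.loc[gene, "direction"]),
                "log2fc": float(deg_info.loc[gene, "log2fc"]),
            }
        else:
            net.node_attrs.setdefault(gene, {"type": "target"})
    net.validate()
    logger.info(
        "bipartite network: %d ingredients, %d targets, %d edges",
        len(net.left_nodes), len(net.right_nodes), len(net.edges),
    )
    return net


def multi_target_report(net: BipartiteNet, k_min: int = 2) -> pd.DataFrame:
    """Ingredients hitting at least ``k_min`` targets, sorted by degree
    descending then molecule_id; targets listed per row."""
    targets_of: Dict[str, list] = {m: [] for m in net.left_nodes}
    for m, g in net.edges:
        targets_of[m].append(g)
    rows = [
        {
            "molecule_id": m,
            "n_targets": len(ts),
            "targets": ";".join(sorted(ts)),
            "source_herbs": net.node_attrs.get(m, {}).get("source_herbs", ""),
        }
        for m, ts in targets_of.items()
        if len(ts) >= k_min
    ]
    frame = pd.DataFrame(
        rows, columns=["molecule_id", "n_targets", "targets", "source_herbs"]
    )
    return frame.sort_values(
        ["n_targets", "molecule_id"], ascending=[False, True]
    ).reset_index(drop=True)
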