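"""PPI neighborhood construction and the two-stage centrality filtration.

The seed genes (targets of the pharmacological network) are expanded
against a genome-scale interactome into a protein-protein interaction
graph. The core is then extracted in two stages: nodes in the top 30% by
degree centrality (DC) form a subnetwork, and nodes in the top 30% by
betweenness centrality (BC) — recomputed on that subnetwork — form the
core. Seed genes surviving both cuts are the crucial genes.

Betweenness here is the unnormalized shortest-path betweenness for
undirected, unweighted graphs with endpoints excluded and each unordered
pair counted once, computed by Brandes' dependency accumulation.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import networkx as nx
import pandas as pd

from .exceptions import InputError

logger = logging.getLogger(__name__)

__all__ = [
    "PPIGraph",
    "FiltrationResult",
    "expand_seeds",
    "degree_centrality",
    "betweenness_centrality",
    "top_fraction_filter",
    "extract_core",
    "read_interactome",
]


@dataclass
class PPIGraph:
    """Undirected simple graph over gene symbols with seed-gene flags."""

    graph: nx.Graph
    seeds: Set[str] = field(default_factory=set)

    def __post_init__(self):
        # enforce simplicity: drop self-loops; nx.Graph already collapses
        # parallel edges and either orientation of an undirected edge
        loops = list(nx.selfloop_edges(self.graph))
        if loops:
            self.graph.remove_edges_from(loops)
        self.seeds = set(self.seeds) & set(self.graph.nodes)

    @property
    def nodes(self) -> Set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes: Iterable[str]) -> "PPIGraph":
        keep = set(nodes)
        return PPIGraph(nx.Graph(self.graph.subgraph(keep)), seeds=self.seeds & keep)

    def centrality_table(self) -> pd.DataFrame:
        dc = degree_centrality(self)
        bc = betweenness_centrality(self)
        rows = [
            {"node": n, "dc": dc[n], "bc": bc[n], "is_seed": n in self.seeds}
            for n in sorted(self.graph.nodes)
        ]
        return pd.DataFrame(rows, columns=["node", "dc", "bc", "is_seed"])

    def write_sif(self, path, interaction: str = "pp") -> None:
        with open(path, "w") as fh:
            for u, v in sorted(tuple(sorted(e)) for e in self.graph.edges()):
                fh.write(f"{u}\t{interaction}\t{v}\n")

    def write_graphml(self, path) -> None:
        g = self.graph.copy()
        for n in g.nodes:
            g.nodes[n]["is_seed"] = n in self.seeds
        nx.write_graphml(g, path)


@dataclass
class FiltrationResult:
    """Outcome of the DC -> BC cascade."""

    full: PPIGraph
    subnetwork: PPIGraph
    core: PPIGraph
    crucial_genes: Set[str]
    thresholds: Tuple[float, float]  # (dc cut, bc cut)
    fraction: float


def read_interactome(path) -> List[Tuple[str, str]]:
    """Read an interactome edge list from SIF (nodeA TAB type TAB nodeB) or
    a 2-column TSV; returns raw (u, v) pairs."""
    edges = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if not parts or parts == [""]:
                continue
            if len(parts) >= 3:
                edges.append((parts[0], parts[2]))
            elif len(parts) == 2:
                edges.append((parts[0], parts[1]))
            else:
                raise InputError(f"cannot parse interactome line: {line!r}")
    if not edges:
        raise InputError(f"interactome {path} contains no edges")
    return edges


def expand_seeds(
    seeds: Iterable[str],
    interactome: Iterable[Tuple[str, str]],
    expansion: str = "direct",
) -> PPIGraph:
    """Build the PPI graph around the seed genes.

    ``expansion="direct"``: node set = seeds found in the interactome plus
    their direct interactors; edge set = all interactome edges with both
    endpoints inside that node set (so interactor-interactor edges within
    the neighborhood are retained). ``"seeds-only"``: induced subgraph on
    the seeds alone. Seeds absent from the interactome are logged; if no
    seed is present at all this is an error.
    """
    if expansion not in ("direct", "seeds-only"):
        raise InputError(f"expansion must be 'direct' or 'seeds-only', got {expansion!r}")
    seeds = set(seeds)
    g = nx.Graph()
    g.add_edges_from((u, v) for u, v in interactome if u != v)
    present = seeds & set(g.nodes)
    missing = seeds - present
    if missing:
        logger.warning("%d seed genes absent from interactome: %s",
                       len(missing), ", ".join(sorted(missing)[:10]))
    if not present:
        raise InputError("no seed gene is present in the interactome")
    if expansion == "seeds-only":
        keep = present
    else:
        keep = set(present)
        for s in present:
            keep |= set(g.neighbors(s))
    sub = nx.Graph(g.subgraph(keep))
    ppi = PPIGraph(sub, seeds=present)
    logger.info("seed expansion (%s): %d nodes, %d edges from %d seeds",
                expansion, ppi.n_nodes, ppi.n_edges, len(present))
    return ppi


def degree_centrality(g: PPIGraph) -> Dict[str, int]:
    """DC(v) = number of incident edges (a count, not normalized)."""
    return {n: d for n, d in g.graph.degree()}


def betweenness_centrality(g: PPIGraph, normalized: bool = False) -> Dict[str, float]:
    """Brandes' betweenness for undirected unweighted graphs.

    BC(v) = sum over unordered pairs {s, t}, s != v != t, of
    sigma_st(v) / sigma_st, where sigma_st counts shortest s-t paths and
    sigma_st(v) those passing through v. Unnormalized by default (each
    unordered pair counted once); ``normalized=True`` divides by
    (n-1)(n-2)/2.
    """
    graph = g.graph if isinstance(g, PPIGraph) else g
    bc = dict.fromkeys(graph.nodes, 0.0)
    for s in graph.nodes:
        # single-source shortest-path counting (BFS)
        stack: List = []
        pred: Dict = {v: [] for v in graph.nodes}
        sigma = dict.fromkeys(graph.nodes, 0.0)
        dist = dict.fromkeys(graph.nodes, -1)
        sigma[s] = 1.0
        dist[s] = 0
        queue = deque([s])
        while queue:
            v = queue.popleft()
            stack.append(v)
            for w in graph.neighbors(v):
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    pred[w].append(v)
        # dependency accumulation
        delta = dict.fromkeys(graph.nodes, 0.0)
        while stack:
            w = stack.pop()
            for v in pred[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    n = graph.number_of_nodes()
    # ordered-pair accumulation counts each unordered pair twice
    scale = 0.5
    if normalized:
        scale = 0.0 if n < 3 else 1.0 / ((n - 1) * (n - 2))
    for v in bc:
        bc[v] *= scale
    return bc


def top_fraction_filter(
    g: PPIGraph,
    scores: Dict[str, float],
    fraction: float = 0.30,
) -> PPIGraph:
    """Induced subgraph on the top-``fraction`` scoring nodes.

    k = ceil(fraction * n); the cut is the k-th largest score and every
    node scoring >= cut is kept, so ties at the cut can push the output
    above k.
    """
    if not (0.0 < fraction <= 1.0):
        raise InputError(f"fraction must lie in (0, 1], got {fraction!r}")
    nodes = list(g.graph.nodes)
    if not nodes:
        return PPIGraph(nx.Graph(), seeds=set())
    ranked = sorted((scores[n] for n in nodes), reverse=True)
    k = math.ceil(fraction * len(nodes))
    cut = ranked[k - 1]
    keep = [n for n in nodes if scores[n] >= cut]
    return g.subgraph(keep)


def extract_core(full: PPIGraph, fraction: float = 0.30) -> FiltrationResult:
    """Two-stage cascade: top-fraction DC on the full graph gives the
    subnetwork; top-fraction BC, recomputed on the subnetwork, gives the
    core. Crucial genes are the seeds remaining in the core.

    The DC ranking is global (not restricted to seeds), so the subnetwork
    generally contains both seed and non-seed nodes.
    """
    if full.n_nodes == 0:
        raise InputError("cannot filter an empty PPI graph")
    dc = degree_centrality(full)
    sub = top_fraction_filter(full, dc, fraction)
    if sub.n_nodes == 0:
        raise InputError("DC filtration produced an empty subnetwork")
    dc_cut = min(dc[n] for n in sub.nodes)
    bc = betweenness_centrality(sub)
    core = top_fraction_filter(sub, bc, fraction)
    bc_cut = min(bc[n] for n in core.nodes) if core.n_nodes else float("nan")
    crucial = full.seeds & core.nodes
    logger.info(
        "filtration: full %d/%d -> subnetwork %d/%d -> core %d/%d; %d crucial genes",
        full.n_nodes, full.n_edges, sub.n_nodes, sub.n_edges,
        core.n_nodes, core.n_edges, len(crucial),
    )
    return FiltrationResult(
        full=full, subnetwork=sub, core=core,
        crucial_genes=crucial, thresholds=(float(dc_cut), float(bc_cut)),
        fraction=fraction,
    )
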