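"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force
(enumeration, naive BFS path counting, sort/cummin) so the library
implementations are checked against code that shares nothing with them.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb

import numpy as np
import pytest

from netpharm.config import SynthConfig


@pytest.fixture
def small_cfg():
    """A small but fully structured synthetic configuration."""
    return SynthConfig(
        n_gene_total=500,
        n_pairs=8,
        frac_de=0.1,
        n_herbs=3,
        n_compounds_per_herb=40,
        n_shared_compounds=4,
        interactome_nodes=200,
        interactome_attach=3,
        n_gene_sets=40,
        set_size_range=(5, 20),
        seed=11,
    )


# --------------------------------------------------------------- oracles

def bh_naive(p):
    """Independent BH: sort ascending, m*p/rank, cumulative min from the
    right, clip at 1, unsort."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def hypergeom_enum(k, n, K, N):
    """P(X >= k) by direct summation of the hypergeometric pmf from
    binomial coefficients."""
    total = comb(N, n)
    return sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1)) / total


def betweenness_naive(graph):
    """All-pairs BFS path-counting betweenness (unnormalized, endpoints
    excluded, unordered pairs counted once).

    For each source s, BFS gives distances d_s and path counts sigma_s.
    v lies on a shortest s-t path iff d_s(v) + d_t(v) == d_s(t), and then
    carries sigma_s(v) * sigma_t(v) / sigma_s(t).
    """
    nodes = list(graph.nodes)

    def bfs(s):
        dist = {s: 0}
        sigma = {s: 1.0}
        q = deque([s])
        while q:
            v = q.popleft()
            for w in graph.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
        return dist, sigma

    sp = {s: bfs(s) for s in nodes}
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        dist_s, sigma_s = sp[s]
        if t not in dist_s:
            continue
        dist_t, sigma_t = sp[t]
        d = dist_s[t]
        for v in nodes:
            if v in (s, t) or v not in dist_s or v not in dist_t:
                continue
            if dist_s[v] + dist_t[v] == d:
                bc[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    return bc
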