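"""Shared fixtures: tiny graph builders, random typed graphs, and an
independent transition-matrix HeteSim oracle used to cross-check the
walk-based implementation."""

from __future__ import annotations

import math

import numpy as np
import pytest

from lbdhub.kgraph import IN, OUT, KnowledgeGraph
from lbdhub.pathscore import MetapathSchema


def build_graph(edges, semtypes=None, names=None):
    """Build a graph from (subject, predicate, object[, pmids]) tuples.

    Nodes default to semantic type AAPP and name == cui; override per node
    via the ``semtypes`` / ``names`` dicts.
    """
    semtypes = semtypes or {}
    names = names or {}
    g = KnowledgeGraph()
    pmid = 11_000_000
    cuis = {e[0] for e in edges} | {e[2] for e in edges}
    for cui in sorted(cuis):
        g.add_concept(cui, names.get(cui, cui), semtypes.get(cui, {"AAPP"}))
    for e in edges:
        pmids = e[3] if len(e) > 3 else {str(pmid)}
        pmid += 1
        g.add_predication(e[0], e[1], e[2], pmids)
    return g


def random_typed_graph(rng, n_nodes=None, predicates=("REL", "ACT")):
    """A small random directed typed multigraph (for oracle comparisons)."""
    n = int(n_nodes if n_nodes is not None else rng.integers(4, 13))
    cuis = [f"C{i + 1:07d}" for i in range(n)]
    g = KnowledgeGraph()
    types = ["AAPP", "GNGM", "HORM", "DSYN", "PHSU"]
    for i, cui in enumerate(cuis):
        g.add_concept(cui, f"node {i}", {types[int(rng.integers(len(types)))]})
    n_edges = int(rng.integers(2 * n, 3 * n + 1))
    pmid = 20_000_000
    for _ in range(n_edges):
        u, v = rng.choice(n, size=2, replace=False)
        pred = predicates[int(rng.integers(len(predicates)))]
        g.add_predication(cuis[int(u)], pred, cuis[int(v)], {str(pmid)})
        pmid += 1
    return g, cuis


def all_schemas(predicates, max_len):
    """Every schema of length <= max_len over a predicate/direction alphabet."""
    steps = [(p, d) for p in predicates for d in (OUT, IN)]
    out = []

    def grow(prefix):
        if prefix:
            out.append(MetapathSchema.parse("|".join(f"{d.upper()}:{p}" for p, d in prefix)))
        if len(prefix) >= max_len:
            return
        for s in steps:
            grow(prefix + [s])

    grow([])
    return out


# -- independent HeteSim oracle -------------------------------------------
#
# Explicit transition matrices over the node list, built directly from the
# edge list (never through the package's adjacency index), multiplied with
# numpy; odd-length schemas use an explicit node-to-middle-edge incidence.


class HetesimOracle:
    def __init__(self, graph: KnowledgeGraph):
        self.nodes = sorted(c.cui for c in graph.nodes())
        self.idx = {c: i for i, c in enumerate(self.nodes)}
        self.edges = [(e.subject, e.predicate, e.object) for e in graph.edges()]

    def _trans(self, predicate, direction):
        n = len(self.nodes)
        m = np.zeros((n, n))
        for s, p, o in self.edges:
            if p != predicate:
                continue
            if direction == OUT:
                m[self.idx[s], self.idx[o]] += 1.0
            else:
                m[self.idx[o], self.idx[s]] += 1.0
        rowsums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(rowsums > 0, m / rowsums, 0.0)
        return m

    def _edge_incidence(self, predicate, forward, direction):
        """Node -> middle-edge pseudo-node transition for one half step."""
        mids = [e for e in self.edges if e[1] == predicate]
        n = len(self.nodes)
        m = np.zeros((n, len(mids)))
        for j, (s, p, o) in enumerate(mids):
            start = s if (direction == OUT) == forward else o
            m[self.idx[start], j] += 1.0
        rowsums = m.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(rowsums > 0, m / rowsums, 0.0)
        return m

    def all_pairs(self, schema: MetapathSchema) -> np.ndarray:
        """Matrix of HeteSim scores for every (source, target) node pair."""
        steps = schema.steps
        length = len(steps)
        half = length // 2
        n = len(self.nodes)

        u = np.eye(n)
        for st in steps[:half]:
            u = u @ self._trans(st.predicate, st.direction)
        v = np.eye(n)
        for st in reversed(steps[half if length % 2 == 0 else half + 1 :]):
            # walking backward: flip the step's direction
            v = v @ self._trans(st.predicate, IN if st.direction == OUT else OUT)
        if length % 2 == 1:
            mid = steps[half]
            u = u @ self._edge_incidence(mid.predicate, True, mid.direction)
            v = v @ self._edge_incidence(mid.predicate, False, mid.direction)

        dots = u @ v.T
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        denom = np.outer(nu, nv)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(denom > 0, dots / denom, 0.0)
        return np.clip(cos, 0.0, 1.0)

    def score(self, source, target, schema) -> float:
        return float(self.all_pairs(schema)[self.idx[source], self.idx[target]])


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def tau_b_oracle(x, y) -> float:
    """Exhaustive O(N^2) pair classification with tie corrections."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    conc = disc = ties_x = ties_y = 0
    for i in range(n):
        for j in range(i + 1, n):
            a = (x[i] > x[j]) - (x[i] < x[j])
            b = (y[i] > y[j]) - (y[i] < y[j])
            if a == 0:
                ties_x += 1
            if b == 0:
                ties_y += 1
            if a != 0 and b != 0:
                if a == b:
                    conc += 1
                else:
                    disc += 1
    n0 = n * (n - 1) // 2
    denom = math.sqrt((n0 - ties_x) * (n0 - ties_y))
    return (conc - disc) / denom
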