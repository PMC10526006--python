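"""Metapath enumeration and path-based relevance scoring.

A *metapath schema* is a typed relation pattern: an ordered sequence of
(predicate, direction) steps read from the source toward the target, e.g.
``OUT:CAUSES|IN:TREATS`` for  source --CAUSES--> mid <--TREATS-- target.
A *path instance* is a concrete simple node sequence realizing a schema.

Two scores are computed per (source, target, schema):

HeteSim
    The cosine of the forward and backward meeting-probability vectors.
    A uniform random walk leaves the source along the first half of the
    schema while a second walk leaves the target backward along the second
    half; the probability mass each walk places on the middle layer forms a
    vector, and the score is ``u.v / (|u||v|)`` in [0, 1].  For odd-length
    schemas the middle *edge* is split: each concrete middle-edge instance
    becomes a pseudo-node on which both walks can meet.

DWPC (degree-weighted path count)
    The sum over path instances of the product over path nodes of
    ``degree**(-w)``, where each node contributes its degree along the
    relation it traverses (the first node in forward orientation, every
    later node in the orientation by which the path arrives at it).  The
    damping exponent ``w >= 0`` down-weights paths through promiscuous
    hub concepts; ``w = 0`` recovers the raw path count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .kgraph import IN, OUT, KnowledgeGraph

Direction = str


def _flip(direction: Direction) -> Direction:
    return IN if direction == OUT else OUT


@dataclass(frozen=True, order=True)
class MetapathStep:
    """One (predicate, direction) hop, read source-to-target."""

    predicate: str
    direction: Direction


@dataclass(frozen=True, order=True)
class MetapathSchema:
    """An ordered tuple of steps; equality and ordering are exact."""

    steps: tuple[MetapathStep, ...]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a metapath schema needs at least one step")

    def __len__(self) -> int:
        return len(self.steps)

    def __str__(self) -> str:
        return "|".join(f"{s.direction.upper()}:{s.predicate}" for s in self.steps)

    @classmethod
    def parse(cls, text: str) -> "MetapathSchema":
        """Parse the ``OUT:CAUSES|IN:TREATS`` string form."""
        steps = []
        for token in text.split("|"):
            direction, _, predicate = token.partition(":")
            if direction.lower() not in (OUT, IN) or not predicate:
                raise ValueError(f"malformed schema token {token!r}")
            steps.append(MetapathStep(predicate, direction.lower()))
        return cls(tuple(steps))

    def reversed(self) -> "MetapathSchema":
        """The same pattern read target-to-source."""
        return MetapathSchema(
            tuple(MetapathStep(s.predicate, _flip(s.direction)) for s in reversed(self.steps))
        )


@dataclass(frozen=True)
class PathInstance:
    """A concrete simple node sequence conforming to a schema."""

    nodes: tuple[str, ...]
    schema: MetapathSchema

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.schema) + 1:
            raise ValueError("path instance length does not match its schema")
        if len(set(self.nodes)) != len(self.nodes):
            raise ValueError("path instances must be simple (no repeated node)")


@dataclass(frozen=True)
class PathScore:
    """Scores for one (source, target, schema) triple."""

    schema: MetapathSchema
    source: str
    target: str
    hetesim: float
    dwpc: float
    instance_count: int
    damping: float


def enumerate_metapaths(
    graph: KnowledgeGraph, source: str, target: str, max_len: int
) -> dict[MetapathSchema, list[PathInstance]]:
    """All simple path instances from ``source`` to ``target`` of length <= max_len.

    Results are grouped by schema; groups and the instances inside each group
    are deterministically ordered (lexicographic by schema string, then node
    sequence), independent of edge insertion order.
    """
    for cui in (source, target):
        if cui not in graph:
            raise KeyError(f"unknown concept {cui!r}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")

    grouped: dict[MetapathSchema, list[PathInstance]] = {}

    def extend(nodes: list[str], steps: list[MetapathStep]) -> None:
        here = nodes[-1]
        if here == target and steps:
            # A simple path ends the moment it reaches the target.
            schema = MetapathSchema(tuple(steps))
            grouped.setdefault(schema, []).append(PathInstance(tuple(nodes), schema))
            return
        if len(steps) >= max_len:
            return
        for direction in (OUT, IN):
            for pred in graph.predicates(here, direction):
                for nxt in graph.neighbors(here, pred, direction):
                    if nxt in nodes:
                        continue
                    extend(nodes + [nxt], steps + [MetapathStep(pred, direction)])

    extend([source], [])
    return {
        schema: sorted(grouped[schema], key=lambda p: p.nodes)
        for schema in sorted(grouped, key=str)
    }


def enumerate_to_target(
    graph: KnowledgeGraph,
    target: str,
    max_len: int,
    sources: set[str] | None = None,
) -> dict[tuple[str, MetapathSchema], list[PathInstance]]:
    """All simple paths of length <= max_len ending at ``target``, by source.

    Equivalent to calling :func:`enumerate_metapaths` for every source, but
    explored once backward from the target, which is what a simulation over
    hundreds of candidate sources needs.  ``sources`` optionally restricts
    which start nodes are collected (exploration is unrestricted, so paths
    may pass through non-candidate intermediates).
    """
    if target not in graph:
        raise KeyError(f"unknown concept {target!r}")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    collected: dict[tuple[str, MetapathSchema], list[PathInstance]] = {}

    def extend(nodes: list[str], steps: list[MetapathStep]) -> None:
        front = nodes[0]
        if steps and front != target and (sources is None or front in sources):
            schema = MetapathSchema(tuple(steps))
            collected.setdefault((front, schema), []).append(
                PathInstance(tuple(nodes), schema)
            )
        if len(steps) >= max_len:
            return
        # Prepend a step: (pred, OUT) arrives at `front` from an in-neighbor,
        # (pred, IN) from an out-neighbor (directions read source-to-target).
        for pred in graph.predicates(front, IN):
            for x in graph.neighbors(front, pred, IN):
                if x in nodes:
                    continue
                extend([x] + nodes, [MetapathStep(pred, OUT)] + steps)
        for pred in graph.predicates(front, OUT):
            for x in graph.neighbors(front, pred, OUT):
                if x in nodes:
                    continue
                extend([x] + nodes, [MetapathStep(pred, IN)] + steps)

    extend([target], [])
    return {
        key: sorted(insts, key=lambda p: p.nodes)
        for key, insts in sorted(collected.items(), key=lambda kv: (kv[0][0], str(kv[0][1])))
    }


# -- HeteSim ---------------------------------------------------------------


def _walk(
    graph: KnowledgeGraph, start: str, steps: Sequence[MetapathStep]
) -> dict[str, float]:
    """Uniform-transition walk distribution after following ``steps``.

    Mass entering a node with no matching continuation is dropped (the walk
    dies there), so the result need not sum to 1.
    """
    probs: dict[str, float] = {start: 1.0}
    for step in steps:
        nxt: dict[str, float] = {}
        for node, p in probs.items():
            nbrs = graph.neighbors(node, step.predicate, step.direction)
            if not nbrs:
                continue
            share = p / len(nbrs)
            for nb in nbrs:
                nxt[nb] = nxt.get(nb, 0.0) + share
        probs = nxt
        if not probs:
            break
    return probs


def _half_step_to_edges(
    graph: KnowledgeGraph, probs: Mapping[str, float], step: MetapathStep, forward: bool
) -> dict[tuple[str, str, str], float]:
    """Distribute node mass onto the pseudo-nodes of a middle edge layer.

    Forward: from the step's origin side; backward: from its destination
    side (the step as written runs source-to-target).  Pseudo-node identity
    is the concrete edge written in its source-to-target orientation.
    """
    direction = step.direction if forward else _flip(step.direction)
    out: dict[tuple[str, str, str], float] = {}
    for node, p in probs.items():
        nbrs = graph.neighbors(node, step.predicate, direction)
        if not nbrs:
            continue
        share = p / len(nbrs)
        for nb in nbrs:
            a, b = (node, nb) if forward else (nb, node)
            if step.direction == IN:
                a, b = b, a  # store edges as (subject, predicate, object)
            key = (a, step.predicate, b)
            out[key] = out.get(key, 0.0) + share
    return out


def _cosine(u: Mapping, v: Mapping) -> float:
    dot = sum(p * v.get(k, 0.0) for k, p in u.items())
    nu = math.sqrt(sum(p * p for p in u.values()))
    nv = math.sqrt(sum(p * p for p in v.values()))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return min(1.0, dot / (nu * nv))


def hetesim(
    graph: KnowledgeGraph, source: str, target: str, schema: MetapathSchema
) -> float:
    """HeteSim relevance of ``source`` and ``target`` along ``schema``, in [0, 1].

    Returns 0.0 when either walk places no mass on the middle layer
    (unreachable along the schema); never raises for valid nodes.
    """
    for cui in (source, target):
        if cui not in graph:
            raise KeyError(f"unknown concept {cui!r}")
    u, v = meeting_vectors(graph, source, target, schema)
    return _cosine(u, v)


def hetesim_cached(
    graph: KnowledgeGraph,
    source: str,
    target: str,
    schema: MetapathSchema,
    cache: dict,
) -> float:
    """Like :func:`hetesim`, memoizing the target-side vector in ``cache``.

    The backward vector depends only on (target, schema); a simulation that
    scores hundreds of sources against one target reuses it.
    """
    key = (target, schema)
    if key not in cache:
        cache[key] = backward_vector(graph, target, schema)
    return _cosine(forward_vector(graph, source, schema), cache[key])


def forward_vector(
    graph: KnowledgeGraph, source: str, schema: MetapathSchema
) -> dict:
    """Source-side meeting-probability vector over the middle layer."""
    length = len(schema)
    half = length // 2
    u_nodes = _walk(graph, source, schema.steps[:half])
    if length % 2 == 0:
        return u_nodes
    return _half_step_to_edges(graph, u_nodes, schema.steps[half], forward=True)


def backward_vector(
    graph: KnowledgeGraph, target: str, schema: MetapathSchema
) -> dict:
    """Target-side meeting-probability vector over the middle layer."""
    length = len(schema)
    half = length // 2
    rev = schema.reversed().steps
    if length % 2 == 0:
        return _walk(graph, target, rev[: length - half])
    v_nodes = _walk(graph, target, rev[: length - half - 1])
    return _half_step_to_edges(graph, v_nodes, schema.steps[half], forward=False)


def meeting_vectors(
    graph: KnowledgeGraph, source: str, target: str, schema: MetapathSchema
) -> tuple[dict, dict]:
    """Forward/backward meeting-probability vectors over the middle layer.

    For odd-length schemas the middle edge is split: each concrete
    middle-edge instance becomes a pseudo-node on which the walks meet.
    """
    return (
        forward_vector(graph, source, schema),
        backward_vector(graph, target, schema),
    )


# -- degree-weighted path counts ------------------------------------------


def along_path_degrees(graph: KnowledgeGraph, instance: PathInstance) -> tuple[int, ...]:
    """Per-node degrees along the traversed relations of one path instance.

    Node 0 contributes its degree along the first step as traversed; each
    subsequent node contributes its degree along the step by which the path
    arrives at it (reverse orientation).  An L-step path yields L+1 degrees,
    all >= 1 on any realized path.
    """
    degs = []
    steps = instance.schema.steps
    degs.append(graph.degree(instance.nodes[0], steps[0].predicate, steps[0].direction))
    for i, step in enumerate(steps):
        degs.append(
            graph.degree(instance.nodes[i + 1], step.predicate, _flip(step.direction))
        )
    return tuple(degs)


def dwpc(
    instances: Iterable[PathInstance], graph: KnowledgeGraph, w: float = 0.4
) -> float:
    """Degree-weighted path count of one schema's instances.

    ``sum_i prod_nodes degree**(-w)``; ``w = 0`` gives the raw instance count.
    """
    if w < 0:
        raise ValueError("damping exponent w must be >= 0")
    total = 0.0
    for inst in instances:
        prod = 1.0
        for d in along_path_degrees(graph, inst):
            prod *= float(d) ** (-w)
        total += prod
    return total


def score_schema(
    graph: KnowledgeGraph,
    source: str,
    target: str,
    schema: MetapathSchema,
    instances: Sequence[PathInstance],
    w: float = 0.4,
) -> PathScore:
    """Bundle HeteSim + DWPC for one (source, target, schema)."""
    return PathScore(
        schema=schema,
        source=source,
        target=target,
        hetesim=hetesim(graph, source, target, schema),
        dwpc=dwpc(instances, graph, w),
        instance_count=len(instances),
        damping=w,
    )
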