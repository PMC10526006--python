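"""Synthetic predication graphs and document corpora with planted truth.

The generator emulates the structure a literature knowledge graph presents
to a two-target discovery study, at desk scale:

* two disease-like target concepts (DSYN), never directly connected;
* a large background of typed source concepts (AAPP/GNGM/HORM/DSYN/PHSU),
  each tied to at most *one* target, directly or through per-target
  intermediate concepts, with extra preferential-attachment edges that give
  the degree distribution a heavy tail;
* planted *bridge* sources connected to **both** targets through several
  distinct predicates and intermediates (the recoverable signal);
* a planted *hub pathway* (a receptor-cascade analog): a chain of heavily
  connected nodes sitting at graph distance 2 from both targets that alone
  reach a downstream cluster at distance 3–4 — invisible to any depth-2
  simulation and recoverable only through hub re-targeting;
* composite-identifier variants ("baseCUI|linkedCUI") for a fraction of
  background sources;
* a theme-mixed corpus of per-(source, PMID) pseudo-documents whose tokens
  are drawn from the true theme's lexicon pool plus uniform noise.

All randomness flows from one seed; sub-streams for the graph and the
corpus are derived at fixed offsets, so every output is a pure function of
the configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import themes as themes_mod
from .kgraph import KnowledgeGraph

DEFAULT_PREDICATES = (
    "CAUSES",
    "STIMULATES",
    "INHIBITS",
    "TREATS",
    "AFFECTS",
    "INTERACTS_WITH",
    "ASSOCIATED_WITH",
    "PREDISPOSES",
)

DEFAULT_SEMTYPE_PROPORTIONS = {
    "AAPP": 0.35,
    "GNGM": 0.30,
    "HORM": 0.15,
    "DSYN": 0.10,
    "PHSU": 0.10,
}

#: Figure-style physiological theme mixture used for corpus generation.
DEFAULT_THEME_MIXTURE = {
    "endocrine": 0.231,
    "inflammation": 0.213,
    "lipid": 0.176,
    "sympathetic": 0.167,
    "viral_entry": 0.148,
    "unknown": 0.065,
}

#: Generic research-prose filler words; disjoint from every lexicon token.
NOISE_VOCABULARY = (
    "patients", "cohort", "analysis", "measured", "baseline", "clinical",
    "observed", "significant", "reported", "levels", "increased", "decreased",
    "expression", "samples", "followup", "outcomes", "evaluated", "controls",
    "assay", "model", "groups", "findings", "treated", "compared",
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the defaults define the benchmark conditions."""

    seed: int = 0
    n_background_sources: int = 500
    semtype_proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SEMTYPE_PROPORTIONS)
    )
    n_bridges: int = 10
    bridge_edge_multiplicity: int = 5
    n_hub_pathway_nodes: int = 3
    hub_fanout: int = 30
    n_intermediates: int = 60  # split evenly across the two targets
    composite_fraction: float = 0.1
    predicates: tuple[str, ...] = DEFAULT_PREDICATES
    background_direct_prob: float = 0.3
    n_pref_attachment_edges: int = 250
    theme_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THEME_MIXTURE)
    )
    tokens_per_doc: int = 12
    noise_rate: float = 0.2
    n_documents: int = 2000

    def __post_init__(self) -> None:
        for name in (
            "n_background_sources",
            "n_bridges",
            "n_hub_pathway_nodes",
            "hub_fanout",
            "n_intermediates",
            "n_pref_attachment_edges",
            "n_documents",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_bridges > self.n_background_sources and self.n_bridges > 0:
            raise ValueError(
                "infeasible config: n_bridges exceeds n_background_sources"
            )
        if abs(sum(self.semtype_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("semtype proportions must sum to 1")
        if abs(sum(self.theme_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("theme mixture must sum to 1")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")
        if not 0.0 <= self.composite_fraction <= 1.0:
            raise ValueError("composite_fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What was planted, for recovery benchmarks (never fed to the pipeline)."""

    targets: list[str]
    bridges: list[str]
    hubs: list[str]
    downstream: list[str]
    composites: list[str] = field(default_factory=list)
    theme_labels: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


class _Ids:
    """Deterministic CUI and PMID minting."""

    def __init__(self) -> None:
        self.counters = {}
        self.pmid = 10_000_000

    def cui(self, family: int) -> str:
        n = self.counters.get(family, 0) + 1
        self.counters[family] = n
        return f"C{family}{n:05d}"

    def next_pmid(self, count: int = 1) -> frozenset[str]:
        out = frozenset(str(self.pmid + i) for i in range(count))
        self.pmid += count
        return out


def _choice(rng: np.random.Generator, seq: Sequence[str]) -> str:
    return seq[int(rng.integers(len(seq)))]


def _semtype(rng: np.random.Generator, proportions: dict[str, float]) -> str:
    names = sorted(proportions)
    probs = np.array([proportions[n] for n in names])
    return names[int(rng.choice(len(names), p=probs / probs.sum()))]


def generate_kg(config: SyntheticConfig) -> tuple[KnowledgeGraph, GroundTruth]:
    """Build the planted knowledge graph and its ground truth."""
    rng = np.random.default_rng([config.seed, 0])
    ids = _Ids()
    g = KnowledgeGraph()
    preds = list(config.predicates)

    target_a, target_b = "C9000001", "C9000002"
    g.add_concept(target_a, "disease alpha", {"DSYN"})
    g.add_concept(target_b, "disease beta", {"DSYN"})
    targets = [target_a, target_b]

    allowed_props = {
        k: v for k, v in config.semtype_proportions.items() if k in ("AAPP", "GNGM", "HORM")
    } or {"AAPP": 1.0}

    any_sources = (
        config.n_background_sources + config.n_bridges + config.n_hub_pathway_nodes
    ) > 0

    # Per-target intermediate concepts; every indirect connection routes
    # through them, so each target's depth-2 neighborhood is well defined.
    intermediates: dict[str, list[str]] = {target_a: [], target_b: []}
    if any_sources:
        n_per = max(3, config.n_intermediates // 2)
        for t_idx, t in enumerate(targets):
            for j in range(n_per):
                cui = ids.cui(81)
                g.add_concept(
                    cui,
                    f"mediator {t_idx}-{j}",
                    {_semtype(rng, config.semtype_proportions)},
                )
                g.add_predication(cui, _choice(rng, preds), t, ids.next_pmid())
                if rng.random() < 0.3:
                    g.add_predication(t, _choice(rng, preds), cui, ids.next_pmid())
                intermediates[t].append(cui)

    # Background sources: tied to exactly one target, directly or via its
    # intermediates.  Each source belongs to one target's community.
    background: list[str] = []
    side_of: dict[str, str] = {}
    for t in targets:
        for inter in intermediates[t]:
            side_of[inter] = t
    for i in range(config.n_background_sources):
        cui = ids.cui(82)
        g.add_concept(cui, f"concept {i}", {_semtype(rng, config.semtype_proportions)})
        t = targets[int(rng.integers(2))]
        side_of[cui] = t
        if rng.random() < config.background_direct_prob:
            g.add_predication(cui, _choice(rng, preds), t, ids.next_pmid())
        else:
            n_links = 1 + int(rng.random() < 0.4)
            for inter in rng.choice(
                intermediates[t], size=min(n_links, len(intermediates[t])), replace=False
            ):
                g.add_predication(cui, _choice(rng, preds), str(inter), ids.next_pmid())
        background.append(cui)

    # Heavy-tailed degrees: extra edges attach preferentially to already
    # well-connected members of the same community, so background stays
    # tied to a single target.
    for t in targets:
        pool = [c for c in background + intermediates[t] if side_of.get(c) == t]
        if len(pool) < 2:
            continue
        deg = np.array([1.0 + g.degree(c) for c in pool])
        index_of = {c: i for i, c in enumerate(pool)}
        for _ in range(config.n_pref_attachment_edges // 2):
            u = _choice(rng, pool)
            weights = deg.copy()
            weights[index_of[u]] = 0.0
            v = pool[int(rng.choice(len(pool), p=weights / weights.sum()))]
            g.add_predication(u, _choice(rng, preds), v, ids.next_pmid())
            deg[index_of[u]] += 1
            deg[index_of[v]] += 1

    # Bridges: connected to BOTH targets through several distinct predicates
    # and intermediates.  More supporting articles per edge comes with more
    # distinct connection routes, which is what makes a bridge detectable to
    # a uniform-transition walker.
    bridges: list[str] = []
    n_direct = min(len(preds), 2 + config.bridge_edge_multiplicity // 2)
    n_bridge_links = 2 * config.bridge_edge_multiplicity
    for i in range(config.n_bridges):
        cui = ids.cui(83)
        g.add_concept(cui, f"bridge concept {i}", {_semtype(rng, allowed_props)})
        for t in targets:
            for p in rng.choice(preds, size=n_direct, replace=False):
                g.add_predication(
                    cui, str(p), t, ids.next_pmid(config.bridge_edge_multiplicity)
                )
            for inter in rng.choice(
                intermediates[t],
                size=min(n_bridge_links, len(intermediates[t])),
                replace=False,
            ):
                g.add_predication(
                    cui, _choice(rng, preds), str(inter),
                    ids.next_pmid(config.bridge_edge_multiplicity),
                )
        bridges.append(cui)

    # Hub pathway: a chain of heavily connected nodes at distance exactly 2
    # from both targets (always through intermediates, never adjacent).
    hubs: list[str] = []
    for i in range(config.n_hub_pathway_nodes):
        cui = ids.cui(84)
        g.add_concept(cui, f"pathway receptor {i}", {"AAPP"})
        for t in targets:
            # hubs adjoin most of each target's mediators, twice over
            # (two distinct predicates): they must be the best-connected
            # members of the two-target intersection
            n_links = max(8, (3 * len(intermediates[t])) // 4)
            n_links = min(n_links, len(intermediates[t]))
            for inter in rng.choice(intermediates[t], size=n_links, replace=False):
                p1, p2 = rng.choice(preds, size=2, replace=False)
                g.add_predication(cui, str(p1), str(inter), ids.next_pmid(5))
                g.add_predication(cui, str(p2), str(inter), ids.next_pmid(5))
        hubs.append(cui)
    for a, b in zip(hubs, hubs[1:]):
        g.add_predication(a, "STIMULATES", b, ids.next_pmid(5))

    # Downstream cascade: reachable only through the hub pathway; level 1
    # adjoins every hub (distance 3 from the targets), level 2 adjoins
    # level 1 (distance 4).
    downstream: list[str] = []
    if hubs and config.hub_fanout > 0:
        n_level1 = max(1, math.ceil(config.hub_fanout * 2 / 3))
        n_level2 = config.hub_fanout - n_level1
        level1: list[str] = []
        for i in range(n_level1):
            cui = ids.cui(85)
            g.add_concept(cui, f"downstream effector {i}", {_semtype(rng, allowed_props)})
            for h in hubs:
                p1, p2 = rng.choice(preds, size=2, replace=False)
                g.add_predication(h, str(p1), cui, ids.next_pmid(2))
                g.add_predication(h, str(p2), cui, ids.next_pmid(2))
                if rng.random() < 0.5:
                    g.add_predication(cui, _choice(rng, preds), h, ids.next_pmid(2))
            level1.append(cui)
            downstream.append(cui)
        for i in range(max(0, n_level2)):
            cui = ids.cui(86)
            g.add_concept(
                cui, f"distal effector {i}", {_semtype(rng, allowed_props)}
            )
            for parent in rng.choice(level1, size=min(2, len(level1)), replace=False):
                g.add_predication(str(parent), _choice(rng, preds), cui, ids.next_pmid())
            downstream.append(cui)

    # Composite-identifier variants of a fraction of background sources.
    composites: list[str] = []
    n_comp = round(config.composite_fraction * len(background))
    if n_comp:
        chosen = rng.choice(background, size=n_comp, replace=False)
        for base in sorted(str(c) for c in chosen):
            partner = ids.cui(87)
            variant = f"{base}|{partner}"
            node = g.node(base)
            g.add_concept(variant, f"{node.name} (gene-linked form)", node.semtypes)
            # mirror one of the base's outgoing connections
            nbrs = g.neighbors(base, direction="out")
            if nbrs:
                nb = _choice(rng, nbrs)
                g.add_predication(variant, _choice(rng, preds), nb, ids.next_pmid())
            composites.append(variant)

    truth = GroundTruth(
        targets=targets,
        bridges=bridges,
        hubs=hubs,
        downstream=downstream,
        composites=composites,
    )
    return g, truth


# -- corpus ----------------------------------------------------------------


def generate_corpus(
    config: SyntheticConfig,
    graph: KnowledgeGraph | None = None,
    lexicon: themes_mod.ThemeLexicon | None = None,
) -> tuple[list[themes_mod.RelationshipDocument], list[str]]:
    """Theme-mixed pseudo-documents with known true labels.

    One document per (source concept, PMID).  A document's true theme is
    drawn from ``config.theme_mixture``; its tokens come from that theme's
    lexicon pool, each replaced by a generic noise word with probability
    ``config.noise_rate``.  True-"unknown" documents contain only noise
    words.  Returns (documents, true labels), index-aligned.
    """
    rng = np.random.default_rng([config.seed, 1])
    lexicon = lexicon or themes_mod.default_lexicon()
    pools = {name: sorted(tokens) for name, tokens in lexicon.themes}
    noise = [w for w in NOISE_VOCABULARY if all(w not in p for p in pools.values())]

    mixture_names = sorted(config.theme_mixture)
    probs = np.array([config.theme_mixture[n] for n in mixture_names])
    for name in mixture_names:
        if name != themes_mod.UNKNOWN and name not in pools:
            raise ValueError(f"theme {name!r} in mixture but not in lexicon")

    if graph is not None:
        cuis = sorted(c.cui for c in graph.nodes())
    else:
        cuis = [f"C82{i:05d}" for i in range(1, 101)]

    pmid = 50_000_000
    docs: list[themes_mod.RelationshipDocument] = []
    labels: list[str] = []
    for _ in range(config.n_documents):
        theme = mixture_names[int(rng.choice(len(mixture_names), p=probs / probs.sum()))]
        words = []
        for _ in range(config.tokens_per_doc):
            if theme == themes_mod.UNKNOWN or rng.random() < config.noise_rate:
                words.append(_choice(rng, noise))
            else:
                words.append(_choice(rng, pools[theme]))
        docs.append(
            themes_mod.RelationshipDocument(
                cui=_choice(rng, cuis), pmid=str(pmid), text=" ".join(words)
            )
        )
        labels.append(theme)
        pmid += 1
    return docs, labels


def write_labels(labels: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(list(labels), fh)
        fh.write("\n")
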