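"""Serial simulation architecture for hub-based literature discovery.

The workflow mirrors a cross-domain knowledge-graph study design:

1. Run one depth-bounded simulation per clinical target (e.g. a disease
   pair), ranking every semantically allowed source concept by aggregated
   HeteSim relevance.
2. Intersect the two rankings on base concept identifiers to find sources
   tied to *both* targets.
3. Select highly connected, highly ranked intersection members as *hub
   nodes* (e.g. receptor-pathway members).
4. Re-run simulations with each hub as a target ("hub network analysis"),
   which effectively extends the search depth into graph regions invisible
   to the original depth-2 runs.
5. Intersect the hub simulations, sort by a declared hub priority order,
   and report the top-k sources per semantic type.

All operations are deterministic: identical graph + spec produce identical
tables (stable sorts, lexicographic CUI tie-breaks).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import aggregate, pathscore
from .kgraph import KnowledgeGraph

DEFAULT_SEMTYPES = frozenset({"AAPP", "GNGM", "HORM"})

#: column order of the per-simulation detail table
DETAIL_COLUMNS = [
    "cui",
    "name",
    "semtypes",
    "relevance",
    "normalized",
    "percentile",
    "metapath_count",
    "schema_count",
]


@dataclass
class SimulationSpec:
    """Inputs of one simulation: targets, type constraint, search depth."""

    sim_id: str
    targets: list[str]
    allowed_semtypes: frozenset[str] = DEFAULT_SEMTYPES
    depth: int = 2
    damping: float = 0.4
    combine: str = "mean"  # multi-target combination: "mean" or "min"

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(f"simulation {self.sim_id!r} needs >= 1 target")
        if self.depth < 1:
            raise ValueError("search depth must be >= 1")
        if self.combine not in ("mean", "min"):
            raise ValueError("combine must be 'mean' or 'min'")
        self.allowed_semtypes = frozenset(self.allowed_semtypes)


@dataclass
class SimulationResult:
    """Ranked source table plus recomputable summary metadata."""

    sim_id: str
    spec: SimulationSpec
    table: pd.DataFrame
    metadata: dict

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False, float_format="%.12g")

    def write_metadata(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.metadata, fh, indent=2, sort_keys=True)
            fh.write("\n")


@dataclass
class HubCriteria:
    """Filter/selection rule for hub nodes drawn from an intersection."""

    min_percentile: float = 0.0
    min_metapath_count: int = 0
    candidate_whitelist: frozenset[str] | None = None
    n_hubs: int = 3

    def __post_init__(self) -> None:
        if self.n_hubs < 1:
            raise ValueError("n_hubs must be >= 1")
        if self.candidate_whitelist is not None:
            self.candidate_whitelist = frozenset(self.candidate_whitelist)


def run_simulation(graph: KnowledgeGraph, spec: SimulationSpec) -> SimulationResult:
    """Score every allowed source against the spec's targets.

    For each candidate source (semantic type intersecting the allowed set,
    not itself a target): enumerate simple metapaths to every target at
    length <= depth, score HeteSim per schema, rank schemas' lists by
    DWPC-weighted HeteSim, aggregate with ULARA, combine across targets,
    min–max normalize and percentile-rank.
    """
    for t in spec.targets:
        if t not in graph:
            raise KeyError(f"unknown target {t}")
    candidates = sorted(graph.filter_semtypes(spec.allowed_semtypes) - set(spec.targets))

    per_target: dict[str, dict[str, float]] = {}
    detail_instances: dict[str, int] = {}
    detail_schemas: dict[str, set] = {}
    total_instances = 0
    hetesim_cache: dict = {}

    candidate_set = set(candidates)
    for t in spec.targets:
        schema_scores: dict[pathscore.MetapathSchema, dict[str, float]] = {}
        schema_keys: dict[pathscore.MetapathSchema, dict[str, float]] = {}
        by_source_schema = pathscore.enumerate_to_target(
            graph, t, spec.depth, sources=candidate_set
        )
        for (src, schema), insts in by_source_schema.items():
            het = pathscore.hetesim_cached(graph, src, t, schema, hetesim_cache)
            dw = pathscore.dwpc(insts, graph, spec.damping)
            schema_scores.setdefault(schema, {})[src] = het
            schema_keys.setdefault(schema, {})[src] = het * dw
            detail_instances[src] = detail_instances.get(src, 0) + len(insts)
            detail_schemas.setdefault(src, set()).add((t, schema))
            total_instances += len(insts)
        rank_lists = [
            aggregate.RankList(schema, schema_scores[schema], schema_keys[schema])
            for schema in sorted(schema_scores, key=str)
        ]
        per_target[t] = (
            aggregate.ulara(rank_lists).relevance if rank_lists else {}
        )

    sources = sorted({s for rel in per_target.values() for s in rel})
    combined: dict[str, float] = {}
    for s in sources:
        vals = [per_target[t].get(s, 0.0) for t in spec.targets]
        combined[s] = min(vals) if spec.combine == "min" else sum(vals) / len(vals)

    if combined:
        cuis, raw, norm, pct = aggregate.ranked_table(combined)
        table = pd.DataFrame(
            {
                "cui": cuis,
                "name": [graph.node(c).name for c in cuis],
                "semtypes": [",".join(sorted(graph.node(c).semtypes)) for c in cuis],
                "relevance": raw,
                "normalized": norm,
                "percentile": pct,
                "metapath_count": [detail_instances[c] for c in cuis],
                "schema_count": [len(detail_schemas[c]) for c in cuis],
            }
        )
        table = table.sort_values(
            ["percentile", "cui"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        meta_scores = table["relevance"]
        metadata = {
            "sim_id": spec.sim_id,
            "targets": list(spec.targets),
            "source_node_count": int(len(table)),
            "metapath_count": int(total_instances),
            "min_hetesim": float(meta_scores.min()),
            "max_hetesim": float(meta_scores.max()),
            "mean_hetesim": float(meta_scores.mean()),
        }
    else:
        table = pd.DataFrame(columns=DETAIL_COLUMNS)
        metadata = {
            "sim_id": spec.sim_id,
            "targets": list(spec.targets),
            "source_node_count": 0,
            "metapath_count": 0,
            "min_hetesim": 0.0,
            "max_hetesim": 0.0,
            "mean_hetesim": 0.0,
        }
    return SimulationResult(spec.sim_id, spec, table, metadata)


# -- intersection ----------------------------------------------------------


def _base_reduce(table: pd.DataFrame) -> dict[str, dict]:
    """Collapse composite CUIs onto base IDs (percentile = max over variants)."""
    out: dict[str, dict] = {}
    for row in table.itertuples(index=False):
        base = row.cui.split("|", 1)[0]
        rec = out.get(base)
        if rec is None:
            out[base] = {
                "percentile": float(row.percentile),
                "variants": 1,
                "metapath_count": int(row.metapath_count),
                "name": row.name,
                "semtypes": row.semtypes,
            }
        else:
            if float(row.percentile) > rec["percentile"]:
                rec["percentile"] = float(row.percentile)
                rec["name"] = row.name
                rec["semtypes"] = row.semtypes
            rec["variants"] += 1
            rec["metapath_count"] += int(row.metapath_count)
    return out


def intersect(
    results: Sequence[SimulationResult], min_frequency: int = 2
) -> pd.DataFrame:
    """Base-ID intersection of >= 2 simulations.

    A base concept qualifies when present (as any composite variant) in all
    simulations and its frequency — the number of contributing (variant,
    simulation) rows — reaches ``min_frequency``.  Columns: one percentile
    per simulation, their mean, summed metapath counts and the frequency.
    """
    if len(results) < 2:
        raise ValueError("intersect requires at least two simulation results")
    reduced = {r.sim_id: _base_reduce(r.table) for r in results}
    sim_ids = [r.sim_id for r in results]
    common = set.intersection(*(set(m) for m in reduced.values()))

    rows = []
    for base in sorted(common):
        freq = sum(reduced[sid][base]["variants"] for sid in sim_ids)
        if freq < min_frequency:
            continue
        first = reduced[sim_ids[0]][base]
        row = {
            "cui": base,
            "name": first["name"],
            "semtypes": first["semtypes"],
            "frequency": freq,
            "metapath_count": sum(
                reduced[sid][base]["metapath_count"] for sid in sim_ids
            ),
        }
        for sid in sim_ids:
            row[f"pct_{sid}"] = reduced[sid][base]["percentile"]
        row["mean_percentile"] = sum(
            reduced[sid][base]["percentile"] for sid in sim_ids
        ) / len(sim_ids)
        rows.append(row)

    columns = (
        ["cui", "name", "semtypes", "frequency", "metapath_count"]
        + [f"pct_{sid}" for sid in sim_ids]
        + ["mean_percentile"]
    )
    table = pd.DataFrame(rows, columns=columns)
    if len(table):
        table = table.sort_values(
            ["mean_percentile", "cui"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
    return table


def select_hubs(
    intersection: pd.DataFrame,
    criteria: HubCriteria,
    details: Mapping[str, pd.DataFrame] | None = None,
) -> list[str]:
    """Pick hub nodes: well connected, highly ranked intersection members.

    Rows must pass ``min_percentile`` (on the mean percentile across
    simulations) and ``min_metapath_count``; an optional whitelist restricts
    candidates.  Survivors are ordered by (metapath count desc, mean
    percentile desc, CUI) and truncated to ``n_hubs``.  ``details`` is
    accepted for callers that carry the per-simulation tables alongside; the
    intersection table already folds in the needed counts.
    """
    del details  # counts are already aggregated into the intersection table
    t = intersection
    mask = (t["mean_percentile"] >= criteria.min_percentile) & (
        t["metapath_count"] >= criteria.min_metapath_count
    )
    if criteria.candidate_whitelist is not None:
        mask &= t["cui"].isin(criteria.candidate_whitelist)
    picked = t[mask].sort_values(
        ["metapath_count", "mean_percentile", "cui"],
        ascending=[False, False, True],
        kind="stable",
    )
    if picked.empty:
        raise ValueError(
            "no hub candidates satisfy the criteria; relax min_percentile "
            "or min_metapath_count (or provide a whitelist)"
        )
    return picked["cui"].head(criteria.n_hubs).tolist()


def cross_domain_sort(
    intersection: pd.DataFrame, hub_order: Sequence[str]
) -> pd.DataFrame:
    """Multi-key descending sort of a hub-simulation intersection.

    ``hub_order`` lists simulation ids by priority; rows sort descending by
    ``pct_<sim>`` in that order, stable ties broken by CUI.
    """
    if len(hub_order) < 2:
        raise ValueError("cross-domain sorting needs >= 2 hub simulations")
    if intersection.empty:
        warnings.warn("empty cross-domain intersection", stacklevel=2)
        return intersection.copy()
    keys = [f"pct_{sid}" for sid in hub_order]
    for k in keys:
        if k not in intersection.columns:
            raise KeyError(f"intersection lacks column {k!r}")
    return intersection.sort_values(
        keys + ["cui"],
        ascending=[False] * len(keys) + [True],
        kind="stable",
    ).reset_index(drop=True)


def top_k_by_semtype(
    table: pd.DataFrame,
    k: int = 10,
    semtypes: Sequence[str] = ("AAPP", "GNGM", "HORM"),
) -> dict[str, pd.DataFrame]:
    """Top-k rows per semantic type, preserving the table's sort order.

    A row carrying several semantic types appears in each matching list;
    types with fewer than k rows return what exists.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    out: dict[str, pd.DataFrame] = {}
    sets = table["semtypes"].map(lambda s: set(s.split(",")))
    for st in semtypes:
        mask = sets.map(lambda have, st=st: st in have)
        out[st] = table[mask].head(k).reset_index(drop=True)
    return out


# -- configuration files ---------------------------------------------------


@dataclass
class PipelineConfig:
    """A full analysis plan: simulations, intersections, reporting knobs."""

    specs: dict[str, SimulationSpec]
    intersections: dict[str, list[str]] = field(default_factory=dict)
    hub_order: list[str] = field(default_factory=list)
    k: int = 10
    min_frequency: int = 2
    hub_criteria: HubCriteria = field(default_factory=HubCriteria)


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML/JSON analysis plan.

    Each ``simulations`` entry either lists ``targets`` (a runnable
    simulation) or ``intersect_of`` (a derived intersection analysis).
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    defaults = raw.get("defaults", {})
    specs: dict[str, SimulationSpec] = {}
    intersections: dict[str, list[str]] = {}
    for sim_id, entry in raw.get("simulations", {}).items():
        if "intersect_of" in entry:
            intersections[sim_id] = list(entry["intersect_of"])
            continue
        specs[sim_id] = SimulationSpec(
            sim_id=sim_id,
            targets=list(entry["targets"]),
            allowed_semtypes=frozenset(
                entry.get("allowed_semtypes", defaults.get("allowed_semtypes", DEFAULT_SEMTYPES))
            ),
            depth=int(entry.get("depth", defaults.get("depth", 2))),
            damping=float(entry.get("damping", defaults.get("damping", 0.4))),
            combine=entry.get("combine", defaults.get("combine", "mean")),
        )
    hc = raw.get("hub_criteria", {})
    return PipelineConfig(
        specs=specs,
        intersections=intersections,
        hub_order=list(raw.get("hub_order", [])),
        k=int(raw.get("k", 10)),
        min_frequency=int(raw.get("min_frequency", 2)),
        hub_criteria=HubCriteria(
            min_percentile=float(hc.get("min_percentile", 0.0)),
            min_metapath_count=int(hc.get("min_metapath_count", 0)),
            candidate_whitelist=(
                frozenset(hc["candidate_whitelist"])
                if hc.get("candidate_whitelist")
                else None
            ),
            n_hubs=int(hc.get("n_hubs", 3)),
        ),
    )


def save_config(config: PipelineConfig, path: str | Path) -> None:
    """Write a plan back to YAML (round-trips through :func:`load_config`)."""
    sims: dict[str, dict] = {}
    for sim_id, spec in config.specs.items():
        sims[sim_id] = {
            "targets": list(spec.targets),
            "allowed_semtypes": sorted(spec.allowed_semtypes),
            "depth": spec.depth,
            "damping": spec.damping,
            "combine": spec.combine,
        }
    for sim_id, of in config.intersections.items():
        sims[sim_id] = {"intersect_of": list(of)}
    doc = {
        "simulations": sims,
        "hub_order": list(config.hub_order),
        "k": config.k,
        "min_frequency": config.min_frequency,
        "hub_criteria": {
            "min_percentile": config.hub_criteria.min_percentile,
            "min_metapath_count": config.hub_criteria.min_metapath_count,
            "n_hubs": config.hub_criteria.n_hubs,
            **(
                {"candidate_whitelist": sorted(config.hub_criteria.candidate_whitelist)}
                if config.hub_criteria.candidate_whitelist
                else {}
            ),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def table1_config_path() -> Path:
    """Path of the shipped six-analysis study plan (real UMLS CUIs)."""
    return Path(__file__).parent / "data" / "table1_analyses.yaml"


def synthetic_config_path() -> Path:
    """Path of the shipped study plan for synthetic benchmark graphs."""
    return Path(__file__).parent / "data" / "synthetic_sims.yaml"
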