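"""Greedy co-optimization of inconsistent landmarks against the unlabeled data.

Divisions and deaths near the sampled stage make the landmark sets of labeled
and unlabeled clouds differ, and a single missing or extra landmark can
cascade into many wrong matches.  Each lineage event therefore spawns
hypothesis edits of the labeled cloud — remove a dead cell, merge two
daughters back into their parent at the midpoint, or split a parent into two
co-located daughters — and an edit is kept only when it reduces the
missing-adjacency violation total by at least the acceptance threshold.
Accepted edits accumulate greedily, divisions considered before deaths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .adjacency import (AdjacencyGraph, EnsembleModel, gabriel_graph)
from .assign import Assignment, lap_with_iteration
from .landmarks_io import LandmarkCloud, LineageEvent, RunConfig

logger = logging.getLogger("nucalign")


@dataclass(frozen=True)
class Modification:
    """One hypothesis edit of a labeled cloud."""

    kind: str  # "remove_death" | "merge_daughters" | "split_parent"
    event: LineageEvent
    accepted: bool = False
    delta_violations: int = 0


@dataclass(frozen=True)
class MemberAlignment:
    """Co-optimization outcome for one labeled member.

    Carries the modified cloud together with the remapped constraint set so a
    later round can re-match under a new warp without re-deriving the
    modifications.
    """

    cloud: LandmarkCloud
    assignment: "Assignment"
    modifications: tuple[Modification, ...]
    graph: AdjacencyGraph
    aliases: Mapping[str, tuple[str, ...]]


def apply_modification(cloud: LandmarkCloud, m: Modification) -> LandmarkCloud:
    """Apply one edit, returning a new cloud.

    remove_death drops the dying cell; merge_daughters replaces the two
    daughters by the parent at their midpoint; split_parent replaces the
    parent by both daughters at the parent's exact position.
    """
    if cloud.names is None:
        raise ValueError("modifications require a named cloud")
    names = list(cloud.names)
    pts = cloud.points
    idx = cloud.name_index

    def require(name: str) -> int:
        if name not in idx:
            raise ValueError(f"{m.kind}: landmark {name!r} absent from cloud")
        return idx[name]

    if m.kind == "remove_death":
        i = require(m.event.subject)
        keep = [j for j in range(len(names)) if j != i]
        return replace(cloud, points=pts[keep], names=tuple(names[j] for j in keep))
    if m.kind == "merge_daughters":
        d1, d2 = m.event.daughters
        i1, i2 = require(d1), require(d2)
        mid = 0.5 * (pts[i1] + pts[i2])
        keep = [j for j in range(len(names)) if j not in (i1, i2)]
        new_pts = np.vstack([pts[keep], mid])
        new_names = tuple(names[j] for j in keep) + (m.event.subject,)
        return replace(cloud, points=new_pts, names=new_names)
    if m.kind == "split_parent":
        i = require(m.event.subject)
        d1, d2 = m.event.daughters
        keep = [j for j in range(len(names)) if j != i]
        new_pts = np.vstack([pts[keep], pts[i], pts[i]])
        new_names = tuple(names[j] for j in keep) + (d1, d2)
        return replace(cloud, points=new_pts, names=new_names)
    raise ValueError(f"unknown modification kind {m.kind!r}")


def _remap_constraints(graph: AdjacencyGraph, aliases: dict, m: Modification,
                       remap: bool) -> tuple[AdjacencyGraph, dict]:
    """Adjust the consistent-edge set to the modified name space.

    With ``remap`` on (default), edges touching merged daughters are renamed
    to the parent and edges touching a split parent are satisfied by either
    co-located daughter (via the alias map).  With ``remap`` off, edges
    touching any modified cell are simply dropped from the constraint set.
    Edges of a removed dead cell are dropped in both modes: the identity can
    never be assigned again, so they carry no signal.
    """
    aliases = dict(aliases)
    if m.kind == "remove_death":
        return graph.without_node(m.event.subject), aliases
    if m.kind == "merge_daughters":
        d1, d2 = m.event.daughters
        if remap:
            g = graph.relabel({d1: m.event.subject, d2: m.event.subject})
        else:
            g = graph.without_node(d1).without_node(d2)
        aliases.pop(d1, None)
        aliases.pop(d2, None)
        return g, aliases
    if m.kind == "split_parent":
        p = m.event.subject
        if remap:
            if p in graph.nodes:
                aliases[p] = m.event.daughters
            return graph, aliases
        return graph.without_node(p), aliases
    raise ValueError(f"unknown modification kind {m.kind!r}")


def _hypotheses(event: LineageEvent, cloud: LandmarkCloud) -> list[str]:
    """Edit kinds applicable to this event given the names present."""
    idx = cloud.name_index
    kinds = []
    if event.kind == "division":
        d1, d2 = event.daughters
        if d1 in idx and d2 in idx:
            kinds.append("merge_daughters")
        if event.subject in idx:
            kinds.append("split_parent")
    elif event.subject in idx:
        kinds.append("remove_death")
    return kinds


def cooptimize_labeled(labeled: LandmarkCloud, unlabeled: LandmarkCloud,
                       model: EnsembleModel, cfg: RunConfig, *,
                       frozen: Mapping[int, str] | None = None,
                       skip_modifications: bool = False
                       ) -> MemberAlignment:
    """Greedy modification sweep plus final long error correction.

    Returns the (possibly modified) labeled cloud, the best alignment found,
    the log of tried modifications, and the remapped constraint set.
    ``skip_modifications`` disables the sweep (ablation mode) but keeps the
    final correction run.
    """
    ugraph = gabriel_graph(unlabeled)
    graph = model.consistent_edges
    aliases: dict = {}
    cloud = labeled
    kw = dict(unlabeled_graph=ugraph, squared=cfg.squared_distance, frozen=frozen)

    best = lap_with_iteration(cloud, unlabeled, graph, cfg.correction_iters_inner,
                              aliases=aliases, **kw)
    log: list[Modification] = []
    frozen_idents = set((frozen or {}).values())
    if not skip_modifications:
        for event in model.inconsistent:
            # settled (frozen-confident) cells are not up for modification
            touched = {event.subject, *(event.daughters or ())}
            if touched & frozen_idents:
                continue
            for kind in _hypotheses(event, cloud):
                mod = Modification(kind=kind, event=event)
                try:
                    new_cloud = apply_modification(cloud, mod)
                except ValueError:
                    continue
                new_graph, new_aliases = _remap_constraints(
                    graph, aliases, mod, cfg.constraint_remap)
                cand = lap_with_iteration(new_cloud, unlabeled, new_graph,
                                          cfg.correction_iters_inner,
                                          aliases=new_aliases, **kw)
                delta = best.violations.total - cand.violations.total
                accepted = delta >= cfg.accept_threshold
                log.append(replace(mod, accepted=accepted, delta_violations=int(delta)))
                logger.debug("hypothesis %s(%s): delta %d -> %s", kind,
                             event.subject, delta, "accept" if accepted else "reject")
                if accepted:
                    cloud, graph, aliases, best = new_cloud, new_graph, new_aliases, cand
                    if kind == "merge_daughters":
                        break  # merge and split are mutually exclusive hypotheses

    final = lap_with_iteration(cloud, unlabeled, graph, cfg.correction_iters_final,
                               aliases=aliases, **kw)
    fv, bv = final.violations.total, best.violations.total
    if (fv, final.total_distance) > (bv, best.total_distance):
        final = best
    return MemberAlignment(cloud=cloud, assignment=final,
                           modifications=tuple(log), graph=graph, aliases=aliases)
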