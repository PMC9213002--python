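"""Linear-assignment matching with iterative, adjacency-driven error correction.

Matching a named cloud against a pre-aligned anonymous cloud is a linear
assignment problem minimizing total Euclidean distance.  Error correction then
repeatedly forbids (sets to infinite cost) the single matched identity with
the most missing consistent adjacencies and re-solves; over N iterations the
assignment with the fewest total violations is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .adjacency import AdjacencyGraph, ViolationScore, gabriel_graph, score_assignment
from .landmarks_io import LandmarkCloud

logger = logging.getLogger("nucalign")


class InfeasibleMatchError(RuntimeError):
    """Raised when forbidden pairs leave a landmark with no legal match."""


@dataclass(frozen=True)
class Assignment:
    """One solved matching: unlabeled index -> identity, with its scores."""

    mapping: Mapping[int, str]
    total_distance: float
    violations: ViolationScore | None = None
    forbidden: frozenset = frozenset()
    warnings: tuple[str, ...] = ()
    best_totals: tuple[int, ...] = ()  # best-so-far violation trace (diagnostics)

    def identity_of(self, idx: int) -> str | None:
        return self.mapping.get(idx)

    @property
    def index_of(self) -> dict[str, int]:
        return {v: k for k, v in self.mapping.items()}


def _cost_matrix(labeled: LandmarkCloud, unlabeled: LandmarkCloud,
                 squared: bool, frozen: Mapping[int, str] | None
                 ) -> tuple[np.ndarray, list[int], list[str]]:
    if labeled.names is None:
        raise ValueError("labeled cloud must be named")
    frozen = frozen or {}
    frozen_idents = set(frozen.values())
    rows = [i for i in range(len(unlabeled)) if i not in frozen]
    cols = [n for n in labeled.names if n not in frozen_idents]
    lp = np.array([labeled.position_of(n) for n in cols]) if cols else np.zeros((0, 3))
    up = unlabeled.points[rows] if rows else np.zeros((0, 3))
    diff = up[:, None, :] - lp[None, :, :]
    cost = (diff ** 2).sum(axis=2)
    if not squared:
        cost = np.sqrt(cost)
    return cost, rows, cols


def lap_match(labeled: LandmarkCloud, unlabeled: LandmarkCloud,
              forbidden: frozenset | set = frozenset(), *,
              squared: bool = False,
              frozen: Mapping[int, str] | None = None) -> Assignment:
    """Minimum-total-distance one-to-one matching.

    ``forbidden`` is a set of (unlabeled index, identity) pairs excluded from
    the solution.  In the rectangular case the excess side stays unmatched.
    ``frozen`` pairs are fixed a priori: they are removed from the problem and
    re-inserted into the returned mapping (at zero added distance).
    """
    cost, rows, cols = _cost_matrix(labeled, unlabeled, squared, frozen)
    col_of = {n: j for j, n in enumerate(cols)}
    row_of = {i: r for r, i in enumerate(rows)}
    work = cost.copy()
    for idx, ident in forbidden:
        r, c = row_of.get(idx), col_of.get(ident)
        if r is not None and c is not None:
            work[r, c] = np.inf
    try:
        ri, ci = linear_sum_assignment(work)
    except ValueError as exc:
        bad_rows = [rows[r] for r in range(len(rows)) if np.all(np.isinf(work[r]))]
        bad_cols = [cols[c] for c in range(len(cols)) if np.all(np.isinf(work[:, c]))]
        raise InfeasibleMatchError(
            f"no feasible assignment (fully forbidden landmarks: "
            f"indices {bad_rows}, identities {bad_cols})") from exc
    if np.any(np.isinf(work[ri, ci])):
        raise InfeasibleMatchError("forbidden pairs admit no feasible assignment")
    mapping = {rows[r]: cols[c] for r, c in zip(ri, ci)}
    total = float(cost[ri, ci].sum())
    if frozen:
        mapping.update(frozen)
    return Assignment(mapping=mapping, total_distance=total,
                      forbidden=frozenset(forbidden))


def _pick_worst(assignment: Assignment, score: ViolationScore,
                labeled: LandmarkCloud, unlabeled: LandmarkCloud,
                aliases: Mapping | None,
                frozen: Mapping[int, str] | None) -> tuple[int, str] | None:
    """The matched (index, identity) pair to forbid next.

    Among assigned identities sharing the maximal per-identity violation
    count, the one with the largest matched distance is chosen (the least
    spatially plausible match), remaining ties broken lexicographically.
    Frozen pairs and unassigned identities are never selected.
    """
    frozen = frozen or {}
    candidates: list[tuple[int, float, str, int]] = []
    alias_of = aliases or {}
    for node, count in score.per_identity.items():
        if count <= 0:
            continue
        for name in alias_of.get(node, (node,)):
            idx = assignment.index_of.get(name)
            if idx is None or idx in frozen:
                continue
            if name not in labeled.name_index:
                continue
            d = float(np.linalg.norm(unlabeled.points[idx] - labeled.position_of(name)))
            candidates.append((count, d, name, idx))
    if not candidates:
        return None
    worst = min(candidates, key=lambda t: (-t[0], -t[1], t[2]))
    return worst[3], worst[2]


def lap_with_iteration(labeled: LandmarkCloud, unlabeled: LandmarkCloud,
                       consistent: AdjacencyGraph, n_iters: int, *,
                       unlabeled_graph: AdjacencyGraph | None = None,
                       aliases: Mapping | None = None,
                       squared: bool = False,
                       frozen: Mapping[int, str] | None = None) -> Assignment:
    """LAP matching with up to ``n_iters`` rounds of iterative error correction.

    Each round scores the current assignment against the consistent
    adjacencies, forbids the worst-violating matched pair, and re-solves.
    The best assignment seen (fewest total violations, ties by smaller total
    distance) is returned; iteration stops early at zero violations or when no
    matched identity carries a violation.  Forbidden pairs accumulate within
    this call only.
    """
    if unlabeled_graph is None:
        unlabeled_graph = gabriel_graph(unlabeled)
    forbidden: set[tuple[int, str]] = set()
    warnings: list[str] = []

    def solved_and_scored(fb: set) -> Assignment:
        a = lap_match(labeled, unlabeled, frozenset(fb), squared=squared, frozen=frozen)
        v = score_assignment(a, consistent, unlabeled_graph, aliases=aliases)
        return replace(a, violations=v)

    current = solved_and_scored(forbidden)
    best = current
    trace = [best.violations.total]
    logger.debug("lap_with_iteration start: %d violations, distance %.3f",
                 best.violations.total, best.total_distance)
    for it in range(n_iters):
        if best.violations.total == 0:
            break
        pair = _pick_worst(current, current.violations, labeled, unlabeled,
                           aliases, frozen)
        if pair is None:
            break
        forbidden.add(pair)
        try:
            current = solved_and_scored(forbidden)
        except InfeasibleMatchError as exc:
            forbidden.discard(pair)
            warnings.append(f"iteration {it}: dropped forbidden pair {pair}: {exc}")
            logger.warning("iterative correction infeasible; %s", warnings[-1])
            break
        cv, bv = current.violations.total, best.violations.total
        if cv < bv or (cv == bv and current.total_distance < best.total_distance):
            best = current
        trace.append(best.violations.total)
        logger.debug("correction iter %d: current %d violations, best %d",
                     it, cv, trace[-1])
    return replace(best, warnings=best.warnings + tuple(warnings),
                   best_totals=tuple(trace))
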