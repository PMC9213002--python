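"""Consensus voting across per-member alignments, and the full pipeline.

The anonymous cloud is aligned independently against every labeled member of
the ensemble; each landmark then receives one identity vote per member.  The
most common name wins, and a landmark is *confident* when the winner holds a
supermajority (default 75%) of its votes.  Confident matches seed a second
round: a fresh thin-plate-spline warp fitted on them replaces the manual
pre-alignment, confident identities are frozen, and only the uncertain
landmarks are re-matched.  Duplicate winning identities across landmarks are
deliberately not resolved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .adjacency import EnsembleModel
from .assign import Assignment, lap_with_iteration
from .cooptimize import MemberAlignment, Modification, cooptimize_labeled
from .landmarks_io import (CorrespondenceTable, LandmarkCloud, RunConfig)
from .prealign import affine_fit, apply_transform, cpd_refine, tps_fit

logger = logging.getLogger("nucalign")

#: TPS smoothing grid for the reiteration re-fit, as fractions of the diameter
_REITER_LAMBDA_GRID = (0.0, 1e-3, 1e-2, 0.1, 0.3, 1.0, 3.0)


def _cv_tps_lambda(src: np.ndarray, dst: np.ndarray, diameter: float,
                   n_folds: int = 5) -> float:
    """Pick the TPS smoothing by k-fold cross-validation on the correspondences.

    Confident matches are numerous but carry positional jitter (and the odd
    unanimously wrong anchor); exact interpolation would bend the warp to
    every jittered control point.  Held-out prediction error selects how much
    smoothing that warrants.
    """
    n = len(src)
    if n < 2 * n_folds:
        return 0.0
    folds = [np.arange(n) % n_folds == f for f in range(n_folds)]
    lams, means, ses = [], [], []
    for frac in _REITER_LAMBDA_GRID:
        lam = frac * diameter
        errs = []
        try:
            for hold in folds:
                t = tps_fit(src[~hold], dst[~hold], lam)
                errs.append(float(((t(src[hold]) - dst[hold]) ** 2).sum()))
        except Exception:
            continue
        lams.append(lam)
        means.append(float(np.mean(errs)))
        ses.append(float(np.std(errs) / np.sqrt(len(errs))))
    if not lams:
        return 0.0
    return lams[int(np.argmin(means))]


def _trim_anchors(src: np.ndarray, dst: np.ndarray, lam: float
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Drop control pairs with outlying fit residuals (robust refit).

    A landmark can be confidently voted and still wrong (all members agree on
    the same neighbour swap); such anchors sit several median absolute
    deviations off the smoothed fit and are excluded before the final warp.
    """
    if len(src) < 8 or lam <= 0:
        return src, dst
    fit = tps_fit(src, dst, lam)
    r = np.linalg.norm(fit(src) - dst, axis=1)
    med = np.median(r)
    mad = np.median(np.abs(r - med))
    if mad <= 0:
        return src, dst
    keep = r <= med + 3.5 * 1.4826 * mad
    if keep.sum() < max(5, len(src) // 2):
        return src, dst
    return src[keep], dst[keep]


@dataclass(frozen=True)
class LandmarkVote:
    identity: str | None
    votes_for_winner: int
    total_votes: int
    confident: bool


@dataclass(frozen=True)
class ConsensusResult:
    """Per-landmark vote tallies, winners, and confidence flags."""

    per_landmark: Mapping[int, LandmarkVote]
    round: int = 1
    warnings: tuple[str, ...] = ()
    member_states: tuple[MemberAlignment, ...] = ()
    prior_rounds: tuple["ConsensusResult", ...] = ()

    @property
    def member_assignments(self) -> tuple[Assignment, ...]:
        return tuple(s.assignment for s in self.member_states)

    @property
    def modification_log(self) -> tuple[tuple[Modification, ...], ...]:
        return tuple(s.modifications for s in self.member_states)

    def identities(self) -> dict[int, str | None]:
        return {i: v.identity for i, v in self.per_landmark.items()}

    def confident_indices(self) -> list[int]:
        return [i for i, v in self.per_landmark.items()
                if v.confident and v.identity is not None]


def vote(assignments: Sequence[Assignment], cfg: RunConfig,
         n_points: int | None = None) -> ConsensusResult:
    """Tally identity votes per landmark across per-member assignments.

    Unmatched indices abstain (excluded from the denominator).  Ties go to
    the identity voted by the assignment with the lowest violation total,
    then lexicographically.
    """
    if not assignments:
        raise ValueError("need at least one assignment to vote")
    if n_points is None:
        n_points = max((max(a.mapping, default=-1) for a in assignments), default=-1) + 1
    per: dict[int, LandmarkVote] = {}
    for i in range(n_points):
        counts: dict[str, int] = {}
        best_viol: dict[str, float] = {}
        for a in assignments:
            ident = a.mapping.get(i)
            if ident is None:
                continue
            counts[ident] = counts.get(ident, 0) + 1
            v = a.violations.total if a.violations is not None else np.inf
            best_viol[ident] = min(best_viol.get(ident, np.inf), v)
        if not counts:
            per[i] = LandmarkVote(None, 0, 0, False)
            continue
        winner = min(counts, key=lambda n: (-counts[n], best_viol[n], n))
        total = sum(counts.values())
        per[i] = LandmarkVote(winner, counts[winner], total,
                              counts[winner] / total >= cfg.supermajority)
    return ConsensusResult(per_landmark=per, round=1)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def _prealign_member(unlabeled: LandmarkCloud, member: LandmarkCloud,
                     corr: CorrespondenceTable, cfg: RunConfig) -> LandmarkCloud:
    """Manual-landmark global fit, then CPD refinement, into the member frame."""
    src = unlabeled.points[corr.indices]
    dst = np.array([member.position_of(n) for n in corr.identities])
    if cfg.prealign_mode == "tps":
        pre = tps_fit(src, dst, cfg.tps_lambda)
    else:
        pre = affine_fit(src, dst)
    warped = apply_transform(pre, unlabeled)
    disp = cpd_refine(warped, member, cfg.cpd_params)
    return apply_transform(disp, warped)


def _align_one(member: LandmarkCloud, warped: LandmarkCloud,
               model: EnsembleModel, cfg: RunConfig, mode: str,
               frozen: Mapping[int, str] | None = None) -> MemberAlignment:
    skip = mode in ("no_coopt", "lap_only")
    c = cfg
    if mode == "lap_only":
        c = replace(cfg, correction_iters_inner=0, correction_iters_final=0)
    return cooptimize_labeled(member, warped, model, c, frozen=frozen,
                              skip_modifications=skip)


def reiterate(unlabeled: LandmarkCloud, model: EnsembleModel,
              consensus: ConsensusResult, cfg: RunConfig,
              mode: str = "full") -> ConsensusResult:
    """One re-alignment round seeded by a TPS fit on confident matches.

    Confident identities are frozen (reinserted when scoring adjacencies) and
    never overwritten; only uncertain landmarks are re-matched.  With fewer
    than 5 usable confident matches the round is skipped with a warning.
    """
    conf = {i: consensus.per_landmark[i].identity
            for i in consensus.confident_indices()}
    # identities confidently claimed by several landmarks are ambiguous as
    # TPS control points; keep one landmark (the most-voted) per identity
    by_ident: dict[str, int] = {}
    for i, ident in conf.items():
        j = by_ident.get(ident)
        if j is None or (consensus.per_landmark[i].votes_for_winner
                         > consensus.per_landmark[j].votes_for_winner):
            by_ident[ident] = i
    control = {i: ident for ident, i in by_ident.items()}
    if len(control) < 5:
        msg = f"reiteration skipped: only {len(control)} confident landmarks (< 5)"
        logger.warning(msg)
        return replace(consensus, warnings=consensus.warnings + (msg,))

    uncertain = [i for i in consensus.per_landmark if i not in conf]
    if not uncertain:
        return consensus

    states, warns = [], []
    for k, member in enumerate(model.labeled_clouds):
        prev = (consensus.member_states[k]
                if k < len(consensus.member_states) else None)
        pairs = [(i, ident) for i, ident in control.items()
                 if ident in member.name_index]
        if len(pairs) < 5:
            warns.append(f"member {member.source_id!r}: too few confident "
                         f"matches for TPS; skipped in reiteration")
            if prev is not None:
                states.append(prev)
            continue
        src = unlabeled.points[[i for i, _ in pairs]]
        dst = np.array([member.position_of(ident) for _, ident in pairs])
        lam = _cv_tps_lambda(src, dst, unlabeled.diameter)
        src_t, dst_t = _trim_anchors(src, dst, lam)
        warped = apply_transform(tps_fit(src_t, dst_t, lam), unlabeled)
        disp = cpd_refine(warped, member, cfg.cpd_params)
        warped = apply_transform(disp, warped)
        if prev is not None:
            # re-match only: the sample-side modifications settled in the
            # previous round are facts about the data, not the warp
            a = lap_with_iteration(prev.cloud, warped, prev.graph,
                                   cfg.correction_iters_final,
                                   aliases=prev.aliases,
                                   squared=cfg.squared_distance, frozen=conf)
            state = replace(prev, assignment=a)
        else:
            state = _align_one(member, warped, model, cfg, mode, frozen=conf)
        # greedy acceptance in the method's own objective: keep the
        # re-initialized alignment only if it strictly reduces violations
        # (total distance is biased toward the new warp, so it breaks no ties)
        a = state.assignment
        if (prev is not None and prev.assignment.violations is not None
                and a.violations.total >= prev.assignment.violations.total):
            state = prev
        states.append(state)
    if not states:
        msg = "reiteration skipped: no member had enough confident matches"
        logger.warning(msg)
        return replace(consensus, warnings=consensus.warnings + tuple(warns) + (msg,))

    revote = vote([s.assignment for s in states], cfg, n_points=len(unlabeled))
    per = dict(consensus.per_landmark)
    for i in uncertain:
        per[i] = revote.per_landmark[i]
    return ConsensusResult(per_landmark=per, round=consensus.round + 1,
                           warnings=consensus.warnings + tuple(warns),
                           member_states=tuple(states),
                           prior_rounds=consensus.prior_rounds + (consensus,))


def align_unlabeled(unlabeled: LandmarkCloud, model: EnsembleModel,
                    corr: CorrespondenceTable, cfg: RunConfig,
                    mode: str = "full") -> ConsensusResult:
    """Full pipeline: pre-align, co-optimize per member, vote, reiterate.

    ``mode`` selects the ablation variant: "full", "no_coopt" (skip the
    modification sweep), or "lap_only" (plain LAP + vote, no correction, no
    reiteration).  Deterministic given identical inputs and config.
    """
    if mode not in ("full", "no_coopt", "lap_only"):
        raise ValueError(f"unknown mode {mode!r}")
    states = []
    for member in model.labeled_clouds:
        w = _prealign_member(unlabeled, member, corr, cfg)
        states.append(_align_one(member, w, model, cfg, mode))
    result = vote([s.assignment for s in states], cfg, n_points=len(unlabeled))
    result = replace(result, member_states=tuple(states))
    if mode != "lap_only":
        for _ in range(cfg.reiteration_rounds):
            result = reiterate(unlabeled, model, result, cfg, mode=mode)
    return result
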