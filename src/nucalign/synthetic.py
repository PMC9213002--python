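"""Synthetic embryo-like benchmark data with ground truth.

Generates a named reference cloud of nuclear centroids filling a 2:1:1
ellipsoid (the rough aspect of a bean-stage C. elegans embryo, long axis
~50 um), an ensemble of labeled members with per-point jitter and a smooth
random warp, and an anonymized test cloud with an extra modality distortion
(anisotropic scaling + rotation, standing in for section compression and
acquisition orientation).  Division and death events realized independently
per sample emulate developmental heterochrony, so the landmark sets of
members and test cloud genuinely differ — the situation co-optimization
exists to handle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .landmarks_io import CorrespondenceTable, LandmarkCloud, LineageEvent

logger = logging.getLogger("nucalign")

#: semi-axes of the reference ellipsoid, micrometres (2:1:1 aspect)
_SEMI_AXES = np.array([25.0, 12.5, 12.5])
#: reference stage time, minutes post first cleavage
_STAGE_TIME = 100.0
#: temporal window within which heterochronic events are drawn
_EVENT_WINDOW = 13.0
#: SD of a sample's developmental-time offset, minutes (heterochrony scale)
_HETEROCHRONY_SD = 3.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; fractions are relative to the cloud diameter."""

    n_landmarks: int = 150
    n_members: int = 3
    jitter_sigma: float = 0.02
    warp_amplitude: float = 0.03
    warp_smoothness: float = 0.3
    frac_inconsistent: float = 0.05
    division_fraction_of_events: float = 0.5
    anisotropy: tuple[float, float, float] = (1.0, 1.0, 0.8)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.jitter_sigma <= 0.2 and 0 <= self.warp_amplitude <= 0.2):
            raise ValueError("jitter_sigma and warp_amplitude must lie in [0, 0.2]")
        if not 0 <= self.frac_inconsistent <= 0.2:
            raise ValueError("frac_inconsistent must lie in [0, 0.2]")
        if self.n_members < 1:
            raise ValueError("need at least one ensemble member")


@dataclass(frozen=True)
class GroundTruth:
    """True identity per unlabeled index, plus the realized lineage events."""

    true_names: dict[int, str]
    events_realized: tuple[LineageEvent, ...]


class DensityError(RuntimeError):
    """Raised when the requested point density cannot honor the separation."""


def make_reference(spec: SyntheticSpec) -> LandmarkCloud:
    """Quasi-uniform named cloud inside the reference ellipsoid.

    Dart throwing enforces a minimum pairwise separation of 0.3x the expected
    nearest-neighbor distance of a uniform sample at the same density.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n = spec.n_landmarks
    volume = 4.0 / 3.0 * np.pi * np.prod(_SEMI_AXES)
    # mean NN distance of a spatial Poisson process: 0.554 * density^(-1/3)
    min_sep = 0.3 * 0.554 * (volume / n) ** (1.0 / 3.0)
    points: list[np.ndarray] = []
    attempts = 0
    while len(points) < n:
        attempts += 1
        if attempts > 500 * n:
            raise DensityError(
                f"cannot place {n} points with separation {min_sep:.2f} um")
        p = rng.uniform(-1.0, 1.0, size=3)
        if (p ** 2).sum() > 1.0:
            continue
        p = p * _SEMI_AXES
        if points and np.min(np.linalg.norm(np.array(points) - p, axis=1)) < min_sep:
            continue
        points.append(p)
    names = tuple(f"c{i + 1:04d}" for i in range(n))
    return LandmarkCloud(points=np.array(points), names=names, time=_STAGE_TIME,
                         stage_label="synthetic", source_id=f"ref{spec.rng_seed}")


def designate_events(reference: LandmarkCloud, spec: SyntheticSpec) -> list[LineageEvent]:
    """Choose the inconsistent landmarks: which cells divide or die, and when."""
    rng = np.random.default_rng(spec.rng_seed + 1)
    n_events = int(round(spec.frac_inconsistent * spec.n_landmarks))
    subjects = [str(s) for s in rng.choice(reference.names, size=n_events,
                                           replace=False)]
    n_div = int(round(spec.division_fraction_of_events * n_events))
    events = []
    for k, subject in enumerate(subjects):
        t = _STAGE_TIME + float(rng.uniform(-0.45, 0.45)) * _EVENT_WINDOW
        if k < n_div:
            events.append(LineageEvent(kind="division", subject=subject,
                                       daughters=(f"{subject}a", f"{subject}p"), time=t))
        else:
            events.append(LineageEvent(kind="death", subject=subject, time=t))
    return events


def _smooth_warp(points: np.ndarray, rng: np.random.Generator,
                 amplitude: float, smoothness: float, diameter: float) -> np.ndarray:
    """Sum of <= 5 Gaussian-bump displacement fields."""
    if amplitude <= 0:
        return points
    n_bumps = int(rng.integers(3, 6))
    out = points.copy()
    scale = smoothness * diameter
    per_bump = amplitude * diameter / np.sqrt(n_bumps)
    for _ in range(n_bumps):
        center = rng.uniform(-1.0, 1.0, size=3) * _SEMI_AXES
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        w = np.exp(-((points - center) ** 2).sum(axis=1) / (2.0 * scale ** 2))
        out = out + per_bump * w[:, None] * direction
    return out


def _realize_events(points: np.ndarray, names: list[str],
                    events: Sequence[LineageEvent], rng: np.random.Generator
                    ) -> tuple[np.ndarray, list[str], list[LineageEvent]]:
    """Realize the subset of events this sample has already undergone.

    Each sample sits at a random developmental-time offset from the nominal
    stage; an event is realized iff its time precedes the sample's time.
    Samples thus differ in which divisions/deaths they show (heterochrony),
    with events far from the stage time realized consistently.
    """
    sample_time = _STAGE_TIME + rng.normal(scale=_HETEROCHRONY_SD)
    realized = []
    for e in events:
        if e.time > sample_time:
            continue
        idx = {n: i for i, n in enumerate(names)}
        if e.subject not in idx:
            continue
        i = idx[e.subject]
        if e.kind == "death":
            points = np.delete(points, i, axis=0)
            names = names[:i] + names[i + 1:]
        else:
            tree = cKDTree(points)
            d, _ = tree.query(points[i], k=2)
            offset = 0.5 * d[1]
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            p = points[i]
            points = np.delete(points, i, axis=0)
            names = names[:i] + names[i + 1:]
            points = np.vstack([points, p + offset * axis, p - offset * axis])
            names = names + [e.daughters[0], e.daughters[1]]
        realized.append(e)
    return points, names, realized


def sample_member(reference: LandmarkCloud, spec: SyntheticSpec, member_seed: int
                  ) -> tuple[LandmarkCloud, list[LineageEvent]]:
    """One labeled ensemble member: events + smooth warp + jitter."""
    rng = np.random.default_rng(member_seed)
    events = designate_events(reference, spec)
    points, names, realized = _realize_events(
        reference.points.copy(), list(reference.names), events, rng)
    diameter = reference.diameter
    points = _smooth_warp(points, rng, spec.warp_amplitude,
                          spec.warp_smoothness, diameter)
    points = points + rng.normal(scale=spec.jitter_sigma * diameter,
                                 size=points.shape)
    cloud = LandmarkCloud(points=points, names=tuple(names), time=_STAGE_TIME,
                          stage_label="synthetic", source_id=f"member{member_seed}")
    return cloud, realized


def make_unlabeled(reference: LandmarkCloud, spec: SyntheticSpec, seed: int
                   ) -> tuple[LandmarkCloud, GroundTruth, CorrespondenceTable]:
    """Anonymized test cloud with modality distortion, plus ground truth.

    On top of a member-like sample, an anisotropic scale and a random global
    rotation emulate the cross-modality distortion; names are stripped and
    point order permuted.  The correspondence table points at 6 well-spread
    landmarks untouched by any designated event (the manual landmarks).
    """
    rng = np.random.default_rng(seed)
    events = designate_events(reference, spec)
    points, names, realized = _realize_events(
        reference.points.copy(), list(reference.names), events, rng)
    diameter = reference.diameter
    points = _smooth_warp(points, rng, spec.warp_amplitude,
                          spec.warp_smoothness, diameter)
    points = points + rng.normal(scale=spec.jitter_sigma * diameter,
                                 size=points.shape)
    # modality distortion: anisotropic scale about the centroid, then rotation
    centroid = points.mean(axis=0)
    points = (points - centroid) * np.asarray(spec.anisotropy)
    rot = Rotation.random(rng=rng).as_matrix()
    points = points @ rot.T + centroid

    perm = rng.permutation(len(points))
    cloud = LandmarkCloud(points=points[perm], time=_STAGE_TIME,
                          stage_label="synthetic", source_id=f"unlabeled{seed}")
    pos_of = {name: i for i, name in enumerate(names)}
    inv = np.empty(len(perm), dtype=int)
    inv[perm] = np.arange(len(perm))
    true_names = {int(inv[pos_of[name]]): name for name in names}

    touched = {e.subject for e in events}
    for e in events:
        if e.daughters:
            touched.update(e.daughters)
    stable = [n for n in reference.names if n not in touched]
    chosen = _farthest_point_subset(reference, stable, k=6)
    pairs = tuple((name, int(inv[pos_of[name]])) for name in chosen)
    return cloud, GroundTruth(true_names=true_names,
                              events_realized=tuple(realized)), CorrespondenceTable(pairs)


def _farthest_point_subset(reference: LandmarkCloud, names: Sequence[str],
                           k: int) -> list[str]:
    """Greedy farthest-point selection for well-spread manual landmarks."""
    pts = np.array([reference.position_of(n) for n in names])
    chosen = [int(np.argmax(pts[:, 0]))]  # start at an extreme of the long axis
    for _ in range(k - 1):
        d = np.min(
            np.linalg.norm(pts[:, None, :] - pts[chosen][None, :, :], axis=2), axis=1)
        chosen.append(int(np.argmax(d)))
    return [names[i] for i in chosen]


def make_benchmark(spec: SyntheticSpec) -> tuple[
        list[tuple[LandmarkCloud, list[LineageEvent]]], list[LineageEvent],
        LandmarkCloud, GroundTruth, CorrespondenceTable]:
    """Reference + members + unlabeled test cloud in one call.

    Returns (members_with_realized_events, designated_events, unlabeled,
    ground_truth, correspondences).  All randomness derives from
    ``spec.rng_seed``.
    """
    reference = make_reference(spec)
    events = designate_events(reference, spec)
    members = [sample_member(reference, spec, spec.rng_seed + 100 + i)
               for i in range(spec.n_members)]
    unlabeled, truth, corr = make_unlabeled(reference, spec, spec.rng_seed + 999)
    return members, events, unlabeled, truth, corr
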