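"""Core data containers and on-disk formats.

Landmark clouds are tables of named 3D nuclear centroids (micrometres, in an
arbitrary right-handed frame); lineage events record divisions and deaths in
minutes post first cleavage.  CSV is the single on-disk dialect (comma
separator, header row, UTF-8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nucalign")


def setup_logging(level: int = logging.INFO, logfile: str | Path | None = None) -> None:
    """Configure the package logger (stderr, optionally a file)."""
    logger.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        logger.addHandler(fh)


class FormatError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when a configuration or container violates its invariants."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LandmarkCloud:
    """A set of 3D points, optionally named, with stage/time metadata.

    Parameters
    ----------
    points
        ``(n, 3)`` float array of positions in micrometres.
    names
        Identity strings, one per point, or ``None`` for anonymous clouds.
        Names must be unique within a cloud.
    time
        Minutes post first cleavage, or ``None``.
    stage_label, source_id
        Free-text metadata.
    """

    points: np.ndarray
    names: tuple[str, ...] | None = None
    time: float | None = None
    stage_label: str = ""
    source_id: str = ""

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValidationError(f"points must be (n, 3); got shape {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise ValidationError("all positions must be finite")
        object.__setattr__(self, "points", pts)
        if self.names is not None:
            names = tuple(str(n) for n in self.names)
            if len(names) != len(pts):
                raise ValidationError(
                    f"{len(names)} names for {len(pts)} points"
                )
            if len(set(names)) != len(names):
                dup = sorted({n for n in names if names.count(n) > 1})
                raise ValidationError(f"duplicate names: {dup}")
            object.__setattr__(self, "names", names)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def is_labeled(self) -> bool:
        return self.names is not None

    @property
    def diameter(self) -> float:
        """Diameter of the point set: the maximum pairwise distance."""
        if len(self.points) < 2:
            return 0.0
        from scipy.spatial.distance import pdist
        return float(pdist(self.points).max())

    @property
    def name_index(self) -> dict[str, int]:
        if self.names is None:
            return {}
        return {n: i for i, n in enumerate(self.names)}

    def position_of(self, name: str) -> np.ndarray:
        try:
            return self.points[self.name_index[name]]
        except KeyError:
            raise KeyError(f"landmark {name!r} not in cloud {self.source_id!r}") from None

    def with_points(self, points: np.ndarray) -> "LandmarkCloud":
        return replace(self, points=np.asarray(points, dtype=float))


@dataclass(frozen=True)
class LineageEvent:
    """A division or programmed death of one named cell."""

    kind: str  # "division" | "death"
    subject: str
    daughters: tuple[str, str] | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("division", "death"):
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "division":
            if self.daughters is None or len(self.daughters) != 2:
                raise ValidationError(f"division of {self.subject!r} needs two daughters")
            if self.daughters[0] == self.daughters[1]:
                raise ValidationError(f"division daughters of {self.subject!r} must differ")
            object.__setattr__(self, "daughters", tuple(self.daughters))
        elif self.daughters is not None:
            raise ValidationError(f"death of {self.subject!r} cannot have daughters")


@dataclass(frozen=True)
class CorrespondenceTable:
    """Manual landmark correspondences: (labeled identity, unlabeled index)."""

    pairs: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((str(a), int(b)) for a, b in self.pairs)
        idents = [p[0] for p in pairs]
        idxs = [p[1] for p in pairs]
        if len(set(idents)) != len(idents) or len(set(idxs)) != len(idxs):
            raise ValidationError("correspondence table has repeated identity or index")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def identities(self) -> list[str]:
        return [p[0] for p in self.pairs]

    @property
    def indices(self) -> list[int]:
        return [p[1] for p in self.pairs]


@dataclass(frozen=True)
class CpdParams:
    """Coherent-point-drift parameters (normalized, zero-mean unit-RMS frame)."""

    beta: float = 2.0
    lam: float = 3.0
    outlier_weight: float = 0.1
    max_iters: int = 100
    tol: float = 1e-6


@dataclass(frozen=True)
class RunConfig:
    """Tunable parameters of the alignment pipeline.

    Defaults follow the published procedure: a 13-minute temporal window for
    the ensemble model, modifications accepted on a violation reduction of at
    least 3, 200 error-correction iterations per modification and 1400 on the
    final cloud, a 75% supermajority for confidence, and one reiteration round.
    """

    window_minutes: float = 13.0
    accept_threshold: float = 3
    correction_iters_inner: int = 200
    correction_iters_final: int = 1400
    supermajority: float = 0.75
    reiteration_rounds: int = 1
    prealign_mode: str = "affine"  # "affine" | "tps"
    cpd_params: CpdParams = field(default_factory=CpdParams)
    rng_seed: int = 0
    squared_distance: bool = False
    constraint_remap: bool = True
    tps_lambda: float = 0.0

    def __post_init__(self) -> None:
        if not (0.5 < self.supermajority <= 1.0):
            raise ValidationError(
                f"supermajority must lie in (0.5, 1]; got {self.supermajority}"
            )
        if self.accept_threshold < 1:
            raise ValidationError("accept_threshold must be >= 1")
        for k in ("correction_iters_inner", "correction_iters_final", "reiteration_rounds"):
            if getattr(self, k) < 0:
                raise ValidationError(f"{k} must be >= 0")
        if self.prealign_mode not in ("affine", "tps"):
            raise ValidationError(f"prealign_mode must be affine or tps; got {self.prealign_mode!r}")


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"  # >= 9 significant digits for round-trips


def read_cloud(path: str | Path) -> LandmarkCloud:
    """Read a landmark cloud from CSV with columns ``x,y,z`` (+ optional ``name,time``)."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"name": str})
    for col in ("x", "y", "z"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing coordinate column {col!r}")
    try:
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        for row, rec in enumerate(df[["x", "y", "z"]].itertuples(index=False)):
            for v in rec:
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise FormatError(
                        f"{path}: non-numeric coordinate {v!r} in data row {row}"
                    ) from exc
        raise FormatError(f"{path}: non-numeric coordinates") from exc
    names = tuple(df["name"].astype(str)) if "name" in df.columns else None
    time = None
    if "time" in df.columns and len(df):
        tvals = df["time"].to_numpy(dtype=float)
        time = float(tvals[0])
    return LandmarkCloud(points=pts, names=names, time=time, source_id=path.stem)


def write_cloud(cloud: LandmarkCloud, path: str | Path) -> None:
    cols: dict[str, object] = {}
    if cloud.names is not None:
        cols["name"] = list(cloud.names)
    cols.update(x=cloud.points[:, 0], y=cloud.points[:, 1], z=cloud.points[:, 2])
    if cloud.time is not None:
        cols["time"] = [cloud.time] * len(cloud)
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_lineage(path: str | Path) -> list[LineageEvent]:
    """Read lineage events from CSV ``kind,subject,daughter1,daughter2,time``."""
    df = pd.read_csv(path, dtype={"subject": str, "daughter1": str, "daughter2": str})
    for col in ("kind", "subject", "time"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    events = []
    for rec in df.itertuples(index=False):
        daughters = None
        if rec.kind == "division":
            daughters = (str(rec.daughter1), str(rec.daughter2))
        events.append(LineageEvent(kind=str(rec.kind), subject=str(rec.subject),
                                   daughters=daughters, time=float(rec.time)))
    return events


def write_lineage(events: Iterable[LineageEvent], path: str | Path) -> None:
    rows = []
    for e in events:
        d1, d2 = e.daughters if e.daughters else ("", "")
        rows.append({"kind": e.kind, "subject": e.subject,
                     "daughter1": d1, "daughter2": d2, "time": e.time})
    pd.DataFrame(rows, columns=["kind", "subject", "daughter1", "daughter2", "time"]
                 ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_correspondence(path: str | Path) -> CorrespondenceTable:
    df = pd.read_csv(path, dtype={"identity": str})
    for col in ("identity", "index"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return CorrespondenceTable(tuple((str(r.identity), int(r.index))
                                     for r in df.itertuples(index=False)))


def write_correspondence(table: CorrespondenceTable, path: str | Path) -> None:
    pd.DataFrame(table.pairs, columns=["identity", "index"]).to_csv(path, index=False)


def write_assignment(result, cloud: LandmarkCloud, path: str | Path) -> None:
    """Write a consensus result as ``index,x,y,z,identity,votes_for_winner,total_votes,confident``."""
    rows = []
    for i in range(len(cloud)):
        entry = result.per_landmark.get(i)
        if entry is None or entry.identity is None:
            ident, vw, tv, conf = "", 0, 0, False
        else:
            ident, vw, tv, conf = (entry.identity, entry.votes_for_winner,
                                   entry.total_votes, entry.confident)
        x, y, z = cloud.points[i]
        rows.append({"index": i, "x": x, "y": y, "z": z, "identity": ident,
                     "votes_for_winner": vw, "total_votes": tv, "confident": conf})
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_assignment(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, dtype={"identity": str})
    df["confident"] = df["confident"].astype(str).str.lower().isin(("true", "1"))
    return df


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a :class:`RunConfig` from a YAML file, applying defaults for absent keys."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is not None:
            if not isinstance(loaded, Mapping):
                raise FormatError(f"{path}: config must be a mapping")
            data.update(loaded)
    data.update(overrides)
    cpd_raw = data.pop("cpd_params", None)
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    cfg_kwargs = dict(data)
    if cpd_raw is not None:
        if isinstance(cpd_raw, CpdParams):
            cfg_kwargs["cpd_params"] = cpd_raw
        else:
            cfg_kwargs["cpd_params"] = CpdParams(**cpd_raw)
    return RunConfig(**cfg_kwargs)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    data = {k: getattr(cfg, k) for k in RunConfig.__dataclass_fields__ if k != "cpd_params"}
    data["cpd_params"] = {k: getattr(cfg.cpd_params, k)
                          for k in CpdParams.__dataclass_fields__}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
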