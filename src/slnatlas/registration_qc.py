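"""Landmark-based registration-error metrics and reference-subject selection.

Registration accuracy is quantified by Euclidean distances between
corresponding named skeletal landmarks annotated in two coordinate frames
(e.g. before/after registration, or by two observers).  The registration
algorithms themselves are out of scope; this module only scores point sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkSet",
    "ErrorSummary",
    "landmark_errors",
    "interobserver_summary",
    "select_reference_by_scapula",
    "read_landmarks_csv",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkSet:
    """Named 3-D landmarks (mm) annotated by one observer on one subject."""

    observer_id: str
    subject_id: str
    points: tuple[tuple[str, float, float, float], ...]

    def __post_init__(self) -> None:
        names = [p[0] for p in self.points]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate landmark names in set {self.observer_id}/{self.subject_id}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(p[0] for p in self.points)

    def coords(self) -> dict[str, np.ndarray]:
        return {p[0]: np.array(p[1:], dtype=float) for p in self.points}


@dataclass(frozen=True)
class ErrorSummary:
    """Per-landmark distances (mm) with pooled mean and sample SD."""

    distances: tuple[tuple[str, float], ...]
    mean_mm: float
    sd_mm: float | None
    n: int


def _summarize(named_distances: list[tuple[str, float]]) -> ErrorSummary:
    d = np.array([v for _, v in named_distances], dtype=float)
    return ErrorSummary(
        distances=tuple(named_distances),
        mean_mm=float(d.mean()),
        sd_mm=float(d.std(ddof=1)) if len(d) > 1 else None,
        n=len(d),
    )


def landmark_errors(a: LandmarkSet, b: LandmarkSet) -> ErrorSummary:
    """Euclidean distances between corresponding landmarks of two sets."""
    ca, cb = a.coords(), b.coords()
    shared = [n for n in a.names if n in cb]
    if not shared:
        raise ValueError("no shared landmark names between the two sets")
    dists = [(n, float(np.linalg.norm(ca[n] - cb[n]))) for n in shared]
    return _summarize(dists)


def interobserver_summary(sets) -> dict[tuple[str, str], ErrorSummary]:
    """Pairwise observer agreement pooled over shared subjects.

    For each observer pair, distances between corresponding landmarks are
    pooled over every subject both observers annotated.  Subjects annotated
    by a single observer are skipped with a warning.
    """
    by_subject: dict[str, dict[str, LandmarkSet]] = {}
    for s in sets:
        by_subject.setdefault(s.subject_id, {})[s.observer_id] = s
    observers = sorted({s.observer_id for s in sets})
    pooled: dict[tuple[str, str], list[tuple[str, float]]] = {
        pair: [] for pair in combinations(observers, 2)
    }
    for subject, obs_sets in sorted(by_subject.items()):
        if len(obs_sets) < 2:
            log.warning("subject %s annotated by a single observer; skipped", subject)
            continue
        for o1, o2 in combinations(sorted(obs_sets), 2):
            err = landmark_errors(obs_sets[o1], obs_sets[o2])
            pooled[(o1, o2)].extend(
                (f"{subject}:{name}", d) for name, d in err.distances
            )
    out = {pair: _summarize(d) for pair, d in pooled.items() if d}
    if not out:
        raise ValueError("no observer pair shares any subject")
    return out


def select_reference_by_scapula(lengths: dict[str, float]) -> str:
    """Subject whose scapula length equals the sample median.

    For an even count the lower of the two middle values is used (so the
    selected subject is always a real one); ties on length are broken by
    lexicographic subject id.
    """
    if not lengths:
        raise ValueError("empty length map")
    ordered = sorted(lengths.items(), key=lambda kv: (kv[1], kv[0]))
    median_value = ordered[(len(ordered) - 1) // 2][1]
    for subject, value in ordered:
        if value == median_value:
            return subject
    raise AssertionError("unreachable: median value is always attained")


def read_landmarks_csv(path) -> list[LandmarkSet]:
    """Read landmark CSV (observer_id, subject_id, landmark_name, x_mm, y_mm, z_mm)."""
    df = pd.read_csv(path)
    required = {"observer_id", "subject_id", "landmark_name", "x_mm", "y_mm", "z_mm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for (obs, subj), grp in df.groupby(["observer_id", "subject_id"], sort=True):
        pts = tuple(
            (str(r.landmark_name), float(r.x_mm), float(r.y_mm), float(r.z_mm))
            for r in grp.itertuples()
        )
        out.append(LandmarkSet(observer_id=str(obs), subject_id=str(subj), points=pts))
    return out
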