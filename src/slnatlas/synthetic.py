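"""Synthetic cohorts and 3-D geometry with the structure the analysis assumes.

The cohort generator is the generative counterpart of the estimation models:
tumour regions are multinomial over the 13 clockface regions, and drainage to
each of the 12 node fields is an independent region-conditional Bernoulli
(multi-label, non-exclusive).  Tumours that drain to no field are redrawn
(field vector only, region kept), encoding the enrolment filter that imaging
proceeded only when SLNs were seen; the induced conditional truth has the
closed form p / (1 - prod(1 - p_row)), exposed via
:func:`conditional_drainage_truth` for oracle use.

The geometry generator rasterizes simple labelled primitives (boxes, balls)
into CTV masks and scatters SLN points, reporting analytic ground-truth
coverage and distances computed from the primitives themselves (not from the
rasterized masks) wherever a closed form exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import N_REGIONS, NODE_FIELDS, Cohort, TumourRecord
from .ctv_geometry import CTVMask, SLNPoint
from .datasets import FIELD_COUNTS, REGION_TOTALS

__all__ = [
    "CohortSimSpec",
    "simulate_cohort",
    "conditional_drainage_truth",
    "Box",
    "Ball",
    "SLNPlacement",
    "GeometrySimSpec",
    "simulate_geometry",
]


def reference_region_probs() -> np.ndarray:
    """Region proportions of the reference cohort (sums to 1)."""
    totals = np.asarray(REGION_TOTALS, dtype=float)
    return totals / totals.sum()


def reference_drainage_matrix() -> np.ndarray:
    """13 x 12 region-conditional drainage probabilities of the reference cohort."""
    counts = np.column_stack([FIELD_COUNTS[f] for f in NODE_FIELDS]).astype(float)
    return counts / np.asarray(REGION_TOTALS, dtype=float)[:, None]


@dataclass(frozen=True)
class CohortSimSpec:
    """Cohort generator settings; defaults reproduce the reference cohort's
    size and composition (861 patients, 8 bilateral, 417/869 right-sided,
    region mix and drainage rates from the reference contingency table)."""

    n_patients: int = 861
    bilateral_rate: float = 8 / 861
    region_probs: tuple[float, ...] = tuple(reference_region_probs())
    drainage_matrix: tuple[tuple[float, ...], ...] = tuple(
        tuple(row) for row in reference_drainage_matrix()
    )
    right_fraction: float = 417 / 869
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.region_probs, dtype=float)
        mat = np.asarray(self.drainage_matrix, dtype=float)
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.bilateral_rate <= 1 or not 0 <= self.right_fraction <= 1:
            raise ValueError("rates must be probabilities")
        if probs.shape != (N_REGIONS,) or abs(probs.sum() - 1.0) > 1e-12 or (probs < 0).any():
            raise ValueError("region_probs must be a 13-simplex vector (sum 1 within 1e-12)")
        if mat.shape != (N_REGIONS, len(NODE_FIELDS)) or ((mat < 0) | (mat > 1)).any():
            raise ValueError("drainage_matrix must be 13 x 12 with entries in [0, 1]")
        if (mat.sum(axis=1) == 0).any():
            raise ValueError(
                "drainage_matrix has an all-zero region row: zero-drainage redraw "
                "would not terminate"
            )


def conditional_drainage_truth(spec: CohortSimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Post-enrolment drainage probabilities implied by the redraw rule.

    Returns ``(per_region, whole_breast)``: conditioning a tumour on draining
    to at least one field multiplies every field probability in region ``r``
    by ``1 / (1 - prod_f(1 - p[r, f]))``; the whole-breast truth mixes the
    per-region rows with the region probabilities.
    """
    mat = np.asarray(spec.drainage_matrix, dtype=float)
    probs = np.asarray(spec.region_probs, dtype=float)
    p_none = np.prod(1.0 - mat, axis=1)
    per_region = mat / (1.0 - p_none)[:, None]
    whole = probs @ per_region
    return per_region, whole


def simulate_cohort(spec: CohortSimSpec) -> Cohort:
    """Draw a synthetic (unreflected) cohort, reproducible under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    mat = np.asarray(spec.drainage_matrix, dtype=float)
    probs = np.asarray(spec.region_probs, dtype=float)
    records = []
    for p in range(spec.n_patients):
        pid = f"S{p:04d}"
        first_right = rng.random() < spec.right_fraction
        sides = ["R" if first_right else "L"]
        if rng.random() < spec.bilateral_rate:
            sides.append("L" if first_right else "R")
        for side in sides:
            region = int(rng.choice(N_REGIONS, p=probs))
            for _ in range(10_000):
                drained = rng.random(len(NODE_FIELDS)) < mat[region]
                if drained.any():
                    break
            else:  # pragma: no cover - guarded by the all-zero-row check
                raise RuntimeError(f"zero-drainage redraw did not terminate for region {region}")
            fields = frozenset(f for f, d in zip(NODE_FIELDS, drained) if d)
            clock = region if (side == "L" or region in (0, 12)) else 12 - region
            records.append(
                TumourRecord(
                    patient_id=pid,
                    sex="F",
                    age_years=float(np.round(np.clip(rng.normal(60.0, 11.0), 25.0, 93.0), 1)),
                    side=side,
                    clockface=clock,
                    nipple_distance_cm=0.5 if region == 0 else float(rng.uniform(1.5, 10.0)),
                    drained_fields=fields,
                )
            )
    return Cohort(tuple(records))


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class Box:
    """Axis-aligned box primitive (physical mm)."""

    label: str
    side: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return ((pts >= np.asarray(self.lo)) & (pts <= np.asarray(self.hi))).all(axis=1)

    def signed_distance(self, p: np.ndarray) -> float:
        """Euclidean distance to the box surface; negative inside."""
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        d_out = np.maximum(np.maximum(lo - p, p - hi), 0.0)
        outside = float(np.linalg.norm(d_out))
        if outside > 0:
            return outside
        return -float(np.min(np.minimum(p - lo, hi - p)))

    def sphere_fraction(self, center: np.ndarray, radius: float) -> float | None:
        """Analytic volume fraction of a sphere inside the box.

        Closed form when the sphere is fully inside/outside or cut by a
        single face plane within the face's lateral extent (spherical cap);
        None when the configuration is not analytically certified.
        """
        sd = self.signed_distance(center)
        if sd <= -radius:
            return 1.0
        if sd >= radius:
            return 0.0
        lo, hi = np.asarray(self.lo, float), np.asarray(self.hi, float)
        # signed distances to the 6 face planes, positive towards the inside
        plane_d = np.concatenate([center - lo, hi - center])
        cutting = np.abs(plane_d) < radius
        if cutting.sum() != 1:
            return None
        axis = int(np.argmax(cutting)) % 3
        lateral = [a for a in range(3) if a != axis]
        # cap certified only if the sphere stays within the face extent laterally
        for a in lateral:
            if center[a] - radius < lo[a] or center[a] + radius > hi[a]:
                return None
        d = float(plane_d[cutting][0])  # signed: >0 means centre on inside
        h = radius + d  # height of the cap on the inside of the plane
        return float(h * h * (3 * radius - h) / (4 * radius**3))


@dataclass(frozen=True)
class Ball:
    """Sphere primitive (physical mm)."""

    label: str
    side: str
    center: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return ((pts - np.asarray(self.center)) ** 2).sum(axis=1) <= self.radius**2

    def signed_distance(self, p: np.ndarray) -> float:
        return float(np.linalg.norm(p - np.asarray(self.center)) - self.radius)

    def sphere_fraction(self, center: np.ndarray, radius: float) -> float | None:
        """Exact sphere-sphere intersection (lens) volume fraction."""
        R = self.radius
        d = float(np.linalg.norm(np.asarray(center, float) - np.asarray(self.center, float)))
        if d >= R + radius:
            return 0.0
        if d <= R - radius:
            return 1.0
        if d <= radius - R:  # CTV ball entirely inside the SLN sphere
            return float((R / radius) ** 3)
        lens = (
            np.pi
            * (R + radius - d) ** 2
            * (d**2 + 2 * d * (R + radius) - 3 * (radius - R) ** 2)
            / (12 * d)
        )
        return float(lens / (4 / 3 * np.pi * radius**3))


@dataclass(frozen=True)
class SLNPlacement:
    """Placement rule: ``count`` SLNs at ``center`` with isotropic scatter
    ``sigma_mm`` (0 = deterministic), assigned to one node field and side."""

    node_field: str
    side: str
    center: tuple[float, float, float]
    sigma_mm: float = 0.0
    count: int = 1
    diameter_mm: float = 5.0


@dataclass(frozen=True)
class GeometrySimSpec:
    """Grid geometry, CTV primitives and SLN placement rules."""

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    primitives: tuple = ()
    placements: tuple[SLNPlacement, ...] = ()
    seed: int = 0

    def grid_extent(self) -> tuple[np.ndarray, np.ndarray]:
        org = np.asarray(self.origin, float)
        return org, org + np.asarray(self.spacing, float) * np.asarray(self.shape)


def _rasterize(prim, spec: GeometrySimSpec) -> CTVMask:
    shape = spec.shape
    idx = np.stack(
        np.meshgrid(*(np.arange(s) for s in shape), indexing="ij"), axis=-1
    ).reshape(-1, 3)
    phys = np.asarray(spec.origin) + idx * np.asarray(spec.spacing)
    data = prim.contains(phys).reshape(shape)
    return CTVMask(
        data=data,
        spacing=np.asarray(spec.spacing, float),
        origin=np.asarray(spec.origin, float),
        direction=np.eye(3),
        label=prim.label,
        side=prim.side,
    )


def simulate_geometry(
    spec: GeometrySimSpec,
) -> tuple[list[SLNPoint], list[CTVMask], pd.DataFrame]:
    """Rasterize the primitives, scatter SLN points and build the analytic
    ground-truth table.

    The truth table has one row per (point, primitive) pair with the analytic
    volume fraction (NaN when no closed form applies), the covered flag under
    the strict >50% rule, and the centroid-to-primitive-surface distance.
    Primitives are assumed pairwise disjoint, so the per-point truth against
    a set of CTVs is the row with the maximal fraction.
    """
    lo, hi = spec.grid_extent()
    rng = np.random.default_rng(spec.seed)
    masks = [_rasterize(p, spec) for p in spec.primitives]
    points: list[SLNPoint] = []
    for rule in spec.placements:
        for _ in range(rule.count):
            c = np.asarray(rule.center, float)
            if rule.sigma_mm > 0:
                c = c + rng.normal(0.0, rule.sigma_mm, size=3)
            if (c < lo).any() or (c > hi).any():
                raise ValueError(f"SLN centre {c} falls outside the grid extent")
            points.append(
                SLNPoint(
                    x=float(c[0]),
                    y=float(c[1]),
                    z=float(c[2]),
                    node_field=rule.node_field,
                    side=rule.side,
                    diameter_mm=rule.diameter_mm,
                )
            )
    rows = []
    for i, pt in enumerate(points):
        for prim in spec.primitives:
            frac = prim.sphere_fraction(pt.centroid, pt.diameter_mm / 2.0)
            sd = prim.signed_distance(pt.centroid)
            rows.append(
                {
                    "point": i,
                    "node_field": pt.node_field,
                    "side": pt.side,
                    "ctv_label": prim.label,
                    "ctv_side": prim.side,
                    "fraction_truth": np.nan if frac is None else frac,
                    "covered_truth": None if frac is None else frac > 0.5,
                    "distance_truth_mm": max(sd, 0.0),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "point",
            "node_field",
            "side",
            "ctv_label",
            "ctv_side",
            "fraction_truth",
            "covered_truth",
            "distance_truth_mm",
        ],
    )
    return points, masks, truth
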