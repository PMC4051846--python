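"""Shaft-curvature comparison via two-point (Bookstein) baseline registration.

Each specimen's ten shaft landmarks, digitized in 3-D along the anterior
femoral shaft, are first flattened to the plane by a per-specimen PCA
(the first two principal axes of the ten points), then registered by the
similarity transform — rotation, translation, uniform scaling, no
reflection — that sends the first landmark to (0, 0) and the last to
(1, 0).  After registration the x coordinates mark comparable stations
along the shaft and the y coordinates carry the curvature signal in
baseline units (fractions of the proximal-to-distal chord).

Curve shapes are compared by the mean Euclidean distance between
corresponding registered landmarks; the two endpoint landmarks are pinned
by construction and excluded from the mean by default (including them
simply rescales the distance by 8/10 and is available as an option).

PCA axes carry an arbitrary sign, so orientation is normalized: the first
axis points proximal -> distal (positive from landmark 1 to landmark 10)
and the second axis is chosen so the summed off-chord coordinate of the
interior landmarks is >= 0 (anterior bow positive).  Without this rule
distances would be flip-ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .morphodata import Clade, CurveLandmarks, CurveState, ValidationError

__all__ = [
    "CurveDistance",
    "flatten_to_plane",
    "baseline_register",
    "register",
    "mean_curve",
    "curve_distance",
    "rank_taxa",
    "estimate_kappa",
]


@dataclass(frozen=True)
class CurveDistance:
    """Mean landmark distance between a query curve and a taxon, in
    baseline units (dimensionless fractions of the chord)."""

    fossil_id: str
    taxon: str
    d: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValidationError("a curve distance cannot be negative")


def flatten_to_plane(curve: CurveLandmarks) -> CurveLandmarks:
    """Project a raw 3-D chain onto its own first two principal axes.

    Orientation is normalized (see module docstring) so the output is
    unique, not merely unique up to flips.  Degenerate input (all points
    coincident) is an error.
    """
    if curve.state is not CurveState.RAW3D:
        raise ValidationError("flatten_to_plane expects a raw3d curve")
    pts = curve.points
    centered = pts - pts.mean(axis=0)
    # principal axes of the 10-point cloud
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12:
        raise ValidationError(
            f"specimen {curve.specimen_id!r}: degenerate landmark chain "
            "(all points coincident)"
        )
    xy = centered @ vt[:2].T
    # axis 1: proximal -> distal
    if xy[-1, 0] - xy[0, 0] < 0:
        xy[:, 0] = -xy[:, 0]
    # axis 2: summed off-chord coordinate of interior landmarks >= 0
    chord = xy[-1] - xy[0]
    norm = np.hypot(*chord)
    if norm > 0:
        # signed perpendicular offset of each interior point from the chord
        rel = xy[1:-1] - xy[0]
        offsets = (chord[0] * rel[:, 1] - chord[1] * rel[:, 0]) / norm
        if offsets.sum() < 0:
            xy[:, 1] = -xy[:, 1]
    return replace(curve, points=xy, state=CurveState.PLANAR2D)


def baseline_register(curve: CurveLandmarks) -> CurveLandmarks:
    """Similarity-register a planar chain to the (0,0)-(1,0) baseline.

    The unique rotation + translation + uniform scaling (no reflection)
    sending landmark 1 to the origin and landmark 10 to (1, 0) is applied
    to all ten points; the endpoints are set exactly.
    """
    if curve.state is not CurveState.PLANAR2D:
        raise ValidationError("baseline_register expects a planar2d curve")
    z = curve.points[:, 0] + 1j * curve.points[:, 1]
    denom = z[-1] - z[0]
    if abs(denom) < 1e-12:
        raise ValidationError(
            f"specimen {curve.specimen_id!r}: baseline endpoints coincide"
        )
    w = (z - z[0]) / denom
    pts = np.column_stack([w.real, w.imag])
    pts[0] = (0.0, 0.0)
    pts[-1] = (1.0, 0.0)
    return replace(curve, points=pts, state=CurveState.BOOKSTEIN2D)


def register(curve: CurveLandmarks) -> CurveLandmarks:
    """Flatten (if 3-D) and baseline-register in one step."""
    if curve.state is CurveState.RAW3D:
        curve = flatten_to_plane(curve)
    if curve.state is CurveState.PLANAR2D:
        curve = baseline_register(curve)
    return curve


def mean_curve(shapes: Sequence[CurveLandmarks]) -> CurveLandmarks:
    """Landmark-wise arithmetic mean of registered shapes.

    Endpoints remain exactly (0,0) and (1,0).  The mean carries the taxon
    of the first shape (callers group by taxon before averaging).
    """
    if not shapes:
        raise ValidationError("mean_curve needs at least one shape")
    for s in shapes:
        if s.state is not CurveState.BOOKSTEIN2D:
            raise ValidationError("mean_curve expects bookstein2d shapes")
    pts = np.mean([s.points for s in shapes], axis=0)
    pts[0] = (0.0, 0.0)
    pts[-1] = (1.0, 0.0)
    first = shapes[0]
    return CurveLandmarks(
        specimen_id=f"mean({first.taxon}, n={len(shapes)})",
        taxon=first.taxon,
        clade=first.clade,
        points=pts,
        state=CurveState.BOOKSTEIN2D,
    )


def curve_distance(
    a: CurveLandmarks,
    b: CurveLandmarks,
    *,
    include_endpoints: bool = False,
    coords: str = "xy",
) -> CurveDistance:
    """Mean per-landmark distance between two registered shapes.

    By default the mean runs over the eight interior landmarks using both
    registered coordinates; ``coords="y"`` uses only the off-baseline
    coordinate, and ``include_endpoints=True`` divides by ten instead of
    eight (the endpoint distances are identically zero).
    """
    for s in (a, b):
        if s.state is not CurveState.BOOKSTEIN2D:
            raise ValidationError("curve_distance expects bookstein2d shapes")
    if a.points.shape != b.points.shape:
        raise ValidationError("landmark count mismatch")
    diff = a.points - b.points
    if coords == "y":
        per_landmark = np.abs(diff[:, 1])
    elif coords == "xy":
        per_landmark = np.hypot(diff[:, 0], diff[:, 1])
    else:
        raise ValidationError(f"coords must be 'xy' or 'y', got {coords!r}")
    if include_endpoints:
        d = float(per_landmark.mean())
    else:
        d = float(per_landmark[1:-1].mean())
    return CurveDistance(fossil_id=a.specimen_id, taxon=b.taxon, d=d)


def rank_taxa(
    fossil: CurveLandmarks,
    taxa: Mapping[str, Sequence[CurveLandmarks]],
    *,
    mode: str = "mean",
    include_endpoints: bool = False,
    coords: str = "xy",
) -> list[CurveDistance]:
    """Distances from a registered fossil curve to each taxon, ascending.

    ``mode="mean"`` compares against each taxon's mean registered shape;
    ``mode="pairwise"`` averages the fossil's distance to every individual
    of the taxon.  Ties order alphabetically by taxon.
    """
    if not taxa:
        raise ValidationError("rank_taxa needs at least one taxon")
    out: list[CurveDistance] = []
    for taxon in taxa:
        shapes = [register(s) if s.state is not CurveState.BOOKSTEIN2D else s
                  for s in taxa[taxon]]
        if mode == "mean":
            target = mean_curve(shapes)
            cd = curve_distance(
                fossil, target, include_endpoints=include_endpoints, coords=coords
            )
            d = cd.d
        elif mode == "pairwise":
            ds = [
                curve_distance(
                    fossil, s, include_endpoints=include_endpoints, coords=coords
                ).d
                for s in shapes
            ]
            d = float(np.mean(ds))
        else:
            raise ValidationError(f"mode must be 'mean' or 'pairwise', got {mode!r}")
        out.append(CurveDistance(fossil_id=fossil.specimen_id, taxon=taxon, d=d))
    return sorted(out, key=lambda cd: (cd.d, cd.taxon))


def estimate_kappa(shape: CurveLandmarks) -> float:
    """Mid-chord bow of a registered shape, in baseline units.

    Fits a quadratic to the registered (x, y) landmarks and evaluates it at
    mid-chord (x = 1/2); for a noiseless quadratic arc this recovers the
    generating sagitta/chord ratio exactly even though no landmark sits at
    the apex itself.
    """
    if shape.state is not CurveState.BOOKSTEIN2D:
        raise ValidationError("estimate_kappa expects a bookstein2d shape")
    coef = np.polynomial.polynomial.polyfit(shape.points[:, 0], shape.points[:, 1], 2)
    return float(np.polynomial.polynomial.polyval(0.5, coef))
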