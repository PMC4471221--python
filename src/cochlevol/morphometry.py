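"""Cochlear morphometrics from ordered 3D landmark paths.

Five variables are computed from two kinds of landmark paths:

* a *spiral* path following the outer circumference of the cochlea from the
  cupula (apex) to the origin of the basal turn (or the reverse, declared);
* an optional *window outline* path around the oval window.

The variables are ECL (external cochlear length, mm), TUR (number of turns),
CUR (curvature gradient R2/R1), RECL (relative length, ECL/TUR, mm) and OWA
(oval window area, mm^2).  All computation is done at full precision; the
reporting layer rounds ECL/TUR/CUR/RECL to one decimal and OWA to two,
half-away-from-zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import (
    InsufficientTurnsError,
    InvalidInputError,
    InvalidOutlineError,
    SingularGeometryError,
    UndefinedAngleError,
)

__all__ = [
    "LandmarkPath",
    "SpiralGeometry",
    "CochlearMeasurements",
    "polyline_length",
    "best_fit_plane",
    "spiral_center",
    "fit_turn_circles",
    "count_turns",
    "curvature_gradient",
    "oval_window_area",
    "measure_cochlea",
    "round_half_away",
]

#: number of landmarks taken at each spiral extremity to form local chords
CHORD_GROUP_SIZE = 5


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported values)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class LandmarkPath:
    """An ordered sequence of 3D landmarks (mm).

    Parameters
    ----------
    points
        (n, 3) array-like of coordinates in mm, in path order.
    role
        ``"spiral"`` for the cochlear outer circumference,
        ``"window-outline"`` for the oval window outline.
    start
        For spiral paths, which anatomical end the first point is:
        ``"apex"`` (cupula) or ``"base"`` (basal-turn origin).
    """

    points: np.ndarray
    role: str = "spiral"
    start: Optional[str] = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InvalidInputError(
                f"landmarks must be an (n, 3) array, got shape {pts.shape}"
            )
        if pts.shape[0] < 3:
            raise InvalidInputError("a landmark path needs at least 3 points")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("landmark coordinates must be finite")
        seg = np.diff(pts, axis=0)
        if np.any(np.linalg.norm(seg, axis=1) == 0.0):
            raise InvalidInputError("consecutive landmarks must be distinct")
        if self.role not in ("spiral", "window-outline"):
            raise InvalidInputError(f"unknown path role {self.role!r}")
        if self.role == "spiral":
            if self.start not in ("apex", "base"):
                raise InvalidInputError(
                    "spiral paths must declare start='apex' or start='base'"
                )
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return self.points.shape[0]

    def reversed(self) -> "LandmarkPath":
        start = None
        if self.start is not None:
            start = "apex" if self.start == "base" else "base"
        return LandmarkPath(self.points[::-1].copy(), role=self.role, start=start)


@dataclass(frozen=True)
class SpiralGeometry:
    """Fitted spiral frame: center A, best-fit plane, turn radii."""

    center: np.ndarray            # point A, 3D, lies in the best-fit plane
    plane_normal: np.ndarray      # unit normal of the total-least-squares plane
    plane_origin: np.ndarray      # centroid of the spiral landmarks
    r1: Optional[float] = None    # radius of the smaller (apical, last) turn
    r2: Optional[float] = None    # radius of the larger (basal, first) turn


@dataclass(frozen=True)
class CochlearMeasurements:
    """The five cochlear variables at full precision.

    ``owa`` is ``None`` when no window outline was available (fossils may
    lack one); it is *missing*, never zero.
    """

    ecl: float
    tur: float
    cur: float
    recl: float
    owa: Optional[float] = None

    def __post_init__(self):
        for name in ("ecl", "tur", "cur", "recl"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name.upper()} must be positive")
        if self.owa is not None and self.owa <= 0:
            raise InvalidInputError("OWA must be positive when present")

    def rounded(self) -> dict:
        """Reporting-rule values: one decimal, OWA two decimals."""
        out = {
            "ECL": round_half_away(self.ecl, 1),
            "TUR": round_half_away(self.tur, 1),
            "CUR": round_half_away(self.cur, 1),
            "RECL": round_half_away(self.recl, 1),
        }
        out["OWA"] = None if self.owa is None else round_half_away(self.owa, 2)
        return out


def polyline_length(path: LandmarkPath | np.ndarray) -> float:
    """Sum of Euclidean distances between consecutive landmarks (mm)."""
    pts = path.points if isinstance(path, LandmarkPath) else np.asarray(path, float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InvalidInputError("need at least 2 points for a length")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def best_fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Total-least-squares plane through a point cloud.

    Returns ``(origin, normal)`` where *origin* is the centroid and *normal*
    the unit vector of smallest variance (SVD of the centered cloud).
    """
    pts = np.asarray(points, float)
    origin = pts.mean(axis=0)
    _, s, vt = np.linalg.svd(pts - origin, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise SingularGeometryError("points are (near-)collinear; no plane")
    return origin, vt[2]


def _plane_basis(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two orthonormal in-plane axes for a given unit normal."""
    n = normal / np.linalg.norm(normal)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(n @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, helper)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _project_2d(points: np.ndarray, origin: np.ndarray, normal: np.ndarray) -> np.ndarray:
    u, v = _plane_basis(normal)
    rel = points - origin
    return np.column_stack([rel @ u, rel @ v])


def _chord_center(xy: np.ndarray, groups) -> np.ndarray:
    """Least-squares intersection of perpendicular bisectors of local chords."""
    rows, rhs = [], []
    for g in groups:
        for p, q in zip(g[:-1], g[1:]):
            d = q - p
            norm = np.linalg.norm(d)
            if norm == 0.0:
                continue
            d = d / norm
            m = 0.5 * (p + q)
            rows.append(d)
            rhs.append(d @ m)
    a_mat = np.array(rows)
    b_vec = np.array(rhs)
    sol, _, rank, sv = np.linalg.lstsq(a_mat, b_vec, rcond=None)
    if rank < 2 or sv[1] < 1e-7 * max(sv[0], 1.0):
        raise SingularGeometryError(
            "chord bisectors are (near-)parallel; cannot locate spiral center"
        )
    return sol


def _unwrapped(xy: np.ndarray, center: np.ndarray):
    rel = xy - center
    radii = np.linalg.norm(rel, axis=1)
    theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    return theta, radii


def _radius_profile_residuals(xy: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Residuals of the radii against a quadratic-in-angle radius profile.

    At the true center the radius of a circle or of a gently widening
    spiral is a smooth, low-order function of the unwrapped angle; any
    center offset injects a sinusoidal ripple these residuals pick up.
    """
    theta, radii = _unwrapped(xy, center)
    if np.any(radii < 1e-12):
        return np.full(xy.shape[0], np.inf)
    design = np.column_stack([np.ones_like(theta), theta, theta**2])
    coef, *_ = np.linalg.lstsq(design, radii, rcond=None)
    return radii - design @ coef


def spiral_center(path: LandmarkPath, refine: bool = True) -> SpiralGeometry:
    """Locate the spiral center A from local chords at the two extremities.

    k = 5 landmarks spread over the first ~quarter turn at each end of the
    path form consecutive local chords; each chord constrains A to its
    in-plane perpendicular bisector and A starts as the least-squares
    intersection of all bisectors, after orthogonal projection of the path
    onto its total-least-squares plane.  For a circular arc this is the
    exact center.  A short Gauss-Newton refinement then minimizes the
    ripple of the radius-vs-angle profile, which corrects the small bias
    the chord construction has on spirals whose radius drifts along the
    turn (it is a no-op for circles).
    """
    pts = path.points if isinstance(path, LandmarkPath) else np.asarray(path, float)
    if pts.shape[0] < 2 * CHORD_GROUP_SIZE:
        raise InvalidInputError(
            f"need at least {2 * CHORD_GROUP_SIZE} landmarks to locate the center"
        )
    origin, normal = best_fit_plane(pts)
    xy = _project_2d(pts, origin, normal)

    # provisional angles about the centroid set the local angular scale so
    # each extremity group spans about a quarter turn regardless of density
    c0 = xy.mean(axis=0)
    rel = xy - c0
    with np.errstate(invalid="ignore"):
        theta0 = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    sweep0 = abs(theta0[-1] - theta0[0])
    window = min(math.pi / 2.0, max(sweep0 / 4.0, 1e-6))

    def group(from_start: bool) -> np.ndarray:
        if from_start:
            off = np.abs(theta0 - theta0[0])
        else:
            off = np.abs(theta0 - theta0[-1])
        idx = np.nonzero(off <= window)[0]
        if idx.size < 2:
            idx = np.arange(min(CHORD_GROUP_SIZE, xy.shape[0]))
            idx = idx if from_start else xy.shape[0] - 1 - idx
        take = np.unique(np.linspace(0, idx.size - 1, CHORD_GROUP_SIZE).round()
                         .astype(int))
        return xy[idx[take]]

    center2d = _chord_center(xy, [group(True), group(False)])

    if refine:
        from scipy.optimize import least_squares

        scale = float(np.median(np.linalg.norm(xy - center2d, axis=1)))
        res = least_squares(
            lambda c: _radius_profile_residuals(xy, c),
            center2d, method="lm", xtol=1e-12, ftol=1e-12, max_nfev=200,
        )
        # accept the refinement only if it stayed in the neighbourhood
        if np.all(np.isfinite(res.x)) and np.linalg.norm(res.x - center2d) < scale:
            center2d = res.x

    u, v = _plane_basis(normal)
    center3d = origin + center2d[0] * u + center2d[1] * v
    return SpiralGeometry(center=center3d, plane_normal=normal, plane_origin=origin)


def _angles_about_center(path: LandmarkPath, geometry: SpiralGeometry):
    """Unwrapped in-plane polar angles (radians) of each landmark about A."""
    xy = _project_2d(path.points, geometry.plane_origin, geometry.plane_normal)
    c = _project_2d(geometry.center[None, :], geometry.plane_origin,
                    geometry.plane_normal)[0]
    rel = xy - c
    radii = np.linalg.norm(rel, axis=1)
    if np.any(radii < 1e-12):
        raise UndefinedAngleError("a landmark coincides with the spiral center")
    theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    return theta, radii


def count_turns(path: LandmarkPath, geometry: SpiralGeometry) -> float:
    """Number of turns: |cumulative angular sweep about A| / 360 degrees.

    Full rotations plus the fractional angle between the center-to-apex and
    center-to-base rays; the absolute value makes the count independent of
    winding direction (left vs right cochlea).
    """
    theta, _ = _angles_about_center(path, geometry)
    return float(abs(theta[-1] - theta[0]) / (2.0 * math.pi))


def _turn_radius(theta: np.ndarray, radii: np.ndarray, at: float) -> float:
    """Circle radius for one turn's landmarks, evaluated at the extremity.

    The in-plane distances to A are regressed linearly on the unwrapped
    angle and the fit is read off at the extreme angle ``at``.  For
    landmarks on a true circle the slope vanishes and this is the mean
    distance (the least-squares radius for a fixed center); on a spiral it
    tracks the radius where the turn actually starts instead of averaging
    the drift across the whole turn.
    """
    if theta.size == 1 or np.ptp(theta) == 0.0:
        return float(radii.mean())
    design = np.column_stack([np.ones_like(theta), theta - at])
    coef, *_ = np.linalg.lstsq(design, radii, rcond=None)
    return float(coef[0])


def fit_turn_circles(path: LandmarkPath, geometry: SpiralGeometry) -> tuple[float, float]:
    """Radii (R1, R2) of circles centred on A fitted to the last and first turns.

    The *first* (basal) turn collects landmarks within 360 degrees of angular
    sweep from the basal end; the *last* (apical) turn those within 360
    degrees of the apical end.  Each subset's radius is evaluated at its
    extremity (see :func:`_turn_radius`).  Returns ``(R1, R2)`` with R1 the
    apical (smaller) and R2 the basal (larger) radius.
    """
    theta, radii = _angles_about_center(path, geometry)
    sweep = abs(theta[-1] - theta[0])
    if sweep < 2.0 * math.pi * (1.0 - 1e-6):
        raise InsufficientTurnsError(
            f"path spans only {sweep / (2 * math.pi):.2f} turns; need >= 1"
        )
    # window of one full turn at each end, shrunk so the two subsets cannot
    # overlap on short (1-2 turn) paths
    window = min(2.0 * math.pi, sweep / 2.0) - 1e-9
    rel = np.abs(theta - theta[0])
    rev = np.abs(theta - theta[-1])
    if path.start == "base":
        basal_mask = rel <= window
        apical_mask = rev <= window
    else:  # starts at apex
        apical_mask = rel <= window
        basal_mask = rev <= window
    first_end = theta[0] if path.start == "base" else theta[-1]
    last_end = theta[-1] if path.start == "base" else theta[0]
    r_basal = _turn_radius(theta[basal_mask], radii[basal_mask], first_end)
    r_apical = _turn_radius(theta[apical_mask], radii[apical_mask], last_end)
    if r_basal < r_apical:
        if r_basal >= r_apical * (1.0 - 1e-6):
            r_basal = r_apical = 0.5 * (r_basal + r_apical)  # circle, tied radii
        else:
            raise SingularGeometryError(
                "basal-turn radius smaller than apical-turn radius; check the "
                "declared spiral orientation"
            )
    return r_apical, r_basal


def curvature_gradient(r1: float, r2: float) -> float:
    """CUR = R2 / R1 for the fitted first- and last-turn radii."""
    if r1 <= 0 or r2 <= 0:
        raise InvalidInputError("turn radii must be positive")
    return float(r2) / float(r1)


def _polygon_is_simple(xy: np.ndarray) -> bool:
    """Check the closed polygon for self-intersection (O(n^2) segment test)."""
    n = xy.shape[0]
    segs = [(xy[i], xy[(i + 1) % n]) for i in range(n)]

    def ccw(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue  # shared endpoint with a neighbour
            p1, p2 = segs[i]
            p3, p4 = segs[j]
            d1, d2 = ccw(p3, p4, p1), ccw(p3, p4, p2)
            d3, d4 = ccw(p1, p2, p3), ccw(p1, p2, p4)
            if ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0)):
                return False
    return True


def oval_window_area(outline: LandmarkPath) -> float:
    """Planar (shoelace) area of the outline projected on its best-fit plane."""
    pts = outline.points if isinstance(outline, LandmarkPath) else np.asarray(outline, float)
    if pts.shape[0] < 5:
        raise InvalidInputError("window outline needs at least 5 points")
    origin, normal = best_fit_plane(pts)
    xy = _project_2d(pts, origin, normal)
    # drop a duplicated closing point if present
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    if not _polygon_is_simple(xy):
        raise InvalidOutlineError("projected outline is self-intersecting")
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    return float(area)


def measure_cochlea(
    spiral: LandmarkPath,
    outline: Optional[LandmarkPath] = None,
) -> CochlearMeasurements:
    """Compute all five variables from a spiral path and optional outline.

    RECL is computed from the unrounded ECL and TUR; rounding happens only
    in :meth:`CochlearMeasurements.rounded`.
    """
    ecl = polyline_length(spiral)
    geom = spiral_center(spiral)
    tur = count_turns(spiral, geom)
    r1, r2 = fit_turn_circles(spiral, geom)
    cur = curvature_gradient(r1, r2)
    recl = ecl / tur
    owa = None if outline is None else oval_window_area(outline)
    return CochlearMeasurements(ecl=ecl, tur=tur, cur=cur, recl=recl, owa=owa)


def read_landmark_csv(path, role: str = "spiral", start: Optional[str] = None) -> LandmarkPath:
    """Read an ordered landmark CSV with header ``x,y,z`` (units mm)."""
    import pandas as pd

    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:3] != ["x", "y", "z"]:
        raise InvalidInputError(
            f"{path}: expected header 'x,y,z', got {list(df.columns)!r}"
        )
    return LandmarkPath(df.iloc[:, :3].to_numpy(float), role=role, start=start)
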