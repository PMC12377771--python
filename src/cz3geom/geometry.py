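"""Exact planar polygon geometry and per-compartment shape metrics.

All quantities live in a fixed planar "top view" analysis frame with x to
the right, y up, and physical units of micrometres.  The central object is
the second-moment (shape) tensor of a compartment outline,

    M2 = integral over the compartment of (x - xbar) (x - xbar)^T dA,

whose normalisation ``Sigma = M2 / a`` plays the role of an elastic strain
tensor relative to an isotropic shape: the eigenvalues ``lam_max >= lam_min``
are squared principal stretches, their ratio is the (squared-axis) aspect
ratio, and displacements can be "whitened" by ``Sigma^{-1}`` to measure cell
offsets in shape-adapted, unit-free coordinates.

Everything here is computed in closed form from the polygon vertices
(per-edge shoelace accumulation); nothing is rasterized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import shapely.geometry as sgeom

__all__ = [
    "QHEX",
    "DEGENERACY_RTOL",
    "Polygon2D",
    "MomentSet",
    "FeatureRecord",
    "polygon_moments",
    "shape_descriptors",
    "offset_metrics",
    "voronoi_error",
    "matched_ellipse",
]

#: Isoperimetric quotient q = 4*pi*a / l**2 of a regular hexagon.  Used as the
#: natural offset when correlating circularity against other metrics, because
#: a space-filling mesh of equal hexagons is the most circular tiling possible.
QHEX = math.pi * math.sqrt(3.0) / 6.0

#: Relative eigenvalue-gap tolerance below which the principal axis of a
#: shape tensor is considered undefined (isotropic shape).
DEGENERACY_RTOL = 1e-6

#: Absolute area (um^2) below which a polygon is rejected as degenerate.
_AREA_TOL = 1e-12


class DegeneratePolygonError(ValueError):
    """Polygon has (near-)zero area or is otherwise unusable."""


class SelfIntersectionError(ValueError):
    """Polygon boundary crosses itself."""


@dataclass(frozen=True)
class Polygon2D:
    """A closed simple polygon in the planar analysis frame (um).

    Vertices are stored counter-clockwise without a repeated closing vertex.
    Clockwise input is silently reversed; self-intersecting or degenerate
    input is rejected.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("Polygon2D needs an (n >= 3, 2) vertex array")
        # drop explicit closure
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise DegeneratePolygonError("fewer than 3 distinct vertices")
        sa = _signed_area(v)
        if abs(sa) < _AREA_TOL:
            raise DegeneratePolygonError(f"polygon area {abs(sa):.3e} below tolerance")
        if sa < 0:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)
        ring = sgeom.LinearRing(v)
        if not ring.is_simple:
            raise SelfIntersectionError("polygon boundary self-intersects")

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    def to_shapely(self) -> sgeom.Polygon:
        return sgeom.Polygon(self.vertices)

    @classmethod
    def from_shapely(cls, poly: sgeom.Polygon) -> "Polygon2D":
        return cls(np.asarray(poly.exterior.coords)[:-1])

    def transformed(self, fn) -> "Polygon2D":
        """Apply ``fn: (n,2) -> (n,2)`` to the vertices."""
        return Polygon2D(np.asarray(fn(self.vertices), dtype=float))


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    return 0.5 * float(np.sum(x * yn - xn * y))


@dataclass(frozen=True)
class MomentSet:
    """Area moments of a compartment or cell outline.

    ``sigma = M2 / area`` exactly; ``lam_max >= lam_min`` are the eigenvalues
    of ``sigma`` (um^2) and ``principal_axis`` the unit eigenvector of
    ``lam_max`` (None when the tensor is isotropic to ``DEGENERACY_RTOL``).
    """

    area: float                  # um^2
    centroid: np.ndarray         # (2,) um
    perimeter: float             # um
    M2: np.ndarray               # (2,2) um^4
    sigma: np.ndarray            # (2,2) um^2
    lam_max: float               # um^2
    lam_min: float               # um^2
    principal_axis: Optional[np.ndarray]  # (2,) unit vector or None

    @property
    def axis_defined(self) -> bool:
        return self.principal_axis is not None


def polygon_moments(poly: Polygon2D) -> MomentSet:
    """Exact area, centroid, perimeter and central second moments.

    Uses the closed-form per-edge (shoelace) accumulation for the 0th, 1st
    and 2nd area moments of a simple polygon; the second moments are then
    recentred on the centroid.  The perimeter is the vertex-chain length.
    """
    v = poly.vertices
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y

    a = 0.5 * float(np.sum(cross))
    if a <= _AREA_TOL:
        raise DegeneratePolygonError("polygon area below tolerance")
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)

    # raw second moments about the origin
    ixx = float(np.sum((x * x + x * xn + xn * xn) * cross)) / 12.0
    iyy = float(np.sum((y * y + y * yn + yn * yn) * cross)) / 12.0
    ixy = float(np.sum((x * yn + 2.0 * x * y + 2.0 * xn * yn + xn * y) * cross)) / 24.0
    # parallel-axis shift to the centroid
    m_xx = ixx - a * cx * cx
    m_yy = iyy - a * cy * cy
    m_xy = ixy - a * cx * cy
    M2 = np.array([[m_xx, m_xy], [m_xy, m_yy]])

    perimeter = float(np.sum(np.hypot(xn - x, yn - y)))

    sigma = M2 / a
    lam, vec = np.linalg.eigh(sigma)      # ascending
    lam_min, lam_max = float(max(lam[0], 0.0)), float(max(lam[1], 0.0))
    if lam_max - lam_min < DEGENERACY_RTOL * max(lam_max, _AREA_TOL):
        axis = None
    else:
        axis = vec[:, 1].copy()
        if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
            axis = -axis
    return MomentSet(
        area=a,
        centroid=np.array([cx, cy]),
        perimeter=perimeter,
        M2=M2,
        sigma=sigma,
        lam_max=lam_max,
        lam_min=lam_min,
        principal_axis=axis,
    )


def shape_descriptors(m: MomentSet, *, sqrt_aspect: bool = False) -> dict:
    """Aspect ratio and circularity of a shape.

    ``alpha`` is the eigenvalue ratio ``lam_max/lam_min`` of the normalised
    shape tensor by default; with ``sqrt_aspect=True`` the square root is
    taken instead, giving the major/minor *axis-length* ratio.  ``q`` is the
    isoperimetric quotient ``4*pi*a / l**2``, 1 for a circle and < 1 for any
    other shape.

    Returns ``{"alpha": float, "q": float, "alpha_definition": str}``;
    ``alpha`` is ``inf`` for a degenerate (zero ``lam_min``) tensor.
    """
    if m.lam_min <= DEGENERACY_RTOL * max(m.lam_max, _AREA_TOL):
        alpha = math.inf
    else:
        alpha = m.lam_max / m.lam_min
        if sqrt_aspect:
            alpha = math.sqrt(alpha)
    q = 4.0 * math.pi * m.area / m.perimeter**2
    return {
        "alpha": alpha,
        "q": q,
        "alpha_definition": "sqrt_eigenvalue_ratio" if sqrt_aspect else "eigenvalue_ratio",
    }


def offset_metrics(
    x_cell: np.ndarray,
    m: MomentSet,
    *,
    sqrt_whiten: bool = False,
) -> dict:
    """Cell-centroid offset from the compartment centroid.

    Returns ``dx`` (um pair), ``r = |dx|`` (um), the whitened offset
    ``r_white = dx . Sigma^-1 . dx`` (unitless quadratic form; its square
    root with ``sqrt_whiten=True``) and ``theta_offset``, the acute angle
    between ``dx`` and the principal stretch axis folded into [0, pi/2].
    ``r_white`` is None when Sigma is singular; ``theta_offset`` is None for
    a zero offset or an isotropic shape.
    """
    x_cell = np.asarray(x_cell, dtype=float)
    dx = x_cell - m.centroid
    r = float(np.hypot(*dx))

    r_white: Optional[float]
    if m.lam_min <= DEGENERACY_RTOL * max(m.lam_max, _AREA_TOL):
        r_white = None
    else:
        sol = np.linalg.solve(m.sigma, dx)
        r_white = float(dx @ sol)
        if sqrt_whiten:
            r_white = math.sqrt(r_white)

    theta: Optional[float]
    if r == 0.0 or m.principal_axis is None:
        theta = None
    else:
        cosang = abs(float(dx @ m.principal_axis)) / r
        theta = math.acos(min(1.0, max(-1.0, cosang)))
    return {"dx": dx, "r": r, "r_white": r_white, "theta_offset": theta}


def voronoi_error(compartment: Polygon2D, voronoi_cell: Polygon2D) -> float:
    """Deviation of a compartment from the Voronoi cell of its somatic cell.

    Defined as one minus the intersection-over-union of the two polygons, so
    that 0 means the compartment coincides with the Voronoi reference and the
    value grows toward 1 as the shapes diverge.
    """
    p = compartment.to_shapely()
    q = voronoi_cell.to_shapely()
    union = p.union(q).area
    if union <= 0:
        raise ValueError("empty union of compartment and Voronoi cell")
    iou = p.intersection(q).area / union
    return float(min(1.0, max(0.0, 1.0 - iou)))


def matched_ellipse(
    m: MomentSet, area_scale: float = 1.0, n_vertices: int = 64
) -> Polygon2D:
    """Moment-matched ellipse of a shape, as a discretized polygon.

    The ellipse is centred on the centroid, has its axes along the
    eigenvectors of the shape tensor with semi-axes proportional to
    ``sqrt(lam_max), sqrt(lam_min)``, and is scaled so its area equals
    ``area_scale * area``.  This is the "same aspect ratio, relaxed shape"
    reference used when modelling polygonal compartments rounding up into
    ellipses.
    """
    if area_scale <= 0:
        raise ValueError("area_scale must be positive")
    if m.lam_min <= 0:
        raise DegeneratePolygonError("lam_min must be positive for an ellipse")
    target = area_scale * m.area
    ratio = m.lam_max / m.lam_min          # = (p/q)^2 for semi-axes p >= q
    q_ax = math.sqrt(target / (math.pi * math.sqrt(ratio)))
    p_ax = q_ax * math.sqrt(ratio)
    if m.principal_axis is not None:
        e1 = m.principal_axis
    else:
        e1 = np.array([1.0, 0.0])
    e2 = np.array([-e1[1], e1[0]])
    t = np.linspace(0.0, 2.0 * math.pi, n_vertices, endpoint=False)
    pts = (
        m.centroid[None, :]
        + np.outer(p_ax * np.cos(t), e1)
        + np.outer(q_ax * np.sin(t), e2)
    )
    return Polygon2D(pts)


@dataclass
class FeatureRecord:
    """All per-pair metrics for one somatic cell / compartment pair.

    Areas and lengths in um / um^2; ``alpha``, ``q``, ``r_white`` and ``e_v``
    unitless; ``theta_offset`` in radians in [0, pi/2].  Optional entries are
    None when undefined (degenerate shape tensor, missing Voronoi reference).
    ``flags`` collects quality annotations such as ``boundary`` (compartment
    clipped by the analysis window) or ``ambiguous_pairing``.
    """

    cell_id: int
    a_cell: float
    x_cell: np.ndarray
    a_cz3: float
    x_cz3: np.ndarray
    l_cz3: float
    alpha: float
    q: float
    dx: np.ndarray
    r: float
    r_white: Optional[float]
    theta_offset: Optional[float]
    e_v: Optional[float] = None
    flags: list = field(default_factory=list)

    @classmethod
    def from_polygons(
        cls,
        cell_id: int,
        cell_poly: Polygon2D,
        compartment_poly: Polygon2D,
        voronoi_cell: Optional[Polygon2D] = None,
        *,
        sqrt_aspect: bool = False,
        sqrt_whiten: bool = False,
        flags: Optional[list] = None,
    ) -> "FeatureRecord":
        mc = polygon_moments(cell_poly)
        mz = polygon_moments(compartment_poly)
        sd = shape_descriptors(mz, sqrt_aspect=sqrt_aspect)
        off = offset_metrics(mc.centroid, mz, sqrt_whiten=sqrt_whiten)
        e_v = None
        if voronoi_cell is not None:
            e_v = voronoi_error(compartment_poly, voronoi_cell)
        return cls(
            cell_id=cell_id,
            a_cell=mc.area,
            x_cell=mc.centroid,
            a_cz3=mz.area,
            x_cz3=mz.centroid,
            l_cz3=mz.perimeter,
            alpha=sd["alpha"],
            q=sd["q"],
            dx=off["dx"],
            r=off["r"],
            r_white=off["r_white"],
            theta_offset=off["theta_offset"],
            e_v=e_v,
            flags=list(flags) if flags else [],
        )
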