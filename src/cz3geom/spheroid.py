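"""Organism-level geometry of a spheroid in top view.

Builds on the per-compartment metrics: elliptical outline fitting, the
posterior-anterior (PA) body axis, the reference Voronoi tessellation of the
somatic cell positions, covering fraction, the space-partitioning cost of
the compartment mesh, PA-binned metric profiles, feature correlations, a
pluggable top-view distortion correction, and ECM volume bookkeeping from
stage-mean radii.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import Voronoi
from shapely import STRtree
import shapely.geometry as sgeom
from shapely.ops import unary_union, voronoi_diagram
from skimage.measure import EllipseModel

from .geometry import (
    FeatureRecord,
    MomentSet,
    Polygon2D,
    polygon_moments,
)

__all__ = [
    "SpheroidOutline",
    "SpheroidRecord",
    "SpheroidSummary",
    "PAProfile",
    "fit_outline",
    "estimate_pa_axis",
    "pa_coordinate",
    "pa_profile",
    "planar_voronoi",
    "covering_fraction",
    "partition_cost",
    "neighbor_stats",
    "ecm_volume_estimate",
    "correct_distortion",
    "feature_correlations",
    "summarize_spheroid",
    "features_to_dataframe",
]


@dataclass(frozen=True)
class SpheroidOutline:
    """Best-fit ellipse of the spheroid boundary in top view (um).

    ``circular_radius`` is the geometric mean of the semi-axes and
    ``aspect`` their ratio (>= 1).
    """

    center: np.ndarray
    semi_major: float
    semi_minor: float
    orientation: float  # radians, direction of the major axis

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise ValueError("need semi_major >= semi_minor > 0")

    @property
    def circular_radius(self) -> float:
        return math.sqrt(self.semi_major * self.semi_minor)

    @property
    def aspect(self) -> float:
        return self.semi_major / self.semi_minor

    def extent_along(self, direction: np.ndarray) -> float:
        """Half-extent of the ellipse along a unit direction."""
        d = np.asarray(direction, dtype=float)
        e1 = np.array([math.cos(self.orientation), math.sin(self.orientation)])
        e2 = np.array([-e1[1], e1[0]])
        return math.hypot(self.semi_major * float(d @ e1),
                          self.semi_minor * float(d @ e2))

    def to_polygon(self, n_vertices: int = 128) -> Polygon2D:
        t = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
        e1 = np.array([math.cos(self.orientation), math.sin(self.orientation)])
        e2 = np.array([-e1[1], e1[0]])
        pts = (self.center[None, :]
               + np.outer(self.semi_major * np.cos(t), e1)
               + np.outer(self.semi_minor * np.sin(t), e2))
        return Polygon2D(pts)


@dataclass
class SpheroidRecord:
    """One spheroid's top-view data: outline, PA axis and paired features.

    ``pa_axis`` is a unit vector pointing anterior; ``features`` align with
    the optional per-pair polygon lists when those are present.
    """

    stage: str
    outline: SpheroidOutline
    pa_axis: Optional[np.ndarray] = None
    features: list = field(default_factory=list)
    offspring_centroids: Optional[np.ndarray] = None
    compartment_polys: Optional[list] = None
    cell_polys: Optional[list] = None
    pixel_size: Optional[float] = None
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class SpheroidSummary:
    """Per-spheroid aggregate metrics (one row of the stage-level tables)."""

    stage: str
    n_features: int
    k_alpha: Optional[float]
    k_area: Optional[float]
    partition_cost: float
    median_e_v: Optional[float]
    circular_radius: float
    spheroid_aspect: float
    covering_fraction: Optional[float]


@dataclass(frozen=True)
class PAProfile:
    """Binned means/SDs of one metric along the normalized PA coordinate."""

    metric: str
    edges: np.ndarray       # n_bins + 1 edges in [0, 1]
    mean: np.ndarray
    sd: np.ndarray
    count: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def empty_bins(self) -> np.ndarray:
        return self.count == 0


def fit_outline(boundary_points: np.ndarray) -> SpheroidOutline:
    """Least-squares ellipse through boundary points (direct algebraic fit)."""
    pts = np.asarray(boundary_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 6:
        raise ValueError("need >= 6 boundary points")
    # collinearity check via PCA
    s = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise ValueError("boundary points are collinear")
    model = EllipseModel.from_estimate(pts)
    if not model:
        raise ValueError("ellipse fit failed")
    (xc, yc), (a, b), theta = model.center, model.axis_lengths, model.theta
    if b > a:
        a, b = b, a
        theta += math.pi / 2
    theta = math.atan2(math.sin(theta), math.cos(theta))
    if theta <= -math.pi / 2:
        theta += math.pi
    elif theta > math.pi / 2:
        theta -= math.pi
    return SpheroidOutline(center=np.array([xc, yc]), semi_major=float(a),
                           semi_minor=float(b), orientation=float(theta))


def estimate_pa_axis(
    outline: SpheroidOutline,
    offspring_centroids: Optional[np.ndarray] = None,
    mode: str = "offspring_normal",
) -> np.ndarray:
    """Posterior-anterior axis as a unit vector through the outline center.

    ``offspring_normal`` takes the normal to the total-least-squares line
    through the offspring centroids (the offspring lie roughly on a line
    transverse to the PA axis); the anterior sign points away from their
    centre of mass.  ``major_axis`` falls back to the elliptical major axis,
    which approximates the PA axis well in practice.
    """
    if mode not in ("offspring_normal", "major_axis"):
        raise ValueError(f"unknown PA mode {mode!r}")
    if mode == "offspring_normal":
        pts = None if offspring_centroids is None else np.asarray(
            offspring_centroids, dtype=float)
        if pts is None or pts.shape[0] < 2:
            warnings.warn("fewer than 2 offspring; falling back to major_axis")
            mode = "major_axis"
        else:
            com = pts.mean(axis=0)
            # TLS line direction = leading right-singular vector
            _, _, vt = np.linalg.svd(pts - com)
            line_dir = vt[0]
            axis = np.array([-line_dir[1], line_dir[0]])
            # anterior points away from the offspring centre of mass
            if float(axis @ (com - outline.center)) > 0:
                axis = -axis
            return axis / np.linalg.norm(axis)
    axis = np.array([math.cos(outline.orientation), math.sin(outline.orientation)])
    if offspring_centroids is not None and len(offspring_centroids) > 0:
        com = np.asarray(offspring_centroids, dtype=float).mean(axis=0)
        if float(axis @ (com - outline.center)) > 0:
            axis = -axis
    return axis


def pa_coordinate(rec: SpheroidRecord, points: np.ndarray) -> np.ndarray:
    """Normalized PA coordinate in [0, 1] (0 = posterior, 1 = anterior)."""
    if rec.pa_axis is None:
        raise ValueError("record has no PA axis")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    proj = (pts - rec.outline.center[None, :]) @ rec.pa_axis
    h = rec.outline.extent_along(rec.pa_axis)
    return np.clip((proj / h + 1.0) / 2.0, 0.0, 1.0)


def pa_profile(
    rec: SpheroidRecord,
    metric: str,
    n_bins: int = 8,
    *,
    include_flagged: bool = False,
) -> PAProfile:
    """Per-bin mean/SD of a feature metric along the PA axis.

    Compartments are assigned by the PA coordinate of their centroid into
    ``n_bins`` equal segments of [0, 1].  Boundary-flagged compartments are
    excluded by default (clipping biases their shape metrics).
    """
    feats = [f for f in rec.features
             if include_flagged or "boundary" not in f.flags]
    if not feats:
        raise ValueError("no usable features")
    if not hasattr(feats[0], metric):
        raise ValueError(f"metric {metric!r} not in FeatureRecord")
    vals = np.array([getattr(f, metric) if getattr(f, metric) is not None
                     else np.nan for f in feats], dtype=float)
    cents = np.array([f.x_cz3 for f in feats])
    u = pa_coordinate(rec, cents)
    keep = np.isfinite(vals)
    vals, u = vals[keep], u[keep]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(u, edges) - 1, 0, n_bins - 1)
    mean = np.full(n_bins, np.nan)
    sd = np.full(n_bins, np.nan)
    count = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        count[b] = int(sel.sum())
        if count[b]:
            mean[b] = float(np.mean(vals[sel]))
            sd[b] = float(np.std(vals[sel], ddof=1)) if count[b] > 1 else 0.0
    return PAProfile(metric=metric, edges=edges, mean=mean, sd=sd, count=count)


def planar_voronoi(
    cell_centroids: np.ndarray, clip_region: Polygon2D
) -> list[Polygon2D]:
    """Voronoi cells of the cell positions, clipped to a window polygon.

    The cells tile the window exactly (up to floating-point clipping) and
    the i-th output corresponds to the i-th input centroid.
    """
    pts = np.asarray(cell_centroids, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need >= 2 centroids")
    if len(np.unique(pts.round(9), axis=0)) != len(pts):
        raise ValueError("duplicate centroids")
    window = clip_region.to_shapely()
    if pts.shape[0] == 2:
        return _bisector_split(pts, window)
    mp = sgeom.MultiPoint([sgeom.Point(p) for p in pts])
    # generous envelope so every finite cell covers the window before clipping
    env = window.buffer(4.0 * math.sqrt(window.area)).envelope
    cells = voronoi_diagram(mp, envelope=env)
    tree = STRtree(list(cells.geoms))
    out: list[Optional[Polygon2D]] = [None] * len(pts)
    for i, p in enumerate(pts):
        hits = tree.query(sgeom.Point(p), predicate="intersects")
        best, best_d = None, math.inf
        for h in hits:
            g = cells.geoms[int(h)]
            d = g.centroid.distance(sgeom.Point(p))
            if g.covers(sgeom.Point(p)) and d < best_d:
                best, best_d = g, d
        if best is None:
            raise RuntimeError(f"no Voronoi cell found for centroid {i}")
        clipped = best.intersection(window)
        if clipped.is_empty or clipped.area <= 0:
            raise RuntimeError(f"centroid {i} has empty clipped cell")
        if clipped.geom_type == "MultiPolygon":
            clipped = max(clipped.geoms, key=lambda g: g.area)
        out[i] = Polygon2D.from_shapely(clipped)
    return out  # type: ignore[return-value]


def _bisector_split(pts: np.ndarray, window) -> list[Polygon2D]:
    """Two-generator Voronoi: cut the window along the perpendicular bisector."""
    from shapely.ops import split as shp_split

    mid = pts.mean(axis=0)
    d = pts[1] - pts[0]
    n = np.array([-d[1], d[0]])
    n = n / np.linalg.norm(n)
    span = 10.0 * math.sqrt(window.area) + float(np.abs(pts).max())
    line = sgeom.LineString([mid - span * n, mid + span * n])
    pieces = shp_split(window, line)
    out: list[Optional[Polygon2D]] = [None, None]
    for g in pieces.geoms:
        rp = g.representative_point()
        i = int(np.argmin([rp.distance(sgeom.Point(p)) for p in pts]))
        if out[i] is None:
            out[i] = Polygon2D.from_shapely(g)
    if any(o is None for o in out):
        raise RuntimeError("bisector split failed to assign both cells")
    return out  # type: ignore[return-value]


def covering_fraction(
    compartments: Sequence[Polygon2D], window: Polygon2D
) -> float:
    """Fraction of the window area covered by the union of compartments."""
    if not compartments:
        raise ValueError("empty compartment list")
    w = window.to_shapely()
    union = unary_union([c.to_shapely() for c in compartments])
    return float(union.intersection(w).area / w.area)


def partition_cost(
    moments: Sequence[MomentSet], *, denominator: str = "sum_sq"
) -> float:
    """Space-partitioning cost of a compartment configuration.

    ``n * sum_i Tr(M2_i) / (sum_i a_i)**2`` — a scale- and n-invariant
    disorder readout, minimized (at value 5*sqrt(3)/54) by meshes of equal
    regular hexagons, equal to 1/6 on any square tiling, and bounded below
    by 1/(2*pi) (the value for a single disc).  ``denominator="sq_sum"``
    selects the non-invariant variant ``n * sum Tr(M2) / sum(a_i**2)`` for
    sensitivity analysis.
    """
    if not moments:
        raise ValueError("need >= 1 compartment")
    tr = sum(float(np.trace(m.M2)) for m in moments)
    areas = np.array([m.area for m in moments])
    n = len(moments)
    if denominator == "sum_sq":
        return n * tr / float(np.sum(areas)) ** 2
    if denominator == "sq_sum":
        return n * tr / float(np.sum(areas**2))
    raise ValueError(f"unknown denominator {denominator!r}")


def neighbor_stats(
    items, *, clip_region: Optional[Polygon2D] = None, contact_tol: float = 1e-6
) -> dict:
    """Contact counts and the polygon-class (pentagon/hexagon) histogram.

    With point input, adjacency comes from shared Voronoi ridges (cells whose
    regions share an edge); interior points are those whose Voronoi cell is
    bounded and, when ``clip_region`` is given, clear of its boundary.  With
    polygon input, two compartments are neighbors when their boundaries come
    within ``contact_tol``.
    """
    pts = np.asarray(items, dtype=float) if not isinstance(items[0], Polygon2D) else None
    n = len(items)
    counts = np.zeros(n, dtype=int)
    interior = np.ones(n, dtype=bool)
    if pts is not None:
        vor = Voronoi(pts)
        for i, j in vor.ridge_points:
            counts[i] += 1
            counts[j] += 1
        for i, reg in enumerate(vor.point_region):
            verts = vor.regions[reg]
            if -1 in verts or len(verts) == 0:
                interior[i] = False
            elif clip_region is not None:
                cell = sgeom.Polygon(vor.vertices[verts])
                if not clip_region.to_shapely().contains(cell):
                    interior[i] = False
    else:
        shp = [p.to_shapely() for p in items]
        tree = STRtree(shp)
        for i, g in enumerate(shp):
            hits = tree.query(g, predicate="dwithin", distance=contact_tol)
            counts[i] = sum(1 for h in hits if int(h) != i)
        if clip_region is not None:
            boundary = clip_region.to_shapely().exterior
            for i, g in enumerate(shp):
                if g.distance(boundary) < contact_tol:
                    interior[i] = False
    interior_counts = counts[interior]
    hist: dict[int, int] = {}
    for c in interior_counts:
        hist[int(c)] = hist.get(int(c), 0) + 1
    n5, n6 = hist.get(5, 0), hist.get(6, 0)
    return {
        "counts": counts,
        "interior": interior,
        "histogram": hist,
        "mean_interior_neighbors": (
            float(np.mean(interior_counts)) if interior_counts.size else math.nan),
        "pentagon_hexagon_ratio": (n5 / n6) if n6 else math.nan,
    }


_UM3_PER_MM3 = 1e9


def ecm_volume_estimate(
    r_parent: float,
    r_offspring: float,
    n_offspring: int,
    r_cell: float,
    n_cell: int,
) -> float:
    """Estimated parental ECM volume in mm^3 from stage-mean radii in um.

    Spheroid volume minus the estimated volume of its offspring and somatic
    cells, all treated as spheres:
    ``V = (4/3) pi (R^3 - n_o r_o^3 - n_c r_c^3)``.
    """
    if min(r_parent, r_offspring, r_cell) <= 0:
        raise ValueError("radii must be positive")
    if min(n_offspring, n_cell) < 0:
        raise ValueError("counts must be non-negative")
    v_um3 = (4.0 / 3.0) * math.pi * (
        r_parent**3 - n_offspring * r_offspring**3 - n_cell * r_cell**3)
    if v_um3 < 0:
        raise ValueError("inconsistent inputs: negative ECM volume")
    return v_um3 / _UM3_PER_MM3


class IdentityDistortion:
    """No-op distortion model."""

    name = "identity"

    def transform(self, vertices, center, anchor=None) -> np.ndarray:
        return np.asarray(vertices, dtype=float)


class OrthographicSphereDistortion:
    """Undo the orthographic foreshortening of a sphere seen in top view.

    A feature at planar distance rho from the spheroid centre sits at polar
    angle theta with cos(theta) = sqrt(1 - (rho/R)^2); the orthographic
    projection compresses radial lengths by cos(theta) while leaving
    tangential lengths unchanged.  Each compartment is corrected in the
    locally isometric tangent frame anchored at its centroid: radial
    in-plane components are stretched by 1/cos(theta) and the anchor is
    moved out to its arc-length radius R*arcsin(rho/R).  Vertices with
    rho >= R cannot be deprojected and mark the compartment for exclusion.
    """

    name = "orthographic_sphere"

    def __init__(self, radius: float):
        if radius <= 0:
            raise ValueError("sphere radius must be positive")
        self.radius = float(radius)

    def transform(
        self,
        vertices: np.ndarray,
        center: np.ndarray,
        anchor: Optional[np.ndarray] = None,
    ) -> np.ndarray:
        v = np.asarray(vertices, dtype=float)
        R = self.radius
        if anchor is None:
            anchor = v.mean(axis=0)
        rel = np.asarray(anchor, dtype=float) - center
        rho0 = float(np.hypot(*rel))
        if rho0 >= R or np.any(np.hypot(*(v - center).T) >= R):
            raise ValueError("vertex at or beyond the sphere silhouette")
        if rho0 < 1e-12:
            return v.copy()
        cos_t = math.sqrt(1.0 - (rho0 / R) ** 2)
        e_r = rel / rho0
        e_t = np.array([-e_r[1], e_r[0]])
        local = v - center - rel
        rad = local @ e_r
        tan = local @ e_t
        new_anchor = e_r * (R * math.asin(rho0 / R))
        return (center + new_anchor[None, :]
                + np.outer(rad / cos_t, e_r) + np.outer(tan, e_t))


def _resolve_model(model):
    if isinstance(model, str):
        if model == "identity":
            return IdentityDistortion()
        raise ValueError(
            f"model {model!r} needs parameters; pass a model instance")
    return model


def correct_distortion(rec: SpheroidRecord, model) -> SpheroidRecord:
    """Recompute a record's features from distortion-corrected polygons.

    ``model`` is ``"identity"``, an :class:`IdentityDistortion` or an
    :class:`OrthographicSphereDistortion` (or any object with a matching
    ``transform(vertices, center)`` method).  Features are recomputed from
    the transformed cell/compartment polygons — never rescaled post hoc —
    so the record must carry its polygons.  Compartments the model cannot
    deproject are dropped with a warning.
    """
    model = _resolve_model(model)
    if isinstance(model, IdentityDistortion):
        return rec
    if rec.compartment_polys is None or rec.cell_polys is None:
        raise ValueError("record lacks polygons; cannot correct distortion")
    center = rec.outline.center
    new_feats, new_comp, new_cell = [], [], []
    for f, comp, cell in zip(rec.features, rec.compartment_polys, rec.cell_polys):
        try:
            anchor = comp.vertices.mean(axis=0)
            cv = model.transform(comp.vertices, center, anchor)
            # the cell shares its compartment's tangent frame
            lv = model.transform(cell.vertices, center, anchor)
        except ValueError:
            warnings.warn(f"compartment {f.cell_id} beyond silhouette; excluded")
            continue
        comp2, cell2 = Polygon2D(cv), Polygon2D(lv)
        f2 = FeatureRecord.from_polygons(f.cell_id, cell2, comp2,
                                         flags=list(f.flags))
        f2.e_v = None  # Voronoi reference must be rebuilt downstream
        new_feats.append(f2)
        new_comp.append(comp2)
        new_cell.append(cell2)
    return replace(rec, features=new_feats, compartment_polys=new_comp,
                   cell_polys=new_cell,
                   meta={**rec.meta, "distortion_model": model.name})


def features_to_dataframe(features: Sequence[FeatureRecord]) -> pd.DataFrame:
    """Flatten FeatureRecords into a tidy table (one row per pair)."""
    rows = []
    for f in features:
        rows.append({
            "cell_id": f.cell_id,
            "a_cell": f.a_cell,
            "x_cell_x": f.x_cell[0], "x_cell_y": f.x_cell[1],
            "a_cz3": f.a_cz3,
            "x_cz3_x": f.x_cz3[0], "x_cz3_y": f.x_cz3[1],
            "l_cz3": f.l_cz3,
            "alpha": f.alpha, "q": f.q,
            "dx_x": f.dx[0], "dx_y": f.dx[1],
            "r": f.r,
            "r_white": np.nan if f.r_white is None else f.r_white,
            "theta_offset": np.nan if f.theta_offset is None else f.theta_offset,
            "e_v": np.nan if f.e_v is None else f.e_v,
            "flags": ";".join(f.flags),
        })
    return pd.DataFrame(rows)


def feature_correlations(
    features, specs: Sequence[dict]
) -> pd.DataFrame:
    """Ordinary least-squares fits between transformed feature pairs.

    Each spec names an ``x`` and ``y`` column plus optional per-axis
    ``transform`` ("linear" or "log") and additive ``offset`` applied before
    the transform (e.g. ``q - qhex`` or ``alpha - 1``).  Non-finite rows
    after transformation are dropped and counted.
    """
    df = features if isinstance(features, pd.DataFrame) else \
        features_to_dataframe(features)
    rows = []
    for spec in specs:
        x = df[spec["x"]].to_numpy(dtype=float) - spec.get("x_offset", 0.0)
        y = df[spec["y"]].to_numpy(dtype=float) - spec.get("y_offset", 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            if spec.get("x_transform", "linear") == "log":
                x = np.log(x)
            if spec.get("y_transform", "linear") == "log":
                y = np.log(y)
        keep = np.isfinite(x) & np.isfinite(y)
        n_dropped = int((~keep).sum())
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError(
                f"fewer than 3 finite pairs for {spec['x']} vs {spec['y']}")
        res = stats.linregress(x, y)
        rows.append({
            "x": spec["x"], "y": spec["y"],
            "x_transform": spec.get("x_transform", "linear"),
            "y_transform": spec.get("y_transform", "linear"),
            "x_offset": spec.get("x_offset", 0.0),
            "y_offset": spec.get("y_offset", 0.0),
            "slope": float(res.slope), "intercept": float(res.intercept),
            "r2": float(res.rvalue**2), "n": int(x.size),
            "n_dropped": n_dropped,
        })
    return pd.DataFrame(rows)


def summarize_spheroid(
    rec: SpheroidRecord,
    *,
    window: Optional[Polygon2D] = None,
    include_flagged: bool = False,
) -> SpheroidSummary:
    """Per-spheroid aggregates: gamma shapes, partition cost, median e_V, phi.

    Gamma shapes are fitted to standardized aspect ratios (alpha - 1, then
    mean-scaled) and mean-scaled compartment areas of unflagged compartments.
    The covering fraction uses *all* compartments against ``window`` (by
    default the outline ellipse) since clipping does not bias areas there.
    """
    from .distributions import fit_gamma_mle, standardize

    feats = [f for f in rec.features
             if include_flagged or "boundary" not in f.flags]
    if not feats:
        raise ValueError("no usable features")
    alphas = np.array([f.alpha for f in feats if np.isfinite(f.alpha)])
    areas = np.array([f.a_cz3 for f in feats])

    def _k(vals, mode, x0=0.0):
        try:
            std, _ = standardize(vals, mode=mode, x0=x0)
            return fit_gamma_mle(std).k
        except (ValueError, RuntimeError):
            return None

    k_alpha = _k(alphas, "offset_then_scale", x0=1.0)
    k_area = _k(areas, "mean_scale")

    cost = math.nan
    if rec.compartment_polys is not None:
        moments = [polygon_moments(p) for p, f in
                   zip(rec.compartment_polys, rec.features)
                   if include_flagged or "boundary" not in f.flags]
        if moments:
            cost = partition_cost(moments)

    evs = np.array([f.e_v for f in feats if f.e_v is not None], dtype=float)
    median_ev = float(np.median(evs)) if evs.size else None

    phi = None
    if rec.compartment_polys is not None:
        win = window if window is not None else rec.outline.to_polygon()
        phi = covering_fraction(rec.compartment_polys, win)

    return SpheroidSummary(
        stage=rec.stage,
        n_features=len(feats),
        k_alpha=k_alpha,
        k_area=k_area,
        partition_cost=cost,
        median_e_v=median_ev,
        circular_radius=rec.outline.circular_radius,
        spheroid_aspect=rec.outline.aspect,
        covering_fraction=phi,
    )
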