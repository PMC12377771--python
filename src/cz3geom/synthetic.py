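"""Synthetic top-view spheroid configurations with full ground truth.

The generator emulates, phenomenologically, the statistical structure of
the somatic compartment mesh seen in top view: a near-space-filling
Voronoi-like partition of a disc; gamma-distributed compartment areas whose
polydispersity is set by lattice jitter; a stable aspect-ratio distribution
(mean around 1.2); "acircular relaxation" of polygonal cells toward their
moment-matched ellipses at fixed aspect ratio, which opens
extracompartmental space and lowers the covering fraction; somatic cell
offsets scaling as sqrt(area) with a uniformly random direction; and an
anterior-ward compartment-area gradient along the body (PA) axis.

Stage presets I, II, III, IV and S bundle parameter sets whose pipeline
readouts follow the observed trends (covering fraction near 1 early and
near 0.81 in stage IV; mean aspect ratio ~1.2 at every stage; area
polydispersity growing with stage).  Every stochastic step is driven by a
single explicit seed; identical configurations produce identical polygons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import shapely
import shapely.geometry as sgeom

from .geometry import Polygon2D, matched_ellipse, polygon_moments
from .spheroid import (
    SpheroidOutline,
    SpheroidRecord,
    planar_voronoi,
)

__all__ = [
    "SynthConfig",
    "SyntheticSpheroid",
    "sample_cell_centers",
    "build_compartments",
    "relax_compartments",
    "place_cells",
    "stage_preset",
    "generate",
    "render_label_masks",
    "STAGE_PRESETS",
]


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; all lengths in um.

    ``lattice_sigma`` is the lattice jitter as a fraction of the lattice
    spacing (controls area polydispersity, hence the fitted gamma shape k);
    ``pa_gradient`` the fractional posterior->anterior area increase;
    ``relaxation`` the morph fraction toward the moment-matched ellipse;
    ``shrink`` the linear scale of that target ellipse (covering fraction
    tends to ``shrink**2`` at full relaxation); ``offset_coeff`` sets the
    cell offset law r = offset_coeff * sqrt(a) * |N(0,1)|.
    """

    n_cells: int = 600
    window_radius: float = 220.0
    seed: int = 0
    lattice_sigma: float = 0.18
    pa_gradient: float = 0.6
    relaxation: float = 0.2
    shrink: float = 1.0
    offset_coeff: float = 0.10
    cell_radius: float = 3.9
    wall_thickness: float = 1.6
    target_k: Optional[float] = None
    stage: str = "custom"

    def __post_init__(self):
        if self.n_cells < 10:
            raise ValueError("n_cells must be >= 10")
        if not (0.0 <= self.relaxation <= 1.0):
            raise ValueError("relaxation must be in [0, 1]")
        if not (0.0 < self.shrink <= 1.0):
            raise ValueError("shrink must be in (0, 1]")
        if self.lattice_sigma < 0 or self.offset_coeff < 0:
            raise ValueError("lattice_sigma and offset_coeff must be >= 0")
        if self.pa_gradient < 0:
            raise ValueError("pa_gradient must be >= 0")
        if self.target_k is not None and self.target_k <= 0:
            raise ValueError("target_k must be positive")


#: Stage presets.  Jitter, relaxation and shrink increase with stage so that
#: area polydispersity rises (fitted k falls), compartments become more
#: elliptical (Voronoi error rises) and the covering fraction drops toward
#: ~0.81 by stage IV, while the jitter is kept in the range that leaves the
#: mean aspect ratio near 1.2 at every stage.  Window radii and cell radii
#: follow the stage-mean spheroid and somatic cell sizes; the PA area
#: gradient grows from ~44% to ~130% across the vegetative life cycle.
STAGE_PRESETS: dict[str, dict] = {
    "I": dict(window_radius=106.0, lattice_sigma=0.05, pa_gradient=0.44,
              relaxation=0.05, shrink=1.0, cell_radius=2.8,
              wall_thickness=1.6),
    "II": dict(window_radius=221.0, lattice_sigma=0.06, pa_gradient=0.60,
               relaxation=0.20, shrink=0.995, cell_radius=3.9,
               wall_thickness=1.6),
    "III": dict(window_radius=244.0, lattice_sigma=0.07, pa_gradient=0.80,
                relaxation=0.50, shrink=0.97, cell_radius=4.0,
                wall_thickness=1.7),
    "IV": dict(window_radius=422.0, lattice_sigma=0.085, pa_gradient=1.30,
               relaxation=1.00, shrink=0.92, cell_radius=4.2,
               wall_thickness=1.9),
    "S": dict(window_radius=265.0, lattice_sigma=0.065, pa_gradient=0.60,
              relaxation=0.40, shrink=0.97, cell_radius=4.1,
              wall_thickness=1.7),
}


def stage_preset(name: str, *, seed: int = 0, n_cells: int = 600) -> SynthConfig:
    """Named parameter set for one life-cycle stage (I, II, III, IV, S)."""
    if name not in STAGE_PRESETS:
        raise ValueError(f"unknown stage preset {name!r}")
    return SynthConfig(n_cells=n_cells, seed=seed, stage=name,
                       **STAGE_PRESETS[name])


@dataclass
class SyntheticSpheroid:
    """A generated configuration plus its ground truth.

    ``record`` is the analysis-ready SpheroidRecord (without extracted
    features); ``truth`` carries the per-compartment generator-side values
    computed exactly from the generated polygons.
    """

    config: SynthConfig
    record: SpheroidRecord
    compartments: list            # relaxed compartment polygons
    voronoi_cells: list           # parent Voronoi polygons
    cell_centroids: np.ndarray
    cell_polys: list
    boundary_flags: np.ndarray    # True where the Voronoi cell touches the rim
    truth: "np.recarray"


def _window_polygon(radius: float, n: int = 256) -> Polygon2D:
    t = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return Polygon2D(np.column_stack([radius * np.cos(t), radius * np.sin(t)]))


def sample_cell_centers(cfg: SynthConfig) -> np.ndarray:
    """Jittered triangular-lattice points in the disc window.

    The lattice is first laid out uniformly, then the coordinate along the
    PA axis (+y is anterior) is remapped so the local point density falls as
    1/(1 + c*u) with u the normalized PA coordinate — downstream Voronoi
    areas then grow anteriorly by the factor (1 + c).  Jitter is isotropic
    Gaussian with SD ``lattice_sigma`` times the lattice spacing.
    """
    rng = np.random.default_rng(cfg.seed)
    Rw = cfg.window_radius
    # spacing for a triangular lattice slightly denser than the target so the
    # window always holds n_cells after jitter; the excess is shed from the rim
    spacing = math.sqrt(
        2.0 * math.pi * Rw**2 / (math.sqrt(3.0) * 1.10 * cfg.n_cells))
    m = int(math.ceil(2.2 * Rw / spacing)) + 2
    i = np.arange(-m, m + 1)
    j = np.arange(-m, m + 1)
    ii, jj = np.meshgrid(i, j, indexing="ij")
    x = (jj + 0.5 * (ii % 2)) * spacing
    y = ii * (math.sqrt(3.0) / 2.0) * spacing
    pts = np.column_stack([x.ravel(), y.ravel()])
    pts = pts + rng.normal(scale=cfg.lattice_sigma * spacing, size=pts.shape)

    if cfg.pa_gradient > 0:
        pts = _apply_pa_stretch(pts, Rw, cfg.pa_gradient)

    r = np.hypot(pts[:, 0], pts[:, 1])
    inside = pts[r < Rw]
    if inside.shape[0] < cfg.n_cells:
        raise ValueError("infeasible density: lattice does not fill window")
    # deterministically keep the n_cells points closest to the centre-biased
    # order: sort by radius then angle for reproducibility
    order = np.lexsort((np.arctan2(inside[:, 1], inside[:, 0]),
                        np.hypot(inside[:, 0], inside[:, 1])))
    pts = inside[order][: cfg.n_cells]
    if cfg.target_k is not None:
        # Approximate polydispersity dial: replace a fraction of lattice
        # points with uniform (Poisson) points.  Poisson-Voronoi areas are
        # gamma with shape ~3.6, so the replaced fraction interpolates the
        # fitted k between the lattice's (large) and ~3.6; the mapping is
        # monotone, not exact.
        frac = min(1.0, 3.6 / cfg.target_k)
        n_swap = int(round(frac * cfg.n_cells))
        if n_swap > 0:
            idx = rng.choice(cfg.n_cells, size=n_swap, replace=False)
            rad = Rw * np.sqrt(rng.uniform(size=n_swap))
            ang = rng.uniform(0.0, 2.0 * math.pi, size=n_swap)
            pts = pts.copy()
            pts[idx] = np.column_stack([rad * np.cos(ang), rad * np.sin(ang)])
    return pts


def _apply_pa_stretch(pts: np.ndarray, Rw: float, c: float) -> np.ndarray:
    """Thin the lattice anteriorly with a *locally isotropic* (conformal) map.

    The exponential map ``zeta -> (1/k) (exp(k zeta) - 1)`` (zeta = (y+ix)/Rw,
    PA along the real axis) is locally a similarity, so Voronoi cells stay as
    round as the unmapped lattice's; its area scale e^(2k y/Rw) makes local
    point density fall — and downstream compartment areas grow — by the
    factor (1 + c) from the posterior to the anterior rim (k = log(1+c)/4).
    """
    k = 0.25 * math.log1p(c)
    zeta = (pts[:, 1] + 1j * pts[:, 0]) / Rw
    w = (Rw / k) * (np.exp(k * zeta) - 1.0)
    return np.column_stack([w.imag, w.real])


def build_compartments(
    centroids: np.ndarray, window: Polygon2D
) -> tuple[list, np.ndarray]:
    """Voronoi partition of the window; returns (cells, boundary_flags)."""
    cells = planar_voronoi(centroids, window)
    rim = window.to_shapely().exterior
    flags = np.array([c.to_shapely().distance(rim) < 1e-9 for c in cells])
    return cells, flags


def relax_compartments(
    polys: list, gamma: float, s: float = 1.0, *, densify: float = 0.35
) -> list:
    """Morph each polygon toward its moment-matched ellipse of area s^2*a.

    Vertices (after densifying long edges so the gamma=1 limit is a smooth
    ellipse) move along rays from the centroid: at fraction ``gamma`` of the
    way from the polygon boundary to the ellipse boundary.  Aspect ratio is
    preserved by construction of the target ellipse; circularity rises with
    ``gamma`` and the area falls toward s^2*a.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must be in [0, 1]")
    if not (0.0 < s <= 1.0):
        raise ValueError("s must be in (0, 1]")
    if gamma == 0.0 and s == 1.0:
        return list(polys)
    out = []
    for poly in polys:
        m = polygon_moments(poly)
        scale = math.sqrt(m.area)
        dens = shapely.segmentize(poly.to_shapely(), densify * scale)
        v = np.asarray(dens.exterior.coords)[:-1]
        rel = v - m.centroid[None, :]
        radii = np.hypot(rel[:, 0], rel[:, 1])
        ang = np.arctan2(rel[:, 1], rel[:, 0])
        star_ok = np.all(radii > 0)
        r_ell = _ellipse_radius(m, ang, s)
        if star_ok:
            new_r = (1.0 - gamma) * radii + gamma * r_ell
            new_v = m.centroid[None, :] + np.column_stack(
                [new_r * np.cos(ang), new_r * np.sin(ang)])
        else:  # degenerate ray: interpolate boundary points directly
            ell = matched_ellipse(m, area_scale=s * s, n_vertices=len(v))
            new_v = (1.0 - gamma) * v + gamma * ell.vertices
        out.append(Polygon2D(new_v))
    return out


def _ellipse_radius(m, angles: np.ndarray, s: float) -> np.ndarray:
    """Radius of the moment-matched ellipse (area s^2*a) at polar angles."""
    ratio = m.lam_max / max(m.lam_min, 1e-300)
    target = s * s * m.area
    q_ax = math.sqrt(target / (math.pi * math.sqrt(ratio)))
    p_ax = q_ax * math.sqrt(ratio)
    e1 = m.principal_axis if m.principal_axis is not None else np.array([1.0, 0.0])
    phi0 = math.atan2(e1[1], e1[0])
    a_loc = angles - phi0
    return (p_ax * q_ax) / np.sqrt(
        (q_ax * np.cos(a_loc)) ** 2 + (p_ax * np.sin(a_loc)) ** 2)


def place_cells(
    polys: list, cfg: SynthConfig, rng: Optional[np.random.Generator] = None
) -> tuple[np.ndarray, list, np.ndarray]:
    """Somatic cell centroids and disc outlines inside each compartment.

    The offset from the compartment centroid has magnitude
    ``offset_coeff * sqrt(area) * |N(0,1)|`` and a uniform direction,
    rejection-resampled until the centroid falls inside the compartment
    (after 100 failures the cell sits at the centroid, flagged).  Returns
    (centroids, cell polygons, at_centroid_flags).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    cents, cells, flagged = [], [], []
    t = np.linspace(0, 2 * math.pi, 32, endpoint=False)
    circ = np.column_stack([np.cos(t), np.sin(t)])
    for poly in polys:
        m = polygon_moments(poly)
        shp = poly.to_shapely()
        placed = None
        for _ in range(100):
            r = cfg.offset_coeff * math.sqrt(m.area) * abs(rng.normal())
            psi = rng.uniform(0.0, 2.0 * math.pi)
            cand = m.centroid + r * np.array([math.cos(psi), math.sin(psi)])
            if shp.contains(sgeom.Point(cand)):
                placed = cand
                break
        if placed is None:
            placed = m.centroid.copy()
            flagged.append(True)
        else:
            flagged.append(False)
        cents.append(placed)
        cells.append(Polygon2D(placed[None, :] + cfg.cell_radius * circ))
    return np.array(cents), cells, np.array(flagged)


def generate(cfg: SynthConfig) -> SyntheticSpheroid:
    """Run the full generator: centers -> Voronoi -> relax -> place cells."""
    window = _window_polygon(cfg.window_radius)
    centers = sample_cell_centers(cfg)
    vor_cells, boundary = build_compartments(centers, window)
    comps = relax_compartments(vor_cells, cfg.relaxation, cfg.shrink)
    rng = np.random.default_rng(cfg.seed + 1)
    cell_cents, cell_polys, at_centroid = place_cells(comps, cfg, rng)

    outline = SpheroidOutline(
        center=np.zeros(2), semi_major=cfg.window_radius,
        semi_minor=cfg.window_radius, orientation=0.0)
    rec = SpheroidRecord(
        stage=cfg.stage, outline=outline, pa_axis=np.array([0.0, 1.0]),
        compartment_polys=list(comps), cell_polys=list(cell_polys),
        meta={"synthetic": True, "config": asdict(cfg)},
    )

    rows = []
    for i, (comp, vor) in enumerate(zip(comps, vor_cells)):
        m = polygon_moments(comp)
        alpha = m.lam_max / m.lam_min if m.lam_min > 0 else math.inf
        dx = cell_cents[i] - m.centroid
        u = np.clip((m.centroid[1] / cfg.window_radius + 1.0) / 2.0, 0.0, 1.0)
        rows.append((i, m.area, alpha, dx[0], dx[1], float(np.hypot(*dx)),
                     u, bool(boundary[i]), bool(at_centroid[i])))
    truth = np.rec.fromrecords(
        rows, names="cell_id,a,alpha,dx_x,dx_y,r,pa_coord,boundary,at_centroid")
    return SyntheticSpheroid(
        config=cfg, record=rec, compartments=list(comps),
        voronoi_cells=list(vor_cells), cell_centroids=cell_cents,
        cell_polys=list(cell_polys), boundary_flags=boundary, truth=truth)


def render_label_masks(
    sphere: SyntheticSpheroid,
    pixel_size: float,
    wall_thickness: Optional[float] = None,
) -> dict:
    """Rasterize a synthetic spheroid to 16-bit label masks.

    Returns ``{"wall": binary wall mask, "compartments": label mask,
    "cells": label mask, "pixel_size": um/px, "origin": (x0, y0) um}``.
    Walls are drawn centred on the compartment boundaries (half the
    thickness to either side), as a physical wall of finite width would be;
    compartment labels fill the polygon interiors (walls overwrite them with
    0 in the wall mask only, not in the label mask).  Label i+1 marks
    compartment/cell i; background is 0.
    """
    from skimage.draw import polygon as draw_polygon

    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    wt = sphere.config.wall_thickness if wall_thickness is None else wall_thickness
    if wt < 2.0 * pixel_size:
        import warnings
        warnings.warn("wall thinner than 2 px; rendered walls may break")

    Rw = sphere.config.window_radius
    pad = wt + 2.0 * pixel_size
    x0, y0 = -Rw - pad, -Rw - pad
    size = int(math.ceil(2.0 * (Rw + pad) / pixel_size))
    H = W = size

    def to_rc(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        # x = x0 + (col + 0.5) px ; y = y0 + (H - row - 0.5) px
        col = (v[:, 0] - x0) / pixel_size - 0.5
        row = H - 0.5 - (v[:, 1] - y0) / pixel_size
        return row, col

    comp_mask = np.zeros((H, W), dtype=np.uint16)
    cell_mask = np.zeros((H, W), dtype=np.uint16)
    wall = np.zeros((H, W), dtype=bool)

    for i, comp in enumerate(sphere.compartments):
        r, c = to_rc(comp.vertices)
        rr, cc = draw_polygon(r, c, shape=comp_mask.shape)
        comp_mask[rr, cc] = i + 1
        # wall band: boundary buffered by wt/2 on each side; mitre joins keep
        # wall junctions sharp so compartment interiors retain their corners
        band = comp.to_shapely().exterior.buffer(
            wt / 2.0, join_style="mitre", mitre_limit=4.0)
        _fill_shape(wall, band, to_rc, draw_polygon)
    for i, cell in enumerate(sphere.cell_polys):
        r, c = to_rc(cell.vertices)
        rr, cc = draw_polygon(r, c, shape=cell_mask.shape)
        cell_mask[rr, cc] = i + 1

    return {"wall": wall, "compartments": comp_mask, "cells": cell_mask,
            "pixel_size": pixel_size, "origin": (x0, y0)}


def _fill_shape(target: np.ndarray, shape_geom, to_rc, draw_polygon) -> None:
    """Rasterize a (multi)polygon with holes into a boolean mask."""
    geoms = getattr(shape_geom, "geoms", [shape_geom])
    for g in geoms:
        ext = np.asarray(g.exterior.coords)
        r, c = to_rc(ext)
        rr, cc = draw_polygon(r, c, shape=target.shape)
        patch = np.zeros_like(target)
        patch[rr, cc] = True
        for hole in g.interiors:
            hv = np.asarray(hole.coords)
            r, c = to_rc(hv)
            rr, cc = draw_polygon(r, c, shape=target.shape)
            patch[rr, cc] = False
        target |= patch
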