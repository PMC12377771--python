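"""End-to-end orchestration: simulate, extract, analyze.

The pipeline ties the modules together: the synthetic generator (or a pair
of label masks) supplies cell and compartment outlines; pairing, the
Voronoi reference and the per-pair metrics produce a
:class:`~cz3geom.spheroid.SpheroidRecord`; spheroid-level summaries, PA
profiles, gamma fits and feature correlations are computed from it.  All
convention switches (aspect-ratio definition, whitening, partition-cost
variant, PA mode) live in :class:`PipelineConfig` and are echoed into every
output so results are self-describing.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from shapely.ops import unary_union

from .geometry import FeatureRecord, Polygon2D
from .maskio import (
    LabelMask,
    mask_to_polygons,
    pair_cells_to_compartments,
)
from .spheroid import (
    SpheroidRecord,
    fit_outline,
    estimate_pa_axis,
    feature_correlations,
    pa_profile,
    planar_voronoi,
    summarize_spheroid,
)

log = logging.getLogger("cz3geom")

__all__ = ["PipelineConfig", "extract_record", "extract_from_masks",
           "analyze_record", "DEFAULT_CORRELATIONS"]


@dataclass
class PipelineConfig:
    """Convention flags and knobs shared by extraction and analysis."""

    sqrt_aspect: bool = False          # alpha as axis-length (sqrt) ratio
    sqrt_whiten: bool = False          # whitened offset as sqrt of the form
    cost_denominator: str = "sum_sq"   # partition-cost variant
    pa_mode: str = "major_axis"        # or "offspring_normal"
    n_bins: int = 8
    wall_compensation: float = 0.0     # um added outward to extracted outlines
    distance_cap: Optional[float] = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


#: Feature pairs mirrored from the standard correlation panels: compartment
#: area against cell area, aspect ratio, circularity (offset by the regular
#: hexagon's), cell offset (log-log; the offset shows a power law in area)
#: and whitened offset.
DEFAULT_CORRELATIONS = [
    {"x": "a_cell", "y": "a_cz3"},
    {"x": "a_cz3", "y": "alpha", "x_transform": "log", "y_offset": 1.0,
     "y_transform": "log"},
    {"x": "a_cz3", "y": "q", "x_transform": "log"},
    {"x": "a_cz3", "y": "r", "x_transform": "log", "y_transform": "log"},
    {"x": "a_cz3", "y": "r_white", "x_transform": "log"},
]


def extract_record(
    cell_polys: Sequence[Polygon2D],
    compartment_polys: Sequence[Polygon2D],
    *,
    config: Optional[PipelineConfig] = None,
    stage: str = "?",
    window: Optional[Polygon2D] = None,
    offspring_centroids: Optional[np.ndarray] = None,
    compartment_flags: Optional[Sequence[list]] = None,
    cell_ids: Optional[Sequence[int]] = None,
) -> SpheroidRecord:
    """Pair cells with compartments and compute all per-pair metrics.

    The Voronoi reference tessellation is built from the matched cell
    centroids, clipped to ``window`` (default: convex hull of the
    compartments).  Compartments touching the window rim are flagged
    ``boundary``; ambiguous pairings are excluded with a log line so every
    filter is auditable.
    """
    cfg = config or PipelineConfig()
    pairing = pair_cells_to_compartments(
        cell_polys, compartment_polys, distance_cap=cfg.distance_cap)
    log.info("pairing: %d pairs, %d unmatched cells, %d ambiguous compartments",
             len(pairing["pairs"]), len(pairing["unmatched_cells"]),
             len(pairing["ambiguous_compartments"]))
    if not pairing["pairs"]:
        raise ValueError("zero valid cell/compartment pairs")

    comp_union = unary_union([c.to_shapely() for c in compartment_polys])
    if window is None:
        window = Polygon2D.from_shapely(comp_union.convex_hull)
    rim = window.to_shapely().exterior

    # outline from the hull of the covered region
    hull_pts = np.asarray(comp_union.convex_hull.exterior.coords)[:-1]
    outline = fit_outline(hull_pts)
    pa_axis = estimate_pa_axis(outline, offspring_centroids, mode=cfg.pa_mode)

    cents = []
    for ci, _, _ in pairing["pairs"]:
        c = cell_polys[ci].to_shapely().centroid
        cents.append([c.x, c.y])
    cents = np.array(cents)
    vor = None
    if len(cents) >= 3:
        try:
            vor = planar_voronoi(cents, window)
        except (ValueError, RuntimeError) as err:
            log.warning("Voronoi reference unavailable: %s", err)

    features, comp_used, cell_used = [], [], []
    n_boundary = 0
    for k, (ci, zi, pflags) in enumerate(pairing["pairs"]):
        comp = compartment_polys[zi]
        flags = list(pflags)
        if compartment_flags is not None:
            flags.extend(compartment_flags[zi])
        if comp.to_shapely().distance(rim) < 1e-9:
            flags.append("boundary")
            n_boundary += 1
        rec = FeatureRecord.from_polygons(
            cell_ids[ci] if cell_ids is not None else ci, cell_polys[ci], comp,
            voronoi_cell=vor[k] if vor is not None else None,
            sqrt_aspect=cfg.sqrt_aspect, sqrt_whiten=cfg.sqrt_whiten,
            flags=flags)
        features.append(rec)
        comp_used.append(comp)
        cell_used.append(cell_polys[ci])
    log.info("features: %d records (%d boundary-flagged)",
             len(features), n_boundary)

    return SpheroidRecord(
        stage=stage, outline=outline, pa_axis=pa_axis, features=features,
        offspring_centroids=offspring_centroids,
        compartment_polys=comp_used, cell_polys=cell_used,
        meta={"config": cfg.to_dict(),
              "n_unmatched_cells": len(pairing["unmatched_cells"]),
              "n_ambiguous": len(pairing["ambiguous_compartments"])})


def extract_from_masks(
    compartment_mask: LabelMask,
    cell_mask: LabelMask,
    *,
    config: Optional[PipelineConfig] = None,
    stage: str = "?",
    window: Optional[Polygon2D] = None,
    offspring_centroids: Optional[np.ndarray] = None,
) -> SpheroidRecord:
    """Mask pair -> SpheroidRecord.

    ``config.wall_compensation`` (um) buffers each extracted compartment
    outline outward, recovering the wall mid-line when the segmentation
    labels only the intra-wall interior (use half the wall thickness).
    """
    cfg = config or PipelineConfig()
    comp_items = mask_to_polygons(compartment_mask)
    cell_items = mask_to_polygons(cell_mask)
    log.info("ingested %d compartment and %d cell outlines",
             len(comp_items), len(cell_items))
    comp_polys, comp_flags = [], []
    for it in comp_items:
        p = it["polygon"]
        if cfg.wall_compensation > 0:
            # mitre joins keep polygonal corners sharp; round joins would
            # shave ~r^2 per corner, biasing small-compartment areas low
            shp = p.to_shapely().buffer(cfg.wall_compensation,
                                        join_style="mitre", mitre_limit=4.0)
            p = Polygon2D.from_shapely(shp)
        comp_polys.append(p)
        comp_flags.append(list(it["flags"]))
    cell_polys = [it["polygon"] for it in cell_items]
    return extract_record(
        cell_polys, comp_polys, config=cfg, stage=stage, window=window,
        offspring_centroids=offspring_centroids,
        compartment_flags=comp_flags,
        cell_ids=[it["label"] for it in cell_items])


def analyze_record(
    rec: SpheroidRecord,
    *,
    config: Optional[PipelineConfig] = None,
    window: Optional[Polygon2D] = None,
    profile_metrics: Sequence[str] = (
        "a_cell", "a_cz3", "alpha", "q", "r", "r_white", "e_v"),
    correlations: Optional[Sequence[dict]] = None,
) -> dict:
    """Spheroid summary, PA profiles and feature correlations.

    Returns ``{"summary": DataFrame(1 row), "profiles": DataFrame(long),
    "correlations": DataFrame}`` with convention flags echoed as columns.
    """
    cfg = config or PipelineConfig()
    summary = summarize_spheroid(rec, window=window)
    srow = dataclasses.asdict(summary)
    srow.update({f"flag_{k}": v for k, v in cfg.to_dict().items()
                 if k in ("sqrt_aspect", "sqrt_whiten", "cost_denominator",
                          "pa_mode")})
    summary_df = pd.DataFrame([srow])

    prof_rows = []
    for metric in profile_metrics:
        try:
            prof = pa_profile(rec, metric, n_bins=cfg.n_bins)
        except ValueError:
            continue
        for b in range(len(prof.mean)):
            prof_rows.append({
                "stage": rec.stage, "metric": metric, "bin": b,
                "u_low": prof.edges[b], "u_high": prof.edges[b + 1],
                "mean": prof.mean[b], "sd": prof.sd[b],
                "count": prof.count[b]})
    profiles_df = pd.DataFrame(prof_rows)

    feats = [f for f in rec.features if "boundary" not in f.flags]
    corr_df = pd.DataFrame()
    specs = list(correlations) if correlations is not None else [
        dict(s) for s in DEFAULT_CORRELATIONS]
    if len(feats) >= 3:
        try:
            corr_df = feature_correlations(feats, specs)
        except (ValueError, KeyError) as err:
            log.warning("correlations unavailable: %s", err)
    return {"summary": summary_df, "profiles": profiles_df,
            "correlations": corr_df}
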