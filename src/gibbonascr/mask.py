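"""Habitat masks: regular grids of candidate group locations with covariates.

A habitat mask is a fine grid of equally spaced points over a region.  It
serves two roles: (i) the latent group location is integrated over the mask
in the likelihood (quadrature with weight = cell area), and (ii) spatial
covariates entering the log-linear density model are measured at mask
points.  Two kinds of mask are used: a park-wide prediction mask over the
survey-region polygon, and per-site local masks (a buffer around each
site's listening posts) used when fitting.

Coordinates are assumed to be in a single metric projection (e.g. UTM);
no reprojection is performed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import shape as _geojson_shape

__all__ = [
    "HabitatMask",
    "RasterGrid",
    "build_mask",
    "attach_covariates",
    "local_mask",
    "restrict_mask",
    "read_boundary_geojson",
    "mask_to_frame",
    "mask_from_frame",
]

FOREST_CLASSES = ("F1_evergreen", "F2_semi_evergreen", "F3_other")


@dataclass
class HabitatMask:
    """Regular grid of locations with per-point covariate values.

    x, y : point coordinates (metres, projected).
    cell_area_km2 : area represented by each point (spacing^2, in km^2).
    covariates : name -> per-point array; ``forest_class`` holds strings
        from FOREST_CLASSES, everything else is float.
    """

    x: np.ndarray
    y: np.ndarray
    cell_area_km2: float
    covariates: dict = field(default_factory=dict)
    region_label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.cell_area_km2 <= 0:
            raise ValueError("cell_area_km2 must be > 0")

    def __len__(self) -> int:
        return self.x.size

    @property
    def n_points(self) -> int:
        return self.x.size

    @property
    def total_area_km2(self) -> float:
        return self.n_points * self.cell_area_km2

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, idx) -> "HabitatMask":
        cov = {k: np.asarray(v)[idx] for k, v in self.covariates.items()}
        return HabitatMask(self.x[idx], self.y[idx], self.cell_area_km2, cov,
                           self.region_label)


@dataclass
class RasterGrid:
    """Minimal in-memory raster: values[i, j] covers cell with centre
    (x0 + j*dx, y0 + i*dy).  Sampling is nearest-cell."""

    values: np.ndarray
    x0: float
    y0: float
    dx: float
    dy: float

    def sample(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        j = np.rint((x - self.x0) / self.dx).astype(int)
        i = np.rint((y - self.y0) / self.dy).astype(int)
        ni, nj = self.values.shape
        bad = (i < 0) | (i >= ni) | (j < 0) | (j >= nj)
        if np.any(bad):
            coords = np.column_stack([np.atleast_1d(x)[np.atleast_1d(bad)],
                                      np.atleast_1d(y)[np.atleast_1d(bad)]])
            raise ValueError(
                f"{coords.shape[0]} mask point(s) outside raster extent, "
                f"first at {tuple(coords[0])}")
        return self.values[i, j]


def read_boundary_geojson(path) -> shapely.Geometry:
    """Read a (Multi)Polygon boundary from a GeoJSON file."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [_geojson_shape(f["geometry"]) for f in gj["features"]]
        return shapely.union_all(geoms)
    if gj.get("type") == "Feature":
        return _geojson_shape(gj["geometry"])
    return _geojson_shape(gj)


def _grid_in(predicate, bounds, spacing_m):
    minx, miny, maxx, maxy = bounds
    xs = np.arange(minx + spacing_m / 2.0, maxx, spacing_m)
    ys = np.arange(miny + spacing_m / 2.0, maxy, spacing_m)
    if xs.size == 0 or ys.size == 0:
        return np.empty(0), np.empty(0)
    gx, gy = np.meshgrid(xs, ys)
    gx = gx.ravel()
    gy = gy.ravel()
    keep = predicate(gx, gy)
    return gx[keep], gy[keep]


def build_mask(boundary, spacing_m: float, region_label: str = "") -> HabitatMask:
    """Regular grid of cell centres inside ``boundary`` (a shapely polygon).

    cell_area = spacing^2 in km^2; the grid is aligned to the boundary's
    bounding box with a half-spacing inset so cells tile the box exactly.
    """
    if spacing_m <= 0:
        raise ValueError("spacing_m must be > 0")
    if boundary.area == 0:
        raise ValueError("boundary polygon has zero area")
    gx, gy = _grid_in(
        lambda x, y: shapely.contains_xy(boundary, x, y), boundary.bounds, spacing_m
    )
    if gx.size <= 1:
        warnings.warn("mask grid has <= 1 point; spacing may exceed the region extent")
    return HabitatMask(gx, gy, (spacing_m / 1000.0) ** 2, {}, region_label)


def local_mask(posts, buffer_m: float = 4000.0, spacing_m: float = 100.0,
               layers=None) -> HabitatMask:
    """Grid restricted to the union of discs of radius ``buffer_m`` around posts.

    This is the fitting-side mask: it must extend past the distance at which
    detection becomes negligible.  Covariates are attached when ``layers``
    is given.
    """
    pts = np.asarray([[p.x, p.y] if hasattr(p, "x") else p for p in posts],
                     dtype=float).reshape(-1, 2)
    if pts.shape[0] == 0:
        warnings.warn("empty post list: returning empty mask")
        return HabitatMask(np.empty(0), np.empty(0), (spacing_m / 1000.0) ** 2)
    bounds = (pts[:, 0].min() - buffer_m, pts[:, 1].min() - buffer_m,
              pts[:, 0].max() + buffer_m, pts[:, 1].max() + buffer_m)

    def near(x, y):
        d2 = np.min(
            (x[:, None] - pts[None, :, 0]) ** 2 + (y[:, None] - pts[None, :, 1]) ** 2,
            axis=1,
        )
        return d2 <= buffer_m**2

    gx, gy = _grid_in(near, bounds, spacing_m)
    m = HabitatMask(gx, gy, (spacing_m / 1000.0) ** 2)
    if layers:
        m = attach_covariates(m, layers)
    return m


def restrict_mask(mask: HabitatMask, posts, buffer_m: float) -> HabitatMask:
    """Subset an existing mask to points within ``buffer_m`` of any post,
    keeping attached covariates (used to carve fitting masks out of a
    simulated or park-wide landscape grid)."""
    pts = np.asarray([[p.x, p.y] if hasattr(p, "x") else p for p in posts],
                     dtype=float).reshape(-1, 2)
    d2 = np.min(
        (mask.x[:, None] - pts[None, :, 0]) ** 2
        + (mask.y[:, None] - pts[None, :, 1]) ** 2,
        axis=1,
    )
    return mask.subset(d2 <= buffer_m**2)


def attach_covariates(mask: HabitatMask, layers: dict) -> HabitatMask:
    """Attach named covariate layers to every mask point.

    Layer values may be:

    * an (n, 2) array of feature points  -> Euclidean distance to nearest
      feature (for ``dist_*`` covariates);
    * a shapely geometry (lines, polygons, points) -> distance to it;
    * a :class:`RasterGrid`               -> nearest-cell sample;
    * a list of ``(polygon, class_label)`` pairs plus implicit default, or a
      plain string, for the categorical ``forest_class`` layer;
    * a scalar                            -> constant covariate.

    Order-independent across layers; each layer writes one covariate.
    """
    cov = dict(mask.covariates)
    xy = mask.points
    for name, layer in layers.items():
        if isinstance(layer, RasterGrid):
            cov[name] = np.asarray(layer.sample(mask.x, mask.y), dtype=float)
        elif isinstance(layer, shapely.Geometry):
            cov[name] = shapely.distance(layer, shapely.points(xy))
        elif isinstance(layer, str):
            cov[name] = np.full(mask.n_points, layer, dtype=object)
        elif np.isscalar(layer):
            cov[name] = np.full(mask.n_points, float(layer))
        elif isinstance(layer, (list, tuple)) and layer and isinstance(layer[0], tuple):
            vals = np.full(mask.n_points, FOREST_CLASSES[0], dtype=object)
            for geom, label in layer:
                inside = shapely.contains_xy(geom, mask.x, mask.y)
                vals[inside] = label
            cov[name] = vals
        else:
            feats = np.asarray(layer, dtype=float).reshape(-1, 2)
            if feats.shape[0] == 0:
                raise ValueError(f"layer {name!r} has no features")
            dist, _ = cKDTree(feats).query(xy)
            cov[name] = np.asarray(dist, dtype=float)
    return HabitatMask(mask.x, mask.y, mask.cell_area_km2, cov, mask.region_label)


def mask_to_frame(mask: HabitatMask) -> pd.DataFrame:
    """Flatten a mask to a DataFrame (x, y, cell_area_km2, covariates) for CSV export."""
    data = {"x": mask.x, "y": mask.y,
            "cell_area_km2": np.full(mask.n_points, mask.cell_area_km2)}
    data.update({k: v for k, v in mask.covariates.items()})
    return pd.DataFrame(data)


def mask_from_frame(df: pd.DataFrame, region_label: str = "") -> HabitatMask:
    cov_cols = [c for c in df.columns if c not in ("x", "y", "cell_area_km2")]
    cov = {}
    for c in cov_cols:
        col = df[c]
        cov[c] = col.to_numpy(dtype=object if col.dtype == object else float)
    return HabitatMask(df["x"].to_numpy(float), df["y"].to_numpy(float),
                       float(df["cell_area_km2"].iloc[0]), cov, region_label)
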