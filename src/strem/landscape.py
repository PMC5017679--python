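"""Study-domain geometry and habitat rasters.

All coordinates are planar kilometres (an equal-area projection is assumed
for user-supplied data).  The study domain is a simple polygon; habitat is a
regular raster of integer class codes ``1..H`` indexed row-major from the
lower-left corner with half-open cells ``[x0, x0+cell) x [y0, y0+cell)``.

A synthetic landscape generator stands in for a real land-cover grid: a
smoothed Gaussian random field is rank-thresholded so that the realised
class proportions match requested targets while remaining spatially patchy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, shape as _geojson_shape

__all__ = [
    "StudyDomain",
    "HabitatRaster",
    "generate_synthetic_landscape",
    "uniform_raster",
    "DEFAULT_CLASS_LABELS",
    "DEFAULT_DOMAIN_KM",
]

#: Level-1 land-cover classes used throughout the simulation study.
DEFAULT_CLASS_LABELS = ("artificial", "agricultural", "forest", "wetland", "water")

#: Default synthetic domain: a Finland-like rectangle (area = 332,000 km^2).
DEFAULT_DOMAIN_KM = (400.0, 830.0)


@dataclass(frozen=True)
class StudyDomain:
    """Simple closed polygon delimiting the focal area, in km coordinates."""

    boundary: Polygon

    def __post_init__(self) -> None:
        if not isinstance(self.boundary, Polygon):
            object.__setattr__(self, "boundary", Polygon(self.boundary))
        if not self.boundary.is_valid or not self.boundary.is_simple:
            raise ValueError("domain boundary must be a simple, valid polygon")
        if self.boundary.area <= 0:
            raise ValueError("domain area must be positive")

    @property
    def area(self) -> float:
        """Domain area in km^2."""
        return float(self.boundary.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        return tuple(self.boundary.bounds)

    @classmethod
    def rectangle(cls, width_km: float, height_km: float,
                  origin: tuple[float, float] = (0.0, 0.0)) -> "StudyDomain":
        x0, y0 = origin
        return cls(Polygon([(x0, y0), (x0 + width_km, y0),
                            (x0 + width_km, y0 + height_km), (x0, y0 + height_km)]))

    @classmethod
    def from_wkt(cls, wkt: str) -> "StudyDomain":
        return cls(shapely.from_wkt(wkt))

    @classmethod
    def from_geojson(cls, src) -> "StudyDomain":
        """Build from a GeoJSON geometry mapping or JSON string."""
        if isinstance(src, str):
            src = json.loads(src)
        return cls(_geojson_shape(src))

    def contains(self, x, y):
        """Even-odd point-in-polygon test; boundary points count as inside.

        Accepts scalars or arrays; returns a bool of matching shape.
        """
        res = shapely.intersects_xy(self.boundary, x, y)
        if np.ndim(x) == 0:
            return bool(res)
        return np.asarray(res)

    def sample_points(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n points uniformly inside the domain (rejection from bbox)."""
        x0, y0, x1, y1 = self.bounds
        out = np.empty((n, 2))
        filled = 0
        while filled < n:
            m = max(2 * (n - filled), 16)
            pts = rng.uniform((x0, y0), (x1, y1), size=(m, 2))
            ok = self.contains(pts[:, 0], pts[:, 1])
            take = pts[ok][: n - filled]
            out[filled:filled + len(take)] = take
            filled += len(take)
        return out


@dataclass
class HabitatRaster:
    """Regular grid of habitat class codes 1..H.

    ``classes[iy, ix]`` holds the code of the cell whose lower-left corner is
    ``origin + cell_size * (ix, iy)``.  Exactly one class is flagged as the
    reference class (transect-survey habitat, "forest" by convention); habitat
    weights are expressed relative to it.
    """

    origin: tuple[float, float]
    cell_size: float
    classes: np.ndarray
    class_labels: tuple[str, ...]
    reference_class: int  # class code, 1-based

    def __post_init__(self) -> None:
        self.classes = np.ascontiguousarray(self.classes, dtype=np.int16)
        if self.classes.ndim != 2:
            raise ValueError("classes must be a 2-D grid")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        H = len(self.class_labels)
        if H < 1:
            raise ValueError("need at least one habitat class")
        if self.classes.min() < 1 or self.classes.max() > H:
            raise ValueError("class codes must lie in 1..H")
        if not (1 <= self.reference_class <= H):
            raise ValueError("reference_class must be a valid class code")

    @property
    def n_classes(self) -> int:
        return len(self.class_labels)

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) grid dimensions."""
        return self.classes.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the rastered area in km."""
        ny, nx = self.classes.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + nx * self.cell_size, y0 + ny * self.cell_size)

    @property
    def reference_label(self) -> str:
        return self.class_labels[self.reference_class - 1]

    def cell_index(self, x, y):
        """(ix, iy) indices of the half-open cells containing the points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        ix = np.floor((x - self.origin[0]) / self.cell_size).astype(np.int64)
        iy = np.floor((y - self.origin[1]) / self.cell_size).astype(np.int64)
        return ix, iy

    def habitat_at(self, x, y):
        """Habitat class code at the given point(s); raises outside extent."""
        scalar = np.ndim(x) == 0
        ix, iy = self.cell_index(x, y)
        ny, nx = self.classes.shape
        bad = (ix < 0) | (ix >= nx) | (iy < 0) | (iy >= ny)
        if np.any(bad):
            raise ValueError("point outside raster extent")
        out = self.classes[iy, ix]
        return int(out) if scalar else out

    def habitat_at_or_zero(self, x, y):
        """Like :meth:`habitat_at` but returns 0 for out-of-extent points."""
        ix, iy = self.cell_index(x, y)
        ny, nx = self.classes.shape
        ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        out = np.zeros(np.shape(ix), dtype=np.int16)
        out[ok] = self.classes[iy[ok], ix[ok]]
        return out

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (X, Y) of cell-centre coordinates."""
        ny, nx = self.classes.shape
        xs = self.origin[0] + (np.arange(nx) + 0.5) * self.cell_size
        ys = self.origin[1] + (np.arange(ny) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def class_areas(self, domain: StudyDomain | None = None) -> np.ndarray:
        """Area (km^2) of each class, optionally clipped to the domain.

        Cells are attributed by their centre (consistent with the raster's
        own discretisation error).
        """
        cell_area = self.cell_size ** 2
        if domain is None:
            counts = np.bincount(self.classes.ravel(), minlength=self.n_classes + 1)
        else:
            X, Y = self.cell_centers()
            inside = domain.contains(X.ravel(), Y.ravel())
            counts = np.bincount(self.classes.ravel()[inside],
                                 minlength=self.n_classes + 1)
        return counts[1:] * cell_area

    # ------------------------------------------------------------------ I/O
    def to_ascii(self, path) -> None:
        """Write the class grid as an ESRI ASCII grid."""
        ny, nx = self.classes.shape
        header = (f"ncols {nx}\nnrows {ny}\n"
                  f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n"
                  f"cellsize {self.cell_size}\nNODATA_value -9999\n")
        with open(path, "w") as fh:
            fh.write(header)
            # ASCII grids store the top row first
            np.savetxt(fh, self.classes[::-1], fmt="%d")

    @classmethod
    def from_ascii(cls, path, class_labels: tuple[str, ...],
                   reference_class: int) -> "HabitatRaster":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        for ln in lines[:6]:
            key, val = ln.split()
            meta[key.lower()] = float(val)
        grid = np.loadtxt(lines[6:], dtype=np.int16)[::-1]
        grid = np.atleast_2d(grid)
        return cls(origin=(meta["xllcorner"], meta["yllcorner"]),
                   cell_size=meta["cellsize"], classes=grid,
                   class_labels=tuple(class_labels),
                   reference_class=reference_class)


def generate_synthetic_landscape(extent, cell_size: float, class_proportions,
                                 clustering_scale: float,
                                 rng: np.random.Generator | int,
                                 class_labels: tuple[str, ...] | None = None,
                                 reference_class: int | None = None,
                                 ) -> HabitatRaster:
    """Generate a patchy habitat raster with given class proportions.

    A white-noise field is smoothed with a Gaussian kernel of standard
    deviation ``clustering_scale`` (km) and the cells are rank-assigned to
    classes so the realised proportions match the targets to within one cell.
    Thresholding a smooth field yields spatially contiguous patches whose
    characteristic size scales with ``clustering_scale``.

    Parameters
    ----------
    extent : (xmin, ymin, xmax, ymax) in km.
    class_proportions : sequence summing to 1 (length H).
    rng : numpy Generator or integer seed (same seed -> identical raster).
    reference_class : 1-based code of the reference class; defaults to the
        "forest" label when present, else the most abundant class.
    """
    from scipy import ndimage

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    props = np.asarray(class_proportions, dtype=float)
    if props.ndim != 1 or len(props) < 1:
        raise ValueError("class_proportions must be a 1-D simplex")
    if np.any(props < 0) or abs(props.sum() - 1.0) > 1e-9:
        raise ValueError("class_proportions must be nonnegative and sum to 1")
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    x0, y0, x1, y1 = extent
    nx = int(round((x1 - x0) / cell_size))
    ny = int(round((y1 - y0) / cell_size))
    if nx < 1 or ny < 1:
        raise ValueError("empty extent")

    H = len(props)
    if class_labels is None:
        class_labels = (DEFAULT_CLASS_LABELS if H == len(DEFAULT_CLASS_LABELS)
                        else tuple(f"class_{i + 1}" for i in range(H)))
    if reference_class is None:
        if "forest" in class_labels:
            reference_class = class_labels.index("forest") + 1
        else:
            reference_class = int(np.argmax(props)) + 1

    field = rng.standard_normal((ny, nx))
    sigma = clustering_scale / cell_size
    if sigma > 0:
        field = ndimage.gaussian_filter(field, sigma=sigma, mode="reflect")
    # rank-threshold: lowest-field cells -> class 1, and so on
    order = np.argsort(field.ravel(), kind="stable")
    n_cells = nx * ny
    cuts = np.floor(np.cumsum(props) * n_cells + 0.5).astype(np.int64)
    cuts[-1] = n_cells
    codes = np.empty(n_cells, dtype=np.int16)
    start = 0
    for c, stop in enumerate(cuts, start=1):
        codes[order[start:stop]] = c
        start = stop
    return HabitatRaster(origin=(x0, y0), cell_size=cell_size,
                         classes=codes.reshape(ny, nx),
                         class_labels=tuple(class_labels),
                         reference_class=int(reference_class))


def uniform_raster(extent, cell_size: float, label: str = "forest") -> HabitatRaster:
    """Single-class raster (homogeneous landscape scenarios)."""
    x0, y0, x1, y1 = extent
    nx = max(int(round((x1 - x0) / cell_size)), 1)
    ny = max(int(round((y1 - y0) / cell_size)), 1)
    return HabitatRaster(origin=(x0, y0), cell_size=cell_size,
                         classes=np.ones((ny, nx), dtype=np.int16),
                         class_labels=(label,), reference_class=1)
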