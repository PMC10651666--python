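"""Synthetic muscle cross-sections and fiber-type morphometry.

A section is a disc of tissue tiled by convex fiber cross-sections
(a Voronoi mosaic of blue-noise seed points, Lloyd-relaxed, each cell
shrunk inward to leave a boundary gap).  Two fluorescence channels are
rendered: green marks the interior of slow (type 1, MYH7-positive)
fibers, red marks the sarcolemmal boundary network around every fiber
(dystrophin).  Ground truth records each fiber's polygon and type.

Quantification mirrors the immunofluorescence workflow: threshold the
green channel to get slow fibers; threshold the red channel, fill the
enclosed interiors, and subtract the slow area to get fast fibers; then
measure each fiber's minimal Feret diameter (the minimum caliper width
over all orientations, computed by rotating calipers on the convex
hull), count fiber types, and flag sections with fewer than 70 fibers
as failing QC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_fill_holes
from scipy.spatial import ConvexHull, QhullError, Voronoi
from shapely.geometry import Point, Polygon
from skimage import draw, measure, morphology
from skimage.filters import threshold_otsu

from .errors import GeometryError, ValidationError

__all__ = [
    "SectionGeometry",
    "NoiseParams",
    "SectionTruth",
    "FiberRecord",
    "SectionSummary",
    "render_section",
    "segment_fibers",
    "min_feret",
    "measure_fibers",
    "summarize_section",
    "mean_tissue_intensity",
]

#: Sections with fewer fibers than this fail QC and are excluded.
MIN_FIBERS_QC = 70

#: Physical pixel pitch of rendered sections (20x-objective scale).
DEFAULT_PIXEL_SIZE_UM = 0.5


@dataclass(frozen=True)
class SectionGeometry:
    """Geometry of the synthetic mosaic, in pixels."""

    mean_fiber_diameter_px: float = 60.0
    boundary_gap_px: float = 3.0
    margin_px: float = 12.0
    min_spacing_frac: float = 0.6  # seed spacing as a fraction of the diameter
    lloyd_iterations: int = 2


@dataclass(frozen=True)
class NoiseParams:
    """Channel intensities (8-bit scale) and additive Gaussian noise."""

    background: float = 20.0
    green_foreground: float = 200.0
    red_foreground: float = 200.0
    sigma: float = 15.0


@dataclass
class SectionTruth:
    """Ground truth of one rendered section."""

    polygons: list[np.ndarray]  # (x, y) vertex arrays, one convex polygon per fiber
    types: list[str]  # 'type1' | 'type2'
    center: tuple[float, float]
    radius: float
    pixel_size_um: float
    noise: NoiseParams
    geometry: SectionGeometry

    @property
    def n_fibers(self) -> int:
        return len(self.polygons)

    def pct_type1(self) -> float:
        return 100.0 * sum(t == "type1" for t in self.types) / len(self.types)

    def min_feret_um(self) -> np.ndarray:
        """Analytic minimal Feret diameter of every truth polygon, in um."""
        return np.array([min_feret(p, pixel_size=self.pixel_size_um) for p in self.polygons])


@dataclass(frozen=True)
class FiberRecord:
    fiber_id: int
    fiber_type: str
    min_feret_um: float
    area_um2: float
    centroid: tuple[float, float] = field(default=(np.nan, np.nan), compare=False)


@dataclass(frozen=True)
class SectionSummary:
    n_type1: int
    n_type2: int
    pct_type1: float
    mean_min_feret_um: dict
    histogram: dict
    qc_pass: bool

    def to_dict(self) -> dict:
        return {
            "n_type1": self.n_type1,
            "n_type2": self.n_type2,
            "pct_type1": self.pct_type1,
            "mean_min_feret_um": self.mean_min_feret_um,
            "histogram": self.histogram,
            "qc_pass": self.qc_pass,
        }


# ---------------------------------------------------------------------------
# rendering


def _blue_noise_points(
    rng: np.random.Generator, n: int, radius: float, min_dist: float
) -> np.ndarray:
    """Dart-throwing with a minimum pairwise distance inside a disc."""
    pts: list[np.ndarray] = []
    tries = 0
    max_tries = 400 * n
    while len(pts) < n:
        if tries >= max_tries:
            raise GeometryError(
                f"could not place {n} fiber seeds at spacing {min_dist:.1f} px "
                f"in a disc of radius {radius:.1f} px"
            )
        tries += 1
        r = radius * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        cand = np.array([r * np.cos(th), r * np.sin(th)])
        if all(np.hypot(*(cand - p)) >= min_dist for p in pts):
            pts.append(cand)
    return np.array(pts)


def _bounded_voronoi(points: np.ndarray, disc: Polygon) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to the disc.

    Ghost points on a far circle make every real cell finite before
    clipping; cells stay convex (intersection of convex regions).
    """
    r_ghost = 4 * np.sqrt(disc.area / np.pi)
    th = np.linspace(0, 2 * np.pi, 64, endpoint=False)
    ghosts = np.column_stack([r_ghost * np.cos(th), r_ghost * np.sin(th)])
    vor = Voronoi(np.vstack([points, ghosts]))
    cells = []
    for i in range(len(points)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or not region:
            raise GeometryError("unbounded Voronoi cell despite ghost frame")
        poly = Polygon(vor.vertices[region]).intersection(disc)
        if poly.is_empty or poly.geom_type != "Polygon":
            raise GeometryError("degenerate fiber cell after disc clipping")
        cells.append(poly)
    return cells


def render_section(
    n_fibers: int,
    pct_type1: float = 50.0,
    size_params: SectionGeometry | None = None,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> tuple[np.ndarray, SectionTruth]:
    """Render a two-channel section image and its ground truth.

    Returns ``(image, truth)`` where ``image`` is uint8 of shape
    (H, W, 2) with channel 0 = green (MYH7) and channel 1 = red
    (dystrophin).  Deterministic given ``seed``.
    """
    if n_fibers < 1:
        raise ValidationError(f"n_fibers must be >= 1, got {n_fibers}")
    if not 0 <= pct_type1 <= 100:
        raise ValidationError(f"pct_type1 must be in [0, 100], got {pct_type1}")
    geo = size_params or SectionGeometry()
    noise = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)

    d = geo.mean_fiber_diameter_px
    radius = (d / 2.0) * np.sqrt(n_fibers)  # mean cell area == pi*(d/2)^2
    side = int(np.ceil(2 * (radius + geo.margin_px)))
    center = (side / 2.0, side / 2.0)
    disc = Point(0.0, 0.0).buffer(radius, quad_segs=64)

    pts = _blue_noise_points(rng, n_fibers, radius * 0.98, geo.min_spacing_frac * d)
    cells = _bounded_voronoi(pts, disc)
    for _ in range(geo.lloyd_iterations):
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
        cells = _bounded_voronoi(pts, disc)

    polygons: list[np.ndarray] = []
    for c in cells:
        inner = c.buffer(-geo.boundary_gap_px / 2.0, join_style="mitre")
        if inner.is_empty or inner.geom_type != "Polygon" or inner.area < 4:
            raise GeometryError(
                "a fiber cell collapsed under the boundary gap; reduce n_fibers "
                "or the gap, or enlarge the fiber diameter"
            )
        hull = inner.convex_hull  # guard against mitre artifacts
        xy = np.asarray(hull.exterior.coords)[:-1] + np.array(center)
        polygons.append(xy)

    n_type1 = int(round(n_fibers * pct_type1 / 100.0))
    order = rng.permutation(n_fibers)
    types = ["type2"] * n_fibers
    for i in order[:n_type1]:
        types[i] = "type1"

    interior = np.zeros((side, side), dtype=bool)
    green_mask = np.zeros((side, side), dtype=bool)
    for poly, t in zip(polygons, types):
        rr, cc = draw.polygon(poly[:, 1], poly[:, 0], shape=(side, side))
        interior[rr, cc] = True
        if t == "type1":
            green_mask[rr, cc] = True
    rr, cc = draw.disk((center[1], center[0]), radius, shape=(side, side))
    disc_mask = np.zeros((side, side), dtype=bool)
    disc_mask[rr, cc] = True
    red_mask = disc_mask & ~interior

    img = np.full((side, side, 2), noise.background, dtype=float)
    img[..., 0][green_mask] = noise.green_foreground
    img[..., 1][red_mask] = noise.red_foreground
    img += rng.normal(0.0, noise.sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = SectionTruth(
        polygons=polygons,
        types=types,
        center=center,
        radius=radius,
        pixel_size_um=pixel_size_um,
        noise=noise,
        geometry=geo,
    )
    return img, truth


# ---------------------------------------------------------------------------
# segmentation


def segment_fibers(
    image: np.ndarray,
    thresholds: tuple[float, float] | None = None,
    area_min_px: int = 50,
    fast_mode: str = "filled",
) -> tuple[np.ndarray, np.ndarray]:
    """Label slow and fast fibers in a two-channel image.

    Slow fibers are connected components (8-connectivity) of the
    thresholded green channel.  Fast fibers are, in the default
    ``filled`` mode, the interiors enclosed by the thresholded red
    boundary network minus the slow area; ``raw`` mode subtracts the
    green area from the raw red-threshold mask instead.  Components
    smaller than ``area_min_px`` are discarded.  ``thresholds`` gives
    fixed (green, red) cutoffs; by default each channel is thresholded
    with Otsu's method.
    """
    if image.ndim != 3 or image.shape[2] < 2:
        raise ValidationError("expected an (H, W, 2) two-channel image")
    if fast_mode not in ("filled", "raw"):
        raise ValidationError(f"fast_mode must be 'filled' or 'raw', got {fast_mode!r}")
    green = image[..., 0].astype(float)
    red = image[..., 1].astype(float)
    if thresholds is None:
        thr_g, thr_r = threshold_otsu(green), threshold_otsu(red)
    else:
        thr_g, thr_r = thresholds

    green_mask = green >= thr_g
    red_mask = morphology.closing(red >= thr_r, morphology.disk(1))
    if not red_mask.any() and not green_mask.any():
        raise ValidationError("no tissue above threshold in either channel")

    drop = max(area_min_px - 1, 0)
    slow = morphology.remove_small_objects(green_mask, max_size=drop, connectivity=2)
    slow = morphology.remove_small_holes(slow, max_size=drop)
    if fast_mode == "filled":
        interiors = binary_fill_holes(red_mask) & ~red_mask
    else:
        interiors = red_mask
    fast = morphology.remove_small_holes(interiors, max_size=drop) & ~slow
    fast = morphology.remove_small_objects(fast, max_size=drop, connectivity=2)

    slow_labels = measure.label(slow, connectivity=2)
    fast_labels = measure.label(fast, connectivity=2)
    return slow_labels, fast_labels


# ---------------------------------------------------------------------------
# morphometry


def _hull_min_width(points: np.ndarray) -> float:
    """Minimum caliper width of a point set via rotating calipers.

    The minimal width of a convex polygon is attained with one caliper
    flush against a hull edge, so it suffices to take, for every hull
    edge, the farthest vertex distance from the edge's line, and
    minimize over edges.
    """
    try:
        hull = ConvexHull(points)
    except QhullError:
        return 0.0  # collinear/degenerate input has zero width
    verts = points[hull.vertices]
    edges = np.diff(np.vstack([verts, verts[:1]]), axis=0)
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    keep = lengths > 0
    edges, anchors, lengths = edges[keep], verts[keep], lengths[keep]
    normals = np.column_stack([-edges[:, 1], edges[:, 0]]) / lengths[:, None]
    # distance of every vertex from every edge line; width per edge = max
    dists = np.abs((verts[None, :, :] - anchors[:, None, :]) @ normals[:, :, None]).squeeze(-1)
    return float(dists.max(axis=1).min())


def min_feret(obj, pixel_size: float = 1.0) -> float:
    """Minimal Feret (caliper) diameter of a polygon or a pixel mask.

    ``obj`` may be an (N, 2) vertex array, a shapely polygon, or a 2-D
    boolean mask.  Masks are measured on the corner points of their
    boundary pixels, so a filled axis-aligned square of side s measures
    exactly s.  Degenerate (collinear) inputs return 0.0.
    """
    if hasattr(obj, "exterior"):
        pts = np.asarray(obj.exterior.coords)[:-1]
    else:
        arr = np.asarray(obj)
        if arr.ndim == 2 and arr.dtype == bool:
            if arr.sum() < 3:
                return 0.0
            boundary = arr & ~morphology.erosion(arr)
            rc = np.argwhere(boundary).astype(float)
            offs = np.array([[-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5]])
            pts = (rc[:, None, :] + offs[None, :, :]).reshape(-1, 2)
        elif arr.ndim == 2 and arr.shape[1] == 2:
            pts = arr.astype(float)
        else:
            raise ValidationError("min_feret expects a polygon or a boolean mask")
    if len(pts) < 3:
        return 0.0
    return _hull_min_width(pts) * pixel_size


def measure_fibers(
    slow_labels: np.ndarray,
    fast_labels: np.ndarray,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> list[FiberRecord]:
    """Per-fiber type, minimal Feret diameter and area from label images."""
    records: list[FiberRecord] = []
    fid = 0
    for labels, ftype in ((slow_labels, "type1"), (fast_labels, "type2")):
        for region in measure.regionprops(labels):
            fid += 1
            mask = np.zeros(labels.shape, dtype=bool)
            rs, cs = region.slice
            mask[rs, cs] = region.image
            records.append(
                FiberRecord(
                    fiber_id=fid,
                    fiber_type=ftype,
                    min_feret_um=min_feret(mask[rs, cs], pixel_size=pixel_size_um),
                    area_um2=float(region.area) * pixel_size_um**2,
                    centroid=(float(region.centroid[0]), float(region.centroid[1])),
                )
            )
    return records


def summarize_section(
    fibers: list[FiberRecord], bin_width_um: float = 5.0
) -> SectionSummary:
    """Counts, type percentages, per-type size statistics and the QC flag."""
    n1 = sum(f.fiber_type == "type1" for f in fibers)
    n2 = len(fibers) - n1
    total = n1 + n2
    means: dict[str, float] = {}
    hist: dict[str, dict] = {}
    for ftype in ("type1", "type2"):
        sizes = np.array([f.min_feret_um for f in fibers if f.fiber_type == ftype])
        means[ftype] = float(sizes.mean()) if len(sizes) else float("nan")
        if len(sizes):
            top = bin_width_um * np.ceil(sizes.max() / bin_width_um)
            edges = np.arange(0.0, top + bin_width_um / 2, bin_width_um)
            counts, _ = np.histogram(sizes, bins=edges)
            hist[ftype] = {"bin_edges_um": edges.tolist(), "counts": counts.tolist()}
        else:
            hist[ftype] = {"bin_edges_um": [], "counts": []}
    return SectionSummary(
        n_type1=n1,
        n_type2=n2,
        pct_type1=100.0 * n1 / total if total else float("nan"),
        mean_min_feret_um=means,
        histogram=hist,
        qc_pass=total >= MIN_FIBERS_QC,
    )


def mean_tissue_intensity(
    image: np.ndarray, channel: int, tissue_threshold: float
) -> float:
    """Mean intensity of a channel over its pixels >= tissue_threshold.

    The threshold must be held constant across a batch for intensities
    to be comparable (enforced by configuration, not here).
    """
    chan = image[..., channel].astype(float) if image.ndim == 3 else image.astype(float)
    mask = chan >= tissue_threshold
    if not mask.any():
        raise ValidationError(f"no pixel reaches tissue_threshold={tissue_threshold}")
    return float(chan[mask].mean())
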