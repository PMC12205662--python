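"""Invasion-distance and surface-roughness quantification.

Invasion metrics follow the convention used for gap-connected chips:
distances are measured from the matrix-side edge of the slit
(``InterfaceLine.x_interface``) into the matrix, per cell, and the ROI
statistic is the per-cell maximum d_max.  Roughness metrics are the
ISO 4287 amplitude parameters Ra, Rq and Rz computed on a mean-detrended
1-D height profile.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from skimage.measure import label as cc_label, regionprops

logger = logging.getLogger(__name__)

DEFAULT_INVASION_THRESHOLD = 20.0  # μm, ≈ one cell diameter


@dataclass
class CellPoints:
    """Labelled cell centroids in μm."""

    coordinates: np.ndarray  # (n, 2) array of (x, y)
    label: str = "cell"

    def __post_init__(self):
        self.coordinates = np.atleast_2d(np.asarray(self.coordinates, dtype=float))
        if self.coordinates.size and self.coordinates.shape[1] != 2:
            raise ValueError("coordinates must be (n, 2)")
        if self.coordinates.size and not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if not self.label:
            raise ValueError("label must be non-empty")

    @property
    def n(self) -> int:
        return 0 if self.coordinates.size == 0 else self.coordinates.shape[0]


@dataclass(frozen=True)
class InterfaceLine:
    """Lumen–matrix boundary; invasion is measured along +x · orientation."""

    x_interface: float  # μm
    orientation: int = 1  # +1: matrix lies at larger x; −1: mirrored

    def __post_init__(self):
        if not np.isfinite(self.x_interface):
            raise ValueError("x_interface must be finite")
        if self.orientation not in (-1, 1):
            raise ValueError("orientation must be ±1")


@dataclass
class InvasionMetrics:
    d_max: float  # μm
    distances: np.ndarray  # μm, one per cell, negatives clipped to 0
    n_invaded: int
    threshold: float


@dataclass
class ProtrusionSet:
    lengths: np.ndarray = field(default_factory=lambda: np.empty(0))  # μm

    def __post_init__(self):
        self.lengths = np.asarray(self.lengths, dtype=float)
        if np.any(self.lengths < 0):
            raise ValueError("protrusion lengths must be non-negative")


@dataclass
class HeightProfile:
    positions: np.ndarray  # μm
    heights: np.ndarray  # nm

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.heights = np.asarray(self.heights, dtype=float)
        if self.positions.shape != self.heights.shape:
            raise ValueError("positions and heights must have the same shape")


@dataclass(frozen=True)
class RoughnessMetrics:
    Ra: float  # nm
    Rq: float  # nm
    Rz: float  # nm


def invasion_metrics(
    points: CellPoints,
    interface: InterfaceLine,
    min_distance: float = DEFAULT_INVASION_THRESHOLD,
) -> InvasionMetrics:
    """Per-cell invasion distances beyond the interface and their summary.

    A cell's distance is its signed offset past the interface along the
    invasion direction, clipped below at 0; ``n_invaded`` counts cells
    strictly deeper than ``min_distance``.
    """
    if points.n == 0:
        raise ValueError("point set must be non-empty")
    signed = interface.orientation * (points.coordinates[:, 0] - interface.x_interface)
    distances = np.maximum(signed, 0.0)
    return InvasionMetrics(
        d_max=float(distances.max()),
        distances=distances,
        n_invaded=int(np.count_nonzero(distances > min_distance)),
        threshold=float(min_distance),
    )


def cell_points_from_label_image(
    label_image: np.ndarray, pixel_pitch: float, label: str = "cell"
) -> CellPoints:
    """Centroid table from a labelled nucleus image (pixel-centre coords).

    Image axes are (row → y, col → x); centroids convert to μm via the
    pixel pitch, matching the coordinate convention of the synthetic
    scene generator (round-trip safe).
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    props = regionprops(np.asarray(label_image, dtype=int))
    coords = np.array([[p.centroid[1] * pixel_pitch, p.centroid[0] * pixel_pitch] for p in props])
    return CellPoints(coordinates=coords.reshape(-1, 2), label=label)


def _skeleton_geodesic_lengths(skel: np.ndarray, source_mask: np.ndarray) -> float:
    """Max geodesic distance (px) over a skeleton from any source pixel."""
    pts = np.argwhere(skel)
    index = {tuple(p): i for i, p in enumerate(pts)}
    rows, cols, w = [], [], []
    for i, (r, c) in enumerate(pts):
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == dc == 0:
                    continue
                j = index.get((r + dr, c + dc))
                if j is not None:
                    rows.append(i)
                    cols.append(j)
                    w.append(np.hypot(dr, dc))
    n = len(pts)
    graph = coo_matrix((w, (rows, cols)), shape=(n, n))
    sources = [i for i, p in enumerate(pts) if source_mask[tuple(p)]]
    if not sources:
        return 0.0
    dist = dijkstra(graph, directed=False, indices=sources, min_only=True)
    finite = dist[np.isfinite(dist)]
    return float(finite.max()) if finite.size else 0.0


def protrusion_lengths(
    epithelium_mask: np.ndarray,
    interface: InterfaceLine,
    pixel_pitch: float,
) -> ProtrusionSet:
    """Lengths of epithelial protrusions reaching across the interface.

    Each 8-connected component of the binary mask that crosses the
    interface contributes one length: the geodesic distance through the
    component from its interface-crossing pixels to the farthest
    matrix-side pixel, in μm.  (A geodesic through the shape rather than
    its skeleton keeps the full protrusion tip, which thinning would trim
    by about half the protrusion width.)  Components entirely on one side
    contribute nothing; an empty result is not an error.
    """
    if pixel_pitch <= 0:
        raise ValueError("pixel_pitch must be positive")
    mask = np.asarray(epithelium_mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("epithelium_mask must be a 2-D binary image")
    col_interface = interface.x_interface / pixel_pitch
    cols = np.arange(mask.shape[1], dtype=float)
    signed_cols = interface.orientation * (cols - col_interface)  # px past interface

    lengths = []
    labelled = cc_label(mask, connectivity=2)
    for region in regionprops(labelled):
        comp = labelled == region.label
        comp_signed = signed_cols[np.any(comp, axis=0)]
        if comp_signed.min() > 0.5 or comp_signed.max() <= 0:
            continue  # does not cross the interface
        pix_signed = signed_cols[np.argwhere(comp)[:, 1]]
        near = np.abs(pix_signed) <= 0.5
        if not near.any():  # no pixel centred on the crossing column
            near = np.abs(pix_signed) == np.abs(pix_signed).min()
        crossing = np.zeros_like(comp)
        for (r, c), is_src in zip(np.argwhere(comp), near):
            if is_src:
                crossing[r, c] = True
        lengths.append(_skeleton_geodesic_lengths(comp, crossing) * pixel_pitch)
    return ProtrusionSet(lengths=np.array(sorted(lengths)))


def _strict_local_extrema(h: np.ndarray):
    """Strict interior local maxima and minima values."""
    interior = h[1:-1]
    maxima = interior[(interior > h[:-2]) & (interior > h[2:])]
    minima = interior[(interior < h[:-2]) & (interior < h[2:])]
    return maxima, minima


def roughness_metrics(profile: HeightProfile) -> RoughnessMetrics:
    """ISO 4287 amplitude parameters of a mean-detrended height profile.

    Ra is the mean absolute deviation, Rq the RMS deviation, and Rz the
    mean of the five highest local maxima minus the mean of the five
    lowest local minima.  With fewer than five extrema on a side, all
    available ones are used (with a warning); a monotone or flat profile
    falls back to the global extremes.
    """
    h = profile.heights
    if h.size < 2:
        raise ValueError("roughness needs at least two samples")
    if h.size < 10:
        warnings.warn("fewer than 10 samples: Rz uses fewer than five peaks/valleys", stacklevel=2)
    dev = h - h.mean()
    Ra = float(np.abs(dev).mean())
    Rq = float(np.sqrt((dev**2).mean()))

    maxima, minima = _strict_local_extrema(dev)
    if maxima.size == 0:
        maxima = np.array([dev.max()])
    if minima.size == 0:
        minima = np.array([dev.min()])
    if maxima.size < 5 or minima.size < 5:
        warnings.warn(
            f"only {maxima.size} peaks / {minima.size} valleys available for Rz "
            "(five of each preferred)", stacklevel=2,
        )
    top = np.sort(maxima)[-5:]
    bottom = np.sort(minima)[:5]
    Rz = float(top.mean() - bottom.mean())
    return RoughnessMetrics(Ra=Ra, Rq=Rq, Rz=max(Rz, 0.0))
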