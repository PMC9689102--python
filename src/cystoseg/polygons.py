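"""Post-processing: polygon outlines from a segmentation map.

The stages, composed by :func:`segmap_to_polygons`:

1. *Boundary simplification* — pixels whose 8-neighbourhood contains
   more than four differently classified pixels sit on high-curvature
   noise; they are reassigned to the majority neighbour class. The rule
   shrinks regions slightly, so the number of passes is limited
   (default 2).
2. *Boundary detection* — a pixel is boundary if any of its four
   neighbours belongs to a different class; pixels on the image frame
   count as boundary so lesions touching the frame edge are outlined.
3. *Contour tracing* — starting from the lexicographically smallest
   boundary pixel of a class, the tracer repeatedly steps to the next
   boundary pixel, scanning the 8-neighbourhood clockwise beginning
   with the previous step's direction and widening the search to
   Chebyshev rings of radius 2..5 on dead ends. Visited pixels are
   consumed. Chains that cannot continue or close are discarded as
   noise; the procedure reseeds until no boundary pixels remain.
4. *Area filtering* — polygon area from the shoelace formula
   ``A = ½ |Σ r_i × r_{i+1}|``; polygons below 0.25 % of the image area
   (64 px on a 160 x 160 map) are discarded as prediction noise.

Vertices are integer (row, col) pixel coordinates, row-major, 0-based.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line

from .scheme import ClassScheme, DEFAULT_SCHEME, N_CLASSES, NORMAL


@dataclass
class Polygon:
    """Closed loop of integer (row, col) vertices with a class label."""

    vertices: list[tuple[int, int]]
    class_index: int

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")
        if not 0 <= self.class_index < N_CLASSES:
            raise ValueError(f"bad class index {self.class_index}")

    def __len__(self) -> int:
        return len(self.vertices)

    def to_json(self, scheme: ClassScheme = DEFAULT_SCHEME) -> dict:
        return {
            "class": self.class_index,
            "class_name": scheme.class_names[self.class_index],
            "vertices": [[int(r), int(c)] for r, c in self.vertices],
            "area": shoelace_area(self),
        }


@dataclass
class TraceDiagnostics:
    """Bookkeeping from contour tracing (noise chains are dropped)."""

    n_noise_chains: int = 0
    n_noise_pixels: int = 0


@dataclass
class PolygonConfig:
    min_area_frac: float = 0.0025
    simplify_passes: int = 2
    max_search_radius: int = 5


def _check_seg(seg: np.ndarray) -> np.ndarray:
    seg = np.asarray(seg)
    if seg.ndim != 2:
        raise ValueError(f"segmentation map must be 2-D, got {seg.shape}")
    if seg.min(initial=0) < 0 or seg.max(initial=0) >= N_CLASSES:
        raise ValueError("segmentation map holds invalid class indices")
    return seg


_SHIFTS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
            (0, 1), (1, -1), (1, 0), (1, 1)]


def _shifted(padded: np.ndarray, dr: int, dc: int, h: int, w: int) -> np.ndarray:
    return padded[1 + dr:1 + dr + h, 1 + dc:1 + dc + w]


def find_boundaries(seg: np.ndarray) -> dict[int, np.ndarray]:
    """Per-class boolean boundary masks (4-connectivity, frame counts).

    A pixel of class c is boundary if at least one of its four
    neighbours has a different class, or it lies on the image border
    (out-of-image counts as "different class").
    """
    seg = _check_seg(seg)
    h, w = seg.shape
    padded = np.pad(seg, 1, constant_values=-1)
    differs = np.zeros((h, w), dtype=bool)
    for dr, dc in [(-1, 0), (1, 0), (0, -1), (0, 1)]:
        differs |= _shifted(padded, dr, dc, h, w) != seg
    return {int(c): differs & (seg == c) for c in np.unique(seg)}


def simplify_boundary(seg: np.ndarray, max_passes: int = 2) -> np.ndarray:
    """Remove high-curvature boundary pixels (the >4-of-8 rule).

    Each pass reassigns every pixel with more than four differing
    8-neighbours to the majority class of those neighbours (ties to the
    lowest class index), simultaneously over the map. Out-of-image is
    treated as the pixel's own class so frame-edge regions are not
    eroded. Stops early when a pass changes nothing.
    """
    seg = _check_seg(seg).copy()
    h, w = seg.shape
    for _ in range(max_passes):
        padded = np.pad(seg, 1, mode="edge")
        n_diff = np.zeros((h, w), dtype=np.int32)
        counts = np.zeros((N_CLASSES, h, w), dtype=np.int32)
        for dr, dc in _SHIFTS8:
            nb = _shifted(padded, dr, dc, h, w)
            n_diff += nb != seg
            for c in np.unique(nb):
                counts[c] += nb == c
        flagged = n_diff > 4
        if not flagged.any():
            break
        majority = counts.argmax(axis=0)  # argmax ties -> lowest index
        seg[flagged] = majority[flagged]
    return seg


def _rings(max_radius: int) -> list[list[tuple[int, int, float]]]:
    """Chebyshev rings 1..max_radius as (dr, dc, angle) offset lists."""
    rings = []
    for k in range(1, max_radius + 1):
        ring = []
        for dr in range(-k, k + 1):
            for dc in range(-k, k + 1):
                if max(abs(dr), abs(dc)) == k:
                    ring.append((dr, dc, math.atan2(dr, dc)))
        rings.append(ring)
    return rings


def trace_contour(boundary: dict[int, np.ndarray], class_index: int,
                  max_search_radius: int = 5
                  ) -> tuple[list[Polygon], TraceDiagnostics]:
    """Trace closed outlines through the boundary pixels of one class.

    Seeds at the lexicographically smallest remaining boundary pixel
    and walks pixel to pixel, scanning candidates clockwise starting
    from the previous step's direction (first step: East), widening the
    Chebyshev search ring up to ``max_search_radius`` on dead ends.
    Every visited pixel is consumed. A chain closes once it has at
    least 3 vertices and re-enters the radius-1 reach of its seed; a
    dead-ended chain still within radius ``max_search_radius`` of the
    seed is closed there, otherwise it is discarded as noise. Reseeds
    until the class's boundary pool is empty.
    """
    mask = boundary.get(class_index)
    diag = TraceDiagnostics()
    if mask is None or not mask.any():
        return [], diag
    remaining = mask.copy()
    h, w = remaining.shape
    rings = _rings(max_search_radius)
    polygons: list[Polygon] = []

    while remaining.any():
        seeds = np.argwhere(remaining)
        start = (int(seeds[0, 0]), int(seeds[0, 1]))  # lexicographic min
        remaining[start] = False
        chain = [start]
        prev_angle = 0.0  # East
        cur = start
        while True:
            if len(chain) >= 3 and max(abs(cur[0] - start[0]),
                                       abs(cur[1] - start[1])) <= 1:
                polygons.append(Polygon(vertices=chain, class_index=class_index))
                break
            nxt = None
            for ring in rings:
                best_key = None
                for dr, dc, ang in ring:
                    r, c = cur[0] + dr, cur[1] + dc
                    if 0 <= r < h and 0 <= c < w and remaining[r, c]:
                        key = (ang - prev_angle) % (2.0 * math.pi)
                        if best_key is None or key < best_key[0]:
                            best_key = (key, r, c, ang)
                if best_key is not None:
                    nxt = best_key
                    break
            if nxt is None:
                # dead end: close if the seed is still within reach
                if len(chain) >= 3 and max(abs(cur[0] - start[0]),
                                           abs(cur[1] - start[1])) <= max_search_radius:
                    polygons.append(Polygon(vertices=chain,
                                            class_index=class_index))
                else:
                    diag.n_noise_chains += 1
                    diag.n_noise_pixels += len(chain)
                break
            _, r, c, ang = nxt
            remaining[r, c] = False
            chain.append((r, c))
            cur = (r, c)
            prev_angle = ang
    return polygons, diag


def shoelace_area(poly: Polygon | list[tuple[int, int]]) -> float:
    """Polygon area ``½ |Σ r_i × r_{i+1}|`` in pixel² units.

    Orientation-independent; degenerate inputs (< 3 vertices) have
    area 0.
    """
    verts = poly.vertices if isinstance(poly, Polygon) else poly
    if len(verts) < 3:
        return 0.0
    v = np.asarray(verts, dtype=np.float64)
    r, c = v[:, 0], v[:, 1]
    r2, c2 = np.roll(r, -1), np.roll(c, -1)
    return float(abs(np.sum(r * c2 - r2 * c)) / 2.0)


def filter_small(polys: list[Polygon], seg_shape: tuple[int, int],
                 min_fraction: float = 0.0025) -> list[Polygon]:
    """Keep polygons whose shoelace area is >= min_fraction * H * W.

    With the default 0.25 % on a 160 x 160 map the threshold is 64
    pixels; the comparison is inclusive (area exactly at the threshold
    is kept).
    """
    threshold = min_fraction * seg_shape[0] * seg_shape[1]
    return [p for p in polys if shoelace_area(p) >= threshold]


def render_overlay(img: np.ndarray, polys: list[Polygon],
                   scheme: ClassScheme = DEFAULT_SCHEME) -> np.ndarray:
    """Draw 1-pixel class-coloured polyline loops on a copy of the image."""
    img = np.asarray(img, dtype=np.float64)
    out = img.copy()
    for poly in polys:
        color = scheme.color_of[poly.class_index]
        verts = poly.vertices
        for i in range(len(verts)):
            r0, c0 = verts[i]
            r1, c1 = verts[(i + 1) % len(verts)]
            rr, cc = draw_line(r0, c0, r1, c1)
            out[rr, cc] = color
    return out


def rasterize(poly: Polygon, shape: tuple[int, int]) -> np.ndarray:
    """Filled boolean mask of the polygon (boundary pixels included)."""
    from skimage.draw import polygon as draw_polygon
    v = np.asarray(poly.vertices)
    mask = np.zeros(shape, dtype=bool)
    rr, cc = draw_polygon(v[:, 0], v[:, 1], shape=shape)
    mask[rr, cc] = True
    for i in range(len(poly)):
        r0, c0 = poly.vertices[i]
        r1, c1 = poly.vertices[(i + 1) % len(poly)]
        rr, cc = draw_line(r0, c0, r1, c1)
        mask[rr, cc] = True
    return mask


def segmap_to_polygons(seg: np.ndarray,
                       config: PolygonConfig | None = None
                       ) -> tuple[list[Polygon], TraceDiagnostics]:
    """Simplify, find boundaries, trace each non-background class, filter.

    The normal-tissue class is never outlined.
    """
    config = config or PolygonConfig()
    seg = _check_seg(seg)
    simplified = simplify_boundary(seg, config.simplify_passes)
    boundary = find_boundaries(simplified)
    polys: list[Polygon] = []
    diag = TraceDiagnostics()
    for c in sorted(boundary):
        if c == NORMAL:
            continue
        p, d = trace_contour(boundary, c, config.max_search_radius)
        polys.extend(p)
        diag.n_noise_chains += d.n_noise_chains
        diag.n_noise_pixels += d.n_noise_pixels
    return filter_small(polys, seg.shape, config.min_area_frac), diag
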