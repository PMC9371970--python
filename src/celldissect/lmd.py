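"""Laser-microdissection planning: contours, offsets, cut order, registration.

Turns classified objects into an executable cut plan for an LMD
microscope: polygonize mask objects into physical-coordinate contours,
apply an outward safety offset so the laser never clips the object of
interest, order the cuts to minimize stage travel, register scan
coordinates onto the cutting stage via fiducial landmarks, route contours
into 384-well plate wells, and export/import the plan as XML.

Contour XML dialect (all coordinates integer nanometers, round-half-up):

    <ImageData>
      <GlobalCoordinates>1</GlobalCoordinates>
      <Calibration_0><X>...</X><Y>...</Y></Calibration_0>   (three points)
      ...
      <ShapeCount>N</ShapeCount>
      <Shape_1>
        <PointCount>M</PointCount>
        <CapID>A1</CapID>
        <X_1>...</X_1><Y_1>...</Y_1> ... <X_M>...</X_M><Y_M>...</Y_M>
      </Shape_1>
      ...
    </ImageData>

This dialect is this package's own documented stand-in for proprietary
vendor schemas; adapters for other dialects can be layered on the reader.
"""

from __future__ import annotations

import itertools
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from shapely.geometry.polygon import orient
from skimage.measure import find_contours

from .segmentation import LabelMask

__all__ = [
    "Contour",
    "AffineTransform",
    "CutPlan",
    "mask_to_contours",
    "offset_contour",
    "order_cuts",
    "register_coordinates",
    "theoretical_accuracy_um",
    "estimate_cell_count",
    "assign_wells",
    "well_ids_384",
    "write_cutplan_xml",
    "read_cutplan_xml",
]


@dataclass(frozen=True)
class Contour:
    """Closed simple polygon in physical µm coordinates, CCW orientation.

    Vertices are an (n, 2) array of (x, y); the closing edge back to the
    first vertex is implied.  "CCW" means positive shoelace signed area in
    the stored (x, y) coordinates.
    """

    object_id: int
    vertices: np.ndarray
    class_label: int | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ValueError("contour needs an (n>=3, 2) vertex array")
        if np.allclose(v[0], v[-1]) and len(v) > 3:
            v = v[:-1]
        poly = Polygon(v)
        if not poly.is_valid or poly.area <= 0:
            raise ValueError(f"contour {self.object_id}: not a simple positive-area polygon")
        if not poly.exterior.is_ccw:
            v = v[::-1].copy()
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        return self.polygon.area

    @property
    def centroid_um(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass(frozen=True)
class AffineTransform:
    """2D affine map x ↦ A x + b (µm → µm) with its fit residual."""

    matrix: np.ndarray  # (2, 2)
    translation: np.ndarray  # (2,)
    rms_residual_um: float = 0.0

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        b = np.asarray(self.translation, dtype=float).reshape(2)
        if abs(np.linalg.det(A)) < 1e-15:
            raise ValueError("affine linear part is singular")
        object.__setattr__(self, "matrix", A)
        object.__setattr__(self, "translation", b)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + self.translation

    def inverse(self) -> "AffineTransform":
        Ainv = np.linalg.inv(self.matrix)
        return AffineTransform(Ainv, -Ainv @ self.translation, self.rms_residual_um)


@dataclass(frozen=True)
class CutPlan:
    """Ordered, offset contours routed to 384-well plate wells."""

    contours: list[Contour]
    wells: list[str]
    offset_um: float
    total_travel_um: float
    well_summary: dict[str, dict]  # well -> {n_objects, total_area_um2, estimated_cells}

    def __post_init__(self) -> None:
        if len(self.contours) != len(self.wells):
            raise ValueError("one well id per contour required")
        valid = set(well_ids_384())
        bad = [w for w in self.wells if w not in valid]
        if bad:
            raise ValueError(f"invalid 384-well ids: {sorted(set(bad))}")


def well_ids_384() -> list[str]:
    """All 384-well plate well ids, row-major A1..P24."""
    return [f"{r}{c}" for r in "ABCDEFGHIJKLMNOP" for c in range(1, 25)]


def mask_to_contours(mask: LabelMask) -> list[Contour]:
    """Polygonize each labeled object into one outer contour in µm.

    Uses the marching-squares boundary at the 0.5 level; holes are
    discarded (the laser cuts outer boundaries only).  Objects whose
    boundary degenerates below 3 vertices are skipped.
    """
    px = mask.pixel_size_um
    out: list[Contour] = []
    for idx, sl in enumerate(ndi.find_objects(mask.labels), start=1):
        if sl is None:
            continue
        obj = (mask.labels[sl] == idx).astype(float)
        padded = np.pad(obj, 1)
        contours = find_contours(padded, 0.5)
        if not contours:
            continue
        boundary = max(contours, key=lambda c: Polygon(c).area if len(c) >= 3 else 0.0)
        if len(boundary) < 3:
            continue
        rows = boundary[:, 0] - 1 + sl[0].start
        cols = boundary[:, 1] - 1 + sl[1].start
        verts = np.column_stack([(cols + 0.5) * px, (rows + 0.5) * px])
        try:
            out.append(Contour(object_id=idx, vertices=verts))
        except ValueError:
            continue
    return out


def offset_contour(c: Contour, offset_um: float, quad_segs: int = 32) -> Contour:
    """Outward safety offset: Minkowski buffer with round joins.

    The returned contour strictly contains the input; offset 0 returns the
    contour unchanged.  Negative offsets are rejected — the laser must
    never cut inside the object of interest.
    """
    if offset_um < 0:
        raise ValueError("offset must be non-negative")
    if offset_um == 0:
        return c
    buffered = c.polygon.buffer(offset_um, quad_segs=quad_segs, join_style="round")
    ext = orient(Polygon(buffered.exterior.coords), sign=1.0)
    return replace(c, vertices=np.asarray(ext.exterior.coords)[:-1])


def _path_length(points: np.ndarray, order: np.ndarray, start: np.ndarray) -> float:
    path = np.vstack([start, points[order]])
    return float(np.sqrt(((np.diff(path, axis=0)) ** 2).sum(axis=1)).sum())


def _held_karp(points: np.ndarray, start: np.ndarray) -> np.ndarray:
    """Exact open-path TSP from a fixed start over <= ~12 points."""
    n = len(points)
    d0 = np.sqrt(((points - start) ** 2).sum(axis=1))
    D = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=2))
    full = 1 << n
    INF = math.inf
    cost = np.full((full, n), INF)
    parent = np.full((full, n), -1, dtype=int)
    for j in range(n):
        cost[1 << j, j] = d0[j]
    for mask in range(full):
        for j in range(n):
            cj = cost[mask, j]
            if not (mask >> j) & 1 or cj == INF:
                continue
            for k in range(n):
                if (mask >> k) & 1:
                    continue
                nm = mask | (1 << k)
                nc = cj + D[j, k]
                if nc < cost[nm, k] - 1e-12:
                    cost[nm, k] = nc
                    parent[nm, k] = j
    last = int(np.argmin(cost[full - 1]))
    order = [last]
    mask = full - 1
    while parent[mask, order[-1]] >= 0:
        p = parent[mask, order[-1]]
        mask ^= 1 << order[-1]
        order.append(p)
    return np.array(order[::-1])


def _two_opt(points: np.ndarray, order: np.ndarray, start: np.ndarray) -> np.ndarray:
    best = order.copy()
    best_len = _path_length(points, best, start)
    improved = True
    while improved:
        improved = False
        for i in range(len(best) - 1):
            for j in range(i + 1, len(best)):
                cand = best.copy()
                cand[i : j + 1] = cand[i : j + 1][::-1]
                cl = _path_length(points, cand, start)
                if cl < best_len - 1e-12:
                    best, best_len = cand, cl
                    improved = True
    return best


def order_cuts(
    contours: list[Contour], start: tuple[float, float] = (0.0, 0.0), exact_max: int = 10
) -> tuple[list[Contour], float]:
    """Order contours to minimize stage travel between cut centroids.

    Travel is the open-path length start → centroid₁ → … → centroidₙ.
    Exact dynamic-programming solution for n ≤ ``exact_max``; beyond that,
    nearest-neighbor construction refined by 2-opt.  Deterministic: ties
    broken by ascending object_id via a stable pre-sort.
    """
    if not contours:
        raise ValueError("order_cuts requires at least one contour")
    contours = sorted(contours, key=lambda c: c.object_id)
    pts = np.array([c.centroid_um for c in contours])
    s = np.asarray(start, dtype=float)
    n = len(contours)
    if n == 1:
        return list(contours), _path_length(pts, np.array([0]), s)
    if n <= exact_max:
        order = _held_karp(pts, s)
    else:
        remaining = list(range(n))
        order_list = []
        cur = s
        while remaining:
            dists = [float(np.hypot(*(pts[i] - cur))) for i in remaining]
            pick = remaining[int(np.argmin(dists))]
            order_list.append(pick)
            remaining.remove(pick)
            cur = pts[pick]
        order = _two_opt(pts, np.array(order_list), s)
    return [contours[i] for i in order], _path_length(pts, order, s)


def register_coordinates(
    fiducials_scan: np.ndarray, fiducials_stage: np.ndarray
) -> AffineTransform:
    """Least-squares affine fit from scan to stage coordinates.

    Needs at least 3 non-collinear fiducial pairs; reports the RMS
    residual in µm so bad fiducials are visible.
    """
    src = np.asarray(fiducials_scan, dtype=float).reshape(-1, 2)
    dst = np.asarray(fiducials_stage, dtype=float).reshape(-1, 2)
    if src.shape != dst.shape or len(src) < 3:
        raise ValueError("need >= 3 fiducial pairs of matching length")
    centered = src - src.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max())) < 2:
        raise ValueError("fiducials are collinear; affine fit is degenerate")
    design = np.column_stack([src, np.ones(len(src))])
    params, *_ = np.linalg.lstsq(design, dst, rcond=None)
    A = params[:2].T
    b = params[2]
    tf = AffineTransform(A, b)
    resid = tf.apply(src) - dst
    rms = float(np.sqrt((resid**2).sum(axis=1).mean()))
    return AffineTransform(A, b, rms)


def theoretical_accuracy_um(objective_magnification: float) -> float:
    """Theoretical LMD cutting accuracy in µm for a given objective.

    10 / magnification µm — e.g. 10/150 ≈ 0.067 µm (~70 nm) for a ×150
    objective.
    """
    if objective_magnification <= 0:
        raise ValueError("magnification must be positive")
    return 10.0 / objective_magnification


def estimate_cell_count(
    total_area_um2: float, thickness_um: float, cell_volume_um3: float = 2000.0
) -> float:
    """Cells contained in a dissected area: area × section thickness / cell volume.

    The default 2,000 µm³ is the average mammalian cell volume; e.g.
    160,000 µm² of a 2.5 µm section ≈ 200 cells.
    """
    if total_area_um2 < 0 or thickness_um <= 0 or cell_volume_um3 <= 0:
        raise ValueError("area must be >= 0; thickness and volume positive")
    return total_area_um2 * thickness_um / cell_volume_um3


def assign_wells(
    ordered_contours: list[Contour],
    per_class_well: dict[int, str] | None = None,
    objects_per_well: int | None = None,
    offset_um: float = 0.0,
    total_travel_um: float = 0.0,
    section_thickness_um: float = 2.5,
    cell_volume_um3: float = 2000.0,
    start_well: str = "A1",
) -> CutPlan:
    """Route ordered contours into 384-well plate wells.

    Exactly one routing mode: ``per_class_well`` sends every contour of a
    class to its stated well (so per-class samples can be normalized by
    collected object count), or ``objects_per_well`` fills consecutive
    wells from ``start_well`` with fixed-size batches.  The plan reports
    per-well object counts, summed contour area and the estimated cell
    count for that area.
    """
    if (per_class_well is None) == (objects_per_well is None):
        raise ValueError("specify exactly one of per_class_well / objects_per_well")
    all_wells = well_ids_384()
    if not ordered_contours:
        return CutPlan([], [], offset_um, total_travel_um, {})
    wells: list[str] = []
    if per_class_well is not None:
        for c in ordered_contours:
            if c.class_label not in per_class_well:
                raise KeyError(f"no well assigned for class {c.class_label!r}")
            wells.append(per_class_well[c.class_label])
    else:
        if objects_per_well <= 0:
            raise ValueError("objects_per_well must be positive")
        first = all_wells.index(start_well)
        n_wells = math.ceil(len(ordered_contours) / objects_per_well)
        if first + n_wells > len(all_wells):
            raise ValueError("plan exceeds plate capacity")
        for i in range(len(ordered_contours)):
            wells.append(all_wells[first + i // objects_per_well])
    summary: dict[str, dict] = {}
    for c, w in zip(ordered_contours, wells):
        s = summary.setdefault(w, {"n_objects": 0, "total_area_um2": 0.0})
        s["n_objects"] += 1
        s["total_area_um2"] += c.area_um2
    for s in summary.values():
        s["estimated_cells"] = estimate_cell_count(
            s["total_area_um2"], section_thickness_um, cell_volume_um3
        )
    return CutPlan(list(ordered_contours), wells, offset_um, total_travel_um, summary)


def _nm(value_um: float) -> int:
    """µm → integer nm, round half up (toward +∞)."""
    return int(math.floor(value_um * 1000.0 + 0.5))


def write_cutplan_xml(path, plan: CutPlan, calibration_points_um: np.ndarray) -> None:
    """Write a cut plan in the package's LMD contour XML dialect.

    ``calibration_points_um`` are the three stage fiducials, shape (3, 2),
    in µm; all coordinates are stored as integer nanometers.
    """
    cal = np.asarray(calibration_points_um, dtype=float).reshape(-1, 2)
    if len(cal) != 3:
        raise ValueError("exactly three calibration points required")
    root = ET.Element("ImageData")
    ET.SubElement(root, "GlobalCoordinates").text = "1"
    for i, (x, y) in enumerate(cal):
        el = ET.SubElement(root, f"Calibration_{i}")
        ET.SubElement(el, "X").text = str(_nm(x))
        ET.SubElement(el, "Y").text = str(_nm(y))
    ET.SubElement(root, "ShapeCount").text = str(len(plan.contours))
    for i, (c, well) in enumerate(zip(plan.contours, plan.wells), start=1):
        shape = ET.SubElement(root, f"Shape_{i}")
        ET.SubElement(shape, "PointCount").text = str(len(c.vertices))
        ET.SubElement(shape, "CapID").text = well
        for j, (x, y) in enumerate(c.vertices, start=1):
            ET.SubElement(shape, f"X_{j}").text = str(_nm(x))
            ET.SubElement(shape, f"Y_{j}").text = str(_nm(y))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def read_cutplan_xml(path) -> tuple[list[Contour], list[str], np.ndarray]:
    """Read the LMD contour XML dialect back.

    Returns ``(contours, wells, calibration_points_um)``; vertex
    coordinates are exact integer-nanometer values divided by 1000.
    """
    root = ET.parse(path).getroot()
    if root.tag != "ImageData":
        raise ValueError(f"not an LMD contour file (root {root.tag!r})")
    cal = []
    for i in itertools.count():
        el = root.find(f"Calibration_{i}")
        if el is None:
            break
        cal.append([int(el.findtext("X")) / 1000.0, int(el.findtext("Y")) / 1000.0])
    shape_count = int(root.findtext("ShapeCount"))
    contours: list[Contour] = []
    wells: list[str] = []
    for i in range(1, shape_count + 1):
        shape = root.find(f"Shape_{i}")
        if shape is None:
            raise ValueError(f"missing Shape_{i}")
        n_pts = int(shape.findtext("PointCount"))
        verts = np.array(
            [
                [int(shape.findtext(f"X_{j}")) / 1000.0, int(shape.findtext(f"Y_{j}")) / 1000.0]
                for j in range(1, n_pts + 1)
            ]
        )
        contours.append(Contour(object_id=i, vertices=verts))
        wells.append(shape.findtext("CapID"))
    return contours, wells, np.array(cal)
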