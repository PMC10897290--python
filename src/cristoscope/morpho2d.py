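"""Projection-plane morphometry: areas, coverage, densities, junction geometry.

These are the measurements read off summed projection images: mitochondrial
outline area (shoelace over a picked polygon), field coverage, cristae count
per area, matrix gray density along probe lines, and crista-junction width
and angle.  Junction and outline picks are inputs (from ground truth or
interactive picking) — localisation is not automated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon

from .volio import Image2D

__all__ = [
    "JunctionRecord",
    "MitoOutline",
    "polygon_area",
    "mito_coverage",
    "cristae_density",
    "matrix_density",
    "junction_width",
    "junction_angle",
    "aggregate_junction",
]

NM2_TO_UM2 = 1e-6


@dataclass
class JunctionRecord:
    """Measurements of one crista junction, possibly from several sections.

    When a junction is visible in multiple non-overlapping sections, each
    section contributes one width and one angle measurement; the record's
    summary values are the arithmetic means over those measurements.
    """

    junction_id: int
    crista_id: int
    width_measurements_nm: list[float] = field(default_factory=list)
    angle_measurements_deg: list[float] = field(default_factory=list)
    width_nm: float | None = None
    angle_deg: float | None = None


@dataclass
class MitoOutline:
    """A picked mitochondrial outline on a projection image."""

    mito_id: int
    vertices_px: np.ndarray  # (n, 2) as (row, col)
    shape_class: str = "ellipsoidal"
    area_um2: float | None = None


def polygon_area(vertices_px: np.ndarray, pixel_size_nm: float) -> float:
    """Shoelace area of a picked outline, in um^2.

    ``vertices_px`` is an ordered (n, 2) array of pixel coordinates; the
    result is orientation-independent.  Degenerate (collinear) or
    self-intersecting outlines raise a geometry error.
    """
    vertices_px = np.asarray(vertices_px, dtype=float)
    if vertices_px.ndim != 2 or vertices_px.shape[0] < 3:
        raise ValueError("an outline needs at least 3 vertices")
    poly = Polygon(vertices_px)
    if not poly.is_valid:
        raise ValueError("outline is self-intersecting or otherwise invalid")
    if poly.area == 0:
        raise ValueError("outline vertices are collinear")
    return poly.area * pixel_size_nm**2 * NM2_TO_UM2


def mito_coverage(area_um2: float, image: Image2D) -> float:
    """Fraction of the projected field covered by one mitochondrion."""
    h, w = image.data.shape
    field_um2 = h * w * image.pixel_size_nm**2 * NM2_TO_UM2
    if field_um2 == 0:
        raise ValueError("image has zero area")
    if area_um2 > field_um2 * (1 + 1e-9):
        raise ValueError("mitochondrial area exceeds the image area")
    return min(area_um2 / field_um2, 1.0)


def cristae_density(n_cristae: int, area_um2: float) -> float:
    """Cristae count normalized by mitochondrial area (per um^2)."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if n_cristae < 0:
        raise ValueError("negative crista count")
    return n_cristae / area_um2


def _sample_line(image: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Bilinear samples along a segment at <= 0.5 px spacing (FIJI-style)."""
    length = np.linalg.norm(p2 - p1)
    n = max(int(np.ceil(length / 0.5)) + 1, 2)
    ts = np.linspace(0.0, 1.0, n)
    pts = p1[None, :] + ts[:, None] * (p2 - p1)[None, :]
    return ndimage.map_coordinates(image, pts.T, order=1, mode="nearest")


def matrix_density(image: Image2D, probes) -> float:
    """Mean gray value of the matrix from exactly three probe lines.

    ``probes`` is a sequence of three ((row, col), (row, col)) segments drawn
    inside the matrix region of a contrast-normalized projection; each line
    is sampled bilinearly at half-pixel steps, and the three per-line means
    are averaged into a single density value per mitochondrion.
    """
    probes = list(probes)
    if len(probes) != 3:
        raise ValueError(f"matrix density uses exactly 3 probe lines, got {len(probes)}")
    h, w = image.data.shape
    means = []
    for p1, p2 in probes:
        p1 = np.asarray(p1, dtype=float)
        p2 = np.asarray(p2, dtype=float)
        for p in (p1, p2):
            if not (0 <= p[0] <= h - 1 and 0 <= p[1] <= w - 1):
                raise IndexError(f"probe endpoint {tuple(p)} outside image {image.data.shape}")
        means.append(float(np.mean(_sample_line(np.asarray(image.data, float), p1, p2))))
    return float(np.mean(means))


def junction_width(p1, p2, pixel_size_nm: float) -> float:
    """Euclidean distance between the two membrane points delimiting a CJ, nm."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    d = np.linalg.norm(p2 - p1)
    if d == 0:
        raise ValueError("junction endpoints coincide")
    return float(d * pixel_size_nm)


def junction_angle(vertex, ray_a, ray_b) -> float:
    """Interior angle at ``vertex`` between two picked rays, in (0, 180].

    For crista junctions, ``ray_a`` follows the local inner boundary membrane
    and ``ray_b`` the crista axis, so a crista perpendicular to the boundary
    scores 90 degrees.
    """
    vertex = np.asarray(vertex, dtype=float)
    a = np.asarray(ray_a, dtype=float) - vertex
    b = np.asarray(ray_b, dtype=float) - vertex
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero-length ray")
    cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def aggregate_junction(record: JunctionRecord) -> JunctionRecord:
    """Set a junction's summary width/angle to the means of its measurements."""
    if not record.width_measurements_nm or not record.angle_measurements_deg:
        raise ValueError("junction record has empty measurement lists")
    record.width_nm = float(np.mean(record.width_measurements_nm))
    record.angle_deg = float(np.mean(record.angle_measurements_deg))
    return record
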