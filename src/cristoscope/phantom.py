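"""Synthetic cryo-ET phantoms of mitochondria with known ground truth.

The generator renders a double-membrane mitochondrion (outer membrane, inner
boundary membrane, intermembrane space, matrix) as nested ellipsoids, carves
cristae of specified shape/width/junction geometry into the matrix, and then
corrupts the density the way a tomographic reconstruction is corrupted:
membranes dark, additive Gaussian noise, and a missing wedge in Fourier space
consistent with a limited tilt range (a +/-70 deg tilt series leaves a 20 deg
half-angle wedge around the beam axis unsampled).

Conventions
-----------
* axis order (z, y, x); beam along z, tilt axis along y
* 0-based voxel indices; all metric fields in nm (volumes in um^3)
* membranes are LOW intensity (dark), as in cryo-ET
* a crista's ``width_nm`` is the membrane centre-to-centre distance, i.e. the
  trough-to-trough distance of the density profile across the crista; the
  lumen clearance is ``width_nm - membrane_thickness_nm``
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .labels import Compartment
from .volio import Tomogram

__all__ = [
    "CristaSpec",
    "JunctionSpec",
    "PhantomSpec",
    "GroundTruth",
    "GeometryError",
    "generate_phantom",
    "apply_missing_wedge",
    "sample_particles",
    "noise_sigma_for_snr",
    "analytic_shell_volumes",
    "exemplar_cristae",
]

NM3_TO_UM3 = 1e-9

SHAPE_CLASSES = (
    "lamellar",
    "tubular",
    "globular",
    "ring",
    "loop",
    "straight_across",
    "split",
)


class GeometryError(ValueError):
    """Raised when a phantom's geometry is inconsistent."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class JunctionSpec:
    """A crista junction: where the crista membrane meets the IBM.

    ``angle_deg`` is the angle between the crista axis and the local IBM,
    with 90 deg meaning the crista is perpendicular to the boundary membrane.
    """

    angle_deg: float = 90.0
    width_nm: float = 20.0
    position_nm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0 < self.angle_deg < 180:
            raise ValueError(f"junction angle must be in (0, 180), got {self.angle_deg}")
        if not self.width_nm > 0:
            raise ValueError("junction width must be positive")


@dataclass
class CristaSpec:
    """Geometry of one crista.

    ``width_nm`` is the membrane centre-to-centre distance across the crista
    (slab thickness for lamellar cristae, tube diameter for tubular ones).
    ``length_nm`` is the extent along the main axis (circumference for rings,
    arc length for loops).  ``orientation`` is the sheet normal for lamellar
    shapes and the long axis for tubular ones, in (z, y, x) order.
    """

    shape_class: str
    width_nm: float
    length_nm: float
    center_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    height_nm: float | None = None
    junctions: list[JunctionSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.shape_class not in SHAPE_CLASSES:
            raise ValueError(
                f"unknown shape_class {self.shape_class!r}; expected one of {SHAPE_CLASSES}"
            )
        if not self.width_nm > 0:
            raise ValueError("width_nm must be positive")
        if not self.length_nm > 0:
            raise ValueError("length_nm must be positive")
        n_j = len(self.junctions)
        if self.shape_class == "ring" and n_j != 0:
            raise ValueError("ring cristae are closed: junction count must be 0")
        if self.shape_class in ("loop", "straight_across") and n_j != 2:
            raise ValueError(f"{self.shape_class} cristae must carry exactly 2 junctions")
        n = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(n)
        if norm == 0:
            raise ValueError("orientation must be a nonzero vector")
        self.orientation = tuple(n / norm)

    @property
    def sheet_height_nm(self) -> float:
        return self.height_nm if self.height_nm is not None else 0.75 * self.length_nm


@dataclass
class PhantomSpec:
    """Full description of a synthetic mitochondrion tomogram.

    Defaults follow the imaging frame of the width-measurement pipeline:
    2.2 nm voxels and a 20 deg missing-wedge half-angle (tilt range +/-70 deg).
    ``semi_axes_nm`` are the outer-membrane ellipsoid semi-axes in (z, y, x).
    ``ibm_offset_nm`` is the OMM->IBM gap (the intermembrane spacing).
    """

    box_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_nm: float = 2.2
    semi_axes_nm: tuple[float, float, float] = (80.0, 90.0, 95.0)
    center_nm: tuple[float, float, float] | None = None
    ibm_offset_nm: float = 10.0
    cristae: list[CristaSpec] = field(default_factory=list)
    membrane_thickness_nm: float = 5.0
    membrane_density: float = -1.0
    solvent_density: float = 0.0
    smoothing_sigma_px: float = 1.0
    noise_sigma: float = 0.0
    wedge_half_angle_deg: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.voxel_size_nm > 0:
            raise ValueError("voxel_size_nm must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 <= self.wedge_half_angle_deg <= 90:
            raise ValueError("wedge_half_angle_deg must be in [0, 90]")
        if self.membrane_density >= self.solvent_density:
            raise ValueError("membranes must be darker than solvent")
        t = self.membrane_thickness_nm
        if not t > 0:
            raise ValueError("membrane_thickness_nm must be positive")
        if min(self.semi_axes_nm) <= 2 * t:
            raise GeometryError("semi-axes must exceed twice the membrane thickness")
        if min(self.semi_axes_nm) - 2 * t - self.ibm_offset_nm <= 0:
            raise GeometryError("no matrix interior left after membranes and IMS gap")

    @property
    def center(self) -> np.ndarray:
        if self.center_nm is not None:
            return np.asarray(self.center_nm, dtype=float)
        return (np.asarray(self.box_shape, dtype=float) - 1) / 2.0 * self.voxel_size_nm


@dataclass
class GroundTruth:
    """Known truth for a rendered phantom: the downstream oracle.

    ``volumes_um3`` are measured on the rendered label volume (the phantom's
    true voxelized compartments); ``midplane_sites`` maps crista index to
    (voxel coordinates, unit normals) of crista mid-plane voxels, the sites
    particle sampling draws from.
    """

    cristae: list[dict]
    junctions: list[dict]
    volumes_um3: dict[str, float]
    midplane_sites: dict[int, tuple[np.ndarray, np.ndarray]]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        return pd.DataFrame(self.cristae), pd.DataFrame(self.junctions)

    def save(self, csv_prefix: str) -> None:
        cristae, junctions = self.to_frames()
        cristae.to_csv(f"{csv_prefix}_cristae.csv", index=False)
        junctions.to_csv(f"{csv_prefix}_junctions.csv", index=False)
        with open(f"{csv_prefix}_volumes.json", "w") as fh:
            json.dump(self.volumes_um3, fh, indent=2)


# ---------------------------------------------------------------------------
# Geometry primitives (signed distance to the membrane mid-surface, in nm)
# ---------------------------------------------------------------------------


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic right-handed frame (u, v, s) from a unit vector u."""
    u = u / np.linalg.norm(u)
    helper = np.zeros(3)
    helper[int(np.argmin(np.abs(u)))] = 1.0
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    s = np.cross(u, v)
    return u, v, s


def _box_sdf(u, v, s, half: tuple[float, float, float]) -> np.ndarray:
    qu = np.abs(u) - half[0]
    qv = np.abs(v) - half[1]
    qs = np.abs(s) - half[2]
    outside = np.sqrt(
        np.maximum(qu, 0) ** 2 + np.maximum(qv, 0) ** 2 + np.maximum(qs, 0) ** 2
    )
    inside = np.minimum(np.maximum(qu, np.maximum(qv, qs)), 0)
    return outside + inside


def _segment_sdf(u, v, s, axis_len: float, radius: float) -> np.ndarray:
    """Capsule along the u axis, tip-to-tip length axis_len (incl. caps)."""
    h = max(axis_len / 2.0 - radius, 0.0)
    uc = np.clip(u, -h, h)
    return np.sqrt((u - uc) ** 2 + v**2 + s**2) - radius


def _crista_core_sdf(crista: CristaSpec, u, v, s) -> np.ndarray:
    """Signed distance (nm) to the region bounded by the membrane mid-surface."""
    w = crista.width_nm
    L = crista.length_nm
    cls = crista.shape_class
    if cls in ("lamellar", "straight_across"):
        span = 1e4 if cls == "straight_across" else L
        return _box_sdf(u, v, s, (w / 2.0, span / 2.0, crista.sheet_height_nm / 2.0))
    if cls == "tubular":
        return _segment_sdf(u, v, s, L, w / 2.0)
    if cls == "globular":
        return np.sqrt(u**2 + v**2 + s**2) - w / 2.0
    if cls == "ring":
        R = L / (2 * np.pi)
        rho = np.sqrt(v**2 + s**2)
        return np.sqrt((rho - R) ** 2 + u**2) - w / 2.0
    if cls == "loop":
        # half-torus: arc in the s >= 0 half of the (v, s) plane, spherical caps
        R = L / np.pi
        rho = np.sqrt(v**2 + s**2)
        d_arc = np.sqrt((rho - R) ** 2 + u**2) - w / 2.0
        d_cap_a = np.sqrt((v - R) ** 2 + s**2 + u**2) - w / 2.0
        d_cap_b = np.sqrt((v + R) ** 2 + s**2 + u**2) - w / 2.0
        return np.where(s >= 0, d_arc, np.minimum(d_cap_a, d_cap_b))
    if cls == "split":
        # Y: stem along -v plus two branches diverging at +/-45 deg in (v, s)
        r = w / 2.0
        stem = _segment_sdf(v + L / 4.0, u, s, L / 2.0, r)
        c, si = np.cos(np.pi / 4), np.sin(np.pi / 4)
        arm_len = L / 2.0
        # branch axes: (v, s) rotated; each branch starts at the origin
        for sign in (1.0, -1.0):
            av = c * v + sign * si * s - arm_len / 2.0
            aperp1 = -sign * si * v + c * s
            d = _segment_sdf(av, u, aperp1, arm_len, r)
            stem = np.minimum(stem, d)
        return stem
    raise ValueError(f"unhandled shape_class {cls!r}")  # pragma: no cover


def _crista_normal(crista: CristaSpec, frame, points_nm: np.ndarray) -> np.ndarray:
    """Unit membrane-pair normal at crista mid-plane points (world frame)."""
    u_ax, v_ax, s_ax = frame
    n = points_nm.shape[0]
    cls = crista.shape_class
    if cls in ("lamellar", "straight_across"):
        return np.tile(u_ax, (n, 1))
    if cls in ("tubular", "split"):
        # radial: perpendicular component of the offset from the axis
        rad = points_nm - np.outer(points_nm @ u_ax, u_ax)
        norms = np.linalg.norm(rad, axis=1, keepdims=True)
        out = np.where(norms > 1e-9, rad / np.maximum(norms, 1e-9), u_ax)
        return out
    if cls == "globular":
        norms = np.linalg.norm(points_nm, axis=1, keepdims=True)
        return np.where(norms > 1e-9, points_nm / np.maximum(norms, 1e-9), u_ax)
    # ring / loop: radial in the (rho, u) plane from the centreline circle
    R = crista.length_nm / (2 * np.pi) if cls == "ring" else crista.length_nm / np.pi
    vv = points_nm @ v_ax
    ss = points_nm @ s_ax
    uu = points_nm @ u_ax
    rho = np.sqrt(vv**2 + ss**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        er = np.stack([np.zeros_like(rho), vv / np.maximum(rho, 1e-9), ss / np.maximum(rho, 1e-9)], axis=1)
    vec = (rho - R)[:, None] * (er[:, 1:2] * v_ax + er[:, 2:3] * s_ax) + uu[:, None] * u_ax
    norms = np.linalg.norm(vec, axis=1, keepdims=True)
    return np.where(norms > 1e-9, vec / np.maximum(norms, 1e-9), np.tile(u_ax, (n, 1)))


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _ellipsoid_inside(coords: list[np.ndarray], semi: np.ndarray) -> np.ndarray:
    q = sum((coords[i] / semi[i]) ** 2 for i in range(3))
    return q <= 1.0


def analytic_shell_volumes(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form compartment volumes (um^3) for the crista-free shells.

    Matrix = inner-ellipsoid volume; IMS = shell between the membranes.
    Cristae reduce the matrix and add lumen; those terms depend on clipping
    and are not included here.
    """
    a0 = np.asarray(spec.semi_axes_nm, dtype=float)
    t = spec.membrane_thickness_nm
    g = spec.ibm_offset_nm
    vol = lambda s: 4.0 / 3.0 * np.pi * float(np.prod(s))
    a1, a2, a3 = a0 - t, a0 - t - g, a0 - 2 * t - g
    return {
        "matrix_um3": vol(a3) * NM3_TO_UM3,
        "ims_um3": (vol(a1) - vol(a2)) * NM3_TO_UM3,
        "cl_um3": 0.0,
        "omm_enclosed_um3": vol(a0) * NM3_TO_UM3,
    }


def render_density(labels: np.ndarray, spec: PhantomSpec, smooth: bool = True) -> np.ndarray:
    """Noise-free density from a label volume: membranes dark, solvent flat."""
    membrane = np.isin(
        labels,
        (Compartment.OMM, Compartment.IBM, Compartment.CRISTA_MEMBRANE),
    )
    density = np.full(labels.shape, spec.solvent_density, dtype=np.float64)
    density[membrane] = spec.membrane_density
    if smooth and spec.smoothing_sigma_px > 0:
        density = ndimage.gaussian_filter(density, spec.smoothing_sigma_px)
    return density


def generate_phantom(spec: PhantomSpec) -> tuple[Tomogram, np.ndarray, GroundTruth]:
    """Render a phantom tomogram, its label volume, and ground truth.

    Rendering order: geometry -> Gaussian smoothing -> additive noise ->
    missing wedge (the wedge is the last corruption step, as in a real
    reconstruction).  Identical spec + seed gives a bit-identical volume.
    """
    vx = spec.voxel_size_nm
    center = spec.center
    idx = [np.arange(n, dtype=np.float64) * vx for n in spec.box_shape]
    coords = [
        (idx[0] - center[0])[:, None, None],
        (idx[1] - center[1])[None, :, None],
        (idx[2] - center[2])[None, None, :],
    ]
    a0 = np.asarray(spec.semi_axes_nm, dtype=float)
    t = spec.membrane_thickness_nm
    g = spec.ibm_offset_nm
    a1, a2, a3 = a0 - t, a0 - t - g, a0 - 2 * t - g

    in0 = _ellipsoid_inside(coords, a0)
    in1 = _ellipsoid_inside(coords, a1)
    in2 = _ellipsoid_inside(coords, a2)
    in3 = _ellipsoid_inside(coords, a3)

    labels = np.zeros(spec.box_shape, dtype=np.int16)
    labels[in0 & ~in1] = Compartment.OMM
    labels[in1 & ~in2] = Compartment.IMS
    labels[in2 & ~in3] = Compartment.IBM
    labels[in3] = Compartment.MATRIX

    crista_rows: list[dict] = []
    junction_rows: list[dict] = []
    midplane_sites: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    membrane_any = np.zeros(spec.box_shape, dtype=bool)
    lumen_any = np.zeros(spec.box_shape, dtype=bool)

    for ci, crista in enumerate(spec.cristae):
        frame = _orthonormal_frame(np.asarray(crista.orientation, dtype=float))
        u_ax, v_ax, s_ax = frame
        c = np.asarray(crista.center_nm, dtype=float)
        pz = coords[0] - c[0]
        py = coords[1] - c[1]
        px = coords[2] - c[2]
        u = pz * u_ax[0] + py * u_ax[1] + px * u_ax[2]
        v = pz * v_ax[0] + py * v_ax[1] + px * v_ax[2]
        s = pz * s_ax[0] + py * s_ax[1] + px * s_ax[2]
        d = _crista_core_sdf(crista, u, v, s)

        solid = np.abs(d) <= t / 2.0
        lumen = d < -t / 2.0
        if not np.any((solid | lumen) & in3):
            raise GeometryError(f"crista {ci} ({crista.shape_class}) lies outside the matrix")
        if len(crista.junctions) == 0 and np.any(solid & ~in3):
            raise GeometryError(
                f"crista {ci} ({crista.shape_class}) exceeds the IBM interior "
                "but declares no junctions"
            )
        membrane_any |= solid & in3
        lumen_any |= lumen & in3

        mid = (d <= -crista.width_nm / 2.0 + vx) & in3
        zz, yy, xx = np.nonzero(mid)
        pts_local = (
            np.stack([zz, yy, xx], axis=1) * vx
            - center[None, :]
            - c[None, :]
        )
        normals = _crista_normal(crista, frame, pts_local)
        midplane_sites[ci] = (np.stack([zz, yy, xx], axis=1), normals)

        crista_rows.append(
            {
                "crista_id": ci,
                "shape_class": crista.shape_class,
                "width_nm": crista.width_nm,
                "length_nm": crista.length_nm,
                "n_junctions": len(crista.junctions),
                "orientation_z": u_ax[0],
                "orientation_y": u_ax[1],
                "orientation_x": u_ax[2],
            }
        )
        for ji, j in enumerate(crista.junctions):
            pos = j.position_nm
            if pos is None:
                # walk the crista's long axis outward to the IBM mid-surface
                sign = 1.0 if ji % 2 == 0 else -1.0
                pos = tuple(_ray_to_ellipsoid(c + center, sign * v_ax, center, a2 - t / 2))
            junction_rows.append(
                {
                    "junction_id": len(junction_rows),
                    "crista_id": ci,
                    "angle_deg": j.angle_deg,
                    "width_nm": j.width_nm,
                    "pos_z_nm": pos[0],
                    "pos_y_nm": pos[1],
                    "pos_x_nm": pos[2],
                }
            )

    labels[membrane_any] = Compartment.CRISTA_MEMBRANE
    labels[lumen_any & ~membrane_any] = Compartment.CRISTA_LUMEN

    voxel_um3 = (vx**3) * NM3_TO_UM3
    volumes = {
        "matrix_um3": int(np.sum(labels == Compartment.MATRIX)) * voxel_um3,
        "ims_um3": int(np.sum(labels == Compartment.IMS)) * voxel_um3,
        "cl_um3": int(np.sum(labels == Compartment.CRISTA_LUMEN)) * voxel_um3,
    }
    ground = GroundTruth(
        cristae=crista_rows,
        junctions=junction_rows,
        volumes_um3=volumes,
        midplane_sites=midplane_sites,
    )

    density = render_density(labels, spec, smooth=True)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        density = density + rng.normal(0.0, spec.noise_sigma, size=density.shape)
    tomo = Tomogram(
        data=density.astype(np.float32),
        voxel_size_nm=vx,
        meta={"phantom": True, "seed": spec.seed},
    )
    if spec.wedge_half_angle_deg > 0:
        tomo = apply_missing_wedge(tomo, spec.wedge_half_angle_deg)
    return tomo, labels, ground


def _ray_to_ellipsoid(origin, direction, center, semi) -> np.ndarray:
    """Point where the ray origin + t*direction crosses the ellipsoid surface."""
    o = (np.asarray(origin, float) - center) / semi
    d = np.asarray(direction, float) / semi
    a = d @ d
    b = 2 * o @ d
    c = o @ o - 1.0
    disc = b * b - 4 * a * c
    if disc < 0 or a == 0:
        return np.asarray(origin, float)
    lam = (-b + np.sqrt(disc)) / (2 * a)
    return np.asarray(origin, float) + lam * np.asarray(direction, float)


# ---------------------------------------------------------------------------
# Missing wedge
# ---------------------------------------------------------------------------


def apply_missing_wedge(tomogram: Tomogram, wedge_half_angle_deg: float) -> Tomogram:
    """Zero the Fourier components inside the missing wedge.

    The wedge is the double cone of directions within ``wedge_half_angle_deg``
    of the beam axis (z) in the (kx, kz) plane, invariant along the tilt axis
    (y): exactly the region a tilt series with range +/-(90 - half-angle) deg
    never samples.  The operation is an orthogonal projection, hence
    idempotent; the DC component (kz = 0 plane) is always kept.
    """
    if not 0 <= wedge_half_angle_deg <= 90:
        raise ValueError("wedge half-angle must be in [0, 90]")
    if wedge_half_angle_deg == 0:
        return Tomogram(
            tomogram.data.copy(), tomogram.voxel_size_nm, tomogram.origin, dict(tomogram.meta)
        )
    data = np.asarray(tomogram.data, dtype=np.float64)
    nz, ny, nx = data.shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    tan_a = np.tan(np.deg2rad(wedge_half_angle_deg))
    missing = np.abs(kx) < tan_a * np.abs(kz)  # strict: keeps the kz = 0 plane
    spectrum = np.fft.fftn(data)
    spectrum[np.broadcast_to(missing, spectrum.shape)] = 0.0
    out = np.fft.ifftn(spectrum).real.astype(tomogram.data.dtype)
    meta = dict(tomogram.meta)
    meta["wedge_half_angle_deg"] = wedge_half_angle_deg
    return Tomogram(out, tomogram.voxel_size_nm, tomogram.origin, meta)


def wedge_fraction(shape: tuple[int, int, int], wedge_half_angle_deg: float) -> float:
    """Fraction of Fourier voxels inside the missing wedge (mask solid fraction)."""
    nz, ny, nx = shape
    kz = np.fft.fftfreq(nz)[:, None, None]
    kx = np.fft.fftfreq(nx)[None, None, :]
    tan_a = np.tan(np.deg2rad(wedge_half_angle_deg))
    missing = np.abs(kx) < tan_a * np.abs(kz)
    return float(np.broadcast_to(missing, (nz, ny, nx)).mean())


# ---------------------------------------------------------------------------
# Particle sampling
# ---------------------------------------------------------------------------


def sample_particles(
    labels: np.ndarray,
    ground: GroundTruth,
    n: int,
    seed: int,
    min_margin_px: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` seeded particle positions on crista mid-planes.

    Returns (positions, normals): integer voxel coordinates (z, y, x) on the
    mid-plane between the two crista membranes, each with the local membrane
    normal, pooled over all cristae.  ``min_margin_px`` discards sites closer
    than that to any volume face (so a box centred there fits).  Deterministic
    under a fixed seed; sampling is without replacement.
    """
    if not ground.midplane_sites:
        raise GeometryError("phantom contains no cristae to sample from")
    pools = []
    norm_pools = []
    shape = np.asarray(labels.shape)
    for ci, (coords, normals) in sorted(ground.midplane_sites.items()):
        if coords.size == 0:
            continue
        keep = np.all(
            (coords >= min_margin_px) & (coords <= shape[None, :] - 1 - min_margin_px),
            axis=1,
        )
        pools.append(coords[keep])
        norm_pools.append(normals[keep])
    if not pools:
        raise GeometryError("no mid-plane sites available")
    coords = np.concatenate(pools, axis=0)
    normals = np.concatenate(norm_pools, axis=0)
    if n == 0:
        return coords[:0], normals[:0]
    if n > len(coords):
        raise ValueError(f"requested {n} particles but only {len(coords)} distinct sites")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(coords), size=n, replace=False)
    pick.sort()
    return coords[pick], normals[pick]


def noise_sigma_for_snr(noiseless: np.ndarray, snr: float) -> float:
    """Gaussian noise sigma giving signal-variance / noise-variance = snr."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(np.sqrt(np.var(noiseless) / snr))


# ---------------------------------------------------------------------------
# Exemplar suite: one canonical phantom per crista class
# ---------------------------------------------------------------------------


def exemplar_cristae() -> dict[str, CristaSpec]:
    """One geometric exemplar per crista shape class, sized to sit inside the
    default classifier-suite mitochondrion (see :func:`exemplar_phantom`)."""
    return {
        "lamellar": CristaSpec("lamellar", width_nm=15, length_nm=200, height_nm=150),
        "tubular": CristaSpec(
            "tubular", width_nm=25, length_nm=150, orientation=(0, 0, 1)
        ),
        "globular": CristaSpec("globular", width_nm=60, length_nm=60),
        "ring": CristaSpec("ring", width_nm=15, length_nm=2 * np.pi * 40),
        "loop": CristaSpec(
            "loop",
            width_nm=15,
            length_nm=np.pi * 50,
            junctions=[JunctionSpec(), JunctionSpec()],
        ),
        "straight_across": CristaSpec(
            "straight_across",
            width_nm=15,
            length_nm=400,
            height_nm=40,
            junctions=[JunctionSpec(), JunctionSpec()],
        ),
        "split": CristaSpec("split", width_nm=20, length_nm=160, orientation=(0, 0, 1)),
    }


def exemplar_phantom(crista: CristaSpec, seed: int = 0, **overrides) -> PhantomSpec:
    """A roomy mitochondrion phantom holding a single exemplar crista."""
    defaults = dict(
        box_shape=(146, 152, 160),
        voxel_size_nm=2.2,
        semi_axes_nm=(150.0, 160.0, 170.0),
        ibm_offset_nm=10.0,
        cristae=[crista],
        noise_sigma=0.0,
        wedge_half_angle_deg=0.0,
        seed=seed,
    )
    defaults.update(overrides)
    return PhantomSpec(**defaults)
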