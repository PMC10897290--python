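"""Volume and image containers, MRC I/O, projections and contrast normalization.

Tomograms are 3-D grayscale volumes with axis order (z, y, x); the beam runs
along z and the tilt axis along y, the convention used throughout the package.
All metric quantities are carried in nanometres.

The MRC reader/writer implements the MRC2014 interchange format (mode 2,
float32) directly: a fixed 1024-byte header followed by the section-major
data block.  Voxel size is stored in the ``cella`` cell-dimension fields in
Angstrom, as tomography packages write it.
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "Tomogram",
    "Image2D",
    "FormatError",
    "read_volume",
    "write_volume",
    "summed_projection",
    "normalize_contrast",
]


class FormatError(ValueError):
    """Raised for malformed or unsupported volume files."""


@dataclass
class Tomogram:
    """A reconstructed 3-D volume with voxel-size metadata.

    Parameters
    ----------
    data : numpy.ndarray
        3-D real array, axis order (z, y, x).
    voxel_size_nm : float
        Isotropic voxel edge length in nanometres; must be positive.
    origin : tuple of int
        Voxel offset of this volume within its parent frame.
    meta : dict
        Free-form provenance (phantom spec hash, source path, ...).
    """

    data: np.ndarray
    voxel_size_nm: float
    origin: tuple[int, int, int] = (0, 0, 0)
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"tomogram data must be 3-D, got shape {self.data.shape}")
        if not self.voxel_size_nm > 0:
            raise ValueError(f"voxel_size_nm must be positive, got {self.voxel_size_nm}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("tomogram data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class Image2D:
    """A 2-D projection image with pixel size in nanometres."""

    data: np.ndarray
    pixel_size_nm: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"image data must be 2-D, got shape {self.data.shape}")
        if not self.pixel_size_nm > 0:
            raise ValueError(f"pixel_size_nm must be positive, got {self.pixel_size_nm}")


# ---------------------------------------------------------------------------
# MRC2014 I/O (mode 2 float32 only — the interchange subset tomography uses)
# ---------------------------------------------------------------------------

_HEADER_SIZE = 1024
_MAP_ID = b"MAP "
# little-endian machine stamp per the MRC2014 standard
_MACHST_LE = b"\x44\x44\x00\x00"


def write_volume(tomogram: Tomogram, path: str | os.PathLike) -> None:
    """Write a tomogram as MRC2014 mode 2 (float32).

    The voxel size is recorded via the cell dimensions in Angstrom
    (``cella = shape * voxel_size * 10``) with ``mx,my,mz`` equal to the
    grid shape, so standard readers recover it exactly.
    """
    data = np.ascontiguousarray(tomogram.data, dtype="<f4")
    nz, ny, nx = data.shape
    vs_A = tomogram.voxel_size_nm * 10.0
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<3i", header, 0, nx, ny, nz)          # nx ny nz
    struct.pack_into("<i", header, 12, 2)                   # mode 2 = float32
    struct.pack_into("<3i", header, 16, 0, 0, 0)            # nxstart...
    struct.pack_into("<3i", header, 28, nx, ny, nz)         # mx my mz
    struct.pack_into("<3f", header, 40, nx * vs_A, ny * vs_A, nz * vs_A)  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)   # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)            # mapc mapr maps
    struct.pack_into(
        "<3f", header, 76, float(data.min()), float(data.max()), float(data.mean())
    )
    struct.pack_into("<i", header, 88, 1)                   # ispg (volume)
    struct.pack_into("<i", header, 92, 0)                   # nsymbt
    header[208:212] = _MAP_ID
    header[212:216] = _MACHST_LE
    struct.pack_into("<f", header, 216, float(data.std()))  # rms
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def read_volume(path: str | os.PathLike) -> Tomogram:
    """Read an MRC2014 mode-2 volume into a :class:`Tomogram`.

    Raises
    ------
    FormatError
        If the header is malformed, the mode is unsupported, or the data
        block is truncated.
    """
    with open(path, "rb") as fh:
        header = fh.read(_HEADER_SIZE)
        if len(header) < _HEADER_SIZE:
            raise FormatError(f"{path}: file shorter than MRC header")
        if header[208:212] != _MAP_ID:
            raise FormatError(f"{path}: missing 'MAP ' identifier — not MRC2014")
        nx, ny, nz = struct.unpack_from("<3i", header, 0)
        (mode,) = struct.unpack_from("<i", header, 12)
        if mode != 2:
            raise FormatError(f"{path}: unsupported MRC mode {mode} (only 2/float32)")
        if min(nx, ny, nz) <= 0:
            raise FormatError(f"{path}: invalid dimensions {(nx, ny, nz)}")
        mx, my, mz = struct.unpack_from("<3i", header, 28)
        cella = struct.unpack_from("<3f", header, 40)
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        fh.seek(_HEADER_SIZE + nsymbt)
        n_vox = nx * ny * nz
        raw = fh.read(n_vox * 4)
        if len(raw) < n_vox * 4:
            raise FormatError(f"{path}: truncated data block")
        data = np.frombuffer(raw, dtype="<f4").reshape(nz, ny, nx).copy()
    if mx > 0 and cella[0] > 0:
        voxel_size_nm = cella[0] / mx / 10.0
    else:
        voxel_size_nm = 1.0
    return Tomogram(data=data, voxel_size_nm=float(voxel_size_nm), meta={"path": str(path)})


def write_labels(labels: np.ndarray, voxel_size_nm: float, path: str | os.PathLike) -> None:
    """Write an integer label volume as MRC (stored as float32 mode 2)."""
    write_volume(Tomogram(labels.astype(np.float32), voxel_size_nm), path)


def read_labels(path: str | os.PathLike) -> tuple[np.ndarray, float]:
    """Read a label volume written by :func:`write_labels`."""
    tomo = read_volume(path)
    return np.rint(tomo.data).astype(np.int16), tomo.voxel_size_nm


# ---------------------------------------------------------------------------
# Projections and contrast
# ---------------------------------------------------------------------------


def summed_projection(tomogram: Tomogram, z_center: int, n_slices: int) -> Image2D:
    """Sum ``n_slices`` consecutive z-slices centred on ``z_center``.

    This mirrors the "summed projection of central slices" from which the
    2-D morphometry (areas, junction measurements, matrix density) is read.
    The window is ``[z_center - n_slices//2, z_center - n_slices//2 + n_slices)``.
    """
    if n_slices < 1:
        raise ValueError("n_slices must be >= 1")
    z0 = z_center - n_slices // 2
    z1 = z0 + n_slices
    nz = tomogram.data.shape[0]
    if z0 < 0 or z1 > nz:
        raise IndexError(
            f"slice window [{z0}, {z1}) out of bounds for volume of depth {nz}"
        )
    proj = tomogram.data[z0:z1].sum(axis=0)
    return Image2D(data=proj, pixel_size_nm=tomogram.voxel_size_nm)


def normalize_contrast(image: Image2D, saturation_fraction: float = 0.0035) -> Image2D:
    """Saturated linear contrast stretch to [0, 1].

    The lowest and highest ``saturation_fraction / 2`` quantiles are clipped
    before rescaling, matching a saturated "enhance contrast" normalization
    at 0.35% total saturation.  Interpreting the normalization as a linear
    stretch (rather than rank equalization) preserves mean gray values as a
    comparable density scale across images, which is what the matrix-density
    measurement needs.  Constant images map to all zeros.
    """
    if not 0 <= saturation_fraction < 1:
        raise ValueError(f"saturation_fraction must be in [0, 1), got {saturation_fraction}")
    if image.data.size == 0:
        raise ValueError("empty image")
    data = np.asarray(image.data, dtype=np.float64)
    lo = np.quantile(data, saturation_fraction / 2.0)
    hi = np.quantile(data, 1.0 - saturation_fraction / 2.0)
    if hi <= lo:
        out = np.zeros_like(data)
    else:
        out = np.clip((data - lo) / (hi - lo), 0.0, 1.0)
    return Image2D(data=out, pixel_size_nm=image.pixel_size_nm)
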