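"""Multi-angle ball-and-stick snapshot rendering.

A molecule with 3D (or planar) coordinates is rotated through the Cartesian
cube of per-axis angle multiples and each orientation is rasterized into a
fixed-size RGB PNG: atoms as Lambert-shaded spheres scaled from van der Waals
radii, bonds as cylindrical sticks, orthographic projection with a single
directional light plus an ambient term. Rendering is fully deterministic —
identical molecule, rotation and config give byte-identical PNG files — which
makes image datasets reproducible and cacheable.

This renderer is a functional analog of the Jmol-based depiction used in the
original workflow, not a pixel-compatible reimplementation.
"""

from __future__ import annotations

import io
import math
import zlib
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .chemio import Molecule

__all__ = [
    "BACKGROUND_COLORS",
    "VDW_RADII",
    "CPK_COLORS",
    "RenderConfig",
    "SnapshotSet",
    "rotation_grid",
    "rotation_matrix",
    "render_snapshot",
    "snap_molecule",
    "select_combination",
]

#: The six named background colors (RGB triples).
BACKGROUND_COLORS: dict[str, tuple[int, int, int]] = {
    "black": (0, 0, 0),
    "white": (255, 255, 255),
    "red": (255, 0, 0),
    "yellow": (255, 255, 0),
    "green": (0, 255, 0),
    "blue": (0, 0, 255),
}

#: van der Waals radii in Angstrom (Bondi-style values).
VDW_RADII: dict[str, float] = {
    "H": 1.20, "B": 1.92, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Si": 2.10, "P": 1.80, "S": 1.80, "Cl": 1.75, "Se": 1.90,
    "Br": 1.85, "I": 1.98,
}

#: Covalent radii in Angstrom, used only for bond inference.
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Se": 1.20,
    "Br": 1.20, "I": 1.39,
}

#: CPK element colors.
CPK_COLORS: dict[str, tuple[int, int, int]] = {
    "H": (255, 255, 255), "C": (144, 144, 144), "N": (48, 80, 248),
    "O": (255, 13, 13), "F": (144, 224, 80), "Cl": (31, 240, 31),
    "Br": (166, 41, 41), "I": (148, 0, 148), "S": (255, 255, 48),
    "P": (255, 128, 0), "B": (255, 181, 181), "Si": (240, 200, 160),
    "Se": (255, 161, 0),
}
_DEFAULT_COLOR = (255, 20, 147)  # unknown element fallback
_BOND_COLOR = (200, 200, 200)


@dataclass(frozen=True)
class RenderConfig:
    """All depiction parameters for the snapshot step.

    Parameters
    ----------
    angle_increment_deg : float
        Per-axis rotation step in degrees, in (0, 360].
    image_px : int
        Output width = height in pixels (square), >= 16.
    zoom_factor_pct : float
        ZF: the molecule's bounding sphere is scaled to ZF% of the frame
        half-width.
    atom_scale_pct : float
        AT: sphere radius as a percentage of the element vdW radius.
    bond_radius_mA : float
        BR: stick radius in milli-Angstrom.
    min_bond_distance : float
        MBD in Angstrom; lower distance bound for bond inference.
    bond_tolerance : float
        BT (unitless); bond inferred iff
        MBD < d(i, j) < BT * (rcov_i + rcov_j). Only used when the input
        molecule carries no bond list.
    background_rgb : (int, int, int)
        Background color, each component in [0, 255].
    image_format : str
        Only "png" is supported.
    """

    angle_increment_deg: float = 300.0
    image_px: int = 256
    zoom_factor_pct: float = 100.0
    atom_scale_pct: float = 25.0
    bond_radius_mA: float = 150.0
    min_bond_distance: float = 0.4
    bond_tolerance: float = 1.25
    background_rgb: tuple[int, int, int] = BACKGROUND_COLORS["white"]
    image_format: str = "png"

    def __post_init__(self) -> None:
        if not (0 < self.angle_increment_deg <= 360):
            raise ValueError("angle_increment_deg must be in (0, 360]")
        if self.image_px < 16:
            raise ValueError("image_px must be >= 16")
        for name in ("zoom_factor_pct", "atom_scale_pct", "bond_radius_mA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if any(not (0 <= c <= 255) for c in self.background_rgb):
            raise ValueError("background_rgb components must be in [0, 255]")
        if self.image_format != "png":
            raise ValueError("only png output is supported")

    @classmethod
    def with_background(cls, name: str, **kwargs) -> "RenderConfig":
        return cls(background_rgb=BACKGROUND_COLORS[name], **kwargs)


@dataclass
class SnapshotSet:
    """Ordered collection of rendered rotations for one molecule."""

    molecule_id: str
    config: RenderConfig
    entries: list[dict] = field(default_factory=list)
    # each entry: {"rotation": (rx, ry, rz), "path": Path | None,
    #              "image": np.ndarray | None}

    def rotations(self) -> list[tuple[float, float, float]]:
        return [e["rotation"] for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# rotation grid
# ---------------------------------------------------------------------------

def rotation_grid(angle_increment_deg: float) -> list[tuple[float, float, float]]:
    """Cartesian cube of per-axis angle multiples below 360 degrees.

    Per axis the angles are ``{k * theta : k = 0 .. ceil(360/theta) - 1}``,
    i.e. all non-negative multiples of the increment strictly below 360.
    The grid is their Cartesian cube in lexicographic (rx, ry, rz) order, so
    increments 120/180/240/300/360 give 27/8/8/8/1 tuples.
    """
    theta = float(angle_increment_deg)
    if not (0 < theta <= 360):
        raise ValueError("angle increment must be in (0, 360]")
    n = math.ceil(360.0 / theta)
    axis = [k * theta for k in range(n)]
    return [(rx, ry, rz) for rx in axis for ry in axis for rz in axis]


def rotation_matrix(rx: float, ry: float, rz: float) -> np.ndarray:
    """Extrinsic rotation about x, then y, then z (degrees)."""
    ax, ay, az = (math.radians(a) for a in (rx, ry, rz))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

_LIGHT = np.array([-0.4, 0.4, 0.82])
_LIGHT = _LIGHT / np.linalg.norm(_LIGHT)
_AMBIENT = 0.35


def render_snapshot(
    mol: Molecule,
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0),
    config: RenderConfig | None = None,
) -> np.ndarray:
    """Rasterize one orientation of a molecule into an (px, px, 3) uint8 array.

    The molecule is centered on its centroid, rotated, and orthographically
    projected; the bounding sphere (atom centers plus sphere radii) is scaled
    to ``zoom_factor_pct`` percent of the frame half-width. Atoms are drawn
    as Lambert-shaded CPK-colored spheres, bonds as sticks; a z-buffer
    resolves occlusion. Output is deterministic.
    """
    config = config or RenderConfig()
    if mol.n_atoms == 0:
        raise ValueError(f"molecule {mol.id!r} has no atoms")

    px = config.image_px
    coords = mol.coordinates()
    coords = coords - coords.mean(axis=0)
    R = rotation_matrix(*rotation)
    coords = coords @ R.T

    symbols = [a[0] for a in mol.atoms]
    radii = np.array(
        [VDW_RADII.get(s, 1.7) * config.atom_scale_pct / 100.0 for s in symbols]
    )
    bond_r = config.bond_radius_mA / 1000.0  # mA -> A

    # world-to-pixel scale: bounding sphere occupies ZF% of the half-width
    extent = float(np.max(np.linalg.norm(coords, axis=1) + radii))
    extent = max(extent, 1e-6)
    scale = (config.zoom_factor_pct / 100.0) * (px / 2.0 - 1.0) / extent

    centers = coords * scale
    centers[:, 0] += px / 2.0
    centers[:, 1] = px / 2.0 - centers[:, 1]  # y up -> row down
    r_px = radii * scale
    bond_r_px = max(bond_r * scale, 0.5)

    img = np.empty((px, px, 3), dtype=np.float64)
    img[:] = np.asarray(config.background_rgb, dtype=np.float64)
    zbuf = np.full((px, px), -np.inf)

    bonds = mol.bonds if mol.bonds else _infer_bonds(mol, config)
    for i, j, _order in bonds:
        _draw_stick(img, zbuf, centers[i], centers[j], bond_r_px, _BOND_COLOR)
    for idx in np.argsort(centers[:, 2]):
        color = CPK_COLORS.get(symbols[idx], _DEFAULT_COLOR)
        _draw_sphere(img, zbuf, centers[idx], r_px[idx], color)

    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def _draw_sphere(img, zbuf, center, radius, color) -> None:
    px = img.shape[0]
    cx, cy, cz = center
    r = max(float(radius), 0.75)
    x0, x1 = max(int(cx - r) - 1, 0), min(int(cx + r) + 2, px)
    y0, y1 = max(int(cy - r) - 1, 0), min(int(cy + r) + 2, px)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    dx = xs + 0.5 - cx
    dy = ys + 0.5 - cy
    d2 = dx * dx + dy * dy
    inside = d2 <= r * r
    if not inside.any():
        return
    h = np.sqrt(np.maximum(r * r - d2, 0.0))
    z = cz + h
    # Lambert shading from the sphere normal
    nx, ny, nz = dx / r, -dy / r, h / r
    diffuse = np.maximum(nx * _LIGHT[0] + ny * _LIGHT[1] + nz * _LIGHT[2], 0.0)
    shade = np.clip(_AMBIENT + (1.0 - _AMBIENT) * diffuse, 0.0, 1.0)
    sub_z = zbuf[y0:y1, x0:x1]
    mask = inside & (z > sub_z)
    sub_z[mask] = z[mask]
    col = np.asarray(color, dtype=np.float64)
    sub_img = img[y0:y1, x0:x1]
    sub_img[mask] = shade[mask, None] * col[None, :]


def _draw_stick(img, zbuf, p0, p1, radius, color) -> None:
    """Bond stick: a 2D capsule with interpolated depth and cylinder shading."""
    px = img.shape[0]
    a = np.asarray(p0, dtype=float)
    b = np.asarray(p1, dtype=float)
    d = b - a
    seg2 = d[0] * d[0] + d[1] * d[1]
    r = max(float(radius), 0.5)
    x0 = max(int(min(a[0], b[0]) - r) - 1, 0)
    x1 = min(int(max(a[0], b[0]) + r) + 2, px)
    y0 = max(int(min(a[1], b[1]) - r) - 1, 0)
    y1 = min(int(max(a[1], b[1]) + r) + 2, px)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    qx = xs + 0.5 - a[0]
    qy = ys + 0.5 - a[1]
    if seg2 > 1e-12:
        t = np.clip((qx * d[0] + qy * d[1]) / seg2, 0.0, 1.0)
    else:
        t = np.zeros_like(qx)
    ex = qx - t * d[0]
    ey = qy - t * d[1]
    e2 = ex * ex + ey * ey
    inside = e2 <= r * r
    if not inside.any():
        return
    h = np.sqrt(np.maximum(r * r - e2, 0.0))
    z = a[2] + t * d[2] + h
    frac = np.sqrt(e2) / r
    shade = np.clip(_AMBIENT + (1.0 - _AMBIENT) * np.sqrt(np.maximum(1 - frac**2, 0)), 0, 1)
    sub_z = zbuf[y0:y1, x0:x1]
    mask = inside & (z > sub_z)
    sub_z[mask] = z[mask]
    col = np.asarray(color, dtype=np.float64)
    sub_img = img[y0:y1, x0:x1]
    sub_img[mask] = shade[mask, None] * col[None, :]


def _infer_bonds(mol: Molecule, config: RenderConfig) -> list[tuple[int, int, int]]:
    """Distance-based bond inference for bondless inputs."""
    coords = mol.coordinates()
    out = []
    for i in range(mol.n_atoms):
        for j in range(i + 1, mol.n_atoms):
            d = float(np.linalg.norm(coords[i] - coords[j]))
            rc = COVALENT_RADII.get(mol.atoms[i][0], 0.76) + COVALENT_RADII.get(
                mol.atoms[j][0], 0.76
            )
            if config.min_bond_distance < d < config.bond_tolerance * rc:
                out.append((i, j, 1))
    return out


# ---------------------------------------------------------------------------
# deterministic PNG encoding
# ---------------------------------------------------------------------------

def encode_png(img: np.ndarray) -> bytes:
    """Encode an (h, w, 3) uint8 array as 8-bit RGB PNG, byte-deterministic.

    Fixed filter (none) and fixed zlib level so identical pixels always give
    identical files, independent of any image-library version.
    """
    if img.ndim != 3 or img.shape[2] != 3 or img.dtype != np.uint8:
        raise ValueError("expected (h, w, 3) uint8 image")
    h, w = img.shape[:2]

    def chunk(tag: bytes, payload: bytes) -> bytes:
        out = struct.pack(">I", len(payload)) + tag + payload
        return out + struct.pack(">I", zlib.crc32(tag + payload) & 0xFFFFFFFF)

    ihdr = struct.pack(">IIBBBBB", w, h, 8, 2, 0, 0, 0)
    raw = b"".join(b"\x00" + img[row].tobytes() for row in range(h))
    idat = zlib.compress(raw, 6)
    return (
        b"\x89PNG\r\n\x1a\n"
        + chunk(b"IHDR", ihdr)
        + chunk(b"IDAT", idat)
        + chunk(b"IEND", b"")
    )


def decode_png(data: bytes) -> np.ndarray:
    """Decode a PNG into an (h, w, 3) uint8 array (via Pillow)."""
    from PIL import Image

    with Image.open(io.BytesIO(data)) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def load_image(path: str | Path) -> np.ndarray:
    return decode_png(Path(path).read_bytes())


# ---------------------------------------------------------------------------
# per-molecule snapshot sets
# ---------------------------------------------------------------------------

def snapshot_filename(mol_id: str, rotation: tuple[float, float, float]) -> str:
    rx, ry, rz = (int(round(a)) for a in rotation)
    return f"{mol_id}_{rx}_{ry}_{rz}.png"


def snap_molecule(
    mol: Molecule,
    config: RenderConfig | None = None,
    out_dir: str | Path | None = None,
    keep_images: bool = True,
) -> SnapshotSet:
    """Render every rotation-grid orientation of one molecule.

    When ``out_dir`` is given, one PNG per rotation tuple is written there
    with the molecule id and angles encoded in the file name.
    """
    config = config or RenderConfig()
    out_path: Path | None = None
    if out_dir is not None:
        out_path = Path(out_dir)
        out_path.mkdir(parents=True, exist_ok=True)
        if not out_path.is_dir():
            raise NotADirectoryError(out_path)
    ss = SnapshotSet(molecule_id=mol.id, config=config)
    for rot in rotation_grid(config.angle_increment_deg):
        img = render_snapshot(mol, rot, config)
        path = None
        if out_path is not None:
            path = out_path / snapshot_filename(mol.id, rot)
            path.write_bytes(encode_png(img))
        ss.entries.append(
            {"rotation": rot, "path": path, "image": img if keep_images else None}
        )
    return ss


def select_combination(
    s: SnapshotSet, tuples: Sequence[tuple[float, float, float]]
) -> SnapshotSet:
    """Subset of a snapshot set given explicit rotation tuples.

    Order follows ``tuples``; repeated tuples are kept as repeated entries,
    matching the published picture-combination lists which include repeats.
    """
    index = {tuple(float(a) for a in e["rotation"]): e for e in s.entries}
    out = SnapshotSet(molecule_id=s.molecule_id, config=s.config)
    for t in tuples:
        key = tuple(float(a) for a in t)
        if key not in index:
            raise KeyError(f"rotation tuple {t} not present in snapshot set")
        out.entries.append(dict(index[key]))
    return out
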