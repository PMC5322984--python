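"""Digital objects: voxel grids, tissue assignment, field/coil maps.

Coordinate convention (used everywhere): voxel centers, axis origin at
the grid center, 0-based indices with x fastest; ``voxel_size`` in mm.
Partial volume can be simulated either by refining the grid below the
acquisition resolution or by assigning per-voxel aggregate models; the
two routes agree for linear acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import MU0
from .tissue import TissueModel, aggregate_models, preset_model

__all__ = [
    "DigitalObject",
    "CoilGeometry",
    "make_cylinder",
    "make_fat_fraction_phantom",
    "refine_for_partial_volume",
    "biot_savart_b1",
    "ring_coil",
]


@dataclass
class DigitalObject:
    """Voxelized object: tissue labels plus per-voxel field maps."""

    shape: tuple                 # (nx, ny, nz)
    voxel_size: tuple            # mm per axis
    tissue_id: np.ndarray        # int labels, 0 = background
    tissue_table: dict           # label -> TissueModel
    delta_b: np.ndarray | None = None    # T, macroscopic off-resonance
    transmit: np.ndarray | None = None   # complex B1+ scale
    receive: np.ndarray | None = None    # complex sensitivity (..., channels)

    def __post_init__(self):
        self.shape = tuple(int(n) for n in self.shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.tissue_id = np.asarray(self.tissue_id, dtype=int)
        if self.tissue_id.shape != self.shape:
            raise ValueError("tissue_id shape does not match grid shape")
        if self.delta_b is None:
            self.delta_b = np.zeros(self.shape)
        if self.transmit is None:
            self.transmit = np.ones(self.shape, dtype=complex)
        for name in ("delta_b", "transmit"):
            arr = getattr(self, name)
            if arr.shape[: len(self.shape)] != self.shape:
                raise ValueError(f"{name} map shape mismatch")
        missing = set(np.unique(self.tissue_id)) - {0} - set(self.tissue_table)
        if missing:
            raise ValueError(f"tissue ids {sorted(missing)} not in tissue_table")

    def positions(self) -> np.ndarray:
        """Voxel-center coordinates in meters, shape (*grid, 3)."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v * 1e-3
            for n, v in zip(self.shape, self.voxel_size)
        ]
        grids = np.meshgrid(*axes, indexing="ij")
        return np.stack(grids, axis=-1)

    def to_dict(self) -> dict:
        from .config import tissue_to_dict
        return {
            "shape": list(self.shape),
            "voxel_size": list(self.voxel_size),
            "tissue_id": self.tissue_id.tolist(),
            "tissue_table": {int(k): tissue_to_dict(v)
                             for k, v in self.tissue_table.items()},
            "delta_b": self.delta_b.tolist(),
            "transmit_real": self.transmit.real.tolist(),
            "transmit_imag": self.transmit.imag.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DigitalObject":
        from .config import tissue_from_dict
        return cls(
            shape=tuple(d["shape"]),
            voxel_size=tuple(d["voxel_size"]),
            tissue_id=np.array(d["tissue_id"], dtype=int),
            tissue_table={int(k): tissue_from_dict(v)
                          for k, v in d["tissue_table"].items()},
            delta_b=np.array(d["delta_b"]),
            transmit=np.array(d["transmit_real"])
            + 1j * np.array(d["transmit_imag"]),
        )

    def save_nifti(self, path) -> None:
        import nibabel as nib
        affine = np.diag(list(self.voxel_size) + [1.0])
        nib.save(nib.Nifti1Image(self.tissue_id.astype(np.int16), affine),
                 str(path))

    @staticmethod
    def load_labels_nifti(path) -> np.ndarray:
        """Loader stub for externally supplied labeled volumes in NIfTI."""
        import nibabel as nib
        return np.asarray(nib.load(str(path)).dataobj).astype(int)


def make_cylinder(shape, voxel_size, radius_mm: float,
                  tissue: TissueModel) -> DigitalObject:
    """Cylinder along z: voxels whose in-plane center distance from the
    grid center is <= radius get the tissue; others are background."""
    shape = tuple(shape)
    ids = np.zeros(shape, dtype=int)
    nx, ny = shape[0], shape[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) * voxel_size[0]
    y = (np.arange(ny) - (ny - 1) / 2.0) * voxel_size[1]
    X, Y = np.meshgrid(x, y, indexing="ij")
    disk = (X ** 2 + Y ** 2) <= radius_mm ** 2
    ids[...] = disk[(...,) + (None,) * (len(shape) - 2)]
    return DigitalObject(shape, tuple(voxel_size), ids, {1: tissue})


def make_fat_fraction_phantom(shape, voxel_size, fat_fractions=(0.0, 0.3, 0.5),
                              agar_model: TissueModel | None = None,
                              fat_model: TissueModel | None = None,
                              **preset_params) -> DigitalObject:
    """Stripe phantom: one compartment per fat fraction along x.

    Each compartment's tissue is the intra-voxel aggregate of the
    agar (two-pool MT) and fat models at that volume fraction; labels
    run 1..len(fat_fractions).
    """
    if agar_model is None:
        agar_model = preset_model("mt_fat_three_pool",
                                  {**preset_params, "fat_fraction": 0.0})
    if fat_model is None:
        fat_model = _pure_fat_model(preset_params)
    shape = tuple(shape)
    ids = np.zeros(shape, dtype=int)
    nx = shape[0]
    edges = np.linspace(0, nx, len(fat_fractions) + 1).astype(int)
    table = {}
    for k, ff in enumerate(fat_fractions):
        if not 0.0 <= ff <= 1.0:
            raise ValueError("fat fractions must lie in [0, 1]")
        label = k + 1
        ids[edges[k]:edges[k + 1], ...] = label
        if ff == 0.0:
            table[label] = agar_model
        elif ff == 1.0:
            table[label] = fat_model
        else:
            table[label] = aggregate_models([agar_model, fat_model],
                                            [1.0 - ff, ff])
    return DigitalObject(shape, tuple(voxel_size), ids, table)


def _pure_fat_model(params: dict) -> TissueModel:
    from .tissue import ExchangeMatrix, PoolSpec, FAT_SPECTRUM_6PEAK
    return TissueModel(
        (PoolSpec("fat", "free", 1.0, params.get("t1_fat", 0.3),
                  params.get("t2_fat", 0.060),
                  spectrum=params.get("fat_spectrum", FAT_SPECTRUM_6PEAK)),),
        ExchangeMatrix(np.zeros((1, 1))), name="fat")


def refine_for_partial_volume(obj: DigitalObject, factor: int) -> DigitalObject:
    """Split each voxel into ``factor``^d subvoxels (d = number of axes
    with size > 1) inheriting tissue and maps; total proton content is
    conserved because fractions are per-unit-volume quantities."""
    if factor < 1 or int(factor) != factor:
        raise ValueError("factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return obj
    reps = tuple(factor if n > 1 else 1 for n in obj.shape)
    def up(a):
        out = a
        for ax, r in enumerate(reps):
            out = np.repeat(out, r, axis=ax)
        return out
    return DigitalObject(
        shape=tuple(n * r for n, r in zip(obj.shape, reps)),
        voxel_size=tuple(v / r for v, r in zip(obj.voxel_size, reps)),
        tissue_id=up(obj.tissue_id),
        tissue_table=dict(obj.tissue_table),
        delta_b=up(obj.delta_b),
        transmit=up(obj.transmit),
    )


@dataclass(frozen=True)
class CoilGeometry:
    """Straight-line filament segments per channel.

    ``channels`` is a list; each channel a list of
    (start_xyz_m, end_xyz_m, current_A) filaments.
    """

    channels: tuple

    def __post_init__(self):
        chans = []
        for ch in self.channels:
            segs = []
            for a, b, cur in ch:
                a = np.asarray(a, dtype=float)
                b = np.asarray(b, dtype=float)
                if np.linalg.norm(b - a) == 0:
                    raise ValueError("filament segment has zero length")
                segs.append((a, b, float(cur)))
            chans.append(tuple(segs))
        object.__setattr__(self, "channels", tuple(chans))


def _segment_field(a: np.ndarray, b: np.ndarray, current: float,
                   pos: np.ndarray) -> np.ndarray:
    """Closed-form Biot-Savart field of one finite straight filament."""
    dl = b - a
    L = np.linalg.norm(dl)
    u = dl / L
    ap = pos - a
    # perpendicular distance vector from the line
    proj = ap @ u
    perp = ap - np.multiply.outer(proj, u)
    d = np.linalg.norm(perp, axis=-1)
    if np.any(d < 1e-12):
        raise ValueError("field position lies on a filament")
    bp = pos - b
    sin1 = proj / np.linalg.norm(ap, axis=-1)
    sin2 = (bp @ u) / np.linalg.norm(bp, axis=-1)
    mag = MU0 * current / (4.0 * np.pi * d) * (sin1 - sin2)
    phi = np.cross(np.broadcast_to(u, perp.shape), perp / d[..., None])
    return mag[..., None] * phi


def biot_savart_b1(coil: CoilGeometry, positions) -> np.ndarray:
    """Complex transverse field (Bx + i By, tesla) per channel.

    ``positions``: array (..., 3) in meters.  Returns (..., n_channels).
    """
    pos = np.asarray(positions, dtype=float)
    out = np.zeros(pos.shape[:-1] + (len(coil.channels),), dtype=complex)
    for c, segs in enumerate(coil.channels):
        B = np.zeros(pos.shape)
        for a, b, cur in segs:
            B = B + _segment_field(a, b, cur, pos)
        out[..., c] = B[..., 0] + 1j * B[..., 1]
    return out


def ring_coil(n_channels: int = 8, radius: float = 0.15,
              length: float = 0.4, current: float = 1.0) -> CoilGeometry:
    """Symmetric ring of axial filaments (a rung-only birdcage sketch)."""
    chans = []
    for k in range(n_channels):
        phi = 2 * np.pi * k / n_channels
        x, y = radius * np.cos(phi), radius * np.sin(phi)
        chans.append([((x, y, -length / 2), (x, y, length / 2), current)])
    return CoilGeometry(tuple(chans))


def shim_residual_map(shape, voxel_size, linear=(0.0, 0.0, 0.0),
                      quadratic: float = 0.0) -> np.ndarray:
    """Optional linear+quadratic off-resonance generator (tesla)."""
    obj = DigitalObject(tuple(shape), tuple(voxel_size),
                        np.zeros(shape, dtype=int), {})
    r = obj.positions()
    lin = r @ np.asarray(linear, dtype=float)
    return lin + quadratic * (r ** 2).sum(axis=-1)
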