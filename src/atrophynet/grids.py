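"""Voxel grids and affines for normalized gray-matter volumes.

All spatial logic (slice z-coordinates, sagittal mirroring, midline
location) is defined through the voxel-to-mm affine, never through raw
array indices, so that full-size and reduced grids behave identically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "GMVolume", "FULL_GRID", "REDUCED_GRID", "get_grid"]


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel grid with an affine mapping voxel indices to mm.

    The first axis is left-right (x, sagittal), the second
    posterior-anterior (y), the third inferior-superior (z, axial).
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)
    #: axial extraction range in mm, closed interval
    default_z_range: tuple[int, int] = (-29, 28)

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "affine", affine)

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def z_of_index(self, k: int | np.ndarray) -> np.ndarray:
        """mm z-coordinate of axial plane index ``k`` (center of plane)."""
        k = np.asarray(k, dtype=float)
        return self.affine[2, 2] * k + self.affine[2, 3]

    def index_of_z(self, z_mm: float) -> float:
        return (z_mm - self.affine[2, 3]) / self.affine[2, 2]

    def z_range_mm(self) -> tuple[float, float]:
        zs = self.z_of_index(np.array([0, self.shape[2] - 1]))
        return float(zs.min()), float(zs.max())

    def mirror_index_map(self) -> int:
        """Return c such that sagittal reflection maps x-index i -> c - i.

        The reflection is about the affine's x = 0 (midsagittal) plane and
        must land voxel centers on voxel centers for the whole grid.
        """
        a = self.affine[0, 0]
        b = self.affine[0, 3]
        c = -2.0 * b / a
        c_int = int(round(c))
        if abs(c - c_int) > 1e-9 or c_int != self.shape[0] - 1:
            raise ValueError(
                "grid is not mirror-compatible: reflection of index 0 about "
                f"the midsagittal plane lands at index {c:.3f}, expected "
                f"{self.shape[0] - 1}"
            )
        return c_int

    def mirror_volume(self, data: np.ndarray) -> np.ndarray:
        """Reflect a volume about the midsagittal plane (x -> -x)."""
        self.mirror_index_map()  # validates compatibility
        return np.flip(data, axis=0).copy()

    def matches(self, other: "GridSpec", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


def _make_affine(offsets: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, 3] = offsets
    return aff


#: 113x137x113 MNI-like grid, 1 mm isotropic, x=0 and z=0 at index 56.
FULL_GRID = GridSpec(
    shape=(113, 137, 113),
    affine=_make_affine((-56.0, -68.0, -56.0)),
    default_z_range=(-29, 28),
)

#: desk-scale grid; x midline sits between indices 15/16 so the sagittal
#: flip is exact, while z keeps integer-mm planes (z=0 at index 16).
REDUCED_GRID = GridSpec(
    shape=(32, 40, 32),
    affine=_make_affine((-15.5, -19.5, -16.0)),
    default_z_range=(-8, 7),
)

_PRESETS = {"full": FULL_GRID, "reduced": REDUCED_GRID}


def get_grid(preset: str) -> GridSpec:
    try:
        return _PRESETS[preset]
    except KeyError:
        raise ValueError(
            f"unknown grid preset {preset!r}; choose from {sorted(_PRESETS)}"
        ) from None


@dataclass
class GMVolume:
    """A gray-matter probability (or residual) volume for one subject."""

    data: np.ndarray
    grid: GridSpec
    subject_id: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid "
                f"{self.grid.shape}"
            )

    @property
    def affine(self) -> np.ndarray:
        return self.grid.affine

    def with_data(self, data: np.ndarray) -> "GMVolume":
        return GMVolume(data=data, grid=self.grid, subject_id=self.subject_id)
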