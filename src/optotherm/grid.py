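"""Voxel grid shared by the photon-transport and bioheat solvers.

Conventions: isotropic spacing; 0-based indices; a voxel value represents its
center; voxel ``(i, j, k)`` spans ``origin + ([i,i+1], [j,j+1], [k,k+1]) * h``
so centers sit at ``origin + (idx + 0.5) * h``.  The brain surface is the
plane z = 0 with tissue at z ≥ 0 (half-open: z ∈ [0, zmax)); air is z < 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class VoxelGrid:
    spacing_mm: float
    dims: tuple  # (nx, ny, nz)
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be > 0")
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError("dims must be three positive integers")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "origin_mm", tuple(float(c) for c in self.origin_mm))

    @property
    def shape(self) -> tuple:
        return self.dims

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.dims[axis]
        return self.origin_mm[axis] + (np.arange(n) + 0.5) * self.spacing_mm

    def extent(self, axis: int) -> tuple:
        lo = self.origin_mm[axis]
        return lo, lo + self.dims[axis] * self.spacing_mm

    def contains_point(self, p) -> bool:
        return all(
            self.extent(a)[0] <= p[a] < self.extent(a)[1] for a in range(3)
        )

    def index_of(self, p) -> tuple:
        if not self.contains_point(p):
            raise ValueError(f"point {p} outside grid")
        return tuple(
            int((p[a] - self.origin_mm[a]) / self.spacing_mm) for a in range(3)
        )

    @classmethod
    def default_tissue(cls, spacing_mm: float = 0.1) -> "VoxelGrid":
        """12×12×6 mm tissue block, surface at z=0, fiber tip at (0,0,0.5).

        x spans [-2, 10] so the emission axis (+x) has ≥6 mm of tissue ahead
        of the tip with 2 mm behind; y spans [-6, 6]; z spans [0, 6].
        """
        n = lambda mm: int(round(mm / spacing_mm))
        return cls(
            spacing_mm=spacing_mm,
            dims=(n(12.0), n(12.0), n(6.0)),
            origin_mm=(-2.0, -6.0, 0.0),
        )
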