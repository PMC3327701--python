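"""Integer label volumes and NIfTI round-tripping."""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["LabelVolume"]


@dataclass
class LabelVolume:
    """A 3-D integer label grid with voxel dimensions and a region code map.

    Label 0 is background. ``codes`` maps positive label integers to region
    names; labels without an entry are anonymous but still fused/counted.
    """

    grid: np.ndarray
    voxel_dims: tuple[float, float, float] = (1.0, 1.0, 1.0)
    codes: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3:
            raise ValueError("label grid must be 3-D")
        if not np.issubdtype(self.grid.dtype, np.integer):
            raise ValueError("label grid must be integer-typed")
        if self.grid.min() < 0:
            raise ValueError("labels must be non-negative (0 = background)")
        if len(self.voxel_dims) != 3 or any(d <= 0 for d in self.voxel_dims):
            raise ValueError("voxel_dims must be three positive lengths (mm)")
        self.voxel_dims = tuple(float(d) for d in self.voxel_dims)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_dims))

    def same_grid(self, other: "LabelVolume") -> bool:
        return self.grid.shape == other.grid.shape and self.voxel_dims == other.voxel_dims

    def label_for(self, region: str) -> int | None:
        for code, name in self.codes.items():
            if name == region:
                return code
        return None

    def mask(self, region: str) -> np.ndarray:
        code = self.label_for(region)
        if code is None:
            raise KeyError(f"region {region!r} not in code map")
        return self.grid == code

    # --- NIfTI I/O -------------------------------------------------------

    def to_nifti(self, path) -> None:
        affine = np.diag(list(self.voxel_dims) + [1.0])
        img = nib.Nifti1Image(self.grid.astype(np.int16), affine)
        # region code map travels in the NIfTI description (best effort)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, codes: dict[int, str] | None = None) -> "LabelVolume":
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj).astype(np.int32)
        dims = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(grid=grid, voxel_dims=dims, codes=dict(codes or {}))
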