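"""Image geometry and the multi-contrast image container.

Coordinates are 0-based continuous voxel coordinates with voxel centers at
integers; the world affine is carried as metadata only and never used for
computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ImageGeometry:
    """Grid shape, physical voxel size (mm per axis) and world affine."""

    shape: tuple[int, ...]
    voxel_size: tuple[float, ...] = None
    affine: np.ndarray = None

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        if self.voxel_size is None:
            self.voxel_size = (1.0,) * len(self.shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != len(self.shape):
            raise ValueError("voxel_size and shape dimensionality mismatch")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^ndim."""
        return float(np.prod(self.voxel_size))

    def voxel_coords(self, mask: np.ndarray | None = None) -> np.ndarray:
        """(M, ndim) array of voxel-center coordinates, optionally masked."""
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in self.shape],
                            indexing="ij")
        coords = np.stack([g.ravel() for g in grids], axis=1)
        if mask is not None:
            coords = coords[np.asarray(mask, bool).ravel()]
        return coords


@dataclass
class MultiContrastImage:
    """Co-registered multi-contrast intensities on one grid.

    ``intensities`` has shape ``(*grid, N)`` for N contrasts.  ``roles``
    optionally names each channel ('t1w', 't2w', 'flair', 'other') so that
    intensity-based lesion candidate rules know which channels are
    FLAIR/T2-like.
    """

    intensities: np.ndarray
    geometry: ImageGeometry
    brain_mask: np.ndarray = None
    roles: tuple[str, ...] = None
    log_domain: bool = False
    log_floor: np.ndarray = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape[:-1] != self.geometry.shape:
            raise ValueError(
                f"intensity grid {self.intensities.shape[:-1]} does not match "
                f"geometry {self.geometry.shape}")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.geometry.shape, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if not self.brain_mask.any():
            raise ValueError("brain mask is empty")
        if self.roles is None:
            self.roles = ("other",) * self.n_contrasts
        self.roles = tuple(self.roles)
        if len(self.roles) != self.n_contrasts:
            raise ValueError("one role per contrast required")

    @property
    def n_contrasts(self) -> int:
        return self.intensities.shape[-1]

    @property
    def n_voxels(self) -> int:
        """Number of voxels inside the brain mask."""
        return int(self.brain_mask.sum())

    def masked(self) -> np.ndarray:
        """(I, N) intensities of masked voxels, in grid raveling order."""
        return self.intensities[self.brain_mask]

    def unmask(self, values: np.ndarray, fill=0.0) -> np.ndarray:
        """Scatter per-masked-voxel values back onto the full grid."""
        values = np.asarray(values)
        out = np.full(self.geometry.shape + values.shape[1:], fill,
                      dtype=values.dtype if values.dtype.kind == "f" else float)
        out[self.brain_mask] = values
        return out
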