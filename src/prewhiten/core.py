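"""Shared containers for 4D BOLD-like data.

A :class:`VolumeSeries` is the unit of data throughout the package: a 4D
scalar field (X x Y x Z x T) with a repetition time (TR, seconds) and a
binary brain mask.  Analysis code works on the flattened in-mask
``voxels x T`` view; NIfTI I/O lives in :mod:`prewhiten.runner`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VolumeSeries:
    """4D scalar field with TR and binary mask.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz, T)
        Image intensities over time.
    tr : float
        Repetition time in seconds (> 0).
    mask : ndarray of bool, shape (nx, ny, nz), optional
        Brain mask; defaults to all-true.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (X,Y,Z,T), got ndim={self.data.ndim}")
        if not self.tr > 0:
            raise ValueError(f"TR must be positive, got {self.tr}")
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape must match spatial dims of data")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels."""
        return int(self.mask.sum())

    def to_matrix(self) -> np.ndarray:
        """In-mask time series as a ``(n_voxels, T)`` float64 array."""
        return np.asarray(self.data[self.mask], dtype=np.float64)

    def from_matrix(self, values: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter a per-voxel vector or matrix back into image space.

        ``values`` of shape ``(n_voxels,)`` yields a 3D map; shape
        ``(n_voxels, T)`` yields a 4D image.  Out-of-mask voxels get ``fill``.
        """
        values = np.asarray(values)
        if values.ndim == 1:
            out = np.full(self.mask.shape, fill, dtype=values.dtype)
            out[self.mask] = values
            return out
        out = np.full(self.mask.shape + (values.shape[1],), fill, dtype=values.dtype)
        out[self.mask] = values
        return out
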