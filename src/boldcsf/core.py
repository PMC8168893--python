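"""Core in-memory containers shared across the pipeline.

Array axis order is fixed as (x, y, z, t); the slice axis is the third
spatial axis, and "bottom slice" means slice index 0. All coordinates are
0-based voxel indices — no world-space geometry is needed anywhere in the
pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeSeries", "RegionMask", "SessionSignals"]


@dataclass
class VolumeSeries:
    """A 4D intensity array (x, y, z, t) with acquisition metadata.

    Parameters
    ----------
    data
        Float array of shape (nx, ny, nz, nt).
    tr_seconds
        Repetition time (sampling interval of the t axis), in seconds.
    voxel_size_mm
        Spatial voxel dimensions (dx, dy, dz) in millimetres; needed for
        smoothing-kernel conversion.
    """

    data: np.ndarray
    tr_seconds: float
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries requires 4D data, got {self.data.ndim}D")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class RegionMask:
    """A 3D boolean mask aligned to a VolumeSeries grid.

    ``role`` labels the mask's purpose: ``"gray_matter"``,
    ``"csf_bottom_slice"`` or ``"template"``.
    """

    data: np.ndarray
    role: str = "gray_matter"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"RegionMask requires 3D data, got {self.data.ndim}D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def indices(self) -> tuple[np.ndarray, ...]:
        return np.nonzero(self.data)


@dataclass
class SessionSignals:
    """The two 1D series extracted from one session.

    ``global_bold`` is the average of per-voxel z-scored gray-matter series
    (its SD measures inter-voxel synchrony and is reused as the session's
    amplitude metric); ``csf`` is the averaged bottom-slice CSF series,
    z-scored as one series.
    """

    global_bold: np.ndarray
    csf: np.ndarray
    tr_seconds: float
    n_discarded_edge_volumes: int = 0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.global_bold = np.asarray(self.global_bold, dtype=float)
        self.csf = np.asarray(self.csf, dtype=float)
        if self.global_bold.shape != self.csf.shape:
            raise ValueError(
                "global_bold and csf must have equal length, got "
                f"{self.global_bold.shape} vs {self.csf.shape}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.global_bold.size
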