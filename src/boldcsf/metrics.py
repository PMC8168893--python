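"""Session-level state and nuisance metrics: global-signal amplitude,
template-based arousal index, framewise displacement."""

from __future__ import annotations

import numpy as np

from .core import VolumeSeries

__all__ = ["global_amplitude", "arousal_index", "framewise_displacement"]


def global_amplitude(global_signal: np.ndarray) -> float:
    """Sample SD of the global BOLD signal.

    Because the global signal is an average of unit-variance voxel series,
    its SD indexes global synchronization; large values mark the drowsy or
    lightly sleeping state.
    """
    x = np.asarray(global_signal, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    return float(x.std(ddof=1))


def arousal_index(volumes: VolumeSeries | np.ndarray, template: np.ndarray) -> float:
    """SD of the volume-to-template spatial-correlation time course.

    Each volume is spatially correlated (Pearson, over the template's
    nonzero support) with an arousal template; the sample SD of that
    correlation time course quantifies the session's arousal fluctuation.
    The index is invariant to affine rescaling of the template.

    ``volumes`` may be a ``VolumeSeries`` with a 3D template, or an
    (n_voxels, n_t) matrix with a length-n_voxels template vector.
    """
    if isinstance(volumes, VolumeSeries):
        template = np.asarray(template, dtype=float)
        if template.shape != volumes.grid_dims:
            raise ValueError("template shape does not match the volume grid")
        support = template != 0
        mat = volumes.data[support]
        tvec = template[support]
    else:
        mat = np.atleast_2d(np.asarray(volumes, dtype=float))
        tvec = np.asarray(template, dtype=float).ravel()
        if tvec.size != mat.shape[0]:
            raise ValueError("template length does not match the voxel count")
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 volumes")
    tvec = tvec - tvec.mean()
    tnorm = np.sqrt(tvec @ tvec)
    if tnorm == 0:
        raise ValueError("template is constant over its support")
    centered = mat - mat.mean(axis=0, keepdims=True)
    norms = np.sqrt((centered * centered).sum(axis=0))
    norms[norms == 0] = np.nan  # a spatially flat volume has undefined correlation
    corr = (tvec @ centered) / (tnorm * norms)
    return float(np.nanstd(corr, ddof=1))


def framewise_displacement(
    motion_params: np.ndarray, radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Framewise displacement from 6 realignment parameter series.

    ``motion_params`` is (6, T): rows 0–2 translations in mm, rows 3–5
    rotations in radians. FD at frame t is the sum of absolute backward
    differences of the three translations plus the three rotational
    differences converted to arc length on a sphere of ``radius_mm``
    (default 50 mm). Returns the T−1 per-frame values and their mean.
    """
    p = np.asarray(motion_params, dtype=float)
    if p.ndim != 2 or p.shape[0] != 6:
        raise ValueError(f"motion_params must be (6, T), got {p.shape}")
    if p.shape[1] < 2:
        raise ValueError("need at least 2 frames")
    d = np.abs(np.diff(p, axis=1))
    fd = d[:3].sum(axis=0) + radius_mm * d[3:].sum(axis=0)
    return fd, float(fd.mean())
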