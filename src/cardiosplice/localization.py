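"""Nuclear/cytoplasmic signal partitioning and Pearson co-localization.

A segmented nuclear mask splits a 3D intensity volume into
compartments; the nuclear percentage is the intensity-weighted share of
total signal inside the mask (percent in compartment divided by total
signal). Co-localization of two channels is the Pearson correlation of
voxel intensities, optionally after max-intensity projection along z
and restricted to a region of interest.
"""

from __future__ import annotations

import numpy as np


def compartment_fractions(
    signal: np.ndarray, nuclear_mask: np.ndarray, intensity_weighted: bool = True
) -> tuple[float, float]:
    """(percent nuclear, percent cytoplasmic) of total signal.

    Intensity-weighted by default; ``intensity_weighted=False`` counts
    signal-positive voxels instead. The two percentages sum to 100.
    """
    signal = np.asarray(signal, dtype=float)
    mask = np.asarray(nuclear_mask, dtype=bool)
    if signal.shape != mask.shape:
        raise ValueError("signal and mask shapes differ")
    if (signal < 0).any() or not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite and non-negative")
    if not intensity_weighted:
        signal = (signal > 0).astype(float)
    total = signal.sum()
    if total <= 0:
        raise ValueError("zero total signal: fractions undefined")
    nuclear = 100.0 * float(signal[mask].sum()) / float(total)
    return nuclear, 100.0 - nuclear


def pearson_colocalization(
    a: np.ndarray,
    b: np.ndarray,
    roi: np.ndarray | None = None,
    max_project: bool = False,
) -> float:
    """Pearson correlation of voxel intensities between two channels.

    With ``max_project`` the volumes (and ROI) are max-projected along
    the first axis before correlating, matching the common
    segment-then-project co-localization workflow.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != a.shape:
            raise ValueError("ROI shape differs from channels")
    if max_project and a.ndim >= 3:
        a = a.max(axis=0)
        b = b.max(axis=0)
        if roi is not None:
            roi = roi.any(axis=0)
    if roi is not None:
        x, y = a[roi], b[roi]
    else:
        x, y = a.ravel(), b.ravel()
    if x.size < 2:
        raise ValueError("need >= 2 voxels to correlate")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance channel: correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])
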