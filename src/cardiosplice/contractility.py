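"""Micropost contractility and MEA field-potential quantification.

Engineered heart tissues are suspended between a rigid and a flexible
PDMS post; contraction bends the flexible post, and twitch force is the
post bending stiffness times the measured deflection,
F_twitch(t) = k_post * delta_post(t). The stiffness of an end-loaded
cantilever of length L and diameter d is k = 3*E*I/L^3 with
I = pi*d^4/64; for E = 2.5 MPa, d = 1.5 mm, L = 12.5 mm this gives
0.95 uN/um. Field potential duration from multi-electrode arrays is
rate-corrected with Fridericia's formula, FPDc = FPD / (beat period)^(1/3),
over the most stable beats per electrode, averaged across electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from skimage import filters, measure


@dataclass(frozen=True)
class PostGeometry:
    """Flexible-post dimensions and material stiffness (SI units)."""

    length_m: float = 12.5e-3
    diameter_m: float = 1.5e-3
    youngs_modulus_pa: float = 2.5e6
    cap_diameter_m: float = 0.0
    cap_length_m: float = 0.0

    def __post_init__(self) -> None:
        if self.length_m <= 0 or self.diameter_m <= 0 or self.youngs_modulus_pa <= 0:
            raise ValueError("post dimensions and modulus must be positive")
        if self.cap_length_m >= self.length_m:
            raise ValueError("cap_length must be smaller than post length")


def post_stiffness(g: PostGeometry) -> float:
    """End-load cantilever stiffness k = 3*E*I/L^3, in uN/um (== N/m).

    The full post length is used as the lever arm.
    """
    second_moment = math.pi * g.diameter_m**4 / 64.0
    return 3.0 * g.youngs_modulus_pa * second_moment / g.length_m**3


@dataclass
class TwitchTrace:
    """Uniformly sampled post deflection, optionally with force."""

    time_s: np.ndarray
    deflection_um: np.ndarray
    force_un: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.time_s) != len(self.deflection_um):
            raise ValueError("time and deflection must have equal length")
        if not np.all(np.isfinite(self.deflection_um)):
            raise ValueError("deflection must be finite")

    @property
    def fps(self) -> float:
        return 1.0 / float(np.median(np.diff(self.time_s)))


@dataclass(frozen=True)
class TwitchMetrics:
    peak_force_un: float
    max_upstroke_un_per_s: float
    max_relaxation_un_per_s: float
    time_to_peak_s: float
    rt50_s: float
    rt90_s: float
    beats_analyzed: int


def track_posts(
    frames: np.ndarray,
    fps: float = 66.0,
    um_per_px: float = 8.3,
) -> TwitchTrace:
    """Deflection trace from a two-post video by centroid tracking.

    Each frame is binarized (Otsu over the whole stack), the two
    largest components are taken as the posts, and intensity-weighted
    centroids give the post separation. Deflection is the decrease of
    separation relative to the resting baseline, taken as the maximum
    of the lightly smoothed separation trace (contraction pulls the
    posts together, so the largest separation is the resting state).
    """
    thresh = filters.threshold_otsu(frames)
    seps = np.empty(frames.shape[0])
    for i, frame in enumerate(frames):
        lab = measure.label(frame > thresh)
        props = measure.regionprops(lab, intensity_image=frame)
        if len(props) < 2:
            raise ValueError(f"frame {i}: found {len(props)} components, expected 2 posts")
        props = sorted(props, key=lambda p: p.area, reverse=True)[:2]
        c0 = np.asarray(props[0].centroid_weighted)
        c1 = np.asarray(props[1].centroid_weighted)
        seps[i] = float(np.hypot(*(c0 - c1))) * um_per_px
    smoothed = savgol_filter(seps, 7, 3) if len(seps) >= 7 else seps
    baseline = float(smoothed.max())
    deflection = baseline - seps
    time = np.arange(frames.shape[0]) / fps
    return TwitchTrace(time, deflection)


def force_trace(trace: TwitchTrace, k_post_un_per_um: float) -> TwitchTrace:
    """F_twitch(t) = k_post * delta_post(t)."""
    return TwitchTrace(
        trace.time_s, trace.deflection_um, k_post_un_per_um * trace.deflection_um
    )


def twitch_metrics(
    trace: TwitchTrace,
    pacing_hz: float = 2.0,
    n_beats: int = 10,
    savgol_window: int = 7,
    savgol_order: int = 3,
) -> TwitchMetrics:
    """Per-beat twitch force and kinetics, averaged over ``n_beats``.

    The force trace is Savitzky-Golay smoothed; per beat, peak force
    above the local baseline (window minimum), time to peak, smoothed
    dF/dt extremes, and RT50/RT90 (time from peak to 50%/90%
    relaxation) are computed and averaged.
    """
    if trace.force_un is None:
        raise ValueError("trace carries no force; apply force_trace first")
    fps = trace.fps
    period_frames = int(round(fps / pacing_hz))
    n_available = len(trace.force_un) // period_frames
    if n_available < n_beats:
        raise ValueError(f"trace contains {n_available} complete beats, need {n_beats}")
    force = trace.force_un
    if len(force) >= savgol_window:
        force = savgol_filter(force, savgol_window, savgol_order)
    dfdt = savgol_filter(
        trace.force_un, savgol_window, savgol_order, deriv=1, delta=1.0 / fps
    )
    peaks, ttps, ups, downs, rt50s, rt90s = [], [], [], [], [], []
    for b in range(n_beats):
        lo, hi = b * period_frames, (b + 1) * period_frames
        f = force[lo:hi]
        base = float(f.min())
        ipk = int(np.argmax(f))
        amp = float(f[ipk] - base)
        peaks.append(amp)
        ttps.append(ipk / fps)
        ups.append(float(dfdt[lo:hi].max()))
        downs.append(float(-dfdt[lo:hi].min()))
        after = f[ipk:]
        rt50s.append(_relax_time(after, base, amp, 0.5, fps))
        rt90s.append(_relax_time(after, base, amp, 0.9, fps))
    return TwitchMetrics(
        peak_force_un=float(np.mean(peaks)),
        max_upstroke_un_per_s=float(np.mean(ups)),
        max_relaxation_un_per_s=float(np.mean(downs)),
        time_to_peak_s=float(np.mean(ttps)),
        rt50_s=float(np.nanmean(rt50s)),
        rt90_s=float(np.nanmean(rt90s)),
        beats_analyzed=n_beats,
    )


def _relax_time(after: np.ndarray, base: float, amp: float, frac: float, fps: float) -> float:
    target = base + (1.0 - frac) * amp
    below = np.flatnonzero(after <= target)
    return float(below[0] / fps) if below.size else float("nan")


# ---------------------------------------------------------------------------
# MEA


def fpdc(records: pd.DataFrame, n_stable_beats: int = 30) -> pd.Series:
    """Rate-corrected field potential duration per well.

    ``records`` columns: electrode, beat, period_s, fpd_s. Per
    electrode, the ``n_stable_beats`` beats with the smallest absolute
    deviation of period from the electrode median are kept; FPDc =
    fpd / period^(1/3) per beat, averaged per electrode and then
    across electrodes. Returns a summary Series.
    """
    req = {"electrode", "period_s", "fpd_s"}
    if not req <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(req)}")
    if (records["fpd_s"] >= records["period_s"]).any():
        bad = records[records["fpd_s"] >= records["period_s"]].index[0]
        raise ValueError(f"row {bad}: FPD must be smaller than the beat period")
    per_electrode = {}
    for e, grp in records.groupby("electrode"):
        dev = (grp["period_s"] - grp["period_s"].median()).abs()
        stable = grp.loc[dev.sort_values(kind="stable").index[:n_stable_beats]]
        vals = stable["fpd_s"] / np.cbrt(stable["period_s"])
        per_electrode[e] = float(vals.mean())
    s = pd.Series(per_electrode)
    return pd.Series(
        {
            "fpdc_s": float(s.mean()),
            "n_electrodes": float(len(s)),
            "mean_period_s": float(records["period_s"].mean()),
            "mean_fpd_s": float(records["fpd_s"].mean()),
        }
    )
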