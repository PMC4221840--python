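"""TIC/EIC construction, peak detection and trapezoidal area integration."""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .simulate import Run


class EmptyRunError(ValueError):
    pass


class OutOfRangeError(ValueError):
    """Target m/z outside the run's scanned range."""


class WindowError(ValueError):
    """Integration window outside the chromatogram."""


@dataclass
class Chromatogram:
    """An intensity-vs-retention-time trace: total (TIC) or extracted (EIC)."""

    kind: str  # "tic" or "eic"
    rt: np.ndarray
    intensity: np.ndarray
    target_mz: Optional[int] = None

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.size != self.intensity.size:
            raise ValueError("rt and intensity lengths differ")
        if np.any(np.diff(self.rt) <= 0):
            raise ValueError("rt must be strictly increasing")
        if self.kind == "eic" and self.target_mz is None:
            raise ValueError("an EIC needs a target m/z")


@dataclass(frozen=True)
class Peak:
    """A detected, baseline-corrected chromatographic peak."""

    apex_rt: float
    start_rt: float
    end_rt: float
    height: float
    area: float

    def __post_init__(self) -> None:
        if not (self.start_rt < self.apex_rt < self.end_rt):
            raise ValueError("peak boundaries must bracket the apex")
        if self.height <= 0 or self.area <= 0:
            raise ValueError("peak height and area must be positive")


def compute_tic(run: Run) -> Chromatogram:
    """Total ion chromatogram: per-scan sum of all centroid intensities."""
    if not run.scans:
        raise EmptyRunError("cannot compute a TIC of an empty run")
    intensity = np.array([float(s.intensity.sum()) for s in run.scans])
    return Chromatogram(kind="tic", rt=run.rts, intensity=intensity)


def extract_eic(run: Run, mz: int, tol: float = 0.5) -> Chromatogram:
    """Extracted-ion chromatogram at ``mz`` +/- ``tol`` Th (mass chromatogram)."""
    if not run.scans:
        raise EmptyRunError("cannot extract an EIC from an empty run")
    lo, hi = run.mz_range
    if not (lo <= mz <= hi):
        raise OutOfRangeError(f"m/z {mz} outside scanned range {lo}-{hi}")
    idx, flat_mz, flat_int = run.flat()
    mask = np.abs(flat_mz - mz) <= tol
    intensity = np.zeros(len(run.scans))
    np.add.at(intensity, idx[mask], flat_int[mask])
    return Chromatogram(kind="eic", rt=run.rts, intensity=intensity, target_mz=mz)


def _smooth(intensity: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd number of points")
    if window == 1:
        return intensity.astype(float)
    kernel = np.ones(window)
    # 'same' convolution normalized by the actual number of points averaged,
    # so edges are true means rather than zero-padded ones
    num = np.convolve(intensity, kernel, mode="same")
    den = np.convolve(np.ones_like(intensity, dtype=float), kernel, mode="same")
    return num / den


def _merge_shallow_valleys(smoothed: np.ndarray, apexes: list[int]) -> list[int]:
    """Collapse apex pairs whose separating valley stays above half the
    lower apex: such doublets are intensity jitter on one peak top, not two
    chromatographically (valley-)resolved peaks."""
    merged = True
    while merged and len(apexes) > 1:
        merged = False
        for i in range(len(apexes) - 1):
            a, b = apexes[i], apexes[i + 1]
            valley = float(smoothed[a : b + 1].min())
            if valley > 0.5 * min(smoothed[a], smoothed[b]):
                drop = i if smoothed[a] < smoothed[b] else i + 1
                del apexes[drop]
                merged = True
                break
    return apexes


def detect_peaks(
    chrom: Chromatogram,
    min_height_frac: float = 0.01,
    smooth_window: int = 5,
) -> list[Peak]:
    """Detect peaks on a smoothed trace.

    Local maxima of the moving-average trace above ``min_height_frac`` of
    its global maximum become peak apexes; boundaries extend downhill to
    the nearest flanking local minimum or to where the smoothed signal
    drops below 0.5% of the apex.  Returns peaks sorted by apex rt.
    """
    if chrom.rt.size < 5:
        raise ValueError("need at least 5 points to detect peaks")
    smoothed = _smooth(chrom.intensity, smooth_window)
    gmax = float(smoothed.max(initial=0.0))
    if gmax <= 0:
        return []
    apexes, _ = signal.find_peaks(smoothed, height=min_height_frac * gmax)
    apexes = _merge_shallow_valleys(smoothed, list(apexes))
    peaks: list[Peak] = []
    for apex in apexes:
        floor = 0.005 * smoothed[apex]
        left = apex
        while left > 0 and smoothed[left - 1] <= smoothed[left] and smoothed[left - 1] >= floor:
            left -= 1
        if left > 0 and smoothed[left - 1] < floor:
            left -= 1
        right = apex
        n = smoothed.size
        while (
            right < n - 1
            and smoothed[right + 1] <= smoothed[right]
            and smoothed[right + 1] >= floor
        ):
            right += 1
        if right < n - 1 and smoothed[right + 1] < floor:
            right += 1
        if left >= apex or right <= apex:
            continue  # apex at the chromatogram edge: not an integrable peak
        window = (float(chrom.rt[left]), float(chrom.rt[right]))
        area = integrate(chrom, window)
        height = float(chrom.intensity[left : right + 1].max())
        if area <= 0 or height <= 0:
            continue
        peaks.append(
            Peak(
                apex_rt=float(chrom.rt[apex]),
                start_rt=window[0],
                end_rt=window[1],
                height=height,
                area=area,
            )
        )
    return sorted(peaks, key=lambda p: p.apex_rt)


def integrate(chrom: Chromatogram, window: tuple[float, float]) -> float:
    """Trapezoidal peak area over ``window`` minus a local linear baseline.

    The baseline runs between the trace values at the window endpoints;
    the result is floored at zero.
    """
    lo, hi = window
    if lo >= hi:
        raise WindowError(f"empty window {window}")
    if lo < chrom.rt[0] - 1e-12 or hi > chrom.rt[-1] + 1e-12:
        raise WindowError(f"window {window} outside chromatogram range "
                          f"({chrom.rt[0]}, {chrom.rt[-1]})")
    mask = (chrom.rt >= lo - 1e-12) & (chrom.rt <= hi + 1e-12)
    rt = chrom.rt[mask]
    y = chrom.intensity[mask]
    if rt.size < 2:
        raise WindowError(f"window {window} contains fewer than 2 points")
    baseline = np.interp(rt, [rt[0], rt[-1]], [y[0], y[-1]])
    area = float(np.trapezoid(y - baseline, rt))
    return max(area, 0.0)


def peak_list_frame(peaks: list[Peak]) -> pd.DataFrame:
    """Peak list as a DataFrame (apex_rt, start_rt, end_rt, height, area),
    ready for CSV export."""
    return pd.DataFrame(
        [
            {
                "apex_rt": p.apex_rt,
                "start_rt": p.start_rt,
                "end_rt": p.end_rt,
                "height": p.height,
                "area": p.area,
            }
            for p in peaks
        ],
        columns=["apex_rt", "start_rt", "end_rt", "height", "area"],
    )
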