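"""Chromatographic peak detection and cross-channel alignment.

Peak picking operates on extracted-ion chromatograms: traces are smoothed
with a 3-point moving average, local maxima are extended to their flanking
valleys, and the noise level is estimated robustly (median absolute
deviation of the off-peak trace scaled to sigma). Peaks from the diagnostic
ion EICs of different in-source collision-energy channels are then grouped
by apex retention time, so that a monophthalate eluting at one RT appears as
a single co-elution group carrying all its diagnostic ions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .msdata_io import EICTrace

__all__ = [
    "ChromatographicPeak",
    "CoelutionGroup",
    "detect_peaks",
    "align_across_channels",
    "peaks_to_frame",
]

MAD_TO_SIGMA = 1.4826


@dataclass
class ChromatographicPeak:
    """A detected EIC peak: apex, integration bounds, area and S/N."""

    apex_rt_min: float
    apex_intensity: float
    area: float
    left_rt: float
    right_rt: float
    snr: float
    source_trace: EICTrace | None = None
    ion_mz: float | None = None
    channel_ce_v: float | None = None

    def __post_init__(self) -> None:
        if not (self.left_rt <= self.apex_rt_min <= self.right_rt):
            raise ValueError("apex RT must lie within the peak bounds")
        if self.apex_intensity <= 0:
            raise ValueError("apex intensity must be positive")
        if self.snr < 0:
            raise ValueError("snr must be non-negative")


@dataclass
class CoelutionGroup:
    """Diagnostic-ion peaks from several channels sharing one apex RT."""

    consensus_rt_min: float
    member_peaks: list[ChromatographicPeak] = field(default_factory=list)

    @property
    def n_distinct_diagnostic_ions(self) -> int:
        return len({p.ion_mz for p in self.member_peaks if p.ion_mz is not None})

    @property
    def max_intensity(self) -> float:
        return max(p.apex_intensity for p in self.member_peaks)


def _smooth3(y: np.ndarray) -> np.ndarray:
    # 3-point moving average with shrinking window at the edges
    s = np.convolve(y, np.ones(3), mode="same")
    n = np.convolve(np.ones_like(y), np.ones(3), mode="same")
    return s / n


def detect_peaks(
    trace: EICTrace,
    min_intensity: float = 0.0,
    snr_min: float = 3.0,
    ion_mz: float | None = None,
    channel_ce_v: float | None = None,
) -> list[ChromatographicPeak]:
    """Detect chromatographic peaks on an EIC trace.

    Local maxima of the 3-point-smoothed trace are extended left and right
    to the nearest valleys; the noise is the MAD of the raw trace outside
    all detected peak regions, scaled by 1.4826 (floored at 1 count), and
    S/N is apex/noise. Peaks with raw apex below ``min_intensity`` or S/N
    below ``snr_min`` are discarded. Traces shorter than 5 points produce
    an empty list with a warning.
    """
    y = np.asarray(trace.intensity, dtype=np.float64)
    rt = np.asarray(trace.rt_min, dtype=np.float64)
    if y.size < 5:
        warnings.warn("trace has fewer than 5 points; no peak detection")
        return []

    ys = _smooth3(y)
    candidates: list[tuple[int, int, int]] = []  # (left, apex, right) indices
    in_peak = np.zeros(y.size, dtype=bool)
    for i in range(1, y.size - 1):
        if ys[i] > ys[i - 1] and ys[i] >= ys[i + 1] and ys[i] > 0:
            left = i
            while left > 0 and ys[left - 1] < ys[left]:
                left -= 1
            right = i
            while right < y.size - 1 and ys[right + 1] < ys[right]:
                right += 1
            candidates.append((left, i, right))
            in_peak[left : right + 1] = True

    if not candidates:
        return []

    off_peak = y[~in_peak]
    if off_peak.size:
        mad = np.median(np.abs(off_peak - np.median(off_peak)))
        noise = max(MAD_TO_SIGMA * mad, 1.0)
    else:
        noise = 1.0

    peaks: list[ChromatographicPeak] = []
    for left, apex_s, right in candidates:
        seg = slice(left, right + 1)
        apex_i = left + int(np.argmax(y[seg]))
        apex = float(y[apex_i])
        if apex <= 0 or apex < min_intensity:
            continue
        snr = apex / noise
        if snr < snr_min:
            continue
        area = float(np.trapezoid(y[seg], rt[seg]))
        peaks.append(
            ChromatographicPeak(
                apex_rt_min=float(rt[apex_i]),
                apex_intensity=apex,
                area=area,
                left_rt=float(rt[left]),
                right_rt=float(rt[right]),
                snr=snr,
                source_trace=trace,
                ion_mz=ion_mz if ion_mz is not None else (trace.target_mz or None),
                channel_ce_v=channel_ce_v,
            )
        )
    peaks.sort(key=lambda p: p.apex_rt_min)
    return peaks


def align_across_channels(
    peaks: list[ChromatographicPeak],
    rt_align_tol_min: float = 0.1,
) -> list[CoelutionGroup]:
    """Group peaks whose apexes co-elute across ions and CE channels.

    Single-linkage clustering on apex RT: peaks are sorted by apex and a new
    group starts whenever the gap to the previous apex exceeds
    ``rt_align_tol_min``. The consensus RT is the intensity-weighted mean of
    member apexes.
    """
    if not peaks:
        return []
    ordered = sorted(peaks, key=lambda p: p.apex_rt_min)
    groups: list[list[ChromatographicPeak]] = [[ordered[0]]]
    for p in ordered[1:]:
        if p.apex_rt_min - groups[-1][-1].apex_rt_min <= rt_align_tol_min:
            groups[-1].append(p)
        else:
            groups.append([p])

    out = []
    for members in groups:
        w = np.array([p.apex_intensity for p in members])
        rts = np.array([p.apex_rt_min for p in members])
        out.append(
            CoelutionGroup(
                consensus_rt_min=float(np.average(rts, weights=w)),
                member_peaks=members,
            )
        )
    return out


def peaks_to_frame(peaks: list[ChromatographicPeak]):
    """Peak table as a DataFrame (one row per detected peak)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "ion_mz": p.ion_mz,
                "channel_ce_v": p.channel_ce_v,
                "apex_rt_min": p.apex_rt_min,
                "apex_intensity": p.apex_intensity,
                "area": p.area,
                "snr": p.snr,
            }
            for p in peaks
        ]
    )
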