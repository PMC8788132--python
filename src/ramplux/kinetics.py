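"""Peak detection and half-max kinetics on cycle-averaged responses.

A significant peak is a local maximum of the cycle-averaged z-trace whose
topographic prominence exceeds 0.75 z-units. Peaks are detected on the
cyclically extended signal (three tiled periods) so a response straddling
the cycle seam is found once, with the standard lowest-contour-line
prominence definition.

Two summary statistics describe response kinetics:

* **LUX-at-half-max** — the stimulus luminance at the time the response
  first reaches 50% of its peak value (the rising, pre-peak crossing of
  the half-height level). For DUAL responses the more prominent
  falling-phase (OFF) peak is used.
* **width-at-half-max** — the duration between the two half-height
  crossings flanking a peak; with multiple significant peaks the widths
  are averaged.

Half-height is referenced to the baseline of the cycle response, taken as
the minimum of the cycle-averaged trace (switchable to prominence-
referenced half-height via ``baseline="prominence"``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.signal import find_peaks as _scipy_find_peaks

from .preprocess import CycleResponse
from .stimulus import Phase, RampStimulus

#: minimum topographic prominence (z-units) for a significant peak
MIN_PROMINENCE = 0.75


@dataclass
class Peak:
    """A significant peak of a cycle response.

    Times are seconds-in-cycle; ``left_half_t``/``right_half_t`` are the
    interpolated crossings of the half-height level flanking the peak and
    may extend beyond ``[0, period)`` when a crossing wraps the seam.
    ``truncated`` flags a crossing not found within one full cycle.
    """

    t_peak: float
    height: float
    prominence: float
    left_half_t: float
    right_half_t: float
    half_level: float
    truncated: bool = False

    @property
    def width(self) -> float:
        return self.right_half_t - self.left_half_t


@dataclass
class KineticsSummary:
    """Per-ROI kinetics: significant peaks and half-max statistics."""

    peaks: List[Peak]
    lux_at_half_max: Optional[float]
    width_at_half_max: Optional[float]
    class_hint: str  # "none" | "single-peak" | "dual-peak"
    roi_id: str = ""


def find_peaks(
    cr: CycleResponse,
    min_prominence: float = MIN_PROMINENCE,
    baseline: str = "cycle-min",
) -> List[Peak]:
    """Detect significant peaks of a cycle response (circular topography).

    The cycle is tiled three times, peaks are located with their
    topographic prominences, and those of the middle tile with prominence
    strictly greater than ``min_prominence`` are reported, each once, at
    seconds-in-cycle in ``[0, period)``.
    """
    z = np.asarray(cr.z, dtype=float)
    n = z.size
    if n < 3:
        raise ValueError("cycle response needs >= 3 samples")
    tiled = np.concatenate([z, z, z])
    idx, props = _scipy_find_peaks(tiled, prominence=(None, None))
    keep = (idx >= n) & (idx < 2 * n) & (props["prominences"] > min_prominence)
    peak_idx = idx[keep]
    proms = props["prominences"][keep]

    if baseline == "cycle-min":
        base = float(z.min())
    elif baseline == "prominence":
        base = None  # per-peak: height - prominence
    else:
        raise ValueError("baseline must be 'cycle-min' or 'prominence'")

    dt = 1.0 / cr.rate_hz
    peaks = []
    for i, prom in zip(peak_idx, proms):
        h = float(tiled[i])
        b = (h - float(prom)) if base is None else base
        half = b + 0.5 * (h - b)
        lt, l_trunc = _cross_left(tiled, i, half, n)
        rt, r_trunc = _cross_right(tiled, i, half, n)
        peaks.append(
            Peak(
                t_peak=(i - n) * dt,
                height=h,
                prominence=float(prom),
                left_half_t=(lt - n) * dt,
                right_half_t=(rt - n) * dt,
                half_level=half,
                truncated=l_trunc or r_trunc,
            )
        )
    peaks.sort(key=lambda p: p.t_peak)
    return peaks


def _cross_left(y: np.ndarray, i: int, level: float, max_steps: int):
    """Interpolated index where y first drops to ``level`` left of peak i."""
    j = i
    while j > i - max_steps and j > 0 and y[j] > level:
        j -= 1
    if y[j] > level:  # never crossed within one cycle
        return float(j), True
    if y[j] == level or j == i:
        return float(j), False
    # linear interpolation between j (<= level) and j+1 (> level)
    frac = (level - y[j]) / (y[j + 1] - y[j])
    return j + frac, False


def _cross_right(y: np.ndarray, i: int, level: float, max_steps: int):
    j = i
    last = min(i + max_steps, y.size - 1)
    while j < last and y[j] > level:
        j += 1
    if y[j] > level:
        return float(j), True
    if y[j] == level or j == i:
        return float(j), False
    frac = (y[j - 1] - level) / (y[j - 1] - y[j])
    return j - 1 + frac, False


def peak_phase(peak: Peak, stim: RampStimulus) -> Phase:
    """Ramp phase (RISING/FALLING) at the peak time."""
    return stim.phase_at(stim.t_start + peak.t_peak)


def select_offpeak(peaks: List[Peak], stim: RampStimulus) -> Peak:
    """Peak used for LUX-at-half-max.

    Single peak: that peak. Multiple peaks: the most prominent peak on the
    falling (OFF) leg; if no peak falls on the falling leg, the most
    prominent peak overall is used with a warning.
    """
    if not peaks:
        raise ValueError("no significant peaks")
    if len(peaks) == 1:
        return peaks[0]
    falling = [p for p in peaks if peak_phase(p, stim) is Phase.FALLING]
    pool = falling
    if not falling:
        warnings.warn(
            "multi-peak response with no falling-phase peak; "
            "using the most prominent peak"
        )
        pool = peaks
    return max(pool, key=lambda p: p.prominence)


def lux_at_half_max(
    peaks: List[Peak], cr: CycleResponse, stim: RampStimulus
) -> Optional[float]:
    """Luminance at which the response reaches 50% of its peak.

    The rising (pre-peak) half-height crossing time of the selected peak is
    mapped through the triangular luminance trajectory. Returns ``None``
    when there is no significant peak.
    """
    if not peaks:
        return None
    p = select_offpeak(peaks, stim)
    tau = p.left_half_t % stim.period
    lux, _ = stim.lux_at(stim.t_start + tau)
    return float(lux)


def width_at_half_max(peaks: List[Peak], cr: CycleResponse) -> Optional[float]:
    """Mean width (s) between half-height crossings over significant peaks."""
    if not peaks:
        return None
    return float(np.mean([p.width for p in peaks]))


def analyze(
    cr: CycleResponse,
    stim: RampStimulus,
    min_prominence: float = MIN_PROMINENCE,
    baseline: str = "cycle-min",
) -> KineticsSummary:
    """Full kinetics for one cycle response."""
    peaks = find_peaks(cr, min_prominence=min_prominence, baseline=baseline)
    hint = "none" if not peaks else ("single-peak" if len(peaks) == 1 else "dual-peak")
    return KineticsSummary(
        peaks=peaks,
        lux_at_half_max=lux_at_half_max(peaks, cr, stim),
        width_at_half_max=width_at_half_max(peaks, cr),
        class_hint=hint,
        roi_id=cr.roi_id,
    )


def kinetics_table(summaries: List[KineticsSummary]) -> pd.DataFrame:
    """Tabulate kinetics summaries (one row per ROI; units in column names)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "roi_id": s.roi_id,
                "n_peaks": len(s.peaks),
                "lux_at_half_max_lux": s.lux_at_half_max,
                "width_at_half_max_s": s.width_at_half_max,
                "class_hint": s.class_hint,
                "peak_times_s": ";".join(f"{p.t_peak:.3f}" for p in s.peaks),
                "peak_prominences_z": ";".join(
                    f"{p.prominence:.3f}" for p in s.peaks
                ),
            }
        )
    return pd.DataFrame(rows)
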