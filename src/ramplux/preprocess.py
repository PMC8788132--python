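"""Trace normalization, responsiveness gating, and cycle averaging.

Raw fluorescence traces are z-scored with statistics taken over the stimulus
window (z = (x - mu) / sigma, with mu and sigma computed from stimulus onset
to stimulus end), traces whose z-score never leaves +/-0.5 are flagged
nonresponsive, and responsive traces are folded over the ramp cycle and
averaged to one representative cycle response.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .stimulus import RampStimulus

#: z-score bound of the responsiveness gate: a trace whose z-score never
#: exceeds +/- this value over the stimulus window is nonresponsive.
GATE_Z = 0.5

RESPONSIVE = "RESPONSIVE"
NONRESPONSIVE = "NONRESPONSIVE"


@dataclass
class Trace:
    """One ROI's fluorescence series sampled uniformly at ``rate_hz``."""

    values: np.ndarray
    rate_hz: float
    roi_id: str = ""
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValueError("trace needs >= 2 samples")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.rate_hz


@dataclass
class NormalizedTrace:
    """z-scored trace plus the stimulus window used for the statistics."""

    z: np.ndarray
    rate_hz: float
    window: tuple
    roi_id: str = ""
    t0: float = 0.0
    constant: bool = False

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.z.size) / self.rate_hz

    def window_mask(self) -> np.ndarray:
        lo, hi = self.window
        t = self.times
        return (t >= lo - 1e-9) & (t <= hi + 1e-9)


@dataclass
class CycleResponse:
    """Cycle-averaged z-scored response over one ramp period."""

    z: np.ndarray
    rate_hz: float
    period_s: float
    n_cycles_averaged: int
    roi_id: str = ""

    @property
    def times(self) -> np.ndarray:
        """Seconds-in-cycle of each sample (cycle start = luminance minimum)."""
        return np.arange(self.z.size) / self.rate_hz


def zscore(trace: Trace, stim: RampStimulus, ddof: int = 0) -> NormalizedTrace:
    """z-score a trace with mean/sd taken over the stimulus window.

    ``sigma`` uses the population (N) denominator by default; pass
    ``ddof=1`` for the sample convention. A constant window (sigma == 0)
    yields an all-zero trace flagged ``constant`` — treated as
    nonresponsive downstream — rather than a division by zero.
    """
    t = trace.times
    mask = (t >= stim.t_start - 1e-9) & (t <= stim.t_end + 1e-9)
    if mask.sum() < 2:
        raise ValueError("stimulus window contains fewer than 2 samples")
    win = trace.values[mask]
    mu = float(win.mean())
    sigma = float(win.std(ddof=ddof))
    if sigma == 0.0 or np.ptp(win) == 0.0:
        return NormalizedTrace(
            z=np.zeros_like(trace.values),
            rate_hz=trace.rate_hz,
            window=(stim.t_start, stim.t_end),
            roi_id=trace.roi_id,
            t0=trace.t0,
            constant=True,
        )
    return NormalizedTrace(
        z=(trace.values - mu) / sigma,
        rate_hz=trace.rate_hz,
        window=(stim.t_start, stim.t_end),
        roi_id=trace.roi_id,
        t0=trace.t0,
    )


def responsiveness_gate(nt: NormalizedTrace, bound: float = GATE_Z) -> str:
    """Gate on the z-score never exceeding ``+/-bound`` in the window.

    Returns NONRESPONSIVE iff max |z| <= bound over the stimulus window
    (the boundary value itself does not count as a response).
    """
    if nt.constant:
        return NONRESPONSIVE
    zwin = nt.z[nt.window_mask()]
    return NONRESPONSIVE if np.max(np.abs(zwin)) <= bound else RESPONSIVE


def cycle_average(nt: NormalizedTrace, stim: RampStimulus) -> CycleResponse:
    """Fold the windowed trace over the ramp period and average pointwise.

    Samples are assigned to the canonical cycle grid of
    ``round(period * rate_hz)`` points by nearest folded time (for uniform
    sampling this is index-modulo assignment); partial trailing cycles are
    discarded. Raises if the window holds no complete cycle.
    """
    n = int(round(stim.period * nt.rate_hz))
    if n < 1:
        raise ValueError("sampling rate too low to resolve one cycle")
    mask = nt.window_mask()
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        raise ValueError("no samples in stimulus window")
    # first sample at/after stimulus onset anchors cycle phase zero
    z = nt.z[idx[0]:]
    n_complete = z.size // n
    if n_complete < 1:
        raise ValueError("stimulus window contains no complete cycle")
    folded = z[: n_complete * n].reshape(n_complete, n)
    return CycleResponse(
        z=folded.mean(axis=0),
        rate_hz=nt.rate_hz,
        period_s=stim.period,
        n_cycles_averaged=n_complete,
        roi_id=nt.roi_id,
    )


def preprocess_trace(trace: Trace, stim: RampStimulus):
    """Run zscore -> gate -> cycle_average for one trace.

    Returns ``(NormalizedTrace, gate_label, CycleResponse)``; the cycle
    response is computed for gated-out traces too (callers may still want
    the averaged shape of a nonresponder).
    """
    nt = zscore(trace, stim)
    gate = responsiveness_gate(nt)
    cr = cycle_average(nt, stim)
    return nt, gate, cr


# ---------------------------------------------------------------------------
# trace-table I/O: rows = ROIs, columns = time samples, header row of times


def read_traces(path, rate_hz: Optional[float] = None) -> list:
    """Read a delimited trace table (rows = ROIs, columns = time samples).

    The header row holds sample times in seconds; a leading ``roi_id``
    column is used as the ROI identifier when present. ``rate_hz`` is
    inferred from the header spacing unless given.
    """
    df = pd.read_csv(path)
    meta_cols = [c for c in df.columns if not _is_number(c)]
    time_cols = [c for c in df.columns if _is_number(c)]
    if len(time_cols) < 2:
        raise ValueError(f"{path}: expected a header row of sample times")
    times = np.array([float(c) for c in time_cols])
    if rate_hz is None:
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-3):
            raise ValueError(f"{path}: non-uniform sample times in header")
        rate_hz = 1.0 / dt[0]
    traces = []
    for i, row in df.iterrows():
        roi = str(row["roi_id"]) if "roi_id" in meta_cols else str(i)
        meta = {c: row[c] for c in meta_cols if c != "roi_id"}
        traces.append(
            Trace(
                values=row[time_cols].to_numpy(dtype=float),
                rate_hz=rate_hz,
                roi_id=roi,
                t0=float(times[0]),
                meta=meta,
            )
        )
    return traces


def write_traces(path, traces: list) -> None:
    """Write traces in the same rows-as-ROIs delimited layout."""
    rows = []
    for tr in traces:
        row = {"roi_id": tr.roi_id}
        row.update(tr.meta)
        row.update({f"{t:.6g}": v for t, v in zip(tr.times, tr.values)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _is_number(s) -> bool:
    try:
        float(s)
        return True
    except (TypeError, ValueError):
        return False
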