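"""Receptive-field mapping from checkerboard trials.

The peak z-scored signal during each square presentation (z computed over
the entire recording) fills a per-hemifield response grid; RF size is the
number of positions with z >= 1.5 (1.5 SDs above the whole-trace mean);
binocular units have at least one suprathreshold position in each
hemifield, and the contra/ipsi size ratio and the count of discontiguous
suprathreshold regions describe RF asymmetry and compoundness. Tier
comparisons test spatial summation along the RGC -> SMTL -> PyrN pathway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .preprocess import Trace
from .segment import EIGHT_CONN
from .stimulus import CheckerboardStimulus

#: RF inclusion threshold (z-units, inclusive)
RF_Z_MIN = 1.5

#: seconds after stimulus offset still searched for the (slow indicator) peak
DEFAULT_LAG_S = 2.0


@dataclass
class RFMap:
    """Per-position peak-response grid for one hemifield."""

    grid: np.ndarray  # n_rows x n_cols of z values
    side: str = ""
    unit_id: str = ""
    threshold: float = RF_Z_MIN

    def suprathreshold(self, z_min: Optional[float] = None) -> np.ndarray:
        z = self.threshold if z_min is None else z_min
        return self.grid >= z


@dataclass
class RFSummary:
    """Binocular RF summary for one unit."""

    unit_id: str
    size_contra: int
    size_ipsi: int
    ratio: Optional[float]  # contra/ipsi; None when monocular
    binocular: bool
    n_components_contra: int
    n_components_ipsi: int
    tier: str = ""


def rf_map(
    trace: Trace,
    stim: CheckerboardStimulus,
    lag_s: float = DEFAULT_LAG_S,
    side: str = "",
    stats: Optional[tuple] = None,
) -> RFMap:
    """Build a hemifield RF map from one unit's full-schedule trace.

    The trace is z-scored with its whole-recording mean and SD (pass
    ``stats=(mu, sd)`` to normalize against statistics pooled over a
    longer recording, e.g. both hemifield presentations of one session);
    each trial's value is the maximum z within ``[t_on, t_off + lag_s]``
    (the lag catches the slow indicator's peak after square offset),
    placed at the trial's grid position. The map is independent of the
    pseudorandom presentation order.
    """
    sched = stim.trial_schedule()
    t = trace.times - trace.t0
    if t[-1] + 1.0 / trace.rate_hz < sched[-1][2]:
        raise ValueError("trace does not span the full trial schedule")
    mu, sd = stats if stats is not None else (
        trace.values.mean(), trace.values.std()
    )
    if sd == 0:
        z = np.zeros_like(trace.values)
    else:
        z = (trace.values - mu) / sd
    grid = np.full((stim.n_rows, stim.n_cols), np.nan)
    for row, col, t_on, t_off in sched:
        m = (t >= t_on - 1e-9) & (t <= t_off + lag_s + 1e-9)
        if not m.any():
            raise ValueError(f"no samples in trial window [{t_on}, {t_off}]")
        grid[row, col] = z[m].max()
    if np.isnan(grid).any():
        raise ValueError("incomplete schedule: some positions missing")
    return RFMap(grid=grid, side=side or stim.side, unit_id=trace.roi_id)


def binocular_maps(
    traces: Dict[str, Trace],
    stims: Dict[str, "CheckerboardStimulus"],
    lag_s: float = DEFAULT_LAG_S,
) -> Dict[str, RFMap]:
    """RF maps for both hemifields with z statistics pooled across sides.

    The two hemifield presentations belong to one imaging session of the
    same unit, so "the entire trace" for normalization is their
    concatenation: a hemifield that evokes no response is then scored
    against the unit's genuine response variance rather than against its
    own noise floor.
    """
    allv = np.concatenate([traces[s].values for s in stims])
    stats = (float(allv.mean()), float(allv.std()))
    return {
        s: rf_map(traces[s], stims[s], lag_s=lag_s, side=s, stats=stats)
        for s in stims
    }


def rf_map_from_peaks(
    peaks: pd.DataFrame, stim: CheckerboardStimulus, side: str = "", unit_id: str = ""
) -> RFMap:
    """RF map from a per-trial peak table (columns row, col, value).

    Values are z-scored against the mean/SD of the full set of trial
    peaks — the peak-table analogue of whole-trace normalization.
    """
    if len(peaks) != stim.n_positions:
        raise ValueError("peak table must have one row per grid position")
    v = peaks["value"].to_numpy(dtype=float)
    sd = v.std()
    z = np.zeros_like(v) if sd == 0 else (v - v.mean()) / sd
    grid = np.full((stim.n_rows, stim.n_cols), np.nan)
    for (r, c), zz in zip(peaks[["row", "col"]].to_numpy(int), z):
        grid[r, c] = zz
    if np.isnan(grid).any():
        raise ValueError("peak table does not cover every grid position")
    return RFMap(grid=grid, side=side, unit_id=unit_id)


def rf_size(rfmap: RFMap, z_min: float = RF_Z_MIN) -> int:
    """Number of positions whose response z-score is >= ``z_min``."""
    return int(rfmap.suprathreshold(z_min).sum())


def n_components(rfmap: RFMap, z_min: float = RF_Z_MIN) -> int:
    """Discontiguous (8-connected) suprathreshold regions — compound-RF count."""
    _, n = ndimage.label(rfmap.suprathreshold(z_min), structure=EIGHT_CONN)
    return int(n)


def binocular_summary(
    contra: RFMap,
    ipsi: RFMap,
    z_min: float = RF_Z_MIN,
    tier: str = "",
) -> RFSummary:
    """Combine both hemifield maps into sizes, ratio, and binocularity."""
    sc, si = rf_size(contra, z_min), rf_size(ipsi, z_min)
    return RFSummary(
        unit_id=contra.unit_id or ipsi.unit_id,
        size_contra=sc,
        size_ipsi=si,
        ratio=(sc / si) if (si > 0 and sc > 0) else None,
        binocular=(sc >= 1 and si >= 1),
        n_components_contra=n_components(contra, z_min),
        n_components_ipsi=n_components(ipsi, z_min),
        tier=tier,
    )


def summary_table(summaries: Sequence[RFSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "unit_id": s.unit_id,
                "tier": s.tier,
                "size_contra": s.size_contra,
                "size_ipsi": s.size_ipsi,
                "ratio": s.ratio,
                "binocular": s.binocular,
                "n_components_contra": s.n_components_contra,
                "n_components_ipsi": s.n_components_ipsi,
            }
            for s in summaries
        ]
    )


def tier_comparison(sizes_by_tier: Dict[str, Sequence[float]]) -> pd.DataFrame:
    """Per-tier RF size mean +/- SEM and the spatial-summation ordering.

    The returned frame carries an ``ordering_pyrn_gt_smtl_ge_rgc``
    attribute: True when mean(PyrN) > mean(SMTL) >= mean(RGC), the
    signature of union convergence along the pathway.
    """
    rows = []
    means = {}
    for tier, sizes in sizes_by_tier.items():
        sizes = np.asarray(list(sizes), dtype=float)
        if sizes.size == 0:
            raise ValueError(f"empty tier {tier!r}")
        sem = sizes.std(ddof=1) / np.sqrt(sizes.size) if sizes.size > 1 else np.nan
        means[tier] = sizes.mean()
        rows.append(
            {"tier": tier, "n": sizes.size, "mean_size": sizes.mean(), "sem": sem}
        )
    df = pd.DataFrame(rows)
    if {"PyrN", "SMTL", "RGC"} <= set(means):
        df.attrs["ordering_pyrn_gt_smtl_ge_rgc"] = bool(
            means["PyrN"] > means["SMTL"] >= means["RGC"]
        )
    return df
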