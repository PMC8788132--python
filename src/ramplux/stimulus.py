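"""Deterministic stimulus models.

Two stimuli drive every analysis in this package:

* a whole-field triangular luminance ramp (linear rise from ``min_lux`` to
  ``max_lux`` over ``ramp_s`` seconds, then a linear fall back, repeated for
  ``n_cycles`` cycles), and
* a receptive-field mapping checkerboard — single bright squares flashed one
  at a time at each position of a grid in a seeded pseudorandom order.

Both are pure time->value maps; no display rendering happens here.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np


class Phase(enum.Enum):
    """Leg of the triangular ramp a time point falls on.

    Legs are half-open: cycle time 0 is RISING, cycle time ``ramp_s``
    (the apex) is FALLING, so every sample has an unambiguous phase.
    """

    RISING = "RISING"
    FALLING = "FALLING"


class OutOfWindowError(ValueError):
    """Requested time lies outside the stimulus presentation window."""


@dataclass(frozen=True)
class RampStimulus:
    """Triangular whole-field luminance ramp.

    Parameters
    ----------
    min_lux, max_lux:
        Luminance extremes in LUX. The default 0.4–32 LUX range matches a
        dim-adapted background rising to moderate photopic illumination.
    ramp_s:
        Duration of one linear leg in seconds; the full cycle is
        ``2 * ramp_s`` (20 s for a 10 s ramp, 60 s for a 30 s ramp).
    n_cycles:
        Number of consecutive cycles presented.
    t_start:
        Stimulus onset in recording time (seconds); the cycle starts at the
        luminance minimum.
    """

    min_lux: float = 0.4
    max_lux: float = 32.0
    ramp_s: float = 10.0
    n_cycles: int = 1
    t_start: float = 0.0

    def __post_init__(self) -> None:
        if not self.min_lux < self.max_lux:
            raise ValueError("min_lux must be < max_lux")
        if self.ramp_s <= 0:
            raise ValueError("ramp_s must be positive")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")

    @property
    def period(self) -> float:
        """Cycle duration in seconds (rise + fall)."""
        return 2.0 * self.ramp_s

    @property
    def t_end(self) -> float:
        return self.t_start + self.n_cycles * self.period

    def _check_window(self, t: np.ndarray) -> None:
        if np.any(t < self.t_start - 1e-9) or np.any(t > self.t_end + 1e-9):
            raise OutOfWindowError(
                f"time outside stimulus window [{self.t_start}, {self.t_end}]"
            )

    def cycle_fold(self, t, check_window: bool = True):
        """Map recording time(s) to seconds-in-cycle in ``[0, 2*ramp_s)``."""
        t = np.asarray(t, dtype=float)
        if check_window:
            self._check_window(t)
        tau = np.mod(t - self.t_start, self.period)
        return tau if tau.ndim else float(tau)

    def lux_at(self, t, check_window: bool = True):
        """Luminance and ramp phase at recording time(s) ``t``.

        Returns ``(lux, phase)``; scalars in, scalars out. ``phase`` is a
        :class:`Phase` for scalar input, else an array of :class:`Phase`.
        """
        tau = np.atleast_1d(self.cycle_fold(t, check_window=check_window))
        rising = tau < self.ramp_s
        frac = np.where(rising, tau / self.ramp_s, 2.0 - tau / self.ramp_s)
        lux = self.min_lux + frac * (self.max_lux - self.min_lux)
        phase = np.where(rising, Phase.RISING, Phase.FALLING)
        if np.isscalar(t) or np.ndim(t) == 0:
            return float(lux[0]), phase[0]
        return lux, phase

    def phase_at(self, t, check_window: bool = True):
        """Ramp phase (RISING/FALLING) at time(s) ``t``."""
        return self.lux_at(t, check_window=check_window)[1]

    def to_dict(self) -> dict:
        return {
            "type": "ramp",
            "min_lux": self.min_lux,
            "max_lux": self.max_lux,
            "ramp_s": self.ramp_s,
            "n_cycles": self.n_cycles,
            "t_start": self.t_start,
        }


@dataclass(frozen=True)
class CheckerboardStimulus:
    """Receptive-field mapping stimulus: one square at a time on a grid.

    A 6 x 4 array of 15 degree squares spanning 90 x 60 degrees of one
    visual hemifield; each square is shown for ``present_s`` seconds with a
    ``gap_s`` blank between presentations, in a seeded pseudorandom order.
    """

    n_cols: int = 6
    n_rows: int = 4
    square_deg: float = 15.0
    present_s: float = 10.0
    gap_s: float = 10.0
    side: str = "left"
    seed: int = 0
    span_deg: tuple = (90.0, 60.0)

    def __post_init__(self) -> None:
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one row and column")
        if self.present_s <= 0 or self.gap_s < 0:
            raise ValueError("present_s must be > 0 and gap_s >= 0")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")

    @property
    def n_positions(self) -> int:
        return self.n_cols * self.n_rows

    @property
    def trial_s(self) -> float:
        return self.present_s + self.gap_s

    @property
    def total_s(self) -> float:
        return self.n_positions * self.trial_s

    def order(self) -> np.ndarray:
        """Seeded pseudorandom permutation of flat position indices."""
        rng = np.random.default_rng(self.seed)
        return rng.permutation(self.n_positions)

    def trial_schedule(self) -> list:
        """Trials as ``(row, col, t_on, t_off)`` in presentation order.

        ``t_off`` is the end of the square presentation; the following
        ``gap_s`` blank belongs to the same trial slot.
        """
        trials = []
        for i, flat in enumerate(self.order()):
            row, col = divmod(int(flat), self.n_cols)
            t_on = i * self.trial_s
            trials.append((row, col, t_on, t_on + self.present_s))
        return trials

    def to_dict(self) -> dict:
        return {
            "type": "checkerboard",
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "square_deg": self.square_deg,
            "present_s": self.present_s,
            "gap_s": self.gap_s,
            "side": self.side,
            "seed": self.seed,
        }


def stimulus_from_dict(d: dict):
    """Build a stimulus from a config mapping (``type: ramp|checkerboard``)."""
    d = dict(d)
    kind = d.pop("type")
    if kind == "ramp":
        return RampStimulus(**d)
    if kind == "checkerboard":
        d.pop("span_deg", None)
        return CheckerboardStimulus(**d)
    raise ValueError(f"unknown stimulus type {kind!r}")
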