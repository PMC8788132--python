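"""Synthetic GCaMP6s data with known ground truth.

Generates the three kinds of input the pipeline consumes, each with the
statistical structure the analysis assumes and with ground-truth sidecars:

* **labeled ramp traces** — ON/OFF/DUAL/nonresponsive responses to the
  triangular luminance ramp. Firing kernels are Gaussians in
  (luminance, ramp-phase) space, so the same kernel yields the same
  LUX-at-half-max for 10 s and 30 s ramps; firing is convolved with a
  causal double-exponential indicator kernel (slow GCaMP6s kinetics) and
  corrupted with additive i.i.d. Gaussian noise.
* **calcium movies** — image stacks with known active regions whose pixels
  share a kernel-driven trace plus per-pixel noise, for segmentation.
* **receptive-field scenes** — RGC -> SMTL -> PyrN populations with
  union-convergent footprints on a two-hemifield 6 x 4 grid, and the
  checkerboard-trial traces they produce.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .preprocess import Trace
from .stimulus import CheckerboardStimulus, Phase, RampStimulus

LABELS = ("ON", "OFF", "DUAL", "NONRESPONSIVE")

#: fine simulation step (s) used before downsampling to the imaging rate;
#: resolves the indicator rise time (tau_rise default 0.2 s)
DT_FINE = 0.05


@dataclass(frozen=True)
class IndicatorSpec:
    """Calcium-indicator and acquisition model.

    ``tau_rise``/``tau_decay`` parameterize the causal double-exponential
    impulse response (0.2 s / 1.8 s defaults emulate slow GCaMP6s);
    ``rate_hz`` is the imaging frame rate (1–2 Hz regime); ``noise_sd`` is
    the additive Gaussian noise sd in the same arbitrary units as the
    signal amplitude.
    """

    tau_rise: float = 0.2
    tau_decay: float = 1.8
    noise_sd: float = 0.2
    rate_hz: float = 2.0

    def __post_init__(self) -> None:
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.rate_hz <= 0 or self.noise_sd < 0:
            raise ValueError("rate_hz must be > 0 and noise_sd >= 0")

    def kernel(self, dt: float = DT_FINE) -> np.ndarray:
        """Discrete causal impulse response, normalized to peak 1."""
        t = np.arange(0.0, self.tau_decay * 8, dt)
        h = np.exp(-t / self.tau_decay) - np.exp(-t / self.tau_rise)
        return h / h.max()


@dataclass(frozen=True)
class ResponseKernelSpec:
    """Firing-rate kernel of one response class in (luminance, phase) space.

    ON cells fire near the luminance maximum, OFF cells near the minimum
    (Gaussian in luminance, both ramp legs); DUAL cells carry two
    phase-gated Gaussians at intermediate luminance, one on the rising leg
    and one on the falling leg, the falling (OFF-phase) peak being the
    stronger of the two (``dual_ratio`` < 1 scales the rising peak).
    """

    label: str
    center_lux: float
    width_lux: float
    amplitude: float = 1.0
    dual_ratio: float = 0.6
    rise_center_lux: Optional[float] = None  # DUAL only; defaults to center_lux

    def __post_init__(self) -> None:
        if self.label not in ("ON", "OFF", "DUAL"):
            raise ValueError("label must be ON, OFF, or DUAL")
        if self.amplitude <= 0 or self.width_lux <= 0:
            raise ValueError("amplitude and width_lux must be positive")
        if self.label == "DUAL" and not (0 < self.dual_ratio < 1):
            raise ValueError("dual_ratio must lie in (0, 1)")

    def rate(self, lux: np.ndarray, phase: np.ndarray) -> np.ndarray:
        """Instantaneous firing rate along the ramp trajectory."""
        lux = np.asarray(lux, dtype=float)
        g = np.exp(-((lux - self.center_lux) ** 2) / (2 * self.width_lux**2))
        if self.label != "DUAL":
            return self.amplitude * g
        falling = np.asarray([p is Phase.FALLING for p in np.atleast_1d(phase)])
        c_rise = self.center_lux if self.rise_center_lux is None else self.rise_center_lux
        g_rise = np.exp(-((lux - c_rise) ** 2) / (2 * self.width_lux**2))
        return self.amplitude * np.where(falling, g, self.dual_ratio * g_rise)


def default_kernel(label: str, stim: RampStimulus) -> ResponseKernelSpec:
    """Class-typical kernel for a given ramp's luminance range."""
    span = stim.max_lux - stim.min_lux
    if label == "ON":
        return ResponseKernelSpec("ON", center_lux=stim.max_lux, width_lux=0.18 * span)
    if label == "OFF":
        return ResponseKernelSpec("OFF", center_lux=stim.min_lux, width_lux=0.18 * span)
    if label == "DUAL":
        mid = 0.5 * (stim.min_lux + stim.max_lux)
        return ResponseKernelSpec("DUAL", center_lux=mid, width_lux=0.15 * span)
    raise ValueError(f"no kernel for label {label!r}")


def movie_kernel(label: str, stim: RampStimulus) -> ResponseKernelSpec:
    """Brief-firing kernel for movie fixtures.

    Ramp-responsive RGC terminals fire in short bursts around their
    preferred luminance, so active pixels spend most of the recording near
    baseline; the narrow width (6% of the luminance span) keeps a pixel's
    temporal mean close to baseline, which is what makes the
    max-over-mean activity threshold informative.
    """
    k = default_kernel(label, stim)
    return replace(k, width_lux=0.06 * (stim.max_lux - stim.min_lux))


# ---------------------------------------------------------------------------
# trace generation


def _noiseless_fluorescence(
    stim: RampStimulus, kernel: Optional[ResponseKernelSpec],
    indicator: IndicatorSpec, dt: float = DT_FINE,
) -> Tuple[np.ndarray, np.ndarray]:
    """Fine-grid noiseless fluorescence over the stimulus window.

    Returns ``(t_fine, f_fine)`` with t measured from ``stim.t_start``.
    """
    t = np.arange(0.0, stim.n_cycles * stim.period, dt)
    if kernel is None:
        return t, np.zeros_like(t)
    lux, phase = stim.lux_at(stim.t_start + t)
    r = kernel.rate(lux, phase)
    f = np.convolve(r, indicator.kernel(dt))[: t.size] * dt
    # scale so the steady-state peak equals the kernel amplitude
    peak = f[t >= stim.period].max() if stim.n_cycles > 1 else f.max()
    if peak > 0:
        f *= kernel.amplitude / peak
    return t, f


def true_lux_at_half_max(
    stim: RampStimulus, kernel: ResponseKernelSpec, indicator: IndicatorSpec,
    dt: float = 0.01,
) -> float:
    """Ground-truth LUX-at-half-max of the noiseless fluorescence signal.

    Evaluated on a fine grid over one steady-state cycle, independently of
    the detection path in :mod:`ramplux.kinetics`: the selected peak is the
    cycle's global maximum (for DUAL, the falling-phase maximum), half
    height is referenced to the cycle minimum, and the luminance at the
    rising half crossing is read off the triangular trajectory.
    """
    n_settle = 3
    sim = replace(stim, n_cycles=n_settle + 1, t_start=0.0)
    t, f = _noiseless_fluorescence(sim, kernel, indicator, dt)
    cyc = f[t >= n_settle * stim.period]
    tau = np.arange(cyc.size) * dt
    if kernel.label == "DUAL":
        mask = tau >= stim.ramp_s  # falling leg
        i_pk = np.argmax(np.where(mask, cyc, -np.inf))
    else:
        i_pk = int(np.argmax(cyc))
    base = cyc.min()
    half = base + 0.5 * (cyc[i_pk] - base)
    two = np.concatenate([cyc, cyc])  # allow the crossing to wrap the seam
    j = i_pk + cyc.size
    while j > i_pk and two[j] > half:
        j -= 1
    frac = 0.0 if two[j + 1] == two[j] else (half - two[j]) / (two[j + 1] - two[j])
    tau_half = ((j + frac) * dt) % stim.period
    lux, _ = stim.lux_at(stim.t_start + tau_half)
    return float(lux)


def gen_trace(
    stim: RampStimulus,
    kernel: Optional[ResponseKernelSpec],
    indicator: IndicatorSpec = IndicatorSpec(),
    rng: Optional[np.random.Generator] = None,
    roi_id: str = "",
    baseline: float = 1.0,
) -> Trace:
    """Generate one labeled fluorescence trace.

    ``kernel=None`` produces a nonresponsive trace (baseline + noise).
    Ground truth (label, LUX-at-half-max of the noiseless signal) is
    attached as trace metadata.
    """
    rng = np.random.default_rng() if rng is None else rng
    t_fine, f_fine = _noiseless_fluorescence(stim, kernel, indicator)
    t_samp = np.arange(0.0, stim.n_cycles * stim.period - 1e-9, 1.0 / indicator.rate_hz)
    f = baseline + np.interp(t_samp, t_fine, f_fine)
    if indicator.noise_sd > 0:
        f = f + rng.normal(0.0, indicator.noise_sd, size=f.size)
    meta = {"label": "NONRESPONSIVE" if kernel is None else kernel.label}
    if kernel is not None:
        meta["true_lux_half_max"] = true_lux_at_half_max(stim, kernel, indicator)
        meta["amplitude"] = kernel.amplitude
    return Trace(values=f, rate_hz=indicator.rate_hz, roi_id=roi_id,
                 t0=stim.t_start, meta=meta)


def gen_dataset(
    n_per_class: int,
    stim: RampStimulus,
    seed: int,
    indicator: IndicatorSpec = IndicatorSpec(),
    noise_frac: float = 0.2,
    jitter: float = 0.1,
    labels: Sequence[str] = LABELS,
) -> Tuple[List[Trace], pd.DataFrame]:
    """Balanced labeled trace dataset with per-unit parameter jitter.

    Each unit draws its kernel center (+/- ``jitter`` of the luminance
    span), width and amplitude (+/- 2*``jitter`` relative) around the class
    defaults; noise sd is ``noise_frac`` of the unit's amplitude. Returns
    the traces and a ground-truth metadata table.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    span = stim.max_lux - stim.min_lux
    traces, rows = [], []
    for label in labels:
        for i in range(n_per_class):
            roi = f"{label.lower()}_{i:03d}"
            if label == "NONRESPONSIVE":
                kernel = None
                ind = replace(indicator, noise_sd=noise_frac * 1.0)
            else:
                base = default_kernel(label, stim)
                center = np.clip(
                    base.center_lux + rng.uniform(-jitter, jitter) * span,
                    stim.min_lux, stim.max_lux,
                )
                width = base.width_lux * (1 + rng.uniform(-2 * jitter, 2 * jitter))
                amp = base.amplitude * (1 + rng.uniform(-2 * jitter, 2 * jitter))
                kernel = replace(base, center_lux=float(center),
                                 width_lux=float(width), amplitude=float(amp))
                ind = replace(indicator, noise_sd=noise_frac * kernel.amplitude)
            tr = gen_trace(stim, kernel, ind, rng=rng, roi_id=roi)
            traces.append(tr)
            rows.append({"roi_id": roi, **tr.meta, "seed": seed})
    return traces, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# movie generation


def gen_movie(
    shape: Tuple[int, int, int],
    active_regions: List[Tuple[np.ndarray, ResponseKernelSpec]],
    stim: RampStimulus,
    indicator: IndicatorSpec = IndicatorSpec(),
    seed: int = 0,
    baseline: float = 50.0,
    snr: float = 5.0,
    pixel_noise_sd: float = 10.0,
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Calcium movie with known active regions.

    Every pixel of a region follows that region's noiseless kernel trace
    (amplitude ``snr * pixel_noise_sd`` over ``baseline``) plus i.i.d.
    pixel noise; background pixels are baseline + noise. Returns
    ``(movie, truth_labels, info)`` where ``truth_labels`` is an H x W
    integer mask (0 = background, 1..R = regions) and ``info`` holds the
    ground-truth active-area fraction and region traces.
    """
    T, H, W = shape
    if T / indicator.rate_hz < 2 * stim.period:
        raise ValueError("movie must span at least two stimulus cycles")
    truth = np.zeros((H, W), dtype=int)
    for k, (mask, _) in enumerate(active_regions, start=1):
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (H, W):
            raise ValueError("region mask shape must match frame shape")
        if np.any(truth[mask]):
            raise ValueError("active regions must not overlap")
        truth[mask] = k
    rng = np.random.default_rng(seed)
    sim = replace(stim, n_cycles=max(stim.n_cycles,
                                     int(np.ceil(T / indicator.rate_hz / stim.period))))
    movie = np.full((T, H, W), baseline, dtype=float)
    amp = snr * pixel_noise_sd
    region_traces = {}
    t_samp = np.arange(T) / indicator.rate_hz
    for k, (mask, kernel) in enumerate(active_regions, start=1):
        t_fine, f_fine = _noiseless_fluorescence(sim, kernel, indicator)
        tr = amp * np.interp(t_samp, t_fine, f_fine) / max(kernel.amplitude, 1e-12)
        region_traces[k] = tr
        movie[:, np.asarray(mask, dtype=bool)] += tr[:, None]
    if pixel_noise_sd > 0:
        movie += rng.normal(0.0, pixel_noise_sd, size=movie.shape)
    info = {
        "active_fraction": float((truth > 0).sum() / (H * W)),
        "region_traces": region_traces,
        "n_regions": len(active_regions),
    }
    return movie, truth, info


def random_region_masks(
    n_regions: int, frame_shape: Tuple[int, int], region_side: int,
    rng: np.random.Generator, margin: int = 1,
) -> List[np.ndarray]:
    """Non-overlapping, non-adjacent square region masks placed at random."""
    H, W = frame_shape
    occupied = np.zeros((H, W), dtype=bool)
    masks: List[np.ndarray] = []
    attempts = 0
    while len(masks) < n_regions:
        attempts += 1
        if attempts > 2000:
            raise RuntimeError("could not place non-overlapping regions")
        r = int(rng.integers(margin, H - region_side - margin))
        c = int(rng.integers(margin, W - region_side - margin))
        lo_r, hi_r = max(r - 1, 0), min(r + region_side + 1, H)
        lo_c, hi_c = max(c - 1, 0), min(c + region_side + 1, W)
        if occupied[lo_r:hi_r, lo_c:hi_c].any():
            continue
        m = np.zeros((H, W), dtype=bool)
        m[r : r + region_side, c : c + region_side] = True
        occupied[lo_r:hi_r, lo_c:hi_c] = True
        masks.append(m)
    return masks


# ---------------------------------------------------------------------------
# receptive-field scenes


@dataclass
class RFUnit:
    """One unit's receptive-field footprint per hemifield grid."""

    unit_id: str
    tier: str  # RGC | SMTL | PyrN
    footprints: Dict[str, np.ndarray]  # side -> bool (n_rows, n_cols)
    sources: List[str] = field(default_factory=list)

    def footprint_size(self) -> int:
        return int(sum(fp.sum() for fp in self.footprints.values()))


@dataclass
class RFScene:
    """RGC -> SMTL -> PyrN convergence scene over two hemifield grids.

    Invariant: every SMTL footprint is the union of its source RGC
    footprints; every PyrN footprint is the union of its source SMTL
    footprints plus its direct RGC footprint.
    """

    rgcs: List[RFUnit]
    smtls: List[RFUnit]
    pyrns: List[RFUnit]
    n_rows: int = 4
    n_cols: int = 6

    @property
    def units(self) -> List[RFUnit]:
        return self.rgcs + self.smtls + self.pyrns


def random_scene(
    seed: int,
    n_rgc: int = 12,
    n_smtl: int = 6,
    n_pyrn: int = 4,
    rgc_per_smtl: int = 3,
    smtl_per_pyrn: int = 3,
    n_rows: int = 4,
    n_cols: int = 6,
) -> RFScene:
    """Random convergence scene with retinotopic single/double-cell RGC RFs.

    RGCs are split between hemifields with compact 1–2 position footprints
    placed retinotopically (unit index maps to grid column); SMTLs pool
    ``rgc_per_smtl`` RGCs drawn from both hemifields; PyrNs pool
    ``smtl_per_pyrn`` SMTLs plus one direct RGC.
    """
    rng = np.random.default_rng(seed)
    sides = ("left", "right")

    def empty():
        return {s: np.zeros((n_rows, n_cols), dtype=bool) for s in sides}

    rgcs = []
    for i in range(n_rgc):
        side = sides[i % 2]
        fp = empty()
        # retinotopy: unit order within a hemifield sweeps the columns
        col = int((i // 2) * n_cols / max(1, (n_rgc + 1) // 2)) % n_cols
        row = int(rng.integers(n_rows))
        fp[side][row, col] = True
        if rng.random() < 0.5:  # occasional 2-cell footprint
            r2 = min(row + 1, n_rows - 1)
            fp[side][r2, col] = True
        rgcs.append(RFUnit(f"rgc_{i:02d}", "RGC", fp))

    smtls = []
    for i in range(n_smtl):
        src = rng.choice(n_rgc, size=min(rgc_per_smtl, n_rgc), replace=False)
        fp = empty()
        for j in src:
            for s in sides:
                fp[s] |= rgcs[j].footprints[s]
        smtls.append(RFUnit(f"smtl_{i:02d}", "SMTL", fp,
                            sources=[rgcs[j].unit_id for j in src]))

    pyrns = []
    for i in range(n_pyrn):
        src = rng.choice(n_smtl, size=min(smtl_per_pyrn, n_smtl), replace=False)
        direct = int(rng.integers(n_rgc))
        fp = empty()
        for j in src:
            for s in sides:
                fp[s] |= smtls[j].footprints[s]
        for s in sides:
            fp[s] |= rgcs[direct].footprints[s]
        pyrns.append(RFUnit(f"pyrn_{i:02d}", "PyrN", fp,
                            sources=[smtls[j].unit_id for j in src]
                            + [rgcs[direct].unit_id]))
    return RFScene(rgcs, smtls, pyrns, n_rows=n_rows, n_cols=n_cols)


def gen_rf_responses(
    scene: RFScene,
    stims: Dict[str, CheckerboardStimulus],
    indicator: IndicatorSpec = IndicatorSpec(noise_sd=0.05),
    seed: int = 0,
    amplitude: float = 1.0,
    baseline: float = 1.0,
) -> Dict[str, Dict[str, Trace]]:
    """Checkerboard-trial traces for every unit and hemifield.

    A unit fires at ``amplitude`` for the duration of any presentation
    whose square falls inside its footprint on that side; firing is
    convolved with the indicator kernel and sampled at the imaging rate
    with additive noise. Returns ``responses[unit_id][side]``.

    The default noise floor is 5% of the response amplitude — the regime
    of ROI-averaged traces from strong responders, whose transients stand
    many fold above the noise. A much noisier trace would make the
    max-over-trial statistic cross the Z >= 1.5 size rule spuriously in
    silent hemifields, which is a property of the rule, not of the
    generator.
    """
    rng = np.random.default_rng(seed)
    out: Dict[str, Dict[str, Trace]] = {}
    kern = indicator.kernel(DT_FINE)
    for unit in scene.units:
        out[unit.unit_id] = {}
        for side, stim in stims.items():
            sched = stim.trial_schedule()
            n_fine = int(round(stim.total_s / DT_FINE))
            r = np.zeros(n_fine)
            fp = unit.footprints[side]
            for row, col, t_on, t_off in sched:
                if fp[row, col]:
                    i0 = int(round(t_on / DT_FINE))
                    i1 = int(round(t_off / DT_FINE))
                    r[i0:i1] = amplitude
            f_fine = np.convolve(r, kern)[:n_fine] * DT_FINE
            if f_fine.max() > 0:
                f_fine *= amplitude / f_fine.max()
            t_fine = np.arange(n_fine) * DT_FINE
            t_samp = np.arange(0.0, stim.total_s - 1e-9, 1.0 / indicator.rate_hz)
            f = baseline + np.interp(t_samp, t_fine, f_fine)
            if indicator.noise_sd > 0:
                f = f + rng.normal(0.0, indicator.noise_sd, size=f.size)
            out[unit.unit_id][side] = Trace(
                values=f, rate_hz=indicator.rate_hz,
                roi_id=f"{unit.unit_id}:{side}",
                meta={"tier": unit.tier, "side": side,
                      "true_size": int(fp.sum())},
            )
    return out
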