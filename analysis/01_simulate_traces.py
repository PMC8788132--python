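#!/usr/bin/env python
"""Simulate a labeled cohort of luminance-ramp responses.

Generates 50 units per class (ON / OFF / DUAL / nonresponsive) responding
to the 0.4–32 LUX, 10 s-ramp stimulus with GCaMP6s-like kinetics and a
noise floor of 20% of response amplitude, and writes the trace table plus
its ground-truth sidecar under results/. Downstream scripts consume these
files.
"""

from pathlib import Path

from ramplux import preprocess, synth
from ramplux.stimulus import RampStimulus

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    stim = RampStimulus(min_lux=0.4, max_lux=32.0, ramp_s=10.0, n_cycles=6)
    traces, meta = synth.gen_dataset(50, stim, seed=SEED, noise_frac=0.2)
    preprocess.write_traces(OUT / "synthetic_traces_10s.csv", traces)
    meta.to_csv(OUT / "synthetic_ground_truth.csv", index=False)
    n_resp = (meta.label != "NONRESPONSIVE").sum()
    print(f"wrote {len(traces)} traces ({n_resp} responsive) "
          f"to {OUT / 'synthetic_traces_10s.csv'}")
    print(f"ground truth (labels, half-max LUX) in "
          f"{OUT / 'synthetic_ground_truth.csv'}")


if __name__ == "__main__":
    main()
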