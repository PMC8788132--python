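# ramplux

Analysis pipeline for calcium-imaging experiments that probe how visual
neurons encode slow, whole-field luminance changes — written for the
zebrafish tectum / torus longitudinalis (TL) circuit, where tectal
pyramidal neurons (PyrNs), their retinal ganglion cell (RGC) inputs, and
TL feedback neurons (SMTLs) respond to triangular luminance ramps with
distinct ON, OFF, and DUAL response classes and build large binocular
receptive fields by convergence.

The package is aimed at imaging labs running GCaMP recordings against
ramp or sparse-noise stimuli: it takes fluorescence trace tables, calcium
movies (TIFF), and receptive-field trial recordings, and returns response
classes, peak kinetics, active-ROI segmentations, and receptive-field
summaries. A synthetic-data module generates all three input modalities
with ground truth, so every stage is testable without microscopy data.

## What it computes

**Normalization and gating.** Each trace is z-scored, z = (x − μ)/σ,
with μ, σ taken from stimulus onset to end; traces whose z never leaves
±0.5 are flagged unresponsive. Responses to repeated ramps are folded
over the cycle and averaged.

**Peak kinetics.** Significant peaks are local maxima of the
cycle-averaged z-trace with topographic prominence > 0.75. Two
statistics summarize each response:

* *LUX-at-half-max* — the stimulus luminance when the signal first
  reaches 50% of its peak (for DUAL responses, the more prominent
  OFF-phase peak is used);
* *width-at-half-max* — the duration between the half-height crossings
  (averaged over peaks for multi-peak responses).

**Classification.** A linear SVM with stratified 5-fold
cross-validation assigns ON / OFF / DUAL / nonresponsive labels;
K-means with Calinski–Harabasz elbow selection (k ≤ 8, best of 1000
replicates) provides the unsupervised route, with clusters binned to
classes via the peak phase of their centroids.

**Movie segmentation.** Pixels whose temporal maximum reaches 175% of
their temporal mean are grouped into 8-connected,
correlation-coherent ROIs; outputs include the active-area fraction
relative to a total-label mask and ROI tallies per anatomical layer.

**Receptive fields.** Peak z per checkerboard trial (z over the entire
recording, pooled across both hemifield presentations) fills a 6 × 4
grid per hemifield; RF size counts positions with z ≥ 1.5, and
summaries report binocularity, contra/ipsi size ratios, compound-RF
component counts, and the RGC → SMTL → PyrN spatial-summation ordering.

See `docs/methods.md` for models, defaults, and numerical conventions.

## Worked example

Simulate a labeled cohort and run the full classification path:

```sh
python analysis/01_simulate_traces.py
python analysis/02_classify_responses.py
```

which prints (seed 1):

```
SVM 5-fold mean accuracy: 100.0%
confusion matrix (true x predicted):
               ON  OFF  DUAL  NONRESPONSIVE
ON             50    0     0              0
OFF             0   50     0              0
DUAL            0    0    50              0
NONRESPONSIVE   0    0     0             50

per-class kinetics (mean +/- SEM):
class           measure      mean      sem  n
   ON   lux_at_half_max 27.987014 0.196511 50
  OFF   lux_at_half_max  5.803604 0.709035 50
 DUAL   lux_at_half_max 19.005858 0.267387 50
...
K-means: optimal k = 4, agreement with ground truth 100.0%
```

The kinetics means say that synthetic ON units reach half their response
near 28 LUX (close to the 32 LUX apex), OFF units near 6 LUX (close to
the 0.4 LUX trough), and DUAL units in between — the class ordering the
method is designed to resolve. `analysis/03_segment_movie.py` and
`analysis/04_map_receptive_fields.py` continue with segmentation
(3 ROIs recovered from 3 seeded regions; active-area fraction 7.30% vs
7.32% truth) and receptive-field mapping (mean RF size
RGC 1.6 < SMTL 4.1 < PyrN 10.1 positions; spatial-summation ordering in
50/50 scenes).

The same stages are available as a CLI for external data:

```sh
ramplux simulate --config run.yaml --out sim/
ramplux classify --config run.yaml --traces traces.csv --labels labels.csv --out out/
ramplux segment  --config run.yaml --movie movie.tif --out out/
ramplux rf       --config run.yaml --out out/
```

Trace tables are delimited text (rows = ROIs, header row of sample
times); movies and masks are TIFF; every run writes its resolved config
next to its outputs.

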