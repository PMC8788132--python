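"""End-to-end compositions of the analysis stages.

These are the functions the command-line interface, the analysis drivers,
and the acceptance checks all call, so every route through the package
exercises the same code.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import classify, kinetics, preprocess, rf
from .preprocess import NONRESPONSIVE, Trace
from .stimulus import CheckerboardStimulus, RampStimulus


def classify_traces(
    traces: Sequence[Trace],
    stim: RampStimulus,
    seed: int = 0,
    L: int = classify.FEATURE_LEN,
    train_labels: Optional[Sequence[str]] = None,
    min_prominence: float = kinetics.MIN_PROMINENCE,
):
    """preprocess -> kinetics -> classify for a trace table.

    When ``train_labels`` is given (ground truth or manual labels), a
    linear SVM is trained with stratified 5-fold cross-validation and its
    predictions (gate-forced to NONRESPONSIVE where applicable) are
    reported alongside the CV result; otherwise only gate + kinetics run.

    Returns ``(table, cv_result)``; ``cv_result`` is None without labels.
    """
    gates, crs = [], []
    for tr in traces:
        _, gate, cr = preprocess.preprocess_trace(tr, stim)
        gates.append(gate)
        crs.append(cr)
    summaries = [
        kinetics.analyze(cr, stim, min_prominence=min_prominence) for cr in crs
    ]
    table = kinetics.kinetics_table(summaries)
    table.insert(0, "roi_id", [tr.roi_id for tr in traces], allow_duplicates=True)
    table = table.loc[:, ~table.columns.duplicated()]
    table["gate"] = gates

    cv = None
    if train_labels is not None:
        X = classify.featurize_all(crs, L)
        model, cv = classify.train_svm(X, list(train_labels), seed=seed)
        table["label"] = classify.predict(model, X, gates=gates)
    return table, cv


def class_kinetics_means(table: pd.DataFrame, label_col: str = "label") -> pd.DataFrame:
    """Per-class mean +/- SEM of LUX- and width-at-half-max."""
    rows = []
    for c in ("ON", "OFF", "DUAL"):
        sub = table[(table[label_col] == c)]
        for col, name in (
            ("lux_at_half_max_lux", "lux_at_half_max"),
            ("width_at_half_max_s", "width_at_half_max"),
        ):
            v = sub[col].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "class": c,
                    "measure": name,
                    "mean": v.mean() if v.size else np.nan,
                    "sem": v.std(ddof=1) / np.sqrt(v.size) if v.size > 1 else np.nan,
                    "n": v.size,
                }
            )
    return pd.DataFrame(rows)


def summarize_rf_scene(
    responses: Dict[str, Dict[str, Trace]],
    stims: Dict[str, CheckerboardStimulus],
    contra_side: str = "left",
    z_min: float = rf.RF_Z_MIN,
    lag_s: float = rf.DEFAULT_LAG_S,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """RF maps and binocular summaries for every unit of a scene.

    Returns ``(summary_table, tier_table)``; the tier table carries the
    PyrN > SMTL >= RGC ordering flag in ``attrs``.
    """
    ipsi_side = [s for s in stims if s != contra_side][0]
    summaries = []
    for unit_id, per_side in responses.items():
        tier = per_side[contra_side].meta.get("tier", "")
        maps = rf.binocular_maps(per_side, stims, lag_s=lag_s)
        summaries.append(
            rf.binocular_summary(maps[contra_side], maps[ipsi_side],
                                 z_min=z_min, tier=tier)
        )
    table = rf.summary_table(summaries)
    sizes_by_tier = {
        t: (table.loc[table.tier == t, "size_contra"]
            + table.loc[table.tier == t, "size_ipsi"]).tolist()
        for t in table.tier.unique()
    }
    tiers = rf.tier_comparison(sizes_by_tier)
    return table, tiers
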