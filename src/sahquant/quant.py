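"""Molecular quantification: qPCR ΔΔCT, blot densitometry, zymogram activity.

qPCR follows the comparative-CT (Livak) method with amplification efficiency
fixed at 2: ΔCT = CT_gene − CT_reference per sample, ΔΔCT subtracts the
control group's mean ΔCT for the same gene, and expression is 2^−ΔΔCT as a
fold change relative to controls (the geometric mean of control folds is 1
by construction).

Densitometry subtracts the mean of the membrane background measured above
and beneath each band, normalizes against the loading control, and expresses
fold changes against the mean of control samples *on the same membrane*, so
per-membrane gain cancels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


class QuantError(ValueError):
    pass


def ddct_fold_changes(
    ct: pd.DataFrame,
    reference_gene: str = "GAPDH",
    control_group: str = "SHAM",
) -> pd.DataFrame:
    """2^−ΔΔCT fold change per sample and gene.

    Expects columns sample, group, gene, ct. Every sample must carry a
    reference-gene row and the control group must be present. Returns one row
    per (sample, gene != reference) with delta_ct, delta_delta_ct and fold.
    """
    required = {"sample", "group", "gene", "ct"}
    if missing := required - set(ct.columns):
        raise QuantError(f"CT table missing columns: {sorted(missing)}")
    if not np.all(np.isfinite(ct["ct"])):
        raise QuantError("CT values must be finite")
    if control_group not in set(ct["group"]):
        raise QuantError(f"control group {control_group!r} absent from CT table")

    ref = ct[ct["gene"] == reference_gene].set_index("sample")["ct"]
    targets = ct[ct["gene"] != reference_gene].copy()
    missing_ref = sorted(set(targets["sample"]) - set(ref.index))
    if missing_ref:
        raise QuantError(f"samples lacking a {reference_gene} row: {missing_ref}")

    targets["delta_ct"] = targets["ct"] - targets["sample"].map(ref).to_numpy()
    control_mean = (
        targets[targets["group"] == control_group].groupby("gene")["delta_ct"].mean()
    )
    unseen = sorted(set(targets["gene"]) - set(control_mean.index))
    if unseen:
        raise QuantError(f"genes without control-group samples: {unseen}")
    targets["delta_delta_ct"] = targets["delta_ct"] - targets["gene"].map(control_mean).to_numpy()
    targets["fold"] = 2.0 ** (-targets["delta_delta_ct"])
    return targets[["sample", "group", "gene", "delta_ct", "delta_delta_ct", "fold"]].reset_index(drop=True)


def blot_fold_changes(lanes: pd.DataFrame, control_group: str = "SHAM") -> pd.DataFrame:
    """Background-adjusted, loading-normalized band intensity fold changes.

    Expects columns membrane, sample, group, band, background_above,
    background_below, loading. adjusted = band − mean(backgrounds), floored
    at 0; normalized = adjusted / loading-control intensity; fold divides by
    the mean normalized value of control samples on the same membrane.
    """
    required = {
        "membrane", "sample", "group", "band",
        "background_above", "background_below", "loading",
    }
    if missing := required - set(lanes.columns):
        raise QuantError(f"densitometry table missing columns: {sorted(missing)}")

    out = lanes.copy()
    bg = (out["background_above"] + out["background_below"]) / 2.0
    out["adjusted"] = np.maximum(out["band"] - bg, 0.0)
    if np.any(out["loading"] <= 0):
        bad = out.loc[out["loading"] <= 0, "sample"].tolist()
        raise QuantError(f"non-positive loading-control intensity for: {bad}")
    out["normalized"] = out["adjusted"] / out["loading"]

    folds = np.empty(len(out))
    for membrane, idx in out.groupby("membrane").groups.items():
        sub = out.loc[idx]
        ctrl = sub.loc[sub["group"] == control_group, "normalized"]
        if ctrl.empty:
            raise QuantError(f"membrane {membrane!r} has no {control_group} sample")
        folds[out.index.get_indexer(idx)] = sub["normalized"] / ctrl.mean()
    out["fold"] = folds
    return out[["membrane", "sample", "group", "adjusted", "normalized", "fold"]]


def zymogram_activity(
    trace: np.ndarray,
    band_window: tuple[int, int],
    background_window: tuple[int, int],
    loading_value: float | None = None,
) -> float:
    """Gelatinolytic activity from a 1-D lane intensity trace.

    Clear (digested) bands are intensity minima on the stained background, so
    activity is Σ max(background level − intensity, 0) over the band window;
    the background level is the mean over the background window. Dividing by
    a parallel-gel loading value is optional.
    """
    trace = np.asarray(trace, dtype=float)
    b0, b1 = band_window
    g0, g1 = background_window
    if not (0 <= b0 < b1 <= trace.size) or not (0 <= g0 < g1 <= trace.size):
        raise QuantError("windows must be non-empty and inside the trace")
    background = trace[g0:g1].mean()
    activity = float(np.maximum(background - trace[b0:b1], 0.0).sum())
    if loading_value is not None:
        if loading_value <= 0:
            raise QuantError("loading value must be positive")
        activity /= loading_value
    return activity
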