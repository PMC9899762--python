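"""Threshold-based 3-D colocalization of two-channel confocal stacks.

Channel thresholds follow the automatic scheme of Costes: an orthogonal
(total least squares) regression of channel b on channel a fixes the line
T_b = slope·T_a + intercept, and T_a is lowered from the maximum intensity
until the Pearson correlation of the voxels *below* both thresholds first
drops to zero or below — those voxels are then "background", everything above
both thresholds is colocalized signal. Reported statistics:

- percent of material colocalized (%MC) per channel: the share of a
  channel's total intensity residing in colocalized voxels;
- Pearson's r over the colocalized voxels (and over the whole stack, for
  transparency);
- the study's classification rule: two signals correlate when r >= 0.5.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np


class ColocError(ValueError):
    pass


@dataclass
class VolumePair:
    """Two aligned non-negative intensity volumes with voxel size in µm."""

    channel_a: np.ndarray
    channel_b: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        a, b = np.asarray(self.channel_a, float), np.asarray(self.channel_b, float)
        if a.shape != b.shape:
            raise ColocError(f"channel shapes differ: {a.shape} vs {b.shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise ColocError("voxel sizes must be positive")
        if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
            raise ColocError("intensities must be finite")
        if a.min() < 0 or b.min() < 0:
            raise ColocError("intensities must be non-negative")
        if self.mask is not None and self.mask.shape != a.shape:
            raise ColocError("mask shape must match the channels")
        self.channel_a, self.channel_b = a, b

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        if self.mask is not None:
            return self.channel_a[self.mask], self.channel_b[self.mask]
        return self.channel_a.ravel(), self.channel_b.ravel()


@dataclass
class ColocResult:
    slope: float
    intercept: float
    threshold_a: float
    threshold_b: float
    pcc: float  # over colocalized voxels; NaN when that set is empty/degenerate
    pcc_whole_stack: float
    percent_material_a: float
    percent_material_b: float
    correlated: bool
    n_colocalized: int
    threshold_warning: bool = False  # scan never reached r <= 0


def classify_correlated(pcc: float, cutoff: float = 0.5) -> bool:
    """The study's rule: signals correlate when r is equal to or above the cutoff."""
    return (not math.isnan(pcc)) and pcc >= cutoff


def pearson(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    """Product-moment correlation over the (optionally masked) voxels."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if mask is not None:
        a, b = a[mask], b[mask]
    a, b = a.ravel(), b.ravel()
    if a.size < 2:
        raise ColocError("need at least two voxels")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ColocError("zero variance in a channel")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def orthogonal_regression(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Orthogonal line b = slope·a + intercept fitted on standardized channels.

    Both channels carry noise, so an ordinary least-squares fit of b on a is
    biased; the orthogonal fit is computed on standardized intensities
    (making it equivariant under per-channel gain, which raw total least
    squares is not) and back-transformed — equivalently the geometric-mean
    slope sign(r)·sd_b/sd_a.
    """
    a, b = a.ravel(), b.ravel()
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ColocError("regression undefined: a channel has no spread")
    r = np.corrcoef(a, b)[0, 1]
    slope = float(np.sign(r) if r != 0 else 1.0) * float(sb / sa)
    intercept = float(b.mean() - slope * a.mean())
    return slope, intercept


def costes_thresholds(
    v: VolumePair,
    n_steps: int = 256,
    min_below_voxels: int = 20,
) -> tuple[float, float, float, float, bool]:
    """(T_a, T_b, slope, intercept, warned) by the descending threshold scan.

    T_a walks down a grid of candidate intensities (integer grey levels for
    integer data, `n_steps` quantiles otherwise) with T_b tied to it through
    the orthogonal regression; the first candidate for which the correlation
    of voxels below both thresholds is <= 0 wins. If the scan exhausts the
    grid the minimum intensity is returned with a warning flag.
    """
    a, b = v.flat()
    nonzero = (a > 0) | (b > 0)  # empty space inflates correlation
    if nonzero.sum() < 2:
        raise ColocError("volume contains no signal")
    slope, intercept = orthogonal_regression(a[nonzero], b[nonzero])

    integer_data = np.allclose(a, np.round(a)) and np.allclose(b, np.round(b))
    if integer_data and (a.max() - a.min()) <= 4096:
        candidates = np.arange(a.max(), a.min() - 1, -1.0)
    else:
        qs = np.linspace(1.0, 0.0, n_steps)
        candidates = np.unique(np.quantile(a, qs))[::-1]

    # fallback: just below the minimum, so everything counts as colocalized
    warned = True
    t_a = float(a.min()) - (1.0 if integer_data else 1e-6 * max(1.0, float(a.max() - a.min())))
    for cand in candidates:
        t_b = slope * cand + intercept
        below = (a < cand) & (b < t_b)
        if below.sum() < min_below_voxels:
            continue
        av, bv = a[below], b[below]
        if av.std() == 0 or bv.std() == 0:
            continue
        r = pearson(av, bv)
        if r <= 0:
            t_a, warned = float(cand), False
            break
    if warned:
        warnings.warn(
            "Costes scan never reached non-positive below-threshold correlation; "
            "using the minimum intensity",
            stacklevel=2,
        )
    return t_a, float(slope * t_a + intercept), slope, intercept, warned


def coloc_stats(v: VolumePair, cutoff: float = 0.5, n_steps: int = 256) -> ColocResult:
    """Full colocalization readout of a two-channel stack.

    Colocalized voxels are those above both Costes thresholds; percent of
    material is each channel's intensity share in that set; `correlated`
    applies the r >= cutoff classification to the colocalized-voxel PCC.
    """
    a, b = v.flat()
    t_a, t_b, slope, intercept, warned = costes_thresholds(v, n_steps=n_steps)
    coloc = (a > t_a) & (b > t_b)
    n = int(coloc.sum())

    total_a, total_b = a.sum(), b.sum()
    pm_a = 100.0 * a[coloc].sum() / total_a if total_a > 0 else 0.0
    pm_b = 100.0 * b[coloc].sum() / total_b if total_b > 0 else 0.0

    if n >= 2 and a[coloc].std() > 0 and b[coloc].std() > 0:
        pcc = pearson(a[coloc], b[coloc])
    else:
        pcc = math.nan
    whole = pearson(a, b)
    correlated = classify_correlated(pcc, cutoff)

    return ColocResult(
        slope=slope,
        intercept=intercept,
        threshold_a=t_a,
        threshold_b=t_b,
        pcc=pcc,
        pcc_whole_stack=whole,
        percent_material_a=pm_a,
        percent_material_b=pm_b,
        correlated=correlated,
        n_colocalized=n,
        threshold_warning=warned,
    )


def percent_material(v: VolumePair, t_a: float, t_b: float) -> tuple[float, float]:
    """%MC of each channel at explicit thresholds (monotone in T_a and T_b)."""
    a, b = v.flat()
    coloc = (a > t_a) & (b > t_b)
    pa = 100.0 * a[coloc].sum() / a.sum() if a.sum() > 0 else 0.0
    pb = 100.0 * b[coloc].sum() / b.sum() if b.sum() > 0 else 0.0
    return pa, pb
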