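"""Hemorrhage grading, animal-level aggregation, and group comparison.

The severity of a hemorrhage is graded on the basal brain divided into six
segments, each scored 0–3 by the amount of blood, summed to a total grade of
0–18; animals graded below 8 are excluded from analysis. Morphometric
parameters are averaged over each animal's included capillary profiles (the
animal is the statistical unit), compared across the three groups by one-way
ANOVA per parameter, and followed by pairwise Welch t-tests with a
Benjamini–Hochberg false-discovery-rate correction across the comparison
family. Star flags encode comparison identity, not significance tiers:
* SAH vs SHAM, ** SAH+Mino vs SHAM, *** SAH+Mino vs SAH — a star is set when
that comparison's FDR-adjusted q is below alpha.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

N_SEGMENTS = 6
MAX_SEGMENT_GRADE = 3

#: Table-legend star codes for the three pairwise comparisons
STAR_CODES = {
    ("SAH", "SHAM"): "*",
    ("SAH+Mino", "SHAM"): "**",
    ("SAH+Mino", "SAH"): "***",
}


class StatsError(ValueError):
    pass


def sah_grade(segments) -> int:
    """Total hemorrhage grade: sum of six segment scores, each in 0–3."""
    seg = list(segments)
    if len(seg) != N_SEGMENTS:
        raise StatsError(f"grade sheet needs {N_SEGMENTS} segments, got {len(seg)}")
    for g in seg:
        if int(g) != g or not (0 <= g <= MAX_SEGMENT_GRADE):
            raise StatsError(f"segment grade {g!r} outside 0–{MAX_SEGMENT_GRADE}")
    return int(sum(seg))


def grade_sheet_totals(sheets: pd.DataFrame) -> pd.Series:
    """Per-animal total grades from a sheet with columns animal, seg1..seg6."""
    seg_cols = [f"seg{i + 1}" for i in range(N_SEGMENTS)]
    if missing := set(seg_cols) - set(sheets.columns):
        raise StatsError(f"grade sheet missing columns: {sorted(missing)}")
    totals = sheets.apply(lambda row: sah_grade([row[c] for c in seg_cols]), axis=1)
    return pd.Series(totals.values, index=sheets["animal"].values, name="grade")


def inclusion_filter(sheets: pd.DataFrame, min_grade: int = 8) -> list[str]:
    """Animal ids whose total grade reaches the inclusion cut (>= 8)."""
    if sheets.empty:
        return []
    totals = grade_sheet_totals(sheets)
    return [animal for animal, g in totals.items() if g >= min_grade]


def per_animal_means(records: pd.DataFrame, parameters: list[str] | None = None) -> pd.DataFrame:
    """Animal-level means of per-profile records (the unit of analysis).

    Missing values are excluded pairwise, so a parameter absent from some
    profiles is averaged over the profiles that carry it. Returns one row per
    (group, animal) plus a profile count.
    """
    if records.empty:
        raise StatsError("no records to aggregate")
    for col in ("group", "animal"):
        if col not in records.columns:
            raise StatsError(f"records lack a {col!r} column")
    params = parameters or [
        c for c in records.columns
        if c not in ("group", "animal", "profile") and pd.api.types.is_numeric_dtype(records[c])
    ]
    grouped = records.groupby(["group", "animal"], sort=False)
    out = grouped[params].mean().reset_index()
    out["n_profiles"] = grouped.size().values
    return out


@dataclass
class ParameterComparison:
    parameter: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    group_ns: dict[str, int]
    f_statistic: float
    p_anova: float
    pairwise_p: dict[tuple[str, str], float]
    pairwise_q: dict[tuple[str, str], float]
    stars: str


def anova_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way fixed-effects ANOVA F and p."""
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def _welch_p(x: np.ndarray, y: np.ndarray) -> float:
    """Welch t-test p, with degenerate zero-variance groups handled.

    Two constant groups give an undefined t statistic; equal constants carry
    no evidence of a difference (p = 1), unequal constants are certainly
    different (p = 0).
    """
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if np.mean(x) == np.mean(y) else 0.0
    _, tp = stats.ttest_ind(x, y, equal_var=False)
    return float(tp) if np.isfinite(tp) else 1.0


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values (monotone, >= p, <= 1)."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return p_values
    return multipletests(p_values, method="fdr_bh")[1]


def compare_groups(
    summaries: pd.DataFrame,
    parameters: list[str],
    alpha: float = 0.05,
    fdr_method: str = "fdr_bh",
    fdr_family: str = "per_parameter",
) -> list[ParameterComparison]:
    """Three-group comparison on animal-level means, one result per parameter.

    One-way ANOVA per parameter, then pairwise Welch t-tests adjusted by FDR
    (`fdr_bh` by default; `fdr_tsbky` selects the two-stage variant). The
    adjustment family is the three pairwise comparisons of one parameter
    (`per_parameter`) or all comparisons pooled across parameters (`pooled`).
    """
    if fdr_family not in ("per_parameter", "pooled"):
        raise StatsError(f"unknown fdr_family {fdr_family!r}")
    groups = list(dict.fromkeys(summaries["group"]))
    if len(groups) < 2:
        raise StatsError("need at least two groups")
    counts = summaries.groupby("group").size()
    if (counts < 2).any():
        raise StatsError("every group needs at least two animals")

    pairs = [
        (g2, g1) for g1, g2 in itertools.combinations(groups, 2)
    ]  # later-vs-earlier ordering (treatment vs control)

    results, all_p, index = [], [], []
    for param in parameters:
        samples = {
            g: summaries.loc[summaries["group"] == g, param].dropna().to_numpy()
            for g in groups
        }
        if any(len(v) < 2 for v in samples.values()):
            raise StatsError(f"{param}: fewer than two animal means in a group")
        f, p = anova_oneway(list(samples.values()))
        pairwise_p = {}
        for g2, g1 in pairs:
            pairwise_p[(g2, g1)] = _welch_p(samples[g2], samples[g1])
        results.append(
            ParameterComparison(
                parameter=param,
                group_means={g: float(np.mean(v)) for g, v in samples.items()},
                group_sds={g: float(np.std(v, ddof=1)) for g, v in samples.items()},
                group_ns={g: int(len(v)) for g, v in samples.items()},
                f_statistic=f,
                p_anova=p,
                pairwise_p=pairwise_p,
                pairwise_q={},
                stars="",
            )
        )
        for pair, tp in pairwise_p.items():
            all_p.append(tp)
            index.append((param, pair))

    if fdr_family == "per_parameter":
        for res in results:
            pairs_here = list(res.pairwise_p)
            q = multipletests(
                np.array([res.pairwise_p[k] for k in pairs_here]), method=fdr_method
            )[1]
            res.pairwise_q = dict(zip(pairs_here, map(float, q)))
    else:
        q = multipletests(np.array(all_p), method=fdr_method)[1]
        by_param: dict[str, dict] = {}
        for (param, pair), qi in zip(index, q):
            by_param.setdefault(param, {})[pair] = float(qi)
        for res in results:
            res.pairwise_q = by_param[res.parameter]

    for res in results:
        stars = "".join(
            code
            for pair, code in STAR_CODES.items()
            if pair in res.pairwise_q and res.pairwise_q[pair] < alpha
        )
        res.stars = stars
    return results


def report_table(results: list[ParameterComparison]) -> pd.DataFrame:
    """Reference-table-shaped report: parameter × group mean/SD with stars."""
    rows = []
    for res in results:
        row: dict = {"parameter": res.parameter}
        for g in res.group_means:
            row[f"{g}_mean"] = res.group_means[g]
            row[f"{g}_sd"] = res.group_sds[g]
            row[f"{g}_n"] = res.group_ns[g]
        row["F"] = res.f_statistic
        row["p_anova"] = res.p_anova
        for pair, q in res.pairwise_q.items():
            row[f"q[{pair[0]} vs {pair[1]}]"] = q
        row["stars"] = res.stars
        rows.append(row)
    return pd.DataFrame(rows)
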