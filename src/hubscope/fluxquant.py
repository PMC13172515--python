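"""Normalized high-content flux readouts and their group statistics.

High-content autophagy experiments produce per-cell feature tables
(intensities, puncta counts, per-cell correlations) annotated with well,
replicate, condition and genotype.  The quantities analysed here are
ratios — marker-in-lysosome over marker-total intensity as a flux proxy,
surface over total intensity for receptor routing, the mCherry/GFP MFI
ratio of a tandem reporter — normalized to an untreated reference group
within an experiment or replicate stratum, so the reference mean is 1 by
construction.

Group statistics follow common high-content practice: two-sided one-sample
t-tests of normalized per-well means against the reference value 1;
two-sided Wilcoxon rank-sum (Mann–Whitney) tests between groups, exact for
small tie-free samples (combined n <= 25) and normal-approximated with tie
correction otherwise; Benjamini–Hochberg correction across each comparison
family; Tukey box summaries (whiskers at the most extreme points within
1.5x IQR of the box).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ratio_metric",
    "normalize_to_reference",
    "well_aggregate",
    "one_sample_test",
    "group_compare",
    "box_summary",
    "mfi_fold_change",
    "log2_intensity_scatter",
    "p_to_stars",
]

#: combined sample size at or below which tie-free rank-sum tests are exact
EXACT_RANKSUM_MAX_N = 25


def ratio_metric(table: pd.DataFrame, numerator_feature: str,
                 denominator_feature: str, name: str | None = None,
                 ) -> tuple[pd.DataFrame, int]:
    """Per-cell ratio metric numerator/denominator.

    Cells with missing or non-positive denominator are excluded; the
    exclusion count is returned alongside the filtered table (which gains
    the metric column).
    """
    for col in (numerator_feature, denominator_feature):
        if col not in table.columns:
            raise KeyError(f"feature column {col!r} absent from table")
    name = name or f"{numerator_feature}_over_{denominator_feature}"
    denom = table[denominator_feature]
    bad = denom.isna() | (denom <= 0) | table[numerator_feature].isna()
    kept = table.loc[~bad].copy()
    kept[name] = kept[numerator_feature] / kept[denominator_feature]
    return kept, int(bad.sum())


def normalize_to_reference(table: pd.DataFrame, value_col: str,
                           reference: dict[str, object],
                           stratum_col: str | None = None,
                           out_col: str | None = None) -> pd.DataFrame:
    """Divide values by the reference-group mean within each stratum.

    ``reference`` maps column names to the values identifying the reference
    group (e.g. ``{"condition": "UT", "genotype": "WT"}``).  With a
    ``stratum_col`` (experiment / replicate), normalization runs per
    stratum and the reference mean is 1 in every stratum; without, a single
    global reference mean is used.  An empty reference group in any stratum
    is an error naming the stratum.
    """
    out_col = out_col or f"{value_col}_normalized"
    is_ref = pd.Series(True, index=table.index)
    for col, val in reference.items():
        is_ref &= table[col] == val
    out = table.copy()
    strata = [(None, table.index)] if stratum_col is None \
        else list(table.groupby(stratum_col, sort=False).groups.items())
    for stratum, idx in strata:
        ref_vals = table.loc[idx][is_ref.loc[idx]][value_col].dropna()
        if ref_vals.empty:
            raise ValueError(f"no reference values in stratum {stratum!r}")
        out.loc[idx, out_col] = table.loc[idx, value_col] / ref_vals.mean()
    return out


def well_aggregate(table: pd.DataFrame, metric: str,
                   keep_cols: list[str] | None = None) -> pd.DataFrame:
    """Arithmetic per-well means of a metric with cell counts.

    Wells whose every cell lacks the metric are dropped (they simply do not
    appear; their ids are listed in the ``attrs['dropped_wells']``).
    """
    if "well_id" not in table.columns:
        raise KeyError("table has no well_id column")
    grouped = table.groupby("well_id", sort=False)
    means = grouped[metric].mean()
    counts = grouped[metric].count()
    dropped = counts.index[counts == 0].tolist()
    out = pd.DataFrame({"well_id": means.index, metric: means.to_numpy(),
                        "n_cells": counts.to_numpy()})
    out = out[out["n_cells"] > 0].reset_index(drop=True)
    if keep_cols:
        anno = grouped[keep_cols].first().reset_index()
        out = out.merge(anno, on="well_id", how="left")
    out.attrs["dropped_wells"] = dropped
    return out


def one_sample_test(values, mu: float = 1.0) -> dict:
    """Two-sided one-sample t-test against ``mu``.

    Returns a dict with t, df, p_two_sided and an ``untestable`` flag set
    when the sample standard deviation is zero.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) < 2:
        raise ValueError(f"one-sample t-test needs n >= 2, got n={len(x)}")
    if np.std(x, ddof=1) == 0:
        return {"t": np.nan, "df": len(x) - 1, "p_two_sided": np.nan,
                "n": len(x), "untestable": True}
    res = stats.ttest_1samp(x, popmean=mu)
    return {"t": float(res.statistic), "df": len(x) - 1,
            "p_two_sided": float(res.pvalue), "n": len(x), "untestable": False}


def _ranksum_two_sided(x: np.ndarray, y: np.ndarray) -> tuple[float, float, str]:
    """Two-sided Mann–Whitney U with the documented exact/asymptotic switch."""
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    if not has_ties and len(combined) <= EXACT_RANKSUM_MAX_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method


def group_compare(table: pd.DataFrame, value_col: str, group_col: str,
                  comparisons: list[tuple[str, str]],
                  correction: str = "bh") -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests for planned comparisons.

    One row per comparison: U statistic, two-sided p, BH q across the
    family, the exact/asymptotic method used, group sizes and stars.
    """
    groups = {g: sub[value_col].dropna().to_numpy(dtype=float)
              for g, sub in table.groupby(group_col, sort=False)}
    rows = []
    for g1, g2 in comparisons:
        for g in (g1, g2):
            if g not in groups:
                raise KeyError(f"group {g!r} not present in column {group_col!r}")
        u, p, method = _ranksum_two_sided(groups[g1], groups[g2])
        rows.append({"group_1": g1, "group_2": g2, "U": u, "p": p,
                     "method": method, "n_1": len(groups[g1]),
                     "n_2": len(groups[g2])})
    out = pd.DataFrame(rows)
    if correction == "bh":
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    elif correction is None or correction == "none":
        out["q"] = out["p"]
    else:
        raise ValueError(f"unknown correction {correction!r}")
    out["stars"] = [p_to_stars(q) for q in out["q"]]
    return out


def box_summary(values) -> dict:
    """Tukey box-plot summary.

    Median, quartiles (linear interpolation between order statistics),
    whiskers at the most extreme data points within 1.5x IQR of the box,
    and the count of points beyond the whiskers.
    """
    x = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(x) == 0:
        raise ValueError("box_summary needs at least one value")
    q25, med, q75 = np.percentile(x, [25, 50, 75])
    iqr = q75 - q25
    lo_fence, hi_fence = q25 - 1.5 * iqr, q75 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    return {
        "median": float(med), "q25": float(q25), "q75": float(q75),
        "whisker_lo": float(inside.min()), "whisker_hi": float(inside.max()),
        "outlier_count": int(len(x) - len(inside)),
    }


def mfi_fold_change(facs: pd.DataFrame, numerator: str = "mfi_mcherry",
                    denominator: str = "mfi_gfp",
                    untreated_label: str = "UT") -> pd.DataFrame:
    """Per-sample tandem-reporter ratio fold change over untreated.

    The reporter ratio (default mCherry/GFP) is computed per sample, then
    divided by the mean ratio of that cell line's untreated samples; the
    untreated mean fold change is therefore exactly 1 per line.
    """
    out = facs.copy()
    if (out[[numerator, denominator]] <= 0).any().any():
        raise ValueError("MFI values must be positive")
    out["ratio"] = out[numerator] / out[denominator]
    folds = np.empty(len(out))
    for line, idx in out.groupby("cell_line", sort=False).groups.items():
        sub = out.loc[idx]
        ut = sub.loc[sub["condition"] == untreated_label, "ratio"]
        if ut.empty:
            raise ValueError(f"cell line {line!r} has no untreated "
                             f"({untreated_label!r}) sample")
        folds[out.index.get_indexer(idx)] = sub["ratio"] / ut.mean()
    out["fold_change"] = folds
    return out


def log2_intensity_scatter(table: pd.DataFrame, feature_x: str, feature_y: str,
                           puncta_col: str = "puncta_count",
                           ) -> tuple[pd.DataFrame, int]:
    """Per-cell (log2 x, log2 y, puncta count); non-positive cells excluded."""
    bad = (table[feature_x].isna() | table[feature_y].isna()
           | (table[feature_x] <= 0) | (table[feature_y] <= 0))
    kept = table.loc[~bad]
    out = pd.DataFrame({
        "log2_x": np.log2(kept[feature_x].to_numpy(dtype=float)),
        "log2_y": np.log2(kept[feature_y].to_numpy(dtype=float)),
    }, index=kept.index)
    if puncta_col in table.columns:
        out[puncta_col] = kept[puncta_col]
    return out, int(bad.sum())


def p_to_stars(p: float) -> str:
    """Significance annotation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if np.isnan(p):
        return "na"
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"
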