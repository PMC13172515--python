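"""Interactor calling from label-free quantification (LFQ) matrices.

The calling rule follows standard affinity-purification proteomics
practice: per protein, a two-sample Student t-test (pooled variance)
compares log2 bait intensities against control; proteins passing a 5%
FDR-corrected one-sided test with a minimal enrichment factor of two
(linear scale, i.e. log2 difference >= 1) are called interactors.  The
module also produces volcano-plot coordinates (t-test difference vs
-log10 p), pairwise linear fold-change gates between two conditions, and
per-condition z-scores of average log intensity for heatmaps.

Missing values (zeros in the raw export) may optionally be imputed from a
downshifted normal per sample — the common Perseus convention — before
testing; whether imputation ran is recorded in the result metadata.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .structio import LFQMatrix

__all__ = [
    "preprocess_lfq",
    "impute_missing",
    "test_enrichment",
    "adjust_fdr",
    "call_interactors",
    "pairwise_fc_gate",
    "condition_zscore",
]


def _group_columns(lfq: LFQMatrix, condition: str) -> list[str]:
    return lfq.condition_samples(condition)


def preprocess_lfq(lfq: LFQMatrix, tested_conditions: list[str],
                   min_valid_per_group: int = 2,
                   ) -> tuple[pd.DataFrame, list[str]]:
    """Log2-transform a linear LFQ matrix and filter sparse proteins.

    Zeros become missing; proteins with fewer than ``min_valid_per_group``
    valid values in *every* tested condition are dropped (kept if at least
    one condition passes).  Returns (log2 matrix, dropped protein ids).
    """
    mat = lfq.intensities.astype(float).copy()
    if (mat.to_numpy() < 0).any():
        raise ValueError("negative intensities are not allowed on the linear scale")
    mat = mat.mask(mat == 0)
    log2 = np.log2(mat)
    keep = pd.Series(False, index=log2.index)
    for cond in tested_conditions:
        cols = _group_columns(lfq, cond)
        keep |= log2[cols].notna().sum(axis=1) >= min_valid_per_group
    dropped = log2.index[~keep].tolist()
    return log2.loc[keep], dropped


def impute_missing(log2_matrix: pd.DataFrame, shift: float = 1.8,
                   width: float = 0.3, seed: int | None = None) -> pd.DataFrame:
    """Downshifted-normal imputation, per sample (column).

    Missing entries of each sample are drawn from
    Normal(mean - shift*sd, (width*sd)^2) of that sample's observed values.
    """
    rng = np.random.default_rng(seed)
    out = log2_matrix.copy()
    for col in out.columns:
        vals = out[col]
        observed = vals.dropna()
        n_missing = vals.isna().sum()
        if n_missing == 0:
            continue
        if len(observed) < 2:
            raise ValueError(f"sample {col!r} has fewer than 2 observed values")
        mu, sd = observed.mean(), observed.std(ddof=1)
        draws = rng.normal(mu - shift * sd, width * sd, size=n_missing)
        out.loc[vals.isna(), col] = draws
    return out


def test_enrichment(log2_matrix: pd.DataFrame, lfq: LFQMatrix,
                    bait_condition: str, control_condition: str,
                    equal_var: bool = True) -> pd.DataFrame:
    """Per-protein two-sample t statistics of bait vs control.

    Student's pooled-variance t by default (Welch via ``equal_var=False``);
    ``difference`` is the t-test difference mean(bait) - mean(control) on
    log2 scale.  One-sided p is for enrichment in bait; a two-sided p is
    reported alongside for volcano plotting.  Proteins with fewer than two
    valid values in either group are flagged untestable (statistics NaN).
    """
    bait_cols = _group_columns(lfq, bait_condition)
    ctrl_cols = _group_columns(lfq, control_condition)
    bait = log2_matrix[bait_cols].to_numpy(dtype=float)
    ctrl = log2_matrix[ctrl_cols].to_numpy(dtype=float)
    n_bait = np.sum(~np.isnan(bait), axis=1)
    n_ctrl = np.sum(~np.isnan(ctrl), axis=1)
    testable = (n_bait >= 2) & (n_ctrl >= 2)

    mean_bait = log2_matrix[bait_cols].mean(axis=1, skipna=True).to_numpy()
    mean_ctrl = log2_matrix[ctrl_cols].mean(axis=1, skipna=True).to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # untestable rows handled via the mask
        res = stats.ttest_ind(bait, ctrl, axis=1, equal_var=equal_var,
                              nan_policy="omit", alternative="greater")
        res2 = stats.ttest_ind(bait, ctrl, axis=1, equal_var=equal_var,
                               nan_policy="omit", alternative="two-sided")
    t = np.where(testable, res.statistic, np.nan)
    out = pd.DataFrame({
        "mean_log2_bait": mean_bait,
        "mean_log2_control": mean_ctrl,
        "difference": mean_bait - mean_ctrl,
        "t_statistic": t,
        "p_one_sided": np.where(testable, res.pvalue, np.nan),
        "p_two_sided": np.where(testable, res2.pvalue, np.nan),
        "n_bait": n_bait,
        "n_control": n_ctrl,
        "testable": testable,
    }, index=log2_matrix.index)
    return out


def adjust_fdr(p_values, method: str = "bh", seed: int | None = None, *,
               log2_matrix: pd.DataFrame | None = None,
               lfq: LFQMatrix | None = None,
               bait_condition: str | None = None,
               control_condition: str | None = None,
               n_permutations: int = 250) -> np.ndarray:
    """FDR-adjusted q-values.

    ``bh``: Benjamini–Hochberg step-up (monotone).  ``permutation``:
    group-label permutation null of the one-sided t statistic; q for a
    protein is the ratio of the mean number of null statistics at least as
    extreme to the number of observed statistics at least as extreme
    (clipped to [0, 1], made monotone in the observed ranking).  The
    permutation route needs the matrix and group labels as keywords.
    NaN p-values (untestable proteins) are excluded from the denominator
    and returned as NaN.
    """
    p = np.asarray(p_values, dtype=float)
    valid = ~np.isnan(p)
    if ((p[valid] < 0) | (p[valid] > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full_like(p, np.nan)
    if method == "bh":
        if valid.any():
            q[valid] = _bh_stepup(p[valid])
        return q
    if method != "permutation":
        raise ValueError(f"unknown FDR method {method!r}")
    if log2_matrix is None or lfq is None or bait_condition is None \
            or control_condition is None:
        raise ValueError("permutation FDR requires log2_matrix, lfq, "
                         "bait_condition and control_condition")
    return _permutation_fdr(log2_matrix, lfq, bait_condition, control_condition,
                            n_permutations, seed)


def _bh_stepup(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up: q_(i) = min_{j>=i} p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(q_sorted[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _permutation_fdr(log2_matrix, lfq, bait_condition, control_condition,
                     n_permutations, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    obs = test_enrichment(log2_matrix, lfq, bait_condition, control_condition)
    t_obs = obs["t_statistic"].to_numpy()
    valid = ~np.isnan(t_obs)
    cols = (_group_columns(lfq, bait_condition)
            + _group_columns(lfq, control_condition))
    n_bait = len(_group_columns(lfq, bait_condition))
    data = log2_matrix[cols].to_numpy(dtype=float)
    null_exceed = np.zeros(valid.sum())
    order = np.sort(t_obs[valid])
    for _ in range(n_permutations):
        perm = rng.permutation(data.shape[1])
        pb, pc = data[:, perm[:n_bait]], data[:, perm[n_bait:]]
        tn = stats.ttest_ind(pb, pc, axis=1, equal_var=True,
                             nan_policy="omit").statistic
        tn = tn[~np.isnan(tn)]
        # for each observed t, count null t >= it
        null_exceed += len(tn) - np.searchsorted(np.sort(tn), order, side="left")
    mean_null = null_exceed / n_permutations
    obs_exceed = np.arange(len(order), 0, -1)  # counts of observed >= sorted obs
    q_sorted = np.clip(mean_null / obs_exceed, 0.0, 1.0)
    # enforce monotonicity: larger t never gets larger q
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.full_like(t_obs, np.nan)
    ranks = np.searchsorted(order, t_obs[valid])
    q[valid] = q_sorted[ranks]
    return q


def call_interactors(enrichment: pd.DataFrame, q_values,
                     q_threshold: float = 0.05,
                     min_enrichment_factor: float = 2.0,
                     volcano_p: str = "p_two_sided") -> pd.DataFrame:
    """Apply the interactor rule and emit volcano coordinates.

    A protein is an interactor iff q <= ``q_threshold`` and its linear
    enrichment factor 2^difference >= ``min_enrichment_factor``.  Volcano
    coordinates (difference, -log10 p) are produced for every protein; the
    volcano p-value is two-sided by default, the call is one-sided.
    """
    out = enrichment.copy()
    out["q_fdr"] = np.asarray(q_values, dtype=float)
    out["enrichment_factor"] = 2.0 ** out["difference"]
    out["interactor"] = (
        (out["q_fdr"] <= q_threshold)
        & (out["enrichment_factor"] >= min_enrichment_factor)
    ).fillna(False)
    with np.errstate(divide="ignore"):
        out["neg_log10_p"] = -np.log10(out[volcano_p])
    return out


def pairwise_fc_gate(lfq: LFQMatrix, condition_x: str, condition_y: str,
                     threshold: float = 2.0) -> pd.DataFrame:
    """Gate proteins on the linear mean ratio x/y >= threshold (inclusive).

    Proteins whose denominator mean is zero or missing are flagged
    incomputable and excluded from the gate.
    """
    x_cols = _group_columns(lfq, condition_x)
    y_cols = _group_columns(lfq, condition_y)
    mx = lfq.intensities[x_cols].mean(axis=1, skipna=True)
    my = lfq.intensities[y_cols].mean(axis=1, skipna=True)
    incomputable = my.isna() | (my <= 0) | mx.isna()
    ratio = mx / my.mask(my <= 0)
    return pd.DataFrame({
        "mean_x": mx,
        "mean_y": my,
        "fold_change": ratio,
        "incomputable": incomputable,
        "flagged": (~incomputable) & (ratio >= threshold),
    })


def condition_zscore(log2_matrix: pd.DataFrame, lfq: LFQMatrix,
                     conditions: list[str] | None = None) -> pd.DataFrame:
    """Z-score of the per-condition average log intensity, across conditions.

    Per protein, condition means are z-scored with the sample standard
    deviation (ddof=1); constant rows get z = 0 everywhere and a
    ``constant`` flag column.
    """
    if conditions is None:
        conditions = list(pd.unique(lfq.samples["condition"]))
    if len(conditions) < 2:
        raise ValueError("z-scoring needs at least two conditions")
    means = pd.DataFrame({
        cond: log2_matrix[_group_columns(lfq, cond)].mean(axis=1, skipna=True)
        for cond in conditions
    })
    mu = means.mean(axis=1)
    sd = means.std(axis=1, ddof=1)
    constant = sd == 0
    z = means.sub(mu, axis=0).div(sd.mask(constant), axis=0)
    z[constant] = 0.0
    z["constant"] = constant
    return z
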