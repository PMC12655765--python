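"""Drug-gene correlation testing with Holm family-wise error control.

Pearson and Spearman coefficients are computed for every (drug, gene) pair
across the cell-line panel on pairwise-complete observations, two-sided
p-values come from the t transform with n-2 degrees of freedom, p-values
are Holm-adjusted (per-drug families by default, optionally one global
family), and pairs are retained when the coefficient clears the CellMiner
style threshold (default r >= 0.334, positive sign) and the adjusted
p-value clears alpha (default 0.05). Both thresholds are inclusive.

Record tables are plain DataFrames with the columns in ``RECORD_COLUMNS``;
pairs that cannot be tested (fewer than 3 complete observations, or a
constant profile) carry NaN coefficients and ``testable = False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FilterPolicy",
    "correlate_all",
    "filter_records",
    "holm_adjust",
    "mark_retained",
    "pearson_correlation",
    "qc_filter_drugs",
    "spearman_correlation",
    "write_correlation_table",
]

RECORD_COLUMNS = [
    "drug_id", "gene_id", "n_obs",
    "pearson_r", "pearson_p", "spearman_rho", "spearman_p",
    "holm_p", "holm_p_spearman", "testable",
]

COEFFICIENT_MODES = ("pearson", "spearman", "either", "both")
SIGN_MODES = ("positive", "both")
HOLM_SCOPES = ("per_drug", "global")


@dataclass(frozen=True)
class FilterPolicy:
    """Retention thresholds for drug-gene correlation records."""

    r_threshold: float = 0.334
    alpha: float = 0.05
    coefficient_mode: str = "pearson"
    sign_mode: str = "positive"
    min_n_obs: int = 40
    min_sd: float = 1e-8
    holm_scope: str = "per_drug"

    def __post_init__(self):
        if self.coefficient_mode not in COEFFICIENT_MODES:
            raise ValueError(f"coefficient_mode must be one of {COEFFICIENT_MODES}")
        if self.sign_mode not in SIGN_MODES:
            raise ValueError(f"sign_mode must be one of {SIGN_MODES}")
        if self.holm_scope not in HOLM_SCOPES:
            raise ValueError(f"holm_scope must be one of {HOLM_SCOPES}")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if self.min_sd < 0 or self.min_n_obs < 3:
            raise ValueError("min_sd >= 0 and min_n_obs >= 3 required")


def _t_pvalue(r: np.ndarray, n) -> np.ndarray:
    """Two-sided p from the t transform with n-2 df; p=0 at |r|=1."""
    r = np.asarray(r, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt((n - 2.0) / np.clip(1.0 - r * r, 0.0, None))
    p = 2.0 * stats.t.sf(t, n - 2.0)
    return np.clip(p, 0.0, 1.0)


def _pair_complete(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    obs = np.isfinite(x) & np.isfinite(y)
    return x[obs], y[obs], int(obs.sum())


def pearson_correlation(x, y) -> tuple[float, float, int]:
    """Pearson r, two-sided p (t transform, n-2 df) and n on pairwise-complete data.

    Returns ``(nan, nan, n)`` when fewer than 3 complete observations remain
    or either vector is constant; such pairs are flagged untestable
    downstream rather than raising.
    """
    xs, ys, n = _pair_complete(x, y)
    if n < 3 or xs.std() == 0 or ys.std() == 0:
        return float("nan"), float("nan"), n
    r = _product_moment(xs, ys)
    return r, float(_t_pvalue(r, n)), n


def _product_moment(xs: np.ndarray, ys: np.ndarray) -> float:
    # symmetric in its arguments to the last bit
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    r = float(np.dot(xc, yc) / (np.linalg.norm(xc) * np.linalg.norm(yc)))
    return max(-1.0, min(1.0, r))


def spearman_correlation(x, y) -> tuple[float, float, int]:
    """Spearman rho (mid-rank ties), two-sided t-approximation p, and n."""
    xs, ys, n = _pair_complete(x, y)
    if n < 3 or xs.std() == 0 or ys.std() == 0:
        return float("nan"), float("nan"), n
    rho = _product_moment(stats.rankdata(xs), stats.rankdata(ys))
    return rho, float(_t_pvalue(rho, n)), n


def qc_filter_drugs(
    activity: pd.DataFrame, policy: FilterPolicy = FilterPolicy()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop drugs with weak or degenerate activity profiles.

    A drug row is removed when it has fewer than ``min_n_obs`` non-missing
    values or a standard deviation below ``min_sd`` over the non-missing
    values. Returns the reduced matrix and a removal log
    (drug_id, n_obs, sd, reason).
    """
    n_obs = activity.notna().sum(axis=1)
    sd = activity.std(axis=1, ddof=1).fillna(0.0)
    removals = []
    for d in activity.index:
        if n_obs[d] < policy.min_n_obs:
            removals.append((d, int(n_obs[d]), float(sd[d]), "too_few_observations"))
        elif sd[d] < policy.min_sd:
            removals.append((d, int(n_obs[d]), float(sd[d]), "low_variance"))
    log = pd.DataFrame(removals, columns=["drug_id", "n_obs", "sd", "reason"])
    kept = activity.drop(index=log["drug_id"].tolist())
    if kept.empty:
        raise ValueError("QC removed every drug; check activity matrix and policy")
    return kept, log


def _check_cell_lines(expression: pd.DataFrame, activity: pd.DataFrame) -> None:
    if list(expression.columns) != list(activity.columns):
        only_e = [c for c in expression.columns if c not in set(activity.columns)]
        only_a = [c for c in activity.columns if c not in set(expression.columns)]
        raise ValueError(
            "expression and activity matrices must share identical cell-line "
            f"ordering; expression-only: {only_e[:5]}, activity-only: {only_a[:5]}"
        )


def _correlate_dense(expression: pd.DataFrame, activity: pd.DataFrame) -> pd.DataFrame:
    """Vectorized path for complete matrices (no missing entries)."""
    n = expression.shape[1]
    X = expression.to_numpy(dtype=float)
    A = activity.to_numpy(dtype=float)

    def row_corr(P, Q):
        P = P - P.mean(axis=1, keepdims=True)
        Q = Q - Q.mean(axis=1, keepdims=True)
        ps = np.sqrt((P * P).sum(axis=1))
        qs = np.sqrt((Q * Q).sum(axis=1))
        with np.errstate(divide="ignore", invalid="ignore"):
            C = (Q @ P.T) / np.outer(qs, ps)
        return np.clip(C, -1.0, 1.0)

    R = row_corr(X, A)
    ranksX = np.apply_along_axis(stats.rankdata, 1, X)
    ranksA = np.apply_along_axis(stats.rankdata, 1, A)
    RHO = row_corr(ranksX, ranksA)
    P = _t_pvalue(R, n)
    PS = _t_pvalue(RHO, n)

    drugs = np.repeat(activity.index.to_numpy(), expression.shape[0])
    genes = np.tile(expression.index.to_numpy(), activity.shape[0])
    out = pd.DataFrame({
        "drug_id": drugs,
        "gene_id": genes,
        "n_obs": n,
        "pearson_r": R.ravel(),
        "pearson_p": P.ravel(),
        "spearman_rho": RHO.ravel(),
        "spearman_p": PS.ravel(),
    })
    out["testable"] = np.isfinite(out["pearson_r"])
    out.loc[~out["testable"], ["pearson_p", "spearman_rho", "spearman_p"]] = np.nan
    return out


def correlate_all(
    expression: pd.DataFrame,
    activity: pd.DataFrame,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """One record per (drug, gene) pair, Holm-adjusted within ``holm_scope``.

    Matrices are genes x cell lines and drugs x cell lines with identical
    column ordering (a mismatch raises, naming the offending ids). Missing
    entries are handled by pairwise-complete deletion. The result has the
    ``RECORD_COLUMNS`` layout; ``holm_p`` adjusts the Pearson p-values and
    ``holm_p_spearman`` the Spearman ones.
    """
    _check_cell_lines(expression, activity)
    if not expression.index.is_unique or not activity.index.is_unique:
        raise ValueError("gene and drug ids must be unique")

    complete = not (
        expression.isna().to_numpy().any() or activity.isna().to_numpy().any()
    )
    if complete:
        records = _correlate_dense(expression, activity)
    else:
        rows = []
        for d, a_row in zip(activity.index, activity.to_numpy(dtype=float)):
            for g, x_row in zip(expression.index, expression.to_numpy(dtype=float)):
                r, p, n = pearson_correlation(x_row, a_row)
                rho, ps, _ = spearman_correlation(x_row, a_row)
                rows.append((d, g, n, r, p, rho, ps, np.isfinite(r)))
        records = pd.DataFrame(rows, columns=[
            "drug_id", "gene_id", "n_obs", "pearson_r", "pearson_p",
            "spearman_rho", "spearman_p", "testable",
        ])
    return add_holm(records, scope=policy.holm_scope)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values, returned in the input order.

    Sort ascending, multiply the i-th smallest by (m - i + 1), enforce the
    running maximum, cap at 1. Untestable entries must be excluded before
    calling; values outside [0, 1] raise.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * (m - np.arange(m))
    adjusted = np.minimum(np.maximum.accumulate(scaled), 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def add_holm(records: pd.DataFrame, scope: str = "per_drug") -> pd.DataFrame:
    """Attach ``holm_p`` (Pearson) and ``holm_p_spearman`` columns.

    ``scope='per_drug'`` adjusts within the family of all genes tested for
    each drug; ``scope='global'`` treats every testable record as one family.
    """
    if scope not in HOLM_SCOPES:
        raise ValueError(f"scope must be one of {HOLM_SCOPES}")
    records = records.reset_index(drop=True).copy()
    records["holm_p"] = np.nan
    records["holm_p_spearman"] = np.nan
    if records["testable"].any():
        if scope == "global":
            groups = [records.index[records["testable"]]]
        else:
            groups = [
                sub.index[sub["testable"]]
                for _, sub in records.groupby("drug_id", sort=False)
            ]
        for idx in groups:
            if len(idx) == 0:
                continue
            records.loc[idx, "holm_p"] = holm_adjust(records.loc[idx, "pearson_p"])
            records.loc[idx, "holm_p_spearman"] = holm_adjust(
                records.loc[idx, "spearman_p"]
            )
    return records[RECORD_COLUMNS]


def _passes(records: pd.DataFrame, coef_col: str, holm_col: str,
            policy: FilterPolicy) -> pd.Series:
    coef = records[coef_col]
    if policy.sign_mode == "positive":
        size_ok = coef >= policy.r_threshold
    else:
        size_ok = coef.abs() >= policy.r_threshold
    return size_ok & (records[holm_col] <= policy.alpha)


def mark_retained(records: pd.DataFrame, policy: FilterPolicy = FilterPolicy()) -> pd.Series:
    """Boolean retention mask under the policy (thresholds inclusive)."""
    pearson_ok = _passes(records, "pearson_r", "holm_p", policy)
    spearman_ok = _passes(records, "spearman_rho", "holm_p_spearman", policy)
    mode = policy.coefficient_mode
    if mode == "pearson":
        keep = pearson_ok
    elif mode == "spearman":
        keep = spearman_ok
    elif mode == "either":
        keep = pearson_ok | spearman_ok
    else:
        keep = pearson_ok & spearman_ok
    return (keep & records["testable"]).fillna(False)


def filter_records(
    records: pd.DataFrame, policy: FilterPolicy = FilterPolicy()
) -> pd.DataFrame:
    """Retained records, sorted by drug id then descending Pearson r."""
    kept = records[mark_retained(records, policy)].copy()
    kept = kept.sort_values(
        ["drug_id", "pearson_r"], ascending=[True, False], kind="stable"
    )
    return kept.reset_index(drop=True)


def write_correlation_table(records: pd.DataFrame, path,
                            policy: FilterPolicy = FilterPolicy()) -> None:
    out = records.copy()
    out["retained"] = mark_retained(records, policy).astype(int)
    out.drop(columns=["testable"]).to_csv(
        path, sep="\t", index=False, na_rep="NA", float_format="%.6g"
    )


def read_correlation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"drug_id": str, "gene_id": str})
    df["testable"] = df["pearson_r"].notna()
    return df
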