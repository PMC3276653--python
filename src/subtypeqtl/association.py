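"""Classical per-gene association of expression with a quantitative trait.

Pearson correlation tests, extreme-group Student t-tests, Benjamini-Hochberg
adjustment, and the two classical gene-list constructions (correlation-only
and correlation-or-t-test union).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "correlation_test",
    "extreme_group_ttest",
    "bh_adjust",
    "classical_gene_lists",
    "gene_test_table",
]


def _check_expr_trait(expr: pd.DataFrame, trait: pd.Series):
    trait = trait.reindex(expr.columns)
    if trait.isna().any():
        missing = list(trait.index[trait.isna()])
        raise ValueError(f"trait missing for animals {missing}")
    return trait.to_numpy(dtype=float)


def correlation_test(expr: pd.DataFrame, trait: pd.Series, extra_df_loss: int = 0) -> pd.DataFrame:
    """Per-gene Pearson correlation with the trait.

    Two-sided p-values from the t transform of r with ``n - 2 -
    extra_df_loss`` degrees of freedom (``extra_df_loss`` accounts for
    covariate directions removed upstream, e.g. estimated latent factors).
    Genes with zero variance are flagged (``tested = False``) and carry NaN
    statistics rather than being silently dropped.

    Parameters
    ----------
    expr : DataFrame, genes x animals
    trait : Series indexed by animal
    """
    y = _check_expr_trait(expr, trait)
    n = y.size
    if n - extra_df_loss < 4:
        raise ValueError("need at least 4 residual degrees of freedom")
    if np.isclose(y.std(), 0.0):
        raise ValueError("trait is constant; correlation is undefined")
    x = expr.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    tested = sx > 0
    r = np.full(x.shape[0], np.nan)
    r[tested] = (xc[tested] @ yc) / (sx[tested] * sy)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2 - extra_df_loss
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return pd.DataFrame(
        {"r": r, "t_corr": t, "p_corr": np.where(tested, p, np.nan), "tested": tested},
        index=expr.index,
    )


def extreme_group_ttest(expr: pd.DataFrame, trait: pd.Series, k: int = 10) -> pd.DataFrame:
    """Equal-variance Student t-test between the k leanest and k fattest animals.

    Ties straddling the k-th trait rank are broken deterministically by
    animal-id order (a stable sort on trait then id), and the tie-break is
    logged through :mod:`warnings`.
    """
    y = trait.reindex(expr.columns)
    n = len(y)
    if 2 * k > n:
        raise ValueError("2k must not exceed the number of animals")
    ranked = y.sort_values(kind="mergesort")  # stable: ties keep id order
    low_ids = list(ranked.index[:k])
    high_ids = list(ranked.index[-k:])
    boundary_low = ranked.iloc[k - 1]
    boundary_high = ranked.iloc[-k]
    if (ranked == boundary_low).sum() > 1 or (ranked == boundary_high).sum() > 1:
        warnings.warn(
            "trait ties straddle the extreme-group boundary; broken by animal-id order",
            stacklevel=2,
        )
    lo = expr[low_ids].to_numpy(dtype=float)
    hi = expr[high_ids].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(lo, hi, axis=1, equal_var=True)
    const = (lo.std(axis=1) == 0) & (hi.std(axis=1) == 0)
    same = const & np.isclose(lo.mean(axis=1), hi.mean(axis=1))
    t = np.where(same, 0.0, t)
    p = np.where(same, 1.0, p)
    return pd.DataFrame(
        {"t_stat": t, "p_ttest": p, "group_low": ",".join(low_ids), "group_high": ",".join(high_ids)},
        index=expr.index,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Input values must lie in (0, 1]; output is capped at 1 and is monotone in
    p-value rank.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_test_table(
    expr: pd.DataFrame, trait: pd.Series, k: int = 10, extra_df_loss: int = 0
) -> pd.DataFrame:
    """Combined per-gene result table: correlation test, extreme-group t-test
    and BH-adjusted correlation p-values."""
    corr = correlation_test(expr, trait, extra_df_loss=extra_df_loss)
    tt = extreme_group_ttest(expr, trait, k=k)
    out = corr.join(tt[["t_stat", "p_ttest"]])
    p_bh = np.full(len(out), np.nan)
    ok = out["tested"].to_numpy() & np.isfinite(out["p_corr"].to_numpy())
    if ok.any():
        p_bh[ok] = bh_adjust(np.clip(out.loc[ok, "p_corr"].to_numpy(), 1e-300, 1.0))
    out["p_bh"] = p_bh
    return out


def classical_gene_lists(results: pd.DataFrame, alpha: float = 0.05):
    """The two classical gene lists at an uncorrected threshold.

    correlation_list = {p_corr < alpha};
    union_list = {p_corr < alpha} | {p_ttest < alpha}  (a superset).
    """
    p_corr = results["p_corr"]
    p_ttest = results["p_ttest"]
    corr_list = list(results.index[(p_corr < alpha).fillna(False)])
    union_mask = (p_corr < alpha).fillna(False) | (p_ttest < alpha).fillna(False)
    union_list = list(results.index[union_mask])
    return corr_list, union_list
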