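"""Sensitivity battery: heterogeneity, pleiotropy, directionality,
leave-one-out, single-SNP and plot-ready data.

These diagnostics probe the instrumental-variable assumptions that the
point estimates cannot check by themselves: Cochran's Q measures the
variation of per-SNP causal estimates about the pooled fit (a horizontal
pleiotropy red flag), the Egger intercept estimates average directional
pleiotropy, the directionality (Steiger-type) test asks whether the
instruments explain more variance in the exposure than in the outcome,
and leave-one-out / single-SNP tables reveal estimates driven by one
outlying variant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (MRResult, PleiotropyResult, _arrays, _egger_wls,
                         _ivw_core, _orient, egger, ivw, method_display_name,
                         wald_ratio)

__all__ = [
    "HeterogeneityResult", "DirectionResult", "heterogeneity_q",
    "egger_intercept", "direction_test", "leave_one_out", "single_snp",
    "funnel_data", "scatter_data",
]


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q about the IVW or Egger fit; chi^2 upper-tail p."""

    method: str
    Q: float
    df: int
    pval: float


@dataclass(frozen=True)
class DirectionResult:
    """Variance-explained comparison between exposure and outcome.

    ``correct_direction`` is True when the instruments explain more
    variance in the exposure than in the outcome, i.e. the assumed causal
    orientation is supported.  This is a flag, never an effect estimate.
    """

    r2_exposure: float
    r2_outcome: float
    correct_direction: bool
    test_pval: float


def heterogeneity_q(dataset, method: str = "ivw") -> HeterogeneityResult:
    """Q = sum w_j (beta_out_j - fitted_j)^2 with w_j = se_out_j^-2.

    Fitted values come from the fixed-effect IVW line (df = L - 1) or the
    Egger regression (df = L - 2).  Lower heterogeneity indicates better
    reliability of the pooled estimate.
    """
    bx, sx, by, sy = _arrays(dataset)
    L = bx.size
    if method == "ivw":
        if L < 2:
            raise ValueError("heterogeneity (ivw) needs >= 2 SNPs")
        b, _, q = _ivw_core(bx, by, sy)
        df = L - 1
    elif method == "egger":
        if L < 3:
            raise ValueError("heterogeneity (egger) needs >= 3 SNPs")
        bxo, byo = _orient(bx, by)
        coef, _, _ = _egger_wls(bxo, byo, sy)
        resid = byo - (coef[0] + coef[1] * bxo)
        q = float(np.sum(sy ** -2.0 * resid ** 2))
        df = L - 2
    else:
        raise ValueError(f"unknown heterogeneity method: {method!r}")
    return HeterogeneityResult(method, q, df, float(stats.chi2.sf(q, df)))


def egger_intercept(dataset) -> PleiotropyResult:
    """The Egger regression intercept block (identical to the egger fit)."""
    _, intercept = egger(dataset)
    return intercept


def _sum_r2(beta, se, n):
    """Variance explained summed over SNPs, via the t-statistic form."""
    t = beta / se
    r2 = t ** 2 / (t ** 2 + n - 2.0)
    return float(np.sum(r2))


def direction_test(dataset, n_exp=None, n_out=None) -> DirectionResult:
    """Causal-direction (Steiger-type) test.

    Per-SNP variance explained is r2_j = t_j^2 / (t_j^2 + n - 2), summed
    per study; the test statistic compares the Fisher transforms of
    sqrt(r2) scaled by the two studies' sampling variances.  The result
    says whether the assumed exposure-to-outcome orientation is supported;
    it cannot establish that a causal association exists.
    """
    kept = dataset.kept()
    if n_exp is None:
        n_exp = kept["n_exp"].dropna().median() if kept["n_exp"].notna().any() else None
    if n_out is None:
        n_out = kept["n_out"].dropna().median() if kept["n_out"].notna().any() else None
    if n_exp is None or not np.isfinite(n_exp):
        raise ValueError("direction test needs a sample size for the exposure study")
    if n_out is None or not np.isfinite(n_out):
        raise ValueError("direction test needs a sample size for the outcome study")
    bx, sx, by, sy = _arrays(dataset)
    r2_exp = min(_sum_r2(bx, sx, float(n_exp)), 1.0)
    r2_out = min(_sum_r2(by, sy, float(n_out)), 1.0)
    z_exp = np.arctanh(min(math.sqrt(r2_exp), 1 - 1e-15))
    z_out = np.arctanh(min(math.sqrt(r2_out), 1 - 1e-15))
    se_diff = math.sqrt(1.0 / (n_exp - 3) + 1.0 / (n_out - 3))
    z = (z_exp - z_out) / se_diff
    return DirectionResult(r2_exp, r2_out, bool(r2_exp > r2_out),
                           float(2.0 * stats.norm.sf(abs(z))))


def leave_one_out(dataset) -> pd.DataFrame:
    """Default-IVW estimate omitting each SNP in turn, plus an "All" row.

    Used to see whether the pooled result is driven by a single outlying
    SNP.  Requires >= 3 kept SNPs.
    """
    kept = dataset.kept()
    if len(kept) < 3:
        raise ValueError("leave-one-out needs >= 3 SNPs")
    from .harmonise import HarmonisedDataset
    rows = []
    for snp in kept["snp_id"]:
        sub = HarmonisedDataset(df=kept[kept["snp_id"] != snp].copy())
        res = ivw(sub)
        rows.append({"snp": snp, "b": res.b, "se": res.se, "pval": res.pval,
                     "nsnp": res.nsnp})
    res_all = ivw(dataset)
    rows.append({"snp": "All", "b": res_all.b, "se": res_all.se,
                 "pval": res_all.pval, "nsnp": res_all.nsnp})
    return pd.DataFrame(rows, columns=["snp", "b", "se", "pval", "nsnp"])


def single_snp(dataset) -> pd.DataFrame:
    """Per-SNP Wald ratios plus overall IVW (and Egger when L >= 3).

    Supplies the forest-plot data: one row per SNP and "All - <method>"
    rows for the pooled estimates.  With a single SNP only its ratio row
    is returned.
    """
    bx, sx, by, sy = _arrays(dataset)
    kept = dataset.kept()
    rows = []
    for snp, args in zip(kept["snp_id"], zip(bx, sx, by, sy)):
        res = wald_ratio(*args)
        rows.append({"snp": snp, "b": res.b, "se": res.se, "pval": res.pval})
    L = bx.size
    if L >= 2:
        res = ivw(dataset)
        rows.append({"snp": "All - Inverse variance weighted",
                     "b": res.b, "se": res.se, "pval": res.pval})
    if L >= 3:
        slope, _ = egger(dataset)
        rows.append({"snp": "All - MR Egger", "b": slope.b, "se": slope.se,
                     "pval": slope.pval})
    return pd.DataFrame(rows, columns=["snp", "b", "se", "pval"])


def funnel_data(dataset) -> pd.DataFrame:
    """Per-SNP (Wald ratio, precision = 1/se_ratio) for the funnel plot.

    Asymmetry of the funnel about the pooled estimate suggests directional
    horizontal pleiotropy.
    """
    bx, sx, by, sy = _arrays(dataset)
    kept = dataset.kept()
    ratio = by / bx
    precision = np.abs(bx) / sy
    return pd.DataFrame({"snp": kept["snp_id"], "ratio": ratio,
                         "precision": precision})


def scatter_data(dataset, results) -> pd.DataFrame:
    """Oriented per-SNP effects plus one fitted line per method.

    Points are oriented so the exposure effect is always positive; every
    non-Egger line passes through the origin, the Egger line carries its
    intercept.  Returns a frame of point rows (kind="point") and line rows
    (kind="line", slope/intercept).
    """
    bx, sx, by, sy = _arrays(dataset)
    if not results:
        raise ValueError("scatter_data needs at least one MR result")
    kept = dataset.kept()
    bxo, byo = _orient(bx, by)
    point_rows = pd.DataFrame({
        "kind": "point", "snp": kept["snp_id"], "beta_exp": bxo,
        "se_exp": sx, "beta_out": byo, "se_out": sy,
        "method": "", "slope": np.nan, "intercept": np.nan,
    })
    line_rows = []
    for res in results:
        intercept = 0.0
        if res.method in ("mr_egger", "mr_egger_bootstrap"):
            _, pleio = egger(dataset)
            intercept = pleio.intercept
        line_rows.append({
            "kind": "line", "snp": "", "beta_exp": np.nan, "se_exp": np.nan,
            "beta_out": np.nan, "se_out": np.nan,
            "method": method_display_name(res.method),
            "slope": res.b, "intercept": intercept,
        })
    return pd.concat([point_rows, pd.DataFrame(line_rows)], ignore_index=True)
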