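"""Renderers for the four standard MR diagnostic graphs.

Forest (single-SNP), method-comparison scatter, leave-one-out forest and
funnel plots, written as SVG/PNG.  No plots are produced for single-SNP
instruments, since the underlying sensitivity analyses need multiple SNPs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_forest", "plot_scatter", "plot_leave_one_out", "plot_funnel"]

_Z = 1.959963984540054  # 95% normal quantile


def _save(fig, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return path


def plot_forest(single_snp: pd.DataFrame, path, title: str = "Single SNP analysis") -> Path:
    """Forest plot of per-SNP Wald ratios with the pooled estimates."""
    df = single_snp.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(df))))
    y = np.arange(len(df))
    ax.errorbar(df["b"], y, xerr=_Z * df["se"], fmt="o", ms=3,
                color="black", ecolor="grey", lw=1)
    ax.axvline(0, color="lightgrey", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(df["snp"], fontsize=6)
    ax.set_xlabel("MR effect size")
    ax.set_title(title)
    return _save(fig, path)


def plot_scatter(scatter: pd.DataFrame, path, title: str = "Method comparison") -> Path:
    """SNP effects on exposure vs outcome with one fitted line per method."""
    points = scatter[scatter["kind"] == "point"]
    lines = scatter[scatter["kind"] == "line"]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.errorbar(points["beta_exp"], points["beta_out"],
                xerr=_Z * points["se_exp"], yerr=_Z * points["se_out"],
                fmt="o", ms=3, color="black", ecolor="lightgrey", lw=1)
    xs = np.linspace(0, float(points["beta_exp"].max()) * 1.05, 50)
    for row in lines.itertuples(index=False):
        ax.plot(xs, row.intercept + row.slope * xs, label=row.method, lw=1.5)
    ax.set_xlabel("SNP effect on exposure")
    ax.set_ylabel("SNP effect on outcome")
    ax.legend(fontsize=7)
    ax.set_title(title)
    return _save(fig, path)


def plot_leave_one_out(loo: pd.DataFrame, path, title: str = "Leave-one-out analysis") -> Path:
    """Forest plot of IVW estimates omitting one SNP at a time."""
    df = loo.iloc[::-1]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.22 * len(df))))
    y = np.arange(len(df))
    ax.errorbar(df["b"], y, xerr=_Z * df["se"], fmt="o", ms=3,
                color="black", ecolor="grey", lw=1)
    ax.axvline(0, color="lightgrey", lw=1)
    ax.set_yticks(y)
    ax.set_yticklabels(df["snp"], fontsize=6)
    ax.set_xlabel("IVW estimate omitting each SNP")
    ax.set_title(title)
    return _save(fig, path)


def plot_funnel(funnel: pd.DataFrame, path, pooled_b: float | None = None,
                title: str = "Funnel plot") -> Path:
    """Per-SNP ratio estimate against its precision (1/se)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.plot(funnel["ratio"], funnel["precision"], "o", ms=3, color="black")
    if pooled_b is not None:
        ax.axvline(pooled_b, color="steelblue", lw=1.5, label="IVW")
        ax.legend(fontsize=7)
    ax.set_xlabel("Wald ratio")
    ax.set_ylabel("Precision (1/SE)")
    ax.set_title(title)
    return _save(fig, path)
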