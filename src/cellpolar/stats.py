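"""Group-level comparisons of per-cell metrics and report rendering.

Supports the comparisons conventionally applied to per-cell organelle
metrics: unpaired two-sided t-test, Mann-Whitney, Kruskal-Wallis, and
one-way ANOVA followed by Dunnett's multiple-comparison test against a
named reference group.  Summaries are reported as mean +/- s.d. with the
sample (n-1) standard deviation.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UsageError

__all__ = ["METRIC_COLUMNS", "compare_groups", "group_summary", "render_report"]

METRIC_COLUMNS = ("mdr_normalized", "mdr_raw", "asymmetry")
TESTS = ("t", "mannwhitney", "kruskal", "anova_dunnett")


def _check_table(table: pd.DataFrame, metric: str) -> None:
    for col in ("group", metric):
        if col not in table.columns:
            raise UsageError(f"metrics table lacks column {col!r}")
    if table[metric].isna().any():
        raise UsageError(f"missing values in metric {metric!r}")
    counts = table.groupby("group").size()
    small = counts[counts < 2]
    if len(small):
        raise UsageError(f"groups with < 2 cells: {list(small.index)}")


def group_summary(table: pd.DataFrame,
                  metrics: tuple[str, ...] = METRIC_COLUMNS) -> pd.DataFrame:
    """Per-group n, mean and sample s.d. for each metric present."""
    metrics = tuple(m for m in metrics if m in table.columns)
    rows = []
    for group, sub in table.groupby("group", sort=True):
        row: dict = {"group": group, "n": len(sub)}
        for m in metrics:
            row[f"{m}_mean"] = sub[m].mean()
            row[f"{m}_sd"] = sub[m].std(ddof=1)
        rows.append(row)
    return pd.DataFrame(rows)


def _pair_row(metric, test, g1, g2, x1, x2, stat, p) -> dict:
    return {
        "metric": metric, "test": test, "group1": g1, "group2": g2,
        "n1": len(x1), "n2": len(x2),
        "mean1": float(np.mean(x1)), "sd1": float(np.std(x1, ddof=1)),
        "mean2": float(np.mean(x2)), "sd2": float(np.std(x2, ddof=1)),
        "mean_diff": float(np.mean(x1) - np.mean(x2)),
        "statistic": float(stat), "pvalue": float(f"{p:.4g}"),
    }


def compare_groups(table: pd.DataFrame, metric: str, test: str = "t",
                   reference: str | None = None) -> pd.DataFrame:
    """Compare groups on one metric.

    * ``t`` / ``mannwhitney``: pairwise two-sided comparisons — each group
      against ``reference`` when given, else all pairs.
    * ``kruskal``: one omnibus row across all groups.
    * ``anova_dunnett``: one omnibus one-way ANOVA row plus one row per
      non-reference group with Dunnett-adjusted two-sided P values
      (``reference`` required).

    P values are reported to 4 significant figures.
    """
    if test not in TESTS:
        raise UsageError(f"unknown test {test!r}; choose one of {TESTS}")
    _check_table(table, metric)
    groups = sorted(table["group"].unique())
    if reference is not None and reference not in groups:
        raise UsageError(f"reference group {reference!r} not in table")
    by = {g: table.loc[table["group"] == g, metric].to_numpy(float) for g in groups}

    rows: list[dict] = []
    if test in ("t", "mannwhitney"):
        if reference is not None:
            pairs = [(g, reference) for g in groups if g != reference]
        else:
            pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        for g1, g2 in pairs:
            x1, x2 = by[g1], by[g2]
            if test == "t":
                res = sps.ttest_ind(x1, x2)
            else:
                res = sps.mannwhitneyu(x1, x2, alternative="two-sided")
            rows.append(_pair_row(metric, test, g1, g2, x1, x2,
                                  res.statistic, res.pvalue))
    elif test == "kruskal":
        if len(groups) < 2:
            raise UsageError("kruskal needs >= 2 groups")
        res = sps.kruskal(*(by[g] for g in groups))
        rows.append({
            "metric": metric, "test": test, "group1": "|".join(groups),
            "group2": "", "n1": len(table), "n2": 0,
            "mean1": float(table[metric].mean()),
            "sd1": float(table[metric].std(ddof=1)),
            "mean2": np.nan, "sd2": np.nan, "mean_diff": np.nan,
            "statistic": float(res.statistic),
            "pvalue": float(f"{res.pvalue:.4g}"),
        })
    else:  # anova_dunnett
        if reference is None:
            raise UsageError("anova_dunnett requires a reference group")
        others = [g for g in groups if g != reference]
        if not others:
            raise UsageError("anova_dunnett needs >= 1 non-reference group")
        f = sps.f_oneway(*(by[g] for g in groups))
        rows.append({
            "metric": metric, "test": "anova", "group1": "|".join(groups),
            "group2": "", "n1": len(table), "n2": 0,
            "mean1": float(table[metric].mean()),
            "sd1": float(table[metric].std(ddof=1)),
            "mean2": np.nan, "sd2": np.nan, "mean_diff": np.nan,
            "statistic": float(f.statistic),
            "pvalue": float(f"{f.pvalue:.4g}"),
        })
        dn = sps.dunnett(*(by[g] for g in others), control=by[reference])
        for g, stat, p in zip(others, np.atleast_1d(dn.statistic),
                              np.atleast_1d(dn.pvalue)):
            rows.append(_pair_row(metric, "dunnett", g, reference,
                                  by[g], by[reference], stat, p))
    return pd.DataFrame(rows)


def render_report(table: pd.DataFrame, comparisons: pd.DataFrame | None,
                  out_dir: str | Path, plot_metric: str | None = None) -> list[Path]:
    """Write the per-group summary, the comparison table, and optionally a
    scatter-with-mean+/-sd panel.  File names are deterministic.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        summary = group_summary(table)
        path = out / "summary.csv"
        summary.to_csv(path, index=False)
        written.append(path)
        if comparisons is not None and len(comparisons):
            path = out / "comparisons.csv"
            comparisons.to_csv(path, index=False)
            written.append(path)
        if plot_metric is not None:
            written.append(_scatter_panel(table, plot_metric, out))
        return written
    except OSError as exc:
        raise UsageError(f"cannot write report to {out}: {exc}") from exc


def _scatter_panel(table: pd.DataFrame, metric: str, out: Path) -> Path:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _check_table(table, metric)
    groups = sorted(table["group"].unique())
    fig, ax = plt.subplots(figsize=(1.2 + 0.9 * len(groups), 3.2))
    rng = np.random.default_rng(0)  # fixed jitter for reproducible figures
    for i, g in enumerate(groups):
        y = table.loc[table["group"] == g, metric].to_numpy(float)
        x = i + rng.uniform(-0.12, 0.12, size=y.size)
        ax.plot(x, y, "o", ms=3, alpha=0.6)
        ax.errorbar([i], [y.mean()], yerr=[y.std(ddof=1)], fmt="_", ms=18,
                    color="black", capsize=4, lw=1.5)
    ax.set_xticks(range(len(groups)), groups, rotation=30, ha="right")
    ax.set_ylabel(metric)
    fig.tight_layout()
    path = out / f"{metric}_groups.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
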