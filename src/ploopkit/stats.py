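"""Per-class aggregation and comparison of site measurements.

Reproduces the survey-style comparative statistics: records are filtered
by resolution and QC, grouped by ligand class, summarised (n, mean,
median, quartiles, sd, share of short H-bonds), and compared pairwise
with a two-sided Mann–Whitney U test, Benjamini–Hochberg-adjusted across
all pairwise class comparisons in a report. The rank test is a documented
stand-in: the measured distance distributions are visibly non-normal, so
a location test free of normality assumptions is appropriate.
"""

from __future__ import annotations

import itertools
import warnings
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .geometry import HBOND_SHORT_MAX

CLASS_ORDER = ["native", "non_hydrolyzable", "substrate_analog", "ts_analog"]


def _filter(records: pd.DataFrame, resolution_max: Optional[float], require_qc: bool) -> pd.DataFrame:
    df = records.copy()
    if resolution_max is not None and "resolution" in df:
        df = df[df["resolution"].notna() & (df["resolution"] <= resolution_max)]
    if require_qc and "qc_all_pass" in df:
        df = df[df["qc_all_pass"].astype(bool)]
    return df


def aggregate_by_class(
    records: pd.DataFrame,
    metric: str = "wb_k1_distance",
    resolution_max: Optional[float] = 2.5,
    require_qc: bool = True,
) -> pd.DataFrame:
    """Per-ligand-class summaries of a metric, plus an "all" row.

    Records failing the resolution threshold or QC are excluded before
    grouping. Classes absent from the data get n=0 rows with NA moments.
    """
    if metric not in records.columns:
        raise KeyError(f"metric column {metric!r} not in records")
    df = _filter(records, resolution_max, require_qc)

    def _summary(group: pd.DataFrame, label: str) -> dict:
        x = pd.to_numeric(group[metric], errors="coerce").dropna()
        row = {"ligand_class": label, "n": int(len(x))}
        if len(x):
            row.update(
                mean=float(x.mean()), median=float(x.median()),
                q1=float(x.quantile(0.25)), q3=float(x.quantile(0.75)),
                sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                share_short=float((x < HBOND_SHORT_MAX).mean()),
            )
        else:
            row.update(mean=np.nan, median=np.nan, q1=np.nan, q3=np.nan,
                       sd=np.nan, share_short=np.nan)
        return row

    classes = [c for c in CLASS_ORDER if c in set(df.get("ligand_class", []))]
    extra = sorted(set(df.get("ligand_class", [])) - set(CLASS_ORDER))
    rows = [_summary(df[df["ligand_class"] == c], c) for c in classes + extra]
    rows.append(_summary(df, "all"))
    return pd.DataFrame(rows)


def compare_classes(
    records: pd.DataFrame,
    metric: str,
    class_a: str,
    class_b: str,
    resolution_max: Optional[float] = None,
    require_qc: bool = False,
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U between two ligand classes on one metric.

    Returns ``(U, p)``; p is NaN (with a warning) for groups of size < 3.
    """
    df = _filter(records, resolution_max, require_qc)
    xa = pd.to_numeric(df.loc[df["ligand_class"] == class_a, metric], errors="coerce").dropna()
    xb = pd.to_numeric(df.loc[df["ligand_class"] == class_b, metric], errors="coerce").dropna()
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError(f"empty group for {class_a!r} vs {class_b!r}")
    if len(xa) < 3 or len(xb) < 3:
        warnings.warn(f"group size < 3 for {class_a} vs {class_b}; p-value not reported")
        return np.nan, np.nan
    res = sps.mannwhitneyu(xa, xb, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_comparisons(
    records: pd.DataFrame,
    metric: str = "wb_k1_distance",
    resolution_max: Optional[float] = 2.5,
    require_qc: bool = True,
) -> pd.DataFrame:
    """All pairwise class comparisons with Benjamini–Hochberg adjustment."""
    df = _filter(records, resolution_max, require_qc)
    present = [c for c in CLASS_ORDER if (df["ligand_class"] == c).sum() > 0]
    rows = []
    for a, b in itertools.combinations(present, 2):
        try:
            u, p = compare_classes(df, metric, a, b)
        except ValueError:
            continue
        rows.append({"class_a": a, "class_b": b, "U": u, "p": p})
    out = pd.DataFrame(rows, columns=["class_a", "class_b", "U", "p"])
    if len(out):
        valid = out["p"].notna()
        out["p_adj"] = np.nan
        if valid.any():
            out.loc[valid, "p_adj"] = multipletests(out.loc[valid, "p"], method="fdr_bh")[1]
    else:
        out["p_adj"] = []
    return out


def render_report(
    records: pd.DataFrame,
    out_dir: str | Path,
    metric: str = "wb_k1_distance",
    resolution_max: Optional[float] = 2.5,
    require_qc: bool = True,
) -> list[Path]:
    """Write summary TSV, comparison TSV and per-class KDE+box figures."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    summaries = aggregate_by_class(records, metric, resolution_max, require_qc)
    p_sum = out_dir / f"summary_{metric}.tsv"
    summaries.to_csv(p_sum, sep="\t", index=False, na_rep="NA", float_format="%.4f")
    written.append(p_sum)

    comparisons = pairwise_comparisons(records, metric, resolution_max, require_qc)
    p_cmp = out_dir / f"comparisons_{metric}.tsv"
    comparisons.to_csv(p_cmp, sep="\t", index=False, na_rep="NA", float_format="%.4g")
    written.append(p_cmp)

    df = _filter(records, resolution_max, require_qc)
    for cls in [c for c in CLASS_ORDER if (df.get("ligand_class") == c).sum() > 0]:
        x = pd.to_numeric(df.loc[df["ligand_class"] == cls, metric], errors="coerce").dropna()
        if x.empty:
            continue
        fig, ax = plt.subplots(figsize=(4, 3))
        if len(x) > 2 and x.std() > 0:
            grid = np.linspace(x.min() - 0.2, x.max() + 0.2, 200)
            kde = sps.gaussian_kde(x)  # Scott's rule bandwidth
            ax.fill_between(grid, kde(grid), alpha=0.35)
        ax.boxplot(x, positions=[0], orientation="horizontal", widths=0.12,
                   manage_ticks=False)
        ax.plot(x, np.full(len(x), -0.15), "|", ms=10, alpha=0.6)
        ax.axvspan(2.2, 2.7, color="cyan", alpha=0.12)
        ax.axvspan(2.7, 3.2, color="pink", alpha=0.15)
        ax.set_xlabel(f"{metric} (Å)")
        ax.set_title(f"{cls} (n={len(x)})")
        fig.tight_layout()
        p_fig = out_dir / f"{metric}_{cls}.png"
        fig.savefig(p_fig, dpi=120)
        plt.close(fig)
        written.append(p_fig)
    return written
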