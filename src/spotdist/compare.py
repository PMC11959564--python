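"""Responder vs non-responder contrasts and cluster-composition summaries."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class GroupComparison:
    """Per-gene coefficient differences between two response groups.

    ``table`` covers genes modeled in both groups; genes modeled in only
    one group are reported in ``only_r`` / ``only_nr`` rather than silently
    dropped.
    """

    table: pd.DataFrame  # gene, beta_R, beta_NR, delta, outlier, significant_R/NR
    only_r: pd.DataFrame
    only_nr: pd.DataFrame
    k_sd: float
    two_sided: bool


def compare_groups(
    models_r: pd.DataFrame,
    models_nr: pd.DataFrame,
    k_sd: float = 2.0,
    two_sided: bool = True,
) -> GroupComparison:
    """Contrast distance coefficients: delta = beta_NR - beta_R per gene.

    A gene is an outlier when its delta deviates from the mean delta by
    more than ``k_sd`` SD; the default is two-sided (|delta - mean| rule)
    so genes closer to the feature in either group can be flagged, with a
    one-sided (signed upper-tail) alternative behind ``two_sided=False``.
    """
    if models_r.empty or models_nr.empty:
        raise ValueError("both model tables must be nonempty")
    r = models_r.set_index("gene")
    nr = models_nr.set_index("gene")
    shared = r.index.intersection(nr.index)
    if len(shared) < 10:
        raise ValueError(f"need >= 10 shared genes, got {len(shared)}")
    delta = nr.loc[shared, "beta_d"].to_numpy(float) - r.loc[shared, "beta_d"].to_numpy(float)
    sd = delta.std(ddof=1)
    dev = delta - delta.mean()
    if sd == 0:
        outlier = np.zeros(len(delta), dtype=bool)
    elif two_sided:
        outlier = np.abs(dev) > k_sd * sd
    else:
        outlier = dev > k_sd * sd
    table = pd.DataFrame(
        {
            "gene": shared,
            "beta_R": r.loc[shared, "beta_d"].to_numpy(float),
            "beta_NR": nr.loc[shared, "beta_d"].to_numpy(float),
            "delta": delta,
            "outlier": outlier,
            "significant_R": r.loc[shared, "significant"].to_numpy(bool),
            "significant_NR": nr.loc[shared, "significant"].to_numpy(bool),
        }
    ).reset_index(drop=True)
    only_r = r.loc[r.index.difference(nr.index)].reset_index()
    only_nr = nr.loc[nr.index.difference(r.index)].reset_index()
    return GroupComparison(table, only_r, only_nr, k_sd, two_sided)


def composition_by_group(
    annotations: pd.DataFrame,
    cluster_col: str = "cluster",
    section_col: str = "section_id",
    tumor_col: str = "tumor_id",
    group_col: str = "group",
) -> pd.DataFrame:
    """Hierarchical cluster proportions per treatment/response group.

    Spot-level cluster proportions are computed per section, averaged over
    the replicate sections of each tumor, then averaged over the tumors of
    each group, and finally renormalized to sum to one per group.  This is
    deliberately not the pooled-spot proportion: each tumor contributes
    equally regardless of its section count or size.
    """
    needed = [cluster_col, section_col, tumor_col, group_col]
    missing = [c for c in needed if c not in annotations.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if annotations[needed].isna().any().any():
        bad = [c for c in needed if annotations[c].isna().any()]
        raise ValueError(f"missing labels in columns: {bad}")

    clusters = sorted(annotations[cluster_col].unique())
    per_section = (
        annotations.groupby([group_col, tumor_col, section_col])[cluster_col]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=clusters, fill_value=0.0)
    )
    per_tumor = per_section.groupby([group_col, tumor_col]).mean()
    per_group = per_tumor.groupby(group_col).mean()
    per_group = per_group.div(per_group.sum(axis=1), axis=0)
    out = per_group.stack().rename("proportion").reset_index()
    out.columns = ["group", "cluster", "proportion"]
    return out[["cluster", "group", "proportion"]]


def plot_coefficients(comparison: GroupComparison, path: str | Path) -> Path:
    """Scatter of (beta_R, beta_NR) with outlier genes highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = comparison.table
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(t["beta_R"], t["beta_NR"], s=10, c="lightgray", label="other genes")
    out = t[t["outlier"]]
    if not out.empty:
        ax.scatter(out["beta_R"], out["beta_NR"], s=14, c="crimson", label="outliers")
        for _, row in out.iterrows():
            ax.annotate(row["gene"], (row["beta_R"], row["beta_NR"]), fontsize=6)
    lim = float(np.nanmax(np.abs(t[["beta_R", "beta_NR"]].to_numpy()))) * 1.1 or 1.0
    ax.plot([-lim, lim], [-lim, lim], lw=0.5, c="k", ls="--")
    ax.set_xlabel("distance coefficient, responders")
    ax.set_ylabel("distance coefficient, non-responders")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
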