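"""Nonparametric comparison of per-cell summaries across genotype groups.

The unit of observation is one cell's summary statistic over one
observation window.  Two groups are compared with a two-sided
Wilcoxon/Mann–Whitney rank-sum test (exact distribution for small
tie-free samples, normal approximation with tie correction otherwise);
three or more with a Kruskal–Wallis test followed by post-hoc Dunn
pairwise z-tests on the shared ranks, with Benjamini–Hochberg FDR
adjustment across the pairs.  Correction is applied only *within* a
Dunn pairwise set — never across different summary statistics — with a
global-correction helper available but off by default.

``summarize_cohort`` runs the physical and network pipelines over a
collection of cells and returns the long-format per-cell table those
tests (and the boxplot helper) consume.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .io import CellRecord
from .network import network_series
from .netstats import summarize_series
from .physical import physical_summary

logger = logging.getLogger(__name__)

#: Largest combined sample size for which the exact Wilcoxon null is used.
EXACT_WILCOXON_MAX_N = 25


@dataclass
class ComparisonResult:
    """Outcome of a two-group or multi-group nonparametric comparison."""

    statistic_name: str
    groups: dict[str, int]  # label -> n
    test: str  # "wilcoxon_rank_sum" | "kruskal_wallis"
    statistic: float  # U for two groups, H for >= 3
    p_value: float
    method: str  # "exact" | "asymptotic" | "chi2"
    posthoc: Optional[pd.DataFrame] = None  # Dunn pairwise table


def _as_groups(
    groups: Sequence[Sequence[float]] | dict[str, Sequence[float]],
) -> dict[str, np.ndarray]:
    if isinstance(groups, dict):
        items = groups.items()
    else:
        items = ((f"group{i + 1}", g) for i, g in enumerate(groups))
    out = {str(k): np.asarray(v, dtype=float) for k, v in items}
    for label, vals in out.items():
        if vals.size == 0:
            raise ValueError(f"group '{label}' is empty")
        if not np.isfinite(vals).all():
            raise ValueError(f"group '{label}' contains non-finite values")
    return out


def compare_two(
    groups: Sequence[Sequence[float]] | dict[str, Sequence[float]],
    statistic_name: str = "statistic",
) -> ComparisonResult:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) test between two groups.

    The exact null distribution is used when the combined sample size is
    at most 25 and the data are tie-free; otherwise the normal
    approximation with tie correction.  The path taken is recorded in
    ``method``.
    """
    g = _as_groups(groups)
    if len(g) != 2:
        raise ValueError(f"compare_two needs exactly 2 groups, got {len(g)}")
    (la, a), (lb, b) = g.items()
    pooled = np.concatenate([a, b])
    ties = len(np.unique(pooled)) < len(pooled)
    exact = (len(pooled) <= EXACT_WILCOXON_MAX_N) and not ties
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return ComparisonResult(
        statistic_name=statistic_name,
        groups={la: len(a), lb: len(b)},
        test="wilcoxon_rank_sum",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        method="exact" if exact else "asymptotic",
    )


def _dunn_posthoc(g: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn pairwise z-tests on shared ranks, BH-adjusted across pairs.

    z_ij = (R̄_i − R̄_j) / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the
    tie correction T = Σ(t³ − t)/(12(N−1)) over tied groups of size t.
    """
    labels = list(g)
    pooled = np.concatenate([g[l] for l in labels])
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    start = 0
    for l in labels:
        n = len(g[l])
        mean_ranks[l] = ranks[start : start + n].mean()
        sizes[l] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    rows = []
    for la, lb in itertools.combinations(labels, 2):
        se = math.sqrt(var_base * (1.0 / sizes[la] + 1.0 / sizes[lb]))
        z = (mean_ranks[la] - mean_ranks[lb]) / se if se > 0 else float("nan")
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else float("nan")
        rows.append((la, lb, z, p))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "z", "p_raw"])
    table["p_adjusted"] = benjamini_hochberg(table["p_raw"].values)
    return table


def compare_multi(
    groups: Sequence[Sequence[float]] | dict[str, Sequence[float]],
    statistic_name: str = "statistic",
) -> ComparisonResult:
    """Kruskal–Wallis H test across >= 3 groups, with post-hoc Dunn tests.

    The Dunn pairwise p-values are FDR-adjusted (Benjamini–Hochberg)
    within the pairwise set.  For exactly two groups use
    :func:`compare_two`.
    """
    g = _as_groups(groups)
    if len(g) < 3:
        raise ValueError("compare_multi needs >= 3 groups; use compare_two for 2")
    arrays = list(g.values())
    if len(np.unique(np.concatenate(arrays))) == 1:
        # all observations identical: H = 0 and ranks carry no information
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*arrays)
    return ComparisonResult(
        statistic_name=statistic_name,
        groups={l: len(v) for l, v in g.items()},
        test="kruskal_wallis",
        statistic=float(h),
        p_value=float(p),
        method="chi2",
        posthoc=_dunn_posthoc(g),
    )


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg FDR adjustment (via statsmodels)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# cohort summarisation

#: Statistics emitted per cell per checkpoint window.
SUMMARY_STATISTICS = (
    "mean_speed_um_per_frame",
    "median_speed_um_per_frame",
    "mean_intermito_distance_um",
    "mean_coloc_time_frames",
    "mean_degree",
    "efficiency",
    "diameter",
    "mean_betweenness",
    "n_components",
    "n_nodes",
    "n_edges",
)


def summarize_cohort(
    cells: Sequence[CellRecord],
    config: Optional[AnalysisConfig] = None,
) -> pd.DataFrame:
    """Per-cell physical + network summaries, long format.

    For each cell, physical statistics are computed on the full window
    and network statistics at each checkpoint of the accumulating
    encounter network (quarter/half/three-quarter/full windows by
    default; physical rows carry the full-window checkpoint).  Returns
    a tidy table with columns ``cell_id, genotype, checkpoint_frame,
    statistic, value`` — one row per cell per statistic per checkpoint,
    ready for :func:`compare_two` / :func:`compare_multi` and plotting.

    A failure in one cell is logged and flagged (statistic
    ``"analysis_failed"``), not fatal to the cohort.
    """
    if not cells:
        raise ValueError("empty cohort")
    config = config or AnalysisConfig()
    rows: list[tuple] = []
    for cell in cells:
        try:
            checkpoints = config.checkpoints(cell.mito.n_frames)
            full = checkpoints[-1]
            phys = physical_summary(cell.mito, config.encounter_threshold_um)
            for name in (
                "mean_speed_um_per_frame",
                "median_speed_um_per_frame",
                "mean_intermito_distance_um",
                "mean_coloc_time_frames",
            ):
                rows.append((cell.cell_id, cell.genotype, full, name, getattr(phys, name)))
            series = network_series(
                cell.mito, config.encounter_threshold_um, checkpoints
            )
            for summ in summarize_series(series):
                for name in (
                    "mean_degree",
                    "efficiency",
                    "diameter",
                    "mean_betweenness",
                    "n_components",
                    "n_nodes",
                    "n_edges",
                ):
                    rows.append(
                        (
                            cell.cell_id,
                            cell.genotype,
                            summ.window_end_frame,
                            name,
                            float(getattr(summ, name)),
                        )
                    )
        except Exception:  # noqa: BLE001 - per-cell failures must not kill the cohort
            logger.exception("analysis failed for cell %s", cell.cell_id)
            rows.append((cell.cell_id, cell.genotype, -1, "analysis_failed", 1.0))
    return pd.DataFrame(
        rows, columns=["cell_id", "genotype", "checkpoint_frame", "statistic", "value"]
    )


def compare_statistic(
    table: pd.DataFrame,
    statistic: str,
    group_col: str = "genotype",
    checkpoint: Optional[int] = None,
) -> ComparisonResult:
    """Compare one summary statistic across the groups of a cohort table.

    ``checkpoint`` selects a window end frame (default: the latest
    available for that statistic).  Dispatches to :func:`compare_two`
    or :func:`compare_multi` by the number of groups.
    """
    sub = table[table["statistic"] == statistic]
    if sub.empty:
        raise ValueError(f"statistic {statistic!r} not in table")
    cp = checkpoint if checkpoint is not None else sub["checkpoint_frame"].max()
    sub = sub[sub["checkpoint_frame"] == cp].dropna(subset=["value"])
    groups = {str(k): v["value"].values for k, v in sub.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to compare")
    fn = compare_two if len(groups) == 2 else compare_multi
    return fn(groups, statistic_name=statistic)


def plot_statistic(
    table: pd.DataFrame,
    statistic: str,
    group_col: str = "genotype",
    checkpoint: Optional[int] = None,
    ax=None,
):
    """Boxplot (median, quartile box, 1.5×IQR whiskers) with per-cell points.

    Mirrors the standard presentation of per-cell summaries: one jittered
    point per cell over a box-and-whisker per group.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    sub = table[table["statistic"] == statistic]
    cp = checkpoint if checkpoint is not None else sub["checkpoint_frame"].max()
    sub = sub[sub["checkpoint_frame"] == cp].dropna(subset=["value"])
    labels = sorted(sub[group_col].unique())
    data = [sub.loc[sub[group_col] == l, "value"].values for l in labels]
    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(labels) + 1.5, 3.5))
    ax.boxplot(data, tick_labels=labels, whis=1.5, showfliers=False)
    rng = np.random.default_rng(0)
    for i, vals in enumerate(data, start=1):
        ax.plot(i + rng.uniform(-0.12, 0.12, len(vals)), vals, "o", ms=4, alpha=0.6)
    ax.set_ylabel(statistic)
    return ax
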