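"""Multivariate R² evaluation over the scenario x position x fold grid.

The estimation quality metric pools squared errors and target variances over
all evaluated DoFs before forming a single ratio:

    R² = 1 - [sum_i sum_t (est_i(t) - ang_i(t))²]
             / [sum_i sum_t (ang_i(t) - mean_i)²]

with ``mean_i`` the temporal mean of measured angle i. Pooling makes the
index robust when one DoF's excursion is small. Internally R² is a fraction;
report tables print percentages.

Inter-position scores are normalized by their fold-matched intra-position
baseline (training position and fold identical), isolating the arm-position
effect from the baseline accuracy differences between scenarios.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MetricError",
    "multivariate_r2",
    "normalize_to_intra",
    "summarize",
    "GRID_COLUMNS",
]

#: Long-format evaluation grid columns. ``train`` is a position name or
#: "POOLED"; ``kind`` is intra / inter / pooled.
GRID_COLUMNS = ("scenario", "train", "test", "fold", "kind", "r2")


class MetricError(ValueError):
    """The metric is undefined for the given inputs (zero target variance)."""


def multivariate_r2(estimates: np.ndarray, targets: np.ndarray) -> float:
    """Pooled multivariate R² over D DoFs; columns are DoFs, rows time.

    Accepts (N,) or (N, D) arrays. Returns a value <= 1 (can be negative).
    Raises :class:`MetricError` when the pooled target variance is zero.
    """
    est = np.asarray(estimates, dtype=float)
    tgt = np.asarray(targets, dtype=float)
    if est.shape != tgt.shape:
        raise ValueError(f"shape mismatch: estimates {est.shape} vs targets {tgt.shape}")
    if est.ndim == 1:
        est, tgt = est[:, None], tgt[:, None]
    if est.size == 0:
        raise MetricError("empty inputs")
    num = float(np.sum((est - tgt) ** 2))
    den = float(np.sum((tgt - tgt.mean(axis=0, keepdims=True)) ** 2))
    if den <= 0:
        raise MetricError("total target variance is zero; R² undefined")
    return 1.0 - num / den


def normalize_to_intra(grid: pd.DataFrame) -> pd.DataFrame:
    """Add ``r2_norm``: each entry / its fold-matched intra-position baseline.

    Baseline for a row with training position p and fold f is the intra entry
    of (scenario, p, f). Intra rows normalize to 1 by construction. Pooled
    training rows have no single-position baseline and get NaN. A baseline
    <= 0 is flagged with a warning and yields NaN for its dependents.
    """
    grid = grid.copy()
    intra = grid[grid["kind"] == "intra"].set_index(["scenario", "train", "fold"])["r2"]
    if intra.index.has_duplicates:
        raise ValueError("duplicate intra-position entries in grid")

    def baseline(row):
        if row["kind"] == "pooled" or row["train"] == "POOLED":
            return np.nan
        key = (row["scenario"], row["train"], row["fold"])
        if key not in intra.index:
            raise KeyError(f"missing intra-position baseline for {key}")
        b = intra.loc[key]
        if b <= 0:
            warnings.warn(f"non-positive intra baseline for {key}; entry omitted")
            return np.nan
        return b

    grid["r2_norm"] = [
        row["r2"] / b if np.isfinite(b := baseline(row)) else np.nan
        for _, row in grid.iterrows()
    ]
    return grid


def summarize(grid: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Report tables from a (normalized) evaluation grid.

    Returns:
      ``summary`` — per scenario: mean ± sd of intra and inter R² (percent);
      ``relative_matrix`` — per scenario, the 3x3 training x testing position
      matrix of mean normalized R² (diagonal 1 by construction);
      ``pooling`` — per scenario, pooled-training vs matched single-position
      training on the same inter-position test sets, with the one-tailed
      paired t test (pooled > single) across matched (train, test, fold)
      triples.
    """
    if "r2_norm" not in grid.columns:
        grid = normalize_to_intra(grid)
    rows = []
    for scen, g in grid.groupby("scenario", sort=False):
        intra = g.loc[g["kind"] == "intra", "r2"]
        inter = g.loc[g["kind"] == "inter", "r2"]
        rows.append({
            "scenario": scen,
            "intra_mean_pct": 100 * intra.mean(),
            "intra_sd_pct": 100 * intra.std(ddof=1),
            "inter_mean_pct": 100 * inter.mean(),
            "inter_sd_pct": 100 * inter.std(ddof=1),
        })
    summary = pd.DataFrame(rows)

    single = grid[grid["train"] != "POOLED"]
    rel = (
        single.groupby(["scenario", "train", "test"], sort=False)["r2_norm"]
        .mean()
        .reset_index()
        .pivot_table(index=["scenario", "train"], columns="test", values="r2_norm")
        .reset_index()
    )

    pooling_rows = []
    pooled = grid[(grid["train"] == "POOLED")].set_index(["scenario", "test", "fold"])["r2"]
    inter = grid[grid["kind"] == "inter"]
    for scen, g in inter.groupby("scenario", sort=False):
        singles, pooleds = [], []
        for _, row in g.iterrows():
            key = (scen, row["test"], row["fold"])
            if key in pooled.index:
                singles.append(row["r2"])
                pooleds.append(float(pooled.loc[key]))
        if not singles:
            continue
        singles = np.asarray(singles)
        pooleds = np.asarray(pooleds)
        diff = pooleds - singles
        if np.allclose(diff.std(ddof=1), 0):
            # constant difference: t test degenerates; report by sign
            p = 0.0 if diff.mean() > 0 else 1.0
            t = np.inf if diff.mean() > 0 else -np.inf
        else:
            t, p = stats.ttest_rel(pooleds, singles, alternative="greater")
        pooling_rows.append({
            "scenario": scen,
            "n_pairs": len(singles),
            "single_mean_pct": 100 * singles.mean(),
            "pooled_mean_pct": 100 * pooleds.mean(),
            "t": float(t),
            "p_one_tailed": float(p),
        })
    pooling = pd.DataFrame(pooling_rows)
    return {"summary": summary, "relative_matrix": rel, "pooling": pooling}
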