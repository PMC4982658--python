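"""Density-table preprocessing: Box-Cox, z-scoring, outlier removal and
category assignment.

Raw per-adhesion densities are right-skewed; each dataset is variance-
stabilized with the two-parameter Box-Cox transform

    x(λ1, λ2) = ((y + λ2)^λ1 − 1)/λ1      if λ1 ≠ 0
    x(λ1, λ2) = log(y + λ2)               if λ1 = 0

where λ1 is the mean of the per-component maximum-likelihood estimates
within the dataset.  Transformed columns are z-scored and outliers removed
with Tukey fences widened to 2·IQR.  Adhesions are then categorized by
area, eccentricity and mean normalized internal density using multilevel
Otsu thresholding on values pooled across all datasets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import (
    AREA_CATEGORIES,
    DensityTable,
    PHOSPHO_COMPONENTS,
    TERNARY_CATEGORIES,
)

logger = logging.getLogger(__name__)

#: λ1 maximum-likelihood search grid (bounds and step).
LAMBDA_GRID = (-2.0, 2.0, 0.01)
#: Tukey fence multiplier (2·IQR, wider than the classic 1.5).
TUKEY_K = 2.0
#: Histogram resolution for multilevel Otsu.
OTSU_BINS = 256

#: Thresholds reported for the study's own (unreleased) datasets, kept as
#: reference constants only — they are data-dependent and not reproduced.
REFERENCE_AREA_THRESHOLDS_UM2 = (2.71, 6.17)
REFERENCE_ECCENTRICITY_THRESHOLDS = (0.86, 0.92)
REFERENCE_DENSITY_THRESHOLDS = (-0.42, 0.282)


# ---------------------------------------------------------------------------
# Box-Cox
# ---------------------------------------------------------------------------

def boxcox(y, lambda1: float, lambda2: float = 0.0):
    """Two-parameter Box-Cox transform (scalar or array).

    Raises
    ------
    ValueError
        If any ``y + λ2`` is not positive.
    """
    y = np.asarray(y, dtype=float)
    shifted = y + lambda2
    if np.any(shifted <= 0):
        raise ValueError("Box-Cox requires y + lambda2 > 0")
    if lambda1 == 0:
        out = np.log(shifted)
    else:
        # expm1 keeps ((y+l2)^l1 - 1)/l1 accurate as l1 -> 0
        out = np.expm1(lambda1 * np.log(shifted)) / lambda1
    return out if out.ndim else float(out)


def _default_lambda2(values: np.ndarray) -> float:
    """λ2 = 0 when all values are positive, else a shift making them so."""
    vmin = float(np.min(values))
    if vmin > 0:
        return 0.0
    spread = float(np.max(values) - vmin)
    return -vmin + max(1e-6, 1e-3 * spread)


def estimate_lambda_column(
    values, lambda2: float | None = None, grid=LAMBDA_GRID
) -> float:
    """ML λ1 for one component by profile log-likelihood over a bounded grid."""
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValueError("lambda estimation needs at least 10 values")
    if lambda2 is None:
        lambda2 = _default_lambda2(v)
    shifted = v + lambda2
    if np.any(shifted <= 0):
        raise ValueError("Box-Cox requires y + lambda2 > 0")
    lo, hi, step = grid
    lambdas = np.arange(lo, hi + step / 2, step)
    # profile log-likelihood: (λ−1)·Σ log y − n/2 · log σ²_mle(x(λ)),
    # evaluated on the whole grid at once
    n = shifted.size
    logy = np.log(shifted)
    sum_logy = logy.sum()
    with np.errstate(over="ignore", invalid="ignore"):
        X = np.where(
            lambdas[:, None] == 0,
            logy[None, :],
            (np.exp(lambdas[:, None] * logy[None, :]) - 1.0) / np.where(lambdas[:, None] == 0, 1.0, lambdas[:, None]),
        )
        var = X.var(axis=1, ddof=0)
        ll = (lambdas - 1.0) * sum_logy - n / 2.0 * np.log(var)
    ll[~np.isfinite(ll)] = -np.inf
    return float(lambdas[np.argmax(ll)])


def estimate_lambda(table: DensityTable, grid=LAMBDA_GRID) -> tuple[float, dict[str, float]]:
    """Dataset λ1: the mean of per-component maximum-likelihood estimates.

    Returns ``(dataset_lambda1, per_component_lambdas)``.
    """
    per_comp = {
        c: estimate_lambda_column(table.raw[c].to_numpy(), grid=grid)
        for c in table.components
    }
    return float(np.mean(list(per_comp.values()))), per_comp


# ---------------------------------------------------------------------------
# z-scoring and Tukey outlier removal
# ---------------------------------------------------------------------------

def zscore_and_tukey(values, k: float = TUKEY_K) -> tuple[np.ndarray, np.ndarray]:
    """Z-score a vector and flag Tukey outliers in a single pass.

    Fences are ``[Q1 − k·IQR, Q3 + k·IQR]`` computed on the full z vector
    (quartiles by linear interpolation of order statistics); entries outside
    are flagged.  Returns ``(z, keep_mask)``.

    Raises
    ------
    ValueError
        For constant input (sd = 0).
    """
    v = np.asarray(values, dtype=float)
    sd = v.std(ddof=1) if v.size > 1 else 0.0
    if sd == 0:
        raise ValueError("cannot z-score constant input")
    z = (v - v.mean()) / sd
    q1, q3 = np.percentile(z, [25, 75], method="linear")
    iqr = q3 - q1
    keep = (z >= q1 - k * iqr) & (z <= q3 + k * iqr)
    return z, keep


# ---------------------------------------------------------------------------
# multilevel Otsu
# ---------------------------------------------------------------------------

def otsu_multilevel(values, n_classes: int = 3, nbins: int = OTSU_BINS) -> np.ndarray:
    """Multilevel Otsu thresholds maximizing between-class variance.

    Values are binned into ``nbins`` histogram bins; all combinations of
    ``n_classes − 1`` cut bins are searched exhaustively and the thresholds
    (bin centers) maximizing the between-class variance of the binned data
    are returned.  Ties — which arise whenever a cut may move freely across
    empty bins between separated modes — resolve to the element-wise median
    of the tied optima, i.e. the middle of each empty gap.

    Raises
    ------
    ValueError
        If the input has fewer distinct values than classes.
    """
    v = np.asarray(values, dtype=float).ravel()
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if np.unique(v).size < n_classes:
        raise ValueError("fewer distinct values than classes")
    hist, edges = np.histogram(v, bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    prob = hist / hist.sum()
    # between-class variance via cumulative moments over candidate cuts
    w = np.concatenate([[0.0], np.cumsum(prob)])          # w[i] = P(bin < i)
    mu = np.concatenate([[0.0], np.cumsum(prob * centers)])  # first moment
    best = -np.inf
    tied: list[tuple[int, ...]] = []
    for cuts in combinations(range(1, nbins), n_classes - 1):
        bounds = (0, *cuts, nbins)
        var_between = 0.0
        ok = True
        for a, b in zip(bounds[:-1], bounds[1:]):
            wk = w[b] - w[a]
            if wk <= 0:
                ok = False
                break
            mk = (mu[b] - mu[a]) / wk
            var_between += wk * mk * mk
        if not ok:
            continue
        if var_between > best + 1e-12 * max(1.0, abs(best)):
            best, tied = var_between, [cuts]
        elif var_between >= best - 1e-12 * max(1.0, abs(best)):
            tied.append(cuts)
    if not tied:
        raise ValueError("no valid threshold placement (degenerate histogram)")
    cuts = tuple(
        int(np.median([t[i] for t in tied])) for i in range(n_classes - 1)
    )
    # threshold = center of the last bin of the lower class, matching the
    # convention that values > threshold fall in the upper class
    return centers[np.array(cuts) - 1]


def categorize(values, thresholds) -> np.ndarray:
    """Integer class per value given ascending thresholds (value > t_k)."""
    return np.searchsorted(np.asarray(thresholds, dtype=float), np.asarray(values, dtype=float), side="right")


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class PreprocessResult:
    """Preprocessed tables plus the fitted transform/threshold state."""

    tables: list[DensityTable]
    lambda1: dict[str, float]
    per_component_lambda: dict[str, dict[str, float]]
    area_thresholds: np.ndarray | None = None
    ecc_thresholds: np.ndarray | None = None
    density_thresholds: np.ndarray | None = None
    n_removed: dict[str, int] = field(default_factory=dict)


def transform_table(table: DensityTable, grid=LAMBDA_GRID, tukey_k: float = TUKEY_K) -> tuple[DensityTable, dict]:
    """Box-Cox transform, z-score and Tukey-filter one dataset.

    A single dataset-wide λ1 (mean of per-component ML estimates) is applied
    to every component; per-component λ2 follows the positivity rule.  Rows
    flagged as outliers in any component are dropped (the matrix stays
    rectangular).  The fitted state is stored in ``table.transform``.
    """
    lam1, per_comp = estimate_lambda(table, grid=grid)
    data = table.data.copy()
    keep = np.ones(len(data), dtype=bool)
    state: dict[str, dict[str, float]] = {}
    for c in table.components:
        raw = data[c].to_numpy(dtype=float)
        lam2 = _default_lambda2(raw)
        x = boxcox(raw, lam1, lam2)
        z, keep_c = zscore_and_tukey(x, k=tukey_k)
        data[f"z_{c}"] = z
        keep &= keep_c
        state[c] = {
            "lambda1": lam1,
            "lambda2": lam2,
            "mean": float(np.mean(x)),
            "sd": float(np.std(x, ddof=1)),
            "lambda1_component": per_comp[c],
        }
    out = DensityTable(
        data=data.loc[keep].reset_index(drop=True),
        components=table.components,
        dataset_id=table.dataset_id,
        repeat=table.repeat,
        labeling_order=table.labeling_order,
        transform=state,
    )
    info = {"lambda1": lam1, "per_component": per_comp, "n_removed": int((~keep).sum())}
    return out, info


def mean_normalized_density(
    tables: Sequence[DensityTable],
    exclude: Sequence[str] = PHOSPHO_COMPONENTS,
    n_classes: int = 3,
) -> tuple[list[DensityTable], np.ndarray]:
    """Per-adhesion mean normalized density score and low/mid/high category.

    Each protein component (the phosphosite channels are excluded) is
    z-scored per dataset on raw densities, the z-scores are averaged per
    adhesion, and the pooled scores across all datasets are categorized by
    multilevel Otsu.  Returns the annotated tables and the thresholds.
    """
    proteins = [c for c in tables[0].components if c not in exclude]
    missing = [c for c in proteins if c not in tables[0].data.columns]
    if missing:
        raise KeyError(f"missing protein columns: {missing}")
    scored: list[pd.Series] = []
    for t in tables:
        zs = []
        for c in proteins:
            v = t.raw[c].to_numpy(dtype=float)
            sd = v.std(ddof=1)
            if sd == 0:
                raise ValueError(f"constant component {c!r} in {t.dataset_id}")
            zs.append((v - v.mean()) / sd)
        scored.append(pd.Series(np.mean(zs, axis=0)))
    pooled = np.concatenate([s.to_numpy() for s in scored])
    thresholds = otsu_multilevel(pooled, n_classes=n_classes)
    out = []
    for t, s in zip(tables, scored):
        data = t.data.copy()
        data["density_score"] = s.to_numpy()
        data["density_cat"] = np.array(TERNARY_CATEGORIES)[categorize(s, thresholds)]
        out.append(
            DensityTable(
                data=data, components=t.components, dataset_id=t.dataset_id,
                repeat=t.repeat, labeling_order=t.labeling_order,
                transform=dict(t.transform),
            )
        )
    return out, thresholds


def _categorize_pooled(
    tables: Sequence[DensityTable], column: str, out_column: str, labels: Sequence[str]
) -> tuple[list[DensityTable], np.ndarray]:
    pooled = np.concatenate([t.data[column].to_numpy(dtype=float) for t in tables])
    thresholds = otsu_multilevel(pooled, n_classes=len(labels))
    out = []
    for t in tables:
        data = t.data.copy()
        data[out_column] = np.array(labels)[categorize(data[column], thresholds)]
        out.append(
            DensityTable(
                data=data, components=t.components, dataset_id=t.dataset_id,
                repeat=t.repeat, labeling_order=t.labeling_order,
                transform=dict(t.transform),
            )
        )
    return out, thresholds


def preprocess_study(
    tables: Sequence[DensityTable],
    grid=LAMBDA_GRID,
    tukey_k: float = TUKEY_K,
    categorize_geometry: bool = True,
) -> PreprocessResult:
    """Run the full preprocessing chain on all datasets of a study.

    Per dataset: Box-Cox (dataset-mean λ1) → z-score → Tukey removal.
    Across datasets: pooled Otsu categorization of area, eccentricity and
    mean normalized density (when the geometry columns are present).
    """
    transformed, lam1, per_comp, removed = [], {}, {}, {}
    for t in tables:
        tt, info = transform_table(t, grid=grid, tukey_k=tukey_k)
        transformed.append(tt)
        lam1[t.dataset_id] = info["lambda1"]
        per_comp[t.dataset_id] = info["per_component"]
        removed[t.dataset_id] = info["n_removed"]
        logger.info(
            "dataset %s: lambda1=%.3f, removed %d outlier rows",
            t.dataset_id, info["lambda1"], info["n_removed"],
        )
    result = PreprocessResult(
        tables=transformed, lambda1=lam1, per_component_lambda=per_comp, n_removed=removed
    )
    if categorize_geometry and "area" in transformed[0].data.columns:
        result.tables, result.area_thresholds = _categorize_pooled(
            result.tables, "area", "area_cat", AREA_CATEGORIES
        )
        result.tables, result.ecc_thresholds = _categorize_pooled(
            result.tables, "eccentricity", "ecc_cat", TERNARY_CATEGORIES
        )
    result.tables, result.density_thresholds = mean_normalized_density(result.tables)
    return result
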