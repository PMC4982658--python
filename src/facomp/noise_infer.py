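"""Inferring changes in compositional noise between focal-adhesion categories.

Diversity (a common factor scaling all component levels in an adhesion) and
binding noise (independent stochastic fluctuations per component) both
inflate the coefficient of variation (CV) of component densities across
adhesions, but they move the pairwise correlations in opposite directions:
diversity strengthens them, noise weakens them.  Comparing two adhesion
categories through the joint signs of

* ``Δlog(CV₁,CV₂)`` — per-component ``log(CV₂/CV₁)``, averaged over datasets
  then components, and
* ``Δ(r₁²,r₂²)`` — per-pair ``r₂² − r₁²``, averaged over datasets then pairs,

therefore disentangles the two sources:

======================  =======================
(sign ΔlogCV, sign Δr²)  verdict
======================  =======================
(−, +)                   noise lower in category 2
(+, −)                   noise lower in category 1
(+, +)                   diversity higher in category 2
(−, −)                   diversity higher in category 1
======================  =======================

A mean whose absolute value is smaller than its standard error of the mean
is treated as sign-insignificant and the comparison as inconclusive.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .tables import DensityTable

logger = logging.getLogger(__name__)

#: Datasets contribute to a comparison only if both compared groups hold at
#: least this many adhesions.
MIN_ADHESIONS_PER_GROUP = 5


class Verdict(str, Enum):
    """Outcome of a two-category noise/diversity comparison."""

    NOISE_LOWER_IN_1 = "noise_lower_in_1"
    NOISE_LOWER_IN_2 = "noise_lower_in_2"
    DIVERSITY_HIGHER_IN_1 = "diversity_higher_in_1"
    DIVERSITY_HIGHER_IN_2 = "diversity_higher_in_2"
    INCONCLUSIVE = "inconclusive"

    def swapped(self) -> "Verdict":
        """The verdict obtained when the two categories are exchanged."""
        swap = {
            Verdict.NOISE_LOWER_IN_1: Verdict.NOISE_LOWER_IN_2,
            Verdict.NOISE_LOWER_IN_2: Verdict.NOISE_LOWER_IN_1,
            Verdict.DIVERSITY_HIGHER_IN_1: Verdict.DIVERSITY_HIGHER_IN_2,
            Verdict.DIVERSITY_HIGHER_IN_2: Verdict.DIVERSITY_HIGHER_IN_1,
            Verdict.INCONCLUSIVE: Verdict.INCONCLUSIVE,
        }
        return swap[self]


# ---------------------------------------------------------------------------
# elementary statistics
# ---------------------------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """Sample standard deviation divided by the mean.

    Raises
    ------
    ValueError
        If fewer than two values are supplied or the mean is not positive
        (a CV of a non-positive-mean sample is meaningless here: densities
        are nonnegative).
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("CV requires at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"CV requires a positive mean, got {mean}")
    return float(v.std(ddof=1) / mean)


def fano_factor(values) -> float:
    """Sample variance divided by the mean (dispersion index)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("Fano factor requires at least two values")
    mean = v.mean()
    if mean <= 0:
        raise ValueError(f"Fano factor requires a positive mean, got {mean}")
    return float(v.var(ddof=1) / mean)


def pairwise_r2(
    table: DensityTable | pd.DataFrame, use_zscores: bool | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson ``r`` and ``r²`` matrices over all component pairs.

    By default the correlation is computed on Box-Cox z-scores when the
    table carries them (scatter linearity is asserted on transformed data)
    and on raw densities otherwise.  Pairs involving a zero-variance column
    are flagged as NaN.

    Returns
    -------
    (r, r2)
        Symmetric DataFrames indexed by component, unit diagonal.
    """
    if isinstance(table, DensityTable):
        if use_zscores is None:
            use_zscores = table.has_zscores
        frame = table.zscores if use_zscores else table.raw
    else:
        frame = table
    X = frame.to_numpy(dtype=float)
    if X.shape[0] < 3:
        raise ValueError("pairwise r2 requires at least 3 adhesions")
    sd = X.std(axis=0, ddof=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        r = np.corrcoef(X, rowvar=False)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance columns flagged undefined: %s",
            list(frame.columns[degenerate]),
        )
        r[degenerate, :] = np.nan
        r[:, degenerate] = np.nan
    np.fill_diagonal(r, 1.0)
    r_df = pd.DataFrame(r, index=frame.columns, columns=frame.columns)
    return r_df, r_df**2


# ---------------------------------------------------------------------------
# the Δ statistics
# ---------------------------------------------------------------------------

@dataclass
class DeltaMeasure:
    """A dataset-then-item averaged difference with its SEM.

    ``per_dataset`` holds the raw matrix (rows = qualifying datasets,
    columns = components or component pairs).
    """

    mean: float
    sem: float
    per_dataset: pd.DataFrame
    n_datasets: int

    def as_tuple(self) -> tuple[float, float]:
        return self.mean, self.sem


def _aggregate(per_dataset: pd.DataFrame) -> DeltaMeasure:
    """Average over datasets, then items; SEM across datasets.

    The headline SEM is computed between dataset means (matching error bars
    drawn between datasets).  With a single qualifying dataset the spread
    between items within that dataset is used instead.
    """
    if per_dataset.empty:
        raise ValueError("no dataset qualifies for the comparison")
    item_means = per_dataset.mean(axis=0)  # mean over datasets, per item
    mean = float(item_means.mean())
    n_datasets = len(per_dataset)
    if n_datasets >= 2:
        dataset_means = per_dataset.mean(axis=1)
        sem = float(dataset_means.std(ddof=1) / np.sqrt(n_datasets))
    else:
        vals = per_dataset.iloc[0].dropna().to_numpy()
        sem = float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
    return DeltaMeasure(mean=mean, sem=sem, per_dataset=per_dataset, n_datasets=n_datasets)


def _paired_datasets(
    cat1: Sequence[DensityTable], cat2: Sequence[DensityTable], min_per_group: int
) -> list[tuple[str, DensityTable, DensityTable]]:
    if len(cat1) != len(cat2):
        raise ValueError("category slices must pair up dataset by dataset")
    kept = []
    for t1, t2 in zip(cat1, cat2):
        if t1.dataset_id != t2.dataset_id:
            raise ValueError(
                f"dataset mismatch: {t1.dataset_id!r} vs {t2.dataset_id!r}"
            )
        if len(t1) >= min_per_group and len(t2) >= min_per_group:
            kept.append((t1.dataset_id, t1, t2))
        else:
            logger.info(
                "dataset %s dropped (<%d adhesions in a group: %d vs %d)",
                t1.dataset_id, min_per_group, len(t1), len(t2),
            )
    if not kept:
        raise ValueError(
            f"no dataset has at least {min_per_group} adhesions in both groups"
        )
    return kept


def _per_component_dispersion(
    cat1: Sequence[DensityTable],
    cat2: Sequence[DensityTable],
    min_per_group: int,
    measure,
) -> DeltaMeasure:
    rows = {}
    for ds, t1, t2 in _paired_datasets(cat1, cat2, min_per_group):
        rows[ds] = {
            c: np.log(measure(t2.raw[c]) / measure(t1.raw[c]))
            for c in t1.components
        }
    return _aggregate(pd.DataFrame.from_dict(rows, orient="index"))


def delta_log_cv(
    cat1: Sequence[DensityTable],
    cat2: Sequence[DensityTable],
    min_per_group: int = MIN_ADHESIONS_PER_GROUP,
) -> DeltaMeasure:
    """``Δlog(CV₁,CV₂)``: per-component ``log(CV₂/CV₁)`` on raw densities,
    averaged over qualifying datasets then components.

    Datasets with fewer than ``min_per_group`` adhesions in either category
    are dropped.  CVs are taken on raw densities (of rows surviving outlier
    removal): z-scored columns have zero mean, so their CV is undefined.
    """
    return _per_component_dispersion(cat1, cat2, min_per_group, coefficient_of_variation)


def delta_fano(
    cat1: Sequence[DensityTable],
    cat2: Sequence[DensityTable],
    min_per_group: int = MIN_ADHESIONS_PER_GROUP,
) -> DeltaMeasure:
    """Fano-factor variant of :func:`delta_log_cv`: ``log(F₂/F₁)`` with
    ``F = variance/mean``.  Unlike the CV, the Fano factor is not scale-free,
    so it responds differently when fluctuation amplitude is coupled to the
    mean; in most comparisons its change shares the sign of ``Δlog CV``."""
    return _per_component_dispersion(cat1, cat2, min_per_group, fano_factor)


def delta_r2(
    cat1: Sequence[DensityTable],
    cat2: Sequence[DensityTable],
    min_per_group: int = MIN_ADHESIONS_PER_GROUP,
    use_zscores: bool | None = None,
) -> DeltaMeasure:
    """``Δ(r₁²,r₂²)``: per-pair ``r₂² − r₁²`` averaged over qualifying
    datasets then component pairs.  Pairs undefined in either category
    (zero variance) are dropped from the pair average with a warning."""
    rows = {}
    for ds, t1, t2 in _paired_datasets(cat1, cat2, min_per_group):
        _, r2_1 = pairwise_r2(t1, use_zscores=use_zscores)
        _, r2_2 = pairwise_r2(t2, use_zscores=use_zscores)
        row = {}
        for a, b in combinations(t1.components, 2):
            v1, v2 = r2_1.loc[a, b], r2_2.loc[a, b]
            if np.isnan(v1) or np.isnan(v2):
                logger.warning("pair (%s, %s) undefined in dataset %s; dropped", a, b, ds)
                continue
            row[(a, b)] = v2 - v1
        rows[ds] = row
    return _aggregate(pd.DataFrame.from_dict(rows, orient="index"))


def infer_change(
    dlogcv: tuple[float, float] | DeltaMeasure,
    dr2: tuple[float, float] | DeltaMeasure,
) -> Verdict:
    """Map the joint signs of ``Δlog CV`` and ``Δr²`` to a verdict.

    Either mean whose absolute value is below its SEM (or exactly zero) has
    an insignificant sign, making the comparison inconclusive.
    """
    m_cv, s_cv = dlogcv.as_tuple() if isinstance(dlogcv, DeltaMeasure) else dlogcv
    m_r2, s_r2 = dr2.as_tuple() if isinstance(dr2, DeltaMeasure) else dr2
    if s_cv < 0 or s_r2 < 0:
        raise ValueError("SEMs must be nonnegative")
    if m_cv == 0 or abs(m_cv) < s_cv or m_r2 == 0 or abs(m_r2) < s_r2:
        return Verdict.INCONCLUSIVE
    if m_cv < 0 and m_r2 > 0:
        return Verdict.NOISE_LOWER_IN_2
    if m_cv > 0 and m_r2 < 0:
        return Verdict.NOISE_LOWER_IN_1
    if m_cv > 0 and m_r2 > 0:
        return Verdict.DIVERSITY_HIGHER_IN_2
    return Verdict.DIVERSITY_HIGHER_IN_1


# ---------------------------------------------------------------------------
# category comparisons on full study tables
# ---------------------------------------------------------------------------

@dataclass
class DeltaStats:
    """A complete two-category comparison along one categorization axis."""

    axis: str
    category1: str
    category2: str
    dlogcv: DeltaMeasure
    dr2: DeltaMeasure
    verdict: Verdict
    fixed: tuple[str, str] | None = None
    extras: dict = field(default_factory=dict)

    @property
    def n_datasets(self) -> int:
        return min(self.dlogcv.n_datasets, self.dr2.n_datasets)

    def summary(self) -> dict:
        out = {
            "axis": self.axis,
            "category1": self.category1,
            "category2": self.category2,
            "delta_log_cv": self.dlogcv.mean,
            "delta_log_cv_sem": self.dlogcv.sem,
            "delta_r2": self.dr2.mean,
            "delta_r2_sem": self.dr2.sem,
            "verdict": self.verdict.value,
            "n_datasets": self.n_datasets,
        }
        if self.fixed is not None:
            out["fixed_axis"], out["fixed_value"] = self.fixed
        return out


def compare_categories(
    tables: Sequence[DensityTable],
    axis: str,
    value1: str,
    value2: str,
    fix: tuple[str, str] | None = None,
    min_per_group: int = MIN_ADHESIONS_PER_GROUP,
) -> DeltaStats:
    """Compare two values of a categorization axis across all datasets.

    Parameters
    ----------
    axis
        A category column of the tables (``area_cat``, ``age``, ``ecc_cat``,
        ``density_cat``, ``dynamics``).
    fix
        Optional ``(column, value)`` restricting the comparison to one
        sub-category of another axis (two-way sub-categorization).
    """
    base = tables
    if fix is not None:
        col, val = fix
        base = [t.category_slice(col, val) for t in tables]
    cat1 = [t.category_slice(axis, value1) for t in base]
    cat2 = [t.category_slice(axis, value2) for t in base]
    dcv = delta_log_cv(cat1, cat2, min_per_group)
    dr2_ = delta_r2(cat1, cat2, min_per_group)
    return DeltaStats(
        axis=axis,
        category1=value1,
        category2=value2,
        dlogcv=dcv,
        dr2=dr2_,
        verdict=infer_change(dcv, dr2_),
        fixed=fix,
    )


def equal_pixel_control(
    datasets: Sequence[tuple],
    axis: str,
    value1: str,
    value2: str,
    mode: str = "mean",
    n_fixed: int = 10,
    seed: int = 0,
    pixel_size: float = 1.0,
    min_per_group: int = MIN_ADHESIONS_PER_GROUP,
) -> DeltaStats:
    """Re-derive densities from subsampled pixels, then rerun the inference.

    Controls that a verdict along the area axis is not an artifact of bigger
    adhesions contributing more pixels: densities are recomputed using only
    a random subset of each adhesion's pixels such that either the *mean*
    sampled pixel count is equal across area categories (``mode="mean"``)
    or every adhesion contributes the same fixed number of pixels
    (``mode="fixed"``, default 10).  Adhesions smaller than the requested
    sample keep all their pixels.

    Parameters
    ----------
    datasets
        One ``(label_map, channel_images, table)`` triple per dataset, where
        ``table`` is the measured :class:`DensityTable` carrying category
        columns and an ``adhesion_id`` column equal to the region label.
    """
    from .imaging import measure_regions  # local import: imaging is optional here

    rng = np.random.default_rng(seed)
    resampled: list[DensityTable] = []
    for labels, channels, table in datasets:
        targets = _pixel_sample_targets(table, axis, mode, n_fixed)
        measured = measure_regions(
            labels, channels, components=table.components,
            pixel_size=pixel_size, sample_pixels=targets, rng=rng,
        )
        merged = table.data.drop(columns=list(table.components)).merge(
            measured.data[["adhesion_id", *table.components]],
            on="adhesion_id", how="inner",
        )
        resampled.append(
            DensityTable(
                data=merged, components=table.components,
                dataset_id=table.dataset_id, repeat=table.repeat,
                labeling_order=table.labeling_order,
            )
        )
    stats = compare_categories(resampled, axis, value1, value2, min_per_group=min_per_group)
    stats.extras["pixel_sampling_mode"] = mode
    return stats


def _pixel_sample_targets(
    table: DensityTable, axis: str, mode: str, n_fixed: int
) -> dict[int, int]:
    """Per-label pixel sample sizes equalizing sampling across categories."""
    df = table.data
    if mode == "fixed":
        return {int(l): n_fixed for l in df["adhesion_id"]}
    if mode != "mean":
        raise ValueError(f"unknown mode {mode!r}")
    cat_means = df.groupby(axis)["pixel_count"].mean()
    target = float(cat_means.min())
    fractions = (target / cat_means).clip(upper=1.0)
    return {
        int(row.adhesion_id): max(1, int(round(fractions[getattr(row, axis)] * row.pixel_count)))
        for row in df.itertuples()
    }
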