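"""Epigenetic age acceleration and its descriptive/test statistics.

Age acceleration is the residual of DNAm age from an ordinary least squares
regression of DNAm age on chronological age, fitted in a *reference* sample
set (by convention all non-cerebellar samples).  A negative residual means a
sample is epigenetically younger than its chronological age predicts.  The
module also provides the group statistics used to summarize acceleration
across tissues: Kruskal–Wallis comparisons within age bands, Pearson
correlations, per-tissue mean ± SE summaries (replicates collapsed to the
subject level first) and replicate concordance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgeModelFit",
    "DEFAULT_AGE_BANDS",
    "fit_reference_model",
    "compute_acceleration",
    "group_compare_kruskal",
    "pearson_cor",
    "tissue_summary",
    "replicate_concordance",
]

#: Default age bands (years), closed on the left: [lo, hi)
DEFAULT_AGE_BANDS: list[tuple[float, float]] = [
    (0.0, 60.0),
    (60.0, 80.0),
    (80.0, 100.0),
    (100.0, float("inf")),
]


@dataclass
class AgeModelFit:
    """OLS fit of DNAm age on chronological age over reference samples."""

    intercept: float
    slope: float
    reference_sample_ids: list[str]
    residual_sd: float

    def predict(self, age) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(age, dtype=float)


def fit_reference_model(
    table: pd.DataFrame,
    reference_tissues: list[str] | None = None,
    exclude_tissues: list[str] | None = None,
) -> AgeModelFit:
    """Fit the reference regression of DNAm age on chronological age.

    ``table`` needs columns sample_id, tissue, age, dnam_age.  The reference
    set is either an explicit tissue whitelist or everything outside
    ``exclude_tissues`` (the typical call excludes the cerebellum).
    Requires >= 3 reference samples with >= 2 distinct ages.
    """
    ref = table
    if reference_tissues is not None:
        ref = ref[ref.tissue.isin(reference_tissues)]
    if exclude_tissues is not None:
        ref = ref[~ref.tissue.isin(exclude_tissues)]
    if len(ref) < 3:
        raise ValueError(f"need >= 3 reference samples, got {len(ref)}")
    x = ref.age.to_numpy(dtype=float)
    y = ref.dnam_age.to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("degenerate design: all reference ages equal")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (intercept + slope * x)
    return AgeModelFit(
        intercept=float(intercept),
        slope=float(slope),
        reference_sample_ids=ref.sample_id.to_list(),
        residual_sd=float(np.sqrt(np.mean(resid**2))),
    )


def compute_acceleration(fit: AgeModelFit, table: pd.DataFrame) -> pd.DataFrame:
    """Residual age acceleration for every sample (reference or not)."""
    out = table.copy()
    out["acceleration"] = out.dnam_age.to_numpy(dtype=float) - fit.predict(out.age)
    return out


def _subject_level(accel: pd.DataFrame) -> pd.DataFrame:
    """Average replicate samples to one value per (subject, tissue).

    Collapsing before group tests avoids pseudo-replication: technical
    replicates are not independent observations.
    """
    return (
        accel.groupby(["subject_id", "tissue"], sort=False, as_index=False)
        .agg(age=("age", "mean"), dnam_age=("dnam_age", "mean"),
             acceleration=("acceleration", "mean"))
    )


def group_compare_kruskal(
    accel: pd.DataFrame,
    group_col: str = "tissue",
    age_band: tuple[float, float] | None = None,
    collapse_replicates: bool = True,
):
    """Kruskal–Wallis comparison of acceleration across groups.

    Mid-ranks with tie correction (chi-square reference with k-1 df).  With
    all observations identical the statistic is H=0 and p is reported as 1
    with ``degenerate=True``.  ``age_band`` filters samples to
    ``lo <= age < hi`` first.

    Returns ``(H, p, degenerate)``.
    """
    data = _subject_level(accel) if collapse_replicates else accel
    if age_band is not None:
        lo, hi = age_band
        data = data[(data.age >= lo) & (data.age < hi)]
    groups = [g.acceleration.to_numpy(dtype=float)
              for _, g in data.groupby(group_col, sort=True)]
    groups = [g for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0, True
    h, p = stats.kruskal(*groups)
    return float(h), float(p), False


def pearson_cor(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with a two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def tissue_summary(
    accel: pd.DataFrame,
    age_bands: list[tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Per-tissue, per-age-band mean acceleration, standard error and n.

    Replicates are first averaged to subject level; SE = sd/sqrt(n) with
    ``ddof=1``.  A band/tissue cell with a single subject reports SE = 0 and
    ``se_undefined=True``.
    """
    bands = DEFAULT_AGE_BANDS if age_bands is None else age_bands
    data = _subject_level(accel)
    rows = []
    for lo, hi in bands:
        band = data[(data.age >= lo) & (data.age < hi)]
        for tissue, g in band.groupby("tissue", sort=True):
            n = len(g)
            mean = float(g.acceleration.mean())
            if n > 1:
                se = float(g.acceleration.std(ddof=1) / np.sqrt(n))
                undef = False
            else:
                se, undef = 0.0, True
            rows.append((f"[{lo:g},{hi:g})", tissue, n, mean, se, undef))
    return pd.DataFrame(
        rows, columns=["age_band", "tissue", "n", "mean", "se", "se_undefined"]
    )


def replicate_concordance(accel: pd.DataFrame) -> tuple[float, int]:
    """Pearson correlation of DNAm age between replicate measurements.

    Replicates are paired within (subject, tissue) by sorted replicate
    index; more than two replicates contribute all unordered pairs (lower
    index first).  Returns ``(r, n_pairs)``; requires >= 3 pairs.
    """
    first, second = [], []
    for _, g in accel.groupby(["subject_id", "tissue"], sort=False):
        if len(g) < 2:
            continue
        g = g.sort_values("replicate")
        ages = g.dnam_age.to_numpy(dtype=float)
        for i, j in itertools.combinations(range(len(ages)), 2):
            first.append(ages[i])
            second.append(ages[j])
    if len(first) < 3:
        raise ValueError("need >= 3 replicate pairs")
    r, _ = pearson_cor(first, second)
    return r, len(first)
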