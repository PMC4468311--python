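"""Epigenetic clock core: beta values, gold-standard normalization, DNAm age.

The clock is a penalized-regression style age predictor: a weighted linear
combination of CpG methylation fractions (beta values) plus an intercept,
evaluated on a calibrated age scale.  Chronological age is mapped onto that
scale with a piecewise log-linear transform that is logarithmic during
development (age <= ``adult_age``) and linear afterwards, reflecting the
faster methylome remodelling of growing tissue.  Predicted values are mapped
back to years with the exact inverse transform and reported as *DNAm age*.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ClockDefinition",
    "beta_from_intensities",
    "transform_age",
    "inverse_transform_age",
    "make_gold_standard",
    "normalize_to_gold_standard",
    "predict_dnam_age",
]

#: Stabilizing offset in the beta-value denominator (Illumina convention).
#: Not configurable: the published formula is exact.
BETA_OFFSET = 100.0

DEFAULT_ADULT_AGE = 20.0


@dataclass
class ClockDefinition:
    """A DNAm-age predictor: CpG weights, intercept and calibration parameter.

    Parameters
    ----------
    cpg_ids
        Ordered, unique CpG identifiers.
    weights
        Per-CpG regression coefficients, aligned with ``cpg_ids``.
    intercept
        Intercept on the transformed-age scale.
    adult_age
        Calibration parameter ``a`` of the piecewise age transform, in years.
    baseline, slope
        Optional generative ground truth (per-CpG beta at transformed age 0
        and beta change per unit transformed age).  Present for synthetic
        clocks; ``None`` for clocks read from file.
    """

    cpg_ids: list[str]
    weights: np.ndarray
    intercept: float
    adult_age: float = DEFAULT_ADULT_AGE
    baseline: np.ndarray | None = field(default=None, repr=False)
    slope: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.cpg_ids) != len(set(self.cpg_ids)):
            raise ValueError("clock CpG ids must be unique")
        if len(self.weights) != len(self.cpg_ids):
            raise ValueError("weights and cpg_ids must have equal length")
        if not self.adult_age > 0:
            raise ValueError("adult_age must be positive")

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_ids)


def beta_from_intensities(M, U):
    """Beta value from methylated/unmethylated fluorescence intensities.

    beta = max(M, 0) / (max(M, 0) + max(U, 0) + 100).  Negative intensities
    (background-corrected channels) are clamped to zero, and the +100 offset
    keeps the ratio defined and below 1 for all finite inputs.  Accepts
    scalars or arrays.
    """
    m = np.maximum(np.asarray(M, dtype=float), 0.0)
    u = np.maximum(np.asarray(U, dtype=float), 0.0)
    out = m / (m + u + BETA_OFFSET)
    if out.ndim == 0:
        return float(out)
    return out


def transform_age(x, adult_age: float = DEFAULT_ADULT_AGE):
    """Calibrated age transform F(x).

    ``F(x) = log(x + 1) - log(a + 1)`` for ``x <= a`` and
    ``F(x) = (x - a) / (a + 1)`` for ``x > a``; continuous and strictly
    increasing, with ``F(a) = 0``.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("chronological age must be non-negative")
    a = float(adult_age)
    out = np.where(
        x <= a,
        np.log1p(x) - np.log1p(a),
        (x - a) / (a + 1.0),
    )
    if out.ndim == 0:
        return float(out)
    return out


def inverse_transform_age(t, adult_age: float = DEFAULT_ADULT_AGE):
    """Exact inverse of :func:`transform_age` (years from transformed age)."""
    t = np.asarray(t, dtype=float)
    a = float(adult_age)
    out = np.where(
        t <= 0,
        np.expm1(t + np.log1p(a)),
        t * (a + 1.0) + a,
    )
    if out.ndim == 0:
        return float(out)
    return out


def make_gold_standard(beta: pd.DataFrame, reference_samples=None) -> pd.Series:
    """Per-CpG mean beta over a designated reference sample set.

    ``beta`` is a CpG x sample DataFrame; ``reference_samples`` selects the
    columns used (default: all).  Missing values are ignored per CpG.
    """
    cols = beta.columns if reference_samples is None else list(reference_samples)
    gold = beta[cols].mean(axis=1, skipna=True)
    gold.name = "mean"
    return gold


def normalize_to_gold_standard(
    beta: pd.DataFrame,
    gold: pd.Series,
    enabled: bool = True,
) -> pd.DataFrame:
    """Anchor each sample's clock-CpG distribution to a gold standard.

    A per-sample monotone quantile map: within the CpGs covered by ``gold``,
    each sample's values are replaced by the gold-standard values at the same
    within-sample quantile (mid-ranks for ties, linear interpolation between
    order statistics).  Rank order within a sample is preserved, the output
    marginal over those CpGs equals the gold standard's, and the map is
    idempotent.  CpGs not covered by the gold standard pass through
    unchanged.  This is a deliberately simple stand-in for beta-mixture
    (BMIQ-style) normalization that honours the same contract: every sample
    is referenced to one common standard.

    With ``enabled=False`` the input is returned untouched.
    """
    if not enabled:
        return beta
    common = beta.index.intersection(gold.index)
    if len(common) < 2:
        raise ValueError(
            f"need >= 2 CpGs shared with the gold standard, got {len(common)}"
        )
    g_sorted = np.sort(gold.loc[common].to_numpy(dtype=float))
    n = len(g_sorted)
    grid = np.arange(n, dtype=float) / (n - 1)
    out = beta.copy()
    sub = beta.loc[common]
    for col in beta.columns:
        x = sub[col].to_numpy(dtype=float)
        ok = ~np.isnan(x)
        if ok.sum() < 2:
            continue
        ranks = rankdata(x[ok], method="average")
        pos = (ranks - 1.0) / (ok.sum() - 1.0)
        y = x.copy()
        y[ok] = np.interp(pos, grid, g_sorted)
        out.loc[common, col] = y
    return out


def predict_dnam_age(
    beta: pd.DataFrame,
    clock: ClockDefinition,
    impute_missing: bool = False,
    gold: pd.Series | None = None,
) -> pd.DataFrame:
    """Evaluate a clock on a beta matrix.

    DNAm age per sample = ``inverse_transform(intercept + sum_i w_i * beta_i)``
    over the clock CpGs.  Missing clock CpGs (absent rows or NaN entries) are
    an error unless ``impute_missing`` is set, in which case they are filled
    from the gold-standard mean — deterministic and auditable, never silently
    dropped.

    Returns a DataFrame indexed by sample id with columns ``dnam_age`` and
    ``n_imputed``.
    """
    idx = pd.Index(clock.cpg_ids)
    sub = beta.reindex(idx)
    vals = sub.to_numpy(dtype=float)
    missing = np.isnan(vals)

    if missing.all(axis=0).any():
        bad = sub.columns[missing.all(axis=0)][0]
        raise ValueError(f"sample {bad!r}: all clock CpGs missing")
    n_imputed = missing.sum(axis=0)
    if missing.any():
        if not impute_missing:
            raise ValueError(
                f"{int(missing.any(axis=1).sum())} clock CpGs have missing "
                "values; pass impute_missing=True with a gold standard"
            )
        if gold is None:
            raise ValueError("impute_missing requires a gold standard")
        fill = gold.reindex(idx).to_numpy(dtype=float)
        if np.isnan(fill[missing.any(axis=1)]).any():
            raise ValueError("gold standard does not cover all missing clock CpGs")
        vals = np.where(missing, fill[:, None], vals)

    t = clock.intercept + clock.weights @ vals
    ages = inverse_transform_age(t, clock.adult_age)
    return pd.DataFrame(
        {"dnam_age": np.atleast_1d(ages), "n_imputed": n_imputed.astype(int)},
        index=pd.Index(beta.columns, name="sample_id"),
    )
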