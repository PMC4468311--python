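"""Matched-design differential-expression meta-analysis.

For each region contrast a paired t-statistic is computed on within-subject
expression differences — the matched design cancels subject-level
confounders (age, sex, ancestry) by construction.  The per-contrast
t-statistics are then combined with the *scaled Stouffer* method: within
each contrast, probes' statistics are replaced by scaled mid-ranks
``r / (m + 1)``, mapped through the standard normal quantile function, and
the resulting z-scores are summed over the k contrasts and divided by
sqrt(k).  Two one-sided scales are kept: the *high* scale ranks large
statistics as significant (over-expression in the contrast region), the
*low* scale the reverse.  Upper-tail normal p-values are converted to
Storey-style q-values, and probe sets are selected at a one-sided FDR
threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr, ndtri

__all__ = [
    "paired_t",
    "scaled_stouffer_combine",
    "qvalues",
    "select_de",
    "run_de_meta",
]


def paired_t(
    expr: pd.DataFrame,
    sample_map: pd.DataFrame,
    region_a: str,
    region_b: str,
) -> pd.DataFrame:
    """Paired t-statistics (region_a minus region_b) for every probe.

    ``expr`` is probe x sample; ``sample_map`` has columns sample_id,
    subject_id, region.  Only subjects with both regions contribute and at
    least two complete pairs are required.  Probes with zero difference
    variance get ``degenerate=True`` and a signed-infinity t sentinel
    (0 when the mean difference is also 0); they are excluded from the
    rank-combination universe downstream.

    Returns a DataFrame indexed by probe with columns mean_diff, t, df,
    n_pairs, degenerate.
    """
    sm = sample_map.set_index("sample_id")
    a = sm[sm.region == region_a]
    b = sm[sm.region == region_b]
    merged = pd.merge(
        a.reset_index()[["sample_id", "subject_id"]],
        b.reset_index()[["sample_id", "subject_id"]],
        on="subject_id",
        suffixes=("_a", "_b"),
    )
    n = len(merged)
    if n < 2:
        raise ValueError(
            f"need >= 2 subjects with both {region_a!r} and {region_b!r}, got {n}"
        )
    d = (
        expr[merged.sample_id_a.to_list()].to_numpy(dtype=float)
        - expr[merged.sample_id_b.to_list()].to_numpy(dtype=float)
    )
    mean = d.mean(axis=1)
    sd = d.std(axis=1, ddof=1)
    degenerate = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    sentinel = np.where(mean > 0, np.inf, np.where(mean < 0, -np.inf, 0.0))
    t = np.where(degenerate, sentinel, t)
    return pd.DataFrame(
        {
            "mean_diff": mean,
            "t": t,
            "df": n - 1,
            "n_pairs": n,
            "degenerate": degenerate,
        },
        index=expr.index,
    )


def scaled_stouffer_combine(results: list[pd.DataFrame]) -> pd.DataFrame:
    """Combine k paired-comparison results with the scaled Stouffer method.

    Per comparison, the *high* scale converts ascending mid-ranks of the
    t-statistics to scaled ranks ``r / (m + 1)`` and then to normal
    quantiles ``z = Phi^-1(r / (m + 1))`` (so the largest statistic maps to
    the largest z); the *low* scale does the same for ``-t``.  Combined
    ``Z = sum_k z / sqrt(k)``; p-values are upper-tail normal.  Probes
    degenerate in any comparison are excluded from the ranking universe and
    returned with NaN statistics and ``degenerate=True``.
    """
    if len(results) < 1:
        raise ValueError("need at least one comparison")
    idx = results[0].index
    for r in results[1:]:
        if not r.index.equals(idx):
            raise ValueError("mismatched probe universes across comparisons")
    degenerate = np.zeros(len(idx), dtype=bool)
    for r in results:
        degenerate |= r.degenerate.to_numpy()
    ok = ~degenerate
    m = int(ok.sum())
    k = len(results)

    z_high = np.zeros(m)
    z_low = np.zeros(m)
    for r in results:
        t = r.t.to_numpy(dtype=float)[ok]
        ranks_hi = stats.rankdata(t, method="average")
        ranks_lo = stats.rankdata(-t, method="average")
        z_high += ndtri(ranks_hi / (m + 1))
        z_low += ndtri(ranks_lo / (m + 1))
    z_high /= np.sqrt(k)
    z_low /= np.sqrt(k)

    out = pd.DataFrame(
        {
            "z_high": np.nan,
            "z_low": np.nan,
            "p_high": np.nan,
            "p_low": np.nan,
            "degenerate": degenerate,
        },
        index=idx,
    )
    out.loc[ok, "z_high"] = z_high
    out.loc[ok, "z_low"] = z_low
    out.loc[ok, "p_high"] = ndtr(-z_high)  # upper tail
    out.loc[ok, "p_low"] = ndtr(-z_low)
    return out


def estimate_pi0(p: np.ndarray) -> float:
    """Storey pi0 estimate: lambda grid 0.05..0.90, cubic-smoother endpoint.

    ``pi0(lambda) = #{p > lambda} / (m * (1 - lambda))`` is fitted with a
    cubic polynomial over the grid and evaluated at the largest lambda;
    the result is clipped to (0, 1].  Falls back to 1 for m < 100, where
    the extrapolation is unstable.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    if m < 100:
        return 1.0
    grid = np.arange(0.05, 0.9001, 0.05)
    pi0_l = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in grid])
    coefs = np.polyfit(grid, pi0_l, deg=3)
    pi0 = float(np.polyval(coefs, grid[-1]))
    return float(min(max(pi0, 1.0 / m), 1.0))


def qvalues(p, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """Tail-area q-values from a vector of p-values.

    ``q_(i) = min_{j >= i} pi0 * m * p_(j) / j`` over the ordered p-values;
    with ``pi0=1`` this is exactly the Benjamini–Hochberg adjusted p-value.
    Returns ``(q, pi0)`` with q in the input order, monotone in p.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = estimate_pi0(p)
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, float(pi0)


def select_de(meta: pd.DataFrame, fdr: float = 0.05) -> tuple[set, set]:
    """One-sided selection at an FDR threshold.

    Over-expressed = {q_high <= fdr}; under-expressed = {q_low <= fdr}.
    A probe significant on both scales (possible only in pathological
    inputs) is excluded from both sets with a warning flag.
    """
    if not 0 <= fdr < 1:
        raise ValueError("fdr must lie in [0, 1)")
    if fdr == 0:
        return set(), set()
    over = set(meta.index[meta.q_high <= fdr])
    under = set(meta.index[meta.q_low <= fdr])
    both = over & under
    if both:
        import warnings

        warnings.warn(
            f"{len(both)} probes significant on both scales; excluded from both sets"
        )
        over -= both
        under -= both
    return over, under


def run_de_meta(
    expr: pd.DataFrame,
    sample_map: pd.DataFrame,
    contrast_region: str,
    other_regions: list[str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Full meta-analysis: paired t per contrast, combine, q-values, flags.

    Returns a per-probe DataFrame with the per-contrast t-statistics,
    combined z/p on both scales, q_high/q_low and selection flags.
    """
    results = [paired_t(expr, sample_map, contrast_region, reg) for reg in other_regions]
    meta = scaled_stouffer_combine(results)
    for reg, r in zip(other_regions, results):
        meta[f"t_vs_{reg}"] = r.t
    ok = ~meta.degenerate
    q_high, pi0_high = qvalues(meta.loc[ok, "p_high"].to_numpy())
    q_low, pi0_low = qvalues(meta.loc[ok, "p_low"].to_numpy())
    meta["q_high"] = np.nan
    meta["q_low"] = np.nan
    meta.loc[ok, "q_high"] = q_high
    meta.loc[ok, "q_low"] = q_low
    meta.attrs["pi0_high"] = pi0_high
    meta.attrs["pi0_low"] = pi0_low
    over, under = select_de(meta, fdr)
    meta["over_expressed"] = meta.index.isin(over)
    meta["under_expressed"] = meta.index.isin(under)
    return meta
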