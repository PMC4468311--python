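"""GWAS meta-analysis, gene scoring, and permutation gene-set enrichment.

Per-study SNP effect estimates are combined with a fixed-effects
inverse-variance meta-analysis.  SNPs are assigned to every gene whose
interval extended by a flanking window (default +/-50 kb) contains them,
each gene is scored by its best (minimum) assigned SNP p-value, and
MAGENTA-style enrichment of a gene set is assessed by counting members in
the most significant tail of the gene-score distribution (default: beyond
the 95th percentile) against random gene sets of equal size drawn from the
scored universe.  Permutation counts escalate adaptively for small
p-values.  A DAVID-style hypergeometric over-representation test for
expression gene lists is also provided.

The gene score deliberately omits any correction for gene size or SNP
density (MAGENTA's confounder regression); ``score_hook`` on
:func:`gene_scores` lets callers plug in an adjusted score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "meta_analyze_gwas",
    "map_snps_to_genes",
    "gene_scores",
    "gsea_cutoff_enrichment",
    "hypergeom_overrep",
    "enrich_gene_sets",
]


@dataclass
class EnrichmentConfig:
    """Parameters of the permutation enrichment procedure.

    ``window``: flank added to each gene interval for SNP assignment (bp).
    ``cutoff_percentile``: gene scores beyond this percentile of the scored
    universe count as significant (95 → top 5% smallest p-values).
    ``perms_initial``/``perms_escalated``: permutation counts; a set whose
    initial p-value falls below ``escalate_below`` is re-run at the
    escalated count.
    """

    window: int = 50_000
    cutoff_percentile: float = 95.0
    perms_initial: int = 10_000
    perms_escalated: int = 100_000
    escalate_below: float = 1.0e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.cutoff_percentile < 100:
            raise ValueError("cutoff_percentile must be in (0, 100)")
        if self.perms_escalated < self.perms_initial:
            raise ValueError("perms_escalated must be >= perms_initial")


@dataclass
class EnrichmentResult:
    set_name: str
    set_size_scored: int
    observed: int
    expected: float
    p_value: float
    n_perms: int


def meta_analyze_gwas(studies: list[pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effects inverse-variance meta-analysis of GWAS summary stats.

    Each study table has columns snp_id, chrom, pos, beta, se (positions
    1-based).  SNPs are joined by id; a SNP present in a subset of studies
    is combined over that subset.  Weights are ``w = se^-2``; the combined
    effect is ``sum(w b) / sum(w)`` with ``SE = sum(w)^-1/2`` and a
    two-sided normal p-value.
    """
    if len(studies) < 1:
        raise ValueError("need at least one study")
    for i, s in enumerate(studies):
        if (s.se <= 0).any():
            raise ValueError(f"study {i}: standard errors must be > 0")
    num = None  # sum of w*b per snp
    den = None  # sum of w per snp
    coords = {}
    for s in studies:
        w = 1.0 / s.se.to_numpy(dtype=float) ** 2
        wb = pd.Series(w * s.beta.to_numpy(dtype=float), index=s.snp_id)
        ws = pd.Series(w, index=s.snp_id)
        num = wb if num is None else num.add(wb, fill_value=0.0)
        den = ws if den is None else den.add(ws, fill_value=0.0)
        for rec in s.itertuples(index=False):
            coords.setdefault(rec.snp_id, (rec.chrom, rec.pos))
    beta = num / den
    se = 1.0 / np.sqrt(den)
    z = beta / se
    out = pd.DataFrame(
        {
            "snp_id": beta.index,
            "chrom": [coords[s][0] for s in beta.index],
            "pos": [coords[s][1] for s in beta.index],
            "beta": beta.to_numpy(),
            "se": se.to_numpy(),
            "p": 2.0 * ndtr(-np.abs(z.to_numpy())),
        }
    ).reset_index(drop=True)
    return out


def map_snps_to_genes(
    meta: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 50_000,
) -> pd.DataFrame:
    """Assign each SNP to every gene whose windowed interval contains it.

    Gene intervals are 0-based half-open ``[start, end)``; SNP positions are
    1-based and converted here, so a SNP is assigned when
    ``start - window <= pos0 < end + window``.  Multi-assignment is allowed
    (overlapping windows).  Returns a DataFrame with columns gene_id,
    snp_id.
    """
    rows = []
    pos0_all = meta.pos.to_numpy(dtype=np.int64) - 1
    for chrom, gsub in genes.groupby("chrom", sort=False):
        mask = (meta.chrom == chrom).to_numpy()
        if not mask.any():
            continue
        pos0 = pos0_all[mask]
        snps = meta.snp_id.to_numpy()[mask]
        starts = gsub.start.to_numpy(dtype=np.int64) - window
        ends = gsub.end.to_numpy(dtype=np.int64) + window
        hit = (pos0[None, :] >= starts[:, None]) & (pos0[None, :] < ends[:, None])
        gi, si = np.nonzero(hit)
        gids = gsub.gene_id.to_numpy()
        rows.append(pd.DataFrame({"gene_id": gids[gi], "snp_id": snps[si]}))
    if not rows:
        return pd.DataFrame(columns=["gene_id", "snp_id"])
    return pd.concat(rows, ignore_index=True)


def gene_scores(
    assignment: pd.DataFrame,
    meta: pd.DataFrame,
    score_hook: Callable[[pd.DataFrame], pd.Series] | None = None,
) -> pd.DataFrame:
    """Score each gene by its best assigned SNP p-value.

    Genes with no assigned SNPs are absent from the output (their count is
    available as the difference from the annotation).  ``score_hook``
    receives the per-gene assigned SNP table and may return an adjusted
    score series, replacing the min-p rule.
    """
    if len(assignment) == 0:
        raise ValueError("empty SNP-to-gene assignment")
    joined = assignment.merge(meta[["snp_id", "p"]], on="snp_id", how="left")
    if score_hook is not None:
        scores = score_hook(joined)
        n_snps = joined.groupby("gene_id").size()
        out = pd.DataFrame({"score": scores, "n_snps": n_snps})
    else:
        grp = joined.groupby("gene_id")["p"]
        out = pd.DataFrame({"score": grp.min(), "n_snps": grp.size()})
    out.index.name = "gene_id"
    return out.sort_index()


def _permuted_tail_counts(
    indicator: np.ndarray,
    set_size: int,
    n_perms: int,
    rng: np.random.Generator,
    chunk: int = 2048,
) -> np.ndarray:
    """Tail counts of random equal-size gene sets (without replacement).

    Vectorized: random keys + argpartition pick a uniform ``set_size``-subset
    of the universe per permutation.
    """
    G = indicator.size
    counts = np.empty(n_perms, dtype=np.int64)
    done = 0
    while done < n_perms:
        c = min(chunk, n_perms - done)
        keys = rng.random((c, G))
        picks = np.argpartition(keys, set_size - 1, axis=1)[:, :set_size]
        counts[done : done + c] = indicator[picks].sum(axis=1)
        done += c
    return counts


def gsea_cutoff_enrichment(
    scores: pd.DataFrame,
    gene_set: tuple[str, list[str]],
    cfg: EnrichmentConfig,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Permutation enrichment of a gene set in the tail of the gene scores.

    The significance cutoff is the empirical ``(100 - cutoff_percentile)``
    quantile of all gene scores; ``observed`` counts set members at or below
    it.  The null resamples gene *sets* of equal size from the scored
    universe without replacement (preserving the score distribution), and
    ``p = (1 + #{perm count >= observed}) / (1 + n_perms)`` — never exactly
    0 and never above 1.  When the initial p-value is below
    ``cfg.escalate_below`` the permutation count escalates to
    ``cfg.perms_escalated``.
    """
    set_name, members = gene_set
    universe = scores.index
    in_set = universe.isin(set(members)).astype(bool)
    k = int(in_set.sum())
    if k == 0:
        raise ValueError(f"gene set {set_name!r} does not intersect scored genes")
    vals = scores.score.to_numpy(dtype=float)
    cutoff = np.quantile(vals, (100.0 - cfg.cutoff_percentile) / 100.0)
    tail = vals <= cutoff
    observed = int((tail & in_set).sum())
    expected = k * tail.sum() / len(universe)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    n_perms = cfg.perms_initial
    counts = _permuted_tail_counts(tail.astype(np.int64), k, n_perms, rng)
    p = (1 + int((counts >= observed).sum())) / (1 + n_perms)
    if p < cfg.escalate_below and cfg.perms_escalated > n_perms:
        n_perms = cfg.perms_escalated
        counts = _permuted_tail_counts(tail.astype(np.int64), k, n_perms, rng)
        p = (1 + int((counts >= observed).sum())) / (1 + n_perms)
    return EnrichmentResult(
        set_name=set_name,
        set_size_scored=k,
        observed=observed,
        expected=float(expected),
        p_value=float(p),
        n_perms=n_perms,
    )


def enrich_gene_sets(
    scores: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    cfg: EnrichmentConfig,
) -> pd.DataFrame:
    """Run the permutation enrichment over a GMT-style collection of sets.

    Sets that do not intersect the scored universe are reported with NaN
    statistics.  One RNG drives all sets so the whole table is reproducible
    from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for name in sorted(gene_sets):
        try:
            res = gsea_cutoff_enrichment(scores, (name, gene_sets[name]), cfg, rng=rng)
        except ValueError:
            rows.append((name, 0, np.nan, np.nan, np.nan, 0))
            continue
        rows.append(
            (name, res.set_size_scored, res.observed, res.expected,
             res.p_value, res.n_perms)
        )
    return pd.DataFrame(
        rows,
        columns=["set_name", "set_size_scored", "observed", "expected",
                 "p_value", "n_perms"],
    )


def hypergeom_overrep(
    gene_list: list[str],
    gene_set: list[str],
    universe: list[str],
    n_sets_tested: int = 1,
) -> tuple[int, float, float, float]:
    """Over-representation of a gene set within a hit list.

    Returns ``(n_overlap, fold_enrichment, p, p_bonferroni)`` where
    ``FE = (n/|list|) / (|set|/|universe|)`` and p is the upper-tail
    hypergeometric probability ``P(X >= n)``.  Bonferroni multiplies by the
    number of sets tested in the run, capped at 1.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    lst = set(gene_list) & uni
    st = set(gene_set) & uni
    if not lst:
        raise ValueError("empty gene list")
    n = len(lst & st)
    fe = (n / len(lst)) / (len(st) / len(uni)) if st else np.nan
    p = float(stats.hypergeom.sf(n - 1, len(uni), len(st), len(lst)))
    return n, float(fe), p, float(min(1.0, p * n_sets_tested))
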