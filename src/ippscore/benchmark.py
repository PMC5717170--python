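"""Baselines, robustness resampling and null-distribution machinery.

Contains everything needed to compare IPP against the conventional
single-threshold log-rank test: mean/median-threshold z-scores, shared-gene
counting across datasets, outcome-relation consistency tallies, the pooled
two-proportion z-test for shared-gene counts, bootstrap/subsample score
robustness, and the Monte-Carlo null distribution of the IPP score at a
given cohort size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import Cohort
from .core import ipp_matrix, ipp_score, score_all_genes
from .errors import GeneUniverseMismatchError, UnknownGeneError
from .logrank import SurvivalGroup, logrank_z
from .synthetic import generate_null_cohort

logger = logging.getLogger("ippscore")

__all__ = [
    "ConsistencySummary",
    "ResampleSummary",
    "threshold_logrank_score",
    "count_shared_genes",
    "outcome_consistency",
    "resample_scores",
    "binomial_shared_test",
    "null_ipp_distribution",
]


# ---------------------------------------------------------------------------
# conventional-threshold baseline
# ---------------------------------------------------------------------------

def threshold_logrank_score(cohort: Cohort, gene: str, rule: str = "average") -> float:
    """Signed log-rank z for the conventional single-threshold split.

    The threshold is the gene's mean (``rule='average'``) or median
    (``rule='median'``) across the cohort; the high group is expression
    strictly above the threshold, the low group at or below it.  Sign
    convention matches IPP (negative = high group at higher risk).  If one
    side is empty the split is degenerate and z = 0 (logged).
    """
    if gene not in cohort.gene_ids:
        raise UnknownGeneError(f"gene {gene!r} not in cohort")
    if rule not in ("average", "median"):
        raise ValueError("rule must be 'average' or 'median'")
    row = cohort.expression.row(gene)
    thr = float(np.mean(row)) if rule == "average" else float(np.median(row))
    high = row > thr
    if not high.any() or high.all():
        logger.warning("%s/%s: %s-threshold split is degenerate; z = 0",
                       cohort.name or "cohort", gene, rule)
        return 0.0
    return logrank_z(cohort.survival_group(high),
                     cohort.survival_group(~high)).z


def _baseline_scores(cohort: Cohort, rule: str) -> np.ndarray:
    return np.array([threshold_logrank_score(cohort, g, rule)
                     for g in cohort.gene_ids])


# ---------------------------------------------------------------------------
# cross-dataset agreement
# ---------------------------------------------------------------------------

def count_shared_genes(top_sets: Sequence[Iterable[str]], min_datasets: int = 5) -> set[str]:
    """Genes appearing in at least ``min_datasets`` of the per-dataset top
    sets (default 5)."""
    if len(top_sets) < min_datasets:
        raise ValueError("fewer top sets supplied than min_datasets")
    counts: dict[str, int] = {}
    for s in top_sets:
        for g in set(map(str, s)):
            counts[g] = counts.get(g, 0) + 1
    return {g for g, c in counts.items() if c >= min_datasets}


@dataclass(frozen=True)
class ConsistencySummary:
    """Outcome-relation agreement of genes across datasets.

    ``per_gene`` has one row per gene with ``n_adverse``/``n_favorable``
    dataset tallies (exact-zero scores count to neither side and are logged);
    ``n_consistent_adverse``/``n_consistent_favorable`` count genes with the
    same sign in at least ``min_datasets`` of the ``n_datasets`` tables.
    """

    per_gene: pd.DataFrame
    n_datasets: int
    min_datasets: int
    n_consistent_adverse: int
    n_consistent_favorable: int


def outcome_consistency(
    score_tables: Mapping[str, object] | Sequence[object],
    min_datasets: int = 17,
) -> ConsistencySummary:
    """Tally adverse/favorable signs per gene over per-dataset score tables."""
    from .integration import _as_score_series

    if isinstance(score_tables, Mapping):
        tables = [_as_score_series(t) for t in score_tables.values()]
    else:
        tables = [_as_score_series(t) for t in score_tables]
    if not tables:
        raise ValueError("at least one score table is required")
    genes = sorted(tables[0].index)
    for t in tables[1:]:
        if sorted(t.index) != genes:
            raise GeneUniverseMismatchError("score tables differ in gene universe")

    mat = np.column_stack([t.loc[genes].to_numpy() for t in tables])
    n_adv = (mat < 0).sum(axis=1)
    n_fav = (mat > 0).sum(axis=1)
    n_zero = (mat == 0).sum(axis=1)
    if n_zero.any():
        logger.info("outcome_consistency: %d exact-zero score(s) counted to "
                    "neither side", int(n_zero.sum()))
    per_gene = pd.DataFrame({"gene_id": genes, "n_adverse": n_adv,
                             "n_favorable": n_fav, "n_none": n_zero})
    return ConsistencySummary(
        per_gene=per_gene,
        n_datasets=len(tables),
        min_datasets=min_datasets,
        n_consistent_adverse=int((n_adv >= min_datasets).sum()),
        n_consistent_favorable=int((n_fav >= min_datasets).sum()),
    )


def binomial_shared_test(k_a: int, k_b: int, total: int) -> tuple[float, float]:
    """One-tailed two-proportion z-test for shared-gene counts.

    Compares the proportions ``k_a/total`` vs ``k_b/total`` with the pooled
    estimate p = (k_a + k_b) / (2 total); the alternative is k_a > k_b.
    Returns (z, one-tailed p).  Degenerate pooled proportions (0 or 1) give
    p = 1 when the counts are equal and 0 otherwise.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= k_a <= total and 0 <= k_b <= total):
        raise ValueError("counts must lie in [0, total]")
    pooled = (k_a + k_b) / (2 * total)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0 if k_a == k_b else 0.0
    z = (k_a / total - k_b / total) / np.sqrt(2 * pooled * (1 - pooled) / total)
    return float(z), float(norm.sf(z))


# ---------------------------------------------------------------------------
# resampling robustness
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResampleSummary:
    """Robustness of gene scores under bootstrap/subsample draws.

    ``per_gene``: full-cohort score, mean resampled score, and the per-gene
    ratio mean/full (NaN where |full| is below ``min_abs_full`` — near-zero
    denominators make the ratio meaningless).  ``pearson_r`` correlates the
    full and mean-resampled score vectors across genes.
    """

    per_gene: pd.DataFrame
    pearson_r: float
    scheme: str
    n_draws: int
    subsample_size: int
    scorer: str


def _score_vector(cohort: Cohort, scorer: str) -> np.ndarray:
    if scorer == "ipp":
        return score_all_genes(cohort)["ipp_score"].to_numpy()
    return _baseline_scores(cohort, scorer)


def resample_scores(
    cohort: Cohort,
    scheme: str = "subsample",
    size: int | None = None,
    n_draws: int = 1000,
    scorer: str = "ipp",
    seed: int = 0,
    min_abs_full: float = 0.05,
) -> ResampleSummary:
    """Score all genes on resampled cohorts and compare with the full run.

    ``scheme='bootstrap'`` draws ``size`` patients with replacement,
    ``'subsample'`` without.  ``scorer`` is ``'ipp'`` or a threshold rule
    (``'average'``/``'median'``).
    """
    n = cohort.n_patients
    size = n if size is None else int(size)
    if scheme not in ("bootstrap", "subsample"):
        raise ValueError("scheme must be 'bootstrap' or 'subsample'")
    if scorer not in ("ipp", "average", "median"):
        raise ValueError("scorer must be 'ipp', 'average' or 'median'")
    if size < 2 or (scheme == "subsample" and size > n):
        raise ValueError(f"resample size {size} out of range for N={n}")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")

    full = _score_vector(cohort, scorer)
    rng = np.random.default_rng(seed)
    acc = np.zeros(cohort.n_genes)
    for _ in range(n_draws):
        idx = rng.choice(n, size=size, replace=(scheme == "bootstrap"))
        acc += _score_vector(cohort.take(np.sort(idx)), scorer)
    mean_resampled = acc / n_draws

    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(np.abs(full) >= min_abs_full,
                              mean_resampled / full, np.nan)
    if cohort.n_genes >= 2 and np.std(full) > 0 and np.std(mean_resampled) > 0:
        r = float(np.corrcoef(full, mean_resampled)[0, 1])
    else:
        r = float("nan")
    per_gene = pd.DataFrame({
        "gene_id": list(cohort.gene_ids),
        "full_score": full,
        "mean_resampled_score": mean_resampled,
        "normalized_mean": normalized,
    })
    return ResampleSummary(per_gene=per_gene, pearson_r=r, scheme=scheme,
                           n_draws=n_draws, subsample_size=size, scorer=scorer)


# ---------------------------------------------------------------------------
# null distribution of the IPP score
# ---------------------------------------------------------------------------

def null_ipp_distribution(
    sample_sizes: Sequence[int],
    n_reps: int = 10000,
    seed: int = 0,
    quantiles: Sequence[float] = (0.01, 0.05, 0.5, 0.95, 0.99),
) -> pd.DataFrame:
    """Monte-Carlo distribution of the IPP score under the null.

    For each cohort size, ``n_reps`` virtual cohorts with random survival
    and random expression order are generated and scored.  Returns one row
    per size with mean, sd and the requested quantiles.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rows = []
    root = np.random.SeedSequence(seed)
    for n, child in zip(sample_sizes, root.spawn(len(sample_sizes))):
        if n < 2:
            raise ValueError("sample sizes must be >= 2")
        rng = np.random.Generator(np.random.Philox(child))
        scores = np.empty(n_reps)
        for r in range(n_reps):
            cohort = generate_null_cohort(n, rng)
            scores[r] = ipp_score(ipp_matrix(cohort, "g0"))
        row = {"n_patients": int(n), "n_reps": n_reps,
               "mean": float(scores.mean()), "sd": float(scores.std(ddof=1))}
        for q, v in zip(quantiles, np.quantile(scores, quantiles)):
            row[f"q{q:g}"] = float(v)
        rows.append(row)
    return pd.DataFrame(rows)
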