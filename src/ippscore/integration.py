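"""Cross-dataset integration of per-dataset IPP scores.

Per-dataset scores for one gene are combined with Liptak's (weighted
Stouffer) method, weighting each dataset by the square root of its patient
count:

    combined = sum_d w_d * S_d / sqrt(sum_d w_d^2),   w_d = sqrt(n_d).

Prognostic genes are then the top fraction of the gene universe ranked by
absolute (combined) score, and the sign of a score classifies the gene's
outcome relation: negative = adverse (high expression, poor prognosis),
positive = favorable.
"""

from __future__ import annotations

import logging
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ippscore")

__all__ = ["liptak_combine", "select_top_fraction", "top_fraction_count",
           "classify_outcome_relation"]

_SCORE_COLUMNS = ("ipp_score", "combined_score", "score", "z")


def classify_outcome_relation(score: float) -> str:
    """adverse (score < 0) / favorable (score > 0) / none (score == 0)."""
    if not np.isfinite(score):
        raise ValueError(f"score must be finite, got {score!r}")
    if score < 0:
        return "adverse"
    if score > 0:
        return "favorable"
    return "none"


def _as_score_series(table) -> pd.Series:
    """Extract a gene_id -> score mapping from the accepted table shapes."""
    if isinstance(table, pd.Series):
        s = table.astype(float)
        s.index = s.index.astype(str)
        return s
    if isinstance(table, pd.DataFrame):
        for col in _SCORE_COLUMNS:
            if col in table.columns:
                idx = (table["gene_id"].astype(str)
                       if "gene_id" in table.columns else table.index.astype(str))
                return pd.Series(table[col].to_numpy(dtype=float), index=idx)
        raise ValueError(f"no score column among {_SCORE_COLUMNS} in table")
    if isinstance(table, Mapping):
        return pd.Series({str(k): float(v) for k, v in table.items()})
    raise TypeError(f"unsupported score table type {type(table)!r}")


def liptak_combine(
    scores: Mapping[str, object],
    sizes: Mapping[str, int],
    null_sd: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Combine per-dataset gene score tables into representative scores.

    Parameters
    ----------
    scores
        dataset label -> score table (gene score DataFrame, Series, or
        plain mapping gene_id -> score).
    sizes
        dataset label -> patient count; weights are sqrt(size).
    null_sd
        Optional dataset label -> null-score standard deviation.  When given,
        each dataset's scores are divided by its null SD before combination
        (standardisation hook); default is raw combination.

    Genes missing from any dataset are excluded with a logged warning.
    Returns a table with ``gene_id``, ``combined_score``, ``n_datasets``,
    ``outcome_relation`` plus one ``score:<label>`` column per dataset.
    """
    if not scores:
        raise ValueError("at least one dataset is required")
    labels = list(scores)
    series = {}
    for lab in labels:
        s = _as_score_series(scores[lab])
        if null_sd is not None:
            s = s / float(null_sd[lab])
        series[lab] = s

    common = set(series[labels[0]].index)
    universe = set(common)
    for lab in labels[1:]:
        universe |= set(series[lab].index)
        common &= set(series[lab].index)
    dropped = universe - common
    if dropped:
        logger.warning("liptak_combine: excluding %d gene(s) absent from "
                       "some dataset(s)", len(dropped))
    genes = sorted(common)

    w = np.array([math.sqrt(sizes[lab]) for lab in labels])
    mat = np.column_stack([series[lab].loc[genes].to_numpy() for lab in labels])
    combined = mat @ w / math.sqrt(float(np.sum(w * w)))

    out = pd.DataFrame({
        "gene_id": genes,
        "combined_score": combined,
        "n_datasets": len(labels),
        "outcome_relation": [classify_outcome_relation(c) for c in combined],
    })
    for k, lab in enumerate(labels):
        out[f"score:{lab}"] = mat[:, k]
    return out


def top_fraction_count(n_genes: int, fraction: float = 0.05) -> int:
    """Number of genes in the top ``fraction``: ceil(fraction * n_genes).

    A small guard absorbs binary-float artifacts so that e.g. 5% of 100 is
    exactly 5 while 5% of 11,123 is 557.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return max(1, math.ceil(fraction * n_genes - 1e-9))


def select_top_fraction(table, fraction: float = 0.05) -> list[str]:
    """Top-fraction prognostic genes by absolute score.

    Ranks genes by |score| descending, boundary ties broken by gene id
    ascending, and returns the first ceil(fraction * G) gene ids in rank
    order.  The selected *set* is invariant to the input row order.
    """
    s = _as_score_series(table)
    k = top_fraction_count(len(s), fraction)
    ranked = sorted(s.index, key=lambda g: (-abs(s[g]), g))
    return list(ranked[:k])
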