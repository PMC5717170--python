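"""Iterative patient partitioning: the IPP matrix and score.

For one gene, patients are sorted by expression (ties broken by sample id).
Every non-overlapping bipartition — the top ``i`` patients as the "high"
group and the bottom ``j`` as the "low" group, ``i + j <= N``, middle
patients excluded — yields one signed log-rank z-score Z_ij.  The IPP score
of the gene is the plain average

    S = sum(Z_ij) / (N (N - 1) / 2),

the denominator being the full count of partitions even when individual
elements are degenerate (those contribute 0).  Negative S marks an adverse
gene (high expression, higher risk), positive S a favorable one.

The matrix is filled by a compiled kernel that maintains the integer risk
tables incrementally: for a fixed high-group size the at-risk and event
counts per distinct event time are updated in O(N) as the low group grows by
one patient, instead of re-sorting and rebuilding the table for each of the
N(N-1)/2 elements.  The floating-point statistic is recomputed per element
from those exact integer tables in ascending time order, so the result is
identical to evaluating each partition independently.
"""

from __future__ import annotations

import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .cohort import Cohort
from .errors import UnknownGeneError
from .integration import classify_outcome_relation

__all__ = ["IPPMatrix", "ipp_matrix", "ipp_score", "score_all_genes"]


@njit(cache=True, nogil=True)
def _ipp_kernel(time_idx, event, m):  # pragma: no cover - exercised via wrappers
    """Fill the IPP z-matrix for one gene.

    ``time_idx``/``event``: per patient, in ascending-expression order;
    ``time_idx`` indexes the ascending grid of distinct follow-up times
    (length ``m``).  Returns Z with Z[i, j] valid for i, j >= 1, i + j <= N.
    """
    n = time_idx.shape[0]
    z = np.zeros((n + 1, n + 1))
    d = np.zeros(m, dtype=np.int64)      # events at time t among included
    d_h = np.zeros(m, dtype=np.int64)    # ... in the high group
    n_at = np.zeros(m, dtype=np.int64)   # at risk at t among included
    nh_at = np.zeros(m, dtype=np.int64)  # ... in the high group
    for i in range(1, n):
        for t in range(m):
            d[t] = 0
            d_h[t] = 0
            nh_at[t] = 0
        for p in range(n - i, n):  # high group: top i by expression
            tp = time_idx[p]
            nh_at[tp] += 1
            if event[p] == 1:
                d_h[tp] += 1
                d[tp] += 1
        for t in range(m - 2, -1, -1):  # counts -> at-risk suffix sums
            nh_at[t] += nh_at[t + 1]
        for t in range(m):
            n_at[t] = nh_at[t]
        for j in range(1, n - i + 1):
            q = j - 1  # add patient q to the low group
            tq = time_idx[q]
            if event[q] == 1:
                d[tq] += 1
            for t in range(tq + 1):
                n_at[t] += 1
            u = 0.0
            v = 0.0
            for t in range(m):
                dt = d[t]
                if dt > 0:
                    nt = n_at[t]
                    nht = nh_at[t]
                    nlt = nt - nht
                    dht = d_h[t]
                    dlt = dt - dht
                    u += (dht * nlt - dlt * nht) / nt
                    if nt > 1:
                        v += (dt * nht * nlt * (nt - dt)) / (nt * nt * (nt - 1))
            if v > 0.0:
                z[i, j] = -u / math.sqrt(v)
    return z


@dataclass(frozen=True)
class IPPMatrix:
    """Triangular collection of signed z-scores over all bipartitions.

    ``zmat[i, j]`` holds Z_ij for high-group size i and low-group size j
    (1-based, i + j <= N); other positions are zero padding.
    """

    gene_id: str
    n_patients: int
    zmat: np.ndarray

    @property
    def n_entries(self) -> int:
        n = self.n_patients
        return n * (n - 1) // 2

    def entry(self, i: int, j: int) -> float:
        n = self.n_patients
        if not (1 <= i and 1 <= j and i + j <= n):
            raise KeyError(f"(i={i}, j={j}) outside the partition domain for N={n}")
        return float(self.zmat[i, j])

    __getitem__ = lambda self, ij: self.entry(*ij)

    @property
    def entries(self) -> dict[tuple[int, int], float]:
        n = self.n_patients
        return {(i, j): float(self.zmat[i, j])
                for i in range(1, n) for j in range(1, n - i + 1)}

    def values(self) -> np.ndarray:
        """All N(N-1)/2 entries, row-major over (i, j)."""
        n = self.n_patients
        return np.concatenate([self.zmat[i, 1:n - i + 1] for i in range(1, n)])


def _expression_order(cohort: Cohort, row: np.ndarray) -> np.ndarray:
    """Ascending expression order, ties broken by sample id (stable)."""
    sids = np.asarray(cohort.sample_ids)
    return np.lexsort((sids, row))


def ipp_matrix(cohort: Cohort, gene: str) -> IPPMatrix:
    """IPP matrix of one gene over all non-overlapping high/low partitions."""
    if gene not in cohort.gene_ids:
        raise UnknownGeneError(f"gene {gene!r} not in cohort")
    n = cohort.n_patients
    if n < 2:
        raise ValueError("IPP requires at least 2 patients")
    row = cohort.expression.row(gene)
    order = _expression_order(cohort, row)
    ut, tidx = np.unique(cohort.time[order], return_inverse=True)
    zmat = _ipp_kernel(tidx.astype(np.int64),
                       cohort.event[order].astype(np.int64), ut.size)
    return IPPMatrix(gene_id=str(gene), n_patients=n, zmat=zmat)


def ipp_score(matrix: IPPMatrix) -> float:
    """Average of all N(N-1)/2 partition z-scores (degenerate entries count
    as zero but stay in the denominator).

    Summed with :func:`math.fsum`, so the result does not depend on the
    enumeration order of the matrix.
    """
    return math.fsum(matrix.values()) / matrix.n_entries


def _score_one(args) -> float:
    tidx, events, m, n = args
    zmat = _ipp_kernel(tidx, events, m)
    total = math.fsum(np.concatenate([zmat[i, 1:n - i + 1] for i in range(1, n)]))
    return total / (n * (n - 1) // 2)


def score_all_genes(cohort: Cohort, threads: int = 1) -> pd.DataFrame:
    """IPP scores for every gene in the cohort.

    Returns a gene score table: ``gene_id``, ``ipp_score``, ``n_patients``,
    ``outcome_relation``.  The cohort is expected to have passed
    :func:`ippscore.cohort.filter_invariant_genes`.  With ``threads > 1``
    genes are scored in a thread pool (the kernel releases the GIL); results
    are identical to the single-threaded run.
    """
    n = cohort.n_patients
    if n < 2:
        raise ValueError("IPP requires at least 2 patients")
    ut, tidx_all = np.unique(cohort.time, return_inverse=True)
    m = ut.size
    sids = np.asarray(cohort.sample_ids)

    jobs = []
    for row in cohort.expression.values:
        order = np.lexsort((sids, row))
        jobs.append((tidx_all[order].astype(np.int64),
                     cohort.event[order].astype(np.int64), m, n))

    if threads > 1 and len(jobs) > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            scores = list(pool.map(_score_one, jobs))
    else:
        scores = [_score_one(j) for j in jobs]

    return pd.DataFrame({
        "gene_id": list(cohort.gene_ids),
        "ipp_score": scores,
        "n_patients": n,
        "outcome_relation": [classify_outcome_relation(s) for s in scores],
    })
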