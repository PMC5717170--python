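"""Synthetic cohorts for calibration and recovery experiments.

Two generators:

* :func:`generate_null_cohort` — virtual patients with survival unrelated to
  expression (Bernoulli(0.5) events, Uniform(0, 10) follow-up, expression =
  a random permutation of ranks).  Because the IPP score depends on
  expression only through patient order, any exchangeable null law gives the
  same score distribution; these cohorts feed the random-score distribution.
* :func:`generate_planted_cohort` — proportional-hazards cohorts with
  standard-normal expression and a configurable set of planted prognostic
  genes.  A planted log-hazard-ratio beta > 0 makes high expression shorten
  survival (an adverse gene, negative IPP score); beta < 0 is favorable.
  Event times are exponential with patient mean
  ``baseline_scale * exp(-sum_g beta_g x_g)``; censoring is uniform on
  (0, censor_horizon].

All randomness flows from one seed through counter-based Philox streams
keyed per gene, so each gene's expression is reproducible independently of
generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import Cohort, ExpressionMatrix

__all__ = ["SimulationConfig", "generate_null_cohort", "generate_planted_cohort"]


def _rng(seed, stream: int = 0) -> np.random.Generator:
    key = (int(seed) << 32) + stream
    return np.random.Generator(np.random.Philox(key=key))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-signal cohort.

    ``planted`` lists (gene index, log-hazard-ratio beta) pairs; all other
    genes are pure noise.  ``event_rate`` is the Bernoulli event probability
    used for null-style virtual patients (the planted generator controls
    censoring through ``censor_horizon`` instead).  ``baseline_scale`` is the
    exponential mean event time of a patient with zero linear predictor.
    """

    n_patients: int = 100
    n_genes: int = 200
    event_rate: float = 0.5
    baseline_scale: float = 5.0
    censor_horizon: float = 10.0
    planted: Sequence[tuple[int, float]] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not 0 < self.event_rate <= 1:
            raise ValueError("event_rate must be in (0, 1]")
        if self.baseline_scale <= 0 or self.censor_horizon <= 0:
            raise ValueError("scales must be positive")
        for g, beta in self.planted:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"planted gene index {g} out of range")
            if not np.isfinite(beta):
                raise ValueError("planted effect must be finite")
        object.__setattr__(self, "planted", tuple((int(g), float(b))
                                                  for g, b in self.planted))


def _sample_ids(n: int) -> tuple[str, ...]:
    return tuple(f"S{k:04d}" for k in range(n))


def generate_null_cohort(n: int, seed) -> Cohort:
    """Virtual cohort with no expression-survival association.

    Events are Bernoulli(0.5), follow-up times Uniform(0, 10), and the single
    synthetic gene carries a uniform-random permutation of patient ranks as
    its expression.  Fully determined by ``seed``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else _rng(seed)
    event = (rng.random(n) < 0.5).astype(np.int64)
    time = rng.uniform(0.0, 10.0, size=n)
    time[time <= 0] = 1e-9  # measure-zero guard for the positivity invariant
    expr = rng.permutation(n).astype(float)[None, :]
    matrix = ExpressionMatrix(("g0",), _sample_ids(n), expr)
    return Cohort(matrix, time, event, endpoint="synthetic", name=f"null_n{n}")


def generate_planted_cohort(config: SimulationConfig) -> Cohort:
    """Proportional-hazards cohort with planted prognostic genes."""
    n, k = config.n_patients, config.n_genes
    expr = np.empty((k, n))
    for g in range(k):
        expr[g] = _rng(config.seed, stream=g).standard_normal(n)

    linpred = np.zeros(n)
    for g, beta in config.planted:
        linpred += beta * expr[g]
    surv_rng = _rng(config.seed, stream=k)
    cens_rng = _rng(config.seed, stream=k + 1)
    t_event = surv_rng.exponential(1.0, size=n) * config.baseline_scale * np.exp(-linpred)
    t_cens = cens_rng.uniform(0.0, config.censor_horizon, size=n)
    t_cens[t_cens <= 0] = config.censor_horizon * 1e-12
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(np.int64)

    gene_ids = tuple(f"g{g}" for g in range(k))
    matrix = ExpressionMatrix(gene_ids, _sample_ids(n), expr)
    return Cohort(matrix, time, event, endpoint="synthetic",
                  name=f"planted_seed{config.seed}")
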