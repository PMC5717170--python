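import numpy as np
import pytest

from ippscore import Cohort, ExpressionMatrix


def make_cohort(expr, time, event, gene_ids=None, name="test") -> Cohort:
    """Build a cohort from raw arrays with auto-generated identifiers."""
    expr = np.atleast_2d(np.asarray(expr, dtype=float))
    k, n = expr.shape
    genes = tuple(gene_ids) if gene_ids is not None else tuple(f"g{i}" for i in range(k))
    samples = tuple(f"S{j:03d}" for j in range(n))
    matrix = ExpressionMatrix(genes, samples, expr)
    return Cohort(matrix, np.asarray(time, float), np.asarray(event, np.int64),
                  endpoint="DMFS", name=name)


def random_cohort(rng, n, k=1, event_rate=0.6) -> Cohort:
    """Small random cohort with continuous expression (no ties)."""
    expr = rng.normal(size=(k, n))
    time = rng.exponential(5.0, size=n) + 1e-3
    event = (rng.random(n) < event_rate).astype(int)
    if event.sum() == 0:  # guarantee at least one event
        event[int(rng.integers(n))] = 1
    return make_cohort(expr, time, event)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def toy_cohort():
    """5 patients, expression order g0: S0<S1<S2<S3<S4."""
    return make_cohort(
        expr=[[0.1, 0.4, 1.2, 2.5, 3.3]],
        time=[3.0, 1.0, 4.0, 2.0, 5.0],
        event=[1, 1, 0, 1, 0],
    )
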