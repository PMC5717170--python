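"""Two-group log-rank test reported as a signed z-score.

The statistic follows the classical Mantel–Haenszel construction: at every
distinct event time the observed number of events in the "high" group is
compared with its expectation under the hypergeometric null, and the
differences are pooled over time.  The score is reported as

    z = -(O_H - E_H) / sqrt(V)

so that a *negative* z means the high-expression group experienced more
events than expected, i.e. high expression is associated with higher risk.
This sign convention is shared by every partition element of the IPP matrix.

Numerical note: the per-time numerator is computed as the integer cross-term
``(d_H * n_L - d_L * n_H) / n`` (algebraically equal to ``d_H - d * n_H / n``)
and the variance via the symmetric product ``n_H * n_L``.  Both are exactly
antisymmetric / symmetric under swapping the group labels in floating point,
which makes label-swap antisymmetry of z hold bit-for-bit, not just
approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from scipy.stats import norm

from .errors import EmptyGroupError, MissingDirectionError

__all__ = ["SurvivalGroup", "LogrankResult", "logrank_z", "logrank_p"]


@dataclass(frozen=True)
class SurvivalGroup:
    """Right-censored survival records for one group of patients.

    Parameters
    ----------
    time
        Positive follow-up times (any consistent unit).
    event
        1 if the event was observed at ``time``, 0 if censored there.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=np.int64)
        if t.shape != e.shape or t.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if t.size and not np.all(np.isfinite(t) & (t > 0)):
            raise ValueError("survival times must be finite and positive")
        if not np.all((e == 0) | (e == 1)):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    @classmethod
    def from_records(cls, records: Iterable[tuple[float, int]]) -> "SurvivalGroup":
        recs = list(records)
        if recs:
            t, e = zip(*recs)
        else:
            t, e = (), ()
        return cls(np.asarray(t, dtype=float), np.asarray(e, dtype=np.int64))

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class LogrankResult:
    """Signed log-rank z-score with its ingredients.

    ``z = -(observed_high - expected_high)/sqrt(variance)``; when the variance
    is zero (no events, or fully degenerate risk sets) the result is the
    degenerate z = 0 with ``degenerate=True``.
    """

    z: float
    observed_high: float
    expected_high: float
    variance: float
    degenerate: bool = field(default=False)


def logrank_z(high: SurvivalGroup, low: SurvivalGroup) -> LogrankResult:
    """Log-rank comparison of ``high`` vs ``low``, signed so that negative z
    means the high group is at higher risk.

    Ties between events and censorings at the same time are resolved the
    standard way: all subjects with observed time >= t are at risk at t, so
    censorings at t happen after the events at t.  The variance uses the
    hypergeometric tie correction ``(n_t - d_t)/(n_t - 1)``.
    """
    if len(high) == 0 or len(low) == 0:
        raise EmptyGroupError("both survival groups must be non-empty")

    times = np.concatenate([high.time, low.time])
    events = np.concatenate([high.event, low.event])
    in_high = np.zeros(times.size, dtype=np.int64)
    in_high[: len(high)] = 1

    ut, tidx = np.unique(times, return_inverse=True)
    m = ut.size
    # per-time counts; at-risk = suffix sums over the ascending time grid
    d = np.bincount(tidx, weights=events, minlength=m).astype(np.int64)
    d_h = np.bincount(tidx, weights=events * in_high, minlength=m).astype(np.int64)
    c_all = np.bincount(tidx, minlength=m)
    c_high = np.bincount(tidx, weights=in_high, minlength=m).astype(np.int64)
    n_at = np.cumsum(c_all[::-1])[::-1]
    nh_at = np.cumsum(c_high[::-1])[::-1]

    u = 0.0  # O_H - E_H, accumulated in ascending time order
    v = 0.0
    e_h = 0.0
    for t in range(m):
        dt = int(d[t])
        if dt == 0:
            continue
        nt = int(n_at[t])
        nht = int(nh_at[t])
        nlt = nt - nht
        dht = int(d_h[t])
        dlt = dt - dht
        u += (dht * nlt - dlt * nht) / nt
        e_h += dt * nht / nt
        if nt > 1:
            v += (dt * nht * nlt * (nt - dt)) / (nt * nt * (nt - 1))

    o_h = float(high.event.sum())
    if v > 0.0:
        return LogrankResult(z=-u / np.sqrt(v), observed_high=o_h,
                             expected_high=e_h, variance=v)
    return LogrankResult(z=0.0, observed_high=o_h, expected_high=e_h,
                         variance=0.0, degenerate=True)


def logrank_p(
    result: LogrankResult,
    sidedness: Literal["one", "two"] = "two",
    direction: int | str | None = None,
) -> float:
    """P-value for a :class:`LogrankResult`.

    Two-sided: ``2 * Phi(-|z|)``.  One-sided: the caller must state the
    alternative via ``direction`` — ``-1``/"negative" for "high group at
    higher risk" (alternative z < 0), ``+1``/"positive" for the reverse.
    """
    z = result.z
    if sidedness == "two":
        return float(2.0 * norm.cdf(-abs(z)))
    if sidedness != "one":
        raise ValueError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    if direction is None:
        raise MissingDirectionError("one-sided p-value requires a direction")
    if isinstance(direction, str):
        key = direction.lower()
        if key in ("negative", "high_risk", "less"):
            s = -1
        elif key in ("positive", "low_risk", "greater"):
            s = 1
        else:
            raise MissingDirectionError(f"unrecognised direction {direction!r}")
    else:
        s = 1 if direction > 0 else -1
    # alternative "z has sign s": small p when z lies far on that side
    return float(norm.cdf(-s * z))
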