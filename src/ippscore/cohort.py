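"""Expression/clinical input handling and cohort assembly.

Readers accept plain or gzip-compressed TSV.  Expression tables are genes x
samples with the gene identifier in the first column; clinical tables are one
row per sample with ``sample_id``, ``time``, ``event`` and optional receptor
statuses (``er``/``pr``/``her2`` coded pos/neg/NA), CNA calls and mutation
flags.  Joins and all outputs are ordered by sample id so repeated runs are
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIdentifierError,
    EmptyCohortError,
    EmptyGeneSetError,
    InvalidCNACallError,
    NonNumericValueError,
)
from .logrank import SurvivalGroup

logger = logging.getLogger("ippscore")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "Cohort",
    "SurvivalGroup",
    "read_expression",
    "read_clinical",
    "write_expression",
    "build_cohort",
    "stratify_by_subtype",
    "filter_min_cohort_size",
    "filter_invariant_genes",
    "collapse_cna_states",
    "split_by_mutation",
]

SUBTYPE_LUMINAL = "luminal"
SUBTYPE_HER2 = "her2_enriched"
SUBTYPE_TNBC = "triple_negative"

#: five-level copy-number calls -> three analysis groups
CNA_COLLAPSE: dict[str, str] = {
    "homozygous deletion": "deletion",
    "hemizygous deletion": "deletion",
    "neutral/no change": "normal",
    "gain": "amplification",
    "high-level amplification": "amplification",
}
#: GISTIC-style integer calls accepted as synonyms
_CNA_NUMERIC = {-2: "homozygous deletion", -1: "hemizygous deletion",
                0: "neutral/no change", 1: "gain", 2: "high-level amplification"}


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray  # shape (K, N), float64

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        vals = np.asarray(self.values, dtype=float)
        if len(set(genes)) != len(genes):
            raise DuplicateIdentifierError("duplicate gene identifiers")
        if len(set(samples)) != len(samples):
            raise DuplicateIdentifierError("duplicate sample identifiers")
        if vals.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        if vals.size and not np.all(np.isfinite(vals)):
            raise NonNumericValueError("expression matrix contains non-finite values")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_ids.index(str(gene))]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {s: k for k, s in enumerate(self.sample_ids)}
        idx = [pos[str(s)] for s in sample_ids]
        return ExpressionMatrix(self.gene_ids, tuple(sample_ids), self.values[:, idx])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {g: k for k, g in enumerate(self.gene_ids)}
        idx = [pos[str(g)] for g in gene_ids]
        return ExpressionMatrix(tuple(gene_ids), self.sample_ids, self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class ClinicalTable:
    """Per-sample clinical annotations (survival plus optional covariates)."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise DuplicateIdentifierError("duplicate sample identifiers in clinical table")
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"clinical table lacks required columns: {sorted(missing)}")
        object.__setattr__(self, "data", df)

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.data.index)


@dataclass(frozen=True)
class Cohort:
    """Expression matrix aligned with survival outcomes for one dataset.

    ``expression`` column order, ``time`` and ``event`` refer to the same
    patients in the same order.
    """

    expression: ExpressionMatrix
    time: np.ndarray
    event: np.ndarray
    endpoint: str = "DMFS"
    name: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=np.int64)
        n = self.expression.n_samples
        if t.shape != (n,) or e.shape != (n,):
            raise ValueError("survival arrays must align with expression samples")
        if t.size and not np.all(np.isfinite(t) & (t > 0)):
            raise ValueError("survival times must be finite and positive")
        if not np.all((e == 0) | (e == 1)):
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    @property
    def n_patients(self) -> int:
        return self.expression.n_samples

    @property
    def n_genes(self) -> int:
        return self.expression.n_genes

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return self.expression.sample_ids

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.expression.gene_ids

    def survival_group(self, mask: np.ndarray | None = None) -> SurvivalGroup:
        if mask is None:
            return SurvivalGroup(self.time, self.event)
        return SurvivalGroup(self.time[mask], self.event[mask])

    def take(self, indices: Sequence[int], name: str | None = None) -> "Cohort":
        """Cohort restricted to ``indices`` (duplicates allowed, e.g. for
        bootstrap draws; duplicated samples get a ``#k`` suffix)."""
        idx = np.asarray(indices, dtype=np.intp)
        ids = [self.sample_ids[i] for i in idx]
        seen: dict[str, int] = {}
        uniq = []
        for s in ids:
            k = seen.get(s, 0)
            uniq.append(s if k == 0 else f"{s}#{k}")
            seen[s] = k + 1
        expr = ExpressionMatrix(self.gene_ids, tuple(uniq), self.expression.values[:, idx])
        return Cohort(expr, self.time[idx], self.event[idx], self.endpoint,
                      name if name is not None else self.name)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression(path, dialect: Mapping | None = None) -> ExpressionMatrix:
    """Read a genes x samples expression TSV (first column = gene id,
    header row = sample ids; gzip accepted)."""
    opts = {"sep": "\t", "index_col": 0, "compression": "infer"}
    if dialect:
        opts.update(dialect)
    df = pd.read_csv(path, **opts)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise DuplicateIdentifierError(f"duplicate gene rows: {dups[:5]}")
    if df.columns.has_duplicates:
        raise DuplicateIdentifierError("duplicate sample columns")
    try:
        body = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise NonNumericValueError(f"non-numeric expression cell: {exc}") from exc
    vals = body.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise NonNumericValueError(
            f"missing/non-finite expression at gene {df.index[bad[0]]!r}, "
            f"sample {df.columns[bad[1]]!r}"
        )
    return ExpressionMatrix(tuple(map(str, df.index)), tuple(map(str, df.columns)), vals)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")


def read_clinical(path, dialect: Mapping | None = None) -> ClinicalTable:
    """Read a per-sample clinical TSV with at least sample_id/time/event."""
    opts = {"sep": "\t", "compression": "infer"}
    if dialect:
        opts.update(dialect)
    df = pd.read_csv(path, **opts)
    if "sample_id" not in df.columns:
        raise ValueError("clinical table lacks a sample_id column")
    df["sample_id"] = df["sample_id"].astype(str)
    df = df.set_index("sample_id")
    for col in ("er", "pr", "her2"):
        if col in df.columns:
            df[col] = df[col].astype("string").str.lower()
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# cohort assembly and filters
# ---------------------------------------------------------------------------

def build_cohort(
    expr: ExpressionMatrix,
    clin: ClinicalTable,
    endpoint: str = "DMFS",
    name: str = "",
) -> Cohort:
    """Inner-join expression and clinical records into a cohort.

    Samples without a valid ``(time, event)`` pair are dropped: missing or
    non-finite times, times <= 0 (logged), and event flags outside {0, 1}.
    The joined cohort is sorted by sample id.
    """
    shared = sorted(set(expr.sample_ids) & set(clin.data.index))
    if not shared:
        raise EmptyCohortError("expression and clinical tables share no samples")

    sub = clin.data.loc[shared, ["time", "event"]]
    time = pd.to_numeric(sub["time"], errors="coerce").to_numpy(dtype=float)
    event = pd.to_numeric(sub["event"], errors="coerce").to_numpy(dtype=float)
    valid = np.isfinite(time) & np.isfinite(event) & ((event == 0) | (event == 1))
    zero_t = valid & (time <= 0)
    if zero_t.any():
        logger.warning(
            "%s: dropping %d sample(s) with follow-up time <= 0",
            name or "cohort", int(zero_t.sum()),
        )
    valid &= time > 0
    kept = [s for s, ok in zip(shared, valid) if ok]
    if not kept:
        raise EmptyCohortError("no sample has valid survival for the endpoint")
    mask = np.asarray(valid)
    return Cohort(
        expr.subset_samples(kept),
        time[mask],
        event[mask].astype(np.int64),
        endpoint=endpoint,
        name=name,
    )


def _status(value) -> str:
    if value is None or (isinstance(value, float) and np.isnan(value)) or pd.isna(value):
        return "na"
    v = str(value).strip().lower()
    if v in ("pos", "positive", "+", "1"):
        return "pos"
    if v in ("neg", "negative", "-", "0"):
        return "neg"
    return "na"


def stratify_by_subtype(cohort: Cohort, statuses) -> dict[str, Cohort]:
    """Split a cohort into the three receptor-defined molecular subtypes.

    luminal = ER+ and PR+ (HER2 not consulted); HER2-enriched = ER-, PR-,
    HER2+; triple-negative = ER-, PR-, HER2-.  A sample with any *required*
    status unknown is assigned to no subtype.  ``statuses`` is a
    :class:`ClinicalTable` or a DataFrame indexed by sample id with er/pr/her2
    columns.
    """
    df = statuses.data if isinstance(statuses, ClinicalTable) else statuses
    missing = set(cohort.sample_ids) - set(map(str, df.index))
    if missing:
        raise ValueError(f"receptor statuses missing for samples: {sorted(missing)[:5]}")

    members: dict[str, list[int]] = {SUBTYPE_LUMINAL: [], SUBTYPE_HER2: [], SUBTYPE_TNBC: []}
    for i, s in enumerate(cohort.sample_ids):
        row = df.loc[s]
        er, pr = _status(row.get("er")), _status(row.get("pr"))
        her2 = _status(row.get("her2"))
        if er == "pos" and pr == "pos":
            members[SUBTYPE_LUMINAL].append(i)
        elif er == "neg" and pr == "neg" and her2 == "pos":
            members[SUBTYPE_HER2].append(i)
        elif er == "neg" and pr == "neg" and her2 == "neg":
            members[SUBTYPE_TNBC].append(i)
        # anything else (unknown required status) stays unassigned

    out = {}
    for label, idx in members.items():
        sub_name = f"{cohort.name}:{label}" if cohort.name else label
        out[label] = cohort.take(idx, name=sub_name)
    return out


def filter_min_cohort_size(cohorts: Mapping[str, Cohort], min_n: int = 20) -> dict[str, Cohort]:
    """Keep only cohorts with at least ``min_n`` patients (default 20)."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    dropped = {k: c.n_patients for k, c in cohorts.items() if c.n_patients < min_n}
    if dropped:
        logger.info("excluding %d cohort(s) below %d patients: %s",
                    len(dropped), min_n, dropped)
    return {k: c for k, c in cohorts.items() if c.n_patients >= min_n}


def _round_sig(x: np.ndarray, sig: int = 6) -> np.ndarray:
    """Round to ``sig`` significant digits (elementwise, zeros preserved)."""
    out = np.asarray(x, dtype=float).copy()
    nz = out != 0
    mag = np.floor(np.log10(np.abs(out[nz])))
    scale = 10.0 ** (sig - 1 - mag)
    out[nz] = np.round(out[nz] * scale) / scale
    return out


def filter_invariant_genes(cohort: Cohort, modal_fraction: float = 0.5) -> Cohort:
    """Drop genes whose expression is nearly constant across the cohort.

    A gene is removed when its most frequent value — values compared after
    rounding to 6 significant digits — occurs in strictly more than
    ``modal_fraction`` of the samples.  Such genes cannot support meaningful
    high/low partitions and would flood the IPP matrix with tied thresholds.
    """
    if not 0 < modal_fraction <= 1:
        raise ValueError("modal_fraction must be in (0, 1]")
    n = cohort.n_patients
    keep: list[str] = []
    for g, row in zip(cohort.gene_ids, cohort.expression.values):
        _, counts = np.unique(_round_sig(row), return_counts=True)
        if counts.max() <= modal_fraction * n:
            keep.append(g)
    if not keep:
        raise EmptyGeneSetError("invariant-gene filter removed every gene")
    if len(keep) < cohort.n_genes:
        logger.info("%s: invariant-gene filter removed %d of %d genes",
                    cohort.name or "cohort", cohort.n_genes - len(keep), cohort.n_genes)
    expr = cohort.expression.subset_genes(keep)
    return replace(cohort, expression=expr)


# ---------------------------------------------------------------------------
# CNA / mutation groupings
# ---------------------------------------------------------------------------

def collapse_cna_states(calls) -> dict[str, str] | pd.Series:
    """Collapse five-level copy-number calls to deletion/normal/amplification.

    homo-/hemizygous deletion -> deletion; neutral/no change -> normal;
    gain / high-level amplification -> amplification.  GISTIC-style integers
    -2..2 are accepted as synonyms of the five levels.
    """
    def one(call):
        c = call
        if isinstance(c, (int, np.integer)):
            if int(c) not in _CNA_NUMERIC:
                raise InvalidCNACallError(f"unknown CNA call {call!r}")
            c = _CNA_NUMERIC[int(c)]
        key = str(c).strip().lower()
        if key not in CNA_COLLAPSE:
            raise InvalidCNACallError(f"unknown CNA call {call!r}")
        return CNA_COLLAPSE[key]

    if isinstance(calls, pd.Series):
        return calls.map(one)
    if isinstance(calls, Mapping):
        return {k: one(v) for k, v in calls.items()}
    return {k: one(v) for k, v in enumerate(calls)}  # pragma: no cover


def split_by_mutation(
    records: pd.DataFrame,
    gene: str,
    samples: Iterable[str],
) -> tuple[list[str], list[str]]:
    """Partition ``samples`` into (mutated, none) for one gene.

    ``records`` lists one row per sample-gene mutation call with columns
    ``sample_id`` and ``gene_id`` (a consequence-type column may be present
    but any record counts).  Samples with at least one record for ``gene``
    form the mutation group; every other cohort sample goes to the none
    group.
    """
    samples = [str(s) for s in samples]
    if len(records):
        hits = set(records.loc[records["gene_id"].astype(str) == str(gene),
                               "sample_id"].astype(str))
    else:
        hits = set()
    mutated = [s for s in samples if s in hits]
    none = [s for s in samples if s not in hits]
    return mutated, none
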