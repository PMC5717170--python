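"""Cohort assembly: IO, joins, subtype stratification, gene/cohort filters,
CNA collapsing, mutation grouping."""

import gzip

import numpy as np
import pandas as pd
import pytest

from ippscore import (
    ClinicalTable,
    build_cohort,
    collapse_cna_states,
    filter_invariant_genes,
    filter_min_cohort_size,
    read_clinical,
    read_expression,
    split_by_mutation,
    stratify_by_subtype,
)
from ippscore.cohort import SUBTYPE_HER2, SUBTYPE_LUMINAL, SUBTYPE_TNBC
from ippscore.errors import (
    DuplicateIdentifierError,
    EmptyCohortError,
    EmptyGeneSetError,
    InvalidCNACallError,
    NonNumericValueError,
)
from conftest import make_cohort

EXPR_TSV = (
    "gene_id\tA\tB\tC\tD\n"
    "g1\t0.1\t0.2\t0.3\t0.4\n"
    "g2\t1.0\t1.1\t1.2\t1.3\n"
    "g3\t-1.0\t0.0\t1.0\t2.0\n"
)


def clinical_frame(**cols) -> ClinicalTable:
    df = pd.DataFrame(cols)
    df["sample_id"] = df["sample_id"].astype(str)
    return ClinicalTable(df.set_index("sample_id"))


class TestReadExpression:
    def test_dimensions(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(EXPR_TSV)
        m = read_expression(p)
        assert m.n_genes == 3 and m.n_samples == 4
        assert m.gene_ids == ("g1", "g2", "g3")
        assert m.row("g2")[2] == 1.2

    def test_gzip_accepted(self, tmp_path):
        p = tmp_path / "e.tsv.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(EXPR_TSV)
        assert read_expression(p).n_samples == 4

    def test_duplicate_gene_row_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tA\tB\ng1\t1\t2\ng1\t3\t4\n")
        with pytest.raises(DuplicateIdentifierError):
            read_expression(p)

    def test_na_cell_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tA\tB\ng1\t1\tNA\n")
        with pytest.raises(NonNumericValueError):
            read_expression(p)

    def test_text_cell_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene_id\tA\tB\ng1\t1\tlow\n")
        with pytest.raises(NonNumericValueError):
            read_expression(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_expression(tmp_path / "absent.tsv")


class TestBuildCohort:
    def _expr(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text(EXPR_TSV)
        return read_expression(p)

    def test_inner_join_on_valid_survival(self, tmp_path):
        expr = self._expr(tmp_path)
        clin = clinical_frame(sample_id=["A", "C", "Z"], time=[5.0, 2.0, 9.0],
                              event=[1, 0, 1])
        cohort = build_cohort(expr, clin)
        assert cohort.sample_ids == ("A", "C")
        assert cohort.n_patients == 2
        # brute-force check: join size = |valid clinical ∩ expression samples|
        assert cohort.n_patients == len({"A", "C", "Z"} & {"A", "B", "C", "D"})

    def test_missing_time_excludes_sample(self, tmp_path):
        expr = self._expr(tmp_path)
        clin = clinical_frame(sample_id=["A", "B"], time=[np.nan, 3.0], event=[1, 1])
        assert build_cohort(expr, clin).sample_ids == ("B",)

    def test_zero_time_dropped_with_warning(self, tmp_path, caplog):
        expr = self._expr(tmp_path)
        clin = clinical_frame(sample_id=["A", "B"], time=[0.0, 3.0], event=[1, 1])
        with caplog.at_level("WARNING", logger="ippscore"):
            cohort = build_cohort(expr, clin)
        assert cohort.sample_ids == ("B",)
        assert any("time" in rec.message for rec in caplog.records)

    def test_disjoint_samples_raise(self, tmp_path):
        expr = self._expr(tmp_path)
        clin = clinical_frame(sample_id=["X", "Y"], time=[1.0, 2.0], event=[0, 1])
        with pytest.raises(EmptyCohortError):
            build_cohort(expr, clin)

    def test_output_sorted_by_sample_id(self, tmp_path):
        expr = self._expr(tmp_path)
        clin = clinical_frame(sample_id=["D", "A", "B"], time=[1, 2, 3], event=[1, 1, 0])
        assert build_cohort(expr, clin).sample_ids == ("A", "B", "D")


class TestStratifyBySubtype:
    def _cohort_and_statuses(self):
        cohort = make_cohort(np.arange(6.0)[None, :], [1, 2, 3, 4, 5, 6],
                             [1, 0, 1, 0, 1, 0])
        statuses = pd.DataFrame(
            {"er": ["pos", "pos", "neg", "neg", "neg", "neg"],
             "pr": ["pos", "pos", "neg", "neg", "neg", "neg"],
             "her2": ["pos", "neg", "pos", "pos", "neg", "neg"]},
            index=list(cohort.sample_ids))
        return cohort, statuses

    def test_two_per_subtype(self):
        cohort, statuses = self._cohort_and_statuses()
        parts = stratify_by_subtype(cohort, statuses)
        assert {k: v.n_patients for k, v in parts.items()} == {
            SUBTYPE_LUMINAL: 2, SUBTYPE_HER2: 2, SUBTYPE_TNBC: 2}

    def test_her2_not_consulted_for_luminal(self):
        cohort, statuses = self._cohort_and_statuses()
        parts = stratify_by_subtype(cohort, statuses)
        # S000 is ER+/PR+/HER2+ and must land in luminal
        assert "S000" in parts[SUBTYPE_LUMINAL].sample_ids

    def test_unknown_required_status_unassigned(self):
        cohort, statuses = self._cohort_and_statuses()
        statuses.loc["S004", "her2"] = "NA"  # ER-/PR-/HER2 unknown
        parts = stratify_by_subtype(cohort, statuses)
        assigned = set().union(*(p.sample_ids for p in parts.values()))
        assert "S004" not in assigned

    def test_outputs_pairwise_disjoint_subsets_of_input(self):
        cohort, statuses = self._cohort_and_statuses()
        parts = list(stratify_by_subtype(cohort, statuses).values())
        ids = [set(p.sample_ids) for p in parts]
        assert ids[0] | ids[1] | ids[2] <= set(cohort.sample_ids)
        assert not (ids[0] & ids[1] or ids[0] & ids[2] or ids[1] & ids[2])


class TestCohortFilters:
    def test_min_size_boundary(self):
        cohorts = {
            f"d{n}": make_cohort(np.random.default_rng(n).normal(size=(1, n)),
                                 np.ones(n), np.ones(n, int))
            for n in (19, 20, 45)
        }
        kept = filter_min_cohort_size(cohorts, min_n=20)
        assert set(kept) == {"d20", "d45"}
        assert filter_min_cohort_size(cohorts, min_n=1) == cohorts
        assert filter_min_cohort_size({}, min_n=20) == {}

    def test_invariant_gene_removal(self):
        n = 10
        rows = np.vstack([
            np.full(n, 3.14),                              # constant: removed
            np.arange(n, dtype=float),                     # all distinct: kept
            np.r_[np.full(6, 1.0), [2, 3, 4, 5.0]],        # modal 6/10 > 0.5: removed
            np.r_[np.full(5, 1.0), [2, 3, 4, 5, 6.0]],     # modal 5/10 = 0.5: kept
        ])
        cohort = make_cohort(rows, np.arange(1, n + 1.0), np.ones(n, int))
        kept = filter_invariant_genes(cohort, modal_fraction=0.5)
        assert kept.gene_ids == ("g1", "g3")

    def test_sig_digit_rounding_merges_near_ties(self):
        # values differing only in the 8th significant digit count as one
        row = np.array([1.0000000, 1.00000001, 1.00000002, 2.0, 3.0])
        cohort = make_cohort(row[None, :], np.arange(1, 6.0), np.ones(5, int))
        with pytest.raises(EmptyGeneSetError):
            filter_invariant_genes(cohort, modal_fraction=0.5)

    def test_idempotent(self, rng):
        cohort = make_cohort(rng.normal(size=(5, 12)), np.arange(1, 13.0),
                             np.ones(12, int))
        once = filter_invariant_genes(cohort)
        twice = filter_invariant_genes(once)
        assert once.gene_ids == twice.gene_ids


class TestCNAAndMutation:
    def test_five_levels_collapse_to_three(self):
        levels = ["homozygous deletion", "hemizygous deletion",
                  "neutral/no change", "gain", "high-level amplification"]
        out = collapse_cna_states({f"s{i}": lv for i, lv in enumerate(levels)})
        assert list(out.values()) == ["deletion", "deletion", "normal",
                                      "amplification", "amplification"]
        assert set(out.values()) == {"deletion", "normal", "amplification"}

    def test_numeric_synonyms(self):
        assert collapse_cna_states({"s": -1})["s"] == "deletion"
        assert collapse_cna_states({"s": 2})["s"] == "amplification"

    def test_unknown_call_raises(self):
        with pytest.raises(InvalidCNACallError):
            collapse_cna_states({"s": "partial gain"})

    def test_mutation_partition(self):
        records = pd.DataFrame({
            "sample_id": ["P1", "P2", "P2"],
            "gene_id": ["TP53", "BRCA1", "TP53"],
            "consequence_type": ["missense", "frameshift", "stop_gained"],
        })
        mutated, none = split_by_mutation(records, "TP53", ["P1", "P2", "P3"])
        assert mutated == ["P1", "P2"] and none == ["P3"]
        # records only for other genes -> none group
        mutated, none = split_by_mutation(records, "EGFR", ["P1", "P2"])
        assert mutated == [] and none == ["P1", "P2"]
        # no records at all
        mutated, none = split_by_mutation(records.iloc[:0], "TP53", ["P1"])
        assert mutated == [] and none == ["P1"]


class TestReadClinical:
    def test_roundtrip(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\ttime\tevent\ter\npr1\t10\t1\tpos\n")
        clin = read_clinical(p)
        assert clin.sample_ids == ("pr1",)
        assert clin.data.loc["pr1", "er"] == "pos"

    def test_missing_required_column(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("sample_id\ttime\npr1\t10\n")
        with pytest.raises(ValueError):
            read_clinical(p)
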