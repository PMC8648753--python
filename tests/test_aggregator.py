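import itertools

import numpy as np
import pytest

from stringagg.aggregator import (
    Sentinel,
    aggregate,
    build_results,
    build_summary,
    check_consistency,
    merge_by_label,
    merge_directions,
    read_results,
    read_summary,
    summarize_all_kinds,
    write_results,
    write_summary,
)
from stringagg.errors import InputError, StringaggError
from stringagg.string_client import ComparisonEnrichment

from .conftest import make_record


def comparison(label, records, kind="KEGG", direction="MERGED"):
    return ComparisonEnrichment(label=label, direction=direction, records={kind: records})


class TestMergeDirections:
    def test_term_in_both_directions_keeps_lowest_fdr_and_gene_union(self):
        up = [make_record("T", 0.01, genes=("A", "B"))]
        down = [make_record("T", 0.002, genes=("C",))]
        (merged,) = merge_directions(up, down)
        assert merged.fdr == 0.002
        assert set(merged.gene_labels) == {"A", "B", "C"}
        assert merged.number_of_genes == 3

    def test_single_direction_passes_through(self):
        up = [make_record("T1", 0.01), make_record("T2", 0.02)]
        assert merge_directions(up, []) == up
        assert merge_directions([], up) == up

    def test_kind_mismatch_is_a_logic_error(self):
        with pytest.raises(StringaggError):
            merge_directions(
                [make_record("a", 0.01, kind="KEGG")],
                [make_record("b", 0.01, kind="RCTM")],
            )

    def test_random_overlapping_lists_match_elementwise_min_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            terms_up = rng.choice(30, size=rng.integers(1, 15), replace=False)
            terms_down = rng.choice(30, size=rng.integers(1, 15), replace=False)
            up = [make_record(f"t{t}", float(f"{rng.uniform(1e-6, 0.04):.6g}"))
                  for t in terms_up]
            down = [make_record(f"t{t}", float(f"{rng.uniform(1e-6, 0.04):.6g}"))
                    for t in terms_down]
            merged = {r.term_id: r.fdr for r in merge_directions(up, down)}
            # brute-force min over the two lists, term by term
            oracle: dict[str, float] = {}
            for rec in itertools.chain(up, down):
                oracle[rec.term_id] = min(oracle.get(rec.term_id, 1.0), rec.fdr)
            assert merged == oracle


class TestBuildSummary:
    def test_single_condition_sentinel(self):
        comps = [comparison("c1", [make_record("T", 0.01, genes=("A", "B"))])]
        (row,) = build_summary(comps, "KEGG")
        assert row.occurrence == 1
        assert row.common_genes is Sentinel.SINGLE_CONDITION
        assert row.all_genes == {"A", "B"}

    def test_disjoint_gene_sets_give_no_common_gene(self):
        comps = [
            comparison("c1", [make_record("T", 0.01, genes=("A",))]),
            comparison("c2", [make_record("T", 0.02, genes=("B",))]),
        ]
        (row,) = build_summary(comps, "KEGG")
        assert row.occurrence == 2
        assert row.common_genes is Sentinel.NO_COMMON_GENE
        assert row.all_genes == {"A", "B"}
        assert row.min_fdr == 0.01

    def test_duplicate_labels_rejected(self):
        comps = [comparison("c1", [make_record("T", 0.01)])] * 2
        with pytest.raises(InputError):
            build_summary(comps, "KEGG")

    def test_planted_overlaps_match_set_algebra_oracle(self):
        """Four comparisons with overlapping planted gene sets: every summary
        field equals a naive union/intersection/min recomputation."""
        rng = np.random.default_rng(3)
        labels = [f"c{i}" for i in range(4)]
        genes = [f"G{i}" for i in range(12)]
        raw: dict[str, dict[str, tuple[float, frozenset]]] = {}
        comps = []
        for lab in labels:
            records = []
            for t in range(6):
                if rng.random() < 0.4:
                    continue
                fdr = float(f"{rng.uniform(1e-6, 0.04):.6g}")
                gset = frozenset(rng.choice(genes, size=rng.integers(1, 6), replace=False))
                raw.setdefault(f"T{t}", {})[lab] = (fdr, gset)
                records.append(make_record(f"T{t}", fdr, genes=tuple(sorted(gset))))
            comps.append(comparison(lab, records))
        rows = {r.term_id: r for r in build_summary(comps, "KEGG")}
        assert set(rows) == set(raw)
        for term, per_comp in raw.items():
            row = rows[term]
            fdrs = [f for f, _ in per_comp.values()]
            sets = [s for _, s in per_comp.values()]
            assert row.min_fdr == min(fdrs)
            assert row.occurrence == len(per_comp)
            assert row.all_genes == frozenset().union(*sets)
            if len(per_comp) == 1:
                assert row.common_genes is Sentinel.SINGLE_CONDITION
            else:
                inter = frozenset.intersection(*sets)
                assert row.common_genes == (inter or Sentinel.NO_COMMON_GENE)


class TestBuildResults:
    def test_absent_comparisons_get_fdr_exactly_one(self):
        comps = [
            comparison("c1", [make_record("T", 0.01)]),
            comparison("c2", []),
            comparison("c3", []),
        ]
        (row,) = build_results(comps, "KEGG")
        assert row.fdr_by_comparison == {"c1": 0.01, "c2": 1.0, "c3": 1.0}
        assert row.fdr_by_comparison["c2"] == 1  # exact default, not approximate

    def test_column_order_follows_input_comparisons(self):
        comps = [comparison(lab, [make_record("T", 0.01)]) for lab in ("b", "a", "c")]
        (row,) = build_results(comps, "KEGG")
        assert list(row.fdr_by_comparison) == ["b", "a", "c"]
        assert all(v != 1 for v in row.fdr_by_comparison.values())

    def test_matrix_matches_per_term_lookup_oracle(self):
        rng = np.random.default_rng(9)
        labels = [f"c{i}" for i in range(5)]
        planted: dict[tuple[str, str], float] = {}
        comps = []
        for lab in labels:
            records = []
            for t in range(8):
                if rng.random() < 0.5:
                    continue
                fdr = float(f"{rng.uniform(1e-8, 0.049):.6g}")
                planted[(f"T{t}", lab)] = fdr
                records.append(make_record(f"T{t}", fdr))
            comps.append(comparison(lab, records))
        rows = {r.term_id: r for r in build_results(comps, "KEGG")}
        terms = {t for t, _ in planted}
        assert set(rows) == terms
        for term in terms:
            for lab in labels:
                expected = planted.get((term, lab), 1.0)
                assert rows[term].fdr_by_comparison[lab] == expected


class TestConsistencyAndModes:
    def test_summary_and_results_are_mutually_consistent(self, small_dataset):
        from stringagg.string_client import DirectoryTransport, AnalysisSettings, fetch_enrichment
        from stringagg.de_input import parse_de_table, split_directions

        transport = DirectoryTransport(small_dataset["enrichment_dir"])
        enrichments = []
        for path in small_dataset["de_paths"]:
            table = parse_de_table(path)
            enrichments += fetch_enrichment(
                table.label, split_directions(table), AnalysisSettings(), transport
            )
        for kind, tables in summarize_all_kinds(enrichments).items():
            check_consistency(tables)  # raises on any violation

    def test_up_only_equals_separate_mode_when_down_is_empty(self):
        up_records = [make_record("T1", 0.01), make_record("T2", 0.003)]
        separate = [
            ComparisonEnrichment("c1", "UP", {"KEGG": up_records}),
            ComparisonEnrichment("c1", "DOWN", {}),
        ]
        up_only = [ComparisonEnrichment("c1", "UP", {"KEGG": up_records})]
        agg_a = aggregate(merge_by_label(separate), "KEGG")
        agg_b = aggregate(merge_by_label(up_only), "KEGG")
        assert agg_a.summary == agg_b.summary
        assert agg_a.results == agg_b.results

    def test_adding_a_comparison_is_monotone(self):
        """More comparisons never decrease occurrence, increase min FDR,
        shrink all_genes or grow common_genes."""
        rng = np.random.default_rng(17)
        comps = []
        for i in range(6):
            records = [
                make_record(f"T{t}", float(f"{rng.uniform(1e-6, 0.04):.6g}"),
                            genes=tuple(rng.choice([f"G{g}" for g in range(10)],
                                                   size=3, replace=False)))
                for t in range(4) if rng.random() < 0.7
            ]
            comps.append(comparison(f"c{i}", records))
        prev = {}
        for n in range(1, len(comps) + 1):
            rows = {r.term_id: r for r in build_summary(comps[:n], "KEGG")}
            for term, row in prev.items():
                assert rows[term].occurrence >= row.occurrence
                assert rows[term].min_fdr <= row.min_fdr
                assert rows[term].all_genes >= row.all_genes
                if isinstance(row.common_genes, frozenset) and isinstance(
                    rows[term].common_genes, frozenset
                ):
                    assert rows[term].common_genes <= row.common_genes
            prev = rows


class TestSerialization:
    def _summary_rows(self):
        comps = [
            comparison("c1", [make_record("T1", 0.01, genes=("A", "B")),
                              make_record("T2", 0.002, genes=("X",))]),
            comparison("c2", [make_record("T1", 0.03, genes=("B", "C")),
                              make_record("T3", 0.04, genes=("Q", "R"))]),
            comparison("c3", [make_record("T2", 0.001, genes=("Y",))]),
        ]
        return comps

    def test_summary_round_trip_and_sentinel_text(self, tmp_path):
        rows = build_summary(self._summary_rows(), "KEGG")
        path = tmp_path / "summary_KEGG.tsv"
        write_summary(rows, path)
        text = path.read_text()
        assert "n/a: just one condition" in text  # T3, one comparison
        assert "No common gene" in text  # T2, disjoint {X} and {Y}
        assert read_summary(path) == rows

    def test_results_round_trip(self, tmp_path):
        rows = build_results(self._summary_rows(), "KEGG")
        path = tmp_path / "results_KEGG.tsv"
        write_results(rows, path)
        assert read_results(path) == rows

    def test_round_trip_of_many_synthetic_rows(self, tmp_path):
        rng = np.random.default_rng(23)
        comps = []
        for i in range(5):
            records = [
                make_record(f"T{t}", float(f"{rng.uniform(1e-9, 0.04):.6g}"),
                            genes=tuple(f"G{g}" for g in rng.choice(20, size=4, replace=False)))
                for t in range(10) if rng.random() < 0.6
            ]
            comps.append(comparison(f"c{i}", records))
        summary = build_summary(comps, "KEGG")
        results = build_results(comps, "KEGG")
        write_summary(summary, tmp_path / "s.tsv")
        write_results(results, tmp_path / "r.tsv")
        assert read_summary(tmp_path / "s.tsv") == summary
        assert read_results(tmp_path / "r.tsv") == results
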