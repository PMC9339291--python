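"""Gene-set mapping, contingency tables, Fisher p-values, FDR and batch runs."""

from __future__ import annotations

import io
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from wormcat.annotation import AnnotationError, CategoryPath
from wormcat.enrichment import (
    ContingencyTable,
    EnrichmentConfig,
    MappingError,
    batch_run,
    bh_adjust,
    build_contingency,
    fisher_enrichment_p,
    map_genes,
    read_gene_list,
    run_enrichment,
)
from wormcat.synth import PlantedSignal, SyntheticSpec, generate_annotation_list, generate_rgs

from conftest import make_ann


def exact_tail(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exact upper-tail hypergeometric by integer enumeration."""
    N, K, n = a + b + c + d, a + c, a + b
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(a, min(K, n) + 1))
    return float(Fraction(num, comb(N, n)))


class TestReadGeneList:
    def test_order_preserved(self):
        ids = read_gene_list(io.StringIO("Wormbase ID\nWBGene3\nWBGene1\nWBGene2\n"))
        assert ids == ["WBGene3", "WBGene1", "WBGene2"]

    def test_blanks_skipped_and_whitespace_stripped(self):
        ids = read_gene_list(io.StringIO("Wormbase ID\n WBGene1 \n\nWBGene2\n"))
        assert ids == ["WBGene1", "WBGene2"]

    def test_duplicates_kept_at_read_time(self):
        ids = read_gene_list(io.StringIO("WBGene1\nWBGene1\n"))
        assert ids == ["WBGene1", "WBGene1"]

    def test_empty_file_is_fatal(self):
        with pytest.raises(Exception):
            read_gene_list(io.StringIO("Wormbase ID\n"))


class TestMapGenes:
    UNIVERSE = make_ann([(f"WBGene{i}", "A") for i in range(5)])

    def test_all_resolved(self):
        rgs = map_genes([f"WBGene{i}" for i in range(5)], self.UNIVERSE)
        assert len(rgs.mapped) == 5 and not rgs.unmapped

    def test_unknown_id_listed_verbatim(self):
        rgs = map_genes(["WBGene0", "WBGene1", "WBGene2", "X"], self.UNIVERSE)
        assert len(rgs.mapped) == 3 and rgs.unmapped == ["X"]

    def test_alias_collapsed_as_duplicate(self):
        # same gene as primary ID and as its sequence name (case-insensitive)
        rgs = map_genes(["WBGene1", "SEQ-WBGENE1"], self.UNIVERSE)
        assert rgs.mapped == {"WBGene1"} and rgs.duplicates_removed == 1

    def test_bookkeeping_identity(self):
        rgs = map_genes(["WBGene1", "WBGene1", "nope", "WBGene2"], self.UNIVERSE)
        assert len(rgs.mapped) + len(rgs.unmapped) + rgs.duplicates_removed == len(rgs.raw_ids)

    def test_zero_mapped_is_fatal_with_unmapped_attached(self):
        with pytest.raises(MappingError) as err:
            map_genes(["X", "Y"], self.UNIVERSE)
        assert err.value.unmapped == ["X", "Y"]


class TestContingency:
    def test_set_arithmetic_example(self):
        # 100-gene universe, category of 10, mapped RGS of 20 with overlap 6
        rows = [(f"g{i}", "TARGET" if i < 10 else "OTHER") for i in range(100)]
        universe = make_ann(rows)
        rgs_ids = [f"g{i}" for i in range(6)] + [f"g{i}" for i in range(50, 64)]
        rgs = map_genes(rgs_ids, universe)
        t = build_contingency(rgs, CategoryPath("TARGET"), 1, universe)
        assert (t.a, t.b, t.c, t.d) == (6, 14, 4, 76)

    def test_rgs_equal_to_universe(self):
        universe = make_ann([(f"g{i}", "T" if i < 3 else "O") for i in range(10)])
        rgs = map_genes([f"g{i}" for i in range(10)], universe)
        t = build_contingency(rgs, CategoryPath("T"), 1, universe)
        assert (t.a, t.b, t.c, t.d) == (3, 7, 0, 0)

    def test_disjoint_rgs(self):
        universe = make_ann([(f"g{i}", "T" if i < 3 else "O") for i in range(10)])
        rgs = map_genes([f"g{i}" for i in range(5, 10)], universe)
        assert build_contingency(rgs, CategoryPath("T"), 1, universe).a == 0

    def test_absent_category_is_named_in_error(self):
        universe = make_ann([("g1", "A")])
        rgs = map_genes(["g1"], universe)
        with pytest.raises(AnnotationError, match="NOPE"):
            build_contingency(rgs, CategoryPath("NOPE"), 1, universe)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(1, -1, 2, 3)


class TestFisher:
    def test_frozen_oracle_value(self):
        # exact tail = 894931/227539690, frozen from integer enumeration
        p = fisher_enrichment_p(ContingencyTable(6, 14, 4, 76))
        assert p == pytest.approx(0.0039330764667913545, rel=1e-12)
        assert p == pytest.approx(exact_tail(6, 14, 4, 76), rel=1e-12)

    def test_zero_overlap_gives_p_one(self):
        assert fisher_enrichment_p(ContingencyTable(0, 20, 10, 70)) == 1.0

    def test_saturated_table_enumeration(self):
        # only one of C(10,5) = 252 margin-fixed tables attains a = 5
        p = fisher_enrichment_p(ContingencyTable(5, 0, 0, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    @given(
        st.integers(min_value=1, max_value=40).flatmap(
            lambda N: st.tuples(
                st.just(N),
                st.integers(min_value=0, max_value=N),
                st.integers(min_value=0, max_value=N),
            )
        ),
        st.data(),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_overlap_with_margins_fixed(self, margins, data):
        N, K, n = margins
        lo, hi = max(0, K + n - N), min(K, n)
        a = data.draw(st.integers(min_value=lo, max_value=hi))
        p_a = fisher_enrichment_p(ContingencyTable(a, n - a, K - a, N - K - n + a))
        if a + 1 <= hi:
            p_next = fisher_enrichment_p(
                ContingencyTable(a + 1, n - a - 1, K - a - 1, N - K - n + a + 1)
            )
            assert p_next <= p_a + 1e-15


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037]) == pytest.approx([0.037])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_step_up_worked_example(self):
        # min over j>=i of p_(j) * m / j: 0.04*4/4 = 0.04 dominates every rank
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    def test_bonferroni_option(self):
        assert bh_adjust([0.01, 0.4], method="bonferroni") == pytest.approx([0.02, 0.8])

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.random(97)
        ours = bh_adjust(p)
        theirs = statsmodels.multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(ours, theirs, rtol=1e-12)

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_output_dominates_input_and_is_permutation_equivariant(self, pvals):
        adj = bh_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)
        perm = np.random.default_rng(0).permutation(len(pvals))
        adj_perm = bh_adjust(list(np.asarray(pvals)[perm]))
        np.testing.assert_allclose(adj_perm, adj[perm], rtol=1e-12)


class TestRunEnrichment:
    def test_whole_universe_rgs_scores_p_one_everywhere(self, synthetic_universe):
        rgs = map_genes([r.gene_id for r in synthetic_universe], synthetic_universe)
        res = run_enrichment(rgs, synthetic_universe)
        for level in (1, 2, 3):
            assert all(r.p == 1.0 for r in res.rows[level])
            assert not res.significant_rows(level)

    def test_planted_category_recovered(self, planted_spec, synthetic_universe):
        ids, truth = generate_rgs(planted_spec, synthetic_universe)
        rgs = map_genes(ids, synthetic_universe)
        res = run_enrichment(rgs, synthetic_universe)
        best = min(r.p_adjusted for r in res.rows[1])
        planted_row = next(
            r for r in res.rows[1] if r.category.cat1 == truth["planted_cat1"]
        )
        assert planted_row.p_adjusted == best

    def test_cat1_rgs_counts_partition_mapped_genes(self, planted_spec, synthetic_universe):
        ids, _ = generate_rgs(planted_spec, synthetic_universe)
        rgs = map_genes(ids, synthetic_universe)
        res = run_enrichment(rgs, synthetic_universe)
        assert sum(r.rgs_count for r in res.rows[1]) == len(rgs.mapped)

    def test_level_consistency(self, planted_spec, synthetic_universe):
        ids, _ = generate_rgs(planted_spec, synthetic_universe)
        res = run_enrichment(map_genes(ids, synthetic_universe), synthetic_universe)
        c1 = {r.category: r.rgs_count for r in res.rows[1]}
        c2 = {r.category: r.rgs_count for r in res.rows[2]}
        for row in res.rows[3]:
            if row.rgs_count:
                assert c2[row.category.truncate(2)] >= row.rgs_count
                assert c1[row.category.truncate(1)] >= row.rgs_count

    def test_shrinking_universe_changes_p(self, planted_spec, synthetic_universe):
        # dropping a category's genes from the universe (cf. an "assigned only"
        # background) changes the remaining categories' statistics
        from wormcat.annotation import derive_background

        ids, truth = generate_rgs(planted_spec, synthetic_universe)
        keep = [
            r.gene_id
            for r in synthetic_universe
            if r.path.cat1 != "SYNCAT 02"
        ]
        smaller, _ = derive_background(synthetic_universe, "subset", gene_ids=keep)
        res_all = run_enrichment(map_genes(ids, synthetic_universe), synthetic_universe)
        res_small = run_enrichment(map_genes(ids, smaller), smaller)
        p_all = {r.category: r.p for r in res_all.rows[1]}
        p_small = {r.category: r.p for r in res_small.rows[1]}
        changed = [
            c for c in p_small
            if c in p_all and p_small[c] != p_all[c]
        ]
        assert changed, "removing a category from the universe must alter p-values"
        # independent recount for one category confirms the new table
        cat = changed[0]
        rgs_small = map_genes(ids, smaller)
        t = build_contingency(rgs_small, cat, 1, smaller)
        assert fisher_enrichment_p(t) == pytest.approx(p_small[cat], rel=1e-12)

    def test_deterministic_csv_output(self, tmp_path, planted_spec, synthetic_universe):
        ids, _ = generate_rgs(planted_spec, synthetic_universe)
        res = run_enrichment(map_genes(ids, synthetic_universe), synthetic_universe)
        res.write(tmp_path / "a")
        res.write(tmp_path / "b")
        for name in ("cat1.csv", "cat2.csv", "cat3.csv", "rgs_and_categories.csv"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()


class TestBatch:
    def test_batch_of_one_equals_single_run(self, planted_spec, synthetic_universe):
        ids, _ = generate_rgs(planted_spec, synthetic_universe)
        single = run_enrichment(map_genes(ids, synthetic_universe, name="ds"), synthetic_universe)
        batch = batch_run([("ds", ids)], synthetic_universe)
        assert len(batch.results) == 1
        for level in (1, 2, 3):
            assert batch.results[0].rows[level] == single.rows[level]
        assert set(batch.combined["dataset"]) == {"ds"}
        assert len(batch.combined) == sum(len(single.rows[lv]) for lv in (1, 2, 3))

    def test_identical_sets_give_identical_rows(self, planted_spec, synthetic_universe):
        ids, _ = generate_rgs(planted_spec, synthetic_universe)
        batch = batch_run([("x", ids), ("y", ids)], synthetic_universe)
        cx = batch.combined[batch.combined.dataset == "x"].drop(columns="dataset")
        cy = batch.combined[batch.combined.dataset == "y"].drop(columns="dataset")
        assert cx.reset_index(drop=True).equals(cy.reset_index(drop=True))

    def test_each_planted_set_recovers_its_own_truth(self, synthetic_universe):
        sets = []
        truths = []
        for i, cat in enumerate(["SYNCAT 03", "SYNCAT 05", "SYNCAT 07"]):
            spec = SyntheticSpec(
                seed=11,  # same universe shape as the fixture
                planted=PlantedSignal(cat1=cat, category_size=100, rgs_size=50, fold=5.0),
            )
            ids, truth = generate_rgs(
                spec, synthetic_universe, rng=np.random.default_rng(100 + i)
            )
            sets.append((cat, ids))
            truths.append(truth)
        batch = batch_run(sets, synthetic_universe)
        for res, truth in zip(batch.results, truths):
            assert res.rows[1][0].category.cat1 == truth["planted_cat1"]

    def test_failing_set_logged_but_others_complete(self, synthetic_universe):
        good = [r.gene_id for r in synthetic_universe.records[:20]]
        batch = batch_run([("bad", ["XXX"]), ("good", good)], synthetic_universe)
        assert len(batch.results) == 1 and batch.results[0].rgs.name == "good"
        assert any(line.startswith("FAILED bad") for line in batch.log)
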