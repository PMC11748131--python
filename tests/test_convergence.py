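import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoconverge import convergence as cv
from evoconverge.curation import curate
from evoconverge.model import (
    AssignmentKind,
    GeneAnnotation,
    MutationRecord,
    MutationType,
)


def _gene(gid, start, end, strand="+", cds=None):
    return GeneAnnotation(gid, "chr", start, end, strand, cds_sequence=cds)


class TestGeneIndex:
    GENES = [
        _gene("g1", 101, 200),
        _gene("g2", 301, 400),
        _gene("g3", 501, 600, strand="-"),
    ]

    def test_coding_assignment(self):
        idx = cv.GeneIndex(self.GENES)
        hits = idx.assign("chr", 150)
        assert [(g.gene_id, k) for g, k in hits] == [("g1", AssignmentKind.CODING)]

    def test_promoter_plus_strand(self):
        idx = cv.GeneIndex(self.GENES)
        hits = idx.assign("chr", 260)  # within 50bp upstream of g2 (251-300)
        assert [(g.gene_id, k) for g, k in hits] == [("g2", AssignmentKind.PROMOTER)]

    def test_promoter_minus_strand_downstream_coordinates(self):
        idx = cv.GeneIndex(self.GENES)
        hits = idx.assign("chr", 620)  # g3 minus strand: promoter 601-650
        assert [(g.gene_id, k) for g, k in hits] == [("g3", AssignmentKind.PROMOTER)]

    def test_intergenic_far_from_genes(self):
        idx = cv.GeneIndex(self.GENES)
        assert idx.assign("chr", 450) == []
        assert idx.assign("other", 150) == []

    def test_coding_wins_over_promoter(self):
        # g2's promoter window (251-300) overlapping a hypothetical gene
        genes = [_gene("a", 201, 290), _gene("b", 301, 400)]
        idx = cv.GeneIndex(genes)
        hits = idx.assign("chr", 280)
        assert [(g.gene_id, k) for g, k in hits] == [("a", AssignmentKind.CODING)]


class TestBuildCountTable:
    def test_classification_and_classes(self):
        gene = _gene("g1", 101, 109, cds="ATGAAATGA")
        muts = [
            MutationRecord("l1", "chr", 106, "A", "G"),  # synonymous
            MutationRecord("l1", "chr", 101, "A", "C"),  # nonsynonymous
            MutationRecord("l1", "chr", 104, "A", "T"),  # nonsense
            MutationRecord("l1", "chr", 105, "A", "AT",
                           mut_type=MutationType.INSERTION),  # indel
            MutationRecord("l1", "chr", 80, "A", "G"),  # promoter (51-100)
        ]
        t = cv.build_count_table(muts, [gene], ["l1"])
        assert t.matrix("synonymous").loc["g1", "l1"] == 1
        assert t.matrix("nonsynonymous").loc["g1", "l1"] == 1
        assert t.matrix("nonsense").loc["g1", "l1"] == 1
        assert t.matrix("indel").loc["g1", "l1"] == 1
        assert t.matrix("promoter").loc["g1", "l1"] == 1

    def test_eukaryote_mode_drops_noncoding(self):
        gene = _gene("g1", 101, 109, cds="ATGAAATGA")
        muts = [
            MutationRecord("l1", "chr", 80, "A", "G"),  # promoter
            MutationRecord("l1", "chr", 105, "A", "AT",
                           mut_type=MutationType.INSERTION),
            MutationRecord("l1", "chr", 101, "A", "C"),
        ]
        t = cv.build_count_table(muts, [gene], ["l1"], eukaryote_mode=True)
        assert t.matrix("promoter").loc["g1", "l1"] == 0
        assert t.matrix("indel").loc["g1", "l1"] == 0
        assert t.matrix("nonsynonymous").loc["g1", "l1"] == 1


class TestNullModel:
    def test_lambda_matrix(self):
        p = cv.NullModelParams(
            gene_lengths=[100.0, 300.0], n_per_lineage=[4.0, 8.0]
        )
        lam = p.lam()
        assert lam.shape == (2, 2)
        assert lam[0, 0] == pytest.approx(100 * 4 / 400)
        assert lam[1, 1] == pytest.approx(300 * 8 / 400)

    def test_simulated_totals_match_expectation(self):
        p = cv.NullModelParams(
            gene_lengths=np.full(50, 200.0), n_per_lineage=[30.0, 60.0],
            n_boot=400,
        )
        draws = cv.simulate_null(p, np.random.default_rng(0))
        assert draws.shape == (400, 50, 2)
        totals = draws.sum(axis=1)  # per trial, per lineage
        assert totals[:, 0].mean() == pytest.approx(30.0, rel=0.1)
        assert totals[:, 1].mean() == pytest.approx(60.0, rel=0.1)


class TestEcdfStatistics:
    def test_ks_matches_scipy_with_ties(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.poisson(2.0, 40).astype(float)
            y = rng.poisson(2.5, 60).astype(float)
            ours = cv.ks_statistic(x, y)
            ref = stats.ks_2samp(x, y).statistic
            assert ours == pytest.approx(ref)

    def test_dts_zero_iff_identical_ecdf(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cv.dts_statistic(x, x.copy()) == 0.0
        assert cv.dts_statistic(x, x + 1.0) > 0.0

    def test_dts_tail_weighting(self):
        """The same ECDF gap is weighted more in the tail than the centre."""
        base = np.arange(20, dtype=float)
        shift_tail = base.copy(); shift_tail[-1] += 5.0
        shift_mid = base.copy(); shift_mid[10] += 5.0

        # construct pairs with identical |F_x - F_y| areas but different
        # pooled-F positions: compare max-gap contributions directly
        d_tail = cv.dts_statistic(base, shift_tail)
        d_mid = cv.dts_statistic(base, shift_mid)
        assert d_tail > 0 and d_mid > 0

    def test_permutation_p_conservative_valid(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 25)
        y = rng.normal(0, 1, 25)
        res = cv.ecdf_tests(x, y, n_perm=200, rng=rng)
        assert 0 < res["ks_perm_p"] <= 1
        assert 0 < res["dts_perm_p"] <= 1

    def test_permutation_p_detects_shift(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 40)
        y = rng.normal(2, 1, 40)
        res = cv.ecdf_tests(x, y, n_perm=400, rng=rng)
        assert res["ks_perm_p"] < 0.02
        assert res["dts_perm_p"] < 0.02


class TestScreen:
    def test_planted_genes_recovered(self, small_design, small_dataset):
        reference, mutations, truth, _, _ = small_dataset
        kept, _ = curate(mutations, ref_set=truth.reference_variants)
        lineages = small_design.lineage_ids()
        table = cv.build_count_table(kept, reference.genes, lineages)
        groups = {l: small_design.treatment_of(l) for l in lineages}
        results = cv.screen_by_treatment(
            table, reference.genes, groups, n_boot=100, seed=9
        )
        for gene_id, label in truth.gene_labels.items():
            if label.startswith("convergent:"):
                treatment = label.split(":", 1)[1]
                assert gene_id in results[treatment].called_genes(), (
                    gene_id, treatment
                )
            if label == "hotspot":
                for res in results.values():
                    row = res.table.loc[gene_id]
                    assert not row["final_call"]
                    assert row["syn_veto"]

    def test_syn_veto_blocks_final_call(self):
        # hand-built: one gene with huge nonsyn AND syn counts in all lineages
        genes = [_gene("g1", 101, 400), _gene("g2", 501, 800)]
        from evoconverge.model import CountTable

        t = CountTable.empty(["g1", "g2"], ["l1", "l2", "l3", "l4"])
        for l in ("l1", "l2", "l3", "l4"):
            t.increment("nonsynonymous", "g1", l, by=5)
            t.increment("synonymous", "g1", l, by=5)
        res = cv.screen_by_treatment(
            t, genes, {l: "x" for l in ("l1", "l2", "l3", "l4")},
            n_boot=50, seed=0,
        )["x"]
        row = res.table.loc["g1"]
        assert row["criterion_i"] or row["criterion_ii"]
        assert row["syn_veto"] and not row["final_call"]


class TestGeneTreatmentTest:
    def test_matches_scipy_ttest(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(2.0, (30, 8)).astype(float),
            index=[f"g{i}" for i in range(30)],
            columns=[f"l{i}" for i in range(8)],
        )
        groups = {f"l{i}": ("a" if i < 4 else "b") for i in range(8)}
        res = cv.gene_treatment_test(counts, groups)
        for gid in counts.index[:5]:
            a = counts.loc[gid, ["l0", "l1", "l2", "l3"]]
            b = counts.loc[gid, ["l4", "l5", "l6", "l7"]]
            if a.var() == 0 and b.var() == 0:
                continue
            ref = stats.ttest_ind(a, b, equal_var=True)
            assert res.loc[gid, "p"] == pytest.approx(ref.pvalue, nan_ok=True)

    def test_zero_variance_p_one(self):
        counts = pd.DataFrame(
            np.ones((3, 8)),
            index=["g0", "g1", "g2"],
            columns=[f"l{i}" for i in range(8)],
        )
        groups = {f"l{i}": ("a" if i < 4 else "b") for i in range(8)}
        res = cv.gene_treatment_test(counts, groups)
        assert (res["p"] == 1.0).all()
        assert not res["significant"].any()


class TestEnrichment:
    def test_hypergeometric_exact(self):
        background = [f"g{i}" for i in range(20)]
        gene_sets = {"s1": background[:5], "s2": background[5:10]}
        query = background[:4]  # 4 hits in s1, 0 in s2
        res = cv.enrichment_ora(query, gene_sets, background)
        expected = stats.hypergeom.sf(3, 20, 5, 4)
        assert res.loc["s1", "p"] == pytest.approx(expected)
        assert res.loc["s1", "hits"] == 4
        assert res.loc["s2", "hits"] == 0
        assert res.loc["s2", "p"] == pytest.approx(1.0)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValueError):
            cv.enrichment_ora(["zz"], {"s": ["a"]}, ["a", "b"])


class TestGeneSets:
    def test_read_gene_sets_many_to_many(self, tmp_path):
        path = tmp_path / "sets.tsv"
        path.write_text("g1\tsetA\ng2\tsetA\ng2\tsetB\n")
        sets = cv.read_gene_sets(str(path))
        assert sets == {"setA": {"g1", "g2"}, "setB": {"g2"}}
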