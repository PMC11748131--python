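import numpy as np
import pandas as pd
import pytest

from evoconverge import copynumber as cn
from evoconverge.model import CoverageTrack, GeneAnnotation


def _track(depth, lineage="l1", element="plasmid"):
    return CoverageTrack(lineage, element, np.asarray(depth, dtype=float))


class TestRegionCopyNumber:
    def test_ratio_and_loss(self):
        track = _track(np.full(1000, 200.0))
        region = cn.RegionSpec("r", "plasmid", 101, 200)
        call = cn.region_copy_number(track, region, chromosome_mean=100.0)
        assert call.copy_number == pytest.approx(2.0)
        assert not call.loss

    def test_loss_threshold_strict(self):
        region = cn.RegionSpec("r", "plasmid", 1, 100)
        at = cn.region_copy_number(
            _track(np.full(100, 1.0)), region, chromosome_mean=100.0
        )
        below = cn.region_copy_number(
            _track(np.full(100, 0.5)), region, chromosome_mean=100.0
        )
        assert at.copy_number == pytest.approx(0.01) and not at.loss
        assert below.loss

    def test_zero_chromosome_mean_rejected(self):
        region = cn.RegionSpec("r", "plasmid", 1, 10)
        with pytest.raises(ValueError):
            cn.region_copy_number(_track(np.ones(10)), region, chromosome_mean=0.0)

    def test_canonical_regions(self):
        regions = cn.canonical_plasmid_regions("plasmid")
        assert regions["insertable"].start == 170_000
        assert regions["full_plasmid"].end == 130_000
        assert regions["reduced"].start == 40_000

    def test_loss_by_breadth(self):
        region = cn.RegionSpec("r", "plasmid", 1, 1000)
        depth = np.zeros(1000)
        depth[:5] = 3.0  # 0.5% of positions covered
        assert cn.loss_by_breadth(_track(depth), region)
        depth[:900] = 3.0
        assert not cn.loss_by_breadth(_track(depth), region)


class TestDetectDuplications:
    GENES = [GeneAnnotation("g1", "chr", 1001, 1600, "+")]

    def test_fold_mode_finds_planted_region(self):
        depth = np.full(5000, 100.0)
        depth[1100:1400] = 800.0  # 8x mean, overlaps g1
        track = _track(depth, element="chr")
        out = cn.detect_duplications(track, self.GENES, mode="fold", threshold=5.0)
        assert len(out) == 1
        s, e = out[0]
        assert s == 1101 and e == 1400

    def test_non_genic_runs_filtered(self):
        depth = np.full(5000, 100.0)
        depth[3000:3300] = 900.0  # far from any gene/promoter
        track = _track(depth, element="chr")
        assert cn.detect_duplications(track, self.GENES) == []

    def test_merge_across_small_gap(self):
        depth = np.full(5000, 100.0)
        depth[1100:1200] = 900.0
        depth[1250:1350] = 900.0  # 50bp gap < 100 merge_gap
        track = _track(depth, element="chr")
        out = cn.detect_duplications(track, self.GENES)
        assert out == [(1101, 1350)]

    def test_sd_mode(self):
        rng = np.random.default_rng(0)
        # spike must be small relative to the element so the global SD stays low
        depth = rng.poisson(10.0, 50_000).astype(float)
        depth[1100:1400] += 200.0
        track = _track(depth, element="chr")
        out = cn.detect_duplications(track, self.GENES, mode="sd", threshold=5.0)
        assert len(out) == 1

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            cn.detect_duplications(_track(np.ones(10), element="chr"),
                                   self.GENES, mode="zz")


class TestCompareCopyNumbers:
    def test_exact_mwu_worked_example(self):
        """4 identical values vs 4 identical larger values: exact p = 2/70."""
        calls = pd.DataFrame(
            {
                "treatment": ["a"] * 4 + ["b"] * 4,
                "copy_number": [1.0] * 4 + [10.0] * 4,
            }
        )
        res = cn.compare_copy_numbers(calls, "treatment")
        assert len(res) == 1
        assert res.iloc[0]["p"] == pytest.approx(2 / 70)

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(1)
        calls = pd.DataFrame(
            {
                "treatment": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
                "copy_number": np.concatenate(
                    [rng.normal(1, 0.1, 4), rng.normal(2, 0.1, 4), rng.normal(3, 0.1, 4)]
                ),
            }
        )
        res = cn.compare_copy_numbers(calls, "treatment")
        assert len(res) == 3
        assert (res["p_holm"] >= res["p"] - 1e-12).all()

    def test_small_group_rejected(self):
        calls = pd.DataFrame(
            {"treatment": ["a", "a", "b"], "copy_number": [1.0, 1.1, 2.0]}
        )
        with pytest.raises(ValueError):
            cn.compare_copy_numbers(calls, "treatment")


class TestLossContingency:
    def test_fisher_exact_worked_example(self):
        # helpers: 0/4 lost; non-helpers: 4/4 lost
        loss = [False] * 4 + [True] * 4
        partner = ["helper"] * 4 + ["nonhelper"] * 4
        p, table = cn.loss_contingency_test(loss, partner)
        from scipy import stats

        ref = stats.fisher_exact([[0, 4], [4, 0]]).pvalue
        assert p == pytest.approx(ref)
        assert table.tolist() == [[0, 4], [4, 0]]

    def test_needs_two_classes(self):
        with pytest.raises(ValueError):
            cn.loss_contingency_test([True, False], ["x", "x"])


class TestSimulatedCoverage:
    def test_planted_copy_numbers_recovered(self):
        from evoconverge.simulate import PLASMID, SimulationDesign, generate_reference, simulate_coverage
        from evoconverge.simulate import PlasmidTruth

        design = SimulationDesign(
            n_genes=50,
            master_seed=3,
            plasmid_length=60_000,
            plasmid_truth={
                "phyto_400_r1": PlasmidTruth(copy_number=2.0),
                "phyto_400_r2": PlasmidTruth(
                    copy_number=1.0,
                    retention={"insertable": 1.0, "full_plasmid": 0.0, "reduced": 1.0},
                ),
            },
        )
        ref = generate_reference(design)
        tracks = simulate_coverage(
            design, ref, lineages=["phyto_400_r1", "phyto_400_r2"]
        )
        region = cn.RegionSpec("body", PLASMID, 1, 30_000)
        chrom_mean, _ = cn.element_stats(tracks[("phyto_400_r1", "chr")])
        call = cn.region_copy_number(
            tracks[("phyto_400_r1", PLASMID)], region, chrom_mean
        )
        assert call.copy_number == pytest.approx(2.0, rel=0.05)
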