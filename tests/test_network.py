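import numpy as np
import pandas as pd
import pytest
from scipy import stats

from evoconverge import network as net
from evoconverge.model import CountTable


def _table(rows, genes, lineages):
    """Build a CountTable whose nonsynonymous matrix equals ``rows``."""
    t = CountTable.empty(genes, lineages)
    arr = np.asarray(rows)
    for i, g in enumerate(genes):
        for j, l in enumerate(lineages):
            if arr[i, j]:
                t.increment("nonsynonymous", g, l, by=int(arr[i, j]))
    return t


class TestPresenceAndPrevalence:
    def test_presence_is_binary_any_count(self):
        t = _table([[0, 3], [1, 0]], ["g1", "g2"], ["l1", "l2"])
        m = net.presence_matrix(t)
        assert m.loc["g1"].tolist() == [0, 1]
        assert m.loc["g2"].tolist() == [1, 0]

    def test_prevalence_window_inclusive(self):
        lineages = [f"l{i}" for i in range(10)]
        rows = [
            [1] * 4 + [0] * 6,   # 0.4 -> excluded
            [1] * 5 + [0] * 5,   # 0.5 -> kept (lower bound)
            [1] * 9 + [0] * 1,   # 0.9 -> kept (upper bound)
            [1] * 10,            # 1.0 -> excluded
        ]
        m = net.presence_matrix(_table(rows, ["a", "b", "c", "d"], lineages))
        kept = net.filter_by_prevalence(m, 0.5, 0.9)
        assert list(kept.index) == ["b", "c"]


class TestAssociation:
    def test_spearman_and_direction(self):
        lineages = [f"l{i}" for i in range(8)]
        # a present in first 5; b present in first 4 -> strong overlap
        rows = [
            [1, 1, 1, 1, 1, 0, 0, 0],
            [1, 1, 1, 1, 0, 0, 0, 0],
        ]
        m = net.presence_matrix(_table(rows, ["a", "b"], lineages))
        assoc = net.pairwise_association(m)
        assert len(assoc) == 1
        row = assoc.iloc[0]
        ref_rho = stats.spearmanr(rows[0], rows[1]).statistic
        assert row["spearman_rho"] == pytest.approx(ref_rho)
        # P(a|b) = 4/4 = 1 > P(b|a) = 4/5 -> direction b -> a
        assert (row["source"], row["target"]) == ("b", "a")

    def test_haldane_odds_ratio_with_zero_cell(self):
        lineages = [f"l{i}" for i in range(6)]
        rows = [
            [1, 1, 1, 0, 0, 0],
            [1, 1, 1, 0, 0, 0],  # perfectly concordant: two zero cells
        ]
        m = net.presence_matrix(_table(rows, ["a", "b"], lineages))
        assoc = net.pairwise_association(m)
        # (3.5 * 3.5) / (0.5 * 0.5) = 49
        assert assoc.iloc[0]["odds_ratio"] == pytest.approx(49.0)

    def test_constant_pair_skipped(self):
        lineages = [f"l{i}" for i in range(4)]
        rows = [[1, 1, 1, 1], [1, 0, 1, 0]]
        m = net.presence_matrix(_table(rows, ["a", "b"], lineages))
        assoc = net.pairwise_association(m)
        assert len(assoc) == 0


class TestBuildNetwork:
    def test_edge_windows_closed(self):
        assoc = pd.DataFrame(
            [
                {"source": "a", "target": "b", "spearman_rho": 0.5, "odds_ratio": 3.0, "sign": "positive"},
                {"source": "a", "target": "c", "spearman_rho": 0.9, "odds_ratio": 5.0, "sign": "positive"},
                {"source": "a", "target": "d", "spearman_rho": 0.95, "odds_ratio": 9.0, "sign": "positive"},
                {"source": "b", "target": "c", "spearman_rho": -0.25, "odds_ratio": 0.2, "sign": "negative"},
                {"source": "b", "target": "d", "spearman_rho": -0.31, "odds_ratio": 0.1, "sign": "negative"},
                {"source": "c", "target": "d", "spearman_rho": 0.4, "odds_ratio": 2.0, "sign": "positive"},
            ]
        )
        graph, degrees = net.build_network(assoc)
        kept = {(u, v) for u, v in graph.edges}
        assert ("a", "b") in kept      # rho = 0.5 lower bound
        assert ("a", "c") in kept      # rho = 0.9 upper bound
        assert ("a", "d") not in kept  # above window
        assert ("b", "c") in kept      # negative window [-0.3, -0.2]
        assert ("b", "d") not in kept  # below negative window
        assert ("c", "d") not in kept  # between windows
        assert degrees.loc["a", "outdegree"] == 2
        assert degrees.loc["c", "indegree"] == 2

    def test_edge_sign_attribute(self):
        assoc = pd.DataFrame(
            [
                {"source": "a", "target": "b", "spearman_rho": 0.6, "odds_ratio": 3.0, "sign": "positive"},
                {"source": "b", "target": "c", "spearman_rho": -0.25, "odds_ratio": 0.2, "sign": "negative"},
            ]
        )
        graph, _ = net.build_network(assoc)
        assert graph.edges["a", "b"]["spearman_rho"] == pytest.approx(0.6)
        assert graph.edges["b", "c"]["spearman_rho"] == pytest.approx(-0.25)

    def test_export_edge_list(self, tmp_path):
        assoc = pd.DataFrame(
            [{"source": "a", "target": "b", "spearman_rho": 0.6, "odds_ratio": 3.0, "sign": "positive"}]
        )
        graph, _ = net.build_network(assoc)
        path = tmp_path / "edges.tsv"
        net.export_edge_list(graph, str(path))
        df = pd.read_csv(path, sep="\t")
        assert {"source", "target"} <= set(df.columns)
        assert len(df) == 1


class TestEndToEnd:
    def test_runs_on_synthetic_counts(self, small_design, small_dataset):
        from evoconverge.convergence import build_count_table

        reference, mutations, _, _, _ = small_dataset
        lineages = small_design.lineage_ids()
        table = build_count_table(mutations, reference.genes, lineages)
        m = net.filter_by_prevalence(net.presence_matrix(table), 0.5, 0.9)
        assoc = net.pairwise_association(m)
        graph, degrees = net.build_network(assoc)
        assert set(degrees.columns) == {"indegree", "outdegree"}
        # every edge respects the windows
        for _, _, data in graph.edges(data=True):
            r = data["spearman_rho"]
            assert (0.5 <= r <= 0.9) or (-0.3 <= r <= -0.2)


def test_export_graphml(tmp_path):
    import networkx as nx

    assoc = pd.DataFrame(
        [{"source": "a", "target": "b", "spearman_rho": 0.6,
          "odds_ratio": 3.0, "sign": "positive"}]
    )
    graph, _ = net.build_network(assoc)
    path = tmp_path / "net.graphml"
    net.export_graphml(graph, str(path))
    back = nx.read_graphml(str(path))
    assert set(back.edges) == {("a", "b")}
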