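"""Directed mutation co-occurrence networks across replicate lineages.

Gene-level mutation counts are collapsed to presence/absence across
lineages (a gene "present" in a lineage if it carries at least one
qualifying mutation), genes with uninformative prevalence are dropped, and
every remaining gene pair is scored by Spearman rank correlation of the
binary vectors plus a Haldane-corrected odds ratio. Pairs whose correlation
falls inside the configured positive or negative window become directed
edges, oriented from the gene whose presence better predicts the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .model import CountTable

logger = logging.getLogger(__name__)

POSITIVE_WINDOW = (0.5, 0.9)
NEGATIVE_WINDOW = (-0.3, -0.2)


def presence_matrix(
    table: CountTable, classes: Iterable[str] = ("nonsynonymous", "nonsense")
) -> pd.DataFrame:
    """Binary genes x lineages matrix: 1 iff summed counts >= 1."""
    return (table.combined(classes) >= 1).astype(int)


def filter_by_prevalence(
    matrix: pd.DataFrame, min_freq: float = 0.5, max_freq: float = 0.9
) -> pd.DataFrame:
    """Keep genes whose across-lineage prevalence lies in [min, max]."""
    prevalence = matrix.mean(axis=1)
    kept = matrix[(prevalence >= min_freq) & (prevalence <= max_freq)]
    if kept.empty:
        logger.warning("prevalence filter retained no genes; network will be empty")
    return kept


def _odds_ratio(a: np.ndarray, b: np.ndarray, haldane: bool = True) -> float:
    """Odds ratio of the 2x2 presence table, +0.5 to all cells if any is 0."""
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    if haldane and min(n11, n10, n01, n00) == 0:
        n11, n10, n01, n00 = n11 + 0.5, n10 + 0.5, n01 + 0.5, n00 + 0.5
    if n10 * n01 == 0:
        return np.inf
    return (n11 * n00) / (n10 * n01)


def pairwise_association(
    matrix: pd.DataFrame, haldane: bool = True, verbose_orientations: bool = False
) -> pd.DataFrame:
    """Spearman rho, odds ratio and predicted direction for each gene pair.

    The directed orientation points from the gene whose presence is the
    better predictor: source = argmax over the two conditional frequencies
    P(other mutated | this mutated). With ``verbose_orientations`` both
    orientations are emitted. Pairs with a constant vector are skipped.
    """
    genes = list(matrix.index)
    data = matrix.to_numpy()
    rows = []
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            a, b = data[i], data[j]
            if a.std() == 0 or b.std() == 0:
                logger.info(
                    "skipping pair (%s, %s): constant presence vector",
                    genes[i],
                    genes[j],
                )
                continue
            rho = float(stats.spearmanr(a, b).statistic)
            orr = _odds_ratio(a, b, haldane)
            # conditional prediction strengths
            p_b_given_a = float(b[a == 1].mean()) if (a == 1).any() else 0.0
            p_a_given_b = float(a[b == 1].mean()) if (b == 1).any() else 0.0
            if p_b_given_a >= p_a_given_b:
                source, target = genes[i], genes[j]
            else:
                source, target = genes[j], genes[i]
            rows.append(
                {
                    "source": source,
                    "target": target,
                    "spearman_rho": rho,
                    "odds_ratio": orr,
                    "sign": "positive" if rho >= 0 else "negative",
                }
            )
            if verbose_orientations:
                rows.append(
                    {
                        "source": target,
                        "target": source,
                        "spearman_rho": rho,
                        "odds_ratio": orr,
                        "sign": "positive" if rho >= 0 else "negative",
                    }
                )
    return pd.DataFrame(
        rows, columns=["source", "target", "spearman_rho", "odds_ratio", "sign"]
    )


def build_network(
    associations: pd.DataFrame,
    pos_window: tuple[float, float] = POSITIVE_WINDOW,
    neg_window: tuple[float, float] = NEGATIVE_WINDOW,
) -> tuple[nx.DiGraph, pd.DataFrame]:
    """Retain edges with rho inside either closed window; return graph+degrees."""
    graph = nx.DiGraph()
    for row in associations.itertuples(index=False):
        rho = row.spearman_rho
        keep = (pos_window[0] <= rho <= pos_window[1]) or (
            neg_window[0] <= rho <= neg_window[1]
        )
        if keep:
            graph.add_edge(
                row.source,
                row.target,
                spearman_rho=float(rho),
                odds_ratio=float(row.odds_ratio),
                sign=row.sign,
            )
    degrees = pd.DataFrame(
        {
            "indegree": pd.Series(dict(graph.in_degree()), dtype=int),
            "outdegree": pd.Series(dict(graph.out_degree()), dtype=int),
        }
    ).fillna(0)
    return graph, degrees


def export_edge_list(graph: nx.DiGraph, path: str) -> None:
    rows = [
        {
            "source": u,
            "target": v,
            "spearman_rho": d["spearman_rho"],
            "odds_ratio": d["odds_ratio"],
            "sign": d["sign"],
        }
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(
        rows, columns=["source", "target", "spearman_rho", "odds_ratio", "sign"]
    ).to_csv(path, sep="\t", index=False)


def export_graphml(graph: nx.DiGraph, path: str) -> None:
    nx.write_graphml(graph, path)
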