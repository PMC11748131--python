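"""Convergent-mutation detection against a gene-length-weighted Poisson null.

Mutations are binned into gene x lineage count tables. The null model places
each lineage's observed mutation total randomly over the coding genome: with
total coding size g and n observed mutations, the per-bp hit probability is
p = n/g and a gene of length l receives Poisson(lambda = p*l) mutations per
randomized trial. A gene is called convergently mutated when it

(i)  accumulates more protein-affecting mutations, summed across replicate
     lineages, than ANY gene received in ANY randomized trial (strict >), or
(ii) carries at least one qualifying mutation in at least half of the
     eligible replicate lineages,

and is NOT vetoed by meeting either criterion on the synonymous table
(hotspots elevate silent and non-silent mutation rates alike).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .codon import EffectClass, GeneticCode, STANDARD_CODE, classify_snp
from .model import (
    AssignmentKind,
    CountTable,
    GeneAnnotation,
    MutationRecord,
    MutationType,
)

#: classes that "qualify" a gene toward convergence in prokaryote mode
QUALIFYING_CLASSES_PROKARYOTE = ("nonsynonymous", "nonsense", "promoter", "indel")
#: eukaryote tables only consider coding sequences
QUALIFYING_CLASSES_EUKARYOTE = ("nonsynonymous", "nonsense")


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

class GeneIndex:
    """Positional lookup over a non-overlapping gene annotation."""

    def __init__(self, genes: Sequence[GeneAnnotation]):
        self._by_element: dict[str, tuple[np.ndarray, np.ndarray, list]] = {}
        for element in {g.element_id for g in genes}:
            elem_genes = sorted(
                (g for g in genes if g.element_id == element), key=lambda g: g.start
            )
            self._by_element[element] = (
                np.array([g.start for g in elem_genes]),
                np.array([g.end for g in elem_genes]),
                elem_genes,
            )

    def assign(
        self, element_id: str, position: int, promoter_window: int = 50
    ) -> list[tuple[GeneAnnotation, AssignmentKind]]:
        """Coding if inside a gene, else promoter of nearby gene(s).

        A position inside one gene that also falls in a neighbour's upstream
        window counts only for the containing gene; a genuinely intergenic
        position inside two overlapping windows counts for both.
        """
        entry = self._by_element.get(element_id)
        if entry is None:
            return []
        starts, ends, elem_genes = entry
        i = int(np.searchsorted(starts, position, side="right")) - 1
        if i >= 0 and position <= ends[i]:
            return [(elem_genes[i], AssignmentKind.CODING)]
        hits = []
        for j in range(max(i - 2, 0), min(i + 4, len(elem_genes))):
            if elem_genes[j].in_promoter(position, promoter_window):
                hits.append((elem_genes[j], AssignmentKind.PROMOTER))
        return hits


def assign_mutation(
    m: MutationRecord,
    genes: Sequence[GeneAnnotation],
    promoter_window: int = 50,
) -> list[tuple[GeneAnnotation, AssignmentKind]]:
    """Assign one mutation against a gene list (see :meth:`GeneIndex.assign`)."""
    return GeneIndex(genes).assign(m.element_id, m.position, promoter_window)


def build_count_table(
    mutations: Sequence[MutationRecord],
    genes: Sequence[GeneAnnotation],
    lineages: Sequence[str],
    include_promoter_indel: bool = True,
    promoter_window: int = 50,
    eukaryote_mode: bool = False,
    code: GeneticCode = STANDARD_CODE,
) -> CountTable:
    """Bin curated mutations into a genes x lineages CountTable.

    Coding SNPs are classified codon-aware into nonsynonymous / synonymous /
    nonsense (stop-loss is tallied with nonsynonymous); indels within genes
    go to the indel class and intergenic mutations within ``promoter_window``
    bp upstream of a start codon to the promoter class. Eukaryote mode drops
    everything except coding SNPs.
    """
    table = CountTable.empty([g.gene_id for g in genes], list(lineages))
    index = GeneIndex(genes)
    lineage_set = set(table.lineages)
    for m in mutations:
        if m.lineage_id not in lineage_set:
            continue
        for gene, kind in index.assign(m.element_id, m.position, promoter_window):
            if kind is AssignmentKind.CODING:
                if m.mut_type is MutationType.SNP:
                    if not gene.is_coding or gene.cds_sequence is None:
                        continue
                    effect = classify_snp(
                        gene, m.position, m.ref_allele, m.alt_allele, code
                    )
                    if effect is EffectClass.SYNONYMOUS:
                        cls = "synonymous"
                    elif effect is EffectClass.NONSENSE:
                        cls = "nonsense"
                    else:
                        cls = "nonsynonymous"
                    table.increment(cls, gene.gene_id, m.lineage_id)
                elif not eukaryote_mode and include_promoter_indel:
                    table.increment("indel", gene.gene_id, m.lineage_id)
            elif (
                kind is AssignmentKind.PROMOTER
                and not eukaryote_mode
                and include_promoter_indel
            ):
                table.increment("promoter", gene.gene_id, m.lineage_id)
    return table


# ---------------------------------------------------------------------------
# Poisson null
# ---------------------------------------------------------------------------

@dataclass
class NullModelParams:
    """Parameters of the length-weighted Poisson null for one lineage group."""

    gene_lengths: np.ndarray  # bp per gene (coding lengths)
    n_per_lineage: np.ndarray  # observed mutation totals, one per lineage
    n_boot: int = 100
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.gene_lengths = np.asarray(self.gene_lengths, dtype=float)
        self.n_per_lineage = np.asarray(self.n_per_lineage, dtype=float)
        if (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive")
        if (self.n_per_lineage < 0).any():
            raise ValueError("mutation totals must be nonnegative")

    @property
    def g(self) -> float:
        """Total coding genome size (bp)."""
        return float(self.gene_lengths.sum())

    def lam(self) -> np.ndarray:
        """Per-gene, per-lineage Poisson rates lambda = (n/g) * l."""
        p = self.n_per_lineage / self.g  # per-bp probability, one per lineage
        return np.outer(self.gene_lengths, p)


def simulate_null(params: NullModelParams, rng=None) -> np.ndarray:
    """Draw randomized count matrices; shape (n_boot, n_genes, n_lineages).

    Each lineage's own mutation total sets its rates, so summing a trial
    across lineages yields trial-level totals whose expectation matches the
    observed organism total.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    lam = params.lam()  # (genes, lineages)
    return rng.poisson(lam, size=(params.n_boot,) + lam.shape)


# ---------------------------------------------------------------------------
# ECDF comparison tests
# ---------------------------------------------------------------------------

def dts_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Variance-weighted ECDF distance between two samples.

    Integrates |F_x - F_y| over the pooled support, each inter-order-statistic
    gap weighted by its width and by 1/sqrt(F(1-F)) of the pooled ECDF, so
    tail discrepancies (where the variance of the ECDF difference is small)
    weigh more than central ones. Zero iff the ECDFs coincide.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = x.size, y.size
    z = np.concatenate([x, y])
    labels = np.concatenate([np.ones(n), np.zeros(m)])
    order = np.argsort(z, kind="mergesort")
    z_sorted = z[order]
    lab_sorted = labels[order]
    fx = np.cumsum(lab_sorted) / n
    fy = np.cumsum(1.0 - lab_sorted) / m
    d = np.abs(fx - fy)[:-1]
    widths = np.diff(z_sorted)
    k = np.arange(1, n + m)
    fp = k / (n + m)
    w = 1.0 / np.sqrt(fp * (1.0 - fp))
    return float(np.sum(d * widths * w))


def ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sample sup-distance between ECDFs (handles ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    z = np.concatenate([x, y])
    labels = np.concatenate([np.ones(n), np.zeros(m)])
    order = np.argsort(z, kind="mergesort")
    z_sorted = z[order]
    lab_sorted = labels[order]
    fx = np.cumsum(lab_sorted) / n
    fy = np.cumsum(1.0 - lab_sorted) / m
    # evaluate only at the end of tie blocks
    block_end = np.append(np.diff(z_sorted) > 0, True)
    return float(np.max(np.abs(fx - fy)[block_end]))


def _permutation_pvalues(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int,
    rng,
    tie_break: str = "conservative",
) -> tuple[float, float]:
    """Permutation p-values for (KS, DTS) by pooled-sample label shuffling.

    ``tie_break='conservative'`` gives the standard (1 + #{T_perm >= T_obs})
    /(B + 1) estimate; ``'random'`` breaks ties in the permutation ranks
    uniformly, making the p-value exactly uniform under exchangeability.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    z = np.sort(np.concatenate([x, y]), kind="mergesort")
    widths = np.diff(z)
    total = n + m
    k = np.arange(1, total)
    fp = k / total
    dts_w = widths / np.sqrt(fp * (1.0 - fp))
    block_end = np.append(widths > 0, True)

    base = np.zeros(total)
    base[:n] = 1.0
    perms = np.tile(base, (n_perm + 1, 1))
    # row 0 carries the observed labelling in sorted-pool order
    order = np.argsort(
        np.concatenate([x, y]), kind="mergesort"
    )
    obs_labels = np.concatenate([np.ones(n), np.zeros(m)])[order]
    perms[0] = obs_labels
    perms[1:] = rng.permuted(perms[1:], axis=1)

    fx = np.cumsum(perms, axis=1) / n
    fy = np.cumsum(1.0 - perms, axis=1) / m
    d = np.abs(fx - fy)
    ks_all = d[:, block_end].max(axis=1)
    dts_all = d[:, :-1] @ dts_w

    out = []
    for stat_all in (ks_all, dts_all):
        obs = stat_all[0]
        perm = stat_all[1:]
        if tie_break == "random":
            greater = int(np.sum(perm > obs))
            ties = int(np.sum(perm == obs))
            u = rng.random()
            p = (greater + u * (ties + 1)) / (n_perm + 1)
        else:
            p = (1 + int(np.sum(perm >= obs))) / (n_perm + 1)
        out.append(float(p))
    return out[0], out[1]


def ecdf_tests(
    observed: np.ndarray,
    null_counts: np.ndarray,
    n_perm: int = 1000,
    rng=None,
    tie_break: str = "conservative",
) -> dict:
    """Compare observed per-gene counts to randomized ones via ECDFs.

    ``null_counts`` may be a single trial or a pooled array of trials.
    Returns the KS statistic with its asymptotic/exact p (scipy) and a
    permutation p, plus the DTS statistic with its permutation p.
    """
    if rng is None:
        rng = np.random.default_rng()
    observed = np.asarray(observed, dtype=float).ravel()
    null_counts = np.asarray(null_counts, dtype=float).ravel()
    if observed.size == 0 or null_counts.size == 0:
        raise ValueError("both samples must be nonempty")
    # asymptotic mode: count data is tie-heavy and scipy's exact method
    # bails out (with a warning) on ties anyway
    ks_res = stats.ks_2samp(observed, null_counts, method="asymp")
    ks_perm_p, dts_perm_p = _permutation_pvalues(
        observed, null_counts, n_perm, rng, tie_break
    )
    return {
        "ks_stat": ks_statistic(observed, null_counts),
        "ks_p": float(ks_res.pvalue),
        "ks_perm_p": ks_perm_p,
        "dts_stat": dts_statistic(observed, null_counts),
        "dts_perm_p": dts_perm_p,
    }


# ---------------------------------------------------------------------------
# Convergence screen
# ---------------------------------------------------------------------------

@dataclass
class ConvergenceResult:
    """Per-gene convergence calls for one treatment group."""

    table: pd.DataFrame  # index gene_id; columns per screen outputs
    bootstrap_max: int
    syn_bootstrap_max: int

    def called_genes(self) -> list[str]:
        return list(self.table.index[self.table["final_call"]])


def _criteria(
    counts: pd.DataFrame,
    boot: np.ndarray,
    prevalence_threshold: float,
    eligible: Optional[pd.DataFrame],
) -> tuple[pd.Series, pd.Series, pd.Series, int]:
    """(observed sums, criterion-i flags, prevalence, bootstrap max)."""
    obs_sum = counts.sum(axis=1)
    trial_sums = boot.sum(axis=2)  # (n_boot, genes)
    boot_max = int(trial_sums.max()) if trial_sums.size else 0
    crit_i = obs_sum > boot_max  # strict: ties at the max do not pass
    present = counts > 0
    if eligible is None:
        n_eligible = counts.shape[1]
        prevalence = present.sum(axis=1) / n_eligible
    else:
        n_elig = eligible.sum(axis=1).replace(0, np.nan)
        prevalence = (present & eligible).sum(axis=1) / n_elig
        prevalence = prevalence.fillna(0.0)
    return obs_sum, crit_i, prevalence, boot_max


def convergence_screen(
    nonsyn_counts: pd.DataFrame,
    syn_counts: pd.DataFrame,
    nonsyn_boot: np.ndarray,
    syn_boot: np.ndarray,
    prevalence_threshold: float = 0.5,
    eligible: Optional[pd.DataFrame] = None,
) -> ConvergenceResult:
    """Screen one treatment group's tables for convergently mutated genes.

    ``*_counts`` are genes x lineages DataFrames restricted to the group;
    ``*_boot`` are (n_boot, genes, lineages) randomized matrices from
    :func:`simulate_null` with matching gene order. ``eligible`` optionally
    marks, per gene x lineage, whether that lineage has data at the locus.
    """
    if not nonsyn_counts.index.equals(syn_counts.index):
        raise ValueError("nonsyn and syn tables must share the gene universe")
    if nonsyn_boot.size == 0 or syn_boot.size == 0:
        raise ValueError("empty bootstrap")
    obs_sum, crit_i, prevalence, boot_max = _criteria(
        nonsyn_counts, nonsyn_boot, prevalence_threshold, eligible
    )
    crit_ii = prevalence >= prevalence_threshold
    s_sum, s_crit_i, s_prev, s_boot_max = _criteria(
        syn_counts, syn_boot, prevalence_threshold, eligible
    )
    syn_veto = s_crit_i | (s_prev >= prevalence_threshold)
    final = (crit_i | crit_ii) & ~syn_veto
    table = pd.DataFrame(
        {
            "observed_sum": obs_sum.astype(int),
            "prevalence": prevalence,
            "criterion_i": crit_i,
            "criterion_ii": crit_ii,
            "syn_veto": syn_veto,
            "final_call": final,
        },
        index=nonsyn_counts.index,
    )
    return ConvergenceResult(
        table=table, bootstrap_max=boot_max, syn_bootstrap_max=s_boot_max
    )


def screen_by_treatment(
    table: CountTable,
    genes: Sequence[GeneAnnotation],
    groups: Mapping[str, str],
    n_boot: int = 100,
    seed: Optional[int] = None,
    qualifying_classes: Sequence[str] = QUALIFYING_CLASSES_PROKARYOTE,
    prevalence_threshold: float = 0.5,
) -> dict[str, ConvergenceResult]:
    """Run the convergence screen separately for each treatment group.

    ``groups`` maps lineage_id -> treatment label. Null rates use each
    lineage's own observed mutation total for the table being screened, so
    a gene may be called in either treatment or in both.
    """
    rng = np.random.default_rng(seed)
    gene_lengths = np.array([g.length for g in genes], dtype=float)
    nonsyn_all = table.combined(qualifying_classes)
    syn_all = table.matrix("synonymous")
    out = {}
    for treatment in sorted(set(groups.values())):
        lineages = [l for l in table.lineages if groups[l] == treatment]
        nonsyn = nonsyn_all.loc[:, lineages]
        syn = syn_all.loc[:, lineages]
        nonsyn_boot = simulate_null(
            NullModelParams(gene_lengths, nonsyn.sum(axis=0).to_numpy(), n_boot),
            rng,
        )
        syn_boot = simulate_null(
            NullModelParams(gene_lengths, syn.sum(axis=0).to_numpy(), n_boot), rng
        )
        out[treatment] = convergence_screen(
            nonsyn, syn, nonsyn_boot, syn_boot, prevalence_threshold
        )
    return out


def gene_treatment_test(
    counts: pd.DataFrame, groups: Mapping[str, str]
) -> pd.DataFrame:
    """Per-gene OLS test of count on treatment indicator (two groups).

    The group-indicator OLS t-test equals the pooled-variance two-sample
    t-test, computed here vectorized across genes. Zero-variance genes get
    p = 1 by convention. Returns effect direction (mean difference, first
    group minus second in sorted label order) and a flag at unadjusted
    p < .05.
    """
    labels = pd.Series({l: groups[l] for l in counts.columns})
    uniq = sorted(labels.unique())
    if len(uniq) != 2:
        raise ValueError("gene_treatment_test expects exactly 2 groups")
    a = counts.loc[:, labels[labels == uniq[0]].index].to_numpy(float)
    b = counts.loc[:, labels[labels == uniq[1]].index].to_numpy(float)
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("each group needs >= 2 lineages")
    with warnings.catch_warnings():
        # constant genes trigger scipy's catastrophic-cancellation warning;
        # their p-values are overridden below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    diff = a.mean(axis=1) - b.mean(axis=1)
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0) & (diff == 0)
    p = np.where(zero_var, 1.0, p)
    p = np.where(np.isnan(p), 1.0, p)
    return pd.DataFrame(
        {
            "p": p,
            "effect": diff,
            "significant": p < 0.05,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def enrichment_ora(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of a gene list in gene sets.

    For each set, p = P(overlap >= observed) under sampling |query| genes
    from the background without replacement; Benjamini-Hochberg adjusts
    across sets. Gene ratio = hits/|query|; background ratio = |set|/
    |background|.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise ValueError("empty query gene list")
    if not query <= background:
        raise ValueError("query genes must be a subset of the background")
    rows = []
    for set_id, members in gene_sets.items():
        members = set(members) & background
        hits = len(query & members)
        # hypergeom: population N, successes K, draws n
        p = float(
            stats.hypergeom.sf(hits - 1, len(background), len(members), len(query))
        )
        rows.append(
            {
                "set_id": set_id,
                "hits": hits,
                "set_size": len(members),
                "gene_ratio": hits / len(query),
                "background_ratio": len(members) / len(background),
                "p": p,
            }
        )
    df = pd.DataFrame(rows).set_index("set_id")
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    else:
        df["p_adj"] = []
    return df


def read_gene_sets(path: str) -> dict[str, set]:
    """Two-column TSV (gene_id, set_id), many-to-many -> set_id -> genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "set_id"])
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.set_id), set()).add(str(row.gene_id))
    return out
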