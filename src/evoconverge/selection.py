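"""Directional-selection metrics per lineage and their group comparison.

Three metrics summarise the spectrum of fixed and segregating coding SNPs in
each evolved lineage:

* ``dnds`` — (N/nonsyn sites)/(S/syn sites); ~1 under neutrality, >1 under
  directional selection, <1 under purifying selection. Protein-changing
  events (nonsynonymous, nonsense, stop-loss) enter the numerator.
* ``tstv`` — transitions over transversions; 0.5 under a uniform model.
* ``nonsense_ratio`` — observed nonsense fraction over the genome-specific
  neutral expectation; ~1 when premature stops accrue at the neutral rate.

Group comparisons use an ordinary least-squares group-means model (the
mixed-model alternative fit the motivating data worse and is out of scope).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .codon import (
    EffectClass,
    GeneticCode,
    STANDARD_CODE,
    SiteCounts,
    classify_snp,
    is_transition,
)
from .model import GeneAnnotation, MutationRecord, MutationType


@dataclass
class SelectionMetrics:
    lineage_id: str
    dnds: Optional[float]
    tstv: Optional[float]
    nonsense_ratio: Optional[float]
    n_snps: int

    def as_dict(self) -> dict:
        return {
            "lineage_id": self.lineage_id,
            "dnds": self.dnds,
            "tstv": self.tstv,
            "nonsense_ratio": self.nonsense_ratio,
            "n_snps": self.n_snps,
        }


def dnds(
    n_obs: int,
    s_obs: int,
    sites: SiteCounts,
    pseudocount: bool = False,
) -> Optional[float]:
    """Site-normalised nonsynonymous/synonymous ratio; None when undefined.

    With ``pseudocount`` a Haldane-Anscombe +0.5 is added to both counts so
    sparse lineages yield a finite value.
    """
    if sites.syn_sites <= 0 or sites.nonsyn_sites <= 0:
        raise ValueError("site counts must be positive")
    n, s = float(n_obs), float(s_obs)
    if pseudocount:
        n, s = n + 0.5, s + 0.5
    if s == 0:
        return None
    return (n / sites.nonsyn_sites) / (s / sites.syn_sites)


def dnds_raw(n_obs: int, s_obs: int, pseudocount: bool = False) -> Optional[float]:
    """Raw N/S count ratio (no site normalisation)."""
    n, s = float(n_obs), float(s_obs)
    if pseudocount:
        n, s = n + 0.5, s + 0.5
    if s == 0:
        return None
    return n / s


def tstv(snps: Iterable[tuple[str, str]]) -> Optional[float]:
    """Transition:transversion ratio from (ref, alt) pairs; None if no tv."""
    ts = tv = 0
    for ref, alt in snps:
        if is_transition(ref, alt):
            ts += 1
        else:
            tv += 1
    if tv == 0:
        return None
    return ts / tv


def nonsense_ratio(
    n_nonsense: int, n_total_coding: int, expected_fraction: float
) -> Optional[float]:
    """Observed/expected nonsense fraction; None with no coding SNPs."""
    if not (0 < expected_fraction < 1):
        raise ValueError("expected_fraction must lie in (0, 1)")
    if n_total_coding == 0:
        return None
    return (n_nonsense / n_total_coding) / expected_fraction


def classify_lineage_snps(
    mutations: Sequence[MutationRecord],
    genes: Sequence[GeneAnnotation],
    code: GeneticCode = STANDARD_CODE,
) -> pd.DataFrame:
    """Classify coding SNPs; one row per (lineage, effect, ref, alt).

    Only SNPs falling inside coding genes enter the metrics (indels and
    multi-nucleotide events are excluded from the mutation-spectrum
    statistics by design).
    """
    by_element: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        if g.is_coding and g.cds_sequence is not None:
            by_element.setdefault(g.element_id, []).append(g)
    rows = []
    for m in mutations:
        if m.mut_type is not MutationType.SNP:
            continue
        for g in by_element.get(m.element_id, ()):
            if g.contains(m.position):
                effect = classify_snp(g, m.position, m.ref_allele, m.alt_allele, code)
                rows.append(
                    {
                        "lineage_id": m.lineage_id,
                        "gene_id": g.gene_id,
                        "effect": effect.value,
                        "ref": m.ref_allele,
                        "alt": m.alt_allele,
                    }
                )
                break
    return pd.DataFrame(
        rows, columns=["lineage_id", "gene_id", "effect", "ref", "alt"]
    )


def selection_metrics_table(
    mutations: Sequence[MutationRecord],
    genes: Sequence[GeneAnnotation],
    sites: SiteCounts,
    expected_nonsense: float,
    code: GeneticCode = STANDARD_CODE,
    pseudocount: bool = False,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-lineage (or pooled) selection metrics from curated mutations."""
    classified = classify_lineage_snps(mutations, genes, code)
    if pooled:
        classified = classified.assign(lineage_id="pooled")
    out = []
    for lineage_id, sub in classified.groupby("lineage_id", sort=True):
        counts = sub["effect"].value_counts()
        n_syn = int(counts.get(EffectClass.SYNONYMOUS.value, 0))
        n_nonsense = int(counts.get(EffectClass.NONSENSE.value, 0))
        n_protein_changing = int(
            counts.get(EffectClass.NONSYNONYMOUS.value, 0)
            + n_nonsense
            + counts.get(EffectClass.STOP_LOSS.value, 0)
        )
        total = len(sub)
        metrics = SelectionMetrics(
            lineage_id=str(lineage_id),
            dnds=dnds(n_protein_changing, n_syn, sites, pseudocount),
            tstv=tstv(zip(sub["ref"], sub["alt"])),
            nonsense_ratio=nonsense_ratio(n_nonsense, total, expected_nonsense)
            if total
            else None,
            n_snps=total,
        )
        out.append(metrics.as_dict())
    return pd.DataFrame(
        out, columns=["lineage_id", "dnds", "tstv", "nonsense_ratio", "n_snps"]
    )


def compare_groups(
    metrics: pd.DataFrame,
    metric: str,
    group: str,
    neutral_value: float = 1.0,
    log_transform: bool = False,
) -> dict:
    """OLS group-means model on a per-lineage metric.

    Returns per-group means with 95% CIs, flags for CIs excluding the
    neutral expectation, and unadjusted pairwise contrast p-values. Groups
    with fewer than 2 defined values are omitted with a warning entry.
    """
    df = metrics[[group, metric]].dropna().copy()
    sizes = df.groupby(group).size()
    omitted = [str(g) for g in sizes[sizes < 2].index]
    df = df[~df[group].astype(str).isin(omitted)]
    if df.empty or df[group].nunique() < 1:
        raise ValueError("no group has >= 2 defined metric values")
    y = np.log(df[metric]) if log_transform else df[metric]
    df = df.assign(_y=y)
    model = smf.ols(f"_y ~ C({group}) - 1", data=df).fit()
    groups = sorted(df[group].astype(str).unique())
    means, cis = {}, {}
    conf = model.conf_int()
    for g, name in zip(groups, model.params.index):
        est = model.params[name]
        lo, hi = conf.loc[name]
        if log_transform:
            est, lo, hi = math.exp(est), math.exp(lo), math.exp(hi)
        means[g] = est
        cis[g] = (lo, hi)
    excludes_neutral = {
        g: not (cis[g][0] <= neutral_value <= cis[g][1]) for g in groups
    }
    pairwise = {}
    for i, gi in enumerate(groups):
        for gj in groups[i + 1 :]:
            contrast = np.zeros(len(groups))
            contrast[groups.index(gi)] = 1.0
            contrast[groups.index(gj)] = -1.0
            test = model.t_test(contrast)
            pairwise[(gi, gj)] = float(test.pvalue)
    return {
        "means": means,
        "ci95": cis,
        "excludes_neutral": excludes_neutral,
        "pairwise_p": pairwise,
        "omitted_groups": omitted,
        "n": sizes.to_dict(),
    }
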