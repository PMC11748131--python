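"""Plasmid copy number, plasmid loss and duplications from depth of coverage.

Copy number for a plasmid region is its mean depth divided by the mean depth
of the chromosome in the same lineage; a region is called lost when that
ratio drops below 1% (depth scales vary run-to-run, so the criterion is a
ratio, not an absolute depth). Three named plasmid windows capture the
distinct coverage behaviours seen in the motivating system: a chromosomally
"insertable" segment, a window diagnostic of the full free plasmid, and a
window covering a reduced-size plasmid variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import CoverageTrack, GeneAnnotation

logger = logging.getLogger(__name__)

LOSS_RATIO_THRESHOLD = 0.01
DUPLICATION_FOLD = 5.0


@dataclass(frozen=True)
class RegionSpec:
    name: str
    element_id: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad region interval {self.start}-{self.end}")


def canonical_plasmid_regions(element_id: str) -> dict[str, RegionSpec]:
    """The three diagnostic plasmid windows (kb coordinates on the plasmid)."""
    return {
        "insertable": RegionSpec("insertable", element_id, 170_000, 180_000),
        "full_plasmid": RegionSpec("full_plasmid", element_id, 120_000, 130_000),
        "reduced": RegionSpec("reduced", element_id, 40_000, 50_000),
    }


@dataclass
class CopyNumberCall:
    lineage_id: str
    region: str
    region_mean: float
    chromosome_mean: float
    copy_number: float
    loss: bool


def element_stats(track: CoverageTrack) -> tuple[float, float]:
    """(mean, SD) of depth over all positions of a replicon."""
    if track.length == 0:
        raise ValueError("empty coverage track")
    return float(track.depth.mean()), float(track.depth.std())


def region_copy_number(
    plasmid_track: CoverageTrack,
    region: RegionSpec,
    chromosome_mean: float,
    loss_threshold: float = LOSS_RATIO_THRESHOLD,
) -> CopyNumberCall:
    """Copy number = region mean depth / chromosome mean depth.

    Loss is flagged when the ratio is strictly below ``loss_threshold``.
    """
    if chromosome_mean <= 0:
        raise ValueError("chromosome mean depth must be positive")
    region_mean = float(plasmid_track.region(region.start, region.end).mean())
    ratio = region_mean / chromosome_mean
    return CopyNumberCall(
        lineage_id=plasmid_track.lineage_id,
        region=region.name,
        region_mean=region_mean,
        chromosome_mean=chromosome_mean,
        copy_number=ratio,
        loss=ratio < loss_threshold,
    )


def loss_by_breadth(
    plasmid_track: CoverageTrack,
    region: RegionSpec,
    breadth_threshold: float = LOSS_RATIO_THRESHOLD,
) -> bool:
    """Alternative loss call: < threshold fraction of positions with any read."""
    depths = plasmid_track.region(region.start, region.end)
    return float((depths > 0).mean()) < breadth_threshold


def detect_duplications(
    track: CoverageTrack,
    genes: Sequence[GeneAnnotation],
    mode: str = "fold",
    threshold: float = DUPLICATION_FOLD,
    merge_gap: int = 100,
    promoter_window: int = 50,
    max_intervals: int = 1000,
) -> list[tuple[int, int]]:
    """Flag elevated-coverage runs overlapping CDS or promoter windows.

    ``fold`` mode flags positions with depth >= threshold x element mean;
    ``sd`` mode (for low-coverage genomes) uses mean + threshold x SD.
    Maximal runs are merged across gaps <= ``merge_gap`` bp, then filtered
    to those overlapping a coding sequence or a promoter window. A
    per-element cap guards against repetitive-element blowups.
    """
    mean, sd = element_stats(track)
    if mode == "fold":
        cut = threshold * mean
    elif mode == "sd":
        cut = mean + threshold * sd
    else:
        raise ValueError(f"unknown mode {mode!r}")
    above = track.depth >= cut
    if mean == 0 or not above.any():
        return []
    # maximal runs of above-threshold positions (1-based inclusive)
    idx = np.flatnonzero(above)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    run_starts = np.concatenate([[idx[0]], idx[breaks + 1]]) + 1
    run_ends = np.concatenate([idx[breaks], [idx[-1]]]) + 1
    # merge runs across small gaps
    merged: list[list[int]] = []
    for s, e in zip(run_starts, run_ends):
        if merged and s - merged[-1][1] - 1 <= merge_gap:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])
    # keep runs overlapping CDS or promoter windows on this element
    windows = []
    for g in genes:
        if g.element_id != track.element_id:
            continue
        windows.append((g.start, g.end))
        windows.append(g.promoter_interval(promoter_window))
    out = []
    for s, e in merged:
        if any(s <= hi and e >= lo for lo, hi in windows):
            out.append((s, e))
    if len(out) > max_intervals:
        logger.warning(
            "element %s: %d qualifying duplications, capping at %d",
            track.element_id,
            len(out),
            max_intervals,
        )
        out = out[:max_intervals]
    return out


def compare_copy_numbers(
    calls: pd.DataFrame,
    group_col: str,
    value_col: str = "copy_number",
    method: str = "exact",
) -> pd.DataFrame:
    """Pairwise Mann-Whitney U tests with Holm-Bonferroni adjustment.

    ``calls`` holds one row per lineage with the grouping factor and the
    copy-number value. The exact U distribution is used by default because
    the asymptotic tie-corrected approximation is unreliable at the handful
    of lineages typical here (e.g. 4 vs 4 identical-valued groups must give
    p = 2/70); pass ``method='asymptotic'`` for large groups.
    """
    groups = calls.groupby(group_col)[value_col].apply(list)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    if any(len(v) < 2 for v in groups):
        raise ValueError("each group needs >= 2 calls")
    rows = []
    for ga, gb in combinations(sorted(groups.index), 2):
        res = stats.mannwhitneyu(
            groups[ga], groups[gb], alternative="two-sided", method=method
        )
        rows.append({"group_a": ga, "group_b": gb, "p": float(res.pvalue)})
    df = pd.DataFrame(rows)
    df["p_holm"] = multipletests(df["p"], method="holm")[1]
    return df


def loss_contingency_test(
    loss_flags: Sequence[bool], partner_class: Sequence[str]
) -> tuple[float, np.ndarray]:
    """Fisher's exact test of plasmid loss vs partner class.

    Returns (two-sided p, 2x2 table with rows = classes in sorted order,
    columns = [lost, retained]).
    """
    classes = sorted(set(partner_class))
    if len(classes) != 2:
        raise ValueError("need exactly two partner classes")
    flags = np.asarray(loss_flags, dtype=bool)
    labels = np.asarray(partner_class)
    table = np.array(
        [
            [int(np.sum(flags & (labels == c))), int(np.sum(~flags & (labels == c)))]
            for c in classes
        ]
    )
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.pvalue), table
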