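"""Between-condition comparison of enrichment-score distributions.

Global hypo-acetylation shows up as fewer called regions with lower
fold-change scores in the exposed arm; this module summarizes and bins
score distributions, tests the between-condition shift with a two-sided
Mann–Whitney rank test (distribution-free, since fold-change scores are
heavily right-skewed), and partitions two gene-symbol lists into
condition-unique and shared sets as used for the KRAB-family gene table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import floor
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import EnrichedRegion
from .errors import ValidationError


@dataclass(frozen=True)
class ScoreDistributionSummary:
    """Order statistics of one condition's region scores."""

    median: float
    mean: float
    min: float
    max: float
    n_regions: int


@dataclass(frozen=True)
class ComparisonResult:
    summary_a: ScoreDistributionSummary
    summary_b: ScoreDistributionSummary
    p_value: float
    direction: str  # "a<b" | "b<a" | "equal" (on medians)


@dataclass(frozen=True)
class OverlapPartition:
    """Symbols unique to each input list and shared between them."""

    unique_a: list[str]
    shared: list[str]
    unique_b: list[str]


def _scores(regions: Sequence[EnrichedRegion] | Sequence[float] | np.ndarray) -> np.ndarray:
    if len(regions) and isinstance(regions[0], EnrichedRegion):
        return np.asarray([r.score for r in regions], dtype=np.float64)
    return np.asarray(regions, dtype=np.float64)


def summarize_scores(regions) -> ScoreDistributionSummary:
    """Median/mean/min/max/count of the score vector (even-n median = midpair mean)."""
    s = _scores(regions)
    if s.size == 0:
        raise ValidationError("no regions to summarize")
    return ScoreDistributionSummary(
        median=float(np.median(s)), mean=float(np.mean(s)),
        min=float(np.min(s)), max=float(np.max(s)), n_regions=int(s.size))


def score_histogram(regions, bin_width: float) -> dict[float, int]:
    """Counts in half-open bins [lo, lo+w) anchored at zero; sums to n."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be > 0")
    s = _scores(regions)
    out: dict[float, int] = {}
    for x in s:
        lo = floor(x / bin_width) * bin_width
        out[lo] = out.get(lo, 0) + 1
    return out


def compare_conditions(regions_a, regions_b) -> ComparisonResult:
    """Summaries, two-sided Mann–Whitney p-value, and median direction flag."""
    sa, sb = _scores(regions_a), _scores(regions_b)
    summary_a, summary_b = summarize_scores(sa), summarize_scores(sb)
    p = float(stats.mannwhitneyu(sa, sb, alternative="two-sided").pvalue)
    if summary_a.median < summary_b.median:
        direction = "a<b"
    elif summary_b.median < summary_a.median:
        direction = "b<a"
    else:
        direction = "equal"
    return ComparisonResult(summary_a, summary_b, p, direction)


def partition_gene_sets(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapPartition:
    """Unique/shared partition of two symbol lists.

    Symbols are uppercased before comparison (mixed RIKEN-identifier and
    symbol capitalization is common) and duplicates collapse; each output
    list is sorted.
    """
    a = {str(s).upper() for s in set_a}
    b = {str(s).upper() for s in set_b}
    return OverlapPartition(unique_a=sorted(a - b), shared=sorted(a & b),
                            unique_b=sorted(b - a))


def load_krab_reference() -> pd.DataFrame:
    """Packaged reference partition of KRAB-domain gene symbols.

    Columns ``arsenic`` (54 symbols unique to the arsenic-exposed
    condition), ``shared`` (14) and ``control`` (36), reproduced verbatim
    from the published comparison. The printed columns are internally
    inconsistent — ZFP867 appears in both the arsenic-unique and shared
    columns and ZFP788 in both unique columns — so re-partitioning the
    column unions with :func:`partition_gene_sets` does not reproduce
    them exactly; they are preserved as printed for reference.
    """
    with resources.files("acetyldiff").joinpath("data/krab_genes.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
    return df


def krab_reference_columns() -> OverlapPartition:
    """The packaged KRAB table as three symbol lists (empty cells dropped)."""
    df = load_krab_reference()
    return OverlapPartition(
        unique_a=[s for s in df["arsenic"] if s],
        shared=[s for s in df["shared"] if s],
        unique_b=[s for s in df["control"] if s])
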