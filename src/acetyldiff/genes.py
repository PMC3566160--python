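"""Region-to-gene association and gene-list selection.

Each enrichment region is linked to (a) every gene whose body overlaps
it, (b) the nearest non-overlapping TSS within a distance cap (100 kb by
default), and (c) any other TSS within 1.5 times the nearest distance —
the master link list. Stricter lists are obtained by distance filtering,
and the gene list for functional-class analysis takes the top-scoring
regions whose nearest gene lies within 1 kb.

Distances are unsigned. The region reference point for TSS distances is
configurable (midpoint by default; nearest edge or summit optional); a
TSS lying inside the region counts as distance 0, which cannot arise for
non-overlapping genes since the TSS is an endpoint of the gene body.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import EnrichedRegion
from .errors import ValidationError

MASTER_MAX_DISTANCE = 100_000  # bp cap on region-to-TSS links
GENELIST_MAX_DISTANCE = 1_000  # bp cap for the top-region gene list
GENELIST_TOP_N = 3_000

REFERENCE_POINTS = ("midpoint", "edge", "summit")

ANNOTATION_COLUMNS = ["gene_id", "symbol", "chrom", "strand", "start", "end",
                      "tss", "classes"]


@dataclass(frozen=True)
class RegionGeneLink:
    """One region-gene association with its distance and relation kind."""

    region_id: str
    gene_id: str
    symbol: str
    distance: int
    relation: str  # overlapping | nearest_tss | within_1p5x


def validate_annotation(annotation: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, unique gene ids, and strand-resolved TSSs."""
    missing = [c for c in ("gene_id", "symbol", "chrom", "strand", "start", "end")
               if c not in annotation.columns]
    if missing:
        raise ValidationError(f"annotation missing columns {missing}")
    if annotation["gene_id"].duplicated().any():
        dup = annotation.loc[annotation["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValidationError(f"duplicate gene id {dup!r} in annotation")
    ann = annotation.copy()
    if "tss" not in ann.columns:
        ann["tss"] = np.where(ann["strand"] == "+", ann["start"], ann["end"] - 1)
    return ann


def _reference_point(region: EnrichedRegion, mode: str) -> int:
    if mode == "summit":
        return region.summit
    return (region.start + region.end) // 2


def _tss_distance(tss: np.ndarray, region: EnrichedRegion, mode: str) -> np.ndarray:
    if mode == "edge":
        d = np.where(tss < region.start, region.start - tss,
                     np.where(tss >= region.end, tss - (region.end - 1), 0))
    else:
        d = np.abs(tss - _reference_point(region, mode))
    # a TSS inside the region is at distance 0 regardless of reference mode
    inside = (tss >= region.start) & (tss < region.end)
    return np.where(inside, 0, d)


def associate_regions(regions: Sequence[EnrichedRegion], annotation: pd.DataFrame,
                      max_distance: int = MASTER_MAX_DISTANCE,
                      reference: str = "midpoint") -> list[RegionGeneLink]:
    """Build the master region-gene link list.

    For each region: every gene whose body overlaps it links with
    relation ``overlapping`` at distance 0; among non-overlapping genes
    the nearest TSS within ``max_distance`` links as ``nearest_tss``, and
    every other TSS within 1.5x that distance (and within the cap) links
    as ``within_1p5x``. Regions with no qualifying gene yield no links.
    Output order: region order, then overlapping links (by gene id), then
    TSS links by distance.
    """
    if reference not in REFERENCE_POINTS:
        raise ValidationError(f"reference must be one of {REFERENCE_POINTS}")
    ann = validate_annotation(annotation)
    links: list[RegionGeneLink] = []
    by_chrom = {chrom: sub.reset_index(drop=True)
                for chrom, sub in ann.groupby("chrom", sort=False)}
    for region in regions:
        sub = by_chrom.get(region.chrom)
        if sub is None:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        tss = sub["tss"].to_numpy()
        overlap = (starts < region.end) & (ends > region.start)
        ov_idx = np.flatnonzero(overlap)
        ov_order = ov_idx[np.argsort(sub["gene_id"].to_numpy()[ov_idx])]
        for i in ov_order:
            links.append(RegionGeneLink(region.name, sub["gene_id"][i],
                                        sub["symbol"][i], 0, "overlapping"))
        rest = np.flatnonzero(~overlap)
        if not len(rest):
            continue
        d = _tss_distance(tss[rest], region, reference)
        # ties on distance break deterministically by gene id
        order = np.lexsort((sub["gene_id"].to_numpy()[rest], d))
        d_near = int(d[order[0]])
        if d_near > max_distance:
            continue
        near_i = rest[order[0]]
        links.append(RegionGeneLink(region.name, sub["gene_id"][near_i],
                                    sub["symbol"][near_i], d_near, "nearest_tss"))
        limit = min(1.5 * d_near, max_distance)
        for o in order[1:]:
            if d[o] > limit:
                break
            gi = rest[o]
            links.append(RegionGeneLink(region.name, sub["gene_id"][gi],
                                        sub["symbol"][gi], int(d[o]), "within_1p5x"))
    return links


def filter_links(links: Sequence[RegionGeneLink],
                 max_distance: int) -> list[RegionGeneLink]:
    """Retain links at distance <= max_distance, preserving order."""
    return [l for l in links if l.distance <= max_distance]


def top_regions_gene_list(regions: Sequence[EnrichedRegion],
                          links: Sequence[RegionGeneLink],
                          n: int = GENELIST_TOP_N,
                          max_distance: int = GENELIST_MAX_DISTANCE) -> list[str]:
    """Gene symbols of the top-n scoring regions near a gene.

    Regions are ranked by score descending (ties by chrom, start); those
    whose nearest gene — distance 0 for an overlapping gene, else the
    nearest-TSS distance — lies within ``max_distance`` are kept, the
    list truncated to ``n`` regions, and the symbols of their links at
    distance <= ``max_distance`` returned, de-duplicated in rank order.
    """
    if n <= 0:
        raise ValidationError("n must be positive")
    nearest: dict[str, int] = {}
    by_region: dict[str, list[RegionGeneLink]] = {}
    for l in links:
        by_region.setdefault(l.region_id, []).append(l)
        if l.relation in ("overlapping", "nearest_tss"):
            nearest[l.region_id] = min(nearest.get(l.region_id, l.distance),
                                       l.distance)
    ranked = sorted(regions, key=lambda r: (-r.score, r.chrom, r.start))
    symbols: list[str] = []
    seen: set[str] = set()
    taken = 0
    for r in ranked:
        if taken >= n:
            break
        if nearest.get(r.name, max_distance + 1) > max_distance:
            continue
        taken += 1
        for l in by_region.get(r.name, []):
            if l.distance <= max_distance and l.symbol not in seen:
                seen.add(l.symbol)
                symbols.append(l.symbol)
    return symbols


def links_to_dataframe(links: Sequence[RegionGeneLink]) -> pd.DataFrame:
    return pd.DataFrame([l.__dict__ for l in links],
                        columns=["region_id", "gene_id", "symbol", "distance",
                                 "relation"])
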