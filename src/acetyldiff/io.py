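"""Plain-text readers and writers for every pipeline artifact.

All intermediate files are BED/TSV/JSON for inspectability: tags as
6-column BED, regions as BED6+ with p/q/summit extras, the gene
annotation and link lists as TSV, gene lists as one symbol per line,
and the run configuration as a YAML key-value file. Writers and readers
round-trip exactly.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .calling import EnrichedRegion
from .errors import ParseError, ValidationError
from .genes import ANNOTATION_COLUMNS, RegionGeneLink, links_to_dataframe
from .tags import TagSet


# ---------------------------------------------------------------------------
# Tags (BED)
# ---------------------------------------------------------------------------

def read_tags_bed(path) -> TagSet:
    """Read aligned tags from BED; 5' position is start (+) or end-1 (-).

    Requires >= 6 columns so every tag carries a strand; '.' strands are
    rejected because a tag without orientation cannot be extended.
    Malformed lines raise :class:`ParseError` with their line number.
    """
    chroms: list[str] = []
    positions: list[int] = []
    strands: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ParseError(
                    f"{path}:{lineno}: invalid interval [{start}, {end})")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}:{lineno}: tag files need a strand column (6 fields)")
            strand = fields[5]
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}:{lineno}: strand must be + or - for tags, got {strand!r}")
            chroms.append(fields[0])
            positions.append(start if strand == "+" else end - 1)
            strands.append(strand)
    if not chroms:
        warnings.warn(f"{path}: empty tag file", stacklevel=2)
    return TagSet.from_arrays(chroms, positions, strands)


def write_tags_bed(tags: TagSet, path) -> None:
    """Write tags as 6-column BED covering one base at the 5' position."""
    with open(path, "w") as fh:
        for row in tags.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.pos}\t{row.pos + 1}\t.\t0\t{row.strand}\n")


# ---------------------------------------------------------------------------
# Chromosome sizes / annotation / class tables
# ---------------------------------------------------------------------------

def read_chrom_sizes(path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: expected chrom<TAB>size")
            try:
                size = int(fields[1])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer size") from exc
            if size <= 0:
                raise ParseError(f"{path}:{lineno}: size must be positive")
            sizes[fields[0]] = size
    if not sizes:
        raise ParseError(f"{path}: no chromosomes")
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(sizes):
            fh.write(f"{chrom}\t{sizes[chrom]}\n")


def read_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str,
                                             "symbol": str, "strand": str,
                                             "classes": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ParseError(f"{path}: annotation missing columns {missing}")
    return ann


def write_annotation(annotation: pd.DataFrame, path) -> None:
    annotation.to_csv(path, sep="\t", index=False, columns=ANNOTATION_COLUMNS)


def classes_from_annotation(annotation: pd.DataFrame) -> dict[str, set[str]]:
    """Class -> member gene symbols, from the semicolon-separated labels."""
    classes: dict[str, set[str]] = {}
    for row in annotation.itertuples(index=False):
        for cls in str(row.classes).split(";"):
            cls = cls.strip()
            if cls:
                classes.setdefault(cls, set()).add(str(row.symbol))
    return classes


def read_class_table(path) -> dict[str, set[str]]:
    """Two-column TSV (class, gene) -> class membership mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (class, gene)")
    out: dict[str, set[str]] = {}
    for cls, sub in df.groupby(df.columns[0], sort=False):
        out[str(cls)] = set(sub[df.columns[1]].astype(str))
    return out


def write_class_table(classes: Mapping[str, set[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("class\tgene\n")
        for cls in sorted(classes):
            for gene in sorted(classes[cls]):
                fh.write(f"{cls}\t{gene}\n")


# ---------------------------------------------------------------------------
# Regions (BED6+)
# ---------------------------------------------------------------------------

_REGION_HEADER = ("#chrom\tstart\tend\tname\tscore_x10\tstrand\t"
                  "fold_change\tchip_tags\tinput_expected\tp_value\tq_value\tsummit")


def write_regions_bed(regions: Sequence[EnrichedRegion], path) -> None:
    """BED6+ region export; BED score = fold change x 10, rounded."""
    with open(path, "w") as fh:
        fh.write(_REGION_HEADER + "\n")
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\t"
                     f"{round(r.score * 10)}\t.\t{r.score:.6g}\t{r.chip_tags}\t"
                     f"{r.input_expected:.6g}\t{r.p_value:.6g}\t{r.q_value:.6g}\t"
                     f"{r.summit}\n")


def read_regions_bed(path) -> list[EnrichedRegion]:
    regions: list[EnrichedRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected 12 region columns")
            regions.append(EnrichedRegion(
                chrom=f[0], start=int(f[1]), end=int(f[2]), name=f[3],
                score=float(f[6]), chip_tags=int(f[7]),
                input_expected=float(f[8]), p_value=float(f[9]),
                q_value=float(f[10]), summit=int(f[11])))
    return regions


# ---------------------------------------------------------------------------
# Links, gene lists, tables
# ---------------------------------------------------------------------------

def write_links_tsv(links: Sequence[RegionGeneLink], path) -> None:
    links_to_dataframe(links).to_csv(path, sep="\t", index=False)


def read_links_tsv(path) -> list[RegionGeneLink]:
    df = pd.read_csv(path, sep="\t", dtype={"region_id": str, "gene_id": str,
                                            "symbol": str, "relation": str})
    return [RegionGeneLink(row.region_id, row.gene_id, row.symbol,
                           int(row.distance), row.relation)
            for row in df.itertuples(index=False)]


def write_gene_list(symbols: Sequence[str], path) -> None:
    with open(path, "w") as fh:
        for s in symbols:
            fh.write(f"{s}\n")


def read_gene_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_enrichment_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

def read_config_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a key-value mapping")
    return data


def write_config_yaml(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
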