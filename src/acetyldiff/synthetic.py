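"""Synthetic two-condition histone-acetylation ChIP-seq data.

Emulates the statistical structure the downstream caller assumes: a
homogeneous Poisson background of aligned tags, planted enrichment
regions near gene TSSs with configurable fold enrichment, and an
"exposed" condition in which a depletion factor shrinks the planted
fold enrichments and a dropout fraction removes regions outright —
the two knobs that jointly reproduce the qualitative signature of
global hypo-acetylation (fewer called regions with lower scores in
the exposed arm). Input libraries are background-only in both
conditions, so any between-condition difference originates in the
immunoprecipitated signal.

Reproducibility: one global ``seed`` drives a fixed splitting scheme
into independent substreams, one per library plus dedicated streams
for annotation layout, region planting and exposed-condition dropout,
so each library is individually reproducible regardless of the order
in which libraries are simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import SizingError, ValidationError
from .tags import TagSet

CONDITIONS = ("control", "exposed")
ROLES = ("chip", "input")

# Fixed substream keys: (condition, role) -> spawn key. Annotation, planting
# and dropout get their own keys so tag simulation never perturbs them.
_STREAM_KEYS = {
    ("control", "chip"): 11,
    ("control", "input"): 12,
    ("exposed", "chip"): 13,
    ("exposed", "input"): 14,
}
_ANNOTATION_KEY = 1
_PLANT_KEY = 2
_DROPOUT_KEY = 3

KRAB_CLASS = "KRAB box transcription factor"
_GENERIC_CLASSES = (
    "zinc finger transcription factor",
    "protein kinase",
    "membrane transporter",
    "RNA-binding protein",
    "cytoskeletal protein",
)


def _stream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class PlantedRegion:
    """One enrichment region planted into the ChIP signal."""

    chrom: str
    start: int
    end: int
    fold_enrichment: float
    gene_id: str | None = None


@dataclass
class SimConfig:
    """Study-design parameters of the simulated two-condition experiment.

    ``genome_length`` is per chromosome (bp); ``background_rate`` is the
    expected tags per bp of the un-enriched ChIP signal, ``input_rate``
    of the input library (defaults to the same). ``depletion_factor``
    multiplies every surviving planted fold enrichment in the exposed
    condition; ``dropout_fraction`` of planted regions revert fully to
    background there.
    """

    genome_length: int = 2_000_000
    n_chromosomes: int = 8
    n_genes: int = 800
    background_rate: float = 0.02
    input_rate: float | None = None
    fragment_length: int = 200
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    depletion_factor: float = 0.6
    dropout_fraction: float = 0.5
    krab_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_rate <= 0:
            raise ValidationError("background_rate must be > 0")
        if self.input_rate is not None and self.input_rate <= 0:
            raise ValidationError("input_rate must be > 0")
        if not (0 < self.depletion_factor <= 1):
            raise ValidationError("depletion_factor must be in (0, 1]")
        if not (0 <= self.dropout_fraction < 1):
            raise ValidationError("dropout_fraction must be in [0, 1)")
        if not (0 <= self.krab_fraction <= 1):
            raise ValidationError("krab_fraction must be in [0, 1]")
        if self.n_chromosomes < 1 or self.genome_length < 1:
            raise ValidationError("genome must have >= 1 chromosome of >= 1 bp")
        sizes = self.chrom_sizes()
        for pr in self.planted_regions:
            if pr.fold_enrichment < 1:
                raise ValidationError(
                    f"planted fold enrichment must be >= 1, got {pr.fold_enrichment}")
            if pr.chrom not in sizes:
                raise ValidationError(f"planted region on unknown chromosome {pr.chrom!r}")
            if not (0 <= pr.start < pr.end <= sizes[pr.chrom]):
                raise ValidationError(
                    f"planted region {pr.chrom}:{pr.start}-{pr.end} outside chromosome")

    @property
    def effective_input_rate(self) -> float:
        return self.background_rate if self.input_rate is None else self.input_rate

    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    def chrom_sizes(self) -> dict[str, int]:
        return {c: self.genome_length for c in self.chrom_names()}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def make_annotation(config: SimConfig) -> pd.DataFrame:
    """Lay out ``n_genes`` genes with strand-aware TSSs and class labels.

    Genes are placed in non-overlapping slots (round-robin across
    chromosomes) so TSSs never collide; each gene carries one generic
    functional class and a ``krab_fraction`` of genes additionally carry
    the KRAB label. Deterministic given ``config.seed``.

    Returns a frame with columns gene_id, symbol, chrom, strand, start,
    end, tss, classes (semicolon-separated).
    """
    if config.n_genes < 1:
        raise SizingError("n_genes must be >= 1")
    rng = _stream(config.seed, _ANNOTATION_KEY)
    chroms = config.chrom_names()
    per_chrom = [config.n_genes // config.n_chromosomes +
                 (1 if i < config.n_genes % config.n_chromosomes else 0)
                 for i in range(config.n_chromosomes)]
    min_slot = 4_000  # room for a gene body plus flanks
    for n_c in per_chrom:
        if n_c and config.genome_length // n_c < min_slot:
            raise SizingError(
                f"genome too small: {config.genome_length} bp cannot hold "
                f"{n_c} genes at >= {min_slot} bp per gene")

    records = []
    gid = 0
    for chrom, n_c in zip(chroms, per_chrom):
        if n_c == 0:
            continue
        slot = config.genome_length // n_c
        for j in range(n_c):
            gid += 1
            lo, hi = j * slot, (j + 1) * slot
            length = int(rng.integers(2_000, min(20_000, slot - 1_000) + 1))
            start = int(rng.integers(lo + 500, hi - length - 499))
            end = start + length
            strand = "+" if rng.random() < 0.5 else "-"
            tss = start if strand == "+" else end - 1
            records.append((f"g{gid:05d}", f"GENE{gid:05d}", chrom, strand,
                            start, end, tss))
    ann = pd.DataFrame(records, columns=[
        "gene_id", "symbol", "chrom", "strand", "start", "end", "tss"])

    n_krab = int(round(config.krab_fraction * config.n_genes))
    krab_idx = set(rng.choice(config.n_genes, size=n_krab, replace=False).tolist())
    classes = []
    for i in range(config.n_genes):
        cls = [str(rng.choice(_GENERIC_CLASSES))]
        if i in krab_idx:
            cls.insert(0, KRAB_CLASS)
        classes.append(";".join(cls))
    ann["classes"] = classes
    return ann


def plant_regions_near_tss(config: SimConfig, annotation: pd.DataFrame,
                           n_regions: int, width: int = 1_000,
                           fold_median: float = 9.0,
                           fold_sigma: float = 0.5) -> list[PlantedRegion]:
    """Plant ``n_regions`` enrichment regions centered on distinct gene TSSs.

    Fold enrichments are log-normal with the given median and log-sd,
    clipped to [1.5, 100] — a right-skewed score distribution whose bulk
    sits around the median with a long high tail, as histone-acetylation
    peak scores over input typically show. Deterministic given seed.
    """
    if n_regions < 1:
        raise ValidationError("n_regions must be >= 1")
    if n_regions > len(annotation):
        raise SizingError("cannot plant more regions than genes")
    rng = _stream(config.seed, _PLANT_KEY)
    chosen = rng.choice(len(annotation), size=n_regions, replace=False)
    folds = np.clip(rng.lognormal(mean=math.log(fold_median), sigma=fold_sigma,
                                  size=n_regions), 1.5, 100.0)
    sizes = config.chrom_sizes()
    plants = []
    for idx, fe in zip(chosen, folds):
        row = annotation.iloc[int(idx)]
        center = int(row["tss"])
        start = max(0, center - width // 2)
        end = min(sizes[row["chrom"]], start + width)
        plants.append(PlantedRegion(str(row["chrom"]), start, end, float(fe),
                                    str(row["gene_id"])))
    return sorted(plants, key=lambda p: (p.chrom, p.start))


def make_study(seed: int, n_regions: int = 250, region_width: int = 1_000,
               **overrides) -> tuple[SimConfig, pd.DataFrame]:
    """Assemble the default study: annotation plus planted regions.

    Returns the configuration (with ``planted_regions`` filled in) and
    the gene annotation table.
    """
    config = SimConfig(seed=seed, **overrides)
    annotation = make_annotation(config)
    plants = plant_regions_near_tss(config, annotation, n_regions, region_width)
    return replace(config, planted_regions=plants), annotation


# ---------------------------------------------------------------------------
# Tag simulation
# ---------------------------------------------------------------------------

def _dropout_indices(config: SimConfig) -> set[int]:
    n = len(config.planted_regions)
    n_drop = int(round(config.dropout_fraction * n))
    if n_drop == 0:
        return set()
    rng = _stream(config.seed, _DROPOUT_KEY)
    return set(rng.choice(n, size=n_drop, replace=False).tolist())


def exposed_dropout_regions(config: SimConfig) -> list[PlantedRegion]:
    """The planted regions that are absent in the exposed condition."""
    drop = _dropout_indices(config)
    return [p for i, p in enumerate(config.planted_regions) if i in drop]


def simulate_tags(config: SimConfig, condition: str, role: str) -> TagSet:
    """Draw one library of aligned tags.

    Background tag 5' positions form a homogeneous Poisson process at the
    library's background rate on every chromosome. For ChIP libraries the
    rate inside a planted region is ``background_rate * fold_enrichment``
    (times ``depletion_factor`` in the exposed condition; dropout regions
    revert to background). Input libraries are background-only in both
    conditions, identical in law. Strands are assigned equiprobably.
    """
    if condition not in CONDITIONS:
        raise ValidationError(f"unknown condition {condition!r}; expected {CONDITIONS}")
    if role not in ROLES:
        raise ValidationError(f"unknown role {role!r}; expected {ROLES}")
    rng = _stream(config.seed, _STREAM_KEYS[(condition, role)])
    rate = config.background_rate if role == "chip" else config.effective_input_rate

    chrom_list: list[str] = []
    pos_list: list[np.ndarray] = []
    for chrom, size in config.chrom_sizes().items():
        n_bg = rng.poisson(rate * size)
        chrom_list.extend([chrom] * n_bg)
        pos_list.append(rng.integers(0, size, size=n_bg))

    if role == "chip":
        drop = _dropout_indices(config) if condition == "exposed" else set()
        for i, pr in enumerate(config.planted_regions):
            if i in drop:
                continue
            fe = pr.fold_enrichment
            if condition == "exposed":
                fe *= config.depletion_factor
            extra_rate = rate * max(fe - 1.0, 0.0)
            if extra_rate <= 0:
                continue
            n_extra = rng.poisson(extra_rate * (pr.end - pr.start))
            chrom_list.extend([pr.chrom] * n_extra)
            pos_list.append(rng.integers(pr.start, pr.end, size=n_extra))

    positions = (np.concatenate(pos_list) if pos_list else
                 np.empty(0, dtype=np.int64))
    strands = np.where(rng.random(len(positions)) < 0.5, "+", "-")
    return TagSet.from_arrays(chrom_list, positions, strands)


def simulate_study(config: SimConfig) -> dict[tuple[str, str], TagSet]:
    """All four libraries (condition x role) of the two-condition design."""
    return {(c, r): simulate_tags(config, c, r) for c in CONDITIONS for r in ROLES}
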