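"""End-to-end pipeline driver.

Chains the stages on two conditions (control and exposed): enrichment
calling against input, peak splitting on the smoothed ChIP coverage,
region-to-gene association, selection of the top-scoring near-TSS gene
lists, functional-class enrichment, and the between-condition score
comparison with the KRAB-family overlap partition. Every intermediate
is written as plain text under the output directory together with a
machine-readable JSON manifest (parameters, per-stage counts); rerunning
with identical config and inputs is bit-identical.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .calling import CallerParams, call_enriched_regions, smooth_profile, split_regions
from .compare import compare_conditions, partition_gene_sets
from .coverage import build_profile
from .enrich import BENJAMINI_MAX, FE_MIN, enrich_classes
from .errors import PipelineStageError, ValidationError
from .genes import (GENELIST_MAX_DISTANCE, GENELIST_TOP_N, MASTER_MAX_DISTANCE,
                    associate_regions, filter_links, top_regions_gene_list)
from .io import (classes_from_annotation, read_annotation, read_chrom_sizes,
                 read_class_table, read_tags_bed, write_enrichment_tsv,
                 write_gene_list, write_links_tsv, write_manifest,
                 write_regions_bed)
from .synthetic import KRAB_CLASS

logger = logging.getLogger("acetyldiff")

CONDITIONS = ("control", "exposed")


@dataclass
class PipelineConfig:
    """Paths and parameters of one two-condition run."""

    chip_control: str
    input_control: str
    chip_exposed: str
    input_exposed: str
    chrom_sizes: str
    annotation: str
    output_dir: str
    class_table: str | None = None  # default: classes from annotation labels
    caller: CallerParams = field(default_factory=CallerParams)
    master_distance: int = MASTER_MAX_DISTANCE
    genelist_distance: int = GENELIST_MAX_DISTANCE
    top_n: int = GENELIST_TOP_N
    fe_min: float = FE_MIN
    benjamini_max: float = BENJAMINI_MAX
    enrichment_mode: str = "ease"
    seed: int = 0

    def tag_paths(self) -> dict[tuple[str, str], str]:
        return {("control", "chip"): self.chip_control,
                ("control", "input"): self.input_control,
                ("exposed", "chip"): self.chip_exposed,
                ("exposed", "input"): self.input_exposed}

    def validate(self) -> None:
        """Fail before any compute if a referenced input is missing."""
        required = list(self.tag_paths().values()) + [self.chrom_sizes,
                                                      self.annotation]
        if self.class_table is not None:
            required.append(self.class_table)
        for p in required:
            if not Path(p).is_file():
                raise ValidationError(f"input file not found: {p}")
        if self.top_n <= 0:
            raise ValidationError("top_n must be positive")
        if not (0 < self.benjamini_max < 1) or self.fe_min < 0:
            raise ValidationError("enrichment thresholds out of range")

    @classmethod
    def from_mapping(cls, data: dict) -> "PipelineConfig":
        caller = CallerParams(**data.pop("caller", {}))
        return cls(caller=caller, **data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineStageError:
                raise
            except Exception as exc:
                raise PipelineStageError(name, exc) from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "caller": dataclasses.asdict(config.caller),
            "master_distance": config.master_distance,
            "genelist_distance": config.genelist_distance,
            "top_n": config.top_n,
            "fe_min": config.fe_min,
            "benjamini_max": config.benjamini_max,
            "enrichment_mode": config.enrichment_mode,
        },
        "counts": {},
    }
    counts = manifest["counts"]

    @_stage("load")
    def load():
        sizes = read_chrom_sizes(config.chrom_sizes)
        annotation = read_annotation(config.annotation)
        tags = {key: read_tags_bed(path)
                for key, path in config.tag_paths().items()}
        for (cond, role), ts in tags.items():
            counts[f"tags_{cond}_{role}"] = ts.n_tags
            logger.info("loaded %d tags for %s/%s", ts.n_tags, cond, role)
        classes = (read_class_table(config.class_table)
                   if config.class_table is not None
                   else classes_from_annotation(annotation))
        return sizes, annotation, tags, classes

    sizes, annotation, tags, classes = load()

    @_stage("calling")
    def call(cond: str):
        chip, inp = tags[(cond, "chip")], tags[(cond, "input")]
        regions = call_enriched_regions(chip, inp, config.caller, sizes)
        counts[f"regions_{cond}"] = len(regions)
        profile = build_profile(chip, config.caller.window, sizes)
        smoothed = smooth_profile(profile, config.caller.smoothing_window)
        peaks = split_regions(regions, smoothed, config.caller.valley_fraction,
                              chip=chip, input_tags=inp,
                              pseudocount=config.caller.input_pseudocount)
        counts[f"peaks_{cond}"] = len(peaks)
        logger.info("%s: %d regions, %d peaks after splitting",
                    cond, len(regions), len(peaks))
        write_regions_bed(regions, out / f"regions_{cond}.bed")
        write_regions_bed(peaks, out / f"peaks_{cond}.bed")
        return peaks

    peaks = {cond: call(cond) for cond in CONDITIONS}

    @_stage("association")
    def associate(cond: str):
        links = associate_regions(peaks[cond], annotation,
                                  config.master_distance)
        counts[f"links_master_{cond}"] = len(links)
        write_links_tsv(links, out / f"links_master_{cond}.tsv")
        near = filter_links(links, config.genelist_distance)
        counts[f"links_{config.genelist_distance}bp_{cond}"] = len(near)
        write_links_tsv(near, out / f"links_near_{cond}.tsv")
        genes = top_regions_gene_list(peaks[cond], links, config.top_n,
                                      config.genelist_distance)
        counts[f"gene_list_{cond}"] = len(genes)
        write_gene_list(genes, out / f"gene_list_{cond}.txt")
        return links, genes

    gene_lists = {}
    for cond in CONDITIONS:
        _, gene_lists[cond] = associate(cond)

    @_stage("class_enrichment")
    def enrich(cond: str):
        table = enrich_classes(gene_lists[cond], classes,
                               annotation["symbol"],
                               mode=config.enrichment_mode,
                               fe_min=config.fe_min,
                               benjamini_max=config.benjamini_max)
        counts[f"classes_tested_{cond}"] = len(table)
        counts[f"classes_passing_{cond}"] = int(table["passes"].sum())
        write_enrichment_tsv(table, out / f"class_enrichment_{cond}.tsv")
        return table

    enrichment = {cond: enrich(cond) for cond in CONDITIONS
                  if gene_lists[cond]}

    @_stage("comparison")
    def compare():
        result = compare_conditions(peaks["exposed"], peaks["control"])
        manifest["comparison"] = {
            "exposed": dataclasses.asdict(result.summary_a),
            "control": dataclasses.asdict(result.summary_b),
            "mannwhitney_p": result.p_value,
            "direction": ("exposed<control" if result.direction == "a<b"
                          else "control<exposed" if result.direction == "b<a"
                          else "equal"),
        }
        krab = {cond: [g for g in gene_lists[cond]
                       if g.upper() in {s.upper() for s in classes.get(KRAB_CLASS, set())}]
                for cond in CONDITIONS}
        part = partition_gene_sets(krab["exposed"], krab["control"])
        counts["krab_unique_exposed"] = len(part.unique_a)
        counts["krab_shared"] = len(part.shared)
        counts["krab_unique_control"] = len(part.unique_b)
        width = max(len(part.unique_a), len(part.shared), len(part.unique_b))
        with open(out / "krab_partition.tsv", "w") as fh:
            fh.write("exposed_unique\tshared\tcontrol_unique\n")
            for i in range(width):
                row = [lst[i] if i < len(lst) else ""
                       for lst in (part.unique_a, part.shared, part.unique_b)]
                fh.write("\t".join(row) + "\n")

    if all(len(peaks[c]) for c in CONDITIONS):
        compare()

    write_manifest(manifest, out / "manifest.json")
    return manifest
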