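"""Region-to-gene association rules: overlap, nearest TSS, 1.5x, filters."""

import numpy as np
import pandas as pd
import pytest

import acetyldiff as ad
from acetyldiff.genes import (associate_regions, filter_links,
                              top_regions_gene_list)


def region(chrom="chr1", start=0, end=100, score=5.0, name="r1"):
    return ad.EnrichedRegion(chrom=chrom, start=start, end=end, chip_tags=10,
                             input_expected=1.0, score=score, p_value=1e-9,
                             q_value=1e-6, summit=(start + end) // 2, name=name)


def annotation(rows):
    """rows: (gene_id, symbol, chrom, strand, start, end)."""
    df = pd.DataFrame(rows, columns=["gene_id", "symbol", "chrom", "strand",
                                     "start", "end"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df


def brute_force_links(regions, ann, cap):
    """All-pairs oracle applying the stated rules literally (midpoint ref)."""
    out = set()
    for r in regions:
        mid = (r.start + r.end) // 2
        cands = []
        for g in ann.itertuples(index=False):
            if g.chrom != r.chrom:
                continue
            if g.start < r.end and g.end > r.start:
                out.add((r.name, g.gene_id, 0, "overlapping"))
                continue
            cands.append((abs(g.tss - mid), g.gene_id))
        cands.sort()
        if cands and cands[0][0] <= cap:
            d_near = cands[0][0]
            out.add((r.name, cands[0][1], d_near, "nearest_tss"))
            for d, gid in cands[1:]:
                if d <= min(1.5 * d_near, cap):
                    out.add((r.name, gid, d, "within_1p5x"))
    return out


class TestAssociateRegions:
    def test_one_point_five_x_rule(self):
        # TSSs at 400/550/700 bp from the region midpoint: nearest 400
        # links, 550 <= 1.5*400 links, 700 excluded
        ann = annotation([("g1", "A", "chr1", "+", 450, 3_000),
                          ("g2", "B", "chr1", "+", 600, 3_000),
                          ("g3", "C", "chr1", "+", 750, 3_000)])
        links = associate_regions([region(start=0, end=100)], ann)
        got = {(l.gene_id, l.distance, l.relation) for l in links}
        assert got == {("g1", 400, "nearest_tss"), ("g2", 550, "within_1p5x")}

    def test_region_inside_gene_body_single_overlap_link(self):
        ann = annotation([("g1", "A", "chr1", "+", 0, 10_000)])
        links = associate_regions([region(start=4_000, end=4_200)], ann)
        assert [(l.gene_id, l.distance, l.relation) for l in links] == \
            [("g1", 0, "overlapping")]

    def test_beyond_100kb_cap_yields_no_links(self):
        ann = annotation([("g1", "A", "chr1", "+", 120_050, 125_000)])
        assert associate_regions([region(start=0, end=100)], ann) == []

    def test_duplicate_gene_ids_rejected(self):
        ann = annotation([("g1", "A", "chr1", "+", 500, 1_000),
                          ("g1", "B", "chr1", "+", 2_000, 3_000)])
        with pytest.raises(ad.ValidationError, match="duplicate"):
            associate_regions([region()], ann)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(12)
        rows = []
        for i in range(150):
            chrom = f"chr{rng.integers(1, 3)}"
            start = int(rng.integers(0, 480_000))
            end = start + int(rng.integers(1_000, 15_000))
            strand = rng.choice(["+", "-"])
            rows.append((f"g{i:03d}", f"S{i:03d}", chrom, strand, start, end))
        ann = annotation(rows)
        regions = [region(chrom=f"chr{rng.integers(1, 3)}",
                          start=int(s), end=int(s) + 500, name=f"r{j}")
                   for j, s in enumerate(rng.integers(0, 490_000, 40))]
        got = {(l.region_id, l.gene_id, l.distance, l.relation)
               for l in associate_regions(regions, ann)}
        assert got == brute_force_links(regions, ann, 100_000)

    def test_invariant_to_input_ordering(self):
        ann = annotation([("g1", "A", "chr1", "+", 450, 3_000),
                          ("g2", "B", "chr1", "-", 5_000, 6_001)])
        regions = [region(name="r1"), region(start=7_000, end=7_100, name="r2")]
        a = associate_regions(regions, ann)
        b = associate_regions(regions[::-1], ann.iloc[::-1].reset_index(drop=True))
        assert {tuple(l.__dict__.values()) for l in a} == \
            {tuple(l.__dict__.values()) for l in b}


class TestFilterLinks:
    def make_links(self, distances):
        return [ad.RegionGeneLink("r1", f"g{i}", f"S{i}", d, "within_1p5x")
                for i, d in enumerate(distances)]

    def test_threshold_filter(self):
        links = self.make_links([0, 400, 550, 5_000])
        assert [l.distance for l in filter_links(links, 1_000)] == [0, 400, 550]

    def test_zero_distance_bound(self):
        links = self.make_links([0, 400])
        assert [l.distance for l in filter_links(links, 0)] == [0]

    def test_identity_at_master_cap(self):
        ann = annotation([("g1", "A", "chr1", "+", 450, 3_000),
                          ("g2", "B", "chr1", "+", 600, 3_000)])
        master = associate_regions([region()], ann, max_distance=100_000)
        assert filter_links(master, 100_000) == master


class TestTopRegionsGeneList:
    def setup_method(self):
        self.ann = annotation(
            [(f"g{i}", f"S{i}", "chr1", "+", 10_000 * i + 500,
              10_000 * i + 5_000) for i in range(1, 6)])
        self.regions = [region(start=10_000 * i, end=10_000 * i + 600,
                               score=10 - i, name=f"r{i}") for i in range(1, 6)]
        self.links = associate_regions(self.regions, self.ann)

    def test_top_n_semantics(self):
        got = top_regions_gene_list(self.regions, self.links, n=3,
                                    max_distance=1_000)
        # highest scores are r1, r2, r3 -> their overlapping genes
        assert got == ["S1", "S2", "S3"]

    def test_deduplicates_shared_genes(self):
        regions = [region(start=1_000, end=1_200, score=9, name="ra"),
                   region(start=1_300, end=1_500, score=8, name="rb")]
        ann = annotation([("g1", "A", "chr1", "+", 500, 2_000)])
        links = associate_regions(regions, ann)
        assert top_regions_gene_list(regions, links, n=10,
                                     max_distance=1_000) == ["A"]

    def test_far_regions_not_counted_against_n(self):
        got = top_regions_gene_list(self.regions, self.links, n=5,
                                    max_distance=1_000)
        assert got == [f"S{i}" for i in range(1, 6)]

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ad.ValidationError):
            top_regions_gene_list(self.regions, self.links, n=0)

    def test_planted_genes_recovered_end_to_end(self, small_study,
                                                small_regions):
        config, annotation_df, _ = small_study
        links = associate_regions(small_regions, annotation_df)
        genes = top_regions_gene_list(small_regions, links, n=3_000,
                                      max_distance=1_000)
        planted = {p.gene_id for p in config.planted_regions}
        id_to_symbol = dict(zip(annotation_df["gene_id"],
                                annotation_df["symbol"]))
        recovered_plants = set()
        for r in small_regions:
            for p in config.planted_regions:
                if r.chrom == p.chrom and r.start < p.end and r.end > p.start:
                    recovered_plants.add(p.gene_id)
        assert {id_to_symbol[g] for g in recovered_plants} <= set(genes)
        assert planted  # sanity: the study actually planted regions
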