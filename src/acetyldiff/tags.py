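"""Aligned sequence tags.

A *tag* is a single aligned single-end read, reduced to its 5' genomic
position and strand. Coordinates are 0-based half-open (BED convention)
throughout the package; a tag itself occupies a single base pair at its
5' end until it is computationally extended to the fragment length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import CoordinateError, ValidationError

STRANDS = ("+", "-")


@dataclass
class TagSet:
    """Tags of one sequencing library, stored as a position-sorted table.

    ``df`` has columns ``chrom`` (str), ``pos`` (int64, 5' position) and
    ``strand`` ('+' or '-'), sorted by (chrom, pos, strand).
    """

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        {"chrom": pd.Series(dtype=str),
         "pos": pd.Series(dtype=np.int64),
         "strand": pd.Series(dtype=str)}))

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand"}
        if not required.issubset(self.df.columns):
            raise ValidationError(f"TagSet frame needs columns {sorted(required)}")
        if len(self.df):
            if (self.df["pos"].to_numpy() < 0).any():
                raise ValidationError("negative tag position")
            bad = ~self.df["strand"].isin(STRANDS)
            if bad.any():
                raise ValidationError(
                    f"invalid strand value(s): {sorted(self.df.loc[bad, 'strand'].unique())}")
        self.df = (self.df.sort_values(["chrom", "pos", "strand"], kind="mergesort")
                   .reset_index(drop=True))

    @classmethod
    def from_arrays(cls, chroms: Iterable[str], positions: Iterable[int],
                    strands: Iterable[str]) -> "TagSet":
        return cls(pd.DataFrame({
            "chrom": pd.Series(list(chroms), dtype=str),
            "pos": pd.Series(np.asarray(list(positions), dtype=np.int64)),
            "strand": pd.Series(list(strands), dtype=str)}))

    @property
    def n_tags(self) -> int:
        return len(self.df)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self.df["chrom"].unique())

    def positions(self, chrom: str, strand: str | None = None) -> np.ndarray:
        """Sorted 5' positions on one chromosome, optionally one strand."""
        sub = self.df[self.df["chrom"] == chrom]
        if strand is not None:
            sub = sub[sub["strand"] == strand]
        return sub["pos"].to_numpy()

    def validate_bounds(self, chrom_sizes: Mapping[str, int]) -> None:
        """Raise :class:`CoordinateError` naming the first out-of-bounds tag."""
        for chrom, sub in self.df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise CoordinateError(f"tag on unknown chromosome {chrom!r}")
            size = chrom_sizes[chrom]
            over = sub[sub["pos"] >= size]
            if len(over):
                row = over.iloc[0]
                raise CoordinateError(
                    f"tag {row['chrom']}:{row['pos']}({row['strand']}) "
                    f"beyond chromosome end {size}")

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.df)
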