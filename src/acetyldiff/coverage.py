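"""Fragment-length estimation and read-extension coverage profiles.

Single-end tags are computationally extended to the library's fragment
length and the per-base coverage accumulated over each chromosome; the
raw profile can then be scaled to reads-per-million (RPM) units for
cross-library comparability. The fragment length is estimated from the
library size distribution measured on an analyzer trace: the mode of
the observed insert lengths minus the total adapter contribution
(120 bp for TruSeq-style adapters).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import CoordinateError, InvalidLibraryError, StateError, ValidationError
from .tags import TagSet

TRUSEQ_ADAPTER_TOTAL = 120  # bp of adapter sequence in each measured insert


@dataclass
class LibrarySizeDistribution:
    """Observed library insert lengths (bp) plus the adapter constant."""

    lengths: Sequence[int]
    adapter_total: int = TRUSEQ_ADAPTER_TOTAL

    def __post_init__(self) -> None:
        if not len(self.lengths):
            raise ValidationError("need at least one observed length")
        if any(l <= 0 for l in self.lengths):
            raise ValidationError("library lengths must be positive")
        if self.adapter_total < 0:
            raise ValidationError("adapter_total must be >= 0")


def estimate_fragment_length(dist: LibrarySizeDistribution) -> int:
    """Modal insert length minus the adapter total; mode ties break low."""
    counts = Counter(dist.lengths)
    top = max(counts.values())
    mode = min(l for l, c in counts.items() if c == top)
    frag = mode - dist.adapter_total
    if frag <= 0:
        raise InvalidLibraryError(
            f"fragment length {frag} <= 0 (mode {mode}, adapter {dist.adapter_total})")
    return int(frag)


@dataclass
class CoverageProfile:
    """Per-chromosome depth vectors, raw tag coverage or RPM-scaled.

    ``values`` maps chromosome name to a vector whose length equals the
    chromosome length; ``units`` is set exactly once to ``"rpm"`` by
    :func:`scale_rpm`.
    """

    values: dict[str, np.ndarray] = field(default_factory=dict)
    units: str = "raw"
    fragment_length: int = 0

    def __post_init__(self) -> None:
        if self.units not in ("raw", "rpm"):
            raise ValidationError(f"units must be raw|rpm, got {self.units!r}")
        for chrom, v in self.values.items():
            if (np.asarray(v) < 0).any():
                raise ValidationError(f"negative depth on {chrom}")

    def total(self) -> float:
        """Sum of depth over the whole genome (covered base pairs if raw)."""
        return float(sum(v.sum() for v in self.values.values()))


def build_profile(tags: TagSet, fragment_length: int,
                  chrom_sizes: Mapping[str, int]) -> CoverageProfile:
    """Extend each tag to the fragment length and count per-base coverage.

    A + strand tag with 5' end at p covers [p, p+F); a - strand tag with
    5' end at p covers [p-F+1, p+1). Extensions are clipped at chromosome
    bounds, so edge tags contribute fewer than F covered bases rather
    than erroring. The sum of the raw profile therefore equals the number
    of tags times F minus the clipped bases.
    """
    if fragment_length < 1:
        raise ValidationError("fragment_length must be >= 1")
    tags.validate_bounds(chrom_sizes)
    values: dict[str, np.ndarray] = {}
    for chrom, size in chrom_sizes.items():
        diff = np.zeros(size + 1, dtype=np.int64)
        fwd = tags.positions(chrom, "+")
        if len(fwd):
            np.add.at(diff, fwd, 1)
            np.add.at(diff, np.minimum(fwd + fragment_length, size), -1)
        rev = tags.positions(chrom, "-")
        if len(rev):
            starts = np.maximum(rev - fragment_length + 1, 0)
            np.add.at(diff, starts, 1)
            np.add.at(diff, rev + 1, -1)
        values[chrom] = np.cumsum(diff[:-1])
    return CoverageProfile(values=values, units="raw",
                           fragment_length=fragment_length)


def scale_rpm(profile: CoverageProfile, total_tags: int) -> CoverageProfile:
    """Scale a raw profile by 1e6 / library size; sets units to rpm."""
    if profile.units != "raw":
        raise StateError("profile already RPM-scaled")
    if total_tags < 1:
        raise ValidationError("total_tags must be >= 1")
    factor = 1e6 / total_tags
    scaled = {c: v.astype(np.float64) * factor for c, v in profile.values.items()}
    return CoverageProfile(values=scaled, units="rpm",
                           fragment_length=profile.fragment_length)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def profile_to_bedgraph(profile: CoverageProfile) -> Iterator[tuple[str, int, int, float]]:
    """Run-length collapsed (chrom, start, end, value) records, zeros skipped."""
    for chrom in sorted(profile.values):
        v = profile.values[chrom]
        if not len(v):
            continue
        change = np.flatnonzero(np.diff(v)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(v)]))
        for s, e in zip(starts, ends):
            val = v[s]
            if val != 0:
                yield chrom, int(s), int(e), float(val)


def write_bedgraph(profile: CoverageProfile, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, val in profile_to_bedgraph(profile):
            fh.write(f"{chrom}\t{s}\t{e}\t{val:g}\n")


def write_wiggle(profile: CoverageProfile, path, step: int = 1) -> None:
    """Fixed-step wiggle export (step also used as the span)."""
    if step < 1:
        raise ValidationError("step must be >= 1")
    with open(path, "w") as fh:
        for chrom in sorted(profile.values):
            v = profile.values[chrom]
            fh.write(f"fixedStep chrom={chrom} start=1 step={step} span={step}\n")
            for i in range(0, len(v), step):
                fh.write(f"{np.mean(v[i:i + step]):g}\n")
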