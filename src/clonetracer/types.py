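"""Core domain types: somatic variants, copy-number segments, sample metadata.

Coordinates follow the conventions of the formats being imitated: VCF
positions and segment tables are 1-based with inclusive segment ends
(Battenberg dialect); BED intervals are 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

_BASES = frozenset("ACGT")

SITES = ("prostate", "seminal_vesicle", "lymph_node", "other")


@dataclass(frozen=True)
class SnvRecord:
    """One somatic SNV with per-sample read support.

    ``alt_reads`` / ``total_reads`` are aligned to the cohort's ordered
    sample list, which is carried alongside the records (every record in a
    cohort shares the same order).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: tuple
    total_reads: tuple
    somatic_score: float
    context: Optional[str] = None

    def __post_init__(self) -> None:
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"{self.chrom}:{self.pos}: ref/alt must be single bases "
                f"from ACGT, got {self.ref!r}>{self.alt!r}")
        if self.ref == self.alt:
            raise ValueError(f"{self.chrom}:{self.pos}: ref == alt")
        if len(self.alt_reads) != len(self.total_reads):
            raise ValueError("alt_reads and total_reads length mismatch")
        for a, t in zip(self.alt_reads, self.total_reads):
            if a < 0 or t < a:
                raise ValueError(
                    f"{self.chrom}:{self.pos}: need 0 <= alt <= total, "
                    f"got alt={a} total={t}")
        if self.context is not None:
            if len(self.context) != 3 or any(c not in _BASES for c in self.context):
                raise ValueError(f"bad trinucleotide context {self.context!r}")
            if self.context[1] != self.ref:
                raise ValueError(
                    f"context {self.context} not centred on ref {self.ref}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def vaf(self, sample_index: int) -> float:
        t = self.total_reads[sample_index]
        return self.alt_reads[sample_index] / t if t > 0 else float("nan")


@dataclass(frozen=True)
class CnState:
    """One allele-specific copy-number state with its cell fraction."""

    n_major: int
    n_minor: int
    fraction: float

    def __post_init__(self) -> None:
        if self.n_major < 0 or self.n_minor < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.n_major < self.n_minor:
            raise ValueError(
                f"n_major ({self.n_major}) < n_minor ({self.n_minor})")
        if not (0 < self.fraction <= 1 + 1e-9):
            raise ValueError(f"state fraction {self.fraction} not in (0, 1]")

    @property
    def total(self) -> int:
        return self.n_major + self.n_minor


@dataclass(frozen=True)
class Segment:
    """A copy-number segment, 1-based inclusive, with up to two states."""

    chrom: str
    start: int
    end: int
    state1: CnState
    state2: Optional[CnState] = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")
        if self.state2 is not None:
            s = self.state1.fraction + self.state2.fraction
            if abs(s - 1.0) > 1e-6:
                raise ValueError(
                    f"{self.chrom}:{self.start}-{self.end}: state fractions "
                    f"sum to {s}, expected 1")
        elif abs(self.state1.fraction - 1.0) > 1e-6:
            raise ValueError(
                f"{self.chrom}:{self.start}-{self.end}: single-state segment "
                f"must have fraction 1, got {self.state1.fraction}")

    @property
    def subclonal(self) -> bool:
        return self.state2 is not None

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def tumour_total(self) -> float:
        """Fraction-weighted total tumour copy number (n_t)."""
        n = self.state1.fraction * self.state1.total
        if self.state2 is not None:
            n += self.state2.fraction * self.state2.total
        return n

    @property
    def n_major_max(self) -> int:
        """Largest major copy number across states; multiplicity ceiling."""
        if self.state2 is not None:
            return max(self.state1.n_major, self.state2.n_major)
        return self.state1.n_major

    @property
    def major_state(self) -> CnState:
        """The state carried by the larger cell fraction."""
        if self.state2 is not None and self.state2.fraction > self.state1.fraction:
            return self.state2
        return self.state1

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos <= self.end


@dataclass
class SegmentProfile:
    """Per-sample allele-specific copy-number segmentation."""

    sample_id: str
    segments: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.segments = sorted(
            self.segments, key=lambda s: (_chrom_key(s.chrom), s.start))
        prev: dict = {}
        for seg in self.segments:
            p = prev.get(seg.chrom)
            if p is not None and seg.start <= p.end:
                raise ValueError(
                    f"overlapping segments on {seg.chrom}: "
                    f"{p.start}-{p.end} and {seg.start}-{seg.end}")
            prev[seg.chrom] = seg

    def find(self, chrom: str, pos: int) -> Optional[Segment]:
        """Segment covering ``chrom:pos``, or None."""
        for seg in self.segments:
            if seg.contains(chrom, pos):
                return seg
        return None

    @property
    def total_length(self) -> int:
        return sum(s.length for s in self.segments)

    def chromosomes(self) -> list:
        seen: list = []
        for s in self.segments:
            if s.chrom not in seen:
                seen.append(s.chrom)
        return seen


def _chrom_key(chrom: str):
    c = chrom.removeprefix("chr")
    return (0, int(c)) if c.isdigit() else (1, c)


@dataclass(frozen=True)
class PuritySample:
    """Purity/ploidy estimate and anatomical site for one sample."""

    sample_id: str
    purity: float
    ploidy: float
    site: str = "prostate"

    def __post_init__(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity {self.purity} not in (0, 1]")
        if self.ploidy <= 0:
            raise ValueError(f"ploidy {self.ploidy} must be > 0")
        if self.site not in SITES:
            raise ValueError(f"site {self.site!r} not one of {SITES}")


def check_cohort(records: Sequence[SnvRecord], samples: Sequence[str]) -> None:
    """Verify every record carries counts for the full ordered sample list."""
    n = len(samples)
    for r in records:
        if len(r.alt_reads) != n:
            raise ValueError(
                f"{r.locus_id}: {len(r.alt_reads)} samples, expected {n}")
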