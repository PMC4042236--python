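"""Core genomic coordinate types.

All coordinates are 0-based half-open ([start, end)), the BED convention.
Wiggle output is the only place a 1-based shift happens.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class BindpatError(Exception):
    """Base class for package errors."""


class ParseError(BindpatError):
    """A genomic text file could not be parsed; message names the line."""


class ConfigError(BindpatError):
    """Invalid configuration or parameter value."""


class DegenerateInputError(BindpatError):
    """Input is structurally valid but the operation is undefined on it."""


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval.

    Parameters
    ----------
    chrom : str
        Chromosome name (non-empty).
    start, end : int
        0-based half-open coordinates, ``0 <= start < end``.
    strand : str
        '+', '-' or '.' (unknown).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Integer midpoint, used for read-to-bin assignment."""
        return (self.start + self.end) // 2

    @property
    def center(self) -> float:
        """Geometric center, used for region-to-region distances."""
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between nearest edges; 0 when overlapping.

        Raises ValueError for intervals on different chromosomes.
        """
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if other.start >= self.end:
            return other.start - self.end
        return self.start - other.end


@dataclass(frozen=True)
class Peak:
    """An enriched region from an external peak caller, tagged with its sample."""

    interval: GenomicInterval
    sample: str
    name: str = ""


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene (one row per transcript/isoform; identity is the name)."""

    name: str
    interval: GenomicInterval

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene name must be non-empty")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site (bp)."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start
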