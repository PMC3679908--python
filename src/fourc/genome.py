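"""Coordinate-space primitives shared by every pipeline stage.

All coordinates are 0-based, half-open (BED convention). 1-based SAM
positions are converted on ingest in :mod:`fourc.io`. Distances between
positions on different chromosomes are reported as the sentinel
:data:`DIFFERENT_CHROMOSOME` (``math.inf``), so distance thresholds
compose naturally with ``<``/``>`` comparisons.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

DIFFERENT_CHROMOSOME: float = math.inf


class UnknownChromosomeError(KeyError):
    """Raised when a coordinate references a chromosome absent from the layout."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths defining the coordinate space.

    Parameters
    ----------
    chromosomes
        Ordered ``(name, length)`` pairs. Names must be unique and lengths
        strictly positive.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __init__(self, chromosomes: Iterable[tuple[str, int]]):
        chroms = tuple((str(n), int(l)) for n, l in chromosomes)
        names = [n for n, _ in chroms]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in chroms:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "chromosomes", chroms)
        object.__setattr__(self, "_lengths", dict(chroms))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(n for n, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]  # type: ignore[attr-defined]
        except KeyError:
            raise UnknownChromosomeError(chrom) from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths  # type: ignore[attr-defined]

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.chromosomes)

    def total_length(self, exclude: Iterable[str] = ()) -> int:
        skip = set(exclude)
        return sum(l for n, l in self.chromosomes if n not in skip)

    @classmethod
    def from_chrom_sizes(cls, path: str | Path) -> "GenomeLayout":
        """Read a UCSC chrom.sizes file (two whitespace-separated columns)."""
        chroms = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            chroms.append((fields[0], int(fields[1])))
        return cls(chroms)

    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str]) -> "GenomeLayout":
        """Derive a layout from in-memory chromosome sequences."""
        return cls((name, len(seq)) for name, seq in sequences.items())


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def validate(self, layout: GenomeLayout) -> None:
        if self.end > layout.length(self.chrom):
            raise ValueError(
                f"interval [{self.start}, {self.end}) exceeds {self.chrom} "
                f"length {layout.length(self.chrom)}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class SitePosition:
    """Single-base position, the anchor of an interacting site."""

    chrom: str
    pos: int

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError(f"negative position {self.pos}")


@dataclass(frozen=True)
class BaitRegion:
    """The fixed viewpoint whose interactome is assayed.

    Defined as the span of the nested (2nd-round) inverse-PCR primers
    extended by 500 bp on each side, giving a ~1 kb region.
    """

    chrom: str
    start: int
    end: int
    primer_fwd: int
    primer_rev: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid bait span [{self.start}, {self.end})")

    @classmethod
    def from_primers(
        cls,
        chrom: str,
        primer_fwd: int,
        primer_rev: int,
        layout: GenomeLayout,
        extension: int = 500,
    ) -> "BaitRegion":
        start = min(primer_fwd, primer_rev) - extension
        end = max(primer_fwd, primer_rev) + extension
        if start < 0 or end > layout.length(chrom):
            raise ValueError("extended bait region exceeds chromosome bounds")
        return cls(chrom, start, end, primer_fwd, primer_rev)

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def distance(a: SitePosition, b: SitePosition, layout: GenomeLayout | None = None) -> float:
    """Base-pair separation of two positions; inf across chromosomes.

    Symmetric; a metric when restricted to one chromosome.
    """
    if layout is not None:
        for p in (a, b):
            if p.pos >= layout.length(p.chrom):
                raise ValueError(f"position {p.pos} beyond {p.chrom}")
    if a.chrom != b.chrom:
        return DIFFERENT_CHROMOSOME
    return float(abs(a.pos - b.pos))


def interval_distance(
    p: SitePosition, iv: GenomicInterval, layout: GenomeLayout | None = None
) -> float:
    """Gap between a position and the nearest base contained in the interval.

    0 when ``iv.start <= p.pos < iv.end``; on the same chromosome outside the
    interval, the distance to the nearest contained base, so a position one
    past the last base has distance 1 + 0 = ``p.pos - (end - 1)``; inf across
    chromosomes.
    """
    if layout is not None:
        iv.validate(layout)
        if p.pos >= layout.length(p.chrom):
            raise ValueError(f"position {p.pos} beyond {p.chrom}")
    if p.chrom != iv.chrom:
        return DIFFERENT_CHROMOSOME
    if p.pos < iv.start:
        return float(iv.start - p.pos)
    if p.pos >= iv.end:
        return float(p.pos - (iv.end - 1))
    return 0.0
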