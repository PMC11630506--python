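"""Absolute <-> chromosome-relative genomic coordinate conversion.

Genome browsers address the concatenated canonical chromosomes of an
assembly with a single 1-based "absolute" coordinate.  Descriptions meant
for people are phrased in chromosome-relative terms instead ("chromosome 6,
position 130737676").  This module holds the assembly table (ordered
chromosome lengths with cumulative offsets), the bidirectional conversion,
and the natural-language phrasing of genomic ranges, including the
"unmapped part of the genome at the end" that appears when an absolute
position runs past the canonical total.

Both scales are 1-based and inclusive.  Positions greater than the
assembly total are unmapped: they belong to no chromosome.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .assemblies import BUNDLED_ASSEMBLIES


class CoordinateError(ValueError):
    """Raised for invalid assemblies, chromosomes or positions."""


@dataclass(frozen=True)
class RelativePosition:
    """A chromosome-relative genomic position.

    ``mapped`` is False for absolute positions beyond the assembly total;
    such positions carry no chromosome.
    """

    chromosome: str | None
    position: int | None
    mapped: bool = True

    def phrase(self) -> str:
        if not self.mapped:
            return "an unmapped part of the genome"
        return f"{chromosome_phrase(self.chromosome)}, position {self.position}"


@dataclass(frozen=True)
class AssemblyTable:
    """Ordered chromosomes of one assembly with cumulative offsets."""

    name: str
    chromosomes: tuple[str, ...]
    lengths: tuple[int, ...]
    offsets: tuple[int, ...] = field(init=False)
    total: int = field(init=False)

    def __post_init__(self) -> None:
        if len(self.chromosomes) != len(set(self.chromosomes)):
            raise CoordinateError(f"duplicate chromosome in assembly {self.name!r}")
        if not self.chromosomes:
            raise CoordinateError("assembly has no chromosomes")
        for chrom, length in zip(self.chromosomes, self.lengths):
            if length <= 0:
                raise CoordinateError(f"non-positive length for {chrom!r}: {length}")
        offsets = []
        running = 0
        for length in self.lengths:
            offsets.append(running)
            running += length
        object.__setattr__(self, "offsets", tuple(offsets))
        object.__setattr__(self, "total", running)

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[self.chromosomes.index(chrom)]
        except ValueError:
            raise CoordinateError(f"unknown chromosome {chrom!r} in {self.name}") from None

    def offset_of(self, chrom: str) -> int:
        try:
            return self.offsets[self.chromosomes.index(chrom)]
        except ValueError:
            raise CoordinateError(f"unknown chromosome {chrom!r} in {self.name}") from None


def build_assembly(source: str | Path | Iterable[tuple[str, int]], *, name: str | None = None) -> AssemblyTable:
    """Build an :class:`AssemblyTable`.

    ``source`` is a bundled assembly name (``hg38``/``hg19``), a path to a
    UCSC-style two-column chrom.sizes file (tab- or space-separated), or an
    iterable of ``(chromosome, length)`` pairs in the desired order.
    """
    if isinstance(source, str) and source in BUNDLED_ASSEMBLIES:
        table = BUNDLED_ASSEMBLIES[source]
        return AssemblyTable(source, tuple(table), tuple(table.values()))
    if isinstance(source, (str, Path)):
        path = Path(source)
        if not path.exists():
            raise CoordinateError(
                f"{source!r} is neither a bundled assembly ({', '.join(BUNDLED_ASSEMBLIES)}) "
                "nor an existing chrom.sizes file"
            )
        pairs = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise CoordinateError(f"malformed chrom.sizes line: {line!r}")
            pairs.append((fields[0], int(fields[1])))
        return AssemblyTable(name or path.stem, tuple(c for c, _ in pairs), tuple(l for _, l in pairs))
    pairs = list(source)
    return AssemblyTable(name or "custom", tuple(c for c, _ in pairs), tuple(l for _, l in pairs))


def abs_to_rel(pos: int, table: AssemblyTable) -> RelativePosition:
    """Convert a 1-based absolute position to a chromosome-relative one.

    Positions past the assembly total are returned unmapped.
    """
    if pos < 1:
        raise CoordinateError(f"absolute position must be >= 1, got {pos}")
    if pos > table.total:
        return RelativePosition(None, None, mapped=False)
    # rightmost chromosome whose offset is < pos
    i = bisect.bisect_left(table.offsets, pos) - 1
    return RelativePosition(table.chromosomes[i], pos - table.offsets[i])


def rel_to_abs(chrom: str, pos: int, table: AssemblyTable) -> int:
    """Convert a chromosome-relative position to the absolute scale."""
    length = table.length_of(chrom)
    if not 1 <= pos <= length:
        raise CoordinateError(f"position {pos} outside {chrom} (1..{length})")
    return table.offset_of(chrom) + pos


def chromosome_phrase(chrom: str) -> str:
    """Human phrasing of a chromosome name: numerals by number, X/Y by letter.

    ``chr6`` -> "chromosome 6"; ``chrX`` -> "the X chromosome"; a custom name
    like ``scaffold_1`` -> "chromosome scaffold_1".
    """
    short = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if short.upper() in ("X", "Y"):
        return f"the {short.upper()} chromosome"
    return f"chromosome {short}"


def _span_phrase(start: RelativePosition, end_chrom_index: int | None,
                 table: AssemblyTable, unmapped_tail: bool) -> str:
    """Phrase the chromosomes covered from ``start`` to the end chromosome."""
    start_i = table.chromosomes.index(start.chromosome)
    covered = table.chromosomes[start_i: (end_chrom_index + 1) if end_chrom_index is not None else len(table.chromosomes)]
    # split the trailing sex chromosomes (named by letter) from numbered ones
    letters = []
    while covered and (covered[-1][3:] if covered[-1].lower().startswith("chr") else covered[-1]).upper() in ("X", "Y"):
        letters.insert(0, covered[-1])
        covered = covered[:-1]
    if covered:
        head = chromosome_phrase(covered[0])
        tail = chromosome_phrase(covered[-1])
        if letters:
            letter_names = " and ".join(
                (c[3:] if c.lower().startswith("chr") else c).upper() for c in letters
            )
            suffix = "chromosomes" if len(letters) > 1 else "chromosome"
            phrase = f"from {head} to {tail} and the {letter_names} {suffix}"
        elif len(covered) == 1:
            phrase = f"on {head}"
        else:
            phrase = f"from {head} to {tail}"
    else:
        # range lies entirely on sex chromosomes
        names = [chromosome_phrase(c) for c in letters]
        phrase = f"from {names[0]} to {names[-1]}" if len(names) > 1 else f"on {names[0]}"
    if unmapped_tail:
        phrase += ", as well as an unmapped part of the genome at the end"
    return phrase


def describe_range(start_abs: int, end_abs: int, table: AssemblyTable) -> str:
    """Phrase the genomic range between two absolute positions.

    A range within one chromosome names it once with both relative
    positions; a multi-chromosome range names the first and last covered
    chromosomes; an end past the assembly total appends the unmapped-tail
    clause rather than naming an unknown chromosome.
    """
    if start_abs > end_abs:
        raise CoordinateError(f"start {start_abs} > end {end_abs}")
    start = abs_to_rel(start_abs, table)
    unmapped_tail = end_abs > table.total
    if not start.mapped:
        return "The genomic range is shown on an unmapped part of the genome."
    end = abs_to_rel(min(end_abs, table.total), table)
    if not unmapped_tail and start.chromosome == end.chromosome:
        return (
            f"The genomic range is shown on {chromosome_phrase(start.chromosome)}, "
            f"position {start.position} to position {end.position}."
        )
    end_i = table.chromosomes.index(end.chromosome)
    return f"The genomic range is shown {_span_phrase(start, end_i, table, unmapped_tail)}."
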