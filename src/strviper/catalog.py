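"""STR catalogs: parsing, validation and interval lookup.

A catalog is the set of short-tandem-repeat loci whose length variation is to
be estimated.  Catalogs typically come from Tandem Repeats Finder (``.dat``
output) or from a BED-like table; both are normalised into
:class:`STRLocus` records with 0-based half-open coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "STRLocus",
    "Catalog",
    "CatalogError",
    "parse_trf_dat",
    "parse_bed_catalog",
    "write_bed_catalog",
]


class CatalogError(ValueError):
    """Raised on malformed catalog input."""


@dataclass(frozen=True)
class STRLocus:
    """One catalogued tandem repeat.

    Coordinates are 0-based half-open on the reference.  ``unit_size`` is the
    repeat unit length u in bp (2-6 for classical STRs, any >= 1 accepted)
    and ``ref_copies`` the (possibly fractional) copy number in the
    reference, as reported by repeat finders.
    """

    chrom: str
    start: int
    end: int
    unit_size: int
    unit_seq: str
    ref_copies: float
    purity: Optional[float] = None
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise CatalogError(
                f"locus end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.unit_size < 1:
            raise CatalogError(f"unit_size must be >= 1, got {self.unit_size}")
        if len(self.unit_seq) != self.unit_size:
            raise CatalogError(
                f"unit_seq {self.unit_seq!r} length != unit_size {self.unit_size}"
            )
        if self.purity is not None and not (0.0 <= self.purity <= 1.0):
            raise CatalogError(f"purity must lie in [0,1], got {self.purity}")
        # TRF reports fractional copies; tract length and u must agree to ~1 unit.
        implied = (self.end - self.start) / self.unit_size
        if abs(implied - self.ref_copies) > 1.0 + 1e-9:
            raise CatalogError(
                f"ref_copies {self.ref_copies} inconsistent with span "
                f"{self.end - self.start} / u={self.unit_size} (implies {implied:.2f})"
            )
        if not self.locus_id:
            object.__setattr__(
                self, "locus_id", f"{self.chrom}:{self.start}-{self.end}:{self.unit_seq}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start


class Catalog:
    """An indexed collection of :class:`STRLocus` supporting point queries."""

    def __init__(self, loci: Iterable[STRLocus]):
        self.loci: list[STRLocus] = list(loci)
        seen: set[str] = set()
        for loc in self.loci:
            if loc.locus_id in seen:
                raise CatalogError(f"duplicate locus_id {loc.locus_id!r}")
            seen.add(loc.locus_id)
        self._trees: dict[str, IntervalTree] = {}
        self._warned_pairs: set[frozenset] = set()
        for loc in self.loci:
            self._trees.setdefault(loc.chrom, IntervalTree()).addi(
                loc.start, loc.end, loc
            )
        self._by_id = {loc.locus_id: loc for loc in self.loci}

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self) -> Iterator[STRLocus]:
        return iter(self.loci)

    def __getitem__(self, locus_id: str) -> STRLocus:
        return self._by_id[locus_id]

    def overlapping_locus(self, chrom: str, pos: int) -> Optional[STRLocus]:
        """The locus whose [start, end) contains ``pos``, or None.

        When several loci overlap the position, the one with the smallest
        start wins (a warning is logged once per overlapping pair).
        """
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        hits = sorted(tree.at(pos), key=lambda iv: (iv.begin, iv.data.locus_id))
        if not hits:
            return None
        if len(hits) > 1:
            key = frozenset(iv.data.locus_id for iv in hits[:2])
            if key not in self._warned_pairs:
                self._warned_pairs.add(key)
                logger.warning(
                    "overlapping catalog loci %s; attributing to the leftmost",
                    sorted(key),
                )
        return hits[0].data

    def overlapping_all(self, chrom: str, start: int, end: int) -> list[STRLocus]:
        """All loci intersecting [start, end), sorted by start."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.data for iv in tree.overlap(start, end)),
                      key=lambda l: (l.start, l.locus_id))


def parse_trf_dat(stream: IO[str]) -> list[STRLocus]:
    """Parse Tandem Repeats Finder ``.dat`` output into loci.

    TRF records are whitespace-delimited lines of >= 14 fields following a
    ``Sequence: <name>`` header.  TRF's 1-based inclusive coordinates are
    converted to 0-based half-open; the consensus column supplies the unit
    sequence and the percent-matches column the purity.
    """
    loci: list[STRLocus] = []
    chrom: Optional[str] = None
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("Sequence:"):
            chrom = line.split(None, 1)[1].split()[0]
            continue
        if line.startswith(("Parameters:", "Tandem Repeats Finder", "Gary Benson",
                            "Program written", "Version", "Boston University",
                            "Please cite")):
            continue
        fields = line.split()
        if len(fields) < 14 or not fields[0].isdigit():
            # other free-text banner lines are tolerated only before any record
            if chrom is None and not fields[0].isdigit():
                continue
            raise CatalogError(f"malformed TRF record at line {lineno}: {line!r}")
        if chrom is None:
            raise CatalogError(f"TRF record before any 'Sequence:' header (line {lineno})")
        try:
            start1 = int(fields[0])
            end1 = int(fields[1])
            period = int(fields[2])
            copies = float(fields[3])
            pct_match = float(fields[5])
            consensus = fields[13]
        except (ValueError, IndexError) as exc:
            raise CatalogError(f"malformed TRF record at line {lineno}: {exc}") from exc
        if period == 0:
            raise CatalogError(f"TRF record with unit size 0 at line {lineno}")
        loci.append(
            STRLocus(
                chrom=chrom,
                start=start1 - 1,
                end=end1,
                unit_size=period,
                unit_seq=consensus,
                ref_copies=copies,
                purity=pct_match / 100.0,
            )
        )
    return loci


#: BED dialect: chrom, start, end, unit_seq, unit_size
#: [, ref_copies [, purity [, locus_id]]]
_BED_HEADER = "#chrom\tstart\tend\tunit_seq\tunit_size\tref_copies\tpurity\tlocus_id"


def parse_bed_catalog(stream: IO[str]) -> list[STRLocus]:
    """Parse a BED3+2 (or +4) STR table; coordinates kept 0-based half-open."""
    loci: list[STRLocus] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise CatalogError(f"BED catalog line {lineno}: expected >= 5 columns")
        chrom, start_s, end_s, unit_seq, unit_size_s = fields[:5]
        try:
            start, end, unit_size = int(start_s), int(end_s), int(unit_size_s)
        except ValueError as exc:
            raise CatalogError(f"BED catalog line {lineno}: {exc}") from exc
        if len(unit_seq) != unit_size:
            raise CatalogError(
                f"BED catalog line {lineno}: unit_size {unit_size} != len({unit_seq!r})"
            )
        if end <= start:
            raise CatalogError(f"BED catalog line {lineno}: end <= start")
        ref_copies = float(fields[5]) if len(fields) > 5 and fields[5] != "." else (
            (end - start) / unit_size
        )
        purity = float(fields[6]) if len(fields) > 6 and fields[6] != "." else None
        locus_id = fields[7] if len(fields) > 7 and fields[7] != "." else ""
        loci.append(
            STRLocus(chrom, start, end, unit_size, unit_seq, ref_copies, purity,
                     locus_id)
        )
    return loci


def write_bed_catalog(loci: Iterable[STRLocus], stream: IO[str]) -> None:
    """Serialise loci in the BED3+ dialect read by :func:`parse_bed_catalog`."""
    stream.write(_BED_HEADER + "\n")
    for loc in loci:
        # repr round-trips floats exactly, so parse(write(x)) == x
        purity = repr(loc.purity) if loc.purity is not None else "."
        stream.write(
            f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.unit_seq}\t"
            f"{loc.unit_size}\t{loc.ref_copies!r}\t{purity}\t{loc.locus_id}\n"
        )
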