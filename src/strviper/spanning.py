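"""Collect fragments spanning each STR locus with both reads in the flanks.

A pair supports a locus when the repeat tract lies strictly between the two
aligned reads, so the observed fragment size responds linearly to repeat
length change while both reads remain reliably mappable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import pysam

from .catalog import Catalog

__all__ = ["SpanningSet", "CollectorConfig", "collect_spanning", "spanning_depth_report"]


@dataclass
class SpanningSet:
    """Observed fragment sizes x_1..x_n spanning one locus from one library."""

    locus_id: str
    library_id: str
    sizes: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.sizes)


@dataclass
class CollectorConfig:
    min_mapq: int = 10
    max_size: int = 2000
    # reads may end this many bp inside the repeat tract before being rejected
    allow_edge_overlap: int = 0


def _library_of(read: pysam.AlignedSegment) -> str:
    try:
        return read.get_tag("RG")
    except KeyError:
        return "default"


def pair_spans_locus(
    left_start: int,
    left_end: int,
    right_start: int,
    right_end: int,
    locus_start: int,
    locus_end: int,
    allow_edge_overlap: int = 0,
) -> bool:
    """Both-flank anchoring rule: reads may touch but not enter the repeat."""
    return (
        left_end <= locus_start + allow_edge_overlap
        and right_start >= locus_end - allow_edge_overlap
    )


def collect_spanning(
    alignments: Iterable[pysam.AlignedSegment],
    catalog: Catalog,
    config: Optional[CollectorConfig] = None,
) -> dict[tuple[str, str], SpanningSet]:
    """Map (locus_id, library_id) -> SpanningSet of observed fragment sizes.

    A pair contributes to locus L iff both primary mates map to L's reference
    sequence in forward-reverse orientation with mapping quality >=
    ``min_mapq``, the leftmost mate ends at or before L.start, the rightmost
    mate starts at or after L.end, and the outer span is <= ``max_size``.
    A pair spanning several nearby loci contributes to each of them.

    Mates are resolved by query name in a single pass, so any record order is
    accepted as long as both mates are present.
    """
    cfg = config or CollectorConfig()
    pending: dict[str, pysam.AlignedSegment] = {}
    sets: dict[tuple[str, str], SpanningSet] = {}

    def process(a: pysam.AlignedSegment, b: pysam.AlignedSegment) -> None:
        if a.reference_name != b.reference_name:
            return
        left, right = (a, b) if a.reference_start <= b.reference_start else (b, a)
        if left.is_reverse or not right.is_reverse:
            return
        if min(a.mapping_quality, b.mapping_quality) < cfg.min_mapq:
            return
        size = right.reference_end - left.reference_start
        if size <= 0 or size > cfg.max_size:
            return
        lib = _library_of(left)
        for locus in catalog.overlapping_all(
            left.reference_name, left.reference_start, right.reference_end
        ):
            if pair_spans_locus(
                left.reference_start, left.reference_end,
                right.reference_start, right.reference_end,
                locus.start, locus.end, cfg.allow_edge_overlap,
            ):
                key = (locus.locus_id, lib)
                if key not in sets:
                    sets[key] = SpanningSet(locus.locus_id, lib)
                sets[key].sizes.append(size)

    for read in alignments:
        if read.is_secondary or read.is_supplementary:
            continue
        if not read.is_paired:
            raise ValueError(f"unpaired record {read.query_name!r}; paired input required")
        if read.is_unmapped or read.mate_is_unmapped:
            continue
        mate = pending.pop(read.query_name, None)
        if mate is None:
            pending[read.query_name] = read
        else:
            process(mate, read)
    return sets


def spanning_depth_report(sets: dict[tuple[str, str], SpanningSet]) -> pd.DataFrame:
    """Per-(locus, library) depth summary, ordered by (locus_id, library_id)."""
    rows = []
    for (locus_id, library_id) in sorted(sets):
        s = sets[(locus_id, library_id)]
        arr = np.asarray(s.sizes)
        rows.append(
            {
                "locus_id": locus_id,
                "library_id": library_id,
                "n": s.n,
                "min": int(arr.min()) if s.n else np.nan,
                "median": float(np.median(arr)) if s.n else np.nan,
                "max": int(arr.max()) if s.n else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["locus_id", "library_id", "n", "min", "median", "max"]
    )
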