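"""Synthetic donor genomes and paired-end read/fragment simulation.

Reproduces the evaluation protocol at desk scale: a reference sequence is
mutated into a donor genome carrying SNPs, short non-repeat indels and STR
copy-number changes; paired-end fragments are then sampled from the donor
with a Gaussian size distribution.  Every edit is recorded so the donor is
exactly reconstructable from the reference plus the edit table, and the STR
changes form the truth table used for scoring.

Per-locus repeat change delta (units) is drawn from a zero-mean Gaussian
whose SD is ``str_scale * weight`` for that locus, discretised to integers;
scaling several donors by factors 1:2:3 therefore scales the mean |delta|
accordingly.  Weights default to 1 so relative variability can be supplied
by the caller (e.g. from an external variability score).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import Catalog, STRLocus
from .fragments import FragmentLibraryStats
from .spanning import SpanningSet

__all__ = [
    "DonorSpec",
    "TruthRecord",
    "synthetic_reference",
    "mutate_genome",
    "apply_edits",
    "simulate_fragments",
    "write_fastq_pair",
    "simulate_spanning_sizes",
    "expected_spanning_n",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_BASES = np.array(list("ACGT"))


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DonorSpec:
    """Mutation rates for one synthetic donor genome."""

    snp_rate: float = 0.06
    indel_rate: float = 0.01
    str_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("snp_rate", "indel_rate"):
            rate = getattr(self, name)
            if not (0.0 <= rate <= 0.5):
                raise ValueError(f"{name} must lie in [0, 0.5], got {rate}")
        if self.str_scale < 0:
            raise ValueError("str_scale must be non-negative")


@dataclass(frozen=True)
class TruthRecord:
    locus_id: str
    true_delta_units: int
    true_delta_bp: int


def synthetic_reference(
    n_loci: int,
    chrom_len: int,
    seed: int = 0,
    unit_sizes: Sequence[int] = (2, 3, 4),
    copies_range: tuple[int, int] = (8, 14),
    chrom: str = "chr1",
) -> tuple[dict[str, str], Catalog]:
    """Random reference with pure STR tracts implanted at regular spacing.

    Returns the sequence and its matching catalog; loci are well separated
    so spanning pairs are unambiguous.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(_BASES, size=chrom_len))
    spacing = chrom_len // (n_loci + 1)
    loci = []
    for i in range(n_loci):
        u = int(rng.choice(unit_sizes))
        copies = int(rng.integers(*copies_range))
        unit = "".join(rng.choice(_BASES, size=u))
        start = spacing * (i + 1)
        tract = unit * copies
        seq[start: start + len(tract)] = list(tract)
        loci.append(STRLocus(chrom, start, start + len(tract), u, unit,
                             float(copies), locus_id=f"S{i}"))
    return {chrom: "".join(seq)}, Catalog(loci)


def _draw_delta(rng: np.random.Generator, sd: float, max_del_units: int) -> int:
    """Zero-mean discretised Gaussian delta; deletions below zero copies resampled."""
    if sd <= 0:
        return 0
    for _ in range(100):
        delta = int(round(rng.normal(0.0, sd)))
        if delta >= -max_del_units:
            return delta
    return 0


def mutate_genome(
    reference: Mapping[str, str],
    catalog: Catalog,
    spec: DonorSpec,
    variability_weights: Optional[Mapping[str, float]] = None,
    forced_deltas: Optional[Mapping[str, int]] = None,
) -> tuple[dict[str, str], list[TruthRecord], pd.DataFrame]:
    """Implant SNPs, short indels and STR length changes into a reference.

    Returns ``(donor, truth, edits)`` where ``donor`` maps chrom -> mutated
    sequence, ``truth`` lists the nonzero STR changes, and ``edits`` is a
    table of every applied edit (chrom, ref_start, ref_allele, alt_allele,
    kind, donor_start) — the liftover map.  Applying ``edits`` back to the
    reference with :func:`apply_edits` reproduces the donor exactly.

    SNPs and non-repeat indels (1-10 bp, uniform) are placed per-base at the
    given Bernoulli rates outside repeat tracts; each repeat tract with a
    nonzero delta is rewritten as ``ref_copies + delta`` copies of its unit.
    ``forced_deltas`` pins specific loci to exact unit changes instead of
    drawing them (useful for controlled experiments).
    """
    rng = np.random.default_rng(spec.seed)
    weights = variability_weights or {}
    for loc in catalog:
        if loc.chrom not in reference:
            raise ValueError(f"catalog chrom {loc.chrom!r} absent from reference")

    truth: list[TruthRecord] = []
    edit_rows: list[dict] = []
    donor: dict[str, str] = {}

    for chrom in reference:
        seq = reference[chrom]
        n = len(seq)
        loci = sorted(
            (l for l in catalog if l.chrom == chrom), key=lambda l: l.start
        )
        in_repeat = np.zeros(n, dtype=bool)
        for loc in loci:
            in_repeat[loc.start: loc.end] = True

        # point edits first: SNPs, then indel sites, outside repeat tracts
        edits: list[tuple[int, int, str, str, str]] = []  # (start, ref_len, ref, alt, kind)
        if spec.snp_rate > 0:
            snp_pos = np.nonzero((rng.random(n) < spec.snp_rate) & ~in_repeat)[0]
            for pos in snp_pos:
                ref_base = seq[pos]
                if ref_base.upper() not in "ACGT":
                    continue
                alt = str(rng.choice(_BASES[_BASES != ref_base.upper()]))
                edits.append((int(pos), 1, ref_base, alt, "snp"))
        if spec.indel_rate > 0:
            indel_pos = np.nonzero((rng.random(n) < spec.indel_rate) & ~in_repeat)[0]
            for pos in indel_pos:
                length = int(rng.integers(1, 11))
                anchor = seq[pos]
                if rng.random() < 0.5:  # insertion after anchor
                    ins = "".join(rng.choice(_BASES, size=length))
                    edits.append((int(pos), 1, anchor, anchor + ins, "ins"))
                else:  # deletion of `length` bases after anchor
                    if pos + 1 + length > n or in_repeat[pos + 1: pos + 1 + length].any():
                        continue
                    edits.append(
                        (int(pos), 1 + length, seq[pos: pos + 1 + length], anchor, "del")
                    )

        # STR rewrites
        for loc in loci:
            sd = spec.str_scale * float(weights.get(loc.locus_id, 1.0))
            max_del = int((loc.end - loc.start) // loc.unit_size)
            if forced_deltas is not None and loc.locus_id in forced_deltas:
                delta = int(forced_deltas[loc.locus_id])
            else:
                delta = _draw_delta(rng, sd, max_del)
            if delta == 0:
                continue
            new_len = (loc.end - loc.start) + delta * loc.unit_size
            tile = loc.unit_seq * (new_len // loc.unit_size + 1)
            new_tract = tile[:new_len]
            edits.append(
                (loc.start, loc.end - loc.start, seq[loc.start: loc.end], new_tract, "str")
            )
            truth.append(TruthRecord(loc.locus_id, delta, delta * loc.unit_size))

        # apply left-to-right, dropping any edit overlapping an earlier one
        edits.sort(key=lambda e: (e[0], e[1]))
        pieces: list[str] = []
        cursor = 0
        donor_pos = 0
        for start, ref_len, ref_allele, alt_allele, kind in edits:
            if start < cursor:
                continue  # overlaps the previous edit; skip
            pieces.append(seq[cursor:start])
            donor_pos += start - cursor
            pieces.append(alt_allele)
            edit_rows.append(
                {
                    "chrom": chrom,
                    "ref_start": start,
                    "ref_allele": ref_allele,
                    "alt_allele": alt_allele,
                    "kind": kind,
                    "donor_start": donor_pos,
                }
            )
            donor_pos += len(alt_allele)
            cursor = start + ref_len
        pieces.append(seq[cursor:])
        donor[chrom] = "".join(pieces)

    edits_df = pd.DataFrame(
        edit_rows,
        columns=["chrom", "ref_start", "ref_allele", "alt_allele", "kind", "donor_start"],
    )
    return donor, truth, edits_df


def apply_edits(reference: Mapping[str, str], edits: pd.DataFrame) -> dict[str, str]:
    """Reconstruct a donor genome from the reference and an edit table."""
    donor: dict[str, str] = {}
    for chrom, seq in reference.items():
        sub = edits[edits["chrom"] == chrom].sort_values("ref_start")
        pieces: list[str] = []
        cursor = 0
        for row in sub.itertuples():
            start = int(row.ref_start)
            if seq[start: start + len(row.ref_allele)] != row.ref_allele:
                raise ValueError(
                    f"edit table does not match reference at {chrom}:{start}"
                )
            pieces.append(seq[cursor:start])
            pieces.append(row.alt_allele)
            cursor = start + len(row.ref_allele)
        pieces.append(seq[cursor:])
        donor[chrom] = "".join(pieces)
    return donor


def _sequence_read(rng: np.random.Generator, template: str,
                   error_sub: float, error_indel: float) -> str:
    """Apply per-base substitution and 1-bp indel errors to a read template."""
    if error_sub <= 0 and error_indel <= 0:
        return template
    out: list[str] = []
    for base in template:
        r = rng.random()
        if r < error_indel:
            if rng.random() < 0.5:
                out.append(base + str(rng.choice(_BASES)))  # insertion
            # else deletion: drop the base
        elif r < error_indel + error_sub and base.upper() in "ACGT":
            out.append(str(rng.choice(_BASES[_BASES != base.upper()])))
        else:
            out.append(base)
    return "".join(out)


def simulate_fragments(
    donor: Mapping[str, str],
    lib_mean: float = 200.0,
    lib_sd: float = 15.0,
    read_len: int = 50,
    coverage: float = 40.0,
    error_sub: float = 0.005,
    error_indel: float = 0.0005,
    seed: int = 0,
) -> Iterable[tuple[str, str, str]]:
    """Yield (name, read1, read2) paired-end reads from a donor genome.

    Fragment count is ``coverage * genome_len / (2 * read_len)``; starts are
    uniform, lengths Normal(lib_mean, lib_sd^2) rounded and truncated to
    [2*read_len, chrom length].  Mate 2 is the reverse complement of the
    fragment's 3' end.  Read names encode the fragment origin
    (``frag<i>:<chrom>:<start>:<len>``) for debugging.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if lib_sd <= 0:
        raise ValueError("lib_sd must be positive")
    if read_len > lib_mean:
        raise ValueError("read_len must not exceed lib_mean")
    rng = np.random.default_rng(seed)
    chroms = list(donor)
    lengths = np.array([len(donor[c]) for c in chroms], dtype=float)
    genome_len = lengths.sum()
    n_fragments = int(coverage * genome_len / (2 * read_len))
    probs = lengths / genome_len
    for i in range(n_fragments):
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        seq = donor[chrom]
        frag_len = int(round(rng.normal(lib_mean, lib_sd)))
        frag_len = max(2 * read_len, min(frag_len, len(seq)))
        start = int(rng.integers(0, len(seq) - frag_len + 1))
        fragment = seq[start: start + frag_len]
        r1 = _sequence_read(rng, fragment[:read_len], error_sub, error_indel)
        r2 = _sequence_read(rng, _revcomp(fragment[-read_len:]), error_sub, error_indel)
        yield f"frag{i}:{chrom}:{start}:{frag_len}", r1, r2


def write_fastq_pair(
    reads: Iterable[tuple[str, str, str]], out1: IO[str], out2: IO[str]
) -> int:
    """Write paired reads to two FASTQ streams (constant quality 'I')."""
    count = 0
    for name, r1, r2 in reads:
        out1.write(f"@{name}/1\n{r1}\n+\n{'I' * len(r1)}\n")
        out2.write(f"@{name}/2\n{r2}\n+\n{'I' * len(r2)}\n")
        count += 1
    return count


def expected_spanning_n(
    locus_len: int, lib: FragmentLibraryStats, read_len: int, coverage: float
) -> float:
    """Expected number of fragments spanning a locus with both reads anchored.

    With uniform fragment starts at density coverage/(2*read_len) per bp, a
    fragment of typical length mu spans the locus with both reads fully in
    the flanks when its start falls in a window of width
    ``mu - locus_len - 2*read_len`` (zero if negative).
    """
    window = lib.mu - locus_len - 2 * read_len
    return max(0.0, coverage / (2 * read_len) * window)


def simulate_spanning_sizes(
    truth: Sequence[TruthRecord],
    catalog: Catalog,
    lib: FragmentLibraryStats,
    n_per_locus: int | Mapping[str, int] = 40,
    seed: int = 0,
) -> dict[str, SpanningSet]:
    """Draw spanning fragment sizes directly from the observation model.

    Alignment-free shortcut: for each catalog locus, sizes are drawn from
    Normal(mu + u * delta_true, sigma^2) and rounded to integers, bypassing
    read generation and mapping entirely.  Loci absent from the truth table
    have delta_true = 0.
    """
    rng = np.random.default_rng(seed)
    delta_by_id = {t.locus_id: t.true_delta_units for t in truth}
    out: dict[str, SpanningSet] = {}
    for loc in catalog:
        n = (
            int(n_per_locus.get(loc.locus_id, 0))
            if isinstance(n_per_locus, Mapping)
            else int(n_per_locus)
        )
        delta = delta_by_id.get(loc.locus_id, 0)
        sizes = np.rint(
            rng.normal(lib.mu + loc.unit_size * delta, lib.sigma, size=n)
        ).astype(int)
        out[loc.locus_id] = SpanningSet(loc.locus_id, lib.library_id, sizes.tolist())
    return out
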