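"""Shared fixtures: toy catalogs, synthetic aligned pairs, the grid oracle."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from strviper.catalog import Catalog, STRLocus


@pytest.fixture
def toy_catalog() -> Catalog:
    """Three well-separated trinucleotide loci on one 10 kb contig."""
    return Catalog([
        STRLocus("chr1", 1000, 1030, 3, "GAA", 10.0),
        STRLocus("chr1", 4000, 4024, 2, "AT", 12.0),
        STRLocus("chr1", 7000, 7035, 5, "ACGTA", 7.0),
    ])


@pytest.fixture
def sam_header() -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": "chr1", "LN": 100_000}, {"SN": "chr2", "LN": 100_000}],
    })


def make_pair(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    left_start: int,
    right_start: int,
    read_len: int = 50,
    mapq: int = 60,
    rg: str | None = None,
    chrom2: str | None = None,
    orientation: str = "FR",
) -> tuple[pysam.AlignedSegment, pysam.AlignedSegment]:
    """Two mapped primary mates with simple read_len-M CIGARs."""
    tid = header.get_tid(chrom)
    tid2 = header.get_tid(chrom2) if chrom2 else tid
    a = pysam.AlignedSegment(header)
    b = pysam.AlignedSegment(header)
    for seg, start, t in ((a, left_start, tid), (b, right_start, tid2)):
        seg.query_name = name
        seg.query_sequence = "A" * read_len
        seg.query_qualities = pysam.qualitystring_to_array("I" * read_len)
        seg.cigartuples = [(0, read_len)]
        seg.reference_id = t
        seg.reference_start = start
        seg.mapping_quality = mapq
        seg.is_paired = True
        if rg is not None:
            seg.set_tag("RG", rg)
    a.is_read1, b.is_read2 = True, True
    a.is_reverse = orientation[0] == "R"
    b.is_reverse = orientation[1] == "R"
    a.mate_is_reverse, b.mate_is_reverse = b.is_reverse, a.is_reverse
    a.next_reference_id, b.next_reference_id = tid2, tid
    a.next_reference_start, b.next_reference_start = right_start, left_start
    tlen = (right_start + read_len) - left_start
    a.template_length, b.template_length = tlen, -tlen
    return a, b


from strviper.simulate import synthetic_reference as make_reference  # noqa: E402


def grid_posterior(
    prior_mean: float,
    prior_sd: float,
    sizes,
    mu: float,
    sigma: float,
    u: int,
    lo: float | None = None,
    hi: float | None = None,
    step: float = 1e-3,
) -> tuple[float, float]:
    """Numerical-integration oracle: moments of prior x likelihood on a grid.

    Independent of the closed form under test: evaluates
    N(delta; mu0, sd0^2) * prod_i N(x_i; mu + u*delta, sigma^2) on a dense
    grid of delta and returns (mean, variance) of the normalised density.
    Default bounds cover the prior and the per-observation likelihoods out
    to 10 SDs, so no mass is truncated.
    """
    if lo is None or hi is None:
        bounds = [prior_mean - 10 * prior_sd, prior_mean + 10 * prior_sd]
        for x in sizes:
            centre = (x - mu) / u
            bounds += [centre - 10 * sigma / u, centre + 10 * sigma / u]
        lo = min(bounds) if lo is None else lo
        hi = max(bounds) if hi is None else hi
    delta = np.arange(lo, hi + step / 2, step)
    logp = -0.5 * ((delta - prior_mean) / prior_sd) ** 2
    for x in sizes:
        logp += -0.5 * ((x - mu - u * delta) / sigma) ** 2
    logp -= logp.max()
    w = np.exp(logp)
    w /= w.sum()
    mean = float(np.sum(w * delta))
    var = float(np.sum(w * (delta - mean) ** 2))
    return mean, var
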