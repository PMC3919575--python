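"""Conjugate normal Bayesian estimation of repeat-length change.

Model
-----
Let delta be the change in repeat copy number (units) between donor and
reference at a locus with unit size u.  A fragment spanning the repeat has an
observed (reference-projected) size

    x_i ~ Normal(mu + u * delta, sigma^2)

where (mu, sigma) are the library fragment statistics.  With a Gaussian prior
delta ~ Normal(mu0, sigma0^2) the posterior is again Gaussian with

    1/sigma1^2 = 1/sigma0^2 + n u^2 / sigma^2
    mu1        = sigma1^2 * ( mu0/sigma0^2 + (u/sigma^2) * sum_i (x_i - mu) )

so mu1 is a precision-weighted convex combination of the prior mean and the
data estimate sum(x_i - mu)/(n u), and sigma1 shrinks monotonically with n.
The prior may come from external indel predictions (a VCF) or default to a
bland, effectively non-informative Gaussian.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pysam

from .catalog import Catalog, STRLocus
from .fragments import FragmentLibraryStats

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianBelief",
    "VariantCall",
    "PriorConfig",
    "CallConfig",
    "bland_prior",
    "posterior_update",
    "sequential_update",
    "prior_from_vcf",
    "make_call",
    "write_calls_vcf",
]


@dataclass(frozen=True)
class GaussianBelief:
    """A Gaussian belief over delta (repeat units): prior or posterior."""

    mean: float
    sd: float
    n_obs: int = 0
    source: str = "bland"  # provenance of the prior: "bland" | "vcf"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError(f"sd must be positive, got {self.sd}")
        if self.n_obs < 0:
            raise ValueError("n_obs must be >= 0")

    def interval(self, z: float = 1.96) -> tuple[float, float]:
        """Central credible interval at +/- z posterior SDs."""
        return (self.mean - z * self.sd, self.mean + z * self.sd)


@dataclass(frozen=True)
class VariantCall:
    """Per-locus decision derived from the posterior over delta."""

    locus_id: str
    delta_units: float
    delta_bp: float
    sd_units: float
    n_fragments: int
    is_variant: bool
    prior_source: str = "bland"  # "bland" | "vcf"


@dataclass
class PriorConfig:
    bland_sd_units: float = 1000.0
    prior_sd_units: float = 2.0   # SD attached to an external VCF prediction
    prior_pad: int = 5            # bp slack when matching VCF records to loci


@dataclass
class CallConfig:
    min_indel_bp: float = 9.0
    z: float = 1.96
    min_fragments: int = 3


def bland_prior(config: Optional[PriorConfig] = None) -> GaussianBelief:
    """Weakly informative default prior: Normal(0, bland_sd_units^2).

    With sd = 1000 units the prior precision is ~1e-6, so even a handful of
    fragments dominates the posterior.
    """
    cfg = config or PriorConfig()
    return GaussianBelief(0.0, cfg.bland_sd_units)


def posterior_update(
    prior: GaussianBelief,
    sizes: Sequence[float],
    lib: FragmentLibraryStats,
    u: int,
) -> GaussianBelief:
    """Exact conjugate posterior over delta given spanning fragment sizes.

    Empty ``sizes`` returns the prior unchanged (no data, no update).
    """
    if lib.sigma <= 0:
        raise ValueError("library sigma must be positive")
    if u < 1:
        raise ValueError("unit size must be >= 1")
    n = len(sizes)
    if n == 0:
        return prior
    arr = np.asarray(sizes, dtype=float)
    prec0 = 1.0 / prior.sd**2
    prec_data = n * u**2 / lib.sigma**2
    var1 = 1.0 / (prec0 + prec_data)
    mean1 = var1 * (prior.mean * prec0 + (u / lib.sigma**2) * float(np.sum(arr - lib.mu)))
    return GaussianBelief(mean1, float(np.sqrt(var1)), prior.n_obs + n, prior.source)


def sequential_update(
    prior: GaussianBelief,
    per_library_sets: Iterable[tuple[Sequence[float], FragmentLibraryStats]],
    u: int,
) -> GaussianBelief:
    """Fold the posterior update over several libraries.

    Each library carries its own (mu, sigma); conjugacy makes the result
    independent of library order.
    """
    belief = prior
    for sizes, lib in per_library_sets:
        belief = posterior_update(belief, sizes, lib, u)
    return belief


def prior_from_vcf(
    vcf_path: str,
    catalog: Catalog,
    config: Optional[PriorConfig] = None,
) -> dict[str, GaussianBelief]:
    """Priors per locus from external indel predictions in a VCF.

    An indel record (len(ALT) != len(REF)) whose position falls within a
    locus, or within ``prior_pad`` bp of it, yields a prior centred on the
    predicted length change in repeat units with SD ``prior_sd_units``.
    Loci without a matching record get the bland prior.  When several records
    hit one locus the largest |length change| wins.
    """
    cfg = config or PriorConfig()
    bland = bland_prior(cfg)
    priors: dict[str, GaussianBelief] = {loc.locus_id: bland for loc in catalog}
    best_change: dict[str, int] = {}
    with pysam.VariantFile(vcf_path) as vcf:
        for rec in vcf:
            if rec.alts is None:
                continue
            for alt in rec.alts:
                if alt is None or any(c not in "ACGTNacgtn" for c in alt):
                    continue
                change = len(alt) - len(rec.ref)
                if change == 0:
                    continue  # not an indel
                pos0 = rec.pos - 1  # VCF is 1-based
                for locus in catalog.overlapping_all(
                    rec.chrom, pos0 - cfg.prior_pad, pos0 + cfg.prior_pad + 1
                ):
                    prev = best_change.get(locus.locus_id)
                    if prev is not None and abs(change) <= abs(prev):
                        continue
                    if prev is not None:
                        logger.warning(
                            "multiple prior records for %s; keeping the larger "
                            "|length change|", locus.locus_id,
                        )
                    best_change[locus.locus_id] = change
                    mu0 = round(change / locus.unit_size, 2)
                    priors[locus.locus_id] = GaussianBelief(
                        mu0, cfg.prior_sd_units, source="vcf"
                    )
    return priors


def make_call(
    posterior: GaussianBelief,
    locus: STRLocus,
    config: Optional[CallConfig] = None,
    prior_source: str = "bland",
) -> VariantCall:
    """Turn a posterior into a variant decision.

    A locus is called variant when all three hold: the estimated change is at
    least ``min_indel_bp`` in absolute bp; the posterior excludes zero at the
    ``z`` level (|mu1| >= z * sigma1); and at least ``min_fragments``
    fragments informed the posterior.  The magnitude threshold alone would
    call fragment-size noise at tiny n.
    """
    cfg = config or CallConfig()
    delta_bp = locus.unit_size * posterior.mean
    is_variant = (
        abs(delta_bp) >= cfg.min_indel_bp
        and abs(posterior.mean) >= cfg.z * posterior.sd
        and posterior.n_obs >= cfg.min_fragments
    )
    return VariantCall(
        locus_id=locus.locus_id,
        delta_units=posterior.mean,
        delta_bp=delta_bp,
        sd_units=posterior.sd,
        n_fragments=posterior.n_obs,
        is_variant=is_variant,
        prior_source=prior_source,
    )


_VCF_HEADER_LINES = [
    ('INFO', 'DU', '1', 'Float', 'Estimated repeat change, units (posterior mean)'),
    ('INFO', 'DBP', '1', 'Float', 'Estimated repeat change, bp'),
    ('INFO', 'DUI', '1', 'Integer', 'Nearest-integer repeat change, units'),
    ('INFO', 'SDU', '1', 'Float', 'Posterior SD, units'),
    ('INFO', 'NF', '1', 'Integer', 'Number of spanning fragments'),
    ('INFO', 'PRIOR', '1', 'String', 'Prior source: bland or vcf'),
]


def write_calls_vcf(
    calls: Sequence[VariantCall],
    catalog: Catalog,
    path: str,
    reference_lengths: Optional[Mapping[str, int]] = None,
    variants_only: bool = False,
) -> None:
    """Write one VCF record per catalog locus with the posterior summaries.

    Non-variant loci carry FILTER ``NO_VARIANT`` unless ``variants_only``.
    """
    header = pysam.VariantHeader()
    chroms = []
    for loc in catalog:
        if loc.chrom not in chroms:
            chroms.append(loc.chrom)
    for chrom in chroms:
        length = (reference_lengths or {}).get(chrom)
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    header.filters.add("NO_VARIANT", None, None, "Posterior does not support a call")
    for kind, name, num, typ, desc in _VCF_HEADER_LINES:
        header.info.add(name, num, typ, desc)
    by_id = {c.locus_id: c for c in calls}
    with pysam.VariantFile(path, "w", header=header) as out:
        for loc in catalog:
            call = by_id.get(loc.locus_id)
            if call is None or (variants_only and not call.is_variant):
                continue
            rec = out.new_record(
                contig=loc.chrom,
                start=loc.start,
                stop=loc.end,
                alleles=("N", "<STR>"),
                id=loc.locus_id,
            )
            rec.info["DU"] = round(call.delta_units, 4)
            rec.info["DBP"] = round(call.delta_bp, 4)
            rec.info["DUI"] = int(round(call.delta_units))
            rec.info["SDU"] = round(call.sd_units, 4)
            rec.info["NF"] = call.n_fragments
            rec.info["PRIOR"] = call.prior_source
            if call.is_variant:
                rec.filter.add("PASS")
            else:
                rec.filter.add("NO_VARIANT")
            out.write(rec)
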