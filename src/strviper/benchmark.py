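"""Desk-scale benchmark experiments: recovery and coverage/SD trends.

These routines reproduce, on small synthetic genomes, the calibration
experiments behind the method: drawing repeat changes, simulating the
fragment-size evidence a sequencing run would yield at a given coverage and
library SD, estimating, and scoring.  They are used by the test suite and
the reproduction script, and are available to users who want to gauge the
coverage / fragment-SD operating range for their own library parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bayes import CallConfig, bland_prior, posterior_update
from .evaluate import EvalConfig, EvalResult, score_calls
from .fragments import FragmentLibraryStats
from .pipeline import estimate_calls
from .simulate import (
    DonorSpec,
    expected_spanning_n,
    mutate_genome,
    simulate_spanning_sizes,
    synthetic_reference,
)

__all__ = ["RecoveryResult", "parameter_recovery", "simulate_and_score"]

# mean |delta| of a zero-mean Gaussian is sd*sqrt(2/pi); this scale targets
# a mean repeat change of ~3 units (~9 bp at u=3)
SCALE_FOR_3_UNITS = 3.0 / float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class RecoveryResult:
    n_loci: int
    ci_coverage: float      # fraction of loci whose 95% CI covers true delta
    rmse_units: float       # RMSE of the posterior mean
    analytic_rmse: float    # sigma/sqrt(n) * sqrt(mean(1/u^2)) under a flat prior


def parameter_recovery(
    seed: int = 0,
    n_loci: int = 500,
    n_fragments: int = 40,
    sigma: float = 15.0,
    mu: float = 200.0,
    unit_sizes: Sequence[int] = (2, 3, 4),
    delta_range: tuple[int, int] = (-5, 5),
    z: float = 1.96,
) -> RecoveryResult:
    """Simulate loci with known deltas, estimate each with a bland prior.

    Per locus: u and delta are drawn uniformly, ``n_fragments`` spanning
    sizes are drawn from Normal(mu + u*delta, sigma^2), and the posterior is
    computed.  Reports how often the central 95% credible interval covers
    the true delta and the RMSE of the posterior mean against its analytic
    sampling value sigma/(u*sqrt(n)).
    """
    rng = np.random.default_rng(seed)
    covered = 0
    sq_err = []
    inv_u2 = []
    prior = bland_prior()
    for _ in range(n_loci):
        u = int(rng.choice(unit_sizes))
        delta = int(rng.integers(delta_range[0], delta_range[1] + 1))
        sizes = rng.normal(mu + u * delta, sigma, size=n_fragments)
        lib = FragmentLibraryStats("sim", mu, sigma)
        post = posterior_update(prior, sizes, lib, u)
        lo, hi = post.interval(z)
        covered += lo <= delta <= hi
        sq_err.append((post.mean - delta) ** 2)
        inv_u2.append(1.0 / u**2)
    analytic = sigma / np.sqrt(n_fragments) * float(np.sqrt(np.mean(inv_u2)))
    return RecoveryResult(
        n_loci=n_loci,
        ci_coverage=covered / n_loci,
        rmse_units=float(np.sqrt(np.mean(sq_err))),
        analytic_rmse=analytic,
    )


def simulate_and_score(
    seed: int = 0,
    lib_sd: float = 15.0,
    coverage: float = 40.0,
    n_loci: int = 100,
    chrom_len: int = 200_000,
    str_scale: float = SCALE_FOR_3_UNITS,
    lib_mean: float = 200.0,
    read_len: int = 50,
    unit_sizes: Sequence[int] = (3,),
    snp_rate: float = 0.06,
    indel_rate: float = 0.01,
    min_indel_bp: float = 9.0,
) -> EvalResult:
    """Full scaled-down pipeline: mutate, observe spanning sizes, call, score.

    The donor genome is mutated from a synthetic reference; the number of
    fragments spanning each locus is Poisson with the geometric expectation
    for the given coverage, and their sizes are drawn from the observation
    model — the alignment-free route, so no read mapping is involved.
    """
    ref, catalog = synthetic_reference(
        n_loci, chrom_len, seed=seed, unit_sizes=unit_sizes,
        copies_range=(10, 16),
    )
    spec = DonorSpec(snp_rate, indel_rate, str_scale, seed=seed + 1)
    _, truth, _ = mutate_genome(ref, catalog, spec)
    lib = FragmentLibraryStats("sim", lib_mean, lib_sd)
    rng = np.random.default_rng(seed + 2)
    n_per_locus = {
        loc.locus_id: int(rng.poisson(
            expected_spanning_n(loc.length_bp, lib, read_len, coverage)
        ))
        for loc in catalog
    }
    sets = simulate_spanning_sizes(truth, catalog, lib, n_per_locus, seed=seed + 3)
    spanning = {(lid, lib.library_id): s for lid, s in sets.items()}
    calls = estimate_calls(
        spanning, {lib.library_id: lib}, catalog,
        call_config=CallConfig(min_indel_bp=min_indel_bp),
    )
    return score_calls(calls, truth, catalog, EvalConfig(min_indel_bp=min_indel_bp))
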