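"""High-level glue: spanning sets -> posteriors -> per-locus calls."""

from __future__ import annotations

from typing import Mapping, Optional

from .bayes import (
    CallConfig,
    GaussianBelief,
    VariantCall,
    bland_prior,
    make_call,
    sequential_update,
)
from .catalog import Catalog
from .fragments import FragmentLibraryStats
from .spanning import SpanningSet

__all__ = ["estimate_calls"]


def estimate_calls(
    spanning: Mapping[tuple[str, str], SpanningSet],
    libraries: Mapping[str, FragmentLibraryStats],
    catalog: Catalog,
    priors: Optional[Mapping[str, GaussianBelief]] = None,
    call_config: Optional[CallConfig] = None,
) -> list[VariantCall]:
    """One VariantCall per catalog locus from per-library spanning sets.

    ``spanning`` is keyed by (locus_id, library_id) as produced by the
    collector; each locus folds its libraries' evidence into one posterior.
    Loci without an entry in ``priors`` use the bland prior.
    """
    priors = priors or {}
    default_prior = bland_prior()
    by_locus: dict[str, list[tuple[list[int], FragmentLibraryStats]]] = {}
    for (locus_id, library_id), sset in spanning.items():
        lib = libraries[library_id]
        by_locus.setdefault(locus_id, []).append((sset.sizes, lib))
    calls = []
    for loc in catalog:
        prior = priors.get(loc.locus_id, default_prior)
        posterior = sequential_update(prior, by_locus.get(loc.locus_id, []), loc.unit_size)
        calls.append(make_call(posterior, loc, call_config, prior_source=prior.source))
    return calls
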