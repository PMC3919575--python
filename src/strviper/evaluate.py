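"""Scoring against truth, and cross-strain repeat variability analysis.

Call accuracy is summarised by RMSE (in repeat units) plus the confusion
metrics sensitivity, positive predictive value and their harmonic mean
(F-score).  Across a panel of strains, each locus's variability is the
unbiased standard deviation of its repeat lengths (reference included);
variability is then related to locus properties by Pearson correlation and
to genomic-region membership by the Mann-Whitney rank-sum test, reported as
a signed z so the sign encodes the direction of the shift.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .bayes import VariantCall
from .catalog import Catalog
from .simulate import TruthRecord

__all__ = [
    "EvalResult",
    "EvalConfig",
    "VariabilityRecord",
    "score_calls",
    "variability",
    "correlate_property",
    "region_test",
]


@dataclass(frozen=True)
class EvalResult:
    rmse_units: float
    sensitivity: float
    ppv: float
    f_score: float
    tp: int
    fp: int
    fn: int
    tn: int


@dataclass
class EvalConfig:
    # |true delta| (bp) at or above which a locus counts as a true variant;
    # mirrors the calling threshold
    min_indel_bp: float = 9.0


@dataclass(frozen=True)
class VariabilityRecord:
    locus_id: str
    lengths_bp: tuple
    variability: float


def score_calls(
    calls: Sequence[VariantCall],
    truth: Sequence[TruthRecord],
    catalog: Catalog,
    config: Optional[EvalConfig] = None,
) -> EvalResult:
    """Confusion metrics and RMSE of calls against a simulation truth table.

    A locus is a truth-variant iff |true_delta_bp| >= ``min_indel_bp``.  A
    true positive requires a variant call at a truth-variant locus with the
    matching sign; a called variant at a non-variant locus, or with the wrong
    sign, is a false positive.  RMSE is computed in units over every locus
    with both a call and a (possibly zero) truth value.
    """
    cfg = config or EvalConfig()
    call_ids = {c.locus_id for c in calls}
    catalog_ids = {loc.locus_id for loc in catalog}
    extra = call_ids - catalog_ids
    if extra:
        raise ValueError(f"calls reference loci outside the catalog: {sorted(extra)[:5]}")
    extra_truth = {t.locus_id for t in truth} - catalog_ids
    if extra_truth:
        raise ValueError(
            f"truth references loci outside the catalog: {sorted(extra_truth)[:5]}"
        )

    truth_by_id = {t.locus_id: t for t in truth}
    calls_by_id = {c.locus_id: c for c in calls}
    tp = fp = fn = tn = 0
    sq_errors: list[float] = []
    for loc in catalog:
        t = truth_by_id.get(loc.locus_id)
        true_units = t.true_delta_units if t else 0
        true_bp = t.true_delta_bp if t else 0
        c = calls_by_id.get(loc.locus_id)
        if c is not None:
            sq_errors.append((c.delta_units - true_units) ** 2)
        is_truth_variant = abs(true_bp) >= cfg.min_indel_bp
        called = c is not None and c.is_variant
        sign_ok = called and is_truth_variant and (c.delta_units * true_units > 0)
        if sign_ok:
            tp += 1
        elif called:
            fp += 1
            if is_truth_variant:  # wrong sign also misses the real variant
                fn += 1
        elif is_truth_variant:
            fn += 1
        else:
            tn += 1

    sensitivity = tp / (tp + fn) if (tp + fn) else 0.0
    ppv = tp / (tp + fp) if (tp + fp) else 0.0
    f_score = (
        2 * sensitivity * ppv / (sensitivity + ppv) if (sensitivity + ppv) > 0 else 0.0
    )
    rmse = math.sqrt(float(np.mean(sq_errors))) if sq_errors else float("nan")
    return EvalResult(rmse, sensitivity, ppv, f_score, tp, fp, fn, tn)


def variability(
    per_strain_calls: Mapping[str, Sequence[VariantCall]],
    catalog: Catalog,
) -> list[VariabilityRecord]:
    """Unbiased SD of per-locus repeat lengths across strains plus reference.

    For each locus the length sample is the reference tract length followed
    by the reference length plus each strain's estimated bp change (strains
    without a call at the locus contribute the reference length, delta = 0).
    """
    strains = sorted(per_strain_calls)
    if not strains:
        raise ValueError("at least one strain is required")
    by_strain = {
        s: {c.locus_id: c for c in per_strain_calls[s]} for s in strains
    }
    records: list[VariabilityRecord] = []
    for loc in catalog:
        ref_len = float(loc.end - loc.start)
        lengths = [ref_len]
        for s in strains:
            call = by_strain[s].get(loc.locus_id)
            delta_bp = call.delta_bp if call is not None else 0.0
            lengths.append(ref_len + delta_bp)
        if len(lengths) < 2:
            raise ValueError(f"fewer than 2 lengths at {loc.locus_id}")
        sd = float(np.std(lengths, ddof=1))
        records.append(VariabilityRecord(loc.locus_id, tuple(lengths), sd))
    return records


def correlate_property(
    records: Sequence[VariabilityRecord],
    prop: Mapping[str, float],
) -> tuple[float, float, int]:
    """Pearson correlation between variability and a per-locus property.

    Returns (r, two-sided p, n_pairs_used); loci missing from ``prop`` are
    dropped and reflected in the pair count.
    """
    xs, ys = [], []
    for rec in records:
        value = prop.get(rec.locus_id)
        if value is None:
            continue
        xs.append(rec.variability)
        ys.append(float(value))
    if len(xs) < 3:
        raise ValueError("need at least 3 paired observations")
    x = np.asarray(xs)
    y = np.asarray(ys)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one vector; correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), len(xs)


def region_test(
    records: Sequence[VariabilityRecord],
    region_membership: Mapping[str, bool],
) -> tuple[float, float]:
    """Rank-sum comparison of in-region vs out-of-region variability.

    Returns (z, two-sided p) where z is the tie-corrected standardised
    Mann-Whitney statistic, signed so that z > 0 means in-region loci are
    more variable than the rest.
    """
    inside = [r.variability for r in records if region_membership.get(r.locus_id, False)]
    outside = [r.variability for r in records if not region_membership.get(r.locus_id, False)]
    if not inside or not outside:
        raise ValueError("both groups must be non-empty")
    n1, n2 = len(inside), len(outside)
    res = stats.mannwhitneyu(inside, outside, alternative="two-sided",
                             method="asymptotic", use_continuity=False)
    u = float(res.statistic)  # U for the first (in-region) sample
    mean_u = n1 * n2 / 2.0
    # tie-corrected variance of U
    combined = np.concatenate([inside, outside])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        raise ValueError("degenerate samples: all values tied")
    z = (u - mean_u) / math.sqrt(var_u)
    return z, float(res.pvalue)
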