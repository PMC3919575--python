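# Methods

## Observation model and inference

Each sequencing library is modelled by a Gaussian fragment-size distribution
with mean μ and SD σ (bp). For a catalogued repeat with unit size *u* and
unknown copy-number change Δ (units, donor minus reference), a read pair
whose two mates map entirely to the repeat's flanks has an observed
reference-projected outer span

  x ~ Normal(μ + uΔ, σ²),

because the repeat indel between the reads stretches or shrinks the mapped
span while the true fragment length is unchanged. The model assumes one Δ
per locus (appropriate for inbred/haploid material; heterozygous loci would
produce a two-component mixture this model averages over), Gaussian fragment
sizes, and correctly anchored flank alignments.

Inference is exact conjugate updating. With prior Δ ~ Normal(μ₀, σ₀²) and
observations x₁…xₙ:

  1/σ₁² = 1/σ₀² + n·u²/σ²
  μ₁    = σ₁²·( μ₀/σ₀² + (u/σ²)·Σ(xᵢ−μ) )

μ₁ is a precision-weighted convex combination of μ₀ and the moment estimate
Σ(xᵢ−μ)/(n·u); σ₁ decreases monotonically in n and increases with σ. The
closed form is validated in the test suite against an independent numerical
integration of prior × likelihood on a dense Δ grid (≤10⁻⁶ relative error
over randomized instances, including n = 0).

Multiple libraries (e.g. a 200 bp and a 400 bp insert library of the same
sample) are folded sequentially, each with its own (μ, σ); conjugacy makes
the result order-invariant, and equal to the batch update when σ is shared.

## Priors

* Bland default: Normal(0, 1000² units). 1000 units gives a prior precision
  of 10⁻⁶, so its pull on the posterior is below 10⁻⁴ relative at any
  realistic depth (asserted by test). Configurable
  (`PriorConfig.bland_sd_units`).
* VCF-informed: an indel record within (or within `prior_pad` = 5 bp of) a
  locus sets μ₀ = (len(ALT) − len(REF))/u, rounded to 0.01 units, with
  σ₀ = 2 units by default. External predictors rarely publish calibrated
  uncertainties, so σ₀ is a user knob, not an estimate. When several records
  hit one locus the largest |length change| wins (a warning is logged).

## Calling rule

A locus is reported as variant when all of:

1. |u·μ₁| ≥ `min_indel_bp` (default 9 bp — a magnitude large enough to
   resolve on a gel and to clear single-unit slippage noise for the common
   2–3 bp units);
2. |μ₁| ≥ z·σ₁ with z = 1.96 (the posterior excludes zero at the 95% level);
3. n ≥ `min_fragments` (default 3).

The magnitude threshold alone would call fragment-size noise at n = 1;
clauses 2–3 are this package's guard rails and are configurable. Δ is
reported as a real number (`DU`), with the nearest integer unit change
(`DUI`) alongside in the output VCF.

## Library statistics

If (μ, σ) are not supplied they are estimated from all concordant pairs:
both mates mapped to the same reference in forward–reverse orientation,
MAPQ ≥ 10, observed size ≤ 2000 bp. Robust trimming (median ± 10 MADs,
disable with `trim_mads=None`) guards against chimeric pairs; on clean
Gaussian input it removes essentially nothing (property-tested). Pairs
spanning a catalog locus are excluded when a catalog is supplied so repeat
variation does not inflate σ. Estimation requires ≥1000 usable pairs by
default (relaxable), otherwise the caller must pass μ, σ explicitly.

## Spanning-pair collection

A pair supports locus L iff the leftmost mate's aligned end is ≤ L.start and
the rightmost mate's aligned start is ≥ L.end (reads may touch but not enter
the repeat), same reference, FR orientation, MAPQ ≥ 10, size ≤ cap. Strict
anchoring is the conservative reading of "reads not fully within the
repeat": alignments ending inside a repeat edge are slippage-prone.
`allow_edge_overlap=N` relaxes the rule by N bp for users who want the
permissive behaviour. Pairs spanning several nearby loci count once per
locus: the per-locus model treats loci independently, so shared evidence is
not double-counted within any single posterior. Secondary and supplementary
alignments are ignored.

## Simulator

`mutate_genome` implants three kinds of edits outside/at catalog loci:

* SNPs: per-base Bernoulli(snp_rate) outside repeat tracts, random
  different base;
* non-repeat indels: per-base Bernoulli(indel_rate); length uniform on
  1–10 bp ("short indels"), insertion or deletion with equal probability;
* STR changes: Δ per locus drawn from a zero-mean Gaussian with
  SD = `str_scale` × per-locus weight, discretised to integers; draws that
  would delete below zero copies are resampled. A discretised Gaussian is
  the simplest symmetric choice whose scale maps linearly onto graded
  divergence designs such as 1:2:3 scaling (mean |Δ| = SD·√(2/π)).
  Per-locus variability weights default to 1 and can be supplied externally.

Every applied edit is recorded with its reference and donor coordinates and
both alleles, so `apply_edits(reference, edits)` reconstructs the donor
byte-for-byte — the round-trip is asserted in the tests at nonzero SNP and
indel rates. Default rates (snp 0.06, indel 0.01) correspond to a moderately
diverged plant accession.

`simulate_fragments` draws `coverage × genome_len / (2·read_len)` fragments
with uniform starts and Normal(lib_mean, lib_sd²) lengths (truncated to
[2·read_len, chrom length]), sequences `read_len` bases from each end
(mate 2 reverse-complemented) with per-base substitution (0.005) and 1-bp
indel (0.0005) error rates, and emits FASTQ with constant qualities — the
method never reads base qualities. Defaults: read length 50, μ = 200,
σ ∈ {10, 15, 20, 25} typical, coverage 40×.

`simulate_spanning_sizes` is the alignment-free shortcut: it samples
observed sizes directly from Normal(μ + uΔ_true, σ²). This isolates the
inference from mapping artefacts; pipeline experiments that use it test the
statistical machinery, not an aligner. The expected spanning depth per locus
follows from uniform fragment starts: a fragment of typical length μ spans a
locus of length ℓ with both reads anchored when its start falls in a window
of μ − ℓ − 2·read_len bp, giving E[n] = coverage/(2·read_len) × that window
(Poisson-drawn per locus in the benchmark).

What the simulator does **not** emulate: PCR slippage ("stutter") in reads,
GC bias, platform-specific error profiles, diploid heterozygosity, and
mapping ambiguity in repetitive flanks. Passing the synthetic benchmarks
therefore demonstrates correctness of the statistical method under its own
model, not robustness to those real-data artefacts.

## Evaluation

`score_calls` uses a truth threshold mirroring the calling magnitude
(|true Δ·u| ≥ 9 bp by default): TP requires a variant call with the correct
sign; a wrong-sign call counts as FP *and* FN (a called insertion where the
truth is a deletion detects nothing). RMSE is computed in units over all
loci with calls, zero-truth loci included. F is the harmonic mean of
sensitivity and PPV, defined as 0 when both are 0.

`variability` follows the cross-strain protocol: per locus, the sample is
the reference tract length plus (reference + estimated Δbp) for each strain
(strains without a call contribute Δ = 0), summarised by the unbiased
(n−1) SD. Associations use `scipy.stats.pearsonr` and a tie-corrected
signed Mann–Whitney z (positive ⇒ in-region loci more variable); the z/p
are cross-checked against a 10⁴-draw permutation oracle in the tests. Both
the signed z and the p-value are returned because signed standardised values
are what small-magnitude published region statistics correspond to.

## Benchmark problem sizes

The bundled experiments run on a 200 kb single-chromosome synthetic
reference with 100 trinucleotide loci (benchmark default), 500 loci for the
credible-interval calibration, and 2000 pairs for the collector geometry
check — sizes chosen so the whole suite and the reproduction script each
complete in well under a minute while keeping binomial/Monte-Carlo error
comfortably inside the asserted bands. `str_scale` defaults to 3.76 in the
benchmark, targeting a mean repeat change of ~3 units (~9 bp at u = 3).

## Numerical notes and edge cases

* Empty observation sets return the prior unchanged; n = 0 is a valid state.
* All randomness flows through `numpy.random.default_rng(seed)`; every
  simulator entry point is byte-reproducible under a fixed seed.
* Coordinates are 0-based half-open internally; TRF (1-based inclusive) and
  VCF (1-based) are converted at the parsing boundary.
* Overlapping catalog loci are allowed; point lookup resolves to the
  smallest start (warned once per pair), and spanning pairs are attributed
  to every locus they span.
* Catalog round-trips are exact: the BED writer emits `repr` floats.
* Degenerate statistics raise instead of returning NaN: zero-variance
  Pearson inputs, empty Mann–Whitney groups, fewer than 2 lengths for a
  variability sample.

## Known limitations

* No diploid genotyping: one Δ per locus.
* Only length variation is modelled; unit-sequence changes and interrupted
  repeats are out of scope (purity is carried through from the catalog but
  not used by the model).
* Fragment sizes are assumed Gaussian; heavy-tailed libraries should be
  trimmed (default) or characterised externally.
* The caller does not realign or use split reads; loci whose flanks are
  themselves repetitive will lose spanning pairs to mapping-quality filters
  upstream.
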