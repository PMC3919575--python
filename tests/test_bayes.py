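"""Conjugate posterior correctness, priors from VCF, and the calling rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from strviper.bayes import (
    CallConfig,
    GaussianBelief,
    PriorConfig,
    bland_prior,
    make_call,
    posterior_update,
    prior_from_vcf,
    sequential_update,
)
from strviper.catalog import Catalog, STRLocus
from strviper.fragments import FragmentLibraryStats

from conftest import grid_posterior

LIB = FragmentLibraryStats("lib", 200.0, 15.0)


class TestPosteriorUpdate:
    def test_no_data_returns_prior(self):
        prior = GaussianBelief(1.5, 2.0)
        assert posterior_update(prior, [], LIB, 3) == prior

    def test_three_fragment_worked_example(self):
        # mu=200, sigma=15, u=3, prior (0, 10), sizes [209, 212, 206]:
        # precision 1/100 + 3*9/225 = 0.13 -> var 7.692; mean 7.692*0.36 = 2.769
        post = posterior_update(GaussianBelief(0.0, 10.0), [209, 212, 206], LIB, 3)
        assert post.mean == pytest.approx(2.769, abs=1e-3)
        assert post.sd**2 == pytest.approx(7.692, abs=1e-3)
        assert post.n_obs == 3

    def test_agrees_with_grid_integration_oracle(self):
        sizes = [209.0, 212.0, 206.0]
        post = posterior_update(GaussianBelief(0.0, 10.0), sizes, LIB, 3)
        gmean, gvar = grid_posterior(0.0, 10.0, sizes, 200.0, 15.0, 3)
        assert post.mean == pytest.approx(gmean, rel=1e-6, abs=1e-6)
        assert post.sd**2 == pytest.approx(gvar, rel=1e-6, abs=1e-6)

    def test_bland_prior_reaches_maximum_likelihood_limit(self):
        rng = np.random.default_rng(2)
        sizes = rng.normal(209, 15, size=25)
        post = posterior_update(GaussianBelief(0.0, 1e6), sizes, LIB, 3)
        ml = np.sum(sizes - 200.0) / (len(sizes) * 3)
        assert post.mean == pytest.approx(ml, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            posterior_update(GaussianBelief(0.0, 10.0), [200],
                             FragmentLibraryStats("l", 200.0, 1.0), 0)
        with pytest.raises(ValueError):
            GaussianBelief(0.0, -1.0)

    @given(
        mu=st.floats(150, 450),
        sigma=st.floats(7, 25),
        u=st.integers(2, 6),
        prior_mean=st.floats(-5, 5),
        prior_sd=st.floats(0.5, 20),
        n=st.integers(0, 40),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_randomised_agreement_with_grid_oracle(
        self, mu, sigma, u, prior_mean, prior_sd, n, seed
    ):
        rng = np.random.default_rng(seed)
        delta = rng.uniform(-5, 5)
        sizes = rng.normal(mu + u * delta, sigma, size=n)
        lib = FragmentLibraryStats("l", mu, sigma)
        post = posterior_update(GaussianBelief(prior_mean, prior_sd), sizes, lib, u)
        gmean, gvar = grid_posterior(prior_mean, prior_sd, sizes, mu, sigma, u)
        assert post.mean == pytest.approx(gmean, rel=1e-6, abs=1e-6)
        assert post.sd**2 == pytest.approx(gvar, rel=1e-6, abs=1e-6)


class TestConjugacyIdentities:
    def test_single_library_equals_direct_update(self):
        prior = bland_prior()
        sizes = [210, 195, 204]
        assert sequential_update(prior, [(sizes, LIB)], 3) == \
            posterior_update(prior, sizes, LIB, 3)

    def test_library_order_invariance(self):
        lib2 = FragmentLibraryStats("lib2", 400.0, 20.0)
        prior = GaussianBelief(1.0, 3.0)
        s1, s2 = [210.0, 196.0], [420.0, 411.0, 395.0]
        a = sequential_update(prior, [(s1, LIB), (s2, lib2)], 3)
        b = sequential_update(prior, [(s2, lib2), (s1, LIB)], 3)
        assert a.mean == pytest.approx(b.mean, abs=1e-9)
        assert a.sd == pytest.approx(b.sd, abs=1e-9)

    def test_batch_equals_sequential_for_same_sigma(self):
        prior = GaussianBelief(0.5, 4.0)
        s1, s2 = [203.0, 215.0], [198.0, 207.0, 210.0]
        seq = sequential_update(prior, [(s1, LIB), (s2, LIB)], 3)
        batch = posterior_update(prior, s1 + s2, LIB, 3)
        assert seq.mean == pytest.approx(batch.mean, abs=1e-9)
        assert seq.sd == pytest.approx(batch.sd, abs=1e-9)

    @given(
        n=st.integers(1, 60),
        prior_sd=st.floats(0.5, 50),
        u=st.integers(2, 6),
        seed=st.integers(0, 1000),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_posterior_sd_shrinks_and_mean_is_convex(self, n, prior_sd, u, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.normal(206, 15, size=n)
        prior = GaussianBelief(rng.uniform(-3, 3), prior_sd)
        post = posterior_update(prior, sizes, LIB, u)
        assert post.sd < prior.sd
        assert post.sd**2 <= LIB.sigma**2 / (n * u**2) + 1e-12
        data_mean = np.sum(sizes - LIB.mu) / (n * u)
        lo, hi = sorted((prior.mean, data_mean))
        assert lo - 1e-9 <= post.mean <= hi + 1e-9
        # and strictly tighter with one more observation
        post2 = posterior_update(prior, np.append(sizes, 206.0), LIB, u)
        assert post2.sd < post.sd

    def test_affine_equivariance(self):
        # shifting every size by +u*k moves the mean by k * data weight
        prior = GaussianBelief(0.0, 5.0)
        sizes = np.array([201.0, 214.0, 189.0, 207.0])
        u, k = 3, 2.5
        base = posterior_update(prior, sizes, LIB, u)
        shifted = posterior_update(prior, sizes + u * k, LIB, u)
        n = len(sizes)
        weight = (n * u**2 / LIB.sigma**2) * base.sd**2
        assert shifted.mean == pytest.approx(base.mean + k * weight, abs=1e-9)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-12)


@pytest.fixture
def ten_locus_catalog():
    return Catalog([
        STRLocus("chr1", 1000 * (i + 1), 1000 * (i + 1) + 30, 3, "GAA", 10.0,
                 locus_id=f"L{i}")
        for i in range(10)
    ])


def _write_vcf(path, records):
    lines = [
        "##fileformat=VCFv4.2",
        "##contig=<ID=chr1,length=100000>",
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for chrom, pos1, ref, alt in records:
        lines.append(f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\t.\t.")
    path.write_text("\n".join(lines) + "\n")


class TestPriorFromVcf:
    def test_indel_record_sets_prior_mean_in_units(self, tmp_path, ten_locus_catalog):
        vcf = tmp_path / "p.vcf"
        _write_vcf(vcf, [("chr1", 1005, "A", "AGAAGAA")])  # +6 bp at u=3 locus
        priors = prior_from_vcf(str(vcf), ten_locus_catalog)
        assert priors["L0"].mean == pytest.approx(2.0)
        assert priors["L0"].sd == pytest.approx(2.0)
        assert priors["L0"].source == "vcf"

    def test_empty_vcf_gives_all_bland(self, tmp_path, ten_locus_catalog):
        vcf = tmp_path / "empty.vcf"
        _write_vcf(vcf, [])
        priors = prior_from_vcf(str(vcf), ten_locus_catalog)
        assert len(priors) == 10
        assert all(p == bland_prior() for p in priors.values())

    def test_five_records_over_ten_loci(self, tmp_path, ten_locus_catalog):
        vcf = tmp_path / "five.vcf"
        _write_vcf(vcf, [
            ("chr1", 1000 * (i + 1) + 5, "A", "A" + "GAA" * (i + 1))
            for i in range(5)
        ])
        priors = prior_from_vcf(str(vcf), ten_locus_catalog)
        informed = [lid for lid, p in priors.items() if p.source == "vcf"]
        assert sorted(informed) == [f"L{i}" for i in range(5)]
        assert priors["L3"].mean == pytest.approx(4.0)

    def test_snv_records_skipped_and_largest_indel_wins(
        self, tmp_path, ten_locus_catalog
    ):
        vcf = tmp_path / "mix.vcf"
        _write_vcf(vcf, [
            ("chr1", 1003, "A", "C"),            # SNV: ignored
            ("chr1", 1004, "A", "AGAA"),          # +1 unit
            ("chr1", 1010, "AGAAGAA", "A"),       # -2 units: larger, wins
        ])
        priors = prior_from_vcf(str(vcf), ten_locus_catalog)
        assert priors["L0"].mean == pytest.approx(-2.0)


class TestCallingRule:
    LOCUS = STRLocus("chr1", 1000, 1030, 3, "GAA", 10.0, locus_id="L")

    def test_zero_estimate_is_never_variant(self):
        post = GaussianBelief(0.0, 0.1, n_obs=100)
        assert not make_call(post, self.LOCUS).is_variant

    def test_clear_variant_passes_all_clauses(self):
        post = GaussianBelief(3.5, 0.5, n_obs=40)
        call = make_call(post, self.LOCUS)
        assert call.is_variant
        assert call.delta_bp == pytest.approx(10.5)
        assert call.delta_bp == pytest.approx(self.LOCUS.unit_size * call.delta_units)

    def test_rule_matches_independent_re_evaluation_over_grid(self):
        cfg = CallConfig()
        for mu1 in np.linspace(-6, 6, 61):
            for sd1 in (0.2, 1.0, 3.0):
                for n in (1, 3, 40):
                    call = make_call(GaussianBelief(mu1, sd1, n), self.LOCUS, cfg)
                    expected = (
                        abs(3 * mu1) >= 9.0
                        and abs(mu1) >= 1.96 * sd1
                        and n >= 3
                    )
                    assert call.is_variant == expected

    def test_bland_prior_recovery_within_two_posterior_sds(self):
        rng = np.random.default_rng(42)
        sizes = rng.normal(200 + 3 * 3, 15, size=40)
        post = posterior_update(bland_prior(), sizes, LIB, 3)
        assert abs(post.mean - 3.0) <= 2 * post.sd

    def test_bland_prior_shift_is_negligible_at_n_ten(self):
        rng = np.random.default_rng(7)
        sizes = rng.normal(209, 15, size=10)
        post = posterior_update(bland_prior(), sizes, LIB, 3)
        ml = np.sum(sizes - 200.0) / (10 * 3)
        assert abs(post.mean - ml) / abs(ml) < 1e-4
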