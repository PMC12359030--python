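"""Read simulation, ML genotype calling and error-rate analytics."""

from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from readcoal import (
    analytic_error_rate,
    analytic_error_rate_exact,
    call_genotype_ml,
    corrupt_alignment,
    ml_decision_table,
    read_count_sampler,
    simulate_reads,
)
from readcoal.genotype import (
    AliasTable,
    HETEROZYGOTE,
    HOMOZYGOTE,
    classify_call,
    ml_call_exact,
)
from readcoal.seqevolve import DiploidAlignment


class TestMLDecision:
    def test_all_reference_reads_call_homozygote(self):
        # L(00) = 0.99^5 ~ 0.951 beats L(01) = 2^-5 and L(11) = 0.01^5
        assert ml_decision_table(5, 0.01)[0] == 0

    def test_single_alternative_read_calls_heterozygote(self):
        # L(00|k=1) ~ 0.0096 < L(01) = 0.03125: one error read flips the call
        assert ml_decision_table(5, 0.01)[1] == 1

    def test_zero_error_rate_is_deterministic(self):
        table = ml_decision_table(3, 0.0)
        assert list(table) == [0, 1, 1, 2]

    def test_tie_breaks_toward_majority_homozygote(self):
        # eps = 0.5 makes all three likelihoods equal for every k
        table = ml_decision_table(4, 0.5)
        assert table[0] == 0 and table[4] == 2
        assert table[2] == 0  # exact tie k == n - k goes to allele 0

    def test_agrees_with_exact_arithmetic_on_spot_checks(self):
        for es in ("0.001", "0.05"):
            eps = Fraction(es)
            for n in (1, 7, 19):
                table = ml_decision_table(n, float(eps))
                for k in range(n + 1):
                    assert table[k] == ml_call_exact(n, k, eps)


class TestAnalyticRates:
    def test_error_free_closed_forms(self):
        """At eps = 0 homozygotes are never miscalled and heterozygotes are
        miscalled exactly when all reads show one allele: (1/2)^(d-1)."""
        for d in range(1, 31):
            assert analytic_error_rate(HOMOZYGOTE, d, 0.0) == 0.0
            assert analytic_error_rate(HETEROZYGOTE, d, 0.0) == pytest.approx(
                0.5 ** (d - 1)
            )

    def test_decomposition_at_depth_five(self):
        """The published decomposition: e_hom = 1 - 0.99^5 and e_het = 1/16
        at d = 5, eps = 0.01."""
        assert analytic_error_rate(HOMOZYGOTE, 5, 0.01) == pytest.approx(
            1 - 0.99**5, abs=1e-12
        )
        assert analytic_error_rate(HETEROZYGOTE, 5, 0.01) == pytest.approx(0.0625)

    def test_exact_variant_matches_float_variant(self):
        for cls in (HOMOZYGOTE, HETEROZYGOTE):
            for d in (2, 5, 8, 20):
                exact = float(analytic_error_rate_exact(cls, d, Fraction("0.01")))
                assert analytic_error_rate(cls, d, 0.01) == pytest.approx(exact, abs=1e-12)

    def test_homozygote_rate_nondecreasing_in_eps_on_study_grid(self):
        """Over the base-calling error grid used in the study the homozygote
        error rate grows with eps.  (Beyond it the discrete ML threshold can
        move and break monotonicity, e.g. d = 5 at eps = 0.05.)"""
        for d in (3, 5, 10):
            rates = [analytic_error_rate(HOMOZYGOTE, d, e)
                     for e in (0.0, 0.001, 0.005, 0.01)]
            assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert analytic_error_rate(HOMOZYGOTE, 5, 0.05) < analytic_error_rate(
            HOMOZYGOTE, 5, 0.01
        )

    def test_heterozygote_rate_halves_per_read_at_zero_eps(self):
        for d in range(1, 20):
            assert analytic_error_rate(HETEROZYGOTE, d + 1, 0.0) == pytest.approx(
                analytic_error_rate(HETEROZYGOTE, d, 0.0) / 2
            )

    def test_non_monotonicity_in_depth(self):
        """Because the ML decision boundary moves discretely with d, the
        heterozygote error at eps = 0.01 is higher at d = 8 than at d = 5."""
        assert analytic_error_rate(HETEROZYGOTE, 8, 0.01) > analytic_error_rate(
            HETEROZYGOTE, 5, 0.01
        )


class TestAliasSampler:
    def test_matches_naive_binomial_sampling(self, rng):
        """The alias table over k | (n, class, eps) is distributionally
        identical to naive per-read Bernoulli sampling (chi-square)."""
        n, n_draws = 10, 100_000
        for cls, p in ((HETEROZYGOTE, 0.5), (HOMOZYGOTE, 0.05)):
            k_alias = read_count_sampler(n, cls, 0.05).sample(rng, n_draws)
            k_naive = rng.binomial(n, p, size=n_draws)
            counts_a = np.bincount(k_alias, minlength=n + 1)
            counts_n = np.bincount(k_naive, minlength=n + 1)
            expected = stats.binom.pmf(np.arange(n + 1), n, p) * n_draws
            keep = expected > 5
            for counts in (counts_a, counts_n):
                chi = stats.chisquare(counts[keep], expected[keep] * counts[keep].sum()
                                      / expected[keep].sum())
                assert chi.pvalue > 0.001

    def test_rejects_bad_distributions(self):
        with pytest.raises(ValueError):
            AliasTable([0.5, 0.4])
        with pytest.raises(ValueError):
            AliasTable([-0.5, 1.5])

    def test_caching_returns_same_table(self):
        assert read_count_sampler(7, HETEROZYGOTE, 0.01) is read_count_sampler(
            7, HETEROZYGOTE, 0.01
        )


class TestSimulateReads:
    def test_error_free_homozygote_reads(self, rng):
        reads = simulate_reads("AA", 7, 0.0, rng)
        assert reads.counts[0] == 7 and reads.counts[1:].sum() == 0
        assert reads.k == 0

    def test_error_free_heterozygote_reads(self, rng):
        counts_a = []
        for _ in range(2000):
            reads = simulate_reads("AT", 7, 0.0, rng)
            assert reads.counts[1] == 0 and reads.counts[2] == 0  # only A or T
            counts_a.append(int(reads.counts[0]))
        assert np.mean(counts_a) == pytest.approx(3.5, abs=0.15)

    def test_aggregate_error_fraction_matches_eps(self, rng):
        """Across many homozygous sites the fraction of non-reference reads
        is eps.  Depth 2 keeps the check exact: two reads can never show
        more than two bases, so no site is ever resampled."""
        eps, depth, n_sites = 0.01, 2, 500_000
        n_err = 0
        for _ in range(n_sites):
            reads = simulate_reads("GG", depth, eps, rng)
            n_err += depth - int(reads.counts[2])
        total = depth * n_sites
        se = np.sqrt(eps * (1 - eps) / total)
        assert abs(n_err / total - eps) < 4 * se

    def test_at_most_two_distinct_bases_survive(self, rng):
        for _ in range(500):
            reads = simulate_reads("AT", 30, 0.05, rng)
            assert int((reads.counts > 0).sum()) <= 2

    def test_two_allele_model_keeps_true_alleles(self, rng):
        reads = simulate_reads("CT", 9, 0.01, rng, model="two-allele")
        assert reads.allele0 == 1  # C
        assert reads.counts[1] + reads.counts[3] == 9


class TestCalling:
    def test_call_examples_at_depth_five(self, rng):
        reads = simulate_reads("AA", 5, 0.0, rng)
        call = call_genotype_ml(reads, 0.01, true_genotype="AA")
        assert call.called == (0, 0) and call.error_class == "none"

    def test_hom_as_het_classification(self):
        assert classify_call("TT", "TC") == "hom-as-het"
        assert classify_call("TC", "TT") == "het-as-hom"
        assert classify_call("AA", "CC") == "hom-as-other-hom"
        assert classify_call("AC", "AG") == "het-as-other-het"
        assert classify_call("CT", "TC") == "none"

    def test_full_read_model_deviates_by_order_eps_at_low_depth(self, rng):
        """Third-base reads make the full model's heterozygote miscall
        probability 0.5066 at d = 2, eps = 0.01 (reads like {A, C} for a true
        A/T call a wrong heterozygote), versus exactly 0.5 under the
        two-allele reduction — the reason analytic comparisons run under the
        two-allele model."""
        n_sites = 60_000
        miscalls = 0
        for _ in range(n_sites):
            reads = simulate_reads("AT", 2, 0.01, rng)
            call = call_genotype_ml(reads, 0.01, true_genotype="AT")
            miscalls += call.error_class != "none"
        observed = miscalls / n_sites
        expected = 0.506644  # exact enumeration of the 2-read outcome space
        se = np.sqrt(expected * (1 - expected) / n_sites)
        assert abs(observed - expected) < 4 * se
        assert observed > 0.5

    def test_fixed_depth_miscall_rates_match_analytic(self, rng):
        """Monte-Carlo miscall frequencies of the two-allele sampler plus ML
        caller sit within 3 binomial SE of the exact enumeration."""
        n_sites = 50_000
        for cls, gt, truth_code in ((HOMOZYGOTE, "AA", 0), (HETEROZYGOTE, "AT", 1)):
            for d, eps in ((5, 0.01), (8, 0.01), (10, 0.005)):
                table = ml_decision_table(d, eps)
                k = read_count_sampler(d, cls, eps).sample(rng, n_sites)
                observed = float(np.mean(table[k] != truth_code))
                p = analytic_error_rate(cls, d, eps)
                se = np.sqrt(p * (1 - p) / n_sites)
                assert abs(observed - p) < 3 * se


def _truth_alignment(rng, n_ind=2, n_sites=400, het_fraction=0.05):
    a = rng.integers(0, 4, size=(n_ind, n_sites, 2)).astype(np.uint8)
    a[:, :, 1] = a[:, :, 0]
    het = rng.random((n_ind, n_sites)) < het_fraction
    a[..., 1][het] = (a[..., 0][het] + rng.integers(1, 4, size=int(het.sum()))) % 4
    individuals = [("A", f"a{i + 1}") for i in range(n_ind)]
    return DiploidAlignment(individuals=individuals, alleles=a)


class TestCorruptAlignment:
    def test_no_err_mode_returns_truth(self, rng):
        truth = _truth_alignment(rng)
        tracks = np.full((2, 400), 5)
        called, ledger = corrupt_alignment(truth, tracks, 0.01, "no-err", rng)
        assert np.array_equal(called.alleles, truth.alleles)
        assert not called.phased_truth
        assert (~ledger["committed"]).all()

    def test_het_err_mode_preserves_homozygous_sites(self, rng):
        truth = _truth_alignment(rng)
        tracks = np.full((2, 400), 4)
        called, _ = corrupt_alignment(truth, tracks, 0.01, "het-err", rng)
        hom = ~truth.heterozygous()
        assert np.array_equal(called.alleles[hom], truth.alleles[hom])

    def test_hom_err_mode_preserves_heterozygous_sites(self, rng):
        truth = _truth_alignment(rng)
        tracks = np.full((2, 400), 4)
        called, _ = corrupt_alignment(truth, tracks, 0.01, "hom-err", rng)
        het = truth.heterozygous()
        assert np.array_equal(called.alleles[het], truth.alleles[het])

    def test_committed_hom_error_fraction_matches_depth_average(self, rng):
        """With depths uniform over {3..8} the committed hom-error fraction
        matches the analytic rate averaged over that depth distribution.
        (The rate is not monotone in depth — a single error read is tolerated
        at d = 7, 8 but flips the call at d = 3..6 — so the right oracle is
        the depth-weighted mean, not a bracket.)"""
        n_ind, n_sites = 4, 5000
        truth = _truth_alignment(rng, n_ind=n_ind, n_sites=n_sites, het_fraction=0.0)
        tracks = rng.integers(3, 9, size=(n_ind, n_sites))
        _, ledger = corrupt_alignment(truth, tracks, 0.01, "both-err", rng)
        rate = ledger["error_class"].isin(["hom-as-het", "hom-as-other-hom"]).sum() / (
            n_ind * n_sites
        )
        expected = np.mean([analytic_error_rate(HOMOZYGOTE, d, 0.01)
                            for d in range(3, 9)])
        se = np.sqrt(expected * (1 - expected) / (n_ind * n_sites))
        assert abs(rate - expected) < 4 * se

    def test_ledger_records_depth_and_site_one_based(self, rng):
        truth = _truth_alignment(rng)
        tracks = np.full((2, 400), 3)
        _, ledger = corrupt_alignment(truth, tracks, 0.05, "both-err", rng, locus=7)
        assert len(ledger) > 0
        assert (ledger["locus"] == 7).all()
        assert ledger["site"].between(1, 400).all()
        assert (ledger["depth"] == 3).all()

    def test_dimension_mismatch_rejected(self, rng):
        truth = _truth_alignment(rng)
        with pytest.raises(ValueError, match="shape"):
            corrupt_alignment(truth, np.full((2, 399), 5), 0.01, "both-err", rng)
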