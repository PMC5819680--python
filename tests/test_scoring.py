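import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varprior import (HET, HOM, AlleleCounts, BackgroundIndex, ImpactTable,
                      VariantRecord, binomial_loglik, raw_score, score_variant)
from varprior.io import ConsequenceAnnotation


def oracle_lambda(x_u, n_b, x_a, n_t, impact):
    """Independent direct evaluation of the likelihood-ratio score from raw
    binomial probabilities (0**0 == 1 handles degenerate frequencies)."""
    x, n = x_u + x_a, n_b + n_t
    p, p_u, p_a = x / n, x_u / n_b, x_a / n_t

    def lik(k, m, q):
        return (q ** k) * ((1.0 - q) ** (m - k))

    alt = lik(x_u, n_b, p_u) * lik(x_a, n_t, p_a)
    null = lik(x, n, p)
    return math.log(alt / null * impact)


class TestBinomialLoglik:
    def test_closed_form_value(self):
        expected = math.log(1 / 12) + 11 * math.log(11 / 12)  # ~= -3.44203
        assert binomial_loglik(1, 12, 1 / 12) == pytest.approx(expected, abs=1e-12)

    def test_zero_log_zero_convention(self):
        assert binomial_loglik(0, 10, 0.0) == 0.0
        assert binomial_loglik(10, 10, 1.0) == 0.0

    def test_symmetric_case(self):
        assert binomial_loglik(5, 10, 0.5) == pytest.approx(10 * math.log(0.5))

    def test_impossible_observation_is_neg_inf(self):
        assert binomial_loglik(1, 10, 0.0) == -math.inf
        assert binomial_loglik(9, 10, 1.0) == -math.inf

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            binomial_loglik(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_loglik(5, 10, 1.5)


class TestRawScore:
    def test_equal_frequencies_score_zero(self):
        # proband het (p_a = 0.5) matching a 50% background frequency
        assert raw_score(AlleleCounts(50, 100), HET, 1.0) == pytest.approx(0.0, abs=1e-12)

    def test_absent_variant_het_value(self):
        expected = math.log(0.25) - (math.log(1 / 12) + 11 * math.log(11 / 12))
        lam = raw_score(AlleleCounts(0, 10), HET, 1.0)
        assert lam == pytest.approx(expected, abs=1e-12)
        assert lam == pytest.approx(2.056, abs=1e-3)

    def test_hom_exceeds_het_for_absent_variant(self):
        counts = AlleleCounts(0, 10)
        assert raw_score(counts, HOM, 1.0) > raw_score(counts, HET, 1.0)

    def test_matches_oracle_on_small_grid(self):
        for n_b in range(2, 20):
            for x_u in range(n_b + 1):
                for geno in (HET, HOM):
                    for impact in (0.5, 1.0, 2.0):
                        got = raw_score(AlleleCounts(x_u, n_b), geno, impact)
                        want = oracle_lambda(x_u, n_b, geno.x_a, geno.n_t, impact)
                        assert got == pytest.approx(want, abs=1e-9), (x_u, n_b, geno)

    def test_monotone_in_rarity(self):
        for n_b in (10, 100, 1000):
            lams = [raw_score(AlleleCounts(x_u, n_b), HET, 1.0)
                    for x_u in range(n_b // 2 + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(lams, lams[1:]))

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            raw_score(AlleleCounts(0, 0), HET, 1.0)

    @given(x_u=st.integers(0, 200), n_b=st.integers(1, 200),
           impact=st.floats(0.1, 10.0), hom=st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_always_finite(self, x_u, n_b, impact, hom):
        if x_u > n_b:
            return
        lam = raw_score(AlleleCounts(x_u, n_b), HOM if hom else HET, impact)
        assert math.isfinite(lam)

    @given(n_b=st.integers(2, 500).filter(lambda n: n % 2 == 0),
           impact=st.floats(0.1, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_null_coincidence_decomposition(self, n_b, impact):
        """When proband and background frequencies agree, the frequency terms
        cancel and the score is exactly the log impact ratio."""
        lam = raw_score(AlleleCounts(n_b // 2, n_b), HET, impact)
        assert lam == pytest.approx(math.log(impact), abs=1e-12)


class TestScoreVariant:
    @pytest.fixture
    def index(self):
        return BackgroundIndex(counts={("chr1", 100, "G", "A"): AlleleCounts(50, 1000)},
                               default_n_b=1000)

    def test_winning_transcript_maximizes_het_score(self, index):
        # empirical-style table where missense carries more impact than intron
        table = ImpactTable(mode="empirical", n_bins=1,
                            a={("missense", 0): 0.5, ("non_coding_change", 0): 0.1,
                               **{(k, 0): 0.05 for k in
                                  ("stop_gained", "stop_lost", "start_lost", "splice_site",
                                   "synonymous", "inframe_indel", "frameshift_indel",
                                   "intergenic_change")}},
                            h={(k, 0): 0.1 for k in
                               ("missense", "stop_gained", "stop_lost", "start_lost",
                                "splice_site", "synonymous", "inframe_indel",
                                "frameshift_indel", "non_coding_change", "intergenic_change")})
        rec = VariantRecord("chr1", 100, "G", "A", [
            ConsequenceAnnotation("G1", "T1", "missense_variant", ("R", "V")),
            ConsequenceAnnotation("G1", "T2", "intron_variant"),
        ])
        res = score_variant(rec, index, table)
        assert res.winning_transcript == "T1"
        assert res.effect_group == "coding"
        assert res.raw_het == pytest.approx(
            oracle_lambda(50, 1000, 1, 2, 0.5 / 0.1), abs=1e-9)

    def test_unannotated_scored_with_unit_impact(self, index):
        rec = VariantRecord("chr1", 100, "G", "A", [])
        res = score_variant(rec, index, ImpactTable.off())
        assert res.effect_group == "intergenic"
        assert res.impact_ratio_used == 1.0
        assert res.raw_het == pytest.approx(oracle_lambda(50, 1000, 1, 2, 1.0), abs=1e-9)

    def test_rarer_variant_scores_higher(self, index):
        table = ImpactTable.off()
        seen = score_variant(VariantRecord("chr1", 100, "G", "A", []), index, table)
        unseen = score_variant(VariantRecord("chr1", 200, "G", "A", []), index, table)
        assert unseen.raw_het > seen.raw_het

    def test_both_states_always_reported(self, index):
        res = score_variant(VariantRecord("chr1", 100, "G", "A", []), index,
                            ImpactTable.off())
        assert math.isfinite(res.raw_het) and math.isfinite(res.raw_hom)


class TestLeaveOneOut:
    def test_proband_exclusion_negligible_at_repository_scale(self):
        """Removing the proband's own chromosomes (c=2) from the background
        barely moves the score once the repository is large."""
        deltas = []
        for n_b in (10 ** 3, 10 ** 4, 10 ** 5):
            x_u = max(20, int(0.01 * n_b))
            with_proband = raw_score(AlleleCounts(x_u, n_b), HOM, 1.0)
            without = raw_score(AlleleCounts(x_u - 2, n_b - 2), HOM, 1.0)
            deltas.append(abs(with_proband - without))
        assert deltas[0] > deltas[1] > deltas[2]
        assert deltas[2] < 0.1
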