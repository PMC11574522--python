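"""Telegraph stationary distributions: mutual oracles, moments, limits, conversions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import poisson

from burstkit.core import (
    BurstStatistics,
    CountDistribution,
    DimensionlessRates,
    TelegraphRates,
    TruncationError,
    burst_statistics,
    cme_steady_state,
    convolve_alleles,
    decay_from_halflife,
    decay_to_halflife,
    steady_state_closed_form,
    telegraph_moments,
)
from conftest import ORACLE_GRID


def aligned(d1: CountDistribution, d2: CountDistribution):
    n = max(d1.probs.size, d2.probs.size)
    p = np.zeros(n)
    q = np.zeros(n)
    p[: d1.probs.size] = d1.probs
    q[: d2.probs.size] = d2.probs
    return p, q


class TestRateTypes:
    @pytest.mark.parametrize("bad", [0.0, -1.0, float("nan"), float("inf")])
    def test_nonpositive_rates_rejected(self, bad):
        with pytest.raises(ValueError):
            TelegraphRates(k_on=bad, k_off=1.0, k_eject=1.0, k_decay=1.0)
        with pytest.raises(ValueError):
            DimensionlessRates(a=1.0, b=bad, lam=1.0)

    def test_dimensionless_round_trip(self):
        rates = TelegraphRates(k_on=0.05, k_off=0.5, k_eject=2.5, k_decay=0.02)
        d = rates.dimensionless()
        assert d.a == pytest.approx(2.5)
        assert d.b == pytest.approx(25.0)
        assert d.lam == pytest.approx(125.0)
        back = TelegraphRates.from_dimensionless(d, rates.k_decay)
        for name in ("k_on", "k_off", "k_eject", "k_decay"):
            assert getattr(back, name) == pytest.approx(getattr(rates, name), rel=1e-12)


class TestClosedForm:
    def test_near_always_on_is_poisson(self):
        # with k_off -> 0 the promoter never closes: pure Poisson(lam)
        dist = steady_state_closed_form(DimensionlessRates(a=50.0, b=0.001, lam=10.0))
        ref = CountDistribution(poisson.pmf(np.arange(dist.probs.size), 10.0))
        assert dist.total_variation(ref) < 1e-3

    def test_no_production_concentrates_at_zero(self):
        dist = steady_state_closed_form(DimensionlessRates(a=1.0, b=1.0, lam=1e-12))
        assert dist.probs[0] >= 1.0 - 1e-9

    def test_insufficient_n_max_raises_with_requirement(self):
        with pytest.raises(TruncationError) as err:
            steady_state_closed_form(DimensionlessRates(a=1.0, b=1.0, lam=10.0), n_max=3)
        assert err.value.required_n_max is not None and err.value.required_n_max > 3


class TestCmeOracle:
    def test_probabilities_conserved_before_renormalization(self):
        dist = cme_steady_state(DimensionlessRates(a=0.7, b=3.0, lam=12.0))
        assert abs(dist.raw_sum - 1.0) < 1e-10

    def test_known_stationary_mean(self):
        dist = cme_steady_state(DimensionlessRates(a=0.5, b=2.0, lam=20.0))
        assert dist.mean() == pytest.approx(4.0, abs=1e-6)

    def test_agrees_with_closed_form_pointwise(self):
        d = DimensionlessRates(a=1.0, b=1.0, lam=10.0)
        p, q = aligned(steady_state_closed_form(d), cme_steady_state(d))
        assert abs(p[0] - q[0]) < 1e-8
        assert np.abs(p - q).max() < 1e-8

    @pytest.mark.parametrize("a,b,lam", ORACLE_GRID[::5])
    def test_oracle_equivalence_spot_checks(self, a, b, lam):
        d = DimensionlessRates(a=a, b=b, lam=lam)
        p, q = aligned(steady_state_closed_form(d), cme_steady_state(d))
        assert np.abs(p - q).max() < 1e-8


class TestConvolution:
    def test_single_allele_is_identity(self):
        dist = steady_state_closed_form(DimensionlessRates(1.0, 1.0, 5.0))
        assert convolve_alleles(dist, 1) is dist

    def test_poisson_additivity(self):
        lam = 4.0
        base = CountDistribution(poisson.pmf(np.arange(80), lam), normalize=False)
        two = convolve_alleles(base, 2)
        ref = poisson.pmf(np.arange(two.probs.size), 2 * lam)
        assert np.abs(two.probs - ref / ref.sum()).max() < 1e-8

    def test_mean_additivity_against_cme(self):
        d = DimensionlessRates(a=1.0, b=1.0, lam=5.0)
        single = cme_steady_state(d)
        double = convolve_alleles(single, 2)
        assert double.mean() == pytest.approx(2 * single.mean(), abs=1e-6)

    def test_invalid_allele_count(self):
        dist = steady_state_closed_form(DimensionlessRates(1.0, 1.0, 5.0))
        with pytest.raises(ValueError):
            convolve_alleles(dist, 0)

    def test_unusual_allele_count_warns(self):
        dist = steady_state_closed_form(DimensionlessRates(1.0, 1.0, 5.0))
        with pytest.warns(UserWarning, match="unusual allele count"):
            convolve_alleles(dist, 3)


class TestBurstStatistics:
    @pytest.mark.parametrize(
        "k_eject,k_off,expected", [(2.0, 1.0, 2.0), (0.7, 0.7, 1.0), (10.0, 0.5, 20.0)]
    )
    def test_burst_size_is_eject_over_off(self, k_eject, k_off, expected):
        rates = TelegraphRates(k_on=0.1, k_off=k_off, k_eject=k_eject, k_decay=0.01)
        assert burst_statistics(rates).burst_size == pytest.approx(expected)

    def test_mean_expression_matches_cme_mean(self):
        rates = TelegraphRates(k_on=0.1, k_off=1.0, k_eject=10.0, k_decay=0.5)
        stats = burst_statistics(rates, n_alleles=2)
        assert stats.mean_expression == pytest.approx(2 * 20.0 * (0.1 / 1.1), rel=1e-12)
        assert stats.frequency == pytest.approx(0.1)
        dist = convolve_alleles(cme_steady_state(rates), 2)
        assert stats.mean_expression == pytest.approx(dist.mean(), abs=1e-4)


class TestHalfLifeConversion:
    def test_halflife_of_ln2_minutes_gives_unit_rate(self):
        assert decay_from_halflife(math.log(2.0)) == pytest.approx(1.0)

    def test_sixty_minute_halflife(self):
        assert decay_from_halflife(60.0) == pytest.approx(math.log(2.0) / 60.0, rel=1e-9)
        assert decay_from_halflife(60.0) == pytest.approx(0.011552, abs=1e-6)

    def test_round_trip(self):
        assert decay_to_halflife(decay_from_halflife(0.03)) == pytest.approx(0.03)
        assert decay_from_halflife(decay_to_halflife(0.03)) == pytest.approx(0.03)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            decay_from_halflife(0.0)


class TestInvariants:
    @given(
        a=st.floats(0.05, 30.0),
        b=st.floats(0.05, 30.0),
        lam=st.floats(0.01, 60.0),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_normalization_and_mean_identity(self, a, b, lam):
        dist = steady_state_closed_form(DimensionlessRates(a, b, lam))
        assert abs(dist.probs.sum() - 1.0) < 1e-6
        assert np.all(dist.probs >= 0)
        mean, _ = telegraph_moments(a, b, lam)
        assert dist.mean() == pytest.approx(mean, abs=1e-6)

    def test_poisson_limit_fano(self):
        # b -> 0: the ON fraction is pinned at 1 and the Fano factor goes to 1
        dist = steady_state_closed_form(DimensionlessRates(a=1.0, b=1e-4, lam=10.0))
        assert abs(dist.fano() - 1.0) < 1e-3

    def test_bursty_limit_mean_factorizes(self):
        # a << b, lam >> 1: mean ~ burst_size * frequency / k_decay
        rates = TelegraphRates(k_on=0.01, k_off=10.0, k_eject=100.0, k_decay=1.0)
        stats = burst_statistics(rates, n_alleles=1)
        approx = stats.burst_size * stats.frequency / rates.k_decay
        assert stats.mean_expression == pytest.approx(approx, rel=0.05)

    def test_distribution_tsv_round_trip(self, tmp_path):
        dist = steady_state_closed_form(DimensionlessRates(1.0, 2.0, 8.0))
        path = tmp_path / "dist.tsv"
        dist.to_tsv(path)
        data = np.loadtxt(path, skiprows=1)
        assert np.allclose(data[:, 1], dist.probs)
        assert np.array_equal(data[:, 0], dist.support)
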