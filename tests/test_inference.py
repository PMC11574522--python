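"""Likelihood correctness, MH behavior, QC filter and parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from burstkit.core import (
    DimensionlessRates,
    TelegraphRates,
    convolve_alleles,
    steady_state_closed_form,
)
from burstkit.inference import (
    TelegraphModel,
    fit_gene_mcmc,
    fit_gene_table,
    qc_filter,
)
from burstkit.simulate import SimulationConfig, betapoisson_counts

RECOVERY_RATES = TelegraphRates(k_on=0.05, k_off=0.5, k_eject=2.5, k_decay=0.02)


@pytest.fixture(scope="module")
def recovery_counts():
    cfg = SimulationConfig(rates=RECOVERY_RATES, n_alleles=2, n_cells=2000, seed=100)
    return betapoisson_counts(cfg)


@pytest.fixture(scope="module")
def recovery_fit(recovery_counts):
    return fit_gene_mcmc(
        recovery_counts, k_decay=0.02, n_alleles=2, n_steps=3000, n_burn=1000, seed=21
    )


class TestLogLikelihood:
    def test_empty_histogram_gives_zero(self):
        model = TelegraphModel([], k_decay=1.0)
        assert model.loglike(np.log10([1.0, 1.0, 1.0])) == 0.0

    def test_zero_count_cell_with_no_production(self):
        model = TelegraphModel([0], k_decay=1.0, n_alleles=1)
        rates = TelegraphRates(k_on=1.0, k_off=1.0, k_eject=1e-12, k_decay=1.0)
        assert model.loglike_rates(rates) >= -1e-9

    def test_termwise_sum_against_closed_form(self):
        counts = [0, 1, 2]
        model = TelegraphModel(counts, k_decay=1.0, n_alleles=1)
        dist = steady_state_closed_form(DimensionlessRates(1.0, 1.0, 10.0))
        expected = sum(math.log(dist.probs[c] * dist.raw_sum) for c in counts)
        got = model.loglike(np.log10([1.0, 1.0, 10.0]))
        assert got == pytest.approx(expected, abs=1e-8)

    def test_termwise_sum_two_alleles(self):
        counts = [0, 3, 7, 7]
        model = TelegraphModel(counts, k_decay=0.5, n_alleles=2)
        rates = TelegraphRates(k_on=0.5, k_off=1.0, k_eject=5.0, k_decay=0.5)
        per_allele = steady_state_closed_form(rates)
        total = convolve_alleles(per_allele, 2)
        expected = sum(math.log(total.probs[c]) for c in counts)
        assert model.loglike_rates(rates) == pytest.approx(expected, abs=1e-6)

    def test_out_of_bounds_returns_neg_inf_not_raise(self):
        model = TelegraphModel([1, 2], k_decay=1.0)
        assert model.loglike([10.0, 0.0, 0.0]) == -math.inf
        assert model.loglike([np.nan, 0.0, 0.0]) == -math.inf


class TestFit:
    def test_recovers_burst_size_within_factor(self, recovery_fit):
        true_burst = 2.5 / 0.5
        ratio = recovery_fit.median["burst_size"] / true_burst
        assert 1 / 1.5 < ratio < 1.5
        ratio_f = recovery_fit.median["frequency"] / 0.05
        assert 1 / 1.5 < ratio_f < 1.5

    def test_same_seed_identical_results(self, recovery_counts):
        kwargs = dict(k_decay=0.02, n_alleles=2, n_steps=400, n_burn=200, seed=33)
        r1 = fit_gene_mcmc(recovery_counts, **kwargs)
        r2 = fit_gene_mcmc(recovery_counts, **kwargs)
        assert r1.median == r2.median
        assert r1.mad == r2.mad
        assert r1.acceptance_rate == r2.acceptance_rate

    def test_all_zero_counts_degenerate(self):
        res = fit_gene_mcmc(
            np.zeros(200, dtype=int), k_decay=0.01, n_steps=600, n_burn=300, seed=2
        )
        assert res.degenerate
        assert not res.qc_pass
        # production rate posterior hugs the prior's lower boundary
        assert res.median["k_eject"] < 1e-2

    def test_chain_health(self, recovery_fit):
        assert 0.15 <= recovery_fit.acceptance_rate <= 0.5

    def test_posterior_predictive_mean_close_to_observed(self, recovery_fit, recovery_counts):
        assert recovery_fit.qc_pass
        predicted = recovery_fit.posterior_predictive().mean()
        assert predicted == pytest.approx(recovery_counts.mean(), rel=0.15)

    def test_few_cells_warns(self):
        with pytest.warns(UserWarning, match="cells"):
            fit_gene_mcmc([1, 2, 3], k_decay=0.1, n_steps=50, n_burn=20, seed=0)

    def test_summary_table(self, recovery_fit):
        df = recovery_fit.summary()
        assert set(df.index) == {"k_on", "k_off", "k_eject", "burst_size", "frequency"}
        assert (df["median"] > 0).all()
        rec = recovery_fit.to_record()
        assert rec["qc_pass"] == recovery_fit.qc_pass
        assert rec["burst_size_median"] == recovery_fit.median["burst_size"]


class TestQcFilter:
    BASE = {
        "k_on_median": 1.0,
        "k_on_mad": 0.1,
        "burst_size_median": 1.0,
        "burst_size_mad": 0.1,
        "mean_expression": 5.0,
    }

    def qc(self, **overrides):
        return qc_filter({**self.BASE, **overrides})

    def test_passes_well_constrained_fit(self):
        assert self.qc()

    def test_k_on_spread_above_threshold_fails(self):
        assert not self.qc(k_on_mad=0.76)

    def test_zero_mads_pass(self):
        assert self.qc(k_on_mad=0.0, burst_size_mad=0.0)

    def test_boundary_ratio_exactly_075_fails(self):
        # strict inequality: MAD/median == 0.75 is a fail
        assert not self.qc(burst_size_mad=0.75)
        assert not self.qc(k_on_mad=0.75)

    def test_just_below_boundary_passes(self):
        assert self.qc(burst_size_mad=0.7499999)

    def test_expression_boundary(self):
        assert not self.qc(mean_expression=0.01)
        assert self.qc(mean_expression=0.010001)

    def test_nonpositive_median_fails(self):
        assert not self.qc(k_on_median=0.0)
        assert not self.qc(burst_size_median=-1.0)


class TestFitTable:
    def test_missing_halflife_uses_cohort_median(self, recovery_counts):
        counts = {"g1": recovery_counts[:300], "g2": recovery_counts[:300]}
        half_lives = pd.Series({"g1": math.log(2) / 0.02})  # g2 absent
        table = fit_gene_table(counts, half_lives, n_steps=200, n_burn=100, seed=1)
        assert set(table.gene_id) == {"g1", "g2"}
        assert table.k_decay.iloc[0] == pytest.approx(table.k_decay.iloc[1])

    def test_reproducible_and_order_insensitive_seeds(self, recovery_counts):
        counts = {"g1": recovery_counts[:400], "g2": recovery_counts[400:800]}
        hl = pd.Series({"g1": 60.0, "g2": 60.0})
        t1 = fit_gene_table(counts, hl, n_steps=200, n_burn=100, seed=4)
        t2 = fit_gene_table(counts, hl, n_steps=200, n_burn=100, seed=4)
        pd.testing.assert_frame_equal(t1, t2)
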