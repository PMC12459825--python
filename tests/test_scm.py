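"""Generative behaviour of the four structural causal simulators."""

import numpy as np
import pytest

import srmkit
from srmkit.scm import (
    ScmConfig,
    assemble_rate,
    assign_ranks_scm4,
    dyadic_effort,
    rank_difference_term,
    relatedness_indicator,
    sample_counts,
    simulate,
)


class TestRateArithmetic:
    @pytest.mark.parametrize(
        "args,printed",
        [
            ((0.2, 0, 0, 0), 1.2),
            ((-1.2, 0, 0, np.log(3.5)), 1.1),
            ((0, 0, 0, 0), 1.0),
        ],
    )
    def test_worked_examples(self, args, printed):
        assert assemble_rate(*args) == pytest.approx(printed, abs=0.05)

    def test_exactness(self):
        assert assemble_rate(0.2, 0.1, -0.3, 0.4) == pytest.approx(np.exp(0.4))

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            assemble_rate(np.inf, 0, 0, 0)


class TestObservationProcess:
    def test_zero_rate_gives_zero_counts(self):
        assert np.all(sample_counts(np.zeros(100), seed=0) == 0)

    def test_poisson_mean_and_equidispersion(self):
        draws = sample_counts(np.full(100_000, 1.2), seed=42)
        se = np.sqrt(1.2 / len(draws))
        assert abs(draws.mean() - 1.2) < 3 * se
        assert draws.var() / draws.mean() == pytest.approx(1.0, abs=0.05)

    def test_rejects_negative_rate(self):
        with pytest.raises(ValueError):
            sample_counts(np.array([1.0, -0.1]), seed=0)

    def test_seed_reproducibility(self):
        a = sample_counts(np.full(50, 2.0), seed=7)
        assert np.array_equal(a, sample_counts(np.full(50, 2.0), seed=7))


class TestDyadLevelPrimitives:
    def test_effort_worked_examples(self):
        assert dyadic_effort(1.0, 2.5) == pytest.approx(3.5)
        assert dyadic_effort(2, 2) == pytest.approx(4.0)
        assert dyadic_effort(1.3, 2.2) == dyadic_effort(2.2, 1.3)
        with pytest.raises(ValueError):
            dyadic_effort(0.0, 1.0)

    def test_relatedness_indicator(self):
        assert relatedness_indicator(3, 3) == 1
        assert relatedness_indicator(3, 5) == 0
        assert relatedness_indicator(2, 7) == relatedness_indicator(7, 2)

    def test_rank_difference_branches(self):
        # active only when the giver outranks (lower value) the receiver
        assert rank_difference_term(0.1, 0.8, 0.8) == pytest.approx(0.8 * 0.7)
        assert rank_difference_term(0.8, 0.1, 0.8) == 0.0
        assert rank_difference_term(0.5, 0.5, 0.8) == 0.0
        assert rank_difference_term(0.5, 0.5, 0.0) == 0.0


class TestRankAssignment:
    def test_stratified_enumeration(self):
        # kin groups {1, 1, 2}: the kin-1 pair occupies {1/3, 2/3}, kin-2 gets 1
        seen = set()
        for seed in range(40):
            ranks = assign_ranks_scm4([1, 1, 2], seed=seed)
            assert sorted(ranks[:2]) == pytest.approx([1 / 3, 2 / 3])
            assert ranks[2] == pytest.approx(1.0)
            seen.add(tuple(np.round(ranks[:2], 6)))
        # both admissible within-matriline orders occur
        assert len(seen) == 2

    def test_single_individual(self):
        assert assign_ranks_scm4([1], seed=0) == pytest.approx([1.0])

    def test_deterministic_under_seed(self):
        a = assign_ranks_scm4([1, 2, 1, 3, 2], seed=5)
        b = assign_ranks_scm4([1, 2, 1, 3, 2], seed=5)
        assert np.array_equal(a, b)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            assign_ranks_scm4([], seed=0)


class TestScm1:
    def test_zero_noise_rate_is_average_dyad_rate(self):
        net = simulate(ScmConfig(scm_id=1, seed=0, zero_noise=True))
        assert np.allclose(net.rate_m, np.exp(0.2))
        assert np.exp(0.2) == pytest.approx(1.2, abs=0.05)

    def test_lognormal_mean_oracle(self):
        # E exp(0.2 + Z), Z ~ N(0, 3 * 0.25) => exp(0.2 + 0.375)
        rates = np.concatenate(
            [simulate(ScmConfig(scm_id=1, seed=s, n_individuals=40)).rate_m
             for s in range(12)]
        )
        assert rates.mean() == pytest.approx(np.exp(0.575), rel=0.08)

    def test_log_rate_equals_linear_predictor_exactly(self, scm1_network):
        assert np.allclose(np.log(scm1_network.rate_m),
                           scm1_network.linear_predictor())

    def test_same_seed_bit_identical(self):
        a = simulate(ScmConfig(scm_id=1, seed=3))
        b = simulate(ScmConfig(scm_id=1, seed=3))
        assert np.array_equal(a.dataset.counts, b.dataset.counts)
        assert np.array_equal(a.gamma, b.gamma)
        assert a.truth == b.truth


class TestScm2:
    def test_covariate_shifts_conditional_means(self):
        # effect -0.7: gamma - (-0.7 x) should be centred noise, and the
        # giving latent strongly anti-correlates with x
        net = simulate(ScmConfig(scm_id=2, seed=1, n_individuals=200))
        x = net.dataset.roster.x
        resid = net.gamma - (-0.7) * x
        assert abs(resid.mean()) < 0.15
        assert np.std(resid) == pytest.approx(0.5, abs=0.1)
        assert np.corrcoef(x, net.gamma)[0, 1] < -0.5

    def test_row_mean_log_rate_tracks_covariate(self):
        net = simulate(ScmConfig(scm_id=2, seed=2, n_individuals=60))
        ds = net.dataset
        log_m = np.log(net.rate_m)
        row_means = np.array(
            [log_m[ds.giver_pos() == a].mean() for a in range(ds.roster.n)]
        )
        assert np.corrcoef(ds.roster.x, row_means)[0, 1] < -0.5

    def test_null_effects_reduce_to_scm1_moments(self):
        logs1, logs2 = [], []
        for s in range(40):
            logs1.append(np.log(simulate(ScmConfig(scm_id=1, seed=s)).rate_m))
            logs2.append(np.log(simulate(ScmConfig(
                scm_id=2, seed=100 + s, effect_x_on_gamma=0.0, effect_x_on_rho=0.0
            )).rate_m))
        m1, m2 = np.concatenate(logs1), np.concatenate(logs2)
        assert m1.mean() == pytest.approx(m2.mean(), abs=0.06)
        assert m1.var() == pytest.approx(m2.var(), rel=0.15)


class TestScm3:
    def test_default_design(self, scm3_network):
        kin = scm3_network.dataset.roster.kin_group
        assert len(kin) == 20
        values, counts = np.unique(kin, return_counts=True)
        assert len(values) == 11
        assert sorted(counts, reverse=True) == [10] + [1] * 10

    def test_worked_offset_examples(self):
        # rates for average non-kin dyads observed 4 and 2 time units
        assert assemble_rate(-1.2, 0, 0, np.log(4)) == pytest.approx(1.2, abs=0.05)
        assert assemble_rate(-1.2, 0, 0, np.log(2)) == pytest.approx(0.6, abs=0.05)

    def test_effort_bounds_and_dyadic_sum(self, scm3_network):
        r = scm3_network.dataset.roster
        assert np.all((r.effort >= 1.0) & (r.effort <= 2.5))
        d = scm3_network.dataset
        expected = r.effort[d.giver_pos()] + r.effort[d.receiver_pos()]
        assert np.allclose(d.dyadic_effort, expected)

    def test_doubling_effort_doubles_rates(self):
        # Uniform(2, 5) = 2 * Uniform(1, 2.5) draw-for-draw under one seed,
        # so the log-effort offset must exactly double every rate
        base = simulate(ScmConfig(scm_id=3, seed=8, zero_noise=True))
        doubled = simulate(ScmConfig(scm_id=3, seed=8, zero_noise=True,
                                     effort_low=2.0, effort_high=5.0))
        assert np.allclose(doubled.rate_m, 2.0 * base.rate_m)

    def test_standardized_relatedness_enters_tie_mean(self):
        net = simulate(ScmConfig(scm_id=3, seed=5, zero_noise=True))
        ds = net.dataset
        # zero-noise tau = log S|a,b| + 0.8 * standardized Re
        resid = net.tau - np.log(ds.dyadic_effort)
        re_std = resid / 0.8
        assert abs(re_std.mean()) < 1e-10
        kin = ds.relatedness == 1
        assert np.all(re_std[kin] > 0) and np.all(re_std[~kin] < 0)


class TestScm4:
    def test_worked_rate_examples(self):
        kin_adjacent = assemble_rate(-1.2, 0, 0, 0.6 * 1 + 0.8 * 0)
        nonkin_distant = assemble_rate(-1.2, 0, 0, 0.6 * 0 + 0.8 * 0.7)
        assert kin_adjacent == pytest.approx(0.5, abs=0.05)
        assert nonkin_distant == pytest.approx(0.5, abs=0.05)

    def test_design_shape(self, scm4_network):
        r = scm4_network.dataset.roster
        sizes = [np.sum(r.group == g) for g in (1, 2, 3)]
        assert sizes == [10, 15, 20]
        assert scm4_network.dataset.n_dyads == 90 + 210 + 380
        for g, nk in zip((1, 2, 3), (3, 5, 7)):
            labels = r.kin_group[r.group == g]
            assert np.all((labels >= 1) & (labels <= nk))

    def test_confounding_premise_kin_closer_in_rank(self):
        kin_gap, nonkin_gap, contrasts = [], [], []
        for seed in range(1, 9):
            net = simulate(ScmConfig(scm_id=4, seed=seed))
            ds = net.dataset
            rank = ds.roster.rank
            gap = np.abs(rank[ds.receiver_pos()] - rank[ds.giver_pos()])
            kin = ds.relatedness == 1
            kin_gap.append(gap[kin].mean())
            nonkin_gap.append(gap[~kin].mean())
            log_m = np.log(net.rate_m) - np.log(ds.dyadic_effort)
            contrasts.append(log_m[kin].mean() - log_m[~kin].mean())
        assert np.mean(kin_gap) < np.mean(nonkin_gap)
        # marginal kin contrast of log rates is NOT the structural 0.6
        assert abs(np.mean(contrasts) - 0.6) > 0.1

    def test_smaller_groups_more_related(self):
        small, large = [], []
        for seed in range(40):
            ds = simulate(ScmConfig(scm_id=4, seed=seed)).dataset
            re, grp = ds.relatedness, ds.roster.group
            g_of_dyad = grp[ds.giver_pos()]
            small.append(re[g_of_dyad == 1].mean())
            large.append(re[g_of_dyad == 3].mean())
        # with-replacement labels: P(match) = 1/3 vs 1/7
        assert np.mean(small) == pytest.approx(1 / 3, abs=0.05)
        assert np.mean(large) == pytest.approx(1 / 7, abs=0.04)
        assert np.mean(small) > np.mean(large)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScmConfig(scm_id=5)
        with pytest.raises(ValueError):
            ScmConfig(scm_id=1, latent_sd=-0.1)
        with pytest.raises(ValueError):
            ScmConfig(scm_id=2, effect_rank=0.5)


def test_all_rates_strictly_positive_and_exact():
    for scm_id in (1, 2, 3, 4):
        net = simulate(ScmConfig(scm_id=scm_id, seed=17))
        assert np.all(net.rate_m > 0)
        assert np.allclose(np.log(net.rate_m), net.linear_predictor(), atol=1e-12)
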