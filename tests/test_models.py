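"""Linear predictor, likelihood, prior layers, and model-spec plumbing."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import srmkit
from srmkit.data import DyadicDataset, Roster, build_dyad_index, derive_dyadic_effort
from srmkit.models import (
    ModelSpec,
    ParameterSet,
    build_spec,
    design_arrays,
    linear_predictor,
    log_likelihood,
    log_prior_with_index,
)
from srmkit.potential import SrmPotential


def tiny_dataset(n=4, seed=0, with_covariates=True):
    rng = np.random.default_rng(seed)
    cols = {"id": np.arange(1, n + 1), "group": np.ones(n, dtype=int)}
    if with_covariates:
        cols.update(
            kin_group=rng.integers(1, 3, n),
            x=rng.normal(size=n),
            rank=np.arange(1, n + 1) / n,
            effort=rng.uniform(1, 2.5, n),
        )
    roster = Roster(pd.DataFrame(cols))
    idx = build_dyad_index(roster)
    counts = rng.poisson(1.0, idx.n_directed)
    kwargs = {}
    if with_covariates:
        k = roster.kin_group
        kwargs["relatedness"] = (k[idx.giver - 1] == k[idx.receiver - 1]).astype(float)
        kwargs["dyadic_effort"] = derive_dyadic_effort(roster, idx)
    return DyadicDataset(roster, idx, counts, **kwargs)


def random_params(data, rng, **fixed):
    n, nd = data.roster.n, data.n_dyads
    base = dict(
        D=rng.normal(), G=rng.normal(size=n) * 0.5, R=rng.normal(size=n) * 0.5,
        T=rng.normal(size=nd) * 0.5, sG=0.5, sR=0.6, sT=0.4, cGR=0.2, cTT=-0.3,
        bG=rng.normal(), bR=rng.normal(), bRe=rng.normal(),
        bRa1=rng.normal(), bRa2=rng.normal(),
    )
    base.update(fixed)
    return ParameterSet(**base)


class TestLinearPredictor:
    def test_intercept_only_constant(self):
        data = tiny_dataset(with_covariates=False)
        p = random_params(data, np.random.default_rng(1),
                          G=np.zeros(4), R=np.zeros(4), T=np.zeros(12), D=0.2)
        eta = linear_predictor(p, data, build_spec(1))
        assert np.allclose(eta, 0.2)
        assert np.exp(0.2) == pytest.approx(1.2, abs=0.05)

    def test_submodel_equals_flattened_form(self):
        """The giver/receiver submodel notation and the single-line form agree."""
        data = tiny_dataset()
        rng = np.random.default_rng(2)
        p = random_params(data, rng)
        eta = linear_predictor(p, data, build_spec(2))
        g_pos, r_pos = data.giver_pos(), data.receiver_pos()
        x = data.roster.x
        g_hat = p.G + p.bG * x        # submodel per individual
        r_hat = p.R + p.bR * x
        flat = p.D + g_hat[g_pos] + r_hat[r_pos] + p.T
        assert np.allclose(eta, flat)

    def test_variant4_worked_example(self):
        data = tiny_dataset()
        # equal ranks and unit joint effort isolate D + bRe
        data.roster.table["rank"] = 0.5
        data = DyadicDataset(
            data.roster, data.dyads, data.counts,
            relatedness=np.ones(data.n_dyads),
            dyadic_effort=np.ones(data.n_dyads),
        )
        p = random_params(data, np.random.default_rng(3),
                          D=-1.2, bRe=0.6, bRa1=0.8, bRa2=0.0,
                          G=np.zeros(4), R=np.zeros(4), T=np.zeros(12))
        m = np.exp(linear_predictor(p, data, build_spec(4)))
        assert np.allclose(m, np.exp(-1.2 + 0.6))
        assert m[0] == pytest.approx(0.5, abs=0.06)

    def test_variant4_manual_loop(self):
        data = tiny_dataset(seed=5)
        spec = build_spec(4)
        p = random_params(data, np.random.default_rng(4))
        eta = linear_predictor(p, data, spec)
        d = data.dyads
        rank = data.roster.rank
        for i in range(data.n_dyads):
            a, b = d.giver[i] - 1, d.receiver[i] - 1
            delta = rank[b] - rank[a]
            rank_term = p.bRa1 * delta if delta > 0 else p.bRa2 * delta
            expected = (p.D + p.G[a] + p.R[b] + p.T[i]
                        + math.log(data.dyadic_effort[i])
                        + p.bRe * data.relatedness[i] + rank_term)
            assert eta[i] == pytest.approx(expected)

    def test_missing_covariate_named_in_error(self):
        data = tiny_dataset(with_covariates=False)
        with pytest.raises(ValueError, match="effort"):
            design_arrays(data, build_spec(3))
        with pytest.raises(ValueError, match="'x'"):
            design_arrays(data, build_spec(2))

    def test_offset_shift_equivalent_to_intercept_shift(self):
        """Adding log c to all offsets equals adding log c to D (offset property)."""
        data = tiny_dataset(seed=6)
        spec = build_spec(3)
        p = random_params(data, np.random.default_rng(5))
        eta = linear_predictor(p, data, spec)
        scaled = DyadicDataset(data.roster, data.dyads, data.counts,
                               relatedness=data.relatedness,
                               dyadic_effort=3.0 * data.dyadic_effort)
        eta_scaled = linear_predictor(p, scaled, spec)
        assert np.allclose(eta_scaled, eta + np.log(3.0))


class TestLogLikelihood:
    def test_zero_count_unit_rate(self):
        data = tiny_dataset(with_covariates=False)
        data.counts[:] = 0
        p = random_params(data, np.random.default_rng(1),
                          G=np.zeros(4), R=np.zeros(4), T=np.zeros(12), D=0.0)
        assert log_likelihood(p, data, build_spec(1)) == pytest.approx(-data.n_dyads)

    def test_matches_brute_force_factorial(self):
        data = tiny_dataset(seed=7, with_covariates=False)
        p = random_params(data, np.random.default_rng(8))
        spec = build_spec(1)
        ll = log_likelihood(p, data, spec)
        m = np.exp(linear_predictor(p, data, spec))
        brute = sum(
            -mi + yi * math.log(mi) - math.log(math.factorial(int(yi)))
            for yi, mi in zip(data.counts, m)
        )
        assert ll == pytest.approx(brute)

    def test_rate_equal_to_count_maximises_term(self):
        for k in (1, 3, 7):
            grid = np.linspace(0.2, 3 * k, 400)
            terms = stats.poisson.logpmf(k, grid)
            assert grid[np.argmax(terms)] == pytest.approx(k, rel=0.05)

    def test_non_integer_counts_rejected(self):
        data = tiny_dataset(with_covariates=False)
        data.counts = data.counts.astype(float)
        p = random_params(data, np.random.default_rng(1))
        with pytest.raises(ValueError, match="integer"):
            log_likelihood(p, data, build_spec(1))


class TestLogPrior:
    def test_matches_brute_force_density(self):
        data = tiny_dataset(with_covariates=False)
        p = random_params(data, np.random.default_rng(9))
        spec = build_spec(1)
        total = log_prior_with_index(p, spec, data.dyads)
        # brute-force: scipy 2x2 MVN densities plus exact hyperprior terms
        cov_gr = np.array([[p.sG**2, p.cGR * p.sG * p.sR],
                           [p.cGR * p.sG * p.sR, p.sR**2]])
        brute = sum(
            stats.multivariate_normal.logpdf([p.G[a], p.R[a]], cov=cov_gr)
            for a in range(4)
        )
        cov_tt = np.array([[p.sT**2, p.cTT * p.sT**2],
                           [p.cTT * p.sT**2, p.sT**2]])
        first, second = data.dyads.first_rows, data.dyads.second_rows
        brute += sum(
            stats.multivariate_normal.logpdf([p.T[i], p.T[j]], cov=cov_tt)
            for i, j in zip(first, second)
        )
        brute += float(stats.norm.logpdf(p.D))
        brute += sum(stats.expon.logpdf(s) for s in (p.sG, p.sR, p.sT))
        brute += _lkj_ref(p.cGR) + _lkj_ref(p.cTT)
        assert total == pytest.approx(brute, abs=1e-9)

    def test_exchangeability_under_direction_swap(self):
        data = tiny_dataset(with_covariates=False)
        p = random_params(data, np.random.default_rng(11))
        spec = build_spec(1)
        before = log_prior_with_index(p, spec, data.dyads)
        T = p.T.copy()
        first, second = data.dyads.first_rows, data.dyads.second_rows
        T[first], T[second] = p.T[second].copy(), p.T[first].copy()
        p_swapped = random_params(data, np.random.default_rng(11))
        p_swapped.T = T
        assert log_prior_with_index(p_swapped, spec, data.dyads) == pytest.approx(before)

    def test_zero_corr_factorises(self):
        data = tiny_dataset(with_covariates=False)
        p = random_params(data, np.random.default_rng(12), cTT=0.0)
        spec = build_spec(1)
        total = log_prior_with_index(p, spec, data.dyads)
        # independent Normal(0, sT) per directed tie
        indep = stats.norm.logpdf(p.T, scale=p.sT).sum()
        cov_tt = np.eye(2) * p.sT**2
        first, second = data.dyads.first_rows, data.dyads.second_rows
        joint = sum(
            stats.multivariate_normal.logpdf([p.T[i], p.T[j]], cov=cov_tt)
            for i, j in zip(first, second)
        )
        assert indep == pytest.approx(joint)
        assert np.isfinite(total)

    def test_out_of_support_is_minus_inf_not_exception(self):
        data = tiny_dataset(with_covariates=False)
        spec = build_spec(1)
        p = random_params(data, np.random.default_rng(13), sG=-1.0)
        assert log_prior_with_index(p, spec, data.dyads) == -np.inf
        p = random_params(data, np.random.default_rng(13), cGR=1.0)
        assert log_prior_with_index(p, spec, data.dyads) == -np.inf


def _lkj_ref(c, shape=2.0):
    from scipy.special import betaln

    return (shape - 1) * np.log1p(-c**2) - ((2 * shape - 1) * np.log(2) + betaln(shape, shape))


class TestBuildSpec:
    def test_variant_structures(self):
        s1 = build_spec(1)
        assert not s1.individual_covariates and not s1.use_offset
        assert s1.fixed_effect_names() == ["D"]
        s3 = build_spec(3)
        assert s3.use_offset and s3.dyadic_covariates == ["relatedness"]
        assert s3.standardize_dyadic and not s3.use_rank_term
        s4 = build_spec(4)
        assert s4.use_rank_term and not s4.standardize_dyadic
        s4n = build_spec(4, rank_term=False)
        assert not s4n.use_rank_term and s4n.dyadic_covariates == ["relatedness"]

    def test_incompatible_options_rejected(self):
        with pytest.raises(ValueError):
            build_spec(1, rank_term=True)
        with pytest.raises(ValueError):
            build_spec(2, relatedness=True)
        with pytest.raises(ValueError):
            ModelSpec(variant=1, use_offset=True)

    def test_yaml_round_trip(self, tmp_path):
        spec = build_spec(4, rank_term=False)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        spec2 = ModelSpec.from_yaml(path)
        assert spec2 == spec


class TestPotentialConsistency:
    """The sampler's density must agree with the declarative model components."""

    @pytest.mark.parametrize("variant", [1, 2, 3, 4])
    def test_eta_matches_linear_predictor(self, variant):
        net = srmkit.simulate(srmkit.ScmConfig(scm_id=variant, seed=3,
                                               n_individuals=8,
                                               group_sizes=(5, 6),
                                               max_kin_groups=(2, 3)))
        spec = build_spec(variant)
        pot = SrmPotential(net.dataset, spec)
        rng = np.random.default_rng(0)
        q = pot.initial_point(rng) + 0.5 * rng.standard_normal(pot.dim)
        params = pot.unpack(q)
        assert np.allclose(pot.eta(q), linear_predictor(params, net.dataset, spec))

    @pytest.mark.parametrize("variant", [1, 4])
    def test_compiled_kernel_matches_reference(self, variant):
        net = srmkit.simulate(srmkit.ScmConfig(scm_id=variant, seed=3))
        pot = SrmPotential(net.dataset, build_spec(variant))
        rng = np.random.default_rng(1)
        for _ in range(5):
            q = pot.initial_point(rng) + 0.5 * rng.standard_normal(pot.dim)
            lp_fast, g_fast = pot.logp_and_grad(q)
            lp_ref, g_ref = pot.logp_and_grad_reference(q)
            assert lp_fast == pytest.approx(lp_ref, rel=1e-10, abs=1e-8)
            assert np.allclose(g_fast, g_ref, rtol=1e-9, atol=1e-8)

    def test_gradient_matches_finite_differences(self):
        net = srmkit.simulate(srmkit.ScmConfig(scm_id=2, seed=3, n_individuals=6))
        pot = SrmPotential(net.dataset, build_spec(2))
        rng = np.random.default_rng(2)
        q = pot.initial_point(rng) + 0.3 * rng.standard_normal(pot.dim)
        _, grad = pot.logp_and_grad(q)
        eps = 1e-6
        for i in rng.choice(pot.dim, size=12, replace=False):
            qp, qm = q.copy(), q.copy()
            qp[i] += eps
            qm[i] -= eps
            fd = (pot.logp_and_grad(qp)[0] - pot.logp_and_grad(qm)[0]) / (2 * eps)
            assert grad[i] == pytest.approx(fd, rel=1e-4, abs=1e-5)
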