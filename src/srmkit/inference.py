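"""Fitting SRM variants by NUTS and packaging posterior draws.

``fit`` draws from the joint posterior with the package's No-U-Turn
sampler (default 4 chains x 2000 kept draws after 1000 warmup
iterations each, i.e. 8000 posterior samples) and returns a
:class:`PosteriorDraws` container holding per-draw values of every
statistical parameter, indexed by chain and iteration. ``diagnose``
computes split R-hat and effective sample sizes for all scalar
parameters (via arviz) and flags chains with R-hat > 1.01 or any
divergent transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from .data import DyadicDataset
from .models import ModelSpec, ParameterSet, design_arrays
from .potential import SrmPotential
from .sampler import nuts

SCALAR_ORDER = ["D", "bG", "bR", "bRe", "bRa1", "bRa2", "sG", "sR", "sT", "cGR", "cTT"]


@dataclass
class PosteriorDraws:
    """Per-draw parameter values with (chain, iteration) indexing."""

    params: dict                      # name -> (chains, draws[, k]) arrays
    seed: int
    spec_snapshot: ModelSpec
    data_fingerprint: str
    divergences_per_chain: list
    sampler_info: dict = field(default_factory=dict)
    design: dict | None = field(default=None, repr=False)

    def __post_init__(self):
        for name in ("sG", "sR", "sT"):
            if np.any(self.params[name] <= 0):
                raise ValueError(f"{name} draws must be positive")
        for name in ("cGR", "cTT"):
            if np.any(np.abs(self.params[name]) >= 1):
                raise ValueError(f"{name} draws must lie in (-1, 1)")

    @property
    def n_chains(self) -> int:
        return self.params["D"].shape[0]

    @property
    def n_draws_per_chain(self) -> int:
        return self.params["D"].shape[1]

    @property
    def n_total_draws(self) -> int:
        return self.n_chains * self.n_draws_per_chain

    @property
    def divergences(self) -> int:
        return int(sum(self.divergences_per_chain))

    def scalar_names(self) -> list:
        return [n for n in SCALAR_ORDER if n in self.params]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter pooled across chains (first axis = draw)."""
        v = self.params[name]
        return v.reshape(-1, *v.shape[2:])

    def summary(self, probs=(0.05, 0.5, 0.95)) -> pd.DataFrame:
        rows = []
        for name in self.scalar_names():
            v = self.stacked(name)
            row = {"parameter": name, "mean": float(v.mean()), "sd": float(v.std())}
            for p in probs:
                row[f"q{int(round(100 * p))}"] = float(np.quantile(v, p))
            rows.append(row)
        return pd.DataFrame(rows)

    def to_dataframe(self) -> pd.DataFrame:
        """Scalar draws as a long table with chain/draw columns."""
        chains, draws = self.n_chains, self.n_draws_per_chain
        out = {
            "chain": np.repeat(np.arange(chains), draws),
            "draw": np.tile(np.arange(draws), chains),
        }
        for name in self.scalar_names():
            out[name] = self.params[name].reshape(-1)
        return pd.DataFrame(out)

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def linear_predictor_draws(self) -> np.ndarray:
        """Per-draw log-rate (eta) for every directed dyad, pooled across chains."""
        if self.design is None:
            raise ValueError("posterior was built without a design snapshot")
        d = self.design
        G = self.stacked("G")
        R = self.stacked("R")
        T = self.stacked("T")
        eta = (
            self.stacked("D")[:, None]
            + G[:, d["g_pos"]]
            + R[:, d["r_pos"]]
            + T
            + d["offset"][None, :]
        )
        for name, key in (("bG", "x_giver"), ("bR", "x_receiver"),
                          ("bRe", "relatedness"), ("bRa1", "rank_up"),
                          ("bRa2", "rank_down")):
            if name in self.params and key in d:
                eta = eta + self.stacked(name)[:, None] * d[key][None, :]
        return eta

    def parameter_set(self, draw: int) -> ParameterSet:
        """The full ParameterSet of one pooled draw index."""
        kw = {}
        for name in self.scalar_names():
            kw[name] = float(self.stacked(name)[draw])
        return ParameterSet(
            G=self.stacked("G")[draw], R=self.stacked("R")[draw],
            T=self.stacked("T")[draw], **kw,
        )


def fit(
    spec: ModelSpec,
    data: DyadicDataset,
    chains: int = 4,
    iterations: int = 2000,
    seed: int = 0,
    warmup: int = 1000,
    max_depth: int = 9,
    target_accept: float = 0.87,
    fixed_sds: float | None = None,
) -> PosteriorDraws:
    """Draw from the joint posterior of ``spec`` given ``data``.

    ``iterations`` is the number of post-warmup draws kept per chain;
    the default 4 x 2000 gives 8000 posterior samples. ``fixed_sds``
    clamps all varying-effect SDs at a constant (diagnostic use: a tiny
    value reduces the model to a Poisson GLM in the fixed effects).
    """
    pot = SrmPotential(data, spec, fixed_sds=fixed_sds)
    seeds = np.random.SeedSequence(seed).spawn(chains)
    chain_results = []
    for c in range(chains):
        rng = np.random.default_rng(seeds[c])
        q0 = pot.initial_point(rng)
        logp0, _ = pot.logp_and_grad(q0)
        if not np.isfinite(logp0):
            raise ValueError(
                "non-finite log density at the initial point; "
                "check covariates and counts for non-finite values"
            )
        chain_results.append(
            nuts(pot.logp_and_grad, q0, warmup, iterations, rng,
                 max_depth=max_depth, target_accept=target_accept)
        )
    params = _collect(pot, chain_results, fixed_sds)
    cols = design_arrays(data, spec)
    return PosteriorDraws(
        params=params,
        seed=seed,
        spec_snapshot=spec,
        data_fingerprint=data.fingerprint(),
        divergences_per_chain=[r.divergences for r in chain_results],
        sampler_info={
            "step_sizes": [r.step_size for r in chain_results],
            "accept_rates": [r.accept_rate for r in chain_results],
            "mean_tree_depth": float(np.mean([r.tree_depths.mean() for r in chain_results])),
            "warmup": warmup,
        },
        design=cols,
    )


def _collect(pot: SrmPotential, chain_results, fixed_sds) -> dict:
    chains = len(chain_results)
    draws = chain_results[0].draws.shape[0]
    names = ["D"] + pot.slope_names + ["sG", "sR", "sT", "cGR", "cTT"]
    params = {n: np.empty((chains, draws)) for n in names}
    params["G"] = np.empty((chains, draws, pot.n))
    params["R"] = np.empty((chains, draws, pot.n))
    params["T"] = np.empty((chains, draws, pot.n_dyads))
    for c, res in enumerate(chain_results):
        Q = res.draws
        params["D"][c] = Q[:, pot.i_d]
        for j, name in enumerate(pot.slope_names):
            params[name][c] = Q[:, pot.i_slopes][:, j]
        if fixed_sds is None:
            ls = Q[:, pot.i_ls]
            params["sG"][c], params["sR"][c], params["sT"][c] = np.exp(ls).T
            u = Q[:, pot.i_u]
            params["cGR"][c], params["cTT"][c] = np.tanh(u).T
        else:
            s = float(fixed_sds)
            params["sG"][c] = params["sR"][c] = params["sT"][c] = s
            params["cGR"][c] = params["cTT"][c] = 0.0
        zG = Q[:, pot.i_zg]
        zR = Q[:, pot.i_zr]
        z1 = Q[:, pot.i_z1]
        z2 = Q[:, pot.i_z2]
        sG = params["sG"][c][:, None]
        sR = params["sR"][c][:, None]
        sT = params["sT"][c][:, None]
        cGR = params["cGR"][c][:, None]
        cTT = params["cTT"][c][:, None]
        params["G"][c] = sG * zG
        params["R"][c] = sR * (cGR * zG + np.sqrt(1 - cGR**2) * zR)
        T = np.empty((draws, pot.n_dyads))
        T[:, pot.first] = sT * z1
        T[:, pot.second] = sT * (cTT * z1 + np.sqrt(1 - cTT**2) * z2)
        params["T"][c] = T
    return params


@dataclass
class DiagnosticsReport:
    """Split R-hat, ESS, and divergence flags for the scalar parameters."""

    table: pd.DataFrame          # parameter, rhat, ess_bulk
    divergences: int
    rhat_threshold: float
    passed: bool
    notes: str = ""

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [
            f"MCMC diagnostics: {status} "
            f"(divergences={self.divergences}, R-hat threshold {self.rhat_threshold})",
        ]
        if self.notes:
            lines.append(self.notes)
        lines.append(self.table.to_string(index=False))
        return "\n".join(lines)


def diagnose(posterior: PosteriorDraws, rhat_threshold: float = 1.01) -> DiagnosticsReport:
    """Convergence diagnostics for every scalar parameter of a fit."""
    names = posterior.scalar_names()
    data = {n: posterior.params[n] for n in names}
    idata = az.from_dict(posterior=data)
    single_chain = posterior.n_chains < 2
    rows = []
    if single_chain:
        ess = az.ess(idata)
        for n in names:
            rows.append({"parameter": n, "rhat": np.nan, "ess_bulk": float(ess[n])})
        notes = "single chain: split R-hat is undefined and reported as NaN"
        rhat_ok = False
    else:
        rhat = az.rhat(idata)
        ess = az.ess(idata)
        for n in names:
            rows.append(
                {"parameter": n, "rhat": float(rhat[n]), "ess_bulk": float(ess[n])}
            )
        notes = ""
        rhat_ok = all(np.isfinite(r["rhat"]) and r["rhat"] <= rhat_threshold for r in rows)
    table = pd.DataFrame(rows)
    passed = rhat_ok and posterior.divergences == 0
    return DiagnosticsReport(
        table=table,
        divergences=posterior.divergences,
        rhat_threshold=rhat_threshold,
        passed=passed,
        notes=notes,
    )


def diagnose_arrays(draws_by_name: dict, divergences: int = 0,
                    rhat_threshold: float = 1.01) -> DiagnosticsReport:
    """Diagnostics for raw (chains, draws) arrays, without a full fit."""
    idata = az.from_dict(posterior=draws_by_name)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    rows = [
        {"parameter": n, "rhat": float(rhat[n]), "ess_bulk": float(ess[n])}
        for n in draws_by_name
    ]
    table = pd.DataFrame(rows)
    passed = (
        all(r["rhat"] <= rhat_threshold for r in rows) and divergences == 0
    )
    return DiagnosticsReport(table, divergences, rhat_threshold, passed)
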