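"""Structural causal simulators of directed dyadic count networks.

Four seeded generative models produce :class:`~srmkit.data.SimulatedNetwork`
objects with known ground truth:

1. Random structuring features: giving (gamma), receiving (rho) and tie
   (tau) latents are independent Normal(0, 0.5); the true rate is
   ``m[a,b] = exp(0.2 + gamma[a] + rho[b] + tau[a,b])`` and counts are
   Poisson.
2. An individual covariate X ~ Normal(0, 1) shifts both giving and
   receiving latents (default effect -0.7 on each).
3. Dyad-level features: binary kinship (standardized before entering
   the tie latent, default effect 0.8 per SD) and a log sampling-effort
   exposure, with intercept -1.2. Default design: 20 individuals, one
   kin group of 10 plus 10 singleton kin groups.
4. Kinship confounded by matriline-stratified dominance rank: three
   social groups of 10/15/20 individuals with at most 3/5/7 kin groups,
   raw binary relatedness (effect 0.6), and an asymmetric rank-difference
   effect (0.8 when the giver outranks the receiver, 0 otherwise).

Each simulator is a deterministic function of its config and seed.
A ``zero_noise`` flag sets the latent SDs to 0 so that the deterministic
worked-example rates can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    DyadicDataset,
    Roster,
    SimulatedNetwork,
    build_dyad_index,
    derive_dyadic_effort,
    derive_relatedness,
    standardize,
)

__all__ = [
    "ScmConfig",
    "assemble_rate",
    "sample_counts",
    "dyadic_effort",
    "relatedness_indicator",
    "assign_ranks_scm4",
    "rank_difference_term",
    "simulate_scm1",
    "simulate_scm2",
    "simulate_scm3",
    "simulate_scm4",
    "simulate",
]


@dataclass
class ScmConfig:
    """Configuration of one structural causal model.

    Defaults are the canonical study conditions; only fields meaningful
    for the chosen ``scm_id`` may be overridden.
    """

    scm_id: int
    n_individuals: int = 20
    effect_x_on_gamma: float = -0.7
    effect_x_on_rho: float = -0.7
    effect_relatedness: float | None = None
    effect_rank: float = 0.8
    intercept: float | None = None
    latent_sd: float = 0.5
    group_sizes: tuple = (10, 15, 20)
    max_kin_groups: tuple = (3, 5, 7)
    kin_design: tuple | None = None
    effort_low: float = 1.0
    effort_high: float = 2.5
    zero_noise: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.scm_id not in (1, 2, 3, 4):
            raise ValueError("scm_id must be one of 1, 2, 3, 4")
        if self.latent_sd <= 0 and not self.zero_noise:
            raise ValueError("latent_sd must be positive")
        if self.intercept is None:
            self.intercept = 0.2 if self.scm_id in (1, 2) else -1.2
        if self.effect_relatedness is None:
            self.effect_relatedness = {3: 0.8, 4: 0.6}.get(self.scm_id, 0.0)
        if self.n_individuals < 3:
            raise ValueError("need at least 3 individuals")
        if self.scm_id != 4 and self.effect_rank != 0.8:
            raise ValueError("effect_rank is only meaningful for scm_id=4")

    @property
    def sd(self) -> float:
        return 0.0 if self.zero_noise else self.latent_sd


def assemble_rate(intercept, gamma, rho, tau):
    """True interaction rate exp(intercept + gamma + rho + tau); always > 0."""
    parts = np.broadcast_arrays(
        *(np.asarray(v, dtype=float) for v in (intercept, gamma, rho, tau))
    )
    total = parts[0] + parts[1] + parts[2] + parts[3]
    if not np.all(np.isfinite(total)):
        raise ValueError("non-finite input to assemble_rate")
    out = np.exp(total)
    return float(out) if out.ndim == 0 else out


def sample_counts(rate_m, seed) -> np.ndarray:
    """Independent Poisson observation of the true rates, reproducible by seed."""
    rate = np.asarray(rate_m, dtype=float)
    if np.any(~np.isfinite(rate)) or np.any(rate < 0):
        raise ValueError("Poisson rates must be finite and nonnegative")
    rng = _as_rng(seed)
    return rng.poisson(rate)


def dyadic_effort(s_a, s_b):
    """Dyad-level sampling effort S|a,b| = S[a] + S[b]; symmetric."""
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if np.any(s_a <= 0) or np.any(s_b <= 0):
        raise ValueError("sampling efforts must be positive")
    out = s_a + s_b
    return float(out) if out.ndim == 0 else out


def relatedness_indicator(k_a, k_b):
    """1 if the two kin-group labels are equal, else 0; symmetric."""
    out = (np.asarray(k_a) == np.asarray(k_b)).astype(int)
    return int(out) if out.ndim == 0 else out


def rank_difference_term(ra_a, ra_b, coef):
    """Asymmetric rank effect: coef * (Ra[b] - Ra[a]) when Ra[a] < Ra[b], else 0.

    Lower rank value means higher dominance, so the term is active when
    the giver outranks the receiver.
    """
    ra_a = np.asarray(ra_a, dtype=float)
    ra_b = np.asarray(ra_b, dtype=float)
    out = np.where(ra_a < ra_b, coef * (ra_b - ra_a), 0.0)
    return float(out) if out.ndim == 0 else out


def assign_ranks_scm4(kin_groups, seed) -> np.ndarray:
    """Matriline-stratified ranks on (0, 1] within one social group.

    All members of a lower-labelled kin group outrank all members of
    higher-labelled ones; within a kin group the order is uniformly
    random under the seed. Ordinal positions are rescaled by group size,
    so rank 1/n is the most dominant individual and 1 the least.
    """
    k = np.asarray(kin_groups)
    n = len(k)
    if n == 0:
        raise ValueError("empty group")
    rng = _as_rng(seed)
    order = []
    for label in np.sort(np.unique(k)):
        members = np.flatnonzero(k == label)
        order.extend(rng.permutation(members))
    ranks = np.empty(n, dtype=float)
    ranks[np.asarray(order)] = np.arange(1, n + 1) / n
    return ranks


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _streams(seed, n):
    """Deterministic child generators for the independent noise sources."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _single_group_roster(n, **columns) -> Roster:
    base = {
        "id": np.arange(1, n + 1),
        "group": np.ones(n, dtype=int),
        "kin_group": np.nan,
        "x": np.nan,
        "rank": np.nan,
        "effort": np.nan,
    }
    base.update(columns)
    return Roster(pd.DataFrame(base))


def _finish(config, roster, extra_tau, truth, rngs) -> SimulatedNetwork:
    """Shared tail of all four simulators: latents, rates, Poisson counts."""
    dyads = build_dyad_index(roster)
    n, nd = roster.n, dyads.n_directed
    sd = config.sd
    rng_g, rng_r, rng_t, rng_y = rngs
    gamma = truth.pop("_gamma_mean", np.zeros(n)) + rng_g.normal(0.0, sd, size=n)
    rho = truth.pop("_rho_mean", np.zeros(n)) + rng_r.normal(0.0, sd, size=n)
    tau = extra_tau + rng_t.normal(0.0, sd, size=nd)
    g_pos, r_pos = dyads.giver - 1, dyads.receiver - 1
    rate = assemble_rate(config.intercept, gamma[g_pos], rho[r_pos], tau)
    counts = sample_counts(rate, rng_y)
    dataset = DyadicDataset(
        roster,
        dyads,
        counts,
        relatedness=truth.pop("_relatedness", None),
        dyadic_effort=truth.pop("_dyadic_effort", None),
    )
    return SimulatedNetwork(dataset, gamma, rho, tau, rate, truth, config.seed)


def simulate_scm1(config: ScmConfig) -> SimulatedNetwork:
    """Random structuring features: independent Gaussian latents, Poisson counts."""
    rngs = _streams(config.seed, 4)
    roster = _single_group_roster(config.n_individuals)
    truth = {
        "intercept": config.intercept,
        "sd_gamma": config.sd,
        "sd_rho": config.sd,
        "sd_tau": config.sd,
    }
    nd = config.n_individuals * (config.n_individuals - 1)
    return _finish(config, roster, np.zeros(nd), truth, rngs)


def simulate_scm2(config: ScmConfig) -> SimulatedNetwork:
    """An individual covariate X shifts both the giving and receiving latents."""
    rng_x, rng_g, rng_r, rng_t, rng_y = _streams(config.seed, 5)
    n = config.n_individuals
    x = rng_x.normal(0.0, 1.0, size=n)
    roster = _single_group_roster(n, x=x)
    truth = {
        "intercept": config.intercept,
        "sd_gamma": config.sd,
        "sd_rho": config.sd,
        "sd_tau": config.sd,
        "effect_x_on_gamma": config.effect_x_on_gamma,
        "effect_x_on_rho": config.effect_x_on_rho,
        "_gamma_mean": config.effect_x_on_gamma * x,
        "_rho_mean": config.effect_x_on_rho * x,
    }
    return _finish(config, roster, np.zeros(n * (n - 1)), truth, (rng_g, rng_r, rng_t, rng_y))


def _default_kin_design_scm3(n):
    """One kin group holding half the individuals; the rest are singletons."""
    half = n // 2
    return np.concatenate([np.ones(half, dtype=int), np.arange(2, n - half + 2)])


def simulate_scm3(config: ScmConfig) -> SimulatedNetwork:
    """Dyad-level kinship (standardized) plus a log sampling-effort exposure.

    The fixed default design has 20 individuals in 11 kin groups: 10 in
    kin group 1 and the remaining 10 each alone.
    """
    rng_s, rng_g, rng_r, rng_t, rng_y = _streams(config.seed, 5)
    n = config.n_individuals
    kin = (
        np.asarray(config.kin_design)
        if config.kin_design is not None
        else _default_kin_design_scm3(n)
    )
    if len(kin) != n:
        raise ValueError("kin_design length must match n_individuals")
    effort = rng_s.uniform(config.effort_low, config.effort_high, size=n)
    roster = _single_group_roster(n, kin_group=kin, effort=effort)
    dyads = build_dyad_index(roster)
    re_raw = derive_relatedness(roster, dyads)
    re_std_unordered = standardize(re_raw[dyads.first_rows], "relatedness")
    re_std = np.empty(dyads.n_directed)
    re_std[dyads.first_rows] = re_std_unordered
    re_std[dyads.second_rows] = re_std_unordered
    s_ab = derive_dyadic_effort(roster, dyads)
    extra_tau = np.log(s_ab) + config.effect_relatedness * re_std
    truth = {
        "intercept": config.intercept,
        "sd_gamma": config.sd,
        "sd_rho": config.sd,
        "sd_tau": config.sd,
        "effect_relatedness": config.effect_relatedness,
        "_relatedness": re_raw,
        "_dyadic_effort": s_ab,
    }
    return _finish(config, roster, extra_tau, truth, (rng_g, rng_r, rng_t, rng_y))


def simulate_scm4(config: ScmConfig) -> SimulatedNetwork:
    """Kinship confounded by matriline-stratified rank, across three groups.

    Kin labels are drawn with replacement from {1..NK_g} per group (so
    smaller groups, with fewer kin groups, are more related on average);
    ranks are stratified by kin group and the rank effect is asymmetric.
    """
    rng_k, rng_rank, rng_s, rng_g, rng_r, rng_t, rng_y = _streams(config.seed, 7)
    sizes = tuple(config.group_sizes)
    nks = tuple(config.max_kin_groups)
    if len(sizes) != len(nks):
        raise ValueError("group_sizes and max_kin_groups must align")
    n = sum(sizes)
    group = np.concatenate([np.full(s, g + 1, dtype=int) for g, s in enumerate(sizes)])
    kin = np.concatenate(
        [rng_k.integers(1, nk + 1, size=s) for s, nk in zip(sizes, nks)]
    )
    rank = np.empty(n)
    start = 0
    for s in sizes:
        rank[start : start + s] = assign_ranks_scm4(kin[start : start + s], rng_rank)
        start += s
    effort = rng_s.uniform(config.effort_low, config.effort_high, size=n)
    roster = Roster(
        pd.DataFrame(
            {
                "id": np.arange(1, n + 1),
                "group": group,
                "kin_group": kin,
                "x": np.nan,
                "rank": rank,
                "effort": effort,
            }
        )
    )
    dyads = build_dyad_index(roster)
    re = derive_relatedness(roster, dyads)
    s_ab = derive_dyadic_effort(roster, dyads)
    g_pos, r_pos = dyads.giver - 1, dyads.receiver - 1
    rank_term = rank_difference_term(rank[g_pos], rank[r_pos], config.effect_rank)
    extra_tau = np.log(s_ab) + config.effect_relatedness * re + rank_term
    truth = {
        "intercept": config.intercept,
        "sd_gamma": config.sd,
        "sd_rho": config.sd,
        "sd_tau": config.sd,
        "effect_relatedness": config.effect_relatedness,
        "effect_rank_dominant_giver": config.effect_rank,
        "effect_rank_subordinate_giver": 0.0,
        "_relatedness": re,
        "_dyadic_effort": s_ab,
    }
    return _finish(config, roster, extra_tau, truth, (rng_g, rng_r, rng_t, rng_y))


_SIMULATORS = {1: simulate_scm1, 2: simulate_scm2, 3: simulate_scm3, 4: simulate_scm4}


def simulate(config: ScmConfig) -> SimulatedNetwork:
    """Dispatch to the simulator selected by ``config.scm_id``."""
    return _SIMULATORS[config.scm_id](config)


def export_truth(network: SimulatedNetwork, out_dir) -> None:
    """Write truth and latent CSVs next to the dataset files."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"parameter": list(network.truth), "value": list(network.truth.values())}
    ).to_csv(out / "truth.csv", index=False)
    pd.DataFrame({"id": network.dataset.roster.ids, "gamma": network.gamma, "rho": network.rho}).to_csv(
        out / "latents_individual.csv", index=False
    )
    d = network.dataset.dyads
    pd.DataFrame(
        {"giver": d.giver, "receiver": d.receiver, "tau": network.tau, "rate": network.rate_m}
    ).to_csv(out / "latents_dyadic.csv", index=False)
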