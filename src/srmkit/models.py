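"""Declarative specification and log-density components of the SRM variants.

The Social Relations Model (SRM) decomposes a directed dyadic count
``y[a,b] ~ Poisson(m[a,b])`` on the log scale into an intercept ``D``,
giver effects ``G[a]``, receiver effects ``R[b]`` and directed tie
effects ``T[a,b]``:

    log m[a,b] = D + G[a] + R[b] + T[a,b] + covariate terms + offset

``(G[a], R[a])`` are jointly multivariate normal with SDs ``sG, sR`` and
generalized-reciprocity correlation ``cGR``; ``(T[a,b], T[b,a])`` share a
single SD ``sT`` and dyadic-reciprocity correlation ``cTT`` (the
exchangeable structure: the labels a, b are arbitrary, so both
directions must have the same variance).

Four estimator variants are supported, mirroring the generative models
in :mod:`srmkit.scm`:

1. intercept-only (the non-adjusted SRM);
2. an individual covariate x entering the giver and receiver submodels
   with slopes ``bG`` and ``bR``;
3. a log sampling-effort offset plus standardized binary relatedness
   with dyadic slope ``bRe``;
4. offset, raw binary relatedness, and a piecewise rank-difference term
   with slopes ``bRa1`` (giver outranks receiver) and ``bRa2`` (otherwise).

Dropping a term (e.g. variant 4 without the rank adjustment) yields the
deliberately mis-specified comparators used to demonstrate confounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy import special, stats

from .data import DyadicDataset, standardize

FIXED_EFFECTS = {
    1: ["D"],
    2: ["D", "bG", "bR"],
    3: ["D", "bRe"],
    4: ["D", "bRe", "bRa1", "bRa2"],
}
HYPERS = ["sG", "sR", "sT", "cGR", "cTT"]

DEFAULT_PRIORS = {
    "intercept": {"dist": "normal", "loc": 0.0, "scale": 1.0},
    "slope": {"dist": "normal", "loc": 0.0, "scale": 1.0},
    "sd": {"dist": "exponential", "rate": 1.0},
    "correlation": {"dist": "lkj", "shape": 2.0},
}


@dataclass
class ModelSpec:
    """Declarative description of one SRM estimator variant."""

    variant: int
    individual_covariates: list = field(default_factory=list)
    dyadic_covariates: list = field(default_factory=list)
    use_offset: bool = False
    use_rank_term: bool = False
    standardize_dyadic: bool = False
    prior_config: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PRIORS.items()})

    def __post_init__(self):
        if self.variant not in (1, 2, 3, 4):
            raise ValueError("variant must be one of 1, 2, 3, 4")
        if self.use_rank_term and self.variant != 4:
            raise ValueError("the rank term belongs to variant 4 only")
        if self.variant == 1 and (
            self.individual_covariates or self.dyadic_covariates or self.use_offset
        ):
            raise ValueError("variant 1 has no covariates or offset")

    def fixed_effect_names(self) -> list:
        names = ["D"]
        if self.individual_covariates:
            names += ["bG", "bR"]
        if self.dyadic_covariates:
            names += ["bRe"]
        if self.use_rank_term:
            names += ["bRa1", "bRa2"]
        return names

    def parameter_names(self) -> list:
        return self.fixed_effect_names() + HYPERS

    def to_yaml(self, path) -> None:
        payload = {
            "variant": self.variant,
            "individual_covariates": list(self.individual_covariates),
            "dyadic_covariates": list(self.dyadic_covariates),
            "use_offset": self.use_offset,
            "use_rank_term": self.use_rank_term,
            "standardize_dyadic": self.standardize_dyadic,
            "prior_config": self.prior_config,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ModelSpec":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh)
        return cls(**payload)


def build_spec(
    variant: int,
    rank_term: bool | None = None,
    relatedness: bool | None = None,
    individual_covariate: bool | None = None,
    prior_config: dict | None = None,
) -> ModelSpec:
    """Construct the canonical spec for a variant, or a mis-specified comparator.

    ``build_spec(4, rank_term=False)`` is the non-adjusted estimator that
    leaves the rank backdoor open; ``build_spec(3, relatedness=False)``
    keeps only the offset.
    """
    if variant not in (1, 2, 3, 4):
        raise ValueError("variant must be one of 1, 2, 3, 4")
    if rank_term and variant != 4:
        raise ValueError("the rank term is incompatible with variants 1-3")
    if relatedness and variant in (1, 2):
        raise ValueError("the relatedness covariate belongs to variants 3-4")
    if individual_covariate and variant != 2:
        raise ValueError("the individual covariate belongs to variant 2")
    kwargs = dict(variant=variant)
    if variant == 2:
        use_x = True if individual_covariate is None else individual_covariate
        kwargs["individual_covariates"] = ["x"] if use_x else []
    if variant in (3, 4):
        kwargs["use_offset"] = True
        use_re = True if relatedness is None else relatedness
        kwargs["dyadic_covariates"] = ["relatedness"] if use_re else []
        kwargs["standardize_dyadic"] = variant == 3
    if variant == 4:
        kwargs["use_rank_term"] = True if rank_term is None else rank_term
    if prior_config is not None:
        merged = {k: dict(v) for k, v in DEFAULT_PRIORS.items()}
        merged.update(prior_config)
        kwargs["prior_config"] = merged
    return ModelSpec(**kwargs)


@dataclass
class ParameterSet:
    """One full set of SRM parameter values (e.g. a posterior draw)."""

    D: float
    G: np.ndarray
    R: np.ndarray
    T: np.ndarray
    sG: float
    sR: float
    sT: float
    cGR: float
    cTT: float
    bG: float = 0.0
    bR: float = 0.0
    bRe: float = 0.0
    bRa1: float = 0.0
    bRa2: float = 0.0


def design_arrays(data: DyadicDataset, spec: ModelSpec) -> dict:
    """Covariate/offset columns of the linear predictor, per directed dyad.

    Shared by the reference densities here and the MCMC potential, so a
    single definition governs what each variant conditions on. Raises a
    named error when the data lack a covariate the variant requires.
    """
    d = data.dyads
    g_pos, r_pos = data.giver_pos(), data.receiver_pos()
    out = {"g_pos": g_pos, "r_pos": r_pos, "n": data.roster.n, "n_dyads": d.n_directed}
    out["offset"] = np.zeros(d.n_directed)
    if spec.use_offset:
        if data.dyadic_effort is None:
            raise ValueError("variant requires dyadic sampling effort, missing from data")
        out["offset"] = np.log(data.dyadic_effort)
    if spec.individual_covariates:
        x = data.roster.x
        if np.any(np.isnan(x)):
            raise ValueError("variant requires individual covariate 'x', missing from data")
        out["x_giver"] = x[g_pos]
        out["x_receiver"] = x[r_pos]
    if spec.dyadic_covariates:
        if data.relatedness is None:
            raise ValueError("variant requires dyadic covariate 'relatedness', missing from data")
        re = data.relatedness.astype(float)
        if spec.standardize_dyadic:
            re_u = standardize(re[d.first_rows], "relatedness")
            re = np.empty(d.n_directed)
            re[d.first_rows] = re_u
            re[d.second_rows] = re_u
        out["relatedness"] = re
    if spec.use_rank_term:
        rank = data.roster.rank
        if np.any(np.isnan(rank)):
            raise ValueError("variant requires individual ranks, missing from data")
        delta = rank[r_pos] - rank[g_pos]
        out["rank_up"] = np.where(delta > 0, delta, 0.0)
        out["rank_down"] = np.where(delta <= 0, delta, 0.0)
    return out


def linear_predictor(params: ParameterSet, data: DyadicDataset, spec: ModelSpec) -> np.ndarray:
    """log m[a,b] per directed dyad for the given parameter values."""
    cols = design_arrays(data, spec)
    eta = (
        params.D
        + np.asarray(params.G)[cols["g_pos"]]
        + np.asarray(params.R)[cols["r_pos"]]
        + np.asarray(params.T)
        + cols["offset"]
    )
    if spec.individual_covariates:
        eta = eta + params.bG * cols["x_giver"] + params.bR * cols["x_receiver"]
    if spec.dyadic_covariates:
        eta = eta + params.bRe * cols["relatedness"]
    if spec.use_rank_term:
        eta = eta + params.bRa1 * cols["rank_up"] + params.bRa2 * cols["rank_down"]
    return eta


def log_likelihood(params: ParameterSet, data: DyadicDataset, spec: ModelSpec) -> float:
    """Poisson log likelihood of the observed counts at m = exp(linear predictor)."""
    y = np.asarray(data.counts)
    if not np.issubdtype(y.dtype, np.integer):
        raise ValueError("counts must be integers")
    eta = linear_predictor(params, data, spec)
    return float(stats.poisson.logpmf(y, np.exp(eta)).sum())


def _bivariate_normal_logpdf(u, v, s1, s2, c) -> float:
    """Sum of centred bivariate normal log densities over paired vectors."""
    u, v = np.asarray(u, float), np.asarray(v, float)
    det = (s1 * s2) ** 2 * (1 - c**2)
    q = (
        (u / s1) ** 2 - 2 * c * (u / s1) * (v / s2) + (v / s2) ** 2
    ) / (1 - c**2)
    return float(np.sum(-np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * q))


def _lkj_2x2_logpdf(c: float, shape: float) -> float:
    """Exact density of the single correlation of a 2x2 LKJ(shape) matrix.

    c ~ 2 Beta(shape, shape) - 1, i.e. p(c) = (1-c^2)^(shape-1) / Z with
    Z = 2^(2 shape - 1) B(shape, shape).
    """
    log_z = (2 * shape - 1) * np.log(2.0) + special.betaln(shape, shape)
    return float((shape - 1) * np.log1p(-c**2) - log_z)


def log_prior(params: ParameterSet, spec: ModelSpec) -> float:
    """Log prior: hyperpriors plus both multivariate-normal varying-effect layers.

    Out-of-support values (SDs <= 0, |correlation| >= 1) yield -inf
    rather than an exception, so samplers can reject them.
    """
    p = spec.prior_config
    if params.sG <= 0 or params.sR <= 0 or params.sT <= 0:
        return -np.inf
    if abs(params.cGR) >= 1 or abs(params.cTT) >= 1:
        return -np.inf
    total = stats.norm.logpdf(params.D, p["intercept"]["loc"], p["intercept"]["scale"])
    slope_names = [n for n in spec.fixed_effect_names() if n != "D"]
    for name in slope_names:
        total += stats.norm.logpdf(
            getattr(params, name), p["slope"]["loc"], p["slope"]["scale"]
        )
    rate = p["sd"]["rate"]
    for s in (params.sG, params.sR, params.sT):
        total += np.log(rate) - rate * s
    shape = p["correlation"]["shape"]
    total += _lkj_2x2_logpdf(params.cGR, shape) + _lkj_2x2_logpdf(params.cTT, shape)
    # individual layer: (G[a], R[a]) pairs
    total += _bivariate_normal_logpdf(params.G, params.R, params.sG, params.sR, params.cGR)
    # dyadic layer: (T[a,b], T[b,a]) pairs, single variance (exchangeable)
    T = np.asarray(params.T)
    n_dir = len(T)
    # pair up directions: caller supplies T aligned with a dyad index when
    # available; for standalone use we require an explicit pairing.
    pairing = getattr(params, "_dyad_pairing", None)
    if pairing is not None:
        first, second = pairing
    else:
        first = np.arange(0, n_dir, 2)
        second = np.arange(1, n_dir, 2)
    total += _bivariate_normal_logpdf(T[first], T[second], params.sT, params.sT, params.cTT)
    return float(total)


def log_prior_with_index(params: ParameterSet, spec: ModelSpec, dyads) -> float:
    """log_prior with the (T[a,b], T[b,a]) pairing taken from a dyad index."""
    params._dyad_pairing = (dyads.first_rows, dyads.second_rows)
    try:
        return log_prior(params, spec)
    finally:
        del params._dyad_pairing
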