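"""Unconstrained log posterior and analytic gradient of the SRM variants.

The sampler works on an unconstrained vector ``q`` containing, in order:
the intercept, the variant's slopes, log varying-effect SDs, atanh-type
(tanh-transformed) correlations, and the non-centred standard-normal
innovations of the giver/receiver and tie layers. The non-centred
parameterisation (G = sG * zG, etc.) keeps the geometry of the
hierarchical scales benign for gradient-based MCMC.

Transforms and their Jacobians:

* sG = exp(lsG) with Exponential(rate) prior -> log density
  ``-rate * sG + lsG`` (constant dropped);
* cGR = tanh(uGR) with LKJ(shape) prior on the 2x2 correlation ->
  ``shape * log(1 - c^2)`` (the shape-1 prior exponent plus one power
  from the tanh Jacobian);
* (G[a], R[a]) = (sG zG[a], sR (c zG[a] + sqrt(1-c^2) zR[a]));
* (T[a,b], T[b,a]) likewise from (z1, z2) with scale sT and corr cTT.

The Poisson likelihood enters as ``sum(y * eta - exp(eta))``.
"""

from __future__ import annotations

import numpy as np

from .data import DyadicDataset
from .models import ModelSpec, ParameterSet, design_arrays

try:  # compiled fast path; the numpy implementation remains the reference
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap

_COV_KEYS = {"bG": "x_giver", "bR": "x_receiver", "bRe": "relatedness",
             "bRa1": "rank_up", "bRa2": "rank_down"}


class SrmPotential:
    """Log posterior density and gradient on the unconstrained scale."""

    def __init__(self, data: DyadicDataset, spec: ModelSpec, fixed_sds: float | None = None):
        self.spec = spec
        self.fixed_sds = fixed_sds
        cols = design_arrays(data, spec)
        self.n = cols["n"]
        self.n_dyads = cols["n_dyads"]
        self.y = np.ascontiguousarray(data.counts, dtype=np.float64)
        self.g_pos = np.ascontiguousarray(cols["g_pos"], dtype=np.int64)
        self.r_pos = np.ascontiguousarray(cols["r_pos"], dtype=np.int64)
        self.offset = np.ascontiguousarray(cols["offset"], dtype=np.float64)
        self.first = np.ascontiguousarray(data.dyads.first_rows, dtype=np.int64)
        self.second = np.ascontiguousarray(data.dyads.second_rows, dtype=np.int64)
        self.n_un = len(self.first)
        self.slope_names = [n for n in spec.fixed_effect_names() if n != "D"]
        self.covs = np.ascontiguousarray(
            np.array([cols[_COV_KEYS[name]] for name in self.slope_names],
                     dtype=np.float64).reshape(len(self.slope_names), self.n_dyads)
        )
        p = spec.prior_config
        self.d_loc, self.d_scale = p["intercept"]["loc"], p["intercept"]["scale"]
        self.b_loc, self.b_scale = p["slope"]["loc"], p["slope"]["scale"]
        self.sd_rate = p["sd"]["rate"]
        self.lkj_shape = p["correlation"]["shape"]
        # index layout
        k = 0
        self.i_d = k; k += 1
        self.i_slopes = slice(k, k + len(self.slope_names)); k += len(self.slope_names)
        if fixed_sds is None:
            self.i_ls = slice(k, k + 3); k += 3
            self.i_u = slice(k, k + 2); k += 2
        else:
            self.i_ls = None
            self.i_u = None
        self.i_zg = slice(k, k + self.n); k += self.n
        self.i_zr = slice(k, k + self.n); k += self.n
        self.i_z1 = slice(k, k + self.n_un); k += self.n_un
        self.i_z2 = slice(k, k + self.n_un); k += self.n_un
        self.dim = k

    # -- transforms ---------------------------------------------------------

    def _scales_corrs(self, q):
        if self.fixed_sds is not None:
            s = float(self.fixed_sds)
            return s, s, s, 0.0, 0.0
        lsG, lsR, lsT = q[self.i_ls]
        uGR, uTT = q[self.i_u]
        return np.exp(lsG), np.exp(lsR), np.exp(lsT), np.tanh(uGR), np.tanh(uTT)

    def _latents(self, q):
        sG, sR, sT, cGR, cTT = self._scales_corrs(q)
        zG, zR = q[self.i_zg], q[self.i_zr]
        z1, z2 = q[self.i_z1], q[self.i_z2]
        qq = np.sqrt(1.0 - cGR**2)
        qt = np.sqrt(1.0 - cTT**2)
        G = sG * zG
        R = sR * (cGR * zG + qq * zR)
        T = np.empty(self.n_dyads)
        T[self.first] = sT * z1
        T[self.second] = sT * (cTT * z1 + qt * z2)
        return (sG, sR, sT, cGR, cTT, qq, qt, zG, zR, z1, z2, G, R, T)

    def eta(self, q) -> np.ndarray:
        """Linear predictor per directed dyad at unconstrained point q."""
        (*_, G, R, T) = self._latents(q)
        eta = q[self.i_d] + G[self.g_pos] + R[self.r_pos] + T + self.offset
        if self.slope_names:
            eta = eta + q[self.i_slopes] @ self.covs
        return eta

    def unpack(self, q) -> ParameterSet:
        """Constrained parameter values at unconstrained point q."""
        sG, sR, sT, cGR, cTT, qq, qt, zG, zR, z1, z2, G, R, T = self._latents(q)
        kwargs = dict(zip(self.slope_names, np.atleast_1d(q[self.i_slopes])))
        return ParameterSet(
            D=float(q[self.i_d]), G=G, R=R, T=T,
            sG=float(sG), sR=float(sR), sT=float(sT),
            cGR=float(cGR), cTT=float(cTT), **{k: float(v) for k, v in kwargs.items()},
        )

    # -- density ------------------------------------------------------------

    def logp_and_grad(self, q):
        """Log density and gradient; compiled kernel when available."""
        if self.fixed_sds is None and _HAVE_NUMBA:
            return _srm_kernel(
                q, self.y, self.g_pos, self.r_pos, self.first, self.second,
                self.offset, self.covs, self.n, self.n_un, self.n_dyads,
                self.d_loc, self.d_scale, self.b_loc, self.b_scale,
                self.sd_rate, self.lkj_shape,
            )
        return self.logp_and_grad_reference(q)

    def logp_and_grad_reference(self, q):
        sG, sR, sT, cGR, cTT, qq, qt, zG, zR, z1, z2, G, R, T = self._latents(q)
        D = q[self.i_d]
        eta = D + G[self.g_pos] + R[self.r_pos] + T + self.offset
        slopes = q[self.i_slopes]
        if self.slope_names:
            eta = eta + slopes @ self.covs
        mu = np.exp(eta)
        logp = float(np.dot(self.y, eta) - mu.sum())
        # priors
        logp -= 0.5 * float(
            np.dot(zG, zG) + np.dot(zR, zR) + np.dot(z1, z1) + np.dot(z2, z2)
        )
        logp -= 0.5 * ((D - self.d_loc) / self.d_scale) ** 2
        if self.slope_names:
            logp -= 0.5 * float(np.sum(((slopes - self.b_loc) / self.b_scale) ** 2))
        if self.fixed_sds is None:
            ls = q[self.i_ls]
            logp += float(-self.sd_rate * (sG + sR + sT) + ls.sum())
            logp += self.lkj_shape * float(np.log1p(-cGR**2) + np.log1p(-cTT**2))

        grad = np.empty(self.dim)
        w = self.y - mu
        gG = np.bincount(self.g_pos, weights=w, minlength=self.n)
        gR = np.bincount(self.r_pos, weights=w, minlength=self.n)
        w1 = w[self.first]
        w2 = w[self.second]
        grad[self.i_d] = w.sum() - (D - self.d_loc) / self.d_scale**2
        if self.slope_names:
            grad[self.i_slopes] = self.covs @ w - (slopes - self.b_loc) / self.b_scale**2
        grad[self.i_zg] = sG * gG + sR * cGR * gR - zG
        grad[self.i_zr] = sR * qq * gR - zR
        grad[self.i_z1] = sT * (w1 + cTT * w2) - z1
        grad[self.i_z2] = sT * qt * w2 - z2
        if self.fixed_sds is None:
            dlsG = float(np.dot(gG, G)) - self.sd_rate * sG + 1.0
            dlsR = float(np.dot(gR, R)) - self.sd_rate * sR + 1.0
            dlsT = float(np.dot(w1, T[self.first]) + np.dot(w2, T[self.second])) \
                - self.sd_rate * sT + 1.0
            grad[self.i_ls] = (dlsG, dlsR, dlsT)
            duGR = float(np.dot(gR, sR * ((1 - cGR**2) * zG - cGR * qq * zR))) \
                - 2.0 * self.lkj_shape * cGR
            duTT = float(np.dot(w2, sT * ((1 - cTT**2) * z1 - cTT * qt * z2))) \
                - 2.0 * self.lkj_shape * cTT
            grad[self.i_u] = (duGR, duTT)
        return logp, grad

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        q0 = 0.1 * rng.uniform(-1.0, 1.0, size=self.dim)
        if self.i_ls is not None:
            q0[self.i_ls] = np.log(0.5) + 0.1 * rng.uniform(-1, 1, size=3)
        return q0


@njit(cache=True)
def _srm_kernel(q, y, g_pos, r_pos, first, second, offset, covs,
                n, n_un, n_dyads, d_loc, d_scale, b_loc, b_scale,
                sd_rate, lkj_shape):  # pragma: no cover - exercised via wrapper
    n_slopes = covs.shape[0]
    i_sl = 1
    i_ls = 1 + n_slopes
    i_u = i_ls + 3
    i_zg = i_u + 2
    i_zr = i_zg + n
    i_z1 = i_zr + n
    i_z2 = i_z1 + n_un
    dim = i_z2 + n_un

    D = q[0]
    sG = np.exp(q[i_ls])
    sR = np.exp(q[i_ls + 1])
    sT = np.exp(q[i_ls + 2])
    cGR = np.tanh(q[i_u])
    cTT = np.tanh(q[i_u + 1])
    qq = np.sqrt(1.0 - cGR * cGR)
    qt = np.sqrt(1.0 - cTT * cTT)

    G = np.empty(n)
    R = np.empty(n)
    for a in range(n):
        zg = q[i_zg + a]
        zr = q[i_zr + a]
        G[a] = sG * zg
        R[a] = sR * (cGR * zg + qq * zr)
    T = np.empty(n_dyads)
    for d in range(n_un):
        z1 = q[i_z1 + d]
        z2 = q[i_z2 + d]
        T[first[d]] = sT * z1
        T[second[d]] = sT * (cTT * z1 + qt * z2)

    grad = np.zeros(dim)
    gG = np.zeros(n)
    gR = np.zeros(n)
    w = np.empty(n_dyads)
    logp = 0.0
    wsum = 0.0
    for i in range(n_dyads):
        eta = D + G[g_pos[i]] + R[r_pos[i]] + T[i] + offset[i]
        for k in range(n_slopes):
            eta += q[i_sl + k] * covs[k, i]
        mu = np.exp(eta)
        wi = y[i] - mu
        logp += y[i] * eta - mu
        wsum += wi
        w[i] = wi
        gG[g_pos[i]] += wi
        gR[r_pos[i]] += wi
        for k in range(n_slopes):
            grad[i_sl + k] += wi * covs[k, i]

    # priors: standard-normal innovations, Normal fixed effects,
    # Exponential SDs (log-scale Jacobian), LKJ correlations (tanh Jacobian)
    grad[0] = wsum - (D - d_loc) / (d_scale * d_scale)
    logp -= 0.5 * ((D - d_loc) / d_scale) ** 2
    for k in range(n_slopes):
        b = q[i_sl + k]
        logp -= 0.5 * ((b - b_loc) / b_scale) ** 2
        grad[i_sl + k] -= (b - b_loc) / (b_scale * b_scale)
    logp += -sd_rate * (sG + sR + sT) + q[i_ls] + q[i_ls + 1] + q[i_ls + 2]
    logp += lkj_shape * (np.log1p(-cGR * cGR) + np.log1p(-cTT * cTT))

    dlsG = -sd_rate * sG + 1.0
    dlsR = -sd_rate * sR + 1.0
    duGR = -2.0 * lkj_shape * cGR
    for a in range(n):
        zg = q[i_zg + a]
        zr = q[i_zr + a]
        logp -= 0.5 * (zg * zg + zr * zr)
        grad[i_zg + a] = sG * gG[a] + sR * cGR * gR[a] - zg
        grad[i_zr + a] = sR * qq * gR[a] - zr
        dlsG += gG[a] * G[a]
        dlsR += gR[a] * R[a]
        duGR += gR[a] * sR * ((1.0 - cGR * cGR) * zg - cGR * qq * zr)
    dlsT = -sd_rate * sT + 1.0
    duTT = -2.0 * lkj_shape * cTT
    for d in range(n_un):
        z1 = q[i_z1 + d]
        z2 = q[i_z2 + d]
        w1 = w[first[d]]
        w2 = w[second[d]]
        logp -= 0.5 * (z1 * z1 + z2 * z2)
        grad[i_z1 + d] = sT * (w1 + cTT * w2) - z1
        grad[i_z2 + d] = sT * qt * w2 - z2
        dlsT += w1 * T[first[d]] + w2 * T[second[d]]
        duTT += w2 * sT * ((1.0 - cTT * cTT) * z1 - cTT * qt * z2)
    grad[i_ls] = dlsG
    grad[i_ls + 1] = dlsR
    grad[i_ls + 2] = dlsT
    grad[i_u] = duGR
    grad[i_u + 1] = duTT
    return logp, grad
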