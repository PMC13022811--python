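"""Bayesian integration model for merged SV calls.

Each merged position i carries a latent truth indicator z_i (1 = true
variant).  Given z_i, the number of reporting tools x_i follows one of two
categorical distributions over 1..J — omega1 (increasing in k) for true
positives, omega0 (decreasing in k) for false ones — expressing the voting
effect: real variants tend to be seen by more callers.  Which tools make up
the reporting set of size x_i is a weighted selection without replacement
that does not depend on z_i, so that factor cancels from the posterior of z.
Scores from tools in the index set A are censored Gaussians: a latent
o_ij ~ N(mu_{z_i j}, sigma_{z_i j}^2) observed exactly inside (a_j, b_j) and
clamped at the bounds outside, with mu_{1j} > mu_{0j}.

Inference is a data-augmented Gibbs sampler: z and the latent scores o have
exact conditional draws; the ordered probability vectors omega and the
mean-ordered score parameters are updated by independence
Metropolis-within-Gibbs (propose from the unconstrained conjugate
conditional, accept iff the order constraint holds — a valid move for the
truncated target).  The per-position posterior error probability (PEP) is
the posterior mean of 1{z_i = 0}.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy.special import betainc, betaincinv, expit, log_ndtr, ndtri_exp

from .callset import CallMatrix

__all__ = [
    "ModelParams",
    "LatentState",
    "PriorConfig",
    "McmcConfig",
    "PosteriorSummary",
    "censored_score_loglik",
    "subset_logprob",
    "position_log_odds",
    "exact_pep",
    "full_loglik",
    "gibbs_step_z",
    "gibbs_step_o",
    "gibbs_step_scoreparams",
    "gibbs_step_omega",
    "gibbs_step_pi",
    "run_mcmc",
]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ModelParams:
    """All model parameters.

    Score parameters are length-J arrays with NaN outside the score set A;
    ``a``/``b`` are the per-tool censoring bounds (+-inf when unbounded).
    ``v`` (J x J, column k = inclusion weights given x = k) is optional: it
    cancels from the z posterior and is only needed for simulation or full
    likelihood evaluation.
    """

    pi: float
    omega1: np.ndarray
    omega0: np.ndarray
    mu1: np.ndarray
    mu0: np.ndarray
    sigma1: np.ndarray
    sigma0: np.ndarray
    a: np.ndarray
    b: np.ndarray
    v: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("omega1", "omega0", "mu1", "mu0", "sigma1", "sigma0", "a", "b"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.v is not None:
            self.v = np.asarray(self.v, dtype=float)

    @property
    def J(self) -> int:
        return int(self.omega1.shape[0])

    @property
    def score_tools(self) -> tuple[int, ...]:
        return tuple(int(j) for j in np.flatnonzero(np.isfinite(self.mu1)))

    def validate(self) -> None:
        J = self.J
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must lie in [0, 1]")
        for name, w in (("omega1", self.omega1), ("omega0", self.omega0)):
            if w.shape != (J,) or abs(w.sum() - 1.0) > 1e-8 or np.any(w < 0):
                raise ValueError(f"{name} must be a length-J probability vector")
        if not np.all(np.diff(self.omega1) > 0):
            raise ValueError("omega1 must be strictly increasing in k")
        if not np.all(np.diff(self.omega0) < 0):
            raise ValueError("omega0 must be strictly decreasing in k")
        for j in self.score_tools:
            if not self.mu1[j] > self.mu0[j]:
                raise ValueError(f"require mu1 > mu0 for scoring tool {j}")
            if not (self.sigma1[j] > 0 and self.sigma0[j] > 0):
                raise ValueError(f"require positive sigmas for scoring tool {j}")
            if not self.a[j] < self.b[j]:
                raise ValueError(f"require a < b for scoring tool {j}")
        if self.v is not None:
            if self.v.shape != (J, J) or np.any(self.v < 0) or \
                    not np.allclose(self.v.sum(axis=0), 1.0, atol=1e-8):
                raise ValueError("v must be J x J with columns on the simplex")


@dataclass
class LatentState:
    """Current latent variables: truth indicators z and uncensored scores o.

    ``o`` is an (n, J) array, NaN where no score was observed; at interior
    observations o equals the observed score, at censored observations it is
    the imputed Gaussian tail draw.
    """

    z: np.ndarray
    o: np.ndarray


@dataclass
class PriorConfig:
    """Weakly informative conjugate priors.

    ``score_prior`` is the Normal-Inverse-Gamma (m, kappa, shape, scale)
    shared by every (tool, component); ``alpha_omega`` the symmetric
    Dirichlet concentration; ``beta_pi`` the Beta prior on P(z=1).
    """

    alpha_omega: float = 1.0
    beta_pi: tuple[float, float] = (1.0, 1.0)
    score_prior: tuple[float, float, float, float] = (0.0, 0.01, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.alpha_omega <= 0 or min(self.beta_pi) <= 0 or \
                min(self.score_prior[1:]) <= 0:
            raise ValueError("prior hyperparameters must be strictly positive")


@dataclass
class McmcConfig:
    iterations: int = 5000
    burn_in: int = 2000
    thin: int = 1
    seed: int = 0
    n_chains: int = 2
    constraint_retry_cap: int = 10

    def __post_init__(self) -> None:
        if not (self.iterations > self.burn_in >= 0):
            raise ValueError("need iterations > burn_in >= 0")
        if self.thin < 1 or self.n_chains < 1 or self.constraint_retry_cap < 1:
            raise ValueError("thin, n_chains, constraint_retry_cap must be >= 1")


@dataclass
class PosteriorSummary:
    """MCMC output: PEPs, posterior means/SDs, retained chains, diagnostics."""

    pep: np.ndarray
    param_means: Optional[ModelParams]
    param_sds: dict
    chains: dict
    diagnostics: dict
    converged: bool = True


# ---------------------------------------------------------------------------
# likelihood pieces
# ---------------------------------------------------------------------------


def censored_score_loglik(s: float, mu: float, sigma: float,
                          a: float = -np.inf, b: float = np.inf) -> float:
    """Log-likelihood of one observed score under censoring at (a, b).

    Interior observations contribute the Gaussian density; an observation at
    a bound contributes the corresponding tail mass (lower tail at ``a``,
    upper tail at ``b``).
    """
    if not a < b:
        raise ValueError("require a < b")
    if sigma <= 0:
        raise ValueError("require sigma > 0")
    if s < a or s > b:
        raise ValueError(f"score {s} outside censoring bounds ({a}, {b})")
    if s == a:
        return float(log_ndtr((a - mu) / sigma))
    if s == b:
        return float(log_ndtr(-(b - mu) / sigma))
    zz = (s - mu) / sigma
    return -0.5 * zz * zz - math.log(sigma) - _LOG_SQRT_2PI


def subset_logprob(y_row: np.ndarray, k: int, v_col: np.ndarray) -> float:
    """Log-probability of an unordered reporting set of size k.

    The set is drawn by successive weighted selection without replacement
    with weights ``v_col``; the unordered probability sums the sequential
    product over all k! draw orders (exact enumeration, intended for small J).
    """
    y_row = np.asarray(y_row)
    v_col = np.asarray(v_col, dtype=float)
    sel = np.flatnonzero(y_row)
    if len(sel) != k or k < 1:
        raise ValueError("k must equal the number of selected tools (>= 1)")
    if abs(v_col.sum() - 1.0) > 1e-8 or np.any(v_col < 0):
        raise ValueError("v_col must be a probability vector")
    total = 0.0
    for order in itertools.permutations(sel):
        prob, remaining = 1.0, 1.0
        for j in order:
            prob *= v_col[j] / remaining
            remaining -= v_col[j]
        total += prob
    return math.log(total)


class _ScoreIndex:
    """Per-tool index of observed scores split by censoring status."""

    __slots__ = ("n", "entries")

    def __init__(self, cm: CallMatrix):
        self.n = cm.n
        self.entries = []
        for j in cm.score_tools:
            t = cm.tools[j]
            col = cm.S[:, j]
            rows = np.flatnonzero(~np.isnan(col))
            if rows.size == 0:
                continue
            s = col[rows]
            lo = s <= t.a
            hi = s >= t.b
            interior = ~(lo | hi)
            self.entries.append((j, rows, s, interior, lo, hi, t.a, t.b))

    def loglik_sums(self, params: ModelParams) -> tuple[np.ndarray, np.ndarray]:
        """Row-wise sums of censored-score log-likelihood for both components."""
        L1 = np.zeros(self.n)
        L0 = np.zeros(self.n)
        for j, rows, s, interior, lo, hi, a, b in self.entries:
            for L, mu, sg in ((L1, params.mu1[j], params.sigma1[j]),
                              (L0, params.mu0[j], params.sigma0[j])):
                ll = np.empty(s.shape)
                si = s[interior]
                zz = (si - mu) / sg
                ll[interior] = -0.5 * zz * zz - math.log(sg) - _LOG_SQRT_2PI
                if lo.any():
                    ll[lo] = log_ndtr((a - mu) / sg)
                if hi.any():
                    ll[hi] = log_ndtr(-(b - mu) / sg)
                L[rows] += ll
        return L1, L0


def position_log_odds(cm: CallMatrix, params: ModelParams,
                      _idx: Optional[_ScoreIndex] = None) -> np.ndarray:
    """log P(z_i=1, data_i) - log P(z_i=0, data_i) for every position.

    The weighted-subset factor p(y | x) does not depend on z and cancels, so
    only pi, the count probabilities and the censored-score likelihoods enter.
    """
    params.validate()
    idx = _idx or _ScoreIndex(cm)
    L1, L0 = idx.loglik_sums(params)
    k = cm.X - 1
    with np.errstate(divide="ignore"):
        odds = (np.log(params.pi) - np.log1p(-params.pi)
                + np.log(params.omega1[k]) - np.log(params.omega0[k]))
    return odds + L1 - L0


def exact_pep(cm: CallMatrix, params: ModelParams) -> np.ndarray:
    """Closed-form PEP P(z_i = 0 | data, params) for fixed parameters."""
    return expit(-position_log_odds(cm, params))


def full_loglik(cm: CallMatrix, params: ModelParams) -> float:
    """Complete observed-data log-likelihood, including the subset factor.

    Requires ``params.v``; used for reporting only — the subset factor is
    irrelevant to the z posterior.
    """
    if params.v is None:
        raise ValueError("full_loglik requires the inclusion-weight matrix v")
    params.validate()
    idx = _ScoreIndex(cm)
    L1, L0 = idx.loglik_sums(params)
    k = cm.X - 1
    joint1 = np.log(params.pi) + np.log(params.omega1[k]) + L1
    joint0 = np.log1p(-params.pi) + np.log(params.omega0[k]) + L0
    total = float(np.logaddexp(joint1, joint0).sum())
    for i in range(cm.n):
        total += subset_logprob(cm.Y[i], int(cm.X[i]), params.v[:, cm.X[i] - 1])
    return total


# ---------------------------------------------------------------------------
# Gibbs sweeps
# ---------------------------------------------------------------------------


def gibbs_step_z(cm: CallMatrix, params: ModelParams, state: LatentState,
                 rng: np.random.Generator,
                 _idx: Optional[_ScoreIndex] = None) -> np.ndarray:
    """Draw z_i ~ Bernoulli(1 - PEP_i) from its collapsed full conditional.

    The latent scores o are integrated out (the censored likelihood of the
    observed s is used directly), so this step pairs with a fresh o draw.
    """
    p1 = expit(position_log_odds(cm, params, _idx=_idx))
    state.z = (rng.random(cm.n) < p1).astype(np.int8)
    return state.z


def _lower_tail_draw(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standard-normal draws truncated to (-inf, alpha], by inverse CDF.

    Works in log space (Phi^{-1}(u * Phi(alpha)) via ``ndtri_exp``), which
    stays accurate arbitrarily far into the tail.
    """
    logu = np.log(rng.random(alpha.shape))
    return ndtri_exp(logu + log_ndtr(alpha))


def gibbs_step_o(cm: CallMatrix, params: ModelParams, state: LatentState,
                 rng: np.random.Generator,
                 _idx: Optional[_ScoreIndex] = None) -> np.ndarray:
    """Impute the latent uncensored scores given z.

    Interior observations are copied; bound observations are drawn from the
    matching Gaussian tail by a log-space inverse-CDF sampler that remains
    robust for extreme tail probabilities.
    """
    idx = _idx or _ScoreIndex(cm)
    for j, rows, s, interior, lo, hi, a, b in idx.entries:
        o = state.o[:, j]
        zr = state.z[rows]
        mu = np.where(zr == 1, params.mu1[j], params.mu0[j])
        sg = np.where(zr == 1, params.sigma1[j], params.sigma0[j])
        vals = np.array(s, dtype=float)
        if lo.any():
            alpha = (a - mu[lo]) / sg[lo]
            vals[lo] = mu[lo] + sg[lo] * _lower_tail_draw(alpha, rng)
        if hi.any():
            beta = (b - mu[hi]) / sg[hi]
            vals[hi] = mu[hi] - sg[hi] * _lower_tail_draw(-beta, rng)
        o[rows] = vals
    return state.o


def _nig_draw(data: np.ndarray, prior: PriorConfig,
              rng: np.random.Generator) -> tuple[float, float]:
    """One (mu, sigma) draw from the Normal-Inverse-Gamma posterior."""
    m0, k0, a0, b0 = prior.score_prior
    n = data.size
    if n == 0:
        var = b0 / rng.gamma(a0)
        return float(rng.normal(m0, math.sqrt(var / k0))), float(math.sqrt(var))
    ybar = float(data.mean())
    ss = float(((data - ybar) ** 2).sum())
    kn = k0 + n
    mn = (k0 * m0 + n * ybar) / kn
    an = a0 + 0.5 * n
    bn = b0 + 0.5 * ss + 0.5 * k0 * n * (ybar - m0) ** 2 / kn
    var = bn / rng.gamma(an)
    return float(rng.normal(mn, math.sqrt(var / kn))), float(math.sqrt(var))


def gibbs_step_scoreparams(cm: CallMatrix, params: ModelParams,
                           state: LatentState, prior: PriorConfig,
                           rng: np.random.Generator,
                           _idx: Optional[_ScoreIndex] = None) -> ModelParams:
    """Update (mu, sigma) for both components of every scoring tool.

    Per tool, both components are proposed jointly from their unconstrained
    conjugate conditionals; the pair is accepted iff mu1 > mu0, otherwise the
    previous values are kept (independence Metropolis on the truncated
    target).  An empty component falls back to a prior draw.
    """
    idx = _idx or _ScoreIndex(cm)
    for j, rows, s, interior, lo, hi, a, b in idx.entries:
        o = state.o[rows, j]
        zr = state.z[rows]
        mu1p, sg1p = _nig_draw(o[zr == 1], prior, rng)
        mu0p, sg0p = _nig_draw(o[zr == 0], prior, rng)
        if mu1p > mu0p:
            params.mu1[j], params.sigma1[j] = mu1p, sg1p
            params.mu0[j], params.sigma0[j] = mu0p, sg0p
    return params


def _collapsed_score_mh(entry, z: np.ndarray, params: ModelParams,
                        prior: PriorConfig, rng: np.random.Generator,
                        n_prop: int = 5, step: float = 0.15) -> None:
    """Extra Metropolis moves on (mu, sigma) under the *observed* censored
    likelihood, with the latent scores integrated out.

    For heavily censored components (most observations sitting at a bound)
    the conjugate update given imputed o's mixes very slowly; these
    collapsed random-walk moves on (mu, log sigma) target the marginal
    conditional p(mu, sigma | z, s) directly and restore mixing.  Interleaving
    them with the conjugate sweep leaves the posterior invariant.
    """
    j, rows, s, interior, lo, hi, a, b = entry
    m0, k0, a0, b0 = prior.score_prior
    zr = z[rows]
    for comp in (1, 0):
        sel = zr == comp
        si = s[sel & interior]
        n_int = si.size
        sum_s = float(si.sum())
        sum_s2 = float((si * si).sum())
        n_lo = int(np.count_nonzero(sel & lo))
        n_hi = int(np.count_nonzero(sel & hi))

        mu_attr = "mu1" if comp == 1 else "mu0"
        sg_attr = "sigma1" if comp == 1 else "sigma0"

        def logtarget(mu: float, sg: float) -> float:
            # NIG prior on (mu, sigma^2), expressed in (mu, log sigma) space
            lp = (-math.log(sg) - 0.5 * k0 * (mu - m0) ** 2 / (sg * sg)
                  - (2 * a0 + 2) * math.log(sg) - b0 / (sg * sg)
                  + 2 * math.log(sg))  # Jacobian d(sigma^2)/d(log sigma)
            ll = (-n_int * math.log(sg)
                  - 0.5 * (sum_s2 - 2 * mu * sum_s + n_int * mu * mu) / (sg * sg))
            if n_lo:
                ll += n_lo * float(log_ndtr((a - mu) / sg))
            if n_hi:
                ll += n_hi * float(log_ndtr(-(b - mu) / sg))
            return lp + ll

        mu = float(getattr(params, mu_attr)[j])
        sg = float(getattr(params, sg_attr)[j])
        cur = logtarget(mu, sg)
        for _ in range(n_prop):
            mu_p = mu + step * rng.standard_normal()
            sg_p = sg * math.exp(step * rng.standard_normal())
            if comp == 1 and not mu_p > params.mu0[j]:
                continue
            if comp == 0 and not params.mu1[j] > mu_p:
                continue
            new = logtarget(mu_p, sg_p)
            if math.log(rng.random()) < new - cur:
                mu, sg, cur = mu_p, sg_p, new
        getattr(params, mu_attr)[j] = mu
        getattr(params, sg_attr)[j] = sg


def _ordered(w: np.ndarray, increasing: bool) -> bool:
    d = np.diff(w)
    return bool(np.all(d > 0)) if increasing else bool(np.all(d < 0))


def _ordered_dirichlet_gibbs_pass(w: np.ndarray, conc: np.ndarray,
                                  rng: np.random.Generator) -> np.ndarray:
    """One Gibbs sweep over a Dirichlet truncated to w_1 < w_2 < ... < w_J.

    Holding all but an adjacent pair (w_k, w_{k+1}) fixed, the fraction
    u = w_k / (w_k + w_{k+1}) follows a Beta(conc_k, conc_{k+1}) truncated to
    the interval implied by the neighbours and u < 1/2; it is drawn exactly
    by inverse-CDF.  Exact conditional draws, no rejections — effective even
    when the posterior presses against the ordering boundary.
    """
    w = np.array(w, dtype=float)
    J = w.size
    for k in range(J - 1):
        t = w[k] + w[k + 1]
        lo = w[k - 1] / t if k > 0 else 0.0
        hi = 0.5
        if k + 2 < J:
            lo = max(lo, 1.0 - w[k + 2] / t)
        if not lo < hi:
            continue
        ak, bk = conc[k], conc[k + 1]
        c_lo = float(betainc(ak, bk, lo))
        c_hi = float(betainc(ak, bk, hi))
        if c_hi - c_lo < 1e-14:
            continue
        u = float(betaincinv(ak, bk, c_lo + rng.random() * (c_hi - c_lo)))
        if lo < u < hi:
            w[k], w[k + 1] = u * t, (1.0 - u) * t
    return w


def gibbs_step_omega(cm: CallMatrix, params: ModelParams, state: LatentState,
                     prior: PriorConfig, rng: np.random.Generator,
                     retry_cap: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Update the ordered count-probability vectors omega1 and omega0.

    Proposals come from the unconstrained Dirichlet(alpha + counts)
    conditional; a proposal is accepted iff the strict ordering (increasing
    for omega1, decreasing for omega0) holds — an accepted draw is then an
    exact sample from the order-truncated conditional.  If ``retry_cap``
    proposals all violate the ordering (typical when the data push against
    the constraint), one random-walk Metropolis move with a Dirichlet
    proposal concentrated at the current value is attempted instead, so the
    chain keeps mixing near the boundary of the ordered region.
    """
    J = cm.J
    n1 = np.bincount(cm.X[state.z == 1], minlength=J + 1)[1:].astype(float)
    n0 = np.bincount(cm.X[state.z == 0], minlength=J + 1)[1:].astype(float)
    for attr, counts, increasing in (("omega1", n1, True), ("omega0", n0, False)):
        conc = prior.alpha_omega + counts
        accepted = False
        for _ in range(retry_cap):
            w = rng.dirichlet(conc)
            if _ordered(w, increasing):
                setattr(params, attr, w)
                accepted = True
                break
        if not accepted:
            # the unconstrained conditional has negligible mass in the
            # ordered region (posterior hugging the constraint boundary):
            # run an exact coordinate-Gibbs pass on the truncated Dirichlet
            cur = getattr(params, attr)
            if increasing:
                w = _ordered_dirichlet_gibbs_pass(cur, conc, rng)
            else:
                w = _ordered_dirichlet_gibbs_pass(cur[::-1], conc[::-1],
                                                  rng)[::-1]
            if _ordered(w, increasing):
                setattr(params, attr, w)
    return params.omega1, params.omega0


def gibbs_step_pi(state: LatentState, prior: PriorConfig,
                  rng: np.random.Generator) -> float:
    """Conjugate Beta update of pi = P(z_i = 1)."""
    a, b = prior.beta_pi
    nz = int(state.z.sum())
    return float(rng.beta(a + nz, b + state.z.size - nz))


# ---------------------------------------------------------------------------
# full sampler
# ---------------------------------------------------------------------------


def _initial_z(cm: CallMatrix) -> np.ndarray:
    """Data-driven starting truth assignment.

    Positions with observed scores are split by the sign of their mean
    tool-centred score (scores separate the components even when the support
    counts do not); score-less positions fall back to the majority vote
    x >= ceil(J/2).
    """
    J = cm.J
    z0 = (cm.X >= math.ceil(J / 2)).astype(np.int8)
    centred = np.full_like(cm.S, np.nan)
    for j in cm.score_tools:
        col = cm.S[:, j]
        have = ~np.isnan(col)
        if have.any():
            centred[have, j] = col[have] - col[have].mean()
    n_obs = (~np.isnan(centred)).sum(axis=1)
    scored = n_obs > 0
    row_score = np.where(scored, np.nansum(centred, axis=1), 0.0)
    z0[scored] = (row_score[scored] > 0).astype(np.int8)
    return z0


def _initial_params(cm: CallMatrix, rng: np.random.Generator) -> tuple[ModelParams, np.ndarray]:
    """Deterministic data-driven initialisation (rng only for degenerate falls)."""
    J = cm.J
    z0 = _initial_z(cm)
    pi0 = float(np.clip(z0.mean(), 0.05, 0.95))

    def _ordered_freqs(x: np.ndarray, increasing: bool) -> np.ndarray:
        counts = np.bincount(x, minlength=J + 1)[1:].astype(float) + 1.0
        w = np.sort(counts / counts.sum())
        if not increasing:
            w = w[::-1]
        # break ties so the strict ordering holds
        jitter = np.arange(J) * 1e-6 * (1 if increasing else -1)
        w = w + jitter - jitter.mean() / J
        w = np.clip(w, 1e-9, None)
        return w / w.sum()

    omega1 = _ordered_freqs(cm.X[z0 == 1] if z0.any() else cm.X, True)
    omega0 = _ordered_freqs(cm.X[z0 == 0] if (z0 == 0).any() else cm.X, False)

    mu1 = np.full(J, np.nan)
    mu0 = np.full(J, np.nan)
    sg1 = np.full(J, np.nan)
    sg0 = np.full(J, np.nan)
    a = np.full(J, -np.inf)
    b = np.full(J, np.inf)
    for j in cm.score_tools:
        t = cm.tools[j]
        a[j], b[j] = t.a, t.b
        col = cm.S[:, j]
        have = ~np.isnan(col)
        s1 = col[have & (z0 == 1)]
        s0 = col[have & (z0 == 0)]
        m1 = float(s1.mean()) if s1.size else float(col[have].mean() + 1.0)
        m0 = float(s0.mean()) if s0.size else float(col[have].mean() - 1.0)
        if not m1 > m0:
            mid = 0.5 * (m1 + m0)
            m1, m0 = mid + 0.5, mid - 0.5
        mu1[j], mu0[j] = m1, m0
        sg1[j] = float(s1.std()) if s1.size > 1 else 1.0
        sg0[j] = float(s0.std()) if s0.size > 1 else 1.0
        sg1[j] = max(sg1[j], 1e-3)
        sg0[j] = max(sg0[j], 1e-3)
    params = ModelParams(pi=pi0, omega1=omega1, omega0=omega0, mu1=mu1, mu0=mu0,
                         sigma1=sg1, sigma0=sg0, a=a, b=b)
    params.validate()
    return params, z0


def _run_chain(cm: CallMatrix, prior: PriorConfig, mcfg: McmcConfig,
               seed_seq: np.random.SeedSequence,
               init_params: Optional[ModelParams], sample_params: bool):
    rng = np.random.default_rng(seed_seq)
    idx = _ScoreIndex(cm)
    if init_params is None:
        params, z0 = _initial_params(cm, rng)
    else:
        params = replace(init_params,
                         omega1=init_params.omega1.copy(),
                         omega0=init_params.omega0.copy(),
                         mu1=init_params.mu1.copy(), mu0=init_params.mu0.copy(),
                         sigma1=init_params.sigma1.copy(),
                         sigma0=init_params.sigma0.copy())
        params.validate()
        z0 = _initial_z(cm)
    state = LatentState(z=z0, o=np.where(np.isnan(cm.S), np.nan, cm.S).copy())

    n_draws = (mcfg.iterations - mcfg.burn_in + mcfg.thin - 1) // mcfg.thin
    J = cm.J
    A = list(cm.score_tools)
    pep_counts = np.zeros(cm.n)
    draws = {
        "pi": np.empty(n_draws),
        "omega1": np.empty((n_draws, J)),
        "omega0": np.empty((n_draws, J)),
        "mu1": np.empty((n_draws, J)),
        "mu0": np.empty((n_draws, J)),
        "sigma1": np.empty((n_draws, J)),
        "sigma0": np.empty((n_draws, J)),
    }
    kept = 0
    for it in range(mcfg.iterations):
        gibbs_step_z(cm, params, state, rng, _idx=idx)
        if A:
            gibbs_step_o(cm, params, state, rng, _idx=idx)
        if sample_params:
            if A:
                gibbs_step_scoreparams(cm, params, state, prior, rng, _idx=idx)
                for entry in idx.entries:
                    _collapsed_score_mh(entry, state.z, params, prior, rng)
            gibbs_step_omega(cm, params, state, prior, rng,
                             retry_cap=mcfg.constraint_retry_cap)
            params.pi = gibbs_step_pi(state, prior, rng)
        if it >= mcfg.burn_in and (it - mcfg.burn_in) % mcfg.thin == 0:
            pep_counts += state.z == 0
            draws["pi"][kept] = params.pi
            draws["omega1"][kept] = params.omega1
            draws["omega0"][kept] = params.omega0
            draws["mu1"][kept] = params.mu1
            draws["mu0"][kept] = params.mu0
            draws["sigma1"][kept] = params.sigma1
            draws["sigma0"][kept] = params.sigma0
            kept += 1
    return pep_counts, draws, kept, params


def _diagnostics(chains: dict, score_tools: list[int], J: int) -> dict:
    """Split-R-hat and bulk ESS per scalar parameter via arviz."""
    import warnings

    import arviz as az

    scalars = {"pi": chains["pi"]}
    for k in range(J):
        scalars[f"omega1[{k + 1}]"] = chains["omega1"][:, :, k]
        scalars[f"omega0[{k + 1}]"] = chains["omega0"][:, :, k]
    for j in score_tools:
        for name in ("mu1", "mu0", "sigma1", "sigma0"):
            scalars[f"{name}[{j}]"] = chains[name][:, :, j]
    if next(iter(scalars.values())).shape[0] == 1:
        # single chain: split it in two so split-R-hat is defined
        scalars = {k: v[:, : 2 * (v.shape[1] // 2)].reshape(2, -1)
                   for k, v in scalars.items()}
    out = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset({k: v for k, v in scalars.items()})
        rhat = az.rhat(ds)
        ess = az.ess(ds)
    for k in scalars:
        out[k] = {"rhat": float(rhat[k].values), "ess": float(ess[k].values)}
    return out


def run_mcmc(cm: CallMatrix, prior: Optional[PriorConfig] = None,
             mcfg: Optional[McmcConfig] = None,
             init_params: Optional[ModelParams] = None,
             sample_params: bool = True) -> PosteriorSummary:
    """Run the Gibbs sampler and summarise the posterior.

    Sweeps update z, the latent scores o, the score parameters, the ordered
    omega vectors and pi, in that order.  ``sample_params=False`` clamps the
    parameters at ``init_params`` (useful for validating the z draws against
    the closed-form PEP).  The run is bit-reproducible for a fixed seed.
    """
    prior = prior or PriorConfig()
    mcfg = mcfg or McmcConfig()
    if cm.n == 0:
        return PosteriorSummary(pep=np.empty(0), param_means=None, param_sds={},
                                chains={}, diagnostics={}, converged=True)
    cm.validate()
    if not sample_params and init_params is None:
        raise ValueError("clamped runs need init_params")

    seeds = np.random.SeedSequence(mcfg.seed).spawn(mcfg.n_chains)
    pep_total = np.zeros(cm.n)
    per_chain = []
    total_draws = 0
    for c in range(mcfg.n_chains):
        pep_counts, draws, kept, _ = _run_chain(cm, prior, mcfg, seeds[c],
                                                init_params, sample_params)
        pep_total += pep_counts
        per_chain.append(draws)
        total_draws += kept

    chains = {k: np.stack([d[k] for d in per_chain]) for k in per_chain[0]}
    pep = pep_total / total_draws

    A = list(cm.score_tools)
    a = np.full(cm.J, -np.inf)
    b = np.full(cm.J, np.inf)
    for j in A:
        a[j], b[j] = cm.tools[j].a, cm.tools[j].b

    def _mean(name):
        return chains[name].reshape(-1, *chains[name].shape[2:]).mean(axis=0)

    def _sd(name):
        return chains[name].reshape(-1, *chains[name].shape[2:]).std(axis=0)

    mask = np.full(cm.J, np.nan)
    mask[A] = 1.0
    param_means = ModelParams(
        pi=float(_mean("pi")),
        omega1=_mean("omega1") / _mean("omega1").sum(),
        omega0=_mean("omega0") / _mean("omega0").sum(),
        mu1=_mean("mu1") * mask, mu0=_mean("mu0") * mask,
        sigma1=_mean("sigma1") * mask, sigma0=_mean("sigma0") * mask,
        a=a, b=b,
    )
    param_sds = {name: _sd(name) for name in
                 ("pi", "omega1", "omega0", "mu1", "mu0", "sigma1", "sigma0")}

    if sample_params:
        diagnostics = _diagnostics(chains, A, cm.J)
        converged = all(np.isnan(d["rhat"]) or d["rhat"] <= 1.1
                        for d in diagnostics.values())
    else:
        diagnostics = {}
        converged = True
    return PosteriorSummary(pep=pep, param_means=param_means, param_sds=param_sds,
                            chains=chains, diagnostics=diagnostics,
                            converged=converged)
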