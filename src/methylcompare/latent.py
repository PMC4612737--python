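"""Bayesian latent-class model for two conditionally dependent binary tests.

Neither methylation platform can serve as a gold standard, so true
methylation status is treated as a latent class behind two imperfect,
possibly correlated, binary tests applied to one population of CpG loci.
The model has seven parameters:

* ``se1``, ``se2`` — conditional sensitivities of tests 1 and 2,
* ``sp1``, ``sp2`` — conditional specificities,
* ``pi``          — prevalence of methylation among the loci,
* ``covp``        — covariance of the two tests within the methylated class,
* ``covn``        — covariance within the unmethylated class.

The covariances capture conditional dependence: two tests that miss the same
hard-to-assay loci agree more than independence predicts.  Each covariance is
constrained to the range that keeps all four conditional joint-outcome
probabilities of its class inside [0, 1] (``covariance_bounds``).

The observed data are the 2x2 cross-tabulation of paired calls over loci.
Only the four cell probabilities are identified; with seven parameters and
three degrees of freedom the model is non-identifiable and priors matter.
Inference uses Metropolis-within-Gibbs with reflected random-walk proposals,
multiple chains from overdispersed starts, half-burn-in, and the
Gelman-Rubin potential-scale-reduction diagnostic (rule of thumb: converged
when R-hat < 1.1 for every parameter).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "LatentClassParams",
    "CrossTabulation",
    "MCMCConfig",
    "PosteriorSummary",
    "covariance_bounds",
    "joint_cell_probs",
    "class_cell_probs",
    "log_likelihood",
    "gelman_rubin",
    "run_mcmc",
    "sample_prior",
    "estimate_sample",
    "cross_tabulate",
]

PARAM_NAMES = ("se1", "se2", "sp1", "sp2", "pi", "covp", "covn")


def covariance_bounds(a1: float, a2: float) -> tuple[float, float]:
    """Feasible range for a within-class covariance given the two accuracies.

    For the methylated class pass the sensitivities, for the unmethylated
    class the specificities.  The bounds are exactly those that keep all four
    conditional joint probabilities of the class in [0, 1]; zero (conditional
    independence) is always feasible.
    """
    lo = max(-a1 * a2, -(1.0 - a1) * (1.0 - a2))
    hi = min(a1 * (1.0 - a2), (1.0 - a1) * a2)
    return lo, hi


@dataclass(frozen=True)
class LatentClassParams:
    """The seven parameters; validates covariance feasibility on creation."""

    se1: float
    se2: float
    sp1: float
    sp2: float
    pi: float
    covp: float = 0.0
    covn: float = 0.0

    def __post_init__(self) -> None:
        for name in ("se1", "se2", "sp1", "sp2", "pi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        lo, hi = covariance_bounds(self.se1, self.se2)
        if not lo - 1e-12 <= self.covp <= hi + 1e-12:
            raise ValidationError(f"covp={self.covp} outside bounds [{lo}, {hi}]")
        lo, hi = covariance_bounds(self.sp1, self.sp2)
        if not lo - 1e-12 <= self.covn <= hi + 1e-12:
            raise ValidationError(f"covn={self.covn} outside bounds [{lo}, {hi}]")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)


@dataclass(frozen=True)
class CrossTabulation:
    """Counts of loci by paired outcome (test1, test2): ++, +-, -+, --."""

    n_pp: int
    n_pm: int
    n_mp: int
    n_mm: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if min(self.n_pp, self.n_pm, self.n_mp, self.n_mm) < 0:
            raise ValidationError("negative cell count")

    @property
    def total(self) -> int:
        return self.n_pp + self.n_pm + self.n_mp + self.n_mm

    def as_array(self) -> np.ndarray:
        return np.array([self.n_pp, self.n_pm, self.n_mp, self.n_mm], dtype=float)


def class_cell_probs(params: LatentClassParams) -> tuple[np.ndarray, np.ndarray]:
    """Joint outcome probabilities (++, +-, -+, --) within each latent class."""
    se1, se2, sp1, sp2 = params.se1, params.se2, params.sp1, params.sp2
    cp, cn = params.covp, params.covn
    meth = np.array(
        [
            se1 * se2 + cp,
            se1 * (1 - se2) - cp,
            (1 - se1) * se2 - cp,
            (1 - se1) * (1 - se2) + cp,
        ]
    )
    unmeth = np.array(
        [
            (1 - sp1) * (1 - sp2) + cn,
            (1 - sp1) * sp2 - cn,
            sp1 * (1 - sp2) - cn,
            sp1 * sp2 + cn,
        ]
    )
    return meth, unmeth


def joint_cell_probs(params: LatentClassParams) -> np.ndarray:
    """Marginal probabilities of the four paired outcomes (++, +-, -+, --)."""
    meth, unmeth = class_cell_probs(params)
    return params.pi * meth + (1.0 - params.pi) * unmeth


def log_likelihood(tab: CrossTabulation, params: LatentClassParams) -> float:
    """Multinomial log likelihood (up to the multinomial coefficient)."""
    n = tab.as_array()
    p = joint_cell_probs(params)
    out = 0.0
    for ni, pi in zip(n, p):
        if ni > 0:
            if pi <= 0:
                return -np.inf
            out += ni * np.log(pi)
    return float(out)


# ---------------------------------------------------------------------------
# Gelman-Rubin diagnostic
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray, split: bool = False) -> float:
    """Potential scale reduction factor R-hat for one scalar parameter.

    ``chains`` is an (m, n) array: m >= 2 chains of n >= 2 draws.  The
    classic (non-split) formula is

        R-hat = sqrt( ((n-1)/n * W + B/n) / W )

    with W the mean within-chain variance and B the between-chain variance
    of the chain means scaled by n.  ``split=True`` halves each chain first
    (the modern variant, sensitive to non-stationarity within a chain).
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValidationError("need >=2 chains of equal length")
    if chains.shape[1] < 2:
        raise ValidationError("need >=2 draws per chain")
    if split:
        half = chains.shape[1] // 2
        chains = np.vstack([chains[:, :half], chains[:, half : 2 * half]])
    m, n = chains.shape
    within = chains.var(axis=1, ddof=1)
    w = within.mean()
    b = n * chains.mean(axis=1).var(ddof=1)
    if w == 0.0:
        return np.inf if b > 0 else 1.0
    var_hat = (n - 1) / n * w + b / n
    return float(np.sqrt(var_hat / w))


# ---------------------------------------------------------------------------
# sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings.

    Defaults mirror the full-fidelity analysis profile (5 chains of 200,000
    iterations with the first half discarded); tests and the desk-scale
    pipeline use shorter profiles.  Priors are Beta(a, b) on the five
    probability parameters (flat by default) and uniform over the dynamic
    feasibility bounds for the covariances.
    """

    n_chains: int = 5
    n_iter: int = 200_000
    seed: int = 0
    rhat_threshold: float = 1.1
    prior_a: Mapping[str, float] = field(default_factory=dict)
    prior_b: Mapping[str, float] = field(default_factory=dict)
    thin: int = 1
    # truncate the prior to Se_i + Sp_i > 1 (each test better than chance);
    # breaks the latent-class label-swap symmetry that otherwise makes the
    # posterior bimodal and the chains irreconcilable
    constrain_accuracy: bool = True

    def ab(self, name: str) -> tuple[float, float]:
        return float(self.prior_a.get(name, 1.0)), float(self.prior_b.get(name, 1.0))


@dataclass(frozen=True)
class PosteriorSummary:
    """Post-burn-in draws plus convergence diagnostics.

    ``draws`` maps parameter name to an (n_chains, n_kept) array.  R-hat is
    computed on kept (post-burn-in) draws only; ``converged`` is true iff
    every parameter's R-hat is below the threshold.
    """

    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    median: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    converged: bool
    n_missing: int = 0

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def implied_cell_probs(self, point: str = "median") -> np.ndarray:
        """Posterior point estimate of the four joint cell probabilities.

        The cell probabilities are the identified functionals of the model;
        they are summarized per draw (median by default, or mean), unlike
        the seven raw parameters whose marginal medians need not be jointly
        feasible.
        """
        se1, se2 = self.pooled("se1"), self.pooled("se2")
        sp1, sp2 = self.pooled("sp1"), self.pooled("sp2")
        pi = self.pooled("pi")
        cp, cn = self.pooled("covp"), self.pooled("covn")
        cells = np.stack(
            [
                pi * (se1 * se2 + cp) + (1 - pi) * ((1 - sp1) * (1 - sp2) + cn),
                pi * (se1 * (1 - se2) - cp) + (1 - pi) * ((1 - sp1) * sp2 - cn),
                pi * ((1 - se1) * se2 - cp) + (1 - pi) * (sp1 * (1 - sp2) - cn),
                pi * ((1 - se1) * (1 - se2) + cp) + (1 - pi) * (sp1 * sp2 + cn),
            ]
        )
        agg = np.median if point == "median" else np.mean
        return agg(cells, axis=1)

    def median_params(self) -> LatentClassParams:
        """Posterior-median parameter vector, with covariances clipped to the
        range the median accuracies allow (medians of the seven marginals are
        not guaranteed jointly feasible)."""
        m = self.median
        lo_p, hi_p = covariance_bounds(m["se1"], m["se2"])
        lo_n, hi_n = covariance_bounds(m["sp1"], m["sp2"])
        return LatentClassParams(
            se1=m["se1"],
            se2=m["se2"],
            sp1=m["sp1"],
            sp2=m["sp2"],
            pi=m["pi"],
            covp=float(np.clip(m["covp"], lo_p, hi_p)),
            covn=float(np.clip(m["covn"], lo_n, hi_n)),
        )


def _log_posterior(theta: np.ndarray, n: np.ndarray, cfg: MCMCConfig) -> np.ndarray:
    """Vectorized log posterior for theta of shape (7, C) over C chains.

    Returns -inf where the parameter vector is infeasible.
    """
    se1, se2, sp1, sp2, pi, covp, covn = theta
    lo_p = np.maximum(-se1 * se2, -(1 - se1) * (1 - se2))
    hi_p = np.minimum(se1 * (1 - se2), (1 - se1) * se2)
    lo_n = np.maximum(-sp1 * sp2, -(1 - sp1) * (1 - sp2))
    hi_n = np.minimum(sp1 * (1 - sp2), (1 - sp1) * sp2)
    ok = (
        (covp >= lo_p)
        & (covp <= hi_p)
        & (covn >= lo_n)
        & (covn <= hi_n)
        & (hi_p > lo_p)
        & (hi_n > lo_n)
    )
    for v in (se1, se2, sp1, sp2, pi):
        ok &= (v >= 0.0) & (v <= 1.0)
    if cfg.constrain_accuracy:
        ok &= (se1 + sp1 > 1.0) & (se2 + sp2 > 1.0)

    p_pp = pi * (se1 * se2 + covp) + (1 - pi) * ((1 - sp1) * (1 - sp2) + covn)
    p_pm = pi * (se1 * (1 - se2) - covp) + (1 - pi) * ((1 - sp1) * sp2 - covn)
    p_mp = pi * ((1 - se1) * se2 - covp) + (1 - pi) * (sp1 * (1 - sp2) - covn)
    p_mm = pi * ((1 - se1) * (1 - se2) + covp) + (1 - pi) * (sp1 * sp2 + covn)

    logp = np.zeros_like(pi)
    with np.errstate(divide="ignore", invalid="ignore"):
        for ni, pc in zip(n, (p_pp, p_pm, p_mp, p_mm)):
            if ni > 0:
                logp = logp + ni * np.log(np.where(pc > 0, pc, np.nan))
        # uniform priors over the dynamic covariance bounds
        logp = logp - np.log(np.where(hi_p > lo_p, hi_p - lo_p, np.nan))
        logp = logp - np.log(np.where(hi_n > lo_n, hi_n - lo_n, np.nan))
        # Beta priors on the five probability parameters
        for name, v in zip(("se1", "se2", "sp1", "sp2", "pi"), (se1, se2, sp1, sp2, pi)):
            a, b = cfg.ab(name)
            if a != 1.0:
                logp = logp + (a - 1.0) * np.log(np.where(v > 0, v, np.nan))
            if b != 1.0:
                logp = logp + (b - 1.0) * np.log(np.where(v < 1, 1 - v, np.nan))
    logp = np.where(ok & np.isfinite(logp), logp, -np.inf)
    return logp


def _initial_values(rng: np.random.Generator, cfg: MCMCConfig, n_chains: int) -> np.ndarray:
    """Overdispersed starts: probability parameters from their priors, each
    covariance uniform over the bounds its accuracies imply."""
    theta = np.empty((7, n_chains))
    for j, name in enumerate(("se1", "se2", "sp1", "sp2", "pi")):
        a, b = cfg.ab(name)
        theta[j] = rng.beta(a, b, size=n_chains)
    if cfg.constrain_accuracy:
        # rejection-sample accuracy pairs into the better-than-chance region
        for i1, i2 in ((0, 2), (1, 3)):
            for _ in range(1000):
                bad = theta[i1] + theta[i2] <= 1.0
                if not bad.any():
                    break
                a1, b1 = cfg.ab(PARAM_NAMES[i1])
                a2, b2 = cfg.ab(PARAM_NAMES[i2])
                theta[i1, bad] = rng.beta(a1, b1, size=bad.sum())
                theta[i2, bad] = rng.beta(a2, b2, size=bad.sum())
            else:
                theta[i1] = np.maximum(theta[i1], 1.001 - theta[i2])
    lo_p = np.maximum(-theta[0] * theta[1], -(1 - theta[0]) * (1 - theta[1]))
    hi_p = np.minimum(theta[0] * (1 - theta[1]), (1 - theta[0]) * theta[1])
    lo_n = np.maximum(-theta[2] * theta[3], -(1 - theta[2]) * (1 - theta[3]))
    hi_n = np.minimum(theta[2] * (1 - theta[3]), (1 - theta[2]) * theta[3])
    theta[5] = lo_p + rng.random(n_chains) * (hi_p - lo_p)
    theta[6] = lo_n + rng.random(n_chains) * (hi_n - lo_n)
    return theta


def _theta_to_q(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(7, C) parameters -> per-class joint-outcome probabilities (C, 4)."""
    se1, se2, sp1, sp2, _, cp, cn = theta
    qm = np.stack(
        [se1 * se2 + cp, se1 * (1 - se2) - cp, (1 - se1) * se2 - cp,
         (1 - se1) * (1 - se2) + cp],
        axis=-1,
    )
    qu = np.stack(
        [(1 - sp1) * (1 - sp2) + cn, (1 - sp1) * sp2 - cn, sp1 * (1 - sp2) - cn,
         sp1 * sp2 + cn],
        axis=-1,
    )
    return qm, qu


def _q_to_accuracy(qm: np.ndarray, qu: np.ndarray) -> tuple[np.ndarray, ...]:
    """Class simplices (C, 4) -> (se1, se2, sp1, sp2, covp, covn)."""
    se1 = qm[..., 0] + qm[..., 1]
    se2 = qm[..., 0] + qm[..., 2]
    covp = qm[..., 0] - se1 * se2
    sp1 = qu[..., 2] + qu[..., 3]
    sp2 = qu[..., 1] + qu[..., 3]
    covn = qu[..., 3] - sp1 * sp2
    return se1, se2, sp1, sp2, covp, covn


def _log_prior_class(a1v, a2v, cfg: MCMCConfig, names: tuple[str, str]) -> np.ndarray:
    """Log prior factor carried by one class's accuracies (a1, a2).

    The map between (a1, a2, cov) and the class simplex has unit Jacobian,
    so the stated priors — Beta on each accuracy, uniform over the dynamic
    covariance bounds — contribute Beta densities and -log(bound range).
    """
    lo = np.maximum(-a1v * a2v, -(1 - a1v) * (1 - a2v))
    hi = np.minimum(a1v * (1 - a2v), (1 - a1v) * a2v)
    rng_w = hi - lo
    with np.errstate(divide="ignore", invalid="ignore"):
        out = -np.log(np.where(rng_w > 0, rng_w, np.nan))
        for name, v in zip(names, (a1v, a2v)):
            a, b = cfg.ab(name)
            if a != 1.0:
                out = out + (a - 1.0) * np.log(np.where(v > 0, v, np.nan))
            if b != 1.0:
                out = out + (b - 1.0) * np.log(np.where(v < 1, 1 - v, np.nan))
    return np.where(np.isfinite(out), out, -np.inf)


def _dirichlet(rng: np.random.Generator, alpha: np.ndarray) -> np.ndarray:
    """Row-wise Dirichlet draws for an (C, k) alpha array via Gamma draws."""
    g = rng.gamma(np.maximum(alpha, 1e-12))
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def run_mcmc(tab: CrossTabulation, config: MCMCConfig | None = None) -> PosteriorSummary:
    """Sample the posterior by data-augmented Gibbs with MH corrections.

    Each iteration (per chain, vectorized across chains):

    1. *Augment*: for each observed cell, draw the number of truly
       methylated loci from its conditional binomial.
    2. *Prevalence*: conjugate Beta update given the augmented total.
    3. *Class simplices*: the methylated-class joint-outcome probabilities
       get an independence-MH update with a Dirichlet(1 + counts) proposal;
       the multinomial likelihood cancels against the proposal, leaving the
       smooth prior factor (Beta densities on the accuracies and the
       uniform-over-dynamic-bounds covariance prior, which transfer with
       unit Jacobian) plus the better-than-chance truncation in the
       acceptance ratio.  Likewise for the unmethylated class.

    Chains start overdispersed from the prior; the first half of the
    iterations is burn-in.  Deterministic given the seed.
    """
    cfg = config or MCMCConfig()
    if tab.total <= 0:
        raise ValidationError("cross-tabulation has no complete pairs")
    rng = np.random.default_rng(cfg.seed)
    n = tab.as_array()
    C = cfg.n_chains
    n_iter = cfg.n_iter
    burn = n_iter // 2
    a_pi, b_pi = cfg.ab("pi")

    theta = _initial_values(rng, cfg, C)
    qm, qu = _theta_to_q(theta)
    qm = np.clip(qm, 1e-12, None)
    qm /= qm.sum(axis=-1, keepdims=True)
    qu = np.clip(qu, 1e-12, None)
    qu /= qu.sum(axis=-1, keepdims=True)
    pi = theta[4].copy()

    se1, se2, sp1, sp2, covp, covn = _q_to_accuracy(qm, qu)
    logprior_m = _log_prior_class(se1, se2, cfg, ("se1", "se2"))
    logprior_u = _log_prior_class(sp1, sp2, cfg, ("sp1", "sp2"))

    n_kept = (n_iter - burn + cfg.thin - 1) // cfg.thin
    kept = np.empty((7, C, n_kept))
    k = 0
    for it in range(n_iter):
        # 1. augmentation: latent methylated count per observed cell
        num = pi[:, None] * qm
        denom = num + (1 - pi)[:, None] * qu
        prob = np.where(denom > 0, num / np.maximum(denom, 1e-300), 0.0)
        y = rng.binomial(n.astype(np.int64), np.clip(prob, 0.0, 1.0))

        # 2. prevalence: conjugate Beta
        y_tot = y.sum(axis=-1)
        pi = rng.beta(a_pi + y_tot, b_pi + tab.total - y_tot)

        # 3. class simplices: independence MH, Dirichlet(1 + counts) proposal
        for which in ("m", "u"):
            counts = y if which == "m" else n[None, :] - y
            prop = _dirichlet(rng, 1.0 + counts)
            if which == "m":
                p_se1, p_se2, _, _, _, _ = _q_to_accuracy(prop, qu)
                lp_prop = _log_prior_class(p_se1, p_se2, cfg, ("se1", "se2"))
                if cfg.constrain_accuracy:
                    lp_prop = np.where((p_se1 + sp1 > 1) & (p_se2 + sp2 > 1), lp_prop, -np.inf)
                accept = np.log(rng.random(C)) < (lp_prop - logprior_m)
                qm[accept] = prop[accept]
                logprior_m = np.where(accept, lp_prop, logprior_m)
                se1, se2, _, _, covp, _ = _q_to_accuracy(qm, qu)
            else:
                _, _, p_sp1, p_sp2, _, _ = _q_to_accuracy(qm, prop)
                lp_prop = _log_prior_class(p_sp1, p_sp2, cfg, ("sp1", "sp2"))
                if cfg.constrain_accuracy:
                    lp_prop = np.where((se1 + p_sp1 > 1) & (se2 + p_sp2 > 1), lp_prop, -np.inf)
                accept = np.log(rng.random(C)) < (lp_prop - logprior_u)
                qu[accept] = prop[accept]
                logprior_u = np.where(accept, lp_prop, logprior_u)
                _, _, sp1, sp2, _, covn = _q_to_accuracy(qm, qu)

        if it >= burn and (it - burn) % cfg.thin == 0:
            kept[0, :, k] = se1
            kept[1, :, k] = se2
            kept[2, :, k] = sp1
            kept[3, :, k] = sp2
            kept[4, :, k] = pi
            kept[5, :, k] = covp
            kept[6, :, k] = covn
            k += 1
    kept = kept[:, :, :k]

    draws = {name: kept[j] for j, name in enumerate(PARAM_NAMES)}
    rhat = {name: gelman_rubin(d) if C >= 2 else np.nan for name, d in draws.items()}
    median = {name: float(np.median(d)) for name, d in draws.items()}
    ci_low = {name: float(np.quantile(d, 0.025)) for name, d in draws.items()}
    ci_high = {name: float(np.quantile(d, 0.975)) for name, d in draws.items()}
    converged = bool(all(r < cfg.rhat_threshold for r in rhat.values()))
    return PosteriorSummary(
        draws=draws,
        rhat=rhat,
        median=median,
        ci_low=ci_low,
        ci_high=ci_high,
        converged=converged,
        n_missing=tab.n_missing,
    )


def sample_prior(rng: np.random.Generator, config: MCMCConfig | None = None) -> LatentClassParams:
    """One parameter vector drawn from the sampler's prior.

    Beta draws for the five probability parameters (rejected into the
    better-than-chance region when the constraint is on), then uniform
    draws over the covariance bounds those accuracies imply.
    """
    cfg = config or MCMCConfig()
    theta = _initial_values(rng, cfg, 1)[:, 0]
    return LatentClassParams(*theta)


def cross_tabulate(calls1: pd.Series | np.ndarray, calls2: pd.Series | np.ndarray) -> CrossTabulation:
    """Cross-tabulate two call vectors over the same loci.

    Loci with a missing call in either test are excluded pairwise and
    counted in ``n_missing``.
    """
    a = np.asarray(calls1, dtype=float)
    b = np.asarray(calls2, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("call vectors must cover the same loci")
    complete = ~(np.isnan(a) | np.isnan(b))
    a, b = a[complete], b[complete]
    return CrossTabulation(
        n_pp=int(((a == 1) & (b == 1)).sum()),
        n_pm=int(((a == 1) & (b == 0)).sum()),
        n_mp=int(((a == 0) & (b == 1)).sum()),
        n_mm=int(((a == 0) & (b == 0)).sum()),
        n_missing=int((~complete).sum()),
    )


def estimate_sample(
    calls1: pd.Series | np.ndarray,
    calls2: pd.Series | np.ndarray,
    config: MCMCConfig | None = None,
) -> PosteriorSummary:
    """Estimate the seven parameters for one sample from its paired calls."""
    return run_mcmc(cross_tabulate(calls1, calls2), config)
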