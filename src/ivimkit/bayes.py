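"""Bayesian IVIM fitters.

Two samplers share a vectorised adaptive random-walk Metropolis core that
updates every voxel of a region in parallel:

* :func:`fit_bayes_uniform` — per-voxel posterior over (S0, f, D, D*) under a
  Gaussian likelihood with the noise scale marginalised analytically
  (Jeffreys prior) and a uniform box prior over the constrained parameter
  space.
* :func:`fit_bayes_loggauss` — hierarchical (empirical-Bayes) model in which
  each voxel's transformed parameters θ = (logit f, log D, log D*) are drawn
  from a shared multivariate Gaussian prior N(μ0, Σ0) whose hyperparameters
  are learned from the voxel population by conjugate Gibbs updates
  (Normal for μ0, inverse-Wishart for Σ0). S0 and the noise scale are
  nuisance parameters marginalised analytically (flat and Jeffreys priors).

The shared prior shrinks noisy voxel estimates toward the population centre,
which is what makes the hierarchical fitter's maps smooth — and what can
drive tumour voxels toward values typical of the (larger) surrounding
tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky
from scipy.stats import invwishart

from .fitters import FitConstraints, FitResult, VoxelSeries, initialize
from .model import BValueScheme, IVIMParams, TransformedParams, to_transformed

__all__ = [
    "MCMCConfig",
    "EmpiricalPrior",
    "fit_bayes_uniform",
    "fit_bayes_loggauss",
]

#: relative floor on the residual sum of squares inside the marginal
#: likelihood; keeps log(SSE) finite on noise-free data (acts like a
#: minimal noise scale of ~1e-6 of the signal RMS).
_SSE_FLOOR_REL = 1e-6

_PARAM_NAMES = ("S0", "f", "D", "Dstar")


@dataclass
class MCMCConfig:
    """Markov-chain settings for both Bayesian fitters.

    Defaults: 12 000 iterations with 4 000 burn-in; proposal scales adapt
    during burn-in toward ~30% acceptance (kept within the 20–45% band that
    random-walk Metropolis mixes well in).
    """

    n_iter: int = 12_000
    burn_in: int = 4_000
    seed: int = 0
    target_accept: float = 0.3
    adapt_interval: int = 50
    summary: str = "mean"  # or "mode" (highest-posterior sample)

    def __post_init__(self) -> None:
        if self.n_iter <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.summary not in ("mean", "mode"):
            raise ValueError("summary must be 'mean' or 'mode'")


@dataclass
class EmpiricalPrior:
    """Fitted population prior of the hierarchical sampler, over
    (logit f, log D, log D*)."""

    mu0: np.ndarray
    Sigma0: np.ndarray

    def __post_init__(self) -> None:
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(3)
        self.Sigma0 = np.asarray(self.Sigma0, dtype=float).reshape(3, 3)
        if not np.allclose(self.Sigma0, self.Sigma0.T, atol=1e-10):
            raise ValueError("Sigma0 must be symmetric")
        if np.any(np.linalg.eigvalsh(self.Sigma0) <= 0):
            raise ValueError("Sigma0 must be positive definite")

    def mean_params(self) -> TransformedParams:
        return TransformedParams(*self.mu0)


def _stack_signals(voxels: list[VoxelSeries], scheme: BValueScheme) -> np.ndarray:
    for v in voxels:
        v.check_scheme(scheme)
    return np.stack([v.signals for v in voxels])


def _adapt(log_scale: np.ndarray, accepted: np.ndarray, proposed: int, target: float) -> None:
    rate = accepted / max(proposed, 1)
    log_scale += np.clip(rate - target, -0.5, 0.5)
    np.clip(log_scale, -25.0, 3.0, out=log_scale)


def fit_bayes_uniform(
    voxels: list[VoxelSeries],
    scheme: BValueScheme,
    constraints: FitConstraints | None = None,
    config: MCMCConfig | None = None,
    fix: dict[str, float] | None = None,
    s0_bounds: tuple[float, float] | None = None,
    prior_only: bool = False,
) -> list[FitResult]:
    """Per-voxel Bayesian fit with a uniform box prior.

    The noise scale is marginalised under a Jeffreys prior, giving the
    marginal log-likelihood −(n/2)·log SSE(S0, f, D, D*); the prior is
    uniform over the constraint box (S0's box defaults to (0, 2·max signal)
    per voxel). Returns posterior-mean parameters (posterior spread in
    ``extras['posterior_sd']``). Reproducible given ``config.seed``.

    ``fix`` freezes named parameters (e.g. ``{"S0": 1.0, "D": 1.2e-3}``) for
    reduced-dimension problems; ``prior_only=True`` replaces the likelihood
    with a constant (validation mode — posterior means must then equal the
    box midpoints).
    """
    constraints = constraints or FitConstraints()
    config = config or MCMCConfig()
    fix = dict(fix or {})
    if not voxels:
        raise ValueError("need at least one voxel")
    Y = _stack_signals(voxels, scheme)
    V, nb = Y.shape
    b = scheme.b_values
    rng = np.random.default_rng(config.seed)

    free = [p for p in _PARAM_NAMES if p not in fix]
    if not free:
        raise ValueError("at least one parameter must be free")
    idx = {p: i for i, p in enumerate(_PARAM_NAMES)}

    # per-voxel bounds, shape (V, 4)
    lo = np.empty((V, 4))
    hi = np.empty((V, 4))
    s0_hi = 2.0 * np.maximum(Y.max(axis=1), 1e-12) if s0_bounds is None else np.full(V, s0_bounds[1])
    s0_lo = 1e-12 if s0_bounds is None else s0_bounds[0]
    lo[:, 0], hi[:, 0] = s0_lo, s0_hi
    lo[:, 1], hi[:, 1] = constraints.f_bounds
    lo[:, 2], hi[:, 2] = constraints.D_bounds
    lo[:, 3], hi[:, 3] = constraints.Dstar_bounds

    # state, shape (V, 4); fixed entries stay put
    X = np.empty((V, 4))
    for v, vox in enumerate(voxels):
        X[v] = initialize(vox, scheme, constraints).as_array()
    X = np.clip(X, lo + 1e-15, hi - 1e-15)
    for p, val in fix.items():
        X[:, idx[p]] = val

    floor = np.maximum((_SSE_FLOOR_REL * np.sqrt(np.mean(Y**2, axis=1))) ** 2 * nb, 1e-300)

    def loglik(Xc: np.ndarray, rows: np.ndarray | slice = slice(None)) -> np.ndarray:
        if prior_only:
            return np.zeros(Xc.shape[0])
        model = Xc[:, [0]] * (
            Xc[:, [1]] * np.exp(-b * Xc[:, [3]]) + (1.0 - Xc[:, [1]]) * np.exp(-b * Xc[:, [2]])
        )
        sse = np.sum((model - Y[rows]) ** 2, axis=1)
        return -0.5 * nb * np.log(sse + floor[rows])

    free_idx = np.array([idx[p] for p in free])
    box_width = (hi - lo)[:, free_idx]
    width = box_width.copy()  # per-coordinate proposal widths, adapted in burn-in
    log_scale = np.full(V, np.log(0.1))
    ll = loglik(X)
    mean_acc = np.zeros((V, 4))
    mean_sq = np.zeros((V, 4))
    best_ll = ll.copy()
    best_X = X.copy()
    n_kept = 0
    accepted = np.zeros(V)
    acc_total = np.zeros(V)
    proposed = 0

    # Mixture kernel: mostly random-walk steps, occasionally an independent
    # uniform draw over the box — the latter cuts autocorrelation when the
    # posterior is broad (weakly identified voxels), while the adaptive
    # random walk handles sharply peaked posteriors. During burn-in the
    # per-coordinate proposal widths are additionally matched to the running
    # posterior spread (the box is extremely anisotropic relative to typical
    # posteriors, so a single scalar scale mixes one coordinate at a time).
    indep_frac = 0.1
    rw_proposed = np.zeros(V)
    run_n = 0
    run_sum = np.zeros((V, free_idx.size))
    run_sq = np.zeros((V, free_idx.size))

    for it in range(config.n_iter):
        step = np.exp(log_scale)[:, None] * width * rng.standard_normal((V, free_idx.size))
        indep = rng.uniform(size=V) < indep_frac
        Xp = X.copy()
        Xp[:, free_idx] += step
        if np.any(indep):
            draws = lo[:, free_idx] + rng.uniform(size=(V, free_idx.size)) * box_width
            Xp[indep[:, None] & np.isin(np.arange(4), free_idx)] = draws[indep].ravel()
        inside = np.all(
            (Xp[:, free_idx] >= lo[:, free_idx]) & (Xp[:, free_idx] <= hi[:, free_idx]), axis=1
        )
        llp = np.full(V, -np.inf)
        if np.any(inside):
            llp[inside] = loglik(Xp[inside], inside)
        accept = np.log(rng.uniform(size=V)) < llp - ll
        X[accept] = Xp[accept]
        ll[accept] = llp[accept]
        accepted += accept & ~indep
        rw_proposed += ~indep
        acc_total += accept
        proposed += 1
        if it < config.burn_in:
            run_sum += X[:, free_idx]
            run_sq += X[:, free_idx] ** 2
            run_n += 1
            if (it + 1) % config.adapt_interval == 0:
                _adapt(log_scale, accepted / np.maximum(rw_proposed, 1), 1, config.target_accept)
                accepted[:] = 0
                rw_proposed[:] = 0
                mean = run_sum / run_n
                sd = np.sqrt(np.maximum(run_sq / run_n - mean**2, 0.0))
                # 2.4/sqrt(d): classic adaptive-Metropolis width; floor avoids collapse
                width = np.clip(
                    2.4 / np.sqrt(free_idx.size) * sd, 1e-4 * box_width, box_width
                )
                run_sum[:] = 0.0
                run_sq[:] = 0.0
                run_n = 0
        else:
            mean_acc += X
            mean_sq += X**2
            n_kept += 1
            better = ll > best_ll
            best_ll[better] = ll[better]
            best_X[better] = X[better]

    post_mean = mean_acc / n_kept
    post_sd = np.sqrt(np.maximum(mean_sq / n_kept - post_mean**2, 0.0))
    summary = post_mean if config.summary == "mean" else best_X

    results: list[FitResult] = []
    for v in range(V):
        x = summary[v]
        params = IVIMParams(S0=float(x[0]), f=float(x[1]), D=float(x[2]), Dstar=float(x[3]))
        model = x[0] * (x[1] * np.exp(-b * x[3]) + (1.0 - x[1]) * np.exp(-b * x[2]))
        results.append(
            FitResult(
                params=params,
                converged=True,
                sse=float(np.sum((model - Y[v]) ** 2)),
                n_iter=config.n_iter,
                extras={
                    "posterior_sd": dict(zip(_PARAM_NAMES, post_sd[v])),
                    "acceptance_rate": float(acc_total[v] / proposed),
                },
            )
        )
    return results


#: weak inverse-Wishart prior for Σ0: identity ridge keeps the draw positive
#: definite even when the voxel population collapses to a point.
_IW_RIDGE = 1e-6
_IW_DF0 = 5  # p + 2 for p = 3: weakest proper df


def _transformed_loglik(theta: np.ndarray, Y: np.ndarray, b: np.ndarray, yy: np.ndarray,
                        floor: np.ndarray) -> np.ndarray:
    """Marginal log-likelihood of θ = (logit f, log D, log D*) per voxel.

    S0 (flat prior) and the Gaussian noise scale (Jeffreys prior) are
    integrated out analytically: with g(b; θ) the unit-amplitude model curve,
    log p(y|θ) = −½ log(g·g) − (n−1)/2 · log(y·y − (g·y)²/(g·g)).
    """
    n = Y.shape[1]
    f = 1.0 / (1.0 + np.exp(-theta[:, [0]]))
    D = np.exp(theta[:, [1]])
    Dstar = np.exp(theta[:, [2]])
    g = f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D)
    gg = np.sum(g * g, axis=1)
    gy = np.sum(g * Y, axis=1)
    sse = yy - gy**2 / gg
    return -0.5 * np.log(gg) - 0.5 * (n - 1) * np.log(np.maximum(sse, 0.0) + floor)


def fit_bayes_loggauss(
    voxels: list[VoxelSeries],
    scheme: BValueScheme,
    config: MCMCConfig | None = None,
) -> tuple[list[FitResult], EmpiricalPrior]:
    """Hierarchical Bayesian fit with a data-driven Gaussian prior in
    transformed (logit-f, log-D, log-D*) space.

    Every Gibbs sweep performs (a) one vectorised Metropolis update of each
    voxel's θ given (μ0, Σ0) and (b) conjugate draws of μ0 (Normal) and Σ0
    (inverse-Wishart with a weak identity ridge). The transforms enforce
    0 < f < 1, D > 0, D* > 0 without hard boxes. Returns back-transformed
    posterior-mean parameters per voxel plus the fitted population prior
    (posterior means of μ0, Σ0).

    Needs ≥ 10 voxels for a stable covariance estimate — fit over a generous
    region (e.g. a rough outline of the whole organ) and mask afterwards.
    """
    config = config or MCMCConfig()
    if len(voxels) < 10:
        raise ValueError(
            "hierarchical prior estimation needs at least 10 voxels; "
            "fit over a larger region (rough organ outline) and mask afterwards"
        )
    Y = _stack_signals(voxels, scheme)
    V, nb = Y.shape
    b = scheme.b_values
    rng = np.random.default_rng(config.seed)
    yy = np.sum(Y * Y, axis=1)
    floor = np.maximum((_SSE_FLOOR_REL * np.sqrt(np.mean(Y**2, axis=1))) ** 2 * nb, 1e-300)

    # initial per-voxel transformed state from the deterministic initialiser
    theta = np.empty((V, 3))
    for v, vox in enumerate(voxels):
        p = initialize(vox, scheme)
        f0 = float(np.clip(p.f, 1e-3, 0.95))
        theta[v] = to_transformed(
            IVIMParams(S0=p.S0, f=f0, D=max(p.D, 1e-5), Dstar=max(p.Dstar, 1e-4))
        ).as_array()

    mu0 = theta.mean(axis=0)
    Sigma0 = np.cov(theta.T) + 1e-2 * np.eye(3)

    log_scale = np.full(V, np.log(0.25))
    base_width = np.array([1.0, 0.3, 0.7])  # typical spreads of logit f, log D, log D*
    ll = _transformed_loglik(theta, Y, b, yy, floor)

    cf = cho_factor(Sigma0, lower=True)

    def log_prior(th: np.ndarray) -> np.ndarray:
        diff = th - mu0
        sol = cho_solve(cf, diff.T).T
        return -0.5 * np.sum(diff * sol, axis=1)

    lp = log_prior(theta)
    accepted = np.zeros(V)
    sum_params = np.zeros((V, 4))  # S0_hat, f, D, Dstar
    sum_sq = np.zeros((V, 4))
    sum_mu0 = np.zeros(3)
    sum_Sigma0 = np.zeros((3, 3))
    n_kept = 0
    best_lp = np.full(V, -np.inf)
    best_theta = theta.copy()

    for it in range(config.n_iter):
        # (a) Metropolis update of every voxel's θ
        step = np.exp(log_scale)[:, None] * base_width * rng.standard_normal((V, 3))
        theta_p = theta + step
        llp = _transformed_loglik(theta_p, Y, b, yy, floor)
        lpp = log_prior(theta_p)
        accept = np.log(rng.uniform(size=V)) < (llp + lpp) - (ll + lp)
        theta[accept] = theta_p[accept]
        ll[accept] = llp[accept]
        lp[accept] = lpp[accept]
        accepted += accept

        # (b) conjugate updates of the population prior
        theta_bar = theta.mean(axis=0)
        L = cholesky(Sigma0 / V, lower=True)
        mu0 = theta_bar + L @ rng.standard_normal(3)
        diff = theta - mu0
        scale = _IW_RIDGE * np.eye(3) + diff.T @ diff
        Sigma0 = invwishart.rvs(df=_IW_DF0 + V, scale=scale, random_state=rng)
        cf = cho_factor(Sigma0, lower=True)
        lp = log_prior(theta)

        if it < config.burn_in:
            if (it + 1) % config.adapt_interval == 0:
                _adapt(log_scale, accepted, config.adapt_interval, config.target_accept)
                accepted[:] = 0
        else:
            f = 1.0 / (1.0 + np.exp(-theta[:, [0]]))
            D = np.exp(theta[:, [1]])
            Dstar = np.exp(theta[:, [2]])
            g = f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D)
            s0_hat = np.sum(g * Y, axis=1) / np.sum(g * g, axis=1)
            draw = np.column_stack([s0_hat, f[:, 0], D[:, 0], Dstar[:, 0]])
            sum_params += draw
            sum_sq += draw**2
            sum_mu0 += mu0
            sum_Sigma0 += Sigma0
            n_kept += 1
            better = (ll + lp) > best_lp
            best_lp[better] = (ll + lp)[better]
            best_theta[better] = theta[better]

    post_mean = sum_params / n_kept
    if config.summary == "mode":
        f = 1.0 / (1.0 + np.exp(-best_theta[:, [0]]))
        D = np.exp(best_theta[:, [1]])
        Dstar = np.exp(best_theta[:, [2]])
        g = f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D)
        s0_hat = np.sum(g * Y, axis=1) / np.sum(g * g, axis=1)
        post_mean = np.column_stack([s0_hat, f[:, 0], D[:, 0], Dstar[:, 0]])
    post_sd = np.sqrt(np.maximum(sum_sq / n_kept - post_mean**2, 0.0))
    prior = EmpiricalPrior(mu0=sum_mu0 / n_kept, Sigma0=sum_Sigma0 / n_kept)

    results: list[FitResult] = []
    for v in range(V):
        s0, fv, dv, dsv = post_mean[v]
        params = IVIMParams(S0=float(max(s0, 1e-12)), f=float(np.clip(fv, 0.0, 1.0)),
                            D=float(dv), Dstar=float(dsv))
        model = params.S0 * (params.f * np.exp(-b * params.Dstar)
                             + (1.0 - params.f) * np.exp(-b * params.D))
        results.append(
            FitResult(
                params=params,
                converged=True,
                sse=float(np.sum((model - Y[v]) ** 2)),
                n_iter=config.n_iter,
                extras={"posterior_sd": dict(zip(_PARAM_NAMES, post_sd[v]))},
            )
        )
    return results, prior
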