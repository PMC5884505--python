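"""Voxel-wise IVIM fit algorithms: constrained least squares (free and
fixed-D*), adaptive-threshold segmented fit, and Rician maximum likelihood.

All fitters share one constraint/initialisation layer and return a
:class:`FitResult`. The two Bayesian fitters live in :mod:`ivimkit.bayes`
behind the same result contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, minimize, minimize_scalar
from scipy.special import ive

from .model import BValueScheme, IVIMParams, ivim_signal_array

__all__ = [
    "FitConstraints",
    "VoxelSeries",
    "FitResult",
    "NoiseModel",
    "DSTAR_FIXED",
    "initialize",
    "fit_free",
    "fit_fixed_dstar",
    "fit_segmented_adaptive",
    "rician_loglik",
    "fit_mle_rician",
]

#: fixed pseudo-diffusion coefficient (mm²/s) of the fixed-D* fit.
DSTAR_FIXED = 70e-3

#: starting value for D* in all iterative fitters (mm²/s).
_DSTAR_INIT = 70e-3

#: high-b cut (s/mm²) for the mono-exponential initialisation fit.
_INIT_B_CUT = 150.0


@dataclass
class FitConstraints:
    """Box constraints applied during fitting.

    Defaults: 0.5×10⁻³ < D < 6×10⁻³ mm²/s, 6×10⁻³ < D* < 200×10⁻³ mm²/s and
    0.001 < f < 0.99. The segmented fit leaves D unconstrained and the
    hierarchical Bayesian fitter constrains only through its transforms.
    """

    D_bounds: tuple[float, float] = (0.5e-3, 6e-3)
    Dstar_bounds: tuple[float, float] = (6e-3, 200e-3)
    f_bounds: tuple[float, float] = (0.001, 0.99)

    def __post_init__(self) -> None:
        for name in ("D_bounds", "Dstar_bounds", "f_bounds"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise ValueError(f"{name}: lower bound must be below upper bound")

    def midpoint(self) -> IVIMParams:
        return IVIMParams(
            S0=1.0,
            f=0.5 * sum(self.f_bounds),
            D=0.5 * sum(self.D_bounds),
            Dstar=0.5 * sum(self.Dstar_bounds),
        )


@dataclass
class VoxelSeries:
    """One voxel's direction-averaged signal per b-value plus its provenance."""

    signals: np.ndarray
    voxel_id: int = 0
    roi_label: str = "tumour"
    patient: int = 0
    session: int = 1
    acquisition: int = 1

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 1:
            raise ValueError("signals must be one-dimensional")
        if np.any(self.signals < 0):
            raise ValueError("signals must be non-negative")

    def check_scheme(self, scheme: BValueScheme) -> None:
        if self.signals.size != len(scheme):
            raise ValueError(
                f"series length {self.signals.size} does not match scheme length {len(scheme)}"
            )


@dataclass
class FitResult:
    """Fitted parameters plus diagnostics for one voxel."""

    params: IVIMParams
    converged: bool = True
    sse: float = 0.0
    n_iter: int = 0
    extras: dict = field(default_factory=dict)


@dataclass
class NoiseModel:
    """Rician noise scale for the maximum-likelihood fitter.

    ``mode='fixed'`` uses the given sigma; ``mode='estimated'`` lets the
    fitter estimate sigma jointly per voxel.
    """

    sigma: float | None = None
    mode: str = "estimated"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "estimated"):
            raise ValueError("mode must be 'fixed' or 'estimated'")
        if self.mode == "fixed" and not (self.sigma is not None and self.sigma > 0):
            raise ValueError("fixed mode requires sigma > 0")


def _model(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    S0, f, D, Dstar = x
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D))


def _clip(x: float, bounds: tuple[float, float]) -> float:
    return float(min(max(x, bounds[0]), bounds[1]))


def initialize(
    series: VoxelSeries, scheme: BValueScheme, constraints: FitConstraints | None = None
) -> IVIMParams:
    """Starting values for the iterative fitters.

    S0 starts at the b=0 signal; D and the high-b intercept come from a
    log-linear fit to b ≥ 150 s/mm² (where the perfusion term is negligible);
    f is the intercept deficit 1 − A/S0 clipped to bounds; D* starts at
    70×10⁻³ mm²/s. Non-positive high-b signals fall back to box midpoints.
    """
    constraints = constraints or FitConstraints()
    series.check_scheme(scheme)
    b = scheme.b_values
    y = series.signals
    S0 = float(y[b == 0].mean()) if np.any(b == 0) else float(y[0])
    if S0 <= 0:
        S0 = max(float(y.max()), 1e-12)
    high = b >= _INIT_B_CUT
    if high.sum() < 2 or np.any(y[high] <= 0):
        mid = constraints.midpoint()
        return IVIMParams(S0=S0, f=mid.f, D=mid.D, Dstar=_DSTAR_INIT)
    slope, log_a = np.polyfit(b[high], np.log(y[high]), 1)
    D = _clip(-slope, constraints.D_bounds)
    intercept = float(np.exp(log_a))
    f = _clip(1.0 - intercept / S0, constraints.f_bounds)
    return IVIMParams(S0=S0, f=f, D=D, Dstar=_DSTAR_INIT)


def fit_free(
    series: VoxelSeries,
    scheme: BValueScheme,
    constraints: FitConstraints | None = None,
    x0: IVIMParams | None = None,
) -> FitResult:
    """Constrained non-linear least squares over (S0, f, D, D*).

    Minimises Σ_b (S_obs − S_model)² inside the constraint box using a
    trust-region-reflective solver (box constraints preclude plain
    Levenberg–Marquardt). Deterministic for fixed input and start.
    """
    constraints = constraints or FitConstraints()
    series.check_scheme(scheme)
    if np.all(series.signals == 0):
        raise ValueError("all-zero signal cannot be fitted")
    b, y = scheme.b_values, series.signals
    p0 = x0 or initialize(series, scheme, constraints)
    lb = np.array([1e-12, constraints.f_bounds[0], constraints.D_bounds[0], constraints.Dstar_bounds[0]])
    ub = np.array([np.inf, constraints.f_bounds[1], constraints.D_bounds[1], constraints.Dstar_bounds[1]])
    start = np.clip(p0.as_array(), lb, ub)
    res = least_squares(
        lambda x: _model(x, b) - y,
        start,
        bounds=(lb, ub),
        x_scale=[max(p0.S0, 1e-6), 0.1, 1e-3, 1e-2],
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
        method="trf",
    )
    params = IVIMParams(*res.x)
    return FitResult(
        params=params,
        converged=bool(res.success),
        sse=float(2.0 * res.cost),
        n_iter=int(res.nfev),
    )


def fit_fixed_dstar(
    series: VoxelSeries,
    scheme: BValueScheme,
    constraints: FitConstraints | None = None,
    dstar: float = DSTAR_FIXED,
) -> FitResult:
    """Least squares over (S0, f, D) with D* frozen at 70×10⁻³ mm²/s.

    Removing the poorly conditioned D* direction stabilises the fit; the
    returned Dstar is exactly the frozen value.
    """
    constraints = constraints or FitConstraints()
    series.check_scheme(scheme)
    if np.all(series.signals == 0):
        raise ValueError("all-zero signal cannot be fitted")
    b, y = scheme.b_values, series.signals
    p0 = initialize(series, scheme, constraints)
    lb = np.array([1e-12, constraints.f_bounds[0], constraints.D_bounds[0]])
    ub = np.array([np.inf, constraints.f_bounds[1], constraints.D_bounds[1]])
    start = np.clip([p0.S0, p0.f, p0.D], lb, ub)
    res = least_squares(
        lambda x: _model(np.array([x[0], x[1], x[2], dstar]), b) - y,
        start,
        bounds=(lb, ub),
        x_scale=[max(p0.S0, 1e-6), 0.1, 1e-3],
        ftol=1e-14,
        xtol=1e-14,
        gtol=1e-14,
        method="trf",
    )
    params = IVIMParams(S0=res.x[0], f=res.x[1], D=res.x[2], Dstar=dstar)
    return FitResult(
        params=params,
        converged=bool(res.success),
        sse=float(2.0 * res.cost),
        n_iter=int(res.nfev),
    )


#: candidate-threshold window (s/mm²) of the segmented fit.
_THRESHOLD_WINDOW = (40.0, 400.0)


def fit_segmented_adaptive(
    series: VoxelSeries,
    scheme: BValueScheme,
    constraints: FitConstraints | None = None,
) -> FitResult:
    """Adaptive-threshold segmented fit.

    For every candidate threshold b_t among the scheme's b-values in
    [40, 400] s/mm² (with ≥ 3 b-values at/above and ≥ 2 below):

    1. log-linear least squares on b ≥ b_t gives D (unconstrained) and the
       intercept A;
    2. f = 1 − A/S(b=0), clipped to the f box;
    3. D* is then fitted alone by bounded 1-D least squares on the full curve.

    The threshold minimising full-curve SSE wins; ties break toward the
    smaller b_t. The selected threshold is recorded in ``extras``.
    """
    constraints = constraints or FitConstraints()
    series.check_scheme(scheme)
    b, y = scheme.b_values, series.signals
    s0_obs = float(y[0])
    if s0_obs <= 0:
        raise ValueError("non-positive b=0 signal")
    lo, hi = _THRESHOLD_WINDOW
    best: tuple[float, float, IVIMParams] | None = None  # (sse, b_t, params)
    for b_t in b[(b >= lo) & (b <= hi)]:
        high = b >= b_t
        if high.sum() < 3 or (~high).sum() < 2:
            continue
        if np.any(y[high] <= 0):
            continue  # log fit undefined for this threshold
        slope, log_a = np.polyfit(b[high], np.log(y[high]), 1)
        D = float(-slope)
        intercept = float(np.exp(log_a))
        f = _clip(1.0 - intercept / s0_obs, constraints.f_bounds)

        def sse_of_dstar(dstar: float) -> float:
            model = s0_obs * (f * np.exp(-b * dstar) + (1.0 - f) * np.exp(-b * D))
            return float(np.sum((model - y) ** 2))

        opt = minimize_scalar(
            sse_of_dstar, bounds=constraints.Dstar_bounds, method="bounded",
            options={"xatol": 1e-8},
        )
        sse = float(opt.fun)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, float(b_t), IVIMParams(S0=s0_obs, f=f, D=max(D, 0.0), Dstar=float(opt.x)))
    if best is None:
        raise ValueError("no valid segmentation threshold for this series")
    sse, b_t, params = best
    return FitResult(params=params, converged=True, sse=sse, extras={"threshold_b": b_t})


def rician_loglik(
    signals: np.ndarray | Sequence[float],
    model_signals: np.ndarray | Sequence[float],
    sigma: float,
) -> float:
    """Log-likelihood of observed magnitudes under Rician noise.

    Σ_b log[ (S/σ²)·exp(−(S²+ν²)/(2σ²))·I0(S·ν/σ²) ] with ν the noise-free
    model signal. Uses the exponentially scaled Bessel function for
    stability, log I0(x) = x + log ive(0, x). S = 0 is handled by the density
    limit (the log-density → −inf as S→0⁺; a zero observation contributes the
    Rayleigh log-density limit at S=0, i.e. −inf·0 convention avoided by
    flooring S at tiny positive).
    """
    if not sigma > 0:
        raise ValueError("sigma must be > 0")
    s = np.maximum(np.asarray(signals, dtype=float), 1e-300)
    nu = np.asarray(model_signals, dtype=float)
    z = s * nu / sigma**2
    log_i0 = z + np.log(ive(0, z))
    return float(np.sum(np.log(s) - 2.0 * np.log(sigma) - (s**2 + nu**2) / (2.0 * sigma**2) + log_i0))


def fit_mle_rician(
    series: VoxelSeries,
    scheme: BValueScheme,
    constraints: FitConstraints | None = None,
    noise: NoiseModel | None = None,
) -> FitResult:
    """Maximum-likelihood fit assuming Rician magnitude noise.

    Maximises :func:`rician_loglik` over (S0, f, D, D*) — and σ, unless a
    fixed :class:`NoiseModel` is supplied — inside the constraint box. The
    Rician likelihood removes the noise-floor bias that plain least squares
    suffers at low SNR. Initialised from the least-squares solution; at high
    SNR the two agree.
    """
    constraints = constraints or FitConstraints()
    noise = noise or NoiseModel()
    series.check_scheme(scheme)
    if len(scheme) < 5:
        raise ValueError("under-determined: need at least 5 b-values for the 5-parameter MLE")
    b, y = scheme.b_values, series.signals
    ls = fit_free(series, scheme, constraints)
    p0 = ls.params.as_array()
    n = y.size
    sigma0 = max(np.sqrt(ls.sse / max(n - 4, 1)), 1e-6 * max(p0[0], 1.0))

    lb = [1e-12, constraints.f_bounds[0], constraints.D_bounds[0], constraints.Dstar_bounds[0]]
    ub = [np.inf, constraints.f_bounds[1], constraints.D_bounds[1], constraints.Dstar_bounds[1]]

    if noise.mode == "fixed":
        sigma_fixed = float(noise.sigma)

        def negll(x: np.ndarray) -> float:
            return -rician_loglik(y, _model(x, b), sigma_fixed)

        res = minimize(negll, np.clip(p0, lb, ub), method="L-BFGS-B",
                       bounds=list(zip(lb, ub)), options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12})
        x = res.x
        sigma_hat = sigma_fixed
    else:
        lb5 = lb + [1e-6 * max(p0[0], 1.0)]
        ub5 = ub + [np.inf]

        def negll5(x: np.ndarray) -> float:
            return -rician_loglik(y, _model(x[:4], b), x[4])

        res = minimize(negll5, np.clip(np.append(p0, sigma0), lb5, ub5), method="L-BFGS-B",
                       bounds=list(zip(lb5, ub5)), options={"maxiter": 500, "ftol": 1e-15, "gtol": 1e-12})
        x = res.x[:4]
        sigma_hat = float(res.x[4])

    params = IVIMParams(*x)
    model = _model(x, b)
    return FitResult(
        params=params,
        converged=bool(res.success),
        sse=float(np.sum((model - y) ** 2)),
        n_iter=int(res.nit),
        extras={"sigma": sigma_hat, "loglik": float(-res.fun)},
    )
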