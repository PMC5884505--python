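"""IVIM signal model, relaxation-corrected perfusion fraction, parameter transforms.

The intravoxel incoherent motion (IVIM) model describes diffusion-weighted MRI
signal decay as a bi-exponential in the diffusion weighting b (s/mm²):

    S(b) = S0 · [ f · exp(−b·D*) + (1 − f) · exp(−b·D) ]

where ``D`` is the tissue diffusivity (mm²/s), ``D*`` the pseudo-diffusion
coefficient of the capillary compartment (mm²/s) and ``f`` the perfusion
(signal) fraction. Because blood and tissue differ in T1 and T2, the fitted
signal fraction over-weights blood; :func:`blood_volume_fraction` converts it
to a relaxation-compensated blood-volume fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IVIMParams",
    "BValueScheme",
    "RelaxationConstants",
    "TransformedParams",
    "ivim_signal",
    "blood_volume_fraction",
    "to_transformed",
    "from_transformed",
]


@dataclass
class IVIMParams:
    """One voxel's IVIM model state.

    Parameters
    ----------
    S0 : float
        Unweighted (b=0) signal amplitude, arbitrary units. Must be > 0.
    f : float
        Perfusion fraction, stored as a fraction in [0, 1] (reported as %).
    D : float
        Tissue diffusivity in mm²/s, ≥ 0.
    Dstar : float
        Pseudo-diffusion coefficient in mm²/s, ≥ 0.
    """

    S0: float
    f: float
    D: float
    Dstar: float

    def __post_init__(self) -> None:
        if not (self.S0 > 0):
            raise ValueError(f"S0 must be > 0, got {self.S0}")
        if not (0.0 <= self.f <= 1.0):
            raise ValueError(f"f must lie in [0, 1], got {self.f}")
        if self.D < 0:
            raise ValueError(f"D must be >= 0, got {self.D}")
        if self.Dstar < 0:
            raise ValueError(f"Dstar must be >= 0, got {self.Dstar}")

    def is_physical(self) -> bool:
        """Whether the pseudo-diffusion coefficient exceeds the diffusivity.

        ``D* >= D`` is expected physically (perfusion decays faster) but is not
        enforced by the constructor; fits may legitimately land outside.
        """
        return bool(np.isfinite(self.Dstar) and np.isfinite(self.D) and self.Dstar >= self.D)

    def as_array(self) -> np.ndarray:
        return np.array([self.S0, self.f, self.D, self.Dstar], dtype=float)


#: b-values (s/mm²) of the default 12-point acquisition scheme.
_DEFAULT_B = (0.0, 10.0, 20.0, 30.0, 40.0, 50.0, 75.0, 100.0, 150.0, 250.0, 400.0, 600.0)
#: per-b number of (isotropically distributed) diffusion directions / repeats.
_DEFAULT_NDIR = (15, 9, 9, 9, 9, 9, 4, 12, 4, 4, 4, 16)


@dataclass
class BValueScheme:
    """Diffusion-weighting protocol: b-values and per-b direction counts."""

    b_values: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_B))
    n_directions: np.ndarray = field(default_factory=lambda: np.array(_DEFAULT_NDIR))

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.n_directions = np.asarray(self.n_directions, dtype=int)
        if self.b_values.ndim != 1 or self.b_values.size < 2:
            raise ValueError("need a 1-D array of at least two b-values")
        if self.b_values[0] != 0.0:
            raise ValueError("first b-value must be 0")
        if np.any(np.diff(self.b_values) <= 0):
            raise ValueError("b-values must be strictly increasing")
        if self.n_directions.shape != self.b_values.shape:
            raise ValueError("n_directions must align with b_values")
        if np.any(self.n_directions < 1):
            raise ValueError("direction counts must be positive")

    def __len__(self) -> int:
        return self.b_values.size

    @classmethod
    def default(cls) -> "BValueScheme":
        return cls()


@dataclass
class RelaxationConstants:
    """Sequence timing and tissue/blood relaxation times (ms) for the
    blood-volume-fraction conversion.

    Defaults are for pancreas at 3 T with a respiratory-triggered sequence:
    TE = 45 ms, TR = 5000 ms (typical respiratory cycle), tissue T1/T2 =
    725/43 ms, blood T1/T2 = 1932/275 ms.
    """

    TE: float = 45.0
    TR: float = 5000.0
    T1_tissue: float = 725.0
    T2_tissue: float = 43.0
    T1_blood: float = 1932.0
    T2_blood: float = 275.0

    def __post_init__(self) -> None:
        for name in ("TE", "TR", "T1_tissue", "T2_tissue", "T1_blood", "T2_blood"):
            if not (getattr(self, name) > 0):
                raise ValueError(f"{name} must be strictly positive")

    def tissue_weight(self) -> float:
        """Relaxation weighting exp(−TE/T2)·(1−exp(−TR/T1)) of tissue signal."""
        return math.exp(-self.TE / self.T2_tissue) * (1.0 - math.exp(-self.TR / self.T1_tissue))

    def blood_weight(self) -> float:
        """Relaxation weighting exp(−TE/T2)·(1−exp(−TR/T1)) of blood signal."""
        return math.exp(-self.TE / self.T2_blood) * (1.0 - math.exp(-self.TR / self.T1_blood))


@dataclass
class TransformedParams:
    """Log/logit re-parametrisation used by the hierarchical Bayesian fitter.

    f_logit = log(F) − log(1−F), d_log = log(D), dstar_log = log(D*); the
    transforms confine (F, D, D*) to their physical domain without hard
    constraints.
    """

    f_logit: float
    d_log: float
    dstar_log: float

    def as_array(self) -> np.ndarray:
        return np.array([self.f_logit, self.d_log, self.dstar_log], dtype=float)


def ivim_signal(params: IVIMParams, b) -> np.ndarray | float:
    """Noise-free IVIM model signal at diffusion weighting ``b``.

    S(b) = S0·[f·exp(−b·D*) + (1−f)·exp(−b·D)]; strictly positive and, for
    D*, D > 0, non-increasing in b. ``b`` may be scalar or array (s/mm²).
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0):
        raise ValueError("b-values must be non-negative")
    out = params.S0 * (
        params.f * np.exp(-b_arr * params.Dstar) + (1.0 - params.f) * np.exp(-b_arr * params.D)
    )
    if np.isscalar(b) or b_arr.ndim == 0:
        return float(out)
    return out


def ivim_signal_array(S0, f, D, Dstar, b: np.ndarray) -> np.ndarray:
    """Vectorised model evaluation; parameters broadcast against ``b``.

    Parameter arrays of shape ``(...,)`` against b of shape ``(nb,)`` give
    signals of shape ``(..., nb)``.
    """
    S0, f, D, Dstar = (np.asarray(x, dtype=float)[..., None] for x in (S0, f, D, Dstar))
    return S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D))


def blood_volume_fraction(f_signal, rc: RelaxationConstants | None = None):
    """Convert an IVIM signal fraction into a blood-volume fraction.

    The measured signal fraction weighs the blood compartment by its
    relaxation factor w_b = exp(−TE/T2_blood)·(1−exp(−TR/T1_blood)) and the
    tissue compartment by the analogous w_t. Undoing that weighting,

        f_blood = f·w_t / (f·w_t + (1−f)·w_b).

    The map is the identity when w_t = w_b, fixes 0 and 1, and is monotone
    increasing in ``f_signal``. Accepts scalars or arrays in [0, 1].
    """
    rc = rc or RelaxationConstants()
    f_arr = np.asarray(f_signal, dtype=float)
    if np.any((f_arr < 0) | (f_arr > 1)):
        raise ValueError("signal fraction must lie in [0, 1]")
    w_t = rc.tissue_weight()
    w_b = rc.blood_weight()
    num = f_arr * w_t
    out = num / (num + (1.0 - f_arr) * w_b)
    if np.isscalar(f_signal) or f_arr.ndim == 0:
        return float(out)
    return out


def to_transformed(params: IVIMParams) -> TransformedParams:
    """Forward transform (F, D, D*) → (logit F, log D, log D*).

    Raises ``ValueError`` at the non-transformable boundaries F∈{0,1}, D=0 or
    D*=0.
    """
    if not (0.0 < params.f < 1.0):
        raise ValueError("f must lie strictly inside (0, 1) for the logit transform")
    if params.D <= 0 or params.Dstar <= 0:
        raise ValueError("D and D* must be strictly positive for the log transform")
    return TransformedParams(
        f_logit=math.log(params.f) - math.log(1.0 - params.f),
        d_log=math.log(params.D),
        dstar_log=math.log(params.Dstar),
    )


def from_transformed(tp: TransformedParams, S0: float = 1.0) -> IVIMParams:
    """Inverse transform back to (F, D, D*); ``S0`` is carried through."""
    f = 1.0 / (1.0 + math.exp(-tp.f_logit))
    return IVIMParams(S0=S0, f=f, D=math.exp(tp.d_log), Dstar=math.exp(tp.dstar_log))
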