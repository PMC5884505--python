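"""Synthetic DWI study generation with known ground truth.

Emulates the structure of a test-retest pancreatic DWI study: per patient, a
tumour and a normal-tissue ROI of voxel-wise IVIM parameters drawn from
tissue-specific distributions; two scan sessions, the first with two
acquisitions (intra-session repeat) and the second with one; multiplicative
lognormal session/acquisition effects on the true parameters; bi-exponential
signals at the 12-point b-value scheme; independent Rician noise per
diffusion direction, then direction averaging.

Everything is deterministic given the spec seed, so parameter-recovery bias
and RMSE of every fitter can be measured against the retained truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitters import VoxelSeries
from .model import BValueScheme

__all__ = [
    "TissueRanges",
    "PhantomSpec",
    "StudyDataset",
    "generate_phantom",
    "add_rician_noise",
    "simulate_study",
    "write_fixture",
    "SESSION_DESIGN",
]

#: (session, acquisition) pairs of the study design: two acquisitions in
#: session 1 (the second used for intra-session analysis only), one in
#: session 2.
SESSION_DESIGN: tuple[tuple[int, int], ...] = ((1, 1), (1, 2), (2, 1))

_PARAMS = ("f", "D", "Dstar")


@dataclass
class TissueRanges:
    """Uniform ranges of the voxel-wise true parameters for one tissue."""

    f: tuple[float, float]
    D: tuple[float, float]
    Dstar: tuple[float, float]

    def __post_init__(self) -> None:
        for name in _PARAMS:
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise ValueError(f"{name} range must satisfy 0 <= lo <= hi")
        if self.f[1] > 1:
            raise ValueError("f range must stay within [0, 1]")


#: tumour-like defaults: envelope of poorly perfused pancreatic tumours
#: (f of a few %, D around 1.2×10⁻³ mm²/s, broad D*).
_TUMOUR = TissueRanges(f=(0.01, 0.07), D=(1.0e-3, 1.5e-3), Dstar=(15e-3, 100e-3))
#: normal-pancreas defaults: better perfused, slightly higher diffusivity.
#: These are package configuration, not measured values.
_NORMAL = TissueRanges(f=(0.04, 0.12), D=(1.2e-3, 1.8e-3), Dstar=(30e-3, 100e-3))


@dataclass
class PhantomSpec:
    """Design of a synthetic study.

    ``snr`` is the signal-to-noise ratio of the direction-averaged b = 0
    signal that enters the fits (per-direction noise is larger by
    √n_directions(b=0)); ``np.inf`` disables noise. Session and acquisition
    effects are multiplicative lognormal perturbations (mean 1, coefficient
    of variation as given) of each true parameter, shared by all voxels of a
    patient — so they survive ROI averaging, as scanner/physiology drift
    does.
    """

    n_patients: int = 14
    n_voxels_tumour: int = 210
    n_voxels_normal: int = 118
    tumour: TissueRanges = field(default_factory=lambda: TissueRanges(**vars(_TUMOUR).copy()))
    normal: TissueRanges = field(default_factory=lambda: TissueRanges(**vars(_NORMAL).copy()))
    snr: float = 20.0
    session_cv: float = 0.05
    acquisition_cv: float = 0.02
    S0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("need at least one patient")
        if self.n_voxels_tumour < 1 or self.n_voxels_normal < 0:
            raise ValueError("ROI sizes must be positive (normal may be 0)")
        if not (self.snr > 0):
            raise ValueError("SNR must be > 0 (np.inf for noise-free)")
        if self.session_cv < 0 or self.acquisition_cv < 0:
            raise ValueError("CVs must be non-negative")

    def roi_sizes(self) -> dict[str, int]:
        sizes = {"tumour": self.n_voxels_tumour}
        if self.n_voxels_normal:
            sizes["normal"] = self.n_voxels_normal
        return sizes


@dataclass
class StudyDataset:
    """Simulated (or loaded) study: long-format signals plus ground truth.

    ``data`` columns: patient, session, acquisition, roi, voxel_id, b_value,
    signal. ``truth`` (None for loaded patient data): the base voxel-wise
    parameters. ``truth_by_acquisition``: parameters after session /
    acquisition perturbation, i.e. the truth each acquisition actually
    realised.
    """

    data: pd.DataFrame
    scheme: BValueScheme
    truth: pd.DataFrame | None = None
    truth_by_acquisition: pd.DataFrame | None = None

    def voxel_series(self) -> list[VoxelSeries]:
        """All voxels as fitter-ready series (signals ordered by b-value)."""
        out: list[VoxelSeries] = []
        d = self.data.sort_values(["patient", "session", "acquisition", "roi", "voxel_id", "b_value"])
        nb = len(self.scheme)
        keys = d[["patient", "session", "acquisition", "roi", "voxel_id"]].to_numpy()[::nb]
        sig = d["signal"].to_numpy().reshape(-1, nb)
        for (pat, ses, acq, roi, vid), s in zip(keys, sig):
            out.append(VoxelSeries(signals=s, voxel_id=int(vid), roi_label=str(roi),
                                   patient=int(pat), session=int(ses), acquisition=int(acq)))
        return out

    def true_roi_means(self) -> pd.DataFrame | None:
        """ROI means of the perturbed true parameters, per acquisition."""
        if self.truth_by_acquisition is None:
            return None
        return (
            self.truth_by_acquisition.groupby(["patient", "session", "acquisition", "roi"])[
                list(_PARAMS)
            ]
            .mean()
            .reset_index()
        )


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the base voxel-wise true parameters for every patient and ROI."""
    rng = rng or np.random.default_rng(spec.seed)
    rows = []
    for patient in range(1, spec.n_patients + 1):
        for roi, n_vox in spec.roi_sizes().items():
            ranges = spec.tumour if roi == "tumour" else spec.normal
            draws = {
                name: rng.uniform(*getattr(ranges, name), size=n_vox) for name in _PARAMS
            }
            rows.append(
                pd.DataFrame(
                    {
                        "patient": patient,
                        "roi": roi,
                        "voxel_id": np.arange(n_vox),
                        "S0": spec.S0,
                        **draws,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def add_rician_noise(signal, sigma: float, rng: np.random.Generator) -> np.ndarray | float:
    """Rician magnitude noise: |(S + n1) + i·n2| with n1, n2 ~ N(0, σ²).

    ``sigma = 0`` returns the input unchanged. At S = 0 the output is
    Rayleigh distributed (mean σ·√(π/2)); at S ≫ σ the mean approaches S.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return signal
    n1 = rng.normal(0.0, sigma, size=s.shape)
    n2 = rng.normal(0.0, sigma, size=s.shape)
    out = np.hypot(s + n1, n2)
    if np.isscalar(signal):
        return float(out)
    return out


def _lognormal_factor(cv: float, rng: np.random.Generator, size=None):
    """Multiplicative mean-1 lognormal factor with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = np.log1p(cv**2)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def simulate_study(spec: PhantomSpec, scheme: BValueScheme | None = None) -> StudyDataset:
    """Simulate the full test-retest study defined by ``spec``.

    Per acquisition, each patient's voxel truths are perturbed by the
    session- and acquisition-level lognormal factors (one factor per
    parameter per patient×session and per acquisition, shared across the
    patient's voxels), signals are generated at the b-value scheme, and each
    direction replicate is noised independently before averaging — so the
    effective noise at a b-value scales as 1/√n_directions.
    """
    scheme = scheme or BValueScheme.default()
    rng = np.random.default_rng(spec.seed)
    base = generate_phantom(spec, rng)
    b = scheme.b_values
    ndir = scheme.n_directions
    sigma_dir = 0.0 if np.isinf(spec.snr) else (spec.S0 / spec.snr) * np.sqrt(ndir[0])

    data_rows = []
    truth_rows = []
    for patient, pat_truth in base.groupby("patient"):
        session_factors = {
            ses: {p: _lognormal_factor(spec.session_cv, rng) for p in _PARAMS} for ses in (1, 2)
        }
        for ses, acq in SESSION_DESIGN:
            acq_factors = {p: _lognormal_factor(spec.acquisition_cv, rng) for p in _PARAMS}
            pert = pat_truth.copy()
            for p in _PARAMS:
                pert[p] = pert[p] * session_factors[ses][p] * acq_factors[p]
            pert["f"] = pert["f"].clip(upper=0.999)
            pert["session"] = ses
            pert["acquisition"] = acq
            truth_rows.append(pert)

            S0 = pert["S0"].to_numpy()[:, None]
            f = pert["f"].to_numpy()[:, None]
            D = pert["D"].to_numpy()[:, None]
            Dstar = pert["Dstar"].to_numpy()[:, None]
            clean = S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D))  # (V, nb)
            if sigma_dir == 0:
                avg = clean
            else:
                avg = np.empty_like(clean)
                for j, nd in enumerate(ndir):
                    reps = np.repeat(clean[:, [j]], nd, axis=1)
                    avg[:, j] = add_rician_noise(reps, sigma_dir, rng).mean(axis=1)
            nb = b.size
            nvox = len(pert)
            data_rows.append(
                pd.DataFrame(
                    {
                        "patient": np.repeat(int(patient), nvox * nb),
                        "session": ses,
                        "acquisition": acq,
                        "roi": np.repeat(pert["roi"].to_numpy(), nb),
                        "voxel_id": np.repeat(pert["voxel_id"].to_numpy(), nb),
                        "b_value": np.tile(b, nvox),
                        "signal": avg.ravel(),
                    }
                )
            )

    data = pd.concat(data_rows, ignore_index=True)
    truth_by_acq = pd.concat(truth_rows, ignore_index=True)[
        ["patient", "session", "acquisition", "roi", "voxel_id", "S0", "f", "D", "Dstar"]
    ]
    return StudyDataset(data=data, scheme=scheme, truth=base, truth_by_acquisition=truth_by_acq)


def write_fixture(dataset: StudyDataset, path: str | Path) -> list[Path]:
    """Write a dataset as CSV files (study.csv, scheme.csv, truth sidecars).

    Round-trips losslessly through :func:`ivimkit.io.read_study`.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    study_path = path / "study.csv"
    dataset.data.sort_values(
        ["patient", "session", "acquisition", "roi", "voxel_id", "b_value"]
    ).to_csv(study_path, index=False)
    written.append(study_path)
    scheme_path = path / "scheme.csv"
    pd.DataFrame(
        {"b_value": dataset.scheme.b_values, "n_directions": dataset.scheme.n_directions}
    ).to_csv(scheme_path, index=False)
    written.append(scheme_path)
    if dataset.truth is not None:
        truth_path = path / "truth.csv"
        dataset.truth.to_csv(truth_path, index=False)
        written.append(truth_path)
    if dataset.truth_by_acquisition is not None:
        tba_path = path / "truth_by_acquisition.csv"
        dataset.truth_by_acquisition.to_csv(tba_path, index=False)
        written.append(tba_path)
    return written
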