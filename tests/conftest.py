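import numpy as np
import pytest

from ivimkit import BValueScheme, IVIMParams, VoxelSeries, add_rician_noise
from ivimkit.model import ivim_signal


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    return BValueScheme.default()


@pytest.fixture(scope="session")
def tumour_params() -> IVIMParams:
    """A tumour-like voxel: low perfusion fraction, moderate diffusivity."""
    return IVIMParams(S0=1.0, f=0.05, D=1.2e-3, Dstar=70e-3)


@pytest.fixture(scope="session")
def clean_series(scheme, tumour_params) -> VoxelSeries:
    return VoxelSeries(signals=ivim_signal(tumour_params, scheme.b_values))


def make_noisy_voxels(params: IVIMParams, scheme: BValueScheme, n: int, snr: float,
                      seed: int) -> list[VoxelSeries]:
    """Direction-replicated Rician noise, averaged, at b=0 SNR ``snr``."""
    rng = np.random.default_rng(seed)
    clean = ivim_signal(params, scheme.b_values)
    sigma_dir = (params.S0 / snr) * np.sqrt(scheme.n_directions[0])
    out = []
    for i in range(n):
        avg = np.empty(len(scheme))
        for j, nd in enumerate(scheme.n_directions):
            avg[j] = add_rician_noise(np.full(nd, clean[j]), sigma_dir, rng).mean()
        out.append(VoxelSeries(signals=avg, voxel_id=i))
    return out
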