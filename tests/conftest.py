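import numpy as np
import pytest

from fretpipe.trace_sim import IntensityTrace, SimParams


@pytest.fixture
def noiseless_params():
    """Symmetric, noise-free, bleach-free acquisition: analytic levels exact."""
    return SimParams(
        n_molecules=5,
        n_frames=100,
        states=((0.5, 1.0),),
        total_intensity=100.0,
        noise_sd=0.0,
        gamma_mean=1.0,
        gamma_sd=0.0,
        donor_bleach_rate=0.0,
        acceptor_bleach_rate=0.0,
        background=0.0,
        seed=7,
    )


def make_step_trace(
    n_frames=200,
    a_bleach=80,
    d_bleach=150,
    e=0.6,
    gamma=1.0,
    total=100.0,
    noise_sd=0.0,
    background=0.0,
    seed=0,
    molecule_id="constructed",
):
    """Hand-built trace with ideal photobleaching steps at known frames."""
    rng = np.random.default_rng(seed)
    donor = np.full(n_frames, total * (1 - e) / gamma)
    acceptor = np.full(n_frames, total * e)
    if a_bleach is not None:
        acceptor[a_bleach:] = 0.0
        donor[a_bleach:] = total / gamma
    if d_bleach is not None:
        donor[d_bleach:] = 0.0
        if a_bleach is None or d_bleach < a_bleach:
            acceptor[d_bleach:] = 0.0
    donor = donor + background
    acceptor = acceptor + background
    if noise_sd > 0:
        donor = donor + rng.normal(0, noise_sd, n_frames)
        acceptor = acceptor + rng.normal(0, noise_sd, n_frames)
    return IntensityTrace(molecule_id=molecule_id, donor=donor, acceptor=acceptor)
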