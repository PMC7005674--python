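import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from smtirfkit.simkit import (
    BindingModel,
    FretStateModel,
    IlluminationScheme,
    OpticsModel,
    PhotophysicsModel,
    TraceNoise,
    random_positions,
    render_movie,
    simulate_binding_timeline,
    simulate_fret_trace,
)

REF_BETA = 0.073
REF_GAMMA = 0.423


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fast_illum():
    """Quasi-continuous camera timing (100 ms on / 0.3 ms off)."""
    return IlluminationScheme(t_on_ms=100.0, t_off_ms=0.3, n_frames=600)


@pytest.fixture
def strobe_illum():
    """Duty-cycled timing used for long-dwell movies (100 ms on / 600 ms off)."""
    return IlluminationScheme(t_on_ms=100.0, t_off_ms=600.0, n_frames=1500)


@pytest.fixture
def noiseless_optics():
    return OpticsModel(
        image_size=(48, 48), background_level=0.0, read_noise_sd=0.0, shot_noise=False
    )


@pytest.fixture
def small_movie(fast_illum):
    """5-molecule noisy movie with ground-truth sidecar."""
    illum = IlluminationScheme(t_on_ms=100.0, t_off_ms=0.3, n_frames=400)
    binding = BindingModel(on_rate=0.25, off_components=((1.0, 2.0),))
    streams = np.random.SeedSequence(7).spawn(6)
    timelines = [
        simulate_binding_timeline(
            binding, PhotophysicsModel(), illum, seed=np.random.default_rng(s)
        )
        for s in streams[:5]
    ]
    optics = OpticsModel(image_size=(64, 64), background_level=100.0, read_noise_sd=10.0)
    positions = random_positions(5, (64, 64), margin=8, min_separation=12, rng=3)
    movie = render_movie(
        timelines, optics, illum, positions=positions, seed=np.random.default_rng(streams[5])
    )
    return movie, timelines


def make_fret_trace(
    e_levels=((0.3, 3000.0), (0.5, 3000.0)),
    rate=1.0,
    n_frames=600,
    noise=None,
    donor_bleach_rate=0.0,
    acceptor_bleach_rate=0.0,
    seed=0,
    gamma=REF_GAMMA,
    beta=REF_BETA,
):
    n = len(e_levels)
    rates = tuple(
        tuple(rate if i != j else 0.0 for j in range(n)) for i in range(n)
    )
    model = FretStateModel(
        states=tuple(e_levels),
        transition_rates=rates if n > 1 else (),
        gamma_true=gamma,
        beta_true=beta,
        donor_bleach_rate=donor_bleach_rate,
        acceptor_bleach_rate=acceptor_bleach_rate,
    )
    illum = IlluminationScheme(t_on_ms=100.0, t_off_ms=0.3, n_frames=n_frames)
    noise = noise if noise is not None else TraceNoise()
    return simulate_fret_trace(model, illum, noise=noise, seed=seed), illum
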