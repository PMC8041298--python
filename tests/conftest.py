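import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from torsionlsq import (
    DihedralTyping,
    FourierParams,
    build_design_system,
    dmph_typing,
    generate_dataset,
    random_params,
)


@pytest.fixture(scope="session")
def dmph():
    return dmph_typing()


@pytest.fixture(scope="session")
def single_type():
    return DihedralTyping(type_of=(0,))


@pytest.fixture(scope="session")
def noiseless_dmph(dmph):
    params = random_params(dmph, n_terms=4, seed=11)
    dataset = generate_dataset(dmph, params, noise_sd=0.0, seed=11)
    return dataset, params


@pytest.fixture(scope="session")
def noisy_dmph(dmph):
    params = random_params(dmph, n_terms=4, seed=7)
    dataset = generate_dataset(dmph, params, noise_sd=0.5, seed=7)
    return dataset, params


def random_system(rng, n_conf=30, n_types=2, n_terms=4, offset=True):
    """Small random design system built from a random synthetic scan."""
    type_of = tuple(rng.integers(0, n_types, size=n_types + 2).tolist())
    # guarantee every type used
    type_of = tuple(list(range(n_types)) + list(type_of))
    typing = DihedralTyping(type_of=type_of)
    params = FourierParams(
        k=rng.uniform(-5, 5, size=(n_types, n_terms)),
        offset=float(rng.normal()) if offset else None,
    )
    dataset = generate_dataset(
        typing,
        params,
        grid_step=360.0 / n_conf,
        coupling="random",
        noise_sd=1.0,
        seed=int(rng.integers(2**31)),
    )
    return build_design_system(dataset, n_terms=n_terms, include_offset=offset)
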