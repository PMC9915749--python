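import numpy as np
import pytest

from fibrilsim import BuildConfig, assemble_fibril, default_forcefield


@pytest.fixture(scope="session")
def forcefield():
    return default_forcefield()


@pytest.fixture(scope="session")
def tiny_geometry():
    """The tiny-preset fibril geometry (a few hundred particles)."""
    from fibrilsim.presets import make_preset

    return assemble_fibril(make_preset("tiny").build)


@pytest.fixture(scope="session")
def parallel_bundle_config():
    """Unstaggered bundle of full molecules with bare telopeptide ends.

    Every molecule is complete (two physiological ends) and axially aligned,
    which makes the cross-link counting rules exact.
    """
    return BuildConfig(
        fibril_diameter=67.0,
        n_d_periods=1,
        d_period=210.0,
        particles_per_molecule=37,
        n_extension_particles=0,
        n_clamp_particles=0,
        truncate=False,
    )


@pytest.fixture(scope="session")
def parallel_bundle(parallel_bundle_config):
    return assemble_fibril(parallel_bundle_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
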