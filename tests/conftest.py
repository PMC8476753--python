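import pytest

from tapromp import PhaseGrid, SyntheticConfig


@pytest.fixture(scope="session")
def grid() -> PhaseGrid:
    return PhaseGrid.uniform(100)


@pytest.fixture
def fast_config():
    """Reduced-rate generation config for desk-scale runs (protocol otherwise)."""

    def make(**overrides) -> SyntheticConfig:
        kwargs = {"sampling_rate": 250.0}
        kwargs.update(overrides)
        return SyntheticConfig(**kwargs)

    return make


@pytest.fixture
def clean_config(fast_config):
    """Noiseless, jitter-free config: every stroke equals the template."""

    def make(**overrides) -> SyntheticConfig:
        kwargs = {
            "noise_std": 0.0,
            "duration_jitter": 0.0,
            "amplitude_cv": 0.0,
            "shape_cv": 0.0,
        }
        kwargs.update(overrides)
        return fast_config(**kwargs)

    return make
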