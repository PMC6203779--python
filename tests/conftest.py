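"""Shared fixtures and deterministic hypothesis configuration."""

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")

from divtx import synthetic_data  # noqa: E402


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A reduced-size synthetic bundle for fast structural checks."""
    cfg = synthetic_data.SimConfig(
        n_promoters=40,
        n_enhancers=10,
        chrom_sizes={"chr1": 100_000, "chr2": 100_000},
    )
    out = tmp_path_factory.mktemp("small_bundle")
    return synthetic_data.generate(3, cfg, str(out))


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory):
    """The full default-condition synthetic bundle (600 promoters, 200 enhancers)."""
    out = tmp_path_factory.mktemp("default_bundle")
    return synthetic_data.generate(11, None, str(out))
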