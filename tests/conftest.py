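import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def probes():
    """The packaged 19-probe scFISH set."""
    from dachroma.genomic_core import load_scfish_probes

    return load_scfish_probes()


@pytest.fixture(scope="session")
def domains_and_singletons(probes):
    from dachroma.domain_tads import build_domains

    return build_domains(probes)
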