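import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from dirseq.datasets import write_demo_manifest
from dirseq.design import build_constructs, load_snp_manifest


@pytest.fixture(scope="session")
def manifest_path(tmp_path_factory):
    return write_demo_manifest(tmp_path_factory.mktemp("manifest") / "snps.tsv")


@pytest.fixture(scope="session")
def records(manifest_path):
    return load_snp_manifest(manifest_path)


@pytest.fixture(scope="session")
def constructs(records):
    return build_constructs(records)
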