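import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")

from dpiscope.core_io import ProteinRecord, ResidueTrack


def make_record(pid="P1", length=100, tracks=None, counts=None, sequence=None):
    rec = ProteinRecord(id=pid, length=length, sequence=sequence, counts=counts or {})
    for name, segs in (tracks or {}).items():
        rec.tracks[name] = ResidueTrack(name, length, segs)
    return rec


@pytest.fixture
def record_factory():
    return make_record


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study shared by read-only tests."""
    from dpiscope.synthetic_data import GeneratorConfig, generate_feature_table

    cfg = GeneratorConfig(size_factor=0.03)
    table, coll = generate_feature_table(cfg, seed=11)
    return cfg, table, coll
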