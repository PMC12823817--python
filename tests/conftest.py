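import pytest
from hypothesis import HealthCheck, settings

from faersig.records import AEReport
from faersig.synthetic_data import write_fixture_suite

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def micro4():
    """Four hand-enumerated reports: multi-drug, multi-PT, two target-event cases."""
    return [
        AEReport("101", "1", 20240115, sex="F", age_years=55.0, weight_kg=70.0,
                 reporter="consumer", country="United States", outcome="HO",
                 drugs=[("drug a", "PS"), ("drug b", "SS")],
                 reactions={"peroneal nerve palsy", "nausea", "headache"}),
        AEReport("201", "2", 20240120, sex="M", age_years=60.0,
                 reporter="health-professional", country="Canada", outcome="OT",
                 drugs=[("drug a", "PS")], reactions={"nausea"}),
        AEReport("301", "3", 20240201, sex="F",
                 drugs=[("drug c", "PS"), ("drug b", "C")],
                 reactions={"radial nerve palsy"}),
        AEReport("401", "4", 20240210, sex="M", age_years=20.0,
                 drugs=[("drug b", "PS")], reactions={"rash", "fatigue"}),
    ]


@pytest.fixture(scope="session")
def fixture_dirs(tmp_path_factory):
    return write_fixture_suite(tmp_path_factory.mktemp("fixtures"))
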