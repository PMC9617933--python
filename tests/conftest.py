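import pytest

from dbsteer.lead import LeadGeometry
from dbsteer.optimizer import AlgorithmConfig
from dbsteer.scoring import SymptomAssessment, select_symptoms


@pytest.fixture
def geometry():
    return LeadGeometry()


@pytest.fixture
def config():
    return AlgorithmConfig()


@pytest.fixture
def two_symptom_spec():
    return select_symptoms(
        [
            SymptomAssessment(name="rigidity", baseline_off=4.0, baseline_on=0.0),
            SymptomAssessment(name="tremor", baseline_off=2.0, baseline_on=0.0),
        ]
    )
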