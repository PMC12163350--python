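import pandas as pd
import pytest

import facsurvey as fs


@pytest.fixture(scope="session")
def default_data() -> fs.SurveyData:
    """One default synthetic survey draw (seed 1), shared across tests."""
    return fs.simulate_survey()


@pytest.fixture(scope="session")
def pipeline_result(default_data) -> fs.PipelineResult:
    """Full in-memory pipeline run on the default configuration."""
    return fs.run_pipeline(data=default_data)


def make_responses(rows: list[dict]) -> pd.DataFrame:
    """Minimal hand-built response table for status-coding tests."""
    defaults = {"instrument": "none", "mode": "none", "completed": False,
                "accessed": False, "address_verified_only": False,
                "valid_response_count": 0}
    return pd.DataFrame([{**defaults, **r} for r in rows])
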