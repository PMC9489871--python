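from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ehrfusion import (
    ImageStudy,
    NoteDocument,
    PatientFile,
    SourceRegistry,
    stub_image_model,
    stub_text_encoder,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

ADMIT = datetime(2001, 6, 1)


@pytest.fixture(scope="session")
def registry() -> SourceRegistry:
    return SourceRegistry.default()


@pytest.fixture(scope="session")
def text_encoder():
    return stub_text_encoder(seed=0)


@pytest.fixture(scope="session")
def image_model():
    return stub_image_model(seed=0)


def make_event_table(rows):
    return pd.DataFrame(rows, columns=["signal_name", "time_hours", "value"]).astype(
        {"signal_name": str, "time_hours": float, "value": float}
    )


def make_patient_file(
    *,
    patient_id="p1",
    stay_id="p1-s0",
    event_rows=(),
    notes=None,
    study_times=(10.0,),
    images_per_study=1,
    discharge_hours=None,
    death_hours=None,
    demographics=None,
    ground_truth=None,
    image_value=128,
):
    rng = np.random.default_rng(0)
    studies = [
        ImageStudy(
            time_hours=float(t),
            images=tuple(
                np.full((16, 16), image_value, dtype=np.uint8)
                for _ in range(images_per_study)
            ),
        )
        for t in study_times
    ]
    return PatientFile(
        patient_id=patient_id,
        stay_id=stay_id,
        admit_time=ADMIT,
        discharge_time=(
            ADMIT + timedelta(hours=discharge_hours)
            if discharge_hours is not None
            else None
        ),
        death_time=(
            ADMIT + timedelta(hours=death_hours) if death_hours is not None else None
        ),
        demographics=dict(demographics or {"age": 60.0, "sex_code": 1.0}),
        event_tables={"ce": make_event_table(list(event_rows))} if event_rows else {},
        notes=dict(notes or {}),
        image_studies=studies,
        pathology_ground_truth=dict(ground_truth or {}),
    )
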