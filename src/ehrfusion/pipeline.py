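"""End-to-end glue: patient files → windowed per-source embedding matrices.

This is the stage boundary at which a real extracted-embedding store can
replace the synthetic path: downstream (experiments, attribution) only sees
per-source matrices, labels and patient ids.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .extractors import (
    ImageModelContract,
    TextEncoderContract,
    embed_patient,
)
from .patient_record import PatientFile, window_events
from .registry import SourceRegistry
from .tasks import TaskSpec, label_samples


@dataclass
class TaskDataset:
    """Aligned per-source matrices, labels and patient ids for one task."""

    X: dict[str, np.ndarray]          # source name → (n_samples, dim)
    y: np.ndarray                     # binary labels
    patient_ids: np.ndarray
    samples: pd.DataFrame             # eligible labeled samples, row-aligned
    registry: SourceRegistry          # restricted to the task's allowed sources
    presence: pd.DataFrame            # per-sample per-source presence flags

    @property
    def n_samples(self) -> int:
        return len(self.y)


def extract_task_dataset(
    files: Sequence[PatientFile],
    task: TaskSpec,
    registry: SourceRegistry,
    text_encoder: Optional[TextEncoderContract] = None,
    image_model: Optional[ImageModelContract] = None,
) -> TaskDataset:
    """Label, window and embed every eligible sample of a task.

    For each eligible (stay, t) sample the record is windowed at t
    (boundary inclusive) and every allowed source is embedded; sources
    excluded by the task (radiology notes for pathology targets) are
    dropped from the registry entirely.
    """
    allowed = registry.restrict(
        [n for n in registry.names if n not in task.excluded_sources]
    )
    labels = label_samples(files, task)
    eligible = labels[labels["eligible"]].reset_index(drop=True)
    if eligible.empty:
        raise ValueError(f"task {task.name!r} has no eligible samples")
    by_stay = {f.stay_id: f for f in files}

    columns: dict[str, list[np.ndarray]] = {n: [] for n in allowed.names}
    presence_rows = []
    for _, row in eligible.iterrows():
        file = by_stay[row["stay_id"]]
        view = window_events(file, float(row["t_hours"]))
        emb = embed_patient(view, allowed, text_encoder, image_model)
        for name in allowed.names:
            columns[name].append(emb.vectors[name])
        presence_rows.append(emb.presence)

    return TaskDataset(
        X={name: np.vstack(vecs) for name, vecs in columns.items()},
        y=eligible["label"].to_numpy(dtype=int),
        patient_ids=eligible["patient_id"].to_numpy(dtype=str),
        samples=eligible,
        registry=allowed,
        presence=pd.DataFrame(presence_rows),
    )
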