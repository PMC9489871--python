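"""Binary labels and eligibility filters for the predictive tasks.

Twelve tasks are supported in the default configuration: ten chest-pathology
diagnosis tasks (one per pathology, anchored at image-study times, with the
radiology-note source excluded from the allowable inputs to avoid target
leakage), a 48 h length-of-stay task and a 48 h mortality task (both
anchored at end-of-day points).

The operational labels are causal: the outcome window is ``(t, t + 48]`` —
an event must happen strictly after the sampling point and no later than
48 h after it (boundary inclusive) to count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import pandas as pd

from .patient_record import PatientFile, extract_samples

HORIZON_HOURS = 48.0

PATHOLOGIES: tuple[str, ...] = (
    "fracture",
    "lung_lesion",
    "enlarged_cardiomediastinum",
    "consolidation",
    "pneumonia",
    "lung_opacity",
    "atelectasis",
    "pneumothorax",
    "edema",
    "cardiomegaly",
)

TaskKind = Literal["pathology", "los48", "mortality48"]


@dataclass(frozen=True)
class TaskSpec:
    """One predictive task: its kind, anchor rule and excluded sources."""

    name: str
    kind: TaskKind
    excluded_sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.kind == "pathology" and "radn" not in self.excluded_sources:
            raise ValueError(
                "pathology tasks must exclude the radiology-note source"
            )
        if self.kind in ("los48", "mortality48") and self.excluded_sources:
            raise ValueError("operational tasks exclude no sources")

    @property
    def anchor(self) -> str:
        return "image_time" if self.kind == "pathology" else "end_of_day"


def pathology_task(name: str) -> TaskSpec:
    return TaskSpec(name=name, kind="pathology", excluded_sources=frozenset({"radn"}))


def default_tasks() -> tuple[TaskSpec, ...]:
    """The 12-task reference configuration."""
    return tuple(pathology_task(p) for p in PATHOLOGIES) + (
        TaskSpec(name="los48", kind="los48"),
        TaskSpec(name="mortality48", kind="mortality48"),
    )


def label_pathology(value: Optional[int]) -> Optional[int]:
    """Map a 4-state study finding to a binary label or drop.

    Confirmed present (1) and confirmed absent (0) are kept; inconclusive
    (−1) and unexplored (``None``) samples are dropped (returns ``None``).
    """
    if value is None:
        return None
    if value == 1:
        return 1
    if value == 0:
        return 0
    if value == -1:
        return None
    raise ValueError(f"pathology ground truth must be in {{1, 0, -1, None}}, got {value!r}")


def label_los48(
    t: float,
    discharge_hours: Optional[float],
    death_hours: Optional[float],
) -> int:
    """1 iff the patient is discharged alive within (t, t+48]; death ⇒ 0."""
    if discharge_hours is not None and discharge_hours < t:
        raise ValueError(
            f"discharge at {discharge_hours} h precedes sampling time {t} h"
        )
    if death_hours is not None and death_hours < t:
        raise ValueError(f"death at {death_hours} h precedes sampling time {t} h")
    if death_hours is not None:
        return 0
    if discharge_hours is None:
        return 0
    return int(t < discharge_hours <= t + HORIZON_HOURS)


def label_mortality48(t: float, death_hours: Optional[float]) -> int:
    """1 iff death occurs within (t, t+48]; no recorded death ⇒ 0."""
    if death_hours is None:
        return 0
    if death_hours < t:
        raise ValueError(f"death at {death_hours} h precedes sampling time {t} h")
    return int(t < death_hours <= t + HORIZON_HOURS)


LABEL_COLUMNS = ("patient_id", "stay_id", "t_hours", "task", "label", "eligible")


def label_samples(
    files: Sequence[PatientFile], task: TaskSpec
) -> pd.DataFrame:
    """Anchor samples per the task rule and label each one.

    Returns a table with columns ``patient_id, stay_id, t_hours, task,
    label, eligible``.  Ineligible rows (dropped pathology findings, or
    operational samples at/after the recorded outcome) carry ``label = -1``
    and must never enter training or testing.
    """
    rows = []
    for file in files:
        for sample in extract_samples(file, anchor=task.anchor):
            t = sample.time_hours
            eligible = True
            label = -1
            if task.kind == "pathology":
                raw = file.pathology_ground_truth.get(task.name)
                binary = label_pathology(raw)
                if binary is None:
                    eligible = False
                else:
                    label = binary
            else:
                death = file.death_hours
                discharge = file.discharge_hours
                # a day boundary at/after the recorded exit is not a valid
                # prediction point: the stay has already ended
                exit_hours = death if death is not None else discharge
                if exit_hours is not None and t >= exit_hours:
                    eligible = False
                elif task.kind == "los48":
                    label = label_los48(t, discharge, death)
                else:
                    label = label_mortality48(t, death)
            rows.append(
                (sample.patient_id, sample.stay_id, t, task.name, label, eligible)
            )
    return pd.DataFrame(rows, columns=LABEL_COLUMNS)
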