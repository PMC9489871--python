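"""Patient-centric multimodal record container.

One :class:`PatientFile` holds everything recorded for a single hospital
admission: demographics, irregular time-stamped event tables, free-text
notes, image studies, and outcome timestamps.  All within-stay times are
real-valued hours since admission.  The on-disk format is an open directory
container::

    <stay>/
      manifest.json            # ids, timestamps, demographics, note/study index
      events/<source>.csv      # signal_name,time_hours,value
      notes/<source>/<k>.txt
      images/study_<i>/img_<k>.png

Images are stored as 8- or 16-bit grayscale PNGs; the round trip
``save_patient_file`` → ``load_patient_file`` is lossless.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from PIL import Image

EVENT_COLUMNS = ("signal_name", "time_hours", "value")

MANIFEST_NAME = "manifest.json"


class PatientRecordError(Exception):
    """Base class for container errors."""


class FormatError(PatientRecordError):
    """The container layout or manifest cannot be parsed."""


class RecordValidationError(PatientRecordError):
    """A record violates a container invariant."""


@dataclass(frozen=True)
class NoteDocument:
    """One free-text note at a time point (hours since admission)."""

    time_hours: float
    text: str


@dataclass(frozen=True)
class ImageStudy:
    """One imaging study: possibly several planes acquired at one time."""

    time_hours: float
    images: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if len(self.images) == 0:
            raise RecordValidationError("image study must contain >=1 image")


@dataclass(frozen=True)
class Sample:
    """One (stay, inference-time) prediction point."""

    patient_id: str
    stay_id: str
    time_hours: float


@dataclass
class PatientFile:
    """All multimodal data recorded for one hospital admission."""

    patient_id: str
    stay_id: str
    admit_time: datetime
    discharge_time: Optional[datetime] = None
    death_time: Optional[datetime] = None
    demographics: dict[str, float] = field(default_factory=dict)
    event_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    notes: dict[str, list[NoteDocument]] = field(default_factory=dict)
    image_studies: list[ImageStudy] = field(default_factory=list)
    pathology_ground_truth: dict[str, int] = field(default_factory=dict)

    def _hours_since_admit(self, when: Optional[datetime]) -> Optional[float]:
        if when is None:
            return None
        return (when - self.admit_time).total_seconds() / 3600.0

    @property
    def discharge_hours(self) -> Optional[float]:
        return self._hours_since_admit(self.discharge_time)

    @property
    def death_hours(self) -> Optional[float]:
        return self._hours_since_admit(self.death_time)


def validate_event_table(name: str, table: pd.DataFrame, stay_id: str) -> None:
    if tuple(table.columns) != EVENT_COLUMNS:
        raise FormatError(
            f"event table {name!r} of stay {stay_id!r} must have columns "
            f"{EVENT_COLUMNS}, got {tuple(table.columns)}"
        )
    times = table["time_hours"].to_numpy(dtype=float)
    values = table["value"].to_numpy(dtype=float)
    if not np.all(np.isfinite(times)):
        raise RecordValidationError(
            f"non-finite event time in table {name!r} of stay {stay_id!r}"
        )
    if np.any(times < 0):
        raise RecordValidationError(
            f"event before admission (negative time) in table {name!r} "
            f"of stay {stay_id!r}"
        )
    if not np.all(np.isfinite(values)):
        raise RecordValidationError(
            f"non-finite event value in table {name!r} of stay {stay_id!r}"
        )


def validate_patient_file(file: PatientFile, *, require_image: bool = True) -> None:
    """Check every container invariant; raise a named error on violation."""
    sid = file.stay_id
    for when, what in ((file.discharge_time, "discharge"), (file.death_time, "death")):
        if when is not None and when < file.admit_time:
            raise RecordValidationError(
                f"{what} time before admission in stay {sid!r}"
            )
    for name, table in file.event_tables.items():
        validate_event_table(name, table, sid)
    for source, docs in file.notes.items():
        for doc in docs:
            if not math.isfinite(doc.time_hours) or doc.time_hours < 0:
                raise RecordValidationError(
                    f"note before admission in source {source!r} of stay {sid!r}"
                )
    if require_image and len(file.image_studies) == 0:
        raise RecordValidationError(
            f"stay {sid!r} has no image study (at least one is required)"
        )
    for i, study in enumerate(file.image_studies):
        if not math.isfinite(study.time_hours) or study.time_hours < 0:
            raise RecordValidationError(
                f"image study {i} before admission in stay {sid!r}"
            )
        for k, img in enumerate(study.images):
            arr = np.asarray(img)
            if arr.ndim != 2 or arr.size == 0:
                raise RecordValidationError(
                    f"image {k} of study {i} in stay {sid!r} is not a "
                    "non-empty 2-D array"
                )
            if not np.all(np.isfinite(arr.astype(np.float64))):
                raise RecordValidationError(
                    f"non-finite intensities in image {k} of study {i} "
                    f"of stay {sid!r}"
                )
    for name, value in file.pathology_ground_truth.items():
        if value not in (1, 0, -1):
            raise RecordValidationError(
                f"pathology ground truth {name!r}={value!r} of stay {sid!r} "
                "outside {1, 0, -1}"
            )


# ---------------------------------------------------------------------------
# on-disk container
# ---------------------------------------------------------------------------

def _save_image(arr: np.ndarray, path: Path) -> None:
    arr = np.asarray(arr)
    if arr.dtype == np.uint8:
        img = Image.fromarray(arr, mode="L")
    elif arr.dtype == np.uint16:
        img = Image.fromarray(arr, mode="I;16")
    else:
        raise RecordValidationError(
            f"container images must be uint8 or uint16, got {arr.dtype} "
            f"for {path.name}"
        )
    img.save(path, format="PNG")


def _load_image(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            img.load()
            if img.mode in ("L", "P"):
                return np.asarray(img.convert("L"), dtype=np.uint8)
            if img.mode in ("I;16", "I"):
                return np.asarray(img, dtype=np.uint16)
            return np.asarray(img.convert("L"), dtype=np.uint8)
    except (OSError, ValueError) as exc:
        raise PatientRecordError(f"unreadable image file {path}") from exc


def save_patient_file(file: PatientFile, path: str | Path) -> Path:
    """Write a validated :class:`PatientFile` as a directory container.

    The manifest is written with sorted keys so that save → load → save is
    byte-identical.
    """
    validate_patient_file(file)
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "schema_version": 1,
        "patient_id": file.patient_id,
        "stay_id": file.stay_id,
        "admit_time": file.admit_time.isoformat(),
        "demographics": {k: float(v) for k, v in sorted(file.demographics.items())},
        "pathology_ground_truth": {
            k: int(v) for k, v in sorted(file.pathology_ground_truth.items())
        },
    }
    if file.discharge_time is not None:
        manifest["discharge_time"] = file.discharge_time.isoformat()
    if file.death_time is not None:
        manifest["death_time"] = file.death_time.isoformat()

    events_dir = root / "events"
    manifest["event_sources"] = sorted(file.event_tables)
    if file.event_tables:
        events_dir.mkdir(exist_ok=True)
    for name, table in file.event_tables.items():
        table.to_csv(events_dir / f"{name}.csv", index=False)

    notes_index: dict[str, list[dict]] = {}
    for source in sorted(file.notes):
        docs = file.notes[source]
        src_dir = root / "notes" / source
        if docs:
            src_dir.mkdir(parents=True, exist_ok=True)
        entries = []
        for k, doc in enumerate(docs):
            rel = f"notes/{source}/{k}.txt"
            (root / rel).write_text(doc.text, encoding="utf-8")
            entries.append({"path": rel, "time_hours": float(doc.time_hours)})
        notes_index[source] = entries
    manifest["notes"] = notes_index

    studies_index = []
    for i, study in enumerate(file.image_studies):
        study_dir = root / "images" / f"study_{i}"
        study_dir.mkdir(parents=True, exist_ok=True)
        entry = {"time_hours": float(study.time_hours), "images": []}
        for k, arr in enumerate(study.images):
            rel = f"images/study_{i}/img_{k}.png"
            _save_image(np.asarray(arr), root / rel)
            entry["images"].append(rel)
        studies_index.append(entry)
    manifest["image_studies"] = studies_index

    (root / MANIFEST_NAME).write_text(
        json.dumps(manifest, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )
    return root


def load_patient_file(path: str | Path) -> PatientFile:
    """Load and fully validate a directory container."""
    root = Path(path)
    manifest_path = root / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"missing {MANIFEST_NAME} in {root}")
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"unparseable manifest in {root}: {exc}") from exc

    def _optional_time(key: str) -> Optional[datetime]:
        raw = manifest.get(key)
        return datetime.fromisoformat(raw) if raw is not None else None

    try:
        file = PatientFile(
            patient_id=str(manifest["patient_id"]),
            stay_id=str(manifest["stay_id"]),
            admit_time=datetime.fromisoformat(manifest["admit_time"]),
            discharge_time=_optional_time("discharge_time"),
            death_time=_optional_time("death_time"),
            demographics={
                str(k): float(v) for k, v in manifest.get("demographics", {}).items()
            },
            pathology_ground_truth={
                str(k): int(v)
                for k, v in manifest.get("pathology_ground_truth", {}).items()
            },
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise FormatError(f"malformed manifest in {root}: {exc}") from exc

    for name in manifest.get("event_sources", []):
        csv_path = root / "events" / f"{name}.csv"
        if not csv_path.exists():
            raise FormatError(f"missing event table {csv_path}")
        table = pd.read_csv(csv_path)
        if table.empty:
            table = pd.DataFrame(columns=EVENT_COLUMNS)
        file.event_tables[name] = table[list(EVENT_COLUMNS)].assign(
            signal_name=lambda d: d["signal_name"].astype(str),
            time_hours=lambda d: d["time_hours"].astype(float),
            value=lambda d: d["value"].astype(float),
        )

    for source, entries in manifest.get("notes", {}).items():
        docs = []
        for entry in entries:
            note_path = root / entry["path"]
            if not note_path.exists():
                raise FormatError(f"missing note file {note_path}")
            docs.append(
                NoteDocument(
                    time_hours=float(entry["time_hours"]),
                    text=note_path.read_text(encoding="utf-8"),
                )
            )
        file.notes[source] = docs

    for entry in manifest.get("image_studies", []):
        images = []
        for rel in entry["images"]:
            img_path = root / rel
            if not img_path.exists():
                raise FormatError(f"missing image file {img_path}")
            images.append(_load_image(img_path))
        file.image_studies.append(
            ImageStudy(time_hours=float(entry["time_hours"]), images=tuple(images))
        )

    validate_patient_file(file)
    return file


# ---------------------------------------------------------------------------
# time windowing and sample extraction
# ---------------------------------------------------------------------------

def window_events(file: PatientFile, t: float) -> PatientFile:
    """Restrict a record to data observed up to and including hour ``t``.

    Demographics and outcome timestamps are unchanged (labels, not inputs,
    read the latter).  The window boundary is inclusive: an event at exactly
    ``t`` is kept.  The returned view may legitimately contain no image study.
    """
    if not math.isfinite(t) and not (isinstance(t, float) and t == math.inf):
        raise ValueError(f"window time must be finite or +inf, got {t!r}")
    if t < 0:
        raise ValueError(f"window time must be non-negative, got {t!r}")
    tables = {
        name: table.loc[table["time_hours"] <= t].reset_index(drop=True)
        for name, table in file.event_tables.items()
    }
    notes = {
        source: [d for d in docs if d.time_hours <= t]
        for source, docs in file.notes.items()
    }
    studies = [s for s in file.image_studies if s.time_hours <= t]
    return replace(
        file,
        event_tables=tables,
        notes=notes,
        image_studies=studies,
        demographics=dict(file.demographics),
        pathology_ground_truth=dict(file.pathology_ground_truth),
    )


def end_of_day(t: float) -> float:
    """Next multiple of 24 h at or after ``t``."""
    return 24.0 * math.ceil(t / 24.0)


Anchor = Literal["image_time", "end_of_day"]


def extract_samples(file: PatientFile, anchor: Anchor = "image_time") -> list[Sample]:
    """One prediction point per imaging event.

    ``image_time`` anchors a sample at each distinct study time; ``end_of_day``
    anchors at the 24 h day boundary following each study (duplicates
    collapsed either way).  Samples are sorted by time.
    """
    if anchor not in ("image_time", "end_of_day"):
        raise ValueError(f"unknown anchor {anchor!r}")
    times = [s.time_hours for s in file.image_studies]
    if anchor == "end_of_day":
        times = [end_of_day(t) for t in times]
    unique = sorted(set(times))
    return [
        Sample(patient_id=file.patient_id, stay_id=file.stay_id, time_hours=t)
        for t in unique
    ]
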