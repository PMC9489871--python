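"""Canonical registry of multimodal data sources.

A *modality* is a broad data class (tabular, time-series, text, image)
distinguished by its digital format; a *source* is a named input variable
group within a modality (e.g., chart events, echocardiogram notes).  The
default registry fixes the 11 sources of the reference configuration, their
modalities, and their embedding dimensions.  The registry order is canonical:
every fusion embedding, subset bitmask and result table uses it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

TABULAR = "tabular"
TIME_SERIES = "time-series"
TEXT = "text"
IMAGE = "image"

MODALITIES: tuple[str, ...] = (TABULAR, TIME_SERIES, TEXT, IMAGE)

#: statistics computed per clinical time-series signal (see extractors)
TS_FEATURES_PER_SIGNAL = 11

#: chart-event signals: routine bedside vitals plus the Glasgow coma subscores
CHART_SIGNALS: tuple[str, ...] = (
    "heart_rate",
    "nbp_systolic",
    "nbp_diastolic",
    "respiratory_rate",
    "spo2",
    "temperature",
    "gcs_verbal",
    "gcs_eye",
    "gcs_motor",
)

#: laboratory signals (22 unique assays)
LAB_SIGNALS: tuple[str, ...] = (
    "glucose",
    "potassium",
    "sodium",
    "chloride",
    "creatinine",
    "urea_nitrogen",
    "bicarbonate",
    "anion_gap",
    "hemoglobin",
    "hematocrit",
    "magnesium",
    "platelet_count",
    "phosphate",
    "white_blood_cells",
    "total_calcium",
    "mch",
    "red_blood_cells",
    "mchc",
    "mcv",
    "rdw",
    "neutrophils",
    "vancomycin",
)

#: procedure-event signals
PROCEDURE_SIGNALS: tuple[str, ...] = (
    "foley_catheter",
    "picc_line",
    "intubation",
    "peritoneal_dialysis",
    "bronchoscopy",
    "eeg",
    "dialysis_crrt",
    "dialysis_catheter",
    "chest_tube_removal",
    "hemodialysis",
)

#: demographics schema: (field name, min, max) used for min-max normalization
DEMOGRAPHIC_SCHEMA: tuple[tuple[str, float, float], ...] = (
    ("age", 0.0, 100.0),
    ("sex_code", 0.0, 1.0),
    ("ethnicity_code", 0.0, 7.0),
    ("marital_status_code", 0.0, 4.0),
    ("language_code", 0.0, 1.0),
    ("insurance_code", 0.0, 4.0),
)

TEXT_EMBED_DIM = 768
IMAGE_PROB_DIM = 18
IMAGE_DENSE_DIM = 1024


@dataclass(frozen=True)
class SourceSpec:
    """One named data source: its modality and embedding dimension."""

    name: str
    modality: str
    dim: int

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.dim <= 0:
            raise ValueError("embedding dimension must be positive")


#: per-source ordered signal lists for the time-series sources
TIMESERIES_SIGNALS: Mapping[str, tuple[str, ...]] = {
    "ce": CHART_SIGNALS,
    "le": LAB_SIGNALS,
    "pe": PROCEDURE_SIGNALS,
}

_DEFAULT_SPECS: tuple[SourceSpec, ...] = (
    SourceSpec("de", TABULAR, len(DEMOGRAPHIC_SCHEMA)),
    SourceSpec("ce", TIME_SERIES, len(CHART_SIGNALS) * TS_FEATURES_PER_SIGNAL),
    SourceSpec("le", TIME_SERIES, len(LAB_SIGNALS) * TS_FEATURES_PER_SIGNAL),
    SourceSpec("pe", TIME_SERIES, len(PROCEDURE_SIGNALS) * TS_FEATURES_PER_SIGNAL),
    SourceSpec("radn", TEXT, TEXT_EMBED_DIM),
    SourceSpec("ecgn", TEXT, TEXT_EMBED_DIM),
    SourceSpec("econ", TEXT, TEXT_EMBED_DIM),
    SourceSpec("vp", IMAGE, IMAGE_PROB_DIM),
    SourceSpec("vd", IMAGE, IMAGE_DENSE_DIM),
    SourceSpec("vmp", IMAGE, IMAGE_PROB_DIM),
    SourceSpec("vmd", IMAGE, IMAGE_DENSE_DIM),
)


class SourceRegistry:
    """Ordered collection of :class:`SourceSpec`, fixing canonical order.

    The default registry covers 11 sources across the 4 modalities and a
    total fusion dimension of 4845.
    """

    def __init__(self, specs: Sequence[SourceSpec]):
        names = [s.name for s in specs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate source names in registry")
        if not specs:
            raise ValueError("registry must contain at least one source")
        self._specs: tuple[SourceSpec, ...] = tuple(specs)
        self._by_name = {s.name: s for s in self._specs}

    @classmethod
    def default(cls) -> "SourceRegistry":
        return cls(_DEFAULT_SPECS)

    def __iter__(self) -> Iterator[SourceSpec]:
        return iter(self._specs)

    def __len__(self) -> int:
        return len(self._specs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self._specs)

    def spec(self, name: str) -> SourceSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown source {name!r}") from None

    def modality(self, name: str) -> str:
        return self.spec(name).modality

    def dim(self, name: str) -> int:
        return self.spec(name).dim

    @property
    def total_dim(self) -> int:
        return sum(s.dim for s in self._specs)

    def modalities_of(self, names: Iterable[str]) -> frozenset[str]:
        return frozenset(self.spec(n).modality for n in names)

    def restrict(self, names: Iterable[str]) -> "SourceRegistry":
        """Sub-registry keeping canonical order; unknown names rejected."""
        keep = set(names)
        unknown = keep - set(self.names)
        if unknown:
            raise KeyError(f"unknown sources {sorted(unknown)!r}")
        return SourceRegistry([s for s in self._specs if s.name in keep])

    def canonical_order(self, names: Iterable[str]) -> tuple[str, ...]:
        keep = set(names)
        return tuple(n for n in self.names if n in keep)
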