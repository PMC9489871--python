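"""Per-source embedding extraction.

Each data source is mapped to a fixed-dimensional real vector by a
modality-specific stream:

* tabular demographics → min-max-normalized values in schema order;
* irregular clinical time-series → 11 summary statistics per signal
  (count, max, min, mean, median, population SD, population variance,
  strict-local-maxima count, mean per-step slope, mean absolute per-step
  change rate, and overall trend), concatenated over the source's signal
  list;
* free-text notes → token chunks of at most 512 tokens fed to a pluggable
  text encoder, with the chunk embeddings averaged into one 768-vector;
* images → area-resampled to 224×224 and fed to a pluggable image model
  returning an 18-dim class-probability vector and a 1024-dim dense-feature
  vector, for the most recent image (single-image sources) or averaged over
  all images in the window (multi-image sources).

Encoders are contracts, not weights: any object with the right signature
and output dimensions plugs in (a clinical-domain transformer and an X-ray
CNN in production; deterministic stubs in tests).

Missing data (no notes, no events for a signal, no study in the window)
yields a zero block so the fusion dimensionality is invariant; presence is
reported alongside for auditability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd
from PIL import Image

from .patient_record import ImageStudy, NoteDocument, PatientFile
from .registry import (
    DEMOGRAPHIC_SCHEMA,
    IMAGE_DENSE_DIM,
    IMAGE_PROB_DIM,
    TEXT_EMBED_DIM,
    TIMESERIES_SIGNALS,
    TS_FEATURES_PER_SIGNAL,
    SourceRegistry,
)

logger = logging.getLogger(__name__)

MAX_TEXT_TOKENS = 512
IMAGE_INPUT_SIZE = (224, 224)


class ContractError(ValueError):
    """A pluggable encoder violated its output contract."""


@runtime_checkable
class TextEncoderContract(Protocol):
    """Maps a token chunk (≤ ``max_tokens`` tokens) to a fixed vector."""

    max_tokens: int
    output_dim: int

    def encode(self, tokens: Sequence[str]) -> np.ndarray: ...


@runtime_checkable
class ImageModelContract(Protocol):
    """Maps a 224×224 intensity array to (probabilities, dense features)."""

    input_size: tuple[int, int]
    prob_dim: int
    dense_dim: int

    def forward(self, image: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...


# ---------------------------------------------------------------------------
# tabular
# ---------------------------------------------------------------------------

def embed_tabular(
    demographics: Mapping[str, float],
    schema: Sequence[tuple[str, float, float]] = DEMOGRAPHIC_SCHEMA,
) -> np.ndarray:
    """Min-max normalize demographics to [0, 1] in schema order.

    Missing fields map to 0; out-of-range values are clipped with a logged
    warning.
    """
    out = np.zeros(len(schema), dtype=np.float64)
    for i, (name, lo, hi) in enumerate(schema):
        if name not in demographics:
            continue
        v = float(demographics[name])
        if v < lo or v > hi:
            logger.warning(
                "demographic %r=%g outside declared range [%g, %g]; clipped",
                name, v, lo, hi,
            )
            v = min(max(v, lo), hi)
        out[i] = (v - lo) / (hi - lo) if hi > lo else 0.0
    return out


# ---------------------------------------------------------------------------
# time-series
# ---------------------------------------------------------------------------

def embed_timeseries_signal(series: Sequence[tuple[float, float]]) -> np.ndarray:
    """11 summary statistics of one irregularly sampled signal.

    Feature order: [count, max, min, mean, median, population SD,
    population variance, # strict local maxima, mean per-step slope
    Δv/Δt, mean |Δv|/Δt, overall trend (v_last−v_first)/(t_last−t_first)].
    Consecutive pairs with zero time gap are skipped in the slope terms.
    An empty series yields the zero vector.
    """
    n = len(series)
    out = np.zeros(TS_FEATURES_PER_SIGNAL, dtype=np.float64)
    if n == 0:
        return out
    t = np.asarray([p[0] for p in series], dtype=np.float64)
    v = np.asarray([p[1] for p in series], dtype=np.float64)
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
        raise ValueError("non-finite entry in time series")
    if np.any(np.diff(t) < 0):
        raise ValueError("time series must be sorted by time")

    out[0] = n
    out[1] = v.max()
    out[2] = v.min()
    out[3] = v.mean()
    out[4] = float(np.median(v))
    out[5] = v.std()        # population SD (defined for n = 1)
    out[6] = v.var()
    if n >= 3:
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        out[7] = int(interior.sum())
    if n >= 2:
        dt = np.diff(t)
        dv = np.diff(v)
        ok = dt > 0
        if ok.any():
            slopes = dv[ok] / dt[ok]
            out[8] = slopes.mean()
            out[9] = np.abs(slopes).mean()
        span = t[-1] - t[0]
        if span > 0:
            out[10] = (v[-1] - v[0]) / span
    return out


def embed_timeseries_source(
    table: Optional[pd.DataFrame],
    signals: Sequence[str],
) -> np.ndarray:
    """Concatenate per-signal statistics over an ordered signal list.

    Signals absent from the table contribute zero blocks; an absent table is
    treated as empty.  Output length is ``11 * len(signals)``.
    """
    blocks = []
    if table is not None and len(table):
        grouped = {
            name: grp.sort_values("time_hours")
            for name, grp in table.groupby("signal_name", sort=False)
        }
    else:
        grouped = {}
    for sig in signals:
        grp = grouped.get(sig)
        if grp is None or not len(grp):
            blocks.append(np.zeros(TS_FEATURES_PER_SIGNAL))
        else:
            pairs = list(zip(grp["time_hours"].to_numpy(float),
                             grp["value"].to_numpy(float)))
            blocks.append(embed_timeseries_signal(pairs))
    return np.concatenate(blocks)


# ---------------------------------------------------------------------------
# text
# ---------------------------------------------------------------------------

def chunk_text(tokens: Sequence[str], max_tokens: int = MAX_TEXT_TOKENS) -> list[list[str]]:
    """Greedy contiguous chunks of at most ``max_tokens`` tokens.

    Produces the minimal number of chunks, ``ceil(len(tokens)/max_tokens)``;
    their concatenation equals the input.  Empty input yields no chunks.
    """
    if max_tokens < 1:
        raise ValueError("max_tokens must be >= 1")
    toks = list(tokens)
    return [toks[i : i + max_tokens] for i in range(0, len(toks), max_tokens)]


def whitespace_tokenize(text: str) -> list[str]:
    return text.split()


def embed_text_source(
    notes: Sequence[NoteDocument],
    encoder: TextEncoderContract,
    tokenizer: Callable[[str], list[str]] = whitespace_tokenize,
) -> np.ndarray:
    """Average chunk embeddings of the time-ordered concatenated note text.

    No notes, or only empty text, yields the zero vector.
    """
    ordered = sorted(notes, key=lambda d: d.time_hours)
    text = " ".join(d.text for d in ordered)
    tokens = tokenizer(text)
    if not tokens:
        return np.zeros(encoder.output_dim, dtype=np.float64)
    chunks = chunk_text(tokens, encoder.max_tokens)
    vecs = []
    for chunk in chunks:
        vec = np.asarray(encoder.encode(chunk), dtype=np.float64)
        if vec.shape != (encoder.output_dim,):
            raise ContractError(
                f"text encoder returned shape {vec.shape}, "
                f"expected ({encoder.output_dim},)"
            )
        vecs.append(vec)
    return np.mean(vecs, axis=0)


# ---------------------------------------------------------------------------
# image
# ---------------------------------------------------------------------------

def preprocess_image(
    image: np.ndarray, size: tuple[int, int] = IMAGE_INPUT_SIZE
) -> np.ndarray:
    """Resample an intensity array to ``size`` using pixel-area relations.

    Downscaling averages source pixel areas (a box filter), so constant
    images stay constant and the output range never exceeds the input range.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError("image must be a non-empty 2-D array")
    if arr.shape == size:
        return arr.copy()
    pil = Image.fromarray(arr.astype(np.float32), mode="F")
    resized = pil.resize((size[1], size[0]), resample=Image.Resampling.BOX)
    return np.asarray(resized, dtype=np.float64)


def _forward_checked(
    model: ImageModelContract, image: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    probs, dense = model.forward(preprocess_image(image, model.input_size))
    probs = np.asarray(probs, dtype=np.float64)
    dense = np.asarray(dense, dtype=np.float64)
    if probs.shape != (model.prob_dim,):
        raise ContractError(
            f"image model probability output shape {probs.shape}, "
            f"expected ({model.prob_dim},)"
        )
    if dense.shape != (model.dense_dim,):
        raise ContractError(
            f"image model dense output shape {dense.shape}, "
            f"expected ({model.dense_dim},)"
        )
    if np.any(probs < 0) or np.any(probs > 1):
        raise ContractError("image model probabilities outside [0, 1]")
    return probs, dense


def embed_image_single(
    study: ImageStudy, model: ImageModelContract
) -> tuple[np.ndarray, np.ndarray]:
    """Probability and dense embeddings of the study's most recent image."""
    return _forward_checked(model, study.images[-1])


def embed_image_multi(
    studies: Sequence[ImageStudy], model: ImageModelContract
) -> tuple[np.ndarray, np.ndarray]:
    """Element-wise mean of per-image embeddings over all images of all studies."""
    if not studies:
        raise ValueError("embed_image_multi requires at least one study")
    probs, denses = [], []
    for study in studies:
        for img in study.images:
            p, d = _forward_checked(model, img)
            probs.append(p)
            denses.append(d)
    return np.mean(probs, axis=0), np.mean(denses, axis=0)


# ---------------------------------------------------------------------------
# whole-patient extraction
# ---------------------------------------------------------------------------

@dataclass
class PatientEmbeddings:
    """Per-source embeddings of one (windowed) record plus presence flags."""

    vectors: dict[str, np.ndarray]
    presence: dict[str, bool]


def embed_patient(
    file: PatientFile,
    registry: SourceRegistry,
    text_encoder: Optional[TextEncoderContract] = None,
    image_model: Optional[ImageModelContract] = None,
) -> PatientEmbeddings:
    """Extract every registry source from one (already windowed) record.

    Sources with no data in the record yield zero blocks and a ``False``
    presence flag.  Encoders are required only for the modalities actually
    present in the registry.
    """
    vectors: dict[str, np.ndarray] = {}
    presence: dict[str, bool] = {}
    latest_study = max(
        file.image_studies, key=lambda s: s.time_hours, default=None
    )
    # vp/vd share one forward pass; vmp/vmd share one multi-image pass
    single_cache: Optional[tuple[np.ndarray, np.ndarray]] = None
    multi_cache: Optional[tuple[np.ndarray, np.ndarray]] = None

    def _single() -> tuple[np.ndarray, np.ndarray]:
        nonlocal single_cache
        if single_cache is None:
            assert latest_study is not None and image_model is not None
            single_cache = embed_image_single(latest_study, image_model)
        return single_cache

    def _multi() -> tuple[np.ndarray, np.ndarray]:
        nonlocal multi_cache
        if multi_cache is None:
            assert image_model is not None
            multi_cache = embed_image_multi(file.image_studies, image_model)
        return multi_cache

    for spec in registry:
        name = spec.name
        if spec.modality == "tabular":
            vec = embed_tabular(file.demographics)
            present = bool(file.demographics)
        elif spec.modality == "time-series":
            signals = TIMESERIES_SIGNALS.get(name)
            if signals is None:
                raise KeyError(f"no signal list registered for source {name!r}")
            table = file.event_tables.get(name)
            vec = embed_timeseries_source(table, signals)
            present = table is not None and len(table) > 0
        elif spec.modality == "text":
            if text_encoder is None:
                raise ValueError(f"text encoder required for source {name!r}")
            docs = file.notes.get(name, [])
            vec = embed_text_source(docs, text_encoder)
            present = any(d.text.strip() for d in docs)
        elif spec.modality == "image":
            if image_model is None:
                raise ValueError(f"image model required for source {name!r}")
            present = latest_study is not None
            if not present:
                vec = np.zeros(spec.dim)
            elif name == "vp":
                vec = _single()[0]
            elif name == "vd":
                vec = _single()[1]
            elif name == "vmp":
                vec = _multi()[0]
            elif name == "vmd":
                vec = _multi()[1]
            else:
                raise KeyError(f"unknown image source {name!r}")
        else:  # pragma: no cover - registry validates modalities
            raise KeyError(f"unknown modality {spec.modality!r}")
        vec = np.asarray(vec, dtype=np.float64)
        if vec.shape != (spec.dim,):
            raise ContractError(
                f"source {name!r} produced length {vec.shape}, "
                f"expected ({spec.dim},)"
            )
        vectors[name] = vec
        presence[name] = present
    return PatientEmbeddings(vectors=vectors, presence=presence)
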