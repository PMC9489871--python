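"""Fusion-embedding assembly, normalization and source subsetting.

Per-source embedding vectors are concatenated in canonical registry order
into one flat fusion embedding per prediction point (4845-dimensional for
the full default registry).  A :class:`SourceSubset` selects which sources
enter a model; its 11-character bitstring (canonical order) is the stable
serialized form used in result tables.

Normalization is a per-feature z-score whose center and scale are fitted on
the training rows of each experiment only — fitting and applying are
separate steps so test-set statistics can never leak into the transform.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .registry import SourceRegistry


@dataclass(frozen=True)
class SourceSubset:
    """A non-empty set of sources, stored in canonical registry order."""

    sources: tuple[str, ...]

    @classmethod
    def from_names(
        cls, names: Iterable[str], registry: SourceRegistry
    ) -> "SourceSubset":
        ordered = registry.canonical_order(names)
        missing = set(names) - set(ordered)
        if missing:
            raise KeyError(f"unknown sources {sorted(missing)!r}")
        if not ordered:
            raise ValueError("source subset must be non-empty")
        return cls(sources=ordered)

    @classmethod
    def from_bitmask(cls, bits: str, registry: SourceRegistry) -> "SourceSubset":
        if len(bits) != len(registry) or set(bits) - {"0", "1"}:
            raise ValueError(
                f"bitmask must be {len(registry)} characters of 0/1, got {bits!r}"
            )
        names = [n for n, b in zip(registry.names, bits) if b == "1"]
        return cls.from_names(names, registry)

    def bitmask(self, registry: SourceRegistry) -> str:
        members = set(self.sources)
        return "".join("1" if n in members else "0" for n in registry.names)

    @property
    def n_sources(self) -> int:
        return len(self.sources)

    def modalities(self, registry: SourceRegistry) -> frozenset[str]:
        return registry.modalities_of(self.sources)

    def n_modalities(self, registry: SourceRegistry) -> int:
        return len(self.modalities(registry))

    def total_dim(self, registry: SourceRegistry) -> int:
        return sum(registry.dim(n) for n in self.sources)


@dataclass(frozen=True)
class FusionEmbedding:
    """Flat multimodal vector plus its (source, offset, length) layout."""

    values: np.ndarray
    layout: tuple[tuple[str, int, int], ...]

    def block(self, source: str) -> np.ndarray:
        for name, offset, length in self.layout:
            if name == source:
                return self.values[offset : offset + length]
        raise KeyError(f"source {source!r} not in fusion layout")

    def slice_to(self, subset: SourceSubset) -> "FusionEmbedding":
        """Restrict to a subset of the layout's sources (layout order kept)."""
        members = set(subset.sources)
        blocks, layout = [], []
        offset = 0
        for name, off, length in self.layout:
            if name in members:
                blocks.append(self.values[off : off + length])
                layout.append((name, offset, length))
                offset += length
        if len(layout) != len(members):
            missing = members - {name for name, _, _ in layout}
            raise KeyError(f"sources {sorted(missing)!r} not in fusion layout")
        return FusionEmbedding(np.concatenate(blocks), tuple(layout))


def assemble_fusion(
    embeddings: Mapping[str, np.ndarray],
    subset: SourceSubset,
    registry: SourceRegistry,
) -> FusionEmbedding:
    """Concatenate subset members' embeddings in canonical order."""
    if subset.n_sources == 0:
        raise ValueError("cannot assemble an empty subset")
    blocks, layout = [], []
    offset = 0
    for name in subset.sources:
        dim = registry.dim(name)
        if name not in embeddings:
            raise KeyError(f"no embedding provided for source {name!r}")
        vec = np.asarray(embeddings[name], dtype=np.float64)
        if vec.shape != (dim,):
            raise ValueError(
                f"embedding for {name!r} has shape {vec.shape}, expected ({dim},)"
            )
        blocks.append(vec)
        layout.append((name, offset, dim))
        offset += dim
    return FusionEmbedding(np.concatenate(blocks), tuple(layout))


def stack_fusion_matrix(
    embeddings: Mapping[str, np.ndarray],
    subset: SourceSubset,
    registry: SourceRegistry,
) -> np.ndarray:
    """Column-stack per-source matrices (n_samples × dim) for a subset."""
    blocks = []
    n_rows = None
    for name in subset.sources:
        mat = np.asarray(embeddings[name], dtype=np.float64)
        if mat.ndim != 2 or mat.shape[1] != registry.dim(name):
            raise ValueError(
                f"matrix for {name!r} has shape {mat.shape}, expected "
                f"(n, {registry.dim(name)})"
            )
        if n_rows is None:
            n_rows = mat.shape[0]
        elif mat.shape[0] != n_rows:
            raise ValueError("per-source matrices have inconsistent row counts")
        blocks.append(mat)
    return np.hstack(blocks)


@dataclass(frozen=True)
class Normalizer:
    """Per-feature center/scale fitted on training rows only."""

    center: np.ndarray
    scale: np.ndarray

    def __post_init__(self) -> None:
        if self.center.shape != self.scale.shape:
            raise ValueError("center and scale must have matching shapes")
        if np.any(self.scale <= 0):
            raise ValueError("scales must be strictly positive")


def fit_normalizer(train: np.ndarray) -> Normalizer:
    """Fit a per-feature z-score on a training matrix.

    Uses the population SD; zero-variance features get scale 1 so they map
    to exactly zero after centering.
    """
    train = np.asarray(train, dtype=np.float64)
    if train.ndim != 2 or train.shape[0] == 0:
        raise ValueError("training matrix must be 2-D and non-empty")
    center = train.mean(axis=0)
    scale = train.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return Normalizer(center=center, scale=scale)


def apply_normalizer(normalizer: Normalizer, matrix: np.ndarray) -> np.ndarray:
    """Apply a fitted z-score; never refits."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.ndim != 2 or matrix.shape[1] != normalizer.center.shape[0]:
        raise ValueError(
            f"matrix has {matrix.shape[1] if matrix.ndim == 2 else '?'} features, "
            f"normalizer was fitted on {normalizer.center.shape[0]}"
        )
    return (matrix - normalizer.center) / normalizer.scale
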