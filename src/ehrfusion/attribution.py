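"""Exact Shapley attribution of data sources and modalities.

The cooperative game has the data sources as players and the mean test
AUROC of the subset's model as the payoff, with the empty coalition valued
at 0.5 (the discrimination of a coin flip).  Because the experiment engine
evaluates every subset exhaustively, the Shapley value is computed exactly:

    φ_i = Σ_{S ⊆ N\\{i}}  |S|! (k−|S|−1)! / k!  · [v(S ∪ {i}) − v(S)]

Per-modality attributions are reported two ways, since the aggregation can
be read either as summing member-source values or as a 4-player game on
modalities (with a modality coalition valued by the average AUROC of the
subset models it covers); both are emitted and labeled.

A permutation-based oracle (average marginal contribution over all k!
orderings) is provided for cross-checking the closed-form summation on
small games.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import factorial
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .registry import SourceRegistry

EMPTY_COALITION_AUROC = 0.5

MAX_EXACT_PLAYERS = 20
MAX_ORACLE_PLAYERS = 8


class MissingCoalitionError(KeyError):
    """The value function lacks an entry for a required subset."""


@dataclass
class ValueFunction:
    """v: subset of sources → mean test AUROC, with v(∅) fixed at 0.5."""

    values: dict[frozenset, float]
    players: tuple[str, ...]
    empty_value: float = EMPTY_COALITION_AUROC

    def __call__(self, coalition: Iterable[str]) -> float:
        key = frozenset(coalition)
        if not key:
            return self.empty_value
        try:
            return self.values[key]
        except KeyError:
            raise MissingCoalitionError(
                f"no value recorded for coalition {tuple(sorted(key))!r}"
            ) from None

    @classmethod
    def from_auroc_table(
        cls, table: pd.DataFrame, registry: SourceRegistry, task: str | None = None
    ) -> "ValueFunction":
        """Build v(S) from an experiment-engine AUROC table.

        The 5-repetition mean AUROC is the coalition value.  Players are
        the union of sources appearing in any subset row.
        """
        if task is not None:
            table = table[table["task"] == task]
        if table.empty:
            raise ValueError("empty AUROC table")
        values: dict[frozenset, float] = {}
        players: set[str] = set()
        for _, row in table.iterrows():
            if len(row["subset"]) != len(registry):
                raise ValueError(
                    f"subset bitmask {row['subset']!r} does not match the "
                    f"{len(registry)}-source registry"
                )
            members = frozenset(
                n for n, b in zip(registry.names, row["subset"]) if b == "1"
            )
            values[members] = float(row["auroc_mean"])
            players |= members
        return cls(values=values, players=registry.canonical_order(players))


def shapley_sources(
    v: ValueFunction, sources: Sequence[str] | None = None
) -> dict[str, float]:
    """Exact Shapley value of every source under the value function ``v``.

    Requires ``v`` to be complete over all 2^k subsets of the players; a
    missing subset raises :class:`MissingCoalitionError` naming it.
    """
    players = tuple(sources) if sources is not None else v.players
    k = len(players)
    if k == 0:
        raise ValueError("no players")
    if k > MAX_EXACT_PLAYERS:
        raise ValueError(
            f"{k} players is too many for exact enumeration (max "
            f"{MAX_EXACT_PLAYERS}); consider a sampling approximation"
        )
    k_fact = factorial(k)
    phi = {p: 0.0 for p in players}
    others = {p: [q for q in players if q != p] for p in players}
    for p in players:
        total = 0.0
        rest = others[p]
        for r in range(len(rest) + 1):
            weight = factorial(r) * factorial(k - r - 1) / k_fact
            for combo in itertools.combinations(rest, r):
                s = frozenset(combo)
                total += weight * (v(s | {p}) - v(s))
        phi[p] = total
    return phi


def permutation_oracle(
    v: ValueFunction, sources: Sequence[str] | None = None
) -> dict[str, float]:
    """Average marginal contribution over all k! orderings.

    Independent of :func:`shapley_sources`; refuses k > 8 (factorial cost).
    """
    players = tuple(sources) if sources is not None else v.players
    k = len(players)
    if k == 0:
        raise ValueError("no players")
    if k > MAX_ORACLE_PLAYERS:
        raise ValueError(f"permutation oracle limited to {MAX_ORACLE_PLAYERS} players")
    totals = {p: 0.0 for p in players}
    count = 0
    for order in itertools.permutations(players):
        coalition: set[str] = set()
        prev = v(coalition)
        for p in order:
            coalition.add(p)
            cur = v(coalition)
            totals[p] += cur - prev
            prev = cur
        count += 1
    return {p: t / count for p, t in totals.items()}


def aggregate_modalities(
    phi: Mapping[str, float], registry: SourceRegistry
) -> dict[str, float]:
    """Sum source values within each modality (additive aggregation)."""
    out: dict[str, float] = {}
    for name, value in phi.items():
        modality = registry.modality(name)
        out[modality] = out.get(modality, 0.0) + value
    return out


@dataclass
class AttributionResult:
    """Per-source and per-modality Shapley values with the efficiency residual."""

    phi: dict[str, float]
    modality_phi: dict[str, float]
    v_full: float
    v_empty: float

    @property
    def efficiency_residual(self) -> float:
        """v(full) − v(∅) − Σφ; ~0 by construction, reported not absorbed."""
        return self.v_full - self.v_empty - sum(self.phi.values())

    def to_frame(self, registry: SourceRegistry) -> pd.DataFrame:
        rows = [
            {
                "source": name,
                "modality": registry.modality(name),
                "phi": self.phi[name],
                "modality_phi": self.modality_phi[registry.modality(name)],
                "efficiency_residual": self.efficiency_residual,
            }
            for name in registry.canonical_order(self.phi)
        ]
        return pd.DataFrame(rows)


def attribute_sources(
    table: pd.DataFrame, registry: SourceRegistry, task: str | None = None
) -> AttributionResult:
    """End-to-end source attribution from an experiment AUROC table."""
    v = ValueFunction.from_auroc_table(table, registry, task)
    phi = shapley_sources(v)
    return AttributionResult(
        phi=phi,
        modality_phi=aggregate_modalities(phi, registry),
        v_full=v(v.players),
        v_empty=v.empty_value,
    )


def modality_game_values(
    table: pd.DataFrame, registry: SourceRegistry, task: str | None = None
) -> ValueFunction:
    """The alternative 4-player reading: modalities as players.

    A modality coalition M is valued by the average AUROC over all subset
    models whose modality coverage is exactly M.
    """
    if task is not None:
        table = table[table["task"] == task]
    if table.empty:
        raise ValueError("empty AUROC table")
    sums: dict[frozenset, list[float]] = {}
    modalities: set[str] = set()
    for _, row in table.iterrows():
        if len(row["subset"]) != len(registry):
            raise ValueError(
                f"subset bitmask {row['subset']!r} does not match the "
                f"{len(registry)}-source registry"
            )
        members = [n for n, b in zip(registry.names, row["subset"]) if b == "1"]
        cover = frozenset(registry.modality(n) for n in members)
        sums.setdefault(cover, []).append(float(row["auroc_mean"]))
        modalities |= cover
    values = {cover: sum(v) / len(v) for cover, v in sums.items()}
    return ValueFunction(
        values=values, players=tuple(sorted(modalities))
    )


def shapley_modalities(
    table: pd.DataFrame, registry: SourceRegistry, task: str | None = None
) -> dict[str, float]:
    """Exact Shapley values of the 4-player modality game."""
    return shapley_sources(modality_game_values(table, registry, task))
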