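"""Monte Carlo metaphase-fusion simulator.

Generates synthetic metaphase spreads: fusion events are drawn sequentially
without replacement, each event picking an unordered pair of free telomeres
with probability proportional to the product of the telomere weights.
Heterochromatin-associated termini carry weight ``w`` (the fusigenicity
bias); ``w = 1`` recovers the random-involvement null exactly.  Events are
labelled DTA with probability ``p_g1`` (G1-origin fusions duplicated by
replication), otherwise STA.

Fused chromosomes are assembled into multicentric chains and rings by
:func:`derive_structures`; per-cell counts aggregate into the S1-shaped
:class:`CountTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .karyotype import CATEGORIES, KaryotypeConfig, TelomereID

__all__ = [
    "BiasModel",
    "FusionEvent",
    "Structure",
    "Metaphase",
    "CountTable",
    "SimulationError",
    "simulate_metaphase",
    "derive_structures",
    "count_fused_telomeres",
    "simulate_experiment",
]


class SimulationError(ValueError):
    """Raised for infeasible simulation requests or inconsistent events."""


@dataclass(frozen=True)
class BiasModel:
    """Parameters of the biased-pairing generative model.

    ``het_weight`` is the relative fusigenicity of heterochromatin-associated
    telomeres (1 = random null).  ``p_g1`` is the probability a fusion arose
    in G1 and is scored as a DTA.  ``events_per_cell_mean`` is the Poisson
    mean number of fusions per cell, truncated at the free telomere slots.
    """

    het_weight: float = 1.0
    p_g1: float = 0.9
    events_per_cell_mean: float = 1.0

    def __post_init__(self) -> None:
        if not self.het_weight > 0:
            raise SimulationError("het_weight must be positive")
        if not 0.0 <= self.p_g1 <= 1.0:
            raise SimulationError("p_g1 must lie in [0, 1]")
        if not self.events_per_cell_mean > 0:
            raise SimulationError("events_per_cell_mean must be positive")


@dataclass(frozen=True)
class FusionEvent:
    """An end-to-end fusion of two distinct telomeres."""

    a: TelomereID
    b: TelomereID
    association: str = "DTA"  # "STA" or "DTA"

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise SimulationError("fusion event requires two distinct telomeres")
        if self.association not in ("STA", "DTA"):
            raise SimulationError(f"unknown association label {self.association!r}")
        if self.b < self.a:  # canonical end order
            a, b = self.a, self.b
            object.__setattr__(self, "a", b)
            object.__setattr__(self, "b", a)

    @property
    def ends(self) -> tuple[TelomereID, TelomereID]:
        return (self.a, self.b)

    @property
    def involves_y(self) -> bool:
        return self.a.chromosome == "Y" or self.b.chromosome == "Y"

    @property
    def is_ring(self) -> bool:
        """True when both ends belong to the same chromosome copy."""
        return self.a.chromosome == self.b.chromosome and self.a.homolog == self.b.homolog

    @property
    def is_y_ring(self) -> bool:
        return self.is_ring and self.a.chromosome == "Y"


@dataclass(frozen=True)
class Structure:
    """A maximal chain or ring of end-to-end joined chromosomes.

    ``members`` are ``(chromosome, homolog)`` keys in canonical traversal
    order; a lone unfused chromosome is a chain of length 1.
    """

    kind: str  # "chain" or "ring"
    members: tuple[tuple[str, int], ...]

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(chromosome for chromosome, _ in self.members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class Metaphase:
    """One simulated (or hand-built) metaphase spread."""

    karyotype: KaryotypeConfig
    events: tuple[FusionEvent, ...]

    @cached_property
    def structures(self) -> tuple[Structure, ...]:
        return derive_structures(self.events, self.karyotype)


@dataclass(frozen=True)
class CountTable:
    """S1-shaped observable: per-category fused-telomere counts plus tallies.

    Invariants: category counts sum to ``2 * n_tfs`` (each fusion contributes
    both of its telomere identities), ``sta_count + dta_count == n_tfs`` and
    ``y_ring_count <= y_fusion_count``.
    """

    ft_counts: Mapping[str, int]
    n_cells: int
    n_tfs: int
    sta_count: int
    dta_count: int
    y_fusion_count: int
    y_ring_count: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "ft_counts", dict(self.ft_counts))
        for c in self.ft_counts:
            if c not in CATEGORIES:
                raise SimulationError(f"unknown category {c!r}")
            if self.ft_counts[c] < 0:
                raise SimulationError(f"negative count for category {c!r}")
        total = sum(self.ft_counts.values())
        if total != 2 * self.n_tfs:
            raise SimulationError(
                f"category counts sum to {total}, expected 2 * n_tfs = {2 * self.n_tfs}"
            )
        if self.sta_count + self.dta_count != self.n_tfs:
            raise SimulationError("sta_count + dta_count must equal n_tfs")
        if not 0 <= self.y_ring_count <= self.y_fusion_count:
            raise SimulationError("y_ring_count must lie in [0, y_fusion_count]")
        if min(self.n_cells, self.sta_count, self.dta_count, self.y_fusion_count) < 0:
            raise SimulationError("tallies must be non-negative")

    @property
    def total_fts(self) -> int:
        return 2 * self.n_tfs

    def category_fractions(self) -> dict[str, float]:
        total = self.total_fts
        if total == 0:
            return {c: 0.0 for c in self.ft_counts}
        return {c: k / total for c, k in self.ft_counts.items()}


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class _PairSampler:
    """Precomputed pair arrays for weighted sampling without replacement."""

    def __init__(self, karyotype: KaryotypeConfig, bias: BiasModel):
        self.karyotype = karyotype
        self.telomeres = karyotype.telomeres
        n = len(self.telomeres)
        weights = np.array(
            [bias.het_weight if t.het_associated else 1.0 for t in self.telomeres]
        )
        self.ii, self.jj = np.triu_indices(n, k=1)
        self.wprod = weights[self.ii] * weights[self.jj]
        self.n = n

    def draw_events(
        self, n_events: int, rng: np.random.Generator, p_g1: float
    ) -> list[FusionEvent]:
        free = np.ones(self.n, dtype=bool)
        events: list[FusionEvent] = []
        for _ in range(n_events):
            p = self.wprod * (free[self.ii] & free[self.jj])
            p = p / p.sum()
            k = rng.choice(p.size, p=p)
            a, b = int(self.ii[k]), int(self.jj[k])
            free[a] = free[b] = False
            label = "DTA" if rng.random() < p_g1 else "STA"
            events.append(FusionEvent(self.telomeres[a], self.telomeres[b], label))
        return events


def simulate_metaphase(
    karyotype: KaryotypeConfig,
    bias: BiasModel,
    n_events: int,
    seed: int | np.random.Generator,
) -> Metaphase:
    """Simulate one metaphase with exactly ``n_events`` fusions.

    Pairs are drawn sequentially, each with probability proportional to the
    product of the two telomere weights among the remaining free telomeres.
    Deterministic for a given integer seed.
    """
    n = karyotype.total_telomeres
    if not 0 <= n_events <= n // 2:
        raise SimulationError(
            f"n_events must lie in [0, {n // 2}] for {n} telomeres, got {n_events}"
        )
    rng = _as_rng(seed)
    sampler = _PairSampler(karyotype, bias)
    events = sampler.draw_events(n_events, rng, bias.p_g1)
    return Metaphase(karyotype=karyotype, events=tuple(events))


def derive_structures(
    events: Sequence[FusionEvent], karyotype: KaryotypeConfig
) -> tuple[Structure, ...]:
    """Assemble chains and rings from a metaphase's fusion events.

    Chromosomes are nodes with two telomere ports; events are edges.
    Connected paths become chains, cycles become rings (a YL-YS fusion is a
    single-chromosome ring via a self-loop).  Chains are listed from their
    lexicographically smallest endpoint, rings from their smallest member.
    """
    seen: set[TelomereID] = set()
    for ev in events:
        for t in ev.ends:
            if t in seen:
                raise SimulationError(f"telomere {t} appears in more than one event")
            seen.add(t)

    graph = nx.MultiGraph()
    graph.add_nodes_from((t.chromosome, t.homolog) for t in karyotype.telomeres)
    for ev in events:
        graph.add_edge(
            (ev.a.chromosome, ev.a.homolog), (ev.b.chromosome, ev.b.homolog)
        )

    structures: list[Structure] = []
    for component in nx.connected_components(graph):
        sub = graph.subgraph(component)
        nodes = sorted(component)
        n_edges = sub.number_of_edges()
        if n_edges == len(nodes):  # cycle
            structures.append(Structure("ring", _walk(sub, nodes[0], len(nodes))))
        else:  # path (n_edges == len(nodes) - 1)
            endpoints = sorted(v for v in nodes if sub.degree(v) <= 1)
            structures.append(Structure("chain", _walk(sub, endpoints[0], len(nodes))))
    structures.sort(key=lambda s: (s.kind, s.members))
    return tuple(structures)


def _walk(sub: nx.MultiGraph, start, n_nodes: int) -> tuple[tuple[str, int], ...]:
    """Traverse a path or cycle component edge-by-edge from ``start``."""
    used: set = set()
    order = [start]
    node = start
    while len(order) < n_nodes:
        candidates = [
            (nbr, key)
            for _, nbr, key in sub.edges(node, keys=True)
            if (min(node, nbr), max(node, nbr), key) not in used and nbr != node
        ]
        if not candidates:
            break
        nbr, key = min(candidates)
        used.add((min(node, nbr), max(node, nbr), key))
        order.append(nbr)
        node = nbr
    return tuple(order)


def count_fused_telomeres(metaphases: Sequence[Metaphase]) -> CountTable:
    """Aggregate fusion events over metaphases into a :class:`CountTable`."""
    if len(metaphases) == 0:
        raise SimulationError("need at least one metaphase")
    categories = metaphases[0].karyotype.categories
    ft: dict[str, int] = {c: 0 for c in categories}
    n_tfs = sta = dta = y_fus = y_ring = 0
    for mp in metaphases:
        for ev in mp.events:
            ft[ev.a.category] += 1
            ft[ev.b.category] += 1
            n_tfs += 1
            if ev.association == "STA":
                sta += 1
            else:
                dta += 1
            if ev.involves_y:
                y_fus += 1
            if ev.is_y_ring:
                y_ring += 1
    return CountTable(
        ft_counts=ft,
        n_cells=len(metaphases),
        n_tfs=n_tfs,
        sta_count=sta,
        dta_count=dta,
        y_fusion_count=y_fus,
        y_ring_count=y_ring,
    )


def simulate_experiment(
    karyotype: KaryotypeConfig,
    bias: BiasModel,
    n_cells: int,
    seed: int,
) -> CountTable:
    """Simulate ``n_cells`` metaphases and aggregate their counts.

    Per-cell event counts are Poisson(``events_per_cell_mean``) truncated at
    the feasible maximum (half the telomere slots).  One root seed drives
    everything; each cell consumes a deterministic child substream, so
    results are fully reproducible.
    """
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_cells + 1)
    count_rng = np.random.default_rng(children[0])
    max_events = karyotype.total_telomeres // 2
    event_counts = np.minimum(
        count_rng.poisson(bias.events_per_cell_mean, size=n_cells), max_events
    )

    sampler = _PairSampler(karyotype, bias)
    metaphases: list[Metaphase] = []
    empty = Metaphase(karyotype=karyotype, events=())
    for i, k in enumerate(event_counts):
        if k == 0:
            metaphases.append(empty)
            continue
        rng = np.random.default_rng(children[i + 1])
        events = sampler.draw_events(int(k), rng, bias.p_g1)
        metaphases.append(Metaphase(karyotype=karyotype, events=tuple(events)))
    return count_fused_telomeres(metaphases)
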