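"""Stage 1 of the annotation-transfer pipeline: hit filtering and mapping.

Remote-homology hit tables (one per model-organism query) are filtered
by E-value and probability, reduced to per-query top hits, inverted
into non-redundant target lists, intersected bidirectionally into
best-bidirectional-hit (BBH) candidate pairs, and tallied across
organisms into a consensus matrix of high-confidence targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

from .io_formats import HitTable, HomologyHit

# One-decimal display rounding: a selection threshold t admits printed
# probabilities that round to >= t (e.g. 99.95 displays as 100.0).
_DISPLAY_TOL = 0.05


@dataclass(frozen=True)
class FilterConfig:
    """Hit-list filtering thresholds.

    Defaults mirror a standard remote-homology search configuration:
    E-value cutoff 1e-3, minimum probability 20 (on the printed 0-100
    scale), hit lists truncated at 250 entries.  ``probability_select``
    is used only by the consensus tally (100 = hits whose printed
    probability displays as 100.0).
    """

    evalue_max: float = 1e-3
    probability_min: float = 20.0
    max_hits: int = 250
    probability_select: float = 100.0

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not 0 <= self.probability_min <= 100:
            raise ValueError("probability_min must be on the 0-100 scale")
        if self.max_hits < 1:
            raise ValueError("max_hits must be >= 1")


@dataclass
class TopHitMap:
    """Per-query rank-1 passing hit; queries with no passing hit are unmapped."""

    entries: dict[str, HomologyHit] = field(default_factory=dict)
    unmapped: set[str] = field(default_factory=set)

    @property
    def queries(self) -> set[str]:
        return set(self.entries) | self.unmapped


@dataclass
class NonRedundantMap:
    """Inversion of a top-hit map: target -> set of queries it tops."""

    groups: dict[str, set[str]] = field(default_factory=dict)

    @property
    def targets(self) -> set[str]:
        return set(self.groups)


@dataclass(frozen=True)
class BBHPair:
    """Symmetric best-bidirectional pair between two proteomes."""

    id_a: str
    id_b: str
    forward_hit: HomologyHit
    reverse_hit: HomologyHit


@dataclass
class ConsensusMatrix:
    """Organism x target tally of high-probability homology incidences."""

    organisms: list[str]
    targets: list[str]
    counts: pd.DataFrame  # index = organisms, columns = targets, int

    @classmethod
    def from_counts(cls, counts: pd.DataFrame) -> "ConsensusMatrix":
        counts = counts.astype(int)
        return cls(list(counts.index), list(counts.columns), counts)

    @classmethod
    def from_tsv(cls, stream) -> "ConsensusMatrix":
        df = pd.read_csv(stream, sep="\t", index_col=0, comment="#")
        return cls.from_counts(df)


def filter_hits(table: HitTable, cfg: FilterConfig) -> HitTable:
    """Keep hits with evalue <= evalue_max and probability >= probability_min.

    Source order is preserved, the list is truncated to ``max_hits``
    and ranks are renumbered from 1.
    """
    passing = [
        h
        for h in table.hits
        if h.evalue <= cfg.evalue_max and h.probability >= cfg.probability_min
    ][: cfg.max_hits]
    renumbered = [replace(h, rank=i) for i, h in enumerate(passing, start=1)]
    return HitTable(table.query_id, renumbered, table.query_length)


def top_hits(tables: Iterable[HitTable], cfg: FilterConfig) -> TopHitMap:
    """Per query, the rank-1 hit surviving the filter (the tool's own ranking)."""
    thm = TopHitMap()
    for table in tables:
        if table.query_id in thm.queries:
            raise ValueError(f"duplicate query id {table.query_id}")
        filtered = filter_hits(table, cfg)
        if filtered.hits:
            thm.entries[table.query_id] = filtered.hits[0]
        else:
            thm.unmapped.add(table.query_id)
    return thm


def nonredundant_targets(thm: TopHitMap) -> NonRedundantMap:
    """Invert query -> top-target into target -> {queries}."""
    nrm = NonRedundantMap()
    for query, hit in thm.entries.items():
        nrm.groups.setdefault(hit.target_id, set()).add(query)
    return nrm


def merge_nonredundant(
    maps: Mapping[str, NonRedundantMap],
) -> tuple[set[str], dict]:
    """Union the target sets of several non-redundant maps.

    Returns the combined unique-target set plus an overlap report with
    the pairwise intersections and, for each map, the targets exclusive
    to it and the targets it misses relative to each other map (both
    directions of every set difference are reported).
    """
    if not maps:
        raise ValueError("at least one map required")
    sets = {name: m.targets for name, m in maps.items()}
    union: set[str] = set().union(*sets.values())
    names = list(sets)
    report = {
        "sizes": {n: len(s) for n, s in sets.items()},
        "union_size": len(union),
        "pairwise_intersection": {
            (a, b): sets[a] & sets[b] for i, a in enumerate(names) for b in names[i + 1 :]
        },
        "exclusive": {
            n: sets[n] - set().union(*(s for m, s in sets.items() if m != n))
            if len(sets) > 1
            else set(sets[n])
            for n in names
        },
        "missed_by": {
            (a, b): sets[b] - sets[a] for a in names for b in names if a != b
        },
    }
    return union, report


def bidirectional_best(forward: TopHitMap, reverse: TopHitMap) -> list[BBHPair]:
    """Pairs (a, b) with forward[a].target == b and reverse[b].target == a."""
    pairs = []
    for a, fhit in forward.entries.items():
        b = fhit.target_id
        rhit = reverse.entries.get(b)
        if rhit is not None and rhit.target_id == a:
            pairs.append(BBHPair(a, b, fhit, rhit))
    return sorted(pairs, key=lambda p: p.id_a)


def consensus_matrix(
    per_organism_tables: Mapping[str, Iterable[HitTable]],
    cfg: FilterConfig | None = None,
) -> ConsensusMatrix:
    """Tally, per organism and target, how many queries hit the target at
    probability >= ``probability_select`` (display-rounded).

    A query counts once per (query, target) incidence regardless of how
    many alignment blocks it has to the target.  Targets with all-zero
    columns are dropped; columns are ordered by total count descending,
    then id.
    """
    cfg = cfg or FilterConfig()
    threshold = cfg.probability_select - _DISPLAY_TOL
    organisms = list(per_organism_tables)
    tallies: dict[str, dict[str, int]] = {o: {} for o in organisms}
    for organism, tables in per_organism_tables.items():
        for table in tables:
            targets_hit = {
                h.target_id for h in table.hits if h.probability >= threshold
            }
            for t in targets_hit:
                tallies[organism][t] = tallies[organism].get(t, 0) + 1
    all_targets = sorted({t for d in tallies.values() for t in d})
    counts = pd.DataFrame(
        [[tallies[o].get(t, 0) for t in all_targets] for o in organisms],
        index=organisms,
        columns=all_targets,
        dtype=int,
    )
    counts = counts.loc[:, counts.sum(axis=0) > 0]
    order = sorted(counts.columns, key=lambda t: (-counts[t].sum(), t))
    counts = counts[order]
    return ConsensusMatrix(organisms, list(counts.columns), counts)


def select_consensus_targets(
    m: ConsensusMatrix, required_organisms: Iterable[str]
) -> list[str]:
    """Targets with >= 1 count in every required organism, ordered by
    total count descending then id."""
    required = set(required_organisms)
    unknown = required - set(m.organisms)
    if unknown:
        raise ValueError(f"unknown organism(s): {sorted(unknown)}")
    selected = [
        t for t in m.targets if all(m.counts.at[o, t] >= 1 for o in required)
    ]
    return sorted(selected, key=lambda t: (-m.counts[t].sum(), t))


def load_tlr_consensus_counts() -> ConsensusMatrix:
    """Published tally of 100%-probability TLR/Toll homology incidences of
    five model organisms (plus C. elegans) against the coral candidate set."""
    ref = resources.files("homolot.data").joinpath("tlr_consensus_counts.tsv")
    with ref.open("r") as fh:
        return ConsensusMatrix.from_tsv(fh)
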