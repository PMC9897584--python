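"""Deterministic toy corpora for exercising the full pipeline offline.

Every generator is a pure function of a :class:`SyntheticConfig` (same
config, same bytes) and emits files readable by :mod:`homolot.io_formats`
plus a truth table, so every pipeline stage can be checked against
planted ground truth without network access.

The homolog corpus emulates the regime the pipeline targets: model- and
target-organism family members diverged deep into the twilight zone of
homology (default point-substitution rate 0.75 per residue per lineage,
i.e. ~25% residual identity).  The accompanying HHR files encode the
planted homology as rank-1 hits with probability in [95, 100] and tiny
E-values, over a background of weaker decoy hits.  Substitutions are
uniform over the 19 alternative residues; no indels, paralog trees or
realistic score distributions are simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    AtomRecord,
    HitTable,
    HomologyHit,
    PrositePattern,
    ProteinRecord,
    STANDARD_AA,
    TMSegment,
    parse_pattern_string,
    write_fasta,
    write_hhr,
)

# Background sequences avoid tryptophan; every planted domain motif
# contains a literal W, so planted pattern instances cannot arise by
# chance in the background.
BACKGROUND_AA = STANDARD_AA.replace("W", "")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic corpora."""

    seed: int = 0
    n_model_queries: int = 200
    n_families: int = 60
    n_decoy_queries: int = 10
    mutation_rate: float = 0.75  # per residue per lineage; ~25% identity
    sequence_length: int = 200
    organisms: tuple[str, ...] = ("human",)
    prob100_fraction: float = 0.5  # planted hits printed as probability 100.0
    n_decoy_hits: int = 3

    def __post_init__(self) -> None:
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")
        if self.n_families < 1 or self.n_model_queries < self.n_families:
            raise ValueError("need at least one query per family")


@dataclass
class HomologCorpus:
    model_records: list[ProteinRecord]
    target_records: list[ProteinRecord]
    truth: pd.DataFrame  # columns: query_id, target_id, family
    decoy_queries: list[ProteinRecord]


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = BACKGROUND_AA) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    mask = rng.random(len(seq)) < rate
    for i in np.flatnonzero(mask):
        alternatives = [c for c in STANDARD_AA if c != out[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def make_homolog_corpus(cfg: SyntheticConfig) -> HomologCorpus:
    """Planted homolog families across a model and a target proteome.

    Each family has one target-organism member and >= 1 model-organism
    members derived from it by point substitution at ``mutation_rate``.
    The truth table records the intended top hit of every model query.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    targets, model, rows = [], [], []
    for fam in range(cfg.n_families):
        tid = f"pdam_{fam + 1:08d}-RA"
        tseq = _random_seq(rng, cfg.sequence_length)
        targets.append(ProteinRecord(tid, f"{tid} synthetic family {fam}", tseq))
    members = np.full(cfg.n_families, cfg.n_model_queries // cfg.n_families)
    members[: cfg.n_model_queries % cfg.n_families] += 1
    q = 0
    for fam, n_members in enumerate(members):
        for _ in range(n_members):
            qid = f"hsQ{q + 1:05d}"
            qseq = _mutate(rng, targets[fam].sequence, cfg.mutation_rate)
            model.append(ProteinRecord(qid, f"{qid} synthetic query fam {fam}", qseq))
            rows.append(
                {"query_id": qid, "target_id": targets[fam].id, "family": fam}
            )
            q += 1
    decoys = [
        ProteinRecord(
            f"hsDECOY{i + 1:03d}",
            f"hsDECOY{i + 1:03d} unrelated query",
            _random_seq(rng, cfg.sequence_length),
        )
        for i in range(cfg.n_decoy_queries)
    ]
    return HomologCorpus(model, targets, pd.DataFrame(rows), decoys)


def _planted_hit(
    rng: np.random.Generator,
    query: ProteinRecord,
    target: ProteinRecord,
    rank: int,
    probability: float,
    evalue: float,
) -> HomologyHit:
    n = min(len(query.sequence), len(target.sequence))
    return HomologyHit(
        query_id=query.id,
        target_id=target.id,
        rank=rank,
        probability=round(probability, 1),
        evalue=float(f"{evalue:.1E}"),
        pvalue=float(f"{evalue / 10:.1E}"),
        score=round(float(50 + probability), 1),
        cols_matched=n,
        query_aln=query.sequence[:n],
        target_aln=target.sequence[:n],
        query_start=1,
        query_end=n,
        target_start=1,
        target_end=n,
        target_length=len(target.sequence),
    )


def _decoy_hits(
    rng: np.random.Generator,
    query: ProteinRecord,
    pool: Sequence[ProteinRecord],
    exclude: str,
    start_rank: int,
    n_decoys: int,
) -> list[HomologyHit]:
    candidates = [t for t in pool if t.id != exclude]
    chosen = rng.choice(len(candidates), size=min(n_decoys, len(candidates)), replace=False)
    probs = sorted(rng.uniform(20, 90, size=len(chosen)), reverse=True)
    hits = []
    for i, (ci, prob) in enumerate(zip(chosen, probs)):
        evalue = 10.0 ** rng.uniform(-8, -4)
        # the last decoy fails the E-value filter, exercising the cutoff
        if i == len(chosen) - 1:
            evalue = 10.0 ** rng.uniform(-2.5, -1.5)
        hits.append(
            _planted_hit(rng, query, candidates[ci], start_rank + i, prob, evalue)
        )
    return hits


def make_hhr_tables(
    corpus: HomologCorpus, cfg: SyntheticConfig
) -> tuple[list[HitTable], list[HitTable], pd.DataFrame]:
    """Forward (model -> target) and reverse (target -> model) hit tables
    consistent with the planted homology.

    The forward rank-1 hit of every model query is its planted target
    (probability in [95, 100], E-value <= 1e-10); the reverse rank-1 hit
    of every target is the designated reverse-best member of its family
    (the first query, in id order).  Returns the two table lists plus
    the best-bidirectional truth table.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    by_query = {r.id: r for r in corpus.model_records}
    by_target = {r.id: r for r in corpus.target_records}

    forward: list[HitTable] = []
    for _, row in corpus.truth.iterrows():
        query = by_query[row.query_id]
        target = by_target[row.target_id]
        if rng.random() < cfg.prob100_fraction:
            prob = 100.0
        else:
            prob = rng.uniform(95, 99.9)
        planted = _planted_hit(rng, query, target, 1, prob, 10.0 ** rng.uniform(-40, -10))
        decoys = _decoy_hits(
            rng, query, corpus.target_records, target.id, 2, cfg.n_decoy_hits
        )
        forward.append(HitTable(query.id, [planted] + decoys, len(query.sequence)))
    for decoy in corpus.decoy_queries:
        # decoy-only queries: every hit fails the default thresholds
        weak = [
            _planted_hit(
                rng,
                decoy,
                corpus.target_records[int(rng.integers(len(corpus.target_records)))],
                i + 1,
                rng.uniform(5, 19),
                10.0 ** rng.uniform(-2, 0),
            )
            for i in range(2)
        ]
        forward.append(HitTable(decoy.id, weak, len(decoy.sequence)))

    reverse: list[HitTable] = []
    bbh_rows = []
    for target in corpus.target_records:
        fam_queries = sorted(
            corpus.truth.loc[corpus.truth.target_id == target.id, "query_id"]
        )
        best_query = by_query[fam_queries[0]]
        planted = _planted_hit(
            rng, target, best_query, 1, rng.uniform(95, 100), 10.0 ** rng.uniform(-40, -10)
        )
        decoys = _decoy_hits(
            rng, target, corpus.model_records, best_query.id, 2, cfg.n_decoy_hits
        )
        reverse.append(HitTable(target.id, [planted] + decoys, len(target.sequence)))
        bbh_rows.append({"query_id": best_query.id, "target_id": target.id})
    return forward, reverse, pd.DataFrame(bbh_rows)


def write_corpus(
    corpus: HomologCorpus,
    forward: Sequence[HitTable],
    reverse: Sequence[HitTable],
    out_dir: str | Path,
) -> None:
    """Write FASTA proteomes and per-query HHR files under ``out_dir``."""
    out = Path(out_dir)
    (out / "forward").mkdir(parents=True, exist_ok=True)
    (out / "reverse").mkdir(parents=True, exist_ok=True)
    with open(out / "model.faa", "w") as fh:
        write_fasta(corpus.model_records + corpus.decoy_queries, fh)
    with open(out / "target.faa", "w") as fh:
        write_fasta(corpus.target_records, fh)
    corpus.truth.to_csv(out / "truth_top_hits.tsv", sep="\t", index=False)
    for table in forward:
        with open(out / "forward" / f"{table.query_id}.hhr", "w") as fh:
            write_hhr(table, fh)
    for table in reverse:
        with open(out / "reverse" / f"{table.query_id}.hhr", "w") as fh:
            write_hhr(table, fh)


def make_consensus_tables(
    counts: pd.DataFrame, seed: int = 0
) -> dict[str, list[HitTable]]:
    """Per-organism hit tables whose 100%-probability tally reproduces a
    seeded organism x target count matrix exactly."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    tables: dict[str, list[HitTable]] = {}
    for organism in counts.index:
        org_tables = []
        q = 0
        for target in counts.columns:
            for _ in range(int(counts.at[organism, target])):
                qid = f"{organism.replace(' ', '').replace('.', '')}_q{q:04d}"
                hit = HomologyHit(
                    query_id=qid,
                    target_id=str(target),
                    rank=1,
                    probability=100.0,
                    evalue=1e-30,
                    pvalue=1e-34,
                    score=200.0,
                    cols_matched=100,
                    query_start=1,
                    query_end=100,
                    target_start=1,
                    target_end=100,
                )
                org_tables.append(HitTable(qid, [hit]))
                q += 1
        tables[str(organism)] = org_tables
    return tables


# ---------------------------------------------------------------------------
# Domain-architecture fixtures
# ---------------------------------------------------------------------------

# Toy motifs; every motif contains a literal W so it cannot occur in the
# W-free background.
DOMAIN_PATTERNS: dict[str, str] = {
    "LRR": "L-W-x(2)-L-L-N.",
    "TIR": "F-W-D-A-F-I-S-Y.",
    "CADHERIN": "D-W-N-D-N-G.",
    "EGF_CA": "C-W-C-x-C-E.",
    "TSP3": "G-W-G-G-E-D.",
}

_CATEGORY_LAYOUT: dict[str, dict] = {
    "canonical_TLR": {"ec": ["LRR", "LRR", "LRR"], "cp": ["TIR"]},
    "TIR_only": {"ec": [], "cp": ["TIR"]},
    "LRR_only": {"ec": ["LRR", "LRR"], "cp": []},
    "TLR_with_extra_domains": {
        "ec": ["LRR", "LRR", "CADHERIN", "EGF_CA"],
        "cp": ["TIR"],
    },
    "not_TLR": {"ec": [], "cp": []},
}


@dataclass
class DomainCorpus:
    records: list[ProteinRecord]
    tm_segments: list[TMSegment]
    patterns: list[PrositePattern]
    truth: pd.DataFrame  # columns: protein_id, category


def _concrete_instance(rng: np.random.Generator, pattern: PrositePattern) -> str:
    out = []
    for e in pattern.elements:
        reps = int(rng.integers(e.min_rep, e.max_rep + 1))
        for _ in range(reps):
            if e.kind == "literal":
                out.append(e.residues)
            elif e.kind == "any":
                out.append(rng.choice(list(STANDARD_AA)))
            elif e.kind == "allowed":
                out.append(rng.choice(list(e.residues)))
            else:
                choices = [c for c in STANDARD_AA if c not in e.residues]
                out.append(rng.choice(choices))
    return "".join(out)


def make_domain_proteins(
    cfg: SyntheticConfig,
    categories: Mapping[str, int] | None = None,
    length: int = 900,
    tm_span: tuple[int, int] = (600, 622),
) -> DomainCorpus:
    """Sequences with planted domain instances on the recorded side of a
    planted TM helix, one protein per requested (category, replicate).

    The extracellular side is the N-terminal side (type I convention);
    planted extracellular motifs land before the helix, cytoplasmic
    motifs after it.
    """
    categories = dict(categories or {c: 1 for c in _CATEGORY_LAYOUT})
    unknown = set(categories) - set(_CATEGORY_LAYOUT)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 4]))
    patterns = [parse_pattern_string(pa, pid) for pid, pa in DOMAIN_PATTERNS.items()]
    by_id = {p.pattern_id: p for p in patterns}
    records, tms, rows = [], [], []
    idx = 0
    for category, n in categories.items():
        layout = _CATEGORY_LAYOUT[category]
        for _ in range(n):
            idx += 1
            pid = f"dom_{idx:05d}"
            seq = list(_random_seq(rng, length))
            seq[tm_span[0] - 1 : tm_span[1]] = "A" * (tm_span[1] - tm_span[0] + 1)
            # extracellular instances in [20, tm_start-60), spaced 40 apart
            for j, dom in enumerate(layout["ec"]):
                instance = _concrete_instance(rng, by_id[dom])
                start = 20 + j * 40
                seq[start - 1 : start - 1 + len(instance)] = instance
            for j, dom in enumerate(layout["cp"]):
                instance = _concrete_instance(rng, by_id[dom])
                start = tm_span[1] + 30 + j * 40
                seq[start - 1 : start - 1 + len(instance)] = instance
            records.append(ProteinRecord(pid, f"{pid} planted {category}", "".join(seq)))
            tms.append(TMSegment(pid, tm_span[0], tm_span[1], "TMhelix"))
            tms.append(TMSegment(pid, 1, tm_span[0] - 1, "outside"))
            tms.append(TMSegment(pid, tm_span[1] + 1, length, "inside"))
            rows.append({"protein_id": pid, "category": category})
    return DomainCorpus(records, tms, patterns, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Interface / perturbation fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticInterfaceScorer:
    """Mock pair scorer whose output depends only on how intact the
    planted interface of sequence A is.

    score = sigmoid(steepness * (fraction of interface residues still
    matching the reference - midpoint)); deterministic by construction.
    """

    reference_seq: str
    interface_positions: tuple[int, ...]
    steepness: float = 10.0
    midpoint: float = 0.5

    def score(self, seq_a: str, seq_b: str) -> float:
        intact = sum(
            1
            for p in self.interface_positions
            if p <= len(seq_a) and seq_a[p - 1] == self.reference_seq[p - 1]
        )
        frac = intact / len(self.interface_positions)
        return float(1.0 / (1.0 + np.exp(-self.steepness * (frac - self.midpoint))))


@dataclass(frozen=True)
class ConstantScorer:
    value: float = 0.8

    def score(self, seq_a: str, seq_b: str) -> float:
        return self.value


@dataclass
class InterfaceComplex:
    seq_a: ProteinRecord
    seq_b: ProteinRecord
    scorer: LogisticInterfaceScorer
    atoms_a: list[AtomRecord]
    atoms_b: list[AtomRecord]
    interface_positions: set[int]


def make_interface_complex(
    cfg: SyntheticConfig,
    length_a: int = 300,
    length_b: int = 120,
    n_interface: int = 30,
    index: int = 0,
) -> InterfaceComplex:
    """A toy alpha-beta complex with a planted binding interface.

    ``n_interface`` residues of chain A sit within 5 angstrom of chain B
    in the toy coordinates; all other chain-A residues are >= 10 angstrom
    away.  The mock scorer is a logistic function of how many planted
    interface residues of sequence A are unchanged.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5, index]))
    seq_a = _random_seq(rng, length_a, STANDARD_AA)
    seq_b = _random_seq(rng, length_b, STANDARD_AA)
    positions = tuple(
        sorted(int(p) + 1 for p in rng.choice(length_a, size=n_interface, replace=False))
    )
    atoms_b = [AtomRecord("B", 1, "GLY", "CA", 0.0, 0.0, 0.0)]
    atoms_a = []
    for p in range(1, length_a + 1):
        if p in positions:
            theta = 2 * np.pi * (p / length_a)
            x, y, z = 4.0 * np.cos(theta), 4.0 * np.sin(theta), 0.0
        else:
            x, y, z = 30.0 + p, 50.0, 0.0
        atoms_a.append(AtomRecord("A", p, "ALA", "CA", round(x, 3), round(y, 3), z))
    scorer = LogisticInterfaceScorer(seq_a, positions)
    return InterfaceComplex(
        ProteinRecord(f"alphaA{index:03d}", f"alphaA{index:03d} planted alpha", seq_a),
        ProteinRecord(f"betaB{index:03d}", f"betaB{index:03d} planted beta", seq_b),
        scorer,
        atoms_a,
        atoms_b,
        set(positions),
    )
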