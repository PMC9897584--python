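"""Stage-2 evidence for heterotrimeric G-protein candidates.

A pluggable pair scorer (the contract satisfied by sequence-based
protein-protein interaction predictors) drives an all-vs-all screen of
candidate alpha, beta and gamma subunits.  Evidence for true G-protein
subunits is then gathered three ways: alpha-beta-gamma triangles in the
predicted network, conservation of predicted edges in a second coral
species through a best-bidirectional BLAST map, and an in-silico
mutagenesis test in which perturbing putative binding-site residues
depresses the predicted interaction probability far more than
perturbing random residues.  Structural interface residues are
extracted from co-crystal coordinates with a distance cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .io_formats import AtomRecord, BlastRow, ProteinRecord, STANDARD_AA

ROLES = ("alpha", "beta", "gamma")


class PairScorer(Protocol):
    """Contract for an interaction predictor.

    ``score(seq_a, seq_b)`` returns an interaction probability in
    [0, 1], deterministically for fixed inputs and fixed scorer state.
    Symmetry is not assumed; callers pass sequences in a documented
    role order (alpha first for alpha-beta pairs, beta first for
    beta-gamma pairs).
    """

    def score(self, seq_a: str, seq_b: str) -> float: ...


@dataclass
class PPINetwork:
    """Role-tagged interaction network over candidate subunits."""

    roles: dict[str, str]  # node id -> alpha | beta | gamma
    edges: dict[frozenset, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for node, role in self.roles.items():
            if role not in ROLES:
                raise ValueError(f"node {node}: unknown role {role!r}")
        for edge in self.edges:
            a, b = tuple(edge)
            if self.roles[a] == self.roles[b]:
                raise ValueError(f"edge {a}-{b} joins two {self.roles[a]} nodes")

    def has_edge(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.edges

    def add_edge(self, a: str, b: str, probability: float) -> None:
        if self.roles[a] == self.roles[b]:
            raise ValueError(f"edge {a}-{b} joins two {self.roles[a]} nodes")
        self.edges[frozenset((a, b))] = probability


@dataclass
class CrossSpeciesMap:
    """Best-bidirectional pairs between two proteomes (each id at most once)."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("an id appears in more than one pair")

    def forward(self) -> dict[str, str]:
        return {a: b for a, b in self.pairs}


@dataclass(frozen=True)
class PerturbationResult:
    """Interaction probabilities before and after in-silico mutagenesis."""

    original: float
    permuted_mean: float
    permuted_sd: float
    random_mean: float
    random_sd: float
    n_trials: int
    k: int
    seed: int


def interface_residues(
    atoms_a: Sequence[AtomRecord],
    atoms_b: Sequence[AtomRecord],
    cutoff: float = 5.0,
) -> set[tuple[str, int]]:
    """Residues of chain set A with any atom within ``cutoff`` angstrom of
    any atom of chain set B (Euclidean, any-atom rule)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not atoms_a or not atoms_b:
        raise ValueError("both atom lists must be non-empty")
    coords_a = np.array([[a.x, a.y, a.z] for a in atoms_a])
    coords_b = np.array([[b.x, b.y, b.z] for b in atoms_b])
    tree = cKDTree(coords_b)
    close = tree.query_ball_point(coords_a, cutoff)
    return {
        (atoms_a[i].chain, atoms_a[i].residue_number)
        for i, neighbours in enumerate(close)
        if neighbours
    }


def screen(
    alphas: Sequence[ProteinRecord],
    betas: Sequence[ProteinRecord],
    gammas: Sequence[ProteinRecord],
    scorer: PairScorer,
    edge_threshold: float = 0.5,
) -> tuple[PPINetwork, pd.DataFrame]:
    """All-vs-all screen of alpha-beta, beta-gamma and alpha-gamma pairs.

    Every cross-role pair is scored exactly once (first argument in role
    order alpha < beta < gamma).  Returns the thresholded network plus
    the full score table.
    """
    ids = [r.id for r in (*alphas, *betas, *gammas)]
    if len(set(ids)) != len(ids):
        raise ValueError("role lists must be disjoint with unique ids")
    roles = {r.id: "alpha" for r in alphas}
    roles.update({r.id: "beta" for r in betas})
    roles.update({r.id: "gamma" for r in gammas})
    net = PPINetwork(roles)
    rows = []
    for group_a, group_b in ((alphas, betas), (betas, gammas), (alphas, gammas)):
        for ra in group_a:
            for rb in group_b:
                p = scorer.score(ra.sequence, rb.sequence)
                rows.append(
                    {
                        "id_a": ra.id,
                        "id_b": rb.id,
                        "role_a": roles[ra.id],
                        "role_b": roles[rb.id],
                        "probability": p,
                    }
                )
                if p >= edge_threshold:
                    net.add_edge(ra.id, rb.id, p)
    return net, pd.DataFrame(rows)


def _best_hits(rows: Iterable[BlastRow]) -> dict[str, str]:
    """Best hit per query: max bitscore, ties by min evalue then target id."""
    best: dict[str, BlastRow] = {}
    for row in rows:
        cur = best.get(row.query_id)
        if cur is None or (-row.bitscore, row.evalue, row.target_id) < (
            -cur.bitscore,
            cur.evalue,
            cur.target_id,
        ):
            best[row.query_id] = row
    return {q: r.target_id for q, r in best.items()}


def bbh_map(
    blast_forward: Iterable[BlastRow], blast_reverse: Iterable[BlastRow]
) -> CrossSpeciesMap:
    """Mutual-best pairs from two directed BLAST tabular result sets."""
    fwd = _best_hits(blast_forward)
    rev = _best_hits(blast_reverse)
    pairs = {(a, b) for a, b in fwd.items() if rev.get(b) == a}
    return CrossSpeciesMap(pairs)


def overlay(
    net_1: PPINetwork, net_2: PPINetwork, cross_map: CrossSpeciesMap
) -> set[frozenset]:
    """Edges of ``net_1`` whose mapped endpoints are also an edge of ``net_2``."""
    mapping = cross_map.forward()
    conserved = set()
    for edge in net_1.edges:
        a, b = tuple(edge)
        ma, mb = mapping.get(a), mapping.get(b)
        if ma is not None and mb is not None and net_2.has_edge(ma, mb):
            conserved.add(edge)
    return conserved


def triangle_evidence(net: PPINetwork) -> list[tuple[str, str, str]]:
    """Alpha-beta-gamma triples with all three role-respecting edges present."""
    by_role: dict[str, list[str]] = {r: [] for r in ROLES}
    for node, role in net.roles.items():
        by_role[role].append(node)
    triples = []
    for a in sorted(by_role["alpha"]):
        for b in sorted(by_role["beta"]):
            if not net.has_edge(a, b):
                continue
            for g in sorted(by_role["gamma"]):
                if net.has_edge(b, g) and net.has_edge(a, g):
                    triples.append((a, b, g))
    return triples


def perturbation_test(
    seq_a: ProteinRecord | str,
    seq_b: ProteinRecord | str,
    scorer: PairScorer,
    site_positions: Iterable[int],
    k: int | None = 25,
    n_trials: int = 50,
    seed: int = 0,
) -> PerturbationResult:
    """In-silico mutagenesis test of a putative binding interface.

    The pair is scored unperturbed, then re-scored over ``n_trials``
    trials per arm.  Site arm: ``k`` positions sampled uniformly without
    replacement from ``site_positions`` on sequence A, each substituted
    by a residue drawn uniformly from the 19 non-identical standard
    residues.  Random arm: identical, but positions are drawn from the
    whole of sequence A.  ``k=None`` uses min(25, len(site_positions))
    with a warning when the site set is smaller than 25.  Fully
    reproducible from ``seed``: one base seed spawns independent
    per-trial streams.
    """
    a = seq_a.sequence if isinstance(seq_a, ProteinRecord) else seq_a
    b = seq_b.sequence if isinstance(seq_b, ProteinRecord) else seq_b
    sites = sorted(set(site_positions))
    if any(p < 1 or p > len(a) for p in sites):
        raise ValueError("site positions outside sequence A")
    if k is None:
        k = min(25, len(sites))
        if k < 25:
            warnings.warn(f"site set smaller than 25; using k={k}")
    if k > len(sites):
        raise ValueError(f"k={k} exceeds the {len(sites)} site positions")
    if k > len(a):
        raise ValueError(f"k={k} exceeds sequence length {len(a)}")

    original = scorer.score(a, b)
    base = np.random.SeedSequence(seed)
    site_ss, random_ss = base.spawn(2)

    def arm(pool: Sequence[int], arm_ss: np.random.SeedSequence) -> tuple[float, float]:
        scores = np.empty(n_trials)
        pool_arr = np.asarray(pool)
        for t, child in enumerate(arm_ss.spawn(n_trials)):
            rng = np.random.default_rng(child)
            chosen = rng.choice(pool_arr, size=k, replace=False) if k else []
            mutated = list(a)
            for p in chosen:
                alternatives = [c for c in STANDARD_AA if c != mutated[p - 1]]
                mutated[p - 1] = alternatives[rng.integers(len(alternatives))]
            scores[t] = scorer.score("".join(mutated), b)
        if np.all(scores == scores[0]):
            # degenerate arm (e.g. a constant scorer, or k = 0): report the
            # common value exactly rather than a rounding-noise mean
            return float(scores[0]), 0.0
        return float(scores.mean()), float(scores.std(ddof=0))

    permuted_mean, permuted_sd = arm(sites, site_ss)
    random_mean, random_sd = arm(range(1, len(a) + 1), random_ss)
    return PerturbationResult(
        original=original,
        permuted_mean=permuted_mean,
        permuted_sd=permuted_sd,
        random_mean=random_mean,
        random_sd=random_sd,
        n_trials=n_trials,
        k=k,
        seed=seed,
    )


def site_positions_from_alignment(
    candidate_aln: str, reference_aln: str, reference_site: Iterable[int]
) -> set[int]:
    """Map reference binding-site positions onto a candidate through a
    pairwise alignment; sites falling in candidate gaps are dropped
    with a warning."""
    if len(candidate_aln) != len(reference_aln):
        raise ValueError("alignment rows differ in length")
    wanted = set(reference_site)
    mapped: set[int] = set()
    dropped: set[int] = set()
    ref_pos = cand_pos = 0
    for r, c in zip(reference_aln, candidate_aln):
        if r != "-":
            ref_pos += 1
        if c != "-":
            cand_pos += 1
        if r != "-" and ref_pos in wanted:
            if c != "-":
                mapped.add(cand_pos)
            else:
                dropped.add(ref_pos)
    if dropped:
        warnings.warn(f"reference sites {sorted(dropped)} fall in candidate gaps")
    return mapped
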