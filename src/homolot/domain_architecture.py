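"""Stage-2 filter for type I receptor candidates.

Candidate sequences are scanned with PROSITE-style patterns, the
resulting domain hits are placed on the extracellular or cytoplasmic
side of a predicted transmembrane (TM) helix, and the domain topology
is classified against the canonical Toll-like receptor architecture
(extracellular leucine-rich repeats, single TM helix, cytoplasmic TIR
domain).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, NamedTuple, Sequence

from .io_formats import PrositePattern, ProteinRecord, TMSegment

# Extracellular domain classes that, added to the canonical LRR+TIR core,
# mark a receptor as a TLR variant with extra ectodomain modules.
DEFAULT_EXTRA_DOMAIN_CLASSES = frozenset({"CADHERIN", "EGF_CA", "TSP3", "TSP_CTER"})

CATEGORIES = ("canonical_TLR", "TIR_only", "LRR_only", "TLR_with_extra_domains", "not_TLR")


@dataclass(frozen=True)
class DomainHit:
    pattern_id: str
    protein_id: str
    start: int  # 1-based inclusive
    end: int
    matched_text: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("hit end before start")


class Placement(NamedTuple):
    ec_domains: list[DomainHit]
    cp_domains: list[DomainHit]
    straddling: list[DomainHit]
    unplaced: list[DomainHit]


@dataclass(frozen=True)
class ArchitectureCall:
    protein_id: str
    ec_domains: tuple[str, ...]
    cp_domains: tuple[str, ...]
    tm_count: int
    category: str
    evidence: str = ""


def scan_pattern(
    seq: ProteinRecord | str,
    pattern: PrositePattern,
    mode: str = "all",
    protein_id: str | None = None,
) -> list[DomainHit]:
    """Match a PROSITE pattern against a sequence.

    ``mode="all"`` reports every (start, end) span that matches the
    pattern, including multiple end points of a variable-length pattern
    at the same start.  ``mode="scan"`` reports non-overlapping matches
    in a leftmost greedy scan: at most one (longest) hit per distinct
    start, resuming after each match.  ``<`` / ``>`` anchors restrict
    starts/ends to the sequence termini.
    """
    if isinstance(seq, ProteinRecord):
        sequence, pid = seq.sequence, protein_id or seq.id
    else:
        sequence, pid = seq, protein_id or ""
    if mode not in ("all", "scan"):
        raise ValueError(f"unknown mode {mode!r}")
    regex = re.compile(pattern.to_regex())
    n = len(sequence)
    starts = [0] if pattern.anchored_start else range(n)
    hits: list[DomainHit] = []
    if mode == "all":
        min_l, max_l = pattern.min_length, pattern.max_length
        for s in starts:
            for length in range(min_l, min(max_l, n - s) + 1):
                end = s + length
                if pattern.anchored_end and end != n:
                    continue
                if regex.fullmatch(sequence, s, end):
                    hits.append(DomainHit(pattern.pattern_id, pid, s + 1, end, sequence[s:end]))
        return hits
    # scan mode: greedy leftmost, non-overlapping
    pos = 0
    while pos < n:
        if pattern.anchored_start and pos > 0:
            break
        m = regex.match(sequence, pos) if pattern.anchored_start else regex.search(sequence, pos)
        if not m:
            break
        if pattern.anchored_end and m.end() != n:
            pos = m.start() + 1
            continue
        hits.append(
            DomainHit(pattern.pattern_id, pid, m.start() + 1, m.end(), m.group(0))
        )
        pos = m.end()
    return hits


def expand_pattern(pattern: PrositePattern, limit: int = 10**5) -> list[str]:
    """Enumerate every concrete string a pattern can match.

    Intended as an independent brute-force oracle for small patterns;
    raises if the expansion would exceed ``limit`` strings.
    """
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    element_choices: list[list[str]] = []
    for e in pattern.elements:
        if e.kind == "literal":
            letters = [e.residues]
        elif e.kind == "any":
            letters = list(alphabet)
        elif e.kind == "allowed":
            letters = list(e.residues)
        else:
            letters = [c for c in alphabet if c not in e.residues]
        reps: list[str] = []
        for r in range(e.min_rep, e.max_rep + 1):
            reps.extend("".join(t) for t in product(letters, repeat=r))
        element_choices.append(reps)
        count = 1
        for choices in element_choices:
            count *= len(choices)
        if count > limit:
            raise ValueError(f"expansion exceeds {limit} strings")
    return ["".join(parts) for parts in product(*element_choices)]


def place_domains(
    hits: Sequence[DomainHit],
    tms: Sequence[TMSegment],
    orientation: str = "n_term_out",
    strict_single_tm: bool = True,
) -> Placement:
    """Assign domain hits to the membrane sides of a single-TM receptor.

    With ``n_term_out`` (the type I receptor convention), domains ending
    before the TM helix are extracellular and domains starting after it
    are cytoplasmic; ``n_term_in`` swaps the two sides.  Domains
    overlapping the helix are straddling.  Zero TM helices leaves every
    domain unplaced (with a warning); more than one is an error when
    ``strict_single_tm`` is set.
    """
    if orientation not in ("n_term_out", "n_term_in"):
        raise ValueError(f"unknown orientation {orientation!r}")
    helices = [t for t in tms if t.kind == "TMhelix"]
    if len(helices) == 0:
        if hits:
            warnings.warn("no TM helix: domains left unplaced")
        return Placement([], [], [], list(hits))
    if len(helices) > 1 and strict_single_tm:
        raise ValueError(f"{len(helices)} TM helices; single-TM topology required")
    tm = helices[0]
    before, after, straddling = [], [], []
    for h in hits:
        if h.end < tm.start:
            before.append(h)
        elif h.start > tm.end:
            after.append(h)
        else:
            straddling.append(h)
    if orientation == "n_term_out":
        return Placement(before, after, straddling, [])
    return Placement(after, before, straddling, [])


def classify_tlr(
    protein_id: str,
    placement: Placement,
    lrr_ids: Iterable[str] = ("LRR",),
    tir_ids: Iterable[str] = ("TIR",),
    extra_domain_classes: Iterable[str] = DEFAULT_EXTRA_DOMAIN_CLASSES,
    tm_count: int = 1,
) -> ArchitectureCall:
    """Classify a placed domain composition against TLR architectures.

    canonical_TLR: >= 1 extracellular LRR, a cytoplasmic TIR and no extra
    ectodomain classes.  TLR_with_extra_domains: the canonical core plus
    extra extracellular domain classes (cadherin, calcium-binding EGF,
    thrombospondin modules, ...).  TIR_only: a TIR domain and zero LRRs
    anywhere.  LRR_only: LRRs and no TIR (rejected as a TLR).  Anything
    else: not_TLR.  The category is a pure function of the placed
    domain-class sets; hit order never matters.
    """
    lrr_ids, tir_ids = set(lrr_ids), set(tir_ids)
    extra_classes = set(extra_domain_classes)
    ec = [h.pattern_id for h in placement.ec_domains]
    cp = [h.pattern_id for h in placement.cp_domains]
    all_ids = (
        ec
        + cp
        + [h.pattern_id for h in placement.straddling]
        + [h.pattern_id for h in placement.unplaced]
    )
    n_lrr = sum(1 for d in all_ids if d in lrr_ids)
    has_tir = any(d in tir_ids for d in all_ids)
    ec_lrr = sum(1 for d in ec if d in lrr_ids)
    cp_tir = any(d in tir_ids for d in cp)
    ec_extra = sorted({d for d in ec if d in extra_classes})
    ec_other = sorted({d for d in ec if d not in lrr_ids | tir_ids | extra_classes})

    if has_tir and n_lrr == 0:
        category = "TIR_only"
    elif n_lrr > 0 and not has_tir:
        category = "LRR_only"
    elif ec_lrr >= 1 and cp_tir and not ec_extra and not ec_other:
        category = "canonical_TLR"
    elif ec_lrr >= 1 and cp_tir and ec_extra:
        category = "TLR_with_extra_domains"
    else:
        category = "not_TLR"
    evidence = (
        f"LRR={n_lrr} (ec={ec_lrr}), TIR_cp={cp_tir}, extra_ec={ec_extra}, "
        f"other_ec={ec_other}, tm={tm_count}"
    )
    return ArchitectureCall(
        protein_id=protein_id,
        ec_domains=tuple(ec),
        cp_domains=tuple(cp),
        tm_count=tm_count,
        category=category,
        evidence=evidence,
    )


def classify_protein(
    seq: ProteinRecord,
    patterns: Sequence[PrositePattern],
    tms: Sequence[TMSegment],
    orientation: str = "n_term_out",
    mode: str = "scan",
    **classify_kwargs,
) -> ArchitectureCall:
    """Scan, place and classify one protein in a single call."""
    hits: list[DomainHit] = []
    for pattern in patterns:
        hits.extend(scan_pattern(seq, pattern, mode=mode))
    own_tms = [t for t in tms if t.protein_id == seq.id]
    placement = place_domains(hits, own_tms, orientation=orientation)
    tm_count = sum(1 for t in own_tms if t.kind == "TMhelix")
    return classify_tlr(seq.id, placement, tm_count=tm_count, **classify_kwargs)
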