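"""Stage-2 filter for GPCR candidates: ligand-pocket conservation.

A candidate surviving the remote-homology stage is aligned pairwise to a
reference receptor (e.g. rod opsin).  Ballesteros-Weinstein (BW) labels
are transferred from the reference to the candidate through the
alignment, the residues at a configured set of cavity-facing positions
are read off into a pocket profile, and retinal-binding rules (Schiff
base lysine, counter-ion identity, minimal signalling pocket) decide
whether the candidate is plausibly a functional, light-sensitive opsin.

BW labels are strings ``"h.nn"``: helix index 1-7 and an offset around
the most conserved position of the helix, which is defined to be x.50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .io_formats import ProteinRecord

GAP = "-"


@dataclass(frozen=True)
class BWAnchorSet:
    """Reference-sequence positions of the x.50 residue of each helix."""

    anchors: Mapping[int, int]  # helix (1-7) -> 1-based reference position
    reference_id: str = ""

    def __post_init__(self) -> None:
        if sorted(self.anchors) != list(range(1, 8)):
            raise ValueError("anchors must cover helices 1-7")
        positions = [self.anchors[h] for h in range(1, 8)]
        if positions != sorted(positions) or len(set(positions)) != 7:
            raise ValueError("anchor positions must be strictly increasing")


@dataclass(frozen=True)
class PocketDefinition:
    """Ordered list of BW labels defining a ligand-binding pocket."""

    positions: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        if len(set(self.positions)) != len(self.positions):
            raise ValueError("pocket positions must be unique")


@dataclass
class PocketProfile:
    """Residues of one protein at the pocket's BW positions (gap if absent)."""

    protein_id: str
    residues: dict[str, str]  # BW label -> one-letter residue or GAP
    definition: PocketDefinition

    def __post_init__(self) -> None:
        if list(self.residues) != list(self.definition.positions):
            raise ValueError("profile ordering must match its pocket definition")


@dataclass(frozen=True)
class RetinalRule:
    """Positions involved in covalent retinal binding.

    ``schiff_position`` must hold the lysine that forms the Schiff base
    with retinal; ``counterion_position`` holds the residue stabilising
    it (acidic in vertebrate rod opsin).  ``minimal_pocket`` optionally
    names the 4 positions of the minimal signalling pocket.
    """

    schiff_position: str = "7.43"
    counterion_position: str = "3.28"
    minimal_pocket: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.schiff_position == self.counterion_position:
            raise ValueError("Schiff and counter-ion positions must differ")


@dataclass(frozen=True)
class RetinalVerdict:
    protein_id: str
    has_schiff_lysine: bool
    counterion_residue: str
    counterion_class: str  # acidic | tyrosine | serine | other
    minimal_pocket_conserved: int | None = None  # out of len(rule.minimal_pocket)


def _classify_counterion(residue: str) -> str:
    if residue in ("D", "E"):
        return "acidic"
    if residue == "Y":
        return "tyrosine"
    if residue == "S":
        return "serine"
    return "other"


def assign_bw(
    reference_aln: str,
    candidate_aln: str,
    anchors: BWAnchorSet,
    helix_bounds: Mapping[int, tuple[int, int]],
) -> dict[int, str]:
    """Transfer BW labels from the reference to the candidate through a
    pairwise alignment.

    Within each helix span of the reference, position p gets the label
    ``h.(50 + p - anchor[h])``; candidate positions aligned one-to-one
    with a labelled reference position inherit its label.  Candidate
    positions aligned to reference gaps receive no label.
    """
    if len(reference_aln) != len(candidate_aln):
        raise ValueError("alignment rows differ in length")
    ref_len = len(reference_aln.replace(GAP, ""))
    for helix, pos in anchors.anchors.items():
        lo, hi = helix_bounds[helix]
        if not lo <= pos <= hi:
            raise ValueError(f"anchor of helix {helix} outside its helix span")
        if pos > ref_len:
            raise ValueError(
                f"anchor of helix {helix} beyond the aligned reference (position {pos})"
            )

    ref_labels: dict[int, str] = {}
    for helix in range(1, 8):
        lo, hi = helix_bounds[helix]
        anchor = anchors.anchors[helix]
        for p in range(lo, hi + 1):
            ref_labels[p] = f"{helix}.{50 + p - anchor}"

    mapping: dict[int, str] = {}
    ref_pos = cand_pos = 0
    for r, c in zip(reference_aln, candidate_aln):
        if r != GAP:
            ref_pos += 1
        if c != GAP:
            cand_pos += 1
        if r != GAP and c != GAP:
            label = ref_labels.get(ref_pos)
            if label is not None:
                mapping[cand_pos] = label
    return mapping


def extract_profile(
    seq: ProteinRecord | str,
    bw_map: Mapping[int, str],
    pocket: PocketDefinition,
    protein_id: str | None = None,
) -> PocketProfile:
    """Read the residues at each pocket position off a BW-labelled sequence."""
    if isinstance(seq, ProteinRecord):
        sequence = seq.sequence
        pid = protein_id or seq.id
    else:
        sequence = seq
        pid = protein_id or ""
    label_to_pos = {label: pos for pos, label in bw_map.items()}
    residues = {
        label: (sequence[label_to_pos[label] - 1] if label in label_to_pos else GAP)
        for label in pocket.positions
    }
    return PocketProfile(pid, residues, pocket)


def profile_identity(
    a: PocketProfile, b: PocketProfile, strict: bool = False
) -> tuple[int, int]:
    """Count identical pocket residues between two profiles.

    Default mode excludes positions gapped on either side from
    ``n_compared``; ``strict=True`` counts such positions as compared
    (hence as mismatches) unless both are gaps.
    """
    if a.definition.positions != b.definition.positions:
        raise ValueError("profiles use different pocket definitions")
    n_identical = n_compared = 0
    for label in a.definition.positions:
        ra, rb = a.residues[label], b.residues[label]
        if ra == GAP and rb == GAP:
            continue
        if ra == GAP or rb == GAP:
            if strict:
                n_compared += 1
            continue
        n_compared += 1
        if ra == rb:
            n_identical += 1
    return n_identical, n_compared


def check_retinal(
    profile: PocketProfile,
    rule: RetinalRule,
    reference_profile: PocketProfile | None = None,
) -> RetinalVerdict:
    """Apply the retinal-binding rule to a pocket profile.

    The Schiff-base position must hold a lysine; the counter-ion residue
    is classified (acidic/tyrosine/serine/other).  When the rule names a
    minimal pocket and a reference profile is supplied, the number of
    conserved minimal-pocket residues is reported as well.
    """
    for pos in (rule.schiff_position, rule.counterion_position, *rule.minimal_pocket):
        if pos not in profile.residues:
            raise ValueError(f"rule position {pos} absent from the pocket definition")
    counterion = profile.residues[rule.counterion_position]
    conserved: int | None = None
    if rule.minimal_pocket and reference_profile is not None:
        conserved = sum(
            1
            for pos in rule.minimal_pocket
            if profile.residues[pos] != GAP
            and profile.residues[pos] == reference_profile.residues[pos]
        )
    return RetinalVerdict(
        protein_id=profile.protein_id,
        has_schiff_lysine=profile.residues[rule.schiff_position] == "K",
        counterion_residue=counterion,
        counterion_class=_classify_counterion(counterion),
        minimal_pocket_conserved=conserved,
    )


def rank_opsin_candidates(
    candidates: Iterable[PocketProfile],
    references: Iterable[PocketProfile],
    rule: RetinalRule,
) -> pd.DataFrame:
    """Score candidates against reference pocket profiles.

    Per candidate: the best-matching reference (most identical pocket
    residues, ties broken by reference id), identity counts, the retinal
    verdict, and a pass flag requiring the Schiff-base lysine.  Rows are
    ordered passing first, then by identity to the best reference.
    """
    references = list(references)
    if not references:
        raise ValueError("at least one reference profile required")
    rows = []
    for cand in candidates:
        scored = sorted(
            (
                (*profile_identity(cand, ref), ref)
                for ref in references
            ),
            key=lambda t: (-t[0], t[2].protein_id),
        )
        n_ident, n_comp, best = scored[0]
        verdict = check_retinal(cand, rule)
        rows.append(
            {
                "candidate": cand.protein_id,
                "best_reference": best.protein_id,
                "n_identical": n_ident,
                "n_compared": n_comp,
                "has_schiff_lysine": verdict.has_schiff_lysine,
                "counterion_residue": verdict.counterion_residue,
                "counterion_class": verdict.counterion_class,
                "passes": verdict.has_schiff_lysine,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["passes", "n_identical", "candidate"], ascending=[False, False, True]
        ).reset_index(drop=True)
    return df


def load_bw_config(path=None) -> dict:
    """Load a BW configuration (anchors, helix bounds, pocket, retinal rule).

    Without ``path`` the packaged rod-opsin reference configuration is
    used.  Returns a dict with keys ``anchors`` (:class:`BWAnchorSet`),
    ``helix_bounds``, ``pocket`` (:class:`PocketDefinition`) and
    ``rule`` (:class:`RetinalRule`).
    """
    if path is None:
        ref = resources.files("homolot.data").joinpath("rhodopsin_bw.yaml")
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    anchors = BWAnchorSet(
        {int(k): int(v) for k, v in raw["anchors"].items()},
        raw.get("reference_id", ""),
    )
    helix_bounds = {int(k): tuple(v) for k, v in raw["helix_bounds"].items()}
    pocket = PocketDefinition(tuple(raw["pocket_positions"]), raw.get("reference_id", ""))
    rule = RetinalRule(
        schiff_position=raw.get("schiff_position", "7.43"),
        counterion_position=raw.get("counterion_position", "3.28"),
        minimal_pocket=tuple(raw.get("minimal_pocket") or ()),
    )
    return {"anchors": anchors, "helix_bounds": helix_bounds, "pocket": pocket, "rule": rule}
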