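"""Readers and writers for the file formats the annotation-transfer pipeline touches.

The pipeline consumes FASTA proteomes, HHblits result files (HHR text
layout), BLAST tabular hit lists, TMHMM-style transmembrane-segment
tables, PROSITE patterns in PA-line syntax, and PDB-format coordinates.
Each parser returns plain domain objects; FASTA, TM tables and PROSITE
patterns round-trip exactly through the matching writer.

Coordinate convention throughout: 1-based positions, inclusive ends.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, NamedTuple, TextIO

from Bio import SeqIO

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
# Ambiguity / rare codes folded into X on input (with a warning).
_AMBIGUOUS_AA = {"B": "X", "Z": "X", "U": "X", "J": "X", "O": "X"}


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_SHORT_ID_RE = re.compile(r"^(?:[A-Za-z]+_)?0*(\d+)(?:[-.][A-Za-z0-9]+)?$")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; ``id`` is the first whitespace token of the header."""

    id: str
    description: str
    sequence: str

    @property
    def short_id(self) -> str:
        """Numeric form of a genome-browser id: ``pdam_00017423-RA`` -> ``17423``.

        Ids without an embedded number are returned unchanged.
        """
        m = _SHORT_ID_RE.match(self.id)
        return m.group(1) if m else self.id

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequence)


def parse_fasta(stream: TextIO) -> list[ProteinRecord]:
    """Parse FASTA text into :class:`ProteinRecord` objects.

    Sequences are upper-cased; B/Z/U/J/O are folded to X with a warning;
    any other letter outside the 20 standard residues plus X raises
    :class:`ParseError` naming the offending record.  Ids must be unique.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(stream, "fasta"):
        seq = str(rec.seq).upper()
        folded = set(seq) & set(_AMBIGUOUS_AA)
        if folded:
            warnings.warn(
                f"record {rec.id}: ambiguous residue(s) {sorted(folded)} mapped to X"
            )
            seq = "".join(_AMBIGUOUS_AA.get(c, c) for c in seq)
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ParseError(f"record {rec.id}: invalid residue(s) {sorted(bad)}")
        if not seq:
            raise ParseError(f"record {rec.id}: empty sequence")
        if rec.id in seen:
            raise ParseError(f"duplicate record id {rec.id}")
        seen.add(rec.id)
        records.append(ProteinRecord(rec.id, rec.description, seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], stream: TextIO, width: int = 60) -> None:
    for rec in records:
        header = rec.description if rec.description else rec.id
        stream.write(f">{header}\n")
        for i in range(0, len(rec.sequence), width):
            stream.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# HHR (HHblits / HHsearch result text)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HomologyHit:
    """One remote-homology hit as printed in an HHR result file."""

    query_id: str
    target_id: str
    rank: int
    probability: float  # printed 0-100 scale
    evalue: float
    pvalue: float
    score: float
    cols_matched: int
    query_aln: str = ""
    target_aln: str = ""
    query_start: int = 0
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0
    target_length: int | None = None

    def validate(self) -> None:
        if len(self.query_aln) != len(self.target_aln):
            raise ValueError(f"hit {self.target_id}: alignment strings differ in length")
        if self.query_aln:
            qlen = len(self.query_aln.replace("-", ""))
            tlen = len(self.target_aln.replace("-", ""))
            if qlen != self.query_end - self.query_start + 1:
                raise ValueError(f"hit {self.target_id}: query span/alignment mismatch")
            if tlen != self.target_end - self.target_start + 1:
                raise ValueError(f"hit {self.target_id}: target span/alignment mismatch")


@dataclass
class HitTable:
    """Ranked hit list of one query, in the source file's order."""

    query_id: str
    hits: list[HomologyHit] = field(default_factory=list)
    query_length: int | None = None

    def __post_init__(self) -> None:
        for h in self.hits:
            if h.query_id != self.query_id:
                raise ValueError(
                    f"hit for query {h.query_id} placed in table of {self.query_id}"
                )


_SUMMARY_RE = re.compile(
    r"^\s*(\d+)\s+(.*?)\s+(\d+(?:\.\d+)?)\s+(\S+)\s+(\S+)\s+(-?\d+(?:\.\d+)?)"
    r"\s+(-?\d+(?:\.\d+)?)\s+(\d+)\s+(\d+)-(\d+)\s+(\d+)-(\d+)\s*\((\d+)\)\s*$"
)
_ALN_LINE_RE = re.compile(r"^([QT])\s+(\S+)\s+(\d+)\s+([A-Za-z~.\-]+)\s+(\d+)")
_SKIP_ALN_IDS = ("Consensus", "ss_pred", "ss_dssp", "ss_conf")


def parse_hhr(stream: TextIO) -> HitTable:
    """Parse a single-query HHR result into a :class:`HitTable`.

    Probability, E-value, P-value, score and matched-column counts come
    from the summary hit list; alignment strings and spans come from the
    per-hit alignment blocks.  A listed hit whose alignment block is
    missing is kept with empty alignment fields (with a warning).
    """
    lines = stream.read().splitlines()
    query_id = ""
    query_length: int | None = None
    for line in lines:
        if line.startswith("Query"):
            parts = line.split()
            if len(parts) >= 2:
                query_id = parts[1]
        elif line.startswith("Match_columns"):
            try:
                query_length = int(line.split()[1])
            except (IndexError, ValueError):
                pass

    if any("No hits found" in line for line in lines):
        return HitTable(query_id=query_id, hits=[], query_length=query_length)

    # --- summary block ---
    header_idx = None
    for i, line in enumerate(lines):
        if re.match(r"^\s*No Hit\b", line):
            header_idx = i
            break
    if header_idx is None:
        raise ParseError("no summary hit-list header ('No Hit') found")

    summaries: dict[int, dict] = {}
    i = header_idx + 1
    while i < len(lines) and lines[i].strip():
        m = _SUMMARY_RE.match(lines[i])
        if not m:
            raise ParseError(f"line {i + 1}: malformed summary line: {lines[i]!r}")
        rank = int(m.group(1))
        summaries[rank] = {
            "name": m.group(2).split()[0],
            "probability": float(m.group(3)),
            "evalue": float(m.group(4)),
            "pvalue": float(m.group(5)),
            "score": float(m.group(6)),
            "cols": int(m.group(8)),
            "q_span": (int(m.group(9)), int(m.group(10))),
            "t_span": (int(m.group(11)), int(m.group(12))),
            "t_len": int(m.group(13)),
        }
        i += 1

    # --- alignment blocks ---
    blocks: dict[int, dict] = {}
    current: dict | None = None
    for line in lines[i:]:
        m_no = re.match(r"^No (\d+)\s*$", line)
        if m_no:
            current = {
                "target_id": "",
                "q_aln": [],
                "t_aln": [],
                "q_start": None,
                "q_end": 0,
                "t_start": None,
                "t_end": 0,
            }
            blocks[int(m_no.group(1))] = current
            continue
        if current is None:
            continue
        if line.startswith(">"):
            current["target_id"] = line[1:].split()[0] if line[1:].split() else ""
            continue
        m_aln = _ALN_LINE_RE.match(line)
        if m_aln:
            side, name, start, seq, end = m_aln.groups()
            if any(tag in name for tag in _SKIP_ALN_IDS):
                continue
            key = "q" if side == "Q" else "t"
            current[f"{key}_aln"].append(seq)
            if current[f"{key}_start"] is None:
                current[f"{key}_start"] = int(start)
            current[f"{key}_end"] = int(end)

    hits: list[HomologyHit] = []
    for rank in sorted(summaries):
        s = summaries[rank]
        b = blocks.get(rank)
        if b is None or not b["q_aln"]:
            warnings.warn(
                f"hit {rank} ({s['name']}): no alignment block; kept without alignment"
            )
            hit = HomologyHit(
                query_id=query_id,
                target_id=s["name"],
                rank=rank,
                probability=s["probability"],
                evalue=s["evalue"],
                pvalue=s["pvalue"],
                score=s["score"],
                cols_matched=s["cols"],
                query_start=s["q_span"][0],
                query_end=s["q_span"][1],
                target_start=s["t_span"][0],
                target_end=s["t_span"][1],
                target_length=s["t_len"],
            )
        else:
            hit = HomologyHit(
                query_id=query_id,
                target_id=b["target_id"] or s["name"],
                rank=rank,
                probability=s["probability"],
                evalue=s["evalue"],
                pvalue=s["pvalue"],
                score=s["score"],
                cols_matched=s["cols"],
                query_aln="".join(b["q_aln"]),
                target_aln="".join(b["t_aln"]),
                query_start=b["q_start"],
                query_end=b["q_end"],
                target_start=b["t_start"],
                target_end=b["t_end"],
                target_length=s["t_len"],
            )
            hit.validate()
        hits.append(hit)
    return HitTable(query_id=query_id, hits=hits, query_length=query_length)


def write_hhr(table: HitTable, stream: TextIO) -> None:
    """Emit a :class:`HitTable` in HHR text layout readable by :func:`parse_hhr`."""
    qlen = table.query_length or max((h.query_end for h in table.hits), default=0)
    stream.write(f"Query         {table.query_id}\n")
    stream.write(f"Match_columns {qlen}\n")
    stream.write("No_of_seqs    1 out of 1\n")
    stream.write("Neff          1.0\n\n")
    if not table.hits:
        stream.write("No hits found\n")
        return
    stream.write(
        " No Hit                             Prob E-value P-value  Score    SS Cols Query HMM  Template HMM\n"
    )
    for h in table.hits:
        tlen = h.target_length or h.target_end
        stream.write(
            f"{h.rank:>3} {h.target_id[:30]:<30} {h.probability:>5.1f} "
            f"{h.evalue:>8.1E} {h.pvalue:>8.1E} {h.score:>7.1f}   0.0 "
            f"{h.cols_matched:>4} {h.query_start:>4}-{h.query_end:<4} "
            f"{h.target_start:>4}-{h.target_end:<4}({tlen})\n"
        )
    stream.write("\n")
    for h in table.hits:
        stream.write(f"No {h.rank}\n")
        stream.write(f">{h.target_id}\n")
        stream.write(
            f"Probab={h.probability:.2f}  E-value={h.evalue:.2g}  "
            f"Score={h.score:.2f}  Aligned_cols={h.cols_matched}\n\n"
        )
        if h.query_aln:
            stream.write(
                f"Q {h.query_id:<18} {h.query_start:>4} {h.query_aln} {h.query_end} ({qlen})\n"
            )
            stream.write(
                f"T {h.target_id:<18} {h.target_start:>4} {h.target_aln} {h.target_end} "
                f"({h.target_length or h.target_end})\n"
            )
        stream.write("\n")
    stream.write("Done!\n")


# ---------------------------------------------------------------------------
# BLAST tabular (-outfmt 6)
# ---------------------------------------------------------------------------


class BlastRow(NamedTuple):
    query_id: str
    target_id: str
    percent_identity: float
    evalue: float
    bitscore: float


def parse_blast_tabular(stream: TextIO) -> list[BlastRow]:
    """Parse 12-column BLAST tabular output; rows kept in file order."""
    rows: list[BlastRow] = []
    for i, line in enumerate(stream):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 12:
            raise ParseError(f"row {i + 1}: expected 12 tab-separated columns, got {len(parts)}")
        rows.append(
            BlastRow(parts[0], parts[1], float(parts[2]), float(parts[10]), float(parts[11]))
        )
    return rows


# ---------------------------------------------------------------------------
# TMHMM-style transmembrane segment tables
# ---------------------------------------------------------------------------

TM_KINDS = ("TMhelix", "inside", "outside")


@dataclass(frozen=True)
class TMSegment:
    protein_id: str
    start: int
    end: int
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in TM_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.start > self.end:
            raise ValueError(f"segment start {self.start} > end {self.end}")


def parse_tm_table(stream: TextIO) -> list[TMSegment]:
    """Parse TMHMM long-format lines (protein, source, kind, start, end).

    Segments for one protein must not overlap.
    """
    segments: list[TMSegment] = []
    for i, line in enumerate(stream):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ParseError(f"line {i + 1}: expected 5 fields, got {len(parts)}")
        try:
            seg = TMSegment(parts[0], int(parts[3]), int(parts[4]), parts[2])
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: {exc}") from exc
        segments.append(seg)
    by_protein: dict[str, list[TMSegment]] = {}
    for seg in segments:
        by_protein.setdefault(seg.protein_id, []).append(seg)
    for pid, segs in by_protein.items():
        ordered = sorted(segs, key=lambda s: s.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start <= a.end:
                raise ParseError(
                    f"protein {pid}: overlapping segments {a.start}-{a.end} and {b.start}-{b.end}"
                )
    return segments


def write_tm_table(segments: Iterable[TMSegment], stream: TextIO) -> None:
    for seg in segments:
        stream.write(f"{seg.protein_id}\tTMHMM2.0\t{seg.kind}\t{seg.start}\t{seg.end}\n")


# ---------------------------------------------------------------------------
# PROSITE PA-line patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PatternElement:
    """One element of a PROSITE pattern.

    kind: ``literal`` | ``any`` | ``allowed`` | ``forbidden``.
    ``residues`` holds the literal letter or the set members.
    ``min_rep``/``max_rep`` encode ``(n)`` and ``(n,m)`` repeats.
    """

    kind: str
    residues: str
    min_rep: int = 1
    max_rep: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("literal", "any", "allowed", "forbidden"):
            raise ValueError(f"unknown element kind {self.kind!r}")
        if self.kind in ("allowed", "forbidden") and not self.residues:
            raise ValueError("empty residue set")
        if not (0 <= self.min_rep <= self.max_rep):
            raise ValueError(f"bad repeat bounds ({self.min_rep},{self.max_rep})")

    def render(self) -> str:
        if self.kind == "literal":
            core = self.residues
        elif self.kind == "any":
            core = "x"
        elif self.kind == "allowed":
            core = f"[{self.residues}]"
        else:
            core = "{" + self.residues + "}"
        if (self.min_rep, self.max_rep) == (1, 1):
            return core
        if self.min_rep == self.max_rep:
            return f"{core}({self.min_rep})"
        return f"{core}({self.min_rep},{self.max_rep})"

    def to_regex(self) -> str:
        if self.kind == "literal":
            core = re.escape(self.residues)
        elif self.kind == "any":
            core = "[A-Z]"
        elif self.kind == "allowed":
            core = f"[{self.residues}]"
        else:
            core = f"[^{self.residues}]"
        if (self.min_rep, self.max_rep) == (1, 1):
            return core
        if self.min_rep == self.max_rep:
            return f"{core}{{{self.min_rep}}}"
        return f"{core}{{{self.min_rep},{self.max_rep}}}"


@dataclass(frozen=True)
class PrositePattern:
    pattern_id: str
    elements: tuple[PatternElement, ...]
    anchored_start: bool = False
    anchored_end: bool = False

    def render(self) -> str:
        body = "-".join(e.render() for e in self.elements)
        return ("<" if self.anchored_start else "") + body + (">" if self.anchored_end else "") + "."

    def to_regex(self) -> str:
        return "".join(e.to_regex() for e in self.elements)

    @property
    def min_length(self) -> int:
        return sum(e.min_rep for e in self.elements)

    @property
    def max_length(self) -> int:
        return sum(e.max_rep for e in self.elements)


_ELEMENT_RE = re.compile(
    r"^(?:([A-Z])|(x)|\[([A-Z]+)\]|\{([A-Z]+)\})(?:\((\d+)(?:,(\d+))?\))?$"
)


def parse_pattern_string(text: str, pattern_id: str = "") -> PrositePattern:
    """Parse one PA-syntax pattern string, e.g. ``C-x(2)-[DE]-{P}.``."""
    raw = text.strip()
    if raw.endswith("."):
        raw = raw[:-1]
    anchored_start = raw.startswith("<")
    if anchored_start:
        raw = raw[1:]
    anchored_end = raw.endswith(">")
    if anchored_end:
        raw = raw[:-1]
    if not raw:
        raise ParseError(f"pattern {pattern_id!r}: empty pattern")
    elements: list[PatternElement] = []
    for pos, token in enumerate(raw.split("-"), start=1):
        m = _ELEMENT_RE.match(token)
        if not m:
            raise ParseError(
                f"pattern {pattern_id!r}: cannot parse element {pos} ({token!r})"
            )
        lit, anych, allowed, forbidden, n, mx = m.groups()
        if lit:
            kind, residues = "literal", lit
        elif anych:
            kind, residues = "any", ""
        elif allowed:
            kind, residues = "allowed", allowed
        else:
            kind, residues = "forbidden", forbidden
        min_rep = int(n) if n is not None else 1
        max_rep = int(mx) if mx is not None else min_rep
        try:
            elements.append(PatternElement(kind, residues, min_rep, max_rep))
        except ValueError as exc:
            raise ParseError(f"pattern {pattern_id!r}: element {pos}: {exc}") from exc
    return PrositePattern(pattern_id, tuple(elements), anchored_start, anchored_end)


def parse_prosite_patterns(stream: TextIO) -> list[PrositePattern]:
    """Parse a file of PA-syntax patterns, optionally preceded by ID lines."""
    patterns: list[PrositePattern] = []
    current_id = ""
    counter = 0
    for line in stream:
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("//"):
            continue
        if line.startswith("ID"):
            current_id = line[2:].strip().rstrip(";").split(";")[0].strip()
            continue
        if line.startswith("PA"):
            line = line[2:].strip()
        counter += 1
        pid = current_id or f"pattern_{counter}"
        patterns.append(parse_pattern_string(line, pid))
        current_id = ""
    return patterns


def write_prosite_patterns(patterns: Iterable[PrositePattern], stream: TextIO) -> None:
    for p in patterns:
        stream.write(f"ID {p.pattern_id}\n")
        stream.write(f"PA {p.render()}\n")


# ---------------------------------------------------------------------------
# PDB ATOM/HETATM records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_number: int
    residue_name: str
    atom_name: str
    x: float
    y: float
    z: float


def parse_pdb_atoms(stream: TextIO) -> list[AtomRecord]:
    """Extract ATOM/HETATM records from PDB fixed-column text.

    Record types other than ATOM/HETATM are ignored; a truncated ATOM
    line raises :class:`ParseError` with its line number.
    """
    atoms: list[AtomRecord] = []
    for i, line in enumerate(stream):
        if not (line.startswith("ATOM") or line.startswith("HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise ParseError(f"line {i + 1}: truncated ATOM record")
        try:
            atoms.append(
                AtomRecord(
                    chain=line[21].strip(),
                    residue_number=int(line[22:26]),
                    residue_name=line[17:20].strip(),
                    atom_name=line[12:16].strip(),
                    x=float(line[30:38]),
                    y=float(line[38:46]),
                    z=float(line[46:54]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"line {i + 1}: malformed ATOM record: {exc}") from exc
    return atoms


def write_pdb_atoms(atoms: Iterable[AtomRecord], stream: TextIO) -> None:
    for serial, a in enumerate(atoms, start=1):
        name = a.atom_name if len(a.atom_name) >= 4 else f" {a.atom_name:<3}"
        stream.write(
            f"ATOM  {serial:>5} {name:<4}{a.residue_name:>4} {a.chain}"
            f"{a.residue_number:>4}    {a.x:8.3f}{a.y:8.3f}{a.z:8.3f}  1.00  0.00\n"
        )
    stream.write("END\n")
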