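"""RepeatMasker `.out` parsing, FASTA I/O, element extraction, and
genome-level family summary statistics.

Coordinates are 1-based inclusive everywhere, matching the `.out` dialect;
the parse/format boundary is the only place the dialect's quirks (bracketed
"left" fields, reversed consensus columns on C-strand hits) are handled.
A *copy* is an insertion event, which the annotation table may represent as
several fragments joined by a shared link id (the `.out` ID column) — e.g.
when a younger element inserted into it. Summary statistics count copies,
not fragments.
"""
from __future__ import annotations

import io
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import revcomp

__all__ = [
    "RepeatAnnotation",
    "ConsensusLibrary",
    "FamilySummaryRow",
    "RepeatMaskerParseError",
    "parse_repeatmasker_out",
    "format_repeatmasker_out",
    "read_fasta",
    "write_fasta",
    "extract_element_copies",
    "summarize_families",
    "summary_to_frame",
]


@dataclass
class RepeatAnnotation:
    """One annotated repeat hit (one `.out` data line), consensus
    coordinates normalized so c_start <= c_end regardless of strand."""

    query_id: str
    q_start: int
    q_end: int
    strand: str  # '+' or 'C'
    family: str
    c_start: int
    c_end: int
    c_left: int
    divergence_pct: float = 0.0
    del_pct: float = 0.0
    ins_pct: float = 0.0
    sw_score: int = 0
    repeat_class: str = "SINE"
    link_id: int | None = None

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"q_start {self.q_start} > q_end {self.q_end} ({self.query_id})"
            )
        if not (1 <= self.c_start <= self.c_end):
            raise ValueError(
                f"bad consensus interval {self.c_start}..{self.c_end} ({self.family})"
            )
        if self.strand == "-":
            self.strand = "C"
        if self.strand not in ("+", "C"):
            raise ValueError(f"strand must be '+' or 'C', got {self.strand!r}")

    @property
    def genomic_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class ConsensusLibrary:
    """Family name -> consensus sequence, with optional per-family
    annotation: CORE-region interval, poly(A)-tail start, diagnostic indels."""

    entries: dict[str, str] = field(default_factory=dict)
    core_regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    polya_starts: dict[str, int] = field(default_factory=dict)
    diagnostics: dict[str, list] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for fam, seq in self.entries.items():
            if not seq:
                raise ValueError(f"empty consensus for {fam}")
        for fam, (lo, hi) in self.core_regions.items():
            L = len(self.entries[fam])
            if not (1 <= lo <= hi <= L):
                raise ValueError(f"CORE interval {lo}..{hi} outside consensus ({fam})")

    def __getitem__(self, family: str) -> str:
        return self.entries[family]

    def __contains__(self, family: str) -> bool:
        return family in self.entries


class RepeatMaskerParseError(ValueError):
    """Raised with the offending line number(s) on malformed `.out` input."""


_HEADER_RE = re.compile(r"^\s*(SW|score|perc|query|There were no repeats)", re.IGNORECASE)
_PAREN_RE = re.compile(r"^\((\d+)\)$")


def _unparen(tok: str) -> int | None:
    m = _PAREN_RE.match(tok)
    return int(m.group(1)) if m else None


def parse_repeatmasker_out(stream: TextIO | str) -> list[RepeatAnnotation]:
    """Parse the whitespace-delimited `.out` dialect.

    Header lines (and an empty file) are tolerated; the trailing ID and '*'
    columns are optional. C-strand consensus columns arrive as
    ``(left) end begin`` and are normalized to c_start <= c_end.
    Malformed data lines raise :class:`RepeatMaskerParseError` naming them.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    annotations: list[RepeatAnnotation] = []
    errors: list[str] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or _HEADER_RE.match(line):
            continue
        toks = line.split()
        if len(toks) < 14:
            errors.append(f"line {lineno}: expected >= 14 fields, got {len(toks)}")
            continue
        try:
            sw = int(toks[0])
            div, dele, ins = float(toks[1]), float(toks[2]), float(toks[3])
            query = toks[4]
            q_start, q_end = int(toks[5]), int(toks[6])
            strand = toks[8]
            family = toks[9]
            rclass = toks[10]
            if strand in ("+",):
                c_start, c_end = int(toks[11]), int(toks[12])
                c_left = _unparen(toks[13])
                if c_left is None:
                    raise ValueError(f"expected (left) field, got {toks[13]!r}")
            elif strand in ("C", "-"):
                c_left = _unparen(toks[11])
                if c_left is None:
                    raise ValueError(f"expected (left) field, got {toks[11]!r}")
                c_end, c_start = int(toks[12]), int(toks[13])
            else:
                raise ValueError(f"bad strand {strand!r}")
            link_id = None
            for tok in toks[14:16]:
                if tok == "*":
                    continue
                if tok.isdigit():
                    link_id = int(tok)
            annotations.append(
                RepeatAnnotation(
                    query_id=query,
                    q_start=q_start,
                    q_end=q_end,
                    strand=strand,
                    family=family,
                    c_start=c_start,
                    c_end=c_end,
                    c_left=c_left,
                    divergence_pct=div,
                    del_pct=dele,
                    ins_pct=ins,
                    sw_score=sw,
                    repeat_class=rclass,
                    link_id=link_id,
                )
            )
        except ValueError as exc:
            errors.append(f"line {lineno}: {exc}")
    if errors:
        raise RepeatMaskerParseError("; ".join(errors))
    return annotations


def format_repeatmasker_out(
    annotations: Iterable[RepeatAnnotation],
    header: bool = False,
    link_ids: bool = True,
) -> str:
    """Render annotations back into the `.out` dialect (round-trip safe on
    the retained fields)."""
    lines = []
    if header:
        lines += [
            "   SW  perc perc perc  query     position in query    matching repeat",
            "score  div. del. ins.  sequence  begin  end   (left)  repeat  class/family",
            "",
        ]
    for a in annotations:
        if a.strand == "+":
            cons = f"{a.c_start} {a.c_end} ({a.c_left})"
        else:
            cons = f"({a.c_left}) {a.c_end} {a.c_start}"
        tail = f" {a.link_id}" if (link_ids and a.link_id is not None) else ""
        lines.append(
            f"{a.sw_score} {a.divergence_pct:.1f} {a.del_pct:.1f} {a.ins_pct:.1f} "
            f"{a.query_id} {a.q_start} {a.q_end} (0) {a.strand} {a.family} "
            f"{a.repeat_class} {cons}{tail}"
        )
    return "\n".join(lines) + "\n"


def read_fasta(stream) -> list[tuple[str, str]]:
    """Read FASTA records as (id, sequence); uppercased, U mapped to T.
    Duplicate ids are an error."""
    if isinstance(stream, str) and "\n" not in stream and ">" not in stream:
        handle = open(stream)
        close = True
    elif isinstance(stream, str):
        handle = io.StringIO(stream)
        close = False
    else:
        handle = stream
        close = False
    try:
        records = [
            (rec.id, str(rec.seq).upper().replace("U", "T"))
            for rec in SeqIO.parse(handle, "fasta")
        ]
    finally:
        if close:
            handle.close()
    seen: dict[str, int] = {}
    for rid, _ in records:
        seen[rid] = seen.get(rid, 0) + 1
    dups = sorted(r for r, k in seen.items() if k > 1)
    if dups:
        raise ValueError(f"duplicate FASTA ids: {dups}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], stream) -> None:
    """Write (id, sequence) records; accepts a path or a text handle."""
    recs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records]
    if isinstance(stream, str):
        with open(stream, "w") as fh:
            SeqIO.write(recs, fh, "fasta")
    else:
        SeqIO.write(recs, stream, "fasta")


def _chain_key(ann: RepeatAnnotation, idx: int):
    if ann.link_id is not None:
        return (ann.query_id, "link", ann.link_id)
    return (ann.query_id, "hit", idx)


def extract_element_copies(
    genome: Mapping[str, str],
    annotations: Sequence[RepeatAnnotation],
) -> list[tuple[str, str]]:
    """Cut element copies out of the genome, one per fragment chain.

    Fragments sharing a link id are concatenated in consensus order;
    C-strand fragments are reverse-complemented so every emitted copy reads
    in consensus orientation. Returns (copy_id, sequence) sorted by genomic
    position.
    """
    groups: dict = {}
    order: dict = {}
    for idx, ann in enumerate(annotations):
        if ann.query_id not in genome:
            raise KeyError(f"query {ann.query_id!r} missing from genome")
        if ann.q_end > len(genome[ann.query_id]) or ann.q_start < 1:
            raise ValueError(
                f"annotation out of bounds: {ann.query_id}:{ann.q_start}-{ann.q_end}"
            )
        key = _chain_key(ann, idx)
        groups.setdefault(key, []).append(ann)
        order.setdefault(key, (ann.query_id, ann.q_start))
    copies = []
    for key, frags in groups.items():
        frags = sorted(frags, key=lambda a: a.c_start)
        parts = []
        for a in frags:
            piece = genome[a.query_id][a.q_start - 1 : a.q_end]
            parts.append(revcomp(piece) if a.strand == "C" else piece)
        span_lo = min(a.q_start for a in frags)
        span_hi = max(a.q_end for a in frags)
        fam = frags[0].family
        copy_id = f"{fam}|{frags[0].query_id}:{span_lo}-{span_hi}"
        copies.append((order[key], copy_id, "".join(parts)))
    copies.sort(key=lambda t: t[0])
    return [(cid, seq) for _, cid, seq in copies]


@dataclass
class FamilySummaryRow:
    """One family's genome-wide abundance (copy-event counting)."""

    family: str
    copy_number: int
    total_nt: int
    pct_genome: float
    density: float  # copies per Mbp, unrounded
    density_rounded: int

    def __post_init__(self) -> None:
        if self.copy_number < 0 or self.total_nt < self.copy_number:
            raise ValueError("inconsistent copy_number / total_nt")


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def summarize_families(
    annotations: Sequence[RepeatAnnotation],
    assembly_size_bp: float,
) -> list[FamilySummaryRow]:
    """Per-family copy counts, summed genomic span, % of assembly, and
    density in copies/Mbp (rounded half away from zero alongside the
    unrounded value). Fragment chains count once.
    """
    if assembly_size_bp <= 0:
        raise ValueError("assembly_size_bp must be > 0")
    from .tint_activity import link_fragments  # chaining heuristic lives there

    chains = link_fragments(annotations)
    copy_counts: dict[str, int] = {}
    total_nt: dict[str, int] = {}
    for chain in chains:
        fam = chain.family
        copy_counts[fam] = copy_counts.get(fam, 0) + 1
        total_nt[fam] = total_nt.get(fam, 0) + sum(a.genomic_span for a in chain.fragments)
    rows = []
    for fam in copy_counts:
        dens = copy_counts[fam] / (assembly_size_bp / 1e6)
        rows.append(
            FamilySummaryRow(
                family=fam,
                copy_number=copy_counts[fam],
                total_nt=total_nt[fam],
                pct_genome=100.0 * total_nt[fam] / assembly_size_bp,
                density=dens,
                density_rounded=_round_half_away(dens),
            )
        )
    rows.sort(key=lambda r: (-r.copy_number, r.family))
    return rows


def summary_to_frame(rows: Sequence[FamilySummaryRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "family": r.family,
                "copy_number": r.copy_number,
                "total_nt": r.total_nt,
                "pct_genome": r.pct_genome,
                "density": r.density,
                "density_rounded": r.density_rounded,
            }
            for r in rows
        ]
    )
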