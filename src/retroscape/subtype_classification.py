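"""Classification of full-length WSINE1 copies into the WSINE1 / WSINE1a /
WSINE1b subtypes by their signature insertions, and per-taxon tallies.

The scheme: WSINE1a and WSINE1b both carry a 7-nt insertion near consensus
position 80; WSINE1a additionally carries an 11-nt insertion near position
120 (just upstream of the poly(A) tail); plain WSINE1 carries neither.
The fourth truth-table cell (120-insert without the 80-insert) matches no
described subtype and is surfaced as ``unclassified`` rather than
force-fit. Position/length tolerances absorb alignment jitter around
homopolymers, which can shift a recorded insertion by several nt.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import yaml

from .indel_profiling import DiagnosticIndel, PairwiseAlignment

__all__ = [
    "SubtypeScheme",
    "SubtypeCall",
    "SubtypeTally",
    "filter_full_length",
    "classify_copy",
    "tally_subtypes",
    "tally_from_counts",
]

UNCLASSIFIED = "unclassified"


@dataclass
class SubtypeScheme:
    """Signature-indel scheme mapping (has_80, has_120) to a subtype label."""

    family: str = "WSINE1"
    min_full_length: int = 130
    insert_80: DiagnosticIndel = field(
        default_factory=lambda: DiagnosticIndel("WSINE1", "insertion", 80, 7)
    )
    insert_120: DiagnosticIndel = field(
        default_factory=lambda: DiagnosticIndel("WSINE1", "insertion", 120, 11)
    )
    label_map: dict[tuple[bool, bool], str] = field(
        default_factory=lambda: {
            (False, False): "WSINE1",
            (True, True): "WSINE1a",
            (True, False): "WSINE1b",
            (False, True): UNCLASSIFIED,
        }
    )

    def __post_init__(self) -> None:
        gap = abs(self.insert_120.consensus_position - self.insert_80.consensus_position)
        if gap <= self.insert_80.position_tolerance + self.insert_120.position_tolerance:
            raise ValueError(
                "diagnostic positions closer than their combined tolerances: "
                f"{gap} nt apart"
            )

    @property
    def named_labels(self) -> list[str]:
        return sorted(set(self.label_map.values()) - {UNCLASSIFIED})

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "family": self.family,
                "min_full_length": self.min_full_length,
                "insert_80": {
                    "position": self.insert_80.consensus_position,
                    "length": self.insert_80.length,
                    "position_tolerance": self.insert_80.position_tolerance,
                    "length_tolerance": self.insert_80.length_tolerance,
                },
                "insert_120": {
                    "position": self.insert_120.consensus_position,
                    "length": self.insert_120.length,
                    "position_tolerance": self.insert_120.position_tolerance,
                    "length_tolerance": self.insert_120.length_tolerance,
                },
            },
            sort_keys=False,
        )

    @classmethod
    def from_yaml(cls, text: str) -> "SubtypeScheme":
        data = yaml.safe_load(text)
        fam = data.get("family", "WSINE1")

        def diag(key, pos, length):
            d = data.get(key, {})
            return DiagnosticIndel(
                fam,
                "insertion",
                d.get("position", pos),
                d.get("length", length),
                d.get("position_tolerance", 5),
                d.get("length_tolerance", 2),
            )

        return cls(
            family=fam,
            min_full_length=data.get("min_full_length", 130),
            insert_80=diag("insert_80", 80, 7),
            insert_120=diag("insert_120", 120, 11),
        )


@dataclass
class SubtypeCall:
    copy_id: str
    label: str
    evidence: list  # matched IndelOps


def filter_full_length(
    copies: Sequence[tuple[str, str]], min_full_length: int = 130
) -> list[tuple[str, str]]:
    """Keep copies whose ungapped length exceeds min_full_length
    (strictly: a 131-nt copy passes the default 130-nt threshold,
    a 130-nt copy does not)."""
    if min_full_length < 0:
        raise ValueError("min_full_length must be >= 0")
    return [(cid, seq) for cid, seq in copies if len(seq.replace("-", "")) > min_full_length]


def classify_copy(alignment: PairwiseAlignment, scheme: SubtypeScheme) -> SubtypeCall:
    """Label one aligned copy by the presence of the two signature inserts."""
    if alignment.family and alignment.family != scheme.family:
        raise ValueError(
            f"alignment family {alignment.family!r} != scheme family {scheme.family!r}"
        )
    ev80 = [op for op in alignment.ops if scheme.insert_80.matches(op)]
    ev120 = [op for op in alignment.ops if scheme.insert_120.matches(op)]
    label = scheme.label_map[(bool(ev80), bool(ev120))]
    return SubtypeCall(alignment.copy_id, label, ev80 + ev120)


@dataclass
class SubtypeTally:
    """Per-taxon subtype counts and percentages (percentages over the named
    subtypes only; unclassified copies are reported but excluded)."""

    taxon: str
    counts: dict[str, int]
    percentages: dict[str, float]
    n_unclassified: int = 0


def tally_from_counts(
    counts: Mapping[str, int], taxon: str, n_unclassified: int = 0
) -> SubtypeTally:
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no copies with a named subtype label")
    pct = {label: 100.0 * c / total for label, c in counts.items()}
    return SubtypeTally(taxon, dict(counts), pct, n_unclassified)


def tally_subtypes(calls: Iterable[SubtypeCall], taxon: str) -> SubtypeTally:
    """Table of subtype counts/percentages for one taxon's copies."""
    counter = Counter(call.label for call in calls)
    n_uncl = counter.pop(UNCLASSIFIED, 0)
    if not counter:
        raise ValueError("all copies unclassified; nothing to tally")
    return tally_from_counts(dict(counter), taxon, n_uncl)
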