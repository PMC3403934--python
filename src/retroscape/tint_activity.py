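"""Transposition-in-transposition (TinT): nested-insertion detection and
relative activity ordering of repeat families.

A retroposon can only receive an insertion while the host copy already
exists and the inserting family is still active, so old, inactive families
cannot appear *inside* copies of younger families. Counting who-inserted-
into-whom across a genome therefore constrains the relative order of
family activity. The estimator here is deliberately simple and fully
specified: for family i, with I_i events where i is the inner (inserted)
element and O_i events where i is the outer (host), the activity score

    s_i = I_i / (I_i + O_i)

is 1 for a family younger than everything it touched and 0 for a family
that only ever hosted. Families are ranked by s_i (most recent first);
per-pair direction counts get a two-sided binomial test against the
symmetric null so unresolved pairs are flagged. Activity *durations* and
the likelihood machinery of the full TinT model are out of scope.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binomtest

from .repeat_io import RepeatAnnotation

__all__ = [
    "FragmentChain",
    "NestedInsertionEvent",
    "PrecedenceMatrix",
    "ActivityOrder",
    "link_fragments",
    "detect_nested",
    "build_precedence_matrix",
    "estimate_activity_order",
]


@dataclass
class FragmentChain:
    """Fragments of one insertion event, in genomic order."""

    fragments: list[RepeatAnnotation]

    @property
    def family(self) -> str:
        return self.fragments[0].family

    @property
    def query_id(self) -> str:
        return self.fragments[0].query_id

    @property
    def strand(self) -> str:
        return self.fragments[0].strand

    @property
    def span(self) -> tuple[int, int]:
        return (
            min(a.q_start for a in self.fragments),
            max(a.q_end for a in self.fragments),
        )


def link_fragments(
    annotations: Sequence[RepeatAnnotation],
    max_consensus_gap: int = 20,
    min_consensus_overlap: int = -10,
    max_genomic_gap: int = 20_000,
) -> list[FragmentChain]:
    """Group annotation hits into insertion-event chains.

    Hits sharing a link id are chained directly. Otherwise, same-family,
    same-strand hits on one query are chained when the consensus
    coordinates continue across the genomic gap: the consensus gap must lie
    in [min_consensus_overlap, max_consensus_gap] and the genomic gap must
    not exceed max_genomic_gap. On C-strand chains the consensus runs
    backwards along the genome.
    """
    by_query: dict[str, list[RepeatAnnotation]] = {}
    for ann in annotations:
        by_query.setdefault(ann.query_id, []).append(ann)

    chains: list[FragmentChain] = []
    for query in sorted(by_query):
        hits = sorted(by_query[query], key=lambda a: (a.q_start, a.q_end))
        linked: dict[int, list[RepeatAnnotation]] = {}
        loose: list[RepeatAnnotation] = []
        for ann in hits:
            if ann.link_id is not None:
                linked.setdefault(ann.link_id, []).append(ann)
            else:
                loose.append(ann)
        for lid in sorted(linked):
            chains.append(FragmentChain(linked[lid]))
        # heuristic chaining for hits without link ids
        open_chains: list[list[RepeatAnnotation]] = []
        for ann in loose:
            best = None
            best_gap = None
            for chain in open_chains:
                last = chain[-1]
                if last.family != ann.family or last.strand != ann.strand:
                    continue
                g_gap = ann.q_start - last.q_end - 1
                if g_gap < 0 or g_gap > max_genomic_gap:
                    continue
                if ann.strand == "+":
                    c_gap = ann.c_start - last.c_end - 1
                else:  # consensus runs backwards along the genome
                    c_gap = last.c_start - ann.c_end - 1
                if min_consensus_overlap <= c_gap <= max_consensus_gap:
                    if best is None or g_gap < best_gap:
                        best, best_gap = chain, g_gap
            if best is not None:
                best.append(ann)
            else:
                open_chains.append([ann])
        chains.extend(FragmentChain(c) for c in open_chains)
    chains.sort(key=lambda c: (c.query_id, c.span))
    return chains


@dataclass
class NestedInsertionEvent:
    query_id: str
    outer_family: str
    inner_family: str
    outer_chain: FragmentChain
    inner_chain: FragmentChain
    gap: tuple[int, int]  # genomic interval between the outer fragments

    @property
    def genomic_span(self) -> tuple[int, int]:
        return self.outer_chain.span


def detect_nested(chains: Sequence[FragmentChain]) -> list[NestedInsertionEvent]:
    """One event per (outer-chain gap, maximal inner chain fully inside it).

    Inner chains partially overlapping the outer fragments are discarded;
    a chain contained in another contained chain's span is not maximal and
    is credited to that chain's own gap instead (so a doubly nested
    A/B/C/B/A stack yields C-into-B and B-into-A, not C-into-A).
    """
    by_query: dict[str, list[FragmentChain]] = {}
    for ch in chains:
        by_query.setdefault(ch.query_id, []).append(ch)
    events: list[NestedInsertionEvent] = []
    for query in sorted(by_query):
        qchains = by_query[query]
        for outer in qchains:
            if len(outer.fragments) < 2:
                continue
            frags = sorted(outer.fragments, key=lambda a: a.q_start)
            for left, right in zip(frags, frags[1:]):
                gap_lo, gap_hi = left.q_end + 1, right.q_start - 1
                if gap_lo > gap_hi:
                    continue
                contained = [
                    ch
                    for ch in qchains
                    if ch is not outer
                    and ch.span[0] >= gap_lo
                    and ch.span[1] <= gap_hi
                ]
                maximal = [
                    ch
                    for ch in contained
                    if not any(
                        other is not ch
                        and other.span[0] <= ch.span[0]
                        and ch.span[1] <= other.span[1]
                        for other in contained
                    )
                ]
                for inner in sorted(maximal, key=lambda c: c.span):
                    events.append(
                        NestedInsertionEvent(
                            query_id=query,
                            outer_family=outer.family,
                            inner_family=inner.family,
                            outer_chain=outer,
                            inner_chain=inner,
                            gap=(gap_lo, gap_hi),
                        )
                    )
    return events


@dataclass
class PrecedenceMatrix:
    """N[inner, outer]: counts of nested events by direction."""

    counts: pd.DataFrame  # index = inner family, columns = outer family

    @classmethod
    def from_pairs(
        cls, pairs: Iterable[tuple[str, str]], families: Sequence[str] | None = None
    ) -> "PrecedenceMatrix":
        pairs = list(pairs)
        fams = sorted(families or {f for pair in pairs for f in pair})
        df = pd.DataFrame(0, index=fams, columns=fams, dtype=int)
        for inner, outer in pairs:
            df.loc[inner, outer] += 1
        return cls(df)

    @property
    def families(self) -> list[str]:
        return list(self.counts.index)

    @property
    def total_events(self) -> int:
        return int(self.counts.values.sum())


def build_precedence_matrix(
    events: Sequence[NestedInsertionEvent], families: Sequence[str] | None = None
) -> PrecedenceMatrix:
    return PrecedenceMatrix.from_pairs(
        [(e.inner_family, e.outer_family) for e in events], families
    )


@dataclass
class ActivityOrder:
    """Families ranked most-recent-first by inner-fraction score."""

    ranking: list[tuple[str, float]]  # (family, score), score descending
    pair_tests: pd.DataFrame
    insufficient: list[str] = field(default_factory=list)

    @property
    def families(self) -> list[str]:
        return [f for f, _ in self.ranking]


def estimate_activity_order(
    matrix: PrecedenceMatrix, min_events: int = 10, alpha: float = 0.05
) -> ActivityOrder:
    """Rank families by s_i = I_i / (I_i + O_i), excluding self-nesting,
    with per-pair two-sided binomial tests against the symmetric null."""
    N = matrix.counts
    diag = pd.Series(np.diag(N.values), index=N.index)
    inner = N.sum(axis=1) - diag
    outer = N.sum(axis=0) - diag
    tot = inner + outer
    eligible = [f for f in N.index if tot[f] >= max(min_events, 1)]
    insufficient = [f for f in N.index if f not in eligible]
    if len(eligible) < 2:
        raise ValueError(
            f"need >= 2 families with at least {min_events} events; "
            f"got {len(eligible)}"
        )
    scores = {f: float(inner[f] / tot[f]) for f in eligible}
    ranking = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    rows = []
    for i, fi in enumerate(eligible):
        for fj in eligible[i + 1 :]:
            a = int(N.loc[fi, fj])
            b = int(N.loc[fj, fi])
            if a + b == 0:
                pval = 1.0
            else:
                pval = binomtest(a, a + b, 0.5).pvalue
            rows.append(
                {
                    "family_a": fi,
                    "family_b": fj,
                    "a_into_b": a,
                    "b_into_a": b,
                    "p_value": pval,
                    "resolved": pval < alpha,
                }
            )
    return ActivityOrder(
        ranking=ranking,
        pair_tests=pd.DataFrame(rows),
        insufficient=insufficient,
    )
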