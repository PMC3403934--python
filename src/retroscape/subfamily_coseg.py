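"""Subfamily discovery by co-segregating diagnostic mutations.

Copies descending from a distinct master share that master's private
substitutions, so positions whose derived states co-occur far more often
than independence predicts mark a subfamily. The greedy recursion here:

1. project every copy onto consensus coordinates (insertions dropped,
   deletions as '-');
2. within a subfamily's members, find the candidate — a position pair or a
   single position with its derived state(s) — whose carrier set has at
   least ``min_count`` copies and the smallest probability under
   independence (one-sided binomial on the joint count given the marginal
   frequencies; single positions are tested against the background
   per-state mismatch frequency), Bonferroni-corrected;
3. split the carriers off as a child subfamily with a majority-rule
   consensus, then re-scan both parent and child until no candidate
   passes or ``max_subfamilies`` is reached.

CpG dinucleotide columns of the consensus are masked by default: CpG
transitions are hypermutable and mimic diagnostic sites. After the
recursion, every copy is assigned to the nearest subfamily consensus
(ties toward the deeper subfamily), which recovers copies whose diagnostic
site back-mutated after insertion; the split-defining carrier rule alone
would strand those in the parent.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import _seq
from . import chronology
from .chronology import DistanceModelParams
from .indel_profiling import PairwiseAlignment

__all__ = [
    "AlignedCopyMatrix",
    "Subfamily",
    "SubfamilyNetwork",
    "SplitCandidate",
    "build_aligned_matrix",
    "matrix_from_sequences",
    "find_cosegregating_split",
    "segregate",
    "filter_foreign_elements",
]


@dataclass
class AlignedCopyMatrix:
    """Copies projected onto consensus coordinates.

    rows[i, p] is the int8 code of copy i at consensus position p+1
    ('-' where the copy is deleted; insertions relative to the consensus
    are dropped).
    """

    consensus: str
    copy_ids: list[str]
    rows: np.ndarray  # (n_copies, len(consensus)) int8

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int8)
        if self.rows.ndim != 2 or self.rows.shape[1] != len(self.consensus):
            raise ValueError("rows must be (n_copies, consensus_length)")
        if len(self.copy_ids) != self.rows.shape[0]:
            raise ValueError("copy_ids and rows disagree in length")

    @property
    def n_copies(self) -> int:
        return self.rows.shape[0]

    @property
    def consensus_codes(self) -> np.ndarray:
        return _seq.encode(self.consensus)


def build_aligned_matrix(alignments: Sequence[PairwiseAlignment]) -> AlignedCopyMatrix:
    """Project pairwise alignments (all against one consensus) onto the
    consensus coordinate system."""
    if not alignments:
        raise ValueError("no alignments")
    consensuses = {al.consensus for al in alignments}
    if len(consensuses) > 1:
        raise ValueError("alignments use different consensuses")
    consensus = consensuses.pop()
    L = len(consensus)
    rows = np.full((len(alignments), L), _seq.GAP, dtype=np.int8)
    ids = []
    for i, al in enumerate(alignments):
        ids.append(al.copy_id)
        p = 0
        for ac, bc in zip(al.aligned_copy, al.aligned_consensus):
            if bc == "-":
                continue  # insertion relative to consensus: dropped
            rows[i, p] = _seq._CODE["-" if ac == "-" else ac]
            p += 1
        if p != L:
            raise ValueError(f"alignment {al.copy_id!r} does not cover the consensus")
    return AlignedCopyMatrix(consensus, ids, rows)


def matrix_from_sequences(
    consensus: str, records: Sequence[tuple[str, str]]
) -> AlignedCopyMatrix:
    """Matrix from already-projected equal-length sequences (convenience
    for substitution-only data)."""
    ids = [rid for rid, _ in records]
    rows = np.vstack([_seq.encode(seq) for _, seq in records]) if records else np.zeros((0, len(consensus)), dtype=np.int8)
    return AlignedCopyMatrix(consensus, ids, rows)


@dataclass
class SplitCandidate:
    positions: tuple[int, ...]  # 1-based consensus positions
    states: tuple[str, ...]  # derived states, aligned with positions
    carrier_index: np.ndarray  # indices into the member list
    p_value: float  # Bonferroni-corrected


@dataclass
class Subfamily:
    id: str
    parent_id: str | None
    diagnostic_set: list[tuple[int, str]]  # split-defining (position, state)
    consensus: str
    member_ids: list[str] = field(default_factory=list)
    mean_distance: float = float("nan")
    sd_distance: float = float("nan")
    age_myr: float = float("nan")
    creation_order: int = 0

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


@dataclass
class SubfamilyNetwork:
    subfamilies: dict[str, Subfamily]
    root_id: str
    assignment: pd.Series  # copy_id -> subfamily id

    @property
    def edges(self) -> list[tuple[str, str]]:
        return [
            (sf.parent_id, sf.id)
            for sf in sorted(self.subfamilies.values(), key=lambda s: s.creation_order)
            if sf.parent_id is not None
        ]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sf in sorted(self.subfamilies.values(), key=lambda s: s.creation_order):
            rows.append(
                {
                    "id": sf.id,
                    "parent": sf.parent_id if sf.parent_id is not None else "",
                    "n_members": sf.n_members,
                    "diagnostics": ";".join(f"{p}{s}" for p, s in sf.diagnostic_set),
                    "mean_distance": sf.mean_distance,
                    "sd_distance": sf.sd_distance,
                    "age_myr": sf.age_myr,
                }
            )
        return pd.DataFrame(rows)


def _derived_state_counts(sub_rows: np.ndarray, cons_codes: np.ndarray):
    """counts[s, p] = members carrying base s at position p, s in 0..3."""
    counts = np.zeros((4, sub_rows.shape[1]), dtype=np.int64)
    for s in range(4):
        counts[s] = (sub_rows == s).sum(axis=0)
    return counts


def find_cosegregating_split(
    matrix: AlignedCopyMatrix,
    member_index: np.ndarray,
    subfamily_consensus: str,
    min_count: int = 500,
    alpha: float = 0.01,
    masked_columns: frozenset[int] = frozenset(),
) -> SplitCandidate | None:
    """Best co-segregation candidate among a subfamily's members, or None.

    Candidates are single derived states and pairs of derived states with
    carrier sets of size >= min_count that also leave >= min_count members
    behind. Pairs are scored by a one-sided binomial test of the joint
    count under independence of the marginals; singles against the
    background per-state mismatch frequency. The best Bonferroni-corrected
    p-value must fall below alpha. Ties break toward the larger carrier
    set, then the lexicographically smallest position tuple.
    """
    member_index = np.asarray(member_index)
    n = len(member_index)
    if n < 2 * min_count:
        return None
    cons_codes = _seq.encode(subfamily_consensus)
    sub = matrix.rows[member_index]
    usable = np.ones(sub.shape[1], dtype=bool)
    for col in masked_columns:
        if 1 <= col <= sub.shape[1]:
            usable[col - 1] = False
    counts = _derived_state_counts(sub, cons_codes)
    # background per-specific-state mismatch frequency
    base_mask = sub < 4
    mismatch = base_mask & (sub != cons_codes[None, :]) & usable[None, :]
    denom = (base_mask & usable[None, :]).sum()
    p0 = (mismatch.sum() / denom / 3.0) if denom else 0.0

    singles = []
    for s in range(4):
        derived = (counts[s] >= min_count) & (counts[s] <= n - min_count)
        derived &= usable & (cons_codes != s)
        for p in np.nonzero(derived)[0]:
            singles.append((int(p) + 1, s, int(counts[s, p])))
    if not singles:
        return None

    single_tests = []  # (raw_p, -carriers, positions, states, carrier_mask)
    pair_tests = []
    for pos, s, cnt in singles:
        raw = float(binom.sf(cnt - 1, n, p0)) if p0 > 0 else 0.0
        mask = sub[:, pos - 1] == s
        single_tests.append((raw, -cnt, (pos,), (s,), mask))
    for i in range(len(singles)):
        for j in range(i + 1, len(singles)):
            pi, si, ci = singles[i]
            pj, sj, cj = singles[j]
            if pi == pj:
                continue
            mi = sub[:, pi - 1] == si
            mj = sub[:, pj - 1] == sj
            joint = int((mi & mj).sum())
            if joint < min_count or joint > n - min_count:
                continue
            raw = float(binom.sf(joint - 1, n, (ci / n) * (cj / n)))
            pair_tests.append((raw, -joint, (pi, pj), (si, sj), mi & mj))
    n_tests = len(single_tests) + len(pair_tests)
    # co-segregating pairs are the primary signal; a lone diagnostic
    # position is accepted only when no pair passes
    for pool in (pair_tests, single_tests):
        if not pool:
            continue
        best = min(pool, key=lambda t: (t[0], t[1], t[2]))
        corrected = min(1.0, best[0] * n_tests)
        if corrected < alpha:
            return SplitCandidate(
                positions=best[2],
                states=tuple(_seq._CHAR[s] for s in best[3]),
                carrier_index=member_index[np.nonzero(best[4])[0]],
                p_value=corrected,
            )
    return None


def _majority_consensus(rows: np.ndarray, fallback: str) -> str:
    """Per-position majority base among carriers; ties and gap-majority
    columns fall back to the parent consensus."""
    fb = _seq.encode(fallback)
    out = fb.copy()
    for p in range(rows.shape[1]):
        col = rows[:, p]
        col = col[col < 4]
        if len(col) == 0:
            continue
        freq = np.bincount(col, minlength=4)
        top = int(freq.argmax())
        if (freq == freq[top]).sum() == 1:
            out[p] = top
    return _seq.decode(out)


def segregate(
    matrix: AlignedCopyMatrix,
    min_count: int = 500,
    alpha: float = 0.01,
    max_subfamilies: int = 100,
    cpg_mask: bool = True,
    distance_params: DistanceModelParams | None = None,
    rate: float | None = None,
) -> SubfamilyNetwork:
    """Greedy recursive co-segregation partitioning of a family's copies.

    Returns a tree of subfamilies rooted at the family consensus, each
    with its majority consensus, split diagnostics, members (final
    nearest-consensus assignment), and mean member-to-consensus distance;
    ages are filled when a substitution rate is supplied.
    """
    if matrix.n_copies == 0:
        raise ValueError("empty copy matrix")
    masked = (
        frozenset(chronology.cpg_columns(matrix.consensus)) if cpg_mask else frozenset()
    )
    root = Subfamily(
        id="SF00",
        parent_id=None,
        diagnostic_set=[],
        consensus=matrix.consensus,
        creation_order=0,
    )
    members: dict[str, np.ndarray] = {root.id: np.arange(matrix.n_copies)}
    subfamilies = {root.id: root}
    queue = [root.id]
    order = 1
    while queue and len(subfamilies) < max_subfamilies:
        sf_id = queue.pop(0)
        sf = subfamilies[sf_id]
        cand = find_cosegregating_split(
            matrix, members[sf_id], sf.consensus, min_count, alpha, masked
        )
        if cand is None:
            continue
        child_id = f"SF{order:02d}"
        carrier_rows = matrix.rows[cand.carrier_index]
        child = Subfamily(
            id=child_id,
            parent_id=sf_id,
            diagnostic_set=list(zip(cand.positions, cand.states)),
            consensus=_majority_consensus(carrier_rows, sf.consensus),
            creation_order=order,
        )
        order += 1
        subfamilies[child_id] = child
        carrier_set = set(cand.carrier_index.tolist())
        members[sf_id] = np.array(
            [i for i in members[sf_id] if i not in carrier_set], dtype=int
        )
        members[child_id] = np.asarray(cand.carrier_index, dtype=int)
        queue.extend([sf_id, child_id])

    # final assignment: nearest subfamily consensus, ties toward the
    # deeper (later-created) subfamily
    sf_list = sorted(subfamilies.values(), key=lambda s: s.creation_order)
    cons_stack = np.vstack([_seq.encode(s.consensus) for s in sf_list])
    usable_cols = np.ones(matrix.rows.shape[1], dtype=bool)
    for col in masked:
        usable_cols[col - 1] = False
    dist = np.zeros((matrix.n_copies, len(sf_list)), dtype=np.int64)
    for k in range(len(sf_list)):
        comparable = (matrix.rows < 4) & (cons_stack[k][None, :] < 4) & usable_cols[None, :]
        dist[:, k] = ((matrix.rows != cons_stack[k][None, :]) & comparable).sum(axis=1)
    # argmax over reversed order implements "ties toward deeper"
    best = len(sf_list) - 1 - np.argmin(dist[:, ::-1], axis=1)
    assignment = pd.Series(
        [sf_list[k].id for k in best], index=matrix.copy_ids, name="subfamily"
    )
    for k, sf in enumerate(sf_list):
        idx = np.nonzero(best == k)[0]
        sf.member_ids = [matrix.copy_ids[i] for i in idx]
        if len(idx) == 0:
            continue
        params = distance_params or DistanceModelParams()
        try:
            mean, sd, _, _ = chronology.mean_distance_to_consensus(
                matrix.rows[idx], sf.consensus, params
            )
            sf.mean_distance = mean
            sf.sd_distance = sd
            if rate is not None and rate > 0:
                sf.age_myr = chronology.estimate_age(mean, rate, sf.id).age_myr
        except ValueError:
            pass
    return SubfamilyNetwork(subfamilies=subfamilies, root_id=root.id, assignment=assignment)


def filter_foreign_elements(
    matrix: AlignedCopyMatrix, max_distance: float = 0.35
) -> tuple[AlignedCopyMatrix, list[str]]:
    """Drop copies whose p-distance to the family consensus exceeds
    max_distance (screening out unrelated elements caught by the family
    screen); copies with too few comparable sites are dropped too.
    Returns (kept matrix, dropped ids)."""
    if not (0 < max_distance <= 1):
        raise ValueError("max_distance must be in (0, 1]")
    cons = matrix.consensus_codes
    params = DistanceModelParams(model="p", cpg_mask=False)
    keep = []
    dropped = []
    for i in range(matrix.n_copies):
        try:
            d = chronology.pairwise_distance(matrix.rows[i], cons, params)
        except ValueError:
            dropped.append(matrix.copy_ids[i])
            continue
        if d <= max_distance:
            keep.append(i)
        else:
            dropped.append(matrix.copy_ids[i])
    kept = AlignedCopyMatrix(
        matrix.consensus,
        [matrix.copy_ids[i] for i in keep],
        matrix.rows[keep] if keep else np.zeros((0, len(matrix.consensus)), dtype=np.int8),
    )
    return kept, dropped
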