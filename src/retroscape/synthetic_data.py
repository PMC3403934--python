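"""Synthetic retroposon landscapes with known ground truth.

The generator emulates how a SINE landscape accumulates in a genome:
master (source) copies spawn subfamily lineages over a timeline measured
in Myr ago; each lineage master carries the private diagnostic
substitutions of its ancestors plus its own, and — for the WSINE1-like
subtypes — the 7-nt insertion near consensus position 80 (subtypes a and
b) and the 11-nt insertion near position 120 (subtype a only). Copies are
drawn as a Poisson process over each lineage's activity window, evolved
for their age under an HKY substitution process (transition bias kappa,
gamma-distributed site-rate multipliers, a CpG-context multiplier on
transitions, applied event-by-event so CpG context tracks the current
sequence), optionally hit by small indels and 5'-truncation, wrapped in a
poly(A) tail and target-site duplications, and placed in a background
genome — or, with the nesting probability, inside an already-placed older
copy, splitting that copy's annotation into link-joined fragments.

Everything downstream (family summaries, indel profiling, subtype calls,
activity ordering, subfamily discovery, ages) can therefore be checked
against recorded truth. Deliberately not modelled: population-genetic
fixation, LINE partner sequences, horizontal transfer.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import _seq
from .repeat_io import ConsensusLibrary, RepeatAnnotation, format_repeatmasker_out, write_fasta

__all__ = [
    "MasterEvent",
    "SimConfig",
    "SimResult",
    "evolve_sequence",
    "apply_indels",
    "simulate_landscape",
    "simulate_activity_history",
    "simulate_subtype_cohort",
    "simulate_subfamily_cohort",
    "simulate_aged_cohort",
    "simulate_dated_insertion",
]


@dataclass
class MasterEvent:
    """One subfamily lineage: a master active from birth to death (Myr ago)."""

    subfamily_id: str
    parent_id: str | None
    family: str
    birth_myr: float
    death_myr: float
    n_diagnostics: int
    insertion_rate: float  # copies per Myr while active
    subtype: str | None = None  # None, "WSINE1", "WSINE1a", "WSINE1b"

    def __post_init__(self) -> None:
        if not (self.birth_myr > self.death_myr >= 0):
            raise ValueError(
                f"need birth > death >= 0 (Myr ago); got {self.birth_myr}, {self.death_myr}"
            )
        if self.insertion_rate < 0 or self.n_diagnostics < 0:
            raise ValueError("rates and diagnostic counts must be >= 0")


def _default_master_events() -> list[MasterEvent]:
    """A devil-like two-family scenario: a WSINE1 lineage tree whose b
    subtype dominates recent activity, plus an older unrelated family."""
    return [
        MasterEvent("WSINE1_root", None, "WSINE1", 75, 45, 0, 4.0, "WSINE1"),
        MasterEvent("WSINE1a_1", "WSINE1_root", "WSINE1", 60, 35, 3, 2.0, "WSINE1a"),
        MasterEvent("WSINE1b_1", "WSINE1_root", "WSINE1", 55, 25, 3, 4.0, "WSINE1b"),
        MasterEvent("WSINE1b_2", "WSINE1b_1", "WSINE1", 40, 15, 3, 5.0, "WSINE1b"),
        MasterEvent("WALLSI1a_root", None, "WALLSI1a", 70, 40, 0, 3.0, None),
    ]


@dataclass
class SimConfig:
    """Generator parameters. Times are Myr ago; rates per site per Myr."""

    seed: int = 0
    timeline_myr: float = 80.0
    consensus_length: int = 150
    master_events: list[MasterEvent] = field(default_factory=_default_master_events)
    substitution_rate: float = 0.0045
    kappa: float = 4.0
    gamma_alpha: float | None = 0.5
    cpg_multiplier: float = 10.0
    indel_rate: float = 2e-4
    indel_geom_p: float = 0.5
    insert_80_seq: str = "TCAGGCT"
    insert_120_seq: str = "AGGTCAAGGCT"
    polya_range: tuple[int, int] = (8, 30)
    tsd_range: tuple[int, int] = (5, 15)
    genome_length: int = 400_000
    gc: float = 0.42
    nesting_prob: float = 0.05
    truncation_prob: float = 0.10
    truncation_frac_range: tuple[float, float] = (0.1, 0.6)
    emit_link_ids: bool = True

    def __post_init__(self) -> None:
        for p in (self.nesting_prob, self.truncation_prob, self.gc):
            if not (0 <= p <= 1):
                raise ValueError("probabilities must lie in [0, 1]")
        for ev in self.master_events:
            if ev.birth_myr > self.timeline_myr:
                raise ValueError(f"{ev.subfamily_id}: birth beyond the timeline")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["master_events"] = [dataclasses.asdict(ev) for ev in self.master_events]
        return d


def _random_consensus(length: int, rng: np.random.Generator) -> str:
    return _seq.decode(rng.integers(0, 4, size=length))


def evolve_sequence(
    codes: np.ndarray,
    time_myr: float,
    rate: float,
    kappa: float,
    gamma_alpha: float | None,
    cpg_multiplier: float,
    rng: np.random.Generator,
    site_mult: np.ndarray | None = None,
) -> tuple[np.ndarray, int]:
    """Evolve a sequence for `time_myr` under HKY(kappa) with gamma site
    rates and a CpG transition multiplier, event by event (Gillespie), so
    CpG context follows the mutating sequence. Site-rate multipliers are
    drawn fresh unless `site_mult` is given — pass one shared array when
    evolving several lineages of the *same* locus, since rate variation is
    a property of the site. Returns (sequence, n_substitution_events)."""
    seq = np.asarray(codes, dtype=np.int8).copy()
    L = len(seq)
    if L == 0 or time_myr <= 0 or rate <= 0:
        return seq, 0
    b = rate / (kappa + 2.0)  # per-transversion-target rate
    a = kappa * b  # transition rate
    if site_mult is not None:
        mult = np.asarray(site_mult, dtype=float)
    elif gamma_alpha:
        mult = rng.gamma(gamma_alpha, 1.0 / gamma_alpha, size=L)
    else:
        mult = np.ones(L)
    n_events = 0
    t = 0.0
    while True:
        is_c_g = np.zeros(L, dtype=bool)
        cg = (seq[:-1] == _seq.C) & (seq[1:] == _seq.G)
        is_c_g[:-1] |= cg
        is_c_g[1:] |= cg
        a_site = np.where(is_c_g, a * cpg_multiplier, a)
        site_rate = mult * (a_site + 2.0 * b)
        total = float(site_rate.sum())
        if total <= 0:
            break
        t += rng.exponential(1.0 / total)
        if t > time_myr:
            break
        i = int(rng.choice(L, p=site_rate / total))
        p_transition = a_site[i] / (a_site[i] + 2.0 * b)
        c = int(seq[i])
        if rng.random() < p_transition:
            seq[i] = c ^ 2  # A<->G, C<->T
        else:
            tv = [x for x in range(4) if x != c and x != (c ^ 2)]
            seq[i] = tv[int(rng.integers(0, 2))]
        n_events += 1
    return seq, n_events


def apply_indels(
    codes: np.ndarray,
    time_myr: float,
    indel_rate: float,
    geom_p: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int, int]:
    """Poisson small indels: count ~ Poisson(rate * L * t), geometric
    lengths, insertions and deletions equally likely. Returns (sequence,
    inserted_nt, deleted_nt)."""
    seq = list(np.asarray(codes, dtype=np.int8))
    if indel_rate <= 0 or time_myr <= 0:
        return np.asarray(seq, dtype=np.int8), 0, 0
    n = rng.poisson(indel_rate * len(seq) * time_myr)
    ins_nt = del_nt = 0
    for _ in range(n):
        if not seq:
            break
        length = int(rng.geometric(geom_p))
        pos = int(rng.integers(0, len(seq)))
        if rng.random() < 0.5:
            seq[pos:pos] = list(rng.integers(0, 4, size=length).astype(np.int8))
            ins_nt += length
        else:
            removed = len(seq[pos : pos + length])
            del seq[pos : pos + length]
            del_nt += removed
    return np.asarray(seq, dtype=np.int8), ins_nt, del_nt


@dataclass
class _SubfamilyMaster:
    subfamily_id: str
    family: str
    core: str  # family-consensus coordinates, no subtype inserts
    master: str  # with subtype inserts applied
    diagnostics: list[tuple[int, str]]
    subtype: str | None


def _build_masters(config: SimConfig, rng: np.random.Generator):
    roots: dict[str, str] = {}
    masters: dict[str, _SubfamilyMaster] = {}
    used_positions: dict[str, set[int]] = {}
    for ev in config.master_events:
        if ev.family not in roots:
            roots[ev.family] = _random_consensus(config.consensus_length, rng)
            used_positions[ev.family] = set()
        if ev.parent_id is None:
            core = roots[ev.family]
            diagnostics: list[tuple[int, str]] = []
        else:
            parent = masters[ev.parent_id]
            if parent.family != ev.family:
                raise ValueError(f"{ev.subfamily_id}: parent from another family")
            core_codes = _seq.encode(parent.core)
            diagnostics = list(parent.diagnostics)
            free = [
                p
                for p in range(len(core_codes))
                if (p + 1) not in used_positions[ev.family]
            ]
            picks = rng.choice(len(free), size=ev.n_diagnostics, replace=False)
            for k in sorted(int(x) for x in picks):
                p = free[k]
                old = int(core_codes[p])
                new = int((old + 1 + rng.integers(0, 3)) % 4)
                core_codes[p] = new
                used_positions[ev.family].add(p + 1)
                diagnostics.append((p + 1, _seq._CHAR[new]))
            core = _seq.decode(core_codes)
        master = core
        if ev.subtype in ("WSINE1a",):
            master = master[:120] + config.insert_120_seq + master[120:]
        if ev.subtype in ("WSINE1a", "WSINE1b"):
            master = master[:80] + config.insert_80_seq + master[80:]
        masters[ev.subfamily_id] = _SubfamilyMaster(
            ev.subfamily_id, ev.family, core, master, diagnostics, ev.subtype
        )
    return roots, masters


@dataclass
class _Block:
    owner: int | None  # copy index, or None for background / TSD sequence
    seq: str  # genomic orientation
    e_start: int = 0  # element-local coordinates (1-based) when owned
    e_end: int = 0
    strand: str = "+"


def _split_block(block: _Block, offset: int) -> tuple[_Block, _Block]:
    """Split at genomic offset (left part keeps `offset` bases)."""
    left_seq, right_seq = block.seq[:offset], block.seq[offset:]
    if block.owner is None:
        return _Block(None, left_seq), _Block(None, right_seq)
    if block.strand == "+":
        left = _Block(block.owner, left_seq, block.e_start, block.e_start + offset - 1, "+")
        right = _Block(block.owner, right_seq, block.e_start + offset, block.e_end, "+")
    else:
        left = _Block(block.owner, left_seq, block.e_end - offset + 1, block.e_end, "C")
        right = _Block(block.owner, right_seq, block.e_start, block.e_end - offset, "C")
    return left, right


@dataclass
class SimResult:
    genome: dict[str, str]
    annotations: list[RepeatAnnotation]
    copies: list[tuple[str, str]]
    truth: pd.DataFrame
    library: ConsensusLibrary
    config: SimConfig
    subfamily_masters: dict[str, str] = field(default_factory=dict)

    def write_outputs(self, outdir) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        write_fasta(self.genome.items(), os.path.join(outdir, "genome.fa"))
        write_fasta(self.copies, os.path.join(outdir, "copies.fa"))
        write_fasta(
            self.library.entries.items(), os.path.join(outdir, "consensus.fa")
        )
        with open(os.path.join(outdir, "annotations.out"), "w") as fh:
            fh.write(
                format_repeatmasker_out(
                    self.annotations, header=True, link_ids=self.config.emit_link_ids
                )
            )
        self.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
        with open(os.path.join(outdir, "config-echo.yaml"), "w") as fh:
            yaml.safe_dump(self.config.to_dict(), fh, sort_keys=False)


def simulate_landscape(config: SimConfig) -> SimResult:
    """Generate a mutually consistent (genome, annotations, copies, truth)
    bundle from one seeded generator."""
    rng = np.random.default_rng(config.seed)
    roots, masters = _build_masters(config, rng)

    # draw copies per lineage
    draws = []  # (time_myr, subfamily_id)
    for ev in config.master_events:
        window = ev.birth_myr - ev.death_myr
        n = rng.poisson(ev.insertion_rate * window)
        times = rng.uniform(ev.death_myr, ev.birth_myr, size=n)
        draws.extend((float(t), ev.subfamily_id) for t in times)
    draws.sort(key=lambda x: (-x[0], x[1]))  # oldest first
    if len(draws) * 30 > config.genome_length:
        raise ValueError(
            f"genome of {config.genome_length} bp too small to host "
            f"{len(draws)} copies"
        )

    background = _seq.decode(
        rng.choice(
            4,
            size=config.genome_length,
            p=[
                (1 - config.gc) / 2,
                config.gc / 2,
                config.gc / 2,
                (1 - config.gc) / 2,
            ],
        )
    )
    blocks: list[_Block] = [_Block(None, background)]

    copy_meta = []  # dicts per copy
    copy_seqs: list[str] = []  # element (consensus orientation, incl poly(A))
    copy_age: list[float] = []
    virtual_len: list[int] = []

    for idx, (t, sid) in enumerate(draws):
        sm = masters[sid]
        master_codes = _seq.encode(sm.master)
        evolved, n_subst = evolve_sequence(
            master_codes,
            t,
            config.substitution_rate,
            config.kappa,
            config.gamma_alpha,
            config.cpg_multiplier,
            rng,
        )
        evolved, ins_nt, del_nt = apply_indels(
            evolved, t, config.indel_rate, config.indel_geom_p, rng
        )
        trunc = 0
        if rng.random() < config.truncation_prob:
            frac = rng.uniform(*config.truncation_frac_range)
            trunc = int(frac * len(evolved))
            evolved = evolved[trunc:]
        polya = "A" * int(rng.integers(config.polya_range[0], config.polya_range[1] + 1))
        element = _seq.decode(evolved) + polya
        if len(element) < 10:
            element = (_seq.decode(evolved) or "A") + polya  # degenerate guard
        strand = "+" if rng.random() < 0.5 else "C"
        oriented = element if strand == "+" else _seq.revcomp(element)

        tsd_len = int(rng.integers(config.tsd_range[0], config.tsd_range[1] + 1))
        # choose a host block
        nested_into = None
        host_idx = None
        if rng.random() < config.nesting_prob:
            owned = [
                k
                for k, blk in enumerate(blocks)
                if blk.owner is not None and len(blk.seq) >= tsd_len + 2
            ]
            if owned:
                host_idx = int(owned[int(rng.integers(0, len(owned)))])
                nested_into = blocks[host_idx].owner
        if host_idx is None:
            bg = [
                k
                for k, blk in enumerate(blocks)
                if blk.owner is None and len(blk.seq) >= tsd_len + 2
            ]
            weights = np.array([len(blocks[k].seq) for k in bg], dtype=float)
            host_idx = int(bg[int(rng.choice(len(bg), p=weights / weights.sum()))])
        host = blocks[host_idx]
        k = int(rng.integers(1, len(host.seq) - tsd_len))
        site = host.seq[k : k + tsd_len]
        left, right = _split_block(host, k + tsd_len)
        new_blocks = [
            left,
            _Block(idx, oriented, trunc + 1, trunc + len(element), strand),
            _Block(None, site),
            right,
        ]
        blocks[host_idx : host_idx + 1] = new_blocks

        copy_meta.append(
            {
                "copy_id": f"cp{idx:05d}",
                "family": sm.family,
                "subfamily": sid,
                "subtype": sm.subtype or "",
                "insertion_time_myr": t,
                "strand": strand,
                "nested_into": f"cp{nested_into:05d}" if nested_into is not None else "",
                "truncated_nt": trunc,
                "n_substitutions": n_subst,
                "ins_nt": ins_nt,
                "del_nt": del_nt,
                "full_length": len(element) > 130,
                "distance_to_master": n_subst / max(1, len(sm.master)),
            }
        )
        copy_seqs.append(element)
        copy_age.append(t)
        virtual_len.append(trunc + len(element))

    # emit genome, annotations, and genomic positions
    scaffold = "sim_scaffold_1"
    genome = {scaffold: "".join(b.seq for b in blocks)}
    annotations: list[RepeatAnnotation] = []
    first_start: dict[int, int] = {}
    pos = 1
    for blk in blocks:
        if blk.owner is not None and blk.seq:
            meta = copy_meta[blk.owner]
            annotations.append(
                RepeatAnnotation(
                    query_id=scaffold,
                    q_start=pos,
                    q_end=pos + len(blk.seq) - 1,
                    strand=blk.strand,
                    family=meta["family"],
                    c_start=blk.e_start,
                    c_end=blk.e_end,
                    c_left=max(0, virtual_len[blk.owner] - blk.e_end),
                    divergence_pct=round(100.0 * meta["distance_to_master"], 1),
                    del_pct=round(
                        100.0 * meta["del_nt"] / max(1, len(copy_seqs[blk.owner])), 1
                    ),
                    ins_pct=round(
                        100.0 * meta["ins_nt"] / max(1, len(copy_seqs[blk.owner])), 1
                    ),
                    sw_score=1000,
                    repeat_class="SINE",
                    link_id=(blk.owner + 1) if config.emit_link_ids else None,
                )
            )
            first_start.setdefault(blk.owner, pos)
        pos += len(blk.seq)

    for idx, meta in enumerate(copy_meta):
        meta["locus"] = first_start.get(idx, -1)
    truth = pd.DataFrame(copy_meta)
    copies = [(m["copy_id"], copy_seqs[i]) for i, m in enumerate(copy_meta)]

    library = ConsensusLibrary(
        entries=dict(roots),
        polya_starts={fam: config.consensus_length for fam in roots},
    )
    return SimResult(
        genome,
        annotations,
        copies,
        truth,
        library,
        config,
        subfamily_masters={sid: sm.master for sid, sm in masters.items()},
    )


def simulate_activity_history(
    windows: dict[str, tuple[float, float]],
    n_events: int,
    seed: int,
    max_retries: int = 1000,
) -> tuple[list[RepeatAnnotation], pd.DataFrame, list[str]]:
    """Nested-insertion events from per-family activity windows.

    windows maps family -> (birth, death) in Myr ago (birth > death). Each
    event samples an inner insertion time uniformly over the combined
    activity span (the inner family must be active then) and an outer,
    strictly older host insertion (its family active at the older time).
    Returns (annotation rows: outer fragment / inner hit / outer fragment
    per event on its own scaffold, truth table, true activity order —
    most recent first by window midpoint).
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    for fam, (birth, death) in windows.items():
        if not birth > death >= 0:
            raise ValueError(f"{fam}: need birth > death >= 0")
    rng = np.random.default_rng(seed)
    fams = sorted(windows)
    t_max = max(b for b, _ in windows.values())
    t_min = min(d for _, d in windows.values())

    def active(t: float) -> list[str]:
        return [f for f in fams if windows[f][1] <= t <= windows[f][0]]

    rows = []
    annotations: list[RepeatAnnotation] = []
    for k in range(n_events):
        inner = outer = None
        for _ in range(max_retries):
            t_in = float(rng.uniform(t_min, t_max))
            act = active(t_in)
            if act:
                inner = act[int(rng.integers(0, len(act)))]
                break
        if inner is None:
            raise RuntimeError("no family active at any sampled time")
        for _ in range(max_retries):
            t_out = float(rng.uniform(t_in, t_max))
            act = active(t_out)
            if act and t_out > t_in:
                outer = act[int(rng.integers(0, len(act)))]
                break
        if outer is None:
            raise RuntimeError("no active host found older than the inner insertion")
        scaffold = f"evt{k:05d}"
        annotations.extend(
            [
                RepeatAnnotation(scaffold, 1001, 1300, "+", outer, 1, 300, 300,
                                 sw_score=800, link_id=1),
                RepeatAnnotation(scaffold, 1401, 1650, "+", inner, 1, 250, 0,
                                 sw_score=800, link_id=2),
                RepeatAnnotation(scaffold, 1751, 2050, "+", outer, 301, 600, 0,
                                 sw_score=800, link_id=1),
            ]
        )
        rows.append(
            {
                "event": k,
                "inner_family": inner,
                "outer_family": outer,
                "t_inner_myr": t_in,
                "t_outer_myr": t_out,
            }
        )
    truth = pd.DataFrame(rows)
    true_order = sorted(fams, key=lambda f: (windows[f][0] + windows[f][1]) / 2.0)
    return annotations, truth, true_order


# ---------------------------------------------------------------------------
# focused cohorts for parameter-recovery experiments
# ---------------------------------------------------------------------------

SUBTYPE_MIX = (0.093, 0.014, 0.893)  # WSINE1 : WSINE1a : WSINE1b


def simulate_subtype_cohort(
    n_copies: int,
    distance: float,
    seed: int,
    length: int = 150,
    mix: tuple[float, float, float] = SUBTYPE_MIX,
    insert_80_seq: str = "TCAGGCT",
    insert_120_seq: str = "AGGTCAAGGCT",
) -> tuple[list[tuple[str, str]], list[str], str]:
    """Copies of known subtype at a given expected substitution divergence.

    Each copy is the family consensus plus its subtype's signature inserts,
    then evolved to the requested expected distance (HKY kappa 4, gamma
    0.5; no CpG boost — the condition of interest is the divergence
    level). Returns (copies, true labels, base consensus).
    """
    rng = np.random.default_rng(seed)
    consensus = _random_consensus(length, rng)
    labels_all = ("WSINE1", "WSINE1a", "WSINE1b")
    copies = []
    labels = []
    for i in range(n_copies):
        label = labels_all[int(rng.choice(3, p=mix))]
        seq = consensus
        if label == "WSINE1a":
            seq = seq[:120] + insert_120_seq + seq[120:]
        if label in ("WSINE1a", "WSINE1b"):
            seq = seq[:80] + insert_80_seq + seq[80:]
        codes, _ = evolve_sequence(
            _seq.encode(seq), 1.0, distance, 4.0, 0.5, 1.0, rng
        )
        copies.append((f"st{i:05d}", _seq.decode(codes)))
        labels.append(label)
    return copies, labels, consensus


def simulate_subfamily_cohort(
    n_subfamilies: int,
    copies_per: int,
    n_diagnostics: int,
    distance: float,
    seed: int,
    length: int = 150,
) -> tuple[str, list[tuple[str, str]], list[str]]:
    """Planted-subfamily data for co-segregation recovery.

    Each subfamily master is the root consensus plus `n_diagnostics`
    private substitutions at non-CpG positions (stable markers — CpG-sited
    mutations are hypermutable and make poor diagnostics); copies evolve
    from their master to the requested expected (non-CpG) distance under
    the full substitution process. Substitution-only, so rows are already
    in consensus coordinates. Returns (consensus, records, true labels).
    """
    rng = np.random.default_rng(seed)
    consensus = _random_consensus(length, rng)
    cpg = set()
    for i in range(length - 1):
        if consensus[i] == "C" and consensus[i + 1] == "G":
            cpg.update((i, i + 1))
    free = [p for p in range(length) if p not in cpg]
    picks = rng.choice(len(free), size=n_subfamilies * n_diagnostics, replace=False)
    records = []
    labels = []
    cons_codes = _seq.encode(consensus)
    for s in range(n_subfamilies):
        master = cons_codes.copy()
        for k in range(n_diagnostics):
            p = free[int(picks[s * n_diagnostics + k])]
            master[p] = (int(master[p]) + 1 + int(rng.integers(0, 3))) % 4
        for c in range(copies_per):
            codes, _ = evolve_sequence(master, 1.0, distance, 4.0, 0.5, 10.0, rng)
            records.append((f"sf{s}_{c:04d}", _seq.decode(codes)))
            labels.append(f"true{s}")
    return consensus, records, labels


def simulate_aged_cohort(
    age_myr: float,
    n_copies: int,
    seed: int,
    rate: float = 0.0045,
    length: int = 150,
) -> tuple[str, list[tuple[str, str]]]:
    """Copies of one master inserted `age_myr` ago, evolved under the full
    substitution process (kappa 4, gamma 0.5, CpG x10). Returns (master,
    records)."""
    rng = np.random.default_rng(seed)
    master = _random_consensus(length, rng)
    codes = _seq.encode(master)
    records = []
    for i in range(n_copies):
        evolved, _ = evolve_sequence(codes, age_myr, rate, 4.0, 0.5, 10.0, rng)
        records.append((f"age{i:04d}", _seq.decode(evolved)))
    return master, records


def simulate_dated_insertion(
    split_age_myr: float,
    n_taxa: int,
    seed: int,
    rate: float = 0.0045,
    length: int = 170,
) -> list[tuple[str, str]]:
    """Orthologous copies of one insertion fixed before a dated lineage
    split. Each taxon's orthologue evolves independently for half the
    split age, so the expected pairwise path between two orthologues
    equals rate x split_age — the convention under which dividing the mean
    pairwise distance by the split age recovers the rate."""
    rng = np.random.default_rng(seed)
    ancestor = _seq.encode(_random_consensus(length, rng))
    site_mult = rng.gamma(0.5, 2.0, size=length)  # shared: one locus
    rows = []
    for i in range(n_taxa):
        evolved, _ = evolve_sequence(
            ancestor, split_age_myr / 2.0, rate, 4.0, 0.5, 10.0, rng,
            site_mult=site_mult,
        )
        rows.append((f"taxon{i:02d}", _seq.decode(evolved)))
    return rows
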