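# Methods

## Scope and model of the data

The package analyses a genome's *retroposon landscape*: the accumulated
copies of SINE families (here modelled on the marsupial CORE-SINE family
WSINE1 and its relatives) as annotated by a RepeatMasker-style screen.
Each copy descends from a master element active during some window of
time, acquires substitutions and small indels after insertion, and may be
5′-truncated, tailed with poly(A), flanked by target-site duplications
(TSDs), and fragmented by later insertions nesting inside it. All
coordinates are 1-based inclusive; times are Myr ago; rates are
substitutions per site per Myr.

## Alignment and indel profiling

Copies are aligned globally to their family consensus with
Needleman–Wunsch under affine gap scoring (Gotoh three-state DP,
numba-compiled). Defaults follow the EMBOSS needle convention: match +5,
mismatch −4, gap open 10, gap extend 0.5, a length-L gap costing
`open + L·extend`; N scores 0 against everything. Among co-optimal
alignments the traceback prefers match/mismatch over deletion over
insertion at every step, which places every gap at its leftmost
equivalent position in consensus coordinates and puts deletions before
insertions — profiles are then a pure function of the inputs. An
insertion between consensus positions p and p+1 is recorded at p;
deletions are recorded by the consensus positions they cover.

Leftmost placement has a documented side effect: when the edge of an
inserted segment matches the adjacent consensus sequence, the recorded
insertion position slides upstream of the true insertion point. The test
suite asserts this shift rather than hiding it, because real indel
profiles show the same secondary peak below a planted insertion.

The indel profile counts, per consensus position, the number of copies
with an insertion at that position and the number whose deletions cover
it. Over-represented indels are called where the per-copy fraction
reaches `min_fraction` (default 0.05), merged within a ±3 position
window, and reported with the modal event length.

## Subtype classification

Full-length copies (ungapped length strictly greater than 130 nt) are
classified by two signature insertions: ~7 nt near consensus position 80
(carried by subtypes a and b) and ~11 nt near position 120 (subtype a
only). Position tolerance is ±5 nt and length tolerance ±2 nt — wide
enough to absorb the alignment-jitter artifact above, narrow enough that
the two diagnostics (40 nt apart) never collide. The truth table is
(no,no)→WSINE1, (80 only)→WSINE1b, (both)→WSINE1a; the fourth cell
(120 without 80) matches no described subtype and is surfaced as
`unclassified` rather than force-fit. Percentages in tallies are taken
over the three named subtypes; unclassified copies are reported
separately.

## Nested-insertion activity ordering

Fragment chains are built from shared link ids when the annotation table
provides them, otherwise by a heuristic: same family, same strand,
consensus coordinates continuing within [−10, +20] nt across a genomic
gap of at most 20 kb (consensus runs backwards along the genome on
C-strand chains). A nested event is a chain lying strictly inside the gap
between two consecutive fragments of another chain; chains contained in
another contained chain are credited to the inner gap (a doubly nested
A/B/C stack yields C-into-B and B-into-A, never C-into-A).

Events populate a precedence matrix N[inner, outer]. Family i's activity
score is s_i = I_i/(I_i + O_i) with I_i = Σ_j N[i,j], O_i = Σ_j N[j,i]
(self-nesting tabulated but excluded — its direction carries no ordering
information); families are ranked by s_i, most recent first. Families
with fewer than `min_events` (default 10) participations are reported as
"insufficient data". Each family pair gets a two-sided binomial test of
its direction counts against the symmetric null; pairs that cannot reject
symmetry are flagged unresolved. This is a deliberately simple,
simulation-validated estimator of the *order* of activity; activity
durations and likelihood modelling of activity periods are out of scope.

## Co-segregation subfamilies

Copies are projected onto consensus coordinates (insertions dropped,
deletions as gaps). Within a subfamily's members, candidate diagnostics
are derived states carried by at least `min_count` copies (and leaving at
least `min_count` behind). Position pairs are scored by a one-sided
binomial test of their joint carrier count under independence of the
marginals; single positions against the background per-state mismatch
frequency. Pairs are the primary signal — a lone position is accepted
only when no pair passes — and the best candidate must clear a
Bonferroni-corrected alpha (default 0.01). Ties break toward the larger
carrier set, then the smallest position tuple. Accepted carriers become a
child subfamily with a majority-rule consensus; parent and child are
re-scanned until nothing passes or `max_subfamilies` is reached.
`min_count` defaults to 500, the established genome-scale threshold;
desk-scale analyses and tests override it.

After the recursion, every copy is assigned to the nearest subfamily
consensus (Hamming distance over comparable, non-masked columns; ties
toward the deeper subfamily). This final step is needed because the
carrier rule is strict: a copy whose diagnostic site back-mutated after
insertion carries only part of the signature and would otherwise be
stranded in the parent. Subfamily consensus CpG columns are masked in the
split test by default, since CpG transitions are hypermutable and mimic
diagnostics.

Copies farther than `max_distance` (default 0.35 substitutions/site,
p-distance) from the family consensus are screened out beforehand as
foreign elements caught by the annotation screen.

## Distances, rates, and ages

Distances are computed over columns where both rows carry a real base,
excluding user-specified columns (poly(A), TSDs) and — when `cpg_mask` is
on (default) — every column lying in a CpG dinucleotide in *either*
compared row. The per-comparison rule matters: a site can enter CpG
context through a neighbouring substitution along either lineage and
then mutate at the accelerated CpG rate; masking only the ancestral CpG
columns leaves that acceleration in, while masking columns CpG in any
row of a large alignment discards genuine substitutions. Corrections:
JC69 d = −(3/4)·ln(1 − 4p/3); K80 d = −(1/2)·ln(1−2P−Q) − (1/4)·ln(1−2Q)
with transition/transversion proportions P, Q; the +Γ variants use the
standard gamma forms (e.g. (3/4)·a·[(1−4p/3)^(−1/a) − 1]) with shape a
(default 0.5), converging to the uncorrected forms as a → ∞. Saturation
(p ≥ 3/4, or a K80 log argument ≤ 0) raises a hard error rather than
returning NaN, so silent saturation cannot corrupt an age table; rows
with fewer than 20 comparable columns are rejected. A pairwise HKY+Γ+I
maximum-likelihood distance would need numerical optimisation and
parameter values that are not identifiable pairwise; the closed-form
JC69/K80(±Γ) family is used instead, and the rate constant is a
configuration input, so the age arithmetic is unchanged however the rate
was obtained.

Subfamily age: t̂ = d̄/r, where d̄ is the mean member-to-consensus
distance (the consensus stands in for the non-evolving master) and r the
local rate, default 0.0045/site/Myr. Rate calibration uses insertions
fixed shortly before a dated lineage split: the mean *pairwise* distance
among the orthologous copies divided by the upper and lower split-age
bound gives a bracketing rate range (point estimate: geometric mean);
several calibrating insertions combine by taking the envelope of their
ranges. This convention treats the split age as the total tree path
separating two orthologues, and the synthetic generator mirrors it
(per-lineage time = split_age/2), keeping the calibration
self-consistent end to end.

## The synthetic generator

`simulate_landscape` draws copies per lineage as Poisson(rate × activity
window), evolves each copy from its subfamily master for its age, and
places it in a background genome — or, with probability `nesting_prob`
(default 0.05), inside an already-placed older copy, splitting that
copy's annotation into link-joined fragments with near-contiguous
consensus coordinates. Substitution is simulated event-by-event
(Gillespie) under HKY with κ = 4, gamma site-rate multipliers
(shape 0.5), and a ×10 multiplier on transitions at sites currently in
CpG context — context tracks the mutating sequence, so sites can enter
and leave the accelerated class. Site multipliers are drawn per copy,
except for orthologues of one dated insertion, which share one draw:
rate variation is a property of the site. Indels are Poisson with
geometric lengths (p = 0.5) at 2×10⁻⁴ /site/Myr; 5′ truncation removes a
uniform 10–60% of the element with probability 0.1; poly(A) tails are
8–30 nt, TSDs 5–15 nt. The default scenario is a devil-like history: a
WSINE1 root lineage (75–45 Myr ago) spawning an a-subtype lineage and two
b-subtype lineages (the youngest active 40–15 Myr ago), plus an older
unrelated family, in a 400 kb background at GC 0.42; subfamily masters
carry 3 private diagnostic substitutions each. Element base composition
is uniform, so the HKY process reduces exactly to K80 and the closed-form
corrections apply.

What the generator does *not* emulate — population-genetic fixation,
master-sequence drift during a lineage's activity, LINE partner
sequences, annotation false negatives, assembly artifacts — bounds what
green tests show: recovery results demonstrate estimator correctness
under the stated generative model at desk scale, not performance on a
real assembly.

## Validation experiments and problem sizes

The recovery suite (and the acceptance tests) use these study conditions:
subtype accuracy on 1,000 copies at ≤0.10 expected substitutions/site
(no CpG boost there — the condition of interest is the divergence level;
accuracy must be ≥95%, and 100% at zero divergence); subfamily recovery
on 5 planted subfamilies × 600 copies with 2 diagnostics each at
0.05/site, `min_count` 300, mean ARI ≥ 0.9 over 20 replicates (planted
diagnostics sit at non-CpG positions — markers at hypermutable sites are
poor diagnostics by construction); activity order exactly recovered from
4 disjoint activity windows with 2,000 events, and mean Kendall τ ≥ 0.8
over 100 replicates of 6 overlapping windows with 600 events each;
cohort ages of 10/30/60 Myr recovered within ±15% from 500 copies
(K80+Γ, a = 0.5, CpG-masked); and the three-insertion calibration
envelope covering the true rate in ≥90% of 50 replicates (3 loci of
170 nt, 10 orthologues each, split windows 12–16, 22–28, and 34–42 Myr
with true ages at the midpoints). These sizes keep the full suite around
a minute of CPU while leaving each statistic comfortably away from its
small-sample noise floor.

## Numerical and degenerate-input policies

Ties in the aligner are resolved by the fixed preference order above;
ties in majority consensus fall back to the parent consensus state; ties
in nearest-consensus assignment go to the deeper subfamily. Empty inputs
are errors where silence would corrupt downstream tables (empty profile
in indel calling, all-unclassified tallies, all-saturated distance sets)
and empty outputs where that is the honest answer (no annotations → empty
summary; header-only annotation files). Density values are reported both
unrounded and rounded to the nearest integer (ties away from zero).
Percent-of-genome uses the literal assembly size supplied by the caller;
published tables sometimes use a non-gap denominator, so the parameter is
exposed rather than guessed.

## Known limitations

The activity-ordering score ranks families but does not estimate activity
durations or absolute times. The co-segregation algorithm is a defined,
simulation-validated procedure of the same class as established
subfamily-partitioning tools, not a reimplementation of any of them;
networks from different tools will differ in detail. Ages inherit the
calibration convention above: if a user's mean pairwise distances derive
from a different tree shape than the star assumed here, the rate should
be recalibrated accordingly. Genome-scale figures (hundreds of thousands
of copies, tens of subfamilies) require a real assembly and are outside
what the desk-scale generator can reproduce.
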