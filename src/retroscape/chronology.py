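"""Nucleotide distances, substitution-rate calibration, and subfamily ages.

Distances are computed on consensus-projected rows (see
:mod:`retroscape.subfamily_coseg`): equal-length vectors over {A,C,G,T,-,N}
in which only columns where both rows carry a real base are compared.
Closed-form corrections are provided for multiple hits:

* ``p``      raw mismatch proportion,
* ``JC69``   d = -(3/4) ln(1 - 4p/3),
* ``K80``    d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q), with P and Q the
  transition and transversion proportions,
* ``JC69+G`` / ``K80+G``  the standard gamma-rate-heterogeneity variants,
  e.g. JC69+G: d = (3/4) a [(1 - 4p/3)^(-1/a) - 1] with shape ``a``.

Subfamily ages follow the repeat molecular clock: a copy inserted t Myr ago
has accumulated d = r t substitutions/site against its (non-evolving)
master, so t = d / r.  The default rate r = 0.0045 substitutions/site/Myr
is the local SINE rate calibrated from dated insertions; it is a
configuration input, not a fitted constant.

Rate calibration from a dated insertion: orthologous copies of one
insertion event present on both sides of a dated lineage split are
compared; their mean pairwise distance divided by the upper and lower age
bound of the split brackets the local rate.  The convention here (as in
the calibration this emulates) treats the split age as the total tree path
separating two orthologues.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from . import _seq
from ._seq import cpg_columns  # re-exported convenience

__all__ = [
    "DistanceModelParams",
    "RateCalibration",
    "AgeEstimate",
    "SaturationError",
    "TooFewSitesError",
    "pairwise_distance",
    "mean_distance_to_consensus",
    "calibrate_rate",
    "combine_calibrations",
    "estimate_age",
    "cpg_columns",
]

MIN_COMPARABLE_SITES = 20


class SaturationError(ValueError):
    """Distance correction left its log/power domain (too many multiple hits)."""


class TooFewSitesError(ValueError):
    """Fewer comparable (non-gap, non-N, non-excluded) columns than required."""


_MODELS = ("p", "JC69", "K80", "JC69+G", "K80+G")


@dataclass
class DistanceModelParams:
    """Distance model configuration.

    excluded_columns are 1-based consensus positions dropped before
    comparison (poly(A) tail, TSD columns). cpg_mask additionally drops,
    per comparison, every column lying in a CpG dinucleotide in either
    row — CpG transitions are hypermutable, and a site can enter CpG
    context along either lineage, not only in the ancestor.
    """

    model: str = "K80"
    gamma_alpha: float | None = None
    cpg_mask: bool = True
    excluded_columns: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; choose from {_MODELS}")
        if self.model.endswith("+G"):
            if self.gamma_alpha is None:
                self.gamma_alpha = 0.5
            if self.gamma_alpha <= 0:
                raise ValueError("gamma_alpha must be > 0 for +G models")
        self.excluded_columns = frozenset(self.excluded_columns)


def _as_codes(row) -> np.ndarray:
    if isinstance(row, str):
        return _seq.encode(row)
    return np.asarray(row, dtype=np.int8)


def _comparable_mask(a: np.ndarray, b: np.ndarray, params: DistanceModelParams) -> np.ndarray:
    mask = (a < 4) & (b < 4) & (a >= 0) & (b >= 0)
    if params.excluded_columns:
        excl = np.fromiter((p - 1 for p in params.excluded_columns), dtype=np.int64)
        excl = excl[(excl >= 0) & (excl < len(a))]
        mask[excl] = False
    if params.cpg_mask:
        # drop columns lying in a CpG dinucleotide in either row: CpG
        # transitions are hypermutable, and a site may enter CpG context
        # along either lineage, not only in the ancestor
        for row in (a, b):
            cg = (row[:-1] == _seq.C) & (row[1:] == _seq.G)
            mask[:-1] &= ~cg
            mask[1:] &= ~cg
    return mask


def _jc69(p: float, alpha: float | None) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0.0:
        raise SaturationError(f"JC69 saturated at p={p:.4f} (requires p < 3/4)")
    if alpha is None:
        return -0.75 * math.log(arg)
    return 0.75 * alpha * (arg ** (-1.0 / alpha) - 1.0)


def _k80(P: float, Q: float, alpha: float | None) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(f"K80 saturated at P={P:.4f}, Q={Q:.4f}")
    if alpha is None:
        return -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return 0.5 * alpha * (w1 ** (-1.0 / alpha) - 1.0) + 0.25 * alpha * (
        w2 ** (-1.0 / alpha) - 1.0
    )


def pairwise_distance(a, b, params: DistanceModelParams | None = None) -> float:
    """Distance in substitutions/site between two consensus-projected rows.

    Rows may be strings over {A,C,G,T,-,N} or int8 code arrays of equal
    length. Raises TooFewSitesError below 20 comparable columns and
    SaturationError when the chosen correction is undefined.
    """
    params = params or DistanceModelParams()
    a = _as_codes(a)
    b = _as_codes(b)
    if a.shape != b.shape:
        raise ValueError(f"rows differ in length: {len(a)} vs {len(b)}")
    mask = _comparable_mask(a, b, params)
    n = int(mask.sum())
    if n < MIN_COMPARABLE_SITES:
        raise TooFewSitesError(
            f"only {n} comparable sites (< {MIN_COMPARABLE_SITES})"
        )
    aa = a[mask]
    bb = b[mask]
    diff = aa != bb
    p = float(diff.mean())
    if params.model == "p":
        return p
    if params.model.startswith("JC69"):
        return _jc69(p, params.gamma_alpha if params.model.endswith("+G") else None)
    # K80: transitions are same-parity substitutions in this coding
    ts = diff & ((aa & 1) == (bb & 1))
    P = float(ts.mean())
    Q = p - P
    return _k80(P, Q, params.gamma_alpha if params.model.endswith("+G") else None)


def mean_distance_to_consensus(
    members: Iterable,
    consensus,
    params: DistanceModelParams | None = None,
) -> tuple[float, float, int, int]:
    """Mean and sd of member-to-consensus distances.

    Members failing the distance preconditions (saturation, too few sites)
    are skipped and counted. Returns (mean, sd, n_used, n_skipped); sd is 0
    for a single usable member. Raises if every member is skipped.
    """
    params = params or DistanceModelParams()
    cons = _as_codes(consensus)
    dists = []
    skipped = 0
    for row in members:
        try:
            dists.append(pairwise_distance(row, cons, params))
        except (SaturationError, TooFewSitesError):
            skipped += 1
    if not dists:
        raise ValueError("all members skipped: no usable distances")
    arr = np.asarray(dists)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return float(arr.mean()), sd, len(arr), skipped


@dataclass
class RateCalibration:
    """Substitution-rate range from one dated insertion."""

    split_name: str
    lower_age_myr: float
    upper_age_myr: float
    mean_distance: float
    rate_range: tuple[float, float]  # (low, high) per site per Myr

    @property
    def point_rate(self) -> float:
        lo, hi = self.rate_range
        return math.sqrt(lo * hi)


def calibrate_rate(
    insertion_rows: Sequence,
    lower_age: float,
    upper_age: float,
    params: DistanceModelParams | None = None,
    split_name: str = "",
) -> RateCalibration:
    """Mean pairwise distance among orthologous copies of a dated insertion,
    divided by the upper and lower split age, gives a bracketing rate range.
    """
    if lower_age <= 0 or upper_age <= 0:
        raise ValueError("split ages must be positive")
    if lower_age > upper_age:
        raise ValueError("lower_age must not exceed upper_age")
    rows = [_as_codes(r) for r in insertion_rows]
    if len(rows) < 2:
        raise ValueError("need at least two orthologous copies to calibrate")
    params = params or DistanceModelParams()
    dists = [pairwise_distance(a, b, params) for a, b in combinations(rows, 2)]
    d = float(np.mean(dists))
    return RateCalibration(
        split_name=split_name,
        lower_age_myr=lower_age,
        upper_age_myr=upper_age,
        mean_distance=d,
        rate_range=(d / upper_age, d / lower_age),
    )


def combine_calibrations(calibrations: Sequence[RateCalibration]) -> RateCalibration:
    """Envelope over several dated insertions: the combined range spans the
    per-insertion ranges, as when three calibrating insertions bracket one
    local rate."""
    if not calibrations:
        raise ValueError("no calibrations to combine")
    lo = min(c.rate_range[0] for c in calibrations)
    hi = max(c.rate_range[1] for c in calibrations)
    return RateCalibration(
        split_name="+".join(c.split_name or "?" for c in calibrations),
        lower_age_myr=min(c.lower_age_myr for c in calibrations),
        upper_age_myr=max(c.upper_age_myr for c in calibrations),
        mean_distance=float(np.mean([c.mean_distance for c in calibrations])),
        rate_range=(lo, hi),
    )


@dataclass
class AgeEstimate:
    subfamily_id: str
    mean_distance: float
    rate: float
    age_myr: float


def estimate_age(mean_distance: float, rate: float, subfamily_id: str = "") -> AgeEstimate:
    """Age (Myr) of a subfamily from its mean member-to-consensus distance."""
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if mean_distance < 0:
        raise ValueError("mean_distance must be >= 0")
    return AgeEstimate(subfamily_id, mean_distance, rate, mean_distance / rate)
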