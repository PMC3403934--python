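import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from retroscape._seq import decode
from retroscape.chronology import (
    DistanceModelParams,
    SaturationError,
    TooFewSitesError,
    calibrate_rate,
    combine_calibrations,
    estimate_age,
    mean_distance_to_consensus,
    pairwise_distance,
)


def _rows_with_p(n_sites, n_mismatch, transitions=None):
    """Pair of rows with an exact mismatch composition, CpG-free."""
    a = "A" * n_sites
    b = list(a)
    transitions = n_mismatch if transitions is None else transitions
    for i in range(transitions):
        b[i] = "G"  # A->G transition
    for i in range(transitions, n_mismatch):
        b[i] = "T"  # A->T transversion
    return a, "".join(b)


P_PARAMS = DistanceModelParams(model="p", cpg_mask=False)
JC_PARAMS = DistanceModelParams(model="JC69", cpg_mask=False)
K80_PARAMS = DistanceModelParams(model="K80", cpg_mask=False)


class TestPairwiseDistance:
    def test_identical_rows_zero_under_every_model(self):
        a, b = _rows_with_p(100, 0)
        for model in ("p", "JC69", "K80", "JC69+G", "K80+G"):
            params = DistanceModelParams(model=model, cpg_mask=False)
            assert pairwise_distance(a, b, params) == 0.0

    def test_jc69_closed_form(self):
        a, b = _rows_with_p(1000, 100)
        assert pairwise_distance(a, b, JC_PARAMS) == pytest.approx(0.107326, abs=1e-6)

    def test_k80_closed_form(self):
        a, b = _rows_with_p(1000, 150, transitions=100)  # P=0.10, Q=0.05
        assert pairwise_distance(a, b, K80_PARAMS) == pytest.approx(0.170182, abs=1e-6)

    def test_jc69_saturation(self):
        a, b = _rows_with_p(100, 75)
        with pytest.raises(SaturationError):
            pairwise_distance(a, b, JC_PARAMS)

    def test_too_few_comparable_sites(self):
        with pytest.raises(TooFewSitesError):
            pairwise_distance("ACGTACGTAC", "ACGTACGTAC", P_PARAMS)

    def test_gap_and_n_columns_excluded(self):
        a = "A" * 30 + "--NN"
        b = "A" * 29 + "G" + "AAAA"
        assert pairwise_distance(a, b, P_PARAMS) == pytest.approx(1 / 30)

    def test_gamma_limit_recovers_uncorrected(self):
        a, b = _rows_with_p(1000, 150, transitions=100)
        for model in ("JC69", "K80"):
            plain = pairwise_distance(a, b, DistanceModelParams(model=model, cpg_mask=False))
            g = pairwise_distance(
                a, b,
                DistanceModelParams(model=model + "+G", gamma_alpha=1e4, cpg_mask=False),
            )
            assert abs(g - plain) / plain < 1e-3

    def test_corrections_ordered(self):
        a, b = _rows_with_p(1000, 150, transitions=100)
        p = pairwise_distance(a, b, P_PARAMS)
        jc = pairwise_distance(a, b, JC_PARAMS)
        assert 0 <= p <= jc

    def test_cpg_mask_excludes_context_columns(self):
        # mismatch at a CpG column disappears when masking is on
        a = "CGAAAAAAAAAAAAAAAAAAAAAAAA" * 2
        b = "TGAAAAAAAAAAAAAAAAAAAAAAAA" * 2
        masked = DistanceModelParams(model="p", cpg_mask=True)
        assert pairwise_distance(a, b, masked) == 0.0
        assert pairwise_distance(a, b, P_PARAMS) > 0.0


class TestMeanDistance:
    def test_members_equal_consensus(self):
        mean, sd, n, skipped = mean_distance_to_consensus(
            ["A" * 50] * 5, "A" * 50, P_PARAMS
        )
        assert (mean, sd, n, skipped) == (0.0, 0.0, 5, 0)

    def test_single_member_sd_zero(self):
        a, b = _rows_with_p(100, 10)
        mean, sd, n, _ = mean_distance_to_consensus([b], a, P_PARAMS)
        assert n == 1 and sd == 0.0 and mean == pytest.approx(0.1)

    def test_saturated_members_skipped_and_counted(self):
        good = _rows_with_p(100, 10)[1]
        bad = _rows_with_p(100, 80)[1]
        mean, _, n, skipped = mean_distance_to_consensus(
            [good, bad], "A" * 100, JC_PARAMS
        )
        assert (n, skipped) == (1, 1)

    def test_all_skipped_is_error(self):
        bad = _rows_with_p(100, 80)[1]
        with pytest.raises(ValueError, match="skipped"):
            mean_distance_to_consensus([bad], "A" * 100, JC_PARAMS)


class TestCalibration:
    def test_rate_range_arithmetic(self):
        a, b = _rows_with_p(1000, 63)
        calib = calibrate_rate([a, b], 12, 16, P_PARAMS, split_name="s1")
        assert calib.mean_distance == pytest.approx(0.063)
        assert calib.rate_range == (pytest.approx(0.0039375), pytest.approx(0.00525))
        assert calib.point_rate == pytest.approx(math.sqrt(0.0039375 * 0.00525))

    def test_zero_distance_zero_range(self):
        calib = calibrate_rate(["A" * 50, "A" * 50], 12, 16, P_PARAMS)
        assert calib.rate_range == (0.0, 0.0)

    def test_bad_ages_rejected(self):
        with pytest.raises(ValueError):
            calibrate_rate(["A" * 50, "A" * 50], 16, 12, P_PARAMS)
        with pytest.raises(ValueError):
            calibrate_rate(["A" * 50, "A" * 50], 0, 16, P_PARAMS)

    def test_combined_range_is_envelope(self):
        a1, b1 = _rows_with_p(1000, 63)
        a2, b2 = _rows_with_p(1000, 120)
        c1 = calibrate_rate([a1, b1], 12, 16, P_PARAMS)
        c2 = calibrate_rate([a2, b2], 22, 28, P_PARAMS)
        comb = combine_calibrations([c1, c2])
        assert comb.rate_range[0] == min(c1.rate_range[0], c2.rate_range[0])
        assert comb.rate_range[1] == max(c1.rate_range[1], c2.rate_range[1])


class TestAges:
    def test_oldest_and_youngest_subfamily_arithmetic(self):
        assert estimate_age(0.3285, 0.0045).age_myr == pytest.approx(73.0)
        assert estimate_age(0.1035, 0.0045).age_myr == pytest.approx(23.0)
        assert estimate_age(0.0, 0.0045).age_myr == 0.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            estimate_age(0.1, 0.0)
        with pytest.raises(ValueError):
            estimate_age(0.1, -1.0)

    @settings(max_examples=50, deadline=None)
    @given(
        d=st.floats(0, 0.7, allow_nan=False),
        k=st.floats(0.01, 10, allow_nan=False),
        r=st.floats(1e-4, 0.01, allow_nan=False),
    )
    def test_age_exactly_linear_in_distance(self, d, k, r):
        lhs = estimate_age(k * d, r).age_myr
        rhs = k * estimate_age(d, r).age_myr
        assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-9)
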