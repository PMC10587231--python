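"""The CDF-matching transform: oracle equivalence and its invariants."""

import bisect
import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from upalign.align import (
    AlignmentTransform,
    DomainError,
    FitError,
    apply_alignment,
    detect_shift,
    empirical_cdf,
    fit_alignment,
)
from upalign.metrics import roc_auc


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def oracle_quantile(reference, q):
    """Reference quantile at level q: order statistic i of n sits at level
    i/n, linear in between, minimum below level 1/n.  Scalar, loop-free of
    the production code path."""
    ref = sorted(reference)
    m = len(ref)
    if q <= 1.0 / m:
        return ref[0]
    if q >= 1.0:
        return ref[-1]
    # find i such that i/m <= q <= (i+1)/m, interpolate between ref[i-1], ref[i]
    levels = [(i + 1) / m for i in range(m)]
    j = bisect.bisect_left(levels, q)
    lo_level, hi_level = levels[j - 1], levels[j]
    w = (q - lo_level) / (hi_level - lo_level)
    return ref[j - 1] + w * (ref[j] - ref[j - 1])


def oracle_transform_at_knots(reference, alignment):
    """Brute-force quantile matching evaluated at every distinct alignment
    score: q = #(alignment <= a)/n, output = reference quantile at q."""
    ali = list(alignment)
    out = {}
    for a in sorted(set(ali)):
        q = sum(1 for x in ali if x <= a) / len(ali)
        out[a] = oracle_quantile(reference, q)
    return out


# ---------------------------------------------------------------------------
# empirical_cdf
# ---------------------------------------------------------------------------


class TestEmpiricalCdf:
    def test_counts_fraction_at_or_below(self):
        cdf = empirical_cdf([0.2, 0.4, 0.6, 0.8])
        assert cdf(0.4) == 0.5

    def test_boundaries(self):
        cdf = empirical_cdf([0.2, 0.4, 0.6, 0.8])
        assert cdf(0.1) == 0.0
        assert cdf(0.8) == 1.0
        assert cdf(0.95) == 1.0

    def test_empty_input_errors(self):
        with pytest.raises(DomainError):
            empirical_cdf([])

    def test_matches_counting_oracle(self, rng):
        sample = rng.random(200)
        cdf = empirical_cdf(sample)
        for x in rng.random(50):
            assert cdf(x) == sum(1 for s in sample if s <= x) / 200


# ---------------------------------------------------------------------------
# fit / apply
# ---------------------------------------------------------------------------


class TestFitAlignment:
    def test_identity_when_distributions_coincide(self):
        v = [0.1, 0.3, 0.5, 0.7, 0.9]
        t = fit_alignment(v, v)
        assert np.allclose(t(np.asarray(v)), v)

    def test_pure_location_shift_is_inverted(self):
        reference = np.arange(0.1, 0.81, 0.1)
        alignment = reference + 0.1
        t = fit_alignment(reference, alignment)
        assert np.allclose(t(alignment), alignment - 0.1, atol=1e-12)

    def test_matches_bruteforce_oracle(self, rng):
        reference = rng.random(50)
        alignment = rng.random(40)
        t = fit_alignment(reference, alignment)
        oracle = oracle_transform_at_knots(reference, alignment)
        got = t(np.asarray(sorted(oracle)))
        want = np.asarray([oracle[a] for a in sorted(oracle)])
        assert np.max(np.abs(got - want)) < 1e-10

    def test_too_few_points_refused(self):
        with pytest.raises(FitError):
            fit_alignment([0.1, 0.9], [0.5])
        with pytest.raises(FitError):
            fit_alignment([0.1, 0.9], [0.5, 0.5, 0.5])  # < 2 distinct

    def test_out_of_range_scores_refused(self):
        with pytest.raises(DomainError):
            fit_alignment([0.1, 1.2], [0.2, 0.4])
        with pytest.raises(DomainError):
            fit_alignment([0.1, 0.9], [-0.1, 0.4])

    def test_records_sizes(self, rng):
        t = fit_alignment(rng.random(30), rng.random(20))
        assert (t.reference_size, t.fit_size) == (30, 20)


class TestApplyAlignment:
    def test_identity_transform(self, rng):
        t = AlignmentTransform.identity()
        x = rng.random(10)
        assert np.array_equal(apply_alignment(t, x), x)

    def test_value_at_source_knot_is_target_knot(self):
        t = AlignmentTransform(np.array([0.2, 0.4]), np.array([0.1, 0.3]), 2, 2)
        assert t(np.array([0.2]))[0] == 0.1
        assert t(np.array([0.4]))[0] == 0.3

    def test_linear_midpoint(self):
        t = AlignmentTransform(np.array([0.2, 0.4]), np.array([0.1, 0.3]), 2, 2)
        assert t(np.array([0.3]))[0] == pytest.approx(0.2, abs=1e-15)

    def test_input_outside_unit_interval_rejected(self):
        t = AlignmentTransform.identity()
        with pytest.raises(DomainError):
            t(np.array([1.5]))

    def test_extrapolation_is_clipped_and_monotone(self):
        t = AlignmentTransform(np.array([0.4, 0.6]), np.array([0.1, 0.9]), 2, 2)
        x = np.linspace(0, 1, 101)
        y = t(x)
        assert y.min() >= 0.0 and y.max() <= 1.0
        assert (np.diff(y) >= -1e-15).all()
        # continues linearly with slope 4 just outside the knots
        assert t(np.array([0.39]))[0] == pytest.approx(0.1 - 4 * 0.01)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_monotone_and_in_range_property(self, seed):
        rng = np.random.default_rng(seed)
        t = fit_alignment(rng.random(rng.integers(5, 60)), rng.random(rng.integers(5, 60)))
        x = np.sort(rng.random(50))
        y = t(x)
        assert (np.diff(y) >= -1e-15).all()
        assert (y >= 0).all() and (y <= 1).all()

    def test_json_round_trip(self, rng):
        t = fit_alignment(rng.random(30), rng.random(25))
        back = AlignmentTransform.from_json(t.to_json())
        assert np.array_equal(back.source_knots, t.source_knots)
        assert np.array_equal(back.target_knots, t.target_knots)
        x = rng.random(100)
        assert np.array_equal(back(x), t(x))


# ---------------------------------------------------------------------------
# Statistical invariants
# ---------------------------------------------------------------------------


class TestStatisticalInvariants:
    def test_auc_exactly_conserved_without_ties(self, rng):
        scores = rng.random(500)
        labels = (rng.random(500) < 0.3).astype(int)
        t = fit_alignment(rng.random(300), scores)
        aligned = t(scores)
        assert abs(roc_auc(scores, labels) - roc_auc(aligned, labels)) <= 1e-12

    def test_auc_change_bounded_by_tie_mass(self, rng):
        scores = rng.random(400)
        labels = (rng.random(400) < 0.4).astype(int)
        # flat target segment collapses the middle of the range onto one value
        t = AlignmentTransform(
            np.array([0.0, 0.3, 0.7, 1.0]), np.array([0.0, 0.5, 0.5, 1.0]), 4, 4
        )
        aligned = t(scores)
        pos, neg = aligned[labels == 1], aligned[labels == 0]
        tied_pairs = np.mean(pos[:, None] == neg[None, :])
        delta = abs(roc_auc(scores, labels) - roc_auc(aligned, labels))
        assert tied_pairs > 0  # the construction really creates ties
        assert delta <= 0.5 * tied_pairs + 1e-12

    def test_ks_distance_shrinks_after_alignment(self, rng):
        reference = rng.beta(2, 5, 5000)
        alignment = rng.beta(5, 2, 5000)
        t = fit_alignment(reference, alignment)
        before = detect_shift(reference, alignment).statistic
        after = detect_shift(reference, t(alignment)).statistic
        assert after <= before
        assert after < 0.05

    def test_self_alignment_near_identity(self, rng):
        reference = rng.beta(2, 2, 5000)
        alignment = rng.beta(2, 2, 5000)
        t = fit_alignment(reference, alignment)
        grid = np.linspace(0.01, 0.99, 99)
        assert np.mean(np.abs(t(grid) - grid)) < 0.02

    def test_recovers_inverse_of_monotone_warp(self, rng):
        # alignment = g(X) with X reference-distributed; transform ~ g^{-1}
        g = lambda s: s**2
        g_inv = lambda s: np.sqrt(s)
        x_ref = rng.beta(2, 2, 5000)
        x_new = rng.beta(2, 2, 5000)
        t = fit_alignment(x_ref, g(x_new))
        q05, q95 = np.quantile(g(x_new), [0.05, 0.95])
        grid = np.linspace(q05, q95, 200)
        assert np.max(np.abs(t(grid) - g_inv(grid))) < 0.03


# ---------------------------------------------------------------------------
# detect_shift
# ---------------------------------------------------------------------------


class TestDetectShift:
    def test_identical_samples_not_flagged(self, rng):
        x = rng.random(100)
        rep = detect_shift(x, x)
        assert rep.statistic == 0.0 and not rep.flagged

    def test_disjoint_supports_maximal(self, rng):
        a = rng.uniform(0.0, 0.1, 50)
        b = rng.uniform(0.9, 1.0, 60)
        rep = detect_shift(a, b)
        assert rep.statistic == 1.0 and rep.flagged

    def test_matches_exhaustive_sup_oracle(self, rng):
        a, b = rng.random(37), rng.random(53)
        cdf_a, cdf_b = empirical_cdf(a), empirical_cdf(b)
        pooled = np.concatenate([a, b])
        brute = max(abs(cdf_a(x) - cdf_b(x)) for x in pooled)
        assert detect_shift(a, b).statistic == pytest.approx(brute, abs=1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(DomainError):
            detect_shift([], [0.5])
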