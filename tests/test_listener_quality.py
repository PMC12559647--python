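"""Simulated observers, rating model, cohorts, and derived statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caeqsim import hearing, quality_analysis as qa, simulated_listener as sl


class TestObserver:
    def test_percent_correct_at_threshold_is_70_7(self, on1_listener, rng):
        t = on1_listener.threshold("ripple", "LRL")
        hits = sum(
            sl.simulate_trial_response(on1_listener, "ripple", "LRL", t, rng)
            for _ in range(10_000)
        )
        assert hits / 10_000 == pytest.approx(0.707, abs=0.015)

    def test_guessing_and_ceiling_limits(self, on1_listener):
        p0 = on1_listener.prob_correct("ripple", "LRL", 1e-6)
        assert p0 == pytest.approx(1 / 3, abs=1e-3)
        p_hi = on1_listener.prob_correct("ripple", "LRL", 1e6)
        assert p_hi == pytest.approx(1.0, abs=1e-3)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(0.1, 50.0), st.floats(0.1, 50.0))
    def test_monotone_in_amount(self, on1_listener, a1, a2):
        lo, hi = sorted((a1, a2))
        assert on1_listener.prob_correct("ripple", "LRL", lo) <= (
            on1_listener.prob_correct("ripple", "LRL", hi) + 1e-12
        )

    def test_unknown_context_rejected(self, on1_listener, rng):
        with pytest.raises(ValueError):
            sl.simulate_trial_response(on1_listener, "ripple", "booth", 5.0, rng)


class TestRatingModel:
    def test_hidden_reference_full_score(self, on1_listener):
        item = qa.RatingItem("reference", "ref", 0.0)
        assert sl.expected_rating(on1_listener, item) == 100.0

    def test_at_threshold_score_near_100(self, on1_listener):
        t = on1_listener.threshold("ripple", "LRL")
        item = qa.RatingItem("ripple", "low", t)
        assert sl.expected_rating(on1_listener, item) >= 95.0

    def test_high_distortion_scores_below_low(self, small_cohort):
        for listener in small_cohort[:4]:
            lo = qa.RatingItem("ripple", "low", 12.0)
            hi = qa.RatingItem("ripple", "high", 18.0)
            assert sl.expected_rating(listener, hi) <= sl.expected_rating(listener, lo)

    def test_on3_masked_reference_downrated(self):
        on3 = sl.make_listener(0, "ON3", seed=1)
        ref0 = qa.RatingItem("reference", "ref", 0.0, masker_config="0M")
        ref2 = qa.RatingItem("reference", "ref", 0.0, masker_config="2M_sep")
        assert sl.expected_rating(on3, ref2) < sl.expected_rating(on3, ref0)

    def test_on1_maskers_partially_mask_distortions(self):
        on1 = sl.make_listener(0, "ON1", seed=1)
        hi0 = qa.RatingItem("ripple", "high", 18.0, masker_config="0M")
        hi2 = qa.RatingItem("ripple", "high", 18.0, masker_config="2M_sep")
        assert sl.expected_rating(on1, hi2) > sl.expected_rating(on1, hi0)

    def test_scores_clipped(self, rng):
        on1 = sl.make_listener(0, "ON1", seed=1)
        anchor = qa.RatingItem("anchor", "anchor", 0.0)
        for _ in range(50):
            s = sl.simulate_rating(on1, anchor, rng)
            assert 0 <= s <= 100


class TestCohort:
    def test_shape_and_determinism(self, small_cohort):
        assert len(small_cohort) == 24
        again = sl.generate_cohort(12, ("ON1", "ON3"), seed=5)
        assert [l.group for l in again] == [l.group for l in small_cohort]
        assert all(
            a.thresholds == b.thresholds for a, b in zip(again, small_cohort)
        )

    def test_asymmetry_invariant(self, small_cohort):
        for listener in small_cohort:
            assert (
                listener.audiogram.max_asymmetry()
                <= hearing.MAX_INTERAURAL_ASYMMETRY_DB
            )

    def test_masked_threshold_group_ordering(self):
        # ON3 mean masked thresholds exceed ON1 across independent cohorts
        for seed in range(20):
            cohort = sl.generate_cohort(12, ("ON1", "ON3"), seed=100 + seed)
            for kind in ("ripple", "saturation"):
                m1 = np.mean(
                    [l.threshold(kind, "LRL_2Msep") for l in cohort if l.group == "ON1"]
                )
                m3 = np.mean(
                    [l.threshold(kind, "LRL_2Msep") for l in cohort if l.group == "ON3"]
                )
                assert m3 > m1

    def test_comfort_offsets_valid(self, small_cohort):
        assert all(
            l.comfort_offset in hearing.COMFORT_OFFSETS for l in small_cohort
        )


class TestSddr:
    def test_identity_and_ratio(self):
        assert qa.sddr(9.0, 9.0) == 1.0
        assert qa.sddr(18.0, 9.0) == 2.0
        assert qa.sddr(4.0, 9.0) < 1.0  # below-threshold region

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            qa.sddr(1.0, 0.0)

    @settings(derandomize=True, deadline=None)
    @given(st.floats(0.01, 100), st.floats(0.01, 100), st.floats(0.1, 10))
    def test_scale_equivariance(self, amount, threshold, k):
        assert qa.sddr(k * amount, k * threshold) == pytest.approx(
            qa.sddr(amount, threshold), rel=1e-9
        )


class TestRatingSessions:
    def test_session_requires_reference_and_anchor(self, on1_listener):
        items = [qa.RatingItem("ripple", "low", 12.0)]
        with pytest.raises(ValueError):
            qa.run_rating_session(on1_listener, items, seed=0)

    def test_item_set_composition(self):
        items = qa.build_rating_items("speech", "LRL", "0M")
        levels = [i.level for i in items]
        assert levels.count("ref") == 1 and levels.count("anchor") == 1
        assert len(items) == 10  # ref + anchor + 4 kinds x 2 levels

    def test_noise_free_anchor_is_session_minimum_for_on1(self):
        on1 = sl.SimulatedListener(
            listener_id=0,
            group="ON1",
            audiogram=hearing.generate_audiogram("N1", 0),
            thresholds=sl.make_listener(0, "ON1", seed=1).thresholds,
            spreads=sl.make_listener(0, "ON1", seed=1).spreads,
            rating_params={**sl.RATING_PARAMS["ON1"], "noise_sd": 0.0},
        )
        session = qa.run_rating_session(
            on1, qa.build_rating_items("speech"), seed=0
        )
        anchor_idx = [i.level for i in session.items].index("anchor")
        assert session.scores[anchor_idx] == min(session.scores)

    def test_seed_reproducibility(self, on1_listener):
        items = qa.build_rating_items("speech")
        a = qa.run_rating_session(on1_listener, items, seed=9)
        b = qa.run_rating_session(on1_listener, items, seed=9)
        assert a.scores == b.scores


class TestTestRetest:
    def _session(self, scores):
        items = tuple(
            [qa.RatingItem("reference", "ref", 0.0), qa.RatingItem("anchor", "anchor", 0.0)]
            + [qa.RatingItem("ripple", "low", 12.0)] * (len(scores) - 2)
        )
        return qa.RatingSession(0, items, tuple(scores))

    def test_perfect_and_reversed(self):
        a = self._session([100, 20, 60, 80, 40])
        b = self._session([0, 80, 40, 20, 60])
        assert qa.test_retest_pcc(a, a) == pytest.approx(1.0)
        assert qa.test_retest_pcc(a, b) == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        a = self._session([50, 50, 50])
        b = self._session([10, 20, 30])
        with pytest.raises(ValueError, match="variance"):
            qa.test_retest_pcc(a, b)

    def test_independent_noise_sessions_uncorrelated(self, rng):
        # null distribution: |r| small for 100 unrelated item scores
        rs = []
        for _ in range(40):
            scores_a = rng.integers(0, 101, 100)
            scores_b = rng.integers(0, 101, 100)
            a = self._session(list(scores_a))
            b = self._session(list(scores_b))
            rs.append(qa.test_retest_pcc(a, b))
        assert np.quantile(np.abs(rs), 0.95) < 0.25


class TestPtaCorrelation:
    def test_affine_relation_r1(self):
        pta = np.linspace(10, 60, 24)
        th = 2.0 + 0.1 * pta
        r, p, stars = qa.threshold_pta_correlation(th, pta)
        assert r == pytest.approx(1.0)
        assert stars == "**"

    def test_synthetic_cohort_significant_masked_correlation(self):
        # construction + power check across independent cohorts
        sig = 0
        n_rep = 25
        for seed in range(n_rep):
            cohort = sl.generate_cohort(12, ("ON1", "ON3"), seed=300 + seed)
            pta = np.array([hearing.pta_better_ear(l.audiogram) for l in cohort])
            th = np.array([l.threshold("ripple", "LRL_2Msep") for l in cohort])
            r, p, _ = qa.threshold_pta_correlation(th, pta)
            sig += (r > 0) and (p < 0.05)
        assert sig == n_rep

    def test_permuted_pairing_null(self, rng):
        pta = np.linspace(10, 60, 24)
        th = 2.0 + 0.1 * pta
        rs = []
        for _ in range(200):
            rs.append(qa.threshold_pta_correlation(rng.permutation(th), pta)[0])
        assert abs(np.mean(rs)) < 0.1

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            qa.threshold_pta_correlation([1.0, 2.0], [3.0, 4.0])


def test_sddr_quality_anticorrelation(small_cohort):
    rho, table = qa.sddr_quality_relationship(small_cohort, seed=11)
    assert rho < -0.5
    assert len(table) == 16  # 8 kind x level cells, 2 groups
    # high-level ON1 SDDR exceeds 1 in every kind
    on1_high = table[(table.group == "ON1") & (table.level == "high")]
    assert (on1_high.mean_sddr > 1.0).all()
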