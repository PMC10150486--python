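import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize

from snvtrack.panel import SiteAlleleCounts, SiteKey
from snvtrack.scoring import (
    FilterConfig,
    binomial_log_likelihood,
    compute_signatures,
    filter_sites,
    fit_excluded_mixture,
    score_panel,
    score_site,
    select_signature_snvs,
)

from conftest import make_panel


def site(sink_ref, sink_alt, source_counts):
    return SiteAlleleCounts(
        key=SiteKey("sp", "c1", 100, "A", "G"),
        sink_ref=sink_ref,
        sink_alt=sink_alt,
        source_ref=np.array([c[0] for c in source_counts]),
        source_alt=np.array([c[1] for c in source_counts]),
    )


class TestFilterSites:
    def test_sink_below_min_depth_dropped(self):
        panel = make_panel([(9, 0)], [[(20, 0)]])
        filtered, _ = filter_sites(panel, FilterConfig(min_site_depth=10))
        assert filtered.n_sites == 0

    def test_biallelic_single_read_allele_dropped(self):
        # sink 9 ref / 1 alt has depth 10 but only one alt read
        panel = make_panel([(9, 1)], [[(20, 0)]])
        filtered, _ = filter_sites(panel, FilterConfig(min_site_depth=10))
        assert filtered.n_sites == 0

    def test_low_coverage_mode_retains_depth_five(self):
        panel = make_panel([(5, 0)], [[(5, 0)]])
        filtered, mask = filter_sites(panel, FilterConfig(min_site_depth=5))
        assert filtered.n_sites == 1 and mask.tolist() == [[True]]

    def test_requires_at_least_one_covered_source(self):
        panel = make_panel([(20, 0)], [[(4, 0)]])
        filtered, _ = filter_sites(panel, FilterConfig(min_site_depth=10))
        assert filtered.n_sites == 0

    def test_mask_records_passing_sources(self):
        panel = make_panel([(20, 0)], [[(4, 0), (15, 0)]])
        _, mask = filter_sites(panel, FilterConfig(min_site_depth=10))
        assert mask.tolist() == [[False, True]]


class TestBinomialLogLikelihood:
    @pytest.mark.parametrize(
        "theta, n, m, expected",
        [
            (0.5, 3, 1, 4 * math.log(0.5)),
            (1.0, 5, 0, 5 * math.log(1 - 1e-6)),  # clipped certainty limit
            (0.25, 1, 3, math.log(0.25) + 3 * math.log(0.75)),
        ],
    )
    def test_worked_examples(self, theta, n, m, expected):
        assert binomial_log_likelihood(theta, n, m) == pytest.approx(expected, abs=1e-9)

    def test_no_sink_reads_is_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            binomial_log_likelihood(0.5, 0, 0)

    @given(
        theta=st.floats(-0.5, 1.5),
        n=st.integers(0, 10_000),
        m=st.integers(0, 10_000),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_finite_after_clipping(self, theta, n, m):
        if n == 0 and m == 0:
            return
        assert math.isfinite(binomial_log_likelihood(theta, n, m))


class TestFitExcludedMixture:
    def test_single_nonfocal_source_forces_alpha_one(self):
        s = site(3, 7, [(5, 5), (3, 7)])
        fit = fit_excluded_mixture(s, focal_source=0, passing_mask=[True, True])
        np.testing.assert_allclose(fit.alpha, [1.0])
        assert fit.theta_hat == pytest.approx(0.3)

    def test_interior_optimum_is_sink_mle(self):
        # non-focal frequencies 0 and 1 (clipped); sink 7/3 -> theta 0.7
        s = site(7, 3, [(5, 5), (0, 10), (10, 0)])
        fit = fit_excluded_mixture(s, focal_source=0, passing_mask=[True] * 3)
        assert fit.theta_hat == pytest.approx(0.7, abs=1e-5)
        np.testing.assert_allclose(fit.alpha, [0.3, 0.7], atol=1e-5)

    def test_boundary_solution(self):
        # hull [0.2, 0.4] cannot reach the MLE 0.9 -> boundary alpha (0, 1)
        s = site(9, 1, [(5, 5), (2, 8), (4, 6)])
        fit = fit_excluded_mixture(s, focal_source=0, passing_mask=[True] * 3)
        assert fit.theta_hat == pytest.approx(0.4)
        np.testing.assert_allclose(fit.alpha, [0.0, 1.0], atol=1e-9)

    def test_no_nonfocal_source_gives_zero_loglik(self):
        s = site(5, 5, [(10, 0), (1, 0)])
        fit = fit_excluded_mixture(s, focal_source=0, passing_mask=[True, False])
        assert fit.loglik == 0.0

    def test_matches_slsqp_on_random_sites(self, rng):
        """Dual route: the closed form equals a constrained SLSQP optimiser."""
        for _ in range(50):
            J = int(rng.integers(2, 5))
            depth = rng.integers(10, 80, size=J)
            p_true = rng.random(J)
            ref = rng.binomial(depth, p_true)
            s = site(
                int(rng.integers(1, 40)),
                int(rng.integers(1, 40)),
                list(zip(ref, depth - ref)),
            )
            mask = np.ones(J, bool)
            fit = fit_excluded_mixture(s, 0, mask)
            p = np.clip(s.source_ref[1:] / s.source_depth[1:], 1e-6, 1 - 1e-6)

            def neg_ll(a):
                theta = float(np.clip(a @ p, 1e-6, 1 - 1e-6))
                return -(s.sink_ref * np.log(theta) + s.sink_alt * np.log(1 - theta))

            k = p.size
            res = minimize(
                neg_ll,
                np.full(k, 1.0 / k),
                method="SLSQP",
                bounds=[(0.0, 1.0)] * k,
                constraints={"type": "eq", "fun": lambda a: a.sum() - 1},
            )
            assert fit.loglik >= -res.fun - 1e-6


class TestScoreSite:
    def test_identical_sources_score_zero(self):
        s = site(6, 4, [(6, 4), (12, 8), (60, 40)])
        out = score_site(s, np.ones(3, bool))
        np.testing.assert_allclose(out.per_source_llr, 0.0, atol=1e-9)
        assert out.score == pytest.approx(0.0, abs=1e-9)

    def test_single_passing_source_uses_l1_alone(self):
        # l2 = 0, so score = l1 = 9 ln 0.9 + ln 0.1
        s = site(9, 1, [(9, 1), (1, 0)])
        out = score_site(s, np.array([True, False]))
        expected = 9 * math.log(0.9) + math.log(0.1)
        assert out.score == pytest.approx(expected, abs=1e-9)

    def test_distinctive_source_wins(self):
        s = site(19, 1, [(19, 1), (1, 19), (1, 19)])
        out = score_site(s, np.ones(3, bool))
        assert out.best_source == 0 and out.score > 0

    def test_sink_unique_allele_flagged(self):
        s = site(8, 2, [(10, 0), (12, 0)])
        assert score_site(s, np.ones(2, bool)).sink_unique

    def test_score_panel_matches_score_site(self, rng):
        S, J = 60, 4
        depth = rng.integers(10, 60, size=(S, J))
        ref = rng.binomial(depth, rng.random((S, J)))
        sink_depth = rng.integers(10, 60, size=S)
        sink_ref = rng.binomial(sink_depth, rng.random(S))
        panel = make_panel(
            np.column_stack([sink_ref, sink_depth - sink_ref]),
            np.stack([ref, depth - ref], axis=-1),
        )
        filtered, mask = filter_sites(panel, FilterConfig())
        table = score_panel(filtered, mask)
        for i in range(filtered.n_sites):
            ref_score = score_site(filtered.site(i), mask[i])
            assert table.loc[i, "score"] == pytest.approx(ref_score.score, abs=1e-9)
            assert table.loc[i, "best_source"] == ref_score.best_source
            assert bool(table.loc[i, "sink_unique"]) == ref_score.sink_unique


def scores_frame(scores, positions=None, sink_unique=None, species="sp1"):
    n = len(scores)
    return pd.DataFrame(
        {
            "species_id": [species] * n,
            "contig_id": [f"{species}_c1"] * n,
            "position": positions if positions is not None else range(1, n + 1),
            "ref_allele": ["A"] * n,
            "alt_allele": ["G"] * n,
            "score": scores,
            "best_source": [0] * n,
            "sink_unique": sink_unique if sink_unique is not None else [False] * n,
        }
    )


class TestSelectSignatures:
    def test_equal_scores_select_nothing(self):
        out = select_signature_snvs(scores_frame([3.0] * 10))
        assert len(out) == 0

    def test_outlier_selected_against_window_stats(self):
        # twenty zeros and one ten: mean 10/21, population SD ~2.132
        scores = [0.0] * 20 + [10.0]
        out = select_signature_snvs(scores_frame(scores))
        sd = float(np.std(scores))
        assert sd == pytest.approx(2.1296, abs=1e-4)
        assert len(out.selected) == 1 and out.selected[0].position == 21

    def test_rescue_selects_sink_unique_regardless_of_score(self):
        out = select_signature_snvs(
            scores_frame([0.0, 5.0, 0.0], sink_unique=[True, False, False])
        )
        assert any(k.position == 1 for k in out.selected)
        assert out.rescue_count == 1

    def test_rescue_can_be_disabled(self):
        out = select_signature_snvs(
            scores_frame([0.0, 5.0, 0.0], sink_unique=[True, False, False]),
            FilterConfig(rescue_sink_unique=False),
        )
        assert out.rescue_count == 0 and len(out) == 0

    def test_single_site_window_selects_nothing(self):
        out = select_signature_snvs(scores_frame([99.0]))
        assert len(out) == 0

    def test_windows_are_independent(self):
        # same scores, two windows 200 kb apart: selection happens per window
        scores = [0.0] * 10 + [5.0] + [0.0] * 10 + [5.0]
        positions = list(range(1, 12)) + [200_001 + i for i in range(11)]
        out = select_signature_snvs(scores_frame(scores, positions=positions))
        assert sorted(k.position for k in out.selected) == [11, 200_011]
        assert len(out.per_window_stats) == 2

    def test_global_threshold_pools_windows(self):
        scores = [0.0] * 10 + [5.0] + [0.0] * 10 + [5.0]
        positions = list(range(1, 12)) + [200_001 + i for i in range(11)]
        out = select_signature_snvs(
            scores_frame(scores, positions=positions),
            FilterConfig(global_threshold=True),
        )
        assert sorted(k.position for k in out.selected) == [11, 200_011]

    @given(shift=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_selection_invariant_under_score_shift(self, shift):
        scores = [0.0, 1.0, 2.0, 0.5, 9.0, 1.5, 0.2, 0.1, 0.3, 0.4]
        base = select_signature_snvs(scores_frame(scores))
        shifted = select_signature_snvs(scores_frame([s + shift for s in scores]))
        assert [k.position for k in base.selected] == [
            k.position for k in shifted.selected
        ]


def test_pipeline_deterministic(rng):
    depth = rng.integers(10, 60, size=(200, 3))
    ref = rng.binomial(depth, rng.random((200, 3)))
    sink_depth = rng.integers(10, 60, size=200)
    sink_ref = rng.binomial(sink_depth, rng.random(200))
    panel = make_panel(
        np.column_stack([sink_ref, sink_depth - sink_ref]),
        np.stack([ref, depth - ref], axis=-1),
    )
    _, sig_a, scores_a = compute_signatures(panel)
    _, sig_b, scores_b = compute_signatures(panel)
    pd.testing.assert_frame_equal(scores_a, scores_b)
    assert [k.position for k in sig_a.selected] == [k.position for k in sig_b.selected]
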