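"""Feature-matrix assembly, quality filtering, Spearman screening, trend groups."""

import numpy as np
import pandas as pd
import pytest

import oracles
from oxiscale import DomainError
from oxiscale.screening import (
    GROUP_A,
    GROUP_B,
    GROUP_C,
    GROUP_D,
    UNCLASSIFIED,
    IntegrityError,
    build_feature_matrix,
    classify_trends,
    column_quality,
    filter_features,
    spearman_screen,
    summarize_profiles,
)


def labels_frame(ids, ahis):
    return pd.DataFrame({"subject_id": ids, "ahi": ahis})


class TestBuildMatrix:
    def test_shape_and_labels(self):
        records = [
            (f"s{i}", tau, {"f1": 1.0, "f2": 2.0, "f3": 3.0, "f4": 4.0})
            for i in range(3)
            for tau in (1, 60)
        ]
        m = build_feature_matrix(records)
        assert m.shape == (3, 8)
        assert "f1@1s" in m.columns and "f4@60s" in m.columns

    def test_missing_scale_leaves_nan(self):
        records = [("a", 1, {"f": 1.0}), ("a", 600, {"f": 2.0}), ("b", 1, {"f": 3.0})]
        m = build_feature_matrix(records)
        assert np.isnan(m.loc["b", "f@600s"])
        assert m.loc["b", "f@1s"] == 3.0

    def test_duplicate_entry_rejected(self):
        records = [("a", 1, {"f": 1.0}), ("a", 1, {"f": 2.0})]
        with pytest.raises(IntegrityError):
            build_feature_matrix(records)


class TestFilter:
    @pytest.fixture
    def fixture_matrix(self):
        """10 subjects x 6 columns with exact missing/zero fractions."""
        n = 10
        cols = {
            "ok@1s": np.arange(1.0, n + 1),
            "miss30@1s": [np.nan] * 3 + list(range(7)),        # 30 % missing
            "miss20@1s": [np.nan] * 2 + list(range(1, 9)),      # exactly 20 %
            "zero50@1s": [0.0] * 5 + list(range(1, 6)),         # 50 % zeros
            "zero40@1s": [0.0] * 4 + list(range(1, 7)),         # exactly 40 %
            "both@1s": [np.nan] * 3 + [0.0] * 5 + [1.0, 2.0],   # 30 % + 50 %
        }
        return pd.DataFrame(cols, index=[f"s{i}" for i in range(n)])

    def test_strict_inequality_boundaries(self, fixture_matrix):
        kept = filter_features(fixture_matrix)
        assert sorted(kept.columns) == ["miss20@1s", "ok@1s", "zero40@1s"]

    def test_idempotent(self, fixture_matrix):
        once = filter_features(fixture_matrix)
        pd.testing.assert_frame_equal(filter_features(once), once)

    def test_quality_metadata_recomputable(self, fixture_matrix):
        q = column_quality(fixture_matrix)
        assert q.loc["miss30@1s", "missing_frac"] == pytest.approx(0.3)
        assert q.loc["zero50@1s", "zero_frac"] == pytest.approx(0.5)

    def test_all_dropped_is_error(self):
        m = pd.DataFrame({"a@1s": [np.nan] * 8 + [1.0, 2.0]})
        with pytest.raises(DomainError):
            filter_features(m)


class TestSpearman:
    def test_perfect_monotone(self):
        m = pd.DataFrame({"f@1s": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
        lab = labels_frame(list("abcde"), [2.0, 4, 6, 8, 100])
        rep = spearman_screen(m, lab)
        assert rep.rho.item() == pytest.approx(1.0)

    def test_perfect_inverse(self):
        m = pd.DataFrame({"f@1s": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
        lab = labels_frame(list("abcde"), [5.0, 4, 3, 2, 1])
        assert spearman_screen(m, lab).rho.item() == pytest.approx(-1.0)

    def test_five_pair_toy_against_rank_formula(self):
        """Ranks 1..5 vs 2,1,3,5,4: the closed-form rank correlation."""
        x = [1.0, 2, 3, 4, 5]
        y = [2.0, 1, 3, 5, 4]
        want = oracles.spearman_rho(x, y)
        d2 = sum((a - b) ** 2 for a, b in zip(x, y))
        assert want == pytest.approx(1 - 6 * d2 / (5 * 24))  # = 0.8
        m = pd.DataFrame({"f@1s": x}, index=list("abcde"))
        rep = spearman_screen(m, labels_frame(list("abcde"), y))
        assert rep.rho.item() == pytest.approx(want, abs=1e-12)

    def test_pairwise_complete_and_min_pairs(self):
        m = pd.DataFrame(
            {"f@1s": [1.0, 2, np.nan, 4, 5], "g@1s": [np.nan, np.nan, np.nan, 1, 2]},
            index=list("abcde"),
        )
        rep = spearman_screen(m, labels_frame(list("abcde"), [1.0, 2, 3, 4, 5]))
        f = rep[rep.feature == "f"].iloc[0]
        assert f.n_used == 4 and not np.isnan(f.rho)
        g = rep[rep.feature == "g"].iloc[0]
        assert g.n_used == 2 and np.isnan(g.rho)

    def test_monotone_transform_invariance(self, rng):
        x = rng.uniform(0, 1, 40)
        y = rng.uniform(0, 60, 40)
        ids = [f"s{i}" for i in range(40)]
        m1 = pd.DataFrame({"f@1s": x}, index=ids)
        m2 = pd.DataFrame({"f@1s": np.exp(3 * x)}, index=ids)
        lab1 = labels_frame(ids, y)
        lab2 = labels_frame(ids, np.argsort(np.argsort(y)).astype(float))
        r11 = spearman_screen(m1, lab1).rho.item()
        assert spearman_screen(m2, lab1).rho.item() == pytest.approx(r11, abs=1e-12)
        assert spearman_screen(m1, lab2).rho.item() == pytest.approx(r11, abs=1e-12)


def report_from_profile(feature, profile):
    return pd.DataFrame(
        [{"feature": feature, "tau": t, "rho": r, "n_used": 100}
         for t, r in profile.items()]
    )


class TestTrendGroups:
    TAUS = (1, 2, 3, 5, 10, 20, 30, 60)

    def _classify(self, profile):
        rep = report_from_profile("f", profile)
        return classify_trends(rep).trend_group.item()

    def test_constant_high_is_group_d(self):
        assert self._classify({t: 0.8 for t in self.TAUS}) == GROUP_D

    def test_decaying_is_group_a(self):
        prof = {1: 0.75, 2: 0.7, 3: 0.6, 5: 0.5, 10: 0.4, 20: 0.3, 30: 0.2, 60: 0.1}
        assert self._classify(prof) == GROUP_A

    def test_coarser_peak_is_group_b(self):
        """Weak natively, strong at a coarser scale (the mean-crossing shape)."""
        prof = {1: -0.01, 2: 0.05, 3: 0.1, 5: 0.2, 10: 0.45, 20: 0.61, 30: 0.5, 60: 0.45}
        assert self._classify(prof) == GROUP_B

    def test_polarity_shift_is_group_c(self):
        prof = {1: 0.4, 2: 0.3, 3: 0.2, 5: 0.05, 10: -0.2, 20: -0.5, 30: -0.6, 60: -0.5}
        assert self._classify(prof) == GROUP_C

    def test_precedence_d_over_c(self):
        """A profile strong everywhere below 60 s is D even if it flips above."""
        prof = {**{t: 0.6 for t in self.TAUS if t <= 60}, 120: -0.5, 600: -0.3}
        assert self._classify(prof) == GROUP_D

    def test_missing_required_scale_unclassified(self):
        prof = {1: 0.8, 2: 0.7, 3: 0.6, 5: 0.5, 10: 0.4}  # no 30/60
        assert self._classify(prof) == UNCLASSIFIED

    def test_summary_shape(self):
        rep = report_from_profile("f", {1: 0.5, 30: -0.8, 60: 0.2})
        s = summarize_profiles(rep)
        row = s.iloc[0]
        assert row.rho_max == 0.5 and row.rho_min == -0.8
        assert row.tau_best == 30 and row.rho_best == -0.8
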