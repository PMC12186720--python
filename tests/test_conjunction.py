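"""Conjunction classifier and the optimal-additive single-feature model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.special import erf

import graspmvpa as g
from graspmvpa.pipeline import features_for_subject


# ---------------------------------------------------------------------------
# single-feature mapping


class TestSingleFeatureMapping:
    @pytest.mark.parametrize("p, expected", [(0.7, 0.6), (0.5, 0.5),
                                             (1.0, 0.75), (0.0, 0.25)])
    def test_worked_values(self, p, expected):
        assert g.single_feature_test_performance(p) == \
            pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            g.single_feature_test_performance(1.2)
        with pytest.raises(ValueError):
            g.single_feature_test_performance(-0.1)

    @given(st.floats(0.0, 1.0))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_range_and_fixed_point(self, p):
        out = g.single_feature_test_performance(p)
        assert 0.25 <= out <= 0.75


# ---------------------------------------------------------------------------
# optimal additive combination


def _cum_gauss(sigma, mu, x):
    return 0.5 * (1.0 + erf((x - mu) / (sigma * np.sqrt(2.0))))


def _numeric_oracle(p1, p2, mu, x):
    """Independent route: root-find each sigma, combine, re-evaluate."""
    s1 = brentq(lambda s: _cum_gauss(s, mu, x) - p1, 1e-9, 1e9)
    s2 = brentq(lambda s: _cum_gauss(s, mu, x) - p2, 1e-9, 1e9)
    s12 = np.sqrt(s1 ** 2 * s2 ** 2 / (s1 ** 2 + s2 ** 2))
    return _cum_gauss(s12, mu, x)


class TestOptimalAdditive:
    def test_worked_value(self):
        # frozen from the numeric oracle at (mu, x) = (0, 1) and (3, 7)
        assert g.optimal_additive(0.6, 0.6) == pytest.approx(0.639936, abs=1e-5)

    def test_exception_rule_at_or_below_chance(self):
        assert g.optimal_additive(0.6, 0.5) == 0.6
        assert g.optimal_additive(0.5, 0.5) == 0.5
        assert g.optimal_additive(0.3, 0.2) == 0.5
        for p in (0.55, 0.8, 0.99):
            assert g.optimal_additive(p, 0.49) == p

    def test_mu_x_invariance(self):
        for p1, p2 in [(0.6, 0.6), (0.55, 0.72), (0.9, 0.51), (0.7, 0.65)]:
            a = g.optimal_additive(p1, p2, mu=0.0, x=1.0)
            b = g.optimal_additive(p1, p2, mu=3.0, x=7.0)
            assert abs(a - b) < 1e-10

    @given(st.floats(0.505, 0.995), st.floats(0.505, 0.995))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_symmetry_and_dominance(self, p1, p2):
        p12 = g.optimal_additive(p1, p2)
        assert p12 == pytest.approx(g.optimal_additive(p2, p1), abs=1e-12)
        assert p12 >= max(p1, p2) - 1e-12

    def test_equality_only_when_one_at_chance(self):
        assert g.optimal_additive(0.7, 0.5) == 0.7
        assert g.optimal_additive(0.7, 0.51) > 0.7

    def test_closed_form_matches_numeric_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(100):
            p1, p2 = rng.uniform(0.501, 0.999, size=2)
            want = _numeric_oracle(p1, p2, 0.0, 1.0)
            assert g.optimal_additive_closed_form(p1, p2) == \
                pytest.approx(want, abs=1e-9)
            assert g.optimal_additive(p1, p2) == pytest.approx(want, abs=1e-9)

    def test_saturation_warns(self):
        with pytest.warns(UserWarning, match="saturated"):
            assert g.optimal_additive(1.0, 0.8) == 1.0

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            g.optimal_additive(1.2, 0.6)
        with pytest.raises(ValueError):
            g.optimal_additive(0.6, 0.6, mu=2.0, x=1.0)

    def test_additive_baseline_elementwise(self):
        a = np.array([0.7, 0.5, 0.9])
        b = np.array([0.7, 0.6, 0.4])
        out = g.additive_baseline(a, b)
        p1 = g.single_feature_test_performance(a)
        p2 = g.single_feature_test_performance(b)
        assert out[0] == pytest.approx(
            g.optimal_additive_closed_form(p1[0], p2[0]))
        assert out[1] == max(p1[1], p2[1], 0.5)   # first input maps to chance
        assert out[2] == p1[2]                    # second below chance


# ---------------------------------------------------------------------------
# conjunction CV scheme and decoding


class TestConjunctionScheme:
    def test_grasping_fold_shape(self, default_pseudo_labels):
        s = g.make_conjunction_scheme(default_pseudo_labels, "grasping",
                                      ("pillow", "red"))
        assert all(len(tr) == 33 and len(te) == 2 for tr, te in s.folds)
        assert len(s.folds) == 24
        assert s.class_weight == {0: 1.0, 1: 2.0}
        for _, te in s.folds:
            assert {s.y[i] for i in te} == {0, 1}

    def test_knuckling_fold_shape(self, default_pseudo_labels):
        s = g.make_conjunction_scheme(default_pseudo_labels, "knuckling",
                                      ("flower", "blue"))
        assert all(len(tr) == 15 and len(te) == 2 for tr, te in s.folds)
        assert len(s.folds) == 12

    def test_share_neither_object_excluded(self, default_pseudo_labels):
        s = g.make_conjunction_scheme(default_pseudo_labels, "grasping",
                                      ("pillow", "red"))
        lab = default_pseudo_labels
        used = {i for tr, te in s.folds for i in np.concatenate([tr, te])}
        for i in used:
            row = lab.iloc[i]
            assert (row["shape"], row["color"]) != ("flower", "blue")

    def test_missing_cell_rejected(self, default_pseudo_labels):
        lab = default_pseudo_labels
        drop = ~((lab["shape"] == "pillow") & (lab["color"] == "red"))
        with pytest.raises(ValueError, match="conjunction cell"):
            g.make_conjunction_scheme(lab.loc[drop].reset_index(drop=True),
                                      "grasping", ("pillow", "red"))


@pytest.fixture(scope="module")
def montage():
    return g.standard_montage(16)


class TestConjunctionDecoding:
    def _features(self, effect_feature, seed, montage, amplitude=5.0):
        d = g.build_design(1, seed=seed, blocks_per_action=2,
                           reps_per_object=2, sampling_rate=128.0,
                           epoch_window=(-100.0, 400.0), n_electrodes=16)
        topo = g.make_topography(montage, 0)
        eff = g.GroundTruthEffect(effect_feature, "sustained", [(100, 300)],
                                  topo, amplitude=amplitude)
        ep = g.simulate_epochs(d, [eff], g.NoiseModel(invalid_fraction=0.0),
                               seed=seed + 1, montage=montage)[0]
        return features_for_subject(ep)

    def test_single_feature_signal_stays_below_additive_model(self, montage):
        # with only a shape code present, conjunction accuracy should track
        # the Eq.-style mapped shape accuracy, not exceed the additive model
        ft = self._features("shape", 60, montage)
        window = (ft.window_centers_ms >= 120) & (ft.window_centers_ms <= 280)
        shape_acc = g.decode_timeresolved(
            ft, g.make_cv_scheme(ft.labels, "shape", "grasping")
        ).accuracy[window].mean()
        color_acc = g.decode_timeresolved(
            ft, g.make_cv_scheme(ft.labels, "color", "grasping")
        ).accuracy[window].mean()
        conj = g.conjunction_decode(ft, "grasping").accuracy[window].mean()
        mapped = g.single_feature_test_performance(shape_acc)
        additive = g.optimal_additive(
            mapped, g.single_feature_test_performance(color_acc))
        # the classifier picks up the shape signal (above chance) but a
        # single-feature code can never push it past the additive ceiling;
        # the idealized mapped value is an upper bound at finite samples
        assert 0.5 < conj <= additive + 0.02
        assert conj <= mapped + 0.02

    def test_xor_code_beats_additive_model(self, montage):
        # a pattern present only for one exact shape-color combination is
        # invisible to single-feature classifiers but not to the
        # conjunction classifier
        ft = self._features("conjunction", 70, montage)
        window = (ft.window_centers_ms >= 120) & (ft.window_centers_ms <= 280)
        shape_acc = g.decode_timeresolved(
            ft, g.make_cv_scheme(ft.labels, "shape", "grasping")
        ).accuracy[window].mean()
        color_acc = g.decode_timeresolved(
            ft, g.make_cv_scheme(ft.labels, "color", "grasping")
        ).accuracy[window].mean()
        assert abs(shape_acc - 0.5) < 0.15
        assert abs(color_acc - 0.5) < 0.15
        conj = g.conjunction_decode(ft, "grasping").accuracy[window].mean()
        additive = g.optimal_additive(
            g.single_feature_test_performance(shape_acc),
            g.single_feature_test_performance(color_acc))
        assert conj > additive + 0.1
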