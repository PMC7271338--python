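"""Trait summaries, correlations, heterosis, knockout contrasts."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tetramosaic._util import round_half_up
from tetramosaic.sim import simulate_traits
from tetramosaic.traits import (
    TraitTable,
    corr_matrix,
    fertility_decrease_range,
    heterosis,
    knockout_contrasts,
    star_code,
    summarize,
)


def _table(rows):
    return TraitTable(pd.DataFrame(rows))


class TestSummarize:
    def test_equal_replicates_give_zero_se(self):
        t = _table([{"line": "A", "replicate": i, "ss": 50.0} for i in (1, 2, 3)])
        out = summarize(t)
        assert out.loc["A", ("ss", "mean")] == 50.0
        assert out.loc["A", ("ss", "se")] == 0.0

    def test_long_hand_three_value_sample(self):
        vals = [2.0, 4.0, 9.0]
        t = _table([{"line": "A", "replicate": i + 1, "x": v}
                    for i, v in enumerate(vals)])
        out = summarize(t)
        mean = sum(vals) / 3
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / 2)
        assert out.loc["A", ("x", "mean")] == pytest.approx(mean)
        assert out.loc["A", ("x", "se")] == pytest.approx(sd / math.sqrt(3))

    def test_single_replicate_rejected(self):
        t = _table([{"line": "A", "replicate": 1, "x": 1.0},
                    {"line": "B", "replicate": 1, "x": 2.0},
                    {"line": "B", "replicate": 2, "x": 3.0}])
        with pytest.raises(ValueError, match="A"):
            summarize(t)

    def test_non_finite_values_rejected(self):
        with pytest.raises(ValueError):
            _table([{"line": "A", "replicate": 1, "x": float("nan")},
                    {"line": "A", "replicate": 2, "x": 1.0}])


class TestCorrMatrix:
    def _lines(self, xs, ys):
        rows = []
        for i, (x, y) in enumerate(zip(xs, ys)):
            for rep in (1, 2):
                rows.append({"line": f"L{i}", "replicate": rep, "x": x, "y": y})
        return _table(rows)

    def test_self_correlation_is_one_and_negation_minus_one(self):
        xs = [1.0, 3.0, 7.0, 2.0, 9.0]
        t = self._lines(xs, [-v for v in xs])
        r = corr_matrix(t)
        assert r.loc["x", "x"] == pytest.approx(1.0)
        assert r.loc["x", "y"] == pytest.approx(-1.0)
        assert r.equals(r.T)

    def test_five_point_long_hand_pearson(self):
        xs = [1.0, 2.0, 3.0, 4.0, 5.0]
        ys = [2.0, 1.0, 4.0, 3.0, 7.0]
        t = self._lines(xs, ys)
        mx, my = np.mean(xs), np.mean(ys)
        num = sum((a - mx) * (b - my) for a, b in zip(xs, ys))
        den = math.sqrt(sum((a - mx) ** 2 for a in xs)
                        * sum((b - my) ** 2 for b in ys))
        assert corr_matrix(t).loc["x", "y"] == pytest.approx(num / den)

    def test_bounds_on_random_tables(self):
        rng = np.random.default_rng(0)
        rows = [{"line": f"L{i}", "replicate": r, "a": rng.normal(),
                 "b": rng.normal(), "c": rng.normal()}
                for i in range(10) for r in (1, 2)]
        r = corr_matrix(_table(rows))
        assert ((r.to_numpy() >= -1 - 1e-12) & (r.to_numpy() <= 1 + 1e-12)).all()
        assert np.allclose(np.diag(r), 1.0)

    def test_affine_rescaling_invariance(self):
        xs = [1.0, 4.0, 2.0, 8.0, 5.0]
        ys = [3.0, 1.0, 4.0, 9.0, 2.0]
        r1 = corr_matrix(self._lines(xs, ys)).loc["x", "y"]
        r2 = corr_matrix(self._lines([10 + 3 * v for v in xs], ys)).loc["x", "y"]
        assert r1 == pytest.approx(r2)

    def test_zero_variance_flagged_not_silently_zero(self):
        t = self._lines([1.0, 1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.warns(UserWarning, match="zero-variance"):
            r = corr_matrix(t)
        assert math.isnan(r.loc["x", "y"])

    def test_fewer_than_three_lines_rejected(self):
        with pytest.raises(ValueError):
            corr_matrix(self._lines([1.0, 2.0], [2.0, 1.0]))


class TestHeterosis:
    def test_f1_at_mid_parent_gives_zero_mph(self):
        assert heterosis(10, 20, 15)[0] == 0.0

    def test_f1_at_better_parent_gives_zero_oph(self):
        assert heterosis(10, 20, 20)[1] == 0.0

    def test_direct_formula_evaluation(self):
        assert heterosis(10, 20, 18) == (20.00, -10.00)

    def test_non_positive_parent_rejected(self):
        with pytest.raises(ValueError):
            heterosis(0, 20, 10)

    @given(st.floats(1, 1e3), st.floats(1, 1e3), st.floats(0, 1e3))
    def test_oph_never_exceeds_mph(self, p1, p2, f1):
        mph, oph = heterosis(p1, p2, f1)
        assert oph <= mph + 1e-9  # better parent >= mid parent


class TestKnockoutContrasts:
    def _wt_mut(self, wt_vals, mut_vals):
        rows = [{"line": "WT", "replicate": i + 1, "ss": v}
                for i, v in enumerate(wt_vals)]
        rows += [{"line": "M", "replicate": i + 1, "ss": v}
                 for i, v in enumerate(mut_vals)]
        return _table(rows)

    def test_identical_groups_give_zero_and_no_star(self):
        t = self._wt_mut([50.0, 51.0, 52.0], [50.0, 51.0, 52.0])
        (res,), avg = knockout_contrasts(t, "WT", ["M"])
        assert res.difference == 0.0
        assert res.stars == ""
        assert avg["ss"] == 0.0

    def test_antisymmetry(self):
        t = self._wt_mut([50.0, 55.0, 60.0], [40.0, 42.0, 44.0])
        (fwd,), _ = knockout_contrasts(t, "WT", ["M"])
        (rev,), _ = knockout_contrasts(t, "M", ["WT"])
        assert fwd.difference == -rev.difference
        assert fwd.p_value == pytest.approx(rev.p_value)

    def test_clear_separation_earns_two_stars(self):
        t = self._wt_mut([80.0, 80.5, 81.0, 79.5], [35.0, 36.0, 35.5, 34.5])
        (res,), _ = knockout_contrasts(t, "WT", ["M"])
        assert res.p_value <= 0.01 and res.stars == "**"

    def test_missing_line_rejected(self):
        t = self._wt_mut([1.0, 2.0], [3.0, 4.0])
        with pytest.raises(KeyError):
            knockout_contrasts(t, "WT", ["nope"])

    def test_star_boundaries(self):
        assert star_code(0.01) == "**"
        assert star_code(0.011) == "*"
        assert star_code(0.05) == "*"
        assert star_code(0.051) == ""


class TestFertilityDecreaseRange:
    def test_single_mutant_collapses(self):
        assert fertility_decrease_range(90.0, [70.0]) == (20.0, 20.0, 20.0)

    def test_mutants_equal_wt(self):
        assert fertility_decrease_range(90.0, [90.0, 90.0]) == (0.0, 0.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fertility_decrease_range(90.0, [])


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (96.0784313, 96.08), (25.6277, 25.63), (4.8711, 4.87),
        (2.005, 2.01), (2.675, 2.68), (-1.005, -1.01),
    ])
    def test_half_up_to_two_decimals(self, x, expected):
        assert round_half_up(x, 2) == expected


class TestSimulatedTables:
    def test_sd_zero_replicates_equal_mean(self):
        t = simulate_traits([("A", {"x": 5.5}, {"x": 0.0}, 4)], seed=1)
        assert (t.replicates("A", "x") == 5.5).all()

    def test_equal_mean_groups_contrast_near_zero(self):
        specs = [("A", {"x": 50.0}, {"x": 2.0}, 400),
                 ("B", {"x": 50.0}, {"x": 2.0}, 400)]
        t = simulate_traits(specs, seed=3)
        (res,), _ = knockout_contrasts(t, "A", ["B"])
        assert abs(res.difference) < 0.5
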