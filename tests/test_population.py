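"""Average time courses, cosine distances, dose–response, sTNFRII effect."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import cosine as scipy_cosine

from nfdyn.features import Trace
from nfdyn.population import (
    ConditionSummary,
    average_time_course,
    cosine_distance,
    fraction_active,
    receptor_effect,
    similarity_matrix,
)
from nfdyn.response_model import sample_population


def _trace(time, values, track_id=0):
    v = np.asarray(values, dtype=float)
    return Trace(
        track_id=track_id,
        time=np.asarray(time, dtype=float),
        values=v,
        valid=np.ones_like(v, dtype=bool),
    )


def _summary(prep, conc, stnfr, course, grid=None, n_active=10):
    grid = np.arange(0.0, 100.0, 5.0) if grid is None else grid
    return ConditionSummary(
        preparation=prep,
        concentration=conc,
        stnfr=stnfr,
        n_total=12,
        n_active=n_active if course is not None else 0,
        grid=grid,
        average_course=course,
    )


class TestAverageTimeCourse:
    grid = np.arange(0.0, 30.0, 5.0)

    def test_identical_traces_average_to_input(self):
        tr = _trace(self.grid, [1, 2, 3, 2, 1, 1])
        avg = average_time_course([tr, tr, tr], self.grid)
        np.testing.assert_allclose(avg, tr.values)

    def test_pointwise_mean_of_two(self):
        a = _trace(self.grid, [1, 2, 3, 2, 1, 1])
        b = _trace(self.grid, [3, 2, 1, 2, 3, 3])
        np.testing.assert_allclose(average_time_course([a, b], self.grid), 2.0)

    def test_resampling_matches_hand_interpolation(self):
        """6-min acquisition resampled to a 5-min grid, 3-point fixture."""
        tr = _trace([0.0, 6.0, 12.0], [1.0, 4.0, 2.0])
        avg = average_time_course([tr], np.array([0.0, 5.0, 10.0]))
        np.testing.assert_allclose(avg, [1.0, 1.0 + 5 / 6 * 3.0, 4.0 - 4 / 6 * 2.0])

    def test_edge_values_held_beyond_valid_range(self):
        tr = _trace([10.0, 20.0], [2.0, 4.0])
        avg = average_time_course([tr], np.array([0.0, 10.0, 20.0, 30.0]))
        np.testing.assert_allclose(avg, [2.0, 2.0, 4.0, 4.0])

    def test_empty_set_returns_marker(self):
        assert average_time_course([], self.grid) is None

    def test_permutation_invariance(self):
        rng = np.random.default_rng(0)
        traces = [
            _trace(self.grid, rng.uniform(0.5, 3.0, self.grid.size), track_id=i)
            for i in range(5)
        ]
        a = average_time_course(traces, self.grid)
        b = average_time_course(traces[::-1], self.grid)
        np.testing.assert_allclose(a, b)


class TestCosineDistance:
    def test_identical_profiles_zero(self):
        assert cosine_distance([1, 2, 3], [1, 2, 3]) == pytest.approx(0.0, abs=1e-12)

    def test_orthogonal_profiles_one(self):
        assert cosine_distance([1, 0], [0, 1]) == pytest.approx(1.0)

    def test_collinear_profiles_zero(self):
        assert cosine_distance([1, 2, 3], [2, 4, 6]) == pytest.approx(0.0, abs=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            cosine_distance([0, 0], [1, 2])

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            u = rng.normal(size=12)
            v = rng.normal(size=12)
            assert cosine_distance(u, v) == pytest.approx(scipy_cosine(u, v), abs=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(
        c=st.floats(1e-3, 1e3),
        seed=st.integers(0, 2**31 - 1),
    )
    def test_scale_invariance_property(self, c, seed):
        rng = np.random.default_rng(seed)
        u = rng.uniform(0.1, 3.0, 10)
        v = rng.uniform(0.1, 3.0, 10)
        assert cosine_distance(u, c * v) == pytest.approx(cosine_distance(u, v), abs=1e-9)


class TestSimilarityMatrix:
    def _make(self, n=4):
        rng = np.random.default_rng(2)
        out = []
        for i in range(n):
            course = rng.uniform(0.5, 2.5, 20)
            out.append(_summary("Sigma", 0.5 / (i + 1), False, course))
        return out

    def test_zero_diagonal_symmetric_bounded(self):
        mat = similarity_matrix(self._make())
        np.testing.assert_array_equal(np.diag(mat.distances), 0.0)
        np.testing.assert_allclose(mat.distances, mat.distances.T)
        assert np.all((mat.distances >= 0) & (mat.distances <= 2))

    def test_duplicate_condition_zero_off_diagonal(self):
        s = self._make(2)
        dup = _summary("Sigma", s[0].concentration / 7, False, s[0].average_course.copy())
        mat = similarity_matrix([*s, dup])
        i = mat.labels.index(s[0].label)
        j = mat.labels.index(dup.label)
        assert mat.distances[i, j] == pytest.approx(0.0, abs=1e-12)

    def test_ordering_grouped_by_prep_descending_conc(self):
        rng = np.random.default_rng(3)
        summaries = [
            _summary(prep, conc, False, rng.uniform(0.5, 2.5, 20))
            for prep in ("Sigma", "EB")
            for conc in (0.05, 5.0, 0.5)
        ]
        mat = similarity_matrix(summaries)
        assert mat.labels == [
            "Sigma 5", "Sigma 0.5", "Sigma 0.05", "EB 5", "EB 0.5", "EB 0.05",
        ]

    def test_grid_mismatch_rejected(self):
        a = _summary("Sigma", 0.5, False, np.ones(20))
        b = _summary("Sigma", 0.05, False, np.ones(10), grid=np.arange(0, 100, 10.0))
        with pytest.raises(ValueError, match="grid"):
            similarity_matrix([a, b])

    def test_same_preset_seeds_closer_than_cross_preparation(self, presets):
        """Replicate conditions (same central params, different seeds) lie
        closer than any cross-preparation pair at matched concentration."""
        grid = np.arange(-15.0, 600.0, 5.0)
        out_grid = np.arange(0.0, 600.0, 5.0)

        def avg(preset, seed):
            cells = sample_population(preset, 0.5, False, 120, rng=seed, time_grid=grid)
            traces = [
                _trace(grid, c.true_trace, track_id=c.cell_id)
                for c in cells
                if c.active
            ]
            return average_time_course(traces, out_grid)

        rep1 = avg(presets["Sigma"], 101)
        rep2 = avg(presets["Sigma"], 202)
        within = cosine_distance(rep1, rep2)
        for other in ("EB", "UP"):
            across = cosine_distance(rep1, avg(presets[other], 303))
            assert within < across


class TestFractionActive:
    def test_none_active(self):
        df = pd.DataFrame({"active": [False] * 100})
        assert fraction_active(df) == (0, 100, 0.0)

    def test_all_active(self):
        df = pd.DataFrame({"active": [True] * 100})
        assert fraction_active(df) == (100, 100, 1.0)

    def test_dose_response_monotone_within_binomial_noise(self, presets):
        """Fraction active is nondecreasing in concentration up to 3 SEs."""
        grid = np.array([-5.0, 0.0, 30.0, 60.0])
        n = 300
        concs = [5e-7, 5e-6, 5e-5, 5e-4, 5e-3, 5e-2, 0.5, 5.0, 50.0]
        fracs = []
        for i, conc in enumerate(concs):
            cells = sample_population(
                presets["Sigma"], conc, False, n, rng=500 + i, time_grid=grid
            )
            fracs.append(np.mean([c.active for c in cells]))
        se = np.sqrt(0.25 / n)
        assert all(b >= a - 3 * 2**0.5 * se for a, b in zip(fracs, fracs[1:]))


class TestReceptorEffect:
    grid = np.arange(-15.0, 600.0, 5.0)
    out_grid = np.arange(0.0, 600.0, 5.0)

    def _course(self, preset, stnfr, seed, n=150):
        cells = sample_population(preset, 0.5, stnfr, n, rng=seed, time_grid=self.grid)
        traces = [
            _trace(self.grid, c.true_trace, track_id=c.cell_id)
            for c in cells
            if c.active
        ]
        return average_time_course(traces, self.out_grid), sum(c.active for c in cells)

    def test_mismatched_conditions_rejected(self):
        a = _summary("Sigma", 0.5, False, np.ones(20))
        b = _summary("UP", 0.5, True, np.ones(20))
        with pytest.raises(ValueError, match="mismatch"):
            receptor_effect(a, b)

    def test_empty_arm_flagged_not_raised(self):
        a = _summary("UP", 5e-7, False, None)
        b = _summary("UP", 5e-7, True, np.ones(20))
        eff = receptor_effect(a, b)
        assert not eff.defensible
        assert np.isnan(eff.distance)

    def test_null_modifier_within_replicate_noise(self, presets):
        """An identity sTNFRII modifier leaves only seed-to-seed variation."""
        from dataclasses import replace
        from nfdyn.response_model import StnfrModifier

        null = replace(
            presets["Sigma"],
            stnfr_modifier=StnfrModifier(persistent_prob_factor=1.0, plateau_amp_factor=1.0),
        )
        ctrl, n1 = self._course(null, False, 11)
        block, n2 = self._course(null, True, 12)
        rep, _ = self._course(null, False, 13)
        d_null = cosine_distance(ctrl, block)
        d_rep = cosine_distance(ctrl, rep)
        assert d_null < 10 * max(d_rep, 1e-6)

    def test_sigma_more_affected_than_up(self, presets):
        """TNF blocking distorts Sigma's average course more than UP's."""
        def effect(preset):
            ctrl, n1 = self._course(preset, False, 21)
            block, n2 = self._course(preset, True, 22)
            a = _summary(preset.name, 0.5, False, ctrl, grid=self.out_grid, n_active=n1)
            b = _summary(preset.name, 0.5, True, block, grid=self.out_grid, n_active=n2)
            return receptor_effect(a, b).distance

        assert effect(presets["Sigma"]) > effect(presets["UP"])
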