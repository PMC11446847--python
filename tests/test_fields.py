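import numpy as np
import pytest

from avpconn.connectivity import WeightMatrix
from avpconn.errors import GeometryError, ValidationError
from avpconn.fields import (
    ResponseGrid,
    backtrace_field,
    column_occupancy,
    dff_from_raw,
    dot_layout_38,
    population_outline,
    rf_ellipse,
    stimulus_response,
    visual_area,
)
from avpconn.synth import generate_response_grid
from avpconn.types import ColumnWeightField, EllipseFit, EyeMap, MedullaColumn, Occupancy


def _col(cid, x, y):
    return MedullaColumn(cid, 0, 0, np.array([0, 0, 1.0]), np.array([x, y, 0.0]), 0.0, 1.0)


def _wm(values, pres, posts):
    return WeightMatrix(region="", pre_ids=pres, post_ids=posts,
                        values=np.asarray(values, dtype=float))


class TestOccupancy:
    def test_all_sites_one_column(self):
        cols = [_col("a", 0, 0), _col("b", 100, 0)]
        occ = column_occupancy(np.array([[1.0, 0, 0], [2.0, 1, 0]]), cols, "m")
        assert occ.fractions == {"a": 1.0}

    def test_two_one_split(self):
        cols = [_col("a", 0, 0), _col("b", 100, 0)]
        occ = column_occupancy(np.array([[1.0, 0, 0], [2.0, 0, 0], [99.0, 0, 0]]), cols, "m")
        assert occ.fractions["a"] == pytest.approx(2 / 3)
        assert occ.fractions["b"] == pytest.approx(1 / 3)

    def test_empty_sites_warn(self):
        with pytest.warns(UserWarning):
            occ = column_occupancy(np.empty((0, 3)), [_col("a", 0, 0)], "m")
        assert occ.fractions == {}

    def test_matches_brute_force_nearest_axis(self, rng):
        cols = [_col(f"c{i}", *rng.uniform(-50, 50, 2)) for i in range(12)]
        pts = rng.uniform(-60, 60, (200, 3))
        occ = column_occupancy(pts, cols, "m")
        # brute force: perpendicular distance to each vertical axis
        counts = {}
        for p in pts:
            best, best_d = None, np.inf
            for c in sorted(cols, key=lambda c: c.column_id):
                d = np.hypot(p[0] - c.anchor[0], p[1] - c.anchor[1])
                if d < best_d:
                    best, best_d = c.column_id, d
            counts[best] = counts.get(best, 0) + 1
        expected = {c: n / 200 for c, n in counts.items()}
        assert occ.fractions == pytest.approx(expected)


def brute_force_field(er_id, tubu_er, metu_tubu, occupancies):
    """Path-enumeration oracle for the direct pathway."""
    out = {}
    for b, tubu in enumerate(tubu_er.pre_ids):
        w_b = tubu_er.values[b, tubu_er.post_ids.index(er_id)]
        if tubu not in metu_tubu.post_ids:
            continue
        for m, metu in enumerate(metu_tubu.pre_ids):
            w_m = metu_tubu.values[m, metu_tubu.post_ids.index(tubu)]
            occ = occupancies.get(metu)
            if occ is None:
                continue
            for cid, frac in occ.fractions.items():
                out[cid] = out.get(cid, 0.0) + w_b * w_m * frac
    return out


class TestBacktrace:
    def test_single_chain_hand_arithmetic(self):
        tubu_er = _wm([[0.5]], ["b"], ["er"])
        metu_tubu = _wm([[0.4]], ["m"], ["b"])
        occ = {"m": Occupancy("m", {"c": 1.0})}
        fld = backtrace_field("er", tubu_er, metu_tubu, occ, pathway="direct")
        assert fld.direct == pytest.approx({"c": 0.2})

    def test_no_upstream_metu_all_zero(self):
        tubu_er = _wm([[0.5]], ["b"], ["er"])
        metu_tubu = _wm([[0.0]], ["m"], ["b"])
        fld = backtrace_field("er", tubu_er, metu_tubu, {"m": Occupancy("m", {"c": 1.0})})
        assert fld.direct == {}

    def test_er_without_tubu_input_warns_empty(self):
        tubu_er = _wm([[0.5]], ["b"], ["er"])
        metu_tubu = _wm([[0.4]], ["m"], ["b"])
        with pytest.warns(UserWarning):
            fld = backtrace_field("ghost", tubu_er, metu_tubu, {})
        assert fld.direct == {} and fld.indirect == {}

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            nb, nm, nc = rng.integers(2, 6), rng.integers(2, 8), rng.integers(2, 6)
            tubu_er = _wm(rng.random((nb, 1)), [f"b{i}" for i in range(nb)], ["er"])
            metu_tubu = _wm(rng.random((nm, nb)), [f"m{i}" for i in range(nm)],
                            [f"b{i}" for i in range(nb)])
            occ = {}
            for i in range(nm):
                f = rng.dirichlet(np.ones(nc))
                occ[f"m{i}"] = Occupancy(f"m{i}", {f"c{j}": f[j] for j in range(nc)})
            fld = backtrace_field("er", tubu_er, metu_tubu, occ, pathway="direct")
            oracle = brute_force_field("er", tubu_er, metu_tubu, occ)
            assert set(fld.direct) == set(oracle)
            for c in oracle:
                assert fld.direct[c] == pytest.approx(oracle[c], abs=1e-12)

    def test_indirect_pathway_hand_arithmetic(self):
        tubu_er = _wm([[0.5]], ["b"], ["er"])
        metu_tubu = _wm([[0.0]], ["m"], ["b"])
        metu_tutu = _wm([[0.6]], ["m"], ["t"])
        tutu_tubu = _wm([[0.3]], ["t"], ["b"])
        occ = {"m": Occupancy("m", {"c": 1.0})}
        fld = backtrace_field("er", tubu_er, metu_tubu, occ, pathway="both",
                              metu_tutu=metu_tutu, tutu_tubu=tutu_tubu)
        assert fld.indirect == pytest.approx({"c": 0.5 * 0.3 * 0.6})

    def test_conservation_identity(self, rng):
        nb, nm, nc = 4, 6, 5
        tubu_er = _wm(rng.random((nb, 1)), [f"b{i}" for i in range(nb)], ["er"])
        metu_tubu = _wm(rng.random((nm, nb)), [f"m{i}" for i in range(nm)],
                        [f"b{i}" for i in range(nb)])
        occ = {f"m{i}": Occupancy(f"m{i}", dict(zip([f"c{j}" for j in range(nc)],
                                                    rng.dirichlet(np.ones(nc)))))
               for i in range(nm)}
        fld = backtrace_field("er", tubu_er, metu_tubu, occ, pathway="direct")
        expect = sum(
            tubu_er.values[b, 0] * metu_tubu.values[:, b].sum() for b in range(nb)
        )
        assert sum(fld.direct.values()) == pytest.approx(expect, abs=1e-9)


class TestVisualArea:
    def _eye_map(self):
        dirs = {f"c{i}": (float(i * 5 - 30), 0.0) for i in range(13)}
        return EyeMap(directions=dirs, equator=set(), unmatched=[])

    def test_count_nonzero_columns(self):
        fld = ColumnWeightField("er", direct={f"c{i}": 0.1 for i in range(7)})
        count, _ = visual_area(fld)
        assert count == 7

    def test_eps_above_max_gives_zero(self):
        fld = ColumnWeightField("er", direct={"c1": 0.1})
        count, outline = visual_area(fld, eps=0.5)
        assert count == 0 and outline == []

    def test_outline_area_matches_patch(self):
        em = self._eye_map()
        covered = [f"c{i}" for i in range(4)]
        fld = ColumnWeightField("er", direct={c: 1.0 for c in covered})
        count, outline = visual_area(fld, eye_map=em)
        assert count == 4
        from shapely.geometry import Polygon

        # hexagon size from 5-degree nearest-neighbour spacing
        hex_area = 3 * np.sqrt(3) / 2 * (5.0 / np.sqrt(3)) ** 2
        total = sum(Polygon(p).area for p in outline)
        assert total == pytest.approx(4 * hex_area, rel=1e-6)

    def test_population_outline_union(self):
        em = self._eye_map()
        f1 = ColumnWeightField("e1", direct={"c0": 1.0})
        f2 = ColumnWeightField("e2", direct={"c0": 1.0, "c1": 1.0})
        out = population_outline([f1, f2], em)
        from shapely.geometry import Polygon

        hex_area = 3 * np.sqrt(3) / 2 * (5.0 / np.sqrt(3)) ** 2
        assert sum(Polygon(p).area for p in out) == pytest.approx(2 * hex_area, rel=1e-6)


class TestStimulusResponse:
    def test_constant_trace_zero_unresponsive(self):
        trials = np.ones((10, 30))
        resp, mean, flag = stimulus_response(trials, (10, 20), (0, 5))
        assert mean == 0.0 and not flag
        np.testing.assert_allclose(resp, 0.0)

    def test_unit_step_during_stimulation(self):
        trials = np.zeros((10, 30))
        trials[:, 10:20] = 1.0
        resp, mean, flag = stimulus_response(trials, (10, 20), (0, 5))
        assert mean == pytest.approx(1.0) and flag
        np.testing.assert_allclose(resp, 1.0)

    def test_noisy_planted_effect(self):
        rng = np.random.default_rng(5)
        trials = rng.normal(0.0, 0.1, (10, 30))
        trials[:, 10:20] += 0.5
        resp, mean, flag = stimulus_response(trials, (10, 20), (0, 5))
        assert abs(mean - 0.5) <= 0.1 and flag

    def test_small_sample_uses_exact_test(self):
        trials = np.zeros((4, 30))
        trials[:, 10:20] = 1.0
        _, _, flag = stimulus_response(trials, (10, 20), (0, 5))
        # exact signed-rank with n=4 cannot reach p <= 0.05
        assert not flag

    def test_zero_trials_rejected(self):
        with pytest.raises(ValidationError):
            stimulus_response(np.zeros((0, 30)), (10, 20), (0, 5))

    def test_window_outside_trace_rejected(self):
        with pytest.raises(ValidationError):
            stimulus_response(np.zeros((3, 30)), (25, 35), (0, 5))


class TestDff:
    def test_constant_series_zero(self):
        out = dff_from_raw(np.full(100, 10.0), np.zeros(100))
        np.testing.assert_allclose(out, 0.0)

    def test_hand_arithmetic(self):
        raw = np.array([5.0] * 10 + [10.0])
        out = dff_from_raw(raw, np.zeros(11))
        assert out[-1] == pytest.approx(1.0)

    def test_control_equal_raw_rejected(self):
        raw = np.full(50, 7.0)
        with pytest.raises(ValidationError, match="F0"):
            dff_from_raw(raw, raw)


class TestRfEllipse:
    def test_layout_has_38_nonoverlapping_squares(self):
        pos = dot_layout_38()
        assert pos.shape == (38, 2)
        # non-overlap: any two centres at least 18 degrees apart in one axis
        for i in range(38):
            for j in range(i + 1, 38):
                d = np.abs(pos[i] - pos[j])
                assert d.max() >= 18.0 - 1e-9

    def test_circular_profile_near_unit_ratio(self):
        planted = EllipseFit(centroid=(0.0, 0.0), semi_major=20.0, semi_minor=20.0, angle_deg=0.0)
        grid = generate_response_grid(planted, n_trials=10, noise_sd=0.0, seed=0)
        fit, _ = rf_ellipse(grid, level=0.2)
        assert 1.0 <= fit.ratio <= 1.1

    def test_planted_elongated_ellipse_recovered(self):
        # ratio 2.5 along the azimuth axis; the 20 % contour (about 1.8
        # sigma) must fit inside the dot field and the minor sigma must
        # stay resolvable (>= half the 18-degree stimulus spacing)
        planted = EllipseFit(centroid=(0.0, 0.0), semi_major=25.0, semi_minor=10.0, angle_deg=90.0)
        grid = generate_response_grid(planted, n_trials=10, noise_sd=0.0, seed=0)
        fit, _ = rf_ellipse(grid, level=0.2)
        assert abs(fit.ratio - 2.5) / 2.5 < 0.10
        assert abs(fit.angle_deg - 90.0) < 5.0

    def test_flat_grid_rejected(self):
        grid = ResponseGrid(positions=dot_layout_38(), trials=np.ones((38, 10)))
        with pytest.raises(ValidationError):
            rf_ellipse(grid)

    def test_planted_recovery_across_random_ellipses(self):
        """Planted contour ellipses are recovered over a range of shapes."""
        rng = np.random.default_rng(99)
        for _ in range(20):
            ratio = float(rng.uniform(1.2, 2.0))
            b = float(rng.uniform(10.0, 12.0))
            angle = float(rng.choice([0.0, 90.0]))
            if angle == 0.0 and b * ratio > 24.0:
                angle = 90.0  # keep the 20 % contour inside the dot field
            planted = EllipseFit(centroid=(float(rng.uniform(-5, 5)), float(rng.uniform(-3, 3))),
                                 semi_major=b * ratio, semi_minor=b, angle_deg=angle)
            grid = generate_response_grid(planted, n_trials=10, noise_sd=0.0, seed=1)
            fit, _ = rf_ellipse(grid, level=0.2)
            assert abs(fit.ratio - ratio) / ratio < 0.10
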