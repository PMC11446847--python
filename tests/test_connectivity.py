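import numpy as np
import pandas as pd
import pytest
from scipy.ndimage import gaussian_filter

from avpconn.config import PipelineConfig
from avpconn.connectivity import (
    WeightMatrix,
    filter_synapses,
    mean_nt_profile,
    neuron_weight_matrix,
    order_matrix_rows,
    synapse_density_map,
    type_weight_matrix,
    upstream_traversal,
)
from avpconn.errors import ValidationError


def syn_table(rows):
    return pd.DataFrame(rows, columns=["pre_id", "post_id", "x_nm", "y_nm", "z_nm", "cleft_score"])


class TestFilter:
    def test_cleft_threshold_boundary(self):
        df = syn_table([("a", "b", 0, 0, 0, 49), ("a", "b", 0, 0, 0, 50)])
        kept = filter_synapses(df)
        assert list(kept["cleft_score"]) == [50]

    def test_autapse_removed_despite_high_cleft(self):
        df = syn_table([("a", "a", 0, 0, 0, 90)])
        assert len(filter_synapses(df)) == 0

    def test_mixed_fixture_hand_count(self):
        rows = [("p%d" % i, "q%d" % i, 0, 0, 0, 80) for i in range(14)]
        rows += [("x", "y", 0, 0, 0, 10)] * 3          # low cleft
        rows += [("z", "z", 0, 0, 0, 80)] * 2          # autapses
        rows += [("w", "0", 0, 0, 0, 80)]              # background
        kept = filter_synapses(syn_table(rows))
        assert len(kept) == 14

    def test_idempotent(self):
        df = syn_table([("a", "b", 0, 0, 0, 49), ("c", "d", 0, 0, 0, 51), ("e", "0", 0, 0, 0, 99)])
        once = filter_synapses(df)
        pd.testing.assert_frame_equal(once, filter_synapses(once))


class TestNeuronWeights:
    def test_hand_arithmetic(self):
        rows = [("A", "p", 0, 0, 0, 80)] * 10 + [("B", "p", 0, 0, 0, 80)] * 30
        m = neuron_weight_matrix(syn_table(rows), ["A", "B"], ["p"])
        assert m.weight("A", "p") == pytest.approx(0.25)
        assert m.weight("B", "p") == pytest.approx(0.75)

    def test_min_regional_connections_boundary(self):
        rows4 = [("A", "p", 0, 0, 0, 80)] * 4
        rows5 = [("A", "q", 0, 0, 0, 80)] * 5
        with pytest.warns(UserWarning):
            m4 = neuron_weight_matrix(syn_table(rows4), ["A"], ["p"])
        assert m4.post_ids == []
        m5 = neuron_weight_matrix(syn_table(rows4 + rows5), ["A"], ["p", "q"])
        assert m5.post_ids == ["q"]

    def test_complete_pre_set_columns_sum_to_one(self, rng):
        pres = [f"u{i}" for i in range(8)]
        rows = []
        for post in ("p", "q"):
            for pre in pres:
                rows += [(pre, post, 0, 0, 0, 80)] * int(rng.integers(1, 6))
        m = neuron_weight_matrix(syn_table(rows), pres, ["p", "q"])
        np.testing.assert_allclose(m.values.sum(axis=0), 1.0, atol=1e-12)

    def test_exclusion_list(self):
        rows = [("A", "p", 0, 0, 0, 80)] * 10
        m = neuron_weight_matrix(syn_table(rows), ["A"], ["p"], exclude=["A"])
        assert m.pre_ids == []


class TestTypeWeights:
    def test_single_supplier_is_one(self):
        rows = [("a1", "p1", 0, 0, 0, 80)] * 7
        tm = {"a1": "T1", "p1": "P"}
        m = type_weight_matrix(syn_table(rows), tm)
        assert m.weight("T1", "P") == pytest.approx(1.0)

    def test_hand_arithmetic_two_suppliers(self):
        rows = [("a", "p", 0, 0, 0, 80)] * 30 + [("b", "p", 0, 0, 0, 80)] * 10
        rows += [("c", "p", 0, 0, 0, 80)] * 40
        tm = {"a": "T1", "b": "T2", "c": "T3", "p": "P"}
        m = type_weight_matrix(syn_table(rows), tm)
        assert m.weight("T1", "P") == pytest.approx(0.375)
        assert m.weight("T2", "P") == pytest.approx(0.125)

    def test_neuron_order_invariance(self, rng):
        rows = [(f"a{i}", f"p{j}", 0, 0, 0, 80) for i in range(4) for j in range(3) for _ in range(i + j + 1)]
        tm = {f"a{i}": "T" for i in range(4)} | {f"p{j}": "P" for j in range(3)}
        df = syn_table(rows)
        m1 = type_weight_matrix(df, tm)
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        m2 = type_weight_matrix(shuffled, tm)
        np.testing.assert_allclose(m1.values, m2.values)

    def test_type_matrix_equals_aggregated_individual_matrix(self, rng):
        """Algebraic identity: type weights = count aggregation over the
        individual matrix re-weighted by denominators."""
        pres = [f"a{i}" for i in range(6)]
        posts = [f"p{j}" for j in range(4)]
        rows = []
        for pre in pres:
            for post in posts:
                rows += [(pre, post, 0, 0, 0, 80)] * int(rng.integers(1, 8))
        df = syn_table(rows)
        tm = {p: ("TA" if p in pres[:3] else "TB") for p in pres}
        tm |= {p: ("PA" if p in posts[:2] else "PB") for p in posts}
        cfg = PipelineConfig(min_regional_connections=0)
        ind = neuron_weight_matrix(df, pres, posts, config=cfg)
        typ = type_weight_matrix(df, tm, config=cfg)
        for tp in typ.pre_ids:
            for tq in typ.post_ids:
                num = sum(
                    ind.values[i, j] * ind.denominators[j]
                    for i, a in enumerate(ind.pre_ids) if tm[a] == tp
                    for j, p in enumerate(ind.post_ids) if tm[p] == tq
                )
                den = sum(ind.denominators[j] for j, p in enumerate(ind.post_ids) if tm[p] == tq)
                assert typ.weight(tp, tq) == pytest.approx(num / den, abs=1e-12)


class TestOrdering:
    def _matrix(self, counts, pres, posts):
        counts = np.asarray(counts, dtype=float)
        return WeightMatrix(region="", pre_ids=pres, post_ids=posts,
                            values=counts / counts.sum(), counts=counts)

    def test_groups_follow_dorsoventral_position(self):
        m = self._matrix([[0, 0, 5], [5, 0, 0], [0, 5, 0]], ["n1", "n2", "n3"], ["t1", "t2", "t3"])
        out = order_matrix_rows(m, {"t1": 2.0, "t2": 3.0, "t3": 1.0})
        assert out.pre_ids == ["n1", "n2", "n3"]  # t3 (dv 1) < t1 (2) < t2 (3)

    def test_within_group_descending_synapse_count(self):
        m = self._matrix([[7], [12]], ["n1", "n2"], ["t1"])
        out = order_matrix_rows(m, {"t1": 0.0})
        assert out.pre_ids == ["n2", "n1"]

    def test_tie_breaks_by_neuron_id(self):
        m = self._matrix([[5], [5]], ["nb", "na"], ["t1"])
        out = order_matrix_rows(m, {"t1": 0.0})
        assert out.pre_ids == ["na", "nb"]

    def test_partnerless_neuron_trails_with_warning(self):
        m = self._matrix([[5, 0], [0, 0]], ["n1", "n2"], ["t1", "x"])
        with pytest.warns(UserWarning, match="n2"):
            out = order_matrix_rows(m, {"t1": 0.0})
        assert out.pre_ids == ["n1", "n2"]


class TestTraversal:
    def test_two_hop_chain_found(self):
        rows = [("A", "B", 0, 0, 0, 80)] * 5 + [("B", "seed", 0, 0, 0, 80)] * 5
        out = upstream_traversal(["seed"], syn_table(rows), optic_lobe_ids={"A"})
        hops = dict(zip(out["neuron_id"], out["hop"]))
        assert hops == {"seed": 0, "B": 1, "A": 2}

    def test_weak_link_pruned(self):
        rows = [("A", "B", 0, 0, 0, 80)] * 4 + [("B", "seed", 0, 0, 0, 80)] * 5
        out = upstream_traversal(["seed"], syn_table(rows), optic_lobe_ids={"A"})
        assert "A" not in set(out["neuron_id"])

    def test_unknown_seed_rejected(self):
        with pytest.raises(ValidationError, match="nope"):
            upstream_traversal(["nope"], syn_table([("a", "b", 0, 0, 0, 80)]), optic_lobe_ids=set())

    def test_cc_intrinsic_not_expanded(self):
        rows = [("A", "CC", 0, 0, 0, 80)] * 5 + [("CC", "seed", 0, 0, 0, 80)] * 5
        out = upstream_traversal(["seed"], syn_table(rows), optic_lobe_ids={"A"},
                                 central_complex_ids={"CC"})
        names = set(out["neuron_id"])
        assert "CC" in names and "A" not in names

    def test_matches_brute_force_two_step_enumeration(self, rng):
        nodes = [f"n{i}" for i in range(50)]
        rows = []
        edges = set()
        for _ in range(150):
            a, b = rng.choice(50, 2, replace=False)
            n = int(rng.integers(1, 9))
            rows += [(nodes[a], nodes[b], 0, 0, 0, 80)] * n
        df = syn_table(rows)
        counts = df.groupby(["pre_id", "post_id"]).size()
        strong = {(p, q) for (p, q), n in counts.items() if n >= 5}
        seed = "n0"
        one = {p for (p, q) in strong if q == seed}
        two = {p for (p, q) in strong if q in one} - one - {seed}
        out = upstream_traversal([seed], df, optic_lobe_ids=set())
        got = {r.neuron_id: r.hop for r in out.itertuples()}
        assert {n for n, h in got.items() if h == 1} == one
        assert {n for n, h in got.items() if h == 2} == two


class TestNTProfile:
    def test_single_site_identity(self):
        p = mean_nt_profile("n", [[0.2, 0.8]])
        np.testing.assert_allclose(p.probabilities, [0.2, 0.8])

    def test_two_sites_symmetric(self):
        p = mean_nt_profile("n", [[1.0, 0.0], [0.0, 1.0]])
        np.testing.assert_allclose(p.probabilities, [0.5, 0.5])

    def test_zero_sites_rejected(self):
        with pytest.raises(ValidationError):
            mean_nt_profile("n", np.zeros((0, 3)))

    def test_matches_independent_summation_oracle(self, rng):
        vecs = rng.dirichlet(np.ones(6), size=100)
        p = mean_nt_profile("n", vecs)
        oracle = np.array([sum(vecs[i, j] for i in range(100)) / 100 for j in range(6)])
        oracle = oracle / oracle.sum()
        np.testing.assert_allclose(p.probabilities, oracle, atol=1e-12)


class TestDensityMap:
    def test_single_synapse_mass_conserved(self):
        df = syn_table([("a", "b", 1000.0, 2000.0, 3000.0, 80)])
        grid, _ = synapse_density_map(df, view="lateral")
        assert grid.sum() == pytest.approx(1.0, rel=1e-3)

    def test_two_distant_synapses_two_maxima(self):
        cfg = PipelineConfig(density_sigma_bins=2.0)
        df = syn_table([("a", "b", 0.0, 0.0, 0.0, 80), ("a", "b", 20000.0, 0.0, 0.0, 80)])
        grid, _ = synapse_density_map(df, view="lateral", config=cfg, sigma_bins=2.0)
        # two separated local maxima of equal mass
        flat = grid.ravel()
        top = np.sort(flat)[-2:]
        assert top[0] == pytest.approx(top[1], rel=1e-6)
        assert grid.sum() == pytest.approx(2.0, rel=1e-3)

    def test_matches_dense_convolution_oracle(self, rng):
        pts = rng.uniform(0, 20000, size=(500, 3))
        df = syn_table([("a", "b", x, y, z, 80) for x, y, z in pts])
        cfg = PipelineConfig(density_sigma_bins=3.0)
        grid, edges = synapse_density_map(df, view=np.eye(3), config=cfg)
        frame = np.eye(3)
        uv = pts @ frame[:, :2]
        raw, _, _ = np.histogram2d(uv[:, 0], uv[:, 1], bins=edges)
        # dense convolution with an explicitly renormalized truncated kernel
        sigma = 3.0
        rad = int(4 * sigma + 0.5)
        x = np.arange(-rad, rad + 1)
        k1 = np.exp(-0.5 * (x / sigma) ** 2)
        k1 /= k1.sum()
        from scipy.signal import convolve2d

        oracle = convolve2d(convolve2d(raw, k1[:, None], mode="same"), k1[None, :], mode="same")
        assert np.abs(grid - oracle).max() < 1e-9

    def test_empty_set_warns_all_zero(self):
        df = syn_table([])
        with pytest.warns(UserWarning):
            grid, _ = synapse_density_map(df, view="lateral")
        assert grid.sum() == 0
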