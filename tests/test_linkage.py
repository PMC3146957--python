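import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pinemap.formats import GenotypeMatrix
from pinemap.linkage import (
    InsufficientDataError,
    estimate_two_point,
    group_markers,
    haldane,
    kosambi,
    kosambi_inverse,
    order_group,
    split_pseudo_testcross,
    two_point_table,
    TwoPointTable,
)
from pinemap.simulate import SimulationConfig, simulate_cross, simulate_genome


class TestMappingFunctions:
    def test_kosambi_zero(self):
        assert kosambi(0.0) == 0.0

    def test_kosambi_closed_form(self):
        assert kosambi(0.2) == pytest.approx(25 * math.log(1.4 / 0.6), abs=1e-9)
        assert kosambi(0.2) == pytest.approx(21.18, abs=0.01)

    @settings(max_examples=49, derandomize=True)
    @given(st.floats(0.01, 0.49))
    def test_inverse_identity(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            haldane(0.5)
        with pytest.raises(ValueError):
            kosambi_inverse(-1.0)


def make_testcross_matrix(calls_a, calls_b, code="lmxll"):
    return GenotypeMatrix(
        pedigree_type="CP",
        marker_ids=["A", "B"],
        seg_codes=[code, code],
        calls=[calls_a, calls_b],
        offspring_ids=[f"o{j}" for j in range(len(calls_a))],
    )


class TestTwoPointTestcross:
    def test_twenty_offspring_two_recombinants(self):
        """r = 2/20 = 0.10; LOD = 20 log10(2) + 2 log10(.1) + 18 log10(.9)."""
        a = ["ll"] * 10 + ["lm"] * 10
        b = ["ll"] * 8 + ["lm", "lm"] + ["lm"] * 10
        res = estimate_two_point(make_testcross_matrix(a, b), "A", "B")
        assert res.r_hat == pytest.approx(0.10, abs=1e-6)
        expected_lod = 20 * math.log10(2) + 2 * math.log10(0.1) + 18 * math.log10(0.9)
        assert res.lod == pytest.approx(expected_lod, abs=0.01)
        assert res.lod == pytest.approx(3.20, abs=0.01)

    def test_phase_maximization(self):
        # perfectly anti-correlated calls: repulsion phase, r = 0
        a = ["ll"] * 10 + ["lm"] * 10
        b = ["lm"] * 10 + ["ll"] * 10
        res = estimate_two_point(make_testcross_matrix(a, b), "A", "B")
        assert res.r_hat == 0.0
        assert res.phase == "repulsion"

    def test_different_parents_uninformative(self):
        m = GenotypeMatrix(
            "CP", ["A", "B"], ["lmxll", "nnxnp"],
            [["ll", "lm"] * 5, ["nn", "np"] * 5],
            [f"o{j}" for j in range(10)],
        )
        res = estimate_two_point(m, "A", "B")
        assert res.phase == "uninformative"
        assert res.lod == 0.0 and res.r_hat == 0.5

    def test_no_shared_offspring(self):
        m = make_testcross_matrix(["ll", "--"], ["--", "lm"])
        with pytest.raises(InsufficientDataError):
            estimate_two_point(m, "A", "B")


def f2_matrix_from_counts(counts):
    """Build an F2 matrix realizing a 9-class joint count table."""
    calls_a, calls_b = [], []
    for (ca, cb), n in counts.items():
        calls_a.extend([ca] * n)
        calls_b.extend([cb] * n)
    return GenotypeMatrix(
        "F2", ["A", "B"], ["codom", "codom"],
        [calls_a, calls_b],
        [f"o{j}" for j in range(len(calls_a))],
    )


def f2_grid_oracle(counts, step=1e-4):
    """Brute-force likelihood grid over r in [0, 0.5], both phases."""
    grid = np.arange(0.0, 0.5 + step / 2, step)
    swap = {"a": "b", "h": "h", "b": "a"}

    def loglik(cnts):
        p, q = 1 - grid, grid
        probs = {
            ("a", "a"): p * p / 4, ("a", "h"): p * q / 2, ("a", "b"): q * q / 4,
            ("h", "a"): p * q / 2, ("h", "h"): (p * p + q * q) / 2, ("h", "b"): p * q / 2,
            ("b", "a"): q * q / 4, ("b", "h"): p * q / 2, ("b", "b"): p * p / 4,
        }
        total = np.zeros_like(grid)
        for c, n in cnts.items():
            total += n * np.log(np.maximum(probs[c], 1e-300))
        return total

    ll_c = loglik(counts)
    counts_r = {}
    for (ca, cb), n in counts.items():
        key = (ca, swap[cb])
        counts_r[key] = counts_r.get(key, 0) + n
    ll_r = loglik(counts_r)
    if ll_c.max() >= ll_r.max():
        return grid[np.argmax(ll_c)]
    return grid[np.argmax(ll_r)]


class TestTwoPointF2:
    def test_all_parental_r_zero(self):
        m = f2_matrix_from_counts({("a", "a"): 5, ("b", "b"): 5})
        res = estimate_two_point(m, "A", "B")
        assert res.r_hat == pytest.approx(0.0, abs=1e-9)

    def test_mixed_table_matches_grid_oracle(self):
        counts = {("a", "a"): 20, ("a", "h"): 5, ("h", "h"): 35, ("h", "b"): 6,
                  ("b", "b"): 18, ("a", "b"): 1, ("h", "a"): 7, ("b", "h"): 4}
        m = f2_matrix_from_counts(counts)
        res = estimate_two_point(m, "A", "B")
        assert res.r_hat == pytest.approx(f2_grid_oracle(counts), abs=1e-3)

    def test_random_tables_match_grid_oracle(self):
        """EM maximum agrees with a 1e-4 likelihood grid on random tables."""
        rng = np.random.default_rng(12)
        cells = [(a, b) for a in "ahb" for b in "ahb"]
        for _ in range(20):
            raw = rng.multinomial(60, rng.dirichlet(np.ones(9)))
            counts = {c: int(n) for c, n in zip(cells, raw) if n > 0}
            if len(counts) < 2:
                continue
            m = f2_matrix_from_counts(counts)
            res = estimate_two_point(m, "A", "B")
            assert res.r_hat == pytest.approx(f2_grid_oracle(counts), abs=1e-3)

    def test_vectorized_table_agrees_with_per_pair(self, f2_matrix):
        t = two_point_table(f2_matrix)
        for i in range(3):
            for j in range(i + 1, 4):
                res = estimate_two_point(
                    f2_matrix, f2_matrix.marker_ids[i], f2_matrix.marker_ids[j]
                )
                assert t.r[i, j] == pytest.approx(res.r_hat, abs=1e-3)
                assert t.lod[i, j] == pytest.approx(res.lod, abs=0.05)


class TestTwoPointIntercross:
    def test_hkxhk_pair_recovers_linkage(self):
        cfg = SimulationConfig(seed=21, n_offspring=300, error_rate=0.0,
                               missing_rate=0.0, cp_mixture=(0.0, 0.0, 1.0))
        g = simulate_genome(cfg, n_groups=1, group_lengths_cM=[30.0], n_markers=2,
                            positions=[(0, 0.0), (0, 10.0)])
        cp = simulate_cross(g, cfg, "CP")
        res = estimate_two_point(cp, "M0000", "M0001")
        r_true = 0.5 * (1 - np.exp(-0.2))
        assert res.r_hat == pytest.approx(r_true, abs=0.05)
        assert res.lod > 10

    def test_lod_nonnegative_and_zero_at_half(self):
        # counts matching the r=0.5 expectation exactly (1:2:1 x 1:2:1)
        counts = {}
        for ca, wa in (("a", 1), ("h", 2), ("b", 1)):
            for cb, wb in (("a", 1), ("h", 2), ("b", 1)):
                counts[(ca, cb)] = wa * wb
        m = f2_matrix_from_counts(counts)
        res = estimate_two_point(m, "A", "B")
        assert res.lod == pytest.approx(0.0, abs=1e-6)


class TestGrouping:
    def table(self, lods):
        ids = sorted({m for pair in lods for m in pair})
        n = len(ids)
        idx = {m: i for i, m in enumerate(ids)}
        lod = np.zeros((n, n))
        for (a, b), v in lods.items():
            lod[idx[a], idx[b]] = lod[idx[b], idx[a]] = v
        return TwoPointTable(ids, np.full((n, n), 0.3), lod)

    def test_transitive_chain(self):
        t = self.table({("A", "B"): 5, ("B", "C"): 4, ("A", "C"): 1})
        assert group_markers(t, 3.0) == [["A", "B", "C"]]

    def test_all_weak_pairs_are_singletons(self):
        t = self.table({("A", "B"): 2, ("B", "C"): 1, ("A", "C"): 0.5})
        assert group_markers(t, 3.0) == [["A"], ["B"], ["C"]]

    def test_simulated_groups_nest_in_chromosomes(self):
        cfg = SimulationConfig(seed=31, n_offspring=200, error_rate=0.01,
                               missing_rate=0.02)
        g = simulate_genome(cfg, n_groups=4, group_lengths_cM=[100.0] * 4,
                            n_markers=24,
                            positions=[(c, 20.0 * i) for c in range(4) for i in range(6)])
        f2 = simulate_cross(g, cfg, "F2")
        groups = group_markers(two_point_table(f2), 3.0)
        assert len(groups) >= 4
        truth = {m: int(g.group_of[i]) for i, m in enumerate(g.marker_ids)}
        for comp in groups:
            assert len({truth[m] for m in comp}) == 1


class TestSplitPseudoTestcross:
    def make(self, codes):
        calls = {"lmxll": "ll", "nnxnp": "nn", "hkxhk": "hh"}
        return GenotypeMatrix(
            "CP", [f"M{i}" for i in range(len(codes))], list(codes),
            [[calls[c]] for c in codes], ["o0"],
        )

    def test_sets_by_definition(self):
        m = self.make(["lmxll"] * 3 + ["nnxnp"] * 2 + ["hkxhk"])
        f, ma, sh = split_pseudo_testcross(m)
        assert (len(f), len(ma), len(sh)) == (4, 3, 1)

    def test_all_intercross_shared(self):
        m = self.make(["hkxhk"] * 4)
        f, ma, sh = split_pseudo_testcross(m)
        assert f == ma == sh

    def test_study_shaped_counts(self):
        # 95 maternal + 118 paternal 1:1 markers + 74 1:2:1 markers
        m = self.make(["lmxll"] * 95 + ["nnxnp"] * 118 + ["hkxhk"] * 74)
        f, ma, sh = split_pseudo_testcross(m)
        assert len(f) == 95 + 74
        assert len(ma) == 118 + 74
        assert len(sh) == 74

    def test_f2_rejected(self, f2_matrix):
        with pytest.raises(ValueError):
            split_pseudo_testcross(f2_matrix)


def simulate_chain(seed=41, n=500, spacing=10.0, k=5, error=0.0):
    cfg = SimulationConfig(seed=seed, n_offspring=n, error_rate=error,
                           missing_rate=0.0)
    g = simulate_genome(cfg, n_groups=1, group_lengths_cM=[spacing * (k - 1) + 1],
                        n_markers=k, positions=[(0, spacing * i) for i in range(k)])
    return g, simulate_cross(g, cfg, "F2")


class TestOrdering:
    def test_colinear_markers_recovered(self):
        g, f2 = simulate_chain()
        t = two_point_table(f2)
        res = order_group(list(t.marker_ids), t)
        assert res.order in (g.marker_ids, g.marker_ids[::-1])
        assert res.accessory == []
        assert res.positions == sorted(res.positions)
        assert res.positions[0] == 0.0

    def test_duplicate_marker_placed_at_zero_distance(self):
        g, f2 = simulate_chain(k=4)
        dup = f2.subset(f2.marker_ids)
        dup.marker_ids.append("DUP")
        dup.seg_codes.append("codom")
        dup.calls.append(list(f2.calls[1]))
        t = two_point_table(dup)
        res = order_group(list(t.marker_ids), t)
        assert "DUP" in res.order  # not demoted
        i, j = res.order.index("DUP"), res.order.index(f2.marker_ids[1])
        assert abs(res.positions[i] - res.positions[j]) < 1e-6

    def test_unlinked_noise_marker_demoted(self):
        g, f2 = simulate_chain(k=5)
        rng = np.random.default_rng(5)
        noisy = f2.subset(f2.marker_ids)
        noisy.marker_ids.append("NOISE")
        noisy.seg_codes.append("codom")
        noisy.calls.append(list(rng.choice(["a", "h", "b"], p=[0.25, 0.5, 0.25],
                                           size=f2.n_offspring)))
        t = two_point_table(noisy)
        res = order_group(list(t.marker_ids), t)
        demoted = [m for m, *_ in res.accessory]
        assert demoted == ["NOISE"]
        assert "NOISE" not in res.order

    def test_input_order_invariance(self):
        g, f2 = simulate_chain(seed=43, n=300, error=0.005)
        t = two_point_table(f2)
        ref = order_group(list(t.marker_ids), t).order
        shuffled = list(t.marker_ids)
        np.random.default_rng(9).shuffle(shuffled)
        res = order_group(shuffled, t)
        assert res.order in (ref, ref[::-1])

    def test_spearman_on_noisy_group(self):
        from scipy.stats import spearmanr

        g, f2 = simulate_chain(seed=47, n=200, spacing=15.0, k=6, error=0.01)
        t = two_point_table(f2)
        res = order_group(list(t.marker_ids), t)
        true_pos = [g.pos_cM[g.marker_ids.index(m)] for m in res.order]
        rho = abs(spearmanr(true_pos, res.positions).statistic)
        assert rho >= 0.98
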