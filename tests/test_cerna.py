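"""Unit and property tests for the shared-miRNA test and pair calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from cernaforge.cerna import (
    assemble_network,
    call_cerna_pairs,
    hypergeom_shared_test,
    stage_networks,
)
from cernaforge.expression import ExpressionMatrix
from cernaforge.interactions import union_merge


def enumeration_tail(k, K_a, K_b, N):
    """Oracle: exhaustive enumeration of all C(N, K_b) draws."""
    a = set(range(K_a))
    hits = total = 0
    for draw in itertools.combinations(range(N), K_b):
        total += 1
        hits += len(a & set(draw)) >= k
    return hits / total


class TestHypergeomSharedTest:
    def test_zero_overlap_gives_one(self):
        assert hypergeom_shared_test(0, 5, 4, 10) == 1.0

    def test_forced_full_overlap(self):
        assert hypergeom_shared_test(5, 5, 5, 5) == pytest.approx(1.0)

    def test_worked_example(self):
        assert hypergeom_shared_test(3, 5, 4, 10) == pytest.approx(55 / 210, abs=1e-12)

    def test_matches_enumeration_small(self):
        for N in range(1, 9):
            for K_a in range(N + 1):
                for K_b in range(N + 1):
                    for k in range(min(K_a, K_b) + 1):
                        assert hypergeom_shared_test(k, K_a, K_b, N) == pytest.approx(
                            enumeration_tail(k, K_a, K_b, N), abs=1e-12)

    @given(st.integers(1, 40), st.data())
    def test_symmetry_and_monotonicity(self, N, data):
        K_a = data.draw(st.integers(0, N))
        K_b = data.draw(st.integers(0, N))
        ps = [hypergeom_shared_test(k, K_a, K_b, N) for k in range(min(K_a, K_b) + 1)]
        assert ps[0] == 1.0
        assert all(p1 >= p2 - 1e-12 for p1, p2 in zip(ps, ps[1:]))
        k = data.draw(st.integers(0, min(K_a, K_b)))
        assert hypergeom_shared_test(k, K_a, K_b, N) == pytest.approx(
            hypergeom_shared_test(k, K_b, K_a, N), abs=1e-12)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_shared_test(3, 2, 2, 10)
        with pytest.raises(ValueError):
            hypergeom_shared_test(1, 11, 2, 10)


def toy_table(pairs):
    rows = []
    for mirna, target, cls in pairs:
        rows.append((mirna, target, cls))
    df = pd.DataFrame(rows, columns=["mirna_id", "target_id", "target_class"])
    df["predictors"] = [frozenset({"P"}) for _ in range(len(df))]
    return union_merge([df])


def toy_expr(profiles, classes=None):
    cols = [f"Day{4 + 2 * i}" for i in range(len(next(iter(profiles.values()))))]
    df = pd.DataFrame(profiles).T
    df.columns = cols
    cls = pd.Series({t: (classes or {}).get(t, "mRNA") for t in df.index})
    return ExpressionMatrix(df, cls, "log2p1")


class TestCallCernaPairs:
    def make_inputs(self):
        rng = np.random.default_rng(0)
        shared = rng.normal(5, 1.5, 14)
        table = toy_table(
            [(f"miR{i}", "a", "mRNA") for i in range(4)]
            + [(f"miR{i}", "b", "mRNA") for i in range(4)]
            + [("miR9", "c", "mRNA")]
        )
        expr = toy_expr({
            "a": shared + rng.normal(0, 0.2, 14),
            "b": shared + rng.normal(0, 0.2, 14),
            "c": rng.normal(5, 1.5, 14),
        })
        return table, expr

    def test_planted_pair_accepted_and_consistent(self):
        table, expr = self.make_inputs()
        calls = call_cerna_pairs(table, expr, universe_size=20)
        acc = calls.accepted
        assert set(map(tuple, acc[["id_a", "id_b"]].values)) == {("a", "b")}
        row = acc.iloc[0]
        # recheck both criteria independently
        assert row.p_hyper == pytest.approx(
            float(stats.hypergeom.sf(row.k_shared - 1, 20, row.K_a, row.K_b)))
        r, p = stats.pearsonr(expr.values.loc["a"], expr.values.loc["b"])
        assert row.r == pytest.approx(r, abs=1e-12)
        assert row.p_corr == pytest.approx(p, abs=1e-9)

    def test_zero_shared_never_candidate(self):
        table, expr = self.make_inputs()
        calls = call_cerna_pairs(table, expr, universe_size=20)
        tested = set(map(frozenset, calls.candidates[["id_a", "id_b"]].values))
        assert frozenset({"a", "c"}) not in tested

    def test_missing_expression_rejected(self):
        table, expr = self.make_inputs()
        expr2 = expr.subset(["a", "b"])
        with pytest.raises(ValueError, match="absent"):
            call_cerna_pairs(table, expr2, universe_size=20)

    def test_row_order_invariance(self):
        table, expr = self.make_inputs()
        shuffled = table.edges.sample(frac=1.0, random_state=3).reset_index(drop=True)
        from cernaforge.interactions import TargetTable

        calls1 = call_cerna_pairs(table, expr, universe_size=20)
        calls2 = call_cerna_pairs(TargetTable(edges=shuffled), expr, universe_size=20)
        pd.testing.assert_frame_equal(calls1.candidates, calls2.candidates)

    def test_accepted_pairs_on_simulated_bundle_self_consistent(self, default_dataset):
        from cernaforge.pipeline import RunConfig, bundle_from_dataset, run_pipeline

        r = run_pipeline(bundle_from_dataset(default_dataset),
                         RunConfig(input_dir="x", seed=1, n_perm=200))
        acc = r.calls.accepted
        assert len(acc) > 0
        target_mirnas = r.target_table.mirnas_of()
        N = len(r.target_table.mirna_universe)
        for row in acc.itertuples():
            k = len(target_mirnas[row.id_a] & target_mirnas[row.id_b])
            assert k == row.k_shared
            assert float(stats.hypergeom.sf(k - 1, N, row.K_a, row.K_b)) < 0.05
            assert row.r > 0.5 and row.p_corr < 0.05


class TestAssembleNetwork:
    def test_single_pair_construction(self):
        table = toy_table([("m1", "a", "mRNA"), ("m2", "a", "mRNA"),
                           ("m1", "b", "mRNA"), ("m2", "b", "mRNA")])
        expr = toy_expr({"a": np.arange(14.0), "b": np.arange(14.0) * 2})
        calls = call_cerna_pairs(table, expr, universe_size=10)
        net = assemble_network(calls, table)
        assert net.rna_nodes == {"a", "b"}
        assert net.mirna_nodes == {"m1", "m2"}
        assert len(net.competing_edges) == 1
        assert len(net.regulatory_edges) == 4

    def test_empty_pairs_empty_network(self):
        table = toy_table([("m1", "a", "mRNA")])
        net = assemble_network(pd.DataFrame(columns=["id_a", "id_b", "class_a", "class_b",
                                                     "k_shared", "p_hyper", "r", "p_corr"]), table)
        assert net.graph.number_of_nodes() == 0


class TestStageNetworks:
    def test_growth_only_correlation(self):
        rng = np.random.default_rng(2)
        growth = [f"Day{4 + 2 * i}" for i in range(8)]
        senescence = [f"Day{20 + 2 * i}" for i in range(6)]
        shared_g = rng.normal(5, 2, 8)
        a = np.r_[shared_g + rng.normal(0, 0.1, 8), rng.normal(5, 2, 6)]
        b = np.r_[shared_g + rng.normal(0, 0.1, 8), -(a[8:] - 5) + 5]
        table = toy_table([("m1", "a", "mRNA"), ("m2", "a", "mRNA"),
                           ("m1", "b", "mRNA"), ("m2", "b", "mRNA")])
        expr = toy_expr({"a": a, "b": b})
        nets = stage_networks(table, expr, {"growth": growth, "senescence": senescence},
                              universe_size=10)
        assert frozenset({"a", "b"}) in nets["growth"].competing_edges
        assert frozenset({"a", "b"}) not in nets["senescence"].competing_edges

    def test_identical_profiles_in_both_stages(self):
        x = np.r_[np.arange(8.0), np.arange(6.0)]
        table = toy_table([("m1", "a", "mRNA"), ("m2", "a", "mRNA"),
                           ("m1", "b", "mRNA"), ("m2", "b", "mRNA")])
        expr = toy_expr({"a": x, "b": x + 1})
        nets = stage_networks(table, expr,
                              {"growth": expr.samples[:8], "senescence": expr.samples[8:]},
                              universe_size=10)
        for net in nets.values():
            assert frozenset({"a", "b"}) in net.competing_edges

    def test_small_stage_rejected(self):
        table = toy_table([("m1", "a", "mRNA")])
        expr = toy_expr({"a": np.arange(14.0)})
        with pytest.raises(ValueError, match="need >= 3"):
            stage_networks(table, expr, {"growth": expr.samples[:2],
                                         "senescence": expr.samples[2:]})
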