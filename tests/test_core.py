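"""Binarization, observation frequencies, q-values and dPPI calls."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diffint import core
from diffint.io import ExpressionMatrix

from conftest import brute_force_calls, make_expression, random_instance


class TestBinarize:
    def test_gene_median_rule(self):
        expr = make_expression(
            [[1.0, 2.0, 3.0, 4.0]], ["g"], list("abcd"), ["normal", "normal", "tumor", "tumor"]
        )
        bm = core.binarize(expr)
        assert list(bm.active.loc["g"]) == [False, False, True, True]
        assert bm.thresholds["g"] == 2.5

    def test_constant_gene_is_never_active(self):
        expr = make_expression(
            [[5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0]],
            ["flat", "g"],
            list("abcd"),
            ["normal", "normal", "tumor", "tumor"],
        )
        assert not core.binarize(expr).active.loc["flat"].any()

    def test_matches_brute_force_recompute(self):
        expr, _ = random_instance(seed=11, n_genes=20, n_samples=12)
        bm = core.binarize(expr)
        import statistics

        for g in expr.gene_ids:
            med = statistics.median(float(x) for x in expr.values.loc[g])
            for s in expr.sample_ids:
                assert bm.active.loc[g, s] == (float(expr.values.loc[g, s]) > med)

    def test_alternative_rules(self):
        expr = make_expression(
            [[0.0, 0.0, 0.0, 8.0]], ["g"], list("abcd"), ["normal", "normal", "tumor", "tumor"]
        )
        assert list(core.binarize(expr, "gene-mean").active.loc["g"]) == [False] * 3 + [True]
        assert list(core.binarize(expr, "absolute", cutoff=-1.0).active.loc["g"]) == [True] * 4

    def test_unknown_rule_rejected(self, small_expr):
        with pytest.raises(ValueError, match="unknown binarization rule"):
            core.binarize(small_expr, "z-score")

    def test_all_zero_matrix_warns(self):
        expr = make_expression(
            [[0.0, 0.0], [0.0, 0.0]], ["g1", "g2"], ["a", "b"], ["normal", "tumor"]
        )
        with pytest.warns(UserWarning, match="all-inactive"):
            core.binarize(expr)


def binarized(active_rows, genes, samples, labels) -> core.BinarizedMatrix:
    return core.BinarizedMatrix(
        active=pd.DataFrame(active_rows, index=genes, columns=samples, dtype=bool),
        thresholds=pd.Series(0.0, index=genes),
        phenotype=pd.Series(labels, index=samples),
    )


class TestObservationFrequencies:
    def test_intersection_count(self):
        # a active in {s1, s2}, b active in {s2, s3}; normal = s1..s4
        bm = binarized(
            [[1, 1, 0, 0, 0, 0], [0, 1, 1, 0, 0, 0]],
            ["a", "b"],
            [f"s{i}" for i in range(1, 7)],
            ["normal"] * 4 + ["tumor"] * 2,
        )
        out = core.observation_frequencies(bm, nx.Graph([("a", "b")]))
        assert out.loc[0, "f_N"] == pytest.approx(1 / 4)
        assert out.loc[0, "f_T"] == 0.0

    def test_never_coactive_edge(self):
        bm = binarized(
            [[1, 0, 1, 0], [0, 1, 0, 1]], ["a", "b"], list("wxyz"), ["normal"] * 2 + ["tumor"] * 2
        )
        out = core.observation_frequencies(bm, nx.Graph([("a", "b")]))
        assert out.loc[0, "f_N"] == 0.0 and out.loc[0, "f_T"] == 0.0

    def test_missing_endpoint_names_edge(self):
        bm = binarized([[1, 0]], ["a"], ["s1", "s2"], ["normal", "tumor"])
        with pytest.raises(KeyError, match="a.*b|b.*a"):
            core.observation_frequencies(bm, nx.Graph([("a", "b")]))

    def test_empty_phenotype_is_error(self):
        bm = binarized([[1, 1], [1, 1]], ["a", "b"], ["s1", "s2"], ["tumor", "tumor"])
        with pytest.raises(ValueError, match="normal"):
            core.observation_frequencies(bm, nx.Graph([("a", "b")]))


class TestQValue:
    @pytest.mark.parametrize(
        "f_n,f_t,expected",
        [(0.5, 0.5, 0.5), (0.4, 0.0, 0.0), (0.02, 0.38, 0.95), (0.0, 0.7, 1.0)],
    )
    def test_values(self, f_n, f_t, expected):
        assert core.q_value(f_n, f_t) == pytest.approx(expected)

    def test_unobserved_is_nan(self):
        assert math.isnan(core.q_value(0.0, 0.0))


class TestCallDppis:
    def make_freqs(self, rows):
        return pd.DataFrame(
            [{"protein_a": f"a{i}", "protein_b": f"b{i}", "f_N": fn, "f_T": ft}
             for i, (fn, ft) in enumerate(rows)]
        )

    @pytest.mark.parametrize(
        "f_n,f_t,expected",
        [
            (0.6, 0.03, "repressed"),  # q ~ 0.048, freq gate passes
            (0.01, 0.15, "not_differential"),  # q ~ 0.94 but max freq <= 0.2
            (0.5, 0.5, "not_differential"),
            (0.0, 0.0, "unobserved"),
            (0.01, 0.30, "activated"),
        ],
    )
    def test_call_rule(self, f_n, f_t, expected):
        audit = core.call_dppis(self.make_freqs([(f_n, f_t)]))
        assert audit.loc[0, "call"] == expected

    def test_threshold_ties_are_not_called(self):
        # q exactly 0.90 and exactly 0.10 (ratios of exact binary fractions):
        # strict inequalities exclude both
        audit = core.call_dppis(self.make_freqs([(0.0625, 0.5625), (0.5625, 0.0625)]))
        assert list(audit["call"]) == ["not_differential"] * 2

    def test_dppi_subset_keeps_only_differential(self):
        audit = core.call_dppis(self.make_freqs([(0.6, 0.03), (0.5, 0.5), (0.0, 0.0)]))
        assert list(core.dppi_subset(audit)["call"]) == ["repressed"]


class TestDifferentialInteractome:
    def test_oracle_equivalence_on_random_instances(self):
        """Vectorized frequencies, q and calls equal a plain double loop."""
        for seed in range(5):
            expr, net = random_instance(seed=seed, n_genes=25, n_samples=16, n_edges=60)
            res = core.differential_interactome(expr, net)
            oracle = brute_force_calls(expr, net.edges)
            assert len(res.audit) == net.number_of_edges()
            for row in res.audit.itertuples(index=False):
                f_n, f_t, q, call = oracle[(row.protein_a, row.protein_b)]
                assert row.f_N == pytest.approx(f_n)
                assert row.f_T == pytest.approx(f_t)
                assert (q is None and math.isnan(row.q)) or row.q == pytest.approx(q)
                assert row.call == call

    def test_null_case_identical_data_in_both_phenotypes(self, small_expr):
        values = np.hstack([small_expr.values.to_numpy()] * 2)
        samples = [f"n{i}" for i in range(6)] + [f"t{i}" for i in range(6)]
        expr = make_expression(
            values, small_expr.gene_ids, samples, ["normal"] * 6 + ["tumor"] * 6
        )
        net = nx.Graph([("gA", "gB"), ("gB", "gC"), ("gA", "gC")])
        res = core.differential_interactome(expr, net)
        assert len(res.dppis) == 0
        observed = res.audit[res.audit["call"] != "unobserved"]
        assert (observed["q"] == 0.5).all()

    def test_label_swap_antisymmetry(self):
        expr, net = random_instance(seed=42, n_genes=20, n_samples=14, n_edges=40)
        swapped = ExpressionMatrix(
            values=expr.values.copy(),
            phenotype=expr.phenotype.map({"normal": "tumor", "tumor": "normal"}),
        )
        a = core.differential_interactome(expr, net).audit.set_index(["protein_a", "protein_b"])
        b = core.differential_interactome(swapped, net).audit.set_index(["protein_a", "protein_b"])
        for e in a.index:
            if a.loc[e, "call"] == "unobserved":
                assert b.loc[e, "call"] == "unobserved"
            else:
                assert b.loc[e, "q"] == pytest.approx(1 - a.loc[e, "q"])
        flip = {"activated": "repressed", "repressed": "activated"}
        a_diff = {e: c for e, c in a["call"].items() if c in flip}
        b_diff = {e: c for e, c in b["call"].items() if c in flip}
        assert b_diff == {e: flip[c] for e, c in a_diff.items()}

    def test_sample_and_edge_order_invariance(self):
        expr, net = random_instance(seed=9, n_genes=15, n_samples=10, n_edges=25)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.sample_ids)
        shuffled = ExpressionMatrix(
            values=expr.values[perm], phenotype=expr.phenotype[perm]
        )
        reordered_net = nx.Graph()
        reordered_net.add_edges_from((b, a) for a, b in reversed(list(net.edges)))
        a = core.differential_interactome(expr, net).audit
        b = core.differential_interactome(shuffled, reordered_net).audit
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_monotonicity(self):
        expr, net = random_instance(seed=21, n_genes=25, n_samples=16, n_edges=60)
        base = core.differential_interactome(expr, net, core.DiffIntParams())
        loose_freq = core.differential_interactome(
            expr, net, core.DiffIntParams(min_freq=0.05)
        )
        wide_q = core.differential_interactome(
            expr, net, core.DiffIntParams(q_low=0.02, q_high=0.98)
        )
        def edge_set(res):
            return set(map(tuple, res.dppis[["protein_a", "protein_b"]].to_numpy()))
        assert edge_set(base) <= edge_set(loose_freq)
        assert edge_set(wide_q) <= edge_set(base)

    def test_empty_network_rejected(self, small_expr):
        with pytest.raises(ValueError, match="no edges"):
            core.differential_interactome(small_expr, nx.Graph())


@given(
    data=st.data(),
    n_genes=st.integers(2, 5),
    n_normal=st.integers(1, 4),
    n_tumor=st.integers(1, 4),
)
@settings(max_examples=40, deadline=None, derandomize=True)
def test_frequency_bounds_property(data, n_genes, n_normal, n_tumor):
    """f_N, f_T in [0, 1]; q in [0, 1] and NaN exactly when f_N + f_T = 0."""
    n_samples = n_normal + n_tumor
    raw = data.draw(
        st.lists(
            st.lists(st.integers(0, 30), min_size=n_samples, max_size=n_samples),
            min_size=n_genes,
            max_size=n_genes,
        )
    )
    expr = make_expression(
        np.asarray(raw, dtype=float),
        [f"g{i}" for i in range(n_genes)],
        [f"s{i}" for i in range(n_samples)],
        ["normal"] * n_normal + ["tumor"] * n_tumor,
    )
    net = nx.Graph(
        [(f"g{i}", f"g{j}") for i in range(n_genes) for j in range(i + 1, n_genes)]
    )
    audit = core.differential_interactome(expr, net).audit
    assert ((audit["f_N"] >= 0) & (audit["f_N"] <= 1)).all()
    assert ((audit["f_T"] >= 0) & (audit["f_T"] <= 1)).all()
    unobserved = audit["f_N"] + audit["f_T"] == 0
    assert audit.loc[unobserved, "q"].isna().all()
    assert (audit.loc[unobserved, "call"] == "unobserved").all()
    q_obs = audit.loc[~unobserved, "q"]
    assert ((q_obs >= 0) & (q_obs <= 1)).all()
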