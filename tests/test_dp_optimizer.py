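"""The layered-graph DP against its brute-force oracle."""

from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonopt import (
    CodonPairScoreTable,
    SizeError,
    brute_force_oracle,
    build_graph,
    optimize,
    state_space_size,
)
from codonopt.fixtures import random_protein, random_score_table
from codonopt.genetic_code import AMINO_ACIDS
from codonopt.pair_scoring import ALL_CODONS

SMALL_PROTEINS = st.text(alphabet=sorted(AMINO_ACIDS), min_size=1, max_size=6)


class TestGraph:
    def test_mqvt_layers_and_edges(self, code):
        g = build_graph("MQVT", code)
        assert [len(layer) for layer in g.layers] == [1, 2, 4, 4]
        assert g.edge_counts == [2, 8, 16]  # Q->V bipartite edges = 2*4 = 8

    def test_mqvt_state_space(self, code):
        assert state_space_size(build_graph("MQVT", code)) == 1 * 2 + 2 * 4 + 4 * 4 == 26

    def test_single_residue(self, code):
        g = build_graph("M", code)
        assert len(g.layers) == 1 and state_space_size(g) == 0

    @pytest.mark.parametrize("n", [2, 5, 9])
    def test_poly_met_state_space(self, code, n):
        assert state_space_size(build_graph("M" * n, code)) == n - 1

    def test_append_stop_adds_layer(self, code):
        g = build_graph("MQ", code, append_stop=True)
        assert len(g.layers) == 3 and g.layers[-1] == ("TAA", "TAG", "TGA")

    def test_self_concatenation_adds_one_junction_term(self, code):
        # work grows linearly, not quadratically, in protein length
        p = "MQVTWY"
        s1 = state_space_size(build_graph(p, code))
        s2 = state_space_size(build_graph(p + p, code))
        join = len(code.synonymous_codons(p[-1])) * len(code.synonymous_codons(p[0]))
        assert s2 == 2 * s1 + join


class TestOptimize:
    def test_zero_table_gives_lexicographically_first_path(self, code):
        zero = CodonPairScoreTable(
            {(a, b): 0 for a in ALL_CODONS for b in ALL_CODONS}, "zeros"
        )
        r = optimize("MQVT", zero, "best", code)
        assert r.total_score == 0
        assert r.cds.codons == ("ATG", "CAA", "GTA", "ACA")
        assert r.ties_encountered > 0

    def test_states_explored_equals_state_space(self, rule_table, code):
        r = optimize("MQVTWYLS", rule_table, "best", code)
        assert r.states_explored == state_space_size(build_graph("MQVTWYLS", code))

    def test_translation_fidelity_all_modes(self, rule_table, code):
        for mode in ("best", "worst", "unbiased"):
            r = optimize("MQVTWYLS", rule_table, mode, code)
            assert code.translate(r.cds) == "MQVTWYLS"
            assert r.total_score == rule_table.score_sequence(r.cds)[0]

    def test_append_stop_scores_stop_junction(self, code):
        # table favoring TTT->TGA: the DP must pick TGA over TAA/TAG
        scores = {(a, b): 0.0 for a in ALL_CODONS for b in ALL_CODONS}
        scores[("TTT", "TGA")] = 2.0
        t = CodonPairScoreTable(scores, "stop-favoring")
        r = optimize("F", t, "best", code, append_stop=True)
        assert r.cds.codons[-1] == "TGA" and r.total_score == 2.0
        assert code.translate(r.cds) == "F*"

    def test_worst_equals_best_of_negated_table(self, rule_table, code):
        rb = optimize("MQVTWYLS", rule_table.negated(), "best", code)
        rw = optimize("MQVTWYLS", rule_table, "worst", code)
        assert rw.total_score == -rb.total_score
        assert rw.cds == rb.cds

    def test_optimal_substructure(self, rule_table, code):
        # every prefix of the best path is a best path to its end node
        protein = "MQVTW"
        r = optimize(protein, rule_table, "best", code)
        layers = build_graph(protein, code).layers
        for k in range(1, len(protein) + 1):
            end = r.cds.codons[k - 1]
            best_to_end = max(
                rule_table.score_sequence(p)[0]
                for p in product(*layers[:k])
                if p[-1] == end
            )
            assert rule_table.score_sequence(r.cds.codons[:k])[0] == best_to_end


class TestOracle:
    def test_cap_refusal(self, rule_table, code):
        with pytest.raises(SizeError, match=str(6**21)):
            brute_force_oracle("L" * 21, rule_table, "best", code)

    def test_mqvt_agreement(self, rule_table, code):
        r = optimize("MQVT", rule_table, "best", code)
        o = brute_force_oracle("MQVT", rule_table, "best", code)
        assert o.states_explored == 32  # = candidate_combination_count(MQVT)
        assert (r.total_score, r.cds) == (o.total_score, o.cds)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(SMALL_PROTEINS, st.integers(min_value=0, max_value=2**31 - 1))
    def test_equivalence_random_tables(self, code, protein, seed):
        import numpy as np

        table = random_score_table(np.random.default_rng(seed))
        for mode in ("best", "worst", "unbiased"):
            r = optimize(protein, table, mode, code)
            o = brute_force_oracle(protein, table, mode, code)
            assert r.total_score == o.total_score
            assert r.cds == o.cds, mode

    def test_continuous_table_equivalence(self, code, rng):
        # non-discretized scores exercise the float comparison path
        for _ in range(20):
            protein = random_protein(rng, int(rng.integers(3, 6)))
            scores = {
                (a, b): float(s)
                for (a, b), s in zip(
                    ((a, b) for a in ALL_CODONS for b in ALL_CODONS),
                    rng.normal(size=4096),
                )
            }
            table = CodonPairScoreTable(scores, "gaussian")
            for mode in ("best", "worst"):
                r = optimize(protein, table, mode, code)
                o = brute_force_oracle(protein, table, mode, code)
                assert r.total_score == pytest.approx(o.total_score, abs=1e-9)
                assert r.cds == o.cds

    def test_mode_ordering(self, code, rng):
        # worst <= unbiased <= best: all three optimize over the same set
        for _ in range(25):
            protein = random_protein(rng, int(rng.integers(3, 7)))
            table = random_score_table(rng)
            totals = {
                m: optimize(protein, table, m, code).total_score
                for m in ("best", "worst", "unbiased")
            }
            assert totals["worst"] <= totals["unbiased"] <= totals["best"]

    def test_unbiased_prefers_neutral_paths(self, rule_table, code):
        # a context-neutral coding of MQVT exists, so unbiased finds |.|=0
        r = optimize("MQVT", rule_table, "unbiased", code)
        assert r.objective_value == 0
        assert all(s == 0 for s in r.junction_scores)
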