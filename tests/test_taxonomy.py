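"""Relabelling convention, C/P/R classification, transition graphs."""

import json

import networkx as nx
import numpy as np
import pytest

from normscan import (
    ErrorModel,
    NotRelabelable,
    UnclassifiableNorm,
    classify,
    classify_p,
    classify_r,
    embed_binary,
    extrapolate_mu_zero,
    graph_to_dot,
    graph_to_json,
    leading_eight,
    merge_annotation,
    parse_norm,
    permute_norm,
    relabel_by_convention,
    stationary,
    transition_graph,
)

GOLDEN = (3 - np.sqrt(5)) / 2  # inverse golden ratio squared


class TestRelabelling:
    def test_conventional_norm_is_fixed_point(self, fixtures_by_name, err_1e3):
        for name, norm in fixtures_by_name.items():
            relabeled, sigma = relabel_by_convention(norm, err=err_1e3)
            assert sigma == (0, 1, 2), name
            assert relabeled == norm, name

    def test_permuted_norm_recovers_printed_form(self, fixtures_by_name, err_1e3):
        for sigma in [(0, 2, 1), (1, 0, 2), (2, 1, 0)]:
            for name in ("c1p1r1", "c3p2r2"):
                norm = fixtures_by_name[name]
                scrambled = permute_norm(norm, sigma)
                recovered, tau = relabel_by_convention(scrambled, err=err_1e3)
                assert recovered == norm, (name, sigma)
                # tau undoes sigma
                assert tuple(tau[sigma[i]] for i in range(3)) == (0, 1, 2)

    def test_near_tied_shares_resolved_deterministically(self, fixtures_by_name, err_1e3):
        # C3 examples have h_G* barely above h_N*; the convention still
        # singles out the labelling with B = R(G,G,D)
        norm = fixtures_by_name["c3p1r1"]
        relabeled, sigma = relabel_by_convention(norm, err=err_1e3)
        assert sigma == (0, 1, 2)
        assert relabeled.assignment[2, 2, 1] == 0  # R(G,G,D) = B

    def test_defector_keeping_top_label_is_rejected(self):
        # R(G,G,D) = G with an all-G assignment: majority label absorbs all
        from normscan import Norm

        R = np.full((3, 3, 2), 2, dtype=np.int64)
        P = np.zeros((3, 3), dtype=np.int64)
        norm = Norm(3, R, P)
        with pytest.raises(NotRelabelable):
            relabel_by_convention(norm, err=ErrorModel.tied(1e-3))


class TestClassification:
    def test_all_examples_classify_to_their_subclass(self, fixtures_by_name, err_1e3):
        for name, norm in fixtures_by_name.items():
            label = classify(norm, err_1e3)
            assert label.label.lower().replace("-", "") == name, name

    def test_classification_stable_under_alternative_mu_grid(self, fixtures_by_name, err_1e3):
        for name in ("c1p1r1", "c2p1r1", "c3p1r1"):
            label = classify(fixtures_by_name[name], err_1e3, mu_grid=(3e-3, 3e-4, 3e-5))
            assert label.label.lower().replace("-", "") == name

    def test_leading_eight_embed_as_c1p1r1(self, err_1e3):
        """With an unused neutral label, each leading-eight norm lands in the
        subclass whose mechanism it shares: C1-P1-R1."""
        for norm in leading_eight():
            label = classify(embed_binary(norm), err_1e3)
            assert label.label == "C1-P1-R1"

    def test_punishment_pattern_requires_defection(self, fixtures_by_name):
        norm = fixtures_by_name["c2p2r2"]  # P(G,B) = D with R(G,B,D) = N
        assert classify_p(norm, "C2") == "P2"
        # forgiving variant (P(G,B) = C) has no punishment pattern
        forgiving = parse_norm(
            [r.replace("GB:DN:G", "GB:CN:G") for r in norm.prescriptions()]
        )
        with pytest.raises(UnclassifiableNorm):
            classify_p(forgiving, "C2")

    def test_recovery_pattern_examples(self, fixtures_by_name):
        assert classify_r(fixtures_by_name["c1p1r2"], "C1") == "R2"
        assert classify_r(fixtures_by_name["c2p2r1"], "C2") == "R1"
        assert classify_r(fixtures_by_name["c3p1r2"], "C3") == "R2"


class TestClosedFormLimits:
    def test_golden_ratio_family(self, fixtures_by_name):
        lim = extrapolate_mu_zero(fixtures_by_name["c3p2r2"], "h_N_star")
        assert lim == pytest.approx(GOLDEN, abs=1e-6)

    def test_oscillation_family_reaches_half(self, fixtures_by_name):
        lim = extrapolate_mu_zero(fixtures_by_name["c3p2r1"], "h_N_star")
        assert lim == pytest.approx(0.5, abs=1e-6)

    def test_frozen_family_reaches_one_fifth(self):
        # G and N non-interacting (GG:CG, NN:CN, G/N meetings swap or keep);
        # the O(mu) coupling through B selects h_N* = 1/5
        rows = (
            [f"{x}B:DG:G" for x in "BNG"]
            + [f"{x}N:CN:B" for x in "BNG"]
            + [f"{x}G:CG:B" for x in "BNG"]
        )
        lim = extrapolate_mu_zero(parse_norm(rows), "h_N_star")
        assert lim == pytest.approx(0.2, abs=1e-6)


class TestTransitionGraph:
    def test_leading_eight_mechanism_edges(self, err_1e3):
        norm = leading_eight()[0]
        st = stationary(norm, err_1e3)
        g = transition_graph(norm, st, err_1e3)
        labels = {d["label"] for _, _, d in g.edges(data=True)}
        assert labels == {"GG:CG", "GB:DG", "BG:CG", "GG:DB"}
        dashed = {d["label"] for _, _, d in g.edges(data=True) if d["error"]}
        assert dashed == {"GG:DB"}

    def test_p2_norm_has_solid_edge_g_to_n(self, fixtures_by_name, err_1e3):
        norm = fixtures_by_name["c1p2r1"]
        st = stationary(norm, err_1e3)
        g = transition_graph(norm, st, err_1e3)
        labels = {d["label"] for _, _, d in g.edges(data=True) if not d["error"]}
        assert "GB:DN" in labels  # punishment demotes the punisher
        assert "GN:DG" in labels  # ...and acting against N restores G

    def test_r2_norm_recovery_path_b_n_g(self, fixtures_by_name, err_1e3):
        norm = fixtures_by_name["c2p1r2"]
        st = stationary(norm, err_1e3)
        g = transition_graph(norm, st, err_1e3)
        simple = nx.DiGraph(g.edges())
        assert nx.has_path(simple, "B", "N") and nx.has_path(simple, "N", "G")

    def test_zero_threshold_emits_all_context_edges(self, fixtures_by_name, err_1e3):
        norm = fixtures_by_name["c1p1r1"]
        st = stationary(norm, err_1e3)
        g = transition_graph(norm, st, err_1e3, threshold=0.0)
        # 9 contexts x 2 realized actions x 3 assigned labels, minus the
        # contexts prescribing D where C never happens
        assert g.number_of_edges() == 54

    def test_node_balance_at_stationarity(self, fixtures_by_name, err_1e3):
        norm = fixtures_by_name["c3p2r2"]
        st = stationary(norm, err_1e3)
        g = transition_graph(norm, st, err_1e3, threshold=0.0)
        for node in g.nodes:
            inflow = sum(d["weight"] for _, v, d in g.edges(data=True) if v == node)
            outflow = sum(d["weight"] for u, _, d in g.edges(data=True) if u == node)
            assert inflow == pytest.approx(outflow, abs=1e-8)

    def test_serialisations(self, fixtures_by_name, err_1e3):
        norm = fixtures_by_name["c1p1r1"]
        st = stationary(norm, err_1e3)
        g = transition_graph(norm, st, err_1e3)
        dot = graph_to_dot(g)
        assert "digraph" in dot and "style=dashed" in dot
        payload = json.loads(graph_to_json(g))
        assert {n["id"] for n in payload["nodes"]} == {"B", "N", "G"}
        assert all(e["weight"] > 0 for e in payload["edges"])


class TestMergeAnnotations:
    def test_table_rows(self):
        spade = parse_norm(
            [f"{x}B:DG:B" for x in "BNG"]
            + [f"{x}N:DG:G" for x in "BNG"]
            + [f"{x}G:CG:B" for x in "BNG"]
        )
        assert merge_annotation(spade) == "spade"
        club = parse_norm(
            [f"{x}B:DG:N" for x in "BNG"]
            + [f"{x}N:CG:B" for x in "BNG"]
            + [f"{x}G:CN:B" for x in "BNG"]
        )
        assert merge_annotation(club) == "club"
        unmarked = parse_norm(
            [f"{x}B:DG:B" for x in "BNG"]
            + [f"{x}N:DB:N" for x in "BNG"]
            + [f"{x}G:CG:B" for x in "BNG"]
        )
        assert merge_annotation(unmarked) is None
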