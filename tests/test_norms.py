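"""Norm representation: parsing, encoding, permutation orbits, families."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from normscan import (
    Norm,
    canonicalize,
    count_assignment_orbits,
    count_joint_orbits,
    leading_eight,
    parse_norm,
    permute_norm,
    second_order_norms,
)
from normscan.norms import all_permutations, merge_labels


def ternary_norms():
    return st.builds(
        Norm.from_ints,
        st.just(3),
        st.integers(min_value=0, max_value=3**18 - 1),
        st.integers(min_value=0, max_value=2**9 - 1),
    )


def binary_norms():
    return st.builds(
        Norm.from_ints,
        st.just(2),
        st.integers(min_value=0, max_value=2**8 - 1),
        st.integers(min_value=0, max_value=2**4 - 1),
    )


class TestParsing:
    def test_round_trip_through_prescriptions(self, fixtures_by_name):
        for name, norm in fixtures_by_name.items():
            again = parse_norm(norm.prescriptions())
            assert again == norm, name

    def test_table_example_entries(self, fixtures_by_name):
        n = fixtures_by_name["c1p1r1"]
        B, N, G = 0, 1, 2
        C, D = 0, 1
        assert n.action[G, G] == C
        assert n.assignment[G, G, C] == G
        assert n.assignment[G, G, D] == B
        assert n.assignment[G, B, D] == G  # justified punishment

    def test_binary_leading_eight_member_parses(self):
        n = parse_norm(["GG:CG:B", "GB:DG:B", "BG:CG:B", "BB:DB:B"])
        assert n.k == 2
        assert n in leading_eight()

    @pytest.mark.parametrize(
        "rows, match",
        [
            (["GG:CG:B", "GG:DB:G", "GB:DG:B", "BG:CG:B"], "duplicate"),
            (["GG:CG:B", "GB:DG:B", "BG:CG:B"], "missing|cannot infer"),
            (["GG:CX:B", "GB:DG:B", "BG:CG:B", "BB:DB:B"], "illegal"),
            (["GGCGB", "GB:DG:B", "BG:CG:B", "BB:DB:B"], "malformed"),
        ],
    )
    def test_malformed_inputs_rejected(self, rows, match):
        with pytest.raises(ValueError, match=match):
            parse_norm(rows)

    def test_missing_pair_reported_when_k_known(self):
        with pytest.raises(ValueError, match="missing"):
            parse_norm(["GG:CG:B", "GB:DG:B", "BG:CG:B"], k=2)

    def test_comments_and_blank_lines_ignored(self, fixtures_by_name):
        from normscan.fixtures import fixture_text
        from normscan.norms import parse_norm_text

        assert parse_norm_text(fixture_text("c1p1r1")) == fixtures_by_name["c1p1r1"]


class TestEncoding:
    @settings(max_examples=100, deadline=None)
    @given(ternary_norms())
    def test_integer_round_trip(self, norm):
        again = Norm.from_ints(3, norm.assignment_int, norm.action_int)
        assert again == norm

    def test_binary_space_is_exactly_covered(self):
        seen = set()
        for a in range(2**8):
            for p in range(2**4):
                seen.add(Norm.from_ints(2, a, p).encode())
        assert len(seen) == 4096

    def test_compact_id_round_trip(self, fixtures_by_name):
        for norm in fixtures_by_name.values():
            assert Norm.from_compact_id(3, norm.compact_id) == norm


class TestPermutations:
    def test_identity_is_neutral(self, fixtures_by_name):
        n = fixtures_by_name["c1p1r1"]
        assert permute_norm(n, (0, 1, 2)) == n

    @settings(max_examples=50, deadline=None)
    @given(ternary_norms(), st.permutations(range(3)))
    def test_inverse_restores(self, norm, sigma):
        inv = tuple(int(i) for i in np.argsort(sigma))
        assert permute_norm(permute_norm(norm, sigma), inv) == norm

    @settings(max_examples=30, deadline=None)
    @given(ternary_norms(), st.permutations(range(3)), st.permutations(range(3)))
    def test_composition(self, norm, s1, s2):
        composed = tuple(s2[s1[i]] for i in range(3))
        assert permute_norm(permute_norm(norm, s1), s2) == permute_norm(norm, composed)

    def test_swap_g_n_on_printed_example(self, fixtures_by_name):
        # relabelling G<->N moves the GG:CG prescription to the NN cell
        p = permute_norm(fixtures_by_name["c1p1r1"], (0, 2, 1))
        assert p.action[1, 1] == 0  # P(N,N) = C
        assert p.assignment[1, 1, 0] == 1  # R(N,N,C) = N


class TestCanonicalization:
    @settings(max_examples=50, deadline=None)
    @given(ternary_norms(), st.permutations(range(3)))
    def test_constant_on_orbits(self, norm, sigma):
        rep1, _ = canonicalize(norm)
        rep2, _ = canonicalize(permute_norm(norm, sigma))
        assert rep1 == rep2

    @settings(max_examples=50, deadline=None)
    @given(ternary_norms())
    def test_idempotent_and_achieving_permutation(self, norm):
        rep, sigma = canonicalize(norm)
        assert permute_norm(norm, sigma) == rep
        again, sigma2 = canonicalize(rep)
        assert again == rep
        assert sigma2 == (0, 1, 2)

    @settings(max_examples=50, deadline=None)
    @given(ternary_norms())
    def test_orbit_sizes_divide_group_order(self, norm):
        orbit = {permute_norm(norm, s).encode() for s in all_permutations(3)}
        assert len(orbit) in (1, 2, 3, 6)


class TestOrbitCounting:
    def test_ternary_assignment_orbits(self):
        assert count_assignment_orbits(3) == 64_573_605
        assert count_assignment_orbits(3) * 2**9 == 33_061_685_760

    def test_binary_burnside_matches_explicit_canonicalization(self):
        canonical = set()
        for a_int in range(2**8):
            norm = Norm.from_ints(2, a_int, 0)
            best = min(
                permute_norm(norm, s).assignment_int for s in all_permutations(2)
            )
            canonical.add(best)
        assert count_assignment_orbits(2) == len(canonical)

    def test_joint_orbits_at_most_assignment_times_actions(self):
        assert count_joint_orbits(2) <= count_assignment_orbits(2) * 2**4
        # explicit joint canonicalization over the full binary space
        reps = set()
        for a in range(2**8):
            for p in range(2**4):
                reps.add(canonicalize(Norm.from_ints(2, a, p))[0].encode())
        assert len(reps) == count_joint_orbits(2)

    def test_sampled_orbit_mass_consistent_with_burnside(self, rng):
        # sum of 1/orbit_size over one representative per orbit equals
        # #orbits; on a uniform sample, k! / orbit_size averages to
        # #orbits * k! / #norms -- check the identity on sampled orbits
        total = 3**18 * 2**9
        n_orbits = count_joint_orbits(3)
        samples = 1000
        inv_sizes = []
        for _ in range(samples):
            norm = Norm.from_ints(
                3, int(rng.integers(3**18)), int(rng.integers(2**9))
            )
            orbit = {permute_norm(norm, s).encode() for s in all_permutations(3)}
            inv_sizes.append(6 / len(orbit))
        est = np.mean(inv_sizes) * total / 6
        assert abs(est - n_orbits) / n_orbits < 0.05


class TestFamilies:
    def test_leading_eight_shared_prescriptions(self):
        norms = leading_eight()
        assert len({n.encode() for n in norms}) == 8
        b, g = 0, 1
        for n in norms:
            assert n.action[g, b] == 1 and n.assignment[g, b, 1] == g
            assert n.assignment[g, g, 1] == b and n.assignment[b, g, 1] == b
            assert n.action[g, g] == 0 and n.assignment[g, g, 0] == g
            assert n.action[b, g] == 0 and n.assignment[b, g, 0] == g
            # dagger rule for the B-B encounter
            coop = n.assignment[b, b, 0] == g and n.assignment[b, b, 1] == b
            assert n.action[b, b] == (0 if coop else 1)

    def test_second_order_count_and_donor_independence(self):
        count = 0
        for n in second_order_norms(3):
            count += 1
            assert (n.assignment[0] == n.assignment[1]).all()
            assert (n.assignment[0] == n.assignment[2]).all()
            assert (n.action[0] == n.action[1]).all()
        assert count == 5832

    def test_table_family_expansion_is_subset_of_second_order(self):
        all_ids = {n.encode() for n in second_order_norms(3)}
        for w1 in "BNG":
            for w2 in "BNG":
                rows = (
                    [f"{x}B:DG:{w1}" for x in "BNG"]
                    + [f"{x}N:DG:{w2}" for x in "BNG"]
                    + [f"{x}G:CG:B" for x in "BNG"]
                )
                assert parse_norm(rows).encode() in all_ids

    def test_merge_labels_consistency(self, fixtures_by_name):
        # a strict merge must either fail or produce a well-formed binary norm
        n = fixtures_by_name["c3p2r2"]
        for pair in [(0, 1), (1, 2)]:
            merged = merge_labels(n, pair)
            assert merged is None or merged.k == 2
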