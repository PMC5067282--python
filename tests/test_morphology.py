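"""Morphometry on traced neurons: SWC I/O, lengths, branchpoints, Sholl, BP90."""

import numpy as np
import pytest

from mitoarbor.morphology import (
    DENDRITES,
    MorphologyError,
    Structure,
    UndefinedValueError,
    bp90,
    branchpoints,
    parse_swc,
    sholl,
    summarize_morphometry,
    total_length,
    write_swc,
)
from mitoarbor.synthetic import TreeModel, generate_tree

from conftest import A, D, S, build_morphology

MINIMAL_SWC = """
# soma with two children
1 1 0 0 0 5 -1
2 3 10 0 0 1 1
3 3 0 10 0 1 1
"""


class TestParseSWC:
    def test_minimal_tree(self):
        morph = parse_swc(MINIMAL_SWC)
        assert len(morph) == 3
        assert morph.root.structure is Structure.SOMA
        assert len(morph.children(1)) == 2

    def test_missing_parent_is_structure_error(self):
        bad = "1 1 0 0 0 5 -1\n2 3 10 0 0 1 99\n"
        with pytest.raises(MorphologyError, match="missing parent 99"):
            parse_swc(bad)

    def test_malformed_line_reports_line_number(self):
        bad = "1 1 0 0 0 5 -1\n2 3 10 0 0 1\n"
        with pytest.raises(MorphologyError, match="line 2"):
            parse_swc(bad)

    def test_cycle_detected(self):
        # two nodes pointing at each other plus a root is disconnected/cyclic
        bad = "1 1 0 0 0 5 -1\n2 3 1 0 0 1 3\n3 3 2 0 0 1 2\n"
        with pytest.raises(MorphologyError):
            parse_swc(bad)

    def test_unknown_code_maps_to_basal_dendrite(self, caplog):
        morph = parse_swc("1 1 0 0 0 5 -1\n2 7 10 0 0 1 1\n")
        assert morph.node(2).structure is Structure.DENDRITE_BASAL

    def test_generated_tree_round_trips(self):
        morph = generate_tree(
            TreeModel(n_primary=2, branch_rate=0.05, segment_length=(12, 4),
                      max_depth=3, seed=42)
        )
        again = parse_swc(write_swc(morph))
        assert len(again) == len(morph)
        for a, b in zip(morph.nodes, again.nodes):
            assert a.node_id == b.node_id
            assert a.structure is b.structure
            assert a.parent_id == b.parent_id
            np.testing.assert_allclose(a.xyz, b.xyz, atol=1e-4)


class TestTotalLength:
    def test_straight_cable_is_45um(self, straight_cable):
        assert total_length(straight_cable, DENDRITES) == pytest.approx(45.0)

    def test_no_axon_means_zero(self, straight_cable):
        assert total_length(straight_cable, {A}) == 0.0

    def test_empty_selection_rejected(self, straight_cable):
        with pytest.raises(ValueError):
            total_length(straight_cable, set())

    def test_matches_brute_force_edge_sum(self):
        morph = generate_tree(TreeModel(n_primary=3, seed=7, max_depth=3,
                                        segment_length=(20, 6)))
        expected = 0.0
        for node in morph.nodes:
            if node.parent_id is None or node.structure not in DENDRITES:
                continue
            parent = morph.node(node.parent_id)
            expected += float(np.linalg.norm(node.xyz - parent.xyz))
        assert total_length(morph, DENDRITES) == pytest.approx(expected, abs=1e-9)

    def test_invariant_under_reindexing(self, binary_tree_depth3):
        base = total_length(binary_tree_depth3, DENDRITES)
        remap = {nid: 100 - nid for nid in range(1, 9)}
        rows = [
            (remap[n.node_id], n.structure, n.x, n.y, n.z, n.radius,
             None if n.parent_id is None else remap[n.parent_id])
            for n in binary_tree_depth3.nodes
        ]
        assert total_length(build_morphology(rows), DENDRITES) == pytest.approx(base)


class TestBranchpoints:
    def test_unbranched_cable_has_none(self, straight_cable):
        assert branchpoints(straight_cable, DENDRITES) == []

    def test_binary_tree_depth3_has_three(self, binary_tree_depth3):
        bps = branchpoints(binary_tree_depth3, DENDRITES)
        assert sorted(nid for nid, _ in bps) == [2, 3, 4]

    def test_soma_is_not_a_branchpoint(self, binary_tree_depth3):
        # soma has one dendritic child here; give it several and re-check
        bps = branchpoints(binary_tree_depth3, DENDRITES)
        assert all(binary_tree_depth3.node(nid).structure in DENDRITES
                   for nid, _ in bps)

    def test_matches_brute_force_child_scan(self):
        morph = generate_tree(TreeModel(n_primary=4, seed=11, max_depth=4,
                                        segment_length=(18, 6)))
        expected = set()
        for node in morph.nodes:
            if node.structure not in DENDRITES:
                continue
            kids = [c for c in morph.children(node.node_id)
                    if c.structure in DENDRITES]
            if len(kids) >= 2:
                expected.add(node.node_id)
        assert {nid for nid, _ in branchpoints(morph, DENDRITES)} == expected


def _sampling_crossings(morph, radii, n_samples=4001):
    """Independent intersection counter: dense sampling of the distance
    function along each edge, counting sign changes against each radius."""
    center = morph.soma_center
    counts = np.zeros(len(radii), dtype=int)
    t = np.linspace(0.0, 1.0, n_samples)
    for parent, child in morph.edges(DENDRITES):
        pts = parent.xyz[None, :] + t[:, None] * (child.xyz - parent.xyz)[None, :]
        d = np.linalg.norm(pts - center, axis=1)
        for k, r in enumerate(radii):
            s = np.sign(d - r)
            counts[k] += int(np.count_nonzero(s[:-1] * s[1:] < 0))
    return counts


class TestSholl:
    def test_straight_cable_all_ones(self, straight_cable):
        profile = sholl(straight_cable, step=10.0, quantity="intersections")
        assert np.all(profile.counts == 1)
        # the cable reaches 45 μm, so the outermost sampled sphere is at 40
        assert profile.shell_edges[-1] == 40.0

    def test_tip_exactly_on_outermost_sphere_counts(self):
        rows = [(1, D, 0.0, 0.0, 0.0, 0.5, None)]
        for i in range(1, 11):
            rows.append((i + 1, D, 10.0 * i, 0.0, 0.0, 0.5, i))
        morph = build_morphology(rows, soma_center=(0, 0, 0))
        profile = sholl(morph, step=10.0, quantity="intersections")
        assert profile.shell_edges[-1] == 100.0
        assert np.all(profile.counts == 1)

    def test_branchpoint_on_shell_edge_goes_outward(self):
        rows = [
            (1, S, 0.0, 0.0, 0.0, 1.0, None),
            (2, D, 10.0, 0.0, 0.0, 1.0, 1),  # branchpoint exactly at r = 10
            (3, D, 20.0, 5.0, 0.0, 1.0, 2),
            (4, D, 20.0, -5.0, 0.0, 1.0, 2),
        ]
        morph = build_morphology(rows, soma_center=(0, 0, 0))
        profile = sholl(morph, step=10.0, quantity="branchpoints")
        # half-open [10, 20): the branchpoint at exactly 10 lands in shell 1
        assert profile.counts[0] == 0
        assert profile.counts[1] == 1

    def test_step_must_be_positive(self, straight_cable):
        with pytest.raises(ValueError):
            sholl(straight_cable, step=0.0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_intersections_match_sampling_oracle(self, seed):
        morph = generate_tree(TreeModel(n_primary=3, branch_rate=0.04,
                                        segment_length=(20, 6), max_depth=4,
                                        tortuosity=0.3, seed=seed))
        step = 7.0
        profile = sholl(morph, step=step, quantity="intersections")
        radii = profile.shell_edges[1:]
        oracle = _sampling_crossings(morph, radii)
        np.testing.assert_array_equal(profile.counts, oracle)

    @pytest.mark.parametrize("seed", [3, 4, 5])
    def test_branchpoint_shell_sums_conserve_count(self, seed):
        morph = generate_tree(TreeModel(seed=seed, max_depth=4,
                                        segment_length=(22, 7)))
        profile = sholl(morph, step=12.0, quantity="branchpoints")
        assert profile.counts.sum() == len(branchpoints(morph, DENDRITES))


class TestBP90:
    def test_all_branchpoints_at_half_max_tip(self):
        rows = [
            (1, S, 0.0, 0.0, 0.0, 1.0, None),
            (2, D, 50.0, 0.0, 0.0, 1.0, 1),   # branchpoint at 50
            (3, D, 100.0, 1.0, 0.0, 1.0, 2),  # tips at ~100
            (4, D, 100.0, -1.0, 0.0, 1.0, 2),
        ]
        morph = build_morphology(rows, soma_center=(0, 0, 0))
        tip_d = np.hypot(100.0, 1.0)
        assert bp90(morph) == pytest.approx(50.0 / tip_d)

    def test_matches_independent_quantile(self):
        # 10 branchpoints at normalized distances 0.05, 0.15, ..., 0.95 along
        # a straight spine with the tip at 100 μm
        rows = [(1, S, 0.0, 0.0, 0.0, 1.0, None)]
        nid = 2
        parent = 1
        positions = np.arange(0.05, 1.0, 0.10) * 100.0
        for x in positions:
            rows.append((nid, D, x, 0.0, 0.0, 1.0, parent))
            rows.append((nid + 1, D, x, 5.0, 0.0, 1.0, nid))  # side twig → branchpoint
            parent = nid
            nid += 2
        rows.append((nid, D, 100.0, 0.0, 0.0, 1.0, parent))  # the tip
        morph = build_morphology(rows, soma_center=(0, 0, 0))
        norm = np.array(sorted(
            morph.radial_distance(b) / 100.0
            for b, _ in branchpoints(morph, DENDRITES)
        ))
        # independent quantile with the same interpolation rule
        h = 0.90 * (len(norm) - 1)
        lo, frac = int(np.floor(h)), h - int(np.floor(h))
        expected = norm[lo] + frac * (norm[lo + 1] - norm[lo])
        assert bp90(morph) == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_similarity_transform(self):
        morph = generate_tree(TreeModel(seed=9, max_depth=4, segment_length=(20, 6)))
        base = bp90(morph)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        rows = []
        for n in morph.nodes:
            xyz = 2.0 * rot @ n.xyz + np.array([13.0, -4.0, 2.0])
            rows.append((n.node_id, n.structure, *xyz, n.radius, n.parent_id))
        moved = build_morphology(rows)
        assert bp90(moved) == pytest.approx(base, abs=1e-9)

    def test_no_branchpoints_is_undefined(self, straight_cable):
        with pytest.raises(UndefinedValueError):
            bp90(straight_cable)


def test_summary_fields_consistent(binary_tree_depth3):
    s = summarize_morphometry(binary_tree_depth3)
    assert s.n_branchpoints == 3
    assert s.n_primary_dendrites == 1
    assert s.total_axonal_length == 0.0
    assert 0 < s.bp90 <= 1
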