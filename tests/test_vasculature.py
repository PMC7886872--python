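import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepasim.vasculature import (
    HEALTHY_VOLUME_RANGE,
    K1_RANGE,
    K2_RANGE,
    TUMOR_VOLUME_RANGE,
    CatheterPlacement,
    generate_liver_phantom,
    generate_tree,
    map_outlets_to_segments,
    node_positions,
    synthesize_observed_distribution,
    tree_from_json,
    tree_to_json,
    validate_tree,
)


class TestGenerateTree:
    def test_symmetric_depth2_radii(self):
        tree = generate_tree(depth=2, root_radius=1e-3, asymmetry=1.0, seed=0)
        assert tree.n_outlets == 2
        expected = 1e-3 * 2.0 ** (-1.0 / 3.0)
        for out in tree.outlet_ids:
            assert tree.nodes[out].radius == pytest.approx(expected, rel=1e-12)

    def test_deterministic_serialization(self):
        a = tree_to_json(generate_tree(depth=4, root_radius=2e-3, seed=7))
        b = tree_to_json(generate_tree(depth=4, root_radius=2e-3, seed=7))
        assert a == b

    @pytest.mark.parametrize("seed", range(5))
    def test_branching_law_at_every_bifurcation(self, seed):
        tree = generate_tree(depth=5, root_radius=3e-3, asymmetry=0.6,
                             seed=seed)
        m = tree.murray_exponent
        for node in tree.nodes.values():
            if len(node.daughter_ids) == 2:
                rhs = sum(tree.nodes[d].radius**m for d in node.daughter_ids)
                assert rhs == pytest.approx(node.radius**m, rel=1e-6)

    def test_outlet_count_full_binary(self):
        for depth in (2, 3, 4, 5):
            tree = generate_tree(depth=depth, root_radius=1e-3, seed=1)
            assert tree.n_outlets == 2 ** (depth - 1)

    def test_radii_decrease_along_paths(self):
        tree = generate_tree(depth=5, root_radius=3e-3, asymmetry=0.5, seed=3)
        for node in tree.nodes.values():
            for d in node.daughter_ids:
                assert tree.nodes[d].radius < node.radius

    def test_generated_trees_validate(self):
        for seed in range(10):
            validate_tree(generate_tree(depth=4, root_radius=2e-3,
                                        asymmetry=0.7, seed=seed))

    @pytest.mark.parametrize("kwargs", [
        {"depth": 1, "root_radius": 1e-3},
        {"depth": 4, "root_radius": 0.0},
        {"depth": 4, "root_radius": 1e-3, "asymmetry": 0.0},
    ])
    def test_rejects_bad_inputs(self, kwargs):
        with pytest.raises(ValueError):
            generate_tree(**kwargs)

    def test_json_round_trip(self):
        tree = generate_tree(depth=4, root_radius=2e-3, asymmetry=0.8, seed=5)
        text = tree_to_json(tree)
        back = tree_from_json(text)
        assert tree_to_json(back) == text

    def test_positions_are_connected(self):
        tree = generate_tree(depth=3, root_radius=2e-3, seed=2)
        pos = node_positions(tree)
        for node in tree.nodes.values():
            start, end = pos[node.id]
            assert np.linalg.norm(end - start) == pytest.approx(node.length)
            for d in node.daughter_ids:
                assert np.allclose(pos[d][0], end)


class TestLiverPhantom:
    def test_no_tumors(self):
        segments, tumors, _ = generate_liver_phantom(0, seed=0)
        assert tumors == []
        assert all(r.tumor_volume == 0.0 for r in segments)
        assert len(segments) == 8

    def test_deterministic(self):
        a = generate_liver_phantom(3, seed=11)
        b = generate_liver_phantom(3, seed=11)
        assert a == b

    def test_envelopes_over_seed_sweep(self):
        for seed in range(1000):
            segments, tumors, perfusion = generate_liver_phantom(
                seed % 4, seed=seed)
            for r in segments:
                assert HEALTHY_VOLUME_RANGE[0] <= r.healthy_volume <= HEALTHY_VOLUME_RANGE[1]
                assert TUMOR_VOLUME_RANGE[0] <= r.tumor_volume <= TUMOR_VOLUME_RANGE[1]
            for t in tumors:
                assert K2_RANGE[0] <= t.k2 <= K2_RANGE[1]
                assert sum(t.host_segments.values()) == pytest.approx(
                    t.total_volume, rel=1e-9)
            for v in perfusion.k1_healthy.values():
                assert K1_RANGE[0] <= v <= K1_RANGE[1]

    def test_rejects_negative_tumors(self):
        with pytest.raises(ValueError):
            generate_liver_phantom(-1, seed=0)


class TestOutletMapping:
    def test_bijection_with_matching_counts(self):
        tree = generate_tree(depth=4, root_radius=2e-3, seed=0)  # 8 outlets
        segments, _, _ = generate_liver_phantom(0, seed=0)
        mapping = map_outlets_to_segments(tree, segments, seed=0)
        assert sorted(mapping) == sorted(tree.outlet_ids)
        assert sorted(mapping.values()) == sorted(r.segment for r in segments)

    def test_surplus_outlets_all_segments_covered(self):
        tree = generate_tree(depth=5, root_radius=2e-3, seed=0)  # 16 outlets
        segments, _, _ = generate_liver_phantom(0, seed=0)
        mapping = map_outlets_to_segments(tree, segments, seed=0)
        counts = {r.segment: 0 for r in segments}
        for seg in mapping.values():
            counts[seg] += 1
        assert all(c >= 1 for c in counts.values())
        assert sum(counts.values()) == 16

    def test_zero_volume_segment_gets_no_outlet(self):
        from hepasim.vasculature import LiverSegmentRecord
        segments = [LiverSegmentRecord(f"S{i}", 100.0) for i in range(1, 9)]
        segments.append(LiverSegmentRecord("S9", 0.0))
        tree = generate_tree(depth=4, root_radius=2e-3, seed=0)
        mapping = map_outlets_to_segments(tree, segments, seed=0)
        assert "S9" not in mapping.values()
        covered = set(mapping.values())
        assert covered == {f"S{i}" for i in range(1, 9)}

    def test_too_few_outlets_rejected(self):
        tree = generate_tree(depth=3, root_radius=2e-3, seed=0)  # 4 outlets
        segments, _, _ = generate_liver_phantom(0, seed=0)
        with pytest.raises(ValueError):
            map_outlets_to_segments(tree, segments, seed=0)


class TestSynthesizeObserved:
    TRUTH = {"S1": 20.0, "S2": 15.0, "S3": 10.0, "S4": 5.0,
             "S5": 12.5, "S6": 12.5, "S7": 12.5, "S8": 12.5}

    def test_zero_noise_is_identity(self):
        obs = synthesize_observed_distribution(self.TRUTH, 0.0, seed=1)
        assert obs.percent == self.TRUTH

    def test_clamping_and_renormalization(self):
        truth = {"S1": 100.0} | {f"S{i}": 0.0 for i in range(2, 9)}
        obs = synthesize_observed_distribution(truth, 0.5, seed=3)
        assert all(v >= 0 for v in obs.percent.values())
        assert sum(obs.percent.values()) == pytest.approx(100.0, abs=1e-9)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthesize_observed_distribution(self.TRUTH, -1.0, seed=0)

    def test_mean_abs_deviation_matches_folded_normal(self):
        # after renormalization the per-segment deviation is approximately
        # N(0, sigma^2 (1 + k p_i^2 - 2 p_i)); compare mean |deviation|
        # against the folded-normal expectation over 10^4 replicates
        sigma = 2.0
        keys = sorted(self.TRUTH)
        p = np.array([self.TRUTH[k] for k in keys]) / 100.0
        sd = sigma * np.sqrt(1.0 + len(p) * p**2 - 2.0 * p)
        expected = sd * math.sqrt(2.0 / math.pi)
        acc = np.zeros(len(keys))
        n_rep = 10_000
        for i in range(n_rep):
            obs = synthesize_observed_distribution(self.TRUTH, sigma, seed=i)
            acc += np.abs([obs.percent[k] - self.TRUTH[k] for k in keys])
        emp = acc / n_rep
        assert np.all(np.abs(emp - expected) < 0.06 * expected + 0.02)


class TestCatheterPlacement:
    def test_lumen_must_fit(self):
        c = CatheterPlacement("v", 0.5, 0.9, 0.0, 1.0, 0.5, 5e-4)
        with pytest.raises(ValueError):
            c.check_fits(2e-3)

    def test_centered_fits(self):
        CatheterPlacement("v", 0.5, 0.0, 0.0, 1.0, 0.5, 5e-4).check_fits(2e-3)

    @given(st.floats(min_value=1.0, max_value=2.0))
    @settings(max_examples=20, deadline=None)
    def test_negative_velocity_rejected(self, v):
        with pytest.raises(ValueError):
            CatheterPlacement("v", 0.5, 0.0, 0.0, -v, 0.5, 5e-4)
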