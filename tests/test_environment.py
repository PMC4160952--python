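"""Room geometry, stimulus conditions and distance measures."""

import itertools

import numpy as np
import pytest

from cogmap import environment as env


class TestHeading:
    def test_printed_exemplar_labels(self, room):
        assert env.heading_of("P1", "V6", room) == "S"
        assert env.heading_of("P6", "V8", room) == "E"

    def test_due_north_view(self, room):
        # P6 is the south-side midpoint, P1 the north-side midpoint above it
        assert env.heading_of("P6", "V1", room) == "N"

    def test_same_location_is_undefined(self, room):
        with pytest.raises(env.UndefinedBearingError):
            env.heading_of("P3", "V3", room)

    def test_quantization_tie_goes_to_lower_bin(self):
        assert env._quantize_heading(22.5) == "N"
        assert env._quantize_heading(67.5) == "NE"
        assert env._quantize_heading(23.0) == "NE"

    def test_consistent_with_packaged_set(self, room, stimuli):
        for snap in stimuli:
            assert snap.heading == env.heading_of(snap.place_id, snap.view_id, room)


class TestDistances:
    def test_place_distance_examples(self, room):
        assert env.place_distance("P3", "P3", room) == 0.0
        # corner (0,0) = P7 to adjacent south-side midpoint (1,0) = P6
        assert env.place_distance("P7", "P6", room) == pytest.approx(1.0)
        # diagonal corners of the side-2 square
        assert env.view_distance("V7", "V2", room) == pytest.approx(2 * np.sqrt(2))

    @pytest.mark.parametrize("pair", [("N", "N", 0), ("N", "S", 180), ("N", "NW", 45), ("NE", "W", 135)])
    def test_heading_distance(self, pair):
        h1, h2, expected = pair
        assert env.heading_distance(h1, h2) == expected

    def test_metric_properties(self, room):
        labels = list(room.place_coords)
        for p, q, r in itertools.islice(itertools.permutations(labels, 3), 80):
            dpq = env.place_distance(p, q, room)
            assert dpq == env.place_distance(q, p, room)
            assert dpq >= 0
            assert (dpq == 0) == (p == q)
            assert dpq <= env.place_distance(p, r, room) + env.place_distance(r, q, room) + 1e-12
        for h1, h2 in itertools.product(env.COMPASS, repeat=2):
            d = env.heading_distance(h1, h2)
            assert 0 <= d <= 180
            assert d == env.heading_distance(h2, h1)


class TestVisibility:
    def test_exemplar_visible_sets_share_l4_l5(self, room):
        a = env.visible_landmarks("P1", "V6", room)
        b = env.visible_landmarks("P6", "V8", room)
        assert {"L4", "L5"} <= a
        assert a & b == {"L4", "L5"}

    def test_full_fov_sees_everything_not_at_camera(self, room):
        vis = env.visible_landmarks("P3", "V5", room, fov=360.0)
        assert vis == set(room.landmark_positions)

    def test_landmark_behind_camera_excluded(self, room):
        # camera at north midpoint looking south: north-wall landmarks behind
        vis = env.visible_landmarks("P1", "V6", room, fov=74.0)
        assert "L1" not in vis and "L2" not in vis


class TestLandmarkSimilarity:
    def test_worked_example_count_is_two(self, stimuli):
        a = stimuli[stimuli.condition_of("P1", "V6")]
        b = stimuli[stimuli.condition_of("P6", "V8")]
        assert env.landmark_similarity(a, b, "count") == 2.0

    def test_self_similarity_and_variants(self, stimuli):
        a = stimuli[1]
        assert env.landmark_similarity(a, a, "count") == len(a.visible_landmarks)
        assert env.landmark_similarity(a, a, "proportion") == 1.0
        assert env.landmark_similarity(a, a, "binary") == 1.0

    def test_disjoint_sets_binary_zero(self, stimuli):
        pairs = itertools.combinations(stimuli, 2)
        disjoint = [(a, b) for a, b in pairs if not (a.visible_landmarks & b.visible_landmarks)]
        assert disjoint, "reference set should contain disjoint visible sets"
        a, b = disjoint[0]
        assert env.landmark_similarity(a, b, "binary") == 0.0
        assert env.landmark_similarity(a, b, "count") == 0.0

    def test_symmetry(self, stimuli):
        a, b = stimuli[3], stimuli[17]
        for variant in ("count", "proportion", "binary"):
            assert env.landmark_similarity(a, b, variant) == env.landmark_similarity(b, a, variant)


class TestLandmarkDistribution:
    def test_shape_and_bounds(self, stimuli):
        for entity in ("P1", "V6"):
            v = env.landmark_distribution(entity, stimuli)
            n_snaps = sum(
                1 for s in stimuli if (s.place_id if entity[0] == "P" else s.view_id) == entity
            )
            assert v.shape == (8,)
            assert (v >= 0).all() and (v <= n_snaps).all()

    def test_unknown_entity(self, stimuli):
        with pytest.raises(KeyError):
            env.landmark_distribution("X1", stimuli)

    def test_corresponding_views_less_similar_on_average(self, stimuli):
        # brute force over all 28 place pairs: distance to the corresponding
        # view's landmark distribution exceeds the non-corresponding one
        locs = [f"{i}" for i in range(1, 9)]
        p = {l: env.landmark_distribution(f"P{l}", stimuli) for l in locs}
        v = {l: env.landmark_distribution(f"V{l}", stimuli) for l in locs}
        diffs = []
        for a, b in itertools.combinations(locs, 2):
            corr = 0.5 * (np.linalg.norm(p[a] - v[a]) + np.linalg.norm(p[b] - v[b]))
            nonc = 0.5 * (np.linalg.norm(p[a] - v[b]) + np.linalg.norm(p[b] - v[a]))
            diffs.append(corr - nonc)
        assert np.mean(diffs) > 0


class TestStimulusSet:
    def test_coverage_invariants(self, stimuli):
        assert len(stimuli) == 32
        assert {s.place_id for s in stimuli} == {f"P{i}" for i in range(1, 9)}
        assert {s.view_id for s in stimuli} == {f"V{i}" for i in range(1, 9)}
        assert {s.heading for s in stimuli} == set(env.COMPASS)
        assert all(s.place_id[1:] != s.view_id[1:] for s in stimuli)

    def test_heading_collinearity_matches_reported_design(self, stimuli):
        H = stimuli.pairwise("heading")
        P = stimuli.pairwise("place")
        V = stimuli.pairwise("view")
        off = ~np.eye(len(stimuli), dtype=bool)
        rhp = np.corrcoef(H[off], P[off])[0, 1]
        rhv = np.corrcoef(H[off], V[off])[0, 1]
        assert rhp > 0 and rhv > 0
        assert rhp == pytest.approx(0.18, abs=0.05)
        assert rhv == pytest.approx(0.39, abs=0.05)

    def test_duplicate_snapshot_rejected(self, room, stimuli):
        snaps = stimuli.snapshots + (stimuli.snapshots[0],)
        with pytest.raises(ValueError, match="duplicate"):
            env.StimulusSet(snapshots=snaps, room=room)

    def test_room_invariant_violations_detected(self):
        with pytest.raises(ValueError, match="wall"):
            env.RoomModel(
                side_length=2.0,
                place_coords={f"P{i+1}": c for i, c in enumerate(
                    [(0, 0), (2, 0), (2, 2), (0, 2), (1, 0), (2, 1), (1, 2), (0, 1)])},
                view_coords={f"V{i+1}": c for i, c in enumerate(
                    [(0, 0), (2, 0), (2, 2), (0, 2), (1, 0), (2, 1), (1, 2), (0, 1)])},
                landmark_positions={"L1": (1.0, 1.0)},
            )
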