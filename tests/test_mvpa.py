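"""Pattern estimation, SVM-RFE decoding, searchlight and cross-decoding."""

import numpy as np
import pytest

from cogmap import mvpa
from cogmap import synthgen as sg
from cogmap.environment import SnapshotSpec, StimulusSet
from cogmap.mvpa import PatternEstimate, RfeSpec


def _patterns_from_code(code, n_runs=3, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = code.mean_pattern.T  # (n_cond, n_vox)
    runs = [base + noise * rng.standard_normal(base.shape) for _ in range(n_runs)]
    return PatternEstimate(betas=np.stack(runs), run_ids=list(range(n_runs)))


@pytest.fixture(scope="module")
def place_code(room, stimuli):
    return sg.make_population_code(64, room, stimuli, mixture_weights=(1, 0, 0),
                                   tuning_widths=(0.4, 0.4, 60.0), seed=0)


class TestPatternEstimation:
    def test_noiseless_round_trip_and_run_count(self, room, stimuli):
        ds = sg.make_cohort(
            n_subjects=1, n_runs=2, trials_per_run=176, n_voxels=27,
            noise=sg.NoiseSpec(sigma=0.0, rho=0.0, drift_amplitude=0.0),
            room=room, stimuli=stimuli, seed=3, miss_rate=0.0,
        )
        pat = mvpa.estimate_condition_patterns(ds.subjects[0])
        assert pat.n_runs == 2
        assert np.abs(pat.betas - ds.subjects[0].code.mean_pattern.T[None]).max() < 1e-6

    def test_single_run_rejected(self, room, stimuli):
        ds = sg.make_cohort(n_subjects=1, n_runs=1, trials_per_run=176, n_voxels=8,
                            room=room, stimuli=stimuli, seed=1)
        with pytest.raises(ValueError, match="two runs"):
            mvpa.estimate_condition_patterns(ds.subjects[0])


class TestPairwiseDecode:
    def test_separable_patterns_decode_perfectly(self, stimuli, place_code):
        pat = _patterns_from_code(place_code, noise=0.01)
        res = mvpa.pairwise_decode(pat, "place", stimuli, rfe=None)
        assert res.mean_accuracy == 1.0
        assert len(res.pair_accuracy) == 28

    def test_permuted_patterns_are_at_chance(self, stimuli, place_code):
        rng = np.random.default_rng(5)
        pat = _patterns_from_code(place_code, noise=0.3, seed=2)
        # destroy condition identity independently per run
        shuffled = np.stack([pat.betas[r][rng.permutation(32)] for r in range(pat.n_runs)])
        res = mvpa.pairwise_decode(
            PatternEstimate(betas=shuffled, run_ids=pat.run_ids), "place", stimuli, rfe=None
        )
        # 95% binomial band around 0.5 for the number of test decisions
        n_tests = 28 * 3 * 8
        half_width = 1.96 * np.sqrt(0.25 / n_tests)
        assert abs(res.mean_accuracy - 0.5) < 3 * half_width

    def test_voxel_permutation_invariance(self, stimuli, place_code):
        pat = _patterns_from_code(place_code, noise=0.2, seed=3)
        perm = np.random.default_rng(0).permutation(pat.betas.shape[2])
        permuted = PatternEstimate(betas=pat.betas[:, :, perm], run_ids=pat.run_ids)
        a = mvpa.pairwise_decode(pat, "view", stimuli, rfe=None)
        b = mvpa.pairwise_decode(permuted, "view", stimuli, rfe=None)
        assert a.mean_accuracy == pytest.approx(b.mean_accuracy)

    def test_test_set_cannot_leak_into_training(self, stimuli, place_code):
        # corrupting the held-out run's patterns must leave accuracy on other
        # folds untouched: compare per-fold agreement via full determinism
        pat = _patterns_from_code(place_code, noise=0.2, seed=4)
        res1 = mvpa.pairwise_decode(pat, "place", stimuli, rfe=RfeSpec())
        res2 = mvpa.pairwise_decode(pat, "place", stimuli, rfe=RfeSpec())
        assert res1.pair_accuracy["accuracy"].tolist() == res2.pair_accuracy["accuracy"].tolist()

    def test_rfe_levels_schedule(self):
        assert RfeSpec().levels(100) == [100, 50, 25, 12, 10]
        assert RfeSpec().levels(10)[-1] == 1


class TestMatchedView:
    def test_reference_set_matches_corners_and_sides(self, stimuli, place_code):
        pat = _patterns_from_code(place_code, noise=0.2, seed=5)
        res = mvpa.matched_view_place_decode(pat, stimuli, rfe=None)
        assert res.mean_accuracy > 0.5
        assert len(res.pair_accuracy) + len(res.skipped_pairs) == 28
        assert len(res.skipped_pairs) > 0

    def test_restriction_never_increases_exemplars(self, stimuli):
        by_place = stimuli.groups("place")
        import itertools

        for a, b in itertools.combinations(sorted(by_place), 2):
            va = {stimuli[c].view_id for c in by_place[a]}
            vb = {stimuli[c].view_id for c in by_place[b]}
            assert len(va & vb) <= min(len(by_place[a]), len(by_place[b]))


class TestSearchlight:
    def test_sphere_size_matches_brute_force(self):
        offs = mvpa.sphere_offsets(4.5, 3.0)
        brute = sum(
            1
            for i in range(-3, 4)
            for j in range(-3, 4)
            for k in range(-3, 4)
            if (i**2 + j**2 + k**2) * 3.0**2 <= 4.5**2
        )
        assert len(offs) == brute == 19

    def test_informative_region_lights_up(self, stimuli):
        rng = np.random.default_rng(0)
        nx = ny = nz = 6
        n_runs, n_cond = 3, 32
        vol = rng.standard_normal((n_runs, n_cond, nx, ny, nz)) * 0.5
        # plant condition-discriminative signal in a corner cube
        signal = rng.standard_normal((n_cond, 2, 2, 2)) * 3.0
        vol[:, :, :2, :2, :2] += signal[None]
        groups = stimuli.groups("place")

        def op(neigh):
            flat = neigh.reshape(n_runs, n_cond, -1)
            pe = PatternEstimate(betas=flat, run_ids=list(range(n_runs)))
            return mvpa.pairwise_decode(pe, "place", stimuli, rfe=None).mean_accuracy

        mask = np.zeros((nx, ny, nz), bool)
        mask[1, 1, 1] = True
        mask[4, 4, 4] = True
        out = mvpa.searchlight(vol, op, radius_mm=4.5, voxel_size_mm=3.0, mask=mask)
        assert out[1, 1, 1] > out[4, 4, 4]
        assert out[1, 1, 1] > 0.8

    def test_border_spheres_are_clipped_not_empty(self):
        vol = np.zeros((2, 4, 3, 3, 3))
        sizes = []

        def op(neigh):
            sizes.append(neigh.shape[2])
            return float(neigh.shape[2])

        out = mvpa.searchlight(vol, op, radius_mm=4.5, voxel_size_mm=3.0)
        assert np.nanmin(out) > 0
        assert np.nanmax(out) <= 19
        assert out[0, 0, 0] < 19  # corner sphere clipped

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            mvpa.searchlight(np.zeros((1, 2, 2, 2, 2)), lambda n: 0.0,
                             mask=np.zeros((2, 2, 2), bool))


class TestCrossDecode:
    def test_identical_place_view_patterns_cross_decode(self, room, stimuli):
        # location code only: standing at and looking at a location share
        # the same pattern component
        code = sg.make_population_code(
            64, room, stimuli, mixture_weights=(0, 0, 0), location_code_weight=1.0,
            location_width=0.3, seed=1,
        )
        pat = _patterns_from_code(code, noise=0.02, seed=1)
        res = mvpa.cross_decode(pat, stimuli)
        assert res["place_to_view"].mean_accuracy > 0.9
        assert res["view_to_place"].mean_accuracy > 0.9

    def test_independent_codes_stay_near_chance(self, room, stimuli):
        code = sg.make_population_code(
            64, room, stimuli, mixture_weights=(1, 1, 0), tuning_widths=(0.3, 0.3, 60.0), seed=2,
        )
        pat = _patterns_from_code(code, noise=0.1, seed=2)
        res = mvpa.cross_decode(pat, stimuli)
        for r in res.values():
            assert abs(r.mean_accuracy - 0.5) < 0.1


class TestLandmarkConfound:
    def test_reference_set_direction_is_positive(self, stimuli):
        t, df = mvpa.landmark_confound_check(stimuli)
        assert t > 0
        assert len(df) == 28

    def test_identical_distributions_give_zero(self, room):
        # two places, each looking at the other: symmetric visibility makes
        # every distribution comparison degenerate
        snaps = (
            SnapshotSpec("P1", "V6", "S", frozenset({"L5"})),
            SnapshotSpec("P6", "V1", "N", frozenset({"L5"})),
        )
        t, df = mvpa.landmark_confound_check(StimulusSet(snapshots=snaps, room=None))
        assert t == 0.0
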