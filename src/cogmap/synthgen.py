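"""Synthetic multivoxel BOLD with planted place/view/heading codes.

Each simulated voxel carries Gaussian spatial tuning to a preferred place
and a preferred viewed location (widths in room units) and wrapped-Gaussian
tuning to a preferred heading (period 360 deg), mimicking place, spatial
view and head-direction cells. The voxel-by-condition mean pattern induces
pattern similarity that decays with physical distance — the map-like
structure the downstream analyses are designed to detect. Trial amplitudes
implement repetition suppression (exact repeats) and distance-dependent
adaptation, linear in the within-run z-scored change covariates so that the
GLM's linear modulator is the correctly specified estimand. Runs are the
carry-over sequences of the paradigm, convolved with the canonical HRF and
corrupted by sinusoidal drift and AR(1) Gaussian noise.

Voxels live on a 3-D grid so searchlight mapping and volumetric I/O can be
exercised; ROIs are boolean masks over this grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .environment import RoomModel, StimulusSet
from .glm import canonical_hrf
from .sequence import (
    LabeledSequence,
    TimingSpec,
    Trial,
    generate_carryover_sequence,
    label_trials,
    pair_regressors,
    runs_to_events,
)

__all__ = [
    "PopulationCode",
    "AdaptationSpec",
    "NoiseSpec",
    "SubjectData",
    "SyntheticDataset",
    "make_population_code",
    "simulate_run",
    "make_cohort",
]


@dataclass
class PopulationCode:
    """Voxel-by-condition mean responses plus the tuning that produced them."""

    mean_pattern: np.ndarray  # (n_voxels, n_conditions)
    preferred_place: np.ndarray  # (n_voxels, 2)
    preferred_view: np.ndarray  # (n_voxels, 2)
    preferred_heading: np.ndarray  # (n_voxels,) degrees
    gains: np.ndarray
    grid_shape: tuple[int, int, int]

    @property
    def n_voxels(self) -> int:
        return self.mean_pattern.shape[0]


@dataclass(frozen=True)
class AdaptationSpec:
    """Trial-amplitude model: suppression for exact repeats and linear gain
    per unit (z-scored) change; positive slopes mean larger responses for
    larger changes (release from adaptation)."""

    repeat_suppression: float = 0.0
    slope_place: float = 0.0
    slope_view: float = 0.0
    slope_heading: float = 0.0
    slope_texture: float = 0.0
    slope_landmark: float = 0.0


@dataclass(frozen=True)
class NoiseSpec:
    sigma: float = 1.0
    rho: float = 0.3
    drift_amplitude: float = 0.0
    drift_period: float = 300.0

    def __post_init__(self) -> None:
        if not (0 <= self.rho < 1):
            raise ValueError("rho must be in [0, 1)")


@dataclass
class SubjectData:
    """One subject: a population code and its simulated runs."""

    code: PopulationCode
    runs: list[np.ndarray]  # each (n_scans, n_voxels)
    sequence: LabeledSequence
    tr: float
    seed: int


@dataclass
class SyntheticDataset:
    subjects: list[SubjectData]
    stimuli: StimulusSet = field(repr=False)
    room: RoomModel = field(repr=False)
    adapt: AdaptationSpec = AdaptationSpec()
    noise: NoiseSpec = NoiseSpec()
    master_seed: int = 0

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def to_bids(self, out_dir: str | Path) -> None:
        """Write 4-D NIfTI volumes, events tables and a ground-truth manifest."""
        import nibabel as nib

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for s, subj in enumerate(self.subjects):
            sdir = out / f"sub-{s+1:02d}"
            sdir.mkdir(exist_ok=True)
            gx, gy, gz = subj.code.grid_shape
            for r, Y in enumerate(subj.runs):
                vol = Y.T.reshape(gx, gy, gz, Y.shape[0])
                nib.save(
                    nib.Nifti1Image(vol.astype(np.float32), affine=np.eye(4) * 3.0),
                    sdir / f"sub-{s+1:02d}_run-{r+1}_bold.nii.gz",
                )
            ev = runs_to_events(subj.sequence.runs)
            ev.to_csv(sdir / f"sub-{s+1:02d}_events.tsv", sep="\t", index=False)
        manifest = {
            "master_seed": self.master_seed,
            "n_subjects": self.n_subjects,
            "adaptation": asdict(self.adapt),
            "noise": asdict(self.noise),
            "subject_seeds": [s.seed for s in self.subjects],
        }
        (out / "ground_truth.json").write_text(json.dumps(manifest, indent=2))


def _wrapped_gaussian(delta_deg: np.ndarray, sigma: float) -> np.ndarray:
    acc = np.zeros_like(delta_deg, dtype=float)
    for k in (-1, 0, 1):
        acc += np.exp(-((delta_deg + 360.0 * k) ** 2) / (2 * sigma**2))
    return acc


def make_population_code(
    n_voxels: int,
    room: RoomModel,
    stimuli: StimulusSet,
    tuning_widths: tuple[float, float, float] = (0.8, 0.8, 60.0),
    mixture_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    seed: int = 0,
    location_code_weight: float = 0.0,
    location_width: float = 0.8,
    baseline: float = 0.1,
    equalize_condition_means: bool = True,
    grid_shape: tuple[int, int, int] | None = None,
) -> PopulationCode:
    """Draw a voxel population tuned to place, view and heading.

    The population is a mixture of distinct cell types, mirroring the
    physiology the paradigm probes: *place cells* (Gaussian tuning to the
    observer's location), *spatial view cells* (Gaussian tuning to the viewed
    location), *head-direction cells* (wrapped-Gaussian tuning to heading,
    period 360 deg) and, when ``location_code_weight > 0``, *location cells*
    that respond both when the observer stands at their preferred location
    and when the camera aims at it — the substrate for place/view
    cross-decoding. ``mixture_weights`` are the relative population
    proportions of the three feature-specific types; a zero weight silences
    that feature entirely (e.g. ``(1, 0, 0)`` is a place-only code).
    """
    if n_voxels < 1:
        raise ValueError("need at least one voxel")
    sp, sv, sh = tuning_widths
    if sp <= 0 or sv <= 0 or sh <= 0:
        raise ValueError("tuning widths must be positive")
    rng = np.random.default_rng(seed)
    s = room.side_length
    # preferred locations extend one tuning width beyond the walls so that
    # corner places are not under-represented by boundary truncation
    mp, mv = min(sp, s), min(sv, s)
    pref_p = rng.uniform(-mp, s + mp, size=(n_voxels, 2))
    pref_v = rng.uniform(-mv, s + mv, size=(n_voxels, 2))
    pref_h = rng.uniform(0, 360.0, size=n_voxels)
    gains = rng.uniform(0.5, 1.5, size=n_voxels)
    w = np.array([max(0.0, float(x)) for x in mixture_weights] + [max(0.0, location_code_weight)])
    if w.sum() <= 0:
        raise ValueError("at least one mixture weight must be positive")
    types = rng.choice(4, size=n_voxels, p=w / w.sum())

    n_cond = stimuli.n_conditions
    pattern = np.zeros((n_voxels, n_cond))
    norm_h = _wrapped_gaussian(np.zeros(1), sh)[0]
    for j, snap in enumerate(stimuli):
        ppos = np.asarray(room.place_coords[snap.place_id], float)
        vpos = np.asarray(room.view_coords[snap.view_id], float)
        hdeg = room.heading_degrees(snap.heading)
        dh = (pref_h - hdeg + 180.0) % 360.0 - 180.0
        resp_place = np.exp(-((pref_p - ppos) ** 2).sum(1) / (2 * sp**2))
        resp_view = np.exp(-((pref_v - vpos) ** 2).sum(1) / (2 * sv**2))
        resp_head = _wrapped_gaussian(dh, sh) / norm_h
        # location cells reuse the preferred-place field for both roles
        resp_loc = 0.5 * (
            np.exp(-((pref_p - ppos) ** 2).sum(1) / (2 * location_width**2))
            + np.exp(-((pref_p - vpos) ** 2).sum(1) / (2 * location_width**2))
        )
        resp = np.choose(types, [resp_place, resp_view, resp_head, resp_loc])
        pattern[:, j] = baseline + gains * resp
    if equalize_condition_means and n_voxels > 1:
        # remove the uniform (voxel-average) component per condition so the
        # region-average univariate response is condition-balanced: amplitude
        # effects planted later are then the only univariate signal, matching
        # the single-trial-type adaptation models
        pattern += pattern.mean() - pattern.mean(axis=0, keepdims=True)
    if grid_shape is None:
        side = int(np.ceil(n_voxels ** (1 / 3)))
        grid_shape = (side, side, max(1, int(np.ceil(n_voxels / side**2))))
    gx, gy, gz = grid_shape
    if gx * gy * gz != n_voxels:
        pad = gx * gy * gz - n_voxels
        if pad < 0:
            raise ValueError("grid smaller than voxel count")
        pattern = np.vstack([pattern, np.zeros((pad, n_cond))])
        pref_p = np.vstack([pref_p, np.zeros((pad, 2))])
        pref_v = np.vstack([pref_v, np.zeros((pad, 2))])
        pref_h = np.concatenate([pref_h, np.zeros(pad)])
        gains = np.concatenate([gains, np.zeros(pad)])
    return PopulationCode(
        mean_pattern=pattern,
        preferred_place=pref_p,
        preferred_view=pref_v,
        preferred_heading=pref_h,
        gains=gains,
        grid_shape=grid_shape,
    )


def _zscore_or_zero(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)


def trial_amplitudes(
    run: Sequence[Trial],
    labels: dict[int, str],
    changes: dict[int, "PairChange"],
    adapt: AdaptationSpec,
) -> dict[int, float]:
    """Per-target-trial amplitude under the adaptation model.

    Base amplitude 1; exact repeats are suppressed multiplicatively; the
    change covariates (z-scored within run over the trials that have them)
    scale the amplitude linearly. Amplitudes are clipped at 0.05 so the
    resulting responses stay positive.
    """
    # distance modulation applies to included non-identical repeats; exact
    # repeats get only the suppression factor
    idx = sorted(i for i in changes if labels.get(i) != "all_same")
    amp = {t.index: 1.0 for t in run if t.kind == "target"}
    if idx:
        z = {
            "place": _zscore_or_zero(np.array([changes[i].place_change for i in idx])),
            "view": _zscore_or_zero(np.array([changes[i].view_change for i in idx])),
            "heading": _zscore_or_zero(np.array([changes[i].heading_change for i in idx])),
            "texture": _zscore_or_zero(np.array([changes[i].texture_change for i in idx])),
            "landmark": _zscore_or_zero(np.array([changes[i].landmark_similarity for i in idx])),
        }
        slopes = {
            "place": adapt.slope_place,
            "view": adapt.slope_view,
            "heading": adapt.slope_heading,
            "texture": adapt.slope_texture,
            "landmark": adapt.slope_landmark,
        }
        for k, i in enumerate(idx):
            mod = 1.0
            for name, slope in slopes.items():
                if slope:
                    mod += slope * z[name][k]
            amp[i] *= mod
    for t in run:
        if t.kind == "target" and labels.get(t.index) == "all_same":
            amp[t.index] *= 1.0 - adapt.repeat_suppression
    return {i: max(a, 0.05) for i, a in amp.items()}


def simulate_run(
    code: PopulationCode,
    run: Sequence[Trial],
    labels: dict[int, str],
    changes: dict[int, "PairChange"],
    adapt: AdaptationSpec,
    noise: NoiseSpec,
    tr: float = 1.914,
    seed: int = 0,
    n_scans: int | None = None,
    oversampling: int = 16,
    hrf_kwargs: dict | None = None,
) -> np.ndarray:
    """Simulate one run's (n_scans, n_voxels) BOLD matrix."""
    rng = np.random.default_rng(seed)
    if n_scans is None:
        end = max(t.onset + t.duration for t in run)
        n_scans = int(np.ceil((end + 24.0) / tr))
    hrf = canonical_hrf(tr, oversampling=oversampling, **(hrf_kwargs or {}))
    dt = tr / oversampling
    n_fine = n_scans * oversampling
    amps = trial_amplitudes(run, labels, changes, adapt)
    n_cond = code.mean_pattern.shape[1]
    sticks = np.zeros((n_fine, n_cond))
    for t in run:
        if t.kind != "target":
            continue
        k = min(int(round(t.onset / dt)), n_fine - 1)
        sticks[k, t.condition_id - 1] += amps[t.index]
    regs = np.empty((n_scans, n_cond))
    for c in range(n_cond):
        regs[:, c] = np.convolve(sticks[:, c], hrf)[:n_fine][::oversampling]
    Y = regs @ code.mean_pattern.T

    n_vox = Y.shape[1]
    if noise.drift_amplitude > 0:
        tsec = np.arange(n_scans) * tr
        phase = rng.uniform(0, 2 * np.pi)
        coef = rng.normal(1.0, 0.2, size=n_vox)
        Y = Y + noise.drift_amplitude * np.sin(2 * np.pi * tsec / noise.drift_period + phase)[:, None] * coef
    if noise.sigma > 0:
        from scipy.signal import lfilter

        innov = rng.standard_normal((n_scans, n_vox)) * noise.sigma * np.sqrt(1 - noise.rho**2)
        ar = lfilter([1.0], [1.0, -noise.rho], innov, axis=0)
        Y = Y + ar
    return Y


def make_cohort(
    n_subjects: int = 16,
    n_runs: int = 4,
    trials_per_run: int = 176,
    room: RoomModel | None = None,
    stimuli: StimulusSet | None = None,
    texture_table: np.ndarray | None = None,
    adapt: AdaptationSpec = AdaptationSpec(),
    noise: NoiseSpec = NoiseSpec(),
    n_voxels: int = 216,
    tuning_widths: tuple[float, float, float] = (0.8, 0.8, 60.0),
    mixture_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    location_code_weight: float = 0.0,
    location_width: float = 0.8,
    between_subject_variability: float = 0.1,
    catch_rate: float = 25 / 176,
    n_fixation_blocks: int = 10,
    miss_rate: float = 0.01,
    tr: float = 1.914,
    timing: TimingSpec | None = None,
    seed: int = 0,
) -> SyntheticDataset:
    """Simulate a cohort in the carry-over paradigm.

    Defaults mirror the study layout: 16 subjects x 4 runs of 176 target
    trials (plus ~25 catch trials and 10 fixation blocks per run) over the
    packaged 32-condition stimulus set at TR 1.914 s. Per-subject tuning
    widths and gains are jittered around the shared hyperparameters by
    ``between_subject_variability`` (relative SD); all randomness descends
    from ``seed`` via independent per-subject streams.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    from .environment import load_room

    if room is None or stimuli is None:
        room, stimuli = load_room()
    ss = np.random.SeedSequence(seed)
    subj_seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n_subjects)]
    subjects = []
    for s_idx, s_seed in enumerate(subj_seeds):
        rng = np.random.default_rng(s_seed)
        if between_subject_variability > 0:
            jitter = lambda x: float(x * np.exp(rng.normal(0, between_subject_variability)))
            widths = tuple(jitter(w) for w in tuning_widths)
            code_seed = int(rng.integers(2**31 - 1))
        else:
            # zero variability: every subject carries the same code
            widths = tuple(tuning_widths)
            code_seed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
        code = make_population_code(
            n_voxels,
            room,
            stimuli,
            tuning_widths=widths,
            mixture_weights=mixture_weights,
            location_code_weight=location_code_weight,
            location_width=location_width,
            seed=code_seed,
        )
        runs = generate_carryover_sequence(
            stimuli.n_conditions,
            n_runs=n_runs,
            trials_per_run=trials_per_run,
            catch_rate=catch_rate,
            n_fixation_blocks=n_fixation_blocks,
            timing=timing,
            seed=int(rng.integers(2**31 - 1)),
            miss_rate=miss_rate,
        )
        seq = label_trials(runs, stimuli)
        pair_regressors(seq, room, texture_table)
        Ys = [
            simulate_run(
                code,
                run,
                seq.labels[r],
                seq.pair_changes[r],
                adapt,
                noise,
                tr=tr,
                seed=int(rng.integers(2**31 - 1)),
            )
            for r, run in enumerate(runs)
        ]
        subjects.append(SubjectData(code=code, runs=Ys, sequence=seq, tr=tr, seed=s_seed))
    return SyntheticDataset(
        subjects=subjects, stimuli=stimuli, room=room, adapt=adapt, noise=noise, master_seed=seed
    )
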