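"""Multivoxel pattern analysis: pairwise SVM-RFE decoding, matched-view
control, searchlight mapping, place/view cross-decoding and the
landmark-distribution confound check.

Per-run condition patterns come from a 32-regressor GLM on unsmoothed data
(one regressor per condition; catch and missed trials modeled separately
and discarded). Decoding groups the 32 conditions into eight places, views
or headings and trains a linear support vector machine (C = 1) for every
pair of categories under leave-one-run-out cross-validation. Recursive
feature elimination halves the voxel set per step down to a floor of 10% of
the initial count, ranking voxels by absolute SVM weight; the retained
level is chosen by an inner leave-one-run-out split within the training
folds. Chance is 0.5 throughout.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .environment import StimulusSet, landmark_distribution
from .glm import build_design, fit_glm
from .synthgen import SubjectData

__all__ = [
    "PatternEstimate",
    "DecodingResult",
    "estimate_condition_patterns",
    "pairwise_decode",
    "matched_view_place_decode",
    "sphere_offsets",
    "searchlight",
    "cross_decode",
    "landmark_confound_check",
]


@dataclass
class PatternEstimate:
    """Run x condition x voxel parameter estimates within a mask."""

    betas: np.ndarray  # (n_runs, n_conditions, n_voxels)
    run_ids: list[int]
    mask: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_runs(self) -> int:
        return self.betas.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.betas.shape[1]


@dataclass
class DecodingResult:
    grouping: str
    pair_accuracy: pd.DataFrame  # pair label -> accuracy
    mean_accuracy: float
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert 0.0 <= self.mean_accuracy <= 1.0


def estimate_condition_patterns(
    subject: SubjectData, mask: np.ndarray | None = None
) -> PatternEstimate:
    """Per-run GLM with one regressor per condition; betas within the mask.

    Catch trials and missed-response targets are modeled as separate
    regressors and excluded from the returned patterns.
    """
    seq = subject.sequence
    if len(subject.runs) < 2:
        raise ValueError("need at least two runs for cross-validated decoding")
    n_cond = seq.stimuli.n_conditions
    out = []
    for r, Y in enumerate(subject.runs):
        cond_map = {}
        present = set()
        for tr in seq.runs[r]:
            if tr.kind == "catch":
                cond_map[tr.index] = "catch"
            elif tr.kind == "target":
                if not tr.response_valid:
                    cond_map[tr.index] = "missed"
                else:
                    cond_map[tr.index] = f"cond_{tr.condition_id:02d}"
                    present.add(tr.condition_id)
        missing = set(range(1, n_cond + 1)) - present
        if missing:
            raise ValueError(f"run {r} lacks conditions {sorted(missing)}")
        data = Y if mask is None else Y[:, mask]
        X = build_design(seq.runs[r], cond_map, n_scans=Y.shape[0], tr=subject.tr)
        fit = fit_glm(data, X)
        out.append(np.stack([fit.beta(f"cond_{c:02d}") for c in range(1, n_cond + 1)]))
    return PatternEstimate(betas=np.stack(out), run_ids=list(range(len(out))), mask=mask)


@dataclass(frozen=True)
class RfeSpec:
    """Recursive feature elimination schedule."""

    fraction_dropped: float = 0.5
    floor_fraction: float = 0.1

    def levels(self, n_voxels: int) -> list[int]:
        floor = max(1, int(round(self.floor_fraction * n_voxels)))
        out = [n_voxels]
        while out[-1] > floor:
            nxt = max(floor, int(round(out[-1] * (1 - self.fraction_dropped))))
            if nxt == out[-1]:
                break
            out.append(nxt)
        return out


def _svm() -> SVC:
    return SVC(kernel="linear", C=1.0)


def _rfe_rank(Xtr: np.ndarray, ytr: np.ndarray, levels: list[int]) -> dict[int, np.ndarray]:
    """Voxel index sets at each RFE level, eliminating lowest |weight|."""
    active = np.arange(Xtr.shape[1])
    out = {}
    for lvl in levels:
        if len(active) > lvl:
            clf = _svm().fit(Xtr[:, active], ytr)
            w = np.abs(clf.coef_.ravel())
            keep = np.argsort(w)[::-1][:lvl]
            active = active[np.sort(keep)]
        out[lvl] = active.copy()
    return out


def _decode_pair(
    samples: list[tuple[int, int, np.ndarray]],  # (run, class, pattern)
    rfe: RfeSpec | None,
) -> float:
    """Leave-one-run-out accuracy for one category pair."""
    runs = sorted({r for r, _, _ in samples})
    accs = []
    for test_run in runs:
        train = [(r, c, x) for r, c, x in samples if r != test_run]
        test = [(r, c, x) for r, c, x in samples if r == test_run]
        Xtr = np.stack([x for _, _, x in train])
        ytr = np.array([c for _, c, _ in train])
        Xte = np.stack([x for _, _, x in test])
        yte = np.array([c for _, c, _ in test])
        voxels = np.arange(Xtr.shape[1])
        if rfe is not None and len(runs) >= 3:
            levels = rfe.levels(Xtr.shape[1])
            if len(levels) > 1:
                inner_runs = sorted({r for r, _, _ in train})
                level_scores = {lvl: [] for lvl in levels}
                for held in inner_runs:
                    itr = [(r, c, x) for r, c, x in train if r != held]
                    ite = [(r, c, x) for r, c, x in train if r == held]
                    Xi = np.stack([x for _, _, x in itr])
                    yi = np.array([c for _, c, _ in itr])
                    Xv = np.stack([x for _, _, x in ite])
                    yv = np.array([c for _, c, _ in ite])
                    if len(set(yi)) < 2:
                        continue
                    sets = _rfe_rank(Xi, yi, levels)
                    for lvl, idx in sets.items():
                        clf = _svm().fit(Xi[:, idx], yi)
                        level_scores[lvl].append(clf.score(Xv[:, idx], yv))
                means = {lvl: np.mean(s) for lvl, s in level_scores.items() if s}
                if means:
                    best = max(means.values())
                    # prefer the largest voxel count among tied levels
                    chosen = max(lvl for lvl, m in means.items() if m == best)
                    voxels = _rfe_rank(Xtr, ytr, levels)[chosen]
        clf = _svm().fit(Xtr[:, voxels], ytr)
        accs.append(clf.score(Xte[:, voxels], yte))
    return float(np.mean(accs))


def pairwise_decode(
    patterns: PatternEstimate,
    grouping: str,
    stimuli: StimulusSet,
    rfe: RfeSpec | None = RfeSpec(),
    seed: int = 0,
) -> DecodingResult:
    """Mean pairwise leave-one-run-out SVM accuracy for a feature grouping.

    ``grouping`` is ``place``, ``view`` or ``heading``; the 8 categories are
    decoded pair by pair, training on all runs but one and testing on the
    held-out run, with SVM-RFE voxel selection inside each training fold.
    """
    groups = stimuli.groups(grouping)
    if len(groups) < 2:
        raise ValueError("need at least two categories")
    cats = sorted(groups)
    rows = []
    for a, b in itertools.combinations(cats, 2):
        samples = []
        for r in range(patterns.n_runs):
            for cls, cat in enumerate((a, b)):
                for cond in groups[cat]:
                    samples.append((r, cls, patterns.betas[r, cond - 1]))
        acc = _decode_pair(samples, rfe)
        rows.append({"pair": f"{a}|{b}", "accuracy": acc})
    df = pd.DataFrame(rows)
    return DecodingResult(grouping=grouping, pair_accuracy=df, mean_accuracy=float(df["accuracy"].mean()))


def matched_view_place_decode(
    patterns: PatternEstimate,
    stimuli: StimulusSet,
    rfe: RfeSpec | None = RfeSpec(),
) -> DecodingResult:
    """Place decoding restricted to views visible from both places.

    For each place pair only the conditions whose view occurs for both
    places enter the analysis, so view identity cannot drive the
    classifier. Pairs with no shared view are skipped and reported.
    """
    by_place = stimuli.groups("place")
    places = sorted(by_place)
    rows, skipped = [], []
    for a, b in itertools.combinations(places, 2):
        views_a = {stimuli[c].view_id: c for c in by_place[a]}
        views_b = {stimuli[c].view_id: c for c in by_place[b]}
        shared = sorted(set(views_a) & set(views_b))
        if not shared:
            skipped.append((a, b))
            continue
        samples = []
        for r in range(patterns.n_runs):
            for v in shared:
                samples.append((r, 0, patterns.betas[r, views_a[v] - 1]))
                samples.append((r, 1, patterns.betas[r, views_b[v] - 1]))
        rows.append({"pair": f"{a}|{b}", "accuracy": _decode_pair(samples, rfe)})
    if not rows:
        raise ValueError("no place pairs share views")
    df = pd.DataFrame(rows)
    return DecodingResult(
        grouping="place_matched_view",
        pair_accuracy=df,
        mean_accuracy=float(df["accuracy"].mean()),
        skipped_pairs=skipped,
    )


def sphere_offsets(radius_mm: float, voxel_size_mm: float) -> np.ndarray:
    """Integer voxel offsets within a sphere of the given radius."""
    if radius_mm < voxel_size_mm / 2:
        raise ValueError("radius smaller than half a voxel")
    r_vox = radius_mm / voxel_size_mm
    lim = int(np.floor(r_vox))
    offs = [
        (i, j, k)
        for i in range(-lim, lim + 1)
        for j in range(-lim, lim + 1)
        for k in range(-lim, lim + 1)
        if i * i + j * j + k * k <= r_vox * r_vox
    ]
    return np.array(offs, dtype=int)


def searchlight(
    pattern_volume: np.ndarray,
    op,
    radius_mm: float = 4.5,
    voxel_size_mm: float = 3.0,
    mask: np.ndarray | None = None,
) -> np.ndarray:
    """Apply ``op`` to every spherical neighborhood of a pattern volume.

    ``pattern_volume`` has shape (n_runs, n_conditions, nx, ny, nz); for
    each in-mask center voxel the patterns of the in-volume sphere voxels
    are passed to ``op`` as an (n_runs, n_conditions, n_sphere_voxels)
    array, and the scalar result is written at the center. Spheres are
    clipped at the volume border.
    """
    _, _, nx, ny, nz = pattern_volume.shape
    if mask is None:
        mask = np.ones((nx, ny, nz), bool)
    if not mask.any():
        raise ValueError("empty mask")
    offs = sphere_offsets(radius_mm, voxel_size_mm)
    out = np.full((nx, ny, nz), np.nan)
    for x, y, z in np.argwhere(mask):
        pts = offs + (x, y, z)
        ok = (
            (pts[:, 0] >= 0) & (pts[:, 0] < nx)
            & (pts[:, 1] >= 0) & (pts[:, 1] < ny)
            & (pts[:, 2] >= 0) & (pts[:, 2] < nz)
        )
        pts = pts[ok]
        neigh = pattern_volume[:, :, pts[:, 0], pts[:, 1], pts[:, 2]]
        out[x, y, z] = op(neigh)
    return out


def mean_decoding_op(grouping: str, stimuli: StimulusSet, rfe: RfeSpec | None = None):
    """Searchlight op: mean pairwise decoding accuracy for a grouping."""

    def op(neigh: np.ndarray) -> float:
        pe = PatternEstimate(betas=neigh, run_ids=list(range(neigh.shape[0])))
        return pairwise_decode(pe, grouping, stimuli, rfe=rfe).mean_accuracy

    return op


def cross_decode(
    patterns: PatternEstimate,
    stimuli: StimulusSet,
    rfe: RfeSpec | None = None,
) -> dict[str, DecodingResult]:
    """Train on place discrimination, test on view discrimination (and back).

    For every pair of locations (a, b), the classifier learns to separate
    snapshots taken *from* a vs b and is tested on snapshots *aimed at* a vs
    b (direction ``place_to_view``), and vice versa. Conditions involving
    both locations at once (taken from one while aiming at the other) belong
    to both sets with conflicting labels and are excluded from each.
    """
    by_place = stimuli.groups("place")
    by_view = stimuli.groups("view")
    locations = sorted(k[1:] for k in by_place)
    results = {}
    for direction in ("place_to_view", "view_to_place"):
        rows = []
        for a, b in itertools.combinations(locations, 2):
            pa, pb, va, vb = f"P{a}", f"P{b}", f"V{a}", f"V{b}"
            both = {
                c
                for c in range(1, stimuli.n_conditions + 1)
                if stimuli[c].place_id in (pa, pb) and stimuli[c].view_id in (va, vb)
            }
            place_set = [(0, c) for c in by_place[pa] if c not in both] + [
                (1, c) for c in by_place[pb] if c not in both
            ]
            view_set = [(0, c) for c in by_view[va] if c not in both] + [
                (1, c) for c in by_view[vb] if c not in both
            ]
            train_set, test_set = (
                (place_set, view_set) if direction == "place_to_view" else (view_set, place_set)
            )
            if len({cls for cls, _ in train_set}) < 2 or not test_set:
                continue
            Xtr = np.stack(
                [patterns.betas[r, c - 1] for r in range(patterns.n_runs) for _, c in train_set]
            )
            ytr = np.array([cls for r in range(patterns.n_runs) for cls, _ in train_set])
            Xte = np.stack(
                [patterns.betas[r, c - 1] for r in range(patterns.n_runs) for _, c in test_set]
            )
            yte = np.array([cls for r in range(patterns.n_runs) for cls, _ in test_set])
            clf = _svm().fit(Xtr, ytr)
            rows.append({"pair": f"{a}|{b}", "accuracy": clf.score(Xte, yte)})
        df = pd.DataFrame(rows)
        results[direction] = DecodingResult(
            grouping=direction, pair_accuracy=df, mean_accuracy=float(df["accuracy"].mean())
        )
    return results


def landmark_confound_check(stimuli: StimulusSet) -> tuple[float, pd.DataFrame]:
    """Paired t over place pairs: corresponding vs non-corresponding
    landmark-distribution distances.

    For each place pair (a, b), compares the Euclidean distance between the
    landmark distribution seen from a place and that of its *corresponding*
    view against the distance to the *other* place's view (averaged over
    the two places of the pair). Positive t means the corresponding view is
    *less* similar — the direction that rules out landmark identity as a
    shortcut for place/view cross-decoding.
    """
    locations = sorted(k[1:] for k in stimuli.groups("place"))
    pdist = {a: landmark_distribution(f"P{a}", stimuli) for a in locations}
    vdist = {a: landmark_distribution(f"V{a}", stimuli) for a in locations}
    rows = []
    for a, b in itertools.combinations(locations, 2):
        corr = 0.5 * (
            np.linalg.norm(pdist[a] - vdist[a]) + np.linalg.norm(pdist[b] - vdist[b])
        )
        nonc = 0.5 * (
            np.linalg.norm(pdist[a] - vdist[b]) + np.linalg.norm(pdist[b] - vdist[a])
        )
        rows.append({"pair": f"{a}|{b}", "corresponding": corr, "non_corresponding": nonc})
    df = pd.DataFrame(rows)
    diff = df["corresponding"] - df["non_corresponding"]
    if np.allclose(diff, 0):
        return 0.0, df
    t = float(diff.mean() / (diff.std(ddof=1) / np.sqrt(len(diff))))
    return t, df
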