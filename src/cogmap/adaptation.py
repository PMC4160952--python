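"""Repetition-suppression contrasts and distance-modulated adaptation.

Two complementary subject-level GLMs, each followed by group-level
one-sample t-tests:

* the *label* model codes every included target trial by its relation to
  the previous trial (all same / same place / same view / same heading /
  all different, with texture change and landmark similarity as parametric
  covariates) and tests the repeated-trial conditions against the
  all-different baseline — a negative contrast is adaptation;

* the *distance* model treats all included, non-identical target trials as
  one trial type whose amplitude is polynomially modulated (orders 1-3) by
  the pairwise change covariates, in two variants: the place/view model
  (place change, view change, texture change, landmark similarity) and the
  heading model (heading change, texture change, landmark similarity).
  View change is orthogonalized to texture change, and view and heading
  change to landmark similarity, before expansion. A positive linear
  loading means the response grows with the amount of change
  (distance-related adaptation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import GlmFit, build_design, fit_glm, group_test
from .synthgen import SubjectData

__all__ = [
    "AdaptationResult",
    "DistanceModulationResult",
    "fit_label_model",
    "adaptation_contrasts",
    "fit_distance_model",
    "distance_modulation",
    "DEFAULT_ORTH_PLAN",
]

REPEAT_LABELS = ("same_place", "same_view", "same_heading", "all_same")

#: (target, reference) orthogonalizations applied before polynomial expansion.
DEFAULT_ORTH_PLAN = {
    "place_view": (("view_change", "texture_change"), ("view_change", "landmark_similarity")),
    "heading": (("heading_change", "landmark_similarity"),),
}

MODEL_MODULATORS = {
    "place_view": ("place_change", "view_change", "texture_change", "landmark_similarity"),
    "heading": ("heading_change", "texture_change", "landmark_similarity"),
}


@dataclass
class AdaptationResult:
    """Per-subject repeat-vs-baseline contrasts and their group tests."""

    subject_contrasts: pd.DataFrame  # subject, contrast, value
    group: pd.DataFrame  # contrast, t, p (one-tailed, reduction)


@dataclass
class DistanceModulationResult:
    subject_betas: pd.DataFrame  # subject, term, order, beta
    group: pd.DataFrame  # term, order, t, p (one-tailed, positive)
    model: str


def _label_condition_map(seq, run_idx: int) -> dict[int, str]:
    out = {}
    for tr in seq.runs[run_idx]:
        if tr.kind == "catch":
            out[tr.index] = "catch"
        elif tr.kind == "target":
            out[tr.index] = seq.labels[run_idx][tr.index]
    return out


def fit_label_model(subject: SubjectData, roi_mask: np.ndarray | None = None) -> list[GlmFit]:
    """Per-run GLM with one regressor per relation label (plus texture and
    landmark covariates on the included trials)."""
    seq = subject.sequence
    fits = []
    for r, Y in enumerate(subject.runs):
        cond_map = _label_condition_map(seq, r)
        changes = seq.pair_changes[r] if seq.pair_changes else {}
        # covariates modulate all included trials regardless of label; model
        # them on a merged "included" regressor added alongside the labels
        mods = None
        if changes:
            mods = {
                "texture_change": {i: c.texture_change for i, c in changes.items()},
                "landmark_similarity": {i: c.landmark_similarity for i, c in changes.items()},
            }
        data = Y if roi_mask is None else Y[:, roi_mask]
        X = build_design(
            seq.runs[r],
            cond_map,
            n_scans=Y.shape[0],
            tr=subject.tr,
            modulators=mods,
            modulated_condition="all_different",
            poly_order=1,
        )
        fits.append(fit_glm(data, X))
    return fits


def adaptation_contrasts(subject_fits: list[list[GlmFit]], average_voxels: bool = True) -> AdaptationResult:
    """Group adaptation statistics from per-subject label-model fits.

    For each subject, the repeated-trial betas are contrasted against the
    all-different baseline and averaged across runs (and voxels when
    ``average_voxels``). Group inference is a one-tailed one-sample t-test
    in the adaptation direction (reduction, i.e. negative contrast).
    """
    rows = []
    for s, fits in enumerate(subject_fits):
        for label in REPEAT_LABELS:
            per_run = []
            for fit in fits:
                if label not in fit.design.names:
                    continue
                diff = fit.beta(label) - fit.beta("all_different")
                per_run.append(diff.mean() if average_voxels else diff)
            if not per_run:
                raise ValueError(f"label regressor {label!r} missing from every run")
            rows.append({"subject": s, "contrast": f"{label}-all_different", "value": float(np.mean(per_run))})
    df = pd.DataFrame(rows)
    grows = []
    for contrast, sub in df.groupby("contrast", sort=False):
        t, p = group_test(sub["value"].to_numpy(), "one_sample", tail="less")
        grows.append({"contrast": contrast, "t": t, "p": p})
    return AdaptationResult(subject_contrasts=df, group=pd.DataFrame(grows))


def fit_distance_model(
    subject: SubjectData,
    model: str = "place_view",
    poly_order: int = 3,
    roi_mask: np.ndarray | None = None,
) -> list[GlmFit]:
    """Per-run polynomial distance-modulation GLM for one subject.

    Included non-identical target trials form a single modulated trial type;
    all-same trials, excluded trials and catch trials get separate
    regressors and are not modulated.
    """
    if model not in MODEL_MODULATORS:
        raise ValueError(f"unknown model {model!r}")
    seq = subject.sequence
    if not seq.pair_changes:
        raise ValueError("pair regressors not computed for this sequence")
    fits = []
    for r, Y in enumerate(subject.runs):
        cond_map = {}
        for tr in seq.runs[r]:
            if tr.kind == "catch":
                cond_map[tr.index] = "catch"
            elif tr.kind == "target":
                lbl = seq.labels[r][tr.index]
                if lbl == "excluded":
                    cond_map[tr.index] = "excluded"
                elif lbl == "all_same":
                    cond_map[tr.index] = "all_same"
                else:
                    cond_map[tr.index] = "trial"
        changes = {
            i: c
            for i, c in seq.pair_changes[r].items()
            if seq.labels[r][i] != "all_same"
        }
        mods = {
            name: {i: getattr(changes[i], name) for i in changes}
            for name in (
                "place_change",
                "view_change",
                "heading_change",
                "texture_change",
                "landmark_similarity",
            )
            if name in MODEL_MODULATORS[model]
        }
        # a covariate with no variance (e.g. texture without a texture table)
        # carries no information and would produce empty columns
        mods = {k: v for k, v in mods.items() if np.ptp(list(v.values())) > 0}
        plan = tuple((t, r) for t, r in DEFAULT_ORTH_PLAN[model] if t in mods and r in mods)
        data = Y if roi_mask is None else Y[:, roi_mask]
        X = build_design(
            seq.runs[r],
            cond_map,
            n_scans=Y.shape[0],
            tr=subject.tr,
            modulators=mods,
            modulated_condition="trial",
            orth_plan=plan,
            poly_order=poly_order,
        )
        fits.append(fit_glm(data, X))
    return fits


def distance_modulation(
    subject_fits: list[list[GlmFit]],
    model: str = "place_view",
    poly_order: int = 3,
    average_voxels: bool = True,
) -> DistanceModulationResult:
    """Group one-sample t (one-tailed, positive) on each modulator term."""
    # report the modeled terms actually present in the designs (a covariate
    # with no variance in the session is not modeled)
    terms = [
        t for t in MODEL_MODULATORS[model] if t in subject_fits[0][0].design.names
    ]
    if not terms:
        raise ValueError("no model terms present in the design (model mismatch?)")
    rows = []
    for s, fits in enumerate(subject_fits):
        for term in terms:
            for order in range(1, poly_order + 1):
                name = term if order == 1 else f"{term}^{order}"
                vals = []
                for fit in fits:
                    if name not in fit.design.names:
                        raise ValueError(f"term {name!r} missing from design (model mismatch?)")
                    b = fit.beta(name)
                    vals.append(b.mean() if average_voxels else b)
                rows.append({"subject": s, "term": term, "order": order, "beta": float(np.mean(vals))})
    df = pd.DataFrame(rows)
    grows = []
    for (term, order), sub in df.groupby(["term", "order"], sort=False):
        t, p = group_test(sub["beta"].to_numpy(), "one_sample", tail="greater")
        grows.append({"term": term, "order": order, "t": t, "p": p})
    return DistanceModulationResult(subject_betas=df, group=pd.DataFrame(grows), model=model)
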