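"""Representational similarity analysis by RDM regression.

The neural representational dissimilarity matrix (RDM) holds Euclidean
distances between run-averaged condition patterns. Its vectorized upper
triangle is regressed on model predictors built from the room geometry —
place distance, view distance, heading displacement, texture dissimilarity
and landmark dissimilarity (proportion of non-shared visible landmarks) —
each z-scored over the same off-diagonal entries so the betas are
comparable. Two models mirror the adaptation analysis: ``place_view``
(place, view, texture, landmark) and ``heading`` (heading, texture,
landmark). Group inference is a one-tailed one-sample t-test per predictor
with Bonferroni correction across the tested regions (p < 0.01).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .environment import RoomModel, StimulusSet
from .mvpa import PatternEstimate

__all__ = [
    "NeuralRdm",
    "PredictorSet",
    "RsaFit",
    "neural_rdm",
    "model_rdms",
    "rsa_regression",
    "group_rsa",
    "MODEL_PREDICTORS",
]

MODEL_PREDICTORS = {
    "place_view": ("place", "view", "texture", "landmark"),
    "heading": ("heading", "texture", "landmark"),
}


@dataclass
class NeuralRdm:
    """Condition-by-condition Euclidean pattern distances."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0) or (m < 0).any():
            raise ValueError("RDM must be symmetric, nonnegative, zero-diagonal")

    def vector(self) -> np.ndarray:
        return squareform(self.matrix, checks=False)


@dataclass
class PredictorSet:
    """Model dissimilarity matrices, same condition order as the neural RDM."""

    matrices: dict[str, np.ndarray]

    def design(self, model: str) -> tuple[np.ndarray, list[str]]:
        """Z-scored upper-triangle predictor columns for a model."""
        names = list(MODEL_PREDICTORS[model])
        cols = []
        for n in names:
            v = squareform(self.matrices[n], checks=False).astype(float)
            sd = v.std()
            cols.append((v - v.mean()) / sd if sd > 0 else v - v.mean())
        return np.column_stack(cols), names


@dataclass
class RsaFit:
    subject_betas: pd.DataFrame  # predictor, beta
    model: str
    r_squared: float
    condition_number: float


def neural_rdm(patterns: PatternEstimate, average_runs: bool = True) -> NeuralRdm:
    """Euclidean RDM of (by default run-averaged) condition patterns.

    With ``average_runs=False`` the per-run RDMs are computed and averaged
    instead.
    """
    if patterns.n_conditions < 2:
        raise ValueError("need at least two conditions")
    if average_runs:
        mean_pat = patterns.betas.mean(axis=0)
        return NeuralRdm(squareform(pdist(mean_pat)))
    mats = [squareform(pdist(patterns.betas[r])) for r in range(patterns.n_runs)]
    return NeuralRdm(np.mean(mats, axis=0))


def model_rdms(
    stimuli: StimulusSet,
    room: RoomModel | None = None,
    texture_table: np.ndarray | None = None,
) -> PredictorSet:
    """Predictor RDMs from the room geometry (and a texture table if given)."""
    mats = {
        "place": stimuli.pairwise("place"),
        "view": stimuli.pairwise("view"),
        "heading": stimuli.pairwise("heading"),
        "landmark": stimuli.pairwise("landmark"),
    }
    if texture_table is not None:
        mats["texture"] = np.asarray(texture_table, float)
    else:
        mats["texture"] = np.zeros_like(mats["place"])
    return PredictorSet(matrices=mats)


def rsa_regression(
    neural: NeuralRdm,
    predictors: PredictorSet,
    model: str = "place_view",
    max_condition_number: float = 1e6,
) -> RsaFit:
    """OLS of the vectorized neural RDM on a model's predictors + intercept."""
    X, names = predictors.design(model)
    # drop constant (all-zero) predictors, e.g. an absent texture table
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    names = [n for n, k in zip(names, keep) if k]
    y = neural.vector()
    Xc = np.column_stack([np.ones(len(y)), X])
    cond = float(np.linalg.cond(Xc))
    if cond > max_condition_number:
        raise ValueError(f"predictors nearly collinear (condition number {cond:.3g})")
    beta, res, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    fitted = Xc @ beta
    ss_res = float(((y - fitted) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    df = pd.DataFrame({"predictor": ["intercept"] + names, "beta": beta})
    return RsaFit(subject_betas=df, model=model, r_squared=r2, condition_number=cond)


def group_rsa(
    fits: list[RsaFit],
    alpha: float = 0.01,
    n_comparisons: int = 1,
) -> pd.DataFrame:
    """One-tailed group t per predictor with a Bonferroni-corrected flag.

    ``n_comparisons`` is the number of regions tested (the Bonferroni family
    in the ROI analyses); a predictor is significant when its one-tailed p
    falls below ``alpha / n_comparisons``.
    """
    if len(fits) < 2:
        raise ValueError("need at least two subjects")
    model = fits[0].model
    rows = []
    predictors = [p for p in fits[0].subject_betas["predictor"] if p != "intercept"]
    for pred in predictors:
        vals = np.array(
            [f.subject_betas.set_index("predictor").loc[pred, "beta"] for f in fits], float
        )
        if vals.std(ddof=1) == 0:
            raise ValueError(f"zero variance across subjects for {pred!r}")
        res = stats.ttest_1samp(vals, 0.0, alternative="greater")
        rows.append(
            {
                "predictor": pred,
                "mean_beta": float(vals.mean()),
                "t": float(res.statistic),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha / n_comparisons),
                "model": model,
            }
        )
    return pd.DataFrame(rows)
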