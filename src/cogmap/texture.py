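"""Texton-histogram texture dissimilarity between images.

Grayscale images are passed through a bank of V1-like filters (even and odd
oriented Gabor pairs at two spatial scales plus two center-surround
kernels), every pixel's filter-response vector is assigned to the nearest of
100 prototype vectors (textons, learned by k-means across the image set),
and each image is summarized by its normalized texton histogram. The
dissimilarity between two images is the chi-square statistic between their
histograms,

    chi2(h1, h2) = sum_b (h1_b - h2_b)**2 / (h1_b + h2_b),

with empty bins skipped; smaller values mean more similar texture. Only
relative values matter downstream (the covariate is z-scored in the GLM),
so the unhalved convention is used throughout.

The exact filter parameters of the original texture model are not public;
this bank is a standard approximation (2 scales x 6 orientations x
{even, odd} + 2 center-surround = 26 zero-mean, unit-norm kernels) and is
configurable.

Because the package never renders the actual room photographs, synthetic
snapshot proxies (oriented texture patches laid out by landmark bearing)
stand in for them when a condition-by-condition texture table is needed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve
from sklearn.cluster import KMeans

from .environment import RoomModel, SnapshotSpec, StimulusSet, _bearing

__all__ = [
    "build_filter_bank",
    "filter_responses",
    "TextonCodebook",
    "learn_codebook",
    "texture_histogram",
    "texture_dissimilarity",
    "render_snapshot_proxy",
    "condition_texture_table",
]


def _gabor(size: int, wavelength: float, theta: float, phase: float, sigma: float) -> np.ndarray:
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    xr = x * np.cos(theta) + y * np.sin(theta)
    env = np.exp(-(x**2 + y**2) / (2 * sigma**2))
    g = env * np.cos(2 * np.pi * xr / wavelength + phase)
    g -= g.mean()
    n = np.linalg.norm(g)
    return g / n if n > 0 else g


def _center_surround(size: int, sigma: float) -> np.ndarray:
    half = size // 2
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    r2 = x**2 + y**2
    g = np.exp(-r2 / (2 * sigma**2)) / sigma**2 - np.exp(-r2 / (2 * (1.6 * sigma) ** 2)) / (1.6 * sigma) ** 2
    g -= g.mean()
    n = np.linalg.norm(g)
    return g / n if n > 0 else g


def build_filter_bank(
    scales: Sequence[float] = (3.0, 6.0),
    n_orientations: int = 6,
    size: int = 15,
) -> np.ndarray:
    """Zero-DC, unit-norm V1-like kernels, shape (n_filters, size, size)."""
    if len(scales) < 2 or n_orientations < 4:
        raise ValueError("need >= 2 scales and >= 4 orientations")
    kernels = []
    for wl in scales:
        for k in range(n_orientations):
            theta = np.pi * k / n_orientations
            for phase in (0.0, np.pi / 2):  # even, odd
                kernels.append(_gabor(size, wl, theta, phase, sigma=0.56 * wl))
    for wl in scales:
        kernels.append(_center_surround(size, sigma=wl / 3.0))
    return np.stack(kernels)


def filter_responses(image: np.ndarray, bank: np.ndarray) -> np.ndarray:
    """Per-pixel absolute filter responses, shape (n_pixels, n_filters)."""
    image = np.asarray(image, float)
    resp = [np.abs(fftconvolve(image, k, mode="same")) for k in bank]
    return np.stack([r.ravel() for r in resp], axis=1)


@dataclass(frozen=True)
class TextonCodebook:
    """K prototype filter-response vectors plus the bank that produced them."""

    prototypes: np.ndarray  # (k, n_filters)
    bank: np.ndarray

    def __post_init__(self) -> None:
        if self.prototypes.shape[1] != self.bank.shape[0]:
            raise ValueError("prototype dimensionality must equal filter count")


def learn_codebook(
    images: Sequence[np.ndarray],
    k: int = 100,
    seed: int = 0,
    bank: np.ndarray | None = None,
    max_pixels_per_image: int = 400,
) -> TextonCodebook:
    """Cluster per-pixel filter responses into ``k`` texton prototypes."""
    if not len(images):
        raise ValueError("empty image collection")
    bank = bank if bank is not None else build_filter_bank()
    rng = np.random.default_rng(seed)
    samples = []
    for img in images:
        r = filter_responses(img, bank)
        if r.shape[0] > max_pixels_per_image:
            r = r[rng.choice(r.shape[0], max_pixels_per_image, replace=False)]
        samples.append(r)
    data = np.vstack(samples)
    if data.shape[0] < k:
        raise ValueError("fewer pixels than prototypes")
    km = KMeans(n_clusters=k, random_state=seed, n_init=4).fit(data)
    return TextonCodebook(prototypes=km.cluster_centers_, bank=bank)


def texture_histogram(image: np.ndarray, codebook: TextonCodebook) -> np.ndarray:
    """Normalized texton-frequency histogram of an image."""
    resp = filter_responses(image, codebook.bank)
    d2 = ((resp[:, None, :] - codebook.prototypes[None]) ** 2).sum(-1)
    assign = d2.argmin(axis=1)
    hist = np.bincount(assign, minlength=codebook.prototypes.shape[0]).astype(float)
    return hist / hist.sum()


def texture_dissimilarity(h1: np.ndarray, h2: np.ndarray) -> float:
    """Chi-square dissimilarity between two normalized histograms."""
    h1 = np.asarray(h1, float)
    h2 = np.asarray(h2, float)
    if h1.shape != h2.shape:
        raise ValueError("histogram length mismatch")
    s = h1 + h2
    mask = s > 0
    return float((((h1 - h2) ** 2)[mask] / s[mask]).sum())


def render_snapshot_proxy(
    spec: SnapshotSpec,
    room: RoomModel,
    shape: tuple[int, int] = (48, 64),
    seed: int = 1234,
) -> np.ndarray:
    """Synthetic grayscale stand-in for a rendered snapshot.

    Each visible landmark contributes an oriented grating patch whose
    orientation and spatial frequency identify the landmark and whose
    horizontal position tracks the landmark's angular offset from the aiming
    direction; a wall-dependent background gradient plus deterministic
    low-amplitude noise fill the rest. Images of snapshots sharing visible
    landmarks therefore share texture statistics, which is the property the
    texture-change covariate needs to emulate.
    """
    h, w = shape
    rng = np.random.default_rng(seed + 7919)  # same background for all snapshots
    img = 0.08 * rng.standard_normal(shape)
    hdg = room.heading_degrees(spec.heading)
    img += 0.3 * np.cos(np.radians(hdg)) * np.linspace(-1, 1, w)[None, :]
    img += 0.3 * np.sin(np.radians(hdg)) * np.linspace(-1, 1, h)[:, None]
    cam = room.place_coords[spec.place_id]
    direction = _bearing(cam, room.view_coords[spec.view_id])
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    for lbl in sorted(spec.visible_landmarks):
        i = int(lbl[1:]) - 1
        dev = (_bearing(cam, room.landmark_positions[lbl]) - direction + 180.0) % 360.0 - 180.0
        cx = (0.5 + dev / spec.fov[0]) * (w - 1)
        cy = h / 2.0
        dist = np.linalg.norm(np.asarray(room.landmark_positions[lbl], float) - np.asarray(cam, float))
        width = max(4.0, 12.0 / max(dist, 0.5))
        env = np.exp(-(((xx - cx) ** 2) + (yy - cy) ** 2 / 4.0) / (2 * width**2))
        theta = np.pi * i / 8.0
        freq = 0.25 + 0.08 * i
        grating = np.cos(freq * (xx * np.cos(theta) + yy * np.sin(theta)) * 2 * np.pi / 4.0)
        img += env * grating
    return img


def condition_texture_table(
    stimuli: StimulusSet,
    room: RoomModel,
    k: int = 100,
    seed: int = 1234,
    shape: tuple[int, int] = (48, 64),
) -> np.ndarray:
    """Pairwise chi-square texture dissimilarity between all conditions.

    Renders the synthetic snapshot proxies, learns a texton codebook across
    them, and compares the resulting histograms. Deterministic given the
    seed; diagonal is zero.
    """
    images = [render_snapshot_proxy(s, room, shape=shape, seed=seed) for s in stimuli]
    codebook = learn_codebook(images, k=min(k, 100), seed=seed)
    hists = [texture_histogram(img, codebook) for img in images]
    n = len(hists)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = texture_dissimilarity(hists[i], hists[j])
    return out
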