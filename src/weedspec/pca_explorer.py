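"""Pixel-level PCA with full-variance accounting and score/density outputs.

PCA runs on mean-centred, unscaled reflectance (the chemometrics default for
homogeneous percent units).  Explained-variance percentages are taken
against the *total* variance — the trace of the band covariance matrix —
so they remain well-defined when only the leading k components are kept.
Loadings carry a deterministic sign convention (largest-magnitude element of
each column made positive) so scores reproduce across runs and libraries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

__all__ = [
    "PCAModel",
    "fit_pixel_pca",
    "explained_variance",
    "cumulative_variance",
    "variance_scatter",
]


@dataclass
class PCAModel:
    mean_spectrum: np.ndarray  # (bands,)
    loadings: np.ndarray  # (bands, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,), non-increasing
    total_variance: float  # trace of the covariance over all bands
    scores: np.ndarray  # (n, k), centred per component
    wavelengths: np.ndarray | None = None

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def transform(self, pixels: np.ndarray) -> np.ndarray:
        return (np.asarray(pixels, dtype=float) - self.mean_spectrum) @ self.loadings

    def save(self, path: str | Path) -> None:
        payload = {
            "mean_spectrum": self.mean_spectrum.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "total_variance": self.total_variance,
            "wavelengths": None if self.wavelengths is None else self.wavelengths.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "PCAModel":
        payload = json.loads(Path(path).read_text())
        wl = payload["wavelengths"]
        return cls(
            np.array(payload["mean_spectrum"]),
            np.array(payload["loadings"]),
            np.array(payload["eigenvalues"]),
            float(payload["total_variance"]),
            scores=np.empty((0, len(payload["eigenvalues"]))),
            wavelengths=None if wl is None else np.array(wl),
        )


def _fix_signs(loadings: np.ndarray, scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    for j in range(loadings.shape[1]):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1.0
            scores[:, j] *= -1.0
    return loadings, scores


def fit_pixel_pca(
    pixels: np.ndarray, k: int = 6, wavelengths: np.ndarray | None = None
) -> PCAModel:
    """Fit a k-component PCA to an (n_pixels, bands) matrix.

    Eigenvalues use the sample (n-1) covariance convention and are checked
    against a direct eigendecomposition oracle in the test suite.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2:
        raise ValueError("pixels must be a 2-D (n, bands) matrix")
    n, bands = pixels.shape
    if k > min(n, bands):
        raise ValueError(f"k={k} exceeds min(n, bands)={min(n, bands)}")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(pixels)
    loadings = model.components_.T.copy()
    loadings, scores = _fix_signs(loadings, scores)
    total = float(np.trace(np.cov(pixels, rowvar=False))) if n > 1 else 0.0
    return PCAModel(
        mean_spectrum=model.mean_,
        loadings=loadings,
        eigenvalues=model.explained_variance_.copy(),
        total_variance=total,
        scores=scores,
        wavelengths=None if wavelengths is None else np.asarray(wavelengths, float),
    )


def explained_variance(model: PCAModel) -> np.ndarray:
    """Per-component explained variance, percent of the all-band total."""
    if model.total_variance <= 0:
        return np.zeros(model.k)
    return 100.0 * model.eigenvalues / model.total_variance


def cumulative_variance(model: PCAModel, k: int) -> float:
    """Cumulative explained variance (%) through component k (k=0 -> 0)."""
    if k < 0 or k > model.k:
        raise ValueError(f"k must be in [0, {model.k}], got {k}")
    return float(np.sum(explained_variance(model)[:k]))


def variance_scatter(
    model: PCAModel, grid: int = 100
) -> tuple[np.ndarray, np.ndarray]:
    """(t1, t2) score pairs with a 2-D histogram density value per point.

    The density estimate is display-grade (a grid x grid histogram lookup)
    and enters no statistic.
    """
    if model.k < 2:
        raise ValueError("variance scatter needs at least 2 components")
    pts = model.scores[:, :2]
    hist, xe, ye = np.histogram2d(pts[:, 0], pts[:, 1], bins=grid)
    ix = np.clip(np.searchsorted(xe, pts[:, 0], side="right") - 1, 0, grid - 1)
    iy = np.clip(np.searchsorted(ye, pts[:, 1], side="right") - 1, 0, grid - 1)
    return pts, hist[ix, iy]
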