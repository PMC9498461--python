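"""PCA dimensionality reduction and low-/mid-level multi-sensor fusion.

Low-level fusion (LDF) concatenates the preprocessed spectral block and the
image-feature block column-wise.  Mid-level fusion (MDF) first reduces each
block by PCA (components chosen by a cumulative explained-variance
threshold, 0.99 by default, or a fixed count), min-max scales each score
column with training-set statistics, and then concatenates.  All parameters
are fitted on training rows only and reused on prediction rows, which may
therefore fall outside [0, 1] after scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.preprocessing import MinMaxScaler
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = ["PcaModel", "FusedMatrix", "pca_fit", "low_level_fuse", "MidLevelFusion"]


@dataclass
class PcaModel:
    """Fitted principal-component model with a deterministic sign convention.

    Each loading's largest-magnitude element is made positive so scores are
    reproducible across linear-algebra backends.
    """

    mean_: np.ndarray
    components_: np.ndarray  # (k, n_features), orthonormal rows
    explained_variance_ratio_: np.ndarray
    k: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    def to_dict(self) -> dict:
        return {
            "mean": self.mean_.tolist(),
            "components": self.components_.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio_.tolist(),
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PcaModel":
        return cls(
            np.array(d["mean"]),
            np.array(d["components"]),
            np.array(d["explained_variance_ratio"]),
            int(d["k"]),
        )


def _fix_signs(components: np.ndarray) -> np.ndarray:
    flip = np.sign(components[np.arange(len(components)),
                              np.abs(components).argmax(axis=1)])
    flip[flip == 0] = 1.0
    return components * flip[:, None]


def pca_fit(
    X: np.ndarray,
    cum_threshold: float | None = 0.99,
    fixed_k: int | None = None,
) -> PcaModel:
    """Mean-centred PCA keeping the smallest k whose cumulative explained
    variance ratio reaches ``cum_threshold``, or exactly ``fixed_k``."""
    X = check_array(X)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    full = PCA(svd_solver="full").fit(X)
    ratios = full.explained_variance_ratio_
    if fixed_k is not None:
        if not 1 <= fixed_k <= len(ratios):
            raise ValueError(f"fixed_k={fixed_k} outside 1..{len(ratios)}")
        k = int(fixed_k)
    else:
        if cum_threshold is None or not 0 < cum_threshold <= 1:
            raise ValueError("cum_threshold must lie in (0, 1]")
        csum = np.cumsum(ratios)
        reached = np.flatnonzero(csum >= cum_threshold - 1e-12)
        k = int(reached[0]) + 1 if reached.size else len(ratios)
    return PcaModel(
        mean_=full.mean_,
        components_=_fix_signs(full.components_[:k].copy()),
        explained_variance_ratio_=ratios[:k].copy(),
        k=k,
    )


@dataclass
class FusedMatrix:
    """Fused design matrix with per-column provenance labels."""

    values: np.ndarray
    block_labels: list[str]  # "spectral" | "image" per column

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[1] != len(self.block_labels):
            raise ValueError("one block label per column required")


def low_level_fuse(spectra_block: np.ndarray, image_block: np.ndarray) -> FusedMatrix:
    """Column-wise concatenation of the raw sensor blocks (LDF)."""
    A = np.atleast_2d(np.asarray(spectra_block, dtype=float))
    B = np.atleast_2d(np.asarray(image_block, dtype=float))
    if B.size == 0:
        B = B.reshape(A.shape[0], 0)
    if A.shape[0] != B.shape[0]:
        raise ValueError(f"row mismatch: {A.shape[0]} vs {B.shape[0]} samples")
    return FusedMatrix(
        np.hstack([A, B]),
        ["spectral"] * A.shape[1] + ["image"] * B.shape[1],
    )


class MidLevelFusion(TransformerMixin, BaseEstimator):
    """Mid-level fusion: per-block PCA, per-column min-max scaling, concat.

    Parameters
    ----------
    n_spectral : int
        Number of leading columns of X belonging to the spectral block;
        the rest form the image block (either block may be empty).
    cum_threshold : float
        Cumulative explained-variance threshold for picking k per block.
    k_spectral, k_image : int or None
        Fixed component counts overriding the threshold per block.
    """

    def __init__(self, n_spectral, cum_threshold=0.99, k_spectral=None, k_image=None):
        self.n_spectral = n_spectral
        self.cum_threshold = cum_threshold
        self.k_spectral = k_spectral
        self.k_image = k_image

    def _blocks(self, X):
        X = check_array(X)
        return X[:, : self.n_spectral], X[:, self.n_spectral :]

    def fit(self, X, y=None):
        S, I = self._blocks(X)
        self.pca_spectral_ = (
            pca_fit(S, self.cum_threshold, self.k_spectral) if S.shape[1] else None
        )
        self.pca_image_ = (
            pca_fit(I, self.cum_threshold, self.k_image) if I.shape[1] else None
        )
        scores = self._scores(S, I)
        self.scalers_ = []
        for block in scores:
            if block.shape[1] == 0:
                self.scalers_.append(None)
                continue
            if np.any(block.max(axis=0) - block.min(axis=0) < 1e-12):
                raise ValueError("constant PCA score column; cannot min-max scale")
            self.scalers_.append(MinMaxScaler().fit(block))
        self.n_features_in_ = X.shape[1] if hasattr(X, "shape") else S.shape[1] + I.shape[1]
        return self

    def _scores(self, S, I):
        return (
            self.pca_spectral_.transform(S) if self.pca_spectral_ else S[:, :0],
            self.pca_image_.transform(I) if self.pca_image_ else I[:, :0],
        )

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self)
        S, I = self._blocks(X)
        blocks = [
            scaler.transform(block) if scaler is not None else block
            for scaler, block in zip(self.scalers_, self._scores(S, I))
        ]
        return np.hstack(blocks)

    def fuse(self, X) -> FusedMatrix:
        """Like transform, but keeping per-column provenance labels."""
        check_is_fitted(self)
        values = self.transform(X)
        ks = (self.pca_spectral_.k if self.pca_spectral_ else 0,
              self.pca_image_.k if self.pca_image_ else 0)
        return FusedMatrix(values, ["spectral"] * ks[0] + ["image"] * ks[1])
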