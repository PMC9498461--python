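"""Spectral preprocessing: wavelength cropping, SNV, MSC and max-min scaling.

SNV and max-min act per spectrum (row-wise), the chemometrics convention;
MSC regresses each spectrum on a reference (by default the mean of the
training spectra) and inverts the fitted offset and slope.  The transformer
classes follow the scikit-learn fit/transform protocol so they can sit in a
Pipeline; the bare functions are kept for one-off use.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .io import SpectraTable, WavelengthGrid

__all__ = [
    "crop_wavelengths",
    "snv",
    "msc",
    "maxmin",
    "SNVTransformer",
    "MSCTransformer",
]

_EPS = 1e-12


def crop_wavelengths(table: SpectraTable, lo_nm: float, hi_nm: float) -> SpectraTable:
    """Retain channels with lo_nm <= wavelength <= hi_nm (inclusive bounds).

    The instrument's first and last channels are noisy, so analysis keeps an
    interior window (980-1670 nm in the standard protocol).
    """
    if lo_nm >= hi_nm:
        raise ValueError("crop bounds must satisfy lo < hi")
    wl = table.grid.wavelengths
    keep = (wl >= lo_nm) & (wl <= hi_nm)
    if keep.sum() < 2:
        raise ValueError(
            f"cropping to [{lo_nm}, {hi_nm}] nm leaves {int(keep.sum())} channel(s)"
        )
    return SpectraTable(
        table.sample_ids,
        WavelengthGrid(wl[keep]),
        table.values[:, keep],
        table.moisture,
        table.time_s,
    )


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centring and unit scaling.

    Uses the sample standard deviation (n-1 denominator).  Accepts a single
    spectrum or a 2-D (samples x channels) matrix, applied row-wise.
    """
    x = np.asarray(x, dtype=float)
    one_d = x.ndim == 1
    X = np.atleast_2d(x)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd < _EPS):
        raise ValueError("SNV undefined for a constant spectrum")
    out = (X - X.mean(axis=1, keepdims=True)) / sd
    return out[0] if one_d else out


def msc(X: np.ndarray, reference: np.ndarray | str = "mean") -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is modelled as ``x ~ a + b * ref`` by least squares and
    corrected to ``(x - a) / b``.  Returns ``(corrected, reference)`` so the
    reference fitted on training data can be reused on prediction data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    ref = X.mean(axis=0) if isinstance(reference, str) and reference == "mean" \
        else np.asarray(reference, dtype=float)
    if ref.shape != (X.shape[1],):
        raise ValueError("reference must match the spectra's wavelength grid")
    if ref.std() < _EPS:
        raise ValueError("MSC reference spectrum is constant")
    rc = ref - ref.mean()
    denom = rc @ rc
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < _EPS):
        raise ValueError("degenerate MSC fit: near-zero slope against reference")
    a = X.mean(axis=1) - b * ref.mean()
    return (X - a[:, None]) / b[:, None], ref


def maxmin(x: np.ndarray) -> np.ndarray:
    """Max-min normalization of a vector onto [0, 1], endpoints attained."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < _EPS:
        raise ValueError("max-min normalization undefined for constant input")
    return (x - lo) / (hi - lo)


class SNVTransformer(TransformerMixin, BaseEstimator):
    """Row-wise standard normal variate as a stateless sklearn transformer."""

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        return snv(check_array(X))


class MSCTransformer(TransformerMixin, BaseEstimator):
    """Multiplicative scatter correction with the reference learnt on fit.

    The reference is the mean of the *training* spectra, stored at fit time
    and reused on new data so no prediction-set information leaks into it.
    """

    def fit(self, X, y=None):
        X = check_array(X)
        self.reference_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        corrected, _ = msc(check_array(X), self.reference_)
        return corrected


class MaxMinRowTransformer(TransformerMixin, BaseEstimator):
    """Row-wise max-min scaling of each spectrum onto [0, 1] (stateless)."""

    def fit(self, X, y=None):
        check_array(X)
        self.n_features_in_ = np.asarray(X).shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self)
        X = check_array(X)
        return np.vstack([maxmin(row) for row in X])


#: preprocessing registry used by the pipeline config ("raw" is identity)
METHODS = {
    "raw": lambda: None,
    "snv": SNVTransformer,
    "msc": MSCTransformer,
    "maxmin": MaxMinRowTransformer,
}
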