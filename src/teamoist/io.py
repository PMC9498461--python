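"""Spectra containers, CSV round-trip, replicate averaging and the train/prediction split.

The on-disk layout is a plain CSV with one header row: the first two columns
are ``sample_id`` and ``moisture`` (fraction in [0, 1]), an optional third
column ``time_s`` (fixation time in seconds), and the remaining column names
are wavelengths in nm.  One row per sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "WavelengthGrid",
    "SpectraTable",
    "DatasetSplit",
    "read_spectra_csv",
    "write_spectra_csv",
    "average_replicate_scans",
    "split_dataset",
]

_NM_LO, _NM_HI = 300.0, 2600.0


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength axis in nanometres."""

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid needs at least 2 points")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if wl[0] < _NM_LO or wl[-1] > _NM_HI:
            raise ValueError(f"wavelengths must lie within [{_NM_LO}, {_NM_HI}] nm")

    def __len__(self) -> int:
        return int(self.wavelengths.size)


@dataclass
class SpectraTable:
    """Sample x wavelength reflectance matrix with per-sample moisture labels.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique identifiers, one per row.
    grid : WavelengthGrid
        Shared wavelength axis.
    values : ndarray, shape (n_samples, n_channels)
        Non-negative reflectance (unitless).
    moisture : ndarray, shape (n_samples,)
        Reference moisture as a fraction in [0, 1].
    time_s : ndarray or None
        Fixation time in seconds, if known.
    """

    sample_ids: list[str]
    grid: WavelengthGrid
    values: np.ndarray
    moisture: np.ndarray
    time_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.moisture = np.asarray(self.moisture, dtype=float)
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        if self.values.shape != (n, len(self.grid)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{n} samples x {len(self.grid)} channels"
            )
        if self.moisture.shape != (n,):
            raise ValueError("moisture must have one entry per sample")
        if np.any(~np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("reflectance must be finite and non-negative")
        if np.any((self.moisture < 0) | (self.moisture > 1)):
            raise ValueError("moisture must be a fraction in [0, 1]")
        if self.time_s is not None:
            self.time_s = np.asarray(self.time_s, dtype=float)
            if self.time_s.shape != (n,):
                raise ValueError("time_s must have one entry per sample")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def select(self, indices) -> "SpectraTable":
        """Row subset preserving order of ``indices``."""
        idx = np.asarray(indices, dtype=int)
        return SpectraTable(
            [self.sample_ids[i] for i in idx],
            self.grid,
            self.values[idx],
            self.moisture[idx],
            None if self.time_s is None else self.time_s[idx],
        )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/prediction index sets covering 0..n-1."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_indices, dtype=int)
        te = np.asarray(self.test_indices, dtype=int)
        object.__setattr__(self, "train_indices", tr)
        object.__setattr__(self, "test_indices", te)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test indices overlap")


def read_spectra_csv(path) -> SpectraTable:
    """Read a spectra table from CSV (see module docstring for the layout)."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "sample_id":
        raise ValueError("first column must be 'sample_id'")
    if cols[1] != "moisture":
        raise ValueError("labeled data required: second column must be 'moisture'")
    has_time = len(cols) > 2 and cols[2] == "time_s"
    wl_cols = cols[3:] if has_time else cols[2:]
    try:
        wavelengths = np.array([float(c) for c in wl_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header: {exc}") from exc
    values = df[wl_cols].to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ValueError("non-numeric or missing reflectance cells")
    return SpectraTable(
        sample_ids=df["sample_id"].astype(str).tolist(),
        grid=WavelengthGrid(wavelengths),
        values=values,
        moisture=df["moisture"].to_numpy(dtype=float),
        time_s=df["time_s"].to_numpy(dtype=float) if has_time else None,
    )


def write_spectra_csv(table: SpectraTable, path) -> None:
    """Write a spectra table in the layout ``read_spectra_csv`` accepts."""
    data = {"sample_id": table.sample_ids, "moisture": table.moisture}
    if table.time_s is not None:
        data["time_s"] = table.time_s
    for j, wl in enumerate(table.grid.wavelengths):
        data[repr(float(wl))] = table.values[:, j]
    pd.DataFrame(data).to_csv(path, index=False)


def average_replicate_scans(scans) -> np.ndarray:
    """Element-wise mean of replicate scans of one sample.

    Each acquisition scans a sample several times (three in the standard
    protocol) and the mean is taken as that sample's spectrum.
    """
    arrs = [np.asarray(s, dtype=float) for s in scans]
    if not arrs:
        raise ValueError("need at least one scan")
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise ValueError("scans must share a wavelength grid")
    return np.mean(arrs, axis=0)


def split_dataset(
    n_samples: int,
    ratio: tuple[int, int] = (4, 1),
    seed: int = 0,
    time_s: np.ndarray | None = None,
) -> DatasetSplit:
    """Random train/prediction split in ``ratio`` (train:test), seeded.

    ``|train| = round(n * train/(train+test))``.  With ``time_s`` given, the
    split is stratified by fixation time point so every time point is
    represented in both subsets; by default the split is simple random.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples to split")
    tr_part, te_part = ratio
    frac = tr_part / (tr_part + te_part)
    n_train = int(round(frac * n_samples))
    if n_train == n_samples or n_train == 0:
        raise ValueError(f"ratio {ratio} yields an empty subset for n={n_samples}")
    rng = np.random.default_rng(seed)
    if time_s is None:
        perm = rng.permutation(n_samples)
        return DatasetSplit(np.sort(perm[:n_train]), np.sort(perm[n_train:]), seed)
    # stratified: split each time point at the same fraction
    time_s = np.asarray(time_s)
    train, test = [], []
    for t in np.unique(time_s):
        idx = np.flatnonzero(time_s == t)
        k = int(round(frac * idx.size))
        perm = rng.permutation(idx)
        train.extend(perm[:k])
        test.extend(perm[k:])
    if not test or not train:
        raise ValueError("stratified split produced an empty subset")
    return DatasetSplit(np.sort(train), np.sort(test), seed)
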