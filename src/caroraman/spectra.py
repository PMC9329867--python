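"""Spectral data containers and plain-text I/O.

A :class:`Spectrum` is a single intensity trace on a strictly increasing
axis, either a Raman shift axis in cm^-1 or a wavelength axis in nm.
A :class:`SpectrumSet` is a stack of spectra sharing one axis, with
per-row labels (analyte, concentration in mg/mL, replicate id) carried in
a :class:`pandas.DataFrame`.

Files are wide-format delimited text: first column the axis, one column
per spectrum, header row required.  An optional JSON (or YAML) sidecar
maps column names to label dictionaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RAMAN_SHIFT = "raman_shift_cm1"
WAVELENGTH = "wavelength_nm"

#: default Raman analysis window, cm^-1
DEFAULT_WINDOW = (400.0, 3100.0)


@dataclass
class Spectrum:
    """One intensity trace on a strictly increasing axis.

    Parameters
    ----------
    axis : array-like
        Raman shift (cm^-1) or wavelength (nm), strictly increasing,
        length >= 2.
    intensity : array-like
        Same length as ``axis``; counts or absorbance units.
    axis_kind : str
        ``"raman_shift_cm1"`` or ``"wavelength_nm"``.
    meta : dict
        Free-form metadata (``source_wavelength_nm``, ``analyte``,
        ``concentration``, ``replicate`` ...).
    """

    axis: np.ndarray
    intensity: np.ndarray
    axis_kind: str = RAMAN_SHIFT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.axis.ndim != 1 or self.axis.size < 2:
            raise ValueError("axis must be a 1-D vector of length >= 2")
        if self.intensity.shape != self.axis.shape:
            raise ValueError(
                f"axis and intensity lengths differ: "
                f"{self.axis.size} vs {self.intensity.size}"
            )
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.axis_kind not in (RAMAN_SHIFT, WAVELENGTH):
            raise ValueError(f"unknown axis_kind {self.axis_kind!r}")
        if self.axis_kind == RAMAN_SHIFT:
            lam = self.meta.get("source_wavelength_nm")
            if lam is not None and lam <= 0:
                raise ValueError("source_wavelength_nm must be positive")

    def __len__(self) -> int:
        return self.axis.size

    def copy(self, intensity: np.ndarray | None = None) -> "Spectrum":
        """Copy, optionally replacing the intensity vector."""
        return Spectrum(
            self.axis.copy(),
            self.intensity.copy() if intensity is None else np.asarray(intensity, float),
            self.axis_kind,
            dict(self.meta),
        )

    def value_at(self, x: float) -> float:
        """Linearly interpolated intensity at axis position ``x``."""
        if x < self.axis[0] or x > self.axis[-1]:
            raise ValueError(
                f"{x} outside axis span [{self.axis[0]}, {self.axis[-1]}]"
            )
        return float(np.interp(x, self.axis, self.intensity))

    def crop(self, lo: float, hi: float) -> "Spectrum":
        """Channels with lo <= axis <= hi."""
        if lo >= hi:
            raise ValueError("crop requires lo < hi")
        mask = (self.axis >= lo) & (self.axis <= hi)
        if mask.sum() < 2:
            raise ValueError(
                f"crop [{lo}, {hi}] leaves fewer than 2 channels of the "
                f"axis span [{self.axis[0]}, {self.axis[-1]}]"
            )
        return Spectrum(self.axis[mask], self.intensity[mask], self.axis_kind, dict(self.meta))


@dataclass
class SpectrumSet:
    """Aligned matrix of spectra (rows) on one shared axis.

    ``labels`` is a DataFrame with one row per spectrum; conventional
    columns are ``analyte``, ``concentration`` (mg/mL) and ``replicate``.
    """

    axis: np.ndarray
    matrix: np.ndarray
    labels: pd.DataFrame
    axis_kind: str = RAMAN_SHIFT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if not np.all(np.diff(self.axis) > 0):
            raise ValueError("axis must be strictly increasing")
        if self.matrix.shape[1] != self.axis.size:
            raise ValueError(
                f"matrix has {self.matrix.shape[1]} channels, axis has {self.axis.size}"
            )
        if self.matrix.shape[0] < 1:
            raise ValueError("SpectrumSet needs at least one spectrum")
        if not isinstance(self.labels, pd.DataFrame):
            self.labels = pd.DataFrame(self.labels)
        if len(self.labels) != self.matrix.shape[0]:
            raise ValueError("labels must have one row per spectrum")
        if "concentration" in self.labels:
            conc = pd.to_numeric(self.labels["concentration"], errors="coerce")
            if (conc.dropna() < 0).any():
                raise ValueError("concentrations must be >= 0")

    @property
    def n_spectra(self) -> int:
        return self.matrix.shape[0]

    def __len__(self) -> int:
        return self.n_spectra

    def spectrum(self, i: int) -> Spectrum:
        """Row ``i`` as a standalone Spectrum; labels go into meta."""
        meta = dict(self.meta)
        meta.update({k: v for k, v in self.labels.iloc[i].items() if pd.notna(v)})
        return Spectrum(self.axis.copy(), self.matrix[i].copy(), self.axis_kind, meta)

    def __iter__(self):
        return (self.spectrum(i) for i in range(self.n_spectra))

    def subset(self, rows: Sequence[int] | np.ndarray) -> "SpectrumSet":
        rows = np.asarray(rows)
        return SpectrumSet(
            self.axis.copy(),
            self.matrix[rows],
            self.labels.iloc[rows].reset_index(drop=True),
            self.axis_kind,
            dict(self.meta),
        )

    @classmethod
    def from_spectra(cls, spectra: Iterable[Spectrum]) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("need at least one spectrum")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if s.axis.shape != axis.shape or not np.allclose(s.axis, axis):
                raise ValueError("all spectra must share one axis; resample first")
        labels = pd.DataFrame(
            [
                {
                    k: s.meta.get(k)
                    for k in ("analyte", "concentration", "replicate")
                    if k in s.meta
                }
                for s in spectra
            ]
        )
        if labels.empty:
            labels = pd.DataFrame(index=range(len(spectra)))
        return cls(axis.copy(), np.vstack([s.intensity for s in spectra]),
                   labels, spectra[0].axis_kind)


def _load_sidecar(path: Path) -> Mapping:
    text = path.read_text()
    if path.suffix.lower() in (".yaml", ".yml"):
        import yaml

        return yaml.safe_load(text) or {}
    return json.loads(text)


def read_spectra(
    path: str | Path,
    sidecar: str | Path | None = None,
    axis_kind: str = RAMAN_SHIFT,
) -> SpectrumSet:
    """Read a wide-format delimited text file of spectra.

    First column is the axis; every further column is one spectrum.  Rows
    are re-sorted to an ascending axis if needed.  ``sidecar`` (JSON or
    YAML) may map column names to label dicts, e.g.
    ``{"s1": {"analyte": "beta_carotene", "concentration": 0.5}}``.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need an axis column plus >=1 intensity column")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any() and not df[col].isna().any():
            row = int(np.argmax(coerced.isna().values))
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r}, data row {row}"
            )
        df[col] = coerced
    axis = df.iloc[:, 0].to_numpy(float)
    if np.unique(axis).size != axis.size:
        raise ValueError(f"{path}: duplicate axis values")
    order = np.argsort(axis)
    axis = axis[order]
    matrix = df.iloc[:, 1:].to_numpy(float)[order].T

    names = list(df.columns[1:])
    label_map: Mapping = {}
    if sidecar is not None:
        label_map = _load_sidecar(Path(sidecar))
    rows = []
    for name in names:
        entry = dict(label_map.get(name, {}))
        entry.setdefault("name", name)
        rows.append(entry)
    labels = pd.DataFrame(rows)
    return SpectrumSet(axis, matrix, labels, axis_kind=axis_kind)


def write_spectra(
    sset: SpectrumSet,
    path: str | Path,
    sidecar: str | Path | None = None,
) -> None:
    """Write a SpectrumSet as wide CSV (+ optional JSON label sidecar)."""
    path = Path(path)
    names = (
        [str(n) for n in sset.labels["name"]]
        if "name" in sset.labels
        else [f"s{i}" for i in range(sset.n_spectra)]
    )
    axis_col = "wavenumber_cm1" if sset.axis_kind == RAMAN_SHIFT else "wavelength_nm"
    df = pd.DataFrame({axis_col: sset.axis})
    for name, row in zip(names, sset.matrix):
        df[name] = row
    df.to_csv(path, index=False)
    if sidecar is not None:
        payload = {}
        for name, (_, lab) in zip(names, sset.labels.iterrows()):
            entry = {k: v for k, v in lab.items() if k != "name" and pd.notna(v)}
            payload[name] = entry
        Path(sidecar).write_text(json.dumps(payload, indent=2, default=float))


def resample(spectrum: Spectrum, grid: np.ndarray) -> Spectrum:
    """Linear interpolation of a spectrum onto ``grid``.

    The grid must lie within the original axis span; no extrapolation.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.min() < spectrum.axis[0] or grid.max() > spectrum.axis[-1]:
        raise ValueError(
            f"grid [{grid.min()}, {grid.max()}] extends beyond the axis span "
            f"[{spectrum.axis[0]}, {spectrum.axis[-1]}]; refusing to extrapolate"
        )
    values = np.interp(grid, spectrum.axis, spectrum.intensity)
    return Spectrum(grid, values, spectrum.axis_kind, dict(spectrum.meta))


def crop(sset: SpectrumSet, lo: float = DEFAULT_WINDOW[0], hi: float = DEFAULT_WINDOW[1]) -> SpectrumSet:
    """Restrict a SpectrumSet to channels with lo <= axis <= hi."""
    if lo >= hi:
        raise ValueError("crop requires lo < hi")
    mask = (sset.axis >= lo) & (sset.axis <= hi)
    if mask.sum() < 2:
        raise ValueError(
            f"crop [{lo}, {hi}] leaves fewer than 2 channels of axis span "
            f"[{sset.axis[0]}, {sset.axis[-1]}]"
        )
    return SpectrumSet(
        sset.axis[mask], sset.matrix[:, mask], sset.labels.copy(), sset.axis_kind, dict(sset.meta)
    )
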