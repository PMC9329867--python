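"""Smoothing, EMSC interferent removal and water internal-standard normalization.

The extended multiplicative signal correction (EMSC) step decomposes each
measured spectrum into a carotenoid reference contribution, known
interferent spectra (water, BSA), and a polynomial stray-light baseline,
by ordinary least squares.  The corrected spectrum keeps the analyte
contribution and the fit residual:

    corrected = spectrum - sum_j w_j * interferent_j - baseline

Because the same volume of solution is measured every time, the fitted
water coefficient acts as an internal standard: dividing the corrected
spectrum by it cancels per-measurement collection-efficiency variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial import chebyshev
from scipy.signal import savgol_filter

from .spectra import Spectrum, SpectrumSet, crop as crop_set

WATER_WEIGHT_TOL = 1e-6


def savgol_smooth(spectrum: Spectrum, order: int = 5, window: int = 9) -> Spectrum:
    """Savitzky-Golay smoothing (default polynomial order 5, window 9).

    Edge channels are handled by evaluating the polynomial fitted to the
    first/last window (``mode='interp'``), so a polynomial signal of
    degree <= ``order`` is reproduced exactly everywhere.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= order:
        raise ValueError(f"window ({window}) must exceed polynomial order ({order})")
    if window > len(spectrum):
        raise ValueError("window longer than the spectrum")
    smoothed = savgol_filter(spectrum.intensity, window, order, mode="interp")
    return spectrum.copy(intensity=smoothed)


@dataclass
class EMSCFit:
    """Least-squares decomposition of one spectrum.

    ``baseline_coeffs`` are Chebyshev coefficients on the axis rescaled
    to [-1, 1].  ``corrected`` keeps the analyte signal plus the fit
    residual; interferents and baseline are subtracted.
    """

    ref_weight: float
    interferent_weights: np.ndarray
    interferent_names: tuple
    baseline_coeffs: np.ndarray
    residual_norm: float
    corrected: Spectrum
    baseline: np.ndarray = field(repr=False, default=None)

    def weight(self, name: str) -> float:
        try:
            return float(self.interferent_weights[self.interferent_names.index(name)])
        except ValueError:
            raise KeyError(f"no interferent named {name!r}; have {self.interferent_names}") from None

    @property
    def water_weight(self) -> float | None:
        return self.weight("water") if "water" in self.interferent_names else None

    @property
    def bsa_weight(self) -> float | None:
        return self.weight("bsa") if "bsa" in self.interferent_names else None


class EMSC:
    """EMSC model: reference + interferents + Chebyshev baseline.

    Parameters
    ----------
    reference : Spectrum
        Analyte reference (pure-compound paste analogue).  Only needs to
        span the analyte signal so the baseline does not absorb it.
    interferents : sequence of Spectrum
        Known background spectra (water, BSA); names are taken from
        ``meta['analyte']`` falling back to ``interferent<i>``.
    poly_order : int
        Baseline polynomial order (default 7, deliberately generous).
    """

    def __init__(
        self,
        reference: Spectrum,
        interferents: Sequence[Spectrum] = (),
        poly_order: int = 7,
    ) -> None:
        if poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        self.reference = reference
        self.interferents = list(interferents)
        self.poly_order = poly_order
        axis = reference.axis
        for s in self.interferents:
            if s.axis.shape != axis.shape or not np.allclose(s.axis, axis):
                raise ValueError("reference and interferents must share one grid; resample first")
        self.names = ["reference"] + [
            s.meta.get("analyte", f"interferent{i}") for i, s in enumerate(self.interferents)
        ]
        x = 2.0 * (axis - axis[0]) / (axis[-1] - axis[0]) - 1.0
        self._poly = chebyshev.chebvander(x, poly_order)          # (n, p+1)
        cols = [reference.intensity] + [s.intensity for s in self.interferents]
        self._design = np.column_stack(cols + [self._poly])
        self._check_rank()

    def _check_rank(self) -> None:
        d = self._design
        norms = np.linalg.norm(d, axis=0)
        if (norms == 0).any():
            raise ValueError("design contains an all-zero column")
        rank = np.linalg.matrix_rank(d, tol=1e-10 * norms.max())
        if rank < d.shape[1]:
            # name the most collinear pair among the named (non-poly) columns
            k = 1 + len(self.interferents)
            unit = d[:, :k] / norms[:k]
            gram = np.abs(unit.T @ unit)
            np.fill_diagonal(gram, 0.0)
            i, j = np.unravel_index(np.argmax(gram), gram.shape)
            pair = f"{self.names[i]!r} and {self.names[j]!r}" if gram[i, j] > 0.999999 \
                else "a polynomial term and a spectral column"
            raise ValueError(f"EMSC design is rank deficient: collinear columns {pair}")

    @property
    def design(self) -> np.ndarray:
        """Design matrix (channels x columns): reference, interferents, polynomial."""
        return self._design

    def project(self, intensity: np.ndarray) -> dict:
        """OLS coefficients of an arbitrary vector on the EMSC design.

        Returns named weights (``reference``, each interferent) plus the
        ``baseline`` coefficient vector.  Used e.g. to evaluate how an
        attenuated copy of an interferent projects onto its own column.
        """
        intensity = np.asarray(intensity, dtype=float)
        coef, *_ = np.linalg.lstsq(self._design, intensity, rcond=None)
        n_int = len(self.interferents)
        out = {"reference": float(coef[0])}
        for name, w in zip(self.names[1:], coef[1 : 1 + n_int]):
            out[name] = float(w)
        out["baseline"] = coef[1 + n_int :].copy()
        return out

    def fit(self, spectrum: Spectrum) -> EMSCFit:
        """Ordinary least squares decomposition of one spectrum."""
        axis = self.reference.axis
        if spectrum.axis.shape != axis.shape or not np.allclose(spectrum.axis, axis):
            raise ValueError("spectrum is not on the model grid; resample first")
        coef, *_ = np.linalg.lstsq(self._design, spectrum.intensity, rcond=None)
        n_int = len(self.interferents)
        ref_w = float(coef[0])
        int_w = coef[1 : 1 + n_int].copy()
        poly_w = coef[1 + n_int :].copy()
        baseline = self._poly @ poly_w
        model = self._design @ coef
        residual = spectrum.intensity - model
        corrected = spectrum.intensity - baseline
        for w, s in zip(int_w, self.interferents):
            corrected = corrected - w * s.intensity
        meta = dict(spectrum.meta)
        meta["emsc_ref_weight"] = ref_w
        return EMSCFit(
            ref_weight=ref_w,
            interferent_weights=int_w,
            interferent_names=tuple(self.names[1:]),
            baseline_coeffs=poly_w,
            residual_norm=float(np.linalg.norm(residual)),
            corrected=Spectrum(axis.copy(), corrected, spectrum.axis_kind, meta),
            baseline=baseline,
        )


def emsc_fit(
    spectrum: Spectrum,
    reference: Spectrum,
    interferents: Sequence[Spectrum] = (),
    poly_order: int = 7,
) -> EMSCFit:
    """One-shot EMSC decomposition (see :class:`EMSC`)."""
    return EMSC(reference, interferents, poly_order).fit(spectrum)


def water_normalize(fit: EMSCFit, tol: float = WATER_WEIGHT_TOL) -> Spectrum:
    """Divide the corrected spectrum by its fitted water coefficient."""
    w = fit.water_weight
    if w is None:
        raise ValueError("EMSC fit has no 'water' interferent to normalise by")
    if w <= tol:
        raise ValueError(
            f"water coefficient non-positive ({w:.3g}); cannot normalise"
        )
    out = fit.corrected.copy(intensity=fit.corrected.intensity / w)
    out.meta["water_weight"] = w
    return out


@dataclass
class PreprocessConfig:
    """Settings of the smoothing -> EMSC -> normalization pipeline."""

    sg_order: int = 5
    sg_window: int = 9
    poly_order: int = 7
    crop: tuple = (400.0, 3100.0)
    normalize: bool = True
    smooth: bool = True

    def validate(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError(f"sg_window must be odd, got {self.sg_window}")
        if self.sg_window <= self.sg_order:
            raise ValueError("sg_window must exceed sg_order")
        if self.crop[0] >= self.crop[1]:
            raise ValueError("crop window must satisfy lo < hi")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")


def preprocess_set(
    sset: SpectrumSet,
    reference: Spectrum,
    interferents: Sequence[Spectrum] = (),
    cfg: PreprocessConfig | None = None,
    return_fits: bool = False,
):
    """Crop -> smooth -> EMSC-correct -> water-normalize every row.

    The analysis window is cropped *before* the EMSC fit (better
    conditioned than fitting the full range and cropping after); the
    reference and interferents are smoothed with the same settings as
    the data so the linear model stays exact on noise-free input.  Row
    order and labels are preserved.  Not idempotent: smoothing twice is
    not smoothing once.
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    lo, hi = cfg.crop
    sset = crop_set(sset, lo, hi)

    def prep(s: Spectrum) -> Spectrum:
        s = s.crop(lo, hi)
        return savgol_smooth(s, cfg.sg_order, cfg.sg_window) if cfg.smooth else s

    model = EMSC(prep(reference), [prep(s) for s in interferents], cfg.poly_order)
    rows, fits = [], []
    for spec in sset:
        s = savgol_smooth(spec, cfg.sg_order, cfg.sg_window) if cfg.smooth else spec
        fit = model.fit(s)
        fits.append(fit)
        out = water_normalize(fit) if (cfg.normalize and "water" in fit.interferent_names) else fit.corrected
        rows.append(out.intensity)
    result = SpectrumSet(
        sset.axis.copy(), np.vstack(rows), sset.labels.copy(), sset.axis_kind, dict(sset.meta)
    )
    return (result, fits, model) if return_fits else result
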