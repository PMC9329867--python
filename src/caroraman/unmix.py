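"""Constrained spectral unmixing of carotenoid admixtures.

The measured (preprocessed) admixture spectrum is modelled as a
self-absorption-attenuated weighted sum of the three pure-complex
component spectra:

    measured(shift) ~ T(u_mix(shift)) * sum_i A_i * ref_i(shift)
    u_mix(shift)    = sum_i A_i * (alpha_L,i d1 + alpha_R,i(shift) d2)

where the references are attenuation-free spectra at stock
concentration, A_i are non-negative stock-concentration fractions, and
the mixture optical depth is weight-additive (Beer's law).  The weights
are found by bounded nonlinear least squares with seeded multistart.
Fitted percentages 100*A_i/sum(A) are scored against the nominal
(as-prepared) percentages by ordinary linear regression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .selfabs import AbsorptionModel, attenuation_factor, stokes_wavelength
from .spectra import Spectrum

COMPONENT_ORDER = ("beta_carotene", "lutein", "zeaxanthin")


def nominal_percent(ratio: Sequence[float]) -> np.ndarray:
    """Nominal percentages 100 * parts_i / sum(parts) of a parts ratio."""
    parts = np.asarray(ratio, dtype=float)
    if (parts < 0).any():
        raise ValueError("ratio parts must be >= 0")
    total = parts.sum()
    if total == 0:
        raise ValueError("ratio parts must not all be zero")
    return 100.0 * parts / total


@dataclass
class UnmixResult:
    """Weights and derived percentages from one admixture fit."""

    weights: np.ndarray            # A_i >= 0, stock-concentration fractions
    component_names: tuple
    residual_norm: float
    converged: bool
    degenerate: bool = False       # all-zero input

    @property
    def fitted_pct(self) -> np.ndarray:
        """100 * A_i / sum(A); zeros for a degenerate (all-zero) input."""
        total = self.weights.sum()
        if total <= 0:
            return np.zeros_like(self.weights)
        return 100.0 * self.weights / total

    def fitted_ratio(self, total_parts: float) -> np.ndarray:
        """Percentages rescaled by the declared total nominal parts.

        A nominal 100:50:10 preparation has 160 total parts, so a
        perfect fit reports 100:50:10 again.
        """
        return self.fitted_pct * total_parts / 100.0

    def summary(self) -> str:
        lines = ["Admixture unmixing" + ("  [degenerate input]" if self.degenerate else "")]
        for name, w, p in zip(self.component_names, self.weights, self.fitted_pct):
            lines.append(f"  {name:<14s} A = {w:8.4f}   fitted = {p:6.2f} %")
        lines.append(f"  residual norm = {self.residual_norm:.4g}   converged = {self.converged}")
        return "\n".join(lines)


class AdmixtureModel:
    """Self-absorption-aware linear mixture model of three components.

    Parameters
    ----------
    references : sequence of Spectrum
        Attenuation-free pure-complex spectra at ``stock_conc``, on one
        shared Raman-shift grid (preprocessed the same way as the
        admixture spectra to be fitted).
    models : sequence of AbsorptionModel or None
        Per-component absorption; None (or all-zero absorbance) turns
        the fit into bounded non-negative linear least squares.
    d1, d2 : float
        Shared path factors (defaults: the fitted/printed values).
    stock_conc : float
        Concentration each reference represents (mg/mL).
    """

    def __init__(
        self,
        references: Sequence[Spectrum],
        models: Sequence[AbsorptionModel] | None = None,
        d1: float = 1.3,
        d2: float = 1.75,
        stock_conc: float = 1.0,
        names: Sequence[str] | None = None,
    ) -> None:
        if len(references) < 2:
            raise ValueError("need at least two component references")
        axis = references[0].axis
        for r in references[1:]:
            if r.axis.shape != axis.shape or not np.allclose(r.axis, axis):
                raise ValueError("references must share one grid; resample first")
        if models is not None and len(models) != len(references):
            raise ValueError("one AbsorptionModel per reference (or None)")
        if d1 < 0 or d2 < 0:
            raise ValueError("path factors must be >= 0")
        self.axis = axis
        self.references = list(references)
        self.models = list(models) if models is not None else None
        self.d1, self.d2 = d1, d2
        self.stock_conc = stock_conc
        self.names = tuple(
            names
            if names is not None
            else [r.meta.get("analyte", f"component{i}") for i, r in enumerate(references)]
        )
        self.ref_matrix = np.vstack([r.intensity for r in self.references])  # (m, n)
        # per-component optical depth at stock concentration, per channel
        if self.models is None:
            self._u_stock = np.zeros_like(self.ref_matrix)
        else:
            rows = []
            for mdl in self.models:
                lam_r = stokes_wavelength(mdl.laser_wavelength_nm, axis)
                alpha_l = mdl.alpha_at(mdl.laser_wavelength_nm, stock_conc)
                alpha_r = mdl.alpha_at(lam_r, stock_conc)
                rows.append(alpha_l * self.d1 + alpha_r * self.d2)
            self._u_stock = np.vstack(rows)

    def predict(self, weights: np.ndarray) -> np.ndarray:
        """Model spectrum for weights A."""
        weights = np.asarray(weights, dtype=float)
        u = weights @ self._u_stock
        return attenuation_factor(np.maximum(u, 0.0)) * (weights @ self.ref_matrix)

    def fit(
        self,
        measured: Spectrum,
        window: tuple[float, float] | None = None,
        bounds: tuple[float, float] = (0.0, 2.0),
        n_starts: int = 8,
        seed: int = 0,
    ) -> UnmixResult:
        """Bounded NLLS fit of the component weights to one spectrum.

        ``window`` restricts the fitted Raman-shift range (default: the
        full grid, which gave the best admixture fits).
        """
        if measured.axis.shape != self.axis.shape or not np.allclose(measured.axis, self.axis):
            raise ValueError("measured spectrum is not on the model grid; resample first")
        mask = np.ones_like(self.axis, dtype=bool)
        if window is not None:
            mask = (self.axis >= window[0]) & (self.axis <= window[1])
            if mask.sum() < len(self.references):
                raise ValueError("fit window leaves too few channels")
        y = measured.intensity[mask]
        refs = self.ref_matrix[:, mask]
        u_stock = self._u_stock[:, mask]
        m = refs.shape[0]

        if np.allclose(y, 0.0):
            return UnmixResult(
                weights=np.zeros(m),
                component_names=self.names,
                residual_norm=0.0,
                converged=True,
                degenerate=True,
            )

        def residuals(a):
            u = a @ u_stock
            return attenuation_factor(np.maximum(u, 0.0)) * (a @ refs) - y

        lo, hi = bounds
        rng = np.random.default_rng(seed)
        scale = max(float(np.max(np.abs(y)) / max(np.max(np.abs(refs)), 1e-12)), 1e-3)
        starts = [np.full(m, min(max(scale / m, lo + 1e-6), hi - 1e-6))]
        while len(starts) < max(n_starts, 1):
            starts.append(rng.uniform(lo + 1e-6, min(hi, lo + 2.0 * scale), size=m))
        best = None
        for x0 in starts:
            try:
                sol = optimize.least_squares(
                    residuals, x0, bounds=(np.full(m, lo), np.full(m, hi)),
                    x_scale=np.maximum(np.abs(x0), 1e-3),
                    ftol=1e-14, xtol=1e-14, gtol=1e-14,
                )
            except Exception:
                continue
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise RuntimeError(
                f"admixture fit failed to converge after {n_starts} starts"
                + ("" if best is None else f": {best.message}")
            )
        return UnmixResult(
            weights=np.asarray(best.x, dtype=float),
            component_names=self.names,
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            converged=bool(best.success),
        )


def fit_admixture(
    measured: Spectrum,
    references: Sequence[Spectrum],
    models: Sequence[AbsorptionModel] | None = None,
    d1: float = 1.3,
    d2: float = 1.75,
    stock_conc: float = 1.0,
    **fit_kw,
) -> UnmixResult:
    """One-shot admixture fit (see :class:`AdmixtureModel`)."""
    return AdmixtureModel(references, models, d1, d2, stock_conc).fit(measured, **fit_kw)


@dataclass
class RecoveryReport:
    """Fitted % versus nominal % regression across an admixture battery."""

    nominal_pct: np.ndarray
    fitted_pct: np.ndarray
    slope: float
    intercept: float
    r_squared: float
    std_error_pct: float
    per_component: Mapping[str, "RecoveryReport"] | None = None

    def summary(self) -> str:
        lines = [
            "Recovery of nominal composition",
            f"  n points      : {self.nominal_pct.size}",
            f"  slope         : {self.slope:.3f}",
            f"  intercept     : {self.intercept:.2f} %",
            f"  R^2           : {self.r_squared:.3f}",
            f"  std. error    : {self.std_error_pct:.2f} %",
        ]
        if self.per_component:
            for name, rep in self.per_component.items():
                lines.append(
                    f"  {name:<14s} R^2 = {rep.r_squared:.3f}, SE = {rep.std_error_pct:.2f} %"
                )
        return "\n".join(lines)


def recovery_regression(
    nominal_pct: Sequence[float],
    fitted_pct: Sequence[float],
    labels: Sequence[str] | None = None,
) -> RecoveryReport:
    """OLS of fitted % on nominal %; SE = sqrt(SS_res / (n - 2)).

    With ``labels`` (component name per point), per-component
    sub-reports are attached when a component has >= 3 points and a
    non-constant nominal range.
    """
    nominal = np.asarray(nominal_pct, dtype=float)
    fitted = np.asarray(fitted_pct, dtype=float)
    if nominal.size != fitted.size:
        raise ValueError("nominal and fitted vectors must have equal length")
    if nominal.size < 3:
        raise ValueError("need at least 3 points for a recovery regression")
    if np.ptp(nominal) == 0:
        raise ValueError("nominal percentages are constant; no regression possible")
    res = stats.linregress(nominal, fitted)
    ss_res = float(np.sum((fitted - (res.slope * nominal + res.intercept)) ** 2))
    report = RecoveryReport(
        nominal_pct=nominal,
        fitted_pct=fitted,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        std_error_pct=float(np.sqrt(ss_res / (nominal.size - 2))),
    )
    if labels is not None:
        labels = np.asarray(labels)
        sub = {}
        for name in dict.fromkeys(labels.tolist()):
            sel = labels == name
            if sel.sum() >= 3 and np.ptp(nominal[sel]) > 0:
                sub[name] = recovery_regression(nominal[sel], fitted[sel])
        report.per_component = sub
    return report
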