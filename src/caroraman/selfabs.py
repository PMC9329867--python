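"""Self-absorption modelling and correction for resonance Raman solutions.

When the excitation line (532 nm) falls inside the electronic absorption
band of the analyte, both the incident laser and the Stokes-shifted
scattered light are attenuated by the solution itself.  Integrating
Beer-Lambert decay over the (normalized) sampled depth gives the
measured intensity

    I_Rm = I_R0 * T(u),    T(u) = (1 - exp(-u)) / u,

with total optical depth u = alpha_L * d1 + alpha_R * d2, where alpha_L
and alpha_R are the natural extinctions at the laser and Raman
wavelengths and d1, d2 are dimensionless path factors absorbing the
(different) effective pathlengths of the absorption and Raman
geometries.  Correction divides the measured spectrum channel-wise by
T(u(shift)).  The path factors are estimated by nonlinear least squares
from the sub-linear concentration dependence of a strong band.

Absorbance utilities: scattering-background subtraction at 700 nm and
the Beer-law linearity check of absorbance versus concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .spectra import RAMAN_SHIFT, WAVELENGTH, Spectrum

LN10 = float(np.log(10.0))

#: path factors printed for the Beta Carotene series when no fit is run
PAPER_DEFAULTS = {"d1": 1.3, "d2": 1.75}


def stokes_wavelength(laser_nm: float, shift_cm1: float) -> float:
    """Wavelength (nm) of Stokes-scattered light at a given Raman shift.

    lambda_R = 1 / (1/lambda_L - shift * 1e-7)
    """
    if laser_nm <= 0:
        raise ValueError("laser wavelength must be positive")
    excitation_wavenumber = 1e7 / laser_nm
    if np.any(np.asarray(shift_cm1) >= excitation_wavenumber):
        raise ValueError(
            f"Raman shift must be below the excitation wavenumber "
            f"({excitation_wavenumber:.1f} cm^-1)"
        )
    return 1.0 / (1.0 / laser_nm - np.asarray(shift_cm1, dtype=float) * 1e-7)


def subtract_scatter_background(absorbance: Spectrum) -> Spectrum:
    """Subtract the 700 nm background value from the whole spectrum.

    The Mie-like scattering background is estimated by the (interpolated)
    absorbance at 700 nm, where the carotenoid complexes no longer
    absorb.  Negative residuals are clipped at zero for downstream
    extinction use; the raw subtracted values are kept in
    ``meta['raw_subtracted']``.
    """
    if absorbance.axis_kind != WAVELENGTH:
        raise ValueError("absorbance spectrum must be on a wavelength (nm) axis")
    if absorbance.axis[0] > 700.0 or absorbance.axis[-1] < 700.0:
        raise ValueError("absorbance axis must cover 700 nm")
    a700 = absorbance.value_at(700.0)
    raw = absorbance.intensity - a700
    out = absorbance.copy(intensity=np.clip(raw, 0.0, None))
    out.meta["raw_subtracted"] = raw
    out.meta["background_700nm"] = a700
    return out


def absorbance_linear_fit(
    concs: Sequence[float], a_at_peak: Sequence[float]
) -> tuple[float, float, float]:
    """OLS line through absorbance-vs-concentration points.

    Returns (slope, intercept, r_squared); the Beer-law linearity check
    that licenses scaling extinction linearly with concentration.
    """
    concs = np.asarray(concs, dtype=float)
    a = np.asarray(a_at_peak, dtype=float)
    if concs.size < 3:
        raise ValueError("need at least 3 points for a linearity check")
    if np.ptp(concs) == 0:
        raise ValueError("concentrations are constant; no line to fit")
    res = stats.linregress(concs, a)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


@dataclass
class AbsorptionModel:
    """Absorption properties of one carotenoid:BSA complex.

    ``absorbance`` is the background-subtracted visible absorbance
    spectrum (AU) measured at reference concentration ``c_ref`` (mg/mL);
    extinction at any other concentration scales linearly (Beer's law).
    ``d1``/``d2`` are the dimensionless path factors at the laser and
    Raman wavelengths; ``k`` the fitted intensity-per-concentration
    amplitude of the attenuation-free response.
    """

    laser_wavelength_nm: float
    absorbance: Spectrum
    c_ref: float = 1.0
    d1: float | None = None
    d2: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if self.c_ref <= 0:
            raise ValueError("c_ref must be positive")
        if self.absorbance.axis_kind != WAVELENGTH:
            raise ValueError("absorbance must be on a wavelength (nm) axis")
        for d in (self.d1, self.d2):
            if d is not None and d < 0:
                raise ValueError("path factors must be >= 0")

    @classmethod
    def from_raw_absorbance(
        cls, absorbance: Spectrum, laser_wavelength_nm: float, c_ref: float = 1.0, **kw
    ) -> "AbsorptionModel":
        """Build from an as-measured absorbance spectrum (background on)."""
        return cls(laser_wavelength_nm, subtract_scatter_background(absorbance), c_ref, **kw)

    def with_paper_defaults(self) -> "AbsorptionModel":
        """Copy with the printed default path factors d1=1.3, d2=1.75."""
        return replace(self, **PAPER_DEFAULTS)

    def alpha_at(self, wavelength_nm, conc: float):
        """Natural extinction at ``wavelength_nm`` for ``conc`` mg/mL.

        alpha = ln(10) * A'(lambda) * conc / c_ref; the decadic-to-natural
        conversion, with pathlength absorbed into d1/d2.
        """
        lam = np.asarray(wavelength_nm, dtype=float)
        ax = self.absorbance.axis
        if lam.min() < ax[0] or lam.max() > ax[-1]:
            raise ValueError(
                f"wavelength {lam.min():.1f}-{lam.max():.1f} nm outside the "
                f"absorbance axis [{ax[0]:.1f}, {ax[-1]:.1f}] nm"
            )
        a = np.interp(lam, ax, self.absorbance.intensity)
        out = LN10 * a * conc / self.c_ref
        return float(out) if np.isscalar(wavelength_nm) else out

    @property
    def alpha_laser_per_mgml(self) -> float:
        return self.alpha_at(self.laser_wavelength_nm, 1.0)


def attenuation_factor(u):
    """T(u) = (1 - e^-u)/u, the depth-integrated Beer-Lambert factor.

    T(0) = 1 (analytic limit used for u < 1e-8); strictly decreasing.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("optical depth u must be >= 0")
    small = u_arr < 1e-8
    safe = np.where(small, 1.0, u_arr)
    t = np.where(small, 1.0 - u_arr / 2.0, -np.expm1(-safe) / safe)
    return float(t) if np.isscalar(u) else t


def optical_depth(
    model: AbsorptionModel,
    shift_cm1,
    conc: float,
    d1: float | None = None,
    d2: float | None = None,
    per_channel: bool = True,
    reference_shift_cm1: float = 1519.0,
):
    """u(shift) = alpha_L d1 + alpha_R(lambda_R(shift)) d2 at ``conc``.

    With ``per_channel=False`` the single extinction at the reference
    band's Stokes wavelength (579 nm for 1519 cm^-1 at 532 nm) is used
    for the whole spectrum.
    """
    d1 = model.d1 if d1 is None else d1
    d2 = model.d2 if d2 is None else d2
    if d1 is None or d2 is None:
        raise ValueError("path factors d1/d2 are not set; fit them or use paper defaults")
    lam_l = model.laser_wavelength_nm
    alpha_l = model.alpha_at(lam_l, conc)
    if per_channel:
        lam_r = stokes_wavelength(lam_l, np.asarray(shift_cm1, dtype=float))
    else:
        lam_r = stokes_wavelength(lam_l, reference_shift_cm1)
    try:
        alpha_r = model.alpha_at(lam_r, conc)
    except ValueError as err:
        raise ValueError(
            f"{err}; crop the Raman spectrum so all Stokes wavelengths fall "
            f"inside the absorbance axis"
        ) from None
    return alpha_l * d1 + alpha_r * d2


def correct_self_absorption(
    spectrum: Spectrum,
    model: AbsorptionModel,
    conc: float,
    per_channel: bool = True,
) -> Spectrum:
    """Divide a measured Raman spectrum channel-wise by T(u(shift)).

    Output intensity >= input intensity channel-wise (T <= 1).
    """
    if spectrum.axis_kind != RAMAN_SHIFT:
        raise ValueError("expected a Raman-shift (cm^-1) spectrum")
    u = optical_depth(model, spectrum.axis, conc, per_channel=per_channel)
    t = attenuation_factor(u)
    out = spectrum.copy(intensity=spectrum.intensity / t)
    out.meta["self_absorption_corrected"] = True
    return out


@dataclass
class PathFactorFit:
    """Results of the nonlinear path-factor fit.

    d1 and d2 enter the model only through u = alpha_L d1 + alpha_R d2;
    when alpha_R/alpha_L is (near-)constant across the series only that
    combination is identifiable and ``collinear`` is set.  ``u_slope``
    is the identifiable quantity: du/dc evaluated with the fitted pair.
    """

    d1: float
    d2: float
    k: float
    residual_norm: float
    u_slope: float
    collinear: bool
    converged: bool
    n_starts: int
    message: str = ""

    def predict(self, model: "AbsorptionModel", concs) -> np.ndarray:
        concs = np.asarray(concs, dtype=float)
        lam_r = stokes_wavelength(model.laser_wavelength_nm, 1519.0)
        u = np.array(
            [
                model.alpha_at(model.laser_wavelength_nm, c) * self.d1
                + model.alpha_at(lam_r, c) * self.d2
                for c in concs
            ]
        )
        return self.k * concs * attenuation_factor(u)


def fit_path_factors(
    concs: Sequence[float],
    peak_intensities: Sequence[float],
    model: AbsorptionModel,
    shift_cm1: float = 1519.0,
    n_starts: int = 8,
    seed: int = 0,
    bounds: tuple = (0.0, 20.0),
) -> PathFactorFit:
    """Fit (k, d1, d2) to the sub-linear concentration response.

    Minimizes sum_c [I(c) - k * c * T(alpha_L(c) d1 + alpha_R(c) d2)]^2
    with d1, d2 in ``bounds`` and k > 0, from ``n_starts`` log-uniform
    random initializations of (d1, d2).
    """
    concs = np.asarray(concs, dtype=float)
    y = np.asarray(peak_intensities, dtype=float)
    if concs.size != y.size:
        raise ValueError("concs and peak_intensities must have equal length")
    if concs.size < 4:
        raise ValueError("need >= 4 concentrations spanning the sub-linear regime")
    if np.allclose(y, 0):
        raise ValueError("all peak intensities are zero; nothing to fit")

    lam_l = model.laser_wavelength_nm
    lam_r = stokes_wavelength(lam_l, shift_cm1)
    alpha_l = np.array([model.alpha_at(lam_l, c) for c in concs])
    alpha_r = np.array([model.alpha_at(lam_r, c) for c in concs])

    # degenerate: no absorption at all -> T == 1, plain linear response
    if np.allclose(alpha_l, 0) and np.allclose(alpha_r, 0):
        k = float(np.dot(concs, y) / np.dot(concs, concs))
        resid = float(np.linalg.norm(y - k * concs))
        return PathFactorFit(0.0, 0.0, k, resid, 0.0, collinear=True,
                             converged=True, n_starts=0,
                             message="zero absorbance: d1/d2 unidentifiable, linear fit returned")

    # alpha_R/alpha_L constant across the series <=> only u identifiable
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(alpha_l > 0, alpha_r / np.where(alpha_l > 0, alpha_l, 1.0), np.nan)
    ratio = ratio[np.isfinite(ratio)]
    collinear = ratio.size > 0 and (np.ptp(ratio) <= 1e-6 * max(1.0, np.abs(ratio).max()))

    def residuals(theta):
        k, d1, d2 = theta
        return k * concs * attenuation_factor(alpha_l * d1 + alpha_r * d2) - y

    rng = np.random.default_rng(seed)
    k0 = max(y.max() / max(concs.max(), 1e-12), 1e-9)
    best = None
    lo, hi = bounds
    for _ in range(max(n_starts, 1)):
        d0 = np.exp(rng.uniform(np.log(0.1), np.log(10.0), size=2))
        d0 = np.clip(d0, lo + 1e-9, hi - 1e-9)
        # compensate the start's attenuation so k0 is in the right ballpark
        t_mid = attenuation_factor(alpha_l * d0[0] + alpha_r * d0[1]).mean()
        x0 = np.array([k0 / max(t_mid, 1e-6), d0[0], d0[1]])
        try:
            sol = optimize.least_squares(
                residuals, x0,
                bounds=([1e-12, lo, lo], [np.inf, hi, hi]),
                x_scale=np.maximum(np.abs(x0), 1e-3),
                ftol=1e-14, xtol=1e-14, gtol=1e-14,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        raise RuntimeError(
            f"path-factor fit failed to converge after {n_starts} starts"
            + ("" if best is None else f": {best.message}")
        )
    k, d1, d2 = (float(v) for v in best.x)
    # identifiable combination: du/dc (alpha is linear in c)
    a_l1 = model.alpha_at(lam_l, 1.0)
    a_r1 = model.alpha_at(lam_r, 1.0)
    return PathFactorFit(
        d1=d1, d2=d2, k=k,
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        u_slope=float(a_l1 * d1 + a_r1 * d2),
        collinear=bool(collinear),
        converged=bool(best.success),
        n_starts=n_starts,
        message="d1/d2 enter only through u = alpha_L d1 + alpha_R d2; "
                "report u_slope when collinear" if collinear else "",
    )
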