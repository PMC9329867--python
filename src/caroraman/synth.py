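"""Synthetic 532 nm solution Raman and visible-absorbance spectra.

The generator emulates resonance-Raman measurements of carotenoid:BSA
complexes in water: Lorentzian carotenoid bands (strong nu1 ~1519, nu2
~1158, nu3 ~1004 cm^-1 plus weak fundamentals and broad overtones), a
water spectrum (1640 cm^-1 bend, broad OH stretch rising towards the
3100 cm^-1 grid edge), a BSA protein spectrum (sharp phenylalanine 1004,
Amide I ~1650, CH ~2900 cm^-1), a slowly varying stray-light baseline,
Beer-Lambert self-absorption attenuation of the emitted light, and
multiplicative + additive Gaussian noise.  Every stochastic quantity is
drawn from a seeded generator, so fixed seeds give bit-identical output.

The three carotenoids differ by the position of the strongest C=C
stretch band (nu1): Beta Carotene < Zeaxanthin < Lutein in cm^-1, the
relative strength of the 1004/1158 cm^-1 bands (strongest in Beta
Carotene), and the overtone region > 2000 cm^-1 (strongest and slightly
shifted in Zeaxanthin).  Visible absorbance bands peak at 540 / 528 /
486 nm for Beta Carotene / Zeaxanthin / Lutein complexes, on top of a
monotone Mie-like scattering background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .spectra import RAMAN_SHIFT, WAVELENGTH, Spectrum, SpectrumSet

CAROTENOIDS = ("beta_carotene", "lutein", "zeaxanthin")
COMPONENTS = CAROTENOIDS + ("water", "bsa")


@dataclass(frozen=True)
class Peak:
    """One vibrational band: center (cm^-1), FWHM (cm^-1), relative height."""

    center: float
    fwhm: float
    height: float
    shape: str = "lorentzian"  # or "gaussian"

    def profile(self, axis: np.ndarray) -> np.ndarray:
        if self.fwhm <= 0:
            raise ValueError("peak width must be positive")
        if self.height < 0:
            raise ValueError("peak height must be >= 0")
        if self.shape == "lorentzian":
            g = self.fwhm / 2.0
            return self.height * g**2 / ((axis - self.center) ** 2 + g**2)
        if self.shape == "gaussian":
            sigma = self.fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
            return self.height * np.exp(-0.5 * ((axis - self.center) / sigma) ** 2)
        raise ValueError(f"unknown peak shape {self.shape!r}")


PeakTable = Sequence[Peak]

# nu1 defaults fix only the ordering Beta Carotene < Zeaxanthin < Lutein
# and the ~1519 cm^-1 vicinity; the exact numbers are package choices.
NU1_CENTERS = {"beta_carotene": 1516.0, "zeaxanthin": 1521.0, "lutein": 1524.0}


def _carotenoid_peaks(name: str, nu1: float) -> tuple[Peak, ...]:
    # nu2/nu3 relatively stronger in Beta Carotene; overtones strongest
    # and shifted in Zeaxanthin.
    carotene = name == "beta_carotene"
    zea = name == "zeaxanthin"
    ot_shift = 8.0 if zea else 0.0
    ot_gain = 1.5 if zea else 1.0
    return (
        Peak(nu1, 12.0, 1.0),
        Peak(1158.0, 12.0, 0.62 if carotene else 0.52),
        Peak(1004.0, 10.0, 0.40 if carotene else 0.30),
        Peak(950.0, 14.0, 0.06),
        Peak(2157.0 + ot_shift, 40.0, 0.05 * ot_gain),
        Peak(2526.0 + ot_shift, 40.0, 0.04 * ot_gain),
        Peak(2679.0 + ot_shift, 40.0, 0.05 * ot_gain),
        Peak(2950.0, 40.0, 0.03),
        Peak(3036.0 + ot_shift, 40.0, 0.04 * ot_gain),
    )


def default_peak_tables() -> dict[str, tuple[Peak, ...]]:
    tables = {
        name: _carotenoid_peaks(name, NU1_CENTERS[name]) for name in CAROTENOIDS
    }
    tables["water"] = (
        Peak(1640.0, 90.0, 0.25, "gaussian"),
        Peak(3300.0, 400.0, 1.0, "gaussian"),
    )
    tables["bsa"] = (
        Peak(1004.0, 10.0, 0.50),
        Peak(1240.0, 40.0, 0.25, "gaussian"),
        Peak(1450.0, 35.0, 0.30, "gaussian"),
        Peak(1650.0, 50.0, 0.60, "gaussian"),
        Peak(2880.0, 50.0, 0.70, "gaussian"),
        Peak(2935.0, 45.0, 1.00, "gaussian"),
    )
    return tables


@dataclass(frozen=True)
class AbsorbanceBand:
    """Visible absorption of one carotenoid:BSA complex.

    ``peak_au_per_mgml`` is the background-subtracted absorbance at the
    longest-wavelength maximum for a 1 mg/mL solution.  An optional
    vibronic shoulder to the blue (off by default: it merges with the
    main band and would displace the stated maximum) mimics the
    carotenoid double-hump.
    """

    peak_nm: float
    sigma_nm: float
    peak_au_per_mgml: float
    shoulder_rel: float = 0.0
    shoulder_offset_nm: float = 60.0

    def profile(self, wavelength_nm: np.ndarray) -> np.ndarray:
        """AU per mg/mL, before any scattering background."""
        lam = np.asarray(wavelength_nm, dtype=float)
        main = np.exp(-0.5 * ((lam - self.peak_nm) / self.sigma_nm) ** 2)
        out = main + self.shoulder_rel * np.exp(
            -0.5 * ((lam - (self.peak_nm - self.shoulder_offset_nm)) / self.sigma_nm) ** 2
        )
        # value at the nominal peak, so peak_au_per_mgml is hit there
        norm = 1.0 + self.shoulder_rel * np.exp(
            -0.5 * (self.shoulder_offset_nm / self.sigma_nm) ** 2
        )
        return self.peak_au_per_mgml * out / norm


# Longest-wavelength maxima 540 / 528 / 486 nm; peak amplitudes chosen so
# the 532 nm extinction orders Zeaxanthin > Beta Carotene > Lutein
# (relative resonance enhancement) and saturation of the measured Raman
# response sets in near 0.6 mg/mL.
DEFAULT_ABSORBANCE = {
    "beta_carotene": AbsorbanceBand(540.0, 35.0, 0.40),
    "zeaxanthin": AbsorbanceBand(528.0, 32.0, 0.48),
    "lutein": AbsorbanceBand(486.0, 30.0, 0.32),
}

# Stray-light baseline: positive, decreasing with wavenumber.  Power-basis
# coefficients of the axis rescaled to [0, 1]; expansion of
# 0.3 + 0.8 (1 - x)^3, padded to degree 5 (EMSC deliberately
# over-parameterizes with order 7).
DEFAULT_BASELINE_COEFFS = (1.1, -2.4, 2.4, -0.8, 0.0, 0.0)


@dataclass
class SynthConfig:
    """Stated world of the synthetic experiment.

    Defaults mirror the measurement conditions the analysis assumes:
    532 nm excitation, 400-3100 cm^-1 analysis window at 2 cm^-1 steps,
    fixed water/BSA amplitudes per simulation, self-absorption with path
    factors d1/d2, ~1% multiplicative and 0.5%-of-max additive noise and
    a 5% per-spectrum collection-gain jitter that water normalization is
    meant to cancel.
    """

    grid: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 3100.0 + 1e-9, 2.0)
    )
    source_wavelength_nm: float = 532.0
    peak_tables: dict = field(default_factory=default_peak_tables)
    nu1_centers: dict = field(default_factory=lambda: dict(NU1_CENTERS))
    absorbance: dict = field(default_factory=lambda: dict(DEFAULT_ABSORBANCE))
    absorbance_grid: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 700.0 + 1e-9, 1.0)
    )
    scatter_au_400: float = 0.08          # Mie-like background AU at 400 nm
    scatter_au_per_mgml: float = 0.02     # its concentration dependence
    baseline_coeffs: tuple = DEFAULT_BASELINE_COEFFS
    water_amplitude: float = 0.6
    bsa_amplitude: float = 0.3
    attenuation: bool = True
    d1: float = 1.3
    d2: float = 1.75
    noise_multiplicative: float = 0.01    # fractional sd per channel
    noise_additive: float = 0.005         # sd as fraction of max clean signal
    gain_jitter: float = 0.05             # per-spectrum lognormal gain sd
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        nu1 = self.nu1_centers
        if not (nu1["beta_carotene"] < nu1["zeaxanthin"] < nu1["lutein"]):
            raise ValueError(
                "nu1 ordering must be beta_carotene < zeaxanthin < lutein (cm^-1)"
            )
        for label, sd in (
            ("noise_multiplicative", self.noise_multiplicative),
            ("noise_additive", self.noise_additive),
            ("gain_jitter", self.gain_jitter),
        ):
            if sd < 0:
                raise ValueError(f"{label} must be >= 0")

    def noise_free(self) -> "SynthConfig":
        """Copy with every noise source switched off."""
        return replace(
            self, noise_multiplicative=0.0, noise_additive=0.0, gain_jitter=0.0
        )

    def without_attenuation(self) -> "SynthConfig":
        return replace(self, attenuation=False)


def make_reference_spectrum(component: str, cfg: SynthConfig | None = None) -> Spectrum:
    """Noise-free, baseline-free, unit-maximum spectrum of one component.

    The analogue of measuring a thick paste of the pure compound to serve
    as the EMSC reference, or of the pure water / BSA interferent
    spectra.
    """
    cfg = cfg or SynthConfig()
    try:
        peaks = cfg.peak_tables[component]
    except KeyError:
        raise ValueError(
            f"unknown component {component!r}; known: {sorted(cfg.peak_tables)}"
        ) from None
    if not peaks:
        raise ValueError(f"component {component!r} has an empty peak table")
    signal = np.zeros_like(cfg.grid)
    for peak in peaks:
        signal += peak.profile(cfg.grid)
    peak_max = signal.max()
    if peak_max <= 0:
        raise ValueError(f"component {component!r} produced a non-positive spectrum")
    return Spectrum(
        cfg.grid.copy(),
        signal / peak_max,
        RAMAN_SHIFT,
        {"analyte": component, "source_wavelength_nm": cfg.source_wavelength_nm,
         "role": "reference"},
    )


def scatter_background(cfg: SynthConfig, conc: float = 0.0) -> np.ndarray:
    """Mie-like absorbance background, monotone decreasing in wavelength."""
    lam = cfg.absorbance_grid
    amp = cfg.scatter_au_400 + cfg.scatter_au_per_mgml * conc
    return amp * (400.0 / lam) ** 4


def simulate_absorbance(component: str, conc: float, cfg: SynthConfig | None = None) -> Spectrum:
    """Visible absorbance spectrum (AU) of one complex at ``conc`` mg/mL."""
    cfg = cfg or SynthConfig()
    if conc < 0:
        raise ValueError("concentration must be >= 0")
    try:
        band = cfg.absorbance[component]
    except KeyError:
        raise ValueError(
            f"no absorbance band for component {component!r}; "
            f"known: {sorted(cfg.absorbance)}"
        ) from None
    au = conc * band.profile(cfg.absorbance_grid) + scatter_background(cfg, conc)
    return Spectrum(
        cfg.absorbance_grid.copy(),
        au,
        WAVELENGTH,
        {"analyte": component, "concentration": conc, "role": "absorbance"},
    )


def unit_alpha(component: str, cfg: SynthConfig, wavelength_nm) -> np.ndarray:
    """Natural extinction per mg/mL: ln(10) * A'(lambda) at 1 mg/mL.

    A' is the 700 nm background-subtracted absorbance of the 1 mg/mL
    solution, so the attenuation embedded in simulated measurements is
    exactly what an analyst reconstructs from
    ``simulate_absorbance(component, 1.0)`` after background
    subtraction; extinction is Beer-linear in concentration by
    construction.
    """
    lam = np.asarray(wavelength_nm, dtype=float)
    band = cfg.absorbance[component]
    scatter_amp = cfg.scatter_au_400 + cfg.scatter_au_per_mgml  # at 1 mg/mL
    scatter_diff = scatter_amp * ((400.0 / lam) ** 4 - (400.0 / 700.0) ** 4)
    return np.log(10.0) * np.clip(band.profile(lam) + scatter_diff, 0.0, None)


def _optical_depth(
    composition: Mapping[str, float], cfg: SynthConfig
) -> np.ndarray:
    """u(shift) = sum_i alpha_L,i d1 + alpha_R,i(shift) d2 over carotenoids."""
    lam_l = cfg.source_wavelength_nm
    shift = cfg.grid
    lam_r = 1.0 / (1.0 / lam_l - shift * 1e-7)
    u = np.zeros_like(shift)
    for name, conc in composition.items():
        if conc <= 0 or name not in cfg.absorbance:
            continue
        alpha_l = float(unit_alpha(name, cfg, np.array([lam_l]))[0]) * conc
        alpha_r = unit_alpha(name, cfg, lam_r) * conc
        u += alpha_l * cfg.d1 + alpha_r * cfg.d2
    return u


def attenuation_profile(composition: Mapping[str, float], cfg: SynthConfig) -> np.ndarray:
    """Closed-form attenuation T(u) = (1 - e^-u)/u per channel.

    Ground-truth counterpart of the correction implemented in
    :mod:`caroraman.selfabs`; exposed so tests can compare round trips
    against the exact factor.
    """
    u = _optical_depth(composition, cfg)
    return np.where(u < 1e-8, 1.0 - u / 2.0, -np.expm1(-np.maximum(u, 1e-300)) / np.where(u == 0, 1.0, u))


def baseline_profile(cfg: SynthConfig) -> np.ndarray:
    """Stray-light baseline evaluated on the grid."""
    x = (cfg.grid - cfg.grid[0]) / (cfg.grid[-1] - cfg.grid[0])
    return np.polynomial.polynomial.polyval(x, np.asarray(cfg.baseline_coeffs))


def clean_signal(composition: Mapping[str, float], cfg: SynthConfig) -> np.ndarray:
    """Attenuation-free emitted signal: carotenoids + water + BSA + baseline."""
    signal = baseline_profile(cfg).copy()
    signal += cfg.water_amplitude * make_reference_spectrum("water", cfg).intensity
    signal += cfg.bsa_amplitude * make_reference_spectrum("bsa", cfg).intensity
    for name, conc in composition.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc > 0:
            signal += conc * make_reference_spectrum(name, cfg).intensity
    return signal


def simulate_measurement(
    composition: Mapping[str, float],
    cfg: SynthConfig | None = None,
    seed: int | None = None,
) -> Spectrum:
    """One measured solution spectrum with ground truth in ``meta``.

    intensity = gain * T(u) * (sum_i c_i ref_i + water + BSA + baseline)
                * (1 + mult. noise) + additive noise
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    signal = clean_signal(composition, cfg)
    if cfg.attenuation:
        signal = signal * attenuation_profile(composition, cfg)
    gain = float(np.exp(cfg.gain_jitter * rng.standard_normal())) if cfg.gain_jitter else 1.0
    measured = gain * signal
    if cfg.noise_multiplicative:
        measured = measured * (1.0 + cfg.noise_multiplicative * rng.standard_normal(measured.size))
    if cfg.noise_additive:
        measured = measured + cfg.noise_additive * signal.max() * rng.standard_normal(measured.size)
    meta = {
        "source_wavelength_nm": cfg.source_wavelength_nm,
        "composition": dict(composition),
        "gain": gain,
        "attenuation": cfg.attenuation,
        "d1": cfg.d1,
        "d2": cfg.d2,
    }
    carotenoids = [n for n, c in composition.items() if n in CAROTENOIDS and c > 0]
    if len(carotenoids) == 1:
        meta["analyte"] = carotenoids[0]
        meta["concentration"] = composition[carotenoids[0]]
    return Spectrum(cfg.grid.copy(), measured, RAMAN_SHIFT, meta)


DEFAULT_CONCENTRATIONS = tuple(np.round(np.linspace(0.05, 2.0, 14), 4))


def simulate_concentration_series(
    concs: Sequence[float] | None = None,
    replicates: int = 6,
    cfg: SynthConfig | None = None,
    seed: int = 0,
    analyte: str = "beta_carotene",
) -> SpectrumSet:
    """Replicated single-analyte dilution series (default 0.05-2.0 mg/mL)."""
    cfg = cfg or SynthConfig()
    concs = DEFAULT_CONCENTRATIONS if concs is None else tuple(concs)
    if len(concs) == 0:
        raise ValueError("need at least one concentration")
    root = np.random.default_rng(seed)
    seeds = root.integers(0, 2**31 - 1, size=len(concs) * replicates)
    spectra = []
    i = 0
    for conc in concs:
        for rep in range(replicates):
            s = simulate_measurement({analyte: float(conc)}, cfg, seed=int(seeds[i]))
            s.meta.update({"analyte": analyte, "concentration": float(conc), "replicate": rep})
            spectra.append(s)
            i += 1
    sset = SpectrumSet.from_spectra(spectra)
    sset.meta["seed"] = seed
    return sset


# Admixture B:L:Z part ratios as prepared (Methods listing).
DEFAULT_ADMIXTURE_RATIOS = (
    (100, 40, 20),
    (100, 30, 30),
    (100, 50, 10),
    (100, 20, 40),
)


def simulate_admixture(
    ratio: Sequence[float],
    stock_conc: float = 1.0,
    cfg: SynthConfig | None = None,
    seed: int = 0,
) -> Spectrum:
    """Admixture of the three carotenoids mixed by volume parts B:L:Z.

    Component concentrations are ``stock_conc * parts / sum(parts)``
    (equal-stock volume mixing); ``meta`` records the parts and the
    nominal percentages 100 * parts / sum(parts).
    """
    cfg = cfg or SynthConfig()
    parts = np.asarray(ratio, dtype=float)
    if parts.size != 3:
        raise ValueError("ratio must have three parts (B:L:Z)")
    if (parts < 0).any():
        raise ValueError("ratio parts must be >= 0")
    total = parts.sum()
    if total == 0:
        raise ValueError("ratio parts must not all be zero")
    composition = {
        name: stock_conc * p / total for name, p in zip(("beta_carotene", "lutein", "zeaxanthin"), parts)
    }
    s = simulate_measurement(composition, cfg, seed=seed)
    s.meta["parts"] = tuple(float(p) for p in parts)
    s.meta["nominal_pct"] = tuple(100.0 * p / total for p in parts)
    s.meta["stock_conc"] = stock_conc
    return s
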