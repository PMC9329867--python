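"""End-to-end synthetic-twin experiment driver.

``run_paper_twin`` executes the full analysis chain on generated data:
simulate -> smooth/EMSC/water-normalize -> path-factor fit and
self-absorption correction -> PLSR calibration with repeated 10-fold CV
(RMSECV, LOD, CV R^2) -> PCA differentiation of the three carotenoids
(full and pairwise) -> admixture unmixing with a fitted-vs-nominal
recovery regression.  Everything is driven by one seed; two runs with
the same config hash and seed produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from . import chemometrics, preprocess, selfabs, synth, unmix
from .spectra import SpectrumSet, write_spectra

log = logging.getLogger("caroraman")

CAROTENOIDS = synth.CAROTENOIDS


@dataclass
class PipelineConfig:
    """Settings of the synthetic-twin experiment.

    Printed-method defaults: Savitzky-Golay order 5 / window 9, EMSC
    polynomial order 7, 400-3100 cm^-1 window, 532 nm source, 10-fold
    cross-validation repeated 100 times, admixture ratios
    100:40:20 / 100:30:30 / 100:50:10 / 100:20:40.  The replicate
    layout (41 concentrations x 2 replicates = 82 calibration spectra)
    is a package choice; the study does not state its own.
    """

    seed: int = 0
    # preprocessing
    sg_order: int = 5
    sg_window: int = 9
    emsc_poly: int = 7
    crop: tuple = (400.0, 3100.0)
    # self-absorption
    laser_nm: float = 532.0
    d1: float = selfabs.PAPER_DEFAULTS["d1"]
    d2: float = selfabs.PAPER_DEFAULTS["d2"]
    fit_path_factors: bool = True
    # calibration
    n_concentrations: int = 41
    conc_range: tuple = (0.05, 2.0)
    replicates: int = 2
    n_lv: int = 8
    cv_folds: int = 10
    cv_repeats: int = 100
    # differentiation
    pca_replicates: int = 10
    # unmixing
    admixture_ratios: tuple = synth.DEFAULT_ADMIXTURE_RATIOS
    admixture_replicates: int = 3
    stock_conc: float = 1.0
    unmix_window: tuple | None = None
    unmix_starts: int = 8

    def validate(self) -> None:
        preprocess.PreprocessConfig(
            sg_order=self.sg_order, sg_window=self.sg_window,
            poly_order=self.emsc_poly, crop=tuple(self.crop),
        ).validate()
        if self.laser_nm <= 0:
            raise ValueError("laser wavelength must be positive")
        if self.d1 < 0 or self.d2 < 0:
            raise ValueError("path factors must be >= 0")
        if self.n_concentrations < 4:
            raise ValueError("need >= 4 concentrations")
        if self.conc_range[0] <= 0 or self.conc_range[0] >= self.conc_range[1]:
            raise ValueError("conc_range must be 0 < lo < hi")
        if self.replicates < 1 or self.pca_replicates < 2 or self.admixture_replicates < 1:
            raise ValueError("replicate counts out of range")
        if self.cv_folds < 2 or self.cv_repeats < 1 or self.n_lv < 1:
            raise ValueError("cross-validation settings out of range")
        if self.stock_conc <= 0:
            raise ValueError("stock_conc must be positive")
        if not self.admixture_ratios:
            raise ValueError("need at least one admixture ratio")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("crop", "conc_range", "unmix_window"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "admixture_ratios" in data:
            data["admixture_ratios"] = tuple(tuple(r) for r in data["admixture_ratios"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _preprocess_cfg(config: PipelineConfig) -> preprocess.PreprocessConfig:
    return preprocess.PreprocessConfig(
        sg_order=config.sg_order,
        sg_window=config.sg_window,
        poly_order=config.emsc_poly,
        crop=tuple(config.crop),
    )


def build_world(config: PipelineConfig, scfg: synth.SynthConfig | None = None):
    """Shared references, interferents and absorption models."""
    scfg = scfg or synth.SynthConfig(
        source_wavelength_nm=config.laser_nm, seed=config.seed
    )
    refs = {c: synth.make_reference_spectrum(c, scfg) for c in CAROTENOIDS}
    water = synth.make_reference_spectrum("water", scfg)
    bsa = synth.make_reference_spectrum("bsa", scfg)
    models = {
        c: selfabs.AbsorptionModel.from_raw_absorbance(
            synth.simulate_absorbance(c, 1.0, scfg), config.laser_nm, c_ref=1.0,
            d1=config.d1, d2=config.d2,
        )
        for c in CAROTENOIDS
    }
    return scfg, refs, water, bsa, models


def pure_corrected_references(config, scfg, refs, water, bsa, models):
    """Preprocessed, self-absorption-corrected pure-complex spectra.

    These play the role of the corrected single-component spectra that
    the admixture fits use as basis spectra (stock concentration).

    The unmixing pathway deliberately skips water normalization: each
    spectrum's fitted water coefficient embeds the component-specific
    attenuation of the water bands, so dividing basis spectra by their
    own coefficients would put them on inconsistent scales and bias the
    fitted composition.
    """
    ref_sum = refs["beta_carotene"].copy()
    ref_sum.intensity = sum(r.intensity for r in refs.values())
    ref_sum.meta = {"analyte": "carotenoid_sum"}
    pp_cfg = _preprocess_cfg(config)
    pp_cfg.normalize = False
    out = []
    clean = scfg.noise_free()
    for name in CAROTENOIDS:
        spec = synth.simulate_measurement({name: config.stock_conc}, clean, seed=0)
        sset = SpectrumSet.from_spectra([spec])
        done = preprocess.preprocess_set(sset, ref_sum, [water, bsa], pp_cfg)
        corrected = selfabs.correct_self_absorption(
            done.spectrum(0), models[name], config.stock_conc
        )
        corrected.meta["analyte"] = name
        out.append(corrected)
    return out, ref_sum


def pure_component_recovery(seed: int = 0, config: PipelineConfig | None = None) -> dict:
    """Fitted % of the matching component for each pure complex.

    Generates a noise-free pure spectrum per carotenoid (default
    config), preprocesses it, and unmixes it against the three
    corrected component references; a perfect analysis returns 100 for
    every component.
    """
    config = config or PipelineConfig(seed=seed)
    scfg, refs, water, bsa, models = build_world(config)
    clean = scfg.noise_free()
    basis, ref_sum = pure_corrected_references(config, clean, refs, water, bsa, models)
    mixer = unmix.AdmixtureModel(
        basis, [models[c] for c in CAROTENOIDS],
        d1=config.d1, d2=config.d2, stock_conc=config.stock_conc,
    )
    pp = _preprocess_cfg(config)
    pp.normalize = False
    out = {}
    for i, name in enumerate(CAROTENOIDS):
        spec = synth.simulate_measurement({name: config.stock_conc}, clean, seed=seed)
        proc = preprocess.preprocess_set(
            SpectrumSet.from_spectra([spec]), ref_sum, [water, bsa], pp
        )
        res = mixer.fit(proc.spectrum(0), n_starts=config.unmix_starts, seed=seed)
        out[name] = float(res.fitted_pct[i])
    return out


def run_paper_twin(config: PipelineConfig | None = None, out_dir: str | Path | None = None) -> dict:
    """Run the full synthetic-twin experiment; return the report dict."""
    config = config or PipelineConfig()
    config.validate()
    t0 = time.time()
    report: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    scfg, refs, water, bsa, models = build_world(config)
    pp_cfg = _preprocess_cfg(config)

    # --- calibration series: simulate, preprocess -------------------------
    t = time.time()
    concs = np.round(np.linspace(*config.conc_range, config.n_concentrations), 6)
    series = synth.simulate_concentration_series(
        concs, config.replicates, scfg, seed=config.seed, analyte="beta_carotene"
    )
    processed, fits, emsc_model = preprocess.preprocess_set(
        series, refs["beta_carotene"], [water, bsa], pp_cfg, return_fits=True
    )
    y = processed.labels["concentration"].to_numpy(float)
    log.info("simulated + preprocessed %d calibration spectra", len(processed))
    report["stages"]["preprocess"] = {
        "n_spectra": int(len(processed)),
        "seconds": round(time.time() - t, 2),
    }

    # --- self-absorption: path-factor fit on the raw peak response ---------
    # The saturation of the concentration response is visible in the
    # EMSC-corrected (unnormalized) peak intensities; water-normalized
    # peaks hide most of it because the fitted water coefficient is
    # attenuated at nearly the same Stokes wavelengths as the nu1 band.
    t = time.time()
    model_b = models["beta_carotene"]
    nu1 = scfg.nu1_centers["beta_carotene"]
    raw_peak = np.array([f.corrected.value_at(nu1) for f in fits])
    if config.fit_path_factors:
        pf = selfabs.fit_path_factors(y, raw_peak, model_b, shift_cm1=nu1, seed=config.seed)
        model_b = replace(model_b, d1=pf.d1, d2=pf.d2, k=pf.k)
        corrected_peak = raw_peak / selfabs.attenuation_factor(
            (model_b.alpha_at(config.laser_nm, 1.0) * pf.d1
             + model_b.alpha_at(selfabs.stokes_wavelength(config.laser_nm, nu1), 1.0) * pf.d2) * y
        )
        report["stages"]["self_absorption"] = {
            "d1": pf.d1, "d2": pf.d2, "k": pf.k,
            "u_slope": pf.u_slope, "collinear": pf.collinear,
            "raw_peak_linearity_r": float(np.corrcoef(raw_peak, y)[0, 1]),
            "corrected_peak_linearity_r": float(np.corrcoef(corrected_peak, y)[0, 1]),
            "seconds": round(time.time() - t, 2),
        }
    else:
        report["stages"]["self_absorption"] = {"d1": model_b.d1, "d2": model_b.d2,
                                               "fit": False}
    # PLSR works on the water-normalized spectra: normalization cancels
    # the per-spectrum collection gain, and the latent variables absorb
    # the smooth residual attenuation curvature.
    corrected = processed

    # --- PLSR calibration --------------------------------------------------
    t = time.time()
    cal = chemometrics.calibrate(
        corrected, y, n_lv=config.n_lv, n_lv_max=config.n_lv,
        k=config.cv_folds, repeats=config.cv_repeats, seed=config.seed,
    )
    report["stages"]["plsr"] = {
        "n_lv": cal.n_lv,
        "rmsecv_per_lv": [round(float(v), 6) for v in cal.rmsecv_per_lv],
        "rmsecv": float(cal.rmsecv),
        "lod": float(cal.lod),
        "r_squared_cv": float(cal.r_squared),
        "cumulative_y_variance": [round(float(v), 4) for v in cal.cumulative_variance],
        "seconds": round(time.time() - t, 2),
    }
    log.info("PLSR: RMSECV=%.4g mg/mL, LOD=%.4g mg/mL, CV R^2=%.5f",
             cal.rmsecv, cal.lod, cal.r_squared)

    # --- PCA differentiation ------------------------------------------------
    t = time.time()
    ref_sum = refs["beta_carotene"].copy()
    ref_sum.intensity = sum(r.intensity for r in refs.values())
    ref_sum.meta = {"analyte": "carotenoid_sum"}
    rng = np.random.default_rng(config.seed + 1)
    pca_specs = []
    for name in CAROTENOIDS:
        for rep in range(config.pca_replicates):
            s = synth.simulate_measurement(
                {name: 1.0}, scfg, seed=int(rng.integers(0, 2**31 - 1))
            )
            s.meta.update({"analyte": name, "concentration": 1.0, "replicate": rep})
            pca_specs.append(s)
    pca_set = SpectrumSet.from_spectra(pca_specs)
    pca_proc = preprocess.preprocess_set(pca_set, ref_sum, [water, bsa], pp_cfg)
    pca_corr_rows = [
        selfabs.correct_self_absorption(
            pca_proc.spectrum(i), models[pca_proc.labels["analyte"].iloc[i]], 1.0
        ).intensity
        for i in range(len(pca_proc))
    ]
    pca_corr = SpectrumSet(pca_proc.axis, np.vstack(pca_corr_rows),
                           pca_proc.labels, pca_proc.axis_kind)
    pca = chemometrics.fit_pca(pca_corr)
    pairs = [("lutein", "zeaxanthin"), ("beta_carotene", "zeaxanthin"),
             ("beta_carotene", "lutein")]
    pairwise = {
        "/".join(p): [round(float(v), 2)
                      for v in chemometrics.pairwise_pca(pca_corr, p).explained_variance_pct[:2]]
        for p in pairs
    }
    report["stages"]["pca"] = {
        "explained_variance_pct": [round(float(v), 2) for v in pca.explained_variance_pct[:4]],
        "pairwise_pc_variance_pct": pairwise,
        "seconds": round(time.time() - t, 2),
    }

    # --- admixture unmixing --------------------------------------------------
    t = time.time()
    basis, _ = pure_corrected_references(config, scfg, refs, water, bsa, models)
    mixer = unmix.AdmixtureModel(
        basis,
        [models[c] for c in CAROTENOIDS],
        d1=float(report["stages"]["self_absorption"]["d1"]),
        d2=float(report["stages"]["self_absorption"]["d2"]),
        stock_conc=config.stock_conc,
    )
    batteries = list(config.admixture_ratios) + [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
    rng = np.random.default_rng(config.seed + 2)
    unmix_pp = _preprocess_cfg(config)
    unmix_pp.normalize = False
    nominal, fitted, labels, table = [], [], [], []
    for ratio in batteries:
        nom = unmix.nominal_percent(ratio)
        for rep in range(config.admixture_replicates):
            spec = synth.simulate_admixture(
                ratio, config.stock_conc, scfg, seed=int(rng.integers(0, 2**31 - 1))
            )
            sset = SpectrumSet.from_spectra([spec])
            proc = preprocess.preprocess_set(sset, ref_sum, [water, bsa], unmix_pp)
            res = mixer.fit(proc.spectrum(0), window=config.unmix_window,
                            n_starts=config.unmix_starts, seed=config.seed)
            nominal.extend(nom)
            fitted.extend(res.fitted_pct)
            labels.extend(CAROTENOIDS)
            table.append({
                "ratio": ":".join(str(int(p)) for p in ratio),
                "replicate": rep,
                "nominal_pct": [round(float(v), 3) for v in nom],
                "fitted_pct": [round(float(v), 3) for v in res.fitted_pct],
                "fitted_ratio": [round(float(v), 2) for v in res.fitted_ratio(sum(ratio))],
                "converged": bool(res.converged),
            })
    recovery = unmix.recovery_regression(nominal, fitted, labels)
    report["stages"]["unmixing"] = {
        "recovery_r_squared": float(recovery.r_squared),
        "recovery_std_error_pct": float(recovery.std_error_pct),
        "per_component": {
            name: {"r_squared": float(r.r_squared), "std_error_pct": float(r.std_error_pct)}
            for name, r in (recovery.per_component or {}).items()
        },
        "fits": table,
        "seconds": round(time.time() - t, 2),
    }
    report["total_seconds"] = round(time.time() - t0, 2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_spectra(series, out / "calibration_raw.csv")
        write_spectra(corrected, out / "calibration_corrected.csv")
        write_spectra(pca_corr, out / "pca_corrected.csv")
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        log.info("report written to %s", out / "report.json")
    return report
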