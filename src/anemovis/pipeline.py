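"""End-to-end orchestration: synthetic inputs through every analysis stage.

Stage order follows the structure of the analysis: generate (or ingest)
spectra and counts → lens T50 → pigment λ_max fits → receptor-noise
sweeps (monochromatic and coexpression) → expression summary →
topographic maps, totals and the coexpression region → acuity.  Every
artefact is a tidy CSV (or JSON sidecar) written once into the output
directory, listed in a manifest with stage provenance.  All randomness
flows from the single root seed in the config, so a rerun with the same
config is bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import acuity as acuity_mod
from . import expression as expr_mod
from . import rnl, synthetic, topography
from .pigments import DEFAULT_LAMBDA_MAX, fit_lambda_max, template_absorbance
from .spectra import is_uv_transmitting, t50, write_spectrum
from .synthetic import GeneratorConfig

log = logging.getLogger("anemovis")

ALL_STAGES = ("spectra", "pigments", "visual_model", "expression",
              "topography", "acuity")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Pipeline run configuration: seed, output directory, stage toggles."""

    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    generator: GeneratorConfig | None = None
    lens_diameter_mm: float = 2.5
    sweep_step_nm: float = 2.0
    coexp_step_pct: float = 2.0

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        bad = set(self.stages) - set(ALL_STAGES)
        if bad:
            raise ConfigError(f"unknown stages {sorted(bad)}; valid: {ALL_STAGES}")
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)
        elif self.generator.seed != self.seed:
            self.generator = dataclasses.replace(self.generator, seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        if "outdir" not in raw:
            raise ConfigError(f"{path}: missing required field 'outdir'")
        gen = raw.pop("generator", None)
        kwargs = {}
        for f in dataclasses.fields(cls):
            if f.name in raw:
                kwargs[f.name] = raw.pop(f.name)
        if raw:
            raise ConfigError(f"unknown config fields {sorted(raw)}")
        if "stages" in kwargs:
            kwargs["stages"] = tuple(kwargs["stages"])
        cfg = cls(**kwargs)
        if gen:
            valid = {f.name for f in dataclasses.fields(GeneratorConfig)}
            bad = set(gen) - valid
            if bad:
                raise ConfigError(f"unknown generator fields {sorted(bad)}")
            cfg.generator = GeneratorConfig(seed=cfg.seed, **gen)
        return cfg


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all enabled stages; return (and write) the artefact manifest."""
    out = cfg.outdir
    out.mkdir(parents=True, exist_ok=True)
    gen = cfg.generator
    manifest: dict = {
        "seed": cfg.seed,
        "stages": list(cfg.stages),
        "generator": dataclasses.asdict(gen) | {"grid": [gen.grid.start_nm, gen.grid.stop_nm, gen.grid.step_nm]},
        "artefacts": [],
    }

    def emit(stage: str, name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["artefacts"].append({"stage": stage, "path": name})
        log.info("%s: wrote %s", stage, path)
        return path

    # shared synthetic inputs
    reflectances = synthetic.gen_reflectances(gen)
    light = synthetic.gen_lightfield(gen)
    lens = synthetic.gen_lens_transmission(gen)
    for name, s in reflectances.items():
        emit("inputs", f"reflectance_{name}.csv", lambda p, s=s: write_spectrum(s, p))
    emit("inputs", "lens_transmission.csv", lambda p: write_spectrum(lens, p))
    emit("inputs", "irradiance_downwelling.csv",
         lambda p: write_spectrum(light.downwelling_irradiance, p))
    emit("inputs", "irradiance_horizontal.csv",
         lambda p: write_spectrum(light.horizontal_irradiance, p))
    emit("inputs", "radiance_horizontal.csv",
         lambda p: write_spectrum(light.horizontal_radiance, p))

    if "spectra" in cfg.stages:
        t50_nm = t50(lens)
        df = pd.DataFrame([{
            "t50_nm": t50_nm,
            "uv_transmitting": is_uv_transmitting(t50_nm),
        }])
        emit("spectra", "lens_t50.csv", lambda p: df.to_csv(p, index=False))

    if "pigments" in cfg.stages:
        rows = []
        rng = gen.rng("msp")
        for name, lam in DEFAULT_LAMBDA_MAX.items():
            meas = synthetic.gen_msp_spectrum(gen, lam, rng=rng)
            fit = fit_lambda_max(meas, search=(max(330.0, lam - 60), min(620.0, lam + 60)))
            rows.append({"opsin": name, "lambda_max_true_nm": lam,
                         "lambda_max_fit_nm": fit.lambda_max, "rss": fit.rss})
        df = pd.DataFrame(rows)
        emit("pigments", "msp_fits.csv", lambda p: df.to_csv(p, index=False))

    if "visual_model" in cfg.stages:
        lmax = DEFAULT_LAMBDA_MAX
        g = gen.grid
        abs_ = {k: template_absorbance(v, g) for k, v in lmax.items()}
        scenarios = {
            "orange_vs_stripe": rnl.ViewingScenario(
                reflectances["body_orange"],
                background_reflectance=reflectances["white_stripe"]),
            "stripe_vs_spacelight": rnl.ViewingScenario(reflectances["white_stripe"]),
            "anemone_vs_spacelight": rnl.ViewingScenario(reflectances["anemone"]),
            "zooplankton_vs_spacelight": rnl.ViewingScenario(
                reflectances["zooplankton"], target_illuminant="downwelling"),
            "predator_vs_spacelight": rnl.ViewingScenario(reflectances["predator"]),
        }
        mono_rows, coexp_rows = [], []
        for name, sc in scenarios.items():
            tgt = sc.target_stimulus(light)
            bkg = sc.background_stimulus(light)
            mono = rnl.monochromatic_sweep(tgt, bkg, lens,
                                           step_nm=cfg.sweep_step_nm)
            mc = mono.curve.assign(scenario=name)
            mono_rows.append(mc)
            fr = np.arange(0.0, 100.0 + 1e-9, cfg.coexp_step_pct)
            co = rnl.coexpression_sweep(tgt, bkg, abs_["SWS1"], abs_["SWS2B"],
                                        abs_["RH2B"], abs_["RH2A"], lens,
                                        fractions_pct=fr)
            coexp_rows.append(co.curve.assign(scenario=name))
        mono_df = pd.concat(mono_rows, ignore_index=True)
        coexp_df = pd.concat(coexp_rows, ignore_index=True)
        emit("visual_model", "monochromatic_sweep.csv",
             lambda p: mono_df.to_csv(p, index=False))
        emit("visual_model", "coexpression_sweep.csv",
             lambda p: coexp_df.to_csv(p, index=False))

    if "expression" in cfg.stages:
        cohort = synthetic.gen_expression_cohort(gen)
        tidy = expr_mod.tidy_proportions(cohort)
        summary = expr_mod.cohort_summary(cohort)
        emit("expression", "expression_counts.csv",
             lambda p: expr_mod.write_counts(cohort, p))
        emit("expression", "expression_proportions.csv",
             lambda p: tidy.to_csv(p, index=False))
        emit("expression", "expression_summary.csv",
             lambda p: summary.to_csv(p, index=False))

    gc_peak_density = None
    if "topography" in cfg.stages:
        classes = ("ganglion", "total_cone", "double_cone", "single_cone")
        outline, counts = synthetic.gen_retina_counts(gen, classes)
        stat_rows, maps = [], {}
        for cls in classes:
            m = topography.kernel_map(counts, outline, cls)
            maps[cls] = m
            px, py, pd_ = topography.find_peak(m)
            stat_rows.append({
                "class": cls,
                "total": topography.fractionator_total(counts, cls),
                "ce": topography.scheaffer_ce(counts, cls),
                "peak_x_mm": px, "peak_y_mm": py,
                "peak_density_mm2": pd_,
            })
            emit("topography", f"density_map_{cls}.csv",
                 lambda p, m=m: m.to_frame().to_csv(p, index=False))
        gc_peak_density = stat_rows[0]["peak_density_mm2"]
        stats = pd.DataFrame(stat_rows)
        emit("topography", "stereology_summary.csv",
             lambda p: stats.to_csv(p, index=False))
        rmap = topography.ratio_map(maps["total_cone"], maps["ganglion"])
        emit("topography", "cone_gc_ratio_map.csv",
             lambda p: rmap.to_frame().to_csv(p, index=False))

        f_outline, f_counts = synthetic.gen_fish_counts(gen)
        per_site, pooled = topography.fish_proportions(f_counts)
        emit("topography", "fish_site_fractions.csv",
             lambda p: per_site.to_csv(p, index=False))
        emit("topography", "fish_pooled_fractions.csv",
             lambda p: pooled.to_csv(p, index=False))
        region = topography.coexpression_region(f_counts, f_outline)
        reg = ({"found": False} if region is None else {
            "found": True,
            "centroid_x_mm": region.centroid_mm[0],
            "centroid_y_mm": region.centroid_mm[1],
            "area_mm2": region.area_mm2,
            "peak_fraction": region.peak_fraction,
        })
        emit("topography", "coexpression_region.json",
             lambda p: p.write_text(json.dumps(reg, indent=2)))

    if "acuity" in cfg.stages:
        peak = gc_peak_density
        if peak is None:  # topography disabled: use the generating surface peak
            peak = float(synthetic.density_surface(
                gen, np.array([gen.peak_center_mm[0]]),
                np.array([gen.peak_center_mm[1]]))[0])
        eye = acuity_mod.EyeGeometry(cfg.lens_diameter_mm)
        res = acuity_mod.srp(peak, eye)
        rows = [{
            "peak_gc_density_mm2": peak,
            "lens_diameter_mm": cfg.lens_diameter_mm,
            "focal_length_mm": res.focal_length_mm,
            "srp_cycles_per_deg": res.srp_cycles_per_deg,
            "detect_8cm_fish_m": acuity_mod.detection_distance(
                0.08, res.srp_cycles_per_deg, 0),
            "detect_5mm_stripe_m": acuity_mod.detection_distance(
                0.005, res.srp_cycles_per_deg, 1),
        }]
        df = pd.DataFrame(rows)
        emit("acuity", "acuity.csv", lambda p: df.to_csv(p, index=False))

    emit("manifest", "manifest.json",
         lambda p: p.write_text(json.dumps(manifest, indent=2, default=str)))
    return manifest
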