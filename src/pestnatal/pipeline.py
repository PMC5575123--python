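"""Reproducible pipeline: simulate -> expose -> cohort -> fit -> report.

Every stage reads its inputs from and writes its outputs to delimited text
files in the artifact directory, so a single stage can be re-run on prior
outputs and gives byte-identical results under a fixed seed.  A manifest
records the config hash and library versions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import build_samples
from .exposure import EXPOSURE_COLUMNS, SectionMonthPanel, attach_exposures, \
    binarize_exposures, ym_index
from .panelfe import full_battery, run_model_battery
from .report import summarize_effects
from .synth import GridSpec, SimConfig, generate_applications, generate_births

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

log = logging.getLogger("pestnatal.pipeline")


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Fully serializable run configuration; a run is reproducible from the
    config (including its seed) alone."""

    grid: GridSpec = GridSpec()
    sim: SimConfig = SimConfig()
    cutoff_probs: tuple[float, ...] = (0.75, 0.95, 0.99)
    high_cutoff_prob: float = 0.95
    buffer_m: float = 200.0
    require_pesticides_every_year: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for key in ("grid", "sim", "cutoffs"):
            if key not in d:
                raise ValueError(f"config is missing required section {key!r}")
        cut = d["cutoffs"]
        if "probs" not in cut or "high" not in cut:
            raise ValueError("config section 'cutoffs' needs 'probs' and 'high'")
        sim = dict(d["sim"])
        if "years" in sim:
            sim["years"] = tuple(sim["years"])
        if "true_effects" in sim:
            sim["true_effects"] = dict(sim["true_effects"])
        return cls(
            grid=GridSpec(**d["grid"]),
            sim=SimConfig(**sim),
            cutoff_probs=tuple(cut["probs"]),
            high_cutoff_prob=float(cut["high"]),
            buffer_m=float(d.get("buffer_m", 200.0)),
            require_pesticides_every_year=bool(d.get("require_pesticides_every_year",
                                                     False)),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "grid": dataclasses.asdict(self.grid),
            "sim": dataclasses.asdict(self.sim),
            "cutoffs": {"probs": list(self.cutoff_probs),
                        "high": self.high_cutoff_prob},
            "buffer_m": self.buffer_m,
            "require_pesticides_every_year": self.require_pesticides_every_year,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _panel(cfg: PipelineConfig, apps: pd.DataFrame) -> SectionMonthPanel:
    y0, y1 = cfg.sim.app_years
    return SectionMonthPanel(apps, cfg.grid.section_ids(),
                             ym_index(y0, 1), ym_index(y1, 12))


def stage_simulate(cfg: PipelineConfig, out: Path) -> None:
    apps = generate_applications(cfg.grid, cfg.sim)
    births = generate_births(cfg.grid, cfg.sim, _panel(cfg, apps))
    apps.to_csv(out / "applications.csv", index=False)
    births.to_csv(out / "births.csv", index=False)
    log.info("simulate: %d applications, %d births", len(apps), len(births))


def stage_expose(cfg: PipelineConfig, out: Path) -> None:
    apps = pd.read_csv(out / "applications.csv")
    births = pd.read_csv(out / "births.csv")
    expo = attach_exposures(births, _panel(cfg, apps))
    expo.insert(0, "birth_id", births["birth_id"].to_numpy())
    expo.to_csv(out / "exposures.csv", index=False)
    log.info("expose: %d exposure vectors", len(expo))


def stage_cohort(cfg: PipelineConfig, out: Path) -> None:
    births = pd.read_csv(out / "births.csv")
    expo = pd.read_csv(out / "exposures.csv")
    apps = pd.read_csv(out / "applications.csv")
    merged = births.merge(expo, on="birth_id", validate="1:1")
    sim = cfg.sim
    dropped = (sim.missing_tobacco_year
               if sim.missing_tobacco_year is not None
               and sim.years[0] <= sim.missing_tobacco_year <= sim.years[1] else None)
    frame, tally = build_samples(
        merged, apps, cfg.grid, dropped_year=dropped, buffer_m=cfg.buffer_m,
        require_pesticides_every_year=cfg.require_pesticides_every_year)
    high, cutoffs = binarize_exposures(frame, reference_mask=frame["all_births"],
                                       prob=cfg.high_cutoff_prob)
    frame = pd.concat([frame, high], axis=1)
    keep = ["birth_id", "all_births", "full_estimation", "focal",
            "interior_buffer", *high.columns]
    frame[keep].to_csv(out / "samples.csv", index=False)

    ref = frame.loc[frame["all_births"], "total_kg"].to_numpy()
    qs = {f"q{int(p * 100)}_kg": float(np.quantile(ref, p, method="inverted_cdf"))
          for p in cfg.cutoff_probs}
    meta = {"quantile_method": "inverted_cdf",
            "reference_sample": "all_births (post base restrictions, pre year drop)",
            "high_cutoff_prob": cfg.high_cutoff_prob,
            "gestational_total_quantiles": qs,
            "per_measure_high_cutoffs_kg": cutoffs}
    (out / "cutoffs.json").write_text(json.dumps(meta, indent=2))
    (out / "exclusions.log").write_text(json.dumps(tally, indent=2))
    log.info("cohort: %s", tally["n"])


def stage_fit(cfg: PipelineConfig, out: Path) -> None:
    births = pd.read_csv(out / "births.csv")
    expo = pd.read_csv(out / "exposures.csv")
    samples = pd.read_csv(out / "samples.csv")
    frame = births.merge(expo, on="birth_id").merge(samples, on="birth_id")
    results = run_model_battery(frame, full_battery())
    results.to_csv(out / "results.csv", index=False)
    log.info("fit: %d coefficients (%d ok)", len(results),
             int((results["status"] == "ok").sum()))


def stage_report(cfg: PipelineConfig, out: Path) -> None:
    births = pd.read_csv(out / "births.csv")
    samples = pd.read_csv(out / "samples.csv")
    results = pd.read_csv(out / "results.csv")
    focal = births.merge(samples[samples["focal"]][["birth_id"]], on="birth_id")
    rates = {o: float(focal[o].mean()) for o in ("low_bw", "preterm", "abnormality")}
    means = {"log_bw": float(focal["birth_weight_g"].mean()),
             "log_gest": float(focal["gestation_days"].mean())}
    effects = summarize_effects(results, rates, means)
    effects.to_csv(out / "effects.csv", index=False)

    lines = ["# Effect summary", "",
             f"Focal-sample outcome rates: {json.dumps(rates)}",
             f"Focal-sample means: birth weight {means['log_bw']:.0f} g, "
             f"gestation {means['log_gest']:.1f} d", "",
             effects[effects["status"] == "ok"]
             [["model_id", "term", "coef", "se", "p", "pct_change",
               "unit_change", "stars"]].to_string(index=False)]
    (out / "summary.md").write_text("\n".join(lines) + "\n")
    log.info("report: %d effects", len(effects))


STAGES = {"simulate": stage_simulate, "expose": stage_expose,
          "cohort": stage_cohort, "fit": stage_fit, "report": stage_report}


def run_pipeline(cfg: PipelineConfig, outdir, stages=None) -> dict:
    """Run the requested stages (default: all) into ``outdir``.

    Stage failures abort with the stage name and cause.  Returns the
    manifest, which is also written to ``manifest.json``.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name in stages or STAGES:
        try:
            STAGES[name](cfg, out)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    import importlib.metadata as md
    versions = {}
    for dist in ("pestnatal", "numpy", "pandas", "scipy", "statsmodels"):
        try:
            versions[dist] = md.version(dist)
        except md.PackageNotFoundError:  # pragma: no cover
            versions[dist] = "unknown"
    manifest = {"config_hash": cfg.config_hash(), "config": cfg.to_dict(),
                "versions": versions,
                "outputs": sorted(p.name for p in out.iterdir() if p.is_file())}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return manifest
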