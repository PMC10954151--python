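"""Orchestration: run every analysis stage from a single config file.

Stage order follows the analysis narrative: site summaries -> enrichment
factors -> receptor model (PCA/APCS-MLR) -> seasonal diagnostic ratios ->
network variable importance -> inhalation risk.  Every output table is TSV
with provenance headers (input checksum, seed, stage) and a machine-
readable ``manifest.json`` ties the run together.  A stage failure aborts
with a stage-named error and removes that run's partial outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ann import AnnConfig, ann_table
from .core import (ConcentrationTable, ElementPanel, ValidationError,
                   read_concentration_table, site_ratio_table,
                   summarise_by_site, write_concentration_table)
from .enrichment import CrustalReference, ef_table
from .ratios import pearson_matrix, seasonal_ratio_table
from .receptor import fit_receptor_model, site_mean_mp
from .risk import (ExposureParams, ToxicityTable, load_exposure_yaml,
                   risk_table, write_default_risk_config)
from .synth import SynthConfig, make_source_profiles, simulate_dataset

log = logging.getLogger("pm25elements")

STAGES = ("summaries", "ef", "apportion", "ratios", "ann", "risk")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    concentrations: Path
    met: Path | None = None
    crustal: Path | None = None
    risk_config: Path | None = None
    outdir: Path = Path("pipeline_out")
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    ann_max_epochs: int = 2000
    nd_policy: str = "exclude"
    precision: int = 6

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        base = path.parent

        def _p(key):
            return (base / doc[key]).resolve() if doc.get(key) else None

        stages = {s: True for s in STAGES}
        stages.update(doc.get("stages", {}))
        cfg = cls(concentrations=_p("concentrations"), met=_p("met"),
                  crustal=_p("crustal"), risk_config=_p("risk_config"),
                  outdir=(base / doc.get("outdir", "pipeline_out")),
                  seed=int(doc.get("seed", 0)), stages=stages,
                  ann_max_epochs=int(doc.get("ann_max_epochs", 2000)),
                  nd_policy=str(doc.get("nd_policy", "exclude")),
                  precision=int(doc.get("precision", 6)))
        if cfg.concentrations is None or not cfg.concentrations.exists():
            raise ValidationError("config must name an existing concentrations CSV")
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, provenance: dict,
               precision: int) -> None:
    with open(path, "w") as fh:
        for key, val in provenance.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", float_format=f"%.{precision}g")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dictionary."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    input_hash = _sha256(cfg.concentrations)
    manifest = {"version": __version__, "seed": cfg.seed,
                "inputs": {"concentrations": input_hash}, "stages": [],
                "outputs": {}}
    if cfg.met:
        manifest["inputs"]["met"] = _sha256(cfg.met)

    table = read_concentration_table(cfg.concentrations)
    nd_counts = (table.flags == "not_detected").sum().sum()
    log.info("loaded %d samples, %d not-detected cells", table.n_samples, nd_counts)

    def emit(name: str, df: pd.DataFrame, stage: str) -> None:
        path = outdir / name
        _write_tsv(df, path, {"stage": stage, "seed": cfg.seed,
                              "input_sha256": input_hash}, cfg.precision)
        written.append(path)
        manifest["outputs"][name] = _sha256(path)

    current = "setup"
    try:
        if cfg.stages.get("summaries", True):
            current = "summaries"
            summary = summarise_by_site(table, cfg.nd_policy)
            emit("site_summary.tsv", summary.frame, current)
            sites = summary.sites
            if len(sites) >= 2:
                rows = {}
                for i, num in enumerate(sites):
                    for den in sites[i + 1:]:
                        ratios, total = site_ratio_table(summary, num, den)
                        rows[f"{num}/{den}"] = pd.concat(
                            [ratios, pd.Series({"TOTAL": total})])
                emit("site_ratios.tsv", pd.DataFrame(rows), current)
            manifest["stages"].append(current)
        else:
            summary = summarise_by_site(table, cfg.nd_policy)

        if cfg.stages.get("ef", True):
            current = "ef"
            crust = (CrustalReference.from_yaml(cfg.crustal)
                     if cfg.crustal else CrustalReference.default())
            emit("enrichment_factors.tsv", ef_table(summary, crust), current)
            manifest["stages"].append(current)

        if cfg.stages.get("apportion", True):
            current = "apportion"
            mp_frames = []
            for site in table.sites:
                sub = table.for_site(site)
                model, apcs, mp = fit_receptor_model(sub)
                loadings = pd.DataFrame(
                    model.rotated_loadings, index=list(model.columns),
                    columns=[f"PC{i+1}" for i in range(model.retained)])
                loadings.loc["% of Total Variance"] = model.rotated_variance_pct()
                emit(f"loadings_{site}.tsv", loadings, current)
                mp_frames.append(mp)
            mp_all = pd.concat(mp_frames, ignore_index=True)
            emit("mp_ratios.tsv", mp_all.set_index(["site", "date"]), current)
            emit("mp_site_means.tsv", site_mean_mp(mp_all).to_frame(), current)
            manifest["stages"].append(current)

        if cfg.stages.get("ratios", True):
            current = "ratios"
            emit("seasonal_ratios.tsv", seasonal_ratio_table(table), current)
            for site in table.sites:
                corr = pearson_matrix(table.for_site(site).matrix())
                emit(f"correlation_{site}.tsv", corr, current)
            manifest["stages"].append(current)

        if cfg.stages.get("ann", True):
            current = "ann"
            if cfg.met is None:
                raise ValidationError("ann stage needs a met table")
            met = pd.read_csv(cfg.met, comment="#")
            targets = table.matrix().fillna(0.0)
            targets["total"] = targets.sum(axis=1)
            ann_cfg = AnnConfig(seed=cfg.seed, max_epochs=cfg.ann_max_epochs)
            emit("ann_summary.tsv", ann_table(met, targets, ann_cfg), current)
            manifest["stages"].append(current)

        if cfg.stages.get("risk", True):
            current = "risk"
            if cfg.risk_config:
                with open(cfg.risk_config) as fh:
                    doc = yaml.safe_load(fh)
                exposure = {g: ExposureParams(**p)
                            for g, p in doc["exposure"].items()}
                toxicity = ToxicityTable(
                    rfd=doc["toxicity"]["rfd"], iur=doc["toxicity"]["iur"])
            else:
                exposure = toxicity = None
            emit("risk_metrics.tsv",
                 risk_table(table, exposure, toxicity, cfg.nd_policy), current)
            manifest["stages"].append(current)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise PipelineError(f"stage {current!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def generate_demo(outdir, seed: int = 0, k: int = 3) -> Path:
    """Write a complete synthetic input set sized like the campaign
    (82/48/61 samples over three sites) plus a ready-to-run config.

    Returns the path of the written config file.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    profiles = make_source_profiles(k, seed=seed)
    cfg = SynthConfig.met_coupled(seed=seed)
    table, met, truth = simulate_dataset(profiles, cfg)
    write_concentration_table(table, outdir / "concentrations.csv")
    met.to_csv(outdir / "met.csv", index=False)
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    CrustalReference.default().to_yaml(outdir / "crustal.yaml")
    write_default_risk_config(outdir / "risk.yaml")
    config = {"concentrations": "concentrations.csv", "met": "met.csv",
              "crustal": "crustal.yaml", "risk_config": "risk.yaml",
              "outdir": "out", "seed": seed}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return outdir / "config.yaml"
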