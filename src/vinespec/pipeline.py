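"""End-to-end orchestration: simulate/load -> indices -> search -> stats -> models.

Every stage writes plain CSV/JSON files into the run directory before the
next stage starts, so any stage can be re-run or inspected in isolation.
A :class:`RunManifest` (manifest.json) records the configuration snapshot,
software version, timestamps and the per-stage output files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bandsearch import BandSearch, fit_simple_regression
from .groupstats import describe_groups, pearson_matrix, significance_stars
from .indices import IndexForm, IndexRegistry, default_registry, evaluate_registry
from .regression import FEATURE_PRESETS, SRIRegression
from .simulate import (
    GroupSpec,
    SpectralModelSpec,
    default_groups,
    default_spectral_model,
    groups_from_dict,
    groups_to_dict,
    make_dataset,
    spectral_model_from_dict,
    spectral_model_to_dict,
    write_truth_json,
)
from .spectra import (
    TRAIT_NAMES,
    read_spectra_csv,
    read_traits_csv,
    write_spectra_csv,
    write_traits_csv,
)

log = logging.getLogger("vinespec")

ALL_STAGES = ("data", "stats", "indices", "bandsearch", "models")


@dataclass
class PipelineConfig:
    out_dir: str = "vinespec_run"
    seed: int = 0
    synthetic: bool = True
    spectra_path: str | None = None
    traits_path: str | None = None
    groups: list[GroupSpec] = field(default_factory=default_groups)
    spectral_model: SpectralModelSpec = field(default_factory=default_spectral_model)
    registry: IndexRegistry = field(default_factory=default_registry)
    stages: tuple[str, ...] = ALL_STAGES
    # band search
    search_traits: tuple[str, ...] = TRAIT_NAMES
    search_forms: tuple[str, ...] = ("NDI2",)
    stride: float = 8.0
    top_k: int = 10
    # stats
    alpha: float = 0.05
    # models
    model_kinds: tuple[str, ...] = ("dt", "gbr")
    model_traits: tuple[str, ...] = TRAIT_NAMES
    feature_mode: str = "all"      # "all" | "preset" | "select"
    max_subset: int = 5

    def __post_init__(self):
        if self.synthetic and (self.spectra_path or self.traits_path):
            raise ValueError("choose synthetic data or file inputs, not both")
        if not self.synthetic and not (self.spectra_path and self.traits_path):
            raise ValueError("file inputs need both spectra_path and traits_path")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "groups" in raw:
            raw["groups"] = groups_from_dict(raw["groups"])
        if "spectral_model" in raw:
            raw["spectral_model"] = spectral_model_from_dict(raw["spectral_model"])
        if "registry" in raw:
            raw["registry"] = IndexRegistry.from_json(raw["registry"])
        for key in ("stages", "search_traits", "search_forms", "model_kinds",
                    "model_traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["groups"] = groups_to_dict(self.groups)
        d["spectral_model"] = spectral_model_to_dict(self.spectral_model)
        d["registry"] = json.loads(self.registry.to_json())
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    started: str
    finished: str
    outputs: dict[str, list[str]]     # stage -> file names
    log_path: str
    completed_stages: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _canonical_features(registry: IndexRegistry, names: list[str]) -> list[str]:
    return [registry.get(n).name for n in names]


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the configured stages in order, writing files per stage."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    outputs: dict[str, list[str]] = {}
    completed: list[str] = []

    def record(stage: str, *paths: Path):
        outputs.setdefault(stage, []).extend(p.name for p in paths)

    try:
        t0 = time.time()
        # -- data ----------------------------------------------------------
        if config.synthetic:
            ds = make_dataset(config.groups, config.spectral_model,
                              seed=config.seed)
            spectra, traits = ds.spectra, ds.traits
        else:
            spectra = read_spectra_csv(config.spectra_path)
            traits = read_traits_csv(config.traits_path)
        if "data" in config.stages:
            sp, tp = out / "spectra.csv", out / "traits.csv"
            write_spectra_csv(spectra, sp)
            write_traits_csv(traits, tp)
            record("data", sp, tp)
            if config.synthetic:
                truth = out / "truth.json"
                write_truth_json(config.spectral_model, truth)
                record("data", truth)
            completed.append("data")
            log.info("data stage done in %.1fs (%d samples x %d bands)",
                     time.time() - t0, spectra.n_samples, spectra.n_bands)

        # -- stats ---------------------------------------------------------
        if "stats" in config.stages:
            t0 = time.time()
            gs = describe_groups(traits, alpha=config.alpha)
            gpath = out / "group_stats.csv"
            gs.to_csv(gpath)
            cpath = out / "correlation_pooled.csv"
            pearson_matrix(traits, "pooled").to_csv(cpath)
            record("stats", gpath, cpath)
            completed.append("stats")
            log.info("stats stage done in %.1fs", time.time() - t0)

        # -- indices -------------------------------------------------------
        features = evaluate_registry(spectra, config.registry)
        if "indices" in config.stages:
            t0 = time.time()
            fpath = out / "features.csv"
            features.to_csv(fpath, float_format="%.10g")
            rpath = out / "registry.json"
            config.registry.to_json(rpath)
            record("indices", fpath, rpath)
            completed.append("indices")
            log.info("indices stage done in %.1fs (%d indices)",
                     time.time() - t0, len(config.registry))

        # -- band search ---------------------------------------------------
        if "bandsearch" in config.stages:
            t0 = time.time()
            for trait in config.search_traits:
                res = BandSearch(spectra, traits, trait,
                                 forms=tuple(IndexForm(f) for f in config.search_forms),
                                 stride=config.stride,
                                 top_k=config.top_k).fit()
                for cg in res.correlograms:
                    cpath = out / f"correlogram_{trait}_{cg.form.value.lower()}.csv"
                    cg.to_csv(cpath)
                    record("bandsearch", cpath)
                spath = out / f"top_indices_{trait}.json"
                res.select_top(config.top_k).to_json(spath)
                record("bandsearch", spath)
                log.debug("band search for %s done", trait)
            completed.append("bandsearch")
            log.info("bandsearch stage done in %.1fs", time.time() - t0)

        # -- models --------------------------------------------------------
        if "models" in config.stages:
            t0 = time.time()
            rows: dict[str, list[dict]] = {k: [] for k in config.model_kinds}
            for kind in config.model_kinds:
                for trait in config.model_traits:
                    model = SRIRegression(features, traits[trait], kind=kind,
                                          trait=trait, seed=config.seed)
                    if config.feature_mode == "preset":
                        preset = FEATURE_PRESETS.get((kind, trait))
                        sel = (_canonical_features(config.registry, preset)
                               if preset else "all")
                        res = model.fit(features=sel)
                    elif config.feature_mode == "select":
                        res = model.fit(features="select",
                                        max_subset=config.max_subset)
                    else:
                        res = model.fit(features="all")
                    jpath = out / f"model_{kind}_{trait}.json"
                    res.report.to_json(jpath)
                    record("models", jpath)
                    rows[kind].append(res.report.table_row())
                    log.info("%s model for %s: cv R2=%.3f", kind, trait,
                             res.cv_r2)
            for kind in config.model_kinds:
                tpath = out / f"model_table_{kind}.csv"
                pd.DataFrame(rows[kind]).to_csv(tpath, index=False)
                record("models", tpath)
            completed.append("models")
            log.info("models stage done in %.1fs", time.time() - t0)
    except Exception:
        log.exception("pipeline aborted after stages %s", completed)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()

    manifest = RunManifest(
        config=config.snapshot(), version=__version__,
        started=started, finished=time.strftime("%Y-%m-%dT%H:%M:%S"),
        outputs=outputs, log_path=log_path.name, completed_stages=completed,
    )
    manifest.to_json(out / "manifest.json")
    missing = [f for fs in outputs.values() for f in fs if not (out / f).exists()]
    if missing:  # pragma: no cover - safety net
        raise RuntimeError(f"manifest lists missing files: {missing}")
    return manifest


def make_report(manifest: RunManifest, out_dir: str | Path) -> str:
    """Render a single human-readable report from a completed run.

    Missing stages produce explicit gaps rather than failures, except a
    fully empty manifest, which is an error.
    """
    out = Path(out_dir)
    if not manifest.completed_stages:
        raise ValueError("manifest records no completed stages")
    lines: list[str] = ["# Ripening-indicator analysis report", ""]

    def have(stage: str) -> bool:
        return stage in manifest.completed_stages

    if have("stats"):
        gs = pd.read_csv(out / "group_stats.csv")
        lines += ["## Group-wise descriptive statistics", "",
                  gs.to_string(index=False), ""]
    else:
        lines += ["## Group-wise descriptive statistics", "", "(stage not run)", ""]

    if have("indices") and have("data"):
        features = pd.read_csv(out / "features.csv", index_col=0)
        traits = read_traits_csv(out / "traits.csv")
        rows = []
        for name in features.columns:
            row = {"SRIs": name}
            for trait in TRAIT_NAMES:
                fit = fit_simple_regression(features[name].to_numpy(),
                                            traits[trait])
                row[trait] = f"{fit.r2:.2f}{significance_stars(fit.pvalue)}"
            rows.append(row)
        lines += ["## SRI vs trait determination coefficients (R²)", "",
                  pd.DataFrame(rows).to_string(index=False), "",
                  "*, **, *** significant at P ≤ 0.05, 0.01, 0.001; "
                  "ns = not significant", ""]
    else:
        lines += ["## SRI vs trait determination coefficients", "",
                  "(stage not run)", ""]

    if have("models"):
        for kind in ("dt", "gbr"):
            path = out / f"model_table_{kind}.csv"
            if path.exists():
                tbl = pd.read_csv(path)
                lines += [f"## {kind.upper()} model outcomes", "",
                          tbl.to_string(index=False), ""]
    else:
        lines += ["## Model outcomes", "", "(stage not run)", ""]

    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
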