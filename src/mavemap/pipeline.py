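"""End-to-end pipeline: simulate -> score -> map -> calibrate.

One :class:`RunConfig` (flat YAML-friendly dataclass) drives every stage;
all inter-stage contracts are plain TSV/CSV/JSON files under a run
directory, so any synthetic intermediate can be replaced by real data in
the same format.  Reruns with an identical config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calibration import calibrate, write_calibration
from .maps import build_effect_map, find_bimodal_threshold, write_effect_map
from .scoring import score_counts, write_scores
from .synthetic import (
    SimulationConfig,
    simulate_reference_sets,
    simulate_run,
    write_run_directory,
)

log = logging.getLogger("mavemap")


@dataclass
class RunConfig:
    """All pipeline parameters with assay-standard defaults.

    Defaults encode the canonical thresholds of the analysis: 10-read /
    10-cpm pre-selection floors and the within-tile WT 90th-percentile
    filter (see :mod:`mavemap.scoring`), damaging-score cutoff 0.5
    (activity) or -0.4 (abundance), 20%/35% burial thresholds and the
    5.0 A interface cutoff (:mod:`mavemap.structure`), 3.4 A / 120 deg
    hydrogen bonds (:mod:`mavemap.trajectory`), and op_vst = 350 for
    evidence strengths (:mod:`mavemap.calibration`).
    """

    out_dir: str = "runs/demo"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "score", "map", "calibrate")

    # simulation (see SimulationConfig for the remaining study conditions)
    scenario: str = "activity"  # or "abundance"
    simulation: dict = field(default_factory=dict)

    # scoring
    error_pseudo_weight: float = 2.0

    # map assembly
    damaging_threshold: float | None = None  # None -> KDE valley, scenario fallback
    kde_threshold: bool = True

    # calibration
    n_pos: int = 85
    n_neg: int = 100
    label_noise: float = 0.0
    n_boot: int = 500
    op_vst: float = 350.0
    ci_gated: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        if self.scenario == "abundance":
            return SimulationConfig.abundance_preset(**kwargs)
        if self.scenario != "activity":
            raise ValueError(f"unknown scenario {self.scenario!r}")
        return SimulationConfig(**kwargs)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def run_end_to_end(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    log.addHandler(handler)
    sim_cfg = config.simulation_config()
    artifacts: dict[str, str] = {}
    try:
        run = scores = emap = None
        if "simulate" in config.stages:
            log.info("stage simulate: seed=%d L=%d depth=%d",
                     sim_cfg.seed, sim_cfg.L, sim_cfg.depth)
            try:
                run = simulate_run(sim_cfg)
                write_run_directory(run, sim_cfg, out / "simulate")
            except Exception as e:
                raise RuntimeError(f"stage 'simulate' failed: {e}") from e
            artifacts["simulate"] = "simulate/"

        if "score" in config.stages:
            try:
                if run is None:
                    lib = pd.read_csv(out / "simulate" / "library_counts.tsv", sep="\t")
                    wt = pd.read_csv(out / "simulate" / "wt_control_counts.tsv", sep="\t")
                else:
                    lib, wt = run["lib_counts"], run["wt_counts"]
                scores = score_counts(lib, wt, m=config.error_pseudo_weight)
                write_scores(scores, out / "score")
            except Exception as e:
                raise RuntimeError(f"stage 'score' failed: {e}") from e
            log.info("stage score: %d variants, %d scored",
                     len(scores), int(scores["score"].notna().sum()))
            artifacts["score"] = "score/"

        if "map" in config.stages:
            try:
                if scores is None:
                    scores = pd.read_csv(out / "score" / "scores.tsv", sep="\t")
                if run is None:
                    manifest = json.loads((out / "simulate" / "manifest.json").read_text())
                    wt_seq = manifest["wt_sequence"]
                else:
                    wt_seq = run["wt_sequence"]
                threshold = config.damaging_threshold
                if threshold is None:
                    fallback = 0.5 if config.scenario == "activity" else -0.4
                    if config.kde_threshold:
                        mis = scores[(scores["vclass"] == "missense")
                                     & scores["score"].notna()]["score"]
                        threshold = find_bimodal_threshold(mis, fallback=fallback)
                    else:
                        threshold = fallback
                emap = build_effect_map(scores, wt_seq, damaging_threshold=threshold)
                write_effect_map(emap, out / "map")
            except Exception as e:
                raise RuntimeError(f"stage 'map' failed: {e}") from e
            log.info("stage map: threshold=%.3f", emap.damaging_threshold)
            artifacts["map"] = "map/"

        if "calibrate" in config.stages:
            try:
                if scores is None:
                    scores = pd.read_csv(out / "score" / "scores.tsv", sep="\t")
                if run is None:
                    raise RuntimeError(
                        "calibrate stage needs the simulate stage (for truth-"
                        "derived reference sets) or external reference files"
                    )
                refsets = simulate_reference_sets(
                    run["truth"], n_pos=config.n_pos, n_neg=config.n_neg,
                    label_noise=config.label_noise, seed=config.seed,
                )
                report = calibrate(
                    scores, refsets, n_boot=config.n_boot, seed=config.seed,
                    op_vst=config.op_vst, ci_gated=config.ci_gated,
                )
                write_calibration(report, out / "calibrate")
            except Exception as e:
                raise RuntimeError(f"stage 'calibrate' failed: {e}") from e
            log.info("stage calibrate: AUBPRC=%.3f R90BP=%.3f",
                     report.aubprc, report.r90bp)
            artifacts["calibrate"] = "calibrate/"

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
            "config": dataclasses.asdict(config),
            "stages_run": list(artifacts),
            "artifacts": artifacts,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    finally:
        log.removeHandler(handler)
        handler.close()
    return out
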