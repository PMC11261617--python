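"""Run configuration: YAML parsing into the typed objects of the pipeline.

Every stochastic stage receives a seed derived deterministically from the
single global seed, so a run configuration fully determines its outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .events import DetectionParams
from .geometry import ForsterModel
from .sim_kinetics import AssayDesign, GroundTruthGeometry, ImagerSpecies, NoiseModel


@dataclass
class RunConfig:
    seed: int = 0
    n_molecules: int = 50
    design: AssayDesign | None = None
    truth: GroundTruthGeometry | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    forster: ForsterModel = field(default_factory=ForsterModel)
    detection: DetectionParams = field(default_factory=DetectionParams)
    peaks_k_max: int = 6
    bootstrap_B: int = 200
    traces_path: str | None = None  # analyze existing traces instead of simulating

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed below 2**31."""
        stages = ("synthesize", "peaks", "reconstruct", "bootstrap", "classify")
        if stage not in stages:
            raise KeyError(f"unknown stage {stage!r}")
        state = np.random.SeedSequence(self.seed).generate_state(len(stages), dtype=np.uint32)
        return int(state[stages.index(stage)] % (2**31))


def _species_from_dict(d: dict) -> ImagerSpecies:
    return ImagerSpecies(
        label=d["label"],
        concentration=float(d["concentration"]),
        dwell_time=float(d["dwell_time"]),
        k_on=float(d.get("k_on", 1e-3)),
    )


def design_from_dict(d: dict) -> AssayDesign:
    return AssayDesign(
        n_sites=int(d["n_sites"]),
        species=tuple(_species_from_dict(s) for s in d["species"]),
        frame_time=float(d.get("frame_time", 0.1)),
        duration=float(d.get("duration", 60.0)),
    )


def truth_from_dict(d: dict) -> GroundTruthGeometry:
    return GroundTruthGeometry(
        site_coords=np.asarray(d["site_coords"], dtype=float),
        forster_radius=float(d.get("forster_radius", 5.4)),
        linker_length=float(d.get("linker_length", 0.0)),
    )


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        n_molecules=int(raw.get("n_molecules", 50)),
        traces_path=raw.get("traces"),
    )
    if "design" in raw:
        cfg.design = design_from_dict(raw["design"])
    if "truth" in raw:
        cfg.truth = truth_from_dict(raw["truth"])
    if "noise" in raw:
        cfg.noise = NoiseModel(**{k: float(v) for k, v in raw["noise"].items()})
    if "forster" in raw:
        cfg.forster = ForsterModel(**{k: float(v) for k, v in raw["forster"].items()})
    if "detection" in raw:
        d = raw["detection"]
        cfg.detection = DetectionParams(
            threshold_k=float(d.get("threshold_k", 3.0)),
            baseline_quantile=float(d.get("baseline_quantile", 0.20)),
            min_frames=int(d.get("min_frames", 3)),
            gap_frames=int(d.get("gap_frames", 1)),
        )
    if "peaks" in raw:
        cfg.peaks_k_max = int(raw["peaks"].get("k_max", 6))
    if "bootstrap" in raw:
        cfg.bootstrap_B = int(raw["bootstrap"].get("B", 200))
    return cfg
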