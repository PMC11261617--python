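"""End-to-end pipeline: traces -> events -> peaks -> distances -> shape.

Stages run in order and write their artifacts as they complete, so a failure
at any stage leaves the earlier outputs on disk and raises a
:class:`PipelineError` naming the stage.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig
from .events import detect_events_all
from .geometry import (
    DistanceSet,
    EdgeAssignment,
    bootstrap_shape,
    embed_assignment,
    peaks_to_distances,
    reconstruct_best,
    reconstruct_triangle,
    ReconstructedShape,
    triangular_edge_count,
    write_shape_csv,
    write_shape_pdb,
)
from .peaks import fit_peaks, histogram_tsv
from .sim_kinetics import read_traces_tsv, synthesize_traces, write_traces_tsv

log = logging.getLogger("fret3d")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def _per_molecule_distance_sets(table, peakset, forster, zero_k: float = 3.0):
    """Per-molecule mean E per peak, for molecules covering every peak.

    Non-zero events are hard-assigned to the nearest fitted peak (within
    zero_k SDs of some peak, and further than zero_k zero-peak SDs from 0);
    molecules missing any peak are skipped.
    """
    means = peakset.means()
    sds = np.array([p.sd for p in peakset.peaks])
    zero_sd = peakset.zero_peak.sd if peakset.zero_peak else 0.02
    out = []
    mols = table.molecule_ids()
    evals = table.e_values()
    for mol in np.unique(mols):
        e = evals[mols == mol]
        e = e[e > zero_k * zero_sd]
        if e.size == 0:
            continue
        idx = np.argmin(np.abs(e[:, None] - means[None, :]), axis=1)
        keep = np.abs(e - means[idx]) <= zero_k * sds[idx]
        e, idx = e[keep], idx[keep]
        if set(idx.tolist()) != set(range(len(means))):
            continue
        mol_means = np.array([e[idx == k].mean() for k in range(len(means))])
        if np.any((mol_means <= 0) | (mol_means >= 1)):
            continue
        dists = forster.efficiency_to_distance(mol_means)
        out.append((str(mol), DistanceSet(tuple(dists))))
    return out


def _molecule_shape(ds: DistanceSet, multiplicities, edge_peaks, n_sites: int,
                    seed: int) -> ReconstructedShape:
    """Reconstruct one molecule with the globally chosen peak multiplicities
    and (for quadrangles) the globally chosen edge-to-peak mapping."""
    if n_sites == 3:
        lengths = ds.with_multiplicities(multiplicities).expand()
        return reconstruct_triangle(*lengths)
    lengths = tuple(ds.distances[k] for k in edge_peaks)
    return embed_assignment(EdgeAssignment(lengths), seed=seed)


def _edge_peak_indices(best_shape, global_ds: DistanceSet) -> tuple:
    """Map each K4 edge of the best assignment back to its source peak."""
    lengths = best_shape.assignment.lengths
    out = []
    for L in lengths:
        k = int(np.argmin([abs(L - d) for d in global_ds.distances]))
        if abs(global_ds.distances[k] - L) > 1e-9:
            raise ValueError("assignment length does not match any peak distance")
        out.append(k)
    return tuple(out)


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute the full computational pipeline and write all artifacts.

    Returns a result bundle (dict) with the key objects; byte-identical
    outputs are produced for identical configurations.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"config_seed": config.seed, "version": __version__}

    stage = "synthesize"
    try:
        if config.traces_path:
            traces = read_traces_tsv(config.traces_path)
        else:
            if config.design is None or config.truth is None:
                raise ValueError("config needs either traces or design+truth")
            traces = synthesize_traces(
                config.design,
                config.truth,
                noise=config.noise,
                seed=config.stage_seed("synthesize"),
                n_molecules=config.n_molecules,
            )
            write_traces_tsv(traces, outdir / "traces.tsv")
        bundle["n_traces"] = len(traces)
        log.info("%s: %d traces", stage, len(traces))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "events"
    try:
        table_raw = detect_events_all(traces, config.detection)
        if len(table_raw) == 0:
            raise ValueError("no binding events detected")
        table_raw.write_tsv(outdir / "events.tsv")
        # keep only events whose intra-event scatter is at the noise floor:
        # events spanning a binding-state change mix two FRET levels
        table = table_raw.filter_pure()
        table.write_provenance(outdir / "events.json")
        bundle["n_events"] = len(table_raw)
        bundle["n_events_pure"] = len(table)
        log.info("%s: %d events (%d pure)", stage, len(table_raw), len(table))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "peaks"
    try:
        k_max = config.peaks_k_max
        if config.design is not None:
            # at most n(n-1)/2 resolvable distances for n docking sites
            k_max = min(k_max, triangular_edge_count(config.design.n_sites))
        peakset = fit_peaks(table, k_max=k_max, seed=config.stage_seed("peaks"))
        peakset.write_json(outdir / "peaks.json")
        histogram_tsv(table.e_values(), outdir / "histogram.tsv")
        bundle["peaks"] = peakset
        log.info("%s: %d non-zero peaks (zero peak: %s)", stage, peakset.n_peaks,
                 "yes" if peakset.zero_peak else "no")
    except Exception as e:
        raise PipelineError(stage, e) from e

    n_sites = config.design.n_sites if config.design else None
    stage = "distances"
    try:
        global_ds = peaks_to_distances(peakset, config.forster)
        _json_dump(
            {
                "distances_nm": list(global_ds.distances),
                "sigmas_nm": list(global_ds.sigmas),
                "n_peaks": len(global_ds.distances),
                "forster_radius_nm": config.forster.forster_radius,
            },
            outdir / "distances.json",
        )
        bundle["distances"] = global_ds
    except Exception as e:
        raise PipelineError(stage, e) from e

    if n_sites is None or n_sites < 3:
        # a single distance carries no shape information beyond its value
        bundle["shape"] = None
        _json_dump({"reconstruction": None, "reason": "fewer than 3 sites"}, outdir / "shape.json")
        _json_dump(bundle_summary(bundle), outdir / "run.json")
        return bundle

    stage = "reconstruct"
    try:
        m = triangular_edge_count(n_sites)
        if len(global_ds.distances) > m:
            raise ValueError(
                f"{len(global_ds.distances)} peaks found but n_sites={n_sites} allows at most {m}"
            )
        result = reconstruct_best(global_ds, n_sites=n_sites, seed=config.stage_seed("reconstruct"))
        best = result.best
        write_shape_csv(best, outdir / "shape.csv")
        write_shape_pdb(best, outdir / "shape.pdb")
        _json_dump(
            {
                "residual_nm": best.residual,
                "multiplicities": list(best.multiplicities) if best.multiplicities else None,
                "n_candidates": len(result.shapes),
                "n_tied": len(result.tied),
                "coords_nm": best.coords.tolist(),
            },
            outdir / "shape.json",
        )
        bundle["reconstruction"] = result
        bundle["shape"] = best
        log.info("%s: best residual %.3g nm over %d candidates", stage, best.residual, len(result.shapes))
    except Exception as e:
        raise PipelineError(stage, e) from e

    stage = "bootstrap"
    try:
        mol_sets = _per_molecule_distance_sets(table, peakset, config.forster)
        bundle["n_molecules_usable"] = len(mol_sets)
        if len(mol_sets) < 2:
            warnings.warn("fewer than 2 molecules cover every peak; bootstrap skipped")
            _json_dump({"skipped": True, "n_molecules": len(mol_sets)}, outdir / "bootstrap.json")
        else:
            edge_peaks = _edge_peak_indices(best, global_ds) if n_sites == 4 else None
            seed = config.stage_seed("bootstrap")
            shapes = [
                _molecule_shape(ds, best.multiplicities, edge_peaks, n_sites, seed)
                for _, ds in mol_sets
            ]
            boot = bootstrap_shape(shapes, B=config.bootstrap_B, seed=seed)
            _json_dump(
                {
                    "B": boot.n_replicates,
                    "n_molecules": len(mol_sets),
                    "vertex_sd_nm": boot.vertex_sd.tolist(),
                    "mean_vertex_sd_nm": boot.mean_vertex_sd,
                    "mean_coords_nm": boot.mean_shape.coords.tolist(),
                },
                outdir / "bootstrap.json",
            )
            bundle["bootstrap"] = boot
            log.info("%s: mean vertex SD %.3g nm over %d molecules", stage,
                     boot.mean_vertex_sd, len(mol_sets))
    except Exception as e:
        raise PipelineError(stage, e) from e

    _json_dump(bundle_summary(bundle), outdir / "run.json")
    return bundle


def bundle_summary(bundle: dict) -> dict:
    out = {
        "version": bundle.get("version"),
        "config_seed": bundle.get("config_seed"),
        "n_traces": bundle.get("n_traces"),
        "n_events": bundle.get("n_events"),
    }
    peaks = bundle.get("peaks")
    if peaks is not None:
        out["peak_means"] = [p.mean for p in peaks.peaks]
        out["zero_peak_weight"] = peaks.zero_peak.weight if peaks.zero_peak else None
    shape = bundle.get("shape")
    if shape is not None:
        out["residual_nm"] = shape.residual
    boot = bundle.get("bootstrap")
    if boot is not None:
        out["mean_vertex_sd_nm"] = boot.mean_vertex_sd
    return out
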