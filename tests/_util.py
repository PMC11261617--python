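"""Shared builders for test scenarios."""

import numpy as np

import fret3d as f


def standard_design(n_sites: int, duration: float = 240.0) -> f.AssayDesign:
    """Probe-exchange design with kinetics tuned for single-pair events:
    short-dwell donor, long-dwell acceptor at comparable occupancy."""
    donor = f.ImagerSpecies("donor", 30.0, 1.0)
    acceptor = f.ImagerSpecies("acceptor", 25.0, 10.0)
    return f.AssayDesign(n_sites, (donor, acceptor), frame_time=0.1, duration=duration)


def standard_noise() -> f.NoiseModel:
    return f.NoiseModel(total_intensity=1000.0, channel_sd=40.0, baseline_sd=20.0)


def triangle_truth(efficiencies=(0.67, 0.34, 0.49), forster_radius=5.4) -> f.GroundTruthGeometry:
    """3-site geometry whose pairwise efficiencies (d12, d13, d23 order)
    equal the requested values."""
    model = f.ForsterModel(forster_radius, 0.0)
    d = [f.fret_to_distance(e, model) for e in efficiencies]
    tri = f.reconstruct_triangle(*d)
    assert tri.residual < 1e-9
    return f.GroundTruthGeometry(tri.coords, forster_radius=forster_radius, linker_length=0.0)


def d2_coords(a=1.0, b=2.0, c=3.0) -> np.ndarray:
    """Generic D2-symmetric 4-point configuration (three perpendicular
    two-fold axes): vertices (+-a, +-b, +-c) with an even number of sign
    flips."""
    return np.array([[a, b, c], [-a, -b, c], [-a, b, -c], [a, -b, -c]], dtype=float)


def standard_config(truth: f.GroundTruthGeometry, n_sites: int, seed: int,
                    n_molecules: int = 80) -> f.RunConfig:
    cfg = f.RunConfig(
        seed=seed,
        n_molecules=n_molecules,
        design=standard_design(n_sites),
        truth=truth,
        noise=standard_noise(),
        forster=f.ForsterModel(truth.forster_radius, 0.0),
    )
    cfg.detection = f.DetectionParams(min_frames=5)
    return cfg


def random_quad(rng: np.random.Generator, scale: float = 3.0) -> np.ndarray:
    """Random 4-point configuration, rejected if nearly degenerate."""
    while True:
        coords = rng.normal(0.0, scale, (4, 3))
        d = f.pairwise_distances(coords)
        iu = np.triu_indices(4, 1)
        if d[iu].min() > 0.3 * scale:
            return coords
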