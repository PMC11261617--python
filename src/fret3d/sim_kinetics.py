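"""Stochastic probe-exchange kinetics and synthetic two-color trace generation.

Transient-hybridization FRET assays read out distances by letting dye-labeled
"imager" oligos bind reversibly to docking strands on an immobilized molecule.
Donor- and acceptor-labeled imagers compete for the same 2-4 docking sites;
frames during which exactly one donor and one acceptor are bound (a "single
FRET-pair" frame) report the apparent FRET efficiency of that site pair, and
over time all pairwise distances are sampled in a single one-pot measurement.

This module simulates each docking site as an independent continuous-time
Markov chain (empty <-> bound by one imager species), discretizes the exact
event times to camera frames, and renders synthetic donor/acceptor intensity
traces from a ground-truth 3D geometry through the Foerster model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DONOR = "donor"
ACCEPTOR = "acceptor"
EMPTY = -1

TRACE_COLUMNS = ["molecule_id", "frame", "time_s", "I_D", "I_A"]


@dataclass(frozen=True)
class ImagerSpecies:
    """One imager strand species in solution.

    Parameters
    ----------
    label : {"donor", "acceptor"}
        Which fluorophore the imager carries.
    concentration : float
        Solution concentration in nM.
    dwell_time : float
        Mean bound time tau in seconds (set by duplex length; ~1.0 s for an
        8 nt imager).
    k_on : float
        Association rate constant in nM^-1 s^-1. Default 1e-3, a typical
        short-oligo hybridization scale.
    """

    label: str
    concentration: float
    dwell_time: float
    k_on: float = 1e-3

    def __post_init__(self):
        if self.label not in (DONOR, ACCEPTOR):
            raise ValueError(f"label must be {DONOR!r} or {ACCEPTOR!r}, got {self.label!r}")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.dwell_time <= 0:
            raise ValueError("dwell_time must be > 0")
        if self.k_on <= 0:
            raise ValueError("k_on must be > 0")

    @property
    def binding_rate(self) -> float:
        """Per-site association rate in s^-1 (k_on * concentration)."""
        return self.k_on * self.concentration


@dataclass(frozen=True)
class AssayDesign:
    """Docking-site count, imager species, and acquisition timing."""

    n_sites: int
    species: tuple
    frame_time: float = 0.1
    duration: float = 60.0

    def __post_init__(self):
        if self.n_sites not in (1, 2, 3, 4):
            raise ValueError("n_sites must be 1-4")
        object.__setattr__(self, "species", tuple(self.species))
        if self.frame_time <= 0:
            raise ValueError("frame_time must be > 0")
        if self.duration < self.frame_time:
            raise ValueError("duration must be >= frame_time")
        labels = {s.label for s in self.species}
        if not {DONOR, ACCEPTOR} <= labels:
            raise ValueError("need at least one donor and one acceptor species")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_time))

    @property
    def species_labels(self) -> tuple:
        return tuple(s.label for s in self.species)


@dataclass(frozen=True)
class GroundTruthGeometry:
    """Known site coordinates plus the Foerster model used to emit FRET.

    ``site_coords`` are the docking positions (nm).  Dyes sit a linker length
    radially outward from the centroid of the sites, mirroring how reference
    structures are expanded when fitting reconstructions back to them.
    """

    site_coords: np.ndarray
    forster_radius: float = 5.4
    linker_length: float = 0.0

    def __post_init__(self):
        coords = np.asarray(self.site_coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("site_coords must be (n, 3)")
        object.__setattr__(self, "site_coords", coords)
        if self.forster_radius <= 0:
            raise ValueError("forster_radius must be > 0")
        if self.linker_length < 0:
            raise ValueError("linker_length must be >= 0")
        d = _pairwise_distances(self.dye_coords())
        iu = np.triu_indices(len(coords), 1)
        if np.any(d[iu] <= 0):
            raise ValueError("all pairwise distances must be > 0")

    @property
    def n_sites(self) -> int:
        return self.site_coords.shape[0]

    def dye_coords(self) -> np.ndarray:
        """Site coordinates pushed radially outward by the linker length."""
        c = self.site_coords.mean(axis=0)
        rel = self.site_coords - c
        norms = np.linalg.norm(rel, axis=1, keepdims=True)
        unit = np.divide(rel, norms, out=np.zeros_like(rel), where=norms > 0)
        return self.site_coords + self.linker_length * unit

    def efficiency_matrix(self) -> np.ndarray:
        """Apparent FRET efficiency E = 1/(1+(r/R0)^6) for every dye pair."""
        d = _pairwise_distances(self.dye_coords())
        with np.errstate(divide="ignore"):
            e = 1.0 / (1.0 + (d / self.forster_radius) ** 6)
        np.fill_diagonal(e, 0.0)
        return e


def _pairwise_distances(coords: np.ndarray) -> np.ndarray:
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


@dataclass
class OccupancyTrace:
    """Per-frame, per-site occupancy: EMPTY (-1) or an index into species."""

    states: np.ndarray  # (n_frames, n_sites) int16
    species_labels: tuple
    frame_time: float
    rng_seed: int

    @property
    def n_frames(self) -> int:
        return self.states.shape[0]

    @property
    def n_sites(self) -> int:
        return self.states.shape[1]

    def _label_mask(self, label: str) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.species_labels) if lab == label]
        return np.isin(self.states, idx)

    def donor_counts(self) -> np.ndarray:
        return self._label_mask(DONOR).sum(axis=1)

    def acceptor_counts(self) -> np.ndarray:
        return self._label_mask(ACCEPTOR).sum(axis=1)

    def occupancy_fraction(self, species_index: int) -> float:
        """Fraction of site-frames occupied by a given species."""
        return float((self.states == species_index).mean())


def equilibrium_occupancy(design: AssayDesign) -> np.ndarray:
    """Closed-form steady-state per-site occupancy probability per species.

    For a site that is empty or bound by exactly one of the competing species,
    the stationary probability of being bound by species s is

        p_s = k_on,s * c_s * tau_s / (1 + sum_s' k_on,s' * c_s' * tau_s')
    """
    x = np.array([s.binding_rate * s.dwell_time for s in design.species])
    return x / (1.0 + x.sum())


def _simulate_site(rng: np.random.Generator, species: tuple, duration: float) -> list:
    """Exact event-time (Gillespie) simulation of one site; returns segments
    (t0, t1, state) covering [0, duration) with state EMPTY or species index."""
    rates = np.array([s.binding_rate for s in species])
    total = rates.sum()
    segs = []
    t = 0.0
    if total <= 0:
        return [(0.0, duration, EMPTY)]
    p = rates / total
    while t < duration:
        t_bind = t + rng.exponential(1.0 / total)
        if t_bind > t:
            segs.append((t, min(t_bind, duration), EMPTY))
        if t_bind >= duration:
            break
        s = int(rng.choice(len(species), p=p))
        t_unbind = t_bind + rng.exponential(species[s].dwell_time)
        segs.append((t_bind, min(t_unbind, duration), s))
        t = t_unbind
    return segs


def _majority_states(segs, n_frames: int, frame_time: float, n_species: int) -> np.ndarray:
    # time-in-frame accumulator; ties resolve deterministically (EMPTY first,
    # then species order)
    acc = np.zeros((n_frames, n_species + 1))
    for t0, t1, st in segs:
        if t1 <= t0:
            continue
        f0 = max(int(t0 / frame_time), 0)
        f1 = min(int(np.ceil(t1 / frame_time)), n_frames)
        for f in range(f0, f1):
            lo = max(t0, f * frame_time)
            hi = min(t1, (f + 1) * frame_time)
            if hi > lo:
                acc[f, st + 1] += hi - lo
    return (acc.argmax(axis=1) - 1).astype(np.int16)


def simulate_occupancy(design: AssayDesign, seed: int) -> OccupancyTrace:
    """Simulate per-site imager exchange and discretize to camera frames.

    Each site is an independent continuous-time Markov chain: empty -> bound
    by species s at rate k_on*[s]; bound(s) -> empty at rate 1/tau_s.  The
    per-frame state is the occupant holding the site for the majority of the
    frame, so events shorter than half a frame are not resolved.
    """
    n_frames = design.n_frames
    if n_frames == 0:
        raise ValueError("design has zero frames")
    if all(s.concentration == 0 for s in design.species):
        warnings.warn("all imager concentrations are zero; trace will be empty")
    rng = np.random.default_rng(seed)
    states = np.empty((n_frames, design.n_sites), dtype=np.int16)
    for site in range(design.n_sites):
        segs = _simulate_site(rng, design.species, design.duration)
        states[:, site] = _majority_states(segs, n_frames, design.frame_time, len(design.species))
    return OccupancyTrace(states, design.species_labels, design.frame_time, int(seed))


def single_pair_fraction(occ: OccupancyTrace) -> float:
    """Fraction of frames with exactly one donor AND exactly one acceptor bound.

    These single FRET-pair frames are the usable signal; assay design (imager
    concentrations and dwell times) is tuned to maximize this fraction.
    """
    if occ.n_frames == 0:
        raise ValueError("empty occupancy trace")
    nd = occ.donor_counts()
    na = occ.acceptor_counts()
    return float(np.mean((nd == 1) & (na == 1)))


@dataclass(frozen=True)
class NoiseModel:
    """Additive Gaussian channel noise on top of a constant emitted intensity.

    ``total_intensity`` is the expected summed two-channel signal per bound
    donor (a.u.); ``channel_sd`` the per-frame noise SD while emitting;
    ``baseline_sd`` the dark-frame noise SD.
    """

    total_intensity: float = 1000.0
    channel_sd: float = 80.0
    baseline_sd: float = 30.0

    def __post_init__(self):
        if self.total_intensity <= 0:
            raise ValueError("total_intensity must be > 0")
        if self.channel_sd < 0 or self.baseline_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass
class IntensityTrace:
    """Two-channel intensity time trace for one immobilized molecule."""

    molecule_id: str
    time: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.I_D = np.asarray(self.I_D, dtype=float)
        self.I_A = np.asarray(self.I_A, dtype=float)
        if not (len(self.time) == len(self.I_D) == len(self.I_A)):
            raise ValueError("channel arrays must have equal length")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
                raise ValueError("time must strictly increase with a constant step")

    @property
    def n_frames(self) -> int:
        return len(self.time)

    def total(self) -> np.ndarray:
        return self.I_D + self.I_A


def synthesize_traces(
    design: AssayDesign,
    truth: GroundTruthGeometry,
    noise: NoiseModel | None = None,
    seed: int = 0,
    n_molecules: int = 1,
    return_occupancy: bool = False,
):
    """Generate synthetic intensity traces from a ground-truth geometry.

    Occupancy is simulated per molecule; emission is gated on donor binding.
    A frame with exactly one donor at site i and one acceptor at site j emits
    with apparent efficiency E_ij from the Foerster model; donor-only frames
    emit at E = 0; frames with several bound dyes use the standard
    multi-acceptor transfer sum per donor.  Acceptor-only frames stay near
    baseline (the acceptor is not directly excited).
    """
    if truth.n_sites != design.n_sites:
        raise ValueError(
            f"truth has {truth.n_sites} sites but design expects {design.n_sites}"
        )
    noise = noise or NoiseModel()
    emat = truth.efficiency_matrix()
    # transfer-rate ratio k_ij = (R0/r_ij)^6 = E/(1-E)
    with np.errstate(divide="ignore"):
        kmat = emat / (1.0 - emat)
    master = np.random.default_rng(seed)
    traces, occs = [], []
    for mol in range(n_molecules):
        occ_seed = int(master.integers(2**31))
        noise_rng = np.random.default_rng(int(master.integers(2**31)))
        occ = simulate_occupancy(design, occ_seed)
        donor_mask = occ._label_mask(DONOR)
        acceptor_mask = occ._label_mask(ACCEPTOR)
        nd = donor_mask.sum(axis=1)
        na = acceptor_mask.sum(axis=1)
        n_frames = occ.n_frames
        fa = np.zeros(n_frames)
        fd = np.zeros(n_frames)
        emitting = nd > 0
        donor_only = emitting & (na == 0)
        fd[donor_only] = nd[donor_only]
        single = (nd == 1) & (na == 1)
        if single.any():
            i_idx = donor_mask[single].argmax(axis=1)
            j_idx = acceptor_mask[single].argmax(axis=1)
            e = emat[i_idx, j_idx]
            fa[single] = e
            fd[single] = 1.0 - e
        multi = emitting & (na > 0) & ~single
        for f in np.flatnonzero(multi):
            dsites = np.flatnonzero(donor_mask[f])
            asites = np.flatnonzero(acceptor_mask[f])
            for i in dsites:
                k = kmat[i, asites].sum()
                e_eff = k / (1.0 + k)
                fa[f] += e_eff
                fd[f] += 1.0 - e_eff
        i0 = noise.total_intensity
        i_d = np.where(emitting, i0 * fd, 0.0)
        i_a = np.where(emitting, i0 * fa, 0.0)
        sd = np.where(emitting, noise.channel_sd, noise.baseline_sd)
        i_d = i_d + noise_rng.normal(0.0, 1.0, n_frames) * sd
        i_a = i_a + noise_rng.normal(0.0, 1.0, n_frames) * sd
        time = (np.arange(n_frames) + 0.5) * design.frame_time
        traces.append(IntensityTrace(f"mol{mol:05d}", time, i_d, i_a))
        occs.append(occ)
    if return_occupancy:
        return traces, occs
    return traces


def write_traces_tsv(traces, path) -> None:
    """Write traces as one long-format TSV (molecule_id, frame, time_s, I_D, I_A)."""
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.time,
                    "I_D": tr.I_D,
                    "I_A": tr.I_A,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_traces_tsv(path) -> list:
    """Read traces written by :func:`write_traces_tsv`."""
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace file missing columns: {sorted(missing)}")
    traces = []
    for mol, grp in df.groupby("molecule_id", sort=True):
        grp = grp.sort_values("frame")
        traces.append(
            IntensityTrace(str(mol), grp["time_s"].to_numpy(), grp["I_D"].to_numpy(), grp["I_A"].to_numpy())
        )
    return traces
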