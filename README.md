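# fret3d

**Ab initio 3D coordinates of 2–4 labeled points per single molecule, from
two-color probe-exchange FRET traces.**

Transient-hybridization ("probe-exchange") smFRET assays label positions of
interest on a biomolecule with short DNA docking strands. Dye-labeled imager
oligos in solution bind and unbind the docking sites stochastically; during
frames in which exactly one donor and one acceptor imager are bound, the
apparent FRET efficiency E = I_A/(I_A + I_D) reports the distance between
that pair of sites. Over minutes, a single immobilized molecule samples all
of its pairwise distances in one pot. `fret3d` implements the computational
side of this measurement for scientists running or designing such assays:

1. **Kinetics simulation** (`sim_kinetics`) — per-site continuous-time Markov
   simulation of competing donor/acceptor imager binding, for assay design
   (how many single FRET-pair frames does a given concentration/dwell-time
   choice yield?), plus synthetic two-channel trace generation from a known
   geometry via the Förster model E = 1/(1 + (r/R₀)⁶).
2. **Event analysis** (`events`) — binding-event detection on total
   intensity, per-event averaged apparent efficiency, and a purity filter
   that rejects events spanning a binding-state change.
3. **Peak fitting** (`peaks`) — EM-fitted Gaussian mixture on the event
   efficiencies with a censored zero component for donor-only events and an
   optional uniform blur background; model size chosen by BIC. If the number
   of fitted peaks is not a triangular number m = n(n−1)/2, every integer
   multiplicity expansion of the peaks up to m is enumerated (degenerate
   peaks).
4. **Geometry** (`geometry`) — peaks → distances via r = R₀(1/E − 1)^(1/6);
   enumeration of all dissimilar assignments of the six distances to the
   edges of K₄ (30 classes for six distinct lengths); exact trilateration or
   least-violation stress embedding of each; the assignment whose edge
   lengths must change the least (RMS) is the reconstruction. Generalized
   Procrustes averaging across molecules, bootstrap positional uncertainty,
   rigid fitting to reference (PDB) coordinates with a dye-linker offset,
   and calibration of (R₀, linker length) against the B-DNA helix model.
5. **Classification** (`classify`) — rotation/translation/reflection-
   invariant shape features (sorted pairwise distances, perimeter, Heron
   area) and a gradient-boosted tree classifier evaluated on held-out
   molecules with a row-normalized confusion matrix.
6. **CLI** (`fret3d`) — subcommands `simulate`, `synthesize`, `events`,
   `peaks`, `reconstruct`, `classify`, `calibrate`, and `run` for the full
   pipeline from a YAML configuration.

## Worked example

Simulate a 3-site construct whose pairwise efficiencies are 0.67, 0.34 and
0.49 (a linear DNA with three docking sites), analyze it end to end, and
reconstruct the triangle:

```sh
fret3d run --config examples/three_site.yaml --outdir out/
```

prints (seed 11):

```json
{"config_seed": 11, "mean_vertex_sd_nm": 0.013805647282241403,
 "n_events": 862, "n_traces": 80,
 "peak_means": [0.3405246322374462, 0.49023731261743797, 0.6682579998755768],
 "residual_nm": 5.127900497022837e-16, "version": "0.1.0",
 "zero_peak_weight": 0.6923901281298309}
```

Reading this output: from 80 simulated molecules, 862 binding events were
detected; the efficiency histogram resolves three peaks at E = 0.341, 0.490
and 0.668 — the generating values to within ±0.01 — while 69% of events are
donor-only (the E = 0 peak), the expected situation when donor and acceptor
imagers compete for the same sites. The three distances embed as a triangle
with zero edge violation (`residual_nm` ≈ 0); `out/shape.csv` holds the
canonical-frame coordinates

```
vertex,x_nm,y_nm,z_nm,residual_nm
V1,0.000000,0.000000,0.000000,0.000000
V2,6.028863,0.000000,0.000000,0.000000
V3,3.549611,4.116111,0.000000,0.000000
```

(congruent to the generating geometry: edge lengths 6.03, 5.44 and 4.81 nm
match R₀(1/E − 1)^(1/6) for the three peaks at R₀ = 5.4 nm), and the
bootstrap over molecules puts the mean per-vertex positional SD at 0.014 nm.
`out/shape.pdb` contains the same vertices as HETATM pseudo-atoms for
viewing alongside a reference structure.

The configuration file is plain YAML; see `examples/three_site.yaml` for the
assay design (imager concentrations and dwell times), ground-truth geometry,
noise model, and per-stage parameters.

## Scope and limitations

Apparent efficiencies only (no gamma/leakage/direct-excitation corrections);
at most four labeled sites; distances cannot determine chirality, so every
reconstruction is reported up to reflection; see `docs/methods.md` for the
model assumptions, parameter defaults, and known limitations.
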