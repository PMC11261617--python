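"""Distance geometry: Foerster conversion, embeddings, alignment, calibration."""

import itertools

import numpy as np
import pytest

import fret3d as f
from fret3d.geometry import (
    canonicalize,
    distinct_distances,
    expand_from_centroid,
    helix_dye_position,
    read_reference_pdb,
    write_shape_pdb,
)

from _util import random_quad


class TestForsterConversion:
    def test_midpoint_efficiency_gives_forster_radius(self):
        model = f.ForsterModel(5.4, 0.0)
        assert f.fret_to_distance(0.5, model) == pytest.approx(5.4, abs=1e-12)

    def test_hand_evaluated_closed_form(self):
        # r = 5.4 * (1/0.8 - 1)^(1/6) = 5.4 * 0.25^(1/6)
        model = f.ForsterModel(5.4, 0.0)
        assert f.fret_to_distance(0.8, model) == pytest.approx(4.2864, abs=1e-3)

    def test_round_trip_is_identity(self):
        model = f.ForsterModel(6.0, 0.0)
        for e in (0.05, 0.3, 0.5, 0.77, 0.95):
            r = model.efficiency_to_distance(e)
            assert model.distance_to_efficiency(r) == pytest.approx(e, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.2, 1.5])
    def test_out_of_range_efficiency_is_an_error(self, bad):
        with pytest.raises(ValueError):
            f.fret_to_distance(bad, f.ForsterModel())

    def test_distance_uncertainty_propagates_from_peak_sem(self):
        peak = f.GaussianPeak(mean=0.5, sd=0.05, weight=1.0, sem=0.01, n_events=25)
        ps = f.PeakSet((peak,), None, 0.0, 0.0, 25)
        model = f.ForsterModel(5.4, 0.0)
        ds = f.peaks_to_distances(ps, model)
        # numeric derivative check of the delta method
        h = 1e-6
        drde = (f.fret_to_distance(0.5 + h, model) - f.fret_to_distance(0.5 - h, model)) / (2 * h)
        assert ds.sigmas[0] == pytest.approx(abs(drde) * 0.01, rel=1e-4)


class TestReconstructTriangle:
    def test_pythagorean_placement(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        np.testing.assert_allclose(
            tri.coords, [[0, 0, 0], [3, 0, 0], [0, 4, 0]], atol=1e-12
        )
        assert tri.residual == 0.0

    def test_equilateral_apex(self):
        tri = f.reconstruct_triangle(1.0, 1.0, 1.0)
        np.testing.assert_allclose(tri.coords[2], [0.5, np.sqrt(3) / 2, 0.0], atol=1e-12)

    def test_nonpositive_length_is_an_error(self):
        with pytest.raises(ValueError):
            f.reconstruct_triangle(1.0, -1.0, 1.0)

    def test_violated_inequality_matches_grid_search_oracle(self):
        """(1, 1, 3) cannot close; the least-violation collinear layout must
        match a brute-force grid search over 1-D placements."""
        d12, d13, d23 = 1.0, 1.0, 3.0
        tri = f.reconstruct_triangle(d12, d13, d23)
        assert tri.degenerate
        grid = np.linspace(-3.0, 3.0, 1201)
        best = np.inf
        for t2 in grid:
            d2 = np.abs(t2 - 0.0)
            d3a = np.abs(grid)
            d23a = np.abs(grid - t2)
            rms = np.sqrt(((d2 - d12) ** 2 + (d3a - d13) ** 2 + (d23a - d23) ** 2) / 3.0)
            best = min(best, rms.min())
        assert tri.residual == pytest.approx(best, abs=1e-3)


def _brute_force_class_count(lengths):
    edges = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
    index = {e: i for i, e in enumerate(edges)}
    perms = [
        tuple(index[tuple(sorted((s[i], s[j])))] for (i, j) in edges)
        for s in itertools.permutations(range(4))
    ]
    seen = set()
    for order in set(itertools.permutations(lengths)):
        seen.add(min(tuple(order[i] for i in p) for p in perms))
    return len(seen)


class TestEnumerateAssignments:
    def test_six_distinct_lengths_give_thirty_classes(self):
        assert len(f.enumerate_assignments([1, 2, 3, 4, 5, 6])) == 30

    def test_identical_lengths_give_one_class(self):
        assert len(f.enumerate_assignments([2.0] * 6)) == 1

    @pytest.mark.parametrize(
        "lengths",
        [
            (1, 1, 2, 2, 3, 3),
            (1, 1, 1, 2, 2, 3),
            (1, 1, 1, 1, 2, 3),
            (1, 2, 3, 4, 5, 6),
            (1, 1, 1, 1, 1, 2),
        ],
    )
    def test_counts_match_brute_force_for_every_repetition_pattern(self, lengths):
        assert len(f.enumerate_assignments(lengths)) == _brute_force_class_count(lengths)

    def test_wrong_length_count_is_an_error(self):
        with pytest.raises(ValueError):
            f.enumerate_assignments([1, 2, 3])

    def test_canonical_form_is_permutation_invariant(self):
        a = f.EdgeAssignment((1, 2, 3, 4, 5, 6))
        # apply an explicit vertex swap 0<->1: edges map accordingly
        swapped = f.EdgeAssignment((1, 4, 5, 2, 3, 6))
        assert a.canonical_form() == swapped.canonical_form()


class TestEmbedAssignment:
    def test_regular_tetrahedron_embeds_exactly(self):
        shape = f.embed_assignment(f.EdgeAssignment((1.0,) * 6))
        assert shape.residual < 1e-9
        d = shape.realized_distances()
        iu = np.triu_indices(4, 1)
        np.testing.assert_allclose(d[iu], 1.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_configuration_self_consistency(self, seed):
        """Exact distances from a random 4-point cloud embed back to the
        generating shape (up to relabeling, rigid motion, reflection)."""
        coords = random_quad(np.random.default_rng(seed))
        d = f.pairwise_distances(coords)
        iu = np.triu_indices(4, 1)
        res = f.reconstruct_best(f.DistanceSet(tuple(d[iu])))
        diameter = d.max()
        assert res.best.residual < 1e-9
        rmsd = min(f.fit_to_reference(s, coords).rmsd for s in res.tied)
        assert rmsd < 1e-6 * diameter

    def test_d2_tetrad_collapses_to_three_doubled_distances_and_embeds(self):
        coords = np.array([[1, 2, 3], [-1, -2, 3], [-1, 2, -3], [1, -2, -3]], dtype=float)
        vals, counts = distinct_distances(coords)
        np.testing.assert_allclose(vals, np.sqrt([20.0, 40.0, 52.0]), atol=1e-9)
        assert counts.tolist() == [2, 2, 2]
        ds = f.DistanceSet(tuple(vals), (2, 2, 2))
        res = f.reconstruct_best(ds)
        assert res.best.residual < 1e-9
        rmsd = min(f.fit_to_reference(s, coords).rmsd for s in res.tied)
        assert rmsd < 1e-6 * vals.max()


class TestReconstructBest:
    def test_triangle_distances_give_unique_result(self):
        res = f.reconstruct_best(f.DistanceSet((3.0, 4.0, 5.0)))
        assert len(res.shapes) == 1
        assert res.best.residual == 0.0

    def test_empty_distance_set_is_an_error(self):
        with pytest.raises(ValueError):
            f.DistanceSet(())

    def test_degenerate_peaks_search_all_expansions(self):
        """Four peaks on a four-site molecule search all 10 multiplicity
        expansions; a (1,3,1,1)-type expansion is among candidates
        and admits a violation-free quadrangle."""
        model = f.ForsterModel(5.4, 0.0)
        dists = tuple(f.fret_to_distance(e, model) for e in (0.18, 0.38, 0.55, 0.84))
        res = f.reconstruct_best(f.DistanceSet(dists), n_sites=4, seed=0)
        mus = {s.multiplicities for s in res.shapes}
        assert len({m for m in mus}) == 10
        assert (1, 3, 1, 1) in mus
        best_1311 = min(s.residual for s in res.shapes if s.multiplicities == (1, 3, 1, 1))
        assert best_1311 < 1e-9

    def test_mirror_image_has_identical_residual(self):
        """Distances cannot determine chirality: the best shape and its
        mirror realize the same edge lengths."""
        coords = random_quad(np.random.default_rng(11))
        d = f.pairwise_distances(coords)
        iu = np.triu_indices(4, 1)
        res = f.reconstruct_best(f.DistanceSet(tuple(d[iu])))
        best = res.best
        mirrored = best.mirrored()
        np.testing.assert_allclose(
            best.realized_distances(), mirrored.realized_distances(), atol=1e-12
        )

    def test_two_point_set(self):
        res = f.reconstruct_best(f.DistanceSet((4.2,)))
        np.testing.assert_allclose(res.best.coords, [[0, 0, 0], [4.2, 0, 0]])


class TestCanonicalFrame:
    @pytest.mark.parametrize("seed", range(4))
    def test_canonicalization_is_idempotent(self, seed):
        coords = random_quad(np.random.default_rng(seed))
        once = canonicalize(coords)
        np.testing.assert_allclose(canonicalize(once), once, atol=1e-9)

    def test_canonical_frame_constraints(self):
        coords = canonicalize(random_quad(np.random.default_rng(42)))
        np.testing.assert_allclose(coords[0], 0.0, atol=1e-12)
        assert coords[1, 0] > 0 and abs(coords[1, 1]) < 1e-12 and abs(coords[1, 2]) < 1e-12
        assert coords[2, 1] >= 0 and abs(coords[2, 2]) < 1e-12
        assert coords[3, 2] >= 0


class TestAlignAndAverage:
    def test_identical_copies_average_to_themselves(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        mean, rmsds = f.align_and_average([tri] * 4)
        np.testing.assert_allclose(mean.coords, tri.coords, atol=1e-9)
        assert max(rmsds) < 1e-9

    def test_rigid_transform_and_reflection_align_exactly(self):
        rng = np.random.default_rng(5)
        coords = random_quad(rng)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = coords @ q + rng.normal(0, 10, 3)
        mirrored = moved * np.array([1.0, 1.0, -1.0])
        _, rmsds = f.align_and_average([coords, moved, mirrored])
        assert max(rmsds) < 1e-9

    def test_mean_shape_approaches_generator_under_noise(self):
        """CLT: averaging 100 noisy copies recovers the generator to within
        3 sigma / sqrt(100) per coordinate."""
        rng = np.random.default_rng(6)
        base = canonicalize(random_quad(rng))
        sigma = 0.1
        shapes = [base + rng.normal(0, sigma, base.shape) for _ in range(100)]
        mean, _ = f.align_and_average(shapes)
        fit = f.fit_to_reference(mean, base, search_permutations=False)
        assert fit.rmsd < 3 * sigma / np.sqrt(100) * np.sqrt(3)

    def test_mixed_vertex_counts_are_an_error(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        quad = f.embed_assignment(f.EdgeAssignment((1.0,) * 6))
        with pytest.raises(ValueError):
            f.align_and_average([tri, quad])


class TestBootstrapShape:
    def test_identical_molecules_have_zero_spread(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        out = f.bootstrap_shape([tri] * 6, B=40, seed=0)
        assert out.vertex_sd.max() < 1e-9

    def test_single_replicate_has_zero_spread(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        tri2 = f.reconstruct_triangle(3.1, 4.0, 5.0)
        out = f.bootstrap_shape([tri, tri2], B=1, seed=0)
        assert out.vertex_sd.max() == 0.0

    def test_invalid_arguments(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        with pytest.raises(ValueError):
            f.bootstrap_shape([tri, tri], B=0, seed=0)
        with pytest.raises(ValueError):
            f.bootstrap_shape([tri], B=5, seed=0)

    def test_uncertainty_shrinks_with_molecule_count(self):
        """Vertex SD scales roughly as 1/sqrt(n molecules) over a 4x range."""
        rng = np.random.default_rng(7)
        base = canonicalize(random_quad(rng))

        def molecules(n):
            return [base + rng.normal(0, 0.2, base.shape) for _ in range(n)]

        sd_small = f.bootstrap_shape(molecules(25), B=80, seed=1).mean_vertex_sd
        sd_large = f.bootstrap_shape(molecules(100), B=80, seed=2).mean_vertex_sd
        ratio = sd_small / sd_large
        assert 1.3 < ratio < 3.1


class TestFitToReference:
    def test_linker_expanded_reference_fits_exactly(self):
        rng = np.random.default_rng(8)
        ref = random_quad(rng)
        shape = expand_from_centroid(ref, 1.8)
        fit = f.fit_to_reference(shape, ref, linker_length=1.8, search_permutations=False)
        assert fit.rmsd < 1e-9

    def test_zero_linker_reduces_to_plain_superposition(self):
        rng = np.random.default_rng(9)
        ref = random_quad(rng)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        fit = f.fit_to_reference(ref @ q + 5.0, ref, linker_length=0.0, search_permutations=False)
        assert fit.rmsd < 1e-9

    def test_permutation_and_rigid_motion_recovered(self):
        rng = np.random.default_rng(10)
        ref = random_quad(rng)
        perm = (2, 0, 3, 1)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        shape = expand_from_centroid(ref, 1.2)[list(perm)] @ q + rng.normal(0, 4, 3)
        fit = f.fit_to_reference(shape, ref, linker_length=1.2)
        assert fit.rmsd < 1e-9
        # applying the found permutation must invert the construction
        assert tuple(np.argsort(fit.permutation)) == tuple(np.argsort(np.argsort(perm)))

    def test_vertex_count_mismatch_is_an_error(self):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        with pytest.raises(ValueError):
            f.fit_to_reference(tri, np.zeros((4, 3)))


def _helix_observations(helix, r0, linker, bp_sets):
    obs = []
    for bps in bp_sets:
        pts = helix_dye_position(np.array(bps), helix, linker, 0.0)
        d = f.pairwise_distances(pts)
        es = [1.0 / (1.0 + (d[i, j] / r0) ** 6) for i, j in ((0, 1), (0, 2), (1, 2))]
        obs.append(f.TriangleObservation(bps, es))
    return obs


class TestHelixCalibration:
    BP_SETS = [(0, 12, 16), (0, 8, 20), (3, 10, 22), (0, 5, 28)]

    def test_generative_recovery_at_zero_noise(self):
        helix = f.HelixModel()
        obs = _helix_observations(helix, 5.4, 1.8, self.BP_SETS)
        cal = f.helix_calibrate(obs, helix=helix, initial=f.ForsterModel(5.0, 1.0))
        assert cal.forster_radius == pytest.approx(5.4, rel=0.01)
        assert cal.linker_length == pytest.approx(1.8, rel=0.01)

    def test_subangstrom_positional_residual_at_zero_noise(self):
        helix = f.HelixModel()
        obs = _helix_observations(helix, 5.4, 1.8, self.BP_SETS)
        cal = f.helix_calibrate(obs, helix=helix, initial=f.ForsterModel(5.0, 1.0))
        assert cal.mean_positional_rmsd < 0.1  # nm

    def test_forster_transform_homogeneity(self):
        """Scaling the helix geometry by c scales the fitted R0 by c when
        the linker is held at zero."""
        helix = f.HelixModel()
        obs = _helix_observations(helix, 5.4, 0.0, self.BP_SETS)
        c = 2.0
        scaled = f.HelixModel(rise_per_bp=0.34 * c, bp_per_turn=10.5, helix_radius=1.0 * c)
        cal1 = f.helix_calibrate(obs, helix=helix, initial=f.ForsterModel(5.0, 0.0), fit_linker=False)
        cal2 = f.helix_calibrate(obs, helix=scaled, initial=f.ForsterModel(5.0, 0.0), fit_linker=False)
        assert cal2.forster_radius / cal1.forster_radius == pytest.approx(c, rel=1e-6)

    def test_under_determined_fit_is_an_error(self):
        helix = f.HelixModel()
        obs = _helix_observations(helix, 5.4, 1.8, self.BP_SETS[:1])
        with pytest.raises(ValueError):
            f.helix_calibrate(obs, helix=helix)


class TestShapeIO:
    def test_pdb_round_trip_in_angstrom(self, tmp_path):
        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        path = tmp_path / "shape.pdb"
        write_shape_pdb(tri, path)
        coords = read_reference_pdb(path)  # nm
        np.testing.assert_allclose(coords, tri.coords, atol=1e-3)

    def test_csv_export(self, tmp_path):
        import pandas as pd

        tri = f.reconstruct_triangle(3.0, 4.0, 5.0)
        path = tmp_path / "shape.csv"
        f.geometry.write_shape_csv(tri, path)
        df = pd.read_csv(path)
        assert list(df.columns) == ["vertex", "x_nm", "y_nm", "z_nm", "residual_nm"]
        np.testing.assert_allclose(df[["x_nm", "y_nm", "z_nm"]].to_numpy(), tri.coords, atol=1e-6)
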