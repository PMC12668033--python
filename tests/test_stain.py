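"""Stain separation: OD transform, SNMF recovery, identity assignment."""

import itertools
import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from lewyseg.errors import (
    DegenerateInputError,
    DomainError,
    InvalidWhitePointError,
    ParameterError,
)
from lewyseg.stain import (
    alkaline_probability,
    assign_stain_identities,
    fit_stain_basis,
    od_to_rgb,
    reconstruction_error,
    rgb_to_od,
    separate_stains,
    threshold_stain,
)
from lewyseg.synthetic import DETECTABLE_FAMILIES, render_tile, sample_scene
from lewyseg.types import (
    REFERENCE_OD_VECTORS,
    ConcentrationMaps,
    OpticalDensityImage,
    RGBTile,
    StainBasis,
    StainProbabilityMap,
)


def matched_angles_deg(W):
    sim = REFERENCE_OD_VECTORS.T @ (W / np.linalg.norm(W, axis=0))
    r, c = linear_sum_assignment(-sim)
    return np.degrees(np.arccos(np.clip(sim[r, c], -1, 1)))


def tile_of(value):
    return RGBTile(np.full((16, 16, 3), float(value)))


class TestOpticalDensity:
    def test_white_background_maps_to_zero_od(self):
        od = rgb_to_od(tile_of(255), eps=0.0)
        assert np.allclose(od.od, 0.0)

    def test_tenth_transmission_gives_unit_od(self):
        od = rgb_to_od(tile_of(25.5))
        assert np.allclose(od.od, 1.0, atol=1e-5)

    def test_round_trip_within_one_intensity_level(self, rng):
        pixels = rng.uniform(1.0, 255.0, (32, 32, 3))
        tile = RGBTile(pixels)
        back = od_to_rgb(rgb_to_od(tile), 255.0)
        assert np.max(np.abs(back.pixels - pixels)) < 1.0

    def test_od_round_trip(self, rng):
        od = OpticalDensityImage(rng.uniform(0.0, 1.5, (16, 16, 3)))
        back = rgb_to_od(od_to_rgb(od, 255.0))
        assert np.allclose(back.od, od.od, atol=1e-4)

    def test_monotone_decreasing_in_intensity(self):
        lo = rgb_to_od(tile_of(50)).od
        hi = rgb_to_od(tile_of(200)).od
        assert np.all(lo > hi)

    def test_invalid_white_point_rejected(self):
        with pytest.raises(InvalidWhitePointError):
            RGBTile(np.zeros((16, 16, 3)), white_point=0.0)

    def test_negative_od_rejected(self):
        with pytest.raises(DomainError):
            od_to_rgb(OpticalDensityImage(np.full((16, 16, 3), -0.1)), 255.0)


class TestSNMF:
    def test_recovers_known_basis_within_5_degrees(self):
        spec = sample_scene(5, tile_size=256, seed=0,
                            families=DETECTABLE_FAMILIES, n_dab=3,
                            noise_sd=0.0)
        tile, _ = render_tile(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_stain_basis(rgb_to_od(tile), seed=0)
        assert np.all(matched_angles_deg(res.basis.W) <= 5.0)

    def test_reconstruction_error_below_5_percent(self):
        spec = sample_scene(5, tile_size=256, seed=1,
                            families=DETECTABLE_FAMILIES, n_dab=3)
        tile, _ = render_tile(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_stain_basis(rgb_to_od(tile), seed=1)
        err = reconstruction_error(rgb_to_od(tile), res.basis,
                                   res.concentrations)
        assert err <= 0.05

    def test_objective_non_increasing(self):
        spec = sample_scene(4, tile_size=256, seed=2,
                            families=DETECTABLE_FAMILIES, n_dab=2)
        tile, _ = render_tile(spec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_stain_basis(rgb_to_od(tile), seed=2)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs <= 1e-6 * np.abs(res.objective_trace[:-1]) + 1e-9)

    def test_deterministic_given_seed(self):
        spec = sample_scene(3, tile_size=256, seed=3,
                            families=DETECTABLE_FAMILIES, n_dab=2)
        tile, _ = render_tile(spec)
        od = rgb_to_od(tile)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fit_stain_basis(od, seed=5)
            b = fit_stain_basis(od, seed=5)
        assert np.array_equal(a.basis.W, b.basis.W)

    def test_all_white_tile_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_stain_basis(rgb_to_od(tile_of(255)))

    def test_concentration_scale_invariance(self):
        """Doubling all concentrations leaves W unchanged (within
        tolerance) and doubles H."""
        spec = sample_scene(4, tile_size=256, seed=4,
                            families=DETECTABLE_FAMILIES, n_dab=2,
                            noise_sd=0.0)
        tile, gt = render_tile(spec)
        od1 = rgb_to_od(tile)
        od2 = OpticalDensityImage(od1.od * 2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            r1 = fit_stain_basis(od1, seed=0)
            r2 = fit_stain_basis(od2, seed=0)
        b1, p1 = assign_stain_identities(r1.basis)
        b2, p2 = assign_stain_identities(r2.basis)
        cos = np.abs((b1.W * b2.W).sum(axis=0))
        assert np.all(np.degrees(np.arccos(np.clip(cos, -1, 1))) < 3.0)
        h1 = r1.concentrations.H[p1].sum()
        h2 = r2.concentrations.H[p2].sum()
        assert h2 / h1 == pytest.approx(2.0, rel=0.05)


class TestIdentityAssignment:
    def test_reference_order_is_identity(self):
        basis = StainBasis(REFERENCE_OD_VECTORS.copy())
        out, perm = assign_stain_identities(basis)
        assert np.array_equal(perm, [0, 1, 2])
        assert np.array_equal(out.W, basis.W)

    @pytest.mark.parametrize("perm", list(itertools.permutations(range(3))))
    def test_all_column_orderings_recovered(self, perm):
        shuffled = StainBasis(REFERENCE_OD_VECTORS[:, list(perm)])
        out, recovered = assign_stain_identities(shuffled)
        assert np.allclose(out.W, REFERENCE_OD_VECTORS)
        # brute-force check: recovered permutation inverts the applied one
        assert [perm[i] for i in recovered] == [0, 1, 2] or np.allclose(
            shuffled.W[:, recovered], REFERENCE_OD_VECTORS
        )

    def test_ambiguous_assignment_warns(self):
        W = np.stack([REFERENCE_OD_VECTORS[:, 0]] * 3, axis=1)
        with pytest.warns(RuntimeWarning, match="ambiguous"):
            assign_stain_identities(StainBasis(W + 1e-6))


class TestAlkalineProbability:
    def test_all_zero_row_maps_to_zero(self):
        concs = ConcentrationMaps(np.zeros((3, 64)))
        out = alkaline_probability(concs, (8, 8))
        assert out.normalizer == 0.0
        assert np.all(out.H_alkaline == 0.0)

    def test_max_normalization_at_percentile_100(self):
        h = np.zeros((3, 3))
        h[1] = [0.0, 1.0, 2.0]
        out = alkaline_probability(ConcentrationMaps(h), (1, 3),
                                   norm_percentile=100)
        assert np.allclose(out.H_alkaline, [[0.0, 0.5, 1.0]])

    def test_values_never_exceed_one(self, rng):
        h = np.zeros((3, 100))
        h[1] = rng.exponential(1.0, 100)
        out = alkaline_probability(ConcentrationMaps(h), (10, 10))
        assert out.H_alkaline.max() <= 1.0
        assert out.H_alkaline.min() >= 0.0


class TestThresholdStain:
    def test_strict_threshold_at_half(self):
        prob = StainProbabilityMap(
            np.array([[0.6, 0.4], [0.5, 0.0]]), normalizer=1.0
        )
        mask = threshold_stain(prob, 0.5)
        assert mask.mask.tolist() == [[True, False], [False, False]]
        assert mask.provenance == "stain"

    def test_idempotent_under_rethresholding(self, rng):
        prob = StainProbabilityMap(rng.random((16, 16)), normalizer=1.0)
        m1 = threshold_stain(prob)
        m2 = threshold_stain(
            StainProbabilityMap(m1.mask.astype(float), normalizer=1.0)
        )
        assert np.array_equal(m1.mask, m2.mask)

    def test_out_of_range_threshold_rejected(self):
        prob = StainProbabilityMap(np.zeros((4, 4)), normalizer=1.0)
        with pytest.raises(ParameterError):
            threshold_stain(prob, 1.5)


def test_separate_stains_with_reference_basis_skips_fitting(small_scene):
    tile, _ = small_scene
    basis, concs, prob = separate_stains(
        tile, reference_basis=StainBasis(REFERENCE_OD_VECTORS.copy())
    )
    assert np.array_equal(basis.W, REFERENCE_OD_VECTORS)
    assert prob.H_alkaline.shape == tile.shape
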