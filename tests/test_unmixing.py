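"""NNLS unmixing, global scaling, dominant maps, Z-scores, display images."""

import numpy as np
import pytest

from edxmix import (
    AbundanceStack,
    EnergyAxis,
    HyperspectralCube,
    abundance_to_images,
    dominant_map,
    endmember_zscores,
    finalize_scale,
    nnls_unmix,
)
from edxmix.embedding import EndmemberSet
from edxmix.unmixing import BACKGROUND_LABEL


def _ems(spectra, labels=None):
    spectra = np.asarray(spectra, dtype=float)
    labels = labels or [f"e{i}" for i in range(spectra.shape[0])]
    return EndmemberSet(spectra=spectra, labels=labels, provenance=["test"] * spectra.shape[0])


def _cube_from(pixels):
    pixels = np.asarray(pixels, dtype=float)  # (n, C) -> 1 x n x C cube
    axis = EnergyAxis(0.0, 10.0, pixels.shape[1])
    return HyperspectralCube(counts=pixels[None], energy=axis, pixel_size_nm=1.0)


E1 = np.array([1.0, 0.0, 2.0, 0.0, 1.0])
E2 = np.array([0.0, 3.0, 1.0, 1.0, 0.0])


class TestNNLS:
    def test_pure_pixel_recovers_unit_coefficient(self):
        stack = nnls_unmix(_cube_from([E1]), _ems([E1, E2]))
        assert np.allclose(stack.coeffs[0, 0], [1.0, 0.0], atol=1e-10)

    def test_noiseless_mixture_exact(self):
        mix = 0.3 * E1 + 0.7 * E2
        stack = nnls_unmix(_cube_from([mix]), _ems([E1, E2]))
        assert np.allclose(stack.coeffs[0, 0], [0.3, 0.7], atol=1e-10)

    def test_matches_dense_grid_search(self, rng):
        # oracle: exhaustive search over a in [0, 2]^2 at 1e-3 resolution
        e = np.stack([E1, E2]).T  # (5, 2)
        grid = np.arange(0.0, 2.0 + 1e-9, 1e-3)
        for trial in range(5):
            s = rng.random(5) * 2
            stack = nnls_unmix(_cube_from([s]), _ems([E1, E2]))
            a_hat = stack.coeffs[0, 0]
            # separable scan: residual is quadratic; evaluate on the grid
            best, best_val = None, np.inf
            # coarse-to-exact: evaluate residual norm on the full 2D grid in
            # a vectorised sweep (2001^2 points)
            A, B = np.meshgrid(grid, grid, indexing="ij")
            res = (
                np.einsum("c,ij->cij", e[:, 0], A)
                + np.einsum("c,ij->cij", e[:, 1], B)
                - s[:, None, None]
            )
            val = np.einsum("cij,cij->ij", res, res)
            idx = np.unravel_index(np.argmin(val), val.shape)
            best = np.array([grid[idx[0]], grid[idx[1]]])
            assert np.all(np.abs(a_hat - best) <= 1.5e-3)

    def test_channel_mismatch_rejected(self):
        with pytest.raises(ValueError, match="channels"):
            nnls_unmix(_cube_from([np.ones(4)]), _ems([E1, E2]))

    def test_rank_deficiency_warns(self):
        with pytest.warns(UserWarning, match="rank"):
            nnls_unmix(_cube_from([E1]), _ems([E1, 2 * E1]))

    def test_random_probes_never_beat_nnls(self, rng):
        e = np.stack([E1, E2]).T
        s = rng.random(5) * 3
        stack = nnls_unmix(_cube_from([s]), _ems([E1, E2]))
        a_hat = stack.coeffs[0, 0]
        best = np.linalg.norm(e @ a_hat - s)
        for _ in range(200):
            probe = rng.random(2) * 3
            assert np.linalg.norm(e @ probe - s) >= best - 1e-9

    def test_nonnegative_always(self, rng):
        cube = _cube_from(rng.random((40, 5)))
        stack = nnls_unmix(cube, _ems([E1, E2]))
        assert stack.coeffs.min() >= 0

    @pytest.mark.filterwarnings("ignore:endmember matrix is rank deficient")
    def test_parameter_recovery_on_poisson_phantom(self, phantom_small):
        # the default scene reuses one granule spectrum for two structures,
        # so the matrix is (expectedly) rank deficient; total abundance error
        # must still stay small
        spec, cube, gt = phantom_small
        ems = _ems(gt.spectra, labels=list(gt.class_labels))
        per_frame = cube.with_counts(cube.counts.astype(float) / spec.n_frames)
        stack = nnls_unmix(per_frame, ems)
        mae = np.abs(stack.coeffs - gt.abundances).mean()
        assert mae < 0.05


class TestScaling:
    def test_single_tile_scale(self):
        stack = AbundanceStack(
            coeffs=np.array([[[4.0, 1.0]]]), endmembers=_ems([E1, E2])
        )
        finalize_scale([stack])
        assert stack.global_scale == 4.0
        assert stack.scaled().max() == 1.0

    def test_two_tiles_share_max(self):
        ems = _ems([E1, E2])
        s1 = AbundanceStack(coeffs=np.full((2, 2, 2), 2.0), endmembers=ems)
        s2 = AbundanceStack(coeffs=np.full((2, 2, 2), 8.0), endmembers=ems)
        finalize_scale([s1, s2])
        assert s1.global_scale == s2.global_scale == 8.0
        assert s1.scaled().max() == 0.25

    def test_scaled_mosaic_max_is_exactly_one(self, rng):
        ems = _ems([E1, E2])
        stacks = [
            AbundanceStack(coeffs=rng.random((3, 3, 2)) * s, endmembers=ems)
            for s in (1.0, 5.0)
        ]
        finalize_scale(stacks)
        assert max(s.scaled().max() for s in stacks) == 1.0

    def test_scale_invariance_of_display(self, rng):
        # multiplying spectra and endmembers by gamma leaves scaled maps alone
        pixels = rng.random((10, 5)) * 4
        gamma = 7.3
        s1 = nnls_unmix(_cube_from(pixels), _ems([E1, E2]))
        s2 = nnls_unmix(_cube_from(pixels * gamma), _ems([E1 * gamma, E2 * gamma]))
        finalize_scale([s1])
        finalize_scale([s2])
        assert np.allclose(s1.scaled(), s2.scaled(), atol=1e-9)
        d1, d2 = dominant_map(s1), dominant_map(s2)
        assert np.array_equal(d1.labels, d2.labels)


class TestDominantMap:
    def _stack(self, coeffs):
        c = np.asarray(coeffs, dtype=float)
        stack = AbundanceStack(coeffs=c, endmembers=_ems(np.eye(c.shape[2])))
        finalize_scale([stack])
        return stack

    def test_argmax_and_intensity(self):
        stack = self._stack([[[0.0, 0.5, 0.2]]])
        dom = dominant_map(stack)
        assert dom.labels[0, 0] == 1
        assert dom.intensity[0, 0] == pytest.approx(0.5 / stack.global_scale)

    def test_all_zero_pixel_gets_background(self):
        stack = self._stack([[[0.0, 0.0], [1.0, 0.0]]])
        dom = dominant_map(stack)
        assert dom.labels[0, 0] == BACKGROUND_LABEL
        assert dom.intensity[0, 0] == 0.0

    def test_tie_goes_to_lowest_index(self):
        stack = self._stack([[[0.4, 0.4, 0.1]]])
        assert dominant_map(stack).labels[0, 0] == 0

    def test_noiseless_phantom_label_map_matches_truth(self):
        # three spectrally distinct classes -> exact label recovery
        from edxmix import (
            Geometry,
            PhantomSpec,
            Structure,
            render_phantom,
        )
        from edxmix.synthetic import _CHROMATIN, _INSULIN, _BACKGROUND, default_energy_axis

        spec = PhantomSpec(
            shape=(32, 32),
            structures=(
                Structure("a", Geometry("disk", {"center": (8, 8), "radius": 5}), _INSULIN, 1.0),
                Structure("b", Geometry("disk", {"center": (22, 22), "radius": 6}), _CHROMATIN, 1.0),
            ),
            background=_BACKGROUND,
            energy=default_energy_axis(),
            counts_per_pixel_per_frame=100.0,
            n_frames=4,
        )
        cube, gt = render_phantom(spec, noiseless=True)
        stack = nnls_unmix(
            cube.with_counts(cube.counts / spec.n_frames),
            _ems(gt.spectra, list(gt.class_labels)),
        )
        finalize_scale([stack])
        dom = dominant_map(stack)
        assert np.array_equal(dom.labels, gt.labels)


class TestZScores:
    def test_identical_spectra_all_zero(self):
        z = endmember_zscores(_ems([E1, E1]))
        assert np.all(z == 0)

    def test_two_values_population_std(self):
        z = endmember_zscores(_ems([[0.0], [2.0]]))
        assert np.allclose(z, [[-1.0], [1.0]])

    def test_columns_standardised(self, rng):
        ems = _ems(rng.random((4, 6)) * 5)
        z = endmember_zscores(ems)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        live = ems.spectra.std(axis=0) > 0
        assert np.allclose(z[:, live].std(axis=0), 1.0)

    def test_single_endmember_rejected(self):
        with pytest.raises(ValueError, match="2"):
            endmember_zscores(_ems([E1]))


class TestAbundanceImages:
    def _finalized(self, coeffs):
        stack = AbundanceStack(
            coeffs=np.asarray(coeffs, float), endmembers=_ems(np.eye(np.shape(coeffs)[2]))
        )
        finalize_scale([stack])
        return stack

    def test_uniform_single_endmember_solid_color(self):
        stack = self._finalized(np.ones((3, 3, 1)))
        colors = np.array([[0.2, 0.4, 0.6]])
        _, comp = abundance_to_images(stack, colors=colors)
        assert np.allclose(comp, np.broadcast_to(colors[0], (3, 3, 3)))

    def test_inversion_maps_low_to_white(self):
        stack = self._finalized([[[0.0], [1.0]]])
        grays, _ = abundance_to_images(stack, invert=True)
        assert grays[0][0, 0] == 1.0  # zero abundance -> white
        assert grays[0][0, 1] == 0.0  # max abundance -> black

    def test_composite_uses_argmax_color(self):
        stack = self._finalized([[[1.0, 0.2]]])
        colors = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        _, comp = abundance_to_images(stack, colors=colors)
        assert comp[0, 0, 0] > 0 and comp[0, 0, 1] == 0
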