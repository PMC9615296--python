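"""Dual regression: agreement with a normal-equations oracle, exact
recovery on noise-free data, smoothing behaviour, difference maps, and
control-referenced z-scoring."""

import numpy as np
import pytest

from remicoh import (
    NetworkTemplateSet,
    ScanSession,
    SingularDesignError,
    ValidationError,
    difference_maps,
    dual_regress,
    simulate_subject,
    smooth_pe_maps,
    spatial_regression,
    temporal_regression,
    zscore_vs_controls,
)
from remicoh.types import DifferenceMapSet, PEMapSet


def normal_equations(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Independent least-squares oracle: solve X'X b = X'Y directly."""
    return np.linalg.solve(X.T @ X, X.T @ Y)


def random_templates(rng, K=3, V=40) -> NetworkTemplateSet:
    maps = rng.standard_normal((K, V))
    return NetworkTemplateSet(
        names=[f"N{k}" for k in range(K)], maps=maps, grid_shape=(V,)
    )


class TestSpatialRegression:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            t = random_templates(rng)
            scan = ScanSession("s", "control", "pre",
                               rng.standard_normal((40, 12)))
            got = spatial_regression(t, scan, demean=False,
                                     variance_normalize=False)
            X = np.column_stack([t.maps.T, np.ones(40)])
            want = normal_equations(X, scan.data)[:-1]
            np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-10)

    def test_zero_scan_gives_zero_courses(self, templates_k4):
        scan = ScanSession("s", "control", "pre",
                           np.zeros((templates_k4.n_voxels, 10)))
        courses = spatial_regression(templates_k4, scan,
                                     variance_normalize=False)
        np.testing.assert_allclose(courses, 0, atol=1e-12)

    def test_noise_free_courses_recovered(self, templates_k4):
        s = simulate_subject(templates_k4, np.full(4, 2.0), T=30,
                             noise_sd=0.0, seed=4)
        courses = spatial_regression(templates_k4, s,
                                     variance_normalize=True)
        # up to the variance-normalization scale the true courses return
        for k in range(4):
            c = np.corrcoef(courses[k], s.latent_courses[k])[0, 1]
            assert c > 0.999999

    def test_collinear_templates_named_in_error(self, rng):
        maps = rng.standard_normal((3, 50))
        maps[2] = maps[0] + maps[1]
        t = NetworkTemplateSet(names=["A", "B", "C"], maps=maps,
                               grid_shape=(50,))
        scan = ScanSession("s", "control", "pre",
                           rng.standard_normal((50, 8)))
        with pytest.raises(SingularDesignError, match="collinear"):
            spatial_regression(t, scan)

    def test_voxel_count_mismatch(self, templates_k4, rng):
        scan = ScanSession("s", "control", "pre",
                           rng.standard_normal((10, 8)))
        with pytest.raises(ValidationError, match="voxels"):
            spatial_regression(templates_k4, scan)


class TestTemporalRegression:
    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(50):
            C = rng.standard_normal((3, 15))
            scan = ScanSession("s", "control", "pre",
                               rng.standard_normal((25, 15)))
            got = temporal_regression(C, scan).pe
            X = np.column_stack([C.T, np.ones(15)])
            want = normal_equations(X, scan.data.T)[:-1]
            np.testing.assert_allclose(got, want, rtol=1e-8, atol=1e-10)

    def test_constant_voxel_gives_zero_pe(self, rng):
        C = rng.standard_normal((2, 20))
        data = np.ones((5, 20)) * 3.7
        pe = temporal_regression(C, ScanSession("s", "control", "pre",
                                                data)).pe
        np.testing.assert_allclose(pe, 0, atol=1e-10)

    def test_full_dual_regression_recovers_loadings(self, templates_k4):
        loadings = np.array([0.5, 1.0, 1.5, 2.0])
        s = simulate_subject(templates_k4, loadings, T=40, noise_sd=0.0,
                             seed=8)
        pe = dual_regress(templates_k4, s).pe
        for k in range(4):
            target = loadings[k] * templates_k4.maps[k]
            c = np.corrcoef(pe[k], target)[0, 1]
            assert c > 0.999


class TestSmoothing:
    def test_fwhm_zero_is_identity(self, rng):
        pe = PEMapSet("s", "pre", rng.standard_normal((2, 100)))
        out = smooth_pe_maps(pe, 0.0, (10, 10))
        np.testing.assert_array_equal(out.pe, pe.pe)

    def test_impulse_becomes_gaussian_profile(self):
        imp = np.zeros((1, 21 * 21))
        imp[0, 10 * 21 + 10] = 1.0
        fwhm = 4.0
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        out = smooth_pe_maps(PEMapSet("s", "pre", imp), fwhm,
                             (21, 21)).pe.reshape(21, 21)
        xx, yy = np.meshgrid(np.arange(21), np.arange(21), indexing="ij")
        d2 = (xx - 10) ** 2 + (yy - 10) ** 2
        closed = np.exp(-d2 / (2 * sigma**2))
        sel = d2 <= (3 * sigma) ** 2
        np.testing.assert_allclose((out / out.max())[sel], closed[sel],
                                   atol=1e-6)

    def test_constant_map_unchanged(self):
        pe = PEMapSet("s", "pre", np.full((1, 64), 2.5))
        out = smooth_pe_maps(pe, 6.0, (8, 8))
        np.testing.assert_allclose(out.pe, 2.5, atol=1e-10)

    def test_spatial_mean_conserved(self, rng):
        pe = PEMapSet("s", "pre", rng.standard_normal((3, 12 * 12)))
        out = smooth_pe_maps(pe, 5.0, (12, 12, 1))
        np.testing.assert_allclose(out.pe.mean(1), pe.pe.mean(1),
                                   atol=1e-8)

    def test_unknown_voxel_size_rejected(self, rng):
        pe = PEMapSet("s", "pre", rng.standard_normal((1, 100)))
        with pytest.raises(ValidationError, match="voxel size"):
            smooth_pe_maps(pe, 5.0, (10, 10), voxel_size=0)


class TestDifferenceMaps:
    def test_identical_sessions_zero_diff(self, rng):
        pe = rng.standard_normal((2, 30))
        d = difference_maps(PEMapSet("s", "post", pe),
                            PEMapSet("s", "pre", pe), group="patient")
        np.testing.assert_array_equal(d.diff, 0)

    def test_antisymmetric_under_swap(self, rng):
        a = PEMapSet("s", "post", rng.standard_normal((2, 30)))
        b = PEMapSet("s", "pre", rng.standard_normal((2, 30)))
        d1 = difference_maps(a, b, group="patient").diff
        d2 = difference_maps(b, a, group="patient").diff
        np.testing.assert_allclose(d1, -d2)

    def test_subject_mismatch_raises(self, rng):
        with pytest.raises(ValidationError, match="different subjects"):
            difference_maps(
                PEMapSet("s1", "post", rng.standard_normal((2, 30))),
                PEMapSet("s2", "pre", rng.standard_normal((2, 30))),
                group="patient",
            )


class TestZScoreVsControls:
    @staticmethod
    def _diffs(arrays, group="control"):
        return [
            DifferenceMapSet(f"c{i}", group, a)
            for i, a in enumerate(arrays)
        ]

    def test_patient_equal_to_control_mean_is_zero(self, rng):
        ctrl = [rng.standard_normal((2, 10)) for _ in range(5)]
        mean = np.mean(ctrl, axis=0)
        z = zscore_vs_controls(
            DifferenceMapSet("p", "patient", mean), self._diffs(ctrl)
        )
        np.testing.assert_allclose(z.z, 0, atol=1e-10)

    def test_unit_z_arithmetic(self):
        # controls {0, 1, 2} per voxel: mean 1, sd 1; patient at 2 -> z = 1
        ctrl = [np.full((1, 4), v) for v in (0.0, 1.0, 2.0)]
        z = zscore_vs_controls(
            DifferenceMapSet("p", "patient", np.full((1, 4), 2.0)),
            self._diffs(ctrl),
        )
        np.testing.assert_allclose(z.z, 1.0)

    def test_invariant_to_common_constant_map(self, rng):
        ctrl = [rng.standard_normal((2, 12)) for _ in range(6)]
        pat = rng.standard_normal((2, 12))
        shift = rng.standard_normal((2, 12))
        z1 = zscore_vs_controls(
            DifferenceMapSet("p", "patient", pat), self._diffs(ctrl)
        ).z
        z2 = zscore_vs_controls(
            DifferenceMapSet("p", "patient", pat + shift),
            self._diffs([c + shift for c in ctrl]),
        ).z
        np.testing.assert_allclose(z1, z2, atol=1e-8)

    def test_zero_sd_voxels_masked(self, rng):
        ctrl = [rng.standard_normal((1, 5)) for _ in range(4)]
        for c in ctrl:
            c[0, 2] = 7.0  # identical across controls -> sd 0
        z = zscore_vs_controls(
            DifferenceMapSet("p", "patient", rng.standard_normal((1, 5))),
            self._diffs(ctrl),
        )
        assert not z.mask[0, 2] and np.isnan(z.z[0, 2])
        assert z.mask[0, [0, 1, 3, 4]].all()

    def test_fewer_than_three_controls_rejected(self, rng):
        ctrl = [rng.standard_normal((1, 5)) for _ in range(2)]
        with pytest.raises(ValidationError, match=">= 3"):
            zscore_vs_controls(
                DifferenceMapSet("p", "patient",
                                 rng.standard_normal((1, 5))),
                self._diffs(ctrl),
            )

    def test_pseudo_patient_z_is_standardized(self, templates_k4):
        # a pseudo-patient drawn from the control distribution should have
        # voxelwise z with mean ~0 and sd ~1
        rng = np.random.default_rng(3)
        draws = [rng.standard_normal((4, 300)) for _ in range(60)]
        z = zscore_vs_controls(
            DifferenceMapSet("p", "patient", draws[0]),
            self._diffs(draws[1:]),
        ).z
        assert abs(np.nanmean(z)) < 0.05
        assert abs(np.nanstd(z) - 1.0) < 0.05
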