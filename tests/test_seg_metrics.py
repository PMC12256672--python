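"""DSC / HD95 / MSD and the dosimetric comparison of segmentations."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_mask, random_mask
from rtcohort import dosimetry, geometry, phantom, seg_metrics
from rtcohort.rt_model import DoseGrid, ValidationError


def cube_mask(shape, lo, hi, **kw):
    vox = np.zeros(shape, bool)
    vox[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = True
    return make_mask(vox, **kw)


def brute_force_pooled(mask_a, mask_b):
    """Independent oracle: exhaustive pairwise surface distances."""
    pa = mask_a.grid.voxel_centers(geometry.surface_voxels(mask_a.voxels))
    pb = mask_b.grid.voxel_centers(geometry.surface_voxels(mask_b.voxels))
    d_ab = [min(np.sqrt(((p - q) ** 2).sum()) for q in pb) for p in pa]
    d_ba = [min(np.sqrt(((p - q) ** 2).sum()) for q in pa) for p in pb]
    return np.array(d_ab + d_ba)


class TestDSC:
    def test_identical_masks(self):
        m = cube_mask((12, 12, 12), (2, 2, 2), (8, 8, 8))
        assert seg_metrics.dsc(m, m) == 1.0

    def test_disjoint_masks(self):
        a = cube_mask((12, 12, 12), (0, 0, 0), (3, 3, 3))
        b = cube_mask((12, 12, 12), (6, 6, 6), (9, 9, 9))
        assert seg_metrics.dsc(a, b) == 0.0

    def test_offset_cubes_half_overlap(self):
        # two 10^3 cubes offset by 5 voxels on one axis: 2*500/2000 = 0.5
        a = cube_mask((20, 12, 12), (0, 1, 1), (10, 11, 11))
        b = cube_mask((20, 12, 12), (5, 1, 1), (15, 11, 11))
        assert seg_metrics.dsc(a, b) == 0.5

    def test_both_empty_is_one(self):
        e = make_mask(np.zeros((4, 4, 4), bool))
        assert seg_metrics.dsc(e, e) == 1.0

    def test_grid_mismatch_rejected(self):
        a = cube_mask((6, 6, 6), (1, 1, 1), (3, 3, 3))
        b = cube_mask((6, 6, 6), (1, 1, 1), (3, 3, 3), origin=(5.0, 0.0, 0.0))
        with pytest.raises(ValidationError):
            seg_metrics.dsc(a, b)


class TestSurfaceDistanceMetrics:
    def test_identical_masks_zero(self):
        m = cube_mask((10, 10, 10), (2, 2, 2), (7, 7, 7))
        assert seg_metrics.hd95(m, m) == 0.0
        assert seg_metrics.msd(m, m) == 0.0

    def test_single_voxels_distance_apart(self):
        a = cube_mask((3, 3, 14), (1, 1, 1), (2, 2, 2))
        b = cube_mask((3, 3, 14), (1, 1, 11), (2, 2, 12))
        # pooled distance set is {10, 10}
        assert seg_metrics.hd95(a, b) == pytest.approx(10.0)
        assert seg_metrics.msd(a, b) == pytest.approx(10.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(21)
        a = random_mask(rng, shape=(7, 7, 7), p=0.25, spacing=(2.0, 1.0, 1.5))
        b = random_mask(rng, shape=(7, 7, 7), p=0.25, spacing=(2.0, 1.0, 1.5))
        pooled = brute_force_pooled(a, b)
        assert seg_metrics.msd(a, b) == pytest.approx(pooled.mean(), abs=1e-12)
        assert seg_metrics.hd95(a, b) == pytest.approx(np.percentile(pooled, 95), abs=1e-12)

    def test_dilated_cube_percentile_oracle(self):
        base = cube_mask((16, 16, 16), (5, 5, 5), (11, 11, 11))
        grown = cube_mask((16, 16, 16), (3, 3, 3), (13, 13, 13))
        pooled = brute_force_pooled(base, grown)
        assert seg_metrics.hd95(base, grown) == pytest.approx(np.percentile(pooled, 95))
        assert seg_metrics.msd(base, grown) == pytest.approx(pooled.mean())


@given(st.integers(0, 2**31 - 1))
def test_metrics_are_symmetric(seed):
    """Pooled definitions make dsc, hd95 and msd symmetric in A and B."""
    rng = np.random.default_rng(seed)
    a = random_mask(rng, shape=(6, 6, 6), p=0.3)
    b = random_mask(rng, shape=(6, 6, 6), p=0.3)
    if a.n_voxels == 0 or b.n_voxels == 0:
        return
    assert seg_metrics.dsc(a, b) == seg_metrics.dsc(b, a)
    assert seg_metrics.hd95(a, b) == seg_metrics.hd95(b, a)
    assert seg_metrics.msd(a, b) == seg_metrics.msd(b, a)


class TestCompare:
    def test_identical_structures_agree_perfectly(self, default_case):
        heart = default_case.structure_set.find("Heart")
        comp = seg_metrics.compare(
            heart, heart, default_case.ct.grid, default_case.dose, pd=66.0
        )
        assert comp.dsc == 1.0
        assert comp.hd95 == 0.0 and comp.msd == 0.0
        assert comp.dvol_cm3 == 0.0
        assert comp.ddmean_pct_pd == 0.0 and comp.dd2_pct_pd == 0.0

    def test_translation_in_uniform_dose(self, default_case):
        heart = default_case.structure_set.find("Heart")
        shifted = phantom.perturb_structure(heart, "translate", 3.0)
        comp = seg_metrics.compare(
            shifted, heart, default_case.ct.grid, default_case.dose, pd=66.0
        )
        assert comp.dsc < 1.0
        # msd of a 3 mm shift recovered within a voxel (2.5 mm)
        assert comp.msd == pytest.approx(3.0, abs=2.5)
        # uniform dose field forces zero dose difference
        assert comp.ddmean_pct_pd == pytest.approx(0.0, abs=1e-9)

    def test_shift_along_gradient_gives_predicted_dose_difference(self, gradient_case):
        """Shift s along a gradient g: Delta D_Mean ~ g*s/PD*100."""
        heart = gradient_case.structure_set.find("Heart")
        shifted = phantom.perturb_structure(heart, "translate", 6.0, direction=(1.0, 0.0))
        comp = seg_metrics.compare(
            shifted, heart, gradient_case.ct.grid, gradient_case.dose, pd=66.0
        )
        expected = 0.1 * 6.0 / 66.0 * 100.0  # ~0.91 % of PD
        assert comp.ddmean_pct_pd == pytest.approx(expected, rel=0.15)

    def test_degenerate_comparison_flagged(self):
        from rtcohort.rt_model import Grid3D, Structure

        grid = Grid3D(origin=(0, 0, 0), spacing=(1, 1, 1), shape=(4, 4, 4))
        empty = Structure("nothing", [])
        comp = seg_metrics.compare(empty, empty, grid, None, pd=60.0)
        assert comp.degenerate and comp.dsc == 1.0


class TestSummarize:
    def test_constant_differences(self):
        comps = [seg_metrics.SegComparison(0.9, 1, 1, 0.5, 2.0, 1.0) for _ in range(5)]
        out = seg_metrics.summarize(comps)
        assert out["ddmean_pct_pd"].mu == 2.0 and out["ddmean_pct_pd"].sigma == 0.0

    def test_plus_minus_one(self):
        comps = [
            seg_metrics.SegComparison(1, 0, 0, 0, -1.0, 0),
            seg_metrics.SegComparison(1, 0, 0, 0, +1.0, 0),
        ]
        out = seg_metrics.summarize(comps)
        assert out["ddmean_pct_pd"].mu == 0.0
        assert out["ddmean_pct_pd"].sigma == pytest.approx(np.sqrt(2.0))

    def test_matches_direct_sample_statistics(self):
        rng = np.random.default_rng(2)
        diffs = rng.normal(0.5, 2.0, 20)
        comps = [seg_metrics.SegComparison(1, 0, 0, 0, d, 0) for d in diffs]
        out = seg_metrics.summarize(comps)
        assert out["ddmean_pct_pd"].mu == pytest.approx(diffs.mean())
        assert out["ddmean_pct_pd"].sigma == pytest.approx(diffs.std(ddof=1))

    def test_needs_two(self):
        with pytest.raises(ValidationError):
            seg_metrics.summarize([seg_metrics.SegComparison(1, 0, 0, 0, 0, 0)])
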