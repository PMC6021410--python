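"""3-D bone morphometry: VOI, plate split, BV/TV, thickness, SMI."""

import numpy as np
import pytest

from osteospec.morphometry import (
    BoneVolume,
    bvtv,
    extract_voi,
    local_thickness,
    morphometry_report,
    smi,
    split_plate_trabecular,
)
from osteospec.synthetic import CohortConfig, draw_morphometry, synthesize_volume


def slab_volume(thickness_vox=24, shape=(60, 50, 50), z0=18, voxel_um=12.5):
    v = np.zeros(shape, bool)
    v[z0 : z0 + thickness_vox] = True
    return BoneVolume(v, voxel_um)


def cylinder_volume(radius=12, length=100, side=51, voxel_um=12.5, z_margin=0):
    yy, xx = np.mgrid[0:side, 0:side]
    c = side // 2  # integer centre: voxelised disc radius is unbiased
    disc = (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    v = np.zeros((length + 2 * z_margin, side, side), bool)
    v[z_margin : z_margin + length] = disc
    return BoneVolume(v, voxel_um)


def sphere_volume(radius=18, pad=6, voxel_um=12.5):
    n = 2 * (radius + pad)
    zz, yy, xx = np.mgrid[0:n, 0:n, 0:n]
    c = n / 2 - 0.5
    v = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2
    return BoneVolume(v, voxel_um)


def all_trabecular(vol: BoneVolume) -> BoneVolume:
    labels = np.where(vol.voxels, 2, 0).astype(np.uint8)
    return BoneVolume(vol.voxels, vol.voxel_um, labels=labels)


class TestExtractVoi:
    def test_voxel_count_arithmetic(self):
        vol = BoneVolume(np.ones((160, 100, 100), bool), 12.5)
        voi = extract_voi(vol, (1.8, 1.0, 1.1))
        assert voi.voxels.shape == (144, 80, 88)

    def test_full_extents_identity(self):
        v = np.zeros((40, 40, 40), bool)
        v[5:30] = True
        vol = BoneVolume(v, 25.0)
        voi = extract_voi(vol, (1.0, 1.0, 1.0), anchor="top")
        np.testing.assert_array_equal(voi.voxels, v)

    def test_oversized_extents_rejected(self):
        vol = BoneVolume(np.ones((40, 40, 40), bool), 25.0)
        with pytest.raises(ValueError, match="exceeds"):
            extract_voi(vol, (2.0, 1.0, 1.0))

    def test_anchor_at_first_bone_slice(self):
        v = np.zeros((100, 50, 50), bool)
        v[37:90] = True
        vol = BoneVolume(v, 25.0)
        voi = extract_voi(vol, (1.0, 1.0, 1.0))  # 40 voxels deep
        # first VOI slice is the first slice containing bone
        assert voi.voxels[0].any()
        assert voi.voxels.shape[0] == 40
        np.testing.assert_array_equal(voi.voxels[0], v[37, 5:45, 5:45])


class TestPlateSplit:
    def test_phantom_boundary_matches_truth_everywhere(self):
        cfg = CohortConfig(seed=5)
        truth = draw_morphometry(cfg, np.random.default_rng(5))
        row = truth.iloc[0]
        vol = synthesize_volume(row, 25.0, np.random.default_rng(1), cfg)
        split = split_plate_trabecular(vol)
        err = np.abs(split.endocortical_boundary - vol.truth_boundary)
        assert err.max() <= 1

    def test_small_pore_kept_in_plate(self):
        # several tiny reference pores and one half-their-size pore
        v = np.ones((40, 60, 60), bool)
        v[28:] = False  # plate 0..27, marrow below
        zz, yy, xx = np.mgrid[0:40, 0:60, 0:60]
        for cy in (10, 25, 40):  # reference pores radius 2
            v[(zz - 10) ** 2 + (yy - cy) ** 2 + (xx - 15) ** 2 <= 4] = False
        v[(zz - 10) ** 2 + (yy - 50) ** 2 + (xx - 45) ** 2 <= 1] = False  # small pore
        split = split_plate_trabecular(BoneVolume(v, 12.5))
        table = split.pore_table
        assert len(table) == 4
        smallest = table.loc[table["size_vox"].idxmin()]
        assert bool(smallest["in_plate"])

    def test_large_pore_near_boundary_excluded(self):
        v = np.ones((60, 60, 60), bool)
        v[30:] = False
        zz, yy, xx = np.mgrid[0:60, 0:60, 0:60]
        # small reference pores (radius 1) high in the plate
        for cy in (10, 20, 30, 40, 50):
            v[(zz - 6) ** 2 + (yy - cy) ** 2 + (xx - 10) ** 2 <= 1] = False
        # big pore (radius 5 -> hundreds of voxels) right above the boundary
        v[(zz - 23) ** 2 + (yy - 30) ** 2 + (xx - 40) ** 2 <= 25] = False
        split = split_plate_trabecular(BoneVolume(v, 12.5))
        table = split.pore_table
        big = table.loc[table["size_vox"].idxmax()]
        assert big["size_vox"] > 2 * table["size_vox"].mean() * 0.9
        assert not bool(big["in_plate"])

    def test_no_bone_at_top_rejected(self):
        v = np.zeros((40, 30, 30), bool)
        v[30:] = True
        with pytest.raises(ValueError, match="plate"):
            split_plate_trabecular(BoneVolume(v, 12.5))

    def test_pore_rule_threshold_sensitivity(self):
        """Jittering the pore-rule factor by +-10 % barely moves Sb.Th."""
        cfg = CohortConfig(seed=11)
        truth = draw_morphometry(cfg, np.random.default_rng(11))
        vol = synthesize_volume(truth.iloc[2], 25.0, np.random.default_rng(2), cfg)
        vals = []
        for factor in (1.8, 2.0, 2.2):
            split = split_plate_trabecular(vol, pore_rule_factor=factor)
            sb, _ = local_thickness(split, "plate")
            vals.append(sb)
        assert (max(vals) - min(vals)) / np.mean(vals) < 0.05


class TestBvtv:
    def test_fully_solid(self):
        vol = all_trabecular(BoneVolume(np.ones((20, 20, 20), bool), 12.5))
        assert bvtv(vol, "trabecular") == 1.0

    def test_checkerboard_half(self):
        zz, yy, xx = np.mgrid[0:20, 0:20, 0:20]
        vol = all_trabecular(BoneVolume((zz + yy + xx) % 2 == 0, 12.5))
        assert bvtv(vol, "trabecular") == 0.5

    def test_counting_oracle_exact(self, rng):
        v = rng.random((30, 30, 30)) < 0.3
        v[0] = True  # make the z-band the full volume
        v[-1] = True
        vol = all_trabecular(BoneVolume(v, 12.5))
        assert bvtv(vol, "trabecular") == v.sum() / v.size

    def test_axis_permutation_and_flip_invariance(self, rng):
        v = rng.random((20, 24, 28)) < 0.4
        v[0] = v[-1] = True
        base = bvtv(all_trabecular(BoneVolume(v, 12.5)), "trabecular")
        flipped = bvtv(all_trabecular(BoneVolume(v[::-1].copy(), 12.5)), "trabecular")
        assert base == flipped

    def test_empty_compartment_rejected(self):
        v = np.ones((10, 10, 10), bool)
        labels = np.where(v, 1, 0).astype(np.uint8)  # all plate
        vol = BoneVolume(v, 12.5, labels=labels)
        with pytest.raises(ValueError, match="empty"):
            bvtv(vol, "trabecular")


def brute_force_thickness(structure: np.ndarray) -> np.ndarray:
    """Exhaustive largest-inscribed-sphere oracle (small volumes only).

    For every candidate centre c with EDT radius r(c) (the largest sphere
    around c inside the structure), every voxel within r(c) of c can be
    covered by a sphere of diameter 2 r(c).
    """
    from scipy import ndimage

    padded = np.pad(structure, ((1, 1), (0, 0), (0, 0)))
    radii = ndimage.distance_transform_edt(padded)[1:-1]
    pts = np.argwhere(structure)
    rvals = radii[structure]
    thick = np.zeros(len(pts))
    for center, r in zip(pts, rvals):
        d2 = ((pts - center) ** 2).sum(axis=1)
        inside = d2 <= r * r + 1e-9
        thick[inside] = np.maximum(thick[inside], 2.0 * r)
    out = np.zeros_like(radii)
    out[structure] = thick
    return out


class TestLocalThickness:
    def test_slab_exact(self):
        vol = slab_volume(24)
        mean_mm, _ = local_thickness(vol)
        assert mean_mm == pytest.approx(24 * 0.0125, abs=0.5 * 0.0125)

    def test_cylinder_within_five_percent(self):
        vol = cylinder_volume(radius=12, length=100)
        mean_mm, _ = local_thickness(vol)
        assert mean_mm == pytest.approx(24 * 0.0125, rel=0.05)

    def test_brute_force_oracle_on_random_blob(self, rng):
        # random smooth blob inside a 40^3 box
        from scipy import ndimage

        noise = rng.normal(size=(40, 40, 40))
        smooth = ndimage.gaussian_filter(noise, 4.0)
        structure = smooth > np.quantile(smooth, 0.8)
        vol = BoneVolume(structure, 12.5)
        mean_mm, tmap = local_thickness(vol)
        oracle = brute_force_thickness(structure)
        mean_oracle = oracle[structure].mean() * 0.0125
        assert abs(mean_mm - mean_oracle) <= 1.0 * 0.0125
        # voxelwise agreement within the half-voxel binning for nearly all
        # voxels (thin rim shells may fall between bins)
        frac_close = np.mean(np.abs(tmap[structure] - oracle[structure]) <= 1.0 + 1e-9)
        assert frac_close > 0.95

    def test_flip_invariance(self, rng):
        from scipy import ndimage

        noise = rng.normal(size=(30, 30, 30))
        structure = ndimage.gaussian_filter(noise, 3.0) > 0
        a, _ = local_thickness(BoneVolume(structure, 12.5))
        b, _ = local_thickness(BoneVolume(structure[:, ::-1].copy(), 12.5))
        assert a == pytest.approx(b, rel=1e-6)

    def test_voxel_size_equivariance(self):
        """Halving the voxel size changes the thickness estimate by < 5 %."""
        coarse = cylinder_volume(radius=6, length=40, side=26, voxel_um=25.0)
        fine = cylinder_volume(radius=12, length=80, side=52, voxel_um=12.5)
        a, _ = local_thickness(coarse)
        b, _ = local_thickness(fine)
        assert a == pytest.approx(b, rel=0.05)

    def test_empty_structure_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            local_thickness(BoneVolume(np.zeros((10, 10, 10), bool), 12.5))


class TestSmi:
    def test_plate_limit(self):
        vol = slab_volume(24)
        assert abs(smi(vol)) <= 0.3

    def test_rod_limit(self):
        vol = cylinder_volume(radius=12, length=80)
        assert smi(vol) == pytest.approx(3.0, abs=0.3)

    def test_sphere_limit(self):
        vol = sphere_volume(radius=18)
        assert smi(vol) == pytest.approx(4.0, abs=0.3)

    def test_monotone_on_plate_to_rod_family(self):
        """Square-section beams from wide (plate-like) to thin (rod-like)."""
        vals = []
        for half_width in (24, 16, 10, 7):
            v = np.zeros((80, 60, 60), bool)
            v[:, 30 - half_width : 30 + half_width, 30 - 7 : 30 + 7] = True
            vals.append(smi(BoneVolume(v.transpose(1, 2, 0).copy(), 12.5)))
        assert all(a < b + 1e-9 for a, b in zip(vals, vals[1:]))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            smi(BoneVolume(np.ones((10, 10, 10), bool), 12.5))
        with pytest.raises(ValueError, match="degenerate"):
            smi(BoneVolume(np.zeros((10, 10, 10), bool), 12.5))


@pytest.fixture(scope="module")
def phantom():
    cfg = CohortConfig(seed=21)
    truth = draw_morphometry(cfg, np.random.default_rng(21))
    row = truth.iloc[5]
    vol = synthesize_volume(row, 25.0, np.random.default_rng(3), cfg)
    return row, vol, cfg


class TestMorphometryReport:

    def test_sb_th_within_one_voxel_of_truth(self, phantom):
        row, vol, cfg = phantom
        res = morphometry_report(vol, cfg.voi_mm)
        assert abs(res.sb_th_mm - row["sb_th_mm"]) <= 0.025 + 1e-9

    def test_bvtv_within_tolerance_of_truth(self, phantom):
        row, vol, cfg = phantom
        res = morphometry_report(vol, cfg.voi_mm)
        assert abs(res.bvtv_fraction - row["bvtv_fraction"]) <= 0.03

    def test_doubled_strut_thickness_ratio(self):
        # wider and deeper band so both lattices hold several cells in every
        # dimension and the two phantoms stay geometrically similar
        cfg = CohortConfig(seed=8, voi_mm=(2.4, 2.0, 2.0))
        truth = draw_morphometry(cfg, np.random.default_rng(8))
        row = truth.iloc[1].copy()
        row["tb_th_mm"] = 0.12
        thin = synthesize_volume(row, 12.5, np.random.default_rng(4), cfg)
        row2 = row.copy()
        row2["tb_th_mm"] = 0.24
        thick = synthesize_volume(row2, 12.5, np.random.default_rng(4), cfg)
        a, _ = local_thickness(split_plate_trabecular(thin), "trabecular")
        b, _ = local_thickness(split_plate_trabecular(thick), "trabecular")
        assert b / a == pytest.approx(2.0, rel=0.10)

    def test_all_background_volume_structured_error(self):
        with pytest.raises(ValueError, match="no bone"):
            morphometry_report(BoneVolume(np.zeros((50, 50, 50), bool), 25.0))


class TestRoundTrip:
    def test_tiff_round_trip(self, tmp_path, rng):
        v = rng.random((20, 20, 20)) < 0.5
        vol = BoneVolume(v, 12.5)
        vol.to_tiff(tmp_path / "vol.tiff")
        back = BoneVolume.from_tiff(tmp_path / "vol.tiff")
        np.testing.assert_array_equal(back.voxels, v)
        assert back.voxel_um == 12.5
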