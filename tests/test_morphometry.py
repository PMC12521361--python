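"""Local thickness and the 3D / depth-resolved indices."""

import numpy as np
import pytest
from scipy import ndimage

from tibmorph.morphometry import (local_thickness, morphometry_3d,
                                  morphometry_profile)


def brute_force_thickness(mask: np.ndarray) -> np.ndarray:
    """Exhaustive sphere-fitting oracle: every foreground voxel is a
    candidate sphere center with radius = its EDT value; thickness at p is
    the largest painted diameter among all balls containing p."""
    padded = np.pad(mask, 1)
    edt = ndimage.distance_transform_edt(padded)[1:-1, 1:-1, 1:-1]
    out = np.zeros(mask.shape)
    for z, y, x in np.argwhere(mask):
        r = edt[z, y, x]
        d = 2.0 * r - 1.0
        ri = int(np.ceil(r))
        z0, z1 = max(z - ri, 0), min(z + ri + 1, mask.shape[0])
        y0, y1 = max(y - ri, 0), min(y + ri + 1, mask.shape[1])
        x0, x1 = max(x - ri, 0), min(x + ri + 1, mask.shape[2])
        zz, yy, xx = np.ogrid[z0:z1, y0:y1, x0:x1]
        ball = (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2 < r * r
        sub = out[z0:z1, y0:y1, x0:x1]
        np.maximum(sub, np.where(ball, d, 0.0), out=sub)
    return out


def test_digital_ball_thickness():
    n = 25
    zz, yy, xx = np.ogrid[:n, :n, :n]
    ball = (zz - 12) ** 2 + (yy - 12) ** 2 + (xx - 12) ** 2 <= 10 ** 2
    th = local_thickness(ball)
    assert th.max() == pytest.approx(20, abs=1)


def test_slab_interior_thickness():
    slab = np.zeros((15, 40, 40), bool)
    slab[5:10] = True
    th = local_thickness(slab)
    assert th[7, 20, 20] == pytest.approx(5, abs=1)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_fast_thickness_matches_exhaustive_oracle(seed):
    mask = np.random.default_rng(seed).random((24, 24, 24)) < 0.35
    th = local_thickness(mask)
    oracle = brute_force_thickness(mask)
    assert np.abs(th - oracle).max() <= 1.0


def test_dilation_never_decreases_thickness(rng):
    mask = rng.random((20, 20, 20)) < 0.3
    if not mask.any():
        mask[10, 10, 10] = True
    dilated = ndimage.binary_dilation(mask)
    a = local_thickness(mask)
    b = local_thickness(dilated)
    assert (b[mask] >= a[mask] - 1e-9).all()


def test_2d_input_rejected():
    with pytest.raises(ValueError, match="3D"):
        local_thickness(np.ones((10, 10), bool))


def test_empty_mask_rejected():
    with pytest.raises(ValueError, match="empty"):
        local_thickness(np.zeros((5, 5, 5), bool))


# --------------------------------------------------------------------------
# 3D indices
# --------------------------------------------------------------------------

def test_parallel_plates_analytic_geometry():
    # plates 10 voxels thick separated by 30 voxels of marrow, 5 µm voxels;
    # thickness evaluated away from the lateral walls (the volume border
    # counts as background, so edge voxels are biased thin by design)
    nz, n = 120, 100
    med = np.ones((nz, n, n), bool)
    trab = np.zeros((nz, n, n), bool)
    period = 40
    for start in range(0, nz, period):
        trab[start:start + 10] = True
    res = morphometry_3d(trab, med, 0.005)
    assert res.bvtv_pct == pytest.approx(25.0, abs=1)

    sep = med & ~trab
    th_bone = local_thickness(trab, 0.005)
    th_sep = local_thickness(sep, 0.005)
    interior = np.zeros_like(med)
    interior[:, 16:-16, 16:-16] = True
    tbth = th_bone[trab & interior].mean() * 1000
    tbsp = th_sep[sep & interior].mean() * 1000
    assert tbth == pytest.approx(50.0, abs=5.0)   # ±1 voxel
    assert tbsp == pytest.approx(150.0, abs=5.0)


def test_full_medulla_flags_separation_undefined():
    med = np.ones((10, 10, 10), bool)
    res = morphometry_3d(med.copy(), med, 0.005)
    assert res.bvtv_pct == 100.0
    assert res.tbsp_um is None


def test_phantom_secondary_voi_round_trip(coarse_phantom):
    from tibmorph.phantom import SECONDARY

    spec, _, truth = coarse_phantom
    sel = truth.label_volume == SECONDARY
    trab = truth.trabecular_mask & sel
    med = truth.medullary_mask & sel
    res = morphometry_3d(trab, med, spec.voxel_size_mm)
    tex = spec.compartment_texture["secondary"]
    assert res.bvtv_pct / 100 == pytest.approx(tex["target_bvtv"], abs=0.03)
    assert res.tbth_um == pytest.approx(tex["target_tbth_mm"] * 1000,
                                        abs=2 * spec.voxel_size_mm * 1000)


def test_empty_medulla_rejected():
    with pytest.raises(ValueError, match="medullary"):
        morphometry_3d(np.zeros((5, 5, 5), bool), np.zeros((5, 5, 5), bool),
                       0.005)


# --------------------------------------------------------------------------
# depth profile
# --------------------------------------------------------------------------

def _random_voi(rng, nz=200, n=24, p=0.2):
    med = np.zeros((nz, n, n), bool)
    med[:, 4:20, 4:20] = True
    trab = med & (rng.random((nz, n, n)) < p)
    return trab, med


def test_one_mm_voi_has_fifty_bins(rng):
    trab, med = _random_voi(rng)
    prof = morphometry_profile(trab, med, 0.005, 0.020,
                               include_thickness=False)
    assert len(prof) == 50


def test_bin_counts_sum_to_3d_counts(rng):
    trab, med = _random_voi(rng)
    prof = morphometry_profile(trab, med, 0.005, include_thickness=False)
    assert prof["n_trab_voxels"].sum() == trab.sum()
    assert prof["n_med_voxels"].sum() == med.sum()


def test_volume_weighted_mean_of_bins_equals_3d_bvtv_exactly(rng):
    trab, med = _random_voi(rng)
    prof = morphometry_profile(trab, med, 0.005, include_thickness=False)
    weighted = (prof["bar_tar_pct"] * prof["n_med_voxels"]).sum() \
        / prof["n_med_voxels"].sum()
    bvtv = 100.0 * trab.sum() / med.sum()
    assert weighted == pytest.approx(bvtv, abs=1e-9)


def test_uniform_texture_bins_stay_within_binomial_bound(rng):
    trab, med = _random_voi(rng, p=0.25)
    prof = morphometry_profile(trab, med, 0.005, include_thickness=False)
    p3d = trab.sum() / med.sum()
    n_bin = prof["n_med_voxels"].iloc[0]
    sd = 100.0 * np.sqrt(p3d * (1 - p3d) / n_bin)
    assert (np.abs(prof["bar_tar_pct"] - 100 * p3d) <= 4 * sd).all()


def test_two_layer_voi_shows_step_at_mid_bin(rng):
    nz = 200
    med = np.zeros((nz, 24, 24), bool)
    med[:, 4:20, 4:20] = True
    trab = med.copy()
    trab[:100] &= rng.random((100, 24, 24)) < 0.4
    trab[100:] &= rng.random((100, 24, 24)) < 0.05
    prof = morphometry_profile(trab, med, 0.005, include_thickness=False)
    assert prof["bar_tar_pct"][:25].mean() > 30
    assert prof["bar_tar_pct"][25:].mean() < 10


def test_bin_width_below_voxel_rejected(rng):
    trab, med = _random_voi(rng, nz=10)
    with pytest.raises(ValueError, match="bin width"):
        morphometry_profile(trab, med, 0.005, bin_width_mm=0.004)
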