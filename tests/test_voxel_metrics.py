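"""Voxel-level metric checks against analytic phantoms and hand arithmetic."""

import numpy as np
import pytest

from micalung import (
    AirFractionVolume,
    DisplacementField,
    adi_field,
    air_volume_change,
    classify_prm,
    generate_phantom,
    hu_to_air_fraction,
    jacobian_field,
    lung_shape,
    prm_fractions,
    tissue_fraction,
)
from micalung.synthetic import Blob, PhantomSpec
from micalung.voxel_metrics import (
    LOBES,
    PRM_EMPH,
    PRM_FSAD,
    PRM_NORMAL,
    erode_mask,
)


def _uniform_volume(value, shape=(8, 8, 8), spacing=(1.0, 1.0, 1.0), lobes=True):
    mask = np.ones(shape, dtype=bool)
    lobe_labels = {}
    if lobes:
        # five equal slabs along z
        nz = shape[2]
        for i, lobe in enumerate(LOBES):
            lab = np.zeros(shape, dtype=bool)
            lab[:, :, i * nz // 5:(i + 1) * nz // 5] = True
            lobe_labels[lobe] = lab
    return AirFractionVolume(np.full(shape, float(value)), spacing, mask, lobe_labels)


# ---------------------------------------------------------------- HU mapping

@pytest.mark.parametrize("hu, expected", [(-1000.0, 1.0), (0.0, 0.0), (-950.0, 0.95)])
def test_hu_to_air_fraction_linear_map(hu, expected):
    vol = hu_to_air_fraction(np.full((2, 2, 2), hu), (1, 1, 1), np.ones((2, 2, 2), bool))
    assert vol.values == pytest.approx(expected)


def test_hu_conversion_rejects_degenerate_calibration():
    with pytest.raises(ValueError):
        hu_to_air_fraction(np.zeros((2, 2, 2)), (1, 1, 1), np.ones((2, 2, 2), bool),
                           hu_air=-500, hu_tissue=-500)


# ------------------------------------------------------------------ PRM rule

@pytest.mark.parametrize(
    "f_tlc, f_rv, expected",
    [(0.99, 0.95, PRM_EMPH), (0.80, 0.92, PRM_FSAD), (0.80, 0.50, PRM_NORMAL)],
)
def test_prm_voxel_classification(f_tlc, f_rv, expected):
    tlc = _uniform_volume(f_tlc, lobes=False)
    rv = _uniform_volume(f_rv, lobes=False)
    prm = classify_prm(tlc, rv)
    assert np.all(prm.labels == expected)


def test_prm_grid_mismatch_rejected():
    with pytest.raises(ValueError):
        classify_prm(_uniform_volume(0.8, shape=(8, 8, 8)), _uniform_volume(0.8, shape=(6, 6, 6)))


def test_prm_fractions_conserve_and_count():
    """Emph% + fSAD% + Normal% = 100 in every region; counts are exact."""
    spec = PhantomSpec(
        emph_blob=Blob((0.28, 0.5, 0.62), 16.0, 0.99, 0.95),
        fsad_blob=Blob((0.72, 0.5, 0.40), 20.0, 0.96, 0.92),
    )
    tlc, rv, _, gt = generate_phantom(spec)
    fr = prm_fractions(classify_prm(tlc, rv))
    for region, vals in fr.items():
        assert vals["Emph%"] + vals["fSAD%"] + vals["Normal%"] == pytest.approx(100.0)
    # fractions agree exactly with the geometric membership ground truth
    assert fr["Total"]["Emph%"] == pytest.approx(gt["Emph% Total"])
    assert fr["Total"]["fSAD%"] == pytest.approx(gt["fSAD% Total"])


def test_prm_threshold_monotonicity():
    """Raising the emphysema threshold never increases Emph%."""
    spec = PhantomSpec(emph_blob=Blob((0.28, 0.5, 0.62), 16.0, 0.99, 0.95))
    tlc, rv, _, _ = generate_phantom(spec)
    emph = [
        prm_fractions(classify_prm(tlc, rv, emph_thr=thr))["Total"]["Emph%"]
        for thr in (0.90, 0.95, 0.985, 0.995)
    ]
    assert all(a >= b for a, b in zip(emph, emph[1:]))


# ------------------------------------------------------ Jacobian / ADI

def test_identity_field_has_unit_jacobian_zero_adi():
    mask = np.ones((6, 6, 6), bool)
    disp = DisplacementField(np.zeros((6, 6, 6, 3)), (1, 1, 1), mask)
    J, means, n_fold = jacobian_field(disp)
    assert np.allclose(J, 1.0) and n_fold == 0
    adi, ameans = adi_field(disp)
    assert np.allclose(adi, 0.0)


@pytest.mark.parametrize(
    "model, expected_j, expected_adi",
    [
        ({"type": "uniform_scale", "s": 1.27}, 1.27**3, 0.0),
        ({"type": "axis_scale", "scales": (1.5, 1.2, 1.1)}, 1.98,
         np.sqrt((0.3 / 1.2) ** 2 + (0.1 / 1.1) ** 2)),
    ],
)
def test_affine_phantom_jacobian_adi_match_analytic(model, expected_j, expected_adi):
    """Affine fields are differentiated exactly away from the mask border."""
    _, _, disp, _ = generate_phantom(PhantomSpec(displacement_model=model))
    interior = erode_mask(disp.mask, 2)
    J, _, n_fold = jacobian_field(disp)
    assert n_fold == 0
    assert np.abs(J[interior] - expected_j).max() < 1e-6
    adi, _ = adi_field(disp)
    assert np.abs(adi[interior] - expected_adi).max() < 1e-6


def test_nonlinear_jacobian_converges_under_grid_refinement():
    """Central-difference error vs the analytic Jacobian shrinks when the
    grid is refined (fixed physical extent, doubled sampling)."""
    model = {"type": "smooth_nonlinear", "amplitude_mm": (3.0, 2.0, 4.0),
             "base_scale": 1.2, "n_periods": 1}
    errs = []
    for shape, spacing in [((30, 30, 38), (4.4, 4.4, 4.42)), ((60, 60, 76), (2.2, 2.2, 2.21))]:
        spec = PhantomSpec(grid_shape=shape, spacing=spacing, displacement_model=model)
        tlc, _, disp, _ = generate_phantom(spec)
        # analytic per-voxel Jacobian from the phantom definition
        from micalung.synthetic import _displacement_and_jacobian
        _, J_true, _ = _displacement_and_jacobian(spec)
        J, _, _ = jacobian_field(disp)
        interior = erode_mask(tlc.lung_mask, 2)
        errs.append(np.abs(J - J_true)[interior].max())
    assert errs[1] < errs[0] / 2  # second-order scheme: ~4x per refinement


def test_folding_voxels_flagged_and_excluded():
    # displacement that inverts orientation in half the domain
    shape = (8, 8, 8)
    x = np.arange(8)[:, None, None] * np.ones(shape)
    u = np.zeros(shape + (3,))
    u[..., 0] = np.where(x >= 4, -2.0 * (x - 4.0), 0.0)  # du/dx = -2 -> F_00 = -1
    disp = DisplacementField(u, (1, 1, 1), np.ones(shape, bool))
    _, means, n_fold = jacobian_field(disp)
    assert n_fold > 0
    assert means["Total"] > 0


# --------------------------------------------- tissue fraction, volume change

def test_tissue_fraction_is_one_minus_mean_air_fraction():
    vol = _uniform_volume(0.873)
    bt = tissue_fraction(vol)
    assert bt["Total"] == pytest.approx(0.127)
    # exact complement identity on a non-uniform volume
    rng = np.random.default_rng(0)
    vals = rng.uniform(0.3, 0.99, size=(8, 8, 8))
    vol2 = AirFractionVolume(vals, (1, 1, 1), np.ones((8, 8, 8), bool), vol.lobe_labels)
    bt2 = tissue_fraction(vol2)
    for region in bt2:
        sel = vol2.lung_mask if region == "Total" else vol2.lobe_labels[region]
        assert bt2[region] == pytest.approx(1.0 - vals[sel].mean(), abs=1e-12)


def test_air_volume_change_equal_lobes_symmetry():
    """Five equal lobes with equal inflation: shares 0.2 each, U/(M+L) = 2/3."""
    tlc = _uniform_volume(0.8, shape=(10, 10, 10))
    rv = _uniform_volume(0.5, shape=(10, 10, 10))
    out = air_volume_change(tlc, rv)
    for lobe in LOBES:
        assert out[f"dVair_frac {lobe}"] == pytest.approx(0.2)
    assert out["U_over_ML"] == pytest.approx(2.0 / 3.0)
    assert sum(out[f"dVair_frac {lb}"] for lb in LOBES) == pytest.approx(1.0, abs=1e-9)


def test_air_volume_change_concentrated_in_one_lobe():
    tlc = _uniform_volume(0.5, shape=(10, 10, 10))
    vals = np.full((10, 10, 10), 0.5)
    vals[tlc.lobe_labels["LLL"]] = 0.2  # only LLL inflates
    rv = AirFractionVolume(vals, (1, 1, 1), tlc.lung_mask, tlc.lobe_labels)
    out = air_volume_change(tlc, rv)
    assert out["dVair_frac LLL"] == pytest.approx(1.0)
    for lobe in ("RUL", "RML", "RLL", "LUL"):
        assert out[f"dVair_frac {lobe}"] == pytest.approx(0.0)


def test_air_volume_change_rejects_deflation():
    with pytest.raises(ValueError):
        air_volume_change(_uniform_volume(0.5), _uniform_volume(0.8))


# ------------------------------------------------------------------ lung shape

def test_lung_shape_ellipsoid_ratio():
    """Ellipsoid semi-axes z=150 mm (apical-basal), y=100 mm (ventral-dorsal)
    give a shape ratio of 1.5."""
    xx, yy, zz = np.meshgrid(np.arange(20), np.arange(210), np.arange(310), indexing="ij")
    mask = (((xx - 10) / 8.0) ** 2 + ((yy - 105) / 100.0) ** 2
            + ((zz - 155) / 150.0) ** 2) <= 1
    ratio = lung_shape(mask, (1.0, 1.0, 1.0))
    assert ratio == pytest.approx(1.5, rel=0.02)


def test_lung_shape_uses_physical_spacing_not_voxels():
    mask = np.ones((50, 50, 50), bool)
    assert lung_shape(mask, (1.0, 1.0, 2.0)) == pytest.approx(2.0)
    assert lung_shape(mask, (1.0, 2.0, 1.0)) == pytest.approx(0.5)
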