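"""Registration-based functional lung metrics on paired inspiration/expiration CT.

All metrics operate on per-voxel *air fraction* volumes (``f_air`` in [0, 1])
rather than raw Hounsfield units: reparameterising density as air fraction
makes the emphysema / small-airways-disease thresholds robust to scanner
calibration offsets.  The module computes

* PRM (parametric response map) classification of each voxel as emphysema
  (``Emph``), functional small-airways disease (``fSAD``) or ``Normal`` from
  the inspiration (TLC) and expiration (RV) air fractions,
* the determinant of the deformation-gradient (Jacobian) and the anisotropic
  deformation index (ADI) of the expiration-to-inspiration displacement field,
* tissue fraction ``beta_tissue = 1 - f_air``,
* lobar fractional air-volume change and the upper/(middle+lower) ventilation
  ratio, and
* the apical-basal over ventral-dorsal lung-shape ratio.

Axis convention: axis 0 = left-right, axis 1 = ventral-dorsal,
axis 2 = apical-basal.  All physical quantities are in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LOBES = ("RUL", "RML", "RLL", "LUL", "LLL")
UPPER_LOBES = ("RUL", "LUL")
MIDDLE_LOWER_LOBES = ("RML", "RLL", "LLL")

# Integer codes for PRM label volumes.
PRM_OUTSIDE = 0
PRM_NORMAL = 1
PRM_FSAD = 2
PRM_EMPH = 3

EMPH_THRESHOLD = 0.985  # air fraction at TLC
FSAD_THRESHOLD = 0.90   # air fraction at RV


@dataclass
class AirFractionVolume:
    """Gridded per-voxel air fraction with lung mask and lobe labels.

    Parameters
    ----------
    values : ndarray of float, shape (nx, ny, nz)
        Air fraction per voxel; must lie in [0, 1] inside ``lung_mask``.
    spacing : tuple of 3 floats
        Voxel spacing in mm along each axis.
    lung_mask : ndarray of bool
        True inside the lung.
    lobe_labels : dict of str -> ndarray of bool
        Boolean map per lobe (keys from :data:`LOBES`); the maps partition
        ``lung_mask``.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    lung_mask: np.ndarray
    lobe_labels: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if self.values.shape != self.lung_mask.shape:
            raise ValueError("values and lung_mask shapes differ")
        inside = self.values[self.lung_mask]
        if inside.size and (inside.min() < -1e-9 or inside.max() > 1 + 1e-9):
            raise ValueError("air fraction outside [0, 1] inside lung mask")
        for name, lab in self.lobe_labels.items():
            if np.any(lab & ~self.lung_mask):
                raise ValueError(f"lobe {name} extends outside the lung mask")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DisplacementField:
    """Per-voxel displacement u(x) (mm) mapping RV coordinates to TLC.

    ``vectors`` has shape (nx, ny, nz, 3).  The deformation gradient is
    F = I + du/dx, so J = det(F) > 1 means local inflation from expiration
    to inspiration.
    """

    vectors: np.ndarray
    spacing: tuple[float, float, float]
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        if self.vectors.shape[:3] != self.mask.shape:
            raise ValueError("vectors and mask shapes differ")
        if not np.all(np.isfinite(self.vectors[self.mask])):
            raise ValueError("non-finite displacement inside mask")


@dataclass
class PRMMap:
    """Integer-coded parametric response map (codes PRM_*)."""

    labels: np.ndarray
    lobe_labels: dict[str, np.ndarray] = field(default_factory=dict)


def hu_to_air_fraction(
    hu_volume: np.ndarray,
    spacing: tuple[float, float, float],
    lung_mask: np.ndarray,
    lobe_labels: dict[str, np.ndarray] | None = None,
    hu_air: float = -1000.0,
    hu_tissue: float = 0.0,
) -> AirFractionVolume:
    """Convert Hounsfield units to air fraction by linear interpolation.

    f_air = (hu_tissue - HU) / (hu_tissue - hu_air), clipped to [0, 1];
    pure air (-1000 HU) maps to 1, pure tissue (0 HU) to 0.
    """
    hu = np.asarray(hu_volume, dtype=float)
    if not np.all(np.isfinite(hu)):
        raise ValueError("HU volume contains non-finite values")
    if hu_air == hu_tissue:
        raise ValueError("hu_air and hu_tissue must differ")
    f_air = np.clip((hu_tissue - hu) / (hu_tissue - hu_air), 0.0, 1.0)
    return AirFractionVolume(f_air, spacing, lung_mask, lobe_labels or {})


def classify_prm(
    tlc: AirFractionVolume,
    rv_in_tlc_space: AirFractionVolume,
    emph_thr: float = EMPH_THRESHOLD,
    fsad_thr: float = FSAD_THRESHOLD,
) -> PRMMap:
    """Joint PRM classification of co-registered TLC/RV air fractions.

    Emph where f_air(TLC) >= emph_thr; else fSAD where f_air(RV) >= fsad_thr;
    Normal otherwise; voxels outside the lung mask are coded outside.
    """
    if tlc.values.shape != rv_in_tlc_space.values.shape:
        raise ValueError("TLC and RV volumes are on different grids")
    if not np.array_equal(tlc.lung_mask, rv_in_tlc_space.lung_mask):
        raise ValueError("TLC and RV lung masks differ")
    labels = np.full(tlc.values.shape, PRM_OUTSIDE, dtype=np.int8)
    m = tlc.lung_mask
    labels[m] = PRM_NORMAL
    fsad = m & (rv_in_tlc_space.values >= fsad_thr)
    labels[fsad] = PRM_FSAD
    emph = m & (tlc.values >= emph_thr)
    labels[emph] = PRM_EMPH
    return PRMMap(labels, tlc.lobe_labels)


def prm_fractions(prm: PRMMap) -> dict[str, dict[str, float]]:
    """Percentages of Emph / fSAD / Normal voxels per lobe and Total.

    Returns ``{region: {"Emph%": ..., "fSAD%": ..., "Normal%": ...}}`` with
    region keys from :data:`LOBES` plus ``"Total"``.
    """
    mask = prm.labels != PRM_OUTSIDE
    if not mask.any():
        raise ValueError("empty lung mask in PRM map")
    out: dict[str, dict[str, float]] = {}
    regions: dict[str, np.ndarray] = {"Total": mask}
    regions.update(prm.lobe_labels)
    for name, reg in regions.items():
        n = int(np.count_nonzero(reg))
        if n == 0:
            out[name] = {"Emph%": 0.0, "fSAD%": 0.0, "Normal%": 0.0}
            continue
        lab = prm.labels[reg]
        out[name] = {
            "Emph%": 100.0 * np.count_nonzero(lab == PRM_EMPH) / n,
            "fSAD%": 100.0 * np.count_nonzero(lab == PRM_FSAD) / n,
            "Normal%": 100.0 * np.count_nonzero(lab == PRM_NORMAL) / n,
        }
    return out


def _masked_gradient(values: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """d(values)/dx along ``axis``: central differences where both neighbours
    are inside ``mask``, one-sided at mask borders, 0 where isolated."""
    fwd = np.roll(values, -1, axis=axis)
    bwd = np.roll(values, 1, axis=axis)
    m_fwd = np.roll(mask, -1, axis=axis)
    m_bwd = np.roll(mask, 1, axis=axis)
    # roll wraps around; kill wrapped neighbours at the array edges
    edge_hi = [slice(None)] * values.ndim
    edge_hi[axis] = slice(-1, None)
    edge_lo = [slice(None)] * values.ndim
    edge_lo[axis] = slice(0, 1)
    m_fwd = m_fwd.copy()
    m_bwd = m_bwd.copy()
    m_fwd[tuple(edge_hi)] = False
    m_bwd[tuple(edge_lo)] = False

    grad = np.zeros_like(values)
    central = mask & m_fwd & m_bwd
    grad[central] = (fwd[central] - bwd[central]) / (2.0 * h)
    fwd_only = mask & m_fwd & ~m_bwd
    grad[fwd_only] = (fwd[fwd_only] - values[fwd_only]) / h
    bwd_only = mask & ~m_fwd & m_bwd
    grad[bwd_only] = (values[bwd_only] - bwd[bwd_only]) / h
    return grad


def deformation_gradient(disp: DisplacementField) -> np.ndarray:
    """F = I + du/dx per voxel, shape (nx, ny, nz, 3, 3), mm units."""
    if not disp.mask.any():
        raise ValueError("empty displacement mask")
    shape = disp.mask.shape
    F = np.zeros(shape + (3, 3))
    for i in range(3):
        for j in range(3):
            F[..., i, j] = _masked_gradient(
                disp.vectors[..., i], disp.mask, axis=j, h=disp.spacing[j]
            )
        F[..., i, i] += 1.0
    return F


def _region_means(
    values: np.ndarray,
    valid: np.ndarray,
    lobe_labels: dict[str, np.ndarray],
) -> dict[str, float]:
    out = {"Total": float(values[valid].mean())}
    for name, reg in lobe_labels.items():
        sel = reg & valid
        out[name] = float(values[sel].mean()) if sel.any() else float("nan")
    return out


def jacobian_field(
    disp: DisplacementField,
    lobe_labels: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, float], int]:
    """Jacobian determinant J = det(I + du/dx) and its regional means.

    Voxels with J <= 0 (local folding, non-physical) are excluded from the
    means and counted; returns ``(J_grid, means, n_folding)``.
    """
    F = deformation_gradient(disp)
    J = np.linalg.det(F)
    valid = disp.mask & (J > 0)
    n_fold = int(np.count_nonzero(disp.mask & ~valid))
    if not valid.any():
        raise ValueError("all voxels fold (J <= 0)")
    return J, _region_means(J, valid, lobe_labels or {}), n_fold


def adi_field(
    disp: DisplacementField,
    lobe_labels: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, dict[str, float]]:
    """Anisotropic deformation index and its regional means.

    With principal stretches l1 >= l2 >= l3 (square roots of the eigenvalues
    of F^T F), ADI = sqrt(((l1-l2)/l2)^2 + ((l2-l3)/l3)^2): zero for isotropic
    deformation, growing with preferential stretching along one axis.
    """
    F = deformation_gradient(disp)
    if not np.all(np.isfinite(F[disp.mask])):
        raise ValueError("non-finite deformation gradient inside mask")
    C = np.einsum("...ki,...kj->...ij", F, F)
    eigvals = np.linalg.eigvalsh(C)  # ascending
    eigvals = np.clip(eigvals, 0.0, None)
    stretches = np.sqrt(eigvals)[..., ::-1]  # descending l1 >= l2 >= l3
    l1, l2, l3 = stretches[..., 0], stretches[..., 1], stretches[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        adi = np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)
    adi[~disp.mask] = 0.0
    valid = disp.mask & np.isfinite(adi)
    return adi, _region_means(adi, valid, lobe_labels or {})


def tissue_fraction(tlc: AirFractionVolume) -> dict[str, float]:
    """beta_tissue = regional mean of (1 - f_air) per lobe and Total."""
    if not tlc.lung_mask.any():
        raise ValueError("empty lung mask")
    beta = 1.0 - tlc.values
    return _region_means(beta, tlc.lung_mask, tlc.lobe_labels)


def air_volume_change(
    tlc: AirFractionVolume,
    rv: AirFractionVolume,
) -> dict[str, float]:
    """Lobar fractional air-volume change and the U/(M+L) ventilation ratio.

    V_air(region) = sum of f_air * voxel volume; dVair(lobe) is the lobe's
    TLC-RV air-volume difference and dVair_frac its share of the whole-lung
    change.  Returns ``{"dVair_frac <lobe>": ..., "U_over_ML": ...}``.
    """
    def vair(vol: AirFractionVolume, region: np.ndarray) -> float:
        return float(vol.values[region].sum() * vol.voxel_volume)

    total = vair(tlc, tlc.lung_mask) - vair(rv, rv.lung_mask)
    if total <= 0:
        raise ValueError("whole-lung air-volume change is not positive")
    d: dict[str, float] = {}
    for lobe in LOBES:
        dv = vair(tlc, tlc.lobe_labels[lobe]) - vair(rv, rv.lobe_labels[lobe])
        d[lobe] = dv
    out = {f"dVair_frac {lobe}": d[lobe] / total for lobe in LOBES}
    lower = sum(d[lb] for lb in MIDDLE_LOWER_LOBES)
    if lower == 0:
        raise ValueError("middle+lower lobe air-volume change is zero")
    out["U_over_ML"] = sum(d[lb] for lb in UPPER_LOBES) / lower
    return out


def erode_mask(mask: np.ndarray, iterations: int = 1) -> np.ndarray:
    """Interior of a mask (binary erosion); summaries on the interior avoid
    the one-sided-difference shell at mask borders."""
    from scipy.ndimage import binary_erosion

    return binary_erosion(mask, iterations=iterations)


def lung_shape(lung_mask: np.ndarray, spacing: tuple[float, float, float]) -> float:
    """Apical-basal extent over ventral-dorsal extent of the mask (mm/mm)."""
    mask = np.asarray(lung_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty lung mask")
    idx = np.nonzero(mask)
    # extents from bounding box, +1 voxel to count both end voxels
    extent_ab = (idx[2].max() - idx[2].min() + 1) * spacing[2]
    extent_vd = (idx[1].max() - idx[1].min() + 1) * spacing[1]
    if extent_vd == 0:
        raise ValueError("zero ventral-dorsal extent")
    return float(extent_ab / extent_vd)
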