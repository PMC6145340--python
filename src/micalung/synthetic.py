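"""Synthetic phantoms and a synthetic COPD cohort with known ground truth.

Two generators make the whole pipeline testable without any image download:

1. **Analytic lung phantoms** — paired TLC/RV air-fraction volumes on a
   common (registered) grid, a displacement field with an analytic
   deformation gradient, lobe label maps, and an airway-segment table.  The
   lungs are two axis-aligned ellipsoids split into the five lobes by fixed
   fractional planes along the apical-basal axis; air fractions are
   piecewise constant (background plus optional emphysema / air-trapping
   blobs), so every downstream metric has a closed-form or direct-count
   ground truth computed here from the *geometry*, independently of the
   voxel-level metric code.

2. **A synthetic cohort** — a subjects x 69 feature matrix plus clinical
   covariates emulating a four-cluster current-smoker population
   (default sizes 96/45/88/55, total 284) and 130 healthy controls.  The
   ten feature/cluster mean (SD) pairs that are published for this regime
   are used verbatim; the remaining 59 features follow a documented
   seven-factor latent rule with cluster-specific factor means, so the
   clusters stay separable in the full 69-dimensional space.  Features are
   drawn with diagonal covariance given the factors; truncation clips only
   to physical ranges.

The generators emulate the *statistical* structure of a quantitative-CT
cohort (cluster means, spreads, physical ranges), not CT noise, texture,
scanner effects or registration error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .airway_metrics import REGIONS
from .features import FeatureManifest, FeatureMatrix, default_manifest
from .voxel_metrics import (
    LOBES,
    MIDDLE_LOWER_LOBES,
    UPPER_LOBES,
    AirFractionVolume,
    DisplacementField,
)

# --------------------------------------------------------------------------
# Cohort parameters for the four-cluster current-smoker regime.
# (mean, sd) per group in order: cluster 1, 2, 3, 4, healthy controls.
# --------------------------------------------------------------------------

PRINTED_FEATURES: dict[str, list[tuple[float, float]]] = {
    "fSAD% Total": [(4.6, 5.4), (8.4, 8.2), (12.3, 6.9), (34.9, 7.9), (4.4, 5.2)],
    "Jacobian Total": [(2.09, 0.266), (1.496, 0.218), (1.671, 0.168), (1.353, 0.136), (2.082, 0.41)],
    "beta_tissue Total": [(0.127, 0.02), (0.162, 0.031), (0.117, 0.017), (0.095, 0.019), (0.119, 0.027)],
    "WT* sRML": [(0.599, 0.036), (0.615, 0.047), (0.557, 0.035), (0.563, 0.043), (0.588, 0.047)],
    "ADI RUL": [(0.406, 0.078), (0.314, 0.101), (0.309, 0.079), (0.22, 0.074), (0.35, 0.093)],
    "Dh* sLLL": [(0.349, 0.034), (0.322, 0.048), (0.307, 0.036), (0.289, 0.04), (0.339, 0.041)],
    "Emph% Total": [(2.8, 3.0), (2.4, 3.0), (4.2, 4.5), (13.5, 8.7), (2.8, 3.8)],
    "ADI Total": [(0.467, 0.066), (0.332, 0.086), (0.378, 0.07), (0.269, 0.073), (0.429, 0.101)],
    "dVair_frac LLL": [(0.245, 0.031), (0.207, 0.062), (0.254, 0.041), (0.273, 0.045), (0.263, 0.037)],
    "Cr LMB": [(0.976, 0.009), (0.965, 0.016), (0.973, 0.012), (0.962, 0.015), (0.977, 0.011)],
}

#: Base (cluster-independent) mean and sd for unprinted features, keyed by
#: (metric, region) with ``None`` as a wildcard region.  Cluster structure
#: for these features enters only through the latent factors.
_BASE_PARAMS: dict[tuple[str, str | None], tuple[float, float]] = {
    ("theta", None): (75.0, 8.0),
    ("Cr", None): (0.970, 0.012),
    ("WT*", "Trachea"): (1.0, 0.05),
    ("WT*", None): (0.59, 0.045),
    ("Dh*", "Trachea"): (1.0, 0.05),
    ("Dh*", "LMB"): (0.78, 0.05),
    ("Dh*", "RMB"): (0.80, 0.05),
    ("Dh*", None): (0.33, 0.04),
    ("dVair_frac", "RUL"): (0.20, 0.040),
    ("dVair_frac", "RML"): (0.08, 0.025),
    ("dVair_frac", "RLL"): (0.25, 0.040),
    ("dVair_frac", "LUL"): (0.22, 0.040),
    ("Jacobian", None): (1.70, 0.25),
    ("ADI", None): (0.35, 0.09),
    ("fSAD%", None): (12.0, 8.0),
    ("Emph%", None): (5.0, 4.0),
    ("beta_tissue", None): (0.12, 0.02),
    ("lung_shape", None): (1.45, 0.12),
    ("U_over_ML", None): (0.55, 0.12),
}

#: Physical clipping ranges by metric (truncation never encodes clusters).
_CLIP_RANGES: dict[str, tuple[float, float]] = {
    "fSAD%": (0.0, 100.0),
    "Emph%": (0.0, 100.0),
    "Cr": (1e-6, 1.0),
    "theta": (0.0, 180.0),
    "Jacobian": (0.05, np.inf),
    "beta_tissue": (0.0, 1.0),
    "dVair_frac": (0.0, 1.0),
    "WT*": (1e-3, np.inf),
    "Dh*": (1e-3, np.inf),
    "ADI": (0.0, np.inf),
    "lung_shape": (0.1, np.inf),
    "U_over_ML": (0.0, np.inf),
}

# Clinical parameters per group (cluster 1..4, healthy).  Continuous
# variables as (mean, sd); categorical as level -> probability maps.
CLINICAL_CONTINUOUS: dict[str, list[tuple[float, float]]] = {
    "age": [(54.44, 8.01), (56.76, 8.51), (61.01, 8.24), (64.47, 8.14), (47.8, 16.9)],
    "bmi": [(27.63, 4.7), (31.1, 5.04), (25.58, 4.76), (23.65, 4.26), (27.4, 5.5)],
    "bode_index": [(0.48, 0.9), (1.4, 1.9), (0.98, 1.1), (2.94, 1.7), (0.2, 0.5)],
    "fev1_pct_pre": [(0.91, 0.17), (0.73, 0.22), (0.68, 0.2), (0.42, 0.17), (1.00, 0.13)],
    "fvc_pct_pre": [(1.01, 0.15), (0.86, 0.17), (0.86, 0.18), (0.74, 0.16), (0.99, 0.11)],
    "fev1_fvc_pre": [(0.71, 0.09), (0.66, 0.14), (0.61, 0.1), (0.43, 0.11), (0.80, 0.07)],
    "fev1_pct_post": [(0.97, 0.16), (0.8, 0.2), (0.76, 0.18), (0.49, 0.17), (1.02, 0.11)],
    "fvc_pct_post": [(1.04, 0.15), (0.92, 0.16), (0.93, 0.17), (0.85, 0.16), (0.99, 0.10)],
    "fev1_fvc_post": [(0.74, 0.09), (0.68, 0.13), (0.63, 0.11), (0.44, 0.12), (0.82, 0.06)],
    "pack_years": [(41.79, 22.05), (42.89, 18.7), (47.06, 19.36), (54.95, 21.03), (0.3, 0.3)],
    "cat_score": [(13.17, 7.95), (16.45, 9.54), (13.78, 7.86), (20.06, 7.86), (5.0, 5.0)],
    "exac_severe": [(0.2, 0.6), (0.44, 1.62), (0.31, 0.82), (1.25, 2.27), (0.0, 0.0)],
    "exac_total": [(0.49, 1.19), (1.09, 3.39), (0.92, 2.14), (2.09, 2.91), (0.0, 0.0)],
    "exac_baseline": [(0.25, 0.68), (0.58, 1.39), (0.22, 0.63), (0.62, 0.99), (0.0, 0.0)],
    "walk_6min_m": [(445.66, 91.31), (386.64, 136.27), (420.38, 71.19), (385.16, 94.09), (500.0, 80.0)],
}

CLINICAL_CATEGORICAL: dict[str, tuple[list[str], list[list[float]]]] = {
    "gold_stage": (
        ["0", "1", "2", "3", "4"],
        [[68, 22, 10, 0, 0], [47, 11, 33, 9, 0], [27, 15, 51, 7, 0],
         [4, 2, 40, 47, 7], [100, 0, 0, 0, 0]],
    ),
    "stratum": (
        ["1", "2", "3", "4"],
        [[0, 68, 32, 0], [0, 51, 40, 9], [0, 27, 66, 7], [0, 4, 44, 52],
         [100, 0, 0, 0]],
    ),
    "sex": (
        ["female", "male"],
        [[44, 56], [49, 51], [44, 56], [31, 69], [58.5, 41.5]],
    ),
    "race": (
        ["white", "black", "other"],
        [[60, 32, 7], [36, 58, 7], [72, 26, 2], [80, 15, 5],
         [71.5, 16.2, 12.3]],
    ),
}

_COUNT_VARS = ("bode_index", "cat_score", "exac_severe", "exac_total", "exac_baseline")
_FRACTION_VARS = ("fev1_fvc_pre", "fev1_fvc_post")


@dataclass
class CohortSpec:
    """Parameters of the synthetic four-cluster cohort.

    Defaults reproduce the published study conditions: smoker cluster sizes
    96/45/88/55 (N = 284) plus 130 healthy controls; printed feature
    mean/SD pairs used verbatim; 59 unprinted features generated by a
    seven-factor latent rule with cluster factor means at
    ``factor_separation`` along one coordinate axis per cluster (healthy
    controls share cluster 1's factor mean, matching their printed
    similarity).  ``sd_scale`` multiplies every feature SD (0 collapses
    each subject onto its cluster centroid).
    """

    cluster_sizes: tuple[int, ...] = (96, 45, 88, 55)
    healthy_size: int = 130
    n_factors: int = 7
    factor_separation: float = 3.0
    communality: float = 0.5
    sd_scale: float = 1.0
    feature_overrides: dict[str, list[tuple[float, float]]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) < 2:
            raise ValueError("need at least two clusters")
        if any(n <= 0 for n in self.cluster_sizes) or self.healthy_size < 0:
            raise ValueError("group sizes must be positive")
        if not 0.0 <= self.communality < 1.0:
            raise ValueError("communality must be in [0, 1)")
        for name, rows in self.feature_overrides.items():
            if len(rows) != len(self.cluster_sizes) + 1:
                raise ValueError(
                    f"override for {name!r} must give (mean, sd) per cluster plus healthy"
                )


def _base_params(metric: str, region: str) -> tuple[float, float]:
    if (metric, region) in _BASE_PARAMS:
        return _BASE_PARAMS[(metric, region)]
    if (metric, None) in _BASE_PARAMS:
        return _BASE_PARAMS[(metric, None)]
    raise KeyError(f"no base parameters for metric {metric!r}")


def _clip(metric: str, x: np.ndarray) -> np.ndarray:
    lo, hi = _CLIP_RANGES.get(metric, (-np.inf, np.inf))
    return np.clip(x, lo, hi)


def _factor_means(spec: CohortSpec) -> np.ndarray:
    """(n_groups+1, n_factors) factor means; healthy row last = cluster 1's."""
    k = len(spec.cluster_sizes)
    mu = np.zeros((k + 1, spec.n_factors))
    for c in range(k):
        mu[c, c % spec.n_factors] = spec.factor_separation
    mu[k] = mu[0]
    return mu


def _loadings(spec: CohortSpec, n_unprinted: int) -> np.ndarray:
    """(n_unprinted, n_factors) loading matrix: each feature loads on two
    factors (round-robin with an offset to spread pairs), signs alternating,
    squared loadings summing to the communality."""
    L = np.zeros((n_unprinted, spec.n_factors))
    amp = np.sqrt(spec.communality / 2.0)
    for j in range(n_unprinted):
        f1 = j % spec.n_factors
        f2 = (j + 3) % spec.n_factors
        L[j, f1] = amp
        L[j, f2] = amp if j % 2 == 0 else -amp
    return L


def generate_cohort(
    spec: CohortSpec | None = None,
    seed: int | None = None,
    manifest: FeatureManifest | None = None,
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Draw the synthetic cohort: features plus clinical covariates.

    Returns a :class:`FeatureMatrix` whose ``true_cluster`` column holds the
    generating group (1..k smoker clusters, 0 = healthy control) and an
    aligned clinical table.  Identical (spec, seed) pairs give identical
    output.
    """
    spec = spec or CohortSpec()
    seed = spec.seed if seed is None else seed
    manifest = manifest or default_manifest()
    rng = np.random.default_rng(seed)

    printed = dict(PRINTED_FEATURES)
    printed.update(spec.feature_overrides)
    names = manifest.names
    entry_by_name = {e.name: e for e in manifest.entries}
    unprinted = [e for e in manifest.entries if e.name not in printed]
    unprinted_idx = {e.name: j for j, e in enumerate(unprinted)}
    L = _loadings(spec, len(unprinted))
    mu = _factor_means(spec)
    uniq_sd = np.sqrt(1.0 - spec.communality)

    groups = list(range(1, len(spec.cluster_sizes) + 1)) + [0]
    sizes = list(spec.cluster_sizes) + [spec.healthy_size]
    blocks, truth = [], []
    for gi, (g, n) in enumerate(zip(groups, sizes)):
        if n == 0:
            continue
        cols: dict[str, np.ndarray] = {}
        factors = mu[gi] + rng.standard_normal((n, spec.n_factors))
        for name in names:
            if name in printed:
                mean, sd = printed[name][gi]
                z = rng.standard_normal(n)
                x = mean + spec.sd_scale * sd * z
            else:
                idx = unprinted_idx[name]
                e = unprinted[idx]
                base_mean, base_sd = _base_params(e.metric, e.region)
                z = factors @ L[idx] + uniq_sd * rng.standard_normal(n)
                # sd_scale = 0 still keeps the deterministic factor-mean shift
                shift = L[idx] @ mu[gi]
                x = base_mean + base_sd * (shift + spec.sd_scale * (z - shift))
            cols[name] = _clip(entry_by_name[name].metric, x)
        block = pd.DataFrame(cols, columns=names)
        blocks.append(block)
        truth.extend([g] * n)

    data = pd.concat(blocks, ignore_index=True)
    ids = [f"subj_{i:04d}" for i in range(len(data))]
    data.index = pd.Index(ids, name="subject_id")
    truth_s = pd.Series(truth, index=data.index, name="true_cluster")

    clinical = _generate_clinical(spec, groups, sizes, rng)
    clinical.index = data.index
    matrix = FeatureMatrix(data, manifest, truth_s)
    return matrix, clinical


def _generate_clinical(
    spec: CohortSpec, groups: list[int], sizes: list[int], rng: np.random.Generator
) -> pd.DataFrame:
    frames = []
    for gi, (g, n) in enumerate(zip(groups, sizes)):
        if n == 0:
            continue
        cols: dict[str, Any] = {"true_cluster": np.full(n, g)}
        for var, rows in CLINICAL_CONTINUOUS.items():
            mean, sd = rows[gi]
            x = mean + sd * rng.standard_normal(n)
            if var in _COUNT_VARS:
                x = np.round(np.clip(x, 0, None))
            elif var in _FRACTION_VARS:
                x = np.clip(x, 0.0, 1.0)
            elif var in ("fev1_pct_pre", "fvc_pct_pre", "fev1_pct_post", "fvc_pct_post"):
                x = np.clip(x, 0.05, 2.0)
            elif var in ("pack_years", "walk_6min_m"):
                x = np.clip(x, 0.0, None)
            elif var == "age":
                x = np.clip(x, 18.0, 95.0)
            elif var == "bmi":
                x = np.clip(x, 12.0, 60.0)
            cols[var] = x
        for var, (levels, probs) in CLINICAL_CATEGORICAL.items():
            p = np.asarray(probs[gi], dtype=float)
            p = p / p.sum()
            cols[var] = rng.choice(levels, size=n, p=p)
        frames.append(pd.DataFrame(cols))
    return pd.concat(frames, ignore_index=True)


def smokers_only(matrix: FeatureMatrix) -> FeatureMatrix:
    """Restrict a cohort matrix to the smoker clusters (true_cluster > 0)."""
    if matrix.true_cluster is None:
        raise ValueError("matrix has no true_cluster ground truth")
    keep = matrix.true_cluster > 0
    return FeatureMatrix(
        matrix.data.loc[keep], matrix.manifest, matrix.true_cluster.loc[keep]
    )


# --------------------------------------------------------------------------
# Analytic phantoms
# --------------------------------------------------------------------------


@dataclass
class Blob:
    """Spherical region with plateau air fractions (e.g. emphysema bulla or
    an air-trapping pocket).  ``center`` in fractional grid coordinates."""

    center: tuple[float, float, float]
    radius_mm: float
    f_air_tlc: float
    f_air_rv: float


@dataclass
class PhantomSpec:
    """Analytic two-ellipsoid lung phantom.

    The right and left lungs are axis-aligned ellipsoids; lobes are fixed
    fractional z-planes (right: RLL below 0.40, RML 0.40-0.65, RUL above;
    left: LLL below 0.50, LUL above, as fractions of the ellipsoid z-extent).
    Air fractions are piecewise constant; the displacement model is one of
    ``identity``, ``uniform_scale``, ``axis_scale`` or ``smooth_nonlinear``
    (a sinusoidal diagonal perturbation with an analytic Jacobian).
    """

    grid_shape: tuple[int, int, int] = (44, 44, 56)
    spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    f_air_tlc: float = 0.85
    f_air_rv: float = 0.55
    emph_blob: Blob | None = None
    fsad_blob: Blob | None = None
    displacement_model: dict[str, Any] = field(default_factory=lambda: {"type": "identity"})
    # ellipsoid semi-axes as fractions of the grid physical extent per axis
    semi_axes_frac: tuple[float, float, float] = (0.17, 0.32, 0.42)
    right_split: tuple[float, float] = (0.40, 0.65)
    left_split: float = 0.50

    def __post_init__(self) -> None:
        for f in (self.f_air_tlc, self.f_air_rv):
            if not 0.0 <= f <= 1.0:
                raise ValueError("air fractions must be in [0, 1]")
        model = self.displacement_model
        kind = model.get("type", "identity")
        if kind == "uniform_scale" and model.get("s", 1.0) <= 0:
            raise ValueError("uniform_scale factor must be positive (bijective map)")
        if kind == "axis_scale" and any(s <= 0 for s in model.get("scales", (1, 1, 1))):
            raise ValueError("axis_scale factors must be positive (bijective map)")
        if kind == "smooth_nonlinear":
            amp = np.asarray(model.get("amplitude_mm", (0.0, 0.0, 0.0)), dtype=float)
            omega = self._nonlinear_omega()
            if np.any(np.abs(amp) * omega >= 1.0):
                raise ValueError(
                    "smooth_nonlinear amplitude too large: |a_i|*omega_i must be < 1 "
                    "for a bijective map"
                )
        if kind not in ("identity", "uniform_scale", "axis_scale", "smooth_nonlinear"):
            raise ValueError(f"unknown displacement model {kind!r}")

    def _nonlinear_omega(self) -> np.ndarray:
        extent = np.asarray(self.grid_shape) * np.asarray(self.spacing)
        k = self.displacement_model.get("n_periods", 1)
        return 2.0 * np.pi * k / extent


def _coordinates(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axes = [np.arange(n) * h for n, h in zip(spec.grid_shape, spec.spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _lung_geometry(spec: PhantomSpec) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Lung mask and lobe maps from the two-ellipsoid geometry."""
    x, y, z = _coordinates(spec)
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    a, b, c = (f * e for f, e in zip(spec.semi_axes_frac, extent))
    cy, cz = 0.5 * extent[1], 0.5 * extent[2]
    right_cx, left_cx = 0.28 * extent[0], 0.72 * extent[0]

    def ellipsoid(cx):
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 + ((z - cz) / c) ** 2 <= 1.0

    right = ellipsoid(right_cx)
    left = ellipsoid(left_cx)
    mask = right | left
    z_lo, z_hi = cz - c, cz + c
    zfrac = (z - z_lo) / (z_hi - z_lo)
    lobes = {
        "RLL": right & (zfrac < spec.right_split[0]),
        "RML": right & (zfrac >= spec.right_split[0]) & (zfrac < spec.right_split[1]),
        "RUL": right & (zfrac >= spec.right_split[1]),
        "LLL": left & (zfrac < spec.left_split),
        "LUL": left & (zfrac >= spec.left_split),
    }
    return mask, lobes


def _air_fraction_fields(
    spec: PhantomSpec, mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(f_tlc, f_rv, emph_membership, fsad_membership) on the grid."""
    x, y, z = _coordinates(spec)
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    f_tlc = np.where(mask, spec.f_air_tlc, 0.0)
    f_rv = np.where(mask, spec.f_air_rv, 0.0)

    def membership(blob: Blob) -> np.ndarray:
        cx, cy, cz = (f * e for f, e in zip(blob.center, extent))
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        return mask & (r2 <= blob.radius_mm**2)

    in_fsad = membership(spec.fsad_blob) if spec.fsad_blob else np.zeros_like(mask)
    if spec.fsad_blob:
        f_tlc[in_fsad] = spec.fsad_blob.f_air_tlc
        f_rv[in_fsad] = spec.fsad_blob.f_air_rv
    in_emph = membership(spec.emph_blob) if spec.emph_blob else np.zeros_like(mask)
    if spec.emph_blob:
        f_tlc[in_emph] = spec.emph_blob.f_air_tlc
        f_rv[in_emph] = spec.emph_blob.f_air_rv
    return f_tlc, f_rv, in_emph, in_fsad & ~in_emph


def _displacement_and_jacobian(
    spec: PhantomSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Displacement vectors, analytic per-voxel J and analytic per-voxel ADI."""
    x, y, z = _coordinates(spec)
    extent = np.asarray(spec.grid_shape) * np.asarray(spec.spacing)
    center = 0.5 * extent
    model = spec.displacement_model
    kind = model.get("type", "identity")
    shape = spec.grid_shape
    u = np.zeros(shape + (3,))
    coords = (x, y, z)

    def adi_from_stretches(s: np.ndarray) -> np.ndarray:
        s_sorted = np.sort(s, axis=-1)[..., ::-1]
        l1, l2, l3 = s_sorted[..., 0], s_sorted[..., 1], s_sorted[..., 2]
        return np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)

    if kind == "identity":
        J = np.ones(shape)
        adi = np.zeros(shape)
    elif kind == "uniform_scale":
        s = float(model["s"])
        for i in range(3):
            u[..., i] = (s - 1.0) * (coords[i] - center[i])
        J = np.full(shape, s**3)
        adi = np.zeros(shape)
    elif kind == "axis_scale":
        scales = np.asarray(model["scales"], dtype=float)
        for i in range(3):
            u[..., i] = (scales[i] - 1.0) * (coords[i] - center[i])
        J = np.full(shape, float(np.prod(scales)))
        adi = np.full(shape, float(adi_from_stretches(scales)))
    else:  # smooth_nonlinear: u_i = a_i * sin(omega_i * x_i), diagonal gradient
        amp = np.asarray(model.get("amplitude_mm", (0.0, 0.0, 0.0)), dtype=float)
        omega = spec._nonlinear_omega()
        base = float(model.get("base_scale", 1.0))
        diag = np.empty(shape + (3,))
        for i in range(3):
            u[..., i] = (base - 1.0) * (coords[i] - center[i]) + amp[i] * np.sin(
                omega[i] * coords[i]
            )
            diag[..., i] = base + amp[i] * omega[i] * np.cos(omega[i] * coords[i])
        J = np.prod(diag, axis=-1)
        adi = adi_from_stretches(np.abs(diag))
    return u, J, adi


def generate_phantom(
    spec: PhantomSpec | None = None,
) -> tuple[AirFractionVolume, AirFractionVolume, DisplacementField, dict[str, float]]:
    """Build the phantom volumes, displacement field and analytic ground truth.

    Ground-truth values are computed from the phantom *definition* (geometric
    membership counts and analytic deformation formulas), never through the
    voxel-metric code they are meant to validate.  Keys follow the feature
    naming convention (``"Jacobian Total"``, ``"Emph% RUL"``, ...).
    """
    spec = spec or PhantomSpec()
    mask, lobes = _lung_geometry(spec)
    if not mask.any():
        raise ValueError("phantom lung mask is empty; enlarge the ellipsoids")
    f_tlc, f_rv, in_emph, in_fsad = _air_fraction_fields(spec, mask)
    u, J_true, adi_true = _displacement_and_jacobian(spec)

    tlc = AirFractionVolume(f_tlc, spec.spacing, mask, lobes)
    rv = AirFractionVolume(f_rv, spec.spacing, mask, lobes)
    disp = DisplacementField(u, spec.spacing, mask)

    gt: dict[str, float] = {}
    regions: dict[str, np.ndarray] = {"Total": mask, **lobes}
    voxvol = float(np.prod(spec.spacing))
    dvair = {}
    for name, reg in regions.items():
        n = int(np.count_nonzero(reg))
        gt[f"Jacobian {name}"] = float(J_true[reg].mean())
        gt[f"ADI {name}"] = float(adi_true[reg].mean())
        gt[f"Emph% {name}"] = 100.0 * np.count_nonzero(in_emph & reg) / n
        gt[f"fSAD% {name}"] = 100.0 * np.count_nonzero(in_fsad & reg) / n
        gt[f"beta_tissue {name}"] = float(1.0 - f_tlc[reg].mean())
        dvair[name] = float((f_tlc[reg] - f_rv[reg]).sum() * voxvol)
    if dvair["Total"] > 0:
        for lobe in LOBES:
            gt[f"dVair_frac {lobe}"] = dvair[lobe] / dvair["Total"]
        lower = sum(dvair[lb] for lb in MIDDLE_LOWER_LOBES)
        if lower > 0:
            gt["U_over_ML"] = sum(dvair[lb] for lb in UPPER_LOBES) / lower
    # apical-basal over ventral-dorsal semi-axis ratio
    gt["lung_shape"] = spec.semi_axes_frac[2] * spec.grid_shape[2] * spec.spacing[2] / (
        spec.semi_axes_frac[1] * spec.grid_shape[1] * spec.spacing[1]
    )
    return tlc, rv, disp, gt


# Nominal segment geometry per region: (lumen radius mm, perimeter
# elongation, wall thickness mm, daughter angle deg).  Perimeter elongation
# 1.012 gives circularity ~0.976, the healthy central-airway regime.
_AIRWAY_GEOMETRY: dict[str, tuple[float, float, float, float]] = {
    "Trachea": (9.0, 1.012, 2.5, 70.0),
    "LMB": (6.0, 1.012, 1.6, 72.0),
    "RMB": (6.5, 1.012, 1.7, 68.0),
    "sRUL": (3.2, 1.015, 1.0, 78.0),
    "sRML": (2.8, 1.015, 0.9, 80.0),
    "sRLL": (3.4, 1.015, 1.0, 75.0),
    "sLUL": (3.3, 1.015, 1.0, 77.0),
    "sLLL": (3.5, 1.015, 1.0, 74.0),
}


def generate_airway_table(jitter: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Airway-segment measurement table for a phantom subject.

    ``jitter`` scales multiplicative Gaussian perturbations of the nominal
    geometry (0 gives the deterministic nominal table).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for region in REGIONS:
        r, elong, wt, angle = _AIRWAY_GEOMETRY[region]
        if jitter > 0:
            r *= 1.0 + jitter * rng.standard_normal()
            wt *= 1.0 + jitter * rng.standard_normal()
            angle += 5.0 * jitter * rng.standard_normal()
        area = np.pi * r**2
        perim = 2.0 * np.pi * r * elong
        half = np.radians(angle / 2.0)
        rows.append({
            "region": region,
            "lumen_area": area,
            "lumen_perimeter": perim,
            "wall_thickness": wt,
            "child1_dx": np.sin(half), "child1_dy": 0.0, "child1_dz": -np.cos(half),
            "child2_dx": -np.sin(half), "child2_dy": 0.0, "child2_dz": -np.cos(half),
        })
    return pd.DataFrame(rows)
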