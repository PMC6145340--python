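"""Local structural airway variables from segment-level CT measurements.

Each airway segment is summarised by its lumen area A (mm^2), lumen
perimeter P (mm), wall thickness WT (mm) and branch directions, from which
four local variables are derived:

* hydraulic diameter  D_h = 4A/P      (luminal narrowing),
* circularity         Cr  = 4*pi*A/P^2 (luminal shape; 1 for a circle),
* wall thickness      WT,
* bifurcation angle   theta (degrees) between the two daughter branches.

WT and D_h are additionally normalised by the subject's *predicted* tracheal
WT and D_h from a healthy-control regression on sex, age and height, giving
the starred, dimensionless forms WT* and Dh* that remove inter-subject size
variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Region vocabulary for segment tables (central airways plus the
#: segmental-level groupings per lobe).
REGIONS = ("Trachea", "LMB", "RMB", "sRUL", "sRML", "sRLL", "sLUL", "sLLL")

_ISOPERIMETRIC_TOL = 1e-9


def hydraulic_diameter(area: float, perimeter: float) -> float:
    """D_h = 4A/P (mm); equals the diameter for a circular lumen."""
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be positive")
    return 4.0 * area / perimeter


def circularity(area: float, perimeter: float) -> float:
    """Cr = 4*pi*A/P^2, in (0, 1]; 1 for a circle.

    Values above 1 violate the isoperimetric inequality and indicate an
    inconsistent (A, P) measurement pair.
    """
    area = np.asarray(area, dtype=float)
    perimeter = np.asarray(perimeter, dtype=float)
    if np.any(area <= 0) or np.any(perimeter <= 0):
        raise ValueError("area and perimeter must be positive")
    cr = 4.0 * np.pi * area / perimeter**2
    if np.any(cr > 1.0 + _ISOPERIMETRIC_TOL):
        raise ValueError("Cr > 1: area/perimeter pair violates the isoperimetric inequality")
    return np.minimum(cr, 1.0)


def bifurcation_angle(child1_dir, child2_dir) -> float:
    """Angle (degrees) between the two daughter-branch direction vectors."""
    u = np.asarray(child1_dir, dtype=float)
    v = np.asarray(child2_dir, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("zero-length branch direction vector")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


@dataclass
class TrachealNorm:
    """Linear healthy-control reference predicting tracheal WT and D_h.

    predicted = intercept + b_male*[male] + b_age*(age-50) + b_height*(height-170)

    The default coefficients are a synthetic placeholder reference with
    physiologically plausible magnitudes (tracheal WT ~ 2.5 mm, D_h ~ 17 mm
    for a 50-year-old, 170 cm subject); site-specific references can be
    supplied instead.
    """

    wt_intercept: float = 2.5
    wt_male: float = 0.25
    wt_age: float = 0.004
    wt_height: float = 0.010
    dh_intercept: float = 17.0
    dh_male: float = 1.6
    dh_age: float = 0.01
    dh_height: float = 0.08

    def predict(self, kind: str, sex: str, age: float, height: float) -> float:
        male = 1.0 if str(sex).lower() in ("m", "male", "1") else 0.0
        if kind == "WT":
            pred = (self.wt_intercept + self.wt_male * male
                    + self.wt_age * (age - 50.0) + self.wt_height * (height - 170.0))
        elif kind == "Dh":
            pred = (self.dh_intercept + self.dh_male * male
                    + self.dh_age * (age - 50.0) + self.dh_height * (height - 170.0))
        else:
            raise ValueError(f"kind must be 'WT' or 'Dh', got {kind!r}")
        if pred <= 0:
            raise ValueError("predicted tracheal value is not positive; covariates out of range")
        return float(pred)


def normalize_to_trachea(
    value: float,
    kind: str,
    sex: str,
    age: float,
    height: float,
    norm: TrachealNorm | None = None,
) -> float:
    """Starred (dimensionless) value: measurement / predicted tracheal value."""
    norm = norm or TrachealNorm()
    return float(value) / norm.predict(kind, sex, age, height)


def segment_variables(
    segments: pd.DataFrame,
    sex: str,
    age: float,
    height: float,
    norm: TrachealNorm | None = None,
) -> pd.DataFrame:
    """Per-region local variables (theta, Cr, WT*, Dh*) from a segment table.

    ``segments`` needs columns ``region``, ``lumen_area``, ``lumen_perimeter``,
    ``wall_thickness`` and the daughter-direction columns
    ``child1_dx..dz`` / ``child2_dx..dz``.  Unknown region labels are
    rejected.  Returns a tidy frame with columns (region, variable, value).
    """
    required = {"region", "lumen_area", "lumen_perimeter", "wall_thickness"}
    missing = required - set(segments.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    unknown = set(segments["region"]) - set(REGIONS)
    if unknown:
        raise ValueError(f"unknown airway regions: {sorted(unknown)}")
    norm = norm or TrachealNorm()
    rows = []
    for _, seg in segments.iterrows():
        region = seg["region"]
        a, p = float(seg["lumen_area"]), float(seg["lumen_perimeter"])
        dh = hydraulic_diameter(a, p)
        cr = circularity(a, p)
        theta = bifurcation_angle(
            [seg["child1_dx"], seg["child1_dy"], seg["child1_dz"]],
            [seg["child2_dx"], seg["child2_dy"], seg["child2_dz"]],
        )
        wt_star = normalize_to_trachea(float(seg["wall_thickness"]), "WT", sex, age, height, norm)
        dh_star = normalize_to_trachea(dh, "Dh", sex, age, height, norm)
        rows += [
            {"region": region, "variable": "theta", "value": theta},
            {"region": region, "variable": "Cr", "value": cr},
            {"region": region, "variable": "WT*", "value": wt_star},
            {"region": region, "variable": "Dh*", "value": dh_star},
        ]
    return pd.DataFrame(rows)
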