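"""The multiscale feature manifest and per-subject feature assembly.

The default manifest has 69 imaging variables on three scales:

* 32 *local* structural variables: {theta, Cr, WT*, Dh*} x 8 airway regions,
* 30 *lobar* functional variables: {dVair_frac, Jacobian, ADI, fSAD%, Emph%,
  beta_tissue} x 5 lobes,
* 7 *global* variables: fSAD% Total, Emph% Total, lung_shape, U_over_ML,
  Jacobian Total, ADI Total, beta_tissue Total.

Feature names are "<variable> <region>" (e.g. ``"WT* sRML"``, ``"fSAD% RUL"``)
or the bare global name (``"lung_shape"``, ``"U_over_ML"``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .airway_metrics import REGIONS
from .voxel_metrics import LOBES

LOCAL_VARIABLES = ("theta", "Cr", "WT*", "Dh*")
LOBAR_METRICS = ("dVair_frac", "Jacobian", "ADI", "fSAD%", "Emph%", "beta_tissue")
GLOBAL_FEATURES = (
    "fSAD% Total",
    "Emph% Total",
    "lung_shape",
    "U_over_ML",
    "Jacobian Total",
    "ADI Total",
    "beta_tissue Total",
)


@dataclass(frozen=True)
class ManifestEntry:
    name: str
    scale: str  # local | lobar | global
    metric: str
    region: str


@dataclass
class FeatureManifest:
    """Ordered feature list with per-scale counts enforced at construction."""

    entries: list[ManifestEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate feature names in manifest")
        for e in self.entries:
            if e.scale not in ("local", "lobar", "global"):
                raise ValueError(f"unknown scale {e.scale!r} for {e.name}")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def counts(self) -> dict[str, int]:
        c = {"local": 0, "lobar": 0, "global": 0}
        for e in self.entries:
            c[e.scale] += 1
        c["total"] = len(self.entries)
        return c

    def subset(self, scales: tuple[str, ...]) -> "FeatureManifest":
        return FeatureManifest([e for e in self.entries if e.scale in scales])

    def to_yaml(self, path: str | Path) -> None:
        doc = [vars(e) for e in self.entries]
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureManifest":
        doc = yaml.safe_load(Path(path).read_text())
        return cls([ManifestEntry(**e) for e in doc])


def default_manifest() -> FeatureManifest:
    """The 69-variable manifest: 32 local + 30 lobar + 7 global."""
    entries = []
    for var in LOCAL_VARIABLES:
        for region in REGIONS:
            entries.append(ManifestEntry(f"{var} {region}", "local", var, region))
    for metric in LOBAR_METRICS:
        for lobe in LOBES:
            entries.append(ManifestEntry(f"{metric} {lobe}", "lobar", metric, lobe))
    for name in GLOBAL_FEATURES:
        parts = name.rsplit(" ", 1)
        metric = parts[0] if len(parts) == 2 and parts[1] == "Total" else name
        region = "Total" if len(parts) == 2 and parts[1] == "Total" else "global"
        entries.append(ManifestEntry(name, "global", metric, region))
    m = FeatureManifest(entries)
    c = m.counts()
    assert (c["local"], c["lobar"], c["global"], c["total"]) == (32, 30, 7, 69)
    return m


def assemble_features(
    voxel_summaries: dict[str, float],
    airway_rows: pd.DataFrame,
    manifest: FeatureManifest | None = None,
) -> pd.Series:
    """One named feature vector in manifest order.

    ``voxel_summaries`` maps lobar/global feature names (e.g. ``"Jacobian
    RUL"``, ``"lung_shape"``) to values; ``airway_rows`` is the tidy
    (region, variable, value) frame from
    :func:`micalung.airway_metrics.segment_variables`.  Assembly fails loudly
    on any unresolvable manifest entry or non-finite value.
    """
    manifest = manifest or default_manifest()
    airway_lookup = {
        (r["variable"], r["region"]): float(r["value"])
        for _, r in airway_rows.iterrows()
    }
    values = []
    for e in manifest.entries:
        if e.scale == "local":
            key = (e.metric, e.region)
            if key not in airway_lookup:
                raise KeyError(f"manifest entry {e.name!r} not found in airway rows")
            v = airway_lookup[key]
        else:
            if e.name not in voxel_summaries:
                raise KeyError(f"manifest entry {e.name!r} not found in voxel summaries")
            v = float(voxel_summaries[e.name])
        if not np.isfinite(v):
            raise ValueError(f"non-finite value for feature {e.name!r}")
        values.append(v)
    return pd.Series(values, index=manifest.names, dtype=float)


@dataclass
class FeatureMatrix:
    """Cohort feature table (subjects x manifest features).

    ``true_cluster`` carries the generating cluster label for synthetic
    cohorts (0 = healthy control, 1..4 = smoker clusters); it is hidden
    ground truth, never an input to the analysis.
    """

    data: pd.DataFrame  # index: subject_id, columns: manifest names
    manifest: FeatureManifest
    true_cluster: pd.Series | None = None

    def __post_init__(self) -> None:
        if list(self.data.columns) != self.manifest.names:
            raise ValueError("feature matrix columns do not match manifest order")
        if self.data.isna().any().any():
            bad = self.data.isna().stack()
            row, col = bad[bad].index[0]
            raise ValueError(f"missing value at subject {row!r}, feature {col!r}")

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)


def write_feature_matrix(matrix: FeatureMatrix, path: str | Path) -> None:
    """Write as delimited text: subject_id first, features in manifest order."""
    df = matrix.data.copy()
    if matrix.true_cluster is not None:
        df["true_cluster"] = matrix.true_cluster
    df.to_csv(path, index_label="subject_id")


def read_feature_matrix(
    path: str | Path,
    manifest: FeatureManifest | None = None,
) -> FeatureMatrix:
    """Read a feature matrix, validating the header against the manifest."""
    manifest = manifest or default_manifest()
    df = pd.read_csv(path, index_col="subject_id")
    truth = None
    if "true_cluster" in df.columns:
        truth = df.pop("true_cluster")
    extra = [c for c in df.columns if c not in manifest.names]
    missing = [c for c in manifest.names if c not in df.columns]
    if extra or missing:
        raise ValueError(
            f"feature matrix header mismatch: unexpected={extra[:5]}, missing={missing[:5]}"
        )
    df = df[manifest.names]
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad_rows = df.index[pd.to_numeric(df[col], errors="coerce").isna()].tolist()
            raise ValueError(f"non-numeric cells in column {col!r}, rows {bad_rows[:5]}")
    return FeatureMatrix(df.astype(float), manifest, truth)
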