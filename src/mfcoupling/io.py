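"""Tabular file formats and run configuration.

Everything is interchange-friendly TSV: voxel samples in long format
(subject_id, region_index, value), matrices as labelled square tables,
time series as T x R tables with region columns, plus cohort, partition,
centroid and coupling tables.  Matrices are serialized with 6 significant
digits and validated (symmetry to 1e-9, range checks by matrix kind) on
read; region indices are 1-based in every file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .coupling import CouplingMap, NetworkPartition
from .exceptions import ValidationError
from .funcnet import ConnectivityMatrix, RegionalTimeseries
from .morphnet import SimilarityMatrix, VoxelSampleSet

__all__ = [
    "RunConfig",
    "read_voxel_samples",
    "write_voxel_samples",
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_cohort_table",
    "write_cohort_table",
    "read_partition",
    "write_partition",
    "read_centroids",
    "write_centroids",
    "read_coupling_wide",
    "write_coupling_wide",
    "write_metadata",
]

MATRIX_FLOAT_FMT = "%.6g"


# ---------------------------------------------------------------------------
# voxel samples
# ---------------------------------------------------------------------------


def read_voxel_samples(path: str | Path) -> dict[str, VoxelSampleSet]:
    """Read long-format voxel samples grouped into per-subject sample sets."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str},
                     float_precision="round_trip")
    required = ["subject_id", "region_index", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    region = pd.to_numeric(df["region_index"], errors="coerce")
    bad = region.isna() | (region != region.astype("Int64").astype(float))
    if bad.any():
        line = int(bad.idxmax()) + 2
        raise ValidationError(f"{path}: non-integer region_index at line {line}")
    region = region.astype(int)
    if (region < 1).any():
        line = int((region < 1).idxmax()) + 2
        raise ValidationError(
            f"{path}: region_index must be 1-based (>= 1), line {line}"
        )
    value = pd.to_numeric(df["value"], errors="coerce")
    if value.isna().any():
        line = int(value.isna().idxmax()) + 2
        raise ValidationError(f"{path}: non-numeric value at line {line}")

    out: dict[str, VoxelSampleSet] = {}
    df = df.assign(region_index=region, value=value)
    for sid, sub in df.groupby("subject_id", sort=True):
        regions = sorted(sub["region_index"].unique())
        if regions != list(range(1, len(regions) + 1)):
            raise ValidationError(
                f"{path}: subject {sid} regions are not contiguous 1..R"
            )
        samples = [
            sub.loc[sub["region_index"] == r, "value"].to_numpy(dtype=float)
            for r in regions
        ]
        out[str(sid)] = VoxelSampleSet(
            subject_id=str(sid), samples=samples, region_labels=regions
        )
    return out


def write_voxel_samples(
    subjects: Iterable[VoxelSampleSet], path: str | Path
) -> None:
    frames = []
    for s in subjects:
        for lab, vals in zip(s.region_labels, s.samples):
            frames.append(
                pd.DataFrame(
                    {
                        "subject_id": s.subject_id,
                        "region_index": lab,
                        "value": vals,
                    }
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def write_matrix(
    matrix: SimilarityMatrix | ConnectivityMatrix, path: str | Path
) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.region_labels, columns=matrix.region_labels
    )
    df.to_csv(path, sep="\t", float_format=MATRIX_FLOAT_FMT, index_label="region")


def read_matrix(
    path: str | Path, kind: str
) -> SimilarityMatrix | ConnectivityMatrix:
    """Read a labelled square matrix; ``kind`` is "msn" or "fcn"."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy(dtype=float)
    if values.shape[0] != values.shape[1]:
        raise ValidationError(f"{path}: matrix is not square")
    labels = [int(c) for c in df.columns]
    if [int(i) for i in df.index] != labels:
        raise ValidationError(f"{path}: row and column labels differ")
    if not np.allclose(values, values.T, atol=1e-9):
        raise ValidationError(f"{path}: matrix asymmetric beyond 1e-9")
    values = (values + values.T) / 2.0
    off = values[~np.eye(len(labels), dtype=bool)]
    if kind == "msn":
        if off.size and (off.min() <= 0 or off.max() > 1 + 1e-9):
            raise ValidationError(f"{path}: similarity entries outside (0, 1]")
        np.fill_diagonal(values, 1.0)
        return SimilarityMatrix(values=values, region_labels=labels)
    if kind == "fcn":
        if off.size and (off.min() < -1 - 1e-9 or off.max() > 1 + 1e-9):
            raise ValidationError(f"{path}: correlations outside [-1, 1]")
        np.fill_diagonal(values, 1.0)
        return ConnectivityMatrix(values=values, region_labels=labels)
    raise ValueError(f"unknown matrix kind {kind!r}")


# ---------------------------------------------------------------------------
# time series, cohort, partition, centroids, coupling
# ---------------------------------------------------------------------------


def write_timeseries(series: RegionalTimeseries, path: str | Path) -> None:
    pd.DataFrame(series.values, columns=series.region_labels).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_timeseries(path: str | Path, subject_id: str = "") -> RegionalTimeseries:
    df = pd.read_csv(Path(path), sep="\t", float_precision="round_trip")
    return RegionalTimeseries(
        subject_id=subject_id or Path(path).stem,
        values=df.to_numpy(dtype=float),
        region_labels=[int(c) for c in df.columns],
    )


def write_cohort_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", dtype={"subject_id": str, "site": str})


def write_partition(partition: NetworkPartition, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_index": list(partition.mapping),
            "network_label": [partition.mapping[r] for r in partition.mapping],
        }
    ).to_csv(path, sep="\t", index=False)


def read_partition(path: str | Path) -> NetworkPartition:
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("region_index", "network_label"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col}")
    return NetworkPartition(
        dict(zip(df["region_index"].astype(int), df["network_label"].astype(str)))
    )


def write_centroids(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_centroids(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t")
    required = {"region", "hemisphere", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise ValidationError(f"{path}: centroid table needs {sorted(required)}")
    return df.sort_values("region").reset_index(drop=True)


def write_coupling_wide(df: pd.DataFrame, path: str | Path) -> None:
    """Write a subjects-by-regions coupling table (index subject_id)."""
    df.to_csv(path, sep="\t", index_label="subject_id", float_format="%.17g")


def read_coupling_wide(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", index_col="subject_id",
                     float_precision="round_trip")
    df.columns = [int(c) for c in df.columns]
    return df


def coupling_long_table(
    maps: Iterable[CouplingMap], partition: NetworkPartition
) -> pd.DataFrame:
    """Cohort-level long table (subject, region, network, value)."""
    rows = []
    for m in maps:
        for lab, val in zip(m.region_labels, m.values):
            rows.append(
                {
                    "subject_id": m.subject_id,
                    "region_index": lab,
                    "network_label": partition.network_of(lab),
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def write_metadata(path: str | Path, **entries) -> None:
    """JSON sidecar describing how an artifact was produced."""
    with open(path, "w") as fh:
        json.dump(entries, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Configuration of an end-to-end pipeline run."""

    out_dir: str = "results"
    seed: int = 0
    grid_size: int = 128
    fdr_threshold: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "education", "mean_fd")
    n_perm: int = 1000
    simulate: Mapping | None = None  # CohortConfig overrides, or None
    voxels_path: str | None = None
    timeseries_dir: str | None = None
    cohort_path: str | None = None
    partition_path: str | None = None
    centroids_path: str | None = None

    def __post_init__(self) -> None:
        if self.grid_size < 8:
            raise ValidationError("grid_size must be >= 8")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must lie in (0, 1)")
        if self.n_perm < 100:
            raise ValidationError("n_perm must be >= 100")
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValidationError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)
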