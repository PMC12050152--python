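"""End-to-end orchestration: simulate -> MSN -> FCN -> couple -> compare.

Every stage writes its artifacts as TSV plus a JSON metadata sidecar
(config, seed, package version); all randomness flows from the single
configured seed, so a rerun with the same config produces byte-identical
result tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as mfio
from .coupling import NetworkPartition, global_coupling, regional_coupling
from .funcnet import build_fcn
from .morphnet import build_msn
from .stats import CohortTable, PipelineConfig, group_pipeline
from .synthetic import CohortConfig, generate_cohort

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)


def _config_hash(config: mfio.RunConfig) -> str:
    blob = repr(dataclasses.asdict(config)).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _sidecar(path: Path, config: mfio.RunConfig, stage: str) -> None:
    mfio.write_metadata(
        path,
        stage=stage,
        config_hash=_config_hash(config),
        seed=config.seed,
        version=__version__,
        written=datetime.now(timezone.utc).isoformat(),
    )


def run_pipeline(config: mfio.RunConfig) -> Path:
    """Run the full pipeline described by ``config``; returns the out dir."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        logger.info("simulate: generating synthetic cohort")
        cohort_cfg = CohortConfig(**dict(config.simulate), seed=config.seed)
        cohort = generate_cohort(cohort_cfg)
        voxel_sets = {s.subject_id: s.voxels for s in cohort.subjects}
        series = {s.subject_id: s.timeseries for s in cohort.subjects}
        cohort_df = cohort.cohort
        partition = cohort.partition
        centroids = cohort.centroids
        mfio.write_cohort_table(cohort_df, out / "cohort.tsv")
        mfio.write_partition(partition, out / "partition.tsv")
        mfio.write_centroids(centroids, out / "centroids.tsv")
        _sidecar(out / "cohort.meta.json", config, "simulate")
    else:
        if not (config.voxels_path and config.timeseries_dir and config.cohort_path
                and config.partition_path):
            raise mfio.ValidationError(
                "config needs either a simulate block or paths to voxels, "
                "time series, cohort and partition"
            )
        logger.info("load: reading inputs")
        voxel_sets = mfio.read_voxel_samples(config.voxels_path)
        ts_dir = Path(config.timeseries_dir)
        series = {
            sid: mfio.read_timeseries(ts_dir / f"{sid}.tsv", sid)
            for sid in voxel_sets
        }
        cohort_df = mfio.read_cohort_table(config.cohort_path)
        partition = mfio.read_partition(config.partition_path)
        centroids = (
            mfio.read_centroids(config.centroids_path)
            if config.centroids_path
            else None
        )

    msn_dir, fcn_dir = out / "msn", out / "fcn"
    msn_dir.mkdir(exist_ok=True)
    fcn_dir.mkdir(exist_ok=True)

    maps = []
    global_rows = []
    for sid in sorted(voxel_sets):
        logger.info("msn/fcn/couple: subject %s", sid)
        msn = build_msn(voxel_sets[sid], n_grid=config.grid_size)
        fcn = build_fcn(series[sid])
        mfio.write_matrix(msn, msn_dir / f"{sid}_msn.tsv")
        mfio.write_matrix(fcn, fcn_dir / f"{sid}_fcn.tsv")
        cmap = regional_coupling(msn, fcn)
        cmap.subject_id = sid
        maps.append(cmap)
        global_rows.append(
            {
                "subject_id": sid,
                "global_pairs": global_coupling(msn, fcn, method="pairs"),
                "regional_mean": float(cmap.values.mean()),
            }
        )

    wide = pd.DataFrame(
        [m.values for m in maps],
        index=[m.subject_id for m in maps],
        columns=maps[0].region_labels,
    )
    mfio.write_coupling_wide(wide, out / "coupling_regional.tsv")
    pd.DataFrame(global_rows).to_csv(
        out / "coupling_global.tsv", sep="\t", index=False, float_format="%.17g"
    )
    long = mfio.coupling_long_table(maps, partition)
    long.to_csv(out / "coupling_long.tsv", sep="\t", index=False,
                float_format="%.17g")
    _sidecar(out / "coupling.meta.json", config, "couple")

    logger.info("compare: group-level inference")
    table = CohortTable(cohort_df)
    result = group_pipeline(
        wide,
        table,
        partition,
        PipelineConfig(
            fdr_threshold=config.fdr_threshold, covariates=config.covariates
        ),
    )
    result.regional.to_frame().to_csv(
        out / "compare_regional.tsv", sep="\t", index=False, float_format="%.6g"
    )
    result.network.to_frame().to_csv(
        out / "compare_network.tsv", sep="\t", index=False, float_format="%.6g"
    )
    pd.DataFrame(
        [{"z": result.global_z, "p": result.global_p}]
    ).to_csv(out / "compare_global.tsv", sep="\t", index=False,
             float_format="%.6g")
    if len(result.symptom):
        result.symptom.to_csv(
            out / "symptom_correlations.tsv", sep="\t", index=False,
            float_format="%.6g"
        )
    _sidecar(out / "compare.meta.json", config, "compare")
    logger.info("pipeline complete: %s", out)
    return out
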