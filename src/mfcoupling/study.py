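"""Convenience driver: synthetic cohort -> networks -> coupling table.

Used by simulation studies (calibration, power, recovery) and examples;
the file-based pipeline in :mod:`mfcoupling.pipeline` does the same through
TSV artifacts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .coupling import NetworkPartition, regional_coupling
from .funcnet import build_fcn
from .morphnet import SimilarityMatrix, build_msn
from .synthetic import (
    CohortConfig,
    default_partition,
    iter_subjects,
    planted_similarity_matrix,
)

__all__ = ["coupling_study"]


def coupling_study(
    config: CohortConfig,
    seed: int | None = None,
    morphology: str = "estimated",
    n_grid: int = 128,
) -> tuple[pd.DataFrame, pd.DataFrame, NetworkPartition]:
    """Generate a cohort and compute every subject's regional coupling map.

    Returns (coupling table: subjects x regions, cohort covariate table,
    network partition).

    ``morphology`` selects the morphological network used for coupling:
    ``"estimated"`` builds each subject's MSN from its voxel samples (the
    full pipeline); ``"planted"`` substitutes the closed-form Gaussian
    similarity matrix, which large-voxel-count runs approach, and is the
    economical choice for many-repetition simulation studies where only the
    functional side varies with the planted effects.
    """
    cfg = config.resolved()
    labels = list(range(1, cfg.n_regions + 1))
    planted = None
    if morphology == "planted":
        planted = SimilarityMatrix(
            values=planted_similarity_matrix(cfg.region_mu, cfg.region_sigma),
            region_labels=labels,
        )
    elif morphology != "estimated":
        raise ValueError(f"unknown morphology {morphology!r}")

    rows, feats, sids = [], [], []
    for s in iter_subjects(cfg, seed, make_voxels=planted is None):
        msn = planted if planted is not None else build_msn(s.voxels, n_grid=n_grid)
        fcn = build_fcn(s.timeseries)
        feats.append(regional_coupling(msn, fcn).values)
        sids.append(s.subject_id)
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "site": s.site,
                **s.covariates,
            }
        )
    wide = pd.DataFrame(np.vstack(feats), index=sids, columns=labels)
    wide.index.name = "subject_id"
    return wide, pd.DataFrame(rows), default_partition(cfg.n_regions)
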