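"""Synthetic cohorts with known morphology-function coupling ground truth.

Every downstream stage of the pipeline can be validated against quantities
this generator plants explicitly:

* regional gray-matter values are Gaussian with per-region location and
  scale, so the true pairwise similarity matrix ``S_true`` follows the
  closed-form KLS of the symmetric Gaussian Kullback-Leibler divergence
  (:func:`planted_kls_oracle`);
* each subject's functional covariance mixes a monotone transform of
  ``S_true`` with independent noise at a per-region fidelity ``gamma_r``
  in [0, 1], so the rank-based coupling estimate is a monotone function of
  the planted coupling gradient;
* designated networks receive an additive ``group_effect`` on gamma in the
  case group, sites shift/scale gamma (a batch effect on the coupling
  features), and case symptom scores track the subject's planted coupling
  in one designated network.

Regeneration with the same config and seed is bit-identical: all
randomness flows through one ``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .coupling import NetworkPartition, YEO7_LABELS
from .exceptions import ValidationError
from .funcnet import RegionalTimeseries
from .morphnet import VoxelSampleSet

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "SubjectRecord",
    "planted_kls_oracle",
    "planted_similarity_matrix",
    "generate_cohort",
    "iter_subjects",
    "generate_timeseries",
    "nearest_correlation",
    "default_partition",
    "default_centroids",
]

_GOLDEN = 0.6180339887498949


def planted_kls_oracle(
    mu1: float, sigma1: float, mu2: float, sigma2: float
) -> float:
    """Closed-form KLS between two Gaussians.

    The symmetric Gaussian KLD (log terms cancel) is
    D = (s1^2 + dmu^2) / (2 s2^2) + (s2^2 + dmu^2) / (2 s1^2) - 1,
    and the similarity is exp(-D); with equal scales this reduces to
    exp(-dmu^2 / sigma^2).
    """
    if sigma1 <= 0 or sigma2 <= 0:
        raise ValidationError("scales must be strictly positive")
    dmu2 = (mu1 - mu2) ** 2
    d = (
        (sigma1**2 + dmu2) / (2.0 * sigma2**2)
        + (sigma2**2 + dmu2) / (2.0 * sigma1**2)
        - 1.0
    )
    return float(np.exp(-d))


def planted_similarity_matrix(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Pairwise closed-form KLS matrix for Gaussian regions."""
    r = len(mu)
    s = np.eye(r)
    for i in range(r):
        for j in range(i + 1, r):
            s[i, j] = s[j, i] = planted_kls_oracle(mu[i], sigma[i], mu[j], sigma[j])
    return s


def nearest_correlation(
    matrix: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    eig_floor: float = 1e-8,
) -> np.ndarray:
    """Repair a symmetric matrix to a valid correlation matrix.

    Alternates eigenvalue clipping (at ``eig_floor``) with rescaling to a
    unit diagonal until both properties hold to ``tol``; inputs that are
    already valid correlation matrices are fixed points.
    """
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValidationError("input must be a square matrix")
    if not np.allclose(a, a.T, atol=1e-8):
        raise ValidationError("input must be symmetric")
    a = (a + a.T) / 2.0
    for _ in range(max_iter):
        w, v = np.linalg.eigh(a)
        if w.min() >= -tol and np.max(np.abs(np.diag(a) - 1.0)) <= tol:
            break
        w = np.maximum(w, eig_floor)
        a = (v * w) @ v.T
        d = np.sqrt(np.diag(a))
        a = a / np.outer(d, d)
        a = (a + a.T) / 2.0
    np.fill_diagonal(a, 1.0)
    return a


def generate_timeseries(
    cov_target: np.ndarray,
    t: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw a T x R series of i.i.d. zero-mean Gaussian rows.

    ``cov_target`` must be symmetric with a unit diagonal (a repaired
    correlation matrix); the empirical correlation converges to it as T
    grows.
    """
    c = np.asarray(cov_target, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("covariance target must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValidationError("covariance target must be symmetric")
    if not np.allclose(np.diag(c), 1.0, atol=1e-6):
        raise ValidationError("covariance target must have a unit diagonal")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    try:
        factor = np.linalg.cholesky(c)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(c)
        factor = v * np.sqrt(np.maximum(w, 0.0))
    return rng.standard_normal((t, c.shape[0])) @ factor.T


def default_partition(n_regions: int, labels: Sequence[str] = YEO7_LABELS) -> NetworkPartition:
    """Round-robin assignment of regions 1..R to the seven network labels."""
    return NetworkPartition(
        {r + 1: labels[r % len(labels)] for r in range(n_regions)}
    )


def default_centroids(n_regions: int) -> pd.DataFrame:
    """Deterministic unit-sphere centroids, split into two hemispheres.

    A Fibonacci lattice per hemisphere, mirrored across the x = 0 plane;
    the first half of the regions is labelled L, the rest R.
    """
    n_left = (n_regions + 1) // 2
    rows = []
    for region in range(1, n_regions + 1):
        left = region <= n_left
        k = region - 1 if left else region - 1 - n_left
        m = n_left if left else n_regions - n_left
        z = 1.0 - 2.0 * (k + 0.5) / m
        theta = 2.0 * np.pi * k * _GOLDEN
        rho = np.sqrt(max(0.0, 1.0 - z * z))
        x, y = rho * np.cos(theta), rho * np.sin(theta)
        x = -abs(x) if left else abs(x)
        rows.append(
            {
                "region": region,
                "hemisphere": "L" if left else "R",
                "x": x,
                "y": y,
                "z": z,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CohortConfig:
    """Generative parameters of a synthetic cohort.

    Defaults reflect desk-scale study conditions: 96 cortical regions,
    Gaussian gray-matter value distributions, a coupling-fidelity gradient
    spanning [0.15, 0.85], a group effect concentrated in designated
    networks, balanced sites with small batch shifts on the coupling
    parameters, and case symptom scores in the 0-52 range.
    """

    n_regions: int = 96
    n_subjects_per_group: int = 100
    n_voxels_per_region: int = 5000
    timeseries_length: int = 200
    region_mu: np.ndarray | None = None
    region_sigma: np.ndarray | None = None
    coupling_fidelity: np.ndarray | None = None
    group_effect: float = 0.09
    affected_networks: tuple[str, ...] = ("VIS", "SMN", "DAN")
    n_sites: int = 4
    site_shift: np.ndarray | None = None
    site_scale: np.ndarray | None = None
    symptom_link: float = 60.0
    symptom_baseline: float = 22.0
    symptom_noise_sd: float = 5.0
    subject_mu_jitter_sd: float = 0.02
    gamma_subject_sd: float = 0.05
    signal_scale: float = 0.6
    noise_corr_sd: float = 0.3
    seed: int = 0

    def resolved(self) -> "CohortConfig":
        """Fill derived defaults and validate the invariants."""
        r = self.n_regions
        idx = np.arange(r)
        mu = (
            np.asarray(self.region_mu, dtype=float)
            if self.region_mu is not None
            else 3.0 * ((idx * _GOLDEN) % 1.0)
        )
        sigma = (
            np.asarray(self.region_sigma, dtype=float)
            if self.region_sigma is not None
            else 0.8 + 0.4 * ((idx * _GOLDEN**2) % 1.0)
        )
        gamma = (
            np.asarray(self.coupling_fidelity, dtype=float)
            if self.coupling_fidelity is not None
            else np.linspace(0.15, 0.85, r)
        )
        shift = (
            np.asarray(self.site_shift, dtype=float)
            if self.site_shift is not None
            else np.linspace(-0.04, 0.04, self.n_sites)
        )
        scale = (
            np.asarray(self.site_scale, dtype=float)
            if self.site_scale is not None
            else np.ones(self.n_sites)
        )
        cfg = replace(
            self,
            region_mu=mu,
            region_sigma=sigma,
            coupling_fidelity=gamma,
            site_shift=shift,
            site_scale=scale,
        )
        cfg._validate()
        return cfg

    def _validate(self) -> None:
        r = self.n_regions
        if r < 2:
            raise ValidationError("need at least two regions")
        if self.n_voxels_per_region < 2:
            raise ValidationError("n_voxels_per_region must be >= 2")
        if self.timeseries_length < 3:
            raise ValidationError("timeseries_length must be >= 3")
        if self.n_sites < 1:
            raise ValidationError("need at least one site")
        for name in ("region_mu", "region_sigma", "coupling_fidelity"):
            if len(getattr(self, name)) != r:
                raise ValidationError(f"{name} must have length n_regions")
        for name in ("site_shift", "site_scale"):
            if len(getattr(self, name)) != self.n_sites:
                raise ValidationError(f"{name} must have length n_sites")
        if np.any(self.region_sigma <= 0):
            raise ValidationError("region_sigma must be strictly positive")
        if np.any(self.site_scale <= 0):
            raise ValidationError("site_scale must be strictly positive")
        gamma = self.coupling_fidelity
        if np.any(gamma < 0) or np.any(gamma > 1):
            raise ValidationError("coupling_fidelity must lie in [0, 1]")
        if np.any(gamma + self.group_effect > 1) or np.any(
            gamma + self.group_effect < 0
        ):
            raise ValidationError(
                "coupling_fidelity + group_effect must stay within [0, 1]"
            )
        if not (0.0 <= self.symptom_baseline <= 52.0):
            raise ValidationError("symptom_baseline must lie in [0, 52]")


@dataclass
class SubjectRecord:
    """One subject's generated data plus per-subject ground truth."""

    subject_id: str
    group: str
    site: str
    voxels: VoxelSampleSet
    timeseries: RegionalTimeseries
    gamma_subject: np.ndarray
    covariates: dict


@dataclass
class SyntheticCohort:
    """A full generated cohort with its ground truth."""

    config: CohortConfig
    subjects: list[SubjectRecord]
    cohort: pd.DataFrame
    s_true: np.ndarray
    gamma: np.ndarray
    partition: NetworkPartition
    centroids: pd.DataFrame
    region_labels: list[int] = field(default_factory=list)

    @property
    def voxel_samples(self) -> list[VoxelSampleSet]:
        return [s.voxels for s in self.subjects]

    @property
    def timeseries(self) -> list[RegionalTimeseries]:
        return [s.timeseries for s in self.subjects]


def _affected_mask(cfg: CohortConfig, partition: NetworkPartition) -> np.ndarray:
    return np.array(
        [
            partition.network_of(r + 1) in cfg.affected_networks
            for r in range(cfg.n_regions)
        ]
    )


def iter_subjects(
    config: CohortConfig,
    seed: int | None = None,
    make_voxels: bool = True,
) -> Iterator[SubjectRecord]:
    """Generate subjects one at a time (constant memory for large cohorts).

    Case subjects come first (sub-case-000...), then controls, each
    assigned to sites round-robin within group so sites stay balanced
    across groups.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    r = cfg.n_regions
    partition = default_partition(r)
    affected = _affected_mask(cfg, partition)
    s_true = planted_similarity_matrix(cfg.region_mu, cfg.region_sigma)
    sig = cfg.signal_scale * s_true
    np.fill_diagonal(sig, 1.0)
    gamma_net = cfg.coupling_fidelity[affected].mean() if affected.any() else 0.0
    symptom_net = (
        cfg.affected_networks[0] if cfg.affected_networks else YEO7_LABELS[0]
    )
    symptom_mask = np.array(
        [partition.network_of(i + 1) == symptom_net for i in range(r)]
    )

    for group, n_sub in (("case", cfg.n_subjects_per_group),
                         ("control", cfg.n_subjects_per_group)):
        for k in range(n_sub):
            site = k % cfg.n_sites
            sid = f"sub-{group}-{k:03d}"
            age = float(np.clip(rng.normal(35.8, 13.0), 18.0, 65.0))
            sex = "male" if rng.random() < 0.38 else "female"
            education = float(np.clip(rng.normal(12.5, 3.4), 6.0, 22.0))
            mean_fd = float(np.clip(abs(rng.normal(0.13, 0.08)), 0.02, 0.2))

            mu_s = cfg.region_mu + rng.normal(0.0, cfg.subject_mu_jitter_sd, r)
            if make_voxels:
                voxels = VoxelSampleSet(
                    subject_id=sid,
                    samples=[
                        rng.normal(
                            mu_s[i], cfg.region_sigma[i], cfg.n_voxels_per_region
                        )
                        for i in range(r)
                    ],
                )
            else:
                voxels = VoxelSampleSet(subject_id=sid, samples=[[0.0, 1.0]] * r)

            gamma_base = np.clip(
                cfg.coupling_fidelity * cfg.site_scale[site]
                + cfg.site_shift[site]
                + rng.normal(0.0, cfg.gamma_subject_sd, r),
                0.0,
                1.0,
            )
            boost = (
                cfg.group_effect if group == "case" and cfg.group_effect else 0.0
            )
            gamma_s = np.clip(gamma_base + boost * affected, 0.0, 1.0)

            e = rng.normal(0.0, cfg.noise_corr_sd, (r, r))
            e = np.clip((e + e.T) / 2.0, -0.95, 0.95)
            w = (gamma_base[:, None] + gamma_base[None, :]) / 2.0
            if boost:
                # concentrate the group contrast: only pairs internal to the
                # affected networks gain fidelity, so unaffected columns keep
                # their control-group coupling profile
                w = w + boost * np.outer(affected, affected)
            w = np.clip(w, 0.0, 1.0)
            m = w * sig + (1.0 - w) * e
            m = (m + m.T) / 2.0
            np.fill_diagonal(m, 1.0)
            cov = nearest_correlation(m)
            ts = RegionalTimeseries(
                subject_id=sid,
                values=generate_timeseries(cov, cfg.timeseries_length, rng),
            )

            symptom = np.nan
            if group == "case":
                planted = gamma_s[symptom_mask].mean() if symptom_mask.any() else 0.0
                symptom = float(
                    np.clip(
                        cfg.symptom_baseline
                        + cfg.symptom_link * (planted - gamma_net)
                        + rng.normal(0.0, cfg.symptom_noise_sd),
                        0.0,
                        52.0,
                    )
                )

            yield SubjectRecord(
                subject_id=sid,
                group=group,
                site=f"site-{site}",
                voxels=voxels,
                timeseries=ts,
                gamma_subject=gamma_s,
                covariates={
                    "age": age,
                    "sex": sex,
                    "education": education,
                    "mean_fd": mean_fd,
                    "symptom_score": symptom,
                },
            )


def generate_cohort(config: CohortConfig, seed: int | None = None) -> SyntheticCohort:
    """Generate a complete cohort (see :func:`iter_subjects` for streaming)."""
    cfg = config.resolved()
    subjects = list(iter_subjects(cfg, seed))
    rows = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "site": s.site,
            **s.covariates,
        }
        for s in subjects
    ]
    return SyntheticCohort(
        config=cfg,
        subjects=subjects,
        cohort=pd.DataFrame(rows),
        s_true=planted_similarity_matrix(cfg.region_mu, cfg.region_sigma),
        gamma=np.asarray(cfg.coupling_fidelity, dtype=float),
        partition=default_partition(cfg.n_regions),
        centroids=default_centroids(cfg.n_regions),
        region_labels=list(range(1, cfg.n_regions + 1)),
    )
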