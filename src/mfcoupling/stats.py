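"""Group-level inference for coupling analyses.

Covers the full battery used downstream of the coupling maps: covariate
residualization (GLM), Mann-Whitney U group tests at global / regional /
network levels with Benjamini-Hochberg FDR within each family, partial
correlation of network coupling with symptom severity, spatially
constrained (spin) permutation nulls for map-to-map correspondence,
Kolmogorov-Smirnov distribution comparison, and the summary-statistic
tests used for demographic tables (two-sample t from summaries,
chi-square on a 2x2 table).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from statsmodels.stats.multitest import multipletests

from .coupling import NetworkPartition
from .exceptions import (
    AlignmentError,
    UndefinedCorrelationError,
    ValidationError,
)
from .harmonize import combat_harmonize

__all__ = [
    "CohortTable",
    "GroupComparison",
    "SpinResult",
    "PipelineConfig",
    "GroupPipelineResult",
    "residualize",
    "mann_whitney",
    "bh_fdr",
    "partial_correlation",
    "spin_null_pvalue",
    "ks_two_sample",
    "t_from_summary",
    "chi2_2x2",
    "hamd_total_range",
    "group_pipeline",
]

HAMD_N_ITEMS = 17
HAMD_ITEM_MAXIMA = (4,) * 9 + (2,) * 8  # nine 0-4 items, eight 0-2 items


@dataclass
class CohortTable:
    """Validated per-subject covariate table.

    Required columns: subject_id, group ("case"/"control"), site, age, sex
    ("male"/"female"), education, mean_fd; symptom_score is required for
    cases (total severity score in [0, 52]) and may be missing for
    controls.
    """

    df: pd.DataFrame

    REQUIRED = (
        "subject_id",
        "group",
        "site",
        "age",
        "sex",
        "education",
        "mean_fd",
    )

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if df["subject_id"].duplicated().any():
            raise ValidationError("duplicate subject_id in cohort table")
        bad_group = set(df["group"].unique()) - {"case", "control"}
        if bad_group:
            raise ValidationError(f"unknown group labels: {sorted(bad_group)}")
        if df["group"].isna().any() or df["site"].isna().any():
            raise ValidationError("every subject needs a group and a site")
        if "symptom_score" in df.columns:
            score = pd.to_numeric(df["symptom_score"], errors="coerce")
            present = score.dropna()
            if ((present < 0) | (present > 52)).any():
                raise ValidationError("symptom_score outside [0, 52]")
        self.df = df.reset_index(drop=True)

    def design(self, covariates: Sequence[str]) -> np.ndarray:
        """Numeric covariate design (no intercept); sex coded male=1."""
        cols = []
        for c in covariates:
            if c == "sex":
                cols.append((self.df["sex"] == "male").astype(float).to_numpy())
            else:
                cols.append(pd.to_numeric(self.df[c]).to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(self.df), 0))

    @property
    def is_case(self) -> np.ndarray:
        return (self.df["group"] == "case").to_numpy()


@dataclass
class GroupComparison:
    """Per-unit Mann-Whitney results with BH-FDR correction."""

    labels: list
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    direction: np.ndarray  # +1 cases higher, -1 cases lower, 0 tied

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit": self.labels,
                "z": self.z,
                "p": self.p,
                "q": self.q,
                "direction": self.direction,
            }
        )


@dataclass
class SpinResult:
    """Observed map-to-map correlation against a spatial-rotation null."""

    observed: float
    nulls: np.ndarray
    p_spin: float


def residualize(y: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Least-squares residuals of y on [intercept | covariates].

    Raises
    ------
    ValidationError
        If the design (with intercept) is rank deficient; the message names
        the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if covariates is None or np.asarray(covariates).size == 0:
        return y - y.mean(axis=0)
    x = np.atleast_2d(np.asarray(covariates, dtype=float))
    if x.shape[0] != n:
        raise ValidationError("covariate rows do not match y")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        collinear = [
            j
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValidationError(
            f"rank-deficient covariate design; collinear columns: {collinear}"
        )
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


EXACT_MAX_COMBINATIONS = 20000  # ~ C(16, 8); exact enumeration stays cheap


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Two-sided p by full enumeration of the permutation distribution of U."""
    from itertools import combinations

    n = ranks.size
    mean_u = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    obs_dev = abs(u_obs - mean_u)
    hits = total = 0
    for comb in combinations(range(n), n1):
        u = ranks[list(comb)].sum() - offset
        total += 1
        if abs(u - mean_u) >= obs_dev - 1e-9:
            hits += 1
    return hits / total


def mann_whitney(
    x: np.ndarray, y: np.ndarray, method: str = "auto"
) -> tuple[float, float, float]:
    """Mann-Whitney U test.

    Returns (U, z, p): U counts pairs in which x exceeds y (midranks for
    ties), z always comes from the normal approximation with tie-corrected
    variance and continuity correction (z > 0 means x tends to be larger).
    ``method`` selects the p-value: "asymptotic" uses the normal
    approximation, "exact" enumerates the permutation distribution of U
    (tie-aware), and "auto" (default) uses the exact distribution whenever
    the enumeration is small enough -- both groups of size <= 8 -- and the
    approximation otherwise, the standard small-sample convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    diff = u - mean_u
    if var_u <= 0:
        return float(u), 0.0, 1.0
    cc = 0.5 * np.sign(diff)  # continuity correction toward the null
    z = (diff - cc) / np.sqrt(var_u) if diff != 0 else 0.0
    p_asymp = min(1.0, 2.0 * sps.norm.sf(abs(z)))

    if method == "auto":
        method = (
            "exact"
            if _n_choose_k(n, n1) <= EXACT_MAX_COMBINATIONS
            else "asymptotic"
        )
    if method == "exact":
        p = _exact_two_sided_p(ranks, n1, u)
    elif method == "asymptotic":
        p = p_asymp
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(u), float(z), float(p)


def _n_choose_k(n: int, k: int) -> int:
    from math import comb

    return comb(n, k)


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_correlation(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates z.

    Computed as the correlation of the covariate residuals; the p-value
    uses a t distribution with n - k - 2 degrees of freedom (k = number of
    covariates).  With no covariates this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValidationError("x and y must have equal length")
    k = 0
    if z is not None and np.asarray(z).size:
        zmat = np.atleast_2d(np.asarray(z, dtype=float))
        if zmat.shape[0] != n:
            zmat = zmat.T
        k = zmat.shape[1]
    else:
        zmat = None
    if n <= k + 2:
        raise ValidationError("need n > number of covariates + 2")
    rx = residualize(x, zmat)
    ry = residualize(y, zmat)
    sx, sy = rx.std(), ry.std()
    if sx < 1e-12 * max(1.0, np.abs(x).max()) or sy < 1e-12 * max(
        1.0, np.abs(y).max()
    ):
        raise UndefinedCorrelationError(
            "degenerate residuals: x or y is explained by the covariates"
        )
    r = float(np.dot(rx, ry) / (n * sx * sy))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, 0.0
    t = r * np.sqrt(df / (1.0 - r * r))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    a = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(a)
    q = q @ np.diag(np.sign(np.diag(r)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def spin_permutations(
    centroids: pd.DataFrame, n_perm: int, seed: int
) -> np.ndarray:
    """Spatial-rotation permutations of region indices.

    ``centroids`` needs columns hemisphere ("L"/"R") and x, y, z on a unit
    sphere, one row per region in map order.  Each permutation applies one
    random rotation to the left-hemisphere centroids and its
    mirror-reflected counterpart to the right, then matches rotated to
    original centroids one-to-one (optimal assignment), so every null map
    is an exact permutation of the observed map.
    """
    required = {"hemisphere", "x", "y", "z"}
    if not required.issubset(centroids.columns):
        raise ValidationError(f"centroid table needs columns {sorted(required)}")
    xyz = centroids[["x", "y", "z"]].to_numpy(dtype=float)
    if np.isnan(xyz).any():
        raise ValidationError("missing centroid coordinates")
    hemi = centroids["hemisphere"].to_numpy()
    mirror = np.diag([-1.0, 1.0, 1.0])
    rng = np.random.default_rng(seed)
    sides = [np.flatnonzero(hemi == h) for h in ("L", "R")]
    perms = np.empty((n_perm, xyz.shape[0]), dtype=np.intp)
    for t in range(n_perm):
        q = _random_rotation(rng)
        for idx, rot in zip(sides, (q, mirror @ q @ mirror)):
            if idx.size == 0:
                continue
            rotated = xyz[idx] @ rot.T
            cost = np.linalg.norm(
                rotated[:, None, :] - xyz[idx][None, :, :], axis=2
            )
            rows, cols = optimize.linear_sum_assignment(cost)
            perms[t, idx[rows]] = idx[cols]
    return perms


def spin_null_pvalue(
    map_a: np.ndarray,
    map_b: np.ndarray,
    centroids: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpinResult:
    """Spin-test p-value for the Spearman correlation of two regional maps.

    ``map_a`` is permuted by spatial rotations of the region centroids,
    ``map_b`` stays fixed; the two-sided p-value is
    (1 + #{|null| >= |observed|}) / (n_perm + 1).
    """
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    if a.size != b.size:
        raise ValidationError("maps must have equal length")
    if len(centroids) != a.size:
        raise ValidationError("centroid table must cover every region")
    if n_perm < 100:
        raise ValidationError("n_perm must be at least 100")
    observed = float(sps.spearmanr(a, b).statistic)
    perms = spin_permutations(centroids, n_perm, seed)
    ranks_b = sps.rankdata(b)
    nulls = np.empty(n_perm)
    for t in range(n_perm):
        nulls[t] = np.corrcoef(sps.rankdata(a[perms[t]]), ranks_b)[0, 1]
    p = (1.0 + np.sum(np.abs(nulls) >= abs(observed))) / (n_perm + 1.0)
    return SpinResult(observed=observed, nulls=nulls, p_spin=float(p))


def label_permutation_pvalue(
    map_a: np.ndarray,
    map_b: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> SpinResult:
    """Exchangeable-label permutation fallback when centroids are absent."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    observed = float(sps.spearmanr(a, b).statistic)
    ranks_b = sps.rankdata(b)
    ranks_a = sps.rankdata(a)
    nulls = np.empty(n_perm)
    for t in range(n_perm):
        nulls[t] = np.corrcoef(rng.permutation(ranks_a), ranks_b)[0, 1]
    p = (1.0 + np.sum(np.abs(nulls) >= abs(observed))) / (n_perm + 1.0)
    return SpinResult(observed=observed, nulls=nulls, p_spin=float(p))


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be nonempty")
    res = sps.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    kind: str = "welch",
) -> float:
    """Two-sample t statistic from summary statistics.

    ``kind="welch"`` (default) uses unpooled variances; ``kind="pooled"``
    uses the pooled-variance form.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValidationError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValidationError("need at least two observations per group")
    if kind == "welch":
        se = np.sqrt(sd1**2 / n1 + sd2**2 / n2)
    elif kind == "pooled":
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    else:
        raise ValueError(f"unknown kind {kind!r}")
    return float((mean1 - mean2) / se)


def chi2_2x2(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square (no continuity correction) on a 2x2 count table."""
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any():
        raise ValidationError("counts must be nonnegative")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise ValidationError("all table margins must be positive")
    stat = sps.chi2_contingency(counts, correction=False)[0]
    return float(stat)


def hamd_total_range(item_maxima: Sequence[int]) -> tuple[int, int]:
    """(min, max) total of a 17-item severity scale from per-item maxima."""
    maxima = np.asarray(item_maxima)
    if maxima.size != HAMD_N_ITEMS:
        raise ValidationError(f"expected {HAMD_N_ITEMS} item maxima")
    if (maxima < 0).any():
        raise ValidationError("item maxima must be nonnegative")
    return 0, int(maxima.sum())


# ---------------------------------------------------------------------------
# end-to-end group pipeline
# ---------------------------------------------------------------------------


@dataclass
class PipelineConfig:
    """Knobs of the group-level analysis."""

    fdr_threshold: float = 0.05
    covariates: tuple[str, ...] = ("age", "sex", "education", "mean_fd")
    symptom_covariates: tuple[str, ...] = ("age", "sex", "education")
    eb: bool = True
    harmonize: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValidationError("fdr_threshold must lie in (0, 1)")


@dataclass
class GroupPipelineResult:
    regional: GroupComparison
    network: GroupComparison
    global_z: float
    global_p: float
    symptom: pd.DataFrame = field(default_factory=pd.DataFrame)
    harmonized: pd.DataFrame | None = None


def _compare_units(
    features: np.ndarray, labels: list, is_case: np.ndarray
) -> GroupComparison:
    zs, ps = np.empty(features.shape[1]), np.empty(features.shape[1])
    for j in range(features.shape[1]):
        _, zs[j], ps[j] = mann_whitney(
            features[is_case, j], features[~is_case, j]
        )
    return GroupComparison(
        labels=list(labels),
        z=zs,
        p=ps,
        q=bh_fdr(ps),
        direction=np.sign(zs).astype(int),
    )


def group_pipeline(
    coupling: pd.DataFrame,
    cohort: CohortTable,
    partition: NetworkPartition,
    config: PipelineConfig | None = None,
) -> GroupPipelineResult:
    """Site harmonization, covariate adjustment, and group tests.

    ``coupling`` is a subjects-by-regions wide table (index subject_id,
    columns region labels).  The sequence is: ComBat on the regional
    features (site as batch, group + covariates protected) -> pooled
    residualization on the nuisance covariates (group excluded from that
    design) -> Mann-Whitney case-vs-control tests per region, per network
    (mean of member regions), and globally (mean over all regions) ->
    BH-FDR within the region family and within the network family ->
    partial correlation of case-group network coupling with the symptom
    score for networks passing the FDR threshold, FDR-corrected over the
    tested networks.
    """
    config = config or PipelineConfig()
    order = cohort.df["subject_id"].tolist()
    if set(coupling.index) != set(order):
        raise AlignmentError("coupling table subjects do not match cohort")
    features = coupling.loc[order].to_numpy(dtype=float)
    region_labels = list(coupling.columns)
    for lab in region_labels:
        partition.network_of(lab)  # raises on unassigned regions

    covariates = cohort.design(config.covariates)
    is_case = cohort.is_case
    if config.harmonize:
        protected = np.column_stack([is_case.astype(float), covariates])
        features = combat_harmonize(
            features, cohort.df["site"].to_numpy(), protected, eb=config.eb
        )
    harmonized = pd.DataFrame(features, index=order, columns=region_labels)

    resid = residualize(features, covariates)
    regional = _compare_units(resid, region_labels, is_case)

    networks = partition.networks
    net_features = np.column_stack(
        [
            features[:, [region_labels.index(r) for r in partition.members(n)
                         if r in region_labels]].mean(axis=1)
            for n in networks
        ]
    )
    net_resid = residualize(net_features, covariates)
    network = _compare_units(net_resid, networks, is_case)

    global_feature = features.mean(axis=1)
    global_resid = residualize(global_feature, covariates)
    _, global_z, global_p = mann_whitney(
        global_resid[is_case], global_resid[~is_case]
    )

    rows = []
    hit = [n for n, q in zip(networks, network.q) if q < config.fdr_threshold]
    if hit and "symptom_score" in cohort.df.columns:
        case_df = cohort.df[is_case]
        score = pd.to_numeric(case_df["symptom_score"], errors="coerce")
        ok = score.notna().to_numpy()
        if ok.sum() > len(config.symptom_covariates) + 2:
            zcov = CohortTable(case_df[ok]).design(config.symptom_covariates)
            for n in hit:
                vals = net_features[is_case, networks.index(n)][ok]
                r, p = partial_correlation(vals, score[ok].to_numpy(), zcov)
                rows.append({"network": n, "r": r, "p": p})
    symptom = pd.DataFrame(rows)
    if len(symptom):
        symptom["q"] = bh_fdr(symptom["p"].to_numpy())

    return GroupPipelineResult(
        regional=regional,
        network=network,
        global_z=float(global_z),
        global_p=float(global_p),
        symptom=symptom,
        harmonized=harmonized,
    )
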