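"""Morphology-function coupling (MFC).

Regional coupling for region r is the Spearman rank correlation between
column r of the subject's morphological similarity network and column r of
the functional connectivity network, with the self-connection (r, r)
removed from both columns.  Doing this for all regions gives the subject's
R-dimensional coupling map.  Global coupling pools all unique off-diagonal
pairs of the two matrices into a single Spearman correlation.  Because the
statistic is rank-based, any strictly increasing transform of either
network leaves every coupling value unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .exceptions import AlignmentError, UndefinedCorrelationError, ValidationError
from .funcnet import ConnectivityMatrix
from .morphnet import SimilarityMatrix

__all__ = [
    "CouplingMap",
    "NetworkPartition",
    "YEO7_LABELS",
    "regional_coupling",
    "global_coupling",
    "network_coupling",
    "cohort_mean_map",
]

YEO7_LABELS = ("VIS", "SMN", "DAN", "VAN", "LIM", "FPN", "DMN")


@dataclass
class CouplingMap:
    """Per-region coupling values for one subject, each in [-1, 1]."""

    subject_id: str
    values: np.ndarray
    region_labels: Sequence[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = list(self.region_labels)
        if self.values.ndim != 1:
            raise ValidationError("coupling values must be a 1-D vector")
        if len(self.region_labels) != self.values.size:
            raise ValidationError("region_labels length does not match values")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValidationError("coupling values must lie in [-1, 1]")


@dataclass
class NetworkPartition:
    """Assignment of every region to exactly one network label."""

    mapping: Mapping[int, str]

    def __post_init__(self) -> None:
        self.mapping = dict(self.mapping)
        if not self.mapping:
            raise ValidationError("empty partition")
        for region, net in self.mapping.items():
            if not str(net):
                raise ValidationError(f"region {region} has an empty network label")

    @property
    def networks(self) -> list[str]:
        """Network labels in first-appearance order."""
        seen: dict[str, None] = {}
        for net in self.mapping.values():
            seen.setdefault(net, None)
        return list(seen)

    def members(self, network: str) -> list[int]:
        return [r for r, n in self.mapping.items() if n == network]

    def network_of(self, region: int) -> str:
        try:
            return self.mapping[region]
        except KeyError:
            raise ValidationError(f"region {region} is not assigned to a network")


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    if np.unique(a).size < 2 or np.unique(b).size < 2:
        raise UndefinedCorrelationError("constant column: Spearman is undefined")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def _check_aligned(msn: SimilarityMatrix, fcn: ConnectivityMatrix) -> None:
    if list(msn.region_labels) != list(fcn.region_labels):
        raise AlignmentError("MSN and FCN region labels do not match")


def regional_coupling(msn: SimilarityMatrix, fcn: ConnectivityMatrix) -> CouplingMap:
    """Column-wise Spearman coupling map (self-connections excluded)."""
    _check_aligned(msn, fcn)
    m, f = msn.values, fcn.values
    r = m.shape[0]
    idx = np.arange(r)
    values = np.empty(r)
    for i in range(r):
        a = m[idx != i, i]
        b = f[idx != i, i]
        if a.min() == a.max() or b.min() == b.max():
            raise UndefinedCorrelationError(
                f"constant column for region {msn.region_labels[i]}"
            )
        ra = stats.rankdata(a)
        rb = stats.rankdata(b)
        ra -= ra.mean()
        rb -= rb.mean()
        values[i] = np.dot(ra, rb) / np.sqrt(np.dot(ra, ra) * np.dot(rb, rb))
    return CouplingMap(
        subject_id=getattr(msn, "subject_id", "") or "",
        values=values,
        region_labels=msn.region_labels,
    )


def global_coupling(
    msn: SimilarityMatrix, fcn: ConnectivityMatrix, method: str = "pairs"
) -> float:
    """Whole-brain coupling scalar.

    ``method="pairs"`` (primary) is the Spearman correlation over the
    R(R-1)/2 unique off-diagonal entries of the two matrices;
    ``method="regional-mean"`` is the mean of the regional coupling map,
    reported alongside as an alternative summary.
    """
    _check_aligned(msn, fcn)
    if method == "pairs":
        iu = np.triu_indices(msn.values.shape[0], k=1)
        return _spearman(msn.values[iu], fcn.values[iu])
    if method == "regional-mean":
        return float(np.mean(regional_coupling(msn, fcn).values))
    raise ValueError(f"unknown method {method!r}")


def network_coupling(
    coupling_map: CouplingMap, partition: NetworkPartition
) -> dict[str, float]:
    """Mean coupling over member regions, per network label."""
    idx: dict[str, list[int]] = {}
    for i, region in enumerate(coupling_map.region_labels):
        idx.setdefault(partition.network_of(region), []).append(i)
    return {
        net: float(np.mean(coupling_map.values[members]))
        for net, members in ((n, idx[n]) for n in partition.networks if n in idx)
    }


def cohort_mean_map(maps: Iterable[CouplingMap]) -> CouplingMap:
    """Elementwise mean coupling map across subjects."""
    maps = list(maps)
    if not maps:
        raise ValidationError("cannot average an empty collection of maps")
    labels = maps[0].region_labels
    for m in maps[1:]:
        if m.region_labels != labels:
            raise AlignmentError("coupling maps have mismatched region labels")
    stacked = np.vstack([m.values for m in maps])
    return CouplingMap(
        subject_id="cohort_mean", values=stacked.mean(axis=0), region_labels=labels
    )
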