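"""Functional connectivity networks from regional time series.

A subject's functional network is the R x R matrix of Pearson correlations
between the mean BOLD time series of every region pair.  Preprocessing
(filtering, nuisance regression) is assumed to have happened upstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import UndefinedCorrelationError, ValidationError

__all__ = ["RegionalTimeseries", "ConnectivityMatrix", "build_fcn"]


@dataclass
class RegionalTimeseries:
    """T x R matrix of regional time series (volumes by regions)."""

    subject_id: str
    values: np.ndarray
    region_labels: Sequence[int] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("time series must be a 2-D (T x R) array")
        if self.values.shape[0] < 3:
            raise ValidationError("need at least 3 time points")
        if np.isnan(self.values).any():
            raise ValidationError("time series contain missing values")
        if self.region_labels is None:
            self.region_labels = list(range(1, self.values.shape[1] + 1))
        self.region_labels = list(self.region_labels)
        if len(self.region_labels) != self.values.shape[1]:
            raise ValidationError("region_labels length does not match columns")

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """R x R Pearson correlation matrix, symmetric, unit diagonal."""

    values: np.ndarray
    region_labels: Sequence[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = list(self.region_labels)
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("connectivity matrix must be square")
        if len(self.region_labels) != v.shape[0]:
            raise ValidationError("region_labels length does not match matrix")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("connectivity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0, atol=1e-9):
            raise ValidationError("connectivity matrix diagonal must be 1")
        if v.min() < -1 - 1e-9 or v.max() > 1 + 1e-9:
            raise ValidationError("correlations must lie in [-1, 1]")


def build_fcn(series: RegionalTimeseries) -> ConnectivityMatrix:
    """Pearson correlation matrix over all region pairs.

    Raises
    ------
    UndefinedCorrelationError
        If any region's time series has zero variance (offending region
        labels are listed).
    """
    x = series.values
    sd = x.std(axis=0)
    bad = [lab for lab, s in zip(series.region_labels, sd) if s == 0]
    if bad:
        raise UndefinedCorrelationError(
            f"zero-variance time series for regions: {bad}"
        )
    corr = np.corrcoef(x, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return ConnectivityMatrix(values=corr, region_labels=series.region_labels)
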