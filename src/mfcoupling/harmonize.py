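"""Empirical-Bayes location/scale harmonization of multi-site features (ComBat).

Per feature, the model is

    x_{sg} = alpha_g + X_s beta_g + gamma_{bg} + delta_{bg} eps_{sg}

with site/batch b, protected covariate design X (group membership and
nuisance covariates whose effects must survive harmonization), additive
site effect gamma and multiplicative site effect delta.  Features are
standardized preserving covariate effects; per-site location/scale
estimates are shrunk toward site-level priors (normal for gamma,
inverse-gamma for delta^2, moment-matched) by an iterative conditional
posterior-mean solver; the shrunken effects are removed and the covariate
effects restored.

With a single site there is nothing to remove: the standardize/restore
round trip returns the input (to numerical precision), and the
empirical-Bayes step is skipped because its across-site prior moments are
degenerate.
"""

from __future__ import annotations

import logging
from collections import Counter
from typing import Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = ["combat_harmonize"]

logger = logging.getLogger(__name__)

MIN_SUBJECTS_PER_SITE = 2
RECOMMENDED_SUBJECTS_PER_SITE = 10  # inclusion threshold used upstream


def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_solve(z_batch, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    n = z_batch.shape[0]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((z_batch - g_new[None, :]) ** 2).sum(axis=0)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def combat_harmonize(
    features: np.ndarray,
    site: Sequence,
    covariates: np.ndarray | None = None,
    eb: bool = True,
) -> np.ndarray:
    """Harmonize a subjects-by-units feature matrix across sites.

    Parameters
    ----------
    features
        (n_subjects, n_units) matrix.
    site
        Per-subject site/batch labels (length n_subjects).
    covariates
        Optional (n_subjects, p) design of protected effects, without an
        intercept column (the site indicators span it).
    eb
        Apply empirical-Bayes shrinkage of the per-site estimates
        (skipped automatically when only one site is present).

    Returns
    -------
    np.ndarray
        Harmonized matrix, same shape as the input.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise ValidationError("features must be a 2-D (subjects x units) matrix")
    n, g = x.shape
    site = np.asarray(site)
    if site.shape[0] != n:
        raise ValidationError("site labels length does not match features")

    counts = Counter(site.tolist())
    too_small = [s for s, c in counts.items() if c < MIN_SUBJECTS_PER_SITE]
    if too_small:
        raise ValidationError(
            f"sites with fewer than {MIN_SUBJECTS_PER_SITE} subjects: {too_small}"
        )
    small = [s for s, c in counts.items() if c < RECOMMENDED_SUBJECTS_PER_SITE]
    if small:
        logger.warning(
            "sites with fewer than %d subjects: %s",
            RECOMMENDED_SUBJECTS_PER_SITE,
            small,
        )

    batches = sorted(counts, key=str)
    n_batch = len(batches)
    batch_idx = [np.flatnonzero(site == b) for b in batches]
    batch_design = np.zeros((n, n_batch))
    for k, idx in enumerate(batch_idx):
        batch_design[idx, k] = 1.0

    if covariates is not None and np.asarray(covariates).size:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            raise ValidationError("covariate design rows do not match subjects")
        design = np.hstack([batch_design, cov])
    else:
        cov = None
        design = batch_design
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError("design matrix is rank deficient")

    beta_hat, *_ = np.linalg.lstsq(design, x, rcond=None)
    n_props = np.array([len(idx) / n for idx in batch_idx])
    grand_mean = n_props @ beta_hat[:n_batch]
    stand_mean = np.tile(grand_mean, (n, 1))
    if cov is not None:
        stand_mean = stand_mean + cov @ beta_hat[n_batch:]
    resid = x - design @ beta_hat
    var_pooled = (resid**2).mean(axis=0)
    if np.any(var_pooled <= 0):
        raise ValidationError("zero residual variance in some unit")
    sd_pooled = np.sqrt(var_pooled)

    z = (x - stand_mean) / sd_pooled[None, :]

    gamma_hat = np.vstack([z[idx].mean(axis=0) for idx in batch_idx])
    # population (ddof=0) variance keeps the single-site round trip exact
    delta_hat = np.vstack([z[idx].var(axis=0, ddof=0) for idx in batch_idx])

    if eb and n_batch > 1:
        gamma_star = np.empty_like(gamma_hat)
        delta_star = np.empty_like(delta_hat)
        for k, idx in enumerate(batch_idx):
            g_bar = gamma_hat[k].mean()
            t2 = gamma_hat[k].var(ddof=1)
            m = delta_hat[k].mean()
            s2 = delta_hat[k].var(ddof=1)
            if t2 <= 0 or s2 <= 0:
                gamma_star[k], delta_star[k] = gamma_hat[k], delta_hat[k]
                continue
            a = (2.0 * s2 + m**2) / s2
            b = (m * s2 + m**3) / s2
            gamma_star[k], delta_star[k] = _it_solve(
                z[idx], gamma_hat[k], delta_hat[k], g_bar, t2, a, b
            )
    else:
        gamma_star, delta_star = gamma_hat, delta_hat

    out = z.copy()
    for k, idx in enumerate(batch_idx):
        out[idx] = (z[idx] - gamma_star[k][None, :]) / np.sqrt(
            delta_star[k][None, :]
        )
    return out * sd_pooled[None, :] + stand_mean
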