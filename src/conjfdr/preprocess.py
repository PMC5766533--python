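"""Genomic control and decorrelation of z-scores for shared control samples.

Genomic inflation is corrected by the classical median chi-square ratio
lambda = median(z^2) / 0.4549, with 0.4549 the null median of a 1-df
chi-square; z-scores are divided by sqrt(lambda) and p-values recomputed.

Cohorts sharing control individuals induce correlation between the two
traits' null z-scores. That correlation is estimated on quasi-independent
SNPs with |z| below a null threshold in both traits and removed by the
symmetric inverse square root of the 2x2 correlation matrix, which preserves
unit marginal variances and the exchangeability of the two traits required
by the symmetric conjunction statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .utils import p_from_z

log = logging.getLogger(__name__)

#: Median of a central 1-df chi-square (conventional genomic-control constant).
NULL_MEDIAN_CHISQ = 0.4549

#: Minimum SNP counts for valid estimation.
MIN_SNPS_LAMBDA = 100
MIN_SNPS_NULL = 100


class PreprocessError(ValueError):
    """Raised when a correction cannot be estimated from the given input."""


@dataclass
class GcResult:
    """Genomic-control corrected table and the inflation factor applied."""

    lambda_gc: float
    table: pd.DataFrame


@dataclass
class OverlapModel:
    """Inter-trait null z-score correlation from overlapping samples."""

    rho: float
    n_null: int
    z_threshold: float


def estimate_lambda_gc(z: np.ndarray) -> float:
    """Genomic inflation factor median(z^2)/0.4549, clamped below at 1.

    Clamping never inflates significance for deflated statistics (standard
    conservative practice).
    """
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < MIN_SNPS_LAMBDA:
        raise PreprocessError(
            f"need >= {MIN_SNPS_LAMBDA} finite z-scores to estimate lambda_gc, got {z.size}"
        )
    lam = float(np.median(z**2) / NULL_MEDIAN_CHISQ)
    return max(lam, 1.0)


def apply_genomic_control(ss: pd.DataFrame) -> GcResult:
    """Divide z by sqrt(lambda_gc) and recompute p from the corrected z."""
    lam = estimate_lambda_gc(ss["Z"].to_numpy())
    out = ss.copy()
    if lam > 1.0:
        out["Z"] = out["Z"].to_numpy(float) / np.sqrt(lam)
        out["P"] = p_from_z(out["Z"].to_numpy())
    log.info("genomic control: lambda = %.4f", lam)
    return GcResult(lambda_gc=lam, table=out)


def _box_truncated_corr(rho: float, a: float, n_quad: int = 64) -> float:
    """Correlation of a standard bivariate normal truncated to the box [-a, a]^2.

    Restricting to |z| < a in both coordinates attenuates the correlation;
    this forward map (computed by Gauss-Legendre quadrature) is inverted to
    de-bias the null-set estimate.
    """
    x, w = np.polynomial.legendre.leggauss(n_quad)
    x = a * x
    w = a * w
    xx, yy = np.meshgrid(x, x, indexing="ij")
    ww = np.outer(w, w)
    det = 1.0 - rho**2
    dens = np.exp(-(xx**2 - 2 * rho * xx * yy + yy**2) / (2 * det)) / (
        2 * np.pi * np.sqrt(det)
    )
    mass = np.sum(ww * dens)
    m11 = np.sum(ww * xx * yy * dens) / mass
    m20 = np.sum(ww * xx**2 * dens) / mass
    return m11 / m20  # symmetric: var(x|box) == var(y|box)


def _debias_truncated_corr(r_obs: float, a: float) -> float:
    """Invert the box-truncation attenuation (monotone in rho)."""
    lim = 0.999
    if abs(r_obs) >= _box_truncated_corr(lim, a):
        raise PreprocessError(f"null correlation {r_obs:.4f} too extreme to de-bias")
    return float(optimize.brentq(lambda r: _box_truncated_corr(r, a) - r_obs, -lim, lim, xtol=1e-8))


def estimate_null_correlation(
    z1: np.ndarray,
    z2: np.ndarray,
    z_threshold: float = 2.0,
    panel=None,
    seed: int = 0,
) -> OverlapModel:
    """Estimate the inter-trait correlation of null z-scores.

    Restricts to SNPs with |z| < z_threshold in both traits; when an
    :class:`~conjfdr.ld.LDPanel` is supplied, one random pruning pass at
    r^2 = 0.8 first reduces the set to quasi-independent SNPs. The sample
    correlation of the box-truncated pair underestimates the underlying
    null correlation, so the truncation attenuation of a bivariate normal
    is inverted before returning rho.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape != z2.shape:
        raise PreprocessError("z1 and z2 must be aligned on the same SNPs")
    sel = np.isfinite(z1) & np.isfinite(z2)
    if panel is not None:
        from .ld import random_prune

        sel &= random_prune(panel, r2_threshold=0.8, seed=seed)
    sel &= (np.abs(z1) < z_threshold) & (np.abs(z2) < z_threshold)
    n_null = int(sel.sum())
    if n_null < MIN_SNPS_NULL:
        raise PreprocessError(f"only {n_null} null SNPs; need >= {MIN_SNPS_NULL}")
    r_obs = float(np.corrcoef(z1[sel], z2[sel])[0, 1])
    if not np.isfinite(r_obs) or abs(r_obs) >= 1.0 - 1e-9:
        raise PreprocessError(f"degenerate null correlation estimate rho={r_obs!r}")
    rho = _debias_truncated_corr(r_obs, z_threshold)
    if abs(rho) >= 1.0 - 1e-9:
        raise PreprocessError(f"degenerate null correlation estimate rho={rho!r}")
    log.info("null z correlation: rho = %.4f over %d SNPs", rho, n_null)
    return OverlapModel(rho=rho, n_null=n_null, z_threshold=float(z_threshold))


def decorrelate_overlap(
    z1: np.ndarray, z2: np.ndarray, model: OverlapModel
) -> tuple[np.ndarray, np.ndarray]:
    """Whiten the z pair by the symmetric inverse square root of [[1,rho],[rho,1]].

    Maps a unit-variance pair with correlation rho to an uncorrelated
    unit-variance pair; rho = 0 is the identity.
    """
    rho = model.rho
    if not np.isfinite(rho) or abs(rho) >= 1.0:
        raise PreprocessError(f"invalid overlap model rho={rho!r}")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    a = 0.5 * (1.0 / np.sqrt(1.0 + rho) + 1.0 / np.sqrt(1.0 - rho))
    b = 0.5 * (1.0 / np.sqrt(1.0 + rho) - 1.0 / np.sqrt(1.0 - rho))
    return a * z1 + b * z2, b * z1 + a * z2
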