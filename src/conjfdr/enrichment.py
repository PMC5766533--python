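"""Stratified Q-Q enrichment curves and LD-score fold-enrichment tests.

A stratified Q-Q plot shows the -log10 p quantiles of a primary trait within
nested strata defined by significance in a secondary trait (p2 < 1, 0.1,
0.01, 0.001 by default). Increasing leftward deflection with conditioning
stringency indicates shared polygenic architecture. Curves are computed per
random-pruning mask on continuity-corrected uniform plotting positions
(i - 0.5)/n and averaged across masks on a common theoretical grid (raw
order statistics from differently sized kept sets are not alignable).

Statistical significance of stratum enrichment is tested with a stratified
LD-score regression: z^2 regressed on an intercept, the total LD score, and
the stratum-restricted LD score. Under polygenicity E[z^2] grows linearly
in LD score, so the stratum coefficient measures extra per-SNP heritability
inside the stratum. Fold enrichment is the stratum's heritability share
over its SNP share; its standard error comes from a block jackknife over
contiguous SNP blocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .ld import LDPanel, PruneEnsemble
from .utils import neglog10

log = logging.getLogger(__name__)

#: Below this many stratum SNPs a Q-Q curve is flagged unstable.
MIN_STRATUM_SNPS = 50


class EnrichmentError(ValueError):
    """Raised for degenerate enrichment-test input."""


@dataclass
class QqStrata:
    """Secondary-trait p-value cutoffs (descending, first = 1 meaning all SNPs)."""

    thresholds: tuple = (1.0, 0.1, 0.01, 0.001)
    truncation: float = 7.3    # -log10 of genome-wide significance, display cap

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds)
        if t[0] != 1.0 or any(a <= b for a, b in zip(t, t[1:])):
            raise EnrichmentError("thresholds must be strictly decreasing with first = 1")
        self.thresholds = t


@dataclass
class QqCurve:
    """One stratum's averaged Q-Q curve on the common theoretical grid."""

    threshold: float
    theoretical: np.ndarray
    observed: np.ndarray       # NaN beyond data support or above truncation
    n_snps: float              # kept stratum size, averaged over masks
    unstable: bool


def _default_qq_grid() -> np.ndarray:
    return np.linspace(0.0, 6.0, 121)


def stratified_qq(
    p1,
    p2,
    strata: QqStrata | None = None,
    ensemble: PruneEnsemble | None = None,
    grid: np.ndarray | None = None,
) -> list[QqCurve]:
    """Q-Q curves of trait 1 within nested strata of trait-2 significance."""
    strata = strata or QqStrata()
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.shape != p2.shape:
        raise EnrichmentError("p1 and p2 must be aligned")
    grid = _default_qq_grid() if grid is None else np.asarray(grid, dtype=float)
    masks = ensemble.masks if ensemble is not None else np.ones((1, p1.size), dtype=bool)
    q1 = neglog10(p1)

    curves = []
    for t in strata.thresholds:
        in_stratum = np.ones(p1.size, dtype=bool) if t >= 1.0 else p2 < t
        obs = np.full((len(masks), grid.size), np.nan)
        counts = np.zeros(len(masks))
        for k, mask in enumerate(masks):
            sel = mask & in_stratum
            n = int(sel.sum())
            counts[k] = n
            if n == 0:
                continue
            qs = np.sort(q1[sel])                         # ascending observed
            theo = -np.log10((np.arange(n, 0, -1) - 0.5) / n)  # matched ascending
            obs[k] = np.interp(grid, theo, qs)
            obs[k, grid > theo[-1]] = np.nan              # beyond data support
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mean_obs = np.nanmean(obs, axis=0)
        mean_obs[mean_obs >= strata.truncation] = np.nan  # display truncation
        n_mean = float(counts.mean())
        unstable = n_mean < MIN_STRATUM_SNPS
        if unstable:
            log.warning("stratum p2 < %g has only %.1f kept SNPs; curve unstable", t, n_mean)
        curves.append(
            QqCurve(threshold=t, theoretical=grid, observed=mean_obs, n_snps=n_mean, unstable=unstable)
        )
    return curves


# ---------------------------------------------------------------------------
# LD-score fold enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    """Fold enrichment of a SNP stratum from stratified LD-score regression."""

    fold: float
    se: float
    p_value: float             # one-sided, H1: fold > 1
    p_adjusted: float | None
    n_stratum: int
    informative: bool
    tau_total: float           # per-LD-score-unit coefficient, all SNPs
    tau_stratum: float         # additional coefficient inside the stratum
    h2_proxy: float            # unnormalized total heritability signal


def _fold_from_theta(theta: np.ndarray, n_snps: int, n_stratum: int) -> tuple[float, float]:
    tau, tau_s = theta[1], theta[2]
    h2 = n_snps * tau + n_stratum * tau_s
    if h2 <= 0:
        return np.nan, h2
    return n_snps * (tau + tau_s) / h2, h2


def fold_enrichment_ldsc(
    z,
    ld_scores,
    stratum_mask,
    *,
    stratum_ld_scores=None,
    panel: LDPanel | None = None,
    n_blocks: int = 200,
    n_samples: float | None = None,
) -> EnrichmentResult:
    """Fold enrichment E = (stratum heritability share) / (stratum SNP share).

    Weighted least squares of z^2 on [1, total LD score, stratum LD score]
    with 1/LD-score weights; the stratum LD score of SNP j is its summed
    r^2 to stratum members (self included) and is computed from `panel`
    when not supplied directly (without LD information it degrades to the
    stratum indicator). Standard errors by delete-one block jackknife over
    `n_blocks` contiguous SNP blocks. A trait with no detectable polygenic
    signal (total heritability within 2 jackknife SEs of zero) is flagged
    non-informative instead of returning a spurious fold.
    """
    z = np.asarray(z, dtype=float)
    ell = np.asarray(ld_scores, dtype=float)
    s = np.asarray(stratum_mask, dtype=bool)
    n = z.size
    n_s = int(s.sum())
    if n_s == 0 or n_s == n:
        raise EnrichmentError("stratum must be a nonempty strict subset of SNPs")
    if stratum_ld_scores is not None:
        ell_s = np.asarray(stratum_ld_scores, dtype=float)
    elif panel is not None:
        ell_s = np.asarray(panel.r2 @ s.astype(float)).ravel() + s.astype(float)
    else:
        ell_s = s.astype(float)

    y = z**2
    X = np.column_stack([np.ones(n), ell, ell_s])
    w = 1.0 / np.maximum(ell, 1.0)
    Xw = X * w[:, None]
    A = Xw.T @ X
    c = Xw.T @ y
    if np.linalg.matrix_rank(A) < 3:
        raise EnrichmentError("rank-deficient enrichment design")
    theta = np.linalg.solve(A, c)
    fold, h2 = _fold_from_theta(theta, n, n_s)

    # delete-one block jackknife on contiguous blocks
    blocks = np.array_split(np.arange(n), min(n_blocks, n))
    folds_j, h2_j = [], []
    for blk in blocks:
        A_g = Xw[blk].T @ X[blk]
        c_g = Xw[blk].T @ y[blk]
        th = np.linalg.solve(A - A_g, c - c_g)
        f_g, h_g = _fold_from_theta(th, n, n_s)
        folds_j.append(f_g)
        h2_j.append(h_g)
    folds_j = np.asarray(folds_j)
    h2_j = np.asarray(h2_j)
    g = len(blocks)

    se_h2 = float(np.sqrt((g - 1) / g * np.sum((h2_j - h2_j.mean()) ** 2)))
    informative = bool(h2 > 2.0 * se_h2) and np.isfinite(fold) and np.all(np.isfinite(folds_j))
    if informative:
        se = float(np.sqrt((g - 1) / g * np.sum((folds_j - folds_j.mean()) ** 2)))
        p_value = float(stats.norm.sf((fold - 1.0) / se)) if se > 0 else np.nan
    else:
        fold, se, p_value = np.nan, np.nan, np.nan
        log.warning("no detectable polygenic signal; enrichment non-informative")

    return EnrichmentResult(
        fold=fold,
        se=se,
        p_value=p_value,
        p_adjusted=None,
        n_stratum=n_s,
        informative=informative,
        tau_total=float(theta[1]),
        tau_stratum=float(theta[2]),
        h2_proxy=float(h2),
    )


def bonferroni_adjust(p, n_tests: int):
    """Elementwise min(1, p * n_tests)."""
    if n_tests < 1:
        raise EnrichmentError("n_tests must be >= 1")
    return np.minimum(np.asarray(p, dtype=float) * n_tests, 1.0)


def plot_qq(curves: list[QqCurve], path, title: str = "") -> None:
    """Write a stratified Q-Q plot (observed vs theoretical -log10 p) to `path`."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    lim = 0.0
    for curve in curves:
        ok = np.isfinite(curve.observed)
        ax.plot(curve.theoretical[ok], curve.observed[ok], label=f"p2 < {curve.threshold:g}")
        if ok.any():
            lim = max(lim, float(np.nanmax(curve.observed)))
    top = max(lim, curves[0].theoretical[-1])
    ax.plot([0, top], [0, top], "k--", lw=0.8, label="null")
    ax.set_xlabel(r"theoretical $-\log_{10} p$")
    ax.set_ylabel(r"observed $-\log_{10} p$")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
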