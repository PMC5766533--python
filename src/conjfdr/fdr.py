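"""Empirical tail-area, conditional, and conjunction FDR estimation.

The tail-area FDR of a SNP is the probability it is null given its p-value
is at most the observed one, estimated conservatively (null proportion
pi0 = 1) as p divided by the empirical cdf of p with inclusive ties:

    FDR(p_i) = pi0 * p_i / ( #{j: p_j <= p_i} / N ).

The conditional FDR of trait 1 given trait 2 replaces the empirical cdf by
the cdf within the stratum of SNPs at least as significant in trait 2:

    condFDR_i = pi0 * p1_i * #{j: p2_j <= p2_i} / #{j: p1_j <= p1_i and p2_j <= p2_i}.

The conjunction FDR — the probability of being null for either trait or
both, given both p-values are at most the observed ones — is the maximum of
the two conditional FDRs taken in both trait orders; it is symmetric in the
traits and small only for SNPs jointly associated with both.

Two routes are provided: the exact per-SNP estimators above, and a
grid-surface route in which the conditional estimator is evaluated at
-log10 p grid nodes for each random-pruning mask, averaged across masks,
monotonized, and applied to all SNPs (pruned ones included) by bilinear
interpolation. The surface route is what the pipeline uses: averaging over
pruning masks de-correlates the empirical cdfs that LD would otherwise bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .ld import PruneEnsemble
from .utils import P_FLOOR, neglog10

log = logging.getLogger(__name__)


class FdrError(ValueError):
    """Raised for unusable FDR estimation input."""


def _check_p(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise FdrError(f"{name} is empty")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise FdrError(f"{name} must lie in (0, 1]")
    return p


# ---------------------------------------------------------------------------
# exact per-SNP estimators
# ---------------------------------------------------------------------------

def marginal_fdr(p, pi0: float = 1.0) -> np.ndarray:
    """Tail-area FDR: pi0 * p / empirical cdf(p), inclusive ties, clamped to (0, 1]."""
    p = _check_p(p, "p")
    n = p.size
    rank = np.searchsorted(np.sort(p), p, side="right")  # = #{p_j <= p_i}
    return np.minimum(pi0 * p * n / rank, 1.0)


class _Fenwick:
    """Binary indexed tree counting inserted ranks (1-based)."""

    __slots__ = ("n", "tree")

    def __init__(self, n: int):
        self.n = n
        self.tree = [0] * (n + 1)

    def add(self, i: int) -> None:
        while i <= self.n:
            self.tree[i] += 1
            i += i & -i

    def query(self, i: int) -> int:
        s = 0
        while i > 0:
            s += self.tree[i]
            i -= i & -i
        return s


def cond_fdr(p1, p2, pi0: float = 1.0) -> np.ndarray:
    """Conditional FDR of trait 1 given trait 2, exact, inclusive ties.

    Counts the joint dominance numbers #{p1_j <= p1_i and p2_j <= p2_i} with
    a Fenwick tree over p1-ranks while sweeping p2 in ascending order
    (tie groups inserted before being queried), so duplicated p-values are
    handled by inclusiveness. The conditioning stratum always contains the
    SNP itself, so the estimator is well defined everywhere.
    """
    p1 = _check_p(p1, "p1")
    p2 = _check_p(p2, "p2")
    if p1.shape != p2.shape:
        raise FdrError("p1 and p2 must be aligned")
    n = p1.size
    r1 = np.searchsorted(np.sort(p1), p1, side="right")
    denom = np.searchsorted(np.sort(p2), p2, side="right")
    order = np.argsort(p2, kind="stable")
    p2o = p2[order]
    num = np.empty(n, dtype=float)
    bit = _Fenwick(n)
    i = 0
    while i < n:
        j = i
        while j < n and p2o[j] == p2o[i]:
            j += 1
        for k in range(i, j):
            bit.add(int(r1[order[k]]))
        for k in range(i, j):
            num[order[k]] = bit.query(int(r1[order[k]]))
        i = j
    return np.minimum(pi0 * p1 * denom / num, 1.0)


# ---------------------------------------------------------------------------
# configuration and surface
# ---------------------------------------------------------------------------

def _default_grid() -> np.ndarray:
    # 201 equally spaced -log10 p breakpoints resolving the genome-wide tail
    return np.linspace(0.0, 20.0, 201)


@dataclass
class FdrConfig:
    """Settings for surface-based conjunction FDR estimation."""

    fdr_level: float = 0.01
    grid: np.ndarray = field(default_factory=_default_grid)
    pi0: float = 1.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if not 0.0 < self.fdr_level < 1.0:
            raise FdrError("fdr_level must be in (0, 1)")
        if self.grid.ndim != 1 or self.grid.size < 2 or np.any(np.diff(self.grid) <= 0):
            raise FdrError("grid must be strictly increasing with >= 2 breakpoints")


@dataclass
class FdrSurface:
    """condFDR estimates on a -log10 p grid, averaged over pruning masks.

    `values` are monotonized (nonincreasing along the primary significance
    axis by cumulative minimum); `raw_values` are the ensemble averages
    before monotonization. Off-node lookups interpolate bilinearly in
    -log10 p space, with flat extension beyond the grid.
    """

    grid_x: np.ndarray         # primary trait -log10 p breakpoints
    grid_y: np.ndarray         # conditioning trait -log10 p breakpoints
    values: np.ndarray         # (nx, ny), monotonized
    raw_values: np.ndarray     # (nx, ny), pre-monotonization
    orientation: str = "trait1|trait2"

    def lookup(self, q_primary, q_cond, raw: bool = False) -> np.ndarray:
        vals = self.raw_values if raw else self.values
        itp = RegularGridInterpolator((self.grid_x, self.grid_y), vals, method="linear")
        x = np.clip(np.asarray(q_primary, dtype=float), self.grid_x[0], self.grid_x[-1])
        y = np.clip(np.asarray(q_cond, dtype=float), self.grid_y[0], self.grid_y[-1])
        return itp(np.column_stack([np.atleast_1d(x), np.atleast_1d(y)]))


def _ffill(a: np.ndarray, axis: int) -> np.ndarray:
    """Forward-fill NaNs along `axis` (leading NaNs left in place)."""
    if axis == 1:
        return _ffill(a.T, 0).T
    idx = np.where(np.isnan(a), 0, np.arange(a.shape[0])[:, None])
    np.maximum.accumulate(idx, axis=0, out=idx)
    return a[idx, np.arange(a.shape[1])[None, :]]


def _surface_one_mask(q1, q2, gx, gy, pi0) -> np.ndarray:
    """Raw condFDR node values for one kept-SNP set, flat-extended off support."""
    nx, ny = gx.size, gy.size
    # conditioning-stratum sizes use every kept SNP regardless of q1
    denom = q2.size - np.searchsorted(np.sort(q2), gy, side="left")  # #{q2 >= gy}
    inside = (q1 >= gx[0]) & (q2 >= gy[0])
    ci = np.clip(np.searchsorted(gx, q1[inside], side="right") - 1, 0, nx - 1)
    cj = np.clip(np.searchsorted(gy, q2[inside], side="right") - 1, 0, ny - 1)
    hist = np.zeros((nx, ny))
    np.add.at(hist, (ci, cj), 1.0)
    # reverse 2-D cumulative sum: joint[k, l] = #{q1 >= gx[k] and q2 >= gy[l]}
    joint = np.flip(np.flip(hist, 0).cumsum(0), 0)
    joint = np.flip(np.flip(joint, 1).cumsum(1), 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = pi0 * (10.0 ** -gx)[:, None] * denom[None, :] / joint
    raw[joint == 0] = np.nan
    raw = np.minimum(raw, 1.0)
    # flat extension beyond data support: along significance axis, then
    # conditioning axis; nodes with no support anywhere are conservative 1
    raw = _ffill(raw, axis=0)
    raw = _ffill(raw, axis=1)
    return np.where(np.isnan(raw), 1.0, raw)


def build_fdr_surface(
    p1,
    p2,
    config: FdrConfig | None = None,
    ensemble: PruneEnsemble | None = None,
    monotonize: bool = True,
    orientation: str = "trait1|trait2",
) -> FdrSurface:
    """Ensemble-averaged condFDR(p1 | p2) surface on the config grid.

    For each pruning mask the conditional estimator is evaluated at every
    grid node using only kept SNPs; node values are averaged across masks
    and made nonincreasing along the primary axis by cumulative minimum.
    """
    config = config or FdrConfig()
    p1 = _check_p(p1, "p1")
    p2 = _check_p(p2, "p2")
    if p1.shape != p2.shape:
        raise FdrError("p1 and p2 must be aligned")
    if ensemble is not None and ensemble.n_snps != p1.size:
        raise FdrError("ensemble masks do not align with the SNP vectors")
    masks = ensemble.masks if ensemble is not None else np.ones((1, p1.size), dtype=bool)
    q1, q2 = neglog10(p1), neglog10(p2)
    gx = gy = config.grid
    acc = np.zeros((gx.size, gy.size))
    for mask in masks:
        acc += _surface_one_mask(q1[mask], q2[mask], gx, gy, config.pi0)
    raw = acc / len(masks)
    values = np.minimum.accumulate(raw, axis=0) if monotonize else raw.copy()
    values = np.clip(values, P_FLOOR, 1.0)
    return FdrSurface(grid_x=gx, grid_y=gy, values=values, raw_values=raw, orientation=orientation)


# ---------------------------------------------------------------------------
# conjunction
# ---------------------------------------------------------------------------

@dataclass
class ConjResult:
    """Per-SNP conditional FDRs (both orders), conjunction FDR, discoveries."""

    cond_fdr_1_given_2: np.ndarray
    cond_fdr_2_given_1: np.ndarray
    conj_fdr: np.ndarray
    discovery: np.ndarray
    fdr_level: float
    surfaces: tuple = ()


def conj_fdr(
    p1,
    p2,
    config: FdrConfig | None = None,
    ensemble: PruneEnsemble | None = None,
) -> ConjResult:
    """Surface-based conjunction FDR: max of the two conditional FDR lookups."""
    config = config or FdrConfig()
    s12 = build_fdr_surface(p1, p2, config, ensemble, orientation="trait1|trait2")
    s21 = build_fdr_surface(p2, p1, config, ensemble, orientation="trait2|trait1")
    q1, q2 = neglog10(p1), neglog10(p2)
    c12 = s12.lookup(q1, q2)
    c21 = s21.lookup(q2, q1)
    conj = np.maximum(c12, c21)
    return ConjResult(
        cond_fdr_1_given_2=c12,
        cond_fdr_2_given_1=c21,
        conj_fdr=conj,
        discovery=conj < config.fdr_level,
        fdr_level=config.fdr_level,
        surfaces=(s12, s21),
    )


def conj_fdr_exact(p1, p2, pi0: float = 1.0, fdr_level: float = 0.01) -> ConjResult:
    """Exact per-SNP conjunction FDR (no pruning ensemble, no interpolation)."""
    c12 = cond_fdr(p1, p2, pi0=pi0)
    c21 = cond_fdr(p2, p1, pi0=pi0)
    conj = np.maximum(c12, c21)
    return ConjResult(
        cond_fdr_1_given_2=c12,
        cond_fdr_2_given_1=c21,
        conj_fdr=conj,
        discovery=conj < fdr_level,
        fdr_level=fdr_level,
    )


def call_discoveries(
    conj: ConjResult,
    ss1: pd.DataFrame,
    ss2: pd.DataFrame,
    fdr_level: float | None = None,
) -> pd.DataFrame:
    """Table of SNPs with conjFDR below the level, sorted ascending by conjFDR.

    `ss1` and `ss2` must be aligned row-for-row on the same SNPs; the output
    carries both traits' p and z next to the conjunction FDR.
    """
    level = conj.fdr_level if fdr_level is None else fdr_level
    if not ss1["SNP"].reset_index(drop=True).equals(ss2["SNP"].reset_index(drop=True)):
        raise FdrError("ss1 and ss2 must be aligned on the same SNPs")
    out = pd.DataFrame({"SNP": ss1["SNP"].to_numpy()})
    for col in ("CHR", "BP", "A1", "A2"):
        if col in ss1.columns:
            out[col] = ss1[col].to_numpy()
    out["P_TRAIT1"] = ss1["P"].to_numpy()
    out["P_TRAIT2"] = ss2["P"].to_numpy()
    out["Z_TRAIT1"] = ss1["Z"].to_numpy()
    out["Z_TRAIT2"] = ss2["Z"].to_numpy()
    out["CONJFDR"] = conj.conj_fdr
    out = out[out["CONJFDR"] < level]
    return out.sort_values(["CONJFDR", "P_TRAIT1", "SNP"], kind="mergesort").reset_index(drop=True)
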