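"""Synthetic paired GWAS summary statistics with ground truth.

The generator emulates the statistical structure the cross-trait FDR
analysis assumes: block-diagonal LD (within-block correlation decaying as
rho_ld^|i-j|, hence r^2 = rho_ld^(2|i-j|)), a four-component causal mixture
(shared / trait-1-only / trait-2-only / null), shared effect sizes drawn
with a tunable correlation so both concordant and discordant directions
occur, genomic inflation as a multiplicative z^2 factor, and correlated
null noise from overlapping control samples.

Marginal z-scores follow the standard infinitesimal mapping
E[z] = sqrt(n) * R * beta, where R is the within-block allelic correlation
and the per-causal effect variance is set so the causal contributions sum
to the trait heritability. Noise is drawn block-wise from the LD
correlation (one Cholesky factor serves every block, since all blocks share
the same decay structure), which keeps simulation cost linear in SNPs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .ld import LDPanel
from .utils import p_from_z

log = logging.getLogger(__name__)

_ALLELE_PAIRS = np.array(
    [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "T")],
    dtype=object,
)

#: Base-pair layout of synthetic chromosomes: first SNP position and spacing.
_BASE_POS = 29_000_000
_POS_STEP = 10_000


class SimulationError(ValueError):
    """Raised for inconsistent simulation parameters."""


@dataclass
class SimParams:
    """Study conditions for a simulated GWAS trait pair.

    Defaults describe a desk-scale polygenic pair loosely shaped like a
    large psychiatric GWAS conditioned on a mid-sized cancer GWAS: 20,000
    SNPs in 800 LD blocks, unequal sample sizes, modest heritabilities,
    a small shared-causal fraction with sign-mixed effects, and no
    confounding inflation or sample overlap unless switched on.
    """

    m_blocks: int = 800
    block_size: int = 25
    rho_ld: float = 0.9          # within-block correlation decay base
    n1: int = 75_000
    n2: int = 40_000
    h2_1: float = 0.04           # effective desk-scale heritabilities: at
    h2_2: float = 0.02           # 20k SNPs these give GWAS-like lambda ~1.1-1.3
    pi_shared: float = 0.005     # fraction of SNPs causal for both traits
    pi_1: float = 0.005          # causal for trait 1 only
    pi_2: float = 0.005          # causal for trait 2 only
    effect_corr: float = 0.5     # correlation of shared effect sizes
    rho_overlap: float = 0.0     # null z correlation from shared controls
    lambda_inflation: float = 1.0
    seed: int = 0
    min_r2_store: float = 1e-4   # sparse floor for stored r^2 entries

    def __post_init__(self):
        if self.pi_shared + self.pi_1 + self.pi_2 > 1 + 1e-12:
            raise SimulationError("causal fractions sum above 1")
        for name in ("pi_shared", "pi_1", "pi_2"):
            if not 0 <= getattr(self, name) <= 1:
                raise SimulationError(f"{name} outside [0, 1]")
        if not (0 <= self.h2_1 < 1 and 0 <= self.h2_2 < 1):
            raise SimulationError("heritabilities must lie in [0, 1)")
        if not -1 <= self.effect_corr <= 1:
            raise SimulationError("effect_corr outside [-1, 1]")
        if not -1 < self.rho_overlap < 1:
            raise SimulationError("rho_overlap outside (-1, 1)")
        if not 0 <= self.rho_ld < 1:
            raise SimulationError("rho_ld outside [0, 1)")
        if self.lambda_inflation < 1:
            raise SimulationError("lambda_inflation must be >= 1")

    @property
    def n_snps(self) -> int:
        return self.m_blocks * self.block_size


@dataclass
class SimTruth:
    """Ground-truth causal assignment for one simulated trait pair."""

    causal1: np.ndarray        # bool, causal for trait 1
    causal2: np.ndarray
    shared: np.ndarray         # bool, causal for both (implies causal1 & causal2)
    beta1: np.ndarray
    beta2: np.ndarray
    block: np.ndarray          # LD block index per SNP

    def to_frame(self, snps) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "SNP": snps,
                "BLOCK": self.block,
                "CAUSAL1": self.causal1.astype(int),
                "CAUSAL2": self.causal2.astype(int),
                "SHARED": self.shared.astype(int),
                "BETA1": self.beta1,
                "BETA2": self.beta2,
            }
        )


def _block_corr(params: SimParams) -> np.ndarray:
    k = np.arange(params.block_size)
    return params.rho_ld ** np.abs(k[:, None] - k[None, :])


def simulate_panel(params: SimParams) -> tuple[pd.DataFrame, LDPanel]:
    """Reference SNP set and block-diagonal LD panel, deterministic given seed.

    Blocks are laid out contiguously along synthetic chromosomes 1..22
    (earlier blocks on lower chromosomes) with fixed base-pair spacing, so
    the reference set is sorted by (CHR, BP) in panel order.
    """
    m, size = params.m_blocks, params.block_size
    n = params.n_snps
    rng = np.random.default_rng(params.seed)

    snps = np.array([f"rs{i + 1:07d}" for i in range(n)], dtype=object)
    block = np.repeat(np.arange(m), size)
    n_chrom = min(22, m)
    chrom_of_block = 1 + (np.arange(m) * n_chrom) // m
    chrom = chrom_of_block[block]
    pos = np.empty(n, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        pos[idx] = _BASE_POS + _POS_STEP * np.arange(idx.size)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n)
    a1 = _ALLELE_PAIRS[pair_idx, 0]
    a2 = _ALLELE_PAIRS[pair_idx, 1]
    ref = pd.DataFrame({"SNP": snps, "CHR": chrom, "BP": pos, "A1": a1, "A2": a2})

    rows, cols, vals = [], [], []
    if params.rho_ld > 0:
        base = np.arange(n).reshape(m, size)
        decay = params.rho_ld ** (2.0 * np.arange(1, size))
        for k in np.flatnonzero(decay >= params.min_r2_store) + 1:
            i = base[:, :-k].ravel()
            j = base[:, k:].ravel()
            rows.extend([i, j])
            cols.extend([j, i])
            v = np.full(i.size, decay[k - 1])
            vals.extend([v, v])
    if rows:
        mat = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
    else:
        mat = sp.coo_matrix((n, n))
    return ref, LDPanel(snps, mat, meta=ref)


def _draw_noise(rng, m, size, chol, rho_overlap) -> tuple[np.ndarray, np.ndarray]:
    g_a = rng.standard_normal((m, size))
    g_b = rng.standard_normal((m, size))
    shared = rho_overlap * g_a + np.sqrt(1.0 - rho_overlap**2) * g_b
    return g_a @ chol.T, shared @ chol.T


def simulate_gwas_pair(
    panel: LDPanel, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Paired summary statistics and ground truth from the causal mixture model."""
    m, size = params.m_blocks, params.block_size
    n = params.n_snps
    if panel.n_snps != n:
        raise SimulationError("panel does not match params dimensions")
    rng = np.random.default_rng(params.seed + 1)  # offset from the panel stream

    p_null = 1.0 - params.pi_shared - params.pi_1 - params.pi_2
    cats = rng.choice(4, size=n, p=[params.pi_shared, params.pi_1, params.pi_2, max(p_null, 0.0)])
    shared = cats == 0
    causal1 = shared | (cats == 1)
    causal2 = shared | (cats == 2)

    def causal_sd(h2, pi_causal):
        if h2 == 0:
            return 0.0
        if pi_causal == 0:
            raise SimulationError("nonzero heritability with zero causal fraction")
        var = h2 / (n * pi_causal)
        if var > 1:
            raise SimulationError("per-causal effect variance exceeds 1; reduce h2 or raise pi")
        return float(np.sqrt(var))

    sd1 = causal_sd(params.h2_1, params.pi_shared + params.pi_1)
    sd2 = causal_sd(params.h2_2, params.pi_shared + params.pi_2)

    beta1 = np.zeros(n)
    beta2 = np.zeros(n)
    n_sh = int(shared.sum())
    u = rng.standard_normal(n_sh)
    v = params.effect_corr * u + np.sqrt(1.0 - params.effect_corr**2) * rng.standard_normal(n_sh)
    beta1[shared] = sd1 * u
    beta2[shared] = sd2 * v
    beta1[cats == 1] = sd1 * rng.standard_normal(int((cats == 1).sum()))
    beta2[cats == 2] = sd2 * rng.standard_normal(int((cats == 2).sum()))

    corr = _block_corr(params)
    chol = np.linalg.cholesky(corr) if params.rho_ld > 0 else np.eye(size)
    ez1 = np.sqrt(params.n1) * (beta1.reshape(m, size) @ corr)
    ez2 = np.sqrt(params.n2) * (beta2.reshape(m, size) @ corr)
    e1, e2 = _draw_noise(rng, m, size, chol, params.rho_overlap)
    scale = np.sqrt(params.lambda_inflation)
    z1 = scale * (ez1 + e1).ravel()
    z2 = scale * (ez2 + e2).ravel()

    meta = panel.meta if panel.meta is not None else pd.DataFrame({"SNP": panel.snps})
    ss1 = meta.copy()
    ss1["Z"] = z1
    ss1["P"] = p_from_z(z1)
    ss1["N"] = params.n1
    ss2 = meta.copy()
    ss2["Z"] = z2
    ss2["P"] = p_from_z(z2)
    ss2["N"] = params.n2

    truth = SimTruth(
        causal1=causal1,
        causal2=causal2,
        shared=shared,
        beta1=beta1,
        beta2=beta2,
        block=np.repeat(np.arange(m), size),
    )
    return ss1, ss2, truth


def simulate_z(params: SimParams, beta_var, n_samples: int, seed: int) -> np.ndarray:
    """Single-trait z-scores with an arbitrary per-SNP effect-variance profile.

    Draws beta_j ~ N(0, beta_var_j) and returns
    z = sqrt(n_samples) * R * beta + noise(R) with the panel's block LD.
    Used to plant known per-SNP heritability patterns (e.g. enriched strata).
    """
    m, size = params.m_blocks, params.block_size
    beta_var = np.asarray(beta_var, dtype=float)
    if beta_var.size != params.n_snps:
        raise SimulationError("beta_var length does not match the panel")
    rng = np.random.default_rng(seed)
    beta = rng.standard_normal(params.n_snps) * np.sqrt(beta_var)
    corr = _block_corr(params)
    chol = np.linalg.cholesky(corr) if params.rho_ld > 0 else np.eye(size)
    ez = np.sqrt(n_samples) * (beta.reshape(m, size) @ corr)
    noise = rng.standard_normal((m, size)) @ chol.T
    return (ez + noise).ravel()
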