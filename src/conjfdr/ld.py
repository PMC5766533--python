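"""Reference LD representation, random pruning, LD scores, and locus clumping.

LD is held as a symmetric sparse matrix of pairwise r^2 restricted to a
reference SNP set; pairs absent from the input are r^2 = 0 (the standard
sparse windowed-LD dialect). The self-r^2 of 1 is implied, so the LD score
of SNP j is 1 + sum of stored off-diagonal r^2 in row j.

Random pruning visits SNPs in a seeded random order and keeps a SNP iff its
r^2 with every already-kept SNP is at or below the threshold; repeated with
independent seeds this yields "one random SNP per LD block" ensembles over
which downstream empirical distributions are averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

log = logging.getLogger(__name__)


class LDError(ValueError):
    """Raised for malformed LD input."""


class LDPanel:
    """Sparse symmetric pairwise r^2 over an ordered reference SNP set.

    Parameters
    ----------
    snps : sequence of str
        SNP identifiers, in reference order.
    r2 : scipy.sparse matrix
        Symmetric matrix of off-diagonal r^2 entries (diagonal ignored).
    meta : pandas.DataFrame, optional
        Per-SNP CHR/BP/A1/A2 metadata aligned with `snps`.
    """

    def __init__(self, snps, r2: sp.spmatrix, meta: pd.DataFrame | None = None):
        self.snps = np.asarray(snps, dtype=object)
        r2 = sp.csr_matrix(r2, shape=(len(self.snps), len(self.snps)))
        r2.setdiag(0.0)
        r2.eliminate_zeros()
        self.r2 = r2
        self.meta = meta
        self._index = {s: i for i, s in enumerate(self.snps)}

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def index_of(self, ids) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in ids], dtype=int)
        except KeyError as exc:
            raise LDError(f"SNP {exc.args[0]!r} not in LD panel") from exc

    def ld_scores(self) -> np.ndarray:
        """Per-SNP LD score: 1 (self) + sum of r^2 with all other panel SNPs."""
        return 1.0 + np.asarray(self.r2.sum(axis=1)).ravel()

    def subset(self, ids) -> "LDPanel":
        """Panel restricted to `ids`, in the given order."""
        idx = self.index_of(ids)
        meta = None
        if self.meta is not None:
            meta = self.meta.iloc[idx].reset_index(drop=True)
        return LDPanel(self.snps[idx], self.r2[idx][:, idx], meta=meta)

    def r2_dense(self, ids) -> np.ndarray:
        """Dense r^2 matrix among `ids` with unit diagonal (for small sets)."""
        idx = self.index_of(ids)
        mat = np.asarray(self.r2[idx][:, idx].todense())
        np.fill_diagonal(mat, 1.0)
        return mat


def load_ld(path, panel_snps) -> LDPanel:
    """Read a PLINK-style ``.ld`` pair table (columns SNP_A, SNP_B, R2).

    Extra columns (CHR_A, BP_A, ...) are ignored; pairs involving SNPs
    outside `panel_snps` are skipped with a logged count; duplicate pair
    rows with conflicting r^2 are an error.

    Parameters
    ----------
    panel_snps : pandas.DataFrame or sequence
        Reference SNP set (a DataFrame with a SNP column, used as panel
        metadata) or a plain sequence of SNP ids.
    """
    if isinstance(panel_snps, pd.DataFrame):
        meta = panel_snps.reset_index(drop=True)
        ids = meta["SNP"].astype(str).to_numpy(dtype=object)
    else:
        meta = None
        ids = np.asarray(list(panel_snps), dtype=object)
    index = {s: i for i, s in enumerate(ids)}

    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    needed = {"SNP_A", "SNP_B", "R2"}
    if not needed.issubset(df.columns):
        raise LDError(f"LD file needs columns {sorted(needed)}; got {list(df.columns)}")

    r2 = pd.to_numeric(df["R2"], errors="coerce").to_numpy(float)
    if np.any(~np.isfinite(r2)) or np.any(r2 < 0) or np.any(r2 > 1):
        raise LDError("r^2 values outside [0, 1] in LD file")

    ia = df["SNP_A"].astype(str).map(index)
    ib = df["SNP_B"].astype(str).map(index)
    known = ia.notna().to_numpy() & ib.notna().to_numpy()
    n_skip = int((~known).sum())
    if n_skip:
        log.warning("skipped %d LD pairs with SNPs outside the panel", n_skip)
    ia = ia.to_numpy(float)[known].astype(int)
    ib = ib.to_numpy(float)[known].astype(int)
    r2 = r2[known]

    off = ia != ib  # self-pairs carry no information (self r^2 is implied)
    ia, ib, r2 = ia[off], ib[off], r2[off]
    lo, hi = np.minimum(ia, ib), np.maximum(ia, ib)
    order = np.lexsort((hi, lo))
    lo, hi, r2 = lo[order], hi[order], r2[order]
    if lo.size:
        same = (np.diff(lo) == 0) & (np.diff(hi) == 0)
        conflict = same & (np.abs(np.diff(r2)) > 1e-9)
        if conflict.any():
            k = int(np.flatnonzero(conflict)[0])
            raise LDError(
                f"conflicting r^2 for pair ({ids[lo[k]]}, {ids[hi[k]]}): "
                f"{r2[k]:g} vs {r2[k + 1]:g}"
            )
        first = np.concatenate([[True], ~same])
        lo, hi, r2 = lo[first], hi[first], r2[first]

    n = len(ids)
    mat = sp.coo_matrix(
        (np.concatenate([r2, r2]), (np.concatenate([lo, hi]), np.concatenate([hi, lo]))),
        shape=(n, n),
    )
    return LDPanel(ids, mat, meta=meta)


def write_ld(panel: LDPanel, path) -> None:
    """Write the panel's off-diagonal pairs as a PLINK-style ``.ld`` table."""
    coo = sp.triu(panel.r2, k=1).tocoo()
    pd.DataFrame(
        {
            "SNP_A": panel.snps[coo.row],
            "SNP_B": panel.snps[coo.col],
            "R2": coo.data,
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# random pruning
# ---------------------------------------------------------------------------

def random_prune(panel: LDPanel, r2_threshold: float = 0.8, seed: int = 0) -> np.ndarray:
    """One random-pruning pass: boolean keep-mask, deterministic given seed.

    SNPs are visited in a seeded random order; a SNP is kept iff it has
    r^2 <= threshold with every already-kept SNP. Every dropped SNP is in
    LD above the threshold with at least one kept SNP (maximality).
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in (0, 1]")
    adj = (panel.r2 > r2_threshold).tocsr()
    indptr, indices = adj.indptr, adj.indices
    n = panel.n_snps
    order = np.random.default_rng(seed).permutation(n)
    keep = np.zeros(n, dtype=bool)
    blocked = np.zeros(n, dtype=bool)
    for i in order:
        if not blocked[i]:
            keep[i] = True
            blocked[indices[indptr[i] : indptr[i + 1]]] = True
    return keep


@dataclass
class PruneEnsemble:
    """A set of independent random-pruning masks over one panel."""

    masks: np.ndarray          # (n_iter, n_snps) boolean
    seeds: np.ndarray          # per-iteration seeds
    r2_threshold: float

    @property
    def n_iter(self) -> int:
        return self.masks.shape[0]

    @property
    def n_snps(self) -> int:
        return self.masks.shape[1]


def build_prune_ensemble(
    panel: LDPanel,
    n_iter: int = 100,
    base_seed: int = 0,
    r2_threshold: float = 0.8,
) -> PruneEnsemble:
    """`n_iter` independent pruning masks with seeds derived from `base_seed`."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    seeds = np.random.default_rng(base_seed).integers(0, 2**31 - 1, size=n_iter)
    masks = np.empty((n_iter, panel.n_snps), dtype=bool)
    for k, s in enumerate(seeds):
        masks[k] = random_prune(panel, r2_threshold=r2_threshold, seed=int(s))
    return PruneEnsemble(masks=masks, seeds=seeds, r2_threshold=r2_threshold)


# ---------------------------------------------------------------------------
# clumping
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """An independent discovery locus: a lead SNP and its LD companions."""

    lead: str
    members: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)


def clump_loci(hits: pd.DataFrame, panel: LDPanel, r2_threshold: float = 0.2) -> list[Locus]:
    """Greedy clumping of discovery SNPs into independent loci.

    Hits are ranked by ascending CONJFDR (ties: ascending P_TRAIT1 if
    present, then SNP id); the best unassigned hit becomes a lead and
    absorbs all hits with r^2 above the threshold to it. Lead SNPs of
    distinct loci have pairwise r^2 <= threshold.
    """
    if hits.empty:
        return []
    sort_cols = ["CONJFDR"]
    if "P_TRAIT1" in hits.columns:
        sort_cols.append("P_TRAIT1")
    sort_cols.append("SNP")
    df = hits.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    mat = panel.r2_dense(df["SNP"])
    assigned = np.zeros(len(df), dtype=bool)
    loci: list[Locus] = []
    for k in range(len(df)):
        if assigned[k]:
            continue
        take = np.flatnonzero(~assigned & (mat[k] > r2_threshold))  # includes k
        assigned[take] = True
        loci.append(
            Locus(
                lead=df.at[k, "SNP"],
                members=df["SNP"].to_numpy()[take].tolist(),
                stats=df.iloc[k].to_dict(),
            )
        )
    return loci
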