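"""Reading, validation, harmonization, and region filtering of GWAS summary statistics.

Summary statistics are held as pandas DataFrames with canonical upper-case
columns ``SNP, CHR, BP, A1, A2, Z, P, N`` (A1 = reference allele, A2 = effect
allele; Z is the signed association z-score of A2). Coordinates are 1-based
inclusive throughout; the BED reader converts from 0-based half-open.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .utils import P_FLOOR, neglog10, p_from_z, z_from_p

log = logging.getLogger(__name__)

CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "A1", "A2", "Z", "P", "N")

#: maximum tolerated |(-log10 p) - (-log10 2*Phi(-|z|))| before z wins and p
#: is recomputed (absorbs rounding of published z-scores to a few decimals).
ZP_LOG10_TOL = 0.05

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_VALID_ALLELES = frozenset("ACGT")


class SumStatsError(ValueError):
    """Raised for unusable summary-statistics input."""


# ---------------------------------------------------------------------------
# genomic regions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval."""

    chrom: int
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"region start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> np.ndarray:
        chrom = np.asarray(chrom)
        pos = np.asarray(pos)
        return (chrom == self.chrom) & (pos >= self.start) & (pos <= self.end)


#: Extended major histocompatibility complex (hg19), routinely excluded
#: before cross-trait FDR fitting because of its exceptional LD extent.
MHC = GenomicRegion(6, 29_528_318, 33_373_649, "MHC")

#: Nicotinic acetylcholine receptor cluster CHRNA3/CHRNA5/CHRNB4 (hg19).
CHRNA_CLUSTER = GenomicRegion(15, 78_686_690, 79_231_478, "CHRNA")

_REGION_RE = re.compile(r"^(?:chr)?(\d+):([\d,]+)-([\d,]+)$")


def parse_region(text: str, label: str = "") -> GenomicRegion:
    """Parse an inline 1-based region like ``chr6:29,528,318-33,373,649``."""
    m = _REGION_RE.match(text.strip())
    if m is None:
        raise ValueError(f"cannot parse region {text!r}")
    chrom = int(m.group(1))
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    return GenomicRegion(chrom, start, end, label or text.strip())


def read_bed(path) -> list[GenomicRegion]:
    """Read regions from BED (0-based half-open) into 1-based inclusive form."""
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            chrom = int(fields[0].removeprefix("chr"))
            start0, end0 = int(fields[1]), int(fields[2])
            label = fields[3] if len(fields) > 3 else ""
            regions.append(GenomicRegion(chrom, start0 + 1, end0, label))
    return regions


# ---------------------------------------------------------------------------
# reading and validation
# ---------------------------------------------------------------------------

def _resolve_columns(df: pd.DataFrame, column_map: dict | None) -> pd.DataFrame:
    """Rename file columns to canonical names; unmapped names match case-insensitively."""
    if column_map:
        rename = {v: k.upper() for k, v in column_map.items()}
        missing = [v for v in column_map.values() if v not in df.columns]
        if missing:
            raise SumStatsError(f"column_map refers to absent columns: {missing}")
        df = df.rename(columns=rename)
    canon = set(CANONICAL_COLUMNS) | {"SIGN"}
    df = df.rename(columns={c: c.upper() for c in df.columns if c.upper() in canon})
    return df


def read_sumstats(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read one trait's GWAS summary statistics from delimited text.

    Parameters
    ----------
    path : str or file-like
        Tab- or whitespace-delimited text with a header row.
    column_map : dict, optional
        Mapping from canonical names (``SNP, CHR, BP, A1, A2, Z, P, N`` and
        optionally ``SIGN``) to the file's column names. ``SIGN`` names a
        numeric column (e.g. beta or log-odds) whose sign orients z when
        only p-values are provided.

    Missing z-scores are reconstructed from p and the sign column; missing
    p-values from z. When both are present but inconsistent beyond
    ``ZP_LOG10_TOL`` on the -log10 scale, z wins and p is recomputed. Rows
    failing validation are dropped (logged); more than 50% dropped is an error.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    except Exception as exc:  # noqa: BLE001 - surface as domain error
        raise SumStatsError(f"cannot read summary statistics from {path}: {exc}") from exc
    df = _resolve_columns(df, column_map)

    if "SNP" not in df.columns:
        raise SumStatsError("no SNP identifier column resolvable")
    has_z = "Z" in df.columns
    has_p = "P" in df.columns
    if not has_z and not has_p:
        raise SumStatsError("neither Z nor P column resolvable")
    if not has_z and "SIGN" not in df.columns:
        raise SumStatsError("P without Z requires a SIGN column for effect direction")

    n0 = len(df)
    if n0 == 0:
        raise SumStatsError("empty summary-statistics file")
    drop = np.zeros(n0, dtype=bool)

    snp = df["SNP"].astype(str)
    drop |= df["SNP"].isna().to_numpy() | snp.duplicated(keep="first").to_numpy()

    if "A1" in df.columns and "A2" in df.columns:
        a1 = df["A1"].astype(str).str.upper()
        a2 = df["A2"].astype(str).str.upper()
        ok = a1.isin(_VALID_ALLELES) & a2.isin(_VALID_ALLELES) & (a1 != a2)
        drop |= ~ok.to_numpy()
        df["A1"], df["A2"] = a1, a2

    z = pd.to_numeric(df["Z"], errors="coerce").to_numpy(float) if has_z else np.full(n0, np.nan)
    p = pd.to_numeric(df["P"], errors="coerce").to_numpy(float) if has_p else np.full(n0, np.nan)
    sign = (
        pd.to_numeric(df["SIGN"], errors="coerce").to_numpy(float)
        if "SIGN" in df.columns
        else None
    )

    # out-of-range p is invalid; underflowed p is clamped, not dropped
    bad_p = np.isfinite(p) & ((p < 0) | (p > 1))
    p = np.where(bad_p, np.nan, p)
    p = np.where(np.isfinite(p), np.clip(p, P_FLOOR, 1.0), p)

    zf, pf = np.isfinite(z), np.isfinite(p)
    # reconstruct z from p (+ direction), then p from z
    if sign is not None:
        fix = ~zf & pf & np.isfinite(sign)
        z[fix] = z_from_p(p[fix], sign[fix])
        zf = np.isfinite(z)
    p[zf & ~pf] = p_from_z(z[zf & ~pf])
    pf = np.isfinite(p)

    both = zf & pf
    incons = np.zeros(n0, dtype=bool)
    incons[both] = np.abs(neglog10(p[both]) - neglog10(p_from_z(z[both]))) > ZP_LOG10_TOL
    if incons.any():
        log.warning("%d rows with inconsistent z/p: z wins, p recomputed", int(incons.sum()))
        p[incons] = p_from_z(z[incons])

    drop |= ~(np.isfinite(z) & np.isfinite(p))

    n_drop = int(drop.sum())
    if n_drop:
        log.warning("dropped %d/%d rows failing validation", n_drop, n0)
    if n_drop > 0.5 * n0:
        raise SumStatsError(f"{n_drop}/{n0} rows dropped; input unusable")

    out = df.loc[~drop].copy()
    out["Z"] = z[~drop]
    out["P"] = p[~drop]
    for col in ("CHR", "BP", "N"):
        if col in out.columns:
            out[col] = pd.to_numeric(out[col], errors="coerce")
    cols = [c for c in CANONICAL_COLUMNS if c in out.columns]
    return out[cols].reset_index(drop=True)


def write_sumstats(ss: pd.DataFrame, path) -> None:
    """Write a summary-statistics table as tab-delimited text (full precision)."""
    ss.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_reference(path) -> pd.DataFrame:
    """Read a reference SNP set (columns SNP, CHR, BP, A1, A2), sorted by position."""
    ref = pd.read_csv(path, sep=r"\s+", dtype={"SNP": str})
    ref = _resolve_columns(ref, None)
    required = {"SNP", "CHR", "BP", "A1", "A2"}
    if not required.issubset(ref.columns):
        raise SumStatsError(f"reference set needs columns {sorted(required)}")
    if ref["SNP"].duplicated().any():
        raise SumStatsError("duplicate SNP ids in reference set")
    return ref.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Outcome of aligning one trait's table to the reference SNP set."""

    table: pd.DataFrame
    coverage: float          # fraction of reference SNPs retained
    n_input: int
    n_matched: int
    n_flipped: int           # z-signs flipped due to allele order swap
    n_ambiguous: int         # strand-ambiguous (A/T, C/G) SNPs dropped
    n_mismatch: int          # allele configurations irreconcilable with ref


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.map(_COMPLEMENT)


def align_to_reference(ss: pd.DataFrame, ref: pd.DataFrame) -> AlignmentResult:
    """Restrict to reference SNPs and harmonize alleles to reference orientation.

    Allele pairs matching the reference directly or on the complementary
    strand are kept; pairs matching with a1/a2 swapped have their z-score
    sign flipped; strand-ambiguous SNPs (A/T, C/G) are dropped, as are pairs
    that match no configuration. Output rows carry the reference CHR/BP/A1/A2
    and are sorted by position.
    """
    if not {"A1", "A2"}.issubset(ss.columns):
        raise SumStatsError("alignment requires allele columns A1/A2")
    m = ss.merge(
        ref[["SNP", "CHR", "BP", "A1", "A2"]], on="SNP", suffixes=("", "_REF")
    )
    if m.empty:
        raise SumStatsError("zero SNPs overlap the reference set")

    a1, a2 = m["A1"], m["A2"]
    r1, r2 = m["A1_REF"], m["A2_REF"]
    c1, c2 = _complement(a1), _complement(a2)

    ambiguous = (a1 == c2).to_numpy()  # A/T or C/G pair: complement == swap
    same = ((a1 == r1) & (a2 == r2)) | ((c1 == r1) & (c2 == r2))
    swap = ((a1 == r2) & (a2 == r1)) | ((c1 == r2) & (c2 == r1))
    same, swap = same.to_numpy(), swap.to_numpy()

    keep = ~ambiguous & (same | swap)
    flip = keep & swap & ~same
    n_mismatch = int((~ambiguous & ~(same | swap)).sum())

    out = m.loc[keep].copy()
    out["Z"] = np.where(flip[keep], -out["Z"].to_numpy(float), out["Z"].to_numpy(float))
    out["CHR"] = out["CHR_REF"] if "CHR_REF" in out.columns else out["CHR"]
    out["BP"] = out["BP_REF"] if "BP_REF" in out.columns else out["BP"]
    out["A1"], out["A2"] = out["A1_REF"], out["A2_REF"]
    out = out.drop(columns=[c for c in out.columns if c.endswith("_REF")])
    if out["SNP"].duplicated().any():
        dups = out.loc[out["SNP"].duplicated(), "SNP"].tolist()[:5]
        raise SumStatsError(f"duplicated SNP ids after harmonization, e.g. {dups}")
    out = out.sort_values(["CHR", "BP"], kind="mergesort").reset_index(drop=True)
    cols = [c for c in CANONICAL_COLUMNS if c in out.columns]
    out = out[cols]

    res = AlignmentResult(
        table=out,
        coverage=len(out) / len(ref),
        n_input=len(ss),
        n_matched=len(out),
        n_flipped=int(flip.sum()),
        n_ambiguous=int(ambiguous.sum()),
        n_mismatch=n_mismatch,
    )
    log.info(
        "aligned %d/%d SNPs to reference (coverage %.3f; %d flipped, %d ambiguous, %d mismatched)",
        res.n_matched, res.n_input, res.coverage, res.n_flipped, res.n_ambiguous, res.n_mismatch,
    )
    return res


def exclude_region(ss: pd.DataFrame, region: GenomicRegion) -> pd.DataFrame:
    """Remove all SNPs inside the region (1-based inclusive boundaries)."""
    if not {"CHR", "BP"}.issubset(ss.columns):
        raise SumStatsError("region exclusion requires CHR and BP columns")
    inside = region.contains(ss["CHR"].to_numpy(), ss["BP"].to_numpy())
    log.info("excluded %d SNPs in %s", int(inside.sum()), region.label or "region")
    return ss.loc[~inside].reset_index(drop=True)


def exclude_regions(ss: pd.DataFrame, regions) -> pd.DataFrame:
    for region in regions:
        ss = exclude_region(ss, region)
    return ss
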