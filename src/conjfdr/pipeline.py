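"""End-to-end orchestration: harmonize -> correct -> exclude -> enrich -> conjFDR -> clump.

The pipeline reproduces the workflow shape of a cross-trait conditional-FDR
study: both traits' summary statistics are aligned to a common reference
SNP set, genomic control is applied per trait, shared-control correlation
is estimated on null SNPs and whitened out, high-LD regions (the MHC by
default) are excluded and the FDR estimate refit on the remainder,
stratified Q-Q curves and LD-score fold-enrichment tests describe the
polygenic overlap, and SNPs below the conjunction-FDR level are clumped
into independent (r^2 <= 0.2) discovery loci.

Every stage is a pure function of (inputs, config, seed); a provenance
record captures all constants, counts, and estimates needed to re-execute
the run, and output tables are byte-identical across repeated runs with
the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import fdr as fdrmod
from . import ld as ldmod
from . import preprocess as prep
from . import simulate as sim
from . import sumstats as ssio
from .utils import p_from_z

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage failure; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        self.stage = stage
        self.code = code
        super().__init__(f"[{stage}/{code}] {message}")


@dataclass
class CoverageReport:
    passed: bool
    fraction: float
    min_fraction: float


def coverage_check(ss: pd.DataFrame, ref: pd.DataFrame, min_fraction: float = 0.2) -> CoverageReport:
    """Fail when a study covers too small a fraction of the reference SNPs."""
    frac = float(ss["SNP"].isin(ref["SNP"]).sum()) / len(ref)
    return CoverageReport(passed=frac >= min_fraction, fraction=frac, min_fraction=min_fraction)


@dataclass
class RunConfig:
    """Configuration of one conjunction-FDR run.

    Either file inputs (`sumstats1`, `sumstats2`, `ld_file`, `reference`)
    or `simulate=True` with `sim_params` overrides must be supplied.
    """

    out_dir: str = "conjfdr_run"
    seed: int = 0
    # inputs
    simulate: bool = False
    sim_params: dict = field(default_factory=dict)
    sumstats1: str | None = None
    sumstats2: str | None = None
    ld_file: str | None = None
    reference: str | None = None
    column_map1: dict | None = None
    column_map2: dict | None = None
    # analysis constants
    exclude_mhc: bool = True
    exclude_chrna: bool = False
    extra_regions: list = field(default_factory=list)  # "chr:start-end" strings
    strata_thresholds: tuple = (1.0, 0.1, 0.01, 0.001)
    qq_truncation: float = 7.3
    prune_r2: float = 0.8
    prune_iters: int = 100
    clump_r2: float = 0.2
    fdr_level: float = 0.01
    null_z_threshold: float = 2.0
    adjust_overlap: bool = True
    coverage_min: float = 0.2
    n_enrichment_blocks: int = 200
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineError("config", "unknown-keys", f"unknown config keys {sorted(unknown)}")
        return cls(**data)


def _regions(config: RunConfig) -> list[ssio.GenomicRegion]:
    regions = []
    if config.exclude_mhc:
        regions.append(ssio.MHC)
    if config.exclude_chrna:
        regions.append(ssio.CHRNA_CLUSTER)
    regions += [ssio.parse_region(r) for r in config.extra_regions]
    return regions


def _load_inputs(config: RunConfig, out: Path):
    if config.simulate:
        params = sim.SimParams(**{"seed": config.seed, **config.sim_params})
        ref, panel = sim.simulate_panel(params)
        ss1, ss2, truth = sim.simulate_gwas_pair(panel, params)
        truth.to_frame(panel.snps).to_csv(out / "truth.tsv", sep="\t", index=False, float_format="%.17g")
        return ref, panel, ss1, ss2
    for key in ("sumstats1", "sumstats2", "ld_file", "reference"):
        if getattr(config, key) is None:
            raise PipelineError("inputs", "missing-input", f"config.{key} is required")
    ref = ssio.read_reference(config.reference)
    panel = ldmod.load_ld(config.ld_file, ref)
    ss1 = ssio.read_sumstats(config.sumstats1, config.column_map1)
    ss2 = ssio.read_sumstats(config.sumstats2, config.column_map2)
    return ref, panel, ss1, ss2


@dataclass
class RunReport:
    out_dir: str
    provenance: dict
    discoveries: pd.DataFrame
    loci: list


def run_conjunction_analysis(config: RunConfig) -> RunReport:
    """Execute the full cross-trait workflow; write tables and provenance."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov: dict = {"config": _jsonable(dataclasses.asdict(config)), "stages": {}}

    def stage(name):
        prov["stages"][name] = {}
        return prov["stages"][name]

    # --- inputs -----------------------------------------------------------
    rec = stage("inputs")
    try:
        ref, panel, ss1, ss2 = _load_inputs(config, out)
    except (ssio.SumStatsError, ldmod.LDError, sim.SimulationError) as exc:
        raise PipelineError("inputs", "load-failed", str(exc)) from exc
    rec.update(n_reference=len(ref), n_trait1=len(ss1), n_trait2=len(ss2))

    # --- harmonize --------------------------------------------------------
    rec = stage("harmonize")
    try:
        a1 = ssio.align_to_reference(ss1, ref)
        a2 = ssio.align_to_reference(ss2, ref)
    except ssio.SumStatsError as exc:
        raise PipelineError("harmonize", "align-failed", str(exc)) from exc
    for tag, a in (("trait1", a1), ("trait2", a2)):
        rec[tag] = {
            "coverage": a.coverage,
            "n_matched": a.n_matched,
            "n_flipped": a.n_flipped,
            "n_ambiguous": a.n_ambiguous,
        }
        cov = coverage_check(a.table, ref, config.coverage_min)
        if not cov.passed:
            raise PipelineError(
                "harmonize",
                "low-coverage",
                f"{tag} covers {cov.fraction:.3f} < {config.coverage_min} of reference",
            )
    common = a1.table.merge(a2.table[["SNP"]], on="SNP")["SNP"]
    t1 = a1.table[a1.table["SNP"].isin(common)].reset_index(drop=True)
    t2 = a2.table[a2.table["SNP"].isin(common)].reset_index(drop=True)
    t2 = t2.set_index("SNP").loc[t1["SNP"]].reset_index()
    rec["n_common"] = len(t1)

    # --- genomic control --------------------------------------------------
    rec = stage("genomic_control")
    try:
        gc1 = prep.apply_genomic_control(t1)
        gc2 = prep.apply_genomic_control(t2)
    except prep.PreprocessError as exc:
        raise PipelineError("genomic_control", "estimation-failed", str(exc)) from exc
    t1, t2 = gc1.table, gc2.table
    rec.update(lambda_trait1=gc1.lambda_gc, lambda_trait2=gc2.lambda_gc)

    # --- sample-overlap adjustment ---------------------------------------
    rec = stage("overlap")
    sub_panel = panel.subset(t1["SNP"])
    if config.adjust_overlap:
        try:
            model = prep.estimate_null_correlation(
                t1["Z"].to_numpy(),
                t2["Z"].to_numpy(),
                z_threshold=config.null_z_threshold,
                panel=sub_panel,
                seed=config.seed,
            )
        except prep.PreprocessError as exc:
            raise PipelineError("overlap", "estimation-failed", str(exc)) from exc
        z1w, z2w = prep.decorrelate_overlap(t1["Z"].to_numpy(), t2["Z"].to_numpy(), model)
        t1 = t1.assign(Z=z1w, P=p_from_z(z1w))
        t2 = t2.assign(Z=z2w, P=p_from_z(z2w))
        rec.update(rho=model.rho, n_null=model.n_null, z_threshold=model.z_threshold)
    else:
        rec.update(rho=None, skipped=True)

    # --- region exclusion and refit preparation --------------------------
    rec = stage("exclude_regions")
    regions = _regions(config)
    n_before = len(t1)
    t1 = ssio.exclude_regions(t1, regions)
    t2 = t2[t2["SNP"].isin(t1["SNP"])].reset_index(drop=True)
    rec.update(
        regions=[r.label or f"{r.chrom}:{r.start}-{r.end}" for r in regions],
        n_removed=n_before - len(t1),
        n_remaining=len(t1),
    )
    sub_panel = panel.subset(t1["SNP"])

    # --- pruning ensemble -------------------------------------------------
    rec = stage("prune")
    ensemble = ldmod.build_prune_ensemble(
        sub_panel, n_iter=config.prune_iters, base_seed=config.seed, r2_threshold=config.prune_r2
    )
    rec.update(
        n_iter=ensemble.n_iter,
        r2_threshold=ensemble.r2_threshold,
        mean_kept=float(ensemble.masks.sum(axis=1).mean()),
        base_seed=config.seed,
    )

    p1 = t1["P"].to_numpy()
    p2 = t2["P"].to_numpy()
    z1 = t1["Z"].to_numpy()

    # --- stratified Q-Q and enrichment ------------------------------------
    rec = stage("enrichment")
    strata = enr.QqStrata(thresholds=tuple(config.strata_thresholds), truncation=config.qq_truncation)
    curves = enr.stratified_qq(p1, p2, strata=strata, ensemble=ensemble)
    qq_rows = []
    for c in curves:
        for x, y in zip(c.theoretical, c.observed):
            if np.isfinite(y):
                qq_rows.append((c.threshold, x, y, c.n_snps))
    pd.DataFrame(qq_rows, columns=["THRESHOLD", "THEORETICAL", "OBSERVED", "N_SNPS"]).to_csv(
        out / "qq_curves.tsv", sep="\t", index=False, float_format="%.10g"
    )
    ld_scores = sub_panel.ld_scores()
    n_tests = 12  # conventional 4 secondary traits x 3 conditional strata
    enr_rows = []
    for t in strata.thresholds[1:]:
        mask = p2 < t
        if 0 < mask.sum() < len(p2):
            res = enr.fold_enrichment_ldsc(
                z1, ld_scores, mask, panel=sub_panel, n_blocks=config.n_enrichment_blocks
            )
            p_adj = float(enr.bonferroni_adjust(res.p_value, n_tests)) if np.isfinite(res.p_value) else np.nan
            enr_rows.append((t, res.n_stratum, res.fold, res.se, res.p_value, p_adj, res.informative))
        else:
            enr_rows.append((t, int(mask.sum()), np.nan, np.nan, np.nan, np.nan, False))
    enr_df = pd.DataFrame(
        enr_rows, columns=["THRESHOLD", "N_STRATUM", "FOLD", "SE", "P", "P_ADJ", "INFORMATIVE"]
    )
    enr_df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g")
    rec.update(n_tests_bonferroni=n_tests, strata=list(strata.thresholds))
    if config.make_plots:
        enr.plot_qq(curves, out / "qq.png", title="trait 1 | trait 2")

    # --- conjunction FDR --------------------------------------------------
    rec = stage("conjfdr")
    fcfg = fdrmod.FdrConfig(fdr_level=config.fdr_level)
    conj = fdrmod.conj_fdr(p1, p2, config=fcfg, ensemble=ensemble)
    per_snp = t1[[c for c in ("SNP", "CHR", "BP", "A1", "A2") if c in t1.columns]].copy()
    per_snp["P_TRAIT1"] = p1
    per_snp["P_TRAIT2"] = p2
    per_snp["Z_TRAIT1"] = z1
    per_snp["Z_TRAIT2"] = t2["Z"].to_numpy()
    per_snp["CONDFDR_1_2"] = conj.cond_fdr_1_given_2
    per_snp["CONDFDR_2_1"] = conj.cond_fdr_2_given_1
    per_snp["CONJFDR"] = conj.conj_fdr
    per_snp.to_csv(out / "conjfdr.tsv", sep="\t", index=False, float_format="%.10g")
    discoveries = fdrmod.call_discoveries(conj, t1, t2)
    rec.update(fdr_level=config.fdr_level, n_discovery_snps=len(discoveries))

    # --- clumping ---------------------------------------------------------
    rec = stage("clump")
    loci = ldmod.clump_loci(discoveries, sub_panel, r2_threshold=config.clump_r2)
    loci_rows = []
    for locus in loci:
        row = {k: v for k, v in locus.stats.items()}
        row["N_MEMBERS"] = len(locus.members)
        row["MEMBERS"] = ",".join(locus.members)
        loci_rows.append(row)
    loci_df = pd.DataFrame(loci_rows)
    loci_df.to_csv(out / "loci.tsv", sep="\t", index=False, float_format="%.10g")
    rec.update(r2_threshold=config.clump_r2, n_loci=len(loci))

    with open(out / "provenance.json", "w") as fh:
        json.dump(_jsonable(prov), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunReport(out_dir=str(out), provenance=prov, discoveries=discoveries, loci=loci)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
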