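"""Config-driven end-to-end orchestration.

Stages run in a fixed order — simulate/load, QC, split, discovery
association, clumping, grid scoring, replication fits, FDR adjustment,
overlap — and communicate through files in the output directory, so a
monolithic :func:`run_pipeline` and stage-wise command-line invocation are
the same computation. Everything is deterministic given the master seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import assoc_scan, gene_min_p, read_assoc, write_assoc
from .clumping import ClumpResult, clump
from .evaluation import phenotype_correlations, run_test_families, subset_overlap
from .genotype_io import GenotypeDataset, QCThresholds, qc_filter, read_plink, write_plink
from .profile_scoring import (
    FitResult,
    best_fit_scan,
    compute_score,
    scan_to_frame,
    threshold_grid,
)
from .synthetic_cohort import (
    DEFAULT_GENE_REGIONS,
    LANGUAGE_TRAITS,
    SDQ_TRAITS,
    build_cohort,
    default_config,
    split_cohort,
)

__all__ = ["PipelineConfig", "ReportBundle", "StageError", "run_pipeline",
           "STAGES", "run_stage"]

logger = logging.getLogger("polyprofile")

DEFAULT_CROSS_TARGETS = ["dld_status"] + SDQ_TRAITS


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis end to end."""

    mode: str = "simulate"                       # "simulate" | "load"
    seed: int = 0
    out_dir: str = "polyprofile_out"
    # simulate mode
    n_individuals: int = 5435
    ld_rho: float = 0.93
    missing_rate: float = 0.01
    # load mode
    bed: str | None = None
    bim: str | None = None
    fam: str | None = None
    phenotypes: str | None = None
    gene_regions: dict = field(default_factory=lambda: {
        g: list(v) for g, v in DEFAULT_GENE_REGIONS.items()
    })
    # QC
    qc_min_maf: float = 0.01
    qc_min_call_rate: float = 0.95
    qc_hwe_p_floor: float = 5e-7
    qc_max_individual_missingness: float = 0.03
    # clumping
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    clump_p_ceiling: float = 1.0
    # scoring grid and best-fit mode
    grid_start: float = 0.01
    grid_stop: float = 0.50
    grid_step: float = 0.01
    best_fit_mode: str = "scan_in_target"
    # families
    base_traits: list[str] = field(default_factory=lambda: list(LANGUAGE_TRAITS))
    cross_base: str = "expressive_8y"
    cross_targets: list[str] = field(default_factory=lambda: list(DEFAULT_CROSS_TARGETS))
    dld_link: str = "linear"                      # "linear" | "logistic"
    fdr: float = 0.05

    def validate(self) -> None:
        if self.mode not in ("simulate", "load"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "load":
            for name in ("bed", "bim", "fam", "phenotypes"):
                if getattr(self, name) is None:
                    raise ValueError(f"load mode requires the {name!r} path")
        if self.best_fit_mode not in ("scan_in_target", "fixed_from_discovery"):
            raise ValueError(f"unknown best_fit_mode {self.best_fit_mode!r}")
        if self.dld_link not in ("linear", "logistic"):
            raise ValueError(f"unknown dld_link {self.dld_link!r}")
        if self.cross_base not in self.base_traits:
            raise ValueError("cross_base must be one of base_traits")
        self.qc_thresholds().validate()

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(self.qc_min_maf, self.qc_min_call_rate,
                            self.qc_hwe_p_floor, self.qc_max_individual_missingness)

    def grid(self) -> np.ndarray:
        return threshold_grid(self.grid_start, self.grid_stop, self.grid_step)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class ReportBundle:
    """Paths and in-memory records of everything the pipeline produced."""

    out_dir: Path
    config: PipelineConfig
    files: dict[str, str] = field(default_factory=dict)
    consistency: object = None
    cross: object = None
    overlap: object = None

    def manifest(self) -> dict:
        return json.loads((self.out_dir / "manifest.json").read_text())


# ---------------------------------------------------------------- stage I/O

def _out(cfg: PipelineConfig) -> Path:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise StageError(stage, "missing-dependency",
                         f"{path.name} not found - run the {produced_by!r} stage first")
    return path


def _load_genotypes(prefix: Path, stage: str, produced_by: str) -> GenotypeDataset:
    for ext in (".bed", ".bim", ".fam"):
        _require(prefix.with_suffix(ext), stage, produced_by)
    return read_plink(prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
                      prefix.with_suffix(".fam"))


def _load_phenotypes(path: Path, stage: str, produced_by: str) -> pd.DataFrame:
    _require(path, stage, produced_by)
    return pd.read_csv(path, sep="\t", index_col="iid")


# ------------------------------------------------------------------- stages

def stage_simulate(cfg: PipelineConfig) -> None:
    """Simulate (or import) the cohort; writes genotypes + phenotypes + truth."""
    out = _out(cfg)
    if cfg.mode == "load":
        dataset = read_plink(cfg.bed, cfg.bim, cfg.fam)
        dataset.annotate_genes({g: tuple(v) for g, v in cfg.gene_regions.items()})
        pheno = pd.read_csv(cfg.phenotypes, sep="\t", index_col="iid")
        truth = {"mode": "load", "source": {"bed": cfg.bed, "phenotypes": cfg.phenotypes}}
    else:
        sim = default_config(n_individuals=cfg.n_individuals, seed=cfg.seed,
                             ld_rho=cfg.ld_rho, missing_rate=cfg.missing_rate)
        dataset, cohort = build_cohort(sim)
        pheno = cohort.phenotypes
        truth = {
            "mode": "simulate",
            "seed": cfg.seed,
            "architectures": [
                {
                    "trait": a.name,
                    "h2": a.h2,
                    "causal_snps": list(dataset.variants["snp"].iloc[a.causal_snp_indices]),
                    "effect_sizes": [float(b) for b in a.effect_sizes],
                    "shared_with": None if a.shared_with is None else {
                        "trait": a.shared_with[0],
                        "snps": list(dataset.variants["snp"].iloc[np.asarray(a.shared_with[1])]),
                    },
                }
                for a in sim.architectures
            ],
        }
    write_plink(dataset, out / "genotypes")
    # gene labels live outside the BIM; persisted separately for later stages
    dataset.variants[["snp", "gene"]].to_csv(out / "genes.tsv", sep="\t", index=False)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index_label="iid")
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    logger.info("simulate: %d individuals x %d SNPs", dataset.n_individuals, dataset.n_snps)


def _annotated(out: Path, prefix: str, stage: str, produced_by: str) -> GenotypeDataset:
    dataset = _load_genotypes(out / prefix, stage, produced_by)
    genes_path = out / "genes.tsv"
    if genes_path.exists():
        genes = pd.read_csv(genes_path, sep="\t", dtype=str).set_index("snp")["gene"]
        dataset.variants["gene"] = genes.reindex(dataset.variants["snp"]).fillna("").to_numpy()
    return dataset


def stage_qc(cfg: PipelineConfig) -> None:
    """Sample- then variant-level QC; writes filtered genotypes + report."""
    out = _out(cfg)
    dataset = _annotated(out, "genotypes", "qc", "simulate")
    filtered, report = qc_filter(dataset, cfg.qc_thresholds())
    write_plink(filtered, out / "genotypes_qc")
    report.to_json(out / "qc_report.json")
    logger.info("qc: %d -> %d individuals, %d -> %d SNPs",
                report.n_individuals_in, report.n_individuals_out,
                report.n_snps_in, report.n_snps_out)


def stage_assoc(cfg: PipelineConfig) -> None:
    """Split the cohort and run the discovery association scan per base trait."""
    out = _out(cfg)
    dataset = _annotated(out, "genotypes_qc", "assoc", "qc")
    pheno = _load_phenotypes(out / "phenotypes.tsv", "assoc", "simulate")
    absent = [t for t in cfg.base_traits if t not in pheno.columns]
    if absent:
        raise StageError("assoc", "unknown-trait",
                         f"traits absent from phenotype table: {absent}")

    disc_idx, repl_idx = split_cohort(dataset.n_individuals, cfg.seed)
    split = {
        "discovery": list(dataset.samples["iid"].iloc[disc_idx]),
        "replication": list(dataset.samples["iid"].iloc[repl_idx]),
    }
    (out / "split.json").write_text(json.dumps(split, indent=2))

    discovery = dataset.take_individuals(disc_idx)
    tables = assoc_scan(discovery, pheno, cfg.base_traits)
    for trait, table in tables.items():
        write_assoc(table, out / f"assoc_{trait}.tsv")
    summary = gene_min_p(tables)
    summary.matrix.to_csv(out / "gene_min_p.tsv", sep="\t")
    logger.info("assoc: %d traits x %d SNPs in discovery n=%d",
                len(tables), dataset.n_snps, discovery.n_individuals)


def stage_clump(cfg: PipelineConfig) -> None:
    """LD-clump each base trait's discovery association table."""
    out = _out(cfg)
    dataset = _annotated(out, "genotypes_qc", "clump", "qc")
    split = json.loads(_require(out / "split.json", "clump", "assoc").read_text())
    disc = dataset.take_individuals(dataset.iids.get_indexer(split["discovery"]))
    for trait in cfg.base_traits:
        assoc = read_assoc(_require(out / f"assoc_{trait}.tsv", "clump", "assoc"))
        result = clump(assoc, disc, cfg.clump_r2, cfg.clump_window_kb, cfg.clump_p_ceiling)
        result.to_tsv(out / f"clump_{trait}.tsv")
        logger.info("clump[%s]: %d -> %d index SNPs", trait,
                    len(result.considered), len(result.index_snps))


def _dld_column(pheno: pd.DataFrame) -> pd.Series:
    status = pheno["dld_status"]
    y = pd.Series(np.nan, index=status.index, name="dld_status")
    y[status == "affected"] = 1.0
    y[status == "unaffected"] = 0.0
    return y


def _target_column(pheno: pd.DataFrame, trait: str) -> pd.Series:
    if trait == "dld_status":
        return _dld_column(pheno)
    if trait not in pheno.columns:
        raise StageError("score", "unknown-trait", f"target trait {trait!r} not found")
    return pheno[trait]


def _logistic_fit(score, y: pd.Series) -> FitResult:
    """Logistic alternative for the binary caseness target: McFadden pseudo-R²
    and the likelihood-ratio p."""
    import statsmodels.api as sm

    aligned = pd.concat([score.scores.rename("score"), y.rename("y")],
                        axis=1, join="inner").dropna()
    model = sm.Logit(aligned["y"], sm.add_constant(aligned["score"])).fit(disp=0)
    return FitResult(score.threshold, score.n_snps, float(model.prsquared),
                     float(model.params["score"]), float(model.llr_pvalue),
                     target_trait="dld_status", base_trait=score.base_trait,
                     cohort="replication")


def stage_score(cfg: PipelineConfig) -> None:
    """Grid scoring and best-fit selection for both test families."""
    out = _out(cfg)
    dataset = _annotated(out, "genotypes_qc", "score", "qc")
    pheno = _load_phenotypes(out / "phenotypes.tsv", "score", "simulate")
    split = json.loads(_require(out / "split.json", "score", "assoc").read_text())
    disc = dataset.take_individuals(dataset.iids.get_indexer(split["discovery"]))
    repl = dataset.take_individuals(dataset.iids.get_indexer(split["replication"]))
    grid = cfg.grid()

    def weights_for(trait: str) -> pd.DataFrame:
        assoc = read_assoc(_require(out / f"assoc_{trait}.tsv", "score", "assoc"))
        clumped = ClumpResult.from_tsv(_require(out / f"clump_{trait}.tsv", "score", "clump"))
        return assoc.loc[assoc["snp"].isin(clumped.index_snps),
                         ["snp", "a1", "beta", "p"]].reset_index(drop=True)

    def one_fit(weights: pd.DataFrame, base: str, target: str) -> dict:
        y = _target_column(pheno, target).reindex(pd.Index(repl.iids)).rename(target)
        y_disc = (pheno[base].reindex(pd.Index(disc.iids))
                  if cfg.best_fit_mode == "fixed_from_discovery" else None)
        fits, best = best_fit_scan(
            weights, repl, y, grid, mode=cfg.best_fit_mode,
            discovery_dataset=disc, discovery_trait=y_disc, base_trait=base,
        )
        if target == "dld_status" and cfg.dld_link == "logistic":
            score = compute_score(repl, weights, best.threshold, base)
            best = _logistic_fit(score, y)
        scan_path = out / f"scan_{base}__{target}.tsv"
        scan_to_frame(fits).to_csv(scan_path, sep="\t", index=False, float_format="%.10g")
        best_snps = sorted(weights.loc[weights["p"] <= best.threshold, "snp"])
        return {"base": base, "target": target, "best": best.to_dict(),
                "best_snps": best_snps, "scan_file": scan_path.name}

    records = {"consistency": [], "cross": []}
    for trait in cfg.base_traits:
        records["consistency"].append(one_fit(weights_for(trait), trait, trait))
    cross_weights = weights_for(cfg.cross_base)
    for target in cfg.cross_targets:
        records["cross"].append(one_fit(cross_weights, cfg.cross_base, target))
    (out / "fits.json").write_text(json.dumps(records, indent=2))
    logger.info("score: %d consistency + %d cross-trait best fits",
                len(records["consistency"]), len(records["cross"]))


def stage_evaluate(cfg: PipelineConfig) -> ReportBundle:
    """FDR adjustment, best-fit SNP-set overlap, correlations, manifest."""
    out = _out(cfg)
    records = json.loads(_require(out / "fits.json", "evaluate", "score").read_text())

    def as_fit(rec: dict) -> FitResult:
        b = rec["best"]
        return FitResult(b["threshold"], b["n_snps"], b["r2"], b["coef"], b["p"],
                         target_trait=b["target_trait"], base_trait=b["base_trait"],
                         cohort=b.get("cohort", "replication"),
                         degenerate=b.get("degenerate", False))

    consistency_fits = [(r["base"], r["target"], as_fit(r)) for r in records["consistency"]]
    cross_fits = [(r["base"], r["target"], as_fit(r)) for r in records["cross"]]
    consistency, cross = run_test_families(
        consistency_fits, cross_fits,
        expected_consistency=cfg.base_traits,
        expected_cross=[(cfg.cross_base, t) for t in cfg.cross_targets],
        fdr=cfg.fdr,
    )
    families = {"consistency": consistency.to_dict(), "cross_trait": cross.to_dict()}
    (out / "families.json").write_text(json.dumps(families, indent=2))
    consistency.to_frame().to_csv(out / "family_consistency.tsv", sep="\t", index=False)
    cross.to_frame().to_csv(out / "family_cross_trait.tsv", sep="\t", index=False)

    base_rec = next(r for r in records["consistency"] if r["base"] == cfg.cross_base)
    peer = [r for r in records["cross"] if r["target"] == "peer_problems_11y"]
    overlap = None
    if peer:
        overlap = subset_overlap(base_rec["best_snps"], peer[0]["best_snps"])
        (out / "overlap.json").write_text(json.dumps(overlap.to_dict(), indent=2))

    pheno = _load_phenotypes(out / "phenotypes.tsv", "evaluate", "simulate")
    trait_cols = [t for t in cfg.base_traits + cfg.cross_targets
                  if t in pheno.columns and t != "dld_status"]
    corr = phenotype_correlations(pheno, trait_cols)
    corr.lower_triangle_tsv(out / "correlations.tsv")

    bundle = ReportBundle(out, cfg, consistency=consistency, cross=cross, overlap=overlap)
    files = sorted(p.name for p in out.iterdir()
                   if p.is_file() and p.name != "manifest.json")
    bundle.files = {name: str(out / name) for name in files}
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": asdict(cfg),
        "files": files,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return bundle


STAGES = {
    "simulate": stage_simulate,
    "qc": stage_qc,
    "assoc": stage_assoc,
    "clump": stage_clump,
    "score": stage_score,
    "evaluate": stage_evaluate,
}


def run_stage(name: str, cfg: PipelineConfig):
    """Run one named stage, wrapping unexpected failures with the stage name."""
    cfg.validate()
    start = time.monotonic()
    try:
        result = STAGES[name](cfg)
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise StageError(name, type(exc).__name__, str(exc)) from exc
    logger.info("stage %s finished in %.1fs", name, time.monotonic() - start)
    return result


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Run every stage in order; deterministic given the master seed."""
    config.validate()
    bundle = None
    for name in STAGES:
        bundle = run_stage(name, config)
    return bundle
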