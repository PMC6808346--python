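"""Per-SNP additive-model association and gene-level minimum-p summaries.

Each SNP is tested by ordinary least squares of the quantitative phenotype
on the 0/1/2 dosage with an intercept (complete cases per SNP, matching the
convention of PLINK's ``--linear``); the two-sided p comes from the t
distribution with n-2 degrees of freedom. Monomorphic or zero-variance
cases are flagged degenerate and emitted with undefined beta and p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset

__all__ = ["assoc_linear", "assoc_scan", "gene_min_p", "GeneMinPSummary",
           "ASSOC_COLUMNS", "write_assoc", "read_assoc"]

ASSOC_COLUMNS = ["snp", "chr", "bp", "a1", "beta", "se", "t", "p", "n", "gene"]


def assoc_linear(dosage, phenotype) -> dict:
    """Simple-regression association of one phenotype on one dosage column.

    Returns a dict with keys beta, se, t, p, n, degenerate.
    """
    x = np.asarray(dosage, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete (dosage, phenotype) pairs")

    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx == 0.0 or syy == 0.0:
        return {"beta": np.nan, "se": np.nan, "t": np.nan, "p": 1.0,
                "n": n, "degenerate": True}
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    rss = syy - beta * sxy
    sigma2 = max(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / sxx)
    if se == 0.0:
        return {"beta": beta, "se": 0.0, "t": np.inf, "p": 0.0,
                "n": n, "degenerate": False}
    t = beta / se
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return {"beta": beta, "se": se, "t": t, "p": max(p, np.finfo(float).tiny),
            "n": n, "degenerate": False}


def assoc_scan(dataset: GenotypeDataset, phenotypes: pd.DataFrame,
               traits: list[str] | None = None) -> dict[str, pd.DataFrame]:
    """Vectorized association of every SNP against each requested trait.

    ``phenotypes`` is indexed by iid; rows are aligned to the dataset's
    samples. Returns one association table (``ASSOC_COLUMNS``) per trait.
    """
    if traits is None:
        traits = list(phenotypes.columns)
    missing_traits = [t for t in traits if t not in phenotypes.columns]
    if missing_traits:
        raise KeyError(f"traits absent from phenotype table: {missing_traits}")

    pheno = phenotypes.reindex(dataset.iids)
    g = dataset.dosages
    gmask = ~np.isnan(g)
    g0 = np.nan_to_num(g)

    v = dataset.variants
    base = {
        "snp": v["snp"].to_numpy(),
        "chr": v["chrom"].to_numpy(),
        "bp": v["pos"].to_numpy(),
        "a1": v["a1"].to_numpy(),
        "gene": v["gene"].to_numpy() if "gene" in v.columns else np.full(len(v), ""),
    }

    tables: dict[str, pd.DataFrame] = {}
    tiny = np.finfo(float).tiny
    for trait in traits:
        y = pheno[trait].to_numpy(dtype=float)
        yok = ~np.isnan(y)
        valid = gmask & yok[:, None]
        n = valid.sum(axis=0).astype(float)
        y0 = np.where(yok, y, 0.0)

        sum_x = (g0 * valid).sum(axis=0)
        sum_x2 = (g0 * g0 * valid).sum(axis=0)
        sum_y = y0 @ valid
        sum_y2 = (y0 * y0) @ valid
        sum_xy = y0 @ (g0 * valid)

        with np.errstate(divide="ignore", invalid="ignore"):
            sxx = sum_x2 - sum_x * sum_x / n
            syy = sum_y2 - sum_y * sum_y / n
            sxy = sum_xy - sum_x * sum_y / n
            beta = sxy / sxx
            rss = np.maximum(syy - beta * sxy, 0.0)
            se = np.sqrt(rss / (n - 2) / sxx)
            t = beta / se
            p = 2.0 * stats.t.sf(np.abs(t), np.maximum(n - 2, 1))

        degenerate = (sxx <= 0) | (syy <= 0) | (n < 3)
        beta[degenerate] = np.nan
        se[degenerate] = np.nan
        t[degenerate] = np.nan
        p[degenerate] = 1.0
        p = np.clip(p, tiny, 1.0)

        tables[trait] = pd.DataFrame({
            **base, "beta": beta, "se": se, "t": t, "p": p,
            "n": n.astype(int),
        })[ASSOC_COLUMNS]
    return tables


@dataclass
class GeneMinPSummary:
    """Gene x trait minimum-p matrix with marginal minima and argmin labels."""

    matrix: pd.DataFrame                    # genes x traits, min p per cell
    argmin_snp: pd.DataFrame                # snp id attaining each cell minimum
    gene_min: pd.Series = field(default=None)
    gene_min_trait: pd.Series = field(default=None)
    trait_min: pd.Series = field(default=None)
    trait_min_gene: pd.Series = field(default=None)
    empty_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = self.matrix
        self.gene_min = m.min(axis=1)
        self.gene_min_trait = m.dropna(how="all").idxmin(axis=1).reindex(m.index)
        self.trait_min = m.min(axis=0)
        self.trait_min_gene = (
            m.dropna(axis=1, how="all").idxmin(axis=0).reindex(m.columns)
        )

    @property
    def overall_min(self) -> float:
        return float(np.nanmin(self.matrix.to_numpy()))


def gene_min_p(assoc_tables: dict[str, pd.DataFrame],
               genes: list[str] | None = None) -> GeneMinPSummary:
    """Minimum association p per (gene, trait) cell with margins.

    Genes carrying zero SNPs yield undefined (NaN) cells and are reported
    in ``empty_genes``.
    """
    traits = list(assoc_tables)
    if genes is None:
        genes = sorted({g for t in traits for g in assoc_tables[t]["gene"].unique() if g})
    mat = pd.DataFrame(index=pd.Index(genes, name="gene"),
                       columns=traits, dtype=float)
    arg = pd.DataFrame(index=mat.index, columns=traits, dtype=object)
    empty: set[str] = set(genes)
    for trait, table in assoc_tables.items():
        grouped = table.groupby("gene")["p"]
        for gene, sub in grouped:
            if gene not in mat.index:
                continue
            empty.discard(gene)
            j = sub.idxmin()
            mat.loc[gene, trait] = sub.loc[j]
            arg.loc[gene, trait] = table.loc[j, "snp"]
    return GeneMinPSummary(matrix=mat, argmin_snp=arg, empty_genes=sorted(empty))


def write_assoc(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_assoc(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"snp": str, "chr": str, "a1": str, "gene": str})
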