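"""Weighted polygenic profile scores over a p-value threshold grid.

A profile score at threshold T averages beta_j * dosage_ij over the
post-clump SNPs whose discovery p is at or below T; missing dosages are
imputed as twice the effect-allele frequency of the scored cohort. The
included sets are nested across the grid (S(T1) subset of S(T2) for
T1 <= T2), which the scan exploits by accumulating weighted dosages once.

Averaging (rather than summing) over included SNPs keeps scores comparable
across thresholds with different SNP counts; since R² and the regression p
are invariant to affine rescaling of the score, the reported statistics are
unaffected by this choice.

Two best-fit modes are provided: ``scan_in_target`` scans the grid in the
evaluation cohort and reports the maximal-R² threshold; and
``fixed_from_discovery`` locates the best threshold in the discovery cohort
and evaluates only that threshold in the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeDataset

__all__ = [
    "ScoreProfile",
    "FitResult",
    "threshold_grid",
    "compute_score",
    "fit_score_model",
    "best_fit_scan",
    "AlleleMismatchError",
]

WEIGHT_COLUMNS = ["snp", "a1", "beta", "p"]


class AlleleMismatchError(ValueError):
    """Effect alleles that cannot be reconciled to the scored dataset."""


@dataclass
class ScoreProfile:
    """Per-individual weighted score at one p threshold."""

    threshold: float
    snps: list[str]
    scores: pd.Series | None
    base_trait: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def empty(self) -> bool:
        return self.n_snps == 0


@dataclass
class FitResult:
    """OLS fit of a target trait on a profile score."""

    threshold: float
    n_snps: int
    r2: float
    coef: float
    p: float
    target_trait: str = ""
    base_trait: str = ""
    cohort: str = ""
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "base_trait": self.base_trait,
            "target_trait": self.target_trait,
            "cohort": self.cohort,
            "threshold": self.threshold,
            "n_snps": self.n_snps,
            "r2": self.r2,
            "coef": self.coef,
            "p": self.p,
            "degenerate": self.degenerate,
        }


def threshold_grid(start: float = 0.01, stop: float = 0.50, step: float = 0.01) -> np.ndarray:
    """The p-threshold grid: {0.01, 0.02, ..., 0.50} by default (50 values).

    Zero is excluded (an empty score is undefined) and the upper endpoint
    is included.
    """
    n = int(round((stop - start) / step)) + 1
    return np.round(start + step * np.arange(n), 10)


def _reconcile_weights(dataset: GenotypeDataset, weights: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align weights to the dataset: returns (column indices, betas, p).

    When the weight's effect allele matches the dataset's other allele the
    dosage orientation is flipped by negating beta and offsetting the score
    by a constant (handled via g -> 2 - g at scoring time through the sign
    and the imputation frequency); an allele matching neither is an error.
    """
    w = weights.reset_index(drop=True)
    col_idx = dataset.snp_index(w["snp"])
    v = dataset.variants.iloc[col_idx]
    a1 = v["a1"].to_numpy()
    a2 = v["a2"].to_numpy()
    wa1 = w["a1"].to_numpy()
    direct = wa1 == a1
    flipped = wa1 == a2
    bad = ~(direct | flipped)
    if bad.any():
        raise AlleleMismatchError(
            f"effect alleles irreconcilable for SNPs: {list(w.loc[bad, 'snp'])[:10]}"
        )
    return col_idx, w["beta"].to_numpy(dtype=float), flipped


def _oriented_dosages(dataset: GenotypeDataset, col_idx: np.ndarray,
                      flipped: np.ndarray) -> np.ndarray:
    """Dosages oriented to the weights' effect alleles, mean-imputed."""
    g = dataset.dosages[:, col_idx].copy()
    g[:, flipped] = 2.0 - g[:, flipped]
    freq = np.nanmean(g, axis=0) / 2.0
    fill = np.broadcast_to(2.0 * freq, g.shape)
    miss = np.isnan(g)
    g[miss] = fill[miss]
    return g


def compute_score(dataset: GenotypeDataset, weights: pd.DataFrame,
                  threshold: float, base_trait: str = "") -> ScoreProfile:
    """Profile score at one threshold: mean over S(T) of beta_j * dosage_ij.

    ``weights`` carries columns snp, a1 (effect allele), beta, p — typically
    a discovery association table restricted to clump index SNPs. Missing
    dosages are imputed as 2 x effect-allele frequency in the scored cohort.
    """
    sel = weights.loc[weights["p"] <= threshold]
    if sel.empty:
        return ScoreProfile(threshold, [], None, base_trait)
    col_idx, beta, flipped = _reconcile_weights(dataset, sel)
    g = _oriented_dosages(dataset, col_idx, flipped)
    values = (g @ beta) / len(beta)
    return ScoreProfile(threshold, list(sel["snp"]),
                        pd.Series(values, index=dataset.iids), base_trait)


def fit_score_model(score: ScoreProfile, trait: pd.Series) -> FitResult:
    """OLS of the target trait on the profile score (intercept included).

    R² equals the squared Pearson correlation between score and trait.
    A zero-variance score yields a degenerate fit with R² = 0, p = 1.
    """
    if score.empty or score.scores is None:
        raise ValueError("cannot fit an empty score profile")
    aligned = pd.concat([score.scores.rename("score"), trait.rename("y")],
                        axis=1, join="inner").dropna()
    if len(aligned) < 3:
        raise ValueError("need at least 3 complete (score, trait) pairs")
    x = aligned["score"].to_numpy()
    y = aligned["y"].to_numpy()
    n = x.size
    sxx = np.sum((x - x.mean()) ** 2)
    syy = np.sum((y - y.mean()) ** 2)
    if sxx == 0.0 or syy == 0.0:
        return FitResult(score.threshold, score.n_snps, 0.0, np.nan, 1.0,
                         target_trait=str(trait.name or ""),
                         base_trait=score.base_trait, degenerate=True)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    beta = sxy / sxx
    r2 = (sxy * sxy) / (sxx * syy)
    df = n - 2
    if r2 >= 1.0:
        p = 0.0
    else:
        t = np.sqrt(df * r2 / (1.0 - r2))
        p = 2.0 * stats.t.sf(t, df)
    return FitResult(score.threshold, score.n_snps, float(r2), float(beta), float(p),
                     target_trait=str(trait.name or ""), base_trait=score.base_trait)


def _scan(dataset: GenotypeDataset, weights: pd.DataFrame, trait: pd.Series,
          grid: np.ndarray, base_trait: str, cohort: str) -> list[FitResult]:
    """Fit every grid threshold, sharing one pass over the dosage matrix."""
    w = weights.sort_values(["p", "snp"], kind="mergesort").reset_index(drop=True)
    col_idx, beta, flipped = _reconcile_weights(dataset, w)
    g = _oriented_dosages(dataset, col_idx, flipped)

    y_full = trait.reindex(dataset.iids)
    keep = ~y_full.isna().to_numpy()
    y = y_full.to_numpy(dtype=float)[keep]
    contrib = (g[keep] * beta)            # (n_kept, m) weighted dosages
    cum = np.cumsum(contrib, axis=1)      # nested sums over p-sorted SNPs
    counts = np.searchsorted(w["p"].to_numpy(), grid, side="right")

    n = y.size
    yc = y - y.mean()
    syy = float(yc @ yc)
    results: list[FitResult] = []
    for T, k in zip(grid, counts):
        if k == 0:
            results.append(FitResult(float(T), 0, np.nan, np.nan, np.nan,
                                     target_trait=str(trait.name or ""),
                                     base_trait=base_trait, cohort=cohort,
                                     degenerate=True))
            continue
        s = cum[:, k - 1] / k
        sc = s - s.mean()
        sxx = float(sc @ sc)
        if sxx == 0.0 or syy == 0.0:
            results.append(FitResult(float(T), int(k), 0.0, np.nan, 1.0,
                                     target_trait=str(trait.name or ""),
                                     base_trait=base_trait, cohort=cohort,
                                     degenerate=True))
            continue
        sxy = float(sc @ yc)
        r2 = sxy * sxy / (sxx * syy)
        df = n - 2
        p = 0.0 if r2 >= 1.0 else 2.0 * stats.t.sf(np.sqrt(df * r2 / (1.0 - r2)), df)
        results.append(FitResult(float(T), int(k), float(r2), float(sxy / sxx),
                                 float(p), target_trait=str(trait.name or ""),
                                 base_trait=base_trait, cohort=cohort))
    return results


def _pick_best(fits: Sequence[FitResult]) -> FitResult:
    valid = [f for f in fits if not f.degenerate and np.isfinite(f.r2)]
    if not valid:
        raise ValueError("every threshold yielded an empty or degenerate score")
    # max R2; ties go to the smaller threshold (fewer SNPs, parsimony)
    return max(valid, key=lambda f: (f.r2, -f.threshold))


def best_fit_scan(
    weights: pd.DataFrame,
    eval_dataset: GenotypeDataset,
    eval_trait: pd.Series,
    grid: np.ndarray | None = None,
    mode: str = "scan_in_target",
    discovery_dataset: GenotypeDataset | None = None,
    discovery_trait: pd.Series | None = None,
    base_trait: str = "",
) -> tuple[list[FitResult], FitResult]:
    """Threshold scan and best fit of a profile score against a target trait.

    ``scan_in_target`` fits the whole grid in the evaluation cohort and
    returns the maximal-R² row. ``fixed_from_discovery`` first locates the
    maximal-R² threshold by scanning in the discovery cohort against the
    (base) discovery trait, then evaluates only that threshold in the
    target; the returned scan table is then the discovery scan.
    """
    if grid is None:
        grid = threshold_grid()
    if len(grid) == 0:
        raise ValueError("threshold grid must be non-empty")
    if mode == "scan_in_target":
        fits = _scan(eval_dataset, weights, eval_trait, grid, base_trait, "replication")
        return fits, _pick_best(fits)
    if mode == "fixed_from_discovery":
        if discovery_dataset is None or discovery_trait is None:
            raise ValueError("fixed_from_discovery mode needs the discovery cohort")
        disc = _scan(discovery_dataset, weights, discovery_trait, grid,
                     base_trait, "discovery")
        best_T = _pick_best(disc).threshold
        score = compute_score(eval_dataset, weights, best_T, base_trait)
        best = fit_score_model(score, eval_trait)
        best.cohort = "replication"
        return disc, best
    raise ValueError(f"unknown best-fit mode: {mode!r}")


def scan_to_frame(fits: Sequence[FitResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.threshold, f.n_snps, f.r2, f.coef, f.p) for f in fits],
        columns=["threshold", "n_snps", "r2", "beta", "p"],
    )
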