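"""Test-family assembly, Benjamini-Hochberg correction, SNP-set overlap,
and phenotype correlation matrices.

The analysis produces two families of score-to-trait fits: a consistency
family (each base trait predicting itself in the replication cohort, m = 8
by default) and a cross-trait family (the expressive-language score
predicting disorder caseness and the five psychosocial subscales, m = 6).
False-discovery-rate control is applied within each family separately via
the Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profile_scoring import FitResult

__all__ = [
    "bh_adjust",
    "subset_overlap",
    "phenotype_correlations",
    "run_test_families",
    "TestFamily",
    "OverlapReport",
    "CorrelationMatrix",
]


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    adj(i) = min_{j >= i} (m / j) * p_(j) over the ascending ordering,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D vector")
    if np.any(np.isnan(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class OverlapReport:
    """Intersection of two best-fit SNP sets, as counts and a percentage."""

    set_a: frozenset
    set_b: frozenset
    n_a: int = 0
    n_b: int = 0
    n_shared: int = 0
    shared_pct: float | None = None

    @property
    def shared_pct_rounded(self) -> int | None:
        return None if self.shared_pct is None else int(round(self.shared_pct))

    def to_dict(self) -> dict:
        return {
            "n_a": self.n_a, "n_b": self.n_b, "n_shared": self.n_shared,
            "shared_pct": self.shared_pct,
            "shared_pct_rounded": self.shared_pct_rounded,
            "shared_snps": sorted(self.set_a & self.set_b),
        }


def subset_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> OverlapReport:
    """Exact overlap of SNP-identifier sets; percentage is relative to A.

    An empty A leaves the percentage undefined (None).
    """
    a = frozenset(set_a)
    b = frozenset(set_b)
    shared = len(a & b)
    pct = None if not a else 100.0 * shared / len(a)
    return OverlapReport(a, b, len(a), len(b), shared, pct)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations with per-cell p and significance tiers."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    undefined: list[tuple[str, str]] = field(default_factory=list)

    TIER_CUTOFFS = (0.001, 0.01, 0.05)

    def tiers(self) -> pd.DataFrame:
        stars = pd.DataFrame("", index=self.r.index, columns=self.r.columns)
        for cut, mark in zip(self.TIER_CUTOFFS, ("***", "**", "*")):
            stars = stars.where(~(self.p < cut) | (stars != ""), mark)
        np.fill_diagonal(stars.values, "")
        return stars

    def lower_triangle_tsv(self, path) -> None:
        """Lower-triangular layout with significance stars, as TSV."""
        out = pd.DataFrame("", index=self.r.index, columns=self.r.columns)
        stars = self.tiers()
        cols = list(self.r.columns)
        for i, row in enumerate(cols):
            for j, col in enumerate(cols[: i + 1]):
                val = self.r.loc[row, col]
                cell = "" if np.isnan(val) else f"{val:.2f}"
                out.loc[row, col] = cell + stars.loc[row, col]
        out.to_csv(path, sep="\t")


def phenotype_correlations(phenotypes: pd.DataFrame,
                           traits: Sequence[str] | None = None) -> CorrelationMatrix:
    """Pairwise-deletion Pearson correlation matrix over trait columns.

    Each cell needs at least 3 complete pairs; two-sided p comes from the
    t transform of r. Constant columns yield undefined cells (NaN),
    reported in ``undefined``.
    """
    if traits is None:
        traits = list(phenotypes.columns)
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    n = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    undefined: list[tuple[str, str]] = []
    data = phenotypes[list(traits)].astype(float)
    for i, a in enumerate(traits):
        n.loc[a, a] = int(data[a].notna().sum())
        for b in traits[:i]:
            pair = data[[a, b]].dropna()
            n.loc[a, b] = n.loc[b, a] = len(pair)
            if len(pair) < 3 or pair[a].std() == 0.0 or pair[b].std() == 0.0:
                r.loc[a, b] = r.loc[b, a] = np.nan
                undefined.append((a, b))
                continue
            rr, pp = stats.pearsonr(pair[a], pair[b])
            r.loc[a, b] = r.loc[b, a] = rr
            p.loc[a, b] = p.loc[b, a] = pp
    return CorrelationMatrix(r, p, n, undefined)


@dataclass
class TestFamily:
    """One family of score-to-trait tests with within-family FDR control."""

    name: str
    pairs: list[tuple[str, str]]          # (base trait, target trait)
    fits: list[FitResult]
    nominal_p: np.ndarray = field(default=None)
    adjusted_p: np.ndarray = field(default=None)
    fdr: float = 0.05

    def __post_init__(self) -> None:
        self.nominal_p = np.array([f.p for f in self.fits], dtype=float)
        if self.nominal_p.size:
            self.adjusted_p = bh_adjust(np.clip(self.nominal_p, np.finfo(float).tiny, 1.0))
        else:
            self.adjusted_p = np.empty(0)

    @property
    def passes_fdr(self) -> np.ndarray:
        return self.adjusted_p <= self.fdr

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (base, target), fit, adj, ok in zip(
            self.pairs, self.fits, self.adjusted_p, self.passes_fdr
        ):
            rows.append({
                "base_trait": base, "target_trait": target,
                "best_threshold": fit.threshold, "n_snps": fit.n_snps,
                "r2": fit.r2, "nominal_p": fit.p, "adjusted_p": adj,
                "passes_fdr": bool(ok),
            })
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fdr": self.fdr,
            "rows": self.to_frame().to_dict(orient="records"),
        }


def run_test_families(
    consistency_fits: list[tuple[str, str, FitResult]],
    cross_fits: list[tuple[str, str, FitResult]],
    expected_consistency: Sequence[str] | None = None,
    expected_cross: Sequence[tuple[str, str]] | None = None,
    fdr: float = 0.05,
) -> tuple[TestFamily, TestFamily]:
    """Assemble the two test families and adjust within each separately.

    When expectations are supplied, missing (base, target) pairs raise an
    error listing the absentees.
    """
    if expected_consistency is not None:
        have = {base for base, _, _ in consistency_fits}
        absent = [t for t in expected_consistency if t not in have]
        if absent:
            raise ValueError(f"missing consistency fits for traits: {absent}")
    if expected_cross is not None:
        have_pairs = {(b, t) for b, t, _ in cross_fits}
        absent_pairs = [p for p in expected_cross if tuple(p) not in have_pairs]
        if absent_pairs:
            raise ValueError(f"missing cross-trait fits for pairs: {absent_pairs}")

    consistency = TestFamily(
        "consistency", [(b, t) for b, t, _ in consistency_fits],
        [f for _, _, f in consistency_fits], fdr=fdr,
    )
    cross = TestFamily(
        "cross_trait", [(b, t) for b, t, _ in cross_fits],
        [f for _, _, f in cross_fits], fdr=fdr,
    )
    return consistency, cross
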