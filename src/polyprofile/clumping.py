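"""Greedy LD clumping: thin SNPs so each retained index variant represents
its correlated neighbourhood.

SNPs passing the p ceiling are visited in order of ascending association p
(ties by position, then identifier). Each visited SNP becomes an index SNP
and absorbs, as members, every still-unassigned SNP on the same chromosome
within the window whose dosage r-squared with it exceeds the threshold.
LD is the squared Pearson correlation of 0/1/2 dosages over complete pairs
(composite genotype r-squared; no phase information is modelled). Defaults
follow common PRS-tool conventions: r² = 0.1, 250 kb window, p ceiling 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genotype_io import GenotypeDataset

__all__ = ["dosage_r2", "clump", "ClumpResult"]


def dosage_r2(a, b) -> float:
    """Squared Pearson correlation of two dosage columns over complete pairs.

    Returns NaN when fewer than two complete pairs remain or either column
    is monomorphic; :func:`clump` treats NaN as r² = 0.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        return np.nan
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    r = np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb)
    return float(r * r)


class _PairwiseR2:
    """Pairwise-complete dosage r² of one column against many, sharing the
    zero-filled value/mask matrices across queries (BLAS matrix-vector
    products only; no per-query n x k temporaries)."""

    def __init__(self, dosages: np.ndarray):
        self.mask = (~np.isnan(dosages)).astype(float)
        self.values = np.nan_to_num(dosages)
        self.squares = self.values * self.values

    def query(self, i: int, lo: int, hi: int) -> np.ndarray:
        """r² of column ``i`` against the contiguous slice [lo, hi)."""
        xm = self.mask[:, i]
        x0 = self.values[:, i]          # zero where x missing
        x2 = self.squares[:, i]
        M = self.mask[:, lo:hi]
        B0 = self.values[:, lo:hi]
        B2 = self.squares[:, lo:hi]
        n = xm @ M
        sx = x0 @ M
        sy = xm @ B0
        sxx = x2 @ M
        syy = xm @ B2
        sxy = x0 @ B0
        with np.errstate(divide="ignore", invalid="ignore"):
            cov = sxy - sx * sy / n
            vx = sxx - sx * sx / n
            vy = syy - sy * sy / n
            r2 = (cov * cov) / (vx * vy)
        r2[(n < 2) | ~np.isfinite(r2)] = np.nan
        return r2


@dataclass
class ClumpResult:
    """Outcome of one greedy clumping pass.

    ``members[idx]`` maps each index SNP to the list of (member snp, r² to
    index) it absorbed; index SNPs and members partition the SNPs that
    passed the p ceiling.
    """

    index_snps: list[str]
    members: dict[str, list[tuple[str, float]]]
    r2_threshold: float
    window_kb: float
    p_ceiling: float
    considered: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for snp in self.index_snps:
            mem = self.members.get(snp, [])
            rows.append({
                "index_snp": snp,
                "n_members": len(mem),
                "members": ",".join(m for m, _ in mem),
                "member_r2": ",".join(f"{r:.4g}" for _, r in mem),
            })
        return pd.DataFrame(rows, columns=["index_snp", "n_members", "members", "member_r2"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, r2_threshold: float = np.nan,
                 window_kb: float = np.nan, p_ceiling: float = np.nan) -> "ClumpResult":
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        index_snps = list(df["index_snp"])
        members = {}
        for _, row in df.iterrows():
            mems = row["members"].split(",") if row["members"] else []
            r2s = [float(x) for x in row["member_r2"].split(",")] if row["member_r2"] else []
            members[row["index_snp"]] = list(zip(mems, r2s))
        return cls(index_snps, members, r2_threshold, window_kb, p_ceiling)


def clump(
    assoc: pd.DataFrame,
    dataset: GenotypeDataset,
    r2_threshold: float = 0.1,
    window_kb: float = 250.0,
    p_ceiling: float = 1.0,
) -> ClumpResult:
    """Greedy p-value-ordered LD clumping of an association table.

    ``assoc`` must carry columns snp, chr, bp, p for every SNP present in
    ``dataset`` (LD is computed from the dataset's dosages — in the intended
    workflow the discovery cohort, the same cohort that supplied the p's).
    """
    work = assoc.loc[assoc["p"] <= p_ceiling, ["snp", "chr", "bp", "p"]].copy()
    result = ClumpResult([], {}, r2_threshold, window_kb, p_ceiling,
                         considered=list(work["snp"]))
    if work.empty:
        return result

    work = work.sort_values(["p", "bp", "snp"], kind="mergesort").reset_index(drop=True)
    window = window_kb * 1000.0

    # position-sorted view of the considered SNPs: every LD window becomes a
    # contiguous column slice, so the r² queries run on array views
    pos_order = work.sort_values(["chr", "bp"], kind="mergesort").index.to_numpy()
    rank_of = np.empty(len(work), dtype=int)
    rank_of[pos_order] = np.arange(len(work))
    chrom_s = work["chr"].astype(str).to_numpy()[pos_order]
    bp_s = work["bp"].to_numpy(dtype=float)[pos_order]
    snps_s = work["snp"].to_numpy()[pos_order]
    chrom_start = {c: np.searchsorted(chrom_s, c, side="left") for c in np.unique(chrom_s)}
    chrom_end = {c: np.searchsorted(chrom_s, c, side="right") for c in np.unique(chrom_s)}

    pairwise = _PairwiseR2(dataset.dosages[:, dataset.snp_index(snps_s)])
    unassigned = np.ones(len(work), dtype=bool)  # in position order
    for i in work.index:
        r = rank_of[i]
        if not unassigned[r]:
            continue
        unassigned[r] = False
        index_snp = snps_s[r]
        result.index_snps.append(index_snp)
        c = chrom_s[r]
        a, b = chrom_start[c], chrom_end[c]
        lo = a + np.searchsorted(bp_s[a:b], bp_s[r] - window, side="left")
        hi = a + np.searchsorted(bp_s[a:b], bp_s[r] + window, side="right")
        r2 = np.nan_to_num(pairwise.query(r, lo, hi))  # undefined -> 0
        hit = (r2 > r2_threshold) & unassigned[lo:hi]
        absorbed = lo + np.flatnonzero(hit)
        result.members[index_snp] = [
            (snps_s[j], float(v)) for j, v in zip(absorbed, r2[hit])
        ]
        unassigned[absorbed] = False
    return result
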