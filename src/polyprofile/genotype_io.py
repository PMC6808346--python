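"""PLINK binary genotype I/O and variant/sample quality control.

The central container is :class:`GenotypeDataset`: a dense dosage matrix
(individuals x SNPs, values 0/1/2 counting copies of the effect allele,
``NaN`` for missing) plus variant and sample metadata tables. Reading and
writing use the PLINK 1 binary triplet (BED/BIM/FAM) in SNP-major layout:
magic bytes ``0x6c 0x1b 0x01`` followed, per SNP, by ceil(n/4) bytes of
two-bit genotype codes packed from the low bits (00 = homozygous A1,
01 = missing, 10 = heterozygous, 11 = homozygous A2). The BIM's first
allele (A1) is the counted/effect allele throughout.

Quality control follows the usual candidate-gene workflow: individuals
with excess missingness are dropped first, then SNPs failing minor-allele
frequency, call rate, or exact Hardy-Weinberg tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "GenotypeDataset",
    "QCThresholds",
    "QCReport",
    "PlinkFormatError",
    "read_plink",
    "write_plink",
    "read_vcf",
    "hwe_exact_p",
    "qc_filter",
]

_MAGIC = bytes([0x6C, 0x1B, 0x01])

# two-bit code -> dosage of A1 (the counted allele); 0b01 is the missing code
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

VARIANT_COLUMNS = ["snp", "chrom", "pos", "a1", "a2"]


class PlinkFormatError(ValueError):
    """Raised when a BED/BIM/FAM triplet is malformed or inconsistent."""


@dataclass
class GenotypeDataset:
    """Dosage matrix with aligned variant and sample metadata.

    Attributes
    ----------
    dosages:
        ``(n_individuals, n_snps)`` float array with values in {0, 1, 2}
        or NaN for missing; entry [i, j] counts copies of ``variants.a1[j]``
        carried by individual ``samples.iid[i]``.
    variants:
        One row per SNP: ``snp`` (unique id), ``chrom``, ``pos`` (1-based),
        ``a1`` (effect allele), ``a2``, and optionally ``gene``.
    samples:
        One row per individual with at least ``fid`` and ``iid``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        with np.errstate(invalid="ignore"):
            bad = ~(np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or NaN")
        if self.variants["snp"].duplicated().any():
            raise ValueError("variant identifiers must be unique")
        self.variants = self.variants.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def iids(self) -> pd.Index:
        return pd.Index(self.samples["iid"])

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the effect allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosages).mean(axis=0)

    def individual_missingness(self) -> np.ndarray:
        return np.isnan(self.dosages).mean(axis=1)

    def take_individuals(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.dosages[index, :],
            self.variants.copy(),
            self.samples.iloc[index].reset_index(drop=True),
        )

    def take_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeDataset":
        index = np.asarray(index)
        return GenotypeDataset(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            self.samples.copy(),
        )

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        """Positional indices for the given SNP identifiers (order preserved)."""
        lookup = pd.Series(np.arange(self.n_snps), index=self.variants["snp"])
        missing = [s for s in snp_ids if s not in lookup.index]
        if missing:
            raise KeyError(f"SNPs not in dataset: {missing[:10]}")
        return lookup.loc[list(snp_ids)].to_numpy()

    def annotate_genes(self, gene_regions: Mapping[str, tuple[str, int, int]]) -> None:
        """Label each variant with the gene whose closed interval contains it."""
        genes = np.full(self.n_snps, "", dtype=object)
        chrom = self.variants["chrom"].astype(str).to_numpy()
        pos = self.variants["pos"].to_numpy()
        for gene, (g_chrom, start, end) in gene_regions.items():
            hit = (chrom == str(g_chrom)) & (pos >= start) & (pos <= end)
            genes[hit] = gene
        self.variants["gene"] = genes


def _decode_bed(raw: np.ndarray, n_individuals: int, n_snps: int) -> np.ndarray:
    bytes_per_snp = (n_individuals + 3) // 4
    raw = raw.reshape(n_snps, bytes_per_snp)
    shifts = np.arange(4) * 2
    codes = (raw[:, :, None] >> shifts) & 0b11  # (snps, bytes, 4)
    codes = codes.reshape(n_snps, bytes_per_snp * 4)[:, :n_individuals]
    return _CODE_TO_DOSAGE[codes].T  # -> (individuals, snps)


def read_plink(bed: str | Path, bim: str | Path, fam: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 binary triplet into a :class:`GenotypeDataset`.

    The BIM's A1 column is taken as the counted (effect) allele, so a
    two-bit code of 00 decodes to dosage 2 and 11 to dosage 0.
    """
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n_individuals, n_snps = len(fam_df), len(bim_df)
    data = Path(bed).read_bytes()
    if data[:3] != _MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK v1.00 BED)")
    expected = 3 + ((n_individuals + 3) // 4) * n_snps
    if len(data) != expected:
        raise PlinkFormatError(
            f"{bed}: size {len(data)} does not match {n_individuals} individuals "
            f"x {n_snps} SNPs (expected {expected} bytes)"
        )
    raw = np.frombuffer(data, dtype=np.uint8, offset=3)
    dosages = _decode_bed(raw, n_individuals, n_snps)
    variants = bim_df[["snp", "chrom", "pos", "a1", "a2"]].copy()
    samples = fam_df[["fid", "iid"]].copy()
    return GenotypeDataset(dosages, variants, samples)


def write_plink(dataset: GenotypeDataset, prefix: str | Path) -> tuple[Path, Path, Path]:
    """Write ``prefix``.bed/.bim/.fam; returns the three paths."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = dataset.n_individuals, dataset.n_snps

    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    codes = np.ones((m, n), dtype=np.uint8)  # default = missing (01)
    d = dataset.dosages.T
    for dosage, code in dosage_to_code.items():
        codes[d == dosage] = code
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.ones((m, pad), dtype=np.uint8)], axis=1)
    quads = codes.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)

    bed_path = prefix.with_suffix(".bed")
    bed_path.write_bytes(_MAGIC + packed.tobytes())

    v = dataset.variants
    bim = pd.DataFrame({
        "chrom": v["chrom"], "snp": v["snp"], "cm": 0,
        "pos": v["pos"], "a1": v["a1"], "a2": v["a2"],
    })
    bim_path = prefix.with_suffix(".bim")
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    s = dataset.samples
    fam = pd.DataFrame({
        "fid": s["fid"], "iid": s["iid"], "father": 0, "mother": 0,
        "sex": 0, "phenotype": -9,
    })
    fam_path = prefix.with_suffix(".fam")
    fam.to_csv(fam_path, sep="\t", header=False, index=False)
    return bed_path, bim_path, fam_path


def read_vcf(path: str | Path) -> GenotypeDataset:
    """Import a VCF, mapping GT fields to ALT-allele dosages (ALT = effect allele)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    iids = list(vcf.samples)
    rows, dosage_cols = [], []
    for rec in vcf:
        if len(rec.ALT) != 1:
            continue  # biallelic SNPs only
        rows.append({
            "snp": rec.ID or f"{rec.CHROM}:{rec.POS}",
            "chrom": str(rec.CHROM), "pos": rec.POS,
            "a1": rec.ALT[0], "a2": rec.REF,
        })
        types = rec.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        col = np.choose(types, [0.0, 1.0, np.nan, 2.0])
        dosage_cols.append(col)
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosages = np.column_stack(dosage_cols) if dosage_cols else np.empty((len(iids), 0))
    samples = pd.DataFrame({"fid": iids, "iid": iids})
    return GenotypeDataset(dosages, variants, samples)


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts (same parity), the conditional probabilities that are no larger
    than that of the observed configuration. Classic formulation without
    mid-p correction.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise ValueError("at least one genotype observation required")

    n_a = 2 * n_hom1 + n_het  # allele-1 count
    rare = min(n_a, 2 * n - n_a)
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    hets = np.arange(rare % 2, rare + 1, 2)
    hom_rare = (rare - hets) // 2
    hom_common = n - hets - hom_rare
    # log P(het = h | n, rare) = log [ n! 2^h rare! common! / (hr! h! hc! (2n)!) ]
    log_p = (
        gammaln(n + 1) - gammaln(hom_rare + 1) - gammaln(hets + 1) - gammaln(hom_common + 1)
        + hets * np.log(2.0)
        + gammaln(rare + 1) + gammaln(2 * n - rare + 1) - gammaln(2 * n + 1)
    )
    probs = np.exp(log_p - log_p.max())
    probs /= probs.sum()
    observed = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


@dataclass
class QCThresholds:
    """Variant- and sample-level QC cut-offs, all on [0, 1] scales."""

    min_maf: float = 0.01
    min_call_rate: float = 0.95
    hwe_p_floor: float = 5e-7
    max_individual_missingness: float = 0.03

    def validate(self) -> None:
        for name, value in vars(self).items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"QC threshold {name}={value} outside [0, 1]")


@dataclass
class QCReport:
    thresholds: QCThresholds
    n_individuals_in: int = 0
    n_snps_in: int = 0
    individuals_removed_missingness: list[str] = field(default_factory=list)
    snps_removed_maf: list[str] = field(default_factory=list)
    snps_removed_call_rate: list[str] = field(default_factory=list)
    snps_removed_hwe: list[str] = field(default_factory=list)

    @property
    def n_individuals_out(self) -> int:
        return self.n_individuals_in - len(self.individuals_removed_missingness)

    @property
    def n_snps_out(self) -> int:
        return self.n_snps_in - (
            len(self.snps_removed_maf)
            + len(self.snps_removed_call_rate)
            + len(self.snps_removed_hwe)
        )

    def to_dict(self) -> dict:
        return {
            "thresholds": vars(self.thresholds),
            "n_individuals_in": self.n_individuals_in,
            "n_individuals_out": self.n_individuals_out,
            "n_snps_in": self.n_snps_in,
            "n_snps_out": self.n_snps_out,
            "removed": {
                "individual_missingness": self.individuals_removed_missingness,
                "snp_maf": self.snps_removed_maf,
                "snp_call_rate": self.snps_removed_call_rate,
                "snp_hwe": self.snps_removed_hwe,
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def qc_filter(
    dataset: GenotypeDataset, thresholds: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Apply sample-level then variant-level QC.

    Individuals with missingness above the cap are removed first; SNP
    statistics (MAF, call rate, HWE) are then computed on the remaining
    individuals. Each removed SNP is attributed to the first criterion it
    violates, in the order MAF, call rate, HWE.
    """
    if thresholds is None:
        thresholds = QCThresholds()
    thresholds.validate()
    report = QCReport(thresholds, dataset.n_individuals, dataset.n_snps)

    ind_miss = dataset.individual_missingness()
    keep_ind = ind_miss <= thresholds.max_individual_missingness
    report.individuals_removed_missingness = list(
        dataset.samples.loc[~keep_ind, "iid"]
    )
    dataset = dataset.take_individuals(np.flatnonzero(keep_ind))

    freq = dataset.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    call = dataset.snp_call_rate()
    keep = np.ones(dataset.n_snps, dtype=bool)
    snp_ids = dataset.variants["snp"].to_numpy()

    fail_maf = maf < thresholds.min_maf
    report.snps_removed_maf = list(snp_ids[fail_maf])
    keep &= ~fail_maf

    fail_call = (call < thresholds.min_call_rate) & keep
    report.snps_removed_call_rate = list(snp_ids[fail_call])
    keep &= ~fail_call

    d = dataset.dosages
    fail_hwe = np.zeros(dataset.n_snps, dtype=bool)
    for j in np.flatnonzero(keep):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
        if hwe_exact_p(*counts) < thresholds.hwe_p_floor:
            fail_hwe[j] = True
    report.snps_removed_hwe = list(snp_ids[fail_hwe])
    keep &= ~fail_hwe

    return dataset.take_snps(np.flatnonzero(keep)), report
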