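"""Synthetic genotype-phenotype cohorts for candidate-gene polygenic analyses.

The generator emulates the structure the downstream pipeline assumes: a few
gene loci carrying LD-correlated SNPs, bounded ordinal language instruments,
five 0-10 psychosocial subscales, a derived language-disorder caseness, and
a weak additive polygenic architecture in which some causal variants are
shared between traits (pleiotropy).

Genotypes come from a latent-Gaussian threshold model: within each gene
block two haplotype-level AR(1) Gaussian processes are thresholded at the
allele-frequency quantile, so one correlation parameter per block induces a
block-diagonal LD pattern resembling a real locus, while blocks remain
mutually independent.

Phenotypes are additive: y = sum_j beta_j * standardized dosage_j + noise,
with the noise variance chosen so the genetic component explains exactly h^2
of the latent-trait variance. The latent trait is then affinely mapped onto
the instrument's range (midpoint + z * span/6), clipped, and rounded when
the instrument is a summed item score, which preserves rank order while
honoring the printed score ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.special import expit, ndtri

from ._seeds import rng_for
from .genotype_io import GenotypeDataset

__all__ = [
    "GeneBlock",
    "Instrument",
    "TraitArchitecture",
    "SimulationConfig",
    "TraitSimulation",
    "CohortTables",
    "simulate_genotypes",
    "simulate_phenotypes",
    "derive_dld_status",
    "split_cohort",
    "build_cohort",
    "default_config",
    "DEFAULT_GENE_REGIONS",
    "LANGUAGE_TRAITS",
    "SDQ_TRAITS",
]

# hg38 spans of the six language/reading candidate loci modelled by default.
DEFAULT_GENE_REGIONS: dict[str, tuple[str, int, int]] = {
    "ATP2C2": ("16", 84368615, 84463732),
    "CMIP": ("16", 81445241, 81709799),
    "CNTNAP2": ("7", 146116876, 148415616),
    "DCDC2": ("6", 24174729, 24357750),
    "FOXP2": ("7", 114426511, 114693772),
    "KIAA0319": ("6", 24541241, 24645764),
}

# 1,229 SNPs split across the six blocks proportionally to gene span.
DEFAULT_BLOCK_SIZES: dict[str, int] = {
    "ATP2C2": 36,
    "CMIP": 101,
    "CNTNAP2": 880,
    "DCDC2": 70,
    "FOXP2": 102,
    "KIAA0319": 40,
}

LANGUAGE_TRAITS = [
    "vocab_15m",
    "vocab_24m",
    "receptive_15m",
    "grammar_24m",
    "receptive_8y",
    "expressive_8y",
    "nonword_rep_8y",
    "pragmatic_9y",
]
SDQ_TRAITS = [
    "emotional_11y",
    "peer_problems_11y",
    "conduct_11y",
    "hyperactivity_11y",
    "prosociality_11y",
]

# (lo, hi) printed score range per instrument; all are summed item scores.
INSTRUMENT_BOUNDS: dict[str, tuple[float, float]] = {
    "vocab_15m": (0, 268),
    "vocab_24m": (0, 246),
    "receptive_15m": (0, 12),
    "grammar_24m": (0, 8),
    "receptive_8y": (0, 16),
    "expressive_8y": (0, 10),
    "nonword_rep_8y": (0, 12),
    "pragmatic_9y": (86, 162),
    **{t: (0, 10) for t in SDQ_TRAITS},
}


@dataclass
class GeneBlock:
    """One LD block: a gene locus carrying ``n_snps`` correlated SNPs."""

    gene: str
    n_snps: int
    ld_rho: float
    chrom: str = "1"
    start: int = 1
    end: int = 1_000_000

    def validate(self) -> None:
        if self.n_snps <= 0:
            raise ValueError(f"block {self.gene}: n_snps must be positive")
        if not 0.0 <= self.ld_rho < 1.0:
            raise ValueError(f"block {self.gene}: ld_rho must lie in [0, 1)")


@dataclass
class Instrument:
    """Score bounds and rounding behaviour of a bounded test instrument."""

    lo: float
    hi: float
    integer: bool = True

    def map_latent(self, z: np.ndarray) -> np.ndarray:
        """Affine map of a standardized latent trait onto the score range.

        The midpoint anchors the mean and span/6 scales one latent SD, so
        +/-3 SD covers the printed range before clipping.
        """
        mid = 0.5 * (self.lo + self.hi)
        scale = (self.hi - self.lo) / 6.0
        scores = np.clip(mid + scale * z, self.lo, self.hi)
        return np.round(scores) if self.integer else scores


@dataclass
class TraitArchitecture:
    """Additive genetic architecture of one simulated trait.

    ``shared_with`` marks pleiotropy: (other trait name, indices of the
    causal SNPs shared with it). Shared SNPs must carry effect sizes of
    equal magnitude in both traits for the genetic correlation to be
    controlled by the shared fraction; the sign may differ (e.g. alleles
    lowering language may raise problem scores).
    """

    name: str
    causal_snp_indices: np.ndarray
    effect_sizes: np.ndarray
    h2: float
    instrument: Instrument
    env_loading: float = 0.0
    shared_with: tuple[str, np.ndarray] | None = None

    def validate(self, n_snps: int) -> None:
        if not 0.0 <= self.h2 < 1.0:
            raise ValueError(f"{self.name}: h2 must lie in [0, 1)")
        idx = np.asarray(self.causal_snp_indices)
        if idx.size != np.asarray(self.effect_sizes).size:
            raise ValueError(f"{self.name}: one effect size per causal SNP required")
        if idx.size and (idx.min() < 0 or idx.max() >= n_snps):
            raise ValueError(f"{self.name}: causal SNP indices out of range")
        if self.shared_with is not None:
            shared = np.asarray(self.shared_with[1])
            if not np.isin(shared, idx).all():
                raise ValueError(f"{self.name}: shared subset not within causal set")
        if not -1.0 <= self.env_loading <= 1.0:
            raise ValueError(f"{self.name}: env_loading must lie in [-1, 1]")


@dataclass
class SimulationConfig:
    n_individuals: int
    gene_blocks: list[GeneBlock]
    allele_freq_range: tuple[float, float] = (0.05, 0.5)
    architectures: list[TraitArchitecture] = field(default_factory=list)
    missing_rate: float = 0.01
    seed: int = 0

    @property
    def n_snps(self) -> int:
        return sum(b.n_snps for b in self.gene_blocks)

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not self.gene_blocks or self.n_snps <= 0:
            raise ValueError("at least one gene block with SNPs required")
        for block in self.gene_blocks:
            block.validate()
        lo, hi = self.allele_freq_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("allele frequencies must lie in (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for arch in self.architectures:
            arch.validate(self.n_snps)


@dataclass
class TraitSimulation:
    """One simulated trait column plus the latent pieces that generated it.

    ``genetic_component`` is the standardized weighted dosage sum (unit
    variance, independent of h2); ``liability`` is the standardized latent
    trait sqrt(h2)*genetic + sqrt(1-h2)*noise before instrument mapping.
    """

    scores: pd.Series
    liability: np.ndarray
    genetic_component: np.ndarray
    h2: float


@dataclass
class CohortTables:
    """Simulated phenotype tables plus the generating truth.

    ``phenotypes`` holds one row per individual (indexed by iid) with the
    thirteen trait scores, the speech/language-therapy flag, the ASD-like
    and hearing-like exclusion flags, and the derived ``dld_status``.
    """

    phenotypes: pd.DataFrame
    truth: SimulationConfig

    @property
    def dld_status(self) -> pd.Series:
        return self.phenotypes["dld_status"]


def _ar1_latent(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    z = rng.standard_normal((n, m))
    if rho > 0.0 and m > 1:
        # z_j = rho*z_{j-1} + sqrt(1-rho^2)*e_j, stationary (unit marginals)
        u = np.sqrt(1.0 - rho * rho) * z
        u[:, 0] = z[:, 0]
        z = lfilter([1.0], [1.0, -rho], u, axis=1)
    return z


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw a dosage matrix under the latent-Gaussian AR(1) block model.

    Each individual carries two independent haplotypes per block; an allele
    is present where the latent Gaussian falls below the allele-frequency
    quantile, so adjacent SNPs inherit the AR(1) correlation as LD while
    marginal frequencies are preserved exactly.
    """
    config.validate()
    n = config.n_individuals
    rng = rng_for(config.seed, "genotypes")

    columns, var_rows = [], []
    alleles = np.array(list("ACGT"))
    for block in config.gene_blocks:
        m = block.n_snps
        freqs = rng.uniform(*config.allele_freq_range, size=m)
        thresh = ndtri(freqs)
        hap1 = _ar1_latent(rng, n, m, block.ld_rho) < thresh
        hap2 = _ar1_latent(rng, n, m, block.ld_rho) < thresh
        columns.append((hap1.astype(float) + hap2.astype(float)))

        pos = np.linspace(block.start, block.end, m).astype(int)  # spans >> n_snps, so unique
        pair_idx = rng.integers(0, 4, size=(m, 2))
        pair_idx[:, 1] = (pair_idx[:, 0] + 1 + pair_idx[:, 1] % 3) % 4  # distinct letters
        for k in range(m):
            var_rows.append({
                "snp": f"snp_{block.gene}_{k:04d}",
                "chrom": block.chrom,
                "pos": int(pos[k]),
                "a1": alleles[pair_idx[k, 0]],
                "a2": alleles[pair_idx[k, 1]],
                "gene": block.gene,
            })

    dosages = np.concatenate(columns, axis=1)
    if config.missing_rate > 0.0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan

    variants = pd.DataFrame(var_rows)
    samples = pd.DataFrame({
        "fid": [f"F{i:05d}" for i in range(n)],
        "iid": [f"I{i:05d}" for i in range(n)],
    })
    return GenotypeDataset(dosages, variants, samples)


def _standardized_dosages(dataset: GenotypeDataset, snp_idx: np.ndarray) -> np.ndarray:
    g = dataset.dosages[:, snp_idx]
    mean = np.nanmean(g, axis=0)
    sd = np.nanstd(g, axis=0)
    sd[sd == 0] = 1.0
    z = (g - mean) / sd
    return np.nan_to_num(z)  # missing -> mean after centering


def genetic_component(dataset: GenotypeDataset, architecture: TraitArchitecture) -> np.ndarray:
    """Standardized additive genetic score sum_j beta_j * z(dosage_j)."""
    idx = np.asarray(architecture.causal_snp_indices, dtype=int)
    beta = np.asarray(architecture.effect_sizes, dtype=float)
    if idx.size == 0:
        return np.zeros(dataset.n_individuals)
    raw = _standardized_dosages(dataset, idx) @ beta
    sd = raw.std()
    return raw / sd if sd > 0 else raw


def simulate_phenotypes(
    dataset: GenotypeDataset,
    architecture: TraitArchitecture,
    seed: int,
    shared_environment: np.ndarray | None = None,
) -> TraitSimulation:
    """Simulate one trait column under the additive model.

    The latent liability is sqrt(h2) * genetic + sqrt(1-h2) * noise; when a
    shared environmental factor is supplied, the noise itself mixes it with
    loading ``env_loading`` (keeping unit noise variance, so h2 is
    unaffected). The liability is then mapped onto the instrument.
    """
    architecture.validate(dataset.n_snps)
    rng = rng_for(seed, "phenotype", architecture.name)
    n = dataset.n_individuals

    gc = genetic_component(dataset, architecture)
    noise = rng.standard_normal(n)
    lam = architecture.env_loading
    if shared_environment is not None and lam != 0.0:
        noise = lam * shared_environment + np.sqrt(1.0 - lam * lam) * noise
    h2 = architecture.h2
    liability = np.sqrt(h2) * gc + np.sqrt(1.0 - h2) * noise

    scores = architecture.instrument.map_latent(liability)
    return TraitSimulation(
        scores=pd.Series(scores, index=dataset.iids, name=architecture.name),
        liability=liability,
        genetic_component=gc,
        h2=h2,
    )


def derive_dld_status(
    pragmatic: pd.Series,
    nonword_repetition: pd.Series,
    receptive: pd.Series,
    therapy_flag: pd.Series,
    asd_flag: pd.Series | None = None,
    hearing_flag: pd.Series | None = None,
    z_cutoff: float = -1.0,
) -> pd.Series:
    """Derive language-disorder caseness from the two-of-four criteria rule.

    Criteria: (a) pragmatic, (b) nonword repetition, (c) receptive language
    each more than 1 SD below the sample-standardized mean, (d) a positive
    speech/language-therapy flag. Affected iff at least two criteria hold.
    Individuals with an ASD-like or hearing-like flag are excluded from both
    groups; missing criterion data yields ``excluded_missing``.
    """
    index = pragmatic.index

    def z(s: pd.Series) -> pd.Series:
        return (s - s.mean()) / s.std(ddof=1)

    crits = pd.DataFrame({
        "a": z(pragmatic) < z_cutoff,
        "b": z(nonword_repetition) < z_cutoff,
        "c": z(receptive) < z_cutoff,
        "d": therapy_flag.astype(float) > 0,
    }, index=index)
    missing = (
        pragmatic.isna() | nonword_repetition.isna()
        | receptive.isna() | therapy_flag.isna()
    )

    status = pd.Series(
        np.where(crits.sum(axis=1) >= 2, "affected", "unaffected"),
        index=index, name="dld_status",
    )
    status[missing] = "excluded_missing"
    excluded = pd.Series(False, index=index)
    if asd_flag is not None:
        excluded |= asd_flag.astype(bool)
    if hearing_flag is not None:
        excluded |= hearing_flag.astype(bool)
    status[excluded] = "excluded"
    return status


def split_cohort(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random half-split into discovery (size ceil(n/2)) and replication."""
    if n < 2:
        raise ValueError("need at least two individuals to split")
    perm = rng_for(seed, "split").permutation(n)
    cut = (n + 1) // 2
    return np.sort(perm[:cut]), np.sort(perm[cut:])


def build_cohort(config: SimulationConfig) -> tuple[GenotypeDataset, CohortTables]:
    """Simulate the full cohort: genotypes, all trait columns, flags, caseness."""
    config.validate()
    dataset = simulate_genotypes(config)
    n = dataset.n_individuals
    rng = rng_for(config.seed, "cohort_flags")

    shared_env = rng_for(config.seed, "shared_environment").standard_normal(n)
    sims: dict[str, TraitSimulation] = {}
    table = pd.DataFrame(index=dataset.iids)
    for arch in config.architectures:
        sim = simulate_phenotypes(dataset, arch, config.seed, shared_environment=shared_env)
        sims[arch.name] = sim
        table[arch.name] = sim.scores

    # Therapy uptake: noisy logistic indicator of low latent language.
    lang_names = [t for t in ("receptive_8y", "nonword_rep_8y", "pragmatic_9y") if t in sims]
    if lang_names:
        latent = np.mean([sims[t].liability for t in lang_names], axis=0)
        latent = (latent - latent.mean()) / latent.std()
    else:
        latent = np.zeros(n)
    p_therapy = expit(-3.0 - 1.3 * latent)
    table["therapy"] = (rng.random(n) < p_therapy).astype(int)
    table["asd_flag"] = (rng.random(n) < 0.015).astype(int)
    table["hearing_flag"] = (rng.random(n) < 0.015).astype(int)

    if {"pragmatic_9y", "nonword_rep_8y", "receptive_8y"}.issubset(table.columns):
        table["dld_status"] = derive_dld_status(
            table["pragmatic_9y"], table["nonword_rep_8y"], table["receptive_8y"],
            table["therapy"], table["asd_flag"], table["hearing_flag"],
        )
    return dataset, CohortTables(phenotypes=table, truth=config)


def _draw_causal(rng: np.random.Generator, n_snps: int, k: int) -> np.ndarray:
    return np.sort(rng.choice(n_snps, size=k, replace=False))


def default_config(
    n_individuals: int = 5435,
    seed: int = 0,
    ld_rho: float = 0.93,
    missing_rate: float = 0.01,
    expressive_h2: float = 0.01,
    n_causal_expressive: int = 65,
    n_shared_peer: int = 27,
) -> SimulationConfig:
    """The default study-scale simulation: 5,435 individuals, 1,229 SNPs
    across six gene blocks, eight language instruments, five SDQ subscales.

    The expressive-language trait carries 65 causal SNPs whose additive
    component explains ~1% of variance; the peer-problems trait shares 27 of
    them (sign-flipped, since language-lowering alleles raise problem
    scores), giving the partial pleiotropy the cross-trait analysis probes.
    """
    blocks = [
        GeneBlock(gene, DEFAULT_BLOCK_SIZES[gene], ld_rho,
                  chrom=DEFAULT_GENE_REGIONS[gene][0],
                  start=DEFAULT_GENE_REGIONS[gene][1],
                  end=DEFAULT_GENE_REGIONS[gene][2])
        for gene in DEFAULT_BLOCK_SIZES
    ]
    n_snps = sum(b.n_snps for b in blocks)
    rng = rng_for(seed, "architecture")

    env_loadings = {
        "vocab_15m": 0.45, "vocab_24m": 0.45, "receptive_15m": 0.40,
        "grammar_24m": 0.45, "receptive_8y": 0.35, "expressive_8y": 0.35,
        "nonword_rep_8y": 0.35, "pragmatic_9y": 0.30,
        "emotional_11y": -0.15, "peer_problems_11y": -0.25,
        "conduct_11y": -0.20, "hyperactivity_11y": -0.25,
        "prosociality_11y": 0.15,
    }

    architectures: list[TraitArchitecture] = []
    expr_idx = _draw_causal(rng, n_snps, n_causal_expressive)
    expr_beta = rng.standard_normal(n_causal_expressive)
    for trait in LANGUAGE_TRAITS:
        lo, hi = INSTRUMENT_BOUNDS[trait]
        if trait == "expressive_8y":
            idx, beta, h2 = expr_idx, expr_beta, expressive_h2
        else:
            idx = _draw_causal(rng, n_snps, 40)
            beta = rng.standard_normal(40)
            h2 = 0.005
        architectures.append(TraitArchitecture(
            name=trait, causal_snp_indices=idx, effect_sizes=beta, h2=h2,
            instrument=Instrument(lo, hi), env_loading=env_loadings[trait],
        ))

    shared = np.sort(rng.choice(expr_idx, size=n_shared_peer, replace=False))
    shared_beta = -expr_beta[np.isin(expr_idx, shared)]  # risk alleles flip sign
    own = _draw_causal(rng, n_snps, 13)
    own = own[~np.isin(own, shared)]
    peer_idx = np.sort(np.concatenate([shared, own]))
    peer_beta = np.empty(peer_idx.size)
    peer_beta[np.isin(peer_idx, shared)] = shared_beta
    peer_beta[~np.isin(peer_idx, shared)] = rng.standard_normal((~np.isin(peer_idx, shared)).sum())

    for trait in SDQ_TRAITS:
        lo, hi = INSTRUMENT_BOUNDS[trait]
        if trait == "peer_problems_11y":
            architectures.append(TraitArchitecture(
                name=trait, causal_snp_indices=peer_idx, effect_sizes=peer_beta,
                h2=0.008, instrument=Instrument(lo, hi),
                env_loading=env_loadings[trait],
                shared_with=("expressive_8y", shared),
            ))
        else:
            idx = _draw_causal(rng, n_snps, 30)
            architectures.append(TraitArchitecture(
                name=trait, causal_snp_indices=idx,
                effect_sizes=rng.standard_normal(30), h2=0.002,
                instrument=Instrument(lo, hi), env_loading=env_loadings[trait],
            ))

    return SimulationConfig(
        n_individuals=n_individuals,
        gene_blocks=blocks,
        architectures=architectures,
        missing_rate=missing_rate,
        seed=seed,
    )
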