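"""Shared replicate experiments for calibration and recovery checks.

Each replicate runs the core discovery/replication machinery directly
(simulate, split, associate, clump, score, fit) without the file-backed
pipeline, so many replicates stay affordable.
"""

import numpy as np
import pandas as pd

from polyprofile.association import assoc_scan
from polyprofile.clumping import clump
from polyprofile.profile_scoring import best_fit_scan, compute_score, fit_score_model
from polyprofile.synthetic_cohort import (
    GeneBlock,
    Instrument,
    SimulationConfig,
    TraitArchitecture,
    simulate_genotypes,
    simulate_phenotypes,
    split_cohort,
)

STUDY_N = 5435
FULL_BLOCKS = {"ATP2C2": 36, "CMIP": 101, "CNTNAP2": 880,
               "DCDC2": 70, "FOXP2": 102, "KIAA0319": 40}


def study_config(seed, blocks=None, ld_rho=0.93, n=STUDY_N, missing_rate=0.01):
    if blocks is None:
        blocks = FULL_BLOCKS
    from polyprofile.synthetic_cohort import DEFAULT_GENE_REGIONS

    gene_blocks = [
        GeneBlock(g, m, ld_rho,
                  chrom=DEFAULT_GENE_REGIONS[g][0] if g in DEFAULT_GENE_REGIONS else str(i + 1),
                  start=DEFAULT_GENE_REGIONS[g][1] if g in DEFAULT_GENE_REGIONS else 1_000_000,
                  end=DEFAULT_GENE_REGIONS[g][2] if g in DEFAULT_GENE_REGIONS else 1_000_000 + 400 * m)
        for i, (g, m) in enumerate(blocks.items())
    ]
    return SimulationConfig(n_individuals=n, gene_blocks=gene_blocks,
                            missing_rate=missing_rate, seed=seed)


def make_trait(ds, n_causal, h2, seed, name="trait", shared_from=None,
               shared_fraction=0.0):
    """Architecture with ``n_causal`` random causal SNPs; optionally reusing
    a fraction of another architecture's causal SNPs and effect sizes."""
    rng = np.random.default_rng(seed)
    if shared_from is not None and shared_fraction > 0:
        k = int(round(n_causal * shared_fraction))
        shared = np.sort(rng.choice(shared_from.causal_snp_indices, size=k,
                                    replace=False))
        pool = np.setdiff1d(np.arange(ds.n_snps), shared_from.causal_snp_indices)
        own = np.sort(rng.choice(pool, size=n_causal - k, replace=False))
        idx = np.sort(np.concatenate([shared, own]))
        beta = np.empty(n_causal)
        src = {s: b for s, b in zip(shared_from.causal_snp_indices,
                                    shared_from.effect_sizes)}
        mask = np.isin(idx, shared)
        beta[mask] = [-src[s] for s in idx[mask]]
        beta[~mask] = rng.standard_normal((~mask).sum())
        shared_with = (shared_from.name, shared)
    else:
        idx = np.sort(rng.choice(ds.n_snps, size=n_causal, replace=False))
        beta = rng.standard_normal(n_causal)
        shared_with = None
    return TraitArchitecture(name=name, causal_snp_indices=idx,
                             effect_sizes=beta, h2=h2,
                             instrument=Instrument(0, 10, integer=True),
                             shared_with=shared_with)


def discovery_weights(ds_disc, y_disc, clump_r2=0.1, window_kb=250.0):
    """Associate in discovery, clump, and restrict weights to index SNPs."""
    pheno = pd.DataFrame({"y": y_disc})
    table = assoc_scan(ds_disc, pheno, ["y"])["y"]
    clumped = clump(table, ds_disc, r2_threshold=clump_r2, window_kb=window_kb)
    return table.loc[table["snp"].isin(clumped.index_snps),
                     ["snp", "a1", "beta", "p"]].reset_index(drop=True)


def replication_fit_fixed_T(seed, blocks, n_causal, h2, fixed_T=0.5,
                            target_arch_kwargs=None):
    """One replicate: fixed-threshold replication fit; returns the FitResult."""
    cfg = study_config(seed, blocks=blocks)
    ds = simulate_genotypes(cfg)
    base = make_trait(ds, n_causal, h2, seed=seed + 1, name="base")
    sim_base = simulate_phenotypes(ds, base, seed=seed + 2)

    if target_arch_kwargs is None:
        target_name, y_all = "base", sim_base.scores
    else:
        target = make_trait(ds, shared_from=base, name="target",
                            **target_arch_kwargs)
        y_all = simulate_phenotypes(ds, target, seed=seed + 3).scores
        target_name = "target"

    disc_idx, repl_idx = split_cohort(ds.n_individuals, seed=seed + 4)
    ds_disc, ds_repl = ds.take_individuals(disc_idx), ds.take_individuals(repl_idx)
    weights = discovery_weights(ds_disc, sim_base.scores.iloc[disc_idx])
    score = compute_score(ds_repl, weights, fixed_T)
    y_repl = y_all.iloc[repl_idx].rename(target_name)
    return fit_score_model(score, y_repl)


def best_fit_replication_r2(seed, n_causal=65, h2=0.01, blocks=None):
    """One replicate of the full-width recovery condition: best-fit scan in
    the replication half; returns the best R²."""
    cfg = study_config(seed, blocks=blocks)
    ds = simulate_genotypes(cfg)
    arch = make_trait(ds, n_causal, h2, seed=seed + 1, name="base")
    sim = simulate_phenotypes(ds, arch, seed=seed + 2)
    disc_idx, repl_idx = split_cohort(ds.n_individuals, seed=seed + 4)
    ds_disc, ds_repl = ds.take_individuals(disc_idx), ds.take_individuals(repl_idx)
    weights = discovery_weights(ds_disc, sim.scores.iloc[disc_idx])
    _, best = best_fit_scan(weights, ds_repl, sim.scores.iloc[repl_idx].rename("y"))
    return best.r2
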