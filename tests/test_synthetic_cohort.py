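"""Genotype/phenotype simulator: LD structure, heritability, caseness, split."""

import numpy as np
import pandas as pd
import pytest

from polyprofile.synthetic_cohort import (
    INSTRUMENT_BOUNDS,
    Instrument,
    TraitArchitecture,
    build_cohort,
    default_config,
    derive_dld_status,
    simulate_genotypes,
    simulate_phenotypes,
    split_cohort,
)

from conftest import make_architecture, make_sim_config


# ------------------------------------------------------------- genotypes


def test_allele_frequency_matches_target_at_large_n():
    cfg = make_sim_config(n=10_000, blocks=((12, 0.0),), freq=(0.3, 0.3), seed=1)
    ds = simulate_genotypes(cfg)
    np.testing.assert_allclose(ds.allele_freq(), 0.3, atol=0.02)


def test_ld_rho_induces_adjacent_dosage_correlation():
    """Mean adjacent-pair dosage r² over 50 replicate blocks is strictly
    larger under rho=0.9 than under rho=0."""
    means = {}
    for rho in (0.0, 0.9):
        vals = []
        for rep in range(50):
            cfg = make_sim_config(n=250, blocks=((10, rho),), seed=100 + rep)
            d = simulate_genotypes(cfg).dosages
            r = np.corrcoef(d.T)
            vals.append(np.mean(np.diag(r, k=1) ** 2))
        means[rho] = np.mean(vals)
    assert means[0.9] > means[0.0]


def test_genotype_simulation_deterministic():
    cfg = make_sim_config(n=120, blocks=((30, 0.5),), missing_rate=0.05, seed=42)
    a = simulate_genotypes(cfg)
    b = simulate_genotypes(make_sim_config(n=120, blocks=((30, 0.5),),
                                           missing_rate=0.05, seed=42))
    np.testing.assert_array_equal(a.dosages, b.dosages)
    pd.testing.assert_frame_equal(a.variants, b.variants)


def test_blocks_mutually_independent():
    cfg = make_sim_config(n=4000, blocks=((10, 0.9), (10, 0.9)), seed=3)
    d = simulate_genotypes(cfg).dosages
    cross = np.corrcoef(d.T)[:10, 10:]
    assert np.abs(cross).max() < 0.08


@pytest.mark.parametrize("bad", [
    dict(n=0), dict(blocks=((0, 0.5),)), dict(blocks=((10, 1.0),)),
    dict(freq=(0.0, 0.3)), dict(freq=(0.1, 0.7)),
])
def test_invalid_config_rejected(bad):
    kwargs = dict(n=10, blocks=((5, 0.5),), freq=(0.1, 0.5))
    kwargs.update(bad)
    with pytest.raises(ValueError):
        simulate_genotypes(make_sim_config(**kwargs))


# ------------------------------------------------------------ phenotypes


def test_null_heritability_gives_no_genetic_correlation():
    cfg = make_sim_config(n=5000, blocks=((30, 0.3),), seed=8)
    ds = simulate_genotypes(cfg)
    arch = make_architecture(30, k=10, h2=0.0, seed=2)
    sim = simulate_phenotypes(ds, arch, seed=8)
    r = np.corrcoef(sim.scores, sim.genetic_component)[0, 1]
    assert r * r <= 0.01


def test_heritability_variance_decomposition():
    cfg = make_sim_config(n=5000, blocks=((40, 0.3),), seed=9)
    ds = simulate_genotypes(cfg)
    arch = make_architecture(40, k=10, h2=0.2, seed=4)
    sim = simulate_phenotypes(ds, arch, seed=9)
    genetic = np.sqrt(arch.h2) * sim.genetic_component
    ratio = genetic.var() / sim.liability.var()
    assert ratio == pytest.approx(0.2, abs=0.05)


def test_fully_shared_architecture_gives_identical_genetic_components():
    cfg = make_sim_config(n=800, blocks=((20, 0.4),), seed=10)
    ds = simulate_genotypes(cfg)
    a = make_architecture(20, k=6, h2=0.5, seed=5, name="t1")
    b = TraitArchitecture(
        name="t2", causal_snp_indices=a.causal_snp_indices,
        effect_sizes=a.effect_sizes, h2=0.5, instrument=a.instrument,
        shared_with=("t1", a.causal_snp_indices),
    )
    sa = simulate_phenotypes(ds, a, seed=10)
    sb = simulate_phenotypes(ds, b, seed=10)
    assert np.corrcoef(sa.genetic_component, sb.genetic_component)[0, 1] == pytest.approx(1.0)


def test_genetic_component_correlation_monotone_in_shared_fraction():
    """Over f in {0, .5, 1} (20 replicates), the correlation of the two
    traits' genetic components increases monotonically with the shared
    causal fraction."""
    mean_corr = {}
    for f in (0.0, 0.5, 1.0):
        vals = []
        for rep in range(20):
            cfg = make_sim_config(n=400, blocks=((40, 0.0),), seed=500 + rep)
            ds = simulate_genotypes(cfg)
            rng = np.random.default_rng(900 + rep)
            idx_a = np.sort(rng.choice(40, size=10, replace=False))
            beta_a = rng.standard_normal(10)
            k = int(round(10 * f))
            shared = idx_a[:k]
            rest = np.setdiff1d(np.arange(40), idx_a)
            own = np.sort(rng.choice(rest, size=10 - k, replace=False))
            idx_b = np.sort(np.concatenate([shared, own]))
            beta_b = np.empty(10)
            beta_b[np.isin(idx_b, shared)] = beta_a[:k]
            beta_b[~np.isin(idx_b, shared)] = rng.standard_normal(10 - k)
            inst = Instrument(0, 100, integer=False)
            a = TraitArchitecture("a", idx_a, beta_a, 0.5, inst)
            b = TraitArchitecture("b", idx_b, beta_b, 0.5, inst,
                                  shared_with=("a", shared))
            sa = simulate_phenotypes(ds, a, seed=rep)
            sb = simulate_phenotypes(ds, b, seed=rep + 1)
            vals.append(np.corrcoef(sa.genetic_component, sb.genetic_component)[0, 1])
        mean_corr[f] = np.mean(vals)
    assert mean_corr[0.0] < mean_corr[0.5] < mean_corr[1.0]


def test_invalid_architectures_rejected():
    cfg = make_sim_config(n=20, blocks=((10, 0.2),), seed=1)
    ds = simulate_genotypes(cfg)
    inst = Instrument(0, 10)
    with pytest.raises(ValueError):
        simulate_phenotypes(ds, TraitArchitecture(
            "t", np.array([0]), np.array([1.0]), h2=1.0, instrument=inst), 0)
    with pytest.raises(ValueError):
        simulate_phenotypes(ds, TraitArchitecture(
            "t", np.array([99]), np.array([1.0]), h2=0.1, instrument=inst), 0)


def test_all_instrument_scores_within_bounds():
    ds, cohort = build_cohort(default_config(n_individuals=500, seed=6))
    for trait, (lo, hi) in INSTRUMENT_BOUNDS.items():
        col = cohort.phenotypes[trait]
        assert col.between(lo, hi).all(), trait
        assert (col == np.round(col)).all(), trait


# -------------------------------------------------------------- caseness


def _status_frame(zs, therapy=0, asd=0, hearing=0, n=200):
    """Embed one child with given z-scores in a standard-normal sample."""
    rng = np.random.default_rng(0)
    base = {k: rng.standard_normal(n) for k in ("prag", "nwr", "rec")}
    for k, z in zip(("prag", "nwr", "rec"), zs):
        # place the child exactly z sample-SDs below/above the sample mean
        base[k][0] = base[k][1:].mean() + z * base[k][1:].std(ddof=1)
    idx = pd.RangeIndex(n)
    flags = pd.Series(0, index=idx)
    return derive_dld_status(
        pd.Series(base["prag"], index=idx), pd.Series(base["nwr"], index=idx),
        pd.Series(base["rec"], index=idx),
        therapy_flag=pd.Series([therapy] + [0] * (n - 1), index=idx),
        asd_flag=flags.where(idx != 0, asd),
        hearing_flag=flags.where(idx != 0, hearing),
    )


def test_two_low_scores_yield_affected():
    status = _status_frame((-1.6, -1.3, 0.0))
    assert status.iloc[0] == "affected"


def test_average_child_unaffected():
    status = _status_frame((0.0, 0.0, 0.0))
    assert status.iloc[0] == "unaffected"


def test_asd_flag_excludes_even_with_three_criteria():
    status = _status_frame((-2.0, -2.0, -2.0), asd=1)
    assert status.iloc[0] == "excluded"


def test_missing_criterion_reported_as_excluded_missing():
    idx = pd.RangeIndex(10)
    rng = np.random.default_rng(1)
    cols = [pd.Series(rng.standard_normal(10), index=idx) for _ in range(3)]
    cols[0].iloc[3] = np.nan
    status = derive_dld_status(cols[0], cols[1], cols[2],
                               therapy_flag=pd.Series(0, index=idx))
    assert status.iloc[3] == "excluded_missing"


def test_prevalence_monotone_in_cutoff_severity():
    ds, cohort = build_cohort(default_config(n_individuals=2000, seed=12))
    t = cohort.phenotypes
    prevalences = []
    for cutoff in (-0.5, -1.0, -1.5, -2.0):
        status = derive_dld_status(
            t["pragmatic_9y"], t["nonword_rep_8y"], t["receptive_8y"],
            t["therapy"], z_cutoff=cutoff,
        )
        prevalences.append((status == "affected").mean())
    assert all(a >= b for a, b in zip(prevalences, prevalences[1:]))
    # disabling every criterion: impossible cutoff and no therapy
    none = derive_dld_status(
        t["pragmatic_9y"], t["nonword_rep_8y"], t["receptive_8y"],
        pd.Series(0, index=t.index), z_cutoff=-np.inf,
    )
    assert (none == "affected").sum() == 0


# ------------------------------------------------------------------ split


def test_split_sizes_at_study_scale():
    disc, repl = split_cohort(5435, seed=0)
    assert len(disc) == 2718 and len(repl) == 2717


@pytest.mark.parametrize("n,seed", [(2, 0), (3, 1), (100, 7), (5435, 3)])
def test_split_is_a_partition(n, seed):
    disc, repl = split_cohort(n, seed)
    assert len(disc) == (n + 1) // 2 and len(repl) == n // 2
    union = np.concatenate([disc, repl])
    assert np.array_equal(np.sort(union), np.arange(n))


def test_split_rejects_singletons():
    with pytest.raises(ValueError):
        split_cohort(1, seed=0)
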