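"""Profile scores over the threshold grid, score-model fits, best-fit scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from polyprofile.genotype_io import GenotypeDataset
from polyprofile.profile_scoring import (
    AlleleMismatchError,
    best_fit_scan,
    compute_score,
    fit_score_model,
    threshold_grid,
)

from conftest import make_sim_config
from polyprofile.synthetic_cohort import simulate_genotypes


def _dataset(dosages, a1="A", a2="G"):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    variants = pd.DataFrame({
        "snp": [f"s{j}" for j in range(m)], "chrom": "1",
        "pos": np.arange(1, m + 1) * 1000,
        "a1": [a1] * m if isinstance(a1, str) else a1,
        "a2": [a2] * m if isinstance(a2, str) else a2,
    })
    samples = pd.DataFrame({"fid": [f"F{i}" for i in range(n)],
                            "iid": [f"I{i}" for i in range(n)]})
    return GenotypeDataset(d, variants, samples)


def _weights(snps, a1, beta, p):
    return pd.DataFrame({"snp": snps, "a1": a1, "beta": beta, "p": p})


# ------------------------------------------------------------------- grid


def test_grid_has_fifty_steps_from_001_to_050():
    grid = threshold_grid()
    assert len(grid) == 50
    assert grid[0] == 0.01 and grid[-1] == 0.50
    assert np.allclose(np.diff(grid), 0.01)


# ------------------------------------------------------------------ score


def test_score_hand_arithmetic():
    """Two SNPs with beta (0.5, -0.2) and dosages (2, 1): the averaged
    weighted score is (0.5*2 - 0.2*1)/2 = 0.4."""
    ds = _dataset([[2, 1]])
    w = _weights(["s0", "s1"], ["A", "A"], [0.5, -0.2], [0.01, 0.02])
    profile = compute_score(ds, w, threshold=0.5)
    assert profile.scores.iloc[0] == pytest.approx(0.4)
    assert profile.n_snps == 2


def test_threshold_below_all_p_gives_empty_flag():
    ds = _dataset([[2, 1]])
    w = _weights(["s0", "s1"], ["A", "A"], [0.5, -0.2], [0.01, 0.02])
    profile = compute_score(ds, w, threshold=0.001)
    assert profile.empty and profile.scores is None


def test_score_linear_in_weights(rng):
    d = rng.integers(0, 3, size=(30, 4)).astype(float)
    ds = _dataset(d)
    beta = rng.standard_normal(4)
    w1 = _weights(ds.variants["snp"], ["A"] * 4, beta, [0.01] * 4)
    w2 = w1.assign(beta=2 * beta)
    s1 = compute_score(ds, w1, 0.5).scores
    s2 = compute_score(ds, w2, 0.5).scores
    pd.testing.assert_series_equal(2 * s1, s2)


def test_allele_flip_leaves_score_model_invariant(rng):
    """Flipping a SNP's effect/other alleles while negating beta changes the
    score only by a constant, so the fitted R² and p are unchanged."""
    d = rng.integers(0, 3, size=(60, 3)).astype(float)
    ds = _dataset(d)
    beta = np.array([0.4, -0.3, 0.2])
    w = _weights(ds.variants["snp"], ["A"] * 3, beta, [0.01] * 3)
    w_flipped = w.copy()
    w_flipped.loc[1, "a1"] = "G"        # now matches a2 -> dosage flip
    w_flipped.loc[1, "beta"] = -beta[1]
    y = pd.Series(rng.standard_normal(60), index=ds.iids, name="y")
    f1 = fit_score_model(compute_score(ds, w, 0.5), y)
    f2 = fit_score_model(compute_score(ds, w_flipped, 0.5), y)
    assert f1.r2 == pytest.approx(f2.r2, abs=1e-12)
    assert f1.p == pytest.approx(f2.p, abs=1e-12)


def test_irreconcilable_allele_errors_name_snps():
    ds = _dataset([[2, 1], [0, 1]])
    w = _weights(["s0", "s1"], ["T", "A"], [0.5, -0.2], [0.01, 0.02])
    with pytest.raises(AlleleMismatchError, match="s0"):
        compute_score(ds, w, 0.5)


def test_missing_dosage_imputed_at_twice_allele_frequency():
    d = np.array([[2.0], [0.0], [np.nan], [2.0]])
    ds = _dataset(d)
    w = _weights(["s0"], ["A"], [1.0], [0.01])
    s = compute_score(ds, w, 0.5).scores
    assert s.iloc[2] == pytest.approx(2 * (4 / 6))  # 2 x EAF of non-missing


def test_included_sets_nested_across_grid(rng):
    d = rng.integers(0, 3, size=(40, 10)).astype(float)
    ds = _dataset(d)
    w = _weights(ds.variants["snp"], ["A"] * 10, rng.standard_normal(10),
                 rng.uniform(0, 0.6, 10))
    sets = [set(compute_score(ds, w, T).snps) for T in threshold_grid()]
    for smaller, larger in zip(sets, sets[1:]):
        assert smaller <= larger


# -------------------------------------------------------------------- fit


def test_affine_trait_gives_r2_one(rng):
    d = rng.integers(0, 3, size=(50, 5)).astype(float)
    ds = _dataset(d)
    w = _weights(ds.variants["snp"], ["A"] * 5, rng.standard_normal(5), [0.01] * 5)
    profile = compute_score(ds, w, 0.5)
    y = (3.0 - 2.0 * profile.scores).rename("y")
    fit = fit_score_model(profile, y)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.coef == pytest.approx(-2.0)


def test_fit_matches_closed_form_oracle(rng):
    d = rng.integers(0, 3, size=(25, 4)).astype(float)
    ds = _dataset(d)
    w = _weights(ds.variants["snp"], ["A"] * 4, rng.standard_normal(4), [0.01] * 4)
    profile = compute_score(ds, w, 0.5)
    y = pd.Series(rng.standard_normal(25), index=ds.iids, name="y")
    fit = fit_score_model(profile, y)
    lr = stats.linregress(profile.scores.to_numpy(), y.to_numpy())
    assert fit.r2 == pytest.approx(lr.rvalue ** 2, abs=1e-10)
    assert fit.coef == pytest.approx(lr.slope, abs=1e-10)
    assert fit.p == pytest.approx(lr.pvalue, abs=1e-10)


def test_independent_score_and_trait_rarely_exceed_half_percent_r2():
    """With n=2,717 and no true association, R² stays below .005 in at
    least 95% of 200 seeded replicates."""
    rng = np.random.default_rng(123)
    hits = 0
    for _ in range(200):
        x = rng.standard_normal(2717)
        y = rng.standard_normal(2717)
        r = np.corrcoef(x, y)[0, 1]
        hits += (r * r) < 0.005
    assert hits >= 190


def test_degenerate_zero_variance_score():
    ds = _dataset(np.full((10, 1), 2.0))
    w = _weights(["s0"], ["A"], [1.0], [0.01])
    fit = fit_score_model(compute_score(ds, w, 0.5),
                          pd.Series(np.arange(10.0), index=ds.iids, name="y"))
    assert fit.degenerate and fit.r2 == 0.0 and fit.p == 1.0


# ------------------------------------------------------------- best fit


@pytest.fixture(scope="module")
def scan_instance():
    cfg = make_sim_config(n=300, blocks=((20, 0.0),), seed=91, missing_rate=0.01)
    ds = simulate_genotypes(cfg)
    rng = np.random.default_rng(92)
    w = pd.DataFrame({
        "snp": ds.variants["snp"], "a1": ds.variants["a1"],
        "beta": rng.standard_normal(20), "p": rng.uniform(0, 0.6, 20),
    })
    y = pd.Series(rng.standard_normal(300), index=ds.iids, name="y")
    return ds, w, y


def test_scan_matches_exhaustive_refit_oracle(scan_instance):
    ds, w, y = scan_instance
    grid = threshold_grid()
    fits, best = best_fit_scan(w, ds, y, grid)
    for fit in fits:
        profile = compute_score(ds, w, fit.threshold)
        if profile.empty:
            assert fit.degenerate
            continue
        ref = fit_score_model(profile, y)
        assert fit.r2 == pytest.approx(ref.r2, abs=1e-12)
        assert fit.p == pytest.approx(ref.p, abs=1e-12)
        assert fit.n_snps == ref.n_snps
    valid = [f for f in fits if not f.degenerate]
    assert best.r2 == max(f.r2 for f in valid)
    top = [f.threshold for f in valid if f.r2 == best.r2]
    assert best.threshold == min(top)


def test_n_snps_nondecreasing_across_grid(scan_instance):
    ds, w, y = scan_instance
    fits, _ = best_fit_scan(w, ds, y)
    counts = [f.n_snps for f in fits]
    assert counts == sorted(counts)


def test_dominant_snp_best_at_first_including_threshold(rng):
    """A single overwhelming SNP with p near 0: the best threshold is the
    smallest grid value that includes it."""
    cfg = make_sim_config(n=400, blocks=((5, 0.0),), seed=93)
    ds = simulate_genotypes(cfg)
    y = pd.Series(ds.dosages[:, 0] * 2.0
                  + 0.05 * np.random.default_rng(94).standard_normal(400),
                  index=ds.iids, name="y").fillna(0.0)
    w = pd.DataFrame({
        "snp": ds.variants["snp"], "a1": ds.variants["a1"],
        "beta": [2.0, 0.01, 0.01, 0.01, 0.01],
        "p": [1e-12, 0.3, 0.4, 0.45, 0.5],
    })
    _, best = best_fit_scan(w, ds, y)
    assert best.threshold == 0.01


def test_fixed_from_discovery_mode(scan_instance):
    ds, w, y = scan_instance
    # discovery = same variant panel, independent trait draw
    disc = ds
    y_disc = pd.Series(np.random.default_rng(96).standard_normal(300),
                       index=disc.iids, name="y")
    disc_scan, best = best_fit_scan(
        w, ds, y, mode="fixed_from_discovery",
        discovery_dataset=disc, discovery_trait=y_disc,
    )
    best_disc = max((f for f in disc_scan if not f.degenerate),
                    key=lambda f: (f.r2, -f.threshold))
    assert best.threshold == best_disc.threshold
    assert best.cohort == "replication"
    ref = fit_score_model(compute_score(ds, w, best.threshold), y)
    assert best.r2 == pytest.approx(ref.r2, abs=1e-12)


def test_all_empty_thresholds_error():
    ds = _dataset([[2, 1], [0, 1], [1, 0]])
    w = _weights(["s0", "s1"], ["A", "A"], [0.5, -0.2], [0.9, 0.95])
    with pytest.raises(ValueError):
        best_fit_scan(w, ds, pd.Series([1.0, 2.0, 3.0], index=ds.iids, name="y"),
                      grid=np.array([0.01, 0.02]))
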