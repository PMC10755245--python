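"""OLS/logistic association rows, Welch/Cohen contrasts, BH step-up against
a brute-force oracle, the region scan and the GWAS scan with its thresholds."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smokebag import (
    SimConfig,
    bh_fdr,
    glm_association,
    gwas_scan,
    gwas_thresholds,
    partial_correlation,
    regionwise_scan,
    simulate_genotypes,
    two_sample_comparison,
)


def bh_oracle(p):
    """Step-up BH by direct definition: q_(i) = min_{j>=i} p_(j) * m / j."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = running
    return q


# --- glm_association -------------------------------------------------------

def test_glm_exact_linear_relationship(rng):
    x = rng.standard_normal(100)
    row = glm_association(2.0 * x, x)
    assert row.beta == pytest.approx(2.0, abs=1e-10)
    assert row.p < 1e-50


def test_glm_adjusts_for_independent_covariate(rng):
    x = rng.standard_normal(500)
    c = rng.standard_normal(500)
    row = glm_association(x + c, x, covariates=c)
    assert row.beta == pytest.approx(1.0, abs=1e-8)


def test_glm_null_p_uniform_ks():
    rng = np.random.default_rng(5)
    ps = []
    for _ in range(200):
        y = rng.standard_normal(1000)
        x = rng.standard_normal(1000)
        ps.append(glm_association(y, x).p)
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_glm_logistic_family(rng):
    x = rng.standard_normal(800)
    logit = 1.2 * x
    y = (rng.random(800) < 1 / (1 + np.exp(-logit))).astype(float)
    row = glm_association(y, x, family="binomial")
    assert row.beta == pytest.approx(1.2, abs=0.35)
    assert row.p < 1e-6


def test_glm_rejects_collinearity(rng):
    x = rng.standard_normal(50)
    with pytest.raises(ValueError, match="collinear"):
        glm_association(rng.standard_normal(50), x, covariates=x)


def test_glm_sign_agrees_with_partial_correlation(rng):
    x = rng.standard_normal(400)
    cov = rng.standard_normal((400, 2))
    y = -0.4 * x + cov @ [0.5, -0.3] + rng.standard_normal(400)
    row = glm_association(y, x, cov)
    r, _ = partial_correlation(x, y, cov)
    assert np.sign(row.beta) == np.sign(r)


# --- two-sample comparison -------------------------------------------------

def test_two_sample_identical_groups():
    g = np.array([1.0, 2.0, 3.0, 4.0])
    es = two_sample_comparison(g, g)
    assert es.cohens_d == 0.0
    assert es.p == pytest.approx(1.0)


def test_two_sample_hand_computed_d():
    es = two_sample_comparison([1, 2, 3], [3, 4, 5])
    assert es.cohens_d == pytest.approx(-2.0)


def test_two_sample_antisymmetry(rng):
    a, b = rng.normal(0, 1, 50), rng.normal(0.5, 1, 60)
    e1 = two_sample_comparison(a, b)
    e2 = two_sample_comparison(b, a)
    assert e1.cohens_d == pytest.approx(-e2.cohens_d)
    assert e1.p == pytest.approx(e2.p)


def test_two_sample_guards():
    with pytest.raises(ValueError):
        two_sample_comparison([1.0], [1, 2, 3])
    with pytest.raises(ValueError):
        two_sample_comparison(np.ones(5), np.ones(5))


# --- BH FDR ----------------------------------------------------------------

def test_bh_single_p_unchanged():
    assert bh_fdr([0.03]) == pytest.approx([0.03])


def test_bh_hand_computed_stepup():
    assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_empty_input():
    assert bh_fdr([]).size == 0


def test_bh_matches_bruteforce_oracle_many_seeds():
    rng = np.random.default_rng(8)
    for _ in range(1000):
        p = rng.random(rng.integers(1, 21))
        adj = bh_fdr(p)
        assert np.allclose(adj, bh_oracle(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)


# --- region scan -----------------------------------------------------------

def test_region_scan_null_false_positives_rare():
    total_hits = 0
    for seed in range(10):
        rng = np.random.default_rng(400 + seed)
        prs = rng.standard_normal(1000)
        regions = pd.DataFrame(rng.standard_normal((1000, 40)))
        regions.columns = [f"region_{i}" for i in range(40)]
        out = regionwise_scan(prs, regions, alpha=0.05)
        total_hits += int(out["significant"].sum())
    assert total_hits <= 2


def test_region_scan_planted_signal_ranks_first():
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(500 + seed)
        prs = rng.standard_normal(800)
        regions = pd.DataFrame(rng.standard_normal((800, 30)))
        regions.columns = [f"region_{i}" for i in range(30)]
        regions["region_7"] = -0.5 * prs + rng.standard_normal(800)
        out = regionwise_scan(prs, regions)
        wins += out.loc[out["partial_r"].abs().idxmax(), "region"] == "region_7"
    assert wins >= 9


def test_region_scan_constant_region_and_alpha_one(rng):
    prs = rng.standard_normal(200)
    regions = pd.DataFrame(
        {"region_a": rng.standard_normal(200), "region_b": np.full(200, 5.0)}
    )
    out = regionwise_scan(prs, regions, alpha=1.1)
    const_row = out[out["region"] == "region_b"].iloc[0]
    assert np.isnan(const_row["partial_r"]) and np.isnan(const_row["q"])
    assert out[out["region"] == "region_a"]["significant"].all()


# --- GWAS scan -------------------------------------------------------------

def test_biobank_scale_bonferroni_thresholds():
    gw, sugg = gwas_thresholds(616_339)
    assert gw == pytest.approx(8.112419e-08, rel=1e-6)
    assert sugg == pytest.approx(1.622484e-06, rel=1e-6)
    with pytest.raises(ValueError):
        gwas_thresholds(0)


def test_gwas_planted_signal_is_top_hit():
    cfg = SimConfig(n_subjects=300, n_snps=50, n_causal=0, ld_block_size=1,
                    missing_rate=0.0, seed=21)
    g = simulate_genotypes(cfg)
    dos = g.dosages.to_numpy()
    phen = 2.0 * dos[:, 17]
    res = gwas_scan(g, phen)
    assert res.table["P"].idxmin() == 17
    assert res.m == 50
    assert res.genomewide_threshold == pytest.approx(0.001)
    assert res.n_genomewide >= 1


def test_gwas_matches_full_ols_with_covariates(rng):
    """FWL shortcut reproduces per-SNP OLS beta/SE/p exactly."""
    import statsmodels.api as sm

    cfg = SimConfig(n_subjects=200, n_snps=10, n_causal=0, ld_block_size=1,
                    seed=22)
    g = simulate_genotypes(cfg)
    cov = rng.standard_normal((200, 3))
    y = rng.standard_normal(200) + cov[:, 0]
    res = gwas_scan(g, y, cov)
    dos = g.dosages.to_numpy()
    col_mean = np.nanmean(dos, axis=0)
    G = np.where(np.isnan(dos), col_mean, dos)
    for j in range(10):
        X = np.column_stack([np.ones(200), G[:, j], cov])
        fit = sm.OLS(y, X).fit()
        assert res.table.loc[j, "BETA"] == pytest.approx(fit.params[1], abs=1e-10)
        assert res.table.loc[j, "SE"] == pytest.approx(fit.bse[1], abs=1e-10)
        assert res.table.loc[j, "P"] == pytest.approx(fit.pvalues[1], abs=1e-12)


def test_gwas_monomorphic_snp_reported_na():
    dos = pd.DataFrame(
        {"mono": np.zeros(60), "poly": np.r_[np.zeros(30), np.ones(30)]}
    )
    dos.index = [f"S{i}" for i in range(60)]
    snps = pd.DataFrame(
        {"chr": "1", "pos": [100, 200], "ea": "A", "oa": "G"},
        index=pd.Index(["mono", "poly"], name="SNP"),
    )
    from smokebag import GenotypeMatrix

    rng = np.random.default_rng(3)
    res = gwas_scan(GenotypeMatrix(dos, snps), rng.standard_normal(60))
    assert np.isnan(res.table.set_index("SNP").loc["mono", "P"])
    assert res.m == 1
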