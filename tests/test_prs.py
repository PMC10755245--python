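"""P+T scoring: clumping vs a brute-force reference, the scoring formula,
partial correlation against an independent implementation, threshold scan."""

import numpy as np
import pandas as pd
import pytest

from smokebag import (
    ClumpConfig,
    GenotypeMatrix,
    SimConfig,
    SummaryStats,
    ThresholdGrid,
    clump,
    partial_correlation,
    score,
    simulate_cohort,
    threshold_scan,
)


def brute_force_clump(table: pd.DataFrame, dosages: pd.DataFrame,
                      r2_cutoff: float, window_bp: float) -> list:
    """Reference clumping: recompute the eligible set from scratch each
    round instead of maintaining removal state."""
    removed: set = set()
    index_snps: list = []
    def sort_key(row):
        return (row["P"], row["CHR"], row["POS"], row["SNP"])
    remaining = table.to_dict("records")
    while True:
        pool = [r for r in remaining
                if r["SNP"] not in removed and r["SNP"] not in index_snps]
        if not pool:
            return index_snps
        best = min(pool, key=sort_key)
        index_snps.append(best["SNP"])
        for r in pool:
            if r["SNP"] == best["SNP"] or r["CHR"] != best["CHR"]:
                continue
            if abs(r["POS"] - best["POS"]) > window_bp:
                continue
            a = dosages[best["SNP"]].to_numpy(float)
            b = dosages[r["SNP"]].to_numpy(float)
            ok = ~(np.isnan(a) | np.isnan(b))
            if ok.sum() < 3 or a[ok].std() == 0 or b[ok].std() == 0:
                continue
            if np.corrcoef(a[ok], b[ok])[0, 1] ** 2 > r2_cutoff:
                removed.add(r["SNP"])


def random_fixture(seed: int, n_snps: int = 20, n_samples: int = 200):
    cfg = SimConfig(
        n_subjects=n_samples, n_snps=n_snps, n_causal=0, ld_block_size=4,
        within_block_corr=0.7, seed=seed,
    )
    g = simulate_cohort(cfg)
    rng = np.random.default_rng(seed + 1000)
    stats = g.summary_stats.table.copy()
    stats["P"] = rng.random(n_snps)
    # random positions within one chromosome so windows genuinely vary
    stats["CHR"] = "1"
    stats["POS"] = np.sort(rng.integers(1, 2_000_000, n_snps))
    geno = g.genotypes
    snps = geno.snps.copy()
    snps["chr"] = "1"
    snps["pos"] = stats.set_index("SNP").loc[snps.index, "POS"].to_numpy()
    return GenotypeMatrix(geno.dosages, snps), SummaryStats(stats)


def two_snp_fixture(dist_bp: int, r: float, n: int = 2000):
    rng = np.random.default_rng(99)
    z = rng.standard_normal((n, 2))
    z[:, 1] = r * z[:, 0] + np.sqrt(1 - r * r) * z[:, 1]
    dos = (z > 0).astype(float) + (z > 1).astype(float)
    dosages = pd.DataFrame(dos, columns=["A", "B"],
                           index=[f"S{i}" for i in range(n)])
    snps = pd.DataFrame(
        {"chr": "1", "pos": [100_000, 100_000 + dist_bp],
         "ea": "A", "oa": "G"},
        index=pd.Index(["A", "B"], name="SNP"),
    )
    stats = pd.DataFrame(
        {"SNP": ["A", "B"], "CHR": "1", "POS": snps["pos"].to_numpy(),
         "EA": "A", "OA": "G", "BETA": [0.1, 0.1], "P": [1e-8, 1e-4]}
    )
    return GenotypeMatrix(dosages, snps), SummaryStats(stats)


def test_single_snp_is_sole_index():
    g, s = two_snp_fixture(50_000, 0.8)
    only = SummaryStats(s.table.iloc[[0]].reset_index(drop=True))
    assert clump(only, g) == ["A"]


def test_correlated_neighbor_is_clumped_inside_window():
    g, s = two_snp_fixture(50_000, 0.8)  # dosage r^2 well above 0.1
    assert clump(s, g) == ["A"]


def test_neighbor_outside_window_survives():
    g, s = two_snp_fixture(300_000, 0.8)
    assert clump(s, g) == ["A", "B"]


def test_clump_matches_brute_force_reference():
    cfg = ClumpConfig()
    for seed in range(100):
        g, s = random_fixture(seed)
        expected = brute_force_clump(
            s.table, g.dosages, cfg.r2_cutoff, cfg.window_kb * 1000
        )
        assert clump(s, g, cfg) == expected


def test_score_formula_and_mean_imputation():
    dosages = pd.DataFrame(
        {"A": [2.0, np.nan], "B": [1.0, 1.0]},
        index=["S1", "S2"],
    )
    snps = pd.DataFrame(
        {"chr": "1", "pos": [100, 200_000_000], "ea": "A", "oa": "G"},
        index=pd.Index(["A", "B"], name="SNP"),
    )
    stats = SummaryStats(pd.DataFrame(
        {"SNP": ["A", "B"], "CHR": "1", "POS": [100, 200_000_000],
         "EA": "A", "OA": "G", "BETA": [0.5, -0.2], "P": [1e-6, 1e-3]}
    ))
    g = GenotypeMatrix(dosages, snps)
    s, n_used = score(g, stats, ["A"], p_threshold=0.05)
    assert n_used == 1
    assert s["S1"] == pytest.approx(1.0)  # 0.5 * 2 / 1

    s2, n2 = score(g, stats, ["A", "B"], p_threshold=0.05)
    assert n2 == 2
    assert s2["S1"] == pytest.approx((0.5 * 2 - 0.2 * 1) / 2)  # 0.4
    # S2's missing dosage at A imputed with 2 * effect allele freq = 2*1 = 2
    assert s2["S2"] == pytest.approx((0.5 * 2.0 - 0.2) / 2)

    s3, _ = score(g, stats, ["A", "B"], p_threshold=0.05, average=False)
    assert s3["S1"] == pytest.approx(0.8)

    with pytest.raises(ValueError, match="empty score"):
        score(g, stats, ["A", "B"], p_threshold=1e-9)


def test_score_flips_dosage_when_effect_allele_is_other():
    dosages = pd.DataFrame({"A": [2.0, 0.0]}, index=["S1", "S2"])
    snps = pd.DataFrame({"chr": "1", "pos": [100], "ea": "A", "oa": "G"},
                        index=pd.Index(["A"], name="SNP"))
    stats = SummaryStats(pd.DataFrame(
        {"SNP": ["A"], "CHR": "1", "POS": [100], "EA": "G", "OA": "A",
         "BETA": [0.5], "P": [1e-6]}
    ))
    s, _ = score(GenotypeMatrix(dosages, snps), stats, ["A"], 0.05)
    assert s["S1"] == pytest.approx(0.0)   # 2 copies of A = 0 copies of G
    assert s["S2"] == pytest.approx(1.0)


def test_partial_correlation_identity_and_construction(rng):
    x = rng.standard_normal(500)
    r, p = partial_correlation(x, x)
    assert r == pytest.approx(1.0)

    c = rng.standard_normal(2000)
    x = c + rng.standard_normal(2000)
    y = c.copy()
    r, _ = partial_correlation(x, y, covariates=c)
    assert abs(r) < 0.05


def test_partial_correlation_matches_pingouin(rng):
    pingouin = pytest.importorskip("pingouin")
    x = rng.standard_normal(300)
    cov = rng.standard_normal((300, 2))
    y = 0.3 * x + 0.5 * cov[:, 0] + rng.standard_normal(300)
    r, p = partial_correlation(x, y, cov)
    df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
    assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


def test_partial_correlation_null_p_is_uniform():
    rng = np.random.default_rng(42)
    hits = 0
    n_rep = 200
    for _ in range(n_rep):
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        _, p = partial_correlation(x, y)
        hits += p < 0.05
    assert 0.01 <= hits / n_rep <= 0.10


def test_partial_correlation_errors():
    with pytest.raises(ValueError):
        partial_correlation([1, 2, 3], [1, 2, 3, 4])
    with pytest.raises(ValueError, match="zero-variance"):
        partial_correlation(np.ones(50), np.arange(50.0))


def test_threshold_grid_default_has_100_values_and_validates():
    grid = ThresholdGrid()
    assert len(grid) == 100
    assert grid.p_thresholds[0] == pytest.approx(0.005)
    assert grid.p_thresholds[-1] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        ThresholdGrid([0.5, 0.1])
    with pytest.raises(ValueError):
        ThresholdGrid([])


def test_threshold_scan_single_threshold_and_monotone_snp_count(small_cohort):
    g = small_cohort.genotypes
    ss = small_cohort.summary_stats
    t = small_cohort.cohort.table
    idx = clump(ss, g)
    phen = t["smoker"].to_numpy(float)

    one = threshold_scan(g, ss, idx, grid=ThresholdGrid([0.1]), phenotype=phen)
    assert one.optimal_threshold == pytest.approx(0.1)

    res = threshold_scan(g, ss, idx, phenotype=phen)
    counts = res.per_threshold["n_snps_used"].to_numpy()
    assert np.all(np.diff(counts) >= 0)
    assert len(res.per_threshold) == 100
    assert res.zscored_optimal.mean() == pytest.approx(0.0, abs=1e-9)
    assert res.zscored_optimal.std(ddof=0) == pytest.approx(1.0, abs=1e-9)
    assert len(res.selected_thresholds) == 10


def test_optimal_prs_recovers_liability_sign():
    """With heritable liability, the selected z-scored PRS correlates
    positively with the generative smoking liability (sign recovery)."""
    wins = 0
    for seed in range(10):
        cfg = SimConfig(n_subjects=700, n_snps=300, n_causal=40, seed=100 + seed)
        sim = simulate_cohort(cfg)
        idx = clump(sim.summary_stats, sim.genotypes)
        res = threshold_scan(
            sim.genotypes, sim.summary_stats, idx,
            phenotype=sim.cohort.table["smoker"].to_numpy(float),
        )
        r = np.corrcoef(res.zscored_optimal,
                        sim.cohort.table["liability"])[0, 1]
        wins += r > 0
    assert wins >= 9


def test_causal_snps_at_low_p_select_low_threshold():
    hits = 0
    for seed in range(10):
        cfg = SimConfig(
            n_subjects=800, n_snps=300, n_causal=40, h2_liability=0.5,
            beta_sd=0.08, seed=200 + seed,
        )
        sim = simulate_cohort(cfg)
        idx = clump(sim.summary_stats, sim.genotypes)
        res = threshold_scan(
            sim.genotypes, sim.summary_stats, idx,
            phenotype=sim.cohort.table["smoker"].to_numpy(float),
        )
        hits += res.optimal_threshold <= 0.05
    assert hits >= 8
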