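"""Synthetic cohort generator with the causal chain the analysis assumes:

    genotype --(true polygenic score)--> smoking liability --> pack-years
             --> regional gray-matter atrophy --> brain-age gap

LD is induced with a Gaussian copula: each block of ``ld_block_size`` SNPs
shares an equicorrelated latent factor (correlation ``within_block_corr``)
which is discretized to genotype classes at Hardy-Weinberg proportions, so
marginal allele frequencies are exact and within-block dosage r^2 is
controlled without an external haplotype panel. Missing calls are injected
completely at random. Ancestry PCs are standard normals independent of
genotype (they are nuisance covariates downstream, nothing more).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortTable, GenotypeMatrix, SummaryStats, SyntheticCohort


@dataclass
class SimConfig:
    """Study-condition knobs for the synthetic cohort.

    Volume units are mm^3. ``atrophy_age_slope`` is the per-region loss per
    year of age (modulated by a U(0.5, 1.5) regional weight so regions carry
    different amounts of age information); ``atrophy_packyear_slope`` is the
    whole-brain loss per pack-year, spread evenly over the regions.
    """

    n_subjects: int = 3000
    n_snps: int = 2000
    n_causal: int = 60
    ld_block_size: int = 10
    within_block_corr: float = 0.6
    maf_range: tuple[float, float] = (0.05, 0.5)
    h2_liability: float = 0.3
    smoking_prevalence: float = 0.56
    n_regions: int = 166
    atrophy_age_slope: float = -3.0
    atrophy_packyear_slope: float = -60.0
    noise_sd_region: float = 60.0
    age_range: tuple[float, float] = (44.0, 81.0)
    missing_rate: float = 0.01
    discovery_n: int = 100_000
    beta_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects <= 0 or self.n_snps <= 0:
            raise ValueError("n_subjects and n_snps must be positive")
        if not 0 <= self.n_causal <= self.n_snps:
            raise ValueError("n_causal must be in [0, n_snps]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not 0 <= self.within_block_corr < 1:
            raise ValueError("within_block_corr must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < min <= max <= 0.5")
        for name in ("h2_liability", "smoking_prevalence", "missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be increasing")
        if self.discovery_n <= 0:
            raise ValueError("discovery_n must be positive")


# SNP spacing: 1 kb inside a block (a block spans < 250 kb for any
# reasonable block size), 1 Mb between block starts so clumping windows
# never bridge blocks.
_WITHIN_BP = 1_000
_BETWEEN_BP = 1_000_000


def _snp_map(config: SimConfig) -> pd.DataFrame:
    n_blocks = -(-config.n_snps // config.ld_block_size)
    blocks_per_chrom = -(-n_blocks // 22)
    rows = []
    for j in range(config.n_snps):
        block = j // config.ld_block_size
        within = j % config.ld_block_size
        chrom = block // blocks_per_chrom + 1
        block_on_chrom = block % blocks_per_chrom
        pos = 1 + block_on_chrom * _BETWEEN_BP + within * _WITHIN_BP
        rows.append((f"rs{j + 1}", str(chrom), pos, "A", "G", block))
    return pd.DataFrame(
        rows, columns=["SNP", "chr", "pos", "ea", "oa", "block"]
    ).set_index("SNP")


def simulate_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Draw an LD-blocked dosage matrix at Hardy-Weinberg proportions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    snp_map = _snp_map(config)
    n, m = config.n_subjects, config.n_snps
    rho = config.within_block_corr

    freqs = rng.uniform(*config.maf_range, size=m)
    # equicorrelated latent per block: z = sqrt(rho)*u_block + sqrt(1-rho)*e
    blocks = snp_map["block"].to_numpy()
    n_blocks = blocks.max() + 1
    u = rng.standard_normal((n, n_blocks))
    e = rng.standard_normal((n, m))
    z = np.sqrt(rho) * u[:, blocks] + np.sqrt(1.0 - rho) * e
    uq = stats.norm.cdf(z)
    # HWE class boundaries per SNP: P(0)=(1-p)^2, P(1)=2p(1-p), P(2)=p^2
    q0 = (1.0 - freqs) ** 2
    q1 = q0 + 2.0 * freqs * (1.0 - freqs)
    dos = np.where(uq < q0, 0.0, np.where(uq < q1, 1.0, 2.0))
    if config.missing_rate > 0:
        dos[rng.random((n, m)) < config.missing_rate] = np.nan

    dosages = pd.DataFrame(
        dos,
        index=pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject"),
        columns=snp_map.index,
    )
    return GenotypeMatrix(dosages, snp_map[["chr", "pos", "ea", "oa"]])


def draw_true_effects(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    """Sparse per-SNP effects: ``n_causal`` SNPs get N(0, beta_sd) betas."""
    beta = np.zeros(config.n_snps)
    causal = rng.choice(config.n_snps, size=config.n_causal, replace=False)
    beta[causal] = rng.normal(0.0, config.beta_sd, size=config.n_causal)
    return pd.Series(beta, index=_snp_map(config).index, name="beta_true")


def simulate_discovery_gwas(
    genotypes: GenotypeMatrix,
    true_effects,
    discovery_n: int,
    seed: int,
) -> SummaryStats:
    """Noisy discovery-sample estimates of the true per-SNP effects.

    beta_hat_j = beta_j + N(0, se_j) with se_j = 1/sqrt(2 p_j (1-p_j) N),
    the standard error of an additive GWAS slope on a standardized trait;
    p-values are two-sided Wald.
    """
    if discovery_n <= 0:
        raise ValueError("discovery_n must be positive")
    beta = np.asarray(true_effects, dtype=float)
    if beta.shape[0] != genotypes.n_snps:
        raise ValueError("true_effects length must equal n_snps")
    rng = np.random.default_rng(seed)
    p_allele = genotypes.effect_allele_freq().to_numpy()
    se = 1.0 / np.sqrt(2.0 * p_allele * (1.0 - p_allele) * discovery_n)
    beta_hat = beta + rng.normal(0.0, 1.0, size=beta.shape) * se
    pvals = 2.0 * stats.norm.sf(np.abs(beta_hat / se))
    snps = genotypes.snps
    table = pd.DataFrame(
        {
            "SNP": snps.index,
            "CHR": snps["chr"].to_numpy(),
            "POS": snps["pos"].to_numpy(),
            "EA": snps["ea"].to_numpy(),
            "OA": snps["oa"].to_numpy(),
            "BETA": beta_hat,
            "P": pvals,
        }
    )
    return SummaryStats(table)


def simulate_cohort(config: SimConfig) -> SyntheticCohort:
    """Full synthetic cohort: genotypes, discovery GWAS, smoking, volumes."""
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    genotypes = simulate_genotypes(config)
    true_effects = draw_true_effects(config, rng)
    sumstats = simulate_discovery_gwas(
        genotypes, true_effects, config.discovery_n, seed=config.seed + 101
    )

    n = config.n_subjects
    dos = genotypes.dosages.to_numpy(dtype=float)
    freq = genotypes.effect_allele_freq().to_numpy()
    filled = np.where(np.isnan(dos), 2.0 * freq, dos)
    score = filled @ true_effects.to_numpy()
    sd = score.std()
    score_std = (score - score.mean()) / sd if sd > 0 else np.zeros(n)

    # liability: genetic part explains h2, a small sex effect plus noise the rest
    sex = rng.integers(0, 2, size=n).astype(float)  # 1 = male
    gamma_sex = 0.1
    resid_var = 1.0 - config.h2_liability - gamma_sex**2 * 0.25
    resid_sd = np.sqrt(max(resid_var, 1e-12))
    liability = (
        np.sqrt(config.h2_liability) * score_std
        + gamma_sex * (sex - 0.5)
        + resid_sd * rng.standard_normal(n)
    )
    cut = np.quantile(liability, 1.0 - config.smoking_prevalence)
    smoker = liability > cut

    pack_years = np.zeros(n)
    pack_years[smoker] = np.maximum(
        0.0, 18.0 + 8.0 * liability[smoker] + rng.normal(0.0, 8.0, smoker.sum())
    )
    status = np.where(smoker, "current", "never").astype(object)
    former = smoker & (rng.random(n) < 0.5)
    status[former] = "former"
    quit_years = np.zeros(n)
    quit_years[former] = np.maximum(
        0.0, 12.0 - 3.0 * liability[former] + rng.normal(0.0, 5.0, former.sum())
    )

    age = rng.uniform(*config.age_range, size=n)
    bmi = rng.normal(27.0, 4.0, n)
    alcohol = (rng.random(n) < 0.6).astype(float)
    handedness = (rng.random(n) < 0.1).astype(float)
    site = rng.integers(0, 3, size=n).astype(float)
    education = rng.integers(1, 6, size=n).astype(float)
    tiv = rng.normal(1.5e6, 1.2e5, n)
    pcs = rng.standard_normal((n, 5))

    k = config.n_regions
    baseline = rng.uniform(2500.0, 9000.0, k)
    age_w = rng.uniform(0.5, 1.5, k)
    sex_w = rng.uniform(0.0, 60.0, k)
    regions = (
        baseline[None, :]
        + config.atrophy_age_slope * age_w[None, :] * age[:, None]
        + (config.atrophy_packyear_slope / k) * pack_years[:, None]
        + 0.0004 * (tiv - 1.5e6)[:, None]
        + sex_w[None, :] * sex[:, None]
        - 1.0 * (bmi - 27.0)[:, None]
        + rng.normal(0.0, config.noise_sd_region, (n, k))
    )
    tgmv = regions.sum(axis=1)

    cohort = pd.DataFrame(
        {
            "subject": genotypes.dosages.index,
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "alcohol": alcohol,
            "handedness": handedness,
            "site": site,
            "education": education,
            "tiv": tiv,
            **{f"pc{i + 1}": pcs[:, i] for i in range(5)},
            "smoker": smoker.astype(int),
            "smoking_status": status,
            "pack_years": pack_years,
            "quit_years": quit_years,
            "true_score": score_std,
            "liability": liability,
            **{f"region_{i + 1:04d}": regions[:, i] for i in range(k)},
        }
    )
    cohort["tgmv"] = cohort[[f"region_{i + 1:04d}" for i in range(k)]].sum(axis=1)
    assert np.allclose(cohort["tgmv"], tgmv)

    return SyntheticCohort(
        genotypes=genotypes,
        true_effects=true_effects,
        summary_stats=sumstats,
        cohort=CohortTable(cohort),
        config=config,
    )


def simulate_gene_annotation(
    genotypes: GenotypeMatrix,
    seed: int,
    genes_per_chrom: int = 20,
    n_sets: int = 15,
    genes_per_set: tuple[int, int] = (5, 40),
):
    """Synthetic gene intervals (BED-style, 0-based half-open) spanning the
    simulated SNP positions, plus random gene sets over those genes.

    Returns ``(intervals, sets)`` where ``intervals`` is a DataFrame with
    columns chrom/start/end/gene and ``sets`` is a dict name -> gene list.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in genotypes.snps.groupby("chr", sort=False):
        lo, hi = int(grp["pos"].min()), int(grp["pos"].max())
        span = max(hi - lo, 1)
        for g in range(genes_per_chrom):
            start = int(rng.integers(max(lo - 50_000, 0), lo + span))
            length = int(rng.integers(5_000, 200_000))
            rows.append((chrom, start, start + length, f"GENE{chrom}_{g + 1}"))
    intervals = pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])
    genes = intervals["gene"].tolist()
    sets = {}
    for s in range(n_sets):
        size = int(rng.integers(genes_per_set[0], genes_per_set[1] + 1))
        size = min(size, len(genes))
        members = sorted(rng.choice(genes, size=size, replace=False).tolist())
        sets[f"SET_{s + 1:03d}"] = members
    return intervals, sets


def config_to_dict(config: SimConfig) -> dict:
    return asdict(config)
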