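"""P+T polygenic risk scores.

Clumping is the standard greedy pass: SNPs are visited by ascending
discovery p-value; each index SNP removes, from the remaining pool, SNPs on
its chromosome within the physical window whose dosage r^2 with it exceeds
the cutoff. Scores at a p-value threshold P_T average the per-SNP
contribution beta_j * G_ij over the SNPs entering the sum (PLINK-style
average; the plain sum is available via ``average=False``), with missing
dosages imputed as twice the target-sample effect-allele frequency. The
threshold with the strongest partial correlation against the smoking
phenotype (covariates residualized out) is selected and z-scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import design_matrix, residualize_on
from .containers import GenotypeMatrix, SummaryStats


@dataclass
class ClumpConfig:
    r2_cutoff: float = 0.1
    window_kb: float = 250.0

    def __post_init__(self) -> None:
        if not 0 < self.r2_cutoff < 1:
            raise ValueError("r2_cutoff must be in (0, 1)")
        if self.window_kb <= 0:
            raise ValueError("window_kb must be positive")


@dataclass
class ThresholdGrid:
    """Ordered P_T grid; the default is 0.005 to 0.5 in steps of 0.005."""

    p_thresholds: list[float] = field(
        default_factory=lambda: [round(0.005 * i, 10) for i in range(1, 101)]
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.p_thresholds, dtype=float)
        if t.size == 0:
            raise ValueError("empty threshold grid")
        if np.any(np.diff(t) <= 0):
            raise ValueError("thresholds must be strictly increasing")
        if np.any((t <= 0) | (t > 1)):
            raise ValueError("thresholds must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.p_thresholds)


@dataclass
class PRSResult:
    scores: pd.DataFrame              # subjects x thresholds
    per_threshold: pd.DataFrame       # P_T, n_snps_used, partial_r, p
    selected_thresholds: list[float]  # top-k by ranking criterion
    optimal_threshold: float
    zscored_optimal: pd.Series

    def to_json_dict(self) -> dict:
        return {
            "optimal_threshold": self.optimal_threshold,
            "selected_thresholds": list(self.selected_thresholds),
            "per_threshold": self.per_threshold.to_dict(orient="records"),
        }


def _pairwise_r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    ok = ~(np.isnan(a) | np.isnan(b))
    if ok.sum() < 3:
        return 0.0
    x, y = a[ok], b[ok]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def clump(
    stats_in: SummaryStats,
    ld_panel: GenotypeMatrix,
    config: ClumpConfig | None = None,
    missing_snp_policy: str = "skip",
) -> list[str]:
    """Greedy p-value-informed LD clumping; returns index SNP ids in
    selection order.

    SNPs absent from the LD panel are skipped with a warning (or raise, with
    ``missing_snp_policy="error"``). Ties in p are broken by (chromosome,
    position, SNP id) so the result is deterministic.
    """
    config = config or ClumpConfig()
    table = stats_in.table
    present = table["SNP"].isin(ld_panel.dosages.columns)
    if not present.all():
        missing = table.loc[~present, "SNP"].tolist()
        if missing_snp_policy == "error":
            raise KeyError(f"SNPs absent from LD panel: {missing[:5]}...")
        warnings.warn(f"{len(missing)} SNPs absent from LD panel; skipped")
        table = table[present]
    if table.empty:
        return []

    table = table.sort_values(
        ["P", "CHR", "POS", "SNP"], kind="mergesort"
    ).reset_index(drop=True)
    dos = ld_panel.dosages
    window_bp = config.window_kb * 1_000

    alive = np.ones(len(table), dtype=bool)
    chrom = table["CHR"].to_numpy()
    pos = table["POS"].to_numpy(dtype=float)
    index_snps: list[str] = []
    for i in range(len(table)):
        if not alive[i]:
            continue
        snp_i = table.at[i, "SNP"]
        index_snps.append(snp_i)
        alive[i] = False
        near = alive & (chrom == chrom[i]) & (np.abs(pos - pos[i]) <= window_bp)
        if near.any():
            gi = dos[snp_i].to_numpy(dtype=float)
            for j in np.flatnonzero(near):
                gj = dos[table.at[j, "SNP"]].to_numpy(dtype=float)
                if _pairwise_r2(gi, gj) > config.r2_cutoff:
                    alive[j] = False
    return index_snps


def _oriented_imputed(
    genotypes: GenotypeMatrix, stats_table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Effect-allele-oriented, mean-imputed dosage block for the SNPs in
    ``stats_table`` (panel order follows the table). SNPs whose alleles do
    not match the panel in either orientation are dropped with a warning.
    Returns (dosage matrix, betas, snp ids)."""
    meta = genotypes.snps
    freq = genotypes.effect_allele_freq()
    cols, betas = [], []
    block = np.empty((genotypes.n_samples, len(stats_table)))
    k = 0
    for row in stats_table.itertuples():
        m = meta.loc[row.SNP]
        g = genotypes.dosages[row.SNP].to_numpy(dtype=float)
        if row.EA == m["ea"] and row.OA == m["oa"]:
            pass
        elif row.EA == m["oa"] and row.OA == m["ea"]:
            g = 2.0 - g
        else:
            warnings.warn(f"allele mismatch at {row.SNP}; SNP skipped")
            continue
        ea_freq = freq[row.SNP] if row.EA == m["ea"] else 1.0 - freq[row.SNP]
        g = np.where(np.isnan(g), 2.0 * ea_freq, g)
        block[:, k] = g
        cols.append(row.SNP)
        betas.append(row.BETA)
        k += 1
    return block[:, :k], np.asarray(betas, dtype=float), cols


def score(
    genotypes: GenotypeMatrix,
    stats_in: SummaryStats,
    snps: list[str],
    p_threshold: float,
    average: bool = True,
) -> tuple[pd.Series, int]:
    """PRS at threshold ``p_threshold`` over a clumped SNP list.

    score_i = sum_{j: p_j < P_T} beta_j G_ij / m (m = SNPs entering the sum)
    with effect-allele orientation and mean imputation of missing calls.
    """
    table = stats_in.table.set_index("SNP").loc[list(snps)].reset_index()
    table = table[table["P"] < p_threshold]
    if table.empty:
        raise ValueError("empty score: no SNPs pass the threshold")
    block, betas, used = _oriented_imputed(genotypes, table)
    if not used:
        raise ValueError("empty score: no SNPs with matching alleles")
    vals = block @ betas
    if average:
        vals = vals / len(used)
    return pd.Series(vals, index=genotypes.dosages.index, name="prs"), len(used)


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Pearson correlation of x and y after residualizing both on
    [intercept | covariates]; two-sided p with df = n - 2 - k."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    X, names = design_matrix(n, covariates)
    k = X.shape[1] - 1
    if n <= k + 2:
        raise ValueError("too few observations for partial correlation")
    rx = residualize_on(x, X)
    ry = residualize_on(y, X)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("zero-variance residuals")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_clip = min(max(r, -0.9999999999), 0.9999999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def threshold_scan(
    genotypes: GenotypeMatrix,
    stats_in: SummaryStats,
    clumped_snps: list[str],
    grid: ThresholdGrid | None = None,
    phenotype=None,
    covariates=None,
    top_k: int = 10,
    rank_absolute: bool = True,
    average: bool = True,
) -> PRSResult:
    """Score every P_T on the grid, rank thresholds by the partial
    correlation of the score with the phenotype, and z-score the winner.

    Thresholds admitting zero SNPs are recorded with n_snps_used = 0 and NaN
    correlation and are excluded from the ranking. Ranking uses |r| by
    default (``rank_absolute=False`` ranks by signed r).
    """
    grid = grid or ThresholdGrid()
    phen = np.asarray(phenotype, dtype=float)

    table = stats_in.table.set_index("SNP").loc[list(clumped_snps)].reset_index()
    order = np.argsort(table["P"].to_numpy(), kind="mergesort")
    table = table.iloc[order].reset_index(drop=True)
    block, betas, used_snps = _oriented_imputed(genotypes, table)
    pvals = table.set_index("SNP").loc[used_snps, "P"].to_numpy()

    contrib = block * betas[None, :]
    cum = np.cumsum(contrib, axis=1)

    rows, score_cols = [], {}
    for pt in grid.p_thresholds:
        m = int(np.searchsorted(pvals, pt, side="left"))  # p_j < P_T strict
        if m == 0:
            rows.append((pt, 0, np.nan, np.nan))
            continue
        s = cum[:, m - 1] / m if average else cum[:, m - 1]
        r, p = partial_correlation(s, phen, covariates)
        rows.append((pt, m, r, p))
        score_cols[pt] = s

    per_threshold = pd.DataFrame(
        rows, columns=["p_threshold", "n_snps_used", "partial_r", "p"]
    )
    valid = per_threshold.dropna(subset=["partial_r"])
    if valid.empty:
        raise ValueError("no threshold admitted any SNP")
    key = valid["partial_r"].abs() if rank_absolute else valid["partial_r"]
    ranked = valid.loc[key.sort_values(ascending=False, kind="mergesort").index]
    selected = ranked["p_threshold"].head(top_k).tolist()
    optimal = float(selected[0])

    opt = score_cols[optimal]
    z = (opt - opt.mean()) / opt.std(ddof=0)
    scores = pd.DataFrame(score_cols, index=genotypes.dosages.index)
    return PRSResult(
        scores=scores,
        per_threshold=per_threshold,
        selected_thresholds=[float(t) for t in selected],
        optimal_threshold=optimal,
        zscored_optimal=pd.Series(z, index=genotypes.dosages.index, name="prs_z"),
    )
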