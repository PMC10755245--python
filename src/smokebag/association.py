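"""Covariate-adjusted association models, group contrasts and scans.

``glm_association`` fits the Table-1-style models: ordinary least squares
for continuous outcomes (BAG, tGMV, pack-years, quit duration) and logistic
regression for binary smoking status, always reporting the predictor's
coefficient, SE and two-sided p. Group contrasts use the Welch t-test with
classical pooled-SD Cohen's d. The region-wise scan reports one partial
correlation per region with Benjamini-Hochberg q-values, and the GWAS scan
runs per-SNP additive-dosage regressions with the Bonferroni genome-wide
(0.05/m) and suggestive (1/m) thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._utils import as_2d, collinear_columns, design_matrix, residualize_on
from .containers import GenotypeMatrix
from .prs import partial_correlation


@dataclass
class AssociationRow:
    outcome: str
    beta: float
    se: float
    p: float
    model: str
    n: int


@dataclass
class EffectSize:
    cohens_d: float
    t: float
    p: float
    n1: int
    n2: int


def glm_association(
    outcome,
    predictor,
    covariates=None,
    outcome_name: str = "outcome",
    model_tag: str = "model1",
    family: str = "gaussian",
) -> AssociationRow:
    """Covariate-adjusted association of one predictor with one outcome.

    ``family="gaussian"`` is OLS with an intercept; ``family="binomial"``
    fits a logistic regression for 0/1 outcomes. The returned row carries
    the predictor coefficient only.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    cov, cov_names = as_2d(covariates)
    n = y.size
    if cov.size:
        X = np.column_stack([np.ones(n), x, cov])
    else:
        X = np.column_stack([np.ones(n), x])
    names = ["intercept", "predictor"] + cov_names
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"collinear design columns: {collinear_columns(X, names)}"
        )
    if family == "gaussian":
        fit = sm.OLS(y, X).fit()
    elif family == "binomial":
        fit = sm.Logit(y, X).fit(disp=0)
    else:
        raise ValueError(f"unknown family {family!r}")
    return AssociationRow(
        outcome=outcome_name,
        beta=float(fit.params[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        model=model_tag,
        n=n,
    )


def two_sample_comparison(group1, group2) -> EffectSize:
    """Welch t-test p with classical pooled-SD Cohen's d (group1 - group2)."""
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    s1, s2 = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * s1 + (b.size - 1) * s2) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return EffectSize(
        cohens_d=float((a.mean() - b.mean()) / pooled),
        t=float(t),
        p=float(p),
        n1=a.size,
        n2=b.size,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def regionwise_scan(
    prs, region_volumes: pd.DataFrame, covariates=None, alpha: float = 0.05
) -> pd.DataFrame:
    """One covariate-adjusted partial correlation of the PRS per region.

    Constant regions are reported as NA and excluded from the FDR
    adjustment. Returns columns region, partial_r, p, q, significant.
    """
    prs = np.asarray(prs, dtype=float)
    rows = []
    for col in region_volumes.columns:
        v = region_volumes[col].to_numpy(dtype=float)
        if np.std(v) == 0:
            rows.append((col, np.nan, np.nan))
            continue
        r, p = partial_correlation(prs, v, covariates)
        rows.append((col, r, p))
    out = pd.DataFrame(rows, columns=["region", "partial_r", "p"])
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["significant"] = out["q"] < alpha
    return out


@dataclass
class GwasResult:
    table: pd.DataFrame  # SNP, CHR, POS, BETA, SE, P (NaN for monomorphic)
    m: int
    genomewide_threshold: float
    suggestive_threshold: float
    n_genomewide: int
    n_suggestive: int


def gwas_scan(
    genotypes: GenotypeMatrix, phenotype, covariates=None, family: str = "gaussian"
) -> GwasResult:
    """Per-SNP additive-dosage association scan with Bonferroni thresholds.

    Missing dosages are mean-imputed per SNP. The linear family uses the
    Frisch-Waugh-Lovell shortcut (phenotype and each dosage residualized on
    the covariates once), which reproduces full-OLS estimates, SEs and
    p-values exactly with df = n - k - 2. Thresholds: genome-wide 0.05/m,
    suggestive 1/m, m = SNPs actually tested.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    X, _ = design_matrix(n, covariates)
    k = X.shape[1] - 1

    dos = genotypes.dosages.to_numpy(dtype=float)
    col_mean = np.nanmean(dos, axis=0)
    G = np.where(np.isnan(dos), col_mean[None, :], dos)
    poly = G.std(axis=0) > 0

    snps = genotypes.snps
    table = pd.DataFrame(
        {
            "SNP": snps.index,
            "CHR": snps["chr"].to_numpy(),
            "POS": snps["pos"].to_numpy(),
            "BETA": np.nan,
            "SE": np.nan,
            "P": np.nan,
        }
    )
    if family == "gaussian":
        ry = residualize_on(y, X)
        rg = residualize_on(G[:, poly], X)
        ss_g = (rg**2).sum(axis=0)
        beta = (rg * ry[:, None]).sum(axis=0) / ss_g
        resid = ry[:, None] - rg * beta[None, :]
        df = n - k - 2
        sigma2 = (resid**2).sum(axis=0) / df
        se = np.sqrt(sigma2 / ss_g)
        pvals = 2.0 * stats.t.sf(np.abs(beta / se), df)
        table.loc[poly, "BETA"] = beta
        table.loc[poly, "SE"] = se
        table.loc[poly, "P"] = pvals
    elif family == "binomial":
        for j in np.flatnonzero(poly):
            Xj = np.column_stack([X[:, :1], G[:, j], X[:, 1:]])
            fit = sm.Logit(y, Xj).fit(disp=0)
            table.loc[j, ["BETA", "SE", "P"]] = (
                fit.params[1],
                fit.bse[1],
                fit.pvalues[1],
            )
    else:
        raise ValueError(f"unknown family {family!r}")

    m = int(table["P"].notna().sum())
    if m == 0:
        raise ValueError("no testable (polymorphic) SNPs")
    gw = 0.05 / m
    sugg = 1.0 / m
    return GwasResult(
        table=table,
        m=m,
        genomewide_threshold=gw,
        suggestive_threshold=sugg,
        n_genomewide=int((table["P"] < gw).sum()),
        n_suggestive=int((table["P"] < sugg).sum()),
    )


def gwas_thresholds(m: int) -> tuple[float, float]:
    """Bonferroni genome-wide (0.05/m) and suggestive (1/m) thresholds."""
    if m <= 0:
        raise ValueError("m must be positive")
    return 0.05 / m, 1.0 / m
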