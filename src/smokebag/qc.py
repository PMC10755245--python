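"""SNP- and sample-level genotype quality control.

Filters follow standard array-QC practice: samples with excessive
missingness are dropped first, then SNPs failing minor-allele-frequency,
call-rate or Hardy-Weinberg-equilibrium cuts (strict inequalities) on the
retained samples. The HWE test is the Pearson chi-square goodness-of-fit
with 1 df against expected proportions at the sample allele frequency
(no continuity correction; monomorphic SNPs return p = 1 by convention).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix


@dataclass
class QCThresholds:
    maf_min: float = 0.01
    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-5
    sample_missing_max: float = 0.05

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    n_samples_in: int
    n_samples_out: int
    n_snps_in: int
    n_snps_out: int
    n_samples_excluded: int
    # first-failure attribution (maf checked first, then call rate, then HWE)
    excluded_by: dict = field(default_factory=dict)
    n_snps_any_failure: int = 0
    snp_table: pd.DataFrame | None = None

    def to_json(self, path) -> None:
        payload = {k: v for k, v in asdict(self).items() if k != "snp_table"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_tsv(self, path) -> None:
        if self.snp_table is not None:
            self.snp_table.to_csv(path, sep="\t", index_label="SNP")


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Hardy-Weinberg chi-square p-value from the three genotype counts.

    Expected counts come from the sample allele frequency; the statistic is
    referred to chi-square with 1 df. A monomorphic SNP returns p = 1.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n == 0:
        raise ValueError("all genotype counts are zero")
    p = (2 * counts[0] + counts[1]) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    q = 1.0 - p
    expected = n * np.array([p * p, 2 * p * q, q * q])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def hwe_test_vector(counts: pd.DataFrame) -> pd.Series:
    """Vectorized HWE p over a (n0, n1, n2) count table. Note: n2 counts the
    effect-allele homozygote; the test is symmetric in the labeling."""
    return pd.Series(
        [hwe_test(int(r.n2), int(r.n1), int(r.n0)) for r in counts.itertuples()],
        index=counts.index,
        name="hwe_p",
    )


def qc_filter(
    genotypes: GenotypeMatrix, thresholds: QCThresholds | None = None
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample-then-SNP QC; returns the filtered matrix and a report.

    Exclusion rules (all strict): sample missingness > sample_missing_max;
    then, on retained samples, MAF < maf_min, call rate < call_rate_min,
    HWE p < hwe_p_min. A SNP failing several filters is attributed to the
    first in that order; an any-failure total is also reported.
    """
    thresholds = thresholds or QCThresholds()
    if genotypes.n_samples == 0 or genotypes.n_snps == 0:
        raise ValueError("empty genotype matrix")

    miss = genotypes.sample_missing_rate()
    keep_samples = miss[miss <= thresholds.sample_missing_max].index
    n_samples_excluded = genotypes.n_samples - len(keep_samples)
    if len(keep_samples) == 0:
        raise ValueError("empty after QC: all samples removed")
    g = genotypes.subset(samples=keep_samples)

    maf = g.maf()
    call = g.call_rate()
    hwe = hwe_test_vector(g.genotype_counts())
    fail_maf = maf < thresholds.maf_min
    fail_call = call < thresholds.call_rate_min
    fail_hwe = hwe < thresholds.hwe_p_min
    fail_any = fail_maf | fail_call | fail_hwe

    first = pd.Series("pass", index=g.dosages.columns, dtype=object)
    first[fail_hwe] = "hwe"
    first[fail_call] = "call_rate"
    first[fail_maf] = "maf"

    snp_table = pd.DataFrame(
        {
            "maf": maf,
            "call_rate": call,
            "hwe_p": hwe,
            "pass": ~fail_any,
            "first_failure": first.where(fail_any, other=""),
        }
    )
    keep_snps = snp_table.index[snp_table["pass"]]
    if len(keep_snps) == 0:
        raise ValueError("empty after QC: all SNPs removed")

    report = QCReport(
        n_samples_in=genotypes.n_samples,
        n_samples_out=len(keep_samples),
        n_snps_in=genotypes.n_snps,
        n_snps_out=len(keep_snps),
        n_samples_excluded=n_samples_excluded,
        excluded_by={
            "maf": int(fail_maf.sum()),
            "call_rate": int((fail_call & ~fail_maf).sum()),
            "hwe": int((fail_hwe & ~fail_call & ~fail_maf).sum()),
        },
        n_snps_any_failure=int(fail_any.sum()),
        snp_table=snp_table,
    )
    return g.subset(snps=keep_snps), report
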