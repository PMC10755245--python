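"""Core in-memory containers shared across the pipeline.

Genotypes are held as an effect-allele dosage matrix (samples x SNPs,
values 0/1/2 with NaN for missing calls) plus a per-SNP metadata table.
Discovery GWAS weights travel as a plain summary-statistics table and the
per-subject phenotype/covariate/volume data as a cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SUMSTATS_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "P"]


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with per-SNP metadata.

    Parameters
    ----------
    dosages : DataFrame
        Rows indexed by subject id, columns by SNP id; float values in
        {0, 1, 2} with NaN marking missing calls. Dosages count copies of
        the allele recorded in ``snps["ea"]``.
    snps : DataFrame
        Indexed by SNP id with columns ``chr`` (str), ``pos`` (1-based int),
        ``ea`` and ``oa`` (allele strings).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            raise ValueError("dosage columns and SNP metadata index differ")
        vals = self.dosages.to_numpy(dtype=float)
        bad = ~(np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0)))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def effect_allele_freq(self) -> pd.Series:
        """Per-SNP frequency of the counted (effect) allele, non-missing calls only."""
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def maf(self) -> pd.Series:
        p = self.effect_allele_freq()
        return np.minimum(p, 1.0 - p)

    def call_rate(self) -> pd.Series:
        return self.dosages.notna().mean(axis=0)

    def sample_missing_rate(self) -> pd.Series:
        return self.dosages.isna().mean(axis=1)

    def genotype_counts(self) -> pd.DataFrame:
        """Per-SNP counts of the three genotype classes (columns n0, n1, n2)."""
        vals = self.dosages.to_numpy(dtype=float)
        out = pd.DataFrame(
            {
                "n0": np.nansum(vals == 0.0, axis=0),
                "n1": np.nansum(vals == 1.0, axis=0),
                "n2": np.nansum(vals == 2.0, axis=0),
            },
            index=self.dosages.columns,
        )
        return out.astype(int)

    def subset(self, samples=None, snps=None) -> "GenotypeMatrix":
        dos = self.dosages
        if samples is not None:
            dos = dos.loc[samples]
        if snps is not None:
            dos = dos[list(snps)]
        return GenotypeMatrix(dos, self.snps.loc[dos.columns])

    # --- I/O -------------------------------------------------------------
    def to_tsv(self, dosage_path, snp_path=None) -> None:
        self.dosages.to_csv(dosage_path, sep="\t", na_rep="NA", index_label="subject")
        if snp_path is not None:
            self.snps.to_csv(snp_path, sep="\t", index_label="SNP")

    @classmethod
    def from_tsv(cls, dosage_path, snp_path) -> "GenotypeMatrix":
        dos = pd.read_csv(dosage_path, sep="\t", index_col="subject", na_values="NA")
        snps = pd.read_csv(snp_path, sep="\t", index_col="SNP", dtype={"chr": str})
        return cls(dos, snps.loc[dos.columns])

    def to_vcf(self, path) -> None:
        """Write a minimal unphased-GT VCF (one line per SNP, dosage -> GT)."""
        code = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        samples = list(self.dosages.index.astype(str))
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
            fh.write("\t".join(samples) + "\n")
            for snp, meta in self.snps.iterrows():
                gts = [
                    code.get(v, "./.")
                    for v in self.dosages[snp].to_numpy(dtype=float)
                ]
                fh.write(
                    f"{meta['chr']}\t{int(meta['pos'])}\t{snp}\t{meta['oa']}"
                    f"\t{meta['ea']}\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
                )


@dataclass
class SummaryStats:
    """Discovery-GWAS summary statistics: one row per SNP.

    ``table`` has columns SNP, CHR, POS, EA, OA, BETA, P; BETA is the
    per-effect-allele additive effect and P its two-sided Wald p-value.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMSTATS_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary stats missing columns: {missing}")
        if self.table["SNP"].duplicated().any():
            raise ValueError("duplicate SNP ids in summary stats")
        p = self.table["P"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p-values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    def to_tsv(self, path) -> None:
        self.table[SUMSTATS_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SummaryStats":
        return cls(pd.read_csv(path, sep="\t", dtype={"CHR": str}))


@dataclass
class CohortTable:
    """Per-subject phenotypes, covariates and regional gray-matter volumes.

    Region columns follow the naming ``region_####`` (mm^3); ``tgmv`` is
    their exact sum and ``tiv`` the total intracranial volume covariate.
    """

    table: pd.DataFrame
    region_prefix: str = "region_"

    @property
    def region_columns(self) -> list[str]:
        return [c for c in self.table.columns if c.startswith(self.region_prefix)]

    @property
    def n_regions(self) -> int:
        return len(self.region_columns)

    def regions(self) -> pd.DataFrame:
        return self.table[self.region_columns]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass
class SyntheticCohort:
    """Bundle produced by the cohort simulator: genotypes, the generative
    per-SNP effects, noisy discovery summary statistics and the cohort table."""

    genotypes: GenotypeMatrix
    true_effects: pd.Series
    summary_stats: SummaryStats
    cohort: CohortTable
    config: "object" = field(default=None, repr=False)
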