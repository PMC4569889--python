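"""Biallelic strain genotype matrices for inbred panels.

Strains of a selfing species are effectively homozygous, so genotypes are
haploid 0/1 codes (reference / alternative allele); missing calls are NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "read_genotype_tsv", "read_genotype_vcf", "write_genotype_tsv", "write_genotype_vcf"]


@dataclass
class GenotypeMatrix:
    """Strains x SNPs matrix of haploid 0/1 genotype codes.

    Parameters
    ----------
    strains : list of str
        Strain identifiers (rows).
    snp_ids : list of str
        SNP identifiers (columns).
    chrom : ndarray of str
        Chromosome label per SNP.
    pos : ndarray of int
        1-based position per SNP, non-decreasing within chromosome.
    values : ndarray, shape (n_strains, n_snps)
        Float matrix over {0.0, 1.0, nan}.
    """

    strains: list
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=int)
        n, p = self.values.shape
        if n != len(self.strains) or p != len(self.snp_ids):
            raise ValueError("genotype matrix dimensions do not match strain/SNP ids")
        if len(self.chrom) != p or len(self.pos) != p:
            raise ValueError("chrom/pos metadata length does not match SNP count")
        obs = self.values[~np.isnan(self.values)]
        if obs.size and not np.isin(obs, [0.0, 1.0]).all():
            raise ValueError("genotype codes must be 0, 1 or missing")
        for c in pd.unique(self.chrom):
            p_c = self.pos[self.chrom == c]
            if np.any(np.diff(p_c) < 0):
                raise ValueError(f"positions must be non-decreasing within chromosome {c}")

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.snp_ids)

    def take_snps(self, index) -> "GenotypeMatrix":
        """Subset by SNP positional index, keeping metadata aligned."""
        index = np.asarray(index)
        return GenotypeMatrix(
            strains=list(self.strains),
            snp_ids=[self.snp_ids[i] for i in index],
            chrom=self.chrom[index],
            pos=self.pos[index],
            values=self.values[:, index],
        )

    def take_strains(self, keep) -> "GenotypeMatrix":
        """Subset to the given strain ids (order preserved as given)."""
        lookup = {s: i for i, s in enumerate(self.strains)}
        idx = [lookup[s] for s in keep]
        return GenotypeMatrix(
            strains=list(keep),
            snp_ids=list(self.snp_ids),
            chrom=self.chrom,
            pos=self.pos,
            values=self.values[idx],
        )

    def minor_allele_counts(self) -> np.ndarray:
        """Per-SNP minor allele count over non-missing strains."""
        alt = np.nansum(self.values, axis=0)
        n_obs = np.sum(~np.isnan(self.values), axis=0)
        return np.minimum(alt, n_obs - alt).astype(int)


def read_genotype_tsv(path) -> GenotypeMatrix:
    """Read the TSV dialect: columns snp, chrom, pos, then one column per strain."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta = df[["snp", "chrom", "pos"]]
    strain_cols = [c for c in df.columns if c not in ("snp", "chrom", "pos")]
    values = df[strain_cols].to_numpy(dtype=float).T
    return GenotypeMatrix(
        strains=strain_cols,
        snp_ids=meta["snp"].tolist(),
        chrom=meta["chrom"].to_numpy(),
        pos=meta["pos"].to_numpy(),
        values=values,
    )


def write_genotype_tsv(g: GenotypeMatrix, path) -> None:
    df = pd.DataFrame({"snp": g.snp_ids, "chrom": g.chrom, "pos": g.pos})
    vals = g.values.T
    for j, s in enumerate(g.strains):
        col = pd.array(vals[:, j], dtype="Int64") if not np.isnan(vals[:, j]).any() else vals[:, j]
        df[s] = col
    df.to_csv(path, sep="\t", index=False)


def write_genotype_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal VCF with haploid GT calls (REF=A, ALT=T placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(g.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.strains) + "\n")
        for j, snp in enumerate(g.snp_ids):
            calls = []
            for v in g.values[:, j]:
                calls.append("." if np.isnan(v) else str(int(v)))
            fh.write(f"{g.chrom[j]}\t{g.pos[j]}\t{snp}\tA\tT\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read genotypes from VCF via cyvcf2; haploid or homozygous-diploid GT accepted.

    Heterozygous diploid calls (impossible in fully inbred lines) are treated as
    missing.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    snp_ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        gts = var.genotype.array()[:, :-1]  # drop phase column
        row = np.full(len(strains), np.nan)
        for i in range(len(strains)):
            alleles = [a for a in gts[i] if a >= 0]
            if not alleles:
                continue
            if len(set(alleles)) == 1:
                row[i] = float(alleles[0] > 0)
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        rows.append(row)
    return GenotypeMatrix(
        strains=strains,
        snp_ids=snp_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=int),
        values=np.array(rows).T,
    )
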