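"""Marker filtering, multiple-testing structure, LD blocks and imputation.

In a small inbred panel many SNPs share the exact same genotype vector and so
carry the same association statistic; Bonferroni correction over the number
of *unique genotype classes* (rather than raw SNPs) is the appropriate
multiplicity adjustment. Haplotype blocks group SNPs in high linkage
disequilibrium (pairwise R^2 above a threshold, single linkage) into a single
association signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import GenotypeMatrix

__all__ = [
    "HaplotypeBlock",
    "ImputationMap",
    "filter_mac",
    "unique_genotype_classes",
    "bonferroni_threshold",
    "ld_r2",
    "haplotype_blocks",
    "co_association_map",
    "impute_by_marker_identity",
]


@dataclass
class HaplotypeBlock:
    members: list
    chrom: str
    start: int
    end: int

    def __len__(self):
        return len(self.members)


@dataclass
class ImputationMap:
    """Zero-mismatch proxy candidates for an ungenotyped target strain."""

    target: str
    candidates: list  # (reference strain, n matching markers)
    mismatch_counts: dict  # reference strain -> (matches, mismatches)


def filter_mac(genotypes: GenotypeMatrix, min_count: int = 6):
    """Drop SNPs with minor allele count (over non-missing strains) below min_count.

    Returns (filtered GenotypeMatrix, removal report DataFrame).
    """
    mac = genotypes.minor_allele_counts()
    keep = mac >= min_count
    if not keep.any():
        raise ValueError("MAC filter removed every SNP")
    report = pd.DataFrame({"snp": genotypes.snp_ids, "mac": mac, "kept": keep})
    return genotypes.take_snps(np.flatnonzero(keep)), report


def _column_key(col: np.ndarray) -> tuple:
    return tuple("." if np.isnan(v) else int(v) for v in col)


def _flip_key(key: tuple) -> tuple:
    return tuple("." if v == "." else 1 - v for v in key)


def unique_genotype_classes(genotypes: GenotypeMatrix, collapse_flips: bool = False):
    """Group SNP columns by exact genotype-vector identity.

    Missing calls are a distinct symbol. With ``collapse_flips`` a column and
    its allele-complement fall in one class (they yield statistically
    equivalent association tests). Returns (n_classes, {snp_id: class_index}).
    """
    class_of: dict[tuple, int] = {}
    mapping = {}
    for j, snp in enumerate(genotypes.snp_ids):
        key = _column_key(genotypes.values[:, j])
        if key not in class_of:
            if collapse_flips and _flip_key(key) in class_of:
                class_of[key] = class_of[_flip_key(key)]
            else:
                class_of[key] = len(set(class_of.values())) if class_of else 0
        mapping[snp] = class_of[key]
    return len(set(mapping.values())), mapping


def bonferroni_threshold(alpha: float, n_classes: int) -> float:
    """Per-test significance threshold alpha / n_classes."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return alpha / n_classes


def ld_r2(snp_a, snp_b) -> float:
    """Squared Pearson correlation of two 0/1 genotype vectors.

    Computed over pairwise-complete strains; raises if fewer than two remain
    and returns NaN (flagged undefined) if either SNP is monomorphic on the
    complete set.
    """
    a = np.asarray(snp_a, dtype=float)
    b = np.asarray(snp_b, dtype=float)
    ok = ~np.isnan(a) & ~np.isnan(b)
    if ok.sum() < 2:
        raise ValueError("need >= 2 pairwise-complete strains")
    a, b = a[ok], b[ok]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def haplotype_blocks(genotypes: GenotypeMatrix, r2_threshold: float = 0.9, within_chromosome: bool = True, max_missing: float = 0.2):
    """Single-linkage LD blocks: connected components of the R^2 > threshold graph.

    SNPs with more than ``max_missing`` missingness are excluded from
    blocking. By default SNP pairs are only joined within a chromosome; set
    ``within_chromosome=False`` to allow genome-wide grouping (long-range LD
    is real in selfing species).
    """
    miss = np.mean(np.isnan(genotypes.values), axis=0)
    usable = np.flatnonzero(miss <= max_missing)
    g = genotypes.take_snps(usable)
    p = g.n_snps
    rows, cols = [], []
    for i in range(p):
        for j in range(i + 1, p):
            if within_chromosome and g.chrom[i] != g.chrom[j]:
                continue
            r2 = ld_r2(g.values[:, i], g.values[:, j])
            if np.isfinite(r2) and r2 > r2_threshold:
                rows.append(i)
                cols.append(j)
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(p, p))
    n_comp, labels = connected_components(adj, directed=False)
    blocks = []
    for c in range(n_comp):
        idx = np.flatnonzero(labels == c)
        chroms = set(g.chrom[idx])
        blocks.append(
            HaplotypeBlock(
                members=[g.snp_ids[i] for i in idx],
                chrom=g.chrom[idx[0]] if len(chroms) == 1 else "multiple",
                start=int(g.pos[idx].min()),
                end=int(g.pos[idx].max()),
            )
        )
    blocks.sort(key=lambda b: (str(b.chrom), b.start))
    return blocks


def co_association_map(associations: dict, p_threshold: float, blocks=None) -> dict:
    """SNPs (or blocks) significantly associated with more than one phenotype.

    ``associations`` maps targeted gene -> association DataFrame (columns snp,
    p). Returns {snp_or_block_key: sorted gene list} keeping only entries hit
    by >= 2 genes. If ``blocks`` (list of HaplotypeBlock) is given, hits are
    aggregated per block.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    snp_to_block = {}
    if blocks is not None:
        for bi, b in enumerate(blocks):
            for s in b.members:
                snp_to_block[s] = f"block{bi + 1}({b.chrom}:{b.start}-{b.end})"
    hits: dict[str, set] = {}
    for gene, table in associations.items():
        sig = table.loc[table["p"] < p_threshold, "snp"]
        for snp in sig:
            key = snp_to_block.get(snp, snp) if blocks is not None else snp
            hits.setdefault(key, set()).add(gene)
    return {k: sorted(v) for k, v in hits.items() if len(v) >= 2}


def impute_by_marker_identity(target_markers: pd.Series, reference_panel: pd.DataFrame) -> ImputationMap:
    """Find reference strains identical to the target at its assayed markers.

    ``target_markers`` is a Series of 0/1 calls indexed by marker id for one
    ungenotyped strain; ``reference_panel`` is a strains x SNPs DataFrame that
    must contain all of the target's markers. Candidates are reference
    strains with zero mismatches over shared observed markers — all of them
    are reported, so an ambiguous target can be run once per proxy. When no
    strain matches perfectly the candidate list is empty and the per-strain
    mismatch counts support diagnosis.
    """
    markers = [m for m in target_markers.index if not pd.isna(target_markers[m])]
    missing = set(markers) - set(reference_panel.columns)
    if missing:
        raise ValueError(f"markers absent from reference panel: {sorted(missing)[:5]}...")
    t = target_markers[markers].to_numpy(dtype=float)
    counts = {}
    candidates = []
    for strain, row in reference_panel[markers].iterrows():
        r = row.to_numpy(dtype=float)
        ok = ~np.isnan(r)
        matches = int(np.sum(t[ok] == r[ok]))
        mismatches = int(ok.sum() - matches)
        counts[strain] = (matches, mismatches)
        if mismatches == 0:
            candidates.append((strain, matches))
    name = target_markers.name if target_markers.name is not None else "target"
    return ImputationMap(target=str(name), candidates=candidates, mismatch_counts=counts)
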