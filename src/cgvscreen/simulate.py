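"""Synthetic modifier screens with a known, recoverable genetic architecture.

The generator emulates an RNAi penetrance screen in a panel of inbred strains:
each strain x targeted-gene cell is replicated in several wells, each well
holds the offspring of ~10 adults, and the dead-embryo count per well is
beta-binomial around a logit-linear predictor built from

* a per-gene baseline lethality (how lethal the knockdown is in a typical
  background),
* a strain main effect driven by planted "informational" loci (variants that
  change germline RNAi efficacy for every targeted gene),
* a strain-by-gene interaction driven by planted gene-specific modifier loci,
* nuisance terms (adults per well, date batch), and
* optional fully RNAi-resistant strains with a large negative offset.

Genotypes are haploid 0/1 (fully homozygous selfing lines) organised into LD
blocks by a copy-with-probability rule along the chromosome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .genotypes import GenotypeMatrix

__all__ = ["SimulationConfig", "TruthRecord", "simulate_genotypes", "simulate_screen", "write_counts_csv", "read_counts_csv", "write_truth_json"]


@dataclass
class SimulationConfig:
    """Study-design and architecture parameters for a simulated screen.

    Defaults mirror the screen design the package targets: 55 strains x 29
    targeted genes, each cell replicated in 8 wells, ~10 adults producing on
    average 150 offspring per well, strains assayed in three date batches, and
    two germline-RNAi-resistant strains. Effect sizes are in logit units.
    """

    n_strains: int = 55
    n_genes: int = 29
    wells_per_cell: int = 8
    offspring_per_well: float = 150.0
    n_snps: int = 1000
    n_chromosomes: int = 6
    maf_range: tuple = (0.1, 0.5)
    ld_block_size: int = 5
    ld_copy_prob: float = 0.95
    n_informational_loci: int = 10
    informational_effect_sd: float = 0.5
    per_gene_modifier_loci: int = 8
    modifier_effect_sd: float = 1.2
    baseline_lethality_per_gene: tuple = None
    adults_per_well: float = 10.0
    adults_effect: float = 0.02
    date_effects: tuple = (0.0, 0.2, -0.2)
    overdispersion_rho: float = 0.15
    n_resistant_strains: int = 2
    resistant_offset: float = -4.0
    seed: int = 0

    def __post_init__(self):
        if self.baseline_lethality_per_gene is None:
            # spread knockdown severities over a wide penetrance range
            self.baseline_lethality_per_gene = tuple(np.linspace(0.25, 0.75, self.n_genes))

    def validate(self) -> None:
        for name in ("n_strains", "n_genes", "wells_per_cell", "n_snps", "n_chromosomes", "ld_block_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_resistant_strains < 0 or self.n_resistant_strains >= self.n_strains:
            raise ValueError("n_resistant_strains must be in [0, n_strains)")
        if self.ld_block_size > self.n_snps:
            raise ValueError("ld_block_size cannot exceed n_snps")
        lo, hi = self.maf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.overdispersion_rho < 1:
            raise ValueError("overdispersion_rho must be in [0, 1)")
        if not 0 < self.ld_copy_prob <= 1:
            raise ValueError("ld_copy_prob must be in (0, 1]")
        probs = np.asarray(self.baseline_lethality_per_gene, dtype=float)
        if np.any((probs <= 0) | (probs >= 1)):
            raise ValueError("baseline lethalities must lie in (0, 1)")
        if self.offspring_per_well <= 0 or self.adults_per_well <= 0:
            raise ValueError("offspring_per_well and adults_per_well must be positive")


@dataclass
class TruthRecord:
    """Ground truth of a simulated screen, for parameter-recovery checks."""

    strains: list
    genes: list
    true_strain_effects: np.ndarray = field(repr=False)
    true_interaction_effects: pd.DataFrame = field(repr=False)  # strains x genes, logits
    informational_locus_ids: dict  # snp id -> effect size
    modifier_locus_ids: dict  # gene -> {snp id: effect size}
    baseline_logits: np.ndarray = field(repr=False)

    def to_json(self) -> str:
        d = {
            "strains": list(self.strains),
            "genes": list(self.genes),
            "true_strain_effects": list(map(float, self.true_strain_effects)),
            "true_interaction_effects": self.true_interaction_effects.to_numpy().tolist(),
            "informational_locus_ids": {k: float(v) for k, v in self.informational_locus_ids.items()},
            "modifier_locus_ids": {g: {k: float(v) for k, v in d_.items()} for g, d_ in self.modifier_locus_ids.items()},
            "baseline_logits": list(map(float, self.baseline_logits)),
        }
        return json.dumps(d, indent=1)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a strain x SNP haploid panel organised in LD blocks.

    SNPs are laid down chromosome by chromosome in blocks of
    ``ld_block_size``. The first SNP of a block is Bernoulli(maf); each
    following SNP copies its left neighbour's genotype per strain with
    probability ``ld_copy_prob`` and redraws Bernoulli(maf) otherwise, which
    yields within-block genotype correlation ~ld_copy_prob and (near)
    independence between blocks.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, p = config.n_strains, config.n_snps
    strains = [f"ST{i + 1:03d}" for i in range(n)]
    snp_ids = [f"snp{j + 1:05d}" for j in range(p)]

    per_chrom = int(np.ceil(p / config.n_chromosomes))
    chrom = np.array([f"chr{j // per_chrom + 1}" for j in range(p)], dtype=object)
    pos = np.empty(p, dtype=int)
    for c in pd.unique(chrom):
        k = int((chrom == c).sum())
        pos[chrom == c] = 1000 + 1000 * np.arange(k) + rng.integers(0, 500, size=k)
        pos[chrom == c] = np.sort(pos[chrom == c])

    values = np.empty((n, p))
    lo, hi = config.maf_range
    j = 0
    while j < p:
        block_end = min(j + config.ld_block_size, p)
        # blocks never straddle a chromosome boundary
        same_chrom = np.flatnonzero(chrom[j:block_end] == chrom[j])
        block_end = j + len(same_chrom)
        maf = rng.uniform(lo, hi)
        values[:, j] = rng.random(n) < maf
        for k in range(j + 1, block_end):
            copy = rng.random(n) < config.ld_copy_prob
            fresh = rng.random(n) < maf
            values[:, k] = np.where(copy, values[:, k - 1], fresh)
        j = block_end
    return GenotypeMatrix(strains=strains, snp_ids=snp_ids, chrom=chrom, pos=pos, values=values)


def _center(x: np.ndarray) -> np.ndarray:
    return x - x.mean()


def simulate_screen(config: SimulationConfig, genotypes: GenotypeMatrix, planted_modifiers: dict | None = None):
    """Simulate well-level dead/hatched counts on top of a genotype panel.

    Returns ``(wells, truth)`` where ``wells`` is a tidy DataFrame with one
    row per well (columns: strain, gene, plate, well_row, well_col, date,
    adults, n_dead, n_larvae) and ``truth`` is the :class:`TruthRecord`.

    ``planted_modifiers`` optionally fixes the modifier architecture for
    chosen genes: a mapping ``gene name -> {snp id: effect in logits}`` that
    replaces the random locus draw for those genes (gene names follow the
    generated ``gene01..`` scheme). Power studies use this to plant a locus
    of known effect size.

    Planted effects are mean-centered over strains so that the per-gene
    baseline lethalities retain their interpretation as the lethality of an
    average genetic background.
    """
    config.validate()
    if genotypes.n_strains != config.n_strains:
        raise ValueError("genotype panel row count must equal n_strains")
    # seed offset keeps the screen stream independent of the genotype stream
    rng = np.random.default_rng((config.seed + 1_000_003) % 2**31)
    n, G = config.n_strains, config.n_genes
    strains = list(genotypes.strains)
    genes = [f"gene{g + 1:02d}" for g in range(G)]
    X = np.nan_to_num(genotypes.values, nan=0.0)

    info_idx = rng.choice(genotypes.n_snps, size=min(config.n_informational_loci, genotypes.n_snps), replace=False)
    info_eff = rng.normal(0.0, config.informational_effect_sd, size=len(info_idx))
    strain_eff = _center(X[:, info_idx] @ info_eff) if len(info_idx) else np.zeros(n)
    if config.n_resistant_strains:
        strain_eff[-config.n_resistant_strains:] += config.resistant_offset

    inter = np.zeros((n, G))
    modifier_ids = {}
    snp_index = {s: j for j, s in enumerate(genotypes.snp_ids)}
    for g in range(G):
        if planted_modifiers is not None and genes[g] in planted_modifiers:
            planted = planted_modifiers[genes[g]]
            unknown = set(planted) - set(snp_index)
            if unknown:
                raise ValueError(f"planted modifier SNPs not in panel: {sorted(unknown)}")
            mod_idx = np.array([snp_index[s] for s in planted], dtype=int)
            mod_eff = np.array([planted[s] for s in planted], dtype=float)
        else:
            mod_idx = rng.choice(genotypes.n_snps, size=min(config.per_gene_modifier_loci, genotypes.n_snps), replace=False)
            mod_eff = rng.normal(0.0, config.modifier_effect_sd, size=len(mod_idx))
        if len(mod_idx):
            inter[:, g] = _center(X[:, mod_idx] @ mod_eff)
        modifier_ids[genes[g]] = {genotypes.snp_ids[j]: e for j, e in zip(mod_idx, mod_eff)}

    base = logit(np.asarray(config.baseline_lethality_per_gene, dtype=float)[:G])
    n_batches = len(config.date_effects)
    batch_of_strain = (np.arange(n) * n_batches) // n  # contiguous thirds by default
    rho = config.overdispersion_rho

    rows = []
    for i in range(n):
        for g in range(G):
            eta_cell = base[g] + strain_eff[i] + inter[i, g] + config.date_effects[batch_of_strain[i]]
            for w in range(config.wells_per_cell):
                adults = max(int(rng.poisson(config.adults_per_well)), 1)
                m = int(rng.poisson(config.offspring_per_well))
                p_mean = float(expit(eta_cell + config.adults_effect * (adults - config.adults_per_well)))
                if rho > 0:
                    s = (1.0 - rho) / rho
                    p_well = rng.beta(p_mean * s, (1.0 - p_mean) * s)
                else:
                    p_well = p_mean
                dead = int(rng.binomial(m, p_well)) if m > 0 else 0
                rows.append(
                    {
                        "strain": strains[i],
                        "gene": genes[g],
                        "plate": f"plate{w + 1:02d}",
                        "well_row": i % 8,
                        "well_col": g % 12,
                        "date": f"batch{batch_of_strain[i] + 1}",
                        "adults": adults,
                        "n_dead": dead,
                        "n_larvae": m - dead,
                    }
                )
    wells = pd.DataFrame(rows)
    truth = TruthRecord(
        strains=strains,
        genes=genes,
        true_strain_effects=strain_eff,
        true_interaction_effects=pd.DataFrame(inter, index=strains, columns=genes),
        informational_locus_ids={genotypes.snp_ids[j]: e for j, e in zip(info_idx, info_eff)},
        modifier_locus_ids=modifier_ids,
        baseline_logits=base,
    )
    return wells, truth


def write_counts_csv(wells: pd.DataFrame, path) -> None:
    cols = ["strain", "gene", "plate", "well_row", "well_col", "date", "adults", "n_dead", "n_larvae"]
    wells[cols].to_csv(path, index=False)


def read_counts_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"strain": str, "gene": str, "plate": str, "date": str})
    missing = {"strain", "gene", "adults", "n_dead", "n_larvae"} - set(df.columns)
    if missing:
        raise ValueError(f"count table lacks required columns: {sorted(missing)}")
    return df


def write_truth_json(truth: TruthRecord, path) -> None:
    with open(path, "w") as fh:
        fh.write(truth.to_json())
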