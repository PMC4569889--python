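"""Correlation structure, enrichment, expression comparison and sign test.

These support the interpretation of the derived strain-by-gene phenotypes:
Spearman correlations between gene perturbations (do two knockdowns share
modifiers?), a Kruskal–Wallis test of whether known-interacting gene pairs
show elevated correlation, per-gene strain ANOVAs of expression, the
expression-versus-phenotype correlation tally, and an exact two-tailed
binomial sign test on the direction counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenePairCorrelation",
    "spearman_rho",
    "gene_pair_correlation_matrix",
    "interaction_enrichment_test",
    "expression_strain_anova",
    "expression_phenotype_correlation",
    "binomial_sign_test",
]

EXACT_PERMUTATION_MAX_N = 9


@dataclass
class GenePairCorrelation:
    gene_a: str
    gene_b: str
    rho: float
    p: float
    known_interaction: bool = False


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties.

    p-value: exact permutation enumeration for n <= 9, the t approximation
    otherwise. Pairs with a missing member are dropped first; a constant
    vector yields (nan, nan) — an undefined correlation, flagged rather than
    raised.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        raise ValueError("need >= 4 pairwise-complete observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERMUTATION_MAX_N:
        sx = rx - rx.mean()
        denom = np.sqrt(np.sum(sx**2)) * np.std(ry) * np.sqrt(n)
        count = 0
        total = 0
        obs = abs(rho) - 1e-12
        for perm in permutations(ry):
            r = np.dot(sx, perm) / denom
            if abs(r) >= obs:
                count += 1
            total += 1
        return rho, count / total
    t = rho * np.sqrt((n - 2) / (1 - rho**2)) if abs(rho) < 1 else np.inf * np.sign(rho)
    return rho, float(2 * sps.t.sf(abs(t), n - 2))


def gene_pair_correlation_matrix(phenotypes: pd.DataFrame, known_pairs=None) -> list:
    """Spearman correlation for every unordered pair of gene columns.

    ``phenotypes`` is a strains x genes matrix (e.g.
    ``CGVPhenotypeMatrix.estimates``); ``known_pairs`` an optional iterable of
    (gene, gene) tuples marking pairs with known physical/genetic
    interactions.
    """
    genes = list(phenotypes.columns)
    if len(genes) < 2:
        raise ValueError("need >= 2 genes")
    known = {frozenset(p) for p in (known_pairs or [])}
    out = []
    for a, b in combinations(genes, 2):
        rho, p = spearman_rho(phenotypes[a].to_numpy(), phenotypes[b].to_numpy())
        out.append(GenePairCorrelation(a, b, rho, p, frozenset((a, b)) in known))
    return out


def interaction_enrichment_test(pairs) -> tuple[float, int, float]:
    """Kruskal–Wallis test: do known-interaction pairs have higher rho?

    Rank-based with tie correction, df = 1. Returns (H, df, p).
    """
    known = [p.rho for p in pairs if p.known_interaction and np.isfinite(p.rho)]
    other = [p.rho for p in pairs if not p.known_interaction and np.isfinite(p.rho)]
    if not known or not other:
        raise ValueError("both known-interaction and other pair groups must be non-empty")
    if np.ptp(known + other) == 0:
        return 0.0, 1, 1.0  # all ranks tied; no evidence either way
    H, p = sps.kruskal(known, other)
    return float(H), 1, float(p)


def expression_strain_anova(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene one-way fixed-effects ANOVA of expression across strains.

    ``expression`` is tidy with columns gene, strain, value (replicates as
    rows). Returns a DataFrame with gene, F, p.
    """
    rows = []
    for gene, sub in expression.groupby("gene"):
        groups = [g["value"].to_numpy(dtype=float) for _, g in sub.groupby("strain")]
        if len(groups) < 2:
            raise ValueError(f"gene {gene}: need >= 2 strains")
        if any(len(g) < 2 for g in groups):
            raise ValueError(f"gene {gene}: need >= 2 replicates per strain")
        if np.ptp(np.concatenate(groups)) == 0:
            F, p = 0.0, 1.0
        else:
            F, p = sps.f_oneway(*groups)
            if np.isnan(F):
                F, p = 0.0, 1.0
        rows.append({"gene": gene, "F": float(F), "p": float(p)})
    return pd.DataFrame(rows)


def expression_phenotype_correlation(expression_means: pd.DataFrame, phenotypes: pd.DataFrame):
    """Per-gene Spearman correlation of mean expression with strain coefficients.

    Both inputs are strains x genes tables; the correlation for each gene is
    over strains common to both. Returns (per-gene DataFrame, n_negative)
    where ``n_negative`` counts genes with rho < 0 — with coefficients
    oriented so that larger means more lethal, a negative rho is the
    "lower expression goes with a less severe knockdown phenotype" direction.
    Genes with fewer than 4 shared strains are flagged (rho NaN) and not
    tallied.
    """
    shared = [s for s in expression_means.index if s in phenotypes.index]
    rows = []
    for gene in phenotypes.columns:
        if gene not in expression_means.columns or len(shared) < 4:
            rows.append({"gene": gene, "rho": np.nan, "p": np.nan, "n_strains": len(shared)})
            continue
        rho, p = spearman_rho(expression_means.loc[shared, gene].to_numpy(), phenotypes.loc[shared, gene].to_numpy())
        rows.append({"gene": gene, "rho": rho, "p": p, "n_strains": len(shared)})
    table = pd.DataFrame(rows)
    n_negative = int((table["rho"] < 0).sum())
    return table, n_negative


def binomial_sign_test(k: int, n: int) -> float:
    """Exact two-tailed sign test p-value at null probability 1/2.

    Defined as twice the smaller tail (observed value included), capped at 1.
    """
    if n < 1 or not 0 <= k <= n:
        raise ValueError("require n >= 1 and 0 <= k <= n")
    lower = sps.binom.cdf(k, n, 0.5)
    upper = sps.binom.sf(k - 1, n, 0.5)
    return float(min(1.0, 2 * min(lower, upper)))
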