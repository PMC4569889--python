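"""EMMA-style mixed-model engine for strain-level derived phenotypes.

The model is y = Xb + u + e with u ~ N(0, Vg*K) and e ~ N(0, Ve*I), where K
is a strain kinship matrix. Writing delta = Ve/Vg, the likelihood (ML or
REML) profiles down to a one-dimensional function of delta after a single
eigendecomposition, which is maximised on a log-grid with derivative
bracketing and Brent refinement. Genomic heritability is
h2 = Vg/(Vg+Ve) = 1/(1+delta); its significance comes from phenotype
permutations, and per-SNP association uses the ML likelihood-ratio test of a
SNP fixed effect against a chi-square with one degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "VarianceComponents",
    "VarianceComponentModel",
    "compute_kinship",
    "estimate_variance_components",
    "heritability_permutation_test",
    "ml_lrt_scan",
]

LOG_DELTA_RANGE = (-10.0, 10.0)
N_GRID_INTERVALS = 100
PSD_EPSILON = 1e-6
FLAT_PROFILE_TOL = 1e-6


@dataclass
class KinshipMatrix:
    """Symmetric strains x strains identity-by-state allele-sharing matrix."""

    strains: list
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.strains)
        if self.values.shape != (n, n):
            raise ValueError("kinship dimensions do not match strain list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("kinship matrix must be symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.strains)

    def stabilized(self) -> np.ndarray:
        """PSD-stabilized copy: adds epsilon to the diagonal if needed."""
        vals = np.linalg.eigvalsh(self.values)
        K = self.values.copy()
        if vals.min() < 0:
            if vals.min() < -1e-3:
                raise ValueError("kinship matrix is far from positive semidefinite")
            K = K + PSD_EPSILON * np.eye(len(K))
        return K


@dataclass
class VarianceComponents:
    Vg: float
    Ve: float
    delta: float
    h2: float
    loglik: float
    method: str
    identifiable: bool = True


def compute_kinship(genotypes: GenotypeMatrix, method: str = "ibs") -> KinshipMatrix:
    """Allele-sharing kinship over pairwise-complete sites.

    Entry (i, j) is the fraction of SNPs, among those observed in both
    strains, at which i and j carry the same allele. ``method='centered'``
    gives the centered-covariance alternative (genotypes standardised and
    cross-multiplied), rescaled to unit diagonal mean.
    """
    G = genotypes.values
    O = (~np.isnan(G)).astype(float)
    shared = O @ O.T
    if np.any(shared == 0):
        raise ValueError("a strain pair shares no observed sites")
    if method == "ibs":
        A = np.nan_to_num(G, nan=0.0)
        B = np.nan_to_num(1.0 - G, nan=0.0)
        same = A @ A.T + B @ B.T
        K = same / shared
        np.fill_diagonal(K, 1.0)
    elif method == "centered":
        freq = np.nanmean(G, axis=0)
        Z = np.nan_to_num(G - freq, nan=0.0)
        K = (Z @ Z.T) / G.shape[1]
        K = K / np.mean(np.diag(K))
    else:
        raise ValueError("method must be 'ibs' or 'centered'")
    K = (K + K.T) / 2
    return KinshipMatrix(strains=list(genotypes.strains), values=K)


class _EmmaProfile:
    """Spectral decompositions reused across many evaluations of one (X, K).

    Holds xi (nonzero eigenvalues of S(K+I)S minus one, S the residual-maker
    of X) with their eigenvectors, and the eigenvalues of K itself for the ML
    determinant term. Solving for a new phenotype only recomputes
    eta = U' y.
    """

    def __init__(self, X: np.ndarray, K: np.ndarray):
        n, q = X.shape
        self.n, self.q = n, q
        lam, _ = np.linalg.eigh(K)
        self.lambda_K = lam
        S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
        w, V = np.linalg.eigh(S @ (K + np.eye(n)) @ S)
        order = np.argsort(w)[::-1]
        self.xi = np.maximum(w[order][: n - q] - 1.0, -1.0 + 1e-10)
        self.U = V[:, order[: n - q]]

    def etas(self, y: np.ndarray) -> np.ndarray:
        return self.U.T @ y

    def loglik(self, log_delta, etas, method: str):
        delta = np.exp(log_delta)
        e2 = etas**2
        quad = np.sum(e2 / (self.xi + delta))
        if method == "reml":
            nq = self.n - self.q
            return 0.5 * (nq * (np.log(nq / (2 * np.pi)) - 1 - np.log(quad)) - np.sum(np.log(self.xi + delta)))
        return 0.5 * (self.n * (np.log(self.n / (2 * np.pi)) - 1 - np.log(quad)) - np.sum(np.log(self.lambda_K + delta)))

    def dloglik(self, log_delta, etas, method: str):
        delta = np.exp(log_delta)
        e2 = etas**2
        quad = np.sum(e2 / (self.xi + delta))
        quad2 = np.sum(e2 / (self.xi + delta) ** 2)
        if method == "reml":
            nq = self.n - self.q
            return 0.5 * (nq * quad2 / quad - np.sum(1.0 / (self.xi + delta)))
        return 0.5 * (self.n * quad2 / quad - np.sum(1.0 / (self.lambda_K + delta)))

    def solve(self, y: np.ndarray, method: str) -> VarianceComponents:
        etas = self.etas(y)
        grid = np.linspace(*LOG_DELTA_RANGE, N_GRID_INTERVALS + 1)
        ll_grid = np.array([self.loglik(g, etas, method) for g in grid])
        d_grid = np.array([self.dloglik(g, etas, method) for g in grid])
        identifiable = (ll_grid.max() - ll_grid.min()) > FLAT_PROFILE_TOL * max(1.0, abs(ll_grid.max()))

        candidates = [grid[0], grid[-1]]
        for i in range(len(grid) - 1):
            if d_grid[i] > 0 and d_grid[i + 1] < 0:
                root = optimize.brentq(self.dloglik, grid[i], grid[i + 1], args=(etas, method), xtol=1e-10)
                candidates.append(root)
        lls = [self.loglik(c, etas, method) for c in candidates]
        best = int(np.argmax(lls))
        log_delta, ll = candidates[best], lls[best]
        delta = float(np.exp(log_delta))
        denom = self.n - self.q if method == "reml" else self.n
        Vg = float(np.sum(etas**2 / (self.xi + delta)) / denom)
        return VarianceComponents(
            Vg=Vg, Ve=Vg * delta, delta=delta, h2=1.0 / (1.0 + delta), loglik=float(ll), method=method, identifiable=bool(identifiable)
        )


def _prep(y, X, K):
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if X is None:
        X = np.ones((n, 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    Kv = K.stabilized() if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)
    if Kv.shape != (n, n):
        raise ValueError("kinship dimensions do not match phenotype length")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix X is rank deficient")
    if np.std(y) == 0:
        raise ValueError("phenotype has zero variance")
    return y, X, Kv


class VarianceComponentModel(BaseEstimator):
    """REML/ML variance components of a strain phenotype given kinship.

    Fitted attributes: ``vg_``, ``ve_``, ``delta_``, ``h2_``, ``loglik_``,
    ``identifiable_`` (False when the profile likelihood is flat in delta,
    e.g. for K = I where only Vg + Ve is identified).
    """

    def __init__(self, method: str = "reml"):
        self.method = method

    def fit(self, X, y, K=None):
        if self.method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        y, X, Kv = _prep(y, X, K)
        profile = _EmmaProfile(X, Kv)
        vc = profile.solve(y, self.method)
        self.vg_, self.ve_, self.delta_ = vc.Vg, vc.Ve, vc.delta
        self.h2_, self.loglik_, self.identifiable_ = vc.h2, vc.loglik, vc.identifiable
        self.components_ = vc
        self._profile = profile
        return self


def estimate_variance_components(y, X=None, K=None, method: str = "reml") -> VarianceComponents:
    """EMMA-style profiled variance-component estimate (see module docstring)."""
    model = VarianceComponentModel(method=method.lower())
    model.fit(X, y, K=K)
    return model.components_


def heritability_permutation_test(y, K, X=None, n_perm: int = 1000, seed: int = 0, method: str = "reml"):
    """Permutation p-value for genomic heritability.

    Permutes phenotype values over strains, re-estimates h2 each time, and
    returns (h2_obs, p) with the add-one estimator
    p = (1 + #{h2_perm >= h2_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    y, X, Kv = _prep(y, X, K)
    profile = _EmmaProfile(X, Kv)
    h2_obs = profile.solve(y, method).h2
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        h2_p = profile.solve(rng.permutation(y), method).h2
        if h2_p >= h2_obs:
            exceed += 1
    return h2_obs, (1 + exceed) / (1 + n_perm)


def ml_lrt_scan(y, X=None, K=None, genotypes: GenotypeMatrix = None, min_mac: int = 0) -> pd.DataFrame:
    """Per-SNP maximum-likelihood LRT association scan.

    For each SNP, the ML log-likelihood of the model with the SNP as an extra
    fixed effect is compared with the SNP-free model;
    LRT = 2 * (LL1 - LL0), p from chi-square(1). SNPs below ``min_mac`` are
    skipped; a monomorphic SNP reaching the scan raises (the MAC filter
    should have removed it). Missing genotype calls are mean-imputed per SNP.
    Identical genotype columns receive identical statistics.
    """
    y, X, Kv = _prep(y, X, K)
    if genotypes.n_strains != len(y):
        raise ValueError("genotype strain count does not match phenotype length")
    ll0 = _EmmaProfile(X, Kv).solve(y, "ml").loglik
    macs = genotypes.minor_allele_counts()
    cache: dict[bytes, tuple] = {}
    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        if macs[j] < min_mac:
            continue
        g = genotypes.values[:, j]
        if np.isnan(g).any():
            g = np.where(np.isnan(g), np.nanmean(g), g)
        if np.ptp(g) == 0:
            raise ValueError(f"monomorphic SNP {snp} reached the scan; apply the MAC filter first")
        key = g.tobytes()
        if key in cache:
            lrt, p = cache[key]
        else:
            X1 = np.hstack([X, g[:, None]])
            ll1 = _EmmaProfile(X1, Kv).solve(y, "ml").loglik
            lrt = max(2.0 * (ll1 - ll0), 0.0)
            p = float(stats.chi2.sf(lrt, 1))
            cache[key] = (lrt, p)
        rows.append({"snp": snp, "chrom": genotypes.chrom[j], "pos": int(genotypes.pos[j]), "lrt": lrt, "p": p, "mac": int(macs[j])})
    return pd.DataFrame(rows)
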