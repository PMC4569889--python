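"""Factorial quasi-binomial penetrance model and analysis of deviance.

The response for each well is the pair (dead embryos, hatched larvae),
modelled with a logit link:

    E(Y) = logit^-1( b0 + b_strain + b_gene + b_adults + b_date
                     + b_strain:gene + b_strain:adults + b_gene:adults )

with a quasi-binomial error structure: the binomial variance is scaled by a
free dispersion phi estimated from the Pearson chi-square of the fitted
model. Coefficients are tested against the t-distribution on the residual
degrees of freedom; terms are tested by sequential analysis-of-deviance F
ratios F = (Ddeviance/Ddf) / phi.

The strain-by-gene interaction coefficients are the screen's derived
phenotypes: gene-specific cryptic-variation effects, after the strain main
effect has absorbed non-gene-specific (RNAi-efficacy) modifier variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import stats
from scipy.special import expit, logit, xlogy
from sklearn.base import BaseEstimator

__all__ = [
    "DesignSpec",
    "GLMFit",
    "CGVPhenotypeMatrix",
    "QuasiBinomialLogit",
    "PenetranceModel",
    "fit_quasibinomial_glm",
    "sequential_anova",
    "partition_deviance",
    "extract_cgv_phenotypes",
    "introgression_test",
    "identifiable_contrast",
]

DEFAULT_TERM_ORDER = ("strain", "gene", "adults", "date", "strain:gene", "strain:adults", "gene:adults")
SEPARATION_LOGITS = 15.0  # |coef| beyond this flags (quasi-)complete separation


@dataclass
class DesignSpec:
    """How to turn a well table into a design matrix.

    term_order : tuple of term names, fitted sequentially in this order.
    coding : 'treatment' (reference-cell, the R default) or 'sum' (sum-to-zero).
    reference_strain, reference_gene : reference levels under treatment coding
        (default: alphabetically first, as R's factor handling would give).
    adults_as : 'numeric' (single-df linear covariate) or 'categorical'.
    """

    term_order: tuple = DEFAULT_TERM_ORDER
    coding: str = "treatment"
    reference_strain: str | None = None
    reference_gene: str | None = None
    adults_as: str = "numeric"

    def validate(self) -> None:
        known = {"strain", "gene", "adults", "date", "strain:gene", "strain:adults", "gene:adults"}
        bad = set(self.term_order) - known
        if bad:
            raise ValueError(f"unknown terms: {sorted(bad)}")
        if self.coding not in ("treatment", "sum"):
            raise ValueError("coding must be 'treatment' or 'sum'")
        if self.adults_as not in ("numeric", "categorical"):
            raise ValueError("adults_as must be 'numeric' or 'categorical'")


def _factor_contrasts(levels, coding, ref):
    """Contrast matrix (len(levels) x k) and the non-reference level labels."""
    levels = list(levels)
    if coding == "treatment":
        if ref is None:
            ref = levels[0]
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not present")
        others = [l for l in levels if l != ref]
        C = np.zeros((len(levels), len(others)))
        for j, l in enumerate(others):
            C[levels.index(l), j] = 1.0
        return C, others
    # sum-to-zero: drop the last level, which is coded -1 on every column
    others = levels[:-1]
    C = np.zeros((len(levels), len(others)))
    for j, l in enumerate(others):
        C[levels.index(l), j] = 1.0
    C[-1, :] = -1.0
    return C, others


class _Design:
    """Design matrix with per-term column blocks and factor metadata."""

    def __init__(self, data: pd.DataFrame, spec: DesignSpec):
        spec.validate()
        self.spec = spec
        self.strain_levels = sorted(data["strain"].astype(str).unique())
        self.gene_levels = sorted(data["gene"].astype(str).unique())
        if spec.coding == "treatment":
            self.reference_strain = spec.reference_strain or self.strain_levels[0]
            self.reference_gene = spec.reference_gene or self.gene_levels[0]
        else:
            self.reference_strain = self.reference_gene = None
        self.C_strain, self.strain_cols = _factor_contrasts(self.strain_levels, spec.coding, self.reference_strain)
        self.C_gene, self.gene_cols = _factor_contrasts(self.gene_levels, spec.coding, self.reference_gene)

        n = len(data)
        s_idx = data["strain"].astype(str).map({l: i for i, l in enumerate(self.strain_levels)}).to_numpy()
        g_idx = data["gene"].astype(str).map({l: i for i, l in enumerate(self.gene_levels)}).to_numpy()
        Xs = self.C_strain[s_idx]  # n x ks
        Xg = self.C_gene[g_idx]  # n x kg

        blocks = [np.ones((n, 1))]
        names = ["(Intercept)"]
        self.term_cols: dict[str, list[int]] = {"(Intercept)": [0]}
        col = 1

        def add(term, M, labels):
            nonlocal col
            blocks.append(M)
            names.extend(labels)
            self.term_cols[term] = list(range(col, col + M.shape[1]))
            col += M.shape[1]

        for term in spec.term_order:
            if term == "strain":
                add(term, Xs, [f"strain[{l}]" for l in self.strain_cols])
            elif term == "gene":
                add(term, Xg, [f"gene[{l}]" for l in self.gene_cols])
            elif term == "adults":
                if "adults" not in data:
                    raise ValueError("term 'adults' requested but column missing")
                a = data["adults"].to_numpy(dtype=float)
                if spec.adults_as == "numeric":
                    add(term, a[:, None], ["adults"])
                else:
                    levels = sorted(data["adults"].unique())
                    C, labels = _factor_contrasts(levels, spec.coding, levels[0] if spec.coding == "treatment" else None)
                    idx = data["adults"].map({l: i for i, l in enumerate(levels)}).to_numpy()
                    add(term, C[idx], [f"adults[{l}]" for l in labels])
            elif term == "date":
                if "date" not in data:
                    raise ValueError("term 'date' requested but column missing")
                levels = sorted(data["date"].astype(str).unique())
                C, labels = _factor_contrasts(levels, spec.coding, levels[0] if spec.coding == "treatment" else None)
                idx = data["date"].astype(str).map({l: i for i, l in enumerate(levels)}).to_numpy()
                add(term, C[idx], [f"date[{l}]" for l in labels])
            elif term == "strain:gene":
                M = np.einsum("ni,nj->nij", Xs, Xg).reshape(n, -1)
                labels = [f"strain:gene[{s}|{g}]" for s in self.strain_cols for g in self.gene_cols]
                add(term, M, labels)
            elif term == "strain:adults":
                a = data["adults"].to_numpy(dtype=float)
                add(term, Xs * a[:, None], [f"strain:adults[{l}]" for l in self.strain_cols])
            elif term == "gene:adults":
                a = data["adults"].to_numpy(dtype=float)
                add(term, Xg * a[:, None], [f"gene:adults[{l}]" for l in self.gene_cols])
        self.X = np.hstack(blocks)
        self.names = names

    def interaction_contrast(self, strain: str, gene: str) -> np.ndarray:
        """Row over the strain:gene columns giving that cell's interaction value."""
        cs = self.C_strain[self.strain_levels.index(strain)]
        cg = self.C_gene[self.gene_levels.index(gene)]
        return np.kron(cs, cg)


@dataclass
class GLMFit:
    """A fitted quasi-binomial logit model."""

    params: pd.DataFrame = field(repr=False)  # estimate, se, tvalue, pvalue, aliased, separated
    dispersion: float
    deviance: float
    null_deviance: float
    df_resid: int
    rank: int
    n_obs: int
    converged: bool
    n_iter: int
    cov: pd.DataFrame = field(repr=False)  # kept columns only, scaled by dispersion
    fitted: np.ndarray = field(repr=False, default=None)
    design: object = field(repr=False, default=None)
    n_dropped_wells: int = 0

    @property
    def coefficients(self) -> pd.Series:
        return self.params["estimate"]


class QuasiBinomialLogit(BaseEstimator):
    """IRLS engine for binomial-count regression with a free dispersion.

    The design matrix is passed in full (including the intercept column);
    exactly collinear (aliased) columns are detected by pivoted QR and
    dropped, as R's ``glm`` does. ``y`` is an (n, 2) array of
    (successes, failures) counts per observation.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y, column_names=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim != 2 or y.shape[1] != 2:
            raise ValueError("y must be an (n, 2) array of (successes, failures)")
        if np.any(y < 0):
            raise ValueError("counts must be non-negative")
        d = y[:, 0]
        m = y.sum(axis=1)
        if np.any(m == 0):
            raise ValueError("observations with zero total count must be removed before fitting")
        n, p = X.shape
        names = list(column_names) if column_names is not None else [f"x{j}" for j in range(p)]

        # aliased columns are a rank property of X alone
        _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rtol = diag[0] * max(n, p) * np.finfo(float).eps if diag.size and diag[0] > 0 else 0.0
        rank = int((diag > rtol).sum())
        kept = np.sort(piv[:rank])
        Xk = X[:, kept]

        phat = d / m
        mu = (d + 0.5) / (m + 1.0)
        dev = self._deviance(d, m, mu)
        beta = None
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = logit(mu)
            w = m * mu * (1 - mu)
            z = eta + (phat - mu) / (mu * (1 - mu))
            sw = np.sqrt(w)
            beta, *_ = np.linalg.lstsq(Xk * sw[:, None], z * sw, rcond=None)
            eta = Xk @ beta
            mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            dev_new = self._deviance(d, m, mu)
            if abs(dev_new - dev) / (abs(dev_new) + 0.1) < self.tol:
                dev = dev_new
                converged = True
                break
            dev = dev_new

        df_resid = n - rank
        pearson = float(np.sum(m * (phat - mu) ** 2 / (mu * (1 - mu))))
        dispersion = pearson / df_resid if df_resid > 0 else np.nan

        w = m * mu * (1 - mu)
        XtWX = (Xk * w[:, None]).T @ Xk
        cov_unscaled = np.linalg.pinv(XtWX)
        cov = cov_unscaled * (dispersion if np.isfinite(dispersion) else 1.0)
        se_k = np.sqrt(np.diag(cov))

        est = np.full(p, np.nan)
        se = np.full(p, np.nan)
        est[kept] = beta
        se[kept] = se_k
        with np.errstate(invalid="ignore", divide="ignore"):
            tval = est / se
            pval = 2 * stats.t.sf(np.abs(tval), df_resid) if df_resid > 0 else np.full(p, np.nan)
        aliased = np.ones(p, dtype=bool)
        aliased[kept] = False
        separated = np.abs(est) > SEPARATION_LOGITS

        mu0 = d.sum() / m.sum()
        self.params_ = pd.DataFrame(
            {"estimate": est, "se": se, "tvalue": tval, "pvalue": pval, "aliased": aliased, "separated": separated},
            index=names,
        )
        self.cov_ = pd.DataFrame(cov, index=[names[j] for j in kept], columns=[names[j] for j in kept])
        self.kept_ = kept
        self.rank_ = rank
        self.dispersion_ = dispersion
        self.deviance_ = dev
        self.null_deviance_ = self._deviance(d, m, np.full(n, mu0))
        self.df_resid_ = df_resid
        self.converged_ = converged
        self.n_iter_ = it
        self.fitted_ = mu
        return self

    @staticmethod
    def _deviance(d, m, mu):
        a = m - d
        return float(2 * np.sum(xlogy(d, d) - xlogy(d, m * mu) + xlogy(a, a) - xlogy(a, m * (1 - mu))))

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        beta = self.params_["estimate"].to_numpy(copy=True)
        beta[~np.isfinite(beta)] = 0.0
        return expit(X @ beta)

    def as_fit(self, design=None, n_obs=None, n_dropped=0) -> GLMFit:
        return GLMFit(
            params=self.params_,
            dispersion=self.dispersion_,
            deviance=self.deviance_,
            null_deviance=self.null_deviance_,
            df_resid=self.df_resid_,
            rank=self.rank_,
            n_obs=n_obs if n_obs is not None else len(self.fitted_),
            converged=self.converged_,
            n_iter=self.n_iter_,
            cov=self.cov_,
            fitted=self.fitted_,
            design=design,
            n_dropped_wells=n_dropped,
        )


@dataclass
class CGVPhenotypeMatrix:
    """Strain x gene interaction coefficients used as derived phenotypes."""

    estimates: pd.DataFrame = field(repr=False)
    se: pd.DataFrame = field(repr=False)
    pvalues: pd.DataFrame = field(repr=False)
    separated: pd.DataFrame = field(repr=False)
    coding: str = "treatment"
    reference_strain: str | None = None
    reference_gene: str | None = None
    centered: bool = False

    def to_tsv(self, path) -> None:
        self.estimates.to_csv(path, sep="\t")


class PenetranceModel(BaseEstimator):
    """Factorial penetrance model over a well-level count table.

    Parameters mirror :class:`DesignSpec`; ``fit`` takes the tidy well table
    (columns strain, gene, adults, date, n_dead, n_larvae, ...). Wells with
    zero offspring are dropped (count recorded in ``n_dropped_wells_``), and
    any genes listed in ``exclude_genes`` (e.g. an empty-vector control) are
    removed before fitting.
    """

    def __init__(
        self,
        term_order: tuple = DEFAULT_TERM_ORDER,
        coding: str = "treatment",
        reference_strain: str | None = None,
        reference_gene: str | None = None,
        adults_as: str = "numeric",
        exclude_genes: tuple = (),
        tol: float = 1e-8,
        max_iter: int = 100,
    ):
        self.term_order = term_order
        self.coding = coding
        self.reference_strain = reference_strain
        self.reference_gene = reference_gene
        self.adults_as = adults_as
        self.exclude_genes = exclude_genes
        self.tol = tol
        self.max_iter = max_iter

    def _spec(self) -> DesignSpec:
        return DesignSpec(
            term_order=tuple(self.term_order),
            coding=self.coding,
            reference_strain=self.reference_strain,
            reference_gene=self.reference_gene,
            adults_as=self.adults_as,
        )

    def _clean(self, wells: pd.DataFrame) -> tuple[pd.DataFrame, int]:
        df = wells.copy()
        if self.exclude_genes:
            df = df[~df["gene"].isin(self.exclude_genes)]
        m = df["n_dead"] + df["n_larvae"]
        dropped = int((m == 0).sum())
        df = df[m > 0].reset_index(drop=True)
        if df["strain"].nunique() < 2:
            raise ValueError("need at least 2 strains")
        if df["gene"].nunique() < 1:
            raise ValueError("need at least 1 targeted gene")
        return df, dropped

    def fit(self, wells: pd.DataFrame, y=None):
        df, dropped = self._clean(wells)
        design = _Design(df, self._spec())
        engine = QuasiBinomialLogit(tol=self.tol, max_iter=self.max_iter)
        engine.fit(design.X, df[["n_dead", "n_larvae"]].to_numpy(), column_names=design.names)
        self.design_ = design
        self.fit_ = engine.as_fit(design=design, n_obs=len(df), n_dropped=dropped)
        self.n_dropped_wells_ = dropped
        self._data = df
        return self

    def predict(self, wells: pd.DataFrame) -> np.ndarray:
        """Predicted lethality probability per well (levels must be known)."""
        design = _Design(wells, self._spec())
        beta = self.fit_.params["estimate"].reindex(design.names).to_numpy(copy=True)
        beta[~np.isfinite(beta)] = 0.0
        return expit(design.X @ beta)

    def anova(self) -> pd.DataFrame:
        """Sequential (type-I) analysis of deviance over the term order."""
        df = self._data
        y = df[["n_dead", "n_larvae"]].to_numpy()
        spec = self._spec()
        full = self.fit_
        phi = full.dispersion
        df_resid_full = full.df_resid

        rows = [{"term": "NULL", "df": np.nan, "deviance": np.nan, "resid_df": len(df) - 1, "resid_dev": full.null_deviance, "F": np.nan, "p": np.nan}]
        prev_dev, prev_rank = full.null_deviance, 1
        for k in range(1, len(spec.term_order) + 1):
            sub = DesignSpec(term_order=spec.term_order[:k], coding=spec.coding, reference_strain=spec.reference_strain, reference_gene=spec.reference_gene, adults_as=spec.adults_as)
            d = _Design(df, sub)
            eng = QuasiBinomialLogit(tol=self.tol, max_iter=self.max_iter).fit(d.X, y, column_names=d.names)
            ddf = eng.rank_ - prev_rank
            ddev = prev_dev - eng.deviance_
            if ddf > 0:
                F = (ddev / ddf) / phi
                p = stats.f.sf(F, ddf, df_resid_full)
            else:
                F, p = np.nan, np.nan
            rows.append({"term": spec.term_order[k - 1], "df": ddf, "deviance": ddev, "resid_df": len(df) - eng.rank_, "resid_dev": eng.deviance_, "F": F, "p": p})
            prev_dev, prev_rank = eng.deviance_, eng.rank_
        return pd.DataFrame(rows)

    def cgv_phenotypes(self, center: bool = False) -> CGVPhenotypeMatrix:
        return extract_cgv_phenotypes(self.fit_, center=center)


# ---------------------------------------------------------------------------
# module-level operation wrappers


def fit_quasibinomial_glm(observations: pd.DataFrame, design: DesignSpec | None = None, **kwargs) -> GLMFit:
    """Fit the factorial quasi-binomial penetrance model to a well table."""
    design = design or DesignSpec()
    model = PenetranceModel(
        term_order=design.term_order,
        coding=design.coding,
        reference_strain=design.reference_strain,
        reference_gene=design.reference_gene,
        adults_as=design.adults_as,
        **kwargs,
    )
    model.fit(observations)
    fit = model.fit_
    fit._model = model
    return fit


def sequential_anova(observations: pd.DataFrame, design: DesignSpec | None = None, **kwargs) -> pd.DataFrame:
    """Sequential analysis of deviance; F ratios use the full model's dispersion."""
    design = design or DesignSpec()
    model = PenetranceModel(
        term_order=design.term_order,
        coding=design.coding,
        reference_strain=design.reference_strain,
        reference_gene=design.reference_gene,
        adults_as=design.adults_as,
        **kwargs,
    )
    model.fit(observations)
    return model.anova()


def partition_deviance(table: pd.DataFrame, terms) -> float:
    """Percent of the total (null) deviance carried by the named terms.

    Returns 100 * sum(deviance of the named rows) / null residual deviance.
    """
    if "NULL" not in set(table["term"]):
        raise ValueError("deviance table lacks a NULL row")
    null_dev = float(table.loc[table["term"] == "NULL", "resid_dev"].iloc[0])
    terms = list(terms)
    missing = set(terms) - set(table["term"])
    if missing:
        raise ValueError(f"terms not in table: {sorted(missing)}")
    dev = float(table.loc[table["term"].isin(terms), "deviance"].sum())
    return 100.0 * dev / null_dev


def extract_cgv_phenotypes(fit: GLMFit, center: bool = False) -> CGVPhenotypeMatrix:
    """Interaction coefficients reshaped to a strain x gene phenotype matrix.

    Under treatment coding the reference strain's row and reference gene's
    column are structural zeros. Cells whose coefficients are flagged as
    separated (|estimate| > 15 logits) are marked in ``separated`` and should
    be excluded from downstream association scans.
    """
    design = fit.design
    if design is None or "strain:gene" not in design.term_cols:
        raise ValueError("fit does not carry a strain:gene interaction design")
    cols = design.term_cols["strain:gene"]
    names = [design.names[j] for j in cols]
    beta = fit.params.loc[names, "estimate"].to_numpy(copy=True)
    aliased = fit.params.loc[names, "aliased"].to_numpy()
    beta[aliased | ~np.isfinite(beta)] = 0.0
    kept_names = [nm for nm in names if nm in fit.cov.index]
    cov = fit.cov.loc[kept_names, kept_names].to_numpy()
    kept_mask = np.array([nm in fit.cov.index for nm in names])

    strains, genes = design.strain_levels, design.gene_levels
    est = np.zeros((len(strains), len(genes)))
    se = np.zeros((len(strains), len(genes)))
    for i, s in enumerate(strains):
        for g, gname in enumerate(genes):
            c = design.interaction_contrast(s, gname)
            est[i, g] = c @ beta
            ck = c[kept_mask]
            se[i, g] = np.sqrt(ck @ cov @ ck) if ck.any() else 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        tval = np.where(se > 0, est / se, np.nan)
        pval = 2 * stats.t.sf(np.abs(tval), fit.df_resid)
    separated = np.abs(est) > SEPARATION_LOGITS
    estimates = pd.DataFrame(est, index=strains, columns=genes)
    if center:
        estimates = estimates - estimates.mean(axis=0)
    return CGVPhenotypeMatrix(
        estimates=estimates,
        se=pd.DataFrame(se, index=strains, columns=genes),
        pvalues=pd.DataFrame(pval, index=strains, columns=genes),
        separated=pd.DataFrame(separated, index=strains, columns=genes),
        coding=design.spec.coding,
        reference_strain=design.reference_strain,
        reference_gene=design.reference_gene,
        centered=center,
    )


def identifiable_contrast(matrix: pd.DataFrame, coding: str = "treatment", reference_strain=None, reference_gene=None) -> pd.DataFrame:
    """The estimable contrast of a cell-effect matrix under a factor coding.

    A factorial model with strain and gene main effects can only identify the
    interaction up to row/column recoding: under treatment coding the estimand
    of cell (i, g) is M[i,g] - M[i,ref_g] - M[ref_s,g] + M[ref_s,ref_g]; under
    sum-to-zero coding it is the doubly centered matrix. Use this to compare
    estimated interaction coefficients with a simulation's true cell effects.
    """
    M = matrix.astype(float)
    if coding == "treatment":
        reference_strain = reference_strain or sorted(M.index)[0]
        reference_gene = reference_gene or sorted(M.columns)[0]
        return M - M.loc[[reference_strain]].values - M[[reference_gene]].values + M.loc[reference_strain, reference_gene]
    return M - M.mean(axis=0) - np.asarray(M.mean(axis=1))[:, None] + float(M.to_numpy().mean())


def introgression_test(plate_counts: pd.DataFrame, strain_labels=None) -> tuple[float, int, float]:
    """Quasi-binomial F-test for a strain effect on per-plate (dead, hatched) counts.

    ``plate_counts`` needs columns strain, n_dead, n_larvae (one row per
    plate). Returns (F, df, p) for the strain term, with the dispersion taken
    from the strain model's Pearson chi-square.
    """
    df = plate_counts.copy()
    if strain_labels is not None:
        df = df[df["strain"].isin(strain_labels)]
    m = df["n_dead"] + df["n_larvae"]
    df = df[m > 0].reset_index(drop=True)
    strains = sorted(df["strain"].astype(str).unique())
    if len(strains) < 2:
        raise ValueError("introgression test needs at least 2 strains")
    if (df.groupby("strain").size() < 2).any():
        raise ValueError("introgression test needs >= 2 plates per strain")
    C, others = _factor_contrasts(strains, "treatment", strains[0])
    idx = df["strain"].astype(str).map({l: i for i, l in enumerate(strains)}).to_numpy()
    X = np.hstack([np.ones((len(df), 1)), C[idx]])
    y = df[["n_dead", "n_larvae"]].to_numpy()
    eng = QuasiBinomialLogit().fit(X, y, column_names=["(Intercept)"] + [f"strain[{l}]" for l in others])
    ddf = eng.rank_ - 1
    ddev = max(eng.null_deviance_ - eng.deviance_, 0.0)
    if ddev < 1e-8 * max(1.0, eng.null_deviance_):
        F = 0.0  # no strain signal at all (e.g. identical counts everywhere)
    elif eng.dispersion_ > 0:
        F = (ddev / ddf) / eng.dispersion_
    else:
        # perfectly replicated plates (zero Pearson chi-square) with a strain
        # difference: the quasi-likelihood evidence is unbounded
        F = np.inf
    p = float(stats.f.sf(F, ddf, eng.df_resid_))
    return float(F), int(ddf), p
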