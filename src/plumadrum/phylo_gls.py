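"""Phylogenetic generalized least squares with ML-optimised Pagel's λ.

The error covariance is the Brownian-motion matrix C of shared root-to-MRCA
branch lengths, with its off-diagonal scaled by λ ∈ [0, 1].  λ is estimated
by maximising the profile log-likelihood (ML, not REML).  Also provides the
ordinary-regression body-mass residualisation, the collinearity screen, and
the log10 variable transforms used upstream of model fitting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar


def normalize_name(name: str) -> str:
    """Case-insensitive species-name key: underscores ↔ spaces collapsed."""
    return " ".join(str(name).strip().lower().replace("_", " ").split())


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree with branch lengths."""
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("tree has negative branch lengths")
    return tree


def phylo_covariance(tree: dendropy.Tree, species) -> np.ndarray:
    """Brownian-motion covariance matrix for the given species order.

    C_ij is the shared branch length from the root down to MRCA(i, j);
    C_ii is the root-to-tip depth.  Tips absent from ``species`` are
    pruned; species missing from the tree raise with their names listed.
    Matching is tolerant to case and underscore/space differences.
    """
    species = list(species)
    label_by_key = {}
    for taxon in tree.taxon_namespace:
        label_by_key.setdefault(normalize_name(taxon.label), taxon.label)
    missing = [s for s in species if normalize_name(s) not in label_by_key]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    work = tree.clone(depth=1)
    wanted = {normalize_name(s) for s in species}
    keep = [t for t in work.taxon_namespace if normalize_name(t.label) in wanted]
    if len(keep) < len(work.taxon_namespace):
        work.retain_taxa(keep)
    # node depths from the root
    depth: dict = {}
    for node in work.preorder_node_iter():
        if node.parent_node is None:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
    leaf_by_key = {
        normalize_name(leaf.taxon.label): leaf for leaf in work.leaf_node_iter()
    }
    leaves = [leaf_by_key[normalize_name(s)] for s in species]
    n = len(species)
    c = np.zeros((n, n))
    # accumulate ancestor sets once; n is small (hundreds at most)
    anc = {}
    for leaf in leaves:
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        anc[leaf] = chain
    for i in range(n):
        c[i, i] = depth[leaves[i]]
        anc_i = set(map(id, anc[leaves[i]]))
        for j in range(i + 1, n):
            mrca = next(nd for nd in anc[leaves[j]] if id(nd) in anc_i)
            c[i, j] = c[j, i] = depth[mrca]
    return c


def lambda_transform(c: np.ndarray, lam: float) -> np.ndarray:
    """Scale the off-diagonal of C by λ ∈ [0, 1]; diagonal unchanged."""
    if not (0.0 <= lam <= 1.0):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")
    c = np.asarray(c, dtype=float)
    out = c * lam
    np.fill_diagonal(out, np.diag(c))
    return out


@dataclass
class GLSResult:
    beta: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    sigma2_ml: float
    loglik: float
    residuals: np.ndarray
    rss_whitened: float
    df_resid: int


def gls_fit(x: np.ndarray, y: np.ndarray, v: np.ndarray) -> GLSResult:
    """Generalized least squares with known error covariance ``v``.

    β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y; σ̂²_ML = eᵀV⁻¹e/n; standard errors use the
    n/(n−p) ML→unbiased correction; t statistics are two-sided on n − p
    degrees of freedom.  logLik = −½[n·log(2πσ̂²) + log|V| + n].
    V = I reduces exactly to OLS.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    v = np.asarray(v, dtype=float)
    n, p = x.shape
    if n != len(y) or v.shape != (n, n):
        raise ValueError("shape mismatch between X, y and V")
    if n <= p:
        raise ValueError("need more observations than parameters")
    try:
        cho = linalg.cho_factor(v, lower=True)
    except linalg.LinAlgError as exc:
        raise ValueError(f"covariance matrix is not positive definite: {exc}")
    vinv_x = linalg.cho_solve(cho, x)
    vinv_y = linalg.cho_solve(cho, y)
    xtvx = x.T @ vinv_x
    if np.linalg.matrix_rank(xtvx) < p:
        raise ValueError("design matrix is rank deficient")
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ (x.T @ vinv_y)
    resid = y - x @ beta
    rss_w = float(resid @ linalg.cho_solve(cho, resid))
    sigma2_ml = rss_w / n
    logdet_v = 2.0 * float(np.log(np.diag(cho[0])).sum())
    loglik = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet_v + n)
    cov_beta = sigma2_ml * n / (n - p) * xtvx_inv
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=n - p)
    return GLSResult(
        beta=beta,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        sigma2_ml=sigma2_ml,
        loglik=loglik,
        residuals=resid,
        rss_whitened=rss_w,
        df_resid=n - p,
    )


@dataclass
class PGLSFit:
    """Coefficient table plus model-level statistics (λ̂, F, d.f.)."""

    terms: list[str]
    estimates: np.ndarray
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    lam: float
    fstat: float
    df: tuple[int, int]
    model_pvalue: float
    loglik: float
    sigma2_ml: float
    n: int

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "estimate": self.estimates,
                "s.e.": self.se,
                "t-value": self.tvalues,
                "p-value": self.pvalues,
            }
        )

    def summary(self) -> str:
        head = (
            f"Lambda: {self.lam:.3f}, F-statistic: {self.fstat:.3f}, "
            f"{self.df[0]} and {self.df[1]} d.f., p-value: {self.model_pvalue:.4f}"
        )
        return head + "\n" + self.coef_table().to_string(index=False)


def pgls_ml(
    x: np.ndarray,
    y: np.ndarray,
    c: np.ndarray,
    terms: list[str] | None = None,
    lam: float | str = "ml",
    tol: float = 1e-6,
) -> PGLSFit:
    """PGLS with Pagel's λ fixed or optimised by maximum likelihood.

    With ``lam="ml"`` the profile log-likelihood is maximised over [0, 1]
    by bounded scalar optimisation (endpoints included).  The overall F
    statistic compares the fit against the intercept-only GLS model in the
    V(λ̂)-whitened space: F = [(TSS_w − RSS_w)/(p−1)] / [RSS_w/(n−p)].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = x.shape
    if terms is None:
        terms = [f"x{i}" for i in range(p)]
    if len(terms) != p:
        raise ValueError("terms length must match number of columns in X")

    def negloglik(l: float) -> float:
        return -gls_fit(x, y, lambda_transform(c, l)).loglik

    if lam == "ml":
        grid = [negloglik(l) for l in (0.0, 0.25, 0.5, 0.75, 1.0)]
        if max(grid) - min(grid) < 1e-10:
            warnings.warn("profile likelihood is flat in lambda; using 1.0")
            lam_hat = 1.0
        else:
            res = minimize_scalar(
                negloglik, bounds=(0.0, 1.0), method="bounded",
                options={"xatol": tol},
            )
            cands = [(negloglik(0.0), 0.0), (negloglik(1.0), 1.0),
                     (res.fun, float(res.x))]
            lam_hat = min(cands)[1]
    else:
        lam_hat = float(lam)
        if not (0.0 <= lam_hat <= 1.0):
            raise ValueError("fixed lambda must lie in [0, 1]")

    v = lambda_transform(c, lam_hat)
    fit = gls_fit(x, y, v)
    # intercept-only comparator in the same whitened space
    ones = np.ones((n, 1))
    null_fit = gls_fit(ones, y, v)
    df1, df2 = p - 1, n - p
    if df1 > 0:
        fstat = ((null_fit.rss_whitened - fit.rss_whitened) / df1) / (
            fit.rss_whitened / df2
        )
        model_p = float(stats.f.sf(fstat, df1, df2))
    else:
        fstat, model_p = np.nan, np.nan
    return PGLSFit(
        terms=list(terms),
        estimates=fit.beta,
        se=fit.se,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        lam=lam_hat,
        fstat=float(fstat),
        df=(df1, df2),
        model_pvalue=model_p,
        loglik=fit.loglik,
        sigma2_ml=fit.sigma2_ml,
        n=n,
    )


def mass_correct(log_speed, log_mass, covariance: np.ndarray | None = None) -> np.ndarray:
    """Residuals of a simple regression of speed on body mass.

    Both inputs are expected on the log10 scale.  By default this is an
    ordinary (non-phylogenetic) regression; passing a phylogenetic
    ``covariance`` matrix switches to GLS residuals.  The residuals serve
    as the relative-speed response downstream; they are not re-logged.
    """
    y = np.asarray(log_speed, dtype=float)
    m = np.asarray(log_mass, dtype=float)
    if len(y) != len(m):
        raise ValueError("speed and mass must have equal length")
    if np.var(m) == 0:
        raise ValueError("body mass has zero variance")
    x = np.column_stack([np.ones_like(m), m])
    if covariance is not None:
        return gls_fit(x, y, covariance).residuals
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def collinearity_screen(
    predictors: pd.DataFrame, threshold: float = 0.7
) -> tuple[pd.DataFrame, list[tuple[str, str, float]]]:
    """Pearson correlations among predictors with |r| ≥ threshold flagged."""
    if predictors.shape[1] < 2:
        raise ValueError("need at least two predictors")
    corr = predictors.corr(method="pearson")
    flags = []
    cols = list(corr.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = float(corr.loc[a, b])
            if abs(r) >= threshold:
                flags.append((a, b, r))
    return corr, flags


def transform_variables(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    offset: float = 0.01,
    habitat_column: str = "habitat",
) -> tuple[pd.DataFrame, dict[str, float]]:
    """log10-transform continuous variables; dummy-code habitat.

    The offset (default 0.01) is added only to columns containing zeros,
    and the applied offsets are returned for provenance.  Habitat is coded
    closed = 0 / open = 1.  Negative values raise.
    """
    out = table.copy()
    if columns is None:
        columns = [
            c
            for c in table.columns
            if c != habitat_column and pd.api.types.is_numeric_dtype(table[c])
        ]
    applied: dict[str, float] = {}
    for col in columns:
        x = out[col].to_numpy(dtype=float)
        if (x < 0).any():
            raise ValueError(f"column {col!r} has negative values; cannot log10")
        if (x == 0).any():
            x = x + offset
            applied[col] = offset
        out[col] = np.log10(x)
    if habitat_column in out.columns and not pd.api.types.is_numeric_dtype(
        out[habitat_column]
    ):
        levels = set(out[habitat_column].astype(str).str.lower())
        if not levels <= {"closed", "open"}:
            raise ValueError(f"habitat levels must be closed/open, got {levels}")
        out[habitat_column] = (
            out[habitat_column].astype(str).str.lower() == "open"
        ).astype(int)
    return out, applied
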