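"""Q+K mixed-model association scan for the nested population panel.

The null model is y = Q beta + u + e with u ~ N(0, K sigma_g^2) and
e ~ N(0, I sigma_e^2), where Q is the nested-population factor (fixed
dummies) and K a marker-estimated realized relationship matrix. The
variance components are estimated once by REML on the eigendecomposed
(rotated) model and then held fixed for every marker test — the
"population parameters previously determined" (P3D/EMMAX)
approximation — so each marker costs one generalized-least-squares
regression. Effects are the additive dose of the donor (alternative)
allele with the recurrent parent as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import GenotypeMatrix
from .structure import skim_markers

CHI2_MEDIAN_1DF = stats.chi2.ppf(0.5, 1)  # 0.4549...


# ---------------------------------------------------------------------------
# Marker preparation and kinship
# ---------------------------------------------------------------------------

def prepare_scan_markers(
    G: GenotypeMatrix, min_minor_hom: int = 15
) -> list[str]:
    """Markers eligible for scanning in this trial's genotype subset:
    at least ``min_minor_hom`` minor-allele homozygotes, then an exact
    duplicate skim (one survivor per |r| = 1 group)."""
    counts = G.minor_hom_counts()
    keep = counts.index[counts >= min_minor_hom].tolist()
    if not keep:
        raise ValueError("no markers pass the minor-homozygote filter")
    return skim_markers(G.dosages[keep], r_abs_threshold=1.0)


def compute_kinship(
    G: GenotypeMatrix, skim_r: float = 0.80, markers: list[str] | None = None
) -> pd.DataFrame:
    """Realized relationship matrix from a LD-skimmed marker set.

    Markers are pruned at |r| >= ``skim_r`` (so dense LD blocks do not
    dominate relatedness), zero-variance markers are excluded, and
    K = W W' / m with W the column-centered dosages.
    """
    d = G.dosages if markers is None else G.dosages[markers]
    d = d.loc[:, d.std(axis=0, ddof=0) > 0]
    kept = skim_markers(d, r_abs_threshold=skim_r)
    if len(kept) < 2:
        raise ValueError("fewer than 2 markers after kinship skim")
    W = d[kept].to_numpy(dtype=float)
    W = np.where(np.isnan(W), np.nanmean(W, axis=0), W)
    W = W - W.mean(axis=0)
    K = (W @ W.T) / W.shape[1]
    return pd.DataFrame(K, index=G.genotype_ids, columns=G.genotype_ids)


# ---------------------------------------------------------------------------
# Null model REML (rotated one-dimensional optimization)
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    sigma_g2: float
    sigma_e2: float
    eigvals: np.ndarray  # of K
    U: np.ndarray  # eigenvectors of K
    X: np.ndarray  # fixed covariates (rotated basis not included)
    loglik: float

    @property
    def weights(self) -> np.ndarray:
        """1 / diag variance of the rotated observations."""
        return 1.0 / (self.sigma_g2 * self.eigvals + self.sigma_e2)


def fit_null(y: np.ndarray, X: np.ndarray, K: np.ndarray) -> NullModel:
    """REML of y = X b + u + e, u ~ N(0, K sg2), via eigendecomposition
    of K and a 1-D search over the variance ratio."""
    n, p = X.shape
    eigvals, U = np.linalg.eigh(K)
    eigvals = np.clip(eigvals, 0.0, None)
    yr = U.T @ y
    Xr = U.T @ X

    def negll(log_delta: float) -> float:
        delta = np.exp(log_delta)  # se2 / sg2
        d = eigvals + delta
        w = 1.0 / d
        XtWX = (Xr * w[:, None]).T @ Xr
        sign, logdetX = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
        r = yr - Xr @ beta
        quad = (r**2 * w).sum()
        sg2 = quad / (n - p)
        ll = -0.5 * (
            (n - p) * (1 + np.log(2 * np.pi * sg2))
            + np.log(d).sum()
            + logdetX
        )
        return -ll

    res = optimize.minimize_scalar(
        negll, bounds=(-12.0, 12.0), method="bounded"
    )
    # compare against the boundaries (pure genetic / pure residual)
    best = min(
        [(negll(t), t) for t in (res.x, -12.0, 12.0)], key=lambda v: v[0]
    )
    log_delta = best[1]
    delta = np.exp(log_delta)
    d = eigvals + delta
    w = 1.0 / d
    XtWX = (Xr * w[:, None]).T @ Xr
    beta = np.linalg.solve(XtWX, (Xr * w[:, None]).T @ yr)
    r = yr - Xr @ beta
    sg2 = (r**2 * w).sum() / (n - p)
    return NullModel(
        sigma_g2=float(sg2),
        sigma_e2=float(sg2 * delta),
        eigvals=eigvals,
        U=U,
        X=X,
        loglik=-best[0],
    )


# ---------------------------------------------------------------------------
# Scan
# ---------------------------------------------------------------------------

def _population_dummies(Q: pd.Series) -> np.ndarray:
    dummies = pd.get_dummies(Q.astype(str), drop_first=True, dtype=float)
    return np.column_stack([np.ones(len(Q)), dummies.to_numpy()])


def scan(
    y: pd.Series,
    G: GenotypeMatrix,
    Q: pd.Series,
    K: pd.DataFrame,
    markers: list[str] | None = None,
    mmap: pd.DataFrame | None = None,
    covariate_markers: list[str] | None = None,
) -> pd.DataFrame:
    """Single-marker additive Q+K scan (P3D approximation).

    ``y``, ``Q`` and ``K`` are aligned on genotype ids; ``markers``
    defaults to all matrix columns. Returns a per-marker table with
    ``chrom, bp, effect, se, score`` (score = -log10 P) plus scan
    metadata in ``.attrs`` (n, lambda inflation, variance components).
    Markers whose dosage is constant within every population are
    confounded with Q and reported NA. Wald tests use the marker
    coefficient from GLS with the null variance components fixed.
    """
    ids = y.dropna().index.intersection(G.genotype_ids).intersection(Q.index)
    ids = ids[~pd.Index(ids).duplicated()]
    yv = y.loc[ids].to_numpy(dtype=float)
    Kv = K.loc[ids, ids].to_numpy(dtype=float)
    X = _population_dummies(Q.loc[ids])
    covariate_markers = list(covariate_markers or [])
    pruned: list[str] = []
    if covariate_markers:
        C = G.dosages.loc[ids, covariate_markers].to_numpy(dtype=float)
        C = np.nan_to_num(C)
        keep_cols = []
        for j in range(C.shape[1]):
            trial = np.column_stack([X] + [C[:, k] for k in keep_cols] + [C[:, j]])
            if np.linalg.matrix_rank(trial) == trial.shape[1]:
                keep_cols.append(j)
            else:
                pruned.append(covariate_markers[j])
        if pruned:
            import warnings

            warnings.warn(f"collinear covariates pruned: {pruned}")
        covariate_markers = [covariate_markers[j] for j in keep_cols]
        if keep_cols:
            X = np.column_stack([X, C[:, keep_cols]])

    null = fit_null(yv, X, Kv)
    w = null.weights
    yr = null.U.T @ yv
    Xr = null.U.T @ X

    if markers is None:
        markers = list(G.marker_ids)
    dmat = G.dosages.loc[ids, markers]
    pops = Q.loc[ids].astype(str)
    gmax = dmat.groupby(pops.to_numpy()).max()
    gmin = dmat.groupby(pops.to_numpy()).min()
    confounded = ((gmax - gmin) == 0).all(axis=0)
    results = []
    sw = np.sqrt(w)
    Xw = Xr * sw[:, None]
    yw = yr * sw
    Qx, Rx = np.linalg.qr(Xw)
    resid_y = yw - Qx @ (Qx.T @ yw)
    n, p = X.shape
    df = n - p - 1
    cov_set = set(covariate_markers)
    for m in markers:
        g = dmat[m].to_numpy(dtype=float)
        if m in cov_set or np.isnan(g).any():
            results.append((m, np.nan, np.nan, np.nan))
            continue
        # confounded with Q: constant dosage within every population
        if confounded[m]:
            results.append((m, np.nan, np.nan, np.nan))
            continue
        gw = (null.U.T @ g) * sw
        rg = gw - Qx @ (Qx.T @ gw)
        denom = rg @ rg
        if denom <= 1e-12:
            results.append((m, np.nan, np.nan, np.nan))
            continue
        b = (rg @ resid_y) / denom
        rss = resid_y @ resid_y - b**2 * denom
        se = np.sqrt(rss / df / denom)
        t = b / se
        pval = 2.0 * stats.t.sf(abs(t), df)
        results.append((m, b, se, pval))

    out = pd.DataFrame(
        results, columns=["marker", "effect", "se", "p"]
    ).set_index("marker")
    out["score"] = -np.log10(out["p"])
    out["minor_hom"] = G.minor_hom_counts().reindex(out.index)
    if mmap is not None:
        out["chrom"] = mmap["chrom"].reindex(out.index)
        out["bp"] = mmap["bp"].reindex(out.index)
        out = out.sort_values(["chrom", "bp"], kind="mergesort", na_position="last")
    pvals = out["p"].dropna()
    out.attrs.update(
        n=len(ids),
        sigma_g2=null.sigma_g2,
        sigma_e2=null.sigma_e2,
        loglik_null=null.loglik,
        inflation=inflation_factor(pvals) if len(pvals) >= 10 else np.nan,
        covariates=covariate_markers,
        pruned_covariates=pruned,
    )
    return out


def covariate_scan(
    y: pd.Series,
    G: GenotypeMatrix,
    Q: pd.Series,
    K: pd.DataFrame,
    covariate_markers: list[str],
    **kwargs,
) -> pd.DataFrame:
    """Re-scan with major-hit dosages appended to the fixed effects;
    the covariate markers themselves are reported NA."""
    missing = [m for m in covariate_markers if m not in G.dosages.columns]
    if missing:
        raise KeyError(f"covariate markers not in matrix: {missing}")
    return scan(y, G, Q, K, covariate_markers=covariate_markers, **kwargs)


# ---------------------------------------------------------------------------
# Thresholds and diagnostics
# ---------------------------------------------------------------------------

def effective_markers(dosages: pd.DataFrame, chrom: pd.Series) -> float:
    """Eigenvalue-based effective number of independent tests,
    computed per chromosome on the marker correlation matrix and
    summed (Li & Ji style: each eigenvalue contributes
    I(lambda >= 1) + frac(lambda))."""
    total = 0.0
    for _, cols in chrom.groupby(chrom):
        sub = dosages[cols.index.tolist()]
        sub = sub.loc[:, sub.std(ddof=0) > 0]
        if sub.shape[1] == 0:
            continue
        if sub.shape[1] == 1:
            total += 1.0
            continue
        corr = np.nan_to_num(sub.corr().to_numpy(), nan=0.0)
        np.fill_diagonal(corr, 1.0)
        # round away float noise so an eigenvalue of k - eps does not
        # spuriously contribute an extra fractional test
        ev = np.round(np.abs(np.linalg.eigvalsh(corr)), 8)
        total += float(((ev >= 1).astype(float) + (ev - np.floor(ev))).sum())
    return total


def significance_threshold(
    dosages: pd.DataFrame,
    mmap: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Bonferroni-type threshold on the -log10(P) scale using the
    LD-adjusted effective marker count. Unmapped markers are excluded
    with a warning. Returns (threshold, M_eff)."""
    chrom = mmap["chrom"].reindex(dosages.columns)
    unmapped = chrom[chrom.isna()].index.tolist()
    if unmapped:
        import warnings

        warnings.warn(f"{len(unmapped)} unmapped markers excluded from M_eff")
    chrom = chrom.dropna()
    if chrom.empty:
        raise ValueError("no mapped markers")
    meff = effective_markers(dosages, chrom)
    return float(-np.log10(alpha / meff)), meff


def threshold_from_meff(meff: float, alpha: float = 0.05) -> float:
    """-log10(alpha / M_eff): the Bonferroni-type cutoff given an
    effective marker count."""
    if meff <= 0:
        raise ValueError("M_eff must be positive")
    return float(-np.log10(alpha / meff))


def inflation_factor(pvalues) -> float:
    """Genomic inflation lambda: median association chi-square over its
    null expectation (0.4549 for 1 df)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if len(p) < 10:
        raise ValueError("need >= 10 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_MEDIAN_1DF)
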