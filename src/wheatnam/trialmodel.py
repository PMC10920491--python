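"""Augmented-trial mixed models: genotype BLUEs, backward elimination
of random terms, broad-sense heritability, and descriptive statistics.

The model for a half-plot unit is

    y = mu + g_i + b_j + r_jk + c_jl + d_m + t_n + e

with genotype fixed, and block, row-within-block, column-within-block,
scorer and nursery-lid random. Half-plots are treated as independent
experimental units; an optional plot-level random term is off by
default. The model is fitted by REML; the full model is reduced by
backward elimination of random terms via likelihood-ratio tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class TrialModelSpec:
    """Columns and options for the half-plot trial model.

    ``random_terms`` may include ``block``, ``row``, ``column``
    (row/column are nested within block), ``scorer``, ``lid`` and
    ``plot``; the scorer term is only used when more than one scorer is
    recorded. ``reference`` names the genotype used as the fixed-effect
    baseline (defaults to the lexicographically first genotype).
    """

    response: str = "value"
    genotype: str = "genotype"
    random_terms: tuple[str, ...] = ("block", "row", "column", "scorer", "lid")
    reference: str | None = None
    elimination_alpha: float = 0.10
    include_plot: bool = False


@dataclass
class RemlFit:
    """A fitted variance-components model."""

    varcomp: dict[str, float]  # per-term variances plus "residual"
    loglik: float  # restricted log-likelihood
    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    converged: bool
    n: int
    p: int
    loglik_path: list[float] = field(default_factory=list)


def _random_design(df: pd.DataFrame, term: str) -> np.ndarray | None:
    """Indicator matrix for one random term; None if degenerate."""
    if term in ("row", "column"):
        levels = df["block"].astype(str) + ":" + df[term].astype(str)
    else:
        levels = df[term].astype(str)
    dummies = pd.get_dummies(levels, dtype=float)
    if dummies.shape[1] < 2:
        return None
    return dummies.to_numpy()


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    beta_names: list[str] | None = None,
) -> RemlFit:
    """REML for y = X beta + sum_k Z_k u_k + e, u_k ~ N(0, s2_k I).

    Variance ratios gamma_k = s2_k / s2_e are optimized on the log
    scale (L-BFGS-B) with the residual variance profiled out; the
    restricted log-likelihood is tracked and non-decreasing over
    accepted optimizer steps.
    """
    n, p = X.shape
    names = list(Zs)
    ZZt = [Z @ Z.T for Z in Zs.values()]
    path: list[float] = []

    def negloglik(theta: np.ndarray) -> float:
        V = np.eye(n)
        for g, A in zip(np.exp(theta), ZZt):
            V = V + g * A
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e10
        logdetV = 2.0 * np.log(np.diag(L)).sum()
        Vinv_y = np.linalg.solve(V, y)
        Vinv_X = np.linalg.solve(V, X)
        XtVinvX = X.T @ Vinv_X
        sign, logdetX = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            return 1e10
        beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
        resid = y - X @ beta
        quad = resid @ np.linalg.solve(V, resid)
        s2 = quad / (n - p)
        ll = -0.5 * (
            (n - p) * (1.0 + np.log(2.0 * np.pi * s2)) + logdetV + logdetX
        )
        path.append(ll)
        return -ll

    if names:
        theta0 = np.zeros(len(names))
        res = optimize.minimize(
            negloglik,
            theta0,
            method="L-BFGS-B",
            bounds=[(-12.0, 12.0)] * len(names),
        )
        theta = res.x
        converged = bool(res.success)
    else:
        theta = np.zeros(0)
        converged = True

    V = np.eye(n)
    for g, A in zip(np.exp(theta), ZZt):
        V = V + g * A
    Vinv_X = np.linalg.solve(V, X)
    XtVinvX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVinvX, X.T @ np.linalg.solve(V, y))
    resid = y - X @ beta
    s2 = (resid @ np.linalg.solve(V, resid)) / (n - p)
    beta_cov = s2 * np.linalg.inv(XtVinvX)
    ll = -negloglik(theta)
    varcomp = {nm: float(s2 * np.exp(t)) for nm, t in zip(names, theta)}
    # ratios at the lower optimizer bound are numerically zero variances
    for nm, t in zip(names, theta):
        if t <= -11.9:
            varcomp[nm] = 0.0
    varcomp["residual"] = float(s2)
    accepted = list(np.maximum.accumulate(path))
    return RemlFit(
        varcomp,
        float(ll),
        beta,
        np.sqrt(np.diag(beta_cov)),
        beta_names or [f"b{i}" for i in range(p)],
        converged,
        n,
        p,
        accepted,
    )


def _build_design(
    df: pd.DataFrame, spec: TrialModelSpec, genotype_fixed: bool
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray], list[str], list[str]]:
    y = df[spec.response].to_numpy(dtype=float)
    terms = list(spec.random_terms)
    if spec.include_plot and "plot" not in terms:
        terms.append("plot")
    if "scorer" in terms and "scorer" in df.columns and df["scorer"].nunique() < 2:
        terms.remove("scorer")
    terms = [
        t
        for t in terms
        if t in df.columns and (t not in ("row", "column") or "block" in df.columns)
    ]
    Zs = {}
    for t in terms:
        Z = _random_design(df, t)
        if Z is not None:
            Zs[t] = Z
    if genotype_fixed:
        geno = df[spec.genotype].astype(str)
        levels = sorted(geno.unique())
        ref = spec.reference if spec.reference in levels else levels[0]
        levels = [ref] + [g for g in levels if g != ref]
        dummies = pd.get_dummies(
            pd.Categorical(geno, categories=levels), drop_first=True, dtype=float
        )
        X = np.column_stack([np.ones(len(df)), dummies.to_numpy()])
        names = ["(Intercept)"] + list(dummies.columns.astype(str))
    else:
        X = np.ones((len(df), 1))
        names = ["(Intercept)"]
    return y, X, Zs, names, terms


def backward_eliminate(
    y: np.ndarray,
    X: np.ndarray,
    Zs: dict[str, np.ndarray],
    alpha: float = 0.10,
    beta_names: list[str] | None = None,
) -> tuple[RemlFit, dict[str, float], list[str]]:
    """Drop random terms one at a time by REML likelihood-ratio test.

    At each step the term with the largest chi-square(1) p-value above
    ``alpha`` is removed; fixed effects are unchanged so REML
    likelihoods are comparable. Returns the final fit, the last LRT
    p-value per term, and the retained terms.
    """
    current = dict(Zs)
    fit = reml_fit(y, X, current, beta_names)
    pvals: dict[str, float] = {}
    while current:
        candidates = {}
        for t in current:
            reduced = {k: v for k, v in current.items() if k != t}
            fit_red = reml_fit(y, X, reduced, beta_names)
            lr = max(0.0, 2.0 * (fit.loglik - fit_red.loglik))
            candidates[t] = (stats.chi2.sf(lr, df=1), fit_red)
        worst = max(candidates, key=lambda t: candidates[t][0])
        pvals.update({t: candidates[t][0] for t in candidates})
        if candidates[worst][0] > alpha:
            del current[worst]
            fit = candidates[worst][1]
        else:
            break
    return fit, pvals, list(current)


def fit_blues(
    phenotypes: pd.DataFrame, spec: TrialModelSpec | None = None
) -> tuple[pd.DataFrame, dict[str, float], dict]:
    """Genotype BLUEs from the backward-reduced mixed model.

    ``phenotypes`` is a unit-level table for one trait with the factor
    columns named in the spec. Returns (BLUE table indexed by genotype
    with ``blue`` and ``se``, variance components of the final model,
    metadata with retained terms and elimination p-values). BLUEs are
    on the response scale: intercept plus the genotype's fixed effect.
    """
    spec = spec or TrialModelSpec()
    df = phenotypes.dropna(subset=[spec.response])
    if df[spec.genotype].nunique() < 2:
        raise ValueError("need >= 2 genotypes")
    y, X, Zs, names, _ = _build_design(df, spec, genotype_fixed=True)
    fit, pvals, retained = backward_eliminate(
        y, X, Zs, spec.elimination_alpha, names
    )
    if not fit.converged:
        import warnings

        warnings.warn("REML optimizer did not report convergence")
    geno = sorted(df[spec.genotype].astype(str).unique())
    ref = spec.reference if spec.reference in geno else geno[0]
    blues = {ref: fit.beta[0]}
    ses = {ref: fit.beta_se[0]}
    for nm, b, se in zip(fit.beta_names[1:], fit.beta[1:], fit.beta_se[1:]):
        blues[nm] = fit.beta[0] + b
        ses[nm] = se
    table = pd.DataFrame({"blue": pd.Series(blues), "se": pd.Series(ses)})
    table.index.name = spec.genotype
    meta = {
        "retained_terms": retained,
        "elimination_pvalues": pvals,
        "converged": fit.converged,
        "loglik": fit.loglik,
        "n_units": fit.n,
    }
    return table.sort_index(), fit.varcomp, meta


def heritability(
    phenotypes: pd.DataFrame,
    spec: TrialModelSpec | None = None,
    retained_terms: tuple[str, ...] | None = None,
) -> tuple[float, dict[str, float]]:
    """Broad-sense heritability H2 = Vg / (Vg + Ve).

    The final model is refitted with genotype as a random term (plus
    any retained design random terms); H2 uses only the genotypic and
    residual variances.
    """
    spec = spec or TrialModelSpec()
    if retained_terms is not None:
        spec = TrialModelSpec(
            response=spec.response,
            genotype=spec.genotype,
            random_terms=tuple(retained_terms),
            reference=spec.reference,
            elimination_alpha=spec.elimination_alpha,
            include_plot=spec.include_plot,
        )
    df = phenotypes.dropna(subset=[spec.response])
    y, X, Zs, names, _ = _build_design(df, spec, genotype_fixed=False)
    Zg = pd.get_dummies(df[spec.genotype].astype(str), dtype=float).to_numpy()
    Zs = {"genotype": Zg, **Zs}
    fit = reml_fit(y, X, Zs, names)
    vg = fit.varcomp["genotype"]
    ve = fit.varcomp["residual"]
    if vg + ve == 0:
        raise ZeroDivisionError("Vg + Ve is zero")
    return vg / (vg + ve), fit.varcomp


def cross_trial_correlation(
    tables: dict[str, pd.Series], alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations between trait/trial BLUE
    vectors, with two-sided p-values; cells with p > alpha are flagged
    for masking (as in a correlation heatmap that blanks insignificant
    cells)."""
    keys = list(tables)
    r = pd.DataFrame(np.eye(len(keys)), index=keys, columns=keys)
    p = pd.DataFrame(np.zeros((len(keys), len(keys))), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for j, b in enumerate(keys):
            if j <= i:
                continue
            joined = pd.concat([tables[a], tables[b]], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise ValueError(f"fewer than 3 shared genotypes for {a} vs {b}")
            if joined.iloc[:, 0].std() == 0 or joined.iloc[:, 1].std() == 0:
                raise ValueError(f"zero-variance vector in {a} vs {b}")
            res = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    r.attrs["mask"] = p > alpha
    return r, p


def compare_groups(values: pd.Series, mask: pd.Series) -> tuple[float, float, float]:
    """Welch two-sample t-test (two-sided) between values[mask] and
    values[~mask]. Returns (t, df, p)."""
    a = values[mask.reindex(values.index).fillna(False).astype(bool)].dropna()
    b = values[~mask.reindex(values.index).fillna(False).astype(bool)].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 members")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)
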