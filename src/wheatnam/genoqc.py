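"""Post-calling genotype QC: marker and genotype filters, duplicate and
contamination detection, and iterative random-forest imputation.

The cascade order is fixed — markers, genotypes, duplicates,
non-parental-allele check, imputation — but every stage is individually
re-runnable and records its counts in a :class:`QcReport`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .core import GenotypeMatrix


@dataclass
class QcReport:
    """Per-stage bookkeeping: what was removed, what remains, and why."""

    stages: list[dict] = field(default_factory=list)

    def record(self, stage: str, **counts) -> None:
        self.stages.append({"stage": stage, **counts})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def filter_markers(
    G: GenotypeMatrix,
    het_max: float = 0.10,
    missing_max: float = 0.10,
    min_minor_hom: int = 15,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop markers with excess heterozygosity, excess missingness, or a
    deficit of minor-allele homozygotes.

    A marker is removed iff het fraction (over non-missing calls)
    > ``het_max``, or missing fraction (over all genotypes)
    > ``missing_max``, or fewer than ``min_minor_hom`` genotypes are
    homozygous for the minor allele. Thresholds are exclusive: a marker
    at exactly 10% het or exactly 15 minor homozygotes is retained.
    """
    if G.n_markers == 0:
        raise ValueError("empty genotype matrix")
    if not (0 <= het_max <= 1 and 0 <= missing_max <= 1 and min_minor_hom >= 0):
        raise ValueError("thresholds out of range")
    report = report or QcReport()
    het = G.het_fraction("marker").fillna(0)
    miss = G.missing_fraction("marker")
    mhom = G.minor_hom_counts()
    bad = (het > het_max) | (miss > missing_max) | (mhom < min_minor_hom)
    out = G.subset(markers=G.marker_ids[~bad])
    report.record(
        "filter_markers",
        removed_het=int((het > het_max).sum()),
        removed_missing=int((miss > missing_max).sum()),
        removed_minor_hom=int((mhom < min_minor_hom).sum()),
        removed_total=int(bad.sum()),
        markers_retained=out.n_markers,
        genotypes_retained=out.n_genotypes,
    )
    return out, report


def filter_genotypes(
    G: GenotypeMatrix, het_max: float = 0.10, report: QcReport | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Drop genotypes whose heterozygous fraction of non-missing calls
    exceeds ``het_max``. Missing data never removes a genotype."""
    report = report or QcReport()
    het = G.het_fraction("genotype").fillna(0)
    bad = het > het_max
    out = G.subset(genotypes=G.genotype_ids[~bad])
    report.record(
        "filter_genotypes",
        removed_het=int(bad.sum()),
        markers_retained=out.n_markers,
        genotypes_retained=out.n_genotypes,
    )
    return out, report


@dataclass
class DuplicatePolicy:
    """Dual rule: flag a pair when r exceeds ``r_abs`` outright, or
    exceeds mean + ``k_sd`` standard deviations of the within-population
    pair distribution."""

    r_abs: float = 0.99
    k_sd: float = 6.0


def detect_duplicates(
    G: GenotypeMatrix,
    policy: DuplicatePolicy | None = None,
    report: QcReport | None = None,
    drop: bool = False,
) -> tuple[pd.DataFrame, GenotypeMatrix, QcReport]:
    """Flag genotype pairs that are too similar to be independent lines.

    All pairwise Pearson correlations between genotype dosage vectors
    (pairwise-complete) are computed; a pair is flagged when r exceeds
    the absolute cutoff or the distribution-based cutoff. When
    ``drop=True`` the flagged member with more missing data (ties:
    lexicographically later id) is removed.
    """
    if G.n_genotypes < 2:
        raise ValueError("need >= 2 genotypes")
    policy = policy or DuplicatePolicy()
    report = report or QcReport()
    d = G.dosages
    variances = d.var(axis=1)
    constant = variances[variances == 0].index.tolist()
    use = d.loc[variances > 0]
    R = use.T.corr()
    iu = np.triu_indices(len(R), k=1)
    rvals = R.to_numpy()[iu]
    ids = R.index.to_numpy()
    pairs = pd.DataFrame(
        {"a": ids[iu[0]], "b": ids[iu[1]], "r": rvals}
    ).dropna(subset=["r"])

    # distribution-based cutoff from within-population pairs
    cutoff_dist = np.inf
    if G.populations is not None and len(G.populations) > 0:
        pop = G.populations
        same = (
            pairs["a"].map(pop).notna()
            & (pairs["a"].map(pop) == pairs["b"].map(pop))
        )
        within = pairs.loc[same, "r"]
        if len(within) >= 10 and within.std() > 0:
            cutoff_dist = within.mean() + policy.k_sd * within.std()
    flagged = pairs[(pairs["r"] > policy.r_abs) | (pairs["r"] > cutoff_dist)].copy()
    flagged = flagged.sort_values("r", ascending=False).reset_index(drop=True)

    out = G
    dropped: list[str] = []
    if drop and len(flagged):
        miss = G.missing_fraction("genotype")
        alive = set(G.genotype_ids)
        for _, row in flagged.iterrows():
            a, b = row["a"], row["b"]
            if a not in alive or b not in alive:
                continue
            if miss[a] > miss[b]:
                victim = a
            elif miss[b] > miss[a]:
                victim = b
            else:
                victim = max(a, b)
            alive.discard(victim)
            dropped.append(victim)
        out = G.subset(genotypes=[g for g in G.genotype_ids if g in alive])
    report.record(
        "detect_duplicates",
        flagged_pairs=len(flagged),
        constant_genotypes=len(constant),
        dropped=len(dropped),
        markers_retained=out.n_markers,
        genotypes_retained=out.n_genotypes,
    )
    flagged.attrs["constant_genotypes"] = constant
    flagged.attrs["distribution_cutoff"] = cutoff_dist
    return flagged, out, report


def nonparental_allele_check(
    G: GenotypeMatrix,
    threshold: float = 0.05,
    report: QcReport | None = None,
) -> tuple[pd.Series, QcReport]:
    """Flag genotypes carrying alleles neither parent of their nested
    population carries.

    Within each population, markers where the recurrent parent and the
    donor share the same homozygous dosage are monomorphic for the
    cross: any offspring call disagreeing with that dosage is a
    non-parental allele. A genotype is flagged when its disagreement
    fraction over such markers exceeds ``threshold``.
    """
    if G.populations is None or G.recurrent_id is None:
        raise ValueError("population map and recurrent parent required")
    report = report or QcReport()
    flags = {}
    skipped = []
    rec = G.dosages.loc[G.recurrent_id]
    for pop, members in G.populations.groupby(G.populations):
        donor_id = G.donor_ids.get(pop)
        if donor_id is None or donor_id not in G.dosages.index:
            skipped.append(pop)
            continue
        donor = G.dosages.loc[donor_id]
        mono = (rec == donor) & rec.isin([0.0, 2.0])
        if not mono.any():
            continue
        expected = rec[mono]
        sub = G.dosages.loc[members.index, mono.to_numpy()]
        disagree = sub.ne(expected, axis=1) & sub.notna()
        frac = disagree.sum(axis=1) / sub.notna().sum(axis=1).clip(lower=1)
        for gid, f in frac.items():
            flags[gid] = float(f)
    if skipped:
        import warnings

        warnings.warn(f"populations skipped (missing parent): {skipped}")
    out = pd.Series(flags, name="nonparental_fraction", dtype=float)
    flagged = out[out > threshold]
    report.record(
        "nonparental_allele_check",
        flagged=len(flagged),
        populations_skipped=len(skipped),
    )
    return flagged, report


def impute_missing(
    G: GenotypeMatrix,
    n_trees: int = 200,
    max_iter: int = 10,
    seed: int | None = None,
    max_predictors: int | None = 100,
    report: QcReport | None = None,
) -> tuple[GenotypeMatrix, QcReport]:
    """Iterative random-forest imputation of missing dosage calls.

    Markers are visited in order of increasing missingness; each
    marker's missing calls are predicted by a random-forest classifier
    trained on the other markers (mean-filled), so outputs stay in
    {0, 1, 2}. Iteration stops when the number of changed calls rises
    relative to the previous sweep (classic iterative-RF stopping) or at
    ``max_iter``. ``max_predictors`` caps the predictor set per marker
    to the most correlated markers, which preserves accuracy in
    LD-dense data while bounding cost. Observed cells are never altered.
    Out-of-bag error estimates are averaged into the report.
    """
    report = report or QcReport()
    d = G.dosages.to_numpy().copy()
    miss_mask = np.isnan(d)
    if (miss_mask.all(axis=0)).any():
        bad = G.marker_ids[miss_mask.all(axis=0)].tolist()
        raise ValueError(f"markers with no observed calls: {bad[:5]}")
    if not miss_mask.any():
        report.record("impute_missing", imputed_cells=0, sweeps=0, oob_error=0.0)
        return G.copy(), report
    rng = np.random.default_rng(seed)
    order = np.argsort(miss_mask.sum(axis=0))
    order = order[miss_mask.sum(axis=0)[order] > 0]

    col_means = np.nanmean(d, axis=0)
    filled = np.where(miss_mask, col_means, d)
    prev_changes = np.inf
    prev_filled = filled.copy()
    sweeps = 0
    oob_errors: list[float] = []
    for it in range(max_iter):
        changes = 0
        for j in order:
            rows_miss = miss_mask[:, j]
            rows_obs = ~rows_miss
            y = d[rows_obs, j].astype(int)
            if len(np.unique(y)) == 1:
                pred = np.full(rows_miss.sum(), y[0], dtype=float)
            else:
                pred_cols = np.delete(np.arange(d.shape[1]), j)
                if max_predictors is not None and len(pred_cols) > max_predictors:
                    x = filled[rows_obs][:, pred_cols]
                    yc = y - y.mean()
                    xc = x - x.mean(axis=0)
                    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum()) + 1e-12
                    score = np.abs(xc.T @ yc) / denom
                    pred_cols = pred_cols[np.argsort(score)[::-1][:max_predictors]]
                want_oob = it == 0 and len(y) > 10
                rf = RandomForestClassifier(
                    n_estimators=n_trees,
                    random_state=int(rng.integers(2**31 - 1)),
                    oob_score=want_oob,
                    n_jobs=1,
                )
                rf.fit(filled[rows_obs][:, pred_cols], y)
                if want_oob:
                    oob_errors.append(1.0 - rf.oob_score_)
                pred = rf.predict(filled[rows_miss][:, pred_cols]).astype(float)
            changes += int((filled[rows_miss, j] != pred).sum())
            filled[rows_miss, j] = pred
        sweeps += 1
        if changes >= prev_changes:
            filled = prev_filled  # revert to the better sweep
            break
        if changes == 0:
            break
        prev_changes = changes
        prev_filled = filled.copy()
    out = G.copy()
    out.dosages = pd.DataFrame(
        np.where(miss_mask, np.round(filled), d),
        index=G.dosages.index,
        columns=G.dosages.columns,
    )
    report.record(
        "impute_missing",
        imputed_cells=int(miss_mask.sum()),
        sweeps=sweeps,
        oob_error=float(np.mean(oob_errors)) if oob_errors else float("nan"),
    )
    return out, report
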