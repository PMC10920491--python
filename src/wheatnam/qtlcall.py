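"""From scans to named QTLs: LD-decay window estimation, greedy peak
calling, interval definition, cross-trial merging, and multi-QTL
variance partitioning.

A QTL name follows the Q{Trait}.{lab}-{chrom}.{index} convention, with
indices assigned in chromosome-then-bp order per trait.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core import GenotypeMatrix
from .namgwas import fit_null, _population_dummies

MB = 1_000_000


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LdDecayProfile:
    binned: pd.DataFrame  # distance_mb (bin center), mean_r2, n_pairs
    amplitude: float  # fitted a in a * exp(-b d)
    rate: float  # fitted b (per Mb)
    critical_r2: float
    window_mb: int


def ld_decay_window(
    dosages: pd.DataFrame,
    mmap: pd.DataFrame,
    critical_r2: float = 0.2,
    bin_mb: float = 1.0,
    max_pairs_per_chrom: int | None = 200_000,
    seed: int = 0,
) -> LdDecayProfile:
    """Distance at which pairwise LD decays to the critical R2.

    Within-chromosome pairwise R2 values are pooled across chromosomes,
    binned by physical distance, and a monotone exponential decay
    a*exp(-b*d) is fitted to the binned means; the window is the
    smallest distance where the fitted curve reaches ``critical_r2``,
    rounded up to a whole Mb. Raises when the curve never crosses
    (markers in LD regardless of distance), with guidance to raise the
    critical value.
    """
    placed = mmap[mmap["chrom"].notna() & mmap.index.isin(dosages.columns)]
    rng = np.random.default_rng(seed)
    dists: list[np.ndarray] = []
    r2s: list[np.ndarray] = []
    for _, sub in placed.groupby("chrom"):
        cols = sub.index.tolist()
        if len(cols) < 2:
            continue
        bp = sub["bp"].to_numpy(dtype=float)
        R = dosages[cols].corr().to_numpy() ** 2
        iu = np.triu_indices(len(cols), k=1)
        d = np.abs(bp[iu[0]] - bp[iu[1]]) / MB
        r2 = R[iu]
        ok = ~np.isnan(r2)
        d, r2 = d[ok], r2[ok]
        if max_pairs_per_chrom is not None and len(d) > max_pairs_per_chrom:
            idx = rng.choice(len(d), size=max_pairs_per_chrom, replace=False)
            d, r2 = d[idx], r2[idx]
        dists.append(d)
        r2s.append(r2)
    if not dists:
        raise ValueError("no within-chromosome marker pairs")
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    bins = np.floor(d / bin_mb).astype(int)
    binned = (
        pd.DataFrame({"bin": bins, "r2": r2})
        .groupby("bin")["r2"]
        .agg(["mean", "size"])
        .reset_index()
    )
    binned["distance_mb"] = (binned["bin"] + 0.5) * bin_mb
    xd = binned["distance_mb"].to_numpy()
    ym = binned["mean"].to_numpy()
    try:
        popt, _ = optimize.curve_fit(
            lambda x, a, b: a * np.exp(-b * x),
            xd,
            ym,
            p0=[max(ym.max(), 0.1), 0.05],
            bounds=([1e-6, 0.0], [1.0, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - pathological fits
        raise ValueError(f"LD decay fit failed: {exc}") from exc
    a, b = popt
    if a <= critical_r2:
        window = 1
    else:
        crossing = np.inf if b <= 1e-9 else np.log(a / critical_r2) / b
        if crossing > 2 * xd.max():
            raise ValueError(
                "fitted LD does not decay to the critical value within the "
                "observed distance range; markers are in LD regardless of "
                "distance — raise critical_r2 or check the map"
            )
        window = int(np.ceil(crossing))
    profile = binned.rename(columns={"mean": "mean_r2", "size": "n_pairs"})[
        ["distance_mb", "mean_r2", "n_pairs"]
    ]
    return LdDecayProfile(profile, float(a), float(b), critical_r2, max(window, 1))


# ---------------------------------------------------------------------------
# Peaks and intervals
# ---------------------------------------------------------------------------

def call_peaks(
    scan: pd.DataFrame, threshold: float, window_mb: float
) -> pd.DataFrame:
    """Greedy peak calling with LD-window suppression.

    Repeatedly takes the highest-scoring marker above ``threshold``
    (ties broken toward smaller bp, then marker id) and suppresses all
    markers within +/- ``window_mb`` on the same chromosome. Depends
    only on scores and positions, never on row order.
    """
    sig = scan.dropna(subset=["score", "chrom", "bp"])
    sig = sig[sig["score"] >= threshold].copy()
    # stable order: score desc, bp asc, marker id asc for exact ties
    sig = sig.assign(_marker=sig.index).sort_values(
        ["score", "bp", "_marker"], ascending=[False, True, True], kind="mergesort"
    )
    peaks = []
    alive = sig.copy()
    while len(alive):
        top = alive.iloc[0]
        peaks.append(top.drop("_marker").rename(top["_marker"]))
        same = alive["chrom"] == top["chrom"]
        near = (alive["bp"] - top["bp"]).abs() <= window_mb * MB
        alive = alive[~(same & near)]
    if not peaks:
        return scan.iloc[0:0].copy()
    return pd.DataFrame(peaks)


def qtl_interval(
    scan: pd.DataFrame, peak_marker: str, threshold: float, window_mb: float
) -> tuple[int, int]:
    """First/last significant flanking markers around a peak.

    Walks outward from the peak through markers in bp order on its
    chromosome, extending while markers stay significant and within the
    suppression window; the interval is the bp span of that consecutive
    significant run (a lone peak yields a zero-width interval).
    """
    peak = scan.loc[peak_marker]
    if peak["score"] < threshold:
        raise ValueError("peak is not significant at the given threshold")
    chrom = scan[scan["chrom"] == peak["chrom"]].dropna(subset=["bp", "score"])
    chrom = chrom.sort_values("bp", kind="mergesort")
    pos = chrom.index.get_loc(peak_marker)
    lo = hi = int(peak["bp"])
    for i in range(pos - 1, -1, -1):
        row = chrom.iloc[i]
        if row["score"] < threshold or abs(row["bp"] - peak["bp"]) > window_mb * MB:
            break
        lo = int(row["bp"])
    for i in range(pos + 1, len(chrom)):
        row = chrom.iloc[i]
        if row["score"] < threshold or abs(row["bp"] - peak["bp"]) > window_mb * MB:
            break
        hi = int(row["bp"])
    return lo, hi


# ---------------------------------------------------------------------------
# Cross-trial merging and naming
# ---------------------------------------------------------------------------

@dataclass
class QtlRecord:
    name: str
    trait: str
    chromosome: str
    peak_marker: str
    peak_bp: int
    score: float
    effect: float
    interval: tuple[int, int]
    trials: list[str] = field(default_factory=list)
    variance_pct: float | None = None
    flagged: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.interval
        if not lo <= self.peak_bp <= hi:
            raise ValueError("interval must contain the peak")


def merge_qtls(
    peak_tables: dict[str, pd.DataFrame],
    window_mb: float,
    merge_multiplier: float = 3.0,
    lab: str = "sim",
    audit: list[str] | None = None,
) -> list[QtlRecord]:
    """Merge per-trial peaks into named QTLs.

    Peaks merge iff they share trait, chromosome and effect sign and
    are within ``merge_multiplier * window_mb`` of one another
    (single linkage), accommodating cross-trial peak shifts well beyond
    one LD window. Conflicting signs at the same position stay separate
    and are flagged. Each merged QTL takes its best-supported peak
    (highest score) as representative; names run in chromosome-then-bp
    order per trait. Merge decisions are appended to ``audit``.
    """
    rows = []
    for trial, table in peak_tables.items():
        for marker, r in table.iterrows():
            rows.append(
                {
                    "trial": trial,
                    "marker": marker,
                    "trait": r.get("trait", "trait"),
                    "chrom": r["chrom"],
                    "bp": int(r["bp"]),
                    "score": float(r["score"]),
                    "effect": float(r["effect"]),
                    "interval_lo": int(r.get("interval_lo", r["bp"])),
                    "interval_hi": int(r.get("interval_hi", r["bp"])),
                }
            )
    if not rows:
        return []
    peaks = pd.DataFrame(rows)
    peaks["sign"] = np.sign(peaks["effect"]).astype(int)
    merge_window = merge_multiplier * window_mb * MB
    records: list[QtlRecord] = []
    for (trait, chrom, sign), grp in peaks.groupby(["trait", "chrom", "sign"]):
        grp = grp.sort_values("bp", kind="mergesort")
        cluster_ids = (grp["bp"].diff().fillna(0) > merge_window).cumsum()
        for _, cl in grp.groupby(cluster_ids):
            best = cl.loc[cl["score"].idxmax()]
            rec = QtlRecord(
                name="",
                trait=trait,
                chromosome=str(chrom),
                peak_marker=best["marker"],
                peak_bp=int(best["bp"]),
                score=float(best["score"]),
                effect=float(best["effect"]),
                interval=(int(cl["interval_lo"].min()), int(cl["interval_hi"].max())),
                trials=sorted(cl["trial"].unique()),
            )
            records.append(rec)
            if audit is not None and len(cl) > 1:
                span = cl["bp"].max() - cl["bp"].min()
                audit.append(
                    f"merged {len(cl)} peaks ({trait}, {chrom}, sign {sign:+d}) "
                    f"spanning {span / MB:.1f} Mb into one QTL at {best['marker']}"
                )
    # flag opposite-sign records at identical position
    by_pos: dict[tuple, list[QtlRecord]] = {}
    for rec in records:
        by_pos.setdefault((rec.trait, rec.chromosome, rec.peak_bp), []).append(rec)
    for recs in by_pos.values():
        if len({np.sign(r.effect) for r in recs}) > 1:
            for r in recs:
                r.flagged = True
                if audit is not None:
                    audit.append(
                        f"conflicting effect signs at {r.chromosome}:{r.peak_bp} "
                        f"({r.trait}) kept separate"
                    )
    # names in chromosome-then-bp order per trait
    records.sort(key=lambda r: (r.trait, r.chromosome, r.peak_bp))
    counter: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.trait, rec.chromosome)
        counter[key] = counter.get(key, 0) + 1
        trait_token = rec.trait[:1].upper() + rec.trait[1:].lower()
        rec.name = f"Q{trait_token}.{lab}-{rec.chromosome}.{counter[key]}"
    return records


# ---------------------------------------------------------------------------
# Multi-QTL variance
# ---------------------------------------------------------------------------

def multi_qtl_variance(
    y: pd.Series,
    G: GenotypeMatrix,
    Q: pd.Series,
    K: pd.DataFrame,
    peak_markers: list[str],
) -> pd.Series:
    """Percent phenotypic variance explained by each QTL peak.

    All peaks enter one joint Q+K mixed model as fixed additive
    covariates; each peak's share is the partial R2 from dropping it
    (GLS residual sums of squares on the rotated scale), in percent of
    total phenotypic variation. Collinear peaks are pooled with a
    warning (the duplicate reports NaN).
    """
    ids = y.dropna().index.intersection(G.genotype_ids).intersection(Q.index)
    yv = y.loc[ids].to_numpy(dtype=float)
    X0 = _population_dummies(Q.loc[ids])
    D = G.dosages.loc[ids, peak_markers].to_numpy(dtype=float)
    if np.isnan(D).any():
        raise ValueError("peak dosages contain missing calls")
    keep, dropped = [], []
    for j in range(D.shape[1]):
        trial = np.column_stack([X0] + [D[:, k] for k in keep] + [D[:, j]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
        else:
            dropped.append(peak_markers[j])
    if dropped:
        import warnings

        warnings.warn(f"collinear peaks pooled: {dropped}")
    Kv = K.loc[ids, ids].to_numpy(dtype=float)
    Xfull = np.column_stack([X0, D[:, keep]])
    null = fit_null(yv, Xfull, Kv)
    w = np.sqrt(null.weights)
    yw = (null.U.T @ yv) * w

    def rss(Xm: np.ndarray) -> float:
        Xw = (null.U.T @ Xm) * w[:, None]
        Qx, _ = np.linalg.qr(Xw)
        r = yw - Qx @ (Qx.T @ yw)
        return float(r @ r)

    yw_c = yw - yw.mean()
    total = float(yw_c @ yw_c)
    rss_full = rss(Xfull)
    by_pos: dict[int, float] = {}
    for col in keep:
        Xred = np.column_stack([X0, D[:, [k for k in keep if k != col]]])
        by_pos[col] = 100.0 * max(rss(Xred) - rss_full, 0.0) / total
    return pd.Series(
        [by_pos.get(j, np.nan) for j in range(len(peak_markers))],
        index=peak_markers,
        name="variance_pct",
    )
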