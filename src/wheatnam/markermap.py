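"""Physical marker positioning from alignment hit tables, correlation
transfer, and two-pass LD-bin repositioning.

A marker map here is a DataFrame indexed by marker id with columns
``chrom`` (nullable string), ``bp`` (nullable int) and ``source``
(one of ``curated``, ``hit_median``, ``correlation``, ``ld_bin``;
unplaced markers have null chrom/bp). Alignment hits use the 12-column
tabular format (query, subject, %identity, length, mismatches, gaps,
qstart, qend, sstart, send, e-value, bitscore).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

HIT_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def empty_map(marker_ids) -> pd.DataFrame:
    return pd.DataFrame(
        {"chrom": pd.array([None] * len(marker_ids), dtype="string"),
         "bp": pd.array([None] * len(marker_ids), dtype="Int64"),
         "source": pd.array([None] * len(marker_ids), dtype="string")},
        index=pd.Index(marker_ids, name="marker"),
    )


def hit_midpoint(row: pd.Series) -> int:
    """Midpoint of an alignment, orientation-independent, floored."""
    return int((row["sstart"] + row["send"]) // 2)


def _best_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """One best hit per query: highest bitscore, then lowest e-value,
    then longest alignment, then lexicographic subject."""
    h = hits.sort_values(
        ["bitscore", "evalue", "length", "sseqid"],
        ascending=[False, True, False, True],
        kind="mergesort",
    )
    return h.groupby("qseqid", sort=False).head(1).set_index("qseqid")


def position_from_hits(
    hits: pd.DataFrame, marker_ids=None, base_map: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Place markers at the midpoint of their best alignment hit.

    Markers without hits are left unplaced. When ``base_map`` is given,
    only its unplaced markers are filled in (curated placements win).
    """
    if marker_ids is None:
        marker_ids = (
            base_map.index if base_map is not None else pd.unique(hits["qseqid"])
        )
    mmap = empty_map(marker_ids) if base_map is None else base_map.copy()
    best = _best_hits(hits[hits["qseqid"].isin(mmap.index)])
    for marker, row in best.iterrows():
        if pd.notna(mmap.at[marker, "chrom"]):
            continue
        mmap.at[marker, "chrom"] = row["sseqid"]
        mmap.at[marker, "bp"] = (int(row["sstart"]) + int(row["send"])) // 2
        mmap.at[marker, "source"] = "hit_median"
    return mmap


def _r2_matrix(dosages: pd.DataFrame, cols_a, cols_b=None) -> pd.DataFrame:
    """Pairwise-complete squared Pearson correlation between marker sets."""
    if cols_b is None:
        r = dosages[list(cols_a)].corr()
    else:
        both = list(dict.fromkeys(list(cols_a) + list(cols_b)))
        r = dosages[both].corr().loc[list(cols_a), list(cols_b)]
    return r**2


def position_by_correlation(
    mmap: pd.DataFrame,
    dosages: pd.DataFrame,
    hits: pd.DataFrame,
    min_r2: float = 0.2,
) -> pd.DataFrame:
    """Place unplaced markers via their highest-R2 placed partner.

    For each unplaced marker, take the placed marker with the highest
    squared correlation (if >= ``min_r2``); if the unplaced marker has
    any hit on that partner's chromosome, adopt the hit whose midpoint
    is nearest to the partner's position. No fallback: a best partner
    on a chromosome without hits leaves the marker unplaced.
    """
    out = mmap.copy()
    placed = out.index[out["chrom"].notna()]
    unplaced = out.index[out["chrom"].isna()]
    usable = [m for m in unplaced if m in dosages.columns]
    placed_in_g = [m for m in placed if m in dosages.columns]
    if not usable or not placed_in_g:
        return out
    r2 = _r2_matrix(dosages, usable, placed_in_g)
    hits_by_q = dict(tuple(hits.groupby("qseqid", sort=False)))
    for marker in usable:
        row = r2.loc[marker].dropna()
        if row.empty or row.max() < min_r2:
            continue
        partner = row.idxmax()
        chrom = out.at[partner, "chrom"]
        pos = int(out.at[partner, "bp"])
        h = hits_by_q.get(marker)
        if h is None:
            continue
        h = h[h["sseqid"] == chrom]
        if h.empty:
            continue
        mids = ((h["sstart"].astype(int) + h["send"].astype(int)) // 2).to_numpy()
        best = mids[np.argmin(np.abs(mids - pos))]
        out.at[marker, "chrom"] = chrom
        out.at[marker, "bp"] = int(best)
        out.at[marker, "source"] = "correlation"
    return out


def _ld_components(r2: np.ndarray, threshold: float) -> np.ndarray:
    adj = csr_matrix(np.nan_to_num(r2) > threshold)
    _, labels = connected_components(adj, directed=False)
    return labels


def ld_bin_reposition(
    dosages: pd.DataFrame,
    mmap: pd.DataFrame,
    hits: pd.DataFrame,
    r2_bin: float = 0.5,
    iterations: int = 2,
    majority: str = "strict",
) -> tuple[pd.DataFrame, int]:
    """Repair chromosome mis-assignments using high-LD marker bins.

    Each pass groups placed markers into bins — connected components of
    the R2 > ``r2_bin`` graph — and checks every marker against its
    bin: if its chromosome differs from the bin's majority chromosome
    (strict: more than half of the *other* bin members) and the marker
    has an alignment hit on that chromosome, it is repositioned to the
    midpoint of its best hit there. With no strict majority, the
    chromosome of the single highest-LD partner is the guide. Runs
    exactly ``iterations`` passes; returns the map and the number of
    repositioning events. Markers are never unplaced.
    """
    out = mmap.copy()
    hits_by_q = dict(tuple(hits.groupby("qseqid", sort=False)))
    total_moved = 0
    for _ in range(iterations):
        placed = [
            m
            for m in out.index[out["chrom"].notna()]
            if m in dosages.columns
        ]
        if len(placed) < 2:
            break
        r2 = _r2_matrix(dosages, placed).to_numpy()
        np.fill_diagonal(r2, 0.0)
        labels = _ld_components(r2, r2_bin)
        chrom = out.loc[placed, "chrom"].to_numpy()
        moves: list[tuple[str, str]] = []
        for lab in np.unique(labels):
            members = np.where(labels == lab)[0]
            if len(members) < 2:
                continue
            for i in members:
                others = members[members != i]
                counts = pd.Series(chrom[others]).value_counts()
                guide = None
                if majority == "strict":
                    if counts.iloc[0] * 2 > len(others):
                        guide = counts.index[0]
                else:  # plurality
                    if len(counts) == 1 or counts.iloc[0] > counts.iloc[1]:
                        guide = counts.index[0]
                if guide is None:
                    # no consensus: highest-LD partner's chromosome
                    j = others[np.argmax(np.nan_to_num(r2[i, others]))]
                    guide = chrom[j]
                if guide == chrom[i]:
                    continue
                moves.append((placed[i], guide))
        moved_this_pass = 0
        for marker, guide in moves:
            h = hits_by_q.get(marker)
            if h is None:
                continue
            h = h[h["sseqid"] == guide]
            if h.empty:
                continue
            best = h.sort_values(
                ["bitscore", "evalue", "length"],
                ascending=[False, True, False],
                kind="mergesort",
            ).iloc[0]
            out.at[marker, "chrom"] = guide
            out.at[marker, "bp"] = (int(best["sstart"]) + int(best["send"])) // 2
            out.at[marker, "source"] = "ld_bin"
            moved_this_pass += 1
        total_moved += moved_this_pass
    return out, total_moved


def adjacent_r2(dosages: pd.DataFrame, mmap: pd.DataFrame) -> float:
    """Mean R2 between bp-adjacent placed marker pairs within
    chromosomes; rises when mis-assigned markers are repaired."""
    vals = []
    placed = mmap[mmap["chrom"].notna()]
    for _, sub in placed.groupby("chrom"):
        order = sub.sort_values("bp").index
        order = [m for m in order if m in dosages.columns]
        for a, b in zip(order, order[1:]):
            r = dosages[a].corr(dosages[b])
            if pd.notna(r):
                vals.append(r**2)
    if not vals:
        raise ValueError("no adjacent within-chromosome pairs")
    return float(np.mean(vals))
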