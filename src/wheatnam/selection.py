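"""Breeder-selection summaries: selection proportions by donor
background and allele enrichment among selected genotypes.

These are descriptive tables — donor contributions across a nested
panel are unbalanced, so no inferential claims are attached beyond the
explicit two-group t-tests delegated to :mod:`wheatnam.trialmodel`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix


def summarize_by_background(
    table: pd.DataFrame,
    background: str = "tetraploid_parent",
    selected_col: str = "selected",
) -> pd.DataFrame:
    """Selection counts and percentages per donor background.

    ``table`` has one row per genotype with a background column (e.g.
    tetraploid donor id or diploid lineage label; missing labels are
    bucketed as "unknown") and a boolean/0-1 ``selected`` column.
    Returns per-background ``n_available, n_selected, pct_selected``
    (one decimal).
    """
    t = table.copy()
    t[background] = t[background].fillna("unknown").replace("", "unknown")
    grp = t.groupby(background)[selected_col]
    out = pd.DataFrame(
        {
            "n_available": grp.size(),
            "n_selected": grp.sum().astype(int),
        }
    )
    out["pct_selected"] = (100.0 * out["n_selected"] / out["n_available"]).round(1)
    return out


def allele_enrichment(
    selected: pd.Series,
    dosages: pd.Series,
    populations: pd.Series | None = None,
    carrier_min_dose: int = 2,
) -> pd.DataFrame:
    """2x2 carrier-by-selection counts at one marker.

    ``selected`` is a boolean Series per genotype; ``dosages`` the
    donor-allele dose at the locus. When ``populations`` is given, the
    table is restricted to genotypes from populations actually
    segregating at the locus (both dosage classes observed), since
    fixed populations carry no information about the allele. A carrier
    holds at least ``carrier_min_dose`` doses (default homozygous;
    pass 1 for het-inclusive carrier status). Proportions are reported
    to one decimal.
    """
    ids = selected.index.intersection(dosages.dropna().index)
    sel = selected.loc[ids].astype(bool)
    dos = dosages.loc[ids]
    if dos.nunique() < 2:
        raise ValueError(f"locus {dosages.name!r} is monomorphic in this set")
    if populations is not None:
        pops = populations.reindex(ids)
        seg = dos.groupby(pops).nunique()
        seg_pops = seg.index[seg > 1]
        keep = pops.isin(seg_pops)
        sel, dos = sel[keep], dos[keep]
    carrier = dos >= carrier_min_dose
    rows = []
    for label, m in (("selected", sel), ("unselected", ~sel)):
        n = int(m.sum())
        k = int((carrier & m).sum())
        rows.append(
            {
                "group": label,
                "carriers": k,
                "non_carriers": n - k,
                "n": n,
                "pct_carriers": round(100.0 * k / n, 1) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")


def enrichment_from_counts(
    selected_carriers: int,
    selected_total: int,
    unselected_carriers: int,
    unselected_total: int,
) -> pd.DataFrame:
    """The same 2x2 table built from already-tabulated counts."""
    rows = []
    for label, k, n in (
        ("selected", selected_carriers, selected_total),
        ("unselected", unselected_carriers, unselected_total),
    ):
        rows.append(
            {
                "group": label,
                "carriers": k,
                "non_carriers": n - k,
                "n": n,
                "pct_carriers": round(100.0 * k / n, 1),
            }
        )
    return pd.DataFrame(rows).set_index("group")


def selection_table(
    pedigree: pd.DataFrame,
    selections: dict[str, list[str]],
    lineages: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the per-genotype selection table.

    ``selections`` maps trial name -> list of genotype ids selected by
    any breeder in that trial; ``lineages`` optionally maps diploid
    donor id -> lineage label. Adds ``selected`` (any trial),
    ``selected_by`` (number of trials) and per-trial flags.
    """
    out = pedigree[["population", "tetraploid_parent", "diploid_parent"]].copy()
    count = pd.Series(0, index=out.index)
    for trial, ids in selections.items():
        flag = out.index.isin(ids)
        out[f"selected_{trial}"] = flag
        count += flag.astype(int)
    out["selected_by"] = count
    out["selected"] = count > 0
    if lineages is not None:
        out["lineage"] = out["diploid_parent"].map(lineages).fillna("unknown")
    return out
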