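"""Shared containers for the NAM pipeline.

Dosages follow the backcross convention used throughout the package:
0 = homozygous for the recurrent-parent (reference) allele,
2 = homozygous for the donor (alternative) allele, 1 = heterozygous,
NaN = missing call.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Genotypes x markers dosage table with population metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by genotype id with marker ids as columns;
        cells are 0/1/2 dosages of the donor allele, NaN for missing.
    populations
        Optional Series mapping each non-parent genotype id to its
        nested population. Parent rows (the recurrent parent and the
        per-population donors) may be absent from this map.
    recurrent_id
        Genotype id of the recurrent parent, if genotyped.
    donor_ids
        Mapping of population name -> genotype id of that population's
        donor parent, if genotyped.
    """

    dosages: pd.DataFrame
    populations: pd.Series | None = None
    recurrent_id: str | None = None
    donor_ids: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dosages.index.has_duplicates:
            raise ValueError("duplicate genotype ids")
        if self.dosages.columns.has_duplicates:
            raise ValueError("duplicate marker ids")
        self.dosages = self.dosages.astype(float)

    # -- basic accessors -------------------------------------------------
    @property
    def genotype_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def marker_ids(self) -> pd.Index:
        return self.dosages.columns

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def parent_ids(self) -> set[str]:
        ids = set(self.donor_ids.values())
        if self.recurrent_id is not None:
            ids.add(self.recurrent_id)
        return ids

    # -- derived statistics ----------------------------------------------
    def het_fraction(self, axis: str = "marker") -> pd.Series:
        """Fraction of heterozygous calls among non-missing calls."""
        d = self.dosages
        het = d == 1
        nonmiss = d.notna()
        ax = 0 if axis == "marker" else 1
        with np.errstate(invalid="ignore"):
            return het.sum(axis=ax) / nonmiss.sum(axis=ax)

    def missing_fraction(self, axis: str = "marker") -> pd.Series:
        ax = 0 if axis == "marker" else 1
        return self.dosages.isna().sum(axis=ax) / self.dosages.shape[ax]

    def minor_hom_counts(self) -> pd.Series:
        """Per-marker count of genotypes homozygous for the minor allele.

        The minor allele is the less frequent of the two; on a tie the
        smaller of the two homozygote counts is reported.
        """
        d = self.dosages
        n_ref_hom = (d == 0).sum(axis=0)
        n_alt_hom = (d == 2).sum(axis=0)
        freq_alt = d.mean(axis=0) / 2.0
        out = n_alt_hom.where(freq_alt < 0.5, n_ref_hom)
        tie = freq_alt == 0.5
        if tie.any():
            out[tie] = np.minimum(n_ref_hom[tie], n_alt_hom[tie])
        return out.astype(int)

    def subset(
        self,
        genotypes: pd.Index | list[str] | None = None,
        markers: pd.Index | list[str] | None = None,
    ) -> "GenotypeMatrix":
        d = self.dosages
        if genotypes is not None:
            d = d.loc[genotypes]
        if markers is not None:
            d = d[list(markers)]
        pops = None
        if self.populations is not None:
            pops = self.populations[self.populations.index.isin(d.index)]
        donor_ids = {p: g for p, g in self.donor_ids.items() if g in d.index}
        rec = self.recurrent_id if self.recurrent_id in d.index else None
        return GenotypeMatrix(d.copy(), pops, rec, donor_ids)

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages.copy(),
            None if self.populations is None else self.populations.copy(),
            self.recurrent_id,
            dict(self.donor_ids),
        )


def pairwise_r(dosages: pd.DataFrame, axis: str = "genotype") -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between genotypes or markers."""
    d = dosages if axis == "marker" else dosages.T
    return d.corr()  # pandas corr is pairwise-complete by default
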