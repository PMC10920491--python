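"""File formats: genotype CSV/VCF import, marker-map TSV, tabular
alignment (BLAST outfmt-6 style) hit tables, phenotype long CSV.

All external coordinates are 1-based inclusive. Missing dosages are
"NA" in CSV and "./." in VCF.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GenotypeMatrix
from .markermap import HIT_COLUMNS


def read_genotypes(
    path: str | Path,
    fmt: str | None = None,
    reference_sample: str | None = None,
) -> GenotypeMatrix:
    """Read a genotype dosage matrix from CSV or VCF.

    CSV dialect: header row of marker ids, first column genotype id,
    cells 0/1/2/NA. VCF: biallelic records only (others skipped with a
    count), GT -> ALT-allele dose; if ``reference_sample`` is given and
    carries the ALT allele homozygously at a record, doses at that
    record are flipped so the configured reference sample is dose 0.
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "csv"
    if fmt == "csv":
        df = pd.read_csv(path, index_col=0, na_values=["NA"], dtype=str)
        num = df.apply(pd.to_numeric, errors="coerce")
        bad = (df.notna() & num.isna()) | (num.notna() & ~num.isin([0.0, 1.0, 2.0]))
        if bad.any().any():
            i, j = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"malformed dosage {df.iat[i, j]!r} at genotype "
                f"{df.index[i]!r}, marker {df.columns[j]!r}"
            )
        return GenotypeMatrix(
            pd.DataFrame(
                num.to_numpy(dtype=float),
                index=df.index.astype(str),
                columns=df.columns,
            )
        )
    if fmt == "vcf":
        from cyvcf2 import VCF

        vcf = VCF(str(path), gts012=True)
        samples = list(vcf.samples)
        cols: dict[str, np.ndarray] = {}
        skipped = 0
        for rec in vcf:
            if len(rec.ALT) != 1:
                skipped += 1
                continue
            gt = rec.gt_types.astype(float)  # 0=hom ref, 1=het, 2=hom alt
            gt[gt == 3] = np.nan  # 3 = unknown ("./.")
            dose = gt
            mid = rec.ID or f"{rec.CHROM}_{rec.POS}"
            if reference_sample is not None and reference_sample in samples:
                ref_dose = dose[samples.index(reference_sample)]
                if ref_dose == 2.0:
                    dose = 2.0 - dose
            cols[mid] = dose
        if skipped:
            warnings.warn(f"skipped {skipped} non-biallelic VCF records")
        d = pd.DataFrame(cols, index=samples)
        return GenotypeMatrix(d)
    raise ValueError(f"unknown format {fmt!r}")


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    out = G.dosages.map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    out.to_csv(path)


def read_hits(path: str | Path) -> pd.DataFrame:
    """Parse a 12-column tab-separated alignment hit table.

    Reverse-orientation hits (sstart > send) are retained with
    ``reverse=True`` noted. An empty file yields an empty table with a
    warning; a row with the wrong column count is an error.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path.name}:{ln}: expected 12 tab-separated columns, "
                    f"got {len(parts)}"
                )
            rows.append(parts)
    if not rows:
        warnings.warn(f"{path.name}: empty hit table")
        return pd.DataFrame(columns=HIT_COLUMNS + ["reverse"])
    df = pd.DataFrame(rows, columns=HIT_COLUMNS)
    for col in ["pident", "evalue", "bitscore"]:
        df[col] = df[col].astype(float)
    for col in ["length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send"]:
        df[col] = df[col].astype(int)
    if (df[["sstart", "send"]] <= 0).any().any():
        raise ValueError("alignment coordinates must be positive")
    df["reverse"] = df["sstart"] > df["send"]
    return df


def read_marker_map(path: str | Path) -> pd.DataFrame:
    """TSV of marker, chrom, bp (1-based) with optional source column."""
    df = pd.read_csv(path, sep="\t", dtype={"marker": str, "chrom": str})
    df = df.set_index("marker")
    df["bp"] = df["bp"].astype("Int64")
    df["chrom"] = df["chrom"].astype("string")
    if "source" not in df.columns:
        df["source"] = pd.array(["curated"] * len(df), dtype="string")
    return df


def write_marker_map(mmap: pd.DataFrame, path: str | Path) -> None:
    mmap.to_csv(path, sep="\t", index_label="marker")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Long-format phenotype table: genotype, trial, plot, half, block,
    row, column, lid, scorer, trait, value (extra columns pass
    through)."""
    df = pd.read_csv(path)
    required = {"genotype", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)
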