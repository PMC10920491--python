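"""Synthetic backcross-NAM data: genetic maps, founders, crossing,
trial layouts and phenotypes.

The simulator reproduces the structure of a nested association mapping
panel in which many fully homozygous donors (synthetic hexaploid wheat,
each combining a tetraploid A/B-genome parent with a diploid D-genome
parent) are crossed to one recurrent elite parent, backcrossed once, and
advanced by single-seed descent to BC1F5. Dosages count the donor
(alternative) allele, with the recurrent parent as reference.

Meiosis follows the Haldane model: crossovers form a Poisson process on
the genetic (cM) map with no interference, so the recombination fraction
between loci d cM apart is (1 - exp(-2d/100)) / 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

WHEAT_CHROMOSOMES = [f"{i}{g}" for i in range(1, 8) for g in "ABD"]


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

@dataclass
class GeneticMap:
    """Marker positions on physical (bp, 1-based) and genetic (cM) scales.

    ``chromosomes`` is indexed by chromosome name with columns
    ``length_bp`` and ``length_cM``; ``markers`` is indexed by marker id
    with columns ``chrom``, ``bp`` and ``cM``, sorted by (chrom, bp).
    """

    chromosomes: pd.DataFrame
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        if self.chromosomes.index.has_duplicates:
            raise ValueError("chromosome names must be unique")
        if len(self.chromosomes) > 21:
            raise ValueError("at most 21 chromosomes")
        if (self.chromosomes[["length_bp", "length_cM"]] <= 0).any().any():
            raise ValueError("chromosome lengths must be positive")
        for name, sub in self.markers.groupby("chrom", sort=False):
            if not sub["bp"].is_monotonic_increasing or sub["bp"].duplicated().any():
                raise ValueError(f"bp positions not strictly increasing on {name}")
            if not sub["cM"].is_monotonic_increasing or sub["cM"].duplicated().any():
                raise ValueError(f"cM positions not strictly increasing on {name}")
            if (sub["cM"] < 0).any():
                raise ValueError("cM positions must be non-negative")

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def chrom_slices(self) -> dict[str, slice]:
        """Contiguous row slice of ``markers`` for each chromosome."""
        out: dict[str, slice] = {}
        chroms = self.markers["chrom"].to_numpy()
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[i - 1]:
                out[chroms[start]] = slice(start, i)
                start = i
        return out


def make_genetic_map(
    n_chromosomes: int = 21,
    markers_per_chromosome: int = 500,
    chrom_length_bp: int = 600_000_000,
    chrom_length_cM: float = 150.0,
    seed: int | None = None,
    spacing: str = "uniform",
) -> GeneticMap:
    """Build a genetic map with uniform or random marker spacing.

    cM positions are linearly interpolated from bp along each
    chromosome; chromosome names follow the hexaploid wheat convention
    (1A..7D).
    """
    if markers_per_chromosome < 2:
        raise ValueError("need >= 2 markers per chromosome")
    if chrom_length_bp <= 0 or chrom_length_cM <= 0:
        raise ValueError("chromosome lengths must be positive")
    if n_chromosomes < 1 or n_chromosomes > 21:
        raise ValueError("n_chromosomes must be in 1..21")
    rng = np.random.default_rng(seed)
    names = WHEAT_CHROMOSOMES[:n_chromosomes]
    m = markers_per_chromosome
    rows = []
    for name in names:
        if spacing == "uniform":
            bp = 1 + np.round(np.arange(m) * (chrom_length_bp - 1) / (m - 1)).astype(
                np.int64
            )
            cM = np.arange(m) * (chrom_length_cM / (m - 1))
            for j in range(m):
                rows.append((f"M_{name}_{j + 1:05d}", name, int(bp[j]), float(cM[j])))
            continue
        elif spacing == "random":
            bp = np.unique(rng.integers(1, chrom_length_bp + 1, size=m))
            while len(bp) < m:  # rare collisions at desk scales
                extra = rng.integers(1, chrom_length_bp + 1, size=m - len(bp))
                bp = np.unique(np.concatenate([bp, extra]))
        else:
            raise ValueError(f"unknown spacing {spacing!r}")
        cM = (bp - 1) / (chrom_length_bp - 1) * chrom_length_cM
        for j in range(m):
            rows.append((f"M_{name}_{j + 1:05d}", name, int(bp[j]), float(cM[j])))
    markers = pd.DataFrame(rows, columns=["marker", "chrom", "bp", "cM"]).set_index(
        "marker"
    )
    chromosomes = pd.DataFrame(
        {
            "length_bp": chrom_length_bp,
            "length_cM": chrom_length_cM,
        },
        index=pd.Index(names, name="chrom"),
    )
    return GeneticMap(chromosomes, markers)


# ---------------------------------------------------------------------------
# Founders
# ---------------------------------------------------------------------------

@dataclass
class Donor:
    donor_id: str
    genome: np.ndarray  # (2, n_markers) allele codes
    tetraploid_id: str  # A/B sub-genome parent
    diploid_id: str  # D sub-genome parent


@dataclass
class FounderSet:
    """Recurrent-parent and donor haplotypes over a shared marker set.

    Alleles are coded as donor-allele indicators relative to the
    recurrent parent: the recurrent parent carries 0 everywhere and a
    donor carries 1 at every marker where it differs from the recurrent
    parent.
    """

    recurrent_id: str
    recurrent: np.ndarray  # (2, n_markers)
    donors: list[Donor]
    marker_ids: pd.Index

    def __post_init__(self) -> None:
        for d in self.donors:
            if d.genome.shape != self.recurrent.shape:
                raise ValueError(f"donor {d.donor_id} genome shape mismatch")

    @property
    def n_donors(self) -> int:
        return len(self.donors)


def make_founders(
    gmap: GeneticMap,
    n_donors: int = 54,
    n_tetraploid: int = 15,
    n_diploid: int = 47,
    polymorphic_fraction: float = 0.5,
    seed: int | None = None,
    recurrent_id: str = "Robigus",
) -> FounderSet:
    """Draw fully homozygous founders for the nested cross.

    Each donor inherits one A/B sub-genome pattern from a tetraploid
    parent pool and one D sub-genome pattern from a diploid pool, so
    donors sharing a sub-genome parent are identical over that
    sub-genome. ``polymorphic_fraction`` is the chance a marker differs
    between a given founder pattern and the recurrent parent.
    """
    rng = np.random.default_rng(seed)
    m = gmap.n_markers
    chroms = gmap.markers["chrom"].to_numpy()
    subgenome = np.array([c[-1] for c in chroms])
    ab_mask = (subgenome == "A") | (subgenome == "B")
    d_mask = subgenome == "D"

    tetra_ids = [f"TD-{i + 1:03d}" for i in range(n_tetraploid)]
    dip_ids = [f"AT-{i + 1:03d}" for i in range(n_diploid)]
    tetra_patterns = {
        t: rng.random(m) < polymorphic_fraction for t in tetra_ids
    }
    dip_patterns = {d: rng.random(m) < polymorphic_fraction for d in dip_ids}

    donors = []
    for i in range(n_donors):
        # cycle pools first so each parent is used at least once when possible
        t = tetra_ids[i % n_tetraploid] if i < n_tetraploid else str(rng.choice(tetra_ids))
        d = dip_ids[i % n_diploid] if i < n_diploid else str(rng.choice(dip_ids))
        hap = np.zeros(m, dtype=np.int8)
        hap[ab_mask] = tetra_patterns[t][ab_mask]
        hap[d_mask] = dip_patterns[d][d_mask]
        donors.append(
            Donor(f"SHW.{i + 1:03d}", np.vstack([hap, hap]), t, d)
        )
    recurrent = np.zeros((2, m), dtype=np.int8)
    return FounderSet(recurrent_id, recurrent, donors, gmap.markers.index)


# ---------------------------------------------------------------------------
# Meiosis and crossing
# ---------------------------------------------------------------------------

def simulate_meiosis(
    parent: np.ndarray, gmap: GeneticMap, rng: np.random.Generator
) -> np.ndarray:
    """Produce one gamete from a (2, n_markers) parent under Haldane.

    Crossovers are a Poisson process on the cM map of each chromosome
    (rate 1 per 100 cM, no interference); the starting haplotype is
    chosen at random per chromosome.
    """
    if parent.shape[1] != gmap.n_markers:
        raise ValueError("parent haplotypes do not cover the map")
    gamete = np.empty(gmap.n_markers, dtype=parent.dtype)
    cM = gmap.markers["cM"].to_numpy()
    for chrom, sl in gmap.chrom_slices().items():
        length = float(gmap.chromosomes.loc[chrom, "length_cM"])
        n_xo = rng.poisson(length / 100.0)
        start = rng.integers(2)
        if n_xo == 0:
            hap = np.full(sl.stop - sl.start, start)
        else:
            xo = np.sort(rng.uniform(0.0, length, size=n_xo))
            hap = (start + np.searchsorted(xo, cM[sl])) % 2
        gamete[sl] = parent[hap, np.arange(sl.start, sl.stop)]
    return gamete


def _self(ind: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    return np.vstack(
        [simulate_meiosis(ind, gmap, rng), simulate_meiosis(ind, gmap, rng)]
    )


@dataclass
class CrossPlan:
    """The nested backcross scheme executed by :func:`build_nam`.

    Per population: F1 = recurrent x donor; BC1F1 = F1 x recurrent;
    ``n_bc1f1_streams`` BC1F1 plants each yield ``n_bc1f2_per_stream``
    BC1F2 by selfing; every BC1F2 is then advanced by single-seed
    descent until ``selfing_generations`` selfings separate it from its
    BC1F1 (4 selfings = BC1F5). ``target_size`` genotypes per population
    survive uniform random attrition (None keeps all).
    """

    n_populations: int = 54
    n_bc1f1_streams: int = 12
    n_bc1f2_per_stream: int = 8
    selfing_generations: int = 4
    target_size: int | None = 60

    def __post_init__(self) -> None:
        if self.selfing_generations < 1:
            raise ValueError("selfing_generations must be >= 1")
        if min(self.n_populations, self.n_bc1f1_streams, self.n_bc1f2_per_stream) < 1:
            raise ValueError("plan counts must be positive")

    @property
    def initial_population_size(self) -> int:
        return self.n_bc1f1_streams * self.n_bc1f2_per_stream


def build_nam(
    plan: CrossPlan,
    founders: FounderSet,
    gmap: GeneticMap,
    seed: int | None = None,
    keep_haplotypes: bool = False,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Execute the nested cross and return dosages plus pedigree records.

    Returns the genotype matrix (progeny plus parent rows, dosage =
    donor-allele count) and a pedigree table with one row per progeny
    genotype (population, stream, donor and sub-genome parent ids).
    """
    if plan.n_populations > founders.n_donors:
        raise IndexError(
            f"plan needs {plan.n_populations} donors, founders have {founders.n_donors}"
        )
    rng = np.random.default_rng(seed)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    ped_rows = []
    pop_of: dict[str, str] = {}
    donor_ids: dict[str, str] = {}
    haplotypes: dict[str, np.ndarray] = {}

    for p in range(plan.n_populations):
        donor = founders.donors[p]
        pop = f"P{p + 1:02d}"
        donor_ids[pop] = donor.donor_id
        f1 = np.vstack([founders.recurrent[0], donor.genome[0]])
        finals: list[np.ndarray] = []
        for s in range(plan.n_bc1f1_streams):
            bc1f1 = np.vstack(
                [
                    simulate_meiosis(f1, gmap, rng),
                    simulate_meiosis(founders.recurrent, gmap, rng),
                ]
            )
            for k in range(plan.n_bc1f2_per_stream):
                ind = _self(bc1f1, gmap, rng)  # BC1F2
                for _ in range(plan.selfing_generations - 1):
                    ind = _self(ind, gmap, rng)  # SSD to BC1F{g+1}
                finals.append(ind)
                gen = plan.selfing_generations + 1
                ped_rows.append(
                    (
                        f"{pop}-{s + 1:02d}-{k + 1:02d}",
                        pop,
                        s + 1,
                        donor.donor_id,
                        donor.tetraploid_id,
                        donor.diploid_id,
                        f"BC1F{gen}",
                    )
                )
        keep = np.arange(len(finals))
        if plan.target_size is not None and plan.target_size < len(finals):
            keep = np.sort(
                rng.choice(len(finals), size=plan.target_size, replace=False)
            )
        base = len(ids)
        # dosage = donor-allele count (recurrent carries 0 everywhere)
        for j in keep:
            ind = finals[j]
            gid = ped_rows[base + j][0]
            rows.append((ind[0] != 0).astype(np.int16) + (ind[1] != 0).astype(np.int16))
            ids.append(gid)
            pop_of[gid] = pop
            if keep_haplotypes:
                haplotypes[gid] = ind
        # drop pedigree rows for attrited genotypes
        ped_keep = set(base + j for j in keep)
        ped_rows = [r for i, r in enumerate(ped_rows) if i < base or i in ped_keep]

    pedigree = pd.DataFrame(
        ped_rows,
        columns=[
            "genotype",
            "population",
            "stream",
            "donor",
            "tetraploid_parent",
            "diploid_parent",
            "generation",
        ],
    ).set_index("genotype")

    # parent rows: recurrent and each used donor
    parent_dosages = {founders.recurrent_id: np.zeros(gmap.n_markers, dtype=np.int16)}
    for p in range(plan.n_populations):
        d = founders.donors[p]
        parent_dosages[d.donor_id] = (
            (d.genome[0] != 0).astype(np.int16) + (d.genome[1] != 0).astype(np.int16)
        )
    all_ids = ids + list(parent_dosages)
    data = np.vstack(rows + list(parent_dosages.values()))
    dosages = pd.DataFrame(data.astype(float), index=all_ids, columns=founders.marker_ids)
    G = GenotypeMatrix(
        dosages,
        populations=pd.Series(pop_of, name="population"),
        recurrent_id=founders.recurrent_id,
        donor_ids=donor_ids,
    )
    if keep_haplotypes:
        G.haplotypes = haplotypes  # type: ignore[attr-defined]
    return G, pedigree


def donor_genome_fraction(G: GenotypeMatrix, pedigree: pd.DataFrame) -> pd.Series:
    """Per-progeny mean donor-allele dose / 2 over that population's
    donor-polymorphic markers."""
    out = {}
    for gid, row in pedigree.iterrows():
        donor_row = G.dosages.loc[G.donor_ids[row["population"]]]
        poly = donor_row > 0
        out[gid] = G.dosages.loc[gid, poly.to_numpy()].mean() / 2.0
    return pd.Series(out, name="donor_fraction")


# ---------------------------------------------------------------------------
# Trial layout
# ---------------------------------------------------------------------------

def build_trial_layout(
    entries: list[str],
    checks: dict[str, int],
    seed: int | None = None,
    replicated: dict[str, int] | None = None,
    block_size_range: tuple[int, int] = (144, 156),
    lid_size: int = 20,
    scorers: list[str] | None = None,
) -> pd.DataFrame:
    """Randomize an augmented two-unit-per-plot (half-plot) field trial.

    Replicated checks (and any other replicated entries) are distributed
    randomly across blocks first, never placing the same genotype in
    both halves of one plot; unreplicated entries fill the remaining
    units. Returns a unit-level table with ``unit_id, plot, half, block,
    row, column, lid, scorer, genotype, is_check`` and the realized
    check-unit fraction in ``.attrs["check_fraction"]``.
    """
    rng = np.random.default_rng(seed)
    replicated = dict(replicated or {})
    rep_units: list[str] = []
    for gid, n in {**checks, **replicated}.items():
        if n < 1:
            raise ValueError(f"replicate count for {gid} must be >= 1")
        rep_units += [gid] * n
    n_units = len(entries) + len(rep_units)
    if n_units % 2:
        raise ValueError("total entries must be even (two per plot)")
    n_plots = n_units // 2
    lo, hi = block_size_range
    if max(checks.values(), default=0) > n_plots:
        raise ValueError("more replicates of one check than plots")

    # blocks as equal as possible within the configured size range
    n_blocks = max(1, -(-n_plots // hi))
    sizes = np.full(n_blocks, n_plots // n_blocks)
    sizes[: n_plots % n_blocks] += 1
    if n_plots >= lo and (sizes < lo).any():
        raise ValueError("cannot satisfy block size range")
    block_of = np.repeat(np.arange(n_blocks), sizes)
    row_of = np.empty(n_plots, dtype=int)
    col_of = np.empty(n_plots, dtype=int)
    start = 0
    for b, sz in enumerate(sizes):
        ncol = int(np.ceil(np.sqrt(sz)))
        idx = np.arange(sz)
        row_of[start : start + sz] = idx // ncol
        col_of[start : start + sz] = idx % ncol
        start += sz

    # place replicated units one per visit over a shuffled plot cycle
    plots: list[list[str]] = [[] for _ in range(n_plots)]
    rng.shuffle(rep_units)
    order = rng.permutation(n_plots)
    cursor = 0
    for gid in rep_units:
        placed = False
        for step in range(n_plots):
            p = order[(cursor + step) % n_plots]
            if len(plots[p]) < 2 and gid not in plots[p]:
                plots[p].append(gid)
                cursor = (cursor + step + 1) % n_plots
                placed = True
                break
        if not placed:
            raise ValueError("infeasible replicate counts for layout")
    fill = list(entries)
    rng.shuffle(fill)
    it = iter(fill)
    for p in range(n_plots):
        while len(plots[p]) < 2:
            plots[p].append(next(it))

    check_set = set(checks)
    units = []
    for p in range(n_plots):
        for half in (1, 2):
            gid = plots[p][half - 1]
            units.append(
                (
                    f"U{p + 1:05d}.{half}",
                    p + 1,
                    half,
                    int(block_of[p]) + 1,
                    int(row_of[p]) + 1,
                    int(col_of[p]) + 1,
                    p // lid_size + 1,
                    (scorers or ["S1"])[p * len(scorers or ["S1"]) // n_plots],
                    gid,
                    gid in check_set,
                )
            )
    layout = pd.DataFrame(
        units,
        columns=[
            "unit_id",
            "plot",
            "half",
            "block",
            "row",
            "column",
            "lid",
            "scorer",
            "genotype",
            "is_check",
        ],
    )
    layout.attrs["check_fraction"] = float(layout["is_check"].mean())
    return layout


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

@dataclass
class QtlEffect:
    """A planted QTL: additive effect per donor-allele dose at a marker."""

    marker: str
    effect: float
    carriers: list[str] | None = None  # donor ids expected to segregate (metadata)


@dataclass
class TraitModel:
    """Generative model for one trait on the trial.

    Unit value = mean + sum(QTL effect x dosage) + polygenic value +
    block + row + column + scorer + lid effects + residual; every random
    term is drawn from N(0, its variance). The polygenic value is built
    from ``n_background`` random markers so that genomic relatedness
    carries real signal (set ``polygenic_mode='iid'`` for an
    unstructured draw). Check varieties take fixed true values
    (``check_means``, defaulting to the trait mean).
    """

    trait: str
    mean: float = 0.0
    qtls: list[QtlEffect] = field(default_factory=list)
    polygenic_var: float = 0.0
    residual_var: float = 1.0
    block_var: float = 0.0
    row_var: float = 0.0
    col_var: float = 0.0
    scorer_var: float = 0.0
    lid_var: float = 0.0
    check_means: dict[str, float] = field(default_factory=dict)
    n_background: int = 200
    polygenic_mode: str = "marker"

    def __post_init__(self) -> None:
        for v in (
            self.polygenic_var,
            self.residual_var,
            self.block_var,
            self.row_var,
            self.col_var,
            self.scorer_var,
            self.lid_var,
        ):
            if v < 0:
                raise ValueError("variances must be non-negative")


def genetic_values(
    G: GenotypeMatrix, model: TraitModel, rng: np.random.Generator
) -> pd.Series:
    """True genetic value (mean + QTL + polygenic) per genotype in G."""
    for q in model.qtls:
        if q.marker not in G.dosages.columns:
            raise KeyError(f"planted QTL marker {q.marker} not in genotype matrix")
    g = pd.Series(model.mean, index=G.dosages.index, dtype=float)
    for q in model.qtls:
        g = g + q.effect * G.dosages[q.marker].fillna(0)
    if model.polygenic_var > 0:
        if model.polygenic_mode == "marker":
            k = min(model.n_background, G.n_markers)
            cols = rng.choice(G.n_markers, size=k, replace=False)
            W = G.dosages.iloc[:, cols].fillna(0).to_numpy()
            u = W @ rng.normal(size=k)
            sd = u.std()
            u = u - u.mean()
            if sd > 0:
                u *= np.sqrt(model.polygenic_var) / sd
        else:
            u = rng.normal(0, np.sqrt(model.polygenic_var), size=G.n_genotypes)
        g = g + u
    return g


def simulate_phenotypes(
    G: GenotypeMatrix,
    models: list[TraitModel],
    layout: pd.DataFrame,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw half-plot trait records for a trial layout.

    Returns a long table: one row per unit per trait, with all layout
    factors plus ``trait`` and ``value``.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for model in models:
        is_check = layout["is_check"].to_numpy()
        missing = (
            set(layout.loc[~is_check, "genotype"]) - set(G.dosages.index)
        )
        if missing:
            raise KeyError(
                f"layout genotypes absent from genotype matrix: {sorted(missing)[:5]}"
            )
        gvals = genetic_values(G, model, rng)
        for c in set(layout.loc[is_check, "genotype"]):
            gvals.loc[c] = model.check_means.get(c, model.mean)
        value = layout["genotype"].map(gvals).to_numpy(dtype=float)

        def add(col: str, var: float, keys=None) -> None:
            nonlocal value
            if var <= 0:
                return
            levels = keys if keys is not None else layout[col].astype(str)
            uniq = pd.unique(levels)
            eff = pd.Series(rng.normal(0, np.sqrt(var), size=len(uniq)), index=uniq)
            value = value + levels.map(eff).to_numpy()

        add("block", model.block_var)
        add("row", model.row_var, layout["block"].astype(str) + ":" + layout["row"].astype(str))
        add("column", model.col_var, layout["block"].astype(str) + ":" + layout["column"].astype(str))
        add("scorer", model.scorer_var)
        add("lid", model.lid_var)
        value = value + rng.normal(0, np.sqrt(model.residual_var), size=len(layout))

        out = layout.copy()
        out["trait"] = model.trait
        out["value"] = value
        frames.append(out)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Missingness / error injection
# ---------------------------------------------------------------------------

def inject_missing_and_errors(
    G: GenotypeMatrix,
    missing_rate: float = 0.0,
    error_rate: float = 0.0,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Mask calls at random (MCAR) and flip dosages by +/-1 to mimic
    genotyping error; heterozygote errors go to either homozygote."""
    for r in (missing_rate, error_rate):
        if not 0 <= r <= 1:
            raise ValueError("rates must be in [0, 1]")
    out = G.copy()
    if missing_rate == 0 and error_rate == 0:
        return out
    rng = np.random.default_rng(seed)
    d = out.dosages.to_numpy()
    if error_rate > 0:
        err = rng.random(d.shape) < error_rate
        err &= ~np.isnan(d)
        up = rng.random(d.shape) < 0.5
        new = np.where(d == 0, 1, np.where(d == 2, 1, np.where(up, 0, 2)))
        d[err] = new[err]
    if missing_rate > 0:
        d[rng.random(d.shape) < missing_rate] = np.nan
    out.dosages = pd.DataFrame(d, index=G.dosages.index, columns=G.dosages.columns)
    return out
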