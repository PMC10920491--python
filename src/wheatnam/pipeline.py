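"""End-to-end orchestration: simulate -> qc -> reposition -> structure
-> blues -> gwas -> qtl -> select.

Each stage writes headered TSV/CSV artifacts plus a machine-readable
``report.json`` into the output directory; the resolved configuration
(with its hash and seed) is echoed alongside. Stage failures halt the
run with the stage name; earlier artifacts remain valid.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import genoqc, io, markermap, namgwas, qtlcall, selection, structure, trialmodel
from .config import PipelineConfig
from .core import GenotypeMatrix
from .simdata import (
    CrossPlan,
    QtlEffect,
    TraitModel,
    build_nam,
    build_trial_layout,
    inject_missing_and_errors,
    make_founders,
    make_genetic_map,
    simulate_phenotypes,
)

log = logging.getLogger("wheatnam.pipeline")

TRAITS = ("Ft", "Ph", "Yr")


def default_trait_models(gmap, rng: np.random.Generator) -> list[TraitModel]:
    """Trait models emulating the study's three traits.

    Flowering time (days), plant height (cm) and yellow-rust cover (%),
    each with one planted QTL (donor allele: earlier flowering, taller
    plants, rust resistance), a polygenic term and spatial trial
    variances. Means and directions follow the recurrent parent's
    phenotype; variance ratios give trait repeatabilities in the
    0.7-0.9 range typical of these traits.
    """
    markers = gmap.markers

    def pick(chrom: str, frac: float) -> str:
        sub = markers[markers["chrom"] == chrom]
        if sub.empty:
            sub = markers
        return sub.index[int(frac * (len(sub) - 1))]

    common = dict(block_var=0.5, row_var=0.2, col_var=0.2, lid_var=0.1)
    return [
        TraitModel(
            trait="Ft",
            mean=215.9,
            qtls=[QtlEffect(pick("2B", 0.1), -1.0)],
            polygenic_var=4.0,
            residual_var=1.5,
            **common,
        ),
        TraitModel(
            trait="Ph",
            mean=71.8,
            qtls=[QtlEffect(pick("6A", 0.4), 3.0)],
            polygenic_var=25.0,
            residual_var=8.0,
            **common,
        ),
        TraitModel(
            trait="Yr",
            mean=5.0,
            qtls=[QtlEffect(pick("4D", 0.01), -2.0)],
            polygenic_var=4.0,
            residual_var=2.0,
            **common,
        ),
    ]


def _stage_simulate(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    sc = cfg.simulate
    rng = np.random.default_rng(cfg.seed)
    gmap = make_genetic_map(
        sc.n_chromosomes,
        sc.markers_per_chromosome,
        sc.chrom_length_bp,
        sc.chrom_length_cM,
        seed=cfg.seed,
    )
    founders = make_founders(
        gmap,
        n_donors=sc.n_populations,
        n_tetraploid=min(sc.n_tetraploid, sc.n_populations),
        n_diploid=min(sc.n_diploid, sc.n_populations),
        polymorphic_fraction=sc.polymorphic_fraction,
        seed=cfg.seed + 1,
    )
    plan = CrossPlan(
        n_populations=sc.n_populations,
        n_bc1f1_streams=sc.n_bc1f1_streams,
        n_bc1f2_per_stream=sc.n_bc1f2_per_stream,
        selfing_generations=sc.selfing_generations,
        target_size=sc.target_size,
    )
    G, pedigree = build_nam(plan, founders, gmap, seed=cfg.seed + 2)
    progeny = pedigree.index.tolist()

    # checks sized so check units make up about the configured fraction
    n_entries = len(progeny) + len(G.parent_ids())
    n_checks_total = int(round(sc.check_fraction / (1 - sc.check_fraction) * n_entries))
    if (n_entries + n_checks_total) % 2:
        n_checks_total += 1
    weights = np.array([0.29, 0.28, 0.43])
    reps = np.maximum((weights * n_checks_total).round().astype(int), 1)
    reps[0] += n_checks_total - reps.sum()
    checks = {
        G.recurrent_id or "Robigus": int(reps[0]),
        "Check-B": int(reps[1]),
        "Check-C": int(reps[2]),
    }
    layout = build_trial_layout(
        progeny + sorted(G.parent_ids()),
        checks,
        seed=cfg.seed + 3,
        block_size_range=(1, max(144, (n_entries + n_checks_total) // 2)),
    )
    models = default_trait_models(gmap, rng)
    phenos = simulate_phenotypes(G, models, layout, seed=cfg.seed + 4)
    G_obs = inject_missing_and_errors(
        G, sc.missing_rate, sc.error_rate, seed=cfg.seed + 5
    )

    # true map, with synthetic perfect alignment hits at the true position
    mmap = pd.DataFrame(
        {
            "chrom": gmap.markers["chrom"].astype("string"),
            "bp": gmap.markers["bp"].astype("Int64"),
            "source": pd.array(["curated"] * len(gmap.markers), dtype="string"),
        }
    )
    mmap.index.name = "marker"
    hits = pd.DataFrame(
        {
            "qseqid": gmap.markers.index,
            "sseqid": gmap.markers["chrom"].to_numpy(),
            "pident": 100.0,
            "length": 101,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 1,
            "qend": 101,
            "sstart": np.maximum(gmap.markers["bp"].to_numpy() - 50, 1),
            "send": gmap.markers["bp"].to_numpy() + 50,
            "evalue": 1e-50,
            "bitscore": 200.0,
        }
    ).reset_index(drop=True)
    hits["send"] = hits["sstart"] + 100  # keep midpoint == bp

    # breeder selections favour rust resistance with breeder-specific noise
    yr_true = phenos[phenos["trait"] == "Yr"].groupby("genotype")["value"].mean()
    z = -(yr_true.reindex(progeny) - yr_true.mean()) / (yr_true.std() or 1.0)
    sel_rng = np.random.default_rng(cfg.seed + 6)
    selections = {}
    for b in range(sc.n_breeders):
        p = 1.0 / (1.0 + np.exp(-(z + sel_rng.normal(0, 1, len(z)) - 0.5)))
        selections[f"breeder{b + 1}"] = list(np.array(progeny)[sel_rng.random(len(z)) < p])
    lineages = pd.Series(
        {
            d: f"L{1 + i % 3}"
            for i, d in enumerate(sorted(pedigree["diploid_parent"].unique()))
        },
        name="lineage",
    )

    io.write_genotypes(G_obs, out / "genotypes.csv")
    io.write_table(pedigree, out / "pedigree.tsv")
    io.write_marker_map(mmap, out / "marker_map.tsv")
    hits.to_csv(out / "hits.tsv", sep="\t", header=False, index=False)
    io.write_table(layout, out / "layout.tsv", index=False)
    phenos.to_csv(out / "phenotypes.csv", index=False)
    sel_df = pd.DataFrame(
        [(t, g) for t, ids in selections.items() for g in ids],
        columns=["breeder", "genotype"],
    )
    io.write_table(sel_df, out / "selections.tsv", index=False)
    lineages.rename_axis("diploid_parent").to_frame().to_csv(
        out / "lineages.tsv", sep="\t"
    )

    state.update(
        G_true=G,
        G=G_obs,
        pedigree=pedigree,
        gmap=gmap,
        mmap=mmap.drop(columns=[]),
        hits=hits.assign(reverse=False),
        layout=layout,
        phenotypes=phenos,
        selections=selections,
        lineages=lineages,
        models=models,
    )
    return {
        "genotypes": G_obs.n_genotypes,
        "markers": G_obs.n_markers,
        "populations": sc.n_populations,
        "units": len(layout),
        "check_fraction": round(layout.attrs["check_fraction"], 4),
    }


def _stage_qc(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    q = cfg.qc
    G = state["G"]
    report = genoqc.QcReport()
    G1, _ = genoqc.filter_markers(
        G, q.het_max, q.missing_max, q.min_minor_hom, report
    )
    G2, _ = genoqc.filter_genotypes(G1, q.het_max, report)
    pairs, G3, _ = genoqc.detect_duplicates(
        G2,
        genoqc.DuplicatePolicy(q.duplicate_r_abs, q.duplicate_k_sd),
        report,
        drop=True,
    )
    flagged, _ = genoqc.nonparental_allele_check(
        G3, q.nonparental_threshold, report
    )
    keep = [g for g in G3.genotype_ids if g not in set(flagged.index)]
    G4 = G3.subset(genotypes=keep)
    G5, _ = genoqc.impute_missing(
        G4, n_trees=q.impute_trees, max_iter=q.impute_max_iter, seed=cfg.seed + 10
    )
    io.write_genotypes(G5, out / "genotypes_qc.csv")
    io.write_table(report.to_frame(), out / "qc_report.tsv", index=False)
    state["G"] = G5
    log.info(
        "qc: %d markers and %d genotypes progressed", G5.n_markers, G5.n_genotypes
    )
    return {
        "markers_retained": G5.n_markers,
        "genotypes_retained": G5.n_genotypes,
        "duplicate_pairs": len(pairs),
        "nonparental_flagged": len(flagged),
    }


def _stage_reposition(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    G = state["G"]
    mmap = state["mmap"].loc[state["mmap"].index.isin(G.marker_ids)]
    mmap = markermap.position_from_hits(state["hits"], base_map=mmap)
    mmap = markermap.position_by_correlation(
        mmap, G.dosages, state["hits"], cfg.reposition.correlation_min_r2
    )
    mmap, moved = markermap.ld_bin_reposition(
        G.dosages,
        mmap,
        state["hits"],
        r2_bin=cfg.reposition.r2_bin,
        iterations=cfg.reposition.iterations,
    )
    io.write_marker_map(mmap, out / "marker_map_final.tsv")
    state["mmap"] = mmap
    return {
        "placed": int(mmap["chrom"].notna().sum()),
        "repositioned": moved,
    }


def _stage_structure(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    G = state["G"]
    mmap = state["mmap"]
    order = mmap.loc[mmap.index.isin(G.marker_ids)].sort_values(
        ["chrom", "bp"]
    ).index.tolist()
    kept = structure.skim_markers(G.dosages, cfg.structure.skim_r, order)
    res = structure.pcoa(G.subset(markers=kept), n_axes=cfg.structure.n_axes)
    coords = res.samples
    coords.index = G.genotype_ids
    io.write_table(coords, out / "pcoa_coordinates.tsv")
    pv = (res.proportion_explained * 100).round(2)
    io.write_table(pv.to_frame("percent_variance"), out / "pcoa_variance.tsv")
    state["skimmed_markers"] = kept
    return {
        "markers_skimmed_to": len(kept),
        "pcoa1_pct": float(pv.iloc[0]),
        "pcoa2_pct": float(pv.iloc[1]) if len(pv) > 1 else float("nan"),
    }


def _stage_blues(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    phenos = state["phenotypes"]
    spec = trialmodel.TrialModelSpec(
        elimination_alpha=cfg.blues.elimination_alpha
    )
    tables = {}
    h2 = {}
    varcomps = {}
    for trait in phenos["trait"].unique():
        sub = phenos[phenos["trait"] == trait]
        table, vc, meta = trialmodel.fit_blues(sub, spec)
        tables[trait] = table["blue"]
        varcomps[trait] = vc
        h2[trait], _ = trialmodel.heritability(
            sub, spec, retained_terms=tuple(meta["retained_terms"])
        )
    blues = pd.DataFrame(tables)
    blues.index.name = "genotype"
    io.write_table(blues, out / "blues.tsv")
    io.write_table(
        pd.DataFrame(varcomps).T.rename_axis("trait"), out / "variance_components.tsv"
    )
    io.write_table(
        pd.Series(h2, name="H2").rename_axis("trait").to_frame(),
        out / "heritability.tsv",
    )
    state["blues"] = blues
    return {"traits": list(tables), "H2": {k: round(v, 3) for k, v in h2.items()}}


def _stage_gwas(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    G: GenotypeMatrix = state["G"]
    blues: pd.DataFrame = state["blues"]
    mmap = state["mmap"]
    ids = [g for g in blues.index if g in G.genotype_ids and G.populations is not None
           and g in G.populations.index]
    Gs = G.subset(genotypes=ids)
    Q = G.populations.loc[ids]
    scan_markers = namgwas.prepare_scan_markers(Gs, cfg.gwas.min_minor_hom)
    K = namgwas.compute_kinship(Gs, cfg.gwas.kinship_skim_r, markers=scan_markers)
    threshold, meff = namgwas.significance_threshold(
        Gs.dosages[scan_markers], mmap, cfg.gwas.alpha
    )
    scans = {}
    info = {"threshold": round(threshold, 3), "m_eff": round(meff, 1)}
    for trait in blues.columns:
        sc = namgwas.scan(
            blues[trait], Gs, Q, K, markers=scan_markers, mmap=mmap
        )
        sc.to_csv(out / f"gwas_{trait}.tsv", sep="\t")
        scans[trait] = sc
        info[f"lambda_{trait}"] = round(float(sc.attrs["inflation"]), 3)
    state.update(scans=scans, threshold=threshold, scan_markers=scan_markers, K=K, Q=Q)
    return info


def _stage_qtl(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    G: GenotypeMatrix = state["G"]
    mmap = state["mmap"]
    profile = qtlcall.ld_decay_window(
        G.dosages[state["scan_markers"]], mmap, cfg.qtl.critical_r2,
        seed=cfg.seed + 20,
    )
    io.write_table(profile.binned, out / "ld_decay.tsv", index=False)
    audit: list[str] = []
    records = []
    for trait, sc in state["scans"].items():
        peaks = qtlcall.call_peaks(sc, state["threshold"], profile.window_mb)
        if peaks.empty:
            continue
        peaks = peaks.assign(trait=trait)
        intervals = [
            qtlcall.qtl_interval(sc, m, state["threshold"], profile.window_mb)
            for m in peaks.index
        ]
        peaks["interval_lo"] = [iv[0] for iv in intervals]
        peaks["interval_hi"] = [iv[1] for iv in intervals]
        recs = qtlcall.merge_qtls(
            {"sim_trial": peaks},
            profile.window_mb,
            cfg.qtl.merge_multiplier,
            lab=cfg.qtl.lab,
            audit=audit,
        )
        if recs:
            shares = qtlcall.multi_qtl_variance(
                state["blues"][trait].loc[state["Q"].index],
                G,
                state["Q"],
                state["K"],
                [r.peak_marker for r in recs],
            )
            for r in recs:
                r.variance_pct = float(shares.get(r.peak_marker, np.nan))
        records += recs
    table = pd.DataFrame(
        [
            {
                "name": r.name,
                "trait": r.trait,
                "chrom": r.chromosome,
                "peak_marker": r.peak_marker,
                "peak_bp": r.peak_bp,
                "score": round(r.score, 2),
                "effect": round(r.effect, 3),
                "interval_lo": r.interval[0],
                "interval_hi": r.interval[1],
                "trials": ";".join(r.trials),
                "variance_pct": None if r.variance_pct is None else round(r.variance_pct, 2),
            }
            for r in records
        ]
    )
    io.write_table(table, out / "qtl_table.tsv", index=False)
    (out / "qtl_audit.log").write_text("\n".join(audit) + "\n" if audit else "")
    state["qtls"] = records
    state["ld_window_mb"] = profile.window_mb
    return {"ld_window_mb": profile.window_mb, "n_qtls": len(records)}


def _stage_select(cfg: PipelineConfig, out: Path, state: dict) -> dict:
    table = selection.selection_table(
        state["pedigree"], state["selections"], state["lineages"]
    )
    by_tetra = selection.summarize_by_background(table, "tetraploid_parent")
    by_lineage = selection.summarize_by_background(table, "lineage")
    io.write_table(table, out / "selection_table.tsv")
    io.write_table(by_tetra, out / "selection_by_tetraploid.tsv")
    io.write_table(by_lineage, out / "selection_by_lineage.tsv")
    info = {"selected_total": int(table["selected"].sum()), "n": len(table)}
    yr_qtls = [r for r in state.get("qtls", []) if r.trait == "Yr"]
    if yr_qtls:
        peak = yr_qtls[0].peak_marker
        G: GenotypeMatrix = state["G"]
        try:
            enr = selection.allele_enrichment(
                table["selected"],
                G.dosages[peak],
                G.populations,
                cfg.select.carrier_min_dose,
            )
            io.write_table(enr, out / "allele_enrichment.tsv")
            info["enrichment_marker"] = peak
        except ValueError:
            pass
    return info


STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "reposition": _stage_reposition,
    "structure": _stage_structure,
    "blues": _stage_blues,
    "gwas": _stage_gwas,
    "qtl": _stage_qtl,
    "select": _stage_select,
}


def load_state(out: Path) -> dict:
    """Rehydrate pipeline state from a previous run's artifacts so a
    single stage can be re-run in isolation."""
    state: dict = {}
    geno_path = (
        out / "genotypes_qc.csv"
        if (out / "genotypes_qc.csv").exists()
        else out / "genotypes.csv"
    )
    if geno_path.exists():
        G = io.read_genotypes(geno_path)
        if (out / "pedigree.tsv").exists():
            ped = pd.read_csv(out / "pedigree.tsv", sep="\t", index_col=0)
            state["pedigree"] = ped
            pops = ped["population"]
            G.populations = pops[pops.index.isin(G.genotype_ids)]
            if "Robigus" in G.genotype_ids:
                G.recurrent_id = "Robigus"
            donors = ped[["population", "donor"]].drop_duplicates()
            G.donor_ids = {
                p: d
                for p, d in zip(donors["population"], donors["donor"])
                if d in G.genotype_ids
            }
        state["G"] = G
    map_path = (
        out / "marker_map_final.tsv"
        if (out / "marker_map_final.tsv").exists()
        else out / "marker_map.tsv"
    )
    if map_path.exists():
        state["mmap"] = io.read_marker_map(map_path)
    if (out / "hits.tsv").exists():
        state["hits"] = io.read_hits(out / "hits.tsv")
    if (out / "layout.tsv").exists():
        state["layout"] = pd.read_csv(out / "layout.tsv", sep="\t")
    if (out / "phenotypes.csv").exists():
        state["phenotypes"] = io.read_phenotypes(out / "phenotypes.csv")
    if (out / "blues.tsv").exists():
        state["blues"] = pd.read_csv(out / "blues.tsv", sep="\t", index_col=0)
    if (out / "selections.tsv").exists():
        sel = pd.read_csv(out / "selections.tsv", sep="\t")
        state["selections"] = {
            b: list(sub["genotype"]) for b, sub in sel.groupby("breeder")
        }
    if (out / "lineages.tsv").exists():
        state["lineages"] = pd.read_csv(
            out / "lineages.tsv", sep="\t", index_col=0
        )["lineage"]
    return state


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the configured stages in fixed order into ``cfg.out``."""
    out = Path(cfg.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    (out / "config_hash.txt").write_text(f"{cfg.digest()} seed={cfg.seed}\n")
    report: dict[str, dict] = {"config_hash": cfg.digest(), "seed": cfg.seed}
    state: dict = {} if "simulate" in cfg.stages else load_state(out)
    for stage in [s for s in STAGE_FUNCS if s in cfg.stages]:
        log.info("stage %s starting", stage)
        try:
            report[stage] = STAGE_FUNCS[stage](cfg, out, state)
        except Exception as exc:
            (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        log.info("stage %s done: %s", stage, report[stage])
    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return out
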