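"""End-to-end orchestration of the annotation pipeline.

Stage order: simulate -> fractionation -> rnachrom -> targets -> motifs
-> enrich.  Every stage reads and writes plain TSV files in a run
directory; a JSON manifest records the configuration, input hashes and
per-stage record counts so a run is auditable and reproducible (all
randomness flows from the single seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import expression as expr_mod
from . import hic as hic_mod
from . import motifs as motifs_mod
from . import rnachrom as rc
from . import synthetic as syn

log = logging.getLogger("lnct3d")

STAGE_ORDER = ["simulate", "fractionation", "rnachrom", "targets",
               "motifs", "enrich"]


class DependencyError(RuntimeError):
    """An earlier stage's outputs are missing."""


@dataclass
class RunConfig:
    """All pipeline thresholds; defaults are the study's operating point."""

    indir: str = "inputs"
    outdir: str = "run"
    seed: int = 0
    bin_size: int = 10_000
    compartment_size: int = 1_000_000
    fdr_rnachrom: float = 0.01
    min_reads: int = 3
    hic_min_pairs: int = 5
    hic_max_q: float = 0.05
    max_degree: int = 2
    pad: int = 100_000
    nc_threshold: float = 0.5
    min_tpm: float = 0.5
    min_tags: int = 3
    enhancer_min_total: int = 5
    tfbs_min_score: float = 0.1
    tfbs_pad: int = 250
    tfbs_min_regions: int = 200
    tfbs_min_targets: int = 5
    go_fdr: float = 0.1
    kd_fdr: float = 0.1
    eclip_fdr: float = 0.05
    eclip_lfc: float = 0.5
    ppi_min: float = 0.4
    scope: str = "intra"
    constrain: str = "path"
    kd_sidedness: str = "right"


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _require(indir: Path, names: list[str], stage: str, needed_by: str) -> None:
    missing = [n for n in names if not (indir / n).exists()]
    if missing:
        raise DependencyError(
            f"stage '{needed_by}' needs {missing}; run stage '{stage}' first"
        )


def _save(df: pd.DataFrame, path: Path, counts: dict, name: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    counts[name] = len(df)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(config: RunConfig) -> dict:
    world = syn.generate_world(seed=config.seed,
                               bin_size=config.bin_size,
                               compartment_size=config.compartment_size)
    paths = syn.write_world(world, config.indir)
    truth = {
        "planted_nuclear": sorted(world.planted_nuclear),
        "planted_target_bins": {
            g: sorted([list(b) for b in bins])
            for g, bins in world.planted_target_bins.items()
        },
        "planted_target_genes": {
            g: sorted(v) for g, v in world.planted_target_genes.items()
        },
    }
    with open(Path(config.indir) / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {"tables_written": len(paths)}


def stage_fractionation(config: RunConfig) -> dict:
    indir, outdir = Path(config.indir), Path(config.outdir)
    _require(indir, ["expression.tsv"], "simulate", "fractionation")
    expression = pd.read_csv(indir / "expression.tsv", sep="\t")
    strongest, table = expr_mod.fractionation_from_table(
        expression, config.nc_threshold, config.min_tpm, config.min_tags
    )
    counts: dict = {}
    _save(table, outdir / "nuclear_classification.tsv", counts,
          "nuclear_classification")
    sp = pd.DataFrame(sorted(strongest.items()),
                      columns=["gene_id", "promoter_id"])
    _save(sp, outdir / "strongest_promoters.tsv", counts,
          "strongest_promoters")

    enh = pd.read_csv(indir / "enhancer_expression.tsv", sep="\t")
    mat = enh.pivot_table(index="enhancer_id", columns="library",
                          values="tags", fill_value=0)
    expressed = expr_mod.expressed_enhancers(mat, config.enhancer_min_total)
    _save(pd.DataFrame(sorted(expressed), columns=["enhancer_id"]),
          outdir / "expressed_enhancers.tsv", counts, "expressed_enhancers")
    log.info("fractionation: %d nuclear of %d classified",
             int(table.is_nuclear.sum()), len(table))
    return counts


def _load_promoter_positions(indir: Path) -> dict[str, tuple[str, int]]:
    genes = syn.read_genes_bed(indir / "genes.bed")
    return {p.promoter_id: (p.chrom, p.pos)
            for g in genes for p in g.promoters}


def _strongest_positions(indir: Path, outdir: Path) -> dict[str, tuple[str, int]]:
    """gene id -> (chrom, pos) of its strongest promoter."""
    sp = pd.read_csv(outdir / "strongest_promoters.tsv", sep="\t")
    pos = _load_promoter_positions(indir)
    return {r.gene_id: pos[r.promoter_id] for r in sp.itertuples()
            if r.promoter_id in pos}


def stage_rnachrom(config: RunConfig) -> dict:
    indir, outdir = Path(config.indir), Path(config.outdir)
    _require(indir, ["contacts.tsv", "genes.bed"], "simulate", "rnachrom")
    _require(outdir, ["strongest_promoters.tsv"], "fractionation", "rnachrom")
    contacts = pd.read_csv(indir / "contacts.tsv", sep="\t")
    genes = {g.gene_id: g for g in syn.read_genes_bed(indir / "genes.bed")}
    counts: dict = {"contacts_in": len(contacts)}

    surviving, removal = rc.filter_nascent(contacts, genes)
    counts.update({f"nascent_{k}": v for k, v in removal.items()})
    binned = rc.bin_contacts(surviving, genes, config.bin_size)
    background = rc.estimate_background(binned)
    sig = rc.iterative_binomial_caller(
        binned, background, config.fdr_rnachrom, config.min_reads,
        config.scope,
    )
    _save(rc.interactions_frame(sig, config.bin_size, config.scope),
          outdir / "interactions.tsv", counts, "interactions")

    spos = _strongest_positions(indir, outdir)
    pairs = rc.annotate_interactions(sig, spos, config.bin_size)
    _save(pairs, outdir / "interaction_pairs.tsv", counts,
          "interaction_pairs")
    log.info("rnachrom: %d significant interactions for %d genes",
             len(sig), len({s.gene_id for s in sig}))
    return counts


def stage_targets(config: RunConfig) -> dict:
    indir, outdir = Path(config.indir), Path(config.outdir)
    _require(indir, ["hic.tsv", "compartments.tsv"], "simulate", "targets")
    _require(outdir, ["interactions.tsv", "nuclear_classification.tsv"],
             "rnachrom", "targets")
    counts: dict = {}
    raw_hic = pd.read_csv(indir / "hic.tsv", sep="\t")
    graph = hic_mod.filter_hic(raw_hic, config.hic_min_pairs,
                               config.hic_max_q)
    counts["hic_edges_in"] = len(raw_hic)
    counts["hic_edges_kept"] = graph.number_of_edges()

    expression = pd.read_csv(indir / "expression.tsv", sep="\t")
    prom_pos = _load_promoter_positions(indir)
    seg_expr = hic_mod.segment_expression_from_promoters(
        expression, prom_pos, config.compartment_size
    )
    eigs = pd.read_csv(indir / "compartments.tsv", sep="\t")
    compartments = hic_mod.reassign_compartments(eigs, seg_expr)
    _save(compartments.segments, outdir / "compartments_labeled.tsv",
          counts, "compartments")

    nuclear = pd.read_csv(outdir / "nuclear_classification.tsv", sep="\t")
    nuclear_ids = set(nuclear[nuclear.is_nuclear]["gene_id"])
    spos = _strongest_positions(indir, outdir)
    inter = pd.read_csv(outdir / "interactions.tsv", sep="\t")
    genes = {g.gene_id: g for g in syn.read_genes_bed(indir / "genes.bed")}
    lnc_with_sig = sorted(
        set(inter.gene_id)
        & {g for g, m in genes.items() if m.biotype == "lncRNA"}
        & nuclear_ids & set(spos)
    )

    enhancers = pd.read_csv(indir / "enhancers.tsv", sep="\t")
    expressed_enh = set(pd.read_csv(outdir / "expressed_enhancers.tsv",
                                    sep="\t")["enhancer_id"])
    enhancers = enhancers[enhancers.enhancer_id.isin(expressed_enh)]

    target_rows, gene_rows, skipped = [], [], []
    region_sets = {}
    for gid in lnc_with_sig:
        try:
            regions = hic_mod.define_target_regions(
                gid, spos[gid], graph, compartments, config.bin_size,
                config.max_degree, config.pad, config.constrain,
            )
        except hic_mod.UnlabeledCompartmentError as exc:
            skipped.append(str(exc))
            continue
        region_sets[gid] = regions
        for (chrom, start), deg in sorted(regions.bin_degrees.items()):
            target_rows.append((gid, chrom, start, start + config.bin_size,
                                deg, regions.compartment_interval[0],
                                regions.compartment_interval[1]))
        tg, te = hic_mod.map_target_genes(regions, spos, enhancers,
                                          config.bin_size)
        for t in tg:
            if t != gid:
                gene_rows.append((gid, t, "gene"))
        for e in te:
            gene_rows.append((gid, e, "enhancer"))
    _save(pd.DataFrame(target_rows, columns=[
        "lncrna_id", "chrom", "bin_start", "bin_end", "degree",
        "interval_start", "interval_end"]),
        outdir / "targets.tsv", counts, "targets")
    _save(pd.DataFrame(gene_rows,
                       columns=["lncrna_id", "target_id", "kind"]),
          outdir / "target_genes.tsv", counts, "target_genes")
    if skipped:
        log.info("targets: skipped %d lncRNAs (unlabeled compartment)",
                 len(skipped))

    # comparison statistics on the significant RNA-chromatin bins
    figdir = outdir / "figstats"
    sig_bins = {
        gid: {(r.chrom, int(r.bin_start))
              for r in inter[inter.gene_id == gid].itertuples()}
        for gid in lnc_with_sig
    }
    refs = {
        gid: (spos[gid][0], (spos[gid][1] // config.bin_size)
              * config.bin_size)
        for gid in lnc_with_sig
    }
    cdf = hic_mod.degree_cdf(sig_bins, refs, graph, max_k=5)
    _save(cdf, figdir / "degree_cdf.tsv", counts, "degree_cdf")

    prom_bins = {
        (chrom, (pos // config.bin_size) * config.bin_size)
        for chrom, pos in spos.values()
    }
    ss_rows, enr_rows, dist_pairs = [], [], []
    rng = np.random.default_rng(config.seed)
    for gid in lnc_with_sig:
        chrom = refs[gid][0]
        universe = ({n for n in graph.nodes if n[0] == chrom}
                    | {b for b in prom_bins if b[0] == chrom}
                    | {b for b in sig_bins[gid] if b[0] == chrom})
        bins_here = {b for b in sig_bins[gid] if b[0] == chrom}
        if not bins_here or len(universe) <= len(bins_here):
            continue
        ss = hic_mod.sensitivity_specificity_by_degree(
            bins_here, refs[gid], graph, universe, max_k=4
        )
        for r in ss.itertuples():
            ss_rows.append((gid, r.degree, r.sensitivity,
                            r.one_minus_specificity))
        for randomize in (False, True):
            res = hic_mod.hic_support_enrichment(
                bins_here, refs[gid], graph, universe, config.max_degree,
                randomize=randomize, seed=int(rng.integers(0, 2**31 - 1)),
            )
            (a, b), (c, d) = res.table
            enr_rows.append((gid, randomize, a, b, c, d, res.odds_ratio,
                             res.p_value))
        dist_pairs.extend((gid, b) for b in bins_here)
    _save(pd.DataFrame(ss_rows, columns=[
        "lncrna_id", "degree", "sensitivity", "one_minus_specificity"]),
        figdir / "sens_spec.tsv", counts, "sens_spec")
    _save(pd.DataFrame(enr_rows, columns=[
        "lncrna_id", "randomized", "a", "b", "c", "d", "odds_ratio", "p"]),
        figdir / "enrichment_2x2.tsv", counts, "enrichment_2x2")
    dists = hic_mod.linear_distance_stats(dist_pairs, spos, compartments,
                                          config.bin_size)
    _save(dists, figdir / "distances.tsv", counts, "distances")
    return counts


def stage_motifs(config: RunConfig) -> dict:
    indir, outdir = Path(config.indir), Path(config.outdir)
    _require(indir, ["exons.fasta", "tfbs.tsv"], "simulate", "motifs")
    _require(outdir, ["nuclear_classification.tsv"], "fractionation",
             "motifs")
    counts: dict = {}
    seqs = motifs_mod.read_fasta(indir / "exons.fasta")
    genes = {g.gene_id: g for g in syn.read_genes_bed(indir / "genes.bed")}
    lnc_seqs = {gid: s for gid, s in seqs.items()
                if genes[gid].biotype == "lncRNA"}
    rows = []
    for name, pattern in (("U1", syn.U1_MOTIF),
                          ("SIRLOIN", syn.SIRLOIN_MOTIF)):
        hits = motifs_mod.search_motif(lnc_seqs, pattern)
        rows.extend((gid, name, n) for gid, n in sorted(hits.items()))
    motif_counts = pd.DataFrame(rows, columns=["gene_id", "motif", "count"])
    _save(motif_counts, outdir / "motif_counts.tsv", counts, "motif_counts")

    nuclear = pd.read_csv(outdir / "nuclear_classification.tsv", sep="\t")
    is_nuc = dict(zip(nuclear.gene_id, nuclear.is_nuclear))
    enr_rows = []
    for name in ("U1", "SIRLOIN"):
        sub = motif_counts[motif_counts.motif == name]
        res = motifs_mod.motif_nuclear_enrichment(
            dict(zip(sub.gene_id, sub["count"])),
            {g: bool(v) for g, v in is_nuc.items() if g in set(sub.gene_id)},
        )
        (a, b), (c, d) = res.table
        enr_rows.append((name, a, b, c, d, res.odds_ratio, res.p_value))
    _save(pd.DataFrame(enr_rows, columns=[
        "motif", "a", "b", "c", "d", "odds_ratio", "p"]),
        outdir / "motif_nuclear_enrichment.tsv", counts,
        "motif_nuclear_enrichment")

    sites = pd.read_csv(indir / "tfbs.tsv", sep="\t")
    prom_pos = _load_promoter_positions(indir)
    sp = pd.read_csv(outdir / "strongest_promoters.tsv", sep="\t")
    region_rows = [
        (r.promoter_id, *prom_pos[r.promoter_id],
         prom_pos[r.promoter_id][1] + 1)
        for r in sp.itertuples() if r.promoter_id in prom_pos
    ]
    enhancers = pd.read_csv(indir / "enhancers.tsv", sep="\t")
    expressed_enh = set(pd.read_csv(outdir / "expressed_enhancers.tsv",
                                    sep="\t")["enhancer_id"])
    region_rows += [
        (r.enhancer_id, r.chrom, int(r.start), int(r.end))
        for r in enhancers.itertuples() if r.enhancer_id in expressed_enh
    ]
    regions = pd.DataFrame(region_rows,
                           columns=["region_id", "chrom", "start", "end"])
    assignments = motifs_mod.assign_tfbs(
        sites, regions, config.tfbs_pad, config.tfbs_min_score,
        config.tfbs_min_regions,
    )
    _save(pd.DataFrame(
        [(a.region_id, a.motif, a.aggregate_score, a.assigned)
         for a in assignments],
        columns=["region_id", "motif", "aggregate_score", "assigned"]),
        outdir / "tfbs_assignments.tsv", counts, "tfbs_assignments")
    return counts


def stage_enrich(config: RunConfig) -> dict:
    indir, outdir = Path(config.indir), Path(config.outdir)
    _require(outdir, ["target_genes.tsv", "nuclear_classification.tsv"],
             "targets", "enrich")
    _require(indir, ["de.tsv", "eclip.tsv"], "simulate", "enrich")
    counts: dict = {}
    tg = pd.read_csv(outdir / "target_genes.tsv", sep="\t")
    gene_targets = (
        tg[tg.kind == "gene"].groupby("lncrna_id")["target_id"]
        .agg(set).to_dict()
    )
    genes = {g.gene_id: g for g in syn.read_genes_bed(indir / "genes.bed")}
    mrnas = {g for g, m in genes.items() if m.biotype == "mRNA"}

    # knockdown DE battery
    de = pd.read_csv(indir / "de.tsv", sep="\t")
    universe = set(de["gene_id"]) | mrnas
    kd_rows = []
    for direction in ("up", "down"):
        summary = enr.kd_de_enrichment(
            {g: t & mrnas for g, t in gene_targets.items()},
            de, universe, config.kd_fdr, direction, config.kd_sidedness,
        )
        for r in summary.per_lncrna:
            (a, b), (c, d) = r.table
            kd_rows.append((r.keys["lncrna_id"], direction, a, b, c, d,
                            r.odds_ratio, r.log2_odds_ratio, r.p_value,
                            summary.combined_p))
    _save(pd.DataFrame(kd_rows, columns=[
        "lncrna_id", "direction", "a", "b", "c", "d", "odds_ratio",
        "log2_odds_ratio", "p", "combined_p"]),
        outdir / "kd_de_enrichment.tsv", counts, "kd_de_enrichment")

    # GO battery, leave-one-lncRNA-out background
    gene_sets = enr.read_gmt(indir / "gene_sets.gmt")
    go_rows = []
    for gid in sorted(gene_targets):
        own = gene_targets[gid] & mrnas
        background = set().union(
            *(t for g, t in gene_targets.items() if g != gid)
        ) & mrnas
        background -= own
        if not own or not background:
            continue
        for r in enr.go_enrichment(own, background, gene_sets,
                                   config.go_fdr,
                                   keys={"lncrna_id": gid}):
            (a, b), (c, d) = r.table
            go_rows.append((gid, r.keys["term"], a, b, c, d, r.odds_ratio,
                            r.p_value, r.fdr, r.keys.get("significant")))
    _save(pd.DataFrame(go_rows, columns=[
        "lncrna_id", "term", "a", "b", "c", "d", "odds_ratio", "p", "fdr",
        "significant"]), outdir / "go_enrichment.tsv", counts,
        "go_enrichment")

    # TFBS battery on assigned motifs
    tf_path = outdir / "tfbs_assignments.tsv"
    if tf_path.exists():
        assignments = pd.read_csv(tf_path, sep="\t")
        motif_regions = (
            assignments[assignments.assigned]
            .groupby("motif")["region_id"].agg(set).to_dict()
        )
        sp = pd.read_csv(outdir / "strongest_promoters.tsv", sep="\t")
        prom_of = dict(zip(sp.gene_id, sp.promoter_id))
        lnc_regions = {}
        for gid, sub in tg.groupby("lncrna_id"):
            regions = set()
            for r in sub.itertuples():
                if r.kind == "gene" and r.target_id in prom_of:
                    regions.add(prom_of[r.target_id])
                elif r.kind == "enhancer":
                    regions.add(r.target_id)
            lnc_regions[gid] = regions
        region_universe = set(prom_of.values()) | set(
            tg[tg.kind == "enhancer"]["target_id"]
        )
        tf = enr.tfbs_enrichment(lnc_regions, motif_regions,
                                 region_universe,
                                 config.tfbs_min_targets, config.go_fdr)
        _save(enr.contingency_frame(tf.per_pair),
              outdir / "tfbs_enrichment.tsv", counts, "tfbs_enrichment")
        _save(pd.DataFrame(
            [(m, s, p) for m, (s, p) in sorted(tf.chisq_per_motif.items())],
            columns=["motif", "chi2", "p"]),
            outdir / "tfbs_chisq.tsv", counts, "tfbs_chisq")
        _save(pd.DataFrame(sorted(tf.combined_per_lncrna.items()),
                           columns=["lncrna_id", "combined_p"]),
              outdir / "tfbs_combined.tsv", counts, "tfbs_combined")

    # correlation preference across libraries (conditions)
    expression = pd.read_csv(indir / "expression.tsv", sep="\t")
    cnt = expression.pivot_table(index="promoter_id", columns="library",
                                 values="tags", fill_value=0)
    tpm = expr_mod.normalize_tpm(cnt)
    gmap = dict(expression[["promoter_id", "gene_id"]].drop_duplicates()
                .itertuples(index=False))
    gene_tpm = tpm.groupby([gmap[p] for p in tpm.index]).sum()
    prefs, pct = enr.correlation_preference(gene_tpm, gene_targets)
    _save(pd.DataFrame(
        [(p.lncrna_id, len(p.rhos), p.t_statistic, p.p_value, p.category)
         for p in prefs],
        columns=["lncrna_id", "n_targets", "t", "p", "category"]),
        outdir / "correlation_preference.tsv", counts,
        "correlation_preference")
    _save(pct, outdir / "correlation_pct.tsv", counts, "correlation_pct")

    # RBP batteries
    eclip = pd.read_csv(indir / "eclip.tsv", sep="\t")
    lnc_ids = {g for g, m in genes.items() if m.biotype == "lncRNA"}
    rbp_targets = enr.eclip_target_filter(
        eclip, lnc_ids, config.eclip_fdr, config.eclip_lfc
    )
    nuclear = pd.read_csv(outdir / "nuclear_classification.tsv", sep="\t")
    nc = dict(zip(nuclear.gene_id, nuclear.nc_ratio))
    rbp_kd = pd.read_csv(indir / "rbp_kd.tsv", sep="\t") \
        if (indir / "rbp_kd.tsv").exists() else None
    chip = None
    if (indir / "chip.tsv").exists():
        chip_df = pd.read_csv(indir / "chip.tsv", sep="\t")
        chip = chip_df.groupby("rbp")["promoter_id"].agg(set).to_dict()
    ppi = pd.read_csv(indir / "ppi.tsv", sep="\t") \
        if (indir / "ppi.tsv").exists() else None
    sp = pd.read_csv(outdir / "strongest_promoters.tsv", sep="\t")
    prom_of = dict(zip(sp.gene_id, sp.promoter_id))
    lnc_target_promoters = {
        g: {prom_of[t] for t in t_set if t in prom_of}
        for g, t_set in gene_targets.items()
    }
    rbp_lnc_targets = {r: g & lnc_ids for r, g in rbp_targets.items()}
    res = enr.rbp_batteries(
        rbp_lnc_targets,
        {g: t & mrnas for g, t in gene_targets.items()},
        nc, rbp_kd, chip, lnc_target_promoters, ppi,
        gene_universe=mrnas,
        promoter_universe=set(prom_of.values()),
        fdr_cut=config.go_fdr, ppi_min=config.ppi_min,
    )
    _save(enr.contingency_frame(res.kd_de), outdir / "rbp_kd_de.tsv",
          counts, "rbp_kd_de")
    _save(enr.contingency_frame(res.chip_promoter),
          outdir / "rbp_chip.tsv", counts, "rbp_chip")
    _save(enr.contingency_frame(res.chip_promoter_ppi),
          outdir / "rbp_chip_ppi.tsv", counts, "rbp_chip_ppi")
    summary_rows = [("combined_" + k, v) for k, v in sorted(res.combined.items())]
    if res.nc_ratio_test:
        summary_rows += [("nc_u_statistic", res.nc_ratio_test[0]),
                         ("nc_p_one_sided", res.nc_ratio_test[1])]
    _save(pd.DataFrame(summary_rows, columns=["metric", "value"]),
          outdir / "rbp_summary.tsv", counts, "rbp_summary")
    return counts


STAGES = {
    "simulate": stage_simulate,
    "fractionation": stage_fractionation,
    "rnachrom": stage_rnachrom,
    "targets": stage_targets,
    "motifs": stage_motifs,
    "enrich": stage_enrich,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages in dependency order and write the run
    manifest (config, input hashes, per-stage record counts)."""
    requested = stages or STAGE_ORDER
    unknown = set(requested) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGE_ORDER if s in requested]
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": asdict(config),
        "config_hash": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()
        ).hexdigest(),
        "stages": {},
    }
    for stage in ordered:
        log.info("running stage %s", stage)
        manifest["stages"][stage] = STAGES[stage](config)
    indir = Path(config.indir)
    if indir.is_dir():
        manifest["input_hashes"] = {
            p.name: _hash_file(p) for p in sorted(indir.iterdir())
            if p.is_file()
        }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
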