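"""Contingency and distributional tests downstream of target definition.

Fisher's exact test (with sample odds ratio and explicit 0 / +inf
sentinels on degenerate margins), Benjamini-Hochberg FDR, Fisher's
p-value combination, knockdown differential-expression enrichment, GO
term enrichment against a leave-one-lncRNA-out background, TFBS motif
batteries, expression-correlation preference (Spearman rho + one-sample
t), eCLIP reliable-target filtering and the RBP recruiting batteries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_KD_FDR = 0.1
DEFAULT_GO_FDR = 0.1
DEFAULT_ECLIP_FDR = 0.05
DEFAULT_ECLIP_LFC = 0.5
DEFAULT_PPI_MIN = 0.4
DEFAULT_MIN_DE_TARGETS = 3
DEFAULT_MIN_GO_OVERLAP = 3
DEFAULT_TFBS_MIN_TARGETS = 5
DEFAULT_MIN_LNC_TARGETS = 15
DEFAULT_MAX_RBP_LNCRNAS = 500


@dataclass
class ContingencyResult:
    """A 2x2 test outcome with its table and metadata.

    ``odds_ratio`` is the sample odds ratio (a*d)/(b*c), with +inf when
    only the denominator is zero, 0.0 when only the numerator is, and NaN
    when both are (fully degenerate).  No continuity correction is
    applied.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float
    sidedness: str
    keys: dict = field(default_factory=dict)
    fdr: float | None = None

    @property
    def log2_odds_ratio(self) -> float:
        if self.odds_ratio in (0.0, float("inf")) or math.isnan(self.odds_ratio):
            return self.odds_ratio if self.odds_ratio != 0.0 else float("-inf")
        return math.log2(self.odds_ratio)


_SIDES = {"left": "less", "right": "greater", "two": "two-sided"}


def sample_odds_ratio(a: int, b: int, c: int, d: int) -> float:
    num, den = a * d, b * c
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    if num == 0:
        return 0.0
    return num / den


def fisher_exact(
    table, side: str = "two", keys: dict | None = None
) -> ContingencyResult:
    """Exact Fisher test on a 2x2 table of nonnegative integers.

    ``side`` is "left", "right" or "two" (two-sided sums the
    probabilities of tables at most as probable as the observed one).
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v != int(v) or v < 0:
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if side not in _SIDES:
        raise ValueError(f"side must be one of {sorted(_SIDES)}")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=_SIDES[side])
    return ContingencyResult(
        table=((a, b), (c, d)),
        odds_ratio=sample_odds_ratio(a, b, c, d),
        p_value=float(p),
        sidedness=side,
        keys=keys or {},
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_combine(pvalues) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2m df."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values to combine")
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        import warnings

        warnings.warn("p-value of 0 clipped to smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * p.size))


# ---------------------------------------------------------------------------
# Knockdown DE enrichment (per-lncRNA ASO knockdown)
# ---------------------------------------------------------------------------

def de_genes_from_table(
    de: pd.DataFrame, lncrna_id: str, fdr_cut: float = DEFAULT_KD_FDR,
    direction: str | None = None,
) -> set[str]:
    """Genes DE upon knockdown of ``lncrna_id`` in at least one ASO
    (union over ASO columns at FDR <= cut), optionally restricted to
    up- or down-regulation."""
    sub = de[(de["lncrna_id"] == lncrna_id) & (de["fdr"] <= fdr_cut)]
    if direction == "up":
        sub = sub[sub["log2fc"] > 0]
    elif direction == "down":
        sub = sub[sub["log2fc"] < 0]
    elif direction is not None:
        raise ValueError("direction must be 'up', 'down' or None")
    return set(sub["gene_id"])


@dataclass
class KdDeSummary:
    per_lncrna: list[ContingencyResult]
    combined_p: float
    excluded: list[str]  # lncRNAs with < min_de_targets DE targets


def kd_de_enrichment(
    targets: dict[str, set[str]],
    de: pd.DataFrame,
    universe: set[str],
    fdr_cut: float = DEFAULT_KD_FDR,
    direction: str = "up",
    sidedness: str = "right",
    min_de_targets: int = DEFAULT_MIN_DE_TARGETS,
) -> KdDeSummary:
    """Per-lncRNA enrichment of knockdown-DE genes among its targets.

    2x2 of {target, non-target} x {DE in direction, not} over ``universe``
    (all assayed genes).  lncRNAs with fewer than ``min_de_targets`` DE
    target genes (any direction) are excluded from the headline summary;
    Fisher's method combines the per-lncRNA p-values of the rest.
    """
    results, excluded = [], []
    assayed = set(de["lncrna_id"])
    for gid in sorted(targets):
        if gid not in assayed:
            excluded.append(gid)
            continue
        tset = targets[gid] & universe
        de_dir = de_genes_from_table(de, gid, fdr_cut, direction) & universe
        de_any = de_genes_from_table(de, gid, fdr_cut, None) & universe
        a = len(tset & de_dir)
        b = len(tset - de_dir)
        c = len(de_dir - tset)
        d = len(universe - tset - de_dir)
        res = fisher_exact(((a, b), (c, d)), side=sidedness,
                           keys={"lncrna_id": gid, "direction": direction})
        if len(tset & de_any) < min_de_targets:
            excluded.append(gid)
        else:
            results.append(res)
    combined = fisher_combine([r.p_value for r in results]) if results else 1.0
    return KdDeSummary(per_lncrna=results, combined_p=combined,
                       excluded=excluded)


# ---------------------------------------------------------------------------
# GO enrichment
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, set[str]]:
    """GMT dialect: term <tab> description <tab> gene1 <tab> gene2 ..."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                out[parts[0]] = set(parts[2:])
    return out


def go_enrichment(
    target_genes: set[str],
    background: set[str],
    gene_sets: dict[str, set[str]],
    fdr_cut: float = DEFAULT_GO_FDR,
    min_overlap: int = DEFAULT_MIN_GO_OVERLAP,
    keys: dict | None = None,
) -> list[ContingencyResult]:
    """One-sided (right) Fisher per term sharing >= 1 gene with the
    targets; BH across the tested terms; significant = FDR <= 0.1 and
    overlap >= 3.

    ``background`` is the leave-one-out universe: target genes of all
    other expressed lncRNAs, excluding this lncRNA's own targets.
    """
    if not background:
        raise ValueError("empty background")
    universe = target_genes | background
    tested = []
    for term in sorted(gene_sets):
        members = gene_sets[term] & universe
        overlap = members & target_genes
        if not overlap:
            continue
        a = len(overlap)
        b = len(target_genes - members)
        c = len(members - target_genes)
        d = len(universe - target_genes - members)
        res = fisher_exact(((a, b), (c, d)), side="right",
                           keys={**(keys or {}), "term": term,
                                 "overlap": a})
        tested.append(res)
    if tested:
        fdrs = bh_fdr([r.p_value for r in tested])
        for r, q in zip(tested, fdrs):
            r.fdr = float(q)
            r.keys["significant"] = bool(
                q <= fdr_cut and r.keys["overlap"] >= min_overlap
            )
    return tested


# ---------------------------------------------------------------------------
# TFBS enrichment
# ---------------------------------------------------------------------------

@dataclass
class TfbsEnrichmentSummary:
    per_pair: list[ContingencyResult]  # (lncRNA, motif)
    combined_per_lncrna: dict[str, float]
    chisq_per_motif: dict[str, tuple[float, float]]  # motif -> (stat, p)
    excluded_lncrnas: list[str]


def tfbs_enrichment(
    lnc_regions: dict[str, set[str]],
    motif_regions: dict[str, set[str]],
    universe: set[str],
    min_targets: int = DEFAULT_TFBS_MIN_TARGETS,
    fdr_cut: float = DEFAULT_GO_FDR,
) -> TfbsEnrichmentSummary:
    """Per-(lncRNA, motif) one-sided Fisher of motif occurrence among the
    lncRNA's target regions (promoters + enhancers) vs the rest of the
    universe, BH-corrected per lncRNA across motifs; Fisher-combined p
    per lncRNA over its motifs; per-motif chi-square of target-region
    motif counts across lncRNAs.

    lncRNAs with fewer than ``min_targets`` target regions are excluded.
    """
    per_pair: list[ContingencyResult] = []
    combined: dict[str, float] = {}
    excluded: list[str] = []
    motifs = sorted(motif_regions)
    kept_lncs = []
    for gid in sorted(lnc_regions):
        regions = lnc_regions[gid] & universe
        if len(regions) < min_targets:
            excluded.append(gid)
            continue
        kept_lncs.append(gid)
        rest = universe - regions
        rows = []
        for motif in motifs:
            with_m = motif_regions[motif] & universe
            a = len(regions & with_m)
            b = len(regions - with_m)
            c = len(rest & with_m)
            d = len(rest - with_m)
            rows.append(fisher_exact(
                ((a, b), (c, d)), side="right",
                keys={"lncrna_id": gid, "motif": motif},
            ))
        fdrs = bh_fdr([r.p_value for r in rows])
        for r, q in zip(rows, fdrs):
            r.fdr = float(q)
        per_pair.extend(rows)
        combined[gid] = fisher_combine([r.p_value for r in rows])

    chisq: dict[str, tuple[float, float]] = {}
    for motif in motifs:
        with_m = motif_regions[motif] & universe
        obs = []
        for gid in kept_lncs:
            regions = lnc_regions[gid] & universe
            hit = len(regions & with_m)
            obs.append([hit, len(regions) - hit])
        table = np.array(obs)
        if table.size == 0 or table.sum() == 0 or (table.sum(axis=0) == 0).any():
            chisq[motif] = (0.0, 1.0)
            continue
        stat, p, _, expected = stats.chi2_contingency(table)
        if (expected < 5).any():
            import logging

            logging.getLogger(__name__).warning(
                "chi-square for %s has expected cell counts < 5", motif
            )
        chisq[motif] = (float(stat), float(p))
    return TfbsEnrichmentSummary(per_pair, combined, chisq, excluded)


# ---------------------------------------------------------------------------
# Expression correlation preference
# ---------------------------------------------------------------------------

@dataclass
class CorrelationPreference:
    lncrna_id: str
    rhos: dict[str, float]
    t_statistic: float
    p_value: float
    category: str  # "positive", "negative" or "none"
    dropped_constant: int = 0


def correlation_preference(
    expr: pd.DataFrame,
    targets: dict[str, set[str]],
    alpha: float = 0.05,
    per_pair_alpha: float = 0.01,
) -> tuple[list[CorrelationPreference], pd.DataFrame]:
    """Spearman rho between each lncRNA and its target mRNAs across cell
    types (``expr`` is gene x cell-type), then a one-sample t-test of the
    rhos against 0 per lncRNA.

    Category is positive/negative only when the t-test p <= ``alpha``
    with matching sign.  The second return value summarises, per lncRNA,
    the percentage of targets whose pairwise correlation test has
    p <= ``per_pair_alpha``, split by sign.
    """
    prefs: list[CorrelationPreference] = []
    pct_rows = []
    for gid in sorted(targets):
        if gid not in expr.index:
            continue
        x = expr.loc[gid].to_numpy(dtype=float)
        rhos: dict[str, float] = {}
        dropped = 0
        n_pos = n_neg = n_pairs = 0
        for t in sorted(targets[gid]):
            if t not in expr.index or t == gid:
                continue
            y = expr.loc[t].to_numpy(dtype=float)
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 3:
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                dropped += 1
                continue
            rho, pair_p = stats.spearmanr(x[ok], y[ok])
            rhos[t] = float(rho)
            n_pairs += 1
            if pair_p <= per_pair_alpha:
                if rho > 0:
                    n_pos += 1
                elif rho < 0:
                    n_neg += 1
        if len(rhos) < 2:
            continue
        vals = np.array(list(rhos.values()))
        if np.allclose(vals, vals[0]):
            tstat, p = (float("inf") if vals[0] != 0 else 0.0), 0.0 if vals[0] != 0 else 1.0
        else:
            tstat, p = stats.ttest_1samp(vals, 0.0)
        category = "none"
        if p <= alpha and tstat > 0:
            category = "positive"
        elif p <= alpha and tstat < 0:
            category = "negative"
        prefs.append(CorrelationPreference(
            gid, rhos, float(tstat), float(p), category, dropped
        ))
        if n_pairs:
            pct_rows.append((gid, 100.0 * n_pos / n_pairs,
                             100.0 * n_neg / n_pairs, n_pairs))
    pct = pd.DataFrame(
        pct_rows,
        columns=["lncrna_id", "pct_positive", "pct_negative", "n_pairs"],
    )
    return prefs, pct


# ---------------------------------------------------------------------------
# eCLIP / RBP batteries
# ---------------------------------------------------------------------------

def eclip_target_filter(
    eclip: pd.DataFrame,
    lncrna_ids: set[str],
    fdr_cut: float = DEFAULT_ECLIP_FDR,
    min_lfc: float = DEFAULT_ECLIP_LFC,
    min_lnc_targets: int = DEFAULT_MIN_LNC_TARGETS,
) -> dict[str, set[str]]:
    """Reliable RNA targets per RBP: FDR <= 0.05 and log2FC > 0.5
    (strict).  RBPs with fewer than ``min_lnc_targets`` lncRNA targets
    are dropped entirely."""
    passing = eclip[(eclip["fdr"] <= fdr_cut) & (eclip["log2fc"] > min_lfc)]
    by_rbp = passing.groupby("rbp")["gene_id"].agg(set).to_dict()
    return {
        rbp: genes for rbp, genes in sorted(by_rbp.items())
        if len(genes & lncrna_ids) >= min_lnc_targets
    }


@dataclass
class RbpBatteryResults:
    kd_de: list[ContingencyResult]
    chip_promoter: list[ContingencyResult]
    chip_promoter_ppi: list[ContingencyResult]
    nc_ratio_test: tuple[float, float] | None  # (U statistic, one-sided p)
    combined: dict[str, float]
    skipped: list[str]


def rbp_batteries(
    rbp_targets: dict[str, set[str]],
    lnc_targets: dict[str, set[str]],
    nc_ratios: dict[str, float],
    rbp_kd_de: pd.DataFrame | None = None,
    chip_promoters: dict[str, set[str]] | None = None,
    lnc_target_promoters: dict[str, set[str]] | None = None,
    ppi: pd.DataFrame | None = None,
    gene_universe: set[str] | None = None,
    promoter_universe: set[str] | None = None,
    max_rbp_lncrnas: int = DEFAULT_MAX_RBP_LNCRNAS,
    fdr_cut: float = DEFAULT_GO_FDR,
    min_rbp_targets: int = 3,
    ppi_min: float = DEFAULT_PPI_MIN,
) -> RbpBatteryResults:
    """The RBP recruiting batteries.

    (i) per RBP (binding <= ``max_rbp_lncrnas`` lncRNAs), one-tailed
    Fisher comparing knockdown-DE membership between target genes of
    RBP-bound vs non-bound lncRNAs; (ii) right-tailed Fisher of RBP ChIP
    occupancy among the promoters of lncRNA targets for lncRNAs bound by
    the RBP, BH <= 0.1 and >= 3 RBP-occupied promoters for significance;
    (iii) battery (ii) with the bound-lncRNA set expanded through
    protein-protein interaction partners with score > 0.4 (strict); (iv)
    one-tailed Mann-Whitney U comparing nuclear-to-cytoplasmic ratios of
    RBP-bound vs unbound lncRNAs.  Fisher's method combines each
    battery's p-values.
    """
    skipped: list[str] = []
    lnc_ids = set(lnc_targets)
    combined: dict[str, float] = {}

    # (iv) N/C ratio of bound vs unbound lncRNAs
    bound_any = set().union(*rbp_targets.values()) if rbp_targets else set()
    bound = [nc_ratios[g] for g in lnc_ids & bound_any if g in nc_ratios]
    unbound = [nc_ratios[g] for g in lnc_ids - bound_any if g in nc_ratios]
    if bound and unbound:
        u, p = stats.mannwhitneyu(bound, unbound, alternative="greater")
        nc_test = (float(u), float(p))
    else:
        nc_test = None
        skipped.append("nc_ratio_test")

    # (i) RBP knockdown DE enrichment
    kd_results: list[ContingencyResult] = []
    if rbp_kd_de is not None:
        universe = gene_universe or set(rbp_kd_de["gene_id"])
        for rbp in sorted(rbp_targets):
            bound_lnc = rbp_targets[rbp] & lnc_ids
            if not bound_lnc or len(rbp_targets[rbp] & lnc_ids) > max_rbp_lncrnas:
                continue
            unbound_lnc = lnc_ids - rbp_targets[rbp]
            t_bound = set().union(*(lnc_targets[g] for g in bound_lnc))
            t_unbound = set().union(
                *(lnc_targets[g] for g in unbound_lnc)
            ) if unbound_lnc else set()
            t_unbound -= t_bound
            de = set(rbp_kd_de[(rbp_kd_de["rbp"] == rbp)
                               & (rbp_kd_de["fdr"] <= DEFAULT_KD_FDR)]["gene_id"])
            a = len(t_bound & de & universe)
            b = len((t_bound & universe) - de)
            c = len(t_unbound & de & universe)
            d = len((t_unbound & universe) - de)
            kd_results.append(fisher_exact(
                ((a, b), (c, d)), side="right", keys={"rbp": rbp}
            ))
        if kd_results:
            combined["kd_de"] = fisher_combine(
                [r.p_value for r in kd_results]
            )
    else:
        skipped.append("kd_de")

    # (ii)/(iii) ChIP promoter occupancy batteries
    def chip_battery(bound_map: dict[str, set[str]], label: str
                     ) -> list[ContingencyResult]:
        out: list[ContingencyResult] = []
        universe = promoter_universe or set().union(
            *(lnc_target_promoters or {}).values()
        )
        for rbp in sorted(bound_map):
            bound_lnc = bound_map[rbp] & set(lnc_target_promoters or {})
            if not bound_lnc:
                continue
            proms = set().union(
                *(lnc_target_promoters[g] for g in bound_lnc)
            ) & universe
            occupied = (chip_promoters or {}).get(rbp, set()) & universe
            a = len(proms & occupied)
            b = len(proms - occupied)
            c = len(occupied - proms)
            d = len(universe - proms - occupied)
            out.append(fisher_exact(
                ((a, b), (c, d)), side="right",
                keys={"rbp": rbp, "battery": label, "n_rbp_targets": a},
            ))
        if out:
            fdrs = bh_fdr([r.p_value for r in out])
            for r, q in zip(out, fdrs):
                r.fdr = float(q)
                r.keys["significant"] = bool(
                    q <= fdr_cut and r.keys["n_rbp_targets"] >= min_rbp_targets
                )
            combined[label] = fisher_combine([r.p_value for r in out])
        return out

    chip_results: list[ContingencyResult] = []
    chip_ppi_results: list[ContingencyResult] = []
    if chip_promoters is not None and lnc_target_promoters is not None:
        chip_results = chip_battery(rbp_targets, "chip")
        if ppi is not None:
            partners: dict[str, set[str]] = {}
            for r in ppi.itertuples():
                if float(r.score) > ppi_min:
                    partners.setdefault(str(r.rbp_a), set()).add(str(r.rbp_b))
                    partners.setdefault(str(r.rbp_b), set()).add(str(r.rbp_a))
            expanded = {}
            for rbp in rbp_targets:
                lncs = set(rbp_targets[rbp])
                for other in partners.get(rbp, set()):
                    lncs |= rbp_targets.get(other, set())
                expanded[rbp] = lncs
            chip_ppi_results = chip_battery(expanded, "chip_ppi")
        else:
            skipped.append("chip_ppi")
    else:
        skipped.extend(["chip", "chip_ppi"])

    return RbpBatteryResults(
        kd_de=kd_results,
        chip_promoter=chip_results,
        chip_promoter_ppi=chip_ppi_results,
        nc_ratio_test=nc_test,
        combined=combined,
        skipped=skipped,
    )


def contingency_frame(results: list[ContingencyResult]) -> pd.DataFrame:
    """Flatten ContingencyResults into the battery TSV layout."""
    rows = []
    for r in results:
        (a, b), (c, d) = r.table
        rows.append({**r.keys, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": r.odds_ratio, "p": r.p_value,
                     "fdr": r.fdr, "sidedness": r.sidedness})
    return pd.DataFrame(rows)
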