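"""Hi-C interaction graph, A/B compartments, and candidate target regions.

Significant genomic interactions (>= 5 read pairs, q <= 0.05) at 10 kb
resolution form an undirected graph over bins.  A/B compartment labels
come from 1 Mb eigenvalues, with signs reassigned per chromosome so that
compartment A (positive) is the transcriptionally more active one.  The
candidate target region of a lncRNA is every bin within two degrees of
Hi-C interaction of the bin holding its strongest promoter, constrained
to the compartment interval (maximal run of same-label 1 Mb segments)
containing the promoter, extended by +/- 100 kb.  Expressed promoters
and enhancers mapped into those bins are the candidate target genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import fisher_exact as _scipy_fisher

from .synthetic import BinId

DEFAULT_MIN_PAIRS = 5
DEFAULT_MAX_Q = 0.05
DEFAULT_MAX_DEGREE = 2
DEFAULT_PAD = 100_000
UNREACHABLE = -1


class MalformedTableError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

def filter_hic(
    raw: pd.DataFrame,
    min_pairs: int = DEFAULT_MIN_PAIRS,
    max_q: float = DEFAULT_MAX_Q,
) -> nx.Graph:
    """Build the significant-interaction graph from a raw table.

    Expected columns: chrom, bin_i_start, bin_j_start, read_pairs,
    q_value (intra-chromosomal pairs).  Duplicate pairs are collapsed by
    summing read pairs (keeping the smallest q) before filtering; both
    thresholds are inclusive.  Self-loops are dropped.
    """
    required = {"chrom", "bin_i_start", "bin_j_start", "read_pairs", "q_value"}
    missing = required - set(raw.columns)
    if missing:
        raise MalformedTableError(f"missing columns: {sorted(missing)}")
    bad = raw[raw[["bin_i_start", "bin_j_start", "read_pairs"]].lt(0).any(axis=1)
              | raw["q_value"].isna()]
    if not bad.empty:
        raise MalformedTableError(
            f"malformed rows at lines {sorted(bad.index + 2)}"  # 1 header line
        )
    df = raw.copy()
    lo = df[["bin_i_start", "bin_j_start"]].min(axis=1)
    hi = df[["bin_i_start", "bin_j_start"]].max(axis=1)
    df["a"], df["b"] = lo, hi
    df = df[df["a"] != df["b"]]
    grouped = df.groupby(["chrom", "a", "b"], sort=True).agg(
        read_pairs=("read_pairs", "sum"), q_value=("q_value", "min")
    ).reset_index()
    keep = grouped[(grouped["read_pairs"] >= min_pairs)
                   & (grouped["q_value"] <= max_q)]
    g = nx.Graph()
    for r in keep.itertuples():
        g.add_edge((r.chrom, int(r.a)), (r.chrom, int(r.b)),
                   read_pairs=int(r.read_pairs), q_value=float(r.q_value))
    return g


# ---------------------------------------------------------------------------
# A/B compartments
# ---------------------------------------------------------------------------

@dataclass
class CompartmentMap:
    """1 Mb segments with eigenvalues and A/B labels.

    ``segments`` columns: chrom, start, end, eigenvalue, label
    (A = positive eigenvalue, B = negative, "undefined" when the whole
    chromosome has zero eigenvalues).
    """

    segments: pd.DataFrame

    def label_at(self, chrom: str, pos: int) -> str | None:
        seg = self.segments[
            (self.segments.chrom == chrom)
            & (self.segments.start <= pos) & (pos < self.segments.end)
        ]
        if seg.empty:
            return None
        return str(seg.iloc[0]["label"])

    def compartment_interval(self, chrom: str, pos: int) -> tuple[int, int] | None:
        """Maximal run of contiguous same-label segments containing pos."""
        label = self.label_at(chrom, pos)
        if label is None or label == "undefined":
            return None
        segs = self.segments[self.segments.chrom == chrom].sort_values("start")
        runs: list[tuple[int, int, str]] = []
        for r in segs.itertuples():
            if runs and runs[-1][2] == r.label and runs[-1][1] == r.start:
                runs[-1] = (runs[-1][0], int(r.end), r.label)
            else:
                runs.append((int(r.start), int(r.end), str(r.label)))
        for s, e, lab in runs:
            if s <= pos < e and lab == label:
                return (s, e)
        return None


def reassign_compartments(
    eigenvalues: pd.DataFrame,
    segment_expression: dict[tuple[str, int], float],
) -> CompartmentMap:
    """Flip eigenvalue signs per chromosome when compartment B out-expresses
    compartment A, then label A = positive, B = negative.

    ``segment_expression`` maps (chrom, segment start) to mean CAGE
    expression.  Chromosomes with all-zero eigenvalues are labeled
    "undefined" and excluded from targeting.  Idempotent.
    """
    df = eigenvalues.copy()
    labels = []
    for chrom, sub in df.groupby("chrom", sort=False):
        ev = sub["eigenvalue"].to_numpy(dtype=float)
        if (ev == 0).all():
            labels.extend([("undefined", e) for e in ev])
            continue
        expr = np.array([
            segment_expression.get((chrom, int(s)), 0.0)
            for s in sub["start"]
        ])
        mean_a = expr[ev > 0].mean() if (ev > 0).any() else 0.0
        mean_b = expr[ev < 0].mean() if (ev < 0).any() else 0.0
        if mean_b > mean_a:
            ev = -ev
        labels.extend([("A" if e > 0 else "B", e) for e in ev])
    df["label"] = [lab for lab, _ in labels]
    df["eigenvalue"] = [e for _, e in labels]
    return CompartmentMap(segments=df)


def segment_expression_from_promoters(
    expression: pd.DataFrame,
    promoter_positions: dict[str, tuple[str, int]],
    compartment_size: int = 1_000_000,
) -> dict[tuple[str, int], float]:
    """Mean promoter tag count per 1 Mb segment (CAGE peak proxy).

    ``expression`` is the long table (promoter_id, ..., tags);
    ``promoter_positions`` maps promoter id -> (chrom, pos).
    """
    totals = expression.groupby("promoter_id")["tags"].mean()
    acc: dict[tuple[str, int], list[float]] = {}
    for pid, mean_tags in totals.items():
        if pid not in promoter_positions:
            continue
        chrom, pos = promoter_positions[pid]
        key = (chrom, (pos // compartment_size) * compartment_size)
        acc.setdefault(key, []).append(float(mean_tags))
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# Degrees of separation
# ---------------------------------------------------------------------------

def bfs_degrees(graph: nx.Graph, source: BinId, max_k: int,
                allowed: set[BinId] | None = None) -> dict[BinId, int]:
    """Hop counts from source up to max_k, optionally restricted to a node
    subset (every node on the path must be allowed)."""
    if source not in graph or (allowed is not None and source not in allowed):
        return {source: 0}
    degrees = {source: 0}
    frontier = [source]
    for k in range(1, max_k + 1):
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v in degrees or (allowed is not None and v not in allowed):
                    continue
                degrees[v] = k
                nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return degrees


def degree_of_separation(
    graph: nx.Graph, source: BinId, target: BinId, max_k: int = DEFAULT_MAX_DEGREE
) -> int:
    """Shortest-path hop count between two bins, capped at ``max_k``.

    Returns 0 iff source == target, :data:`UNREACHABLE` when no path of
    length <= max_k exists.
    """
    if source == target:
        return 0
    return bfs_degrees(graph, source, max_k).get(target, UNREACHABLE)


# ---------------------------------------------------------------------------
# Target regions
# ---------------------------------------------------------------------------

@dataclass
class TargetRegionSet:
    lncrna_id: str
    reference_bin: BinId
    compartment_interval: tuple[int, int]  # already padded
    bin_degrees: dict[BinId, int] = field(default_factory=dict)

    @property
    def bins(self) -> set[BinId]:
        return set(self.bin_degrees)


class UnlabeledCompartmentError(ValueError):
    """The lncRNA promoter falls in an unlabeled compartment segment."""


def define_target_regions(
    lncrna_id: str,
    promoter: tuple[str, int],
    graph: nx.Graph,
    compartments: CompartmentMap,
    bin_size: int = 10_000,
    k: int = DEFAULT_MAX_DEGREE,
    pad: int = DEFAULT_PAD,
    constrain: str = "path",
) -> TargetRegionSet:
    """Bins within ``k`` Hi-C degrees of the lncRNA promoter bin, inside
    the padded compartment interval of the promoter.

    ``constrain="path"`` (default) requires every bin on the BFS path to
    lie wholly inside the interval; ``"endpoints"`` only filters the
    returned bins.  The reference bin itself is excluded from targets.
    """
    chrom, pos = promoter
    interval = compartments.compartment_interval(chrom, pos)
    if interval is None:
        raise UnlabeledCompartmentError(
            f"{lncrna_id}: promoter at {chrom}:{pos} in unlabeled compartment"
        )
    lo, hi = interval[0] - pad, interval[1] + pad
    ref = (chrom, (pos // bin_size) * bin_size)

    def inside(b: BinId) -> bool:
        return b[0] == chrom and lo <= b[1] and b[1] + bin_size <= hi

    if constrain == "path":
        allowed = {n for n in graph.nodes if inside(n)} | {ref}
        degrees = bfs_degrees(graph, ref, k, allowed=allowed)
    elif constrain == "endpoints":
        degrees = {b: d for b, d in bfs_degrees(graph, ref, k).items()
                   if inside(b)}
    else:
        raise ValueError(f"unknown constraint mode: {constrain!r}")
    degrees.pop(ref, None)
    degrees = {b: d for b, d in degrees.items() if inside(b)}
    return TargetRegionSet(
        lncrna_id=lncrna_id,
        reference_bin=ref,
        compartment_interval=(lo, hi),
        bin_degrees=degrees,
    )


def map_target_genes(
    regions: TargetRegionSet,
    promoter_positions: dict[str, tuple[str, int]],
    enhancers: pd.DataFrame | None = None,
    bin_size: int = 10_000,
) -> tuple[list[str], list[str]]:
    """Strongest promoters (by gene) and expressed enhancers overlapping
    any target bin.  Multiple genes in one bin each count once per gene.

    ``enhancers`` columns: enhancer_id, chrom, start, end.
    """
    bins = regions.bins
    genes = sorted(
        gid for gid, (chrom, pos) in promoter_positions.items()
        if (chrom, (pos // bin_size) * bin_size) in bins
    )
    enh_hits: list[str] = []
    if enhancers is not None and not enhancers.empty:
        for r in enhancers.itertuples():
            first = (int(r.start) // bin_size) * bin_size
            last = ((int(r.end) - 1) // bin_size) * bin_size
            if any((r.chrom, b) in bins
                   for b in range(first, last + bin_size, bin_size)):
                enh_hits.append(str(r.enhancer_id))
    return genes, sorted(enh_hits)


# ---------------------------------------------------------------------------
# Comparison statistics (degree CDF, sensitivity/specificity, enrichment,
# distances)
# ---------------------------------------------------------------------------

def degree_cdf(
    sig_bins: dict[str, set[BinId]],
    references: dict[str, BinId],
    graph: nx.Graph,
    max_k: int = 5,
) -> pd.DataFrame:
    """Cumulative fraction of significant RNA-chromatin bins within k Hi-C
    degrees of their lncRNA's reference bin, k = 0..max_k, plus the
    unreachable residual.  Empty interaction sets yield an empty frame.
    """
    degs: list[int] = []
    for gid, bins in sig_bins.items():
        if gid not in references:
            continue
        reach = bfs_degrees(graph, references[gid], max_k)
        for b in bins:
            degs.append(reach.get(b, UNREACHABLE))
    if not degs:
        return pd.DataFrame(columns=["degree", "cumulative_fraction"])
    arr = np.array(degs)
    total = len(arr)
    rows = [(k, float(((arr >= 0) & (arr <= k)).sum() / total))
            for k in range(0, max_k + 1)]
    rows.append((UNREACHABLE, float((arr == UNREACHABLE).sum() / total)))
    return pd.DataFrame(rows, columns=["degree", "cumulative_fraction"])


def sensitivity_specificity_by_degree(
    sig_bins: set[BinId],
    reference: BinId,
    graph: nx.Graph,
    universe: set[BinId],
    max_k: int = 5,
) -> pd.DataFrame:
    """Per k: sensitivity and 1-specificity of "within <= k degrees" as a
    predictor of RNA-chromatin significance over ``universe``."""
    if not universe >= sig_bins:
        raise ValueError("universe must contain all significant bins")
    reach = bfs_degrees(graph, reference, max_k)
    non_sig = universe - sig_bins
    rows = []
    for k in range(0, max_k + 1):
        within = {b for b in universe if reach.get(b, UNREACHABLE) in range(0, k + 1)}
        tp = len(sig_bins & within)
        fp = len(non_sig & within)
        sens = tp / len(sig_bins) if sig_bins else float("nan")
        one_minus_spec = fp / len(non_sig) if non_sig else float("nan")
        rows.append((k, sens, one_minus_spec))
    return pd.DataFrame(
        rows, columns=["degree", "sensitivity", "one_minus_specificity"]
    )


@dataclass(frozen=True)
class EnrichmentTable:
    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def hic_support_enrichment(
    sig_bins: set[BinId],
    reference: BinId,
    graph: nx.Graph,
    universe: set[BinId],
    k: int = DEFAULT_MAX_DEGREE,
    randomize: bool = False,
    seed: int | None = None,
) -> EnrichmentTable:
    """2x2 enrichment of RNA-chromatin significance among bins within
    <= k Hi-C degrees of the reference (two-sided Fisher's exact test).

    ``randomize=True`` replaces the significant set with a same-size
    uniform sample from the universe (seeded), which destroys the
    enrichment.
    """
    if randomize:
        rng = np.random.default_rng(seed)
        pool = sorted(universe)
        picks = rng.choice(len(pool), size=min(len(sig_bins), len(pool)),
                           replace=False)
        sig_bins = {pool[int(i)] for i in picks}
    reach = bfs_degrees(graph, reference, k)
    within = {b for b in universe if b in reach}
    a = len(sig_bins & within)
    b = len(sig_bins - within)
    c = len(within - sig_bins)
    d = len(universe - sig_bins - within)
    if (a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0):
        return EnrichmentTable(((a, b), (c, d)), float("nan"), 1.0)
    if b * c == 0:
        odds = float("inf") if a * d > 0 else float("nan")
    else:
        odds = (a * d) / (b * c)
    _, p = _scipy_fisher([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentTable(((a, b), (c, d)), odds, float(p))


def linear_distance_stats(
    pairs: list[tuple[str, BinId]],
    promoter_positions: dict[str, tuple[str, int]],
    compartments: CompartmentMap,
    bin_size: int = 10_000,
) -> pd.DataFrame:
    """Linear genomic distance (bin midpoint to strongest promoter) and
    same/different-compartment flag per (lncRNA, target bin) pair."""
    rows = []
    for gid, (chrom, start) in pairs:
        pchrom, ppos = promoter_positions[gid]
        if pchrom != chrom:
            continue
        midpoint = start + bin_size // 2
        dist = abs(midpoint - ppos)
        lab_bin = compartments.label_at(chrom, midpoint)
        lab_prom = compartments.label_at(chrom, ppos)
        same = (lab_bin is not None and lab_bin == lab_prom)
        rows.append((gid, chrom, start, dist, same))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "bin_start", "distance_bp",
                       "same_compartment"]
    )


def apply_differential_hic_filter(
    table: pd.DataFrame, min_abs_lfc: float = 1.0, max_fdr: float = 0.1
) -> pd.DataFrame:
    """Threshold an externally produced differential Hi-C table
    (|log2FC| >= 1 and FDR <= 0.1); the differential model itself is
    external."""
    return table[(table["log2fc"].abs() >= min_abs_lfc)
                 & (table["fdr"] <= max_fdr)].reset_index(drop=True)
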