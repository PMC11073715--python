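"""Significant RNA-chromatin interaction calling.

Contacts attributable to nascent transcription (RNA tag wholly inside an
intron of the gene of origin, or DNA tag overlapping the gene's genomic
span) are discarded.  Surviving DNA tags are aggregated into 10 kb bins.
The background probability of a bin is the fraction of all trans-binding
mRNA reads that fall in it; significance of a gene's count x in a bin is
the upper tail of Binomial(n, p_b) where n is the gene's remaining read
total.  Because bins near hotspots inflate n, the test is iterated: bins
reaching FDR <= 0.01 (Benjamini-Hochberg within the gene) are set aside
and their reads subtracted from n, and the remaining bins are retested
until an iteration adds nothing.  The final set keeps bins supported by
at least 3 reads.

Subtracting reads from n with x fixed can only shrink an upper-tail
binomial p-value, so the significant set grows monotonically and the
loop terminates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

from .synthetic import BinId, GeneModel

DEFAULT_FDR = 0.01
DEFAULT_MIN_READS = 3
DEFAULT_BIN_SIZE = 10_000


class UnknownGeneError(KeyError):
    """A contact references a gene id absent from the gene models."""


class BackgroundError(ValueError):
    """No trans mRNA reads: the background model is unestimable."""


# ---------------------------------------------------------------------------
# Nascent filtering
# ---------------------------------------------------------------------------

def filter_nascent(
    contacts: pd.DataFrame, genes: dict[str, GeneModel]
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop nascent-RNA contacts; return survivors and per-rule counts.

    A contact is removed when its RNA tag interval lies wholly within an
    intron of its gene, or when its DNA tag position falls inside the
    gene-of-origin's genomic span.  An RNA tag spanning an exon-intron
    junction is retained (not wholly intronic).
    """
    unknown = sorted(set(contacts["gene_id"]) - set(genes))
    if unknown:
        raise UnknownGeneError(f"contacts reference unknown genes: {unknown}")

    intronic = np.zeros(len(contacts), dtype=bool)
    own_gene = np.zeros(len(contacts), dtype=bool)
    for i, row in enumerate(contacts.itertuples(index=False)):
        g = genes[row.gene_id]
        if row.chrom_rna == g.chrom:
            for s, e in g.introns:
                if s <= row.start_rna and row.end_rna <= e:
                    intronic[i] = True
                    break
        if row.chrom_dna == g.chrom and g.start <= row.pos_dna < g.end:
            own_gene[i] = True
    removed = intronic | own_gene
    counts = {
        "intronic_rna_tag": int(intronic.sum()),
        "dna_tag_in_own_gene": int(own_gene.sum()),
        "removed": int(removed.sum()),
        "kept": int((~removed).sum()),
    }
    return contacts.loc[~removed].reset_index(drop=True), counts


# ---------------------------------------------------------------------------
# Binning
# ---------------------------------------------------------------------------

@dataclass
class BinnedContactTable:
    """Per-(gene, bin) contact counts plus gene metadata.

    ``counts`` has columns gene_id, chrom, bin_start, reads, cis (bool:
    bin on the same chromosome as the gene).  ``gene_totals`` maps gene id
    to its total surviving reads (n at iteration 0).
    """

    counts: pd.DataFrame
    gene_totals: dict[str, int]
    gene_chrom: dict[str, str]
    gene_biotype: dict[str, str]
    bin_size: int


def bin_contacts(
    contacts: pd.DataFrame,
    genes: dict[str, GeneModel],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> BinnedContactTable:
    """Aggregate DNA-tag positions into half-open ``bin_size`` bins.

    bin_start = floor(pos / bin_size) * bin_size per chromosome; the per
    (gene, bin) read counts conserve the number of input contacts.
    """
    df = contacts.copy()
    df["bin_start"] = (df["pos_dna"] // bin_size) * bin_size
    counts = (
        df.groupby(["gene_id", "chrom_dna", "bin_start"])
        .size().rename("reads").reset_index()
        .rename(columns={"chrom_dna": "chrom"})
    )
    gene_chrom = {gid: g.chrom for gid, g in genes.items()}
    counts["cis"] = counts["gene_id"].map(gene_chrom) == counts["chrom"]
    totals = counts.groupby("gene_id")["reads"].sum().to_dict()
    return BinnedContactTable(
        counts=counts,
        gene_totals={g: int(t) for g, t in totals.items()},
        gene_chrom=gene_chrom,
        gene_biotype={gid: g.biotype for gid, g in genes.items()},
        bin_size=bin_size,
    )


# ---------------------------------------------------------------------------
# Background model
# ---------------------------------------------------------------------------

@dataclass
class BackgroundModel:
    """Per-bin background probability from trans-binding mRNA reads."""

    probabilities: dict[BinId, float]
    total_trans_reads: int

    def p(self, bin_id: BinId) -> float:
        return self.probabilities.get(bin_id, 0.0)


def estimate_background(binned: BinnedContactTable) -> BackgroundModel:
    """p_b = (trans mRNA reads in bin b) / (total trans mRNA reads).

    Bins without trans mRNA coverage get p_b = 0 and are excluded from
    testing downstream (their p-value is undefined).
    """
    c = binned.counts
    is_mrna = c["gene_id"].map(binned.gene_biotype) == "mRNA"
    trans = c[is_mrna & ~c["cis"]]
    total = int(trans["reads"].sum())
    if total == 0:
        raise BackgroundError("no trans mRNA reads; background unestimable")
    per_bin = trans.groupby(["chrom", "bin_start"])["reads"].sum()
    probs = {
        (str(chrom), int(start)): reads / total
        for (chrom, start), reads in per_bin.items()
    }
    return BackgroundModel(probabilities=probs, total_trans_reads=total)


# ---------------------------------------------------------------------------
# Iterative binomial caller
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificantInteraction:
    gene_id: str
    chrom: str
    bin_start: int
    reads: int
    p_value: float
    fdr: float
    iteration_found: int


def _call_gene(
    bins: pd.DataFrame,
    n_total: int,
    probs: np.ndarray,
    fdr_cut: float,
) -> tuple[list[tuple[int, float, float, int]], int]:
    """Iterate the binomial test for one gene.

    ``bins`` rows are the testable bins (p_b > 0); ``probs`` aligns with
    them.  Returns (records, n_iterations) where each record is
    (row index, p, fdr, iteration).
    """
    x = bins["reads"].to_numpy()
    active = np.ones(len(bins), dtype=bool)
    n = n_total
    found: list[tuple[int, float, float, int]] = []
    iteration = 0
    while n > 0 and active.any():
        iteration += 1
        idx = np.flatnonzero(active)
        # exact upper tail P[X >= x] of Binomial(n, p)
        pvals = binom.sf(x[idx] - 1, n, probs[idx])
        _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
        hits = fdrs <= fdr_cut
        if not hits.any():
            break
        for j, p, q in zip(idx[hits], pvals[hits], fdrs[hits]):
            found.append((int(j), float(p), float(q), iteration))
        n -= int(x[idx[hits]].sum())
        active[idx[hits]] = False
    return found, iteration


def iterative_binomial_caller(
    binned: BinnedContactTable,
    background: BackgroundModel,
    fdr_cut: float = DEFAULT_FDR,
    min_reads: int = DEFAULT_MIN_READS,
    scope: str = "intra",
) -> list[SignificantInteraction]:
    """Call significant (gene, bin) RNA-chromatin interactions.

    ``scope`` selects which bins are tested per gene: "intra" (bin on the
    gene's chromosome), "inter" (other chromosomes) or "all".  The gene's
    read total n always counts all of its surviving reads.  Genes are
    processed independently; the final set keeps bins with at least
    ``min_reads`` reads (applied after the iteration converges).
    """
    if scope not in ("intra", "inter", "all"):
        raise ValueError(f"unknown scope: {scope!r}")
    results: list[SignificantInteraction] = []
    for gene_id, sub in binned.counts.groupby("gene_id", sort=True):
        n_total = binned.gene_totals[gene_id]
        if n_total < 1:
            continue
        if scope == "intra":
            sub = sub[sub["cis"]]
        elif scope == "inter":
            sub = sub[~sub["cis"]]
        if sub.empty:
            continue
        probs = np.array([
            background.p((row.chrom, int(row.bin_start)))
            for row in sub.itertuples()
        ])
        testable = probs > 0
        sub = sub[testable].reset_index(drop=True)
        probs = probs[testable]
        if sub.empty:
            continue
        found, _ = _call_gene(sub, n_total, probs, fdr_cut)
        for j, p, q, it in found:
            row = sub.iloc[j]
            if int(row.reads) >= min_reads:
                results.append(SignificantInteraction(
                    gene_id=str(gene_id),
                    chrom=str(row.chrom),
                    bin_start=int(row.bin_start),
                    reads=int(row.reads),
                    p_value=p,
                    fdr=q,
                    iteration_found=it,
                ))
    results.sort(key=lambda r: (r.gene_id, r.chrom, r.bin_start))
    return results


def interactions_frame(
    sig: list[SignificantInteraction], bin_size: int = DEFAULT_BIN_SIZE,
    scope: str = "intra",
) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.gene_id, s.chrom, s.bin_start, s.bin_start + bin_size, s.reads,
          s.p_value, s.fdr, s.iteration_found, scope) for s in sig],
        columns=["gene_id", "chrom", "bin_start", "bin_end", "reads",
                 "p_value", "fdr", "iteration", "scope"],
    )


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def annotate_interactions(
    sig: list[SignificantInteraction],
    promoter_positions: dict[str, tuple[str, int]],
    bin_size: int = DEFAULT_BIN_SIZE,
) -> pd.DataFrame:
    """Pair each significant bin with every strongest promoter inside it.

    ``promoter_positions`` maps gene id -> (chrom, strongest promoter
    position).  A bin overlapping k promoters yields k pairs (one
    interaction per gene); bins without promoters yield no pair but stay
    in the interaction set.  Columns: gene_id, chrom, bin_start,
    target_gene.
    """
    by_bin: dict[BinId, list[str]] = {}
    for gid, (chrom, pos) in promoter_positions.items():
        key = (chrom, (pos // bin_size) * bin_size)
        by_bin.setdefault(key, []).append(gid)
    rows = []
    for s in sig:
        for target in sorted(by_bin.get((s.chrom, s.bin_start), [])):
            rows.append((s.gene_id, s.chrom, s.bin_start, target))
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "bin_start", "target_gene"]
    )
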