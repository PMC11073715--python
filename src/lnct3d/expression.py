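"""Promoter/enhancer expression and nuclear classification.

CAGE tag counts are normalised to tags per million (tpm) per library; per
gene, the strongest promoter is the highest mean-tpm promoter passing a
minimum of 0.5 tpm and 3 tags in at least one library.  Enhancers pass on
an aggregate cross-library tag count of at least 5.  A gene is classified
nuclear when its nuclear-to-cytoplasmic expression ratio
nuc / (nuc + cyto) is at least 0.5; when chromatin and nucleoplasm
fractions are measured instead of a single nuclear fraction, their mean
stands in for the nuclear expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: sentinel for a 0/0 nuclear-to-cytoplasmic ratio (gene dropped from
#: classification rather than silently treated as 0 or NaN-propagated)
UNDEFINED_RATIO = float("nan")

DEFAULT_NC_THRESHOLD = 0.5
DEFAULT_MIN_TPM = 0.5
DEFAULT_MIN_TAGS = 3
DEFAULT_ENHANCER_MIN_TOTAL = 5


class ZeroLibraryError(ValueError):
    """A library with zero total tags cannot be tpm-normalised."""


def normalize_tpm(tag_counts: pd.DataFrame) -> pd.DataFrame:
    """Scale each library column of a promoter x library count matrix to
    tags per million (column sum 1e6).

    Raises :class:`ZeroLibraryError` naming any all-zero library.
    """
    counts = tag_counts.astype(float)
    if (counts.values < 0).any():
        raise ValueError("negative tag counts")
    totals = counts.sum(axis=0)
    zero = totals[totals == 0].index.tolist()
    if zero:
        raise ZeroLibraryError(
            f"libraries with zero total tags cannot be normalised: {zero}"
        )
    return counts / totals * 1e6


@dataclass(frozen=True)
class PromoterExpression:
    """Per-promoter expression summary used for strongest-promoter choice."""

    promoter_id: str
    gene_id: str
    mean_tpm: float
    max_tags: int  # highest raw tag count over libraries


def summarize_promoters(
    tag_counts: pd.DataFrame, gene_map: dict[str, str]
) -> list[PromoterExpression]:
    """Mean tpm across libraries and max per-library raw tag count per
    promoter.  ``tag_counts`` is promoter x library; ``gene_map`` links
    each promoter to its gene."""
    tpm = normalize_tpm(tag_counts)
    out = []
    for pid in tag_counts.index:
        out.append(PromoterExpression(
            promoter_id=str(pid),
            gene_id=gene_map[str(pid)],
            mean_tpm=float(tpm.loc[pid].mean()),
            max_tags=int(tag_counts.loc[pid].max()),
        ))
    return out


def strongest_promoter(
    expr: list[PromoterExpression],
    min_tpm: float = DEFAULT_MIN_TPM,
    min_tags: int = DEFAULT_MIN_TAGS,
) -> dict[str, str]:
    """Per gene, the max-mean-tpm promoter among those with mean tpm >=
    ``min_tpm`` and at least ``min_tags`` tags in some library.

    Genes with no passing promoter are absent from the returned map.
    Ties are broken by lexicographically smallest promoter id.
    """
    best: dict[str, PromoterExpression] = {}
    for p in expr:
        if p.mean_tpm < min_tpm or p.max_tags < min_tags:
            continue
        cur = best.get(p.gene_id)
        if (cur is None or p.mean_tpm > cur.mean_tpm
                or (p.mean_tpm == cur.mean_tpm
                    and p.promoter_id < cur.promoter_id)):
            best[p.gene_id] = p
    return {g: p.promoter_id for g, p in best.items()}


def expressed_enhancers(
    enhancer_counts: pd.DataFrame,
    min_total: int = DEFAULT_ENHANCER_MIN_TOTAL,
) -> set[str]:
    """Enhancers whose tag count summed over all libraries (directionality
    ignored) is at least ``min_total``.  ``enhancer_counts`` is enhancer x
    library."""
    totals = enhancer_counts.sum(axis=1)
    return {str(e) for e, t in totals.items() if t >= min_total}


def nc_ratio(
    nuclear: float | None = None,
    cytoplasmic: float = 0.0,
    chromatin: float | None = None,
    nucleoplasm: float | None = None,
) -> float:
    """Nuclear-to-cytoplasmic expression ratio in [0, 1].

    Two-fraction form: nuc / (nuc + cyto).  Three-fraction form (chromatin
    and nucleoplasm measured separately): mean(chromatin, nucleoplasm)
    replaces the nuclear expression.  Returns :data:`UNDEFINED_RATIO`
    (NaN) when both the nuclear estimate and cytoplasmic expression are
    zero; such genes are excluded from classification.
    """
    if nuclear is None:
        if chromatin is None or nucleoplasm is None:
            raise ValueError(
                "either nuclear, or both chromatin and nucleoplasm, required"
            )
        nuc = (chromatin + nucleoplasm) / 2.0
        if chromatin < 0 or nucleoplasm < 0:
            raise ValueError("negative expression")
    else:
        nuc = nuclear
    if nuc < 0 or cytoplasmic < 0:
        raise ValueError("negative expression")
    total = nuc + cytoplasmic
    if total == 0:
        return UNDEFINED_RATIO
    return nuc / total


@dataclass(frozen=True)
class NuclearClassification:
    gene_id: str
    nc_ratio: float
    is_nuclear: bool


def classify_nuclear(
    ratios: dict[str, float],
    threshold: float = DEFAULT_NC_THRESHOLD,
    fallback_ratios: dict[str, list[float]] | None = None,
) -> list[NuclearClassification]:
    """Classify genes as nuclear (ratio >= threshold, inclusive).

    ``ratios`` maps gene id to its N/C ratio in this cell type; a NaN
    (undefined 0/0) drops the gene.  ``fallback_ratios`` optionally maps
    genes *absent* from ``ratios`` to their ratios in other cell types;
    such genes receive the unweighted cross-cell-type mean.
    """
    merged: dict[str, float] = {}
    for gid, r in ratios.items():
        if not math.isnan(r):
            merged[gid] = r
    if fallback_ratios:
        for gid, values in fallback_ratios.items():
            if gid in merged or not values:
                continue
            vals = [v for v in values if not math.isnan(v)]
            if vals:
                merged[gid] = float(np.mean(vals))
    return [
        NuclearClassification(gid, r, r >= threshold)
        for gid, r in sorted(merged.items())
    ]


# ---------------------------------------------------------------------------
# Table-level driver used by the pipeline
# ---------------------------------------------------------------------------

def fractionation_from_table(
    expression: pd.DataFrame,
    threshold: float = DEFAULT_NC_THRESHOLD,
    min_tpm: float = DEFAULT_MIN_TPM,
    min_tags: int = DEFAULT_MIN_TAGS,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Run the full fractionation stage on a long-format expression table
    (columns promoter_id, gene_id, fraction, library, tags).

    Returns the strongest-promoter map (computed on all libraries pooled)
    and a classification table (gene_id, nc_ratio, is_nuclear).
    """
    counts = expression.pivot_table(
        index="promoter_id", columns="library", values="tags", fill_value=0
    )
    gene_map = dict(
        expression[["promoter_id", "gene_id"]]
        .drop_duplicates().itertuples(index=False)
    )
    strongest = strongest_promoter(
        summarize_promoters(counts, gene_map), min_tpm, min_tags
    )

    tpm = normalize_tpm(counts)
    lib_fraction = dict(
        expression[["library", "fraction"]].drop_duplicates()
        .itertuples(index=False)
    )
    long = tpm.stack().rename("tpm").reset_index()
    long["fraction"] = long["library"].map(lib_fraction)
    long["gene_id"] = long["promoter_id"].map(gene_map)
    # mean tpm per (gene, fraction): mean over libraries of the gene's
    # summed promoter tpm
    per_lib = long.groupby(["gene_id", "fraction", "library"])["tpm"].sum()
    per_fraction = per_lib.groupby(["gene_id", "fraction"]).mean().unstack(
        fill_value=0.0
    )

    ratios: dict[str, float] = {}
    for gid, row in per_fraction.iterrows():
        if "nuclear" in per_fraction.columns:
            ratios[str(gid)] = nc_ratio(
                nuclear=float(row.get("nuclear", 0.0)),
                cytoplasmic=float(row.get("cytoplasmic", 0.0)),
            )
        else:
            ratios[str(gid)] = nc_ratio(
                cytoplasmic=float(row.get("cytoplasmic", 0.0)),
                chromatin=float(row.get("chromatin", 0.0)),
                nucleoplasm=float(row.get("nucleoplasm", 0.0)),
            )
    classifications = classify_nuclear(ratios, threshold)
    table = pd.DataFrame(
        [(c.gene_id, c.nc_ratio, c.is_nuclear) for c in classifications],
        columns=["gene_id", "nc_ratio", "is_nuclear"],
    )
    return strongest, table
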