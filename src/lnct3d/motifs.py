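"""Degenerate motif search in exon sequences and TFBS assignment.

The nuclear-retention elements searched here are the SIRLOIN element and
the U1 snRNP recognition site, written as degenerate patterns over
{A,C,G,T} with bracketed single-position alternatives (e.g. ``[CT]``).
Matches are counted on the given strand, overlapping occurrences
included (fuzznuc-compatible).  Predicted transcription-factor binding
sites are assigned to promoter/enhancer regions (padded +/- 250 bp) by
summing posterior scores of overlapping sites; an aggregate of at least
0.1 assigns the motif, and motifs hitting fewer than 200 regions are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .enrichment import ContingencyResult, fisher_exact
from .synthetic import SIRLOIN_MOTIF, U1_MOTIF  # noqa: F401  (re-export)

DNA = set("ACGT")
DEFAULT_TFBS_PAD = 250
DEFAULT_TFBS_MIN_SCORE = 0.1
DEFAULT_TFBS_MIN_REGIONS = 200


@dataclass(frozen=True)
class DegeneratePattern:
    """A pattern compiled to per-position allowed-base sets."""

    pattern: str
    positions: tuple[frozenset[str], ...]

    def __len__(self) -> int:
        return len(self.positions)


def compile_pattern(pattern: str) -> DegeneratePattern:
    """Parse a degenerate pattern: plain bases plus ``[...]`` alternative
    sets, one position each.  Ambiguity codes outside brackets are
    rejected."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.find("]", i)
            if j < 0:
                raise ValueError(f"unclosed bracket in pattern: {pattern!r}")
            alts = set(pattern[i + 1:j])
            if not alts or not alts <= DNA:
                raise ValueError(f"invalid alternative set {pattern[i:j+1]!r}")
            positions.append(frozenset(alts))
            i = j + 1
        elif ch in DNA:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(
                f"invalid character {ch!r} in pattern (only ACGT and [...])"
            )
    if not positions:
        raise ValueError("empty pattern")
    return DegeneratePattern(pattern, tuple(positions))


def count_matches(sequence: str, pattern: DegeneratePattern | str,
                  overlap: bool = True) -> int:
    """Number of (by default overlapping) degenerate matches on the given
    strand.  Raises on characters outside the IUPAC DNA alphabet."""
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    seq = sequence.upper()
    bad = set(seq) - set("ACGTNRYSWKMBDHV")
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)}")
    m = len(pattern)
    count = 0
    i = 0
    while i <= len(seq) - m:
        if all(seq[i + k] in pattern.positions[k] for k in range(m)):
            count += 1
            i += 1 if overlap else m
        else:
            i += 1
    return count


def search_motif(
    sequences: dict[str, str],
    pattern: DegeneratePattern | str,
    overlap: bool = True,
) -> dict[str, int]:
    """Per-sequence (gene/transcript) match counts for one pattern."""
    if isinstance(pattern, str):
        pattern = compile_pattern(pattern)
    out = {}
    for name in sorted(sequences):
        try:
            out[name] = count_matches(sequences[name], pattern, overlap)
        except ValueError as exc:
            raise ValueError(f"sequence {name!r}: {exc}") from exc
    return out


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def motif_nuclear_enrichment(
    counts: dict[str, int], nuclear: dict[str, bool]
) -> ContingencyResult:
    """Right-tailed Fisher: {nuclear, not} x {motif-bearing (>= 1), not}.

    Degenerate margins yield the usual sentinels (p = 1)."""
    shared = sorted(set(counts) & set(nuclear))
    a = sum(1 for g in shared if nuclear[g] and counts[g] >= 1)
    b = sum(1 for g in shared if nuclear[g] and counts[g] == 0)
    c = sum(1 for g in shared if not nuclear[g] and counts[g] >= 1)
    d = sum(1 for g in shared if not nuclear[g] and counts[g] == 0)
    return fisher_exact(((a, b), (c, d)), side="right")


# ---------------------------------------------------------------------------
# TFBS assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TfbsAssignment:
    region_id: str
    motif: str
    aggregate_score: float
    assigned: bool


def assign_tfbs(
    sites: pd.DataFrame,
    regions: pd.DataFrame,
    pad: int = DEFAULT_TFBS_PAD,
    min_score: float = DEFAULT_TFBS_MIN_SCORE,
    min_regions: int = DEFAULT_TFBS_MIN_REGIONS,
) -> list[TfbsAssignment]:
    """Sum posterior scores of sites overlapping each padded region.

    ``sites`` columns: chrom, start, end, motif, posterior; ``regions``
    columns: region_id, chrom, start, end.  A (region, motif) pair is
    assigned when its aggregate is >= ``min_score``; motifs assigned to
    fewer than ``min_regions`` regions are dropped entirely.  Overlap is
    any nonzero intersection with [start - pad, end + pad).
    """
    agg: dict[tuple[str, str], float] = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for r in regions.itertuples():
        by_chrom.setdefault(str(r.chrom), []).append(
            (int(r.start) - pad, int(r.end) + pad, str(r.region_id))
        )
    for s in sites.itertuples():
        for lo, hi, rid in by_chrom.get(str(s.chrom), ()):
            if int(s.start) < hi and lo < int(s.end):
                key = (rid, str(s.motif))
                agg[key] = agg.get(key, 0.0) + float(s.posterior)

    assigned_regions: dict[str, set[str]] = {m: set() for _, m in agg}
    for (rid, motif), score in agg.items():
        if score >= min_score:
            assigned_regions[motif].add(rid)
    kept_motifs = {m for m, rs in assigned_regions.items()
                   if len(rs) >= min_regions}
    return [
        TfbsAssignment(rid, motif, score, score >= min_score)
        for (rid, motif), score in sorted(agg.items())
        if motif in kept_motifs
    ]


def assignments_by_motif(
    assignments: list[TfbsAssignment],
) -> dict[str, set[str]]:
    """motif -> set of region ids the motif is assigned to."""
    out: dict[str, set[str]] = {}
    for a in assignments:
        if a.assigned:
            out.setdefault(a.motif, set()).add(a.region_id)
    return out
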