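"""Synthetic input generator with planted ground truth.

Every table the pipeline consumes can be generated here: RNA-DNA contact
tables, significant Hi-C interaction tables with read-pair counts and
q-values, gene models with exon/intron structure, CAGE-like promoter and
enhancer tag counts per subcellular fraction, 1 Mb compartment eigenvalues,
knockdown differential-expression tables, eCLIP/ChIP/PPI tables and TFBS
site predictions.

The generator plants a known truth -- which lncRNAs are nuclear, which
10 kb bins they contact, which mRNAs sit in those bins -- so that every
downstream stage can be scored against it.  Contacts are emitted as
already-mapped coordinate pairs; read-level artefacts (duplicates,
adapters, restriction fragments) are not modelled.

Randomness: one numpy Generator per output table, seeded by
``(master seed, crc32(table name))``, so adding a table never perturbs
the others and a fixed seed reproduces every table byte for byte.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BinId = tuple[str, int]

U1_MOTIF = "CAGGTGAGT"
SIRLOIN_MOTIF = (
    "[CT][GA]CCTCCC[GA][GA]GTTCAAG[CT]GAT[TC]CTCCT[GA]CCTCAGCCTCCCGA"
)

FRACTIONS = ("nuclear", "cytoplasmic")
LIBS_PER_FRACTION = 2


class ConfigurationError(ValueError):
    """Raised when generator parameters are inconsistent or non-positive."""


def _rng(seed: int, table: str) -> np.random.Generator:
    """Independent stream per table: adding a table never perturbs others."""
    return np.random.default_rng([int(seed), zlib.crc32(table.encode())])


# ---------------------------------------------------------------------------
# World model
# ---------------------------------------------------------------------------

@dataclass
class Promoter:
    promoter_id: str
    gene_id: str
    chrom: str
    pos: int  # TSS, 0-based


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    biotype: str  # "mRNA" or "lncRNA"
    exons: list[tuple[int, int]]  # 0-based half-open, sorted, non-adjacent
    promoters: list[Promoter]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class WorldConfig:
    n_chrom: int = 2
    chrom_len: int = 5_000_000
    bin_size: int = 10_000
    compartment_size: int = 1_000_000
    n_mrna: int = 200
    n_lncrna: int = 20
    n_enhancers: int = 100
    n_target_bins: int = 8
    frac_nuclear: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chrom, self.n_mrna, self.n_lncrna) < 1:
            raise ConfigurationError("counts must be >= 1")
        if self.bin_size <= 0 or self.compartment_size <= 0:
            raise ConfigurationError("sizes must be positive")
        if self.chrom_len < 10 * self.bin_size:
            raise ConfigurationError("chrom_len must be >= 10 * bin_size")


@dataclass
class SyntheticWorld:
    config: WorldConfig
    chromosomes: list[tuple[str, int]]
    genes: list[GeneModel]
    enhancers: pd.DataFrame  # enhancer_id, chrom, start, end
    planted_nuclear: set[str]
    planted_target_bins: dict[str, set[BinId]]
    planted_target_genes: dict[str, set[str]]
    eigenvalues: pd.DataFrame  # chrom, start, end, eigenvalue
    expression: pd.DataFrame  # promoter_id, gene_id, fraction, library, tags
    enhancer_counts: pd.DataFrame  # enhancer_id, library, tags
    exon_sequences: dict[str, str] = field(default_factory=dict)

    @property
    def bin_size(self) -> int:
        return self.config.bin_size

    @property
    def rng_seed(self) -> int:
        return self.config.seed

    def bins(self) -> list[BinId]:
        """All 10 kb bins tiling the genome (last bin of a chrom may be short)."""
        out: list[BinId] = []
        for chrom, length in self.chromosomes:
            out.extend(
                (chrom, s) for s in range(0, length, self.config.bin_size)
            )
        return out

    def n_bins(self, chrom: str) -> int:
        length = dict(self.chromosomes)[chrom]
        return -(-length // self.config.bin_size)

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index()[gene_id]

    def _gene_index(self) -> dict[str, GeneModel]:
        if not hasattr(self, "_idx"):
            self._idx = {g.gene_id: g for g in self.genes}
        return self._idx

    def strongest_promoters(self) -> dict[str, Promoter]:
        """Designated strongest promoter (the first) of every gene."""
        return {g.gene_id: g.promoters[0] for g in self.genes}


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _make_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    start: int,
    biotype: str,
    chrom_len: int,
) -> GeneModel:
    """Gene with alternating exon/intron blocks and 1-3 promoters.

    At least two exons so the intronic nascent-RNA filter is exercisable.
    """
    n_exons = int(rng.integers(2, 5))
    exons: list[tuple[int, int]] = []
    pos = start
    for _ in range(n_exons):
        exon_len = int(rng.integers(200, 1500))
        exons.append((pos, pos + exon_len))
        pos += exon_len + int(rng.integers(500, 5000))  # intron
    end = min(exons[-1][1], chrom_len)
    exons = [(s, min(e, chrom_len)) for s, e in exons if s < chrom_len]
    end = exons[-1][1]
    n_prom = int(rng.integers(1, 4))
    promoters = [
        Promoter(f"{gene_id}:p{i}", gene_id, chrom,
                 int(min(start + i * 400, chrom_len - 1)))
        for i in range(n_prom)
    ]
    return GeneModel(gene_id, chrom, start, end, "+", biotype, exons, promoters)


def generate_world(config: WorldConfig | None = None, **kwargs) -> SyntheticWorld:
    """Build a deterministic synthetic genome with planted ground truth.

    Half of the lncRNAs (``frac_nuclear``) are planted as nuclear: their
    promoter tag counts are nucleus-dominated, each receives
    ``n_target_bins`` planted contact bins inside its own A/B compartment
    segment, and one mRNA is placed with its strongest promoter inside each
    planted bin (so target-gene recovery is scorable).
    """
    if config is None:
        config = WorldConfig(**kwargs)
    elif kwargs:
        raise ConfigurationError("pass either a config or keyword overrides")
    config.validate()
    rng = _rng(config.seed, "world")

    chromosomes = [(f"chr{i + 1}", config.chrom_len) for i in range(config.n_chrom)]
    bin_size = config.bin_size
    comp = config.compartment_size

    # 1 Mb eigenvalues, alternating sign along each chromosome; even
    # segments are A (positive).  Expression is generated consistently so
    # the sign-reassignment step leaves these labels unchanged.
    eig_rows = []
    for chrom, length in chromosomes:
        for i, s in enumerate(range(0, length, comp)):
            mag = float(rng.uniform(0.5, 2.0))
            eig_rows.append(
                (chrom, s, min(s + comp, length), mag if i % 2 == 0 else -mag)
            )
    eigenvalues = pd.DataFrame(
        eig_rows, columns=["chrom", "start", "end", "eigenvalue"]
    )

    genes: list[GeneModel] = []
    n_nuclear = max(1, int(round(config.frac_nuclear * config.n_lncrna)))
    planted_nuclear: set[str] = set()
    planted_target_bins: dict[str, set[BinId]] = {}
    planted_target_genes: dict[str, set[str]] = {}

    a_segments = [
        (r.chrom, int(r.start), int(r.end))
        for r in eigenvalues.itertuples()
        if r.eigenvalue > 0
    ]

    mrna_counter = 0
    for i in range(config.n_lncrna):
        gid = f"LNC{i:04d}"
        nuclear = i < n_nuclear
        if nuclear:
            chrom, seg_start, seg_end = a_segments[
                int(rng.integers(0, len(a_segments)))
            ]
            # promoter well inside the segment
            gstart = int(rng.integers(seg_start + bin_size,
                                      seg_end - 40 * bin_size))
            genes.append(_make_gene(rng, gid, chrom, gstart, "lncRNA",
                                    dict(chromosomes)[chrom]))
            planted_nuclear.add(gid)
            gene = genes[-1]
            prom_bin = (chrom, (gstart // bin_size) * bin_size)
            # exclude the gene's own bins: reads there are nascent-filtered
            seg_bins = [
                (chrom, s) for s in range(seg_start, seg_end, bin_size)
                if (chrom, s) != prom_bin
                and not (s + bin_size > gene.start and s < gene.end)
            ]
            picks = rng.choice(len(seg_bins), size=config.n_target_bins,
                               replace=False)
            tbins = {seg_bins[int(j)] for j in picks}
            planted_target_bins[gid] = tbins
            # one mRNA with its strongest promoter inside each planted bin
            tgenes: set[str] = set()
            for (tchrom, tstart) in sorted(tbins):
                mid = f"MRNA{mrna_counter:04d}"
                mrna_counter += 1
                gpos = int(tstart + rng.integers(0, bin_size // 2))
                genes.append(_make_gene(rng, mid, tchrom, gpos, "mRNA",
                                        dict(chromosomes)[tchrom]))
                tgenes.add(mid)
            planted_target_genes[gid] = tgenes
        else:
            chrom, length = chromosomes[int(rng.integers(0, config.n_chrom))]
            gstart = int(rng.integers(0, length - 60_000))
            genes.append(_make_gene(rng, gid, chrom, gstart, "lncRNA", length))

    # Fill remaining mRNAs, balancing counts across chromosomes: the
    # trans-mRNA background a bin receives scales with the mRNA content of
    # the *other* chromosomes, so an uneven split would make the shared
    # background model misspecified per chromosome by construction.
    mrna_per_chrom = {c: 0 for c, _ in chromosomes}
    for g in genes:
        if g.biotype == "mRNA":
            mrna_per_chrom[g.chrom] += 1
    while mrna_counter < config.n_mrna:
        gid = f"MRNA{mrna_counter:04d}"
        mrna_counter += 1
        chrom = min(mrna_per_chrom, key=lambda c: (mrna_per_chrom[c], c))
        mrna_per_chrom[chrom] += 1
        length = dict(chromosomes)[chrom]
        gstart = int(rng.integers(0, length - 60_000))
        genes.append(_make_gene(rng, gid, chrom, gstart, "mRNA", length))

    # enhancers: intergenic-ish random 400 bp windows
    enh_rows = []
    for i in range(config.n_enhancers):
        chrom, length = chromosomes[int(rng.integers(0, config.n_chrom))]
        s = int(rng.integers(0, length - 400))
        enh_rows.append((f"ENH{i:04d}", chrom, s, s + 400))
    enhancers = pd.DataFrame(
        enh_rows, columns=["enhancer_id", "chrom", "start", "end"]
    )

    expression = _simulate_expression(config, genes, planted_nuclear)
    enhancer_counts = _simulate_enhancer_counts(config, enhancers)

    world = SyntheticWorld(
        config=config,
        chromosomes=chromosomes,
        genes=genes,
        enhancers=enhancers,
        planted_nuclear=planted_nuclear,
        planted_target_bins=planted_target_bins,
        planted_target_genes=planted_target_genes,
        eigenvalues=eigenvalues,
        expression=expression,
        enhancer_counts=enhancer_counts,
    )
    world.exon_sequences = _simulate_exon_sequences(config, genes,
                                                    planted_nuclear)
    return world


def _simulate_expression(
    config: WorldConfig, genes: list[GeneModel], planted_nuclear: set[str]
) -> pd.DataFrame:
    """CAGE-like tag counts per promoter x (fraction, library).

    The first promoter of each gene is the strongest by construction;
    secondary promoters get low counts, some below the 0.5 tpm / 3 tag
    selection thresholds.  Planted nuclear lncRNAs are nucleus-dominated,
    everything else cytoplasm-dominated.
    """
    rng = _rng(config.seed, "expression")
    rows = []
    for g in genes:
        nuclear = g.gene_id in planted_nuclear
        for k, p in enumerate(g.promoters):
            base = 60 if k == 0 else int(rng.integers(0, 8))
            for fraction in FRACTIONS:
                # note: tpm renormalisation rescales the sparse nuclear
                # libraries up, so the raw nuclear share of non-nuclear
                # genes must stay well below the classification boundary
                if nuclear:
                    lam = base if fraction == "nuclear" else base * 0.15
                else:
                    lam = base * 0.05 if fraction == "nuclear" else base
                for lib in range(LIBS_PER_FRACTION):
                    rows.append((
                        p.promoter_id, g.gene_id, fraction,
                        f"{fraction}_lib{lib + 1}",
                        int(rng.poisson(max(lam, 0.01))),
                    ))
    return pd.DataFrame(
        rows, columns=["promoter_id", "gene_id", "fraction", "library", "tags"]
    )


def _simulate_enhancer_counts(
    config: WorldConfig, enhancers: pd.DataFrame
) -> pd.DataFrame:
    rng = _rng(config.seed, "enhancer_counts")
    rows = []
    for eid in enhancers["enhancer_id"]:
        for fraction in FRACTIONS:
            for lib in range(LIBS_PER_FRACTION):
                rows.append((
                    eid, f"{fraction}_lib{lib + 1}", int(rng.poisson(2.0))
                ))
    return pd.DataFrame(rows, columns=["enhancer_id", "library", "tags"])


def _sirloin_instance(rng: np.random.Generator) -> str:
    out = []
    i, pat = 0, SIRLOIN_MOTIF
    while i < len(pat):
        if pat[i] == "[":
            j = pat.index("]", i)
            out.append(rng.choice(list(pat[i + 1:j])))
            i = j + 1
        else:
            out.append(pat[i])
            i += 1
    return "".join(out)


def _simulate_exon_sequences(
    config: WorldConfig, genes: list[GeneModel], planted_nuclear: set[str]
) -> dict[str, str]:
    """Concatenated exon sequence per gene; planted nuclear lncRNAs carry
    U1 and SIRLOIN motif instances at elevated rates."""
    rng = _rng(config.seed, "sequences")
    seqs: dict[str, str] = {}
    bases = np.array(list("ACGT"))
    for g in genes:
        n = sum(e - s for s, e in g.exons)
        seq = list(rng.choice(bases, size=n))
        if g.gene_id in planted_nuclear or rng.random() < 0.1:
            for motif in ([U1_MOTIF] * int(rng.integers(1, 4))
                          + [_sirloin_instance(rng)]):
                if len(seq) > len(motif):
                    pos = int(rng.integers(0, len(seq) - len(motif)))
                    seq[pos:pos + len(motif)] = list(motif)
        seqs[g.gene_id] = "".join(seq)
    return seqs


# ---------------------------------------------------------------------------
# RNA-DNA contacts
# ---------------------------------------------------------------------------

def simulate_contacts(
    world: SyntheticWorld,
    background_rate: float = 2.0,
    enrichment_fold: float = 20.0,
    nascent_frac: float = 0.2,
) -> pd.DataFrame:
    """RNA-DNA contact table with uniform background and planted enrichment.

    Every gene emits ``Poisson(background_rate * n_bins)`` contacts whose
    DNA tags are uniform over the genome; planted nuclear lncRNAs emit
    additional contacts into each planted target bin so the bin's total
    mean count is ``enrichment_fold * background_rate``.  A ``nascent_frac`` share of each
    gene's contacts is converted to a nascent signature (RNA tag wholly
    inside an intron, or DNA tag inside the gene body).

    Columns: gene_id, chrom_rna, start_rna, end_rna, chrom_dna, pos_dna.
    """
    if background_rate <= 0:
        raise ConfigurationError("background_rate must be > 0")
    if enrichment_fold < 1:
        raise ConfigurationError("enrichment_fold must be >= 1")
    if not 0 <= nascent_frac < 1:
        raise ConfigurationError("nascent_frac must be in [0, 1)")
    if not any(g.biotype == "mRNA" for g in world.genes):
        raise ConfigurationError(
            "world has no mRNA genes: trans-mRNA background unestimable"
        )

    rng = _rng(world.rng_seed, "contacts")
    all_bins = world.bins()
    bin_chrom = np.array([b[0] for b in all_bins])
    bin_start = np.array([b[1] for b in all_bins])
    bin_size = world.bin_size
    chrom_len = dict(world.chromosomes)
    bin_cap = np.array(
        [min(s + bin_size, chrom_len[c]) for c, s in all_bins]
    )
    frames: list[pd.DataFrame] = []

    for g in world.genes:
        n_bg = int(rng.poisson(background_rate * len(all_bins)))
        picks = rng.integers(0, len(all_bins), size=n_bg)
        chrom_dna = bin_chrom[picks]
        pos_dna = bin_start[picks] + (
            rng.random(n_bg) * (bin_cap[picks] - bin_start[picks])
        ).astype(np.int64)
        if g.gene_id in world.planted_target_bins:
            extra_c, extra_p = [], []
            # planted bins also receive background, so the extra signal is
            # (fold - 1) x rate: total mean = fold x rate, and fold = 1
            # leaves planted bins indistinguishable from background
            for (tchrom, tstart) in sorted(world.planted_target_bins[g.gene_id]):
                k = int(rng.poisson((enrichment_fold - 1.0) * background_rate))
                hi = min(tstart + bin_size, chrom_len[tchrom])
                extra_c.append(np.full(k, tchrom))
                extra_p.append(rng.integers(tstart, hi, size=k))
            chrom_dna = np.concatenate([chrom_dna, *extra_c])
            pos_dna = np.concatenate([pos_dna, *extra_p])
        n = len(pos_dna)

        nascent = rng.random(n) < nascent_frac
        rule1 = nascent & (rng.random(n) < 0.5) & bool(g.introns)
        rule2 = nascent & ~rule1
        # default: RNA tag inside a random exon (non-nascent signature)
        exon_idx = rng.integers(0, len(g.exons), size=n)
        ex = np.array(g.exons)
        lengths = np.minimum(30, ex[exon_idx, 1] - ex[exon_idx, 0])
        span = np.maximum(ex[exon_idx, 1] - lengths - ex[exon_idx, 0], 0)
        start_rna = ex[exon_idx, 0] + (
            rng.random(n) * (span + 1)
        ).astype(np.int64)
        # rule 1: RNA tag wholly inside an intron
        if rule1.any():
            intr = np.array(g.introns)
            ii = rng.integers(0, len(intr), size=int(rule1.sum()))
            ilen = np.minimum(30, intr[ii, 1] - intr[ii, 0])
            ispan = np.maximum(intr[ii, 1] - ilen - intr[ii, 0], 0)
            istart = intr[ii, 0] + (
                rng.random(int(rule1.sum())) * (ispan + 1)
            ).astype(np.int64)
            start_rna[rule1] = istart
            lengths[rule1] = ilen
        # rule 2: DNA tag inside the gene of origin
        if rule2.any():
            chrom_dna = chrom_dna.astype(object)
            chrom_dna[rule2] = g.chrom
            pos_dna[rule2] = rng.integers(g.start, g.end,
                                          size=int(rule2.sum()))
        frames.append(pd.DataFrame({
            "gene_id": g.gene_id,
            "chrom_rna": g.chrom,
            "start_rna": start_rna,
            "end_rna": start_rna + lengths,
            "chrom_dna": chrom_dna.astype(str),
            "pos_dna": pos_dna,
        }))

    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Hi-C interactions
# ---------------------------------------------------------------------------

def simulate_hic(
    world: SyntheticWorld,
    p_neighbor: float = 0.005,
    q_noise: float = 0.05,
) -> pd.DataFrame:
    """Pairwise 10 kb Hi-C interaction table with read pairs and q-values.

    A scaffold guarantees that every planted target bin of a planted
    nuclear lncRNA lies within two hops of its promoter bin (direct edge,
    or via the first planted bin as hub), with passing statistics
    (read_pairs >= 5, q <= 0.05).  Random intra-chromosomal edges are added
    at rate ``p_neighbor``; a ``q_noise`` share of those gets failing
    statistics so the significance filter removes them.
    """
    if not (0 <= p_neighbor <= 1 and 0 <= q_noise <= 1):
        raise ConfigurationError("probabilities must be in [0, 1]")
    rng = _rng(world.rng_seed, "hic")
    bin_size = world.bin_size
    strongest = world.strongest_promoters()

    edges: dict[tuple[str, int, int], tuple[int, float]] = {}

    def passing() -> tuple[int, float]:
        return int(rng.integers(5, 60)), float(rng.uniform(0.0, 0.05))

    def failing() -> tuple[int, float]:
        if rng.random() < 0.5:
            return int(rng.integers(1, 5)), float(rng.uniform(0.0, 0.05))
        return int(rng.integers(5, 60)), float(rng.uniform(0.051, 1.0))

    def add(chrom: str, a: int, b: int, stats: tuple[int, float]) -> None:
        if a == b:
            return
        key = (chrom, min(a, b), max(a, b))
        if key not in edges:
            edges[key] = stats

    scaffold_keys: set[tuple[str, int, int]] = set()
    for gid, tbins in world.planted_target_bins.items():
        prom = strongest[gid]
        pbin = (prom.pos // bin_size) * bin_size
        ordered = sorted(tbins)
        hub = ordered[0][1]
        add(prom.chrom, pbin, hub, passing())
        scaffold_keys.add((prom.chrom, min(pbin, hub), max(pbin, hub)))
        for chrom, tstart in ordered[1:]:
            if rng.random() < 0.5:
                add(chrom, pbin, tstart, passing())
                scaffold_keys.add((chrom, min(pbin, tstart), max(pbin, tstart)))
            else:
                add(chrom, hub, tstart, passing())
                scaffold_keys.add((chrom, min(hub, tstart), max(hub, tstart)))

    for chrom, length in world.chromosomes:
        starts = np.arange(0, length, bin_size)
        n = len(starts)
        n_pairs = n * (n - 1) // 2
        n_rand = int(rng.binomial(n_pairs, p_neighbor))
        ii = rng.integers(0, n, size=n_rand)
        jj = rng.integers(0, n, size=n_rand)
        for i, j in zip(ii, jj):
            if i == j:
                continue
            key = (chrom, int(starts[min(i, j)]), int(starts[max(i, j)]))
            if key in edges:
                continue
            stats = failing() if rng.random() < q_noise else passing()
            edges[key] = stats

    rows = [
        (chrom, a, b, rp, q)
        for (chrom, a, b), (rp, q) in sorted(edges.items())
    ]
    df = pd.DataFrame(
        rows, columns=["chrom", "bin_i_start", "bin_j_start",
                       "read_pairs", "q_value"]
    )
    df.attrs["scaffold_keys"] = scaffold_keys
    return df


# ---------------------------------------------------------------------------
# Knockdown differential expression
# ---------------------------------------------------------------------------

def simulate_knockdown_de(
    world: SyntheticWorld,
    effect_direction: dict[str, int] | int = 1,
    frac_responsive: float = 0.8,
    background_de_rate: float = 0.05,
) -> pd.DataFrame:
    """Per-ASO differential expression after knocking down planted lncRNAs.

    A ``frac_responsive`` share of each planted lncRNA's target genes is
    differentially expressed in the lncRNA's planted direction (FDR drawn
    below 0.1 in at least one of two ASOs); non-target genes are DE at
    ``background_de_rate`` with random sign.

    Columns: lncrna_id, aso, gene_id, log2fc, fdr.
    """
    if not 0 <= frac_responsive <= 1:
        raise ConfigurationError("frac_responsive must be in [0, 1]")
    rng = _rng(world.rng_seed, "knockdown_de")
    mrnas = [g.gene_id for g in world.genes if g.biotype == "mRNA"]
    rows = []
    for gid in sorted(world.planted_target_bins):
        direction = (effect_direction.get(gid, 1)
                     if isinstance(effect_direction, dict)
                     else int(effect_direction))
        targets = world.planted_target_genes.get(gid, set())
        for gene in mrnas:
            if gene in targets and rng.random() < frac_responsive:
                sign, de = direction, True
            elif rng.random() < background_de_rate:
                sign, de = (1 if rng.random() < 0.5 else -1), True
            else:
                sign, de = (1 if rng.random() < 0.5 else -1), False
            de_aso = int(rng.integers(1, 3)) if de else 0  # which ASO responds
            for aso in (1, 2):
                if de and (aso == de_aso or rng.random() < 0.5):
                    fdr = float(rng.uniform(0.0, 0.1))
                    lfc = sign * float(abs(rng.normal(1.5, 0.3)))
                else:
                    fdr = float(rng.uniform(0.2, 1.0))
                    lfc = float(rng.normal(0.0, 0.2))
                rows.append((gid, f"ASO{aso}", gene, lfc, fdr))
    return pd.DataFrame(
        rows, columns=["lncrna_id", "aso", "gene_id", "log2fc", "fdr"]
    )


# ---------------------------------------------------------------------------
# eCLIP / ChIP / PPI / RBP-knockdown tables
# ---------------------------------------------------------------------------

def simulate_eclip(
    world: SyntheticWorld,
    n_rbp: int = 20,
    p_bind_nuclear: float = 0.95,
    p_bind_other: float = 0.5,
    p_bind_mrna: float = 0.15,
) -> pd.DataFrame:
    """Gene-level eCLIP table (rbp, gene_id, log2fc, fdr).

    RBPs bind planted nuclear lncRNAs at a higher rate than other genes;
    bound genes get FDR <= 0.05 and log2FC > 0.5 so they pass the
    reliable-target filter.
    """
    rng = _rng(world.rng_seed, "eclip")
    rows = []
    for r in range(n_rbp):
        rbp = f"RBP{r:03d}"
        for g in world.genes:
            if g.biotype == "lncRNA":
                p = (p_bind_nuclear if g.gene_id in world.planted_nuclear
                     else p_bind_other)
            else:
                p = p_bind_mrna
            if rng.random() < p:
                fdr = float(rng.uniform(0.0, 0.05))
                lfc = float(rng.uniform(0.6, 3.0))
            else:
                fdr = float(rng.uniform(0.1, 1.0))
                lfc = float(rng.normal(0.0, 0.3))
            rows.append((rbp, g.gene_id, lfc, fdr))
    return pd.DataFrame(rows, columns=["rbp", "gene_id", "log2fc", "fdr"])


def simulate_chip(
    world: SyntheticWorld,
    eclip: pd.DataFrame,
    p_target_promoter: float = 0.6,
    p_background: float = 0.05,
) -> pd.DataFrame:
    """ChIP-like RBP -> promoter binding table (rbp, promoter_id).

    Plants the recruiting structure: an RBP that binds a lncRNA tends to
    occupy the promoters of that lncRNA's planted target genes.
    """
    rng = _rng(world.rng_seed, "chip")
    bound = (
        eclip[(eclip.fdr <= 0.05) & (eclip.log2fc > 0.5)]
        .groupby("rbp")["gene_id"].agg(set).to_dict()
    )
    strongest = world.strongest_promoters()
    rows = set()
    for rbp, genes in bound.items():
        for lnc, tgenes in world.planted_target_genes.items():
            if lnc in genes:
                for t in tgenes:
                    if rng.random() < p_target_promoter:
                        rows.add((rbp, strongest[t].promoter_id))
        for g in world.genes:
            if rng.random() < p_background:
                rows.add((rbp, strongest[g.gene_id].promoter_id))
    return pd.DataFrame(sorted(rows), columns=["rbp", "promoter_id"])


def simulate_ppi(world: SyntheticWorld, n_rbp: int = 20) -> pd.DataFrame:
    """STRING-like RBP-RBP scores in [0, 1]; downstream keeps score > 0.4."""
    rng = _rng(world.rng_seed, "ppi")
    rows = []
    for i in range(n_rbp):
        for j in range(i + 1, n_rbp):
            rows.append((f"RBP{i:03d}", f"RBP{j:03d}",
                         round(float(rng.uniform(0.0, 1.0)), 3)))
    return pd.DataFrame(rows, columns=["rbp_a", "rbp_b", "score"])


def simulate_rbp_knockdown_de(
    world: SyntheticWorld,
    eclip: pd.DataFrame,
    p_de_linked: float = 0.5,
    p_de_background: float = 0.05,
) -> pd.DataFrame:
    """Genes DE after RBP silencing (rbp, gene_id, fdr).

    Target genes of lncRNAs bound by the RBP respond at ``p_de_linked``.
    """
    rng = _rng(world.rng_seed, "rbp_kd")
    bound = (
        eclip[(eclip.fdr <= 0.05) & (eclip.log2fc > 0.5)]
        .groupby("rbp")["gene_id"].agg(set).to_dict()
    )
    rows = []
    for rbp in sorted(bound):
        linked: set[str] = set()
        for lnc, tgenes in world.planted_target_genes.items():
            if lnc in bound[rbp]:
                linked |= tgenes
        for g in world.genes:
            if g.biotype != "mRNA":
                continue
            p = p_de_linked if g.gene_id in linked else p_de_background
            fdr = (float(rng.uniform(0.0, 0.1)) if rng.random() < p
                   else float(rng.uniform(0.2, 1.0)))
            rows.append((rbp, g.gene_id, fdr))
    return pd.DataFrame(rows, columns=["rbp", "gene_id", "fdr"])


# ---------------------------------------------------------------------------
# TFBS predictions and GO-style gene sets
# ---------------------------------------------------------------------------

def simulate_tfbs(
    world: SyntheticWorld,
    n_motifs: int = 5,
    p_region: float = 0.75,
) -> pd.DataFrame:
    """Predicted TFBS sites with posterior scores near promoters/enhancers.

    Each motif hits a ``p_region`` share of regions with 1-2 sites of
    posterior 0.05-0.4, so per-region aggregates straddle the 0.1
    assignment threshold.  Columns: chrom, start, end, motif, posterior.
    """
    rng = _rng(world.rng_seed, "tfbs")
    regions = [
        (p.chrom, p.pos, p.pos + 1)
        for p in world.strongest_promoters().values()
    ] + [
        (r.chrom, int(r.start), int(r.end))
        for r in world.enhancers.itertuples()
    ]
    rows = []
    for m in range(n_motifs):
        motif = f"MOTIF{m:02d}"
        for chrom, s, e in regions:
            if rng.random() > p_region:
                continue
            for _ in range(int(rng.integers(1, 3))):
                site = int(rng.integers(max(s - 200, 0), e + 200))
                rows.append((chrom, site, site + 12, motif,
                             round(float(rng.uniform(0.05, 0.4)), 4)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "motif", "posterior"]
    )


def simulate_gene_sets(
    world: SyntheticWorld, n_terms: int = 15, seed_frac: float = 0.4
) -> dict[str, set[str]]:
    """GO-like term -> mRNA gene sets; some terms seeded from planted
    target-gene groups so per-lncRNA enrichment is recoverable."""
    rng = _rng(world.rng_seed, "gene_sets")
    mrnas = [g.gene_id for g in world.genes if g.biotype == "mRNA"]
    terms: dict[str, set[str]] = {}
    planted = sorted(world.planted_target_genes.items())
    for t in range(n_terms):
        name = f"TERM{t:03d}"
        members: set[str] = set()
        if planted and rng.random() < seed_frac:
            _, tgenes = planted[int(rng.integers(0, len(planted)))]
            members |= tgenes
        n_extra = int(rng.integers(5, 30))
        members |= {mrnas[int(j)] for j in
                    rng.integers(0, len(mrnas), size=n_extra)}
        terms[name] = members
    return terms


# ---------------------------------------------------------------------------
# Writers (all plain text, single header line, BED-style coordinates)
# ---------------------------------------------------------------------------

def write_world(world: SyntheticWorld, outdir, *,
                background_rate: float = 2.0,
                enrichment_fold: float = 20.0,
                nascent_frac: float = 0.2,
                frac_responsive: float = 0.8,
                n_rbp: int = 20) -> dict[str, str]:
    """Generate and write every pipeline input table under ``outdir``.

    Returns a map of logical table name -> file path.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save(name: str, df: pd.DataFrame) -> None:
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = str(path)

    contacts = simulate_contacts(world, background_rate, enrichment_fold,
                                 nascent_frac)
    save("contacts", contacts)
    save("hic", simulate_hic(world))
    save("expression", world.expression)
    save("enhancer_expression", world.enhancer_counts)
    save("compartments", world.eigenvalues)
    save("de", simulate_knockdown_de(world, frac_responsive=frac_responsive))
    eclip = simulate_eclip(world, n_rbp=n_rbp)
    save("eclip", eclip)
    save("chip", simulate_chip(world, eclip))
    save("ppi", simulate_ppi(world, n_rbp=n_rbp))
    save("rbp_kd", simulate_rbp_knockdown_de(world, eclip))
    save("tfbs", simulate_tfbs(world))
    save("enhancers", world.enhancers)

    genes_path = outdir / "genes.bed"
    write_genes_bed(world.genes, genes_path)
    paths["genes"] = str(genes_path)

    fasta_path = outdir / "exons.fasta"
    with open(fasta_path, "w") as fh:
        for gid in sorted(world.exon_sequences):
            fh.write(f">{gid}\n{world.exon_sequences[gid]}\n")
    paths["exons"] = str(fasta_path)

    gmt_path = outdir / "gene_sets.gmt"
    with open(gmt_path, "w") as fh:
        for term, members in sorted(simulate_gene_sets(world).items()):
            fh.write("\t".join([term, "synthetic"] + sorted(members)) + "\n")
    paths["gene_sets"] = str(gmt_path)
    return paths


def write_genes_bed(genes: list[GeneModel], path) -> None:
    """BED12-like gene models with exon blocks plus biotype and promoters."""
    rows = []
    for g in genes:
        sizes = ",".join(str(e - s) for s, e in g.exons)
        starts = ",".join(str(s - g.start) for s, _ in g.exons)
        proms = ";".join(f"{p.promoter_id}:{p.pos}" for p in g.promoters)
        rows.append((g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                     g.start, g.end, "0", len(g.exons), sizes, starts,
                     g.biotype, proms))
    pd.DataFrame(rows, columns=[
        "chrom", "start", "end", "name", "score", "strand", "thick_start",
        "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
        "biotype", "promoters",
    ]).to_csv(path, sep="\t", index=False)


def read_genes_bed(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t")
    genes = []
    for r in df.itertuples():
        sizes = [int(x) for x in str(r.block_sizes).split(",")]
        starts = [int(x) for x in str(r.block_starts).split(",")]
        exons = [(r.start + s, r.start + s + sz)
                 for s, sz in zip(starts, sizes)]
        promoters = []
        for tok in str(r.promoters).split(";"):
            pid, pos = tok.rsplit(":", 1)
            promoters.append(Promoter(pid, r.name, r.chrom, int(pos)))
        genes.append(GeneModel(r.name, r.chrom, int(r.start), int(r.end),
                               r.strand, r.biotype, exons, promoters))
    return genes
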