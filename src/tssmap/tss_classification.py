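"""Minimal-transcription-unit model and hierarchical TSS classification.

The MTU of a gene is its CDS extended by fixed minimal UTR margins: 14 nt of
5'-UTR (the minimal ribosome binding site) and 20 nt of 3'-UTR (a minimal
terminator hairpin).  Immediately upstream of the MTU lies a 40-nt promoter
region, so the 54 nt upstream of a start codon (14 + 40) form the "m-window"
whose sense overlap by a TSS contig marks an mRNA TSS.

Six TSS classes are assigned with a fixed precedence so that every TSS gets
exactly one class:

``lmTSS``
    leaderless mRNA; the TSS coincides with the first nucleotide of an
    annotated same-strand ATG start codon.
``mTSS``
    mRNA TSS; the contig overlaps, in sense, the 54-nt window upstream of a
    start codon (or a prior mRNA-leader contig ties it to that gene).
``seTSS``
    internal sense TSS; the TSS position lies within a same-strand MTU.
``asTSS``
    cis-antisense TSS; the contig overlaps an MTU in antisense orientation.
``pmTSS``
    putative mRNA TSS; the contig overlaps no MTU on either strand and the
    TSS is at most 300 nt upstream, in sense, of a start codon.
``sTSS``
    trans-encoded sRNA TSS; everything else (intergenic, with any same-strand
    downstream start codon more than 300 nt away).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import Genome, GeneModel, Operon
from .tss_calling import TSSContig

__all__ = [
    "MTUConfig",
    "MTU",
    "ClassifiedTSS",
    "RNAFeature",
    "CLASS_ORDER",
    "build_mtus",
    "classify_tss",
    "merge_rna_features",
    "summarize_classification",
]

CLASS_ORDER = ("lmTSS", "mTSS", "seTSS", "asTSS", "pmTSS", "sTSS")


@dataclass
class MTUConfig:
    utr5_len: int = 14
    utr3_len: int = 20
    promoter_len: int = 40
    pm_max_dist: int = 300

    def __post_init__(self) -> None:
        for name in ("utr5_len", "utr3_len", "promoter_len", "pm_max_dist"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def m_window(self) -> int:
        """Length of the m-window upstream of a start codon (5'-UTR + promoter)."""
        return self.utr5_len + self.promoter_len


@dataclass
class MTU:
    """A gene's minimal transcription unit, as genomic intervals.

    ``span`` covers [start codon - utr5, stop codon + utr3] in transcription
    direction; ``promoter`` is the 40-nt block immediately upstream of the
    span; ``m_window`` the union of promoter and 5'-UTR margin (54 nt upstream
    of the start codon).  Intervals are clipped at replicon ends, in which
    case ``truncated`` is set.  Circular replicons are treated as linearised:
    windows are not wrapped across the origin.
    """

    gene: GeneModel
    span: tuple[int, int]
    promoter: tuple[int, int] | None
    m_window: tuple[int, int] | None
    truncated: bool = False

    @property
    def strand(self) -> str:
        return self.gene.strand

    @property
    def replicon(self) -> str:
        return self.gene.replicon


def _clip(lo: int, hi: int, length: int) -> tuple[tuple[int, int] | None, bool]:
    clo, chi = max(lo, 1), min(hi, length)
    if clo > chi:
        return None, True
    return (clo, chi), (clo != lo or chi != hi)


def build_mtus(
    genes: list[GeneModel], config: MTUConfig | None = None, genome: Genome | None = None
) -> list[MTU]:
    """One MTU per gene, with exact fixed-margin coordinates."""
    config = config or MTUConfig()
    mtus = []
    for g in genes:
        L = genome.length(g.replicon) if genome is not None else 10**12
        if g.strand == "+":
            span_lo, span_hi = g.start_codon_pos - config.utr5_len, g.stop_codon_pos + config.utr3_len
            prom_lo, prom_hi = span_lo - config.promoter_len, span_lo - 1
            win_lo, win_hi = g.start_codon_pos - config.m_window, g.start_codon_pos - 1
        else:
            span_lo, span_hi = g.stop_codon_pos - config.utr3_len, g.start_codon_pos + config.utr5_len
            prom_lo, prom_hi = span_hi + 1, span_hi + config.promoter_len
            win_lo, win_hi = g.start_codon_pos + 1, g.start_codon_pos + config.m_window
        span, t1 = _clip(span_lo, span_hi, L)
        prom, t2 = _clip(prom_lo, prom_hi, L)
        win, t3 = _clip(win_lo, win_hi, L)
        if span is None:
            raise ValueError(f"gene {g.id}: MTU span entirely outside replicon")
        mtus.append(MTU(gene=g, span=span, promoter=prom, m_window=win, truncated=t1 or t2 or t3))
    return mtus


@dataclass
class ClassifiedTSS:
    tss: TSSContig
    tss_class: str
    target_feature: str | None = None
    utr5_len: int | None = None
    evidence: str = ""


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _updist(tss_pos: int, start_codon: int, strand: str) -> int:
    """Distance from TSS to start codon in transcription direction (>0 = upstream)."""
    return start_codon - tss_pos if strand == "+" else tss_pos - start_codon


def classify_tss(
    tss: list[TSSContig],
    mtus: list[MTU],
    genome: Genome,
    leaders: pd.DataFrame | None = None,
    config: MTUConfig | None = None,
) -> list[ClassifiedTSS]:
    """Assign each TSS contig exactly one of the six classes.

    ``leaders``, when given, is a frame of prior mRNA-leader contigs with
    columns ``replicon``, ``strand``, ``five_prime_pos`` and ``gene_id``; a
    TSS whose contig lies upstream of a gene's promoter region without
    overlapping it is still an mTSS of that gene if such a leader starts at
    the TSS position or upstream of it.
    """
    config = config or MTUConfig()
    by_rep: dict[str, list[MTU]] = {}
    for m in mtus:
        by_rep.setdefault(m.replicon, []).append(m)
    leader_index: dict[str, list[tuple[str, str, int]]] = {}
    if leaders is not None:
        for row in leaders.itertuples(index=False):
            leader_index.setdefault(str(row.gene_id), []).append(
                (str(row.replicon), str(row.strand), int(row.five_prime_pos))
            )
    out = []
    for t in tss:
        if t.tss_pos < 1 or t.tss_pos > genome.length(t.replicon):
            raise ValueError(f"TSS {t.id or t.tss_pos} outside replicon {t.replicon!r}")
        out.append(_classify_one(t, by_rep.get(t.replicon, []), genome, leader_index, config))
    return out


def _classify_one(
    t: TSSContig,
    mtus: list[MTU],
    genome: Genome,
    leader_index: dict[str, list[tuple[str, str, int]]],
    config: MTUConfig,
) -> ClassifiedTSS:
    contig = (t.lo, t.hi)
    sense = [m for m in mtus if m.strand == t.strand]
    antis = [m for m in mtus if m.strand != t.strand]

    # 1. lmTSS: TSS at the first nucleotide of an annotated same-strand ATG start
    for m in sense:
        if m.gene.start_codon_pos == t.tss_pos:
            if genome.triplet_at(t.replicon, t.tss_pos, t.strand) == "ATG":
                return ClassifiedTSS(t, "lmTSS", m.gene.id, 0, "tss at ATG start codon")

    # 2. mTSS: contig overlaps the 54-nt window upstream of a start codon in sense
    m_hits = [
        m
        for m in sense
        if m.m_window is not None
        and _overlaps(contig, m.m_window)
        and _updist(t.tss_pos, m.gene.start_codon_pos, t.strand) > 0
    ]
    if m_hits:
        # several windows may qualify: assign the nearest downstream start codon
        best = min(m_hits, key=lambda m: _updist(t.tss_pos, m.gene.start_codon_pos, t.strand))
        d = _updist(t.tss_pos, best.gene.start_codon_pos, t.strand)
        return ClassifiedTSS(t, "mTSS", best.gene.id, d, "contig overlaps m-window")
    # mTSS via prior mRNA-leader contigs: contig entirely upstream of the
    # promoter region, tied to the gene by a leader starting at/upstream of TSS
    for m in sense:
        if m.promoter is None:
            continue
        for rep, strand, lpos in leader_index.get(m.gene.id, []):
            if rep != t.replicon or strand != t.strand:
                continue
            leader_upstream = (lpos <= t.tss_pos) if t.strand == "+" else (lpos >= t.tss_pos)
            if t.strand == "+":
                contig_upstream = contig[1] < m.promoter[0]
            else:
                contig_upstream = contig[0] > m.promoter[1]
            if leader_upstream and contig_upstream:
                d = _updist(t.tss_pos, m.gene.start_codon_pos, t.strand)
                return ClassifiedTSS(t, "mTSS", m.gene.id, d, "prior mRNA-leader contig")

    # 3. seTSS: TSS position inside a same-strand MTU
    for m in sense:
        if m.span[0] <= t.tss_pos <= m.span[1]:
            return ClassifiedTSS(t, "seTSS", m.gene.id, None, "tss inside sense MTU")

    # 4. asTSS: contig overlaps any MTU in antisense
    as_hits = [m for m in antis if _overlaps(contig, m.span)]
    if as_hits:
        best = max(
            as_hits,
            key=lambda m: (
                min(contig[1], m.span[1]) - max(contig[0], m.span[0]),
                -m.span[0],
            ),
        )
        return ClassifiedTSS(t, "asTSS", best.gene.id, None, "contig overlaps antisense MTU")

    # 5. pmTSS: no MTU overlap on either strand, start codon <= 300 nt downstream
    overlaps_any = any(_overlaps(contig, m.span) for m in mtus)
    if not overlaps_any:
        down = [
            m
            for m in sense
            if 0 < _updist(t.tss_pos, m.gene.start_codon_pos, t.strand) <= config.pm_max_dist
        ]
        if down:
            best = min(down, key=lambda m: _updist(t.tss_pos, m.gene.start_codon_pos, t.strand))
            d = _updist(t.tss_pos, best.gene.start_codon_pos, t.strand)
            return ClassifiedTSS(t, "pmTSS", best.gene.id, d, "start codon within 300 nt")

    # 6. sTSS
    return ClassifiedTSS(t, "sTSS", None, None, "no MTU context")


# ---------------------------------------------------------------------------
# sRNA / asRNA features


@dataclass
class RNAFeature:
    kind: str  # sRNA | asRNA
    id: str
    replicon: str
    strand: str
    lo: int
    hi: int
    member_tss: list[str] = field(default_factory=list)
    target: str | None = None  # gene id (asRNA) or IGR id (sRNA)
    overlap_region: str | None = None  # asRNA: 5'-UTR | CDS | 3'-UTR


def _igr_id(lo: int, hi: int, replicon: str, genes: list[GeneModel]) -> str:
    left = [g for g in genes if g.replicon == replicon and g.right < lo]
    right = [g for g in genes if g.replicon == replicon and g.left > hi]
    lname = max(left, key=lambda g: g.right).id if left else "origin"
    rname = min(right, key=lambda g: g.left).id if right else "end"
    return f"IGR:{lname}|{rname}"


def merge_rna_features(
    classified: list[ClassifiedTSS],
    genes: list[GeneModel],
    config: MTUConfig | None = None,
    replicon_letters: dict[str, str] | None = None,
    prefix: str = "SM",
) -> list[RNAFeature]:
    """Merge overlapping sTSS contigs into sRNAs and asTSS contigs into asRNAs.

    asTSS contigs are grouped per target gene; each asRNA is annotated with
    the region of its target it overlaps (5'-UTR, CDS or 3'-UTR, using the
    fixed 14/20-nt UTR margins; when several regions are touched the most
    5' one wins).
    """
    config = config or MTUConfig()
    if replicon_letters is None:
        reps = sorted({c.tss.replicon for c in classified})
        replicon_letters = {r: chr(ord("A") + i) for i, r in enumerate(reps)}
    gene_by_id = {g.id: g for g in genes}
    features: list[RNAFeature] = []

    def clusters(items: list[ClassifiedTSS]) -> list[list[ClassifiedTSS]]:
        items = sorted(items, key=lambda c: c.tss.lo)
        out: list[list[ClassifiedTSS]] = []
        for c in items:
            if out and c.tss.lo <= max(x.tss.hi for x in out[-1]):
                out[-1].append(c)
            else:
                out.append([c])
        return out

    srna = [c for c in classified if c.tss_class == "sTSS"]
    for (rep, strand), group in sorted(
        _group_by(srna, lambda c: (c.tss.replicon, c.tss.strand)).items()
    ):
        for cl in clusters(group):
            lo = min(c.tss.lo for c in cl)
            hi = max(c.tss.hi for c in cl)
            features.append(
                RNAFeature(
                    kind="sRNA",
                    id="",
                    replicon=rep,
                    strand=strand,
                    lo=lo,
                    hi=hi,
                    member_tss=[c.tss.id or str(c.tss.tss_pos) for c in cl],
                    target=_igr_id(lo, hi, rep, genes),
                )
            )

    asrna = [c for c in classified if c.tss_class == "asTSS"]
    for (rep, strand, target), group in sorted(
        _group_by(asrna, lambda c: (c.tss.replicon, c.tss.strand, c.target_feature or "")).items()
    ):
        gene = gene_by_id.get(target)
        for cl in clusters(group):
            lo = min(c.tss.lo for c in cl)
            hi = max(c.tss.hi for c in cl)
            region = _overlap_region(lo, hi, gene, config) if gene else None
            features.append(
                RNAFeature(
                    kind="asRNA",
                    id="",
                    replicon=rep,
                    strand=strand,
                    lo=lo,
                    hi=hi,
                    member_tss=[c.tss.id or str(c.tss.tss_pos) for c in cl],
                    target=target,
                    overlap_region=region,
                )
            )

    counters: dict[tuple[str, str], int] = {}
    for f in sorted(features, key=lambda f: (f.replicon, f.lo, f.kind)):
        n = counters.get((f.replicon, f.kind), 0) + 1
        counters[(f.replicon, f.kind)] = n
        f.id = f"{prefix}{replicon_letters[f.replicon]}_{f.kind}_{n}"
    features.sort(key=lambda f: (f.replicon, f.lo, f.kind))
    return features


def _group_by(items, keyfunc):
    out: dict = {}
    for it in items:
        out.setdefault(keyfunc(it), []).append(it)
    return out


def _overlap_region(lo: int, hi: int, gene: GeneModel, config: MTUConfig) -> str:
    if gene.strand == "+":
        utr5 = (gene.start_codon_pos - config.utr5_len, gene.start_codon_pos - 1)
        cds = (gene.left, gene.right)
        utr3 = (gene.stop_codon_pos + 1, gene.stop_codon_pos + config.utr3_len)
    else:
        utr5 = (gene.start_codon_pos + 1, gene.start_codon_pos + config.utr5_len)
        cds = (gene.left, gene.right)
        utr3 = (gene.stop_codon_pos - config.utr3_len, gene.stop_codon_pos - 1)
    for name, iv in (("5'-UTR", utr5), ("CDS", cds), ("3'-UTR", utr3)):
        if _overlaps((lo, hi), iv):
            return name
    return "none"


# ---------------------------------------------------------------------------
# summary


def summarize_classification(
    classified: list[ClassifiedTSS],
    features: list[RNAFeature],
    genes: list[GeneModel],
    genome: Genome,
    operons: list[Operon] | None = None,
) -> dict:
    """Classification summary: class counts, per-gene TSS histograms, +1..+3
    nucleotide composition of mTSS transcripts, 5'-UTR length statistics,
    per-replicon/strand proportions and (optionally) an operon report."""
    total = len(classified)
    class_counts = {c: 0 for c in CLASS_ORDER}
    for c in classified:
        class_counts[c.tss_class] += 1

    def histogram(counts: list[int]) -> dict[str, int]:
        hist = {"1": 0, "2": 0, "3": 0, "4": 0, ">4": 0}
        for n in counts:
            hist[str(n) if n <= 4 else ">4"] += 1
        return hist

    per_gene: dict[str, int] = {}
    for c in classified:
        if c.tss_class in ("mTSS", "lmTSS") and c.target_feature:
            per_gene[c.target_feature] = per_gene.get(c.target_feature, 0) + 1
    per_igr: dict[str, int] = {}
    for f in features:
        if f.kind == "sRNA" and f.target:
            per_igr[f.target] = per_igr.get(f.target, 0) + 1
    per_asrna_gene: dict[str, int] = {}
    for c in classified:
        if c.tss_class == "asTSS" and c.target_feature:
            per_asrna_gene[c.target_feature] = per_asrna_gene.get(c.target_feature, 0) + 1

    comp = {k: {b: 0 for b in "ACGT"} for k in ("+1", "+2", "+3")}
    utr_lens = []
    for c in classified:
        if c.tss_class != "mTSS":
            continue
        if c.utr5_len is not None:
            utr_lens.append(c.utr5_len)
        tri = genome.triplet_at(c.tss.replicon, c.tss.tss_pos, c.tss.strand)
        if tri:
            for k, b in zip(("+1", "+2", "+3"), tri):
                if b in "ACGT":
                    comp[k][b] += 1

    by_rep = {r: 0 for r in genome.replicons}
    by_strand = {"+": 0, "-": 0}
    for c in classified:
        by_rep[c.tss.replicon] += 1
        by_strand[c.tss.strand] += 1

    report = {
        "total_tss": total,
        "class_counts": class_counts,
        "gene_tss_histogram": histogram(list(per_gene.values())),
        "igr_srna_histogram": histogram(list(per_igr.values())),
        "asrna_per_gene_histogram": histogram(list(per_asrna_gene.values())),
        "initiation_composition": comp,
        "utr5_mean": float(sum(utr_lens) / len(utr_lens)) if utr_lens else None,
        "utr5_lengths": sorted(utr_lens),
        "tss_per_replicon": by_rep,
        "tss_per_strand": by_strand,
        "n_srna": sum(1 for f in features if f.kind == "sRNA"),
        "n_asrna": sum(1 for f in features if f.kind == "asRNA"),
    }
    if operons is not None:
        first_gene_tss = 0
        for op in operons:
            first = op.gene_ids[0]
            if any(
                c.target_feature == first and c.tss_class in ("mTSS", "lmTSS")
                for c in classified
            ):
                first_gene_tss += 1
        report["operons_total"] = len(operons)
        report["operons_with_first_gene_tss"] = first_gene_tss
    return report
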