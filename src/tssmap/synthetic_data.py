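"""Synthetic genomes with planted transcriptional truth.

The generator emulates the statistical structure the pipeline assumes: GC-rich
multi-replicon genomes with non-overlapping genes on both strands (grouped
into operons), planted TSS of all six classes placed so that each satisfies
its class geometry exactly and unambiguously (>= 10 nt margins from every
class boundary), promoter element pairs written into the sequence 5-12 nt
upstream of a subset of mRNA TSS, Shine-Dalgarno leaders complementary to a
16S 3' tail, gapped TFBS motifs, and unannotated small ORFs on sRNA
transcripts for the gene-discovery path.

Read starts are simulated per planted TSS with negative-binomial depth
(variance = (1 + phi) x mean, phi the overdispersion), positional jitter of
1-2 nt at a configurable rate, and uniform Poisson background noise.  Every
planted pile-up realizes at least one read of maximal length, so the planted
contig extent (and hence the class geometry) is deterministic.

Placement arithmetic is pure-integer; all randomness flows through one
``numpy.random.default_rng`` seeded from the config.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .genome_io import Genome, GeneModel, Operon, revcomp, READ_COLUMNS

__all__ = [
    "SynthConfig",
    "TruthSet",
    "plant_features",
    "simulate_read_starts",
    "half_megabase_config",
]

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    c for c in ("".join(p) for p in product("ACGT", repeat=3)) if c not in _STOPS and c != "ATG"
)


@dataclass
class SynthConfig:
    """Study conditions for the synthetic genome.

    Class counts sum to at most ``n_genes`` plus the intergenic plants; read
    lengths default to the 87-108 nt contig range of the emulated protocol.
    """

    n_replicons: int = 2
    replicon_lengths: tuple[int, ...] | None = None  # None: sized to capacity
    n_genes: int = 200
    operon_fraction: float = 0.3
    gc_content: float = 0.6
    n_mtss: int = 50
    n_lmtss: int = 10
    n_pmtss: int = 20
    n_setss: int = 40
    n_astss: int = 40
    n_stss: int = 20
    read_depth_at_tss: float = 100.0
    nb_overdispersion: float = 0.5  # variance = (1 + phi) * mean
    jitter_rate: float = 0.05
    background_noise_rate: float = 0.5  # spurious read-start positions per kb
    read_length_range: tuple[int, int] = (87, 108)
    promoter_fraction: float = 0.5  # fraction of m/lm TSS receiving a promoter
    promoter_mode: str = "consensus"  # consensus | sampled
    consensus35: str = "TTGACA"
    consensus10: str = "TATAAT"
    spacer_range: tuple[int, int] = (15, 18)
    sampled_min_score_frac: float = 0.8  # sampled promoters keep >= this of max score
    sd_fraction: float = 0.5
    anti_sd_tail: str = "GAUCACCUCCUUA"
    new_orf_fraction: float = 0.5  # fraction of sTSS carrying an unannotated ORF
    n_tfbs: int = 10
    tfbs_box1: str = "TAA"
    tfbs_spacer: int = 7
    tfbs_box2: str = "TTAAC"
    boundary_cases: bool = False
    frac_nonunique: float = 0.03
    frac_mm3: float = 0.03
    frac_short: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0,1)")
        if not 50 <= self.read_length_range[0] <= self.read_length_range[1] <= 200:
            raise ValueError("read_length_range must lie within [50, 200]")
        if self.replicon_lengths is not None:
            if len(self.replicon_lengths) != self.n_replicons:
                raise ValueError("one length per replicon required")
            if any(L < 5000 for L in self.replicon_lengths):
                raise ValueError("replicon lengths must be >= 5000")

    @property
    def class_counts(self) -> dict[str, int]:
        return {
            "mTSS": self.n_mtss,
            "lmTSS": self.n_lmtss,
            "pmTSS": self.n_pmtss,
            "seTSS": self.n_setss,
            "asTSS": self.n_astss,
            "sTSS": self.n_stss,
        }


@dataclass
class TruthSet:
    """Planted ground truth: genes, operons, TSS with intended class, motifs."""

    genes: list[GeneModel]
    operons: list[Operon]
    tss: pd.DataFrame  # replicon strand pos cls gene_id utr5
    promoters: pd.DataFrame
    sd_leaders: pd.DataFrame
    tfbs: pd.DataFrame
    new_orfs: pd.DataFrame
    anti_sd_tail: str


# plant kinds attached to a gene unit; (upstream-pad requirement computed below)
_GENE_KINDS = ("mTSS", "lmTSS", "pmTSS", "sTSS", "seTSS", "asTSS")


def half_megabase_config(seed: int = 0) -> SynthConfig:
    """The bundled ~0.5 Mb benchmark fixture: two replicons, ~660 genes,
    all six TSS classes planted at the default study conditions."""
    return SynthConfig(
        n_replicons=2,
        n_genes=660,
        n_mtss=150,
        n_lmtss=30,
        n_pmtss=60,
        n_setss=120,
        n_astss=120,
        n_stss=60,
        seed=seed,
    )


def plant_features(config: SynthConfig) -> tuple[Genome, TruthSet]:
    """Build the genome and its planted truth, deterministically from the seed."""
    rng = np.random.default_rng([config.seed, 0])
    lmax = config.read_length_range[1]

    total_plants = sum(config.class_counts.values()) + (2 if config.boundary_cases else 0)
    if total_plants > config.n_genes:
        raise ValueError(
            f"capacity error: {total_plants} planted TSS need as many host genes, "
            f"only {config.n_genes} available"
        )

    # assign each gene a replicon (round-robin) and a plant kind
    kinds: list[str | None] = []
    for cls, n in config.class_counts.items():
        kinds += [cls] * n
    if config.boundary_cases:
        kinds += ["m_edge", "pm_edge"]
    kinds += [None] * (config.n_genes - len(kinds))
    order = rng.permutation(len(kinds))
    kinds = [kinds[i] for i in order]

    rep_names = [f"rep{chr(ord('A') + i)}" for i in range(config.n_replicons)]
    per_rep: dict[str, list[str | None]] = {r: [] for r in rep_names}
    for i, kind in enumerate(kinds):
        per_rep[rep_names[i % config.n_replicons]].append(kind)

    genes: list[GeneModel] = []
    operons: list[Operon] = []
    tss_rows, prom_rows, sd_rows, tfbs_rows, orf_rows = [], [], [], [], []
    replicons: dict[str, str] = {}
    gi = 0

    # promoter PSSM used when promoter_mode == "sampled"
    prom_freqs35 = _tight_freqs(config.consensus35)
    prom_freqs10 = _tight_freqs(config.consensus10)

    for rep in rep_names:
        cursor = 1  # next free genomic position
        arr_parts: list[np.ndarray] = []
        prev_strand = None
        operon_members: list[str] = []
        writes: list[tuple[int, str, str]] = []  # (lo, strand, seq 5'->3' on strand)

        def emit_pad(n: int) -> None:
            nonlocal cursor
            arr_parts.append(_random_seq(rng, n, config.gc_content))
            cursor += n

        for kind in per_rep[rep]:
            gi += 1
            gid = f"g{gi:04d}"
            if prev_strand is not None and rng.random() < config.operon_fraction:
                strand = prev_strand
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                if len(operon_members) > 1:
                    operons.append(_make_operon(operon_members, genes, len(operons)))
                operon_members = []
            cds_len = 330 + 3 * int(rng.integers(0, 91))  # 330..600 nt

            up_pad, plant = _plan_plant(kind, cds_len, rng, config, lmax)
            down_pad = 100 + int(rng.integers(0, 41))
            left_pad = up_pad if strand == "+" else down_pad
            right_pad = down_pad if strand == "+" else up_pad

            emit_pad(left_pad)
            cds_lo = cursor
            cds = _random_cds(rng, cds_len)
            arr_parts.append(np.array(list(cds if strand == "+" else revcomp(cds))))
            cursor += cds_len
            cds_hi = cursor - 1
            emit_pad(right_pad)

            start_codon = cds_lo if strand == "+" else cds_hi
            stop_codon = cds_hi if strand == "+" else cds_lo
            gene = GeneModel(gid, rep, strand, start_codon, stop_codon)
            genes.append(gene)
            prev_strand = strand
            operon_members.append(gid)

            if plant is None:
                continue
            cls, d, inside = plant
            if cls in ("seTSS", "asTSS"):
                tss_strand = strand if cls == "seTSS" else ("-" if strand == "+" else "+")
                pos = start_codon + inside if strand == "+" else start_codon - inside
                tss_rows.append((rep, tss_strand, pos, cls, gid, None))
                continue
            # upstream plants: TSS at distance d upstream of the start codon
            pos = start_codon - d if strand == "+" else start_codon + d
            cls_name = {"m_edge": "mTSS", "pm_edge": "pmTSS"}.get(cls, cls)
            utr5 = d if cls_name in ("mTSS", "lmTSS") else None
            tss_rows.append((rep, strand, pos, cls_name, gid if cls_name != "sTSS" else None, utr5))

            if cls in ("mTSS", "lmTSS") and rng.random() < config.promoter_fraction:
                prom_rows.append(
                    _plan_promoter(rep, strand, pos, rng, config, prom_freqs35, prom_freqs10, writes)
                )
            elif cls in ("mTSS", "lmTSS") and len(tfbs_rows) < config.n_tfbs:
                # TFBS ending 23 nt upstream of a promoter-free TSS: -35 overlap case
                tfbs_rows.append(_plan_tfbs(rep, strand, pos, 23, rng, config, writes, near_tss=True))
            if cls == "mTSS" and rng.random() < config.sd_fraction and d >= 20:
                sd_rows.append(_plan_sd(rep, strand, start_codon, pos, gid, config, writes))
            if cls == "sTSS" and rng.random() < config.new_orf_fraction:
                orf_rows.append(_plan_new_orf(rep, strand, pos, rng, config, writes))

        if len(operon_members) > 1:
            operons.append(_make_operon(operon_members, genes, len(operons)))
        emit_pad(200)

        arr = np.concatenate(arr_parts) if arr_parts else _random_seq(rng, 5000, config.gc_content)
        needed = len(arr)
        if config.replicon_lengths is not None:
            want = config.replicon_lengths[rep_names.index(rep)]
            if want < needed:
                raise ValueError(
                    f"capacity error: replicon {rep} needs {needed} nt, got {want}"
                )
            arr = np.concatenate([arr, _random_seq(rng, want - needed, config.gc_content)])
        elif needed < 5000:
            arr = np.concatenate([arr, _random_seq(rng, 5000 - needed, config.gc_content)])
        for lo, strand, seq in writes:
            s = seq if strand == "+" else revcomp(seq)
            arr[lo - 1 : lo - 1 + len(s)] = list(s)
        replicons[rep] = "".join(arr)

    genome = Genome(replicons)
    truth = TruthSet(
        genes=genes,
        operons=operons,
        tss=pd.DataFrame(
            tss_rows, columns=["replicon", "strand", "pos", "cls", "gene_id", "utr5"]
        ).sort_values(["replicon", "pos", "strand"], kind="mergesort").reset_index(drop=True),
        promoters=pd.DataFrame(
            prom_rows,
            columns=[
                "sigma", "replicon", "strand", "pos35", "pos10", "w35", "w10",
                "spacer", "gap", "tss_pos", "seq35", "seq10", "mode",
            ],
        ),
        sd_leaders=pd.DataFrame(
            sd_rows, columns=["replicon", "strand", "gene_id", "tss_pos", "sd_lo", "sd_hi", "sd_seq"]
        ),
        tfbs=pd.DataFrame(
            tfbs_rows, columns=["replicon", "strand", "pos", "end3", "near_tss"]
        ),
        new_orfs=pd.DataFrame(
            orf_rows, columns=["replicon", "strand", "tss_pos", "start_codon_pos", "stop_codon_pos"]
        ),
        anti_sd_tail=config.anti_sd_tail,
    )
    return genome, truth


def _tight_freqs(consensus: str) -> np.ndarray:
    """Per-position frequencies concentrated (0.85) on the consensus base."""
    enc = {"A": 0, "C": 1, "G": 2, "T": 3}
    f = np.full((len(consensus), 4), 0.05)
    for j, b in enumerate(consensus):
        f[j, enc[b]] = 0.85
    return f


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=p)]


def _random_cds(rng: np.random.Generator, cds_len: int) -> str:
    n_body = cds_len // 3 - 2
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_body))
    return "ATG" + body + "TAA"


def _make_operon(member_ids: list[str], genes: list[GeneModel], n: int) -> Operon:
    members = [g for g in genes if g.id in member_ids]
    strand = members[0].strand
    ordered = sorted(members, key=lambda g: g.left, reverse=(strand == "-"))
    return Operon(id=f"op{n + 1:03d}", gene_ids=tuple(g.id for g in ordered), strand=strand)


def _plan_plant(
    kind: str | None, cds_len: int, rng: np.random.Generator, config: SynthConfig, lmax: int
) -> tuple[int, tuple[str, int, int] | None]:
    """Upstream pad size plus the plant descriptor (class, upstream-dist, inside-offset)."""
    base = 120 + int(rng.integers(0, 21))
    if kind is None:
        return base, None
    if kind == "mTSS":
        d = 20 + int(rng.integers(0, 61))  # 5'-UTR 20..80 nt
        return d + 80, (kind, d, 0)
    if kind == "lmTSS":
        return base + 20, (kind, 0, 0)
    if kind == "pmTSS":
        # contig [tss, tss+lmax-1] must stay clear of the 54-nt m-window
        d = lmax + 54 + 10 + int(rng.integers(0, 100))
        return d + 40, (kind, d, 0)
    if kind == "sTSS":
        d = 320 + int(rng.integers(0, 101))
        return d + 40, (kind, d, 0)
    if kind == "seTSS":
        off = 20 + int(rng.integers(0, cds_len - 140))
        return base, (kind, 0, off)
    if kind == "asTSS":
        off = lmax + 5 + int(rng.integers(0, cds_len - lmax - 20))
        return base, (kind, 0, off)
    if kind == "m_edge":
        # contig 3' end overlaps the m-window by exactly one nucleotide
        d = lmax - 1 + 54
        return d + 80, (kind, d, 0)
    if kind == "pm_edge":
        return 340 + 40, (kind, 300, 0)
    raise ValueError(kind)


def _plan_promoter(rep, strand, tss_pos, rng, config, f35, f10, writes) -> tuple:
    gap = 5 + int(rng.integers(0, 8))
    spacer = int(rng.integers(config.spacer_range[0], config.spacer_range[1] + 1))
    if config.promoter_mode == "consensus":
        seq35, seq10 = config.consensus35, config.consensus10
    else:
        seq35 = _sample_motif(rng, f35, config.sampled_min_score_frac)
        seq10 = _sample_motif(rng, f10, config.sampled_min_score_frac)
    w35, w10 = len(seq35), len(seq10)
    # transcription-direction layout: [seq35][spacer][seq10][gap][TSS]
    if strand == "+":
        p10 = tss_pos - gap - w10
        p35 = p10 - spacer - w35
        writes.append((p35, strand, seq35))
        writes.append((p10, strand, seq10))
    else:
        p10 = tss_pos + gap + 1
        p35 = p10 + w10 + spacer
        writes.append((p10, strand, seq10))
        writes.append((p35, strand, seq35))
    return ("RpoD", rep, strand, p35, p10, w35, w10, spacer, gap, tss_pos, seq35, seq10,
            config.promoter_mode)


def _sample_motif(rng: np.random.Generator, freqs: np.ndarray, min_frac: float) -> str:
    """Sample a motif instance from per-position frequencies, rejecting weak draws.

    Rejection keeps instances whose log-odds score (vs uniform background)
    reaches ``min_frac`` of the consensus (maximal) score, so planted
    instances stay within the high-information part of the motif
    distribution.
    """
    logodds = np.log(freqs / 0.25)
    max_score = logodds.max(axis=1).sum()
    for _ in range(1000):
        idx = [int(rng.choice(4, p=freqs[j])) for j in range(len(freqs))]
        score = sum(logodds[j, b] for j, b in enumerate(idx))
        if score >= min_frac * max_score:
            return "".join(_BASES[b] for b in idx)
    return "".join(_BASES[int(np.argmax(freqs[j]))] for j in range(len(freqs)))


def _plan_tfbs(rep, strand, tss_pos, offset, rng, config, writes, near_tss) -> tuple:
    """Write a gapped motif instance whose 3' end is ``offset`` nt upstream of the TSS."""
    span = len(config.tfbs_box1) + config.tfbs_spacer + len(config.tfbs_box2)
    spacer_seq = "".join(_BASES[rng.choice(4, size=config.tfbs_spacer)])
    seq = config.tfbs_box1 + spacer_seq + config.tfbs_box2
    if strand == "+":
        end3 = tss_pos - offset
        lo = end3 - span + 1
    else:
        end3 = tss_pos + offset
        lo = end3
    writes.append((lo, strand, seq))
    return (rep, strand, lo, end3, near_tss)


def _plan_sd(rep, strand, start_codon, tss_pos, gid, config, writes) -> tuple:
    tail_dna = config.anti_sd_tail.replace("U", "T")
    core = revcomp(tail_dna)[-8:]  # e.g. AAGGAGGT for the canonical tail
    sd = core[:6]
    # SD ends 8 nt upstream of the start codon, inside the leader
    if strand == "+":
        hi = start_codon - 8
        lo = hi - len(sd) + 1
    else:
        lo = start_codon + 8
        hi = lo + len(sd) - 1
    writes.append((lo, strand, sd))
    return (rep, strand, gid, tss_pos, lo, hi, sd)


def _plan_new_orf(rep, strand, tss_pos, rng, config, writes) -> tuple:
    """A 90-nt unannotated ORF with an SD leader on an sRNA transcript."""
    leader = 20
    n_body = 90 // 3 - 2
    body = "".join(rng.choice(_SENSE_CODONS) for _ in range(n_body))
    orf = "ATG" + body + "TAA"
    tail_dna = config.anti_sd_tail.replace("U", "T")
    sd = revcomp(tail_dna)[-8:][:6]
    if strand == "+":
        start = tss_pos + leader
        writes.append((start, strand, orf))
        writes.append((start - 8 - len(sd) + 1, strand, sd))
        stop = start + len(orf) - 1
    else:
        start = tss_pos - leader
        writes.append((start - len(orf) + 1, strand, orf))
        writes.append((start + 8, strand, sd))
        stop = start - len(orf) + 1
    return (rep, strand, tss_pos, start, stop)


# ---------------------------------------------------------------------------
# read simulation


def simulate_read_starts(
    genome: Genome, truth: TruthSet, config: SynthConfig
) -> pd.DataFrame:
    """Simulate mapped-read 5' ends for the planted truth.

    Each planted TSS receives a negative-binomial number of reads (mean
    ``read_depth_at_tss``, variance ``(1+phi) x`` mean) sharing its 5'
    position, of which a ``jitter_rate`` fraction is displaced by 1-2 nt;
    one read always realizes the maximal read length.  Background noise adds
    Poisson-distributed spurious single-read 5' positions per kb, a small
    fraction of which is flagged non-unique, 5'-mismatched or short to
    exercise the read filters.
    """
    rng = np.random.default_rng([config.seed, 1])
    lmin, lmax = config.read_length_range
    mean = config.read_depth_at_tss
    phi = config.nb_overdispersion
    rows: list[tuple] = []

    for t in truth.tss.itertuples(index=False):
        if phi > 0:
            p = 1.0 / (1.0 + phi)
            r = mean / phi
            n = int(rng.negative_binomial(r, p))
        else:
            n = int(rng.poisson(mean))
        if n == 0:
            continue
        L = genome.length(t.replicon)
        rows.append((t.replicon, t.strand, t.pos, _clip_len(t.pos, lmax, t.strand, L), 1, True, 0))
        for _ in range(n - 1):
            pos = t.pos
            if config.jitter_rate > 0 and rng.random() < config.jitter_rate:
                pos += int(rng.choice([-2, -1, 1, 2]))
                pos = min(max(pos, 1), L)
            length = int(rng.integers(lmin, lmax + 1))
            rows.append((t.replicon, t.strand, pos, _clip_len(pos, length, t.strand, L), 1, True, 0))

    if config.background_noise_rate > 0:
        for rep, seq in genome.replicons.items():
            L = len(seq)
            n_bg = int(rng.poisson(config.background_noise_rate * L / 1000.0))
            for _ in range(n_bg):
                pos = int(rng.integers(1, L + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                length = int(rng.integers(lmin, lmax + 1))
                u = rng.random()
                unique, mm3 = True, 0
                if u < config.frac_nonunique:
                    unique = False
                elif u < config.frac_nonunique + config.frac_mm3:
                    mm3 = 1
                elif u < config.frac_nonunique + config.frac_mm3 + config.frac_short:
                    length = int(rng.integers(10, 18))
                rows.append((rep, strand, pos, _clip_len(pos, length, strand, L), 1, unique, mm3))

    frame = pd.DataFrame(rows, columns=READ_COLUMNS)
    if frame.empty:
        return frame
    frame = (
        frame.groupby(
            ["replicon", "strand", "five_prime_pos", "length", "unique", "mismatches_first3"],
            sort=True,
        )["count"]
        .sum()
        .reset_index()[READ_COLUMNS]
    )
    return frame


def _clip_len(pos: int, length: int, strand: str, L: int) -> int:
    room = (L - pos + 1) if strand == "+" else pos
    return max(1, min(length, room))
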