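"""Transcription-factor binding-site analysis.

Covers three tasks: scanning upstream regions with a gapped PSSM built from
training sites (the CtrA-style TAA-N7-TTAAC motif, fixed spacer, direct
strand only), positional correlation of externally located motifs with TSS
(PhoB-style: sites whose 3' end falls 22-25 nt upstream of a TSS overlap the
-35 element and are direct-regulation candidates), and extraction of 40-nt
upstream windows of strongly expressed but sigma-unassigned mRNA TSS as input
for external de novo motif discovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .genome_io import Genome, GeneModel, shift_upstream
from .promoter_discovery import PSSM, _encode, _window_scores
from .tss_classification import ClassifiedTSS

__all__ = [
    "GappedMotifConfig",
    "TFBSHit",
    "scan_gapped_motif",
    "correlate_tfbs_with_tss",
    "extract_unassigned_upstream",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class GappedMotifConfig:
    """A two-box motif with fixed spacer, e.g. CtrA's TAA-N7-TTAAC."""

    name: str = "CtrA"
    box1_width: int = 3
    box2_width: int = 5
    spacer: int = 7
    training_sites: list[str] = field(default_factory=list)
    pseudo_frequencies: float = 0.01
    p_max: float = 1e-4
    upstream_window: int = 300
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.p_max < 1:
            raise ValueError("p_max must be in (0, 1)")

    @property
    def motif_span(self) -> int:
        return self.box1_width + self.spacer + self.box2_width


@dataclass
class TFBSHit:
    motif: str
    replicon: str
    strand: str
    pos: int  # leftmost genomic position of the full (gapped) motif placement
    score: float
    pvalue: float
    gene_id: str
    tss_id: str | None = None
    tss_offset: int | None = None
    category: str | None = None

    @property
    def end(self) -> int:
        return self.pos  # placeholder; real end set by scanner


def _split_boxes(site: str, config: GappedMotifConfig) -> str:
    site = site.upper()
    expected = config.motif_span
    if len(site) != expected:
        raise ValueError(
            f"training site {site!r} has length {len(site)}, expected {expected} "
            f"({config.box1_width}+{config.spacer}+{config.box2_width})"
        )
    return site[: config.box1_width] + site[config.box1_width + config.spacer :]


def build_gapped_pssm(config: GappedMotifConfig) -> PSSM:
    """PSSM over the informative (box) columns only, pseudo-frequency smoothed.

    Per column, smoothed frequencies are
    ``(counts + pf * N) / (N * (1 + 4 pf))`` with ``pf`` the pseudo-frequency
    and N the number of training sites, so each column sums to one.
    """
    if len(config.training_sites) < 2:
        raise ValueError("gapped-motif scan requires >= 2 training sites")
    cores = [_split_boxes(s, config) for s in config.training_sites]
    w = config.box1_width + config.box2_width
    counts = np.zeros((w, 4))
    for core in cores:
        for j, b in enumerate(core):
            if b in _ENC:
                counts[j, _ENC[b]] += 1
    n = len(cores)
    pf = config.pseudo_frequencies
    freqs = (counts + pf * n) / (n * (1 + 4 * pf))
    bg = np.full(4, 0.25) if config.background is None else np.asarray(config.background)
    # feed the smoothed frequencies through PSSM as effective counts with a
    # zero pseudocount so the shared exact P-value engine applies unchanged
    pssm = PSSM(freqs, pseudocount=1e-12, background=bg)
    return pssm


def scan_gapped_motif(
    genome: Genome,
    genes: list[GeneModel],
    config: GappedMotifConfig,
    pssm: PSSM | None = None,
) -> list[TFBSHit]:
    """Scan each gene's upstream window on its own (direct) strand.

    The window covers up to ``upstream_window`` nt upstream of the start
    codon, truncated at the nearest annotated gene.  Hits need a positive
    weight score, P-value <= ``p_max`` and must not overlap any annotated
    ORF.  Spacer columns are not scored.
    """
    pssm = pssm or build_gapped_pssm(config)
    w1, w2, sp = config.box1_width, config.box2_width, config.spacer
    span = config.motif_span
    hits: list[TFBSHit] = []
    gene_ivs: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        gene_ivs.setdefault(g.replicon, []).append((g.left, g.right))
    for g in genes:
        L = genome.length(g.replicon)
        if g.strand == "+":
            win_hi = g.start_codon_pos - 1
            win_lo = max(1, g.start_codon_pos - config.upstream_window)
        else:
            win_lo = g.start_codon_pos + 1
            win_hi = min(L, g.start_codon_pos + config.upstream_window)
        # truncate at the nearest other annotated gene
        for lo, hi in gene_ivs.get(g.replicon, []):
            if (lo, hi) == (g.left, g.right):
                continue
            if g.strand == "+" and lo <= win_hi and hi >= win_lo:
                win_lo = max(win_lo, hi + 1)
            elif g.strand == "-" and lo <= win_hi and hi >= win_lo:
                win_hi = min(win_hi, lo - 1)
        if win_hi - win_lo + 1 < span:
            continue
        seq = genome.fetch(g.replicon, win_lo, win_hi, g.strand)  # 5'->3' on gene strand
        enc = _encode(seq)
        n = len(enc) - span + 1
        if n <= 0:
            continue
        # score = box1 columns + box2 columns, spacer skipped
        scores = np.zeros(n)
        ext = np.concatenate([pssm.logodds, np.full((w1 + w2, 1), -1e12)], axis=1)
        for j in range(w1):
            scores += ext[j][enc[j : j + n]]
        for j in range(w2):
            scores += ext[w1 + j][enc[w1 + sp + j : w1 + sp + j + n]]
        ok = np.flatnonzero((scores > 0) & (scores > -1e11))
        if len(ok) == 0:
            continue
        axis, survival = pssm.score_distribution()
        for i in ok:
            p = float(survival[min(np.searchsorted(axis, scores[i], side="left"), len(axis) - 1)])
            if p > config.p_max:
                continue
            # map window offset back to genomic leftmost position
            if g.strand == "+":
                g_lo = win_lo + int(i)
            else:
                g_lo = win_hi - int(i) - span + 1
            g_hi = g_lo + span - 1
            if any(lo <= g_hi and hi >= g_lo for lo, hi in gene_ivs.get(g.replicon, [])):
                continue
            hits.append(
                TFBSHit(
                    motif=config.name,
                    replicon=g.replicon,
                    strand=g.strand,
                    pos=g_lo,
                    score=float(scores[i]),
                    pvalue=p,
                    gene_id=g.id,
                )
            )
    hits.sort(key=lambda h: (h.replicon, h.pos, h.gene_id))
    return hits


def correlate_tfbs_with_tss(
    sites: pd.DataFrame,
    classified: list[ClassifiedTSS],
    overlap_offsets: tuple[int, int] = (22, 25),
    motif_span: int | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Categorize motif sites by their offset to the nearest same-strand TSS.

    ``sites`` needs columns ``replicon``, ``strand`` and either ``end3``
    (transcription-direction 3' end of the site) or ``pos`` plus
    ``motif_span`` to derive it.  The offset is the distance from the site's
    3' end to the nearest same-strand downstream TSS; offsets within
    ``overlap_offsets`` mark -35-overlap candidates (direct regulation),
    larger offsets are 'farther-upstream', anything else 'downstream/none'.
    Category counts partition the input.
    """
    sites = sites.copy()
    if "end3" not in sites.columns:
        if motif_span is None:
            raise ValueError("need either an end3 column or motif_span")
        sites["end3"] = np.where(
            sites["strand"] == "+", sites["pos"] + motif_span - 1, sites["pos"]
        )
    tss_index: dict[tuple[str, str], np.ndarray] = {}
    for (rep, strand), grp in _tss_frame(classified).groupby(["replicon", "strand"]):
        tss_index[(str(rep), str(strand))] = np.sort(grp["pos"].to_numpy())
    cats, offsets = [], []
    lo_off, hi_off = overlap_offsets
    for row in sites.itertuples(index=False):
        arr = tss_index.get((row.replicon, row.strand))
        best = None
        if arr is not None and len(arr):
            # nearest downstream TSS in transcription direction
            if row.strand == "+":
                i = np.searchsorted(arr, row.end3, side="right")
                if i < len(arr):
                    best = int(arr[i]) - int(row.end3)
            else:
                i = np.searchsorted(arr, row.end3, side="left")
                if i > 0:
                    best = int(row.end3) - int(arr[i - 1])
        offsets.append(best)
        if best is not None and lo_off <= best <= hi_off:
            cats.append("-35-overlap")
        elif best is not None and best > hi_off:
            cats.append("farther-upstream")
        else:
            cats.append("downstream/none")
    sites["tss_offset"] = offsets
    sites["category"] = cats
    counts = {c: int((sites["category"] == c).sum()) for c in
              ("-35-overlap", "farther-upstream", "downstream/none")}
    return sites, counts


def _tss_frame(classified: list[ClassifiedTSS]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.tss.replicon, c.tss.strand, c.tss.tss_pos) for c in classified],
        columns=["replicon", "strand", "pos"],
    )


def extract_unassigned_upstream(
    classified: list[ClassifiedTSS],
    promoter_tss_ids: set[str],
    genome: Genome,
    min_coverage: int = 300,
    window: int = 40,
) -> list[tuple[str, str]]:
    """40-nt upstream windows of strong, sigma-unassigned mRNA TSS.

    Selects mTSS/lmTSS with at least ``min_coverage`` reads that carry no
    promoter assignment, and returns ``(name, sequence)`` pairs where the
    sequence is the same-strand window ending 1 nt upstream of the TSS.
    Windows truncated by a replicon edge are skipped with a warning.  The
    output is meant as input for an external motif-discovery tool (e.g. MEME
    with ``-dna -mod anr -minw 18 -maxw 40 -minsites 10``).
    """
    out = []
    for c in classified:
        if c.tss_class not in ("mTSS", "lmTSS"):
            continue
        if c.tss.read_count < min_coverage:
            continue
        if c.tss.id and c.tss.id in promoter_tss_ids:
            continue
        t = c.tss
        far = shift_upstream(t.tss_pos, window, t.strand)
        near = shift_upstream(t.tss_pos, 1, t.strand)
        lo, hi = min(far, near), max(far, near)
        if lo < 1 or hi > genome.length(t.replicon):
            warnings.warn(
                f"upstream window of TSS {t.id or t.tss_pos} truncated at replicon edge; skipped"
            )
            continue
        out.append((t.id or f"{t.replicon}:{t.tss_pos}", genome.fetch(t.replicon, lo, hi, t.strand)))
    return out


def write_upstream_fasta(seqs: list[tuple[str, str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs:
            fh.write(f">{name}\n{seq}\n")
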