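"""Sigma-factor promoter prediction.

Two search strategies, matching what is practical for sparse bacterial
promoter data:

* **profile search** — position-specific scoring matrices (PSSMs) for the
  -35 and -10 elements are built from aligned seed promoters (pseudocount 1),
  the genome is scanned on both strands, collinear -35/-10 element pairs with
  an admissible spacer are chained, and candidates are retained only when a
  TSS (or a prior relaxed contig 5' end) lies 5-12 nt downstream of the -10
  element.  An iterative two-phase procedure first admits only high-confidence
  candidates (element P-values <= 0.005, no seTSS-exclusive associations) to
  enlarge the seed set, then rescans with the enlarged PSSMs at a relaxed
  threshold (0.02, all TSS classes).
* **string search** — for sigma factors known only through a consensus
  (e.g. GAAT-N18-GTCT), all placements with at most one mismatch across both
  boxes and an admissible spacer are matched directly.

Element P-values are exact: the score distribution of a random word under the
(zero-order) background model is computed by dynamic programming over
attainable score sums, so P(score >= t) carries no binning error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import Genome, revcomp

__all__ = [
    "SigmaModel",
    "PSSM",
    "PromoterSeed",
    "PromoterHit",
    "PromoterSearchResult",
    "build_pssm",
    "genome_background",
    "scan_elements",
    "chain_and_associate",
    "extend_seed_exact",
    "run_two_phase",
    "string_promoter_search",
    "cross_sigma_overlap",
    "parse_consensus",
]

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_LUT = np.full(256, 4, dtype=np.int8)
for _b, _i in _ENC.items():
    _LUT[ord(_b)] = _i
    _LUT[ord(_b.lower())] = _i
_N_SENTINEL = -1.0e12


@dataclass
class SigmaModel:
    """Search model for one sigma factor."""

    name: str
    mode: str = "profile"  # profile | string
    w35: int = 6
    w10: int = 7
    spacer_min: int = 14
    spacer_max: int = 20
    tss_gap_min: int = 5
    tss_gap_max: int = 12
    p_phase1: float = 0.005
    p_phase2: float = 0.02
    consensus: str | None = None  # string mode, e.g. "GAAT-N18-GTCT"
    max_mismatch: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("profile", "string"):
            raise ValueError("mode must be 'profile' or 'string'")
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min must be <= spacer_max")
        if self.mode == "string" and not self.consensus:
            raise ValueError("string mode requires a consensus pattern")


def parse_consensus(pattern: str) -> tuple[str, int, str]:
    """Parse ``BOX1-Nk-BOX2`` into (box1, k, box2)."""
    parts = pattern.upper().split("-")
    if len(parts) != 3 or not parts[1].startswith("N"):
        raise ValueError(f"malformed consensus pattern {pattern!r}; expected BOX1-Nk-BOX2")
    try:
        k = int(parts[1][1:])
    except ValueError as exc:
        raise ValueError(f"malformed spacer in pattern {pattern!r}") from exc
    for box in (parts[0], parts[2]):
        if not box or set(box) - set("ACGT"):
            raise ValueError(f"malformed box in pattern {pattern!r}")
    return parts[0], k, parts[2]


# ---------------------------------------------------------------------------
# PSSM


class PSSM:
    """Log-odds matrix over smoothed per-position frequencies vs a background.

    The exact distribution of the score of a random background word is
    computed once by dynamic programming over attainable partial sums and
    reused for all P-value queries.
    """

    def __init__(self, counts: np.ndarray, pseudocount: float = 1.0, background=None):
        counts = np.asarray(counts, dtype=float)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ValueError("counts must be (width, 4)")
        self.counts = counts
        self.width = counts.shape[0]
        self.pseudocount = pseudocount
        bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
        if not np.isclose(bg.sum(), 1.0):
            raise ValueError("background must sum to 1")
        self.background = bg
        smoothed = counts + pseudocount
        self.freqs = smoothed / smoothed.sum(axis=1, keepdims=True)
        self.logodds = np.log(self.freqs / bg)
        self._dist: tuple[np.ndarray, np.ndarray] | None = None

    def score(self, word: str) -> float:
        word = word.upper()
        if len(word) != self.width:
            raise ValueError(f"word length {len(word)} != width {self.width}")
        s = 0.0
        for j, b in enumerate(word):
            if b not in _ENC or b == "N":
                return float("-inf")
            s += self.logodds[j, _ENC[b]]
        return s

    @property
    def max_score(self) -> float:
        return float(self.logodds.max(axis=1).sum())

    def score_distribution(self) -> tuple[np.ndarray, np.ndarray]:
        """(sorted unique scores, survival P(S >= score)) under the background."""
        if self._dist is None:
            dist: dict[float, float] = {0.0: 1.0}
            for j in range(self.width):
                new: dict[float, float] = {}
                row = self.logodds[j]
                for s, p in dist.items():
                    for b in range(4):
                        key = s + row[b]
                        new[key] = new.get(key, 0.0) + p * self.background[b]
                dist = new
            scores = np.array(sorted(dist))
            probs = np.array([dist[s] for s in scores])
            survival = np.cumsum(probs[::-1])[::-1]
            self._dist = (scores, survival)
        return self._dist

    def pvalue(self, threshold: float) -> float:
        """Exact P(score >= threshold) for a random background word."""
        scores, survival = self.score_distribution()
        i = np.searchsorted(scores, threshold, side="left")
        return float(survival[i]) if i < len(scores) else 0.0

    def score_for_pvalue(self, p_max: float) -> float:
        """Smallest attainable score whose P-value is <= ``p_max``."""
        scores, survival = self.score_distribution()
        idx = np.flatnonzero(survival <= p_max)
        return float(scores[idx[0]]) if len(idx) else float("inf")

    def frequency_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freqs, columns=list("ACGT")).rename_axis("position")


def build_pssm(
    sequences: list[str], pseudocount: float = 1.0, background=None
) -> PSSM:
    """Counts + pseudocount per cell from equal-length aligned element sequences."""
    if not sequences:
        raise ValueError("PSSM requires at least one sequence")
    w = len(sequences[0])
    counts = np.zeros((w, 4))
    for s in sequences:
        s = s.upper()
        if len(s) != w:
            raise ValueError("PSSM input sequences must have equal length")
        for j, b in enumerate(s):
            if b in "ACGT":
                counts[j, _ENC[b]] += 1
    return PSSM(counts, pseudocount, background)


def genome_background(genome: Genome) -> np.ndarray:
    """Zero-order nucleotide frequencies of the double-stranded genome.

    Frequencies are strand-symmetrized (A with T, C with G): the same matrix
    scans both strands, so the background must describe the genome regardless
    of which strand was sequenced.  One pseudo-observation per base keeps
    every frequency positive even on degenerate sequences; N is excluded.
    """
    counts = np.ones(4)
    for seq in genome.replicons.values():
        enc = _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
        counts += np.bincount(enc[enc < 4], minlength=4)
    counts = (counts + counts[::-1]) / 2  # A<->T, C<->G under the ACGT encoding
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# scanning


def _encode(seq: str) -> np.ndarray:
    return _LUT[np.frombuffer(seq.encode(), dtype=np.uint8)].astype(np.int64)


def _window_scores(enc: np.ndarray, logodds: np.ndarray, strand: str) -> np.ndarray:
    """Score of every window start (0-based) on one strand; N windows get -inf-like."""
    w = logodds.shape[0]
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0)
    ext = np.concatenate([logodds, np.full((w, 1), _N_SENTINEL)], axis=1)
    scores = np.zeros(n)
    if strand == "+":
        for j in range(w):
            scores += ext[j][enc[j : j + n]]
    else:
        comp = np.where(enc < 4, 3 - enc, 4)
        for j in range(w):
            scores += ext[j][comp[w - 1 - j : w - 1 - j + n]]
    return scores


def scan_elements(
    genome: Genome, pssm: PSSM, p_max: float, replicons: list[str] | None = None
) -> pd.DataFrame:
    """All windows on both strands with element P-value <= ``p_max``.

    Returns a frame with columns ``replicon``, ``strand``, ``start`` (leftmost
    genomic position, 1-based), ``score`` and ``pvalue``.  Windows containing
    N are skipped.  The scan is exhaustive.
    """
    if not 0 < p_max <= 1:
        raise ValueError("p_max must be in (0, 1]")
    thr = pssm.score_for_pvalue(p_max)
    scores_axis, survival = pssm.score_distribution()
    rows = []
    for rep in replicons or sorted(genome.replicons):
        enc = _encode(genome.replicons[rep])
        for strand in "+-":
            sc = _window_scores(enc, pssm.logodds, strand)
            hit_idx = np.flatnonzero((sc >= thr) & (sc > _N_SENTINEL / 2))
            if len(hit_idx) == 0:
                continue
            pv = survival[np.searchsorted(scores_axis, sc[hit_idx], side="left").clip(
                max=len(scores_axis) - 1
            )]
            for i, p in zip(hit_idx, pv):
                rows.append((rep, strand, int(i) + 1, float(sc[i]), float(p)))
    return pd.DataFrame(rows, columns=["replicon", "strand", "start", "score", "pvalue"])


# ---------------------------------------------------------------------------
# promoter records


@dataclass(frozen=True)
class PromoterSeed:
    """A seed promoter: its two elements, spacer and provenance label."""

    sigma: str
    seq35: str
    spacer_seq: str
    seq10: str
    label: str = "model"  # virtual | model | extended_model | new_initial | second_search
    tss_id: str | None = None
    replicon: str | None = None
    strand: str | None = None
    pos35: int | None = None
    pos10: int | None = None

    @property
    def spacer(self) -> int:
        return len(self.spacer_seq)


@dataclass
class PromoterHit:
    """A located promoter: -35/-10 coordinates, spacer, P-values, TSS link.

    ``pos35``/``pos10`` are the leftmost genomic coordinates of the two
    elements; ``gap_to_tss`` counts the nucleotides strictly between the
    transcription-direction end of the -10 element and the TSS.
    """

    sigma: str
    replicon: str
    strand: str
    pos35: int
    pos10: int
    w35: int
    w10: int
    spacer: int
    p35: float
    p10: float
    seq35: str
    seq10: str
    tss_id: str | None
    gap_to_tss: int | None
    label: str
    assoc_classes: tuple[str, ...] = ()

    @property
    def key(self) -> tuple[str, str, str, int, int]:
        return (self.sigma, self.replicon, self.strand, self.pos35, self.pos10)


@dataclass
class PromoterSearchResult:
    sigma: str
    phase1: list[PromoterHit] = field(default_factory=list)
    phase2: list[PromoterHit] = field(default_factory=list)  # superset of phase1
    seeds_final: list[PromoterSeed] = field(default_factory=list)

    @property
    def hits(self) -> list[PromoterHit]:
        return self.phase2


@dataclass(frozen=True)
class TSSAnchor:
    """A TSS (or relaxed-contig 5' end) a promoter may be associated with."""

    id: str
    replicon: str
    strand: str
    pos: int
    tss_class: str | None = None  # None for relaxed contigs


def _element_3p_end(start_left: int, width: int, strand: str) -> int:
    """Transcription-direction last position of an element at leftmost ``start_left``."""
    return start_left + width - 1 if strand == "+" else start_left


def _gap(tss_pos: int, elem_end: int, strand: str) -> int:
    """Nucleotides strictly between the -10 element end and the TSS."""
    return tss_pos - elem_end - 1 if strand == "+" else elem_end - tss_pos - 1


def chain_and_associate(
    hits35: pd.DataFrame,
    hits10: pd.DataFrame,
    sigma: SigmaModel,
    anchors: list[TSSAnchor],
    label: str = "candidate",
) -> list[PromoterHit]:
    """Chain collinear -35/-10 element pairs and keep TSS-proximal ones.

    A pair qualifies when both elements lie on one strand with the -35
    element upstream and a spacer (nt strictly between the elements) within
    the sigma's range; it is retained iff the -10 element ends 5-12 nt
    (``tss_gap_min``..``tss_gap_max``) upstream of an anchor position.
    The reported TSS link is the nearest-gap anchor that is a TSS (relaxed
    contigs serve as fallback); all associated anchor classes are kept for
    downstream filtering.
    """
    anchor_index: dict[tuple[str, str], list[TSSAnchor]] = {}
    for a in anchors:
        anchor_index.setdefault((a.replicon, a.strand), []).append(a)
    for lst in anchor_index.values():
        lst.sort(key=lambda a: a.pos)
    out: list[PromoterHit] = []
    for (rep, strand), h10 in hits10.groupby(["replicon", "strand"], sort=True):
        h35 = hits35[(hits35["replicon"] == rep) & (hits35["strand"] == strand)]
        if h35.empty:
            continue
        pos35_arr = h35["start"].to_numpy()
        order = np.argsort(pos35_arr)
        pos35_sorted = pos35_arr[order]
        rel = anchor_index.get((str(rep), str(strand)), [])
        rel_pos = np.array([a.pos for a in rel])
        for row in h10.itertuples(index=False):
            s10 = int(row.start)
            # admissible -35 leftmost positions for this -10 element
            if strand == "+":
                lo = s10 - sigma.spacer_max - sigma.w35
                hi = s10 - sigma.spacer_min - sigma.w35
            else:
                lo = s10 + sigma.w10 + sigma.spacer_min
                hi = s10 + sigma.w10 + sigma.spacer_max
            i0, i1 = np.searchsorted(pos35_sorted, [lo, hi + 1])
            if i0 == i1:
                continue
            e10 = _element_3p_end(s10, sigma.w10, str(strand))
            # anchors with gap in range
            if strand == "+":
                a_lo, a_hi = e10 + sigma.tss_gap_min + 1, e10 + sigma.tss_gap_max + 1
            else:
                a_lo, a_hi = e10 - sigma.tss_gap_max - 1, e10 - sigma.tss_gap_min - 1
            j0, j1 = np.searchsorted(rel_pos, [a_lo, a_hi + 1]) if len(rel) else (0, 0)
            if j0 == j1:
                continue
            assoc = rel[j0:j1]
            tss_assoc = [a for a in assoc if a.tss_class is not None] or assoc
            best_a = min(tss_assoc, key=lambda a: abs(_gap(a.pos, e10, str(strand))))
            for k in range(i0, i1):
                irow = h35.iloc[int(order[k])]
                s35 = int(irow["start"])
                if strand == "+":
                    spacer = s10 - s35 - sigma.w35
                else:
                    spacer = s35 - s10 - sigma.w10
                out.append(
                    PromoterHit(
                        sigma=sigma.name,
                        replicon=str(rep),
                        strand=str(strand),
                        pos35=s35,
                        pos10=s10,
                        w35=sigma.w35,
                        w10=sigma.w10,
                        spacer=int(spacer),
                        p35=float(irow["pvalue"]),
                        p10=float(row.pvalue),
                        seq35="",
                        seq10="",
                        tss_id=best_a.id,
                        gap_to_tss=_gap(best_a.pos, e10, str(strand)),
                        label=label,
                        assoc_classes=tuple(
                            sorted({a.tss_class for a in assoc if a.tss_class is not None})
                        ),
                    )
                )
    return _dedupe(out)


def _dedupe(hits: list[PromoterHit]) -> list[PromoterHit]:
    seen: dict = {}
    for h in hits:
        if h.key not in seen:
            seen[h.key] = h
    return sorted(seen.values(), key=lambda h: (h.replicon, h.pos35, h.pos10, h.strand))


def _fill_seqs(hits: list[PromoterHit], genome: Genome) -> None:
    for h in hits:
        h.seq35 = genome.fetch(h.replicon, h.pos35, h.pos35 + h.w35 - 1, h.strand)
        h.seq10 = genome.fetch(h.replicon, h.pos10, h.pos10 + h.w10 - 1, h.strand)


def _hit_to_seed(h: PromoterHit, genome: Genome, sigma: SigmaModel, label: str) -> PromoterSeed:
    if h.strand == "+":
        sp_lo, sp_hi = h.pos35 + h.w35, h.pos10 - 1
    else:
        sp_lo, sp_hi = h.pos10 + h.w10, h.pos35 - 1
    spacer_seq = genome.fetch(h.replicon, sp_lo, sp_hi, h.strand) if sp_lo <= sp_hi else ""
    return PromoterSeed(
        sigma=sigma.name,
        seq35=h.seq35,
        spacer_seq=spacer_seq,
        seq10=h.seq10,
        label=label,
        tss_id=h.tss_id,
        replicon=h.replicon,
        strand=h.strand,
        pos35=h.pos35,
        pos10=h.pos10,
    )


# ---------------------------------------------------------------------------
# seed extension (exact string matching of element pairs)


def _find_exact(genome: Genome, rep: str, strand: str, word: str) -> np.ndarray:
    """0-based leftmost offsets where ``word`` occurs reading 5'->3' on strand."""
    hay = genome.replicons[rep]
    needle = word if strand == "+" else revcomp(word)
    out = []
    i = hay.find(needle)
    while i != -1:
        out.append(i)
        i = hay.find(needle, i + 1)
    return np.array(out, dtype=int)


def extend_seed_exact(
    seeds: list[PromoterSeed],
    genome: Genome,
    sigma: SigmaModel,
    anchors: list[TSSAnchor],
) -> list[PromoterSeed]:
    """Add genomic occurrences identical to each seed's element pair.

    Exact matches of (seq35, seq10) with any spacer in the sigma's range and
    a 5-12 nt gap to an anchor are added with label ``extended_model``;
    duplicate coordinates (including the seeds' own, when known) collapse.
    """
    known = {(s.replicon, s.strand, s.pos35, s.pos10) for s in seeds if s.pos35 is not None}
    anchor_pos: dict[tuple[str, str], np.ndarray] = {}
    anchor_by_key: dict[tuple[str, str], list[TSSAnchor]] = {}
    for a in anchors:
        anchor_by_key.setdefault((a.replicon, a.strand), []).append(a)
    for k, lst in anchor_by_key.items():
        lst.sort(key=lambda a: a.pos)
        anchor_pos[k] = np.array([a.pos for a in lst])
    extended = list(seeds)
    for seed in seeds:
        w35, w10 = len(seed.seq35), len(seed.seq10)
        for rep in sorted(genome.replicons):
            for strand in "+-":
                occ35 = _find_exact(genome, rep, strand, seed.seq35)
                occ10 = _find_exact(genome, rep, strand, seed.seq10)
                if len(occ35) == 0 or len(occ10) == 0:
                    continue
                for o10 in occ10:
                    p10 = int(o10) + 1
                    e10 = _element_3p_end(p10, w10, strand)
                    apos = anchor_pos.get((rep, strand))
                    if apos is None:
                        continue
                    if strand == "+":
                        a_lo, a_hi = e10 + sigma.tss_gap_min + 1, e10 + sigma.tss_gap_max + 1
                    else:
                        a_lo, a_hi = e10 - sigma.tss_gap_max - 1, e10 - sigma.tss_gap_min - 1
                    j0, j1 = np.searchsorted(apos, [a_lo, a_hi + 1])
                    if j0 == j1:
                        continue
                    linked = anchor_by_key[(rep, strand)][j0]
                    for o35 in occ35:
                        p35 = int(o35) + 1
                        spacer = (p10 - p35 - w35) if strand == "+" else (p35 - p10 - w10)
                        if not sigma.spacer_min <= spacer <= sigma.spacer_max:
                            continue
                        if (rep, strand, p35, p10) in known:
                            continue
                        known.add((rep, strand, p35, p10))
                        if strand == "+":
                            sp_lo, sp_hi = p35 + w35, p10 - 1
                        else:
                            sp_lo, sp_hi = p10 + w10, p35 - 1
                        extended.append(
                            PromoterSeed(
                                sigma=sigma.name,
                                seq35=seed.seq35,
                                spacer_seq=genome.fetch(rep, sp_lo, sp_hi, strand)
                                if sp_lo <= sp_hi
                                else "",
                                seq10=seed.seq10,
                                label="extended_model",
                                tss_id=linked.id,
                                replicon=rep,
                                strand=strand,
                                pos35=p35,
                                pos10=p10,
                            )
                        )
    return extended


# ---------------------------------------------------------------------------
# two-phase iterative profile search


def run_two_phase(
    seeds: list[PromoterSeed],
    sigma: SigmaModel,
    genome: Genome,
    anchors: list[TSSAnchor],
    background: np.ndarray | None = None,
    pseudocount: float = 1.0,
) -> PromoterSearchResult:
    """The iterative two-phase profile search.

    Phase 1 builds -35/-10 PSSMs from the (exact-match extended) seeds, scans
    the genome, chains element pairs, associates them with anchors, and keeps
    candidates with both element P-values <= ``p_phase1`` whose associations
    are not exclusively seTSS; survivors (label ``new_initial``) join the seed
    set.  Phase 2 rebuilds the PSSMs from the enlarged set and repeats with
    P <= ``p_phase2`` and all TSS classes admitted (label ``second_search``).
    The scan itself always uses the relaxed cutoff, so Phase 2 never needs a
    rescan with looser bounds; the returned ``phase2`` list is the
    deduplicated union of both phases.
    """
    usable = [s for s in seeds if s.seq35 and s.seq10]
    if len(usable) < 2:
        raise ValueError("two-phase search needs at least 2 seed promoters")
    for s in usable:
        if len(s.seq35) != sigma.w35 or len(s.seq10) != sigma.w10:
            raise ValueError(
                f"seed element widths ({len(s.seq35)}/{len(s.seq10)}) do not match "
                f"sigma model {sigma.name} ({sigma.w35}/{sigma.w10})"
            )
    if background is None:
        background = genome_background(genome)
    seeds_ext = extend_seed_exact(usable, genome, sigma, anchors)
    seed_keys = {
        (s.replicon, s.strand, s.pos35, s.pos10) for s in seeds_ext if s.pos35 is not None
    }

    def _search(seed_set: list[PromoterSeed], label: str) -> list[PromoterHit]:
        pssm35 = build_pssm([s.seq35 for s in seed_set], pseudocount, background)
        pssm10 = build_pssm([s.seq10 for s in seed_set], pseudocount, background)
        hits35 = scan_elements(genome, pssm35, sigma.p_phase2)
        hits10 = scan_elements(genome, pssm10, sigma.p_phase2)
        cands = chain_and_associate(hits35, hits10, sigma, anchors, label)
        _fill_seqs(cands, genome)
        return cands

    # Phase 1: strict element P-values, drop seTSS-exclusive associations
    cands1 = _search(seeds_ext, "new_initial")
    phase1 = [
        h
        for h in cands1
        if h.p35 <= sigma.p_phase1
        and h.p10 <= sigma.p_phase1
        and not (h.assoc_classes and set(h.assoc_classes) == {"seTSS"})
        and (h.replicon, h.strand, h.pos35, h.pos10) not in seed_keys
    ]
    seeds2 = seeds_ext + [_hit_to_seed(h, genome, sigma, "new_initial") for h in phase1]

    # Phase 2: enlarged PSSMs, relaxed P-value, all TSS classes
    cands2 = _search(seeds2, "second_search")
    phase1_keys = {(h.replicon, h.strand, h.pos35, h.pos10) for h in phase1}
    new2 = [
        h
        for h in cands2
        if h.p35 <= sigma.p_phase2
        and h.p10 <= sigma.p_phase2
        and (h.replicon, h.strand, h.pos35, h.pos10) not in phase1_keys
        and (h.replicon, h.strand, h.pos35, h.pos10) not in seed_keys
    ]
    phase2 = _dedupe(phase1 + new2)
    seeds_final = seeds2 + [_hit_to_seed(h, genome, sigma, "second_search") for h in new2]
    return PromoterSearchResult(sigma=sigma.name, phase1=phase1, phase2=phase2, seeds_final=seeds_final)


# ---------------------------------------------------------------------------
# string search


def _mismatch_counts(enc: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Mismatches of ``box`` against every window start; N counts as mismatch."""
    w = len(box)
    n = len(enc) - w + 1
    if n <= 0:
        return np.empty(0, dtype=int)
    mm = np.zeros(n, dtype=np.int64)
    for j in range(w):
        mm += (enc[j : j + n] != box[j]).astype(np.int64)
    return mm


def string_promoter_search(
    sigma: SigmaModel,
    genome: Genome,
    anchors: list[TSSAnchor],
) -> list[PromoterHit]:
    """Consensus pattern matching with at most ``max_mismatch`` total mismatches.

    The pattern's two boxes may be separated by any spacer within the sigma's
    range; placements are retained when the second box ends 5-12 nt upstream
    of an anchor.  Both strands are scanned.
    """
    box1_s, _k, box2_s = parse_consensus(sigma.consensus or "")
    box1 = np.array([_ENC[b] for b in box1_s], dtype=np.int64)
    box2 = np.array([_ENC[b] for b in box2_s], dtype=np.int64)
    w1, w2 = len(box1), len(box2)
    out: list[PromoterHit] = []
    anchor_by_key: dict[tuple[str, str], list[TSSAnchor]] = {}
    for a in anchors:
        anchor_by_key.setdefault((a.replicon, a.strand), []).append(a)
    for lst in anchor_by_key.values():
        lst.sort(key=lambda a: a.pos)
    for rep in sorted(genome.replicons):
        seq = genome.replicons[rep]
        L = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            enc = _encode(s)
            mm1 = _mismatch_counts(enc, box1)
            mm2 = _mismatch_counts(enc, box2)
            alist = anchor_by_key.get((rep, strand), [])
            apos = np.array([a.pos for a in alist])
            # anchor positions in scanned-string space (0-based offset of the TSS)
            if strand == "+":
                a0 = apos - 1
            else:
                a0 = L - apos
            order = np.argsort(a0)
            a0_sorted = a0[order]
            for spacer in range(sigma.spacer_min, sigma.spacer_max + 1):
                off2 = w1 + spacer
                n = len(enc) - (off2 + w2) + 1
                if n <= 0:
                    continue
                total = mm1[:n] + mm2[off2 : off2 + n]
                for i in np.flatnonzero(total <= sigma.max_mismatch):
                    e2 = int(i) + off2 + w2 - 1  # 0-based end of box2 in scan space
                    lo0 = e2 + sigma.tss_gap_min + 1
                    hi0 = e2 + sigma.tss_gap_max + 1
                    j0, j1 = np.searchsorted(a0_sorted, [lo0, hi0 + 1]) if len(a0_sorted) else (0, 0)
                    if j0 == j1:
                        continue
                    linked = alist[int(order[j0])]
                    gap0 = int(a0_sorted[j0]) - e2 - 1
                    # map scan-space offsets back to genomic leftmost coordinates
                    if strand == "+":
                        p1, p2 = int(i) + 1, int(i) + off2 + 1
                    else:
                        p1 = L - (int(i) + w1 - 1)
                        p2 = L - e2
                    out.append(
                        PromoterHit(
                            sigma=sigma.name,
                            replicon=rep,
                            strand=strand,
                            pos35=p1,
                            pos10=p2,
                            w35=w1,
                            w10=w2,
                            spacer=spacer,
                            p35=float("nan"),
                            p10=float("nan"),
                            seq35=s[int(i) : int(i) + w1],
                            seq10=s[int(i) + off2 : int(i) + off2 + w2],
                            tss_id=linked.id,
                            gap_to_tss=gap0,
                            label="string",
                            assoc_classes=(linked.tss_class,) if linked.tss_class else (),
                        )
                    )
    return _dedupe(out)


# ---------------------------------------------------------------------------
# cross-sigma overlap


def cross_sigma_overlap(hit_sets: dict[str, list[PromoterHit]]) -> pd.DataFrame:
    """TSS with promoters assigned independently to at least two sigma factors."""
    if len(hit_sets) < 2:
        raise ValueError("cross-sigma overlap needs at least 2 hit sets")
    by_tss: dict[str, set[str]] = {}
    for sigma, hits in hit_sets.items():
        for h in hits:
            if h.tss_id is not None:
                by_tss.setdefault(h.tss_id, set()).add(sigma)
    rows = [
        (tss, ",".join(sorted(sigmas)), len(sigmas))
        for tss, sigmas in sorted(by_tss.items())
        if len(sigmas) >= 2
    ]
    return pd.DataFrame(rows, columns=["tss_id", "sigmas", "n_sigmas"])
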