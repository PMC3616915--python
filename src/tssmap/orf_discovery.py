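"""TSS-guided ORF discovery and Shine-Dalgarno RBS energy scoring.

Two translation-initiation modes are distinguished.  A *leaderless* ORF has
an ATG start codon coinciding with the TSS; an *SD* ORF is preceded by a
leader of at least 14 nt that must hybridize with the 3' tail of the 16S
rRNA (the anti-Shine-Dalgarno sequence) at a duplex free energy at or below
-3.4535 kcal/mol.

The hybridization model is a deliberate, documented simplification of full
RNA duplex folding: the leader (as RNA) is paired against the anti-SD tail
antiparallel and ungapped; contiguous helices of Watson-Crick or G:U pairs of
at least ``min_helix_len`` base pairs are scored with nearest-neighbor
stacking free energies (37 degC Turner-style parameters) plus the duplex
initiation term and the terminal A:U/G:U closing penalty, and the minimum
over all alignment offsets and helices is reported.  Bulges, internal loops
and dangling ends are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genome_io import Genome, GeneModel, shift_downstream
from .tss_calling import TSSContig

__all__ = [
    "RBSConfig",
    "ORFCall",
    "rbs_free_energy",
    "enumerate_candidate_orfs",
    "classify_orf",
    "discover_orfs",
    "DUPLEX_INIT",
    "STACK_ENERGY",
]

START_CODONS_SD = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")

#: duplex initiation free energy, kcal/mol
DUPLEX_INIT = 4.09

#: penalty per helix end closed by an A:U or G:U pair, kcal/mol
TERMINAL_AU = 0.45

#: allowed base pairs (RNA alphabet, A-U / G-C / G-U wobble)
_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}

# Nearest-neighbor stacking free energies (kcal/mol, 37 degC) for RNA/RNA
# duplexes.  Keys are (top, bottom): top = two nt 5'->3' on one strand,
# bottom = the two paired nt 3'->5' on the other, so (top[i], bottom[i]) is a
# base pair.  Watson-Crick values follow the standard Turner/Xia set; G:U
# stacks use the weaker Turner-style wobble parameters.
_STACK_RAW = {
    ("AA", "UU"): -0.93,
    ("AU", "UA"): -1.10,
    ("UA", "AU"): -1.33,
    ("CU", "GA"): -2.08,
    ("CA", "GU"): -2.11,
    ("GU", "CA"): -2.24,
    ("GA", "CU"): -2.35,
    ("CG", "GC"): -2.36,
    ("GG", "CC"): -3.26,
    ("GC", "CG"): -3.42,
    # G:U wobble stacks
    ("AG", "UU"): -0.55,
    ("AU", "UG"): -1.36,
    ("CG", "GU"): -1.41,
    ("CU", "GG"): -2.11,
    ("GG", "CU"): -1.53,
    ("GU", "CG"): -2.51,
    ("GU", "UG"): -0.50,
    ("GG", "UU"): -0.50,
    ("UG", "GU"): -0.30,
    ("UG", "AU"): -1.27,
    ("UU", "AG"): -1.00,
}


def _close_stack_table() -> dict[tuple[str, str], float]:
    """Close the raw table under the 180-degree rotation symmetry."""
    table = dict(_STACK_RAW)
    for (top, bot), e in list(_STACK_RAW.items()):
        table.setdefault((bot[::-1], top[::-1]), e)
    return table


STACK_ENERGY = _close_stack_table()


@dataclass
class RBSConfig:
    """Parameters of the RBS search.

    ``anti_sd_tail`` is the 3' tail of the organism's 16S rRNA written 5'->3'
    in RNA alphabet; there is no universal default across species, so it must
    be supplied.
    """

    anti_sd_tail: str
    energy_cutoff: float = -3.4535
    min_leader_len: int = 14
    min_helix_len: int = 3
    min_orf_len: int = 60
    max_scan: int = 3000
    allow_alt_sd_starts: bool = True
    #: the RBS is sought within this many 3'-terminal nt of the leader (the
    #: region adjacent to the start codon where a bound 30S subunit can act);
    #: None scans the full leader
    search_window: int | None = 30

    def __post_init__(self) -> None:
        self.anti_sd_tail = self.anti_sd_tail.upper().replace("T", "U")
        if self.energy_cutoff >= 0:
            raise ValueError("energy_cutoff must be negative")
        if not 8 <= len(self.anti_sd_tail) <= 20:
            raise ValueError("anti_sd_tail length must be 8-20 nt")


def rbs_free_energy(leader_seq: str, config: RBSConfig) -> float:
    """Minimum hybridization free energy of a leader with the anti-SD tail.

    The leader (DNA or RNA, read 5'->3') is slid ungapped along the tail in
    antiparallel orientation; every contiguous helix of >= ``min_helix_len``
    pairs is scored as initiation + sum of nearest-neighbor stacks, and the
    minimum over all placements is returned.  0.0 means no qualifying helix
    (no RBS).
    """
    leader = leader_seq.upper().replace("T", "U")
    if len(leader) < config.min_leader_len:
        raise ValueError(
            f"leader length {len(leader)} below minimum {config.min_leader_len}"
        )
    if config.search_window is not None and len(leader) > config.search_window:
        leader = leader[-config.search_window :]
    tail = config.anti_sd_tail
    best: float | None = None
    nl, nt = len(leader), len(tail)
    # offset aligns leader[i] with tail[j]: antiparallel, j = off - i
    for off in range(0, nl + nt - 1):
        i_lo = max(0, off - nt + 1)
        i_hi = min(nl - 1, off)
        pairs = []
        for i in range(i_lo, i_hi + 1):
            j = off - i
            pairs.append((leader[i], tail[j]) in _PAIRS)
        # scan maximal True runs, then best sub-helix inside each run
        run_start = None
        for k in range(len(pairs) + 1):
            if k < len(pairs) and pairs[k]:
                if run_start is None:
                    run_start = k
            elif run_start is not None:
                e = _best_subhelix(leader, tail, off, i_lo + run_start, k - run_start, config)
                if e is not None:
                    best = e if best is None else min(best, e)
                run_start = None
    return 0.0 if best is None else best


def _best_subhelix(
    leader: str, tail: str, off: int, i0: int, run_len: int, config: RBSConfig
) -> float | None:
    """Minimum energy over contiguous sub-helices of a maximal paired run."""
    if run_len < config.min_helix_len:
        return None
    # stack k sits between pairs (i0+k, i0+k+1); energy of sub-helix [a, b] in
    # pair indices = init + terminal penalties + sum of stacks a..b-1
    stacks = []
    weak = []  # terminal penalty of each pair
    for k in range(run_len):
        i = i0 + k
        j = off - i
        weak.append(0.0 if (leader[i], tail[j]) in (("C", "G"), ("G", "C")) else TERMINAL_AU)
        if k < run_len - 1:
            # top strand: leader 5'->3' (i, i+1); bottom: tail pairs (j, j-1)
            top = leader[i] + leader[i + 1]
            bot = tail[j] + tail[j - 1]
            stacks.append(STACK_ENERGY[(top, bot)])
    m = config.min_helix_len - 1  # minimum number of stacks
    best = None
    for a in range(0, run_len - m):
        s = 0.0
        for b in range(a, run_len - 1):
            s += stacks[b]
            if b - a + 1 >= m:
                e = DUPLEX_INIT + s + weak[a] + weak[b + 1]
                if best is None or e < best:
                    best = e
    return best


# ---------------------------------------------------------------------------
# ORF enumeration and classification


@dataclass
class ORFCall:
    start_codon_pos: int
    stop_codon_pos: int
    replicon: str
    strand: str
    kind: str  # leaderless | sd
    tss_id: str | None = None
    leader_seq: str | None = None
    rbs_energy: float | None = None
    status: str | None = None  # new | reannotated | discarded
    name: str | None = None

    @property
    def lo(self) -> int:
        return min(self.start_codon_pos, self.stop_codon_pos)

    @property
    def hi(self) -> int:
        return max(self.start_codon_pos, self.stop_codon_pos)

    @property
    def frame(self) -> int:
        return self.start_codon_pos % 3


def enumerate_candidate_orfs(
    tss: TSSContig, genome: Genome, config: RBSConfig
) -> list[ORFCall]:
    """All same-strand ORFs on the transcript starting at a TSS.

    Scans up to ``config.max_scan`` nt downstream of the TSS.  Candidates are
    either leaderless (ATG exactly at the TSS) or SD candidates (start codon
    at least ``min_leader_len`` nt downstream of the TSS; ATG/GTG/TTG when
    ``allow_alt_sd_starts``).  An ORF needs an in-frame stop codon within the
    scan window and a length of at least ``min_orf_len`` nt.
    """
    L = genome.length(tss.replicon)
    if tss.strand == "+":
        lo, hi = tss.tss_pos, min(tss.tss_pos + config.max_scan - 1, L)
    else:
        lo, hi = max(tss.tss_pos - config.max_scan + 1, 1), tss.tss_pos
    window = genome.fetch(tss.replicon, lo, hi, tss.strand)  # 5'->3' on strand
    sd_starts = START_CODONS_SD if config.allow_alt_sd_starts else ("ATG",)
    out = []
    for i in range(len(window) - 2):
        codon = window[i : i + 3]
        if i == 0:
            if codon != "ATG":
                continue
            kind = "leaderless"
        else:
            if codon not in sd_starts or i < config.min_leader_len:
                continue
            kind = "sd"
        stop_i = _find_inframe_stop(window, i)
        if stop_i is None:
            continue
        orf_len = stop_i + 3 - i
        if orf_len < config.min_orf_len:
            continue
        start_pos = shift_downstream(tss.tss_pos, i, tss.strand)
        stop_pos = shift_downstream(tss.tss_pos, stop_i + 2, tss.strand)
        leader = window[:i] if kind == "sd" else None
        out.append(
            ORFCall(
                start_codon_pos=start_pos,
                stop_codon_pos=stop_pos,
                replicon=tss.replicon,
                strand=tss.strand,
                kind=kind,
                tss_id=tss.id,
                leader_seq=leader,
            )
        )
    return out


def _call_rank(o: ORFCall) -> tuple[int, int]:
    return (0, 0) if o.kind == "leaderless" else (1, len(o.leader_seq or ""))


def _find_inframe_stop(window: str, start_i: int) -> int | None:
    for k in range(start_i + 3, len(window) - 2, 3):
        if window[k : k + 3] in STOP_CODONS:
            return k
    return None


def classify_orf(
    candidate: ORFCall,
    annotation: list[GeneModel],
    config: RBSConfig,
    homology_keep: set[tuple[int, int, str]] | None = None,
) -> ORFCall:
    """Assign new / reannotated / discarded status to a candidate ORF.

    SD candidates must first pass the RBS energy cutoff.  A candidate sharing
    its start or stop codon position (same strand) with an annotated gene is
    *reannotated*; one overlapping annotated ORFs by at most a start/stop
    codon (3 nt) is *new*; everything else is *discarded*.  When an external
    protein-homology table is supplied (as a set of
    ``(start_codon_pos, stop_codon_pos, strand)`` keys) it acts as an
    additional keep-filter for new ORFs.
    """
    same_rep = [g for g in annotation if g.replicon == candidate.replicon]
    shares_end = any(
        g.strand == candidate.strand
        and (
            g.start_codon_pos == candidate.start_codon_pos
            or g.stop_codon_pos == candidate.stop_codon_pos
        )
        for g in same_rep
    )
    if shares_end:
        candidate.status = "reannotated"
    else:
        max_overlap = 0
        for g in same_rep:
            ov = min(candidate.hi, g.right) - max(candidate.lo, g.left) + 1
            if ov > max_overlap:
                max_overlap = ov
        if max_overlap <= 3:
            key = (candidate.start_codon_pos, candidate.stop_codon_pos, candidate.strand)
            if homology_keep is not None and key not in homology_keep:
                candidate.status = "discarded"
            else:
                candidate.status = "new"
        else:
            candidate.status = "discarded"
    if candidate.status != "discarded" and candidate.kind == "sd":
        if candidate.rbs_energy is None:
            candidate.rbs_energy = rbs_free_energy(candidate.leader_seq or "", config)
        if candidate.rbs_energy > config.energy_cutoff or candidate.rbs_energy == 0.0:
            candidate.status = "discarded"
    return candidate


def discover_orfs(
    tss_list: list[TSSContig],
    genome: Genome,
    annotation: list[GeneModel],
    config: RBSConfig,
    homology_keep: set[tuple[int, int, str]] | None = None,
    replicon_letters: dict[str, str] | None = None,
    prefix: str = "SM",
) -> list[ORFCall]:
    """Enumerate, score and classify ORFs for every TSS; name new ORFs.

    Candidates reachable from several TSS are collapsed on coordinates,
    keeping the most plausible initiation call (leaderless before SD, then
    the shortest leader).
    """
    if replicon_letters is None:
        reps = sorted(genome.replicons)
        replicon_letters = {r: chr(ord("A") + i) for i, r in enumerate(reps)}
    seen: dict[tuple[str, int, int, str], ORFCall] = {}
    for t in tss_list:
        for cand in enumerate_candidate_orfs(t, genome, config):
            cand = classify_orf(cand, annotation, config, homology_keep)
            if cand.status == "discarded":
                continue
            key = (cand.replicon, cand.lo, cand.hi, cand.strand)
            prev = seen.get(key)
            # one call per ORF: leaderless beats SD, then the shortest leader
            if prev is None or _call_rank(cand) < _call_rank(prev):
                seen[key] = cand
    results = list(seen.values())
    counters: dict[str, int] = {}
    for orf in sorted(results, key=lambda o: (o.replicon, o.lo, o.strand)):
        if orf.status == "new":
            n = counters.get(orf.replicon, 0) + 1
            counters[orf.replicon] = n
            orf.name = f"{prefix}{replicon_letters[orf.replicon]}_ORF_{n}"
    results.sort(key=lambda o: (o.replicon, o.lo, o.strand))
    return results
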