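"""TSS calling: read filtering, contig assembly, merging, relaxed contigs.

A TSS contig is the pile-up of at least ``min_reads_per_tss`` filtered reads
sharing a common 5' end; its 5' position is the TSS and its 3' end is that of
the longest member read.  TSS whose positions differ by less than
``merge_distance_lt`` nucleotides are treated as one TSS and merged
(transitively: chains of candidates with successive gaps below the threshold
collapse into a single contig).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import Genome, shift_downstream

__all__ = [
    "TSSCallConfig",
    "TSSContig",
    "RelaxedContig",
    "filter_reads",
    "call_tss_contigs",
    "merge_tss",
    "assign_tss_ids",
    "call_and_merge",
    "relaxed_contigs_from_coverage",
    "compare_tss_sets",
]


@dataclass
class TSSCallConfig:
    min_read_len: int = 18
    require_unique: bool = True
    max_mismatch_first3: int = 0
    min_reads_per_tss: int = 30
    merge_distance_lt: int = 3

    def __post_init__(self) -> None:
        for name in ("min_read_len", "min_reads_per_tss", "merge_distance_lt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_mismatch_first3 < 0:
            raise ValueError("max_mismatch_first3 must be >= 0")


@dataclass
class TSSContig:
    """A called TSS with its read pile-up contig."""

    replicon: str
    strand: str
    tss_pos: int
    end_pos: int
    read_count: int
    id: str | None = None
    merged_from: list[tuple[int, int]] = field(default_factory=list)

    @property
    def lo(self) -> int:
        return min(self.tss_pos, self.end_pos)

    @property
    def hi(self) -> int:
        return max(self.tss_pos, self.end_pos)

    @property
    def length(self) -> int:
        return self.hi - self.lo + 1


@dataclass
class RelaxedContig:
    """A contiguous coverage run from prior (lower-depth) RNA-seq data."""

    replicon: str
    strand: str
    start: int  # 5' end in transcription direction
    end: int
    max_depth: int
    id: str | None = None


def filter_reads(
    reads: pd.DataFrame, config: TSSCallConfig | None = None
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the read-level filters; returns kept reads and per-criterion drops.

    Reads shorter than ``min_read_len``, non-uniquely mapped reads (when
    ``require_unique``) and reads with more than ``max_mismatch_first3``
    mismatches in their first three 5' bases are removed.  Drop counts are
    attributed in that order, each read to the first criterion it fails.
    """
    config = config or TSSCallConfig()
    counts = reads["count"].to_numpy()
    short = reads["length"].to_numpy() < config.min_read_len
    nonuniq = (~reads["unique"].to_numpy()) if config.require_unique else np.zeros(len(reads), bool)
    mm = reads["mismatches_first3"].to_numpy() > config.max_mismatch_first3
    report = {
        "input": int(counts.sum()),
        "dropped_short": int(counts[short].sum()),
        "dropped_nonunique": int(counts[~short & nonuniq].sum()),
        "dropped_mismatch5p": int(counts[~short & ~nonuniq & mm].sum()),
    }
    kept = reads.loc[~(short | nonuniq | mm)].reset_index(drop=True)
    report["kept"] = int(kept["count"].sum())
    return kept, report


def call_tss_contigs(
    reads: pd.DataFrame, config: TSSCallConfig | None = None
) -> tuple[list[TSSContig], pd.DataFrame]:
    """Assemble pre-merge TSS candidates from filtered reads.

    One candidate per (replicon, strand, 5' position) with at least
    ``min_reads_per_tss`` reads; the contig end is the furthest 3' extent of
    any member read.  Sub-threshold positions are returned separately (second
    element) rather than silently dropped.
    """
    config = config or TSSCallConfig()
    if reads.empty:
        empty = pd.DataFrame(columns=["replicon", "strand", "five_prime_pos", "count"])
        return [], empty
    grouped = (
        reads.groupby(["replicon", "strand", "five_prime_pos"], sort=True)
        .agg(count=("count", "sum"), max_len=("length", "max"))
        .reset_index()
    )
    keep = grouped["count"] >= config.min_reads_per_tss
    sub = grouped.loc[~keep, ["replicon", "strand", "five_prime_pos", "count"]].reset_index(
        drop=True
    )
    contigs = []
    for row in grouped.loc[keep].itertuples(index=False):
        end = shift_downstream(int(row.five_prime_pos), int(row.max_len) - 1, str(row.strand))
        contigs.append(
            TSSContig(
                replicon=str(row.replicon),
                strand=str(row.strand),
                tss_pos=int(row.five_prime_pos),
                end_pos=end,
                read_count=int(row.count),
                merged_from=[(int(row.five_prime_pos), int(row.count))],
            )
        )
    return contigs, sub


def merge_tss(
    candidates: list[TSSContig], config: TSSCallConfig | None = None
) -> list[TSSContig]:
    """Merge candidates whose TSS positions differ by less than the threshold.

    The relation "differs by < merge_distance_lt" is closed transitively: a
    chain 100,102,104 (threshold 3) collapses into one contig.  The surviving
    coordinate is the member with the highest read count (tie: the 5'-most
    member); the read count is summed and the contig end is the furthest 3'
    extent over all members.
    """
    config = config or TSSCallConfig()
    merged: list[TSSContig] = []
    key = lambda c: (c.replicon, c.strand)
    by_group: dict[tuple[str, str], list[TSSContig]] = {}
    for c in candidates:
        by_group.setdefault(key(c), []).append(c)
    for (rep, strand), group in sorted(by_group.items()):
        group.sort(key=lambda c: c.tss_pos)
        chain: list[TSSContig] = []
        for c in group:
            if chain and c.tss_pos - chain[-1].tss_pos < config.merge_distance_lt:
                chain.append(c)
            else:
                if chain:
                    merged.append(_collapse_chain(chain, strand))
                chain = [c]
        if chain:
            merged.append(_collapse_chain(chain, strand))
    merged.sort(key=lambda c: (c.replicon, c.lo, c.strand))
    return merged


def _collapse_chain(chain: list[TSSContig], strand: str) -> TSSContig:
    if len(chain) == 1:
        return chain[0]
    members = [m for c in chain for m in c.merged_from]
    # representative: highest count; ties broken by the 5'-most position
    if strand == "+":
        rep_pos, _ = min(members, key=lambda m: (-m[1], m[0]))
        end = max(c.end_pos for c in chain)
    else:
        rep_pos, _ = min(members, key=lambda m: (-m[1], -m[0]))
        end = min(c.end_pos for c in chain)
    return TSSContig(
        replicon=chain[0].replicon,
        strand=strand,
        tss_pos=rep_pos,
        end_pos=end,
        read_count=sum(m[1] for m in members),
        merged_from=sorted(members),
    )


def assign_tss_ids(
    contigs: list[TSSContig],
    replicon_letters: dict[str, str] | None = None,
    prefix: str = "SM",
) -> list[TSSContig]:
    """Assign ``<prefix><letter>_TSS_nnnn`` ids in genome order, per replicon."""
    if replicon_letters is None:
        reps = sorted({c.replicon for c in contigs})
        replicon_letters = {r: chr(ord("A") + i) for i, r in enumerate(reps)}
    counters: dict[str, int] = {}
    for c in sorted(contigs, key=lambda c: (c.replicon, c.lo, c.strand)):
        n = counters.get(c.replicon, 0) + 1
        counters[c.replicon] = n
        c.id = f"{prefix}{replicon_letters[c.replicon]}_TSS_{n:04d}"
    contigs.sort(key=lambda c: (c.replicon, c.lo, c.strand))
    return contigs


def call_and_merge(
    reads: pd.DataFrame,
    config: TSSCallConfig | None = None,
    replicon_letters: dict[str, str] | None = None,
) -> tuple[list[TSSContig], pd.DataFrame, dict[str, int]]:
    """Filter -> assemble -> merge -> name.  Returns (contigs, sub-threshold, report)."""
    config = config or TSSCallConfig()
    kept, report = filter_reads(reads, config)
    candidates, sub = call_tss_contigs(kept, config)
    merged = merge_tss(candidates, config)
    assign_tss_ids(merged, replicon_letters)
    report["candidates"] = len(candidates)
    report["tss"] = len(merged)
    return merged, sub, report


# ---------------------------------------------------------------------------
# relaxed contigs from prior coverage


def relaxed_contigs_from_coverage(
    prior_reads: pd.DataFrame,
    tss: list[TSSContig],
    genome: Genome,
    min_depth: int = 5,
    length_range: tuple[int, int] = (50, 350),
    prefix: str = "SmelR",
) -> list[RelaxedContig]:
    """Maximal runs of coverage >= ``min_depth`` whose 5' end matches a TSS.

    Coverage is computed per replicon and strand from the prior reads (each
    read covers ``length`` nt from its 5' end in transcription direction).
    Runs outside ``length_range`` are rejected; surviving runs are retained
    only if their 5' end coincides exactly with a called TSS position.
    """
    tss_pos = {(t.replicon, t.strand): set() for t in tss}
    for t in tss:
        tss_pos[(t.replicon, t.strand)].add(t.tss_pos)
    contigs: list[RelaxedContig] = []
    n = 0
    for (rep, strand), grp in prior_reads.groupby(["replicon", "strand"], sort=True):
        L = genome.length(str(rep))
        diff = np.zeros(L + 2, dtype=np.int64)
        pos = grp["five_prime_pos"].to_numpy()
        length = grp["length"].to_numpy()
        cnt = grp["count"].to_numpy()
        if strand == "+":
            lo = pos
            hi = np.minimum(pos + length - 1, L)
        else:
            lo = np.maximum(pos - length + 1, 1)
            hi = pos
        np.add.at(diff, lo, cnt)
        np.add.at(diff, hi + 1, -cnt)
        cov = np.cumsum(diff)[1 : L + 1]  # cov[i-1] = depth at position i
        mask = cov >= min_depth
        edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
        for a, b in zip(edges[::2], edges[1::2]):
            run_lo, run_hi = int(a) + 1, int(b)
            run_len = run_hi - run_lo + 1
            if not length_range[0] <= run_len <= length_range[1]:
                continue
            five = run_lo if strand == "+" else run_hi
            three = run_hi if strand == "+" else run_lo
            if five in tss_pos.get((str(rep), str(strand)), set()):
                n += 1
                contigs.append(
                    RelaxedContig(
                        replicon=str(rep),
                        strand=str(strand),
                        start=five,
                        end=three,
                        max_depth=int(cov[run_lo - 1 : run_hi].max()),
                        id=f"{prefix}{n:03d}",
                    )
                )
    return contigs


# ---------------------------------------------------------------------------
# TSS set comparison


def compare_tss_sets(
    query: pd.DataFrame,
    reference: pd.DataFrame,
    horizon: int = 50,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Bin each query TSS by its distance to the nearest same-strand reference.

    Bins: ``exact`` (0 nt), ``near`` (1-4 nt), ``far`` (>=5 nt within the
    horizon) and ``absent`` (no same-strand reference within ``horizon`` nt).
    Both frames need columns ``replicon``, ``strand`` and ``pos``.  Returns the
    per-query assignment and bin fractions (which sum to 1).
    """
    ref_index: dict[tuple[str, str], np.ndarray] = {}
    for (rep, strand), grp in reference.groupby(["replicon", "strand"]):
        ref_index[(str(rep), str(strand))] = np.sort(grp["pos"].to_numpy())
    rows = []
    for row in query.itertuples(index=False):
        arr = ref_index.get((row.replicon, row.strand))
        if arr is None or len(arr) == 0:
            rows.append((row.replicon, row.strand, row.pos, None, "absent"))
            continue
        i = np.searchsorted(arr, row.pos)
        best = min(
            (abs(int(arr[j]) - int(row.pos)) for j in (i - 1, i) if 0 <= j < len(arr)),
        )
        if best > horizon:
            bin_ = "absent"
        elif best == 0:
            bin_ = "exact"
        elif best <= 4:
            bin_ = "near"
        else:
            bin_ = "far"
        rows.append((row.replicon, row.strand, row.pos, best if bin_ != "absent" else None, bin_))
    assigned = pd.DataFrame(rows, columns=["replicon", "strand", "pos", "distance", "bin"])
    fractions = {b: 0.0 for b in ("exact", "near", "far", "absent")}
    if len(assigned):
        for b, frac in (assigned["bin"].value_counts() / len(assigned)).items():
            fractions[str(b)] = float(frac)
    return assigned, fractions
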