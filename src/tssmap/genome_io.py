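"""Domain types and readers/writers for the formats the pipeline touches.

Internal coordinate convention
------------------------------
All positions are 1-based and inclusive, with an explicit strand.  GFF3 is
native in this convention; BED (0-based, half-open) is converted at the I/O
boundary.  "Upstream" and "downstream" are always meant in the direction of
transcription: on the plus strand downstream means increasing coordinates, on
the minus strand decreasing ones.

Read-start input is accepted either as per-read rows or as pre-aggregated
(position, strand, count, max read length) rows; aggregated rows imply
``unique=True`` and ``mismatches_first3=0``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "Genome",
    "GeneModel",
    "MappedRead",
    "Operon",
    "READ_COLUMNS",
    "revcomp",
    "shift_downstream",
    "shift_upstream",
    "reads_to_frame",
    "frame_to_reads",
    "read_fasta",
    "write_fasta",
    "read_gff3_genes",
    "write_gff3",
    "read_read_starts",
    "write_read_starts_bed",
    "read_bed_intervals",
    "load_inputs",
    "write_outputs",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: canonical column order for the internal read-start table
READ_COLUMNS = [
    "replicon",
    "strand",
    "five_prime_pos",
    "length",
    "count",
    "unique",
    "mismatches_first3",
]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def shift_downstream(pos: int, dist: int, strand: str) -> int:
    """Genomic position ``dist`` nt downstream of ``pos`` in transcription direction."""
    return pos + dist if strand == "+" else pos - dist


def shift_upstream(pos: int, dist: int, strand: str) -> int:
    return pos - dist if strand == "+" else pos + dist


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


@dataclass
class Genome:
    """Named replicon sequences (A/C/G/T/N), with a circularity flag each."""

    replicons: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.replicons:
            raise ValueError("genome must contain at least one replicon")
        clean: dict[str, str] = {}
        for name, seq in self.replicons.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"replicon {name!r} has empty sequence")
            bad = set(seq) - set("ACGTN")
            if bad:
                raise ValueError(f"replicon {name!r}: invalid characters {sorted(bad)}")
            clean[name] = seq
        self.replicons = clean
        for name in self.replicons:
            self.circular.setdefault(name, False)

    def length(self, replicon: str) -> int:
        return len(self.replicons[replicon])

    def fetch(self, replicon: str, lo: int, hi: int, strand: str = "+") -> str:
        """Sequence of ``[lo, hi]`` (1-based inclusive), read 5'->3' on ``strand``."""
        if lo < 1 or hi > self.length(replicon) or lo > hi:
            raise ValueError(
                f"coordinates [{lo},{hi}] outside replicon {replicon!r} "
                f"(length {self.length(replicon)})"
            )
        s = self.replicons[replicon][lo - 1 : hi]
        return s if strand == "+" else revcomp(s)

    def triplet_at(self, replicon: str, pos: int, strand: str) -> str | None:
        """The codon whose first nucleotide (5'->3' on ``strand``) sits at ``pos``."""
        if strand == "+":
            lo, hi = pos, pos + 2
        else:
            lo, hi = pos - 2, pos
        if lo < 1 or hi > self.length(replicon):
            return None
        return self.fetch(replicon, lo, hi, strand)


@dataclass(frozen=True)
class GeneModel:
    """An annotated CDS.

    ``start_codon_pos`` is the 1-based genomic position of the first
    nucleotide of the start codon; ``stop_codon_pos`` that of the last
    nucleotide of the stop codon.  On the minus strand the start codon
    therefore has the larger coordinate.
    """

    id: str
    replicon: str
    strand: str
    start_codon_pos: int
    stop_codon_pos: int

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.id}: strand must be + or -")
        if self.strand == "+" and self.start_codon_pos > self.stop_codon_pos:
            raise ValueError(f"gene {self.id}: start downstream of stop on + strand")
        if self.strand == "-" and self.start_codon_pos < self.stop_codon_pos:
            raise ValueError(f"gene {self.id}: start downstream of stop on - strand")

    @property
    def left(self) -> int:
        """Leftmost genomic coordinate of the CDS."""
        return min(self.start_codon_pos, self.stop_codon_pos)

    @property
    def right(self) -> int:
        return max(self.start_codon_pos, self.stop_codon_pos)

    @property
    def cds_length(self) -> int:
        return self.right - self.left + 1


@dataclass(frozen=True)
class MappedRead:
    """A mapped sequencing read reduced to the attributes the caller needs."""

    replicon: str
    strand: str
    five_prime_pos: int
    length: int
    unique: bool = True
    mismatches_first3: int = 0
    count: int = 1

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("read length must be >= 1")
        if not 0 <= self.mismatches_first3 <= 3:
            raise ValueError("mismatches_first3 must be in 0..3")


@dataclass(frozen=True)
class Operon:
    """Ordered genes transcribed as one unit; first gene is the start gene."""

    id: str
    gene_ids: tuple[str, ...]
    strand: str


# ---------------------------------------------------------------------------
# read-start tables


def reads_to_frame(reads: Iterable[MappedRead]) -> pd.DataFrame:
    rows = [
        (r.replicon, r.strand, r.five_prime_pos, r.length, r.count, r.unique, r.mismatches_first3)
        for r in reads
    ]
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def frame_to_reads(frame: pd.DataFrame) -> list[MappedRead]:
    return [
        MappedRead(
            replicon=row.replicon,
            strand=row.strand,
            five_prime_pos=int(row.five_prime_pos),
            length=int(row.length),
            unique=bool(row.unique),
            mismatches_first3=int(row.mismatches_first3),
            count=int(row.count),
        )
        for row in frame.itertuples(index=False)
    ]


def validate_reads(frame: pd.DataFrame, genome: Genome) -> pd.DataFrame:
    """Reject records referencing unknown replicons or out-of-range positions."""
    unknown = set(frame["replicon"]) - set(genome.replicons)
    if unknown:
        raise ValueError(f"read records reference unknown replicons: {sorted(unknown)}")
    for rep, grp in frame.groupby("replicon"):
        n = genome.length(str(rep))
        bad = grp[(grp["five_prime_pos"] < 1) | (grp["five_prime_pos"] > n)]
        if len(bad):
            pos = int(bad["five_prime_pos"].iloc[0])
            raise ValueError(f"read 5' position {pos} outside replicon {rep!r} (length {n})")
    return frame


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | os.PathLike, circular: Mapping[str, bool] | None = None) -> Genome:
    replicons: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in replicons:
                raise ParseError(f"{path}: duplicate replicon id {rec.id!r}")
            replicons[rec.id] = str(rec.seq).upper()
    except FileNotFoundError:
        raise
    if not replicons:
        raise ParseError(f"{path}: no FASTA records found")
    return Genome(replicons, dict(circular or {}))


def write_fasta(genome: Genome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome.replicons:
            fh.write(f">{name}\n")
            seq = genome.replicons[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3


def read_gff3_genes(path: str | os.PathLike, genome: Genome | None = None) -> list[GeneModel]:
    """Parse gene/CDS records from a GFF3 file into :class:`GeneModel` objects.

    Accepts the flat gene-only GFF3 this pipeline emits as well as files with
    both ``gene`` and ``CDS`` rows (CDS rows are preferred when both carry the
    same ID).
    """
    by_id: dict[str, GeneModel] = {}
    seen_cds: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(parts)}")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "CDS"):
                continue
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: gene record without strand")
            try:
                lo, hi = int(start), int(end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr_map.get("ID") or attr_map.get("locus_tag") or attr_map.get("Parent")
            if gid is None:
                raise ParseError(f"{path}:{lineno}: record without ID attribute")
            gid = gid.removeprefix("cds-").removeprefix("gene-")
            if ftype == "gene" and gid in seen_cds:
                continue
            if genome is not None:
                if seqid not in genome.replicons:
                    raise ParseError(f"{path}:{lineno}: unknown replicon {seqid!r}")
                if lo < 1 or hi > genome.length(seqid):
                    raise ParseError(f"{path}:{lineno}: coordinates outside replicon {seqid!r}")
            start_codon = lo if strand == "+" else hi
            stop_codon = hi if strand == "+" else lo
            by_id[gid] = GeneModel(gid, seqid, strand, start_codon, stop_codon)
            if ftype == "CDS":
                seen_cds.add(gid)
    return sorted(by_id.values(), key=lambda g: (g.replicon, g.left, g.strand, g.id))


def write_gff3(
    records: Sequence[tuple[str, str, str, int, int, str, str, str]],
    path: str | os.PathLike,
    genome: Genome | None = None,
) -> None:
    """Write GFF3 rows ``(seqid, source, type, start, end, score, strand, attrs)``.

    Rows are emitted in deterministic (replicon, start, strand) order.
    """
    rows = sorted(records, key=lambda r: (r[0], r[3], r[4], r[6], r[2], r[7]))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if genome is not None:
            for name, seq in genome.replicons.items():
                fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for seqid, source, ftype, start, end, score, strand, attrs in rows:
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attrs}\n"
            )


def gene_to_gff3_row(gene: GeneModel) -> tuple[str, str, str, int, int, str, str, str]:
    return (
        gene.replicon,
        "tssmap",
        "CDS",
        gene.left,
        gene.right,
        ".",
        gene.strand,
        f"ID={gene.id}",
    )


# ---------------------------------------------------------------------------
# BED and read-start tables


def _bed_to_internal(start0: int, end0: int, strand: str) -> tuple[int, int]:
    """0-based half-open BED interval -> 1-based inclusive (lo, hi)."""
    return start0 + 1, end0


def read_bed_intervals(path: str | os.PathLike, genome: Genome | None = None) -> pd.DataFrame:
    """BED6 intervals as a frame with 1-based inclusive ``start``/``end``."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ParseError(f"{path}:{lineno}: BED6 requires 6 columns")
            rep, s0, e0, name, score, strand = parts[:6]
            try:
                lo, hi = _bed_to_internal(int(s0), int(e0), strand)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer BED coordinates") from exc
            if strand not in "+-":
                raise ParseError(f"{path}:{lineno}: BED strand must be + or -")
            if genome is not None and rep not in genome.replicons:
                raise ParseError(f"{path}:{lineno}: unknown replicon {rep!r}")
            rows.append((rep, lo, hi, name, score, strand))
    return pd.DataFrame(rows, columns=["replicon", "start", "end", "name", "score", "strand"])


def read_read_starts(path: str | os.PathLike, genome: Genome | None = None) -> pd.DataFrame:
    """Load mapped-read 5' end records.

    Two on-disk layouts are accepted:

    * **BED6** — one row per (possibly aggregated) read; the 5' end is the
      interval start on the plus strand and the interval end on the minus
      strand; the score column carries the read count (0/'.' means 1).
      Aggregated rows imply unique mapping and no 5' mismatches.
    * **TSV** with a header line naming at least
      ``replicon strand five_prime_pos length`` and optionally
      ``count unique mismatches_first3``.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("replicon"):
        frame = pd.read_csv(path, sep="\t")
        for col, default in (("count", 1), ("unique", True), ("mismatches_first3", 0)):
            if col not in frame.columns:
                frame[col] = default
        frame = frame[READ_COLUMNS].copy()
    else:
        bed = read_bed_intervals(path, genome)
        five = bed["start"].where(bed["strand"] == "+", bed["end"])
        length = bed["end"] - bed["start"] + 1
        count = pd.to_numeric(bed["score"], errors="coerce").fillna(1).astype(int).clip(lower=1)
        frame = pd.DataFrame(
            {
                "replicon": bed["replicon"],
                "strand": bed["strand"],
                "five_prime_pos": five.astype(int),
                "length": length.astype(int),
                "count": count,
                "unique": True,
                "mismatches_first3": 0,
            }
        )
    frame = frame.astype(
        {
            "five_prime_pos": int,
            "length": int,
            "count": int,
            "unique": bool,
            "mismatches_first3": int,
        }
    )
    if genome is not None:
        validate_reads(frame, genome)
    return frame


def write_read_starts_bed(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write the internal read table as BED6 (score column = read count)."""
    frame = frame.sort_values(
        ["replicon", "five_prime_pos", "strand", "length"], kind="mergesort"
    )
    with open(path, "w") as fh:
        for i, row in enumerate(frame.itertuples(index=False)):
            if row.strand == "+":
                lo, hi = row.five_prime_pos, row.five_prime_pos + row.length - 1
            else:
                lo, hi = row.five_prime_pos - row.length + 1, row.five_prime_pos
            fh.write(
                f"{row.replicon}\t{lo - 1}\t{hi}\tr{i}\t{row.count}\t{row.strand}\n"
            )


# ---------------------------------------------------------------------------
# bundle I/O


def load_inputs(
    genome_path: str | os.PathLike,
    annotation_path: str | os.PathLike,
    reads_path: str | os.PathLike | None = None,
    priors_path: str | os.PathLike | None = None,
) -> tuple[Genome, list[GeneModel], pd.DataFrame | None, pd.DataFrame | None]:
    """Load the genome, annotation, read starts and optional prior contigs."""
    genome = read_fasta(genome_path)
    genes = read_gff3_genes(annotation_path, genome)
    reads = read_read_starts(reads_path, genome) if reads_path else None
    priors = read_bed_intervals(priors_path, genome) if priors_path else None
    return genome, genes, reads, priors


def write_outputs(results: Mapping[str, object], out_dir: str | os.PathLike) -> list[str]:
    """Write result tables/features to ``out_dir``.

    ``results`` maps output names to either a :class:`pandas.DataFrame`
    (written as a TSV named ``<name>.tsv``) or a list of GFF3 row tuples
    (written as ``<name>.gff3``).  Returns the paths written, in deterministic
    order.  Empty frames produce headers-only TSVs; empty row lists a valid
    empty GFF3.
    """
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in sorted(results):
        obj = results[name]
        if isinstance(obj, pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.tsv")
            obj.to_csv(path, sep="\t", index=False)
        else:
            path = os.path.join(out_dir, f"{name}.gff3")
            write_gff3(list(obj), path)  # type: ignore[arg-type]
        written.append(path)
    return written
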