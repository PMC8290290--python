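"""Core sequence/interval data model, FASTA/BED/GFF3 IO and gap/Nx statistics.

Coordinates are 0-based half-open throughout. GFF3 emission converts to
1-based inclusive; BED stays 0-based.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

ALPHABET = frozenset("ACGTN")

_NON_ACGTN = re.compile(r"[^ACGTN]")


@dataclass
class SequenceRecord:
    """A named uppercase DNA sequence over {A,C,G,T,N}."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - ALPHABET
        if bad:
            raise ValueError(f"{self.name}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval on a named sequence."""

    seq_name: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_name == other.seq_name
            and self.start < other.end
            and other.start < self.end
        )

    def shifted(self, offset: int) -> "Interval":
        return Interval(self.seq_name, self.start + offset, self.end + offset, self.strand)


@dataclass(frozen=True)
class GapSegment:
    """A maximal run of N bases."""

    interval: Interval

    @property
    def n_count(self) -> int:
        return self.interval.length


@dataclass
class GeneModel:
    id: str
    interval: Interval
    sequence: str


class Assembly:
    """Ordered collection of uniquely named SequenceRecords."""

    def __init__(self, records: Iterable[SequenceRecord] = ()):
        self._records: dict[str, SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: SequenceRecord) -> None:
        if rec.name in self._records:
            raise ValueError(f"duplicate sequence name {rec.name!r}")
        self._records[rec.name] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __getitem__(self, name: str) -> SequenceRecord:
        return self._records[name]

    @property
    def names(self) -> list[str]:
        return list(self._records)

    @property
    def total_length(self) -> int:
        return sum(rec.length for rec in self)

    def lengths(self) -> list[int]:
        return [rec.length for rec in self]

    def fetch(self, iv: Interval) -> str:
        rec = self._records[iv.seq_name]
        if iv.end > rec.length:
            raise ValueError(f"interval {iv} beyond end of {iv.seq_name} ({rec.length})")
        return rec.seq[iv.start : iv.end]


def normalize_seq(raw: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN IUPAC letters to N.

    Returns (normalized sequence, number of bases remapped).
    """
    up = raw.upper()
    n_mapped = len(_NON_ACGTN.findall(up))
    if n_mapped:
        up = _NON_ACGTN.sub("N", up)
    return up, n_mapped


def load_fasta(path: str | Path) -> Assembly:
    """Load a FASTA file into an Assembly.

    Sequences are uppercased; ambiguity codes other than N are mapped to N
    (count logged). Duplicate names and empty files are hard errors.
    """
    path = Path(path)
    asm = Assembly()
    name: str | None = None
    chunks: list[str] = []
    remapped = 0

    def flush() -> None:
        nonlocal remapped
        if name is None:
            return
        seq, n = normalize_seq("".join(chunks))
        remapped += n
        asm.add(SequenceRecord(name, seq))

    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0]
                chunks = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line)
    flush()
    if len(asm) == 0:
        raise ValueError(f"{path}: empty FASTA")
    if remapped:
        logger.info("%s: %d non-ACGTN bases mapped to N", path, remapped)
    return asm


def write_fasta(assembly: Assembly, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in assembly:
            fh.write(f">{rec.name}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.seq[i : i + width] + "\n")


def gap_segments(assembly: Assembly, min_run: int = 1) -> list[GapSegment]:
    """All maximal N runs of length >= min_run, sorted by position."""
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    out: list[GapSegment] = []
    for rec in assembly:
        for m in re.finditer(r"N+", rec.seq):
            if m.end() - m.start() >= min_run:
                out.append(GapSegment(Interval(rec.name, m.start(), m.end())))
    return out


def contig_segments(assembly: Assembly, min_run: int = 1) -> list[Interval]:
    """Non-N segments complementary to gap_segments."""
    gaps_by_seq: dict[str, list[GapSegment]] = {}
    for g in gap_segments(assembly, min_run):
        gaps_by_seq.setdefault(g.interval.seq_name, []).append(g)
    out: list[Interval] = []
    for rec in assembly:
        pos = 0
        for g in gaps_by_seq.get(rec.name, []):
            if g.interval.start > pos:
                out.append(Interval(rec.name, pos, g.interval.start))
            pos = g.interval.end
        if pos < rec.length:
            out.append(Interval(rec.name, pos, rec.length))
    return out


def nx_stat(lengths: Sequence[int], x: float) -> int:
    """Largest L such that sequences of length >= L hold >= x% of the total."""
    if not lengths:
        raise ValueError("empty length list")
    if not 0 < x <= 100:
        raise ValueError("x must be in (0, 100]")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    target = sum(lengths) * x / 100.0
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= target:
            return l
    return min(lengths)  # pragma: no cover - unreachable


def gene_flank_gap_fraction(
    assembly: Assembly, genes: Sequence[GeneModel], flank: int = 100_000
) -> float:
    """Fraction of genes with zero N in their clipped +/- flank window."""
    missing = [g.id for g in genes if g.interval.seq_name not in assembly]
    if missing:
        raise ValueError(f"genes on unknown sequences: {missing}")
    if not genes:
        raise ValueError("empty gene set")
    clean = 0
    for g in genes:
        rec = assembly[g.interval.seq_name]
        lo = max(0, g.interval.start - flank)
        hi = min(rec.length, g.interval.end + flank)
        if "N" not in rec.seq[lo:hi]:
            clean += 1
    return clean / len(genes)


# ---------------------------------------------------------------------------
# Simple feature IO: BED for gaps, GFF3 for genes/elements.
# ---------------------------------------------------------------------------


@dataclass
class Gff3Feature:
    seq_name: str
    source: str
    type: str
    start: int  # 0-based half-open internally
    end: int
    score: str = "."
    strand: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join(
            [
                self.seq_name,
                self.source,
                self.type,
                str(self.start + 1),
                str(self.end),
                self.score,
                self.strand,
                ".",
                attrs,
            ]
        )


def write_gff3(features: Iterable[Gff3Feature], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for feat in features:
            fh.write(feat.to_line() + "\n")


def read_gff3(path: str | Path) -> list[Gff3Feature]:
    out: list[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            attrs: dict[str, str] = {}
            if f[8] != ".":
                for kv in f[8].split(";"):
                    if kv:
                        k, _, v = kv.partition("=")
                        attrs[k] = v
            out.append(
                Gff3Feature(
                    seq_name=f[0],
                    source=f[1],
                    type=f[2],
                    start=int(f[3]) - 1,
                    end=int(f[4]),
                    score=f[5],
                    strand=f[6],
                    attributes=attrs,
                )
            )
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.seq_name}\t{iv.start}\t{iv.end}\n")


def assembly_stats(assembly: Assembly, min_gap_run: int = 1) -> dict:
    """Summary statistics: sizes, scaffold/contig Nx, gap totals."""
    gaps = gap_segments(assembly, min_gap_run)
    contigs = contig_segments(assembly, min_gap_run)
    scaffold_lengths = assembly.lengths()
    contig_lengths = [c.length for c in contigs]
    return {
        "total_size": assembly.total_length,
        "n_scaffolds": len(assembly),
        "n_contigs": len(contigs),
        "scaffold_n50": nx_stat(scaffold_lengths, 50),
        "scaffold_n90": nx_stat(scaffold_lengths, 90),
        "contig_n50": nx_stat(contig_lengths, 50) if contig_lengths else 0,
        "contig_n90": nx_stat(contig_lengths, 90) if contig_lengths else 0,
        "n_gaps": len(gaps),
        "gap_bases": sum(g.n_count for g in gaps),
    }


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]
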