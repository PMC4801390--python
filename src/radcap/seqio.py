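"""Sequence data model, FASTA/FASTQ I/O, PHRED arithmetic, demultiplexing, trimming.

All coordinates in this package are 0-based, half-open.  Quality strings are
Sanger PHRED+33 only; other encodings are rejected by construction (decoded
values outside 0..93 raise).
"""
from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

SEQ_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed FASTA/FASTQ input."""


class ConfigurationError(ValueError):
    """Raised for invalid run parameters (e.g. colliding barcodes)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence over {A,C,G,T,N}.

    ``meta`` is free-form provenance (e.g. ``{"chrom": ..., "start": ...,
    "end": ...}`` for probes and catalog contigs); it never affects equality
    of the sequence payload.
    """

    id: str
    seq: str
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if not set(self.seq) <= SEQ_ALPHABET:
            bad = sorted(set(self.seq) - SEQ_ALPHABET)
            raise ValueError(f"record {self.id!r}: invalid characters {bad}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class QualityRead:
    """A quality-scored read, optionally tagged with simulation truth.

    ``provenance`` and ``damage_positions`` are populated by the simulator
    only; reads parsed from FASTQ carry ``provenance='unknown'`` and an empty
    damage set.  ``mate`` is 1/2 for paired reads, ``None`` for single-end.
    """

    id: str
    seq: str
    qual: list[int]
    sample: str | None = None
    mate: int | None = None
    provenance: str = "unknown"
    damage_positions: frozenset[int] = frozenset()
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if len(self.qual) != len(self.seq):
            raise ValueError(f"read {self.id!r}: qual length != seq length")
        if self.qual and (min(self.qual) < 0 or max(self.qual) > 93):
            raise ValueError(f"read {self.id!r}: PHRED values must be in 0..93")
        if self.provenance not in ("endogenous", "contaminant", "unknown"):
            raise ValueError(f"read {self.id!r}: bad provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# PHRED arithmetic
# ---------------------------------------------------------------------------

def phred_error(q: float) -> float:
    """Error probability for a PHRED score: 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"negative PHRED score: {q}")
    return 10.0 ** (-q / 10.0)


def error_to_phred(e: float) -> float:
    """PHRED score for an error probability (clipped away from 0)."""
    e = max(e, 1e-300)
    return -10.0 * math.log10(e)


def decode_qual(s: str) -> list[int]:
    qual = [ord(c) - 33 for c in s]
    if qual and (min(qual) < 0 or max(qual) > 93):
        raise FormatError("quality string outside PHRED+33 (Sanger) range")
    return qual


def encode_qual(qual: Sequence[int]) -> str:
    return "".join(chr(q + 33) for q in qual)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def parse_fasta(text: str) -> list[SequenceRecord]:
    """Parse FASTA text (possibly line-wrapped) preserving record order."""
    records: list[SequenceRecord] = []
    header: str | None = None
    chunks: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                records.append(SequenceRecord(header, "".join(chunks)))
            header = line[1:].split()[0] if line[1:].split() else ""
            if not header:
                raise FormatError(f"line {lineno}: empty FASTA header")
            chunks = []
        else:
            if header is None:
                raise FormatError(f"line {lineno}: sequence before any '>' header")
            chunks.append(line)
    if header is not None:
        records.append(SequenceRecord(header, "".join(chunks)))
    return records


def write_fasta(records: Iterable[SequenceRecord], width: int = 70) -> str:
    out: list[str] = []
    for rec in records:
        out.append(f">{rec.id}")
        for i in range(0, len(rec.seq), width):
            out.append(rec.seq[i : i + width])
    return "\n".join(out) + ("\n" if out else "")


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def parse_fastq(text: str) -> list[QualityRead]:
    """Parse 4-line FASTQ records with PHRED+33 qualities."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) % 4 != 0:
        raise FormatError("FASTQ record count is not a multiple of 4 lines")
    reads: list[QualityRead] = []
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i : i + 4]
        if not head.startswith("@"):
            raise FormatError(f"line {i + 1}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"line {i + 3}: expected '+' separator")
        rid = head[1:].split()[0]
        mate: int | None = None
        if rid.endswith("/1"):
            mate = 1
        elif rid.endswith("/2"):
            mate = 2
        if len(seq) != len(qual):
            raise FormatError(f"read {rid!r}: seq/qual length mismatch")
        reads.append(QualityRead(rid, seq, decode_qual(qual), mate=mate))
    return reads


def write_fastq(reads: Iterable[QualityRead]) -> str:
    out: list[str] = []
    for r in reads:
        out.append(f"@{r.id}")
        out.append(r.seq)
        out.append("+")
        out.append(encode_qual(r.qual))
    return "\n".join(out) + ("\n" if out else "")


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    with _open_text(path, "r") as fh:
        return parse_fasta(fh.read())


def write_fasta_file(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        fh.write(write_fasta(records))


def read_fastq(path: str | Path) -> list[QualityRead]:
    with _open_text(path, "r") as fh:
        return parse_fastq(fh.read())


def write_fastq_file(reads: Iterable[QualityRead], path: str | Path) -> None:
    with _open_text(path, "w") as fh:
        fh.write(write_fastq(reads))


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def demultiplex(
    reads: Iterable[QualityRead],
    barcode_map: dict[str, str],
    max_mismatch: int = 0,
) -> tuple[dict[str, list[QualityRead]], list[QualityRead]]:
    """Partition reads by inline 5' barcode, stripping matched prefixes.

    Barcodes must be equal length and pairwise >= 2*max_mismatch+1 apart so
    that assignment is unambiguous.  Reads whose prefix matches no barcode
    within ``max_mismatch`` go to the unassigned bin unchanged.
    """
    barcodes = list(barcode_map)
    if not barcodes:
        raise ConfigurationError("empty barcode map")
    blen = len(barcodes[0])
    if any(len(b) != blen for b in barcodes):
        raise ConfigurationError("barcodes must all have the same length")
    for i, a in enumerate(barcodes):
        for b in barcodes[i + 1 :]:
            if _hamming(a, b) < 2 * max_mismatch + 1:
                raise ConfigurationError(
                    f"barcodes {a} and {b} collide at max_mismatch={max_mismatch}"
                )
    assigned: dict[str, list[QualityRead]] = {s: [] for s in barcode_map.values()}
    unassigned: list[QualityRead] = []
    for read in reads:
        prefix = read.seq[:blen]
        hit = None
        if len(prefix) == blen:
            best = max_mismatch + 1
            for bc in barcodes:
                d = _hamming(prefix, bc)
                if d < best:
                    best, hit = d, bc
        if hit is None:
            unassigned.append(read)
            continue
        sample = barcode_map[hit]
        shifted = frozenset(
            p - blen for p in read.damage_positions if p >= blen
        )
        assigned[sample].append(
            replace(
                read,
                seq=read.seq[blen:],
                qual=read.qual[blen:],
                sample=sample,
                damage_positions=shifted,
            )
        )
    return assigned, unassigned


# ---------------------------------------------------------------------------
# Quality / adapter trimming
# ---------------------------------------------------------------------------

#: Illumina adapter read-through signature (shared prefix of both mates'
#: adapters in the library design); matching is exact-prefix, >= 8 bases.
DEFAULT_ADAPTERS = ("AGATCGGAAGAGC",)

_MIN_ADAPTER_OVERLAP = 8


def _sliding_cut(qual: Sequence[int], window: int, min_q: float) -> int:
    """Index of the first sliding-window start whose mean quality < min_q.

    Returns len(qual) when no window falls below the threshold.
    """
    n = len(qual)
    if n < window:
        return n
    s = sum(qual[:window])
    if s / window < min_q:
        return 0
    for i in range(1, n - window + 1):
        s += qual[i + window - 1] - qual[i - 1]
        if s / window < min_q:
            return i
    return n


def _adapter_cut(seq: str, adapters: Sequence[str]) -> int:
    """Earliest position where a read suffix equals an adapter prefix (>=8 bp)."""
    cut = len(seq)
    for adapter in adapters:
        max_olap = min(len(seq), len(adapter))
        for olap in range(max_olap, _MIN_ADAPTER_OVERLAP - 1, -1):
            if seq.endswith(adapter[:olap]):
                cut = min(cut, len(seq) - olap)
                break
    return cut


def quality_trim(
    reads: Iterable[QualityRead],
    window: int = 4,
    min_q: float = 15,
    adapters: Sequence[str] = DEFAULT_ADAPTERS,
    min_len: int = 30,
) -> list[QualityRead]:
    """3'-trim low-quality windows and adapter suffixes; drop short reads."""
    if window < 1:
        raise ValueError("window must be >= 1")
    out: list[QualityRead] = []
    for read in reads:
        cut = _sliding_cut(read.qual, window, min_q)
        cut = min(cut, _adapter_cut(read.seq, adapters))
        if cut < min_len:
            continue
        if cut == len(read.seq):
            out.append(read)
        else:
            out.append(
                replace(
                    read,
                    seq=read.seq[:cut],
                    qual=read.qual[:cut],
                    damage_positions=frozenset(
                        p for p in read.damage_positions if p < cut
                    ),
                )
            )
    return out
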