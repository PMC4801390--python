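"""Read mapping to a locus catalog, uniqueness classification, duplicate removal.

The mapper is a specified stand-in for a general-purpose aligner: exact
k-mer seeds on both strands nominate candidate placements, each scored
ungapped along the seed diagonal (match +1, mismatch -1; equivalent to the
banded score when no indels are present, which holds for this package's
substitution-only simulations — gapped chaining is out of scope).  A read
is ``unique`` when the
best score beats the runner-up by at least ``score_margin``, ``multi`` when
a second candidate is within the margin, and ``unmapped`` when the best
score falls below half the read length.  Mates are aligned independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _dna
from .catalog import LocusCatalog
from .seqio import QualityRead

UNIQUE, MULTI, UNMAPPED = "unique", "multi", "unmapped"


@dataclass
class AlignmentRecord:
    read_id: str
    sample: str | None
    contig_id: str | None
    start: int  # contig coordinates, 0-based half-open
    end: int
    strand: str  # '+', '-', or '.'
    read_codes: np.ndarray  # contig-oriented aligned read bases
    ref_codes: np.ndarray  # matching contig reference bases
    quals: np.ndarray  # contig-oriented base qualities (mutable: rescaling)
    score: int
    map_class: str
    clip5: int = 0  # read bases clipped before the aligned block (read orientation)
    read_len: int = 0
    provenance: str = "unknown"
    meta: dict = field(default_factory=dict, compare=False)

    def aligned_pairs(self):
        """Yield (read_offset, contig_offset, read_base, qual) per column.

        ``read_offset`` is in original read orientation (0 = sequencing
        start), which is what damage profiling needs.
        """
        n = self.end - self.start
        for j in range(n):
            yield (
                self.read_offset5(j),
                self.start + j,
                "ACGTN"[self.read_codes[j]],
                int(self.quals[j]),
            )

    def read_offset5(self, col: int) -> int:
        """Original-read 5' offset of aligned column ``col``."""
        if self.strand == "-":
            return self.read_len - 1 - (self.clip5 + col)
        return self.clip5 + col

    def offsets5(self) -> np.ndarray:
        cols = np.arange(self.end - self.start)
        if self.strand == "-":
            return self.read_len - 1 - (self.clip5 + cols)
        return self.clip5 + cols


class CatalogIndex:
    def __init__(self, cat: LocusCatalog, k: int = 15):
        self.k = k
        self.catalog = cat
        self.codes = [_dna.encode(c.seq) for c in cat.contigs]
        self.index = _dna.KmerIndex(self.codes, k)
        self.ids = [c.id for c in cat.contigs]


def _score_candidate(
    read: np.ndarray, contig: np.ndarray, diag: int
) -> tuple[int, int, int, int]:
    """(score, q_start, r_start, olap) for an ungapped diagonal placement."""
    matches, olap, q_start, r_start = _dna.diagonal_overlap(read, contig, diag)
    return 2 * matches - olap, q_start, r_start, olap


def map_reads(
    reads: Iterable[QualityRead],
    cat: LocusCatalog | CatalogIndex,
    k: int = 15,
    score_margin: int = 4,
    max_candidates: int = 32,
) -> list[AlignmentRecord]:
    """Map reads to catalog contigs; every input read yields one record."""
    index = cat if isinstance(cat, CatalogIndex) else CatalogIndex(cat, k)
    out: list[AlignmentRecord] = []
    for read in reads:
        fwd = _dna.encode(read.seq)
        rev = _dna.revcomp_codes(fwd)
        candidates: dict[tuple[int, str, int], tuple] = {}
        for oriented, strand in ((fwd, "+"), (rev, "-")):
            kcodes = _dna.kmer_codes(oriented, index.k)
            hit_mask = index.index.member_mask(kcodes)
            for qpos in np.flatnonzero(hit_mask):
                for ref_i, rpos in index.index.lookup(int(kcodes[qpos])):
                    key = (ref_i, strand, rpos - int(qpos))
                    if key in candidates or len(candidates) >= max_candidates:
                        continue
                    score, q_start, r_start, olap = _score_candidate(
                        oriented, index.codes[ref_i], key[2]
                    )
                    if olap > 0:
                        candidates[key] = (score, q_start, r_start, olap, oriented, strand, ref_i)
        if not candidates:
            out.append(_unmapped(read))
            continue
        ranked = sorted(candidates.values(), key=lambda c: -c[0])
        best = ranked[0]
        score = best[0]
        if score < 0.5 * len(read.seq):
            out.append(_unmapped(read))
            continue
        second = ranked[1][0] if len(ranked) > 1 else None
        map_class = UNIQUE if second is None or score - second >= score_margin else MULTI
        _, q_start, r_start, olap, oriented, strand, ref_i = best
        quals = np.array(read.qual, dtype=np.int64)
        if strand == "-":
            quals = quals[::-1]
        out.append(
            AlignmentRecord(
                read_id=read.id,
                sample=read.sample,
                contig_id=index.ids[ref_i],
                start=r_start,
                end=r_start + olap,
                strand=strand,
                read_codes=oriented[q_start : q_start + olap].copy(),
                ref_codes=index.codes[ref_i][r_start : r_start + olap].copy(),
                quals=quals[q_start : q_start + olap].copy(),
                score=score,
                map_class=map_class,
                clip5=q_start,
                read_len=len(read.seq),
                provenance=read.provenance,
                meta=dict(read.meta),
            )
        )
    return out


def _unmapped(read: QualityRead) -> AlignmentRecord:
    return AlignmentRecord(
        read_id=read.id,
        sample=read.sample,
        contig_id=None,
        start=0,
        end=0,
        strand=".",
        read_codes=np.empty(0, dtype=np.uint8),
        ref_codes=np.empty(0, dtype=np.uint8),
        quals=np.empty(0, dtype=np.int64),
        score=0,
        map_class=UNMAPPED,
        read_len=len(read.seq),
        provenance=read.provenance,
        meta=dict(read.meta),
    )


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def remove_duplicates(alignments: Sequence[AlignmentRecord]) -> list[AlignmentRecord]:
    """Keep one read (pair) per fragment coordinate group, by summed quality.

    Mapped mates of a pair landing on the same contig define the fragment by
    both outer coordinates; otherwise each record falls back to its own
    single-end coordinates.  Unmapped records pass through.  Idempotent.
    """
    mapped = [a for a in alignments if a.map_class != UNMAPPED]
    unmapped = [a for a in alignments if a.map_class == UNMAPPED]
    pairs: dict[str, list[AlignmentRecord]] = {}
    for a in mapped:
        pairs.setdefault((a.sample, _pair_key(a.read_id)), []).append(a)

    groups: dict[tuple, list[tuple[int, list[AlignmentRecord]]]] = {}
    for (sample, _), recs in pairs.items():
        contigs = {r.contig_id for r in recs}
        if len(recs) == 2 and len(contigs) == 1:
            key = (
                sample,
                recs[0].contig_id,
                min(r.start for r in recs),
                max(r.end for r in recs),
            )
        else:
            r = recs[0]
            key = (sample, r.contig_id, r.start, r.end, r.strand, _mate_tag(r.read_id))
        qual_sum = int(sum(int(r.quals.sum()) for r in recs))
        groups.setdefault(key, []).append((qual_sum, recs))

    kept: list[AlignmentRecord] = []
    for key, entries in groups.items():
        entries.sort(key=lambda e: (-e[0], e[1][0].read_id))
        kept.extend(entries[0][1])
    kept.sort(key=lambda a: (a.contig_id or "", a.start, a.read_id))
    return kept + unmapped


def _mate_tag(read_id: str) -> str:
    return read_id[-1] if read_id.endswith(("/1", "/2")) else "0"


def mapping_stats(alignments: Sequence[AlignmentRecord]) -> dict[str, dict[str, float]]:
    """Per-sample fractions of unmapped / unique / multi reads (sum to 1)."""
    counts: dict[str, dict[str, int]] = {}
    for a in alignments:
        c = counts.setdefault(a.sample or "", {UNMAPPED: 0, UNIQUE: 0, MULTI: 0})
        c[a.map_class] += 1
    out: dict[str, dict[str, float]] = {}
    for sample, c in counts.items():
        total = sum(c.values())
        out[sample] = {k: v / total for k, v in c.items()}
    return out
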