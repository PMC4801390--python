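"""Locus-catalog construction: greedy identity clustering, contig extension,
and a minimal de Bruijn unitig assembler.

Three catalog strategies are provided:

* ``build_rad_ref`` — two-iteration greedy clustering of probe-precursor
  reads (within samples, then among samples) with threshold optimization;
* ``extend_catalog`` — iterative overlap-vote extension of catalog contigs
  using capture reads, followed by end trimming;
* ``assemble_denovo`` — unitigs of a k-mer de Bruijn graph built from the
  capture reads of (typically) one well-preserved sample.

Clustering emulates length-sorted, first-match centroid assignment; global
identity is matches / alignment columns (substitution-only fast path for
equal lengths, banded alignment otherwise).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from . import _dna
from .seqio import QualityRead, SequenceRecord

RAD_REF, RAD_REF_EXT, ASSEMBLY_REF = "rad_ref", "rad_ref_ext", "assembly_ref"

#: identity-threshold grids scanned when optimizing clustering
WITHIN_GRID = (0.51, 0.61, 0.71, 0.81, 0.83, 0.91, 0.93, 0.96, 0.98)
AMONG_GRID = (0.51, 0.61, 0.71, 0.81, 0.85, 0.88)


def _coerce_seq(item) -> tuple[str, str | None, dict]:
    """Accept str, Member, SequenceRecord, QualityRead, or (seq, sample) tuples."""
    if isinstance(item, Member):
        return item.seq, item.sample, item.meta
    if isinstance(item, str):
        return item, None, {}
    if isinstance(item, SequenceRecord):
        return item.seq, None, item.meta
    if isinstance(item, QualityRead):
        return item.seq, item.sample, item.meta
    seq, sample = item
    return seq, sample, {}


@dataclass
class Member:
    seq: str
    sample: str | None = None
    meta: dict = field(default_factory=dict)
    weight: int = 1  # multiplicity from exact deduplication

    def __post_init__(self) -> None:
        self.codes = _dna.encode(self.seq)


@dataclass
class Cluster:
    centroid: Member
    members: list[Member]

    @property
    def size(self) -> int:
        return sum(m.weight for m in self.members)

    def consensus(self) -> str:
        """Per-column majority over members star-aligned to the centroid.

        Ties keep the centroid base; consensus length equals the centroid.
        """
        L = len(self.centroid.codes)
        votes = np.zeros((L, 4), dtype=np.int64)
        for m in self.members:
            if len(m.codes) == L:
                cols = np.arange(L)
                bases = m.codes
            else:
                pairs = _dna.global_pairs(m.codes, self.centroid.codes)
                if not pairs:
                    continue
                qi, cj = zip(*pairs)
                cols = np.array(cj)
                bases = m.codes[np.array(qi)]
            ok = bases < 4
            np.add.at(votes, cols[ok], m.weight * np.eye(4, dtype=np.int64)[bases[ok]])
        best = votes.argmax(axis=1)
        top = votes.max(axis=1)
        # a strict majority is required to overturn the centroid base
        cen = self.centroid.codes.astype(np.int64)
        cen_votes = votes[np.arange(L), np.minimum(cen, 3)]
        out = np.where((top > cen_votes) | (cen >= 4), best, cen).astype(np.uint8)
        return _dna.decode(out)


@dataclass
class LocusCatalog:
    contigs: list[SequenceRecord]
    method: str
    support: list[float]

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            raise ValueError("catalog contig ids must be unique")
        if any(len(c.seq) == 0 for c in self.contigs):
            raise ValueError("catalog contains an empty contig")

    def __len__(self) -> int:
        return len(self.contigs)


@dataclass
class ThresholdScan:
    grid: list[float]
    n_clusters_ge2: list[int]
    n_clusters_ge3: list[int]
    chosen: float

    def to_tsv(self) -> str:
        lines = ["t\tn_ge2\tn_ge3"]
        for t, a, b in zip(self.grid, self.n_clusters_ge2, self.n_clusters_ge3):
            lines.append(f"{t}\t{a}\t{b}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Exact deduplication (PCR duplicate removal on raw sequences)
# ---------------------------------------------------------------------------

def dedupe_exact(seqs: Iterable) -> list[tuple[Member, int]]:
    """Collapse exact sequence duplicates, keeping first occurrence + count."""
    seen: dict[str, int] = {}
    out: list[tuple[Member, int]] = []
    for item in seqs:
        seq, sample, meta = _coerce_seq(item)
        if seq in seen:
            idx = seen[seq]
            member, count = out[idx]
            member.weight = count + 1
            out[idx] = (member, count + 1)
        else:
            seen[seq] = len(out)
            out.append((Member(seq, sample, dict(meta)), 1))
    return out


# ---------------------------------------------------------------------------
# Greedy identity clustering
# ---------------------------------------------------------------------------

def _identity(a: Member, b: Member, t: float) -> float:
    la, lb = len(a.codes), len(b.codes)
    # identity is bounded by min/max length: skip hopeless pairs early
    if min(la, lb) < t * max(la, lb):
        return 0.0
    return _dna.identity(a.codes, b.codes)


def greedy_cluster(seqs: Sequence, t: float) -> list[Cluster]:
    """Length-sorted, first-match greedy clustering at identity >= t.

    Sequences are processed in decreasing-length order (ties lexicographic);
    each joins the FIRST (creation-order) centroid reaching the threshold,
    otherwise founds a new cluster.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError("identity threshold must be in (0, 1]")
    members = [
        s if isinstance(s, Member) else Member(*_coerce_seq(s)) for s in seqs
    ]
    order = sorted(range(len(members)), key=lambda i: (-len(members[i].seq), members[i].seq))
    clusters: list[Cluster] = []
    for i in order:
        m = members[i]
        placed = False
        for cl in clusters:
            if _identity(m, cl.centroid, t) >= t:
                cl.members.append(m)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(centroid=m, members=[m]))
    return clusters


def optimize_threshold(
    seqs: Sequence, grid: Sequence[float] = WITHIN_GRID, min_cov: int = 2
) -> ThresholdScan:
    """Scan thresholds, counting clusters with >=2 and >=3 members.

    The chosen threshold maximizes the >=3x cluster count, breaking ties by
    the smallest excess of the >=2x count over the >=3x count, then by the
    larger threshold.  Rationale: an overtight threshold splits true loci
    and inflates the shallow-coverage count past the number of real loci
    while the deep-coverage count stalls, so the knee where both curves
    agree at their joint maximum is the usable optimum.  ``min_cov`` is
    kept for interface clarity; both coverage curves are always reported.
    """
    if not grid:
        raise ValueError("threshold grid must be non-empty")
    n2, n3 = [], []
    for t in grid:
        clusters = greedy_cluster(seqs, t)
        n2.append(sum(1 for c in clusters if c.size >= 2))
        n3.append(sum(1 for c in clusters if c.size >= 3))
    best = max(
        range(len(grid)), key=lambda i: (n3[i], n3[i] - n2[i], grid[i])
    )
    if n2[best] == 0:
        warnings.warn("no cluster reached 2x coverage at any threshold", stacklevel=2)
    return ThresholdScan(list(grid), n2, n3, float(grid[best]))


def build_rad_ref(
    per_sample_probe_reads: dict[str, Sequence],
    t_within: float = 0.91,
    t_among: float = 0.71,
) -> LocusCatalog:
    """Two-iteration clustering: within samples, then among pooled consensi.

    Iteration-2 consensus sequences become the locus references.  Consensus
    records inherit the provenance metadata of their centroid member.
    """
    consensi: list[Member] = []
    for sample, reads in per_sample_probe_reads.items():
        for cl in greedy_cluster(list(reads), t_within):
            consensi.append(Member(cl.consensus(), sample, dict(cl.centroid.meta)))
    if not consensi:
        warnings.warn("no probe reads: empty catalog", stacklevel=2)
        return LocusCatalog([], RAD_REF, [])
    contigs: list[SequenceRecord] = []
    support: list[float] = []
    for i, cl in enumerate(greedy_cluster(consensi, t_among)):
        contigs.append(
            SequenceRecord(f"locus_{i:05d}", cl.consensus(), meta=dict(cl.centroid.meta))
        )
        support.append(cl.size)
    return LocusCatalog(contigs, RAD_REF, support)


# ---------------------------------------------------------------------------
# Contig extension with capture reads
# ---------------------------------------------------------------------------

def _end_votes(
    contig: np.ndarray,
    reads: list[np.ndarray],
    min_overlap: int,
    min_identity: float,
    k: int = 15,
) -> tuple[list[dict], list[dict]]:
    """Vote tables for bases beyond the left/right contig ends."""
    index = _dna.KmerIndex([contig], k)
    right: list[dict] = []
    left: list[dict] = []
    for codes in reads:
        for oriented in (codes, _dna.revcomp_codes(codes)):
            kc = _dna.kmer_codes(oriented, k)
            hits = np.flatnonzero(index.member_mask(kc))
            diags = set()
            for qpos in hits[:4]:
                for _, rpos in index.lookup(int(kc[qpos])):
                    diags.add(rpos - int(qpos))
            for diag in diags:
                matches, olap, q_start, r_start = _dna.diagonal_overlap(
                    oriented, contig, diag
                )
                if olap < min_overlap or matches / olap < min_identity:
                    continue
                # right overhang: alignment runs to the contig end
                if r_start + olap == len(contig):
                    over = oriented[q_start + olap :]
                    for col, base in enumerate(over):
                        if base >= 4:
                            break
                        while len(right) <= col:
                            right.append({})
                        right[col][int(base)] = right[col].get(int(base), 0) + 1
                # left overhang: alignment starts at contig position 0
                if r_start == 0 and q_start > 0:
                    over = oriented[:q_start][::-1]  # columns outward from the end
                    for col, base in enumerate(over):
                        if base >= 4:
                            break
                        while len(left) <= col:
                            left.append({})
                        left[col][int(base)] = left[col].get(int(base), 0) + 1
    return left, right


def _walk_votes(votes: list[dict], min_support: int) -> list[int]:
    out: list[int] = []
    for col in votes:
        total = sum(col.values())
        if total < min_support:
            break
        best = max(col.values())
        winners = [b for b, v in col.items() if v == best]
        if len(winners) != 1:
            break  # majority tie freezes extension
        out.append(winners[0])
    return out


def extend_catalog(
    catalog: LocusCatalog,
    capture_reads: Sequence,
    cycles: int = 30,
    min_overlap: int = 30,
    min_identity: float = 0.9,
    min_support: int = 2,
    trim_bp: int = 60,
) -> LocusCatalog:
    """Iteratively extend contig ends by read-overlap majority vote.

    Per cycle, reads whose overlap with a contig end is >= min_overlap bases
    at >= min_identity vote on overhang bases; the contig grows by the
    per-column majority while support stays >= min_support.  After all
    cycles each contig is trimmed by trim_bp per end (putatively low-quality
    extension boundaries); contigs with length <= 2*trim_bp are dropped.
    """
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    read_codes = [_dna.encode(_coerce_seq(r)[0]) for r in capture_reads]
    contigs = [_dna.encode(c.seq) for c in catalog.contigs]
    for _ in range(cycles):
        grew = False
        for ci, contig in enumerate(contigs):
            left, right = _end_votes(contig, read_codes, min_overlap, min_identity)
            ext_r = _walk_votes(right, min_support)
            ext_l = _walk_votes(left, min_support)
            if ext_r or ext_l:
                grew = True
                parts = []
                if ext_l:
                    parts.append(np.array(ext_l[::-1], dtype=np.uint8))
                parts.append(contig)
                if ext_r:
                    parts.append(np.array(ext_r, dtype=np.uint8))
                contigs[ci] = np.concatenate(parts)
        if not grew:
            break
    out_contigs: list[SequenceRecord] = []
    out_support: list[float] = []
    for ci, contig in enumerate(contigs):
        if len(contig) <= 2 * trim_bp:
            continue
        trimmed = contig[trim_bp : len(contig) - trim_bp] if trim_bp else contig
        src = catalog.contigs[ci]
        out_contigs.append(SequenceRecord(src.id, _dna.decode(trimmed), meta=dict(src.meta)))
        out_support.append(catalog.support[ci] if ci < len(catalog.support) else 1)
    return LocusCatalog(out_contigs, RAD_REF_EXT, out_support)


# ---------------------------------------------------------------------------
# Minimal de Bruijn unitig assembly
# ---------------------------------------------------------------------------

def assemble_denovo(
    reads: Sequence, k: int = 31, min_kmer_cov: int = 2
) -> LocusCatalog:
    """Unitigs of the k-mer de Bruijn graph over reads (both strands).

    K-mers below ``min_kmer_cov`` are discarded; unitigs are maximal
    non-branching paths (branching nodes terminate unitigs, no bubble
    popping); contigs shorter than k+10 are dropped and reverse-complement
    duplicates collapse to the lexicographically smaller strand.
    """
    if k % 2 == 0 or not 15 <= k <= 63:
        raise ValueError("k must be odd and in [15, 63]")
    counts: dict[int, int] = {}
    for r in reads:
        seq, _, _ = _coerce_seq(r)
        codes = _dna.encode(seq)
        for oriented in (codes, _dna.revcomp_codes(codes)):
            for code in _dna.kmer_codes(oriented, k):
                if code >= 0:
                    counts[int(code)] = counts.get(int(code), 0) + 1
    kmers = {c for c, n in counts.items() if n >= min_kmer_cov}
    if not kmers:
        return LocusCatalog([], ASSEMBLY_REF, [])

    mask_sufx = 4 ** (k - 1)

    def successors(code: int) -> list[int]:
        base = (code % mask_sufx) * 4
        return [base + b for b in range(4) if base + b in kmers]

    def predecessors(code: int) -> list[int]:
        base = code // 4
        return [b * mask_sufx + base for b in range(4) if b * mask_sufx + base in kmers]

    def is_path_start(code: int) -> bool:
        preds = predecessors(code)
        if len(preds) != 1:
            return True
        return len(successors(preds[0])) != 1

    def decode_kmer(code: int) -> str:
        bases = []
        for _ in range(k):
            bases.append("ACGT"[code % 4])
            code //= 4
        return "".join(reversed(bases))

    visited: set[int] = set()
    unitigs: list[tuple[str, float]] = []

    def walk(start: int) -> None:
        path = [start]
        visited.add(start)
        node = start
        while True:
            succ = successors(node)
            if len(succ) != 1:
                break
            nxt = succ[0]
            if len(predecessors(nxt)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            node = nxt
        seq = decode_kmer(path[0]) + "".join("ACGT"[c % 4] for c in path[1:])
        cov = float(np.mean([counts[c] for c in path]))
        unitigs.append((seq, cov))

    for code in sorted(kmers):
        if code not in visited and is_path_start(code):
            walk(code)
    for code in sorted(kmers):  # isolated cycles, if any
        if code not in visited:
            walk(code)

    from .seqio import revcomp

    best: dict[str, tuple[str, float]] = {}
    for seq, cov in unitigs:
        if len(seq) < k + 10:
            continue
        canon = min(seq, revcomp(seq))
        if canon not in best:
            best[canon] = (seq if seq <= revcomp(seq) else revcomp(seq), cov)
    contigs = []
    support = []
    for i, (canon, (seq, cov)) in enumerate(sorted(best.items())):
        contigs.append(SequenceRecord(f"asm_{i:05d}", seq))
        support.append(cov)
    return LocusCatalog(contigs, ASSEMBLY_REF, support)
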