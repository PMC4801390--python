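"""In-silico double restriction digestion and probe size selection.

A cut is a single coordinate (site start + top-strand cut offset); overhang
chemistry is not modeled.  Fragments between consecutive cuts partition each
chromosome exactly.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

from .seqio import SequenceRecord

CHROM_END = "chrom_end"


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(f"{self.name}: cut_offset outside recognition site")
        if not set(self.recognition) <= set("ACGT"):
            raise ValueError(f"{self.name}: recognition must be over A/C/G/T")


# REBASE definitions; both sites are palindromic.
SBFI = Enzyme("SbfI", "CCTGCAGG", 6)
MSEI = Enzyme("MseI", "TTAA", 1)

ENZYMES = {e.name: e for e in (SBFI, MSEI)}


@dataclass
class Fragment:
    chrom: str
    start: int
    end: int
    left_end: str
    right_end: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("fragment start must be < end")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class ProbeSet:
    """Size-selected double-digest inserts with one SbfI and one MseI end."""

    probes: list[SequenceRecord]
    size_window: tuple[int, int]

    def intervals(self) -> list[tuple[str, int, int]]:
        return [
            (p.meta["chrom"], p.meta["start"], p.meta["end"]) for p in self.probes
        ]

    def __len__(self) -> int:
        return len(self.probes)


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Sorted start positions of all exact recognition-site occurrences.

    Overlapping occurrences are reported; N never matches (the recognition
    alphabet excludes it so exact matching suffices).
    """
    sites: list[int] = []
    start = seq.find(enzyme.recognition)
    while start != -1:
        sites.append(start)
        start = seq.find(enzyme.recognition, start + 1)
    return sites


def double_digest(
    genome: Iterable[SequenceRecord], enz_a: Enzyme = SBFI, enz_b: Enzyme = MSEI
) -> list[Fragment]:
    """Cut every chromosome with both enzymes and return boundary-labeled fragments."""
    fragments: list[Fragment] = []
    for rec in genome:
        cuts: dict[int, str] = {}
        for enz in (enz_a, enz_b):
            for site in find_sites(rec.seq, enz):
                pos = site + enz.cut_offset
                # Coincident cuts from both enzymes are vanishingly rare for
                # the built-ins; first enzyme listed wins the label.
                cuts.setdefault(pos, enz.name)
        boundaries = [(0, CHROM_END)]
        for pos in sorted(cuts):
            if 0 < pos < len(rec.seq):
                boundaries.append((pos, cuts[pos]))
        boundaries.append((len(rec.seq), CHROM_END))
        for (start, left), (end, right) in zip(boundaries, boundaries[1:]):
            if end > start:
                fragments.append(Fragment(rec.id, start, end, left, right))
    return fragments


def select_probes(
    fragments: Sequence[Fragment],
    genome: Iterable[SequenceRecord],
    size_window: tuple[int, int] = (130, 190),
) -> ProbeSet:
    """Keep SbfI-MseI (either orientation) fragments within the size window.

    The default window models a tight ~270 bp selection of adapter-ligated
    constructs minus ~110 bp of adapters (see package docs); it is fully
    configurable.
    """
    lo, hi = size_window
    if lo < 1:
        raise ValueError("size_window minimum must be >= 1")
    by_chrom = {rec.id: rec.seq for rec in genome}
    probes: list[SequenceRecord] = []
    for frag in fragments:
        if {frag.left_end, frag.right_end} != {SBFI.name, MSEI.name}:
            continue
        if not lo <= len(frag) <= hi:
            continue
        seq = by_chrom[frag.chrom][frag.start : frag.end]
        probes.append(
            SequenceRecord(
                f"{frag.chrom}:{frag.start}-{frag.end}",
                seq,
                meta={
                    "chrom": frag.chrom,
                    "start": frag.start,
                    "end": frag.end,
                    "left_end": frag.left_end,
                    "right_end": frag.right_end,
                },
            )
        )
    if not probes:
        warnings.warn("size selection produced an empty probe set", stacklevel=2)
    return ProbeSet(probes=probes, size_window=(lo, hi))


def union_probe_sets(probe_sets: Sequence[ProbeSet]) -> ProbeSet:
    """Pool probes from several source individuals, deduplicating by sequence."""
    if not probe_sets:
        raise ValueError("no probe sets to pool")
    seen: dict[str, SequenceRecord] = {}
    for ps in probe_sets:
        for p in ps.probes:
            seen.setdefault(p.seq, p)
    window = probe_sets[0].size_window
    return ProbeSet(probes=list(seen.values()), size_window=window)


def probes_to_bed(probe_set: ProbeSet) -> str:
    lines = [
        f"{p.meta['chrom']}\t{p.meta['start']}\t{p.meta['end']}\t{p.id}"
        for p in probe_set.probes
    ]
    return "\n".join(lines) + ("\n" if lines else "")
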