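"""Synthetic diploid cohorts with a complete variant truth table.

The generator plants substitution-only variation on a single ancestor
chromosome: population-private fixed differences plus per-individual
heterozygous sites, with an optional rate boost inside restriction-site
occurrences so that restriction-based locus dropout becomes measurable.
No coalescent/recombination realism is attempted.
"""
from __future__ import annotations

import math

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _dna
from .digest import ENZYMES, MSEI, SBFI, CHROM_END, Enzyme, Fragment
from .seqio import SequenceRecord

TRUTH_COLUMNS = ["chrom", "pos", "ref", "alt", "kind"]


@dataclass
class PopulationModel:
    n_pops: int = 2
    n_per_pop: int = 4
    theta_within: float = 0.001
    d_between: float = 0.005
    rs_mutation_boost: float = 1.0

    def __post_init__(self) -> None:
        if self.n_pops < 1:
            raise ValueError("n_pops must be >= 1")
        for name in ("theta_within", "d_between"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.rs_mutation_boost < 0:
            raise ValueError("rs_mutation_boost must be >= 0")


class SimulatedCohort:
    """Diploid individuals, their haplotype code arrays, and the truth table.

    ``truth`` is a DataFrame with columns chrom/pos/ref/alt/kind plus one
    phased-genotype column per individual ("0|0", "0|1", "1|0", "1|1").
    """

    def __init__(
        self,
        ancestor: SequenceRecord,
        haplotypes: dict[str, tuple[np.ndarray, np.ndarray]],
        labels: dict[str, int],
        truth: pd.DataFrame,
    ):
        self.ancestor = ancestor
        self.ancestor_codes = _dna.encode(ancestor.seq)
        self.haplotypes = haplotypes
        self.labels = labels
        self.truth = truth

    @property
    def samples(self) -> list[str]:
        return list(self.haplotypes)

    def haplotype(self, sample: str, h: int) -> np.ndarray:
        return self.haplotypes[sample][h]

    def haplotype_record(self, sample: str, h: int) -> SequenceRecord:
        """Haplotype as a record named after the ancestor chromosome.

        Coordinates are shared with the ancestor (substitution-only model),
        so downstream provenance stays in ancestor space.
        """
        return SequenceRecord(self.ancestor.id, _dna.decode(self.haplotypes[sample][h]))

    def rebuild_haplotype(self, sample: str, h: int) -> np.ndarray:
        """Reconstruct a haplotype from the ancestor plus the truth table."""
        arr = self.ancestor_codes.copy()
        col = self.truth[sample] if sample in self.truth.columns else []
        for pos, alt, gt in zip(self.truth["pos"], self.truth["alt"], col):
            if gt.split("|")[h] == "1":
                arr[pos] = _dna.encode(alt)[0]
        return arr


def simulate_ancestor(
    length: int, gc: float, seed: int, chrom: str = "chr1"
) -> SequenceRecord:
    """I.i.d. ancestor sequence with the requested GC content."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0 < gc <= 1:
        raise ValueError("gc must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=length, p=p / p.sum()).astype(np.uint8)
    return SequenceRecord(chrom, _dna.decode(codes))


def embed_motifs(
    record: SequenceRecord, motif: str, n: int, seed: int, min_gap: int = 1000
) -> tuple[SequenceRecord, list[int]]:
    """Overwrite ``n`` evenly spaced, jittered copies of ``motif`` into a sequence.

    Test/benchmark plumbing: densifies rare recognition sites so that small
    genomes still yield a usable probe space.  Returns the new record and the
    motif start positions.
    """
    L = len(record.seq)
    m = len(motif)
    if n * (min_gap + m) > L:
        raise ValueError("sequence too short for requested motif count/spacing")
    rng = np.random.default_rng(seed)
    stride = L // n
    positions = []
    for i in range(n):
        lo = i * stride
        hi = min(L - m, (i + 1) * stride - min_gap)
        positions.append(int(rng.integers(lo, max(lo + 1, hi))))
    seq = record.seq
    chunks = []
    prev = 0
    for pos in positions:
        chunks.append(seq[prev:pos])
        chunks.append(motif)
        prev = pos + m
    chunks.append(seq[prev:])
    return SequenceRecord(record.id, "".join(chunks)), positions


def _site_mask(codes: np.ndarray, enzymes: Sequence[Enzyme]) -> np.ndarray:
    """Boolean mask of positions covered by any recognition-site occurrence."""
    seq = _dna.decode(codes)
    mask = np.zeros(len(codes), dtype=bool)
    for enz in enzymes:
        start = seq.find(enz.recognition)
        while start != -1:
            mask[start : start + len(enz.recognition)] = True
            start = seq.find(enz.recognition, start + 1)
    return mask


def _creates_new_site(
    codes: np.ndarray, pos: int, alt_code: int, enzymes: Sequence[Enzyme]
) -> bool:
    """Would substituting alt at pos create a recognition occurrence absent before?

    Checked against the ancestor context only (one substitution at a time),
    which is exact for isolated variants and a documented approximation when
    planted variants are adjacent.
    """
    w = max(len(e.recognition) for e in enzymes) - 1
    lo = max(0, pos - w)
    window = codes[lo : pos + w + 1]
    before = _dna.decode(window)
    mutated = window.copy()
    mutated[pos - lo] = alt_code
    after = _dna.decode(mutated)
    for enz in enzymes:
        found_after = set()
        start = after.find(enz.recognition)
        while start != -1:
            found_after.add(start)
            start = after.find(enz.recognition, start + 1)
        start = before.find(enz.recognition)
        while start != -1:
            found_after.discard(start)
            start = before.find(enz.recognition, start + 1)
        if found_after:
            return True
    return False


def _draw_alt(
    rng: np.random.Generator,
    codes: np.ndarray,
    pos: int,
    enzymes: Sequence[Enzyme],
) -> int | None:
    ref = codes[pos]
    for alt in rng.permutation([b for b in range(4) if b != ref]):
        if not _creates_new_site(codes, pos, int(alt), enzymes):
            return int(alt)
    return None


def simulate_cohort(
    ancestor: SequenceRecord,
    model: PopulationModel,
    seed: int,
    enzymes: Sequence[Enzyme] = (SBFI, MSEI),
) -> SimulatedCohort:
    """Plant fixed differences and heterozygous sites on the ancestor.

    Fixed differences are population-private and homozygous within the
    carrier population; heterozygous sites are independent per individual.
    Sites inside any recognition occurrence mutate at rate x rs_mutation_boost.
    A substitution that would create a new recognition site is re-drawn.
    """
    rng = np.random.default_rng(seed)
    codes = _dna.encode(ancestor.seq)
    L = len(codes)
    boost = np.where(_site_mask(codes, enzymes), model.rs_mutation_boost, 1.0)

    samples = [
        f"pop{p}_ind{i}" for p in range(model.n_pops) for i in range(model.n_per_pop)
    ]
    labels = {s: int(s[3 : s.index("_")]) for s in samples}

    used = np.zeros(L, dtype=bool)
    rows: list[dict] = []

    # population-private fixed differences
    p_fix = np.clip(model.d_between * boost, 0.0, 1.0)
    fix_pos = np.flatnonzero(rng.random(L) < p_fix)
    for pos in fix_pos:
        alt = _draw_alt(rng, codes, int(pos), enzymes)
        if alt is None:
            continue
        pop = int(rng.integers(model.n_pops))
        row = {
            "chrom": ancestor.id,
            "pos": int(pos),
            "ref": _dna.decode(codes[pos : pos + 1]),
            "alt": "ACGT"[alt],
            "kind": "fixed_diff",
        }
        for s in samples:
            row[s] = "1|1" if labels[s] == pop else "0|0"
        rows.append(row)
        used[pos] = True

    # per-individual heterozygous sites
    p_het = np.clip(model.theta_within * boost, 0.0, 1.0)
    for s in samples:
        het_pos = np.flatnonzero((rng.random(L) < p_het) & ~used)
        for pos in het_pos:
            alt = _draw_alt(rng, codes, int(pos), enzymes)
            if alt is None:
                continue
            hap = int(rng.integers(2))
            row = {
                "chrom": ancestor.id,
                "pos": int(pos),
                "ref": _dna.decode(codes[pos : pos + 1]),
                "alt": "ACGT"[alt],
                "kind": "het",
            }
            for other in samples:
                row[other] = "0|0"
            row[s] = "1|0" if hap == 0 else "0|1"
            rows.append(row)
            used[pos] = True

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS + samples)
    truth = truth.sort_values("pos", kind="stable").reset_index(drop=True)

    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for s in samples:
        h0, h1 = codes.copy(), codes.copy()
        for pos, alt, gt in zip(truth["pos"], truth["alt"], truth[s]):
            a0, a1 = gt.split("|")
            code = _dna.encode(alt)[0]
            if a0 == "1":
                h0[pos] = code
            if a1 == "1":
                h1[pos] = code
        haplotypes[s] = (h0, h1)

    return SimulatedCohort(ancestor, haplotypes, labels, truth)


def truth_variants_in(
    cohort: SimulatedCohort, intervals: Iterable[tuple[str, int, int]]
) -> pd.DataFrame:
    """Truth rows whose position falls in any 0-based half-open interval."""
    truth = cohort.truth
    keep = np.zeros(len(truth), dtype=bool)
    pos = truth["pos"].to_numpy() if len(truth) else np.empty(0, dtype=int)
    chrom = truth["chrom"].to_numpy() if len(truth) else np.empty(0, dtype=object)
    for c, s, e in intervals:
        keep |= (chrom == c) & (pos >= s) & (pos < e)
    return truth[keep].reset_index(drop=True)


def flanking_sites(fragment: Fragment) -> list[tuple[str, int]]:
    """(enzyme name, site start) for each enzyme-cut boundary of a fragment."""
    sites = []
    if fragment.left_end != CHROM_END:
        enz = ENZYMES[fragment.left_end]
        sites.append((enz.name, fragment.start - enz.cut_offset))
    if fragment.right_end != CHROM_END:
        enz = ENZYMES[fragment.right_end]
        sites.append((enz.name, fragment.end - enz.cut_offset))
    return sites


def plant_site_disruptions(
    cohort: SimulatedCohort,
    loci: Sequence[Fragment],
    mu: float,
    seed: int,
) -> int:
    """Disrupt each locus allele with marginal probability ``mu``.

    Disruptions are drawn per *unique* flanking recognition site at rate
    q = 1 - sqrt(1 - mu): a locus allele needs both its flanking sites
    intact, so its disruption probability is 1 - (1-q)^2 = mu exactly —
    including loci that share a cut site with a neighboring fragment, where
    naive per-locus draws would leak onto the neighbor and overshoot.
    A disruption substitutes one base inside the recognition site on that
    haplotype; events are appended to the truth table
    (kind='site_disruption').  Returns the number of planted events.
    """
    if not 0.0 <= mu <= 1.0:
        raise ValueError("mu must be in [0, 1]")
    rng = np.random.default_rng(seed)
    anc = cohort.ancestor_codes
    existing = set(cohort.truth["pos"]) if len(cohort.truth) else set()
    q = 1.0 - math.sqrt(1.0 - mu)
    unique_sites = sorted(
        {site for frag in loci for site in flanking_sites(frag)},
        key=lambda x: x[1],
    )
    events: dict[int, dict] = {}
    n_events = 0
    for s in cohort.samples:
        for h in (0, 1):
            hap = cohort.haplotypes[s][h]
            for enz_name, site_start in unique_sites:
                if rng.random() >= q:
                    continue
                offset = int(rng.integers(len(ENZYMES[enz_name].recognition)))
                pos = site_start + offset
                if pos in existing:
                    # avoid stacking on a pre-existing variant position;
                    # pick the adjacent site base instead
                    pos = site_start + (offset + 1) % len(ENZYMES[enz_name].recognition)
                    if pos in existing:
                        continue
                ref = int(anc[pos])
                alt = (ref + 1) % 4  # deterministic per position: shared alt allele
                hap[pos] = alt
                n_events += 1
                row = events.setdefault(
                    pos,
                    {
                        "chrom": cohort.ancestor.id,
                        "pos": pos,
                        "ref": "ACGT"[ref],
                        "alt": "ACGT"[alt],
                        "kind": "site_disruption",
                        **{x: "0|0" for x in cohort.samples},
                    },
                )
                gt = row[s].split("|")
                gt[h] = "1"
                row[s] = "|".join(gt)
    if events:
        existing = set(cohort.truth["pos"]) if len(cohort.truth) else set()
        fresh = [r for p, r in events.items() if p not in existing]
        cohort.truth = (
            pd.concat([cohort.truth, pd.DataFrame(fresh)], ignore_index=True)
            .sort_values("pos", kind="stable")
            .reset_index(drop=True)
        )
    return n_events
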