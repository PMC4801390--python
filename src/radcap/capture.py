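"""Hybridization-capture enrichment model.

Capture operates on library molecules (pre-sequencing), mirroring the wet
protocol's order.  A molecule is on-target when its best probe overlap is
long and identical enough; daisy-chaining lets molecules from a probe's
flanking region (truth provenance, +-flank_bp) survive without direct probe
homology; everything else is background carried over at a low rate.  The
three retention probabilities abstract hybridization stringency, blocking
oligos and repetitive-sequence blocking agents.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _dna
from .digest import ProbeSet
from .libsim import MoleculeSet

ON_TARGET, FLANKING, OFF_TARGET = "on_target", "flanking", "off_target"
_CLASS_NAMES = (ON_TARGET, FLANKING, OFF_TARGET)

_SEED_K = 15


@dataclass
class CaptureModel:
    identity_threshold: float = 0.8
    min_overlap_bp: int = 40
    p_on: float = 0.9
    p_bg: float = 0.02
    daisy_chain: bool = True
    p_daisy: float = 0.3
    flank_bp: int = 500

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")
        if not 0.0 <= self.p_bg <= self.p_daisy <= self.p_on <= 1.0:
            raise ValueError("need 0 <= p_bg <= p_daisy <= p_on <= 1")


class ProbeIndex:
    """Seed index plus flanked source intervals for a probe set."""

    def __init__(self, probe_set: ProbeSet, k: int = _SEED_K):
        self.k = k
        self.probe_codes = [_dna.encode(p.seq) for p in probe_set.probes]
        # index both strands of every probe so molecules from either strand seed
        both = []
        self._strand_of = []
        for codes in self.probe_codes:
            both.append(codes)
            self._strand_of.append(1)
        for codes in self.probe_codes:
            both.append(_dna.revcomp_codes(codes))
            self._strand_of.append(-1)
        self.index = _dna.KmerIndex(both, k)
        self.all_codes = both
        self.intervals = sorted(
            (p.meta["chrom"], p.meta["start"], p.meta["end"])
            for p in probe_set.probes
            if "chrom" in p.meta
        )

    def merged_flanks(self, chrom: str, flank: int) -> tuple[np.ndarray, np.ndarray]:
        ivs = sorted(
            (max(0, s - flank), e + flank)
            for c, s, e in self.intervals
            if c == chrom
        )
        starts, ends = [], []
        for s, e in ivs:
            if starts and s <= ends[-1]:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        return np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64)


def _best_probe_overlap(
    codes: np.ndarray, index: ProbeIndex, max_anchors: int = 4
) -> tuple[float, int]:
    """(identity, overlap) of the best seed-anchored ungapped probe overlap."""
    kcodes = _dna.kmer_codes(codes, index.k)
    hit_mask = index.index.member_mask(kcodes)
    best_ident, best_olap = 0.0, 0
    tried: set[tuple[int, int]] = set()
    for qpos in np.flatnonzero(hit_mask):
        for ref_i, rpos in index.index.lookup(int(kcodes[qpos])):
            diag = rpos - int(qpos)
            key = (ref_i, diag)
            if key in tried:
                continue
            tried.add(key)
            matches, olap = _dna.local_diagonal(codes, index.all_codes[ref_i], diag)
            if olap > 0:
                ident = matches / olap
                if (ident, olap) > (best_ident, best_olap):
                    best_ident, best_olap = ident, olap
            if len(tried) >= max_anchors:
                return best_ident, best_olap
    return best_ident, best_olap


def classify_molecule(
    molecule_seq: str,
    index: ProbeIndex,
    model: CaptureModel,
    source_interval: tuple[str, int, int] | None = None,
) -> str:
    """Classify one molecule as on_target / flanking / off_target."""
    codes = _dna.encode(molecule_seq)
    ident, olap = _best_probe_overlap(codes, index)
    if olap >= model.min_overlap_bp and ident >= model.identity_threshold:
        return ON_TARGET
    if model.daisy_chain and source_interval is not None:
        chrom, s, e = source_interval
        starts, ends = index.merged_flanks(chrom, model.flank_bp)
        if len(starts):
            i = np.searchsorted(ends, s, side="right")
            if i < len(starts) and starts[i] < e:
                return FLANKING
    return OFF_TARGET


def classify_molecules(
    molecules: MoleculeSet, index: ProbeIndex, model: CaptureModel
) -> np.ndarray:
    """Vectorized classification of a MoleculeSet; returns class-code array.

    0 = on_target, 1 = flanking, 2 = off_target.  The k-mer prescreen makes
    the common (off-target) case a pure array operation; only molecules
    sharing a seed with a probe are aligned.
    """
    n = len(molecules)
    classes = np.full(n, 2, dtype=np.int8)
    if n == 0:
        return classes
    kcodes = _dna.kmer_codes(molecules.cat, index.k)
    hit = index.index.member_mask(kcodes)
    # a k-mer belongs to molecule i if it starts within [bounds[i], bounds[i+1]-k]
    has_seed = np.zeros(n, dtype=bool)
    if len(kcodes):
        hit_pos = np.flatnonzero(hit)
        mol_of = np.searchsorted(molecules.bounds, hit_pos, side="right") - 1
        ok = hit_pos + index.k <= molecules.bounds[mol_of + 1]
        has_seed[np.unique(mol_of[ok])] = True
    for i in np.flatnonzero(has_seed):
        ident, olap = _best_probe_overlap(molecules.seq_codes(i), index)
        if olap >= model.min_overlap_bp and ident >= model.identity_threshold:
            classes[i] = 0
    if model.daisy_chain and np.any(classes != 0):
        starts, ends = index.merged_flanks(molecules.chrom, model.flank_bp)
        if len(starts):
            endo = (classes != 0) & (molecules.provenance == 0)
            idx = np.flatnonzero(endo)
            i = np.searchsorted(ends, molecules.start[idx], side="right")
            valid = i < len(starts)
            overlaps = np.zeros(len(idx), dtype=bool)
            overlaps[valid] = starts[i[valid]] < molecules.end[idx[valid]]
            classes[idx[overlaps]] = 1
    return classes


def enrich(
    molecules: MoleculeSet,
    index: ProbeIndex,
    model: CaptureModel,
    seed: int,
) -> tuple[MoleculeSet, dict]:
    """Retain each molecule with the probability of its capture class.

    Returns the retained subset plus a per-class report:
    input/retained counts and the retained on-target fraction.
    """
    rng = np.random.default_rng(seed)
    classes = classify_molecules(molecules, index, model)
    p = np.array([model.p_on, model.p_daisy, model.p_bg])[classes]
    keep = rng.random(len(molecules)) < p
    retained = molecules.subset(keep)
    report = {
        "n_input": int(len(molecules)),
        "n_retained": int(keep.sum()),
    }
    for code, name in enumerate(_CLASS_NAMES):
        report[f"input_{name}"] = int(np.sum(classes == code))
        report[f"retained_{name}"] = int(np.sum(keep & (classes == code)))
    report["on_target_fraction"] = (
        report["retained_on_target"] / report["n_retained"]
        if report["n_retained"]
        else 0.0
    )
    return retained, report
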