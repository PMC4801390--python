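"""Shotgun-library read simulator: fragmentation, deamination damage, sequencing.

Fragment lengths are lognormal (mean/sd in bp), truncated at 30 bp.  The
damage model is a two-parameter geometric profile: a cytosine at 5' offset i
deaminates (reads as T) with probability p_max*rho^i, mirrored as G->A from
the 3' end — a deliberate simplification of overhang-based models that still
produces the monotone terminal mismatch enrichment damage estimators detect.
Base qualities are *not* damage-aware: a deaminated base looks confident,
which is what makes downstream quality rescaling meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from . import _dna
from .seqio import QualityRead, SequenceRecord

MIN_FRAGMENT_LEN = 30

#: offsets beyond this contribute < 1e-6 damage probability for default rho
_DAMAGE_WINDOW = 64


@dataclass
class DamageModel:
    p_max: float = 0.3
    rho: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_max <= 1.0:
            raise ValueError("p_max must be in [0, 1]")
        if not 0.0 < self.rho < 1.0:
            raise ValueError("rho must be in (0, 1)")

    def prob(self, offset: int) -> float:
        return self.p_max * self.rho**offset


#: linear age->p_max mapping endpoints (years, p_max); the underlying
#: age-damage relationship is not quantified by any source, so this is a
#: declared, configurable assumption.
AGE_DAMAGE_ENDPOINTS = ((10.0, 0.05), (100.0, 0.3))


def damage_for_age(age_years: float) -> DamageModel:
    (a0, p0), (a1, p1) = AGE_DAMAGE_ENDPOINTS
    t = np.clip((age_years - a0) / (a1 - a0), 0.0, 1.0)
    return DamageModel(p_max=float(p0 + t * (p1 - p0)))


@dataclass
class LibraryConfig:
    mode: str = "fresh"  # fresh | sonicated | museum
    frag_mean: float = 300.0
    frag_sd: float = 60.0
    coverage: float = 10.0
    read_len: int = 150
    seq_error: float = 0.001
    contaminant_fraction: float = 0.0
    contaminant_genome: SequenceRecord | None = None
    damage: DamageModel | None = None
    duplicate_rate: float = 0.0  # PCR duplicate planting (truth-tagged)

    def __post_init__(self) -> None:
        if self.mode not in ("fresh", "sonicated", "museum"):
            raise ValueError(f"unknown library mode {self.mode!r}")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0.0 <= self.contaminant_fraction < 1.0:
            raise ValueError("contaminant_fraction must be in [0, 1)")
        if self.read_len < MIN_FRAGMENT_LEN:
            raise ValueError("read_len must be >= 30")


def museum_config(**overrides) -> LibraryConfig:
    """Degraded-sample defaults: short fragments, terminal deamination."""
    kwargs = dict(
        mode="museum", frag_mean=80.0, frag_sd=30.0, damage=DamageModel()
    )
    kwargs.update(overrides)
    return LibraryConfig(**kwargs)


class MoleculeSet:
    """Columnar container of library molecules for one sample.

    Sequences live in one concatenated uint8 array (``cat``) sliced by
    ``bounds``; per-molecule provenance, source interval and damage offsets
    are truth metadata.  Iteration yields (chrom, start, end, hap) tuples.
    """

    def __init__(
        self,
        sample: str,
        chrom: str,
        start: np.ndarray,
        end: np.ndarray,
        hap: np.ndarray,
        cat: np.ndarray,
        provenance: np.ndarray,  # 0 endogenous, 1 contaminant
        mol_id: np.ndarray | None = None,
    ):
        self.sample = sample
        self.chrom = chrom
        self.start = start
        self.end = end
        self.hap = hap
        self.cat = cat
        self.bounds = np.concatenate([[0], np.cumsum(end - start)])
        self.provenance = provenance
        self.mol_id = (
            mol_id if mol_id is not None else np.arange(len(start), dtype=np.int64)
        )
        self.damage_offsets: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(len(start))
        ]

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[tuple[str, int, int, int]]:
        for i in range(len(self)):
            yield (self.chrom, int(self.start[i]), int(self.end[i]), int(self.hap[i]))

    def seq_codes(self, i: int) -> np.ndarray:
        return self.cat[self.bounds[i] : self.bounds[i + 1]]

    def seq(self, i: int) -> str:
        return _dna.decode(self.seq_codes(i))

    def lengths(self) -> np.ndarray:
        return self.end - self.start

    def subset(self, mask: np.ndarray) -> "MoleculeSet":
        idx = np.flatnonzero(mask)
        keep = np.zeros(len(self.cat), dtype=bool)
        for i in idx:
            keep[self.bounds[i] : self.bounds[i + 1]] = True
        out = MoleculeSet(
            self.sample,
            self.chrom,
            self.start[idx],
            self.end[idx],
            self.hap[idx],
            self.cat[keep],
            self.provenance[idx],
            self.mol_id[idx],
        )
        out.damage_offsets = [self.damage_offsets[i] for i in idx]
        return out

    @staticmethod
    def concatenate(parts: Sequence["MoleculeSet"]) -> "MoleculeSet":
        first = parts[0]
        out = MoleculeSet(
            first.sample,
            first.chrom,
            np.concatenate([p.start for p in parts]),
            np.concatenate([p.end for p in parts]),
            np.concatenate([p.hap for p in parts]),
            np.concatenate([p.cat for p in parts]),
            np.concatenate([p.provenance for p in parts]),
            np.concatenate([p.mol_id for p in parts]),
        )
        out.damage_offsets = [d for p in parts for d in p.damage_offsets]
        return out


def _draw_lengths(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    if sd <= 0:
        return np.full(n, int(round(mean)), dtype=np.int64)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    lens = rng.lognormal(mu, np.sqrt(sigma2), size=n)
    return np.maximum(MIN_FRAGMENT_LEN, np.round(lens)).astype(np.int64)


def fragment_molecules(
    haplotypes: Sequence[np.ndarray | SequenceRecord],
    config: LibraryConfig,
    seed: int,
    sample: str = "s0",
    chrom: str = "chr1",
    provenance: int = 0,
) -> MoleculeSet:
    """Draw random fragments across the haplotypes of one individual.

    Starts are uniform over the (haploid) genome; the molecule count is set
    so that expected depth matches ``config.coverage``.
    """
    haps = [
        _dna.encode(h.seq) if isinstance(h, SequenceRecord) else h for h in haplotypes
    ]
    L = len(haps[0])
    rng = np.random.default_rng(seed)
    n = max(1, int(round(config.coverage * L / config.frag_mean)))
    hap_idx = rng.integers(len(haps), size=n).astype(np.int8)
    lens = _draw_lengths(rng, n, config.frag_mean, config.frag_sd)
    start = rng.integers(0, max(1, L - MIN_FRAGMENT_LEN + 1), size=n)
    end = np.minimum(start + lens, L)

    order = np.argsort(hap_idx, kind="stable")  # gather per haplotype
    start, end, hap_idx = start[order], end[order], hap_idx[order]
    total = int(np.sum(end - start))
    cat = np.empty(total, dtype=np.uint8)
    off = 0
    for i in range(n):
        ln = int(end[i] - start[i])
        cat[off : off + ln] = haps[hap_idx[i]][start[i] : end[i]]
        off += ln
    return MoleculeSet(
        sample,
        chrom,
        start,
        end,
        hap_idx,
        cat,
        np.full(n, provenance, dtype=np.int8),
    )


def apply_damage(
    molecule_seq: str, model: DamageModel, seed: int
) -> tuple[str, list[int]]:
    """Deaminate a single molecule; returns (damaged sequence, hit offsets)."""
    codes = _dna.encode(molecule_seq)
    rng = np.random.default_rng(seed)
    positions = _damage_codes(codes, model, rng)
    return _dna.decode(codes), sorted(int(p) for p in positions)


def _damage_codes(
    codes: np.ndarray, model: DamageModel, rng: np.random.Generator
) -> np.ndarray:
    """In-place damage of one molecule's codes; returns hit offsets."""
    n = len(codes)
    off5 = np.arange(n)
    off3 = off5[::-1]
    p = np.zeros(n)
    is_c = codes == _dna.C
    is_g = codes == _dna.G
    p[is_c] = model.p_max * model.rho ** off5[is_c]
    p[is_g] = model.p_max * model.rho ** off3[is_g].astype(float)
    hits = np.flatnonzero(rng.random(n) < p)
    codes[hits] = np.where(codes[hits] == _dna.C, _dna.T, _dna.A)
    return hits


def damage_molecules(
    molecules: MoleculeSet, model: DamageModel, seed: int
) -> MoleculeSet:
    """Vectorized deamination over a whole MoleculeSet (in place; returns it)."""
    rng = np.random.default_rng(seed)
    cat = molecules.cat
    lens = molecules.lengths()
    starts_rep = np.repeat(molecules.bounds[:-1], lens)
    idx = np.arange(len(cat))
    off5 = idx - starts_rep
    off3 = np.repeat(molecules.bounds[1:] - 1, lens) - idx
    # clip exponents: beyond the window the probability underflows anyway
    off5 = np.minimum(off5, _DAMAGE_WINDOW)
    off3 = np.minimum(off3, _DAMAGE_WINDOW)
    p = np.zeros(len(cat))
    is_c = cat == _dna.C
    is_g = cat == _dna.G
    p[is_c] = model.p_max * model.rho ** off5[is_c].astype(float)
    p[is_g] = model.p_max * model.rho ** off3[is_g].astype(float)
    hits = np.flatnonzero(rng.random(len(cat)) < p)
    cat[hits] = np.where(cat[hits] == _dna.C, _dna.T, _dna.A)
    mol_of_hit = np.searchsorted(molecules.bounds, hits, side="right") - 1
    offsets = hits - molecules.bounds[mol_of_hit]
    molecules.damage_offsets = [
        np.empty(0, dtype=np.int64) for _ in range(len(molecules))
    ]
    for m, o in zip(mol_of_hit, offsets):
        molecules.damage_offsets[m] = np.append(molecules.damage_offsets[m], o)
    return molecules


def _draw_quals(
    rng: np.random.Generator, n: int, seq_error: float
) -> np.ndarray:
    """Integer qualities whose mean PHRED matches -10*log10(seq_error)."""
    if seq_error <= 0:
        return np.full(n, 40, dtype=np.int64)
    q0 = int(round(-10 * np.log10(seq_error)))
    q0 = min(q0, 40)
    lo, hi = max(2, q0 - 2), q0 + 2
    lo = min(lo, q0)  # keep mean at q0 even near the floor
    return rng.integers(lo, hi + 1, size=n)


def sequence_reads(
    molecules: MoleculeSet, config: LibraryConfig, seed: int
) -> list[QualityRead]:
    """Paired-end sequencing of molecules (read-through for short molecules).

    Read 1 covers the molecule 5' end, read 2 is the reverse complement of
    the 3' end.  Substitution errors are i.i.d. at ``seq_error``; qualities
    are drawn around -10*log10(seq_error) and are independent of both the
    error process and damage (deaminated bases look confident).
    """
    rng = np.random.default_rng(seed)
    reads: list[QualityRead] = []
    prov_name = {0: "endogenous", 1: "contaminant"}
    for i in range(len(molecules)):
        codes = molecules.seq_codes(i)
        n_copies = 1 + int(rng.random() < config.duplicate_rate)
        mol_len = len(codes)
        rlen = min(config.read_len, mol_len)
        dmg = set(int(x) for x in molecules.damage_offsets[i])
        for copy in range(n_copies):
            rid = f"{molecules.sample}|m{int(molecules.mol_id[i])}|c{copy}"
            for mate in (1, 2):
                if mate == 1:
                    sub = codes[:rlen].copy()
                    dmg_read = frozenset(p for p in dmg if p < rlen)
                else:
                    tail = codes[mol_len - rlen :]
                    sub = _dna.revcomp_codes(tail)
                    # molecule offset mol_len-1-j maps to read offset j
                    dmg_read = frozenset(
                        mol_len - 1 - p
                        for p in dmg
                        if mol_len - 1 - p < rlen
                    )
                if config.seq_error > 0:
                    errs = np.flatnonzero(rng.random(rlen) < config.seq_error)
                    if len(errs):
                        shift = rng.integers(1, 4, size=len(errs)).astype(np.uint8)
                        sub[errs] = (sub[errs] + shift) % 4
                quals = _draw_quals(rng, rlen, config.seq_error)
                reads.append(
                    QualityRead(
                        id=f"{rid}/{mate}",
                        seq=_dna.decode(sub),
                        qual=[int(q) for q in quals],
                        sample=molecules.sample,
                        mate=mate,
                        provenance=prov_name[int(molecules.provenance[i])],
                        damage_positions=dmg_read,
                        meta={
                            "mol_id": int(molecules.mol_id[i]),
                            "chrom": molecules.chrom,
                            "start": int(molecules.start[i]),
                            "end": int(molecules.end[i]),
                            "hap": int(molecules.hap[i]),
                        },
                    )
                )
    return reads


def spike_contaminants(
    reads: list[QualityRead], config: LibraryConfig, seed: int
) -> list[QualityRead]:
    """Interleave contaminant-genome reads to reach the configured fraction."""
    if config.contaminant_fraction == 0:
        return list(reads)
    if config.contaminant_genome is None:
        raise ValueError("contaminant_fraction > 0 requires a contaminant genome")
    rng = np.random.default_rng(seed)
    f = config.contaminant_fraction
    n_cont_reads = int(round(len(reads) * f / (1 - f)))
    if n_cont_reads == 0:
        return list(reads)
    sample = reads[0].sample if reads else "s0"
    # reads come in pairs; generate enough molecules for the read count
    n_mols = max(1, (n_cont_reads + 1) // 2)
    cont = contaminant_molecules(config, seed=int(rng.integers(2**31)), n=n_mols,
                                 sample=sample or "s0")
    cont_reads = sequence_reads(cont, config, seed=int(rng.integers(2**31)))
    cont_reads = cont_reads[:n_cont_reads]
    merged = list(reads) + cont_reads
    order = rng.permutation(len(merged))
    return [merged[i] for i in order]


def contaminant_molecules(
    config: LibraryConfig, seed: int, n: int | None = None, sample: str = "s0"
) -> MoleculeSet:
    """Fragment the contaminant genome with the same fragment model.

    If ``n`` is None the count follows the coverage/fraction arithmetic used
    for the endogenous library.
    """
    if config.contaminant_genome is None:
        raise ValueError("no contaminant genome configured")
    genome = _dna.encode(config.contaminant_genome.seq)
    rng = np.random.default_rng(seed)
    if n is None:
        f = config.contaminant_fraction
        L = len(genome)
        n_endo = max(1, int(round(config.coverage * L / config.frag_mean)))
        n = int(round(n_endo * f / (1 - f)))
    lens = _draw_lengths(rng, n, config.frag_mean, config.frag_sd)
    L = len(genome)
    start = rng.integers(0, max(1, L - MIN_FRAGMENT_LEN + 1), size=n)
    end = np.minimum(start + lens, L)
    total = int(np.sum(end - start))
    cat = np.empty(total, dtype=np.uint8)
    off = 0
    for i in range(n):
        ln = int(end[i] - start[i])
        cat[off : off + ln] = genome[start[i] : end[i]]
        off += ln
    ms = MoleculeSet(
        sample,
        config.contaminant_genome.id,
        start,
        end,
        np.zeros(n, dtype=np.int8),
        cat,
        np.ones(n, dtype=np.int8),
        mol_id=np.arange(10**9, 10**9 + n, dtype=np.int64),
    )
    return ms
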