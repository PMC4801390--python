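"""Damage-aware genotyping: profile estimation, quality rescaling, diploid
likelihood calling, the site-filter cascade, and cohort-level summaries.

Filter cascade (fixed order, each step only removes):
  1. drop indels; 2. biallelic only; 3. site quality > min_qual;
  4. per-sample genotypes below min_depth become missing;
  5. presence in >= min_presence of samples; 6. minor-allele-count rule;
  7. high-depth paralog removal (mean + sd_mult * SD, strict inequality).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _dna
from .align import UNMAPPED, AlignmentRecord
from .catalog import LocusCatalog
from .digest import MSEI, SBFI, Enzyme, double_digest
from .popsim import SimulatedCohort
from .seqio import error_to_phred, phred_error

_COMP4 = np.array([3, 2, 1, 0, 4])  # complement in code space

MISSING = -1


@dataclass
class DamageProfile:
    """Excess C->T (5') and G->A (3') mismatch rates per terminal read offset."""

    r5: np.ndarray
    r3: np.ndarray
    K: int = 12

    def __post_init__(self) -> None:
        if len(self.r5) != self.K or len(self.r3) != self.K:
            raise ValueError("profile arrays must have length K")
        if np.any(self.r5 < 0) or np.any(self.r3 < 0) or np.any(self.r5 > 1) or np.any(self.r3 > 1):
            raise ValueError("rates must be in [0, 1]")

    @classmethod
    def zeros(cls, K: int = 12) -> "DamageProfile":
        return cls(np.zeros(K), np.zeros(K), K)


@dataclass
class SiteCall:
    contig: str
    pos: int  # 0-based; converted to 1-based only at VCF emission
    ref_base: str
    alt_alleles: list[str]
    genotypes: dict[str, str]  # sample -> "0/0" | "0/1" | "1/1" | "./."
    depths: dict[str, int]
    gquals: dict[str, int]
    site_qual: float
    is_indel: bool = False
    meta: dict = field(default_factory=dict, compare=False)

    @property
    def alt(self) -> str:
        return self.alt_alleles[0] if self.alt_alleles else "."


@dataclass
class FilterConfig:
    min_qual: float = 30.0
    mac_mode: str = "fraction"  # 'fraction' (MAC > alleles/6) or 'absolute' (MAC >= 6)
    mac_fraction: float = 1.0 / 6.0
    mac_absolute: int = 6
    min_presence: float = 0.5
    min_depth: int = 6
    paralog_sd_mult: float = 3.0
    drop_indels: bool = True
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if self.mac_mode not in ("fraction", "absolute"):
            raise ValueError("mac_mode must be 'fraction' or 'absolute'")
        if not 0 < self.mac_fraction < 1:
            raise ValueError("mac_fraction must be in (0, 1)")
        if self.min_qual <= 0 or self.min_depth <= 0 or self.mac_absolute <= 0:
            raise ValueError("thresholds must be positive")


class GenotypeMatrix:
    """samples x sites genotype codes {0,1,2}, -1 for missing."""

    def __init__(self, samples: list[str], sites: pd.DataFrame, codes: np.ndarray):
        if codes.shape != (len(samples), len(sites)):
            raise ValueError("genotype matrix shape mismatch")
        self.samples = samples
        self.sites = sites.reset_index(drop=True)
        self.codes = codes

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape

    def fullness(self) -> float:
        if self.codes.size == 0:
            raise ValueError("empty genotype matrix")
        return float(np.mean(self.codes != MISSING))

    def drop_sites(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.samples, self.sites[keep], self.codes[:, keep])

    def to_tsv(self) -> str:
        header = ["contig", "pos", "ref", "alt"] + self.samples
        lines = ["\t".join(header)]
        for j in range(self.codes.shape[1]):
            row = self.sites.iloc[j]
            cells = [
                str(row["contig"]),
                str(int(row["pos"]) + 1),
                str(row["ref"]),
                str(row["alt"]),
            ] + [
                "." if self.codes[i, j] == MISSING else str(int(self.codes[i, j]))
                for i in range(len(self.samples))
            ]
            lines.append("\t".join(cells))
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Damage profile estimation and base-quality rescaling
# ---------------------------------------------------------------------------

def _read_oriented(
    rec: AlignmentRecord,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(ref, read, offset5) arrays in original read orientation.

    For minus-strand records both base arrays are complemented so that the
    damage signatures read as C->T near the 5' end / G->A near the 3' end,
    exactly as on the sequenced strand.
    """
    ref = rec.ref_codes
    read = rec.read_codes
    off5 = rec.offsets5()
    if rec.strand == "-":
        ref = _COMP4[ref]
        read = _COMP4[read]
    return ref, read, off5


def estimate_damage_profile(
    alignments: Sequence[AlignmentRecord],
    cat: LocusCatalog | None = None,
    K: int = 12,
) -> DamageProfile:
    """Excess terminal C->T / G->A mismatch rates relative to the interior.

    r5[i] is the C->T mismatch rate at 5' read offset i minus the baseline
    rate at offsets >= K, floored at 0; r3 mirrors for G->A from the 3' end.
    Records carry their reference slice, so ``cat`` is accepted only for
    interface symmetry.
    """
    ct_num = np.zeros(K + 1)
    ct_den = np.zeros(K + 1)  # slot K pools the baseline (offsets >= K)
    ga_num = np.zeros(K + 1)
    ga_den = np.zeros(K + 1)
    n_bases = 0
    for rec in alignments:
        if rec.map_class == UNMAPPED or rec.contig_id is None:
            continue
        ref, read, off5 = _read_oriented(rec)
        off3 = rec.read_len - 1 - off5
        n_bases += len(ref)
        b5 = np.minimum(off5, K)
        b3 = np.minimum(off3, K)
        is_c = ref == _dna.C
        is_g = ref == _dna.G
        np.add.at(ct_den, b5[is_c], 1)
        np.add.at(ct_num, b5[is_c & (read == _dna.T)], 1)
        np.add.at(ga_den, b3[is_g], 1)
        np.add.at(ga_num, b3[is_g & (read == _dna.A)], 1)
    if n_bases < 1000:
        warnings.warn(
            f"damage profile estimated from only {n_bases} aligned bases", stacklevel=2
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        ct_rate = np.where(ct_den > 0, ct_num / np.maximum(ct_den, 1), 0.0)
        ga_rate = np.where(ga_den > 0, ga_num / np.maximum(ga_den, 1), 0.0)
    r5 = np.maximum(0.0, ct_rate[:K] - ct_rate[K])
    r3 = np.maximum(0.0, ga_rate[:K] - ga_rate[K])
    return DamageProfile(r5, r3, K)


def _rescaled_q(q: float, r: float) -> float:
    eps = max(phred_error(q), 1e-4)
    p = r + eps - r * eps
    return min(q, error_to_phred(p))


def rescale_qualities(
    alignments: Sequence[AlignmentRecord], profile: DamageProfile
) -> list[AlignmentRecord]:
    """Downscale qualities of damage-signature mismatches (T-over-C near 5',
    A-over-G near 3', in read orientation).  Returns new records; inputs are
    untouched.
    """
    if np.all(profile.r5 == 0) and np.all(profile.r3 == 0):
        return [replace(a, quals=a.quals.copy()) for a in alignments]
    out: list[AlignmentRecord] = []
    K = profile.K
    for rec in alignments:
        quals = rec.quals.copy()
        if rec.map_class != UNMAPPED and rec.contig_id is not None:
            refr, readr, off5 = _read_oriented(rec)
            off3 = rec.read_len - 1 - off5
            ct = (refr == _dna.C) & (readr == _dna.T) & (off5 < K)
            for j in np.flatnonzero(ct):
                quals[j] = int(round(_rescaled_q(float(quals[j]), float(profile.r5[off5[j]]))))
            ga = (refr == _dna.G) & (readr == _dna.A) & (off3 < K)
            for j in np.flatnonzero(ga):
                quals[j] = int(round(_rescaled_q(float(quals[j]), float(profile.r3[off3[j]]))))
        out.append(replace(rec, quals=quals))
    return out


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

def genotype_likelihoods(
    bases: Sequence[int], quals: Sequence[float], ref: int, alt: int
) -> np.ndarray:
    """Log10 likelihoods of (hom-ref, het, hom-alt) for one sample's pileup.

    P(base b | genotype g) = (c_b/2)(1-e) + ((2-c_b)/2)(e/3), where c_b is
    the number of copies of b in g and e the base's error probability.
    """
    ll = np.zeros(3)
    for g, pair in enumerate(((ref, ref), (ref, alt), (alt, alt))):
        total = 0.0
        for b, q in zip(bases, quals):
            e = phred_error(q)
            c = pair.count(b)
            p = (c / 2.0) * (1.0 - e) + ((2.0 - c) / 2.0) * (e / 3.0)
            total += math.log10(max(p, 1e-300))
        ll[g] = total
    return ll


_GT_STRINGS = ("0/0", "0/1", "1/1")


def call_sites(
    alignments: Sequence[AlignmentRecord],
    cat: LocusCatalog,
    min_base_q: int = 13,
) -> list[SiteCall]:
    """Diploid likelihood calling on pileups of deduplicated alignments.

    A contig position becomes a candidate when at least one non-reference
    base with quality >= min_base_q is piled up; only such bases enter the
    likelihoods.  Genotypes are the flat-prior argmax over the three diploid
    genotypes; site quality is the PHRED-scaled probability that every
    sample is homozygous reference.
    """
    contig_codes = {c.id: _dna.encode(c.seq) for c in cat.contigs}
    samples = sorted({a.sample for a in alignments if a.sample is not None})
    piles: dict[str, dict] = {}
    for rec in alignments:
        if rec.map_class == UNMAPPED or rec.contig_id is None:
            continue
        p = piles.setdefault(rec.contig_id, {"pos": [], "base": [], "qual": [], "samp": []})
        n = rec.end - rec.start
        p["pos"].append(np.arange(rec.start, rec.end))
        p["base"].append(rec.read_codes.astype(np.int64))
        p["qual"].append(rec.quals)
        p["samp"].append(np.full(n, samples.index(rec.sample) if rec.sample in samples else -1))
    calls: list[SiteCall] = []
    for contig_id in sorted(piles):
        ref_codes = contig_codes[contig_id]
        p = piles[contig_id]
        pos = np.concatenate(p["pos"])
        base = np.concatenate(p["base"])
        qual = np.concatenate(p["qual"])
        samp = np.concatenate(p["samp"])
        order = np.argsort(pos, kind="stable")
        pos, base, qual, samp = pos[order], base[order], qual[order], samp[order]
        highq = (qual >= min_base_q) & (base < 4)
        nonref = highq & (base != ref_codes[pos])
        cand = np.unique(pos[nonref])
        starts = np.searchsorted(pos, cand, side="left")
        ends = np.searchsorted(pos, cand, side="right")
        for site_pos, lo, hi in zip(cand, starts, ends):
            b = base[lo:hi]
            q = qual[lo:hi]
            s = samp[lo:hi]
            hq = (q >= min_base_q) & (b < 4)
            ref = int(ref_codes[site_pos])
            alt_counts = np.bincount(b[hq & (b != ref)], minlength=4)
            if alt_counts.sum() == 0:
                continue
            alts = [int(x) for x in np.flatnonzero(alt_counts >= 2)]
            top_alt = int(alt_counts.argmax())
            if top_alt not in alts:
                alts = [top_alt] + alts
            alts.sort(key=lambda a: (-alt_counts[a], a))
            alt = alts[0]
            genotypes: dict[str, str] = {}
            depths: dict[str, int] = {}
            gquals: dict[str, int] = {}
            log_p00_all = 0.0
            for si, sample in enumerate(samples):
                mask = (s == si) & hq
                depths[sample] = int(np.sum(s == si))
                if not np.any(mask):
                    genotypes[sample] = "./."
                    gquals[sample] = 0
                    continue
                ll = genotype_likelihoods(b[mask], q[mask], ref, alt)
                post = 10.0 ** (ll - ll.max())
                post = post / post.sum()
                g = int(np.argmax(ll))
                genotypes[sample] = _GT_STRINGS[g]
                gquals[sample] = int(min(99, round(-10 * math.log10(max(1 - post[g], 1e-10)))))
                log_p00_all += math.log10(max(post[0], 1e-300))
            site_qual = min(3000.0, -10.0 * log_p00_all)
            calls.append(
                SiteCall(
                    contig=contig_id,
                    pos=int(site_pos),
                    ref_base="ACGT"[ref],
                    alt_alleles=["ACGT"[a] for a in alts],
                    genotypes=genotypes,
                    depths=depths,
                    gquals=gquals,
                    site_qual=float(site_qual),
                )
            )
    return calls


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

_GT_CODE = {"0/0": 0, "0/1": 1, "1/1": 2, "./.": MISSING}


def _matrix_from_calls(calls: Sequence[SiteCall], samples: list[str]) -> GenotypeMatrix:
    sites = pd.DataFrame(
        {
            "contig": [c.contig for c in calls],
            "pos": [c.pos for c in calls],
            "ref": [c.ref_base for c in calls],
            "alt": [c.alt for c in calls],
            "qual": [c.site_qual for c in calls],
            "mean_depth": [
                float(np.mean([c.depths.get(s, 0) for s in samples])) if samples else 0.0
                for c in calls
            ],
        }
    )
    codes = np.full((len(samples), len(calls)), MISSING, dtype=np.int8)
    for j, c in enumerate(calls):
        for i, s in enumerate(samples):
            codes[i, j] = _GT_CODE.get(c.genotypes.get(s, "./."), MISSING)
    return GenotypeMatrix(samples, sites, codes)


def filter_sites(
    calls: Sequence[SiteCall],
    config: FilterConfig,
    samples: list[str] | None = None,
) -> tuple[GenotypeMatrix, list[dict]]:
    """Apply the fixed-order cascade; returns the matrix + per-step retention."""
    if samples is None:
        samples = sorted({s for c in calls for s in c.genotypes})
    steps: list[dict] = []
    current = list(calls)

    def record(name: str, kept: list[SiteCall]) -> list[SiteCall]:
        steps.append({"step": name, "n_in": len(current), "n_out": len(kept)})
        return kept

    # 1. indels
    kept = [c for c in current if not (config.drop_indels and c.is_indel)]
    current = record("drop_indels", kept)
    # 2. biallelic
    if config.biallelic_only:
        kept = [c for c in current if len(c.alt_alleles) == 1]
    else:
        kept = current
    current = record("biallelic_only", kept)
    # 3. site quality
    kept = [c for c in current if c.site_qual > config.min_qual]
    current = record("min_qual", kept)
    # 4. genotype depth -> missing (site count unchanged)
    masked: list[SiteCall] = []
    for c in current:
        genotypes = dict(c.genotypes)
        for s in samples:
            if c.depths.get(s, 0) < config.min_depth:
                genotypes[s] = "./."
        masked.append(replace(c, genotypes=genotypes))
    current = record("min_depth_genotypes", masked)
    # 5. presence
    kept = []
    for c in current:
        present = sum(1 for s in samples if c.genotypes.get(s, "./.") != "./.")
        if samples and present / len(samples) >= config.min_presence:
            kept.append(c)
    current = record("min_presence", kept)
    # 6. minor allele count
    kept = []
    for c in current:
        gts = [_GT_CODE.get(c.genotypes.get(s, "./."), MISSING) for s in samples]
        called = [g for g in gts if g != MISSING]
        n_alleles = 2 * len(called)
        alt_count = sum(called)
        mac = min(alt_count, n_alleles - alt_count)
        if config.mac_mode == "fraction":
            ok = mac > n_alleles * config.mac_fraction
        else:
            ok = mac >= config.mac_absolute
        if ok:
            kept.append(c)
    current = record("minor_allele_count", kept)
    # 7. paralogs (high mean depth)
    matrix = _matrix_from_calls(current, samples)
    filtered = paralog_filter(
        matrix, matrix.sites["mean_depth"].to_numpy(), config.paralog_sd_mult
    )
    steps.append(
        {"step": "paralog_depth", "n_in": len(current), "n_out": filtered.shape[1]}
    )
    return filtered, steps


def paralog_filter(
    matrix: GenotypeMatrix, site_depths: np.ndarray, sd_mult: float = 3.0
) -> GenotypeMatrix:
    """Remove sites whose mean depth exceeds mean + sd_mult * SD (population
    SD, strict inequality) — collapsed multi-copy regions pile up reads."""
    site_depths = np.asarray(site_depths, dtype=float)
    if matrix.shape[1] == 0:
        return matrix
    if len(site_depths) != matrix.shape[1]:
        raise ValueError("site_depths length must match site count")
    threshold = site_depths.mean() + sd_mult * site_depths.std()
    return matrix.drop_sites(site_depths <= threshold)


def matrix_fullness(matrix: GenotypeMatrix) -> float:
    """Fraction of non-missing genotype cells."""
    return matrix.fullness()


# ---------------------------------------------------------------------------
# Population-structure check
# ---------------------------------------------------------------------------

def structure_check(
    matrix: GenotypeMatrix,
    k: int = 2,
    labels: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[dict[str, int], float | None]:
    """PCA + k-means assignment check (k=2), with label concordance.

    Missing genotypes are mean-imputed per site before projecting samples
    onto the top two principal axes; concordance is the best agreement with
    the true labels over cluster-label permutations (None without truth).
    """
    if k != 2:
        raise ValueError("only k=2 is supported")
    if matrix.fullness() <= 0.2:
        raise ValueError("matrix too sparse for a structure check (fullness <= 0.2)")
    X = matrix.codes.astype(float)
    X[X == MISSING] = np.nan
    col_means = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_means, inds[1])
    X -= X.mean(axis=0)
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("degenerate genotype matrix: no variance")
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    n_comp = min(2, min(X.shape) - 1) or 1
    proj = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(proj)
    assignments = {s: int(g) for s, g in zip(matrix.samples, km.labels_)}
    concordance = None
    if labels is not None:
        truth = np.array([labels[s] for s in matrix.samples])
        pred = km.labels_
        concordance = max(
            float(np.mean(pred == truth)), float(np.mean((1 - pred) == truth))
        )
    return assignments, concordance


# ---------------------------------------------------------------------------
# ddRAD dropout comparator
# ---------------------------------------------------------------------------

def ddrad_dropout_compare(
    cohort: SimulatedCohort,
    enzymes: tuple[Enzyme, Enzyme] = (SBFI, MSEI),
    size_window: tuple[int, int] = (130, 190),
    capture_matrix: GenotypeMatrix | None = None,
) -> dict[str, float]:
    """In-silico ddRAD locus presence vs realized capture-matrix fullness.

    A ddRAD locus (ancestor SbfI-MseI fragment within the size window) is
    present on a haplotype iff both flanking recognition sites are intact
    there; an individual scores the locus only when both haplotypes retain
    it (homozygous presence accounting — one lost allele already biases
    genotypes).  ``ddrad_fullness`` is the mean over individuals x loci.
    """
    from .digest import select_probes

    genome = [cohort.ancestor]
    fragments = double_digest(genome, *enzymes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        loci = select_probes(fragments, genome, size_window)
    enz_by_name = {e.name: e for e in enzymes}
    rec_codes = {e.name: _dna.encode(e.recognition) for e in enzymes}

    present = []
    for probe in loci.probes:
        frag_sites = []
        for end_key, boundary in (("left_end", probe.meta["start"]), ("right_end", probe.meta["end"])):
            enz = enz_by_name[probe.meta[end_key]]
            frag_sites.append((enz.name, boundary - enz.cut_offset))
        for sample in cohort.samples:
            ok_both = True
            for h in (0, 1):
                hap = cohort.haplotypes[sample][h]
                for name, site_start in frag_sites:
                    rec = rec_codes[name]
                    if not np.array_equal(hap[site_start : site_start + len(rec)], rec):
                        ok_both = False
                        break
                if not ok_both:
                    break
            present.append(1.0 if ok_both else 0.0)
    ddrad_fullness = float(np.mean(present)) if present else 0.0
    out = {"ddrad_fullness": ddrad_fullness, "n_loci": float(len(loci.probes))}
    if capture_matrix is not None:
        out["capture_fullness"] = matrix_fullness(capture_matrix)
    return out


# ---------------------------------------------------------------------------
# VCF emission (the only 1-based surface of the package)
# ---------------------------------------------------------------------------

def write_vcf(calls: Sequence[SiteCall], samples: list[str]) -> str:
    lines = [
        "##fileformat=VCFv4.2",
        "##source=radcap",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
    ]
    for c in calls:
        cells = [
            c.contig,
            str(c.pos + 1),
            ".",
            c.ref_base,
            ",".join(c.alt_alleles) or ".",
            f"{c.site_qual:.1f}",
            "PASS",
            ".",
            "GT:DP:GQ",
        ]
        for s in samples:
            cells.append(
                f"{c.genotypes.get(s, './.')}:{c.depths.get(s, 0)}:{c.gquals.get(s, 0)}"
            )
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"
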