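"""variants: damage profiles, rescaling, calling, filters, summaries."""
import math

import numpy as np
import pandas as pd
import pytest

from radcap import _dna, digest, libsim, popsim, variants
from radcap.align import AlignmentRecord, map_reads
from radcap.catalog import LocusCatalog
from radcap.seqio import SequenceRecord
from radcap.variants import (
    DamageProfile,
    FilterConfig,
    GenotypeMatrix,
    SiteCall,
    call_sites,
    ddrad_dropout_compare,
    estimate_damage_profile,
    filter_sites,
    matrix_fullness,
    paralog_filter,
    rescale_qualities,
    structure_check,
    write_vcf,
)

from .conftest import random_seq


# ---------------------------------------------------------------------------
# helpers: fabricate single-base pileup records
# ---------------------------------------------------------------------------

def one_base_record(contig_id, pos, base, qual, sample, ref_base, rid):
    return AlignmentRecord(
        read_id=rid,
        sample=sample,
        contig_id=contig_id,
        start=pos,
        end=pos + 1,
        strand="+",
        read_codes=_dna.encode(base),
        ref_codes=_dna.encode(ref_base),
        quals=np.array([qual], dtype=np.int64),
        score=1,
        map_class="unique",
        read_len=50,  # long enough that offset 0 is the only terminal column
        clip5=20,  # keep the base away from damage-profile terminal windows
    )


def oracle_genotype(bases, quals, ref, alt):
    """Independent brute-force grid over the three diploid genotypes."""
    lls = []
    for pair in ((ref, ref), (ref, alt), (alt, alt)):
        ll = 0.0
        for b, q in zip(bases, quals):
            e = 10.0 ** (-q / 10.0)
            c = (pair[0] == b) + (pair[1] == b)
            ll += math.log10((c / 2) * (1 - e) + ((2 - c) / 2) * (e / 3))
        lls.append(ll)
    return int(np.argmax(lls)), lls


@pytest.fixture(scope="module")
def simple_catalog():
    rng = np.random.default_rng(101)
    return LocusCatalog([SequenceRecord("c0", random_seq(rng, 300))], "rad_ref", [1.0])


# ---------------------------------------------------------------------------
# damage profile + rescaling
# ---------------------------------------------------------------------------

def _simulate_alignments(damage, seed, n_mol=4000, seq_error=0.001):
    rng = np.random.default_rng(seed)
    contig = SequenceRecord("c0", random_seq(rng, 500))
    cat = LocusCatalog([contig], "rad_ref", [1.0])
    cfg = libsim.LibraryConfig(
        coverage=n_mol * 100 / 500, frag_mean=100, frag_sd=15, seq_error=seq_error,
        damage=damage,
    )
    ms = libsim.fragment_molecules([_dna.encode(contig.seq)], cfg, seed=seed + 1, sample="s1")
    if damage is not None:
        libsim.damage_molecules(ms, damage, seed=seed + 2)
    reads = libsim.sequence_reads(ms, cfg, seed=seed + 3)
    return map_reads(reads, cat), cat


class TestDamageProfile:
    def test_undamaged_profile_near_zero(self):
        recs, cat = _simulate_alignments(None, seed=110)
        prof = estimate_damage_profile(recs, cat)
        # baseline-corrected excess should be within noise of zero
        assert prof.r5.max() < 0.01
        assert prof.r3.max() < 0.01

    def test_generator_self_consistency(self):
        dm = libsim.DamageModel(p_max=0.3, rho=0.5)
        recs, cat = _simulate_alignments(dm, seed=120)
        prof = estimate_damage_profile(recs, cat)
        assert abs(prof.r5[0] - 0.3) < 0.05
        assert abs(prof.r5[1] - 0.15) < 0.05

    def test_strand_symmetry(self):
        dm = libsim.DamageModel(p_max=0.3, rho=0.5)
        recs, cat = _simulate_alignments(dm, seed=130)
        prof = estimate_damage_profile(recs, cat)
        assert abs(prof.r5[0] - prof.r3[0]) < 0.05
        assert abs(prof.r5[1] - prof.r3[1]) < 0.05

    def test_validation(self):
        with pytest.raises(ValueError):
            DamageProfile(np.zeros(5), np.zeros(12), K=12)


class TestRescaleQualities:
    def test_zero_profile_identity(self, simple_catalog):
        rec = one_base_record("c0", 10, "T", 40, "s1", "C", "r1/1")
        (out,) = rescale_qualities([rec], DamageProfile.zeros())
        assert out.quals.tolist() == [40]

    def test_closed_form_value(self):
        # r=0.3, Q=40: Q' = -10*log10(0.3 + 1e-4 - 0.3*1e-4) ~ 5.2
        rec = AlignmentRecord(
            read_id="r/1", sample="s1", contig_id="c0", start=0, end=1, strand="+",
            read_codes=_dna.encode("T"), ref_codes=_dna.encode("C"),
            quals=np.array([40]), score=1, map_class="unique", clip5=0, read_len=50,
        )
        prof = DamageProfile.zeros()
        prof.r5[0] = 0.3
        (out,) = rescale_qualities([rec], prof)
        expect = -10 * math.log10(0.3 + 1e-4 - 0.3 * 1e-4)
        assert out.quals[0] == round(expect)
        assert abs(expect - 5.2) < 0.1

    def test_non_signature_mismatch_untouched(self):
        rec = AlignmentRecord(
            read_id="r/1", sample="s1", contig_id="c0", start=0, end=1, strand="+",
            read_codes=_dna.encode("A"), ref_codes=_dna.encode("C"),
            quals=np.array([40]), score=1, map_class="unique", clip5=0, read_len=50,
        )
        prof = DamageProfile.zeros()
        prof.r5[0] = 0.3
        (out,) = rescale_qualities([rec], prof)
        assert out.quals[0] == 40

    def test_never_raises_quality(self):
        rec = AlignmentRecord(
            read_id="r/1", sample="s1", contig_id="c0", start=0, end=1, strand="+",
            read_codes=_dna.encode("T"), ref_codes=_dna.encode("C"),
            quals=np.array([3]), score=1, map_class="unique", clip5=0, read_len=50,
        )
        prof = DamageProfile.zeros()
        prof.r5[0] = 0.01
        (out,) = rescale_qualities([rec], prof)
        assert out.quals[0] <= 3

    def test_inputs_untouched(self):
        rec = AlignmentRecord(
            read_id="r/1", sample="s1", contig_id="c0", start=0, end=1, strand="+",
            read_codes=_dna.encode("T"), ref_codes=_dna.encode("C"),
            quals=np.array([40]), score=1, map_class="unique", clip5=0, read_len=50,
        )
        prof = DamageProfile.zeros()
        prof.r5[0] = 0.3
        rescale_qualities([rec], prof)
        assert rec.quals[0] == 40


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

class TestCallSites:
    def test_all_ref_position_absent(self, simple_catalog):
        ref = simple_catalog.contigs[0].seq[5]
        recs = [
            one_base_record("c0", 5, ref, 35, "s1", ref, f"r{i}/1") for i in range(10)
        ]
        assert call_sites(recs, simple_catalog) == []

    def test_balanced_het_high_qual(self, simple_catalog):
        ref = simple_catalog.contigs[0].seq[7]
        alt = "A" if ref != "A" else "G"
        recs = [
            one_base_record("c0", 7, ref, 30, "s1", ref, f"r{i}/1") for i in range(10)
        ] + [
            one_base_record("c0", 7, alt, 30, "s1", ref, f"a{i}/1") for i in range(10)
        ]
        (call,) = call_sites(recs, simple_catalog)
        assert call.genotypes["s1"] == "0/1"
        assert call.site_qual > 30
        assert call.alt == alt
        assert call.depths["s1"] == 20

    def test_min_base_q_excludes_low_quality_evidence(self, simple_catalog):
        ref = simple_catalog.contigs[0].seq[9]
        alt = "A" if ref != "A" else "G"
        recs = [
            one_base_record("c0", 9, alt, 5, "s1", ref, f"r{i}/1") for i in range(5)
        ]
        assert call_sites(recs, simple_catalog, min_base_q=13) == []

    def test_brute_force_oracle_on_random_pileups(self, simple_catalog):
        rng = np.random.default_rng(140)
        contig_seq = simple_catalog.contigs[0].seq
        for trial in range(200):
            pos = int(rng.integers(0, 300))
            ref = contig_seq[pos]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            n = int(rng.integers(1, 13))
            bases = [ref if rng.random() < 0.5 else alt for _ in range(n)]
            quals = [int(rng.integers(14, 41)) for _ in range(n)]
            if alt not in bases:
                continue
            recs = [
                one_base_record("c0", pos, b, q, "s1", ref, f"t{trial}r{i}/1")
                for i, (b, q) in enumerate(zip(bases, quals))
            ]
            calls = call_sites(recs, simple_catalog)
            got = calls[0].genotypes["s1"] if calls else "0/0"
            g_or, _ = oracle_genotype(bases, quals, ref, alt)
            assert got == ("0/0", "0/1", "1/1")[g_or], (bases, quals, ref, alt)

    def test_multi_sample_independent_genotypes(self, simple_catalog):
        ref = simple_catalog.contigs[0].seq[20]
        alt = "C" if ref != "C" else "T"
        recs = [
            one_base_record("c0", 20, alt, 35, "s1", ref, f"r{i}/1") for i in range(8)
        ] + [
            one_base_record("c0", 20, ref, 35, "s2", ref, f"q{i}/1") for i in range(8)
        ]
        (call,) = call_sites(recs, simple_catalog)
        assert call.genotypes["s1"] == "1/1"
        assert call.genotypes["s2"] == "0/0"

    def test_triallelic_alt_listing(self, simple_catalog):
        ref = simple_catalog.contigs[0].seq[30]
        others = [b for b in "ACGT" if b != ref]
        recs = [
            one_base_record("c0", 30, others[0], 35, "s1", ref, f"r{i}/1")
            for i in range(4)
        ] + [
            one_base_record("c0", 30, others[1], 35, "s1", ref, f"q{i}/1")
            for i in range(3)
        ]
        (call,) = call_sites(recs, simple_catalog)
        assert len(call.alt_alleles) == 2
        assert call.alt == others[0]  # most frequent first


# ---------------------------------------------------------------------------
# filter cascade
# ---------------------------------------------------------------------------

SAMPLES = ["s1", "s2", "s3", "s4"]


def make_call(pos, genotypes, depths=None, qual=50.0, alts=("T",), is_indel=False):
    gts = dict(zip(SAMPLES, genotypes))
    dps = dict(zip(SAMPLES, depths or [10, 10, 10, 10]))
    return SiteCall(
        contig="c0",
        pos=pos,
        ref_base="C",
        alt_alleles=list(alts),
        genotypes=gts,
        depths=dps,
        gquals={s: 40 for s in SAMPLES},
        site_qual=qual,
        is_indel=is_indel,
    )


class TestFilterCascade:
    def toy_table(self):
        return [
            make_call(0, ["0/1", "0/1", "0/0", "0/0"], is_indel=True),  # indel
            make_call(1, ["0/1", "1/1", "0/0", "0/0"], is_indel=True),  # indel
            make_call(2, ["0/1", "0/1", "0/0", "0/0"], alts=("T", "G")),  # triallelic
            make_call(3, ["0/1", "0/1", "0/0", "0/0"], qual=25.0),  # low qual
            make_call(4, ["0/1", "0/1", "0/0", "0/0"], depths=[10, 4, 5, 5]),  # low depth
            make_call(5, ["0/1", "0/0", "0/0", "0/0"]),  # MAC 1 of 8 -> fails
            make_call(6, ["0/1", "0/1", "0/0", "0/0"]),  # passes (MAC 2 > 8/6)
            make_call(7, ["1/1", "0/1", "0/1", "0/0"]),  # passes (MAC 4)
        ]

    def test_hand_enumerated_counts(self):
        matrix, steps = filter_sites(self.toy_table(), FilterConfig(), SAMPLES)
        got = [(s["step"], s["n_in"], s["n_out"]) for s in steps]
        assert got == [
            ("drop_indels", 8, 6),
            ("biallelic_only", 6, 5),
            ("min_qual", 5, 4),
            ("min_depth_genotypes", 4, 4),
            ("min_presence", 4, 3),
            ("minor_allele_count", 3, 2),
            ("paralog_depth", 2, 2),
        ]
        assert matrix.shape == (4, 2)
        assert list(matrix.sites["pos"]) == [6, 7]

    def test_all_passing_unchanged(self):
        calls = [
            make_call(i, ["0/1", "0/1", "0/0", "0/0"]) for i in range(5)
        ]
        matrix, steps = filter_sites(calls, FilterConfig(), SAMPLES)
        assert matrix.shape == (4, 5)
        assert all(s["n_in"] == s["n_out"] for s in steps)

    def test_indel_removed_first(self):
        calls = [make_call(0, ["0/1", "0/1", "0/0", "0/0"], is_indel=True)]
        matrix, steps = filter_sites(calls, FilterConfig(), SAMPLES)
        assert steps[0]["n_out"] == 0
        assert matrix.shape[1] == 0

    def test_absolute_mac_mode(self):
        calls = [make_call(0, ["0/1", "0/1", "0/1", "0/0"])]  # MAC 3
        cfg = FilterConfig(mac_mode="absolute")  # needs >= 6
        matrix, _ = filter_sites(calls, cfg, SAMPLES)
        assert matrix.shape[1] == 0
        cfg2 = FilterConfig(mac_mode="fraction")  # 3 > 8/6 passes
        matrix2, _ = filter_sites(calls, cfg2, SAMPLES)
        assert matrix2.shape[1] == 1

    def test_monotone_shrinkage(self):
        _, steps = filter_sites(self.toy_table(), FilterConfig(), SAMPLES)
        for s in steps:
            assert s["n_out"] <= s["n_in"]
        for a, b in zip(steps, steps[1:]):
            assert b["n_in"] == a["n_out"]


class TestParalogFilter:
    def _matrix(self, depths):
        n = len(depths)
        sites = pd.DataFrame(
            {"contig": ["c"] * n, "pos": range(n), "ref": ["C"] * n,
             "alt": ["T"] * n, "qual": [50.0] * n, "mean_depth": depths}
        )
        codes = np.ones((2, n), dtype=np.int8)
        return GenotypeMatrix(["a", "b"], sites, codes)

    def test_uniform_depths_nothing_removed(self):
        m = paralog_filter(self._matrix([10] * 12), np.array([10.0] * 12))
        assert m.shape[1] == 12

    def test_n20_outlier_removed(self):
        depths = np.array([10.0] * 19 + [100.0])
        m = paralog_filter(self._matrix(depths), depths)
        # threshold = 14.5 + 3*19.615 ~ 73.3 < 100
        assert m.shape[1] == 19
        assert 100.0 not in list(m.sites["mean_depth"])

    def test_n10_boundary_identity_keeps_site(self):
        # 9 sites at 10, 1 at 100: mean+3SD == 100 exactly; strict '>' keeps it
        depths = np.array([10.0] * 9 + [100.0])
        assert depths.mean() + 3 * depths.std() == pytest.approx(100.0)
        m = paralog_filter(self._matrix(depths), depths)
        assert m.shape[1] == 10


class TestMatrixFullness:
    def _matrix(self, codes):
        codes = np.asarray(codes, dtype=np.int8)
        n = codes.shape[1]
        sites = pd.DataFrame(
            {"contig": ["c"] * n, "pos": range(n), "ref": ["C"] * n,
             "alt": ["T"] * n, "qual": [50.0] * n, "mean_depth": [10.0] * n}
        )
        return GenotypeMatrix([f"s{i}" for i in range(codes.shape[0])], sites, codes)

    def test_full(self):
        assert matrix_fullness(self._matrix([[0, 1], [2, 1]])) == 1.0

    def test_half(self):
        assert matrix_fullness(self._matrix([[0, -1], [-1, 1]])) == 0.5

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            matrix_fullness(self._matrix(np.zeros((2, 0))))

    def test_seeded_masking_rate(self, rng):
        codes = rng.integers(0, 3, size=(10, 200)).astype(np.int8)
        mask = rng.random((10, 200)) < 0.3
        codes[mask] = -1
        got = matrix_fullness(self._matrix(codes))
        assert got == pytest.approx(1 - mask.mean())


class TestStructureCheck:
    def _matrix_from_codes(self, codes, samples):
        codes = np.asarray(codes, dtype=np.int8)
        n = codes.shape[1]
        sites = pd.DataFrame(
            {"contig": ["c"] * n, "pos": range(n), "ref": ["C"] * n,
             "alt": ["T"] * n, "qual": [50.0] * n, "mean_depth": [10.0] * n}
        )
        return GenotypeMatrix(samples, sites, codes)

    def test_fully_differentiated_concordance_1(self):
        samples = [f"s{i}" for i in range(8)]
        labels = {s: int(i >= 4) for i, s in enumerate(samples)}
        codes = np.zeros((8, 30), dtype=np.int8)
        codes[4:, :] = 2
        m = self._matrix_from_codes(codes, samples)
        _, conc = structure_check(m, 2, labels, seed=0)
        assert conc == 1.0

    def test_null_concordance_near_chance(self):
        rng = np.random.default_rng(150)
        samples = [f"s{i}" for i in range(8)]
        labels = {s: int(i >= 4) for i, s in enumerate(samples)}
        concs = []
        for seed in range(20):
            codes = rng.integers(0, 3, size=(8, 60)).astype(np.int8)
            m = self._matrix_from_codes(codes, samples)
            _, conc = structure_check(m, 2, labels, seed=seed)
            concs.append(conc)
        assert np.mean(concs) <= 0.75  # chance-level on panmictic data
        assert min(concs) < 1.0

    def test_degenerate_matrix_errors(self):
        samples = ["a", "b", "c"]
        codes = np.ones((3, 10), dtype=np.int8)
        m = self._matrix_from_codes(codes, samples)
        with pytest.raises(ValueError):
            structure_check(m, 2, None, seed=0)

    def test_k_not_2_rejected(self):
        samples = ["a", "b"]
        m = self._matrix_from_codes(np.zeros((2, 3), dtype=np.int8), samples)
        with pytest.raises(ValueError):
            structure_check(m, 3)


# ---------------------------------------------------------------------------
# ddRAD dropout comparator
# ---------------------------------------------------------------------------

class TestDdradDropout:
    def _cohort(self, mu, seed=160):
        anc = popsim.simulate_ancestor(80_000, 0.45, seed=seed)
        anc, _ = popsim.embed_motifs(anc, digest.SBFI.recognition, 15, seed=seed + 1)
        model = popsim.PopulationModel(
            n_pops=2, n_per_pop=3, theta_within=0.0, d_between=0.0
        )
        cohort = popsim.simulate_cohort(anc, model, seed=seed + 2)
        genome = [cohort.ancestor]
        frags = digest.double_digest(genome)
        loci = [
            digest.Fragment(p.meta["chrom"], p.meta["start"], p.meta["end"],
                            p.meta["left_end"], p.meta["right_end"])
            for p in digest.select_probes(frags, genome, (80, 400)).probes
        ]
        if mu > 0:
            popsim.plant_site_disruptions(cohort, loci, mu, seed=seed + 3)
        return cohort

    def test_no_polymorphism_fullness_1(self):
        cohort = self._cohort(mu=0.0)
        out = ddrad_dropout_compare(cohort, size_window=(80, 400))
        assert out["ddrad_fullness"] == 1.0
        assert out["n_loci"] > 0

    def test_closed_form_expectation(self):
        mu = 0.3
        fulls = []
        n_trials = []
        for seed in (170, 180, 190):
            cohort = self._cohort(mu=mu, seed=seed)
            out = ddrad_dropout_compare(cohort, size_window=(80, 400))
            fulls.append(out["ddrad_fullness"])
            n_trials.append(out["n_loci"] * len(cohort.samples))
        expect = (1 - mu) ** 2  # homozygous presence accounting
        n = sum(n_trials)
        pooled = np.average(fulls, weights=n_trials)
        sd = math.sqrt(expect * (1 - expect) / n)
        assert abs(pooled - expect) <= 3 * sd


def test_write_vcf_shape(simple_catalog):
    ref = simple_catalog.contigs[0].seq[7]
    alt = "A" if ref != "A" else "G"
    recs = [
        one_base_record("c0", 7, ref, 30, "s1", ref, f"r{i}/1") for i in range(6)
    ] + [one_base_record("c0", 7, alt, 30, "s1", ref, f"a{i}/1") for i in range(6)]
    calls = call_sites(recs, simple_catalog)
    text = write_vcf(calls, ["s1"])
    lines = text.strip().splitlines()
    assert lines[0] == "##fileformat=VCFv4.2"
    body = [l for l in lines if not l.startswith("#")]
    assert len(body) == 1
    fields = body[0].split("\t")
    assert fields[1] == "8"  # 1-based position
    assert fields[3] == ref and fields[4] == alt
    assert fields[9].startswith("0/1:")
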