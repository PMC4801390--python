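"""catalog: dedupe, greedy clustering, rad-ref build, extension, assembly."""
import numpy as np
import pytest

from radcap import catalog
from radcap.catalog import (
    AMONG_GRID,
    WITHIN_GRID,
    LocusCatalog,
    assemble_denovo,
    build_rad_ref,
    dedupe_exact,
    extend_catalog,
    greedy_cluster,
    optimize_threshold,
)
from radcap.seqio import SequenceRecord, revcomp

from .conftest import random_seq


def mutate(rng, seq: str, rate: float) -> str:
    out = list(seq)
    for i in np.flatnonzero(rng.random(len(seq)) < rate):
        out[i] = "ACGT"[(("ACGT".index(out[i])) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def planted_loci(rng, n_loci=100, copies=5, error=0.01, length=150):
    loci = [random_seq(rng, length) for _ in range(n_loci)]
    reads = []
    for locus in loci:
        for _ in range(copies):
            reads.append(mutate(rng, locus, error))
    order = rng.permutation(len(reads))
    return loci, [reads[i] for i in order]


class TestDedupe:
    def test_simple(self):
        out = dedupe_exact(["AAA", "AAA", "CCC"])
        assert [(m.seq, c) for m, c in out] == [("AAA", 2), ("CCC", 1)]
        assert out[0][0].weight == 2

    def test_all_distinct_identity(self):
        out = dedupe_exact(["AAA", "CCC", "GGG"])
        assert [c for _, c in out] == [1, 1, 1]

    def test_truth_multiplicities(self, rng):
        base = [random_seq(rng, 60) for _ in range(2000)]
        mult = rng.integers(1, 6, size=2000)
        seqs = []
        for s, m in zip(base, mult):
            seqs.extend([s] * int(m))
        truth = {}
        for s, m in zip(base, mult):
            truth[s] = truth.get(s, 0) + int(m)  # collisions accumulate
        out = dedupe_exact(seqs)
        assert {m.seq: c for m, c in out} == truth


class TestGreedyCluster:
    def test_identical_sequences_one_cluster(self):
        clusters = greedy_cluster(["ACGTACGTAC"] * 5, 0.91)
        assert len(clusters) == 1
        assert clusters[0].size == 5
        assert clusters[0].consensus() == "ACGTACGTAC"

    def test_below_threshold_two_clusters(self, rng):
        a = random_seq(rng, 100)
        b = mutate(rng, a, 0.4)  # identity ~0.6
        clusters = greedy_cluster([a, b], 0.91)
        assert len(clusters) == 2

    def test_planted_100_loci_within_5pct(self, rng):
        _, reads = planted_loci(rng, n_loci=100, copies=5, error=0.01)
        clusters = greedy_cluster(reads, 0.91)
        assert abs(len(clusters) - 100) <= 5

    def test_t1_on_deduped_equals_exact_grouping(self, rng):
        seqs = [random_seq(rng, 50) for _ in range(30)]
        seqs = seqs + seqs[:10]
        deduped = [m for m, _ in dedupe_exact(seqs)]
        clusters = greedy_cluster(deduped, 1.0)
        assert len(clusters) == len(set(s for s in seqs))

    def test_consensus_majority_fixes_errors(self, rng):
        locus = random_seq(rng, 120)
        reads = [mutate(rng, locus, 0.01) for _ in range(9)]
        (cluster,) = greedy_cluster(reads, 0.85)
        consensus = cluster.consensus()
        mismatches = sum(a != b for a, b in zip(consensus, locus))
        assert mismatches <= 1  # ties can retain a centroid error


class TestOptimizeThreshold:
    def test_tie_break_takes_max_threshold(self):
        scan = optimize_threshold(["ACGTACGTACGTACGT"] * 5, WITHIN_GRID)
        assert scan.n_clusters_ge2 == [1] * len(WITHIN_GRID)
        assert scan.chosen == max(WITHIN_GRID)

    def test_singletons_degenerate(self, rng):
        seqs = [random_seq(rng, 80) for _ in range(20)]
        with pytest.warns(UserWarning):
            scan = optimize_threshold(seqs, AMONG_GRID)
        assert scan.n_clusters_ge2 == [0] * len(AMONG_GRID)
        assert scan.chosen == max(AMONG_GRID)

    def test_recovers_noisy_loci(self, rng):
        _, reads = planted_loci(rng, n_loci=50, copies=6, error=0.08, length=150)
        scan = optimize_threshold(reads, WITHIN_GRID)
        clusters = greedy_cluster(reads, scan.chosen)
        n_covered = sum(1 for c in clusters if c.size >= 2)
        assert abs(n_covered - 50) <= 5  # within 10% of the planted count

    def test_scan_tsv(self):
        scan = optimize_threshold(["ACGTACGTACGTACGT"] * 3, (0.5, 0.9))
        assert scan.to_tsv().startswith("t\t")


class TestBuildRadRef:
    def test_single_clean_locus(self):
        locus = "ACGT" * 40
        cat = build_rad_ref({"s1": [locus] * 4})
        assert len(cat) == 1
        assert cat.contigs[0].seq == locus
        assert cat.method == "rad_ref"

    def test_two_samples_shared_loci(self, rng):
        loci = [random_seq(rng, 150) for _ in range(100)]
        per_sample = {}
        for s in ("s1", "s2"):
            reads = []
            for locus in loci:
                variant = mutate(rng, locus, 0.03)  # <=5% divergence between samples
                reads.extend(mutate(rng, variant, 0.005) for _ in range(4))
            per_sample[s] = reads
        cat = build_rad_ref(per_sample, t_within=0.91, t_among=0.71)
        assert abs(len(cat) - 100) <= 5

    def test_t_among_1_oversplits(self, rng):
        loci = [random_seq(rng, 150) for _ in range(40)]
        per_sample = {}
        for s in ("s1", "s2"):
            per_sample[s] = [
                m
                for locus in loci
                for m in [mutate(rng, locus, 0.02)] * 3  # distinct alleles per sample
            ]
        merged = build_rad_ref(per_sample, 0.91, 0.71)
        split = build_rad_ref(per_sample, 0.91, 1.0)
        assert len(split) >= len(merged)
        assert len(split) == pytest.approx(80, abs=6)

    def test_two_iteration_merges_what_single_level_splits(self, rng):
        """3% between-sample divergence: t_among=0.71 merges homologs."""
        loci = [random_seq(rng, 150) for _ in range(60)]
        per_sample = {}
        for s in ("s1", "s2"):
            allele = {locus: mutate(rng, locus, 0.03) for locus in loci}
            per_sample[s] = [
                mutate(rng, allele[locus], 0.005) for locus in loci for _ in range(4)
            ]
        cat = build_rad_ref(per_sample, 0.91, 0.71)
        assert abs(len(cat) - 60) <= 3
        # single-level high-threshold clustering of the pool oversplits
        pooled = per_sample["s1"] + per_sample["s2"]
        single = greedy_cluster(pooled, 0.98)
        assert len(single) > len(cat)

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            cat = build_rad_ref({})
        assert len(cat) == 0


class TestExtendCatalog:
    def _tiling_reads(self, source, read_len=60, step=10):
        return [
            source[i : i + read_len]
            for i in range(0, len(source) - read_len + 1, step)
        ] * 2  # duplicate so every vote has support >= 2

    def test_no_reads_no_trim_unchanged(self):
        cat = LocusCatalog([SequenceRecord("c", "ACGT" * 30)], "rad_ref", [1])
        out = extend_catalog(cat, [], cycles=5, trim_bp=0)
        assert out.contigs[0].seq == "ACGT" * 30

    def test_overlap_29_no_extension(self, rng):
        source = random_seq(rng, 300)
        contig = source[100:200]
        cat = LocusCatalog([SequenceRecord("c", contig)], "rad_ref", [1])
        # reads overlap the right end by exactly 29 bases and extend beyond
        reads = [source[171:260]] * 3  # 29 bases inside [100,200)
        out = extend_catalog(cat, reads, cycles=3, min_overlap=30, trim_bp=0)
        assert out.contigs[0].seq == contig

    def test_overlap_30_extends(self, rng):
        source = random_seq(rng, 300)
        contig = source[100:200]
        cat = LocusCatalog([SequenceRecord("c", contig)], "rad_ref", [1])
        reads = [source[170:260]] * 3  # 30 bases inside
        out = extend_catalog(cat, reads, cycles=1, min_overlap=30, trim_bp=0)
        assert len(out.contigs[0].seq) > len(contig)
        assert out.contigs[0].seq in source

    def test_tiling_reads_reach_flanks(self, rng):
        source = random_seq(rng, 300)
        contig = source[100:200]
        cat = LocusCatalog([SequenceRecord("c", contig)], "rad_ref", [1])
        reads = self._tiling_reads(source)
        out = extend_catalog(
            cat, reads, cycles=30, min_overlap=30, min_identity=1.0, trim_bp=0
        )
        extended = out.contigs[0].seq
        assert contig in extended  # exact substring property
        assert len(extended) > 250  # grew toward both flanks
        assert extended in source

    def test_trim_and_drop(self, rng):
        short = SequenceRecord("short", random_seq(rng, 100))
        long = SequenceRecord("long", random_seq(rng, 200))
        cat = LocusCatalog([short, long], "rad_ref", [1, 1])
        out = extend_catalog(cat, [], cycles=0, trim_bp=60)
        assert [c.id for c in out.contigs] == ["long"]
        assert out.contigs[0].seq == long.seq[60:140]

    def test_method_label(self):
        cat = LocusCatalog([SequenceRecord("c", "ACGT" * 50)], "rad_ref", [1])
        assert extend_catalog(cat, [], cycles=0, trim_bp=0).method == "rad_ref_ext"


class TestAssembleDenovo:
    def _reads_for(self, source, read_len=60, step=6):
        starts = list(range(0, len(source) - read_len + 1, step))
        if starts[-1] != len(source) - read_len:
            starts.append(len(source) - read_len)  # cover the tail exactly
        reads = [source[i : i + read_len] for i in starts]
        return reads * 2  # 10x-ish with min kmer coverage >= 2 everywhere

    def test_single_locus_reconstructed(self, rng):
        locus = random_seq(rng, 500)
        cat = assemble_denovo(self._reads_for(locus), k=31, min_kmer_cov=2)
        assert len(cat) == 1
        assert cat.contigs[0].seq in (locus, revcomp(locus))

    def test_two_loci_reconstructed(self, rng):
        l1, l2 = random_seq(rng, 400), random_seq(rng, 450)
        reads = self._reads_for(l1) + self._reads_for(l2)
        cat = assemble_denovo(reads, k=31, min_kmer_cov=2)
        assert len(cat) == 2
        got = {c.seq for c in cat.contigs}
        for locus in (l1, l2):
            assert locus in got or revcomp(locus) in got

    def test_empty_input(self):
        assert len(assemble_denovo([], k=31)) == 0

    def test_low_coverage_kmers_dropped(self, rng):
        locus = random_seq(rng, 300)
        reads = [locus[i : i + 60] for i in range(0, 241, 60)]  # non-overlapping
        cat = assemble_denovo(reads, k=31, min_kmer_cov=2)
        assert len(cat) == 0

    def test_k_validation(self):
        with pytest.raises(ValueError):
            assemble_denovo([], k=30)
        with pytest.raises(ValueError):
            assemble_denovo([], k=13)

    def test_method_label(self, rng):
        locus = random_seq(rng, 200)
        cat = assemble_denovo(self._reads_for(locus), k=31, min_kmer_cov=2)
        assert cat.method == "assembly_ref"
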