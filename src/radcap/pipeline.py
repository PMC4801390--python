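"""End-to-end orchestration: cohort -> probes -> libraries -> capture ->
catalog -> mapping -> damage rescaling -> calling -> filtering -> summaries.

This is the programmatic backbone of the CLI ``pipeline`` subcommand and of
the whole-system tests: everything runs on synthetic cohorts whose truth
tables allow exact sensitivity/FDR accounting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import align as align_mod
from . import capture as capture_mod
from . import catalog as catalog_mod
from . import libsim, popsim, variants
from .digest import MSEI, SBFI, ProbeSet, double_digest, select_probes, union_probe_sets
from .libsim import LibraryConfig, MoleculeSet
from .seqio import QualityRead


@dataclass
class PipelineResult:
    cohort: popsim.SimulatedCohort
    probes: ProbeSet
    catalog: catalog_mod.LocusCatalog
    alignments: list
    capture_reports: dict[str, dict]
    mapping: dict[str, dict[str, float]]
    damage_profiles: dict[str, variants.DamageProfile]
    calls: list[variants.SiteCall]
    calls_unrescaled: list[variants.SiteCall]
    matrix: variants.GenotypeMatrix
    filter_steps: list[dict]
    structure: tuple[dict[str, int], float | None] | None
    metrics: dict = field(default_factory=dict)


def make_probes(
    cohort: popsim.SimulatedCohort,
    probe_samples: list[str],
    size_window: tuple[int, int] = (130, 190),
) -> dict[str, ProbeSet]:
    """Digest each probe-source individual (both haplotypes) into a probe set.

    Mirrors pooling fresh individuals for probe generation; per-sample sets
    are kept separate so the two-iteration catalog build sees sample
    structure, and can be pooled with :func:`union_probe_sets`.
    """
    out: dict[str, ProbeSet] = {}
    for sample in probe_samples:
        per_hap = []
        for h in (0, 1):
            genome = [cohort.haplotype_record(sample, h)]
            frags = double_digest(genome, SBFI, MSEI)
            per_hap.append(select_probes(frags, genome, size_window))
        out[sample] = union_probe_sets(per_hap)
    return out


def probe_reads(
    probe_sets: dict[str, ProbeSet], copies: int = 3, seq_error: float = 0.002, seed: int = 0
) -> dict[str, list[QualityRead]]:
    """Simulate sequencing of the probe-precursor library (single-end,
    full-length probe reads with i.i.d. substitution errors)."""
    rng = np.random.default_rng(seed)
    out: dict[str, list[QualityRead]] = {}
    for sample, ps in probe_sets.items():
        reads: list[QualityRead] = []
        for p_i, probe in enumerate(ps.probes):
            from . import _dna

            codes = _dna.encode(probe.seq)
            for c in range(copies):
                sub = codes.copy()
                if seq_error > 0:
                    errs = np.flatnonzero(rng.random(len(sub)) < seq_error)
                    if len(errs):
                        shift = rng.integers(1, 4, size=len(errs)).astype(np.uint8)
                        sub[errs] = (sub[errs] + shift) % 4
                reads.append(
                    QualityRead(
                        id=f"{sample}|p{p_i}|c{c}",
                        seq=_dna.decode(sub),
                        qual=[38] * len(sub),
                        sample=sample,
                        provenance="endogenous",
                        meta=dict(probe.meta),
                    )
                )
        out[sample] = reads
    return out


def simulate_sample_reads(
    cohort: popsim.SimulatedCohort,
    sample: str,
    lib_cfg: LibraryConfig,
    probe_index: capture_mod.ProbeIndex,
    cap_model: capture_mod.CaptureModel,
    seed: int,
) -> tuple[list[QualityRead], dict]:
    """Library prep + capture + sequencing for one cohort individual."""
    rng = np.random.default_rng(seed)
    mols = libsim.fragment_molecules(
        [cohort.haplotypes[sample][0], cohort.haplotypes[sample][1]],
        lib_cfg,
        seed=int(rng.integers(2**31)),
        sample=sample,
        chrom=cohort.ancestor.id,
    )
    if lib_cfg.damage is not None:
        libsim.damage_molecules(mols, lib_cfg.damage, seed=int(rng.integers(2**31)))
    parts: list[MoleculeSet] = [mols]
    if lib_cfg.contaminant_fraction > 0:
        parts.append(
            libsim.contaminant_molecules(
                lib_cfg, seed=int(rng.integers(2**31)), sample=sample
            )
        )
    retained_parts = []
    report_total: dict[str, float] = {}
    for part in parts:
        retained, report = capture_mod.enrich(
            part, probe_index, cap_model, seed=int(rng.integers(2**31))
        )
        retained_parts.append(retained)
        for k, v in report.items():
            if isinstance(v, int):
                report_total[k] = report_total.get(k, 0) + v
    report_total["on_target_fraction"] = (
        report_total.get("retained_on_target", 0) / report_total["n_retained"]
        if report_total.get("n_retained")
        else 0.0
    )
    reads: list[QualityRead] = []
    for part in retained_parts:
        reads.extend(libsim.sequence_reads(part, lib_cfg, seed=int(rng.integers(2**31))))
    return reads, report_total


def run_capture_pipeline(
    cohort: popsim.SimulatedCohort,
    lib_cfgs: dict[str, LibraryConfig],
    seed: int,
    probe_samples: list[str] | None = None,
    size_window: tuple[int, int] = (130, 190),
    cap_model: capture_mod.CaptureModel | None = None,
    filter_cfg: variants.FilterConfig | None = None,
    rescale: bool = True,
    min_base_q: int = 13,
    probe_read_copies: int = 3,
    check_structure: bool = True,
) -> PipelineResult:
    """Full synthetic run; see module docstring for the stage order."""
    rng = np.random.default_rng(seed)
    cap_model = cap_model or capture_mod.CaptureModel()
    filter_cfg = filter_cfg or variants.FilterConfig()
    samples = cohort.samples
    if probe_samples is None:
        # default: first individual of each population, emulating a small
        # pool of fresh specimens spanning the range
        pops = sorted(set(cohort.labels.values()))
        probe_samples = [
            next(s for s in samples if cohort.labels[s] == p) for p in pops
        ]

    probe_sets = make_probes(cohort, probe_samples, size_window)
    pooled = union_probe_sets(list(probe_sets.values()))
    probe_index = capture_mod.ProbeIndex(pooled)

    preads = probe_reads(
        probe_sets, copies=probe_read_copies, seed=int(rng.integers(2**31))
    )
    deduped = {
        s: [m for m, _count in catalog_mod.dedupe_exact(rl)]
        for s, rl in preads.items()
    }
    cat = catalog_mod.build_rad_ref(deduped)

    all_alignments: list = []
    capture_reports: dict[str, dict] = {}
    cat_index = align_mod.CatalogIndex(cat)
    for sample in samples:
        reads, cap_report = simulate_sample_reads(
            cohort,
            sample,
            lib_cfgs[sample],
            probe_index,
            cap_model,
            seed=int(rng.integers(2**31)),
        )
        capture_reports[sample] = cap_report
        all_alignments.extend(align_mod.map_reads(reads, cat_index))
    all_alignments = align_mod.remove_duplicates(all_alignments)
    mapping = align_mod.mapping_stats(all_alignments)

    # damage handling is per sample: profiles are sample-specific biology
    damage_profiles: dict[str, variants.DamageProfile] = {}
    rescaled: list = []
    by_sample: dict[str, list] = {}
    for a in all_alignments:
        by_sample.setdefault(a.sample, []).append(a)
    import warnings as _warnings

    for sample, recs in by_sample.items():
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            profile = variants.estimate_damage_profile(recs, cat)
        damage_profiles[sample] = profile
        rescaled.extend(variants.rescale_qualities(recs, profile) if rescale else recs)

    calls_unrescaled = variants.call_sites(all_alignments, cat, min_base_q)
    calls = (
        variants.call_sites(rescaled, cat, min_base_q) if rescale else calls_unrescaled
    )
    matrix, steps = variants.filter_sites(calls, filter_cfg, samples)

    structure = None
    if check_structure and matrix.shape[1] >= 2:
        try:
            structure = variants.structure_check(matrix, 2, cohort.labels, seed=seed)
        except ValueError:
            structure = None

    result = PipelineResult(
        cohort=cohort,
        probes=pooled,
        catalog=cat,
        alignments=rescaled if rescale else all_alignments,
        capture_reports=capture_reports,
        mapping=mapping,
        damage_profiles=damage_profiles,
        calls=calls,
        calls_unrescaled=calls_unrescaled,
        matrix=matrix,
        filter_steps=steps,
        structure=structure,
    )
    result.metrics = truth_metrics(result, min_site_qual=filter_cfg.min_qual)
    return result


def contig_intervals(cat: catalog_mod.LocusCatalog) -> list[tuple[str, int, int]]:
    """Ancestor-space intervals of catalog contigs that carry provenance."""
    out = []
    for c in cat.contigs:
        if {"chrom", "start", "end"} <= set(c.meta):
            out.append((c.meta["chrom"], c.meta["start"], c.meta["end"]))
    return out


def _calls_to_ancestor(
    calls: list[variants.SiteCall], cat: catalog_mod.LocusCatalog
) -> dict[tuple[str, int], variants.SiteCall]:
    """Map called contig positions back to ancestor coordinates via provenance."""
    meta_by_id = {c.id: c.meta for c in cat.contigs}
    out: dict[tuple[str, int], variants.SiteCall] = {}
    for call in calls:
        meta = meta_by_id.get(call.contig, {})
        if {"chrom", "start"} <= set(meta):
            out[(meta["chrom"], meta["start"] + call.pos)] = call
    return out


def truth_metrics(
    result: PipelineResult, min_site_qual: float = 30.0
) -> dict[str, float]:
    """Sensitivity / FDR of calls against the planted truth, plus
    damage-signature false-positive counts for both calling arms.

    Scoring is restricted to catalog contigs with genomic provenance and to
    calls passing the site-quality threshold (the cascade's MAC/presence
    steps intentionally drop real singleton heterozygotes, so recovery is
    measured on quality-filtered raw calls, not the final matrix).
    """
    cat = result.catalog
    cohort = result.cohort
    intervals = contig_intervals(cat)
    truth = popsim.truth_variants_in(cohort, intervals)
    truth_pos = {
        (row.chrom, row.pos) for row in truth.itertuples() if row.kind != "invariant"
    }

    def arm_stats(calls: list[variants.SiteCall]) -> tuple[int, int, int, int]:
        anchored = _calls_to_ancestor(calls, cat)
        passing = {
            key: c for key, c in anchored.items() if c.site_qual > min_site_qual
        }
        tp = sum(1 for key in passing if key in truth_pos)
        fp = sum(1 for key in passing if key not in truth_pos)
        dmg_fp = sum(
            1
            for key, c in passing.items()
            if key not in truth_pos
            and (c.ref_base, c.alt) in (("C", "T"), ("G", "A"))
        )
        return tp, fp, dmg_fp, len(passing)

    tp, fp, dmg_fp, n_pass = arm_stats(result.calls)
    _, _, dmg_fp_raw, _ = arm_stats(result.calls_unrescaled)
    n_truth = len(truth_pos)
    metrics = {
        "n_truth_in_catalog": float(n_truth),
        "n_calls": float(n_pass),
        "sensitivity": tp / n_truth if n_truth else float("nan"),
        "fdr": fp / n_pass if n_pass else 0.0,
        "damage_fp_rescaled": float(dmg_fp),
        "damage_fp_unrescaled": float(dmg_fp_raw),
    }
    if result.structure is not None:
        metrics["structure_concordance"] = (
            result.structure[1] if result.structure[1] is not None else float("nan")
        )
    try:
        metrics["matrix_fullness"] = result.matrix.fullness()
    except ValueError:
        metrics["matrix_fullness"] = float("nan")
    return metrics
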