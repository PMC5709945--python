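"""End-to-end simulation studies: genome -> molecules -> calls -> metrics.

These are the canonical study conditions used by the test-bench scripts: a
synthetic 20 Mbp chromosome with 150 large indels (default error model,
100x coverage), in haploid and diploid (p_hom = p_het = 0.5) versions, plus
a complex-SV study seeding inversions and translocations.  The genome is an
i.i.d. random sequence, so nicking-site spacing is exponential-like at
roughly the density of a human chromosome digested with Nt.BspQI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import evaluation
from .aligner import AlignerParams
from .core import ReferenceMap
from .digestion import DigestionParams, digest
from .pipeline import PipelineConfig, run_pipeline
from .simulator import (
    DiploidParams,
    ErrorModelParams,
    HaplotypeMap,
    TruthVariant,
    VariantPlan,
    build_diploid,
    inject_variants,
    random_genome,
)

DEFAULT_GENOME_LENGTH = 20_000_000
DEFAULT_INDEL_PLAN = VariantPlan(n_insertions=75, n_deletions=75)
DEFAULT_COMPLEX_PLAN = VariantPlan(
    n_insertions=10, n_deletions=10, n_inversions=15, n_translocations=15)


@dataclass
class StudyResult:
    truth: list[TruthVariant]
    refmap: ReferenceMap
    report: dict
    metrics: dict = field(default_factory=dict)


def _default_config() -> PipelineConfig:
    return PipelineConfig(aligner=AlignerParams(gamma_align=0.012))


def run_indel_study(
    seed: int,
    diploid: bool,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    plan: VariantPlan = DEFAULT_INDEL_PLAN,
    error_model: ErrorModelParams | None = None,
    config: PipelineConfig | None = None,
) -> StudyResult:
    """Simulate the default indel study and score it.

    Metrics: precision/recall per SV type (zygosity ignored), the
    zygosity-required variants, and the median estimated-to-true size ratio
    over correctly identified indels.  Truth intervals are widened by the
    imaging resolution d_half when matching: an indel within the merge
    radius of a defining nicking site merges with that site's label and its
    distance signal legitimately appears in the adjacent gap.
    """
    rng = np.random.default_rng(seed)
    error_model = error_model or ErrorModelParams()
    config = config or _default_config()
    reference = random_genome(genome_length, seed=int(rng.integers(2**31)))
    mutated, truth_hap = inject_variants(reference, plan, rng)
    refmap = digest({"chr1": reference}, DigestionParams(d_half=error_model.d_half))
    if diploid:
        seq1, seq2, truth = build_diploid(truth_hap, reference, DiploidParams(), rng)
        haplotypes = [
            HaplotypeMap.from_sequences(1, {"chr1": seq1}),
            HaplotypeMap.from_sequences(2, {"chr1": seq2}),
        ]
    else:
        truth = truth_hap
        haplotypes = [HaplotypeMap.from_sequences(1, {"chr1": mutated})]
    from .simulator import simulate_molecules

    molecules = simulate_molecules(haplotypes, error_model, rng)
    report = run_pipeline(molecules, refmap, config)

    indel_calls = [c for c in report["calls"] if c.sv_type in ("insertion", "deletion")]
    truth_indels = [v for v in truth if v.kind in ("insertion", "deletion")]
    slack = error_model.d_half  # localization resolution of the method
    metrics: dict = {"n_calls": len(indel_calls), "n_truth": len(truth_indels)}
    for sv_type in ("deletion", "insertion"):
        sub_calls = [c for c in indel_calls if c.sv_type == sv_type]
        sub_truth = [v for v in truth_indels if v.kind == sv_type]
        if sub_calls and sub_truth:
            p, _ = evaluation.precision_recall(sub_calls, truth_indels, slack=slack)
            _, r = evaluation.precision_recall(sub_calls, sub_truth, slack=slack)
            metrics[f"{sv_type}_precision"] = p * 100
            metrics[f"{sv_type}_recall"] = r * 100
            if diploid:
                pz, _ = evaluation.precision_recall(sub_calls, truth_indels,
                                                    match_zygosity=True, slack=slack)
                _, rz = evaluation.precision_recall(sub_calls, sub_truth,
                                                    match_zygosity=True, slack=slack)
                metrics[f"{sv_type}_precision_zyg"] = pz * 100
                metrics[f"{sv_type}_recall_zyg"] = rz * 100
    metrics["size_ratio_median"] = evaluation.size_ratio_stats(
        indel_calls, truth_indels)["median"]
    if diploid and "deletion_precision_zyg" in metrics:
        metrics["precision_zyg_avg"] = (
            metrics["deletion_precision_zyg"] + metrics["insertion_precision_zyg"]) / 2
        metrics["recall_zyg_avg"] = (
            metrics["deletion_recall_zyg"] + metrics["insertion_recall_zyg"]) / 2
    return StudyResult(truth, refmap, report, metrics)


def run_complex_study(
    seed: int,
    genome_length: int = DEFAULT_GENOME_LENGTH,
    plan: VariantPlan = DEFAULT_COMPLEX_PLAN,
    error_model: ErrorModelParams | None = None,
    config: PipelineConfig | None = None,
) -> StudyResult:
    """Simulate the complex-SV study (haploid) and score inversion and
    translocation calls by overlap with same-type truth.

    Breakpoint estimates from split alignments carry map-scale uncertainty
    (a segment ends at its last matched site, one or two inter-site gaps
    from the true breakpoint), so truth intervals are widened by 30 kbp when
    matching junction calls.
    """
    rng = np.random.default_rng(seed)
    error_model = error_model or ErrorModelParams()
    config = config or _default_config()
    reference = random_genome(genome_length, seed=int(rng.integers(2**31)))
    mutated, truth = inject_variants(reference, plan, rng)
    refmap = digest({"chr1": reference}, DigestionParams(d_half=error_model.d_half))
    haplotypes = [HaplotypeMap.from_sequences(1, {"chr1": mutated})]
    from .simulator import simulate_molecules

    molecules = simulate_molecules(haplotypes, error_model, rng)
    report = run_pipeline(molecules, refmap, config)

    complex_calls = [c for c in report["calls"]
                     if evaluation.TYPE_MAP.get(c.sv_type) in ("inversion", "translocation")]
    complex_truth = [v for v in truth if v.kind in ("inversion", "translocation")]
    metrics: dict = {"n_calls": len(complex_calls), "n_truth": len(complex_truth)}
    if complex_calls and complex_truth:
        slack = 30000.0
        p, _ = evaluation.precision_recall(complex_calls, truth, slack=slack)
        _, r = evaluation.precision_recall(complex_calls, complex_truth, slack=slack)
        metrics["complex_precision"] = p * 100
        metrics["complex_recall"] = r * 100
    return StudyResult(truth, refmap, report, metrics)
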