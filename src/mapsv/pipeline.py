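"""Pipeline orchestration: align -> call -> integrate -> filter.

The stages mirror the two-step design of the framework: an alignment step
(one or two aligners, integrated into a consensus set) followed by the three
SV-calling modules, whose outputs are merged, de-duplicated, and filtered
against mask regions before the final SV table is written.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from intervaltree import IntervalTree

from . import aligner as _aligner
from . import complex_caller, site_caller, size_caller
from .core import MaskRegion, ReferenceMap, SVCall
from .digestion import DigestionParams
from .simulator import ErrorModelParams

INDEL_TYPES = {"insertion", "deletion", "missing_site", "extra_site"}
COMPLEX_TYPES = {
    "inversion_medium", "inversion_large", "translocation_intra",
    "translocation_inter", "cnv_gain", "cnv_loss",
}


@dataclass
class PipelineConfig:
    """All tunable parameters of a pipeline run, one block per stage."""

    digestion: DigestionParams = field(default_factory=DigestionParams)
    error_model: ErrorModelParams = field(default_factory=ErrorModelParams)
    aligner: _aligner.AlignerParams = field(default_factory=_aligner.AlignerParams)
    site: site_caller.SiteCallerParams = field(default_factory=site_caller.SiteCallerParams)
    size: size_caller.SizeCallerParams = field(default_factory=size_caller.SizeCallerParams)
    inversion: complex_caller.InversionParams = field(default_factory=complex_caller.InversionParams)
    cnv: complex_caller.CnvParams = field(default_factory=complex_caller.CnvParams)
    strategy: str = "union"          # alignment integration strategy
    min_confidence: float = 9.0      # alignment confidence filter
    run_complex: bool = True
    run_cnv: bool = False            # depth scan is off unless CNVs are expected
    seed: int = 0


_CONFIG_BLOCKS = {
    "digestion": DigestionParams,
    "error_model": ErrorModelParams,
    "aligner": _aligner.AlignerParams,
    "site": site_caller.SiteCallerParams,
    "size": size_caller.SizeCallerParams,
    "inversion": complex_caller.InversionParams,
    "cnv": complex_caller.CnvParams,
}


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build a PipelineConfig from a plain (e.g. YAML-loaded) mapping.

    Top-level keys name parameter blocks (``aligner``, ``size``, ...) whose
    entries override that block's defaults; scalar keys (``strategy``,
    ``min_confidence``, ``run_complex``, ``run_cnv``, ``seed``) override the
    pipeline-level settings.
    """
    kwargs: dict = {}
    for key, value in (doc or {}).items():
        if key in _CONFIG_BLOCKS:
            kwargs[key] = _CONFIG_BLOCKS[key](**value)
        elif key in ("strategy", "min_confidence", "run_complex", "run_cnv", "seed"):
            kwargs[key] = value
        else:
            raise ValueError(f"unknown configuration key {key!r}")
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# Ultra-dense regions

def find_ultra_dense_regions(refmap: ReferenceMap, min_span: float = 200_000.0,
                             min_density: float = 333.0) -> list[MaskRegion]:
    """Regions spanning >= min_span with >= min_density sites per Mbp.

    Qualifying windows (min_span wide, stepped at min_span/20) are merged
    into maximal regions; the density threshold corresponds to a mean
    adjacent-site distance too small for reliable complex-SV detection.
    """
    masks: list[MaskRegion] = []
    need = min_density * min_span / 1e6
    step = min_span / 20.0
    for contig in refmap:
        sites = np.asarray(contig.sites)
        if len(sites) < need:
            continue
        hits: list[tuple[float, float]] = []
        start = 0.0
        while start + min_span <= contig.length + step:
            end = start + min_span
            count = int(np.searchsorted(sites, end) - np.searchsorted(sites, start))
            if count / (min_span / 1e6) >= min_density:
                hits.append((start, end))
            start += step
        merged: list[list[float]] = []
        for s, e in hits:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        masks.extend(MaskRegion(contig.name, s, e, "ultra_dense") for s, e in merged)
    return masks


# ---------------------------------------------------------------------------
# Mask filtering

_INDEL_MASKS = {"n_gap", "fragile_site", "pseudo_autosomal"}
_COMPLEX_MASKS = {"pseudo_autosomal", "ultra_dense"}


def apply_filters(calls: list[SVCall], masks: list[MaskRegion],
                  refmap: ReferenceMap | None = None) -> tuple[list[SVCall], dict]:
    """Drop indel calls overlapping N-gaps, fragile sites, or PARs, and
    complex calls overlapping PARs or ultra-dense site regions (any-bp
    overlap).  Returns (kept calls, per-mask-class attrition counts)."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for m in masks:
        trees.setdefault((m.chromosome, m.mask_class), IntervalTree()).addi(m.start, m.end)
    kept: list[SVCall] = []
    drops: dict[str, int] = {}
    for call in calls:
        classes = _INDEL_MASKS if call.sv_type in INDEL_TYPES else _COMPLEX_MASKS
        hit = None
        for cls in classes:
            tree = trees.get((call.chromosome, cls))
            if tree is not None and tree.overlap(call.start, max(call.end, call.start + 1)):
                hit = cls
                break
        if hit is None:
            kept.append(call)
        else:
            drops[hit] = drops.get(hit, 0) + 1
    return kept, drops


# ---------------------------------------------------------------------------
# Merge and de-duplicate

def _direction(call: SVCall) -> str:
    if call.sv_type in ("insertion", "extra_site"):
        return "ins"
    if call.sv_type in ("deletion", "missing_site"):
        return "del"
    return "other"


def merge_and_dedup(site_calls: list[SVCall], size_calls: list[SVCall],
                    complex_calls: list[SVCall]) -> list[SVCall]:
    """Integrate the three modules' outputs into one de-duplicated list.

    Same-type overlapping calls collapse to the smallest-likelihood-ratio
    record; a site-module call overlapping a size-module indel of the same
    direction is subsumed by it (size calls carry size estimates).
    Triallelic loci retain both allele records.

    Size-module calls additionally collapse across types: evidence spans over
    nested site intervals re-measure the same event (a variant inside a wide
    span distorts its distance distribution), so among overlapping
    size-module loci only the strongest (smallest-LR) evidence unit is kept,
    with the two allele calls of a triallelic locus treated as one unit.
    """
    # collapse same-type overlaps within each module's list
    def collapse(calls: list[SVCall]) -> list[SVCall]:
        out: list[SVCall] = []
        for call in sorted(calls, key=lambda c: (c.chromosome, c.sv_type, c.start)):
            prev = out[-1] if out else None
            if (prev is not None and prev.sv_type == call.sv_type
                    and prev.overlaps(call.chromosome, call.start, call.end)
                    and not (prev.info.get("multi_allele") and call.info.get("multi_allele"))):
                lr_prev = prev.likelihood_ratio if np.isfinite(prev.likelihood_ratio) else np.inf
                lr_call = call.likelihood_ratio if np.isfinite(call.likelihood_ratio) else np.inf
                if lr_call < lr_prev or (lr_call == lr_prev and call.support > prev.support):
                    out[-1] = call
            else:
                out.append(call)
        return out

    # greedy cross-type collapse of size-module evidence units: tightest
    # spans first (a wide span covering an SV re-measures it with distorted
    # distances, and a span covering two nearby SVs only sees their sum),
    # then strongest evidence
    units: dict[tuple, list[SVCall]] = {}
    for call in size_calls:
        units.setdefault((call.chromosome, call.start, call.end), []).append(call)

    def unit_key(kv):
        (chrom, start, end), calls = kv
        lr = min((c.likelihood_ratio for c in calls
                  if np.isfinite(c.likelihood_ratio)), default=np.inf)
        return (lr, end - start)

    ranked_units = sorted(units.items(), key=unit_key)
    accepted: list[tuple[str, float, float]] = []
    size_kept: list[SVCall] = []
    for (chrom, start, end), unit in ranked_units:
        if any(c == chrom and start < e and s < end for c, s, e in accepted):
            continue
        accepted.append((chrom, start, end))
        size_kept.extend(unit)

    size_f = collapse(size_kept)
    complex_f = collapse(complex_calls)
    # site calls subsumed by a same-direction overlapping size-module indel
    site_f = []
    for sc in collapse(site_calls):
        subsumed = any(
            zc.overlaps(sc.chromosome, sc.start - 1.0, sc.end + 1.0)
            and _direction(zc) == _direction(sc)
            for zc in size_f
        )
        if not subsumed:
            site_f.append(sc)
    final = sorted(site_f + size_f + complex_f, key=lambda c: (c.chromosome, c.start))
    return final


# ---------------------------------------------------------------------------
# End-to-end driver

def run_pipeline(
    molecules,
    refmap: ReferenceMap,
    config: PipelineConfig | None = None,
    masks: list[MaskRegion] | None = None,
    secondary_alignments=None,
    alignments=None,
) -> dict:
    """Align molecules (unless alignments are given), run the three calling
    modules, merge and filter.  Returns a report dict with the final calls
    and per-stage accounting; deterministic for fixed inputs."""
    config = config or PipelineConfig()
    report: dict = {"n_molecules": len(molecules)}
    if alignments is None:
        alignments = _aligner.align_molecules(molecules, refmap, config.aligner)
    report["n_aligned"] = len(alignments)
    if secondary_alignments is not None:
        alignments = _aligner.integrate_alignments(
            alignments, secondary_alignments, config.strategy)
        report["n_consensus"] = len(alignments)
    alignments = _aligner.filter_by_confidence(alignments, config.min_confidence)
    report["n_confident"] = len(alignments)

    site_calls = site_caller.call_sites(alignments, molecules, refmap, config.site)
    size_calls = size_caller.call_sizes(alignments, molecules, refmap, config.size)
    complex_calls: list[SVCall] = []
    if config.run_complex:
        splits = _aligner.two_round_split_align(
            molecules, refmap, alignments, config.aligner)
        complex_calls = complex_caller.detect_medium_inversions(
            alignments, molecules, refmap, config.inversion)
        complex_calls += complex_caller.detect_split_svs(splits, config.cnv)
        if config.run_cnv:
            complex_calls += complex_caller.detect_cnvs(alignments, refmap, config.cnv)
    report["n_site_calls"] = len(site_calls)
    report["n_size_calls"] = len(size_calls)
    report["n_complex_calls"] = len(complex_calls)

    merged = merge_and_dedup(site_calls, size_calls, complex_calls)
    report["n_merged"] = len(merged)

    all_masks = list(masks or [])
    all_masks += find_ultra_dense_regions(refmap)
    final, drops = apply_filters(merged, all_masks, refmap)
    report["filter_drops"] = drops
    report["n_final"] = len(final)
    assert len(merged) == len(final) + sum(drops.values())
    report["calls"] = final
    report["alignments"] = alignments
    return report
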