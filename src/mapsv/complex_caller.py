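"""Detection of inversions, translocations, and CNVs.

Medium inversions (roughly 2-100 kbp) fit inside a single molecule: the
inverted segment shows up in an alignment as a run of unmatched reference
sites and unmatched molecule labels — a reverse-palindromic CIGAR window —
whose label spacing matches the reference spacing after reversal.  Larger
events are caught by two-round split alignments: a molecule crossing a
junction aligns as two segments whose placement (different chromosomes,
opposite orientations, or non-colinear same-chromosome positions) classifies
the event.  CNVs come from a depth scan: the genome is tiled with windows of
twice the imaging resolution, windows are grouped by their nicking-site
count (the depth covariate for optical maps), a Gaussian fit per group gives
each window a Z-test p-value, and significant windows are merged into blocks
that must survive a Benjamini-Hochberg FDR across blocks.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .core import AlignmentRecord, ReferenceMap, SplitAlignment, SVCall


@dataclass
class InversionParams:
    e_t: float = 0.1        # maximum relative scaling error for distance matching
    e_m: float = 500.0      # bp, maximum absolute measurement error
    min_molecules: int = 10
    min_sites: int = 4      # nicking sites required inside the inverted region
    min_size: float = 2000.0
    max_size: float = 100000.0

    def __post_init__(self) -> None:
        if not 0 <= self.e_t < 1:
            raise ValueError("e_t must be in [0, 1)")
        if self.e_m < 0:
            raise ValueError("e_m must be non-negative")


@dataclass
class CnvParams:
    window: float = 3000.0         # bp; 2 * d_half by default
    p_threshold: float = 0.05
    fdr: float = 0.05
    min_group_windows: int = 30
    edge_margin: float = 250000.0  # bp excluded at contig ends (depth taper)
    min_support_splits: int = 2    # molecules required for split-based SV calls
    cluster_radius: float = 20000.0  # junction clustering radius; split-segment
    # ends stop at the last matched site, about one inter-site gap from the
    # true breakpoint, so junction estimates scatter on that scale

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")


# ---------------------------------------------------------------------------
# CIGAR algebra

def reverse_complement_cigar(cigar: str) -> str:
    """Reverse the string and interchange I and D (M is self-complementary)."""
    table = {"M": "M", "D": "I", "I": "D"}
    try:
        return "".join(table[c] for c in reversed(cigar))
    except KeyError as exc:
        raise ValueError(f"CIGAR must be over M, D, I: {cigar!r}") from exc


def is_reverse_palindromic(cigar: str) -> bool:
    return cigar == reverse_complement_cigar(cigar)


def distances_match(d: float, d_prime: float, e_t: float, e_m: float) -> bool:
    """True when d' lies in [d (1 - e_t) - e_m, d (1 + e_t) + e_m] (inclusive)."""
    return d * (1.0 - e_t) - e_m <= d_prime <= d * (1.0 + e_t) + e_m


# ---------------------------------------------------------------------------
# Medium inversions

def _gap_match_cost(ref_gaps, mol_gaps, e_t: float, e_m: float,
                    max_extra: int = 2, max_missing: int = 1) -> float:
    """Best mean |log(d_mol/d_ref)| over matchings of two gap sequences.

    A false-positive label splits one gap in two (two molecule gaps sum to
    one reference gap); a false negative merges two (one molecule gap covers
    two reference gaps).  Each aggregated pair must satisfy
    ``distances_match``; at most ``max_extra`` splits and ``max_missing``
    merges are tolerated overall.  Returns inf when no matching exists.
    """
    from functools import lru_cache

    R, Q = len(ref_gaps), len(mol_gaps)

    @lru_cache(maxsize=None)
    def best(i: int, j: int, extra: int, missing: int) -> float:
        if i == R and j == Q:
            return 0.0
        if i >= R or j >= Q:
            return np.inf
        out = np.inf
        for a in range(1, 2 + 1):          # ref gaps consumed
            if i + a > R or (a - 1) > missing:
                continue
            dr = sum(ref_gaps[i:i + a])
            for b in range(1, 3 + 1):      # molecule gaps consumed
                if j + b > Q or (b - 1) > extra:
                    continue
                dm = sum(mol_gaps[j:j + b])
                if distances_match(dr, dm, e_t, e_m) and dr > 0 and dm > 0:
                    tail = best(i + a, j + b, extra - (b - 1), missing - (a - 1))
                    out = min(out, abs(np.log(dm / dr)) + tail)
        return out

    total = best(0, 0, max_extra, max_missing)
    return total / max(R, 1)


def _cluster_spans(spans: list[tuple[float, float]], min_support: int):
    """Greedy overlap clustering of per-molecule spans, sorted by start."""
    clusters: list[list[tuple[float, float]]] = []
    for span in sorted(spans):
        if clusters and span[0] <= max(e for _, e in clusters[-1]):
            clusters[-1].append(span)
        else:
            clusters.append([span])
    return [cl for cl in clusters if len(cl) >= min_support]


def detect_medium_inversions(
    alignments: list[AlignmentRecord],
    molecules,
    refmap: ReferenceMap,
    params: InversionParams | None = None,
) -> list[SVCall]:
    """Per-molecule scan for inverted windows, then cross-molecule clustering.

    A window between two matched pairs whose interior reference sites and
    molecule labels are all unmatched (CIGAR D...DI...I, which is reverse
    palindromic when counts are equal) supports an inversion when every
    reference gap matches the corresponding reversed molecule gap.  Calls
    need >= min_molecules supporting spans, >= min_sites interior sites, and
    a size inside [min_size, max_size].  Inversions whose interior site
    pattern is symmetric produce direct matches instead of unmatched windows
    and are intrinsically undetectable here.
    """
    params = params or InversionParams()
    mol_by_id = {m.molecule_id: m for m in molecules}
    spans_by_chrom: dict[str, list[tuple[float, float]]] = {}
    max_interior = 30
    for rec in alignments:
        mol = mol_by_id.get(rec.molecule_id)
        if mol is None:
            continue
        sites = refmap[rec.chromosome].sites
        labels = mol.labels
        n_pairs = len(rec.pairs)
        for l1 in range(n_pairs - 1):
            i1, j1 = rec.pairs[l1]
            for l2 in range(l1 + 1, n_pairs):
                i2, j2 = rec.pairs[l2]
                k_ref = j2 - j1 - 1
                if k_ref > max_interior:
                    break
                k_mol = abs(i2 - i1) - 1
                if k_ref < params.min_sites or not k_ref - 1 <= k_mol <= k_ref + 2:
                    continue
                size = sites[j2] - sites[j1]
                if not params.min_size <= size <= params.max_size:
                    continue
                # the inverted window behaves as unmatched reference sites
                # against unmatched labels: cigar D^k I^k, reverse palindromic
                if not is_reverse_palindromic("D" * k_ref + "I" * k_mol):
                    continue
                # interior gaps only: the two gaps out to the anchors mirror
                # onto each other only when the anchors sit symmetrically
                # about the inversion, which is not generally the case
                ref_pts = [sites[j] for j in range(j1 + 1, j2)]
                step = 1 if i2 > i1 else -1
                mol_pts = [labels[i] for i in range(i1 + step, i2, step)]
                ref_gaps = tuple(np.diff(ref_pts))
                fwd_gaps = tuple(np.abs(np.diff(mol_pts)))
                rev_gaps = fwd_gaps[::-1]  # reversed molecule gaps
                rev_cost = _gap_match_cost(ref_gaps, rev_gaps,
                                           params.e_t, params.e_m)
                # an actual inversion matches cleanly in reversed order and
                # clearly worse forward; symmetric site patterns or nearby
                # indels produce comparable costs both ways and are excluded
                fwd_cost = _gap_match_cost(ref_gaps, fwd_gaps,
                                           params.e_t, params.e_m)
                if rev_cost <= 0.05 and fwd_cost > 2.0 * rev_cost:
                    spans_by_chrom.setdefault(rec.chromosome, []).append(
                        (float(sites[j1]), float(sites[j2])))
    calls = []
    for chrom, spans in spans_by_chrom.items():
        for cl in _cluster_spans(spans, params.min_molecules):
            start = float(np.median([s for s, _ in cl]))
            end = float(np.median([e for _, e in cl]))
            calls.append(SVCall(chrom, start, end, "inversion_medium", "na",
                                end - start, len(cl), len(cl), np.nan, np.nan,
                                "complex"))
    return calls


# ---------------------------------------------------------------------------
# Split-alignment SVs

def _junction_coords(seg: AlignmentRecord, side: str) -> float:
    """Reference coordinate of the segment end adjacent to the junction.
    ``side`` is 'late' for the molecule-later end, 'early' for the earlier."""
    if (side == "late") == (seg.orientation == "+"):
        return seg.ref_end
    return seg.ref_start


def detect_split_svs(splits: list[SplitAlignment],
                     params: CnvParams | None = None) -> list[SVCall]:
    """Classify adjacent split-alignment segment pairs and cluster junctions.

    Different chromosomes -> inter-chromosomal translocation; same chromosome
    with opposite orientations -> large inversion; same chromosome, same
    orientation but non-colinear placement -> intra-chromosomal
    translocation.  Junction pairs are clustered across molecules within the
    clustering radius and reported when supported by >= min_support_splits
    molecules.
    """
    params = params or CnvParams()
    junctions: dict[tuple, list[tuple[float, float]]] = {}
    for split in splits:
        segs = split.segments
        for s1, s2 in zip(segs, segs[1:]):
            b1 = _junction_coords(s1, "late")
            b2 = _junction_coords(s2, "early")
            if s1.chromosome != s2.chromosome:
                kind = "translocation_inter"
                key_chrom = tuple(sorted((s1.chromosome, s2.chromosome)))
                if key_chrom[0] != s1.chromosome:
                    b1, b2 = b2, b1
            elif s1.orientation != s2.orientation:
                kind = "inversion_large"
                key_chrom = (s1.chromosome,)
                b1, b2 = min(b1, b2), max(b1, b2)
            else:
                # colinear continuation is not an SV junction
                gap_ref = b2 - b1
                if -20000.0 <= gap_ref <= 100000.0:
                    continue
                kind = "translocation_intra"
                key_chrom = (s1.chromosome,)
                b1, b2 = min(b1, b2), max(b1, b2)
            junctions.setdefault((kind, key_chrom), []).append((b1, b2))
    calls = []
    r = params.cluster_radius
    for (kind, key_chrom), pts in junctions.items():
        pts.sort()
        cluster: list[tuple[float, float]] = []
        clusters = []
        for p in pts:
            if cluster and (abs(p[0] - cluster[-1][0]) <= r
                            and abs(p[1] - cluster[-1][1]) <= r):
                cluster.append(p)
            else:
                cluster = [p]
                clusters.append(cluster)
        for cl in clusters:
            if len(cl) < params.min_support_splits:
                continue
            b1 = float(np.median([p[0] for p in cl]))
            b2 = float(np.median([p[1] for p in cl]))
            chrom = key_chrom[0]
            if kind == "inversion_large":
                start, end, info = b1, b2, {}
            else:
                # junction-type call: a short interval at each breakpoint
                mate_chrom = key_chrom[1] if kind == "translocation_inter" else chrom
                start, end = b1 - 2000.0, b1 + 2000.0
                info = {"mate_chromosome": mate_chrom, "mate_position": b2}
            calls.append(SVCall(chrom, start, end, kind, "na", end - start,
                                len(cl), len(cl), np.nan, np.nan, "complex",
                                info=info))
    return calls


# ---------------------------------------------------------------------------
# CNVs by window depth

def detect_cnvs(alignments: list[AlignmentRecord], refmap: ReferenceMap,
                params: CnvParams | None = None) -> list[SVCall]:
    """Window-depth CNV scan with site-count grouping and block-level FDR."""
    params = params or CnvParams()
    calls = []
    for contig in refmap:
        n_win = int(contig.length // params.window)
        if n_win < 10:
            continue
        edges = np.arange(n_win + 1) * params.window
        depth = np.zeros(n_win)
        for rec in alignments:
            if rec.chromosome != contig.name:
                continue
            lo = int(np.searchsorted(edges, rec.ref_start, side="right")) - 1
            hi = int(np.searchsorted(edges, rec.ref_end, side="left"))
            depth[max(lo, 0):min(hi, n_win)] += 1
        site_counts = np.histogram(contig.sites, bins=edges)[0]
        # group windows by site count; merge sparse groups into the nearest
        groups: dict[int, np.ndarray] = {
            c: np.flatnonzero(site_counts == c) for c in np.unique(site_counts)
        }
        counts = sorted(groups)
        merged: dict[int, list[int]] = {}
        for c in counts:
            idx = groups[c]
            if len(idx) < params.min_group_windows and merged:
                nearest = min(merged, key=lambda k: abs(k - c))
                warnings.warn(
                    f"CNV scan: merging sparse site-count group {c} into {nearest}")
                merged[nearest].extend(idx.tolist())
            else:
                merged[c] = idx.tolist()
        z = np.zeros(n_win)
        for idx in merged.values():
            arr = depth[idx]
            if len(arr) < 2:
                continue
            mu, sd = float(arr.mean()), float(arr.std(ddof=1))
            if not np.isfinite(sd) or sd <= 0:
                continue
            z[idx] = (arr - mu) / sd
        p = 2.0 * norm.sf(np.abs(z))
        candidate = p < params.p_threshold
        # molecules truncate at contig ends, so depth tapers there regardless
        # of copy number; mask those windows
        interior = (edges[1:] > params.edge_margin) & (
            edges[:-1] < contig.length - params.edge_margin)
        candidate &= interior
        # merge adjacent same-direction candidate windows into blocks
        blocks = []
        i = 0
        while i < n_win:
            if candidate[i]:
                sign = np.sign(z[i])
                j = i
                while j + 1 < n_win and candidate[j + 1] and np.sign(z[j + 1]) == sign:
                    j += 1
                blocks.append((i, j, sign))
                i = j + 1
            else:
                i += 1
        if not blocks:
            continue
        # block significance by Stouffer combination, then BH across blocks
        block_p = []
        for i, j, sign in blocks:
            zs = z[i : j + 1]
            stouffer = float(np.sum(zs) / np.sqrt(len(zs)))
            block_p.append(2.0 * float(norm.sf(abs(stouffer))))
        order = np.argsort(block_p)
        n_b = len(blocks)
        keep = np.zeros(n_b, dtype=bool)
        max_k = -1
        for rank, bi in enumerate(order, start=1):
            if block_p[bi] <= params.fdr * rank / n_b:
                max_k = rank
        for rank, bi in enumerate(order, start=1):
            if rank <= max_k:
                keep[bi] = True
        for (i, j, sign), p_b, ok in zip(blocks, block_p, keep):
            if not ok:
                continue
            kind = "cnv_gain" if sign > 0 else "cnv_loss"
            calls.append(SVCall(contig.name, float(edges[i]), float(edges[j + 1]),
                                kind, "na", float(edges[j + 1] - edges[i]),
                                j - i + 1, j - i + 1, p_b, np.nan, "complex"))
    return calls


def call_complex(alignments, molecules, refmap, splits,
                 inversion_params: InversionParams | None = None,
                 cnv_params: CnvParams | None = None) -> list[SVCall]:
    """Run all three complex-SV detectors."""
    calls = detect_medium_inversions(alignments, molecules, refmap, inversion_params)
    calls += detect_split_svs(splits, cnv_params)
    calls += detect_cnvs(alignments, refmap, cnv_params)
    return calls
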