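"""Built-in optical-map-to-reference aligner and alignment integration.

The aligner is a stand-in for the external production aligners: it seeds on
pairs of consecutive inter-label distances, then extends each candidate
placement with a banded dynamic program over (molecule label, reference
site) nodes.  The match score is a log-Cauchy density of the relative
distance deviation — matching the sizing-error model, so alignment errors
resemble the generative model's — with per-site penalties for skipped
reference sites (molecule false negatives) and skipped molecule labels
(false positives).  Both orientations are tried; the reported confidence is
the total alignment score relative to the empty-alignment null, on a log10
scale, so the conventional confidence >= 9 filter is meaningful here too.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .core import AlignmentRecord, MoleculeMap, ReferenceMap, SplitAlignment

LN10 = math.log(10.0)


@dataclass
class AlignerParams:
    seed_width: int = 2                # consecutive inter-label gaps per seed
    sizing_tolerance: float = 0.07     # relative seed gap tolerance
    seed_abs_tolerance: float = 300.0  # bp absolute seed slack (label offsets)
    fallback_tolerance: float = 0.18   # retry tolerance for heavily stretched molecules
    site_miss_penalty: float = 2.5     # log-score units per skipped reference site
    site_extra_penalty: float = 2.5    # per skipped molecule label
    gamma_align: float = 0.02          # Cauchy scale of the match score
    mismatch_floor: float = -6.0       # per-gap score floor (keeps SV gaps bridgeable)
    dev_floor_bp: float = 3000.0       # deviation normalizer floor for short gaps
    max_skip: int = 10                 # max consecutive skipped sites/labels
    max_candidates: int = 4            # candidate windows per orientation
    min_confidence: float = 9.0
    min_aligned_sites: int = 5

    def __post_init__(self) -> None:
        if self.seed_width < 2:
            raise ValueError("seed_width must be >= 2")
        if self.site_miss_penalty <= 0 or self.site_extra_penalty <= 0:
            raise ValueError("penalties must be positive")


# ---------------------------------------------------------------------------
# numba kernels

@njit(cache=True)
def _seed_kernel(g, G_sorted, G_order, G, tol_rel, tol_abs, out_i, out_j):
    """Anchors (molecule gap i) -> (reference gap j) where two consecutive
    gaps match within tolerance.  Returns the number of anchors written."""
    n_out = 0
    cap = out_i.shape[0]
    for i in range(len(g) - 1):
        gi = g[i]
        lo = np.searchsorted(G_sorted, gi * (1.0 - tol_rel) - tol_abs)
        hi = np.searchsorted(G_sorted, gi * (1.0 + tol_rel) + tol_abs)
        for s in range(lo, hi):
            j = G_order[s]
            if j + 1 >= len(G):
                continue
            gj2 = G[j + 1]
            gi2 = g[i + 1]
            if abs(gj2 - gi2) <= gi2 * tol_rel + tol_abs:
                if n_out < cap:
                    out_i[n_out] = i
                    out_j[n_out] = j
                    n_out += 1
    return n_out


@njit(cache=True)
def _dp_kernel(P, R, max_skip, gamma2, c0, miss_pen, extra_pen, floor, dev_floor):
    """Local chaining DP: score[a, b] = best score of a chain ending with
    label a matched to site b.  Returns (score, back_a, back_b)."""
    n = P.shape[0]
    w = R.shape[0]
    score = np.full((n, w), -1e18)
    back_a = np.full((n, w), -1, np.int32)
    back_b = np.full((n, w), -1, np.int32)
    for a in range(n):
        for b in range(w):
            best = 0.0  # start a new chain here
            pa = -1
            pb = -1
            a0 = a - max_skip - 1
            if a0 < 0:
                a0 = 0
            b0 = b - max_skip - 1
            if b0 < 0:
                b0 = 0
            for a2 in range(a0, a):
                for b2 in range(b0, b):
                    prev = score[a2, b2]
                    if prev < -1e17:
                        continue
                    dm = P[a] - P[a2]
                    dr = R[b] - R[b2]
                    if dr <= 0.0 or dm <= 0.0:
                        continue
                    denom = dr if dr > dev_floor else dev_floor
                    dev = (dm - dr) / denom
                    ms = c0 - math.log(dev * dev + gamma2)
                    if ms < floor:
                        ms = floor
                    cand = prev + ms - miss_pen * (b - b2 - 1) - extra_pen * (a - a2 - 1)
                    if cand > best:
                        best = cand
                        pa = a2
                        pb = b2
            score[a, b] = best
            back_a[a, b] = pa
            back_b[a, b] = pb
    return score, back_a, back_b


# ---------------------------------------------------------------------------
# Reference indexing

class _RefIndex:
    """Per-chromosome site arrays plus gap index for seeding."""

    def __init__(self, refmap: ReferenceMap):
        self.chroms: list[str] = []
        self.sites: dict[str, np.ndarray] = {}
        self.length: dict[str, float] = {}
        self.gaps: dict[str, np.ndarray] = {}
        self.gap_order: dict[str, np.ndarray] = {}
        self.gap_sorted: dict[str, np.ndarray] = {}
        for contig in refmap:
            R = np.asarray(contig.sites, dtype=np.float64)
            if len(R) < 3:
                continue
            G = np.diff(R)
            order = np.argsort(G).astype(np.int64)
            self.chroms.append(contig.name)
            self.sites[contig.name] = R
            self.length[contig.name] = contig.length
            self.gaps[contig.name] = G
            self.gap_order[contig.name] = order
            self.gap_sorted[contig.name] = G[order]


def _candidate_windows(P, L, ref: _RefIndex, params: AlignerParams, tol_rel: float):
    """Seed both gap vectors against every chromosome; cluster anchors by
    implied molecule start (diagonal) and return the top windows."""
    g = np.diff(P)
    if len(g) < params.seed_width:
        return []
    votes: dict[tuple[str, int], tuple[int, float]] = {}
    buf_i = np.empty(8192, np.int64)
    buf_j = np.empty(8192, np.int64)
    for chrom in ref.chroms:
        n_hit = _seed_kernel(g, ref.gap_sorted[chrom], ref.gap_order[chrom],
                             ref.gaps[chrom], tol_rel, params.seed_abs_tolerance,
                             buf_i, buf_j)
        if n_hit == 0:
            continue
        R = ref.sites[chrom]
        diag = R[buf_j[:n_hit]] - P[buf_i[:n_hit]]
        keys = np.rint(diag / 30000.0).astype(np.int64)
        for k, d in zip(keys, diag):
            cnt, _ = votes.get((chrom, int(k)), (0, d))
            votes[(chrom, int(k))] = (cnt + 1, d)
    ranked = sorted(votes.items(), key=lambda kv: -kv[1][0])
    windows = []
    seen: set[tuple[str, int]] = set()
    for (chrom, k), (cnt, d) in ranked:
        if any((chrom, kk) in seen for kk in (k - 1, k, k + 1)):
            continue
        seen.add((chrom, k))
        pad = 0.12 * L + 20000.0
        R = ref.sites[chrom]
        b_lo = int(np.searchsorted(R, d - pad))
        b_hi = int(np.searchsorted(R, d + L + pad))
        if b_hi - b_lo >= 2:
            windows.append((chrom, b_lo, b_hi))
        if len(windows) >= params.max_candidates:
            break
    return windows


def _traceback(score, back_a, back_b):
    a, b = np.unravel_index(int(np.argmax(score)), score.shape)
    total = float(score[a, b])
    chain = []
    while a >= 0:
        chain.append((int(a), int(b)))
        a, b = int(back_a[a, b]), int(back_b[a, b])
    chain.reverse()
    return total, chain


def _align_one_orientation(P, L, ref, params, orientation_windows):
    best = None
    gamma2 = params.gamma_align**2
    c0 = math.log(0.25**2 + gamma2)
    for chrom, b_lo, b_hi in orientation_windows:
        R = ref.sites[chrom]
        Rw = R[b_lo:b_hi]
        score, back_a, back_b = _dp_kernel(
            P, Rw, params.max_skip, gamma2, c0,
            params.site_miss_penalty, params.site_extra_penalty,
            params.mismatch_floor, params.dev_floor_bp,
        )
        total, chain = _traceback(score, back_a, back_b)
        if best is None or total > best[0]:
            best = (total, chrom, b_lo, chain)
    return best


def align_molecule(mol: MoleculeMap, ref: _RefIndex,
                   params: AlignerParams) -> AlignmentRecord | None:
    """Align one molecule (both orientations); returns the best record or
    None when the molecule has too few labels or no adequate placement."""
    P_fwd = np.asarray(mol.labels, dtype=np.float64)
    n = len(P_fwd)
    if n < 2:
        return None
    L = mol.length
    P_rev = (L - P_fwd)[::-1].copy()
    best = None
    for tol in (params.sizing_tolerance, params.fallback_tolerance):
        for orientation, P in (("+", P_fwd), ("-", P_rev)):
            windows = _candidate_windows(P, L, ref, params, tol)
            if not windows:
                continue
            result = _align_one_orientation(P, L, ref, params, windows)
            if result is not None and (best is None or result[0] > best[0]):
                best = (*result, orientation, P)
        if best is not None and best[0] > 0:
            break  # tight-tolerance seeding succeeded; no fallback needed
    if best is None:
        return None
    total, chrom, b_lo, chain, orientation, P = best
    if len(chain) < params.min_aligned_sites or total <= 0:
        return None
    # cigar over the aligned span, pairs in reference order
    cigar_parts = []
    pairs = []
    prev = None
    for a, b in chain:
        if prev is not None:
            cigar_parts.append("D" * (b - prev[1] - 1))
            cigar_parts.append("I" * (a - prev[0] - 1))
        cigar_parts.append("M")
        orig_idx = a if orientation == "+" else n - 1 - a
        pairs.append((orig_idx, b_lo + b))
        prev = (a, b)
    R = ref.sites[chrom]
    a_first, b_first = chain[0]
    a_last, b_last = chain[-1]
    lead, trail = P[a_first], L - P[a_last]
    ref_start = max(0.0, R[b_lo + b_first] - lead)
    ref_end = min(ref.length[chrom], R[b_lo + b_last] + trail)
    return AlignmentRecord(
        molecule_id=mol.molecule_id,
        chromosome=chrom,
        ref_start=ref_start,
        ref_end=ref_end,
        orientation=orientation,
        pairs=pairs,
        cigar="".join(cigar_parts),
        confidence=max(0.0, total / LN10),
        source="builtin",
    )


def align_molecules(molecules: list[MoleculeMap], refmap: ReferenceMap,
                    params: AlignerParams | None = None) -> list[AlignmentRecord]:
    """Align every molecule to the reference map; at most one record each."""
    params = params or AlignerParams()
    ref = _RefIndex(refmap)
    if not ref.chroms:
        raise ValueError("reference map has no contigs with >= 3 sites")
    out = []
    for mol in molecules:
        rec = align_molecule(mol, ref, params)
        if rec is not None:
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Consensus integration of two aligners

def integrate_alignments(primary: list[AlignmentRecord],
                         secondary: list[AlignmentRecord],
                         strategy: str = "union") -> list[AlignmentRecord]:
    """Combine two aligners' outputs into a consensus set.

    Agreement means same chromosome and reference-interval midpoints within
    half the molecule's (aligned) length; on agreement the primary record is
    kept.  Under ``union``, a molecule aligned by only one aligner keeps that
    alignment and disagreement leaves it unaligned; under ``intersection``
    only agreeing molecules are kept.
    """
    if strategy not in ("union", "intersection"):
        raise ValueError(f"unknown strategy {strategy!r}")
    by_id_p = {r.molecule_id: r for r in primary}
    by_id_s = {r.molecule_id: r for r in secondary}
    out = []
    for mol_id in sorted(by_id_p.keys() | by_id_s.keys()):
        p, s = by_id_p.get(mol_id), by_id_s.get(mol_id)
        if p is not None and s is not None:
            length = max(p.ref_end - p.ref_start, s.ref_end - s.ref_start)
            mid_p = (p.ref_start + p.ref_end) / 2
            mid_s = (s.ref_start + s.ref_end) / 2
            agree = p.chromosome == s.chromosome and abs(mid_p - mid_s) < length / 2
            if agree:
                out.append(p)
            # disagreement: left unaligned under both strategies
        elif strategy == "union" and (p or s) is not None:
            out.append(p if p is not None else s)
    return out


def filter_by_confidence(alignments: list[AlignmentRecord],
                         min_confidence: float = 9.0) -> list[AlignmentRecord]:
    """Keep alignments with confidence >= threshold (boundary inclusive)."""
    return [r for r in alignments if r.confidence >= min_confidence]


# ---------------------------------------------------------------------------
# Two-round split alignment

def two_round_split_align(molecules: list[MoleculeMap], refmap: ReferenceMap,
                          first_round: list[AlignmentRecord],
                          params: AlignerParams | None = None) -> list[SplitAlignment]:
    """Re-align the unaligned ends of partially aligned molecules.

    A molecule qualifies when at least ``min_aligned_sites`` labels are left
    unaligned at either end of its first-round alignment; each unaligned
    range is aligned independently, anywhere in the genome and in either
    orientation, so all translocation types and large inversions become
    visible as multi-segment alignments.
    """
    params = params or AlignerParams()
    ref = _RefIndex(refmap)
    by_id = {r.molecule_id: r for r in first_round}
    splits = []
    for mol in molecules:
        rec = by_id.get(mol.molecule_id)
        if rec is None or not rec.pairs:
            continue
        idx = [i for i, _ in rec.pairs]
        lo, hi = min(idx), max(idx)
        n = mol.n_labels
        segments = [rec]
        for rng in ((0, lo) if lo >= params.min_aligned_sites else None,
                    (hi + 1, n) if n - 1 - hi >= params.min_aligned_sites else None):
            if rng is None:
                continue
            i0, i1 = rng
            if i1 - i0 < 2:
                continue
            sub_labels = np.asarray(mol.labels[i0:i1])
            offset = sub_labels[0] - 1000.0
            sub = MoleculeMap(mol.molecule_id,
                              float(sub_labels[-1] - offset + 1000.0),
                              [float(x - offset) for x in sub_labels])
            sub_rec = align_molecule(sub, ref, params)
            if sub_rec is None or sub_rec.confidence < params.min_confidence:
                continue  # short segments place spuriously without this gate
            sub_rec = AlignmentRecord(
                molecule_id=mol.molecule_id,
                chromosome=sub_rec.chromosome,
                ref_start=sub_rec.ref_start,
                ref_end=sub_rec.ref_end,
                orientation=sub_rec.orientation,
                pairs=[(i + i0, j) for i, j in sub_rec.pairs],
                cigar=sub_rec.cigar,
                confidence=sub_rec.confidence,
                source="builtin-split",
            )
            segments.append(sub_rec)
        segments.sort(key=lambda r: min(i for i, _ in r.pairs))
        splits.append(SplitAlignment(mol.molecule_id, segments))
    return splits
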