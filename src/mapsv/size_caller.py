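"""Calling large insertions and deletions from inter-site distance ratios.

For a pair of reference nicking sites at distance d0 spanned by M aligned
molecules with label distances d_1 <= ... <= d_M, the ratios r_i = d_i / d0
are modeled as Cauchy-distributed around the true allele ratio — the heavy
tails make the test robust to the occasional mis-aligned molecule.  Five
hypotheses are compared: no indel (all ratios around r0 = 1), a homozygous
indel (all around a shifted location, estimated by the sample median), a
heterozygous insertion or deletion (a mixture of the null and one shifted
component), and a triallelic locus (two shifted components).  The mixture
likelihoods marginalize over which molecules carry the variant; because the
components are well separated relative to the Cauchy scale, only the
contiguous rank-extreme assignments contribute materially, reducing the 2^M
subset sum to a sum over the split point k with at least k_min molecules per
allele.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .core import AlignmentRecord, ReferenceMap, SVCall


@dataclass
class SizeEvidence:
    """Label-distance observations at one pair of reference sites."""

    chromosome: str
    left_site: float
    right_site: float
    d0: float
    distances: np.ndarray  # sorted ascending
    r0: float = 1.0
    left_index: int = -1
    right_index: int = -1

    def __post_init__(self) -> None:
        if self.d0 <= 0:
            raise ValueError("reference distance d0 must be positive")
        self.distances = np.sort(np.asarray(self.distances, dtype=float))

    @property
    def M(self) -> int:
        return len(self.distances)

    @property
    def ratios(self) -> np.ndarray:
        return self.distances / self.d0


@dataclass
class SizeCallerParams:
    gamma: float | None = None  # Cauchy scale; None = estimate from the data
    k_min: int = 4              # minimum molecules per allele in het/tri sums
    het_min_fraction: float = 0.2  # adaptive floor: k_min >= this fraction of M
    delta: float = 2000.0       # bp, minimum absolute distance change
    lr_threshold: float = 1e-6
    M_min: int = 10
    gamma_fallback: float = 0.03

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.k_min < 0 or self.delta < 0:
            raise ValueError("k_min and delta must be non-negative")


def cauchy_density(r, location: float, gamma: float):
    """Cauchy pdf gamma / (pi [(r - location)^2 + gamma^2])."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    r = np.asarray(r, dtype=float)
    out = gamma / (np.pi * ((r - location) ** 2 + gamma**2))
    return float(out) if out.ndim == 0 else out


def log_cauchy(r, location: float, gamma: float):
    r = np.asarray(r, dtype=float)
    out = np.log(gamma / np.pi) - np.log((r - location) ** 2 + gamma**2)
    return float(out) if out.ndim == 0 else out


def estimate_gamma(evidences: list[SizeEvidence], fallback: float = 0.03) -> float:
    """Global Cauchy scale from the pooled ratios: IQR/2, which for a Cauchy
    equals the scale (quartiles sit at location +/- scale).  SV loci are a
    small minority, so the quartiles of the pool track the null component."""
    pool = np.concatenate([ev.ratios for ev in evidences]) if evidences else np.array([])
    if len(pool) < 20:
        return fallback
    q1, q3 = np.percentile(pool, [25, 75])
    est = float((q3 - q1) / 2.0)
    return est if est > 1e-4 else fallback


@dataclass
class SizeLikelihoods:
    """Per-hypothesis log-likelihoods plus the supporting-set bookkeeping
    needed for size estimation (which molecules back the winning term)."""

    log_h0: float
    log_hom: float
    log_het_ins: float
    log_het_del: float
    log_tri: float
    hom_location: float = 1.0
    het_ins_k: int = 0       # molecules carrying the insertion (top k ranks)
    het_del_k: int = 0       # molecules carrying the deletion (bottom k ranks)
    tri_k: int = 0           # split point of the dominant triallelic term
    tri_low_loc: float = 1.0
    tri_high_loc: float = 1.0


def size_likelihoods(evidence: SizeEvidence, params: SizeCallerParams,
                     gamma: float | None = None,
                     k_min: int | None = None) -> SizeLikelihoods:
    """Evaluate the five hypotheses on one evidence record (log space).

    Heterozygous-deletion terms whose low-component median is not below r0
    are dropped (the hypothesis expects a smaller location); the insertion
    side is mirrored.  With fewer than 2 k_min molecules the mixture
    hypotheses are undefined and excluded (-inf).
    """
    g = gamma if gamma is not None else (params.gamma or params.gamma_fallback)
    r = evidence.ratios  # sorted ascending
    M = len(r)
    r0 = evidence.r0
    if k_min is None:
        k_min = params.k_min

    null_lpdf = log_cauchy(r, r0, g)
    log_h0 = float(null_lpdf.sum())

    hom_loc = float(np.median(r))
    log_hom = float(log_cauchy(r, hom_loc, g).sum())

    log_het_ins = -np.inf
    log_het_del = -np.inf
    log_tri = -np.inf
    het_ins_k = het_del_k = tri_k = 0
    tri_low = tri_high = r0

    if M >= 2 * k_min and M >= 2:
        prefix_null = np.concatenate([[0.0], np.cumsum(null_lpdf)])  # sum of first i
        suffix_null = np.concatenate([[0.0], np.cumsum(null_lpdf[::-1])])[::-1]
        logM2 = M * np.log(2.0)

        ins_terms, ins_ks = [], []
        del_terms, del_ks = [], []
        tri_terms, tri_ks, tri_locs = [], [], []
        for k in range(k_min, M - k_min + 1):
            # insertion: top k ranks shifted up
            mu_hi = float(np.median(r[M - k :]))
            if mu_hi > r0:
                t = prefix_null[M - k] + float(log_cauchy(r[M - k :], mu_hi, g).sum()) - logM2
                ins_terms.append(t)
                ins_ks.append(k)
            # deletion: bottom k ranks shifted down
            mu_lo = float(np.median(r[:k]))
            if mu_lo < r0:
                t = float(log_cauchy(r[:k], mu_lo, g).sum()) + suffix_null[k] - logM2
                del_terms.append(t)
                del_ks.append(k)
            # triallelic: both parts shifted
            mu1 = float(np.median(r[:k]))
            mu2 = float(np.median(r[k:]))
            t = (float(log_cauchy(r[:k], mu1, g).sum())
                 + float(log_cauchy(r[k:], mu2, g).sum()) - logM2)
            tri_terms.append(t)
            tri_ks.append(k)
            tri_locs.append((mu1, mu2))
        if ins_terms:
            log_het_ins = float(logsumexp(ins_terms))
            het_ins_k = ins_ks[int(np.argmax(ins_terms))]
        if del_terms:
            log_het_del = float(logsumexp(del_terms))
            het_del_k = del_ks[int(np.argmax(del_terms))]
        if tri_terms:
            log_tri = float(logsumexp(tri_terms))
            i_best = int(np.argmax(tri_terms))
            tri_k = tri_ks[i_best]
            tri_low, tri_high = tri_locs[i_best]

    return SizeLikelihoods(log_h0, log_hom, log_het_ins, log_het_del, log_tri,
                           hom_location=hom_loc, het_ins_k=het_ins_k,
                           het_del_k=het_del_k, tri_k=tri_k,
                           tri_low_loc=tri_low, tri_high_loc=tri_high)


def call_size_sv(evidence: SizeEvidence, params: SizeCallerParams,
                 gamma: float | None = None,
                 decoy_sites: np.ndarray | None = None) -> list[SVCall]:
    """Decide the locus: [] (no call), one indel call, or two for triallelic.

    The winning hypothesis must beat the null by the likelihood-ratio
    threshold; the distance change of the supporting molecules (median of
    the set backing the dominant likelihood term, minus d0) must exceed
    delta.  Ties among hypothesis maxima break toward the simpler model in
    the order hom > het_ins > het_del > tri.

    ``decoy_sites`` are reference positions of novel-label clusters (sites
    present on the sample but absent from the reference, e.g. created by an
    insertion).  A molecule whose distance places one of its end labels at
    such a cluster matched the novel label instead of the reference site; it
    is removed from the evidence before the hypotheses are compared.
    """
    if decoy_sites is not None and len(decoy_sites):
        d = evidence.distances
        p1 = evidence.left_site + d
        p2 = evidence.right_site - d
        bad = (np.min(np.abs(p1[:, None] - decoy_sites[None, :]), axis=1) < 4000.0) | (
            np.min(np.abs(p2[:, None] - decoy_sites[None, :]), axis=1) < 4000.0)
        if bad.any():
            evidence = SizeEvidence(
                evidence.chromosome, evidence.left_site, evidence.right_site,
                evidence.d0, d[~bad], evidence.r0,
                evidence.left_index, evidence.right_index)
    if evidence.M < params.M_min:
        return []
    g = gamma if gamma is not None else (params.gamma or params.gamma_fallback)
    # coverage-adaptive per-allele support floor: a real allele carries about
    # half the molecules, while small coherent clusters of mis-registered
    # alignments scale with coverage and must not masquerade as an allele
    k_eff = max(params.k_min, int(np.ceil(params.het_min_fraction * evidence.M)))
    lik = size_likelihoods(evidence, params, g, k_min=k_eff)
    alternatives = [
        ("hom", lik.log_hom),
        ("het_ins", lik.log_het_ins),
        ("het_del", lik.log_het_del),
        ("tri", lik.log_tri),
    ]
    best_name, log_best = max(alternatives, key=lambda t: t[1])
    # explicit simplest-model tie-break in declared order
    for name, val in alternatives:
        if val == log_best:
            best_name = name
            break
    if not np.isfinite(log_best):
        return []
    lr = float(np.exp(min(lik.log_h0 - log_best, 700.0)))
    if not lr < params.lr_threshold:
        return []

    d = evidence.distances  # sorted, same order as ratios
    d0 = evidence.d0
    M = evidence.M

    def coherent(support_d: np.ndarray) -> bool:
        # a genuine variant allele concentrates like a Cauchy component of
        # scale gamma; incoherent rank-extreme clusters (correlated alignment
        # artifacts) do not
        rr = support_d / d0
        med = float(np.median(rr))
        return float(np.mean(np.abs(rr - med) <= 3.0 * g)) >= 0.5

    def make_call(zygosity: str, support_d: np.ndarray, support: int,
                  multi: bool = False) -> SVCall | None:
        # size from the coherent core of the supporting set: molecules more
        # than 3 gamma from the component median are residual alignment
        # outliers and would bias the median
        med0 = float(np.median(support_d))
        core = support_d[np.abs(support_d - med0) <= 3.0 * g * d0]
        if len(core) >= 3:
            support_d = core
        change = float(np.median(support_d)) - d0 * evidence.r0
        if abs(change) <= params.delta:
            return None
        if zygosity == "het" and not coherent(support_d):
            return None
        return SVCall(
            chromosome=evidence.chromosome,
            start=evidence.left_site,
            end=evidence.right_site,
            sv_type="insertion" if change > 0 else "deletion",
            zygosity=zygosity,
            size=change,
            support=support,
            coverage=M,
            p_value=np.nan,
            likelihood_ratio=lr,
            module="size",
            info={"multi_allele": multi} if multi else {},
        )

    calls: list[SVCall] = []
    if best_name == "hom":
        calls.append(make_call("hom", d, M))
    elif best_name == "het_ins":
        k = lik.het_ins_k
        calls.append(make_call("het", d[M - k :], k))
    elif best_name == "het_del":
        k = lik.het_del_k
        calls.append(make_call("het", d[:k], k))
    else:  # triallelic: one call per variant allele
        k = lik.tri_k
        calls.append(make_call("het", d[:k], k, multi=True))
        calls.append(make_call("het", d[k:], M - k, multi=True))
    return [c for c in calls if c is not None]


# ---------------------------------------------------------------------------
# Evidence extraction from alignments

def enumerate_check_pairs(
    alignments: list[AlignmentRecord],
    molecules,
    refmap: ReferenceMap,
    max_span_sites: int = 12,
    end_trim: int = 3,
) -> list[SizeEvidence]:
    """Build one SizeEvidence per reference site pair worth testing.

    Pairs tested are (a) every adjacent reference site pair with at least one
    spanning molecule and (b) every span between consecutive matched labels
    of some molecule (these cover indels that delete sites or insert new
    ones).  For each tested pair, every molecule with labels aligned to both
    sites contributes its label distance, so both alleles of a heterozygous
    locus are represented.  Each (left, right) pair is tested once.

    The first and last ``end_trim`` matched pairs of every alignment are
    excluded: near a chain end there is too little flanking context to
    resolve register ambiguities, and such matches carry correlated sizing
    errors.
    """
    mol_by_id = {m.molecule_id: m for m in molecules}
    # per chromosome: map site-index pair -> list of molecule distances
    by_pair: dict[tuple[str, int, int], list[float]] = {}
    matched_at: dict[str, dict[int, list[tuple[int, float]]]] = {}
    # first pass: record matched labels per site, and candidate pairs
    candidate_pairs: set[tuple[str, int, int]] = set()
    for rec in alignments:
        mol = mol_by_id.get(rec.molecule_id)
        if mol is None or len(rec.pairs) < 2:
            continue
        chrom = rec.chromosome
        site_map = matched_at.setdefault(chrom, {})
        labels = mol.labels
        kept = rec.pairs[end_trim : len(rec.pairs) - end_trim]
        for i, j in kept:
            site_map.setdefault(j, []).append((rec.molecule_id, labels[i]))
        for (i1, j1), (i2, j2) in zip(kept, kept[1:]):
            if j2 > j1:
                candidate_pairs.add((chrom, j1, j2))
    # adjacent reference pairs inside any matched span
    for chrom, site_map in matched_at.items():
        sites_idx = sorted(site_map)
        for j1, j2 in zip(sites_idx, sites_idx[1:]):
            if j2 == j1 + 1:
                candidate_pairs.add((chrom, j1, j2))
    # second pass: gather distances from every molecule matched at both sites
    for chrom, j1, j2 in candidate_pairs:
        if j2 - j1 > max_span_sites:
            continue
        site_map = matched_at[chrom]
        left = {mid: pos for mid, pos in site_map.get(j1, [])}
        right = {mid: pos for mid, pos in site_map.get(j2, [])}
        dists = [abs(right[mid] - left[mid]) for mid in left.keys() & right.keys()]
        if dists:
            by_pair[(chrom, j1, j2)] = dists
    evidences = []
    for (chrom, j1, j2), dists in sorted(by_pair.items()):
        sites = refmap[chrom].sites
        d0 = sites[j2] - sites[j1]
        if d0 <= 0:
            continue
        evidences.append(
            SizeEvidence(chrom, sites[j1], sites[j2], d0, np.asarray(dists),
                         left_index=j1, right_index=j2)
        )
    return evidences


def call_sizes(
    alignments: list[AlignmentRecord],
    molecules,
    refmap: ReferenceMap,
    params: SizeCallerParams | None = None,
) -> list[SVCall]:
    """Run the full large-size-change module over consensus alignments."""
    from .site_caller import collect_site_evidence

    params = params or SizeCallerParams()
    evidences = enumerate_check_pairs(alignments, molecules, refmap)
    gamma = params.gamma or estimate_gamma(evidences, params.gamma_fallback)
    _, extra_ev = collect_site_evidence(alignments, molecules, refmap)
    # novel-site decoys: clusters of unmatched labels supported by a solid
    # fraction of the covering molecules (random false-positive labels only
    # form small clusters, with support independent of coverage)
    decoy_lists: dict[str, list[float]] = {}
    for ev in extra_ev:
        if ev.m >= 8 and ev.m >= 0.3 * max(ev.M, 1):
            decoy_lists.setdefault(ev.chromosome, []).append(ev.position)
    decoys = {c: np.asarray(p) for c, p in decoy_lists.items()}
    calls: list[SVCall] = []
    for ev in evidences:
        calls.extend(call_size_sv(ev, params, gamma,
                                  decoy_sites=decoys.get(ev.chromosome)))
    return calls
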