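"""Calling missing and extra nicking sites from per-site molecule support.

At a reference site covered by M aligned molecules of which m carry a label,
three hypotheses are compared: the site exists on both chromosomes (null; the
m labels are true positives and the M-m misses are false negatives at rate
fn), the site is absent from both (the m labels are false positives at rate
fp), or the site is absent from one chromosome (each molecule comes from
either chromosome with probability 1/2).  A site is called when both the
binomial tail p-value and the null-to-best-alternative likelihood ratio fall
below their thresholds; the likelihood comparison decides the zygosity.
Extra sites (labels present where the reference has no site) use the same
likelihoods with the null and homozygous-alternative roles swapped and an
upper-tail p-value.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .core import AlignmentRecord, ReferenceMap, SVCall


@dataclass
class SiteEvidence:
    chromosome: str
    position: float
    M: int  # molecules aligned over the locus
    m: int  # molecules supporting the site's presence

    def __post_init__(self) -> None:
        if not 0 <= self.m <= self.M:
            raise ValueError("need 0 <= m <= M")


@dataclass
class SiteCallerParams:
    fn: float = 0.12
    fp: float = 0.018        # per-site-opportunity probability, see fp_from_rate
    p_threshold: float = 1e-3
    lr_threshold: float = 1e-6
    M_min: int = 10

    def __post_init__(self) -> None:
        for name in ("fn", "fp"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        if self.M_min < 1:
            raise ValueError("M_min must be >= 1")


def fp_from_rate(f_plus: float, window: float = 1500.0) -> float:
    """Convert the per-bp false-positive label rate into a per-site-opportunity
    probability over a label-matching window (default the resolution d_half):
    the chance of >=1 Poisson false positive in the window."""
    return 1.0 - float(np.exp(-f_plus * window))


# ---------------------------------------------------------------------------
# p-values and likelihoods

def pvalue_missing(M: int, m: int, fn: float) -> float:
    """P(x <= m) for x ~ Binomial(M, 1-fn): chance of seeing this little
    support if the site were present on both chromosomes."""
    if not 0.0 < fn < 1.0:
        raise ValueError("fn must be in (0, 1)")
    return float(binom.cdf(m, M, 1.0 - fn))


def pvalue_extra(M: int, m: int, fp: float) -> float:
    """P(x >= m) for x ~ Binomial(M, fp): chance of seeing this much support
    if the site did not exist at all."""
    if not 0.0 < fp < 1.0:
        raise ValueError("fp must be in (0, 1)")
    return float(binom.sf(m - 1, M, fp))


def _log_binom(n: int, k: int) -> float:
    return float(gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1))


def log_likelihoods_missing(M: int, m: int, fn: float, fp: float) -> tuple[float, float, float]:
    """Log of (L_H0, L_hom, L_het) for the missing-site test.

    L_het marginalizes over k, the unknown number of molecules drawn from the
    chromosome that still carries the site, and l, how many of those k show a
    label: each molecule comes from either chromosome with probability 1/2.
    """
    log_l0 = float(binom.logpmf(m, M, 1.0 - fn))
    log_lhom = float(binom.logpmf(m, M, fp))
    terms = []
    lfn, l1fn = np.log(fn), np.log1p(-fn)
    lfp, l1fp = np.log(fp), np.log1p(-fp)
    for k in range(M + 1):
        base = _log_binom(M, k) - M * np.log(2.0)
        for l in range(max(0, m - M + k), min(k, m) + 1):
            terms.append(
                base
                + _log_binom(k, l) + l * l1fn + (k - l) * lfn
                + _log_binom(M - k, m - l) + (m - l) * lfp + (M - k - m + l) * l1fp
            )
    log_lhet = float(logsumexp(terms)) if terms else -np.inf
    return log_l0, log_lhom, log_lhet


def likelihoods_missing(M: int, m: int, fn: float, fp: float) -> tuple[float, float, float]:
    return tuple(float(np.exp(x)) for x in log_likelihoods_missing(M, m, fn, fp))


def log_likelihoods_extra(M: int, m: int, fn: float, fp: float) -> tuple[float, float, float]:
    """Extra-site log likelihoods, by symmetry with the missing-site case:
    L_H0(extra) = L_hom(miss), L_hom(extra) = L_H0(miss), L_het equal."""
    log_l0_miss, log_lhom_miss, log_lhet = log_likelihoods_missing(M, m, fn, fp)
    return log_lhom_miss, log_l0_miss, log_lhet


# ---------------------------------------------------------------------------
# Decisions

def _decide(log_l0: float, log_lhom: float, log_lhet: float,
            p: float, params: SiteCallerParams) -> tuple[bool, str, float]:
    log_best_alt = max(log_lhom, log_lhet)
    log_lr = log_l0 - log_best_alt
    lr = float(np.exp(log_lr))
    if p < params.p_threshold and lr < params.lr_threshold:
        zygosity = "hom" if log_lhom >= log_lhet else "het"
        return True, zygosity, lr
    return False, "", lr


def call_missing_site(evidence: SiteEvidence, params: SiteCallerParams) -> SVCall | None:
    if evidence.M < params.M_min:
        return None
    p = pvalue_missing(evidence.M, evidence.m, params.fn)
    log_l0, log_lhom, log_lhet = log_likelihoods_missing(
        evidence.M, evidence.m, params.fn, params.fp)
    called, zygosity, lr = _decide(log_l0, log_lhom, log_lhet, p, params)
    if not called:
        return None
    return SVCall(
        chromosome=evidence.chromosome,
        start=evidence.position,
        end=evidence.position + 1.0,
        sv_type="missing_site",
        zygosity=zygosity,
        size=0.0,
        support=evidence.M - evidence.m,
        coverage=evidence.M,
        p_value=p,
        likelihood_ratio=lr,
        module="site",
    )


def call_extra_site(evidence: SiteEvidence, params: SiteCallerParams) -> SVCall | None:
    if evidence.M < params.M_min:
        return None
    p = pvalue_extra(evidence.M, evidence.m, params.fp)
    log_l0, log_lhom, log_lhet = log_likelihoods_extra(
        evidence.M, evidence.m, params.fn, params.fp)
    called, zygosity, lr = _decide(log_l0, log_lhom, log_lhet, p, params)
    if not called:
        return None
    return SVCall(
        chromosome=evidence.chromosome,
        start=evidence.position,
        end=evidence.position + 1.0,
        sv_type="extra_site",
        zygosity=zygosity,
        size=0.0,
        support=evidence.m,
        coverage=evidence.M,
        p_value=p,
        likelihood_ratio=lr,
        module="site",
    )


# ---------------------------------------------------------------------------
# Evidence extraction from alignments

def collect_site_evidence(
    alignments: list[AlignmentRecord],
    molecules,
    refmap: ReferenceMap,
    cluster_window: float = 1500.0,
) -> tuple[list[SiteEvidence], list[SiteEvidence]]:
    """Tabulate (missing-site, extra-site) evidence from consensus alignments.

    For missing sites, a molecule covers a reference site when the site index
    lies strictly inside its matched span (the span endpoints are matched by
    construction and would bias support), and supports it when the alignment
    pairs a label with it.  For extra sites, unmatched molecule labels are
    projected onto the reference by interpolation between flanking matched
    pairs and clustered across molecules within ``cluster_window``; each
    cluster is one candidate site.
    """
    mol_by_id = {m.molecule_id: m for m in molecules}
    missing: list[SiteEvidence] = []
    extra: list[SiteEvidence] = []
    for contig in refmap:
        n_sites = len(contig.sites)
        cover = np.zeros(n_sites, dtype=np.int64)
        support = np.zeros(n_sites, dtype=np.int64)
        spans: list[tuple[int, int]] = []
        fp_positions: list[float] = []
        for rec in alignments:
            if rec.chromosome != contig.name or not rec.pairs:
                continue
            ref_idx = [j for _, j in rec.pairs]
            j_first, j_last = ref_idx[0], ref_idx[-1]
            spans.append((j_first, j_last))
            if j_last > j_first + 1:
                cover[j_first + 1 : j_last] += 1
            for j in ref_idx[1:-1]:
                support[j] += 1
            # project unmatched labels (I ops) for extra-site candidates
            mol = mol_by_id.get(rec.molecule_id)
            if mol is None:
                continue
            labels = mol.labels
            pos_of = dict(rec.pairs)
            matched_lab = sorted(pos_of)
            for (i1, j1), (i2, j2) in zip(rec.pairs, rec.pairs[1:]):
                lo, hi = sorted((i1, i2))
                for i in range(lo + 1, hi):
                    dm = labels[i2] - labels[i1]
                    if dm == 0:
                        continue
                    frac = (labels[i] - labels[i1]) / dm
                    ref_pos = contig.sites[j1] + frac * (contig.sites[j2] - contig.sites[j1])
                    fp_positions.append(ref_pos)
        for j in range(n_sites):
            if cover[j] > 0:
                missing.append(SiteEvidence(contig.name, contig.sites[j],
                                            int(cover[j]), int(support[j])))
        # cluster projected label positions
        if fp_positions:
            fp_positions.sort()
            site_arr = np.asarray(contig.sites)
            span_arr = np.asarray(spans) if spans else np.zeros((0, 2), dtype=int)
            cluster: list[float] = [fp_positions[0]]
            clusters: list[list[float]] = [cluster]
            for p in fp_positions[1:]:
                if p - cluster[-1] <= cluster_window:
                    cluster.append(p)
                else:
                    cluster = [p]
                    clusters.append(cluster)
            for cl in clusters:
                center = float(np.median(cl))
                # skip candidates sitting on an existing reference site
                j_near = int(np.clip(np.searchsorted(site_arr, center), 1, n_sites - 1))
                near = min(abs(site_arr[j_near - 1] - center),
                           abs(site_arr[min(j_near, n_sites - 1)] - center)) if n_sites else np.inf
                if near < cluster_window / 2:
                    continue
                j_ins = int(np.searchsorted(site_arr, center))
                M = int(np.sum((span_arr[:, 0] < j_ins - 1 + 1) & (span_arr[:, 1] >= j_ins)))
                M = max(M, len(cl))
                extra.append(SiteEvidence(contig.name, center, M, len(cl)))
    return missing, extra


def call_sites(
    alignments: list[AlignmentRecord],
    molecules,
    refmap: ReferenceMap,
    params: SiteCallerParams | None = None,
) -> list[SVCall]:
    """Run the full missing/extra site module over consensus alignments."""
    params = params or SiteCallerParams()
    missing_ev, extra_ev = collect_site_evidence(alignments, molecules, refmap)
    calls: list[SVCall] = []
    for ev in missing_ev:
        call = call_missing_site(ev, params)
        if call is not None:
            calls.append(call)
    for ev in extra_ev:
        call = call_extra_site(ev, params)
        if call is not None:
            calls.append(call)
    return calls
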