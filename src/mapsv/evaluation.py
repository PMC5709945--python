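"""Scoring SV calls against simulation truth, alignment metrics, trio
integration, and Mendelian concordance (observed and expected).

A call is correct when it overlaps (>= 1 bp) a truth variant of the same
type; zygosity equality can additionally be required.  Call types map onto
truth kinds so that site-module deletions and size-module deletions score
against the same "deletion" truth.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from .core import AlignmentRecord, MoleculeMap, SVCall
from .simulator import TruthVariant

#: call type -> truth kind used for matching
TYPE_MAP = {
    "insertion": "insertion",
    "extra_site": "insertion",
    "deletion": "deletion",
    "missing_site": "deletion",
    "inversion_medium": "inversion",
    "inversion_large": "inversion",
    "translocation_intra": "translocation",
    "translocation_inter": "translocation",
    "cnv_gain": "cnv",
    "cnv_loss": "cnv",
}


def _truth_intervals(v: TruthVariant, slack: float = 0.0):
    """Reference intervals where a call may legitimately land for ``v``.
    Pure insertions are points (widened to 1 bp); translocations are
    detectable at the excised span and at the paste site."""
    start, end = v.start - slack, max(v.end, v.start + 1.0) + slack
    ivals = [(v.chromosome, start, end)]
    if v.kind == "translocation" and v.target >= 0:
        ivals.append((v.chromosome, v.target - 1.0 - slack, v.target + 1.0 + slack))
    return ivals


def _matches(call: SVCall, v: TruthVariant, match_type: bool,
             match_zygosity: bool, slack: float = 0.0) -> bool:
    if match_type and TYPE_MAP.get(call.sv_type) != v.kind:
        return False
    if match_zygosity and call.zygosity != v.zygosity:
        return False
    call_ivals = [(call.chromosome, call.start, call.end)]
    if "mate_position" in call.info:  # junction-type calls have two breakpoints
        mp = call.info["mate_position"]
        call_ivals.append((call.info.get("mate_chromosome", call.chromosome),
                           mp - 2000.0, mp + 2000.0))
    truth_ivals = _truth_intervals(v, slack)
    return any(cc == c and cs < e and s < ce
               for cc, cs, ce in call_ivals for c, s, e in truth_ivals)


def precision_recall(
    calls: list[SVCall],
    truth: list[TruthVariant],
    match_type: bool = True,
    match_zygosity: bool = False,
    slack: float = 0.0,
) -> tuple[float, float]:
    """(precision, recall) of ``calls`` against ``truth``.

    Precision is undefined (raises) with zero calls, recall with zero truth
    variants.  ``slack`` widens truth intervals, for junction-type calls
    whose breakpoint estimate has map-resolution uncertainty.
    """
    if not calls:
        raise ValueError("precision undefined: no calls")
    if not truth:
        raise ValueError("recall undefined: empty truth set")
    tp_calls = sum(
        any(_matches(c, v, match_type, match_zygosity, slack) for v in truth)
        for c in calls
    )
    found = sum(
        any(_matches(c, v, match_type, match_zygosity, slack) for c in calls)
        for v in truth
    )
    return tp_calls / len(calls), found / len(truth)


def size_ratio_stats(calls: list[SVCall], truth: list[TruthVariant]) -> dict:
    """Estimated-to-true size ratios over correctly identified indels.

    The true size is the indel's size as measurable between its defining
    nicking sites (for variants placed between sites this is the full size).
    Returns per-call ratios and their median.
    """
    ratios = []
    for call in calls:
        if call.sv_type not in ("insertion", "deletion") or call.size == 0:
            continue
        for v in truth:
            if v.kind in ("insertion", "deletion") and _matches(call, v, True, False):
                ratios.append(abs(call.size) / v.size)
                break
    return {"ratios": ratios, "median": float(np.median(ratios)) if ratios else np.nan}


# ---------------------------------------------------------------------------
# Alignment metrics

def hap_to_ref_offset(truth: list[TruthVariant], hap: int):
    """Piecewise-constant shift mapping haplotype coordinates to reference
    coordinates, accounting for the cumulative length change of indels on
    that haplotype (inversions and balanced events shift nothing beyond
    their span)."""
    events = []  # (hap position from which the new shift applies, shift)
    shift = 0.0
    for v in sorted(truth, key=lambda v: v.start):
        if hap not in v.haplotypes:
            continue
        if v.kind in ("insertion", "small_indel", "deletion"):
            deletion_like = v.end > v.start and not v.alt_seq
            if deletion_like:
                hap_pos = v.start + shift
                shift -= v.end - v.start
            else:
                hap_pos = v.start + shift + v.size
                shift += v.size
            events.append((hap_pos, shift))
        elif v.kind == "cnv":
            extra = (v.end - v.start) * (v.copies - 1)
            hap_pos = v.end + shift + extra
            shift += extra
            events.append((hap_pos, shift))
    xs = np.array([e[0] for e in events])
    ss = np.array([e[1] for e in events])

    def lift(pos: float) -> float:
        i = int(np.searchsorted(xs, pos, side="right")) - 1
        return pos - (ss[i] if i >= 0 else 0.0)

    return lift


def alignment_metrics(
    alignments: list[AlignmentRecord],
    molecules: list[MoleculeMap],
    truth: list[TruthVariant] | None = None,
) -> tuple[float, float]:
    """(precision, recall) of the alignment step against molecule truth.

    A molecule is correctly aligned when placed on its source chromosome
    with the aligned reference interval overlapping the source interval
    (haplotype coordinates lifted to the reference through the truth list).
    Recall counts all generated molecules in the denominator.
    """
    mol_by_id = {m.molecule_id: m for m in molecules}
    lifts: dict[int, object] = {}
    n_correct = 0
    for rec in alignments:
        mol = mol_by_id.get(rec.molecule_id)
        if mol is None or mol.truth is None:
            raise ValueError(f"molecule {rec.molecule_id} lacks simulation truth")
        t = mol.truth
        if truth is not None:
            if t.haplotype not in lifts:
                lifts[t.haplotype] = hap_to_ref_offset(truth, t.haplotype)
            lift = lifts[t.haplotype]
            start, end = lift(t.start), lift(t.end)
        else:
            start, end = t.start, t.end
        if rec.chromosome == t.chromosome and rec.ref_start < end and start < rec.ref_end:
            n_correct += 1
    precision = n_correct / len(alignments) if alignments else np.nan
    recall = n_correct / len(molecules) if molecules else np.nan
    return precision, recall


# ---------------------------------------------------------------------------
# Trio integration

@dataclass
class TrioLocus:
    chromosome: str
    start: float
    end: float
    kind: str
    present: tuple[bool, bool, bool]  # father, mother, daughter


def integrate_trio_indels(call_sets: list[list[SVCall]]) -> list[TrioLocus]:
    """Merge per-individual indels into trio loci by transitive overlap.

    Overlapping same-type indels across individuals merge into one locus
    spanning their union hull; a merged locus is present for an individual
    if that individual had any overlapping original indel.
    """
    assert len(call_sets) == 3
    items = []
    for who, calls in enumerate(call_sets):
        for c in calls:
            if TYPE_MAP.get(c.sv_type) in ("insertion", "deletion"):
                items.append((c.chromosome, TYPE_MAP[c.sv_type],
                              c.start, max(c.end, c.start + 1.0), who))
    loci: list[TrioLocus] = []
    items.sort()
    current = None
    for chrom, kind, start, end, who in items:
        if (current is not None and current.chromosome == chrom
                and current.kind == kind and start <= current.end):
            present = list(current.present)
            present[who] = True
            current = TrioLocus(chrom, current.start, max(current.end, end),
                                kind, tuple(present))
            loci[-1] = current
        else:
            present = [False, False, False]
            present[who] = True
            current = TrioLocus(chrom, start, end, kind, tuple(present))
            loci.append(current)
    return loci


# ---------------------------------------------------------------------------
# Mendelian concordance

GENOTYPES = ("AA", "Aa", "aa")


def _alleles(g: str) -> tuple[str, str]:
    return (g[0], g[1])


def is_mendelian(father: str, mother: str, daughter: str) -> bool:
    """Whether the daughter's genotype can arise from the parents' by
    transmitting one allele from each."""
    d = sorted(_alleles(daughter))
    for fa, mo in product(_alleles(father), _alleles(mother)):
        if sorted((fa, mo)) == d:
            return True
    return False


def mendelian_concordant_set() -> list[tuple[str, str, str]]:
    """The set O of trio genotype combinations concordant with Mendelian
    inheritance (enumerated; contains exactly 15 members)."""
    out = [c for c in product(GENOTYPES, repeat=3) if is_mendelian(*c)]
    assert len(out) == 15
    return out


def observed_mendelian_concordance(
    trio_genotypes: list[tuple[str, str, str]],
    consider_zygosity: bool = True,
) -> float:
    """Fraction of loci whose trio genotypes are Mendelian-concordant.

    Without zygosity, an error is reported only when the daughter carries an
    SV at a locus where neither parent does (called genotypes cannot
    distinguish hom from het reliably enough for the stricter test).
    """
    if not trio_genotypes:
        raise ValueError("no evaluable loci")
    n_ok = 0
    for fa, mo, da in trio_genotypes:
        if consider_zygosity:
            n_ok += is_mendelian(fa, mo, da)
        else:
            n_ok += not (da != "AA" and fa == "AA" and mo == "AA")
    return n_ok / len(trio_genotypes)


@dataclass
class GenotypeConfusion:
    """P(called G2 | actual G1) over genotypes (AA, Aa, aa); rows sum to 1."""

    matrix: np.ndarray  # 3x3, rows actual, columns called

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("confusion must be 3x3")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("confusion rows must sum to 1")

    def p(self, called: str, actual: str) -> float:
        return float(self.matrix[GENOTYPES.index(actual), GENOTYPES.index(called)])


def confusion_from_rates(p_call_given_het: dict, p_call_given_hom: dict,
                         p_het_prior: float = 4e-3) -> GenotypeConfusion:
    """Build the full 3x3 confusion from the directly estimable rows.

    The rows for actual Aa and aa come from simulation-derived call rates;
    the false-call entries of the AA row are closed through Bayes with the
    prior heterozygous/homozygous SV probability (half of the ~8e-3 prior SV
    probability each) and P(AA|AA) = 1 - P(Aa|AA) - P(aa|AA).
    """
    p_aa_row = [p_call_given_hom.get(g, 0.0) for g in GENOTYPES]
    p_het_row = [p_call_given_het.get(g, 0.0) for g in GENOTYPES]
    p_Aa_AA = p_het_row[0] * p_het_prior
    p_aa_AA = p_aa_row[0] * p_het_prior
    row_AA = [1.0 - p_Aa_AA - p_aa_AA, p_Aa_AA, p_aa_AA]
    m = np.array([row_AA, p_het_row, p_aa_row])
    m = m / m.sum(axis=1, keepdims=True)
    return GenotypeConfusion(m)


def estimate_confusion(calls: list[SVCall], truth: list[TruthVariant],
                       p_het_prior: float = 4e-3) -> GenotypeConfusion:
    """Estimate the genotype confusion from a diploid simulation run."""
    counts = {"Aa": {g: 0 for g in GENOTYPES}, "aa": {g: 0 for g in GENOTYPES}}
    for v in truth:
        if v.kind not in ("insertion", "deletion"):
            continue
        actual = "aa" if v.zygosity == "hom" else "Aa"
        called = "AA"
        for c in calls:
            if _matches(c, v, True, False):
                called = "aa" if c.zygosity == "hom" else "Aa"
                break
        counts[actual][called] += 1
    def norm(d):
        tot = sum(d.values())
        return {g: (d[g] / tot if tot else (1.0 if g == "AA" else 0.0)) for g in GENOTYPES}
    return confusion_from_rates(norm(counts["Aa"]), norm(counts["aa"]), p_het_prior)


def expected_mendelian_concordance(
    confusion: GenotypeConfusion,
    priors: dict[tuple[str, str, str], float] | None = None,
    consider_zygosity: bool = True,
) -> float:
    """Expected trio concordance implied by per-individual genotype errors.

    The probability of calling combination C2 from actual C1 is the product
    of three conditional probabilities (independent calling errors).  With
    zygosity: sum over actual C1 in O of P(C1) times the mass of called
    combinations inside O.  Without: one minus the probability of calling
    an SV in the daughter with both parents called reference.
    """
    O = mendelian_concordant_set()
    if priors is None:
        priors = {c: 1.0 / len(O) for c in O}
    tot = sum(priors.values())
    if not np.isclose(tot, 1.0, atol=1e-6):
        raise ValueError("priors over O must sum to 1")

    def p_c2_given_c1(c2, c1):
        return (confusion.p(c2[0], c1[0]) * confusion.p(c2[1], c1[1])
                * confusion.p(c2[2], c1[2]))

    if consider_zygosity:
        rate = 0.0
        for c1 in O:
            inner = sum(p_c2_given_c1(c2, c1) for c2 in O)
            rate += priors.get(c1, 0.0) * inner
        return rate
    bad = 0.0
    for c1 in O:
        p_err = sum(p_c2_given_c1(("AA", "AA", d), c1) for d in ("Aa", "aa"))
        bad += priors.get(c1, 0.0) * p_err
    return 1.0 - bad
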